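# silver: photon mass interaction coefficients [cm^2/g]
# density 10.49 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 3.77536e+06 3.77508e+06 3.77508e+06 1.73878e-01 2.81085e+02 0.00000e+00
1.10526e-03 2.74080e+06 2.74057e+06 2.74057e+06 1.73807e-01 2.30096e+02 0.00000e+00
1.22160e-03 1.98974e+06 1.98956e+06 1.98956e+06 1.73728e-01 1.88357e+02 0.00000e+00
1.35018e-03 1.44450e+06 1.44435e+06 1.44435e+06 1.73641e-01 1.54189e+02 0.00000e+00
1.49230e-03 1.04867e+06 1.04854e+06 1.04854e+06 1.73546e-01 1.26219e+02 0.00000e+00
1.64938e-03 7.61308e+05 7.61205e+05 7.61205e+05 1.73440e-01 1.03323e+02 0.00000e+00
1.82299e-03 5.52692e+05 5.52607e+05 5.52607e+05 1.73323e-01 8.45803e+01 0.00000e+00
2.01488e-03 4.01243e+05 4.01173e+05 4.01173e+05 1.73195e-01 6.92374e+01 0.00000e+00
2.22696e-03 2.91294e+05 2.91237e+05 2.91237e+05 1.73053e-01 5.66778e+01 0.00000e+00
2.46137e-03 2.11474e+05 2.11428e+05 2.11428e+05 1.72897e-01 4.63965e+01 0.00000e+00
2.72045e-03 1.53527e+05 1.53489e+05 1.53489e+05 1.72724e-01 3.79802e+01 0.00000e+00
3.00680e-03 1.11459e+05 1.11428e+05 1.11428e+05 1.72534e-01 3.10906e+01 0.00000e+00
3.32329e-03 8.09180e+04 8.08924e+04 8.08924e+04 1.72325e-01 2.54508e+01 0.00000e+00
3.67310e-03 5.87460e+04 5.87250e+04 5.87250e+04 1.72094e-01 2.08340e+01 0.00000e+00
4.05972e-03 4.26494e+04 4.26322e+04 4.26322e+04 1.71840e-01 1.70547e+01 0.00000e+00
4.48704e-03 3.09636e+04 3.09495e+04 3.09495e+04 1.71560e-01 1.39610e+01 0.00000e+00
4.95934e-03 2.24798e+04 2.24682e+04 2.24682e+04 1.71253e-01 1.14285e+01 0.00000e+00
5.48136e-03 1.63206e+04 1.63111e+04 1.63111e+04 1.70914e-01 9.35537e+00 0.00000e+00
6.05832e-03 1.18491e+04 1.18413e+04 1.18413e+04 1.70542e-01 7.65831e+00 0.00000e+00
6.69601e-03 8.60278e+03 8.59634e+03 8.59634e+03 1.70134e-01 6.26909e+00 0.00000e+00
7.40083e-03 6.24594e+03 6.24064e+03 6.24063e+03 1.69685e-01 5.13188e+00 0.00000e+00
8.17983e-03 4.53485e+03 4.53048e+03 4.53048e+03 1.69192e-01 4.20096e+00 0.00000e+00
9.04083e-03 3.29257e+03 3.28897e+03 3.28896e+03 1.68653e-01 3.43891e+00 0.00000e+00
9.99246e-03 2.39065e+03 2.38767e+03 2.38767e+03 1.68061e-01 2.81509e+00 0.00000e+00
1.10443e-02 1.73583e+03 1.73337e+03 1.73336e+03 1.67414e-01 2.30444e+00 0.00000e+00
1.22068e-02 1.26041e+03 1.25836e+03 1.25836e+03 1.66706e-01 1.88641e+00 0.00000e+00
1.34916e-02 9.15233e+02 9.13527e+02 9.13523e+02 1.65933e-01 1.54422e+00 0.00000e+00
1.49117e-02 6.64614e+02 6.63190e+02 6.63185e+02 1.65089e-01 1.26410e+00 0.00000e+00
1.64813e-02 4.82648e+02 4.81454e+02 4.81449e+02 1.64169e-01 1.03479e+00 0.00000e+00
1.82161e-02 3.50525e+02 3.49520e+02 3.49514e+02 1.63169e-01 8.47080e-01 0.00000e+00
2.01336e-02 2.54590e+02 2.53741e+02 2.53735e+02 1.62082e-01 6.93420e-01 0.00000e+00
2.22528e-02 1.84931e+02 1.84209e+02 1.84202e+02 1.60903e-01 5.67634e-01 0.00000e+00
2.45951e-02 1.34349e+02 1.33731e+02 1.33724e+02 1.59625e-01 4.64665e-01 0.00000e+00
2.71839e-02 9.76177e+01 9.70866e+01 9.70791e+01 1.58245e-01 3.80375e-01 0.00000e+00
3.00453e-02 7.09441e+01 7.04841e+01 7.04759e+01 1.56756e-01 3.11375e-01 0.00000e+00
3.32078e-02 5.15730e+01 5.11718e+01 5.11630e+01 1.55154e-01 2.54892e-01 0.00000e+00
3.67033e-02 3.75046e+01 3.71520e+01 3.71425e+01 1.53434e-01 2.08655e-01 0.00000e+00
4.05666e-02 2.72865e+01 2.69744e+01 2.69641e+01 1.51592e-01 1.70805e-01 0.00000e+00
4.48366e-02 1.98644e+01 1.95860e+01 1.95750e+01 1.49625e-01 1.39821e-01 0.00000e+00
4.95560e-02 1.44727e+01 1.42226e+01 1.42107e+01 1.47530e-01 1.14457e-01 0.00000e+00
5.47723e-02 1.05555e+01 1.03291e+01 1.03165e+01 1.45306e-01 9.36949e-02 0.00000e+00
6.05375e-02 7.70905e+00 7.50288e+00 7.48940e+00 1.42953e-01 7.66987e-02 0.00000e+00
6.69096e-02 5.64029e+00 5.45137e+00 5.43703e+00 1.40472e-01 6.27856e-02 0.00000e+00
7.39525e-02 4.13635e+00 3.96230e+00 3.94709e+00 1.37866e-01 5.13963e-02 0.00000e+00
8.17366e-02 3.04266e+00 2.88153e+00 2.86545e+00 1.35138e-01 4.20730e-02 0.00000e+00
9.03401e-02 2.24695e+00 2.09717e+00 2.08021e+00 1.32294e-01 3.44410e-02 0.00000e+00
9.98492e-02 1.66769e+00 1.52799e+00 1.51016e+00 1.29340e-01 2.81934e-02 0.00000e+00
1.10359e-01 1.24569e+00 1.11500e+00 1.09632e+00 1.26286e-01 2.30791e-02 0.00000e+00
1.21976e-01 9.37923e-01 8.15405e-01 7.95890e-01 1.23141e-01 1.88926e-02 0.00000e+00
1.34815e-01 7.13168e-01 5.98105e-01 5.77787e-01 1.19915e-01 1.54655e-02 0.00000e+00
1.49005e-01 5.48734e-01 4.40537e-01 4.19453e-01 1.16621e-01 1.26601e-02 0.00000e+00
1.64689e-01 4.28143e-01 3.26317e-01 3.04508e-01 1.13272e-01 1.03635e-02 0.00000e+00
1.82024e-01 3.39424e-01 2.43548e-01 2.21062e-01 1.09879e-01 8.48359e-03 0.00000e+00
2.01184e-01 2.73884e-01 1.83594e-01 1.60483e-01 1.06457e-01 6.94467e-03 0.00000e+00
2.22360e-01 2.25207e-01 1.40184e-01 1.16505e-01 1.03018e-01 5.68491e-03 0.00000e+00
2.45765e-01 1.88806e-01 1.08765e-01 8.45783e-02 9.95737e-02 4.65367e-03 0.00000e+00
2.71634e-01 1.61347e-01 8.60325e-02 6.14008e-02 9.61370e-02 3.80950e-03 0.00000e+00
3.00226e-01 1.40411e-01 6.95861e-02 4.45748e-02 9.27180e-02 3.11846e-03 0.00000e+00
3.31828e-01 1.24239e-01 5.76842e-02 3.23597e-02 8.93263e-02 2.55277e-03 0.00000e+00
3.66756e-01 1.11552e-01 4.90623e-02 2.34920e-02 8.59703e-02 2.08970e-03 0.00000e+00
4.05360e-01 1.01422e-01 4.28026e-02 1.70543e-02 8.26573e-02 1.71063e-03 0.00000e+00
4.48028e-01 9.31744e-02 3.82392e-02 1.23808e-02 7.93932e-02 1.40032e-03 0.00000e+00
4.95187e-01 8.63175e-02 3.48890e-02 8.98804e-03 7.61832e-02 1.14630e-03 0.00000e+00
5.47310e-01 8.04944e-02 3.24015e-02 6.52500e-03 7.30311e-02 9.38364e-04 0.00000e+00
6.04919e-01 7.54453e-02 3.05230e-02 4.73691e-03 6.99402e-02 7.68145e-04 0.00000e+00
6.68592e-01 7.09809e-02 2.90696e-02 3.43883e-03 6.69133e-02 6.28804e-04 0.00000e+00
7.38967e-01 6.69635e-02 2.79085e-02 2.49647e-03 6.39522e-02 5.14739e-04 0.00000e+00
8.16750e-01 6.32926e-02 2.69443e-02 1.81234e-03 6.10589e-02 4.21366e-04 0.00000e+00
9.02720e-01 5.98955e-02 2.61083e-02 1.31570e-03 5.82349e-02 3.44930e-04 0.00000e+00
9.97739e-01 5.67189e-02 2.53519e-02 9.55149e-04 5.54814e-02 2.82360e-04 0.00000e+00
1.10276e+00 5.55293e-02 2.47731e-02 6.93404e-04 5.27999e-02 2.31140e-04 1.80483e-03
1.21884e+00 5.52830e-02 2.46621e-02 5.03386e-04 5.01916e-02 1.89211e-04 4.39882e-03
1.34713e+00 5.54440e-02 2.50221e-02 3.65440e-04 4.76578e-02 1.54888e-04 7.26585e-03
1.48893e+00 5.60265e-02 2.58537e-02 2.65297e-04 4.51998e-02 1.26792e-04 1.04347e-02
1.64565e+00 5.70520e-02 2.71661e-02 1.92596e-04 4.28186e-02 1.03792e-04 1.39370e-02
1.81887e+00 5.85483e-02 2.89767e-02 1.39818e-04 4.05155e-02 8.49640e-05 1.78080e-02
2.01032e+00 6.05490e-02 3.13103e-02 1.01503e-04 3.82915e-02 6.95516e-05 2.20865e-02
2.22192e+00 6.30932e-02 3.41984e-02 7.36872e-05 3.61473e-02 5.69349e-05 2.68153e-02
2.45580e+00 6.62256e-02 3.76794e-02 5.34943e-05 3.40837e-02 4.66070e-05 3.20419e-02
2.71430e+00 6.99965e-02 4.17985e-02 3.88349e-05 3.21010e-02 3.81525e-05 3.78186e-02
3.00000e+00 7.44621e-02 4.66077e-02 2.81928e-05 3.01994e-02 3.12316e-05 4.42033e-02
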