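# air: photon mass interaction coefficients [cm^2/g]
# density 0.0012048 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 7.97401e+03 7.95368e+03 7.95368e+03 1.99205e-01 2.01314e+01 0.00000e+00
1.10526e-03 5.79077e+03 5.77409e+03 5.77409e+03 1.99123e-01 1.64796e+01 0.00000e+00
1.22160e-03 4.20547e+03 4.19178e+03 4.19178e+03 1.99033e-01 1.34902e+01 0.00000e+00
1.35018e-03 3.05432e+03 3.04308e+03 3.04308e+03 1.98934e-01 1.10431e+01 0.00000e+00
1.49230e-03 2.21841e+03 2.20917e+03 2.20917e+03 1.98824e-01 9.03987e+00 0.00000e+00
1.64938e-03 1.61138e+03 1.60378e+03 1.60378e+03 1.98703e-01 7.40004e+00 0.00000e+00
1.82299e-03 1.17054e+03 1.16429e+03 1.16428e+03 1.98570e-01 6.05768e+00 0.00000e+00
2.01488e-03 8.50386e+02 8.45230e+02 8.45229e+02 1.98422e-01 4.95882e+00 0.00000e+00
2.22696e-03 6.17863e+02 6.13607e+02 6.13606e+02 1.98260e-01 4.05929e+00 0.00000e+00
2.46137e-03 4.48977e+02 4.45457e+02 4.45456e+02 1.98081e-01 3.32294e+00 0.00000e+00
2.72045e-03 3.26303e+02 3.23386e+02 3.23385e+02 1.97883e-01 2.72016e+00 0.00000e+00
3.00680e-03 2.37190e+02 2.34767e+02 2.34766e+02 1.97666e-01 2.22672e+00 0.00000e+00
3.32329e-03 1.72452e+02 1.70433e+02 1.70432e+02 1.97426e-01 1.82280e+00 0.00000e+00
3.67310e-03 1.25417e+02 1.23729e+02 1.23727e+02 1.97161e-01 1.49214e+00 0.00000e+00
4.05972e-03 9.12399e+01 8.98231e+01 8.98215e+01 1.96870e-01 1.22147e+00 0.00000e+00
4.48704e-03 6.64036e+01 6.52089e+01 6.52072e+01 1.96550e-01 9.99894e-01 0.00000e+00
4.95934e-03 4.83528e+01 4.73400e+01 4.73381e+01 1.96197e-01 8.18514e-01 0.00000e+00
5.48136e-03 3.52316e+01 3.43678e+01 3.43658e+01 1.95810e-01 6.70036e-01 0.00000e+00
6.05832e-03 2.56922e+01 2.49506e+01 2.49483e+01 1.95383e-01 5.48492e-01 0.00000e+00
6.69601e-03 1.87555e+01 1.81141e+01 1.81116e+01 1.94915e-01 4.48995e-01 0.00000e+00
7.40083e-03 1.37103e+01 1.31511e+01 1.31484e+01 1.94401e-01 3.67548e-01 0.00000e+00
8.17983e-03 1.00399e+01 9.54823e+00 9.54523e+00 1.93837e-01 3.00875e-01 0.00000e+00
9.04083e-03 7.36901e+00 6.93279e+00 6.92950e+00 1.93219e-01 2.46296e-01 0.00000e+00
9.99246e-03 5.42472e+00 5.03418e+00 5.03057e+00 1.92541e-01 2.01618e-01 0.00000e+00
1.10443e-02 4.00885e+00 3.65597e+00 3.65201e+00 1.91799e-01 1.65045e-01 0.00000e+00
1.22068e-02 2.97732e+00 2.65556e+00 2.65123e+00 1.90988e-01 1.35106e-01 0.00000e+00
1.34916e-02 2.22540e+00 1.92944e+00 1.92470e+00 1.90102e-01 1.10598e-01 0.00000e+00
1.49117e-02 1.67693e+00 1.40245e+00 1.39726e+00 1.89136e-01 9.05352e-02 0.00000e+00
1.64813e-02 1.27656e+00 1.02003e+00 1.01436e+00 1.88082e-01 7.41122e-02 0.00000e+00
1.82161e-02 9.83994e-01 7.42571e-01 7.36390e-01 1.86936e-01 6.06683e-02 0.00000e+00
2.01336e-02 7.69946e-01 5.41328e-01 5.34592e-01 1.85691e-01 4.96631e-02 0.00000e+00
2.22528e-02 6.13089e-01 3.95424e-01 3.88095e-01 1.84340e-01 4.06542e-02 0.00000e+00
2.45951e-02 4.97899e-01 2.89707e-01 2.81743e-01 1.82877e-01 3.32796e-02 0.00000e+00
2.71839e-02 4.13073e-01 2.13176e-01 2.04535e-01 1.81295e-01 2.72427e-02 0.00000e+00
3.00453e-02 3.50376e-01 1.57843e-01 1.48485e-01 1.79590e-01 2.23008e-02 0.00000e+00
3.32078e-02 3.03804e-01 1.17912e-01 1.07795e-01 1.77754e-01 1.82555e-02 0.00000e+00
3.67033e-02 2.68982e-01 8.91726e-02 7.82553e-02 1.75783e-01 1.49439e-02 0.00000e+00
4.05666e-02 2.42716e-01 6.85666e-02 5.68105e-02 1.73673e-01 1.22331e-02 0.00000e+00
4.48366e-02 2.22675e-01 5.38740e-02 4.12424e-02 1.71419e-01 1.00140e-02 0.00000e+00
4.95560e-02 2.07157e-01 4.34813e-02 2.99405e-02 1.69019e-01 8.19750e-03 0.00000e+00
5.47723e-02 1.94918e-01 3.62156e-02 2.17357e-02 1.66471e-01 6.71047e-03 0.00000e+00
6.05375e-02 1.85048e-01 3.12234e-02 1.57794e-02 1.63776e-01 5.49320e-03 0.00000e+00
6.69096e-02 1.76886e-01 2.78833e-02 1.14553e-02 1.60934e-01 4.49673e-03 0.00000e+00
7.39525e-02 1.69945e-01 2.57416e-02 8.31610e-03 1.57948e-01 3.68103e-03 0.00000e+00
8.17366e-02 1.63873e-01 2.44668e-02 6.03719e-03 1.54822e-01 3.01329e-03 0.00000e+00
9.03401e-02 1.58413e-01 2.38156e-02 4.38278e-03 1.51564e-01 2.46668e-03 0.00000e+00
9.98492e-02 1.53381e-01 2.36090e-02 3.18174e-03 1.48180e-01 2.01923e-03 0.00000e+00
1.10359e-01 1.48644e-01 2.37147e-02 2.30983e-03 1.44681e-01 1.65294e-03 0.00000e+00
1.21976e-01 1.44107e-01 2.40342e-02 1.67686e-03 1.41077e-01 1.35310e-03 0.00000e+00
1.34815e-01 1.39707e-01 2.44940e-02 1.21734e-03 1.37382e-01 1.10765e-03 0.00000e+00
1.49005e-01 1.35399e-01 2.50390e-02 8.83743e-04 1.33608e-01 9.06719e-04 0.00000e+00
1.64689e-01 1.31154e-01 2.56273e-02 6.41565e-04 1.29771e-01 7.42241e-04 0.00000e+00
1.82024e-01 1.26957e-01 2.62276e-02 4.65754e-04 1.25884e-01 6.07599e-04 0.00000e+00
2.01184e-01 1.22799e-01 2.68158e-02 3.38120e-04 1.21963e-01 4.97381e-04 0.00000e+00
2.22360e-01 1.18676e-01 2.73739e-02 2.45463e-04 1.18023e-01 4.07156e-04 0.00000e+00
2.45765e-01 1.14589e-01 2.78883e-02 1.78197e-04 1.14078e-01 3.33298e-04 0.00000e+00
2.71634e-01 1.10543e-01 2.83489e-02 1.29365e-04 1.10140e-01 2.72838e-04 0.00000e+00
3.00226e-01 1.06541e-01 2.87484e-02 9.39143e-05 1.06223e-01 2.23345e-04 0.00000e+00
3.31828e-01 1.02589e-01 2.90815e-02 6.81784e-05 1.02338e-01 1.82831e-04 0.00000e+00
3.66756e-01 9.86920e-02 2.93444e-02 4.94951e-05 9.84928e-02 1.49665e-04 0.00000e+00
4.05360e-01 9.48556e-02 2.95347e-02 3.59317e-05 9.46972e-02 1.22516e-04 0.00000e+00
4.48028e-01 9.10841e-02 2.96510e-02 2.60851e-05 9.09577e-02 1.00292e-04 0.00000e+00
4.95187e-01 8.73811e-02 2.96926e-02 1.89368e-05 8.72800e-02 8.20987e-05 0.00000e+00
5.47310e-01 8.37498e-02 2.96595e-02 1.37475e-05 8.36688e-02 6.72061e-05 0.00000e+00
6.04919e-01 8.01928e-02 2.95521e-02 9.98017e-06 8.01278e-02 5.50149e-05 0.00000e+00
6.68592e-01 7.67122e-02 2.93714e-02 7.24525e-06 7.66599e-02 4.50352e-05 0.00000e+00
7.38967e-01 7.33097e-02 2.91189e-02 5.25979e-06 7.32676e-02 3.68659e-05 0.00000e+00
8.16750e-01 6.99868e-02 2.87965e-02 3.81842e-06 6.99528e-02 3.01784e-05 0.00000e+00
9.02720e-01 6.67448e-02 2.84067e-02 2.77203e-06 6.67174e-02 2.47041e-05 0.00000e+00
9.97739e-01 6.35851e-02 2.79524e-02 2.01240e-06 6.35629e-02 2.02228e-05 0.00000e+00
1.10276e+00 6.08325e-02 2.74608e-02 1.46093e-06 6.04908e-02 1.65544e-05 3.23771e-04
1.21884e+00 5.83063e-02 2.69923e-02 1.06058e-06 5.75026e-02 1.35514e-05 7.89111e-04
1.34713e+00 5.59150e-02 2.65545e-02 7.69944e-07 5.45997e-02 1.10932e-05 1.30343e-03
1.48893e+00 5.36651e-02 2.61542e-02 5.58952e-07 5.17836e-02 9.08089e-06 1.87189e-03
1.64565e+00 5.15636e-02 2.57993e-02 4.05779e-07 4.90556e-02 7.43362e-06 2.50018e-03
1.81887e+00 4.96180e-02 2.54988e-02 2.94581e-07 4.64171e-02 6.08516e-06 3.19461e-03
2.01032e+00 4.78364e-02 2.52629e-02 2.13855e-07 4.38690e-02 4.98132e-06 3.96212e-03
2.22192e+00 4.62272e-02 2.51026e-02 1.55251e-07 4.14125e-02 4.07771e-06 4.81043e-03
2.45580e+00 4.47998e-02 2.50303e-02 1.12707e-07 3.90483e-02 3.33801e-06 5.74803e-03
2.71430e+00 4.35639e-02 2.50589e-02 8.18211e-08 3.67768e-02 2.73250e-06 6.78432e-03
3.00000e+00 4.25303e-02 2.52028e-02 5.93992e-08 3.45983e-02 2.23682e-06 7.92969e-03
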