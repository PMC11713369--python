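# water: photon mass interaction coefficients [cm^2/g]
# density 0.998 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 7.84993e+03 7.82937e+03 7.82937e+03 2.21514e-01 2.03400e+01 0.00000e+00
1.10526e-03 5.70072e+03 5.68384e+03 5.68384e+03 2.21424e-01 1.66503e+01 0.00000e+00
1.22160e-03 4.14012e+03 4.12627e+03 4.12627e+03 2.21324e-01 1.36300e+01 0.00000e+00
1.35018e-03 3.00690e+03 2.99552e+03 2.99552e+03 2.21213e-01 1.11575e+01 0.00000e+00
1.49230e-03 2.18400e+03 2.17464e+03 2.17464e+03 2.21091e-01 9.13353e+00 0.00000e+00
1.64938e-03 1.58641e+03 1.57871e+03 1.57871e+03 2.20957e-01 7.47671e+00 0.00000e+00
1.82299e-03 1.15243e+03 1.14609e+03 1.14609e+03 2.20808e-01 6.12044e+00 0.00000e+00
2.01488e-03 8.37249e+02 8.32019e+02 8.32019e+02 2.20644e-01 5.01020e+00 0.00000e+00
2.22696e-03 6.08337e+02 6.04017e+02 6.04016e+02 2.20464e-01 4.10135e+00 0.00000e+00
2.46137e-03 4.42071e+02 4.38495e+02 4.38494e+02 2.20264e-01 3.35737e+00 0.00000e+00
2.72045e-03 3.21299e+02 3.18332e+02 3.18331e+02 2.20045e-01 2.74834e+00 0.00000e+00
3.00680e-03 2.33566e+02 2.31098e+02 2.31097e+02 2.19803e-01 2.24979e+00 0.00000e+00
3.32329e-03 1.69829e+02 1.67769e+02 1.67768e+02 2.19536e-01 1.84168e+00 0.00000e+00
3.67310e-03 1.23520e+02 1.21795e+02 1.21793e+02 2.19242e-01 1.50760e+00 0.00000e+00
4.05972e-03 8.98707e+01 8.84194e+01 8.84177e+01 2.18918e-01 1.23412e+00 0.00000e+00
4.48704e-03 6.54169e+01 6.41899e+01 6.41881e+01 2.18562e-01 1.01025e+00 0.00000e+00
4.95934e-03 4.76434e+01 4.66003e+01 4.65982e+01 2.18170e-01 8.26994e-01 0.00000e+00
5.48136e-03 3.47234e+01 3.38309e+01 3.38286e+01 2.17739e-01 6.76978e-01 0.00000e+00
6.05832e-03 2.53298e+01 2.45609e+01 2.45584e+01 2.17265e-01 5.54174e-01 0.00000e+00
6.69601e-03 1.84989e+01 1.78313e+01 1.78285e+01 2.16744e-01 4.53647e-01 0.00000e+00
7.40083e-03 1.35304e+01 1.29459e+01 1.29429e+01 2.16173e-01 3.71356e-01 0.00000e+00
8.17983e-03 9.91558e+00 9.39938e+00 9.39605e+00 2.15545e-01 3.03992e-01 0.00000e+00
9.04083e-03 7.28490e+00 6.82485e+00 6.82119e+00 2.14858e-01 2.48848e-01 0.00000e+00
9.99246e-03 5.36975e+00 4.95595e+00 4.95194e+00 2.14104e-01 2.03707e-01 0.00000e+00
1.10443e-02 3.97497e+00 3.59933e+00 3.59493e+00 2.13279e-01 1.66755e-01 0.00000e+00
1.22068e-02 2.95867e+00 2.61461e+00 2.60979e+00 2.12378e-01 1.36506e-01 0.00000e+00
1.34916e-02 2.21775e+00 1.89989e+00 1.89461e+00 2.11392e-01 1.11743e-01 0.00000e+00
1.49117e-02 1.67721e+00 1.38119e+00 1.37542e+00 2.10318e-01 9.14732e-02 0.00000e+00
1.64813e-02 1.28253e+00 1.00481e+00 9.98507e-01 2.09146e-01 7.48800e-02 0.00000e+00
1.82161e-02 9.94049e-01 7.31754e-01 7.24880e-01 2.07872e-01 6.12968e-02 0.00000e+00
2.01336e-02 7.82901e-01 5.33727e-01 5.26237e-01 2.06487e-01 5.01776e-02 0.00000e+00
2.22528e-02 6.28089e-01 3.90179e-01 3.82029e-01 2.04984e-01 4.10754e-02 0.00000e+00
2.45951e-02 5.14321e-01 2.86195e-01 2.77340e-01 2.03357e-01 3.36244e-02 0.00000e+00
2.71839e-02 4.30462e-01 2.10946e-01 2.01339e-01 2.01599e-01 2.75249e-02 0.00000e+00
3.00453e-02 3.68399e-01 1.56571e-01 1.46165e-01 1.99702e-01 2.25319e-02 0.00000e+00
3.32078e-02 3.22216e-01 1.17361e-01 1.06110e-01 1.97661e-01 1.84446e-02 0.00000e+00
3.67033e-02 2.87601e-01 8.91721e-02 7.70322e-02 1.95470e-01 1.50988e-02 0.00000e+00
4.05666e-02 2.61405e-01 6.89953e-02 5.59226e-02 1.93123e-01 1.23599e-02 0.00000e+00
4.48366e-02 2.41332e-01 5.46440e-02 4.05978e-02 1.90617e-01 1.01178e-02 0.00000e+00
4.95560e-02 2.25703e-01 4.45298e-02 2.94726e-02 1.87948e-01 8.28243e-03 0.00000e+00
5.47723e-02 2.13291e-01 3.74975e-02 2.13960e-02 1.85115e-01 6.78000e-03 0.00000e+00
6.05375e-02 2.03200e-01 3.27064e-02 1.55327e-02 1.82118e-01 5.55011e-03 0.00000e+00
6.69096e-02 1.94777e-01 2.95441e-02 1.12762e-02 1.78957e-01 4.54332e-03 0.00000e+00
7.39525e-02 1.87542e-01 2.75632e-02 8.18613e-03 1.75637e-01 3.71917e-03 0.00000e+00
8.17366e-02 1.81148e-01 2.64364e-02 5.94283e-03 1.72161e-01 3.04451e-03 0.00000e+00
9.03401e-02 1.75344e-01 2.59235e-02 4.31428e-03 1.68538e-01 2.49224e-03 0.00000e+00
9.98492e-02 1.69947e-01 2.58470e-02 3.13202e-03 1.64775e-01 2.04015e-03 0.00000e+00
1.10359e-01 1.64828e-01 2.60758e-02 2.27373e-03 1.60884e-01 1.67007e-03 0.00000e+00
1.21976e-01 1.59895e-01 2.65118e-02 1.65065e-03 1.56877e-01 1.36712e-03 0.00000e+00
1.34815e-01 1.55085e-01 2.70818e-02 1.19831e-03 1.52768e-01 1.11912e-03 0.00000e+00
1.49005e-01 1.50357e-01 2.77304e-02 8.69930e-04 1.48571e-01 9.16114e-04 0.00000e+00
1.64689e-01 1.45686e-01 2.84155e-02 6.31538e-04 1.44304e-01 7.49931e-04 0.00000e+00
1.82024e-01 1.41055e-01 2.91054e-02 4.58474e-04 1.39982e-01 6.13894e-04 0.00000e+00
2.01184e-01 1.36458e-01 2.97758e-02 3.32836e-04 1.35622e-01 5.02534e-04 0.00000e+00
2.22360e-01 1.31894e-01 3.04082e-02 2.41627e-04 1.31241e-01 4.11374e-04 0.00000e+00
2.45765e-01 1.27366e-01 3.09888e-02 1.75412e-04 1.26854e-01 3.36751e-04 0.00000e+00
2.71634e-01 1.22878e-01 3.15073e-02 1.27343e-04 1.22475e-01 2.75665e-04 0.00000e+00
3.00226e-01 1.18438e-01 3.19561e-02 9.24465e-05 1.18120e-01 2.25659e-04 0.00000e+00
3.31828e-01 1.14051e-01 3.23297e-02 6.71128e-05 1.13799e-01 1.84725e-04 0.00000e+00
3.66756e-01 1.09723e-01 3.26244e-02 4.87215e-05 1.09523e-01 1.51216e-04 0.00000e+00
4.05360e-01 1.05462e-01 3.28378e-02 3.53701e-05 1.05303e-01 1.23785e-04 0.00000e+00
4.48028e-01 1.01271e-01 3.29684e-02 2.56774e-05 1.01144e-01 1.01331e-04 0.00000e+00
4.95187e-01 9.71564e-02 3.30156e-02 1.86409e-05 9.70548e-02 8.29494e-05 0.00000e+00
5.47310e-01 9.31206e-02 3.29794e-02 1.35326e-05 9.30391e-02 6.79024e-05 0.00000e+00
6.04919e-01 8.91669e-02 3.28604e-02 9.82419e-06 8.91015e-02 5.55849e-05 0.00000e+00
6.68592e-01 8.52979e-02 3.26598e-02 7.13201e-06 8.52452e-02 4.55018e-05 0.00000e+00
7.38967e-01 8.15154e-02 3.23793e-02 5.17758e-06 8.14730e-02 3.72478e-05 0.00000e+00
8.16750e-01 7.78213e-02 3.20210e-02 3.75874e-06 7.77870e-02 3.04911e-05 0.00000e+00
9.02720e-01 7.42169e-02 3.15877e-02 2.72871e-06 7.41892e-02 2.49600e-05 0.00000e+00
9.97739e-01 7.07039e-02 3.10826e-02 1.98094e-06 7.06814e-02 2.04323e-05 0.00000e+00
1.10276e+00 6.76063e-02 3.05334e-02 1.43809e-06 6.72653e-02 1.67259e-05 3.22883e-04
1.21884e+00 6.47441e-02 3.00005e-02 1.04401e-06 6.39424e-02 1.36918e-05 7.86946e-04
1.34713e+00 6.20263e-02 2.94922e-02 7.57910e-07 6.07145e-02 1.12081e-05 1.29986e-03
1.48893e+00 5.94595e-02 2.90159e-02 5.50216e-07 5.75830e-02 9.17497e-06 1.86675e-03
1.64565e+00 5.70507e-02 2.85799e-02 3.99437e-07 5.45495e-02 7.51063e-06 2.49332e-03
1.81887e+00 5.48077e-02 2.81939e-02 2.89977e-07 5.16154e-02 6.14821e-06 3.18584e-03
2.01032e+00 5.27386e-02 2.78686e-02 2.10513e-07 4.87821e-02 5.03293e-06 3.95126e-03
2.22192e+00 5.08520e-02 2.76159e-02 1.52825e-07 4.60504e-02 4.11996e-06 4.79724e-03
2.45580e+00 4.91572e-02 2.74484e-02 1.10945e-07 4.34214e-02 3.37260e-06 5.73227e-03
2.71430e+00 4.76641e-02 2.73800e-02 8.05423e-08 4.08955e-02 2.76081e-06 6.76572e-03
3.00000e+00 4.63833e-02 2.74254e-02 5.84708e-08 3.84730e-02 2.26000e-06 7.90795e-03
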