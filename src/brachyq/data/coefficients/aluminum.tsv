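# aluminum: photon mass interaction coefficients [cm^2/g]
# density 2.699 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 4.65022e+04 4.64568e+04 4.64568e+04 1.92268e-01 4.52136e+01 0.00000e+00
1.10526e-03 3.37631e+04 3.37259e+04 3.37259e+04 1.92190e-01 3.70119e+01 0.00000e+00
1.22160e-03 2.45143e+04 2.44838e+04 2.44838e+04 1.92103e-01 3.02980e+01 0.00000e+00
1.35018e-03 1.77994e+04 1.77744e+04 1.77744e+04 1.92007e-01 2.48019e+01 0.00000e+00
1.49230e-03 1.29241e+04 1.29036e+04 1.29036e+04 1.91901e-01 2.03029e+01 0.00000e+00
1.64938e-03 9.38433e+03 9.36752e+03 9.36752e+03 1.91784e-01 1.66199e+01 0.00000e+00
1.82299e-03 6.81428e+03 6.80049e+03 6.80048e+03 1.91655e-01 1.36051e+01 0.00000e+00
2.01488e-03 4.94824e+03 4.93691e+03 4.93691e+03 1.91513e-01 1.11371e+01 0.00000e+00
2.22696e-03 3.59333e+03 3.58402e+03 3.58402e+03 1.91356e-01 9.11686e+00 0.00000e+00
2.46137e-03 2.60952e+03 2.60187e+03 2.60187e+03 1.91184e-01 7.46307e+00 0.00000e+00
2.72045e-03 1.89516e+03 1.88886e+03 1.88886e+03 1.90993e-01 6.10927e+00 0.00000e+00
3.00680e-03 1.37644e+03 1.37125e+03 1.37125e+03 1.90783e-01 5.00105e+00 0.00000e+00
3.32329e-03 9.99760e+02 9.95477e+02 9.95476e+02 1.90551e-01 4.09386e+00 0.00000e+00
3.67310e-03 7.26221e+02 7.22681e+02 7.22680e+02 1.90296e-01 3.35124e+00 0.00000e+00
4.05972e-03 5.27573e+02 5.24641e+02 5.24640e+02 1.90015e-01 2.74332e+00 0.00000e+00
4.48704e-03 3.83305e+02 3.80871e+02 3.80870e+02 1.89706e-01 2.24569e+00 0.00000e+00
4.95934e-03 2.78525e+02 2.76499e+02 2.76498e+02 1.89366e-01 1.83832e+00 0.00000e+00
5.48136e-03 2.02421e+02 2.00729e+02 2.00727e+02 1.88991e-01 1.50485e+00 0.00000e+00
6.05832e-03 1.47141e+02 1.45723e+02 1.45721e+02 1.88580e-01 1.23187e+00 0.00000e+00
6.69601e-03 1.06985e+02 1.05790e+02 1.05788e+02 1.88128e-01 1.00841e+00 0.00000e+00
7.40083e-03 7.78115e+01 7.68010e+01 7.67984e+01 1.87632e-01 8.25484e-01 0.00000e+00
8.17983e-03 5.66157e+01 5.57557e+01 5.57529e+01 1.87088e-01 6.75742e-01 0.00000e+00
9.04083e-03 4.12142e+01 4.04777e+01 4.04746e+01 1.86491e-01 5.53163e-01 0.00000e+00
9.99246e-03 3.00217e+01 2.93866e+01 2.93831e+01 1.85837e-01 4.52819e-01 0.00000e+00
1.10443e-02 2.18869e+01 2.13349e+01 2.13311e+01 1.85121e-01 3.70678e-01 0.00000e+00
1.22068e-02 1.59734e+01 1.54898e+01 1.54856e+01 1.84338e-01 3.03437e-01 0.00000e+00
1.34916e-02 1.16739e+01 1.12466e+01 1.12420e+01 1.83483e-01 2.48394e-01 0.00000e+00
1.49117e-02 8.54716e+00 8.16628e+00 8.16127e+00 1.82550e-01 2.03335e-01 0.00000e+00
1.64813e-02 6.27278e+00 5.93026e+00 5.92479e+00 1.81533e-01 1.66450e-01 0.00000e+00
1.82161e-02 4.61787e+00 4.30715e+00 4.30119e+00 1.80427e-01 1.36256e-01 0.00000e+00
2.01336e-02 3.41327e+00 3.12901e+00 3.12251e+00 1.79225e-01 1.11539e-01 0.00000e+00
2.22528e-02 2.53606e+00 2.27390e+00 2.26683e+00 1.77921e-01 9.13063e-02 0.00000e+00
2.45951e-02 1.89689e+00 1.65332e+00 1.64564e+00 1.76509e-01 7.47433e-02 0.00000e+00
2.71839e-02 1.43084e+00 1.20301e+00 1.19467e+00 1.74982e-01 6.11849e-02 0.00000e+00
3.00453e-02 1.09071e+00 8.76322e-01 8.67289e-01 1.73336e-01 5.00860e-02 0.00000e+00
3.32078e-02 8.42186e-01 6.39386e-01 6.29621e-01 1.71564e-01 4.10004e-02 0.00000e+00
3.67033e-02 6.60308e-01 4.67619e-01 4.57082e-01 1.69662e-01 3.35630e-02 0.00000e+00
4.05666e-02 5.26925e-01 3.43172e-01 3.31825e-01 1.67625e-01 2.74747e-02 0.00000e+00
4.48366e-02 4.28834e-01 2.53085e-01 2.40893e-01 1.65450e-01 2.24908e-02 0.00000e+00
4.95560e-02 3.56424e-01 1.87949e-01 1.74880e-01 1.63134e-01 1.84110e-02 0.00000e+00
5.47723e-02 3.02702e-01 1.40932e-01 1.26957e-01 1.60675e-01 1.50712e-02 0.00000e+00
6.05375e-02 2.62576e-01 1.07072e-01 9.21659e-02 1.58073e-01 1.23373e-02 0.00000e+00
6.69096e-02 2.32338e-01 8.27651e-02 6.69091e-02 1.55330e-01 1.00993e-02 0.00000e+00
7.39525e-02 2.09289e-01 6.53924e-02 4.85736e-02 1.52448e-01 8.26731e-03 0.00000e+00
8.17366e-02 1.91461e-01 5.30506e-02 3.52627e-02 1.49431e-01 6.76762e-03 0.00000e+00
9.03401e-02 1.77426e-01 4.43556e-02 2.55995e-02 1.46286e-01 5.53998e-03 0.00000e+00
9.98492e-02 1.66140e-01 3.83003e-02 1.85843e-02 1.43020e-01 4.53503e-03 0.00000e+00
1.10359e-01 1.56847e-01 3.41510e-02 1.34915e-02 1.39643e-01 3.71238e-03 0.00000e+00
1.21976e-01 1.48998e-01 3.13732e-02 9.79436e-03 1.36165e-01 3.03895e-03 0.00000e+00
1.34815e-01 1.42196e-01 2.95765e-02 7.11036e-03 1.32598e-01 2.48769e-03 0.00000e+00
1.49005e-01 1.36154e-01 2.84760e-02 5.16186e-03 1.28956e-01 2.03642e-03 0.00000e+00
1.64689e-01 1.30666e-01 2.78631e-02 3.74733e-03 1.25252e-01 1.66702e-03 0.00000e+00
1.82024e-01 1.25586e-01 2.75852e-02 2.72042e-03 1.21501e-01 1.36462e-03 0.00000e+00
2.01184e-01 1.20808e-01 2.75306e-02 1.97493e-03 1.17716e-01 1.11708e-03 0.00000e+00
2.22360e-01 1.16262e-01 2.76175e-02 1.43373e-03 1.13913e-01 9.14441e-04 0.00000e+00
2.45765e-01 1.11895e-01 2.77860e-02 1.04084e-03 1.10105e-01 7.48562e-04 0.00000e+00
2.71634e-01 1.07674e-01 2.79926e-02 7.55609e-04 1.06305e-01 6.12773e-04 0.00000e+00
3.00226e-01 1.03575e-01 2.82053e-02 5.48545e-04 1.02525e-01 5.01616e-04 0.00000e+00
3.31828e-01 9.95830e-02 2.84013e-02 3.98224e-04 9.87742e-02 4.10623e-04 0.00000e+00
3.66756e-01 9.56885e-02 2.85639e-02 2.89096e-04 9.50632e-02 3.36136e-04 0.00000e+00
4.05360e-01 9.18848e-02 2.86815e-02 2.09874e-04 9.13998e-02 2.75161e-04 0.00000e+00
4.48028e-01 8.81681e-02 2.87457e-02 1.52361e-04 8.77905e-02 2.25247e-04 0.00000e+00
4.95187e-01 8.45359e-02 2.87510e-02 1.10608e-04 8.42409e-02 1.84388e-04 0.00000e+00
5.47310e-01 8.09867e-02 2.86938e-02 8.02978e-05 8.07554e-02 1.50940e-04 0.00000e+00
6.04919e-01 7.75195e-02 2.85717e-02 5.82933e-05 7.73377e-02 1.23559e-04 0.00000e+00
6.68592e-01 7.41340e-02 2.83840e-02 4.23188e-05 7.39905e-02 1.01146e-04 0.00000e+00
7.38967e-01 7.08299e-02 2.81306e-02 3.07220e-05 7.07163e-02 8.27979e-05 0.00000e+00
8.16750e-01 6.76071e-02 2.78124e-02 2.23030e-05 6.75170e-02 6.77784e-05 0.00000e+00
9.02720e-01 6.44659e-02 2.74310e-02 1.61912e-05 6.43942e-02 5.54834e-05 0.00000e+00
9.97739e-01 6.14067e-02 2.69889e-02 1.17542e-05 6.13496e-02 4.54188e-05 0.00000e+00
1.10276e+00 5.89822e-02 2.65293e-02 8.53315e-06 5.83844e-02 3.71798e-05 5.52009e-04
1.21884e+00 5.68823e-02 2.61518e-02 6.19476e-06 5.55003e-02 3.04354e-05 1.34538e-03
1.34713e+00 5.49502e-02 2.58663e-02 4.49717e-06 5.26985e-02 2.49144e-05 2.22226e-03
1.48893e+00 5.31956e-02 2.56805e-02 3.26479e-06 4.99805e-02 2.03950e-05 3.19145e-03
1.64565e+00 5.16292e-02 2.56039e-02 2.37012e-06 4.73475e-02 1.66953e-05 4.26264e-03
1.81887e+00 5.02628e-02 2.56477e-02 1.72062e-06 4.48008e-02 1.36668e-05 5.44659e-03
2.01032e+00 4.91091e-02 2.58252e-02 1.24911e-06 4.23415e-02 1.11877e-05 6.75517e-03
2.22192e+00 4.81821e-02 2.61511e-02 9.06808e-07 3.99705e-02 9.15822e-06 8.20148e-03
2.45580e+00 4.74968e-02 2.66418e-02 6.58310e-07 3.76886e-02 7.49692e-06 9.80002e-03
2.71430e+00 4.70697e-02 2.73158e-02 4.77910e-07 3.54962e-02 6.13698e-06 1.15668e-02
3.00000e+00 4.69185e-02 2.81931e-02 3.46945e-07 3.33935e-02 5.02374e-06 1.35196e-02
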