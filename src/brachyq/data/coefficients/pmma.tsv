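# pmma: photon mass interaction coefficients [cm^2/g]
# density 1.19 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 4.76443e+03 4.74800e+03 4.74800e+03 2.15239e-01 1.62171e+01 0.00000e+00
1.10526e-03 3.46037e+03 3.44688e+03 3.44688e+03 2.15151e-01 1.32754e+01 0.00000e+00
1.22160e-03 2.51339e+03 2.50231e+03 2.50231e+03 2.15054e-01 1.08672e+01 0.00000e+00
1.35018e-03 1.82570e+03 1.81659e+03 1.81659e+03 2.14947e-01 8.89590e+00 0.00000e+00
1.49230e-03 1.32627e+03 1.31878e+03 1.31878e+03 2.14828e-01 7.28219e+00 0.00000e+00
1.64938e-03 9.63560e+02 9.57385e+02 9.57384e+02 2.14697e-01 5.96120e+00 0.00000e+00
1.82299e-03 7.00121e+02 6.95027e+02 6.95027e+02 2.14553e-01 4.87984e+00 0.00000e+00
2.01488e-03 5.08773e+02 5.04565e+02 5.04564e+02 2.14394e-01 3.99464e+00 0.00000e+00
2.22696e-03 3.69780e+02 3.66297e+02 3.66296e+02 2.14218e-01 3.27002e+00 0.00000e+00
2.46137e-03 2.68808e+02 2.65919e+02 2.65917e+02 2.14025e-01 2.67684e+00 0.00000e+00
2.72045e-03 1.95452e+02 1.93048e+02 1.93047e+02 2.13811e-01 2.19126e+00 0.00000e+00
3.00680e-03 1.42152e+02 1.40146e+02 1.40145e+02 2.13576e-01 1.79377e+00 0.00000e+00
3.32329e-03 1.03422e+02 1.01742e+02 1.01740e+02 2.13317e-01 1.46838e+00 0.00000e+00
3.67310e-03 7.52747e+01 7.38612e+01 7.38597e+01 2.13031e-01 1.20201e+00 0.00000e+00
4.05972e-03 5.48162e+01 5.36211e+01 5.36195e+01 2.12717e-01 9.83970e-01 0.00000e+00
4.48704e-03 3.99437e+01 3.89277e+01 3.89258e+01 2.12371e-01 8.05478e-01 0.00000e+00
4.95934e-03 2.91301e+01 2.82608e+01 2.82588e+01 2.11990e-01 6.59365e-01 0.00000e+00
5.48136e-03 2.12662e+01 2.05171e+01 2.05148e+01 2.11571e-01 5.39756e-01 0.00000e+00
6.05832e-03 1.55460e+01 1.48955e+01 1.48930e+01 2.11110e-01 4.41845e-01 0.00000e+00
6.69601e-03 1.13841e+01 1.08145e+01 1.08118e+01 2.10604e-01 3.61694e-01 0.00000e+00
7.40083e-03 8.35512e+00 7.85193e+00 7.84899e+00 2.10049e-01 2.96083e-01 0.00000e+00
8.17983e-03 6.14990e+00 5.70132e+00 5.69808e+00 2.09439e-01 2.42374e-01 0.00000e+00
9.04083e-03 4.54378e+00 4.14016e+00 4.13660e+00 2.08771e-01 1.98407e-01 0.00000e+00
9.99246e-03 3.37348e+00 3.00693e+00 3.00303e+00 2.08039e-01 1.62416e-01 0.00000e+00
1.10443e-02 2.52028e+00 2.18436e+00 2.18009e+00 2.07238e-01 1.32954e-01 0.00000e+00
1.22068e-02 1.89786e+00 1.58735e+00 1.58267e+00 2.06361e-01 1.08836e-01 0.00000e+00
1.34916e-02 1.44346e+00 1.15409e+00 1.14896e+00 2.05404e-01 8.90934e-02 0.00000e+00
1.49117e-02 1.11139e+00 8.39708e-01 8.34103e-01 2.04360e-01 7.29319e-02 0.00000e+00
1.64813e-02 8.68452e-01 6.11651e-01 6.05529e-01 2.03222e-01 5.97021e-02 0.00000e+00
1.82161e-02 6.90447e-01 4.46271e-01 4.39592e-01 2.01983e-01 4.88721e-02 0.00000e+00
2.01336e-02 5.59772e-01 3.26406e-01 3.19128e-01 2.00637e-01 4.00067e-02 0.00000e+00
2.22528e-02 4.63603e-01 2.39595e-01 2.31676e-01 1.99178e-01 3.27495e-02 0.00000e+00
2.45951e-02 3.92594e-01 1.76793e-01 1.68188e-01 1.97597e-01 2.68088e-02 0.00000e+00
2.71839e-02 3.39932e-01 1.31434e-01 1.22099e-01 1.95888e-01 2.19457e-02 0.00000e+00
3.00453e-02 3.00649e-01 9.87506e-02 8.86392e-02 1.94045e-01 1.79647e-02 0.00000e+00
3.32078e-02 2.71117e-01 7.52807e-02 6.43489e-02 1.92062e-01 1.47059e-02 0.00000e+00
3.67033e-02 2.48686e-01 5.85110e-02 4.67150e-02 1.89932e-01 1.20383e-02 0.00000e+00
4.05666e-02 2.31420e-01 4.66157e-02 3.39134e-02 1.87652e-01 9.85455e-03 0.00000e+00
4.48366e-02 2.17904e-01 3.82682e-02 2.46199e-02 1.85217e-01 8.06694e-03 0.00000e+00
4.95560e-02 2.07100e-01 3.25039e-02 1.78732e-02 1.82624e-01 6.60360e-03 0.00000e+00
5.47723e-02 1.98252e-01 2.86206e-02 1.29753e-02 1.79871e-01 5.40571e-03 0.00000e+00
6.05375e-02 1.90803e-01 2.61068e-02 9.41958e-03 1.76959e-01 4.42512e-03 0.00000e+00
6.69096e-02 1.84348e-01 2.45887e-02 6.83828e-03 1.73888e-01 3.62240e-03 0.00000e+00
7.39525e-02 1.78591e-01 2.37925e-02 4.96435e-03 1.70661e-01 2.96530e-03 0.00000e+00
8.17366e-02 1.73315e-01 2.35170e-02 3.60394e-03 1.67284e-01 2.42740e-03 0.00000e+00
9.03401e-02 1.68367e-01 2.36134e-02 2.61633e-03 1.63763e-01 1.98707e-03 0.00000e+00
9.98492e-02 1.63633e-01 2.39709e-02 1.89936e-03 1.60107e-01 1.62661e-03 0.00000e+00
1.10359e-01 1.59037e-01 2.45066e-02 1.37887e-03 1.56327e-01 1.33155e-03 0.00000e+00
1.21976e-01 1.54524e-01 2.51579e-02 1.00101e-03 1.52433e-01 1.09001e-03 0.00000e+00
1.34815e-01 1.50059e-01 2.58770e-02 7.26696e-04 1.48440e-01 8.92279e-04 0.00000e+00
1.49005e-01 1.45621e-01 2.66271e-02 5.27555e-04 1.44363e-01 7.30420e-04 0.00000e+00
1.64689e-01 1.41197e-01 2.73799e-02 3.82986e-04 1.40216e-01 5.97922e-04 0.00000e+00
1.82024e-01 1.36784e-01 2.81135e-02 2.78034e-04 1.36017e-01 4.89459e-04 0.00000e+00
2.01184e-01 1.32383e-01 2.88107e-02 2.01843e-04 1.31780e-01 4.00672e-04 0.00000e+00
2.22360e-01 1.27998e-01 2.94586e-02 1.46531e-04 1.27523e-01 3.27990e-04 0.00000e+00
2.45765e-01 1.23635e-01 3.00469e-02 1.06376e-04 1.23260e-01 2.68493e-04 0.00000e+00
2.71634e-01 1.19303e-01 3.05683e-02 7.72252e-05 1.19006e-01 2.19788e-04 0.00000e+00
3.00226e-01 1.15010e-01 3.10171e-02 5.60627e-05 1.14774e-01 1.79919e-04 0.00000e+00
3.31828e-01 1.10763e-01 3.13893e-02 4.06995e-05 1.10575e-01 1.47282e-04 0.00000e+00
3.66756e-01 1.06571e-01 3.16824e-02 2.95464e-05 1.06421e-01 1.20565e-04 0.00000e+00
4.05360e-01 1.02440e-01 3.18946e-02 2.14496e-05 1.02320e-01 9.86943e-05 0.00000e+00
4.48028e-01 9.83755e-02 3.20251e-02 1.55717e-05 9.82791e-02 8.07912e-05 0.00000e+00
4.95187e-01 9.43828e-02 3.20735e-02 1.13045e-05 9.43054e-02 6.61357e-05 0.00000e+00
5.47310e-01 9.04659e-02 3.20402e-02 8.20663e-06 9.04035e-02 5.41387e-05 0.00000e+00
6.04919e-01 8.66277e-02 3.19260e-02 5.95772e-06 8.65775e-02 4.43180e-05 0.00000e+00
6.68592e-01 8.28710e-02 3.17321e-02 4.32509e-06 8.28304e-02 3.62787e-05 0.00000e+00
7.38967e-01 7.91979e-02 3.14602e-02 3.13986e-06 7.91650e-02 2.96978e-05 0.00000e+00
8.16750e-01 7.56101e-02 3.11125e-02 2.27943e-06 7.55835e-02 2.43106e-05 0.00000e+00
9.02720e-01 7.21092e-02 3.06918e-02 1.65478e-06 7.20876e-02 1.99007e-05 0.00000e+00
9.97739e-01 6.86967e-02 3.02014e-02 1.20131e-06 6.86792e-02 1.62907e-05 0.00000e+00
1.10276e+00 6.56522e-02 2.96653e-02 8.72110e-07 6.53598e-02 1.33356e-05 2.78174e-04
1.21884e+00 6.28206e-02 2.91362e-02 6.33120e-07 6.21311e-02 1.09165e-05 6.77978e-04
1.34713e+00 6.01238e-02 2.86219e-02 4.59623e-07 5.89946e-02 8.93626e-06 1.11986e-03
1.48893e+00 5.75677e-02 2.81292e-02 3.33669e-07 5.59518e-02 7.31523e-06 1.60826e-03
1.64565e+00 5.51585e-02 2.76661e-02 2.42232e-07 5.30042e-02 5.98825e-06 2.14807e-03
1.81887e+00 5.29031e-02 2.72414e-02 1.75852e-07 5.01533e-02 4.90198e-06 2.74470e-03
2.01032e+00 5.08084e-02 2.68651e-02 1.27662e-07 4.74002e-02 4.01277e-06 3.40413e-03
2.22192e+00 4.88823e-02 2.65482e-02 9.26781e-08 4.47459e-02 3.28485e-06 4.13297e-03
2.45580e+00 4.71327e-02 2.63022e-02 6.72810e-08 4.21914e-02 2.68898e-06 4.93852e-03
2.71430e+00 4.55682e-02 2.61397e-02 4.88436e-08 3.97371e-02 2.20120e-06 5.82887e-03
3.00000e+00 4.41979e-02 2.60742e-02 3.54587e-08 3.73832e-02 1.80190e-06 6.81293e-03
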