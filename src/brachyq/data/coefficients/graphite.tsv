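# graphite: photon mass interaction coefficients [cm^2/g]
# density 1.7 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 3.23211e+03 3.21721e+03 3.21721e+03 1.99347e-01 1.46989e+01 0.00000e+00
1.10526e-03 2.34781e+03 2.33558e+03 2.33558e+03 1.99266e-01 1.20325e+01 0.00000e+00
1.22160e-03 1.70560e+03 1.69555e+03 1.69555e+03 1.99176e-01 9.84982e+00 0.00000e+00
1.35018e-03 1.23917e+03 1.23091e+03 1.23091e+03 1.99076e-01 8.06306e+00 0.00000e+00
1.49230e-03 9.00393e+02 8.93594e+02 8.93594e+02 1.98967e-01 6.60043e+00 0.00000e+00
1.64938e-03 6.54319e+02 6.48718e+02 6.48717e+02 1.98846e-01 5.40311e+00 0.00000e+00
1.82299e-03 4.75567e+02 4.70946e+02 4.70945e+02 1.98712e-01 4.42299e+00 0.00000e+00
2.01488e-03 3.45709e+02 3.41890e+02 3.41889e+02 1.98565e-01 3.62066e+00 0.00000e+00
2.22696e-03 2.51362e+02 2.48200e+02 2.48199e+02 1.98402e-01 2.96388e+00 0.00000e+00
2.46137e-03 1.82808e+02 1.80185e+02 1.80184e+02 1.98223e-01 2.42623e+00 0.00000e+00
2.72045e-03 1.32991e+02 1.30808e+02 1.30807e+02 1.98025e-01 1.98611e+00 0.00000e+00
3.00680e-03 9.67848e+01 9.49623e+01 9.49612e+01 1.97807e-01 1.62583e+00 0.00000e+00
3.32329e-03 7.04669e+01 6.89397e+01 6.89384e+01 1.97567e-01 1.33091e+00 0.00000e+00
3.67310e-03 5.13336e+01 5.00482e+01 5.00468e+01 1.97303e-01 1.08948e+00 0.00000e+00
4.05972e-03 3.74211e+01 3.63337e+01 3.63322e+01 1.97011e-01 8.91850e-01 0.00000e+00
4.48704e-03 2.73026e+01 2.63776e+01 2.63759e+01 1.96691e-01 7.30069e-01 0.00000e+00
4.95934e-03 1.99419e+01 1.91498e+01 1.91479e+01 1.96338e-01 5.97635e-01 0.00000e+00
5.48136e-03 1.45859e+01 1.39028e+01 1.39007e+01 1.95950e-01 4.89224e-01 0.00000e+00
6.05832e-03 1.06874e+01 1.00937e+01 1.00914e+01 1.95523e-01 4.00479e-01 0.00000e+00
6.69601e-03 7.84889e+00 7.32849e+00 7.32601e+00 1.95055e-01 3.27832e-01 0.00000e+00
7.40083e-03 5.78132e+00 5.32115e+00 5.31842e+00 1.94540e-01 2.68364e-01 0.00000e+00
8.17983e-03 4.27464e+00 3.86398e+00 3.86098e+00 1.93976e-01 2.19683e-01 0.00000e+00
9.04083e-03 3.17612e+00 2.80623e+00 2.80293e+00 1.93357e-01 1.79832e-01 0.00000e+00
9.99246e-03 2.37472e+00 2.03844e+00 2.03483e+00 1.92679e-01 1.47211e-01 0.00000e+00
1.10443e-02 1.78966e+00 1.48117e+00 1.47721e+00 1.91937e-01 1.20507e-01 0.00000e+00
1.22068e-02 1.36218e+00 1.07674e+00 1.07240e+00 1.91125e-01 9.86469e-02 0.00000e+00
1.34916e-02 1.04952e+00 7.83274e-01 7.78526e-01 1.90239e-01 8.07524e-02 0.00000e+00
1.49117e-02 8.20557e-01 5.70373e-01 5.65182e-01 1.89271e-01 6.61039e-02 0.00000e+00
1.64813e-02 6.52632e-01 4.15972e-01 4.10302e-01 1.88217e-01 5.41127e-02 0.00000e+00
1.82161e-02 5.29231e-01 3.04050e-01 2.97865e-01 1.87070e-01 4.42967e-02 0.00000e+00
2.01336e-02 4.38324e-01 2.22979e-01 2.16239e-01 1.85824e-01 3.62613e-02 0.00000e+00
2.22528e-02 3.71137e-01 1.64316e-01 1.56982e-01 1.84472e-01 2.96835e-02 0.00000e+00
2.45951e-02 3.21270e-01 1.21933e-01 1.13963e-01 1.83008e-01 2.42989e-02 0.00000e+00
2.71839e-02 2.84049e-01 9.13796e-02 8.27331e-02 1.81425e-01 1.98911e-02 0.00000e+00
3.00453e-02 2.56062e-01 6.94262e-02 6.00613e-02 1.79718e-01 1.62829e-02 0.00000e+00
3.32078e-02 2.34813e-01 5.37271e-02 4.36023e-02 1.77881e-01 1.33292e-02 0.00000e+00
3.67033e-02 2.18474e-01 4.25788e-02 3.16537e-02 1.75909e-01 1.09113e-02 0.00000e+00
4.05666e-02 2.05709e-01 3.47440e-02 2.29795e-02 1.73797e-01 8.93197e-03 0.00000e+00
4.48366e-02 1.95536e-01 2.93229e-02 1.66823e-02 1.71542e-01 7.31171e-03 0.00000e+00
4.95560e-02 1.87236e-01 2.56612e-02 1.21107e-02 1.69140e-01 5.98537e-03 0.00000e+00
5.47723e-02 1.80282e-01 2.32822e-02 8.79196e-03 1.66591e-01 4.89963e-03 0.00000e+00
6.05375e-02 1.74287e-01 2.18378e-02 6.38264e-03 1.63893e-01 4.01084e-03 0.00000e+00
6.69096e-02 1.68966e-01 2.10734e-02 4.63357e-03 1.61049e-01 3.28327e-03 0.00000e+00
7.39525e-02 1.64112e-01 2.08018e-02 3.36381e-03 1.58061e-01 2.68769e-03 0.00000e+00
8.17366e-02 1.59575e-01 2.08848e-02 2.44200e-03 1.54933e-01 2.20014e-03 0.00000e+00
9.03401e-02 1.55246e-01 2.12196e-02 1.77281e-03 1.51672e-01 1.80104e-03 0.00000e+00
9.98492e-02 1.51047e-01 2.17289e-02 1.28699e-03 1.48286e-01 1.47433e-03 0.00000e+00
1.10359e-01 1.46926e-01 2.23545e-02 9.34311e-04 1.44784e-01 1.20689e-03 0.00000e+00
1.21976e-01 1.42845e-01 2.30516e-02 6.78276e-04 1.41178e-01 9.87959e-04 0.00000e+00
1.34815e-01 1.38781e-01 2.37858e-02 4.92404e-04 1.37480e-01 8.08743e-04 0.00000e+00
1.49005e-01 1.34723e-01 2.45300e-02 3.57468e-04 1.33704e-01 6.62038e-04 0.00000e+00
1.64689e-01 1.30665e-01 2.52632e-02 2.59509e-04 1.29864e-01 5.41944e-04 0.00000e+00
1.82024e-01 1.26606e-01 2.59686e-02 1.88394e-04 1.25974e-01 4.43636e-04 0.00000e+00
2.01184e-01 1.22551e-01 2.66334e-02 1.36767e-04 1.22051e-01 3.63160e-04 0.00000e+00
2.22360e-01 1.18504e-01 2.72471e-02 9.92882e-05 1.18108e-01 2.97283e-04 0.00000e+00
2.45765e-01 1.14475e-01 2.78020e-02 7.20797e-05 1.14159e-01 2.43356e-04 0.00000e+00
2.71634e-01 1.10471e-01 2.82921e-02 5.23272e-05 1.10219e-01 1.99212e-04 0.00000e+00
3.00226e-01 1.06500e-01 2.87130e-02 3.79877e-05 1.06299e-01 1.63075e-04 0.00000e+00
3.31828e-01 1.02572e-01 2.90616e-02 2.75777e-05 1.02411e-01 1.33493e-04 0.00000e+00
3.66756e-01 9.86927e-02 2.93359e-02 2.00204e-05 9.85634e-02 1.09277e-04 0.00000e+00
4.05360e-01 9.48690e-02 2.95344e-02 1.45341e-05 9.47650e-02 8.94545e-05 0.00000e+00
4.48028e-01 9.11066e-02 2.96567e-02 1.05512e-05 9.10228e-02 7.32275e-05 0.00000e+00
4.95187e-01 8.74101e-02 2.97026e-02 7.65982e-06 8.73425e-02 5.99441e-05 0.00000e+00
5.47310e-01 8.37834e-02 2.96725e-02 5.56076e-06 8.37287e-02 4.90702e-05 0.00000e+00
6.04919e-01 8.02294e-02 2.95673e-02 4.03691e-06 8.01852e-02 4.01689e-05 0.00000e+00
6.68592e-01 7.67506e-02 2.93881e-02 2.93065e-06 7.67148e-02 3.28823e-05 0.00000e+00
7.38967e-01 7.33491e-02 2.91366e-02 2.12755e-06 7.33200e-02 2.69175e-05 0.00000e+00
8.16750e-01 7.00265e-02 2.88148e-02 1.54452e-06 7.00029e-02 2.20346e-05 0.00000e+00
9.02720e-01 6.67843e-02 2.84254e-02 1.12127e-06 6.67652e-02 1.80376e-05 0.00000e+00
9.97739e-01 6.36240e-02 2.79712e-02 8.14001e-07 6.36084e-02 1.47656e-05 0.00000e+00
1.10276e+00 6.08109e-02 2.74753e-02 5.90935e-07 6.05341e-02 1.20871e-05 2.64154e-04
1.21884e+00 5.81979e-02 2.69874e-02 4.28998e-07 5.75437e-02 9.89450e-06 6.43808e-04
1.34713e+00 5.57106e-02 2.65149e-02 3.11437e-07 5.46388e-02 8.09964e-06 1.06342e-03
1.48893e+00 5.33548e-02 2.60641e-02 2.26092e-07 5.18207e-02 6.63037e-06 1.52721e-03
1.64565e+00 5.11362e-02 2.56424e-02 1.64135e-07 4.90908e-02 5.42763e-06 2.03981e-03
1.81887e+00 4.90612e-02 2.52582e-02 1.19156e-07 4.64503e-02 4.44306e-06 2.60637e-03
2.01032e+00 4.71367e-02 2.49208e-02 8.65029e-08 4.39005e-02 3.63709e-06 3.23256e-03
2.22192e+00 4.53699e-02 2.46403e-02 6.27980e-08 4.14422e-02 2.97732e-06 3.92467e-03
2.45580e+00 4.37684e-02 2.44278e-02 4.55891e-08 3.90763e-02 2.43724e-06 4.68962e-03
2.71430e+00 4.23403e-02 2.42949e-02 3.30961e-08 3.68031e-02 1.99512e-06 5.53510e-03
3.00000e+00 4.10943e-02 2.42543e-02 2.40266e-08 3.46230e-02 1.63321e-06 6.46956e-03
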