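# spc: photon mass interaction coefficients [cm^2/g]
# density 8.3 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 9.73266e+05 9.73117e+05 9.73117e+05 1.83149e-01 1.48785e+02 0.00000e+00
1.10526e-03 7.06570e+05 7.06448e+05 7.06448e+05 1.83074e-01 1.21795e+02 0.00000e+00
1.22160e-03 5.12956e+05 5.12856e+05 5.12856e+05 1.82992e-01 9.97015e+01 0.00000e+00
1.35018e-03 3.72397e+05 3.72315e+05 3.72315e+05 1.82900e-01 8.16157e+01 0.00000e+00
1.49230e-03 2.70354e+05 2.70287e+05 2.70287e+05 1.82800e-01 6.68106e+01 0.00000e+00
1.64938e-03 1.96274e+05 1.96219e+05 1.96219e+05 1.82688e-01 5.46912e+01 0.00000e+00
1.82299e-03 1.42493e+05 1.42448e+05 1.42448e+05 1.82566e-01 4.47703e+01 0.00000e+00
2.01488e-03 1.03449e+05 1.03412e+05 1.03412e+05 1.82430e-01 3.66490e+01 0.00000e+00
2.22696e-03 7.51036e+04 7.50734e+04 7.50734e+04 1.82281e-01 3.00008e+01 0.00000e+00
2.46137e-03 5.45254e+04 5.45006e+04 5.45006e+04 1.82116e-01 2.45587e+01 0.00000e+00
2.72045e-03 3.95858e+04 3.95655e+04 3.95655e+04 1.81934e-01 2.01038e+01 0.00000e+00
3.00680e-03 2.87398e+04 2.87231e+04 2.87231e+04 1.81734e-01 1.64570e+01 0.00000e+00
3.32329e-03 2.08656e+04 2.08520e+04 2.08520e+04 1.81514e-01 1.34717e+01 0.00000e+00
3.67310e-03 1.51490e+04 1.51378e+04 1.51378e+04 1.81271e-01 1.10279e+01 0.00000e+00
4.05972e-03 1.09987e+04 1.09895e+04 1.09895e+04 1.81003e-01 9.02746e+00 0.00000e+00
4.48704e-03 7.98554e+03 7.97797e+03 7.97797e+03 1.80708e-01 7.38988e+00 0.00000e+00
4.95934e-03 5.79795e+03 5.79172e+03 5.79172e+03 1.80384e-01 6.04936e+00 0.00000e+00
5.48136e-03 4.20971e+03 4.20458e+03 4.20458e+03 1.80028e-01 4.95201e+00 0.00000e+00
6.05832e-03 3.05661e+03 3.05238e+03 3.05237e+03 1.79636e-01 4.05372e+00 0.00000e+00
6.69601e-03 2.21941e+03 2.21592e+03 2.21591e+03 1.79206e-01 3.31837e+00 0.00000e+00
7.40083e-03 1.61157e+03 1.60868e+03 1.60867e+03 1.78733e-01 2.71642e+00 0.00000e+00
8.17983e-03 1.17024e+03 1.16784e+03 1.16784e+03 1.78214e-01 2.22366e+00 0.00000e+00
9.04083e-03 8.49808e+02 8.47813e+02 8.47810e+02 1.77646e-01 1.82029e+00 0.00000e+00
9.99246e-03 6.17147e+02 6.15483e+02 6.15479e+02 1.77023e-01 1.49009e+00 0.00000e+00
1.10443e-02 4.48212e+02 4.46820e+02 4.46816e+02 1.76341e-01 1.21979e+00 0.00000e+00
1.22068e-02 3.25546e+02 3.24376e+02 3.24372e+02 1.75595e-01 9.98521e-01 0.00000e+00
1.34916e-02 2.36475e+02 2.35487e+02 2.35483e+02 1.74781e-01 8.17389e-01 0.00000e+00
1.49117e-02 1.71795e+02 1.70957e+02 1.70952e+02 1.73892e-01 6.69115e-01 0.00000e+00
1.64813e-02 1.24826e+02 1.24110e+02 1.24105e+02 1.72923e-01 5.47738e-01 0.00000e+00
1.82161e-02 9.07160e+01 9.01015e+01 9.00958e+01 1.71870e-01 4.48379e-01 0.00000e+00
2.01336e-02 6.59441e+01 6.54125e+01 6.54063e+01 1.70725e-01 3.67043e-01 0.00000e+00
2.22528e-02 4.79526e+01 4.74894e+01 4.74826e+01 1.69482e-01 3.00462e-01 0.00000e+00
2.45951e-02 3.48848e+01 3.44780e+01 3.44707e+01 1.68137e-01 2.45958e-01 0.00000e+00
2.71839e-02 2.53925e+01 2.50324e+01 2.50245e+01 1.66683e-01 2.01341e-01 0.00000e+00
3.00453e-02 1.84968e+01 1.81755e+01 1.81669e+01 1.65115e-01 1.64818e-01 0.00000e+00
3.32078e-02 1.34868e+01 1.31978e+01 1.31885e+01 1.63427e-01 1.34920e-01 0.00000e+00
3.67033e-02 9.84644e+00 9.58441e+00 9.57438e+00 1.61616e-01 1.10446e-01 0.00000e+00
4.05666e-02 7.20074e+00 6.96146e+00 6.95065e+00 1.59675e-01 9.04109e-02 0.00000e+00
4.48366e-02 5.27754e+00 5.05754e+00 5.04592e+00 1.57603e-01 7.40104e-02 0.00000e+00
4.95560e-02 3.87914e+00 3.67561e+00 3.66316e+00 1.55396e-01 6.05849e-02 0.00000e+00
5.47723e-02 2.86197e+00 2.67264e+00 2.65932e+00 1.53054e-01 4.95948e-02 0.00000e+00
6.05375e-02 2.12175e+00 1.94477e+00 1.93057e+00 1.50576e-01 4.05984e-02 0.00000e+00
6.69096e-02 1.58272e+00 1.41663e+00 1.40153e+00 1.47963e-01 3.32338e-02 0.00000e+00
7.39525e-02 1.18988e+00 1.03348e+00 1.01746e+00 1.45217e-01 2.72052e-02 0.00000e+00
8.17366e-02 9.03252e-01 7.55582e-01 7.38638e-01 1.42344e-01 2.22702e-02 0.00000e+00
9.03401e-02 6.93803e-01 5.54091e-01 5.36225e-01 1.39348e-01 1.82304e-02 0.00000e+00
9.98492e-02 5.40440e-01 4.08061e-01 3.89280e-01 1.36237e-01 1.49234e-02 0.00000e+00
1.10359e-01 4.27839e-01 3.02283e-01 2.82603e-01 1.33020e-01 1.22163e-02 0.00000e+00
1.21976e-01 3.44867e-01 2.25715e-01 2.05160e-01 1.29707e-01 1.00003e-02 0.00000e+00
1.34815e-01 2.83434e-01 1.70339e-01 1.48939e-01 1.26309e-01 8.18624e-03 0.00000e+00
1.49005e-01 2.37665e-01 1.30332e-01 1.08124e-01 1.22840e-01 6.70126e-03 0.00000e+00
1.64689e-01 2.03291e-01 1.01466e-01 7.84942e-02 1.19312e-01 5.48565e-03 0.00000e+00
1.82024e-01 1.77213e-01 8.06695e-02 5.69840e-02 1.15738e-01 4.49056e-03 0.00000e+00
2.01184e-01 1.57178e-01 6.57119e-02 4.13683e-02 1.12133e-01 3.67597e-03 0.00000e+00
2.22360e-01 1.41552e-01 5.49738e-02 3.00319e-02 1.08511e-01 3.00915e-03 0.00000e+00
2.45765e-01 1.29149e-01 4.72788e-02 2.18021e-02 1.04883e-01 2.46329e-03 0.00000e+00
2.71634e-01 1.19107e-01 4.17727e-02 1.58275e-02 1.01263e-01 2.01645e-03 0.00000e+00
3.00226e-01 1.10803e-01 3.78353e-02 1.14902e-02 9.76620e-02 1.65067e-03 0.00000e+00
3.31828e-01 1.03782e-01 3.50164e-02 8.34149e-03 9.40895e-02 1.35124e-03 0.00000e+00
3.66756e-01 9.77163e-02 3.29894e-02 6.05562e-03 9.05546e-02 1.10612e-03 0.00000e+00
4.05360e-01 9.23665e-02 3.15174e-02 4.39617e-03 8.70648e-02 9.05474e-04 0.00000e+00
4.48028e-01 8.75594e-02 3.04287e-02 3.19146e-03 8.36267e-02 7.41221e-04 0.00000e+00
4.95187e-01 8.31691e-02 2.95989e-02 2.31688e-03 8.02455e-02 6.06764e-04 0.00000e+00
5.47310e-01 7.91040e-02 2.89383e-02 1.68197e-03 7.69253e-02 4.96697e-04 0.00000e+00
6.04919e-01 7.52973e-02 2.83821e-02 1.22105e-03 7.36697e-02 4.06597e-04 0.00000e+00
6.68592e-01 7.17006e-02 2.78839e-02 8.86441e-04 7.04813e-02 3.32840e-04 0.00000e+00
7.38967e-01 6.82784e-02 2.74106e-02 6.43524e-04 6.73624e-02 2.72463e-04 0.00000e+00
8.16750e-01 6.50050e-02 2.69392e-02 4.67176e-04 6.43148e-02 2.23038e-04 0.00000e+00
9.02720e-01 6.18619e-02 2.64538e-02 3.39153e-04 6.13401e-02 1.82579e-04 0.00000e+00
9.97739e-01 5.88355e-02 2.59439e-02 2.46213e-04 5.84399e-02 1.49460e-04 0.00000e+00
1.10276e+00 5.71047e-02 2.54902e-02 1.78742e-04 5.56154e-02 1.22348e-04 1.18824e-03
1.21884e+00 5.59940e-02 2.52961e-02 1.29760e-04 5.28680e-02 1.00154e-04 2.89604e-03
1.34713e+00 5.51589e-02 2.53731e-02 9.42011e-05 5.01991e-02 8.19860e-05 4.78360e-03
1.48893e+00 5.46153e-02 2.57288e-02 6.83866e-05 4.76100e-02 6.71138e-05 6.86985e-03
1.64565e+00 5.43821e-02 2.63754e-02 4.96462e-05 4.51019e-02 5.49393e-05 9.17568e-03
1.81887e+00 5.44812e-02 2.73292e-02 3.60414e-05 4.26760e-02 4.49734e-05 1.17242e-02
2.01032e+00 5.49373e-02 2.86106e-02 2.61647e-05 4.03333e-02 3.68152e-05 1.45410e-02
2.22192e+00 5.57783e-02 3.02439e-02 1.89947e-05 3.80748e-02 3.01370e-05 1.76543e-02
2.45580e+00 5.70349e-02 3.22575e-02 1.37894e-05 3.59011e-02 2.46701e-05 2.10953e-02
2.71430e+00 5.87414e-02 3.46839e-02 1.00106e-05 3.38127e-02 2.01950e-05 2.48985e-02
3.00000e+00 6.09356e-02 3.75597e-02 7.26737e-06 3.18097e-02 1.65316e-05 2.91021e-02
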