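# c552: photon mass interaction coefficients [cm^2/g]
# density 1.76 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 7.78832e+03 7.76847e+03 7.76847e+03 1.99406e-01 1.96457e+01 0.00000e+00
1.10526e-03 5.65591e+03 5.63963e+03 5.63963e+03 1.99325e-01 1.60820e+01 0.00000e+00
1.22160e-03 4.10753e+03 4.09417e+03 4.09417e+03 1.99235e-01 1.31647e+01 0.00000e+00
1.35018e-03 2.98320e+03 2.97222e+03 2.97222e+03 1.99135e-01 1.07767e+01 0.00000e+00
1.49230e-03 2.16675e+03 2.15773e+03 2.15773e+03 1.99025e-01 8.82177e+00 0.00000e+00
1.64938e-03 1.57385e+03 1.56643e+03 1.56643e+03 1.98904e-01 7.22151e+00 0.00000e+00
1.82299e-03 1.14328e+03 1.13717e+03 1.13717e+03 1.98771e-01 5.91153e+00 0.00000e+00
2.01488e-03 8.30585e+02 8.25548e+02 8.25547e+02 1.98623e-01 4.83918e+00 0.00000e+00
2.22696e-03 6.03477e+02 5.99318e+02 5.99317e+02 1.98461e-01 3.96135e+00 0.00000e+00
2.46137e-03 4.38524e+02 4.35084e+02 4.35083e+02 1.98281e-01 3.24277e+00 0.00000e+00
2.72045e-03 3.18707e+02 3.15856e+02 3.15855e+02 1.98083e-01 2.65453e+00 0.00000e+00
3.00680e-03 2.31670e+02 2.29300e+02 2.29299e+02 1.97865e-01 2.17300e+00 0.00000e+00
3.32329e-03 1.68439e+02 1.66464e+02 1.66463e+02 1.97625e-01 1.77882e+00 0.00000e+00
3.67310e-03 1.22500e+02 1.20847e+02 1.20846e+02 1.97361e-01 1.45614e+00 0.00000e+00
4.05972e-03 8.91190e+01 8.77315e+01 8.77299e+01 1.97069e-01 1.19200e+00 0.00000e+00
4.48704e-03 6.48613e+01 6.36905e+01 6.36888e+01 1.96749e-01 9.75770e-01 0.00000e+00
4.95934e-03 4.72309e+01 4.62376e+01 4.62358e+01 1.96396e-01 7.98766e-01 0.00000e+00
5.48136e-03 3.44154e+01 3.35676e+01 3.35655e+01 1.96008e-01 6.53870e-01 0.00000e+00
6.05832e-03 2.50982e+01 2.43696e+01 2.43674e+01 1.95581e-01 5.35258e-01 0.00000e+00
6.69601e-03 1.83231e+01 1.76923e+01 1.76898e+01 1.95112e-01 4.38163e-01 0.00000e+00
7.40083e-03 1.33955e+01 1.28449e+01 1.28422e+01 1.94598e-01 3.58680e-01 0.00000e+00
8.17983e-03 9.81061e+00 9.32596e+00 9.32296e+00 1.94033e-01 2.93616e-01 0.00000e+00
9.04083e-03 7.20190e+00 6.77143e+00 6.76813e+00 1.93414e-01 2.40354e-01 0.00000e+00
9.99246e-03 5.30291e+00 4.91704e+00 4.91342e+00 1.92736e-01 1.96754e-01 0.00000e+00
1.10443e-02 3.92002e+00 3.57093e+00 3.56697e+00 1.91993e-01 1.61063e-01 0.00000e+00
1.22068e-02 2.91252e+00 2.59383e+00 2.58949e+00 1.91181e-01 1.31846e-01 0.00000e+00
1.34916e-02 2.17810e+00 1.88463e+00 1.87988e+00 1.90295e-01 1.07929e-01 0.00000e+00
1.49117e-02 1.64240e+00 1.36992e+00 1.36472e+00 1.89327e-01 8.83509e-02 0.00000e+00
1.64813e-02 1.25134e+00 9.96412e-01 9.90740e-01 1.88273e-01 7.23241e-02 0.00000e+00
1.82161e-02 9.65572e-01 7.25429e-01 7.19242e-01 1.87125e-01 5.92046e-02 0.00000e+00
2.01336e-02 7.56487e-01 5.28886e-01 5.22144e-01 1.85879e-01 4.84649e-02 0.00000e+00
2.22528e-02 6.03257e-01 3.86394e-01 3.79058e-01 1.84526e-01 3.96734e-02 0.00000e+00
2.45951e-02 4.90720e-01 2.83154e-01 2.75182e-01 1.83062e-01 3.24766e-02 0.00000e+00
2.71839e-02 4.07836e-01 2.08421e-01 1.99772e-01 1.81479e-01 2.65854e-02 0.00000e+00
3.00453e-02 3.46562e-01 1.54395e-01 1.45028e-01 1.79771e-01 2.17628e-02 0.00000e+00
3.32078e-02 3.01034e-01 1.15413e-01 1.05285e-01 1.77934e-01 1.78150e-02 0.00000e+00
3.67033e-02 2.66977e-01 8.73613e-02 7.64330e-02 1.75961e-01 1.45834e-02 0.00000e+00
4.05666e-02 2.41274e-01 6.72556e-02 5.54876e-02 1.73848e-01 1.19380e-02 0.00000e+00
4.48366e-02 2.21647e-01 5.29264e-02 4.02820e-02 1.71592e-01 9.77244e-03 0.00000e+00
4.95560e-02 2.06433e-01 4.27978e-02 2.92433e-02 1.69190e-01 7.99972e-03 0.00000e+00
5.47723e-02 1.94418e-01 3.57241e-02 2.12296e-02 1.66640e-01 6.54857e-03 0.00000e+00
6.05375e-02 1.84714e-01 3.08716e-02 1.54119e-02 1.63941e-01 5.36067e-03 0.00000e+00
6.69096e-02 1.76673e-01 2.76332e-02 1.11885e-02 1.61096e-01 4.38824e-03 0.00000e+00
7.39525e-02 1.69822e-01 2.55656e-02 8.12245e-03 1.58107e-01 3.59222e-03 0.00000e+00
8.17366e-02 1.63816e-01 2.43449e-02 5.89661e-03 1.54979e-01 2.94059e-03 0.00000e+00
9.03401e-02 1.58405e-01 2.37332e-02 4.28073e-03 1.51717e-01 2.40717e-03 0.00000e+00
9.98492e-02 1.53408e-01 2.35556e-02 3.10765e-03 1.48330e-01 1.97051e-03 0.00000e+00
1.10359e-01 1.48696e-01 2.36825e-02 2.25604e-03 1.44827e-01 1.61306e-03 0.00000e+00
1.21976e-01 1.44178e-01 2.40177e-02 1.63781e-03 1.41220e-01 1.32045e-03 0.00000e+00
1.34815e-01 1.39791e-01 2.44892e-02 1.18899e-03 1.37521e-01 1.08092e-03 0.00000e+00
1.49005e-01 1.35491e-01 2.50428e-02 8.63164e-04 1.33743e-01 8.84843e-04 0.00000e+00
1.64689e-01 1.31253e-01 2.56377e-02 6.26626e-04 1.29902e-01 7.24333e-04 0.00000e+00
1.82024e-01 1.27059e-01 2.62428e-02 4.54908e-04 1.26011e-01 5.92939e-04 0.00000e+00
2.01184e-01 1.22902e-01 2.68347e-02 3.30247e-04 1.22087e-01 4.85381e-04 0.00000e+00
2.22360e-01 1.18780e-01 2.73956e-02 2.39747e-04 1.18142e-01 3.97333e-04 0.00000e+00
2.45765e-01 1.14692e-01 2.79122e-02 1.74048e-04 1.14193e-01 3.25257e-04 0.00000e+00
2.71634e-01 1.10644e-01 2.83745e-02 1.26353e-04 1.10252e-01 2.66255e-04 0.00000e+00
3.00226e-01 1.06640e-01 2.87752e-02 9.17274e-05 1.06331e-01 2.17957e-04 0.00000e+00
3.31828e-01 1.02686e-01 2.91092e-02 6.65908e-05 1.02441e-01 1.78419e-04 0.00000e+00
3.66756e-01 9.87868e-02 2.93728e-02 4.83425e-05 9.85924e-02 1.46054e-04 0.00000e+00
4.05360e-01 9.49476e-02 2.95637e-02 3.50949e-05 9.47930e-02 1.19560e-04 0.00000e+00
4.48028e-01 9.11730e-02 2.96804e-02 2.54777e-05 9.10497e-02 9.78719e-05 0.00000e+00
4.95187e-01 8.74669e-02 2.97222e-02 1.84959e-05 8.73683e-02 8.01180e-05 0.00000e+00
5.47310e-01 8.38324e-02 2.96891e-02 1.34273e-05 8.37534e-02 6.55846e-05 0.00000e+00
6.04919e-01 8.02722e-02 2.95817e-02 9.74777e-06 8.02088e-02 5.36876e-05 0.00000e+00
6.68592e-01 7.67884e-02 2.94009e-02 7.07653e-06 7.67374e-02 4.39487e-05 0.00000e+00
7.38967e-01 7.33828e-02 2.91482e-02 5.13731e-06 7.33417e-02 3.59764e-05 0.00000e+00
8.16750e-01 7.00567e-02 2.88255e-02 3.72950e-06 7.00235e-02 2.94503e-05 0.00000e+00
9.02720e-01 6.68117e-02 2.84353e-02 2.70748e-06 6.67848e-02 2.41080e-05 0.00000e+00
9.97739e-01 6.36488e-02 2.79806e-02 1.96554e-06 6.36271e-02 1.97349e-05 0.00000e+00
1.10276e+00 6.08830e-02 2.74878e-02 1.42691e-06 6.05519e-02 1.61550e-05 3.13507e-04
1.21884e+00 5.83391e-02 2.70154e-02 1.03588e-06 5.75607e-02 1.32245e-05 7.64095e-04
1.34713e+00 5.59286e-02 2.65710e-02 7.52015e-07 5.46549e-02 1.08255e-05 1.26211e-03
1.48893e+00 5.36579e-02 2.61615e-02 5.45936e-07 5.18360e-02 8.86180e-06 1.81255e-03
1.64565e+00 5.15338e-02 2.57944e-02 3.96330e-07 4.91052e-02 7.25427e-06 2.42092e-03
1.81887e+00 4.95636e-02 2.54788e-02 2.87721e-07 4.64640e-02 5.93835e-06 3.09333e-03
2.01032e+00 4.77550e-02 2.52247e-02 2.08875e-07 4.39134e-02 4.86113e-06 3.83652e-03
2.22192e+00 4.61165e-02 2.50430e-02 1.51636e-07 4.14544e-02 3.97933e-06 4.65794e-03
2.45580e+00 4.46570e-02 2.49458e-02 1.10082e-07 3.90878e-02 3.25748e-06 5.56581e-03
2.71430e+00 4.33860e-02 2.49459e-02 7.99158e-08 3.68140e-02 2.66657e-06 6.56925e-03
3.00000e+00 4.23138e-02 2.50572e-02 5.80160e-08 3.46333e-02 2.18286e-06 7.67831e-03
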