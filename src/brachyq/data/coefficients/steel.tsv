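# steel: photon mass interaction coefficients [cm^2/g]
# density 7.9 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 5.67269e+05 5.67141e+05 5.67141e+05 1.84862e-01 1.28030e+02 0.00000e+00
1.10526e-03 4.11829e+05 4.11724e+05 4.11724e+05 1.84786e-01 1.04806e+02 0.00000e+00
1.22160e-03 2.98983e+05 2.98897e+05 2.98897e+05 1.84703e-01 8.57939e+01 0.00000e+00
1.35018e-03 2.17059e+05 2.16988e+05 2.16988e+05 1.84610e-01 7.02309e+01 0.00000e+00
1.49230e-03 1.57583e+05 1.57526e+05 1.57526e+05 1.84509e-01 5.74911e+01 0.00000e+00
1.64938e-03 1.14405e+05 1.14358e+05 1.14358e+05 1.84396e-01 4.70622e+01 0.00000e+00
1.82299e-03 8.30585e+04 8.30198e+04 8.30198e+04 1.84272e-01 3.85251e+01 0.00000e+00
2.01488e-03 6.03011e+04 6.02694e+04 6.02694e+04 1.84136e-01 3.15367e+01 0.00000e+00
2.22696e-03 4.37794e+04 4.37534e+04 4.37534e+04 1.83985e-01 2.58160e+01 0.00000e+00
2.46137e-03 3.17847e+04 3.17634e+04 3.17634e+04 1.83819e-01 2.11329e+01 0.00000e+00
2.72045e-03 2.30766e+04 2.30591e+04 2.30591e+04 1.83635e-01 1.72994e+01 0.00000e+00
3.00680e-03 1.67544e+04 1.67401e+04 1.67401e+04 1.83433e-01 1.41613e+01 0.00000e+00
3.32329e-03 1.21645e+04 1.21527e+04 1.21527e+04 1.83211e-01 1.15925e+01 0.00000e+00
3.67310e-03 8.83209e+03 8.82242e+03 8.82242e+03 1.82965e-01 9.48960e+00 0.00000e+00
4.05972e-03 6.41271e+03 6.40476e+03 6.40476e+03 1.82695e-01 7.76819e+00 0.00000e+00
4.48704e-03 4.65617e+03 4.64963e+03 4.64963e+03 1.82398e-01 6.35905e+00 0.00000e+00
4.95934e-03 3.38085e+03 3.37546e+03 3.37546e+03 1.82071e-01 5.20552e+00 0.00000e+00
5.48136e-03 2.45491e+03 2.45047e+03 2.45046e+03 1.81711e-01 4.26124e+00 0.00000e+00
6.05832e-03 1.78262e+03 1.77895e+03 1.77895e+03 1.81316e-01 3.48825e+00 0.00000e+00
6.69601e-03 1.29449e+03 1.29146e+03 1.29145e+03 1.80881e-01 2.85548e+00 0.00000e+00
7.40083e-03 9.40066e+02 9.37551e+02 9.37548e+02 1.80404e-01 2.33750e+00 0.00000e+00
8.17983e-03 6.82720e+02 6.80629e+02 6.80627e+02 1.79880e-01 1.91348e+00 0.00000e+00
9.04083e-03 4.95856e+02 4.94113e+02 4.94110e+02 1.79307e-01 1.56637e+00 0.00000e+00
9.99246e-03 3.60167e+02 3.58710e+02 3.58706e+02 1.78678e-01 1.28224e+00 0.00000e+00
1.10443e-02 2.61636e+02 2.60412e+02 2.60408e+02 1.77989e-01 1.04964e+00 0.00000e+00
1.22068e-02 1.90083e+02 1.89051e+02 1.89047e+02 1.77237e-01 8.59234e-01 0.00000e+00
1.34916e-02 1.38121e+02 1.37246e+02 1.37241e+02 1.76415e-01 7.03370e-01 0.00000e+00
1.49117e-02 1.00384e+02 9.96370e+01 9.96322e+01 1.75518e-01 5.75779e-01 0.00000e+00
1.64813e-02 7.29753e+01 7.23347e+01 7.23294e+01 1.74540e-01 4.71333e-01 0.00000e+00
1.82161e-02 5.30679e+01 5.25143e+01 5.25086e+01 1.73477e-01 3.85833e-01 0.00000e+00
2.01336e-02 3.86075e+01 3.81256e+01 3.81193e+01 1.72321e-01 3.15843e-01 0.00000e+00
2.22528e-02 2.81029e+01 2.76801e+01 2.76733e+01 1.71067e-01 2.58549e-01 0.00000e+00
2.45951e-02 2.04712e+01 2.00972e+01 2.00898e+01 1.69709e-01 2.11649e-01 0.00000e+00
2.71839e-02 1.49260e+01 1.45925e+01 1.45845e+01 1.68242e-01 1.73256e-01 0.00000e+00
3.00453e-02 1.08963e+01 1.05965e+01 1.05878e+01 1.66659e-01 1.41827e-01 0.00000e+00
3.32078e-02 7.96742e+00 7.69575e+00 7.68636e+00 1.64955e-01 1.16100e-01 0.00000e+00
3.67033e-02 5.83819e+00 5.59016e+00 5.58002e+00 1.63127e-01 9.50393e-02 0.00000e+00
4.05666e-02 4.28986e+00 4.06181e+00 4.05090e+00 1.61168e-01 7.77992e-02 0.00000e+00
4.48366e-02 3.16357e+00 2.95253e+00 2.94081e+00 1.59077e-01 6.36865e-02 0.00000e+00
4.95560e-02 2.34390e+00 2.14749e+00 2.13492e+00 1.56849e-01 5.21338e-02 0.00000e+00
5.47723e-02 1.74704e+00 1.56331e+00 1.54988e+00 1.54485e-01 4.26767e-02 0.00000e+00
6.05375e-02 1.31207e+00 1.13949e+00 1.12515e+00 1.51984e-01 3.49352e-02 0.00000e+00
6.69096e-02 9.94765e-01 8.32066e-01 8.16821e-01 1.49346e-01 2.85980e-02 0.00000e+00
7.39525e-02 7.62968e-01 6.09154e-01 5.92983e-01 1.46575e-01 2.34103e-02 0.00000e+00
8.17366e-02 5.93323e-01 4.47587e-01 4.30484e-01 1.43675e-01 1.91637e-02 0.00000e+00
9.03401e-02 4.68854e-01 3.30550e-01 3.12516e-01 1.40651e-01 1.56874e-02 0.00000e+00
9.98492e-02 3.77228e-01 2.45832e-01 2.26876e-01 1.37511e-01 1.28417e-02 0.00000e+00
1.10359e-01 3.09479e-01 1.84567e-01 1.64703e-01 1.34264e-01 1.05122e-02 0.00000e+00
1.21976e-01 2.59094e-01 1.40316e-01 1.19569e-01 1.30920e-01 8.60532e-03 0.00000e+00
1.34815e-01 2.21337e-01 1.08403e-01 8.68027e-02 1.27490e-01 7.04432e-03 0.00000e+00
1.49005e-01 1.92770e-01 8.54316e-02 6.30156e-02 1.23988e-01 5.76648e-03 0.00000e+00
1.64689e-01 1.70895e-01 6.89338e-02 4.57471e-02 1.20427e-01 4.72044e-03 0.00000e+00
1.82024e-01 1.53895e-01 5.71177e-02 3.32107e-02 1.16820e-01 3.86416e-03 0.00000e+00
2.01184e-01 1.40455e-01 4.86810e-02 2.41098e-02 1.13182e-01 3.16320e-03 0.00000e+00
2.22360e-01 1.29618e-01 4.26780e-02 1.75029e-02 1.09525e-01 2.58940e-03 0.00000e+00
2.45765e-01 1.20690e-01 3.84214e-02 1.27064e-02 1.05864e-01 2.11968e-03 0.00000e+00
2.71634e-01 1.13170e-01 3.54121e-02 9.22442e-03 1.02210e-01 1.73517e-03 0.00000e+00
3.00226e-01 1.06692e-01 3.32880e-02 6.69660e-03 9.85751e-02 1.42041e-03 0.00000e+00
3.31828e-01 1.00993e-01 3.17858e-02 4.86149e-03 9.49692e-02 1.16275e-03 0.00000e+00
3.66756e-01 9.58823e-02 3.07149e-02 3.52927e-03 9.14012e-02 9.51828e-04 0.00000e+00
4.05360e-01 9.12201e-02 2.99369e-02 2.56212e-03 8.78789e-02 7.79167e-04 0.00000e+00
4.48028e-01 8.69064e-02 2.93519e-02 1.86001e-03 8.44086e-02 6.37826e-04 0.00000e+00
4.95187e-01 8.28682e-02 2.88874e-02 1.35030e-03 8.09957e-02 5.22125e-04 0.00000e+00
5.47310e-01 7.90522e-02 2.84915e-02 9.80269e-04 7.76445e-02 4.27412e-04 0.00000e+00
6.04919e-01 7.54200e-02 2.81267e-02 7.11640e-04 7.43585e-02 3.49879e-04 0.00000e+00
6.68592e-01 7.19433e-02 2.77665e-02 5.16625e-04 7.11403e-02 2.86411e-04 0.00000e+00
7.38967e-01 6.86017e-02 2.73924e-02 3.75051e-04 6.79922e-02 2.34457e-04 0.00000e+00
8.16750e-01 6.53803e-02 2.69918e-02 2.72274e-04 6.49161e-02 1.91926e-04 0.00000e+00
9.02720e-01 6.22684e-02 2.65564e-02 1.97661e-04 6.19136e-02 1.57111e-04 0.00000e+00
9.97739e-01 5.92583e-02 2.60814e-02 1.43495e-04 5.89862e-02 1.28611e-04 0.00000e+00
1.10276e+00 5.74325e-02 2.56441e-02 1.04172e-04 5.61353e-02 1.05281e-04 1.08768e-03
1.21884e+00 5.61750e-02 2.54333e-02 7.56252e-05 5.33623e-02 8.61831e-05 2.65093e-03
1.34713e+00 5.51726e-02 2.54616e-02 5.49012e-05 5.06684e-02 7.05495e-05 4.37874e-03
1.48893e+00 5.44411e-02 2.57377e-02 3.98563e-05 4.80551e-02 5.77519e-05 6.28841e-03
1.64565e+00 5.39988e-02 2.62740e-02 2.89342e-05 4.55236e-02 4.72757e-05 8.39909e-03
1.81887e+00 5.38666e-02 2.70866e-02 2.10052e-05 4.30750e-02 3.86999e-05 1.07319e-02
2.01032e+00 5.40677e-02 2.81950e-02 1.52490e-05 4.07104e-02 3.16798e-05 1.33103e-02
2.22192e+00 5.46279e-02 2.96225e-02 1.10702e-05 3.84308e-02 2.59331e-05 1.61601e-02
2.45580e+00 5.55759e-02 3.13956e-02 8.03660e-06 3.62368e-02 2.12288e-05 1.93099e-02
2.71430e+00 5.69432e-02 3.35449e-02 5.83428e-06 3.41288e-02 1.73779e-05 2.27912e-02
3.00000e+00 5.87646e-02 3.61044e-02 4.23548e-06 3.21071e-02 1.42256e-05 2.66390e-02
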