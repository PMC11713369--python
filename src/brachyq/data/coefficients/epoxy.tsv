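# epoxy: photon mass interaction coefficients [cm^2/g]
# density 1.2 g/cm^3; analytic compilation, exact Klein-Nishina incoherent channel
# energy_MeV mu_over_rho mu_en_over_rho photoelectric incoherent coherent pair
1.00000e-03 4.20316e+03 4.18744e+03 4.18744e+03 2.13206e-01 1.55041e+01 0.00000e+00
1.10526e-03 3.05283e+03 3.03993e+03 3.03993e+03 2.13119e-01 1.26917e+01 0.00000e+00
1.22160e-03 2.21748e+03 2.20688e+03 2.20688e+03 2.13023e-01 1.03894e+01 0.00000e+00
1.35018e-03 1.61083e+03 1.60212e+03 1.60212e+03 2.12916e-01 8.50476e+00 0.00000e+00
1.49230e-03 1.17025e+03 1.16308e+03 1.16308e+03 2.12799e-01 6.96200e+00 0.00000e+00
1.64938e-03 8.50265e+02 8.44354e+02 8.44353e+02 2.12670e-01 5.69910e+00 0.00000e+00
1.82299e-03 6.17848e+02 6.12971e+02 6.12970e+02 2.12527e-01 4.66528e+00 0.00000e+00
2.01488e-03 4.49026e+02 4.44995e+02 4.44994e+02 2.12369e-01 3.81900e+00 0.00000e+00
2.22696e-03 3.26388e+02 3.23051e+02 3.23050e+02 2.12195e-01 3.12624e+00 0.00000e+00
2.46137e-03 2.37294e+02 2.34524e+02 2.34523e+02 2.12003e-01 2.55914e+00 0.00000e+00
2.72045e-03 1.72562e+02 1.70256e+02 1.70255e+02 2.11792e-01 2.09491e+00 0.00000e+00
3.00680e-03 1.25525e+02 1.23600e+02 1.23599e+02 2.11559e-01 1.71490e+00 0.00000e+00
3.32329e-03 9.13436e+01 8.97298e+01 8.97284e+01 2.11302e-01 1.40381e+00 0.00000e+00
3.67310e-03 6.64998e+01 6.51411e+01 6.51396e+01 2.11019e-01 1.14916e+00 0.00000e+00
4.05972e-03 4.84404e+01 4.72907e+01 4.72890e+01 2.10708e-01 9.40706e-01 0.00000e+00
4.48704e-03 3.53106e+01 3.43320e+01 3.43301e+01 2.10365e-01 7.70062e-01 0.00000e+00
4.95934e-03 2.57628e+01 2.49244e+01 2.49225e+01 2.09988e-01 6.30373e-01 0.00000e+00
5.48136e-03 1.88184e+01 1.80950e+01 1.80928e+01 2.09573e-01 5.16024e-01 0.00000e+00
6.05832e-03 1.37663e+01 1.31371e+01 1.31347e+01 2.09116e-01 4.22417e-01 0.00000e+00
6.69601e-03 1.00897e+01 9.53800e+00 9.53534e+00 2.08615e-01 3.45791e-01 0.00000e+00
7.40083e-03 7.41344e+00 6.92524e+00 6.92232e+00 2.08065e-01 2.83065e-01 0.00000e+00
8.17983e-03 5.46453e+00 5.02856e+00 5.02535e+00 2.07461e-01 2.31717e-01 0.00000e+00
9.04083e-03 4.04471e+00 3.65175e+00 3.64823e+00 2.06799e-01 1.89683e-01 0.00000e+00
9.99246e-03 3.00983e+00 2.65234e+00 2.64848e+00 2.06074e-01 1.55275e-01 0.00000e+00
1.10443e-02 2.25509e+00 1.92694e+00 1.92270e+00 2.05280e-01 1.27108e-01 0.00000e+00
1.22068e-02 1.70428e+00 1.40045e+00 1.39581e+00 2.04412e-01 1.04051e-01 0.00000e+00
1.34916e-02 1.30195e+00 1.01839e+00 1.01331e+00 2.03464e-01 8.51760e-02 0.00000e+00
1.49117e-02 1.00778e+00 7.41179e-01 7.35627e-01 2.02430e-01 6.97251e-02 0.00000e+00
1.64813e-02 7.92418e-01 5.40103e-01 5.34038e-01 2.01302e-01 5.70770e-02 0.00000e+00
1.82161e-02 6.34491e-01 3.94309e-01 3.87693e-01 2.00075e-01 4.67233e-02 0.00000e+00
2.01336e-02 5.18441e-01 2.88660e-01 2.81451e-01 1.98742e-01 3.82477e-02 0.00000e+00
2.22528e-02 4.32929e-01 2.12168e-01 2.04323e-01 1.97296e-01 3.13096e-02 0.00000e+00
2.45951e-02 3.69692e-01 1.56855e-01 1.48331e-01 1.95730e-01 2.56300e-02 0.00000e+00
2.71839e-02 3.22702e-01 1.16931e-01 1.07683e-01 1.94038e-01 2.09808e-02 0.00000e+00
3.00453e-02 2.87561e-01 8.81901e-02 7.81742e-02 1.92212e-01 1.71749e-02 0.00000e+00
3.32078e-02 2.61059e-01 6.75803e-02 5.67517e-02 1.90248e-01 1.40593e-02 0.00000e+00
3.67033e-02 2.40847e-01 5.28843e-02 4.11997e-02 1.88138e-01 1.15090e-02 0.00000e+00
4.05666e-02 2.25210e-01 4.24919e-02 2.99095e-02 1.85880e-01 9.42126e-03 0.00000e+00
4.48366e-02 2.12893e-01 3.52326e-02 2.17132e-02 1.83467e-01 7.71225e-03 0.00000e+00
4.95560e-02 2.02975e-01 3.02555e-02 1.57630e-02 1.80899e-01 6.31325e-03 0.00000e+00
5.47723e-02 1.94784e-01 2.69410e-02 1.14434e-02 1.78172e-01 5.16803e-03 0.00000e+00
6.05375e-02 1.87825e-01 2.48371e-02 8.30748e-03 1.75287e-01 4.23055e-03 0.00000e+00
6.69096e-02 1.81739e-01 2.36137e-02 6.03094e-03 1.72245e-01 3.46313e-03 0.00000e+00
7.39525e-02 1.76262e-01 2.30286e-02 4.37824e-03 1.69049e-01 2.83492e-03 0.00000e+00
8.17366e-02 1.71203e-01 2.29034e-02 3.17845e-03 1.65704e-01 2.32067e-03 0.00000e+00
9.03401e-02 1.66424e-01 2.31061e-02 2.30744e-03 1.62217e-01 1.89970e-03 0.00000e+00
9.98492e-02 1.61825e-01 2.35382e-02 1.67512e-03 1.58595e-01 1.55509e-03 0.00000e+00
1.10359e-01 1.57339e-01 2.41254e-02 1.21608e-03 1.54850e-01 1.27300e-03 0.00000e+00
1.21976e-01 1.52918e-01 2.48116e-02 8.82827e-04 1.50993e-01 1.04208e-03 0.00000e+00
1.34815e-01 1.48532e-01 2.55536e-02 6.40901e-04 1.47038e-01 8.53046e-04 0.00000e+00
1.49005e-01 1.44163e-01 2.63183e-02 4.65271e-04 1.42999e-01 6.98304e-04 0.00000e+00
1.64689e-01 1.39801e-01 2.70797e-02 3.37770e-04 1.38892e-01 5.71632e-04 0.00000e+00
1.82024e-01 1.35445e-01 2.78177e-02 2.45209e-04 1.34732e-01 4.67938e-04 0.00000e+00
2.01184e-01 1.31097e-01 2.85167e-02 1.78013e-04 1.30536e-01 3.83054e-04 0.00000e+00
2.22360e-01 1.26761e-01 2.91644e-02 1.29231e-04 1.26319e-01 3.13569e-04 0.00000e+00
2.45765e-01 1.22446e-01 2.97516e-02 9.38170e-05 1.22096e-01 2.56687e-04 0.00000e+00
2.71634e-01 1.18160e-01 3.02712e-02 6.81078e-05 1.17882e-01 2.10124e-04 0.00000e+00
3.00226e-01 1.13911e-01 3.07180e-02 4.94438e-05 1.13689e-01 1.72008e-04 0.00000e+00
3.31828e-01 1.09707e-01 3.10884e-02 3.58944e-05 1.09531e-01 1.40806e-04 0.00000e+00
3.66756e-01 1.05557e-01 3.13800e-02 2.60581e-05 1.05416e-01 1.15264e-04 0.00000e+00
4.05360e-01 1.01466e-01 3.15911e-02 1.89172e-05 1.01353e-01 9.43549e-05 0.00000e+00
4.48028e-01 9.74418e-02 3.17209e-02 1.37332e-05 9.73509e-02 7.72389e-05 0.00000e+00
4.95187e-01 9.34879e-02 3.17693e-02 9.96983e-06 9.34147e-02 6.32278e-05 0.00000e+00
5.47310e-01 8.96087e-02 3.17367e-02 7.23774e-06 8.95497e-02 5.17583e-05 0.00000e+00
6.04919e-01 8.58074e-02 3.16238e-02 5.25434e-06 8.57597e-02 4.23694e-05 0.00000e+00
6.68592e-01 8.20866e-02 3.14319e-02 3.81446e-06 8.20481e-02 3.46836e-05 0.00000e+00
7.38967e-01 7.84485e-02 3.11627e-02 2.76916e-06 7.84173e-02 2.83920e-05 0.00000e+00
8.16750e-01 7.48948e-02 3.08184e-02 2.01031e-06 7.48696e-02 2.32417e-05 0.00000e+00
9.02720e-01 7.14272e-02 3.04018e-02 1.45941e-06 7.14067e-02 1.90257e-05 0.00000e+00
9.97739e-01 6.80471e-02 2.99160e-02 1.05948e-06 6.80305e-02 1.55744e-05 0.00000e+00
1.10276e+00 6.50266e-02 2.93846e-02 7.69146e-07 6.47425e-02 1.27492e-05 2.70612e-04
1.21884e+00 6.22148e-02 2.88590e-02 5.58372e-07 6.15442e-02 1.04365e-05 6.59548e-04
1.34713e+00 5.95357e-02 2.83468e-02 4.05358e-07 5.84374e-02 8.54334e-06 1.08942e-03
1.48893e+00 5.69952e-02 2.78546e-02 2.94276e-07 5.54233e-02 6.99359e-06 1.56455e-03
1.64565e+00 5.45992e-02 2.73903e-02 2.13634e-07 5.25036e-02 5.72495e-06 2.08968e-03
1.81887e+00 5.23545e-02 2.69627e-02 1.55090e-07 4.96796e-02 4.68645e-06 2.67009e-03
2.01032e+00 5.02680e-02 2.65817e-02 1.12590e-07 4.69525e-02 3.83633e-06 3.31159e-03
2.22192e+00 4.83471e-02 2.62578e-02 8.17363e-08 4.43233e-02 3.14042e-06 4.02061e-03
2.45580e+00 4.65998e-02 2.60026e-02 5.93376e-08 4.17929e-02 2.57075e-06 4.80427e-03
2.71430e+00 4.50343e-02 2.58284e-02 4.30770e-08 3.93617e-02 2.10442e-06 5.67042e-03
3.00000e+00 4.36596e-02 2.57482e-02 3.12723e-08 3.70301e-02 1.72268e-06 6.62773e-03
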