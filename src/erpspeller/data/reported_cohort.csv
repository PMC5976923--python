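subject,group,accuracy,sensitivity,precision,f1,auc,psnr_db,pet_s
1,H,0.917,0.250,0.028,0.050,0.695,-42.285,0.372
2,H,1.000,0.647,0.131,0.218,0.863,-34.468,0.485
3,H,0.917,0.750,0.188,0.300,0.997,-35.677,0.594
4,H,0.833,0.750,0.255,0.344,0.766,-32.909,0.437
5,H,0.833,0.744,0.242,0.366,0.660,-37.448,0.354
6,H,0.750,0.782,0.276,0.408,0.562,-39.263,0.449
7,H,0.833,0.803,0.292,0.428,0.814,-25.565,0.595
8,H,1.000,0.826,0.317,0.458,0.873,-25.902,0.411
9,H,0.667,0.844,0.333,0.478,0.696,-22.070,0.527
10,H,0.750,0.838,0.346,0.490,0.873,-39.588,0.367
11,H,0.917,0.869,0.327,0.475,0.922,-25.750,0.448
12,H,0.917,0.878,0.342,0.493,0.940,-24.519,0.664
13,H,0.667,0.747,0.294,0.422,0.638,-23.987,0.497
14,H,0.833,0.713,0.279,0.401,0.778,-40.687,0.543
15,H,0.917,0.721,0.290,0.414,0.935,-39.207,0.489
16,H,0.750,0.733,0.302,0.428,0.998,-35.497,0.362
17,H,0.917,0.733,0.289,0.415,0.799,-38.910,0.284
18,H,0.917,0.740,0.295,0.421,0.861,-27.944,0.452
19,H,1.000,0.746,0.298,0.426,0.780,-29.202,0.458
20,L,0.583,0.846,0.344,0.489,0.843,-25.722,0.445
21,L,0.583,0.854,0.343,0.490,0.573,-18.743,0.575
22,L,0.667,0.849,0.338,0.483,0.249,-21.219,0.341
23,L,0.833,0.849,0.341,0.486,0.427,-46.836,0.638
24,L,0.750,0.853,0.337,0.483,0.582,-20.236,0.282
25,L,1.000,0.860,0.343,0.488,0.888,-20.511,0.558
26,L,0.917,0.866,0.343,0.492,0.535,-22.905,0.627
27,L,0.833,0.868,0.337,0.485,0.580,-22.883,0.451
28,L,0.750,0.881,0.362,0.513,0.898,-23.225,0.381
29,L,0.583,0.808,0.321,0.460,0.709,-31.783,0.350
30,L,0.833,0.814,0.324,0.464,0.874,-36.084,0.396
31,L,0.583,0.755,0.298,0.428,0.742,-27.483,0.422
32,L,0.667,0.752,0.303,0.432,0.931,-19.580,0.533
33,L,0.583,0.745,0.294,0.432,0.377,-32.561,0.454
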