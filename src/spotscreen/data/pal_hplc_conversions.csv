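substrate,ar_substituents,pbpal_conversion_pct,al11_conversion_pct
5a,2-MeO,27,68
5b,3-MeO,92,61
5c,4-MeO,8,5
5d,3-MeO-4-F,79,91
5e,3-MeO-4-Cl,91,59
5f,3-F-4-MeO,40,81
5g,3-Cl-4-MeO,38,87
5h,2-Et,48,91
5i,3-Et,30,76
5j,4-Et,48,5
5k,"2,3-(OCH2O)",92,98
5l,"3,4-(OCH2O)",3,11
5m,"2,3-(MeO)2",<1,5
5n,"2,4-(MeO)2",<1,<1
5o,"3,4-(MeO)2",<1,92
5p,"3,4-(MeO)2-6-F",<1,96
5q,"3,5-(MeO)2",<1,98
5r,"2,4,6-(MeO)3",<1,<1
5s,"3,4,5-(MeO)3",<1,97
5t,"2,3,4-(MeO)3",<1,4
5u,"2,4,5-(MeO)3",<1,73
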