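# Synthetic three-chromophore extinction basis (arbitrary units).
# Smooth analytic approximation of the published band shapes:
# HbO2 beta/alpha bands near 542/577 nm, Hb band near 556 nm,
# melanin power-law decay. Not a literature table.
wavelength_nm,eps_hbo2,eps_hb,eps_mel
500.000000,0.080148,0.102297,0.665500
502.000000,0.078360,0.101061,0.657577
504.000000,0.076830,0.100463,0.649780
506.000000,0.075753,0.100729,0.642106
508.000000,0.075476,0.102148,0.634552
510.000000,0.076576,0.105089,0.627116
512.000000,0.079966,0.110005,0.619795
514.000000,0.086998,0.117435,0.612588
516.000000,0.099546,0.128007,0.605493
518.000000,0.120016,0.142418,0.598506
520.000000,0.151226,0.161418,0.591627
522.000000,0.196101,0.185765,0.584853
524.000000,0.257164,0.216184,0.578182
526.000000,0.335839,0.253295,0.571611
528.000000,0.431686,0.297547,0.565140
530.000000,0.541735,0.349133,0.558767
532.000000,0.660156,0.407917,0.552488
534.000000,0.778451,0.473363,0.546304
536.000000,0.886282,0.544488,0.540211
538.000000,0.972873,0.619839,0.534209
540.000000,1.028740,0.697510,0.528295
542.000000,1.047384,0.775193,0.522469
544.000000,1.026526,0.850277,0.516727
546.000000,0.968599,0.919977,0.511070
548.000000,0.880366,0.981503,0.505494
550.000000,0.771827,1.032234,0.500000
552.000000,0.654734,1.069899,0.494585
554.000000,0.541117,1.092744,0.489248
556.000000,0.442148,1.099659,0.483987
558.000000,0.367432,1.090261,0.478801
560.000000,0.324580,1.064932,0.473690
562.000000,0.318750,1.024778,0.468651
564.000000,0.351862,0.971555,0.463683
566.000000,0.421468,0.907530,0.458785
568.000000,0.519672,0.835323,0.453955
570.000000,0.632840,0.757724,0.449194
572.000000,0.742825,0.677514,0.444498
574.000000,0.829986,0.597304,0.439868
576.000000,0.877413,0.519399,0.435302
578.000000,0.875094,0.445705,0.430799
580.000000,0.822449,0.377673,0.426358
582.000000,0.728230,0.316284,0.421977
584.000000,0.607792,0.262072,0.417657
586.000000,0.478798,0.215172,0.413395
588.000000,0.356930,0.175389,0.409191
590.000000,0.252976,0.142273,0.405044
592.000000,0.171893,0.115201,0.400953
594.000000,0.113599,0.093449,0.396916
596.000000,0.074745,0.076253,0.392934
598.000000,0.050611,0.062865,0.389004
600.000000,0.036552,0.052584,0.385127
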