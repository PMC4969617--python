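wavelength_nm,n,k
342.5,1.48,1.871
354.2,1.50,1.866
367.9,1.48,1.895
381.5,1.46,1.933
397.4,1.47,1.952
413.3,1.46,1.958
430.5,1.45,1.948
450.9,1.38,1.914
471.4,1.31,1.849
495.9,1.04,1.833
520.9,0.62,2.081
548.6,0.43,2.455
582.1,0.29,2.863
616.8,0.21,3.272
659.5,0.14,3.697
704.5,0.13,4.103
756.0,0.14,4.542
821.1,0.16,5.083
892.0,0.17,5.663
984.0,0.22,6.350
1088.0,0.27,7.150
1216.0,0.35,8.145
1393.0,0.43,9.519
1610.0,0.56,11.21
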