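wavelength_nm,n,k
342.5,0.14,1.142
354.2,0.10,1.419
367.9,0.07,1.657
381.5,0.05,1.864
397.4,0.05,2.070
413.3,0.05,2.275
430.5,0.04,2.462
450.9,0.04,2.657
471.4,0.05,2.869
495.9,0.05,3.093
521.0,0.05,3.324
548.6,0.06,3.586
582.1,0.05,3.858
616.8,0.06,4.152
659.5,0.05,4.483
704.5,0.04,4.838
756.0,0.03,5.242
821.1,0.04,5.727
892.0,0.04,6.312
984.0,0.04,6.992
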