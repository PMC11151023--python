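grouping,group,n,mean_bits,ci_low,ci_high
by_age,12y,31,0.02300,0.02064,0.02537
by_age,13y,30,0.02415,0.02166,0.02663
by_age,22y,26,0.02538,0.02271,0.02805
by_maturity,decelerated,21,0.02146,0.01866,0.02426
by_maturity,average,21,0.02794,0.02475,0.03113
by_maturity,accelerated,19,0.02208,0.01913,0.02503
by_bin,12y_decelerated,10,0.02032,0.01633,0.02431
by_bin,12y_average,11,0.02823,0.02374,0.03271
by_bin,12y_accelerated,10,0.02145,0.01750,0.02540
by_bin,13y_decelerated,11,0.02299,0.01899,0.02700
by_bin,13y_average,10,0.02728,0.02277,0.03179
by_bin,13y_accelerated,9,0.02257,0.01813,0.02701
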