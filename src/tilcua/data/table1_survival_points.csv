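arm,endpoint,time_months,survival_probability
TIL,pfs,3,0.792
TIL,pfs,6,0.612
TIL,pfs,9,0.485
TIL,pfs,12,0.395
TIL,os,3,0.942
TIL,os,6,0.871
TIL,os,9,0.801
TIL,os,12,0.735
ipilimumab,pfs,3,0.635
ipilimumab,pfs,6,0.269
ipilimumab,pfs,9,0.129
ipilimumab,pfs,12,0.072
ipilimumab,os,3,0.936
ipilimumab,os,6,0.847
ipilimumab,os,9,0.759
ipilimumab,os,12,0.679
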