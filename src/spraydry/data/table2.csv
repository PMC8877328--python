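Tin_K,Text_K,Tout_K,RHext_pct,FR_kg_h,Gin_kg_h,AD_printed
463,296,362,35.8,0.80,18.2,3.27e-2
463,295,360,22.9,0.42,9.4,3.29e-2
463,297,406,24.0,0.07,17.5,3.12e-3
463,297,388,24.0,0.07,9.3,5.86e-3
433,297,357,40.9,0.59,18.2,2.21e-2
433,295,353,30.3,0.32,9.4,2.33e-2
433,298,388,23.7,0.07,18.7,2.81e-3
433,298,371,22.8,0.07,9.8,5.42e-3
403,294,352,44.9,0.34,18.7,1.18e-2
403,297,345,35.6,0.21,9.8,1.37e-2
403,297,367,23.8,0.07,18.7,2.55e-3
403,297,355,23.8,0.07,9.8,4.85e-3
373,295,339,41.7,0.23,19.2,7.05e-3
373,295,331,29.1,0.17,10.3,9.84e-3
373,297,347,24.2,0.07,19.3,2.29e-3
373,297,339,24.2,0.07,10.1,4.35e-3
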