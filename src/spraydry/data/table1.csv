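Tin_K,aspirator_pct,RHext_pct,Text_K,Gin_kg_h,Tout_K
473,100,25.6,294.0,23.8,427.0
473,80,34.4,299.1,20.4,421.0
473,50,24.7,295.7,13.7,417.7
433,100,29.5,293.7,27.8,399.3
433,80,22.3,297.5,22.5,394.7
433,50,26.1,293.0,16.3,391.3
413,100,43.7,297.4,28.4,382.3
413,80,35.7,298.0,24.5,380.7
413,50,35.5,298.0,16.1,377.0
373,100,32.6,294.2,33.8,355.0
373,80,24.8,298.5,26.9,353.0
373,50,32.6,294.4,19.5,351.7
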