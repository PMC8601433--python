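label,a_cm1,b,source
generic soft tissue,12.0,1.1,synthetic illustrative value
fibrous tissue,25.0,1.5,synthetic illustrative value
rayleigh-dominated tissue,30.0,3.8,synthetic illustrative value
large-scatterer tissue,20.0,0.6,synthetic illustrative value
high-scatter epidermis-like,45.0,1.6,synthetic illustrative value
low-scatter organ-like,8.0,1.3,synthetic illustrative value
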