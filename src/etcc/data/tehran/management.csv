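site_name,imc,emc
Lar national park,36,14
Jajrud protected area,75,28
Tangeh Vashi natural monument,5,4
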