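name,hemisphere,x,y,z,network,is_language
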