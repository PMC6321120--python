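hkl,E_att
110,-214.9592
002,-208.9238
11-1,-299.1849
111,-255.0837
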