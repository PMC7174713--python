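tonsillitis
ovarian cysts
fever
cataract
tracheitis
flu
tooth pain
renal colic
drug abuse
self-harm
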