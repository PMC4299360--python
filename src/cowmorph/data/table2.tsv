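balance	integral	nonintegral
A1 balanced	1237	375
A1 unbalanced	528	106
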