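# one case-insensitive substring per line; a trailing "-" marks a stem
no evidence of
negative for
free of
absent
not identified
no residual
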