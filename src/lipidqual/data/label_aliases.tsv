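# raw label -> canonical label; fixes known-bad labels before parsing
C20:5n-	C20:5n-3
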