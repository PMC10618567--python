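gene	chrom	start	end
TP53	17	7571720	7590868
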