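# Published per-type perfect-microsatellite counts for 83 Ixodes mitogenomes.
type	count
mono	466
tri	147
other	304
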