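# Published per-type perfect-microsatellite counts for 357 Ixodidae mitogenomes.
# Only the mono- and tri-nucleotide counts were reported individually; the
# remaining loci are pooled under "other".
type	count
mono	1925
tri	1159
other	1283
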