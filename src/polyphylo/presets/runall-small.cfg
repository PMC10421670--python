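# Bundled end-to-end preset: a complete, desk-scale run of the full chain
# on the two-tetraploid network (sizes chosen for minutes, not hours).
preset = nicotiana-like
n_loci = 40
locus_length = 400
g = 0.3
clock_rate = 0.005
bootstrap_replicates = 200
gene_bootstrap_replicates = 50
qs_replicates = 20
seed = 1
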