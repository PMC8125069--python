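cluster_identity: 0.4
contig_end_margin: 0
core_min_len: 150
dpxg_window: 100
gap_extend: 1
gap_open: 11
immunity_min_identity: 0.4
immunity_min_ref_coverage: 0.9
locus_max_gap: 10000
max_intergenic: 200
min_toxin_len: 30
motif_fpr: 0.001
motif_n_decoys: 1000
require_same_strand: true
seed: 0
substitution: BLOSUM62
t6ss_min_coverage: 0.7
t6ss_min_identity: 0.4
threads: 1
toxin_min_aln_len: 90
toxin_min_identity: 0.4
truncation_fraction: 0.5
vgrg_min_aln_len: 300
vgrg_min_member_len: 500
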