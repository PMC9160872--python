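conditions:
- 30C
- 16C
- 4C
counts_f1: counts_F1.tsv
counts_p1: counts_P1.tsv
counts_p2: counts_P2.tsv
hits_p1_vs_p2: hits_P1_vs_P2.tsv
hits_p2_vs_p1: hits_P2_vs_P1.tsv
lengths: lengths.tsv
library_sizes: library_sizes.tsv
metadata: metadata.tsv
out_dir: results
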