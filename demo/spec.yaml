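# Synthetic discrimination experiment: an IRF-like / NFkB-like motif pair
# implanted in 90% of the positive promoters, absent from the negatives.
pwm_pair: [IRF_like, NFKB_like]
n_pos: 30
n_neg: 30
seq_len: 500
implant_fraction_pos: 0.9
implant_fraction_neg: 0.0
gap_range: [0, 50]
strength: 0.95
seed: 11
pwms:
  - {name: IRF_like, consensus: AATTGAAA, dominance: 0.9}
  - {name: NFKB_like, consensus: GGGACTTTCC, dominance: 0.9}
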