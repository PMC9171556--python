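# Item-panel preset emulating a 12-item obsessive-compulsive symptom
# checklist with never/ever dichotomized responses.  Equal probit loadings
# calibrated (Spearman-Brown) so that the sum score has internal
# consistency alpha = 0.76 at ~30% item endorsement.
name: catss-bocs
kind: items
n_items: 12
n_persons: 9230
loading: 0.7206068924
# raw-scale cutoff: endorse item iff loading*latent + N(0,1) noise >= this
item_threshold: 0.6463700165
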