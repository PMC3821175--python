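# Two-genotype synthetic comparison: wild-type-like kinetics vs a mutant
# with a reduced fast release fraction and fewer docked vesicles.
seed: 11
stages:
  evoked:
    n_per_group: 15
    genotypes:
      wt: {f_fast: 0.7721, tau_fast: 5.29, tau_slow: 40.30}
      mut: {f_fast: 0.45, tau_fast: 5.29, tau_slow: 40.30}
  emdist:
    genotypes:
      wt: {}
      mut: {vesicles_per_profile: 2.0}
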