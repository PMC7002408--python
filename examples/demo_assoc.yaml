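# Demo: simulate a near-isogenic F2 segregating a coding indel and a 3'UTR
# SNP (dosage 2 = derived homozygote), with viability distortion at the SNP
# calibrated to the 135:256:60 pattern, then run the conditional association
# and segregation-distortion stage.
# Run:  tbscan assoc --config examples/demo_assoc.yaml --out demo_out
seed: 7
out_dir: demo_out
simulation:
  cross:
    cross_type: NIL_F2
    n_individuals: 451
    loci: [[indel1, 15273436], [snp3, 15274099]]
    recomb_fraction_between_adjacent: 0.35
    distortion_weights:
      snp3: [1.0, 0.948, 0.4446]
  effects:
    # tillers per derived-allele copy; homozygote contrasts 1.64 and -2.77
    indel1: {40: 0.235, 50: 0.82}
    snp3: {40: -0.41, 50: -1.385}
association:
  timepoints: [40, 50]
  conditions:
    - {site: indel1, condition_site: snp3, required_dosage: 0}
    - {site: snp3, condition_site: indel1, required_dosage: 2}
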