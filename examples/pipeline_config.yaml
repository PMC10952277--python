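# Demo configuration for `ovistep run examples/pipeline_config.yaml`.
# Simulates a small flock, runs QC + parentage + GRM/PCA, estimates scan-weight
# breeding values under both pedigree and single-step BLUP, and writes the
# stratified accuracy comparison. Rerunning with the same seed reproduces
# byte-identical outputs.
output_dir: ovistep_demo_out
pedigree_path: null
genotype_path: null
phenotype_path: null
simulate: true
traits: [swt]
call_rate: 0.894
maf: 0.05
hwe_alpha: 0.05
oh_threshold: 0.01
blend_weight: 0.95
cg_min: 5
run_reml: false
seed: 2024
sim:
  n_founders: 120
  n_generations: 3
  n_flocks: 3
  n_snps: 400
components:
  swt:
    sigma2_a: 8.97
    sigma2_e: 18.58
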