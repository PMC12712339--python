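# Full-pipeline demo on synthetic data: ecmet run --config examples/demo_config.yaml
# Thresholds mirror the study conventions implemented by the package.
outdir: scratch/demo
seed: 7

stages:
  simulate: true        # generate all inputs below instead of reading paths

simulate:
  n_features: 500
  days: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  n_replicates: 3
  frac_state_markers: 0.10
  frac_bed_markers: 0.10
  effect_size_log2: 1.5
  noise_sd_log2: 0.25
  drift_amplitude: 0.5
  n_ions: 50

annotate:
  tolerance: 0.001      # 1 mDa accurate-mass window (intracellular setting;
                        # use 0.003 for supernatant data)
  adduct: "[M-H]-"      # negative ionization, deprotonated species

normalize:
  window: 15            # moving-median drift window, acquisitions

diff:
  variant: welch
  correction: storey    # Storey q-values (proteomics); 'bh' for metabolomics
  fc: 0.5               # significant: |log2 FC| > 0.5 ...
  alpha: 0.05           # ... and q (or adjusted p) < 0.05

enrich:
  mode: protein         # 'metabolite' switches to p < 0.05, |log2 FC| > 0.25
                        # selection with BH-adjusted enrichment p < 0.05

plsda:
  B: 200                # bootstrap replicates
  tail: 0.10            # 10th/90th percentile LV1 weight tails
  consensus: 0.9        # fraction of replicates a feature must stay in a tail
  select_mode: consensus  # or 'ci'
  permutations: 0       # set > 0 to add the label-permutation null

phenotype:
  control: control
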