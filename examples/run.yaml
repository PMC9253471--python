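# Full synthetic pipeline run: `disco run --config examples/run.yaml`
# All fields map 1:1 to disco.pipeline.RunConfig; seed is mandatory.
output_dir: out/demo
seed: 7

# phantom geometry
grid_n: 32            # template grid voxels per axis (1 mm isotropic)
voxel_size: 1.0
n_controls: 10        # normative control tractograms
control_jitter: 0.5   # per-control rigid jitter SD, mm

# cohort
n_subjects: 30
cohort:               # overrides for CohortSimConfig (planted effects etc.)
  beta_nfl_gd: 0.03
  beta_time: -0.04
  beta_interaction: -0.01

# disconnectome scoring
cutoff: 0.5           # strict > cutoff threshold on the overlap map

# voxel-wise inference
n_perm: 500
tfce_h: 2.0
tfce_e: 0.5
tfce_dh: 0.1
tfce_connectivity: 26

# longitudinal models
lmm_center: fixed     # or: random, none
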