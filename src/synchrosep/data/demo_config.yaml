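# Bundled demo configuration for `synchrosep pipeline`.
# Small sizes so the full pipeline runs in well under a minute.
seed: 7
out_dir: synchrosep_demo
library:
  n_precursors: 200
  n_proteins: 40
  gradient_start_min: 5.0
  gradient_end_min: 35.0
  entrapment_fraction: 0.0
offset:
  kind: smooth_drift
  base_offset: 4.0
  drift_params: [0.3, 30.0, 5.0]
run:
  load_ng: 200.0
  suppression: 0.06
  noise_cv: 0.05
  detection_midpoint: 4.0
search:
  rt_shift: model
  rt_gap: 1.0
  q: 0.01
quant:
  level: protein
  normalize: false
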