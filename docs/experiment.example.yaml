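# Full factorial experiment at reduced desk scale.
# For the study-scale protocol raise: cars_params.n_runs to 5000 (with
# cv: loo), bpnn_params.epochs to 5000, n_restarts to 5, and drop
# svr_params to restore the full C grid (1e-7..1e7, all three kernels;
# the extreme-C cells can be very slow).
output_dir: experiment_out
seed: 0
synthetic:
  n_samples: 288
  n_bands: 200
  seed: 11
  noise_sd: 0.002
selections: [full, spa, cars, "gradcampp@0.6", "gradcampp@0.7"]
model_families: [plsr, svr, bpnn, cnn]
analytes: [prolamin, glutelin]
gradcam_split: test
spa_params: {n_min: 30, n_max: 50}
svr_params:
  kernels: [linear, rbf]
  C_grid: [0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
cars_params: {n_runs: 50, max_components: 20, cv: 10}
bpnn_params: {epochs: 500, n_restarts: 1}
cnn_params: {epochs: 500, n_restarts: 1}
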