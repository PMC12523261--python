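# Synthetic-dataset generator configuration (YAML or JSON).
# All fields optional; defaults emulate the study conditions.
n_samples: 288
seed: 0
n_bands: 200
start_nm: 980.0
end_nm: 1684.0
content_params:           # truncated-normal parameters per analyte (%)
  prolamin: {mean: 0.70, sd: 0.07, min: 0.51, max: 0.88}
  glutelin: {mean: 5.01, sd: 0.99, min: 3.43, max: 7.38}
content_correlation: 0.3  # latent correlation between the two fractions
band_library:             # Gaussian absorption features
  - {center_nm: 1020.0, width_nm: 25.0, coupling: {prolamin: 0.50}}
  - {center_nm: 1500.0, width_nm: 35.0, coupling: {prolamin: 0.40}}
  - {center_nm: 1050.0, width_nm: 25.0, coupling: {glutelin: 0.08}}
  - {center_nm: 1480.0, width_nm: 35.0, coupling: {glutelin: 0.06}}
  - {center_nm: 1450.0, width_nm: 40.0, coupling: {prolamin: 0.25, glutelin: 0.04}}
baseline_offset: 0.20     # absorbance units
baseline_slope: 0.0001    # absorbance per nm
noise_sd: 0.005           # absorbance units
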