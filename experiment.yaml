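# Desk-scale end-to-end experiment (see README).
# radiogen-cgan run-all --config experiment.yaml
seed: 1
output_dir: runs/desk
n_patients: 120
latent_dim: 17
volume_shape: [8, 32, 32]
# all genes load on the lesion axis (the image-visible direction), with
# graded strengths so their image AUCs are ordered
genes:
  - {name: TP53,   prevalence: 0.3406, effect_size: 4.0, effect_axis: 0}
  - {name: PIK3CA, prevalence: 0.3580, effect_size: 3.0, effect_axis: 0}
  - {name: CDH1,   prevalence: 0.1623, effect_size: 2.5, effect_axis: 0}
subtype_effect_size: 2.0
lesion_effect_size: 2.0
lesion_effect_axis: 0
noise_sd: 0.05
cgan:      {epochs: 100, batch_size: 16, base_channels: 8}
baseline:  {epochs: 100, batch_size: 16, base_channels: 8}
classifier: {epochs: 10, batch_size: 16}
fid_folds: 2
fid_boot: 20
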