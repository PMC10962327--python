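# Minute-scale demonstration config (see README worked example).
model:
  initial_channels: 4
  levels: 2
  decoder_channels: 4
epochs: 8
patches_per_volume: 2
patch_size: 32
t0: 8
eta_init: 0.002
n_scenes: 6
scene_grid: [48, 48, 48]
transfer_epochs: 2
transfer_patch_size: 32
transfer_padded_size: 32
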