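# Default run configuration for the datbridge pipeline.
#
# Values under `preprocess`, `train.w_*`, and `classify` follow the standard
# full-scale acquisition/training protocol for DAT PET/SPECT translation;
# cohort sizes and epoch counts default to a desk-scale demo that completes
# on one CPU. Pass this file to `datbridge run --config ...` and override
# what you need.

seed: 7            # master seed; every stage seed derives from it
outdir: runs/demo  # run directory (manifest, model, CSV/JSON outputs)
log_level: INFO

phantom:
  grid_shape: [32, 32, 32]   # phantom grid (voxels)
  spacing_mm: [2.0, 2.0, 2.0]
  n_train_nc: 3              # unpaired training cohort sizes per modality
  n_train_pd: 3
  n_test_nc: 10              # held-out test cohort sizes
  n_test_pd: 10

preprocess:
  pet_fwhm_mm: 10.0      # protocol Gaussian smoothing for PET volumes
  spect_fwhm_mm: 6.0     # protocol Gaussian smoothing for SPECT volumes
  post_fwhm: 1.7         # post-generation smoothing of translated volumes
  post_fwhm_units: mm    # "mm" or "voxels" (the protocol leaves this open)

train:
  epochs: 5              # desk-scale; the full-scale protocol uses 200
  batch_size: 1          # full-scale protocol value
  learning_rate: 2.0e-3  # desk-scale slim preset; full-scale protocol: 2.0e-4
  base_channels: 6       # slim architecture width for 32^3 grids
  w_cycle: 10.0          # cycle-consistency L1 weight (protocol)
  w_identity: 1.0        # identity L1 weight (protocol)
  w_adv: 1.0             # adversarial BCE weight (protocol)
  checkpoint_every: 0    # epochs between checkpoints (0 = off)

classify:
  epochs: 25             # desk-scale; full-scale protocol: 50
  early_stop_patience: 20  # full-scale protocol: 30 (on validation accuracy)
  initial_lr: 3.0e-3     # desk-scale; full-scale protocol: 1.0e-4
  lr_factor: 0.5         # plateau LR reduction factor (protocol)
  lr_patience: 8         # full-scale protocol: 10 (on validation loss)
  base_channels: 6
  batch_size: 6          # gradient-accumulation batch

fid:
  n_boot: 200            # bootstrap draws for the FID comparison
  embed_dim: 8           # random-projection embedder output dimension
  embed_seed: 17         # embedder seed (part of the embedder identity)
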