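# smsepi

Simulation, reconstruction and quantitative analysis of multi-contrast,
segmented-EPI **simultaneous multislice (SMS)** MRI acquisitions:

- **`smsepi.phantom`** — structured digital phantoms (background T1 = 289 ms
  plus doped sub-volumes), smooth complex coil sensitivities, gamma-variate
  contrast-agent bolus dynamics, the spoiled-GRE signal model and the Ernst
  angle.
- **`smsepi.plan`** — sequence planning: segment/line interleaving, echo-time
  shifting, slice-group ordering, CAIPIRINHA phase schedules (FOV/f
  inter-slice shifts) with feasibility checking, and scan timing.
- **`smsepi.encode`** — synthetic multi-coil, multi-echo, multi-segment
  k-space for single-band and multiband (collapsed) acquisitions, with
  seeded complex Gaussian noise, odd-line Nyquist-ghost phase errors and
  navigator lines.
- **`smsepi.recon`** — slice-GRAPPA and split-slice-GRAPPA (leak-block)
  kernel calibration from autocalibration data (measured-SMS or synthesized
  source, single kernel or per-echo kernels), SMS unfolding, navigator-based
  ghost correction and sum-of-squares coil combination.
- **`smsepi.qa`** — Huang fuzzy-entropy masking, normalized subtraction
  error maps, pseudo multiple-replica g-factor maps, and the ACS
  contrast/SNR dependency experiment with binned linear fits.
- **`smsepi.relax`** — voxel-wise mono-exponential T2* fitting
  (log-linear initialization + Levenberg–Marquardt) separating dynamic
  signals into S0 (TE = 0 extrapolation) and T2*, plus ROI time courses.
- **`smsepi.pipeline` / `smsepi.cli`** — config-driven orchestration with
  HDF5/NIfTI/CSV/PNG outputs and a reproducibility manifest.

## CLI

Every subcommand accepts `--config CONFIG.yaml`, `--seed`, `--out` and
`--log-level`; see `smsepi --help`.

```sh
smsepi plan                                   # print the sequence plan
smsepi simulate      --config cfg.yaml        # phantom k-space (HDF5) + truth maps (NIfTI)
smsepi train-kernel  --config cfg.yaml --method 2 --algo sg --policy acs111
smsepi recon         --config cfg.yaml        # unfolded 4D series (NIfTI per echo)
smsepi qa            --config cfg.yaml        # error maps, summaries (CSV), histogram (PNG)
smsepi fit-relax     --config cfg.yaml        # S0 / T2* maps + ROI curves
smsepi pipeline      --config cfg.yaml        # all stages end to end
```

A minimal configuration (all keys optional; unknown keys are rejected):

```yaml
seed: 1
output_dir: out
phantom: {n_slices: 8, grid: 64}
coils: {n_coils: 8}
plan: {n_segments: 4, mb: 4, f: 4, te_list: [9.0, 21.5, 34.0], tr: 261.0, n_frames: 20}
acquisition: {fa: 90.0, noise_sd: 0.01}
bolus: {enabled: true}
recon: {method: 2, algo: sg, policy: acs111}
```

## Conventions

k-space stores DC at index `N // 2`, phase encode is the second-to-last
axis, FFTs are centered and orthonormal. A "slice group" is the set of
`mb` equally spaced slices excited together; group-slice `n` of group `g`
is global slice `g + n * n_groups`. CAIPIRINHA phases are applied
per segment (constant across a segment's lines), equivalent to the
line-wise shift-theorem phase for every valid shift factor.
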