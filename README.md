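# punctakit

Quantification toolkit for live-cell fluorescence imaging of labeled DNA
loci — the bright, diffraction-limited puncta produced when a genomic
site (or an extrachromosomal DNA molecule) is tagged by a CRISPR/dCas9- or
nanobody-based labeling system and followed over time in the nucleus.

It is written for microscopists and image analysts who need the standard
quantification stack for such recordings as reusable, tested library code
rather than an interactive-tool workflow:

* **Spot detection** — scale-matched Laplacian-of-Gaussian detection with
  sub-pixel refinement, and threshold/watershed foci counting for
  copy-number histograms.
* **Tracking** — linear-assignment linking with a fixed distance gate
  (5 px) and gap bridging up to 5 frames; longer absences split a track.
* **MSD analysis** — time-averaged and ensemble mean-squared displacement
  and a nonlinear fit of the confined-diffusion motion model

  ```
  MSD(t) = A (1 − e^(−t/τ)) + 4 D t + v² t²,   D_eff = A / (4 τ)
  ```

  with confinement area `A` (µm²), relaxation time `τ` (s), diffusion
  coefficient `D` (µm²/s) and transport speed `v` (µm/s).
* **SNR** — per-punctum signal-to-noise,
  `SNR = (max spot intensity − mean background) / SD background`, with the
  background sampled from seeded random circles inside the nucleus and
  outside all puncta; plus line profiles and a phototoxicity
  percent-change readout.
* **FRAP** — double normalization of bleach/recovery traces against a
  reference region and the nuclear background, and a single-exponential
  recovery fit (mobile fraction, rate, half-time).
* **Nuclear positioning** — the L/D ratio (shortest spot-to-boundary
  distance over centroid-to-boundary distance through the spot): 0 at the
  periphery, 1 at the centroid.
* **Occupancy** — bound-nanobody counts per anchoring complex from
  dual-channel intensity ratios, normalized by a 1:1 fusion-standard
  correction factor and the labeling stoichiometry (6 green per complex /
  2 red per nanobody ⇒ factor 3).
* **Synthetic data** — a generator for all of the above (images with
  Poisson–Gaussian noise, Brownian/confined/directed/hopping motion,
  three-phase FRAP series, dual-channel intensities) that always emits
  exact ground truth, so every estimator is validated end-to-end.

The MSD and FRAP fitting stages follow the model/results convention:
build a model from a curve, call `fit()`, read estimates and `summary()`
off the results object.

## Worked example

The `demo` subcommand runs the full synthetic pipeline — simulate a
nucleus with 12 confined loci (σ_s = 0.08 µm, τ = 1 s, so A = 4σ_s² =
0.0256 µm²), detect, link, fit the motion model, measure SNR and nuclear
positioning — and prints:

```
$ punctakit demo --seed 1 --out-dir demo_out
demo summary
============
seed                 : 1
true spots           : 12
tracks (>=10 samples): 12
MSD fit A            : 0.022642 um^2 (truth 0.0256)
MSD fit tau          : 0.8767 s (truth 1.0)
MSD fit D_eff        : 0.0064569 um^2/s
mean punctum SNR     : 119.47
mean position ratio  : 0.490
```

All 12 simulated loci come back as 12 tracks; the fitted confinement
area and timescale sit within the Monte-Carlo scatter expected of a
single 12-track replicate; `D_eff` is `A/(4τ)` by definition. The mean
SNR reflects the simulated amplitude-to-noise ratio, and the mean L/D
ratio ≈ 0.5 matches loci placed uniformly over the nuclear interior.
Each run writes a JSON manifest (config, seed, input hashes, outputs) to
the output directory.

Library use mirrors the CLI:

```python
from punctakit import (SimulationConfig, SpotSpec, simulate_timelapse,
                       detect, link_spots, compute_msd, average_msd,
                       ConfinedDiffusionModel)
from punctakit.synthetic import ConfinedMotion

cfg = SimulationConfig(spots=[SpotSpec(initial_position=(6.4, 6.4),
                                       motion=ConfinedMotion(sigma_s=0.1, tau=1.0))],
                       seed=0)
stack, truth = simulate_timelapse(cfg)
per_frame = detect.detect_stack(stack, diameter_px=5, quality_threshold=100)
tracks = link_spots(per_frame, max_disp_px=5, max_gap_frames=5,
                    pixel_size=cfg.pixel_size, frame_interval=cfg.frame_interval)
curve = average_msd([compute_msd(t) for t in tracks])
print(ConfinedDiffusionModel(curve, fit_fraction=0.5).fit().summary())
```

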