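# Methods

## The measurement and its model

A nitroxide spin label attached to one chain of a binary complex
enhances the transverse relaxation of every amide proton on the
isotope-labeled partner chain in proportion to 1/r⁶ of the
electron–proton distance. The observable is the per-residue peak-height
ratio between a paramagnetic spectrum and the diamagnetic spectrum
recorded after chemical reduction of the label. With a single evolution
time point *t*, the ratio relates to the transverse PRE rate Γ₂ as

    I_para/I_dia = R₂ · exp(−Γ₂ t) / (R₂ + Γ₂),

the standard peak-height formulation for single-timepoint PRE
experiments. The equation is strictly decreasing in Γ₂, so each ratio in
(0, 1) determines one rate. The rate converts to a distance through a
simplified Solomon–Bloembergen spectral density,

    Γ₂ = (K / r⁶) · (4 τc + 3 τc / (1 + ωH² τc²)),

which assumes a single effective correlation time τc for the
electron–proton vector (valid when the label's electronic relaxation is
slow compared to molecular tumbling) and a single conformation behind
each observed rate. The second assumption matters: for a dynamic or
released label the "distance" is an r⁻⁶-weighted average biased toward
close approach, and downstream interpretation must treat such values as
effective distances.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `t_evolution` | 0.010 | s | single evolution time of the experiment |
| `tau_c` | 1.6e−8 | s | effective correlation time (from linewidths) |
| `spectrometer_mhz` | 600 | MHz | fixes ωH = 2π·10⁶·MHz rad/s |
| `k_label` | 1.23e−32 | cm⁶ s⁻² | nitroxide spin constant |
| `floor_ratio` | 0.05 | — | ratio assigned to undetected peaks |
| `r2_default` | 50 | s⁻¹ | fallback R₂ when no linewidth is present |
| `r_window` | (12, 25) | Å | quantifiable distance window |
| `ratio_sigma_frac` | 0.05 | — | fractional ratio uncertainty |

R₂ is taken per residue from the diamagnetic linewidth (R₂ = π·Δν₁/₂)
when the peak list carries one, else `r2_default`; both conventions are
supported because published analyses rarely state which was used.
Distances are stored in Å and converted to cm only inside the
Solomon–Bloembergen expression, keeping `K` in its conventional units.

The conversion is robust to τc misestimation: because Γ₂ factorizes as
f(τc)/r⁶, a τc offset δ rescales every distance by (f(τc±δ)/f(τc))^(1/6).
At 16 ± 2 ns and 600 MHz this is at most ≈2.2% — comfortably below the
6% figure usually quoted — and `tauc_sensitivity` computes it on an
arbitrary distance grid.

## Numerical choices

* Ratio→rate inversion uses bracketed bisection (scipy) with relative
  tolerance 1e−10 and an automatically grown bracket; the solve fails
  loudly if the forward ratio is still above the target when it has
  already fallen under 1e−6. A closed form via Lambert-W exists but the
  monotone bisection is simpler to reason about and fast at this scale.
* Rate→distance is the exact sixth root; round-trips hold to 1e−9
  relative.
* Ratios ≥ 1 (noise) are preserved in the ratio table and clipped to
  Γ₂ = 0 only at the rate step, keeping raw data auditable; Γ₂ = 0 maps
  to an infinite-distance sentinel flagged `above_ceiling`.
* Undetected paramagnetic peaks carry the floor ratio and are flagged as
  *lower bounds* on Γ₂ / upper limits on r (`below_floor`).
* Uncertainty propagation solves the inversion at ratio·(1 ± σ/ratio);
  the upper ratio may exceed 1, making the lower rate bound 0.
* Boundary values in the broadening classification go to the stronger
  class (a ratio of exactly 0.4 is "strong"); "unaffected" is
  operationalized as ratio ≥ 0.85, configurable because no published
  number exists for "≈ 1".

## The quantifiable window

`quantifiable_window` derives both window edges from the same inverse
chain: the short edge is where the predicted ratio hits the detection
floor, the long edge where the attenuation 1 − ratio equals the ratio
uncertainty σ (solving ratio = 1 − σ). With floor 0.05, σ = 0.05,
t = 10 ms and τc = 16 ns, the short edge lands at 12.9–13.5 Å for any
R₂ in the plausible 30–60 s⁻¹ range, and the long edge at 27.2 Å
(R₂ = 60) to 29.5 Å (R₂ = 30). The conventional 12–25 Å window is
therefore reproduced within ±3 Å at the short edge for every R₂, and at
the long edge for R₂ ≳ 47 s⁻¹; since the R₂ behind any published window
is typically unstated, the acceptance check asserts attainability within
the R₂ range rather than equality at every R₂.

## The synthetic-data generator

The generator runs the physics in reverse plus a noise model:

* **Geometry.** `two_lobe_fixture` builds two disks of amide positions
  perpendicular to their separation axis (default 38 Å apart), so
  distances to an on-axis anchor are nearly uniform within a "lobe".
  `build_two_state_geometry` anchors the bound label 14 Å from the
  N-lobe-like centroid and displaces it (default 10 Å) toward the
  C-lobe-like centroid for the released state, keeping both states of
  both lobes inside the quantifiable window.
* **Noise.** Each paramagnetic height is its diamagnetic partner times
  the forward ratio times a multiplicative Gaussian factor
  (cv = 0.05), so the observed ratio carries exactly 5% noise — the
  quantity whose uncertainty the experiment actually reports. Height
  noise on the diamagnetic reference is deliberately not modeled
  separately: it would compound to ~7% ratio noise and overstate the
  stated experimental uncertainty.
* **Detection floor.** A peak whose noiseless ratio falls below the
  floor is omitted from the paramagnetic list — the same event the
  analyzer maps back to the floor ratio, so simulator and analyzer agree
  by construction.
* **Coverage.** A per-condition random subset of residues (drawn from
  the 32–52% assignment-coverage range unless pinned) is kept in both
  lists of a pair.
* Everything is driven by numpy `default_rng` seeds; scenario parameters
  are recorded in emitted headers.

What the generator does *not* emulate: chemical-shift changes and peak
overlap, exchange broadening, multi-conformer averaging of the released
state (an optional k-anchor average was considered and dropped — the
analyzer's single-conformer assumption is exactly what the recovery
experiment is meant to probe, and a k = 1 truth keeps its ground truth
well-defined), spectrometer artifacts, and assignment errors. Passing
recovery tests therefore demonstrate correctness of the inversion chain
under the stated noise model, not robustness to every pathology of real
spectra.

`recovery_experiment` runs simulate→pair→invert repeatedly and reports
median |bias| and relative RMSE for residues whose true distance lies in
the window, plus window-flag rates for out-of-window probes. At 5%
ratio noise and 40% coverage (50 replicates) recovered in-window
distances show median |bias| ≈ 0.04 Å and ≈3–7% relative RMSE; probes at
8 Å are flagged below-floor essentially always, and probes at 30 Å
above-ceiling in ≈88–95% of detections depending on the residue's drawn
R₂ (the 5% noise genuinely misclassifies a high-R₂ 30 Å residue into
the window several percent of the time — an inherent property of the
detection physics, not an implementation artifact).

## Crystal referencing

Reference distances are measured from the label residue's Cα (an X-ray
model carries no label atoms and usually no protons, so Cα is the only
stable proxy for the label and the backbone N for the amide group) to
every observed-chain backbone N, skipping prolines (no amide proton) and
recording — rather than silently dropping — residues or label sites
missing from the model. For crystals containing multiple copies of the
complex the chain map selects one copy. The default troponin C helix
table (N 3–11, A 14–28, B 38–48, C 54–64, D 74–84, linker 85–93,
E 95–104, F 105–115, G 131–141, H 151–158; author numbering) is the
canonical assignment and deliberately user-editable: published region
averages rarely state their exact residue sets, so bounds must be
adjustable to match any given table.

Distance displacements are stored as Δr = r(−Ca) − r(+Ca) (positive =
moved away from the label); a `table_sign` display flag renders the
r(+Ca) − r(−Ca) convention used in published summary tables. Storage and
display are separated so the stored quantity has a single unambiguous
meaning.

## Problem sizes

The shipped tests and the acceptance checks use deliberately small
problems — 24–40 residues, 20–50 Monte-Carlo replicates, 71-point
distance grids — chosen so the full suite completes in seconds while
every statistical margin above is still resolved with room to spare
(e.g. the recovery criteria pass with 3–10× headroom at these sizes).

## Known limitations

* Single evolution time point only; no multi-timepoint Γ₂ fitting.
* Single-conformer inversion; released/dynamic states yield effective,
  r⁻⁶-biased distances.
* No modeling of the nitroxide side-chain rotamer cloud; the Cα anchor
  convention is used as-is, which contributes a few Å of systematic
  offset between PRE and crystal distances.
* No cross-correlated relaxation corrections or solvent PRE.
* The Sparky-dialect reader accepts `XnnN-H`/`XnnN-HN` assignments with
  one-letter residue codes; other assignment grammars need conversion.
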