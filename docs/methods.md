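# Methods

This note documents the models behind each module, the defaults and their
rationale, the numerical choices, and what the synthetic-data generators
do and do not emulate.

## Protein charge accounting (`seqcharge`)

Net charge is a Henderson–Hasselbalch sum over independent ionizable
groups — the unfolded-chain assumption. Basic groups (N-terminus, His,
Lys, Arg) contribute `+1/(1+10^(pH−pKa))`; acidic groups (C-terminus,
Asp, Glu, Cys, Tyr) contribute `−1/(1+10^(pKa−pH))`. The default pKa
table is a standard unfolded-polypeptide set (N-term 9.0, C-term 3.1,
D 3.65, E 4.25, H 6.0, C 8.3, Y 10.07, K 10.53, R 12.48); published
calculators differ by a few tenths per group, so the table is injectable
and its name is carried in every `ChargeReport`. Terminal groups are
counted only when the analyzed region reaches the corresponding true
terminus; a mid-protein domain has no free termini.

A phosphoserine is a phosphomonoester whose first proton is treated as
fully ionized and whose second titrates with pKa2 (default 5.8):
`Δq = −1 − 1/(1+10^(pKa2−pH))`, i.e. −1.96 e at pH 7.2 and −1.86 e at
pH 6.6. Ser→Asp substitution contributes about −1 e per site at
cytoplasmic pH, which is why aspartate is the usual phosphomimetic.

Regions use 1-based coordinates, half-open internally; user-facing spans
like "251–307" are inclusive and converted on parse.

**BH scan.** The basic-hydrophobic score per window of odd length L
(default 19) is `max(0, B)·H`, with `B = (n_K + n_R − n_D − n_E)/L` and
`H` the window mean of min–max-normalized Kyte–Doolittle hydropathy.
This is a deliberately simple surrogate for web-based BH predictors, and
its scale differs from theirs: because basic residues are themselves
hydrophilic, `B` and `H` trade off and the surrogate's score cannot
exceed ≈ 0.25 even for an ideal Lys/Leu window. The conventional 0.6
threshold is kept as the injectable default for compatibility, but with
the surrogate a relative reading (motif vs background, typical peak
≈ 0.2 vs ≈ 0.1) is the meaningful one. Edge windows are not emitted.

## Membrane electrostatics (`electro`)

All constants are CODATA (F = 96 485.332 C/mol, R = 8.314462 J/(K·mol)).
Default temperature is 298.15 K and is always carried in results. The
model is the linearized Debye–Hückel regime:

* Debye length `λ_D = sqrt(ε_r ε_0 k_B T / (2 N_A e² I·1000))` — 0.785 nm
  for 150 mM 1:1 salt at 25 °C;
* screened potential `V(x) = V_0 e^{−x/λ_D}`;
* Boltzmann partition `exp(−zFV/RT)` of any charged species, protons
  included, which gives the surface pH as
  `pH_s = pH_bulk + FV/(ln 10·RT)`.

Strictly, −35 mV is ~1.4 k_BT/e, at the edge of the linear regime; the
exponential decay matches the closed-form screened values the model is
meant to reproduce, and full nonlinear Gouy–Chapman theory is explicitly
out of scope. Partition exponents beyond ±700 are reported as inf/0 with
an `overflowed` flag rather than raised.

## Three-cube FRET (`fretflow`)

Sensitized emission `F_c = S_DA − r_d·S_DD − r_a·S_AA` removes donor
bleed-through and acceptor cross-excitation; `E_D = F_c/(F_c + G·S_DD)`.
Donor abundance is `f_d(S_DD + F_c/G)` (quenching-corrected), acceptor
abundance `f_a·S_AA`. Events with a nonpositive efficiency denominator
are flagged and excluded from fits, never clamped; negative-`E_D` events
(noise) are retained.

**Binding.** `E_D = E_max·a_free/(K_d,EFF + a_free)` with `a_free`
obtained from total donor/acceptor abundances by the 1:1 mass-action
closed form. Because `a_free` depends on the unknown `K_d`, the fit is a
fixed point: freeze `a_free` at the current `K_d` iterate, least-squares
fit `(E_max, K_d)`, repeat to a relative tolerance of 1e-6 (max 100
iterations; typically < 20). Confidence intervals are a seeded percentile
bootstrap over cells (default 500 resamples, 2.5–97.5%). `K_d,EFF` is in
the same relative fluorescence-derived units as the abundances, so
rescaling concentration units rescales `K_d,EFF` identically and leaves
`E_max` untouched.

**Membrane slope.** Valid events are split into equal-count bins by
directly excited acceptor fluorescence (default 20 bins; quantile binning
is robust to the lognormal skew of expression), and an ordinary
least-squares line through the bin means gives the slope. The intercept
is fitted, not forced through the origin, to absorb baseline collisional
FRET; the slope is the reported statistic and only its *proportionality*
to the membrane-localized acceptor fraction is asserted — the absolute
scale depends on unknown collisional-geometry factors.

## Imaging (`imaging`)

Segmentation: local-mean adaptive threshold over a window of
⌈min(H,W)/8⌉ pixels (forced odd), with an additive offset
`(0.5 − sensitivity)·local_std` (sensitivity 0.5 ⇒ pure local mean;
larger admits more foreground), hole filling, removal of components below
`min_area`, 8-connected labeling. A tiny epsilon relative to the image
range guards the strict-greater comparison against sliding-sum roundoff
in flat regions. On noisy synthetic images a stricter sensitivity (~0)
suppresses background speckle.

Radial profiles peel one-pixel rings by erosion with the full 3×3
structuring element (matching the 8-connected labeling). The recursion
ends at the ring that contains the cell centroid; that final "ring" is
defined as the entire remaining pixel set, so the rings exactly partition
the cell and `Σ(ring count × ring mean)` equals the cell's total
intensity to machine precision. The centroid is the integer-rounded
unweighted centroid of the mask, snapped to the nearest cell pixel for
non-convex cells. The membrane ratio is the maximum of the outermost
rings (default 3 — one-pixel rings under-sample a thin rim) over the
centroid-ring mean.

## Electrophysiology (`ephys`)

Sweep currents are expressed relative to the holding current; under that
convention P/3 subtraction (`main − 3·mean(subs)`) annihilates any
current affine in voltage exactly. Cd²⁺ subtraction is a pointwise
difference on a shared grid. Liquid-junction correction is a constant
voltage offset (−10 mV default).

I–V relations are fitted with
`I(V) = G_max(V − V_rev)/(1 + exp(−(V − V50)/k))` by Levenberg–Marquardt
with five seeded multistart initializations; ties are broken by residual
norm, then by |V50|. Conductance fold change on ramps is
`G(V) = I/(V − V_rev)` per trace (per pF when normalizing to cell size),
averaged per condition, with |V − V_rev| < 10 mV masked because the
division is ill-conditioned there.

Half-height idealization divides the baseline-corrected current by the
unitary line `i(V) = γ(V − V_rev,sc)`; the per-sample open count rounds
with thresholds at the half-amplitude points (an exact half rounds down)
and clips to the channel count. The baseline is the median of
closed-classified samples with one refinement pass — a simple robust
estimator chosen in place of more elaborate crossing-distance schemes.
Samples where |i(V)| falls below a floor (default 0.2 pA, near the
single-channel reversal) are flagged invalid and excluded from P_O.
Ensemble P_O bins valid samples into 5 mV bins centered on multiples of
5 mV and divides the mean stacked level by the channel count; the channel
count itself is the maximal simultaneous open level across ≥ 50
high-activity sweeps. Fractional shortening is
`(L_relax − L_min)/L_relax` per stimulated contraction (L_relax taken
immediately before the stimulus), averaged and reported in percent, with
a warning flag below 8 contractions.

## Synthetic data (`synth`)

One RNG stream per modality, derived as
`default_rng([seed, crc32(modality)])`, so adding a generator never
perturbs another's output; identical configurations are bit-identical.
Noise-free outputs are exactly invertible by the corresponding analyzer
(tested sample-by-sample for gating, to 1e-5 relative for fits).

Defaults define the emulated study conditions: lognormal(0, 1)
expression (×100 a.u.) for donor and acceptor, E_D noise σ = 0.02,
n = 2000 cells; elliptical cells (radius 20–40 px) with a 2-px rim,
cytosol 200 counts over background 20, Poisson + Gaussian (σ = 2) noise;
two-state gating with `k_open(V) = k₀·e^{V/20 mV}`, constant `k_close`,
γ = 0.05 pA/mV with single-channel reversal +60 mV, noise SD = 0.15 of
the unitary amplitude, 200-ms ramps from −80 to +70 mV sampled at
10 kHz and filtered with a causal 4-pole Bessel at 2 kHz; Boltzmann I–V
(G_max 10, V50 −15 mV, k 6 mV, V_rev +60 mV) plus 1 nS linear leak; a
307-residue protein whose CTD (251–307) is Lys/Arg- and
hydrophobic-enriched with a dense basic-hydrophobic motif at 270–297 and
forced serines at the phospho-variant sites; 1-Hz half-sine shortening
twitches dipping 10% from 1.80 µm.

What the generators do **not** emulate: instrument file formats and
compensation matrices, photobleaching and focal drift, cell-to-cell
variability in rim width or point-spread blur, multi-state or modal
gating, capacitance transients, and series resistance. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical structure, not robustness to every artifact of real
recordings.

## Problem sizes used in the validation suite

Parameter-recovery checks run at sizes chosen to make their tolerances
statistically meaningful while keeping the suite fast: 2000 events for
K_d recovery (15%), 4000 events per condition for the slope-ratio check
(10%), 100 sweeps per gating condition for stationary-P_O recovery
(3 SE), 100 replicates for V50 recovery under 2% noise (1 mV mean), six
448² cells per contrast level for the membrane-ratio ladder, and one
1024² ten-cell image for the exact ring-conservation invariant.

## Known limitations

* The charge model ignores folding, local electrostatic shifts of pKa,
  and phosphate–neighbor interactions; it is the standard unfolded-chain
  estimate and matches the printed phospho deltas by construction of the
  model, not by structure.
* The BH score is a surrogate on its own scale (see above).
* Debye–Hückel screening slightly overestimates the potential's reach at
  −35 mV compared with nonlinear Gouy–Chapman theory.
* `K_d,EFF` and the membrane slope are in relative fluorescence units;
  converting to molar units requires calibration outside this package's
  scope.
* The half-height idealizer is biased for dwell times approaching the
  filter rise time (~0.17 ms at 2 kHz); the generators warn when mean
  dwells fall under two samples.
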