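# Methods

This note records the models implemented in nanospring, the parameters
that matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Worm-like chain model

All elasticity analyses share one model: the Marko–Siggia interpolation of
the worm-like chain,

    F(x) = (kB·T / Lp) · [ 1/(4(1 − x/Lc)²) − 1/4 + x/Lc ],

with persistence length `Lp` (nm), contour length `Lc` (nm) and
`kB = 0.0138065 pN·nm/K`; the default temperature is 300 K. This
interpolation is the standard convention for AFM pulling data in the
tens-to-hundreds-of-piconewton range; extensible-WLC and freely-jointed
chain variants are out of scope. The inverse (extension at given force)
is solved by bisection on `[0, Lc·(1−1e-12)]` to `1e-9·Lc`; the force is
strictly increasing in extension, so the root is unique. Fitting is
unweighted least squares on force (no per-point uncertainties are
available from typical trace files) via Levenberg–Marquardt, with
standard errors from the local quadratic approximation at the optimum.
`Lc` is bounded below by the largest observed extension; `Lp` by
`[1e-4, 1e3]` nm. The Hookean small-extension limit
`F ≈ (3kB·T/2Lp)(x/Lc)` carries a leading relative correction of `+u/2`
(u = x/Lc), i.e. it holds to 2% only for u ≲ 0.035.

The back-of-envelope contour-length estimate is
`Lc = N_residues · 0.32 nm + linker`; the PEG/anchor linker is absorbed
into `Lc` rather than modelled as a separate elastic element in series —
for a featureless disordered chain the two descriptions are
indistinguishable at the fitted precision.

## AFM trace analysis

A retract trace is zeroed in two steps. The force offset is the median of
the trailing detached segment (last 10% of samples, ≥ 20 points); the
segment must be stationary — its two halves may differ by no more than
five times the tail's own first-difference noise estimate, otherwise no
baseline is identifiable and the trace is rejected. The distance origin
is the contact point of a WLC fitted with a free offset parameter to the
first stretching branch.

Rupture peaks are local force maxima followed, within 5 samples, by a
drop of at least 30% of the peak value *and* at least five times the
baseline noise; the absolute requirement prevents noise at low force from
faking ruptures. The contour-length transform maps every point with
`F ≥ 10 pN` (below that the inversion in `Lc` is ill-conditioned) to the
`Lc` of the WLC passing through it at a fixed transform `Lp` (default
0.4 nm, the value conventionally assumed for unfolded polypeptides). The
specificity fingerprint is evaluated on the final two peaks: each
branch's `Lc` is the median transform over the samples leading up to its
peak, restricted to the upper half of the branch's force range, where the
inversion is well conditioned and force noise cannot bias the branch
separation. An event is specific iff the separation is within 8 ± 2 nm;
the 2 nm tolerance covers the transform jitter at 5 pN noise. Accepted
traces are fitted (both `Lp` and `Lc` free) from zero extension to the
first peak, with negative-force points excluded. Population statistics
use the uncorrected (population) standard deviation, and histograms at
10 nm (`Lc`) and 0.05 nm (`Lp`) bins.

## WHAM

The potential of mean force G(z) is reconstructed from umbrella windows
by the standard self-consistent WHAM equations on a histogram grid
(default bin width 0.05 nm — below the position SD `sqrt(kBT/k) ≈
0.071 nm` of a window at the protocol spring constant
k = 500 kJ·mol⁻¹·nm⁻²). Convergence is declared when the maximum change
of the per-window free-energy shifts falls below 1e-8 kJ/mol; the
iteration is warm-started by minimising the equivalent convex likelihood
with L-BFGS (analytic gradient), which reaches the same fixed point two
to three orders of magnitude faster than direct iteration for
stiff-spring layouts. Windows are sorted internally by center before any
accumulation, so the result is bit-identical under input permutation.
Neighbouring windows whose sample ranges do not overlap raise a
connectivity error naming the gap; non-convergence is flagged on the
profile, not raised. Empty bins carry NaN free energy.

The mean restoring force is the central-difference derivative of G,
converted with 1 kJ·mol⁻¹·nm⁻¹ = 1.6606 pN, positive when resisting
extension. (The derivative route is implemented; directly averaged
constraint forces are not.) When this profile is fitted with a WLC, the
fit is restricted to below ~90% of the contour length: beyond the last
window's well-sampled range the reconstruction is edge-dominated and the
steep force rise is systematically distorted at the few-percent level.
An optional subsampling stride is exposed for correlated time series; the
default is 1 (no decorrelation is attempted).

## Collapse kinetics

The collapsed state is an end-to-end distance ≤ 1.5 nm. First-passage
times are linearly interpolated between frames; trajectories that never
cross are censored at their final time. The lifetime of the extended
state is obtained, following the cumulative-events construction, by least
squares of `N(t) = n_total·(1 − exp(−t/τ))` against the observed
cumulative curve evaluated at the event times — not by maximum likelihood
on the passage times; censored trajectories inform `n_total` but not the
curve. A free-plateau variant is available. The 95% confidence interval
is a parametric bootstrap (default 1,000 seeded resamples of `n_total`
exponential draws at the fitted τ, censored at the longest observed time
when the data contain censoring) using the basic (reflected) interval on
the log scale — the appropriate construction for a positive scale
parameter with a right-skewed small-sample estimator; it calibrates to
~95% coverage at n = 20, where the plain percentile interval undercovers
(~86%). The estimator's small-sample bias at n = 20 is below 10% of τ
(verified by simulation in the test suite).

The PPII fraction counts residues per frame whose (φ, ψ) fall in a
rectangular window, default φ ∈ [−100°, −50°], ψ ∈ [120°, 180°] —
bracketing the canonical (−75°, +145°) PPII point. The window is
configurable because no consensus dihedral definition of PPII exists.

## Amide-I decomposition

Per-well preprocessing: restriction to 1,600–1,715 cm⁻¹, linear
background removal, and vector normalisation (scaling to unit Euclidean
norm over the region). The background line is fitted by least squares
over the signal-free flanks of the region (lowest 10 and highest 15
samples; the β-sheet sub-band sits closer to the low edge, hence the
shorter low-side flank). A chord-residual statistic over the flanks
distinguishes smooth band-tail contamination from channel noise: in the
low-noise regime the contaminated inner flank samples are excluded from
the line fit (exact recovery on clean spectra), in the noise-dominated
regime all flank samples are averaged (single noisy channels cannot tilt
the baseline — anchoring the line on the two endpoint channels alone
propagates their noise into a spurious spectral component at realistic
signal-to-noise). All steps are built from operators that reproduce
straight lines and are scale-invariant, so preprocessing is exactly
idempotent. Normalisation does not mean-center: the mixture model is a
sum of non-negative Gaussians, which cannot represent a constant negative
offset.

Replicate wells of one carrier are combined by the pointwise median on
their common grid. Mixture fits use bounded least squares (centers within
the region, FWHM ∈ [2, 80] cm⁻¹, amplitudes ≥ 0) from up to 10 seeded
random starts (centers uniform over the region, FWHM uniform in
[5, 50] cm⁻¹, amplitudes from the spectrum's positive range); the
best-RSS start wins and the fit is deterministic given its seed. Model
averaging over the component count k uses

    AICc = n·ln(RSS/n) + 2p + 2p(p+1)/(n − p − 1),   p = 3k + 1,

(the +1 counts the noise variance, the least-squares AICc convention),
with Akaike weights `w_i = exp(−ΔAICc_i/2)/Σ_j exp(−ΔAICc_j/2)` and the
weighted mean/SD of k as the reported component count. In the width
analysis, components below 1% of the total area are dropped; the
surviving component nearest 1,645 cm⁻¹ (± 10 cm⁻¹) is the disorder
marker, compared against all other surviving widths by a two-sided Welch
t-test. Width is reported both as FWHM and as the Gaussian SD
(FWHM/2.3548), since reported peak "widths" in the literature are
ambiguous between the two.

## Sequence metrics

Hydropathy uses the Kyte–Doolittle scale rescaled to [0, 1] via
`(h + 4.5)/9` and averaged over 5-residue sliding windows (the
charge–hydropathy plot convention); a per-residue mode is exposed because
published mean-hydrophobicity values do not always state the averaging.
Mean net charge is `|#K + #R − #D − #E| / length` at neutral pH (H
counted as 0). The classification boundary is `R = 2.785·H − 1.151`;
points exactly on the boundary are assigned to the ordered side. Motif
scanning treats `X` as a single-residue wildcard and returns 1-based,
possibly overlapping match positions. `X` residues in sequences are
tolerated and excluded from composition denominators and hydropathy.

## Synthetic generators

Each generator draws from one explicitly seeded `numpy` Generator and
emits machine-readable ground truth; identical specs give bit-identical
output.

* **AFM traces** — per-trace `Lc` from Normal(94, 43) truncated above
  20 nm, `Lp = 0.37 nm`, white Gaussian force noise (5 pN), a random
  contact point (5–20 nm) and force offset (±20 pN), rupture forces
  uniform in 150–300 pN, and for the specific fraction (default 0.8) a
  terminal second branch at `Lc + 8 nm`. Non-specific traces split
  evenly between single-rupture and no-adhesion. Distance noise is not
  modelled separately; it is subsumed in the contact-point uncertainty.
* **Umbrella windows** — inverse-CDF sampling of the exact biased
  Boltzmann density on a fine grid (1e-3 nm); window ladder 0.4–6.8 nm in
  0.4 nm steps (the largest step grid below the 7.0 nm protocol bound),
  k = 500 kJ·mol⁻¹·nm⁻², 300 K. Asymmetric sampling times are
  represented as per-window sample counts. Samples are independent —
  real umbrella time series are autocorrelated, so passing tests bound
  estimator error, not the effective sample size of real data.
* **Collapse trajectories** — a 1-D overdamped Langevin process
  `z ← z − (D/kBT)·U′(z)·dt + sqrt(2·D·dt)·ξ` on an effective
  end-to-end-distance potential (default: quartic double well with
  minima at 1.0 and 4.5 nm and a thermal-scale barrier, D = 1.5 nm²/ns,
  dt = 2 ps), reflecting at zero and at the maximal extension. This is
  deliberately not a chain model: the analyses consume only end-to-end
  distances, and the barrier-dominated escape yields the near-exponential
  first-passage statistics the lifetime fit assumes. A time step too
  large for the potential stiffness (`dt > kBT/(D·max|U″|)`) is rejected.
* **Amide-I plates** — three Gaussian components (1,625/14, 1,650/18,
  1,680/12 cm⁻¹ center/FWHM, mimicking β-sheet, random-coil and turn
  sub-bands) plus a linear baseline and per-well white noise on a 1 cm⁻¹
  grid, replicated over wells and carriers. Instrument drift,
  atmospheric water-vapour lines and inter-well signal variation are not
  emulated, so passing tests demonstrate correctness of the estimator
  chain, not robustness to those artefacts.

## Problem sizes used in tests

The test suite exercises the pipeline at the study's own scales: 500
traces for population recovery, 17 windows × 5,000 samples for WHAM
(20,000 in the reproduction script, where the tighter profile is worth
the extra seconds), 20 trajectories per lifetime fit with 1,000 bootstrap
resamples and 200 calibration replicates, 9-well × 4-carrier plates with
mixture fits up to k = 7 (the averaging machinery accepts up to 13;
beyond 7 the weights at these signal-to-noise ratios are numerically
zero and contribute nothing but runtime).

## Known limitations

* The AFM contact-point fit assumes a single dominant WLC branch before
  the first rupture; stacked unfolding intermediates would bias it.
* WHAM assumes uncorrelated samples; no statistical-inefficiency
  correction is applied (a stride is exposed instead).
* The AICc-weighted component count is mildly biased upward (~+0.3 at
  signal-to-noise 100) because residual baseline imperfections compete
  with the penalty term; this matches the behaviour of the procedure
  itself, not a defect of the optimiser.
* The charge–hydropathy classification of a full protein requires its
  complete sequence; the bundled peptides are the printed repeat units
  and tags only.
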