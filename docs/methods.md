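# Methods

## Scope and model overview

`cellinflate` models how the mean size and DNA content of exponentially
growing *E. coli* respond to three orthogonal growth limitations:
nutrient quality (`nutrient`), sub-lethal translation inhibition by
chloramphenicol (`cm`), and forced expression of a useless protein such
as LacZ (`oe`). Three model layers are coupled:

1. **Proteome allocation** (`allocation`). The division-initiator
   proteome fraction φ_X(λ) carries all growth-rate dependence:
   φ_X ∝ λ under overexpression, φ_X ∝ (1 − λ/λ₀) under nutrient
   limitation, and φ_X constant under chloramphenicol (a phenomenological
   encoding of the flat measured size, not a mechanistic law). All
   branches are anchored at the unperturbed glucose point
   λ_ref = 0.98 h⁻¹; the nutrient line's x-intercept is λ₀ = 2.2 h⁻¹.
   The nucleotide-enzyme fraction φ_nuc ∝ λ is modelled for the
   overexpression branch only; other modes return the reference value
   (module constant `PHI_NUC_MODELED_MODES` records which branches are
   laws).

2. **Mean-field threshold-initiator division** (`meanfield`). Division
   requires the per-cell abundance of the initiator X to reach a fixed
   threshold P_X\*, giving mean protein at division ⟨P\*⟩ = P_X\*/φ_X and
   extant-population mean ⟨P⟩ = prefactor · ⟨P\*⟩. The prefactor is
   ln 2 ≈ 0.693 for an extant snapshot of deterministic sizer cells
   (default, validated against the simulator and by quadrature of the
   extant age density (2 ln2/τ)·2^(−a/τ)); 3/4, the uniform-cell-cycle
   value, is available as an option. All reported quantities are ratios,
   so the choice does not affect them. Size folds between modes at equal
   λ reduce to φ_X ratios and are parameter-free: at λ = 0.2 h⁻¹ the
   overexpression/nutrient fold is (0.98/0.2)·(1 − 0.2/2.2)/(1 − 0.98/2.2)
   ≈ 8.03.

3. **Cooper–Helmstetter replication** (`replication`). With C the
   chromosome replication time and D the post-termination lag, the
   population-average DNA content is
   G = τ/(C ln 2)·(2^((C+D)/τ) − 2^(D/τ)) genome equivalents. The closed
   form is not taken on trust: an independent numerical oracle integrates
   per-cell DNA over the extant age distribution. The per-age content is
   computed exactly by noting that the copy number of the locus at map
   position x doubles C(1−x)+D minutes before each division; integrating
   copy number along the chromosome (exact, segment-by-segment, after the
   substitution u = C(1−x)+D) and then over age by the trapezoid rule
   reproduces the closed form to ~1e−13 relative at a 10⁶-point grid.
   One wrap-around subtlety matters: age = τ must be treated as the
   pre-division endpoint (twice the newborn content), not wrapped to 0,
   or the quadrature degrades to O(1/n). `c_period_from_dna` inverts the
   closed form by bracketing plus Brent's method (residual < 1e−9);
   reaching 8 genome equivalents at τ = 166 min requires C ≈ 770 min,
   i.e. the multifork slow-fork regime C ≫ τ. The nucleotide-limited
   prediction ⟨D⟩/⟨P⟩ ∝ φ_nuc/λ is constant under overexpression.

## Single-cell simulator

Cells grow as dp/dt = λp and make X as a fixed share of protein flux,
dp_x/dt = φ_X λ p — the simplest kinetics consistent with φ_X being a
proteome fraction. Division triggers at p_x ≥ threshold. Two division
rules are provided:

* **Full consumption** (default): X is reset to zero in both daughters.
  Because p_x then equals φ_X times the protein added since birth, the
  rule is an exact adder with increment P_X\*/φ_X, and the zero-noise
  division size is 2·P_X\*/φ_X.
* **No consumption** (`consume_x=False`): X splits with the protein;
  the zero-noise division size is P_X\*/φ_X, matching the mean-field
  ⟨P\*⟩ exactly.

At the population level the two differ only by a factor-2 rescaling of
the threshold, so every reported ratio is rule-independent; tests
normalise by the rule's own division size.

Numerics: the within-step dynamics are linear, so the update applies the
exact exponential solution and resolves threshold crossings analytically
at their exact sub-step time (division size p₀ + (thr − p_x0)/φ_X, no
discretisation overshoot). A dt ≤ 0.01/λ accuracy contract is enforced
so that multiple divisions per cell per step cannot occur; the default
step is 0.005/λ. Noise: per-division thresholds are
P_X\*·(1 + N(0, cv)) truncated at 0.1 (default cv 0.1), and daughters
receive fraction 0.5·(1 + N(0, cv)) of the protein, clipped to
[0.2, 0.8] (default cv 0.05). The magnitudes are calibration choices —
no single-cell noise measurements are modelled — picked to give
realistic relative size spreads (~25%).

Two population-bookkeeping details are deliberate:

* The initial population is placed on the deterministic steady state
  with ages drawn from the extant density (2 ln2/τ)·2^(−a/τ). This is
  not cosmetic: the zero-noise dynamics preserve the initial age measure
  exactly (there is no mixing), so a uniform-age start would *never*
  relax to the snapshot bias and the mean-size/division-size ratio would
  converge to 3/4 instead of ln 2.
* When the population exceeds 1.5× the target, a uniform random subset
  is kept (unbiased in size). Repeated renormalisation makes the
  population's phase composition drift slowly (a neutral-drift effect),
  so the mean of a single zero-noise run scatters more than the naive
  s/√n standard error; statistical checks therefore use means of
  replicate runs and the empirical standard error across replicates.

Burn-in is 10 generations (snapshots taken earlier carry
`steady=False`); default runs last 14 generations. `attach_dna`
evaluates the Cooper–Helmstetter per-age content at each cell's age
(ages beyond τ, which occur under noise, wrap modulo τ) and agrees with
the closed-form average within Monte-Carlo error plus the drift above
(tested at 2%).

## Morphometry

Cells are measured as spherocylinders: V = πR²(L − 2R/3) with R = W/2,
L the maximum and W the minimum Feret (caliper) diameter — for a
spherocylinder the minimum Feret equals the true width exactly, which
justifies the identification. Segmentation is a global threshold,
connected components, and removal of border-touching components.

The threshold is Otsu's value refined by iterating to the midpoint of
the two class *medians*. Two biases motivated the refinement, both
measured on rendered ground truth: Otsu's criterion drifts toward the
dominant background mode when cells occupy a small area fraction
(masks grow ~0.5 px per side), and class means are dragged by edge
pixels. Feret diameters are computed by rotating calipers on the convex
hull of the sub-pixel iso-threshold contour (`skimage.find_contours`);
measuring on whole-pixel hulls instead adds ~1 px to both L and W and
pushes median volume errors above 15%. With the sub-pixel chain the
benchmark (500 rendered cells, L ∈ [1.8, 4.5] µm, W = 0.9 µm,
0.05 µm/px, blur σ = 1 px, noise SD 0.02) gives a median volume error
of ~4%. Residual width bias (~0.4 px) comes from noise-induced outward
jitter of the hull.

The renderer draws antialiased spherocylinders (linear 1-px edge ramp
on the distance-to-axis field) as dark cells on a light background,
then Gaussian blur and additive noise. The DAPI-like channel assigns
each cell a total intensity proportional to its ground-truth DNA and is
rendered *unblurred* so integrated density is conserved per cell by
construction; quantification sums background-median-subtracted
intensity over each phase-derived mask and calibrates to genome
equivalents against a reference cell. Optics are deliberately
simplified (no PSF model): the measurement chain, not image realism, is
the test surface.

## Synthetic data and calibration

`synthetic.DEFAULT_CALIBRATION` pins every number the generator uses;
`load_calibration` merges YAML overrides. The default panel: glucose
(λ = 0.98), mannose (0.41), slow nutrient (0.20), chloramphenicol
(0.32), LacZ overexpression (0.25) and slowest overexpression (0.20).
Per-cell protein targets come from the mean-field model relative to the
glucose anchor. DNA targets: 8 genome equivalents at the slowest
overexpression point, scaled as 8·(0.2/λ) across the OE series (DNA
tracks protein with an attenuated constant ratio — the constant-ratio
prediction itself overshoots the emulated measurements, so the
calibration encodes the attenuation rather than a mechanism); 2.0 for
slow nutrient growth (making the OE/nutrient DNA fold 4); the
Cooper–Helmstetter value with C = 40, D = 20 min for faster nutrient
conditions; 1.9 for chloramphenicol (size and DNA flat). RNA/protein
ratios are plausibility choices (rising with nutrient quality, elevated
under chloramphenicol) — the RNA trend under overexpression is a
calibration choice, not a measured law. Protein + RNA + DNA account for
90% of dry mass.

Bulk totals are per-cell targets × a count density that scales
inversely with cell size (4×10⁸ cells/ml for glucose at OD 0.4), with
mean-one multiplicative lognormal noise (default CV 5%; no assay CVs
are modelled from data). Counting biases: plating = 0.9× Coulter for
overexpression, 0.8× for chloramphenicol; for nutrient growth below
0.7 h⁻¹ the Coulter counter reads 0.85× the true count (magnitude a
calibration choice; only its sign is constrained) while plating is
unbiased. The per-cell accounting's count-selection rule (plating for
slow nutrient growth, Coulter otherwise) always picks the unbiased
method, so the zero-noise round trip is exact — a deliberate closure
property used as a test invariant.

What the generator does *not* emulate: real assay chemistry,
OD-growth kinetics, instrument-specific count distributions,
correlated assay errors, or biological replicate variability beyond
lognormal noise. Passing round-trip tests therefore demonstrates the
internal consistency of the accounting and fits, not agreement with any
real measurement campaign.

## Fits and the Model front end

1/⟨P⟩-vs-λ fits use unweighted OLS (statsmodels); λ₀ is reported as
−intercept/slope with a delta-method standard error. Proportionality
fits are through-origin least squares with R² computed against the
*centred* total sum of squares, clipped to [0, 1], so data unrelated to
x score near zero even with a non-zero mean.
`ThresholdInitiatorModel.fit()` wraps these per-mode fits into a
Results object (λ₀ ± SE, summary table, predictions, parameter-free
fold predictions, simulator and plotting hooks).

## Problem sizes and numerical defaults

Simulator checks use 2 000–10 000 cells and 14 generations; statistical
assertions use 5 replicate seeds per condition where drift matters. The
replication oracle grid is 10⁶ ages (10⁵ in the grid sweep). The
morphometry benchmark renders 500 cells across twenty 900² frames. The
full-chain `pipeline.reproduce` report uses 6 bulk replicates per
condition and a 120-cell rendering benchmark. These sizes make every
statistical margin comfortable while keeping the whole suite fast on a
single CPU.

## Known limitations

* Protein X is not identified; the chloramphenicol branch is
  phenomenological, and additional division checkpoints (chromosome
  state, elongation) are not modelled — the threshold is the sole
  trigger.
* The DNA–protein attenuation under overexpression is a calibration
  constant, not a mechanism; whether initiation factors or nucleotide
  supply limit DNA content there is left open (both C/D and the
  calibration targets are configurable).
* `attach_dna` assumes the replication clock matches the growth rate
  and wraps noisy ages modulo τ; cells older than τ under strong noise
  are approximated, not modelled.
* The renderer has no point-spread function or phase-contrast halo;
  segmentation accuracy on real micrographs will be worse than on the
  benchmark.
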