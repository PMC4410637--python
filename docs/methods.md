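# Methods

## Model

A two-signal factorial experiment measures a log2-scale output in four
conditions: control (0), X, Y and X+Y. For condition means
`e_0, e_X, e_Y, e_XY`, the increments are `Δe_X = e_X − e_0`,
`Δe_Y = e_Y − e_0`, `Δe_XY = e_XY − e_0`. Additivity on the log scale
(`Δe_XY = Δe_X + Δe_Y`, i.e. multiplicative/Bliss independence on the
raw scale) is the no-interaction null; the strict inequalities
`e_XY − e_X − e_Y + e_0 > 0` (< 0) define positive (negative)
interactions. The qualitative outcome of an experiment is a *ranking*:
a weak ordering of the four means, encoded as the sign vector
`(c1..c6)` of the six ordered pairwise comparisons
(X−0, Y−0, XY−0, Y−X, XY−X, XY−Y), each component in {−1, 0, +1}.

## Enumeration

The number of weak orderings of n conditions with exactly k distinct
levels satisfies `A(n,k) = k·(A(n−1,k) + A(n−1,k−1))`, `A(1,1) = 1`
(equivalently `k!·S(n,k)` with Stirling partition numbers): a new
condition either joins an existing group or founds a new one, and the
group it lands in can be any of the k. For n = 4 the layers contribute
1, 14, 36, 24 → 75 rankings; totals over k are the ordered Bell numbers
1, 3, 13, 75, 541 for n = 1..5. The enumeration is realized by encoding
all 4⁴ rank assignments and deduplicating; a vector is accepted as a
weak ordering iff re-encoding its induced rank assignment (rank = number
of conditions strictly below) reproduces it, which rejects intransitive
sign patterns.

## Feasibility and the catalog

Whether a ranking admits a given interaction sign is decided by exact
linear feasibility: the six (in)equality constraints of the ranking plus
the strict interaction inequality, with all four values bounded to
[2, 16] (the approximate log2 range of Affymetrix intensities; the
bounds are configurable, and they matter — e.g. two-level rankings near
the bounds lose feasible room). Strict inequalities are handled by a
margin variable t shared by all strict constraints; the LP maximizes t
and the system is declared satisfiable iff the optimum exceeds 1e−9.
The labelling of the 75 rankings is 29 positive-only, 29 negative-only,
12 dual-sign ("ambiguous", realized once per sign) and 5 additive-only
(excluded), giving 82 profiles, 41 per sign. The sign-flip reflection
e ↦ 18 − e maps the positive sub-catalog bijectively onto the negative
one; this symmetry is asserted, not assumed.

Each profile carries a deterministic *prototype*: the LP is re-solved in
the k level variables (tied conditions share one variable, so ties are
exact by construction), maximizing the minimum slack of level gaps,
distance to the bounds and the sign inequality — a Chebyshev-center
style representative. A secondary objective of −1e−7·Σlevels resolves
degenerate optima. Prototypes re-encode to their ranking at tolerance 0
and their minimum constraint slack over the catalog is 2.33 log2 units.
How (or whether) representative realizations were chosen in prior work
is not documented; this construction is this package's own.

## Modes

The 82 profiles reduce to 10 interaction modes via a decision tree on
the single-signal effects (c1, c2); for positive profiles:
emergent positive synergy (c1 = c2 = 0), positive synergy
(c1, c2 ≥ 0, not both 0), X restores Y (c2 = −1, c1 ≥ 0), Y restores X
(c1 = −1, c2 ≥ 0), low stabilization (c1 = c2 = −1); negative profiles
use the sign-flipped mirror. The resulting partition (19/8/8/5/1 per
sign) is nonempty in all 10 classes, equivariant under conjugation
(sign flip) and maps the restore/inhibit opposite pairs onto each other
under the stimulus swap (c1↔c2, c5↔c6, c4 ↦ −c4). The tree is a
reconstruction from the verbal mode definitions; because the original
per-profile membership table exists only graphically, it is validated
by these structural invariants rather than by per-mode counts, and it
is versioned — changing it is a breaking change. Stabilization profiles
whose combination crosses the control level are flagged as edge cases.

## Statistical workflow

* **Pre-processing.** Probe sets collapsing to one row per gene symbol
  (highest overall mean wins; ties broken toward the lexicographically
  smaller feature id — the choice is arbitrary but deterministic).
  Detection filter: a gene is kept iff some condition has *every*
  replicate strictly above the log2 detection threshold (default 4).
* **Regulated genes.** Per-gene fixed-effects one-way ANOVA across the
  four conditions; Benjamini–Hochberg across genes; selection at
  q ≤ FDR (default 5%).
* **Non-additive genes.** Among regulated genes only (sequential
  filtering), the 2×2 factorial interaction test. At 2×2 the
  interaction F test equals the squared t test of the contrast
  `L = m_XY − m_X − m_Y + m_0` against the pooled within-condition
  residual (df = N−4); this form is used, is Type-III-equivalent, and
  remains valid for unbalanced replicate counts. BH across the
  regulated genes.
* **Comparison vectors.** For each of the six pairs, a two-sided
  pooled-variance t interval at level 1−α (default α = 0.05, no
  multiplicity adjustment across the six comparisons) codes 0 if the CI
  contains 0, else the sign of the difference. An optional
  practical-equivalence tolerance additionally codes 0 whenever
  |mean difference| ≤ tol. Rationale: a pure CI rule calls a true
  equality non-zero with probability exactly α per comparison, so even
  noiseless-in-the-limit data mis-encode ~5% of tied pairs; when the
  replicate noise and the smallest meaningful effect are known (as in
  synthetic data), tol should be placed between ~8 standard errors of a
  mean difference and the smallest real effect gap. The tests use
  tol = 0.5 against the catalog's minimum gap of 2.33. Default is 0
  (pure CI rule).
* **Matching and learning.** The vector plus the observed sign of L is
  looked up in the catalog (dual-sign rankings are resolved by the
  sign). Vectors that match nothing — intransitive patterns,
  additive-only rankings, sign-infeasible rankings, or a zero contrast —
  fall through to 1-nearest-neighbour assignment over the prototypes of
  the sign-matching sub-catalog, using correlation distance
  d = 1 − Pearson r on the 4-vector of condition means (invariant to
  affine rescaling of the response; within one sign class, affinely
  related prototypes would share a ranking, so the minimizer is
  unambiguous). Ties break by profile id; constant mean profiles are
  reported unclassifiable.
* **Zero-variance guard.** 1e−12 is added to residual mean squares so
  noiseless fixtures keep defined F statistics.

The summary reports per-stage counts, per-mode counts, the mode
distribution normalized by the number of theoretical profiles per mode,
and the dominance fraction within each opposite-mode pair (descriptive).

## Strength and AIC gene-set analysis

`s = <Δe_XY> − (<Δe_X> + <Δe_Y>)` per gene, averaged over replicates.
The background (all genes passing filtering, size n) is fitted by a
Gaussian with ML estimates (σ̂² = 1/n form). For each gene set with
m ≥ 10 members in the background, four nested configurations are
compared by AIC = 2k − 2 lnL: shared (μ, σ) [k=2]; separate means,
shared σ [k=3]; shared mean, separate σ's [k=3, shared-μ ML by
fixed-point iteration of the precision-weighted mean]; separate (μ, σ)
[k=4]. Scenarios 1–2 reduce to the closed forms
`(n+m)(log(2πσ̂²)+1) + 2k`, which the tests assert. By default term
genes remain part of the background group (likelihood over n+m values);
`disjoint_background` removes them first. The AIC penalty of 2 per
parameter implies that under the null each alternative scenario still
wins with probability ≈ P(χ²₁ > 2) ≈ 16%, so null terms retain
scenario 1 roughly 70–80% of the time — an intrinsic property of AIC
selection, not a defect of the fit; users wanting stricter null
retention should compare AIC differences against a larger threshold.
Mode dominance of a term is the per-mode fraction of its interaction
genes (argmax dominant, ties by name).

## Synthetic data

`simulate_experiment` emulates replicated two-signal microarray
experiments: 3 replicates by default (typical donor counts are 3–5),
log2 values in [2, 16], i.i.d. Gaussian replicate noise (default
σ = 0.2, a realistic replicate spread for normalized arrays; no donor
random effect by default, matching a donors-as-replicates analysis).
Profile genes take their profile's prototype as condition means (well
separated: minimum gap 2.33); additive genes draw single-signal
increments uniformly in ±1.5 log2 units with exactly additive
combination; inactive genes are constant with baselines spanning the
full range, so a fraction falls below the detection threshold by
design. The generator does not emulate probe-level artifacts,
saturation, gene–gene correlation, batch effects or time dynamics —
passing recovery tests therefore demonstrates correctness of the
statistical machinery under its own assumptions, not robustness to
those real-data features. `simulate_geneset_collection` plants
pairwise-disjoint null, mean-shifted (default +3σ_b) and
variance-inflated (default ×2) terms of 50 genes in a 5000-gene
N(0, 0.5²) strength background, plus mode-dominated terms taken from an
experiment's truth table.

Test and acceptance runs use deliberately compact problem sizes —
82–410 planted genes, 150-gene × 500-replicate null panels for the
empirical FDR, 200 replicates for scenario-selection frequencies —
chosen to make the suite quick to iterate on while keeping binomial
noise well below the asserted margins.

## Known limitations

* The mode decision tree is a reconstruction; alternative boundary
  choices (e.g. for profiles with one null single-signal effect) would
  move a handful of profiles between synergy and restore/inhibit
  classes without affecting the partition invariants.
* The CI comparison-vector rule has a per-comparison type-I rate of α
  for true ties; without an equivalence tolerance this caps exact
  profile recovery near (1−α)^z for a profile with z tied pairs.
* The workflow is strictly 4-condition (2×2); only the ranking counter
  generalizes to other n.
* Time-course designs are not modelled; runs at different time points
  are analysed independently.
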