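# Methods

## Representation

A substituted [6]helicene is the occupancy of the 16 substitutable
scaffold positions (1-based, standard numbering) by one of 16
substituent groups or H, plus a helical sense (P by default). The only
descriptor channel is the para Hammett constant σ_p of each occupant,
taken from the standard Hansch–Leo–Taft compilation and shipped as an
editable CSV (`heliforge/data/sigma_p.csv`; H 0.00, F 0.06, Cl 0.23,
Br 0.23, I 0.18, NH2 −0.66, OH −0.37, OMe −0.27, SH 0.15, SMe 0.00,
NO2 0.78, CN 0.66, CHO 0.42, COOH 0.45, CH3 −0.17, C≡CH 0.23,
C≡CPh 0.16). The encoding is deliberately degenerate where σ_p
collides (SMe vs H, Cl vs Br vs C≡CH): molecule identity is carried by
the code sequence, and `DescriptorTable.degenerate_codes()` audits the
collisions. Canonical names use the Position-Substituent scheme
(`1-SH_3-F_8-OH`), ascending positions, ASCII hyphens (Unicode hyphen
variants are accepted on input, since PDF-derived text uses them).

The C2 symmetry of the scaffold maps position i to 17 − i; `mirror` is
the corresponding involution on occupancies. Counting the design space
uses exact big-integer arithmetic: without folding,
Σ_{k≤6} C(16,k)·16^k = 139 053 725 953; folding the two-element mirror
group by Burnside's lemma (average of the total and the 236 673
mirror-fixed patterns) gives 69 526 981 313 ≈ 7 × 10¹⁰. Both formulas
are validated against exhaustive orbit enumeration on all small
instances.

## Chiroptics

g_abs = 4|m||µ|cosθ / (|µ|² + |m|²) with |µ| stored in 10⁻¹⁸ esu·cm
and |m| in 10⁻²⁰ erg·G⁻¹ (the units every number in this field is
printed in) and converted to absolute cgs inside the formula; the
result is bounded by ±2, with equality only for equal absolute
magnitudes and parallel/antiparallel vectors. The enantiomer flip
inverts the sign of every chiroptical quantity; because R₊/R₋ are
defined as the spectrum's extreme positive/negative rotatory
strengths, the flip swaps their roles together with their wavelengths,
preserving the R₊ ≥ 0 / R₋ ≤ 0 convention. ECD-style curves are
rendered as sums of Gaussians in wavelength space (default σ = 15 nm,
config-overridable); the broadening is presentation only and never an
evaluation surface.

## Synthetic oracle

The surrogate landscape stands in for a TD-DFT corpus; it emulates the
statistical structure that makes local modelling meaningful, not any
specific molecule's value. Design:

* **Anchors.** The unsubstituted parent reproduces, at zero noise, the
  reference values R₊ = 694, R₋ = −514 (10⁻⁴⁰ esu·cm·erg·G⁻¹),
  λ₊ = 342.6 nm, λ₋ = 254 nm and |m|₁ = 0.36 (10⁻²⁰ erg·G⁻¹). The
  parent's λ₁ (410 nm), R₁ (20), |µ| (1.0) and θ (π/4) are not
  reported anywhere and are declared stand-ins; the parent's g_abs
  (≈ 0.0102) is *computed* from those moments.
* **Responses.** Each channel (six direct properties plus the latent
  m, log |µ| and cos θ) is a per-position linear form in σ_p with a few
  pairwise σᵢσⱼ couplings, squashed through a tanh saturation so
  cumulative shifts stay physical. Position weights are largest at the
  terminal positions (1–3, 14–16), the qualitative trend this family
  exhibits; per-position jitter is drawn once from a structure seed and
  is part of the landscape definition.
* **Moment coupling.** |µ|, |m| and θ are generated first and g_abs is
  always evaluated through the two-vector formula — never sampled — so
  the physical route to extreme g (suppressing |µ| at near-constant
  |m|) exists in the surrogate exactly as it does in reality. The
  log-|µ| response carries three strongly donor-sensitive positions
  (1, 3, 6), giving a rare low-|µ| pocket (|µ| down to ≈ 0.05) with g
  reaching the few-times-10⁻¹ regime; the response is bounded on both
  sides (saturation 3.2, upper log-cap 1.2, |µ| ≤ ≈ 3.3) so the
  emissive tail stays in the range reported for this family and
  held-out residual tails remain in the sub-10 % outlier regime that
  the evaluation protocol expects of the data it emulates.
* **Noise.** Gaussian, per channel, heteroscedastic (R± 25, R₁ 10,
  λ± 3 nm, λ₁ 5 nm, m 0.10; 0.12 / 0.03 on the latent log |µ| /
  cos θ — the moment channels carry the largest irreducible
  variability of the ground-truth protocol they emulate). Noise
  streams derive from the molecule's canonical name, so a dataset is
  reproducible row by row and byte-identical under a fixed seed.
* **Regime switch** (off by default). For the three moment channels,
  the two sides of an oblique hyperplane in descriptor space
  (σ₁+σ₂+σ₃ − σ₁₄−σ₁₅−σ₁₆ = 0) carry different flipped linear
  coefficients *and* different dense quadratic forms. The landscape
  stays smooth within each side but is governed by different couplings
  across it — the heterogeneity under which one global regressor is
  genuinely less informative than query-local ones, used by the
  local-vs-global benchmark.
* **Planted optima.** For optimizer-recovery tests, a localized bonus
  bump (linear decay, support radius δ = 0.05 in descriptor distance,
  height 2×saturation + margin) makes a designated molecule the unique
  global optimum of one property by at least the margin.

Datasets are sampled without replacement, stratified uniformly over
substituent counts 1..6, within one of the six families (halogen, EDG,
EWG, carbon, the F/CN/OMe/C≡CH transferability mix, or the full
inventory); the default corpus spreads 3000 rows evenly over all six.
Strata a small family cannot fill (64 mono-substituted halogenated
molecules < an equal-stratum quota) overflow into the next stratum.

What the surrogate does *not* emulate: conformational effects, vibronic
structure, family-specific resonance effects beyond σ_p, or the true
DFT values of any non-parent molecule. Tests passing against it show
that the machinery (retrieval, regression, optimization, looping) works
on a landscape with the right smoothness, coupling and heterogeneity —
not that the models would reach any particular accuracy on real
TD-DFT data.

## Local model and evaluation

Per query: the k = 100 nearest training molecules under the weighted
Euclidean distance (uniform weights by default; the per-position weight
vector is config-exposed), ties broken deterministically by canonical
name; one `RandomForestRegressor` per property fitted on that
neighbourhood (defaults: 100 trees, unlimited depth, √-feature
sampling, seeded per query and property). 100 trees were adopted after
measuring that per-property MAE on the default corpus is
indistinguishable from 300 trees (within 1 %) at a third of the cost;
the count is config-exposed. g_abs predictions are clamped to the
physical [−2, 2]. A query present in the pool is excluded from its own
neighbourhood (leakage guard); an all-identical-feature neighbourhood
falls back to the neighbourhood mean with a logged warning. The global
baseline fits one forest per property on the whole pool with the same
hyper-parameters.

Evaluation on a seeded 20 % held-out split reports MAE and RMSE per
property and flags outliers by the robust rule
|r − median(r)| > 2.5 × 1.4826 × MAD(r), the 1.4826 factor being the
normal-consistency scaling of the median absolute deviation.

## Genetic algorithm

Individuals are occupancy tuples. Defaults: population 1000 (scenario
runs here use smaller populations; all sizes config-exposed),
uniform crossover at rate 0.8, mutation moves substitute / add / drop /
relocate (0.05 / 0.15 / 0.15 / 0.10), tournament selection of size 3,
elitism 5, fitness caching by canonical name. Objectives scalarize as a
weighted sum: maximize → +v, minimize → −v, target → −|v − t|,
threshold → −deficit when unmet. Structural constraints are enforced by
repair (forbidden codes re-rolled, banned positions cleared, symmetry
restored by copying the lower position of each pair onto its partner,
excess substituents dropped randomly — pairwise under symmetry);
property windows cannot be repaired, so violating candidates rank below
every feasible one during selection (offset 10⁹ minus the violation,
which preserves a gradient toward feasibility) and are never reported.
Reported candidates come from the full archive of evaluated feasible
molecules, not just the final population, and each is re-audited
independently before reporting. A weighted-sum scalarization (rather
than Pareto ranking) matches the single-ranked-list use of the tool;
weights are config-exposed.

## Iterative loop

Each round trains a local-model predictor on the current dataset
(restricted to the target property for speed; remaining record fields
are filled with pool medians solely to keep records well-formed), runs
the GA, sends the top `batch` (default 20) novel candidates to the
ground-truth evaluator, and appends the results. Appended rows always
carry evaluator values — the loop cannot confirm its own predictions.
Convergence is tracked as the best |value − target| reached so far;
the loop stops early when no novel candidate is produced or an optional
tolerance is met. Loop runs inside the test suite use deliberately
small GA populations and forests (e.g. population 40, 50 trees) —
the convergence behaviour, not the polish of any single run, is the
property under test.

## Numerical choices and edge cases

* Distance ties and tournament ties resolve by canonical name order —
  full determinism under a fixed seed, everywhere.
* All sub-seeds derive from one global seed via SHA-256 over a token
  path (stable across platforms/processes, < 2³¹).
* CSV floats are written at repr precision and parsed with pandas'
  round-trip parser, so dataset pipelines are byte-stable.
* Saturations, floors (|µ| ≥ 0.01, |m| ≥ 0.02, λ > 0) and the g clamp
  keep every generated or predicted record inside the physical
  invariants that `PropertyRecord` enforces.
* `weighted_distance` accepts any non-negative, not-all-zero weight
  vector; zero weights deliberately collapse coordinates (and break
  metric identity), which is the intended semantics of "this position
  does not matter".

## Known limitations

* The SI-level details of the original protocol (distance weights,
  forest hyper-parameters, GA operator rates) are not public; the
  defaults here are declared package choices, not inferences.
* The surrogate's σ_p table is a literature compilation; if the exact
  constants used to build the original dataset differ, encodings (and
  the SMe/H degeneracy) shift accordingly.
* Molecule-level DFT-validated numbers from the original study (e.g.
  R₊ = 1486 for the best alkyne candidate, g_abs = 0.389) require
  TD-DFT and appear in this package only as fixture values in
  ranking tests — the surrogate neither reproduces nor aims to
  reproduce them.
* Multi-objective handling is scalarized; no Pareto front is exposed.
* Descriptor degeneracy is audited but not resolved: no auxiliary
  identity channel is appended to the distance metric, so σ_p-identical
  molecules (SMe vs H) are genuinely indistinguishable to the regressor,
  exactly as under the pure-Hammett encoding.
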