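# heliforge

Local machine-learning models and genetic-algorithm inverse design for
the chiroptical properties of substituted [6]helicenes.

## The problem

[6]Helicene is a helically chiral polyaromatic whose 16 substitutable
ring positions, decorated with up to six groups drawn from a
16-substituent inventory (halogens, electron donors, electron
acceptors, carbon-based groups), span a chemical space of roughly
7 × 10¹⁰ molecules. Each molecule carries nine photophysical and
chiroptical descriptors: the extreme rotatory strengths *R₊* / *R₋* and
their wavelengths *λ₊* / *λ₋*, the lowest-energy transition's *R₁* /
*λ₁*, the S₀→S₁ transition dipole magnitudes |µ| and |m|, and the
absorption dissymmetry factor

&nbsp;&nbsp;&nbsp;&nbsp;*g*\_abs = 4 |m| |µ| cos θ / (|µ|² + |m|²),&nbsp;&nbsp;&nbsp;&nbsp;|*g*\_abs| ≤ 2,

where θ is the angle between the two transition dipole vectors.
Computing these properties from first principles (TD-DFT) for more than
a vanishing fraction of the space is impossible, and a single global
regressor is a poor fit to a landscape governed by different electronic
couplings in different regions.

`heliforge` implements the alternative: a **local modelling** strategy
in which every molecule is encoded as the 16-vector of para Hammett
constants σ\_p of its substituents, and each query is predicted by a
random forest trained only on its *k* = 100 nearest neighbours under a
weighted Euclidean distance in that descriptor space. A constrained
**genetic algorithm** searches the substitution space against any
design brief — maximize a property, hit a target value, clear several
thresholds at once — with hard structural constraints (C2 symmetry,
banned groups or positions, substituent budgets) handled by repair and
hard property windows by audit. An **iterative loop** (design →
ground-truth evaluation of the top candidates → dataset augmentation →
retrain) pushes the search into property regions absent from the
initial data, and an **interpretability summary** turns candidate sets
into per-position substitution statistics from which design rules can
be read.

Because the DFT corpus behind the original study is not machine-
readable, the package ships a seeded **synthetic oracle** — a
DFT-surrogate landscape with position-dependent Hammett responses,
pairwise couplings, regime heterogeneity, and physically coupled
transition moments (g\_abs is always derived from |µ|, |m|, θ, never
sampled) — so the entire pipeline is testable end to end at desk scale.

## Worked example

```python
import heliforge as hf

# the 7e10-molecule design space (C2-symmetry folded)
print(hf.count_space(16, 16, 6, fold_symmetry=True))
# 69526981313

# a 3000-molecule six-family surrogate dataset, 80/20 split
ds = hf.generate_mixed_dataset(3000, seed=42)
train, test = hf.split(ds, 0.20, seed=42)

# per-query local random forest (k = 100) for one held-out molecule
mol = test.molecule(0)
print(mol.name)                       # 16-I
rec = hf.fit_predict_local(mol, train, k=100, seed=1)
print(round(rec.R_plus, 1), round(rec.g_abs, 4))
# 762.0 0.0143  -- predicted R+ (10^-40 esu cm erg/G) and g_abs;
# the oracle's ground truth for this molecule is 746.2 / 0.0165

# inverse design: symmetric CPL candidates, no NO2, emissive |mu|
cs = hf.ConstraintSet(
    require_symmetry=True,
    forbidden_codes=frozenset({"NO2"}),
    property_windows=(("mu_abs", 0.5, 1.5), ("g_abs", 1e-2, 2.0)),
)
res = hf.run_ga(
    hf.GAConfig(population_size=150, generations=20, seed=7),
    [hf.Objective("maximize", "g_abs")],
    cs,
    hf.oracle_predictor(hf.default_params(), seed=3),
)
print(res.best)   # 2-CN_4-CN_8-COOH_9-COOH_13-CN_15-CN  (predicted g_abs 0.143)
```

Every candidate reported by `run_ga` has passed an independent audit of
all hard constraints; `res.trace` holds the per-generation best fitness
(monotone under elitism), and `hf.pattern_summary` condenses a
candidate list into position-by-position substitution statistics.

The same operations are available from the shell:

```bash
heliforge count-space --symmetry
heliforge gen-data --n 3000 --seed 42 --out runs/data
heliforge fit-eval --data runs/data/dataset.csv --seed 42 --out runs/eval
heliforge design --spec designspec.json --out runs/design
```

Each run directory contains a `manifest.json` sufficient to replay it.

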