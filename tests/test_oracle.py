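"""The synthetic ground-truth surrogate: anchors, structure, invariants."""

import numpy as np
import pytest

import heliforge as hf
from heliforge._seeds import derive_seed
from heliforge.chem_space import encode, enumerate_molecules, format_name, parse_name
from heliforge.chiroptics import PROPERTY_NAMES, TransitionMoments, g_from_moments
from heliforge.errors import SpaceExhaustedError
from heliforge.synthetic_oracle import (
    FAMILIES,
    default_params,
    generate_dataset,
    oracle_properties,
    plant_optimum,
)

# documented Lipschitz bound of the noiseless landscape in descriptor space
SMOOTHNESS_L = 2000.0


class TestParentAnchors:
    def test_noiseless_parent_reproduces_base(self, noiseless_params, parent):
        rec = oracle_properties(parent, noiseless_params, seed=123)
        assert rec.R_plus == pytest.approx(694.0)
        assert rec.R_minus == pytest.approx(-514.0)
        assert rec.lambda_plus == pytest.approx(342.6)
        assert rec.lambda_minus == pytest.approx(254.0)
        assert rec.m_abs == pytest.approx(0.36)

    def test_parent_g_consistent_with_moments(self, noiseless_params, parent):
        rec = oracle_properties(parent, noiseless_params, seed=0)
        assert rec.g_abs == pytest.approx(
            g_from_moments(
                TransitionMoments(rec.mu_abs, rec.m_abs, noiseless_params.base_theta)
            )
        )


class TestDeterminismAndConsistency:
    def test_same_inputs_same_record(self):
        params = default_params()
        mol = parse_name("2-Br_5-NH2_14-CN")
        assert oracle_properties(mol, params, 9) == oracle_properties(mol, params, 9)

    def test_different_seed_different_noise(self):
        params = default_params()
        mol = parse_name("2-Br_5-NH2_14-CN")
        a = oracle_properties(mol, params, 1)
        b = oracle_properties(mol, params, 2)
        assert a != b

    def test_g_always_derived_from_own_moments(self):
        """g_abs must equal the two-vector formula applied to the record's
        own moments for some theta in [0, pi] — i.e. |g| is bounded by the
        value at cos(theta) = +/-1."""
        params = default_params()
        rng = np.random.default_rng(0)
        for mol in _random_molecules(rng, 200):
            rec = oracle_properties(mol, params, seed=4)
            gmax = abs(g_from_moments(TransitionMoments(rec.mu_abs, rec.m_abs, 0.0)))
            assert abs(rec.g_abs) <= gmax + 1e-12


def _random_molecules(rng, n, codes=None, max_subs=6):
    codes = codes or list(hf.chem_space.SUBSTITUENT_CODES)
    out = []
    for _ in range(n):
        k = int(rng.integers(1, max_subs + 1))
        pos = rng.choice(16, size=k, replace=False) + 1
        out.append(
            hf.HeliceneMolecule.from_substituents(
                {int(p): codes[int(rng.integers(len(codes)))] for p in pos}
            )
        )
    return out


class TestGenerateDataset:
    def test_family_constraint(self):
        ds = generate_dataset(100, family="halogen", max_subs=2, seed=5)
        allowed = set(FAMILIES["halogen"]) | {"H"}
        for mol in ds.molecules():
            assert set(mol.occupancy) <= allowed
        assert len(set(ds.names)) == 100

    def test_stratified_counts(self):
        ds = generate_dataset(600, family="all16", max_subs=6, seed=3)
        counts = np.bincount([m.n_substituents for m in ds.molecules()], minlength=7)
        assert list(counts[1:]) == [100] * 6

    def test_seeded_determinism_byte_identical(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_dataset(150, family="mixed4", seed=21).write(a)
        generate_dataset(150, family="mixed4", seed=21).write(b)
        assert a.read_bytes() == b.read_bytes()

    def test_space_exhaustion(self):
        # only 64 + 1984 distinct <=2-substituted halogenated molecules exist
        with pytest.raises(SpaceExhaustedError):
            generate_dataset(3000, family="halogen", max_subs=2, seed=0)


class TestSmoothness:
    def test_lipschitz_bound_near_pairs(self, noiseless_params):
        """Noiseless property differences at small descriptor distance are
        bounded by L * distance — the property that makes local models work.
        Close pairs are built by swapping one substituent for a code of
        nearby sigma_p (e.g. SH 0.15 <-> CCPh 0.16, F 0.06 <-> H)."""
        near_swaps = [("SH", "CCPh"), ("F", "H"), ("I", "CCH"), ("Br", "I")]
        rng = np.random.default_rng(77)
        checked = 0
        for mol in _random_molecules(rng, 500):
            subs = dict(mol.substituents)
            for pos, code in list(subs.items()):
                for x, y in near_swaps:
                    if code != x:
                        continue
                    other = dict(subs)
                    if y == "H":
                        other.pop(pos)
                    else:
                        other[pos] = y
                    b = hf.HeliceneMolecule.from_substituents(other)
                    d = float(np.linalg.norm(encode(mol) - encode(b)))
                    assert 0 < d < 0.1
                    ra = oracle_properties(mol, noiseless_params, 0).as_array()
                    rb = oracle_properties(b, noiseless_params, 0).as_array()
                    assert np.max(np.abs(ra - rb)) <= SMOOTHNESS_L * d
                    checked += 1
        assert checked >= 100


class TestPlantedOptimum:
    def test_single_substituent_scan(self, noiseless_params):
        target = parse_name("3-I")
        params = plant_optimum(noiseless_params, target, margin=50.0, prop="R_plus")
        mols = list(enumerate_molecules(max_subs=1))  # 257 molecules
        vals = {format_name(m): oracle_properties(m, params, 0).R_plus for m in mols}
        ranked = sorted(vals, key=vals.get, reverse=True)
        assert ranked[0] == "3-I"

    def test_margin_zero_leaves_landscape_unchanged(self, noiseless_params):
        target = parse_name("2-NO2")
        params = plant_optimum(noiseless_params, target, margin=0.0, prop="R_plus")
        far = parse_name("9-NH2_12-CN")  # far outside the bump support
        assert oracle_properties(far, params, 0) == oracle_properties(
            far, noiseless_params, 0
        )

    def test_margin_over_two_substituent_enumeration(self, noiseless_params):
        codes = ("F", "Br", "I", "NH2", "NO2")
        target = parse_name("2-NO2_15-I")
        margin = 50.0
        params = plant_optimum(noiseless_params, target, margin=margin, prop="R_plus")
        vals = {
            format_name(m): oracle_properties(m, params, 0).R_plus
            for m in enumerate_molecules(codes, max_subs=2)
        }
        ranked = sorted(vals.items(), key=lambda t: -t[1])
        assert ranked[0][0] == format_name(target)
        assert ranked[0][1] - ranked[1][1] >= margin


class TestRegimeHeterogeneity:
    def test_global_linear_fit_worse_than_piecewise(self):
        """With the regime switch on, a single linear model of g_abs is
        strictly worse than regime-aware linear fits: the landscape is
        genuinely heterogeneous, not just noisy."""
        from sklearn.linear_model import LinearRegression

        params = default_params(regime_switch=True)
        ds = generate_dataset(2000, family="all16", params=params, seed=8)
        X = ds.features()
        g = ds.targets()[:, PROPERTY_NAMES.index("g_abs")]
        z = X @ params.regime_direction
        global_res = g - LinearRegression().fit(X, g).predict(X)
        piece_res = np.empty_like(g)
        for side in (z >= 0, z < 0):
            piece_res[side] = g[side] - LinearRegression().fit(X[side], g[side]).predict(X[side])
        assert np.mean(np.abs(global_res)) > np.mean(np.abs(piece_res))
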