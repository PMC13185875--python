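"""Genetic-algorithm operators, constraints, and optimum recovery."""

import numpy as np
import pytest

import heliforge as hf
from heliforge._seeds import rng_for
from heliforge.chem_space import SUBSTITUENT_CODES, format_name, mirror, parse_name
from heliforge.errors import InfeasibleConstraintError
from heliforge.ga_design import (
    ConstraintSet,
    GAConfig,
    Objective,
    fitness,
    init_population,
    mutate_drop,
    repair,
    run_ga,
    vary,
)
from heliforge.synthetic_oracle import default_params, oracle_predictor


def constant_predictor(**overrides):
    base = dict(
        R_plus=694.0, R_minus=-514.0, R_1=20.0,
        lambda_plus=342.6, lambda_minus=254.0, lambda_1=410.0,
        m_abs=0.36, mu_abs=1.0, g_abs=0.01,
    )
    base.update(overrides)
    rec = hf.PropertyRecord(**base)
    return lambda mol: rec


class TestObjective:
    def test_maximize_ranks_validated_candidates(self):
        """The two DFT-validated design levels (942 for the best brominated
        pattern, 1486 for the alkyne-bearing one) must rank correctly."""
        obj = [Objective("maximize", "R_plus")]
        f_low = fitness(parse_name("2-Br_3-Br_14-Br_15-Br"), obj,
                        constant_predictor(R_plus=942.0))
        f_high = fitness(parse_name("2-CCH_15-CCH"), obj,
                         constant_predictor(R_plus=1486.0))
        assert f_high > f_low

    def test_target_value_peaks_at_target(self):
        obj = Objective("target_value", "lambda_1", target=400.0, tolerance=1.0)
        assert obj.score(400.0) == 0.0
        assert obj.score(380.0) < 0.0 and obj.score(420.0) < 0.0

    def test_threshold_pair_met(self):
        """A candidate beating both parent levels (R+ > 694, R- < -514),
        e.g. predicted (818, -764), incurs zero penalty."""
        objs = [
            Objective("threshold", "R_plus", bound=694.0, direction="above"),
            Objective("threshold", "R_minus", bound=-514.0, direction="below"),
        ]
        pred = constant_predictor(R_plus=818.0, R_minus=-764.0)
        assert fitness(parse_name("2-SMe_15-CCH"), objs, pred) == 0.0
        short = constant_predictor(R_plus=600.0, R_minus=-764.0)
        assert fitness(parse_name("2-SMe"), objs, short) == pytest.approx(-94.0)

    def test_failing_predictor_scores_minus_inf(self):
        def broken(mol):
            raise RuntimeError("boom")

        assert fitness(parse_name("1-F"), [Objective("maximize", "R_plus")], broken) == float("-inf")

    def test_invalid_objectives_rejected(self):
        with pytest.raises(ValueError):
            Objective("maximise", "R_plus")
        with pytest.raises(ValueError):
            Objective("target_value", "R_plus")  # no target
        with pytest.raises(ValueError):
            Objective("maximize", "nope")


class TestInitPopulation:
    def test_all_codes_forbidden_infeasible(self):
        cs = ConstraintSet(forbidden_codes=frozenset(SUBSTITUENT_CODES))
        with pytest.raises(InfeasibleConstraintError):
            init_population(GAConfig(population_size=10), cs)

    def test_symmetric_population(self):
        cs = ConstraintSet(require_symmetry=True)
        pop = init_population(GAConfig(population_size=50, seed=2), cs)
        assert all(mirror(m) == m for m in pop)

    def test_default_population_spans_counts(self):
        cs = ConstraintSet()
        pop = init_population(GAConfig(population_size=1000, seed=3), cs)
        counts = {m.n_substituents for m in pop}
        assert counts == {1, 2, 3, 4, 5, 6}
        again = init_population(GAConfig(population_size=1000, seed=3), cs)
        assert [format_name(m) for m in pop] == [format_name(m) for m in again]


class TestVariation:
    def test_repair_enforces_budget(self):
        cs = ConstraintSet(max_substituents=6)
        rng = rng_for(0, "t")
        parent_a = parse_name("1-F_2-F_3-F_4-F_5-F_6-F")
        parent_b = parse_name("11-CN_12-CN_13-CN_14-CN_15-CN_16-CN")
        for _ in range(200):
            child = vary([parent_a, parent_b], GAConfig(), cs, rng)
            assert child.n_substituents <= 6
            assert cs.structure_ok(child)

    def test_symmetric_crossover_stays_symmetric(self):
        cs = ConstraintSet(require_symmetry=True)
        rng = rng_for(1, "t")
        a = parse_name("2-Br_15-Br")
        b = parse_name("1-CN_3-OH_14-OH_16-CN")
        for _ in range(100):
            child = vary([a, b], GAConfig(), cs, rng)
            assert mirror(child) == child

    def test_forbidden_code_rerolled(self):
        cs = ConstraintSet(forbidden_codes=frozenset({"NO2"}))
        rng = rng_for(2, "t")
        bad = parse_name("1-NO2_8-NO2")
        for _ in range(50):
            fixed = repair(bad, cs, rng)
            assert "NO2" not in fixed.occupancy

    def test_blocked_position_cleared_with_symmetry_closure(self):
        cs = ConstraintSet(require_symmetry=True, forbidden_positions=frozenset({1}))
        assert cs.blocked_positions == frozenset({1, 16})

    def test_drop_move_uniform(self):
        """Dropping from a two-substituent molecule hits either site with
        equal probability (chi-squared test over 10^4 seeded trials)."""
        from scipy.stats import chisquare

        rng = rng_for(99, "drop")
        mol = parse_name("1-SH_3-F")
        outcomes = {"1-SH": 0, "3-F": 0}
        for _ in range(10_000):
            outcomes[format_name(mutate_drop(mol, rng))] += 1
        assert sum(outcomes.values()) == 10_000
        _, p = chisquare(list(outcomes.values()))
        assert p > 0.01


class TestRunGA:
    def test_deterministic_given_seed(self):
        oracle = oracle_predictor(default_params(noise=False), seed=0)
        cfg = GAConfig(population_size=40, generations=5, seed=4)
        obj = [Objective("maximize", "R_plus")]
        cs = ConstraintSet(max_substituents=3)
        a = run_ga(cfg, obj, cs, oracle)
        b = run_ga(cfg, obj, cs, oracle)
        assert a.candidates.equals(b.candidates)
        assert a.trace == b.trace

    def test_elitism_monotone_trace(self):
        oracle = oracle_predictor(default_params(noise=False), seed=1)
        cfg = GAConfig(population_size=40, generations=10, elitism=2, seed=5)
        res = run_ga(cfg, [Objective("maximize", "m_abs")], ConstraintSet(), oracle)
        assert all(a <= b for a, b in zip(res.trace, res.trace[1:]))

    def test_alkyne_exclusion_audited(self):
        oracle = oracle_predictor(default_params(noise=False), seed=2)
        cs = ConstraintSet(forbidden_codes=frozenset({"CCH", "CCPh"}))
        cfg = GAConfig(population_size=60, generations=8, seed=6)
        res = run_ga(cfg, [Objective("maximize", "R_plus")], cs, oracle)
        assert len(res.candidates)
        for name in res.candidates["name"]:
            occ = parse_name(name).occupancy
            assert "CCH" not in occ and "CCPh" not in occ

    def test_reported_candidates_pass_independent_audit(self):
        oracle = oracle_predictor(default_params(noise=False), seed=3)
        cs = ConstraintSet(
            require_symmetry=True,
            forbidden_codes=frozenset({"NO2"}),
            forbidden_positions=frozenset({1}),
            max_substituents=6,
            property_windows=(("mu_abs", 0.5, 1.5),),
        )
        cfg = GAConfig(population_size=80, generations=10, seed=7)
        res = run_ga(cfg, [Objective("maximize", "g_abs")], cs, oracle)
        for name in res.candidates["name"]:
            m = parse_name(name)
            assert mirror(m) == m
            assert "NO2" not in m.occupancy
            assert 1 not in m.substituents and 16 not in m.substituents
            assert m.n_substituents <= 6
            assert 0.5 <= res.records[name].mu_abs <= 1.5
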