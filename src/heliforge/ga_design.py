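"""Constrained genetic algorithm over helicene substitution patterns.

Inverse design: the desired property profile is stated first (maximize,
minimize, hit a target value, or clear thresholds — singly or combined
as a weighted sum) and the GA searches the substitution space for
molecules that realise it, scoring candidates with any pluggable
molecule -> PropertyRecord predictor (a local model in realistic use, a
ground-truth oracle in tests).

Constraint handling is repair-based: offspring violating structural
constraints (forbidden codes or positions, C2 symmetry, substituent
budget) are repaired rather than discarded, which keeps the population
size stable even under tight constraint ladders. Hard property windows
cannot be repaired; candidates violating them are dominated by every
feasible candidate during selection and are never reported.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed, rng_for
from .chem_space import (
    N_POSITIONS,
    SUBSTITUENT_CODES,
    HeliceneMolecule,
    format_name,
)
from .chiroptics import PROPERTY_NAMES, PropertyRecord
from .errors import InfeasibleConstraintError

__all__ = [
    "Objective",
    "ConstraintSet",
    "GAConfig",
    "DesignResult",
    "init_population",
    "vary",
    "fitness",
    "run_ga",
]

logger = logging.getLogger(__name__)

_INFEASIBLE_OFFSET = 1e9  # any feasible score beats any infeasible one


@dataclass(frozen=True)
class Objective:
    """One scalarisable design goal on a named property.

    kind: 'maximize' | 'minimize' | 'target_value' | 'threshold'.
    target/tolerance apply to target_value; bound/direction ('above' or
    'below') to threshold. Multiple objectives combine as a weighted sum.
    """

    kind: str
    property: str
    target: float | None = None
    tolerance: float = 1.0
    bound: float | None = None
    direction: str = "above"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("maximize", "minimize", "target_value", "threshold"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.property not in PROPERTY_NAMES:
            raise ValueError(f"unknown property {self.property!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.kind == "target_value":
            if self.target is None:
                raise ValueError("target_value objective needs a target")
            if self.tolerance <= 0:
                raise ValueError("tolerance must be positive")
        if self.kind == "threshold":
            if self.bound is None:
                raise ValueError("threshold objective needs a bound")
            if self.direction not in ("above", "below"):
                raise ValueError("direction must be 'above' or 'below'")

    def score(self, value: float) -> float:
        if self.kind == "maximize":
            return self.weight * value
        if self.kind == "minimize":
            return -self.weight * value
        if self.kind == "target_value":
            return -self.weight * abs(value - self.target)
        # threshold: no reward past the bound, linear penalty short of it
        deficit = (
            max(0.0, self.bound - value)
            if self.direction == "above"
            else max(0.0, value - self.bound)
        )
        return -self.weight * deficit


@dataclass(frozen=True)
class ConstraintSet:
    """Hard constraints a reported candidate must satisfy.

    Structural constraints (codes, positions, symmetry, substituent
    budget) are enforced by repair; property_windows (property, low,
    high) are audited on the predicted record. When symmetry is
    required, forbidding a position implicitly forbids its C2 partner.
    """

    forbidden_codes: frozenset[str] = frozenset()
    forbidden_positions: frozenset[int] = frozenset()
    require_symmetry: bool = False
    max_substituents: int = 6
    property_windows: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self) -> None:
        bad = self.forbidden_codes - set(SUBSTITUENT_CODES)
        if bad:
            raise ValueError(f"unknown forbidden codes: {sorted(bad)}")
        if any(not 1 <= p <= N_POSITIONS for p in self.forbidden_positions):
            raise ValueError("forbidden positions must lie in 1..16")
        for prop, lo, hi in self.property_windows:
            if prop not in PROPERTY_NAMES:
                raise ValueError(f"unknown property {prop!r} in window")
            if lo > hi:
                raise ValueError(f"empty window for {prop!r}")

    @property
    def allowed_codes(self) -> tuple[str, ...]:
        return tuple(c for c in SUBSTITUENT_CODES if c not in self.forbidden_codes)

    @property
    def blocked_positions(self) -> frozenset[int]:
        if not self.require_symmetry:
            return self.forbidden_positions
        closed = set(self.forbidden_positions)
        closed |= {N_POSITIONS + 1 - p for p in self.forbidden_positions}
        return frozenset(closed)

    def check_feasible(self) -> None:
        if not self.allowed_codes:
            raise InfeasibleConstraintError("every substituent code is forbidden")
        if len(self.blocked_positions) >= N_POSITIONS:
            raise InfeasibleConstraintError("every position is forbidden")
        if self.max_substituents < 1:
            raise InfeasibleConstraintError("max_substituents must allow >= 1")
        if self.require_symmetry and self.max_substituents < 2:
            raise InfeasibleConstraintError(
                "symmetric molecules need a budget of at least one pair"
            )

    def structure_ok(self, mol: HeliceneMolecule) -> bool:
        subs = mol.substituents
        if len(subs) > self.max_substituents:
            return False
        if any(code in self.forbidden_codes for code in subs.values()):
            return False
        if any(pos in self.blocked_positions for pos in subs):
            return False
        if self.require_symmetry and not mol.is_symmetric():
            return False
        return True

    def windows_ok(self, rec: PropertyRecord) -> bool:
        return all(
            lo <= getattr(rec, prop) <= hi for prop, lo, hi in self.property_windows
        )

    def window_violation(self, rec: PropertyRecord) -> float:
        total = 0.0
        for prop, lo, hi in self.property_windows:
            v = getattr(rec, prop)
            total += max(0.0, lo - v) + max(0.0, v - hi)
        return total


@dataclass(frozen=True)
class GAConfig:
    """GA hyper-parameters; every rate and size is config-exposed."""

    population_size: int = 1000
    generations: int = 100
    crossover_rate: float = 0.8
    mut_code: float = 0.05    # per-position reroll of an existing code
    mut_add: float = 0.15     # add one substituent at a free position
    mut_drop: float = 0.15    # drop one substituent
    mut_move: float = 0.10    # relocate one substituent
    tournament_size: int = 3
    elitism: int = 5
    top_n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_rate, self.mut_code, self.mut_add,
                  self.mut_drop, self.mut_move):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.elitism < 0 or self.tournament_size < 1:
            raise ValueError("invalid selection parameters")


@dataclass
class DesignResult:
    """Ranked feasible candidates plus the best-fitness trace."""

    candidates: pd.DataFrame  # name, fitness, <properties>, feasible
    records: dict[str, PropertyRecord]
    trace: list[float]
    n_evaluated: int

    @property
    def best(self) -> str:
        return str(self.candidates.iloc[0]["name"])

    def to_csv(self, path) -> None:
        self.candidates.to_csv(path, index=False)


# --- population construction and variation --------------------------------


def _random_molecule(
    rng: np.random.Generator, cs: ConstraintSet, n_subs: int
) -> HeliceneMolecule:
    free = sorted(set(range(1, N_POSITIONS + 1)) - cs.blocked_positions)
    codes = cs.allowed_codes
    if cs.require_symmetry:
        pairs = sorted({(min(p, 17 - p), max(p, 17 - p)) for p in free
                        if 17 - p in free})
        n_pairs = max(1, min(n_subs // 2, len(pairs), cs.max_substituents // 2))
        chosen = rng.choice(len(pairs), size=n_pairs, replace=False)
        subs: dict[int, str] = {}
        for ci in chosen:
            lo, hi = pairs[int(ci)]
            code = codes[int(rng.integers(len(codes)))]
            subs[lo] = code
            subs[hi] = code
        return HeliceneMolecule.from_substituents(subs)
    n = max(1, min(n_subs, len(free), cs.max_substituents))
    positions = rng.choice(len(free), size=n, replace=False)
    return HeliceneMolecule.from_substituents(
        {free[int(p)]: codes[int(rng.integers(len(codes)))] for p in positions}
    )


def init_population(
    cfg: GAConfig, cs: ConstraintSet, seed: int | None = None
) -> list[HeliceneMolecule]:
    """Seeded initial population, substituent counts spread over 1..max.

    Individuals are distinct where the constrained space allows;
    duplicates are retried a bounded number of times and then accepted.
    """
    cs.check_feasible()
    rng = rng_for(cfg.seed if seed is None else seed, "ga-init")
    pop: list[HeliceneMolecule] = []
    seen: set[str] = set()
    for i in range(cfg.population_size):
        n_subs = 1 + i % cs.max_substituents
        mol = None
        for _ in range(30):
            cand = _random_molecule(rng, cs, n_subs)
            if format_name(cand) not in seen:
                mol = cand
                break
        mol = mol or cand
        seen.add(format_name(mol))
        pop.append(mol)
    return pop


def repair(
    mol: HeliceneMolecule, cs: ConstraintSet, rng: np.random.Generator
) -> HeliceneMolecule:
    """Minimal stochastic repair to structural-constraint satisfaction.

    Forbidden codes are re-rolled to allowed ones, forbidden positions
    cleared, symmetry restored by copying the lower position of each C2
    pair onto its partner, and excess substituents dropped at random
    (pairwise under symmetry). Always terminates; the result passes
    :meth:`ConstraintSet.structure_ok`.
    """
    occ = list(mol.occupancy)
    codes = cs.allowed_codes
    for i in range(N_POSITIONS):
        if occ[i] != "H" and occ[i] in cs.forbidden_codes:
            occ[i] = codes[int(rng.integers(len(codes)))]
    for p in cs.blocked_positions:
        occ[p - 1] = "H"
    if cs.require_symmetry:
        for i in range(N_POSITIONS // 2):
            occ[N_POSITIONS - 1 - i] = occ[i]
        sub_pairs = [i for i in range(N_POSITIONS // 2) if occ[i] != "H"]
        budget = cs.max_substituents // 2
        while len(sub_pairs) > budget:
            j = int(rng.integers(len(sub_pairs)))
            i = sub_pairs.pop(j)
            occ[i] = occ[N_POSITIONS - 1 - i] = "H"
        if not sub_pairs:  # repair emptied the molecule; re-seed one pair
            free = sorted(
                i for i in range(N_POSITIONS // 2)
                if (i + 1) not in cs.blocked_positions
                and (N_POSITIONS - i) not in cs.blocked_positions
            )
            i = free[int(rng.integers(len(free)))]
            code = codes[int(rng.integers(len(codes)))]
            occ[i] = occ[N_POSITIONS - 1 - i] = code
    else:
        subs = [i for i in range(N_POSITIONS) if occ[i] != "H"]
        while len(subs) > cs.max_substituents:
            j = int(rng.integers(len(subs)))
            occ[subs.pop(j)] = "H"
        if not subs:
            free = sorted(
                i for i in range(N_POSITIONS)
                if (i + 1) not in cs.blocked_positions
            )
            i = free[int(rng.integers(len(free)))]
            occ[i] = codes[int(rng.integers(len(codes)))]
    return HeliceneMolecule(tuple(occ))


def mutate_drop(
    mol: HeliceneMolecule, rng: np.random.Generator
) -> HeliceneMolecule:
    """Drop one substituent chosen uniformly at random."""
    subs = sorted(mol.substituents)
    if not subs:
        return mol
    victim = subs[int(rng.integers(len(subs)))]
    remaining = {p: c for p, c in mol.substituents.items() if p != victim}
    return HeliceneMolecule.from_substituents(remaining)


def _mutate(
    mol: HeliceneMolecule,
    cfg: GAConfig,
    cs: ConstraintSet,
    rng: np.random.Generator,
) -> HeliceneMolecule:
    occ = list(mol.occupancy)
    codes = cs.allowed_codes
    for i in range(N_POSITIONS):
        if occ[i] != "H" and rng.random() < cfg.mut_code:
            occ[i] = codes[int(rng.integers(len(codes)))]
    if rng.random() < cfg.mut_add:
        free = [i for i in range(N_POSITIONS) if occ[i] == "H"]
        if free:
            occ[free[int(rng.integers(len(free)))]] = codes[
                int(rng.integers(len(codes)))
            ]
    if rng.random() < cfg.mut_drop:
        subs = [i for i in range(N_POSITIONS) if occ[i] != "H"]
        if subs:
            occ[subs[int(rng.integers(len(subs)))]] = "H"
    if rng.random() < cfg.mut_move:
        subs = [i for i in range(N_POSITIONS) if occ[i] != "H"]
        free = [i for i in range(N_POSITIONS) if occ[i] == "H"]
        if subs and free:
            src = subs[int(rng.integers(len(subs)))]
            dst = free[int(rng.integers(len(free)))]
            occ[dst], occ[src] = occ[src], "H"
    return HeliceneMolecule(tuple(occ))


def vary(
    parents: Sequence[HeliceneMolecule],
    cfg: GAConfig,
    cs: ConstraintSet,
    seed: int | np.random.Generator = 0,
) -> HeliceneMolecule:
    """One offspring from one or two parents: crossover, mutation, repair."""
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "ga-vary")
    if len(parents) >= 2 and rng.random() < cfg.crossover_rate:
        a, b = parents[0].occupancy, parents[1].occupancy
        mask = rng.random(N_POSITIONS) < 0.5
        child = HeliceneMolecule(
            tuple(a[i] if mask[i] else b[i] for i in range(N_POSITIONS))
        )
    else:
        child = parents[0]
    child = _mutate(child, cfg, cs, rng)
    return repair(child, cs, rng)


# --- fitness ---------------------------------------------------------------


def fitness(
    candidate: HeliceneMolecule,
    objectives: Sequence[Objective],
    predictor: Callable[[HeliceneMolecule], PropertyRecord],
) -> float:
    """Scalarised weighted-sum score of a candidate under the objectives.

    Predictor failures score -inf (and are logged) so a broken
    evaluation can never be reported as a design.
    """
    try:
        rec = predictor(candidate)
    except Exception:
        logger.exception("predictor failed for %s", format_name(candidate))
        return float("-inf")
    return sum(obj.score(getattr(rec, obj.property)) for obj in objectives)


def _selection_score(
    score: float, rec: PropertyRecord | None, cs: ConstraintSet
) -> float:
    """Feasible candidates keep their score; window violators are pushed
    below every feasible score but keep a gradient toward feasibility."""
    if rec is None:
        return float("-inf")
    if cs.windows_ok(rec):
        return score
    return -_INFEASIBLE_OFFSET - cs.window_violation(rec)


def run_ga(
    cfg: GAConfig,
    objectives: Sequence[Objective],
    cs: ConstraintSet,
    predictor: Callable[[HeliceneMolecule], PropertyRecord],
    seed: int | None = None,
) -> DesignResult:
    """Tournament-selection GA with elitism over the substitution space.

    Returns the constraint-audited top candidates (drawn from the full
    archive of evaluated feasible molecules, not just the final
    population) and the per-generation best selection-score trace,
    which is monotone non-decreasing whenever elitism >= 1.
    """
    if not objectives:
        raise ValueError("at least one objective is required")
    cs.check_feasible()
    run_seed = cfg.seed if seed is None else seed
    rng = rng_for(run_seed, "ga-run")

    # archive: name -> (mol, record, raw fitness, selection score)
    archive: dict[str, tuple] = {}

    def eval_mol(mol: HeliceneMolecule):
        name = format_name(mol)
        if name not in archive:
            try:
                rec = predictor(mol)
            except Exception:
                logger.exception("predictor failed for %s", name)
                archive[name] = (mol, None, float("-inf"), float("-inf"))
                return archive[name]
            raw = sum(obj.score(getattr(rec, obj.property)) for obj in objectives)
            archive[name] = (mol, rec, raw, _selection_score(raw, rec, cs))
        return archive[name]

    population = init_population(cfg, cs, seed=derive_seed(run_seed, "init"))
    scores = [eval_mol(m)[3] for m in population]
    trace = [max(scores)]

    for gen in range(cfg.generations):
        order = np.argsort(scores)[::-1]
        elites = [population[i] for i in order[: cfg.elitism]]
        offspring: list[HeliceneMolecule] = list(elites)
        while len(offspring) < cfg.population_size:
            idx = rng.integers(len(population), size=cfg.tournament_size)
            p1 = population[max(idx, key=lambda i: scores[i])]
            idx = rng.integers(len(population), size=cfg.tournament_size)
            p2 = population[max(idx, key=lambda i: scores[i])]
            offspring.append(vary([p1, p2], cfg, cs, rng))
        population = offspring
        scores = [eval_mol(m)[3] for m in population]
        # elites are preserved and scores are cached by name, so with
        # elitism >= 1 this is non-decreasing by construction
        trace.append(max(scores))

    feasible = [
        (name, mol, rec, raw)
        for name, (mol, rec, raw, sel) in archive.items()
        if rec is not None and cs.structure_ok(mol) and cs.windows_ok(rec)
        and math.isfinite(raw)
    ]
    feasible.sort(key=lambda t: (-t[3], t[0]))
    top = feasible[: cfg.top_n]
    rows = []
    records = {}
    for name, mol, rec, raw in top:
        row = {"name": name, "fitness": raw, "n_substituents": mol.n_substituents}
        row.update({p: getattr(rec, p) for p in PROPERTY_NAMES})
        row["feasible"] = True
        rows.append(row)
        records[name] = rec
    candidates = pd.DataFrame(rows)
    return DesignResult(
        candidates=candidates,
        records=records,
        trace=trace,
        n_evaluated=len(archive),
    )
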