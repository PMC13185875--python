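"""The iterative design-evaluate-retrain protocol.

To reach sparse regions of a property distribution, a single GA pass on
a fixed surrogate is not enough: the local models cannot extrapolate far
beyond the data. The loop alternates

    GA (local-model predictor on the current dataset)
      -> ground-truth evaluation of the top novel candidates
      -> append to the dataset
      -> retrain and repeat,

so each round's intermediate candidates pull the training data toward
the target region. The ground-truth evaluator is an abstract
molecule -> PropertyRecord contract (a synthetic oracle in tests, a DFT
pipeline in real use); appended rows always come from the evaluator,
never from the predictor, so the loop cannot confirm its own
predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from typing import Callable, Mapping, Sequence

from ._seeds import derive_seed
from .chem_space import HeliceneMolecule, format_name, parse_name
from .chiroptics import PropertyRecord
from .dataset_io import Dataset
from .ga_design import ConstraintSet, GAConfig, Objective, run_ga
from .local_model import LocalModelPredictor

__all__ = ["LoopState", "iterate_design"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoopState:
    """Snapshot of one loop round."""

    round: int
    dataset_size: int
    best_name: str
    best_value: float
    gap: float  # |best true value - target| for target objectives,
                # else -best true score so far (lower is better)
    n_appended: int

    def to_dict(self) -> dict:
        return asdict(self)


def _true_score(obj: Objective, value: float) -> float:
    return obj.score(value)


def iterate_design(
    target: Objective,
    rounds: int,
    batch: int,
    ga_cfg: GAConfig,
    cs: ConstraintSet,
    dataset: Dataset,
    evaluator: Callable[[HeliceneMolecule], PropertyRecord],
    seed: int = 0,
    k: int = 100,
    forest_params: Mapping | None = None,
    tolerance: float | None = None,
) -> tuple[list[LoopState], Dataset]:
    """Run the iterative protocol; returns (history, grown dataset).

    Each round runs the GA with a local-model predictor trained on the
    current dataset, sends the top ``batch`` novel candidates to the
    ground-truth evaluator, appends the results, and records the best
    gap-to-target reached so far. Stops early when no novel candidate
    can be produced or when ``tolerance`` (on the gap) is met.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    history: list[LoopState] = []
    best_gap = float("inf")
    best_name, best_value = "", float("nan")

    for r in range(1, rounds + 1):
        predictor = LocalModelPredictor(
            dataset,
            k=min(k, len(dataset) - 1),
            forest_params=forest_params,
            seed=derive_seed(seed, "loop-model", r),
            properties=[target.property],
        )
        result = run_ga(
            replace(ga_cfg, top_n=max(ga_cfg.top_n, 3 * batch)),
            [target],
            cs,
            predictor,
            seed=derive_seed(seed, "loop-ga", r),
        )
        novel = [
            parse_name(name)
            for name in result.candidates["name"]
            if name not in dataset
        ][:batch]
        if not novel:
            logger.info("round %d: no novel candidates; stopping early", r)
            history.append(
                LoopState(r, len(dataset), best_name, best_value, best_gap, 0)
            )
            break
        evaluated = [(mol, evaluator(mol)) for mol in novel]
        for mol, rec in evaluated:
            value = getattr(rec, target.property)
            gap = (
                abs(value - target.target)
                if target.kind == "target_value"
                else -_true_score(target, value)
            )
            if gap < best_gap:
                best_gap, best_name, best_value = gap, format_name(mol), value
        dataset = dataset.append(evaluated)
        history.append(
            LoopState(r, len(dataset), best_name, best_value, best_gap, len(evaluated))
        )
        if tolerance is not None and best_gap <= tolerance:
            logger.info("round %d: gap %.4g within tolerance; stopping", r, best_gap)
            break
    return history, dataset


def history_to_json(history: Sequence[LoopState], path) -> None:
    """Serialise a loop history for replay checks."""
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in history], fh, indent=2)
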