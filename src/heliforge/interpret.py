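"""Interpretability: substitution-pattern statistics over a candidate set.

Turns a list of designed molecules into per-position statistics — how
often each scaffold position is substituted, the average Hammett
constant of its occupants, and the most frequent codes — the summary
from which human-readable design rules are read off (e.g. "position 1
carries strongly electron-withdrawing groups; position 2 is frequently
modified with sigma_p around 0.3").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem_space import (
    N_POSITIONS,
    DescriptorTable,
    HeliceneMolecule,
    default_table,
)
from .errors import EmptyInputError

__all__ = ["PatternSummary", "pattern_summary"]


@dataclass
class PatternSummary:
    """Per-position substitution statistics of a candidate set.

    table columns: position (1..16), frequency in [0, 1], mean_sigma_p
    (NaN where nothing is ever substituted), top_codes ("code:count"
    joined by "|", up to three entries).
    """

    table: pd.DataFrame
    n_candidates: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, n_candidates: int = 0) -> "PatternSummary":
        return cls(pd.read_csv(path), n_candidates)


def pattern_summary(
    candidates: Sequence[HeliceneMolecule] | Iterable[HeliceneMolecule],
    table: DescriptorTable | None = None,
    count_h_as_zero: bool = False,
) -> PatternSummary:
    """Frequency, mean sigma_p and top codes for each scaffold position.

    By default the mean sigma_p at a position is computed over its
    substituted (non-H) occupants only; with ``count_h_as_zero`` the
    unsubstituted occupants enter the average as sigma_p(H) = 0,
    pulling rarely-substituted positions toward zero.
    """
    mols = list(candidates)
    if not mols:
        raise EmptyInputError("pattern_summary needs at least one candidate")
    table = table or default_table()
    rows = []
    for pos in range(1, N_POSITIONS + 1):
        occupants = [m.occupancy[pos - 1] for m in mols]
        non_h = [c for c in occupants if c != "H"]
        freq = len(non_h) / len(mols)
        if count_h_as_zero:
            mean_sigma = float(np.mean([table[c] for c in occupants]))
        elif non_h:
            mean_sigma = float(np.mean([table[c] for c in non_h]))
        else:
            mean_sigma = float("nan")
        counts = pd.Series(non_h).value_counts() if non_h else pd.Series(dtype=int)
        top = "|".join(
            f"{code}:{int(n)}"
            for code, n in sorted(
                counts.items(), key=lambda t: (-t[1], t[0])
            )[:3]
        )
        rows.append(
            {
                "position": pos,
                "frequency": freq,
                "mean_sigma_p": mean_sigma,
                "top_codes": top,
            }
        )
    return PatternSummary(pd.DataFrame(rows), n_candidates=len(mols))


def plot_summary(summary: PatternSummary, path) -> None:
    """Bubble plot: circle size = substitution frequency, colour = mean
    sigma_p. Requires matplotlib (the ``plot`` extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = summary.table
    fig, ax = plt.subplots(figsize=(8, 2.5))
    sc = ax.scatter(
        t["position"],
        np.ones(len(t)),
        s=40 + 2000 * t["frequency"],
        c=t["mean_sigma_p"],
        cmap="coolwarm",
        vmin=-0.8,
        vmax=0.8,
        edgecolors="k",
    )
    fig.colorbar(sc, label="mean sigma_p")
    ax.set_xticks(range(1, N_POSITIONS + 1))
    ax.set_yticks([])
    ax.set_xlabel("scaffold position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
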