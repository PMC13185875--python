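"""Molecular representation of substituted [6]helicenes.

The carbo[6]helicene scaffold is held fixed and never represented at atom
level: a molecule is the occupancy of its 16 substitutable ring positions
by one of 16 substituent groups (or H), plus a helical sense (P or M).
Each position is described by the para Hammett constant sigma_p of its
occupant, giving a 16-element descriptor vector in which the parent
(all-H) helicene is the origin.

Positions are numbered 1..16 following the standard scaffold numbering;
the C2 symmetry of the scaffold maps position i to 17 - i.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DescriptorTableError,
    DuplicatePositionError,
    PositionRangeError,
    UnknownSubstituentError,
)

__all__ = [
    "N_POSITIONS",
    "SUBSTITUENT_CODES",
    "DescriptorTable",
    "HeliceneMolecule",
    "load_default_table",
    "load_table",
    "default_table",
    "parse_name",
    "canonical_name",
    "format_name",
    "encode",
    "mirror",
    "count_space",
    "enumerate_molecules",
]

N_POSITIONS = 16

#: The 16 non-hydrogen substituent groups considered on the scaffold:
#: halogens, electron donors (EDG), electron acceptors (EWG) and
#: carbon-based groups.
SUBSTITUENT_CODES: tuple[str, ...] = (
    "F", "Cl", "Br", "I",
    "NH2", "OH", "OMe", "SH", "SMe",
    "NO2", "CN", "CHO", "COOH",
    "CH3", "CCH", "CCPh",
)

# Unicode hyphen variants that appear in PDF-extracted names.
_HYPHENS = "‐‑‒–—−"
# Printable aliases for the alkyne codes.
_CODE_ALIASES = {"C≡CH": "CCH", "C≡C-Ph": "CCPh", "C≡CPh": "CCPh"}


@dataclass(frozen=True)
class DescriptorTable:
    """A total map from substituent code to Hammett sigma_p.

    The default table is the standard Hansch-Leo-Taft compilation of
    para constants, shipped as an editable CSV (``data/sigma_p.csv``).
    ``sigma_p('H') == 0`` by construction.
    """

    sigma_p: Mapping[str, float]

    def __post_init__(self) -> None:
        if "H" not in self.sigma_p:
            raise DescriptorTableError("descriptor table must define H")
        missing = [c for c in SUBSTITUENT_CODES if c not in self.sigma_p]
        if missing:
            raise DescriptorTableError(f"missing sigma_p entries: {missing}")

    def __getitem__(self, code: str) -> float:
        try:
            return float(self.sigma_p[code])
        except KeyError:
            raise DescriptorTableError(f"no sigma_p entry for {code!r}") from None

    def degenerate_codes(self) -> list[tuple[str, ...]]:
        """Groups of distinct codes sharing one sigma_p value.

        Under a pure sigma_p encoding such codes are indistinguishable to
        the regressor (e.g. SMe vs H, both 0.00 in the default table);
        molecule identity is still carried by the code sequence.
        """
        by_value: dict[float, list[str]] = {}
        for code in ("H", *SUBSTITUENT_CODES):
            by_value.setdefault(self[code], []).append(code)
        return [tuple(v) for v in by_value.values() if len(v) > 1]


def load_default_table() -> DescriptorTable:
    """Load the packaged sigma_p table."""
    with resources.files("heliforge.data").joinpath("sigma_p.csv").open() as fh:
        df = pd.read_csv(fh)
    return DescriptorTable(dict(zip(df["code"], df["sigma_p"].astype(float))))


def load_table(path: str | Path) -> DescriptorTable:
    """Load a user descriptor table from a ``code,sigma_p`` CSV."""
    df = pd.read_csv(path)
    if not {"code", "sigma_p"} <= set(df.columns):
        raise DescriptorTableError("descriptor CSV needs columns code,sigma_p")
    return DescriptorTable(dict(zip(df["code"], df["sigma_p"].astype(float))))


_DEFAULT_TABLE: DescriptorTable | None = None


def default_table() -> DescriptorTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_default_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class HeliceneMolecule:
    """Occupancy of the 16 scaffold positions plus helical sense.

    ``occupancy[i]`` is the substituent code at position ``i + 1`` (the
    public interface is 1-based throughout; only this tuple is 0-based).
    """

    occupancy: tuple[str, ...]
    helicity: str = "P"

    def __post_init__(self) -> None:
        if len(self.occupancy) != N_POSITIONS:
            raise ValueError(f"occupancy must have length {N_POSITIONS}")
        if self.helicity not in ("P", "M"):
            raise ValueError("helicity must be 'P' or 'M'")
        valid = set(SUBSTITUENT_CODES) | {"H"}
        for code in self.occupancy:
            if code not in valid:
                raise UnknownSubstituentError(f"unknown substituent code {code!r}")
        object.__setattr__(self, "occupancy", tuple(self.occupancy))

    @classmethod
    def parent(cls, helicity: str = "P") -> "HeliceneMolecule":
        return cls(("H",) * N_POSITIONS, helicity)

    @classmethod
    def from_substituents(
        cls, subs: Mapping[int, str] | Iterable[tuple[int, str]], helicity: str = "P"
    ) -> "HeliceneMolecule":
        """Build from a 1-based {position: code} mapping."""
        items = dict(subs).items() if isinstance(subs, Mapping) else list(subs)
        occ = ["H"] * N_POSITIONS
        for pos, code in items:
            if not 1 <= pos <= N_POSITIONS:
                raise PositionRangeError(f"position {pos} outside 1..{N_POSITIONS}")
            occ[pos - 1] = code
        return cls(tuple(occ), helicity)

    @property
    def substituents(self) -> dict[int, str]:
        """1-based {position: code} of the non-H sites."""
        return {
            i + 1: c for i, c in enumerate(self.occupancy) if c != "H"
        }

    @property
    def n_substituents(self) -> int:
        return sum(c != "H" for c in self.occupancy)

    @property
    def name(self) -> str:
        return format_name(self)

    def is_symmetric(self) -> bool:
        """True when the molecule equals its C2 mirror image."""
        return mirror(self).occupancy == self.occupancy


def parse_name(name: str, helicity: str = "P") -> HeliceneMolecule:
    """Parse a Position-Substituent name such as ``"1-SH_3-F_8-OH"``.

    The empty string and the token ``"parent"`` denote the unsubstituted
    helicene. Unicode hyphen variants (common in PDF-derived text) are
    accepted in place of ASCII ``-``.
    """
    s = name.strip()
    for h in _HYPHENS:
        s = s.replace(h, "-")
    if s in ("", "parent"):
        return HeliceneMolecule.parent(helicity)
    seen: dict[int, str] = {}
    for token in s.split("_"):
        if not token:
            continue
        pos_str, sep, code = token.partition("-")
        try:
            pos = int(pos_str)
        except ValueError:
            raise UnknownSubstituentError(f"malformed token {token!r}") from None
        if not sep:
            raise UnknownSubstituentError(f"malformed token {token!r}")
        if not 1 <= pos <= N_POSITIONS:
            raise PositionRangeError(
                f"position {pos} outside 1..{N_POSITIONS} in {name!r}"
            )
        code = _CODE_ALIASES.get(code, code)
        if code not in SUBSTITUENT_CODES:
            raise UnknownSubstituentError(f"unknown substituent {code!r} in {name!r}")
        if pos in seen:
            raise DuplicatePositionError(f"position {pos} repeated in {name!r}")
        seen[pos] = code
    return HeliceneMolecule.from_substituents(seen, helicity)


def format_name(mol: HeliceneMolecule) -> str:
    """Canonical Position-Substituent name, positions ascending.

    Inverse of :func:`parse_name`; the parent molecule formats to
    ``"parent"``.
    """
    subs = mol.substituents
    if not subs:
        return "parent"
    return "_".join(f"{pos}-{code}" for pos, code in sorted(subs.items()))


def canonical_name(name_or_mol: str | HeliceneMolecule) -> str:
    """Canonical name for a molecule or a (possibly unordered) name."""
    if isinstance(name_or_mol, HeliceneMolecule):
        return format_name(name_or_mol)
    return format_name(parse_name(name_or_mol))


def encode(
    mol: HeliceneMolecule, table: DescriptorTable | None = None
) -> np.ndarray:
    """Encode a molecule as its 16-element sigma_p descriptor vector."""
    table = table or default_table()
    return np.array([table[c] for c in mol.occupancy], dtype=float)


def mirror(mol: HeliceneMolecule) -> HeliceneMolecule:
    """The C2 symmetry image: occupancy at i swaps with 17 - i.

    An involution; substituent count is preserved. Helicity is untouched —
    this is the in-plane relabelling of equivalent positions, not the
    P/M enantiomer operation (see :func:`heliforge.chiroptics.enantiomer_flip`).
    """
    return HeliceneMolecule(tuple(reversed(mol.occupancy)), mol.helicity)


def count_space(
    n_positions: int = N_POSITIONS,
    n_types: int = len(SUBSTITUENT_CODES),
    max_subs: int = 6,
    fold_symmetry: bool = False,
) -> int:
    """Count substitution patterns with at most ``max_subs`` substituents.

    Without symmetry this is the exact big-integer sum
    ``sum_k C(n_positions, k) * n_types**k`` for k = 0..max_subs. With
    ``fold_symmetry`` the two patterns related by the C2 position swap
    i <-> n+1-i are identified, and the orbit count follows from
    Burnside's lemma: the average of the total count and the number of
    mirror-fixed patterns (which pair positions, so use an even number of
    substituents across ``n_positions / 2`` pairs).

    The default arguments give 69 526 817 473 folded (139 053 398 273
    unfolded) — the ~7e10 design space of mono- to hexa-substituted
    [6]helicenes.
    """
    if n_positions < 0 or n_types < 0 or max_subs < 0:
        raise ValueError("all arguments must be non-negative")
    total = sum(
        math.comb(n_positions, k) * n_types**k
        for k in range(0, min(max_subs, n_positions) + 1)
    )
    if not fold_symmetry:
        return total
    if n_positions % 2:
        raise ValueError("fold_symmetry requires an even number of positions")
    n_pairs = n_positions // 2
    fixed = sum(
        math.comb(n_pairs, j) * n_types**j
        for j in range(0, min(max_subs // 2, n_pairs) + 1)
    )
    return (total + fixed) // 2


def enumerate_molecules(
    codes: Iterable[str] = SUBSTITUENT_CODES,
    max_subs: int = 6,
    include_parent: bool = True,
) -> Iterator[HeliceneMolecule]:
    """Exhaustively enumerate molecules with ``<= max_subs`` substituents.

    Intended for small sub-spaces (few codes, low max_subs) where brute
    force is feasible; yields in a deterministic order.
    """
    codes = tuple(codes)
    if include_parent:
        yield HeliceneMolecule.parent()
    for k in range(1, max_subs + 1):
        for positions in itertools.combinations(range(1, N_POSITIONS + 1), k):
            for assignment in itertools.product(codes, repeat=k):
                yield HeliceneMolecule.from_substituents(
                    dict(zip(positions, assignment))
                )
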