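"""Molecule-property tables: reading, writing, validation, splitting.

The on-disk format is a flat CSV with one row per molecule:

    name, pos1..pos16, R_plus, R_minus, R_1,
    lambda_plus, lambda_minus, lambda_1, m_abs, mu_abs, g_abs

``name`` is the canonical ascending-position Position-Substituent name,
which also serves as the unique row key (so ``3-F_1-SH`` and ``1-SH_3-F``
denote one molecule and one row). Floats are serialised at repr precision
so seeded pipelines round-trip losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .chem_space import (
    N_POSITIONS,
    DescriptorTable,
    HeliceneMolecule,
    default_table,
    format_name,
)
from .chiroptics import PROPERTY_NAMES, PropertyRecord
from .errors import (
    DuplicateMoleculeError,
    SchemaError,
    ValidationError,
)
from ._seeds import rng_for

__all__ = ["Dataset", "POSITION_COLUMNS", "SCHEMA_COLUMNS", "read_dataset", "split"]

logger = logging.getLogger(__name__)

POSITION_COLUMNS: tuple[str, ...] = tuple(f"pos{i}" for i in range(1, N_POSITIONS + 1))
SCHEMA_COLUMNS: tuple[str, ...] = ("name", *POSITION_COLUMNS, *PROPERTY_NAMES)
SCHEMA_VERSION = 1


@dataclass
class Dataset:
    """An ordered, name-unique table of (molecule, property record) rows."""

    df: pd.DataFrame
    provenance: str = "oracle"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # --- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        rows: Iterable[tuple[HeliceneMolecule, PropertyRecord]],
        provenance: str = "oracle",
    ) -> "Dataset":
        data = []
        for mol, rec in rows:
            row = {"name": format_name(mol)}
            row.update(dict(zip(POSITION_COLUMNS, mol.occupancy)))
            row.update(dict(zip(PROPERTY_NAMES, rec.as_array())))
            data.append(row)
        df = pd.DataFrame(data, columns=list(SCHEMA_COLUMNS))
        return cls(df, provenance=provenance)

    # --- validation -------------------------------------------------------

    def validate(self) -> None:
        missing = [c for c in SCHEMA_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        extra = [c for c in self.df.columns if c not in SCHEMA_COLUMNS]
        if extra:
            raise SchemaError(f"unexpected columns: {extra}")
        dup = self.df["name"][self.df["name"].duplicated()]
        if len(dup):
            raise DuplicateMoleculeError(
                f"duplicate molecule name(s): {sorted(set(dup))[:5]}"
            )
        if len(self.df) == 0:
            return
        # vectorised invariant checks; report the first offending row index
        from .chem_space import SUBSTITUENT_CODES

        occ = self.df[list(POSITION_COLUMNS)].to_numpy()
        valid_codes = set(SUBSTITUENT_CODES) | {"H"}
        bad = ~np.isin(occ, list(valid_codes))
        if bad.any():
            idx = int(np.argwhere(bad.any(axis=1))[0, 0])
            raise ValidationError(f"row {idx}: unknown substituent code")
        props = self.df[list(PROPERTY_NAMES)].apply(pd.to_numeric, errors="coerce")
        if props.isna().to_numpy().any():
            idx = int(np.argwhere(props.isna().to_numpy().any(axis=1))[0, 0])
            raise ValidationError(f"row {idx}: non-numeric property value")
        checks = [
            (props["R_plus"].to_numpy() < 0, "R_plus must be >= 0"),
            (props["R_minus"].to_numpy() > 0, "R_minus must be <= 0"),
            (props["lambda_plus"].to_numpy() <= 0, "lambda_plus must be > 0"),
            (props["lambda_minus"].to_numpy() <= 0, "lambda_minus must be > 0"),
            (props["lambda_1"].to_numpy() <= 0, "lambda_1 must be > 0"),
            (props["m_abs"].to_numpy() < 0, "m_abs must be >= 0"),
            (props["mu_abs"].to_numpy() < 0, "mu_abs must be >= 0"),
            (np.abs(props["g_abs"].to_numpy()) > 2 + 1e-9, "|g_abs| cannot exceed 2"),
        ]
        for mask, msg in checks:
            if mask.any():
                idx = int(np.argwhere(mask)[0, 0])
                raise ValidationError(
                    f"row {idx} ({self.df['name'].iloc[idx]!r}): {msg}"
                )

    # --- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, name: str) -> bool:
        return name in set(self.df["name"])

    @property
    def names(self) -> list[str]:
        return list(self.df["name"])

    def molecule(self, idx: int) -> HeliceneMolecule:
        occ = tuple(self.df.iloc[idx][list(POSITION_COLUMNS)])
        return HeliceneMolecule(occ)

    def record(self, idx: int) -> PropertyRecord:
        vals = self.df.iloc[idx][list(PROPERTY_NAMES)].astype(float)
        return PropertyRecord.from_array(vals.to_numpy())

    def molecules(self) -> Iterator[HeliceneMolecule]:
        for occ in self.df[list(POSITION_COLUMNS)].itertuples(index=False):
            yield HeliceneMolecule(tuple(occ))

    def features(self, table: DescriptorTable | None = None) -> np.ndarray:
        """(n, 16) sigma_p descriptor matrix."""
        table = table or default_table()
        lut = {c: table[c] for c in set(self.df[list(POSITION_COLUMNS)].to_numpy().ravel())}
        occ = self.df[list(POSITION_COLUMNS)].to_numpy()
        return np.vectorize(lut.__getitem__)(occ).astype(float)

    def targets(self) -> np.ndarray:
        """(n, 9) property matrix in :data:`PROPERTY_NAMES` order."""
        return self.df[list(PROPERTY_NAMES)].to_numpy(dtype=float)

    # --- I/O ---------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write the table as CSV (gzip-compressed when the path ends .gz)."""
        self.df.to_csv(path, index=False)

    # --- transformations ---------------------------------------------------

    def append(
        self,
        new_rows: "Dataset" | Iterable[tuple[HeliceneMolecule, PropertyRecord]],
    ) -> "Dataset":
        """Grow the table; rows whose name already exists are dropped.

        De-duplication is by canonical name and silent apart from a log
        message, so the active-design loop can re-propose known molecules
        without corrupting the table.
        """
        other = new_rows if isinstance(new_rows, Dataset) else Dataset.from_records(new_rows)
        known = set(self.df["name"])
        mask = ~other.df["name"].isin(known)
        n_dup = int((~mask).sum())
        if n_dup:
            logger.warning("append: skipped %d row(s) with existing names", n_dup)
        df = pd.concat([self.df, other.df[mask]], ignore_index=True)
        return Dataset(df, provenance=self.provenance)

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset(
            self.df.iloc[list(indices)].reset_index(drop=True),
            provenance=self.provenance,
        )


def read_dataset(path: str | Path, provenance: str = "external") -> Dataset:
    """Read and validate a dataset CSV (see module docstring for schema)."""
    df = pd.read_csv(
        path,
        dtype={c: str for c in ("name", *POSITION_COLUMNS)},
        float_precision="round_trip",
    )
    return Dataset(df, provenance=provenance)


def split(ds: Dataset, test_fraction: float = 0.20, seed: int = 0) -> tuple[Dataset, Dataset]:
    """Seeded disjoint, exhaustive train/test split.

    The default 20% held-out fraction matches the evaluation protocol
    used throughout the package.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    rng = rng_for(seed, "split")
    n = len(ds)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return ds.subset(train_idx), ds.subset(test_idx)
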