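"""Pedigree records and the additive (numerator) relationship matrix.

The A-matrix is built by the tabular method: for individual x with parents
s and d, a_xy = (a_sy + a_dy)/2 for y processed before x, and
a_xx = 1 + a_sd/2.  Doubled-haploid lines are fully inbred by construction
(F = 1), so their diagonal is forced to 2 while off-diagonals follow the
standard recursion.  Unknown parents contribute 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

CROSS_TYPES = ("founder", "cross", "backcross", "dh")


@dataclasses.dataclass
class PedigreeRecord:
    line: str
    parent1: str | None
    parent2: str | None
    cross_type: str = "cross"


class Pedigree:
    """Ordered line/parent records; parents must precede offspring."""

    def __init__(self, records: list[PedigreeRecord] | None = None):
        self.records: list[PedigreeRecord] = []
        self._index: dict[str, int] = {}
        for r in records or []:
            self.add(r.line, r.parent1, r.parent2, r.cross_type)

    def add(self, line: str, parent1: str | None, parent2: str | None,
            cross_type: str = "cross") -> None:
        if cross_type not in CROSS_TYPES:
            raise ValueError(f"unknown cross type {cross_type!r}")
        if line in self._index:
            raise ValueError(f"duplicate line {line!r}")
        for p in (parent1, parent2):
            if p is not None and p not in self._index:
                raise ValueError(f"parent {p!r} of {line!r} not yet recorded")
        self._index[line] = len(self.records)
        self.records.append(PedigreeRecord(line, parent1, parent2, cross_type))

    def __contains__(self, line: str) -> bool:
        return line in self._index

    def __len__(self) -> int:
        return len(self.records)

    @property
    def line_ids(self) -> list[str]:
        return [r.line for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.line, r.parent1 or "", r.parent2 or "", r.cross_type)
             for r in self.records],
            columns=["line", "parent1", "parent2", "cross_type"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ped = cls()
        for _, row in df.iterrows():
            p1 = row["parent1"] or None
            p2 = row["parent2"] or None
            if isinstance(p1, float) and np.isnan(p1):
                p1 = None
            if isinstance(p2, float) and np.isnan(p2):
                p2 = None
            ped.add(str(row["line"]), p1 and str(p1), p2 and str(p2),
                    str(row.get("cross_type", "cross")))
        return ped

    @classmethod
    def read_csv(cls, path: str | Path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


def a_matrix(ped: Pedigree, line_ids: list[str] | None = None) -> np.ndarray:
    """Additive relationship matrix over all pedigree entries (or the
    requested subset, in that order)."""
    n = len(ped)
    idx = ped._index
    A = np.zeros((n, n))
    for i, rec in enumerate(ped.records):
        s = idx.get(rec.parent1) if rec.parent1 else None
        d = idx.get(rec.parent2) if rec.parent2 else None
        for j in range(i):
            a = 0.0
            if s is not None:
                a += 0.5 * A[s, j]
            if d is not None:
                a += 0.5 * A[d, j]
            A[i, j] = A[j, i] = a
        if rec.cross_type == "dh":
            A[i, i] = 2.0  # fully inbred by construction
        elif s is not None and d is not None:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
    if line_ids is not None:
        sel = np.array([idx[l] for l in line_ids])
        A = A[np.ix_(sel, sel)]
    return A
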