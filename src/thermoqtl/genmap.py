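"""Genetic maps and the Kosambi map function.

A :class:`GeneticMap` is an ordered marker table (marker id, chromosome,
genetic position in centimorgans, optional physical position in bp).  The
Kosambi map function converts between genetic distance and recombination
fraction while allowing for partial crossover interference; it is used both
by the meiosis simulator and by interval mapping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

__all__ = ["GeneticMap", "kosambi", "kosambi_inverse"]


def kosambi(d):
    """Map genetic distance ``d`` (cM) to recombination fraction.

    r = 0.5 * tanh(2 d / 100).  Valid for d >= 0; r approaches 0.5 as the
    distance grows.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise DomainError("genetic distance must be >= 0 cM")
    return 0.5 * np.tanh(2.0 * d / 100.0)


def kosambi_inverse(r):
    """Map recombination fraction ``r`` in [0, 0.5) back to distance in cM.

    d = 25 * ln((1 + 2r) / (1 - 2r)).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise DomainError("recombination fraction must lie in [0, 0.5)")
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


class GeneticMap:
    """Ordered marker map across chromosomes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker`` (str), ``chrom`` (int), ``cM`` (float >= 0) and
        optionally ``bp`` (int).  Markers must be unique; within each
        chromosome positions must be sorted, non-negative and unique.
    """

    REQUIRED = ("marker", "chrom", "cM")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise DataError(f"map table missing columns: {missing}")
        tab = table.copy().reset_index(drop=True)
        tab["marker"] = tab["marker"].astype(str)
        tab["chrom"] = tab["chrom"].astype(int)
        tab["cM"] = tab["cM"].astype(float)
        if tab["marker"].duplicated().any():
            dups = tab.loc[tab["marker"].duplicated(), "marker"].tolist()
            raise DataError(f"duplicate marker ids: {dups}")
        if (tab["cM"] < 0).any():
            raise DataError("genetic positions must be >= 0 cM")
        for chrom, sub in tab.groupby("chrom"):
            pos = sub["cM"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise DataError(
                    f"chromosome {chrom}: positions must be strictly "
                    "increasing (sorted, unique per marker)"
                )
        self.table = tab

    # -- basic accessors ---------------------------------------------------
    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.table["chrom"].unique().tolist())

    def positions(self, chrom: int) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "cM"].to_numpy()

    def chrom_markers(self, chrom: int) -> list[str]:
        return self.table.loc[self.table["chrom"] == chrom, "marker"].tolist()

    def chrom_slice(self, chrom: int) -> slice:
        """Column slice of this chromosome's markers in map order."""
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def nearest_marker(self, chrom: int, pos_cM: float) -> str:
        sub = self.table[self.table["chrom"] == chrom]
        if sub.empty:
            raise DataError(f"no markers on chromosome {chrom}")
        i = (sub["cM"] - pos_cM).abs().idxmin()
        return str(sub.loc[i, "marker"])

    def __len__(self) -> int:
        return self.n_markers

    def __repr__(self) -> str:
        return (
            f"GeneticMap({self.n_markers} markers, "
            f"{len(self.chromosomes)} chromosomes)"
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneticMap) and self.table.equals(other.table)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "GeneticMap":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
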