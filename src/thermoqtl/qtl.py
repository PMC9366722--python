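"""Composite interval mapping by Haley-Knott regression.

The scan regresses a trait (spatially adjusted BLUPs) on the expected donor
dosage at a grid of genome positions — every ``step`` cM plus all marker
positions — while conditioning on cofactor markers outside a window around
the test position.  At each position

    LOD = (n / 2) * log10(RSS0 / RSS1)

where RSS0 is the residual sum of squares of the cofactor-only fit and RSS1
adds the test-position dosage.  The percent phenotypic variance explained
by a QTL is  PVE = 100 * (1 - 10^(-2 LOD / n)).

Expected dosages between markers come from a two-state donor/recurrent
chain with Kosambi recombination fractions; heterozygous calls contribute
dosage 0.5 deterministically (residual heterozygosity in BC2-derived lines
is ~3 %), and when the two flanking genotypes agree the interior dosage
equals the shared value (no-double-crossover conditioning).

Permutation thresholds shuffle the phenotype against the genotypes and take
the empirical (1 - alpha) quantile of the genome-wide maximum LOD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DimensionError,
    DomainError,
    InvalidParameterError,
)
from .genmap import GeneticMap, kosambi, kosambi_inverse  # noqa: F401 (re-export)
from .simulate import PopulationGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "kosambi",
    "kosambi_inverse",
    "pve",
    "DosageGrid",
    "dosage_grid",
    "select_cofactors",
    "CIMScan",
    "CIMScanResult",
    "PermutationThreshold",
    "permutation_threshold",
]

_RANK_TOL = 1e-8


def pve(lod, n: int) -> float:
    """Percent phenotypic variance explained: 100 * (1 - 10^(-2 LOD / n))."""
    lod = np.asarray(lod, dtype=float)
    if np.any(lod < 0):
        raise DomainError("LOD must be >= 0")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    out = 100.0 * (1.0 - np.power(10.0, -2.0 * lod / n))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# expected-dosage grid
# ---------------------------------------------------------------------------
@dataclass
class DosageGrid:
    """Expected donor dosage per line at every scan position.

    ``positions`` has columns chrom, cM, marker ('' for pseudo-positions);
    ``X`` is lines x positions with entries in [0, 1]; ``marker_dosage`` is
    the (missing-imputed) lines x markers dosage frame used for cofactors.
    """

    positions: pd.DataFrame
    X: np.ndarray
    line_ids: list[str]
    marker_dosage: pd.DataFrame = field(repr=False)

    @property
    def n_positions(self) -> int:
        return len(self.positions)


def _impute_nearest(dosage: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Fill missing calls from the nearest typed marker on the chromosome."""
    out = dosage.copy()
    for i in range(out.shape[0]):
        miss = np.isnan(out[i])
        if not miss.any():
            continue
        typed = np.flatnonzero(~miss)
        if typed.size == 0:
            raise DataError(f"line row {i}: no typed markers on a chromosome")
        for j in np.flatnonzero(miss):
            out[i, j] = out[i, typed[np.argmin(np.abs(pos[typed] - pos[j]))]]
    return out


def _conditional_dosage(xL, xR, rL: float, rR: float) -> np.ndarray:
    """E[donor dosage | flanking dosages] under the two-state chain.

    Flankers that agree pin the interior to the shared value; otherwise the
    single-recombination conditional applies, with heterozygous flankers
    entering as dosage 0.5.
    """
    t_L1 = xL * (1 - rL) + (1 - xL) * rL      # P(left -> donor over rL)
    t_L0 = 1.0 - t_L1
    t_1R = xR * (1 - rR) + (1 - xR) * rR      # P(donor -> right over rR)
    t_0R = 1.0 - t_1R
    num1 = t_L1 * t_1R
    num0 = t_L0 * t_0R
    with np.errstate(invalid="ignore"):
        e = num1 / (num1 + num0)
    return np.where(xL == xR, xL, e)


def dosage_grid(
    gmap: GeneticMap, pop: PopulationGenotypes, step: float = 2.0
) -> DosageGrid:
    """Build the scan grid: marker positions plus every ``step`` cM."""
    if step <= 0:
        raise InvalidParameterError("step must be > 0 cM")
    if list(pop.markers) != list(gmap.markers):
        raise DimensionError("genotype columns do not align with the map")
    n = pop.n_lines
    pos_rows = []
    cols = []
    imputed = {}
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        pm = gmap.positions(chrom)
        names = gmap.chrom_markers(chrom)
        if len(pm) < 1:
            raise DataError(f"chromosome {chrom} has no markers")
        D = _impute_nearest(pop.values()[:, sl], pm)
        imputed[chrom] = (names, D)
        grid = np.unique(np.concatenate([np.arange(pm[0], pm[-1], step), pm]))
        for p in grid:
            j = np.searchsorted(pm, p)
            if j < len(pm) and abs(pm[j] - p) < 1e-9:  # typed marker
                pos_rows.append({"chrom": chrom, "cM": float(pm[j]), "marker": names[j]})
                cols.append(D[:, j])
                continue
            l, r = j - 1, j
            e = _conditional_dosage(
                D[:, l], D[:, r], float(kosambi(p - pm[l])), float(kosambi(pm[r] - p))
            )
            pos_rows.append({"chrom": chrom, "cM": float(p), "marker": ""})
            cols.append(e)
    md = pd.DataFrame(
        np.hstack([imputed[c][1] for c in gmap.chromosomes]),
        index=pop.line_ids,
        columns=[m for c in gmap.chromosomes for m in imputed[c][0]],
    )
    return DosageGrid(
        positions=pd.DataFrame(pos_rows),
        X=np.column_stack(cols) if cols else np.empty((n, 0)),
        line_ids=pop.line_ids,
        marker_dosage=md,
    )


# ---------------------------------------------------------------------------
# scan engine
# ---------------------------------------------------------------------------
def _align_y(y, line_ids) -> np.ndarray:
    if isinstance(y, pd.Series):
        missing = [l for l in line_ids if l not in y.index]
        if missing:
            raise DimensionError(f"phenotype missing for lines: {missing[:5]} ...")
        return y.loc[list(line_ids)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape != (len(line_ids),):
        raise DimensionError(f"y must have length {len(line_ids)}")
    return y


def _cofactor_matrix(grid: DosageGrid, cofactors) -> tuple[np.ndarray, list[tuple]]:
    """Cofactor dosage columns plus their (chrom, cM) coordinates."""
    cols, coords = [], []
    pos = grid.positions
    for m in cofactors:
        if m not in grid.marker_dosage.columns:
            raise InvalidParameterError(f"cofactor {m!r} is not a typed marker")
        row = pos[pos["marker"] == m].iloc[0]
        cols.append(grid.marker_dosage[m].to_numpy(dtype=float))
        coords.append((int(row["chrom"]), float(row["cM"])))
    C = np.column_stack(cols) if cols else np.empty((len(grid.line_ids), 0))
    return C, coords


def _scan_lod(
    Y: np.ndarray,
    grid: DosageGrid,
    cofactors,
    window: float,
    want_effects: bool = False,
):
    """Vectorized Haley-Knott scan for one or many phenotype columns.

    Y is (n, p); returns LOD (n_positions, p) and, if requested, the
    dosage regression coefficient per position for Y's first column.
    """
    n, p = Y.shape
    C, coords = _cofactor_matrix(grid, cofactors)
    ones = np.ones((n, 1))
    tot = np.sum(Y * Y, axis=0)

    q_cache: dict[frozenset, tuple[np.ndarray, np.ndarray]] = {}

    def base(include: frozenset):
        if include not in q_cache:
            X0 = np.hstack([ones, C[:, sorted(include)]]) if include else ones
            Q, R = np.linalg.qr(X0)
            keep = np.abs(np.diag(R)) > _RANK_TOL * max(1.0, np.abs(R[0, 0]))
            Q = Q[:, keep]
            QtY = Q.T @ Y
            rss0 = tot - np.sum(QtY * QtY, axis=0)
            q_cache[include] = (Q, rss0)
        return q_cache[include]

    lod = np.zeros((grid.n_positions, p))
    eff = np.full(grid.n_positions, np.nan)
    half = window / 2.0
    chroms = grid.positions["chrom"].to_numpy()
    cms = grid.positions["cM"].to_numpy()
    for j in range(grid.n_positions):
        include = frozenset(
            i
            for i, (cc, cp) in enumerate(coords)
            if not (cc == chroms[j] and abs(cp - cms[j]) < half)
        )
        Q, rss0 = base(include)
        d = grid.X[:, j]
        u = d - Q @ (Q.T @ d)
        norm = np.linalg.norm(u)
        if norm <= _RANK_TOL * max(1.0, np.linalg.norm(d)):
            logger.warning(
                "scan position %s:%.2f is rank-deficient; LOD set to 0",
                chroms[j], cms[j],
            )
            continue
        qt = u / norm
        proj = qt @ Y
        rss1 = np.maximum(rss0 - proj * proj, 1e-300)
        lod[j] = (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1)
        if want_effects:
            eff[j] = proj[0] / norm
    return (lod, eff) if want_effects else lod


def select_cofactors(y, grid: DosageGrid, k: int = 1) -> list[str]:
    """Greedy forward selection of ``k`` cofactor markers.

    Each step adds the typed marker with the highest single-marker
    regression LOD conditional on the markers already chosen; LOD ties are
    broken by lowest (chromosome, cM, marker id).
    """
    if k < 0:
        raise InvalidParameterError("k must be >= 0")
    markers = list(grid.marker_dosage.columns)
    if k > len(markers):
        raise InvalidParameterError(f"k = {k} exceeds marker count {len(markers)}")
    yv = _align_y(y, grid.line_ids)
    n = len(yv)
    pos = grid.positions.set_index("marker")
    chosen: list[str] = []
    ones = np.ones((n, 1))
    for _ in range(k):
        Xc = np.hstack(
            [ones] + [grid.marker_dosage[m].to_numpy()[:, None] for m in chosen]
        )
        Q, R = np.linalg.qr(Xc)
        keep = np.abs(np.diag(R)) > _RANK_TOL
        Q = Q[:, keep]
        r0 = yv - Q @ (Q.T @ yv)
        rss0 = float(r0 @ r0)
        best = None
        for m in markers:
            if m in chosen:
                continue
            d = grid.marker_dosage[m].to_numpy(dtype=float)
            u = d - Q @ (Q.T @ d)
            norm = np.linalg.norm(u)
            if norm <= _RANK_TOL * max(1.0, np.linalg.norm(d)):
                continue
            proj = float((u / norm) @ yv)
            rss1 = max(rss0 - proj * proj, 1e-300)
            lod = (n / 2.0) * np.log10(rss0 / rss1)
            key = (-np.round(lod, 12), int(pos.loc[m, "chrom"]), float(pos.loc[m, "cM"]), m)
            if best is None or key < best[0]:
                best = (key, m)
        if best is None:
            break
        chosen.append(best[1])
    return chosen


# ---------------------------------------------------------------------------
# model/results objects
# ---------------------------------------------------------------------------
class CIMScan:
    """Composite-interval-mapping scan for one trait.

    Parameters
    ----------
    y : phenotype (Series indexed by line id, or array in grid line order) —
        typically averaged spatially adjusted BLUPs.
    grid : DosageGrid from :func:`dosage_grid`.
    cofactors : iterable of typed marker ids to condition on; a cofactor is
        excluded wherever it lies within ``window / 2`` cM of the test
        position on the same chromosome.
    """

    def __init__(self, y, grid: DosageGrid, cofactors=(), window: float = 40.0):
        self.grid = grid
        self.cofactors = list(cofactors)
        self.window = float(window)
        self.y = _align_y(y, grid.line_ids)

    @classmethod
    def from_population(
        cls, y, gmap: GeneticMap, pop: PopulationGenotypes,
        step: float = 2.0, n_cofactors: int = 1, window: float = 40.0,
    ) -> "CIMScan":
        grid = dosage_grid(gmap, pop, step)
        cof = select_cofactors(y, grid, n_cofactors)
        return cls(y, grid, cof, window)

    def fit(self) -> "CIMScanResult":
        lod, eff = _scan_lod(
            self.y[:, None], self.grid, self.cofactors, self.window, want_effects=True
        )
        n = len(self.y)
        tab = self.grid.positions.copy()
        tab["lod"] = lod[:, 0]
        tab["effect"] = eff
        tab["pve"] = pve(tab["lod"].to_numpy(), n)
        return CIMScanResult(
            table=tab, n=n, cofactors=list(self.cofactors), window=self.window
        )


@dataclass
class CIMScanResult:
    """Genome-grid LOD / effect / PVE profile."""

    table: pd.DataFrame
    n: int
    cofactors: list
    window: float
    threshold: "PermutationThreshold | None" = None

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peaks(self, lod_threshold: float | None = None) -> pd.DataFrame:
        """Per-chromosome LOD maxima at or above the threshold."""
        if lod_threshold is None:
            if self.threshold is None:
                raise InvalidParameterError("no threshold attached or supplied")
            lod_threshold = self.threshold.lod_star
        rows = []
        for chrom, sub in self.table.groupby("chrom"):
            i = sub["lod"].idxmax()
            if sub.loc[i, "lod"] >= lod_threshold:
                rows.append(sub.loc[i])
        cols = list(self.table.columns)
        return pd.DataFrame(rows, columns=cols).reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            f"Haley-Knott composite interval mapping  (n = {self.n}, "
            f"cofactors = {self.cofactors or 'none'}, window = {self.window} cM)",
            f"  positions scanned: {len(self.table)}   max LOD: {self.max_lod():.2f}",
        ]
        if self.threshold is not None:
            lines.append(
                f"  permutation threshold (alpha = {self.threshold.alpha}): "
                f"LOD* = {self.threshold.lod_star:.2f} "
                f"[{self.threshold.n_perm} permutations]"
            )
            pk = self.peaks()
            for _, r in pk.iterrows():
                lines.append(
                    f"  QTL chr {int(r['chrom'])} @ {r['cM']:.1f} cM: "
                    f"LOD {r['lod']:.2f}, effect {r['effect']:+.3f}, "
                    f"PVE {r['pve']:.2f} %"
                )
        return "\n".join(lines)

    def plot(self, ax=None):
        """LOD profile by chromosome (cumulative cM on the x axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset = 0.0
        for chrom, sub in self.table.groupby("chrom"):
            x = sub["cM"].to_numpy() + offset
            ax.plot(x, sub["lod"], label=f"chr{chrom}")
            offset = x.max() + 5.0
        if self.threshold is not None:
            ax.axhline(self.threshold.lod_star, ls="--", color="k", lw=0.8)
        ax.set_xlabel("cumulative genetic position (cM)")
        ax.set_ylabel("LOD")
        return ax


@dataclass
class PermutationThreshold:
    """Empirical genome-wide LOD significance threshold."""

    lod_star: float
    alpha: float
    n_perm: int
    null_maxima: np.ndarray = field(repr=False)


def permutation_threshold(
    y,
    grid: DosageGrid,
    cofactors=(),
    window: float = 40.0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PermutationThreshold:
    """Genome-wide LOD threshold by phenotype permutation.

    The phenotype is shuffled against the genotypes ``n_perm`` times, the
    full scan is repeated per shuffle, and LOD* is the inclusive empirical
    (1 - alpha) quantile (R type 1) of the genome-wide maxima.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100 for a stable quantile")
    if not (0 < alpha <= 1):
        raise InvalidParameterError("alpha must lie in (0, 1]")
    yv = _align_y(y, grid.line_ids)
    rng = np.random.default_rng(seed)
    n = len(yv)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = yv[rng.permutation(n)]
    lod = _scan_lod(perms, grid, cofactors, window)
    maxima = lod.max(axis=0)
    lod_star = float(np.quantile(maxima, 1.0 - alpha, method="inverted_cdf"))
    return PermutationThreshold(
        lod_star=lod_star, alpha=alpha, n_perm=n_perm, null_maxima=maxima
    )
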