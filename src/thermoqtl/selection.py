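"""Rank-sum multi-trait selection index and gain-under-selection accounting.

Families are ranked per trait in the favorable direction (rank 1 = best:
highest turgor, lowest canopy temperature), the two ranks are summed into a
simplified multi-trait index (MTI), and the lowest rank sums are selected.
Selection intensity K is the deviation of a selection from the population
mean in standard-deviation units, signed so that favorable deviation is
positive.  Gain under selection is the difference between a selection
group's mean and the base (training) population mean — favorable gain is
positive for turgor and negative for canopy temperature.

The donor-allele-frequency check is a two-category chi-square goodness of
fit of the number of selections carrying a donor QTL region against the
expected inbred-backcross donor frequency (12.5 % for BC2-derived lines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError, InvalidParameterError

__all__ = [
    "TRAIT_DIRECTIONS",
    "rank_trait",
    "mti_select",
    "selection_intensity",
    "co_selection_pct",
    "GainReport",
    "gain_under_selection",
    "FrequencyTest",
    "allele_frequency_chisq",
    "build_selection_report",
]

#: Favorable direction per trait; anything not listed must be given
#: explicitly.
TRAIT_DIRECTIONS = {
    "turgor": "higher_better",
    "canopy_temp": "lower_better",
    "canopy_temperature": "lower_better",
    "irt": "lower_better",
    "vpd": "lower_better",
    "gsw": "higher_better",
}


def _check_direction(direction: str):
    if direction not in ("higher_better", "lower_better"):
        raise InvalidParameterError(
            "direction must be 'higher_better' or 'lower_better'"
        )


def rank_trait(values: pd.Series, direction: str) -> pd.Series:
    """Rank 1 = best under the trait's favorable direction; ties get
    average ranks."""
    _check_direction(direction)
    v = values.to_numpy(dtype=float) if isinstance(values, pd.Series) else np.asarray(values, float)
    if v.size == 0 or np.any(~np.isfinite(v)):
        raise DataError("values must be non-empty and finite")
    signed = -v if direction == "higher_better" else v
    ranks = stats.rankdata(signed, method="average")
    if isinstance(values, pd.Series):
        return pd.Series(ranks, index=values.index, name="rank")
    return pd.Series(ranks, name="rank")


def mti_select(
    ranks_turgor: pd.Series, ranks_canopy: pd.Series, n_select: int
) -> pd.DataFrame:
    """Select the ``n_select`` smallest rank sums (MTI = turgor rank +
    canopy rank).  Ties break by smaller canopy rank, then id."""
    if len(ranks_turgor) != len(ranks_canopy):
        raise InvalidParameterError("rank vectors must have equal length")
    if n_select > len(ranks_turgor):
        raise InvalidParameterError("n_select exceeds the number of families")
    df = pd.DataFrame(
        {
            "rank_turgor": ranks_turgor,
            "rank_canopy": ranks_canopy.loc[ranks_turgor.index],
        }
    )
    df["mti"] = df["rank_turgor"] + df["rank_canopy"]
    # stable two-stage sort: id ascending first, then (mti, canopy rank)
    df = df.sort_index(key=lambda ix: ix.astype(str), kind="mergesort")
    df = df.sort_values(by=["mti", "rank_canopy"], kind="mergesort")
    df["selected"] = False
    df.iloc[: n_select, df.columns.get_loc("selected")] = True
    return df


def selection_intensity(
    value: float, population_mean: float, population_sd: float, direction: str
) -> float:
    """K = deviation from the mean in SD units, positive when favorable."""
    _check_direction(direction)
    if population_sd <= 0:
        raise DomainError("population SD must be > 0")
    k = (value - population_mean) / population_sd
    return float(k if direction == "higher_better" else -k)


def co_selection_pct(pheno_ids, gs_ids) -> float:
    """100 x |intersection| / (|pheno list| + |gs list|)."""
    pheno_ids, gs_ids = list(pheno_ids), list(gs_ids)
    if not pheno_ids or not gs_ids:
        raise InvalidParameterError("both selection lists must be non-empty")
    if len(set(pheno_ids)) != len(pheno_ids) or len(set(gs_ids)) != len(gs_ids):
        raise DataError("duplicated ids within a selection list")
    shared = set(pheno_ids) & set(gs_ids)
    return 100.0 * len(shared) / (len(pheno_ids) + len(gs_ids))


@dataclass
class GainReport:
    """Gain = group mean - base (training population) mean, signed."""

    trait: str
    group: str
    base_mean: float
    group_mean: float
    gain: float


def gain_under_selection(
    group_values, base_mean: float, trait: str = "", group: str = ""
) -> GainReport:
    """Mean of the selection group minus the base-population mean."""
    v = np.asarray(group_values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("selection group is empty")
    gm = float(v.mean())
    return GainReport(
        trait=trait, group=group, base_mean=float(base_mean),
        group_mean=gm, gain=gm - float(base_mean),
    )


@dataclass
class FrequencyTest:
    """Two-category goodness-of-fit of observed donor-QTL carriers."""

    observed: int
    n: int
    p_expected: float
    chi2: float
    p_value: float
    df: int = 1


def allele_frequency_chisq(observed: int, N: int, p_expected: float) -> FrequencyTest:
    """chi2 = (O - Np)^2 / (Np) + ((N - O) - N(1 - p))^2 / (N(1 - p)), 1 df."""
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    if not (0 <= observed <= N):
        raise InvalidParameterError("observed must lie in [0, N]")
    if not (0 < p_expected < 1):
        raise InvalidParameterError("p_expected must lie in (0, 1)")
    e1, e0 = N * p_expected, N * (1.0 - p_expected)
    chi2 = (observed - e1) ** 2 / e1 + ((N - observed) - e0) ** 2 / e0
    return FrequencyTest(
        observed=int(observed), n=int(N), p_expected=float(p_expected),
        chi2=float(chi2), p_value=float(stats.chi2.sf(chi2, df=1)),
    )


def build_selection_report(
    pheno: pd.DataFrame,
    gebv: pd.DataFrame,
    n_pheno: int = 10,
    n_gs: int = 10,
    n_random: int = 10,
    turgor_col: str = "turgor",
    canopy_col: str = "canopy_temp",
    seed: int | None = None,
) -> pd.DataFrame:
    """Form the Pheno / GS / Pheno+GS / Random selection groups.

    ``pheno`` and ``gebv`` are family-indexed frames holding the turgor and
    canopy-temperature phenotypic BLUPs and GEBVs.  The top ``n_pheno``
    rank-sum phenotypic selections and top ``n_gs`` rank-sum genomic
    selections are taken; families in both lists are labelled ``Pheno+GS``
    (groups are disjoint), and ``n_random`` families are drawn uniformly
    without replacement from the unselected remainder.

    Returns one row per family with per-trait ranks, rank-sum MTI under
    each index, the group label, and the selection intensities K for both
    traits (positive = favorable).
    """
    for df, what in ((pheno, "pheno"), (gebv, "gebv")):
        for col in (turgor_col, canopy_col):
            if col not in df.columns:
                raise DataError(f"{what} table lacks column {col!r}")
    fam = pheno.index.astype(str)
    if set(fam) != set(gebv.index.astype(str)):
        raise DataError("pheno and gebv tables must cover the same families")

    rp_t = rank_trait(pheno[turgor_col], "higher_better")
    rp_c = rank_trait(pheno[canopy_col], "lower_better")
    rg_t = rank_trait(gebv[turgor_col], "higher_better")
    rg_c = rank_trait(gebv[canopy_col], "lower_better")
    sel_p = mti_select(rp_t, rp_c, n_pheno)
    sel_g = mti_select(rg_t, rg_c, n_gs)
    pheno_ids = set(sel_p.index[sel_p["selected"]])
    gs_ids = set(sel_g.index[sel_g["selected"]])
    both = pheno_ids & gs_ids

    rng = np.random.default_rng(seed)
    pool = [f for f in pheno.index if f not in pheno_ids | gs_ids]
    if n_random > len(pool):
        raise InvalidParameterError("not enough unselected families for Random group")
    random_ids = set(rng.choice(pool, size=n_random, replace=False)) if n_random else set()

    mu_t, sd_t = float(pheno[turgor_col].mean()), float(pheno[turgor_col].std(ddof=1))
    mu_c, sd_c = float(pheno[canopy_col].mean()), float(pheno[canopy_col].std(ddof=1))

    def label(f):
        if f in both:
            return "Pheno+GS"
        if f in pheno_ids:
            return "Pheno"
        if f in gs_ids:
            return "GS"
        if f in random_ids:
            return "Random"
        return ""

    out = pd.DataFrame(
        {
            "rank_turgor": rp_t,
            "rank_canopy": rp_c,
            "mti": rp_t + rp_c,
            "gebv_rank_turgor": rg_t,
            "gebv_rank_canopy": rg_c,
            "gebv_mti": rg_t + rg_c,
            "group": [label(f) for f in pheno.index],
        },
        index=pheno.index,
    )
    out["selected"] = out["group"] != ""
    out["K_turgor"] = [
        selection_intensity(v, mu_t, sd_t, "higher_better") if sd_t > 0 else np.nan
        for v in pheno[turgor_col]
    ]
    out["K_canopy"] = [
        selection_intensity(v, mu_c, sd_c, "lower_better") if sd_c > 0 else np.nan
        for v in pheno[canopy_col]
    ]
    return out
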