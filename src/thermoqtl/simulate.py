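"""Synthetic inbred-backcross study generator.

Everything the analysis side consumes can be generated here with known truth:

* genetic maps (:func:`simulate_genetic_map`),
* BC\\ :sub:`k`\\ S\\ :sub:`m` inbred-backcross genotypes produced by explicit
  meioses with Kosambi recombination fractions (:func:`simulate_ibc_population`),
* augmented greenhouse layouts with over-replicated parental checks
  (:func:`make_augmented_layout`),
* QTL-driven, spatially structured phenotypes with an ordinal 1-5 turgor
  scale (:func:`simulate_phenotypes`), and
* radiometric thermal scenes with a known canopy mask and temperature
  (:func:`simulate_thermal_scene`).

Defaults mirror the study conditions this package emulates: a 160-family
BC2S3 tomato population genotyped at 157 markers on 12 chromosomes, with an
expected donor-allele frequency of 12.5 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    DomainError,
    InvalidParameterError,
    LayoutError,
    LookupError_,
)
from .genmap import GeneticMap, kosambi

__all__ = [
    "PopulationGenotypes",
    "QtlEffect",
    "TrialLayout",
    "VarianceSpec",
    "ThermalSceneTruth",
    "simulate_genetic_map",
    "simulate_gamete",
    "simulate_ibc_population",
    "make_augmented_layout",
    "simulate_phenotypes",
    "study_conditions",
    "simulate_study",
    "ellipse_mask",
    "simulate_thermal_scene",
    "RECURRENT_CHECK",
    "DONOR_CHECK",
]

#: Default check (parent) names: recurrent parent carries donor dosage 0
#: everywhere, the donor parent dosage 1 everywhere.
RECURRENT_CHECK = "OH8245"
DONOR_CHECK = "LA1141"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------
class PopulationGenotypes:
    """Lines x markers donor-allele dosage matrix tied to a GeneticMap.

    Dosage values are 0 (recurrent homozygote), 0.5 (heterozygote) or
    1 (donor homozygote); NaN marks a missing call.
    """

    def __init__(self, dosage: pd.DataFrame, generation_label: str = ""):
        vals = dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 0.5, 1.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise DomainError(
                f"dosage values must be in {{0, 0.5, 1}} (or NaN); offending "
                f"entry at row {bad[0]}, column {bad[1]}"
            )
        self.dosage = dosage.copy()
        self.dosage.index = self.dosage.index.astype(str)
        self.generation_label = generation_label

    @property
    def line_ids(self) -> list[str]:
        return self.dosage.index.tolist()

    @property
    def n_lines(self) -> int:
        return len(self.dosage)

    @property
    def markers(self) -> list[str]:
        return self.dosage.columns.tolist()

    def values(self) -> np.ndarray:
        return self.dosage.to_numpy(dtype=float)

    def donor_allele_frequency(self) -> float:
        """Mean donor dosage across all lines and loci (ignoring NaN)."""
        return float(np.nanmean(self.values()))

    def heterozygote_fraction(self) -> float:
        """Fraction of non-missing calls that are heterozygous."""
        v = self.values()
        return float(np.mean(v[~np.isnan(v)] == 0.5))

    @classmethod
    def from_csv(cls, path, generation_label: str = "") -> "PopulationGenotypes":
        df = pd.read_csv(path, index_col=0)
        df.index.name = "line_id"
        return cls(df, generation_label)

    def to_csv(self, path) -> None:
        out = self.dosage.copy()
        out.index.name = "line_id"
        out.to_csv(path)

    def __repr__(self) -> str:
        lab = f" {self.generation_label}" if self.generation_label else ""
        return f"PopulationGenotypes({self.n_lines} lines x {len(self.markers)} markers{lab})"


@dataclass(frozen=True)
class QtlEffect:
    """Additive QTL: ``effect`` trait units per unit donor dosage at the
    marker nearest (chromosome, position_cM)."""

    chromosome: int
    position_cM: float
    trait: str
    effect: float


@dataclass
class VarianceSpec:
    """Variance structure of a simulated trial.

    Variances are in squared trait units.  ``turgor_cutpoints`` are the four
    ascending latent thresholds that discretize a continuous turgor liability
    onto the ordinal 1-5 scale (1 = dead ... 5 = turgid).
    """

    genotype_var: float = 1.0
    row_var: float = 0.25
    column_var: float = 0.25
    residual_var: float = 1.0
    trait_means: dict = field(default_factory=dict)
    turgor_cutpoints: tuple = (-1.5, -0.5, 0.5, 1.5)

    def __post_init__(self):
        for name in ("genotype_var", "row_var", "column_var", "residual_var"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        cp = tuple(float(c) for c in self.turgor_cutpoints)
        if len(cp) != 4 or not all(a < b for a, b in zip(cp, cp[1:])):
            raise InvalidParameterError(
                "turgor_cutpoints must be 4 strictly ascending thresholds"
            )
        self.turgor_cutpoints = cp


class TrialLayout:
    """Augmented-design plot list: one row per (environment, row, column)."""

    COLUMNS = ("entry_id", "environment", "row", "column", "is_check", "check_name")

    def __init__(self, plots: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in plots.columns]
        if missing:
            raise LayoutError(f"layout missing columns: {missing}")
        if plots.duplicated(["environment", "row", "column"]).any():
            raise LayoutError("duplicate (environment, row, column) plot")
        self.plots = plots.reset_index(drop=True)

    def entries(self, environment: str | None = None) -> list[str]:
        p = self.plots
        if environment is not None:
            p = p[p["environment"] == environment]
        return p.loc[~p["is_check"], "entry_id"].tolist()

    @property
    def environments(self) -> list[str]:
        return sorted(self.plots["environment"].unique().tolist())

    def __len__(self) -> int:
        return len(self.plots)


@dataclass
class ThermalSceneTruth:
    """Known truth behind a synthetic radiometric scene."""

    true_canopy_temperature: float
    true_background_temperature: float
    true_mask: np.ndarray  # bool, 1 = canopy
    noise_sd: float = 0.0

    def __post_init__(self):
        self.true_mask = np.asarray(self.true_mask, dtype=bool)
        if self.true_mask.sum() == 0:
            raise DomainError("canopy mask is empty")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# map simulation
# ---------------------------------------------------------------------------
def simulate_genetic_map(
    n_chromosomes: int,
    chrom_length: float,
    n_markers_per_chrom: int,
    seed: int,
) -> GeneticMap:
    """Random marker map: each chromosome starts at 0 cM, remaining markers
    uniform on (0, chrom_length], sorted."""
    if n_chromosomes < 1 or n_markers_per_chrom < 2 or chrom_length <= 0:
        raise InvalidParameterError(
            "need n_chromosomes >= 1, n_markers_per_chrom >= 2, chrom_length > 0"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in range(1, n_chromosomes + 1):
        pos = np.sort(rng.uniform(0.0, chrom_length, size=n_markers_per_chrom - 1))
        # enforce unique, strictly increasing, non-zero positions
        pos = np.unique(np.round(pos, 4))
        pos = pos[pos > 0]
        while len(pos) < n_markers_per_chrom - 1:
            extra = np.round(rng.uniform(0.0, chrom_length), 4)
            if extra > 0 and extra not in pos:
                pos = np.sort(np.append(pos, extra))
        pos = np.concatenate([[0.0], pos])
        for i, p in enumerate(pos, start=1):
            rows.append({"marker": f"m{chrom}_{i}", "chrom": chrom, "cM": p})
    return GeneticMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# meiosis and population simulation
# ---------------------------------------------------------------------------
def _recomb_fractions(gmap: GeneticMap) -> list[tuple[slice, np.ndarray]]:
    """Per chromosome: (marker column slice, adjacent-interval r's)."""
    out = []
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        d = np.diff(gmap.positions(chrom))
        out.append((sl, kosambi(d)))
    return out


def _gametes(gmap: GeneticMap, h1: np.ndarray, h2: np.ndarray, rng) -> np.ndarray:
    """Vectorized meiosis: one gamete per row of (h1, h2).

    Crossovers are realized independently per marker interval (Markov along
    the chromosome, no interference) with probability equal to the Kosambi
    inverse of the inter-marker distance; chromosomes assort independently.
    """
    h1 = np.atleast_2d(h1)
    h2 = np.atleast_2d(h2)
    if h1.shape != h2.shape or h1.shape[1] != gmap.n_markers:
        raise DimensionError(
            f"haplotypes must be (n, {gmap.n_markers}); got {h1.shape} and {h2.shape}"
        )
    n = h1.shape[0]
    gam = np.empty_like(h1)
    for sl, r in _recomb_fractions(gmap):
        m = sl.stop - sl.start
        # which parental strand each marker is read from (0 -> h1, 1 -> h2)
        strand = np.empty((n, m), dtype=np.int8)
        strand[:, 0] = rng.integers(0, 2, size=n)
        if m > 1:
            flips = rng.random((n, m - 1)) < r
            strand[:, 1:] = flips
            strand = np.cumsum(strand, axis=1) % 2
        gam[:, sl] = np.where(strand == 0, h1[:, sl], h2[:, sl])
    return gam


def simulate_gamete(gmap: GeneticMap, haplotypes, rng) -> np.ndarray:
    """Single meiosis: mosaic of the two parental haplotypes.

    ``haplotypes`` is a pair (h1, h2) of arrays indexed like the map;
    ``rng`` is a numpy Generator (seed state).
    """
    h1, h2 = (np.asarray(h, dtype=float) for h in haplotypes)
    return _gametes(gmap, h1[None, :], h2[None, :], rng)[0]


def simulate_ibc_population(
    gmap: GeneticMap,
    n_lines: int,
    n_backcrosses: int = 2,
    n_selfs: int = 3,
    seed: int = 0,
    generation_label: str | None = None,
) -> PopulationGenotypes:
    """Simulate an inbred-backcross population by single-seed descent.

    Starting from the F1 (one donor and one recurrent haplotype at every
    locus), each line is carried through ``n_backcrosses`` crosses to the
    recurrent homozygote followed by ``n_selfs`` self generations with
    independent meioses.  The expected donor-allele frequency per locus is
    (1/2)^(1 + n_backcrosses) — 12.5 % for BC2-derived lines — and expected
    heterozygosity halves with every self generation.
    """
    if n_lines < 1:
        raise InvalidParameterError("n_lines must be >= 1")
    if n_backcrosses < 1 or n_selfs < 0:
        raise InvalidParameterError("need n_backcrosses >= 1 and n_selfs >= 0")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    # each line: two haplotypes with 1 = donor allele
    h1 = np.ones((n_lines, m))   # donor haplotype of the F1
    h2 = np.zeros((n_lines, m))  # recurrent haplotype
    for _ in range(n_backcrosses):
        h1 = _gametes(gmap, h1, h2, rng)
        h2 = np.zeros((n_lines, m))
    for _ in range(n_selfs):
        g1 = _gametes(gmap, h1, h2, rng)
        g2 = _gametes(gmap, h1, h2, rng)
        h1, h2 = g1, g2
    dosage = (h1 + h2) / 2.0
    if generation_label is None:
        generation_label = f"BC{n_backcrosses}S{n_selfs}"
    width = len(str(n_lines))
    ids = [f"IBL{str(i + 1).zfill(width)}" for i in range(n_lines)]
    df = pd.DataFrame(dosage, index=ids, columns=gmap.markers)
    return PopulationGenotypes(df, generation_label)


# ---------------------------------------------------------------------------
# trial layout
# ---------------------------------------------------------------------------
def make_augmented_layout(
    n_entries: int,
    check_names: list[str] = (RECURRENT_CHECK, DONOR_CHECK),
    n_check_reps: int = 36,
    n_rows: int = 16,
    n_columns: int = 15,
    environment: str = "env1",
    seed: int = 0,
    entry_ids: list[str] | None = None,
) -> TrialLayout:
    """Augmented design: unreplicated entries plus over-replicated checks.

    Check replicates are spread in a grid-like pattern so that, when
    capacity allows, every row and every column contains at least one check;
    test entries fill the remaining cells at random.
    """
    check_names = list(check_names)
    n_checks_total = n_check_reps * len(check_names)
    if n_rows * n_columns < n_entries + n_checks_total:
        raise LayoutError(
            f"grid {n_rows}x{n_columns} cannot hold {n_entries} entries + "
            f"{n_checks_total} check plots"
        )
    if entry_ids is None:
        width = len(str(max(n_entries, 1)))
        entry_ids = [f"IBL{str(i + 1).zfill(width)}" for i in range(n_entries)]
    elif len(entry_ids) != n_entries:
        raise LayoutError("entry_ids length must equal n_entries")

    rng = np.random.default_rng(seed)
    free = {(r, c) for r in range(1, n_rows + 1) for c in range(1, n_columns + 1)}
    rows_order = rng.permutation(np.arange(1, n_rows + 1))
    cols_wo_check: set[int] = set(range(1, n_columns + 1))
    placements: list[tuple[str, int, int]] = []  # (check_name, row, col)

    # interleave the checks so each is spread over rows and columns
    check_stream = [check_names[i % len(check_names)] for i in range(n_checks_total)]
    ri = 0
    for name in check_stream:
        row = int(rows_order[ri % n_rows])
        ri += 1
        avail = sorted(c for (r, c) in free if r == row)
        if not avail:  # row already full; fall back to any free cell
            r, c = sorted(free)[int(rng.integers(len(free)))]
            row, col = r, c
        else:
            pref = sorted(set(avail) & cols_wo_check)
            pool = pref if pref else avail
            col = int(pool[int(rng.integers(len(pool)))])
        free.discard((row, col))
        cols_wo_check.discard(col)
        placements.append((name, row, col))

    cells = sorted(free)
    rng.shuffle(cells)
    records = [
        {
            "entry_id": name,
            "environment": environment,
            "row": r,
            "column": c,
            "is_check": True,
            "check_name": name,
        }
        for name, r, c in placements
    ]
    for eid, (r, c) in zip(entry_ids, cells):
        records.append(
            {
                "entry_id": eid,
                "environment": environment,
                "row": r,
                "column": c,
                "is_check": False,
                "check_name": None,
            }
        )
    return TrialLayout(pd.DataFrame(records, columns=list(TrialLayout.COLUMNS)))


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------
def _entry_dosage(pop: PopulationGenotypes, entry: str, is_check: bool) -> np.ndarray:
    if not is_check:
        if entry not in pop.dosage.index:
            raise LookupError_(f"layout entry {entry!r} not found in population")
        return pop.dosage.loc[entry].to_numpy(dtype=float)
    if entry == DONOR_CHECK:
        return np.ones(len(pop.markers))
    return np.zeros(len(pop.markers))  # recurrent or any other check


def simulate_phenotypes(
    pop: PopulationGenotypes,
    gmap: GeneticMap,
    qtls: list[QtlEffect],
    layout: TrialLayout,
    vs,
    seed: int = 0,
    traits: list[str] | None = None,
    return_truth: bool = False,
) -> pd.DataFrame:
    """Generate a phenotype table over a trial layout.

    Each observation is  mean + sum(QTL effect x dosage at nearest marker)
    + polygenic N(0, genotype_var) + row + column + residual, with row and
    column effects drawn per environment.  A trait named ``turgor`` is
    additionally discretized through the latent cutpoints onto {1..5}.
    Genetic values (QTL + polygenic) are drawn once per genotype and shared
    across environments.

    ``vs`` is a single :class:`VarianceSpec` shared by all traits or a
    ``{trait: VarianceSpec}`` mapping (different traits in real trials
    partition variance very differently).

    With ``return_truth=True`` also returns the per-genotype true genetic
    values (turgor on the latent liability scale).
    """
    if traits is None:
        traits = sorted({q.trait for q in qtls}) or ["trait"]
    if isinstance(vs, VarianceSpec):
        vs_by_trait = {t: vs for t in traits}
    else:
        missing = [t for t in traits if t not in vs]
        if missing:
            raise InvalidParameterError(f"no VarianceSpec for traits {missing}")
        vs_by_trait = dict(vs)
    rng = np.random.default_rng(seed)
    plots = layout.plots

    # per-genotype genetic values
    genotypes = sorted(set(plots["entry_id"]))
    dos = {
        g: _entry_dosage(pop, g, bool(plots.loc[plots["entry_id"] == g, "is_check"].iloc[0]))
        for g in genotypes
    }
    marker_index = {m: i for i, m in enumerate(gmap.markers)}
    genval: dict[str, dict[str, float]] = {t: {} for t in traits}
    for trait in traits:
        qtl_cols = [
            (marker_index[gmap.nearest_marker(q.chromosome, q.position_cM)], q.effect)
            for q in qtls
            if q.trait == trait
        ]
        poly = rng.normal(0.0, np.sqrt(vs_by_trait[trait].genotype_var), size=len(genotypes))
        for g, p in zip(genotypes, poly):
            d = dos[g]
            genval[trait][g] = sum(eff * d[i] for i, eff in qtl_cols) + p

    out = plots[["entry_id", "environment", "row", "column", "is_check", "check_name"]].copy()
    out = out.rename(columns={"entry_id": "line_id"})
    for trait in traits:
        vst = vs_by_trait[trait]
        mu = float(vst.trait_means.get(trait, 0.0))
        vals = np.empty(len(plots))
        for env, idx in plots.groupby("environment").groups.items():
            sub = plots.loc[idx]
            rows = sorted(sub["row"].unique())
            cols = sorted(sub["column"].unique())
            r_eff = dict(zip(rows, rng.normal(0, np.sqrt(vst.row_var), len(rows))))
            c_eff = dict(zip(cols, rng.normal(0, np.sqrt(vst.column_var), len(cols))))
            resid = rng.normal(0, np.sqrt(vst.residual_var), len(sub))
            vals[sub.index] = (
                mu
                + np.array([genval[trait][g] for g in sub["entry_id"]])
                + np.array([r_eff[r] for r in sub["row"]])
                + np.array([c_eff[c] for c in sub["column"]])
                + resid
            )
        if trait == "turgor":
            vals = np.searchsorted(np.asarray(vst.turgor_cutpoints), vals) + 1.0
        out[trait] = vals
    if return_truth:
        truth = pd.DataFrame(genval)
        truth.index.name = "line_id"
        return out, truth
    return out


def study_conditions() -> dict:
    """Canonical generator settings emulating the tomato introgression study.

    A 160-family BC2S3 population on a 12-chromosome, 157-marker map
    (13 markers per chromosome less one, ~80 cM each), screened twice
    (summer/fall) in 16 x 15 augmented layouts with 36 replicates of each
    parent as checks.  Two QTLs per trait sized so each explains roughly
    7-9 % of the family-mean variance; variance partitions per trait follow
    the magnitudes observed for a visual turgor score (genotype ~46 % of
    plot variance) and image-based canopy temperature (genotype ~22 %,
    plot-level sd ~1.6 degC).  Turgor is generated on a latent liability
    (mean 0, cutpoints at -1.5, -0.5, 0.5, 1.5) and scored 1-5.
    """
    return {
        "map": {"n_chromosomes": 12, "chrom_length": 80.0, "n_markers_per_chrom": 13},
        "population": {"n_lines": 160, "n_backcrosses": 2, "n_selfs": 3},
        "layout": {"n_rows": 16, "n_columns": 15, "n_check_reps": 36},
        "environments": ["summer", "fall"],
        "traits": ["turgor", "canopy_temp"],
        "variance": {
            "turgor": VarianceSpec(
                genotype_var=0.35, row_var=0.114, column_var=0.056,
                residual_var=0.374, trait_means={"turgor": 0.0},
            ),
            "canopy_temp": VarianceSpec(
                genotype_var=0.31, row_var=0.01, column_var=0.068,
                residual_var=1.82, trait_means={"canopy_temp": 24.5},
            ),
        },
        "qtls": [
            QtlEffect(5, 0.0, "turgor", +0.75),
            QtlEffect(7, 42.0, "turgor", +0.65),
            QtlEffect(1, 20.0, "canopy_temp", -1.05),
            QtlEffect(6, 23.0, "canopy_temp", -0.95),
        ],
    }


def simulate_study(seed: int, conditions: dict | None = None):
    """One full synthetic screen under :func:`study_conditions`.

    Returns a dict with the map, population, stacked two-environment
    phenotype table, and the true per-genotype genetic values.  All
    randomness derives from ``seed`` via spawned child seeds.
    """
    cond = conditions or study_conditions()
    ss = np.random.SeedSequence(seed)
    s = [int(x.generate_state(1)[0] % (2**31)) for x in ss.spawn(2 + 2 * len(cond["environments"]))]
    gmap = simulate_genetic_map(**cond["map"], seed=s[0])
    pop = simulate_ibc_population(gmap, **cond["population"], seed=s[1])
    layouts = [
        make_augmented_layout(
            pop.n_lines, **cond["layout"], environment=env,
            seed=s[2 + i], entry_ids=pop.line_ids,
        )
        for i, env in enumerate(cond["environments"])
    ]
    combined = TrialLayout(pd.concat([l.plots for l in layouts], ignore_index=True))
    # one generator call: genetic values are shared across environments
    pheno, truth = simulate_phenotypes(
        pop, gmap, cond["qtls"], combined, cond["variance"],
        seed=s[2 + len(cond["environments"])], traits=cond["traits"],
        return_truth=True,
    )
    return {
        "map": gmap,
        "population": pop,
        "phenotypes": pheno,
        "truth": truth.loc[pop.line_ids],
        "conditions": cond,
    }


# ---------------------------------------------------------------------------
# thermal scenes
# ---------------------------------------------------------------------------
def ellipse_mask(shape: tuple[int, int], center=None, axes=None) -> np.ndarray:
    """Boolean elliptical canopy mask; defaults to an ellipse covering about
    a quarter of the frame, centered."""
    nr, nc = shape
    if center is None:
        center = ((nr - 1) / 2.0, (nc - 1) / 2.0)
    if axes is None:
        axes = (nr / 4.0, nc / 4.0)
    rr, cc = np.mgrid[0:nr, 0:nc]
    mask = ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0
    if mask.sum() == 0:
        raise DomainError("ellipse geometry yields an empty canopy mask")
    return mask


def simulate_thermal_scene(truth: ThermalSceneTruth, calib, shape=None, seed: int = 0):
    """Forward-model a radiometric image from scene truth.

    Per-pixel temperature = canopy or background truth + N(0, noise_sd),
    converted to integer sensor counts by the exact inverse of the
    raw-to-temperature calibration curve.  Returns a RadiometricImage.
    """
    from .thermal import temperature_to_raw  # local import: thermal is I/O-free

    mask = truth.true_mask
    if shape is not None and tuple(shape) != mask.shape:
        raise DimensionError(f"mask shape {mask.shape} != requested {tuple(shape)}")
    rng = np.random.default_rng(seed)
    T = np.where(mask, truth.true_canopy_temperature, truth.true_background_temperature)
    T = T.astype(float)
    if truth.noise_sd > 0:
        T = T + rng.normal(0.0, truth.noise_sd, size=T.shape)
    return temperature_to_raw(T, calib)
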