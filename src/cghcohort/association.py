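"""Breed/region association with permutation family-wise error control,
plus the nonparametric cohort epidemiology comparisons.

The per-region test is Fisher's exact test on the 2x2 table
(breed x region-aberration).  Family-wise error across regions is controlled
by permuting breed labels: each permutation keeps every case's aberration
vector intact (preserving inter-region correlation), all per-region p-values
are recomputed, and the minimum is recorded; the empirical alpha-quantile of
that min-p distribution is the per-test significance cutoff.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .cna_calling import CaseCallResult, Segment
from .io_formats import CaseMeta, Config, chrom_sort_key

__all__ = [
    "Region",
    "RegionAberrationMatrix",
    "AssociationResult",
    "PermutationCutoff",
    "EpidemiologyReport",
    "fisher_exact_2x2",
    "build_region_matrix",
    "permutation_fwer",
    "associate_regions",
    "mann_whitney_u",
    "compare_epidemiology",
    "write_association_results",
]

#: relative tolerance for probability ties in the two-sided Fisher rule
_FISHER_TIE_RTOL = 1e-7

INTERNAL_LOCATIONS = {"one_internal_organ", "multiple_internal_organs"}
LOCALIZED_LOCATIONS = {"limb_only", "skin_only"}


@dataclass(frozen=True)
class Region:
    chrom: str
    start_mb: float
    end_mb: float
    state: str  # "gain" | "loss"

    def label(self) -> str:
        return f"{self.chrom}:{self.start_mb:g}-{self.end_mb:g}:{self.state}"


@dataclass
class RegionAberrationMatrix:
    case_ids: list[str]
    breeds: np.ndarray  # per-case breed label
    regions: list[Region]
    indicator: np.ndarray  # cases x regions, {0,1}

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=np.int8)
        if self.indicator.shape != (len(self.case_ids), len(self.regions)):
            raise ValueError("indicator shape mismatch")
        if not np.isin(self.indicator, (0, 1)).all():
            raise ValueError("indicators must be 0/1")
        if len(self.regions) == 0:
            raise ValueError("no regions to test")


@dataclass(frozen=True)
class AssociationResult:
    region: Region
    a: int  # breed1 carriers
    b: int  # breed2 carriers
    c: int  # breed1 non-carriers
    d: int  # breed2 non-carriers
    p_value: float
    significant: bool


@dataclass
class PermutationCutoff:
    alpha: float
    n_permutations: int
    cutoff: float
    min_p: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))

    def summary(self) -> dict[str, float]:
        q = np.quantile(self.min_p, [0.01, 0.05, 0.25, 0.5])
        return {
            "q01": float(q[0]),
            "q05": float(q[1]),
            "q25": float(q[2]),
            "median": float(q[3]),
        }


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums the probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed the observed table's (with a
    small relative tolerance for floating-point ties).  Degenerate margins
    (an empty row or column) return p = 1.0 with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 margin; returning p = 1.0", stacklevel=2)
        return 1.0
    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_TIE_RTOL)].sum())
    return min(p, 1.0)


def build_region_matrix(
    results: Sequence[CaseCallResult],
    regions: Sequence[Region | tuple],
    meta: Sequence[CaseMeta],
    chrom_lengths: dict[str, float] | None = None,
) -> RegionAberrationMatrix:
    """Binary case x region aberration-overlap matrix over aberrant cases."""
    regs = [r if isinstance(r, Region) else Region(*r) for r in regions]
    regs.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start_mb, r.end_mb))
    for r in regs:
        if not r.end_mb > r.start_mb:
            raise ValueError(f"empty region {r.label()}")
        if chrom_lengths is not None:
            limit = chrom_lengths.get(r.chrom)
            if limit is not None and (r.start_mb < 0 or r.end_mb > limit):
                raise ValueError(f"region off chromosome: {r.label()}")
    breed_of = {m.case_id: m.breed for m in meta}
    aberrant = [r for r in results if r.aberrant]
    case_ids = [r.case_id for r in aberrant]
    indicator = np.zeros((len(aberrant), len(regs)), dtype=np.int8)
    for i, res in enumerate(aberrant):
        for j, reg in enumerate(regs):
            indicator[i, j] = any(
                s.state == reg.state and s.overlaps(reg.chrom, reg.start_mb, reg.end_mb)
                for s in res.segments
            )
    breeds = np.array([breed_of[c] for c in case_ids], dtype=object)
    return RegionAberrationMatrix(case_ids, breeds, regs, indicator)


def _per_region_p_tables(matrix: RegionAberrationMatrix, m1: int):
    """Precompute p(k) lookup arrays per region, k = breed-1 carriers.

    With breed-label permutations the margins of every region's 2x2 table are
    fixed; only the count of breed-1 carriers varies, so Fisher p-values can
    be tabulated once per region.
    """
    n = len(matrix.case_ids)
    tables = []
    for j in range(matrix.indicator.shape[1]):
        K = int(matrix.indicator[:, j].sum())
        p_of_k = np.ones(min(K, m1) + 1)
        for k in range(max(0, K - (n - m1)), min(K, m1) + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p_of_k[k] = fisher_exact_2x2(k, K - k, m1 - k, (n - K) - (m1 - k))
        tables.append(p_of_k)
    return tables


def permutation_fwer(
    matrix: RegionAberrationMatrix,
    cfg: Config,
    rng: np.random.Generator | None = None,
) -> PermutationCutoff:
    """Empirical per-test p-value cutoff controlling FWER at ``fwer_alpha``.

    Cutoff is the ceil(alpha * n_permutations)-th smallest of the permutation
    min-p distribution.
    """
    if cfg.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    levels = sorted(set(matrix.breeds.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two breeds, found {levels}")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    n = len(matrix.case_ids)
    m1 = int(np.sum(matrix.breeds == levels[0]))
    p_tables = _per_region_p_tables(matrix, m1)
    M = matrix.indicator.astype(np.float64)
    n_perm = cfg.n_permutations
    min_p = np.empty(n_perm)
    chunk = 1000
    base = np.zeros(n)
    base[:m1] = 1.0
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        F = np.empty((hi - lo, n))
        for t in range(hi - lo):
            F[t] = rng.permutation(base)
        ks = np.rint(F @ M).astype(int)  # perms x regions
        ps = np.empty_like(ks, dtype=float)
        for j, table in enumerate(p_tables):
            ps[:, j] = table[ks[:, j]]
        min_p[lo:hi] = ps.min(axis=1)
    order = np.sort(min_p)
    rank = max(1, math.ceil(cfg.fwer_alpha * n_perm))
    cutoff = float(order[rank - 1])
    return PermutationCutoff(
        alpha=cfg.fwer_alpha, n_permutations=n_perm, cutoff=cutoff, min_p=min_p
    )


def associate_regions(
    matrix: RegionAberrationMatrix,
    cutoff: PermutationCutoff,
) -> list[AssociationResult]:
    """Observed per-region Fisher p-values with significance under the cutoff."""
    levels = sorted(set(matrix.breeds.tolist()))
    is1 = matrix.breeds == levels[0]
    out = []
    for j, region in enumerate(matrix.regions):
        col = matrix.indicator[:, j].astype(bool)
        a = int(np.sum(col & is1))
        b = int(np.sum(col & ~is1))
        c = int(np.sum(~col & is1))
        d = int(np.sum(~col & ~is1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_2x2(a, b, c, d)
        out.append(AssociationResult(region, a, b, c, d, p, p < cutoff.cutoff))
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (U = min of the two one-sided statistics) and 2-sided p.

    Ties get midranks.  Exact enumeration of all labelings when both samples
    have <= 8 observations; otherwise a normal approximation with
    tie-corrected variance and continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    if n1 <= 8 and n2 <= 8:
        total = 0
        hits = 0
        idx = range(n1 + n2)
        target = u + 1e-9
        for subset in itertools.combinations(idx, n1):
            rs = sum(ranks[i] for i in subset)
            us1 = rs - n1 * (n1 + 1) / 2.0
            total += 1
            if min(us1, n1 * n2 - us1) <= target:
                hits += 1
        return u, hits / total
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    z = (u - n1 * n2 / 2.0 + 0.5) / math.sqrt(var)
    p = 2.0 * stats.norm.cdf(z)
    return u, float(min(p, 1.0))


@dataclass
class EpidemiologyReport:
    age_stats: dict[str, tuple[int, float, float]]  # breed -> (n, mean, sd)
    age_p: float | None
    location_counts: dict[str, tuple[int, int]]  # breed -> (internal, other)
    location_p: float
    internal_frac: dict[str, float]
    localized_frac: dict[str, float]


def compare_epidemiology(meta: Sequence[CaseMeta]) -> EpidemiologyReport:
    """Between-breed age (Mann-Whitney) and tumor-location (Fisher) contrasts.

    Location is collapsed to internal-organ involvement (one or multiple
    internal organs) versus all other categories for the 2x2 test.
    """
    by_breed: dict[str, list[CaseMeta]] = {}
    for m in meta:
        by_breed.setdefault(m.breed, []).append(m)
    if set(by_breed) != {"BMD", "FCR"}:
        raise ValueError("both breeds (BMD, FCR) must be present")
    ages = {
        b: [m.age_years for m in ms if m.age_years is not None]
        for b, ms in by_breed.items()
    }
    age_stats = {}
    for b, vals in ages.items():
        arr = np.asarray(vals)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        age_stats[b] = (len(arr), float(np.mean(arr)) if len(arr) else math.nan, sd)
    if all(len(v) > 0 for v in ages.values()):
        _, age_p = mann_whitney_u(ages["BMD"], ages["FCR"])
    else:
        warnings.warn("ages all unknown in a breed; age test skipped", stacklevel=2)
        age_p = None
    location_counts = {}
    internal_frac = {}
    localized_frac = {}
    for b, ms in by_breed.items():
        known = [m for m in ms if m.tumor_location != "unknown"]
        internal = sum(1 for m in known if m.tumor_location in INTERNAL_LOCATIONS)
        localized = sum(1 for m in known if m.tumor_location in LOCALIZED_LOCATIONS)
        location_counts[b] = (internal, len(known) - internal)
        internal_frac[b] = internal / len(known) if known else math.nan
        localized_frac[b] = localized / len(known) if known else math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        location_p = fisher_exact_2x2(
            location_counts["BMD"][0],
            location_counts["FCR"][0],
            location_counts["BMD"][1],
            location_counts["FCR"][1],
        )
    return EpidemiologyReport(
        age_stats=age_stats,
        age_p=age_p,
        location_counts=location_counts,
        location_p=location_p,
        internal_frac=internal_frac,
        localized_frac=localized_frac,
    )


def write_association_results(
    results: Sequence[AssociationResult],
    cutoff: PermutationCutoff,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart_mb\tend_mb\tstate\ta\tb\tc\td\tp_value\tsignificant\tcutoff\n"
        )
        for r in results:
            fh.write(
                f"{r.region.chrom}\t{r.region.start_mb:.6f}\t{r.region.end_mb:.6f}\t"
                f"{r.region.state}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{r.p_value:.6g}\t"
                f"{int(r.significant)}\t{cutoff.cutoff:.6g}\n"
            )
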