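"""Microsatellite loss-of-heterozygosity scoring from peak-area tables.

For each informative (germline-heterozygous) marker the allelic ratio
AR = area(shorter allele) / area(longer allele) is computed for tumor and
blood, and the allelic imbalance AI = AR(tumor) / AR(blood).  An AI at or
beyond the configured thresholds (default >= 1.5 or <= 0.67) calls the
marker as deleted (LOH).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io_formats import Config

__all__ = [
    "AIResult",
    "RegionLOHSummary",
    "allelic_ratio",
    "allelic_imbalance",
    "call_loh",
    "assess_informative",
    "evaluate_peak_table",
    "summarize_region",
    "write_ai_results",
    "write_region_summaries",
]

#: minimum minor/major blood peak-area ratio for a heterozygous genotype to
#: count as informative (guards against stutter / near-homozygous peaks)
INFORMATIVE_AREA_RATIO = 0.2


@dataclass(frozen=True)
class AIResult:
    case_id: str
    marker_id: str
    ar_tumor: float  # NaN when uninformative
    ar_blood: float
    ai: float
    informative: bool
    loh_call: bool


@dataclass(frozen=True)
class RegionLOHSummary:
    case_id: str
    region: str
    n_informative: int
    n_loh: int
    region_loh: bool | None  # None = indeterminate (no informative markers)


def allelic_ratio(area1: float, area2: float) -> float:
    """Peak-area ratio with canonical ordering (area1 = shorter allele)."""
    if area1 < 0 or area2 < 0:
        raise ValueError("peak areas must be non-negative")
    if area2 == 0:
        raise ValueError("allelic ratio undefined: second peak area is zero")
    return area1 / area2


def allelic_imbalance(ar_tumor: float, ar_blood: float) -> float:
    if ar_blood <= 0:
        raise ValueError("blood allelic ratio must be positive")
    return ar_tumor / ar_blood


def call_loh(ai: float, cfg: Config) -> bool:
    """True iff AI >= ai_upper or AI <= ai_lower (both boundaries inclusive)."""
    if not math.isfinite(ai) or ai <= 0:
        raise ValueError("AI must be finite and positive")
    return ai >= cfg.ai_upper or ai <= cfg.ai_lower


def assess_informative(
    allele1_size: float,
    allele2_size: float,
    allele1_area: float,
    allele2_area: float,
) -> bool:
    """A blood genotype is informative iff heterozygous with two solid peaks."""
    if allele1_size == allele2_size:
        return False
    if allele1_area <= 0 or allele2_area <= 0:
        return False
    minor = min(allele1_area, allele2_area)
    major = max(allele1_area, allele2_area)
    return minor / major >= INFORMATIVE_AREA_RATIO


def evaluate_peak_table(peaks: pd.DataFrame, cfg: Config) -> list[AIResult]:
    """Score every (case, marker) pair that has both a tumor and a blood row."""
    results: list[AIResult] = []
    nan = float("nan")
    for (case_id, marker_id), grp in peaks.groupby(["case_id", "marker_id"], sort=True):
        by_type = {r["sample_type"]: r for _, r in grp.iterrows()}
        blood = by_type.get("blood")
        tumor = by_type.get("tumor")
        if blood is None or tumor is None:
            continue
        informative = assess_informative(
            blood["allele1_size"],
            blood["allele2_size"],
            blood["allele1_area"],
            blood["allele2_area"],
        )
        if not informative:
            results.append(
                AIResult(case_id, marker_id, nan, nan, nan, False, False)
            )
            continue
        ar_blood = allelic_ratio(blood["allele1_area"], blood["allele2_area"])
        if tumor["allele2_area"] == 0:
            # one tumor allele entirely absent: complete allelic loss
            results.append(
                AIResult(case_id, marker_id, math.inf, ar_blood, math.inf, True, True)
            )
            continue
        ar_tumor = allelic_ratio(tumor["allele1_area"], tumor["allele2_area"])
        ai = allelic_imbalance(ar_tumor, ar_blood)
        results.append(
            AIResult(case_id, marker_id, ar_tumor, ar_blood, ai, True, call_loh(ai, cfg))
        )
    return results


def summarize_region(
    results: Sequence[AIResult],
    region: str = "panel",
    markers: set[str] | None = None,
) -> list[RegionLOHSummary]:
    """Per-case region LOH status over a marker panel.

    A case shows region LOH when at least one informative marker carries an
    LOH call; cases with no informative markers are indeterminate
    (``region_loh is None``) rather than negative.
    """
    out: list[RegionLOHSummary] = []
    by_case: dict[str, list[AIResult]] = {}
    for r in results:
        if markers is not None and r.marker_id not in markers:
            continue
        by_case.setdefault(r.case_id, []).append(r)
    for case_id in sorted(by_case):
        rows = by_case[case_id]
        informative = [r for r in rows if r.informative]
        n_loh = sum(1 for r in informative if r.loh_call)
        if not informative:
            warnings.warn(
                f"case {case_id}: no informative markers in region {region!r}",
                stacklevel=2,
            )
            out.append(RegionLOHSummary(case_id, region, 0, 0, None))
        else:
            out.append(
                RegionLOHSummary(case_id, region, len(informative), n_loh, n_loh >= 1)
            )
    return out


def write_ai_results(results: Sequence[AIResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("case_id\tmarker_id\tar_tumor\tar_blood\tai\tinformative\tloh_call\n")
        for r in sorted(results, key=lambda r: (r.case_id, r.marker_id)):
            def fmt(x: float) -> str:
                return "NA" if math.isnan(x) else ("inf" if math.isinf(x) else f"{x:.6f}")

            fh.write(
                f"{r.case_id}\t{r.marker_id}\t{fmt(r.ar_tumor)}\t{fmt(r.ar_blood)}\t"
                f"{fmt(r.ai)}\t{int(r.informative)}\t{int(r.loh_call)}\n"
            )


def write_region_summaries(summaries: Sequence[RegionLOHSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("case_id\tregion\tn_informative\tn_loh\tregion_loh\n")
        for s in sorted(summaries, key=lambda s: (s.region, s.case_id)):
            status = "indeterminate" if s.region_loh is None else str(int(s.region_loh))
            fh.write(f"{s.case_id}\t{s.region}\t{s.n_informative}\t{s.n_loh}\t{status}\n")
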