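"""Cohort penetrance tracks and recurrent-region classification.

Penetrance is the percent of aberrant cases whose called segments of a given
state overlap each 1-Mb grid cell.  The denominator is aberrant cases only;
flat cases never change a percentage.  CFAX is excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cna_calling import CaseCallResult
from .io_formats import CloneMap, Config, FormatError, chrom_sort_key

__all__ = [
    "PenetranceTrack",
    "RecurrentRegion",
    "compute_penetrance",
    "classify_cells",
    "merge_regions",
    "write_penetrance",
    "read_penetrance",
    "write_region_bed",
]


@dataclass
class PenetranceTrack:
    """Per-cell gain/loss penetrance over the 1-Mb grid.

    Cells are the clone-map grid cells ``[pos, pos+1)``; percentages are
    rounded to 1 decimal and share the aberrant-case denominator
    ``n_cases``.
    """

    chroms: np.ndarray  # cell chromosome labels
    start_mb: np.ndarray  # cell starts (cell = [start, start+1))
    pct_gain: np.ndarray
    pct_loss: np.ndarray
    n_cases: int

    def __post_init__(self) -> None:
        for arr in (self.pct_gain, self.pct_loss):
            if np.any(arr < 0) or np.any(arr > 100):
                raise ValueError("penetrance percentages must lie in [0, 100]")
        if np.any(self.pct_gain + self.pct_loss > 100.0 + 1e-9):
            raise ValueError("per-cell gain + loss penetrance cannot exceed 100")

    @property
    def n_cells(self) -> int:
        return len(self.start_mb)

    def cell_value(self, chrom: str, start_mb: float, state: str) -> float:
        mask = (self.chroms == chrom) & (np.abs(self.start_mb - start_mb) < 1e-9)
        idx = np.flatnonzero(mask)
        if len(idx) != 1:
            raise KeyError(f"no unique cell {chrom}:[{start_mb}, {start_mb + 1})")
        arr = self.pct_gain if state == "gain" else self.pct_loss
        return float(arr[idx[0]])


@dataclass(frozen=True)
class RecurrentRegion:
    chrom: str
    start_mb: float
    end_mb: float
    state: str
    peak_pct: float
    label: str  # "recurrent" | "highly_recurrent" | "none"


def compute_penetrance(
    results: Sequence[CaseCallResult],
    clone_map: CloneMap,
    cfg: Config | None = None,
    stratum: set[str] | None = None,
    include_x: bool = False,
) -> PenetranceTrack:
    """Aggregate per-case segments into a per-cell penetrance track.

    ``stratum`` optionally restricts to a set of case ids (e.g. one breed);
    the denominator is always the aberrant cases in the stratum.
    """
    selected = [
        r
        for r in results
        if r.aberrant and (stratum is None or r.case_id in stratum)
    ]
    if not selected:
        raise ValueError("no aberrant cases in requested stratum")
    keep = np.array(
        [include_x or c != "CFAX" for c in clone_map.chroms], dtype=bool
    )
    chroms = clone_map.chroms[keep]
    starts = clone_map.pos_mb[keep]
    n_cells = len(starts)
    gain_counts = np.zeros(n_cells, dtype=int)
    loss_counts = np.zeros(n_cells, dtype=int)
    cell_index: dict[str, np.ndarray] = {}
    for chrom in set(chroms.tolist()):
        cell_index[chrom] = np.flatnonzero(chroms == chrom)
    for r in selected:
        gain_cov = np.zeros(n_cells, dtype=bool)
        loss_cov = np.zeros(n_cells, dtype=bool)
        for seg in r.segments:
            idx = cell_index.get(seg.chrom)
            if idx is None:
                continue
            pos = starts[idx]
            hit = idx[(pos < seg.end_mb) & (pos + 1.0 > seg.start_mb)]
            if seg.state == "gain":
                gain_cov[hit] = True
            else:
                loss_cov[hit] = True
        gain_counts += gain_cov
        loss_counts += loss_cov
    n = len(selected)
    return PenetranceTrack(
        chroms=chroms,
        start_mb=starts,
        pct_gain=np.round(100.0 * gain_counts / n, 1),
        pct_loss=np.round(100.0 * loss_counts / n, 1),
        n_cases=n,
    )


def classify_cells(track: PenetranceTrack, cfg: Config) -> dict[str, np.ndarray]:
    """Recurrence labels per cell and state, from the rounded percentages."""
    out = {}
    hi = 100.0 * cfg.highly_recurrent_frac
    lo = 100.0 * cfg.recurrent_frac
    for state, pct in (("gain", track.pct_gain), ("loss", track.pct_loss)):
        labels = np.full(track.n_cells, "none", dtype=object)
        labels[pct >= lo] = "recurrent"
        labels[pct >= hi] = "highly_recurrent"
        out[state] = labels
    return out


def merge_regions(
    track: PenetranceTrack,
    cfg: Config,
    state: str,
    threshold: float,
) -> list[RecurrentRegion]:
    """Merge maximal runs of adjacent same-chromosome cells at/above threshold.

    Adjacency means consecutive 1-Mb grid cells; there is no gap tolerance.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must lie in (0, 100]")
    pct = track.pct_gain if state == "gain" else track.pct_loss
    qualifying = pct >= threshold
    regions: list[RecurrentRegion] = []
    i = 0
    n = track.n_cells
    while i < n:
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and qualifying[j + 1]
            and track.chroms[j + 1] == track.chroms[i]
            and abs(track.start_mb[j + 1] - track.start_mb[j] - 1.0) < 1e-9
        ):
            j += 1
        peak = float(np.max(pct[i : j + 1]))
        if peak >= 100.0 * cfg.highly_recurrent_frac:
            label = "highly_recurrent"
        elif peak >= 100.0 * cfg.recurrent_frac:
            label = "recurrent"
        else:
            label = "none"
        regions.append(
            RecurrentRegion(
                chrom=str(track.chroms[i]),
                start_mb=float(track.start_mb[i]),
                end_mb=float(track.start_mb[j]) + 1.0,
                state=state,
                peak_pct=peak,
                label=label,
            )
        )
        i = j + 1
    return regions


def write_penetrance(track: PenetranceTrack, cfg: Config, path: str | Path) -> None:
    labels = classify_cells(track, cfg)

    def cell_label(i: int) -> str:
        lg, ll = labels["gain"][i], labels["loss"][i]
        order = {"highly_recurrent": 2, "recurrent": 1, "none": 0}
        return lg if order[lg] >= order[ll] else ll

    with open(path, "w") as fh:
        fh.write("chrom\tstart_mb\tend_mb\tpct_gain\tpct_loss\trecurrence_label\n")
        for i in range(track.n_cells):
            fh.write(
                f"{track.chroms[i]}\t{track.start_mb[i]:.6f}\t{track.start_mb[i] + 1.0:.6f}\t"
                f"{track.pct_gain[i]:.1f}\t{track.pct_loss[i]:.1f}\t{cell_label(i)}\n"
            )


def read_penetrance(path: str | Path, n_cases: int) -> PenetranceTrack:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start_mb", "pct_gain", "pct_loss"}
    if not required.issubset(df.columns):
        raise FormatError(f"penetrance file must have columns {sorted(required)}")
    order = sorted(
        range(len(df)),
        key=lambda i: (chrom_sort_key(df["chrom"].iloc[i]), df["start_mb"].iloc[i]),
    )
    df = df.iloc[order]
    return PenetranceTrack(
        chroms=df["chrom"].to_numpy(dtype=object),
        start_mb=df["start_mb"].to_numpy(dtype=float),
        pct_gain=df["pct_gain"].to_numpy(dtype=float),
        pct_loss=df["pct_loss"].to_numpy(dtype=float),
        n_cases=n_cases,
    )


def write_region_bed(regions: Sequence[RecurrentRegion], path: str | Path) -> None:
    rows = sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start_mb))
    with open(path, "w") as fh:
        fh.write("chrom\tstart_mb\tend_mb\tstate\tpeak_pct\tlabel\n")
        for r in rows:
            fh.write(
                f"{r.chrom}\t{r.start_mb:.6f}\t{r.end_mb:.6f}\t{r.state}\t{r.peak_pct:.1f}\t{r.label}\n"
            )
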