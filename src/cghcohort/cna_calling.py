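"""Per-case copy-number calling from log2 ratio profiles.

The segmentation stand-in is a moving-median smoother (shrinking windows at
chromosome ends, missing clones excluded from each window) followed by fixed
ratio thresholds on the smoothed values.  The smoother is pluggable: pass any
callable with the :func:`smooth_profile` signature to :func:`call_case` /
:func:`call_cohort` to substitute a different segmentation front-end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import CloneMap, Config, RatioTable, chrom_sort_key

__all__ = [
    "Segment",
    "CaseCallResult",
    "StratumStats",
    "smooth_profile",
    "call_states",
    "extract_segments",
    "call_case",
    "call_cohort",
    "summarize_cohort",
    "size_histogram",
]

GAIN, NEUTRAL, LOSS = 1, 0, -1
_STATE_NAME = {GAIN: "gain", LOSS: "loss"}


@dataclass(frozen=True)
class Segment:
    """A maximal run of contiguous same-state aberrant clones."""

    case_id: str
    chrom: str
    start_mb: float
    end_mb: float
    state: str  # "gain" | "loss"
    mean_log2: float
    n_clones: int
    homozygous_flag: bool = False

    def __post_init__(self) -> None:
        if self.state not in ("gain", "loss"):
            raise ValueError(f"unknown segment state {self.state!r}")
        if not self.end_mb > self.start_mb:
            raise ValueError("segment end_mb must exceed start_mb")
        if self.homozygous_flag and self.state != "loss":
            raise ValueError("homozygous_flag requires state == 'loss'")

    @property
    def size_mb(self) -> float:
        return self.end_mb - self.start_mb

    def overlaps(self, chrom: str, start_mb: float, end_mb: float) -> bool:
        return (
            self.chrom == chrom and self.start_mb < end_mb and self.end_mb > start_mb
        )


@dataclass
class CaseCallResult:
    case_id: str
    segments: list[Segment] = field(default_factory=list)

    @property
    def aberrant(self) -> bool:
        return len(self.segments) > 0

    def n_by_state(self, state: str) -> int:
        return sum(1 for s in self.segments if s.state == state)


def smooth_profile(values, window: int) -> np.ndarray:
    """Moving median along axis 0 with shrinking windows at the ends.

    ``values`` may be 1-D (one chromosome, one case) or 2-D
    (clones x cases).  NaNs are excluded from each window; an all-missing
    window yields NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    v = np.asarray(values, dtype=float)
    if v.shape[0] == 0:
        return v.copy()
    if window == 1:
        return v.copy()
    if np.all(np.isnan(v)):
        warnings.warn("all-missing profile; smoothing is a no-op", stacklevel=2)
        return v.copy()
    half = window // 2
    pad = [(half, half)] + [(0, 0)] * (v.ndim - 1)
    padded = np.pad(v, pad, constant_values=np.nan)
    windows = sliding_window_view(padded, window, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmedian(windows, axis=-1)


def call_states(smoothed, cfg: Config) -> np.ndarray:
    """Per-clone state calls: +1 gain, 0 neutral, -1 loss (missing -> neutral)."""
    v = np.asarray(smoothed, dtype=float)
    states = np.zeros(v.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        states[v >= cfg.gain_cut] = GAIN
        states[v <= cfg.loss_cut] = LOSS
    return states


def extract_segments(
    states: Sequence[int],
    raw,
    positions,
    chrom: str,
    case_id: str,
    cfg: Config,
) -> list[Segment]:
    """Maximal non-neutral runs of >= ``min_segment_clones`` clones.

    Segment extent covers the clone grid interval: ``[first clone position,
    last clone position + 1.0)`` so a k-clone run on the 1-Mb grid spans k Mb.
    ``mean_log2`` is the mean of the *raw* (unsmoothed) ratios over member
    clones; a loss run with raw mean below ``homozygous_log2_cut`` is flagged
    as a putative homozygous deletion.
    """
    s = np.asarray(states, dtype=np.int8)
    raw = np.asarray(raw, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if not (len(s) == len(raw) == len(pos)):
        raise ValueError("states, raw and positions must be aligned")
    out: list[Segment] = []
    if len(s) == 0:
        return out
    boundaries = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(s)]))
    for a, b in zip(starts, ends):
        state = int(s[a])
        if state == NEUTRAL or (b - a) < cfg.min_segment_clones:
            continue
        member_raw = raw[a:b]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_log2 = float(np.nanmean(member_raw))
        homo = state == LOSS and mean_log2 < cfg.homozygous_log2_cut
        out.append(
            Segment(
                case_id=case_id,
                chrom=chrom,
                start_mb=float(pos[a]),
                end_mb=float(pos[b - 1]) + 1.0,
                state=_STATE_NAME[state],
                mean_log2=mean_log2,
                n_clones=int(b - a),
                homozygous_flag=bool(homo),
            )
        )
    return out


Smoother = Callable[[np.ndarray, int], np.ndarray]


def call_case(
    case_id: str,
    values,
    clone_map: CloneMap,
    cfg: Config,
    smoother: Smoother = smooth_profile,
) -> CaseCallResult:
    """Smooth -> threshold -> extract, chromosome by chromosome."""
    v = np.asarray(values, dtype=float)
    if v.shape != (clone_map.n_clones,):
        raise ValueError("profile length does not match clone map")
    segments: list[Segment] = []
    for chrom in clone_map.chromosomes():
        idx = clone_map.chrom_indices(chrom)
        chrom_vals = v[idx]
        smoothed = smoother(chrom_vals, cfg.smoothing_window)
        states = call_states(smoothed, cfg)
        segments.extend(
            extract_segments(states, chrom_vals, clone_map.pos_mb[idx], chrom, case_id, cfg)
        )
    segments.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start_mb))
    return CaseCallResult(case_id=case_id, segments=segments)


def call_cohort(
    table: RatioTable,
    clone_map: CloneMap,
    cfg: Config,
    smoother: Smoother = smooth_profile,
) -> list[CaseCallResult]:
    """Call every case of a ratio table (vectorized smoothing per chromosome)."""
    if table.clone_ids != list(clone_map.clone_ids):
        raise ValueError("ratio table is not aligned to the clone map")
    n_cases = len(table.case_ids)
    per_case_segments: list[list[Segment]] = [[] for _ in range(n_cases)]
    for chrom in clone_map.chromosomes():
        idx = clone_map.chrom_indices(chrom)
        block = table.values[idx, :]  # clones x cases
        smoothed = smoother(block, cfg.smoothing_window)
        states = call_states(smoothed, cfg)
        pos = clone_map.pos_mb[idx]
        for j, case_id in enumerate(table.case_ids):
            per_case_segments[j].extend(
                extract_segments(states[:, j], block[:, j], pos, chrom, case_id, cfg)
            )
    results = []
    for case_id, segs in zip(table.case_ids, per_case_segments):
        segs.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start_mb))
        results.append(CaseCallResult(case_id=case_id, segments=segs))
    return results


@dataclass
class StratumStats:
    """Table-1 style per-stratum summary, over aberrant cases only."""

    n_cases: int
    mean_n_cnas: float
    sd_n_cnas: float
    mean_n_losses: float
    sd_n_losses: float
    mean_n_gains: float
    sd_n_gains: float
    loss_gain_ratio: float
    mean_size_loss_mb: float
    sd_size_loss_mb: float
    mean_size_gain_mb: float
    sd_size_gain_mb: float


def _sd(x: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1))


def _stratum_stats(results: list[CaseCallResult]) -> StratumStats:
    n_cnas = np.array([len(r.segments) for r in results], dtype=float)
    n_losses = np.array([r.n_by_state("loss") for r in results], dtype=float)
    n_gains = np.array([r.n_by_state("gain") for r in results], dtype=float)
    loss_sizes = np.array(
        [s.size_mb for r in results for s in r.segments if s.state == "loss"]
    )
    gain_sizes = np.array(
        [s.size_mb for r in results for s in r.segments if s.state == "gain"]
    )
    mean_gains = float(np.mean(n_gains))
    ratio = float(np.mean(n_losses) / mean_gains) if mean_gains > 0 else float("nan")
    return StratumStats(
        n_cases=len(results),
        mean_n_cnas=float(np.mean(n_cnas)),
        sd_n_cnas=_sd(n_cnas),
        mean_n_losses=float(np.mean(n_losses)),
        sd_n_losses=_sd(n_losses),
        mean_n_gains=float(np.mean(n_gains)),
        sd_n_gains=_sd(n_gains),
        loss_gain_ratio=ratio,
        mean_size_loss_mb=float(np.mean(loss_sizes)) if len(loss_sizes) else float("nan"),
        sd_size_loss_mb=_sd(loss_sizes) if len(loss_sizes) else float("nan"),
        mean_size_gain_mb=float(np.mean(gain_sizes)) if len(gain_sizes) else float("nan"),
        sd_size_gain_mb=_sd(gain_sizes) if len(gain_sizes) else float("nan"),
    )


def summarize_cohort(results: list[CaseCallResult], meta) -> dict[str, StratumStats]:
    """Per-breed and combined count/size summaries over aberrant cases."""
    breed_of = {m.case_id: m.breed for m in meta}
    aberrant = [r for r in results if r.aberrant]
    if not aberrant:
        raise ValueError("no aberrant cases to summarize")
    out: dict[str, StratumStats] = {}
    for breed in ("BMD", "FCR"):
        sub = [r for r in aberrant if breed_of.get(r.case_id) == breed]
        if not sub:
            warnings.warn(f"no aberrant {breed} cases; stratum omitted", stacklevel=2)
            continue
        out[breed] = _stratum_stats(sub)
    out["combined"] = _stratum_stats(aberrant)
    return out


def size_histogram(segments: Sequence[Segment], bin_edges_mb) -> dict[str, np.ndarray]:
    """Per-state segment-size counts in left-closed right-open bins."""
    edges = np.asarray(bin_edges_mb, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing with >= 2 values")
    out = {}
    for state in ("gain", "loss"):
        sizes = np.array([s.size_mb for s in segments if s.state == state])
        counts = np.zeros(len(edges) - 1, dtype=int)
        if len(sizes):
            # [e_i, e_{i+1}) for every bin, including the last
            which = np.searchsorted(edges, sizes, side="right") - 1
            valid = (which >= 0) & (which < len(counts)) & (sizes < edges[-1])
            for b in which[valid]:
                counts[b] += 1
        out[state] = counts
    return out
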