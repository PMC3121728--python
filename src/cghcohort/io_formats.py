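"""Tabular I/O, configuration and shared domain types.

All pipeline tables are plain TSV.  Readers canonicalize row order so that
shuffled inputs produce identical in-memory objects; writers use fixed float
formatting so write-then-read round-trips are exact to 6 decimals.

Coordinates are megabases (Mb), 0-based, with half-open intervals
``[start_mb, end_mb)`` throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AUTOSOMES",
    "CHROMOSOMES",
    "MISSING",
    "FormatError",
    "CloneMap",
    "RatioTable",
    "CaseMeta",
    "Config",
    "chrom_sort_key",
    "default_chrom_lengths",
    "read_clone_map",
    "write_clone_map",
    "read_ratio_table",
    "write_ratio_table",
    "read_case_meta",
    "write_case_meta",
    "read_peak_table",
    "write_peak_table",
    "read_regions",
    "write_regions_table",
    "load_config",
    "write_run_log",
    "write_segments",
    "read_segments",
]

AUTOSOMES = tuple(f"CFA{i}" for i in range(1, 39))
CHROMOSOMES = AUTOSOMES + ("CFAX",)
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

#: literal used to mark missing log2 ratios in TSV tables
MISSING = "NA"

BREEDS = ("BMD", "FCR")
GEOGRAPHIES = ("USA", "France")
SEXES = ("M", "F", "unknown")
TUMOR_LOCATIONS = (
    "one_internal_organ",
    "multiple_internal_organs",
    "lymph_node_only",
    "limb_only",
    "skin_only",
    "unknown",
)

PEAK_COLUMNS = [
    "case_id",
    "marker_id",
    "sample_type",
    "allele1_size",
    "allele1_area",
    "allele2_size",
    "allele2_area",
]


class FormatError(ValueError):
    """Raised when an input table violates its format contract."""


def chrom_sort_key(chrom: str) -> int:
    """Canonical rank of a chromosome label (CFA1..CFA38, CFAX)."""
    try:
        return _CHROM_RANK[chrom]
    except KeyError:
        raise FormatError(f"unknown chromosome label: {chrom!r}") from None


def default_chrom_lengths() -> dict[str, float]:
    """Approximate per-chromosome lengths (Mb) shipped with the package."""
    with resources.files("cghcohort.data").joinpath("chrom_lengths.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["chrom"], df["length_mb"].astype(float)))


# ---------------------------------------------------------------------------
# CloneMap
# ---------------------------------------------------------------------------


@dataclass
class CloneMap:
    """Ordered probe grid: one clone per ~1 Mb position on each chromosome.

    Entries are canonically sorted by (chromosome rank, position); positions
    are strictly increasing within a chromosome and clone ids are unique.
    """

    clone_ids: list[str]
    chroms: np.ndarray
    pos_mb: np.ndarray
    chrom_lengths: dict[str, float] = field(default_factory=default_chrom_lengths)

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.pos_mb = np.asarray(self.pos_mb, dtype=float)
        if not (len(self.clone_ids) == len(self.chroms) == len(self.pos_mb)):
            raise FormatError("clone map fields have inconsistent lengths")
        seen: dict[str, int] = {}
        for cid in self.clone_ids:
            seen[cid] = seen.get(cid, 0) + 1
        dups = sorted(k for k, v in seen.items() if v > 1)
        if dups:
            raise FormatError(f"duplicate clone_id in map: {', '.join(dups)}")
        for c in set(self.chroms.tolist()):
            chrom_sort_key(c)  # validates label
        # strictly increasing positions within each chromosome
        for chrom, idx in self._chrom_slices().items():
            p = self.pos_mb[idx]
            if np.any(np.diff(p) <= 0):
                raise FormatError(f"positions not strictly increasing on {chrom}")
            if np.any(p < 0):
                raise FormatError(f"negative position on {chrom}")
            limit = self.chrom_lengths.get(chrom)
            if limit is not None and np.any(p > limit):
                raise FormatError(f"clone position beyond {chrom} length {limit} Mb")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, float]],
        chrom_lengths: dict[str, float] | None = None,
    ) -> "CloneMap":
        rows = list(records)
        for _, chrom, _ in rows:
            chrom_sort_key(chrom)
        rows.sort(key=lambda r: (chrom_sort_key(r[1]), float(r[2])))
        kwargs = {}
        if chrom_lengths is not None:
            kwargs["chrom_lengths"] = chrom_lengths
        return cls(
            clone_ids=[r[0] for r in rows],
            chroms=np.array([r[1] for r in rows], dtype=object),
            pos_mb=np.array([float(r[2]) for r in rows]),
            **kwargs,
        )

    def _chrom_slices(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for chrom in self.chromosomes():
            out[chrom] = np.flatnonzero(self.chroms == chrom)
        return out

    def chromosomes(self) -> list[str]:
        uniq = sorted(set(self.chroms.tolist()), key=chrom_sort_key)
        return uniq

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chroms == chrom)

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_clones

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CloneMap):
            return NotImplemented
        return (
            self.clone_ids == other.clone_ids
            and list(self.chroms) == list(other.chroms)
            and np.allclose(self.pos_mb, other.pos_mb, atol=1e-6)
        )


def read_clone_map(path: str | Path, chrom_lengths: dict[str, float] | None = None) -> CloneMap:
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "chrom": str})
    required = {"clone_id", "chrom", "pos_mb"}
    if not required.issubset(df.columns):
        raise FormatError(f"clone map must have columns {sorted(required)}")
    return CloneMap.from_records(
        zip(df["clone_id"], df["chrom"], df["pos_mb"].astype(float)),
        chrom_lengths=chrom_lengths,
    )


def write_clone_map(clone_map: CloneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\tchrom\tpos_mb\n")
        for cid, chrom, pos in zip(clone_map.clone_ids, clone_map.chroms, clone_map.pos_mb):
            fh.write(f"{cid}\t{chrom}\t{pos:.6f}\n")


# ---------------------------------------------------------------------------
# RatioTable
# ---------------------------------------------------------------------------


@dataclass
class RatioTable:
    """log2 tumor:reference ratios, clones x cases, aligned to a CloneMap."""

    clone_ids: list[str]
    case_ids: list[str]
    values: np.ndarray  # shape (n_clones, n_cases); NaN marks missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.clone_ids), len(self.case_ids)):
            raise FormatError("ratio table shape does not match clone/case ids")
        if np.any(np.isinf(self.values)):
            raise FormatError("ratio table contains non-finite values")
        all_missing = np.all(np.isnan(self.values), axis=0)
        if np.any(all_missing):
            bad = [c for c, m in zip(self.case_ids, all_missing) if m]
            raise FormatError(f"case column entirely missing: {', '.join(bad)}")

    def case_index(self, case_id: str) -> int:
        return self.case_ids.index(case_id)


def read_ratio_table(path: str | Path, clone_map: CloneMap) -> RatioTable:
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    if "clone_id" not in df.columns:
        raise FormatError("ratio table must have a clone_id first column")
    unknown = sorted(set(df["clone_id"]) - set(clone_map.clone_ids))
    if unknown:
        raise FormatError(f"clones absent from map: {', '.join(unknown)}")
    case_ids = [c for c in df.columns if c != "clone_id"]
    df = df.set_index("clone_id")
    for col in case_ids:
        raw = df[col]
        numeric = pd.to_numeric(raw.replace(MISSING, np.nan), errors="coerce")
        bad = raw[numeric.isna() & raw.notna() & (raw.astype(str) != MISSING)]
        if len(bad):
            raise FormatError(
                f"non-numeric cell in case {col!r}: {bad.iloc[0]!r} (use {MISSING} for missing)"
            )
        df[col] = numeric
    missing_clones = [c for c in clone_map.clone_ids if c not in df.index]
    if missing_clones:
        warnings.warn(
            f"{len(missing_clones)} map clones absent from ratio table; filled as missing",
            stacklevel=2,
        )
    aligned = df.reindex(clone_map.clone_ids)
    return RatioTable(
        clone_ids=list(clone_map.clone_ids),
        case_ids=case_ids,
        values=aligned[case_ids].to_numpy(dtype=float),
    )


def write_ratio_table(table: RatioTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\t" + "\t".join(table.case_ids) + "\n")
        for i, cid in enumerate(table.clone_ids):
            cells = [
                MISSING if math.isnan(v) else f"{v:.6f}" for v in table.values[i]
            ]
            fh.write(cid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Case metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseMeta:
    case_id: str
    breed: str
    geography: str
    sex: str = "unknown"
    age_years: float | None = None
    tumor_location: str = "unknown"

    def __post_init__(self) -> None:
        if self.breed not in BREEDS:
            raise FormatError(f"unknown breed {self.breed!r} for case {self.case_id}")
        if self.geography not in GEOGRAPHIES:
            raise FormatError(f"unknown geography {self.geography!r}")
        if self.sex not in SEXES:
            raise FormatError(f"unknown sex {self.sex!r}")
        if self.tumor_location not in TUMOR_LOCATIONS:
            raise FormatError(f"unknown tumor_location {self.tumor_location!r}")
        if self.age_years is not None and not self.age_years > 0:
            raise FormatError(f"age must be positive for case {self.case_id}")


def read_case_meta(path: str | Path) -> list[CaseMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        age = row.get("age_years")
        age_val = None if age in (None, "", MISSING, "unknown") or pd.isna(age) else float(age)
        out.append(
            CaseMeta(
                case_id=row["case_id"],
                breed=row["breed"],
                geography=row["geography"],
                sex=row.get("sex", "unknown"),
                age_years=age_val,
                tumor_location=row.get("tumor_location", "unknown"),
            )
        )
    out.sort(key=lambda m: m.case_id)
    return out


def write_case_meta(meta: Sequence[CaseMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("case_id\tbreed\tgeography\tsex\tage_years\ttumor_location\n")
        for m in sorted(meta, key=lambda m: m.case_id):
            age = MISSING if m.age_years is None else f"{m.age_years:.1f}"
            fh.write(
                f"{m.case_id}\t{m.breed}\t{m.geography}\t{m.sex}\t{age}\t{m.tumor_location}\n"
            )


# ---------------------------------------------------------------------------
# Microsatellite peak tables
# ---------------------------------------------------------------------------


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a peak-area table, canonicalizing allele order (shorter first)."""
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "marker_id": str, "sample_type": str})
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peak table missing columns: {missing}")
    df = df[PEAK_COLUMNS].copy()
    bad_type = set(df["sample_type"]) - {"tumor", "blood"}
    if bad_type:
        raise FormatError(f"unknown sample_type values: {sorted(bad_type)}")
    for col in ("allele1_size", "allele1_area", "allele2_size", "allele2_area"):
        df[col] = pd.to_numeric(df[col])
    if (df[["allele1_area", "allele2_area"]] < 0).any().any():
        raise FormatError("negative peak area")
    swap = df["allele1_size"] > df["allele2_size"]
    if swap.any():
        a = df.loc[swap, ["allele2_size", "allele2_area", "allele1_size", "allele1_area"]].to_numpy()
        df.loc[swap, ["allele1_size", "allele1_area", "allele2_size", "allele2_area"]] = a
    dup = df.duplicated(subset=["case_id", "marker_id", "sample_type"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["case_id", "marker_id"]].iloc[0]
        raise FormatError(
            f"duplicate {df.loc[dup, 'sample_type'].iloc[0]} row for "
            f"({pair['case_id']}, {pair['marker_id']})"
        )
    return df.sort_values(["case_id", "marker_id", "sample_type"]).reset_index(drop=True)


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[PEAK_COLUMNS].sort_values(["case_id", "marker_id", "sample_type"])
    with open(path, "w") as fh:
        fh.write("\t".join(PEAK_COLUMNS) + "\n")
        for _, r in out.iterrows():
            fh.write(
                f"{r['case_id']}\t{r['marker_id']}\t{r['sample_type']}\t"
                f"{r['allele1_size']:.1f}\t{r['allele1_area']:.4f}\t"
                f"{r['allele2_size']:.1f}\t{r['allele2_area']:.4f}\n"
            )


# ---------------------------------------------------------------------------
# Region tables (BED-style)
# ---------------------------------------------------------------------------


def read_regions(path: str | Path) -> list[tuple[str, float, float, str]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "state": str})
    required = {"chrom", "start_mb", "end_mb", "state"}
    if not required.issubset(df.columns):
        raise FormatError(f"region file must have columns {sorted(required)}")
    out = []
    for _, r in df.iterrows():
        chrom_sort_key(r["chrom"])
        if r["state"] not in ("gain", "loss"):
            raise FormatError(f"unknown region state {r['state']!r}")
        out.append((r["chrom"], float(r["start_mb"]), float(r["end_mb"]), r["state"]))
    out.sort(key=lambda t: (chrom_sort_key(t[0]), t[1], t[2]))
    return out


def write_regions_table(regions: Sequence[tuple[str, float, float, str]], path: str | Path) -> None:
    rows = sorted(regions, key=lambda t: (chrom_sort_key(t[0]), t[1], t[2]))
    with open(path, "w") as fh:
        fh.write("chrom\tstart_mb\tend_mb\tstate\n")
        for chrom, s, e, state in rows:
            fh.write(f"{chrom}\t{s:.6f}\t{e:.6f}\t{state}\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class Config:
    """Analysis thresholds and run parameters.

    Ratio thresholds are expressed on the linear tumor:reference scale
    (1.15:1 gain, 0.85:1 loss) and applied on the log2 scale via
    :attr:`gain_cut` / :attr:`loss_cut`.
    """

    gain_ratio: float = 1.15
    loss_ratio: float = 0.85
    homozygous_log2_cut: float = -1.0
    recurrent_frac: float = 0.30
    highly_recurrent_frac: float = 0.50
    ai_upper: float = 1.5
    ai_lower: float = 0.67
    fwer_alpha: float = 0.05
    n_permutations: int = 10000
    smoothing_window: int = 5
    min_segment_clones: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.loss_ratio < 1 < self.gain_ratio):
            raise ValueError("require 0 < loss_ratio < 1 < gain_ratio")
        if not (self.ai_lower < 1 < self.ai_upper):
            raise ValueError("require ai_lower < 1 < ai_upper")
        if not (0 < self.recurrent_frac <= self.highly_recurrent_frac):
            raise ValueError("require 0 < recurrent_frac <= highly_recurrent_frac")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.min_segment_clones < 1:
            raise ValueError("min_segment_clones must be >= 1")
        if not (0 < self.fwer_alpha < 1):
            raise ValueError("fwer_alpha must lie in (0, 1)")

    @property
    def gain_cut(self) -> float:
        return math.log2(self.gain_ratio)

    @property
    def loss_cut(self) -> float:
        return math.log2(self.loss_ratio)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Build a Config from an optional YAML file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(Config)}
        unknown = set(loaded) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update(overrides)
    return Config(**values)


def write_run_log(path: str | Path, config: Config, **extra) -> None:
    """Record the fully-resolved configuration (plus stage notes) as YAML."""
    payload = {"config": config.to_dict()}
    payload.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Segment I/O (Segment type lives in cna_calling; imported lazily to keep
# module dependencies one-directional elsewhere)
# ---------------------------------------------------------------------------

SEG_COLUMNS = [
    "case_id",
    "chrom",
    "start_mb",
    "end_mb",
    "state",
    "mean_log2",
    "homozygous_flag",
    "n_clones",
]


def write_segments(segments, path: str | Path) -> None:
    """Write segments as a SEG-style TSV in canonical (case, chrom, pos) order."""
    rows = sorted(
        segments, key=lambda s: (s.case_id, chrom_sort_key(s.chrom), s.start_mb)
    )
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for s in rows:
            fh.write(
                f"{s.case_id}\t{s.chrom}\t{s.start_mb:.6f}\t{s.end_mb:.6f}\t{s.state}\t"
                f"{s.mean_log2:.6f}\t{int(s.homozygous_flag)}\t{s.n_clones}\n"
            )


def read_segments(path: str | Path):
    from .cna_calling import Segment

    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "chrom": str, "state": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"segment file missing columns: {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            Segment(
                case_id=r["case_id"],
                chrom=r["chrom"],
                start_mb=float(r["start_mb"]),
                end_mb=float(r["end_mb"]),
                state=r["state"],
                mean_log2=float(r["mean_log2"]),
                n_clones=int(r["n_clones"]),
                homozygous_flag=bool(int(r["homozygous_flag"])),
            )
        )
    out.sort(key=lambda s: (s.case_id, chrom_sort_key(s.chrom), s.start_mb))
    return out
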