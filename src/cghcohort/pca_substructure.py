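"""PCA of the case x 1-Mb-interval aberration-state matrix and
component-vs-covariate association tests.

States are encoded -1 (loss), 0 (neutral), +1 (gain) per grid cell; columns
are centered but not scaled (they share a common scale by construction).
Component signs are canonicalized so the largest-magnitude loading of each
component is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .association import mann_whitney_u
from .cna_calling import CaseCallResult
from .io_formats import CloneMap

__all__ = [
    "StateMatrix",
    "PCAResult",
    "build_state_matrix",
    "run_pca",
    "component_association",
    "write_scree",
    "write_scores",
]


@dataclass
class StateMatrix:
    case_ids: list[str]
    chroms: np.ndarray  # per-interval chromosome
    start_mb: np.ndarray  # per-interval cell start
    values: np.ndarray  # cases x intervals, entries in {-1, 0, +1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.case_ids), len(self.start_mb)):
            raise ValueError("state matrix shape mismatch")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("state entries must be -1, 0 or +1")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # all components, non-increasing
    scores: np.ndarray  # cases x retained components
    loadings: np.ndarray  # retained components x intervals
    n_components_retained: int


def build_state_matrix(
    results: Sequence[CaseCallResult],
    clone_map: CloneMap,
    include_x: bool = False,
) -> StateMatrix:
    """Code each aberrant case's called segments onto the 1-Mb grid."""
    aberrant = [r for r in results if r.aberrant]
    keep = np.array([include_x or c != "CFAX" for c in clone_map.chroms], dtype=bool)
    chroms = clone_map.chroms[keep]
    starts = clone_map.pos_mb[keep]
    cell_index = {
        chrom: np.flatnonzero(chroms == chrom) for chrom in set(chroms.tolist())
    }
    values = np.zeros((len(aberrant), len(starts)), dtype=np.int8)
    for i, res in enumerate(aberrant):
        for seg in res.segments:
            idx = cell_index.get(seg.chrom)
            if idx is None:
                continue
            pos = starts[idx]
            hit = idx[(pos < seg.end_mb) & (pos + 1.0 > seg.start_mb)]
            values[i, hit] = 1 if seg.state == "gain" else -1
    return StateMatrix(
        case_ids=[r.case_id for r in aberrant],
        chroms=chroms,
        start_mb=starts,
        values=values,
    )


def run_pca(matrix: StateMatrix, n_components: int = 10) -> PCAResult:
    """Centered (unscaled) PCA by SVD; eigenvalues are s^2 / (n - 1)."""
    X = matrix.values.astype(float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 cases and 2 intervals")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    k = min(n_components, len(s))
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        k = min(k, max(rank, 1))
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k]
    # canonical signs: largest-magnitude loading of each component positive
    for j in range(k):
        lead = np.argmax(np.abs(loadings[j]))
        if loadings[j, lead] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0
    return PCAResult(
        eigenvalues=eigenvalues,
        scores=scores,
        loadings=loadings,
        n_components_retained=k,
    )


def component_association(
    scores: np.ndarray,
    grouping: Sequence,
    components: Sequence[int],
) -> dict[int, float]:
    """Mann-Whitney p-value per component score vector between two groups.

    ``components`` are 1-based component indices (component 1 = top).
    """
    labels = np.asarray(list(grouping), dtype=object)
    if len(labels) != scores.shape[0]:
        raise ValueError("grouping length does not match number of cases")
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValueError(f"grouping must have exactly two levels, got {levels}")
    mask = labels == levels[0]
    out: dict[int, float] = {}
    for comp in components:
        if not (1 <= comp <= scores.shape[1]):
            raise ValueError(f"component {comp} not retained")
        col = scores[:, comp - 1]
        _, p = mann_whitney_u(col[mask], col[~mask])
        out[comp] = p
    return out


def write_scree(result: PCAResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("component\teigenvalue\n")
        for i, ev in enumerate(result.eigenvalues, start=1):
            fh.write(f"{i}\t{ev:.6f}\n")


def write_scores(result: PCAResult, case_ids: Sequence[str], path: str | Path) -> None:
    k = result.n_components_retained
    with open(path, "w") as fh:
        fh.write("case_id\t" + "\t".join(f"PC{i}" for i in range(1, k + 1)) + "\n")
        for i, cid in enumerate(case_ids):
            row = "\t".join(f"{result.scores[i, j]:.6f}" for j in range(k))
            fh.write(f"{cid}\t{row}\n")
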