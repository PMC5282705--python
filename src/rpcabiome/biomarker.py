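"""Scoring and ranking taxa from the recovered sparse component.

After PCP splits the abundance matrix into low-rank background plus sparse
perturbation ``S``, each taxon is scored by the row-wise sum of absolute
values of ``S`` (entries may be positive or negative — activation or
suppression — so magnitudes are summed), and the ``m`` highest-scoring taxa
are reported as candidate biomarkers. Selection is fully unsupervised: class
labels enter only the optional direction annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import AbundanceMatrix, LabelVector
from .rpca import PCPSolution, SolverConfig, solve_pcp

__all__ = [
    "ScoreVector",
    "BiomarkerSet",
    "compute_scores",
    "select_top",
    "annotate_direction",
    "detect_biomarkers",
]

UP_IN_POSITIVE = "up_in_positive"
UP_IN_NEGATIVE = "up_in_negative"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class ScoreVector:
    """Per-taxon nonnegative differential-abundance scores."""

    scores: np.ndarray
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "taxon_ids", tuple(self.taxon_ids))
        if scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if len(self.taxon_ids) != scores.shape[0]:
            raise ValueError(
                f"{len(self.taxon_ids)} taxon ids for {scores.shape[0]} scores"
            )
        if np.any(scores < 0):
            raise ValueError("scores must be nonnegative")


@dataclass(frozen=True)
class BiomarkerSet:
    """Ordered top-``m`` taxa (descending score) with optional directions."""

    members: tuple[str, ...]
    scores: tuple[float, ...]
    directions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        if len(set(self.members)) != len(self.members):
            raise ValueError("biomarker members must be distinct")
        if len(self.scores) != len(self.members):
            raise ValueError("scores and members length mismatch")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing along the ranking")
        if self.directions is not None:
            directions = tuple(self.directions)
            object.__setattr__(self, "directions", directions)
            if len(directions) != len(self.members):
                raise ValueError("directions and members length mismatch")

    @property
    def m(self) -> int:
        return len(self.members)


def compute_scores(S: np.ndarray, taxon_ids) -> ScoreVector:
    """Score taxon ``i`` as ``sum_j |S[i, j]|`` over all samples."""
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite entries in S")
    taxon_ids = tuple(taxon_ids)
    if S.ndim != 2 or S.shape[0] != len(taxon_ids):
        raise ValueError(
            f"S has {S.shape[0] if S.ndim == 2 else '?'} rows for "
            f"{len(taxon_ids)} taxon ids"
        )
    return ScoreVector(np.abs(S).sum(axis=1), taxon_ids)


def select_top(v: ScoreVector, m: int) -> BiomarkerSet:
    """The ``m`` taxa with the largest scores, ties broken by input order."""
    p = len(v.taxon_ids)
    if not 1 <= m <= p:
        raise ValueError(f"m must be in [1, {p}], got {m}")
    # stable sort on -score keeps earlier input rows first among ties
    order = np.argsort(-v.scores, kind="stable")[:m]
    return BiomarkerSet(
        members=tuple(v.taxon_ids[i] for i in order),
        scores=tuple(v.scores[i] for i in order),
    )


def annotate_direction(
    D: AbundanceMatrix, labels: LabelVector, marker_set: BiomarkerSet
) -> BiomarkerSet:
    """Annotate each marker with the class in which its mean abundance is higher.

    Uses class means of the original abundance matrix: a marker is
    ``up_in_positive`` when its mean abundance across positive-class samples
    exceeds its mean across negative-class samples, ``up_in_negative`` when
    lower, and ``undetermined`` on exact equality.
    """
    if len(labels) != D.n_samples:
        raise ValueError(
            f"{len(labels)} labels for {D.n_samples} samples"
        )
    lab = np.asarray(labels.labels)
    pos = lab == labels.positive_class
    neg = ~pos
    row_of = {t: i for i, t in enumerate(D.taxon_ids)}
    directions = []
    for taxon in marker_set.members:
        try:
            row = D.values[row_of[taxon], :]
        except KeyError:
            raise KeyError(f"marker {taxon!r} not present in abundance matrix")
        mean_pos = row[pos].mean()
        mean_neg = row[neg].mean()
        if mean_pos > mean_neg:
            directions.append(UP_IN_POSITIVE)
        elif mean_pos < mean_neg:
            directions.append(UP_IN_NEGATIVE)
        else:
            directions.append(UNDETERMINED)
    return replace(marker_set, directions=tuple(directions))


def detect_biomarkers(
    D: AbundanceMatrix, m: int, config: SolverConfig | None = None
) -> tuple[BiomarkerSet, ScoreVector, PCPSolution]:
    """Full unsupervised pipeline: PCP decomposition, scoring, top-``m`` pick.

    Returns the ranked marker set together with the full score vector and the
    solver diagnostics so callers can judge score magnitudes and convergence.
    Labels play no role here.
    """
    solution = solve_pcp(D.values, config)
    scores = compute_scores(solution.S, D.taxon_ids)
    return select_top(scores, m), scores, solution
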