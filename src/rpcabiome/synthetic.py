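"""Synthetic abundance matrices with planted differential taxa.

Emulates the generative model the decomposition assumes: a low-rank
background of shared community structure plus a sparse perturbation confined
to a few marker taxa whose abundance shifts in one phenotype. Ground truth
(the background ``L0``, the perturbation ``S0`` and the marker identities)
is stored so recovery and recall can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .biomarker import BiomarkerSet
from .io import AbundanceMatrix, LabelVector

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "planted_recall"]

POSITIVE_LABEL = "case"
NEGATIVE_LABEL = "control"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-phenotype study.

    ``effect`` is the mean abundance shift added to each planted marker row
    in positive-class columns, in relative-abundance units (columns of the
    background sum to 1, so an effect of 0.02 is ~6x the mean background
    entry at p = 300). The realized shift varies per sample, uniform on
    [0.5, 1.5] x effect: differential abundance in real studies varies
    across subjects, and a perfectly constant shift would form a rank-1
    block that the decomposition would classify as background rather than
    as a sparse perturbation. ``nonneg`` clips negative entries and
    renormalizes columns, trading exact ground-truth algebra for valid
    compositions.
    """

    p: int = 300
    N_pos: int = 40
    N_neg: int = 40
    rank: int = 3
    n_markers: int = 20
    effect: float = 0.02
    noise_sd: float = 0.0
    seed: int = 7
    nonneg: bool = False
    mixed_signs: bool = False

    def __post_init__(self) -> None:
        N = self.N_pos + self.N_neg
        if self.p < 1 or self.N_pos < 2 or self.N_neg < 2:
            raise ValueError(
                f"need p >= 1 and at least 2 samples per class, got "
                f"p={self.p}, N_pos={self.N_pos}, N_neg={self.N_neg}"
            )
        if not 0 <= self.n_markers <= self.p:
            raise ValueError(f"n_markers must be in [0, p], got {self.n_markers}")
        if not 1 <= self.rank <= min(self.p, N):
            raise ValueError(f"rank must be in [1, min(p, N)], got {self.rank}")
        if self.n_markers > 0 and not self.effect > 0:
            raise ValueError(f"effect must be positive, got {self.effect}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated study with its ground truth."""

    matrix: AbundanceMatrix
    labels: LabelVector
    true_markers: frozenset[str]
    true_directions: dict[str, int] = field(default_factory=dict)
    L0: np.ndarray = field(default=None, repr=False)
    S0: np.ndarray = field(default=None, repr=False)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from ``spec``, fully reproducible from ``spec.seed``.

    The background is ``|A @ B.T|`` with standard-normal factors, columns
    scaled to sum to 1. The sparse part adds a per-sample shift of mean
    ``effect`` (sign drawn per marker when ``mixed_signs``) to ``n_markers``
    uniformly chosen rows, in positive-class columns only.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.N_pos + spec.N_neg

    A = rng.standard_normal((spec.p, spec.rank))
    B = rng.standard_normal((N, spec.rank))
    L0 = np.abs(A @ B.T)
    col_sums = L0.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    L0 = L0 / col_sums

    labels = (POSITIVE_LABEL,) * spec.N_pos + (NEGATIVE_LABEL,) * spec.N_neg
    pos_cols = np.arange(spec.N_pos)

    S0 = np.zeros((spec.p, N))
    marker_rows = np.sort(rng.choice(spec.p, size=spec.n_markers, replace=False))
    directions: dict[str, int] = {}
    taxon_ids = tuple(f"taxon_{i:04d}" for i in range(spec.p))
    for row in marker_rows:
        sign = int(rng.choice([-1, 1])) if spec.mixed_signs else 1
        S0[row, pos_cols] = (
            sign * spec.effect * rng.uniform(0.5, 1.5, size=spec.N_pos)
        )
        directions[taxon_ids[row]] = sign

    D = L0 + S0
    if spec.noise_sd > 0:
        D = D + rng.normal(0.0, spec.noise_sd, size=D.shape)
    if spec.nonneg:
        D = np.clip(D, 0.0, None)
        sums = D.sum(axis=0)
        sums[sums == 0] = 1.0
        D = D / sums
    else:
        # tiny negative values can appear via mixed signs or noise
        D = np.clip(D, 0.0, None)

    sample_ids = tuple(
        f"{'pos' if i < spec.N_pos else 'neg'}_{i:03d}" for i in range(N)
    )
    matrix = AbundanceMatrix(D, taxon_ids, sample_ids)
    label_vec = LabelVector(labels, positive_class=POSITIVE_LABEL)
    return SyntheticDataset(
        matrix=matrix,
        labels=label_vec,
        true_markers=frozenset(taxon_ids[i] for i in marker_rows),
        true_directions=directions,
        L0=L0,
        S0=S0,
    )


def planted_recall(marker_set: BiomarkerSet | frozenset | set, truth) -> float:
    """Fraction of planted markers recovered: ``|selected ∩ truth| / |truth|``."""
    truth = set(truth)
    if not truth:
        raise ValueError("truth set is empty")
    members = (
        set(marker_set.members)
        if isinstance(marker_set, BiomarkerSet)
        else set(marker_set)
    )
    return len(members & truth) / len(truth)
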