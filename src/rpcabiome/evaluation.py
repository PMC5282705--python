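"""Consistency-classification evaluation of biomarker selectors.

The protocol subsamples the study ``K`` times without replacement at train
fraction ``r``, runs the selector on each training subset only, and reports

* stability — the average pairwise Kuncheva index over the ``K(K-1)/2``
  pairs of selected marker sets, and
* predictive value — accuracy / sensitivity / specificity of a nearest
  centroid classifier trained on the train columns restricted to each
  subset's own markers and evaluated on the held-out columns.

A selector is any callable ``selector(train_matrix, rng) -> ranked taxa``
returning taxon ids in descending priority; the protocol slices the top-m
prefix for every requested marker-set size, so expensive selectors run once
per training subset rather than once per (subset, size) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .biomarker import compute_scores, select_top
from .io import AbundanceMatrix, LabelVector
from .rpca import SolverConfig, solve_pcp

__all__ = [
    "SubsampleSplit",
    "ConfusionCounts",
    "ClassifierSummary",
    "ProtocolReport",
    "generate_subsamples",
    "kuncheva_index",
    "average_consistency",
    "ncc_fit",
    "ncc_predict",
    "classification_metrics",
    "run_protocol",
    "ki_histogram",
    "rpca_selector",
    "random_selector",
    "constant_selector",
]

Selector = Callable[[AbundanceMatrix, np.random.Generator], Sequence[str]]


@dataclass(frozen=True)
class SubsampleSplit:
    """One train/test partition of sample indices (replicate ``k``)."""

    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    replicate: int

    def __post_init__(self) -> None:
        train, test = set(self.train_idx), set(self.test_idx)
        if train & test:
            raise ValueError("train and test indices overlap")
        if len(train) != len(self.train_idx) or len(test) != len(self.test_idx):
            raise ValueError("duplicate indices within a split")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for one evaluated test set."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ClassifierSummary:
    """Across-replicate means and SDs for one nearest-centroid variant.

    Replicates where a metric is undefined (no test sample of the relevant
    class) are excluded from that metric's mean/SD; ``n_*`` counts the
    replicates that contributed.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_sd: float
    sensitivity_sd: float
    specificity_sd: float
    n_accuracy: int
    n_sensitivity: int
    n_specificity: int


@dataclass(frozen=True)
class ProtocolReport:
    """Consistency and classification summary for one marker-set size."""

    n_markers: int
    C_avg: float
    ki_values: tuple[float, ...]
    classifiers: dict[str, ClassifierSummary]
    K: int
    r: float
    seed: int

    def __post_init__(self) -> None:
        expected = self.K * (self.K - 1) // 2
        if len(self.ki_values) != expected:
            raise ValueError(
                f"{len(self.ki_values)} pairwise KIs for K={self.K}; "
                f"expected {expected}"
            )
        if not math.isclose(
            self.C_avg, float(np.mean(self.ki_values)), abs_tol=1e-12
        ):
            raise ValueError("C_avg does not equal the mean of ki_values")


def _child_rng(seed: int, k: int) -> np.random.Generator:
    # replicate k is reproducible in isolation from (master seed, k)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))


def generate_subsamples(
    N: int,
    r: float,
    K: int,
    seed: int,
    stratify_labels: LabelVector | None = None,
) -> list[SubsampleSplit]:
    """Draw ``K`` train/test splits with ``ceil(r*N)`` training samples each.

    Sampling is without replacement inside each split. When
    ``stratify_labels`` is given, per-class training counts start at
    ``ceil(r * N_c)`` and are trimmed (largest class first) so the total
    equals ``ceil(r*N)``; this keeps both classes represented at small N.
    """
    if not 0 < r < 1:
        raise ValueError(f"r must be in (0, 1), got {r}")
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    n_train = math.ceil(r * N)
    if n_train >= N:
        raise ValueError(
            f"ceil(r*N) = {n_train} leaves no test samples for N = {N}"
        )
    if stratify_labels is not None and len(stratify_labels) != N:
        raise ValueError(
            f"{len(stratify_labels)} labels for N = {N} samples"
        )

    per_class: list[tuple[np.ndarray, int]] = []
    if stratify_labels is not None:
        lab = np.asarray(stratify_labels.labels)
        classes = sorted(set(lab))
        counts = {c: math.ceil(r * int((lab == c).sum())) for c in classes}
        # trim from the largest class until totals match ceil(r*N)
        while sum(counts.values()) > n_train:
            c = max(classes, key=lambda c: counts[c])
            counts[c] -= 1
        while sum(counts.values()) < n_train:
            c = min(
                classes,
                key=lambda c: counts[c] / max(int((lab == c).sum()), 1),
            )
            counts[c] += 1
        per_class = [(np.where(lab == c)[0], counts[c]) for c in classes]

    splits = []
    for k in range(K):
        rng = _child_rng(seed, k)
        if stratify_labels is None:
            train = np.sort(rng.choice(N, size=n_train, replace=False))
        else:
            chosen = [
                rng.choice(idx, size=size, replace=False)
                for idx, size in per_class
            ]
            train = np.sort(np.concatenate(chosen))
        mask = np.zeros(N, dtype=bool)
        mask[train] = True
        test = np.where(~mask)[0]
        splits.append(
            SubsampleSplit(tuple(int(i) for i in train), tuple(int(i) for i in test), k)
        )
    return splits


def kuncheva_index(F_i, F_j, p: int) -> float:
    """Chance-corrected overlap of two equal-size feature sets.

    ``(|F_i ∩ F_j| - T^2/p) / (T - T^2/p)`` with ``T = |F_i| = |F_j|``:
    1 for identical sets, 0 in expectation for independent uniformly random
    sets, and as low as -1 (attained by disjoint sets when ``T = p/2``).
    """
    F_i, F_j = set(F_i), set(F_j)
    T = len(F_i)
    if len(F_j) != T:
        raise ValueError(
            f"sets must have equal size, got {T} and {len(F_j)}"
        )
    if T == 0 or T >= p:
        raise ValueError(
            f"set size T = {T} must satisfy 0 < T < p = {p}"
        )
    correction = T * T / p
    return (len(F_i & F_j) - correction) / (T - correction)


def average_consistency(sets: Sequence, p: int) -> tuple[float, list[float]]:
    """Mean pairwise Kuncheva index over all ``K(K-1)/2`` pairs of sets."""
    K = len(sets)
    if K < 2:
        raise ValueError(f"need at least 2 sets, got {K}")
    sets = [frozenset(s) for s in sets]
    sizes = {len(s) for s in sets}
    if len(sizes) != 1:
        raise ValueError(f"all sets must have the same size, got sizes {sorted(sizes)}")
    ki_values = [
        kuncheva_index(sets[i], sets[j], p)
        for i in range(K)
        for j in range(i + 1, K)
    ]
    return float(np.mean(ki_values)), ki_values


def _as_labels(labels) -> np.ndarray:
    if isinstance(labels, LabelVector):
        return np.asarray(labels.labels)
    return np.asarray([str(x) for x in labels])


def ncc_fit(train: AbundanceMatrix, labels) -> dict[str, np.ndarray]:
    """Per-class centroids: the arithmetic mean of each class's train columns."""
    lab = _as_labels(labels)
    if lab.shape[0] != train.n_samples:
        raise ValueError(
            f"{lab.shape[0]} labels for {train.n_samples} training samples"
        )
    centroids = {}
    for cls in sorted(set(lab)):
        cols = train.values[:, lab == cls]
        if cols.shape[1] == 0:
            raise ValueError(f"class {cls!r} has no training samples")
        centroids[cls] = cols.mean(axis=1)
    return centroids


def ncc_predict(
    z: np.ndarray, centroids: dict[str, np.ndarray], distance: str = "l2"
) -> str:
    """Label of the nearest centroid; ties go to the smaller class label."""
    if distance not in ("l1", "l2"):
        raise ValueError(f"distance must be 'l1' or 'l2', got {distance!r}")
    z = np.asarray(z, dtype=float).ravel()
    ord_ = 1 if distance == "l1" else 2
    best_label, best_dist = None, np.inf
    for cls in sorted(centroids):
        mu = np.asarray(centroids[cls], dtype=float).ravel()
        if mu.shape != z.shape:
            raise ValueError(
                f"dimension mismatch: sample {z.shape} vs centroid {mu.shape}"
            )
        d = float(np.linalg.norm(z - mu, ord=ord_))
        if d < best_dist:  # strict: earlier (smaller) label wins ties
            best_label, best_dist = cls, d
    return best_label


def classification_metrics(
    c: ConfusionCounts,
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); undefined ratios come back NaN."""
    accuracy = (
        (c.TP + c.TN) / c.total if c.total > 0 else math.nan
    )
    sensitivity = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else math.nan
    specificity = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else math.nan
    return accuracy, sensitivity, specificity


# ---------------------------------------------------------------------------
# selectors


def rpca_selector(config: SolverConfig | None = None) -> Selector:
    """Unsupervised robust-PCA ranking: PCP on the training matrix, then the
    row-wise |S| score, taxa in descending score order (full ranking)."""

    def select(train: AbundanceMatrix, rng: np.random.Generator):
        solution = solve_pcp(train.values, config)
        scores = compute_scores(solution.S, train.taxon_ids)
        return select_top(scores, train.p).members

    return select


def random_selector() -> Selector:
    """Null reference: a uniformly random permutation of the taxa."""

    def select(train: AbundanceMatrix, rng: np.random.Generator):
        order = rng.permutation(train.p)
        return tuple(train.taxon_ids[i] for i in order)

    return select


def constant_selector(ranking: Sequence[str]) -> Selector:
    """Degenerate reference returning the same ranking for every subset."""
    ranking = tuple(ranking)

    def select(train: AbundanceMatrix, rng: np.random.Generator):
        return ranking

    return select


# ---------------------------------------------------------------------------
# protocol


def _nanmean_sd(values: list[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    ok = arr[~np.isnan(arr)]
    if ok.size == 0:
        return math.nan, math.nan, 0
    sd = float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0
    return float(ok.mean()), sd, int(ok.size)


def run_protocol(
    D: AbundanceMatrix,
    labels: LabelVector,
    selector: Selector,
    n_markers_grid: Sequence[int],
    K: int = 500,
    r: float = 0.8,
    seed: int = 0,
    classifiers: Sequence[str] = ("l1", "l2"),
    stratify: bool = True,
) -> list[ProtocolReport]:
    """Run the subsampling consistency-classification protocol.

    For each replicate the selector sees only the training columns; markers,
    centroids and predictions are recomputed per replicate. One report per
    entry of ``n_markers_grid``.
    """
    grid = [int(m) for m in n_markers_grid]
    if not grid:
        raise ValueError("n_markers_grid must be non-empty")
    if any(not 1 <= m <= D.p for m in grid):
        raise ValueError(f"marker-set sizes must lie in [1, p={D.p}]: {grid}")
    if max(grid) >= D.p:
        raise ValueError(
            f"largest marker-set size {max(grid)} must be < p = {D.p} "
            "for the Kuncheva index to be defined"
        )
    for c in classifiers:
        if c not in ("l1", "l2"):
            raise ValueError(f"unknown classifier {c!r}")
    if len(labels) != D.n_samples:
        raise ValueError(f"{len(labels)} labels for {D.n_samples} samples")

    splits = generate_subsamples(
        D.n_samples, r, K, seed, stratify_labels=labels if stratify else None
    )
    lab = np.asarray(labels.labels)
    pos, neg = labels.positive_class, labels.negative_class

    rankings: list[tuple[str, ...]] = []
    # per m, per classifier, per replicate metric lists
    acc: dict[int, dict[str, list[float]]] = {
        m: {c: [] for c in classifiers} for m in grid
    }
    sens = {m: {c: [] for c in classifiers} for m in grid}
    spec = {m: {c: [] for c in classifiers} for m in grid}

    for split in splits:
        rng = _child_rng(seed, split.replicate)
        train_m = D.select_samples(split.train_idx)
        ranking = tuple(selector(train_m, rng))
        if len(set(ranking)) != len(ranking):
            raise ValueError("selector returned duplicate taxa")
        unknown = set(ranking) - set(D.taxon_ids)
        if unknown:
            raise ValueError(f"selector returned unknown taxa: {sorted(unknown)[:5]}")
        if len(ranking) < max(grid):
            raise ValueError(
                f"selector ranking has {len(ranking)} taxa; "
                f"needs at least {max(grid)}"
            )
        rankings.append(ranking)

        train_lab = lab[list(split.train_idx)]
        test_lab = lab[list(split.test_idx)]
        for m in grid:
            markers = list(ranking[:m])
            train_sel = train_m.select_taxa(markers)
            test_sel = D.select_taxa(markers).select_samples(split.test_idx)
            centroids = ncc_fit(train_sel, train_lab)
            for c in classifiers:
                tp = tn = fp = fn = 0
                for j in range(test_sel.n_samples):
                    pred = ncc_predict(test_sel.values[:, j], centroids, c)
                    truth = test_lab[j]
                    if truth == pos:
                        tp += pred == pos
                        fn += pred != pos
                    else:
                        tn += pred == neg
                        fp += pred != neg
                a, s, sp = classification_metrics(
                    ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
                )
                acc[m][c].append(a)
                sens[m][c].append(s)
                spec[m][c].append(sp)

    reports = []
    for m in grid:
        c_avg, ki_values = average_consistency(
            [set(rk[:m]) for rk in rankings], D.p
        )
        summaries = {}
        for c in classifiers:
            a_mean, a_sd, a_n = _nanmean_sd(acc[m][c])
            s_mean, s_sd, s_n = _nanmean_sd(sens[m][c])
            p_mean, p_sd, p_n = _nanmean_sd(spec[m][c])
            summaries[c] = ClassifierSummary(
                accuracy=a_mean,
                sensitivity=s_mean,
                specificity=p_mean,
                accuracy_sd=a_sd,
                sensitivity_sd=s_sd,
                specificity_sd=p_sd,
                n_accuracy=a_n,
                n_sensitivity=s_n,
                n_specificity=p_n,
            )
        reports.append(
            ProtocolReport(
                n_markers=m,
                C_avg=c_avg,
                ki_values=tuple(ki_values),
                classifiers=summaries,
                K=K,
                r=r,
                seed=seed,
            )
        )
    return reports


def ki_histogram(
    ki_values: Sequence[float], bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of pairwise Kuncheva indices over fixed edges on [-1, 1].

    Returns ``(counts, edges)``; counts sum to ``len(ki_values)``.
    """
    values = np.asarray(list(ki_values), dtype=float)
    if values.size and (values.min() < -1 - 1e-9 or values.max() > 1 + 1e-9):
        raise ValueError("Kuncheva indices must lie in [-1, 1]")
    edges = np.linspace(-1.0, 1.0, bins + 1)
    counts, _ = np.histogram(np.clip(values, -1.0, 1.0), bins=edges)
    return counts, edges
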