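"""Reading, validating and writing taxa-by-samples abundance tables.

The canonical in-memory layout is taxa x samples (p x N): each column holds
the abundance levels of all p taxa in one sample, each row the abundance of
one taxon across the N samples. Tables are plain delimited text (TSV or CSV,
chosen by file extension) with one header row of sample identifiers and one
leading column of taxon identifiers. Sample label files are two-column
TSV/CSV ``sample_id<sep>label``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "LabelVector",
    "FormatError",
    "ValidationError",
    "read_abundance_table",
    "write_abundance_table",
    "normalize_relative",
    "read_labels",
]


class FormatError(ValueError):
    """The file does not parse as a valid delimited abundance/label table."""


class ValidationError(ValueError):
    """The parsed table violates an abundance-matrix invariant."""


def _sep_for(path: str | os.PathLike) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass(frozen=True)
class AbundanceMatrix:
    """Nonnegative taxa x samples abundance matrix with axis identifiers.

    Attributes
    ----------
    values
        Array of shape ``(p, N)`` with nonnegative, finite entries.
    taxon_ids
        ``p`` unique row (taxon) identifiers.
    sample_ids
        ``N`` unique column (sample) identifiers.
    """

    values: np.ndarray
    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValidationError(f"expected a 2-D matrix, got ndim={values.ndim}")
        p, n = values.shape
        if p == 0 or n == 0:
            raise ValidationError(f"empty matrix not allowed (shape {values.shape})")
        if len(self.taxon_ids) != p:
            raise ValidationError(
                f"{len(self.taxon_ids)} taxon ids for {p} rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        for axis_name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise FormatError(f"duplicate {axis_name} identifier: {dup!r}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance {values[i, j]!r} at taxon "
                f"{self.taxon_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def p(self) -> int:
        """Number of taxa (rows)."""
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        """Number of samples (columns)."""
        return self.values.shape[1]

    def select_samples(self, indices) -> "AbundanceMatrix":
        """Return the sub-matrix restricted to the sample columns ``indices``."""
        idx = list(indices)
        return AbundanceMatrix(
            self.values[:, idx],
            self.taxon_ids,
            tuple(self.sample_ids[i] for i in idx),
        )

    def select_taxa(self, ids) -> "AbundanceMatrix":
        """Return the sub-matrix restricted to the given taxon ids, in order."""
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        try:
            rows = [pos[t] for t in ids]
        except KeyError as exc:
            raise KeyError(f"unknown taxon id {exc.args[0]!r}") from None
        return AbundanceMatrix(self.values[rows, :], tuple(ids), self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class LabelVector:
    """Per-sample class labels for a two-phenotype study.

    ``positive_class`` names the label treated as the positive (diseased)
    class when computing sensitivity; the other label is the negative class.
    """

    labels: tuple[str, ...]
    positive_class: str

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positive_class", str(self.positive_class))
        distinct = sorted(set(labels))
        if len(distinct) != 2:
            raise ValidationError(
                f"exactly 2 distinct labels required, got {len(distinct)}: {distinct}"
            )
        for cls in distinct:
            count = sum(1 for x in labels if x == cls)
            if count < 2:
                raise ValidationError(
                    f"class {cls!r} has only {count} sample(s); at least 2 required"
                )
        if self.positive_class not in distinct:
            raise ValidationError(
                f"positive_class {self.positive_class!r} not among labels {distinct}"
            )

    @property
    def negative_class(self) -> str:
        return next(c for c in sorted(set(self.labels)) if c != self.positive_class)

    @property
    def classes(self) -> tuple[str, str]:
        """The two class labels in sorted order."""
        a, b = sorted(set(self.labels))
        return a, b

    def subset(self, indices) -> "LabelVector":
        return LabelVector(
            tuple(self.labels[i] for i in indices), self.positive_class
        )

    def __len__(self) -> int:
        return len(self.labels)


def read_abundance_table(
    path: str | os.PathLike, orientation: str = "taxa_rows"
) -> AbundanceMatrix:
    """Read a delimited abundance table into a validated :class:`AbundanceMatrix`.

    Parameters
    ----------
    path
        TSV (default) or CSV file; the separator is chosen by extension.
        The first row is a header of identifiers and the first column holds
        the identifiers of the other axis.
    orientation
        ``"taxa_rows"`` if file rows are taxa (columns samples),
        ``"samples_rows"`` if file rows are samples. The returned matrix is
        always taxa x samples.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if frame.index.has_duplicates or frame.columns.has_duplicates:
        dups = list(frame.index[frame.index.duplicated()]) + list(
            frame.columns[frame.columns.duplicated()]
        )
        raise FormatError(f"duplicate identifiers in {path}: {dups[:5]}")
    if frame.isna().any().any():
        raise ValidationError(f"missing cells in {path}; imputation is not supported")
    # to_numeric only probes parseability; astype(float) below is the
    # correctly-rounded conversion that makes write->read lossless
    probe = frame.apply(pd.to_numeric, errors="coerce")
    if probe.isna().any().any():
        rows, cols = np.where(probe.isna().to_numpy())
        r, c = rows[0], cols[0]
        raise ValidationError(
            f"non-numeric cell {frame.iat[r, c]!r} at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r} in {path}"
        )
    numeric = frame.astype(float)
    if orientation == "samples_rows":
        numeric = numeric.T
    return AbundanceMatrix(
        numeric.to_numpy(dtype=float),
        tuple(str(t) for t in numeric.index),
        tuple(str(s) for s in numeric.columns),
    )


def write_abundance_table(m: AbundanceMatrix, path: str | os.PathLike) -> None:
    """Write ``m`` as a delimited table (taxa rows) that round-trips exactly.

    Cell values are rendered with ``repr`` precision so that
    ``read_abundance_table(path)`` reproduces ``m`` bit-for-bit.
    """
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write("taxon_id" + sep + sep.join(m.sample_ids) + "\n")
        for i, taxon in enumerate(m.taxon_ids):
            cells = (repr(float(x)) for x in m.values[i, :])
            fh.write(taxon + sep + sep.join(cells) + "\n")


def normalize_relative(m: AbundanceMatrix) -> AbundanceMatrix:
    """Rescale every sample column to sum to 1 (relative abundances).

    Idempotent; preserves shape, identifiers and within-column rank order.
    Raises :class:`ValidationError` if any column sums to zero.
    """
    sums = m.values.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValidationError(
            f"sample {m.sample_ids[zero[0]]!r} has zero total abundance; "
            "cannot normalize"
        )
    return AbundanceMatrix(m.values / sums, m.taxon_ids, m.sample_ids)


def read_labels(
    path: str | os.PathLike,
    samples,
    positive_class: str | None = None,
) -> LabelVector:
    """Read a two-column (sample_id, label) file and align it to ``samples``.

    A header row is skipped when its first field equals ``"sample_id"``.
    If ``positive_class`` is None, the lexicographically larger of the two
    labels is used (so e.g. ``disease`` > ``control`` by accident of
    alphabet — pass it explicitly in real analyses).
    """
    sep = _sep_for(path)
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str, comment=None)
    if frame.shape[1] != 2:
        raise FormatError(
            f"label file {path} must have exactly 2 columns, got {frame.shape[1]}"
        )
    if str(frame.iat[0, 0]) == "sample_id":
        frame = frame.iloc[1:]
    mapping: dict[str, str] = {}
    for sid, lab in frame.itertuples(index=False):
        sid, lab = str(sid), str(lab)
        if sid in mapping and mapping[sid] != lab:
            raise FormatError(f"conflicting labels for sample {sid!r} in {path}")
        mapping[sid] = lab
    missing = [s for s in samples if str(s) not in mapping]
    if missing:
        raise ValidationError(
            f"label file {path} is missing sample(s): {missing[:5]}"
        )
    ordered = tuple(mapping[str(s)] for s in samples)
    distinct = sorted(set(ordered))
    if len(distinct) != 2:
        raise ValidationError(
            f"exactly 2 classes required, found {len(distinct)}: {distinct[:5]}"
        )
    if positive_class is None:
        positive_class = distinct[1]
    return LabelVector(ordered, positive_class)
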