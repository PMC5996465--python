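"""Expression-matrix handling: IO, sample alignment, log transform, fold change.

Matrices are features x samples tables of nonnegative abundances, one per
feature class (miR or gene) and condition (e.g. healthy vs cancer). Mutual
information downstream requires the miR and gene matrices of a condition to
be column-aligned on the same samples, which :func:`align_samples` enforces.
The log2 fold change computed here is a plain ratio of condition means used
only to annotate network nodes; it gates nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, ParseError

log = logging.getLogger("cdrenet")

FEATURE_CLASSES = ("mir", "gene")


@dataclass
class ExpressionMatrix:
    """A features x samples abundance table with class and condition labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with sample IDs as columns. All
        entries must be finite; feature and sample IDs must be unique.
    feature_class
        Either ``"mir"`` or ``"gene"``.
    condition
        Free-form condition label (e.g. ``"healthy"``, ``"cancer"``).
    """

    values: pd.DataFrame
    feature_class: str
    condition: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise DomainError(
                f"feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature IDs: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample IDs: {dupes[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise DomainError("expression matrix contains non-finite values")
        self.values.index.name = "feature_id"
        self.values.columns.name = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV: header row of sample IDs, first column feature IDs."""
        self.values.to_csv(path, sep="\t", index_label="feature_id", float_format="%.8g")


def read_expression_table(
    path: str | Path, feature_class: str, condition: str
) -> ExpressionMatrix:
    """Read a TSV expression table (features as rows, samples as columns)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises a zoo of parse exceptions
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicated feature ID(s) {dupes[:5]}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        bad = df[non_numeric[0]]
        rows = bad[pd.to_numeric(bad, errors="coerce").isna()].index.tolist()
        raise ParseError(
            f"{path}: non-numeric values in column {non_numeric[0]!r}, "
            f"feature row(s) {rows[:5]}"
        )
    if df.size and (df.to_numpy() < 0).any():
        neg = df.index[(df.to_numpy() < 0).any(axis=1)].tolist()
        raise DomainError(f"{path}: negative abundances in feature(s) {neg[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    log.info(
        "read %d %s features x %d samples (%s) from %s",
        df.shape[0], feature_class, df.shape[1], condition, path,
    )
    return ExpressionMatrix(df.astype(float), feature_class, condition)


def align_samples(
    mir: ExpressionMatrix, gene: ExpressionMatrix, min_shared: int = 10
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared samples, in one canonical order.

    The canonical order is the miR matrix's column order filtered to the
    intersection, so repeated runs are deterministic.
    """
    shared = [s for s in mir.sample_ids if s in set(gene.sample_ids)]
    if len(shared) < min_shared:
        raise AlignmentError(
            f"only {len(shared)} shared samples (minimum {min_shared})"
        )
    mir_out = ExpressionMatrix(mir.values[shared], mir.feature_class, mir.condition)
    gene_out = ExpressionMatrix(gene.values[shared], gene.feature_class, gene.condition)
    log.info("aligned matrices on %d shared samples", len(shared))
    return mir_out, gene_out


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace every value v with log2(v + pseudocount)."""
    if pseudocount <= 0:
        raise DomainError(f"pseudocount must be positive, got {pseudocount}")
    arr = matrix.values.to_numpy()
    if arr.size and (arr < 0).any():
        raise DomainError("log_transform requires nonnegative values")
    out = pd.DataFrame(
        np.log2(arr + pseudocount), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(out, matrix.feature_class, matrix.condition)


def compute_lfc(
    cond_a: ExpressionMatrix, cond_b: ExpressionMatrix, pseudocount: float = 1.0
) -> pd.Series:
    """Per-feature log2 fold change of mean abundance, condition B over A.

    LFC(f) = log2((mean_b(f) + pseudocount) / (mean_a(f) + pseudocount)).
    Positive values mean higher abundance in condition B. Features present in
    only one condition are omitted (a count is logged). Swapping the two
    conditions negates every value.
    """
    if pseudocount <= 0:
        raise DomainError(f"pseudocount must be positive, got {pseudocount}")
    shared = cond_a.values.index.intersection(cond_b.values.index)
    n_dropped = (len(cond_a.values.index) - len(shared)) + (
        len(cond_b.values.index) - len(shared)
    )
    if n_dropped:
        log.info("compute_lfc: %d features present in only one condition, omitted",
                 n_dropped)
    mean_a = cond_a.values.loc[shared].mean(axis=1)
    mean_b = cond_b.values.loc[shared].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    lfc.name = "lfc"
    lfc.index.name = "feature_id"
    return lfc


def write_lfc(lfc: pd.Series, path: str | Path) -> None:
    """Two-column TSV: feature_id, lfc."""
    lfc.to_csv(path, sep="\t", float_format="%.6f")
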