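"""Binary alteration matrices built from gene-level call tables.

Tumour profiles are encoded as binary sample x feature matrices. A somatic
point mutation (SPM) contributes one feature per gene; a copy-number
alteration (CNA) contributes two features per gene, one for amplification
(AMP) and one for deletion (DEL), because gain and loss of a gene are
distinct alteration events that need not have opposing effects. Matrices
are sanitised before modelling: all-zero columns (genes never altered),
all-zero rows (samples indistinguishable from healthy tissue) and, within
the CNA block, duplicated columns are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

KINDS = ("SPM", "AMP", "DEL")

__all__ = [
    "KINDS",
    "AlterationCall",
    "FeatureDescriptor",
    "BinaryAlterationMatrix",
    "LabeledDataset",
    "SanitationReport",
    "filter_gene_list",
    "build_spm_matrix",
    "build_cna_matrix",
    "sanitize_matrix",
    "concat_matrices",
    "calls_frame",
]


@dataclass(frozen=True)
class AlterationCall:
    """One gene-level alteration event in one tumour sample."""

    sample_id: str
    gene: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not self.sample_id or not self.gene:
            raise ValueError("sample_id and gene must be non-empty")


@dataclass(frozen=True)
class FeatureDescriptor:
    """A column of a binary alteration matrix: a (gene, kind) pair."""

    feature_id: int
    gene: str
    kind: str

    @property
    def label(self) -> str:
        return f"{self.gene}|{self.kind}"


@dataclass
class BinaryAlterationMatrix:
    """Samples x binary (gene, kind) features.

    ``values`` is a dense uint8 array; entry (i, j) is 1 iff sample i
    carries the alteration described by ``features[j]``.
    """

    sample_ids: list[str]
    features: list[FeatureDescriptor]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.sample_ids), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.features)} features"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be binary")
        pairs = [(f.gene, f.kind) for f in self.features]
        if len(set(pairs)) != len(pairs):
            raise ValueError("(gene, kind) pairs must be unique within a matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature_index(self) -> dict[int, int]:
        """Map feature_id -> column position."""
        return {f.feature_id: j for j, f in enumerate(self.features)}

    def subset_features(self, feature_ids: list[int]) -> "BinaryAlterationMatrix":
        """Column subset preserving the requested order; ids are kept stable."""
        idx = self.feature_index()
        missing = [fid for fid in feature_ids if fid not in idx]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        cols = [idx[fid] for fid in feature_ids]
        return BinaryAlterationMatrix(
            sample_ids=list(self.sample_ids),
            features=[self.features[c] for c in cols],
            values=self.values[:, cols].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f.label for f in self.features],
        )


@dataclass
class LabeledDataset:
    """A binary alteration matrix with an integer cancer-type label per sample."""

    matrix: BinaryAlterationMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != self.matrix.n_samples:
            raise ValueError("label count must equal sample count")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset_features(self, feature_ids: list[int]) -> "LabeledDataset":
        return LabeledDataset(self.matrix.subset_features(feature_ids), self.labels.copy())

    def subset_samples(self, row_idx: np.ndarray) -> "LabeledDataset":
        m = BinaryAlterationMatrix(
            sample_ids=[self.matrix.sample_ids[i] for i in row_idx],
            features=list(self.matrix.features),
            values=self.matrix.values[row_idx],
        )
        return LabeledDataset(m, self.labels[row_idx])


@dataclass
class SanitationReport:
    """What sanitisation removed, and why."""

    dropped_zero_columns: list[int] = field(default_factory=list)
    duplicate_map: dict[int, int] = field(default_factory=dict)
    dropped_zero_rows: list[str] = field(default_factory=list)

    @property
    def n_dropped_columns(self) -> int:
        return len(self.dropped_zero_columns) + len(self.duplicate_map)


def filter_gene_list(genes: list[str], exclusion: set[str]) -> list[str]:
    """Drop excluded symbols (e.g. pseudogenes / non-coding genes) and
    collapse duplicates to their first occurrence, preserving order."""
    seen: set[str] = set()
    out: list[str] = []
    for g in genes:
        if g in exclusion or g in seen:
            continue
        seen.add(g)
        out.append(g)
    if genes and not out:
        warnings.warn("gene list is empty after exclusion filtering")
    return out


def calls_frame(calls) -> pd.DataFrame:
    """Normalise a call table (iterable of AlterationCall or a DataFrame
    with columns sample_id/gene/kind) into a validated DataFrame."""
    if isinstance(calls, pd.DataFrame):
        df = calls.loc[:, ["sample_id", "gene", "kind"]].copy()
    else:
        df = pd.DataFrame(
            [(c.sample_id, c.gene, c.kind) for c in calls],
            columns=["sample_id", "gene", "kind"],
        )
    bad = ~df["kind"].isin(KINDS)
    if bad.any():
        raise ValueError(f"unknown alteration kind(s): {sorted(df.loc[bad, 'kind'].unique())}")
    return df


def _sample_order(df: pd.DataFrame, samples: list[str] | None) -> list[str]:
    if samples is not None:
        return list(samples)
    return list(dict.fromkeys(df["sample_id"]))


def _fill(df: pd.DataFrame, order: list[str], col_of: dict[tuple[str, str], int],
          n_cols: int) -> tuple[np.ndarray, int]:
    row_of = {s: i for i, s in enumerate(order)}
    values = np.zeros((len(order), n_cols), dtype=np.uint8)
    skipped = 0
    for sample, gene, kind in df.itertuples(index=False):
        key = (gene, kind)
        if key not in col_of:
            skipped += 1
            continue
        values[row_of[sample], col_of[key]] = 1
    return values, skipped


def build_spm_matrix(calls, genes: list[str],
                     samples: list[str] | None = None) -> BinaryAlterationMatrix:
    """One column per gene; entry (i, j) = 1 iff sample i has >= 1 somatic
    point mutation call for gene j.

    Rows follow ``samples`` when given, else first appearance in the call
    table (the full table, so SPM and CNA matrices built from the same
    table share a sample order). Calls for genes outside ``genes`` are
    skipped with a counted warning.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    df = calls_frame(calls)
    order = _sample_order(df, samples)
    spm = df[df["kind"] == "SPM"]
    features = [FeatureDescriptor(j, g, "SPM") for j, g in enumerate(genes)]
    col_of = {(g, "SPM"): j for j, g in enumerate(genes)}
    values, skipped = _fill(spm, order, col_of, len(genes))
    if skipped:
        warnings.warn(f"{skipped} SPM call(s) referenced genes outside the gene list; skipped")
    return BinaryAlterationMatrix(order, features, values)


def build_cna_matrix(calls, genes: list[str],
                     samples: list[str] | None = None) -> BinaryAlterationMatrix:
    """Two columns per gene — amplification then deletion — set
    independently; a sample may carry both for the same gene. No high/low
    level distinction is made."""
    if not genes:
        raise ValueError("gene list must be non-empty")
    df = calls_frame(calls)
    order = _sample_order(df, samples)
    cna = df[df["kind"].isin(("AMP", "DEL"))]
    features: list[FeatureDescriptor] = []
    col_of: dict[tuple[str, str], int] = {}
    for g in genes:
        for kind in ("AMP", "DEL"):
            col_of[(g, kind)] = len(features)
            features.append(FeatureDescriptor(len(features), g, kind))
    values, skipped = _fill(cna, order, col_of, len(features))
    if skipped:
        warnings.warn(f"{skipped} CNA call(s) referenced genes outside the gene list; skipped")
    return BinaryAlterationMatrix(order, features, values)


def sanitize_matrix(m: BinaryAlterationMatrix, drop_duplicate_columns: bool = False
                    ) -> tuple[BinaryAlterationMatrix, SanitationReport]:
    """Remove all-zero columns, optionally duplicated columns (first
    occurrence kept), then all-zero rows, preserving the order of
    survivors. Idempotent: sanitising a sanitised matrix is a no-op.

    Duplicate dropping is exact equality of binary column vectors; intended
    for the CNA block, where amplification of a whole region duplicates the
    call pattern across its genes.
    """
    report = SanitationReport()
    keep_cols: list[int] = []
    seen: dict[bytes, int] = {}
    for j, f in enumerate(m.features):
        col = m.values[:, j]
        if not col.any():
            report.dropped_zero_columns.append(f.feature_id)
            continue
        if drop_duplicate_columns:
            key = col.tobytes()
            if key in seen:
                report.duplicate_map[f.feature_id] = seen[key]
                continue
            seen[key] = f.feature_id
        keep_cols.append(j)
    values = m.values[:, keep_cols]
    row_mask = values.any(axis=1)
    report.dropped_zero_rows = [s for s, k in zip(m.sample_ids, row_mask) if not k]
    values = values[row_mask]
    if values.size == 0:
        raise ValueError("sanitisation removed every row or column of the matrix")
    clean = BinaryAlterationMatrix(
        sample_ids=[s for s, k in zip(m.sample_ids, row_mask) if k],
        features=[m.features[j] for j in keep_cols],
        values=values,
    )
    return clean, report


def concat_matrices(spm: BinaryAlterationMatrix,
                    cna: BinaryAlterationMatrix) -> BinaryAlterationMatrix:
    """Column-wise concatenation, SPM block first. Rows are aligned by
    sample id in the SPM matrix's order; feature ids are renumbered
    contiguously so the result is self-consistent."""
    left, right = set(spm.sample_ids), set(cna.sample_ids)
    if left != right:
        diff = sorted(left.symmetric_difference(right))
        raise ValueError(f"sample sets differ between matrices: {diff}")
    row_of = {s: i for i, s in enumerate(cna.sample_ids)}
    aligned = cna.values[[row_of[s] for s in spm.sample_ids]]
    features = [replace(f, feature_id=j) for j, f in enumerate(spm.features)] + [
        replace(f, feature_id=spm.n_features + j) for j, f in enumerate(cna.features)
    ]
    return BinaryAlterationMatrix(
        sample_ids=list(spm.sample_ids),
        features=features,
        values=np.hstack([spm.values, aligned]),
    )
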