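"""Readers and writers for the plain-text interchange formats.

* call table: 3-column TSV ``sample_id  gene  kind`` with header,
  kind in {SPM, AMP, DEL};
* MAF-like somatic mutation table: tab-separated with at least
  Hugo_Symbol, Variant_Classification, Tumor_Sample_Barcode — any
  non-silent variant marks the gene SPM for that sample;
* GISTIC gene-level thresholded copy-number table: genes x samples,
  integers in -2..2; any positive value yields an AMP call, any negative
  value a DEL call (high/low levels are not distinguished);
* gene lists / exclusion lists: one symbol per line, ``#`` comments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import AccuracyCurve, ClasswiseMetrics
from .matrix import KINDS, BinaryAlterationMatrix
from .rankers import FeatureRanking
from .stability import StabilityResult

__all__ = [
    "read_call_table", "write_call_table", "read_gene_list",
    "read_maf_calls", "read_gistic_calls",
    "write_matrix_tsv", "write_ranking_tsv", "write_curve_tsv",
    "write_metrics_tsv", "write_stability_tsv",
]

# Variant classes that do not alter the protein product; MAF records with
# these classifications do not produce an SPM call.
SILENT_VARIANT_CLASSES = frozenset({
    "Silent", "Intron", "IGR", "RNA", "3'UTR", "5'UTR", "3'Flank", "5'Flank",
})


class ParseError(ValueError):
    pass


def read_call_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a (sample_id, gene, kind) TSV call table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "gene", "kind"]
    if list(df.columns[:3]) != required:
        raise ParseError(f"{path}: expected header columns {required}, "
                         f"got {list(df.columns[:3])}")
    df = df[required]
    bad = ~df["kind"].isin(KINDS)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # 1-based, after the header line
        raise ParseError(f"{path}:{line}: unknown kind {df.loc[df.index[bad][0], 'kind']!r}")
    if df[required].isna().any().any():
        line = int(df.index[df[required].isna().any(axis=1)][0]) + 2
        raise ParseError(f"{path}:{line}: missing field")
    return df


def write_call_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and ``#`` comments ignored;
    duplicates collapsed to first occurrence."""
    out: list[str] = []
    seen: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line and line not in seen:
            seen.add(line)
            out.append(line)
    return out


def read_maf_calls(path: str | Path) -> pd.DataFrame:
    """Extract SPM calls from a MAF-like table: one call per (sample, gene)
    with at least one non-silent variant classification."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing MAF column(s) {sorted(missing)}")
    keep = ~df["Variant_Classification"].isin(SILENT_VARIANT_CLASSES)
    calls = (df.loc[keep, ["Tumor_Sample_Barcode", "Hugo_Symbol"]]
             .drop_duplicates()
             .rename(columns={"Tumor_Sample_Barcode": "sample_id",
                              "Hugo_Symbol": "gene"}))
    calls["kind"] = "SPM"
    return calls.reset_index(drop=True)


def read_gistic_calls(path: str | Path) -> pd.DataFrame:
    """Extract AMP/DEL calls from a GISTIC-style gene-by-sample table of
    thresholded integer copy-number values (first column = gene symbol)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{path}: copy-number values must be numeric")
    records = []
    genes = df.index.to_list()
    samples = df.columns.to_list()
    for gi, si in zip(*np.nonzero(values != 0)):
        kind = "AMP" if values[gi, si] > 0 else "DEL"
        records.append((samples[si], genes[gi], kind))
    return pd.DataFrame(records, columns=["sample_id", "gene", "kind"])


def write_matrix_tsv(m: BinaryAlterationMatrix, path: str | Path) -> None:
    """Sample-by-feature TSV with ``gene|kind`` column labels."""
    m.to_frame().to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> BinaryAlterationMatrix:
    from .matrix import FeatureDescriptor
    df = pd.read_csv(path, sep="\t", index_col=0)
    features = []
    for j, col in enumerate(df.columns):
        gene, _, kind = col.rpartition("|")
        if kind not in KINDS:
            raise ParseError(f"{path}: column {col!r} lacks a gene|kind label")
        features.append(FeatureDescriptor(j, gene, kind))
    return BinaryAlterationMatrix(
        sample_ids=[str(s) for s in df.index],
        features=features,
        values=df.to_numpy(),
    )


def _descriptor_lookup(features) -> dict[int, tuple[str, str]]:
    return {f.feature_id: (f.gene, f.kind) for f in features}


def write_ranking_tsv(ranking: FeatureRanking, features, path: str | Path) -> None:
    look = _descriptor_lookup(features)
    rows = []
    for rank, (fid, imp) in enumerate(zip(ranking.feature_ids, ranking.importances), 1):
        gene, kind = look.get(fid, ("?", "?"))
        rows.append((rank, fid, gene, kind, imp, ranking.method, ranking.seed))
    pd.DataFrame(rows, columns=["rank", "feature_id", "gene", "kind",
                                "importance", "method", "seed"]
                 ).to_csv(path, sep="\t", index=False)


def write_curve_tsv(curve: AccuracyCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


def write_metrics_tsv(metrics: ClasswiseMetrics, path: str | Path,
                      n_excluded: dict[int, int] | None = None) -> None:
    df = metrics.to_frame()
    df["n_excluded_repeats"] = [0 if n_excluded is None else n_excluded.get(c, 0)
                                for c in metrics.classes]
    df.to_csv(path, sep="\t", index=False)


def write_stability_tsv(result: StabilityResult, features, path: str | Path) -> None:
    look = _descriptor_lookup(features)
    df = result.to_frame()
    df.insert(1, "gene", [look.get(f, ("?", "?"))[0] for f in df["feature_id"]])
    df.insert(2, "kind", [look.get(f, ("?", "?"))[1] for f in df["feature_id"]])
    df.to_csv(path, sep="\t", index=False)
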