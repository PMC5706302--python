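"""Synthetic labelled alteration datasets with planted class-specific signal.

The generator emulates the statistical structure of pan-cancer gene
alteration data: K (possibly imbalanced) tumour classes, each with a small
private set of informative features altered at an elevated Bernoulli rate
``p_signal``, on top of a sparse background where every feature fires at
rate ``p_background``. Features split into an SPM block (one column per
gene) and a CNA block (columns alternately flagged AMP / DEL), so every
downstream stage — matrix building, ranking, resampling evaluation,
stability selection — can be exercised against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BinaryAlterationMatrix, FeatureDescriptor, LabeledDataset

__all__ = ["SyntheticConfig", "PlantedTruth", "generate_dataset",
           "emit_alteration_calls", "planted_recovery_rate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-signal generator.

    ``signal_split`` is the fraction of each class's informative features
    placed in the SPM block; the remainder go to the CNA block.
    """

    n_classes: int = 6
    samples_per_class: tuple[int, ...] = (60,) * 6
    informative_per_class: int = 5
    n_background_spm: int = 150
    n_background_cna: int = 150
    p_signal: float = 0.6
    p_background: float = 0.02
    signal_split: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class must have one entry per class")
        if any(n < 1 for n in self.samples_per_class):
            raise ValueError("samples_per_class entries must be >= 1")
        if self.informative_per_class < 1:
            raise ValueError("informative_per_class must be >= 1")
        if self.n_background_spm < 0 or self.n_background_cna < 0:
            raise ValueError("background feature counts must be >= 0")
        if not (0.0 < self.p_signal <= 1.0):
            raise ValueError("p_signal must lie in (0, 1]")
        if not (0.0 <= self.p_background < 1.0):
            raise ValueError("p_background must lie in [0, 1)")
        if self.p_signal <= self.p_background:
            raise ValueError("p_signal must exceed p_background")
        if not (0.0 <= self.signal_split <= 1.0):
            raise ValueError("signal_split must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_class)

    @property
    def n_informative_spm_per_class(self) -> int:
        return int(self.informative_per_class * self.signal_split + 0.5)

    @property
    def n_features(self) -> int:
        return (self.n_classes * self.informative_per_class
                + self.n_background_spm + self.n_background_cna)


@dataclass
class PlantedTruth:
    """Ground truth of a generated dataset: which features carry class
    signal, and which block each feature lives in."""

    informative_features: dict[int, set[int]]
    block_of_feature: dict[int, str]

    @property
    def all_informative(self) -> set[int]:
        out: set[int] = set()
        for s in self.informative_features.values():
            out |= s
        return out


def _cna_kind(position: int) -> str:
    return "AMP" if position % 2 == 0 else "DEL"


def generate_dataset(config: SyntheticConfig) -> tuple[LabeledDataset, PlantedTruth]:
    """Draw a labelled binary dataset with planted signal.

    Layout: SPM block first (per-class informative SPM features in class
    order, then SPM background), then the CNA block (per-class informative
    CNA features, then CNA background); CNA kinds alternate AMP, DEL along
    the block. Entry (s, j) ~ Bernoulli(p_signal) when j is informative for
    s's class, else Bernoulli(p_background). Deterministic given ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_classes
    k_spm = config.n_informative_spm_per_class
    k_cna = config.informative_per_class - k_spm
    n_spm = K * k_spm + config.n_background_spm
    P = config.n_features

    features: list[FeatureDescriptor] = []
    informative: dict[int, set[int]] = {k + 1: set() for k in range(K)}
    # SPM block: informative then background
    for k in range(K):
        for i in range(k_spm):
            fid = len(features)
            features.append(FeatureDescriptor(fid, f"MS{k + 1:02d}_{i + 1:02d}", "SPM"))
            informative[k + 1].add(fid)
    for i in range(config.n_background_spm):
        features.append(FeatureDescriptor(len(features), f"MB{i + 1:04d}", "SPM"))
    # CNA block: informative then background, kinds alternating along the block
    cna_pos = 0
    for k in range(K):
        for i in range(k_cna):
            fid = len(features)
            features.append(
                FeatureDescriptor(fid, f"CS{k + 1:02d}_{i + 1:02d}", _cna_kind(cna_pos)))
            informative[k + 1].add(fid)
            cna_pos += 1
    for i in range(config.n_background_cna):
        features.append(
            FeatureDescriptor(len(features), f"CB{i + 1:04d}", _cna_kind(cna_pos)))
        cna_pos += 1

    labels = np.concatenate(
        [np.full(n, k + 1, dtype=np.int64) for k, n in enumerate(config.samples_per_class)])
    values = (rng.random((config.n_samples, P)) < config.p_background).astype(np.uint8)
    row = 0
    for k, n_k in enumerate(config.samples_per_class):
        cols = sorted(informative[k + 1])
        if cols:
            values[row:row + n_k, cols] = (
                rng.random((n_k, len(cols))) < config.p_signal).astype(np.uint8)
        row += n_k

    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    matrix = BinaryAlterationMatrix(sample_ids, features, values)
    truth = PlantedTruth(
        informative_features=informative,
        block_of_feature={f.feature_id: f.kind for f in features},
    )
    return LabeledDataset(matrix, labels), truth


def emit_alteration_calls(dataset: LabeledDataset) -> pd.DataFrame:
    """Flatten a binary dataset into a (sample_id, gene, kind) call table,
    one row per 1-entry, in row-major order. Feeding the table back through
    the matrix builders and sanitisation reproduces the dataset up to
    dropped all-zero rows and columns."""
    m = dataset.matrix
    if not np.isin(m.values, (0, 1)).all():
        raise ValueError("dataset matrix must be binary")
    rows, cols = np.nonzero(m.values)
    return pd.DataFrame({
        "sample_id": [m.sample_ids[i] for i in rows],
        "gene": [m.features[j].gene for j in cols],
        "kind": [m.features[j].kind for j in cols],
    })


def planted_recovery_rate(truth: PlantedTruth, panel: set[int]) -> float:
    """Fraction of all planted informative features present in ``panel``."""
    planted = truth.all_informative
    if not planted:
        return 0.0
    return len(planted & set(panel)) / len(planted)
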