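"""Stability selection: aggregate resampled rankings into a robust panel.

Feature rankings obtained from different resampled training sets differ;
features that appear near the top of most rankings are the robust choices.
For each feature we count how many rankings place it within the top ``m``,
then select the ``panel_size`` most frequently selected features. The
resulting panel is validated once on the untouched holdout set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluation import ClasswiseMetrics, SplitPlan, evaluate_fixed_panel
from .matrix import LabeledDataset
from .rankers import FeatureRanking

__all__ = ["StabilityResult", "stability_select", "final_validate"]


@dataclass
class StabilityResult:
    """Selection frequencies across rankings and the chosen panel."""

    frequency: dict[int, int]   # feature id -> number of rankings with it in the top-m
    mean_rank: dict[int, float]  # feature id -> mean 1-based rank position
    panel: list[int]
    top_m: int
    panel_size: int
    n_rankings: int
    tie_trace: list[str]

    def to_frame(self) -> pd.DataFrame:
        fids = sorted(self.frequency, key=lambda f: (-self.frequency[f],
                                                     self.mean_rank[f], f))
        return pd.DataFrame({
            "feature_id": fids,
            "frequency": [self.frequency[f] for f in fids],
            "mean_rank": [self.mean_rank[f] for f in fids],
            "selected": [f in set(self.panel) for f in fids],
        })


def stability_select(rankings: list[FeatureRanking], top_m: int,
                     panel_size: int) -> StabilityResult:
    """Select the features most frequently ranked within the top ``top_m``
    across resampled rankings.

    Ties in frequency are broken by ascending mean rank, then ascending
    feature id — fully deterministic and invariant to the order of the
    input rankings.
    """
    if len(rankings) < 2:
        raise ValueError("stability selection needs at least two rankings")
    if any(top_m > len(r) for r in rankings):
        raise ValueError("top_m exceeds the length of a ranking")

    freq: dict[int, int] = {}
    rank_sums: dict[int, float] = {}
    rank_counts: dict[int, int] = {}
    for ranking in rankings:
        for pos, fid in enumerate(ranking.feature_ids, start=1):
            rank_sums[fid] = rank_sums.get(fid, 0.0) + pos
            rank_counts[fid] = rank_counts.get(fid, 0) + 1
            if pos <= top_m:
                freq[fid] = freq.get(fid, 0) + 1
    mean_rank = {f: rank_sums[f] / rank_counts[f] for f in rank_sums}

    ever_selected = [f for f in freq if freq[f] > 0]
    if panel_size > len(ever_selected):
        raise ValueError(
            f"panel_size {panel_size} exceeds the {len(ever_selected)} features "
            f"ever selected in a top-{top_m} list")

    order = sorted(ever_selected, key=lambda f: (-freq[f], mean_rank[f], f))
    panel = order[:panel_size]

    tie_trace: list[str] = []
    if panel:
        boundary = freq[panel[-1]]
        tied = [f for f in ever_selected if freq[f] == boundary]
        if len(tied) > 1:
            tie_trace.append(
                f"frequency {boundary} shared by {len(tied)} features; "
                f"broken by mean rank then feature id")
    return StabilityResult(
        frequency={f: freq.get(f, 0) for f in rank_sums},
        mean_rank=mean_rank,
        panel=panel,
        top_m=top_m,
        panel_size=panel_size,
        n_rankings=len(rankings),
        tie_trace=tie_trace,
    )


def final_validate(panel: list[int], dataset: LabeledDataset, plan: SplitPlan,
                   cost: float = 1.0,
                   class_subset: list[int] | None = None) -> ClasswiseMetrics:
    """Final assessment of a stability-selected panel on the holdout
    quarter that no ranking or tuning step ever saw."""
    return evaluate_fixed_panel(panel, dataset, plan, cost=cost,
                                class_subset=class_subset)
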