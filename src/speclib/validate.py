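"""Evaluation machinery for annotation runs.

Summarizes score tables the way suspect-screening validation studies
report them: low-tail percentiles of the score distribution, counts per
score bin (confident / tentative / unannotated), acceptance matrices
over a grid of cosine and explained-intensity thresholds against
ground-truth labels, and feature-level overlap between in-silico and
experimental library annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "percentile",
    "bin_counts",
    "threshold_sweep",
    "DistributionSummary",
    "summarize_scores",
    "compare_libraries",
]

SCORE_BIN_EDGES = (0.1, 0.7)


def percentile(scores: Sequence[float], p: float) -> float:
    """Linear-interpolation percentile (the default type-7 estimator:
    h = (n-1) p / 100).  Fixing the estimator keeps low-tail summaries
    such as "10th-percentile cosine" reproducible across tools."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("percentile of an empty score list")
    if not 0 <= p <= 100:
        raise ValueError(f"percentile rank must be in [0, 100], got {p}")
    return float(np.percentile(scores, p, method="linear"))


def bin_counts(
    scores: Sequence[float], edges: Sequence[float] = SCORE_BIN_EDGES
) -> tuple[int, int, int]:
    """Counts per score bin ``(n_high, n_mid, n_low)`` for two edges
    (lower, upper): high is score >= upper edge, low is score < lower
    edge, mid is the half-open band in between (lower boundary counts
    as mid)."""
    lower, upper = edges
    if not lower < upper:
        raise ValueError("edges must be strictly increasing")
    scores = np.asarray(scores, dtype=float)
    n_high = int((scores >= upper).sum())
    n_low = int((scores < lower).sum())
    return n_high, len(scores) - n_high - n_low, n_low


def threshold_sweep(
    table: pd.DataFrame,
    cosine_grid: Sequence[float],
    ei_grid: Sequence[float],
) -> pd.DataFrame:
    """Acceptance counts over a grid of (cosine, explained-intensity)
    threshold pairs, split by truth label.

    ``table`` needs columns ``cosine``, ``explained_intensity`` and
    ``truth_label`` (values ``true_positive`` / ``false_positive`` /
    ``unknown``); rows labelled ``unknown`` contribute to ``n_accepted``
    only.  Returns one row per threshold pair with columns
    ``min_cosine, min_ei, n_accepted, n_true_accepted, n_false_accepted,
    n_true_rejected``.
    """
    labeled = table[table["truth_label"].isin(["true_positive", "false_positive"])]
    if labeled.empty:
        raise ValueError("threshold_sweep requires at least one labeled row")
    cos = table["cosine"].to_numpy(float)
    ei = table["explained_intensity"].to_numpy(float)
    is_tp = (table["truth_label"] == "true_positive").to_numpy()
    is_fp = (table["truth_label"] == "false_positive").to_numpy()
    rows = []
    for c in cosine_grid:
        for e in ei_grid:
            accepted = (cos >= c) & (ei >= e)
            rows.append(
                {
                    "min_cosine": c,
                    "min_ei": e,
                    "n_accepted": int(accepted.sum()),
                    "n_true_accepted": int((accepted & is_tp).sum()),
                    "n_false_accepted": int((accepted & is_fp).sum()),
                    "n_true_rejected": int((~accepted & is_tp).sum()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DistributionSummary:
    n: int
    percentile_10: float
    fraction_ge: dict[float, float] = field(default_factory=dict)
    bin_counts: tuple[int, int, int] = (0, 0, 0)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "percentile_10": self.percentile_10,
            "fraction_ge": {str(k): v for k, v in self.fraction_ge.items()},
            "bin_counts": {
                "high": self.bin_counts[0],
                "mid": self.bin_counts[1],
                "low": self.bin_counts[2],
            },
        }


def summarize_scores(
    scores: Sequence[float], thresholds: Sequence[float] = (0.1, 0.5, 0.7, 0.9)
) -> DistributionSummary:
    arr = np.asarray(scores, dtype=float)
    return DistributionSummary(
        n=int(arr.size),
        percentile_10=percentile(arr, 10),
        fraction_ge={t: float((arr >= t).mean()) for t in thresholds},
        bin_counts=bin_counts(arr),
    )


def compare_libraries(table: pd.DataFrame) -> dict:
    """Compare in-silico and experimental annotation results on the
    same feature set.

    ``table`` needs columns ``query_id``, ``cosine`` and
    ``library_kind`` (``in_silico`` / ``experimental``).  Returns
    per-kind score summaries plus feature-level overlap counts: a
    feature is "annotated by both" when it received any annotation from
    each library kind, regardless of whether those annotations name the
    same compound.
    """
    out: dict = {"per_library": {}, "overlap": {}}
    annotated: dict[str, set] = {}
    for kind, group in table.groupby("library_kind"):
        out["per_library"][kind] = summarize_scores(group["cosine"]).as_dict()
        annotated[kind] = set(group["query_id"])
    in_silico = annotated.get("in_silico", set())
    experimental = annotated.get("experimental", set())
    out["overlap"] = {
        "both": len(in_silico & experimental),
        "in_silico_only": len(in_silico - experimental),
        "experimental_only": len(experimental - in_silico),
        "total_annotated": len(in_silico | experimental),
    }
    return out
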