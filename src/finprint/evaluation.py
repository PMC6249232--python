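"""Scoring identification runs against ground-truth labels.

Accuracy is the fraction of correct identity predictions among *admitted*
queries — images rejected by the admission filter do not enter the
denominator, since the method only claims reliability on images that pass
its gates.  A penalised accuracy that counts rejections as errors is
reported alongside for transparency.  The sharpness-threshold sweep shows
how accuracy responds as blurred images are progressively excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .identification import FeatureBackend, FinModel, Rejection, identify
from .quality import QualityConfig
from .segmentation import FinImage, SegmentationConfig

#: Default sigma_s sweep: these percentiles of the admitted-query sharpness
#: distribution.
DEFAULT_THRESHOLD_PERCENTILES = (1, 10, 25, 50, 75, 90)


@dataclass
class EvaluationResult:
    """Per-query outcomes of one identification run.

    ``per_query`` columns: query, true_name, predicted_name, side, k, k_star,
    d_star, sharpness, warnings, rejected, rejected_reason, correct.
    """

    per_query: pd.DataFrame

    @property
    def n_admitted(self) -> int:
        return int((~self.per_query["rejected"]).sum())

    @property
    def accuracy(self) -> float:
        admitted = self.per_query[~self.per_query["rejected"]]
        return float(admitted["correct"].mean())

    @property
    def penalized_accuracy(self) -> float:
        """Accuracy with rejected queries counted as errors."""
        return float(self.per_query["correct"].sum() / len(self.per_query))


def evaluate(
    models: Sequence[FinModel],
    queries: Sequence[tuple[str, FinImage, str]],
    config: QualityConfig | None = None,
    backend: FeatureBackend | None = None,
    *,
    segmentation_config: SegmentationConfig | None = None,
    omega_unit: str = "rad",
) -> EvaluationResult:
    """Run :func:`finprint.identification.identify` on every labelled query.

    ``queries`` are (query_id, image, true_name) triples.  Raises if every
    query is rejected (accuracy would be undefined).
    """
    rows = []
    for qid, image, true_name in queries:
        out = identify(image, models, config, backend,
                       segmentation_config=segmentation_config,
                       omega_unit=omega_unit)
        if isinstance(out, Rejection):
            rows.append({
                "query": qid, "true_name": true_name, "predicted_name": None,
                "side": None, "k": None, "k_star": None, "d_star": None,
                "sharpness": out.sharpness, "warnings": "",
                "rejected": True, "rejected_reason": ";".join(out.reasons),
                "correct": False,
            })
        else:
            rows.append({
                "query": qid, "true_name": true_name,
                "predicted_name": out.dolphin_name, "side": out.side,
                "k": out.winning_score.k, "k_star": out.winning_score.k_star,
                "d_star": out.winning_score.d_star, "sharpness": out.sharpness,
                "warnings": ";".join(sorted(out.warnings)),
                "rejected": False, "rejected_reason": "",
                "correct": out.dolphin_name == true_name,
            })
    df = pd.DataFrame(rows)
    if df.empty or df["rejected"].all():
        raise ValueError("zero admitted queries: accuracy undefined")
    return EvaluationResult(per_query=df)


def accuracy_by_sharpness(
    result: EvaluationResult, thresholds: Sequence[float] | None = None
) -> pd.DataFrame:
    """Accuracy over admitted queries with sharpness strictly greater than
    each threshold sigma_s.

    Default thresholds are the 1/10/25/50/75/90-percentiles of the admitted
    queries' sharpness values.  A threshold retaining zero queries is
    reported with NaN accuracy rather than dropped.  Columns: sigma_s,
    accuracy, n_retained.
    """
    admitted = result.per_query[~result.per_query["rejected"]]
    if admitted.empty:
        raise ValueError("no admitted queries")
    sharp = admitted["sharpness"].to_numpy(dtype=float)
    if thresholds is None:
        thresholds = np.percentile(sharp, DEFAULT_THRESHOLD_PERCENTILES)
    rows = []
    for sigma_s in thresholds:
        kept = admitted[admitted["sharpness"] > sigma_s]
        rows.append({
            "sigma_s": float(sigma_s),
            "accuracy": float(kept["correct"].mean()) if len(kept) else float("nan"),
            "n_retained": int(len(kept)),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SharpnessSummary:
    """Five-number summary plus 1.5*IQR outliers of query sharpness."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: tuple[float, ...]


def sharpness_distribution(result: EvaluationResult) -> SharpnessSummary:
    """Boxplot statistics of the admitted queries' sharpness values: the
    five-number summary and the points outside [q1 - 1.5 IQR, q3 + 1.5 IQR]."""
    admitted = result.per_query[~result.per_query["rejected"]]
    if admitted.empty:
        raise ValueError("no admitted queries")
    values = np.sort(admitted["sharpness"].to_numpy(dtype=float))
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(v) for v in values if v < lo or v > hi)
    return SharpnessSummary(
        minimum=float(values[0]), q1=float(q1), median=float(med),
        q3=float(q3), maximum=float(values[-1]), outliers=outliers,
    )
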