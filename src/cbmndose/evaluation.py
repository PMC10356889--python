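"""Evaluation of dose estimates against delivered doses.

Two complementary views: binary triage performance at a clinical cutoff
(default 1.5 Gy, the threshold above which acute radiation syndrome becomes
a concern), and dose-estimation quality — whether the 95% confidence
interval covers the true dose, and the mean absolute dose error.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .inference import DoseEstimate, TRIAGE_CUTOFF_GY

__all__ = [
    "TriageConfusion",
    "TriageMetrics",
    "DoseAccuracyReport",
    "triage_confusion",
    "confusion_from_block",
    "confusion_metrics",
    "dose_accuracy",
]


@dataclass(frozen=True)
class TriageConfusion:
    """2x2 triage contingency counts; 'positive' means delivered dose above
    the cutoff.  Unirradiated (true 0 Gy) samples are excluded from triage
    comparison and counted in ``n_excluded_zero_dose``."""

    tp: int
    fn: int
    fp: int
    tn: int
    cutoff: float = TRIAGE_CUTOFF_GY
    n_excluded_zero_dose: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class TriageMetrics:
    """Sensitivity, specificity and accuracy; a metric whose denominator is
    zero is None (flagged undefined, never silently 0)."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def rounded(self, ndigits: int = 2) -> tuple:
        return tuple(
            None if v is None else round(v, ndigits)
            for v in (self.sensitivity, self.specificity, self.accuracy)
        )


def triage_confusion(
    estimates: list[DoseEstimate],
    delivered: list[float],
    cutoff: float = TRIAGE_CUTOFF_GY,
) -> TriageConfusion:
    """Cross-classify estimated vs delivered dose at the triage cutoff.

    Delivered dose exactly at the cutoff counts as the low class (the
    clinical category is inclusive).  True 0 Gy samples are excluded and
    tallied separately; an empty evaluable set is an error.
    """
    if len(estimates) != len(delivered):
        raise ValueError("estimates and delivered doses must be parallel")
    tp = fn = fp = tn = excluded = 0
    for est, true_dose in zip(estimates, delivered):
        if true_dose == 0:
            excluded += 1
            continue
        truly_high = true_dose > cutoff
        called_high = est.dose > cutoff
        if truly_high and called_high:
            tp += 1
        elif truly_high:
            fn += 1
        elif called_high:
            fp += 1
        else:
            tn += 1
    if tp + fn + fp + tn == 0:
        raise ValueError(
            f"no evaluable samples ({excluded} excluded at 0 Gy)"
        )
    return TriageConfusion(tp, fn, fp, tn, cutoff, excluded)


def confusion_from_block(
    block: pd.DataFrame, cutoff: float = TRIAGE_CUTOFF_GY
) -> TriageConfusion:
    """Build a confusion from one published contingency block: rows
    ``delivered_bin`` in {'le','gt'} with columns est_le, est_gt."""
    by_bin = block.set_index("delivered_bin")
    return TriageConfusion(
        tp=int(by_bin.loc["gt", "est_gt"]),
        fn=int(by_bin.loc["gt", "est_le"]),
        fp=int(by_bin.loc["le", "est_gt"]),
        tn=int(by_bin.loc["le", "est_le"]),
        cutoff=cutoff,
    )


def confusion_metrics(conf: TriageConfusion) -> TriageMetrics:
    """sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    accuracy = (tp+tn)/n."""
    sens = conf.tp / (conf.tp + conf.fn) if conf.tp + conf.fn else None
    spec = conf.tn / (conf.tn + conf.fp) if conf.tn + conf.fp else None
    acc = (conf.tp + conf.tn) / conf.n if conf.n else None
    return TriageMetrics(sens, spec, acc)


@dataclass(frozen=True)
class DoseAccuracyReport:
    """Coverage (fraction of samples whose 95% CI contains the delivered
    dose) and mean absolute dose error in Gy."""

    n: int
    coverage_accuracy: float
    mean_abs_diff: float

    def __post_init__(self) -> None:
        if not 0 <= self.coverage_accuracy <= 1 or self.mean_abs_diff < 0:
            raise ValueError("invalid accuracy report")


def dose_accuracy(
    estimates: list[DoseEstimate],
    delivered: list[float],
    *,
    inclusive: bool = True,
) -> DoseAccuracyReport:
    """Coverage accuracy and mean |estimated - delivered| over all samples.

    Unlike triage comparison, 0 Gy samples are included.  CI boundaries
    count as covered when ``inclusive`` (the default reading of a dose
    'falling within' the interval).
    """
    if len(estimates) != len(delivered):
        raise ValueError("estimates and delivered doses must be parallel")
    if not estimates:
        raise ValueError("no estimates to evaluate")
    covered = 0
    abs_diff = 0.0
    for est, true_dose in zip(estimates, delivered):
        if inclusive:
            hit = est.ci_low <= true_dose <= est.ci_high
        else:
            hit = est.ci_low < true_dose < est.ci_high
        covered += hit
        abs_diff += abs(est.dose - true_dose)
    n = len(estimates)
    return DoseAccuracyReport(n, covered / n, abs_diff / n)
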