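"""Per-dose descriptive statistics of MN distributions.

MN frequency (mean MN per BN cell), the dispersion index (variance-to-mean
ratio, 1 under a Poisson model) and the Papworth u statistic, which rescales
the dispersion index to an approximately standard-normal overdispersion
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .datasets import CalibrationDataset, MNDistribution

__all__ = [
    "UndefinedStatisticError",
    "DispersionReport",
    "mn_frequency",
    "dispersion_index",
    "u_statistic",
    "summarize_dataset",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given counts (e.g. zero mean)."""


@dataclass(frozen=True)
class DispersionReport:
    """Summary of one dose point: yield, dispersion and overdispersion score.

    ``u_statistic`` (and ``dispersion_index``) are ``None`` when undefined,
    e.g. at zero total MN; undefined statistics are flagged, not raised,
    in batch summaries.
    """

    dose: float
    mn_frequency: float
    dispersion_index: float | None
    u_statistic: float | None


def mn_frequency(dist: MNDistribution) -> float:
    """Mean MN per BN cell: (sum of k * counts[k]) / n_bn."""
    if dist.n_bn == 0:
        raise UndefinedStatisticError("MN frequency undefined for n_bn = 0")
    return dist.n_mn / dist.n_bn


def dispersion_index(dist: MNDistribution) -> float:
    """Variance-to-mean ratio of the per-cell MN count.

    The sample variance uses the n-1 denominator.  Equals 1 in expectation
    under Poisson counts; values above 1 indicate overdispersion.
    """
    if dist.n_bn <= 1:
        raise UndefinedStatisticError("dispersion index needs n_bn > 1")
    if dist.n_mn == 0:
        raise UndefinedStatisticError("dispersion index undefined at zero mean")
    n = dist.n_bn
    mean = dist.n_mn / n
    ssq = sum(k * k * c for k, c in enumerate(dist.counts))
    var = (ssq - n * mean * mean) / (n - 1)
    return var / mean


def u_statistic(dist: MNDistribution) -> float:
    """Papworth u score: (DI - 1) * sqrt((n-1) / (2 * (1 - 1/X))).

    ``X`` is the total MN count.  Approximately standard normal under the
    Poisson null, so |u| > 1.96 signals significant over/under-dispersion.
    """
    X = dist.n_mn
    if X < 2:
        raise UndefinedStatisticError("u statistic needs total MN >= 2")
    di = dispersion_index(dist)
    return (di - 1.0) * math.sqrt((dist.n_bn - 1) / (2.0 * (1.0 - 1.0 / X)))


def summarize_dataset(dataset: CalibrationDataset) -> pd.DataFrame:
    """Per-dose summary table with columns dose_gy, mn_frequency,
    dispersion_index, u_statistic.  Undefined statistics appear as NaN."""
    rows = []
    for p in dataset:
        try:
            di = dispersion_index(p)
        except UndefinedStatisticError:
            di = float("nan")
        try:
            u = u_statistic(p)
        except UndefinedStatisticError:
            u = float("nan")
        rows.append(
            {
                "dose_gy": p.dose,
                "mn_frequency": mn_frequency(p),
                "dispersion_index": di,
                "u_statistic": u,
            }
        )
    return pd.DataFrame(rows)
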