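"""Domain types and I/O for CBMN micronucleus-count data.

The cytokinesis-block micronucleus (CBMN) assay scores micronuclei (MN) in
binucleated (BN) lymphocytes.  The fundamental record is a per-dose histogram
of MN-per-cell counts; a calibration experiment is an ordered collection of
such histograms, one per delivered dose.  This module defines those
containers, validates their accounting identities, ships the published
reference tables as packaged fixtures, and reads/writes the CSV formats used
throughout the package.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MNDistribution",
    "CalibrationDataset",
    "SampleObservation",
    "ValidationError",
    "load_fixture",
    "read_distribution_csv",
    "write_distribution_csv",
    "read_samples_csv",
    "write_estimates_csv",
    "read_estimates_csv",
]


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class MNDistribution:
    """Histogram of micronucleus counts per binucleated cell at one dose.

    Parameters
    ----------
    dose : float
        Absorbed dose in Gy, finite and non-negative.
    n_bn : int
        Number of binucleated cells scored.
    counts : tuple of int
        ``counts[k]`` is the number of BN cells bearing exactly *k*
        micronuclei.  The class range is open-ended: published tables stop
        at 4 MN/cell, but simulated cells may carry more.
    """

    dose: float
    n_bn: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (self.dose >= 0 and self.dose == self.dose and self.dose != float("inf")):
            raise ValidationError(f"dose must be finite and >= 0, got {self.dose}")
        if any(c < 0 or c != int(c) for c in self.counts):
            raise ValidationError(f"counts must be non-negative integers: {self.counts}")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if sum(self.counts) != self.n_bn:
            raise ValidationError(
                f"sum(counts)={sum(self.counts)} != n_bn={self.n_bn} at dose {self.dose}"
            )

    @property
    def n_mn(self) -> int:
        """Total number of micronuclei, sum over k of k * counts[k]."""
        return sum(k * c for k, c in enumerate(self.counts))


@dataclass(frozen=True)
class CalibrationDataset:
    """Ordered per-dose MN distributions from one calibration experiment.

    ``mode`` records how the slides were scored (``fully-automated``,
    ``semi-automated`` or ``manual``); ``group`` is a free-text stratum label
    such as ``pooled``, ``male`` or ``female``.
    """

    points: tuple[MNDistribution, ...]
    mode: str = "fully-automated"
    group: str = "pooled"
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        doses = [p.dose for p in self.points]
        if len(doses) < 1:
            raise ValidationError("calibration dataset needs at least 1 dose point")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValidationError(f"doses must be strictly increasing, got {doses}")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(p.dose for p in self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)


@dataclass(frozen=True)
class SampleObservation:
    """One blind sample: scored BN cells and observed MN count.

    ``delivered_dose`` is the known dose in Gy, carried only for evaluation
    of the estimates; ``source_label`` tags the radiation quality (e.g.
    ``X-ray``, ``gamma``).
    """

    sample_id: str
    n_bn: int
    n_mn: int
    delivered_dose: float | None = None
    source_label: str | None = None

    def __post_init__(self) -> None:
        if self.n_bn <= 0:
            raise ValidationError(f"sample {self.sample_id}: n_bn must be > 0")
        if self.n_mn < 0:
            raise ValidationError(f"sample {self.sample_id}: n_mn must be >= 0")


_FIXTURES = {
    "table1_fully_automated": "table1_fully_automated.csv",
    "table2_error_rates": "table2_error_rates.csv",
    "table3_contingency": "table3_contingency.csv",
}


def _fixture_path(name: str) -> Path:
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return Path(str(resources.files("cbmndose").joinpath("data", fname)))


def load_fixture(name: str):
    """Load a packaged reference table.

    ``table1_fully_automated`` returns a :class:`CalibrationDataset` with the
    nine pooled fully-automated dose points (0-4 Gy, 159,592 BN cells in
    total).  ``table2_error_rates`` returns a DataFrame of per-dose
    false-positive BN, false-positive MN and false-negative MN percentages.
    ``table3_contingency`` returns a DataFrame of triage contingency blocks
    (group x scoring mode x delivered-dose bin).
    """
    path = _fixture_path(name)
    if name == "table1_fully_automated":
        ds = read_distribution_csv(path)
        return CalibrationDataset(
            ds.points, mode="fully-automated", group="pooled", source=name
        )
    return pd.read_csv(path)


def read_distribution_csv(path) -> CalibrationDataset:
    """Read a per-dose MN distribution CSV.

    Expected header: ``dose_gy,n_bn,mn0,mn1,...,mnK`` with one row per dose
    point, doses strictly increasing.  Each row must satisfy
    ``sum(mnk) == n_bn``.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    mn_cols = [c for c in df.columns if c.startswith("mn")]
    mn_cols.sort(key=lambda c: int(c[2:]))
    if not mn_cols or "dose_gy" not in df.columns or "n_bn" not in df.columns:
        raise ValidationError(
            f"{path}: expected header dose_gy,n_bn,mn0,...,mnK, got {list(df.columns)}"
        )
    points = []
    for i, row in df.iterrows():
        counts = tuple(int(row[c]) for c in mn_cols)
        if sum(counts) != int(row["n_bn"]):
            raise ValidationError(
                f"{path} row {i} (dose {row['dose_gy']}): "
                f"sum of MN-class counts {sum(counts)} != n_bn {int(row['n_bn'])}"
            )
        points.append(MNDistribution(float(row["dose_gy"]), int(row["n_bn"]), counts))
    return CalibrationDataset(tuple(points))


def write_distribution_csv(dataset: CalibrationDataset, path) -> None:
    """Write a :class:`CalibrationDataset` in the format read back by
    :func:`read_distribution_csv`."""
    kmax = max(len(p.counts) for p in dataset.points) - 1
    header = ["dose_gy", "n_bn"] + [f"mn{k}" for k in range(kmax + 1)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for p in dataset.points:
            padded = list(p.counts) + [0] * (kmax + 1 - len(p.counts))
            w.writerow([p.dose, p.n_bn, *padded])


def read_samples_csv(path) -> list[SampleObservation]:
    """Read blind-sample observations.

    Header: ``sample_id,n_bn,n_mn[,delivered_dose,source_label]``.
    """
    df = pd.read_csv(path)
    required = {"sample_id", "n_bn", "n_mn"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: missing columns {required - set(df.columns)}")
    out = []
    for _, row in df.iterrows():
        dd = row.get("delivered_dose")
        out.append(
            SampleObservation(
                sample_id=str(row["sample_id"]),
                n_bn=int(row["n_bn"]),
                n_mn=int(row["n_mn"]),
                delivered_dose=None if dd is None or pd.isna(dd) else float(dd),
                source_label=(
                    str(row["source_label"])
                    if "source_label" in df.columns and pd.notna(row.get("source_label"))
                    else None
                ),
            )
        )
    return out


_ESTIMATE_FIELDS = (
    "sample_id",
    "n_bn",
    "n_mn",
    "yield",
    "dose_gy",
    "ci_low_gy",
    "ci_high_gy",
    "triage_class",
)


def write_estimates_csv(estimates: Sequence, path) -> None:
    """Write dose estimates to CSV (numeric fields at 6 decimal places)."""
    estimates = list(estimates)
    if not estimates:
        raise ValidationError("no estimates to write")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ESTIMATE_FIELDS)
        for e in estimates:
            w.writerow(
                [
                    e.sample_id,
                    e.n_bn,
                    e.n_mn,
                    f"{e.observed_yield:.6f}",
                    f"{e.dose:.6f}",
                    f"{e.ci_low:.6f}",
                    f"{e.ci_high:.6f}",
                    e.triage_class,
                ]
            )


def read_estimates_csv(path) -> pd.DataFrame:
    """Read back an estimates CSV as a DataFrame."""
    df = pd.read_csv(path)
    missing = set(_ESTIMATE_FIELDS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df
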