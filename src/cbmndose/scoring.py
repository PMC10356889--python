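"""Automated-scoring error quantification and correction.

Automated MN scoring makes three kinds of mistakes, each expressed as a
percentage of the total scored BN cells at a dose point:

* false-positive BN: auto-selected binucleated cells a human scorer rejects;
* false-positive MN: automatically counted micronuclei rejected as false;
* false-negative MN: micronuclei the automated scorer missed, found only on
  complete visual re-scoring.

Semi-automated scoring removes the false positives (rejected BN cells and
false MN among flagged cells); manual scoring additionally recovers the
false-negative MN.  ``correct_counts`` applies those corrections to an
automated histogram; ``build_error_model`` turns a per-dose rate table into
an interpolating dose-dependent error model for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import MNDistribution, ValidationError

__all__ = [
    "InspectionRecord",
    "ScoringErrorModel",
    "error_rates",
    "error_rate_table",
    "summarize_error_table",
    "correct_counts",
    "build_error_model",
]


@dataclass(frozen=True)
class InspectionRecord:
    """Outcome of visually inspecting one automated dose point.

    ``n_fp_bn`` auto-selected BN cells were rejected, ``n_fp_mn`` automated
    MN were rejected as false, and ``n_fn_mn`` missed MN were recovered on
    full inspection.  ``n_bn_auto``/``n_mn_auto`` are the automated totals
    the record refers to.
    """

    dose: float
    n_bn_auto: int
    n_fp_bn: int
    n_fp_mn: int
    n_fn_mn: int
    n_mn_auto: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_fp_bn <= self.n_bn_auto:
            raise ValidationError("need 0 <= n_fp_bn <= n_bn_auto")
        if not 0 <= self.n_fp_mn <= self.n_mn_auto:
            raise ValidationError("need 0 <= n_fp_mn <= n_mn_auto")
        if self.n_fn_mn < 0:
            raise ValidationError("n_fn_mn must be >= 0")


def error_rates(record: InspectionRecord) -> tuple[float, float, float]:
    """Percent false-positive BN, false-positive MN and false-negative MN,
    each relative to the total scored BN cells."""
    if record.n_bn_auto <= 0:
        raise ValueError("n_bn_auto must be > 0")
    scale = 100.0 / record.n_bn_auto
    return (
        record.n_fp_bn * scale,
        record.n_fp_mn * scale,
        record.n_fn_mn * scale,
    )


def error_rate_table(records) -> pd.DataFrame:
    """Per-dose error-rate table (columns dose_gy, fp_bn_pct, fp_mn_pct,
    fn_mn_pct) from a sequence of inspection records."""
    rows = []
    for r in records:
        fp_bn, fp_mn, fn_mn = error_rates(r)
        rows.append(
            {"dose_gy": r.dose, "fp_bn_pct": fp_bn, "fp_mn_pct": fp_mn, "fn_mn_pct": fn_mn}
        )
    return pd.DataFrame(rows)


_RATE_COLS = ("fp_bn_pct", "fp_mn_pct", "fn_mn_pct")


def summarize_error_table(table) -> dict:
    """Unweighted means and ranges of each error-rate column.

    ``table`` is either a per-dose rate DataFrame (as from
    :func:`error_rate_table` or the packaged rate fixture) or a sequence of
    :class:`InspectionRecord`.  For each rate the summary reports the
    arithmetic mean over dose points and the (min, max) range both including
    and excluding the unirradiated 0 Gy point, since background error rates
    answer a different question from radiation-induced ones.
    """
    if not isinstance(table, pd.DataFrame):
        table = error_rate_table(table)
    if table.empty:
        raise ValueError("empty error table")
    nonzero = table[table["dose_gy"] > 0]
    out = {"n_doses": len(table)}
    for col in _RATE_COLS:
        vals = table[col]
        out[col] = {
            "mean": float(vals.mean()),
            "range": (float(vals.min()), float(vals.max())),
            "range_excl_zero_dose": (
                (float(nonzero[col].min()), float(nonzero[col].max()))
                if not nonzero.empty
                else None
            ),
        }
    return out


def _take_from_lowest_positive(counts: list[int], n: int) -> None:
    # move n cells one MN class down, lowest occupied positive class first
    while n > 0:
        k = next((i for i in range(1, len(counts)) if counts[i] > 0), None)
        if k is None:
            raise ValidationError("cannot remove MN: no MN-bearing cells left")
        step = min(counts[k], n)
        counts[k] -= step
        counts[k - 1] += step
        n -= step


def _add_from_lowest(counts: list[int], n: int) -> None:
    # move n cells one MN class up, lowest occupied class first
    while n > 0:
        k = next((i for i in range(len(counts)) if counts[i] > 0), None)
        if k is None:
            raise ValidationError("cannot add MN to an empty distribution")
        if k + 1 >= len(counts):
            counts.append(0)
        step = min(counts[k], n)
        counts[k] -= step
        counts[k + 1] += step
        n -= step


def correct_counts(
    dist_auto: MNDistribution, record: InspectionRecord, mode: str
) -> MNDistribution:
    """Apply semi-automated or manual corrections to an automated histogram.

    Both modes reject the false-positive BN cells (taken from the 0-MN
    class) and subtract the false-positive MN; manual mode additionally adds
    back the false-negative MN.  The histogram adjustment is deterministic:
    MN removals demote cells from the lowest occupied positive class first,
    additions promote cells from the lowest occupied class first.  Totals
    therefore satisfy BN' = BN - n_fp_bn and MN' = MN - n_fp_mn (+ n_fn_mn
    in manual mode).
    """
    if mode not in ("semi", "manual"):
        raise ValueError(f"mode must be 'semi' or 'manual', got {mode!r}")
    if record.n_bn_auto != dist_auto.n_bn or record.n_mn_auto != dist_auto.n_mn:
        raise ValidationError(
            "inspection record totals do not match the automated distribution"
        )
    counts = list(dist_auto.counts)
    if counts[0] < record.n_fp_bn:
        raise ValidationError("not enough 0-MN cells to reject the false-positive BN")
    counts[0] -= record.n_fp_bn
    _take_from_lowest_positive(counts, record.n_fp_mn)
    if mode == "manual":
        _add_from_lowest(counts, record.n_fn_mn)
    return MNDistribution(dist_auto.dose, sum(counts), tuple(counts))


@dataclass(frozen=True)
class ScoringErrorModel:
    """Dose-dependent scoring-error rates (percent of scored BN cells).

    Rates are defined on a strictly increasing dose grid and evaluated at
    arbitrary doses by piecewise-linear interpolation with constant
    extrapolation beyond the grid ends — the published rate tables are
    sparse and non-monotone at low dose, so no trend is fitted.
    """

    doses: tuple[float, ...]
    fp_bn_rate: tuple[float, ...]
    fp_mn_rate: tuple[float, ...]
    fn_mn_rate: tuple[float, ...]

    def __post_init__(self) -> None:
        d = self.doses
        if len(d) < 2:
            raise ValidationError("error model needs >= 2 dose points")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValidationError("dose grid must be strictly increasing")
        for rates in (self.fp_bn_rate, self.fp_mn_rate, self.fn_mn_rate):
            if len(rates) != len(d):
                raise ValidationError("rate grids must match the dose grid")
            if any(r < 0 for r in rates):
                raise ValidationError("rates must be >= 0")

    def rates_at(self, dose: float) -> tuple[float, float, float]:
        """(fp_bn %, fp_mn %, fn_mn %) at an arbitrary dose."""
        return (
            float(np.interp(dose, self.doses, self.fp_bn_rate)),
            float(np.interp(dose, self.doses, self.fp_mn_rate)),
            float(np.interp(dose, self.doses, self.fn_mn_rate)),
        )


def build_error_model(table: pd.DataFrame) -> ScoringErrorModel:
    """Build a :class:`ScoringErrorModel` from a per-dose rate table with
    columns dose_gy, fp_bn_pct, fp_mn_pct, fn_mn_pct."""
    missing = {"dose_gy", *_RATE_COLS} - set(table.columns)
    if missing:
        raise ValidationError(f"rate table missing columns {missing}")
    return ScoringErrorModel(
        tuple(float(x) for x in table["dose_gy"]),
        tuple(float(x) for x in table["fp_bn_pct"]),
        tuple(float(x) for x in table["fp_mn_pct"]),
        tuple(float(x) for x in table["fn_mn_pct"]),
    )
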