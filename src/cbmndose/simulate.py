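"""Seeded generator of synthetic CBMN experiments.

The generator draws per-cell MN counts from a linear-quadratic yield curve
— Poisson by default, or a gamma-mixed Poisson (negative binomial) when a
target dispersion index above 1 is requested, matching the mild
overdispersion (variance-to-mean up to ~1.12) seen in real pooled CBMN
data.  An optional corruption step emulates automated scoring against a
dose-dependent error model: spurious BN cells are added, spurious MN are
sprinkled onto random cells, and a dose-increasing fraction of the real MN
is missed.  Each corruption returns the exact inspection record that undoes
it, so the scoring-correction round trip is testable by construction.

Everything is driven by a single integer seed; identical configurations
produce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import LQCurve, predict_yield
from .datasets import CalibrationDataset, MNDistribution, SampleObservation
from .scoring import InspectionRecord, ScoringErrorModel

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_distribution",
    "corrupt_scoring",
    "simulate_study",
]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _histogram(per_cell: np.ndarray, min_classes: int = 5) -> tuple[int, ...]:
    counts = np.bincount(per_cell, minlength=min_classes)
    return tuple(int(c) for c in counts)


def simulate_distribution(
    curve: LQCurve,
    dose: float,
    n_bn: int,
    seed,
    dispersion: str = "poisson",
    target_di: float = 1.1,
) -> MNDistribution:
    """Draw an MN histogram of ``n_bn`` cells at ``dose``.

    ``dispersion='poisson'`` draws each cell Poisson with mean
    lambda = c + alpha*D + beta*D^2.  ``dispersion='overdispersed'`` mixes
    the Poisson mean with a gamma of shape lambda/(target_di - 1), which
    gives a negative-binomial count with dispersion index ``target_di`` at
    the generating mean.
    """
    if n_bn < 1:
        raise ValueError("n_bn must be >= 1")
    rng = _as_rng(seed)
    lam = predict_yield(curve, dose)
    if lam == 0.0:
        return MNDistribution(dose, n_bn, _histogram(np.zeros(n_bn, dtype=int)))
    if dispersion == "poisson":
        per_cell = rng.poisson(lam, n_bn)
    elif dispersion == "overdispersed":
        if target_di <= 1:
            raise ValueError("target dispersion index must be > 1")
        shape = lam / (target_di - 1.0)  # DI = 1 + lambda/shape
        per_cell = rng.poisson(rng.gamma(shape, lam / shape, n_bn))
    else:
        raise ValueError(f"unknown dispersion model {dispersion!r}")
    return MNDistribution(dose, n_bn, _histogram(per_cell))


def _move_random_cells(counts: list[int], n: int, rng, direction: int,
                       from_classes) -> int:
    """Move ``n`` randomly chosen cells one MN class up (+1) or down (-1),
    choosing each cell uniformly among those in ``from_classes``.  Returns
    the number actually moved (limited by availability)."""
    moved = 0
    for _ in range(n):
        eligible = [k for k in from_classes(len(counts)) if counts[k] > 0]
        if not eligible:
            break
        weights = np.array([counts[k] for k in eligible], dtype=float)
        k = int(rng.choice(eligible, p=weights / weights.sum()))
        if direction > 0 and k + 1 >= len(counts):
            counts.append(0)
        counts[k] -= 1
        counts[k + direction] += 1
        moved += 1
    return moved


def corrupt_scoring(
    dist: MNDistribution, model: ScoringErrorModel, seed
) -> tuple[MNDistribution, InspectionRecord]:
    """Corrupt a true distribution as an automated scorer would see it.

    Error counts are binomial draws against the model's rates at the
    distribution's dose: missed (false-negative) MN are removed from
    randomly chosen MN-bearing cells (capped at the MN actually present),
    spurious (false-positive) MN are added to randomly chosen cells, and
    spurious BN cells are appended to the 0-MN class.  Returns the
    corrupted histogram and the inspection record that exactly undoes it
    via :func:`cbmndose.scoring.correct_counts` in manual mode.
    """
    rng = _as_rng(seed)
    fp_bn_pct, fp_mn_pct, fn_mn_pct = model.rates_at(dist.dose)
    n = dist.n_bn
    n_fp_bn = int(rng.binomial(n, fp_bn_pct / 100.0))
    n_fp_mn = int(rng.binomial(n, fp_mn_pct / 100.0))
    n_fn_draw = int(rng.binomial(n, fn_mn_pct / 100.0))

    counts = list(dist.counts)
    # automated scorer misses real MN (demote MN-bearing cells)
    n_fn_mn = _move_random_cells(
        counts, n_fn_draw, rng, -1, lambda L: range(1, L)
    )
    # ... and invents MN on random cells (promote any cell)
    _move_random_cells(counts, n_fp_mn, rng, +1, lambda L: range(L))
    # ... and selects spurious BN cells, carrying no MN
    counts[0] += n_fp_bn

    corrupted = MNDistribution(dist.dose, sum(counts), tuple(counts))
    record = InspectionRecord(
        dose=dist.dose,
        n_bn_auto=corrupted.n_bn,
        n_fp_bn=n_fp_bn,
        n_fp_mn=n_fp_mn,
        n_fn_mn=n_fn_mn,
        n_mn_auto=corrupted.n_mn,
    )
    return corrupted, record


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic CBMN experiment.

    ``curve`` generates the true yields on the ``doses`` grid with
    ``n_bn_per_dose`` cells per point.  ``donor_baseline_multipliers``
    optionally splits each dose point evenly across donors whose background
    frequency c is scaled by the given factors (e.g. 1.4 for female donors,
    who carry higher spontaneous MN frequencies).  ``error_model`` switches
    on automated-scoring corruption.  ``blind_doses`` adds coded validation
    samples of ``n_bn_blind`` cells each, with a truth key.
    """

    curve: LQCurve
    doses: tuple[float, ...]
    n_bn_per_dose: int
    seed: int
    dispersion: str = "poisson"
    target_di: float = 1.1
    error_model: ScoringErrorModel | None = None
    donor_baseline_multipliers: tuple[float, ...] | None = None
    blind_doses: tuple[float, ...] = ()
    n_bn_blind: int = 1000

    def __post_init__(self) -> None:
        if self.n_bn_per_dose < 1 or self.n_bn_blind < 1:
            raise ValueError("cell counts must be >= 1")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")


@dataclass(frozen=True)
class SimulatedStudy:
    """Output bundle of :func:`simulate_study`."""

    clean: CalibrationDataset
    corrupted: CalibrationDataset | None
    inspections: tuple[InspectionRecord, ...] | None
    samples: tuple[SampleObservation, ...]
    truth: dict
    config: SimulationConfig


def _simulate_point(cfg: SimulationConfig, dose: float, rng) -> MNDistribution:
    mults = cfg.donor_baseline_multipliers
    if not mults:
        return simulate_distribution(
            cfg.curve, dose, cfg.n_bn_per_dose, rng, cfg.dispersion, cfg.target_di
        )
    # pool equal-sized per-donor draws with scaled backgrounds
    per = cfg.n_bn_per_dose // len(mults)
    sizes = [per] * len(mults)
    sizes[-1] += cfg.n_bn_per_dose - per * len(mults)
    pooled: list[int] = []
    for mult, size in zip(mults, sizes):
        donor_curve = LQCurve(cfg.curve.c * mult, cfg.curve.alpha, cfg.curve.beta)
        d = simulate_distribution(
            donor_curve, dose, size, rng, cfg.dispersion, cfg.target_di
        )
        if len(d.counts) > len(pooled):
            pooled.extend([0] * (len(d.counts) - len(pooled)))
        for k, c in enumerate(d.counts):
            pooled[k] += c
    return MNDistribution(dose, sum(pooled), tuple(pooled))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete reproducible experiment: clean calibration data,
    optionally the corrupted automated view with its inspection records,
    and coded blind samples with a delivered-dose key."""
    rng = np.random.default_rng(config.seed)
    clean_points, corrupt_points, records = [], [], []
    for dose in config.doses:
        dist = _simulate_point(config, dose, rng)
        clean_points.append(dist)
        if config.error_model is not None:
            auto, rec = corrupt_scoring(dist, config.error_model, rng)
            corrupt_points.append(auto)
            records.append(rec)
    clean = CalibrationDataset(tuple(clean_points), mode="manual", group="simulated")
    corrupted = (
        CalibrationDataset(tuple(corrupt_points), mode="fully-automated",
                           group="simulated")
        if config.error_model is not None
        else None
    )
    samples, truth = [], {}
    for i, dose in enumerate(config.blind_doses):
        dist = simulate_distribution(
            config.curve, dose, config.n_bn_blind, rng,
            config.dispersion, config.target_di,
        )
        sid = f"S{i + 1:02d}"
        samples.append(
            SampleObservation(sid, dist.n_bn, dist.n_mn, delivered_dose=dose)
        )
        truth[sid] = dose
    return SimulatedStudy(
        clean=clean,
        corrupted=corrupted,
        inspections=tuple(records) if records else None,
        samples=tuple(samples),
        truth=truth,
        config=config,
    )
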