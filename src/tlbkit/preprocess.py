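"""Thermogram preprocessing: baseline, interpolation, normalization, features.

Raw DSC curves from different runs differ in instrument baseline, sampling
grid and total signal (sample concentration).  The preprocessing chain
removes these nuisance factors so that only the *shape* of the denaturation
profile remains:

1. :func:`baseline_correct` — subtract a straight line anchored on the
   pre- and post-transition windows (defaults 40–45 °C and 90–95 °C).
2. :func:`interpolate_grid` — resample onto the uniform analysis grid
   (40–95 °C, ΔT = 0.25 °C by default).
3. :func:`area_normalize` — divide by the trapezoidal integral over the
   retained span, removing amplitude/concentration scale.
4. :func:`extract_features` — sub-sample the normalized curve at whole
   degrees on the most informative window (55–85 °C → 31 values).

:func:`prepare` composes the four steps; it is deterministic and invariant
to positive rescaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, DomainError, GridMismatchError, NormalizationError
from .io import Thermogram

DEFAULT_BASELINE_WINDOWS = ((40.0, 45.0), (90.0, 95.0))


@dataclass(frozen=True)
class GridSpec:
    """Uniform analysis grid and feature sub-grid.

    ``t_min``..``t_max`` at step ``dt`` is the interpolation grid (the span
    retained for area normalization); ``feature_lo``..``feature_hi`` at step
    ``feature_step`` are the temperatures kept as predictive variables.
    All temperatures in °C.
    """

    t_min: float = 40.0
    t_max: float = 95.0
    dt: float = 0.25
    feature_lo: float = 55.0
    feature_hi: float = 85.0
    feature_step: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t_min < self.feature_lo < self.feature_hi <= self.t_max):
            raise DomainError(
                "require t_min < feature_lo < feature_hi <= t_max, got "
                f"{self.t_min}, {self.feature_lo}, {self.feature_hi}, {self.t_max}"
            )
        if self.dt <= 0:
            raise DomainError(f"dt must be positive, got {self.dt}")
        for name, span, step in (
            ("(t_max - t_min)/dt", self.t_max - self.t_min, self.dt),
            ("feature_step/dt", self.feature_step, self.dt),
            (
                "(feature_hi - feature_lo)/feature_step",
                self.feature_hi - self.feature_lo,
                self.feature_step,
            ),
        ):
            ratio = span / step
            if abs(ratio - round(ratio)) > 1e-9:
                raise DomainError(f"{name} must be integral, got {ratio}")

    @property
    def n_steps(self) -> int:
        return round((self.t_max - self.t_min) / self.dt)

    def grid(self) -> np.ndarray:
        """Interpolation grid, generated by index arithmetic (no dt drift)."""
        return self.t_min + np.arange(self.n_steps + 1) * self.dt

    def feature_grid(self) -> np.ndarray:
        n = round((self.feature_hi - self.feature_lo) / self.feature_step)
        return self.feature_lo + np.arange(n + 1) * self.feature_step


@dataclass
class FeatureVector:
    """Normalized excess heat capacity sampled on the feature grid."""

    sample_id: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise DomainError(
                f"sample {self.sample_id!r}: grid and values length mismatch"
            )
        if not np.all(np.isfinite(self.values)):
            raise DomainError(f"sample {self.sample_id!r}: non-finite feature value")

    def __len__(self) -> int:
        return len(self.values)


def _window_mask(t: np.ndarray, window: tuple[float, float], what: str) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise DomainError(f"{what}: window ({lo}, {hi}) is empty")
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise DomainError(
            f"{what}: window ({lo}, {hi}) outside data span ({t[0]}, {t[-1]})"
        )
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if mask.sum() < 2:
        raise DomainError(f"{what}: window ({lo}, {hi}) contains < 2 points")
    return mask


def baseline_correct(
    t: Thermogram,
    pre_window: tuple[float, float] = DEFAULT_BASELINE_WINDOWS[0],
    post_window: tuple[float, float] = DEFAULT_BASELINE_WINDOWS[1],
) -> Thermogram:
    """Subtract the chord through the pre/post-transition window means.

    A line is fitted through (mean T, mean cp) of each window and removed
    pointwise, so a curve that is purely linear in both windows is zeroed
    there.  Windows must lie inside the measured span and hold ≥ 2 points.
    """
    temps = t.temperatures
    pre = _window_mask(temps, pre_window, f"sample {t.sample_id!r} pre-window")
    post = _window_mask(temps, post_window, f"sample {t.sample_id!r} post-window")
    x0, y0 = temps[pre].mean(), t.cp[pre].mean()
    x1, y1 = temps[post].mean(), t.cp[post].mean()
    if x1 == x0:
        raise DomainError("baseline windows have identical mean temperature")
    slope = (y1 - y0) / (x1 - x0)
    baseline = y0 + slope * (temps - x0)
    return Thermogram(t.sample_id, temps.copy(), t.cp - baseline, dict(t.meta))


def interpolate_grid(t: Thermogram, g: GridSpec) -> Thermogram:
    """Resample onto the uniform grid of ``g`` by piecewise-linear interpolation.

    The thermogram must cover [t_min, t_max]; a shortfall of up to one raw
    step at either end is tolerated (values clamped to the edge sample).
    """
    temps = t.temperatures
    raw_step = float(np.median(np.diff(temps)))
    lo, hi = t.span
    if lo > g.t_min + raw_step + 1e-9 or hi < g.t_max - raw_step - 1e-9:
        raise CoverageError(
            f"sample {t.sample_id!r} spans ({lo}, {hi}) but the grid requires "
            f"({g.t_min}, {g.t_max}); missing "
            + ", ".join(
                s
                for s, bad in (
                    (f"({g.t_min}, {lo})", lo > g.t_min + raw_step + 1e-9),
                    (f"({hi}, {g.t_max})", hi < g.t_max - raw_step - 1e-9),
                )
                if bad
            )
        )
    grid = g.grid()
    cp = np.interp(grid, temps, t.cp)
    return Thermogram(t.sample_id, grid, cp, dict(t.meta))


def trapezoid_area(t: Thermogram) -> float:
    """Trapezoidal integral of cp over the thermogram's span."""
    return float(np.trapezoid(t.cp, t.temperatures))


def area_normalize(t: Thermogram) -> Thermogram:
    """Divide cp by its trapezoidal integral so the curve has unit area.

    A non-positive area means the scan failed or is pathological and raises
    :class:`~tlbkit.errors.NormalizationError`.
    """
    area = trapezoid_area(t)
    if area <= 0:
        raise NormalizationError(
            f"sample {t.sample_id!r}: non-positive area {area:g}"
        )
    return Thermogram(t.sample_id, t.temperatures.copy(), t.cp / area, dict(t.meta))


def extract_features(t: Thermogram, g: GridSpec) -> FeatureVector:
    """Sample the (already gridded, normalized) curve at the feature temperatures."""
    fgrid = g.feature_grid()
    idx = np.round((fgrid - g.t_min) / g.dt).astype(int)
    ok = (
        (idx >= 0)
        & (idx < len(t.temperatures))
        & (np.abs(t.temperatures[np.clip(idx, 0, len(t.temperatures) - 1)] - fgrid) < 1e-9)
    )
    if not np.all(ok):
        missing = fgrid[~ok]
        raise GridMismatchError(
            f"sample {t.sample_id!r}: feature temperatures {missing.tolist()} "
            "absent from the thermogram grid (run interpolate_grid first)"
        )
    return FeatureVector(t.sample_id, fgrid, t.cp[idx])


def prepare(
    t: Thermogram,
    g: GridSpec | None = None,
    baseline: tuple[tuple[float, float], tuple[float, float]] | None = DEFAULT_BASELINE_WINDOWS,
) -> FeatureVector:
    """Full preprocessing chain: baseline → grid → area → features.

    Pass ``baseline=None`` to skip baseline correction (e.g. for curves that
    were already corrected upstream).  Deterministic; invariant to positive
    rescaling of the raw cp values.
    """
    g = g or GridSpec()
    if baseline is not None:
        t = baseline_correct(t, baseline[0], baseline[1])
    t = interpolate_grid(t, g)
    t = area_normalize(t)
    return extract_features(t, g)


def prepare_cohort(
    thermograms: list[Thermogram],
    g: GridSpec | None = None,
    baseline: tuple[tuple[float, float], tuple[float, float]] | None = DEFAULT_BASELINE_WINDOWS,
) -> list[FeatureVector]:
    """Apply :func:`prepare` to each thermogram."""
    return [prepare(t, g, baseline) for t in thermograms]
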