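"""Synthetic DSC-thermogram cohorts with controlled class structure.

Real intracystic-fluid thermograms are superpositions of the unfolding
transitions of the dissolved protein ensemble; their per-subtype envelopes
show several overlapping peaks between roughly 55 and 85 °C.  The
generator emulates this with a sum of Gaussian transition peaks plus a
linear instrument baseline and white measurement noise:

    cp(T) = Σ_m A_m · exp(−(T − Tm_m)² / (2 σ_m²))
            + baseline_slope · (T − 40) + ε,   ε ~ N(0, noise_sd²)

Per-sample biological variability enters as a Normal(0, tm_jitter_sd)
shift of every transition midpoint and a Normal(1, amp_jitter_cv)
multiplicative amplitude factor (redrawn until positive).  Class structure
is whatever distinguishes the two peak sets — a midpoint shift, an
amplitude redistribution, or nothing at all (null cohorts).

Gaussian peaks are a deliberate simplification of two-state van't Hoff
excess-heat-capacity shapes: the downstream pipeline is rank-based and
shape-agnostic, and Gaussians keep class-mean curves and areas analytic.

Raw curves are sampled at 0.1 °C — intentionally different from the
0.25 °C analysis grid, so interpolation is always exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GenerationError
from .io import NEGATIVE, POSITIVE, Cohort, Thermogram


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian denaturation transition: midpoint, width (σ), amplitude."""

    tm: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (40.0 < self.tm < 95.0):
            raise GenerationError(f"tm must lie in (40, 95) °C, got {self.tm}")
        if self.width <= 0:
            raise GenerationError(f"width must be positive, got {self.width}")
        if self.amplitude <= 0:
            raise GenerationError(f"amplitude must be positive, got {self.amplitude}")


@dataclass(frozen=True)
class CohortRecipe:
    """Parameters of one synthetic two-class cohort.

    ``confirmed_fraction`` of each class (rounded up, taken first) is marked
    as having a confirmed diagnosis; the remainder emulate high-probability
    diagnoses and end up in the validation split of the confirmed-trains
    pipeline preset.
    """

    n_per_class: int
    peaks_class0: tuple[PeakSpec, ...]
    peaks_class1: tuple[PeakSpec, ...]
    tm_jitter_sd: float = 0.5
    amp_jitter_cv: float = 0.1
    baseline_slope: float = 0.002
    noise_sd: float = 0.02
    raw_grid_step: float = 0.1
    confirmed_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise GenerationError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.noise_sd < 0:
            raise GenerationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.tm_jitter_sd < 0 or self.amp_jitter_cv < 0:
            raise GenerationError("jitter parameters must be >= 0")
        if self.raw_grid_step <= 0:
            raise GenerationError(f"raw_grid_step must be > 0, got {self.raw_grid_step}")
        if not (0.0 <= self.confirmed_fraction <= 1.0):
            raise GenerationError("confirmed_fraction must lie in [0, 1]")
        if not self.peaks_class0 or not self.peaks_class1:
            raise GenerationError("each class needs at least one peak")

    def with_seed(self, seed: int) -> "CohortRecipe":
        return replace(self, seed=seed)


def raw_grid(recipe: CohortRecipe) -> np.ndarray:
    n = round(55.0 / recipe.raw_grid_step)
    return 40.0 + np.arange(n + 1) * recipe.raw_grid_step


def mixture_curve(temps: np.ndarray, peaks: tuple[PeakSpec, ...]) -> np.ndarray:
    """Noiseless, jitter-free sum of the Gaussian peaks (no baseline)."""
    cp = np.zeros_like(temps, dtype=float)
    for p in peaks:
        cp += p.amplitude * np.exp(-((temps - p.tm) ** 2) / (2.0 * p.width**2))
    return cp


def class_mean_curve(recipe: CohortRecipe, class_index: int) -> np.ndarray:
    """Analytic expectation of a class's noiseless curve (jitter ignored)."""
    peaks = recipe.peaks_class0 if class_index == 0 else recipe.peaks_class1
    t = raw_grid(recipe)
    return mixture_curve(t, peaks) + recipe.baseline_slope * (t - 40.0)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to (0, ∞) by redraw."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise GenerationError("amplitude jitter cannot produce a positive value")


def generate_cohort(recipe: CohortRecipe) -> Cohort:
    """Draw one labeled cohort; deterministic for a fixed recipe (incl. seed).

    Class 0 samples are labeled ``negative``, class 1 ``positive``; sample
    ids are ``N00..`` / ``P00..``.  Each thermogram's meta records its
    class, confirmed flag and the recipe seed.
    """
    rng = np.random.default_rng(recipe.seed)
    temps = raw_grid(recipe)
    thermograms: list[Thermogram] = []
    labels: dict[str, str] = {}
    confirmed: dict[str, bool] = {}
    n_conf = math.ceil(recipe.confirmed_fraction * recipe.n_per_class)

    for ci, (prefix, peaks, label) in enumerate(
        (
            ("N", recipe.peaks_class0, NEGATIVE),
            ("P", recipe.peaks_class1, POSITIVE),
        )
    ):
        for s in range(recipe.n_per_class):
            cp = np.zeros_like(temps)
            for p in peaks:
                tm = p.tm + rng.normal(0.0, recipe.tm_jitter_sd) if recipe.tm_jitter_sd else p.tm
                amp = p.amplitude * _positive_normal(rng, 1.0, recipe.amp_jitter_cv)
                cp += amp * np.exp(-((temps - tm) ** 2) / (2.0 * p.width**2))
            cp += recipe.baseline_slope * (temps - 40.0)
            if recipe.noise_sd:
                cp += rng.normal(0.0, recipe.noise_sd, size=len(temps))
            sid = f"{prefix}{s:02d}"
            is_conf = s < n_conf
            thermograms.append(
                Thermogram(
                    sid,
                    temps.copy(),
                    cp,
                    meta={
                        "class": label,
                        "confirmed": str(is_conf).lower(),
                        "seed": str(recipe.seed),
                    },
                )
            )
            labels[sid] = label
            confirmed[sid] = is_conf
    return Cohort(thermograms, labels, confirmed)


def default_recipes() -> dict[str, CohortRecipe]:
    """Named study-condition recipes.

    * ``null`` — identical single-peak ensembles in both classes: no class
      signal; the pipeline's held-out AUC should hover around chance.
    * ``shifted-peak`` — class 1's single transition midpoint is shifted
      +4 °C (66 → 70 °C): the pair-recovery benchmark; selected pairs
      should straddle the shift.
    * ``envelope`` — three transitions near 62/70/77 °C whose amplitudes
      redistribute between classes, loosely mimicking multi-transition
      biofluid envelopes.
    """
    base = dict(
        n_per_class=20,
        tm_jitter_sd=0.5,
        amp_jitter_cv=0.1,
        baseline_slope=0.002,
        noise_sd=0.02,
        raw_grid_step=0.1,
        confirmed_fraction=0.6,
        seed=0,
    )
    single = (PeakSpec(tm=66.0, width=5.0, amplitude=1.0),)
    shifted = (PeakSpec(tm=70.0, width=5.0, amplitude=1.0),)
    # widths narrow enough that jittered samples keep resolved maxima
    env0 = (
        PeakSpec(tm=62.0, width=2.6, amplitude=0.9),
        PeakSpec(tm=70.0, width=2.6, amplitude=1.0),
        PeakSpec(tm=77.0, width=3.0, amplitude=0.55),
    )
    env1 = (
        PeakSpec(tm=62.0, width=2.6, amplitude=0.55),
        PeakSpec(tm=70.0, width=2.6, amplitude=0.85),
        PeakSpec(tm=77.0, width=3.0, amplitude=1.0),
    )
    return {
        "null": CohortRecipe(peaks_class0=single, peaks_class1=single, **base),
        "shifted-peak": CohortRecipe(peaks_class0=single, peaks_class1=shifted, **base),
        "envelope": CohortRecipe(peaks_class0=env0, peaks_class1=env1, **base),
    }
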