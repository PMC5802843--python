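"""Quantitative models of single-molecule RNA detection.

Three small models cover the statistics of a proximity-ligation ISH
experiment:

* a Poisson abundance calibration linking FPKM to transcript copies per cell,
  so that the fraction of cells with at least one copy is
  ``1 - exp(-c * FPKM)``;
* the composite detection efficiency of ``k`` independently acting probe
  sites, ``E = 1 - (1 - p)**k``, and its per-site inverse;
* a negative-binomial model of rolling-circle amplicon (punctum) brightness,
  the natural distribution for a replication process that terminates
  stochastically and irreversibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class CalibrationModel:
    """Poisson copies-per-FPKM calibration (reference fit: 2.5 copies/FPKM)."""

    copies_per_fpkm: float = 2.5

    def __post_init__(self) -> None:
        if not self.copies_per_fpkm > 0:
            raise ValueError("copies_per_fpkm must be positive")


def expected_copies(fpkm: float, model: CalibrationModel) -> float:
    """Expected transcript copies per cell at a given FPKM."""
    if fpkm < 0:
        raise ValueError(f"FPKM must be non-negative, got {fpkm}")
    return model.copies_per_fpkm * fpkm


def detection_fraction(fpkm: float, model: CalibrationModel) -> float:
    """Fraction of cells with at least one transcript copy.

    Under Poisson sampling with mean ``c * fpkm`` this is ``1 - exp(-c*fpkm)``:
    zero at FPKM 0, strictly increasing, approaching 1.
    """
    if fpkm < 0:
        raise ValueError(f"FPKM must be non-negative, got {fpkm}")
    return -math.expm1(-model.copies_per_fpkm * fpkm)


def fit_copies_per_fpkm(
    points: Sequence[tuple[float, int, int]],
    method: str = "mle",
) -> CalibrationModel:
    """Fit the calibration constant from (fpkm, n_cells, n_positive) data.

    The default is a binomial maximum-likelihood fit of
    ``P(positive) = 1 - exp(-c * fpkm)``; ``method="lsq"`` minimizes squared
    error on the observed fractions instead, for comparison. Deterministic.
    """
    pts = [(float(f), int(n), int(k)) for f, n, k in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 calibration points")
    for f, n, k in pts:
        if f < 0 or n <= 0 or not 0 <= k <= n:
            raise ValueError(f"invalid calibration point (fpkm={f}, n={n}, pos={k})")
    if not any(0 < k < n for f, n, k in pts if f > 0):
        raise ValueError(
            "calibration is non-identifiable: every point is saturated "
            "(fraction 0 or 1 everywhere)"
        )

    f = np.array([p[0] for p in pts])
    n = np.array([p[1] for p in pts])
    k = np.array([p[2] for p in pts])

    if method == "mle":
        def nll(log_c: float) -> float:
            c = math.exp(log_c)
            p = -np.expm1(-c * f)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())
    elif method == "lsq":
        def nll(log_c: float) -> float:
            c = math.exp(log_c)
            p = -np.expm1(-c * f)
            return float(((k / n - p) ** 2).sum())
    else:
        raise ValueError(f"unknown fit method {method!r}")

    res = optimize.minimize_scalar(nll, bounds=(math.log(1e-4), math.log(1e4)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return CalibrationModel(copies_per_fpkm=math.exp(res.x))


# ---------------------------------------------------------------------------
# probe-site efficiency algebra


def composite_efficiency(p: float, k: int) -> float:
    """Detection efficiency of k independent probe sites each succeeding with
    probability p: ``E = 1 - (1 - p)**k``."""
    if not 0 <= p <= 1:
        raise ValueError(f"per-site efficiency must be in [0, 1], got {p}")
    if k < 1:
        raise ValueError(f"number of sites must be >= 1, got {k}")
    if p == 1.0:
        return 1.0
    return -math.expm1(k * math.log1p(-p))

def per_site_efficiency(E: float, k: int) -> float:
    """Per-site efficiency implied by a composite efficiency over k sites:
    ``p = 1 - (1 - E)**(1/k)`` (exact inverse of :func:`composite_efficiency`)."""
    if not 0 <= E <= 1:
        raise ValueError(f"composite efficiency must be in [0, 1], got {E}")
    if k < 1:
        raise ValueError(f"number of sites must be >= 1, got {k}")
    if E == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-E) / k)


def round_percent(x: float) -> int:
    """Half-up rounding of a probability to a whole percent (0.0919 -> 9)."""
    return int(math.floor(100.0 * x + 0.5))


# ---------------------------------------------------------------------------
# puncta intensity statistics


@dataclass(frozen=True)
class PunctaIntensityModel:
    """Negative-binomial amplicon brightness: variance = mean + mean^2/dispersion."""

    mean: float
    dispersion: float  # NaN when undefined (zero-variance data)
    cv: float

    @property
    def dispersion_defined(self) -> bool:
        return math.isfinite(self.dispersion)


def nb_dispersion_for_cv(mean: float, cv: float) -> float:
    """Dispersion r such that NB(mean, r) has the requested coefficient of
    variation (requires cv^2 * mean > 1, i.e. overdispersion)."""
    var = (cv * mean) ** 2
    if var <= mean:
        raise ValueError("cv too small for a negative binomial at this mean")
    return mean**2 / (var - mean)


def fit_puncta_intensities(intensities: Sequence[float]) -> PunctaIntensityModel:
    """Fit a negative binomial to puncta brightness values.

    Continuous intensities are binned by rounding; the mean is fixed at the
    sample mean and the dispersion r is initialized by method of moments, then
    refined by bounded maximum likelihood. Zero-variance input yields cv=0
    with the dispersion flagged undefined (NaN) rather than an error.
    """
    x = np.asarray(list(intensities), dtype=float)
    if x.size < 50:
        raise ValueError(f"need at least 50 intensity values, got {x.size}")
    if np.any(x < 0):
        raise ValueError("intensities must be non-negative")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if v == 0.0 or m == 0.0:
        return PunctaIntensityModel(mean=m, dispersion=float("nan"), cv=0.0)
    cv = math.sqrt(v) / m
    counts = np.round(x).astype(np.int64)
    if v <= m:
        # no overdispersion: Poisson limit, r -> infinity
        return PunctaIntensityModel(mean=m, dispersion=float("inf"), cv=cv)
    r0 = m**2 / (v - m)

    def nll(log_r: float) -> float:
        r = math.exp(log_r)
        p = r / (r + m)
        return float(-stats.nbinom.logpmf(counts, r, p).sum())

    res = optimize.minimize_scalar(
        nll, bounds=(math.log(r0) - 5, math.log(r0) + 5), method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat = math.exp(res.x)
    var_hat = m + m**2 / r_hat
    return PunctaIntensityModel(mean=m, dispersion=r_hat, cv=math.sqrt(var_hat) / m)


def signal_to_background(
    puncta_peaks: Sequence[float], background_pixels: Sequence[float]
) -> float:
    """Median punctum peak amplitude over median background intensity.

    Returns ``inf`` when the background median is zero.
    """
    peaks = np.asarray(list(puncta_peaks), dtype=float)
    bg = np.asarray(list(background_pixels), dtype=float)
    if peaks.size == 0 or bg.size == 0:
        raise ValueError("both puncta peaks and background pixels must be non-empty")
    bg_med = float(np.median(bg))
    if bg_med == 0.0:
        return float("inf")
    return float(np.median(peaks)) / bg_med
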