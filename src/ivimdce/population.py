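"""Reference population statistics for benign and malignant BI-RADS 4 breast lesions.

This module holds the literature-derived per-group summary statistics of the
quantitative MRI parameters analysed by the pipeline — ROI-level summaries of
the IVIM parameters (D, D*, f), the mono-exponential ADC, and the extended-Tofts
pharmacokinetic parameters (Ktrans, kep, ve) — together with the closed-form
machinery that turns those printed summaries into sampling distributions for the
synthetic cohort generator:

* parameters reported as ``mean ± SD`` are modelled as truncated normals;
* parameters reported as ``median (Q1, Q3)`` are modelled as log-normals whose
  median and interquartile range match the printed values exactly
  (``mu = ln(median)``, ``sigma = ln(Q3/Q1) / (2 z_0.75)``);
* intra-lesion voxel heterogeneity is modelled as a mean-preserving log-normal
  multiplier whose spread is calibrated so that the *expected ROI extreme* of an
  ``n``-voxel lesion reproduces the printed min/max-row to mean-row ratios.

Units follow the reporting convention of the clinical literature: diffusion
coefficients in 1e-3 mm^2/s, perfusion fraction f in percent, Ktrans and kep in
1/min, ve dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, stats

__all__ = [
    "NormalRow",
    "SkewRow",
    "POPULATION",
    "REFERENCE_ICC",
    "ADC_MIN_CUTOFF",
    "TRUTH_PARAMS",
    "lognormal_from_quartiles",
    "expected_extreme_z",
    "heterogeneity_sigma",
    "calibrate_heterogeneity",
    "adc_from_ivim",
]

#: Standard-normal 75th percentile, used for IQR -> sigma conversion.
_Z75 = stats.norm.ppf(0.75)


@dataclass(frozen=True)
class NormalRow:
    """A ``mean ± SD`` population summary (normally distributed parameter)."""

    mean: float
    sd: float


@dataclass(frozen=True)
class SkewRow:
    """A ``median (Q1, Q3)`` population summary (right-skewed parameter).

    ``usable`` is False for rows whose printed quartiles are internally
    inconsistent (Q3 <= Q1 or quartiles not bracketing the median) and which
    must therefore be excluded from quantile matching.
    """

    median: float
    q1: float
    q3: float

    @property
    def usable(self) -> bool:
        return (self.q1 < self.q3) and (self.q1 <= self.median <= self.q3)


# Per-group ROI-summary statistics.  Keys are the analysis-table column names;
# diffusion parameters carry mean/min/max summaries, pharmacokinetic parameters
# carry min/max/median/mean summaries.
POPULATION: dict[str, dict[str, NormalRow | SkewRow]] = {
    "benign": {
        "D_mean": NormalRow(1.41, 0.27),
        "D_min": SkewRow(1.21, 1.02, 1.60),
        "D_max": NormalRow(1.51, 0.25),
        "Dstar_mean": SkewRow(27.05, 10.98, 78.65),
        "Dstar_min": SkewRow(9.88, 5.70, 31.33),
        # Printed upper quartile (29.38) sits below the median: inconsistent
        # as printed; kept for table rendering, excluded from any matching.
        "Dstar_max": SkewRow(44.65, 21.05, 29.38),
        "f_mean": SkewRow(11.00, 5.17, 15.48),
        "f_min": SkewRow(7.44, 2.89, 11.20),
        "f_max": SkewRow(16.90, 9.59, 24.48),
        "ADC_mean": NormalRow(1.52, 0.25),
        "ADC_min": NormalRow(1.46, 0.26),
        "ADC_max": NormalRow(1.58, 0.25),
        "Ktrans_min": SkewRow(0.06, 0.03, 0.09),
        "Ktrans_max": SkewRow(0.42, 0.15, 1.71),
        "Ktrans_median": SkewRow(0.19, 0.09, 0.60),
        "Ktrans_mean": SkewRow(0.20, 0.09, 0.66),
        "Kep_min": SkewRow(0.01, 0.00, 0.06),
        "Kep_max": SkewRow(0.75, 0.46, 0.97),
        "Kep_median": SkewRow(0.28, 0.19, 0.49),
        "Kep_mean": SkewRow(0.31, 0.19, 0.50),
        "Ve_min": SkewRow(0.11, 0.00, 0.32),
        "Ve_max": SkewRow(1.00, 1.00, 1.00),
        "Ve_median": SkewRow(0.75, 0.38, 1.00),
        "Ve_mean": SkewRow(0.73, 0.41, 0.93),
    },
    "malignant": {
        "D_mean": NormalRow(1.07, 0.26),
        "D_min": SkewRow(0.93, 0.74, 1.11),
        "D_max": NormalRow(1.18, 0.26),
        "Dstar_mean": SkewRow(15.20, 8.37, 28.05),
        "Dstar_min": SkewRow(7.97, 4.87, 13.38),
        "Dstar_max": SkewRow(22.50, 13.20, 46.30),
        "f_mean": SkewRow(13.70, 11.20, 19.70),
        "f_min": SkewRow(10.25, 7.94, 12.55),
        "f_max": SkewRow(17.60, 14.53, 29.15),
        "ADC_mean": NormalRow(1.28, 0.25),
        "ADC_min": NormalRow(1.22, 0.25),
        "ADC_max": NormalRow(1.35, 0.25),
        "Ktrans_min": SkewRow(0.06, 0.03, 0.18),
        "Ktrans_max": SkewRow(1.02, 0.46, 2.38),
        "Ktrans_median": SkewRow(0.35, 0.15, 0.75),
        "Ktrans_mean": SkewRow(0.39, 0.16, 0.83),
        "Kep_min": SkewRow(0.00, 0.00, 0.12),
        "Kep_max": SkewRow(1.80, 1.15, 3.07),
        "Kep_median": SkewRow(0.52, 0.37, 0.75),
        "Kep_mean": SkewRow(0.61, 0.39, 0.82),
        "Ve_min": SkewRow(0.00, 0.00, 0.28),
        "Ve_max": SkewRow(1.00, 1.00, 1.00),
        "Ve_median": SkewRow(0.68, 0.33, 0.98),
        "Ve_mean": SkewRow(0.68, 0.38, 0.87),
    },
}

#: Reference inter-reader ICC per ROI summary parameter (two radiologists,
#: two-way random effects, absolute agreement).  Used as the default target
#: agreement when simulating reader measurement noise.
REFERENCE_ICC: dict[str, float] = {
    "Ktrans_min": 0.875, "Ktrans_max": 0.865, "Ktrans_median": 0.951,
    "Ktrans_mean": 0.960, "Kep_min": 0.701, "Kep_max": 0.946,
    "Kep_median": 0.906, "Kep_mean": 0.919,
    "Ve_min": 0.844, "Ve_max": 0.876, "Ve_median": 0.991, "Ve_mean": 0.981,
    "D_mean": 0.913, "D_min": 0.911, "D_max": 0.916,
    "Dstar_mean": 0.954, "Dstar_min": 0.419, "Dstar_max": 0.867,
    "f_mean": 0.913, "f_min": 0.865, "f_max": 0.821,
    "ADC_mean": 0.999, "ADC_min": 0.997, "ADC_max": 0.997,
}

#: Literature optimal ADC_min threshold separating benign from malignant
#: BI-RADS 4 lesions, mm^2/s.
ADC_MIN_CUTOFF: float = 1.31e-3

#: Which population row defines each lesion-level ground-truth parameter,
#: together with the conversion from reported units to internal SI-style units
#: (mm^2/s for diffusion, fraction for f, 1/min for PK rates).  Ktrans is not
#: sampled directly: it is derived as kep * ve, which both ties the two rate
#: constants together (as the model relation kep = Ktrans/ve demands) and
#: reproduces the printed Ktrans summaries from the kep and ve rows
#: (e.g. malignant median 0.61 * 0.68 = 0.41 vs printed 0.39; log-spread
#: sqrt(0.55^2 + 0.61^2) = 0.82 vs printed 0.83).
TRUTH_PARAMS: dict[str, tuple[str, float]] = {
    "D": ("D_mean", 1e-3),
    "Dstar": ("Dstar_mean", 1e-3),
    "f": ("f_mean", 1e-2),
    "kep": ("Kep_mean", 1.0),
    "ve": ("Ve_mean", 1.0),
}

#: Physiological upper bound for the lesion-level pseudo-diffusion truth,
#: mm^2/s.  The matched log-normal has a heavy upper tail; draws above this
#: bound are rejected as non-physiological.
DSTAR_TRUTH_CAP: float = 0.15


def lognormal_from_quartiles(row: SkewRow) -> tuple[float, float]:
    """Return ``(mu, sigma)`` of the log-normal matching a median/IQR row.

    The log-normal median equals ``exp(mu)`` and its quartiles are
    ``exp(mu ± z_0.75 sigma)``, so the match is exact and closed-form.
    """
    if not row.usable:
        raise ValueError(f"quartiles {row} are inconsistent; cannot match")
    if row.median <= 0 or row.q1 <= 0:
        raise ValueError(f"log-normal matching requires positive quartiles: {row}")
    mu = math.log(row.median)
    sigma = math.log(row.q3 / row.q1) / (2.0 * _Z75)
    return mu, sigma


@lru_cache(maxsize=None)
def expected_extreme_z(n: int) -> float:
    """Expected maximum of ``n`` iid standard normals (by symmetry the
    expected minimum is its negative).  Computed by quadrature."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return 0.0

    def integrand(z: float) -> float:
        return n * z * stats.norm.pdf(z) * stats.norm.cdf(z) ** (n - 1)

    value, _ = integrate.quad(integrand, -12.0, 12.0, limit=200)
    return float(value)


def heterogeneity_sigma(ratio: float, n_voxels: int) -> float:
    """Solve for the voxel log-jitter sigma that makes the expected ROI
    extreme of an ``n_voxels`` lesion equal ``ratio`` times the lesion
    central value.

    With a median-centred log-normal voxel multiplier ``exp(sigma Z)``,
    the expected extreme of n voxels is ``exp(sigma z_n)`` (max side) or
    ``exp(-sigma z_n)`` (min side), with ``z_n`` the expected extreme of n
    standard normals — so ``sigma = |ln ratio| / z_n`` for either side.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    zn = expected_extreme_z(n_voxels)
    if zn == 0.0:
        raise ValueError("heterogeneity is unidentifiable from a single voxel")
    return abs(math.log(ratio)) / zn


def _central(row: NormalRow | SkewRow) -> float:
    return row.mean if isinstance(row, NormalRow) else row.median


# Rows excluded from heterogeneity calibration: the Kep_min rows are
# floor-clamped at zero by the mapping software (a reporting artefact, not
# heterogeneity).  The benign Dstar_max row's *quartiles* are inconsistent as
# printed, but calibration only uses the row's central value, which is kept.
_CALIBRATION_SKIP: set[tuple[str, str, str]] = {
    ("benign", "Kep", "min"),
    ("malignant", "Kep", "min"),
}

_FAMILY_OF = {"D": "D", "Dstar": "Dstar", "f": "f", "Ktrans": "Ktrans", "kep": "Kep"}


@lru_cache(maxsize=None)
def calibrate_heterogeneity(n_voxels: int) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group, per-parameter intra-lesion spread, calibrated so expected
    ROI extremes reproduce the population min/max-to-mean ratios.

    The voxel multiplier is a *split* log-normal — ``exp(sigma_low Z)`` for
    negative Z and ``exp(sigma_high Z)`` for positive Z — because the
    population rows are asymmetric (e.g. D_min sits proportionally farther
    below D_mean than D_max sits above it, reflecting low-diffusivity voxel
    tails).  Each side is calibrated from its own extreme row; a side with no
    usable row borrows the other side's value.  Returns
    ``{group: {param: (sigma_low, sigma_high)}}`` including ``vp`` (no
    extreme rows exist for the plasma fraction; a moderate symmetric 0.2 is
    used).
    """
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for group, rows in POPULATION.items():
        sigmas: dict[str, tuple[float, float]] = {}
        for param, family in _FAMILY_OF.items():
            centre = _central(rows[f"{family}_mean"])
            side: dict[str, float | None] = {"min": None, "max": None}
            for which in side:
                if (group, family, which) in _CALIBRATION_SKIP:
                    continue
                extreme = _central(rows[f"{family}_{which}"])
                if extreme <= 0 or centre <= 0:
                    continue
                side[which] = heterogeneity_sigma(extreme / centre, n_voxels)
            if side["min"] is None and side["max"] is None:
                raise RuntimeError(f"no usable extreme rows for {group}/{param}")
            lo = side["min"] if side["min"] is not None else side["max"]
            hi = side["max"] if side["max"] is not None else side["min"]
            sigmas[param] = (float(lo), float(hi))
        sigmas["vp"] = (0.2, 0.2)
        out[group] = sigmas
    return out


def adc_from_ivim(D: float | np.ndarray, Dstar: float | np.ndarray,
                  f: float | np.ndarray, b_high: float = 800.0):
    """Two-point apparent diffusion coefficient implied by a bi-exponential
    IVIM signal at ``b = 0`` and ``b = b_high`` (mm^2/s).

    ADC = -ln((1-f) exp(-b D) + f exp(-b (D+D*))) / b; perfusion inflates the
    ADC above D for any f > 0.
    """
    attenuation = (1.0 - f) * np.exp(-b_high * np.asarray(D)) + f * np.exp(
        -b_high * (np.asarray(D) + np.asarray(Dstar))
    )
    return -np.log(attenuation) / b_high
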