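"""Mono-exponential ADC and segmented bi-exponential IVIM fitting.

The IVIM (intravoxel incoherent motion) signal model is

    S(b) / S0 = (1 - f) exp(-b D) + f exp(-b (D + D*))

with pure diffusion coefficient D, pseudo-diffusion coefficient D* and
perfusion fraction f.  The production estimator is the classical segmented
fit: D is obtained first from a log-linear fit restricted to high b values
(where pseudo-diffusion has decayed away), then f and D* are estimated by
bounded nonlinear least squares with D held fixed.  A free four-parameter
fit is provided as a cross-check oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_B_VALUES",
    "BScheme",
    "DWISignal",
    "ADCResult",
    "IVIMResult",
    "fit_adc_two_point",
    "fit_ivim_segmented",
    "fit_ivim_full",
    "fit_adc_two_point_batch",
    "fit_ivim_segmented_batch",
]

#: Nine-point diffusion-weighting scheme, s/mm^2.
DEFAULT_B_VALUES: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0, 200.0, 400.0, 600.0, 800.0)

#: Upper bound for D and D* in the optimizer, mm^2/s (free water is ~3e-3;
#: pseudo-diffusion in breast lesions is well below 0.5).
DSTAR_UPPER = 0.5


@dataclass(frozen=True)
class BScheme:
    """An ordered set of diffusion weightings (b values, s/mm^2)."""

    b_values: tuple[float, ...] = DEFAULT_B_VALUES

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2:
            raise ValueError("a b-scheme needs at least two b values")
        if b[0] != 0.0:
            raise ValueError("the first b value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b values must be strictly increasing")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)


@dataclass(frozen=True)
class DWISignal:
    """Signal intensities sampled on a b-scheme (arbitrary units)."""

    samples: tuple[float, ...]
    scheme: BScheme = field(default_factory=BScheme)

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.scheme.b_values):
            raise ValueError("signal length must match the b-scheme")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.samples, dtype=float)

    @classmethod
    def from_arrays(cls, samples: np.ndarray, scheme: BScheme) -> "DWISignal":
        return cls(tuple(float(s) for s in np.asarray(samples)), scheme)


@dataclass(frozen=True)
class ADCResult:
    adc: float  # mm^2/s
    s0_hat: float


@dataclass(frozen=True)
class IVIMResult:
    D: float          # mm^2/s
    Dstar: float      # mm^2/s
    f: float          # fraction in [0, 1]
    s0_hat: float
    converged: bool
    rss: float


def _sorted_sb(signal: DWISignal) -> tuple[np.ndarray, np.ndarray]:
    """b-sorted (b, S) arrays; fits are invariant to input b order."""
    b = signal.scheme.array
    s = signal.array
    order = np.argsort(b)
    return b[order], s[order]


def _check_positive(s: np.ndarray) -> None:
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all signal samples must be positive and finite for fitting")


def fit_adc_two_point(signal: DWISignal, b_high: float = 800.0) -> ADCResult:
    """Mono-exponential ADC from the b=0 and b=b_high samples.

    ADC = ln(S(0)/S(b_high)) / b_high, in mm^2/s.
    """
    b, s = _sorted_sb(signal)
    if 0.0 not in b or b_high not in b:
        raise ValueError(f"scheme must contain b=0 and b={b_high:g}")
    s0 = float(s[b == 0.0][0])
    sb = float(s[b == b_high][0])
    if s0 <= 0 or sb <= 0:
        raise ValueError("two-point ADC requires positive signals at both b values")
    adc = float(np.log(s0 / sb) / b_high)
    return ADCResult(adc=adc, s0_hat=s0)


def _biexp(b: np.ndarray, s0: float, D: float, Dstar: float, f: float) -> np.ndarray:
    return s0 * ((1.0 - f) * np.exp(-b * D) + f * np.exp(-b * (D + Dstar)))


def fit_ivim_segmented(signal: DWISignal, b_threshold: float = 200.0) -> IVIMResult:
    """Two-step segmented IVIM fit.

    Step 1: ordinary least squares of ln S(b) on b, restricted to b strictly
    above ``b_threshold``, gives D (pseudo-diffusion is negligible there).
    Step 2: with D fixed, bounded nonlinear least squares over (S0, f, D*)
    on all b values, with f in [0, 1] and D* in [D, 0.5].
    """
    b, s = _sorted_sb(signal)
    _check_positive(s)
    high = b > b_threshold
    if high.sum() < 2:
        raise ValueError("need at least two b values strictly above the threshold")

    if np.ptp(s) == 0.0:
        # Flat signal: no decay, no perfusion compartment.
        return IVIMResult(D=0.0, Dstar=0.0, f=0.0, s0_hat=float(s[0]),
                          converged=True, rss=0.0)

    slope, intercept = np.polyfit(b[high], np.log(s[high]), 1)
    D = max(-float(slope), 0.0)

    s0_obs = float(s[b == 0.0][0])
    f0 = min(max(1.0 - np.exp(intercept) / s0_obs, 0.0), 1.0 - 1e-9)
    dstar0 = min(max(10.0 * D, D + 1e-9), DSTAR_UPPER)

    def residuals(theta: np.ndarray) -> np.ndarray:
        s0, f, dstar = theta
        return _biexp(b, s0, D, dstar, f) - s

    sol = least_squares(
        residuals,
        x0=np.array([s0_obs, f0, dstar0]),
        bounds=(np.array([1e-12, 0.0, D]), np.array([np.inf, 1.0, DSTAR_UPPER])),
        method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    s0_hat, f_hat, dstar_hat = (float(v) for v in sol.x)
    rss = float(np.sum(sol.fun**2))
    return IVIMResult(D=D, Dstar=dstar_hat, f=f_hat, s0_hat=s0_hat,
                      converged=bool(sol.success), rss=rss)


def fit_ivim_full(signal: DWISignal, x0: np.ndarray | None = None) -> IVIMResult:
    """Free four-parameter bi-exponential fit over (S0, D, D*, f).

    Intended as a cross-check oracle for the segmented estimator.  The two
    decay rates are unordered during optimization; the result is canonically
    ordered afterwards (D <= D*, swapping f -> 1-f if needed).  Initialized at
    the segmented solution, so its residual never exceeds the segmented one.
    """
    b, s = _sorted_sb(signal)
    _check_positive(s)

    if x0 is None:
        seg = fit_ivim_segmented(signal)
        # The free fit parametrizes the fast compartment by its absolute rate
        # (D + D* in the additive convention of the segmented model).
        x0 = np.array([seg.s0_hat, max(seg.D, 1e-9),
                       min(max(seg.D + seg.Dstar, 2e-9), DSTAR_UPPER),
                       min(max(seg.f, 0.0), 1.0)])

    def residuals(theta: np.ndarray) -> np.ndarray:
        s0, d, dstar, f = theta
        return s0 * ((1.0 - f) * np.exp(-b * d) + f * np.exp(-b * dstar)) - s

    sol = least_squares(
        residuals,
        x0=np.asarray(x0, dtype=float),
        bounds=(np.array([1e-12, 0.0, 0.0, 0.0]),
                np.array([np.inf, DSTAR_UPPER, DSTAR_UPPER, 1.0])),
        method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    s0_hat, d_hat, dstar_hat, f_hat = (float(v) for v in sol.x)
    if dstar_hat < d_hat:  # canonical order: slow compartment first
        d_hat, dstar_hat = dstar_hat, d_hat
        f_hat = 1.0 - f_hat
    rss = float(np.sum(sol.fun**2))
    # Convention above parametrizes the fast rate as D* directly; convert to
    # the additive convention D + D* used by the segmented model.
    dstar_additive = max(dstar_hat - d_hat, 0.0)
    return IVIMResult(D=d_hat, Dstar=dstar_additive, f=f_hat, s0_hat=s0_hat,
                      converged=bool(sol.success), rss=rss)


# ---------------------------------------------------------------------------
# Batched (vectorized) fitting for whole-cohort voxelwise maps.
#
# The segmented model is linear in the two compartment amplitudes once D and
# D* are fixed, so step 2 profiles the single nonlinear parameter D* by
# variable projection on a coarse-to-fine grid.  This matches the scalar
# optimizer closely and runs on all voxels of a lesion at once.


def fit_adc_two_point_batch(signals: np.ndarray, scheme: BScheme,
                            b_high: float = 800.0) -> np.ndarray:
    """Two-point ADC for a (n_voxels, n_b) signal matrix, mm^2/s."""
    b = scheme.array
    s = np.asarray(signals, dtype=float)
    if s.ndim != 2 or s.shape[1] != b.size:
        raise ValueError("signals must be (n_voxels, n_b)")
    i0 = int(np.flatnonzero(b == 0.0)[0])
    ih = np.flatnonzero(b == b_high)
    if ih.size == 0:
        raise ValueError(f"scheme must contain b={b_high:g}")
    s0 = s[:, i0]
    sb = s[:, int(ih[0])]
    if np.any(s0 <= 0) or np.any(sb <= 0):
        raise ValueError("two-point ADC requires positive signals")
    return np.log(s0 / sb) / b_high


def _profile_rss(b: np.ndarray, s: np.ndarray, D: np.ndarray,
                 dstar_cand: np.ndarray) -> tuple[np.ndarray, ...]:
    """Variable-projection evaluation of candidate D* values.

    ``dstar_cand`` has shape (n_cand, n_voxels); returns per-candidate
    amplitudes (a = S0(1-f), c = S0 f, both >= 0) and residual sums of
    squares, each (n_cand, n_voxels).
    """
    basis1 = np.exp(-b[None, :] * D[:, None])                    # (V, B)
    basis2 = np.exp(-b[None, None, :]
                    * (D[None, :, None] + dstar_cand[:, :, None]))  # (C, V, B)
    g11 = np.sum(basis1 * basis1, axis=1)                        # (V,)
    h1 = np.sum(basis1 * s, axis=1)                              # (V,)
    g12 = np.einsum("vb,cvb->cv", basis1, basis2)
    g22 = np.einsum("cvb,cvb->cv", basis2, basis2)
    h2 = np.einsum("vb,cvb->cv", s, basis2)
    det = g11[None, :] * g22 - g12**2
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    a = (g22 * h1[None, :] - g12 * h2) / det
    c = (g11[None, :] * h2 - g12 * h1[None, :]) / det
    # Non-negativity: clamp to the active-set solutions.
    a_only = h1[None, :] / g11[None, :]
    c_only = h2 / g22
    neg_c = ~(c >= 0)   # catches NaN too
    neg_a = a < 0
    a = np.where(neg_c, a_only, a)
    c = np.where(neg_c, 0.0, c)
    c = np.where(neg_a & ~neg_c, c_only, c)
    a = np.where(neg_a & ~neg_c, 0.0, a)
    ss = np.sum(s * s, axis=1)[None, :]
    rss = ss - (a * h1[None, :] + c * h2)
    # Recompute rss exactly where clamping was applied (projection identity
    # holds only at the unconstrained optimum).
    if np.any(neg_a | neg_c):
        model = a[:, :, None] * basis1[None, :, :] + c[:, :, None] * basis2
        rss_exact = np.sum((model - s[None, :, :]) ** 2, axis=2)
        rss = np.where(neg_a | neg_c, rss_exact, rss)
    return a, c, np.maximum(rss, 0.0)


def fit_ivim_segmented_batch(signals: np.ndarray, scheme: BScheme,
                             b_threshold: float = 200.0,
                             n_coarse: int = 48, n_fine: int = 24
                             ) -> dict[str, np.ndarray]:
    """Segmented IVIM fit of a (n_voxels, n_b) signal matrix.

    Step 1 is a shared log-linear regression over b > b_threshold; step 2
    profiles D* by variable projection on a log-spaced coarse grid refined
    around the per-voxel optimum.  Returns arrays D, Dstar, f, s0 (internal
    units) plus rss.
    """
    b = scheme.array
    order = np.argsort(b)
    b = b[order]
    s = np.asarray(signals, dtype=float)[:, order]
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all signal samples must be positive and finite")
    high = b > b_threshold
    if high.sum() < 2:
        raise ValueError("need at least two b values strictly above the threshold")

    X = np.column_stack([b[high], np.ones(high.sum())])
    coef, *_ = np.linalg.lstsq(X, np.log(s[:, high]).T, rcond=None)
    D = np.maximum(-coef[0], 0.0)

    lo = np.maximum(D, 1e-6)
    grid01 = np.linspace(0.0, 1.0, n_coarse)
    cand = np.exp(np.log(lo)[None, :]
                  + grid01[:, None] * (np.log(DSTAR_UPPER) - np.log(lo))[None, :])
    a, c, rss = _profile_rss(b, s, D, cand)
    best = np.argmin(rss, axis=0)
    v_idx = np.arange(s.shape[0])

    # Refine between the coarse neighbours of the winner.
    lo_ref = cand[np.maximum(best - 1, 0), v_idx]
    hi_ref = cand[np.minimum(best + 1, n_coarse - 1), v_idx]
    grid01f = np.linspace(0.0, 1.0, n_fine)
    cand_f = np.exp(np.log(lo_ref)[None, :]
                    + grid01f[:, None] * (np.log(hi_ref) - np.log(lo_ref))[None, :])
    a_f, c_f, rss_f = _profile_rss(b, s, D, cand_f)
    best_f = np.argmin(rss_f, axis=0)

    dstar = cand_f[best_f, v_idx]
    a_b = a_f[best_f, v_idx]
    c_b = c_f[best_f, v_idx]
    s0 = a_b + c_b
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(s0 > 0, c_b / s0, 0.0)
    f = np.clip(f, 0.0, 1.0)
    return {"D": D, "Dstar": np.maximum(dstar, D), "f": f, "s0": s0,
            "rss": rss_f[best_f, v_idx]}
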