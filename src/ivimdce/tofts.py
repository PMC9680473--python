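"""Extended Tofts pharmacokinetic modelling of DCE-MRI concentration curves.

The extended Tofts model describes the tissue tracer concentration as

    Ct(t) = vp Cp(t) + Ktrans \int_0^t Cp(tau) exp(-kep (t - tau)) dtau

with volume transfer constant Ktrans (1/min), rate constant kep = Ktrans/ve
(1/min), extravascular-extracellular volume fraction ve and plasma volume
fraction vp.  The production estimator is the Murase linearization: integrate
the model equation once and solve

    Ct(t) = alpha \int_0^t Cp + beta \int_0^t Ct + gamma Cp(t)

by linear least squares, with kep = -beta, vp = gamma and
Ktrans = alpha - kep vp.  The pipeline operates directly in concentration
space (mM); conversion from signal intensity is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "TimeGrid",
    "AIFModel",
    "TissueCurve",
    "ETMResult",
    "PARKER_PARAMS",
    "parker_aif",
    "etm_forward",
    "fit_etm_linear",
    "derive_ve",
    "etm_forward_batch",
    "fit_etm_linear_batch",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform DCE sampling grid.

    Defaults follow a 7.84 s/frame acquisition of 42 frames (about 5 min
    29 s) with the contrast bolus given at the start of the fourth frame;
    the first three frames are pre-contrast baseline.
    """

    dt: float = 7.84            # seconds per frame
    n_frames: int = 42
    injection_frame: int = 4    # 1-based

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.injection_frame < 2:
            raise ValueError("injection_frame must be >= 2 (need baseline frames)")
        if self.n_frames < self.injection_frame:
            raise ValueError("grid ends before the injection frame")

    @property
    def times_s(self) -> np.ndarray:
        """Frame start times in seconds (frame 1 at t=0)."""
        return np.arange(self.n_frames) * self.dt

    @property
    def times_min(self) -> np.ndarray:
        return self.times_s / 60.0

    @property
    def injection_time_s(self) -> float:
        return (self.injection_frame - 1) * self.dt

    def n_post_injection(self) -> int:
        return self.n_frames - (self.injection_frame - 1)


#: Population arterial input function coefficients (two Gaussian boluses plus
#: a sigmoid-modulated exponential washout; time in minutes, output in mM).
PARKER_PARAMS: dict[str, float] = {
    "A1": 0.809, "T1": 0.17046, "sigma1": 0.0563,
    "A2": 0.330, "T2": 0.365, "sigma2": 0.132,
    "alpha": 1.050, "beta": 0.1685, "s": 38.078, "tau": 0.483,
}


@dataclass(frozen=True)
class AIFModel:
    """Arterial input function: plasma concentration Cp(t), mM.

    Forms: ``parker`` (population mixture model), ``biexponential``
    (Weinmann-style ``dose * (a1 e^{-m1 t} + a2 e^{-m2 t})``) or
    ``tabulated`` (explicit per-frame values).
    """

    form: str = "parker"
    params: dict = field(default_factory=dict)

    def evaluate(self, grid: TimeGrid) -> "TissueCurve":
        t_min = grid.times_min - grid.injection_time_s / 60.0
        if self.form == "parker":
            p = {**PARKER_PARAMS, **self.params}
            cp = _parker_curve(np.maximum(t_min, 0.0), p)
        elif self.form == "biexponential":
            p = {"dose": 1.0, "a1": 3.99, "m1": 0.144, "a2": 4.78, "m2": 0.0111}
            p.update(self.params)
            tt = np.maximum(t_min, 0.0)
            cp = p["dose"] * (p["a1"] * np.exp(-p["m1"] * tt)
                              + p["a2"] * np.exp(-p["m2"] * tt))
        elif self.form == "tabulated":
            cp = np.asarray(self.params["values"], dtype=float)
            if cp.shape != (grid.n_frames,):
                raise ValueError("tabulated AIF length must match the grid")
        else:
            raise ValueError(f"unknown AIF form: {self.form!r}")
        cp = np.where(t_min < 0.0, 0.0, cp)
        if np.any(cp < 0):
            raise ValueError("AIF must be non-negative")
        return TissueCurve(conc=tuple(float(c) for c in cp), grid=grid)


def _parker_curve(t: np.ndarray, p: dict[str, float]) -> np.ndarray:
    gauss1 = p["A1"] / (p["sigma1"] * np.sqrt(2 * np.pi)) * np.exp(
        -((t - p["T1"]) ** 2) / (2 * p["sigma1"] ** 2))
    gauss2 = p["A2"] / (p["sigma2"] * np.sqrt(2 * np.pi)) * np.exp(
        -((t - p["T2"]) ** 2) / (2 * p["sigma2"] ** 2))
    washout = p["alpha"] * np.exp(-p["beta"] * t) / (1 + np.exp(-p["s"] * (t - p["tau"])))
    return gauss1 + gauss2 + washout


@dataclass(frozen=True)
class TissueCurve:
    """A concentration-time curve (mM) on a fixed grid."""

    conc: tuple[float, ...]
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        if len(self.conc) != self.grid.n_frames:
            raise ValueError("curve length must match the time grid")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.conc, dtype=float)

    @classmethod
    def from_array(cls, conc: np.ndarray, grid: TimeGrid) -> "TissueCurve":
        return cls(tuple(float(c) for c in np.asarray(conc)), grid)


@dataclass(frozen=True)
class ETMResult:
    Ktrans: float      # 1/min
    kep: float         # 1/min
    ve: float          # fraction in [0, 1]
    vp: float          # fraction
    converged: bool
    rss: float
    clamped: bool = False  # quality flag: negative Ktrans/vp clamped to 0


def parker_aif(grid: TimeGrid, params: dict | None = None) -> TissueCurve:
    """Population AIF evaluated on the grid; zero before the injection frame."""
    return AIFModel(form="parker", params=params or {}).evaluate(grid)


def _exp_convolution(cp: np.ndarray, kep: float, dt_min: float) -> np.ndarray:
    """Exact ``\int_0^t Cp(tau) e^{-kep (t-tau)} dtau`` for piecewise-linear Cp.

    Uses the closed-form update over each linear segment, which is exact for
    the linear interpolant of Cp and therefore grid-convergent.
    """
    n = cp.size
    out = np.zeros(n)
    a = kep * dt_min
    decay = np.exp(-a)
    if a < 1e-12:
        seg_const = dt_min
        seg_lin = dt_min / 2.0
    else:
        w = (1.0 - decay) / a           # mean of e^{-kep(dt-u)} over the segment
        seg_const = dt_min * w
        seg_lin = dt_min * (1.0 - w) / a
    for k in range(1, n):
        c0, c1 = cp[k - 1], cp[k]
        increment = c0 * seg_const + (c1 - c0) * seg_lin
        out[k] = out[k - 1] * decay + increment
    return out


def etm_forward(Ktrans: float, kep: float, vp: float, cp: TissueCurve) -> TissueCurve:
    """Noiseless extended-Tofts tissue curve for a given plasma input."""
    if kep <= 0:
        raise ValueError("kep must be positive")
    grid = cp.grid
    dt_min = grid.dt / 60.0
    conv = _exp_convolution(cp.array, kep, dt_min)
    ct = vp * cp.array + Ktrans * conv
    return TissueCurve.from_array(ct, grid)


def fit_etm_linear(ct: TissueCurve, cp: TissueCurve) -> ETMResult:
    """Murase linear least-squares estimator of (Ktrans, kep, ve, vp).

    Builds cumulative-trapezoid integrals of Cp and Ct on the grid (minutes)
    and solves the integrated model equation.  ``converged`` is False when
    kep <= 0, the design matrix is rank-deficient, or the curve carries no
    signal; negative Ktrans/vp estimates are clamped to zero with the
    ``clamped`` quality flag set.
    """
    if ct.grid != cp.grid:
        raise ValueError("tissue and plasma curves must share a time grid")
    grid = ct.grid
    if grid.n_post_injection() < 10:
        raise ValueError("need at least 10 post-injection frames")
    t = grid.times_min
    ct_a = ct.array
    cp_a = cp.array

    if not np.any(ct_a != 0.0):
        return ETMResult(0.0, 0.0, 0.0, 0.0, converged=False, rss=0.0)

    design = np.column_stack([
        cumulative_trapezoid(cp_a, t, initial=0.0),
        cumulative_trapezoid(ct_a, t, initial=0.0),
        cp_a,
    ])
    coef, residual, rank, _ = np.linalg.lstsq(design, ct_a, rcond=None)
    rss = float(np.sum((design @ coef - ct_a) ** 2))
    alpha, beta, gamma = (float(c) for c in coef)
    kep = -beta
    vp = gamma
    Ktrans = alpha - kep * vp

    converged = bool(rank == 3 and kep > 0.0)
    clamped = False
    if Ktrans < 0.0:
        Ktrans, clamped = 0.0, True
    if vp < 0.0:
        vp, clamped = 0.0, True
    ve = derive_ve(Ktrans, kep) if kep > 0.0 else 0.0
    return ETMResult(Ktrans=Ktrans, kep=max(kep, 0.0), ve=ve, vp=vp,
                     converged=converged, rss=rss, clamped=clamped)


def derive_ve(Ktrans: float, kep: float) -> float:
    """ve = Ktrans / kep, clamped to [0, 1] (full extracellular space)."""
    if kep <= 0:
        raise ValueError("kep must be positive to derive ve")
    return float(min(max(Ktrans / kep, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Batched (vectorized) forward simulation and fitting for whole-lesion maps.


def etm_forward_batch(Ktrans: np.ndarray, kep: np.ndarray, vp: np.ndarray,
                      cp: TissueCurve) -> np.ndarray:
    """Noiseless extended-Tofts curves for parameter vectors.

    Returns a (n_voxels, n_frames) concentration matrix; the exponential
    convolution recursion (exact for piecewise-linear Cp) is evaluated for
    all voxels at once, frame by frame.
    """
    Ktrans = np.asarray(Ktrans, dtype=float)
    kep = np.asarray(kep, dtype=float)
    vp = np.asarray(vp, dtype=float)
    if np.any(kep <= 0):
        raise ValueError("kep must be positive")
    grid = cp.grid
    dt_min = grid.dt / 60.0
    cp_a = cp.array
    n_frames = grid.n_frames

    a = kep * dt_min
    decay = np.exp(-a)
    w = np.where(a < 1e-12, 1.0, (1.0 - decay) / np.where(a < 1e-12, 1.0, a))
    seg_const = dt_min * w
    seg_lin = np.where(a < 1e-12, dt_min / 2.0, dt_min * (1.0 - w) / np.where(a < 1e-12, 1.0, a))

    conv = np.zeros((Ktrans.size, n_frames))
    for k in range(1, n_frames):
        c0, c1 = cp_a[k - 1], cp_a[k]
        conv[:, k] = conv[:, k - 1] * decay + c0 * seg_const + (c1 - c0) * seg_lin
    return vp[:, None] * cp_a[None, :] + Ktrans[:, None] * conv


def fit_etm_linear_batch(cts: np.ndarray, cp: TissueCurve) -> dict[str, np.ndarray]:
    """Murase linear estimator applied to a (n_voxels, n_frames) matrix.

    Solves the per-voxel 3x3 normal equations in one batched call; returns
    arrays Ktrans, kep, ve, vp and converged flags with the same clamping
    semantics as :func:`fit_etm_linear`.
    """
    grid = cp.grid
    t = grid.times_min
    cts = np.asarray(cts, dtype=float)
    if cts.ndim != 2 or cts.shape[1] != grid.n_frames:
        raise ValueError("cts must be (n_voxels, n_frames)")
    if grid.n_post_injection() < 10:
        raise ValueError("need at least 10 post-injection frames")
    cp_a = cp.array
    n_vox = cts.shape[0]

    x1 = cumulative_trapezoid(cp_a, t, initial=0.0)          # shared
    x3 = cp_a                                                # shared
    x2 = cumulative_trapezoid(cts, t, initial=0.0, axis=1)   # per voxel

    # Normal equations G theta = h with G symmetric 3x3 per voxel.
    g11 = float(x1 @ x1)
    g13 = float(x1 @ x3)
    g33 = float(x3 @ x3)
    g12 = x2 @ x1
    g23 = x2 @ x3
    g22 = np.einsum("vt,vt->v", x2, x2)
    h1 = cts @ x1
    h3 = cts @ x3
    h2 = np.einsum("vt,vt->v", x2, cts)

    G = np.empty((n_vox, 3, 3))
    G[:, 0, 0] = g11; G[:, 0, 1] = g12; G[:, 0, 2] = g13
    G[:, 1, 0] = g12; G[:, 1, 1] = g22; G[:, 1, 2] = g23
    G[:, 2, 0] = g13; G[:, 2, 1] = g23; G[:, 2, 2] = g33
    h = np.stack([h1, h2, h3], axis=1)

    ok = np.linalg.matrix_rank(G) == 3
    theta = np.zeros((n_vox, 3))
    if np.any(ok):
        theta[ok] = np.linalg.solve(G[ok], h[ok][..., None])[..., 0]
    alpha, beta, gamma = theta[:, 0], theta[:, 1], theta[:, 2]
    kep = -beta
    vp = gamma
    Ktrans = alpha - kep * vp

    silent = ~np.any(cts != 0.0, axis=1)
    converged = ok & (kep > 0.0) & ~silent
    Ktrans = np.where(silent, 0.0, np.maximum(Ktrans, 0.0))
    vp = np.where(silent, 0.0, np.maximum(vp, 0.0))
    kep_pos = np.maximum(kep, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ve = np.where(kep > 0, np.clip(Ktrans / np.where(kep > 0, kep, 1.0), 0.0, 1.0), 0.0)
    return {"Ktrans": Ktrans, "kep": kep_pos, "ve": ve, "vp": vp,
            "converged": converged}
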