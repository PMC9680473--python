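"""Synthetic BI-RADS 4 lesion cohort generator.

Builds a fully synthetic stand-in for a 20-benign / 80-malignant breast-lesion
cohort: per-lesion ground-truth diffusion (D, D*, f) and pharmacokinetic
(Ktrans, kep, vp) parameters drawn from the reference population statistics,
voxelwise parameter maps with calibrated intra-lesion heterogeneity, forward
simulated multi-b DWI signals with Rician noise, extended-Tofts concentration
curves with additive Gaussian noise, and simulated two-reader ROI
measurements with agreement calibrated to the reference inter-reader ICCs.

Every draw flows from a single seeded ``numpy.random.Generator``, so a fixed
seed reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffusion import BScheme, DWISignal
from .population import (
    DSTAR_TRUTH_CAP,
    POPULATION,
    REFERENCE_ICC,
    TRUTH_PARAMS,
    NormalRow,
    SkewRow,
    adc_from_ivim,
    calibrate_heterogeneity,
    lognormal_from_quartiles,
)
from .roi import DIFFUSION_STATS, PK_STATS
from .tofts import (
    AIFModel,
    TimeGrid,
    TissueCurve,
    etm_forward,
    etm_forward_batch,
    parker_aif,
)

__all__ = [
    "GROUPS",
    "LesionTruth",
    "CohortConfig",
    "Cohort",
    "sample_lesion_truth",
    "dwi_forward",
    "dce_forward",
    "add_rician",
    "generate_cohort",
    "generate_summary_cohort",
    "simulate_readers",
]

GROUPS = ("benign", "malignant")

#: Plasma volume fraction sampling range (not reported for this population;
#: a physiologically modest range is used so the extended model is exercised).
VP_RANGE = (0.005, 0.05)

_MAX_REJECT = 10_000


@dataclass(frozen=True)
class LesionTruth:
    """Ground-truth parameters of one synthetic lesion (SI-style units:
    diffusion in mm^2/s, f/vp as fractions, PK rates in 1/min)."""

    lesion_id: str
    group: str
    D: float
    Dstar: float
    f: float
    Ktrans: float
    kep: float
    vp: float
    n_voxels: int = 60
    intra_sigma: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (self.D > 0 and self.Dstar >= self.D):
            raise ValueError("require D > 0 and D* >= D")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must lie in [0, 1]")
        if self.Ktrans < 0 or self.kep <= 0:
            raise ValueError("require Ktrans >= 0 and kep > 0")
        if not (0.0 <= self.vp <= 0.1):
            raise ValueError("vp must lie in [0, 0.1]")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be positive")

    @property
    def ve(self) -> float:
        return min(max(self.Ktrans / self.kep, 0.0), 1.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_benign: int = 20
    n_malignant: int = 80
    seed: int = 20221031
    S0: float = 1000.0            # baseline DWI signal, a.u.
    # Effective per-voxel noise of the *parameter-map source data*.  These
    # emulate vendor maps after spatial filtering, so they sit well above
    # raw-acquisition SNR; they are chosen so that measured ROI extreme/mean
    # ratios stay consistent with the reference population's min/max rows.
    rician_sigma: float = 5.0     # DWI noise scale (SNR 200 at S0=1000)
    conc_sigma: float = 0.02      # concentration noise SD, mM
    n_voxels: int = 60
    intra_cv: float | None = None  # scalar override of calibrated heterogeneity
    width_scale: float = 1.0      # scales all population spreads (0 = degenerate)
    b_scheme: BScheme = field(default_factory=BScheme)
    time_grid: TimeGrid = field(default_factory=TimeGrid)
    aif: AIFModel = field(default_factory=AIFModel)

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_malignant < 1:
            raise ValueError("cohort needs at least one lesion per group")
        if self.rician_sigma < 0 or self.conc_sigma < 0:
            raise ValueError("noise scales must be non-negative")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be positive")
        if self.width_scale < 0:
            raise ValueError("width_scale must be non-negative")


@dataclass
class Cohort:
    """A generated cohort: truth table, voxel maps, signals and curves."""

    config: CohortConfig
    truth: pd.DataFrame                       # one row per lesion
    voxel_params: dict[str, pd.DataFrame]     # lesion_id -> voxel truth table
    dwi_signals: dict[str, np.ndarray]        # lesion_id -> (n_voxels, n_b)
    dce_curves: dict[str, np.ndarray]         # lesion_id -> (n_voxels, n_frames)
    cp: TissueCurve                           # shared plasma input


def _sample_param(row: NormalRow | SkewRow, rng: np.random.Generator,
                  width_scale: float) -> float:
    if isinstance(row, NormalRow):
        sd = row.sd * width_scale
        if sd == 0.0:
            return row.mean
        for _ in range(_MAX_REJECT):
            x = rng.normal(row.mean, sd)
            if x > 0:
                return float(x)
        raise RuntimeError("rejection sampling failed for a truncated normal")
    mu, sigma = lognormal_from_quartiles(row)
    return float(np.exp(mu + sigma * width_scale * rng.standard_normal()))


def sample_lesion_truth(group: str, rng: np.random.Generator, *,
                        lesion_id: str = "lesion",
                        n_voxels: int = 60,
                        width_scale: float = 1.0,
                        intra_cv: float | None = None) -> LesionTruth:
    """Draw one lesion's ground-truth parameter set for a diagnostic group.

    Normal parameters come from truncated normals at the group mean +/- SD;
    skewed parameters from log-normals matched to the group median and IQR.
    Invariants (D* >= D, f in [0,1]) are enforced by rejection.  With
    ``width_scale=0`` every parameter equals its group central value.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    rows = POPULATION[group]
    for _ in range(_MAX_REJECT):
        draws = {
            name: scale * _sample_param(rows[row_key], rng, width_scale)
            for name, (row_key, scale) in TRUTH_PARAMS.items()
        }
        if not (draws["D"] < draws["Dstar"] <= DSTAR_TRUTH_CAP
                and 0.0 <= draws["f"] <= 1.0 and draws["kep"] > 0.0):
            continue
        # Ktrans is tied to kep through the extracellular fraction.
        ve = min(draws.pop("ve"), 1.0)
        draws["Ktrans"] = draws["kep"] * ve
        vp = float(rng.uniform(*VP_RANGE))
        jitter_params = ("D", "Dstar", "f", "Ktrans", "kep", "vp")
        if intra_cv is not None:
            sigma = {p: (float(intra_cv), float(intra_cv)) for p in jitter_params}
        else:
            sigma = dict(calibrate_heterogeneity(n_voxels)[group])
        return LesionTruth(lesion_id=lesion_id, group=group, n_voxels=n_voxels,
                           vp=vp, intra_sigma=sigma, **draws)
    raise RuntimeError("rejection sampling failed to satisfy lesion invariants")


def dwi_forward(truth: LesionTruth, b_scheme: BScheme | None = None,
                S0: float = 1000.0) -> DWISignal:
    """Noiseless bi-exponential IVIM signal for a lesion's truth parameters."""
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    scheme = b_scheme or BScheme()
    b = scheme.array
    s = S0 * ((1.0 - truth.f) * np.exp(-b * truth.D)
              + truth.f * np.exp(-b * (truth.D + truth.Dstar)))
    return DWISignal.from_arrays(s, scheme)


def dce_forward(truth: LesionTruth, cp: TissueCurve) -> TissueCurve:
    """Noiseless extended-Tofts tissue curve for a lesion's truth parameters.

    Zero over the pre-injection baseline frames because the plasma input is.
    """
    if truth.kep <= 0:
        raise ValueError("kep must be positive")
    return etm_forward(truth.Ktrans, truth.kep, truth.vp, cp)


def add_rician(signal: DWISignal, sigma: float,
               rng: np.random.Generator) -> DWISignal:
    """Apply magnitude-MRI (Rician) noise: sqrt((S+n1)^2 + n2^2)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return signal
    s = signal.array
    n1 = rng.normal(0.0, sigma, size=s.shape)
    n2 = rng.normal(0.0, sigma, size=s.shape)
    return DWISignal.from_arrays(np.sqrt((s + n1) ** 2 + n2**2), signal.scheme)


_VOXEL_PARAMS = ("D", "Dstar", "f", "Ktrans", "kep", "vp")


def _voxel_table(truth: LesionTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Per-voxel parameters: split log-normal jitter around the lesion truth
    (independent lower/upper spreads, median at the lesion value)."""
    n = truth.n_voxels
    cols = {}
    for p in _VOXEL_PARAMS:
        sig = truth.intra_sigma.get(p, 0.0)
        lo, hi = (sig if isinstance(sig, (tuple, list)) else (sig, sig))
        centre = getattr(truth, p)
        if lo == 0.0 and hi == 0.0:
            cols[p] = np.full(n, centre)
        else:
            z = rng.standard_normal(n)
            mult = np.exp(np.where(z < 0.0, lo * z, hi * z))
            cols[p] = centre * mult
    df = pd.DataFrame(cols)
    df["f"] = df["f"].clip(upper=1.0)
    df["Dstar"] = np.maximum(df["Dstar"], df["D"])
    df["ve"] = (df["Ktrans"] / df["kep"]).clip(0.0, 1.0)
    return df


def generate_cohort(config: CohortConfig,
                    rng: np.random.Generator | None = None) -> Cohort:
    """Generate the full voxel-level cohort: truth, DWI signals, DCE curves.

    Deterministic given ``config.seed`` (or an explicitly supplied generator).
    """
    rng = rng or np.random.default_rng(config.seed)
    cp = config.aif.evaluate(config.time_grid)
    labels = ["benign"] * config.n_benign + ["malignant"] * config.n_malignant

    truth_rows = []
    voxel_params: dict[str, pd.DataFrame] = {}
    dwi_signals: dict[str, np.ndarray] = {}
    dce_curves: dict[str, np.ndarray] = {}

    for i, group in enumerate(labels):
        lesion_id = f"L{i + 1:03d}"
        truth = sample_lesion_truth(
            group, rng, lesion_id=lesion_id, n_voxels=config.n_voxels,
            width_scale=config.width_scale, intra_cv=config.intra_cv)
        truth_rows.append({
            "lesion_id": lesion_id, "group": group, "D": truth.D,
            "Dstar": truth.Dstar, "f": truth.f, "Ktrans": truth.Ktrans,
            "kep": truth.kep, "vp": truth.vp, "ve": truth.ve,
            "n_voxels": truth.n_voxels,
        })
        voxels = _voxel_table(truth, rng)
        voxel_params[lesion_id] = voxels

        b = config.b_scheme.array
        D = voxels["D"].to_numpy()
        Ds = voxels["Dstar"].to_numpy()
        f = voxels["f"].to_numpy()
        clean = config.S0 * ((1.0 - f)[:, None] * np.exp(-b[None, :] * D[:, None])
                             + f[:, None] * np.exp(-b[None, :] * (D + Ds)[:, None]))
        if config.rician_sigma > 0:
            n1 = rng.normal(0.0, config.rician_sigma, size=clean.shape)
            n2 = rng.normal(0.0, config.rician_sigma, size=clean.shape)
            sig = np.sqrt((clean + n1) ** 2 + n2**2)
        else:
            sig = clean
        cur = etm_forward_batch(voxels["Ktrans"].to_numpy(),
                                voxels["kep"].to_numpy(),
                                voxels["vp"].to_numpy(), cp)
        if config.conc_sigma > 0:
            cur = cur + rng.normal(0.0, config.conc_sigma, size=cur.shape)
        dwi_signals[lesion_id] = sig
        dce_curves[lesion_id] = cur

    truth_df = pd.DataFrame(truth_rows)
    return Cohort(config=config, truth=truth_df, voxel_params=voxel_params,
                  dwi_signals=dwi_signals, dce_curves=dce_curves, cp=cp)


def _summary_row(voxels: pd.DataFrame) -> dict[str, float]:
    """Analytic ROI summaries of a voxel truth table, in reported units
    (diffusion x1e3 mm^2/s, f in %, PK in native units)."""
    out: dict[str, float] = {}
    adc = adc_from_ivim(voxels["D"].to_numpy(), voxels["Dstar"].to_numpy(),
                        voxels["f"].to_numpy())
    series = {
        "D": voxels["D"].to_numpy() * 1e3,
        "Dstar": voxels["Dstar"].to_numpy() * 1e3,
        "f": voxels["f"].to_numpy() * 1e2,
        "ADC": adc * 1e3,
        "Ktrans": voxels["Ktrans"].to_numpy(),
        "Kep": voxels["kep"].to_numpy(),
        "Ve": voxels["ve"].to_numpy(),
    }
    for family, values in series.items():
        stats_wanted = DIFFUSION_STATS if family in ("D", "Dstar", "f", "ADC") else PK_STATS
        for stat in stats_wanted:
            fn = {"mean": np.mean, "min": np.min, "max": np.max,
                  "median": np.median}[stat]
            out[f"{family}_{stat}"] = float(fn(values))
    return out


def generate_summary_cohort(config: CohortConfig,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fast parameter-level cohort: lesion truths -> voxel jitter -> ROI
    summaries, skipping signal synthesis and curve fitting.

    Intended for large repeated-cohort studies of the statistical machinery;
    the signal-level route (``generate_cohort`` plus the fitting modules)
    exercises the full measurement chain.
    """
    rng = rng or np.random.default_rng(config.seed)
    labels = ["benign"] * config.n_benign + ["malignant"] * config.n_malignant
    rows = []
    for i, group in enumerate(labels):
        lesion_id = f"L{i + 1:03d}"
        truth = sample_lesion_truth(
            group, rng, lesion_id=lesion_id, n_voxels=config.n_voxels,
            width_scale=config.width_scale, intra_cv=config.intra_cv)
        row = {"lesion_id": lesion_id, "group": group}
        row.update(_summary_row(_voxel_table(truth, rng)))
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_readers(summaries: pd.DataFrame, rng: np.random.Generator,
                     target_icc: dict[str, float] | None = None,
                     n_readers: int = 2) -> pd.DataFrame:
    """Simulate per-reader ROI measurements with prescribed agreement.

    For each parameter column, each reader observes the true summary plus
    independent Gaussian noise with SD ``sigma_b * sqrt((1-ICC)/ICC)``, where
    ``sigma_b`` is the between-lesion SD — so the expected two-way
    single-measure ICC equals the target (reference ICCs by default).

    Returns a long table (lesion_id, reader, parameter, value).
    """
    target_icc = dict(REFERENCE_ICC if target_icc is None else target_icc)
    param_cols = [c for c in summaries.columns if c not in ("lesion_id", "group")]
    records = []
    for col in param_cols:
        icc = float(target_icc.get(col, 1.0))
        if not (0.0 < icc <= 1.0):
            raise ValueError(f"target ICC for {col} must be in (0, 1]")
        values = summaries[col].to_numpy(dtype=float)
        sigma_b = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        sigma_w = sigma_b * np.sqrt((1.0 - icc) / icc)
        for reader in range(1, n_readers + 1):
            noise = rng.normal(0.0, sigma_w, size=values.shape) if sigma_w > 0 else 0.0
            measured = values + noise
            for lesion_id, value in zip(summaries["lesion_id"], measured):
                records.append({"lesion_id": lesion_id, "reader": reader,
                                "parameter": col, "value": float(value)})
    return pd.DataFrame.from_records(records)
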