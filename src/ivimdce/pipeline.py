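"""End-to-end orchestration, configuration and file I/O.

The pipeline chains: simulate -> fit DWI (ADC + segmented IVIM, voxelwise)
-> fit DCE (linear extended Tofts, voxelwise) -> ROI summaries -> simulated
two-reader measurements -> ICC screening -> group comparison -> diagnostic
model building and comparison.  All intermediate tables are CSV
(RFC 4180, UTF-8) with a comment header carrying the configuration hash;
voxelwise maps can optionally be written as NIfTI-1 volumes.

Unit convention for reported tables: D/D*/ADC in 1e-3 mm^2/s, f in percent,
Ktrans and kep in 1/min, ve dimensionless.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import icc_table, screen_parameters
from .cohort import Cohort, CohortConfig, generate_cohort, simulate_readers
from .comparison import compare_table
from .diagnostics import evaluate_models
from .diffusion import fit_adc_two_point_batch, fit_ivim_segmented_batch
from .roi import DIFFUSION_STATS, PK_STATS, ParamMap, summarize_map
from .tofts import fit_etm_linear_batch

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "fit_dwi_cohort",
    "fit_dce_cohort",
    "summarize_cohort",
    "read_lesion_table",
    "write_table",
    "write_param_map_nifti",
]

#: Scale factors from internal units to reported units, by column prefix.
REPORT_SCALE = {"D_": 1e3, "Dstar_": 1e3, "ADC_": 1e3, "f_": 1e2,
                "Ktrans_": 1.0, "Kep_": 1.0, "Ve_": 1.0}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    b_threshold: float = 200.0
    icc_cutoff: float = 0.75
    outdir: str = "ivimdce_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # Nested non-scalar fields serialize by their defining parameters.
        d["cohort"]["b_scheme"] = list(self.cohort.b_scheme.b_values)
        d["cohort"]["time_grid"] = dataclasses.asdict(self.cohort.time_grid)
        d["cohort"]["aif"] = {"form": self.cohort.aif.form,
                              "params": dict(self.cohort.aif.params)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .diffusion import BScheme
        from .tofts import AIFModel, TimeGrid
        d = dict(d)
        c = dict(d.pop("cohort", {}))
        if "b_scheme" in c:
            c["b_scheme"] = BScheme(tuple(float(b) for b in c["b_scheme"]))
        if "time_grid" in c:
            c["time_grid"] = TimeGrid(**c["time_grid"])
        if "aif" in c:
            c["aif"] = AIFModel(**c["aif"])
        return cls(cohort=CohortConfig(**c), **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    stage_counts: dict[str, int]
    warnings: list[str]
    screened: list[str]
    tables: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# Fitting stages


def fit_dwi_cohort(cohort: Cohort, b_threshold: float = 200.0) -> dict[str, pd.DataFrame]:
    """Voxelwise ADC and segmented IVIM fits for every lesion.

    Returns ``{lesion_id: DataFrame(voxel, ADC, D, Dstar, f)}`` in internal
    units (mm^2/s, fractions).  Uses the batched variable-projection fitter,
    which matches the per-voxel optimizer (see the diffusion module tests).
    """
    maps = {}
    scheme = cohort.config.b_scheme
    for lesion_id, signals in cohort.dwi_signals.items():
        adc = fit_adc_two_point_batch(signals, scheme)
        ivim = fit_ivim_segmented_batch(signals, scheme, b_threshold=b_threshold)
        maps[lesion_id] = pd.DataFrame({
            "voxel": np.arange(signals.shape[0]), "ADC": adc,
            "D": ivim["D"], "Dstar": ivim["Dstar"], "f": ivim["f"],
        })
    return maps


def fit_dce_cohort(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Voxelwise linear extended-Tofts fits for every lesion (batched)."""
    maps = {}
    for lesion_id, curves in cohort.dce_curves.items():
        res = fit_etm_linear_batch(curves, cohort.cp)
        maps[lesion_id] = pd.DataFrame({
            "voxel": np.arange(curves.shape[0]),
            "Ktrans": res["Ktrans"], "Kep": res["kep"], "Ve": res["ve"],
            "Vp": res["vp"], "converged": res["converged"],
        })
    return maps


_FAMILY_STATS = {"D": DIFFUSION_STATS, "Dstar": DIFFUSION_STATS,
                 "f": DIFFUSION_STATS, "ADC": DIFFUSION_STATS,
                 "Ktrans": PK_STATS, "Kep": PK_STATS, "Ve": PK_STATS}


def summarize_cohort(cohort: Cohort, dwi_maps: dict[str, pd.DataFrame],
                     dce_maps: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-lesion ROI summary table in reported units."""
    rows = []
    labels = cohort.truth.set_index("lesion_id")["group"]
    for lesion_id in cohort.truth["lesion_id"]:
        row: dict[str, object] = {"lesion_id": lesion_id,
                                  "group": labels[lesion_id]}
        sources = {"D": (dwi_maps, 1e3), "Dstar": (dwi_maps, 1e3),
                   "f": (dwi_maps, 1e2), "ADC": (dwi_maps, 1e3),
                   "Ktrans": (dce_maps, 1.0), "Kep": (dce_maps, 1.0),
                   "Ve": (dce_maps, 1.0)}
        for family, (maps, scale) in sources.items():
            col = family if family in maps[lesion_id].columns else family
            values = maps[lesion_id][col].to_numpy(dtype=float) * scale
            summary = summarize_map(ParamMap.from_arrays(values), family,
                                    stats=_FAMILY_STATS[family])
            row.update(summary.as_dict(_FAMILY_STATS[family]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O helpers


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str) -> None:
    """CSV with a leading comment line carrying the configuration hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    buf.write(f"# config_hash={config_hash} ivimdce={__version__}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_lesion_table(path: str | Path,
                      required: tuple[str, ...] = ("lesion_id", "group")) -> pd.DataFrame:
    """Read an analysis CSV, skipping comment lines and validating headers."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed / truncated file
        raise ValueError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    return df


def write_param_map_nifti(values: np.ndarray, path: str | Path) -> None:
    """Write a voxelwise parameter map as a NIfTI-1 volume (identity affine).

    Accepts a 1-D vector (stored as an n x 1 x 1 volume) or a 3-D array.
    """
    import nibabel as nib

    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None, None]
    img = nib.Nifti1Image(arr, affine=np.eye(4))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Orchestration


def analysis_table(config: RunConfig, rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, list[str], dict[str, pd.DataFrame]]:
    """Measurement chain up to the analysis-ready lesion table.

    simulate -> voxelwise fits -> ROI summaries -> two simulated readers ->
    ICC screening -> reader-mean analysis table.  Returns the analysis table
    (lesion_id, group, screened parameter columns), the retained parameter
    list, and the intermediate tables.
    """
    rng = rng or np.random.default_rng(config.cohort.seed)
    cohort = generate_cohort(config.cohort, rng=rng)
    dwi_maps = fit_dwi_cohort(cohort, b_threshold=config.b_threshold)
    dce_maps = fit_dce_cohort(cohort)
    summaries = summarize_cohort(cohort, dwi_maps, dce_maps)
    readers = simulate_readers(summaries, rng)
    reports = icc_table(readers, cutoff=config.icc_cutoff)
    screened = screen_parameters(reports, cutoff=config.icc_cutoff)
    analysis = (readers[readers["parameter"].isin(screened)]
                .groupby(["lesion_id", "parameter"])["value"].mean()
                .unstack().reset_index())
    analysis = analysis.merge(summaries[["lesion_id", "group"]], on="lesion_id")
    analysis = analysis[["lesion_id", "group", *screened]]
    tables = {
        "truth": cohort.truth,
        "roi_summaries": summaries,
        "reader_table": readers,
        "icc_report": pd.DataFrame(
            [{"parameter": r.parameter, "icc": r.icc, "retained": r.retained}
             for r in reports]),
        "analysis": analysis,
    }
    return analysis, screened, tables


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Execute the full pipeline under one seeded stream.

    Stages: simulate -> fit-dwi -> fit-dce -> summarize -> readers -> screen
    -> compare -> model.  Deterministic given ``config.cohort.seed``.
    """
    chash = config.config_hash()
    warnings_log: list[str] = []
    counts: dict[str, int] = {}

    analysis, screened, tables = analysis_table(config)
    counts["lesions"] = len(tables["truth"])
    counts["summary_rows"] = len(tables["roi_summaries"])
    counts["screened_parameters"] = len(screened)
    for r in tables["icc_report"].itertuples():
        if not r.retained:
            warnings_log.append(
                f"parameter {r.parameter} removed (ICC={r.icc:.3f} < {config.icc_cutoff})")

    tables["comparison"] = compare_table(analysis, screened)
    perf, delong, _fitted = evaluate_models(analysis, screened)
    tables["model_performance"] = perf
    tables["delong"] = delong
    counts["models"] = len(perf)

    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.save(outdir / "config.yaml")
        for name, df in tables.items():
            write_table(df, outdir / f"{name}.csv", chash)

    return RunReport(config_hash=chash, version=__version__,
                     seed=config.cohort.seed, stage_counts=counts,
                     warnings=warnings_log, screened=screened, tables=tables)
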