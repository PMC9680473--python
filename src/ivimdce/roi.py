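"""ROI reduction of voxelwise parameter maps to per-lesion summaries.

A lesion ROI is a set of included voxels, optionally with an exclusion mask
flagging voxels to avoid (cystic, necrotic, calcified or haemorrhagic areas
in the clinical workflow).  Statistics are computed over included,
non-excluded, finite voxels only.  Diffusion-family parameters (D, D*, f,
ADC) are analysed as mean/min/max; pharmacokinetic parameters (Ktrans, kep,
ve) as min/max/median/mean — the summary sets used in the reference
analysis.  Min/max are single-voxel extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DIFFUSION_STATS",
    "PK_STATS",
    "ParamMap",
    "ROISummary",
    "summarize_map",
]

DIFFUSION_STATS: tuple[str, ...] = ("mean", "min", "max")
PK_STATS: tuple[str, ...] = ("min", "max", "median", "mean")

_STAT_FN = {"mean": np.mean, "min": np.min, "max": np.max, "median": np.median}


@dataclass(frozen=True)
class ParamMap:
    """A voxelwise parameter map with inclusion and exclusion masks."""

    values: tuple[float, ...]
    mask: tuple[bool, ...] | None = None
    exclusion_mask: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.values)
        for m in (self.mask, self.exclusion_mask):
            if m is not None and len(m) != n:
                raise ValueError("masks must match the number of voxels")

    @classmethod
    def from_arrays(cls, values, mask=None, exclusion_mask=None) -> "ParamMap":
        return cls(
            tuple(float(v) for v in np.asarray(values, dtype=float)),
            None if mask is None else tuple(bool(b) for b in mask),
            None if exclusion_mask is None else tuple(bool(b) for b in exclusion_mask),
        )

    def effective_values(self) -> np.ndarray:
        v = np.asarray(self.values, dtype=float)
        keep = np.ones(v.size, dtype=bool)
        if self.mask is not None:
            keep &= np.asarray(self.mask, dtype=bool)
        if self.exclusion_mask is not None:
            keep &= ~np.asarray(self.exclusion_mask, dtype=bool)
        return v[keep]


@dataclass(frozen=True)
class ROISummary:
    parameter: str
    mean: float | None
    min: float | None
    max: float | None
    median: float | None
    n_voxels_used: int
    n_nonfinite_dropped: int = 0

    def as_dict(self, stats: tuple[str, ...]) -> dict[str, float]:
        return {f"{self.parameter}_{s}": getattr(self, s) for s in stats}


def summarize_map(param_map: ParamMap, parameter: str = "param",
                  stats: tuple[str, ...] = PK_STATS) -> ROISummary:
    """Reduce a masked parameter map to ROI summary statistics.

    Non-finite voxel values are dropped (and counted); an empty effective
    ROI is an error.
    """
    values = param_map.effective_values()
    if values.size == 0:
        raise ValueError("ROI is empty after applying masks")
    finite = np.isfinite(values)
    dropped = int(values.size - finite.sum())
    values = values[finite]
    if values.size == 0:
        raise ValueError("ROI contains no finite voxel values")
    computed = {s: float(_STAT_FN[s](values)) for s in set(stats) | {"mean", "min", "max", "median"}}
    return ROISummary(
        parameter=parameter,
        mean=computed["mean"], min=computed["min"],
        max=computed["max"], median=computed["median"],
        n_voxels_used=int(values.size),
        n_nonfinite_dropped=dropped,
    )
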