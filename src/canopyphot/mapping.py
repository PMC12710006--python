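"""Per-pixel trait mapping: apply a trained trait model to a masked scene.

Indices are computed pixel-wise (not from ROI means), soil/shadow pixels are
removed by the ExG threshold, guard-failing pixels are masked, and
predictions are left unclipped — out-of-range pixels are counted in the map
metadata rather than hidden.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import ROIMask, SceneRaster, compute_exg, vegetation_mask
from .indices import compute_index
from .modeling import TrainedTraitModel, UnivariateModel
from .synth import FieldLayout

__all__ = ["TraitMap", "map_traits", "plot_summary", "save_trait_map_tiff"]


@dataclass
class TraitMap:
    """An H×W raster of predicted trait values with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    trait: str
    model_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")
        if self.valid.any() and not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("non-finite trait values on valid pixels")

    def stats(self) -> dict:
        v = self.values[self.valid]
        if v.size == 0:
            return {"n_valid": 0, "min": np.nan, "max": np.nan, "mean": np.nan}
        return {
            "n_valid": int(v.size),
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
        }


def _model_id(model) -> str:
    if isinstance(model, UnivariateModel):
        desc = f"univariate:{model.index}:{model.slope}:{model.intercept}"
    else:
        desc = f"plsr:{','.join(model.selected_indices)}:{np.asarray(model.coef).tobytes().hex()}"
    return hashlib.sha1(desc.encode()).hexdigest()[:12]


def map_traits(
    scene: SceneRaster,
    model: TrainedTraitModel | UnivariateModel,
    exg_threshold: float = 0.07,
) -> TraitMap:
    """Predict the trait for every vegetation pixel of a calibrated scene.

    Vegetation is ExG > ``exg_threshold``; the required spectral indices are
    evaluated per pixel through the registry, and pixels where any index
    guard fails are masked. Predictions are not clipped; pixels outside a
    plausible physiological range [0, 500] are counted in meta.
    """
    names = model.selected_indices
    exg = compute_exg(scene)
    veg = vegetation_mask(exg, exg_threshold, nodata=scene.nodata).mask

    h, w = scene.shape
    cols = np.empty((h * w, len(names)), dtype=float)
    for j, name in enumerate(names):
        cols[:, j] = np.asarray(compute_index(name, scene), dtype=float).ravel()
    finite = np.all(np.isfinite(cols), axis=1).reshape(h, w)
    valid = veg & finite & ~scene.nodata

    if isinstance(model, UnivariateModel):
        pred = model.predict(cols[:, 0]).reshape(h, w)
    else:
        pred = model.predict(cols).reshape(h, w)
    values = np.where(valid, pred, np.nan)
    trait = getattr(model, "trait", "") or "trait"
    tm = TraitMap(values=values, valid=valid, trait=trait, model_id=_model_id(model))
    tm.meta.update(tm.stats())
    v = values[valid]
    tm.meta["n_out_of_range"] = int(np.sum((v < 0) | (v > 500))) if v.size else 0
    tm.meta["n_masked_guard"] = int(np.sum(veg & ~finite & ~scene.nodata))
    return tm


def plot_summary(trait_map: TraitMap, layout: FieldLayout) -> pd.DataFrame:
    """Per-plot mean/min/max of the mapped trait over valid pixels.

    Plots with zero valid pixels are reported with NaN statistics rather
    than silently dropped.
    """
    rows = []
    for plot_id, (treatment, (r0, c0, r1, c1)) in layout.plots.items():
        vals = trait_map.values[r0:r1, c0:c1][trait_map.valid[r0:r1, c0:c1]]
        if vals.size == 0:
            rows.append(
                {
                    "plot_id": plot_id,
                    "treatment": treatment,
                    "n_valid": 0,
                    "mean": np.nan,
                    "min": np.nan,
                    "max": np.nan,
                }
            )
        else:
            rows.append(
                {
                    "plot_id": plot_id,
                    "treatment": treatment,
                    "n_valid": int(vals.size),
                    "mean": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def save_trait_map_tiff(trait_map: TraitMap, path, nodata_value: float = -9999.0) -> None:
    """Write the trait raster as a single-band float TIFF with a nodata fill."""
    import tifffile

    arr = np.where(trait_map.valid, trait_map.values, nodata_value).astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")


def save_quicklook_png(trait_map: TraitMap, path, cmap: str = "viridis") -> None:
    """Optional PNG quicklook (viridis colormap, NaN shown as background)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(np.where(trait_map.valid, trait_map.values, np.nan), cmap=cmap)
    fig.colorbar(im, ax=ax, label=f"{trait_map.trait} (µmol m⁻² s⁻¹)")
    ax.set_title(f"{trait_map.trait} map [{trait_map.model_id}]")
    fig.savefig(path, dpi=120)
    plt.close(fig)
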