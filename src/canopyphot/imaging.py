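"""Radiometric calibration, vegetation masking and ROI reflectance extraction.

Works on 5-band canopy reflectance rasters in the fixed band order
(blue, green, red, red-edge, NIR). Calibration uses the empirical-line
method against a reference panel of known (≈50 %) reflectance; soil and
shadow are suppressed with the excess-green index ExG = 2·ρG − ρR − ρB and
a threshold (0.07 by default).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BAND_NAMES: tuple[str, ...] = ("blue", "green", "red", "red_edge", "nir")
N_BANDS = len(BAND_NAMES)

__all__ = [
    "BAND_NAMES",
    "SceneRaster",
    "ROIMask",
    "PanelObservation",
    "calibrate_reflectance",
    "compute_exg",
    "vegetation_mask",
    "extract_reflectance",
    "gsd_from_geometry",
    "save_scene",
    "load_scene",
    "save_scene_tiff",
    "load_scene_tiff",
    "save_mask_tiff",
]


@dataclass
class SceneRaster:
    """An H×W×5 reflectance raster with a nodata mask and ground sample distance.

    bands holds reflectance (dimensionless, nominally in [0, 1] after
    calibration) in the order (B, G, R, RE, NIR). ``nodata`` is True on
    invalid pixels. ``gsd`` is metres of ground per pixel.
    """

    bands: np.ndarray
    nodata: np.ndarray | None = None
    gsd: float = 0.02
    transform: tuple | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3 or self.bands.shape[2] != N_BANDS:
            raise ValueError(f"bands must be H×W×{N_BANDS}, got {self.bands.shape}")
        if self.nodata is None:
            self.nodata = np.zeros(self.bands.shape[:2], dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.bands.shape[:2]:
                raise ValueError("nodata mask shape does not match bands")
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")
        valid = ~self.nodata
        if valid.any() and not np.all(np.isfinite(self.bands[valid])):
            raise ValueError("non-finite reflectance on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[:2]

    def band(self, name: str) -> np.ndarray:
        return self.bands[:, :, BAND_NAMES.index(name)]


@dataclass
class ROIMask:
    """Boolean region-of-interest mask over a scene."""

    mask: np.ndarray
    roi_id: str = "roi"
    provenance: str = "exg_refined"  # or "manual_polygon"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.provenance not in ("manual_polygon", "exg_refined"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PanelObservation:
    """Per-band mean digital value over calibration-panel pixels, with the
    panel's nominal reflectance (≈0.5 in each band)."""

    mean_dn: np.ndarray
    nominal: np.ndarray | float = 0.5

    def __post_init__(self) -> None:
        self.mean_dn = np.asarray(self.mean_dn, dtype=float)
        if self.mean_dn.shape != (N_BANDS,):
            raise ValueError(f"mean_dn must have {N_BANDS} entries")
        if np.any(self.mean_dn <= 0):
            raise ValueError("panel digital values must be positive")
        self.nominal = np.broadcast_to(np.asarray(self.nominal, dtype=float), (N_BANDS,)).copy()


def calibrate_reflectance(
    raw: np.ndarray,
    panel: PanelObservation,
    gsd: float = 0.02,
    nodata: np.ndarray | None = None,
) -> SceneRaster:
    """Empirical-line radiometric calibration against a reference panel.

    Applies the per-band gain g_b = nominal_b / panel_mean_b multiplicatively
    and clips to [0, 1.5]; the number of clipped samples is logged and stored
    in ``scene.meta['n_clipped']``.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[2] != N_BANDS:
        raise ValueError(f"raw must be H×W×{N_BANDS}")
    gains = panel.nominal / panel.mean_dn
    refl = raw * gains[None, None, :]
    n_clipped = int(np.sum((refl < 0) | (refl > 1.5)))
    if n_clipped:
        logger.warning("calibration clipped %d band samples to [0, 1.5]", n_clipped)
    refl = np.clip(refl, 0.0, 1.5)
    scene = SceneRaster(bands=refl, nodata=nodata, gsd=gsd)
    scene.meta["n_clipped"] = n_clipped
    scene.meta["gains"] = gains.tolist()
    return scene


def compute_exg(scene: SceneRaster) -> np.ndarray:
    """Excess-green index ExG = 2·ρG − ρR − ρB, per pixel."""
    return 2.0 * scene.band("green") - scene.band("red") - scene.band("blue")


def _polygon_mask(shape: tuple[int, int], polygon) -> np.ndarray:
    """Rasterize a polygon given as (col, row) vertex pairs to a boolean mask.

    Even-odd ray casting on pixel centres; no external raster dependency.
    """
    poly = np.asarray(polygon, dtype=float)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cols.ravel() + 0.0
    y = rows.ravel() + 0.0
    inside = np.zeros(x.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = ((y1 > y) != (y2 > y)) & (
            x < (x2 - x1) * (y - y1) / (y2 - y1 + 1e-300) + x1
        )
        inside ^= crosses
    return inside.reshape(shape)


def vegetation_mask(
    exg: np.ndarray,
    threshold: float = 0.07,
    roi_polygon=None,
    nodata: np.ndarray | None = None,
    roi_id: str = "vegetation",
) -> ROIMask:
    """Vegetation mask: pixels with ExG strictly above ``threshold``.

    Optionally intersected with a manual ROI polygon ((col, row) vertices)
    and with the valid-data mask. An empty result is a warning, not an error.
    """
    if not np.isfinite(threshold):
        if threshold == -np.inf:
            mask = np.ones(np.asarray(exg).shape, dtype=bool)
        else:
            raise ValueError("threshold must be finite or -inf")
    else:
        mask = np.asarray(exg) > threshold
    if nodata is not None:
        mask &= ~np.asarray(nodata, dtype=bool)
    provenance = "exg_refined"
    if roi_polygon is not None:
        mask &= _polygon_mask(mask.shape, roi_polygon)
    if not mask.any():
        warnings.warn(f"vegetation mask {roi_id!r} is empty", stacklevel=2)
    return ROIMask(mask=mask, roi_id=roi_id, provenance=provenance)


def extract_reflectance(scene: SceneRaster, mask: ROIMask) -> pd.Series:
    """Mean reflectance per band over the masked pixels (nodata excluded)."""
    m = mask.mask & ~scene.nodata
    if not m.any():
        raise ValueError(f"mask {mask.roi_id!r} selects no valid pixels")
    means = scene.bands[m].mean(axis=0)
    return pd.Series(means, index=list(BAND_NAMES), name=mask.roi_id)


def gsd_from_geometry(altitude: float, pixel_pitch: float, focal_length: float) -> float:
    """Ground sample distance from flight geometry: gsd = H·p/f (all metres)."""
    if altitude <= 0 or pixel_pitch <= 0 or focal_length <= 0:
        raise ValueError("altitude, pixel pitch and focal length must be positive")
    return altitude * pixel_pitch / focal_length


# ---------------------------------------------------------------------------
# I/O


def save_scene(scene: SceneRaster, path) -> None:
    """Save a scene as a compressed .npz (bands + nodata + gsd)."""
    np.savez_compressed(
        path, bands=scene.bands, nodata=scene.nodata, gsd=np.float64(scene.gsd)
    )


def load_scene(path) -> SceneRaster:
    with np.load(path) as z:
        return SceneRaster(bands=z["bands"], nodata=z["nodata"], gsd=float(z["gsd"]))


def save_scene_tiff(scene: SceneRaster, path) -> None:
    """Write the scene as a 5-band float TIFF with gsd in the description tag."""
    import tifffile

    tifffile.imwrite(
        path,
        np.moveaxis(scene.bands.astype(np.float32), 2, 0),
        photometric="minisblack",
        description=json.dumps({"gsd": scene.gsd, "bands": list(BAND_NAMES)}),
    )


def load_scene_tiff(path, gsd: float | None = None) -> SceneRaster:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    if arr.ndim == 3 and arr.shape[0] == N_BANDS:
        arr = np.moveaxis(arr, 0, 2)
    return SceneRaster(bands=arr.astype(float), gsd=gsd or float(meta.get("gsd", 0.02)))


def save_mask_tiff(mask: ROIMask, path) -> None:
    import tifffile

    tifffile.imwrite(path, mask.mask.astype(np.uint8), photometric="minisblack")
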