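"""Seeded synthetic nitrogen-gradient field datasets.

Emulates the statistical structure the downstream analysis assumes: a
nitrogen application gradient (N0..N4 = 0..520 kg/hm²) drives leaf nitrogen
per area, which drives both chlorophyll a+b (hence canopy reflectance in the
visible/red-edge bands) and photosynthetic capacity (Vcmax25, Jmax25). Scenes
are rendered with a Beer-law two-stream caricature of canopy reflectance:

    ρ_band = ρ_soil(band)·exp(−k_band·LAI) + ρ_leaf(band, Cab)·(1 − exp(−k_band·LAI))

so that higher Cab lowers green/red/red-edge reflectance (red-edge most
sensitive) and higher LAI shifts the spectrum from soil toward leaf — the
LAI/soil confounding that ratio indices such as SCCCI are meant to cancel.
A-Ci curves are produced by the forward FvCB model on the rapid-ramp CO2
protocol with additive Gaussian instrument noise.

Every generator is a pure function of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fvcb import ACiCurve, FvCBParameters, forward_assimilation
from .imaging import BAND_NAMES, SceneRaster

__all__ = [
    "TREATMENTS",
    "NitrogenTreatment",
    "PlantTruth",
    "FieldLayout",
    "RampProtocol",
    "GeneratorDefaults",
    "generate_truth",
    "design_layout",
    "render_scene",
    "leaf_reflectance",
    "canopy_reflectance",
    "simulate_aci",
    "write_truth_csv",
    "read_truth_csv",
    "write_layout_csv",
    "read_layout_csv",
]


@dataclass(frozen=True)
class NitrogenTreatment:
    """A nitrogen fertilization level: label N0..N4, rate in kg/hm²."""

    label: str
    rate: float

    _RATES = {"N0": 0.0, "N1": 130.0, "N2": 260.0, "N3": 390.0, "N4": 520.0}

    def __post_init__(self) -> None:
        if self.label not in self._RATES:
            raise ValueError(f"unknown treatment label {self.label!r}")
        if self.rate != self._RATES[self.label]:
            raise ValueError(
                f"treatment {self.label} must have rate {self._RATES[self.label]}, got {self.rate}"
            )

    @classmethod
    def from_label(cls, label: str) -> "NitrogenTreatment":
        return cls(label, cls._RATES[label])


TREATMENTS: tuple[NitrogenTreatment, ...] = tuple(
    NitrogenTreatment.from_label(lbl) for lbl in ("N0", "N1", "N2", "N3", "N4")
)


@dataclass
class PlantTruth:
    """Latent truth for one plant: nitrogen, pigment, structure, capacity."""

    plant_id: str
    plot_id: str
    treatment: NitrogenTreatment
    n_area: float  # leaf N per area, g m⁻²
    cab: float  # chlorophyll a+b, µg cm⁻²
    lai: float  # leaf area index
    vcmax25: float  # µmol m⁻² s⁻¹
    jmax25: float
    rd25: float

    def __post_init__(self) -> None:
        for name in ("n_area", "cab", "lai", "vcmax25", "jmax25", "rd25"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ratio = self.jmax25 / self.vcmax25
        if not 1.2 <= ratio <= 2.5:
            raise ValueError(f"jmax25/vcmax25 = {ratio:.3f} outside [1.2, 2.5]")


@dataclass
class FieldLayout:
    """Plot rectangles and plant marker pixels on the scene grid.

    plots: plot_id -> (treatment label, (row0, col0, row1, col1)), half-open.
    plants: plant_id -> (plot_id, (row, col) marker pixel).
    """

    plots: dict[str, tuple[str, tuple[int, int, int, int]]]
    plants: dict[str, tuple[str, tuple[int, int]]]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        h, w = self.shape
        rects = []
        for pid, (_, (r0, c0, r1, c1)) in self.plots.items():
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"plot {pid} rectangle exceeds raster bounds")
            rects.append((pid, r0, c0, r1, c1))
        for i, (pa, ar0, ac0, ar1, ac1) in enumerate(rects):
            for pb, br0, bc0, br1, bc1 in rects[i + 1 :]:
                if ar0 < br1 and br0 < ar1 and ac0 < bc1 and bc0 < ac1:
                    raise ValueError(f"plots {pa} and {pb} overlap")
        for plant, (plot, (r, c)) in self.plants.items():
            _, (r0, c0, r1, c1) = self.plots[plot]
            if not (r0 <= r < r1 and c0 <= c < c1):
                raise ValueError(f"plant {plant} marker outside its plot {plot}")


@dataclass(frozen=True)
class RampProtocol:
    """Rapid A-Ci ramp: CO2 from ``start`` to ``end`` µmol mol⁻¹ at ``rate``
    µmol mol⁻¹ min⁻¹, one record every ``interval`` seconds."""

    start: float = 30.0
    end: float = 1830.0
    rate: float = 200.0
    interval: float = 5.0
    tleaf: float = 25.0
    q: float = 1500.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("ramp start must be below end")
        if self.rate <= 0 or self.interval <= 0:
            raise ValueError("rate and sampling interval must be positive")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.rate * 60.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s / self.interval))

    def ci_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(t_s, ci): records at t = interval, 2·interval, …, duration, so the
        final record lands exactly on the ramp endpoint."""
        t = self.interval * np.arange(1, self.n_samples + 1)
        ci = self.start + self.rate * t / 60.0
        return t, ci


@dataclass(frozen=True)
class GeneratorDefaults:
    """Parameters of the latent-truth and reflectance generators.

    Slopes/sigmas are the package's stated study conditions; noise terms are
    multiplicative lognormal, exp(N(0, sigma)).
    """

    n_area_base: float = 1.0  # g m⁻² at zero N
    n_area_per_rate: float = 0.002  # g m⁻² per kg/hm² applied N
    n_area_sigma: float = 0.15
    cab_per_n: float = 25.0  # µg cm⁻² per g m⁻²
    cab_sigma: float = 0.06
    vcmax_per_n: float = 45.0  # µmol m⁻² s⁻¹ per g m⁻²
    vcmax_sigma: float = 0.08
    jmax_ratio: float = 1.9
    jmax_sigma: float = 0.05
    rd_frac: float = 0.015
    # canopy structure responds to N as well: LAI mean rises with applied N,
    # uniform plant-to-plant noise, clipped to lai_range
    lai_base: float = 1.8
    lai_per_rate: float = 0.0025
    lai_noise: float = 0.5
    lai_range: tuple[float, float] = (1.5, 4.2)
    # reflectance model
    soil: tuple[float, ...] = (0.15, 0.17, 0.19, 0.21, 0.20)
    k_bands: tuple[float, ...] = (0.85, 0.75, 0.90, 0.65, 0.55)
    leaf_base: tuple[float, ...] = (0.04, 0.13, 0.06, 0.35, 0.45)
    leaf_cab_slope: tuple[float, ...] = (0.0, 0.0007, 0.0006, 0.004, 0.0)
    leaf_floor: tuple[float, ...] = (0.02, 0.02, 0.01, 0.04, 0.10)
    pixel_noise_sd: float = 0.003
    shadow_fraction: float = 0.10
    shadow_factor: float = 0.3
    # per-plant band-neutral illumination/BRDF variability (lognormal sigma);
    # confounds raw-band predictors, cancels in ratio indices
    brightness_sigma: float = 0.06
    # per-plant, per-band lognormal jitter of leaf optics (leaf angle/structure
    # variation unrelated to Cab); makes every index a noisy pigment proxy
    spectral_jitter_sigma: float = 0.10


DEFAULTS = GeneratorDefaults()


def generate_truth(
    n_plots_per_treatment: int,
    plants_per_plot: int,
    seed: int,
    params: GeneratorDefaults = DEFAULTS,
    noise_scale: float = 1.0,
) -> list[PlantTruth]:
    """Draw per-plant latent truth for a 5-treatment nitrogen-gradient field.

    Treatment-specific n_area means increase linearly in applied N; Cab and
    Vcmax25 are proportional to n_area and Jmax25 to Vcmax25, each with
    multiplicative lognormal noise. ``noise_scale=0`` collapses the within-
    treatment distributions to their medians.
    """
    if n_plots_per_treatment < 1 or plants_per_plot < 1:
        raise ValueError("plot and plant counts must be >= 1")
    rng = np.random.default_rng(seed)
    p = params
    truth: list[PlantTruth] = []
    for trt in TREATMENTS:
        mu = p.n_area_base + p.n_area_per_rate * trt.rate
        for k in range(n_plots_per_treatment):
            plot_id = f"{trt.label}-{k + 1}"
            for i in range(plants_per_plot):
                n_area = mu * np.exp(noise_scale * p.n_area_sigma * rng.standard_normal())
                cab = p.cab_per_n * n_area * np.exp(
                    noise_scale * p.cab_sigma * rng.standard_normal()
                )
                vcmax = p.vcmax_per_n * n_area * np.exp(
                    noise_scale * p.vcmax_sigma * rng.standard_normal()
                )
                ratio = np.clip(
                    p.jmax_ratio * np.exp(noise_scale * p.jmax_sigma * rng.standard_normal()),
                    1.2,
                    2.5,
                )
                lai = float(
                    np.clip(
                        p.lai_base
                        + p.lai_per_rate * trt.rate
                        + noise_scale * rng.uniform(-p.lai_noise, p.lai_noise),
                        *p.lai_range,
                    )
                )
                truth.append(
                    PlantTruth(
                        plant_id=f"{plot_id}_p{i + 1:02d}",
                        plot_id=plot_id,
                        treatment=trt,
                        n_area=float(n_area),
                        cab=float(cab),
                        lai=float(lai),
                        vcmax25=float(vcmax),
                        jmax25=float(ratio * vcmax),
                        rd25=float(p.rd_frac * vcmax),
                    )
                )
    return truth


def design_layout(
    n_plots_per_treatment: int,
    plants_per_plot: int,
    plot_rows: int = 18,
    plot_cols: int = 30,
    gap: int = 6,
) -> FieldLayout:
    """Arrange plots on a grid: one column of plots per treatment, one row
    per replicate; plants on a regular grid inside each plot."""
    if n_plots_per_treatment < 1 or plants_per_plot < 1:
        raise ValueError("plot and plant counts must be >= 1")
    n_rows = n_plots_per_treatment
    n_cols = len(TREATMENTS)
    h = gap + n_rows * (plot_rows + gap)
    w = gap + n_cols * (plot_cols + gap)
    plots: dict[str, tuple[str, tuple[int, int, int, int]]] = {}
    plants: dict[str, tuple[str, tuple[int, int]]] = {}
    # plant grid inside a plot
    per_row = max(1, int(np.ceil(np.sqrt(plants_per_plot * plot_cols / plot_rows))))
    n_plant_rows = int(np.ceil(plants_per_plot / per_row))
    for j, trt in enumerate(TREATMENTS):
        for k in range(n_plots_per_treatment):
            plot_id = f"{trt.label}-{k + 1}"
            r0 = gap + k * (plot_rows + gap)
            c0 = gap + j * (plot_cols + gap)
            plots[plot_id] = (trt.label, (r0, c0, r0 + plot_rows, c0 + plot_cols))
            idx = 0
            for pr in range(n_plant_rows):
                for pc in range(per_row):
                    if idx >= plants_per_plot:
                        break
                    rr = r0 + int((pr + 0.5) * plot_rows / n_plant_rows)
                    cc = c0 + int((pc + 0.5) * plot_cols / per_row)
                    plants[f"{plot_id}_p{idx + 1:02d}"] = (plot_id, (rr, cc))
                    idx += 1
    return FieldLayout(plots=plots, plants=plants, shape=(h, w))


def leaf_reflectance(cab: float, params: GeneratorDefaults = DEFAULTS) -> np.ndarray:
    """Leaf-level 5-band reflectance as a linear-in-Cab caricature: visible
    and red-edge bands darken with chlorophyll (red edge most), NIR does not."""
    base = np.asarray(params.leaf_base)
    slope = np.asarray(params.leaf_cab_slope)
    floor = np.asarray(params.leaf_floor)
    return np.maximum(base - slope * cab, floor)


def canopy_reflectance(
    cab: float, lai: float, params: GeneratorDefaults = DEFAULTS
) -> np.ndarray:
    """Beer-law mix of soil and leaf spectra for a canopy of given Cab and LAI."""
    soil = np.asarray(params.soil)
    k = np.asarray(params.k_bands)
    gap = np.exp(-k * lai)
    return soil * gap + leaf_reflectance(cab, params) * (1.0 - gap)


def render_scene(
    layout: FieldLayout,
    truth: list[PlantTruth],
    gsd: float = 0.02,
    seed: int = 0,
    params: GeneratorDefaults = DEFAULTS,
    crown_radius: int = 3,
) -> tuple[SceneRaster, np.ndarray, np.ndarray]:
    """Render a 5-band reflectance scene from layout + truth.

    Each plant paints a circular crown of its canopy spectrum around its
    marker pixel, scaled by a per-plant band-neutral brightness factor
    (illumination/BRDF variability); everywhere else is soil (flat spectrum,
    ρNIR ≈ ρR). A seeded fraction of vegetation pixels is darkened by a
    band-neutral multiplicative shadow factor, and i.i.d. Gaussian pixel
    noise is added.

    Returns (scene, vegetation_mask, shadow_mask); the vegetation mask marks
    every canopy pixel, shadowed or not.
    """
    if gsd <= 0:
        raise ValueError("gsd must be positive")
    rng = np.random.default_rng(seed)
    h, w = layout.shape
    p = params
    bands = np.empty((h, w, 5), dtype=float)
    bands[:] = np.asarray(p.soil)[None, None, :]
    veg = np.zeros((h, w), dtype=bool)

    by_id = {t.plant_id: t for t in truth}
    yy, xx = np.mgrid[0:h, 0:w]
    for plant_id, (_, (r, c)) in layout.plants.items():
        t = by_id.get(plant_id)
        if t is None:
            continue
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= crown_radius**2
        brightness = np.exp(p.brightness_sigma * rng.standard_normal())
        jitter = np.exp(p.spectral_jitter_sigma * rng.standard_normal(5))
        soil_term = np.asarray(p.soil) * np.exp(-np.asarray(p.k_bands) * t.lai)
        leaf_term = (
            jitter
            * leaf_reflectance(t.cab, p)
            * (1.0 - np.exp(-np.asarray(p.k_bands) * t.lai))
        )
        spectrum = brightness * (soil_term + leaf_term)
        bands[disk] = spectrum[None, :]
        veg |= disk

    shadow = np.zeros((h, w), dtype=bool)
    veg_idx = np.flatnonzero(veg.ravel())
    if p.shadow_fraction > 0 and veg_idx.size:
        n_sh = int(round(p.shadow_fraction * veg_idx.size))
        chosen = rng.choice(veg_idx, size=n_sh, replace=False)
        shadow.ravel()[chosen] = True
        bands[shadow] *= p.shadow_factor

    if p.pixel_noise_sd > 0:
        bands = bands + rng.normal(0.0, p.pixel_noise_sd, size=bands.shape)
    bands = np.clip(bands, 0.0, 1.5)
    scene = SceneRaster(bands=bands, gsd=gsd)
    scene.meta["seed"] = seed
    return scene, veg, shadow


def simulate_aci(
    params: FvCBParameters,
    protocol: RampProtocol = RampProtocol(),
    noise_sd: float = 0.5,
    seed: int = 0,
    plant_id: str = "",
) -> ACiCurve:
    """Forward-simulate one rapid A-Ci curve on the ramp protocol with
    additive Gaussian instrument noise on A (µmol m⁻² s⁻¹)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t, ci = protocol.ci_grid()
    a = forward_assimilation(params, ci, q=protocol.q, tleaf=protocol.tleaf)
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=a.shape)
    return ACiCurve(ci=ci, a=a, tleaf=protocol.tleaf, q=protocol.q, plant_id=plant_id, t_s=t)


# ---------------------------------------------------------------------------
# CSV I/O


def write_truth_csv(truth: list[PlantTruth], path) -> None:
    pd.DataFrame(
        {
            "plant_id": [t.plant_id for t in truth],
            "plot_id": [t.plot_id for t in truth],
            "treatment": [t.treatment.label for t in truth],
            "n_rate": [t.treatment.rate for t in truth],
            "n_area": [t.n_area for t in truth],
            "cab": [t.cab for t in truth],
            "lai": [t.lai for t in truth],
            "vcmax25": [t.vcmax25 for t in truth],
            "jmax25": [t.jmax25 for t in truth],
            "rd25": [t.rd25 for t in truth],
        }
    ).to_csv(path, index=False)


def read_truth_csv(path) -> list[PlantTruth]:
    df = pd.read_csv(path)
    return [
        PlantTruth(
            plant_id=row.plant_id,
            plot_id=row.plot_id,
            treatment=NitrogenTreatment.from_label(row.treatment),
            n_area=row.n_area,
            cab=row.cab,
            lai=row.lai,
            vcmax25=row.vcmax25,
            jmax25=row.jmax25,
            rd25=row.rd25,
        )
        for row in df.itertuples()
    ]


def write_layout_csv(layout: FieldLayout, plots_path, plants_path) -> None:
    pd.DataFrame(
        [
            {"plot_id": pid, "treatment": trt, "row0": r0, "col0": c0, "row1": r1, "col1": c1}
            for pid, (trt, (r0, c0, r1, c1)) in layout.plots.items()
        ]
    ).to_csv(plots_path, index=False)
    pd.DataFrame(
        [
            {"plant_id": plant, "plot_id": plot, "row": r, "col": c}
            for plant, (plot, (r, c)) in layout.plants.items()
        ]
    ).to_csv(plants_path, index=False)


def read_layout_csv(plots_path, plants_path, shape: tuple[int, int] | None = None) -> FieldLayout:
    plots_df = pd.read_csv(plots_path)
    plants_df = pd.read_csv(plants_path)
    plots = {
        row.plot_id: (row.treatment, (int(row.row0), int(row.col0), int(row.row1), int(row.col1)))
        for row in plots_df.itertuples()
    }
    plants = {
        row.plant_id: (row.plot_id, (int(row.row), int(row.col))) for row in plants_df.itertuples()
    }
    if shape is None:
        h = int(plots_df["row1"].max()) + 6
        w = int(plots_df["col1"].max()) + 6
        shape = (h, w)
    return FieldLayout(plots=plots, plants=plants, shape=shape)
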