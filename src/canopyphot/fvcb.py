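"""Farquhar–von Caemmerer–Berry (FvCB) model of C3 photosynthesis.

Forward simulation of net assimilation A as a function of intercellular CO2
(Ci), irradiance (Q) and leaf temperature, plus nonlinear least-squares
fitting of A-Ci curves to estimate the photosynthetic capacity parameters
Vcmax25, Jmax25 and Rd25 (all normalized to 25 °C).

Model
-----
A = min(Ac, Aj) − Rd, where

    Ac = Vcmax · (Ci − Γ*) / (Ci + Kc·(1 + O/Ko))      (Rubisco-limited)
    Aj = J · (Ci − Γ*) / (4·Ci + 8·Γ*)                 (RuBP-regeneration-limited)

and J is the lower root of the non-rectangular hyperbola

    θ·J² − (α·Q + Jmax)·J + α·Q·Jmax = 0.

All kinetic parameters follow Arrhenius temperature scaling around 25 °C:

    k(T) = k25 · exp(Ea·(T − 298.15) / (298.15·R·T)),  T in kelvin.

Default kinetic constants and activation energies are the Bernacchi (2001)
set (Γ*25 = 42.75, Kc25 = 404.9 µmol mol⁻¹, Ko25 = 278.4 mmol mol⁻¹,
O = 210 mmol mol⁻¹). TPU limitation is deliberately excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

R_GAS = 8.314  # J mol⁻¹ K⁻¹
T_REF_K = 298.15  # 25 °C
ZERO_K_C = -273.15

__all__ = [
    "FvCBParameters",
    "ACiCurve",
    "FitResult",
    "arrhenius_scale",
    "arrhenius_to_25",
    "electron_transport_rate",
    "forward_assimilation",
    "fit_aci",
    "trait_summary",
    "read_curves_csv",
    "write_curves_csv",
]


@dataclass
class FvCBParameters:
    """FvCB parameter block: fitted capacities plus kinetic constants.

    Rates are µmol m⁻² s⁻¹; gammastar25/kc25 µmol mol⁻¹; ko25 and o
    mmol mol⁻¹; activation energies J mol⁻¹; theta and alpha dimensionless.
    """

    vcmax25: float = 60.0
    jmax25: float = 120.0
    rd25: float = 1.0
    gammastar25: float = 42.75
    kc25: float = 404.9
    ko25: float = 278.4
    o: float = 210.0
    ea_vcmax: float = 65330.0
    ea_jmax: float = 43540.0
    ea_rd: float = 46390.0
    ea_gammastar: float = 37830.0
    ea_kc: float = 79430.0
    ea_ko: float = 36380.0
    theta: float = 0.85
    alpha: float = 0.24

    def __post_init__(self) -> None:
        for name in ("vcmax25", "jmax25", "gammastar25", "kc25", "ko25", "o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.rd25 < 0:
            raise ValueError(f"rd25 must be non-negative, got {self.rd25}")
        if not 0 < self.theta < 1:
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if not 0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")


@dataclass
class ACiCurve:
    """One rapid A-Ci response curve for a single leaf.

    ci: intercellular CO2, µmol mol⁻¹; a: net assimilation, µmol m⁻² s⁻¹;
    tleaf: leaf temperature, °C (scalar or per-point); q: irradiance,
    µmol m⁻² s⁻¹.
    """

    ci: np.ndarray
    a: np.ndarray
    tleaf: float | np.ndarray = 25.0
    q: float = 1500.0
    plant_id: str = ""
    t_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.ci.shape != self.a.shape:
            raise ValueError("ci and a must have equal length")
        if self.ci.size < 8:
            raise ValueError(f"need at least 8 points, got {self.ci.size}")
        if not np.all(np.isfinite(self.ci)) or not np.all(np.isfinite(self.a)):
            raise ValueError("ci and a must be finite (no NaN/inf)")
        if self.q <= 0:
            raise ValueError("irradiance q must be positive")


@dataclass
class FitResult:
    """Outcome of fitting one A-Ci curve."""

    params: FvCBParameters
    rmse_fit: float
    limitation: np.ndarray  # per-point, "rubisco" or "rubp"
    converged: bool
    plant_id: str = ""
    n_points: int = 0


def arrhenius_scale(k25: float | np.ndarray, ea: float, tleaf: float | np.ndarray):
    """Scale a rate from 25 °C to leaf temperature ``tleaf`` (°C).

    k(T) = k25 · exp(Ea·(T − 298.15)/(298.15·R·T)).
    """
    k25 = np.asarray(k25, dtype=float)
    if np.any(k25 <= 0):
        raise ValueError("k25 must be positive")
    t_k = np.asarray(tleaf, dtype=float) + 273.15
    if np.any(t_k <= 0):
        raise ValueError("temperature at or below absolute zero")
    factor = np.exp(ea * (t_k - T_REF_K) / (T_REF_K * R_GAS * t_k))
    out = k25 * factor
    return float(out) if np.isscalar(tleaf) and out.ndim == 0 else out


def arrhenius_to_25(k_t: float | np.ndarray, ea: float, tleaf: float | np.ndarray):
    """Inverse of :func:`arrhenius_scale`: normalize a measured rate back to 25 °C."""
    k_t = np.asarray(k_t, dtype=float)
    if np.any(k_t <= 0):
        raise ValueError("rate must be positive")
    t_k = np.asarray(tleaf, dtype=float) + 273.15
    if np.any(t_k <= 0):
        raise ValueError("temperature at or below absolute zero")
    factor = np.exp(ea * (t_k - T_REF_K) / (T_REF_K * R_GAS * t_k))
    out = k_t / factor
    return float(out) if np.isscalar(tleaf) and out.ndim == 0 else out


def electron_transport_rate(jmax: float | np.ndarray, q: float, theta: float, alpha: float):
    """Potential electron transport rate J: lower root of
    θJ² − (αQ + Jmax)J + αQ·Jmax = 0 (non-rectangular hyperbola)."""
    aq = alpha * q
    b = aq + jmax
    disc = b * b - 4.0 * theta * aq * jmax
    return (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)


def _limiting_rates(params: FvCBParameters, ci, q, tleaf):
    ci = np.asarray(ci, dtype=float)
    if np.any(ci < 0):
        raise ValueError("ci must be non-negative")
    vcmax = arrhenius_scale(params.vcmax25, params.ea_vcmax, tleaf)
    jmax = arrhenius_scale(params.jmax25, params.ea_jmax, tleaf)
    rd = arrhenius_scale(params.rd25, params.ea_rd, tleaf) if params.rd25 > 0 else 0.0
    gstar = arrhenius_scale(params.gammastar25, params.ea_gammastar, tleaf)
    kc = arrhenius_scale(params.kc25, params.ea_kc, tleaf)
    ko = arrhenius_scale(params.ko25, params.ea_ko, tleaf)

    km = kc * (1.0 + params.o / ko)
    ac = vcmax * (ci - gstar) / (ci + km)
    j = electron_transport_rate(jmax, q, params.theta, params.alpha)
    aj = j * (ci - gstar) / (4.0 * ci + 8.0 * gstar)
    return ac, aj, rd


def forward_assimilation(
    params: FvCBParameters,
    ci: float | np.ndarray,
    q: float = 1500.0,
    tleaf: float | np.ndarray = 25.0,
):
    """Net assimilation A = min(Ac, Aj) − Rd at the given Ci, Q and Tleaf."""
    ac, aj, rd = _limiting_rates(params, ci, q, tleaf)
    a = np.minimum(ac, aj) - rd
    return float(a) if np.isscalar(ci) else a


def limitation_state(params: FvCBParameters, ci, q=1500.0, tleaf=25.0) -> np.ndarray:
    """Per-point limitation: 'rubisco' where Ac < Aj, else 'rubp'."""
    ac, aj, _ = _limiting_rates(params, np.atleast_1d(ci), q, tleaf)
    return np.where(ac < aj, "rubisco", "rubp")


# Multi-start initial values (vcmax25, jmax25, rd25) for the bounded fit.
_FIT_STARTS: tuple[tuple[float, float, float], ...] = (
    (50.0, 100.0, 1.0),
    (100.0, 200.0, 1.5),
    (25.0, 50.0, 0.5),
)
_FIT_BOUNDS = (np.array([1.0, 1.0, 0.0]), np.array([500.0, 1000.0, 10.0]))


def fit_aci(
    curve: ACiCurve,
    constants: FvCBParameters | None = None,
    init: tuple[float, float, float] | None = None,
) -> FitResult:
    """Fit (Vcmax25, Jmax25, Rd25) to an A-Ci curve by bounded nonlinear
    least squares with multi-start.

    ``constants`` supplies the kinetic constants / activation energies /
    θ, α block (its vcmax25/jmax25/rd25 fields are ignored). Rd25 is a free
    parameter bounded to [0, 10] µmol m⁻² s⁻¹. Returns best-effort
    parameters with ``converged=False`` if no start converges.
    """
    if np.ptp(curve.ci) == 0:
        raise ValueError("all ci values identical; curve carries no information")
    consts = constants if constants is not None else FvCBParameters()

    ci, a_obs, q, tleaf = curve.ci, curve.a, curve.q, curve.tleaf

    def residuals(x: np.ndarray) -> np.ndarray:
        p = replace(consts, vcmax25=x[0], jmax25=x[1], rd25=max(x[2], 0.0))
        return forward_assimilation(p, ci, q, tleaf) - a_obs

    starts = list(_FIT_STARTS)
    if init is not None:
        starts.insert(0, tuple(init))

    best = None
    any_ok = False
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), *_FIT_BOUNDS)
        try:
            res = least_squares(
                residuals, x0, bounds=_FIT_BOUNDS, xtol=1e-8, ftol=1e-8, gtol=1e-8
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        any_ok = any_ok or res.success

    if best is None:
        params = replace(consts, vcmax25=starts[0][0], jmax25=starts[0][1], rd25=starts[0][2])
        return FitResult(
            params=params,
            rmse_fit=float(np.sqrt(np.mean(residuals(np.asarray(starts[0])) ** 2))),
            limitation=limitation_state(params, ci, q, tleaf),
            converged=False,
            plant_id=curve.plant_id,
            n_points=ci.size,
        )

    vc, jm, rd = best.x
    params = replace(consts, vcmax25=vc, jmax25=jm, rd25=rd)
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return FitResult(
        params=params,
        rmse_fit=rmse,
        limitation=limitation_state(params, ci, q, tleaf),
        converged=bool(any_ok),
        plant_id=curve.plant_id,
        n_points=ci.size,
    )


def trait_summary(
    fits: Sequence[FitResult],
    grouping: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-plant photosynthetic traits: arithmetic mean of converged
    leaf-level fits.

    ``grouping`` optionally maps each fit's plant_id (leaf label) to a plant
    identifier; without it fits sharing a plant_id are averaged. Plants whose
    fits all failed to converge get NaN traits and ``all_converged=False``.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for f in fits:
        plant = grouping.get(f.plant_id, f.plant_id) if grouping else f.plant_id
        rows.append(
            {
                "plant_id": plant,
                "vcmax25": f.params.vcmax25,
                "jmax25": f.params.jmax25,
                "rd25": f.params.rd25,
                "rmse_fit": f.rmse_fit,
                "converged": f.converged,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for plant, grp in df.groupby("plant_id", sort=True):
        ok = grp[grp["converged"]]
        if len(grp) == 0:
            raise ValueError(f"empty group for plant {plant}")
        if len(ok) == 0:
            out.append(
                {
                    "plant_id": plant,
                    "vcmax25": np.nan,
                    "jmax25": np.nan,
                    "rd25": np.nan,
                    "n_leaves": len(grp),
                    "n_converged": 0,
                    "all_converged": False,
                }
            )
        else:
            out.append(
                {
                    "plant_id": plant,
                    "vcmax25": float(ok["vcmax25"].mean()),
                    "jmax25": float(ok["jmax25"].mean()),
                    "rd25": float(ok["rd25"].mean()),
                    "n_leaves": len(grp),
                    "n_converged": len(ok),
                    "all_converged": bool(grp["converged"].all()),
                }
            )
    return pd.DataFrame(out)


def write_curves_csv(curves: Sequence[ACiCurve], path) -> None:
    """Write curves in long format: plant_id, t_s, ci, a, tleaf, q."""
    frames = []
    for c in curves:
        n = c.ci.size
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": np.repeat(c.plant_id, n),
                    "t_s": c.t_s if c.t_s is not None else np.arange(1, n + 1, dtype=float),
                    "ci": c.ci,
                    "a": c.a,
                    "tleaf": np.broadcast_to(np.asarray(c.tleaf, dtype=float), (n,)),
                    "q": np.repeat(float(c.q), n),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path) -> list[ACiCurve]:
    """Read long-format A-Ci curves written by :func:`write_curves_csv`."""
    df = pd.read_csv(path)
    curves = []
    for plant, grp in df.groupby("plant_id", sort=True):
        tleaf = grp["tleaf"].to_numpy()
        tleaf = float(tleaf[0]) if np.ptp(tleaf) == 0 else tleaf
        curves.append(
            ACiCurve(
                ci=grp["ci"].to_numpy(),
                a=grp["a"].to_numpy(),
                tleaf=tleaf,
                q=float(grp["q"].iloc[0]),
                plant_id=str(plant),
                t_s=grp["t_s"].to_numpy(),
            )
        )
    return curves
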