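"""Spectral-index registry over 5-band (B, G, R, RE, NIR) reflectance.

Every index used by the core trait analysis is implemented here; the
registry is extensible so a larger published index bank can be added from a
config file. A handful of index names whose published formulas vary between
sources or could not be verified (IPCA, CI2, WI, NDI, VIre) ship as stubs
that raise :class:`UnregisteredFormulaError` until the user supplies a
definition — formulas are never guessed.

All index functions are numpy-vectorized: they accept scalars or arrays of
any shape, so the same registry serves tabular ROI means and per-pixel maps.
Guard violations (near-zero denominators, negative arguments under a square
root) yield NaN, flagged but never raised mid-batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .imaging import BAND_NAMES

_EPS = 1e-12

__all__ = [
    "IndexDefinition",
    "UnregisteredFormulaError",
    "REGISTRY",
    "STUB_NAMES",
    "registered_names",
    "compute_index",
    "compute_all",
    "register_index",
    "load_registry_config",
    "save_registry_config",
]


class UnregisteredFormulaError(KeyError):
    """An index is known by name but its formula has not been supplied."""


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    func: Callable[..., np.ndarray]
    formula: str


def _div(num, den):
    """Guarded division: NaN where the denominator is (near) zero."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(den) > _EPS, num / np.where(np.abs(den) > _EPS, den, 1.0), np.nan)
    return out


def _sqrt(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(x >= 0, np.sqrt(np.abs(x)), np.nan)


# Each entry: name -> (formula string, callable over (B, G, R, RE, NIR)).
_FORMULAS: dict[str, tuple[str, Callable]] = {
    "NDVI": ("(NIR - R)/(NIR + R)", lambda B, G, R, RE, NIR: _div(NIR - R, NIR + R)),
    "NDRE": ("(NIR - RE)/(NIR + RE)", lambda B, G, R, RE, NIR: _div(NIR - RE, NIR + RE)),
    "SCCCI": (
        "NDRE/NDVI",
        lambda B, G, R, RE, NIR: _div(_div(NIR - RE, NIR + RE), _div(NIR - R, NIR + R)),
    ),
    "CVI": ("NIR*R/G**2", lambda B, G, R, RE, NIR: _div(NIR * R, G**2)),
    "CI_green": ("NIR/G - 1", lambda B, G, R, RE, NIR: _div(NIR, G) - 1.0),
    "CI_RE": ("NIR/RE - 1", lambda B, G, R, RE, NIR: _div(NIR, RE) - 1.0),
    "GNDVI": ("(NIR - G)/(NIR + G)", lambda B, G, R, RE, NIR: _div(NIR - G, NIR + G)),
    "VIg": ("(G - R)/(G + R)", lambda B, G, R, RE, NIR: _div(G - R, G + R)),
    "VARI": ("(G - R)/(G + R - B)", lambda B, G, R, RE, NIR: _div(G - R, G + R - B)),
    "GRRI": ("G/R", lambda B, G, R, RE, NIR: _div(G, R)),
    "GBRI": ("G/B", lambda B, G, R, RE, NIR: _div(G, B)),
    "IKAW": ("(R - B)/(R + B)", lambda B, G, R, RE, NIR: _div(R - B, R + B)),
    "MGRVI": ("(G**2 - R**2)/(G**2 + R**2)", lambda B, G, R, RE, NIR: _div(G**2 - R**2, G**2 + R**2)),
    "RGBVI": (
        "(G**2 - B*R)/(G**2 + B*R)",
        lambda B, G, R, RE, NIR: _div(G**2 - B * R, G**2 + B * R),
    ),
    "GLI": (
        "(2*G - R - B)/(2*G + R + B)",
        lambda B, G, R, RE, NIR: _div(2 * G - R - B, 2 * G + R + B),
    ),
    "ExG": ("2*G - R - B", lambda B, G, R, RE, NIR: 2 * G - R - B),
    "ExB": ("1.4*B - G", lambda B, G, R, RE, NIR: 1.4 * B - G),
    "SIPI": ("(NIR - B)/(NIR - R)", lambda B, G, R, RE, NIR: _div(NIR - B, NIR - R)),
    "MSAVI2": (
        "(2*NIR + 1 - sqrt((2*NIR + 1)**2 - 8*(NIR - R)))/2",
        lambda B, G, R, RE, NIR: (2 * NIR + 1 - _sqrt((2 * NIR + 1) ** 2 - 8 * (NIR - R))) / 2,
    ),
    "MCARI2": (
        "1.5*(2.5*(NIR - R) - 1.3*(NIR - G))/sqrt((2*NIR + 1)**2 - (6*NIR - 5*sqrt(R)) - 0.5)",
        lambda B, G, R, RE, NIR: _div(
            1.5 * (2.5 * (NIR - R) - 1.3 * (NIR - G)),
            _sqrt((2 * NIR + 1) ** 2 - (6 * NIR - 5 * _sqrt(R)) - 0.5),
        ),
    ),
    # raw bands
    "B": ("B", lambda B, G, R, RE, NIR: B + 0.0),
    "G": ("G", lambda B, G, R, RE, NIR: G + 0.0),
    "R": ("R", lambda B, G, R, RE, NIR: R + 0.0),
    "RE": ("RE", lambda B, G, R, RE, NIR: RE + 0.0),
    "NIR": ("NIR", lambda B, G, R, RE, NIR: NIR + 0.0),
    # reciprocals
    "1/B": ("1/B", lambda B, G, R, RE, NIR: _div(1.0, B)),
    "1/G": ("1/G", lambda B, G, R, RE, NIR: _div(1.0, G)),
    "1/R": ("1/R", lambda B, G, R, RE, NIR: _div(1.0, R)),
    "1/RE": ("1/RE", lambda B, G, R, RE, NIR: _div(1.0, RE)),
    "1/NIR": ("1/NIR", lambda B, G, R, RE, NIR: _div(1.0, NIR)),
    # chromatic coordinates
    "g": ("G/(R + G + B)", lambda B, G, R, RE, NIR: _div(G, R + G + B)),
    "b": ("B/(R + G + B)", lambda B, G, R, RE, NIR: _div(B, R + G + B)),
}

#: Index names without a verified formula; computing them raises
#: UnregisteredFormulaError until a definition is registered.
STUB_NAMES: tuple[str, ...] = ("IPCA", "CI2", "WI", "NDI", "VIre")

REGISTRY: dict[str, IndexDefinition] = {
    name: IndexDefinition(name=name, func=func, formula=formula)
    for name, (formula, func) in _FORMULAS.items()
}


def registered_names() -> list[str]:
    """Names of computable indices, in stable registry order."""
    return list(REGISTRY)


def _bands_from(bands) -> tuple[np.ndarray, ...]:
    """Accept a SceneRaster-like, mapping, Series or 5-sequence of bands."""
    if hasattr(bands, "band"):  # SceneRaster
        return tuple(np.asarray(bands.band(n), dtype=float) for n in BAND_NAMES)
    if isinstance(bands, pd.DataFrame):
        return tuple(bands[n].to_numpy(dtype=float) for n in BAND_NAMES)
    if isinstance(bands, (pd.Series, Mapping)):
        return tuple(np.asarray(bands[n], dtype=float) for n in BAND_NAMES)
    arr = [np.asarray(b, dtype=float) for b in bands]
    if len(arr) != 5:
        raise ValueError("expected 5 bands (B, G, R, RE, NIR)")
    return tuple(arr)


def compute_index(name: str, bands):
    """Compute one registered index from reflectance bands.

    ``bands`` may be a mapping/Series keyed by band name, a 5-sequence in
    (B, G, R, RE, NIR) order, a DataFrame with band columns, or a SceneRaster.
    """
    if name in STUB_NAMES and name not in REGISTRY:
        raise UnregisteredFormulaError(
            f"{name!r} has no registered formula; register one with register_index()"
        )
    if name not in REGISTRY:
        raise KeyError(f"unknown index {name!r}")
    out = REGISTRY[name].func(*_bands_from(bands))
    return float(out) if np.ndim(out) == 0 else out


def compute_all(bands, names: list[str] | None = None) -> pd.Series | pd.DataFrame:
    """Compute every registered index (stable column order).

    A single sample returns a Series; a DataFrame of N samples returns an
    N-row DataFrame. NaN flags from guard violations propagate.
    """
    names = names if names is not None else registered_names()
    cols = {n: compute_index(n, bands) for n in names}
    if isinstance(bands, pd.DataFrame):
        return pd.DataFrame(cols, index=bands.index)
    first = next(iter(cols.values()))
    if np.ndim(first) == 0:
        return pd.Series(cols)
    return pd.DataFrame(cols)


_SAFE_NAMESPACE = {"sqrt": _sqrt, "abs": np.abs, "where": np.where, "nan": np.nan}


def register_index(name: str, formula: str) -> IndexDefinition:
    """Register an index from a formula string over B, G, R, RE, NIR.

    The expression is evaluated with numpy semantics and a guarded sqrt;
    e.g. ``register_index("VIre", "(RE - R)/(RE + R)")``.
    """
    code = compile(formula, f"<index {name}>", "eval")

    def func(B, G, R, RE, NIR, _code=code):
        env = dict(_SAFE_NAMESPACE, B=B, G=G, R=R, RE=RE, NIR=NIR)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = eval(_code, {"__builtins__": {}}, env)
        out = np.asarray(out, dtype=float)
        return np.where(np.isfinite(out), out, np.nan)

    definition = IndexDefinition(name=name, func=func, formula=formula)
    REGISTRY[name] = definition
    return definition


def save_registry_config(path) -> None:
    """Serialize the registry (name → formula string) to JSON."""
    with open(path, "w") as fh:
        json.dump({n: d.formula for n, d in REGISTRY.items()}, fh, indent=1)


def load_registry_config(path) -> list[str]:
    """Load user index definitions from JSON; returns the names added."""
    with open(path) as fh:
        formulas = json.load(fh)
    added = []
    for name, formula in formulas.items():
        if name not in REGISTRY:
            register_index(name, formula)
            added.append(name)
    return added
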