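"""Spectral pretreatments: SG smoothing/derivatives, SNV, MSC, Euclidean norm.

All transforms operate row-wise on an (n, p) matrix of corrected spectra and
preserve its shape.  MSC is the only method with a fitted state: its
reference spectrum is the training-set mean, frozen before being applied to
prediction data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PretreatmentSpec",
    "snv",
    "msc",
    "savitzky_golay",
    "norm_unit",
    "apply_pretreatment",
    "PRETREATMENTS",
]

# canonical name -> (window, polyorder, deriv); None entries are not SG-based
_SG_SETTINGS = {
    "SGS": (9, 2, 0),
    "SG-D1": (11, 2, 1),
    "SG-D2": (25, 2, 2),
}

#: Canonical pretreatment names, including the identity "raw".
PRETREATMENTS = ("raw", "SGS", "SNV", "MSC", "SG-D1", "SG-D2", "Norm")

_ALIASES = {
    "raw": "raw", "none": "raw",
    "sgs": "SGS", "snv": "SNV", "msc": "MSC", "norm": "Norm",
    "sg-d1": "SG-D1", "sgd1": "SG-D1", "sg_d1": "SG-D1",
    "sg-d2": "SG-D2", "sgd2": "SG-D2", "sg_d2": "SG-D2",
}


def canonical_name(name: str) -> str:
    key = name.strip().lower()
    if key not in _ALIASES:
        raise ValueError(f"unknown pretreatment {name!r}; expected one of {PRETREATMENTS}")
    return _ALIASES[key]


@dataclass
class PretreatmentSpec:
    """A named pretreatment with its window/order settings.

    Defaults follow the study protocol: SGS window 9, SG-D1 window 11,
    SG-D2 window 25, all with polynomial order 2.
    """

    name: str
    window: int | None = None
    polyorder: int = 2
    reference: np.ndarray | None = None  # MSC only

    def __post_init__(self) -> None:
        self.name = canonical_name(self.name)
        if self.name in _SG_SETTINGS:
            default_window, default_order, _ = _SG_SETTINGS[self.name]
            if self.window is None:
                self.window = default_window
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise ValueError("window must be odd and exceed polyorder")


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-row centering and unit (n−1) scaling."""
    X = _as_matrix(X)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"constant spectrum at row {flat[0]}: SNV undefined")
    return (X - mu) / sd


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row ``x`` is regressed as ``x ≈ a + b·reference`` (ordinary least
    squares) and returned as ``(x − a) / b``.
    """
    X = _as_matrix(X)
    ref = np.asarray(reference, dtype=float).ravel()
    if ref.size != X.shape[1]:
        raise ValueError("reference length must match channel count")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise ValueError("reference spectrum is constant")
    Xc = X - X.mean(axis=1, keepdims=True)
    b = (Xc @ ref_c) / denom
    if np.any(np.abs(b) < 1e-12):
        row = int(np.flatnonzero(np.abs(b) < 1e-12)[0])
        raise ValueError(f"MSC slope ~0 at row {row}")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def savitzky_golay(X: np.ndarray, window: int, polyorder: int,
                   deriv: int = 0, spacing: float = 1.0) -> np.ndarray:
    """Savitzky–Golay filtering, optionally with 1st/2nd derivative per nm.

    ``spacing`` is the wavelength step of the (uniform) grid; derivatives are
    scaled by ``spacing**deriv`` so the output is per-nm.  Edges use the
    boundary polynomial fits, so the channel count is preserved.
    """
    X = _as_matrix(X)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be below window")
    if deriv > polyorder:
        raise ValueError("deriv must not exceed polyorder")
    if window > X.shape[1]:
        raise ValueError("window exceeds channel count")
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         deriv=deriv, delta=spacing, axis=1, mode="interp")


def norm_unit(X: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm."""
    X = _as_matrix(X)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    flat = np.flatnonzero(norms.ravel() == 0)
    if flat.size:
        raise ValueError(f"zero spectrum at row {flat[0]}")
    return X / norms


def apply_pretreatment(spec: PretreatmentSpec, X: np.ndarray,
                       fit_context: np.ndarray | None = None,
                       spacing: float = 1.0) -> np.ndarray:
    """Dispatch a pretreatment; MSC derives its reference from ``fit_context``.

    For MSC the reference is the mean spectrum of ``fit_context`` (the
    training set); pass the same context when transforming prediction data
    so the exact same reference is reused.  An explicit ``spec.reference``
    wins over ``fit_context``.
    """
    name = spec.name
    if name == "raw":
        return _as_matrix(X).copy()
    if name == "SNV":
        return snv(X)
    if name == "Norm":
        return norm_unit(X)
    if name == "MSC":
        if spec.reference is not None:
            ref = spec.reference
        elif fit_context is not None:
            ref = _as_matrix(fit_context).mean(axis=0)
        else:
            raise ValueError("MSC needs fit_context or an explicit reference")
        return msc(X, ref)
    window, polyorder, deriv = _SG_SETTINGS[name]
    window = spec.window if spec.window is not None else window
    polyorder = spec.polyorder if spec.polyorder is not None else polyorder
    return savitzky_golay(X, window, polyorder, deriv=deriv, spacing=spacing)
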