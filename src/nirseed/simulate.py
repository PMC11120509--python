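"""Synthetic single-kernel NIR spectra with planted class structure.

Single-kernel near-infrared spectra of maize seeds are measured on-line as a
raw intensity ``S_raw`` together with a white reference ``S_white`` (the empty
light path); the corrected spectrum is the channel-wise ratio
``S_c = S_raw / S_white``, a dimensionless transmittance-like quantity in
(0, 1].  This module generates two-class datasets in exactly that measurement
form so that every downstream stage — white-reference correction,
pretreatment, classification and wavelength selection — can be exercised and
validated without access to any instrument.

The generative model, per kernel ``i`` with class label ``y_i ∈ {−1, +1}``:

1. a smooth class curve on the wavelength grid λ::

       c_i(λ) = baseline(λ) − Σ_b shared_b(λ) − (y_i / 2) · Σ_e effect_e(λ)

   where every band is a Gaussian absorption profile
   ``A·exp(−(λ−center)² / (2·width²))``; shared bands model the common
   absorption features (around 1110, 1200 and 1300 nm for maize kernels),
   effect bands carry the class-mean amplitude difference concentrated in
   the discriminative regions (1000–1020, 1260–1300, 1420–1480 and
   1500–1520 nm).  The curve is clipped to (0, 1].
2. per-kernel multiplicative scatter ``g_i = 1 + N(0, scatter_sd)`` and an
   additive baseline shift ``o_i = N(0, offset_sd)``:
   ``s_i(λ) = g_i·c_i(λ) + o_i`` — the noise-free corrected signal.
3. channel noise on the corrected-ratio scale:
   ``raw_i(λ) = white(λ) · (s_i(λ) + ε_{iλ})`` with
   ``ε ~ N(0, noise_sd)`` i.i.d. per channel.

The peak class-mean difference at an effect-band center equals that band's
``delta``; halving per class keeps the between-class centroid distance equal
to the planted profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulationConfig",
    "SimulatedBundle",
    "default_config",
    "recovery_config",
    "make_grid",
    "band_profile",
    "simulate_dataset",
    "planted_band_mask",
    "DEFAULT_SHARED_BANDS",
    "DEFAULT_EFFECT_BANDS",
]

#: (center nm, width nm, amplitude) of class-common absorption bands.
DEFAULT_SHARED_BANDS: tuple[tuple[float, float, float], ...] = (
    (1110.0, 25.0, 0.12),
    (1200.0, 30.0, 0.10),
    (1300.0, 40.0, 0.08),
)

#: (center nm, width nm, delta) of class-discriminative bands.  Widths are
#: chosen so that center ± 2·width spans exactly the nominal discriminative
#: intervals 1000–1020, 1260–1300, 1420–1480 and 1500–1520 nm.
DEFAULT_EFFECT_BANDS: tuple[tuple[float, float, float], ...] = (
    (1010.0, 5.0, 0.1),
    (1280.0, 10.0, 0.1),
    (1450.0, 15.0, 0.1),
    (1510.0, 5.0, 0.1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-class spectra generator.

    Attributes
    ----------
    n_per_class : int
        Kernels per harvest-year class (total sample size is twice this).
    n_channels : int
        Spectrometer channels; 512 reproduces the study-scale grid.
    wl_min, wl_max : float
        Wavelength range in nm (899–1715 nm by default).
    shared_bands : tuple of (center, width, amplitude)
        Class-common Gaussian absorption bands.
    effect_bands : tuple of (center, width, delta)
        Class-discriminative bands; ``delta`` is the peak class-mean
        amplitude difference in corrected-ratio units.
    scatter_sd : float
        Std of the per-kernel multiplicative gain around 1.
    offset_sd : float
        Std of the per-kernel additive baseline shift.
    noise_sd : float
        Std of the per-channel additive noise, on the corrected-ratio scale.
    seed : int
        Seed of the single RNG stream used for the whole bundle.
    """

    n_per_class: int = 200
    n_channels: int = 512
    wl_min: float = 899.0
    wl_max: float = 1715.0
    shared_bands: tuple = DEFAULT_SHARED_BANDS
    effect_bands: tuple = DEFAULT_EFFECT_BANDS
    scatter_sd: float = 0.05
    offset_sd: float = 0.02
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if not self.wl_min < self.wl_max:
            raise ValueError("wl_min must be strictly below wl_max")
        for center, width, _ in tuple(self.shared_bands) + tuple(self.effect_bands):
            if width <= 0:
                raise ValueError(f"band width must be > 0, got {width}")
        for center, _, _ in self.effect_bands:
            if not self.wl_min <= center <= self.wl_max:
                raise ValueError(
                    f"effect band center {center} nm outside "
                    f"[{self.wl_min}, {self.wl_max}] nm"
                )
        for name in ("scatter_sd", "offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimulatedBundle:
    """A simulated acquisition: raw intensities, white reference and truth.

    ``truth_transmittance`` is the noise-free corrected signal per kernel
    (class curve with gain and offset applied) and serves as the exact
    oracle for the white-reference correction at ``noise_sd = 0``.
    """

    raw: np.ndarray
    white: np.ndarray
    truth_transmittance: np.ndarray
    labels: np.ndarray
    config: SimulationConfig

    def __post_init__(self) -> None:
        if np.any(self.white <= 0):
            raise ValueError("white reference must be strictly positive")
        n = self.labels.size
        if np.sum(self.labels == -1) != n // 2 or np.sum(self.labels == 1) != n // 2:
            raise ValueError("labels must be balanced in {-1, +1}")


def default_config(effect_delta: float = 0.1, **overrides) -> SimulationConfig:
    """Default study-scale configuration with a uniform effect amplitude.

    ``effect_delta`` rescales every default effect band's class difference;
    0 gives a null (no class signal) dataset.
    """
    bands = tuple((c, w, effect_delta) for c, w, _ in DEFAULT_EFFECT_BANDS)
    return SimulationConfig(effect_bands=bands, **overrides)


def recovery_config(effect_delta: float = 0.1, seed: int = 0, **overrides) -> SimulationConfig:
    """Benchmark configuration for wavelength-selector recovery studies.

    Plants ~30 informative channels — four narrow bands (σ = 3 nm) centered
    in the discriminative regions — against a pure-channel-noise background
    (no multiplicative scatter or baseline offsets), so that band membership
    of the selected channels is a well-defined recovery measure.
    """
    bands = tuple((c, 3.0, effect_delta) for c in (1010.0, 1280.0, 1450.0, 1510.0))
    overrides.setdefault("scatter_sd", 0.0)
    overrides.setdefault("offset_sd", 0.0)
    return SimulationConfig(effect_bands=bands, seed=seed, **overrides)


def make_grid(n_channels: int, wl_min: float, wl_max: float) -> np.ndarray:
    """Linearly spaced wavelength grid from ``wl_min`` to ``wl_max`` nm."""
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if not wl_min < wl_max:
        raise ValueError("wl_min must be strictly below wl_max")
    return np.linspace(float(wl_min), float(wl_max), int(n_channels))


def band_profile(
    grid: np.ndarray, center: float, width: float, amplitude: float
) -> np.ndarray:
    """Gaussian absorption band ``A·exp(−(λ−center)²/(2·width²))`` on a grid."""
    if width <= 0:
        raise ValueError("width must be > 0")
    grid = np.asarray(grid, dtype=float)
    return amplitude * np.exp(-((grid - center) ** 2) / (2.0 * width**2))


def _baseline(grid: np.ndarray, wl_min: float, wl_max: float) -> np.ndarray:
    # Gentle downward-sloping transmittance envelope, well inside (0, 1).
    u = (grid - wl_min) / (wl_max - wl_min)
    return 0.82 - 0.12 * u - 0.06 * u**2


def class_curves(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wavelength grid and the two noise-free class-mean curves (−1, +1)."""
    grid = make_grid(config.n_channels, config.wl_min, config.wl_max)
    common = _baseline(grid, config.wl_min, config.wl_max)
    for c, w, a in config.shared_bands:
        common = common - band_profile(grid, c, w, a)
    effect = np.zeros_like(grid)
    for c, w, d in config.effect_bands:
        effect = effect + band_profile(grid, c, w, d)
    eps = 1e-6
    lo = np.clip(common + 0.5 * effect, eps, 1.0)   # label −1
    hi = np.clip(common - 0.5 * effect, eps, 1.0)   # label +1
    return grid, lo, hi


def _white_reference(grid: np.ndarray) -> np.ndarray:
    # Broad lamp/detector response, strictly positive, in raw counts.
    return 30000.0 * np.exp(-((grid - 1250.0) ** 2) / (2.0 * 350.0**2)) + 5000.0


def simulate_dataset(config: SimulationConfig) -> SimulatedBundle:
    """Draw a full two-class bundle (raw, white, truth, labels).

    Deterministic: identical configs (including seed) give bit-identical
    bundles.  Labels come out as ``n_per_class`` copies of −1 followed by
    ``n_per_class`` copies of +1.
    """
    rng = np.random.default_rng(config.seed)
    grid, curve_neg, curve_pos = class_curves(config)
    n = 2 * config.n_per_class
    labels = np.concatenate(
        [-np.ones(config.n_per_class, dtype=int), np.ones(config.n_per_class, dtype=int)]
    )
    clean = np.where(labels[:, None] < 0, curve_neg[None, :], curve_pos[None, :])

    gain = 1.0 + rng.normal(0.0, config.scatter_sd, size=n)
    offset = rng.normal(0.0, config.offset_sd, size=n)
    truth = gain[:, None] * clean + offset[:, None]

    white = _white_reference(grid)
    noise = rng.normal(0.0, config.noise_sd, size=(n, config.n_channels))
    raw = white[None, :] * (truth + noise)
    return SimulatedBundle(
        raw=raw, white=white, truth_transmittance=truth, labels=labels, config=config
    )


def planted_band_mask(config: SimulationConfig, grid: np.ndarray | None = None,
                      half_width_factor: float = 2.0) -> np.ndarray:
    """Boolean channel mask of the planted discriminative regions.

    A channel belongs to the mask when it lies within
    ``half_width_factor · width`` of any effect-band center; with the default
    factor 2 and default bands this reproduces the nominal discriminative
    intervals (1000–1020, 1260–1300, 1420–1480, 1500–1520 nm).
    """
    if grid is None:
        grid = make_grid(config.n_channels, config.wl_min, config.wl_max)
    mask = np.zeros(grid.shape, dtype=bool)
    for c, w, _ in config.effect_bands:
        mask |= np.abs(grid - c) <= half_width_factor * w
    return mask
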