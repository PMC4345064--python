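"""Synthetic three-class ATR-FTIR dataset generator.

The real authentication problem involves three botanically related root
materials whose mid-IR fingerprints share every major band — broad O-H
stretch near 3300 cm^-1, C-H stretch near 2920 cm^-1, and the
carbohydrate C-O region around 1030-1200 cm^-1 — and differ only in
relative band intensities.  No raw spectra are deposited, so this module
emulates that regime: three class templates with identical band centres
and widths whose amplitudes differ by 5-20% per band, degraded by
additive noise, random linear baseline drift, and multiplicative
intensity jitter.

The default NoiseModel values are the study conditions every evaluation
in this package runs under; they are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "BandSpec",
    "ClassTemplate",
    "NoiseModel",
    "default_grid",
    "default_templates",
    "render_spectrum",
    "generate_dataset",
]


def default_grid() -> np.ndarray:
    """Instrument grid: 4000 -> 650 cm^-1 at 2 cm^-1 steps (1676 points)."""
    return np.arange(4000.0, 649.0, -2.0)


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: centre, full width at half maximum, peak height."""

    center: float  # cm^-1
    fwhm: float  # cm^-1
    amplitude: float  # absorbance units (peak height)
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "lorentzian":
            hw = self.fwhm / 2.0
            return self.amplitude * hw**2 / (d**2 + hw**2)
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.amplitude * np.exp(-0.5 * (d / sigma) ** 2)


@dataclass(frozen=True)
class ClassTemplate:
    """Named set of bands defining a class's noiseless fingerprint."""

    name: str
    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("a class template needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))

    def render(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Noiseless absorbance: sum of the band lineshapes."""
        y = np.zeros_like(wavenumbers, dtype=float)
        for band in self.bands:
            y += band.profile(wavenumbers)
        return y


@dataclass(frozen=True)
class NoiseModel:
    """Degradation model applied on top of a class template.

    additive_sigma
        i.i.d. Gaussian noise per point, absorbance units.
    baseline_slope_sigma
        std of the random linear baseline slope, absorbance per cm^-1
        (the tilt is centred on the middle of the grid).
    intensity_scale_sigma
        std of the multiplicative intensity jitter (1 + eps), emulating
        contact-pressure variation on the ATR crystal.
    """

    additive_sigma: float = 0.005
    baseline_slope_sigma: float = 5e-6
    intensity_scale_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sigma", "baseline_slope_sigma", "intensity_scale_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# Shared band positions/widths of the three root materials.  Tuples are
# (center cm^-1, fwhm cm^-1, base amplitude).  Alongside the broad O-H,
# C-H and C-O envelopes, dried plant-root powders show many narrow
# fingerprint-region peaks (ester carbonyl, aromatic ring modes,
# CH2/CH3 deformations, glycosidic C-O-C and ring vibrations); those
# sharp features are what the detail-scale wavelet energies respond to.
# See docs/methods.md for the assignments these mimic.
_SHARED_BANDS: tuple[tuple[float, float, float], ...] = (
    (3300.0, 300.0, 0.45),  # broad O-H stretch (moisture/polysaccharide)
    (2920.0, 40.0, 0.25),  # aliphatic C-H stretch (asym)
    (2850.0, 30.0, 0.12),  # aliphatic C-H stretch (sym)
    (1740.0, 24.0, 0.12),  # ester C=O stretch
    (1650.0, 50.0, 0.35),  # amide I / bound-water bend
    (1615.0, 22.0, 0.15),  # aromatic ring / COO- asym
    (1515.0, 14.0, 0.08),  # aromatic ring mode
    (1450.0, 18.0, 0.18),  # CH2 scissoring
    (1400.0, 24.0, 0.30),  # COO- sym / CH deformation
    (1370.0, 14.0, 0.15),  # CH3 bending
    (1320.0, 12.0, 0.10),  # CH2 wagging
    (1240.0, 20.0, 0.20),  # C-O stretch (hemicellulose/pectin)
    (1155.0, 14.0, 0.28),  # C-O-C asym stretch (glycosidic)
    (1100.0, 60.0, 0.55),  # C-O / C-O-C stretch envelope (carbohydrates)
    (1078.0, 14.0, 0.35),  # C-O ring stretch
    (1030.0, 22.0, 0.50),  # C-O stretch (polysaccharide backbone)
    (930.0, 14.0, 0.10),  # glycosidic linkage / ring breathing
    (890.0, 10.0, 0.07),  # beta-glycosidic C1-H deformation
    (815.0, 12.0, 0.06),  # ring deformation
    (765.0, 14.0, 0.07),  # skeletal bending
    (700.0, 12.0, 0.08),  # skeletal / out-of-plane bending
)

# Per-band amplitude factor triples (genuine, variant_a, variant_b): the
# only thing distinguishing the classes.  Composition differences move
# whole compound families together, so the factors are tied to band
# character.  Each class pair is contrasted strongly on one band family
# and moderately on the other two, so all three materials are mutually
# separable while every per-band pairwise intensity difference stays
# within 5-20%.
_FACTORS_NARROW = (1.00, 0.91, 1.09)  # fwhm <= 15 cm^-1 (sharp modes)
_FACTORS_MEDIUM = (1.07, 0.99, 0.90)  # 15 < fwhm < 30 cm^-1
_FACTORS_BROAD = (0.91, 1.08, 0.99)  # fwhm >= 30 cm^-1 (envelopes)

_CLASS_NAMES: tuple[str, str, str] = ("genuine", "variant_a", "variant_b")


def _band_factors(fwhm: float) -> tuple[float, float, float]:
    if fwhm <= 15.0:
        return _FACTORS_NARROW
    if fwhm < 30.0:
        return _FACTORS_MEDIUM
    return _FACTORS_BROAD


def default_templates() -> tuple[ClassTemplate, ClassTemplate, ClassTemplate]:
    """Three spectrally similar class templates sharing all band positions."""
    templates = []
    for ci, name in enumerate(_CLASS_NAMES):
        bands = tuple(
            BandSpec(center=c, fwhm=w, amplitude=a * _band_factors(w)[ci])
            for c, w, a in _SHARED_BANDS
        )
        templates.append(ClassTemplate(name=name, bands=bands))
    return tuple(templates)


def render_spectrum(
    template: ClassTemplate,
    grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Render one noisy spectrum from a class template.

    Pipeline: sum of band lineshapes + random linear baseline + additive
    Gaussian noise, then multiplicative intensity jitter.  Reproducible:
    with no ``rng`` given, a fresh generator is seeded from ``noise.seed``.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if noise is None:
        noise = NoiseModel()
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    y = template.render(grid)
    if noise.baseline_slope_sigma > 0:
        slope = rng.normal(0.0, noise.baseline_slope_sigma)
        y = y + slope * (grid - grid.mean())
    if noise.additive_sigma > 0:
        y = y + rng.normal(0.0, noise.additive_sigma, size=grid.size)
    if noise.intensity_scale_sigma > 0:
        y = y * (1.0 + rng.normal(0.0, noise.intensity_scale_sigma))
    return Spectrum(grid, y, label=template.name, meta={"synthetic": True})


def generate_dataset(
    n_per_class: int,
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
    templates: tuple[ClassTemplate, ...] | None = None,
) -> SpectrumSet:
    """Balanced labelled dataset: ``n_per_class`` spectra per template.

    Deterministic given ``noise.seed``: spectra are drawn sequentially from
    one generator, class by class.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if noise is None:
        noise = NoiseModel()
    if templates is None:
        templates = default_templates()
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(noise.seed)
    spectra = [
        render_spectrum(t, grid, noise, rng=rng)
        for t in templates
        for _ in range(n_per_class)
    ]
    return SpectrumSet(spectra)
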