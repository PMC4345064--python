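"""Discrete wavelet decomposition and band-energy feature extraction.

A spectrum is decomposed with an orthogonal Daubechies wavelet into one
approximation and ``levels`` detail coefficient streams (multilevel DWT,
periodization padding so Parseval's identity holds exactly).  For each
selected detail scale the coefficient axis is split into ``n_bands``
contiguous bands and the feature is the mean of squared coefficients per
band; with the defaults (detail levels {2, 3, 4}, three bands each) every
spectrum maps to a 9-component energy feature vector.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pywt

from .spectra import Spectrum, SpectrumError

__all__ = [
    "WaveletFeatureConfig",
    "WaveletDecomposition",
    "FeatureVector",
    "decompose",
    "reconstruct",
    "band_energy_features",
    "extract_features",
]


@dataclass(frozen=True)
class WaveletFeatureConfig:
    """Wavelet, depth, selected detail scales, and feature-band layout.

    wavelet
        Daubechies family member (default 'db4').
    levels
        Decomposition depth (default 5).
    detail_levels
        Which detail scales feed features, level 1 = finest (default (2, 3, 4)).
    n_bands
        Contiguous feature bands per detail signal (default 3).
    band_edges
        Optional {level: index boundaries} overriding the equal-width split.
    mode
        Padding; 'periodization' (default) makes the transform orthonormal.
    use_mean
        Feature = mean of squared coefficients per band (default); set
        False for plain sums (sensitivity checks).
    """

    wavelet: str = "db4"
    levels: int = 5
    detail_levels: tuple[int, ...] = (2, 3, 4)
    n_bands: int = 3
    band_edges: dict[int, tuple[int, ...]] | None = None
    mode: str = "periodization"
    use_mean: bool = True

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        lv = tuple(sorted(self.detail_levels))
        if not lv or lv[0] < 1 or lv[-1] > self.levels:
            raise ValueError(
                f"detail_levels must lie within 1..{self.levels}, got {self.detail_levels}"
            )
        object.__setattr__(self, "detail_levels", lv)

    @property
    def n_features(self) -> int:
        return self.n_bands * len(self.detail_levels)

    def digest(self) -> str:
        """Stable identifier of the configuration (order-insensitive keys)."""
        payload = {
            "wavelet": self.wavelet,
            "levels": self.levels,
            "detail_levels": list(self.detail_levels),
            "n_bands": self.n_bands,
            "band_edges": {str(k): list(v) for k, v in (self.band_edges or {}).items()}
            or None,
            "mode": self.mode,
            "use_mean": self.use_mean,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class WaveletDecomposition:
    """Approximation at max depth plus detail streams for levels 1..levels."""

    approximation: np.ndarray
    details: tuple[np.ndarray, ...]  # details[i] = level i+1 (finest first)
    config: WaveletFeatureConfig
    n_points: int

    @property
    def levels(self) -> int:
        return len(self.details)

    def detail(self, level: int) -> np.ndarray:
        """Detail coefficients at a 1-based level (1 = finest scale)."""
        if not 1 <= level <= self.levels:
            raise SpectrumError(f"detail level {level} outside 1..{self.levels}")
        return self.details[level - 1]


@dataclass(frozen=True)
class FeatureVector:
    """Band-energy features for one spectrum, (level asc, band asc) order."""

    values: np.ndarray
    label: str | None
    config_digest: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise SpectrumError("features must be finite and non-negative")
        object.__setattr__(self, "values", v)


def decompose(
    spectrum: Spectrum | np.ndarray, config: WaveletFeatureConfig | None = None
) -> WaveletDecomposition:
    """Multilevel DWT of a spectrum's absorbance trace."""
    if config is None:
        config = WaveletFeatureConfig()
    y = spectrum.absorbance if isinstance(spectrum, Spectrum) else np.asarray(spectrum, float)
    wavelet = pywt.Wavelet(config.wavelet)
    max_level = pywt.dwt_max_level(y.size, wavelet.dec_len)
    if config.levels > max_level:
        raise SpectrumError(
            f"signal of length {y.size} supports at most {max_level} "
            f"levels with {config.wavelet}, requested {config.levels}"
        )
    coeffs = pywt.wavedec(y, wavelet, mode=config.mode, level=config.levels)
    approx = coeffs[0]
    # wavedec orders details coarsest-first; store finest-first as level 1..L
    details = tuple(coeffs[1:][::-1])
    return WaveletDecomposition(
        approximation=approx, details=details, config=config, n_points=y.size
    )


def reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Inverse transform from all coefficients (exact for orthogonal wavelets)."""
    coeffs = [decomp.approximation, *decomp.details[::-1]]
    y = pywt.waverec(coeffs, pywt.Wavelet(decomp.config.wavelet), mode=decomp.config.mode)
    return y[: decomp.n_points]


def _band_slices(n: int, config: WaveletFeatureConfig, level: int) -> list[slice]:
    if config.band_edges and level in config.band_edges:
        edges = (0, *config.band_edges[level], n)
    else:
        edges = tuple(np.linspace(0, n, config.n_bands + 1).astype(int))
    slices = [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]
    for s, (a, b) in zip(slices, zip(edges[:-1], edges[1:])):
        if b <= a:
            raise SpectrumError(
                f"empty feature band [{a}, {b}) at detail level {level}"
            )
    return slices


def band_energy_features(
    decomp: WaveletDecomposition,
    config: WaveletFeatureConfig | None = None,
    label: str | None = None,
) -> FeatureVector:
    """Average energy (squared coefficients) per feature band.

    For each selected detail level the coefficient index axis is split
    into ``n_bands`` contiguous bands (equal width by default); the
    feature is the mean squared coefficient within each band.  Features
    are concatenated level-ascending then band-ascending.
    """
    if config is None:
        config = decomp.config
    values: list[float] = []
    for level in config.detail_levels:
        d = decomp.detail(level)
        for s in _band_slices(d.size, config, level):
            energy = np.square(d[s])
            values.append(float(energy.mean() if config.use_mean else energy.sum()))
    return FeatureVector(
        values=np.array(values), label=label, config_digest=config.digest()
    )


def extract_features(
    spectrum: Spectrum, config: WaveletFeatureConfig | None = None
) -> FeatureVector:
    """Convenience: decompose + band_energy_features, propagating the label."""
    if config is None:
        config = WaveletFeatureConfig()
    decomp = decompose(spectrum, config)
    return band_energy_features(decomp, config, label=spectrum.label)
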