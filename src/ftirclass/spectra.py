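"""Spectrum data model, file I/O, replicate averaging, and baseline correction.

An ATR-FTIR spectrum is an absorbance trace on a wavenumber grid, by
instrument convention stored descending (4000 -> 650 cm^-1).  Files in
either grid direction are accepted and normalised on read.

Supported on-disk formats:

* two-column CSV/TSV (wavenumber, absorbance), optional one-line header;
* JCAMP-DX with ``##XYPOINTS=(XY..XY)`` or uncompressed AFFN
  ``##XYDATA=(X++(Y..Y))`` records (DIFDUP/PAC compression is rejected
  with a parse error).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "SpectrumError",
    "read_spectrum",
    "write_spectrum",
    "average_replicates",
    "autobaseline",
]


class SpectrumError(ValueError):
    """Raised for malformed spectrum files or invalid spectrum operations."""


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace on a strictly monotonic wavenumber grid.

    Parameters
    ----------
    wavenumbers : array of float, cm^-1
        Strictly monotonic grid; stored descending regardless of input
        direction.
    absorbance : array of float, absorbance units
        Same length as ``wavenumbers``; all values finite.
    label : str or None
        Optional class identifier used in training.
    meta : mapping
        Free-form provenance (resolution, scans, replicate id, ...).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise SpectrumError("wavenumbers and absorbance must be 1-D")
        if wn.size != ab.size:
            raise SpectrumError(
                f"length mismatch: {wn.size} wavenumbers vs {ab.size} absorbances"
            )
        if wn.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        d = np.diff(wn)
        if np.all(d > 0):  # ascending input: flip to instrument convention
            wn, ab = wn[::-1], ab[::-1]
        elif not np.all(d < 0):
            raise SpectrumError("wavenumber grid must be strictly monotonic")
        if not np.all(np.isfinite(wn)) or not np.all(np.isfinite(ab)):
            raise SpectrumError("non-finite values in spectrum")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_absorbance(self, absorbance: np.ndarray, **meta: object) -> "Spectrum":
        """Copy of this spectrum with new absorbance values (grid unchanged)."""
        merged = {**self.meta, **meta}
        return Spectrum(self.wavenumbers.copy(), absorbance, self.label, merged)

    def with_label(self, label: str | None) -> "Spectrum":
        return replace(self, label=label)


@dataclass
class SpectrumSet:
    """Ordered collection of spectra sharing one common wavenumber grid."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise SpectrumError("empty SpectrumSet")
        grid = self.spectra[0].wavenumbers
        for i, s in enumerate(self.spectra):
            if s.wavenumbers.shape != grid.shape or not np.array_equal(
                s.wavenumbers, grid
            ):
                raise SpectrumError(f"spectrum {i} is not on the common grid")

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    @property
    def classes(self) -> list[str]:
        """Distinct labels present, in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            if s.label is not None:
                seen.setdefault(s.label, None)
        return list(seen)

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.spectra]

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i):
        return self.spectra[i]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".jdx", ".dx", ".jcm", ".jcamp"}:
        return "jcamp"
    return "csv"


def read_spectrum(
    path: str | Path, format: str | None = None, label: str | None = None
) -> Spectrum:
    """Read a spectrum from a two-column CSV or a JCAMP-DX file.

    ``format`` is ``"csv"`` or ``"jcamp"``; if omitted it is inferred from
    the file suffix (``.jdx``/``.dx`` -> JCAMP, anything else -> CSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    if fmt == "csv":
        return _read_csv(path, label)
    if fmt == "jcamp":
        return _read_jcamp(path, label)
    raise SpectrumError(f"unknown format {fmt!r} (expected 'csv' or 'jcamp')")


def _read_csv(path: Path, label: str | None) -> Spectrum:
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectrumError(f"{path}: cannot parse as CSV: {exc}") from exc
    # drop a one-line header if the first row is not numeric
    first = df.iloc[0]
    try:
        first.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:]
    if df.shape[1] != 2:
        raise SpectrumError(f"{path}: expected 2 columns, found {df.shape[1]}")
    try:
        arr = df.astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise SpectrumError(f"{path}: non-numeric data row: {exc}") from exc
    meta = {"source": str(path), "format": "csv"}
    return Spectrum(arr[:, 0], arr[:, 1], label=label, meta=meta)


_JCAMP_LABEL = re.compile(r"^\s*##\s*([^=]+?)\s*=\s*(.*)$")
# AFFN numbers only; SQZ/DIF/DUP pseudo-digit compression is not supported
_AFFN_TOKEN = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
_DIFDUP_CHARS = re.compile(r"[A-DF-Za-df-z@%JKLMNOPQRjklmnopqrSTUVWXYZs-z]")


def _read_jcamp(path: Path, label: str | None) -> Spectrum:
    headers: dict[str, str] = {}
    mode: str | None = None
    data_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("$$", 1)[0].rstrip()
        if not line.strip():
            continue
        m = _JCAMP_LABEL.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "")
            val = m.group(2).strip()
            headers[key] = val
            if key == "XYPOINTS":
                mode = "xypoints"
            elif key == "XYDATA":
                if "X++" not in val.replace(" ", ""):
                    raise SpectrumError(
                        f"{path}:{lineno}: unsupported XYDATA variant {val!r}"
                    )
                mode = "xydata"
            elif key == "END":
                break
            continue
        if mode is None:
            raise SpectrumError(f"{path}:{lineno}: data before XYDATA/XYPOINTS")
        data_lines.append((lineno, line))
    if mode is None:
        raise SpectrumError(f"{path}: no XYDATA or XYPOINTS record found")

    xfac = float(headers.get("XFACTOR", 1.0))
    yfac = float(headers.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    if mode == "xypoints":
        for lineno, line in data_lines:
            nums = _AFFN_TOKEN.findall(line)
            if len(nums) % 2:
                raise SpectrumError(
                    f"{path}:{lineno}: odd number of values in XY pair line"
                )
            vals = [float(v) for v in nums]
            xs.extend(v * xfac for v in vals[0::2])
            ys.extend(v * yfac for v in vals[1::2])
    else:  # (X++(Y..Y))
        for lineno, line in data_lines:
            stripped = _AFFN_TOKEN.sub(" ", line)
            if _DIFDUP_CHARS.search(stripped):
                raise SpectrumError(
                    f"{path}:{lineno}: compressed (SQZ/DIF/DUP) JCAMP data "
                    "is not supported; export as AFFN"
                )
            nums = _AFFN_TOKEN.findall(line)
            if len(nums) < 2:
                raise SpectrumError(f"{path}:{lineno}: expected X followed by Ys")
            x0 = float(nums[0]) * xfac
            yvals = [float(v) * yfac for v in nums[1:]]
            if "DELTAX" in headers:
                dx = float(headers["DELTAX"])
            else:
                firstx = float(headers.get("FIRSTX", x0))
                lastx = float(headers["LASTX"])
                npts = int(float(headers["NPOINTS"]))
                dx = (lastx - firstx) / (npts - 1)
            xs.extend(x0 + i * dx for i in range(len(yvals)))
            ys.extend(yvals)
    if "NPOINTS" in headers and int(float(headers["NPOINTS"])) != len(xs):
        raise SpectrumError(
            f"{path}: NPOINTS={headers['NPOINTS']} but parsed {len(xs)} points"
        )
    meta = {
        "source": str(path),
        "format": "jcamp",
        "title": headers.get("TITLE", ""),
    }
    return Spectrum(np.array(xs), np.array(ys), label=label, meta=meta)


def write_spectrum(
    spectrum: Spectrum, path: str | Path, format: str | None = None
) -> Path:
    """Write a spectrum as two-column CSV or JCAMP-DX (``XYPOINTS``)."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "csv":
        df = pd.DataFrame(
            {"wavenumber": spectrum.wavenumbers, "absorbance": spectrum.absorbance}
        )
        df.to_csv(path, index=False)
    elif fmt == "jcamp":
        buf = io.StringIO()
        title = spectrum.label or spectrum.meta.get("title", "spectrum")
        wn, ab = spectrum.wavenumbers, spectrum.absorbance
        buf.write(f"##TITLE={title}\n")
        buf.write("##JCAMP-DX=4.24\n")
        buf.write("##DATA TYPE=INFRARED SPECTRUM\n")
        buf.write("##XUNITS=1/CM\n")
        buf.write("##YUNITS=ABSORBANCE\n")
        buf.write(f"##FIRSTX={wn[0]:.6f}\n")
        buf.write(f"##LASTX={wn[-1]:.6f}\n")
        buf.write(f"##NPOINTS={len(wn)}\n")
        buf.write("##XYPOINTS=(XY..XY)\n")
        for x, y in zip(wn, ab):
            buf.write(f"{x:.6f}, {y:.8f}\n")
        buf.write("##END=\n")
        path.write_text(buf.getvalue())
    else:
        raise SpectrumError(f"unknown format {fmt!r} (expected 'csv' or 'jcamp')")
    return path


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(replicates: Sequence[Spectrum] | Iterable[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate measurements.

    All replicates must share a bit-identical wavenumber grid; no
    interpolation is performed.  The result records the replicate count
    in ``meta['n_replicates']``.
    """
    reps = list(replicates)
    if not reps:
        raise SpectrumError("need at least one replicate")
    grid = reps[0].wavenumbers
    for i, s in enumerate(reps[1:], start=1):
        if s.wavenumbers.shape != grid.shape or not np.array_equal(
            s.wavenumbers, grid
        ):
            raise SpectrumError(f"replicate {i} grid differs from replicate 0")
    mean = np.mean([s.absorbance for s in reps], axis=0)
    return Spectrum(
        grid.copy(),
        mean,
        label=reps[0].label,
        meta={**reps[0].meta, "n_replicates": len(reps)},
    )


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------

def _lower_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of (x, y), x strictly increasing.

    Andrew's monotone chain.  Collinear points are dropped so the hull is
    minimal; this keeps flat and linear spectra (degenerate hulls) valid.
    """
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:  # turn is clockwise or straight: k not on lower hull
                hull.pop()
            else:
                break
        hull.append(i)
    return np.array(hull)


def autobaseline(
    spectrum: Spectrum, method: str = "rubberband", degree: int = 2
) -> Spectrum:
    """Automatic baseline correction.

    ``rubberband`` (default) subtracts the lower convex hull of the trace —
    the standard vendor-equivalent for broadband ATR baselines — so the
    corrected minimum is ~0.  ``polynomial`` subtracts a least-squares
    polynomial of the given ``degree`` fitted to the whole trace.
    Both are idempotent to numerical precision.
    """
    y = spectrum.absorbance
    if method == "rubberband":
        # work on the ascending axis; stored direction is presentation only
        x_asc = spectrum.wavenumbers[::-1]
        y_asc = y[::-1]
        idx = _lower_hull(x_asc, y_asc)
        baseline_asc = np.interp(x_asc, x_asc[idx], y_asc[idx])
        corrected = (y_asc - baseline_asc)[::-1]
    elif method == "polynomial":
        if degree < 0 or degree >= len(spectrum):
            raise SpectrumError(
                f"polynomial degree must be in [0, {len(spectrum) - 1})"
            )
        x = spectrum.wavenumbers
        coeffs = np.polynomial.polynomial.polyfit(x - x.mean(), y, degree)
        corrected = y - np.polynomial.polynomial.polyval(x - x.mean(), coeffs)
    else:
        raise SpectrumError(
            f"unknown baseline method {method!r} (expected 'rubberband' or 'polynomial')"
        )
    return spectrum.with_absorbance(corrected, baseline=method)
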