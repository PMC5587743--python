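"""NIR spectral preprocessing: repetition averaging, Savitzky-Golay
smoothing and derivatives, SNV and MSC scatter correction, and assembly of
the five candidate design matrices (``smooth``, ``snv``, ``msc``,
``deriv1``, ``deriv2``) restricted to the 700-1100 nm analysis band.

Pipeline order is: average repetitions -> Savitzky-Golay (smooth or
derivative) -> scatter normalization -> band restriction.  Restricting the
band last keeps filter edge effects outside the retained wavelengths, and
the MSC reference is the mean of the *training* subset only so that
held-out spectra never leak into the correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .synthetic_data import SpectrumSet

__all__ = [
    "Spectrum",
    "DesignMatrix",
    "METHODS",
    "average_repetitions",
    "savitzky_golay",
    "snv",
    "msc",
    "build_design_matrix",
]

METHODS = ("smooth", "snv", "msc", "deriv1", "deriv2")


@dataclass
class Spectrum:
    """A wavelength-indexed absorbance vector."""

    wavelength_nm: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength_nm.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance lengths differ")
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise ValueError("spectrum must be a 1-D vector of length >= 2")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass
class DesignMatrix:
    """Preprocessed spectra as a points x wavelengths matrix."""

    X: np.ndarray
    wavelength_nm: np.ndarray
    method: str
    point_ids: np.ndarray
    params: dict = field(default_factory=dict)
    repetition_cv: np.ndarray | None = None


def average_repetitions(reps: SpectrumSet | Sequence[Spectrum]) -> tuple[Spectrum, float]:
    """Pointwise mean of the repetition spectra and their repetition CV.

    The CV is the mean over wavelengths of (SD / mean * 100); repetitions
    must share an identical wavelength grid.
    """
    if isinstance(reps, SpectrumSet):
        wl = reps.wavelength_nm
        mat = np.asarray(reps.reps, dtype=float)
    else:
        specs = list(reps)
        wl = specs[0].wavelength_nm
        for s in specs[1:]:
            if s.wavelength_nm.shape != wl.shape or not np.allclose(
                s.wavelength_nm, wl
            ):
                raise ValueError("repetition wavelength grids differ")
        mat = np.stack([s.absorbance for s in specs])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = float(np.mean(np.where(mean != 0, sd / np.abs(mean) * 100.0, 0.0)))
    return Spectrum(wl.copy(), mean), cv


def savitzky_golay(
    s: Spectrum, order: int = 3, window: int = 39, deriv: int = 0
) -> Spectrum:
    """Savitzky-Golay local polynomial filter (default order 3, window 39
    points, ~25 nm).  Derivatives are scaled to per-nm units via the
    wavelength step; edges are handled by refitting the polynomial on the
    truncated terminal windows.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and exceed the polynomial order")
    if s.absorbance.size < window:
        raise ValueError(f"spectrum length {s.absorbance.size} < window {window}")
    steps = np.diff(s.wavelength_nm)
    # tolerate the rounding of grids that passed through text files
    if not np.allclose(steps, steps[0], rtol=1e-4, atol=1e-9):
        raise ValueError("Savitzky-Golay filtering requires a uniform grid")
    out = savgol_filter(
        s.absorbance, window, order, deriv=deriv, delta=steps[0], mode="interp"
    )
    return Spectrum(s.wavelength_nm.copy(), out)


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum centring to mean 0 and
    scaling to unit sample SD (denominator n-1)."""
    sd = float(np.std(s.absorbance, ddof=1))
    if sd <= 1e-12 * max(1.0, float(np.abs(s.absorbance).max())):
        raise ValueError("SNV undefined for a constant spectrum (zero SD)")
    return Spectrum(s.wavelength_nm.copy(), (s.absorbance - s.absorbance.mean()) / sd)


def msc(
    spectra: Sequence[Spectrum], reference: Spectrum | None = None
) -> tuple[list[Spectrum], Spectrum]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed on the reference (a ~ alpha + beta * ref,
    ordinary least squares) and corrected as (a - alpha) / beta.  When no
    reference is given the mean of ``spectra`` is used; in a modelling
    pipeline the reference must come from the training subset only.
    """
    specs = list(spectra)
    if len(specs) < 2 and reference is None:
        raise ValueError("MSC needs at least two spectra or an explicit reference")
    wl = specs[0].wavelength_nm
    for s in specs[1:]:
        if not np.allclose(s.wavelength_nm, wl):
            raise ValueError("spectra must share a wavelength grid")
    if reference is None:
        reference = Spectrum(wl.copy(), np.mean([s.absorbance for s in specs], axis=0))
    ref = reference.absorbance
    A = np.column_stack([np.ones_like(ref), ref])
    out = []
    for s in specs:
        (alpha, beta), *_ = np.linalg.lstsq(A, s.absorbance, rcond=None)
        if beta <= 0:
            warnings.warn(
                "MSC: non-positive scatter slope (pathological spectrum)",
                RuntimeWarning,
                stacklevel=2,
            )
            beta = max(beta, 1e-9)
        out.append(Spectrum(wl.copy(), (s.absorbance - alpha) / beta))
    return out, reference


def build_design_matrix(
    points: Sequence[SpectrumSet],
    method: str,
    band_nm: tuple[float, float] = (700.0, 1100.0),
    train_idx: Sequence[int] | None = None,
    sg_order: int = 3,
    sg_window: int = 39,
    point_ids: Sequence[int] | None = None,
) -> DesignMatrix:
    """Average, filter and normalize a set of repetition spectra into one
    of the five candidate model-input representations, restricted to the
    700-1100 nm NIR band after filtering."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    wl0 = points[0].wavelength_nm
    for p in points:
        if p.wavelength_nm.shape != wl0.shape or not np.allclose(
            p.wavelength_nm, wl0
        ):
            raise ValueError("inconsistent wavelength grids across points")
    deriv = {"deriv1": 1, "deriv2": 2}.get(method, 0)
    averaged, cvs = [], []
    for p in points:
        mean_spec, cv = average_repetitions(p)
        cvs.append(cv)
        averaged.append(
            savitzky_golay(mean_spec, order=sg_order, window=sg_window, deriv=deriv)
        )
    if method == "snv":
        averaged = [snv(s) for s in averaged]
    elif method == "msc":
        if train_idx is not None:
            ref = Spectrum(
                wl0.copy(),
                np.mean([averaged[i].absorbance for i in train_idx], axis=0),
            )
        else:
            ref = None
        averaged, _ = msc(averaged, reference=ref)
    keep = (wl0 >= band_nm[0]) & (wl0 <= band_nm[1])
    X = np.stack([s.absorbance[keep] for s in averaged])
    ids = (
        np.asarray(point_ids)
        if point_ids is not None
        else np.arange(len(points))
    )
    return DesignMatrix(
        X=X,
        wavelength_nm=wl0[keep].copy(),
        method=method,
        point_ids=ids,
        params={
            "sg_order": sg_order,
            "sg_window": sg_window,
            "deriv": deriv,
            "band_nm": list(band_nm),
            "msc_reference": "train" if train_idx is not None else "all",
        },
        repetition_cv=np.asarray(cvs),
    )
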