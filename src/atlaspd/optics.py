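"""Dual-wavelength optics: optical density and the modified Beer-Lambert law.

Conventions
-----------
Concentration changes are in micromolar (uM), path lengths in cm.  The
modified Beer-Lambert law relates optical-density change at wavelength
``lambda`` to chromophore concentration changes::

    dOD_l = (eps_HbO(l) * dHbO + eps_HbR(l) * dHbR) * d * DPF

where ``d`` is the source-detector distance and DPF the differential
pathlength factor.  With two wavelengths this is a 2x2 linear system,
inverted per sample to recover (dHbO, dHbR).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "WAVELENGTHS_NM",
    "extinction_matrix",
    "intensity_to_od",
    "od_to_intensity",
    "hemoglobin_to_od",
    "od_to_hemoglobin",
]

WAVELENGTHS_NM: tuple[float, float] = (695.0, 830.0)

# Molar extinction coefficients, cm^-1 / M, (HbO2, HHb), from the standard
# compiled hemoglobin spectra used throughout the NIRS literature.  Declared
# constants of this package.
_EXTINCTION_CM1_M1: dict[float, tuple[float, float]] = {
    695.0: (320.8, 1845.0),
    830.0: (974.0, 693.0),
}


def extinction_matrix(wavelengths: tuple[float, float] = WAVELENGTHS_NM) -> np.ndarray:
    """2x2 extinction matrix in cm^-1 / uM; rows = wavelengths, cols = (HbO, HbR)."""
    rows = []
    for wl in wavelengths:
        if wl not in _EXTINCTION_CM1_M1:
            raise ValueError(f"no extinction coefficients for {wl} nm")
        rows.append(_EXTINCTION_CM1_M1[wl])
    e = np.asarray(rows, dtype=float) * 1e-6  # per uM
    if abs(np.linalg.det(e)) < 1e-12 * np.abs(e).max() ** 2:
        raise ValueError("extinction matrix is singular for these wavelengths")
    return e


def intensity_to_od(
    intensity: np.ndarray,
    reference: np.ndarray | slice | None = None,
    axis: int = -1,
) -> np.ndarray:
    """Convert raw light intensity to optical density.

    OD(t) = -log10( I(t) / mean(I_ref) ), computed along ``axis``.
    Non-positive or non-finite intensities yield NaN (flagged missing)
    rather than propagating -inf.

    Parameters
    ----------
    intensity : array
        Raw intensity, arbitrary units, time along ``axis``.
    reference : array, slice or None
        Reference window.  ``None`` uses the mean over the whole series;
        a slice indexes the time axis; an array is used directly.
    """
    x = np.asarray(intensity, dtype=float)
    bad = ~np.isfinite(x) | (x <= 0)
    x = np.where(bad, np.nan, x)
    if reference is None:
        ref = np.nanmean(x, axis=axis, keepdims=True)
    elif isinstance(reference, slice):
        idx = [slice(None)] * x.ndim
        idx[axis % x.ndim] = reference
        ref = np.nanmean(x[tuple(idx)], axis=axis, keepdims=True)
    else:
        ref = np.nanmean(np.asarray(reference, dtype=float), axis=axis, keepdims=True)
    if np.any(~np.isfinite(ref)) or np.any(ref <= 0):
        raise ValueError("reference window has no positive intensity")
    with np.errstate(invalid="ignore", divide="ignore"):
        od = -np.log10(x / ref)
    od[bad] = np.nan
    return od


def od_to_intensity(od: np.ndarray, i0: float | np.ndarray = 1.0) -> np.ndarray:
    """Forward projection: I(t) = I0 * 10**(-OD(t))."""
    return np.asarray(i0, dtype=float) * 10.0 ** (-np.asarray(od, dtype=float))


def hemoglobin_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    wavelengths: tuple[float, float] = WAVELENGTHS_NM,
    dpf: float = 6.0,
    distance_cm: float = 3.0,
) -> np.ndarray:
    """Forward Beer-Lambert: concentration changes (uM) -> dOD per wavelength.

    Returns an array with a trailing wavelength axis of length 2.
    """
    e = extinction_matrix(wavelengths)
    conc = np.stack([np.asarray(hbo, float), np.asarray(hbr, float)], axis=-1)
    return conc @ (e.T * (dpf * distance_cm))


def od_to_hemoglobin(
    od: np.ndarray,
    wavelengths: tuple[float, float] = WAVELENGTHS_NM,
    dpf: float = 6.0,
    distance_cm: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law.

    Parameters
    ----------
    od : array, shape (..., 2)
        Optical-density change with the two wavelengths on the last axis.

    Returns
    -------
    (dHbO, dHbR, dHbT) in uM, each of shape ``od.shape[:-1]``.
    """
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 2:
        raise ValueError("expected two wavelengths on the last axis")
    e = extinction_matrix(wavelengths) * (dpf * distance_cm)
    inv = np.linalg.inv(e)
    conc = od @ inv.T
    hbo, hbr = conc[..., 0], conc[..., 1]
    return hbo, hbr, hbo + hbr
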