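"""Spectral pre-processing: rubberband baseline, vector normalization, crop.

The rubberband correction estimates the baseline as the lower convex hull of
the (wavenumber, intensity) points — order-1 "polynomials" between support
points are chords — and subtracts it. Vector normalization rescales each
spectrum to unit Euclidean norm, removing per-spectrum multiplicative
scatter. Cropping restricts the axis to an informative window (used for
benchtop NIR, where signal saturation below 5400 cm^-1 makes that region
unusable).

Steps compose into a :class:`PreprocessPlan`; the per-modality defaults are
raw (identity) for ATR-IR and handheld NIR, crop 5400-9000 cm^-1 for
benchtop NIR, and rubberband followed by vector normalization for Raman.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectralDataset


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Vertices of the lower convex hull, left to right (monotone chain).

    Collinear interior points are excluded; the first and last channel are
    always support points.
    """
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # b lies on or above chord a->i: drop it
            cross = (x[b] - x[a]) * (y[i] - y[a]) - (y[b] - y[a]) * (x[i] - x[a])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def rubberband(
    wavenumbers: np.ndarray, spectrum: np.ndarray, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Rubberband baseline correction of one spectrum.

    Returns ``(baseline, corrected)`` where the baseline is the piecewise
    linear interpolation through the lower-convex-hull support points and
    ``corrected = spectrum - baseline``. The corrected spectrum is exactly 0
    at support points and >= -1e-12 elsewhere.
    """
    if order != 1:
        raise ValueError(f"unsupported order {order}: only order 1 (piecewise linear) is supported")
    x = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(spectrum, dtype=float)
    if x.size < 3:
        raise ValueError(f"rubberband requires >= 3 channels, got {x.size}")
    if x.shape != y.shape:
        raise ValueError("wavenumbers and spectrum must have the same length")
    support = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[support], y[support])
    return baseline, y - baseline


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Spectrum divided by its Euclidean norm; errors on an all-zero input."""
    y = np.asarray(spectrum, dtype=float)
    norm = float(np.linalg.norm(y))
    if norm == 0.0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return y / norm


def crop(ds: SpectralDataset, w_min: float, w_max: float) -> SpectralDataset:
    """Restrict the dataset to channels with w_min <= w <= w_max (inclusive)."""
    if w_min >= w_max:
        raise ValueError(f"crop bounds must satisfy w_min < w_max, got ({w_min}, {w_max})")
    mask = (ds.wavenumbers >= w_min) & (ds.wavenumbers <= w_max)
    if not mask.any():
        raise ValueError(
            f"crop window ({w_min}, {w_max}) does not intersect the axis "
            f"[{ds.wavenumbers[0]}, {ds.wavenumbers[-1]}]"
        )
    return SpectralDataset(
        wavenumbers=ds.wavenumbers[mask],
        intensities=ds.intensities[:, mask],
        meta=list(ds.meta),
        modality=ds.modality,
    )


@dataclass(frozen=True)
class Crop:
    w_min: float
    w_max: float


@dataclass(frozen=True)
class Rubberband:
    order: int = 1


@dataclass(frozen=True)
class VectorNormalize:
    pass


Step = Crop | Rubberband | VectorNormalize


@dataclass(frozen=True)
class PreprocessPlan:
    """An ordered list of preprocessing steps applied to a dataset."""

    steps: tuple[Step, ...] = ()
    name: str = "custom"

    def __iter__(self):
        return iter(self.steps)


NAMED_PLANS = {
    "raw": PreprocessPlan((), name="raw"),
    "raman_rbvn": PreprocessPlan((Rubberband(order=1), VectorNormalize()), name="raman_rbvn"),
    "nirb_crop": PreprocessPlan((Crop(5400.0, 9000.0),), name="nirb_crop"),
    "nirh_crop": PreprocessPlan((Crop(5882.0, 9000.0),), name="nirh_crop"),
}

_DEFAULT_PLAN_BY_MODALITY = {
    "ATR-IR": "raw",
    "NIR-B": "nirb_crop",
    "NIR-H": "raw",
    "Raman-B": "raman_rbvn",
}


def named_plan(name: str) -> PreprocessPlan:
    try:
        return NAMED_PLANS[name]
    except KeyError:
        raise ValueError(f"unknown plan {name!r}; known plans: {sorted(NAMED_PLANS)}") from None


def default_plan_for(modality: str) -> PreprocessPlan:
    """The default plan for a modality (raw / crop / rubberband+VN)."""
    try:
        return NAMED_PLANS[_DEFAULT_PLAN_BY_MODALITY[modality]]
    except KeyError:
        raise ValueError(f"no default plan for modality {modality!r}") from None


def apply_plan(ds: SpectralDataset, plan: PreprocessPlan) -> SpectralDataset:
    """Apply plan steps in order; per-spectrum steps act row by row."""
    out = ds
    for step in plan:
        if isinstance(step, Crop):
            out = crop(out, step.w_min, step.w_max)
        elif isinstance(step, Rubberband):
            corrected = np.empty_like(out.intensities)
            for i in range(out.n_spectra):
                _, corrected[i] = rubberband(out.wavenumbers, out.intensities[i], step.order)
            out = SpectralDataset(
                wavenumbers=out.wavenumbers,
                intensities=corrected,
                meta=list(out.meta),
                modality=out.modality,
            )
        elif isinstance(step, VectorNormalize):
            normalized = np.empty_like(out.intensities)
            for i in range(out.n_spectra):
                normalized[i] = vector_normalize(out.intensities[i])
            out = SpectralDataset(
                wavenumbers=out.wavenumbers,
                intensities=normalized,
                meta=list(out.meta),
                modality=out.modality,
            )
        else:
            raise TypeError(f"unknown preprocessing step {step!r}")
    return out
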