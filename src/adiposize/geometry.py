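"""Spherical-model conversions between adipocyte sizing parameters.

A mature adipocyte is modelled as a sphere, so a single measured size
parameter determines all others.  Histology reports the cross-sectional
area of a cell profile (µm²); collagenase digestion reports the maximal
diameter of the freed, spherical cell (µm).  Under the spherical model

    d = sqrt(4·A / π)           (diameter from great-circle area)
    V = (π/6)·d³                (volume; reported in pl, 1000 µm³ = 1 pl)
    S = 4·A                     (sphere surface is four great circles)

All conversions are routed pairwise through the diameter so that only one
formula exists per parameter pair.  The module also owns the histology
artifact filter (areas outside [200, 16000] µm² are discarded) and the
seeded per-subject cell subsampling used throughout the pipeline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "InsufficientCellsError",
    "area_to_diameter",
    "diameter_to_area",
    "diameter_to_volume",
    "volume_to_diameter",
    "area_to_surface",
    "surface_to_area",
    "convert",
    "FilterResult",
    "filter_histology_areas",
    "sample_cells",
    "subsample_rng",
    "AREA_FILTER_LOW",
    "AREA_FILTER_HIGH",
    "SIZE_PARAMETERS",
    "PARAMETER_UNITS",
]

#: Histology artifact filter bounds, µm².  Objects strictly smaller/larger
#: are treated as tissue-processing artifacts.  Bounds are kept (inclusive).
AREA_FILTER_LOW = 200.0
AREA_FILTER_HIGH = 16000.0

#: µm³ per picolitre (1 µm³ = 1 fl).
UM3_PER_PL = 1000.0

SIZE_PARAMETERS = ("area", "diameter", "volume", "surface_area")
PARAMETER_UNITS = {
    "area": "um2",
    "diameter": "um",
    "volume": "pl",
    "surface_area": "um2",
}


class ValidationError(ValueError):
    """Input failed a domain validity check; the message names offenders."""


class InsufficientCellsError(ValidationError):
    """A subject has fewer cells than the requested sample size."""


def _as_valid(values, name: str, *, positive: bool = False) -> np.ndarray:
    """Coerce to float array; reject non-finite (and optionally non-positive)
    entries with an error naming the offending indices."""
    arr = np.asarray(values, dtype=float)
    bad = ~np.isfinite(arr)
    if positive:
        bad |= ~(arr > 0)
    else:
        bad |= arr < 0
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))[:10].tolist()
        kind = "non-finite or non-positive" if positive else "non-finite or negative"
        raise ValidationError(
            f"{kind} {name} at index(es) {idx}: "
            f"{np.atleast_1d(arr)[idx].tolist()}"
        )
    return arr


def area_to_diameter(area):
    """Diameter (µm) of the sphere whose great-circle area is ``area`` (µm²).

    d = sqrt(4·A/π); strictly increasing in A.  Areas must be > 0.
    """
    a = _as_valid(area, "area", positive=True)
    return np.sqrt(4.0 * a / np.pi)


def diameter_to_area(diameter):
    """Great-circle (cross-sectional) area (µm²) from diameter (µm): A = (π/4)·d²."""
    d = _as_valid(diameter, "diameter")
    return np.pi / 4.0 * d**2


def diameter_to_volume(diameter):
    """Sphere volume in picolitres from diameter in µm.

    V[µm³] = (π/6)·d³, converted with the fixed factor 1000 µm³/pl.
    """
    d = _as_valid(diameter, "diameter")
    return (np.pi / 6.0) * d**3 / UM3_PER_PL


def volume_to_diameter(volume):
    """Diameter (µm) from sphere volume (pl): inverse of :func:`diameter_to_volume`."""
    v = _as_valid(volume, "volume")
    return np.cbrt(6.0 * v * UM3_PER_PL / np.pi)


def area_to_surface(area):
    """Sphere surface area (µm²) from great-circle area (µm²): S = 4·A.

    Linear, so location/scale descriptors of a sample scale by 4 while
    skewness and kurtosis are unchanged.
    """
    a = _as_valid(area, "area")
    return 4.0 * a


def surface_to_area(surface_area):
    """Great-circle area (µm²) from sphere surface area (µm²): A = S/4."""
    s = _as_valid(surface_area, "surface_area")
    return s / 4.0


# Conversions to/from the diameter hub.  Every pairwise conversion is the
# composition through diameter, so each formula exists exactly once.
_TO_DIAMETER = {
    "diameter": lambda x: _as_valid(x, "diameter"),
    "area": area_to_diameter,
    "volume": volume_to_diameter,
    "surface_area": lambda s: area_to_diameter(surface_to_area(s)),
}
_FROM_DIAMETER = {
    "diameter": lambda d: d,
    "area": diameter_to_area,
    "volume": diameter_to_volume,
    "surface_area": lambda d: area_to_surface(diameter_to_area(d)),
}


def convert(values, from_parameter: str, to_parameter: str):
    """Convert size values between any two spherical parameters.

    Parameters are one of ``area`` (µm²), ``diameter`` (µm), ``volume``
    (pl), ``surface_area`` (µm²).  Routing is through diameter.
    """
    for p in (from_parameter, to_parameter):
        if p not in SIZE_PARAMETERS:
            raise ValidationError(
                f"unknown size parameter {p!r}; expected one of {SIZE_PARAMETERS}"
            )
    if from_parameter == to_parameter:
        return _as_valid(values, from_parameter)
    return _FROM_DIAMETER[to_parameter](_TO_DIAMETER[from_parameter](values))


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the histology artifact filter."""

    kept: np.ndarray
    n_excluded_low: int
    n_excluded_high: int

    @property
    def n_kept(self) -> int:
        return int(self.kept.size)


def filter_histology_areas(
    areas,
    low: float = AREA_FILTER_LOW,
    high: float = AREA_FILTER_HIGH,
) -> FilterResult:
    """Drop histology areas outside ``[low, high]`` µm² (artifact removal).

    Boundary values are kept: the rule excludes areas strictly smaller than
    ``low`` or strictly larger than ``high``.  Input order is preserved.
    """
    arr = np.asarray(areas, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        idx = np.flatnonzero(~np.isfinite(arr))[:10].tolist()
        raise ValidationError(f"non-finite area at index(es) {idx}")
    low_mask = arr < low
    high_mask = arr > high
    kept = arr[~(low_mask | high_mask)]
    return FilterResult(kept, int(low_mask.sum()), int(high_mask.sum()))


def subsample_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic per-stratum generator.

    Mixes the run seed with stable digests of the string labels (subject id,
    depot, method, ...) so a subject's draw does not depend on table order.
    """
    keys = [int(seed)]
    for label in labels:
        digest = hashlib.blake2s(str(label).encode(), digest_size=4).digest()
        keys.append(int.from_bytes(digest, "big"))
    return np.random.default_rng(np.random.SeedSequence(keys))


def sample_cells(
    cells: Sequence | np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    *labels,
) -> np.ndarray:
    """Simple random sample of ``n`` cells without replacement.

    Implemented as the first ``n`` entries of a seeded permutation, so for a
    fixed seed the ``n=200`` sample is nested inside the ``n=500`` sample —
    the design used by the reduced-cell-count sensitivity analysis.

    Raises
    ------
    InsufficientCellsError
        If fewer than ``n`` cells are available.  Callers exclude (and log)
        the subject rather than padding.
    """
    arr = np.asarray(cells)
    if n < 0:
        raise ValidationError(f"sample size must be >= 0, got {n}")
    if arr.shape[0] < n:
        raise InsufficientCellsError(
            f"requested {n} cells but only {arr.shape[0]} available"
        )
    rng = seed if isinstance(seed, np.random.Generator) else subsample_rng(seed, *labels)
    order = rng.permutation(arr.shape[0])
    return arr[order[:n]]
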