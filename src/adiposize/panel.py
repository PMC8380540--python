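"""Distribution descriptor panels for adipocyte size samples.

Because histology-derived adipocyte areas are right-skewed, the mean and
median do not coincide with the most frequent cell size.  The panel
therefore reports, per subject×depot×method (and for pooled cohorts with
equal per-subject representation): n, mean, median, first and ninth decile,
interdecile range (IDR = D9 − D1), skewness, kurtosis, the modal size
(argmax of a kernel density estimate), and a Shapiro–Wilk normality test.

Conventions (fixed so results are bit-stable):

* quantiles by linear interpolation of order statistics, h = (n−1)p + 1;
* skewness g1 = m3/m2^1.5 and kurtosis m4/m2² with population central
  moments (Pearson convention, normal → 3);
* mode from a Gaussian KDE with Silverman bandwidth on a 512-point grid
  over [min, max].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .geometry import ValidationError, InsufficientCellsError

__all__ = [
    "DistributionPanel",
    "PooledResult",
    "describe",
    "interdecile_range",
    "modal_size",
    "normality",
    "qq_points",
    "histogram_table",
    "density_table",
    "pooled_panel",
    "per_subject_panels",
    "DEFAULT_BIN_WIDTHS",
    "SHAPIRO_MAX_N",
]

logger = logging.getLogger(__name__)

#: Shapiro–Wilk is defined here for 3 <= n <= 5000; larger samples are
#: subsampled (seeded) with a logged note.
SHAPIRO_MIN_N = 3
SHAPIRO_MAX_N = 5000

#: Default fixed histogram bin widths per size parameter.
DEFAULT_BIN_WIDTHS = {"area": 250.0, "diameter": 2.5, "volume": 25.0, "surface_area": 1000.0}

_KDE_GRID = 512


@dataclass(frozen=True)
class DistributionPanel:
    """Descriptor set for one size sample."""

    n: int
    mean: float
    median: float
    first_decile: float
    ninth_decile: float
    idr: float
    skewness: float
    kurtosis: float
    mode: float
    shapiro_w: float = float("nan")
    shapiro_p: float = float("nan")
    units: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PooledResult:
    """Equal-representation pooled sample and its descriptors."""

    depot: str
    method: str
    size_parameter: str
    values: np.ndarray
    subject_count: int
    retained_subjects: list
    excluded_subjects: list
    panel: DistributionPanel
    histogram: pd.DataFrame = field(repr=False, default=None)
    density: pd.DataFrame = field(repr=False, default=None)


def _quantile(sorted_values: np.ndarray, p: float) -> float:
    """Linear interpolation of order statistics, h = (n−1)p + 1."""
    return float(np.quantile(sorted_values, p, method="linear"))


def interdecile_range(first_decile: float, ninth_decile: float) -> float:
    """IDR = D9 − D1, the dispersion measure robust to distribution tails.

    ``ninth_decile`` below ``first_decile`` indicates an upstream quantile
    bug and raises.
    """
    if ninth_decile < first_decile:
        raise ValidationError(
            f"ninth decile {ninth_decile} < first decile {first_decile}"
        )
    return ninth_decile - first_decile


def modal_size(values) -> float:
    """Most frequent size: argmax of a Silverman-bandwidth Gaussian KDE
    evaluated on a 512-point grid over [min, max].

    A zero-variance sample has its constant value as the mode.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValidationError("modal_size needs at least one value")
    if arr.size < 10:
        logger.warning("modal_size on n=%d < 10 values is unstable", arr.size)
    if np.ptp(arr) == 0:
        return float(arr[0])
    kde = stats.gaussian_kde(arr, bw_method="silverman")
    grid = np.linspace(arr.min(), arr.max(), _KDE_GRID)
    return float(grid[np.argmax(kde(grid))])


def normality(values) -> tuple[float, float]:
    """Shapiro–Wilk statistic W and two-sided p for 3 <= n <= 5000.

    Larger samples must be subsampled by the caller (see ``describe``); the
    pipeline interprets p < 0.05 as evidence against normality.
    """
    arr = np.asarray(values, dtype=float)
    if not (SHAPIRO_MIN_N <= arr.size <= SHAPIRO_MAX_N):
        raise ValidationError(
            f"Shapiro-Wilk defined for {SHAPIRO_MIN_N} <= n <= {SHAPIRO_MAX_N}, "
            f"got n={arr.size}; subsample larger inputs"
        )
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def qq_points(values) -> pd.DataFrame:
    """Normal quantile–quantile table for a sample.

    Plotting positions (i − 0.5)/n.  Both axes are standardized to zero
    mean and unit SD (the theoretical normal scores by their own finite-
    sample moments), so a sample that is itself a set of normal scores
    falls exactly on the identity line.  Returned as a tidy table (one row
    per point), not an image.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n < 3:
        raise ValidationError(f"qq_points needs n >= 3, got {n}")
    pos = (np.arange(1, n + 1) - 0.5) / n

    def _standardize(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    return pd.DataFrame(
        {"theoretical": _standardize(stats.norm.ppf(pos)),
         "sample": _standardize(arr)}
    )


def describe(
    values,
    units: str = "",
    *,
    shapiro: bool = True,
    seed: int = 0,
) -> DistributionPanel:
    """Compute the full descriptor panel for one sample.

    Requires n >= 3; deciles are computed for any n but are flagged (warning)
    below n = 10.  A zero-variance sample reports NaN skewness/kurtosis
    rather than failing.  Samples above 5000 values are subsampled (seeded)
    for the Shapiro–Wilk test only, with a logged note.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValidationError(f"describe needs n >= 3 values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("describe received non-finite values")
    if arr.size < 10:
        logger.warning("deciles computed on n=%d < 10 values are unstable", arr.size)

    srt = np.sort(arr)
    d1 = _quantile(srt, 0.1)
    d9 = _quantile(srt, 0.9)

    m = arr.mean()
    centered = arr - m
    m2 = np.mean(centered**2)
    if m2 > 0:
        skew = float(np.mean(centered**3) / m2**1.5)
        kurt = float(np.mean(centered**4) / m2**2)
    else:
        skew = float("nan")
        kurt = float("nan")

    w = p = float("nan")
    if shapiro:
        test_sample = arr
        if arr.size > SHAPIRO_MAX_N:
            rng = geometry.subsample_rng(seed, "shapiro", arr.size)
            test_sample = geometry.sample_cells(arr, SHAPIRO_MAX_N, rng)
            logger.info(
                "Shapiro-Wilk: subsampled %d of %d values (seed %d)",
                SHAPIRO_MAX_N, arr.size, seed,
            )
        w, p = normality(test_sample)

    return DistributionPanel(
        n=int(arr.size),
        mean=float(m),
        median=_quantile(srt, 0.5),
        first_decile=d1,
        ninth_decile=d9,
        idr=interdecile_range(d1, d9),
        skewness=skew,
        kurtosis=kurt,
        mode=modal_size(arr),
        shapiro_w=w,
        shapiro_p=p,
        units=units,
    )


def histogram_table(values, bin_width: float, origin: float = 0.0) -> pd.DataFrame:
    """Fixed-width histogram as a tidy table (bin_left, bin_right, count)."""
    arr = np.asarray(values, dtype=float)
    if bin_width <= 0:
        raise ValidationError(f"bin width must be > 0, got {bin_width}")
    lo = origin + np.floor((arr.min() - origin) / bin_width) * bin_width
    hi = origin + np.ceil((arr.max() - origin) / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def density_table(values, n_grid: int = _KDE_GRID) -> pd.DataFrame:
    """Silverman-bandwidth Gaussian KDE evaluated on a grid over [min, max]."""
    arr = np.asarray(values, dtype=float)
    if np.ptp(arr) == 0:
        raise ValidationError("density undefined for zero-variance sample")
    kde = stats.gaussian_kde(arr, bw_method="silverman")
    grid = np.linspace(arr.min(), arr.max(), n_grid)
    return pd.DataFrame({"value": grid, "density": kde(grid)})


def _subject_values(
    cells: pd.DataFrame, depot: str, method: str, parameter: str
) -> dict:
    """Per-subject converted size values for one depot×method stratum."""
    sub = cells[(cells["depot"] == depot) & (cells["method"] == method)]
    out = {}
    for subject, grp in sub.groupby("subject_id", sort=True):
        native = grp["size_parameter"].iloc[0]
        out[subject] = geometry.convert(grp["value"].to_numpy(), native, parameter)
    return out


def pooled_panel(
    cells: pd.DataFrame,
    depot: str,
    method: str,
    parameter: str,
    k: int,
    seed: int,
    *,
    bin_width: float | None = None,
) -> PooledResult:
    """Equal-representation pooled cohort sample and its descriptor panel.

    Exactly ``k`` cells are sampled (seeded, without replacement) from every
    subject with at least ``k`` cells in the depot×method stratum; subjects
    below ``k`` are excluded and logged by id.  The pooled concatenation is
    described, with fixed-width histogram and KDE tables attached.
    """
    by_subject = _subject_values(cells, depot, method, parameter)
    retained, excluded, chunks = [], [], []
    for subject in sorted(by_subject):
        vals = by_subject[subject]
        try:
            chunks.append(
                geometry.sample_cells(vals, k, seed, subject, depot, method)
            )
            retained.append(subject)
        except InsufficientCellsError:
            excluded.append(subject)
            logger.info(
                "pooled_panel: subject %s excluded (%d < %d cells, %s/%s)",
                subject, len(vals), k, depot, method,
            )
    if not retained:
        raise ValidationError(
            f"no subject has >= {k} cells for {depot}/{method}"
        )
    pooled = np.concatenate(chunks)
    width = bin_width if bin_width is not None else DEFAULT_BIN_WIDTHS[parameter]
    return PooledResult(
        depot=depot,
        method=method,
        size_parameter=parameter,
        values=pooled,
        subject_count=len(retained),
        retained_subjects=retained,
        excluded_subjects=excluded,
        panel=describe(pooled, units=geometry.PARAMETER_UNITS[parameter], seed=seed),
        histogram=histogram_table(pooled, width),
        density=density_table(pooled),
    )


def per_subject_panels(
    cells: pd.DataFrame,
    parameter: str,
    k: dict | int,
    seed: int,
    *,
    shapiro: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptor panel per subject×depot×method plus the cohort summary.

    ``k`` is the per-subject cell count, either a single integer or a mapping
    ``{method: k}`` (histology and collagenase use different counts).  The
    cohort summary aggregates each descriptor across subjects as arithmetic
    mean ± SD, the form in which cohort tables are reported.

    Returns ``(panels, summary)``; subjects with fewer than the requested
    cells are absent from ``panels`` and logged.
    """
    rows = []
    for (depot, method), _ in cells.groupby(["depot", "method"], sort=True):
        k_m = k[method] if isinstance(k, dict) else int(k)
        by_subject = _subject_values(cells, depot, method, parameter)
        for subject in sorted(by_subject):
            vals = by_subject[subject]
            try:
                sampled = geometry.sample_cells(vals, k_m, seed, subject, depot, method)
            except InsufficientCellsError:
                logger.info(
                    "per_subject_panels: subject %s excluded (%d < %d cells, %s/%s)",
                    subject, len(vals), k_m, depot, method,
                )
                continue
            pan = describe(
                sampled, units=geometry.PARAMETER_UNITS[parameter],
                shapiro=shapiro, seed=seed,
            )
            rows.append(
                {"subject_id": subject, "depot": depot, "method": method,
                 "size_parameter": parameter, **pan.as_dict()}
            )
    panels = pd.DataFrame(rows)
    if panels.empty:
        raise ValidationError("no subject met the requested cell count")

    descriptors = ["mean", "median", "first_decile", "ninth_decile", "idr",
                   "skewness", "kurtosis", "mode"]
    summary = (
        panels.groupby(["depot", "method"], sort=True)
        .agg(
            n_subjects=("subject_id", "size"),
            **{f"{d}_mean": (d, "mean") for d in descriptors},
            **{f"{d}_sd": (d, lambda s: s.std(ddof=1)) for d in descriptors},
        )
        .reset_index()
    )
    summary.insert(2, "size_parameter", parameter)
    return panels, summary
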