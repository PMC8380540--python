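"""Seeded generator of a synthetic adipocyte-sizing study.

No per-cell data are publicly deposited for cohorts of this kind, so the
package ships a generator that emulates the statistical structure the
analysis stages assume, calibrated to published cohort summaries:

* subject phenotypes (age, sex, BMI, T2D, glucose, HbA1c, lipids) drawn
  through a Gaussian copula with configurable couplings and truncated-normal
  marginals, with completely-at-random missingness per variable;
* per-cell histology cross-sectional areas: per subject and depot a
  lognormal truncated to the artifact filter window [200, 16000] µm², whose
  log-mean is linear in a subject-level latent size factor coupled to BMI
  (and, visceral depot only, to glucose / HbA1c / HDL);
* per-cell collagenase diameters: per-subject normal, systematically larger
  than the histology diameters and coupled to the subject's realized
  histology mean diameter at a configured inter-method correlation;
* mitochondrial respirometry (free OXPHOS, OXPHOS, ETS, leak) drawn from a
  linear model in the realized depot mean diameter with negative couplings,
  with the physical state ordering ETS >= OXPHOS >= free OXPHOS >= 0 and
  leak <= OXPHOS enforced by clipping (clip counts are reported).

The within-subject log-scale SD and the depot log-mean offsets are not
tabulated anywhere; they are calibrated at generation time by root-solving
so that the central subject's truncated-lognormal IDR/mean ratio and the
cohort mean area match the configured targets (see docs/methods.md).

Identical seed and config give byte-identical output tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, ndtr, ndtri

from .geometry import (
    AREA_FILTER_LOW,
    AREA_FILTER_HIGH,
    ValidationError,
    area_to_diameter,
)

__all__ = [
    "SyntheticConfig",
    "Cohort",
    "build_latent_correlation",
    "calibrate_area_model",
    "generate_phenotypes",
    "generate_cells",
    "generate_respirometry",
    "generate_cohort",
    "subject_mean_diameters_all_cells",
    "LATENT_ORDER",
]

logger = logging.getLogger(__name__)

LATENT_ORDER = (
    "age", "bmi", "sex", "t2d", "glucose", "hba1c",
    "cholesterol", "ldl", "hdl", "triglycerides", "size_sc", "size_vc",
)

DEPOTS = ("sc", "vc")
_Z90 = float(ndtri(0.9))  # 1.2816; IDR of a normal = 2*z90*sd


def _default_phenotype_marginals() -> dict:
    # name -> (mean, sd, lower, upper, n_observed of 188)
    return {
        "age": (48.0, 13.0, 18.0, 78.0, 188),
        "bmi": (43.6, 13.3, 18.2, 83.3, 184),
        "glucose": (6.0, 3.0, 2.2, 22.1, 139),
        "hba1c": (6.0, 1.2, 4.6, 11.5, 99),
        "cholesterol": (5.1, 1.0, 1.4, 8.0, 97),
        "ldl": (3.1, 0.8, 1.3, 5.3, 92),
        "hdl": (1.3, 0.4, 0.6, 2.4, 94),
        "triglycerides": (1.9, 1.0, 0.6, 6.8, 96),
    }


def _default_couplings() -> dict:
    # latent (Gaussian-copula) correlations; unlisted pairs are zero
    return {
        ("size_sc", "bmi"): 0.47,
        ("size_vc", "bmi"): 0.47,
        ("size_vc", "glucose"): 0.26,
        ("size_vc", "hba1c"): 0.31,
        ("size_vc", "hdl"): -0.32,
        ("size_sc", "size_vc"): 0.60,
        # background phenotype structure
        ("glucose", "hba1c"): 0.60,
        ("cholesterol", "ldl"): 0.80,
        ("hdl", "triglycerides"): -0.30,
        ("t2d", "glucose"): 0.45,
        ("t2d", "hba1c"): 0.55,
        ("bmi", "hdl"): -0.15,
    }


def _default_respirometry() -> dict:
    # state -> (mean, sd) in pmol O2 / (s * ng DNA)
    return {
        "free_oxphos": (0.45, 0.15),
        "oxphos": (1.00, 0.30),
        "ets": (1.35, 0.40),
        "leak": (0.25, 0.08),
    }


def _default_respirometry_couplings() -> dict:
    # depot -> state -> target Pearson r with realized mean diameter
    return {
        "sc": {"free_oxphos": -0.41, "oxphos": -0.53, "ets": -0.59, "leak": -0.45},
        "vc": {"free_oxphos": -0.15, "oxphos": -0.36, "ets": -0.25, "leak": -0.35},
    }


@dataclass
class SyntheticConfig:
    """All generator parameters; the defaults encode the study conditions."""

    n_subjects: int = 188
    n_histology: dict = field(default_factory=lambda: {"sc": 161, "vc": 188})
    n_collagenase: dict = field(default_factory=lambda: {"sc": 84, "vc": 97})
    n_respirometry: dict = field(default_factory=lambda: {"sc": 24, "vc": 35})

    phenotype_marginals: dict = field(default_factory=_default_phenotype_marginals)
    n_male: int = 59
    n_t2d: int = 45
    n_t2d_known: int = 185

    couplings: dict = field(default_factory=_default_couplings)

    # histology cell model (truncated lognormal areas, µm²)
    area_mean: dict = field(default_factory=lambda: {"sc": 3472.0, "vc": 2748.8})
    area_idr: dict = field(default_factory=lambda: {"sc": 7283.1, "vc": 5635.3})
    area_mean_sd: dict = field(default_factory=lambda: {"sc": 886.8, "vc": 863.6})
    area_bounds: tuple = (AREA_FILTER_LOW, AREA_FILTER_HIGH)
    cells_per_subject: tuple = (500, 700)  # inclusive uniform range

    # collagenase cell model (normal diameters, µm)
    collagenase_mean: dict = field(default_factory=lambda: {"sc": 105.6, "vc": 98.3})
    collagenase_between_sd: dict = field(default_factory=lambda: {"sc": 14.7, "vc": 15.3})
    collagenase_idr: dict = field(default_factory=lambda: {"sc": 65.9, "vc": 61.2})
    n_collagenase_cells: int = 100
    r_intermethod: float = 0.46

    respirometry_states: dict = field(default_factory=_default_respirometry)
    respirometry_couplings: dict = field(default_factory=_default_respirometry_couplings)
    respirometry_noise_share: float = 0.7  # correlation of state noise terms

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")
        for d in DEPOTS:
            for table, name in (
                (self.n_histology, "histology"),
                (self.n_collagenase, "collagenase"),
                (self.n_respirometry, "respirometry"),
            ):
                if not 0 <= table[d] <= self.n_subjects:
                    raise ValidationError(
                        f"n_{name}[{d}]={table[d]} outside [0, {self.n_subjects}]"
                    )
        for name, (_, sd, lo, hi, n_obs) in self.phenotype_marginals.items():
            if sd < 0:
                raise ValidationError(f"{name}: negative SD {sd}")
            if hi <= lo:
                raise ValidationError(f"{name}: bounds not ordered ({lo}, {hi})")
            if not 0 <= n_obs <= self.n_subjects:
                raise ValidationError(f"{name}: n_observed {n_obs} out of range")
        for pair, r in self.couplings.items():
            if not abs(r) < 1:
                raise ValidationError(f"coupling {pair} has |r| >= 1: {r}")
        if not 0 <= self.n_male <= self.n_subjects:
            raise ValidationError("n_male out of range")
        if not 0 <= self.n_t2d <= self.n_t2d_known <= self.n_subjects:
            raise ValidationError("T2D counts inconsistent")
        if not abs(self.r_intermethod) < 1:
            raise ValidationError(f"|r_intermethod| >= 1: {self.r_intermethod}")
        for depot, states in self.respirometry_couplings.items():
            for state, r in states.items():
                if not abs(r) < 1:
                    raise ValidationError(f"respirometry {depot}/{state} |r| >= 1: {r}")
        # the copula correlation must be a valid correlation matrix
        build_latent_correlation(self.couplings)


@dataclass(frozen=True)
class Cohort:
    """A generated study: tables plus provenance (config, seed, calibration)."""

    phenotypes: pd.DataFrame
    cells: pd.DataFrame
    respirometry: pd.DataFrame
    provenance: dict


def build_latent_correlation(couplings: dict) -> np.ndarray:
    """Assemble and validate the latent correlation matrix of the copula.

    Unlisted pairs default to zero.  A non-positive-semidefinite target is
    rejected with the most implicated variable pair named.
    """
    idx = {name: i for i, name in enumerate(LATENT_ORDER)}
    corr = np.eye(len(LATENT_ORDER))
    for (a, b), r in couplings.items():
        if a not in idx or b not in idx:
            raise ValidationError(f"unknown latent variable in coupling ({a}, {b})")
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[0] < -1e-10:
        v = np.abs(eigvecs[:, 0])
        a, b = np.argsort(v)[-2:]
        raise ValidationError(
            "latent correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals[0]:.3g}); most implicated pair: "
            f"({LATENT_ORDER[b]}, {LATENT_ORDER[a]})"
        )
    return corr


# ---------------------------------------------------------------------------
# truncated lognormal area model and its calibration

def _log_phi_diff(a: float, b: float) -> float:
    """log(Phi(b) - Phi(a)) for a < b, stable in both far tails."""
    if a > 0:  # reflect into the left tail where log_ndtr is accurate
        a, b = -b, -a
    la, lb = log_ndtr(a), log_ndtr(b)
    return float(lb + np.log1p(-np.exp(la - lb)))


def _trunc_lognorm_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    log_mean = (
        mu + 0.5 * sigma**2
        + _log_phi_diff(a - sigma, b - sigma)
        - _log_phi_diff(a, b)
    )
    return float(np.exp(log_mean))


def _trunc_lognorm_quantile(p, mu, sigma, lo: float, hi: float):
    a = ndtr((np.log(lo) - mu) / sigma)
    b = ndtr((np.log(hi) - mu) / sigma)
    return np.exp(mu + sigma * ndtri(a + p * (b - a)))


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(31)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _solve_mu_for_mean(target: float, sigma: float, lo: float, hi: float) -> float:
    """Log-mean giving a truncated-lognormal mean equal to ``target``."""
    return optimize.brentq(
        lambda mu: _trunc_lognorm_mean(mu, sigma, lo, hi) - target,
        np.log(lo) - 5, np.log(hi) + 5, xtol=1e-12,
    )


def calibrate_area_model(config: SyntheticConfig, depot: str) -> dict:
    """Calibrate the lognormal area model for one depot.

    Three deterministic root-solves fix the three free parameters from the
    configured cohort summaries:

    * ``sigma_w`` (within-subject log SD): the central subject (latent
      z = 0), constrained to have mean area equal to the cohort target, has
      a truncated-lognormal IDR/mean ratio equal to the configured ratio;
    * ``mu0`` (depot log-mean offset): averaging the per-subject
      truncated-lognormal mean over the between-subject latent
      (Gauss–Hermite quadrature) reproduces the cohort mean area;
    * ``sigma_b`` (between-subject log SD): the quadrature SD of the
      per-subject means reproduces the configured between-subject SD.
    """
    lo, hi = config.area_bounds
    mean_target = config.area_mean[depot]
    ratio_target = config.area_idr[depot] / mean_target
    sd_target = config.area_mean_sd[depot]

    def ratio_minus_target(sigma_w: float) -> float:
        mu = _solve_mu_for_mean(mean_target, sigma_w, lo, hi)
        q = _trunc_lognorm_quantile(np.array([0.1, 0.9]), mu, sigma_w, lo, hi)
        return (q[1] - q[0]) / mean_target - ratio_target

    sigma_w = optimize.brentq(ratio_minus_target, 0.05, 3.0, xtol=1e-10)

    def _solve_mu0(sigma_b: float) -> float:
        def cohort_mean_minus_target(mu0: float) -> float:
            means = [
                _trunc_lognorm_mean(mu0 + sigma_b * z, sigma_w, lo, hi)
                for z in _GH_NODES
            ]
            return float(np.dot(_GH_WEIGHTS, means)) - mean_target

        return optimize.brentq(
            cohort_mean_minus_target, np.log(lo) - 8, np.log(hi) + 8, xtol=1e-12
        )

    def sd_minus_target(sigma_b: float) -> float:
        mu0 = _solve_mu0(sigma_b)
        means = np.array([
            _trunc_lognorm_mean(mu0 + sigma_b * z, sigma_w, lo, hi)
            for z in _GH_NODES
        ])
        var = float(np.dot(_GH_WEIGHTS, (means - mean_target) ** 2))
        return np.sqrt(var) - sd_target

    sigma_b = optimize.brentq(sd_minus_target, 0.01, 1.5, xtol=1e-8)
    mu0 = _solve_mu0(sigma_b)
    return {"sigma_w": float(sigma_w), "mu0": float(mu0), "sigma_b": float(sigma_b)}


# ---------------------------------------------------------------------------
# generation stages

def _subject_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def _trunc_norm(rng, mean, sd, lo, hi, size):
    """Vectorized inverse-CDF truncated normal draw."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(0.0, 1.0, size)
    return mean + sd * ndtri(a + u * (b - a))


def generate_phenotypes(
    config: SyntheticConfig, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Draw the subject phenotype table via the Gaussian copula.

    Continuous marginals are truncated normals at the configured mean/SD and
    range; sex and T2D are thresholded at the configured prevalences;
    missingness is completely at random at the per-variable rates implied by
    the configured observed counts.  The returned table carries the latent
    size factors in columns ``_latent_size_sc`` / ``_latent_size_vc``; these
    are generator internals consumed by :func:`generate_cells` and excluded
    by the CSV writers.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_z, rng_miss = [np.random.default_rng(s) for s in ss.spawn(2)]

    corr = build_latent_correlation(config.couplings)
    # eigendecomposition square root: stable also for singular targets
    eigvals, eigvecs = np.linalg.eigh(corr)
    root = eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0, None)))
    z = rng_z.standard_normal((config.n_subjects, len(LATENT_ORDER))) @ root.T
    z = pd.DataFrame(z, columns=list(LATENT_ORDER))

    out = pd.DataFrame({"subject_id": _subject_ids(config.n_subjects)})
    for name, (mean, sd, lo, hi, _) in config.phenotype_marginals.items():
        a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
        out[name] = mean + sd * ndtri(a + ndtr(z[name].to_numpy()) * (b - a))

    male_cut = ndtri(1.0 - config.n_male / config.n_subjects)
    out["sex"] = np.where(z["sex"] > male_cut, "male", "female")
    t2d_cut = ndtri(1.0 - config.n_t2d / config.n_t2d_known)
    out["t2d"] = np.where(z["t2d"] > t2d_cut, "yes", "no")

    # missingness, completely at random
    for name, (_, _, _, _, n_obs) in config.phenotype_marginals.items():
        rate = 1.0 - n_obs / config.n_subjects
        if rate > 0:
            out.loc[rng_miss.uniform(size=config.n_subjects) < rate, name] = np.nan
    unknown_rate = 1.0 - config.n_t2d_known / config.n_subjects
    if unknown_rate > 0:
        mask = rng_miss.uniform(size=config.n_subjects) < unknown_rate
        out.loc[mask, "t2d"] = "unknown"

    out["_latent_size_sc"] = z["size_sc"].to_numpy()
    out["_latent_size_vc"] = z["size_vc"].to_numpy()
    return out


def _available(rng, subject_ids: np.ndarray, n: int) -> np.ndarray:
    """Seeded availability mask: n of the subjects, sorted order preserved."""
    chosen = rng.choice(len(subject_ids), size=n, replace=False)
    mask = np.zeros(len(subject_ids), dtype=bool)
    mask[chosen] = True
    return mask


def generate_cells(
    config: SyntheticConfig,
    phenotypes: pd.DataFrame,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Draw the per-cell size table (long canonical form).

    Histology: per available subject and depot, a uniform 500–700 cell count
    of areas from the calibrated truncated lognormal whose log-mean is
    ``mu0 + sigma_b * latent``.  Collagenase: per available subject, 100
    diameters from a normal (truncated at zero) whose subject mean tracks
    the subject's realized histology mean diameter at the configured
    inter-method correlation and offset.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_avail, rng_hist, rng_coll = [np.random.default_rng(s) for s in ss.spawn(3)]

    ids = phenotypes["subject_id"].to_numpy()
    n = len(ids)
    frames = []
    hist_mask = {}
    hist_mean_d = {}

    for depot in DEPOTS:
        mask = _available(rng_avail, ids, config.n_histology[depot])
        hist_mask[depot] = mask
        cal = calibrate_area_model(config, depot)
        latent = phenotypes[f"_latent_size_{depot}"].to_numpy()
        mu_i = cal["mu0"] + cal["sigma_b"] * latent

        lo, hi = config.area_bounds
        k_lo, k_hi = config.cells_per_subject
        counts = rng_hist.integers(k_lo, k_hi + 1, size=n) * mask
        mu_cell = np.repeat(mu_i, counts)
        log_areas = _trunc_norm(
            rng_hist, mu_cell, cal["sigma_w"], np.log(lo), np.log(hi), mu_cell.size
        )
        areas = np.exp(log_areas)
        subj_cell = np.repeat(ids, counts)
        frames.append(
            pd.DataFrame(
                {"subject_id": subj_cell, "depot": depot, "method": "histology",
                 "size_parameter": "area", "value": areas, "unit": "um2"}
            )
        )
        # realized subject mean diameter over all generated cells
        d = area_to_diameter(areas)
        sums = np.zeros(n)
        np.add.at(sums, np.repeat(np.arange(n), counts), d)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        hist_mean_d[depot] = means

    for depot in DEPOTS:
        mask = _available(rng_avail, ids, config.n_collagenase[depot])
        # standardized driver: realized histology mean diameter where the
        # subject has histology in this depot, latent size factor otherwise
        driver = hist_mean_d[depot].copy()
        have = hist_mask[depot]
        if have.any():
            mu_d, sd_d = np.nanmean(driver[have]), np.nanstd(driver[have])
            z_d = np.where(have, (driver - mu_d) / sd_d,
                           phenotypes[f"_latent_size_{depot}"].to_numpy())
        else:
            z_d = phenotypes[f"_latent_size_{depot}"].to_numpy()
        r = config.r_intermethod
        eps = rng_coll.standard_normal(n)
        m_i = (
            config.collagenase_mean[depot]
            + config.collagenase_between_sd[depot]
            * (r * z_d + np.sqrt(1 - r**2) * eps)
        )
        sd_w = config.collagenase_idr[depot] / (2 * _Z90)
        k = config.n_collagenase_cells
        idx = np.flatnonzero(mask)
        mean_cell = np.repeat(m_i[idx], k)
        diam = _trunc_norm(rng_coll, mean_cell, sd_w, 0.0, np.inf, mean_cell.size)
        frames.append(
            pd.DataFrame(
                {"subject_id": np.repeat(ids[idx], k), "depot": depot,
                 "method": "collagenase", "size_parameter": "diameter",
                 "value": diam, "unit": "um"}
            )
        )

    cells = pd.concat(frames, ignore_index=True)
    return cells


def subject_mean_diameters_all_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Histology mean diameter per subject×depot over all generated cells."""
    hist = cells[cells["method"] == "histology"]
    return (
        hist.assign(diameter=area_to_diameter(hist["value"].to_numpy()))
        .groupby(["subject_id", "depot"], sort=True)["diameter"]
        .mean()
        .reset_index()
    )


def generate_respirometry(
    config: SyntheticConfig,
    phenotypes: pd.DataFrame,
    mean_diameters: pd.DataFrame,
    seed: int | np.random.SeedSequence,
) -> tuple[pd.DataFrame, int]:
    """Draw the respirometry table.

    Per depot, the configured subset size is sampled from subjects with a
    known mean diameter; each state is ``mean + sd * (r * z_d +
    sqrt(1 - r^2) * eps)`` with ``z_d`` the standardized mean diameter and
    the eps terms sharing a common component so states are mutually
    correlated.  The physical ordering (ets >= oxphos >= free_oxphos >= 0,
    0 <= leak <= oxphos) is then enforced by clipping; the number of clipped
    entries is returned and logged.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rows = []
    n_clipped = 0
    rho = config.respirometry_noise_share
    for depot in DEPOTS:
        avail = mean_diameters[mean_diameters["depot"] == depot]
        n_want = config.n_respirometry[depot]
        if n_want == 0:
            continue
        if len(avail) < n_want:
            raise ValidationError(
                f"respirometry[{depot}]: {n_want} subjects requested but only "
                f"{len(avail)} have mean diameters"
            )
        take = np.sort(rng.choice(len(avail), size=n_want, replace=False))
        sub = avail.iloc[take]
        d = sub["diameter"].to_numpy()
        z_d = (d - d.mean()) / d.std(ddof=0)
        shared = rng.standard_normal(n_want)
        block = {"subject_id": sub["subject_id"].to_numpy(), "depot": depot}
        for state, (mean, sd) in config.respirometry_states.items():
            r = config.respirometry_couplings[depot][state]
            own = rng.standard_normal(n_want)
            eps = rho * shared + np.sqrt(1 - rho**2) * own
            block[state] = mean + sd * (r * z_d + np.sqrt(1 - r**2) * eps)
        df = pd.DataFrame(block)
        raw = df[list(RESPIRATION_ORDER)].to_numpy().copy()
        df["oxphos"] = np.maximum(df["oxphos"], 0.0)
        df["free_oxphos"] = np.clip(df["free_oxphos"], 0.0, df["oxphos"])
        df["ets"] = np.maximum(df["ets"], df["oxphos"])
        df["leak"] = np.clip(df["leak"], 0.0, df["oxphos"])
        n_clipped += int((df[list(RESPIRATION_ORDER)].to_numpy() != raw).sum())
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    if n_clipped:
        logger.info("generate_respirometry: %d state values clipped to the "
                    "physical ordering", n_clipped)
    return out, n_clipped


RESPIRATION_ORDER = ("free_oxphos", "oxphos", "ets", "leak")


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int = 0
) -> Cohort:
    """Run the three generation stages and bundle the tables with provenance."""
    if config is None:
        config = SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    s_pheno, s_cells, s_resp = ss.spawn(3)
    phenotypes = generate_phenotypes(config, s_pheno)
    cells = generate_cells(config, phenotypes, s_cells)
    mean_d = subject_mean_diameters_all_cells(cells)
    respirometry, n_clipped = generate_respirometry(config, phenotypes, mean_d, s_resp)
    calibration = {d: calibrate_area_model(config, d) for d in DEPOTS}
    config_dict = asdict(config)
    config_dict["couplings"] = sorted(
        [a, b, r] for (a, b), r in config.couplings.items()
    )
    provenance = {
        "seed": int(seed),
        "config": config_dict,
        "calibration": calibration,
        "respirometry_values_clipped": n_clipped,
    }
    return Cohort(
        phenotypes=phenotypes,
        cells=cells,
        respirometry=respirometry,
        provenance=provenance,
    )
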