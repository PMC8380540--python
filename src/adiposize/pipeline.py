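"""End-to-end orchestration of the analysis stages.

``run_pipeline`` ties the stages together in the order the analysis is
meant to be read: per-subject and pooled descriptor panels for every size
parameter, the histology-vs-collagenase method comparison, the per-depot
association matrices with Bonferroni correction, BMI-adjusted regressions,
respirometry associations, and the reduced-cell-count sensitivity check.
Every output is a CSV; a JSON manifest records the configuration and the
SHA-256 of each written file so a rerun with the same seed is verifiably
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, method_compare, panel
from .geometry import SIZE_PARAMETERS, ValidationError

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    cells_path: str = "cells.csv"
    phenotypes_path: str | None = None
    respirometry_path: str | None = None
    output_dir: str = "adiposize_out"
    depots: tuple = ("sc", "vc")
    parameters: tuple = SIZE_PARAMETERS
    k_histology: int = 500
    k_collagenase: int = 100
    k_reduced: int = 200
    filter_low: float = 200.0
    filter_high: float = 16000.0
    alpha: float = 0.05
    regression_covariates: tuple = ("bmi", "sex", "t2d")
    seed: int = 0

    def __post_init__(self):
        if self.k_histology <= 0 or self.k_collagenase <= 0 or self.k_reduced <= 0:
            raise ValidationError("cell counts k must be > 0")
        if not self.filter_low < self.filter_high:
            raise ValidationError("filter bounds must be ordered")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValidationError(f"unknown config key(s): {unknown}")
        for key in ("depots", "parameters", "regression_covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    cells: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    respirometry: pd.DataFrame | None = None,
) -> dict:
    """Run every stage and write the result bundle under ``config.output_dir``.

    Tables may be passed in memory; otherwise they are read from the
    configured paths.  Returns the manifest dict (also written as
    ``manifest.json``).  Deterministic for a fixed config.
    """
    from . import io as aio  # local import to keep module load light

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    with _stage("read"):
        if cells is None:
            cells = aio.read_cells(config.cells_path)
        if phenotypes is None and config.phenotypes_path:
            phenotypes = aio.read_phenotypes(config.phenotypes_path)
        if respirometry is None and config.respirometry_path:
            respirometry = aio.read_respirometry(config.respirometry_path)

    with _stage("filter"):
        from . import geometry
        hist = cells["method"] == "histology"
        area_rows = hist & (cells["size_parameter"] == "area")
        res = geometry.filter_histology_areas(
            cells.loc[area_rows, "value"].to_numpy(),
            config.filter_low, config.filter_high,
        )
        keep = pd.Series(True, index=cells.index)
        keep.loc[area_rows] = (
            (cells.loc[area_rows, "value"] >= config.filter_low)
            & (cells.loc[area_rows, "value"] <= config.filter_high)
        )
        logger.info(
            "filter: excluded %d low / %d high of %d histology areas",
            res.n_excluded_low, res.n_excluded_high, int(area_rows.sum()),
        )
        cells = cells[keep].reset_index(drop=True)
        filter_counts = {
            "n_excluded_low": res.n_excluded_low,
            "n_excluded_high": res.n_excluded_high,
        }

    k_by_method = {"histology": config.k_histology, "collagenase": config.k_collagenase}

    with _stage("panels"):
        all_panels, all_summaries, pooled_rows = [], [], []
        for parameter in config.parameters:
            panels, summary = panel.per_subject_panels(
                cells, parameter, k_by_method, config.seed
            )
            all_panels.append(panels)
            all_summaries.append(summary)
            for depot in config.depots:
                for method in ("histology", "collagenase"):
                    stratum = cells[(cells["depot"] == depot) & (cells["method"] == method)]
                    if stratum.empty:
                        continue
                    pooled = panel.pooled_panel(
                        cells, depot, method, parameter, k_by_method[method], config.seed
                    )
                    pooled_rows.append(
                        {"depot": depot, "method": method, "size_parameter": parameter,
                         "subject_count": pooled.subject_count,
                         "excluded_subjects": ";".join(map(str, pooled.excluded_subjects)),
                         **pooled.panel.as_dict()}
                    )
        written["panels"] = aio.write_table(
            pd.concat(all_panels, ignore_index=True), out / "panels.csv")
        written["cohort_summary"] = aio.write_table(
            pd.concat(all_summaries, ignore_index=True), out / "cohort_summary.csv")
        written["pooled_panels"] = aio.write_table(
            pd.DataFrame(pooled_rows), out / "pooled_panels.csv")

    with _stage("method_compare"):
        methods_present = set(cells["method"])
        if {"histology", "collagenase"} <= methods_present:
            mh = pd.concat(
                [association.subject_mean_sizes(
                    cells, d, "histology", config.k_histology, config.seed,
                    parameters=("diameter",))
                 for d in config.depots],
                ignore_index=True,
            )
            mc = pd.concat(
                [association.subject_mean_sizes(
                    cells, d, "collagenase", config.k_collagenase, config.seed,
                    parameters=("diameter",))
                 for d in config.depots],
                ignore_index=True,
            )
            paired = method_compare.pair_subjects(mh, mc, pool_depots=True)
            ba = method_compare.bland_altman(paired)
            r, p = method_compare.method_concordance(paired)
            written["method_pairs"] = aio.write_table(ba.pairs, out / "method_pairs.csv")
            written["method_compare"] = aio.write_table(
                pd.DataFrame([{
                    "n_pairs": ba.n_pairs, "bias": ba.bias, "sd_diff": ba.sd_diff,
                    "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                    "pearson_r": r, "pearson_p": p,
                }]),
                out / "method_compare.csv",
            )

    with _stage("associations"):
        if phenotypes is not None:
            assoc_frames = []
            for depot in config.depots:
                sizes = association.subject_mean_sizes(
                    cells, depot, "histology", config.k_histology, config.seed
                )
                if sizes.empty:
                    continue
                mat = association.correlation_matrix(sizes, phenotypes)
                mat.insert(0, "depot", depot)
                assoc_frames.append(mat)
                reg_rows = []
                covars = ["diameter"] + [
                    c for c in config.regression_covariates if c in phenotypes.columns
                ]
                merged = sizes.merge(phenotypes, on="subject_id")
                for var in ("glucose", "hba1c", "hdl", "triglycerides", "age"):
                    if var not in merged.columns:
                        continue
                    try:
                        reg = association.adjusted_regression(
                            merged, var, covars, size_parameter="diameter")
                    except ValidationError:
                        continue
                    reg.insert(0, "depot", depot)
                    reg_rows.append(reg)
                if reg_rows:
                    assoc_frames.append(pd.concat(reg_rows, ignore_index=True))
            if assoc_frames:
                written["associations"] = aio.write_table(
                    pd.concat(assoc_frames, ignore_index=True),
                    out / "associations.csv",
                )

    with _stage("respirometry"):
        if respirometry is not None:
            mean_d = pd.concat(
                [association.subject_mean_sizes(
                    cells, d, "histology", config.k_histology, config.seed,
                    parameters=("diameter",))
                 for d in config.depots],
                ignore_index=True,
            )
            resp = association.respirometry_associations(
                respirometry, mean_d, phenotypes
            )
            written["respirometry_associations"] = aio.write_table(
                resp, out / "respirometry_associations.csv")

    with _stage("sensitivity"):
        try:
            r_sens, p_sens, table = association.cell_count_sensitivity(
                cells, config.k_histology, config.k_reduced, config.seed
            )
            table["pearson_r"] = r_sens
            table["pearson_p"] = p_sens
            written["sensitivity"] = aio.write_table(table, out / "sensitivity.csv")
        except ValidationError as exc:
            logger.info("sensitivity stage skipped: %s", exc)

    manifest = {
        "config": dataclasses.asdict(config),
        "filter": filter_counts,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in written.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
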