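"""Survey table I/O, column-role configuration and the pipeline driver.

The interchange format between pipeline stages is a delimited text table
(CSV, header row, UTF-8) accompanied by a sidecar YAML/JSON file that
records which column plays which design role (weight, PSU, stratum,
outcomes, assets, covariates). DHS recode files ship sampling weights
multiplied by 10**6; :func:`normalize_dhs_weights` undoes that convention.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Recognised weight scales: ``natural`` (use as-is) and ``dhs_millionths``
#: (standard-recode convention; divide by 1e6 before use).
WEIGHT_SCALES = ("natural", "dhs_millionths")

#: Pipeline stages in dependency order.
PIPELINE_STAGES = ("wealth-index", "concentration", "decompose", "summarize")


@dataclass
class ColumnConfig:
    """Mapping from design roles to column names of a survey table.

    Roles must be disjoint and every named column must exist in the table
    the config is applied to (checked in :func:`read_survey_table`).
    """

    weight_col: str = "weight"
    psu_col: str = "psu_id"
    stratum_col: str = "stratum_id"
    outcome_cols: list[str] = field(default_factory=list)
    asset_cols: list[str] = field(default_factory=list)
    covariate_cols: list[str] = field(default_factory=list)
    quintile_col: str | None = None
    weight_scale: str = "natural"

    def __post_init__(self) -> None:
        if self.weight_scale not in WEIGHT_SCALES:
            raise ValueError(
                f"weight_scale must be one of {WEIGHT_SCALES}, got {self.weight_scale!r}"
            )
        roles: list[str] = [self.weight_col, self.psu_col, self.stratum_col]
        roles += list(self.outcome_cols) + list(self.asset_cols) + list(self.covariate_cols)
        if self.quintile_col is not None:
            roles.append(self.quintile_col)
        dupes = {c for c in roles if roles.count(c) > 1}
        if dupes:
            raise ValueError(f"column roles must be disjoint; duplicated: {sorted(dupes)}")

    @property
    def required_cols(self) -> list[str]:
        cols = [self.weight_col, self.psu_col, self.stratum_col]
        cols += list(self.outcome_cols) + list(self.asset_cols) + list(self.covariate_cols)
        if self.quintile_col is not None:
            cols.append(self.quintile_col)
        return cols

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnConfig":
        return cls(**dict(d))

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def read(cls, path: str | Path) -> "ColumnConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class SurveyDataset:
    """A woman-level survey table plus its column-role configuration."""

    table: pd.DataFrame
    config: ColumnConfig

    def __post_init__(self) -> None:
        missing = [c for c in self.config.required_cols if c not in self.table.columns]
        if missing:
            raise KeyError(f"column not found: {missing}")

    @property
    def weights(self) -> np.ndarray:
        return self.table[self.config.weight_col].to_numpy(float)

    @property
    def n(self) -> int:
        return len(self.table)

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` and ``<prefix>.config.yaml``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        cfg_path = prefix.parent / (prefix.name + ".config.yaml")
        self.table.to_csv(csv_path, index=False)
        self.config.write(cfg_path)
        return csv_path, cfg_path


def normalize_dhs_weights(
    weights: Iterable[float] | np.ndarray, scale: str = "natural"
) -> np.ndarray:
    """Convert sampling weights to the natural scale.

    DHS standard recode files store six-decimal weights without the decimal
    point; under ``scale='dhs_millionths'`` they are divided by 1,000,000.
    """
    w = np.asarray(weights, dtype=float)
    if w.size and (np.any(~np.isfinite(w)) or np.any(w <= 0)):
        raise ValueError("weights must be finite and strictly positive")
    if scale == "natural":
        return w
    if scale == "dhs_millionths":
        return w / 1_000_000.0
    raise ValueError(f"unknown weight scale {scale!r}")


def read_survey_table(path: str | Path, config: ColumnConfig) -> SurveyDataset:
    """Read a delimited survey table, applying listwise deletion.

    Rows with missing values in any role column are dropped and counted in
    the log. Weights are brought to the natural scale according to
    ``config.weight_scale``.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in config.required_cols if c not in df.columns]
    if missing:
        raise KeyError(f"column not found: {missing}")
    w_raw = df[config.weight_col]
    non_numeric = pd.to_numeric(w_raw, errors="coerce").isna() & w_raw.notna()
    if non_numeric.any():
        row = int(np.flatnonzero(non_numeric.to_numpy())[0])
        raise ValueError(f"non-numeric weight at row {row}")
    n0 = len(df)
    df = df.dropna(subset=config.required_cols).reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        logger.info("read_survey_table: dropped %d incomplete rows (of %d)", dropped, n0)
    df[config.weight_col] = normalize_dhs_weights(
        df[config.weight_col].to_numpy(float), config.weight_scale
    )
    cfg = dataclasses.replace(config, weight_scale="natural")
    return SurveyDataset(df, cfg)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(
    dataset: SurveyDataset,
    stages: Sequence[str],
    *,
    outcomes: Sequence[str] | None = None,
    covariates: Sequence[str] | None = None,
    bootstrap_reps: int = 0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the analysis stages in order on ``dataset``.

    Stages are a subset of ``wealth-index``, ``concentration``,
    ``decompose``, ``summarize``. The wealth-index stage adds
    ``wealth_score`` and ``wealth_quintile`` columns which the later stages
    require; requesting a later stage without them (and without the stage
    that creates them) raises a dependency error.

    Returns a report dict (JSON-serialisable); when ``out_dir`` is given the
    report and per-stage CSV tables are also written there.
    """
    from . import concentration as conc_mod
    from . import decomposition as dec_mod
    from . import summaries as sum_mod
    from . import wealth as wealth_mod

    stages = list(stages)
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}; valid: {PIPELINE_STAGES}")
    order = {s: i for i, s in enumerate(PIPELINE_STAGES)}
    if stages != sorted(stages, key=order.__getitem__):
        raise ValueError(f"stages out of dependency order; expected order {PIPELINE_STAGES}")

    import copy

    ds = SurveyDataset(dataset.table.copy(), copy.deepcopy(dataset.config))
    cfg = ds.config
    outcomes = list(outcomes) if outcomes is not None else list(cfg.outcome_cols)
    report: dict = {"settings": {"stages": stages, "seed": seed, "outcomes": outcomes}}

    def _need(col: str, stage: str, provider: str) -> None:
        if col not in ds.table.columns:
            raise ValueError(
                f"stage {stage!r} requires column {col!r}; run the {provider!r} "
                "stage first or provide the column in the input table"
            )

    outputs: dict[str, pd.DataFrame] = {}

    if "wealth-index" in stages:
        res = wealth_mod.add_wealth_index(ds)
        report["wealth_index"] = {
            "explained_variance_ratio": float(res.explained_variance_ratio),
            "orientation_flipped": bool(res.orientation_flipped),
            "loadings": {k: float(v) for k, v in res.loadings.items()},
            "dropped_assets": list(res.dropped_assets),
        }
        cfg.quintile_col = "wealth_quintile"

    if "concentration" in stages:
        _need("wealth_score", "concentration", "wealth-index")
        report["concentration"] = {}
        for out in outcomes:
            r = conc_mod.concentration_summary(
                ds, out, rank_by="wealth_score",
                se_method="bootstrap" if bootstrap_reps else "analytic",
                n_reps=bootstrap_reps, seed=seed,
            )
            report["concentration"][out] = r.to_dict()

    if "decompose" in stages:
        _need("wealth_score", "decompose", "wealth-index")
        covs = list(covariates) if covariates is not None else (
            list(cfg.covariate_cols) + ["wealth_score"]
        )
        report["decomposition"] = {}
        for out in outcomes:
            dres = dec_mod.decompose_erreygers(ds, out, covs, rank_by="wealth_score")
            if bootstrap_reps:
                ci = dec_mod.bootstrap_contributions(
                    ds, out, covs, rank_by="wealth_score",
                    n_reps=bootstrap_reps, seed=seed,
                )
                dres = dec_mod.attach_bootstrap_cis(dres, ci)
            report["decomposition"][out] = dres.to_dict()
            outputs[f"decomposition_{out}"] = dres.to_frame()

    if "summarize" in stages:
        qcol = cfg.quintile_col or "wealth_quintile"
        _need(qcol, "summarize", "wealth-index")
        report["summaries"] = {}
        for out in outcomes:
            qs = sum_mod.QuintileSummary.from_dataset(ds, out, quintile_col=qcol)
            report["summaries"][out] = qs.to_dict()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, default=_json_default, allow_nan=True) + "\n"
        )
        for name, frame in outputs.items():
            frame.to_csv(out_dir / f"{name}.csv", index=False)
    return report
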