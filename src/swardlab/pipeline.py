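"""End-to-end pipeline: generate → metrics → traits → effects → models.

A run is fully determined by a :class:`RunConfig` (optionally loaded from
YAML).  Stages execute in dependency order, each writing plain TSV tables
(UTF-8, tab-separated, header row, ``.`` decimal); a ``manifest.json``
records the config hash, per-file checksums and warning counters so tests
and users can assert reproducibility.  Dates are stored as ``year`` and
``doy`` (day-of-year) columns, matching the two-year wrap-around calendar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_traits import build_cwm_table, build_fdq_table
from .design import DesignSpec, Period, PotSpec, SpeciesSpec, build_design, default_species_pool
from .diversity_effects import partition_per_period
from .resource_metrics import build_period_metrics, species_period_table
from .synthetic import GeneratedDataset, InteractionSpec, generate_dataset
from .trait_models import RESPONSES, assemble_matrix, best_subset_by_loocv, importance_table

__all__ = [
    "RunConfig",
    "RunManifest",
    "write_dataset",
    "read_dataset",
    "run",
    "validate_tables",
]

log = logging.getLogger("swardlab")

_FLOAT_FMT = "%.17g"  # round-trip exact, keeps outputs byte-stable

_CONVENTIONS = {
    "proportion_convention": ("sown", "observed"),
    "partition_level": ("composition", "pot"),
    "fd_distance": ("gower", "sq_euclidean"),
    "importance_metric": ("lmg", "pmvd"),
}


@dataclass
class RunConfig:
    """Everything that determines a pipeline run."""

    scenario: str = "synthetic"      # "synthetic" or a directory of input TSVs
    seed: int = 0
    out_dir: str = "swardlab_out"
    # generator knobs (synthetic scenario only)
    n_reps_mono: int = 4
    n_reps_mix: int = 3
    facilitation_ramp: tuple[float, ...] = (0.0, 0.0, 0.1, 0.2, 0.3, 0.4)
    legume_suppression_early: float = 0.35
    complementarity_amplitude: float = 0.12
    noise_cv: float = 0.15
    # analysis conventions
    rew_sm_min: float = 0.054
    rew_sm_max: float = 0.379
    proportion_convention: str = "sown"
    partition_level: str = "composition"
    fd_distance: str = "gower"
    model_scope: str = "whole"
    model_max_size: int = 5
    importance_metric: str = "pmvd"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, allowed in _CONVENTIONS.items():
            if getattr(self, name) not in allowed:
                raise ValueError(
                    f"config field {name}={getattr(self, name)!r}: allowed {allowed}"
                )
        if self.rew_sm_max <= self.rew_sm_min:
            raise ValueError("rew_sm_max must exceed rew_sm_min")
        if self.scenario == "synthetic" and self.seed is None:
            raise ValueError("synthetic runs require a seed")
        self.facilitation_ramp = tuple(float(f) for f in self.facilitation_ramp)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["facilitation_ramp"] = list(self.facilitation_ramp)
        return d

    def interaction(self) -> InteractionSpec:
        return InteractionSpec(
            facilitation_ramp=self.facilitation_ramp,
            legume_suppression_early=self.legume_suppression_early,
            complementarity_amplitude=self.complementarity_amplitude,
            noise_cv=self.noise_cv,
            seed=self.seed,
        )

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    checksums: dict[str, str]
    warnings: dict[str, int]
    stages: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT,
              lineterminator="\n")


def write_dataset(ds: GeneratedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all raw tables of a generated dataset as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    design_rows = [{
        "pot_id": p.pot_id,
        "composition": ",".join(p.composition),
        "proportions": ",".join(f"{v:.17g}" for v in p.proportions),
        "replicate": p.replicate,
        "sward_type": p.sward_type,
    } for p in ds.design.pots]
    period_rows = [{
        "label": p.label, "year_start": p.start[0], "doy_start": p.start[1],
        "year_end": p.end[0], "doy_end": p.end[1],
    } for p in ds.design.periods]
    species_rows = [{
        "species_id": s.species_id, "functional_group": s.functional_group,
        "stature": s.stature, "rooting": s.rooting,
        "green_leaf_fraction": s.green_leaf_fraction,
    } for s in ds.pool]

    tables = {
        "design.tsv": pd.DataFrame(design_rows),
        "periods.tsv": pd.DataFrame(period_rows),
        "species.tsv": pd.DataFrame(species_rows),
        "biomass.tsv": ds.biomass,
        "traits.tsv": ds.traits,
        "weights.tsv": ds.weights,
        "moisture.tsv": ds.moisture,
        "ground_truth.tsv": ds.ground_truth,
    }
    for name, df in tables.items():
        path = out / name
        _write_tsv(df, path)
        files[name] = path
    return files


def read_dataset(data_dir: str | Path) -> tuple[DesignSpec, list[SpeciesSpec], dict[str, pd.DataFrame]]:
    """Read the TSV tables of a dataset directory back into memory."""
    d = Path(data_dir)

    def rd(name: str, **kw) -> pd.DataFrame:
        path = d / name
        if not path.exists():
            raise FileNotFoundError(f"missing input table {path}")
        return pd.read_csv(path, sep="\t", float_precision="round_trip", **kw)

    periods_df = rd("periods.tsv")
    periods = tuple(
        Period(str(r.label), (int(r.year_start), int(r.doy_start)),
               (int(r.year_end), int(r.doy_end)))
        for r in periods_df.itertuples()
    )
    design_df = rd("design.tsv")
    pots = tuple(
        PotSpec(
            pot_id=str(r.pot_id),
            composition=tuple(str(r.composition).split(",")),
            proportions=tuple(float(x) for x in str(r.proportions).split(",")),
            replicate=int(r.replicate),
            sward_type=str(r.sward_type),
        )
        for r in design_df.itertuples()
    )
    species_df = rd("species.tsv")
    n_periods = len(periods)
    pool = [
        SpeciesSpec(
            species_id=str(r.species_id), functional_group=str(r.functional_group),
            stature=str(r.stature), rooting=str(r.rooting),
            mono_yield_by_period=tuple(0.0 for _ in range(n_periods)),
            green_leaf_fraction=float(r.green_leaf_fraction),
        )
        for r in species_df.itertuples()
    ]
    from .design import _default_measurement_dates  # lazy: derived calendar
    design = DesignSpec(pots=pots, periods=periods,
                        measurement_dates=_default_measurement_dates(periods))
    tables = {
        "biomass": rd("biomass.tsv"),
        "traits": rd("traits.tsv", keep_default_na=False,
                     dtype={"pot_id": str, "species": str, "variable": str}),
        "weights": rd("weights.tsv"),
        "moisture": rd("moisture.tsv"),
    }
    tables["traits"]["value"] = tables["traits"]["value"].astype(float)
    for col in ("year", "doy"):
        tables["traits"][col] = tables["traits"][col].astype(int)
    gt = d / "ground_truth.tsv"
    if gt.exists():
        tables["ground_truth"] = pd.read_csv(gt, sep="\t")
    return design, pool, tables


class _WarningCounter:
    """Counts pipeline warnings by category keyword."""

    KEYS = {
        "negative daily ET": "negative_et_clipped",
        "REW values outside": "rew_clipped",
        "constant trait column": "fd_traits_dropped",
        "PMVD": "pmvd_fallback",
        "rank-deficient": "rank_deficient_subsets",
    }

    def __init__(self) -> None:
        self.counts: dict[str, int] = {v: 0 for v in self.KEYS.values()}
        self.other = 0

    def add(self, message: str) -> None:
        for needle, key in self.KEYS.items():
            if needle in message:
                self.counts[key] += 1
                return
        self.other += 1

    def as_dict(self) -> dict[str, int]:
        return {**self.counts, "other": self.other}


def run(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all output tables.

    Stage order: generate (or load) raw tables, per-period resource metrics,
    CWM and FD_Q tables, diversity-effect partition and deviations, trait
    model selection with relative importance, manifest.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    stages: list[str] = []
    files: dict[str, Path] = {}

    def stage(name: str):
        log.info("stage: %s", name)
        stages.append(name)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        stage("inputs")
        if config.scenario == "synthetic":
            ds = generate_dataset(
                ix=config.interaction(),
                n_reps_mono=config.n_reps_mono,
                n_reps_mix=config.n_reps_mix,
            )
            files.update(write_dataset(ds, out))
            design, pool = ds.design, ds.pool
            tables = {"biomass": ds.biomass, "traits": ds.traits,
                      "weights": ds.weights, "moisture": ds.moisture}
        else:
            design, pool, tables = read_dataset(config.scenario)

        try:
            stage("period_metrics")
            sp_table = species_period_table(design, tables["biomass"], tables["traits"])
            metrics = build_period_metrics(
                design, tables["biomass"], tables["traits"], tables["weights"],
                tables["moisture"], sm_min=config.rew_sm_min,
                sm_max=config.rew_sm_max, species_table=sp_table,
            )
            files["period_metrics.tsv"] = out / "period_metrics.tsv"
            _write_tsv(metrics, files["period_metrics.tsv"])

            stage("community_traits")
            cwm_df = build_cwm_table(design, sp_table, metrics)
            fdq_df = build_fdq_table(design, sp_table, distance=config.fd_distance)
            files["cwm.tsv"] = out / "cwm.tsv"
            files["fdq.tsv"] = out / "fdq.tsv"
            _write_tsv(cwm_df, files["cwm.tsv"])
            _write_tsv(fdq_df, files["fdq.tsv"])

            stage("diversity_effects")
            effects, deviations = partition_per_period(
                tables["biomass"], design, pool,
                proportion_convention=config.proportion_convention,
                level=config.partition_level,
            )
            files["diversity_effects.tsv"] = out / "diversity_effects.tsv"
            files["deviations.tsv"] = out / "deviations.tsv"
            _write_tsv(effects, files["diversity_effects.tsv"])
            _write_tsv(deviations, files["deviations.tsv"])

            stage("trait_models")
            matrix = assemble_matrix(cwm_df, effects, metrics, design,
                                     scope=config.model_scope)
            reports = []
            sel_rows = []
            for response in RESPONSES:
                rep = best_subset_by_loocv(
                    matrix.X, matrix.responses[response].to_numpy(),
                    max_size=config.model_max_size, response=response,
                )
                reports.append(rep)
                for k in rep.cv_mse_by_size:
                    sel_rows.append({
                        "response": response, "subset_size": k,
                        "cv_mse": rep.cv_mse_by_size[k],
                        "subset": ",".join(rep.best_by_size[k]),
                        "winner": k == len(rep.selected),
                        "r2_winner": rep.r2,
                    })
            files["model_selection.tsv"] = out / "model_selection.tsv"
            files["importance.tsv"] = out / "importance.tsv"
            _write_tsv(pd.DataFrame(sel_rows), files["model_selection.tsv"])
            _write_tsv(importance_table(reports, metric=config.importance_metric),
                       files["importance.tsv"])
        except Exception as exc:
            raise RuntimeError(f"stage {stages[-1]!r} failed: {exc}") from exc

    for w in caught:
        counter.add(str(w.message))

    stage("manifest")
    manifest = RunManifest(
        config_hash=config.hash(),
        version=__version__,
        checksums={name: _sha256(path) for name, path in sorted(files.items())},
        warnings=counter.as_dict(),
        stages=stages,
    )
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# validation


def _issue(file: str, row, column, message: str) -> dict:
    return {"file": file, "row": row, "column": column, "message": message}


def validate_tables(data_dir: str | Path) -> list[dict]:
    """Schema and consistency checks on a dataset directory.

    Checks: required files and columns, key uniqueness, sown proportions
    summing to 1, non-negative biomass and moisture, strictly increasing
    dates per pot.  Returns a machine-readable list of issues (empty when
    the directory is valid).
    """
    d = Path(data_dir)
    issues: list[dict] = []

    required = {
        "design.tsv": ["pot_id", "composition", "proportions", "replicate", "sward_type"],
        "periods.tsv": ["label", "year_start", "doy_start", "year_end", "doy_end"],
        "species.tsv": ["species_id", "functional_group"],
        "biomass.tsv": ["pot_id", "period", "species", "biomass"],
        "traits.tsv": ["pot_id", "species", "year", "doy", "variable", "value"],
        "weights.tsv": ["pot_id", "year", "doy", "weight_kg", "addition_kg"],
        "moisture.tsv": ["pot_id", "year", "doy", "moisture"],
    }
    frames: dict[str, pd.DataFrame] = {}
    for name, cols in required.items():
        path = d / name
        if not path.exists():
            issues.append(_issue(name, None, None, "file missing"))
            continue
        try:
            df = pd.read_csv(path, sep="\t",
                             keep_default_na=(name != "traits.tsv"))
        except Exception as exc:  # unreadable file
            issues.append(_issue(name, None, None, f"unreadable: {exc}"))
            continue
        missing = [c for c in cols if c not in df.columns]
        if missing:
            issues.append(_issue(name, None, ",".join(missing), "missing columns"))
            continue
        frames[name] = df

    if "design.tsv" in frames:
        df = frames["design.tsv"]
        dup = df["pot_id"].duplicated()
        for idx in df.index[dup]:
            issues.append(_issue("design.tsv", int(idx), "pot_id", "duplicate pot id"))
        for idx, r in df.iterrows():
            props = [float(x) for x in str(r["proportions"]).split(",")]
            if abs(sum(props) - 1.0) > 1e-6:
                issues.append(_issue("design.tsv", int(idx), "proportions",
                                     f"sown proportions sum to {sum(props):g}, not 1"))
            if len(props) != len(str(r["composition"]).split(",")):
                issues.append(_issue("design.tsv", int(idx), "proportions",
                                     "length mismatch with composition"))

    if "biomass.tsv" in frames:
        df = frames["biomass.tsv"]
        key = ["pot_id", "period", "species"]
        dup = df.duplicated(subset=key)
        for idx in df.index[dup]:
            issues.append(_issue("biomass.tsv", int(idx), ",".join(key),
                                 "duplicate (pot, period, species) row"))
        neg = df["biomass"] < 0
        for idx in df.index[neg]:
            issues.append(_issue("biomass.tsv", int(idx), "biomass", "negative biomass"))

    for name in ("weights.tsv", "moisture.tsv"):
        if name not in frames:
            continue
        df = frames[name]
        for pot_id, g in df.groupby("pot_id"):
            days = (g["year"].astype(int) - 1) * 365 + g["doy"].astype(int)
            if np.any(np.diff(days.to_numpy()) <= 0):
                issues.append(_issue(name, str(pot_id), "year,doy",
                                     "dates not strictly increasing"))
    if "moisture.tsv" in frames:
        df = frames["moisture.tsv"]
        neg = df["moisture"] < 0
        for idx in df.index[neg]:
            issues.append(_issue("moisture.tsv", int(idx), "moisture",
                                 "negative soil moisture"))

    if "design.tsv" in frames and "biomass.tsv" in frames and "periods.tsv" in frames:
        pots = set(frames["design.tsv"]["pot_id"].astype(str))
        periods = set(frames["periods.tsv"]["label"].astype(str))
        bm = frames["biomass.tsv"]
        seen = set(zip(bm["pot_id"].astype(str), bm["period"].astype(str)))
        for p in sorted(pots):
            for per in sorted(periods):
                if (p, per) not in seen:
                    issues.append(_issue("biomass.tsv", None, None,
                                         f"no biomass rows for pot {p} period {per}"))
    return issues
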