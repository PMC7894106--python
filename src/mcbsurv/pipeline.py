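"""End-to-end orchestration: preprocess → discover → select → train →
ensemble → evaluate, with a strict YAML config and a provenance record.

The sample split mirrors a training/validation/testing study: blocks are
partitioned and selected on training samples only, validation enters only
as extra rank-product columns, and the testing split is touched once for
the final survival comparison.  A combined mode (single 80/20 split, rank
on training only) is available as ``split.mode: combined``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .base_learners import (
    FitError,
    RiskScoreVector,
    cv_risk_scores,
    fit_cox,
    fit_enet_cox,
    fit_svr,
    select_mcbs_l1,
)
from .data_io import (
    BetaMatrix,
    SurvivalTable,
    read_beta_matrix,
    read_clinical,
    read_manifest,
    write_mcb_bed,
)
from .evaluation import (
    concordance_index,
    km_logrank,
    multivariate_adjustment,
    rank_product,
    time_dependent_auc,
)
from .mcb_discovery import PartitionParams, mcb_mean_matrix, partition_mcbs
from .preprocess import filter_cpgs
from .stacking import StackingSpec, ensemble_cv_scores, fit_fwls, predict_fwls, stacking_target
from .synthetic_data import BlockSpec, SimDesign, default_design, simulate_methylation, simulate_survival

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration is malformed."""


@dataclass(frozen=True)
class SplitConfig:
    mode: str = "train_val_test"  # or "combined"
    train_frac: float = 0.6
    val_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("train_val_test", "combined"):
            raise ConfigError(f"unknown split mode {self.mode!r}")
        if not (0 < self.train_frac < 1) or self.val_frac < 0 or self.train_frac + self.val_frac >= 1:
            raise ConfigError("split fractions must leave a nonempty testing set")


@dataclass(frozen=True)
class SimulateConfig:
    n_samples: int = 300
    n_blocks: int = 21
    causal_block_index: int | None = 0
    n_cpgs_per_block: int = 5
    rho: float = 0.95
    n_noise_cpgs: int = 100


@dataclass(frozen=True)
class InputConfig:
    beta: str | None = None
    manifest: str | None = None
    clinical: str | None = None


@dataclass(frozen=True)
class PartitionConfig:
    r2_cutoff: float = 0.8
    max_gap: int = 1000
    min_cpgs: int = 2


@dataclass(frozen=True)
class SelectionConfig:
    lambda_threshold: float = 0.01
    min_cpgs: int = 5


@dataclass(frozen=True)
class TrainConfig:
    models: tuple[str, ...] = ("cox", "svr", "enet")
    k: int = 10
    alpha_mix: float = 0.5
    svr_target: str = "time"


@dataclass(frozen=True)
class StackConfig:
    target_mode: str = "event"
    nonneg: bool = False


@dataclass(frozen=True)
class EvalConfig:
    horizon_days: float = 1826.0
    missing_threshold: float = 0.30


@dataclass(frozen=True)
class RunConfig:
    seed: int = 42
    out_dir: str = "run_out"
    log_level: str = "INFO"
    simulate: SimulateConfig | None = None
    inputs: InputConfig | None = None
    split: SplitConfig = field(default_factory=SplitConfig)
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    stack: StackConfig = field(default_factory=StackConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' must be given")


_SECTION_TYPES = {
    "simulate": SimulateConfig,
    "inputs": InputConfig,
    "split": SplitConfig,
    "partition": PartitionConfig,
    "selection": SelectionConfig,
    "train": TrainConfig,
    "stack": StackConfig,
    "evaluation": EvalConfig,
}


def _build_section(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    if cls is TrainConfig and "models" in data:
        data = {**data, "models": tuple(data["models"])}
    return cls(**data)


def load_config(source) -> RunConfig:
    """Parse a RunConfig from a YAML file path or an already-loaded dict;
    unknown keys anywhere are rejected before any compute."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        if key in _SECTION_TYPES:
            if val is None:
                continue
            kwargs[key] = _build_section(_SECTION_TYPES[key], dict(val))
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    canon = json.dumps(_config_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _config_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def _split_samples(sample_ids, split: SplitConfig, seed: int):
    rng = np.random.default_rng([seed, 77])
    ids = np.asarray(sample_ids)
    perm = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(round(split.train_frac * n))
    if split.mode == "combined":
        return list(ids[perm[:n_train]]), [], list(ids[perm[n_train:]])
    n_val = int(round(split.val_frac * n))
    train = list(ids[perm[:n_train]])
    val = list(ids[perm[n_train : n_train + n_val]])
    test = list(ids[perm[n_train + n_val :]])
    return train, val, test


_FITTERS = {
    "cox": lambda cfg: (lambda bb, sv: fit_cox(bb, sv)),
    "svr": lambda cfg: (lambda bb, sv: fit_svr(bb, sv, target=cfg.train.svr_target)),
    "enet": lambda cfg: (lambda bb, sv: fit_enet_cox(bb, sv, alpha_mix=cfg.train.alpha_mix)),
}


@dataclass
class EvalReport:
    """Per-block, per-model, per-split metrics plus ranking and tests."""

    auc: pd.DataFrame
    cindex: pd.DataFrame
    rp: pd.Series
    selected_mcb_ids: list[int]
    top_mcb_id: int | None
    km: dict
    multivariate: dict | None
    n_mcbs_discovered: int

    def to_json_dict(self) -> dict:
        return {
            "n_mcbs_discovered": self.n_mcbs_discovered,
            "selected_mcb_ids": list(map(int, self.selected_mcb_ids)),
            "auc": {str(k): {c: _j(v) for c, v in row.items()} for k, row in self.auc.to_dict(orient="index").items()},
            "cindex": {str(k): {c: _j(v) for c, v in row.items()} for k, row in self.cindex.to_dict(orient="index").items()},
            "rank_product": {str(k): _j(v) for k, v in self.rp.items()},
            "top_mcb_id": None if self.top_mcb_id is None else int(self.top_mcb_id),
            "km": self.km,
            "multivariate": self.multivariate,
        }


def _j(v):
    if v is None:
        return None
    v = float(v)
    return None if np.isnan(v) else v


def run_pipeline(config: RunConfig) -> EvalReport:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Stages fail loudly with the failing stage named; the written report is
    byte-identical across reruns with the same config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = config.simulate
            design = default_design(
                seed=config.seed,
                n_samples=sim.n_samples,
                n_blocks=sim.n_blocks,
                causal_block_index=sim.causal_block_index,
                n_cpgs_per_block=sim.n_cpgs_per_block,
                rho=sim.rho,
                n_noise_cpgs=sim.n_noise_cpgs,
            )
            beta, ann = simulate_methylation(design)
            surv = simulate_survival(beta, None, design)
        else:
            inp = config.inputs
            assert inp is not None
            if not (inp.beta and inp.manifest and inp.clinical):
                raise ConfigError("inputs requires beta, manifest and clinical paths")
            beta = read_beta_matrix(inp.beta)
            ann = read_manifest(inp.manifest)
            surv = read_clinical(inp.clinical)

        stage = "preprocess"
        beta = filter_cpgs(beta, ann, missing_threshold=config.evaluation.missing_threshold)
        shared = [s for s in beta.sample_ids if s in set(surv.sample_ids)]
        surv = surv.subset(shared)
        beta = BetaMatrix(beta.values.loc[:, shared])

        stage = "split"
        train_ids, val_ids, test_ids = _split_samples(shared, config.split, config.seed)
        splits = {"training": train_ids, "validation": val_ids, "testing": test_ids}
        beta_train = BetaMatrix(beta.values.loc[:, train_ids])
        surv_train = surv.subset(train_ids)

        stage = "discover"
        params = PartitionParams(
            r2_cutoff=config.partition.r2_cutoff,
            max_gap=config.partition.max_gap,
            min_cpgs=config.partition.min_cpgs,
        )
        mcbs = partition_mcbs(beta_train, ann, params)
        write_mcb_bed(sorted(mcbs, key=lambda m: (m.chrom, m.start)), out / "mcbs.bed")
        if not mcbs:
            raise RuntimeError("no MCBs discovered")

        stage = "select"
        means_train = mcb_mean_matrix(beta_train, mcbs)
        selected = select_mcbs_l1(
            means_train,
            surv_train,
            mcbs,
            lambda_threshold=config.selection.lambda_threshold,
            min_cpgs=config.selection.min_cpgs,
        )
        by_id = {m.mcb_id: m for m in mcbs}

        stage = "train"
        spec = StackingSpec(target_mode=config.stack.target_mode, nonneg=config.stack.nonneg)
        model_tags = list(config.train.models)
        auc_rows, ci_rows = {}, {}
        scores_by_mcb: dict[int, dict[str, dict[str, pd.Series]]] = {}
        for mid in selected:
            m = by_id[mid]
            bb_train = beta_train.values.loc[m.probes]
            try:
                oof: dict[str, RiskScoreVector] = {}
                full_models = {}
                for tag in model_tags:
                    fitter = _FITTERS[tag](config)
                    oof[tag] = cv_risk_scores(
                        fitter, bb_train, surv_train, k=config.train.k, seed=config.seed
                    )
                    full_models[tag] = fitter(bb_train, surv_train)
                ens_oof = ensemble_cv_scores(oof, surv_train, spec=spec)
                base_oof_df = pd.DataFrame({t: oof[t].scores for t in model_tags})
                stack_model = fit_fwls(
                    base_oof_df, stacking_target(surv_train, spec), spec=spec
                )
            except FitError as exc:
                logger.warning("block %d excluded from ranking: %s", mid, exc)
                continue

            per_split: dict[str, dict[str, pd.Series]] = {}
            for split_name, ids in splits.items():
                if not ids:
                    continue
                if split_name == "training":
                    split_scores = {t: oof[t].scores for t in model_tags}
                    split_scores["ensemble"] = ens_oof.scores
                else:
                    bb = beta.values.loc[m.probes, ids]
                    split_scores = {t: full_models[t].predict(bb) for t in model_tags}
                    base_df = pd.DataFrame({t: split_scores[t] for t in model_tags})
                    split_scores["ensemble"] = predict_fwls(stack_model, base_df).scores
                per_split[split_name] = split_scores
            scores_by_mcb[mid] = per_split

            arow, crow = {}, {}
            for split_name, split_scores in per_split.items():
                sv = surv.subset(splits[split_name])
                for tag, sc in split_scores.items():
                    arow[f"{tag}_{split_name}"] = time_dependent_auc(
                        sc, sv, config.evaluation.horizon_days
                    )
                    crow[f"{tag}_{split_name}"] = concordance_index(sc, sv)
            auc_rows[mid] = arow
            ci_rows[mid] = crow

        stage = "evaluate"
        auc_df = pd.DataFrame.from_dict(auc_rows, orient="index").sort_index()
        ci_df = pd.DataFrame.from_dict(ci_rows, orient="index").sort_index()
        rank_splits = ["training"] + (["validation"] if val_ids else [])
        rank_cols = [
            f"{tag}_{sp}" for sp in rank_splits for tag in model_tags + ["ensemble"]
        ]
        rank_cols = [c for c in rank_cols if c in auc_df.columns]
        if len(auc_df) and rank_cols:
            rp = rank_product(auc_df[rank_cols])
        else:
            rp = pd.Series(dtype=float, name="rank_product")

        top_mcb_id = int(rp.idxmin()) if len(rp) else None
        km_info: dict = {}
        multi_info = None
        if top_mcb_id is not None:
            train_scores = scores_by_mcb[top_mcb_id]["training"]["ensemble"]
            cutoff = float(train_scores.median())
            eval_split = "testing" if test_ids else "training"
            sc = scores_by_mcb[top_mcb_id][eval_split]["ensemble"]
            sv = surv.subset(splits[eval_split])
            try:
                km = km_logrank(sc, sv, cutoff)
                km_info = {
                    "split": eval_split,
                    "cutoff": cutoff,
                    "logrank_statistic": km.statistic,
                    "p_value": km.p_value,
                }
            except ValueError as exc:
                km_info = {"split": eval_split, "cutoff": cutoff, "error": str(exc)}
            if not surv_train.covariates.empty:
                res = multivariate_adjustment(train_scores, surv_train, cutoff=cutoff)
                if not res.flagged and res.table is not None:
                    multi_info = {
                        k: {c: _j(v) for c, v in row.items()}
                        for k, row in res.table.to_dict(orient="index").items()
                    }
                else:
                    multi_info = {"flagged": res.message}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report = EvalReport(
        auc=auc_df,
        cindex=ci_df,
        rp=rp,
        selected_mcb_ids=list(selected),
        top_mcb_id=top_mcb_id,
        km=km_info,
        multivariate=multi_info,
        n_mcbs_discovered=len(mcbs),
    )
    payload = {
        "config_hash": config_hash(config),
        "report": report.to_json_dict(),
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    auc_df.to_csv(out / "auc.tsv", sep="\t", na_rep="NA", index_label="mcb_id", lineterminator="\n")
    ci_df.to_csv(out / "cindex.tsv", sep="\t", na_rep="NA", index_label="mcb_id", lineterminator="\n")
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "config": _config_dict(config),
                "config_hash": config_hash(config),
                "package_version": __version__,
                "seed": config.seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return report
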