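"""End-to-end pipeline: screening -> sampling -> NMF -> redundancy -> LSSVM.

A single master seed derives per-stage seeds by fixed offsets so stages are
independently re-runnable; every artifact carries the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset as ds_io
from . import lssvm, nmf, redundancy, sampling, screening, synthetic
from .dataset import ClinicalDataset
from .exceptions import ConfigError, NMFSelectError

log = logging.getLogger("nmfselect")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "subset_to_dict", "subset_from_dict"]

# per-stage seed offsets from the master seed
_SEED_NMF = 1
_SEED_SUBSET = 2
_SEED_CV = 3


@dataclass
class PipelineConfig:
    input_path: str | None = None  # None -> generate the preset synthetic dataset
    outdir: str | None = None
    delimiter: str | None = None
    orientation: str = "samples"
    # screening
    threshold: float = 0.10
    stratify: str = "auto"
    # representative sampling
    per_class: int = 40
    balance: str | None = "sex"
    ratio: dict = field(default_factory=lambda: {0: 20, 1: 20})
    # NMF / rank selection
    rank_range: tuple[int, int] = (2, 7)
    fixed_rank: int | None = None
    n_runs: int = 30
    max_iter: int = 2000
    tol: float = 1e-6
    c: float = 0.0
    alpha: float = 0.0
    lambda_w: float = 0.0
    lambda_h: float = 0.0
    # redundancy
    theta: float = 0.95
    rule: str = "dual"
    same_basis: bool = True
    strategy: str = "mean"
    # validation
    grid: str = "default"  # "default" (24 x 25) or "coarse" (5 x 5)
    folds: int = 5
    evaluate_full_set: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def grid_values(self) -> tuple[np.ndarray, np.ndarray]:
        if self.grid == "default":
            return lssvm.default_grid()
        if self.grid == "coarse":
            return np.linspace(-1.0, 4.0, 5), np.linspace(-1.0, 4.0, 5)
        raise ConfigError(f"unknown grid preset {self.grid!r}")


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: ClinicalDataset
    constant_removed: list[str]
    frequency_table: screening.FrequencyTable
    irrelevant: list[str]
    screened: ClinicalDataset
    representative: sampling.RepresentativeSelection
    survey: nmf.RankSurvey | None
    rank: int
    factorization: nmf.NMFFactorization
    basis_of: np.ndarray
    sims: redundancy.SimilarityMatrices
    groups: redundancy.RedundancyGroups
    subset: redundancy.FeatureSubset
    evaluation: lssvm.SubsetEvaluation
    full_evaluation: lssvm.SubsetEvaluation | None
    report: dict


def _stage(name: str, t0: float, **shapes) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.monotonic() - t0,
             " ".join(f"{k}={v}" for k, v in shapes.items()))


def subset_to_dict(subset: redundancy.FeatureSubset) -> dict:
    return {
        "kept_ids": subset.kept_ids,
        "strategy": subset.strategy,
        "representative_choice": subset.representative_choice,
        "groups": [
            {
                "mixed_id": g.mixed_id,
                "basis": g.basis,
                "members": g.members,
                "mean_sim_dist": g.mean_sim_dist,
                "mean_sim_corr": g.mean_sim_corr,
            }
            for g in subset.groups
        ],
    }


def subset_from_dict(payload: dict, ds: ClinicalDataset) -> redundancy.FeatureSubset:
    groups = redundancy.RedundancyGroups(
        groups=[
            redundancy.RedundantGroup(
                members=g["members"],
                basis=g["basis"],
                mean_sim_dist=g["mean_sim_dist"],
                mean_sim_corr=g["mean_sim_corr"],
                mixed_id=g["mixed_id"],
            )
            for g in payload["groups"]
        ]
    )
    sub = redundancy.assemble_subset(ds, groups, strategy=payload["strategy"])
    sub.representative_choice = dict(payload.get("representative_choice", {}))
    return sub


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t")


def _write_json(payload: dict, path: Path, cfg_hash: str) -> None:
    payload = {"config_hash": cfg_hash, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(
    cfg: PipelineConfig, dataset: ClinicalDataset | None = None
) -> PipelineResult:
    """Run every stage and return the collected artifacts.

    ``dataset`` overrides ``cfg.input_path``; with neither given the preset
    synthetic dataset is generated from the master seed.  When
    ``cfg.outdir`` is set, every intermediate table is written there (TSV /
    JSON) tagged with the config hash.
    """
    t0 = time.monotonic()
    cfg_hash = cfg.config_hash()
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    try:
        # ---- load ---------------------------------------------------------
        if dataset is not None:
            ds = dataset
        elif cfg.input_path:
            ds = ds_io.read_dataset(
                cfg.input_path, delimiter=cfg.delimiter, orientation=cfg.orientation
            )
        else:
            ds, _ = synthetic.generate(synthetic.paper_shape_preset(seed=cfg.seed))
        _stage("load", t0, samples=ds.n_samples, symptoms=ds.n_symptoms)

        ds, constant_removed = ds_io.drop_constant_features(ds)
        if ds.stage is None:
            ds = ds_io.relabel_substages(ds)

        # ---- stage 1: irrelevance screening -------------------------------
        ft = screening.positive_frequencies(ds, stratify_by=cfg.stratify)
        irrelevant = screening.find_irrelevant(ft, cfg.threshold)
        screened = screening.remove_features(ds, irrelevant)
        _stage("screen", t0, flagged=len(irrelevant), remaining=screened.n_symptoms)

        # ---- representative sampling --------------------------------------
        rep = sampling.select_representatives(
            screened,
            per_class=cfg.per_class,
            balance=cfg.balance,
            ratio=cfg.ratio if cfg.balance else None,
        )
        d_r = rep.subset
        X = d_r.values.T.astype(float)  # features x samples
        _stage("sample", t0, representative=d_r.n_samples)

        # ---- rank selection & factorization -------------------------------
        base_cfg = nmf.NMFConfig(
            rank=max(2, cfg.fixed_rank or cfg.rank_range[0]),
            c=cfg.c,
            alpha=cfg.alpha,
            lambda_w=cfg.lambda_w,
            lambda_h=cfg.lambda_h,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            seed=cfg.seed + _SEED_NMF,
        )
        survey = None
        if cfg.fixed_rank is not None:
            rank = cfg.fixed_rank
        else:
            survey = nmf.select_rank(
                X, cfg.rank_range, base_cfg, n_runs=cfg.n_runs, seed=cfg.seed + _SEED_NMF
            )
            rank = survey.selected_rank or survey.ranks[0]
        best = None
        best_obj = np.inf
        for k in range(max(1, cfg.n_runs)):
            run_cfg = nmf.NMFConfig(
                rank=rank, c=cfg.c, alpha=cfg.alpha, lambda_w=cfg.lambda_w,
                lambda_h=cfg.lambda_h, max_iter=cfg.max_iter, tol=cfg.tol,
                seed=nmf._spawn_seed(cfg.seed + _SEED_NMF, 70001 + k),
            )
            fac = nmf.factorize(X, run_cfg)
            obj = fac.objective_trace[-1] if fac.objective_trace else np.inf
            if obj < best_obj:
                best_obj, best = obj, fac
        basis_of = nmf.assign_feature_basis(best.W)
        _stage("nmf", t0, rank=rank, objective=f"{best_obj:.4f}")

        # ---- stage 2: redundancy ------------------------------------------
        sims = redundancy.similarity_matrices(best.W, screened.symptom_ids)
        groups = redundancy.find_redundant_groups(
            sims, basis_of, cfg.theta, rule=cfg.rule, same_basis=cfg.same_basis
        )
        subset = redundancy.assemble_subset(
            screened, groups, strategy=cfg.strategy, seed=cfg.seed + _SEED_SUBSET
        )
        _stage("redundancy", t0, groups=len(groups), features=len(subset.feature_ids))

        # ---- validation ----------------------------------------------------
        rep_ids = set(d_r.sample_ids)
        rest_idx = [i for i, s in enumerate(screened.sample_ids) if s not in rep_ids]
        test_ds = screened.select_samples(rest_idx) if rest_idx else None
        a_vals, b_vals = cfg.grid_values()
        evaluation = lssvm.evaluate_subset(
            d_r, test_ds, subset, a_vals, b_vals, folds=cfg.folds, seed=cfg.seed + _SEED_CV
        )
        full_eval = None
        if cfg.evaluate_full_set:
            full_subset = redundancy.assemble_subset(
                screened, redundancy.RedundancyGroups(), strategy=cfg.strategy
            )
            full_eval = lssvm.evaluate_subset(
                d_r, test_ds, full_subset, a_vals, b_vals,
                folds=cfg.folds, seed=cfg.seed + _SEED_CV,
            )
        _stage("validate", t0, cv=f"{evaluation.cv_mean:.3f}")
    except NMFSelectError as exc:
        raise type(exc)(f"pipeline failed: {exc}") from exc

    report = {
        "config_hash": cfg_hash,
        "n_samples": ds.n_samples,
        "n_symptoms_input": ds.n_symptoms,
        "constant_removed": constant_removed,
        "irrelevant": irrelevant,
        "n_relevant": screened.n_symptoms,
        "representative_samples": d_r.n_samples,
        "rank": int(rank),
        "rank_rule": survey.selection_rule if survey else "fixed",
        "cophenetic": survey.cophenetic if survey else None,
        "rss": survey.rss_values if survey else None,
        "groups": [
            {"mixed_id": g.mixed_id, "basis": g.basis, "members": g.members}
            for g in groups
        ],
        "n_kept": len(subset.kept_ids),
        "n_mixed": len(groups),
        "n_subset_features": len(subset.feature_ids),
        "subset_cv_accuracy": evaluation.cv_mean,
        "subset_cv_sd": evaluation.cv_sd,
        "subset_test_accuracy": evaluation.test_accuracy,
        "full_cv_accuracy": full_eval.cv_mean if full_eval else None,
        "full_test_accuracy": full_eval.test_accuracy if full_eval else None,
        "best_sigma2": evaluation.report.best_sigma2,
        "best_gamma": evaluation.report.best_gamma,
    }

    if outdir:
        _write_artifacts(
            outdir, cfg_hash, ft, irrelevant, rep, survey, best, screened, d_r,
            sims, groups, subset, evaluation, report,
        )
    return PipelineResult(
        config=cfg, dataset=ds, constant_removed=constant_removed,
        frequency_table=ft, irrelevant=irrelevant, screened=screened,
        representative=rep, survey=survey, rank=rank, factorization=best,
        basis_of=basis_of, sims=sims, groups=groups, subset=subset,
        evaluation=evaluation, full_evaluation=full_eval, report=report,
    )


def _write_artifacts(
    outdir: Path, cfg_hash: str, ft, irrelevant, rep, survey, fac, screened,
    d_r, sims, groups, subset, evaluation, report,
) -> None:
    _write_tsv(
        pd.DataFrame(ft.freq, index=ft.symptom_ids, columns=ft.strata_ids),
        outdir / "frequencies.tsv", cfg_hash,
    )
    _write_json({"irrelevant": irrelevant}, outdir / "irrelevant.json", cfg_hash)
    _write_json(
        {"selected": {str(k): v for k, v in rep.selected_ids.items()},
         "distances": rep.distances},
        outdir / "representatives.json", cfg_hash,
    )
    ds_io.write_dataset(d_r, outdir / "representative.tsv")
    if survey is not None:
        _write_tsv(
            pd.DataFrame(
                {"cophenetic": survey.cophenetic, "rss": survey.rss_values},
                index=pd.Index(survey.ranks, name="rank"),
            ),
            outdir / "rank_survey.tsv", cfg_hash,
        )
    basis_cols = [f"B{j + 1}" for j in range(fac.W.shape[1])]
    _write_tsv(
        pd.DataFrame(fac.W, index=screened.symptom_ids, columns=basis_cols),
        outdir / "W.tsv", cfg_hash,
    )
    _write_tsv(
        pd.DataFrame(fac.H, index=basis_cols, columns=d_r.sample_ids),
        outdir / "H.tsv", cfg_hash,
    )
    for name, mat in (("sim_dist", sims.sim_dist), ("sim_corr", sims.sim_corr),
                      ("smx", sims.smx)):
        _write_tsv(
            pd.DataFrame(mat, index=sims.feature_ids, columns=sims.feature_ids),
            outdir / f"{name}.tsv", cfg_hash,
        )
    _write_json(subset_to_dict(subset), outdir / "groups.json", cfg_hash)
    _write_tsv(
        pd.DataFrame(
            subset.values, index=screened.sample_ids, columns=subset.feature_ids
        ).assign(stage=screened.stage),
        outdir / "subset.tsv", cfg_hash,
    )
    _write_json(
        {
            "cv_mean": evaluation.cv_mean,
            "cv_sd": evaluation.cv_sd,
            "fold_accuracies": list(map(float, evaluation.fold_accuracies)),
            "test_accuracy": evaluation.test_accuracy,
            "best_sigma2": evaluation.report.best_sigma2,
            "best_gamma": evaluation.report.best_gamma,
        },
        outdir / "validation.json", cfg_hash,
    )
    _write_json(report, outdir / "report.json", cfg_hash)
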