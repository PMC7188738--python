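"""End-to-end study orchestration: simulate -> extract -> select -> fit -> score -> evaluate.

A run is driven by a single :class:`RunConfig` whose global seed is fanned
out to every stage by hashing the stage name, so stages draw from
independent but reproducible streams and an identical configuration
yields byte-identical artifacts (verified through the SHA-256 manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import evaluation, scoring, selection
from .cohort import CohortConfig, SyntheticPatient, cohort_table, generate_cohort, write_cohort
from .features import FeatureConfig, extract_patient_features
from .io import METADATA_COLUMNS, feature_columns, load_model, save_model, write_feature_table

logger = logging.getLogger(__name__)

CLINICAL_CANDIDATES = (
    "age",
    "enhancement",
    "grade_ordinal",
    "FDG__pet__TBRmax",
    "FDG__pet__TBRmean",
    "MET__pet__TBRmax",
    "MET__pet__TBRmean",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    icc_threshold: float = 0.8
    rho_threshold: float = 0.9
    n_folds: int = 10
    n_lambda: int = 100
    n_boot: int = 2000
    write_volumes: bool = False
    skip_extract: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_kwargs = raw.pop("cohort", {})
        for key in ("grid_shape", "voxel_spacing_mm"):
            if key in cohort_kwargs:
                cohort_kwargs[key] = tuple(cohort_kwargs[key])
        feature_kwargs = raw.pop("features", {})
        for key in ("offsets", "angles"):
            if key in feature_kwargs:
                feature_kwargs[key] = tuple(feature_kwargs[key])
        return cls(
            cohort=CohortConfig(**cohort_kwargs),
            features=FeatureConfig(**feature_kwargs),
            **raw,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def extract_cohort_features(
    patients: list[SyntheticPatient],
    rater: int,
    config: FeatureConfig,
) -> pd.DataFrame:
    """Feature table (metadata + full catalogue) for one rater's masks."""
    rows = {}
    for p in patients:
        mask = p.lesion_mask_rater1 if rater == 1 else p.lesion_mask_rater2
        rows[p.patient_id] = extract_patient_features(
            p.volumes, mask, p.background_mask, config
        )
    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "id"
    meta = cohort_table(patients)
    return meta.join(features)


def _select_and_fit(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    config: RunConfig,
    log: dict,
) -> dict:
    """ICC filter, redundancy pruning, standardization, and two LASSO fits."""
    cols = feature_columns(table1)
    log["n_features_extracted"] = len(cols)

    # drop features undefined for any patient (e.g. empty GLCM offsets)
    bad = [
        c
        for c in cols
        if table1[c].isna().any() or table2[c].isna().any()
    ]
    if bad:
        logger.info("dropping %d feature(s) undefined for some patient", len(bad))
    cols = [c for c in cols if c not in bad]

    icc = selection.icc_estimate(
        table1[cols], table2[cols], threshold=config.icc_threshold
    )
    cols = icc.retained_features
    log["n_features_after_icc"] = len(cols)

    primary1 = table1[table1["cohort"] == "primary"]
    prune = selection.spearman_prune(
        primary1[cols],
        r_threshold=config.rho_threshold,
        seed=stage_seed(config.seed, "prune"),
    )
    cols = prune.retained
    log["n_features_after_prune"] = len(cols)

    texture_cols = [c for c in cols if "__pet__" not in c]
    clinical = _clinical_frame(table1)
    candidates = {
        "radiomics": texture_cols,
        "integrated": texture_cols + [c for c in CLINICAL_CANDIDATES if c in clinical],
    }

    full = table1.join(clinical[[c for c in clinical.columns if c not in table1.columns]])
    primary = full[full["cohort"] == "primary"]
    validation = full[full["cohort"] == "validation"]
    y_primary = primary["label"].to_numpy(int)

    fits, models, stats_all = {}, {}, {}
    for name, cand in candidates.items():
        # a column constant on the primary cohort cannot be standardized
        cand = [c for c in cand if primary[c].std(ddof=0) > 0]
        x_primary, stats = selection.standardize(primary[cand])
        fit = selection.fit_lasso_logistic(
            x_primary,
            y_primary,
            n_folds=config.n_folds,
            seed=stage_seed(config.seed, f"cv-{name}"),
            n_lambda=config.n_lambda,
        )
        model = scoring.build_model(fit, stats, name=name)
        fits[name], models[name], stats_all[name] = fit, model, stats
        log[f"n_selected_{name}"] = int(np.count_nonzero(fit.coef))
    return {
        "icc": icc,
        "prune": prune,
        "fits": fits,
        "models": models,
        "primary": primary,
        "validation": validation,
    }


def _clinical_frame(table: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=table.index)
    out["age"] = table["age"].astype(float)
    out["enhancement"] = table["enhancement"].astype(float)
    out["grade_ordinal"] = table["who_grade"].map({"II": 2.0, "III": 3.0, "IV": 4.0})
    return out


def run_study(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the artifact manifest."""
    outdir = Path(config.outdir)
    for sub in ("cohort", "features", "selection", "models", "evaluation"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    log: dict = {"seed": config.seed}
    stage = "cohort"
    try:
        cohort_cfg = replace(config.cohort, seed=stage_seed(config.seed, "cohort"))
        patients = generate_cohort(cohort_cfg)
        cohort_table(patients).to_csv(outdir / "cohort" / "covariates.csv")
        artifacts["cohort/covariates.csv"] = ""
        if config.write_volumes:
            write_cohort(patients, outdir / "cohort" / "images")

        stage = "extract"
        f1_path = outdir / "features" / "features_rater1.csv"
        f2_path = outdir / "features" / "features_rater2.csv"
        if config.skip_extract and f1_path.exists() and f2_path.exists():
            from .io import read_feature_table

            table1 = read_feature_table(f1_path, require_label=True)
            table2 = read_feature_table(f2_path, require_label=True)
        else:
            table1 = extract_cohort_features(patients, 1, config.features)
            table2 = extract_cohort_features(patients, 2, config.features)
            table1.to_csv(f1_path)
            table2.to_csv(f2_path)
        artifacts["features/features_rater1.csv"] = ""
        artifacts["features/features_rater2.csv"] = ""

        stage = "select"
        sel = _select_and_fit(table1, table2, config, log)
        selection_record = {
            "icc_threshold": config.icc_threshold,
            "rho_threshold": config.rho_threshold,
            "icc": {k: (None if not np.isfinite(v) else round(float(v), 6))
                    for k, v in sel["icc"].icc.items()},
            "retained": sel["prune"].retained,
            "dropped_pairs": [
                [a, b, None if not np.isfinite(r) else round(float(r), 6)]
                for a, b, r in sel["prune"].dropped
            ],
            "prune_seed": sel["prune"].seed,
            "lambda_grid": {
                name: [float(v) for v in fit.lambda_grid]
                for name, fit in sel["fits"].items()
            },
            "cv_curve": {
                name: [float(v) for v in fit.cv_curve]
                for name, fit in sel["fits"].items()
            },
            "chosen_lambda": {
                name: fit.chosen_lambda for name, fit in sel["fits"].items()
            },
            "counts": {k: v for k, v in log.items() if k.startswith("n_")},
        }
        (outdir / "selection" / "selection.json").write_text(
            json.dumps(selection_record, indent=1)
        )
        artifacts["selection/selection.json"] = ""

        stage = "fit"
        for name, model in sel["models"].items():
            save_model(model, outdir / "models" / f"{name}.json")
            artifacts[f"models/{name}.json"] = ""

        stage = "score"
        scores = pd.DataFrame(index=pd.Index(
            list(sel["primary"].index) + list(sel["validation"].index), name="id"))
        both = pd.concat([sel["primary"], sel["validation"]])
        scores["cohort"] = both["cohort"]
        scores["label"] = both["label"].astype(int)
        for name, model in sel["models"].items():
            raw = model.evaluate_table(both)
            scores[f"{name}_score"] = raw
            scores[f"{name}_probability"] = expit(raw.to_numpy())
        scores.to_csv(outdir / "evaluation" / "scores.csv")
        artifacts["evaluation/scores.csv"] = ""

        stage = "evaluate"
        reports = []
        eval_seed = stage_seed(config.seed, "evaluate")
        for name in sel["models"]:
            for cohort_name in ("primary", "validation"):
                sub = scores[scores["cohort"] == cohort_name]
                reports.append(
                    evaluation.evaluate_scores(
                        sub[f"{name}_probability"],
                        sub["label"],
                        model=name,
                        cohort=cohort_name,
                        n_boot=config.n_boot,
                        seed=eval_seed,
                    )
                )
        (outdir / "evaluation" / "evaluation.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=1)
        )
        artifacts["evaluation/evaluation.json"] = ""

        stage = "dca"
        val = scores[scores["cohort"] == "validation"]
        dca = evaluation.decision_curve(
            val["integrated_probability"], val["label"]
        )
        dca.to_frame().to_csv(outdir / "evaluation" / "dca.csv", index=False)
        artifacts["evaluation/dca.csv"] = ""
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "counts": {k: v for k, v in log.items() if k.startswith("n_")},
        "artifacts": {
            rel: _sha256(outdir / rel) for rel in sorted(artifacts)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(outdir: str | Path) -> str:
    """Human-readable summary rendered purely from a run's artifact files."""
    outdir = Path(outdir)
    required = {
        "covariates": outdir / "cohort" / "covariates.csv",
        "evaluation": outdir / "evaluation" / "evaluation.json",
        "dca": outdir / "evaluation" / "dca.csv",
    }
    for name, path in required.items():
        if not path.exists():
            raise FileNotFoundError(f"missing artifact '{name}' at {path}")
    cov = pd.read_csv(required["covariates"], index_col=0)
    lines = ["Cohort summary", "=============="]
    for cohort_name, sub in cov.groupby("cohort"):
        n_rec = int(sub["label"].sum())
        lines.append(
            f"{cohort_name}: n={len(sub)} (recurrence {n_rec}, necrosis "
            f"{len(sub) - n_rec}; recurrence rate {100 * n_rec / len(sub):.1f}%), "
            f"age {sub['age'].mean():.1f} +/- {sub['age'].std():.1f} y"
        )
    reports = json.loads(required["evaluation"].read_text())
    lines += ["", "Model performance", "================="]
    frame = pd.DataFrame(reports)
    for _, row in frame.sort_values(["cohort", "AUC"], ascending=[True, False]).iterrows():
        lines.append(
            f"{row['model']:<12} {row['cohort']:<11} AUC {row['AUC']:.3f} "
            f"(95% CI {row['CI95_low']:.3f}-{row['CI95_high']:.3f}) "
            f"acc {row['Accuracy']:.3f} sens {row['Sensitivity']:.3f} "
            f"spec {row['Specificity']:.3f} thr {row['Threshold']:.3f}"
        )
    dca = pd.read_csv(required["dca"])
    useful = dca[
        (dca["net_benefit_model"] > dca["net_benefit_all"])
        & (dca["net_benefit_model"] > dca["net_benefit_none"])
    ]
    lines += ["", "Decision-curve analysis", "======================="]
    if len(useful):
        lines.append(
            "integrated model beats treat-all and treat-none for threshold "
            f"probabilities {useful['threshold'].min():.2f}-{useful['threshold'].max():.2f}"
        )
    else:
        lines.append("integrated model never beats both default strategies")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def permutation_null_auc(
    x_primary: pd.DataFrame,
    y_primary: np.ndarray,
    x_validation: pd.DataFrame,
    y_validation: np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
    n_lambda: int = 30,
    n_folds: int = 5,
    tol: float = 1e-5,
    lambda_min_ratio: float = 1e-2,
) -> np.ndarray:
    """Validation AUCs of models fitted to label-permuted primary cohorts.

    For each permutation the primary labels are shuffled, the penalized
    path is refitted with cross-validated lambda, and the resulting model
    is scored against the *true* validation labels; an uninformative
    pipeline must center this distribution at 0.5.  The null fits only
    feed an AUC, so the default solver tolerance is looser than for
    reported study models.
    """
    rng = np.random.default_rng(seed)
    x_p, stats = selection.standardize(x_primary)
    x_v, _ = selection.standardize(x_validation, stats=stats)
    aucs = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y_primary)
        fit = selection.fit_lasso_logistic(
            x_p, y_perm, n_folds=n_folds, n_lambda=n_lambda,
            seed=int(rng.integers(2**31)), tol=tol,
            lambda_min_ratio=lambda_min_ratio,
        )
        scores_v = fit.intercept + x_v.to_numpy() @ fit.coef
        if np.allclose(scores_v, scores_v[0]):
            aucs[b] = 0.5
        else:
            aucs[b] = evaluation.roc_auc(scores_v, y_validation)
    return aucs
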