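"""Config-driven orchestration: simulate → construct/score → predict →
evaluate → report, with seeds, per-stage logging and a run manifest.

Exactly one score source is active per experiment: either the
construction block (GWAS → meta-analysis → clumping/LASSO → model
selection on a held-out split) or an external scoring file. Children are
split train / model-selection / test; all reported metrics come from the
test split only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .construct import (
    ClumpParams,
    candidate_model,
    ivw_meta_analysis,
    lasso_fit_path,
    ld_clump_threshold,
    marginal_gwas,
    select_model,
)
from .containers import GenotypeMatrix, TrioCohort
from .errors import ConfigurationError
from .metrics import ShortStatureRule, build_report, write_report
from .predictors import component_table, fit_kr_table, predict_all
from .scoring import (
    calibrate_to_cm,
    compute_scores,
    harmonize_variants,
    read_scoring_file,
    standardize_scores,
    write_scoring_file,
)
from .simulate import SimulationParams, simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = (
    "mph", "adapted_mph", "mother", "father", "prs", "oracle",
    "prs+mph", "prs+mother", "prs+father",
)
DEFAULT_NESTED_PAIRS = [("mph", "mph+prs"), ("prs", "prs+mph"),
                        ("mother", "mother+prs"), ("father", "father+prs")]


@dataclass(frozen=True)
class ConstructionConfig:
    r2_threshold: float = 0.1
    window: int = 250
    p_thresholds: tuple = (5e-8, 1e-5, 1e-3, 1e-2, 1.0)
    n_lambda: int = 8
    lambda_min_ratio: float = 0.01
    meta_split: bool = True  # split training in two and IVW-meta-analyze

    def clump_params(self) -> ClumpParams:
        return ClumpParams(
            r2_threshold=self.r2_threshold,
            window=self.window,
            p_thresholds=tuple(self.p_thresholds),
        )


@dataclass(frozen=True)
class EvaluationConfig:
    sd_multiplier: float = 2.0
    bootstrap_B: int = 500
    seed: int = 0
    or_includes_sex: bool = True

    def rule(self) -> ShortStatureRule:
        return ShortStatureRule(sd_multiplier=self.sd_multiplier)


@dataclass
class ExperimentConfig:
    """Single-document experiment description (YAML-serializable)."""

    simulation: SimulationParams = field(default_factory=SimulationParams)
    construction: ConstructionConfig | None = field(default_factory=ConstructionConfig)
    scoring_file: str | None = None
    predictors: tuple = DEFAULT_PREDICTORS
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    # train / model-selection / test fractions for the child cohort,
    # the study's 80 : 1.5 : 18.5 proportions
    split_fractions: tuple = (0.80, 0.015, 0.185)
    kr_min_per_age: int = 50

    def __post_init__(self) -> None:
        if (self.construction is None) == (self.scoring_file is None):
            raise ConfigurationError(
                "exactly one of the construction block and scoring_file must be set"
            )
        if abs(sum(self.split_fractions) - 1.0) > 1e-6:
            raise ConfigurationError("split fractions must sum to 1")

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            for k in ("allele_freq_range", "growth_ages"):
                if k in sim and sim[k] is not None:
                    sim[k] = tuple(sim[k])
            d["simulation"] = SimulationParams(**sim)
        if d.get("construction") is not None and isinstance(d["construction"], dict):
            c = dict(d["construction"])
            if "p_thresholds" in c:
                c["p_thresholds"] = tuple(c["p_thresholds"])
            d["construction"] = ConstructionConfig(**c)
        if "evaluation" in d and isinstance(d["evaluation"], dict):
            d["evaluation"] = EvaluationConfig(**d["evaluation"])
        for k in ("predictors", "split_fractions"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def split_children(
    child_ids, fractions, seed: int
) -> dict[str, np.ndarray]:
    """Deterministic random train/selection/test split of child ids."""
    ids = np.asarray(child_ids, dtype=object)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fractions[0] * len(ids)))
    n_sel = int(round(fractions[1] * len(ids)))
    return {
        "train": ids[perm[:n_train]],
        "selection": ids[perm[n_train : n_train + n_sel]],
        "test": ids[perm[n_train + n_sel :]],
    }


def build_score(
    genotypes: GenotypeMatrix,
    cohort: TrioCohort,
    train_ids,
    selection_ids,
    cfg: ConstructionConfig,
    seed: int = 0,
):
    """The construction arm: association → meta → clump/LASSO → selection.

    Returns (selected PRSModel, leaderboard DataFrame).
    """
    fam = cohort.families.set_index("child_id")
    train_ids = np.asarray(train_ids, dtype=object)
    g_train = genotypes.subset_samples(train_ids)
    y_train = fam.loc[train_ids, "adult_height_cm"].to_numpy(dtype=float)
    sex_train = fam.loc[train_ids, "sex"].to_numpy()

    if cfg.meta_split and len(train_ids) >= 200:
        half = len(train_ids) // 2
        s1 = marginal_gwas(
            g_train.subset_samples(train_ids[:half]), y_train[:half], sex_train[:half]
        )
        s2 = marginal_gwas(
            g_train.subset_samples(train_ids[half:]), y_train[half:], sex_train[half:]
        )
        stats_df = ivw_meta_analysis(s1, s2)
    else:
        stats_df = marginal_gwas(g_train, y_train, sex_train)

    candidates = []
    clumped = ld_clump_threshold(stats_df, g_train, cfg.clump_params())
    for thr, weights in clumped.items():
        if len(weights):
            candidates.append(candidate_model(weights, name=f"ct_p{thr:g}"))

    X = g_train.dosage_float()
    mu = np.nanmean(X, axis=0)
    r, c = np.where(np.isnan(X))
    X[r, c] = mu[c]
    sex_num = (sex_train == "M").astype(float)
    resid = y_train - y_train.mean()
    Xs = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
    lam_max = float(np.max(np.abs(Xs.T @ resid)) / len(y_train))
    grid = lam_max * np.logspace(0, np.log10(cfg.lambda_min_ratio), cfg.n_lambda)
    path = lasso_fit_path(X, y_train, sex_num, grid)
    for li in range(len(grid)):
        nz = np.flatnonzero(path.coefs[li])
        if len(nz) == 0:
            continue
        w = stats_df.set_index("id").loc[g_train.variant_ids[nz]]
        table = pd.DataFrame(
            {
                "id": g_train.variant_ids[nz],
                "chrom": w["chrom"].to_numpy(),
                "pos": w["pos"].to_numpy(),
                "effect_allele": w["effect_allele"].to_numpy(),
                "other_allele": w["other_allele"].to_numpy(),
                "beta": path.coefs[li][nz],
            }
        )
        candidates.append(candidate_model(table, name=f"lasso_lam{grid[li]:.4g}"))

    sel_ids = np.asarray(selection_ids, dtype=object)
    winner, board = select_model(
        candidates,
        genotypes,
        sel_ids,
        fam.loc[sel_ids, "adult_height_cm"].to_numpy(dtype=float),
        fam.loc[sel_ids, "sex"].to_numpy(),
    )
    logger.info("selected score %s (%d variants)", winner.name, winner.n_variants)
    return winner, board


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seeds: dict
    stage_seconds: dict
    artifact_digests: dict

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(config: ExperimentConfig, outdir: str) -> RunManifest:
    """Execute every stage of an experiment and write all artifacts."""
    from . import __version__

    import os

    os.makedirs(outdir, exist_ok=True)
    timings: dict[str, float] = {}
    paths: dict[str, str] = {}

    t0 = time.perf_counter()
    cohort, genotypes = simulate_cohort(config.simulation)
    timings["simulate"] = time.perf_counter() - t0
    paths.update(hio.write_cohort(cohort, genotypes, outdir, genotype_format="tsv"))

    fam = cohort.families
    splits = split_children(
        fam["child_id"].to_numpy(), config.split_fractions, config.simulation.seed + 1
    )
    pd.DataFrame(
        [(cid, name) for name, ids in splits.items() for cid in ids],
        columns=["child_id", "split"],
    ).to_csv(os.path.join(outdir, "splits.tsv"), sep="\t", index=False)
    paths["splits"] = os.path.join(outdir, "splits.tsv")

    t0 = time.perf_counter()
    if config.construction is not None:
        model, board = build_score(
            genotypes, cohort, splits["train"], splits["selection"],
            config.construction, seed=config.simulation.seed,
        )
        board.to_csv(os.path.join(outdir, "model_selection.tsv"), sep="\t", index=False)
        paths["model_selection"] = os.path.join(outdir, "model_selection.tsv")
    else:
        model = read_scoring_file(config.scoring_file)
    paths["scoring_file"] = os.path.join(outdir, "score.txt")
    write_scoring_file(model, paths["scoring_file"])
    timings["construct"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    child_panel = genotypes.subset_samples(fam["child_id"].to_numpy())
    harmonized, report = harmonize_variants(model, child_panel)
    logger.info(
        "harmonization: kept=%d flipped=%d discarded=%d",
        report.kept, report.flipped, report.discarded,
    )
    scores = standardize_scores(compute_scores(harmonized, child_panel))
    scores.to_frame().to_csv(os.path.join(outdir, "scores.tsv"), sep="\t", index=False)
    paths["scores"] = os.path.join(outdir, "scores.tsv")
    fam_ix = fam.set_index("child_id")
    train = splits["train"]
    calib = calibrate_to_cm(
        pd.Series(scores.std, index=scores.sample_ids).loc[train].to_numpy(),
        fam_ix.loc[train, "adult_height_cm"].to_numpy(),
        fam_ix.loc[train, "sex"].to_numpy(),
        training_ids=train,
        evaluation_ids=set(splits["test"]),
    )
    timings["score"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comp = component_table(cohort, scores=scores, calibration=calib)
    test_mask = comp.index.isin(set(splits["test"]))
    test_cohort = TrioCohort(
        families=fam[fam["child_id"].isin(set(splits["test"]))],
        growth=cohort.growth[cohort.growth["child_id"].isin(set(splits["test"]))],
    )
    kr_table = None
    if any(str(p).startswith("kr_") for p in config.predictors):
        kr_table = fit_kr_table(
            cohort, comp["mph"], child_ids=splits["train"], min_per_cell=30
        )
    predictions, coverage = predict_all(
        test_cohort,
        config.predictors,
        comp,
        train_ids=splits["train"],
        kr_table=kr_table,
    )
    logger.info("predictor coverage: %s", coverage)
    predictions.to_csv(os.path.join(outdir, "predictions.tsv"), sep="\t", index=False)
    paths["predictions"] = os.path.join(outdir, "predictions.tsv")
    timings["predict"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    nested = [p for p in DEFAULT_NESTED_PAIRS
              if all(c in comp.columns for c in set("+".join(p).split("+")))]
    report_dict = build_report(
        predictions,
        test_cohort,
        rule=config.evaluation.rule(),
        nested_pairs=nested,
        components=comp[test_mask],
        B=config.evaluation.bootstrap_B,
        seed=config.evaluation.seed,
        or_includes_sex=config.evaluation.or_includes_sex,
    )
    tsv, js = write_report(report_dict, os.path.join(outdir, "evaluation"))
    report_dict["lrt"].to_csv(os.path.join(outdir, "lrt.tsv"), sep="\t", index=False)
    paths["report_tsv"], paths["report_json"] = tsv, js
    paths["lrt"] = os.path.join(outdir, "lrt.tsv")
    timings["evaluate"] = time.perf_counter() - t0

    config.to_yaml(os.path.join(outdir, "config.yaml"))
    paths["config"] = os.path.join(outdir, "config.yaml")
    manifest = RunManifest(
        config_hash=config.digest(),
        package_version=__version__,
        seeds={
            "simulation": config.simulation.seed,
            "split": config.simulation.seed + 1,
            "evaluation": config.evaluation.seed,
        },
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
        artifact_digests={k: _file_digest(v) for k, v in sorted(paths.items())},
    )
    manifest.write(os.path.join(outdir, "manifest.json"))
    return manifest


def run_age_resolved_comparison(
    cohort: TrioCohort,
    comp: pd.DataFrame,
    splits: dict[str, np.ndarray],
    min_per_age: int = 50,
) -> dict[str, pd.DataFrame]:
    """Age-resolved Khamis-Roche comparison plus the predictor table.

    For every half-year age at which both sexes retain at least
    ``min_per_age`` test-split children, computes test-set R² (with sex)
    and RMSE of the Khamis-Roche predictor with the mid-parental genetic
    component and with the polygenic (calibrated) component. Ages below
    the retention threshold are dropped with a warning.
    """
    from .metrics import adjusted_r2, rmse as rmse_fn
    from .predictors import khamis_roche_predict

    fam = cohort.families.set_index("child_id")
    kr_table = fit_kr_table(cohort, comp["mph"], child_ids=splits["train"])
    test_ids = set(splits["test"])
    growth = cohort.growth[cohort.growth["child_id"].isin(test_ids)]
    rows = []
    for age, grp in growth.groupby("age_years"):
        sub = grp.set_index("child_id").join(fam[["sex", "adult_height_cm"]])
        counts = sub["sex"].value_counts()
        if counts.get("F", 0) < min_per_age or counts.get("M", 0) < min_per_age:
            logger.warning("age %.1f dropped: <%d samples in a sex", age, min_per_age)
            continue
        for comp_name in ("mph", "prs"):
            if comp_name not in comp.columns:
                continue
            gc = comp.loc[sub.index, comp_name].to_numpy(dtype=float)
            ok = np.isfinite(gc)
            if ok.sum() < 2 * min_per_age:
                continue
            pred = khamis_roche_predict(
                sub["age_years"].to_numpy()[ok],
                sub["sex"].to_numpy()[ok],
                sub["height_cm"].to_numpy()[ok],
                sub["weight_kg"].to_numpy()[ok],
                gc[ok],
                kr_table,
            )
            y = sub["adult_height_cm"].to_numpy(dtype=float)[ok]
            sexcol = sub["sex"].to_numpy()[ok]
            from .metrics import _fit_predict

            rows.append(
                dict(
                    age=float(age),
                    genetic_component=comp_name,
                    n=int(ok.sum()),
                    adj_r2=adjusted_r2(y, _fit_predict(y, pred, sexcol), 2),
                    rmse=rmse_fn(y, pred),
                )
            )
    return {"kr_by_age": pd.DataFrame(rows)}
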