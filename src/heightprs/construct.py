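"""Desk-scale polygenic score construction.

Implements the classic score-building arms: per-variant association
(OLS adjusting for sex), fixed-effect inverse-variance meta-analysis,
greedy LD clumping with p-value thresholding, and an L1-penalized
(LASSO) path fitted by cyclic coordinate descent with soft-thresholding.
Candidate scores are then compared on a held-out model-selection split
by adjusted R² (with sex) and the winner becomes the reported score.

Summary statistics travel as a pandas DataFrame with columns
``id, chrom, pos, effect_allele, other_allele, beta, se, p, eaf, n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .errors import ConfigurationError
from .scoring import PRSModel

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "p", "eaf", "n"]


@dataclass(frozen=True)
class ClumpParams:
    """LD-clumping configuration.

    ``window`` is in variant-index units (the simulator's loci are
    unlinked and equally spaced, so index distance is the natural
    window); ``p_thresholds`` gives the candidate significance cuts.
    """

    r2_threshold: float = 0.1
    window: int = 250
    p_thresholds: tuple[float, ...] = (5e-8, 1e-5, 1e-3, 1e-2, 1.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ConfigurationError(f"r2_threshold must be in (0,1], got {self.r2_threshold}")
        if not self.p_thresholds:
            raise ConfigurationError("p_thresholds must be nonempty")
        if any(not (0.0 < p <= 1.0) for p in self.p_thresholds):
            raise ConfigurationError("p_thresholds must lie in (0,1]")
        if list(self.p_thresholds) != sorted(self.p_thresholds):
            raise ConfigurationError("p_thresholds must be sorted ascending")


def _sex_design(sex: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(sex)), (np.asarray(sex) == "M").astype(float)])


def marginal_gwas(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    sex: np.ndarray,
) -> pd.DataFrame:
    """Per-variant least-squares association of height on dosage, with sex.

    Dosage and phenotype are residualized on [1, sex]; the per-variant
    slope, its standard error and a two-sided t-based p-value follow from
    the univariate regression of the residuals (Frisch-Waugh). Variants
    with constant dosage are flagged: beta/se are NaN and p = 1.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.isnan(y).any():
        raise ConfigurationError("phenotype contains missing values")
    n = len(y)
    X = _sex_design(sex)
    # residualize phenotype and dosages on the covariates
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    ry = y - X @ coef_y
    D = genotypes.dosage_float()
    # frequency-impute sporadic missing dosages before association
    col_mean = np.nanmean(D, axis=0)
    nan_r, nan_c = np.where(np.isnan(D))
    D[nan_r, nan_c] = col_mean[nan_c]
    coef_d, *_ = np.linalg.lstsq(X, D, rcond=None)
    RD = D - X @ coef_d
    ss_d = np.sum(RD**2, axis=0)
    constant = ss_d <= 1e-12
    ss_d_safe = np.where(constant, 1.0, ss_d)
    beta = (RD.T @ ry) / ss_d_safe
    dof = n - X.shape[1] - 1
    if dof <= 0:
        raise ConfigurationError(f"too few samples (n={n}) for the association model")
    rss = np.sum(ry**2) - beta**2 * ss_d_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / ss_d_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    beta[constant] = np.nan
    se[constant] = np.nan
    p[constant] = 1.0
    if constant.any():
        logger.warning("%d constant-dosage variants flagged", int(constant.sum()))
    out = genotypes.variants[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["eaf"] = col_mean / 2.0
    out["n"] = n
    return out


def ivw_meta_analysis(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis of two studies.

    Variants are joined on id after harmonizing study b to study a's
    effect allele (matching swapped effect/other alleles flip the sign of
    beta and complement eaf). A variant present in only one study passes
    through unchanged; irreconcilable allele pairs are dropped.

    Combined effect = Σ(βᵢ/SEᵢ²)/Σ(1/SEᵢ²); combined SE = (Σ 1/SEᵢ²)^(-1/2);
    p from the normal approximation of β/SE.
    """
    a = a.copy()
    b = b.copy()
    merged = a.merge(b, on="id", how="outer", suffixes=("_a", "_b"), indicator=True)
    rows = []
    dropped = []
    for _, r in merged.iterrows():
        if r["_merge"] == "left_only":
            rows.append(_study_row(r, "_a"))
            continue
        if r["_merge"] == "right_only":
            rows.append(_study_row(r, "_b"))
            continue
        ea_a, oa_a = r["effect_allele_a"], r["other_allele_a"]
        ea_b, oa_b = r["effect_allele_b"], r["other_allele_b"]
        if (ea_b, oa_b) == (ea_a, oa_a):
            beta_b, eaf_b = r["beta_b"], r["eaf_b"]
        elif (ea_b, oa_b) == (oa_a, ea_a):
            beta_b, eaf_b = -r["beta_b"], 1.0 - r["eaf_b"]
        else:
            dropped.append(r["id"])
            continue
        if np.isnan(r["beta_a"]) or np.isnan(beta_b):
            # a flagged (constant-dosage) arm contributes nothing
            src = "_b" if np.isnan(r["beta_a"]) else "_a"
            row = _study_row(r, src)
            if src == "_b":
                row.update(effect_allele=ea_a, other_allele=oa_a, beta=beta_b, eaf=eaf_b)
            rows.append(row)
            continue
        w_a, w_b = 1.0 / r["se_a"] ** 2, 1.0 / r["se_b"] ** 2
        beta = (r["beta_a"] * w_a + beta_b * w_b) / (w_a + w_b)
        se = (w_a + w_b) ** -0.5
        z = beta / se
        rows.append(
            dict(
                id=r["id"], chrom=r["chrom_a"], pos=r["pos_a"],
                effect_allele=ea_a, other_allele=oa_a,
                beta=beta, se=se, p=float(2.0 * stats.norm.sf(abs(z))),
                eaf=(r["eaf_a"] * r["n_a"] + eaf_b * r["n_b"]) / (r["n_a"] + r["n_b"]),
                n=r["n_a"] + r["n_b"],
            )
        )
    if dropped:
        logger.warning("IVW meta-analysis dropped %d irreconcilable variants", len(dropped))
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _study_row(r, suffix: str) -> dict:
    return {c: r[f"{c}{suffix}"] for c in SUMMARY_COLUMNS if c != "id"} | {"id": r["id"]}


def ld_clump_threshold(
    stats_df: pd.DataFrame,
    genotypes: GenotypeMatrix,
    params: ClumpParams,
) -> dict[float, pd.DataFrame]:
    """Greedy LD clumping followed by p-value thresholding.

    Variants are visited in ascending p (ties broken by variant id); a
    selected index variant removes every still-unselected variant within
    ``window`` index positions whose squared dosage correlation with it
    exceeds ``r2_threshold``. Each p-threshold then keeps the clumped
    variants with p below it; weights are the input (meta-analytic)
    effects.
    """
    usable = stats_df[stats_df["beta"].notna()].copy()
    order_in_panel = {v: j for j, v in enumerate(genotypes.variant_ids)}
    usable = usable[usable["id"].isin(order_in_panel)]
    usable["panel_idx"] = usable["id"].map(order_in_panel)

    D = genotypes.dosage_float()
    col_mean = np.nanmean(D, axis=0)
    nan_r, nan_c = np.where(np.isnan(D))
    D[nan_r, nan_c] = col_mean[nan_c]
    Dc = D - D.mean(axis=0)
    norms = np.sqrt(np.sum(Dc**2, axis=0))
    norms[norms == 0] = np.inf

    visit = usable.sort_values(["p", "id"], kind="stable")
    removed: set[str] = set()
    selected: list[str] = []
    for vid, j in zip(visit["id"], visit["panel_idx"]):
        if vid in removed:
            continue
        selected.append(vid)
        lo, hi = max(0, j - params.window), min(genotypes.n_variants, j + params.window + 1)
        r = (Dc[:, lo:hi].T @ Dc[:, j]) / (norms[lo:hi] * norms[j])
        near = genotypes.variant_ids[lo:hi][r**2 > params.r2_threshold]
        removed.update(v for v in near if v != vid and v not in selected)
    clumped = usable[usable["id"].isin(selected)].sort_values("p", kind="stable")
    out: dict[float, pd.DataFrame] = {}
    for thr in params.p_thresholds:
        keep = clumped[clumped["p"] <= thr].drop(columns="panel_idx").reset_index(drop=True)
        if keep.empty:
            logger.warning("p-threshold %g leaves an empty score", thr)
        out[thr] = keep
    return out


@dataclass
class LassoPath:
    """Coefficients along a descending lambda grid (original dosage scale)."""

    lambdas: np.ndarray
    intercepts: np.ndarray          # per lambda
    covariate_coefs: np.ndarray     # per lambda, unpenalized columns
    coefs: np.ndarray               # (n_lambda, n_variants)
    validation_r2: np.ndarray | None = None

    def n_nonzero(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=1)


def lasso_fit_path(
    genotypes_or_X,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    lambda_grid,
    max_sweeps: int = 10_000,
    tol: float = 1e-6,
) -> LassoPath:
    """L1-penalized least squares along a lambda path.

    Minimizes ``(1/2n)·||y − a − Z·c − X·b||² + λ·Σ|b_j|`` by cyclic
    coordinate descent with soft-thresholding, warm-starting each lambda
    from the previous solution. The intercept and covariate columns
    ``Z`` (e.g. sex) are unpenalized; penalized predictors are
    standardized internally and coefficients reported on the original
    dosage scale. Convergence: max absolute standardized-coefficient
    change below ``tol``; exceeding ``max_sweeps`` raises, naming the
    lambda.
    """
    lambdas = np.asarray(lambda_grid, dtype=float)
    if len(lambdas) == 0 or np.any(np.diff(lambdas) > 0):
        raise ConfigurationError("lambda grid must be nonempty and descending")
    X = (
        genotypes_or_X.dosage_float()
        if isinstance(genotypes_or_X, GenotypeMatrix)
        else np.asarray(genotypes_or_X, dtype=float)
    )
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        r, c = np.where(np.isnan(X))
        X = X.copy()
        X[r, c] = col_mean[c]
    y = np.asarray(phenotype, dtype=float)
    n, p = X.shape
    Z = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    mu = X.mean(axis=0)
    sdev = X.std(axis=0)
    keep = sdev > 0  # constant columns can never enter
    sdev_safe = np.where(keep, sdev, 1.0)
    Xs = (X - mu) / sdev_safe
    Xs[:, ~keep] = 0.0

    b = np.zeros(p)
    coefs = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    cov_coefs = np.zeros((len(lambdas), Z.shape[1] - 1))
    col_sq = (Xs**2).sum(axis=0) / n
    col_sq_safe = np.where(col_sq > 0, col_sq, 1.0)
    ZtZ_inv = np.linalg.pinv(Z.T @ Z)

    for li, lam in enumerate(lambdas):
        for sweep in range(max_sweeps):
            # unpenalized block solved exactly given current b
            gamma = ZtZ_inv @ (Z.T @ (y - Xs @ b))
            r = y - Z @ gamma - Xs @ b
            max_delta = 0.0
            for j in range(p):
                if not keep[j]:
                    continue
                bj_old = b[j]
                rho = (Xs[:, j] @ r) / n + col_sq[j] * bj_old
                bj_new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq_safe[j]
                if bj_new != bj_old:
                    r -= Xs[:, j] * (bj_new - bj_old)
                    b[j] = bj_new
                    max_delta = max(max_delta, abs(bj_new - bj_old))
            if max_delta < tol:
                break
        else:
            raise ConfigurationError(
                f"coordinate descent did not converge at lambda={lam:g} "
                f"within {max_sweeps} sweeps"
            )
        gamma = ZtZ_inv @ (Z.T @ (y - Xs @ b))
        b_orig = b / sdev_safe
        b_orig[~keep] = 0.0
        coefs[li] = b_orig
        intercepts[li] = gamma[0] - float(mu @ b_orig)
        cov_coefs[li] = gamma[1:]
    return LassoPath(
        lambdas=lambdas, intercepts=intercepts, covariate_coefs=cov_coefs, coefs=coefs
    )


def candidate_model(
    weights: pd.DataFrame, name: str, genome_build: str = "simulated-1"
) -> PRSModel:
    """Wrap a weight table (summary-stat layout) as a scoring model."""
    records = weights[["id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    records["effect_weight"] = weights["beta"].to_numpy()
    return PRSModel(records=records, name=name, genome_build=genome_build)


def select_model(
    candidates: list[PRSModel],
    genotypes: GenotypeMatrix,
    selection_ids,
    heights: np.ndarray,
    sex: np.ndarray,
) -> tuple[PRSModel, pd.DataFrame]:
    """Pick the candidate with highest adjusted R² (with sex) on the
    model-selection split; ties go to the smaller model, then to the
    first by name. Returns the winner and the per-candidate leaderboard.
    """
    from .metrics import adjusted_r2
    from .scoring import compute_scores, harmonize_variants

    if not candidates:
        raise ConfigurationError("empty candidate list")
    panel = genotypes.subset_samples(selection_ids)
    y = np.asarray(heights, dtype=float)
    Z = _sex_design(sex)
    rows = []
    for cand in candidates:
        harmonized, _ = harmonize_variants(cand, panel)
        if harmonized.n_variants == 0:
            rows.append(dict(name=cand.name, n_variants=0, adj_r2=-np.inf))
            continue
        sv = compute_scores(harmonized, panel)
        Xfull = np.column_stack([Z, sv.raw])
        coef, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
        rows.append(
            dict(
                name=cand.name,
                n_variants=cand.n_variants,
                adj_r2=adjusted_r2(y, Xfull @ coef, n_predictors=Xfull.shape[1] - 1),
            )
        )
    board = pd.DataFrame(rows)
    board = board.sort_values(
        ["adj_r2", "n_variants", "name"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    winner = next(c for c in candidates if c.name == board.loc[0, "name"])
    return winner, board
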