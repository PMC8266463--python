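"""Evaluation suite: variance explained, RMSE, short-stature screening
metrics, nested-model tests and bootstrap confidence intervals.

Discrimination metrics follow the screening convention that a *lower*
predicted height means a *higher* predicted risk of adult short stature;
callers pass risk scores (e.g. negated predicted heights) explicitly.
AUROC uses the tie-aware Mann-Whitney estimator. AUPRC is average
precision with a conservative tie order (within a tied score, positives
are ranked after negatives). The odds ratio per SD *decrease* comes from
a maximum-likelihood logistic fit with a Wald interval, and nested
linear predictors are compared with the Gaussian likelihood-ratio
statistic n·ln(RSS0/RSS1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "ShortStatureRule",
    "adjusted_r2",
    "rmse",
    "label_short_stature",
    "auroc",
    "auprc",
    "or_per_sd",
    "lrt_nested",
    "bootstrap_ci",
    "build_report",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class ShortStatureRule:
    """Short stature = height below (sex mean − k·sex SD), k = 2 by default.

    Under normality the 2-SD rule labels the shortest ≈2.3% per sex.
    ``mode='quantile'`` instead labels the empirical
    ``expected_tail_fraction`` shortest per sex.
    """

    sd_multiplier: float = 2.0
    expected_tail_fraction: float = 0.0227501  # Phi(-2)
    mode: str = "sd"  # 'sd' or 'quantile'


def adjusted_r2(observed, predicted, n_predictors: int) -> float:
    """1 − (1 − R²)(n − 1)/(n − p − 1) for a p-predictor linear model."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    n = len(y)
    if n <= n_predictors + 1:
        raise ConfigurationError(f"n={n} too small for p={n_predictors} predictors")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_predictors - 1)


def rmse(observed, predicted) -> float:
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if len(y) == 0:
        raise ConfigurationError("rmse of empty input")
    if len(y) != len(yhat):
        raise ConfigurationError("length mismatch")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def label_short_stature(
    heights, sex, rule: ShortStatureRule = ShortStatureRule()
) -> np.ndarray:
    """Boolean short-stature labels computed within sex.

    The threshold derives from the evaluation cohort's own per-sex
    moments (or empirical quantile in quantile mode), not from an
    external growth reference.
    """
    h = np.asarray(heights, dtype=float)
    s = np.asarray(sex)
    labels = np.zeros(len(h), dtype=bool)
    for grp in np.unique(s):
        m = s == grp
        vals = h[m]
        if len(np.unique(vals)) < 2:
            raise ConfigurationError(f"need >= 2 distinct heights for sex {grp!r}")
        if rule.mode == "sd":
            sd = float(np.std(vals, ddof=1))
            if sd == 0.0:
                raise ConfigurationError(f"zero height SD for sex {grp!r}")
            thr = float(np.mean(vals)) - rule.sd_multiplier * sd
        elif rule.mode == "quantile":
            thr = float(np.quantile(vals, rule.expected_tail_fraction))
        else:
            raise ConfigurationError(f"unknown rule mode {rule.mode!r}")
        labels[m] = vals < thr
    return labels


def _check_binary(labels) -> np.ndarray:
    lab = np.asarray(labels).astype(bool)
    if lab.all() or (~lab).all():
        raise ConfigurationError("both classes must be present")
    return lab


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_case > score_noncase) + ½P(tie)."""
    lab = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)  # midranks handle ties
    n_pos = int(lab.sum())
    n_neg = len(lab) - n_pos
    u = ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision, conservative under score ties.

    Sum over positives (descending score; within a tied score, negatives
    ordered first so each positive sees its worst-case precision) of the
    precision at that positive's rank.
    """
    lab = np.asarray(labels).astype(bool)
    if not lab.any():
        raise ConfigurationError("at least one positive required")
    s = np.asarray(scores, dtype=float)
    # sort descending by score, negatives before positives within ties
    order = np.lexsort((lab.astype(int), -s))
    lab_sorted = lab[order]
    ranks = np.arange(1, len(lab) + 1)
    tp = np.cumsum(lab_sorted)
    precisions = tp[lab_sorted] / ranks[lab_sorted]
    return float(np.mean(precisions))


def or_per_sd(
    predictor,
    labels,
    sex=None,
    firth: bool = False,
) -> tuple[float, float, float]:
    """Odds ratio per SD *decrease* of a standardized predictor.

    Fits a maximum-likelihood logistic regression of label on predictor
    (optionally + sex) and reports exp(−β̂) with its Wald 95% CI, so a
    value above 1 means lower predictor → higher risk. Complete
    separation raises with advice to retry with ``firth=True`` (a simple
    ridge-style penalty).
    """
    import warnings

    import statsmodels.api as sm

    z = np.asarray(predictor, dtype=float)
    lab = _check_binary(labels).astype(float)
    X = np.column_stack([np.ones(len(z)), z])
    if sex is not None:
        X = np.column_stack([X, (np.asarray(sex) == "M").astype(float)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings handled below
            if firth:
                res = sm.Logit(lab, X).fit_regularized(alpha=0.5, L1_wt=0.0, disp=0)
                cov = np.linalg.inv(-sm.Logit(lab, X).hessian(res.params))
                beta, se = res.params[1], np.sqrt(cov[1, 1])
            else:
                res = sm.Logit(lab, X).fit(disp=0)
                beta, se = res.params[1], res.bse[1]
        if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ConfigurationError(
            "logistic fit failed (likely complete separation); retry with firth=True"
        ) from exc
    clip = lambda x: float(np.exp(np.clip(x, -700.0, 700.0)))
    or_dec = clip(-beta)
    lo = clip(-beta - 1.959964 * se)
    hi = clip(-beta + 1.959964 * se)
    return or_dec, min(lo, hi), max(lo, hi)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ coef) ** 2))


def lrt_nested(X_small: np.ndarray, X_large: np.ndarray, y) -> tuple[float, int, float]:
    """Gaussian likelihood-ratio test of nested linear designs.

    Requires every column of the small design to appear (up to numerical
    identity) in the large one. Statistic n·ln(RSS0/RSS1); degrees of
    freedom = added column *rank*, so duplicated columns add nothing.
    """
    y = np.asarray(y, dtype=float)
    Xs = np.atleast_2d(np.asarray(X_small, dtype=float))
    Xl = np.atleast_2d(np.asarray(X_large, dtype=float))
    if Xs.shape[0] != Xl.shape[0] or Xs.shape[0] != len(y):
        raise ConfigurationError("designs must share rows with y")
    # nesting check: each small column must be reproducible from the large design
    proj, *_ = np.linalg.lstsq(Xl, Xs, rcond=None)
    if not np.allclose(Xl @ proj, Xs, atol=1e-8 * max(1.0, np.abs(Xs).max())):
        raise ConfigurationError("small design is not nested in large design")
    df = int(np.linalg.matrix_rank(Xl) - np.linalg.matrix_rank(Xs))
    rss0, rss1 = _rss(Xs, y), _rss(Xl, y)
    n = len(y)
    statistic = float(n * np.log(max(rss0, 1e-300) / max(rss1, 1e-300)))
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p


def bootstrap_ci(
    metric_fn,
    data: tuple,
    B: int = 2000,
    seed: int = 0,
    stratify_on: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for ``metric_fn(*data)``.

    ``data`` is a tuple of equal-length arrays resampled jointly by
    case index; for classification metrics pass the labels as
    ``stratify_on`` so each replicate keeps both classes. Replicates on
    which the metric raises are skipped; more than 1% failures aborts.
    """
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(a) for a in data]
    n = len(arrays[0])
    point = float(metric_fn(*arrays))
    vals = np.empty(B)
    failures = 0
    strata = (
        [np.arange(n)]
        if stratify_on is None
        else [np.where(np.asarray(stratify_on) == g)[0] for g in np.unique(stratify_on)]
    )
    for b in range(B):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        try:
            vals[b] = metric_fn(*(a[idx] for a in arrays))
        except Exception:
            vals[b] = np.nan
            failures += 1
    if failures > 0.01 * B:
        raise ConfigurationError(
            f"metric undefined on {failures}/{B} bootstrap resamples"
        )
    ok = vals[~np.isnan(vals)]
    lo, hi = np.quantile(ok, [alpha / 2.0, 1.0 - alpha / 2.0])
    return point, float(lo), float(hi)


# -- report assembly -----------------------------------------------------

REPORT_COLUMNS = [
    "predictor", "stratum", "n", "n_cases",
    "adj_r2", "adj_r2_lo", "adj_r2_hi",
    "rmse", "rmse_lo", "rmse_hi",
    "auroc", "auroc_lo", "auroc_hi",
    "auprc", "auprc_lo", "auprc_hi",
    "or_per_sd", "or_lo", "or_hi",
]


def build_report(
    predictions: pd.DataFrame,
    cohort,
    rule: ShortStatureRule = ShortStatureRule(),
    nested_pairs: list[tuple[str, str]] | None = None,
    components: pd.DataFrame | None = None,
    B: int = 500,
    seed: int = 0,
    or_includes_sex: bool = True,
) -> dict:
    """Assemble the predictor-by-stratum comparison report.

    For each predictor and stratum (all / female / male): adjusted R²
    of observed height on the prediction (plus sex in the pooled
    stratum), RMSE, AUROC/AUPRC for short-stature screening with risk =
    −predicted height, and the odds ratio per SD decrease of the
    standardized prediction. CIs are percentile bootstrap (B replicates)
    except the Wald OR interval. Nested predictor pairs are compared by
    likelihood-ratio test on the pooled stratum using the component
    columns named in each pair.
    """
    fam = cohort.families.set_index("child_id")
    labels_all = pd.Series(
        label_short_stature(fam["adult_height_cm"], fam["sex"], rule), index=fam.index
    )
    rows = []
    for predictor, grp in predictions.groupby("predictor", sort=True):
        merged = grp.set_index("child_id").join(
            fam[["sex", "adult_height_cm"]], how="inner"
        )
        merged["case"] = labels_all.reindex(merged.index)
        for stratum in ("all", "F", "M"):
            sub = merged if stratum == "all" else merged[merged["sex"] == stratum]
            if len(sub) < 10:
                continue
            y = sub["adult_height_cm"].to_numpy(dtype=float)
            yhat = sub["predicted_height_cm"].to_numpy(dtype=float)
            lab = sub["case"].to_numpy(dtype=bool)
            sexcol = sub["sex"].to_numpy()
            p_pred = 2 if stratum == "all" else 1
            r2_pt, r2_lo, r2_hi = bootstrap_ci(
                lambda o, p, s: adjusted_r2(
                    o, _fit_predict(o, p, s if p_pred == 2 else None), p_pred
                ),
                (y, yhat, sexcol),
                B=B,
                seed=seed,
            )
            rm_pt, rm_lo, rm_hi = bootstrap_ci(rmse, (y, yhat), B=B, seed=seed + 1)
            row = dict(
                predictor=predictor, stratum=stratum, n=len(sub), n_cases=int(lab.sum()),
                adj_r2=r2_pt, adj_r2_lo=r2_lo, adj_r2_hi=r2_hi,
                rmse=rm_pt, rmse_lo=rm_lo, rmse_hi=rm_hi,
            )
            if lab.any() and not lab.all():
                risk = -yhat
                au_pt, au_lo, au_hi = bootstrap_ci(
                    auroc, (risk, lab), B=B, seed=seed + 2, stratify_on=lab
                )
                ap_pt, ap_lo, ap_hi = bootstrap_ci(
                    auprc, (risk, lab), B=B, seed=seed + 3, stratify_on=lab
                )
                z = (yhat - yhat.mean()) / yhat.std()
                or_sex = sexcol if (or_includes_sex and stratum == "all") else None
                try:
                    orr, or_lo, or_hi = or_per_sd(z, lab, sex=or_sex)
                except ConfigurationError:
                    # separation at small case counts: penalized fallback
                    orr, or_lo, or_hi = or_per_sd(z, lab, sex=or_sex, firth=True)
                row.update(
                    auroc=au_pt, auroc_lo=au_lo, auroc_hi=au_hi,
                    auprc=ap_pt, auprc_lo=ap_lo, auprc_hi=ap_hi,
                    or_per_sd=orr, or_lo=or_lo, or_hi=or_hi,
                )
            else:
                # a stratum without cases cannot support discrimination metrics
                row.update(
                    auroc=np.nan, auroc_lo=np.nan, auroc_hi=np.nan,
                    auprc=np.nan, auprc_lo=np.nan, auprc_hi=np.nan,
                    or_per_sd=np.nan, or_lo=np.nan, or_hi=np.nan,
                )
            rows.append(row)
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    lrt_rows = []
    if nested_pairs and components is not None:
        comp = components.drop(columns=["adult_height_cm"], errors="ignore").join(
            fam[["adult_height_cm"]], how="inner"
        )
        for small_set, large_set in nested_pairs:
            small = tuple(small_set.split("+"))
            large = tuple(large_set.split("+"))
            cols = sorted(set(small) | set(large))
            sub = comp.dropna(subset=cols)
            y = sub["adult_height_cm"].to_numpy(dtype=float)
            base = [np.ones(len(sub)), (sub["sex"] == "M").to_numpy(dtype=float)]
            Xs = np.column_stack(base + [sub[c].to_numpy(dtype=float) for c in small])
            Xl = np.column_stack(base + [sub[c].to_numpy(dtype=float) for c in large])
            statistic, df, p = lrt_nested(Xs, Xl, y)
            lrt_rows.append(
                dict(small=small_set, large=large_set, n=len(sub),
                     statistic=statistic, df=df, p=p)
            )
    return {"metrics": table, "lrt": pd.DataFrame(lrt_rows)}


def _fit_predict(y, yhat, sexcol):
    """Refit observed on predicted (+ sex) and return fitted values."""
    if sexcol is None:
        X = np.column_stack([np.ones(len(y)), yhat])
    else:
        X = np.column_stack([np.ones(len(y)), (np.asarray(sexcol) == "M"), yhat])
    coef, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
    return X @ coef


def write_report(report: dict, out_prefix: str) -> tuple[str, str]:
    tsv = out_prefix + "_metrics.tsv"
    js = out_prefix + "_report.json"
    report["metrics"].to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    payload = {
        "metrics": report["metrics"].to_dict(orient="records"),
        "lrt": report["lrt"].to_dict(orient="records"),
    }
    with open(js, "w") as fh:
        json.dump(payload, fh, indent=1, allow_nan=True, default=float)
    return tsv, js


def read_report(json_path: str) -> dict:
    with open(json_path) as fh:
        payload = json.load(fh)
    return {
        "metrics": pd.DataFrame(payload["metrics"], columns=REPORT_COLUMNS),
        "lrt": pd.DataFrame(payload["lrt"]),
    }
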