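"""Adult-height predictors: mid-parental formulas, combined linear
predictors, and the Khamis-Roche age-specific predictor.

The classical mid-parental (target) height is the parental mean shifted
by half the adult sex difference, ±6.5 cm. The "adapted" variant is a
sex-specific affine regression of adult height on the parental mean with
published Swedish-population constants. The Khamis-Roche predictor is a
bone-age-free linear combination of current height, current weight and a
genetic component (classically mid-parental height) with coefficients
keyed by sex and half-year age; the genetic component is pluggable, so a
calibrated polygenic-score height can stand in for mid-parental height.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TrioCohort
from .errors import ConfigurationError, FormatError
from .scoring import CalibrationModel, ScoreVector

__all__ = [
    "CONSTANTS",
    "PredictorConstants",
    "midparental_height",
    "adapted_midparental_height",
    "KRCoefficientTable",
    "load_default_kr_table",
    "khamis_roche_predict",
    "fit_kr_table",
    "FittedLinearPredictor",
    "fit_combined_predictor",
    "component_table",
    "predict_all",
    "round_half_year",
]


@dataclass(frozen=True)
class PredictorConstants:
    """Printed constants of the two mid-parental formulas (cm)."""

    mph_offset_cm: float = 6.5
    adapted_girl_slope: float = 0.75
    adapted_girl_intercept: float = 37.85
    adapted_boy_slope: float = 0.78
    adapted_boy_intercept: float = 45.99


CONSTANTS = PredictorConstants()


def _parental_mean(mother_cm, father_cm):
    m = np.asarray(mother_cm, dtype=float)
    f = np.asarray(father_cm, dtype=float)
    return (m + f) / 2.0


def midparental_height(mother_cm, father_cm, child_sex):
    """Classical mid-parental height: (m + f)/2 − 6.5 for girls, +6.5 for boys.

    Missing parental heights propagate as NaN so callers can fall back
    to single-parent or genetic predictors.
    """
    mean = _parental_mean(mother_cm, father_cm)
    sign = np.where(np.asarray(child_sex) == "F", -1.0, 1.0)
    out = mean + sign * CONSTANTS.mph_offset_cm
    return float(out) if out.ndim == 0 else out


def adapted_midparental_height(mother_cm, father_cm, child_sex):
    """Sex-specific affine mid-parental predictor (Swedish regression constants)."""
    mean = _parental_mean(mother_cm, father_cm)
    is_girl = np.asarray(child_sex) == "F"
    slope = np.where(is_girl, CONSTANTS.adapted_girl_slope, CONSTANTS.adapted_boy_slope)
    icpt = np.where(
        is_girl, CONSTANTS.adapted_girl_intercept, CONSTANTS.adapted_boy_intercept
    )
    out = slope * mean + icpt
    return float(out) if out.ndim == 0 else out


# -- Khamis-Roche --------------------------------------------------------

def round_half_year(age: float) -> float:
    """Round age to the nearest half-year; exact ties (x.25/x.75) round up."""
    return np.floor(np.asarray(age, dtype=float) * 2.0 + 0.5) / 2.0


@dataclass
class KRCoefficientTable:
    """Khamis-Roche coefficients keyed by (sex, half-year age).

    Columns: sex, age, intercept, coef_height, coef_weight,
    coef_midparent. The table must cover a complete half-year grid for
    both sexes over its age range.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["sex", "age", "intercept", "coef_height", "coef_weight", "coef_midparent"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise FormatError(f"KR coefficient table missing columns {missing}")
        num = self.table[req[2:]].to_numpy(dtype=float)
        if not np.isfinite(num).all():
            raise FormatError("KR coefficient table has non-finite entries")
        self.table = self.table.reset_index(drop=True)
        self._index = {
            (r["sex"], float(r["age"])): r for _, r in self.table.iterrows()
        }
        for sex in sorted({s for s, _ in self._index}):
            ages = sorted(a for s, a in self._index if s == sex)
            expected = np.arange(ages[0], ages[-1] + 0.25, 0.5)
            if len(ages) != len(expected) or not np.allclose(ages, expected):
                raise FormatError(f"KR table grid for sex {sex!r} has gaps")

    @property
    def ages(self) -> np.ndarray:
        return np.unique(self.table["age"].to_numpy(dtype=float))

    def row(self, sex: str, age: float) -> pd.Series:
        key = (sex, float(age))
        if key not in self._index:
            raise ConfigurationError(f"no KR coefficients for sex={sex!r}, age={age}")
        return self._index[key]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "KRCoefficientTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sex": str}, comment="#"))


def load_default_kr_table() -> KRCoefficientTable:
    """Packaged synthetic coefficient table (half-year grid, ages 8-17).

    The shipped values are synthetic placeholders fitted to this
    package's simulator, not the originally published coefficients;
    replace the data file with a transcription of the published table
    for real-data use.
    """
    ref = importlib.resources.files("heightprs.data").joinpath(
        "kr_coefficients_synthetic.tsv"
    )
    with importlib.resources.as_file(ref) as path:
        return KRCoefficientTable.from_tsv(str(path))


def khamis_roche_predict(
    age_years,
    sex,
    current_height_cm,
    current_weight_kg,
    genetic_component_cm,
    table: KRCoefficientTable,
):
    """Predicted adult height at the coefficients for (sex, rounded age).

    prediction = intercept + c_h·height + c_w·weight + c_m·genetic_component,
    with age rounded to the nearest half-year (ties up). The genetic
    component is whatever cm-scale quantity stands for inherited height
    potential — mid-parental height or a calibrated polygenic prediction.
    """
    scalar = np.isscalar(age_years) or np.asarray(age_years).ndim == 0
    age = np.atleast_1d(np.asarray(age_years, dtype=float))
    sex = np.atleast_1d(np.asarray(sex))
    h = np.atleast_1d(np.asarray(current_height_cm, dtype=float))
    w = np.atleast_1d(np.asarray(current_weight_kg, dtype=float))
    g = np.atleast_1d(np.asarray(genetic_component_cm, dtype=float))
    if np.any(age < 8.0) or np.any(age > 17.0):
        raise ConfigurationError("age outside the supported range [8, 17]")
    out = np.empty(len(age))
    for i in range(len(age)):
        r = table.row(str(sex[i]), round_half_year(age[i]))
        out[i] = (
            r["intercept"]
            + r["coef_height"] * h[i]
            + r["coef_weight"] * w[i]
            + r["coef_midparent"] * g[i]
        )
    return float(out[0]) if scalar else out


def fit_kr_table(
    cohort: TrioCohort,
    genetic_component: pd.Series,
    child_ids=None,
    min_per_cell: int = 30,
) -> KRCoefficientTable:
    """Derive a coefficient table from a training split of a cohort.

    For every (sex, half-year age) cell with enough growth records, fits
    adult height ~ current height + current weight + genetic component by
    least squares. ``genetic_component`` is indexed by child id (e.g.
    mid-parental height). Cells below ``min_per_cell`` are dropped;
    the resulting grid must remain gap-free per sex.
    """
    fam = cohort.families.set_index("child_id")
    growth = cohort.growth
    if child_ids is not None:
        growth = growth[growth["child_id"].isin(set(child_ids))]
    rows = []
    for (sex, age), grp in growth.merge(
        fam[["sex"]], left_on="child_id", right_index=True
    ).groupby(["sex", "age_years"]):
        gc = genetic_component.reindex(grp["child_id"]).to_numpy(dtype=float)
        ok = np.isfinite(gc)
        if ok.sum() < min_per_cell:
            continue
        sub = grp[ok]
        y = fam.loc[sub["child_id"], "adult_height_cm"].to_numpy(dtype=float)
        X = np.column_stack(
            [
                np.ones(len(sub)),
                sub["height_cm"].to_numpy(dtype=float),
                sub["weight_kg"].to_numpy(dtype=float),
                gc[ok],
            ]
        )
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rows.append(
            dict(
                sex=sex, age=float(age), intercept=coef[0],
                coef_height=coef[1], coef_weight=coef[2], coef_midparent=coef[3],
            )
        )
    return KRCoefficientTable(pd.DataFrame(rows))


# -- combined linear predictors -----------------------------------------

VALID_COMPONENTS = ("prs", "mph", "mother", "father", "oracle")


@dataclass
class FittedLinearPredictor:
    """Least-squares predictor over a declared component set."""

    components: tuple
    sex_included: bool
    coef: np.ndarray
    training_split: str = "train"

    def design(self, comp: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(comp))]
        if self.sex_included:
            cols.append((comp["sex"] == "M").to_numpy(dtype=float))
        for c in self.components:
            cols.append(comp[c].to_numpy(dtype=float))
        return np.column_stack(cols)

    def predict(self, comp: pd.DataFrame) -> np.ndarray:
        return self.design(comp) @ self.coef


def fit_combined_predictor(
    comp_train: pd.DataFrame,
    heights_train: np.ndarray,
    components,
    sex_included: bool = True,
    training_split: str = "train",
) -> FittedLinearPredictor:
    """Fit a linear predictor on training components.

    ``comp_train`` must carry a ``sex`` column and one column per
    requested component (see :func:`component_table`). An exactly
    collinear component set (e.g. mph together with both single parents)
    raises a rank-deficiency error.
    """
    components = tuple(components)
    for c in components:
        if c not in comp_train.columns:
            raise ConfigurationError(f"unknown component {c!r}")
    pred = FittedLinearPredictor(
        components=components, sex_included=sex_included, coef=np.zeros(0),
        training_split=training_split,
    )
    X = pred.design(comp_train)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigurationError(
            f"rank-deficient design for components {components} "
            "(exactly collinear inputs)"
        )
    y = np.asarray(heights_train, dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    pred.coef = coef
    return pred


def component_table(
    cohort: TrioCohort,
    scores: ScoreVector | None = None,
    calibration: CalibrationModel | None = None,
) -> pd.DataFrame:
    """Per-child predictor components, indexed by child id.

    Columns: sex, mother, father, mph, adapted_mph, oracle (simulation
    truth + sex mean, when available), and — when scores are given —
    prs_std plus a calibrated cm-scale prs column.
    """
    fam = cohort.families
    comp = pd.DataFrame(index=fam["child_id"])
    comp["sex"] = fam["sex"].to_numpy()
    comp["adult_height_cm"] = fam["adult_height_cm"].to_numpy(dtype=float)
    comp["mother"] = fam["mother_height_cm"].to_numpy(dtype=float)
    comp["father"] = fam["father_height_cm"].to_numpy(dtype=float)
    comp["mph"] = midparental_height(comp["mother"], comp["father"], comp["sex"])
    comp["adapted_mph"] = adapted_midparental_height(
        comp["mother"], comp["father"], comp["sex"]
    )
    if "true_genetic_value_cm" in fam.columns and fam["true_genetic_value_cm"].notna().any():
        sex_mean = fam.groupby("sex")["adult_height_cm"].transform("mean")
        comp["oracle"] = (
            fam["true_genetic_value_cm"].to_numpy(dtype=float) + sex_mean.to_numpy()
        )
    if scores is not None:
        if scores.std is None:
            raise ConfigurationError("scores must be standardized before use")
        sc = pd.Series(scores.std, index=scores.sample_ids)
        comp["prs_std"] = sc.reindex(comp.index).to_numpy()
        if calibration is not None:
            comp["prs"] = calibration.predict(
                comp["prs_std"].to_numpy(), comp["sex"].to_numpy()
            )
    return comp


SIMPLE_PREDICTORS = ("mph", "adapted_mph", "prs", "oracle")
# fitted least-squares predictors over component sets; single parental
# heights are fitted too (a parent's raw height is not on the child's
# predicted-height scale)
COMBINED_PREDICTORS = {
    "mother": ("mother",),
    "father": ("father",),
    "prs+mph": ("prs", "mph"),
    "prs+mother": ("prs", "mother"),
    "prs+father": ("prs", "father"),
    "oracle+mph": ("oracle", "mph"),
}


def predict_all(
    cohort: TrioCohort,
    predictor_names,
    comp: pd.DataFrame,
    train_ids=None,
    kr_table: KRCoefficientTable | None = None,
    kr_age: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run a list of predictors over a cohort.

    Simple predictors read straight from the component table; combined
    predictors (``prs+mph`` etc.) are fitted on ``train_ids`` and applied
    everywhere; Khamis-Roche predictors (``kr_mph``, ``kr_prs``) use the
    growth record nearest ``kr_age``. ``comp`` may cover more children
    than the cohort (e.g. the training split of a larger study);
    predictions are emitted only for the cohort's own children. Children
    missing a required input are excluded per-predictor and counted in
    the coverage map.

    Returns a long-format prediction frame (child_id, predictor,
    predicted_height_cm) and per-predictor coverage counts.
    """
    fam = cohort.families.set_index("child_id")
    frames = []
    coverage: dict[str, int] = {}
    growth_at_age = None
    if any(str(p).startswith("kr_") for p in predictor_names):
        g = cohort.growth.copy()
        g = g[np.isclose(g["age_years"], round_half_year(kr_age))]
        growth_at_age = g.set_index("child_id")
    for name in predictor_names:
        if name in SIMPLE_PREDICTORS:
            if name not in comp.columns:
                raise ConfigurationError(f"component {name!r} unavailable in this cohort")
            vals = comp[name]
        elif name in COMBINED_PREDICTORS:
            needed = COMBINED_PREDICTORS[name]
            for c in needed:
                if c not in comp.columns:
                    raise ConfigurationError(f"component {c!r} unavailable in this cohort")
            mask = comp[list(needed)].notna().all(axis=1)
            tr = comp.index.isin(set(train_ids)) if train_ids is not None else mask
            fit_mask = mask & tr
            # standard MPH already encodes sex; single components do not
            sex_inc = "mph" not in needed
            fitted = fit_combined_predictor(
                comp[fit_mask],
                comp.loc[fit_mask, "adult_height_cm"].to_numpy(dtype=float),
                needed,
                sex_included=sex_inc,
            )
            vals = pd.Series(np.nan, index=comp.index)
            vals[mask] = fitted.predict(comp[mask])
        elif name in ("kr_mph", "kr_prs"):
            if kr_table is None:
                raise ConfigurationError("Khamis-Roche predictors need a coefficient table")
            gc_col = "mph" if name == "kr_mph" else "prs"
            if gc_col not in comp.columns:
                raise ConfigurationError(f"component {gc_col!r} unavailable in this cohort")
            vals = pd.Series(np.nan, index=comp.index)
            common = comp.index.intersection(growth_at_age.index)
            sub = growth_at_age.loc[common]
            gc = comp.loc[common, gc_col].to_numpy(dtype=float)
            ok = np.isfinite(gc)
            if ok.any():
                idx = common[ok]
                vals[idx] = khamis_roche_predict(
                    sub.loc[idx, "age_years"].to_numpy(),
                    comp.loc[idx, "sex"].to_numpy(),
                    sub.loc[idx, "height_cm"].to_numpy(),
                    sub.loc[idx, "weight_kg"].to_numpy(),
                    gc[ok],
                    kr_table,
                )
        else:
            raise ConfigurationError(f"unknown predictor {name!r}")
        mask = pd.Series(vals).notna() & comp.index.isin(fam.index)
        coverage[name] = int(mask.sum())
        frames.append(
            pd.DataFrame(
                {
                    "child_id": comp.index[mask],
                    "predictor": name,
                    "predicted_height_cm": np.asarray(vals, dtype=float)[mask],
                }
            )
        )
    predictions = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["child_id", "predictor", "predicted_height_cm"]
    )
    return predictions, coverage
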