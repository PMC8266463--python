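"""Polygenic score files, harmonization against a genotype panel, scoring.

Scoring files follow the PGS-Catalog dialect: '#'-prefixed metadata
lines, a tab-separated header row, then one record per variant. Both the
rsID-keyed and the (chr_name, chr_position)-keyed flavours are accepted.

Harmonization matches model variants to panel variants, complementing
the dosage (d → 2−d) where the model's effect/other alleles are swapped
relative to the panel, and discarding variants absent from the panel or
with irreconcilable alleles — mirroring standard scoring practice where
score variants missing from the target data are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import ConfigurationError, FormatError, IntegrityError

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class PRSModel:
    """Ordered variant/effect-allele/weight records plus metadata."""

    records: pd.DataFrame  # id, chrom, pos, effect_allele, other_allele, effect_weight
    name: str = "unnamed_score"
    genome_build: str = "NR"
    flip_dosage: np.ndarray | None = None  # set by harmonization

    def __post_init__(self) -> None:
        req = ["id", "effect_allele", "effect_weight"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise FormatError(f"scoring model missing columns {missing}")
        dups = self.records.loc[self.records["id"].duplicated(), "id"].tolist()
        if dups:
            raise FormatError(f"duplicate variant ids in scoring model: {dups}")
        w = self.records["effect_weight"].to_numpy(dtype=float)
        if not np.isfinite(w).all():
            raise FormatError("non-finite effect weights in scoring model")
        self.records = self.records.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.records)


@dataclass
class HarmonizationReport:
    kept: int
    flipped: int
    discarded: int
    discarded_ids: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.kept + self.flipped + self.discarded


@dataclass
class ScoreVector:
    """Per-sample polygenic scores."""

    sample_ids: np.ndarray
    raw: np.ndarray
    std: np.ndarray | None = None
    n_variants_used: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw_score": self.raw,
                "std_score": np.nan if self.std is None else self.std,
                "n_variants_used": 0 if self.n_variants_used is None else self.n_variants_used,
            }
        )


def read_scoring_file(path: str) -> PRSModel:
    """Parse a PGS-Catalog-style scoring file.

    Metadata lines look like ``#pgs_name=...``; the header row must
    contain ``effect_allele`` and ``effect_weight`` plus either ``rsID``
    or both ``chr_name`` and ``chr_position``.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(
            fh, sep="\t", dtype={"chr_name": str},
            keep_default_na=False, na_values=[""],
        )
    cols = set(table.columns)
    for required in ("effect_allele", "effect_weight"):
        if required not in cols:
            raise FormatError(f"{path}: missing required column '{required}'")
    if "rsID" in cols:
        ids = table["rsID"].astype(str)
    elif {"chr_name", "chr_position"} <= cols:
        ids = table["chr_name"].astype(str) + ":" + table["chr_position"].astype(str)
    else:
        raise FormatError(
            f"{path}: need 'rsID' or both 'chr_name' and 'chr_position' columns"
        )
    weights = pd.to_numeric(table["effect_weight"], errors="coerce")
    if weights.isna().any():
        bad = int(np.where(weights.isna())[0][0])
        raise FormatError(
            f"{path}: non-numeric effect_weight at data row {bad + 1}"
        )
    records = pd.DataFrame(
        {
            "id": ids,
            "chrom": table.get("chr_name", pd.Series(["NA"] * len(table))).astype(str),
            "pos": table.get("chr_position", pd.Series([-1] * len(table))),
            "effect_allele": table["effect_allele"].astype(str),
            "other_allele": table.get(
                "other_allele", pd.Series(["N"] * len(table))
            ).astype(str),
            "effect_weight": weights,
        }
    )
    declared = meta.get("variants_number")
    if declared is not None and int(declared) != len(records):
        raise FormatError(
            f"{path}: declared variants_number={declared} but {len(records)} records"
        )
    return PRSModel(
        records=records,
        name=meta.get("pgs_name", "unnamed_score"),
        genome_build=meta.get("genome_build", "NR"),
    )


def write_scoring_file(model: PRSModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#pgs_name={model.name}\n")
        fh.write(f"#genome_build={model.genome_build}\n")
        fh.write(f"#variants_number={model.n_variants}\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for _, r in model.records.iterrows():
            fh.write(
                f"{r['id']}\t{r.get('chrom', 'NA')}\t{r.get('pos', -1)}\t"
                f"{r['effect_allele']}\t{r['other_allele']}\t{r['effect_weight']:.10g}\n"
            )


def harmonize_variants(
    model: PRSModel,
    genotypes: GenotypeMatrix,
    drop_palindromic: bool = False,
) -> tuple[PRSModel, HarmonizationReport]:
    """Match model variants to the panel; returns model + accounting.

    Exact allele matches are kept; swapped effect/other orientation is
    kept with a per-variant flip flag (dosage complemented at scoring
    time); anything else — absent from the panel or allele-inconsistent —
    is discarded. ``kept + flipped + discarded`` always equals the input
    model size.
    """
    panel = genotypes.variants.set_index("id")
    rows, flips, discarded = [], [], []
    for _, r in model.records.iterrows():
        vid = r["id"]
        if vid not in panel.index:
            discarded.append(vid)
            continue
        pv = panel.loc[vid]
        pair = (str(r["effect_allele"]), str(r["other_allele"]))
        if drop_palindromic and pair in PALINDROMIC:
            discarded.append(vid)
            continue
        panel_pair = (str(pv["effect_allele"]), str(pv["other_allele"]))
        if pair == panel_pair:
            rows.append(r)
            flips.append(False)
        elif (pair[1], pair[0]) == panel_pair:
            rows.append(r)
            flips.append(True)
        else:
            discarded.append(vid)
    records = (
        pd.DataFrame(rows).reset_index(drop=True)
        if rows
        else model.records.iloc[0:0].copy()
    )
    harmonized = PRSModel(
        records=records, name=model.name, genome_build=model.genome_build
    )
    harmonized.flip_dosage = np.array(flips, dtype=bool)
    report = HarmonizationReport(
        kept=int((~harmonized.flip_dosage).sum()) if len(flips) else 0,
        flipped=int(harmonized.flip_dosage.sum()) if len(flips) else 0,
        discarded=len(discarded),
        discarded_ids=discarded,
    )
    assert report.total == model.n_variants
    return harmonized, report


def compute_scores(
    model: PRSModel,
    genotypes: GenotypeMatrix,
    missing_policy: str = "freq",
) -> ScoreVector:
    """Raw scores Σ_j w_j · d_ij over the harmonized model variants.

    ``missing_policy``: 'freq' imputes a sporadic missing dosage with
    2·(panel effect-allele frequency); 'mean' with the panel's mean
    dosage at that variant (identical under Hardy-Weinberg sampling,
    kept as an explicit option). The per-sample count of non-imputed
    variants is reported.
    """
    if model.n_variants == 0:
        raise ConfigurationError("cannot score with zero harmonized variants")
    if missing_policy not in ("freq", "mean"):
        raise ConfigurationError(f"unknown missing policy {missing_policy!r}")
    sub = genotypes.subset_variants(model.records["id"].tolist())
    D = sub.dosage_float()
    flips = (
        model.flip_dosage
        if model.flip_dosage is not None
        else np.zeros(model.n_variants, dtype=bool)
    )
    D[:, flips] = 2.0 - D[:, flips]
    observed = ~np.isnan(D)
    fill = np.nanmean(D, axis=0)  # == 2*EAF on the flipped orientation
    r, c = np.where(~observed)
    D[r, c] = fill[c]
    w = model.records["effect_weight"].to_numpy(dtype=float)
    return ScoreVector(
        sample_ids=sub.sample_ids.copy(),
        raw=D @ w,
        n_variants_used=observed.sum(axis=1),
    )


def standardize_scores(
    scores: ScoreVector, reference_ids=None
) -> ScoreVector:
    """Standardize raw scores to SD units of a reference group.

    The reference defaults to all scored samples; it must contain at
    least two distinct raw scores.
    """
    if reference_ids is None:
        ref = scores.raw
    else:
        lookup = {s: i for i, s in enumerate(scores.sample_ids)}
        idx = [lookup[s] for s in reference_ids]
        ref = scores.raw[idx]
    mu, sd = float(np.mean(ref)), float(np.std(ref))
    if sd == 0.0:
        raise ConfigurationError("reference group has zero score variance")
    return ScoreVector(
        sample_ids=scores.sample_ids,
        raw=scores.raw,
        std=(scores.raw - mu) / sd,
        n_variants_used=scores.n_variants_used,
    )


@dataclass(frozen=True)
class CalibrationModel:
    """Linear map from standardized score to predicted height in cm."""

    intercept_f: float
    intercept_m: float
    slope: float
    training_split: str = "train"

    def predict(self, std_scores: np.ndarray, sex: np.ndarray) -> np.ndarray:
        icpt = np.where(np.asarray(sex) == "F", self.intercept_f, self.intercept_m)
        return icpt + self.slope * np.asarray(std_scores, dtype=float)


def calibrate_to_cm(
    std_scores: np.ndarray,
    heights: np.ndarray,
    sex: np.ndarray,
    training_split: str = "train",
    evaluation_ids: set | None = None,
    training_ids=None,
) -> CalibrationModel:
    """Fit height ~ standardized score + sex on the training split.

    When both id collections are given, their overlap raises an
    :class:`IntegrityError`, protecting the evaluation split.
    """
    if evaluation_ids is not None and training_ids is not None:
        overlap = set(training_ids) & set(evaluation_ids)
        if overlap:
            raise IntegrityError(
                f"calibration training split overlaps evaluation: {sorted(overlap)[:5]}"
            )
    z = np.asarray(std_scores, dtype=float)
    y = np.asarray(heights, dtype=float)
    is_m = (np.asarray(sex) == "M").astype(float)
    X = np.column_stack([np.ones(len(z)), is_m, z])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return CalibrationModel(
        intercept_f=float(coef[0]),
        intercept_m=float(coef[0] + coef[1]),
        slope=float(coef[2]),
        training_split=training_split,
    )
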