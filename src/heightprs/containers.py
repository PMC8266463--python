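"""Core in-memory containers: genotype matrices and trio cohorts.

Dosages are stored as an ``int8`` sample-by-variant matrix with ``-1``
marking a missing call; :meth:`GenotypeMatrix.dosage_float` exposes the
conventional float/NaN view. Cohort phenotypes live in two pandas frames,
one row per family and one row per childhood growth measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IntegrityError

MISSING_DOSAGE = -1

#: columns of the per-family phenotype table
FAMILY_COLUMNS = [
    "family_id",
    "child_id",
    "mother_id",
    "father_id",
    "sex",
    "adult_height_cm",
    "mother_height_cm",
    "father_height_cm",
    "true_genetic_value_cm",
]

#: columns of the childhood growth table
GROWTH_COLUMNS = ["child_id", "age_years", "height_cm", "weight_kg"]

#: columns of the variant annotation table
VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele"]


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix with variant annotations.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (length ``n``).
    variants
        DataFrame with columns ``id, chrom, pos, effect_allele,
        other_allele``; ``id`` unique. The dosage counts copies of
        ``effect_allele``.
    dosages
        ``(n_samples, n_variants)`` int8 array of allele counts in
        ``{0, 1, 2}``, with ``-1`` for missing.
    """

    sample_ids: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages)
        if self.dosages.dtype != np.int8:
            d = np.asarray(self.dosages, dtype=float)
            out = np.full(d.shape, MISSING_DOSAGE, dtype=np.int8)
            ok = np.isfinite(d)
            out[ok] = np.rint(d[ok]).astype(np.int8)
            self.dosages = out
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise IntegrityError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IntegrityError("duplicate sample ids")
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise IntegrityError(f"duplicate variant ids: {dups}")
        valid = np.isin(self.dosages, [MISSING_DOSAGE, 0, 1, 2])
        if not valid.all():
            raise IntegrityError("dosages must be in {0,1,2} or -1 (missing)")
        self.variants = self.variants.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def sample_index(self, ids) -> np.ndarray:
        """Row positions of ``ids``, raising on unknown samples."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise IntegrityError(f"unknown sample id {exc.args[0]!r}") from exc

    def dosage_float(self) -> np.ndarray:
        """Dosages as float64 with NaN at missing calls."""
        d = self.dosages.astype(np.float64)
        d[self.dosages == MISSING_DOSAGE] = np.nan
        return d

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency among non-missing calls."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            sample_ids=self.sample_ids[idx],
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )

    def subset_variants(self, variant_ids) -> "GenotypeMatrix":
        pos = {v: j for j, v in enumerate(self.variants["id"])}
        cols = np.array([pos[v] for v in variant_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=self.sample_ids.copy(),
            variants=self.variants.iloc[cols].reset_index(drop=True),
            dosages=self.dosages[:, cols],
        )


@dataclass
class TrioCohort:
    """Child-parent trio phenotypes plus childhood growth records."""

    families: pd.DataFrame
    growth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=GROWTH_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in FAMILY_COLUMNS if c not in self.families.columns]
        if missing:
            raise IntegrityError(f"cohort table missing columns {missing}")
        if self.families["child_id"].duplicated().any():
            raise IntegrityError("duplicate child ids in cohort")
        bad_sex = ~self.families["sex"].isin(["F", "M"])
        if bad_sex.any():
            raise IntegrityError("sex must be 'F' or 'M'")
        h = self.families["adult_height_cm"]
        if (h <= 0).any() or not np.isfinite(h).all():
            raise IntegrityError("adult heights must be positive and finite")
        self.families = self.families.reset_index(drop=True)
        self.growth = self.growth.reset_index(drop=True)

    @property
    def n_children(self) -> int:
        return len(self.families)

    def with_growth(self, growth: pd.DataFrame) -> "TrioCohort":
        unknown = set(growth["child_id"]) - set(self.families["child_id"])
        if unknown:
            raise IntegrityError(f"growth records for unknown children: {sorted(unknown)[:5]}")
        return TrioCohort(families=self.families.copy(), growth=growth.copy())

    def check_genotype_ids(self, genotypes: GenotypeMatrix) -> None:
        """Require child, mother and father genotype rows for every family."""
        have = set(genotypes.sample_ids)
        for col in ("child_id", "mother_id", "father_id"):
            absent = set(self.families[col]) - have
            if absent:
                raise IntegrityError(
                    f"{col} values without genotype rows: {sorted(absent)[:5]}"
                )
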