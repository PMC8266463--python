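"""Scoring-file parsing, harmonization accounting, score arithmetic,
standardization and cm calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heightprs.containers import GenotypeMatrix
from heightprs.errors import ConfigurationError, FormatError, IntegrityError
from heightprs.scoring import (
    PRSModel,
    calibrate_to_cm,
    compute_scores,
    harmonize_variants,
    read_scoring_file,
    standardize_scores,
    write_scoring_file,
)
from heightprs.simulate import SimulationParams, simulate_cohort


def _write(tmp_path, text, name="score.txt"):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


MINIMAL = """#pgs_name=demo
#genome_build=GRCh37
rsID\teffect_allele\tother_allele\teffect_weight
rs1\tA\tG\t0.5
rs2\tC\tT\t-0.25
"""

POSITIONAL = """rsID_absent_dialect
""".replace("rsID_absent_dialect", "chr_name\tchr_position\teffect_allele\teffect_weight") + """1\t100\tA\t0.1
2\t250\tG\t0.2
"""


class TestReadScoringFile:
    def test_minimal_rsid_file(self, tmp_path):
        model = read_scoring_file(_write(tmp_path, MINIMAL))
        assert model.n_variants == 2
        assert model.name == "demo"
        assert list(model.records["id"]) == ["rs1", "rs2"]
        assert model.records["effect_weight"].tolist() == [0.5, -0.25]

    def test_positional_dialect(self, tmp_path):
        model = read_scoring_file(_write(tmp_path, POSITIONAL))
        assert list(model.records["id"]) == ["1:100", "2:250"]

    def test_missing_required_column_named(self, tmp_path):
        bad = "rsID\tother_allele\teffect_weight\nrs1\tG\t0.5\n"
        with pytest.raises(FormatError, match="effect_allele"):
            read_scoring_file(_write(tmp_path, bad))

    def test_non_numeric_weight_reports_row(self, tmp_path):
        bad = "rsID\teffect_allele\teffect_weight\nrs1\tA\t0.5\nrs2\tC\toops\n"
        with pytest.raises(FormatError, match="row 2"):
            read_scoring_file(_write(tmp_path, bad))

    def test_duplicate_ids_rejected(self, tmp_path):
        bad = "rsID\teffect_allele\teffect_weight\nrs1\tA\t0.5\nrs1\tC\t0.1\n"
        with pytest.raises(FormatError, match="rs1"):
            read_scoring_file(_write(tmp_path, bad))

    def test_write_read_round_trip(self, tmp_path):
        model = read_scoring_file(_write(tmp_path, MINIMAL))
        out = str(tmp_path / "rewritten.txt")
        write_scoring_file(model, out)
        back = read_scoring_file(out)
        pd.testing.assert_frame_equal(
            back.records, model.records, check_dtype=False
        )
        assert back.name == model.name


def _model(records) -> PRSModel:
    return PRSModel(records=pd.DataFrame(records))


def _rec(vid, ea, oa, w):
    return dict(id=vid, chrom="1", pos=1, effect_allele=ea, other_allele=oa,
                effect_weight=w)


class TestHarmonize:
    def test_exact_match_kept(self, toy_genotypes):
        model = _model([_rec("v1", "A", "G", 1.0)])
        harm, rep = harmonize_variants(model, toy_genotypes)
        assert (rep.kept, rep.flipped, rep.discarded) == (1, 0, 0)

    def test_flip_complements_dosage(self, toy_genotypes):
        # panel v1: effect A / other G; model counts G
        model = _model([_rec("v1", "G", "A", 0.5)])
        harm, rep = harmonize_variants(model, toy_genotypes)
        assert rep.flipped == 1
        scores = compute_scores(harm, toy_genotypes)
        # panel dosages of A at v1: (0,1,2) -> G dosages (2,1,0)
        assert np.allclose(scores.raw, [1.0, 0.5, 0.0])

    def test_absent_variants_discarded(self, toy_genotypes):
        model = _model(
            [_rec("v1", "A", "G", 1.0), _rec("v2", "C", "T", 1.0),
             _rec("v3", "G", "A", 1.0), _rec("vX", "A", "C", 1.0),
             _rec("vY", "T", "G", 1.0)]
        )
        harm, rep = harmonize_variants(model, toy_genotypes)
        assert harm.n_variants == 3 and rep.discarded == 2

    def test_inconsistent_alleles_discarded(self, toy_genotypes):
        model = _model([_rec("v1", "C", "T", 1.0)])
        harm, rep = harmonize_variants(model, toy_genotypes)
        assert harm.n_variants == 0 and rep.discarded == 1

    def test_palindromic_dropped_on_request(self, toy_genotypes):
        toy_genotypes.variants.loc[0, ["effect_allele", "other_allele"]] = ["A", "T"]
        model = _model([_rec("v1", "A", "T", 1.0)])
        _, keep = harmonize_variants(model, toy_genotypes)
        _, drop = harmonize_variants(model, toy_genotypes, drop_palindromic=True)
        assert keep.kept == 1 and drop.discarded == 1

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from(["match", "flip", "absent", "clash"]),
                    min_size=1, max_size=12))
    def test_accounting_always_balances(self, cases):
        alleles = {"match": ("A", "G"), "flip": ("G", "A"), "clash": ("C", "T")}
        panel_rows, model_rows = [], []
        for i, case in enumerate(cases):
            vid = f"v{i}"
            model_rows.append(_rec(vid, *alleles.get(case, ("A", "G")), 0.1))
            if case != "absent":
                panel_rows.append(
                    dict(id=vid, chrom="1", pos=i + 1, effect_allele="A",
                         other_allele="G")
                )
        panel = GenotypeMatrix(
            sample_ids=np.array(["s"], dtype=object),
            variants=pd.DataFrame(panel_rows) if panel_rows else pd.DataFrame(
                columns=["id", "chrom", "pos", "effect_allele", "other_allele"]
            ),
            dosages=np.ones((1, len(panel_rows)), dtype=np.int8),
        )
        model = _model(model_rows)
        _, rep = harmonize_variants(model, panel)
        assert rep.kept + rep.flipped + rep.discarded == model.n_variants
        assert rep.kept == sum(c == "match" for c in cases)
        assert rep.flipped == sum(c == "flip" for c in cases)


class TestComputeScores:
    def test_zero_weights_zero_scores(self, toy_genotypes):
        model = _model([_rec("v1", "A", "G", 0.0), _rec("v2", "C", "T", 0.0)])
        harm, _ = harmonize_variants(model, toy_genotypes)
        assert np.all(compute_scores(harm, toy_genotypes).raw == 0.0)

    def test_single_variant_linearity(self, toy_genotypes):
        model = _model([_rec("v1", "A", "G", 0.5)])
        harm, _ = harmonize_variants(model, toy_genotypes)
        assert np.allclose(compute_scores(harm, toy_genotypes).raw, [0.0, 0.5, 1.0])

    def test_matches_brute_force_double_loop(self, toy_genotypes):
        weights = {"v1": 0.5, "v2": -1.25, "v3": 2.0}
        model = _model(
            [_rec("v1", "A", "G", 0.5), _rec("v2", "C", "T", -1.25),
             _rec("v3", "G", "A", 2.0)]
        )
        harm, _ = harmonize_variants(model, toy_genotypes)
        scores = compute_scores(harm, toy_genotypes)
        for i in range(3):
            expected = 0.0
            for j, vid in enumerate(["v1", "v2", "v3"]):
                expected += weights[vid] * toy_genotypes.dosages[i, j]
            assert scores.raw[i] == pytest.approx(expected)

    def test_zero_variants_rejected(self, toy_genotypes):
        model = _model([_rec("vZ", "A", "G", 1.0)])
        harm, _ = harmonize_variants(model, toy_genotypes)
        with pytest.raises(ConfigurationError):
            compute_scores(harm, toy_genotypes)

    def test_missing_dosage_frequency_imputed(self, toy_genotypes):
        toy_genotypes.dosages[0, 0] = -1  # s1 missing at v1
        model = _model([_rec("v1", "A", "G", 1.0)])
        harm, _ = harmonize_variants(model, toy_genotypes)
        scores = compute_scores(harm, toy_genotypes, missing_policy="freq")
        assert scores.raw[0] == pytest.approx(np.mean([1, 2]))  # 2*EAF of others
        assert scores.n_variants_used[0] == 0

    def test_sample_permutation_equivariance(self, toy_genotypes):
        model = _model([_rec("v1", "A", "G", 0.3), _rec("v3", "G", "A", -0.7)])
        harm, _ = harmonize_variants(model, toy_genotypes)
        base = compute_scores(harm, toy_genotypes)
        perm = toy_genotypes.subset_samples(["s3", "s1", "s2"])
        perm_scores = compute_scores(harm, perm)
        lookup = dict(zip(base.sample_ids, base.raw))
        assert np.allclose(perm_scores.raw, [lookup[s] for s in perm_scores.sample_ids])

    def test_variant_order_invariance(self, toy_genotypes):
        fwd = _model([_rec("v1", "A", "G", 0.3), _rec("v2", "C", "T", 1.0)])
        rev = _model([_rec("v2", "C", "T", 1.0), _rec("v1", "A", "G", 0.3)])
        h1, _ = harmonize_variants(fwd, toy_genotypes)
        h2, _ = harmonize_variants(rev, toy_genotypes)
        assert np.allclose(
            compute_scores(h1, toy_genotypes).raw, compute_scores(h2, toy_genotypes).raw
        )

    def test_global_allele_flip_leaves_scores_unchanged(self, toy_genotypes):
        model = _model(
            [_rec("v1", "A", "G", 0.5), _rec("v2", "C", "T", -1.0),
             _rec("v3", "G", "A", 0.25)]
        )
        harm, _ = harmonize_variants(model, toy_genotypes)
        base = compute_scores(harm, toy_genotypes)
        flipped_panel = GenotypeMatrix(
            sample_ids=toy_genotypes.sample_ids.copy(),
            variants=toy_genotypes.variants.rename(
                columns={"effect_allele": "other_allele", "other_allele": "effect_allele"}
            )[["id", "chrom", "pos", "effect_allele", "other_allele"]],
            dosages=(2 - toy_genotypes.dosages).astype(np.int8),
        )
        harm2, rep2 = harmonize_variants(model, flipped_panel)
        assert rep2.flipped + rep2.kept == 3
        assert np.allclose(compute_scores(harm2, flipped_panel).raw, base.raw)


class TestStandardize:
    def test_self_reference_gives_zero_one(self):
        sv = compute_like(np.array([1.0, 3.0, 5.0, 7.0]))
        out = standardize_scores(sv)
        assert out.std.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std.std() == pytest.approx(1.0)

    def test_hand_example(self):
        sv = compute_like(np.array([1.0, 2.0, 3.0]))
        out = standardize_scores(sv, reference_ids=["s0", "s1", "s2"])
        # ref mean 2, population SD sqrt(2/3)
        assert np.allclose(out.std * np.std([1, 2, 3]), [-1.0, 0.0, 1.0])

    def test_constant_scores_rejected(self):
        with pytest.raises(ConfigurationError):
            standardize_scores(compute_like(np.array([2.0, 2.0, 2.0])))


def compute_like(raw):
    from heightprs.scoring import ScoreVector

    return ScoreVector(
        sample_ids=np.array([f"s{i}" for i in range(len(raw))], dtype=object),
        raw=raw,
    )


class TestCalibration:
    def test_null_score_predicts_sex_means(self):
        rng = np.random.default_rng(0)
        n = 4000
        sex = np.where(rng.random(n) < 0.5, "F", "M")
        heights = np.where(sex == "F", 162.6, 175.8) + rng.normal(0, 6, n)
        z = rng.normal(size=n)
        cal = calibrate_to_cm(z, heights, sex)
        assert abs(cal.slope) < 0.3
        assert abs(cal.intercept_f - 162.6) < 0.4
        assert abs(cal.intercept_m - 175.8) < 0.4

    def test_oracle_score_recovers_h2_r2(self):
        params = SimulationParams(n_families=15_000, n_loci=300, n_causal=30, seed=21)
        cohort, _ = simulate_cohort(params, with_growth=False)
        fam = cohort.families
        g = fam["true_genetic_value_cm"].to_numpy()
        z = (g - g.mean()) / g.std()
        cal = calibrate_to_cm(z, fam["adult_height_cm"].to_numpy(), fam["sex"].to_numpy())
        pred = cal.predict(z, fam["sex"].to_numpy())
        for sex in ("F", "M"):
            m = fam["sex"] == sex
            r2 = np.corrcoef(pred[m.to_numpy()], fam.loc[m, "adult_height_cm"])[0, 1] ** 2
            assert abs(r2 - params.h2) < 0.03

    def test_invariant_to_raw_score_scale(self):
        rng = np.random.default_rng(1)
        n = 500
        raw = rng.normal(size=n)
        sex = np.array(["F", "M"] * 250)
        heights = 170 + raw * 3 + rng.normal(0, 2, n)
        z1 = (raw - raw.mean()) / raw.std()
        big = raw * 2.0
        z2 = (big - big.mean()) / big.std()
        c1 = calibrate_to_cm(z1, heights, sex)
        c2 = calibrate_to_cm(z2, heights, sex)
        assert np.allclose(c1.predict(z1, sex), c2.predict(z2, sex))

    def test_split_overlap_rejected(self):
        with pytest.raises(IntegrityError):
            calibrate_to_cm(
                np.zeros(3), np.array([160.0, 170, 180]), np.array(["F", "M", "F"]),
                training_ids=["a", "b"], evaluation_ids={"b", "c"},
            )
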