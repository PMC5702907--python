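import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from seedcontrast import proteomics_quant as pq
from seedcontrast.synthetic_data import OmicsScenario, gen_peptide_ion_table
from tests.conftest import make_ion_row


# ---------------------------------------------------------------------------
# partition_features
# ---------------------------------------------------------------------------

class TestPartitionFeatures:
    def test_worked_example_from_per_tissue_totals(self):
        # |A|=2099, |B|=786, |A∩B|=673
        common = {f"c{i}" for i in range(673)}
        a = common | {f"a{i}" for i in range(2099 - 673)}
        b = common | {f"b{i}" for i in range(786 - 673)}
        part = pq.partition_features(a, b)
        assert len(part.specific_a) == 1426
        assert len(part.specific_b) == 113
        assert part.n_union == 2212
        assert round(part.shared_percent, 1) == 30.4

    def test_equal_sets(self):
        part = pq.partition_features({"x", "y"}, {"x", "y"})
        assert part.specific_a == frozenset()
        assert part.specific_b == frozenset()
        assert part.common == {"x", "y"}

    def test_disjoint_sets(self):
        part = pq.partition_features({"a"}, {"b", "c"})
        assert part.common == frozenset()
        assert part.n_union == 3

    @given(
        a=st.sets(st.integers(0, 50)),
        b=st.sets(st.integers(0, 50)),
    )
    def test_inclusion_exclusion_property(self, a, b):
        part = pq.partition_features(a, b)
        assert part.n_union == len(a) + len(b) - len(part.common)
        assert part.specific_a.isdisjoint(part.specific_b)
        assert part.specific_a.isdisjoint(part.common)
        assert part.specific_b.isdisjoint(part.common)


# ---------------------------------------------------------------------------
# filter_peptide_ions
# ---------------------------------------------------------------------------

class TestFilterPeptideIons:
    def test_nonspecific_ion_removed(self, ion_table_builder):
        table = ion_table_builder(
            [
                make_ion_row("i1", ["P1", "P2"], "embryo", r, 10.0)
                for r in (1, 2, 3)
            ]
        )
        out, report = pq.filter_peptide_ions(table)
        assert len(out) == 0
        assert report.n_nonspecific_rows == 3
        assert report.n_nonspecific_ions == 1

    def test_single_detection_removed_two_retained(self, ion_table_builder):
        rows = [
            make_ion_row("once", ["P1"], "embryo", 1, 5.0),
            make_ion_row("once", ["P1"], "embryo", 2, np.nan),
            make_ion_row("once", ["P1"], "embryo", 3, np.nan),
            make_ion_row("twice", ["P2"], "embryo", 1, 5.0),
            make_ion_row("twice", ["P2"], "embryo", 2, np.nan),
            make_ion_row("twice", ["P2"], "embryo", 3, 7.0),
        ]
        out, _ = pq.filter_peptide_ions(ion_table_builder(rows))
        assert set(out["ion_id"]) == {"twice"}
        assert len(out) == 3  # whole ion/tissue group retained incl. NaN row

    def test_per_tissue_independence(self, ion_table_builder):
        rows = [
            make_ion_row("i1", ["P1"], "embryo", 1, 5.0),
            make_ion_row("i1", ["P1"], "embryo", 2, 5.0),
            make_ion_row("i1", ["P1"], "endosperm", 1, 5.0),
        ]
        out, _ = pq.filter_peptide_ions(ion_table_builder(rows))
        assert set(out["tissue"]) == {"embryo"}

    def test_min_detections_above_replicates_errors(self, ion_table_builder):
        table = ion_table_builder([make_ion_row("i", ["P"], "embryo", 1, 1.0)])
        with pytest.raises(ValueError, match="min_detections"):
            pq.filter_peptide_ions(table, min_detections=4, n_replicates=3)

    def test_replicate_out_of_range_errors(self, ion_table_builder):
        table = ion_table_builder([make_ion_row("i", ["P"], "embryo", 5, 1.0)])
        with pytest.raises(ValueError, match="replicate"):
            pq.filter_peptide_ions(table)

    def test_retained_matches_bruteforce_enumeration(self, small_scenario):
        table, _ = gen_peptide_ion_table(small_scenario)
        out, _ = pq.filter_peptide_ions(table, min_detections=2)

        # independent oracle: explicit per-ion enumeration
        expected = set()
        for (ion, tissue), grp in table.groupby(["ion_id", "tissue"]):
            proteins = set(grp["protein_ids"].iloc[0].split(";"))
            n_detected = grp["area"].notna().sum()
            if len(proteins) == 1 and n_detected >= 2:
                expected.add((ion, tissue))
        got = set(map(tuple, out[["ion_id", "tissue"]].drop_duplicates().values))
        assert got == expected


# ---------------------------------------------------------------------------
# sum_within_sample / rollup
# ---------------------------------------------------------------------------

class TestSumWithinSample:
    def test_duplicate_detections_summed(self, ion_table_builder):
        table = ion_table_builder(
            [
                make_ion_row("i1", ["P1"], "embryo", 1, 10.0),
                make_ion_row("i1", ["P1"], "embryo", 1, 15.0),
            ]
        )
        out = pq.sum_within_sample(table)
        assert len(out) == 1
        assert out["area"].iloc[0] == 25.0

    def test_single_detection_identity(self, ion_table_builder):
        table = ion_table_builder([make_ion_row("i1", ["P1"], "embryo", 2, 9.0)])
        out = pq.sum_within_sample(table)
        pd.testing.assert_frame_equal(out, table)

    def test_permutation_invariance(self, small_scenario):
        table, _ = gen_peptide_ion_table(small_scenario)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = pq.sum_within_sample(table)
        b = pq.sum_within_sample(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestRollup:
    def test_log2_of_summed_areas(self, ion_table_builder):
        rows = [
            make_ion_row("i1", ["P1"], "embryo", r, a)
            for r, a in ((1, 4.0), (2, 8.0), (3, 16.0))
        ]
        out = pq.rollup_protein_abundance(ion_table_builder(rows))
        assert list(out["log2_abundance"]) == [2.0, 3.0, 4.0]

    def test_two_ions_summed(self, ion_table_builder):
        rows = [
            make_ion_row("i1", ["P1"], "embryo", 1, 8.0),
            make_ion_row("i2", ["P1"], "embryo", 1, 8.0),
        ]
        out = pq.rollup_protein_abundance(ion_table_builder(rows))
        assert len(out) == 1
        assert out["abundance"].iloc[0] == 16.0

    def test_additivity_split_ion(self, ion_table_builder):
        whole = ion_table_builder([make_ion_row("i1", ["P1"], "embryo", 1, 10.0)])
        split = ion_table_builder(
            [
                make_ion_row("i1a", ["P1"], "embryo", 1, 4.0),
                make_ion_row("i1b", ["P1"], "embryo", 1, 6.0),
            ]
        )
        a = pq.rollup_protein_abundance(whole)["abundance"].iloc[0]
        b = pq.rollup_protein_abundance(split)["abundance"].iloc[0]
        assert a == b

    def test_matches_bruteforce_resum(self, small_scenario):
        table, _ = gen_peptide_ion_table(small_scenario)
        filtered, _ = pq.filter_peptide_ions(table)
        summed = pq.sum_within_sample(filtered)
        rollup = pq.rollup_protein_abundance(summed)

        # oracle: plain dict accumulation over rows
        acc = {}
        for _, row in summed.iterrows():
            if pd.isna(row["area"]):
                continue
            key = (row["protein_ids"], row["tissue"], row["replicate"])
            acc[key] = acc.get(key, 0.0) + row["area"]
        got = {
            (r["protein_id"], r["tissue"], r["replicate"]): r["abundance"]
            for _, r in rollup.iterrows()
            if pd.notna(r["abundance"])
        }
        assert set(got) == set(acc)
        for key in acc:
            assert got[key] == pytest.approx(acc[key], rel=1e-12)

    def test_rejects_unfiltered_nonspecific(self, ion_table_builder):
        table = ion_table_builder(
            [make_ion_row("i1", ["P1", "P2"], "embryo", 1, 1.0)]
        )
        with pytest.raises(ValueError, match="single-protein"):
            pq.rollup_protein_abundance(table)


# ---------------------------------------------------------------------------
# ratios, favored classes, z-scores
# ---------------------------------------------------------------------------

def means_frame(data):
    df = pd.DataFrame(data, columns=["feature_id", "endosperm", "embryo"])
    return df.set_index("feature_id")


class TestTissueLog2Ratio:
    def test_simple_ratio(self):
        ratios = pq.tissue_log2_ratio(means_frame([("f", 8.0, 2.0)]))
        assert ratios["log2_ratio"].iloc[0] == 2.0

    def test_equal_means_zero(self):
        ratios = pq.tissue_log2_ratio(means_frame([("f", 5.0, 5.0)]))
        assert ratios["log2_ratio"].iloc[0] == 0.0

    def test_swapping_tissues_negates(self, rng):
        mf = means_frame(
            [(f"f{i}", rng.uniform(1, 100), rng.uniform(1, 100))
             for i in range(20)]
        )
        fwd = pq.tissue_log2_ratio(mf, "endosperm", "embryo")
        rev = pq.tissue_log2_ratio(mf, "embryo", "endosperm")
        np.testing.assert_allclose(
            fwd["log2_ratio"], -rev["log2_ratio"], rtol=1e-12
        )

    def test_nonpositive_mean_excluded_with_warning(self):
        mf = means_frame([("ok", 4.0, 2.0), ("bad", 0.0, 2.0)])
        with pytest.warns(UserWarning, match="non-positive"):
            ratios = pq.tissue_log2_ratio(mf)
        assert list(ratios["feature_id"]) == ["ok"]


class TestFavoredByMedian:
    def test_positive_median_and_favored(self):
        ratios = pd.DataFrame(
            {"feature_id": ["a", "b", "c"], "log2_ratio": [1.0, 2.0, 3.0]}
        )
        out, thr = pq.favored_by_median(ratios)
        assert thr["positive_median"] == 2.0
        favored = out.loc[out["favored_class"] == "endosperm-favored",
                          "feature_id"]
        assert list(favored) == ["c"]

    def test_all_equal_no_favored(self):
        ratios = pd.DataFrame(
            {"feature_id": list("abcd"), "log2_ratio": [1.5] * 4}
        )
        out, _ = pq.favored_by_median(ratios)
        assert (out["favored_class"] == "none").all()

    def test_empty_negative_subset_threshold_nan(self):
        ratios = pd.DataFrame(
            {"feature_id": ["a", "b"], "log2_ratio": [1.0, 2.0]}
        )
        out, thr = pq.favored_by_median(ratios)
        assert np.isnan(thr["negative_median"])
        assert not (out["favored_class"] == "embryo-favored").any()

    def test_matches_bruteforce_classification(self, rng):
        r = rng.normal(0, 3, size=200)
        ratios = pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(200)], "log2_ratio": r}
        )
        out, thr = pq.favored_by_median(ratios)

        pos = sorted(x for x in r if x > 0)
        neg = sorted(x for x in r if x < 0)
        med_pos = np.median(pos)
        med_neg = np.median(neg)
        assert thr["positive_median"] == pytest.approx(med_pos)
        assert thr["negative_median"] == pytest.approx(med_neg)
        for _, row in out.iterrows():
            v = row["log2_ratio"]
            if v > 0 and v > med_pos:
                expect = "endosperm-favored"
            elif v < 0 and v < med_neg:
                expect = "embryo-favored"
            else:
                expect = "none"
            assert row["favored_class"] == expect


class TestZscoreDifferential:
    def test_ratio_at_mean_gives_z0_p1(self):
        ratios = pd.DataFrame(
            {"feature_id": list("abc"), "log2_ratio": [-1.0, 0.0, 1.0]}
        )
        out = pq.zscore_differential(ratios)
        row = out[out["feature_id"] == "b"].iloc[0]
        assert row["z"] == 0.0
        assert row["p"] == 1.0

    def test_hand_vector_matches_direct_formula(self):
        r = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        ratios = pd.DataFrame(
            {"feature_id": list("abcde"), "log2_ratio": r}
        )
        out = pq.zscore_differential(ratios)
        sd = np.sqrt(np.sum((r - r.mean()) ** 2) / (len(r) - 1))
        np.testing.assert_allclose(out["z"], r / sd, rtol=1e-12)
        np.testing.assert_allclose(
            out["p"], 2 * stats.norm.sf(np.abs(r / sd)), rtol=1e-12
        )

    def test_degenerate_sd_errors(self):
        ratios = pd.DataFrame(
            {"feature_id": list("abc"), "log2_ratio": [2.0, 2.0, 2.0]}
        )
        with pytest.raises(ValueError, match="degenerate"):
            pq.zscore_differential(ratios)

    def test_too_few_ratios_errors(self):
        ratios = pd.DataFrame({"feature_id": ["a"], "log2_ratio": [1.0]})
        with pytest.raises(ValueError, match=">=3"):
            pq.zscore_differential(ratios)

    def test_null_type_i_error_near_alpha(self, rng):
        # lighter companion of the acceptance simulation
        fractions = []
        for _ in range(100):
            r = rng.normal(0, 1, size=673)
            ratios = pd.DataFrame(
                {"feature_id": np.arange(673), "log2_ratio": r}
            )
            out = pq.zscore_differential(ratios, alpha=0.05)
            fractions.append(out["significant"].mean())
        assert abs(np.mean(fractions) - 0.05) < 0.02


class TestShapiroNormality:
    def test_normal_sample_usually_nonsignificant(self, rng):
        n_pass = sum(
            pq.shapiro_normality(rng.normal(0, 1, 300))[1] > 0.05
            for _ in range(100)
        )
        assert n_pass > 50

    def test_bimodal_sample_usually_significant(self, rng):
        n_reject = 0
        for _ in range(100)[:100]:
            x = np.concatenate(
                [rng.normal(-5, 0.3, 150), rng.normal(5, 0.3, 150)]
            )
            if pq.shapiro_normality(x)[1] < 0.05:
                n_reject += 1
        assert n_reject > 90

    def test_n2_errors(self):
        with pytest.raises(ValueError, match="3 <= n"):
            pq.shapiro_normality([1.0, 2.0])

    def test_w_in_range(self, rng):
        w, p = pq.shapiro_normality(rng.normal(size=50))
        assert 0 < w <= 1
        assert 0 <= p <= 1


# ---------------------------------------------------------------------------
# planted-truth recovery (module-level invariant)
# ---------------------------------------------------------------------------

def test_planted_partition_recovered_exactly(clean_scenario):
    table, truth = gen_peptide_ion_table(clean_scenario)
    filtered, _ = pq.filter_peptide_ions(table)
    rollup = pq.rollup_protein_abundance(pq.sum_within_sample(filtered))
    detected = pq.detected_features(rollup)
    part = pq.partition_features(detected["embryo"], detected["endosperm"])

    want_a = set(truth.loc[truth["membership"] == "embryo_specific",
                           "protein_id"])
    want_b = set(truth.loc[truth["membership"] == "endosperm_specific",
                           "protein_id"])
    want_common = set(truth.loc[truth["membership"] == "common", "protein_id"])
    assert part.specific_a == want_a
    assert part.specific_b == want_b
    assert part.common == want_common
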