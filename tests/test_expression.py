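"""Expression loading, calling, normalization, census and similarity."""

import numpy as np
import pandas as pd
import pytest

from txatlas.expression import (
    ExpressionMatrix,
    TissueProfile,
    average_replicates,
    biotype_census,
    call_expressed,
    detection_summary,
    gene_calls_from_transcripts,
    normalize_counts,
    percent,
    read_matrix,
    sample_similarity,
    size_factors_median_of_ratios,
    unique_expression,
)

from conftest import make_annotation

GROUPING = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}


def _matrix(values, units="TPM", grouping=GROUPING, samples=None, features=None):
    samples = samples or list(grouping)
    features = features or [f"g{i+1}" for i in range(len(values))]
    df = pd.DataFrame(values, index=features, columns=samples, dtype=float)
    return ExpressionMatrix(values=df, units=units, grouping=grouping)


class TestReadMatrix:
    def test_loads_tsv_with_grouping(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t0\t0\t0\t0\n")
        m = read_matrix(p, GROUPING, units="TPM")
        assert m.feature_ids == ["g1", "g2"]
        assert m.tissues == ["A", "B"]

    def test_sample_missing_from_grouping_named(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\n")
        with pytest.raises(ValueError, match="s4"):
            read_matrix(p, {"s1": "A", "s2": "A", "s3": "B"}, units="TPM")

    def test_negative_value_named_with_coordinates(self):
        with pytest.raises(ValueError, match=r"\(g1, s2\)"):
            _matrix([[0.0, -1.0, 0.0, 0.0]])

    def test_duplicate_feature_ids_rejected(self):
        df = pd.DataFrame([[1.0] * 4] * 2, index=["g1", "g1"], columns=list(GROUPING))
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(values=df, units="TPM", grouping=GROUPING)


class TestAveragingAndCalling:
    def test_replicate_mean(self):
        m = _matrix([[0.4, 0.8, 2.0, 2.0]])
        profile = average_replicates(m)
        assert profile.values.loc["g1", "A"] == pytest.approx(0.6)

    def test_single_replicate_passthrough(self):
        m = _matrix([[2.0]], grouping={"s1": "A"}, samples=["s1"])
        assert average_replicates(m).values.loc["g1", "A"] == 2.0

    def test_empty_tissue_group_rejected(self):
        grouping = {"s1": "A", "s2": "A", "s3": "B", "s4": "B", "ghost": "C"}
        m = _matrix(
            [[1.0, 1.0, 1.0, 1.0]], grouping=grouping, samples=["s1", "s2", "s3", "s4"]
        )
        with pytest.raises(ValueError, match="C"):
            average_replicates(m)

    @pytest.mark.parametrize(
        "value,expressed", [(0.6, True), (0.5, False), (0.0, False), (0.5000001, True)]
    )
    def test_strict_threshold_boundary(self, value, expressed):
        profile = TissueProfile(
            values=pd.DataFrame({"A": [value]}, index=["g1"]), units="TPM"
        )
        calls = call_expressed(profile, threshold=0.5)
        assert ("g1" in calls.expressed["A"]) is expressed

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        profile = TissueProfile(
            values=pd.DataFrame(
                rng.random((50, 4)) * 3,
                index=[f"g{i}" for i in range(50)],
                columns=list("ABCD"),
            ),
            units="TPM",
        )
        lo, hi = call_expressed(profile, 0.3), call_expressed(profile, 1.5)
        for t in "ABCD":
            assert hi.expressed[t] <= lo.expressed[t]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = _matrix([[5, 5, 5, 5], [9, 9, 9, 9]], units="counts")
        assert size_factors_median_of_ratios(m).tolist() == pytest.approx([1, 1, 1, 1])

    def test_single_feature_hand_derived(self):
        # geometric mean of (2, 8) is 4; ratios 2/4 and 8/4
        m = _matrix([[2, 8]], units="counts", grouping={"s1": "A", "s2": "B"})
        assert size_factors_median_of_ratios(m).tolist() == pytest.approx([0.5, 2.0])

    def test_zero_containing_feature_excluded(self):
        m = _matrix([[0, 5], [3, 3]], units="counts", grouping={"s1": "A", "s2": "B"})
        assert size_factors_median_of_ratios(m).tolist() == pytest.approx([1.0, 1.0])

    def test_no_all_positive_feature_rejected(self):
        m = _matrix([[0, 5], [3, 0]], units="counts", grouping={"s1": "A", "s2": "B"})
        with pytest.raises(ValueError, match="no feature"):
            size_factors_median_of_ratios(m)

    def test_idempotence_after_normalization(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 1000, size=(30, 4)).astype(float)
        counts[:, 2] *= 3.5  # a deep sample
        m = _matrix(counts.tolist(), units="counts")
        renorm = size_factors_median_of_ratios(normalize_counts(m))
        assert np.allclose(renorm, 1.0, atol=1e-9)


class TestCensusAndSummary:
    def _calls_ann(self):
        ann = make_annotation(
            ("g1", 1, 10, "+", "protein_coding"),
            ("g2", 100, 110, "+", "protein_coding"),
            ("g3", 200, 210, "+", "protein_coding"),
            ("g4", 300, 310, "+", "lncRNA"),
        )
        profile = TissueProfile(
            values=pd.DataFrame(
                {"A": [1, 1, 1, 1], "B": [1, 0, 0, 0]},
                index=["g1.1", "g2.1", "g3.1", "g4.1"],
                dtype=float,
            ),
            units="TPM",
        )
        return call_expressed(profile), ann

    def test_census_counts_and_percentages(self):
        calls, ann = self._calls_ann()
        census = biotype_census(calls, ann)
        assert census.counts.loc["A", "protein_coding"] == 3
        assert census.counts.loc["A", "lncRNA"] == 1
        assert census.percentages.loc["A", "protein_coding"] == 75.0
        assert census.percentages.loc["A", "lncRNA"] == 25.0

    def test_census_partitions_detected_total(self):
        calls, ann = self._calls_ann()
        census = biotype_census(calls, ann)
        for t in calls.tissues:
            assert census.counts.loc[t].sum() == len(calls.expressed[t])

    def test_census_rejects_unknown_ids(self):
        calls, ann = self._calls_ann()
        calls.expressed["A"] = calls.expressed["A"] | {"phantom"}
        with pytest.raises(ValueError, match="phantom"):
            biotype_census(calls, ann)

    def test_unique_expression_rules(self):
        calls, ann = self._calls_ann()
        uniq = unique_expression(calls)
        assert uniq["A"] == {"g2.1", "g3.1", "g4.1"}  # expressed only in A
        assert uniq["B"] == frozenset()  # g1.1 is shared
        lnc = unique_expression(calls, ann, biotype_filter="lncRNA")
        assert lnc["A"] == {"g4.1"}

    def test_detection_summary_percentages_rederive(self):
        calls, ann = self._calls_ann()
        genes = gene_calls_from_transcripts(calls, ann)
        summary = detection_summary(genes, calls, ann)
        assert summary.detected_transcripts == 4
        assert summary.transcript_pct == percent(
            summary.detected_transcripts, summary.annotated_transcripts
        )
        assert summary.per_tissue.loc["A", "lncRNA"] == 1
        # union is at least as large as any per-tissue count
        assert (summary.per_tissue["genes"] <= summary.detected_genes).all()


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,nd,expected",
        [(1, 8, 1, 12.5), (125, 1000, 0, 13.0), (135, 1000, 1, 13.5), (1, 3, 1, 33.3)],
    )
    def test_half_away_from_zero(self, num, den, nd, expected):
        assert percent(num, den, nd) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)


class TestSampleSimilarity:
    def test_identical_samples(self):
        m = _matrix([[1, 1], [2, 2]], grouping={"s1": "A", "s2": "A"})
        dist, corr = sample_similarity(m)
        assert dist.loc["s1", "s2"] == 0.0
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)

    def test_three_four_five_triangle(self):
        m = _matrix([[0, 4], [3, 0]], grouping={"s1": "A", "s2": "B"})
        dist, _ = sample_similarity(m)
        assert dist.loc["s1", "s2"] == pytest.approx(5.0)

    def test_symmetry_and_diagonals(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.random((20, 4)).tolist())
        dist, corr = sample_similarity(m)
        assert np.allclose(dist, dist.T) and np.allclose(np.diag(dist), 0.0)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)

    def test_constant_sample_correlation_undefined(self):
        m = _matrix([[1, 5], [1, 9]], grouping={"s1": "A", "s2": "B"})
        _, corr = sample_similarity(m)
        assert np.isnan(corr.loc["s1", "s2"])
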