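"""Tests for barcode mapping, coverage, classification and association scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cryptclones.clones import Biopsy, MutationCall
from cryptclones.neighbourhoods import (
    association_regression,
    barcode_cluster_probability,
    classify_tumour_associated,
    cluster_coverage,
    coverage_correlation,
    malignancy_score,
    map_barcodes_to_biopsies,
    mutation_count_correlation,
)


def barcode_frame(rows):
    return pd.DataFrame(rows, columns=["barcode_id", "sample_id", "x", "y", "cluster"])


def make_call(biopsy_id, gene="Ctnnb1", consequence="missense", pos=100, vaf=0.05):
    return MutationCall(
        biopsy_id=biopsy_id,
        gene=gene,
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="T",
        consequence=consequence,
        vaf_rep1=vaf,
        vaf_rep2=vaf,
        log_ratio_rep1=1.0,
        log_ratio_rep2=1.0,
        adjusted_vaf=vaf,
    )


@pytest.fixture
def one_biopsy():
    return [Biopsy("b0", "S0", 5.0, 5.0, circumference=12.0, diameter=2.0)]


class TestBarcodeMapping:
    def test_inside_radius_assigned(self, one_biopsy):
        bc = barcode_frame([("a", "S0", 5.9, 5.0, 1)])
        mapped = map_barcodes_to_biopsies(bc, one_biopsy)
        assert mapped["biopsy_id"].tolist() == ["b0"]

    def test_outside_every_radius_unassigned(self, one_biopsy):
        bc = barcode_frame([("a", "S0", 6.2, 5.0, 1)])
        mapped = map_barcodes_to_biopsies(bc, one_biopsy)
        assert mapped["biopsy_id"].isna().all()

    def test_overlapping_discs_nearest_centre_wins(self):
        bios = [
            Biopsy("near", "S0", 5.0, 5.0, 12.0, diameter=2.0),
            Biopsy("far", "S0", 6.4, 5.0, 12.0, diameter=2.0),
        ]
        # barcode at 5.6: 0.6 from "near", 0.8 from "far", inside both discs
        bc = barcode_frame([("a", "S0", 5.6, 5.0, 1)])
        mapped = map_barcodes_to_biopsies(bc, bios)
        assert mapped["biopsy_id"].tolist() == ["near"]

    def test_sample_mismatch_leaves_unassigned(self, one_biopsy):
        bc = barcode_frame([("a", "OTHER", 5.0, 5.0, 1)])
        mapped = map_barcodes_to_biopsies(bc, one_biopsy)
        assert mapped["biopsy_id"].isna().all()

    def test_periodic_seam_assignment(self):
        bios = [Biopsy("b0", "S0", 5.0, 0.2, circumference=12.0)]
        bc = barcode_frame([("a", "S0", 5.0, 11.7, 1)])  # 0.5 mm across the seam
        mapped = map_barcodes_to_biopsies(bc, bios)
        assert mapped["biopsy_id"].tolist() == ["b0"]

    def test_missing_columns_rejected(self, one_biopsy):
        with pytest.raises(ValueError, match="cluster"):
            map_barcodes_to_biopsies(pd.DataFrame({"barcode_id": [], "sample_id": [], "x": [], "y": []}), one_biopsy)


class TestClusterCoverage:
    def test_fractions_match_counts(self):
        bc = barcode_frame(
            [(f"a{i}", "S0", 0, 0, 10 if i < 3 else 1) for i in range(10)]
        )
        cov = cluster_coverage(bc)
        assert cov.loc["S0", 10] == pytest.approx(0.3)
        assert cov.loc["S0", 1] == pytest.approx(0.7)

    def test_single_cluster_sample_is_degenerate_simplex(self):
        bc = barcode_frame([(f"a{i}", "S0", 0, 0, 4) for i in range(5)])
        cov = cluster_coverage(bc)
        assert cov.loc["S0", 4] == 1.0

    def test_rows_sum_to_one_on_random_tables(self, rng):
        rows = [
            (f"a{i}", f"S{int(rng.integers(4))}", 0, 0, int(rng.integers(6)))
            for i in range(200)
        ]
        cov = cluster_coverage(barcode_frame(rows))
        assert np.allclose(cov.sum(axis=1), 1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cluster_coverage(barcode_frame([]))


def kendall_brute_force(x, y):
    """Tau-b by exhaustive pair counting (independent oracle).

    tau_b = (C - D) / sqrt((n0 - T_x)(n0 - T_y)) with n0 = n(n-1)/2 and
    T_x/T_y the numbers of pairs tied in x / in y (both-tied pairs count in
    each).
    """
    conc = disc = tx = ty = n0 = 0
    for (xi, yi), (xj, yj) in itertools.combinations(zip(x, y), 2):
        n0 += 1
        dx, dy = xi - xj, yi - yj
        if dx == 0:
            tx += 1
        if dy == 0:
            ty += 1
        if dx != 0 and dy != 0:
            if dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom


class TestCoverageCorrelation:
    def _coverage(self, rows, clusters):
        return pd.DataFrame(rows, columns=clusters, index=[f"S{i}" for i in range(len(rows))])

    def test_identical_ranks_give_tau_one(self):
        cov = self._coverage([[0.1, 0.1], [0.2, 0.3], [0.3, 0.5]], [10, 4])
        out = coverage_correlation(cov, 10)
        assert out.loc[4, "tau"] == pytest.approx(1.0)

    def test_reversed_ranks_give_tau_minus_one(self):
        cov = self._coverage([[0.1, 0.5], [0.2, 0.3], [0.3, 0.1]], [10, 4])
        assert coverage_correlation(cov, 10).loc[4, "tau"] == pytest.approx(-1.0)

    def test_matches_exhaustive_pair_counting(self, rng):
        target = rng.random(5)
        others = {c: rng.random(5) for c in (0, 1, 2)}
        cov = pd.DataFrame({10: target, **others}, index=[f"S{i}" for i in range(5)])
        out = coverage_correlation(cov, 10)
        for c in (0, 1, 2):
            assert out.loc[c, "tau"] == pytest.approx(
                kendall_brute_force(target, others[c])
            )

    def test_constant_column_flagged_undefined(self):
        cov = self._coverage([[0.1, 0.5], [0.2, 0.5], [0.3, 0.5]], [10, 4])
        out = coverage_correlation(cov, 10)
        assert out.loc[4, "undefined"] and np.isnan(out.loc[4, "tau"])

    def test_bh_adjustment_optional(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(
            rng.random((6, 4)), columns=[10, 0, 1, 2], index=[f"S{i}" for i in range(6)]
        )
        out = coverage_correlation(cov, 10, adjust="bh")
        assert "p_adj" in out.columns
        assert (out["p_adj"].dropna() >= out["p"].dropna() - 1e-12).all()

    def test_too_few_samples_rejected(self):
        cov = self._coverage([[0.1, 0.5], [0.2, 0.4]], [10, 4])
        with pytest.raises(ValueError):
            coverage_correlation(cov, 10)


def mapped_with_tumour_counts(counts: dict[str, int], tumour_cluster=10):
    """Mapped-barcode frame giving each biopsy the requested tumour-barcode count."""
    rows = []
    k = 0
    for bid, n in counts.items():
        for _ in range(n):
            rows.append((f"bc{k}", "S0", 0.0, 0.0, tumour_cluster))
            k += 1
        for _ in range(3):  # padding barcodes in another cluster
            rows.append((f"bc{k}", "S0", 0.0, 0.0, 1))
            k += 1
    df = barcode_frame(rows)
    df["biopsy_id"] = [
        bid for bid, n in counts.items() for _ in range(n + 3)
    ]
    return df


class TestClassification:
    def test_five_tumour_barcodes_flags_missense(self):
        mapped = mapped_with_tumour_counts({"b0": 5})
        (ann,) = classify_tumour_associated([make_call("b0")], mapped, 10)
        assert ann.tumour_associated and ann.n_tumour_barcodes_in_biopsy == 5

    def test_four_tumour_barcodes_does_not_flag(self):
        mapped = mapped_with_tumour_counts({"b0": 4})
        (ann,) = classify_tumour_associated([make_call("b0")], mapped, 10)
        assert not ann.tumour_associated

    def test_synonymous_never_flagged_regardless_of_barcodes(self):
        mapped = mapped_with_tumour_counts({"b0": 50})
        (ann,) = classify_tumour_associated(
            [make_call("b0", consequence="synonymous")], mapped, 10
        )
        assert not ann.tumour_associated

    def test_biopsy_absent_from_map_counts_zero(self):
        mapped = mapped_with_tumour_counts({"other": 9})
        (ann,) = classify_tumour_associated([make_call("b0")], mapped, 10)
        assert not ann.tumour_associated and ann.n_tumour_barcodes_in_biopsy == 0

    def test_threshold_monotone(self, rng):
        counts = {f"b{i}": int(rng.integers(0, 12)) for i in range(20)}
        mapped = mapped_with_tumour_counts(counts)
        calls = [make_call(b, pos=100 + i) for i, b in enumerate(counts)]
        flags = {
            thr: [a.tumour_associated for a in classify_tumour_associated(calls, mapped, 10, thr)]
            for thr in (3, 5, 8)
        }
        for lo, hi in ((3, 5), (5, 8)):
            for f_lo, f_hi in zip(flags[lo], flags[hi]):
                assert f_lo or not f_hi  # raising the threshold never adds flags


class TestMalignancyScore:
    def _annotated(self, rows):
        """rows: list of (gene, consequence, flagged)."""
        mapped = mapped_with_tumour_counts({"hot": 9, "cold": 0})
        calls = [
            make_call("hot" if flag else "cold", gene=g, consequence=c, pos=i)
            for i, (g, c, flag) in enumerate(rows)
        ]
        return classify_tumour_associated(calls, mapped, 10)

    def test_two_of_five_gives_forty_percent(self):
        rows = [("Smad4", "missense", True)] * 2 + [("Smad4", "missense", False)] * 3
        out = malignancy_score(self._annotated(rows))
        assert out.loc["Smad4", "score"] == pytest.approx(0.4)

    def test_zero_flagged_gives_zero_score(self):
        out = malignancy_score(self._annotated([("Il17rc", "nonsense", False)] * 3))
        assert out.loc["Il17rc", "score"] == 0.0

    def test_synonymous_only_gene_is_undefined(self):
        out = malignancy_score(self._annotated([("Pigr", "synonymous", False)] * 2))
        assert np.isnan(out.loc["Pigr", "score"])

    def test_matches_independent_tally_on_random_table(self, rng):
        genes = ["Ctnnb1", "Smad4", "Il17rc"]
        rows = [
            (
                genes[int(rng.integers(3))],
                ["missense", "nonsense", "synonymous"][int(rng.integers(3))],
                bool(rng.integers(2)),
            )
            for _ in range(30)
        ]
        ann = self._annotated(rows)
        out = malignancy_score(ann)
        for g in genes:
            nonsyn = [a for a in ann if a.call.gene == g and a.call.is_nonsynonymous]
            flagged = [a for a in nonsyn if a.tumour_associated]
            if nonsyn:
                assert out.loc[g, "score"] == pytest.approx(len(flagged) / len(nonsyn))


class TestBarcodeClusterProbability:
    def test_single_cluster_pool_gives_probability_one(self):
        mapped = mapped_with_tumour_counts({"b0": 6})
        ann = classify_tumour_associated([make_call("b0")], mapped, 10)
        probs = barcode_cluster_probability(ann, mapped, "tumour_associated")
        assert probs.sum() == pytest.approx(1.0)
        # biopsy b0 holds 6 tumour + 3 padding barcodes
        assert probs[10] == pytest.approx(6 / 9)
        assert probs[1] == pytest.approx(3 / 9)

    def test_uniform_cluster_assignment_gives_near_equal_fractions(self, rng):
        # synonymous-control behaviour: no cluster preference
        n_clusters = 8
        rows = [
            (f"bc{i}", "S0", 0.0, 0.0, int(rng.integers(n_clusters))) for i in range(4000)
        ]
        df = barcode_frame(rows)
        df["biopsy_id"] = [f"b{i % 10}" for i in range(4000)]
        calls = [make_call(f"b{i}", consequence="synonymous", pos=i) for i in range(10)]
        ann = classify_tumour_associated(calls, df, 10)
        probs = barcode_cluster_probability(ann, df, "synonymous")
        assert probs.sum() == pytest.approx(1.0)
        assert probs.max() - probs.min() < 4 * np.sqrt(0.125 * 0.875 / 4000) * 2

    def test_no_qualifying_biopsy_rejected(self):
        mapped = mapped_with_tumour_counts({"b0": 2})
        ann = classify_tumour_associated([make_call("b0")], mapped, 10)
        with pytest.raises(ValueError):
            barcode_cluster_probability(ann, mapped, "tumour_associated")


class TestAssociationRegression:
    def test_noise_free_line_recovered_exactly(self):
        x = pd.Series(np.linspace(0, 1, 20))
        y = 2.0 * x + 1.0
        fit = association_regression(y, x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_planted_slope_recovered_within_two_se(self, rng):
        x = pd.Series(rng.random(100))
        y = 0.5 * x + pd.Series(rng.normal(0, 0.1, 100))
        fit = association_regression(y, x)
        se = 0.1 / (np.std(x) * np.sqrt(100))
        assert abs(fit.slope - 0.5) < 2.5 * se

    def test_constant_response_gives_zero_slope(self):
        x = pd.Series(np.linspace(0, 1, 10))
        fit = association_regression(pd.Series(np.full(10, 3.0)), x)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            association_regression(pd.Series([1.0, 2.0, 3.0]), pd.Series([1.0, 1.0, 1.0]))

    def test_filter_note_is_recorded(self):
        x = pd.Series(np.linspace(0, 1, 5))
        fit = association_regression(2 * x, x, filter_note="adjusted VAF < 0.10")
        assert fit.filter_note == "adjusted VAF < 0.10"


class TestMutationCountCorrelation:
    def _setup(self, counts_by_sample, coverage_rows):
        coverage = pd.DataFrame(
            coverage_rows, columns=[10, 4], index=list(counts_by_sample)
        )
        mapped = mapped_with_tumour_counts(
            {f"b_{s}": 9 for s in counts_by_sample}
        )
        calls = []
        pos = 0
        for s, k in counts_by_sample.items():
            for _ in range(k):
                calls.append(make_call(f"b_{s}", pos=pos))
                pos += 1
        ann = classify_tumour_associated(calls, mapped, 10)
        b2s = {f"b_{s}": s for s in counts_by_sample}
        return ann, coverage, b2s

    def test_counts_tracking_coverage_give_tau_one(self):
        ann, cov, b2s = self._setup(
            {"S0": 1, "S1": 2, "S2": 3},
            [[0.0, 0.1], [0.0, 0.2], [0.0, 0.3]],
        )
        out = mutation_count_correlation(ann, cov, b2s, "tumour_associated")
        assert out.loc[4, "tau"] == pytest.approx(1.0)

    def test_matches_brute_force_on_toy(self, rng):
        counts = {f"S{i}": int(rng.integers(0, 6)) for i in range(6)}
        cov_rows = rng.random((6, 2))
        ann, cov, b2s = self._setup(counts, cov_rows)
        out = mutation_count_correlation(ann, cov, b2s, "tumour_associated")
        expected = kendall_brute_force(list(counts.values()), cov_rows[:, 1])
        assert out.loc[4, "tau"] == pytest.approx(expected)

    def test_null_counts_centre_on_zero_over_seeds(self):
        taus = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = {f"S{i}": int(rng.integers(0, 6)) for i in range(8)}
            cov_rows = rng.random((8, 2))
            ann, cov, b2s = self._setup(counts, cov_rows)
            out = mutation_count_correlation(ann, cov, b2s, "tumour_associated")
            taus.append(out.loc[4, "tau"])
        assert abs(np.nanmean(taus)) < 0.15

    def test_unknown_class_rejected(self):
        ann, cov, b2s = self._setup(
            {"S0": 1, "S1": 2, "S2": 3}, [[0, 0.1], [0, 0.2], [0, 0.3]]
        )
        with pytest.raises(ValueError):
            mutation_count_correlation(ann, cov, b2s, "bogus")
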