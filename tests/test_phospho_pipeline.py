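"""The phosphoproteomic pipeline: correction, collapse, averaging, filtering,
clustering, class assignment and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from tcr_phosdyn.phospho_pipeline import (
    TIME_COLUMNS,
    assign_pca_classes,
    average_replicates,
    bh_adjust,
    cluster_timecourses,
    collapse_to_sites,
    correct_proline,
    drop_undetected,
    enrich_terms,
    filter_regulated,
    fisher_pvalue,
    fuzzy_cmeans,
    standardize_courses,
)

from conftest import make_site_table


def peptide_rows(protein, sequence, n_phospho, n_proline, ratios_by_rep):
    rows = []
    for rep, ratios in ratios_by_rep.items():
        row = {"protein": protein, "residues": "100", "sequence": sequence,
               "n_phospho": n_phospho, "n_proline": n_proline, "replicate": rep}
        row.update({c: r for c, r in zip(TIME_COLUMNS, ratios)})
        rows.append(row)
    return rows


class TestCorrectProline:
    def test_identity_without_prolines_or_conversion(self):
        df = pd.DataFrame(peptide_rows("P1", "AAAK", 1, 0, {1: [1.0, 2, 3, 4]}))
        for f in (0.0, 0.2):
            out = correct_proline(df, f)
            assert np.allclose(out[list(TIME_COLUMNS)], df[list(TIME_COLUMNS)])
        out = correct_proline(
            pd.DataFrame(peptide_rows("P1", "APPK", 1, 2, {1: [1.0, 2, 3, 4]})), 0.0
        )
        assert np.allclose(out[list(TIME_COLUMNS)], [[1.0, 2, 3, 4]])

    def test_two_prolines_ten_percent_conversion(self):
        df = pd.DataFrame(peptide_rows("P1", "APPK", 1, 2, {1: [1.0, 1, 1, 1]}))
        out = correct_proline(df, 0.1)
        assert np.allclose(out[list(TIME_COLUMNS)], 1.0 / 0.81)

    def test_full_conversion_rejected(self):
        df = pd.DataFrame(peptide_rows("P1", "APPK", 1, 2, {1: [1.0, 1, 1, 1]}))
        with pytest.raises(ValueError):
            correct_proline(df, 1.0)


class TestCollapse:
    def test_least_modified_peptide_kept(self):
        rows = peptide_rows("P1", "SHORTPEP", 1, 0, {1: [2.0, 2, 2, 2]})
        rows += peptide_rows("P1", "SHORTPEPLONG", 2, 0, {1: [9.0, 9, 9, 9]})
        out = collapse_to_sites(pd.DataFrame(rows))
        assert set(out["n_phospho"]) == {1}
        assert set(out["sequence"]) == {"SHORTPEP"}

    def test_single_record_is_identity(self):
        df = pd.DataFrame(peptide_rows("P1", "ONLYPEP", 1, 0, {1: [2.0, 2, 2, 2]}))
        pd.testing.assert_frame_equal(collapse_to_sites(df), df)

    def test_tie_breaks_to_shortest_sequence(self):
        rows = peptide_rows("P1", "NINECHARS", 1, 0, {1: [2.0, 2, 2, 2]})
        rows += peptide_rows("P1", "TWELVECHARSX", 1, 0, {1: [9.0, 9, 9, 9]})
        out = collapse_to_sites(pd.DataFrame(rows))
        assert set(out["sequence"]) == {"NINECHARS"}


class TestAverageReplicates:
    def test_mean_and_count(self):
        rows = peptide_rows("P1", "PEP", 1, 0, {1: [1.0, 1, 1, 2], 2: [1.0, 1, 1, 4]})
        out = average_replicates(pd.DataFrame(rows))
        assert out.loc[0, "mean_t60"] == pytest.approx(3.0)
        assert out.loc[0, "n_t60"] == 2
        assert out.loc[0, "sd_t60"] == pytest.approx(np.sqrt(2.0))

    def test_single_replicate_has_no_sd(self):
        rows = peptide_rows("P1", "PEP", 1, 0, {1: [1.0, 1, 1, 2]})
        out = average_replicates(pd.DataFrame(rows))
        assert out.loc[0, "mean_t60"] == 2.0
        assert np.isnan(out.loc[0, "sd_t60"])

    def test_missing_values_skipped_not_imputed(self):
        rows = peptide_rows("P1", "PEP", 1, 0,
                            {1: [2.0, np.nan, 1, 2], 2: [4.0, np.nan, 1, 4]})
        out = average_replicates(pd.DataFrame(rows))
        assert out.loc[0, "mean_t5"] == 3.0
        assert np.isnan(out.loc[0, "mean_t15"]) and out.loc[0, "n_t15"] == 0

    def test_site_with_no_values_rejected(self):
        rows = peptide_rows("P1", "PEP", 1, 0, {1: [np.nan] * 4})
        with pytest.raises(ValueError, match="no values"):
            average_replicates(pd.DataFrame(rows))

    def test_drop_undetected_removes_empty_rows(self):
        rows = peptide_rows("P1", "PEP", 1, 0, {1: [np.nan] * 4, 2: [1.0, 1, 1, 1]})
        out = drop_undetected(pd.DataFrame(rows))
        assert len(out) == 1 and out.loc[0, "replicate"] == 2


class TestFilterRegulated:
    def test_upregulated_site(self):
        table = make_site_table({"P1": [1.2, 1.5, 2.0, 1.8]})
        out = filter_regulated(table)
        assert len(out) == 1
        assert out.iloc[0]["direction"] == "up"
        assert out.iloc[0]["earliest_time_s"] == 30.0

    def test_downregulated_site(self):
        table = make_site_table({"P1": [0.9, 0.6, 0.5, 0.55]})
        out = filter_regulated(table)
        assert out.iloc[0]["direction"] == "down"
        assert out.iloc[0]["earliest_time_s"] == 30.0

    def test_unregulated_site_excluded(self):
        table = make_site_table({"P1": [1.2, 1.5, 1.9, 0.6]})
        assert len(filter_regulated(table)) == 0

    def test_strict_comparator_excludes_boundary(self):
        table = make_site_table({"P1": [1.0, 1.0, 2.0, 1.0]})
        assert len(filter_regulated(table, comparator=">=")) == 1
        assert len(filter_regulated(table, comparator=">")) == 0

    def test_monotone_in_threshold(self):
        rng = np.random.Generator(np.random.PCG64(2))
        courses = {
            f"P{i}": list(2.0 ** rng.normal(0, 1.2, size=4)) for i in range(60)
        }
        table = make_site_table(courses)
        sets = [
            set(filter_regulated(table, threshold=th)["protein"])
            for th in (1.5, 2.0, 3.0)
        ]
        assert sets[0] >= sets[1] >= sets[2]

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            filter_regulated(make_site_table({"P1": [1, 1, 1, 1]}), threshold=1.0)


def _reference_fcm(X, c, m, U0, n_iter):
    """Straight-line fuzzy c-means iteration, independent of the package."""
    U = U0.copy()
    for _ in range(n_iter):
        Um = U ** m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = np.maximum(((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2), 1e-12)
        U = (1.0 / d2) ** (1.0 / (m - 1.0))
        U /= U.sum(axis=1, keepdims=True)
    return U, V


class TestFuzzyCMeans:
    def test_matches_reference_iteration(self):
        rng = np.random.Generator(np.random.PCG64(4))
        X = np.vstack([rng.normal(0, 0.1, (6, 3)), rng.normal(3, 0.1, (6, 3))])
        U0 = np.random.Generator(np.random.PCG64(9)).dirichlet(np.ones(2), size=12)
        U_ref, _ = _reference_fcm(X, 2, 2.0, U0, 200)
        U_pkg, _, _, _ = fuzzy_cmeans(X, c=2, m=2.0, seed=9, max_iter=200)
        # both converge to the same fixed point (clusters may be permuted)
        agree = np.allclose(np.sort(U_ref, axis=1), np.sort(U_pkg, axis=1), atol=1e-4)
        assert agree

    def test_separated_archetypes_recovered_exactly(self):
        table = make_site_table(
            {**{f"UP{i}": [3.0, 3.5, 4.0, 4.0] for i in range(6)},
             **{f"DN{i}": [0.4, 0.3, 0.25, 0.25] for i in range(6)}}
        )
        res = cluster_timecourses(table, c=2, seed=1)
        up_labels = {lab for (p, _), lab in zip(res.site_ids, res.labels) if p.startswith("UP")}
        dn_labels = {lab for (p, _), lab in zip(res.site_ids, res.labels) if p.startswith("DN")}
        assert len(up_labels) == 1 and len(dn_labels) == 1 and up_labels != dn_labels

    def test_memberships_sum_to_one(self):
        rng = np.random.Generator(np.random.PCG64(0))
        X = rng.normal(size=(20, 4))
        U, _, _, _ = fuzzy_cmeans(X, c=3, seed=0)
        assert np.allclose(U.sum(axis=1), 1.0, atol=1e-9)

    def test_same_seed_identical(self):
        rng = np.random.Generator(np.random.PCG64(1))
        X = rng.normal(size=(15, 4))
        r1 = fuzzy_cmeans(X, c=3, seed=5)
        r2 = fuzzy_cmeans(X, c=3, seed=5)
        assert np.array_equal(r1[0], r2[0])

    def test_degenerate_input_rejected(self):
        X = np.ones((10, 4))
        with pytest.raises(ValueError, match="degenerate"):
            fuzzy_cmeans(X, c=2, seed=0)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            fuzzy_cmeans(np.ones((2, 4)) * np.arange(2)[:, None], c=4, seed=0)


class TestPCAClasses:
    def test_decreasing_course_is_class_three(self):
        courses = {
            **{f"fast{i}": [2.5 + 0.1 * i, 3.0, 3.1, 3.2] for i in range(3)},
            **{f"slow{i}": [1.1, 1.4 + 0.05 * i, 2.2, 3.0] for i in range(3)},
            **{f"down{i}": [0.8, 0.5, 0.4 - 0.02 * i, 0.3] for i in range(3)},
        }
        classes = assign_pca_classes(courses, seed=0)
        assert all(classes[f"down{i}"] == 3 for i in range(3))

    def test_fast_and_delayed_rise_in_different_classes(self):
        courses = {
            **{f"fast{i}": [2.6 + 0.1 * i, 3.0, 3.1, 3.2] for i in range(3)},
            **{f"slow{i}": [1.1, 1.4 + 0.05 * i, 2.2, 3.0] for i in range(3)},
            **{f"down{i}": [0.8, 0.5, 0.4 - 0.02 * i, 0.3] for i in range(3)},
        }
        classes = assign_pca_classes(courses, seed=0)
        assert {classes[f"fast{i}"] for i in range(3)} == {1}
        assert {classes[f"slow{i}"] for i in range(3)} == {2}
        assert set(classes.values()) == {1, 2, 3}

    def test_too_few_courses_rejected(self):
        with pytest.raises(ValueError):
            assign_pca_classes({"a": [1, 1, 1, 1], "b": [2, 2, 2, 2]})


class TestEnrichment:
    def test_matches_hypergeometric_tail(self):
        # cluster of 5 proteins (3 with term X), background 20 (2 with X)
        cluster = [f"C{i}" for i in range(5)]
        background = [f"B{i}" for i in range(20)]
        ann = pd.DataFrame(
            {"protein": cluster[:3] + background[:2], "term": "X"}
        )
        out = enrich_terms(cluster, background, ann, full=True)
        # independent oracle: P[K >= 3] drawing 5 from 25 with 5 term-positive
        M, n, N = 25, 5, 5
        p_expected = sum(
            math.comb(n, k) * math.comb(M - n, N - k) for k in range(3, min(n, N) + 1)
        ) / math.comb(M, N)
        assert out.loc[0, "p"] == pytest.approx(p_expected, rel=1e-12)

    def test_single_occurrence_term_excluded(self):
        cluster = ["C0", "C1", "C2"]
        background = [f"B{i}" for i in range(10)]
        ann = pd.DataFrame({"protein": ["C0"], "term": ["rare"]})
        out = enrich_terms(cluster, background, ann)
        assert out.empty
        full = enrich_terms(cluster, background, ann, full=True)
        assert not full.loc[0, "significant"]

    def test_bh_hand_example(self):
        adjusted = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adjusted, [0.03, 0.03, 0.04])

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.Generator(np.random.PCG64(3))
        p = rng.uniform(size=25)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_overlapping_cluster_background_rejected(self):
        ann = pd.DataFrame({"protein": ["A"], "term": ["X"]})
        with pytest.raises(ValueError, match="disjoint"):
            enrich_terms(["A"], ["A", "B"], ann)

    def test_empty_cluster_rejected(self):
        ann = pd.DataFrame({"protein": ["A"], "term": ["X"]})
        with pytest.raises(ValueError):
            enrich_terms([], ["B"], ann)
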