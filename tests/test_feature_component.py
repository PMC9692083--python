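"""Row-wise normalization, specificity, FS/FC ratios and intensity filters."""

import numpy as np
import pandas as pd
import pytest

from extractrank.annotation_cleaning import merge_annotation_status
from extractrank.errors import ParameterError
from extractrank.feature_component import (
    apply_intensity_filter,
    apply_quantile_filter,
    compute_fs_fc,
    compute_specificity,
    normalize_rowwise,
)

from conftest import make_table, make_metadata


def empty_ledger(ids):
    return merge_annotation_status(None, None, None, ids)


def annotated_ledger(ids, annotated_ids):
    isdb = pd.DataFrame({"feature_id": list(annotated_ids), "score_final": 0.9})
    return merge_annotation_status(None, isdb, None, ids)


class TestNormalizeRowwise:
    def test_row_becomes_proportions(self):
        table = make_table([[2, 3, 5]], ["a", "b", "c"])
        norm = normalize_rowwise(table, ["a", "b", "c"])
        assert norm.values.iloc[0].tolist() == [0.2, 0.3, 0.5]

    def test_single_extract_row_is_one(self):
        table = make_table([[7]], ["a"])
        norm = normalize_rowwise(table, ["a"])
        assert norm.values.iloc[0, 0] == 1.0

    def test_all_zero_row_preserved(self):
        table = make_table([[0, 0]], ["a", "b"])
        norm = normalize_rowwise(table, ["a", "b"])
        assert norm.values.iloc[0].tolist() == [0.0, 0.0]

    def test_row_sums_one_or_zero_on_seeded_table(self):
        rng = np.random.default_rng(2)
        areas = rng.uniform(0, 100, size=(100, 6))
        areas[rng.random(100) < 0.1] = 0.0
        table = make_table(areas, [f"e{i}" for i in range(6)])
        norm = normalize_rowwise(table, table.extracts)
        sums = norm.values.sum(axis=1)
        assert np.allclose(sums[sums > 0], 1.0, atol=1e-9)


class TestSpecificity:
    def test_single_extract_above_threshold(self):
        table = make_table([[92, 5, 3]], ["a", "b", "c"])
        norm = normalize_rowwise(table, table.extracts)
        res = compute_specificity(norm, make_metadata(table.extracts))
        assert res.specific.iloc[0].tolist() == [True, False, False]

    def test_uniform_feature_specific_nowhere(self):
        table = make_table([[25, 25, 25, 25]], list("abcd"))
        norm = normalize_rowwise(table, table.extracts)
        res = compute_specificity(norm, make_metadata(table.extracts))
        assert not res.specific.to_numpy().any()

    def test_shared_specificity_same_species(self):
        # two same-species extracts holding 0.50 + 0.45 of the mass
        table = make_table([[50, 45, 5]], ["a1", "a2", "b"])
        meta = make_metadata(["a1", "a2", "b"], species=["Sp a", "Sp a", "Sp b"])
        norm = normalize_rowwise(table, table.extracts)
        n1 = compute_specificity(norm, meta, max_occurrence_n=1)
        assert not n1.specific.to_numpy().any()
        n2 = compute_specificity(norm, meta, max_occurrence_n=2)
        assert n2.specific.iloc[0].tolist() == [True, True, False]

    def test_shared_specificity_requires_nonzero_share(self):
        table = make_table([[95, 0, 5]], ["a1", "a2", "b"])
        meta = make_metadata(["a1", "a2", "b"], species=["Sp a", "Sp a", "Sp b"])
        norm = normalize_rowwise(table, table.extracts)
        n2 = compute_specificity(norm, meta, max_occurrence_n=2)
        assert n2.specific.iloc[0].tolist() == [True, False, False]

    def test_n1_equals_brute_force_thresholding(self):
        rng = np.random.default_rng(21)
        areas = rng.uniform(0, 100, size=(80, 5)) * (rng.random((80, 5)) < 0.6)
        table = make_table(areas, [f"e{i}" for i in range(5)])
        norm = normalize_rowwise(table, table.extracts)
        res = compute_specificity(norm, make_metadata(table.extracts))
        brute = norm.values.to_numpy() >= 0.90
        assert (res.specific.to_numpy() == brute).all()

    def test_shared_rule_matches_subset_enumeration(self):
        # brute force: a feature is specific to e iff e belongs to the
        # top-k same-species extracts and their summed share >= 0.9
        from itertools import combinations

        rng = np.random.default_rng(22)
        extracts = ["a1", "a2", "a3", "b1", "b2"]
        species = ["Sp a"] * 3 + ["Sp b"] * 2
        areas = rng.dirichlet(np.ones(5) * 0.4, size=60) * 100
        table = make_table(areas, extracts)
        meta = make_metadata(extracts, species=species)
        norm = normalize_rowwise(table, table.extracts)
        N = 2
        res = compute_specificity(norm, meta, max_occurrence_n=N)
        v = norm.values
        for f in v.index:
            for sp, cols in (("Sp a", ["a1", "a2", "a3"]), ("Sp b", ["b1", "b2"])):
                k = min(N, len(cols))
                top = sorted(cols, key=lambda c: -v.loc[f, c])[:k]
                qualifies = sum(v.loc[f, c] for c in top) >= 0.90
                for c in cols:
                    expected = qualifies and c in top and v.loc[f, c] > 0
                    assert res.specific.loc[f, c] == expected, (f, c)

    def test_bad_min_specificity_rejected(self):
        table = make_table([[1]], ["a"])
        norm = normalize_rowwise(table, ["a"])
        with pytest.raises(ParameterError):
            compute_specificity(norm, make_metadata(["a"]), min_specificity=1.5)

    def test_raising_n_never_decreases_fs(self):
        rng = np.random.default_rng(23)
        extracts = [f"e{i}" for i in range(6)]
        species = ["Sp a"] * 3 + ["Sp b", "Sp c", "Sp d"]
        areas = rng.dirichlet(np.ones(6) * 0.3, size=120) * 1000
        table = make_table(areas, extracts)
        meta = make_metadata(extracts, species=species)
        norm = normalize_rowwise(table, table.extracts)
        ledger = empty_ledger(table.feature_ids)
        prev = None
        for n in (1, 2, 3):
            res = compute_fs_fc(compute_specificity(norm, meta, max_occurrence_n=n), ledger, table)
            if prev is not None:
                assert (res.fs >= prev - 1e-12).all()
            prev = res.fs


class TestFsFc:
    def test_sixty_of_hundred_specific_unannotated(self):
        # 100 detected features in extract a: 60 exclusive+unannotated,
        # 40 shared (non-specific)
        areas = [[100.0, 0.0]] * 60 + [[50.0, 50.0]] * 40
        table = make_table(areas, ["a", "b"])
        norm = normalize_rowwise(table, table.extracts)
        res = compute_specificity(norm, make_metadata(["a", "b"]))
        res = compute_fs_fc(res, empty_ledger(table.feature_ids), table)
        assert res.fc["a"] == pytest.approx(0.6)
        assert res.fs["a"] == pytest.approx(0.6)

    def test_all_annotated_gives_fc_zero(self):
        areas = [[100.0, 0.0]] * 10
        table = make_table(areas, ["a", "b"])
        norm = normalize_rowwise(table, table.extracts)
        res = compute_specificity(norm, make_metadata(["a", "b"]))
        res = compute_fs_fc(res, annotated_ledger(table.feature_ids, table.feature_ids), table)
        assert res.fc["a"] == 0.0
        assert res.fs["a"] == 1.0

    def test_empty_extract_scores_zero(self):
        table = make_table([[10.0, 0.0]], ["a", "b"])
        norm = normalize_rowwise(table, table.extracts)
        res = compute_specificity(norm, make_metadata(["a", "b"]))
        res = compute_fs_fc(res, empty_ledger(table.feature_ids), table)
        assert res.fs["b"] == 0.0 and res.fc["b"] == 0.0

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(31)
        n, m = 300, 8
        areas = rng.uniform(0, 100, size=(n, m)) * (rng.random((n, m)) < 0.5)
        table = make_table(areas, [f"e{i}" for i in range(m)])
        annotated = set(rng.choice(np.arange(1, n + 1), 120, replace=False).tolist())
        ledger = annotated_ledger(table.feature_ids, annotated)
        norm = normalize_rowwise(table, table.extracts)
        res = compute_fs_fc(compute_specificity(norm, make_metadata(table.extracts)), ledger, table)
        for e in table.extracts:
            det = [f for f in table.feature_ids if table.areas.loc[f, e] > 0]
            spec = [f for f in det if norm.values.loc[f, e] >= 0.90]
            spec_un = [f for f in spec if f not in annotated]
            assert res.fs[e] == pytest.approx(len(spec) / len(det))
            assert res.fc[e] == pytest.approx(len(spec_un) / len(det))

    def test_fc_bounded_by_fs_on_seeded_fixtures(self):
        # FC <= FS and both within [0, 1] across many random tables
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n, m = 40, 4
            areas = rng.uniform(0, 50, size=(n, m)) * (rng.random((n, m)) < 0.5)
            table = make_table(areas, [f"e{i}" for i in range(m)])
            annotated = set(rng.choice(np.arange(1, n + 1), n // 3, replace=False).tolist())
            norm = normalize_rowwise(table, table.extracts)
            res = compute_fs_fc(
                compute_specificity(norm, make_metadata(table.extracts)),
                annotated_ledger(table.feature_ids, annotated),
                table,
            )
            assert ((res.fc <= res.fs + 1e-12) & (res.fs <= 1) & (res.fc >= 0)).all()

    def test_raising_min_specificity_never_increases_scores(self):
        rng = np.random.default_rng(33)
        areas = rng.uniform(0, 100, size=(100, 5)) * (rng.random((100, 5)) < 0.6)
        table = make_table(areas, [f"e{i}" for i in range(5)])
        norm = normalize_rowwise(table, table.extracts)
        ledger = empty_ledger(table.feature_ids)
        meta = make_metadata(table.extracts)
        prev = None
        for ms in (0.5, 0.7, 0.9, 0.99):
            res = compute_fs_fc(compute_specificity(norm, meta, min_specificity=ms), ledger, table)
            if prev is not None:
                assert (res.fs <= prev + 1e-12).all()
            prev = res.fs


class TestIntensityFilters:
    def test_two_percent_floor(self):
        table = make_table([[100.0], [1.0], [50.0]], ["a"])
        out = apply_intensity_filter(table, 0.02)
        assert out.areas["a"].tolist() == [100.0, 0.0, 50.0]

    def test_zero_fraction_is_identity(self):
        table = make_table([[100.0], [1.0]], ["a"])
        out = apply_intensity_filter(table, 0.0)
        pd.testing.assert_frame_equal(out.areas, table.areas)

    def test_floor_matches_brute_force(self):
        rng = np.random.default_rng(41)
        areas = rng.uniform(0, 1000, size=(200, 4)) * (rng.random((200, 4)) < 0.7)
        table = make_table(areas, list("abcd"))
        out = apply_intensity_filter(table, 0.02)
        for col in table.extracts:
            colmax = table.areas[col].max()
            brute = (table.areas[col] / colmax >= 0.02).sum()
            assert (out.areas[col] > 0).sum() == brute

    def test_quantile_example_linear_interpolation(self):
        # nonzero areas [1,2,3,4]: 0.75-quantile = 3.25, only 4 survives
        table = make_table([[1.0], [2.0], [3.0], [4.0]], ["a"])
        out = apply_quantile_filter(table, 0.75)
        assert out.areas["a"].tolist() == [0.0, 0.0, 0.0, 4.0]

    def test_quantile_zero_keeps_all_nonzero(self):
        table = make_table([[1.0], [0.0], [3.0]], ["a"])
        out = apply_quantile_filter(table, 0.0)
        pd.testing.assert_frame_equal(out.areas, table.areas)

    @pytest.mark.parametrize("filt", [
        lambda t: apply_intensity_filter(t, 0.02),
        lambda t: apply_quantile_filter(t, 0.75),
    ])
    def test_filters_only_zero_never_alter_survivors(self, filt):
        rng = np.random.default_rng(42)
        areas = rng.uniform(0, 1000, size=(150, 3)) * (rng.random((150, 3)) < 0.8)
        table = make_table(areas, list("abc"))
        once = filt(table)
        assert ((once.areas == 0) | (once.areas == table.areas)).all().all()

    def test_intensity_floor_idempotent(self):
        # the column maximum survives the floor, so the cut is unchanged
        # on re-application (the quantile cut, by contrast, is recomputed
        # on the survivors and intentionally tightens)
        rng = np.random.default_rng(44)
        areas = rng.uniform(0, 1000, size=(150, 3)) * (rng.random((150, 3)) < 0.8)
        table = make_table(areas, list("abc"))
        once = apply_intensity_filter(table, 0.02)
        twice = apply_intensity_filter(once, 0.02)
        pd.testing.assert_frame_equal(twice.areas, once.areas)

    def test_quantile_retains_expected_fraction(self):
        # cut over nonzero values: about (1-q) of an extract's nonzero
        # features survive
        rng = np.random.default_rng(45)
        areas = rng.uniform(0, 1000, size=(400, 2)) * (rng.random((400, 2)) < 0.5)
        table = make_table(areas, list("ab"))
        out = apply_quantile_filter(table, 0.75)
        for col in table.extracts:
            n_nonzero = (table.areas[col] > 0).sum()
            survived = (out.areas[col] > 0).sum()
            assert survived == pytest.approx(0.25 * n_nonzero, abs=2)

    def test_sequential_filters_monotone(self):
        rng = np.random.default_rng(43)
        areas = rng.uniform(0, 1000, size=(150, 3)) * (rng.random((150, 3)) < 0.8)
        table = make_table(areas, list("abc"))
        a = apply_intensity_filter(table, 0.02)
        b = apply_quantile_filter(a, 0.75)
        n_seq = (b.areas > 0).sum().sum()
        n_int = (a.areas > 0).sum().sum()
        n_q = (apply_quantile_filter(table, 0.75).areas > 0).sum().sum()
        assert n_seq <= min(n_int, n_q)
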