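"""Panel statistics, normalized response values R, S scores, eligibility
and compound prioritization."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from toxprofile import (
    ResponseMatrix,
    ToxicityLabels,
    classify_compound,
    coverage_threshold,
    eligibility,
    panel_profiles,
    panel_stats,
    prioritize,
    response_value,
    response_values,
    s_score,
    s_scores,
)
from conftest import brute_panel_counts, random_matrix

# Hand-evaluated normalized responses of the 3x3 toy matrix
#   a1  a2  a3            actives: A_t=4, A_i=(1,1,2), A_j=(1,2,1)
# c1  1  -1   0           inactives: I_t=2, I_i=(1,1,0), I_j=(1,0,1)
# c2  0   1   1
# c3 -1   0   1
TOY_R = {
    ("c1", "a1"): 4.0,    # 4/(1*1)
    ("c1", "a2"): -2.0,   # -2/(1*1)
    ("c1", "a3"): 0.0,
    ("c2", "a1"): 0.0,
    ("c2", "a2"): 2.0,    # 4/(1*2)
    ("c2", "a3"): 1.0,    # 4/(2*2)
    ("c3", "a1"): -2.0,   # -2/(1*1)
    ("c3", "a2"): 0.0,
    ("c3", "a3"): 2.0,    # 4/(2*1)
}
TOY_S = {"c1": 2.0, "c2": 3.0, "c3": 0.0}


class TestPanelStats:
    def test_two_by_two_recount(self):
        m = ResponseMatrix(pd.DataFrame(
            [[1, -1], [0, 1]], index=["c1", "c2"], columns=["a1", "a2"]
        ))
        stats = panel_stats(m, ["a1", "a2"])
        assert stats.a_t == 2 and stats.i_t == 1
        assert stats.a_j.tolist() == [1, 1]
        assert stats.i_j.tolist() == [1, 0]

    def test_all_zero_submatrix(self):
        m = ResponseMatrix(pd.DataFrame(
            np.zeros((3, 2), dtype=int), index=["c1", "c2", "c3"], columns=["a1", "a2"]
        ))
        stats = panel_stats(m, ["a1", "a2"])
        assert stats.a_t == 0 and stats.i_t == 0
        assert stats.a_i.sum() == 0 and stats.i_j.sum() == 0

    def test_single_active_entry(self):
        m = ResponseMatrix(pd.DataFrame(
            [[0, 1], [0, 0]], index=["c1", "c2"], columns=["a1", "a2"]
        ))
        stats = panel_stats(m, ["a1", "a2"])
        assert stats.a_t == 1
        assert (stats.a_i > 0).sum() == 1 and (stats.a_j > 0).sum() == 1

    def test_missing_panel_assay_named(self, toy_matrix):
        with pytest.raises(KeyError, match="a9"):
            panel_stats(toy_matrix, ["a1", "a9"])

    def test_conservation_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = random_matrix(rng, int(rng.integers(1, 15)), int(rng.integers(1, 8)))
            panel = list(m.assay_ids[: max(1, len(m.assay_ids) // 2)])
            stats = panel_stats(m, panel)
            exp = brute_panel_counts(m, panel)
            assert stats.a_t == exp["a_t"] and stats.i_t == exp["i_t"]
            assert stats.a_i.to_dict() == exp["a_i"]
            assert stats.i_i.to_dict() == exp["i_i"]
            assert int(stats.a_i.sum()) == int(stats.a_j.sum()) == stats.a_t
            assert int(stats.i_i.sum()) == int(stats.i_j.sum()) == stats.i_t


class TestResponseValue:
    def test_zero_entry_contributes_exactly_zero(self, toy_matrix):
        stats = panel_stats(toy_matrix, toy_matrix.assay_ids)
        assert response_value(0, stats, "a1", "c1") == 0.0

    def test_toy_matrix_golden_values(self, toy_matrix):
        stats = panel_stats(toy_matrix, toy_matrix.assay_ids)
        for (cid, aid), expected in TOY_R.items():
            got = response_value(toy_matrix.entry(cid, aid), stats, aid, cid)
            assert got == pytest.approx(expected, abs=1e-12)
        r = response_values(toy_matrix, toy_matrix.assay_ids)
        for (cid, aid), expected in TOY_R.items():
            assert r.at[cid, aid] == pytest.approx(expected, abs=1e-12)

    def test_deterministic(self, toy_matrix):
        stats = panel_stats(toy_matrix, toy_matrix.assay_ids)
        assert response_value(1, stats, "a1", "c1") == response_value(1, stats, "a1", "c1")

    def test_invalid_entry_rejected(self, toy_matrix):
        stats = panel_stats(toy_matrix, toy_matrix.assay_ids)
        with pytest.raises(ValueError):
            response_value(2, stats, "a1", "c1")


class TestSScore:
    def test_toy_matrix_golden_sums(self, toy_matrix):
        panel = toy_matrix.assay_ids
        for cid, expected in TOY_S.items():
            assert s_score(toy_matrix, panel, cid) == pytest.approx(expected, abs=1e-12)

    def test_untested_compound_scores_exactly_zero(self):
        m = ResponseMatrix(pd.DataFrame(
            [[1, -1], [0, 0]], index=["c1", "c2"], columns=["a1", "a2"]
        ))
        assert s_score(m, ["a1", "a2"], "c2") == 0.0

    def test_invariant_to_panel_order(self, toy_matrix):
        s1 = s_scores(toy_matrix, ["a1", "a2", "a3"])
        s2 = s_scores(toy_matrix, ["a3", "a1", "a2"])
        pd.testing.assert_series_equal(s1, s2)

    def test_invariant_to_row_order(self, toy_matrix):
        shuffled = ResponseMatrix(toy_matrix.data.loc[["c3", "c1", "c2"]])
        s1 = s_scores(toy_matrix, toy_matrix.assay_ids).sort_index()
        s2 = s_scores(shuffled, shuffled.assay_ids).sort_index()
        pd.testing.assert_series_equal(s1, s2)

    def test_unknown_compound_rejected(self, toy_matrix):
        with pytest.raises(KeyError):
            s_score(toy_matrix, toy_matrix.assay_ids, "c99")

    def test_full_scope_uses_whole_matrix_counts(self):
        df = pd.DataFrame(
            [[1, 1], [1, 0]], index=["c1", "c2"], columns=["a1", "a2"]
        )
        m = ResponseMatrix(df)
        # panel = a1 only; full scope: A_t=3, A_i(a1)=2, A_j(c1)=2 -> R=3/4
        assert s_score(m, ["a1"], "c1", stats_scope="full") == pytest.approx(0.75)
        # panel scope: A_t=2, A_i(a1)=2, A_j(c1)=1 -> R=1
        assert s_score(m, ["a1"], "c1", stats_scope="panel") == pytest.approx(1.0)


class TestEligibility:
    @pytest.mark.parametrize(
        "n_active, n_reported, expected",
        [
            (3, 3, True),     # actives clause
            (0, 25, True),    # coverage clause: 25 of 47
            (0, 24, False),
            (2, 10, False),   # fails both
            (5, 5, True),
        ],
    )
    def test_reference_panel_of_47(self, n_active, n_reported, expected):
        assert eligibility(n_active, n_reported, panel_size=47) is expected

    def test_coverage_threshold_reproduces_25_for_47(self):
        assert coverage_threshold(47, 0.5) == 25

    @pytest.mark.parametrize("size, expected", [(4, 3), (46, 24), (48, 25), (1, 2)])
    def test_coverage_threshold_is_strict_majority(self, size, expected):
        assert coverage_threshold(size, 0.5) == expected

    def test_unlabeled_compounds_use_only_actives_clause(self):
        assert eligibility(0, 40, panel_size=47, labeled=False) is False
        assert eligibility(3, 3, panel_size=47, labeled=False) is True


class TestClassifyCompound:
    @pytest.mark.parametrize(
        "s, expected", [(0.7, True), (0.0, False), (-2.1, False), (1e-9, True)]
    )
    def test_strict_zero_boundary(self, s, expected):
        assert classify_compound(s) is expected


@st.composite
def _matrix_and_panel(draw):
    n_c = draw(st.integers(1, 12))
    n_a = draw(st.integers(1, 8))
    seed = draw(st.integers(0, 10_000))
    rng = np.random.default_rng(seed)
    m = random_matrix(rng, n_c, n_a)
    k = draw(st.integers(1, n_a))
    return m, list(m.assay_ids[:k])


class TestInvariants:
    @given(_matrix_and_panel())
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_conservation_on_generated_panels(self, mp):
        m, panel = mp
        stats = panel_stats(m, panel)
        assert int(stats.a_i.sum()) == int(stats.a_j.sum()) == stats.a_t
        assert int(stats.i_i.sum()) == int(stats.i_j.sum()) == stats.i_t

    @given(_matrix_and_panel())
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_zero_entries_contribute_exactly_zero(self, mp):
        m, panel = mp
        r = response_values(m, panel)
        sub = m.data[panel]
        assert (r.to_numpy()[(sub == 0).to_numpy()] == 0.0).all()
        zero_rows = (sub != 0).sum(axis=1) == 0
        s = s_scores(m, panel)
        assert (s[zero_rows] == 0.0).all()


class TestPrioritize:
    def _labels(self, m):
        classes = ["toxic" if i % 2 == 0 else "nontoxic" for i in range(len(m.compound_ids))]
        return ToxicityLabels(classes=pd.Series(classes, index=m.compound_ids))

    def test_all_ineligible_gives_empty_table(self, caplog):
        m = ResponseMatrix(pd.DataFrame(
            np.zeros((3, 4), dtype=int),
            index=["c1", "c2", "c3"], columns=list("wxyz"),
        ))
        with caplog.at_level("WARNING"):
            df = prioritize(m, list("wxyz"), labels=self._labels(m))
        assert df.empty
        assert "eligibility" in caplog.text

    def test_sorted_by_score_descending(self):
        rng = np.random.default_rng(55)
        m = random_matrix(rng, 30, 6, p=(0.2, 0.4, 0.4))
        df = prioritize(m, m.assay_ids, labels=self._labels(m), min_actives=1)
        s = df["s_score"].to_numpy()
        assert (s[:-1] >= s[1:]).all()
        # ties broken by compound id ascending
        for val, grp in df.groupby("s_score"):
            ids = grp["compound_id"].tolist()
            assert ids == sorted(ids)

    def test_eligibility_columns_consistent(self):
        rng = np.random.default_rng(56)
        m = random_matrix(rng, 25, 8, p=(0.5, 0.3, 0.2))
        df = prioritize(m, m.assay_ids, labels=self._labels(m))
        for _, row in df.iterrows():
            assert row.n_reported == row.n_active + row.n_inactive
            assert row.n_reported <= 8
            assert row.eligible
            assert row.predicted_toxic == (row.s_score > 0)

    def test_unlabeled_compounds_marked_unknown(self, toy_matrix):
        labels = ToxicityLabels.from_classes({"c1": "toxic"})
        df = prioritize(toy_matrix, toy_matrix.assay_ids, labels=labels, min_actives=1)
        lab = dict(zip(df.compound_id, df.label))
        assert lab["c1"] == "toxic"
        assert all(v == "unknown" for k, v in lab.items() if k != "c1")

    def test_planted_toxicants_rank_higher(self):
        """Compounds built active-in-panel rank above inactive ones."""
        rng = np.random.default_rng(57)
        n = 40
        toxic = np.arange(n) < 15
        vals = np.where(
            toxic[:, None], rng.choice([1, -1], (n, 6), p=[0.8, 0.2]),
            rng.choice([1, -1], (n, 6), p=[0.1, 0.9]),
        )
        m = ResponseMatrix(pd.DataFrame(
            vals, index=[f"c{i:02d}" for i in range(n)], columns=list("abcdef")
        ))
        labels = ToxicityLabels(classes=pd.Series(
            np.where(toxic, "toxic", "nontoxic"), index=m.compound_ids
        ))
        df = prioritize(m, m.assay_ids, labels=labels, min_actives=1)
        ranks = pd.Series(np.arange(len(df)), index=df.compound_id)
        toxic_ids = [c for c, t in zip(m.compound_ids, toxic) if t]
        nontoxic_ids = [c for c, t in zip(m.compound_ids, toxic) if not t]
        assert ranks.reindex(toxic_ids).mean() < ranks.reindex(nontoxic_ids).mean()

    def test_empty_panel_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            prioritize(toy_matrix, [])

    def test_profiles_preserve_entries_in_given_order(self, toy_matrix):
        prof = panel_profiles(toy_matrix, ["a1", "a3"], ["c3", "c1"])
        assert prof.index.tolist() == ["c3", "c1"]
        assert prof.loc["c3"].tolist() == [-1, 1]

    def test_heatmap_export_writes_png(self, toy_matrix, tmp_path):
        pytest.importorskip("matplotlib")
        from toxprofile import export_heatmap

        out = tmp_path / "profiles.png"
        export_heatmap(panel_profiles(toy_matrix, toy_matrix.assay_ids), out)
        assert out.stat().st_size > 0
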