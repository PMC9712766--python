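import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosphonet import quant
from phosphonet.core import RatioMatrix, SampleDesign

from conftest import random_matrix


def _mat(rows, index=None, columns=None):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr,
        index=index or [f"S{i}" for i in range(arr.shape[0])],
        columns=columns or [f"c{j}" for j in range(arr.shape[1])],
    )


class TestCenterNormalize:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([2, 4, 6], [0.5, 1.0, 1.5]),
            ([5, 5, 5], [1.0, 1.0, 1.0]),
            ([2, np.nan, 6], [0.5, np.nan, 1.5]),  # mean over present values = 4
        ],
    )
    def test_row_examples(self, row, expected):
        out = quant.center_normalize(_mat([row]))
        np.testing.assert_allclose(out.values.iloc[0].to_numpy(), expected)
        assert out.stage == "centered"

    def test_all_missing_row_dropped_with_warning(self, caplog):
        m = _mat([[1, 2, 3], [np.nan, np.nan, np.nan]])
        with caplog.at_level("WARNING", logger="phosphonet"):
            out = quant.center_normalize(m)
        assert list(out.values.index) == ["S0"]
        assert "dropped 1" in caplog.text

    def test_row_means_equal_one(self):
        rng = np.random.default_rng(0)
        out = quant.center_normalize(random_matrix(rng))
        np.testing.assert_allclose(out.values.mean(axis=1, skipna=True), 1.0, atol=1e-9)


class TestProteinCorrect:
    def _site_table(self):
        return pd.DataFrame(
            {"site_id": ["P1_S1", "P1_S2"], "protein_id": ["P1", "P1"],
             "residue": ["S", "S"], "position": [1, 2]}
        )

    def test_identity_when_protein_flat(self):
        site = RatioMatrix(_mat([[0.5, 1.0, 1.5]], index=["P1_S1"]), "centered")
        prot = RatioMatrix(_mat([[1.0, 1.0, 1.0]], index=["P1"]), "centered")
        out = quant.protein_correct(site, prot, self._site_table())
        np.testing.assert_allclose(out.values.to_numpy(), [[0.5, 1.0, 1.5]])

    def test_self_division_gives_ones(self):
        site = RatioMatrix(_mat([[0.5, 1.5]], index=["P1_S1"]), "centered")
        prot = RatioMatrix(_mat([[0.5, 1.5]], index=["P1"]), "centered")
        out = quant.protein_correct(site, prot, self._site_table())
        np.testing.assert_allclose(out.values.to_numpy(), [[1.0, 1.0]])

    def test_elementwise_division(self):
        site = RatioMatrix(_mat([[0.5, 2.0]], index=["P1_S1"]), "centered")
        prot = RatioMatrix(_mat([[0.5, 1.0]], index=["P1"]), "centered")
        out = quant.protein_correct(site, prot, self._site_table())
        np.testing.assert_allclose(out.values.to_numpy(), [[1.0, 2.0]])

    def test_unquantified_protein_passes_through_flagged(self):
        table = pd.DataFrame(
            {"site_id": ["PX_S1"], "protein_id": ["PX"], "residue": ["S"], "position": [1]}
        )
        site = RatioMatrix(_mat([[0.5, 1.5]], index=["PX_S1"]), "centered")
        prot = RatioMatrix(_mat([[1.0, 1.0]], index=["P1"]), "centered")
        out = quant.protein_correct(site, prot, table)
        np.testing.assert_allclose(out.values.to_numpy(), [[0.5, 1.5]])
        assert out.uncorrected == ("PX_S1",)

    def test_planted_protein_factor_cancels_exactly(self):
        """A per-sample protein profile shared by protein and site intensities
        is fully removed: sites with sample-constant regulation come out at
        exactly 1 whatever the profile."""
        rng = np.random.default_rng(1)
        profile = rng.uniform(0.2, 5.0, 6)  # arbitrary positive per-sample vector
        stoich = np.array([[0.3], [2.0]])  # constant site-level stoichiometry
        site_raw = _mat(stoich * profile, index=["P1_S1", "P1_S2"])
        prot_raw = _mat(profile[None, :] * 7.0, index=["P1"])
        out = quant.protein_correct(
            quant.center_normalize(site_raw), quant.center_normalize(prot_raw),
            self._site_table(),
        )
        np.testing.assert_allclose(out.values.to_numpy(), 1.0, atol=1e-12)

    def test_protein_factor_invariance_of_contrasts(self):
        """With arbitrary site-level regulation, changing the per-sample protein
        profile shifts each corrected log2 row by a constant only: every
        cross-sample contrast is exactly invariant."""
        rng = np.random.default_rng(2)
        reg = rng.uniform(0.5, 2.0, (4, 6))  # site-level regulation
        table = pd.DataFrame(
            {"site_id": [f"P1_S{i}" for i in range(4)], "protein_id": ["P1"] * 4,
             "residue": ["S"] * 4, "position": list(range(1, 5))}
        )

        def corrected_log2(profile):
            site_raw = _mat(reg * profile, index=table["site_id"].tolist())
            prot_raw = _mat(profile[None, :], index=["P1"])
            out = quant.protein_correct(
                quant.center_normalize(site_raw), quant.center_normalize(prot_raw), table
            )
            return quant.log2_transform(out).values.to_numpy()

        a = corrected_log2(np.ones(6))
        b = corrected_log2(rng.uniform(0.1, 10.0, 6))
        centered_a = a - a.mean(axis=1, keepdims=True)
        centered_b = b - b.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(centered_a, centered_b, atol=1e-9)


class TestLog2Transform:
    def test_examples(self):
        out = quant.log2_transform(RatioMatrix(_mat([[0.5, 1.0, 8.0]]), "centered"))
        np.testing.assert_allclose(out.values.to_numpy(), [[-1.0, 0.0, 3.0]])
        assert out.stage == "log2"

    def test_nonpositive_set_missing(self, caplog):
        with caplog.at_level("WARNING", logger="phosphonet"):
            out = quant.log2_transform(RatioMatrix(_mat([[0.0, 2.0]]), "centered"))
        assert np.isnan(out.values.iloc[0, 0]) and out.values.iloc[0, 1] == 1.0


class TestDifferentialTest:
    def _run(self, a_vals, b_vals, design, **kw):
        row = {f"a{i + 1}": v for i, v in enumerate(a_vals)}
        row.update({f"b{i + 1}": v for i, v in enumerate(b_vals)})
        mat = RatioMatrix(pd.DataFrame([row], index=["S0"]), "log2")
        return quant.differential_test(mat, design, "A", "B", **kw)

    @pytest.fixture
    def design(self):
        return SampleDesign(
            {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
            group_order=["A", "B"],
        )

    def test_identical_groups_null(self, design):
        res = self._run([1, 2, 3], [1, 2, 3], design)
        r = res.iloc[0]
        assert r.t == 0 and r.p_value == 1 and r.log2_fc == 0

    def test_closed_form_example(self, design):
        # pooled-variance t for A=[1,2,3] vs B=[2,3,4]
        res = self._run([1, 2, 3], [2, 3, 4], design)
        r = res.iloc[0]
        assert r.t == pytest.approx(-1.224744871, abs=1e-8)
        assert r.df == 4
        assert r.p_value == pytest.approx(0.287954, abs=1e-4)

    def test_matches_independent_t_on_random_instances(self, design):
        """Pooled and one-tailed t match scipy.stats.ttest_ind to 1e-10."""
        rng = np.random.default_rng(3)
        for _ in range(300):
            a = rng.normal(0, 1, int(rng.integers(3, 8)))
            b = rng.normal(0.5, 2, int(rng.integers(3, 8)))
            d = SampleDesign(
                {f"a{i + 1}": "A" for i in range(len(a))}
                | {f"b{i + 1}": "B" for i in range(len(b))},
                group_order=["A", "B"],
            )
            two = self._run(a, b, d).iloc[0]
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert two.t == pytest.approx(ref.statistic, abs=1e-10)
            assert two.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            one = self._run(a, b, d, tails="one").iloc[0]
            ref1 = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
            assert one.p_value == pytest.approx(ref1.pvalue, abs=1e-10)

    def test_welch_flag(self, design):
        res = self._run([1.0, 2, 3], [2.0, 4, 9], design, welch=True)
        ref = stats.ttest_ind([1.0, 2, 3], [2.0, 4, 9], equal_var=False)
        assert res.iloc[0].t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.iloc[0].p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_unequal_means_degenerate(self, design):
        res = self._run([1, 1, 1], [2, 2, 2], design)
        r = res.iloc[0]
        assert r.p_value == 0 and r.degenerate

    def test_too_few_values_reported_untested(self, design):
        res = self._run([1.0, np.nan, np.nan], [2.0, 3.0, 4.0], design)
        r = res.iloc[0]
        assert not r.tested and np.isnan(r.p_value)

    def test_planted_effect_detected(self):
        """A +1.0 log2 shift with n=15/15 and noise SD 0.3 is significant and
        the observed fold change is near 2."""
        rng = np.random.default_rng(4)
        n = 15
        design = SampleDesign(
            {f"a{i}": "A" for i in range(n)} | {f"b{i}": "B" for i in range(n)},
            group_order=["A", "B"],
        )
        rows = rng.normal(0, 0.3, (50, 2 * n))
        rows[:, :n] += 1.0
        mat = RatioMatrix(
            pd.DataFrame(rows, index=[f"S{i}" for i in range(50)],
                         columns=list(design.mapping)),
            "log2",
        )
        res = quant.differential_test(mat, design, "A", "B")
        assert res["significant"].all()
        se = res["fc"].std(ddof=1) / np.sqrt(len(res))
        assert res["fc"].mean() == pytest.approx(2.0, abs=3 * se)

    def test_unknown_group_raises(self, design):
        mat = RatioMatrix(_mat([[1, 2, 3, 4, 5, 6]], columns=list(design.mapping)), "log2")
        with pytest.raises(KeyError):
            quant.differential_test(mat, design, "A", "Z")


class TestSignificantSites:
    def _results(self, ps, fcs):
        return pd.DataFrame(
            {
                "site_id": [f"S{i + 1}" for i in range(len(ps))],
                "comparison": "A_vs_B",
                "p_value": ps,
                "fc": fcs,
                "log2_fc": np.log2(fcs),
                "tested": True,
            }
        )

    def test_threshold_conjunction(self):
        up, down = quant.significant_sites(self._results([0.04], [1.6]))
        assert up == {"S1"} and down == set()
        up, down = quant.significant_sites(self._results([0.04], [1.4]))
        assert up == set() and down == set()

    def test_hand_enumerated_partition(self):
        up, down = quant.significant_sites(
            self._results([0.01, 0.2, 0.01, 0.01, 0.06], [2.0, 3.0, 0.5, 1.2, 1.8])
        )
        assert up == {"S1"} and down == {"S3"}


class TestOverlapSets:
    def test_two_set_venn(self):
        regions = quant.overlap_sets({"A": {"x", "y"}, "B": {"y", "z"}})
        assert regions[frozenset({"A"})] == {"x"}
        assert regions[frozenset({"A", "B"})] == {"y"}
        assert regions[frozenset({"B"})] == {"z"}

    def test_identical_sets_all_in_intersection(self):
        regions = quant.overlap_sets({"A": {"x", "y"}, "B": {"x", "y"}})
        assert regions[frozenset({"A", "B"})] == {"x", "y"}
        assert regions[frozenset({"A"})] == set()

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(5)
        ids = [f"i{k}" for k in range(60)]
        sets = {n: {i for i in ids if rng.random() < 0.4} for n in ("A", "B", "C")}
        regions = quant.overlap_sets(sets)
        # brute force: classify every universe element by its membership tuple
        union = set().union(*sets.values())
        assert sum(len(v) for v in regions.values()) == len(union)
        for combo, members in regions.items():
            for item in members:
                assert all((item in sets[n]) == (n in combo) for n in sets)

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            quant.overlap_sets({"A": {"x"}})
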