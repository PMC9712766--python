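from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from phosphonet import kinase
from phosphonet.core import AMINO_ACIDS
from phosphonet.simulate import MotifSpec


def brute_force_es(metrics, hit_positions, weight_exponent=0.0):
    """Running-sum ES by explicit prefix enumeration (independent oracle)."""
    n = len(metrics)
    hits = set(hit_positions)
    weights = {i: abs(metrics[i]) ** weight_exponent for i in hits}
    total = sum(weights.values())
    running = []
    value = 0.0
    for i in range(n):
        if i in hits:
            value += weights[i] / total if total else 1.0 / len(hits)
        else:
            value -= 1.0 / (n - len(hits))
        running.append(value)
    mx = max(abs(v) for v in running)
    # same tie convention as the implementation: earliest rank within 1e-12
    for v in running:
        if abs(v) >= mx - 1e-12 * max(1.0, mx):
            return v


def _ranked(metrics, ids=None):
    ids = ids or [f"S{i}" for i in range(len(metrics))]
    return pd.DataFrame({"site_id": ids, "metric": metrics})


class TestPSSM:
    def _toy_pssms(self):
        w1 = pd.DataFrame(0.0, index=[-1, 0, 1], columns=list(AMINO_ACIDS))
        w1.loc[-1, "K"] = 2.0
        w1.loc[1, "P"] = 1.0
        w2 = pd.DataFrame(0.0, index=[-1, 0, 1], columns=list(AMINO_ACIDS))
        w2.loc[1, "D"] = 3.0
        return [
            kinase.KinasePSSM("KA", w1, score_threshold=2.5),
            kinase.KinasePSSM("KB", w2, score_threshold=3.0),
        ]

    def _windows(self):
        return pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3", "s4", "s5"],
                "window": ["KKSPA", "AKSPA", "AASDA", "XXSDA", "AASAA"],
            }
        )

    def test_hand_summed_scores_and_membership(self):
        out = kinase.score_substrates(self._windows(), self._toy_pssms())
        # KA: s1 = K@-1 (2.0) + P@+1 (1.0) = 3.0 >= 2.5; s2 identical flanks
        assert out["KA"] == {"s1": 3.0, "s2": 3.0}
        # KB: D@+1 = 3.0 for s3 and s4 (X contributes 0 elsewhere)
        assert out["KB"] == {"s3": 3.0, "s4": 3.0}

    def test_max_scoring_window_reaches_maximum(self):
        pssm = self._toy_pssms()[0]
        assert pssm.score("KKSPA") == 3.0  # argmax residue at every weighted offset

    def test_all_zero_pssm_threshold_zero_matches_everything(self):
        w = pd.DataFrame(0.0, index=[-1, 0, 1], columns=list(AMINO_ACIDS))
        out = kinase.score_substrates(
            self._windows(), [kinase.KinasePSSM("K0", w, score_threshold=0.0)]
        )
        assert set(out["K0"]) == {"s1", "s2", "s3", "s4", "s5"}

    def test_incompatible_length_rejected(self):
        w = pd.DataFrame(0.0, index=range(-6, 7), columns=list(AMINO_ACIDS))
        pssm = kinase.KinasePSSM("KW", w, score_threshold=0.0)
        with pytest.raises(ValueError, match="half-width"):
            kinase.score_substrates(self._windows(), [pssm])

    def test_pssm_from_motif_spec_separates_consensus_from_noise(self):
        pssm = kinase.pssm_from_motif_spec("K1", MotifSpec({-3: "R", -2: "R"}), h=6)
        consensus = "XXXRRXSXXXXXX"
        random_w = "ACDEFGSHIKLMN"
        assert pssm.score(consensus) >= pssm.score_threshold > pssm.score(random_w)


class TestRankSites:
    def _diff(self, site_ids, log2_fcs, tested=None):
        return pd.DataFrame(
            {
                "site_id": site_ids,
                "log2_fc": log2_fcs,
                "tested": tested if tested is not None else [True] * len(site_ids),
            }
        )

    def test_descending_order(self):
        ranked = kinase.rank_sites(self._diff(["a", "b", "c"], [0.0, 1.0, -1.0]))
        assert ranked["site_id"].tolist() == ["b", "a", "c"]

    def test_ties_broken_lexicographically(self):
        ranked = kinase.rank_sites(self._diff(["z", "a", "m"], [1.0, 1.0, 1.0]))
        assert ranked["site_id"].tolist() == ["a", "m", "z"]

    def test_untested_excluded(self):
        ranked = kinase.rank_sites(
            self._diff(["a", "b"], [1.0, 2.0], tested=[True, False])
        )
        assert ranked["site_id"].tolist() == ["a"]

    def test_matches_independent_sort(self):
        rng = np.random.default_rng(0)
        ids = [f"S{i}" for i in range(50)]
        fc = rng.choice([-1.0, 0.0, 0.5, 1.0], size=50)
        ranked = kinase.rank_sites(self._diff(ids, fc))
        oracle = sorted(zip(ids, fc), key=lambda t: (-t[1], t[0]))
        assert ranked["site_id"].tolist() == [i for i, _ in oracle]


class TestEnrichmentScore:
    def test_hits_at_top_unweighted_es_is_one(self):
        metrics = np.linspace(3, -3, 10)
        hit = np.zeros(10, dtype=bool)
        hit[:3] = True
        assert kinase.enrichment_score(metrics, hit, 0.0) == pytest.approx(1.0)

    def test_reversal_negates_unweighted_es(self):
        rng = np.random.default_rng(1)
        metrics = np.sort(rng.normal(size=12))[::-1]
        hit = rng.random(12) < 0.4
        if not 0 < hit.sum() < 12:
            hit[:3] = True
            hit[3:] = False
        es = kinase.enrichment_score(metrics, hit, 0.0)
        es_rev = kinase.enrichment_score(metrics[::-1], hit[::-1], 0.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_brute_force_example(self):
        # N=10, hits at ranks 1, 4, 9 (0-based 0, 3, 8), unweighted
        metrics = np.linspace(2, -2, 10)
        hit = np.zeros(10, dtype=bool)
        hit[[0, 3, 8]] = True
        expected = brute_force_es(list(metrics), {0, 3, 8}, 0.0)
        assert kinase.enrichment_score(metrics, hit, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            metrics = np.sort(rng.normal(size=n))[::-1]
            hit = np.zeros(n, dtype=bool)
            k = int(rng.integers(1, n))
            hit[rng.choice(n, size=k, replace=False)] = True
            es = kinase.enrichment_score(metrics, hit, rng.choice([0.0, 1.0]))
            assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12


class TestKsea:
    def _ranked(self, n=40, seed=3):
        rng = np.random.default_rng(seed)
        metrics = np.sort(rng.normal(size=n))[::-1]
        return _ranked(list(metrics))

    def test_deterministic_under_seed(self):
        ranked = self._ranked()
        sets = {"K1": {"S0", "S1", "S2", "S5"}, "K2": {"S30", "S35", "S39"}}
        r1 = kinase.ksea(ranked, sets, n_perm=200, seed=42)
        r2 = kinase.ksea(ranked, sets, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_result_independent_of_set_ordering(self):
        ranked = self._ranked()
        sets = {"K1": {"S0", "S1", "S2", "S5"}, "K2": {"S30", "S35", "S39"}}
        r1 = kinase.ksea(ranked, sets, n_perm=100, seed=7)
        r2 = kinase.ksea(ranked, dict(reversed(list(sets.items()))), n_perm=100, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_top_concentrated_set_scores_positive_and_significant(self):
        ranked = self._ranked(n=60)
        sets = {"KTOP": {f"S{i}" for i in range(8)},
                "KNULL": {f"S{i}" for i in range(7, 60, 8)}}
        res = kinase.ksea(ranked, sets, n_perm=500, seed=1).set_index("kinase")
        assert res.loc["KTOP", "es"] > 0
        assert res.loc["KTOP", "direction"] == "activated"
        assert res.loc["KTOP", "perm_p"] < 0.05
        assert res.loc["KNULL", "perm_p"] > 0.05

    def test_small_sets_skipped(self):
        ranked = self._ranked()
        res = kinase.ksea(ranked, {"K1": {"S0", "S1"}}, n_perm=50, seed=0)
        assert len(res) == 0

    def test_nes_sign_matches_es(self):
        ranked = self._ranked(n=50, seed=9)
        sets = {f"K{i}": set(np.random.default_rng(i).choice(
            [f"S{j}" for j in range(50)], size=6, replace=False)) for i in range(5)}
        res = kinase.ksea(ranked, sets, n_perm=100, seed=5)
        assert (np.sign(res["nes"]) == np.sign(res["es"])).all()


class TestTopKinases:
    def _activities(self, nes):
        return pd.DataFrame(
            {"kinase": [f"K{i}" for i in range(len(nes))], "nes": nes}
        )

    def test_fewer_than_k_returns_all(self):
        act = self._activities([2.1, -1.3, 0.2])
        up, down = kinase.top_kinases(act, k=10)
        assert up == ["K0", "K2"] and down == ["K1"]

    def test_head_is_largest_nes(self):
        act = self._activities([2.1, -1.3, 0.2])
        up, down = kinase.top_kinases(act, k=1)
        assert up == ["K0"] and down == ["K1"]

    def test_matches_oracle_sort(self):
        rng = np.random.default_rng(6)
        nes = rng.normal(size=30)
        act = self._activities(list(nes))
        up, down = kinase.top_kinases(act, k=10)
        order = sorted(
            ((n, f"K{i}") for i, n in enumerate(nes) if n > 0),
            key=lambda t: (-t[0], t[1]),
        )
        assert up == [k for _, k in order[:10]]
        order_d = sorted(
            ((n, f"K{i}") for i, n in enumerate(nes) if n < 0),
            key=lambda t: (t[0], t[1]),
        )
        assert down == [k for _, k in order_d[:10]]
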