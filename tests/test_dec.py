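import numpy as np
import pytest
from scipy.linalg import expm

import islandrad as ir
from islandrad.dec import build_q, state_name

from conftest import EMERGENCE_AGES, random_ranges
from oracles import dec_enumeration, series_expm


def two_area_params(d=0.1, e=0.05, strata=None):
    return ir.DECParams(d=d, e=e, areas=("A", "B"), strata=strata)


class TestBuildQ:
    def test_single_area(self):
        p = ir.DECParams(d=0.2, e=0.07, areas=("A",))
        Q = build_q(p)
        # states: null (absorbing), {A}
        assert Q[1, 0] == pytest.approx(0.07)
        assert Q[1, 1] == pytest.approx(-0.07)
        assert np.all(Q[0] == 0)

    def test_two_area_rates(self):
        Q = build_q(two_area_params())
        A, B, AB = 0b01, 0b10, 0b11
        assert Q[A, AB] == pytest.approx(0.1)  # gain adjacent area
        assert Q[AB, A] == pytest.approx(0.05)  # lose one area
        assert Q[A, B] == 0.0  # no direct range jump
        assert Q[A, 0] == pytest.approx(0.05)
        assert np.allclose(Q.sum(axis=1), 0.0)

    def test_gain_rate_scales_with_occupancy(self):
        p = ir.DECParams(d=0.1, e=0.0, areas=("A", "B", "C"))
        Q = build_q(p)
        assert Q[0b011, 0b111] == pytest.approx(0.2)  # two source areas

    def test_unavailable_area_unreachable(self):
        strata = ir.Stratification(boundaries=(1.0,), available=(0b11, 0b01))
        Q_old = build_q(two_area_params(strata=strata), stratum=1)
        B_states = [s for s in range(4) if s & 0b10]
        for s in range(4):
            for t in B_states:
                assert Q_old[s, t] == 0.0

    def test_transition_matrix_rows_are_distributions(self):
        p = ir.DECParams(d=0.3, e=0.1, areas=("A", "B", "C"))
        for t in (0.01, 0.5, 3.0, 20.0):
            P = expm(build_q(p) * t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() > -1e-12

    def test_pade_matches_series_expansion(self):
        p = ir.DECParams(d=0.07, e=0.02, areas=ir.HAWAIIAN_ISLANDS)
        Q = build_q(p)
        for t in (0.3, 2.0, 8.0):
            assert np.allclose(
                expm(Q * t), series_expm(Q, t), atol=1e-10
            )


class TestDecLoglik:
    def test_single_area_no_events_possible(self, yule20):
        p = ir.DECParams(d=0.4, e=0.0, areas=("A",))
        rt = ir.RangeTable(
            areas=("A",), ranges={t: frozenset({"A"}) for t in yule20.tip_labels}
        )
        assert ir.dec_loglik(yule20, rt, p) == pytest.approx(0.0, abs=1e-12)

    def test_two_tip_brute_force(self):
        """Hand-built 2-tip 2-area likelihood: explicit matrix exponential,
        explicit sum over root states and cladogenetic splits."""
        d, e, t = 0.1, 0.05, 1.0
        Q = np.zeros((4, 4))
        Q[1, 3] = d; Q[1, 0] = e
        Q[2, 3] = d; Q[2, 0] = e
        Q[3, 1] = e; Q[3, 2] = e
        np.fill_diagonal(Q, -Q.sum(axis=1))
        P = expm(Q * t)
        scen = {1: [(1, 1)], 2: [(2, 2)],
                3: [(1, 3), (3, 1), (2, 3), (3, 2), (1, 2), (2, 1)]}
        total = sum(
            sum(P[l, 1] * P[r, 2] for l, r in scen[s]) / len(scen[s]) / 3
            for s in (1, 2, 3)
        )
        chron = ir.read_newick("(x:1,y:1);")
        rt = ir.RangeTable(
            areas=("A", "B"),
            ranges={"x": frozenset({"A"}), "y": frozenset({"B"})},
        )
        ll = ir.dec_loglik(chron, rt, two_area_params())
        assert ll == pytest.approx(np.log(total), abs=1e-8)

    @pytest.mark.parametrize("n_tips,k,seed", [(3, 2, 0), (4, 3, 1), (5, 3, 2)])
    def test_pruning_matches_enumeration(self, n_tips, k, seed):
        rng = np.random.default_rng(seed)
        chron = ir.simulate_chronogram(
            ir.TreeSimSpec(lam=1.0, n_tips=n_tips), rng
        )
        areas = ("A", "B", "C")[:k]
        rt = random_ranges(chron, areas, rng)
        d, e = rng.uniform(0.01, 0.5, size=2)
        ll = ir.dec_loglik(chron, rt, ir.DECParams(d=d, e=e, areas=areas))
        ll_enum, _ = dec_enumeration(chron, rt, d, e, k)
        assert ll == pytest.approx(ll_enum, abs=1e-8)

    def test_invariant_to_tip_and_area_order(self):
        rng = np.random.default_rng(3)
        chron = ir.simulate_chronogram(ir.TreeSimSpec(lam=0.8, n_tips=8), rng)
        areas = ("A", "B", "C")
        rt = random_ranges(chron, areas, rng)
        p = ir.DECParams(d=0.1, e=0.03, areas=areas)
        ll = ir.dec_loglik(chron, rt, p)
        # rotate the tree by re-reading a ladderised copy (same topology)
        chron2 = ir.read_newick(chron.newick())
        assert ir.dec_loglik(chron2, rt, p) == pytest.approx(ll, abs=1e-10)
        # reverse the area order and re-encode ranges
        areas_r = areas[::-1]
        rt_r = ir.RangeTable(
            areas=areas_r, ranges={t: rt[t] for t in chron.tip_labels}
        )
        p_r = ir.DECParams(d=0.1, e=0.03, areas=areas_r)
        assert ir.dec_loglik(chron, rt_r, p_r) == pytest.approx(ll, abs=1e-10)

    def test_polytomy_rejected(self):
        chron = ir.read_newick("(A:1,B:1,C:1);")
        rt = ir.RangeTable(
            areas=("A",), ranges={t: frozenset({"A"}) for t in "ABC"}
        )
        with pytest.raises(ValueError, match="bifurcating"):
            ir.dec_loglik(chron, rt, ir.DECParams(d=0.1, e=0.0, areas=("A",)))

    def test_stratified_not_above_unconstrained(self):
        rng = np.random.default_rng(8)
        strata = ir.strata_from_emergence(ir.HAWAIIAN_ISLANDS, EMERGENCE_AGES)
        for _ in range(5):
            chron = ir.simulate_chronogram(
                ir.TreeSimSpec(lam=1.2, crown_age=4.5), rng
            )
            avail_root = 0b0001  # only Kauai predates 4.5 my
            rt = random_ranges(chron, ir.HAWAIIAN_ISLANDS, rng)
            p_u = ir.DECParams(d=0.1, e=0.02, areas=ir.HAWAIIAN_ISLANDS)
            p_ts = ir.DECParams(
                d=0.1, e=0.02, areas=ir.HAWAIIAN_ISLANDS, strata=strata
            )
            assert ir.dec_loglik(chron, rt, p_u) >= ir.dec_loglik(
                chron, rt, p_ts
            ) - 1e-9

    def test_root_predating_all_islands_rejected(self):
        chron = ir.read_newick("(x:6,y:6);")
        strata = ir.strata_from_emergence(ir.HAWAIIAN_ISLANDS, EMERGENCE_AGES)
        rt = ir.RangeTable(
            areas=ir.HAWAIIAN_ISLANDS,
            ranges={
                "x": frozenset({"Kauai"}), "y": frozenset({"Kauai"})
            },
        )
        p = ir.DECParams(d=0.1, e=0.02, areas=ir.HAWAIIAN_ISLANDS, strata=strata)
        with pytest.raises(ValueError, match="predates"):
            ir.dec_loglik(chron, rt, p)


class TestAncestralRanges:
    def test_cherry_low_rate_limit(self):
        chron = ir.read_newick("(x:1,y:1);")
        rt = ir.RangeTable(
            areas=("A", "B"),
            ranges={"x": frozenset({"A"}), "y": frozenset({"A"})},
        )
        rep = ir.ancestral_ranges(chron, rt, two_area_params(d=1e-6, e=1e-6))
        assert rep.nodes[0].probs[0b01] > 0.999

    def test_marginals_match_enumeration(self):
        rng = np.random.default_rng(4)
        chron = ir.simulate_chronogram(ir.TreeSimSpec(lam=1.0, n_tips=3), rng)
        areas = ("A", "B")
        rt = random_ranges(chron, areas, rng)
        p = ir.DECParams(d=0.2, e=0.05, areas=areas)
        rep = ir.ancestral_ranges(chron, rt, p)
        _, marg = dec_enumeration(chron, rt, 0.2, 0.05, 2)
        by_tips = {
            frozenset(chron.clade_tip_labels(v)): m for v, m in marg.items()
        }
        for rec in rep.nodes:
            node = chron.mrca(set(rec.tip_pair))
            key = frozenset(chron.clade_tip_labels(node))
            assert np.allclose(rec.probs, by_tips[key], atol=1e-9)

    def test_probabilities_normalized(self, yule20):
        rng = np.random.default_rng(9)
        rt = random_ranges(yule20, ir.HAWAIIAN_ISLANDS, rng)
        rep = ir.ancestral_ranges(
            yule20, rt, ir.DECParams(d=0.05, e=0.01, areas=ir.HAWAIIAN_ISLANDS)
        )
        for rec in rep.nodes:
            assert rec.probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert rec.probs[0] == 0.0  # no mass on the null range


class TestWidespreadSummary:
    def _report_from(self, probs_by_name, areas=ir.HAWAIIAN_ISLANDS):
        from islandrad.dec import AncestralRangeReport, NodeReconstruction

        S = 1 << len(areas)
        probs = np.zeros(S)
        for name, p in probs_by_name.items():
            mask = sum(
                1 << areas.index(a) for a in name.split("/")
            )
            probs[mask] = p
        rec = NodeReconstruction(
            node_id="N1", tip_pair=("x", "y"), age=1.0, probs=probs
        )
        return AncestralRangeReport(
            areas=tuple(areas), nodes=(rec,), loglik=-1.0, stratified=False
        )

    def test_large_multi_island_state_named(self):
        report = self._report_from(
            {"Hawaii": 0.66, "Maui/Hawaii": 0.17, "Maui": 0.12,
             "Kauai/Oahu": 0.05}
        )
        row = ir.summarize_widespread(report, threshold=0.15).iloc[0]
        assert row["Hawaii"] == pytest.approx(0.66)
        assert row["Maui/Hawaii"] == pytest.approx(0.17)
        assert row["Maui"] == pytest.approx(0.12)
        assert row["widespread"] == pytest.approx(0.05)

    def test_single_island_certainty(self):
        report = self._report_from({"Kauai": 1.0})
        row = ir.summarize_widespread(report).iloc[0]
        assert row["Kauai"] == pytest.approx(1.0)
        assert row["widespread"] == 0.0

    def test_mass_conserved(self):
        report = self._report_from(
            {"Hawaii": 0.3, "Maui/Hawaii": 0.2, "Kauai/Oahu/Molokai": 0.25,
             "Oahu": 0.25}
        )
        row = ir.summarize_widespread(report, threshold=0.5).iloc[0]
        singles = [row[a] for a in ir.HAWAIIAN_ISLANDS]
        assert sum(singles) + row["widespread"] == pytest.approx(1.0, abs=1e-9)


class TestModelComparison:
    def test_two_unit_rule_selects_clear_winner(self):
        sel = ir.compare_models([("unconstrained", -94.41), ("stratified", -119.7)])
        assert sel.best == "unconstrained"
        assert sel.separated
        assert sel.margin == pytest.approx(25.29)

    @pytest.mark.parametrize(
        "lls", [(-100.0, -101.5), (-100.0, -100.0)]
    )
    def test_insufficient_separation(self, lls):
        sel = ir.compare_models([("m1", lls[0]), ("m2", lls[1])])
        assert sel.best is None and not sel.separated

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            ir.compare_models([("only", -1.0)])


class TestFitDec:
    def test_no_events_pushes_rates_to_lower_bound(self):
        chron = ir.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        rt = ir.RangeTable(
            areas=("A", "B"),
            ranges={t: frozenset({"A"}) for t in "abcd"},
        )
        fit = ir.fit_dec(
            chron, rt, two_area_params(), bounds=((1e-4, 1.0), (1e-4, 1.0))
        )
        assert fit.params.d == pytest.approx(1e-4, rel=0.5)
        assert fit.params.e == pytest.approx(1e-4, rel=0.5)

    def test_fitted_likelihood_dominates_truth(self):
        rng = np.random.default_rng(12)
        truth = ir.DECParams(d=0.05, e=0.01, areas=("A", "B", "C"))
        chron = ir.simulate_chronogram(ir.TreeSimSpec(lam=0.4, n_tips=25), rng)
        sim = ir.simulate_dec_tips(
            chron, ir.DECSimSpec(params=truth, root_range=frozenset({"A"})), rng
        )
        fit = ir.fit_dec(chron, sim.ranges, truth)
        assert fit.loglik >= ir.dec_loglik(chron, sim.ranges, truth) - 1e-6
        assert fit.converged
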