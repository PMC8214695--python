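"""DEC+J+X state space, likelihood, marginals and stochastic mapping.

The reference oracle here enumerates states as frozensets and composes
dense matrix exponentials explicitly — a separate code path from the
package's bitmask pruning engine.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from islandrad import (DECParams, GeographyModel, ValidationError,
                       ancestral_range_probs, anagenetic_Q,
                       build_state_space, cladogenesis_table, dec_loglik,
                       fit_dec, stochastic_map, tree_from_newick)
from islandrad.biogeography import _DECEngine, _sample_endpoint_path


# ---------------------------------------------------------------------------
# frozenset-based oracle


def oracle_states(areas):
    out = []
    for k in range(1, len(areas) + 1):
        out.extend(frozenset(c) for c in itertools.combinations(areas, k))
    return sorted(out, key=lambda s: (len(s), sorted(s)))


def oracle_Q(states, d, e, x, dists, ref):
    K = len(states)
    Q = np.zeros((K, K))
    for i, R in enumerate(states):
        for b in set().union(*states):
            if b in R:
                continue
            rate = d * sum((dists[(a, b)] / ref) ** (-x) for a in R)
            Q[i, states.index(R | {b})] += rate
        if len(R) >= 2:
            for a in R:
                Q[i, states.index(R - {a})] += e
        Q[i, i] = -Q[i].sum()
    return Q


def oracle_clado(R, all_areas, d_, e_, j, x, dists, ref):
    events = []
    if len(R) == 1:
        events.append((R, R, 1.0))
    else:
        for a in sorted(R):
            s = frozenset([a])
            events.append((s, R, 1.0))
            events.append((R, s, 1.0))
            events.append((s, R - s, 1.0))
            if len(R) > 2:
                events.append((R - s, s, 1.0))
    if j > 0:
        for b in sorted(all_areas - R):
            w = j * sum((dists[(a, b)] / ref) ** (-x) for a in R) / len(R)
            events.append((R, frozenset([b]), w))
            events.append((frozenset([b]), R, w))
    tot = sum(w for _, _, w in events)
    return [(l, r, w / tot) for l, r, w in events]


def oracle_loglik(tree, tip_sets, areas, d, e, j, x, dists, ref,
                  constrain=None):
    """Sum over all internal-node states with dense matrix exponentials.

    ``constrain`` optionally pins one internal node to one state (for
    marginal checks).
    """
    states = oracle_states(areas)
    all_areas = frozenset(areas)
    Q = oracle_Q(states, d, e, x, dists, ref)

    def P(dur):
        return expm(Q * dur)

    def L(node, s):
        if node < tree.n_tips:
            return 1.0 if s == tip_sets[tree.labels[node]] else 0.0
        if constrain and node == constrain[0] and s != constrain[1]:
            return 0.0
        a, b = tree.children[node]
        Pa = P(tree.age[node] - tree.age[a])
        Pb = P(tree.age[node] - tree.age[b])
        tot = 0.0
        for l, r, p in oracle_clado(s, all_areas, d, e, j, x, dists, ref):
            ma = sum(Pa[states.index(l), kk] * L(a, states[kk])
                     for kk in range(len(states)))
            mb = sum(Pb[states.index(r), kk] * L(b, states[kk])
                     for kk in range(len(states)))
            tot += p * ma * mb
        return tot

    lik = np.mean([L(tree.root, s) for s in states])
    return math.log(lik) if lik > 0 else -math.inf


DISTS2 = {("A", "B"): 100.0, ("B", "A"): 100.0}


def params_tuple():
    return [(0.3, 0.1, 0.0, 0.0), (0.2, 0.05, 0.6, 0.0),
            (0.15, 0.02, 0.4, 2.0)]


# ---------------------------------------------------------------------------


class TestStateSpace:
    def test_full_state_count(self, geo4):
        assert build_state_space(geo4).size == 15

    def test_stratum_restriction(self, geo4):
        space = build_state_space(geo4)
        strata = geo4.strata(38.0)
        oldest = strata[0][2]
        assert space.valid(oldest).sum() == 3  # {C},{K},{CK}

    def test_max_range_size_two(self, geo4):
        assert build_state_space(geo4, max_range_size=2).size == 10

    def test_unknown_area_rejected(self, geo4):
        with pytest.raises(ValidationError):
            build_state_space(geo4).mask_of(("Atlantis",))


class TestAnageneticQ:
    def test_zero_rates_zero_matrix(self, geo2):
        space = build_state_space(geo2)
        Q = anagenetic_Q(space, DECParams(0, 0, 0, 0),
                         geo2.available_mask(0))
        assert np.all(Q == 0)

    def test_two_area_rates(self, geo2):
        space = build_state_space(geo2)
        Q = anagenetic_Q(space, DECParams(0.1, 0.05, 0, 0),
                         geo2.available_mask(0))
        iA = space.index[space.mask_of(("A",))]
        iAB = space.index[space.mask_of(("A", "B"))]
        assert Q[iA, iAB] == pytest.approx(0.1)
        assert Q[iAB, iA] == pytest.approx(0.05)

    def test_distance_exponent_quarters_doubled_distance(self):
        geo = GeographyModel(["A", "B", "C"],
                             np.array([[0, 200.0, 100.0],
                                       [200.0, 0, 100.0],
                                       [100.0, 100.0, 0]]),
                             np.full(3, np.inf))
        ref = geo.dist_ref()
        space = build_state_space(geo)
        p = DECParams(0.1, 0.0, 0.0, 2.0, dist_ref=200.0)
        Q = anagenetic_Q(space, p, geo.available_mask(0))
        iA = space.index[space.mask_of(("A",))]
        iAB = space.index[space.mask_of(("A", "B"))]
        # dist(A,B) = 200 = dist_ref; doubled relative distance vs 100
        assert Q[iA, iAB] == pytest.approx(0.1 * 1.0)
        p2 = DECParams(0.1, 0.0, 0.0, 2.0, dist_ref=100.0)
        Q2 = anagenetic_Q(space, p2, geo.available_mask(0))
        assert Q2[iA, iAB] == pytest.approx(0.1 * 0.25)

    def test_rows_sum_to_zero_offdiag_nonneg(self, geo4):
        rng = np.random.default_rng(0)
        space = build_state_space(geo4)
        for _ in range(20):
            p = DECParams(rng.uniform(0, 1), rng.uniform(0, 0.5), 0,
                          rng.uniform(0, 4))
            for _, _, mask in geo4.strata(38.0):
                Q = anagenetic_Q(space, p, mask)
                np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)
                off = Q[~np.eye(space.size, dtype=bool)]
                assert np.all(off >= 0)


class TestCladogenesis:
    def test_single_area_sympatry_only(self, geo2):
        space = build_state_space(geo2)
        tab = cladogenesis_table(space, DECParams(0.1, 0.1, 0, 0),
                                 space.mask_of(("A",)),
                                 geo2.available_mask(0))
        assert tab == [(space.mask_of(("A",)), space.mask_of(("A",)), 1.0)]

    def test_two_area_six_events_equal_weight(self, geo2):
        space = build_state_space(geo2)
        tab = cladogenesis_table(space, DECParams(0.1, 0.1, 0, 0),
                                 space.mask_of(("A", "B")),
                                 geo2.available_mask(0))
        assert len(tab) == 6
        assert all(p == pytest.approx(1 / 6) for _, _, p in tab)
        kinds = {(l, r) for l, r, _ in tab}
        A, B, AB = (space.mask_of(x) for x in (("A",), ("B",), ("A", "B")))
        assert {(A, B), (B, A), (A, AB), (AB, A), (B, AB), (AB, B)} == kinds

    def test_founder_targets_present_with_j(self, geo4):
        space = build_state_space(geo4)
        tab = cladogenesis_table(space, DECParams(0.1, 0.1, 0.5, 0),
                                 space.mask_of(("Crozet",)),
                                 geo4.available_mask(0))
        daughters = {space.areas_of(r) for _, r, _ in tab}
        assert ("Kerguelen",) in daughters
        assert ("PEI",) in daughters
        assert ("HIMI",) in daughters
        assert sum(p for _, _, p in tab) == pytest.approx(1.0)


class TestLikelihood:
    def test_forced_two_tip_case(self, geo2):
        tree = tree_from_newick("(t1:1,t2:1);")
        ll = dec_loglik(tree, {"t1": ("A",), "t2": ("A",)}, geo2,
                        DECParams(0, 0, 0, 0))
        assert math.exp(ll) == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("d,e,j,x", params_tuple())
    def test_total_probability_is_one(self, geo2, tree2, d, e, j, x):
        tot = 0.0
        for ra in itertools.product([("A",), ("B",), ("A", "B")], repeat=2):
            tot += math.exp(dec_loglik(
                tree2, {"t1": ra[0], "t2": ra[1]}, geo2,
                DECParams(d, e, j, x)))
        assert tot == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("d,e,j,x", params_tuple())
    def test_three_tip_matches_enumeration_oracle(self, geo2, tree3,
                                                  d, e, j, x):
        ref = geo2.dist_ref()
        for ra in [(("A",), ("B",), ("A", "B")),
                   (("A",), ("A",), ("A",)),
                   (("A", "B"), ("B",), ("A",))]:
            tips = dict(zip(["t1", "t2", "t3"], ra))
            mine = dec_loglik(tree3, tips, geo2, DECParams(d, e, j, x))
            oracle = oracle_loglik(
                tree3, {k: frozenset(v) for k, v in tips.items()},
                ["A", "B"], d, e, j, x, DISTS2, ref)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_area_order_invariance(self, tree3):
        tips = {"t1": ("A",), "t2": ("B",), "t3": ("A", "B")}
        p = DECParams(0.2, 0.05, 0.4, 1.5)
        geoAB = GeographyModel(["A", "B"],
                               np.array([[0, 100.0], [100.0, 0]]),
                               np.array([np.inf, np.inf]))
        geoBA = GeographyModel(["B", "A"],
                               np.array([[0, 100.0], [100.0, 0]]),
                               np.array([np.inf, np.inf]))
        assert dec_loglik(tree3, tips, geoAB, p) == pytest.approx(
            dec_loglik(tree3, tips, geoBA, p), abs=1e-12)

    def test_x_zero_makes_distances_irrelevant(self, tree3):
        tips = {"t1": ("A",), "t2": ("B",), "t3": ("C",)}
        base = np.array([[0, 100.0, 900.0], [100.0, 0, 300.0],
                         [900.0, 300.0, 0]])
        perm = base[np.ix_([2, 0, 1], [2, 0, 1])]
        perm = (perm + perm.T) / 2
        p = DECParams(0.2, 0.05, 0.3, 0.0)
        g1 = GeographyModel(["A", "B", "C"], base, np.full(3, np.inf))
        g2 = GeographyModel(["A", "B", "C"], perm, np.full(3, np.inf))
        assert dec_loglik(tree3, tips, g1, p) == pytest.approx(
            dec_loglik(tree3, tips, g2, p), abs=1e-12)

    def test_nested_models_never_beat_fuller(self, geo4):
        from islandrad.simulate import simulate_bd_tree, simulate_dec_history
        tree = simulate_bd_tree(0.12, 0.02, crown_age=30, f=1.0, seed=7)
        tips, _ = simulate_dec_history(tree, geo4,
                                       DECParams(0.06, 0.02, 0.2, 1.0),
                                       ("Crozet",), seed=8)
        dec = fit_dec(tree, tips, geo4, "DEC", n_starts=2, seed=0)
        full = fit_dec(tree, tips, geo4, "DEC+J+X", n_starts=2, seed=0)
        assert full.loglik_ >= dec.loglik_ - 1e-6

    def test_plain_dec_fit_keeps_j_and_x_at_zero(self, geo2, tree3):
        tips = {"t1": ("A",), "t2": ("B",), "t3": ("A", "B")}
        fit = fit_dec(tree3, tips, geo2, "DEC", n_starts=2, seed=0)
        assert fit.params_.j == 0.0 and fit.params_.x == 0.0
        assert fit.loglik_ == pytest.approx(
            dec_loglik(tree3, tips, geo2, fit.params_), abs=1e-9)


class TestAncestralProbs:
    def test_probabilities_sum_to_one(self, geo2, tree3):
        tips = {"t1": ("A",), "t2": ("B",), "t3": ("A", "B")}
        probs = ancestral_range_probs(tree3, tips, geo2,
                                      DECParams(0.3, 0.1, 0.5, 1.0))
        for dist in probs.values():
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_forced_root_state(self, geo2, tree3):
        tips = {"t1": ("A",), "t2": ("A",), "t3": ("A",)}
        probs = ancestral_range_probs(tree3, tips, geo2,
                                      DECParams(0, 0, 0, 0))
        assert probs[tree3.root][("A",)] == pytest.approx(1.0)

    def test_marginals_match_constrained_enumeration(self, geo2, tree3):
        tips = {"t1": ("A",), "t2": ("B",), "t3": ("A", "B")}
        d, e, j, x = 0.25, 0.08, 0.5, 1.0
        probs = ancestral_range_probs(tree3, tips, geo2,
                                      DECParams(d, e, j, x))
        ref = geo2.dist_ref()
        fs_tips = {k: frozenset(v) for k, v in tips.items()}
        full = oracle_loglik(tree3, fs_tips, ["A", "B"], d, e, j, x,
                             DISTS2, ref)
        for node in tree3.children:
            for s in oracle_states(["A", "B"]):
                pinned = oracle_loglik(tree3, fs_tips, ["A", "B"],
                                       d, e, j, x, DISTS2, ref,
                                       constrain=(node, s))
                expected = math.exp(pinned - full)
                got = probs[node].get(tuple(sorted(s)), 0.0)
                assert got == pytest.approx(expected, abs=1e-9)

    def test_emergence_blocks_old_ranges(self, geo4):
        """No node older than an island's emergence may contain it."""
        nwk = "((t1:0.2,t2:0.2):29.8,(t3:25,t4:25):5);"
        tree = tree_from_newick(nwk)
        tips = {"t1": ("PEI",), "t2": ("Crozet",), "t3": ("Kerguelen",),
                "t4": ("HIMI",)}
        probs = ancestral_range_probs(tree, tips, geo4,
                                      DECParams(0.1, 0.02, 0.3, 1.0))
        for node, dist in probs.items():
            age = tree.age[node]
            for areas, p in dist.items():
                if age > 0.475 and "PEI" in areas:
                    assert p == 0.0
                if age > 22.0 and "HIMI" in areas:
                    assert p == 0.0


class TestStochasticMapping:
    def test_zero_rates_give_zero_events(self, geo2, tree3):
        tips = {"t1": ("A",), "t2": ("A",), "t3": ("A",)}
        res = stochastic_map(tree3, tips, geo2, DECParams(0, 0, 0, 0),
                             iterations=30, seed=1)
        assert res.mean_dispersal.sum() == 0
        assert res.mean_extirpation.sum() == 0
        assert res.mean_founder.sum() == 0

    def test_dispersal_counts_increase_with_d(self, geo2, tree3):
        tips = {"t1": ("A",), "t2": ("B",), "t3": ("A", "B")}
        means = []
        for d in (0.05, 0.3, 1.0):
            res = stochastic_map(tree3, tips, geo2,
                                 DECParams(d, 0.02, 0.0, 0.0),
                                 iterations=300, seed=2)
            means.append(res.mean_dispersal.sum())
        assert means[0] < means[1] < means[2]

    def test_event_times_inside_branches(self, geo2, tree3):
        tips = {"t1": ("A",), "t2": ("B",), "t3": ("A", "B")}
        res = stochastic_map(tree3, tips, geo2,
                             DECParams(0.4, 0.1, 0.3, 0.0),
                             iterations=50, seed=3)
        for log in res.event_logs:
            for ev in log["anagenetic"]:
                kind, age, *rest = ev
                branch = rest[-1]
                lo = tree3.age[branch]
                hi = tree3.age[tree3.parent[branch]]
                assert lo - 1e-9 <= age <= hi + 1e-9

    def test_single_branch_expected_expansion_count(self, geo2):
        """Endpoint-conditioned path sampler vs the analytic expected count."""
        space = build_state_space(geo2)
        params = DECParams(0.35, 0.15, 0.0, 0.0)
        Q = anagenetic_Q(space, params, geo2.available_mask(0))
        iA = space.index[space.mask_of(("A",))]
        iAB = space.index[space.mask_of(("A", "B"))]
        dur = 1.0
        # E[#i->j | a->b] = q_ij * int P[a,i](t) P[j,b](T-t) dt / P[a,b](T)
        ts = np.linspace(0, dur, 2001)
        Pab = expm(Q * dur)[iA, iAB]
        expansions = [(space.index[space.mask_of(("A",))], iAB),
                      (space.index[space.mask_of(("B",))], iAB)]
        expected = 0.0
        for i, jj in expansions:
            vals = [expm(Q * t)[iA, i] * Q[i, jj]
                    * expm(Q * (dur - t))[jj, iAB] for t in ts[::50]]
            expected += np.trapezoid(vals, ts[::50]) / Pab
        lam = max(-np.diag(Q)) * 1.05
        Pu = np.eye(space.size) + Q / lam
        rng = np.random.default_rng(9)
        count = 0
        n_samp = 20_000
        for _ in range(n_samp):
            path = _sample_endpoint_path(Q, Pu, lam, iA, iAB, dur, rng)
            for _, frm, to in path:
                if to == iAB:
                    count += 1
        assert count / n_samp == pytest.approx(expected, rel=0.02)
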