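"""Dispersal-extinction-cladogenesis (DEC) range evolution on dated trees.

Geographic ranges are non-empty subsets of an ordered area list, encoded as
bitmasks.  Anagenetic evolution is a continuous-time Markov chain: a range R
expands into area b at rate sum_{a in R} d * m_ab and loses one of its
areas at rate e (only multi-area ranges can contract, so ranges never go
extinct and total probability over tip-range datasets is exactly one).  The
dispersal multiplier m_ab = (dist_ab / dist_ref)^(-x) is the +X distance
kernel; x ~ 2 is inverse-square decay.  At nodes, cladogenesis follows the
DEC event menu -- sympatry, subset sympatry, vicariance -- plus optional
founder-event speciation (+J), where one daughter jumps to a single area
outside the ancestral range with weight j scaled by the same distance
kernel.  Event probabilities are normalised per ancestor with equal base
weights for the non-founder classes.

Island emergence makes the process time-stratified: before an island's
subaerial appearance no range may contain it.  Branches are segmented at
stratum boundaries and per-stratum transition matrices (dense matrix
exponentials; the state space never exceeds 2^areas - 1) are composed
oldest to youngest.

Likelihoods use Felsenstein pruning with cladogenesis mixing at nodes and a
uniform root prior over the states available in the root stratum; marginal
ancestral-range probabilities come from an exact outside (down) pass, and
biogeographic stochastic mapping samples complete histories -- node states,
cladogenetic event types, and endpoint-conditioned anagenetic paths via
uniformization -- to count dispersal events by source and destination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy import optimize
from sklearn.base import BaseEstimator

from .datatypes import GeographyModel, TimeTree, ValidationError

DEC_MODELS = ("DEC", "DEC+J", "DEC+X", "DEC+J+X")


@dataclass
class DECParams:
    """Rates of the DEC+J+X process (per Ma; distances in km)."""

    d: float = 0.1
    e: float = 0.01
    j: float = 0.0
    x: float = 0.0
    dist_ref: float | None = None

    def __post_init__(self):
        if min(self.d, self.e, self.j, self.x) < 0:
            raise ValidationError("DEC parameters must be non-negative")
        if self.j >= 3:
            raise ValidationError("founder weight j must be < 3")

    def multipliers(self, geo: GeographyModel) -> np.ndarray:
        """m_ab = (dist_ab/dist_ref)^(-x); diagonal set to 0."""
        ref = self.dist_ref if self.dist_ref is not None else geo.dist_ref()
        with np.errstate(divide="ignore"):
            m = (geo.distance_km / ref) ** (-self.x)
        np.fill_diagonal(m, 0.0)
        if not np.all(np.isfinite(m[~np.eye(len(geo.areas), dtype=bool)])):
            raise ValidationError("non-finite dispersal multiplier")
        return m


class StateSpace:
    """All non-empty area subsets up to max_range_size, globally indexed.

    States are bitmasks over the ordered area list, sorted by (range size,
    mask) so indexing is deterministic and independent of insertion order.
    """

    def __init__(self, geo: GeographyModel, max_range_size: int | None = None):
        k = len(geo.areas)
        mrs = k if max_range_size is None else max_range_size
        if not (1 <= mrs <= k):
            raise ValidationError("max_range_size must be in [1, n_areas]")
        self.geo = geo
        self.n_areas = k
        self.max_range_size = mrs
        self.states = sorted(
            (m for m in range(1, 1 << k) if bin(m).count("1") <= mrs),
            key=lambda m: (bin(m).count("1"), m))
        self.index = {m: i for i, m in enumerate(self.states)}
        self.size = len(self.states)
        self._popcount = np.array([bin(m).count("1") for m in self.states])

    def mask_of(self, area_codes) -> int:
        m = 0
        for a in area_codes:
            try:
                m |= 1 << self.geo.areas.index(a)
            except ValueError:
                raise ValidationError(f"unknown area code {a!r}")
        if m == 0:
            raise ValidationError("empty range")
        return m

    def areas_of(self, mask: int) -> tuple:
        return tuple(a for i, a in enumerate(self.geo.areas)
                     if mask >> i & 1)

    def valid(self, available_mask: np.ndarray) -> np.ndarray:
        """Boolean over states: fully contained in the available areas."""
        avail = 0
        for i, ok in enumerate(available_mask):
            if ok:
                avail |= 1 << i
        return np.array([(s & ~avail) == 0 for s in self.states])

    def states_per_stratum(self, ceiling: float) -> list:
        """Ordered valid-state lists per stratum (old -> young)."""
        return [
            [s for s, ok in zip(self.states, self.valid(mask)) if ok]
            for _, _, mask in self.geo.strata(ceiling)
        ]


def build_state_space(geo: GeographyModel,
                      max_range_size: int | None = None) -> StateSpace:
    return StateSpace(geo, max_range_size)


# ---------------------------------------------------------------------------
# anagenetic process


def anagenetic_Q(space: StateSpace, params: DECParams,
                 available_mask: np.ndarray) -> np.ndarray:
    """Rate matrix over the global state list for one stratum.

    Rows of states invalid in the stratum are zero; valid rows sum to zero.
    """
    geo = space.geo
    m = params.multipliers(geo)
    K = space.size
    Q = np.zeros((K, K))
    valid = space.valid(available_mask)
    for i, R in enumerate(space.states):
        if not valid[i]:
            continue
        members = [a for a in range(space.n_areas) if R >> a & 1]
        # expansion
        if len(members) < space.max_range_size:
            for b in range(space.n_areas):
                if R >> b & 1 or not available_mask[b]:
                    continue
                tgt = R | (1 << b)
                jdx = space.index.get(tgt)
                if jdx is None or not valid[jdx]:
                    continue
                rate = params.d * sum(m[a, b] for a in members)
                Q[i, jdx] += rate
        # contraction (only multi-area ranges; no range extinction)
        if len(members) >= 2:
            for a in members:
                tgt = R & ~(1 << a)
                Q[i, space.index[tgt]] += params.e
        Q[i, i] = -Q[i].sum()
    return Q


# ---------------------------------------------------------------------------
# cladogenesis


def cladogenesis_table(space: StateSpace, params: DECParams,
                       ancestor_mask: int,
                       available_mask: np.ndarray) -> list:
    """Allowed daughter pairs of one ancestor: [(left, right, prob), ...].

    Masks in/out; probabilities normalised to sum 1.  Equal base weight 1
    for each sympatry/subset/vicariance event; founder events carry weight
    j * mean_{a in R} m_ab to target b.
    """
    geo = space.geo
    m = params.multipliers(geo)
    R = ancestor_mask
    members = [a for a in range(space.n_areas) if R >> a & 1]
    events = []
    if len(members) == 1:
        events.append((R, R, 1.0))
    else:
        for a in members:
            single = 1 << a
            rest = R & ~single
            events.append((single, R, 1.0))   # subset sympatry
            events.append((R, single, 1.0))
            events.append((single, rest, 1.0))  # vicariance
            if len(members) > 2:
                events.append((rest, single, 1.0))
            # for |R| = 2 the loop over `a` already yields both orders
    if params.j > 0:
        for b in range(space.n_areas):
            if R >> b & 1 or not available_mask[b]:
                continue
            w = params.j * sum(m[a, b] for a in members) / len(members)
            if w > 0:
                events.append((R, 1 << b, w))
                events.append(((1 << b), R, w))
    total = sum(w for _, _, w in events)
    if total <= 0:
        raise ValidationError("no allowed cladogenetic events")
    return [(l, r, w / total) for l, r, w in events]


# ---------------------------------------------------------------------------
# pruning machinery


class _DECEngine:
    """Shared scaffolding for likelihood, marginals and stochastic maps."""

    def __init__(self, tree: TimeTree, tip_ranges: dict, geo: GeographyModel,
                 params: DECParams, max_range_size=None, root_prior="uniform"):
        self.tree = tree
        self.geo = geo
        self.params = params
        self.space = build_state_space(geo, max_range_size)
        self.strata = geo.strata(tree.crown_age)
        self.Qs = [anagenetic_Q(self.space, params, mask)
                   for _, _, mask in self.strata]
        self.valids = [self.space.valid(mask) for _, _, mask in self.strata]
        K = self.space.size
        # tip partials
        self.tip_state = {}
        for lab in tree.labels:
            if lab not in tip_ranges:
                raise ValidationError(f"no range supplied for tip {lab!r}")
            mask = self.space.mask_of(tip_ranges[lab])
            idx = self.space.index.get(mask)
            if idx is None:
                raise ValidationError(
                    f"tip {lab!r} range exceeds max_range_size")
            tip = tree.tip_index(lab)
            s_idx = self._stratum_at(tree.age[tip])
            if not self.valids[s_idx][idx]:
                raise ValidationError(
                    f"tip {lab!r} occupies an area unavailable at its age")
            self.tip_state[tip] = idx
        # root prior: uniform over states valid in the root stratum
        v0 = self.valids[0]
        if root_prior == "uniform":
            self.root_prior = v0.astype(float) / v0.sum()
        else:
            self.root_prior = np.asarray(root_prior, dtype=float)
        self._expm_cache = {}
        self._clado_cache = {}
        self._eig = [None] * len(self.strata)
        self._clado_tensor = [None] * len(self.strata)

    # -- strata helpers -----------------------------------------------------

    def _stratum_at(self, age: float) -> int:
        for i, (start, end, _) in enumerate(self.strata):
            if age >= end:
                return i
        return len(self.strata) - 1

    def _segments(self, t_child: float, t_parent: float) -> list:
        """(stratum index, duration) pieces of a branch, oldest first."""
        segs = []
        for i, (start, end, _) in enumerate(self.strata):
            lo = max(end, t_child)
            hi = min(start, t_parent)
            if hi - lo > 1e-12:
                segs.append((i, hi - lo))
        return segs

    def _eig_of(self, s_idx: int):
        """Eigendecomposition of one stratum's Q, or None if ill-conditioned."""
        if self._eig[s_idx] is None:
            Q = self.Qs[s_idx]
            w, V = np.linalg.eig(Q)
            try:
                Vinv = np.linalg.inv(V)
                ok = np.linalg.cond(V) < 1e8
            except np.linalg.LinAlgError:
                ok = False
                Vinv = None
            self._eig[s_idx] = (w, V, Vinv) if ok else "dense"
        return self._eig[s_idx]

    def _P_seg(self, s_idx: int, dur: float) -> np.ndarray:
        key = (s_idx, round(dur, 12))
        P = self._expm_cache.get(key)
        if P is None:
            eig = self._eig_of(s_idx)
            if eig == "dense":  # near-defective Q: fall back to expm
                P = expm(self.Qs[s_idx] * dur)
            else:
                w, V, Vinv = eig
                P = np.real((V * np.exp(w * dur)) @ Vinv)
                np.clip(P, 0.0, None, out=P)
            self._expm_cache[key] = P
        return P

    def _projection(self, older: int, younger: int) -> np.ndarray | None:
        """Boundary projection for states that lose validity going young.

        With pure emergence this is the identity (None); if an area ever
        submerged, mass on newly invalid states is renormalised onto their
        largest valid subsets.
        """
        va, vb = self.valids[older], self.valids[younger]
        lost = va & ~vb
        if not lost.any():
            return None
        K = self.space.size
        proj = np.zeros((K, K))
        proj[vb, vb] = 0.0
        for i in range(K):
            if va[i] and vb[i]:
                proj[i, i] = 1.0
            elif va[i] and not vb[i]:
                s = self.space.states[i]
                subs = [jj for jj, t in enumerate(self.space.states)
                        if vb[jj] and (t & ~s) == 0]
                if subs:
                    sizes = [self.space._popcount[jj] for jj in subs]
                    mx = max(sizes)
                    tgt = [jj for jj, sz in zip(subs, sizes) if sz == mx]
                    for jj in tgt:
                        proj[i, jj] = 1.0 / len(tgt)
        return proj

    def branch_P(self, node: int) -> np.ndarray:
        """Forward transition matrix over the branch above `node`.

        Rows index the state at the parent's age, columns at the node's age.
        """
        t_c = self.tree.age[node]
        t_p = self.tree.age[self.tree.parent[node]]
        segs = self._segments(t_c, t_p)
        P = None
        prev = None
        for s_idx, dur in segs:  # oldest -> youngest
            piece = self._P_seg(s_idx, dur)
            if prev is not None and s_idx != prev:
                pj = self._projection(prev, s_idx)
                if pj is not None:
                    piece = pj @ piece
            P = piece if P is None else P @ piece
            prev = s_idx
        if P is None:
            P = np.eye(self.space.size)
        return P

    def clado(self, s_idx: int, anc_index: int) -> list:
        """Cladogenesis table for a valid ancestor state in one stratum."""
        key = (s_idx, anc_index)
        tab = self._clado_cache.get(key)
        if tab is None:
            mask = self.space.states[anc_index]
            raw = cladogenesis_table(self.space, self.params, mask,
                                     self.strata[s_idx][2])
            tab = [(self.space.index[l], self.space.index[r], p)
                   for l, r, p in raw]
            self._clado_cache[key] = tab
        return tab

    def _clado_arrays(self, s_idx: int):
        """All valid-ancestor cladogenesis events as flat index arrays."""
        if self._clado_tensor[s_idx] is None:
            anc_l, l_l, r_l, p_l = [], [], [], []
            for anc in np.flatnonzero(self.valids[s_idx]):
                for l, r, p in self.clado(s_idx, int(anc)):
                    anc_l.append(anc)
                    l_l.append(l)
                    r_l.append(r)
                    p_l.append(p)
            self._clado_tensor[s_idx] = (
                np.array(anc_l, dtype=int), np.array(l_l, dtype=int),
                np.array(r_l, dtype=int), np.array(p_l))
        return self._clado_tensor[s_idx]

    # -- inside (up) pass ---------------------------------------------------

    def up_pass(self):
        """Partial likelihoods L[node][state] and branch matrices."""
        tree = self.tree
        K = self.space.size
        L = np.zeros((tree.n_nodes, K))
        self._bP = {}
        for tip, idx in self.tip_state.items():
            L[tip, idx] = 1.0
        for v in tree.postorder_internal():
            a, b = tree.children[v]
            msgs = []
            for c in (a, b):
                P = self.branch_P(c)
                self._bP[c] = P
                msgs.append(P @ L[c])
            s_idx = self._stratum_at(tree.age[v])
            anc_a, l_a, r_a, p_a = self._clado_arrays(s_idx)
            np.add.at(L[v], anc_a, p_a * msgs[0][l_a] * msgs[1][r_a])
        self.L_ = L
        return L

    def loglik(self) -> float:
        L = self.up_pass()
        lik = float(self.root_prior @ L[self.tree.root])
        if lik <= 0:
            return -math.inf
        return math.log(lik)

    # -- outside (down) pass ------------------------------------------------

    def node_marginals(self) -> dict:
        """P(node state | data) for every internal node (exact)."""
        tree = self.tree
        if not hasattr(self, "L_"):
            self.up_pass()
        L = self.L_
        K = self.space.size
        G = np.zeros((tree.n_nodes, K))       # outside weight at node age
        G[tree.root] = self.root_prior
        order = list(reversed(tree.postorder_internal()))  # root first
        up_msg = {c: self._bP[c] @ L[c]
                  for v in tree.children for c in tree.children[v]}
        for v in order:
            a, b = tree.children[v]
            s_idx = self._stratum_at(tree.age[v])
            anc_a, l_a, r_a, p_a = self._clado_arrays(s_idx)
            top_a = np.zeros(K)
            top_b = np.zeros(K)
            gp = G[v][anc_a] * p_a
            np.add.at(top_a, l_a, gp * up_msg[b][r_a])
            np.add.at(top_b, r_a, gp * up_msg[a][l_a])
            G[a] = self._bP[a].T @ top_a
            G[b] = self._bP[b].T @ top_b
        out = {}
        for v in tree.children:
            w = G[v] * L[v]
            out[v] = w / w.sum()
        self.G_ = G
        return out


def dec_loglik(tree: TimeTree, tip_ranges: dict, geo: GeographyModel,
               params: DECParams, max_range_size=None,
               root_prior="uniform") -> float:
    """Log-likelihood of tip ranges under DEC(+J)(+X) on a dated tree."""
    eng = _DECEngine(tree, tip_ranges, geo, params, max_range_size,
                     root_prior)
    return eng.loglik()


def ancestral_range_probs(tree: TimeTree, tip_ranges: dict,
                          geo: GeographyModel, params: DECParams,
                          max_range_size=None) -> dict:
    """Marginal state probabilities per internal node, keyed by node index.

    Each value maps area-code tuples to probabilities summing to 1.
    """
    eng = _DECEngine(tree, tip_ranges, geo, params, max_range_size)
    marg = eng.node_marginals()
    return {
        v: {eng.space.areas_of(eng.space.states[i]): float(p[i])
            for i in range(eng.space.size) if p[i] > 0}
        for v, p in marg.items()
    }


# ---------------------------------------------------------------------------
# ML fitting


class DECModel(BaseEstimator):
    """ML fit of DEC, DEC+J, DEC+X or DEC+J+X.

    ``model`` selects which of j (founder weight) and x (distance exponent)
    are free; the others are fixed at 0.  Bounded multi-start optimisation;
    ties broken toward the smaller parameter-vector norm.

    Attributes (after fit): ``params_`` (DECParams), ``loglik_``,
    ``converged_``, ``n_params_``.
    """

    def __init__(self, model="DEC+J+X", max_range_size=None, n_starts=8,
                 seed=0, d_bounds=(1e-6, 5.0), e_bounds=(1e-6, 5.0),
                 j_bounds=(0.0, 2.9), x_bounds=(0.0, 5.0)):
        self.model = model
        self.max_range_size = max_range_size
        self.n_starts = n_starts
        self.seed = seed
        self.d_bounds = d_bounds
        self.e_bounds = e_bounds
        self.j_bounds = j_bounds
        self.x_bounds = x_bounds

    def _free(self):
        return "J" in self.model.replace("DEC", ""), "X" in self.model

    def fit(self, tree: TimeTree, tip_ranges: dict, geo: GeographyModel):
        if self.model not in DEC_MODELS:
            raise ValidationError(f"unknown DEC variant {self.model!r}")
        free_j, free_x = self._free()
        rng = np.random.default_rng(self.seed)
        bounds = [(math.log(self.d_bounds[0]), math.log(self.d_bounds[1])),
                  (math.log(self.e_bounds[0]), math.log(self.e_bounds[1]))]
        if free_j:
            bounds.append(self.j_bounds)
        if free_x:
            bounds.append(self.x_bounds)

        def unpack(z):
            d, e = math.exp(z[0]), math.exp(z[1])
            i = 2
            j = 0.0
            if free_j:
                j = z[i]
                i += 1
            x = z[i] if free_x else 0.0
            return DECParams(d, e, j, x)

        def neg(z):
            try:
                val = -dec_loglik(tree, tip_ranges, geo, unpack(z),
                                  self.max_range_size)
            except (ValidationError, FloatingPointError):
                return 1e10
            return val if math.isfinite(val) else 1e10

        starts = [np.array([math.log(0.05), math.log(0.01)]
                           + ([0.1] if free_j else [])
                           + ([1.0] if free_x else []))]
        for _ in range(self.n_starts - 1):
            starts.append(np.array(
                [rng.uniform(lo, hi) for lo, hi in bounds]))
        best, best_val, any_ok = None, math.inf, False
        for z0 in starts:
            res = optimize.minimize(neg, z0, method="L-BFGS-B",
                                    bounds=bounds)
            any_ok = any_ok or res.success
            better = res.fun < best_val - 1e-9 or (
                abs(res.fun - best_val) <= 1e-9 and best is not None
                and np.linalg.norm(res.x) < np.linalg.norm(best))
            if best is None or better:
                best, best_val = res.x, res.fun
        self.params_ = unpack(best)
        self.loglik_ = -best_val
        self.converged_ = bool(any_ok)
        self.n_params_ = 2 + free_j + free_x
        return self

    def ancestral_probs(self, tree, tip_ranges, geo):
        return ancestral_range_probs(tree, tip_ranges, geo, self.params_,
                                     self.max_range_size)


def fit_dec(tree: TimeTree, tip_ranges: dict, geo: GeographyModel,
            model: str = "DEC+J+X", **kw) -> DECModel:
    """Thin functional wrapper over :class:`DECModel`."""
    return DECModel(model=model, **kw).fit(tree, tip_ranges, geo)


# ---------------------------------------------------------------------------
# biogeographic stochastic mapping


@dataclass
class BSMResult:
    """Aggregated event counts over stochastic-mapping iterations."""

    iterations: int
    areas: list
    mean_dispersal: np.ndarray       # anagenetic source -> destination
    mean_founder: np.ndarray         # founder-event source -> destination
    mean_extirpation: np.ndarray     # per-area
    clado_counts: dict               # event type -> mean count per iteration
    within_area_speciation: float    # sympatry + subset, mean per iteration
    between_area_speciation: float   # vicariance + founder
    node_state_freq: dict            # node -> state index -> frequency
    event_logs: list                 # per-iteration raw logs

    @property
    def mean_total_dispersal(self) -> np.ndarray:
        return self.mean_dispersal + self.mean_founder


def _sample_endpoint_path(Q, P_unif, lam, a, b, dur, rng, max_jumps=2000):
    """Endpoint-conditioned CTMC path on [0, dur] via uniformization.

    Returns a list of (time_from_start, from_state, to_state) transitions.
    """
    # P(N = n | a -> b in dur) ~ Poisson(lam*dur) * P_unif^n[a, b]
    powers = [np.eye(Q.shape[0]), P_unif]
    Pdur = expm(Q * dur)
    target = Pdur[a, b]
    if target <= 0:
        raise ValidationError("impossible endpoint pair in path sampling")
    u = rng.random() * target
    n = 0
    acc = 0.0
    pois = math.exp(-lam * dur)
    while True:
        while len(powers) <= n:
            powers.append(powers[-1] @ P_unif)
        acc += pois * powers[n][a, b]
        if acc >= u or n >= max_jumps:
            break
        n += 1
        pois *= lam * dur / n
    # sample the embedded chain bridge of length n
    states = [a]
    for k in range(1, n):
        prev = states[-1]
        w = P_unif[prev] * powers[n - k][:, b]
        w = np.clip(w, 0.0, None)
        tot = w.sum()
        if tot <= 0:
            states.append(b)
            continue
        states.append(int(rng.choice(w.size, p=w / tot)))
    if n > 0:
        states.append(b)
    times = np.sort(rng.random(n)) * dur
    out = []
    for k in range(n):
        frm, to = states[k], states[k + 1]
        if frm != to:
            out.append((float(times[k]), frm, to))
    return out


def stochastic_map(tree: TimeTree, tip_ranges: dict, geo: GeographyModel,
                   params: DECParams, iterations: int = 100, seed: int = 0,
                   max_range_size=None) -> BSMResult:
    """Biogeographic stochastic mapping under fitted DEC(+J)(+X) parameters.

    Per iteration: sample the root state and every node's daughter states
    from the exact conditionals given the tip data, then fill in anagenetic
    histories along each branch with endpoint-conditioned uniformization
    per stratum segment.  Events are aggregated into mean per-iteration
    counts: anagenetic dispersals (range expansions, attributed to a source
    area inside the range proportionally to the distance kernel), founder
    dispersals, extirpations and cladogenetic event types.
    """
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    eng = _DECEngine(tree, tip_ranges, geo, params, max_range_size)
    L = eng.up_pass()
    rng = np.random.default_rng(seed)
    K = eng.space.size
    nA = eng.space.n_areas
    m_kernel = params.multipliers(geo)
    disp = np.zeros((nA, nA))
    found = np.zeros((nA, nA))
    extirp = np.zeros(nA)
    clado_counts = {"sympatry": 0.0, "subset": 0.0, "vicariance": 0.0,
                    "founder": 0.0}
    node_state_counts = {v: np.zeros(K) for v in tree.children}
    logs = []

    # per-stratum uniformization pieces
    unif = []
    for Q in eng.Qs:
        lam = max(-np.diag(Q).min(), 1e-9) * 1.05
        unif.append((Q, np.eye(K) + Q / lam, lam))

    root_w = eng.root_prior * L[tree.root]
    root_w = root_w / root_w.sum()

    def classify(anc_idx, l_idx, r_idx):
        anc = eng.space.states[anc_idx]
        l, r = eng.space.states[l_idx], eng.space.states[r_idx]
        if l == anc and r == anc:
            return "sympatry"
        new_l = l & ~anc
        new_r = r & ~anc
        if new_l or new_r:
            return "founder"
        if (l | r) == anc and (l & r) == 0:
            return "vicariance"
        return "subset"

    def attribute_source(range_mask, dest_area):
        members = [a for a in range(nA) if range_mask >> a & 1]
        w = np.array([m_kernel[a, dest_area] for a in members])
        if w.sum() <= 0:
            return members[int(rng.integers(len(members)))]
        return members[int(rng.choice(len(members), p=w / w.sum()))]

    for it in range(iterations):
        log = {"anagenetic": [], "cladogenetic": []}
        node_state = {tree.root: int(rng.choice(K, p=root_w))}
        stack = [tree.root]
        while stack:
            v = stack.pop()
            anc = node_state[v]
            node_state_counts[v][anc] += 1
            a, b = tree.children[v]
            s_idx = eng._stratum_at(tree.age[v])
            tab = eng.clado(s_idx, anc)
            msg_a = eng._bP[a] @ L[a]
            msg_b = eng._bP[b] @ L[b]
            w = np.array([p * msg_a[l] * msg_b[r] for l, r, p in tab])
            pick = tab[int(rng.choice(len(tab), p=w / w.sum()))]
            l_idx, r_idx, _ = pick
            etype = classify(anc, l_idx, r_idx)
            clado_counts[etype] += 1
            if etype == "founder":
                anc_mask = eng.space.states[anc]
                for d_idx in (l_idx, r_idx):
                    new = eng.space.states[d_idx] & ~anc_mask
                    for dest in range(nA):
                        if new >> dest & 1:
                            src = attribute_source(anc_mask, dest)
                            found[src, dest] += 1
                            log["cladogenetic"].append(
                                ("founder", tree.age[v], src, dest))
            else:
                log["cladogenetic"].append((etype, tree.age[v], None, None))
            # walk both daughter branches down to their endpoints
            for child, top_state in ((a, l_idx), (b, r_idx)):
                segs = eng._segments(tree.age[child], tree.age[v])
                # suffix products for sequential boundary sampling
                mats = [eng._P_seg(si, du) for si, du in segs]
                suffix = [None] * (len(mats) + 1)
                suffix[len(mats)] = np.eye(K)
                for i in range(len(mats) - 1, -1, -1):
                    suffix[i] = mats[i] @ suffix[i + 1]
                if child < tree.n_tips:
                    end_weight = np.zeros(K)
                    end_weight[eng.tip_state[child]] = 1.0
                else:
                    end_weight = L[child]
                cur = top_state
                t_cursor = tree.age[v]
                for i, (si, du) in enumerate(segs):
                    wnext = mats[i][cur] * (suffix[i + 1] @ end_weight)
                    wnext = np.clip(wnext, 0.0, None)
                    nxt = int(rng.choice(K, p=wnext / wnext.sum()))
                    Q, Pu, lam = unif[si]
                    path = _sample_endpoint_path(Q, Pu, lam, cur, nxt, du,
                                                 rng)
                    for (dt, frm, to) in path:
                        age_ev = t_cursor - dt
                        s_frm = eng.space.states[frm]
                        s_to = eng.space.states[to]
                        gained = s_to & ~s_frm
                        lost = s_frm & ~s_to
                        for dest in range(nA):
                            if gained >> dest & 1:
                                src = attribute_source(s_frm, dest)
                                disp[src, dest] += 1
                                log["anagenetic"].append(
                                    ("expansion", age_ev, src, dest, child))
                            if lost >> dest & 1:
                                extirp[dest] += 1
                                log["anagenetic"].append(
                                    ("extirpation", age_ev, dest, None,
                                     child))
                    cur = nxt
                    t_cursor -= du
                if child in tree.children:
                    node_state[child] = cur
                    stack.append(child)
        logs.append(log)

    n = float(iterations)
    return BSMResult(
        iterations=iterations, areas=list(geo.areas),
        mean_dispersal=disp / n, mean_founder=found / n,
        mean_extirpation=extirp / n,
        clado_counts={k: v / n for k, v in clado_counts.items()},
        within_area_speciation=(clado_counts["sympatry"]
                                + clado_counts["subset"]) / n,
        between_area_speciation=(clado_counts["vicariance"]
                                 + clado_counts["founder"]) / n,
        node_state_freq={v: c / n for v, c in node_state_counts.items()},
        event_logs=logs)
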