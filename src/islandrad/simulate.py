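"""Synthetic-data generators emulating the sub-Antarctic island system.

Every stage of the pipeline can be exercised without external downloads:

* a long-term-cooling paleotemperature curve with Plio-Pleistocene
  oscillations,
* reconstructed trees from a time-inhomogeneous birth-death process whose
  speciation rate may track that curve,
* range histories evolved forward under DEC(+J)(+X) on those trees with
  island-emergence strata enforced,
* diploid biallelic genotypes under a (hierarchical) Balding-Nichols
  island model with a target F_ST.

All generators are pure functions of their parameters and an explicit
integer seed: identical inputs give identical outputs.  The default
scenario mirrors the study system this package was built around: four
archipelagos (Crozet, Kerguelen, PEI, HIMI) with realistic inter-island
distances, HIMI emerging 22 Ma and PEI 0.475 Ma ago, a crown age near
38 Ma, and a sampling fraction of 24/36.
"""

from __future__ import annotations

import math

import numpy as np

from .biogeography import DECParams, StateSpace, anagenetic_Q, \
    cladogenesis_table
from .datatypes import ClimateSeries, GenotypeMatrix, GeographyModel, \
    TimeTree, ValidationError

# default geography: approximate great-circle distances (km) between the
# four archipelagos; these are recipe defaults, overridable per call
DEFAULT_AREAS = ["Crozet", "Kerguelen", "PEI", "HIMI"]
DEFAULT_DISTANCES = np.array([
    #  C      K      P      H
    [0.0, 1420.0, 950.0, 1840.0],
    [1420.0, 0.0, 2320.0, 440.0],
    [950.0, 2320.0, 0.0, 2740.0],
    [1840.0, 440.0, 2740.0, 0.0],
])
DEFAULT_EMERGENCE = {"HIMI": 22.0, "PEI": 0.475}

DEFAULT_CROWN_AGE = 38.0
DEFAULT_SAMPLING_FRACTION = 24.0 / 36.0


def default_geography() -> GeographyModel:
    emer = np.array([DEFAULT_EMERGENCE.get(a, np.inf) for a in DEFAULT_AREAS])
    return GeographyModel(DEFAULT_AREAS, DEFAULT_DISTANCES.copy(), emer)


# ---------------------------------------------------------------------------
# climate


# Deep-ocean cooling is far from linear: a steep Eocene-Oligocene drop, a
# partial rebound into the Miocene climatic optimum, a sharp mid-Miocene
# transition, then gradual decline into the Plio-Pleistocene.  The default
# trend follows that shape through control points expressed as (fraction of
# the span, fraction of the total cooling above the modern endpoint), so
# the (T_oldest, T_present) endpoints remain exact whatever the span.
_CENOZOIC_SHAPE = [
    (1.00, 1.00), (0.70, 0.55), (0.60, 0.38),
    (0.34, 0.48), (0.26, 0.22), (0.10, 0.12), (0.00, 0.00),
]


def simulate_climate(span: float = 50.0, trend=(12.0, 1.0),
                     oscillation=(1.0, 0.04), osc_span: float = 5.0,
                     noise_sd: float = 0.1, step: float = 0.05,
                     shape: str = "cenozoic", seed: int = 0) -> ClimateSeries:
    """Cooling trend plus recent oscillations plus white noise.

    ``trend = (T_oldest, T_present)`` in deg C over ``span`` Ma, followed
    either linearly (``shape="linear"``) or through the Cenozoic-like
    piecewise profile above (default); a sinusoid of (amplitude, period
    Ma) is superposed over the youngest ``osc_span`` Ma, emulating
    Plio-Pleistocene glacial cycles on top of long-term cooling.
    """
    if span <= 0 or step <= 0:
        raise ValidationError("span and step must be positive")
    rng = np.random.default_rng(seed)
    age = np.arange(0.0, span + step / 2, step)
    t_old, t_now = trend
    if shape == "linear":
        value = t_now + (t_old - t_now) * age / span
    elif shape == "cenozoic":
        pts = sorted(_CENOZOIC_SHAPE)
        knots = np.array([f * span for f, _ in pts])
        temps = np.array([t_now + g * (t_old - t_now) for _, g in pts])
        value = np.interp(age, knots, temps)
    else:
        raise ValidationError(f"unknown trend shape {shape!r}")
    amp, period = oscillation
    if amp > 0 and period > 0:
        value = value + amp * np.sin(2 * math.pi * age / period) \
            * (age <= osc_span)
    if noise_sd > 0:
        value = value + rng.normal(0, noise_sd, size=age.size)
    return ClimateSeries(age, value, kind="temperature",
                         provenance={"generator": "simulate_climate",
                                     "seed": int(seed)})


# ---------------------------------------------------------------------------
# birth-death trees


class _SimNode:
    __slots__ = ("birth_age", "end_age", "children", "sampled")

    def __init__(self, birth_age):
        self.birth_age = birth_age
        self.end_age = None      # death age, or 0.0 if extant
        self.children = None
        self.sampled = False


def _simulate_bd_once(lam_fn, mu_fn, crown_age, f, rng,
                      lam_max, mu_max, max_lineages=100_000):
    root = _SimNode(crown_age)
    c1, c2 = _SimNode(crown_age), _SimNode(crown_age)
    root.children = (c1, c2)
    root.end_age = crown_age
    alive = [c1, c2]
    t = crown_age
    total_max = lam_max + mu_max
    while alive and t > 0:
        k = len(alive)
        if k > max_lineages:
            raise ValidationError("lineage explosion; lower the rates")
        t -= rng.exponential(1.0 / (k * total_max))
        if t <= 0:
            break
        node = alive[rng.integers(k)]
        if rng.random() < lam_max / total_max:
            if rng.random() < lam_fn(t) / lam_max:  # birth
                node.end_age = t
                a, b = _SimNode(t), _SimNode(t)
                node.children = (a, b)
                alive.remove(node)
                alive.extend([a, b])
        else:
            if mu_max > 0 and rng.random() < mu_fn(t) / mu_max:  # death
                node.end_age = t
                alive.remove(node)
    for node in alive:
        node.end_age = 0.0
        node.sampled = rng.random() < f
    return root


def _count_sampled(node):
    if node.children is None:
        return 1 if node.sampled else 0
    return sum(_count_sampled(c) for c in node.children)


def _prune_to_sampled(node):
    """Reduce to the reconstructed tree of sampled tips.

    Returns (age, label_or_children) nested tuples, or None if no sampled
    descendant.
    """
    if node.children is None:
        return ("tip", node.end_age) if node.sampled else None
    kids = [_prune_to_sampled(c) for c in node.children]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return ("node", node.end_age, kids[0], kids[1])


def _to_timetree(struct) -> TimeTree:
    nodes = []  # (age, children or None)

    def collect(s):
        if s[0] == "tip":
            nodes.append([s[1], None])
            return len(nodes) - 1
        a = collect(s[2])
        b = collect(s[3])
        nodes.append([s[1], (a, b)])
        return len(nodes) - 1

    collect(struct)
    n_tips = sum(1 for a, c in nodes if c is None)
    tip_ids = [i for i, (a, c) in enumerate(nodes) if c is None]
    internal_ids = [i for i, (a, c) in enumerate(nodes) if c is not None]
    remap = {}
    for new, old in enumerate(tip_ids):
        remap[old] = new
    for off, old in enumerate(internal_ids):
        remap[old] = n_tips + off
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    age = np.zeros(n)
    children = {}
    for old, (a, c) in enumerate(nodes):
        age[remap[old]] = a
        if c is not None:
            children[remap[old]] = (remap[c[0]], remap[c[1]])
            parent[remap[c[0]]] = remap[old]
            parent[remap[c[1]]] = remap[old]
    labels = [f"t{i+1}" for i in range(n_tips)]
    return TimeTree(parent, age, children, labels)


def simulate_bd_tree(lam_fn, mu_fn=None, crown_age: float = DEFAULT_CROWN_AGE,
                     f: float = 1.0, seed: int = 0,
                     min_tips: int = 2, max_attempts: int = 10_000
                     ) -> TimeTree:
    """Reconstructed tree from a time-inhomogeneous birth-death process.

    ``lam_fn`` and ``mu_fn`` map age (Ma before present) to per-lineage
    rates; scalars are accepted.  Simulation starts from the two crown
    lineages at ``crown_age`` (thinning algorithm) and is conditioned, by
    rejection, on both crown lineages having at least one sampled tip
    after rho-sampling with fraction ``f`` (uniform tip retention).
    """
    if not callable(lam_fn):
        lam0 = float(lam_fn)
        lam_fn = lambda t: lam0  # noqa: E731
    if mu_fn is None:
        mu_fn = lambda t: 0.0  # noqa: E731
    elif not callable(mu_fn):
        mu0 = float(mu_fn)
        mu_fn = lambda t: mu0  # noqa: E731
    ages = np.linspace(0, crown_age, 512)
    lam_max = float(max(np.max([lam_fn(a) for a in ages]) * 1.0001, 1e-12))
    mu_max = float(np.max([mu_fn(a) for a in ages]) * 1.0001)
    if lam_max <= 0:
        raise ValidationError("speciation rate must be positive somewhere")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        root = _simulate_bd_once(lam_fn, mu_fn, crown_age, f, rng,
                                 lam_max, mu_max)
        c1, c2 = root.children
        if _count_sampled(c1) >= 1 and _count_sampled(c2) >= 1 \
                and _count_sampled(root) >= min_tips:
            struct = _prune_to_sampled(root)
            return _to_timetree(struct)
    raise ValidationError(
        f"no surviving tree in {max_attempts} attempts; "
        "adjust rates, crown age or sampling fraction")


def climate_driven_rate(climate: ClimateSeries, lambda0: float, alpha: float):
    """lambda(t) = lambda0 * exp(alpha * T(t)) as a callable of age."""
    interp = climate.interpolator()

    def lam(t):
        return lambda0 * math.exp(alpha * float(interp(t)))

    return lam


# ---------------------------------------------------------------------------
# DEC histories


def simulate_dec_history(tree: TimeTree, geo: GeographyModel,
                         params: DECParams, root_state, seed: int = 0,
                         max_range_size=None):
    """Forward simulation of range evolution along a dated tree.

    Gillespie simulation of the anagenetic CTMC per branch (piecewise by
    emergence stratum), with cladogenetic events drawn from the DEC event
    menu at each node.  Returns (tip_ranges dict, event log); the log
    records every anagenetic expansion/contraction and every cladogenetic
    event with its age, so stochastic-mapping output can be validated
    against the truth.
    """
    space = StateSpace(geo, max_range_size)
    strata = geo.strata(tree.crown_age)
    Qs = [anagenetic_Q(space, params, mask) for _, _, mask in strata]
    rng = np.random.default_rng(seed)

    if isinstance(root_state, (tuple, list)):
        root_mask = space.mask_of(root_state)
    else:
        root_mask = int(root_state)
    root_idx = space.index[root_mask]
    valid0 = space.valid(strata[0][2])
    if not valid0[root_idx]:
        raise ValidationError("root state unavailable in the root stratum")

    def stratum_at(age, forward=False):
        # forward=True: evolving toward the present from exactly a boundary
        # age must enter the younger stratum, so compare strictly
        for i, (start, end, _) in enumerate(strata):
            if (age > end) if forward else (age >= end):
                return i
        return len(strata) - 1

    events = []

    def evolve_branch(state_idx, t_from, t_to, branch):
        """Anagenetic evolution from age t_from down to t_to (t_from > t_to)."""
        t = t_from
        cur = state_idx
        while t > t_to + 1e-13:
            s_idx = stratum_at(t, forward=True)
            seg_end = max(strata[s_idx][1], t_to)
            Q = Qs[s_idx]
            while True:
                rate = -Q[cur, cur]
                if rate <= 0:
                    t = seg_end
                    break
                dt = rng.exponential(1.0 / rate)
                if t - dt <= seg_end:
                    t = seg_end
                    break
                t -= dt
                probs = np.clip(Q[cur], 0, None)
                probs[cur] = 0.0
                nxt = int(rng.choice(space.size, p=probs / probs.sum()))
                old_mask = space.states[cur]
                new_mask = space.states[nxt]
                gained = new_mask & ~old_mask
                lost = old_mask & ~new_mask
                for a in range(space.n_areas):
                    if gained >> a & 1:
                        events.append(("expansion", t, branch,
                                       space.areas_of(old_mask),
                                       geo.areas[a]))
                    if lost >> a & 1:
                        events.append(("extirpation", t, branch,
                                       space.areas_of(old_mask),
                                       geo.areas[a]))
                cur = nxt
            if abs(t - t_to) <= 1e-13:
                break
        return cur

    tip_ranges = {}

    def recurse(node, state_idx):
        if node < tree.n_tips:
            tip_ranges[tree.labels[node]] = space.areas_of(
                space.states[state_idx])
            return
        s_idx = stratum_at(tree.age[node])
        tab = cladogenesis_table(space, params, space.states[state_idx],
                                 strata[s_idx][2])
        probs = np.array([p for _, _, p in tab])
        pick = tab[int(rng.choice(len(tab), p=probs))]
        l_mask, r_mask, _ = pick
        events.append(("cladogenesis", tree.age[node], node,
                       space.areas_of(space.states[state_idx]),
                       (space.areas_of(l_mask), space.areas_of(r_mask))))
        for child, mask in zip(tree.children[node], (l_mask, r_mask)):
            end_state = evolve_branch(space.index[mask], tree.age[node],
                                      tree.age[child], child)
            recurse(child, end_state)

    recurse(tree.root, root_idx)
    return tip_ranges, events


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(n_pops: int = 4, n_per_pop: int = 20,
                       n_loci: int = 500, target_F: float = 0.1,
                       ancestral_freq=(0.1, 0.9), missing_rate: float = 0.0,
                       seed: int = 0, clusters=None,
                       cluster_F: float | None = None) -> GenotypeMatrix:
    """Balding-Nichols island-model genotypes with a target F_ST.

    Per locus an ancestral frequency p is drawn uniformly from
    ``ancestral_freq``; each population's frequency is Beta(p(1-F)/F,
    (1-p)(1-F)/F) and diploid genotypes are Binomial(2, p_pop).  With
    ``clusters`` (a population->cluster map or list) and ``cluster_F``,
    the model becomes hierarchical: each cluster first draws its own
    frequency at divergence ``cluster_F`` from the ancestral one, then
    populations diverge at ``target_F`` inside their cluster -- emulating
    a deep split between island groups.  Monomorphic loci are retained.
    """
    if not (0 < target_F < 1):
        raise ValidationError("target_F must be in (0, 1)")
    rng = np.random.default_rng(seed)
    pops = [f"pop{i+1}" for i in range(n_pops)]
    if clusters is None:
        cluster_of = {p: 0 for p in pops}
    elif isinstance(clusters, dict):
        cluster_of = {p: clusters[p] for p in pops}
    else:
        cluster_of = dict(zip(pops, clusters))
    cluster_ids = sorted(set(cluster_of.values()))

    p_anc = rng.uniform(*ancestral_freq, size=n_loci)

    def bn_draw(p, F):
        a = np.clip(p * (1 - F) / F, 1e-8, None)
        b = np.clip((1 - p) * (1 - F) / F, 1e-8, None)
        return np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)

    cluster_freq = {}
    for c in cluster_ids:
        if cluster_F is not None and len(cluster_ids) > 1:
            cluster_freq[c] = bn_draw(p_anc, cluster_F)
        else:
            cluster_freq[c] = p_anc

    ids, pop_labels, rows = [], [], []
    for p in pops:
        pf = bn_draw(cluster_freq[cluster_of[p]], target_F)
        g = rng.binomial(2, pf, size=(n_per_pop, n_loci)).astype(np.int8)
        for i in range(n_per_pop):
            ids.append(f"{p}_ind{i+1}")
            pop_labels.append(p)
        rows.append(g)
    geno = np.vstack(rows)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    loci = [f"snp{j+1}" for j in range(n_loci)]
    return GenotypeMatrix(ids, pop_labels, loci, geno)
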