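"""SNP population-structure statistics.

Diversity (observed/expected heterozygosity, F_IS), pairwise F_ST
(Weir-Cockerham theta and Hudson, both multilocus ratio-of-averages),
fixed allelic differences, Hardy-Weinberg conditional exact tests with
Bonferroni correction, principal coordinates analysis, and (partial)
Mantel permutation tests of isolation by distance.

Missing genotypes are handled by per-locus pairwise deletion: a locus
enters a statistic only where the populations involved retain at least two
non-missing genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix, ValidationError

# ---------------------------------------------------------------------------
# per-population allele bookkeeping


def _pop_counts(gm: GenotypeMatrix, pop):
    """(n non-missing diploids, alt-allele count, het count) per locus."""
    g = gm.genotype[gm.pop_mask(pop)]
    miss = g < 0
    n = (~miss).sum(axis=0)
    alt = np.where(miss, 0, g).sum(axis=0)
    het = (g == 1).sum(axis=0)
    return n.astype(float), alt.astype(float), het.astype(float)


def heterozygosity_and_fis(gm: GenotypeMatrix, pop) -> dict:
    """Observed/expected heterozygosity and F_IS for one population.

    H_e uses the small-sample unbiased form 2p(1-p) * 2n/(2n-1); F_IS is
    1 - mean(H_o)/mean(H_e) over loci polymorphic in the population
    (ratio of averages).  A population with no polymorphic locus has
    H_e = 0 and undefined F_IS (returned as nan).
    """
    n, alt, het = _pop_counts(gm, pop)
    if (n >= 2).sum() == 0:
        raise ValidationError(f"population {pop!r} has no usable loci")
    use = n >= 2
    p = np.where(use, alt / np.maximum(2 * n, 1), 0.0)
    ho = np.where(use, het / np.maximum(n, 1), 0.0)
    he = 2 * p * (1 - p) * (2 * n) / np.maximum(2 * n - 1, 1)
    poly = use & (p > 0) & (p < 1)
    mean_ho = float(ho[use].mean())
    mean_he = float(he[use].mean())
    if poly.sum() == 0:
        fis = float("nan")
    else:
        fis = 1.0 - float(ho[poly].mean()) / float(he[poly].mean())
    return {"pop": pop, "H_o": mean_ho, "H_e": mean_he, "F_IS": fis,
            "n_polymorphic": int(poly.sum())}


# ---------------------------------------------------------------------------
# F_ST


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) theta components a, b, c for two populations.

    n_i diploid counts, p_i alt-allele frequencies, h_i observed het
    fractions, vectors over loci.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1))
                       * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def _hudson_components(n1, p1, n2, p2):
    """Hudson F_ST per-locus numerator and denominator (Bhatia et al. form)."""
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
           - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def pairwise_fst(gm: GenotypeMatrix, estimator: str = "weir_cockerham",
                 truncate: bool = True):
    """Multilocus pairwise F_ST matrix between all populations.

    Ratio-of-averages across loci; negative multilocus estimates are
    truncated to 0 in the returned matrix when ``truncate`` (the raw
    values are returned alongside).  Returns (pops, fst, fst_raw).
    """
    pops = gm.populations
    if len(pops) < 2:
        raise ValidationError("need at least two populations")
    stats = {p: _pop_counts(gm, p) for p in pops}
    k = len(pops)
    out = np.zeros((k, k))
    raw = np.zeros((k, k))
    for i in range(k):
        for jj in range(i + 1, k):
            n1, a1, h1 = stats[pops[i]]
            n2, a2, h2 = stats[pops[jj]]
            use = (n1 >= 2) & (n2 >= 2)
            if use.sum() == 0:
                raise ValidationError(
                    f"no shared usable loci for {pops[i]!r}/{pops[jj]!r}")
            nn1, nn2 = n1[use], n2[use]
            p1 = a1[use] / (2 * nn1)
            p2 = a2[use] / (2 * nn2)
            if estimator == "weir_cockerham":
                a, b, c = _wc_components(nn1, p1, h1[use] / nn1,
                                         nn2, p2, h2[use] / nn2)
                denom = (a + b + c).sum()
                val = a.sum() / denom if denom != 0 else 0.0
            elif estimator == "hudson":
                # Hudson uses allele counts, not diploid counts
                num, den = _hudson_components(2 * nn1, p1, 2 * nn2, p2)
                dsum = den.sum()
                val = num.sum() / dsum if dsum != 0 else 0.0
            else:
                raise ValidationError(f"unknown estimator {estimator!r}")
            raw[i, jj] = raw[jj, i] = val
            out[i, jj] = out[jj, i] = max(val, 0.0) if truncate else val
    return pops, out, raw


def fixed_differences(gm: GenotypeMatrix, popA, popB) -> dict:
    """Loci where populations A and B share no observed alleles.

    A locus is evaluated only when both populations have at least one
    non-missing genotype there; a fixed difference means the allele sets
    (ref/alt presence) are disjoint.
    """
    out = {"count": 0, "n_evaluated": 0}
    for pop in (popA, popB):
        if pop not in gm.populations:
            raise ValidationError(f"unknown population {pop!r}")
    gA = gm.genotype[gm.pop_mask(popA)]
    gB = gm.genotype[gm.pop_mask(popB)]

    def allele_sets(g):
        miss = g < 0
        any_obs = (~miss).any(axis=0)
        has_ref = ((g == 0) | (g == 1)).any(axis=0)
        has_alt = ((g == 2) | (g == 1)).any(axis=0)
        return any_obs, has_ref, has_alt

    obsA, refA, altA = allele_sets(gA)
    obsB, refB, altB = allele_sets(gB)
    ev = obsA & obsB
    disjoint = ev & ~((refA & refB) | (altA & altB))
    out["count"] = int(disjoint.sum())
    out["n_evaluated"] = int(ev.sum())
    out["fraction"] = out["count"] / out["n_evaluated"] if out["n_evaluated"] \
        else float("nan")
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact HWE test p-value for one locus.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) that are no more probable than the observed one, under
    the classical conditional distribution
    P(het | nA, n) proportional to  n! / (nAA! nAa! naa!) * 2^het.
    Monomorphic loci give p = 1.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0:
            raise ValidationError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValidationError("empty genotype counts")
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa
    if nA == 0 or na == 0:
        return 1.0
    rare = min(nA, na)
    hets = range(rare % 2, rare + 1, 2)

    def logprob(h):
        hom_A = (nA - h) // 2
        hom_a = (na - h) // 2
        return (gammaln(n + 1) - gammaln(hom_A + 1) - gammaln(h + 1)
                - gammaln(hom_a + 1) + h * math.log(2)
                - (gammaln(2 * n + 1) - gammaln(nA + 1) - gammaln(na + 1)))

    lps = np.array([logprob(h) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs = list(hets).index(n_Aa)
    return float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())


def hwe_scan(gm: GenotypeMatrix, alpha: float = 0.05) -> dict:
    """Per-population HWE exact tests with Bonferroni correction.

    Within each population the threshold is alpha / m where m is the
    number of testable (polymorphic, n >= 2) loci in that population.
    Returns per-population p-value arrays, the Bonferroni-significant
    locus sets, and the loci significant in more than one population.
    """
    res = {}
    sig_sets = {}
    for pop in gm.populations:
        g = gm.genotype[gm.pop_mask(pop)]
        pvals = np.full(gm.n_loci, np.nan)
        for j in range(gm.n_loci):
            col = g[:, j]
            col = col[col >= 0]
            if col.size < 2:
                continue
            pvals[j] = hwe_exact(int((col == 0).sum()), int((col == 1).sum()),
                                 int((col == 2).sum()))
        m = int(np.isfinite(pvals).sum())
        thr = alpha / m if m else 0.0
        sig = set(np.flatnonzero(np.nan_to_num(pvals, nan=1.0) < thr))
        res[pop] = {"p": pvals, "m_tests": m, "threshold": thr,
                    "significant": sig}
        sig_sets[pop] = sig
    counts = {}
    for s in sig_sets.values():
        for j in s:
            counts[j] = counts.get(j, 0) + 1
    res["multi_population_violations"] = sorted(
        j for j, c in counts.items() if c >= 2)
    return res


# ---------------------------------------------------------------------------
# PCoA


class PCoA(BaseEstimator):
    """Principal coordinates analysis (classical MDS) of a distance matrix.

    Gower double-centering followed by eigendecomposition.  Axes are
    ordered by eigenvalue; percent variance uses only the positive
    eigenvalues in the denominator, with negative eigenvalues reported.

    Attributes (after fit): ``coords_`` (n x k, positive axes only),
    ``eigenvalues_`` (all, descending), ``percent_variance_``.
    """

    def __init__(self, n_components=None):
        self.n_components = n_components

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        pos = vals > max(vals.max(), 0) * 1e-12
        self.eigenvalues_ = vals
        possum = vals[pos].sum()
        self.percent_variance_ = np.where(pos, 100 * vals / possum, 0.0)[pos]
        coords = vecs[:, pos] * np.sqrt(vals[pos])
        if self.n_components is not None:
            coords = coords[:, : self.n_components]
            self.percent_variance_ = self.percent_variance_[
                : self.n_components]
        self.coords_ = coords
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).coords_


def pcoa(D, n_components=None) -> PCoA:
    """Thin functional wrapper over :class:`PCoA`."""
    return PCoA(n_components=n_components).fit(D)


def allele_sharing_distance(gm: GenotypeMatrix) -> np.ndarray:
    """1 - proportion of shared alleles between individuals.

    Per pair, over loci where both genotypes are observed; the shared
    proportion at one locus is 1 - |g_i - g_j| / 2.
    """
    g = gm.genotype.astype(float)
    g[gm.genotype < 0] = np.nan
    n = gm.n_individuals
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i] - g[i + 1:])
        ok = ~np.isnan(diff)
        with np.errstate(invalid="ignore"):
            d = np.nansum(diff / 2.0, axis=1) / ok.sum(axis=1)
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


# ---------------------------------------------------------------------------
# Mantel


def linearized_fst(fst: np.ndarray) -> np.ndarray:
    """F_ST / (1 - F_ST), the Rousset linearisation used for IBD regressions.

    Entries at 1 map to inf; the raw-F_ST alternative is the default input
    to the Mantel tests, with this transform available when preferred.
    """
    fst = np.asarray(fst, dtype=float)
    with np.errstate(divide="ignore"):
        out = fst / (1.0 - fst)
    np.fill_diagonal(out, 0.0)
    return out


def _offdiag_upper(D):
    iu = np.triu_indices(D.shape[0], 1)
    return np.asarray(D, dtype=float)[iu]


def _check_matrices(*Ds):
    n = Ds[0].shape[0]
    for D in Ds:
        D = np.asarray(D, dtype=float)
        if D.shape != (n, n):
            raise ValidationError("Mantel matrices must share shape")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValidationError("Mantel matrices must be symmetric")


def mantel(dx, dy, permutations: int = 9999, seed: int = 0):
    """Mantel test: Pearson r over upper-triangle entries, permutation p.

    p = (1 + #{|r*| >= |r|}) / (permutations + 1), permuting rows/columns
    of one matrix jointly.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    _check_matrices(dx, dy)
    if permutations < 99:
        raise ValidationError("use at least 99 permutations")
    vx = _offdiag_upper(dx)
    vy = _offdiag_upper(dy)
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise ValidationError("constant distance matrix")
    xc = vx - vx.mean()
    r_obs = float((xc @ (vy - vy.mean()))
                  / math.sqrt((xc @ xc) * ((vy - vy.mean()) @ (vy - vy.mean()))))
    rng = np.random.default_rng(seed)
    n = dx.shape[0]
    iu = np.triu_indices(n, 1)
    count = 0
    sx = xc / math.sqrt(xc @ xc)
    for _ in range(permutations):
        perm = rng.permutation(n)
        vyp = dy[np.ix_(perm, perm)][iu]
        yc = vyp - vyp.mean()
        denom = math.sqrt(yc @ yc)
        r = float(sx @ yc) / denom if denom > 0 else 0.0
        if abs(r) >= abs(r_obs) - 1e-15:
            count += 1
    p = (1 + count) / (permutations + 1)
    return r_obs, p


def _residualize(v, z):
    zc = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(zc, v, rcond=None)
    return v - zc @ beta


def partial_mantel(dx, dy, dz, permutations: int = 9999, seed: int = 0):
    """Partial Mantel: correlation of dx and dy residualised on dz.

    The permutation scheme permutes the labels of dx and recomputes the
    partial correlation each time.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    dz = np.asarray(dz, dtype=float)
    _check_matrices(dx, dy, dz)
    if permutations < 99:
        raise ValidationError("use at least 99 permutations")
    vz = _offdiag_upper(dz)
    vy = _offdiag_upper(dy)
    vx = _offdiag_upper(dx)
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise ValidationError("constant distance matrix")
    ry = _residualize(vy, vz)

    def pcorr(vx_perm):
        rx = _residualize(vx_perm, vz)
        num = rx @ ry
        den = math.sqrt((rx @ rx) * (ry @ ry))
        return num / den if den > 0 else 0.0

    r_obs = float(pcorr(vx))
    rng = np.random.default_rng(seed)
    n = dx.shape[0]
    iu = np.triu_indices(n, 1)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        vxp = dx[np.ix_(perm, perm)][iu]
        if abs(pcorr(vxp)) >= abs(r_obs) - 1e-15:
            count += 1
    p = (1 + count) / (permutations + 1)
    return r_obs, p
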