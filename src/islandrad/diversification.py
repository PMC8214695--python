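"""Time-varying birth-death diversification models on dated trees.

Three nested model kinds are supported on an ultrametric TimeTree:

* ``constant``  — lambda(t) = lambda0, mu(t) = mu0
* ``time_exp``  — lambda(t) = lambda0 * exp(alpha * t), t in Ma before present
* ``temp_exp``  — lambda(t) = lambda0 * exp(alpha * T(t)) for a paleo-
  temperature curve T(t); a negative alpha with a cooling climate means
  speciation accelerates as the ocean cools.

Extinction is mu0 (optionally mu0 * exp(beta * t or T)).  The likelihood is
the reconstructed-tree birth-death likelihood with rho-sampling (a global
sampling fraction f), conditioned on the crown age and on both crown
lineages being represented in the sample.

Writing r(t) = int_0^t (lambda - mu) ds and A(t) = 1/f + int_0^t
e^{r(s)} lambda(s) ds, the probability that a lineage alive at age t leaves
no sampled descendant is E(t) = 1 - e^{r(t)}/A(t) (the exact solution of
the usual Riccati equation), and each observed branch (t_child, t_parent)
contributes the log-factor

    r(t_parent) - r(t_child) + 2*(log A(t_child) - log A(t_parent)).

Every quantity therefore reduces to two cumulative integrals evaluated on a
dense grid that includes the node ages; grid density is the accuracy knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .datatypes import ClimateSeries, TimeTree, ValidationError

_LOGLIK_FLOOR = -1e10

MODEL_KINDS = ("constant", "time_exp", "temp_exp")


@dataclass
class DiversificationModel:
    """Parameter bundle for one birth-death model."""

    kind: str
    lambda0: float
    alpha: float = 0.0
    mu0: float = 0.0
    beta: float = 0.0
    f: float = 1.0
    climate: ClimateSeries | None = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValidationError(f"unknown model kind {self.kind!r}")
        if self.lambda0 <= 0:
            raise ValidationError("lambda0 must be positive")
        if self.mu0 < 0:
            raise ValidationError("mu0 must be non-negative")
        if not (0 < self.f <= 1):
            raise ValidationError("sampling fraction f must be in (0, 1]")
        if self.kind == "temp_exp" and self.climate is None:
            raise ValidationError("temp_exp needs a temperature ClimateSeries")
        if self.climate is not None and self.climate.kind != "temperature":
            raise ValidationError("climate must be a temperature series")

    def rates_on(self, t: np.ndarray):
        """(lambda(t), mu(t)) evaluated on an age grid."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            drv = np.zeros_like(t)
        elif self.kind == "time_exp":
            drv = t
        else:
            drv = np.interp(t, self.climate.age, self.climate.value)
        lam = self.lambda0 * np.exp(self.alpha * drv)
        mu = self.mu0 * np.exp(self.beta * drv)
        return lam, mu

    def n_free_params(self) -> int:
        k = 2  # lambda0, mu0
        if self.kind != "constant":
            k += 1
        if self.beta != 0.0:
            k += 1
        return k


# ---------------------------------------------------------------------------
# likelihood


def _build_grid(crown_age: float, node_ages: np.ndarray, n_grid: int,
                extra=None):
    base = np.linspace(0.0, crown_age, n_grid)
    grid = np.union1d(base, np.clip(node_ages, 0.0, crown_age))
    if extra is not None:
        grid = np.union1d(grid, np.clip(np.asarray(extra, dtype=float),
                                        0.0, crown_age))
    return grid


def bd_loglik(tree: TimeTree, model: DiversificationModel,
              n_grid: int = 2048, extra_knots=None) -> float:
    """Log-likelihood of the reconstructed tree under `model`.

    Conditioned on the crown age and survival of both crown lineages;
    sampling fraction applied as rho-sampling.  `n_grid` controls the
    resolution of the trapezoid quadrature of the rate integrals (node ages
    are always included exactly).
    """
    T = tree.crown_age
    if model.kind == "temp_exp":
        if model.climate.age[0] > 1e-9 or model.climate.age[-1] < T - 1e-9:
            raise ValidationError(
                "climate series must span [0, crown_age] for temp_exp")
    grid = _build_grid(T, tree.age, n_grid, extra=extra_knots)
    lam, mu = model.rates_on(grid)
    if np.any(~np.isfinite(lam)) or np.any(lam <= 0) or np.any(mu < 0):
        return _LOGLIK_FLOOR
    # r(t) = cumulative integral of (lambda - mu); trapezoid is robust to
    # the near-duplicate grid knots the piecewise shift model inserts
    dt = np.diff(grid)
    net = lam - mu
    r = np.concatenate([[0.0], np.cumsum(0.5 * (net[1:] + net[:-1]) * dt)])
    if np.max(r) > 600:  # exp would overflow; parameters are absurd anyway
        return _LOGLIK_FLOOR
    g_lam = np.exp(r) * lam
    A = 1.0 / model.f + np.concatenate(
        [[0.0], np.cumsum(0.5 * (g_lam[1:] + g_lam[:-1]) * dt)])
    logA = np.log(A)

    idx = np.searchsorted(grid, tree.age)
    # node ages are in the grid exactly; guard against roundoff
    idx = np.clip(idx, 0, grid.size - 1)
    r_at = r[idx]
    logA_at = logA[idx]

    nonroot = np.arange(tree.n_nodes) != tree.root
    par = tree.parent[nonroot]
    ll = float(np.sum(r_at[par] - r_at[nonroot]
                      + 2.0 * (logA_at[nonroot] - logA_at[par])))
    internal = np.array([i for i in tree.children if i != tree.root], dtype=int)
    if internal.size:
        lam_nodes = model.rates_on(tree.age[internal])[0]
        ll += float(np.sum(np.log(lam_nodes)))
    ll += tree.n_tips * math.log(model.f)
    # conditioning: both crown lineages sampled-surviving
    iT = grid.size - 1
    ll -= 2.0 * (r[iT] - logA[iT])
    if not np.isfinite(ll):
        return _LOGLIK_FLOOR
    return ll


def aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_weights(aiccs) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(aiccs, dtype=float)
    if a.size < 2:
        raise ValidationError("need at least two AICc values")
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


# ---------------------------------------------------------------------------
# ML fitting


class BirthDeathModel(BaseEstimator):
    """ML fit of one birth-death model kind to a dated tree.

    Parameters
    ----------
    kind : "constant", "time_exp" or "temp_exp".
    sampling_fraction : global rho-sampling fraction f in (0, 1].
    climate : temperature ClimateSeries (temp_exp only).
    vary_extinction : if True, extinction also responds exponentially to the
        driver (frees beta); default keeps mu constant.
    n_starts : multi-start count for the bounded optimizer.
    n_grid : quadrature grid resolution for the likelihood.
    seed : RNG seed for the randomised starts.

    Attributes (after fit)
    ----------------------
    lambda0_, alpha_, mu0_, beta_ : ML parameter estimates.
    loglik_, aicc_, n_params_ : fit summaries.
    model_ : the fitted DiversificationModel.
    converged_ : False when every optimizer start failed to converge.
    """

    def __init__(self, kind="constant", sampling_fraction=1.0, climate=None,
                 vary_extinction=False, n_starts=6, n_grid=1024, seed=0):
        self.kind = kind
        self.sampling_fraction = sampling_fraction
        self.climate = climate
        self.vary_extinction = vary_extinction
        self.n_starts = n_starts
        self.n_grid = n_grid
        self.seed = seed

    # transformed coordinates: x = (log lambda0, [alpha], log mu0, [beta])
    def _unpack(self, x):
        lam0 = math.exp(x[0])
        j = 1
        alpha = 0.0
        if self.kind != "constant":
            alpha = x[j]
            j += 1
        mu0 = math.exp(x[j])
        j += 1
        beta = x[j] if self.vary_extinction else 0.0
        return lam0, alpha, mu0, beta

    def _bounds(self):
        b = [(math.log(1e-4), math.log(20.0))]
        if self.kind != "constant":
            b.append((-2.0, 2.0))
        b.append((math.log(1e-8), math.log(20.0)))
        if self.vary_extinction:
            b.append((-2.0, 2.0))
        return b

    def _model(self, x):
        lam0, alpha, mu0, beta = self._unpack(x)
        return DiversificationModel(
            self.kind, lam0, alpha, mu0, beta,
            f=self.sampling_fraction, climate=self.climate)

    def fit(self, tree: TimeTree, y=None):
        if self.kind not in MODEL_KINDS:
            raise ValidationError(f"unknown model kind {self.kind!r}")
        rng = np.random.default_rng(self.seed)
        n = tree.n_tips
        # Yule-style heuristic for the initial speciation rate
        tot_bl = float(tree.branch_lengths().sum())
        lam_guess = max((n - 2) / tot_bl, 1e-3) if tot_bl > 0 else 0.1

        # surface structural problems (e.g. climate not spanning the tree)
        # before optimisation rather than silently fitting a flat objective
        if self.kind == "temp_exp":
            probe = DiversificationModel(
                "temp_exp", 0.1, alpha=0.0, mu0=0.0,
                f=self.sampling_fraction, climate=self.climate)
            bd_loglik(tree, probe, n_grid=8)

        def neg(x):
            try:
                return -bd_loglik(tree, self._model(x), n_grid=self.n_grid)
            except ValidationError:
                return -_LOGLIK_FLOOR

        bounds = self._bounds()
        starts = []
        base = [math.log(lam_guess)]
        if self.kind != "constant":
            base.append(0.0)
        base.append(math.log(max(lam_guess * 0.25, 1e-6)))
        if self.vary_extinction:
            base.append(0.0)
        starts.append(np.array(base))
        for _ in range(max(self.n_starts - 1, 0)):
            x = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            # keep random starts near plausible rates rather than the corners
            x[0] = math.log(lam_guess) + rng.normal(0, 1.0)
            starts.append(np.clip(x, [b[0] for b in bounds],
                                  [b[1] for b in bounds]))

        best, best_val, any_ok = None, math.inf, False
        for x0 in starts:
            res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
            any_ok = any_ok or res.success
            val, x = res.fun, res.x
            better = val < best_val - 1e-9 or (
                abs(val - best_val) <= 1e-9
                and best is not None
                and np.linalg.norm(x) < np.linalg.norm(best))
            if best is None or better:
                best, best_val = x, val

        self.converged_ = bool(any_ok)
        self.lambda0_, self.alpha_, self.mu0_, self.beta_ = self._unpack(best)
        self.model_ = self._model(best)
        self.loglik_ = -best_val
        self.n_params_ = self.model_.n_free_params()
        self.aicc_ = aicc(self.loglik_, self.n_params_, n)
        return self

    def score(self, tree: TimeTree, y=None) -> float:
        return bd_loglik(tree, self.model_, n_grid=self.n_grid)


def fit_model(tree: TimeTree, kind: str, climate=None, f: float = 1.0,
              **kw) -> BirthDeathModel:
    """Thin functional wrapper over :class:`BirthDeathModel`."""
    return BirthDeathModel(kind=kind, sampling_fraction=f, climate=climate,
                           **kw).fit(tree)


def compare_models(tree: TimeTree, climate: ClimateSeries, f: float = 1.0,
                   kinds=MODEL_KINDS, **kw) -> dict:
    """Fit every kind and return {kind: fitted estimator} plus AICc weights."""
    fits = {k: fit_model(tree, k, climate=climate if k == "temp_exp" else None,
                         f=f, **kw) for k in kinds}
    w = aicc_weights([fits[k].aicc_ for k in kinds])
    return {"fits": fits, "kinds": list(kinds),
            "aicc": {k: fits[k].aicc_ for k in kinds},
            "weights": dict(zip(kinds, w.tolist()))}


# ---------------------------------------------------------------------------
# posterior sampling


@dataclass
class PosteriorDraw:
    """One retained MCMC draw with its rate trajectory on a shared grid."""

    lambda0: float
    alpha: float
    mu0: float
    log_posterior: float
    grid: np.ndarray
    rate_trajectory: np.ndarray  # lambda(t) on grid
    net_trajectory: np.ndarray   # lambda(t) - mu(t) on grid


@dataclass
class PriorSpec:
    """Independent priors over (log lambda0, alpha, log mu0)."""

    log_lambda0: tuple = (math.log(0.1), 1.5)
    alpha: tuple = (0.0, 1.0)
    log_mu0: tuple = (math.log(0.05), 1.5)

    def logpdf(self, x):
        out = 0.0
        for v, (m, s) in zip(x, (self.log_lambda0, self.alpha, self.log_mu0)):
            out += -0.5 * ((v - m) / s) ** 2 - math.log(s) \
                - 0.5 * math.log(2 * math.pi)
        return out

    def sample(self, rng):
        return np.array([rng.normal(m, s) for m, s in
                         (self.log_lambda0, self.alpha, self.log_mu0)])


def metropolis_sample(logpost, x0, n_iter: int, seed: int,
                      burnin_frac: float = 0.1, thin: int = 1,
                      step0: float = 0.2):
    """Random-walk Metropolis with scale adaptation during burn-in only.

    Returns (draws array, log-posteriors array, acceptance rate).
    """
    if n_iter <= 0:
        raise ValidationError("n_iter must be positive")
    rng = np.random.default_rng(seed)
    d = len(x0)
    x = np.asarray(x0, dtype=float).copy()
    lp = logpost(x)
    step = float(step0)
    n_burn = int(burnin_frac * n_iter)
    draws, lps = [], []
    n_acc = 0
    for it in range(n_iter):
        prop = x + rng.normal(0, step, size=d)
        lp_prop = logpost(prop)
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            n_acc += 1
        if it < n_burn and (it + 1) % 50 == 0:
            acc = n_acc / (it + 1)
            step *= math.exp(0.5 * (acc - 0.3))
            step = min(max(step, 1e-3), 5.0)
        if it >= n_burn and (it - n_burn) % thin == 0:
            draws.append(x.copy())
            lps.append(lp)
    return np.array(draws), np.array(lps), n_acc / n_iter


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chains, n_draws) array of one scalar parameter."""
    half = chains.shape[1] // 2
    if half < 2:
        return float("nan")
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W)) if W > 0 else float("nan")


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence effective sample size of one chain."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or x.var() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (xc @ xc)
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] < 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


class DiversificationSampler(BaseEstimator):
    """Single-regime Bayesian posterior over (lambda0, alpha, mu0).

    Random-walk Metropolis in (log lambda0, alpha, log mu0) under wide
    normal priors; four chains by default, 10% burn-in, thinned so at least
    `min_retained` draws are kept in total.  Each retained draw carries its
    speciation-rate trajectory lambda(t) on a shared age grid.

    Attributes (after fit)
    ----------------------
    draws_ : list of PosteriorDraw
    diagnostics_ : dict with acceptance rates, split-R-hat and ESS
    grid_ : the shared age grid
    """

    def __init__(self, kind="temp_exp", sampling_fraction=1.0, climate=None,
                 priors=None, chains=4, n_iter=50_000, burnin_frac=0.1,
                 min_retained=9_000, n_grid=512, traj_points=101, seed=0):
        self.kind = kind
        self.sampling_fraction = sampling_fraction
        self.climate = climate
        self.priors = priors
        self.chains = chains
        self.n_iter = n_iter
        self.burnin_frac = burnin_frac
        self.min_retained = min_retained
        self.n_grid = n_grid
        self.traj_points = traj_points
        self.seed = seed

    def _make_model(self, x):
        return DiversificationModel(
            self.kind, math.exp(x[0]),
            x[1] if self.kind != "constant" else 0.0, math.exp(x[2]),
            f=self.sampling_fraction, climate=self.climate)

    def fit(self, tree: TimeTree, y=None):
        if self.n_iter <= 0:
            raise ValidationError("n_iter must be positive")
        if self.kind == "temp_exp":
            probe = DiversificationModel(
                "temp_exp", 0.1, alpha=0.0, mu0=0.0,
                f=self.sampling_fraction, climate=self.climate)
            bd_loglik(tree, probe, n_grid=8)
        priors = self.priors or PriorSpec()
        per_chain = max(self.min_retained // self.chains, 1)
        kept_per_chain = self.n_iter - int(self.burnin_frac * self.n_iter)
        thin = max(kept_per_chain // per_chain, 1)

        def logpost(x):
            lp = priors.logpdf(x)
            try:
                ll = bd_loglik(tree, self._make_model(x), n_grid=self.n_grid)
            except ValidationError:
                return -math.inf
            return lp + ll

        grid = np.linspace(0.0, tree.crown_age, self.traj_points)
        all_draws, chain_arrays, accs = [], [], []
        for c in range(self.chains):
            rng = np.random.default_rng((self.seed, c))
            x0 = priors.sample(rng)
            d, lps, acc = metropolis_sample(
                logpost, x0, self.n_iter,
                seed=np.random.SeedSequence((self.seed, 1000 + c))
                    .generate_state(1)[0],
                burnin_frac=self.burnin_frac, thin=thin)
            chain_arrays.append(d)
            accs.append(acc)
            for x, lp in zip(d, lps):
                m = self._make_model(x)
                lam, mu = m.rates_on(grid)
                all_draws.append(PosteriorDraw(
                    m.lambda0, m.alpha, m.mu0, float(lp),
                    grid, lam, lam - mu))
        nmin = min(a.shape[0] for a in chain_arrays)
        stacked = np.stack([a[:nmin] for a in chain_arrays])
        diag = {"acceptance": accs}
        names = ["log_lambda0", "alpha", "log_mu0"]
        diag["split_rhat"] = {
            nm: _split_rhat(stacked[:, :, j]) for j, nm in enumerate(names)}
        diag["ess"] = {
            nm: float(sum(_ess(a[:, j]) for a in chain_arrays))
            for j, nm in enumerate(names)}
        low = {k: v for k, v in diag["ess"].items() if v < 100}
        if low:
            import warnings

            warnings.warn(
                f"low effective sample size {low}; treat posterior "
                "summaries with caution", stacklevel=2)
        self.draws_ = all_draws
        self.diagnostics_ = diag
        self.grid_ = grid
        return self


def sample_posterior(tree: TimeTree, kind: str, climate=None, priors=None,
                     chains: int = 4, iters: int = 50_000,
                     burnin_frac: float = 0.1, seed: int = 0,
                     **kw) -> DiversificationSampler:
    """Thin functional wrapper over :class:`DiversificationSampler`."""
    return DiversificationSampler(
        kind=kind, climate=climate, priors=priors, chains=chains,
        n_iter=iters, burnin_frac=burnin_frac, seed=seed, **kw).fit(tree)


def rate_through_time(draws, grid=None):
    """Pointwise mean and central 95% band of lambda(t) and net r(t).

    Returns a dict with grid, mean/lo/hi for the speciation rate and the
    net diversification rate.
    """
    if not draws:
        raise ValidationError("no posterior draws supplied")
    g0 = draws[0].grid
    for d in draws:
        if d.grid.shape != g0.shape or not np.allclose(d.grid, g0):
            raise ValidationError("draws carry different age grids")
    if grid is not None and not np.allclose(grid, g0):
        raise ValidationError("requested grid differs from the draws' grid")
    lam = np.stack([d.rate_trajectory for d in draws])
    net = np.stack([d.net_trajectory for d in draws])
    out = {"grid": g0.copy()}
    for name, arr in (("speciation", lam), ("net", net)):
        out[name] = {
            "mean": arr.mean(axis=0),
            "lo": np.quantile(arr, 0.025, axis=0),
            "hi": np.quantile(arr, 0.975, axis=0),
        }
    return out


# ---------------------------------------------------------------------------
# single-shift model


@dataclass
class ShiftFit:
    """Best single-shift piecewise-constant fit vs the no-shift model."""

    shift_time: float
    lambda_old: float     # rate before the shift (older than shift_time)
    lambda_young: float   # rate after the shift
    mu: float
    loglik_shift: float
    loglik_constant: float
    delta_aicc: float     # AICc(constant) - AICc(shift); >2 favours shift
    significant: bool
    low_power: bool = False


class _PiecewiseModel(DiversificationModel):
    """Constant-extinction, two-epoch speciation; internal to the shift fit."""

    def __init__(self, lam_old, lam_young, mu, shift, f=1.0):
        # bypass the dataclass init: kind formalities do not apply here
        self.kind = "constant"
        self.lambda0 = lam_young
        self.alpha = 0.0
        self.mu0 = mu
        self.beta = 0.0
        self.f = f
        self.climate = None
        self._lam_old = lam_old
        self._shift = shift

    def rates_on(self, t):
        t = np.asarray(t, dtype=float)
        lam = np.where(t >= self._shift, self._lam_old, self.lambda0)
        return lam, np.full_like(lam, self.mu0)


class SingleShiftModel(BaseEstimator):
    """ML comparison of 0-shift vs 1-shift piecewise-constant birth-death.

    The shift time is profiled over a grid of candidate ages; for each
    candidate the two speciation rates and the extinction rate are fit by
    bounded optimisation.  The shift is called significant when its AICc
    (k = 4: two rates, mu, shift time) beats the constant model's (k = 2)
    by more than 2.
    """

    def __init__(self, sampling_fraction=1.0, n_candidates=24, n_grid=1024,
                 n_starts=3, seed=0):
        self.sampling_fraction = sampling_fraction
        self.n_candidates = n_candidates
        self.n_grid = n_grid
        self.n_starts = n_starts
        self.seed = seed

    def fit(self, tree: TimeTree, y=None):
        n = tree.n_tips
        low_power = n < 10
        const = BirthDeathModel(
            "constant", sampling_fraction=self.sampling_fraction,
            n_starts=self.n_starts, n_grid=self.n_grid, seed=self.seed
        ).fit(tree)
        T = tree.crown_age
        cands = np.linspace(0.05 * T, 0.95 * T, self.n_candidates)
        rng = np.random.default_rng(self.seed)
        bounds = [(math.log(1e-4), math.log(20.0))] * 2 + \
                 [(math.log(1e-8), math.log(20.0))]
        best = None
        for s in cands:
            def neg(x, s=s):
                m = _PiecewiseModel(math.exp(x[0]), math.exp(x[1]),
                                    math.exp(x[2]), s,
                                    f=self.sampling_fraction)
                # put the shift age on the quadrature grid so the step in
                # lambda(t) is integrated exactly
                return -bd_loglik(tree, m, n_grid=self.n_grid,
                                  extra_knots=[s, s - 1e-9])

            x0s = [np.array([math.log(const.lambda0_)] * 2
                            + [math.log(max(const.mu0_, 1e-6))])]
            for _ in range(self.n_starts - 1):
                x0s.append(x0s[0] + rng.normal(0, 0.7, size=3))
            for x0 in x0s:
                res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                        bounds=bounds)
                if best is None or res.fun < best[0]:
                    best = (res.fun, res.x, s)
        ll_shift = -best[0]
        x = best[1]
        a_const = aicc(const.loglik_, 2, n)
        a_shift = aicc(ll_shift, 4, n)
        delta = a_const - a_shift
        self.result_ = ShiftFit(
            shift_time=float(best[2]),
            lambda_old=math.exp(x[0]), lambda_young=math.exp(x[1]),
            mu=math.exp(x[2]), loglik_shift=ll_shift,
            loglik_constant=const.loglik_, delta_aicc=float(delta),
            significant=bool(delta > 2.0), low_power=low_power)
        return self


def fit_single_shift(tree: TimeTree, **kw) -> ShiftFit:
    """Thin functional wrapper over :class:`SingleShiftModel`."""
    return SingleShiftModel(**kw).fit(tree).result_
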