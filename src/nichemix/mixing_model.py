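"""Concentration-dependent Bayesian mixing model with individual random effects.

The model estimates proportional source (prey) contributions to consumer
tissue from trivariate isotope data. For diet proportions p on the K-simplex
the expected consumer signature on isotope axis e is the
concentration-weighted mixture

    w_k = p_k c_ke / sum_j p_j c_je
    mean_e = sum_k w_k (s_ke + D_e)
    var_e  = sum_k w_k^2 (sigma_ke^2 + sigma_De^2)

where c_ke is source k's mass concentration of the element measured on axis
e, s_ke its isotope mean, and D_e / sigma_De the trophic enrichment factor
(TEF) mean / SD. Carbon-rich sources therefore contribute more to the
carbon-isotope mixture than their biomass proportion alone.

Hierarchy: the population diet has a Dirichlet(1,...,1) (uniform-on-simplex)
prior; individual diets deviate from the population in isometric log-ratio
(ILR) coordinates by normal random effects with per-coordinate half-Cauchy
scales; each isotope axis carries an additive residual variance with a
half-Cauchy prior. Sampling is adaptive Metropolis-within-Gibbs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .delta_niche import MCMCSettings, gelman_rubin
from .tables_io import ISOTOPE_AXES, TEFScenario

__all__ = [
    "DietPosterior",
    "MixingProblem",
    "ilr_basis",
    "ilr",
    "ilr_inv",
    "mixture_moments",
    "fit_mixing",
    "mixing_region_probability",
    "posterior_compare",
    "c_index",
]

_ELEMENT_OF_AXIS = {"d13C": "C", "d15N": "N", "d34S": "S"}


# ---------------------------------------------------------------------------
# ILR transform (fixed sequential-binary-partition basis in source order)

def ilr_basis(k: int) -> np.ndarray:
    """Orthonormal (k, k-1) ILR contrast basis (Helmert-type partition)."""
    if k < 2:
        raise ValueError("need k >= 2")
    V = np.zeros((k, k - 1))
    for j in range(1, k):
        V[:j, j - 1] = 1.0 / j
        V[j, j - 1] = -1.0
        V[:, j - 1] *= np.sqrt(j / (j + 1.0))
    return V


def ilr(p, basis: np.ndarray | None = None) -> np.ndarray:
    """Map simplex composition(s) to unconstrained ILR coordinates."""
    p = np.asarray(p, dtype=float)
    k = p.shape[-1]
    V = ilr_basis(k) if basis is None else basis
    return np.log(p) @ V


def ilr_inv(z, basis: np.ndarray | None = None) -> np.ndarray:
    """Inverse ILR: coordinates back to the simplex (rows sum to 1)."""
    z = np.asarray(z, dtype=float)
    k = z.shape[-1] + 1
    V = ilr_basis(k) if basis is None else basis
    logits = z @ V.T
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Problem containers

def _source_arrays(sources, tef: TEFScenario):
    """(K, 3) TEF-adjusted means, combined variances, element concentrations."""
    K = len(sources)
    s_adj = np.zeros((K, 3))
    var_adj = np.zeros((K, 3))
    conc = np.zeros((K, 3))
    dmean = tef.delta_mean.as_array()
    dsd = tef.delta_sd.as_array()
    for k, src in enumerate(sources):
        if not src.conc or any(_ELEMENT_OF_AXIS[a] not in src.conc for a in ISOTOPE_AXES):
            raise ValueError(f"source {src.label} missing element concentrations")
        s_adj[k] = src.iso_mean.as_array() + dmean
        var_adj[k] = src.iso_sd.as_array() ** 2 + dsd**2
        conc[k] = [src.conc[_ELEMENT_OF_AXIS[a]] for a in ISOTOPE_AXES]
    return s_adj, var_adj, conc


@dataclass(frozen=True)
class MixingProblem:
    """Sources + TEF scenario + QC-passed consumer data grouped by individual.

    ``consumers`` maps individual id -> (n_i, 3) array of isotope triples in
    (d13C, d15N, d34S) order.
    """

    sources: tuple
    tef: TEFScenario
    consumers: dict

    def __post_init__(self) -> None:
        if len(self.sources) < 2:
            raise ValueError("need K >= 2 sources")
        for s in self.sources:
            if not s.conc or any(_ELEMENT_OF_AXIS[a] not in s.conc for a in ISOTOPE_AXES):
                raise ValueError(f"source {s.label} missing element concentrations")

    def arrays(self):
        """(s_adj, var_adj, conc): (K, 3) TEF-adjusted means, total variances,
        and element concentrations aligned to the isotope axes."""
        return _source_arrays(self.sources, self.tef)


@dataclass(frozen=True)
class DietPosterior:
    """Posterior draws of diet proportions for one entity (simplex rows)."""

    entity: str
    draws: np.ndarray  # (D, K)
    source_labels: tuple = ()

    def __post_init__(self) -> None:
        d = self.draws
        if d.ndim != 2:
            raise ValueError("draws must be (D, K)")
        if np.any(d < -1e-12) or np.any(np.abs(d.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every draw must lie on the simplex")

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def credible_interval(self, prob: float = 0.95) -> np.ndarray:
        """(2, K) equal-tailed interval per source."""
        a = (1.0 - prob) / 2.0
        return np.quantile(self.draws, [a, 1.0 - a], axis=0)


# ---------------------------------------------------------------------------
# Mixture moments

def _moments_matrix(P, s_adj, var_adj, conc):
    """Vectorised mixture moments: P (I, K) -> mean, var each (I, 3)."""
    denom = P @ conc  # (I, 3)
    if np.any(denom <= 0):
        raise ValueError("all source concentrations zero for some element")
    mean = np.empty((P.shape[0], 3))
    var = np.empty_like(mean)
    for e in range(3):
        w = P * conc[:, e] / denom[:, e : e + 1]
        mean[:, e] = w @ s_adj[:, e]
        var[:, e] = (w**2) @ var_adj[:, e]
    return mean, var


def mixture_moments(p, sources, tef: TEFScenario, element: str):
    """Concentration-weighted mixture mean and variance on one isotope axis."""
    if element not in ISOTOPE_AXES:
        raise ValueError(f"unknown isotope axis {element!r}")
    e = ISOTOPE_AXES.index(element)
    s_adj, var_adj, conc = _source_arrays(tuple(sources), tef)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must lie on the simplex")
    mean, var = _moments_matrix(p[None, :], s_adj, var_adj, conc)
    return float(mean[0, e]), float(var[0, e])


# ---------------------------------------------------------------------------
# Sampler

def _log_halfcauchy_on_log(logx):
    """log prior of half-Cauchy(0,1) variate x, evaluated at logx, with Jacobian."""
    x = np.exp(logx)
    return logx - np.log1p(x**2)


def _simplex_logprior(z, V):
    """log density of the Dirichlet(1) prior expressed in ILR coordinates.

    Flat on the simplex, so only the ILR Jacobian remains: sum_k log p_k.
    """
    p = ilr_inv(z, V if z.ndim == 1 else V)
    return np.sum(np.log(p), axis=-1)


@dataclass
class _State:
    z_pop: np.ndarray
    Z: np.ndarray  # (I, K-1)
    log_sig: np.ndarray  # (K-1,)
    log_xi: np.ndarray  # (3,)
    L: np.ndarray  # cached per-individual x per-isotope loglik (I, 3)


def _loglik_from_moments(mean, var, xi2, n_obs, S1, S2):
    """Per-individual, per-isotope Gaussian loglik using sufficient stats."""
    V = var + xi2  # (I, 3)
    ss = S2 - 2.0 * mean * S1 + n_obs[:, None] * mean**2
    return -0.5 * (n_obs[:, None] * np.log(2.0 * np.pi * V) + ss / V)


def _loglik_rows(P, xi2, s_adj, var_adj, conc, n_obs, S1, S2):
    mean, var = _moments_matrix(P, s_adj, var_adj, conc)
    return _loglik_from_moments(mean, var, xi2, n_obs, S1, S2), mean, var


def _run_chain(problem_arrays, data, K, settings, seed, init_jitter=1.0):
    s_adj, var_adj, conc = problem_arrays
    n_obs, S1, S2 = data  # (I,), (I,3), (I,3)
    I = len(n_obs)
    V = ilr_basis(K)
    rng = np.random.default_rng(seed)

    st = _State(
        z_pop=rng.normal(0.0, 0.3 * init_jitter, K - 1),
        Z=np.zeros((I, K - 1)),
        log_sig=np.log(np.full(K - 1, 0.5)) + rng.normal(0, 0.2 * init_jitter, K - 1),
        log_xi=np.log(np.full(3, 0.5)) + rng.normal(0, 0.2 * init_jitter, 3),
        L=np.zeros((I, 3)),
    )
    st.Z = st.z_pop + rng.normal(0.0, 0.1, (I, K - 1))
    cur_mean = np.zeros((I, 3))
    cur_var = np.zeros((I, 3))
    if I:
        st.L, cur_mean, cur_var = _loglik_rows(
            ilr_inv(st.Z, V), np.exp(2 * st.log_xi), s_adj, var_adj, conc, n_obs, S1, S2
        )

    # adaptive proposal scales
    sc_pop, sc_Z = 0.3, np.full(I, 0.3)
    sc_sig, sc_xi = np.full(K - 1, 0.5), np.full(3, 0.5)
    acc = {"pop": 0, "Z": np.zeros(I), "sig": np.zeros(K - 1), "xi": np.zeros(3)}
    window = 50

    def z_prior_rows(Z, z_pop, log_sig):
        sig2 = np.exp(2 * log_sig)
        d = Z - z_pop
        return -0.5 * np.sum(d**2 / sig2 + np.log(2 * np.pi * sig2), axis=-1)

    keep_pop, keep_P = [], []
    retained = settings.retained_per_chain
    for it in range(settings.iterations):
        # -- population ILR location
        prop = st.z_pop + rng.normal(0, sc_pop, K - 1)
        cur_lp = _simplex_logprior(st.z_pop, V) + (
            z_prior_rows(st.Z, st.z_pop, st.log_sig).sum() if I else 0.0
        )
        prop_lp = _simplex_logprior(prop, V) + (
            z_prior_rows(st.Z, prop, st.log_sig).sum() if I else 0.0
        )
        if np.log(rng.random()) < prop_lp - cur_lp:
            st.z_pop = prop
            acc["pop"] += 1

        if I:
            # -- individual ILR coordinates (independent row proposals)
            propZ = st.Z + rng.normal(0, 1.0, (I, K - 1)) * sc_Z[:, None]
            xi2 = np.exp(2 * st.log_xi)
            Lp, mean_p, var_p = _loglik_rows(
                ilr_inv(propZ, V), xi2, s_adj, var_adj, conc, n_obs, S1, S2
            )
            dlp = (
                Lp.sum(axis=1)
                - st.L.sum(axis=1)
                + z_prior_rows(propZ, st.z_pop, st.log_sig)
                - z_prior_rows(st.Z, st.z_pop, st.log_sig)
            )
            take = np.log(rng.random(I)) < dlp
            st.Z[take] = propZ[take]
            st.L[take] = Lp[take]
            cur_mean[take] = mean_p[take]
            cur_var[take] = var_p[take]
            acc["Z"] += take

            # -- random-effect scales (coordinate-wise)
            d2 = ((st.Z - st.z_pop) ** 2).sum(axis=0)  # (K-1,)
            prop_ls = st.log_sig + rng.normal(0, sc_sig)
            def sig_logpost(ls):
                s2 = np.exp(2 * ls)
                return -0.5 * (I * np.log(2 * np.pi * s2) + d2 / s2) + _log_halfcauchy_on_log(ls)
            dls = sig_logpost(prop_ls) - sig_logpost(st.log_sig)
            take = np.log(rng.random(K - 1)) < dls
            st.log_sig[take] = prop_ls[take]
            acc["sig"] += take

            # -- residual SDs (per isotope; likelihood factorises by axis)
            prop_lx = st.log_xi + rng.normal(0, sc_xi)
            Lp = _loglik_from_moments(cur_mean, cur_var, np.exp(2 * prop_lx), n_obs, S1, S2)
            dlx = (
                Lp.sum(axis=0)
                - st.L.sum(axis=0)
                + _log_halfcauchy_on_log(prop_lx)
                - _log_halfcauchy_on_log(st.log_xi)
            )
            take = np.log(rng.random(3)) < dlx
            st.log_xi[take] = prop_lx[take]
            st.L[:, take] = Lp[:, take]

            acc["xi"] += take

        # -- adaptation during burn-in
        if it < settings.burnin and (it + 1) % window == 0:
            sc_pop *= np.exp((acc["pop"] / window - 0.25) * 0.6)
            if I:
                sc_Z *= np.exp((acc["Z"] / window - 0.25) * 0.6)
                sc_sig *= np.exp((acc["sig"] / window - 0.44) * 0.6)
                sc_xi *= np.exp((acc["xi"] / window - 0.44) * 0.6)
            acc = {"pop": 0, "Z": np.zeros(I), "sig": np.zeros(K - 1), "xi": np.zeros(3)}

        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            keep_pop.append(st.z_pop.copy())
            keep_P.append(ilr_inv(st.Z, V) if I else np.zeros((0, K)))
    return np.array(keep_pop[:retained]), np.array(keep_P[:retained])


def fit_mixing(
    problem: MixingProblem,
    settings: MCMCSettings = MCMCSettings(iterations=50_000, burnin=25_000, thin=10, chains=3),
    seed: int = 0,
    check_mixing_region: bool = False,
    region_n_iter: int = 300,
):
    """Fit the hierarchical mixing model; returns (posteriors, diagnostics).

    ``posteriors`` maps "population" and each individual id to a
    :class:`DietPosterior` with ``settings.retained`` paired draws (stacked
    across chains in a fixed order, so draws are paired by MCMC iteration
    between entities). ``diagnostics`` carries Gelman-Rubin statistics per
    population ILR coordinate when >= 2 chains are run, and warnings for
    consumers outside the 95% mixing region.
    """
    arrays = problem.arrays()
    ids = sorted(problem.consumers)
    K = len(problem.sources)
    n_obs = np.array([len(problem.consumers[i]) for i in ids], dtype=float)
    if ids:
        S1 = np.stack([np.asarray(problem.consumers[i], dtype=float).sum(axis=0) for i in ids])
        S2 = np.stack([(np.asarray(problem.consumers[i], dtype=float) ** 2).sum(axis=0) for i in ids])
    else:
        S1 = np.zeros((0, 3))
        S2 = np.zeros((0, 3))

    warnings = []
    if check_mixing_region:
        for i in ids:
            for t, y in enumerate(np.atleast_2d(problem.consumers[i])):
                pr = mixing_region_probability(
                    y, problem.sources, problem.tef, n_iter=region_n_iter, seed=seed
                )
                if pr < 0.05:
                    warnings.append(
                        f"{i} sample {t}: mixing-region probability {pr:.3f} < 0.05"
                    )

    rng = np.random.default_rng(seed)
    pops, Ps = [], []
    for _ in range(settings.chains):
        zp, P = _run_chain(arrays, (n_obs, S1, S2), K, settings, int(rng.integers(2**31)))
        pops.append(zp)
        Ps.append(P)

    rhat = {}
    if settings.chains >= 2:
        for j in range(K - 1):
            rhat[f"z_pop[{j}]"] = gelman_rubin(np.stack([zp[:, j] for zp in pops]))

    labels = tuple(s.label for s in problem.sources)
    V = ilr_basis(K)
    pop_draws = ilr_inv(np.concatenate(pops), V)
    posteriors = {"population": DietPosterior("population", pop_draws, labels)}
    if ids:
        allP = np.concatenate(Ps)  # (D, I, K)
        for idx, i in enumerate(ids):
            posteriors[i] = DietPosterior(i, allP[:, idx, :], labels)
    return posteriors, {"rhat": rhat, "warnings": warnings}


# ---------------------------------------------------------------------------
# Mixing-region (polytope) membership

def _in_hull(point, vertices, tol):
    """Is ``point`` a convex combination of ``vertices`` within per-axis tol?

    Solved as a feasibility LP over the combination weights, which handles
    degenerate (lower-dimensional) hulls in the same code path.
    """
    V = np.asarray(vertices, dtype=float)
    x = np.asarray(point, dtype=float)
    k, d = V.shape
    A_ub = np.vstack([V.T, -V.T])
    b_ub = np.concatenate([x + tol, -(x - tol)])
    res = linprog(
        c=np.zeros(k),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=np.ones((1, k)),
        b_eq=[1.0],
        bounds=[(0, None)] * k,
        method="highs",
    )
    return bool(res.status == 0)


def mixing_region_probability(
    consumer,
    sources,
    tef: TEFScenario,
    n_iter: int = 3000,
    level: float = 0.95,
    seed: int = 0,
    tol: float | None = None,
):
    """Probability that the consumer lies inside the simulated mixing polytope.

    Each iteration draws every TEF-adjusted source mean from its combined
    source + TEF uncertainty and tests whether the consumer is a convex
    combination of the drawn points. Membership at ``level`` means the
    returned probability is >= 1 - level. ``tol`` is the per-axis slack; it
    defaults to 1e-8 for full-dimensional hulls (K >= 4) and 0.1 permil for
    degenerate hulls (K <= 3 points cannot span 3-D).
    """
    s_adj, var_adj, _ = _source_arrays(tuple(sources), tef)
    K = s_adj.shape[0]
    if tol is None:
        tol = 1e-8 if K >= 4 else 0.1
    x = np.asarray(consumer, dtype=float) if not hasattr(consumer, "as_array") else consumer.as_array()
    rng = np.random.default_rng(seed)
    sd = np.sqrt(var_adj)
    inside = 0
    for _ in range(n_iter):
        draw = rng.normal(s_adj, sd)
        if _in_hull(x, draw, tol):
            inside += 1
    return inside / n_iter


# ---------------------------------------------------------------------------
# Posterior similarity indices

def posterior_compare(ind: DietPosterior, pop: DietPosterior, alpha: float = 0.05):
    """Per-source probability that the individual's proportion is below the
    population's, over paired posterior draws (ties count 0.5).

    Returns a list of dicts with the probability, a significance flag
    (``significant_low`` when > 1-alpha, ``significant_high`` when < alpha),
    and the mean and 95% credible interval of the individual-minus-population
    difference.
    """
    if ind.draws.shape != pop.draws.shape:
        raise ValueError("draw-count (and source-count) mismatch")
    diff = ind.draws - pop.draws
    less = (ind.draws < pop.draws).mean(axis=0) + 0.5 * (ind.draws == pop.draws).mean(axis=0)
    lo, hi = np.quantile(diff, [0.025, 0.975], axis=0)
    out = []
    for k in range(ind.draws.shape[1]):
        p = float(less[k])
        flag = "significant_low" if p > 1 - alpha else ("significant_high" if p < alpha else "none")
        out.append(
            {
                "source": ind.source_labels[k] if ind.source_labels else str(k),
                "p_ind_below_pop": p,
                "flag": flag,
                "mean_diff": float(diff[:, k].mean()),
                "ci_low": float(lo[k]),
                "ci_high": float(hi[k]),
            }
        )
    return out


def c_index(ind_draws, pop_draws) -> float:
    """Mean cosine similarity between paired posterior vectors (in [0, 1])."""
    a = ind_draws.draws if isinstance(ind_draws, DietPosterior) else np.asarray(ind_draws, float)
    b = pop_draws.draws if isinstance(pop_draws, DietPosterior) else np.asarray(pop_draws, float)
    if a.shape != b.shape:
        raise ValueError("paired draws required")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero vector in draws")
    return float(np.mean(np.sum(a * b, axis=1) / (na * nb)))
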