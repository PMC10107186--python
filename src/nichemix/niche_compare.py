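"""Cross-cutting statistics: beta regression with AICc selection, pairwise
PERMANOVA with Benjamini-Hochberg correction.

Specialisation indices (s-, o-, c-indices) live on (0, 1), so effects of
sex and size class are modelled by maximum-likelihood beta regression with
a logit mean link and constant precision, compared via the small-sample
corrected Akaike information criterion. Source groupings for the mixing
model are screened with pairwise permutational ANOVA on normalised
Euclidean isotope distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaGLMFit",
    "PermanovaResult",
    "beta_glm",
    "squeeze_unit_interval",
    "select_model",
    "pairwise_permanova",
    "bh_adjust",
]


@dataclass(frozen=True)
class BetaGLMFit:
    """ML beta-regression fit (logit mean link, constant precision phi)."""

    label: str
    names: tuple
    coef: np.ndarray  # mean-model coefficients, logit scale
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    phi: float
    loglik: float
    k: int  # parameter count including phi
    n: int

    @property
    def aicc(self) -> float:
        k, n = self.k, self.n
        if n <= k + 1:
            return float("inf")
        return -2.0 * self.loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def squeeze_unit_interval(y) -> np.ndarray:
    """Compress boundary values with (y (n-1) + 0.5) / n when any y is 0 or 1."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    if np.any((y == 0) | (y == 1)):
        n = len(y)
        y = (y * (n - 1) + 0.5) / n
    return y


def beta_glm(response, design, names=None, label: str = "beta_glm") -> BetaGLMFit:
    """Maximum-likelihood beta regression of ``response`` on ``design``.

    ``design`` is the full mean-model matrix (include an intercept column).
    Wald z and two-sided p are reported per mean coefficient; the precision
    parameter phi counts toward k for AICc.
    """
    y = squeeze_unit_interval(response)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k_mean = X.shape
    k = k_mean + 1
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (= {k + 1}), got n = {n}")
    res = BetaModel(y, X).fit(disp=False, maxiter=500)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"beta regression did not converge: {res.mle_retvals}")
    coef = res.params[:k_mean]
    se = res.bse[:k_mean]
    z = coef / se
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    return BetaGLMFit(
        label=label,
        names=tuple(names) if names is not None else tuple(f"x{i}" for i in range(k_mean)),
        coef=np.asarray(coef),
        se=np.asarray(se),
        z=np.asarray(z),
        p=np.asarray(p),
        phi=float(np.exp(res.params[k_mean]) if res.model.link_precision.__class__.__name__ == "Log" else res.params[k_mean]),
        loglik=float(res.llf),
        k=k,
        n=n,
    )


def _design(covariates: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    X = [np.ones(len(covariates))]
    names = ["intercept"]
    for term in terms:
        levels = sorted(covariates[term].astype(str).unique())
        for lev in levels[1:]:  # treatment coding, first level as reference
            X.append((covariates[term].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{term}[{lev}]")
    return np.column_stack(X), names


def select_model(response, covariates: pd.DataFrame) -> pd.DataFrame:
    """Fit the candidate set {null, sex, size, sex+size} and rank by AICc.

    ``covariates`` must carry ``sex`` and ``size_class`` columns aligned
    with ``response``. Returns a table sorted ascending by AICc with
    delta-AICc; a candidate that fails to fit is flagged and ranked last.
    """
    candidates = {
        "null": (),
        "sex": ("sex",),
        "size": ("size_class",),
        "sex+size": ("sex", "size_class"),
    }
    rows = []
    fits = {}
    for label, terms in candidates.items():
        X, names = _design(covariates, terms)
        try:
            fit = beta_glm(response, X, names=names, label=label)
            fits[label] = fit
            rows.append(
                {"model": label, "loglik": fit.loglik, "k": fit.k, "aicc": fit.aicc, "error": ""}
            )
        except Exception as exc:  # noqa: BLE001 - report and keep ranking others
            rows.append(
                {"model": label, "loglik": np.nan, "k": np.nan, "aicc": np.inf, "error": str(exc)}
            )
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    table.attrs["fits"] = fits
    return table


@dataclass(frozen=True)
class PermanovaResult:
    pair: tuple
    pseudo_F: float
    p_perm: float
    p_adjusted: float | None = None

    def adjusted(self, p_adj: float) -> "PermanovaResult":
        return PermanovaResult(self.pair, self.pseudo_F, self.p_perm, p_adj)


def _pseudo_f(sqd, labels, uniq):
    """Pseudo-F from a squared-distance matrix and two-group labels."""
    N = len(labels)
    ss_total = sqd[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = sqd[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    g = len(uniq)
    return (ss_between / (g - 1)) / (ss_within / (N - g))


def permanova_pair(a, b, n_perm: int = 9999, seed: int = 0) -> tuple[float, float]:
    """One two-group PERMANOVA on per-pair z-scored Euclidean distances.

    Variables are normalised (mean 0, SD 1 per axis) over the pooled samples
    of the pair before computing distances; p is the permutation p-value
    (1 + #{F_perm >= F_obs}) / (n_perm + 1) under label shuffling.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    X = np.vstack([a, b])
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    labels = np.array([0] * len(a) + [1] * len(b))
    sqd = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    uniq = np.array([0, 1])
    f_obs = _pseudo_f(sqd, labels, uniq)
    rng = np.random.default_rng(seed)
    count = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _pseudo_f(sqd, perm, uniq) >= f_obs:
            count += 1
    return float(f_obs), (1.0 + count) / (n_perm + 1.0)


def pairwise_permanova(data: dict, n_perm: int = 9999, seed: int = 0):
    """All-pairs PERMANOVA over species isotope samples, BH-adjusted.

    ``data`` maps species -> (n, 3) isotope arrays. Species with fewer than
    2 samples are skipped (their pairs omitted with a warning entry in the
    returned list's ``attrs``-free convention: simply absent). Returns a
    list of :class:`PermanovaResult` with BH-adjusted p-values.
    """
    rng = np.random.default_rng(seed)
    results = []
    names = sorted(data)
    for x, yk in combinations(names, 2):
        a, b = np.atleast_2d(data[x]), np.atleast_2d(data[yk])
        if len(a) < 2 or len(b) < 2:
            continue
        f, p = permanova_pair(a, b, n_perm=n_perm, seed=int(rng.integers(2**31)))
        results.append(PermanovaResult((x, yk), f, p))
    if results:
        adj = bh_adjust([r.p_perm for r in results])
        results = [r.adjusted(pa) for r, pa in zip(results, adj)]
    return results


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
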