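"""Genomewide marker-effect models: RR-BLUP and BayesC-pi.

Both models fit the univariate linear model

    y_i = mu + sum_m x_im u_m + e_i

to entry-mean phenotypes, with marker coding used as-is ({-1, 0, 1}; no
allele-frequency centering).  ``RRBLUP`` shrinks all markers with a common
ridge parameter lambda = sigma2_e / sigma2_u estimated by REML on the
eigendecomposition of the marker cross-product matrix.  ``BayesCPi`` is a
Gibbs sampler with marker-inclusion indicators, a common effect variance,
and the zero-effect proportion pi estimated from the data (uniform prior).

The estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MarkerEffects",
    "ChainSettings",
    "RRBLUP",
    "BayesCPi",
    "fit_rrblup",
    "fit_bayescpi",
    "predict_gv",
]


@dataclass
class MarkerEffects:
    """Per-trait intercept plus genomewide marker-effect vector."""

    trait: str
    intercept: float
    effects: np.ndarray
    model: str
    variance_components: dict = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return len(self.effects)


@dataclass
class ChainSettings:
    """MCMC chain settings for BayesC-pi."""

    n_iterations: int = 12000
    burn_in: int = 2000
    thinning: int = 1
    seed: int | None = None
    df_u: float = 4.0
    df_e: float = 4.0
    r2_prior: float = 0.5

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be below n_iterations")


class RRBLUP(BaseEstimator, RegressorMixin):
    """Ridge-regression BLUP of marker effects with REML shrinkage.

    Parameters
    ----------
    shrinkage : "reml" or float
        "reml" (default) estimates lambda = sigma2_e/sigma2_u by restricted
        maximum likelihood via a profiled one-dimensional optimization on the
        eigendecomposition of X X'.  A float fixes lambda (useful for
        oracle checks).
    bounds : (low, high)
        Search bracket for the variance ratio.
    """

    def __init__(self, shrinkage="reml", bounds=(1e-6, 1e6)):
        self.shrinkage = shrinkage
        self.bounds = bounds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be (n, m) with n matching y")
        n, m = X.shape
        if n < 2:
            raise ValueError("need at least 2 individuals")
        self.n_features_in_ = m

        if np.var(y) == 0:
            warnings.warn("zero phenotypic variance: returning all-zero effects")
            self.intercept_ = float(y.mean())
            self.effects_ = np.zeros(m)
            self.sigma2_u_, self.sigma2_e_, self.lambda_ = 0.0, 0.0, np.inf
            self.coef_ = self.effects_
            return self

        K = X @ X.T
        if self.shrinkage == "reml":
            lam, s2u, s2e = self._reml(K, y)
        else:
            lam = float(self.shrinkage)
            s2u = s2e = np.nan
        H = K + lam * np.eye(n)
        Hinv_y = np.linalg.solve(H, y)
        Hinv_1 = np.linalg.solve(H, np.ones(n))
        mu = float(Hinv_y.sum() / Hinv_1.sum())
        u = X.T @ np.linalg.solve(H, y - mu)
        self.intercept_ = mu
        self.effects_ = u
        self.coef_ = u
        self.lambda_ = lam
        self.sigma2_u_ = s2u
        self.sigma2_e_ = s2e
        return self

    def _reml(self, K, y):
        n = len(y)
        q = n - 1
        S = np.eye(n) - np.ones((n, n)) / n
        xi, U = np.linalg.eigh(S @ K @ S)
        # drop the eigenvector spanned by the intercept (eigenvalue ~0)
        xi, U = xi[1:], U[:, 1:]
        xi = np.clip(xi, 0.0, None)
        eta2 = (U.T @ y) ** 2

        def neg_restricted_ll(log_delta):
            d = 10.0 ** log_delta
            denom = xi + d
            return q * math.log(eta2 @ (1.0 / denom)) + np.log(denom).sum()

        lo, hi = np.log10(self.bounds[0]), np.log10(self.bounds[1])
        grid = np.linspace(lo, hi, 121)
        vals = [neg_restricted_ll(g) for g in grid]
        k = int(np.argmin(vals))
        a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(neg_restricted_ll, bounds=(a, b), method="bounded")
        delta = 10.0 ** float(res.x)
        s2u = float(eta2 @ (1.0 / (xi + delta)) / q)
        return delta, s2u, delta * s2u

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("marker count mismatch between fit and predict")
        return self.intercept_ + X @ self.effects_


@njit(cache=True)
def _bayesc_gibbs(Xt, y, n_iter, burn_in, thin, pi_init, estimate_pi,
                  df_u, S_u, df_e, S_e, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    m, n = Xt.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s

    mu = y.mean()
    e = y - mu
    u = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    s2u = S_u
    s2e = S_e
    pi = pi_init

    n_keep = (n_iter - burn_in) // thin
    u_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    pi_sum = 0.0
    s2u_sum = 0.0
    s2e_sum = 0.0
    gvar_chain = np.zeros(n_keep)
    kept = 0

    for it in range(n_iter):
        for j in range(m):
            c = xtx[j]
            if c == 0.0:
                continue
            if delta[j] == 1:
                uj = u[j]
                for i in range(n):
                    e[i] += Xt[j, i] * uj
            r = 0.0
            for i in range(n):
                r += Xt[j, i] * e[i]
            v0 = c * s2e
            v1 = c * c * s2u + c * s2e
            lbf = 0.5 * (math.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
            if lbf > 50.0:
                p1 = 1.0
            else:
                num = (1.0 - pi) * math.exp(lbf)
                p1 = num / (num + pi)
            if np.random.random() < p1:
                lam = s2e / s2u
                mean = r / (c + lam)
                sd = math.sqrt(s2e / (c + lam))
                unew = mean + sd * np.random.standard_normal()
                for i in range(n):
                    e[i] -= Xt[j, i] * unew
                u[j] = unew
                delta[j] = 1
            else:
                u[j] = 0.0
                delta[j] = 0

        # intercept
        se = 0.0
        for i in range(n):
            se += e[i]
        mu_new = (mu + se / n) + math.sqrt(s2e / n) * np.random.standard_normal()
        shift = mu_new - mu
        for i in range(n):
            e[i] -= shift
        mu = mu_new

        m_in = 0
        ssu = 0.0
        for j in range(m):
            if delta[j] == 1:
                m_in += 1
                ssu += u[j] * u[j]
        s2u = (ssu + df_u * S_u) / np.random.chisquare(df_u + m_in)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        s2e = (sse + df_e * S_e) / np.random.chisquare(df_e + n)
        if estimate_pi:
            pi = np.random.beta(m - m_in + 1.0, m_in + 1.0)

        if it >= burn_in and (it - burn_in) % thin == 0:
            u_sum += u
            for j in range(m):
                incl_sum[j] += delta[j]
            mu_sum += mu
            pi_sum += pi
            s2u_sum += s2u
            s2e_sum += s2e
            gvar_chain[kept] = m_in * s2u
            kept += 1

    return (u_sum / kept, incl_sum / kept, mu_sum / kept, pi_sum / kept,
            s2u_sum / kept, s2e_sum / kept, gvar_chain[:kept])


def _split_rhat(chain: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic on a single chain."""
    h = len(chain) // 2
    if h < 2:
        return 1.0
    a, b = chain[:h], chain[h: 2 * h]
    w = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    bvar = h * np.var([a.mean(), b.mean()], ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt(((h - 1) / h * w + bvar / h) / w))


class BayesCPi(BaseEstimator, RegressorMixin):
    """BayesC-pi marker model fitted by Gibbs sampling.

    Markers enter the model through inclusion indicators with a common effect
    variance; pi, the proportion of zero-effect markers, gets a uniform prior
    (or can be fixed via ``pi``; pi=0 keeps every marker in the model, the
    RR-BLUP limit).  Variance priors are scaled-inverse-chi-square with
    ``df_u``/``df_e`` degrees of freedom and scales split from the phenotypic
    variance by ``r2_prior``.  Reproducible under a fixed ``random_state``.
    """

    def __init__(self, n_iter=12000, burn_in=2000, thin=1, pi=None,
                 df_u=4.0, df_e=4.0, r2_prior=0.5, random_state=None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.pi = pi
        self.df_u = df_u
        self.df_e = df_e
        self.r2_prior = r2_prior
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be (n, m) with n matching y")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be below n_iter")
        n, m = X.shape
        self.n_features_in_ = m
        vy = float(np.var(y, ddof=1)) if n > 1 else 0.0
        if vy == 0:
            warnings.warn("zero phenotypic variance: returning all-zero effects")
            self.intercept_ = float(y.mean())
            self.effects_ = np.zeros(m)
            self.coef_ = self.effects_
            self.pi_ = 1.0
            self.inclusion_prob_ = np.zeros(m)
            self.sigma2_u_ = self.sigma2_e_ = 0.0
            return self

        mean_x2 = float((X ** 2).mean()) or 1.0
        pi0 = 0.5 if self.pi is None else float(self.pi)
        S_u = self.r2_prior * vy / (max(1.0 - pi0, 0.05) * m * mean_x2)
        S_e = (1.0 - self.r2_prior) * vy
        seed = np.random.SeedSequence(self.random_state).generate_state(1)[0] % (2 ** 31)

        (u, incl, mu, pi, s2u, s2e, gvar) = _bayesc_gibbs(
            np.ascontiguousarray(X.T), y, int(self.n_iter), int(self.burn_in),
            int(self.thin), pi0, self.pi is None,
            float(self.df_u), S_u, float(self.df_e), S_e, int(seed),
        )
        rhat = _split_rhat(gvar)
        if rhat > 1.2:
            warnings.warn(
                f"BayesC-pi chain may not have converged "
                f"(split R-hat of genetic variance = {rhat:.2f})"
            )
        self.effects_ = u
        self.coef_ = u
        self.intercept_ = float(mu)
        self.pi_ = float(pi)
        self.inclusion_prob_ = incl
        self.sigma2_u_ = float(s2u)
        self.sigma2_e_ = float(s2e)
        self.rhat_ = rhat
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("marker count mismatch between fit and predict")
        return self.intercept_ + X @ self.effects_


# ---------------------------------------------------------------------------
# thin functional wrappers returning MarkerEffects records

def fit_rrblup(phenos, geno, trait: str = "trait") -> MarkerEffects:
    """Fit RR-BLUP to entry-mean phenotypes; returns a MarkerEffects record."""
    X = geno.calls if hasattr(geno, "calls") else np.asarray(geno, dtype=float)
    est = RRBLUP().fit(X, phenos)
    return MarkerEffects(
        trait=trait,
        intercept=est.intercept_,
        effects=est.effects_,
        model="RR-BLUP",
        variance_components={
            "genetic": est.sigma2_u_,
            "residual": est.sigma2_e_,
            "lambda": est.lambda_,
        },
    )


def fit_bayescpi(phenos, geno, chain: ChainSettings | None = None,
                 trait: str = "trait") -> MarkerEffects:
    """Fit BayesC-pi to entry-mean phenotypes; returns a MarkerEffects record."""
    chain = chain or ChainSettings()
    X = geno.calls if hasattr(geno, "calls") else np.asarray(geno, dtype=float)
    est = BayesCPi(
        n_iter=chain.n_iterations, burn_in=chain.burn_in, thin=chain.thinning,
        df_u=chain.df_u, df_e=chain.df_e, r2_prior=chain.r2_prior,
        random_state=chain.seed,
    ).fit(X, phenos)
    return MarkerEffects(
        trait=trait,
        intercept=est.intercept_,
        effects=est.effects_,
        model="BayesCpi",
        variance_components={
            "genetic": est.sigma2_u_,
            "residual": est.sigma2_e_,
            "pi": est.pi_,
        },
    )


def write_marker_effects(effs, gmap, path) -> None:
    """Write effect vectors as TSV (marker, trait, effect) + JSON sidecar."""
    import json

    import pandas as pd

    frames = []
    meta = {}
    for eff in effs:
        frames.append(pd.DataFrame({
            "marker": list(gmap.marker), "trait": eff.trait,
            "effect": eff.effects,
        }))
        meta[eff.trait] = {
            "model": eff.model, "intercept": eff.intercept,
            "variance_components": {k: (None if v is None or not np.isfinite(v)
                                        else float(v))
                                    for k, v in eff.variance_components.items()},
        }
    pd.concat(frames).to_csv(path, sep="\t", index=False, lineterminator="\n")
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_marker_effects(path, gmap) -> dict:
    """Read the effects TSV/JSON pair; returns {trait: MarkerEffects}."""
    import json

    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    out = {}
    for trait, g in df.groupby("trait", sort=False):
        g = g.set_index("marker").reindex(list(gmap.marker))
        if g["effect"].isna().any():
            raise ValueError(f"effects for {trait} do not cover the map markers")
        m = meta[str(trait)]
        out[trait] = MarkerEffects(
            trait=str(trait), intercept=float(m["intercept"]),
            effects=g["effect"].to_numpy(), model=m["model"],
            variance_components=m.get("variance_components", {}),
        )
    return out


def predict_gv(geno, eff: MarkerEffects) -> np.ndarray:
    """Predicted genotypic values mu + X u for a genotype matrix."""
    X = geno.calls if hasattr(geno, "calls") else np.asarray(geno, dtype=float)
    if X.shape[1] != eff.n_markers:
        raise ValueError(
            f"marker mismatch: genotypes have {X.shape[1]} markers, "
            f"effects have {eff.n_markers}"
        )
    return eff.intercept + X @ eff.effects
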