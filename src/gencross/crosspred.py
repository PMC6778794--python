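"""Deterministic prediction of progeny mean, variance and correlation in
biparental RIL crosses, plus a Monte-Carlo oracle.

For two fully inbred parents, re-sign each marker effect so that +alpha
refers to the first parent's allele.  Over the loci segregating in the cross
(where the parents differ), the expected genetic variance of a trait in the
RIL progeny is

    sigma2_G = sum_i alpha_i^2 + 2 sum_{i<j} w_ij alpha_i alpha_j,
    w_ij = (1 - 2 c_ij) / (1 + 2 c_ij),

with c_ij the recombination fraction (w = 0 for unlinked loci).  The
genetic covariance between two traits replaces the single effect vector by
the two traits' effect vectors in a full double sum (same-locus terms carry
weight 1, which is how pleiotropic loci contribute).  The genetic
correlation is the covariance scaled by both standard deviations.  The
superior progeny mean mu_sp = mu + k_sp * sigma_G is the expected mean of
the selected top fraction of progeny for the trait under direct selection;
the correlated progeny mean mu_spC = mu + k_sp * r_G * sigma_G(2) is the
expected correlated response in a second trait.

The pair weight equals the two-locus origin correlation of selfed-to-
fixation RILs, so the weight matrix is positive semi-definite and the
predicted progeny covariance matrix is as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .effects import MarkerEffects, predict_gv
from .genome import GeneticMap, GenotypeMatrix
from .meiosis import make_ril_family

__all__ = [
    "CrossPrediction",
    "SelectionParams",
    "selection_intensity",
    "pair_weight",
    "pair_weight_matrices",
    "predict_cross",
    "predict_all_crosses",
    "mc_predict_cross",
    "crosses_to_frame",
]


def selection_intensity(p: float) -> float:
    """Standardized selection coefficient k_sp for truncating the top
    fraction ``p`` of a standard normal: phi(Phi^-1(1-p)) / p.

    k(0.05) = 2.063; k -> 0 as p -> 1.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("selected fraction must be in (0, 1)")
    return float(norm.pdf(norm.ppf(1.0 - p)) / p)


@dataclass
class SelectionParams:
    """Selected fraction and the implied standardized selection coefficient."""

    p: float = 0.05

    @property
    def ksp(self) -> float:
        return selection_intensity(self.p)


def pair_weight(c):
    """Two-locus disequilibrium weight (1 - 2c) / (1 + 2c) in RIL progeny."""
    c = np.asarray(c, dtype=float)
    w = (1.0 - 2.0 * c) / (1.0 + 2.0 * c)
    return w if w.ndim else float(w)


def pair_weight_matrices(gmap: GeneticMap) -> dict[int, np.ndarray]:
    """Per-chromosome dense pair-weight matrices (diagonal 1).

    Cross-chromosome weights are exactly 0 (c = 0.5), which is what makes
    per-chromosome blocking equal to the naive genomewide double sum.
    """
    from .genome import map_distance_to_recomb

    out = {}
    for ch, sl in gmap.chrom_slices().items():
        d = np.abs(gmap.pos_cM[sl, None] - gmap.pos_cM[None, sl])
        out[ch] = pair_weight(map_distance_to_recomb(d))
    return out


@dataclass
class CrossPrediction:
    """Predicted progeny distribution parameters for one parent pair."""

    parent1: str
    parent2: str
    mean1: float
    mean2: float
    variance1: float
    variance2: float
    covariance: float
    correlation: float
    musp1: float
    musp2C: float
    n_segregating1: int
    n_segregating2: int


_COLUMNS = [
    "parent1", "parent2", "mean1", "mean2", "variance1", "variance2",
    "covariance", "correlation", "musp1", "musp2C",
    "n_segregating1", "n_segregating2",
]


def crosses_to_frame(preds: list[CrossPrediction]) -> pd.DataFrame:
    """Fixed-column-order table of cross predictions."""
    return pd.DataFrame([[getattr(p, c) for c in _COLUMNS] for p in preds],
                        columns=_COLUMNS)


def _check_inbred(p, name):
    if not np.isin(p, (-1.0, 1.0)).all():
        raise ValueError(f"parent {name} is not fully inbred")


def _batch_cross_stats(D, M, u1, u2, mu1_0, mu2_0, weights, gmap):
    """Vectorized Eq-style statistics for a batch of crosses.

    D rows are (p1 - p2)/2 per cross (the phase/segregation vector), M rows
    are (p1 + p2)/2.  Returns per-cross means, variances, covariance.
    """
    G1 = D * u1
    G2 = D * u2
    n = D.shape[0]
    v1 = np.zeros(n)
    v2 = np.zeros(n)
    cov = np.zeros(n)
    for ch, sl in gmap.chrom_slices().items():
        W = weights[ch]
        A = G1[:, sl] @ W
        v1 += (A * G1[:, sl]).sum(axis=1)
        cov += (A * G2[:, sl]).sum(axis=1)
        v2 += ((G2[:, sl] @ W) * G2[:, sl]).sum(axis=1)
    v1 = np.clip(v1, 0.0, None)
    v2 = np.clip(v2, 0.0, None)
    mean1 = mu1_0 + M @ u1
    mean2 = mu2_0 + M @ u2
    return mean1, mean2, v1, v2, cov


def _finish(parent1, parent2, mean1, mean2, v1, v2, cov, d, u1, u2, ksp):
    s1, s2 = np.sqrt(v1), np.sqrt(v2)
    corr = cov / (s1 * s2) if v1 > 0 and v2 > 0 else float("nan")
    musp1 = mean1 + ksp * s1
    musp2C = mean2 + (ksp * corr * s2 if np.isfinite(corr) else 0.0)
    return CrossPrediction(
        parent1=parent1, parent2=parent2,
        mean1=float(mean1), mean2=float(mean2),
        variance1=float(v1), variance2=float(v2),
        covariance=float(cov), correlation=float(corr),
        musp1=float(musp1), musp2C=float(musp2C),
        n_segregating1=int(np.count_nonzero((d != 0) & (u1 != 0))),
        n_segregating2=int(np.count_nonzero((d != 0) & (u2 != 0))),
    )


def predict_cross(
    p1, p2,
    eff_t1: MarkerEffects, eff_t2: MarkerEffects,
    gmap: GeneticMap,
    sel: SelectionParams = SelectionParams(),
    weights=None,
    parent_ids=("P1", "P2"),
) -> CrossPrediction:
    """Predict progeny mean, variance, covariance, correlation and the
    superior/correlated progeny means for one cross of two inbred parents.

    The cross mean per trait is the mean of the two parents' predicted
    genotypic values.  Identical parents give zero variances, NaN
    correlation and mu_sp = mu (with a warning).
    """
    p1 = np.asarray(p1, dtype=float).ravel()
    p2 = np.asarray(p2, dtype=float).ravel()
    _check_inbred(p1, parent_ids[0])
    _check_inbred(p2, parent_ids[1])
    if len(p1) != len(p2) or len(p1) != gmap.n_markers:
        raise ValueError("parents and map must share the marker set")
    if weights is None:
        weights = pair_weight_matrices(gmap)
    d = (p1 - p2) / 2.0
    if not d.any():
        warnings.warn("identical parents: zero variance, NaN correlation")
    mean1, mean2, v1, v2, cov = _batch_cross_stats(
        d[None, :], ((p1 + p2) / 2.0)[None, :],
        eff_t1.effects, eff_t2.effects,
        eff_t1.intercept, eff_t2.intercept, weights, gmap,
    )
    return _finish(parent_ids[0], parent_ids[1], mean1[0], mean2[0],
                   v1[0], v2[0], cov[0], d, eff_t1.effects, eff_t2.effects,
                   sel.ksp)


def predict_all_crosses(
    parents: GenotypeMatrix,
    eff_t1: MarkerEffects, eff_t2: MarkerEffects,
    gmap: GeneticMap,
    sel: SelectionParams = SelectionParams(),
    pairs=None,
    weights=None,
) -> list[CrossPrediction]:
    """Predict every non-reciprocal cross among ``parents``.

    Returns n(n-1)/2 records in lexicographic parent-index order (or the
    crosses listed in ``pairs``).  Uses per-chromosome blocking; results are
    identical to the naive genomewide double sum.
    """
    X = parents.calls
    if not parents.is_inbred():
        raise ValueError("all parents must be fully inbred")
    if pairs is None:
        pairs = list(combinations(range(parents.n_individuals), 2))
    if weights is None:
        weights = pair_weight_matrices(gmap)
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    D = (X[ii] - X[jj]) / 2.0
    M = (X[ii] + X[jj]) / 2.0
    mean1, mean2, v1, v2, cov = _batch_cross_stats(
        D, M, eff_t1.effects, eff_t2.effects,
        eff_t1.intercept, eff_t2.intercept, weights, gmap,
    )
    out = []
    for k, (i, j) in enumerate(pairs):
        out.append(
            _finish(parents.ids[i], parents.ids[j], mean1[k], mean2[k],
                    v1[k], v2[k], cov[k], D[k],
                    eff_t1.effects, eff_t2.effects, sel.ksp)
        )
    return out


def mc_predict_cross(
    p1, p2,
    eff_t1: MarkerEffects, eff_t2: MarkerEffects,
    gmap: GeneticMap,
    n_progeny: int = 100_000,
    seed=None,
    sel: SelectionParams = SelectionParams(),
    parent_ids=("P1", "P2"),
) -> CrossPrediction:
    """Monte-Carlo counterpart of :func:`predict_cross`.

    Simulates ``n_progeny`` RILs and computes the sample mean, variance
    (unbiased) and correlation of their predicted genotypic values.  Serves
    as the brute-force oracle for the deterministic formulas.
    """
    fam = make_ril_family(p1, p2, gmap, n_progeny, method="direct", seed=seed,
                          parent_ids=parent_ids)
    pv1 = predict_gv(fam.progeny, eff_t1)
    pv2 = predict_gv(fam.progeny, eff_t2)
    mean1, mean2 = float(pv1.mean()), float(pv2.mean())
    v1 = float(pv1.var(ddof=1))
    v2 = float(pv2.var(ddof=1))
    cov = float(np.cov(pv1, pv2, ddof=1)[0, 1])
    d = (np.asarray(p1, float) - np.asarray(p2, float)) / 2.0
    return _finish(parent_ids[0], parent_ids[1], mean1, mean2, v1, v2, cov,
                   d, eff_t1.effects, eff_t2.effects, sel.ksp)
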