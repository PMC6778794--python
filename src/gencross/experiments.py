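"""Simulation drivers: cross-parameter prediction accuracy and long-term
recurrent selection under different cross-selection strategies.

Experiment 1 measures, over replicates, the Pearson accuracy of predicted
vs. expected cross means, genetic variances and genetic correlations for a
panel of candidate crosses, where "predicted" uses marker effects estimated
from a training population and "expected" uses the true QTL effects.

Experiment 2 runs a recurrent indirect-selection breeding program: marker
effects are estimated once on the training population and held fixed; each
cycle, crosses among the current parents are ranked either by the sum of the
normalized superior progeny mean of the primary trait and the correlated
progeny mean of the secondary trait (CPM), by the predicted cross mean of
the primary trait (FM), or at random; RIL families from the selected
crosses form the next candidate pool, whose best lines (on predicted
primary-trait values) become the next parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .architecture import TraitArchitecture, build_architecture, genotypic_values
from .crosspred import (
    SelectionParams,
    _batch_cross_stats,
    pair_weight_matrices,
)
from .effects import ChainSettings, MarkerEffects, fit_bayescpi, fit_rrblup
from .genome import GeneticMap, GenotypeMatrix
from .meiosis import make_ril_family
from .phenosim import simulate_phenotypes

__all__ = [
    "SimulationConfig",
    "AccuracyResult",
    "run_accuracy_experiment",
    "run_selection_experiment",
    "haplotype_frequencies",
    "fixation_proportion",
]

_TABLE1_DOMAINS = {
    "h2": (0.3, 0.6, 1.0),
    "n_qtl": (30, 100),
    "rG0": (-0.5, 0.0, 0.5),
    "architecture": ("pleiotropy", "tight_linkage", "loose_linkage"),
    "n_tp": (150, 300, 450, 600),
    "model": ("RR-BLUP", "BayesCpi", "oracle"),
}


@dataclass
class SimulationConfig:
    """Factorial cell for the simulation experiments.

    Defaults follow the study conditions: two traits, 100 effective QTL,
    training population of 600, top-5% selection (k_sp = 2.06), 50 candidate
    crosses (experiment 1), 30 then 50 parents, 20 selected crosses and
    50-RIL families over 10 cycles (experiment 2).
    """

    h2: tuple = (0.6, 0.6)
    n_qtl: int = 100
    rG0: float = 0.5
    architecture: str = "pleiotropy"
    n_tp: int = 600
    model: str = "RR-BLUP"
    n_candidate_crosses: int = 50
    n_parents_first: int = 30
    n_parents: int = 50
    n_crosses_selected: int = 20
    family_size: int = 50
    n_cycles: int = 10
    selected_fraction: float = 0.05
    replicates: int = 100
    n_qtl_per_trait: int = 100
    n_environments: int = 3
    chain: ChainSettings = field(default_factory=ChainSettings)
    seed: int | None = None

    def validate(self) -> None:
        h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        if np.any(h2 <= 0) or np.any(h2 > 1):
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if not -1 <= self.rG0 <= 1:
            raise ValueError(f"rG0 must be in [-1, 1], got {self.rG0}")
        if self.architecture not in _TABLE1_DOMAINS["architecture"]:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.model not in _TABLE1_DOMAINS["model"]:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.selected_fraction < 1:
            raise ValueError("selected_fraction must be in (0, 1)")
        for name in ("n_tp", "n_qtl", "replicates", "n_cycles", "family_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def with_overrides(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _fit_trait(cfg: SimulationConfig, y, geno, trait, seed) -> MarkerEffects:
    if cfg.model == "oracle":
        raise ValueError("the oracle model is only supported by the accuracy "
                         "experiment")
    if cfg.model == "RR-BLUP":
        return fit_rrblup(y, geno, trait=trait)
    chain = replace(cfg.chain, seed=int(seed))
    return fit_bayescpi(y, geno, chain=chain, trait=trait)


def _true_effects(arch: TraitArchitecture, trait: int) -> MarkerEffects:
    return MarkerEffects(trait=f"trait{trait}", intercept=0.0,
                         effects=arch.effect_vector(trait), model="true-QTL")


def _pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


@dataclass
class AccuracyResult:
    """Per-replicate accuracies/biases and their replicate summary."""

    per_replicate: pd.DataFrame
    summary: pd.DataFrame


def _summarize(df: pd.DataFrame, by: list) -> pd.DataFrame:
    """Mean and 95% approximate confidence interval over replicates."""
    metrics = [c for c in df.columns if c not in by + ["replicate"]]
    g = df.groupby(by)[metrics] if by else df[metrics]
    mean = g.mean()
    se = g.sem()
    out = pd.concat({"mean": mean, "lo": mean - 1.96 * se,
                     "hi": mean + 1.96 * se}, axis=1)
    return out.reset_index() if by else out


def run_accuracy_experiment(
    cfg: SimulationConfig,
    founders: GenotypeMatrix,
    gmap: GeneticMap,
    weights=None,
) -> AccuracyResult:
    """Experiment 1: accuracy of predicted cross means, variances and
    correlations over ``cfg.replicates`` replicates.

    Each replicate samples a fresh training population, architecture,
    phenotypes and model fit, then scores ``cfg.n_candidate_crosses`` random
    parent pairs.  Replicates whose correlation accuracy is undefined (all
    candidate crosses degenerate) are dropped and counted.
    """
    cfg.validate()
    if weights is None:
        weights = pair_weight_matrices(gmap)
    master = np.random.SeedSequence(cfg.seed)
    rows = []
    dropped = 0
    for rep, ss in enumerate(master.spawn(cfg.replicates)):
        rng = np.random.default_rng(ss)
        tp_idx = rng.choice(founders.n_individuals, cfg.n_tp, replace=False)
        tp = founders.subset_individuals(tp_idx)
        arch = build_architecture(
            gmap, tp, cfg.architecture, cfg.n_qtl, cfg.rG0,
            n_qtl_per_trait=cfg.n_qtl_per_trait, seed=rng,
        )
        gv = genotypic_values(tp, arch)
        phen = simulate_phenotypes(gv, cfg.h2, cfg.n_environments, seed=rng)
        true = [_true_effects(arch, 1), _true_effects(arch, 2)]
        if cfg.model == "oracle":
            est = true  # diagnostic mode: prediction equals expectation
        else:
            fit_seed = rng.integers(2 ** 31)
            est = [
                _fit_trait(cfg, phen.entry_means[:, t], tp, f"trait{t + 1}",
                           fit_seed + t)
                for t in (0, 1)
            ]

        pairs = []
        for _ in range(cfg.n_candidate_crosses):
            i, j = rng.choice(cfg.n_tp, 2, replace=False)
            pairs.append((int(i), int(j)))
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        D = (tp.calls[ii] - tp.calls[jj]) / 2.0
        M = (tp.calls[ii] + tp.calls[jj]) / 2.0

        def stats(e1, e2):
            m1, m2, v1, v2, cov = _batch_cross_stats(
                D, M, e1.effects, e2.effects, e1.intercept, e2.intercept,
                weights, gmap,
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                rg = np.where((v1 > 0) & (v2 > 0),
                              cov / np.sqrt(v1 * v2), np.nan)
            return m1, m2, v1, v2, cov, rg

        pm1, pm2, pv1, pv2, pcov, prg = stats(est[0], est[1])
        em1, em2, ev1, ev2, ecov, erg = stats(true[0], true[1])

        ok = np.isfinite(prg) & np.isfinite(erg)
        if ok.sum() < 3:
            dropped += 1
            continue
        rows.append({
            "replicate": rep,
            "acc_mean1": _pearson(pm1, em1),
            "acc_mean2": _pearson(pm2, em2),
            "acc_var1": _pearson(pv1, ev1),
            "acc_var2": _pearson(pv2, ev2),
            "acc_corr": _pearson(prg[ok], erg[ok]),
            "bias_corr": float(np.mean(prg[ok] - erg[ok])),
            "bias_cov": float(np.mean(pcov - ecov)),
            "n_crosses_used": int(ok.sum()),
        })
    per_rep = pd.DataFrame(rows)
    per_rep.attrs["dropped_replicates"] = dropped
    return AccuracyResult(per_replicate=per_rep, summary=_summarize(per_rep, []))


def haplotype_frequencies(pop: GenotypeMatrix, arch: TraitArchitecture):
    """Mean frequencies of favorable, unfavorable and antagonistic two-trait
    QTL haplotypes over all effective QTL pairs and individuals.

    A haplotype is favorable when the individual carries the trait-favorable
    allele at both loci of a pair (the same locus twice under pleiotropy),
    unfavorable when it carries neither, antagonistic when one of each.
    Pairs where either trait effect is exactly zero are skipped.
    """
    q1, q2, eff = arch.effective_pairs()
    usable = (eff[:, 0] != 0) & (eff[:, 1] != 0)
    if not usable.any():
        return 0.0, 0.0, 0.0
    f1 = np.sign(eff[usable, 0])
    f2 = np.sign(eff[usable, 1])
    x1 = pop.calls[:, q1[usable]] * f1  # +1 where trait-1-favorable allele
    x2 = pop.calls[:, q2[usable]] * f2
    fav = float(np.mean((x1 == 1) & (x2 == 1)))
    unfav = float(np.mean((x1 == -1) & (x2 == -1)))
    antag = float(np.mean(x1 != x2))
    return fav, unfav, antag


def fixation_proportion(pop: GenotypeMatrix, arch: TraitArchitecture):
    """Per-trait proportion of effective QTL with a single segregating allele."""
    q1, q2, _ = arch.effective_pairs()
    out = []
    for q in (q1, q2):
        cols = pop.calls[:, q]
        fixed = (cols == cols[0]).all(axis=0)
        out.append(float(fixed.mean()))
    return tuple(out)


def _cycle_metrics(pop, arch, base_mean, base_sd, cycle, strategy, rep):
    gv = genotypic_values(pop, arch)
    resp = (gv.values.mean(axis=0) - base_mean) / base_sd
    fav, unfav, antag = haplotype_frequencies(pop, arch)
    fix1, fix2 = fixation_proportion(pop, arch)
    return {
        "replicate": rep, "strategy": strategy, "cycle": cycle,
        "response1": float(resp[0]), "response2": float(resp[1]),
        "index_response": float(resp.sum()),
        "variance1": float(gv.variances[0]), "variance2": float(gv.variances[1]),
        "correlation": gv.correlation,
        "freq_favorable": fav, "freq_unfavorable": unfav,
        "freq_antagonistic": antag,
        "fixed1": fix1, "fixed2": fix2,
    }


def _zscore(x):
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def run_selection_experiment(
    cfg: SimulationConfig,
    founders: GenotypeMatrix,
    gmap: GeneticMap,
    strategies=("CPM", "FM", "random"),
    weights=None,
    random_parents: bool = False,
) -> pd.DataFrame:
    """Experiment 2: recurrent selection trajectories for each strategy.

    Marker effects are fit once per replicate and shared by all strategies
    (a paired design).  Returns a tidy table with one row per replicate x
    strategy x cycle; cycle 0 is the training-population baseline, against
    whose genetic standard deviation responses are standardized.
    ``random_parents`` replaces truncation selection of parents by random
    draws (used to check the no-selection null).
    """
    cfg.validate()
    if isinstance(strategies, str):
        strategies = (strategies,)
    for s in strategies:
        if s not in ("CPM", "FM", "random"):
            raise ValueError(f"unknown strategy {s!r}")
    n_cand = cfg.n_crosses_selected * cfg.family_size
    if weights is None:
        weights = pair_weight_matrices(gmap)
    sel = SelectionParams(cfg.selected_fraction)
    ksp = sel.ksp
    master = np.random.SeedSequence(cfg.seed)
    rows = []
    for rep, ss in enumerate(master.spawn(cfg.replicates)):
        rng = np.random.default_rng(ss)
        tp_idx = rng.choice(founders.n_individuals, cfg.n_tp, replace=False)
        tp = founders.subset_individuals(tp_idx)
        arch = build_architecture(
            gmap, tp, cfg.architecture, cfg.n_qtl, cfg.rG0,
            n_qtl_per_trait=cfg.n_qtl_per_trait, seed=rng,
        )
        gv0 = genotypic_values(tp, arch)
        base_mean = gv0.values.mean(axis=0)
        base_sd = np.sqrt(gv0.variances)
        phen = simulate_phenotypes(gv0, cfg.h2, cfg.n_environments, seed=rng)
        fit_seed = rng.integers(2 ** 31)
        est = [
            _fit_trait(cfg, phen.entry_means[:, t], tp, f"trait{t + 1}",
                       fit_seed + t)
            for t in (0, 1)
        ]
        u1, u2 = est[0].effects, est[1].effects
        mu1, mu2 = est[0].intercept, est[1].intercept

        pgv1_tp = mu1 + tp.calls @ u1
        if random_parents:
            first_parents = rng.choice(cfg.n_tp, cfg.n_parents_first,
                                       replace=False)
        else:
            first_parents = np.argsort(pgv1_tp)[::-1][: cfg.n_parents_first]
        parents0 = tp.subset_individuals(first_parents)

        strat_seeds = {s: np.random.default_rng(ss.spawn(1)[0].entropy + k)
                       for k, s in enumerate(strategies)}
        for strategy in strategies:
            srng = strat_seeds[strategy]
            parents = parents0
            rows.append(_cycle_metrics(tp, arch, base_mean, base_sd, 0,
                                       strategy, rep))
            for cycle in range(1, cfg.n_cycles + 1):
                npar = parents.n_individuals
                ii, jj = np.triu_indices(npar, k=1)
                if len(ii) < cfg.n_crosses_selected:
                    raise ValueError("fewer candidate crosses than required")
                D = (parents.calls[ii] - parents.calls[jj]) / 2.0
                M = (parents.calls[ii] + parents.calls[jj]) / 2.0
                m1, m2, v1, v2, cov = _batch_cross_stats(
                    D, M, u1, u2, mu1, mu2, weights, gmap)
                s1, s2 = np.sqrt(v1), np.sqrt(v2)
                with np.errstate(invalid="ignore", divide="ignore"):
                    rg = np.where((v1 > 0) & (v2 > 0), cov / (s1 * s2), 0.0)
                if strategy == "CPM":
                    musp1 = m1 + ksp * s1
                    musp2c = m2 + ksp * rg * s2
                    score = _zscore(musp1) + _zscore(musp2c)
                    chosen = np.argsort(score)[::-1][: cfg.n_crosses_selected]
                elif strategy == "FM":
                    chosen = np.argsort(m1)[::-1][: cfg.n_crosses_selected]
                else:
                    chosen = srng.choice(len(ii), cfg.n_crosses_selected,
                                         replace=False)
                fams = []
                for k in chosen:
                    fam = make_ril_family(
                        parents.calls[ii[k]], parents.calls[jj[k]], gmap,
                        cfg.family_size, method="direct",
                        seed=srng.integers(2 ** 31),
                        family_id=f"c{cycle}x{k}",
                    )
                    fams.append(fam.progeny)
                cand_calls = np.vstack([f.calls for f in fams])
                cand_ids = [i for f in fams for i in f.ids]
                candidates = GenotypeMatrix(cand_ids, cand_calls)
                assert candidates.n_individuals == n_cand
                rows.append(_cycle_metrics(candidates, arch, base_mean,
                                           base_sd, cycle, strategy, rep))
                pgv1 = mu1 + cand_calls @ u1
                if random_parents:
                    nxt = srng.choice(n_cand, cfg.n_parents, replace=False)
                else:
                    nxt = np.argsort(pgv1)[::-1][: cfg.n_parents]
                parents = candidates.subset_individuals(nxt)
    return pd.DataFrame(rows)


def summarize_trajectories(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and 95% interval per strategy and cycle over replicates."""
    return _summarize(df, ["strategy", "cycle"])
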