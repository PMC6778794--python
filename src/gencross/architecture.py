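"""True two-trait genetic architectures: QTL sampling and correlation control.

A simulated pair of traits is governed by QTL drawn from the genotyped SNPs
(QTL are *not* masked from the marker set seen by prediction models).  QTL
effect magnitudes follow a geometric series; the genetic correlation between
the traits is induced either by pleiotropy (shared loci) or by linkage
disequilibrium between paired loci at a controlled map distance (tight
linkage: <= 5 cM; loose linkage: 25-35 cM).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneticMap, GenotypeMatrix

__all__ = [
    "TraitArchitecture",
    "GenotypicValues",
    "geometric_effects",
    "build_architecture",
    "genotypic_values",
]

ARCHITECTURE_KINDS = ("pleiotropy", "tight_linkage", "loose_linkage")


def geometric_effects(L: int) -> np.ndarray:
    """Geometric series of allele-substitution effect magnitudes.

    The k-th effective QTL (k = 1..L) has favorable-homozygote value a**k
    with a = (L-1)/(L+1); the magnitudes are strictly decreasing.  Because
    the favorable allele is randomized per QTL afterwards, only |a| matters
    and the magnitude convention is used.  L=1 degenerates to a=0.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    a = (L - 1) / (L + 1)
    if L == 1:
        warnings.warn("L=1 gives a=0: the single QTL has zero effect")
    return a ** np.arange(1, L + 1)


@dataclass
class TraitArchitecture:
    """True QTL positions and two-trait allele-substitution effects.

    ``effects[k]`` holds the trait-1 effect at marker ``qtl_markers_trait1[k]``
    and the trait-2 effect at ``qtl_markers_trait2[k]`` (the same marker under
    pleiotropy).  Exactly L rows are effective (non-zero magnitude).
    """

    qtl_markers_trait1: np.ndarray
    qtl_markers_trait2: np.ndarray
    effects: np.ndarray  # (n_qtl, 2)
    effective: np.ndarray  # boolean, L True entries
    architecture_kind: str
    target_correlation: float
    n_markers: int

    def effect_vector(self, trait: int) -> np.ndarray:
        """Genomewide allele-substitution effect vector for trait 1 or 2."""
        qtl = self.qtl_markers_trait1 if trait == 1 else self.qtl_markers_trait2
        v = np.zeros(self.n_markers)
        np.add.at(v, qtl, self.effects[:, trait - 1])
        return v

    def effective_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(trait1 loci, trait2 loci, L x 2 effects) of the effective QTL."""
        e = self.effective
        return (
            self.qtl_markers_trait1[e],
            self.qtl_markers_trait2[e],
            self.effects[e],
        )

    def to_frame(self, gmap: GeneticMap) -> pd.DataFrame:
        rows = []
        for k in range(len(self.effects)):
            i, j = self.qtl_markers_trait1[k], self.qtl_markers_trait2[k]
            rows.append((gmap.marker[i], 1, self.effects[k, 0], gmap.marker[j]))
            rows.append((gmap.marker[j], 2, self.effects[k, 1], gmap.marker[i]))
        return pd.DataFrame(rows, columns=["marker", "trait", "effect", "pair_marker"])

    def save(self, path, gmap: GeneticMap, seed=None) -> None:
        self.to_frame(gmap).to_csv(path, sep="\t", index=False, lineterminator="\n")
        meta = {
            "kind": self.architecture_kind,
            "L": int(self.effective.sum()),
            "rG0": self.target_correlation,
            "seed": seed,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def _sigma_factor(rg0: float) -> np.ndarray:
    """Lower-triangular factor of [[1, rG0], [rG0, 1]] (limit form at |rG0|=1)."""
    return np.array([[1.0, 0.0], [rg0, np.sqrt(max(0.0, 1.0 - rg0 ** 2))]])


def build_architecture(
    gmap: GeneticMap,
    founders: GenotypeMatrix,
    kind: str,
    L: int,
    rG0: float,
    n_qtl_per_trait: int = 100,
    seed=None,
) -> TraitArchitecture:
    """Sample a two-trait QTL architecture targeting base correlation rG0.

    Trait-1 QTL are sampled from the genotyped markers; L of them receive
    geometric magnitudes with independently randomized favorable alleles per
    trait.  Under pleiotropy the L x 2 effect matrix A is post-multiplied by
    the lower Cholesky factor of Sigma = [[1, rG0], [rG0, 1]] (transposed, so
    trait-1 effects are preserved).  Under the linkage kinds each trait-1 QTL
    is paired with a distance-constrained partner marker, the same Sigma
    transform is applied, and each trait-2 effect is then scaled by the
    signed LD correlation r between the paired loci in ``founders``.  The
    realized founder correlation then approximately matches rG0.
    """
    if kind not in ARCHITECTURE_KINDS:
        raise ValueError(f"kind must be one of {ARCHITECTURE_KINDS}")
    if not -1.0 <= rG0 <= 1.0:
        raise ValueError("target correlation must be in [-1, 1]")
    if L > n_qtl_per_trait:
        raise ValueError("L cannot exceed n_qtl_per_trait")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers

    if kind == "pleiotropy":
        candidates = np.arange(m)
    else:
        # only markers with at least one admissible partner can host a
        # trait-1 QTL (map edges/gaps can leave the distance window empty)
        lo, hi = (0.0, 5.0) if kind == "tight_linkage" else (25.0, 35.0)
        partner_pool: dict[int, np.ndarray] = {}
        for i in range(m):
            same = np.flatnonzero(gmap.chrom == gmap.chrom[i])
            d = np.abs(gmap.pos_cM[same] - gmap.pos_cM[i])
            ok = same[(d >= lo) & (d <= hi) & (same != i)]
            if len(ok):
                partner_pool[i] = ok
        candidates = np.array(sorted(partner_pool))
        if len(candidates) < n_qtl_per_trait:
            raise ValueError(
                f"only {len(candidates)} markers have an admissible pairing "
                f"marker within [{lo}, {hi}] cM; need {n_qtl_per_trait}"
            )

    qtl1 = rng.choice(candidates, size=n_qtl_per_trait, replace=False)
    mags = np.zeros(n_qtl_per_trait)
    mags[:L] = geometric_effects(L)
    effective = mags > 0

    signs = rng.choice((-1.0, 1.0), size=(n_qtl_per_trait, 2))
    A = mags[:, None] * signs

    if kind == "pleiotropy":
        qtl2 = qtl1.copy()
    else:
        qtl2 = np.array([rng.choice(partner_pool[i]) for i in qtl1])

    A = A @ _sigma_factor(rG0).T

    if kind != "pleiotropy":
        # scale trait-2 effects by signed LD r with the paired trait-1 locus
        x1 = founders.calls[:, qtl1]
        x2 = founders.calls[:, qtl2]
        x1c = x1 - x1.mean(axis=0)
        x2c = x2 - x2.mean(axis=0)
        denom = np.sqrt((x1c ** 2).sum(axis=0) * (x2c ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (x1c * x2c).sum(axis=0) / denom, 0.0)
        A[:, 1] *= r

    return TraitArchitecture(
        qtl_markers_trait1=qtl1,
        qtl_markers_trait2=qtl2,
        effects=A,
        effective=effective,
        architecture_kind=kind,
        target_correlation=float(rG0),
        n_markers=m,
    )


@dataclass
class GenotypicValues:
    """Per-individual true genotypic values for the two traits."""

    values: np.ndarray  # (n, 2)
    variances: np.ndarray  # (2,), population convention (divide by n)
    correlation: float

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]


def genotypic_values(geno: GenotypeMatrix, arch: TraitArchitecture) -> GenotypicValues:
    """Sum of carried QTL allele effects, per individual and trait.

    Genetic variance uses the population convention (divide by n); the
    realized genetic correlation is the Pearson correlation of the two value
    vectors (NaN, with a warning, if either variance is zero).
    """
    if geno.n_markers != arch.n_markers:
        raise ValueError("genotype matrix does not cover the QTL marker set")
    vals = np.column_stack(
        [geno.calls @ arch.effect_vector(1), geno.calls @ arch.effect_vector(2)]
    )
    var = vals.var(axis=0)
    c = vals - vals.mean(axis=0)
    ss = (c ** 2).sum(axis=0)
    if np.all(ss > 0):
        corr = float((c[:, 0] * c[:, 1]).sum() / np.sqrt(ss[0] * ss[1]))
    else:
        warnings.warn("zero genetic variance: correlation undefined (NaN)")
        corr = float("nan")
    return GenotypicValues(values=vals, variances=var, correlation=corr)
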