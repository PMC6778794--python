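"""Gamete and recombinant-inbred-line (RIL) simulation on a genetic map.

Meiosis assumes no crossover interference and no mutation: crossover counts
per chromosome are Poisson with mean equal to the chromosome length in
Morgans, and crossover positions are uniform.  Under that model the parental
origin along a chromosome is a Markov chain over markers whose transition
probability between adjacent markers is the Haldane recombination fraction;
:func:`bulk_gametes` exploits this for vectorized simulation, while
:func:`simulate_gamete` implements the literal crossover-position mechanism.
Both produce the same marker-level distribution (checked in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GeneticMap, GenotypeMatrix, map_distance_to_recomb

__all__ = [
    "RILFamily",
    "simulate_gamete",
    "bulk_gametes",
    "ril_transition_fraction",
    "make_ril_family",
]


def ril_transition_fraction(c):
    """Two-locus recombinant fraction in selfed-to-fixation RILs.

    R* = 2c / (1 + 2c) (Haldane & Waddington).  Its complement satisfies
    1 - 2 R* = (1 - 2c) / (1 + 2c), the pair weight in the cross-variance
    formula.
    """
    c = np.asarray(c, dtype=float)
    out = 2.0 * c / (1.0 + 2.0 * c)
    return out if out.ndim else float(out)


def simulate_gamete(parent_hap_pair, gmap: GeneticMap, rng) -> np.ndarray:
    """One gamete from a diploid parent via explicit crossover positions.

    Per chromosome: crossover count ~ Poisson(length in Morgans), positions
    uniform over the chromosome, starting haplotype chosen with probability
    1/2.  Returns a haplotype vector over all markers.
    """
    h1, h2 = (np.asarray(h, dtype=float) for h in parent_hap_pair)
    rng = np.random.default_rng(rng)
    gam = np.empty(gmap.n_markers)
    for sl in gmap.chrom_slices().values():
        pos = gmap.pos_cM[sl]
        lo, hi = pos[0], pos[-1]
        n_xo = rng.poisson(max(hi - lo, 0.0) / 100.0)
        xo = np.sort(rng.uniform(lo, hi, n_xo))
        # origin at marker = start + number of crossovers to its left (mod 2)
        origin = (rng.integers(0, 2) + np.searchsorted(xo, pos, side="left")) % 2
        gam[sl] = np.where(origin == 0, h1[sl], h2[sl])
    return gam


def _markov_origins(n: int, gmap: GeneticMap, switch: dict, rng) -> np.ndarray:
    """(n x markers) matrix of 0/1 parental origins from per-interval switch
    probabilities, independently per chromosome."""
    origins = np.empty((n, gmap.n_markers), dtype=np.int8)
    for ch, sl in gmap.chrom_slices().items():
        m = sl.stop - sl.start
        start = rng.integers(0, 2, size=(n, 1))
        if m > 1:
            flips = (rng.random((n, m - 1)) < switch[ch]).astype(np.int8)
            cum = np.cumsum(flips, axis=1) % 2
            origins[:, sl] = np.concatenate([start, (start + cum) % 2], axis=1)
        else:
            origins[:, sl] = start
    return origins


def bulk_gametes(h1: np.ndarray, h2: np.ndarray, gmap: GeneticMap, rng) -> np.ndarray:
    """One gamete from each of n diploid parents (rows of ``h1``/``h2``)."""
    h1 = np.atleast_2d(np.asarray(h1, dtype=float))
    h2 = np.atleast_2d(np.asarray(h2, dtype=float))
    rng = np.random.default_rng(rng)
    switch = gmap.adjacent_recomb()
    origins = _markov_origins(h1.shape[0], gmap, switch, rng)
    return np.where(origins == 0, h1, h2)


@dataclass
class RILFamily:
    """A biparental family of fully inbred recombinant lines."""

    family_id: str
    parent_ids: tuple
    progeny: GenotypeMatrix


def make_ril_family(
    p1: np.ndarray,
    p2: np.ndarray,
    gmap: GeneticMap,
    n_progeny: int,
    method: str = "direct",
    seed=None,
    n_self_generations: int = 5,
    family_id: str = "F1",
    parent_ids: tuple = ("P1", "P2"),
) -> RILFamily:
    """Simulate a family of RILs from two fully inbred parents.

    ``direct`` (default) draws each RIL as a single inbred chromosome set
    using the RIL-by-selfing recombination fraction R* = 2c/(1+2c) between
    adjacent markers; it corresponds to selfing to fixation.  ``selfing``
    simulates the F1 and ``n_self_generations`` of single-seed descent
    explicitly, then doubles a final gamete.  The two methods agree on the
    marker-level distribution up to the residual heterozygosity of finite
    selfing.
    """
    p1 = np.asarray(p1, dtype=float).ravel()
    p2 = np.asarray(p2, dtype=float).ravel()
    for p in (p1, p2):
        if not np.isin(p, (-1.0, 1.0)).all():
            raise ValueError("parents must be fully inbred (+/-1 calls only)")
    rng = np.random.default_rng(seed)

    if method == "direct":
        switch = {
            ch: ril_transition_fraction(c)
            for ch, c in gmap.adjacent_recomb().items()
        }
        origins = _markov_origins(n_progeny, gmap, switch, rng)
        calls = np.where(origins == 0, p1, p2)
    elif method == "selfing":
        h1 = np.repeat(p1[None, :], n_progeny, axis=0)
        h2 = np.repeat(p2[None, :], n_progeny, axis=0)
        for _ in range(n_self_generations):
            g1 = bulk_gametes(h1, h2, gmap, rng)
            g2 = bulk_gametes(h1, h2, gmap, rng)
            h1, h2 = g1, g2
        calls = bulk_gametes(h1, h2, gmap, rng)
    else:
        raise ValueError(f"unknown method {method!r}")

    ids = [f"{family_id}-{k + 1}" for k in range(n_progeny)]
    return RILFamily(family_id, tuple(parent_ids), GenotypeMatrix(ids, calls))
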