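"""Genetic maps, genotype matrices, founder hygiene and synthetic founder panels.

The unit of map distance throughout is the centiMorgan (cM).  Marker order in a
:class:`GeneticMap` is the single source of truth for column order in every
:class:`GenotypeMatrix` attached to it.  Inbred lines are coded -1/+1 per
marker (homozygous for the second/first allele); 0 denotes a heterozygote and
is only expected in raw input, never after :func:`clean_founders`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "map_distance_to_recomb",
    "kosambi_distance_to_recomb",
    "jitter_map",
    "clean_founders",
    "generate_synthetic_founders",
    "read_genetic_map",
    "write_genetic_map",
    "read_genotype_matrix",
    "write_genotype_matrix",
]


def map_distance_to_recomb(d):
    """Haldane mapping function: cM distance -> recombination fraction.

    c = 0.5 * (1 - exp(-2 d / 100)).  Monotone increasing, c(0)=0 and
    c -> 0.5 as d -> inf.  Matches a no-interference (Poisson) crossover
    process, the meiosis model used throughout the package.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    c = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return c if c.ndim else float(c)


def kosambi_distance_to_recomb(d):
    """Kosambi mapping function (interference-adjusted alternative).

    Provided behind the same contract as :func:`map_distance_to_recomb`;
    not used by the meiosis simulator, which assumes no interference.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    c = 0.5 * np.tanh(2.0 * d / 100.0)
    return c if c.ndim else float(c)


@dataclass
class GeneticMap:
    """Ordered bi-allelic marker loci with chromosome and cM position."""

    marker: np.ndarray
    chrom: np.ndarray
    pos_cM: np.ndarray

    def __post_init__(self):
        self.marker = np.asarray(self.marker, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos_cM = np.asarray(self.pos_cM, dtype=float)
        if not (len(self.marker) == len(self.chrom) == len(self.pos_cM)):
            raise ValueError("map columns must have equal length")
        if len(set(self.marker)) != len(self.marker):
            raise ValueError("marker ids must be unique")
        if np.any(self.pos_cM < 0):
            raise ValueError("cM positions must be non-negative")
        order = np.lexsort((self.pos_cM, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            self.marker = self.marker[order]
            self.chrom = self.chrom[order]
            self.pos_cM = self.pos_cM[order]

    @property
    def n_markers(self) -> int:
        return len(self.marker)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chrom)

    def chrom_slices(self) -> dict[int, slice]:
        """Contiguous index slice of each chromosome (markers are sorted)."""
        out = {}
        for ch in self.chromosomes:
            idx = np.flatnonzero(self.chrom == ch)
            out[int(ch)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def is_strictly_increasing(self) -> bool:
        return all(
            np.all(np.diff(self.pos_cM[sl]) > 0) for sl in self.chrom_slices().values()
        )

    def recomb_fraction(self, i: int, j: int) -> float:
        """Pairwise recombination fraction between marker indices i and j.

        0.5 exactly for loci on different chromosomes, 0 on the diagonal.
        """
        if i == j:
            return 0.0
        if self.chrom[i] != self.chrom[j]:
            return 0.5
        return map_distance_to_recomb(abs(self.pos_cM[i] - self.pos_cM[j]))

    def recomb_matrix(self) -> np.ndarray:
        """Full pairwise recombination-fraction matrix (dense; small maps only)."""
        m = self.n_markers
        c = np.full((m, m), 0.5)
        for sl in self.chrom_slices().values():
            d = np.abs(self.pos_cM[sl, None] - self.pos_cM[None, sl])
            c[sl, sl] = map_distance_to_recomb(d)
        np.fill_diagonal(c, 0.0)
        return c

    def adjacent_recomb(self) -> dict[int, np.ndarray]:
        """Per-chromosome recombination fraction between adjacent markers."""
        return {
            ch: map_distance_to_recomb(np.diff(self.pos_cM[sl]))
            for ch, sl in self.chrom_slices().items()
        }

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        return GeneticMap(self.marker[keep], self.chrom[keep], self.pos_cM[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.marker, "chrom": self.chrom, "pos_cM": self.pos_cM}
        )


@dataclass
class GenotypeMatrix:
    """Individuals x markers call matrix in {-1, 0, 1} (NaN = missing).

    Column order matches the attached :class:`GeneticMap`.
    """

    ids: list = field(default_factory=list)
    calls: np.ndarray = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x markers)")
        if len(self.ids) != self.calls.shape[0]:
            raise ValueError("ids length must match number of rows")
        valid = np.isnan(self.calls) | np.isin(self.calls, (-1.0, 0.0, 1.0))
        if not valid.all():
            raise ValueError("genotype calls must be in {-1, 0, 1} or missing")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.calls).any())

    def is_inbred(self) -> bool:
        """True when every call is homozygous (-1 or +1, no missing)."""
        return bool(np.isin(self.calls, (-1.0, 1.0)).all())

    def subset_individuals(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.ids[int(i)] for i in keep], self.calls[keep, :].copy()
        )

    def subset_markers(self, keep) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), self.calls[:, keep].copy())


def jitter_map(gmap: GeneticMap, epsilon: float = 1e-6) -> GeneticMap:
    """Resolve coincident cM positions by adding multiples of ``epsilon``.

    Markers sharing a position (common under low genetic resolution) are
    offset by 0, eps, 2*eps, ... in their stored order, per chromosome, so
    positions become strictly increasing while relative order is preserved.
    """
    pos = gmap.pos_cM.copy()
    for sl in gmap.chrom_slices().values():
        p = pos[sl]
        for k in range(1, len(p)):
            if p[k] <= p[k - 1]:
                p[k] = p[k - 1] + epsilon
        pos[sl] = p
    return GeneticMap(gmap.marker.copy(), gmap.chrom.copy(), pos)


def _mode_impute_column(col: np.ndarray, global_major: float) -> np.ndarray:
    obs = col[~np.isnan(col)]
    vals, counts = np.unique(obs, return_counts=True)
    top = vals[counts == counts.max()]
    if len(top) == 1:
        fill = top[0]
    elif global_major in top:
        fill = global_major
    else:
        fill = 1.0
    out = col.copy()
    out[np.isnan(out)] = fill
    return out


def clean_founders(
    geno: GenotypeMatrix, gmap: GeneticMap, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, GeneticMap]:
    """Founder-panel hygiene for an inbred breeding panel.

    Drops lines then markers with more than ``max_missing`` missing calls,
    sets heterozygous calls to missing, imputes remaining missing calls with
    the per-marker mode, then removes monomorphic markers and redundant
    markers (identical call vector *and* identical map position).  Mode ties
    break toward the major allele of the whole matrix, then toward +1.
    The operation is idempotent.
    """
    calls = geno.calls.copy()
    ids = list(geno.ids)

    line_miss = np.isnan(calls).mean(axis=1)
    keep_lines = line_miss <= max_missing
    calls = calls[keep_lines]
    ids = [i for i, k in zip(ids, keep_lines) if k]
    if calls.shape[0] == 0:
        raise ValueError("all lines removed by the missing-data filter")

    mark_miss = np.isnan(calls).mean(axis=0)
    keep = mark_miss <= max_missing
    calls = calls[:, keep]
    cmap = gmap.subset(keep)
    if calls.shape[1] == 0:
        raise ValueError("all markers removed by the missing-data filter")

    calls[calls == 0.0] = np.nan

    nz = calls[~np.isnan(calls)]
    global_major = 1.0 if (nz == 1.0).sum() >= (nz == -1.0).sum() else -1.0
    for j in range(calls.shape[1]):
        if np.isnan(calls[:, j]).any():
            if np.isnan(calls[:, j]).all():
                continue  # removed below as monomorphic
            calls[:, j] = _mode_impute_column(calls[:, j], global_major)

    poly = np.array(
        [len(np.unique(col[~np.isnan(col)])) > 1 for col in calls.T]
    )
    calls = calls[:, poly]
    cmap = cmap.subset(poly)
    if calls.shape[1] == 0:
        raise ValueError("all markers removed (monomorphic)")

    # redundant: identical calls AND identical (chrom, position)
    keep = np.ones(calls.shape[1], dtype=bool)
    seen: dict[tuple, int] = {}
    for j in range(calls.shape[1]):
        key = (int(cmap.chrom[j]), float(cmap.pos_cM[j]), calls[:, j].tobytes())
        if key in seen:
            keep[j] = False
        else:
            seen[key] = j
    calls = calls[:, keep]
    cmap = cmap.subset(keep)

    return GenotypeMatrix(ids, calls), cmap


def generate_synthetic_founders(
    n_lines: int = 1500,
    n_markers: int = 2300,
    n_chromosomes: int = 7,
    chrom_length: float = 150.0,
    n_base_haplotypes: int = 30,
    n_mixing_generations: int = 1,
    seed=None,
    ld_decay_cM: float = 300.0,
) -> tuple[GenotypeMatrix, GeneticMap]:
    """Synthetic inbred founder panel with tunable long-range LD.

    Emulates an elite inbreeding-crop breeding panel: fully homozygous lines,
    bi-allelic SNPs on a multi-chromosome cM map, and haplotype-block LD
    persisting over tens of cM (as observed in selfing crops, whose low
    effective recombination keeps chromosome-scale blocks intact).  Each
    base haplotype is a Markov mosaic of two deeply diverged ancestral
    chromosomes, with ancestry autocorrelation exp(-d / ``ld_decay_cM``);
    lines then descend from the ``n_base_haplotypes`` base haplotypes
    through ``n_mixing_generations`` of random mating whose final gametes
    are doubled (one-step inbreeding).  Fewer mixing generations and a
    larger ``ld_decay_cM`` both give longer-range LD.  >=95% of markers
    stay polymorphic in the panel.
    """
    from . import meiosis  # deferred: meiosis imports genome types

    if min(n_lines, n_markers, n_chromosomes) <= 0 or chrom_length <= 0:
        raise ValueError("all counts and lengths must be positive")
    if n_base_haplotypes < 2:
        raise ValueError("need at least 2 base haplotypes")
    rng = np.random.default_rng(seed)

    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    chrom, pos = [], []
    for ch in range(1, n_chromosomes + 1):
        chrom.extend([ch] * per[ch - 1])
        pos.extend(np.sort(rng.uniform(0.0, chrom_length, per[ch - 1])))
    marker = np.array([f"M{k + 1:05d}" for k in range(n_markers)], dtype=object)
    gmap = jitter_map(GeneticMap(marker, np.array(chrom), np.array(pos)))

    # base haplotypes: two-ancestor Markov mosaics; ancestry correlation
    # between loci at distance d is exp(-d / ld_decay_cM)
    ancestry = np.empty((n_base_haplotypes, n_markers), dtype=np.int8)
    for sl in gmap.chrom_slices().values():
        m_ch = sl.stop - sl.start
        q = 0.5 * (1.0 - np.exp(-np.diff(gmap.pos_cM[sl]) / ld_decay_cM))
        start = rng.integers(0, 2, size=(n_base_haplotypes, 1))
        if m_ch > 1:
            flips = (rng.random((n_base_haplotypes, m_ch - 1)) < q).astype(np.int8)
            cum = np.cumsum(flips, axis=1) % 2
            ancestry[:, sl] = np.concatenate([start, (start + cum) % 2], axis=1)
        else:
            ancestry[:, sl] = start
    marker_sign = rng.choice((-1.0, 1.0), n_markers)  # which allele is "+1"
    base = marker_sign * (2.0 * ancestry - 1.0)

    if n_mixing_generations == 0:
        pick = rng.integers(0, n_base_haplotypes, n_lines)
        calls = base[pick].copy()
    else:
        h1 = base[rng.integers(0, n_base_haplotypes, n_lines)]
        h2 = base[rng.integers(0, n_base_haplotypes, n_lines)]
        for _ in range(n_mixing_generations - 1):
            sires = rng.integers(0, n_lines, n_lines)
            dams = (sires + 1 + rng.integers(0, n_lines - 1, n_lines)) % n_lines
            g1 = meiosis.bulk_gametes(h1[sires], h2[sires], gmap, rng)
            g2 = meiosis.bulk_gametes(h1[dams], h2[dams], gmap, rng)
            h1, h2 = g1, g2
        # final generation: one gamete per line, doubled (one-step inbreeding)
        sires = rng.integers(0, n_lines, n_lines)
        calls = meiosis.bulk_gametes(h1[sires], h2[sires], gmap, rng)

    ids = [f"L{k + 1:05d}" for k in range(n_lines)]
    return GenotypeMatrix(ids, calls), gmap


# ---------------------------------------------------------------------------
# File formats: tab-separated, UTF-8, LF; missing genotype sentinel is "NA".

def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["marker", "chrom", "pos_cM"]
    if list(df.columns) != expected:
        raise ValueError(f"map header must be {expected}, got {list(df.columns)}")
    return GeneticMap(df["marker"].to_numpy(), df["chrom"].to_numpy(),
                      df["pos_cM"].to_numpy())


def write_genotype_matrix(geno: GenotypeMatrix, gmap: GeneticMap, path) -> None:
    if geno.n_markers != gmap.n_markers:
        raise ValueError("genotype and map marker counts disagree")
    df = pd.DataFrame(geno.calls, columns=list(gmap.marker))
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "line_id", geno.ids)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _marker_set_diff(a, b) -> str:
    a, b = set(a), set(b)
    only_a = sorted(a - b)[:5]
    only_b = sorted(b - a)[:5]
    return (f"{len(a - b)} markers only in genotypes (e.g. {only_a}); "
            f"{len(b - a)} only in map (e.g. {only_b})")


def read_genotype_matrix(path, gmap: GeneticMap) -> GenotypeMatrix:
    """Read a genotype table and align its columns to ``gmap`` marker order.

    The marker sets must agree exactly; a mismatch raises with a diff summary.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], comment="#")
    if df.columns[0] != "line_id":
        raise ValueError("first genotype column must be 'line_id'")
    markers = list(df.columns[1:])
    if set(markers) != set(gmap.marker):
        raise ValueError("genotype/map marker sets disagree: "
                         + _marker_set_diff(markers, gmap.marker))
    df = df.set_index("line_id")[list(gmap.marker)]
    return GenotypeMatrix(list(df.index), df.to_numpy(dtype=float))
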