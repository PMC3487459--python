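"""Genotype spaces, fitness topographies and fitness landscapes.

A genotype over ``L`` biallelic loci is encoded as an integer ``g`` in
``[0, 2**L)``: bit ``l`` (least significant = locus 0) holds the allele at
locus ``l``, with ``0`` the deleterious and ``1`` the beneficial allele.
String renderings are most-significant-bit first, so ``"1111"`` is the
global peak and ``"0000"`` the least fit genotype.

The basal landscape is smooth and single-peaked: a genotype carrying ``k``
deleterious (0) alleles has Malthusian fitness ``m(k) = 1 - s * k**eps``,
where ``s`` is the selection coefficient (fitness reduction per deleterious
allele) and ``eps`` tunes magnitude epistasis (``eps == 1`` additive,
``eps > 1`` negative/antagonistic, ``eps < 1`` positive/synergistic).
A *fitness topography* is a set of intermediate genotypes designated as
low-fitness genotypes (LFGs); these are overlaid with Malthusian fitness
exactly 0, which obstructs mutational paths to the peak.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSpace",
    "FitnessTopography",
    "FitnessLandscape",
    "basal_fitness",
    "build_landscape",
    "enumerate_topographies",
    "orbit_classes",
    "sample_topographies",
    "topography_to_json",
    "topography_from_json",
    "landscape_to_tsv",
]


class GenotypeSpace:
    """The hypercube of ``2**L`` binary genotypes with Hamming structure.

    Attributes
    ----------
    L : int
        Number of biallelic loci (>= 2).
    n_genotypes : int
        ``2**L``.
    genotypes : ndarray of int
        All genotype indices ``0 .. 2**L - 1`` in order.
    neighbors : ndarray, shape (2**L, L)
        ``neighbors[g, l]`` is ``g`` with the allele at locus ``l`` flipped.
    bits : ndarray, shape (2**L, L)
        ``bits[g, l]`` is the allele (0/1) of genotype ``g`` at locus ``l``.
    k : ndarray of int
        Number of deleterious (0) alleles per genotype.
    """

    def __init__(self, L: int):
        if L < 2:
            raise ValueError(f"need at least 2 loci, got L={L}")
        self.L = int(L)
        self.n_genotypes = 1 << L
        self.genotypes = np.arange(self.n_genotypes)
        self.neighbors = np.array(
            [[g ^ (1 << l) for l in range(L)] for g in range(self.n_genotypes)],
            dtype=np.int64,
        )
        self.bits = np.array(
            [[(g >> l) & 1 for l in range(L)] for g in range(self.n_genotypes)],
            dtype=np.int8,
        )
        self.k = (self.L - self.bits.sum(axis=1)).astype(np.int64)
        self.peak = self.n_genotypes - 1  # "111...1"
        self.bottom = 0  # "000...0"

    def hamming(self, i: int, j: int) -> int:
        """Hamming distance between genotypes ``i`` and ``j``."""
        return int(i ^ j).bit_count()

    def to_string(self, g: int) -> str:
        return format(int(g), f"0{self.L}b")

    def from_string(self, s: str) -> int:
        if len(s) != self.L or set(s) - {"0", "1"}:
            raise ValueError(f"not a length-{self.L} binary string: {s!r}")
        return int(s, 2)

    @property
    def intermediates(self) -> np.ndarray:
        """All genotypes except the least fit (all-0) and the peak (all-1)."""
        return np.arange(1, self.n_genotypes - 1)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeSpace(L={self.L})"


@dataclass(frozen=True)
class FitnessTopography:
    """A configuration of low-fitness genotypes (LFGs).

    LFGs may sit at any intermediate genotype, i.e. anywhere except the
    all-0 and all-1 extremes.
    """

    L: int
    lfgs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "lfgs", frozenset(int(g) for g in self.lfgs))
        top = (1 << self.L) - 1
        for g in self.lfgs:
            if g <= 0 or g >= top:
                raise ValueError(
                    "LFGs must be intermediate genotypes; "
                    f"got {format(max(g, 0), f'0{self.L}b')} (index {g})"
                )

    @property
    def n_lfgs(self) -> int:
        return len(self.lfgs)

    def sorted_indices(self) -> tuple:
        return tuple(sorted(self.lfgs))

    def label(self) -> str:
        """Stable identifier, e.g. ``"0101+0110"`` (``"none"`` if empty)."""
        if not self.lfgs:
            return "none"
        return "+".join(format(g, f"0{self.L}b") for g in self.sorted_indices())


class FitnessLandscape:
    """Malthusian fitness per genotype: basal ``1 - s*k**eps`` with LFG overlay.

    Constructed through :func:`build_landscape`; holds the genotype space,
    the parameters ``(s, eps)``, the topography and the fitness vector ``m``.
    """

    def __init__(self, space: GenotypeSpace, s: float, eps: float,
                 topography: FitnessTopography, m: np.ndarray):
        self.space = space
        self.s = float(s)
        self.eps = float(eps)
        self.topography = topography
        self.m = m
        self.m.setflags(write=False)

    @property
    def peak_fitness(self) -> float:
        return float(self.m[self.space.peak])

    def is_lfg(self, g: int) -> bool:
        return g in self.topography.lfgs

    def __repr__(self) -> str:  # pragma: no cover
        return (f"FitnessLandscape(L={self.space.L}, s={self.s}, eps={self.eps}, "
                f"lfgs={self.topography.label()})")


def basal_fitness(k, s: float, eps: float):
    """Basal Malthusian fitness ``1 - s * k**eps`` of a genotype with ``k``
    deleterious alleles.

    Parameters
    ----------
    k : int or array of int
        Number of deleterious (0) alleles, ``0 <= k <= L``.
    s : float
        Selection coefficient: fitness reduction per deleterious allele
        (in the additive case ``eps == 1``). Must be positive.
    eps : float
        Magnitude-epistasis exponent; ``> 1`` makes multi-mutants worse than
        additive (negative epistasis), ``< 1`` better (positive epistasis).

    Raises
    ------
    ValueError
        If the formula would produce a negative fitness for some ``k``
        (i.e. ``s * k**eps > 1``).
    """
    if s <= 0:
        raise ValueError(f"selection coefficient must be positive, got s={s}")
    if eps <= 0:
        raise ValueError(f"epistasis exponent must be positive, got eps={eps}")
    karr = np.asarray(k, dtype=float)
    if np.any(karr < 0) or np.any(karr != np.round(karr)):
        raise ValueError(f"k must be a non-negative integer count, got {k}")
    m = 1.0 - s * karr ** eps
    if np.any(m < 0):
        bad = int(np.atleast_1d(karr)[np.argmin(np.atleast_1d(m))])
        raise ValueError(
            f"negative fitness at k={bad}: s*k**eps = {s * bad ** eps:.6g} > 1"
        )
    if np.isscalar(k) or np.ndim(k) == 0:
        return float(m)
    return m


def build_landscape(space: GenotypeSpace, s: float, eps: float,
                    topography: FitnessTopography | None = None) -> FitnessLandscape:
    """Build a fitness landscape from the basal formula plus an LFG overlay.

    ``m(g) = 0`` for every LFG, otherwise ``m(g) = 1 - s * k(g)**eps`` where
    ``k(g)`` counts the deleterious alleles of ``g``.
    """
    if topography is None:
        topography = FitnessTopography(space.L)
    if topography.L != space.L:
        raise ValueError(
            f"topography has L={topography.L} but space has L={space.L}")
    m = np.asarray(basal_fitness(space.k, s, eps), dtype=float)
    for g in topography.lfgs:
        m[g] = 0.0
    return FitnessLandscape(space, s, eps, topography, m)


def enumerate_topographies(L: int, max_lfgs: int) -> Iterator[FitnessTopography]:
    """Yield every topography with at most ``max_lfgs`` LFGs, exactly once.

    Order is deterministic: by LFG count, then lexicographically over sorted
    genotype-index tuples, so screens are reproducible and resumable.
    """
    n_inter = (1 << L) - 2
    if not 0 <= max_lfgs <= n_inter:
        raise ValueError(
            f"max_lfgs must be in [0, {n_inter}] for L={L}, got {max_lfgs}")
    intermediates = range(1, (1 << L) - 1)
    for j in range(max_lfgs + 1):
        for combo in itertools.combinations(intermediates, j):
            yield FitnessTopography(L, frozenset(combo))


def _apply_locus_permutation(g: int, perm: Sequence[int], L: int) -> int:
    """Image of genotype ``g`` when locus ``l`` is relabelled ``perm[l]``."""
    out = 0
    for l in range(L):
        if (g >> l) & 1:
            out |= 1 << perm[l]
    return out


def canonical_form(topography: FitnessTopography) -> tuple:
    """Lexicographically least sorted index tuple over all locus permutations."""
    L = topography.L
    best = None
    for perm in itertools.permutations(range(L)):
        image = tuple(sorted(_apply_locus_permutation(g, perm, L)
                             for g in topography.lfgs))
        if best is None or image < best:
            best = image
    return best


def orbit_classes(topographies: Iterable[FitnessTopography],
                  L: int | None = None) -> list[list[FitnessTopography]]:
    """Partition topographies into equivalence classes under locus permutation.

    Two topographies are equivalent iff some permutation of locus positions
    maps one LFG set onto the other; equivalent landscapes have identical
    adaptation dynamics (up to relabelling) and hence identical T_fix.
    Classes are returned sorted by their canonical representative, members
    sorted by index tuple; the first member of each class is the
    lexicographically least.
    """
    topos = list(topographies)
    if not topos:
        return []
    Ls = {t.L for t in topos}
    if L is not None:
        Ls.add(L)
    if len(Ls) != 1:
        raise ValueError(f"topographies must share a single L, got {sorted(Ls)}")
    groups: dict[tuple, list[FitnessTopography]] = {}
    for t in topos:
        groups.setdefault(canonical_form(t), []).append(t)
    out = []
    for key in sorted(groups):
        out.append(sorted(groups[key], key=lambda t: t.sorted_indices()))
    return out


def sample_topographies(L: int, n_lfgs: int, count: int,
                        seed) -> list[FitnessTopography]:
    """Uniform sample, without replacement, of topographies with exactly
    ``n_lfgs`` LFGs. Reproducible under ``seed``."""
    n_inter = (1 << L) - 2
    total = math.comb(n_inter, n_lfgs)
    if count > total:
        raise ValueError(
            f"requested {count} topographies but only {total} exist "
            f"with {n_lfgs} LFGs at L={L}")
    rng = np.random.default_rng(seed)
    all_combos = list(itertools.combinations(range(1, (1 << L) - 1), n_lfgs))
    chosen = rng.choice(len(all_combos), size=count, replace=False)
    return [FitnessTopography(L, frozenset(all_combos[i])) for i in chosen]


# ---------------------------------------------------------------------------
# External interchange formats


def topography_to_json(topography: FitnessTopography) -> str:
    return json.dumps({
        "L": topography.L,
        "lfgs": [format(g, f"0{topography.L}b")
                 for g in topography.sorted_indices()],
    })


def topography_from_json(text: str) -> FitnessTopography:
    obj = json.loads(text)
    L = int(obj["L"])
    return FitnessTopography(L, frozenset(int(s, 2) for s in obj["lfgs"]))


def landscape_to_tsv(landscape: FitnessLandscape) -> str:
    """TSV with columns genotype, k, is_lfg, m (one row per genotype)."""
    sp = landscape.space
    df = pd.DataFrame({
        "genotype": [sp.to_string(g) for g in sp.genotypes],
        "k": sp.k,
        "is_lfg": [landscape.is_lfg(g) for g in sp.genotypes],
        "m": landscape.m,
    })
    return df.to_csv(sep="\t", index=False)
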