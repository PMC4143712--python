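"""Haplotypes, diplotypes and phase ambiguity.

A haplotype is an ordered allele string across the SNPs of a block; a
diplotype is an individual's unordered pair of haplotypes.  Unphased
multilocus genotypes do not determine the diplotype: with ``h`` heterozygous
sites there are ``2**(h-1)`` compatible pairs.  Phase is treated as a latent
variable throughout; this module enumerates the compatible set, evaluates the
diplotype probability under a frequency model with an inbreeding coefficient,

    P(z_k / z_k') = d f_k + (1 - d) f_k^2          (k == k')
                  = 2 (1 - d) f_k f_k'             (k != k'),

and estimates starting haplotype frequencies by EM under Hardy-Weinberg
equilibrium (d = 0).  ``d`` captures excess (d > 0) or deficit (d < 0) of
homozygosity; d = 0 is exactly HWE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

RARE_FREQUENCY_THRESHOLD = 0.05


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotype indices ``(k, kp)`` with ``k <= kp``."""

    k: int
    kp: int

    def __post_init__(self):
        if self.k > self.kp:
            object.__setattr__(self, "k", self.kp)
            object.__setattr__(self, "kp", self.k)

    @property
    def is_homozygous(self) -> bool:
        return self.k == self.kp


@dataclass
class FrequencyModel:
    """Haplotype list with frequencies ``f`` and inbreeding coefficient ``d``."""

    haplotypes: list[str]
    f: np.ndarray
    d: float = 0.0

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if len(self.haplotypes) != self.f.size:
            raise ValueError("haplotype list and frequency vector differ in length")
        if np.any(self.f < 0) or not np.isclose(self.f.sum(), 1.0, atol=1e-8):
            raise ValueError("frequencies must be nonnegative and sum to 1")
        lo = d_lower_bound(self.f)
        if not (lo <= self.d < 1.0):
            raise ValueError(f"inbreeding coefficient {self.d} outside valid "
                             f"range [{lo}, 1)")

    @property
    def m(self) -> int:
        return len(self.haplotypes)

    def index(self, haplotype: str) -> int:
        return self.haplotypes.index(haplotype)

    def rare_flags(self) -> np.ndarray:
        return self.f < RARE_FREQUENCY_THRESHOLD


def d_lower_bound(f: np.ndarray) -> float:
    """Smallest ``d`` keeping every diplotype probability nonnegative.

    The homozygote probability ``d f_k + (1-d) f_k^2`` is nonnegative iff
    ``d >= -f_k / (1 - f_k)`` for every haplotype with ``0 < f_k < 1``.
    """
    f = np.asarray(f, dtype=float)
    interior = f[(f > 0) & (f < 1)]
    if interior.size == 0:
        return -1.0
    return float(np.max(-interior / (1.0 - interior)))


def diplotype_probability(model: FrequencyModel, dip: Diplotype) -> float:
    """Probability of an unordered haplotype pair under the frequency model."""
    if not (0 <= dip.k < model.m and 0 <= dip.kp < model.m):
        raise IndexError("diplotype indices outside the frequency model")
    fk, fkp, d = model.f[dip.k], model.f[dip.kp], model.d
    if dip.is_homozygous:
        return d * fk + (1.0 - d) * fk * fk
    return 2.0 * (1.0 - d) * fk * fkp


def diplotype_log_probabilities(f: np.ndarray, d: float,
                                k: np.ndarray, kp: np.ndarray) -> np.ndarray:
    """Vectorized log diplotype probabilities for index arrays ``k``, ``kp``.

    Invalid (nonpositive) probabilities map to ``-inf``.
    """
    f = np.asarray(f, dtype=float)
    homo = k == kp
    p = np.where(homo, d * f[k] + (1.0 - d) * f[k] * f[k],
                 2.0 * (1.0 - d) * f[k] * f[kp])
    with np.errstate(divide="ignore"):
        return np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)


def _pair_haplotypes(genotype: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """All ordered-into-unordered phasings of one unphased genotype.

    Sites are (allele, allele) pairs; heterozygous sites are split both ways.
    """
    het_sites = [i for i, (a, b) in enumerate(genotype) if a != b]
    pairs = []
    # fix the first heterozygous site's orientation to halve the enumeration
    n_free = max(len(het_sites) - 1, 0)
    for bits in itertools.product((0, 1), repeat=n_free):
        h1 = []
        h2 = []
        assignment = {}
        if het_sites:
            assignment[het_sites[0]] = 0
            for site, bit in zip(het_sites[1:], bits):
                assignment[site] = bit
        for i, (a, b) in enumerate(genotype):
            if a == b:
                h1.append(a)
                h2.append(b)
            elif assignment[i] == 0:
                h1.append(a)
                h2.append(b)
            else:
                h1.append(b)
                h2.append(a)
        pairs.append(tuple(sorted(("".join(h1), "".join(h2)))))
    return sorted(set(pairs))


def enumerate_diplotypes(genotype: list[tuple[str, str]],
                         haplotype_universe: list[str] | None = None
                         ) -> list[tuple[str, str]]:
    """Unordered haplotype pairs compatible with an unphased genotype.

    With ``h`` heterozygous sites and an unrestricted universe the count is
    ``2**(h-1)`` (1 when fully homozygous).  Restricting to a universe keeps
    only pairs whose both members belong to it; an empty result raises.
    """
    pairs = _pair_haplotypes(genotype)
    if haplotype_universe is not None:
        uni = set(haplotype_universe)
        pairs = [p for p in pairs if p[0] in uni and p[1] in uni]
    if not pairs:
        raise ValueError("no diplotype in the haplotype universe is compatible "
                         "with this genotype; extend the universe")
    return pairs


@dataclass
class DiplotypeSupport:
    """Per-individual compatible diplotypes, indexed into a haplotype list."""

    haplotypes: list[str]
    supports: list[list[Diplotype]] = field(default_factory=list)

    @classmethod
    def from_genotypes(cls, genotypes: list[list[tuple[str, str]]],
                       haplotype_universe: list[str] | None = None
                       ) -> "DiplotypeSupport":
        raw = [enumerate_diplotypes(g, haplotype_universe) for g in genotypes]
        if haplotype_universe is None:
            haps = sorted({h for pairs in raw for p in pairs for h in p})
        else:
            haps = list(haplotype_universe)
        idx = {h: i for i, h in enumerate(haps)}
        supports = [[Diplotype(idx[a], idx[b]) for a, b in pairs]
                    for pairs in raw]
        return cls(haplotypes=haps, supports=supports)


def em_starting_frequencies(genotypes: list[list[tuple[str, str]]],
                            universe: list[str] | None = None,
                            tol: float = 1e-8, max_iter: int = 500,
                            ) -> tuple[FrequencyModel, list[float]]:
    """EM estimate of haplotype frequencies under HWE (d = 0).

    The E-step distributes each individual over its compatible diplotypes in
    proportion to ``2^het f_k f_k'``; the M-step counts expected haplotype
    copies.  Returns the fitted model (d = 0) and the per-iteration
    observed-data log-likelihood trace (monotone nondecreasing).
    """
    support = DiplotypeSupport.from_genotypes(genotypes, universe)
    haps = support.haplotypes
    m = len(haps)
    n = len(support.supports)
    if n == 0:
        raise ValueError("no individuals")
    # flatten supports for vectorized E-steps
    k = np.array([d.k for s in support.supports for d in s])
    kp = np.array([d.kp for s in support.supports for d in s])
    indiv = np.repeat(np.arange(n), [len(s) for s in support.supports])
    homo = (k == kp)
    mult = np.where(homo, 1.0, 2.0)

    f = np.full(m, 1.0 / m)
    trace: list[float] = []
    for _ in range(max_iter):
        p = mult * f[k] * f[kp]
        denom = np.bincount(indiv, p, minlength=n)
        trace.append(float(np.sum(np.log(np.maximum(denom, 1e-300)))))
        w = p / denom[indiv]
        counts = np.bincount(k, w, minlength=m) + np.bincount(kp, w, minlength=m)
        f_new = counts / (2.0 * n)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1):
            f = f_new
            break
        f = f_new
    f = f / f.sum()
    return FrequencyModel(haplotypes=haps, f=f, d=0.0), trace


def prune_universe(genotypes: list[list[tuple[str, str]]],
                   min_frequency: float | None = None,
                   ) -> tuple[FrequencyModel, DiplotypeSupport]:
    """Frequency-supported haplotype list for a block.

    Runs EM over the full phasing closure of the data, drops haplotypes whose
    fitted frequency falls below ``min_frequency`` (default ``0.5 / (2n)``,
    i.e. half a chromosome's worth), restores any haplotype required to keep
    every individual's support nonempty, and re-runs EM on the reduced
    universe.  Phasing-artifact haplotypes carry essentially zero EM mass, so
    genuinely rare haplotypes (frequency a few percent) are never pruned.
    """
    n = len(genotypes)
    if min_frequency is None:
        min_frequency = 0.5 / (2 * n)
    model, _ = em_starting_frequencies(genotypes)
    keep = {h for h, fr in zip(model.haplotypes, model.f) if fr >= min_frequency}
    # restore haplotypes an individual cannot do without
    for g in genotypes:
        pairs = enumerate_diplotypes(g)
        if not any(a in keep and b in keep for a, b in pairs):
            best = max(pairs, key=lambda p: model.f[model.index(p[0])]
                       * model.f[model.index(p[1])])
            keep.update(best)
    universe = [h for h in model.haplotypes if h in keep]
    model, _ = em_starting_frequencies(genotypes, universe)
    support = DiplotypeSupport.from_genotypes(genotypes, universe)
    return model, support
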