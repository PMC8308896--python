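"""Genotypes, phenotypes and the matching-phenotype infection rule.

Both antagonists are diploid and carry two linked interaction-mediating
loci, ``A`` and ``B``, each with two alleles.  At every locus one allele is
completely dominant, and dominance is the same at both loci within a
species.  A parasite infects a host if and only if their phenotypes match
at both loci; otherwise the host recognizes the parasite and resists.  The
host additionally carries a selectively neutral, unlinked modifier locus
controlling its recombination rate; that locus never enters phenotype or
infection logic.

Indexing conventions used throughout the package
------------------------------------------------
* allele index ``0``/``1`` corresponds to allele labels ``1``/``2``;
* two-locus haplotype ``ab = 2*a + b`` (``0=A1B1, 1=A1B2, 2=A2B1, 3=A2B2``);
* host haplotype ``h = 4*m + ab`` where ``m`` is the modifier allele slot
  (``0`` = resident, ``1`` = invader), so there are 8 host haplotypes;
* ordered host genotype ``t = 8*i + j`` (64 classes), ordered parasite
  genotype ``u = 4*i + j`` (16 classes);
* phenotype index ``ph = 2*pa + pb`` (4 classes per species).

Zygote/adult frequencies are symmetric matrices over ordered haplotype
pairs; the 9-class unordered genotype view used by the printed interaction
matrices is a read-only projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Dominance",
    "Outcome",
    "Regime",
    "phenotype_of",
    "interaction_outcome",
    "interaction_matrix",
    "danger_frequency",
    "marginal_fitnesses",
    "joint_infection_probability",
    "host_phenotype_table",
    "parasite_phenotype_table",
    "unordered_genotypes",
    "genotype_label",
]

N_AB = 4          # two-locus haplotypes per species
N_HOST_HAP = 8    # AB haplotypes x 2 modifier alleles
N_PAR_HAP = 4
N_HOST_GENO = N_HOST_HAP * N_HOST_HAP   # ordered pairs
N_PAR_GENO = N_PAR_HAP * N_PAR_HAP
N_PHENO = 4

_NORM_TOL = 1e-9


class Dominance(str, Enum):
    """Dominance relation between the two antagonists.

    The dominant parasite allele is always allele 2.  Under in-phase
    dominance the host shares that dominant allele; under anti-phase
    dominance allele 1 is dominant in the host.  Dominance is identical at
    loci A and B within each species.
    """

    IN_PHASE = "in_phase"
    ANTI_PHASE = "anti_phase"

    @property
    def parasite_dominant(self) -> int:
        """Dominant allele label in the parasite (always 2)."""
        return 2

    @property
    def host_dominant(self) -> int:
        """Dominant allele label in the host (2 in-phase, 1 anti-phase)."""
        return 2 if self is Dominance.IN_PHASE else 1

    @property
    def _host_dom_idx(self) -> int:
        return self.host_dominant - 1

    @property
    def _parasite_dom_idx(self) -> int:
        return self.parasite_dominant - 1


class Outcome(str, Enum):
    INFECTION = "infection"
    RESISTANCE = "resistance"


@dataclass(frozen=True)
class Regime:
    """One selection regime of the co-evolutionary model.

    Parameters
    ----------
    s_h :
        Host selection intensity: an infected host has viability ``1 - s_h``.
    s_p :
        Parasite selection intensity: a parasite failing to infect has
        viability ``1 - s_p``; ``s_p = 1`` encodes obligate parasitism.
    r_p :
        Fixed recombination fraction between loci A and B in the parasite.
    dominance :
        In-phase or anti-phase dominance between the antagonists.
    """

    s_h: float
    s_p: float
    r_p: float
    dominance: Dominance

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_h <= 1.0:
            raise ValueError(f"s_h must lie in [0, 1], got {self.s_h}")
        if not 0.0 <= self.s_p <= 1.0:
            raise ValueError(f"s_p must lie in [0, 1], got {self.s_p}")
        if not 0.0 <= self.r_p <= 0.5:
            raise ValueError(f"r_p must lie in [0, 0.5], got {self.r_p}")
        if not isinstance(self.dominance, Dominance):
            object.__setattr__(self, "dominance", Dominance(self.dominance))


def _locus_phenotype(a1: int, a2: int, dom_idx: int) -> int:
    """Phenotype (allele index) at one locus under complete dominance."""
    if a1 == a2:
        return a1
    return dom_idx


def _check_genotype(genotype) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    try:
        (a1, b1), (a2, b2) = genotype
    except (TypeError, ValueError) as exc:
        raise ValueError(
            "genotype must be a pair of (a, b) haplotypes"
        ) from exc
    for allele in (a1, b1, a2, b2):
        if allele not in (1, 2):
            raise ValueError(f"allele labels must be 1 or 2, got {allele!r}")
    return (a1, b1), (a2, b2)


def phenotype_of(genotype, species: str, scheme: Dominance) -> Tuple[int, int]:
    """Phenotype of an ordered two-locus genotype.

    ``genotype`` is a pair of ``(a, b)`` haplotypes with allele labels 1/2
    (any modifier component is the caller's business and must not be
    passed).  Returns the ``(A, B)`` phenotype as allele labels.
    """
    scheme = Dominance(scheme)
    if species == "host":
        dom = scheme.host_dominant
    elif species == "parasite":
        dom = scheme.parasite_dominant
    else:
        raise ValueError(f"unknown species {species!r}")
    (a1, b1), (a2, b2) = _check_genotype(genotype)
    pa = a1 if a1 == a2 else dom
    pb = b1 if b1 == b2 else dom
    return pa, pb


def interaction_outcome(host_genotype, parasite_genotype,
                        scheme: Dominance) -> Outcome:
    """Infection iff host and parasite phenotypes match at both loci."""
    hp = phenotype_of(host_genotype, "host", scheme)
    pp = phenotype_of(parasite_genotype, "parasite", scheme)
    return Outcome.INFECTION if hp == pp else Outcome.RESISTANCE


# ---------------------------------------------------------------------------
# array-level lookup tables (ordered-genotype index -> phenotype index)
# ---------------------------------------------------------------------------

def _ab_phenotype_table(dom_idx: int) -> np.ndarray:
    """Phenotype index for each of the 16 ordered AB genotypes."""
    tab = np.empty(N_AB * N_AB, dtype=np.int64)
    for i in range(N_AB):
        a1, b1 = i >> 1, i & 1
        for j in range(N_AB):
            a2, b2 = j >> 1, j & 1
            pa = _locus_phenotype(a1, a2, dom_idx)
            pb = _locus_phenotype(b1, b2, dom_idx)
            tab[N_AB * i + j] = 2 * pa + pb
    return tab


@lru_cache(maxsize=None)
def host_phenotype_table(scheme: Dominance) -> np.ndarray:
    """Phenotype index for each of the 64 ordered host genotypes.

    The modifier component of the haplotype index is ignored (the modifier
    locus is selectively neutral).
    """
    ab = _ab_phenotype_table(Dominance(scheme)._host_dom_idx)
    tab = np.empty(N_HOST_GENO, dtype=np.int64)
    for i in range(N_HOST_HAP):
        for j in range(N_HOST_HAP):
            tab[N_HOST_HAP * i + j] = ab[N_AB * (i % 4) + (j % 4)]
    return tab


@lru_cache(maxsize=None)
def parasite_phenotype_table(scheme: Dominance) -> np.ndarray:
    """Phenotype index for each of the 16 ordered parasite genotypes."""
    return _ab_phenotype_table(Dominance(scheme)._parasite_dom_idx)


# ---------------------------------------------------------------------------
# unordered 9-class projection (the printed interaction matrices)
# ---------------------------------------------------------------------------

def unordered_genotypes():
    """The nine unordered two-locus genotypes, in conventional order.

    Each entry ``(ga, gb)`` counts copies of allele 2 at loci A and B;
    the order is A-major: A1A1B1B1, A1A1B1B2, ..., A2A2B2B2.
    """
    return [(ga, gb) for ga in range(3) for gb in range(3)]


def genotype_label(ga: int, gb: int, species: str) -> str:
    suffix = {"host": "h", "parasite": "p"}[species]
    a = {0: ("A1", "A1"), 1: ("A1", "A2"), 2: ("A2", "A2")}[ga]
    b = {0: ("B1", "B1"), 1: ("B1", "B2"), 2: ("B2", "B2")}[gb]
    return "".join(x + suffix for x in (a[0], a[1], b[0], b[1]))


def _unordered_phenotype(ga: int, gb: int, dom_idx: int) -> Tuple[int, int]:
    pa = {0: 0, 2: 1}.get(ga, dom_idx)
    pb = {0: 0, 2: 1}.get(gb, dom_idx)
    return pa, pb


def interaction_matrix(scheme: Dominance) -> pd.DataFrame:
    """The 9x9 infection/resistance matrix over unordered genotypes.

    Rows are parasite genotypes, columns host genotypes; cells are ``"I"``
    (infection) or ``"R"`` (resistance).
    """
    scheme = Dominance(scheme)
    rows = [genotype_label(ga, gb, "parasite") for ga, gb in unordered_genotypes()]
    cols = [genotype_label(ga, gb, "host") for ga, gb in unordered_genotypes()]
    cells = np.empty((9, 9), dtype=object)
    for r, (pga, pgb) in enumerate(unordered_genotypes()):
        ppheno = _unordered_phenotype(pga, pgb, scheme._parasite_dom_idx)
        for c, (hga, hgb) in enumerate(unordered_genotypes()):
            hpheno = _unordered_phenotype(hga, hgb, scheme._host_dom_idx)
            cells[r, c] = "I" if ppheno == hpheno else "R"
    return pd.DataFrame(cells, index=rows, columns=cols)


# ---------------------------------------------------------------------------
# danger frequencies and frequency-dependent marginal fitnesses
# ---------------------------------------------------------------------------

def _as_flat(z: np.ndarray, n_hap: int, name: str) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape == (n_hap, n_hap):
        z = z.reshape(-1)
    elif z.shape != (n_hap * n_hap,):
        raise ValueError(f"{name} must be {n_hap}x{n_hap} (or flat), got {z.shape}")
    if abs(z.sum() - 1.0) > _NORM_TOL or (z < -_NORM_TOL).any():
        raise ValueError(f"{name} frequencies must be nonnegative and sum to 1")
    return z


def _phenotype_frequencies(z_flat: np.ndarray, pheno_table: np.ndarray) -> np.ndarray:
    return np.bincount(pheno_table, weights=z_flat, minlength=N_PHENO)


def danger_frequency(host_genotype, parasite_z, scheme: Dominance) -> float:
    """Per-encounter infection probability of one host genotype class.

    Equals the total frequency of parasite genotypes whose phenotype
    matches the host class's phenotype ("dangerous exactly for this
    class"), hence it is linear in the parasite frequencies and lies in
    [0, 1].
    """
    scheme = Dominance(scheme)
    pz = _as_flat(parasite_z, N_PAR_HAP, "parasite_z")
    fp = _phenotype_frequencies(pz, parasite_phenotype_table(scheme))
    pa, pb = phenotype_of(host_genotype, "host", scheme)
    return float(fp[2 * (pa - 1) + (pb - 1)])


def joint_infection_probability(host_z, parasite_z, scheme: Dominance) -> float:
    """Probability Q that a random encounter results in infection."""
    scheme = Dominance(scheme)
    hz = _as_flat(host_z, N_HOST_HAP, "host_z")
    pz = _as_flat(parasite_z, N_PAR_HAP, "parasite_z")
    fh = _phenotype_frequencies(hz, host_phenotype_table(scheme))
    fp = _phenotype_frequencies(pz, parasite_phenotype_table(scheme))
    return float(fh @ fp)


def marginal_fitnesses(host_z, parasite_z, regime: Regime):
    """Frequency-dependent genotype-class fitnesses of both species.

    Encounters occur proportionally to class frequencies, so the fitness of
    host class ``i`` is ``W_h(i) = 1 - s_h * p_i`` with ``p_i`` its danger
    frequency, and the fitness of parasite class ``j`` is
    ``W_p(j) = 1 - s_p * (1 - q_j)`` with ``q_j`` the total frequency of
    host classes it infects.

    Returns ``(W_h, W_p, wbar_h, wbar_p)`` where the fitness arrays match
    the shape of the input frequency matrices.
    """
    scheme = Dominance(regime.dominance)
    hz = _as_flat(host_z, N_HOST_HAP, "host_z")
    pz = _as_flat(parasite_z, N_PAR_HAP, "parasite_z")
    ph = host_phenotype_table(scheme)
    pp = parasite_phenotype_table(scheme)
    fh = _phenotype_frequencies(hz, ph)
    fp = _phenotype_frequencies(pz, pp)
    w_h = 1.0 - regime.s_h * fp[ph]
    w_p = 1.0 - regime.s_p * (1.0 - fh[pp])
    wbar_h = float(hz @ w_h)
    wbar_p = float(pz @ w_p)
    host_shape = np.asarray(host_z).shape
    par_shape = np.asarray(parasite_z).shape
    return (w_h.reshape(host_shape), w_p.reshape(par_shape), wbar_h, wbar_p)
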