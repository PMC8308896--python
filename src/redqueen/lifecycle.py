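"""One-generation life cycle and coupled co-evolutionary iteration.

The life cycle of both species is maturation (viability selection),
meiosis, and random mating, iterated with non-overlapping generations in
infinite populations:

* selection:      ``a_ij = z_ij * W_ij / Wbar``
* gamete pool:    ``g_k = sum_ij a_ij * P(ij -> k)``
* random mating:  ``z'_ij = g_i * g_j``

Both species' fitnesses are computed from the same generation-t state
before either is advanced (one parasite generation per host generation).
The host modifier locus is unlinked from the A--B block and segregates
independently, which is equivalent to gene order M--A--B with
``r_MA = 0.5`` and no crossover interference.

The public operations here (:func:`select`, :func:`two_locus_gametes`,
:func:`host_gamete_pool`, :func:`random_mating`, :func:`step`) form the
readable pure-numpy reference path; :func:`run` drives the compiled kernel
for long trajectories and matches :func:`step` to floating-point accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernel
from .genotype_space import (
    N_AB,
    N_HOST_HAP,
    N_PAR_HAP,
    Dominance,
    Regime,
    host_phenotype_table,
    parasite_phenotype_table,
)
from .strategies import Strategy, resolve_effective_rates

__all__ = [
    "ExtinctionError",
    "PopulationState",
    "initial_state",
    "select",
    "two_locus_gametes",
    "host_gamete_tables",
    "parasite_gamete_table",
    "host_gamete_pool",
    "parasite_gamete_pool",
    "random_mating",
    "step",
    "run",
    "inject_modifier",
    "TRACE_COLUMNS",
    "trace_frame",
]

TRACE_COLUMNS = (
    "host_A1",
    "host_B1",
    "host_M_invader",
    "parasite_A1",
    "parasite_B1",
    "wbar_host",
    "wbar_parasite",
)


class ExtinctionError(RuntimeError):
    """Raised when a population's mean fitness reaches zero."""


@dataclass
class PopulationState:
    """Zygote-frequency matrices over ordered haplotype pairs.

    ``host_z`` is 8x8 (4 AB haplotypes x 2 modifier slots), ``parasite_z``
    is 4x4.  Matrices are symmetric and sum to one.
    """

    host_z: np.ndarray
    parasite_z: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.host_z = np.asarray(self.host_z, dtype=float)
        self.parasite_z = np.asarray(self.parasite_z, dtype=float)
        if self.host_z.shape != (N_HOST_HAP, N_HOST_HAP):
            raise ValueError("host_z must be 8x8")
        if self.parasite_z.shape != (N_PAR_HAP, N_PAR_HAP):
            raise ValueError("parasite_z must be 4x4")

    def copy(self) -> "PopulationState":
        return PopulationState(self.host_z.copy(), self.parasite_z.copy(),
                               self.generation)

    def host_hap_freqs(self) -> np.ndarray:
        """Marginal host haplotype frequencies (length 8)."""
        return self.host_z.sum(axis=1)

    def parasite_hap_freqs(self) -> np.ndarray:
        return self.parasite_z.sum(axis=1)

    def invader_modifier_freq(self) -> float:
        """Frequency of the modifier allele in slot 1."""
        return float(self.host_hap_freqs()[4:].sum())

    def host_allele_freqs(self) -> Tuple[float, float]:
        """Frequencies of host alleles A1 and B1."""
        f = self.host_hap_freqs()
        ab = f[:4] + f[4:]
        return float(ab[0] + ab[1]), float(ab[0] + ab[2])

    def parasite_allele_freqs(self) -> Tuple[float, float]:
        f = self.parasite_hap_freqs()
        return float(f[0] + f[1]), float(f[0] + f[2])


def initial_state(perturbation: float = 0.01) -> PopulationState:
    """Linkage-equilibrium start with allele frequencies 0.5 at all loci.

    The resident modifier allele (slot 0) is fixed.  A small deterministic
    excess ``perturbation`` is added to the A1B1 haplotype of both species
    (then renormalized) to move the system off the symmetric unstable
    equilibrium while keeping runs exactly reproducible.
    """
    hap = np.full(N_AB, 0.25)
    hap[0] += perturbation
    hap /= hap.sum()
    host = np.zeros(N_HOST_HAP)
    host[:4] = hap
    return PopulationState(np.outer(host, host), np.outer(hap, hap))


# ---------------------------------------------------------------------------
# elementary operations (reference path)
# ---------------------------------------------------------------------------

def select(z: np.ndarray, w: np.ndarray) -> Tuple[np.ndarray, float]:
    """Viability selection: ``a = z * W / Wbar``; returns ``(a, Wbar)``."""
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    wbar = float((z * w).sum())
    if wbar <= 0.0:
        raise ExtinctionError("mean fitness is zero: all classes lethal")
    return z * w / wbar, wbar


def two_locus_gametes(hap1, hap2, r: float) -> np.ndarray:
    """Gamete distribution of one A--B genotype at recombination rate r.

    ``hap1``/``hap2`` are ``(a, b)`` tuples with allele labels 1/2.
    Parental gametes each have probability ``(1-r)/2``, recombinant ones
    ``r/2``; coinciding gamete types accumulate, so homozygous loci give
    degenerate distributions.  Returns a length-4 vector over AB haplotype
    indices.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction must lie in [0, 0.5], got {r}")
    (a1, b1), (a2, b2) = hap1, hap2
    for allele in (a1, b1, a2, b2):
        if allele not in (1, 2):
            raise ValueError(f"allele labels must be 1 or 2, got {allele!r}")
    out = np.zeros(N_AB)
    parental1 = 2 * (a1 - 1) + (b1 - 1)
    parental2 = 2 * (a2 - 1) + (b2 - 1)
    recomb1 = 2 * (a1 - 1) + (b2 - 1)
    recomb2 = 2 * (a2 - 1) + (b1 - 1)
    out[parental1] += (1.0 - r) / 2.0
    out[parental2] += (1.0 - r) / 2.0
    out[recomb1] += r / 2.0
    out[recomb2] += r / 2.0
    return out


@lru_cache(maxsize=1)
def host_gamete_tables() -> Tuple[np.ndarray, np.ndarray]:
    """Host meiosis tables ``(G0, G1)`` with ``P(r) = G0 + r * G1``.

    Rows index the 64 ordered host genotypes, columns the 8 host gametes.
    The AB gamete distribution is linear in the recombination rate; the
    modifier allele is drawn equiprobably from the two parental modifier
    alleles, independently of the AB gamete (unlinked modifier).
    """
    g0 = np.zeros((64, 8))
    g1 = np.zeros((64, 8))
    for i in range(N_HOST_HAP):
        m1, ab1 = divmod(i, 4)
        a1, b1 = ab1 >> 1, ab1 & 1
        for j in range(N_HOST_HAP):
            m2, ab2 = divmod(j, 4)
            a2, b2 = ab2 >> 1, ab2 & 1
            t = N_HOST_HAP * i + j
            par1, par2 = 2 * a1 + b1, 2 * a2 + b2
            rec1, rec2 = 2 * a1 + b2, 2 * a2 + b1
            for m, pm in ((m1, 0.5), (m2, 0.5)):
                g0[t, 4 * m + par1] += pm * 0.5
                g0[t, 4 * m + par2] += pm * 0.5
                g1[t, 4 * m + par1] -= pm * 0.5
                g1[t, 4 * m + par2] -= pm * 0.5
                g1[t, 4 * m + rec1] += pm * 0.5
                g1[t, 4 * m + rec2] += pm * 0.5
    g0.setflags(write=False)
    g1.setflags(write=False)
    return g0, g1


@lru_cache(maxsize=None)
def parasite_gamete_table(r_p: float) -> np.ndarray:
    """16x4 meiosis table of the parasite at its fixed rate ``r_p``."""
    if not 0.0 <= r_p <= 0.5:
        raise ValueError(f"r_p must lie in [0, 0.5], got {r_p}")
    tab = np.zeros((16, 4))
    for i in range(N_PAR_HAP):
        a1, b1 = i >> 1, i & 1
        for j in range(N_PAR_HAP):
            a2, b2 = j >> 1, j & 1
            u = N_PAR_HAP * i + j
            tab[u, 2 * a1 + b1] += (1.0 - r_p) / 2.0
            tab[u, 2 * a2 + b2] += (1.0 - r_p) / 2.0
            tab[u, 2 * a1 + b2] += r_p / 2.0
            tab[u, 2 * a2 + b1] += r_p / 2.0
    tab.setflags(write=False)
    return tab


def host_gamete_pool(adults: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Host gamete pool given per-genotype effective recombination rates.

    ``rates`` is broadcast over the 64 ordered genotype classes; for
    strategies that split a class into infected/resistant sub-classes the
    caller supplies the selection-weighted mean rate (the meiosis table is
    linear in r, so the weighted mixture of gamete tables equals the table
    at the weighted-mean rate).
    """
    a = np.asarray(adults, dtype=float).reshape(-1)
    if a.shape != (64,):
        raise ValueError("adults must be an 8x8 matrix")
    r = np.broadcast_to(np.asarray(rates, dtype=float).reshape(-1), (64,))
    g0, g1 = host_gamete_tables()
    pool = a @ g0 + (a * r) @ g1
    return pool / pool.sum()


def parasite_gamete_pool(adults: np.ndarray, r_p: float) -> np.ndarray:
    a = np.asarray(adults, dtype=float).reshape(-1)
    pool = a @ parasite_gamete_table(r_p)
    return pool / pool.sum()


def random_mating(g: np.ndarray) -> np.ndarray:
    """Random union of gametes: the outer product of the pool with itself."""
    g = np.asarray(g, dtype=float)
    return np.outer(g, g)


def step(state: PopulationState, regime: Regime,
         strategies: Tuple[Strategy, Optional[Strategy]]) -> PopulationState:
    """One coupled generation (pure-numpy reference implementation).

    ``strategies`` is the (resident, invader) modifier allele pair; pass
    ``(resident, None)`` when the resident is fixed.
    """
    from .genotype_space import marginal_fitnesses

    resident, invader = strategies
    if invader is None:
        invader = resident
    w_h, w_p, _, _ = marginal_fitnesses(state.host_z, state.parasite_z, regime)
    a_h, _ = select(state.host_z, w_h)
    a_p, _ = select(state.parasite_z, w_p)
    rates = resolve_effective_rates(state.parasite_z, regime,
                                    (resident, invader))
    g_h = host_gamete_pool(a_h, rates)
    g_p = parasite_gamete_pool(a_p, regime.r_p)
    return PopulationState(random_mating(g_h), random_mating(g_p),
                           state.generation + 1)


# ---------------------------------------------------------------------------
# compiled fast path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Machine:
    pheno_h: np.ndarray
    pheno_p: np.ndarray
    mod_i: np.ndarray
    mod_j: np.ndarray
    g0: np.ndarray
    g1: np.ndarray
    pp: np.ndarray
    a1h: np.ndarray
    b1h: np.ndarray
    minv: np.ndarray
    a1p: np.ndarray
    b1p: np.ndarray


@lru_cache(maxsize=64)
def _machine(dominance: Dominance, r_p: float) -> _Machine:
    g0, g1 = host_gamete_tables()
    mod_i = np.repeat(np.arange(8) // 4, 8).astype(np.int64)
    mod_j = np.tile(np.arange(8) // 4, 8).astype(np.int64)
    hap_ab = np.arange(8) % 4
    return _Machine(
        pheno_h=host_phenotype_table(dominance),
        pheno_p=parasite_phenotype_table(dominance),
        mod_i=mod_i,
        mod_j=mod_j,
        g0=np.ascontiguousarray(g0),
        g1=np.ascontiguousarray(g1),
        pp=np.ascontiguousarray(parasite_gamete_table(r_p)),
        a1h=(hap_ab >> 1 == 0).astype(float),
        b1h=(hap_ab & 1 == 0).astype(float),
        minv=(np.arange(8) >= 4).astype(float),
        a1p=(np.arange(4) >> 1 == 0).astype(float),
        b1p=(np.arange(4) & 1 == 0).astype(float),
    )


def run(state: PopulationState, regime: Regime, resident: Strategy,
        invader: Optional[Strategy], n_generations: int,
        record: bool = True) -> Tuple[PopulationState, np.ndarray]:
    """Advance ``n_generations`` with the compiled kernel.

    Returns the final state and, when ``record``, an ``(n, 7)`` trace with
    columns :data:`TRACE_COLUMNS` holding the zygote-stage allele
    frequencies and the generation's mean fitnesses (row g describes the
    state after g generations).
    """
    if n_generations < 0:
        raise ValueError("n_generations must be nonnegative")
    m = _machine(Dominance(regime.dominance), regime.r_p)
    pair = (resident, invader if invader is not None else resident)
    form = np.array([s._form_code for s in pair], dtype=np.int64)
    lo = np.array([s.r_min for s in pair], dtype=float)
    hi = np.array([s.r_max for s in pair], dtype=float)
    hz = state.host_z.reshape(-1).copy()
    pz = state.parasite_z.reshape(-1).copy()
    trace = np.empty((n_generations if record else 0, _kernel.N_TRACE))
    status = _kernel.run_generations(
        hz, pz, n_generations, regime.s_h, regime.s_p,
        m.pheno_h, m.pheno_p, m.mod_i, m.mod_j, m.g0, m.g1, m.pp,
        form, lo, hi, m.a1h, m.b1h, m.minv, m.a1p, m.b1p, trace)
    if status != 0:
        raise ExtinctionError(
            f"population extinct under regime {regime} (mean fitness 0)")
    out = PopulationState(hz.reshape(8, 8), pz.reshape(4, 4),
                          state.generation + n_generations)
    return out, trace


def trace_frame(trace: np.ndarray, start_generation: int = 0) -> pd.DataFrame:
    """Trace array as a long-format table (generation, variable, value)."""
    wide = pd.DataFrame(trace, columns=list(TRACE_COLUMNS))
    wide.insert(0, "generation", np.arange(len(wide)) + start_generation)
    long = wide.melt(id_vars="generation", var_name="variable",
                     value_name="value")
    species = long["variable"].map(
        lambda v: "parasite" if v.startswith("parasite") or v.endswith("parasite")
        else "host")
    long.insert(1, "species", species)
    return long.sort_values(["generation", "variable"], kind="stable",
                            ignore_index=True)


def inject_modifier(state: PopulationState, freq: float = 0.05) -> PopulationState:
    """Introduce the invader modifier allele at frequency ``freq``.

    The invader enters at Hardy--Weinberg proportions at the modifier locus
    and in linkage equilibrium with both selected loci: the modifier allele
    on each haplotype is redrawn independently of its AB part, leaving the
    marginal AB genotype distribution untouched.  Requires the resident
    (slot 0) to be fixed.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError("injection frequency must lie in (0, 1)")
    if state.invader_modifier_freq() > 1e-12:
        raise ValueError("invader slot already occupied; resident must be fixed")
    z = state.host_z
    z_ab = (z[:4, :4] + z[:4, 4:] + z[4:, :4] + z[4:, 4:])
    mu = np.array([1.0 - freq, freq])
    new = np.zeros_like(z)
    for m1 in range(2):
        for m2 in range(2):
            new[4 * m1:4 * m1 + 4, 4 * m2:4 * m2 + 4] = z_ab * (mu[m1] * mu[m2])
    return PopulationState(new, state.parasite_z.copy(), state.generation)
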