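"""Modifier-allele recombination strategies and their per-class resolution.

A modifier allele confers one of three policies for the host recombination
rate between the selected loci:

* ``constant`` -- one rate r, independent of the parasite;
* ``prevention`` -- risk-proportional, pre-encounter plasticity:
  ``r = r_min + p * (r_max - r_min)`` with ``p`` the frequency of the
  parasite class dangerous exactly for this host class;
* ``remediation`` -- status-conditional, post-encounter plasticity:
  infected hosts recombine at ``r_max``, resistant ones at ``r_min``.

Any pair of modifier alleles interacts purely co-dominantly: the genotype
rate is the arithmetic mean of the two allele rates in the same context.
Because infection is realized during maturation, a class carrying a
remediation allele splits into an infected sub-class (post-selection share
``p(1-s_h)/W``, rate evaluated with status=infected) and a resistant one
(share ``(1-p)/W``); the meiosis operator is linear in r, so the split is
equivalent to a single effective rate, the share-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Tuple

import numpy as np

from .genotype_space import (
    Dominance,
    Regime,
    host_phenotype_table,
    parasite_phenotype_table,
)

__all__ = [
    "Strategy",
    "PlasticityVariant",
    "plastic_strategy",
    "allele_rate",
    "genotype_rate",
    "resolve_policy",
    "resolve_effective_rates",
]

_FORM_CODES = {"constant": 0, "prevention": 1, "remediation": 2}


@dataclass(frozen=True)
class Strategy:
    """A modifier allele's recombination policy with its rate bounds."""

    form: str
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if self.form not in _FORM_CODES:
            raise ValueError(f"unknown strategy form {self.form!r}")
        if not 0.0 <= self.r_min <= self.r_max <= 0.5:
            raise ValueError(
                f"need 0 <= r_min <= r_max <= 0.5, got ({self.r_min}, {self.r_max})")
        if self.form == "constant" and self.r_min != self.r_max:
            raise ValueError("constant strategy has a single rate")

    @classmethod
    def constant(cls, r: float) -> "Strategy":
        return cls("constant", r, r)

    @classmethod
    def prevention(cls, r_min: float, r_max: float) -> "Strategy":
        return cls("prevention", r_min, r_max)

    @classmethod
    def remediation(cls, r_min: float, r_max: float) -> "Strategy":
        return cls("remediation", r_min, r_max)

    @property
    def r_const(self) -> float:
        if self.form != "constant":
            raise AttributeError("r_const is defined for constant strategies only")
        return self.r_min

    @property
    def _form_code(self) -> int:
        return _FORM_CODES[self.form]

    def to_dict(self) -> dict:
        if self.form == "constant":
            return {"form": "constant", "r_const": self.r_min}
        return {"form": self.form, "r_min": self.r_min, "r_max": self.r_max}

    @classmethod
    def from_dict(cls, d: dict) -> "Strategy":
        d = dict(d)
        form = d.pop("form")
        if form == "constant":
            r = d.pop("r_const")
            strategy = cls.constant(r)
        else:
            strategy = cls(form, d.pop("r_min"), d.pop("r_max"))
        if d:
            raise ValueError(f"unknown strategy keys {sorted(d)}")
        return strategy

    def label(self) -> str:
        if self.form == "constant":
            return f"constant({self.r_min:g})"
        return f"{self.form}({self.r_min:g},{self.r_max:g})"


class PlasticityVariant(str, Enum):
    """Range placement of a plastic strategy around a reference optimum."""

    FRINGE = "fringe"   # [r_opt - dr, r_opt + dr]; [0, dr] when r_opt = 0
    BELOW = "below"     # [r_opt - dr, r_opt]
    ABOVE = "above"     # [r_opt, r_opt + dr]


def plastic_strategy(form: str, r_opt: float, dr: float,
                     variant: PlasticityVariant = PlasticityVariant.FRINGE,
                     ) -> Strategy:
    """Plastic strategy whose range is placed around a reference optimum.

    The fringe variant spans ``[r_opt - dr, r_opt + dr]`` (``[0, dr]`` when
    the optimum is zero); the one-sided variants span only below or only
    above the optimum.  Bounds are clipped to the biological range [0, 0.5].
    """
    variant = PlasticityVariant(variant)
    if dr < 0:
        raise ValueError("plasticity magnitude must be nonnegative")
    if variant is PlasticityVariant.FRINGE:
        lo, hi = (0.0, dr) if r_opt == 0.0 else (r_opt - dr, r_opt + dr)
    elif variant is PlasticityVariant.BELOW:
        lo, hi = r_opt - dr, r_opt
    else:
        lo, hi = r_opt, r_opt + dr
    lo = min(max(lo, 0.0), 0.5)
    hi = min(max(hi, 0.0), 0.5)
    return Strategy(form, lo, hi)


def allele_rate(strategy: Strategy, p: Optional[float] = None,
                infected: Optional[bool] = None) -> float:
    """Recombination rate conferred by one allele in a given context.

    ``p`` is the class's danger frequency (required for prevention);
    ``infected`` is the realized infection status (required for
    remediation).
    """
    if strategy.form == "constant":
        return strategy.r_min
    if strategy.form == "prevention":
        if p is None:
            raise ValueError("prevention strategy requires the danger frequency p")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"danger frequency must lie in [0, 1], got {p}")
        return strategy.r_min + p * (strategy.r_max - strategy.r_min)
    if infected is None:
        raise ValueError("remediation strategy requires the infection status")
    return strategy.r_max if infected else strategy.r_min


def genotype_rate(allele1: Strategy, allele2: Strategy,
                  p: Optional[float] = None,
                  infected: Optional[bool] = None) -> float:
    """Co-dominant modifier interaction: the mean of the two allele rates."""
    return 0.5 * (allele_rate(allele1, p, infected)
                  + allele_rate(allele2, p, infected))


@dataclass(frozen=True)
class ClassPolicy:
    """Recombination policy of one host genotype class.

    ``sub_classes`` lists ``(weight, rate)`` pairs over the post-selection
    composition of the class (a single entry unless a remediation allele
    splits it); weights sum to one.  ``effective_rate`` is the weighted
    mean, which drives the (linear-in-r) meiosis operator.
    """

    sub_classes: Tuple[Tuple[float, float], ...]

    @property
    def effective_rate(self) -> float:
        return sum(w * r for w, r in self.sub_classes)


def resolve_policy(host_state, parasite_z, regime: Regime,
                   pair: Tuple[Strategy, Strategy]) -> List[ClassPolicy]:
    """Per-genotype recombination policy for all 64 ordered host classes.

    ``host_state`` is accepted for interface symmetry (the policy depends
    on the parasite state, the regime, and the modifier pair only; rates of
    absent host classes are still well defined).
    """
    del host_state
    scheme = Dominance(regime.dominance)
    pz = np.asarray(parasite_z, dtype=float).reshape(-1)
    if abs(pz.sum() - 1.0) > 1e-9:
        raise ValueError("parasite frequencies must sum to 1")
    fp = np.bincount(parasite_phenotype_table(scheme), weights=pz, minlength=4)
    pheno_h = host_phenotype_table(scheme)
    policies: List[ClassPolicy] = []
    for t in range(64):
        alleles = (pair[(t // 8) // 4], pair[(t % 8) // 4])
        p = float(fp[pheno_h[t]])
        if any(s.form == "remediation" for s in alleles):
            w_class = 1.0 - regime.s_h * p
            r_inf = genotype_rate(*alleles, p=p, infected=True)
            r_res = genotype_rate(*alleles, p=p, infected=False)
            if w_class <= 0.0 or r_inf == r_res:
                # class removed by selection, or degenerate plastic range
                policies.append(ClassPolicy(((1.0, r_res),)))
                continue
            w_inf = p * (1.0 - regime.s_h) / w_class
            subs = []
            if w_inf > 0.0:
                subs.append((w_inf, r_inf))
            if 1.0 - w_inf > 0.0:
                subs.append((1.0 - w_inf, r_res))
            policies.append(ClassPolicy(tuple(subs)))
        else:
            policies.append(ClassPolicy(((1.0, genotype_rate(*alleles, p=p,
                                                             infected=False)),)))
    return policies


def resolve_effective_rates(parasite_z, regime: Regime,
                            pair: Tuple[Strategy, Strategy]) -> np.ndarray:
    """Length-64 effective recombination rate vector (see ClassPolicy)."""
    policies = resolve_policy(None, parasite_z, regime, pair)
    return np.array([pol.effective_rate for pol in policies])
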