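"""The full experimental pipeline of the modifier analysis.

Strategies are compared by the modifier approach: the system evolves for a
burn-in period with the resident modifier allele fixed, the competing
allele is injected at low frequency in Hardy--Weinberg and linkage
equilibrium, and its fate is followed over an additional horizon.  A
strategy is favored if its allele invades the other's population while the
reciprocal invasion fails; reciprocal success means a protected
polymorphism and partial advantage for both.

On top of that primitive sit the two-sided search for the optimal constant
host recombination rate (climbing from 0 upward and from 0.5 downward,
refined over five passes down to a 0.001 grid), the plasticity tests
(prevention/remediation strategies spanning a fringe around the optimum,
plus the one-sided below/above variants of the two-reference test), regime
sweeps, the Table-style standardized regressions, and an oscillation-period
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.signal import find_peaks

from .genotype_space import Dominance, Regime
from .lifecycle import (
    ExtinctionError,
    PopulationState,
    initial_state,
    inject_modifier,
    run,
)
from .strategies import PlasticityVariant, Strategy, plastic_strategy

__all__ = [
    "ExperimentConfig",
    "InvasionOutcome",
    "InvasionResult",
    "Verdict",
    "CompetitionOutcome",
    "OptSearchResult",
    "Runner",
    "burn_in",
    "inject_modifier",
    "invasion_test",
    "compete",
    "find_optimal_constant_rate",
    "test_plasticity",
    "PlasticityVerdict",
    "sample_regimes",
    "obligate_scan",
    "sweep",
    "verdict_columns",
    "favoring_mask",
    "two_reference_pass",
    "magnitude_counts",
    "fit_relative_effects",
    "RegressionResult",
    "estimate_period",
]

# The step schedule: the initial coarse pass plus four refinements, each
# restarting within the previous bracket, terminating on a 0.001 grid.
DEFAULT_STEPS = (0.05, 0.02, 0.008, 0.003, 0.001)
DEFAULT_DR_SET = (0.001, 0.0025, 0.005, 0.01)


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables of the experimental design (defaults per the study).

    burn_in / horizon: generations before injection / after injection.
    injection: invader modifier frequency at injection.
    delta: half-width of the neutrality band around the injection
        frequency when classifying the tail-mean invader frequency.
        Selection on the modifier is indirect and second-order, so the
        frequency displacement after the horizon is tiny (~1e-5 for rate
        differences of 0.001 under strong selection, down to ~1e-8 under
        weak selection); the band only needs to absorb floating-point
        drift (~1e-12), hence the near-sign-test default.
    window: number of final generations averaged for that classification.
    freeze_tol: below this absolute deviation the invader is considered
        bit-frozen at the injection frequency.  One frozen direction marks
        a definitive failure to spread (degenerate resident dynamics);
        both directions frozen mark exact neutrality (inconclusive).
    steps: step schedule of the five-pass optimal-rate search (fractions).
    eps: regularity threshold on the gap between the two search series.
    dr_set: plasticity magnitudes tested.
    perturbation: deterministic initial asymmetry on the A1B1 haplotype.
    """

    burn_in: int = 10_000
    horizon: int = 10_000
    injection: float = 0.05
    delta: float = 1e-9
    window: int = 1_000
    steps: Tuple[float, ...] = DEFAULT_STEPS
    eps: float = 0.001
    dr_set: Tuple[float, ...] = DEFAULT_DR_SET
    perturbation: float = 0.01
    freeze_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.horizon <= 0:
            raise ValueError("burn_in must be >= 0 and horizon > 0")
        if not 0.0 < self.injection < 0.5:
            raise ValueError("injection frequency must lie in (0, 0.5)")
        if not 0 < self.window <= self.horizon:
            raise ValueError("window must lie in (0, horizon]")


class InvasionOutcome(str, Enum):
    SPREADS = "spreads"
    FAILS = "fails"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class InvasionResult:
    outcome: InvasionOutcome
    tail_mean: float          # invader frequency averaged over the window
    resident: Strategy
    invader: Strategy
    frozen: bool = False      # bit-level stasis at the injection frequency


class Verdict(str, Enum):
    S1_FAVORED = "S1_favored"
    S2_FAVORED = "S2_favored"
    POLYMORPHISM = "polymorphism"
    NEUTRAL = "neutral"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class CompetitionOutcome:
    """Result of the reciprocal invasion test between S1 and S2."""

    verdict: Verdict
    s2_into_s1: InvasionResult
    s1_into_s2: InvasionResult


@dataclass(frozen=True)
class OptSearchResult:
    """Lower/upper estimates of the optimal constant host recombination rate.

    ``regular`` marks a cleanly converged search with gap <= eps;
    ``bistable`` marks a clean search whose two series settled on two
    distinct local optima (gap beyond the terminal step), recorded as
    ``lower_optimum``/``upper_optimum``.  Downstream plasticity tests use
    the upper optimum, exposed as :attr:`r_opt`.
    """

    lower_estimate: float
    upper_estimate: float
    eps: float
    regular: bool
    bistable: bool
    lower_optimum: Optional[float] = None
    upper_optimum: Optional[float] = None
    failure: Optional[str] = None

    @property
    def usable(self) -> bool:
        """Regime enters further analysis (regular, or bistable with a
        well-located upper optimum)."""
        return self.regular or self.bistable

    @property
    def r_opt(self) -> Optional[float]:
        if not self.usable:
            return None
        return self.upper_optimum if self.bistable else self.upper_estimate


class PlasticityVerdict(str, Enum):
    FAVORED_TOTALLY = "favored_totally"
    FAVORED_PARTIALLY = "favored_partially"
    NOT_FAVORED = "not_favored"
    INCONCLUSIVE = "inconclusive"


_FAVORING = {PlasticityVerdict.FAVORED_TOTALLY.value,
             PlasticityVerdict.FAVORED_PARTIALLY.value}


class Runner:
    """Caches burn-ins and competition outcomes for one regime.

    All dynamics are deterministic, so memoising states keyed by the exact
    resident strategy reproduces independent recomputation bit for bit.
    """

    def __init__(self, regime: Regime, config: Optional[ExperimentConfig] = None):
        self.regime = regime
        self.config = config or ExperimentConfig()
        self._burnins: Dict[Strategy, PopulationState] = {}
        self._competes: Dict[Tuple[Strategy, Strategy], CompetitionOutcome] = {}

    # -- primitives --------------------------------------------------------

    def burn_in(self, resident: Strategy,
                generations: Optional[int] = None) -> PopulationState:
        """State after evolving with the resident modifier allele fixed."""
        if generations is not None and generations != self.config.burn_in:
            state, _ = run(initial_state(self.config.perturbation),
                           self.regime, resident, None, generations,
                           record=False)
            return state
        if resident not in self._burnins:
            state, _ = run(initial_state(self.config.perturbation),
                           self.regime, resident, None, self.config.burn_in,
                           record=False)
            self._burnins[resident] = state
        return self._burnins[resident].copy()

    def invade(self, resident: Strategy, invader: Strategy) -> InvasionResult:
        """Inject ``invader`` into the resident's population and track it."""
        if invader == resident:
            raise ValueError("invader must differ from the resident strategy")
        cfg = self.config
        state = inject_modifier(self.burn_in(resident), cfg.injection)
        _, trace = run(state, self.regime, resident, invader, cfg.horizon)
        tail = float(trace[-cfg.window:, 2].mean())
        deviation = tail - cfg.injection
        frozen = abs(deviation) <= cfg.freeze_tol
        if deviation > cfg.delta:
            outcome = InvasionOutcome.SPREADS
        elif deviation < -cfg.delta:
            outcome = InvasionOutcome.FAILS
        else:
            outcome = InvasionOutcome.INCONCLUSIVE
        return InvasionResult(outcome, tail, resident, invader, frozen)

    def compete(self, s1: Strategy, s2: Strategy) -> CompetitionOutcome:
        """Reciprocal invasion test; deterministic verdict."""
        if s1 == s2:
            same = InvasionResult(InvasionOutcome.INCONCLUSIVE,
                                  self.config.injection, s1, s2)
            return CompetitionOutcome(Verdict.NEUTRAL, same, same)
        key = (s1, s2)
        if key not in self._competes:
            fwd = self.invade(s1, s2)   # S2 tries to invade S1's population
            rev = self.invade(s2, s1)   # and vice versa
            if fwd.frozen and rev.frozen:
                # exact neutrality (e.g. s_h = 0): genuinely undecidable
                verdict = Verdict.INCONCLUSIVE
            elif ((fwd.outcome is InvasionOutcome.INCONCLUSIVE
                   and not fwd.frozen)
                  or (rev.outcome is InvasionOutcome.INCONCLUSIVE
                      and not rev.frozen)):
                verdict = Verdict.INCONCLUSIVE
            elif fwd.frozen or rev.frozen:
                # a bit-frozen invader has definitively failed to spread
                # (degenerate resident dynamics, e.g. a no-recombination
                # resident whose haplotype diversity has collapsed)
                f_out = (InvasionOutcome.FAILS if fwd.frozen else fwd.outcome)
                r_out = (InvasionOutcome.FAILS if rev.frozen else rev.outcome)
                if f_out is InvasionOutcome.SPREADS:
                    verdict = Verdict.S2_FAVORED
                elif r_out is InvasionOutcome.SPREADS:
                    verdict = Verdict.S1_FAVORED
                else:
                    verdict = Verdict.NEUTRAL
            elif fwd.outcome is InvasionOutcome.SPREADS:
                verdict = (Verdict.POLYMORPHISM
                           if rev.outcome is InvasionOutcome.SPREADS
                           else Verdict.S2_FAVORED)
            elif rev.outcome is InvasionOutcome.SPREADS:
                verdict = Verdict.S1_FAVORED
            else:
                verdict = Verdict.NEUTRAL
            self._competes[key] = CompetitionOutcome(verdict, fwd, rev)
        return self._competes[key]

    # -- optimal constant rate search --------------------------------------

    def _climb(self, start_milli: int, step_milli: int, upward: bool,
               ) -> Tuple[int, bool]:
        """Advance one series on an integer milli-rate grid.

        The series moves toward the optimum until the incumbent rate
        *strictly* wins the reciprocal test against the moving rate; it
        walks through coexistence (polymorphism) bands and neutral
        stretches, since the sought optimum is a rate favored over both
        lower and higher rates.  Returns (stop point, ok); ok is False
        when a comparison came out inconclusive, which voids the search.
        """
        c = start_milli
        while True:
            n = c + step_milli if upward else c - step_milli
            if n < 0 or n > 500:
                return c, True
            lo, hi = (c, n) if upward else (n, c)
            out = self.compete(Strategy.constant(lo / 1000.0),
                               Strategy.constant(hi / 1000.0))
            if out.verdict is Verdict.INCONCLUSIVE:
                return c, False
            incumbent_wins = (Verdict.S1_FAVORED if upward
                              else Verdict.S2_FAVORED)
            if out.verdict is incumbent_wins:
                return c, True
            c = n

    def _series(self, upward: bool, steps_milli: Sequence[int],
                ) -> Tuple[int, bool]:
        c = 0 if upward else 500
        prev = None
        for s in steps_milli:
            if prev is not None:
                # restart within the previous bracket (one old step back)
                c = max(c - prev, 0) if upward else min(c + prev, 500)
            c, ok = self._climb(c, s, upward)
            if not ok:
                return c, False
            prev = s
        return c, True

    def find_optimal_constant_rate(self) -> OptSearchResult:
        steps_milli = [int(round(s * 1000)) for s in self.config.steps]
        if any(abs(m - s * 1000) > 1e-6 or m < 1 for m, s in
               zip(steps_milli, self.config.steps)):
            raise ValueError("search steps must be positive multiples of 0.001")
        try:
            low, ok_up = self._series(True, steps_milli)
            if ok_up:
                high, ok_down = self._series(False, steps_milli)
            else:
                high, ok_down = 500, False
        except ExtinctionError as exc:
            return OptSearchResult(0.0, 0.5, 0.5, False, False,
                                   failure=str(exc))
        # the upward and downward endpoints may cross by one terminal step
        # (each overshoots into the optimum's coexistence band); report the
        # estimates sorted
        lo_m, hi_m = min(low, high), max(low, high)
        lower, upper = lo_m / 1000.0, hi_m / 1000.0
        gap_milli = high - low          # exact on the integer rate grid
        eps = abs(gap_milli) / 1000.0
        if not (ok_up and ok_down):
            return OptSearchResult(lower, upper, eps, False, False,
                                   failure="inconclusive comparison chain")
        regular = abs(gap_milli) <= int(round(self.config.eps * 1000))
        bistable = False
        failure = None
        if not regular:
            if gap_milli > 0 and (self._confirm_local_optimum(lo_m, steps_milli[-1])
                                  and self._confirm_local_optimum(hi_m, steps_milli[-1])):
                # two genuine local optima: the series bracketed different
                # hills; downstream analysis uses the upper one
                bistable = True
            else:
                failure = "series diverged without two confirmed local optima"
        return OptSearchResult(
            lower, upper, eps, regular, bistable,
            lower_optimum=lower if bistable else None,
            upper_optimum=upper if bistable else None,
            failure=failure)

    def _confirm_local_optimum(self, c_milli: int, step_milli: int) -> bool:
        """No strict improvement one terminal step to either side of c."""
        if c_milli - step_milli >= 0:
            below = self.compete(
                Strategy.constant((c_milli - step_milli) / 1000.0),
                Strategy.constant(c_milli / 1000.0))
            if below.verdict in (Verdict.S1_FAVORED, Verdict.INCONCLUSIVE):
                return False
        if c_milli + step_milli <= 500:
            above = self.compete(
                Strategy.constant(c_milli / 1000.0),
                Strategy.constant((c_milli + step_milli) / 1000.0))
            if above.verdict in (Verdict.S2_FAVORED, Verdict.INCONCLUSIVE):
                return False
        return True

    # -- plasticity tests ---------------------------------------------------

    def test_plasticity(self, r_opt: float, dr: float, form: str,
                        variant: PlasticityVariant = PlasticityVariant.FRINGE,
                        ) -> PlasticityVerdict:
        """Is the plastic strategy favored over constant(r_opt)?"""
        plastic = plastic_strategy(form, r_opt, dr, variant)
        reference = Strategy.constant(r_opt)
        if plastic.r_min == plastic.r_max == r_opt:
            return PlasticityVerdict.NOT_FAVORED  # degenerate: exactly neutral
        out = self.compete(reference, plastic)
        if out.verdict is Verdict.S2_FAVORED:
            return PlasticityVerdict.FAVORED_TOTALLY
        if out.verdict is Verdict.POLYMORPHISM:
            return PlasticityVerdict.FAVORED_PARTIALLY
        if out.verdict is Verdict.INCONCLUSIVE:
            return PlasticityVerdict.INCONCLUSIVE
        return PlasticityVerdict.NOT_FAVORED


# -- module-level convenience wrappers (one-shot, no shared cache) ----------

def burn_in(regime: Regime, resident: Strategy, generations: int = 10_000,
            config: Optional[ExperimentConfig] = None) -> PopulationState:
    cfg = config or ExperimentConfig()
    return Runner(regime, cfg).burn_in(resident, generations)


def invasion_test(regime: Regime, resident: Strategy, invader: Strategy,
                  config: Optional[ExperimentConfig] = None) -> InvasionResult:
    return Runner(regime, config).invade(resident, invader)


def compete(regime: Regime, s1: Strategy, s2: Strategy,
            config: Optional[ExperimentConfig] = None) -> CompetitionOutcome:
    return Runner(regime, config).compete(s1, s2)


def find_optimal_constant_rate(regime: Regime,
                               config: Optional[ExperimentConfig] = None,
                               ) -> OptSearchResult:
    return Runner(regime, config).find_optimal_constant_rate()


def test_plasticity(regime: Regime, r_opt: float, dr: float, form: str,
                    variant: PlasticityVariant = PlasticityVariant.FRINGE,
                    config: Optional[ExperimentConfig] = None,
                    ) -> PlasticityVerdict:
    return Runner(regime, config).test_plasticity(r_opt, dr, form, variant)


# ---------------------------------------------------------------------------
# regime sweeps
# ---------------------------------------------------------------------------

FORMS = ("prevention", "remediation")


def sample_regimes(n: int, seed: int, dominance_set: Sequence[Dominance] = (
        Dominance.IN_PHASE, Dominance.ANTI_PHASE),
        s_p: Optional[float] = None,
        max_overall: Optional[float] = None) -> List[Regime]:
    """Seeded random regimes: s_h, s_p ~ U(0,1), r_p ~ U(0, 0.5).

    ``s_p`` fixes the parasite selection intensity (e.g. 1.0 for obligate
    parasitism); ``max_overall`` restricts sampling to overall selection
    ``s_h * s_p`` below the bound (rejection sampling), used to study the
    weak-selection region where constant recombination is rejected.
    Each sampled parameter triple is applied to every dominance scheme.
    """
    if n < 1:
        raise ValueError("need n >= 1 regimes")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5eed]))
    regimes: List[Regime] = []
    for _ in range(n):
        while True:
            sh = rng.uniform(0.0, 1.0)
            sp = s_p if s_p is not None else rng.uniform(0.0, 1.0)
            if max_overall is None or sh * sp < max_overall:
                break
        rp = rng.uniform(0.0, 0.5)
        for dom in dominance_set:
            regimes.append(Regime(sh, sp, rp, Dominance(dom)))
    return regimes


def obligate_scan(s_h_values: Sequence[float], r_p_values: Sequence[float],
                  dominance: Dominance = Dominance.ANTI_PHASE,
                  config: Optional[ExperimentConfig] = None) -> pd.DataFrame:
    """Optimal-rate estimates over an s_h x r_p grid at s_p = 1.

    The obligate-parasitism scan: a parasite failing to infect has zero
    fitness.  Returns one row per grid point with the lower/upper
    estimates and flags of the search (grid density is the caller's
    choice).
    """
    cfg = config or ExperimentConfig()
    rows = []
    for s_h in s_h_values:
        for r_p in r_p_values:
            regime = Regime(float(s_h), 1.0, float(r_p), Dominance(dominance))
            res = Runner(regime, cfg).find_optimal_constant_rate()
            rows.append({
                "s_h": float(s_h), "r_p": float(r_p),
                "dominance": Dominance(dominance).value,
                "lower_estimate": res.lower_estimate,
                "upper_estimate": res.upper_estimate,
                "eps": res.eps, "regular": res.regular,
                "bistable": res.bistable, "usable": res.usable,
                "r_opt": res.r_opt if res.usable else np.nan,
                "failure": res.failure or "",
            })
    return pd.DataFrame(rows)


def verdict_columns(dr_set: Sequence[float] = DEFAULT_DR_SET,
                    forms: Sequence[str] = FORMS,
                    variants: Sequence[PlasticityVariant] = tuple(PlasticityVariant),
                    ) -> List[str]:
    return [f"{form}_{PlasticityVariant(v).value}_{dr:g}"
            for form in forms for v in variants for dr in dr_set]


def _analyze_regime(regime: Regime, config: ExperimentConfig,
                    forms: Sequence[str], dr_set: Sequence[float]) -> dict:
    rec: dict = {
        "s_h": regime.s_h, "s_p": regime.s_p, "r_p": regime.r_p,
        "dominance": Dominance(regime.dominance).value,
        "regular": False, "bistable": False, "usable": False,
        "lower_estimate": np.nan, "upper_estimate": np.nan,
        "eps": np.nan, "r_opt": np.nan, "failure": "",
    }
    for col in verdict_columns(dr_set, forms):
        rec[col] = ""
    runner = Runner(regime, config)
    try:
        res = runner.find_optimal_constant_rate()
    except ExtinctionError as exc:   # pragma: no cover - defensive
        rec["failure"] = str(exc)
        return rec
    rec.update(regular=res.regular, bistable=res.bistable, usable=res.usable,
               lower_estimate=res.lower_estimate,
               upper_estimate=res.upper_estimate, eps=res.eps,
               failure=res.failure or "")
    if not res.usable:
        return rec
    r_opt = res.r_opt
    rec["r_opt"] = r_opt
    for form in forms:
        for dr in dr_set:
            try:
                fringe = runner.test_plasticity(r_opt, dr, form,
                                                PlasticityVariant.FRINGE)
            except ExtinctionError as exc:
                rec["failure"] = str(exc)
                continue
            rec[f"{form}_fringe_{dr:g}"] = fringe.value
            # the one-sided two-reference variants matter only where the
            # fringe strategy is favored (and are meaningless at r_opt = 0)
            if fringe.value in _FAVORING and r_opt > 0.0:
                for variant in (PlasticityVariant.BELOW, PlasticityVariant.ABOVE):
                    v = runner.test_plasticity(r_opt, dr, form, variant)
                    rec[f"{form}_{variant.value}_{dr:g}"] = v.value
    return rec


def sweep(regimes: Iterable[Regime],
          config: Optional[ExperimentConfig] = None,
          forms: Sequence[str] = FORMS,
          dr_set: Optional[Sequence[float]] = None,
          progress: bool = False) -> pd.DataFrame:
    """Full outcome table, one row per regime.

    Individual regime failures (extinction, inconclusive searches) are
    recorded in the ``failure`` column and never abort the sweep.  With
    identical regimes and config the output is byte-identical across runs.
    """
    cfg = config or ExperimentConfig()
    drs = tuple(dr_set if dr_set is not None else cfg.dr_set)
    rows = []
    for i, regime in enumerate(regimes):
        rows.append(_analyze_regime(regime, cfg, forms, drs))
        if progress and (i + 1) % 10 == 0:   # pragma: no cover
            print(f"  {i + 1} regimes done", flush=True)
    return pd.DataFrame(rows)


# -- sweep summaries --------------------------------------------------------

def favoring_mask(df: pd.DataFrame,
                  forms: Sequence[str] = FORMS,
                  dr_set: Optional[Sequence[float]] = None,
                  variant: PlasticityVariant = PlasticityVariant.FRINGE,
                  ) -> pd.Series:
    """Rows where any (form, magnitude) plastic strategy is favored,
    totally or partially."""
    drs = dr_set if dr_set is not None else _dr_values(df, forms, variant)
    cols = [f"{form}_{variant.value}_{dr:g}" for form in forms for dr in drs
            if f"{form}_{variant.value}_{dr:g}" in df.columns]
    return df[cols].isin(_FAVORING).any(axis=1)


def _dr_values(df: pd.DataFrame, forms, variant) -> List[float]:
    prefix = f"{forms[0]}_{variant.value}_"
    return [float(c[len(prefix):]) for c in df.columns if c.startswith(prefix)]


def two_reference_pass(df: pd.DataFrame,
                       forms: Sequence[str] = FORMS,
                       dr_set: Optional[Sequence[float]] = None) -> pd.Series:
    """Regimes where some favored fringe strategy also has both one-sided
    variants favored (the strict test isolating plasticity per se)."""
    drs = dr_set if dr_set is not None else _dr_values(
        df, forms, PlasticityVariant.FRINGE)
    passed = pd.Series(False, index=df.index)
    for form in forms:
        for dr in drs:
            f = df.get(f"{form}_fringe_{dr:g}")
            b = df.get(f"{form}_below_{dr:g}")
            a = df.get(f"{form}_above_{dr:g}")
            if f is None or b is None or a is None:
                continue
            passed |= (f.isin(_FAVORING) & b.isin(_FAVORING)
                       & a.isin(_FAVORING))
    return passed


def magnitude_counts(df: pd.DataFrame,
                     forms: Sequence[str] = FORMS,
                     dr_set: Optional[Sequence[float]] = None) -> pd.Series:
    """Count of regimes favoring plastic recombination, per magnitude."""
    drs = dr_set if dr_set is not None else _dr_values(
        df, forms, PlasticityVariant.FRINGE)
    counts = {}
    for dr in drs:
        cols = [f"{form}_fringe_{dr:g}" for form in forms
                if f"{form}_fringe_{dr:g}" in df.columns]
        counts[dr] = int(df[cols].isin(_FAVORING).any(axis=1).sum())
    return pd.Series(counts).sort_index()


# ---------------------------------------------------------------------------
# standardized regressions (relative effects of the regime parameters)
# ---------------------------------------------------------------------------

_MODEL_PREDICTORS = {
    "A": ("s_h", "s_p", "r_p"),
    "B": ("r_p", "s_h*s_p"),
    "C": ("s_h", "s_p", "r_p", "s_h*s_p"),
}


@dataclass(frozen=True)
class RegressionResult:
    model: str
    coefficients: Dict[str, float]   # standardized betas
    r2_adjusted: float
    n: int


def fit_relative_effects(table: pd.DataFrame, model: str = "A",
                         response: str = "r_opt") -> RegressionResult:
    """OLS on z-score-standardized response and predictors.

    The caller restricts ``table`` to the regimes of interest (one
    dominance scheme, usable search, estimable optimum); rows with a
    missing response are dropped here.
    """
    if model not in _MODEL_PREDICTORS:
        raise ValueError(f"model must be one of {sorted(_MODEL_PREDICTORS)}")
    names = _MODEL_PREDICTORS[model]
    df = table.dropna(subset=[response]).copy()
    n = len(df)
    if n < len(names) + 2:
        raise ValueError(
            f"insufficient data: n={n} rows for {len(names)} predictors")
    df["s_h*s_p"] = df["s_h"] * df["s_p"]

    def z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {x.name!r} has zero variance")
        return (x - x.mean()) / sd

    y = z(df[response])
    x = sm.add_constant(pd.DataFrame({k: z(df[k]) for k in names}))
    fit = sm.OLS(y, x).fit()
    coefs = {k: float(fit.params[k]) for k in names}
    return RegressionResult(model, coefs, float(fit.rsquared_adj), n)


# ---------------------------------------------------------------------------
# oscillation diagnostics
# ---------------------------------------------------------------------------

def estimate_period(trajectory: np.ndarray, smooth_window: int = 5) -> float:
    """Mean peak-to-peak spacing of an allele-frequency trajectory.

    The series is lightly smoothed with a centered moving average, then
    strict local maxima are located; the period is the mean spacing between
    successive maxima, in generations.  Returns NaN with fewer than two
    peaks (e.g., a constant trajectory).
    """
    x = np.asarray(trajectory, dtype=float)
    if x.ndim != 1:
        raise ValueError("trajectory must be one-dimensional")
    if smooth_window > 1 and len(x) >= smooth_window:
        kernel = np.full(smooth_window, 1.0 / smooth_window)
        x = np.convolve(x, kernel, mode="valid")
    peaks, _ = find_peaks(x)
    if len(peaks) < 2:
        return float("nan")
    return float(np.diff(peaks).mean())
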