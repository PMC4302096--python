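"""Parameter containers: energy model, matching thresholds, traceback controls."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "NEG_INF",
    "is_neg_inf",
    "sadd",
    "EnergyModel",
    "Params",
    "TracebackControls",
    "ParameterError",
]

#: Finite sentinel for "forbidden" (-infinity) scores.  Kept finite so that
#: arithmetic never produces NaN; `sadd` saturates instead of underflowing.
NEG_INF = -1.0e18
_NEG_INF_GUARD = -1.0e17


def is_neg_inf(x: float) -> bool:
    return x <= _NEG_INF_GUARD


def sadd(*xs: float) -> float:
    """Saturating sum: any forbidden operand makes the result forbidden."""
    if any(is_neg_inf(x) for x in xs):
        return NEG_INF
    return sum(xs)


class ParameterError(ValueError):
    """Invalid parameter combination."""


# Default per-pair energies of the lightweight model, kcal/mol.
_DEFAULT_PAIR_ENERGY = {
    "AU": -2.0, "UA": -2.0,
    "CG": -3.0, "GC": -3.0,
    "GU": -1.0, "UG": -1.0,
}


@dataclass(frozen=True)
class EnergyModel:
    """Lightweight loop-decomposed RNA energy model.

    A structure's energy is the sum of per-pair energies, a stacking bonus
    for each directly stacked pair, and constant per-loop terms for
    hairpin, interior and multi-loops.  ``mode="uniform"`` gives every
    structure weight 1 (pure counting semantics); the Boltzmann weight is
    otherwise exp(-E / RT).
    """

    pair_energy: dict = field(default_factory=lambda: dict(_DEFAULT_PAIR_ENERGY))
    stack_bonus: float = -1.0
    hairpin_const: float = 0.0
    interior_const: float = 0.0
    multiloop_const: float = 0.0
    RT: float = 0.6163
    min_hairpin: int = 3
    mode: str = "weighted"

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise ParameterError("RT must be positive")
        if self.min_hairpin < 0:
            raise ParameterError("min_hairpin must be >= 0")
        if self.mode not in ("weighted", "uniform"):
            raise ParameterError(f"unknown energy-model mode {self.mode!r}")

    # Boltzmann factors ----------------------------------------------------
    def _bw(self, energy: float) -> float:
        if self.mode == "uniform":
            return 1.0
        import math

        return math.exp(-energy / self.RT)

    def w_pair(self, a: str, b: str) -> float:
        """Weight of forming pair (a, b); 0 if not complementary."""
        e = self.pair_energy.get(a + b)
        if e is None:
            return 0.0
        return self._bw(e)

    @property
    def w_stack(self) -> float:
        return self._bw(self.stack_bonus)

    @property
    def w_hairpin(self) -> float:
        return self._bw(self.hairpin_const)

    @property
    def w_interior(self) -> float:
        return self._bw(self.interior_const)

    @property
    def w_multi(self) -> float:
        return self._bw(self.multiloop_const)


@dataclass(frozen=True)
class TracebackControls:
    """Controls for EPM enumeration.

    strategy: "suboptimal" (rigorous band-limited enumeration) or
    "heuristic" (one optimal EPM per end match).
    """

    strategy: str = "suboptimal"
    max_score_diff: float = 0.0
    max_epms: int = 100
    min_epm_score: float = 3.0

    def __post_init__(self) -> None:
        if self.strategy not in ("suboptimal", "heuristic"):
            raise ParameterError(f"unknown traceback strategy {self.strategy!r}")
        if self.max_score_diff < 0:
            raise ParameterError("max_score_diff must be >= 0")
        if self.max_epms <= 0:
            raise ParameterError("max_epms must be positive")


@dataclass(frozen=True)
class Params:
    """Matching parameters: significance thresholds and score weights.

    theta1 bounds base-pair probabilities of matched pairs; theta2/theta3
    bound the joint in-loop probabilities of matched unpaired positions and
    base pairs.  alpha1/2/3 weight sequence, structure and stacking score
    contributions; str_mm penalizes a mismatched base-pair-match end
    (strict mode forces it to -infinity, forbidding all mismatches).
    """

    theta1: float = 0.01
    theta2: float = 0.01
    theta3: float = 0.01
    alpha1: float = 1.0
    alpha2: float = 5.0
    alpha3: float = 5.0
    str_mm: float = NEG_INF
    mode: str = "strict"
    traceback: TracebackControls = field(default_factory=TracebackControls)

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "theta3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        for name in ("alpha1", "alpha2", "alpha3"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.mode not in ("strict", "relaxed"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.mode == "strict":
            if not is_neg_inf(self.str_mm):
                raise ParameterError("strict mode forces str_mm = -infinity")
        else:
            if is_neg_inf(self.str_mm):
                raise ParameterError("relaxed mode needs a finite str_mm")
            if self.str_mm >= 0:
                raise ParameterError("str_mm must be negative")

    @staticmethod
    def relaxed(str_mm: float = -10.0, **kw) -> "Params":
        return Params(mode="relaxed", str_mm=str_mm, **kw)

    def with_controls(self, **kw) -> "Params":
        return replace(self, traceback=replace(self.traceback, **kw))
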