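"""Two-state phenotype-switching model and its closed-form relations.

A cell population in suspension is modelled as a mixture of an
anoikis-sensitive (AnS) state, which dies under detachment stress, and an
anoikis-resistant (AnR) state, which survives and proliferates with
doubling time ``T_d_susp``.  At each division in attached growth a daughter
cell may switch state: sensitive -> resistant with probability ``k_on``,
resistant -> sensitive with probability ``k_off``.

Closed-form relations implemented here:

* growth rate from doubling time, ``gamma = ln 2 / T_d``;
* the survival balance ``f * exp(gamma * T) = S_mean`` linking the
  resistant fraction ``f`` at the start of a suspension assay of duration
  ``T`` to the mean observed survival fraction;
* the map between resistant-state memory ``M`` (mean residence time in
  generations, geometric residence so ``k_off = 1/M``) plus equilibrium
  resistant fraction ``f_eq = k_on/(k_on+k_off)`` and the switching rates;
* the per-hour effective growth rate ``ln(N_t/N_0)/T`` of a clone in
  suspension;
* the sensitive/resistant classification rule (viability at 24 h below /
  at-or-above 100 % of plated cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal

__all__ = [
    "AnoikisClass",
    "SensitiveDeath",
    "SwitchingModel",
    "AssayProtocol",
    "InfeasibleParameterError",
    "growth_rate_from_doubling",
    "resistant_fraction_from_survival",
    "rates_from_memory_equilibrium",
    "memory_equilibrium_from_rates",
    "effective_growth_rate",
    "classify_anoikis",
]

NEG_INF = float("-inf")


class InfeasibleParameterError(ValueError):
    """A parameter combination violates the model's feasible range."""


class AnoikisClass(str, Enum):
    """Anoikis phenotype of a cell-line model, from 24-h suspension viability."""

    SENSITIVE = "sensitive"  # AnS: < 100 % viability at 24 h
    RESISTANT = "resistant"  # AnR: >= 100 % viability at 24 h


class SensitiveDeath(str, Enum):
    """Fate of sensitive cells during the suspension assay.

    ``ALL_DEAD_AT_T``: every sensitive cell is dead by the assay endpoint
    (the survival balance then attributes all survivors to the resistant
    state).  ``EXPONENTIAL``: sensitive cells die at a constant per-hour
    hazard ``delta``, so a fraction ``exp(-delta*T)`` remain.
    """

    ALL_DEAD_AT_T = "all_dead_at_T"
    EXPONENTIAL = "exponential"


def growth_rate_from_doubling(T_d: float) -> float:
    """Per-hour exponential growth rate from a doubling time in hours.

    gamma = ln 2 / T_d; an infinite doubling time means zero growth.

    Raises
    ------
    InfeasibleParameterError
        If ``T_d`` is not positive (a doubling time cannot be <= 0).
    """
    if math.isnan(T_d) or T_d <= 0:
        raise InfeasibleParameterError(f"doubling time must be > 0 h, got {T_d}")
    if math.isinf(T_d):
        return 0.0
    return math.log(2.0) / T_d


def resistant_fraction_from_survival(S_mean: float, T: float, T_d: float) -> float:
    """Resistant fraction ``f`` solving the survival balance f*e^(gamma*T) = S_mean.

    Parameters
    ----------
    S_mean : mean suspension survival fraction (may exceed 1 for net growth).
    T : assay duration, hours.
    T_d : resistant-state doubling time in suspension, hours (inf allowed).

    Returns
    -------
    float
        f = S_mean * 2^(-T/T_d), the fraction of plated cells that must have
        been in the resistant state for pure resistant-state growth to
        account for the observed mean survival.

    Raises
    ------
    InfeasibleParameterError
        If the implied fraction exceeds 1: the observed survival is larger
        than unrestricted resistant growth alone could produce, so no valid
        mixture fraction exists.  The value is reported, never clamped.
    """
    if S_mean <= 0:
        raise InfeasibleParameterError(f"mean survival must be > 0, got {S_mean}")
    if T <= 0:
        raise InfeasibleParameterError(f"assay duration must be > 0 h, got {T}")
    gamma = growth_rate_from_doubling(T_d)
    f = S_mean * math.exp(-gamma * T)
    if f > 1.0:
        raise InfeasibleParameterError(
            f"implied resistant fraction {f:.4f} > 1: survival {S_mean} at T={T} h "
            f"exceeds what pure resistant growth with T_d={T_d} h allows"
        )
    return f


def rates_from_memory_equilibrium(M: float, f_eq: float) -> tuple[float, float]:
    """Switching rates from memory (generations) and equilibrium resistant fraction.

    Memory is the mean residence time of the resistant state under geometric
    exit, ``M = 1/k_off`` generations; at switching equilibrium
    ``f_eq = k_on/(k_on+k_off)``, hence ``k_on = f_eq/(1-f_eq) * k_off``.

    Raises
    ------
    InfeasibleParameterError
        If ``f_eq = 1`` with finite ``M`` (no sensitive reservoir can sustain
        equilibrium), or if the implied ``k_on`` exceeds 1 (not a probability).
    """
    if M <= 0:
        raise InfeasibleParameterError(f"memory must be > 0 generations, got {M}")
    if not 0.0 <= f_eq <= 1.0:
        raise InfeasibleParameterError(f"equilibrium fraction must be in [0,1], got {f_eq}")
    if f_eq == 1.0:
        raise InfeasibleParameterError(
            "f_eq = 1 with finite memory is infeasible: no sensitive reservoir"
        )
    k_off = 1.0 / M
    if k_off > 1.0:
        raise InfeasibleParameterError(
            f"memory {M} < 1 generation implies k_off = {k_off:.3f} > 1"
        )
    k_on = f_eq / (1.0 - f_eq) * k_off
    if k_on > 1.0:
        raise InfeasibleParameterError(
            f"(M={M}, f_eq={f_eq}) implies k_on = {k_on:.3f} > 1"
        )
    return k_on, k_off


def memory_equilibrium_from_rates(k_on: float, k_off: float) -> tuple[float, float]:
    """Inverse of :func:`rates_from_memory_equilibrium`: (M, f_eq) from rates."""
    if not (0.0 <= k_on <= 1.0 and 0.0 <= k_off <= 1.0):
        raise InfeasibleParameterError("switching probabilities must be in [0,1]")
    if k_off == 0.0:
        raise InfeasibleParameterError("k_off = 0 implies infinite memory")
    M = 1.0 / k_off
    f_eq = k_on / (k_on + k_off)
    return M, f_eq


def effective_growth_rate(N0: float, Nt: float, T: float) -> float:
    """Effective per-hour growth rate ln(N_t/N_0)/T over a suspension window.

    Negative values indicate net death.  ``Nt = 0`` returns ``-inf`` (total
    clearance), which callers must treat as a distinct class, not a number to
    average.
    """
    if N0 <= 0:
        raise ValueError(f"initial count must be > 0, got {N0}")
    if Nt < 0:
        raise ValueError(f"final count must be >= 0, got {Nt}")
    if T <= 0:
        raise ValueError(f"window must be > 0 h, got {T}")
    if Nt == 0:
        return NEG_INF
    return math.log(Nt / N0) / T


def classify_anoikis(survival: float, threshold: float = 1.0) -> AnoikisClass:
    """Classify a model as anoikis sensitive or resistant from 24-h viability.

    Survival below ``threshold`` (default 1.0, i.e. 100 % of plated cells)
    is sensitive; at or above is resistant.
    """
    if survival < 0:
        raise ValueError(f"survival must be >= 0, got {survival}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    return AnoikisClass.SENSITIVE if survival < threshold else AnoikisClass.RESISTANT


@dataclass(frozen=True)
class SwitchingModel:
    """Parameters of the reversible two-state (AnS/AnR) switching model.

    Parameters
    ----------
    k_on : probability per generation that a daughter of a sensitive cell is
        born resistant.
    k_off : probability per generation that a daughter of a resistant cell is
        born sensitive.
    T_d_susp : doubling time of resistant cells in suspension, hours.
    T_d_2D : doubling time in attached (2D) growth, hours; used for the
        generation <-> hour conversion during expansion.
    sensitive_death : death law of sensitive cells in suspension.
    delta : per-hour death rate of sensitive cells, used only under the
        exponential death law.
    """

    k_on: float
    k_off: float
    T_d_susp: float = 100.0
    T_d_2D: float = 38.0
    sensitive_death: SensitiveDeath = SensitiveDeath.ALL_DEAD_AT_T
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_on <= 1.0 and 0.0 <= self.k_off <= 1.0):
            raise InfeasibleParameterError(
                f"switching probabilities must lie in [0,1]: k_on={self.k_on}, k_off={self.k_off}"
            )
        for name in ("T_d_susp", "T_d_2D"):
            if getattr(self, name) <= 0:
                raise InfeasibleParameterError(f"{name} must be > 0 h")
        if self.delta < 0:
            raise InfeasibleParameterError("delta must be >= 0 per hour")

    @classmethod
    def from_memory_equilibrium(
        cls,
        M: float,
        f_eq: float,
        *,
        T_d_susp: float = 100.0,
        T_d_2D: float = 38.0,
        sensitive_death: SensitiveDeath = SensitiveDeath.ALL_DEAD_AT_T,
        delta: float = 0.0,
    ) -> "SwitchingModel":
        """Build a model from resistant-state memory and equilibrium fraction."""
        k_on, k_off = rates_from_memory_equilibrium(M, f_eq)
        return cls(
            k_on=k_on,
            k_off=k_off,
            T_d_susp=T_d_susp,
            T_d_2D=T_d_2D,
            sensitive_death=sensitive_death,
            delta=delta,
        )

    @classmethod
    def from_survival_balance(
        cls,
        S_mean: float = 0.9,
        T: float = 24.0,
        *,
        M: float = 10.5,
        T_d_susp: float = 100.0,
        T_d_2D: float = 38.0,
    ) -> "SwitchingModel":
        """Default parameterization: f_eq from the survival balance, k_off = 1/M.

        With the defaults (mean survival 0.9 over 24 h, suspension doubling
        time 100 h, memory 10.5 generations) this is the parameterization
        under which the fluctuation protocol is simulated.
        """
        f_eq = resistant_fraction_from_survival(S_mean, T, T_d_susp)
        return cls.from_memory_equilibrium(M, f_eq, T_d_susp=T_d_susp, T_d_2D=T_d_2D)

    @property
    def gamma(self) -> float:
        """Resistant-state growth rate in suspension, per hour."""
        return growth_rate_from_doubling(self.T_d_susp)

    @property
    def f_eq(self) -> float:
        """Equilibrium resistant fraction k_on/(k_on+k_off); NaN if both rates 0."""
        s = self.k_on + self.k_off
        return self.k_on / s if s > 0 else float("nan")

    @property
    def memory(self) -> float:
        """Mean resistant-state residence time, generations (inf if k_off = 0)."""
        return 1.0 / self.k_off if self.k_off > 0 else float("inf")

    @property
    def relaxation_eigenvalue(self) -> float:
        """Per-generation autocorrelation of lineage state, 1 - k_on - k_off."""
        return 1.0 - self.k_on - self.k_off

    def to_dict(self) -> dict:
        return {
            "k_on": self.k_on,
            "k_off": self.k_off,
            "T_d_susp": self.T_d_susp,
            "T_d_2D": self.T_d_2D,
            "sensitive_death": self.sensitive_death.value,
            "delta": self.delta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SwitchingModel":
        d = dict(d)
        d["sensitive_death"] = SensitiveDeath(d.get("sensitive_death", "all_dead_at_T"))
        return cls(**d)


@dataclass(frozen=True)
class AssayProtocol:
    """The clone-expansion / suspension-assay schedule.

    Defaults follow the fluctuation experiment: single-cell clones expanded
    ``G = 20`` generations in attached growth, ``N0 = 250,000`` cells plated
    per suspension assay of ``T = 24`` hours, ``n_clones = 60``, with 100 %
    viability as the resistance threshold.
    """

    T: float = 24.0
    N0: int = 250_000
    G: int = 20
    n_clones: int = 60
    resistance_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InfeasibleParameterError("assay duration T must be > 0 h")
        if self.N0 < 1:
            raise InfeasibleParameterError("N0 must be >= 1 cell")
        if self.G < 0:
            raise InfeasibleParameterError("expansion generations G must be >= 0")
        if self.n_clones < 1:
            raise InfeasibleParameterError("n_clones must be >= 1")
        if self.resistance_threshold <= 0:
            raise InfeasibleParameterError("resistance threshold must be > 0")

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "N0": self.N0,
            "G": self.G,
            "n_clones": self.n_clones,
            "resistance_threshold": self.resistance_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayProtocol":
        return cls(**d)
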