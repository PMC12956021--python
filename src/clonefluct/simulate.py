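"""Monte Carlo simulation of the clonal fluctuation protocol.

The simulated protocol mirrors the experiment: a single founder cell is
expanded for ``G`` generations in attached culture (deterministic doubling;
each daughter independently switches phenotype at birth), ``N0`` cells are
plated into suspension, and survival is scored after ``T`` hours — sensitive
cells die, resistant cells grow as a Yule (pure-birth) process with rate
``gamma = ln2 / T_d_susp``.  Repeating this over many clones yields the
model-predicted distribution of per-clone survival fractions, whose
coefficient of variation (CV) is the quantity the fluctuation test compares
against observation.

Two expansion representations are provided:

* ``aggregate`` (default): the clone is propagated as counts
  ``(n_sensitive, n_resistant)`` with one binomial draw per parental state
  per generation.  Because daughters switch independently, this is exact in
  distribution and makes G = 20 (10^6 cells) and N0 = 250,000 cheap.
* ``exact``: an explicit per-cell state array, feasible only for small G;
  kept as an independent cross-check of the aggregate representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .state_model import (
    AssayProtocol,
    SensitiveDeath,
    SwitchingModel,
)

__all__ = [
    "Founder",
    "CloneState",
    "SimResult",
    "expected_resistant_fraction",
    "expand_clone",
    "suspension_assay",
    "fluctuation_experiment",
    "predicted_cv",
    "predicted_cv_grid",
]


class Founder(str, Enum):
    """Phenotype of the founding cell of a clone."""

    SENSITIVE = "sensitive"
    RESISTANT = "resistant"
    EQUILIBRIUM = "equilibrium"  # drawn Bernoulli(f_eq) per clone


@dataclass(frozen=True)
class CloneState:
    """Composition of one expanded clone."""

    n_sensitive: int
    n_resistant: int
    generation: int

    def __post_init__(self) -> None:
        if self.n_sensitive < 0 or self.n_resistant < 0:
            raise ValueError("cell counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_sensitive + self.n_resistant

    @property
    def resistant_fraction(self) -> float:
        return self.n_resistant / self.total if self.total else float("nan")


def expected_resistant_fraction(
    model: SwitchingModel, G: int, founder: Founder = Founder.EQUILIBRIUM
) -> float:
    """Expected resistant lineage probability after G generations.

    Follows the single-lineage Markov recursion
    ``m_{g+1} = m_g (1 - k_off) + (1 - m_g) k_on`` from the founder state
    (equilibrium founders start at ``f_eq`` and stay there).
    """
    if founder is Founder.EQUILIBRIUM:
        m = model.f_eq
    else:
        m = 1.0 if founder is Founder.RESISTANT else 0.0
    for _ in range(G):
        m = m * (1.0 - model.k_off) + (1.0 - m) * model.k_on
    return m


def _expand_counts(
    n_sens: np.ndarray,
    n_res: np.ndarray,
    model: SwitchingModel,
    G: int,
    rng: np.random.Generator,
    division_prob: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized aggregate-count expansion of many clones at once.

    Each generation every cell divides (or, under ``division_prob`` < 1,
    divides with that probability and otherwise persists unchanged); each
    daughter of a sensitive parent is resistant with probability ``k_on``,
    each daughter of a resistant parent sensitive with probability ``k_off``.
    Counts are int64; G = 20 tops out near 10^6 cells per clone.
    """
    n_sens = n_sens.astype(np.int64).copy()
    n_res = n_res.astype(np.int64).copy()
    for _ in range(G):
        if division_prob >= 1.0:
            div_s, div_r = n_sens, n_res
            keep_s = np.zeros_like(n_sens)
            keep_r = np.zeros_like(n_res)
        else:
            div_s = rng.binomial(n_sens, division_prob)
            div_r = rng.binomial(n_res, division_prob)
            keep_s = n_sens - div_s
            keep_r = n_res - div_r
        res_from_s = rng.binomial(2 * div_s, model.k_on)
        res_from_r = rng.binomial(2 * div_r, 1.0 - model.k_off)
        n_res = res_from_s + res_from_r + keep_r
        n_sens = (2 * div_s - res_from_s) + (2 * div_r - res_from_r) + keep_s
    return n_sens, n_res


def _expand_percell(
    founder_resistant: bool,
    model: SwitchingModel,
    G: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Explicit per-cell expansion of a single clone (exact mode, small G)."""
    if G > 22:
        raise ValueError(
            f"G={G} gives 2^{G} cells; per-cell exact mode is impractical — "
            "use mode='aggregate'"
        )
    states = np.array([founder_resistant], dtype=bool)
    for _ in range(G):
        parents = np.repeat(states, 2)
        switch_p = np.where(parents, model.k_off, model.k_on)
        flips = rng.random(parents.size) < switch_p
        states = parents ^ flips
    n_res = int(states.sum())
    return states.size - n_res, n_res


def expand_clone(
    model: SwitchingModel,
    G: int,
    founder: Founder | str = Founder.EQUILIBRIUM,
    rng: np.random.Generator | int | None = None,
    *,
    mode: str = "aggregate",
    division_prob: float = 1.0,
) -> CloneState:
    """Expand one founder cell for ``G`` generations with phenotype switching.

    Parameters
    ----------
    founder : founding-cell phenotype; ``equilibrium`` draws it Bernoulli(f_eq).
    mode : ``"aggregate"`` (binomial count propagation, exact in
        distribution, any G) or ``"exact"`` (per-cell array, small G only).
    division_prob : probability a cell divides in a given generation;
        1.0 (default) is deterministic doubling.
    """
    rng = np.random.default_rng(rng)
    founder = Founder(founder)
    if G < 0:
        raise ValueError("G must be >= 0")
    if founder is Founder.EQUILIBRIUM:
        f = model.f_eq
        if math.isnan(f):
            raise ValueError(
                "equilibrium founder undefined when k_on = k_off = 0; "
                "specify founder='sensitive' or 'resistant'"
            )
        founder_res = bool(rng.random() < f)
    else:
        founder_res = founder is Founder.RESISTANT

    if mode == "aggregate":
        ns, nr = _expand_counts(
            np.array([0 if founder_res else 1]),
            np.array([1 if founder_res else 0]),
            model,
            G,
            rng,
            division_prob,
        )
        return CloneState(int(ns[0]), int(nr[0]), G)
    if mode == "exact":
        if division_prob < 1.0:
            raise ValueError("stochastic division is only supported in aggregate mode")
        ns, nr = _expand_percell(founder_res, model, G, rng)
        return CloneState(ns, nr, G)
    raise ValueError(f"unknown mode {mode!r}; expected 'aggregate' or 'exact'")


def _assay_counts(
    n_sens: np.ndarray,
    n_res: np.ndarray,
    model: SwitchingModel,
    T: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized suspension assay: live cell count at time T per clone.

    Resistant cells follow a Yule process: a single founder leaves a
    geometric(p = e^(-gamma*T)) family, so the clone total is
    ``n_res + NegBin(n_res, p)``.  Sensitive cells leave zero survivors
    under the default death law, or Binomial(n_sens, e^(-delta*T)) under
    the exponential law.
    """
    gamma = model.gamma
    p = math.exp(-gamma * T)
    live_res = np.where(n_res > 0, n_res, 0).astype(np.int64)
    if gamma > 0:
        extra = np.zeros_like(live_res)
        pos = live_res > 0
        if pos.any():
            extra[pos] = rng.negative_binomial(live_res[pos], p)
        live_res = live_res + extra
    if model.sensitive_death is SensitiveDeath.EXPONENTIAL:
        live_sens = rng.binomial(n_sens, math.exp(-model.delta * T))
    else:
        live_sens = np.zeros_like(n_sens)
    return live_res + live_sens


def _apply_assay_switch(
    n_sens: np.ndarray, n_res: np.ndarray, model: SwitchingModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One switching step at plating (optional; off by default)."""
    res_from_s = rng.binomial(n_sens, model.k_on)
    stay_res = rng.binomial(n_res, 1.0 - model.k_off)
    new_res = res_from_s + stay_res
    new_sens = (n_sens - res_from_s) + (n_res - stay_res)
    return new_sens, new_res


def suspension_assay(
    model: SwitchingModel,
    plated: tuple[int, int],
    T: float = 24.0,
    rng: np.random.Generator | int | None = None,
    *,
    switch_in_assay: bool = False,
) -> float:
    """Survival fraction N_t / N_plated of one plated (n_S, n_R) mixture.

    Expectation under the default death law is
    ``(n_R / (n_S + n_R)) * e^(gamma*T)`` — the survival balance.
    """
    n_s, n_r = plated
    if n_s < 0 or n_r < 0 or n_s + n_r < 1:
        raise ValueError("plated counts must be >= 0 with at least one cell")
    rng = np.random.default_rng(rng)
    ns = np.array([n_s], dtype=np.int64)
    nr = np.array([n_r], dtype=np.int64)
    if switch_in_assay:
        ns, nr = _apply_assay_switch(ns, nr, model, rng)
    live = _assay_counts(ns, nr, model, T, rng)
    return float(live[0]) / (n_s + n_r)


@dataclass
class SimResult:
    """Outcome of one simulated fluctuation experiment.

    ``survival`` holds per-clone survival fractions; ``founders`` the founder
    phenotype of each clone; the model, protocol and seed are echoed so a
    result can be reproduced exactly.
    """

    survival: np.ndarray
    founders: np.ndarray  # bool, True = resistant founder
    n_plated: np.ndarray
    n_live: np.ndarray
    model: SwitchingModel
    protocol: AssayProtocol
    seed: int | None
    mode: str

    def cv(self) -> float:
        """Interclonal CV (sample SD with n-1 over mean) of survival."""
        m = float(np.mean(self.survival))
        if m == 0:
            return float("nan")
        return float(np.std(self.survival, ddof=1)) / m

    def to_table(self, passage: str = "P1", clone_prefix: str = "clone") -> pd.DataFrame:
        """Serialize to the clone-survival table schema."""
        n = len(self.survival)
        width = len(str(n))
        return pd.DataFrame(
            {
                "clone_id": [f"{clone_prefix}{i + 1:0{width}d}" for i in range(n)],
                "passage": passage,
                "n_plated": self.n_plated.astype(np.int64),
                "n_live": self.n_live.astype(np.int64),
                "survival_fraction": self.survival,
            }
        )

    def run_record(self) -> dict:
        """JSON-serializable provenance record (model, protocol, seed, mode)."""
        return {
            "model": self.model.to_dict(),
            "protocol": self.protocol.to_dict(),
            "seed": self.seed,
            "mode": self.mode,
            "n_clones": int(len(self.survival)),
        }


def _simulate_experiments(
    model: SwitchingModel,
    protocol: AssayProtocol,
    n_experiments: int,
    rng: np.random.Generator,
    founder: Founder,
    mode: str,
    division_prob: float,
    switch_in_assay: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core vectorized engine: (n_experiments, n_clones) survival array.

    Returns (survival, founders_resistant, n_live); plating count is
    protocol.N0 (or the whole clone when smaller, aggregate mode only).
    """
    n_tot = n_experiments * protocol.n_clones
    shape = (n_experiments, protocol.n_clones)

    if founder is Founder.EQUILIBRIUM:
        f = model.f_eq
        if math.isnan(f):
            raise ValueError(
                "equilibrium founder undefined when k_on = k_off = 0; "
                "pass founder='sensitive' or 'resistant'"
            )
        founders_res = rng.random(n_tot) < f
    elif founder is Founder.RESISTANT:
        founders_res = np.ones(n_tot, dtype=bool)
    else:
        founders_res = np.zeros(n_tot, dtype=bool)

    clone_total = 2 ** protocol.G
    if mode == "exact":
        if clone_total < protocol.N0:
            raise ValueError(
                f"expanded clone has 2^{protocol.G} = {clone_total} cells, fewer than "
                f"N0 = {protocol.N0} to plate; reduce N0 or use mode='aggregate' "
                "(binomial plating fallback)"
            )
        ns = np.empty(n_tot, dtype=np.int64)
        nr = np.empty(n_tot, dtype=np.int64)
        for i in range(n_tot):
            ns[i], nr[i] = _expand_percell(bool(founders_res[i]), model, protocol.G, rng)
    else:
        nr0 = founders_res.astype(np.int64)
        ns, nr = _expand_counts(
            1 - nr0, nr0, model, protocol.G, rng, division_prob
        )

    totals = ns + nr
    plated_total = np.minimum(totals, protocol.N0)
    # plate N0 cells without replacement; when the clone is smaller than N0
    # (possible only with stochastic division in aggregate mode) plate the
    # whole clone
    plated_res = np.empty(n_tot, dtype=np.int64)
    whole = totals <= protocol.N0
    plated_res[whole] = nr[whole]
    sub = ~whole
    if sub.any():
        plated_res[sub] = rng.hypergeometric(nr[sub], ns[sub], protocol.N0)
    plated_sens = plated_total - plated_res

    if switch_in_assay:
        plated_sens, plated_res = _apply_assay_switch(plated_sens, plated_res, model, rng)

    live = _assay_counts(plated_sens, plated_res, model, protocol.T, rng)
    survival = live / plated_total
    return (
        survival.reshape(shape),
        founders_res.reshape(shape),
        live.reshape(shape),
    )


def fluctuation_experiment(
    model: SwitchingModel,
    protocol: AssayProtocol,
    seed: int | None = None,
    *,
    founder: Founder | str = Founder.EQUILIBRIUM,
    mode: str = "aggregate",
    division_prob: float = 1.0,
    switch_in_assay: bool = False,
) -> SimResult:
    """Simulate one full fluctuation experiment (n_clones clones).

    Each clone: draw the founder phenotype, expand ``G`` generations, plate
    ``N0`` cells sampled without replacement (hypergeometric), run the
    24-h suspension assay, record the survival fraction.
    """
    if mode not in ("aggregate", "exact"):
        raise ValueError(f"unknown mode {mode!r}; expected 'aggregate' or 'exact'")
    rng = np.random.default_rng(seed)
    surv, founders, live = _simulate_experiments(
        model, protocol, 1, rng, Founder(founder), mode, division_prob, switch_in_assay
    )
    clone_total = 2 ** protocol.G
    plated = np.full(protocol.n_clones, min(clone_total, protocol.N0), dtype=np.int64)
    return SimResult(
        survival=surv[0],
        founders=founders[0],
        n_plated=plated,
        n_live=live[0],
        model=model,
        protocol=protocol,
        seed=seed,
        mode=mode,
    )


def predicted_cv(
    model: SwitchingModel,
    protocol: AssayProtocol,
    n_reps: int = 200,
    seed: int | None = None,
    *,
    founder: Founder | str = Founder.EQUILIBRIUM,
    mode: str = "aggregate",
    division_prob: float = 1.0,
    switch_in_assay: bool = False,
) -> tuple[float, float]:
    """Model-predicted interclonal CV: mean and Monte Carlo standard error.

    Runs ``n_reps`` independent replicate experiments and returns the mean
    of the per-experiment sample CVs together with the standard error of
    that mean.  Deterministic given ``seed``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate a Monte Carlo error")
    rng = np.random.default_rng(seed)
    surv, _, _ = _simulate_experiments(
        model, protocol, n_reps, rng, Founder(founder), mode, division_prob, switch_in_assay
    )
    means = surv.mean(axis=1)
    if np.any(means == 0):
        raise ValueError(
            "CV undefined: at least one replicate experiment had all-zero survival"
        )
    cvs = surv.std(axis=1, ddof=1) / means
    return float(cvs.mean()), float(cvs.std(ddof=1) / math.sqrt(n_reps))


def predicted_cv_grid(
    T_d_grid: Sequence[float],
    *,
    S_mean: float = 0.9,
    T: float = 24.0,
    M: float = 10.5,
    protocol: AssayProtocol | None = None,
    n_reps: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Predicted CV across a grid of suspension doubling times.

    For each ``T_d`` the model is re-parameterized from the survival balance
    (``f_eq = S_mean * 2^(-T/T_d)``) with fixed memory ``M``, and
    :func:`predicted_cv` is run.  Returns a DataFrame with columns
    ``T_d, f_eq, k_on, k_off, cv, mc_error``.
    """
    protocol = protocol or AssayProtocol(T=T)
    rng = np.random.default_rng(seed)
    rows = []
    for T_d in T_d_grid:
        m = SwitchingModel.from_survival_balance(S_mean, T, M=M, T_d_susp=T_d)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cv, err = predicted_cv(m, protocol, n_reps=n_reps, seed=sub_seed)
        rows.append(
            {
                "T_d": T_d,
                "f_eq": m.f_eq,
                "k_on": m.k_on,
                "k_off": m.k_off,
                "cv": cv,
                "mc_error": err,
            }
        )
    return pd.DataFrame(rows)
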