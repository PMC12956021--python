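"""Decay of acquired anoikis resistance during stress-free attached growth.

Resistant (AnR) populations returned to attached culture lose resistance
over generations.  The minimal model consistent with a transient
heritability of ``M`` generations is geometric per-generation decay of the
resistant fraction, ``f(g) = f0 * (1 - k_off)^g`` with ``k_off = 1/M``;
with re-induction (``k_on > 0``) the fraction instead relaxes
geometrically to the equilibrium ``k_on/(k_on+k_off)``.

``MemoryDecayModel`` fits the decay law to an observed reversion curve
(suspension survival vs generations in attached culture) by linear least
squares on the log scale; ``MemoryDecayResults`` carries the estimates and
diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state_model import growth_rate_from_doubling

__all__ = [
    "reversion_trajectory",
    "generations_to_threshold",
    "MemoryDecayModel",
    "MemoryDecayResults",
]


def reversion_trajectory(
    f0: float,
    k_off: float,
    g,
    k_on: float = 0.0,
):
    """Resistant fraction after ``g`` stress-free generations.

    Without re-induction (``k_on = 0``): ``f(g) = f0 (1-k_off)^g``.
    With re-induction the fraction relaxes geometrically to the
    equilibrium ``f_eq = k_on/(k_on+k_off)``:
    ``f(g) = f_eq + (f0 - f_eq) (1 - k_on - k_off)^g``.

    ``g`` may be a scalar or array (generations, need not be integer).
    """
    if not 0.0 <= f0 <= 1.0:
        raise ValueError(f"f0 must be in [0,1], got {f0}")
    if not (0.0 <= k_off <= 1.0 and 0.0 <= k_on <= 1.0):
        raise ValueError("switching probabilities must be in [0,1]")
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("generations must be >= 0")
    if k_on == 0.0:
        out = f0 * (1.0 - k_off) ** g
    else:
        f_eq = k_on / (k_on + k_off)
        lam = 1.0 - k_on - k_off
        out = f_eq + (f0 - f_eq) * lam**g
    return float(out) if out.ndim == 0 else out


def generations_to_threshold(
    f0: float,
    k_off: float,
    threshold_survival: float,
    *,
    T: float = 24.0,
    T_d_susp: float = float("inf"),
    k_on: float = 0.0,
) -> float:
    """Smallest integer ``g`` at which predicted suspension survival has
    fallen to the threshold (e.g. the parental population's survival).

    Predicted survival at generation ``g`` is ``f(g) * e^(gamma*T)`` with
    ``gamma = ln2/T_d_susp`` (suspension growth of the resistant cells
    during the rechallenge assay; ``T_d_susp = inf`` tests the resistant
    fraction itself).  Returns ``inf`` when the threshold is unreachable
    (e.g. ``k_off = 0``, or equilibrium above threshold).
    """
    gamma = growth_rate_from_doubling(T_d_susp)
    boost = math.exp(gamma * T)
    s0 = f0 * boost
    if threshold_survival >= s0:
        raise ValueError(
            f"threshold {threshold_survival} is not below the initial predicted "
            f"survival {s0:.4g}"
        )
    # long-run limit of predicted survival: f_eq*boost with re-induction,
    # 0 with pure decay, f0*boost (constant) when k_off = 0
    if k_on > 0:
        lim = k_on / (k_on + k_off) * boost
    elif k_off > 0:
        lim = 0.0
    else:
        lim = s0
    if threshold_survival < lim or k_off == 0.0:
        return float("inf")
    g = 0
    while True:
        s = reversion_trajectory(f0, k_off, g, k_on) * boost
        if s <= threshold_survival:
            return float(g)
        g += 1
        if g > 10_000:  # pragma: no cover - unreachable given the limit check
            return float("inf")


class MemoryDecayModel:
    """Geometric memory-decay model for a reversion curve.

    Parameters
    ----------
    generations : increasing sequence of generation counts in attached,
        stress-free culture.
    fraction : resistant fraction (or suspension survival, proportional to
        it when resistant growth is fixed) at each generation.
    label : optional cell-line label carried into results.

    The fit is ordinary least squares of ``log f`` on ``g``:
    ``log f(g) = log f0 + g log(1-k_off)``, exact on noiseless curves.
    """

    def __init__(self, generations, fraction, label: str | None = None):
        g = np.asarray(generations, dtype=float)
        f = np.asarray(fraction, dtype=float)
        if g.size != f.size:
            raise ValueError("generations and fraction differ in length")
        if g.size < 2:
            raise ValueError("need >= 2 points to fit a decay curve")
        if np.any(np.diff(g) <= 0):
            raise ValueError("generations must be strictly increasing")
        self.generations = g
        self.fraction = f
        self.label = label

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "MemoryDecayModel":
        """Read a two-column reversion-curve CSV (generation, survival_fraction)."""
        df = pd.read_csv(path)
        cols = list(df.columns)
        gcol = "generation" if "generation" in cols else cols[0]
        fcol = (
            "survival_fraction"
            if "survival_fraction" in cols
            else ("resistant_fraction" if "resistant_fraction" in cols else cols[1])
        )
        return cls(df[gcol], df[fcol], label=label)

    def fit(self) -> "MemoryDecayResults":
        """Least-squares fit on the log scale; masks non-positive values."""
        mask = self.fraction > 0
        n_masked = int((~mask).sum())
        if n_masked:
            warnings.warn(
                f"{n_masked} non-positive fraction value(s) masked before log fit",
                stacklevel=2,
            )
        g = self.generations[mask]
        f = self.fraction[mask]
        if g.size < 2:
            raise ValueError("fewer than 2 positive points; cannot fit decay")
        slope, intercept = np.polyfit(g, np.log(f), 1)
        k_off = 1.0 - math.exp(slope)
        f0 = math.exp(intercept)
        fitted = np.exp(intercept + slope * g)
        resid = np.log(f) - np.log(fitted)
        ss_res = float((resid**2).sum())
        ss_tot = float(((np.log(f) - np.log(f).mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return MemoryDecayResults(
            model=self,
            k_off=float(k_off),
            f0=float(f0),
            memory=float(1.0 / k_off) if k_off > 0 else float("inf"),
            r_squared=r2,
            resid_log_sd=float(np.sqrt(ss_res / max(g.size - 2, 1))),
            n_points=int(g.size),
            n_masked=n_masked,
            underdetermined=g.size == 2,
        )


@dataclass
class MemoryDecayResults:
    """Fitted memory-decay parameters and diagnostics."""

    model: MemoryDecayModel
    k_off: float  #: per-generation loss probability of the resistant state
    f0: float  #: fitted initial resistant fraction
    memory: float  #: mean residence time 1/k_off, generations
    r_squared: float
    resid_log_sd: float
    n_points: int
    n_masked: int
    underdetermined: bool  #: True when fitted through exactly 2 points

    def predict(self, g):
        """Fitted trajectory at generations ``g``."""
        return reversion_trajectory(min(self.f0, 1.0), self.k_off, g)

    def generations_to(self, threshold_survival: float, **kw) -> float:
        """Generations until predicted survival falls to ``threshold_survival``."""
        return generations_to_threshold(
            min(self.f0, 1.0), self.k_off, threshold_survival, **kw
        )

    def summary(self) -> str:
        lab = f" ({self.model.label})" if self.model.label else ""
        lines = [
            f"Memory-decay fit{lab}",
            "=" * 48,
            f"k_off     : {self.k_off:.4f} per generation",
            f"memory    : {self.memory:.1f} generations (1/k_off)",
            f"f0        : {self.f0:.4f}",
            f"R^2 (log) : {self.r_squared:.4f}",
            f"points    : {self.n_points} (masked: {self.n_masked})",
        ]
        if self.underdetermined:
            lines.append("warning   : exact 2-point interpolation; fit underdetermined")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k_off": self.k_off,
            "f0": self.f0,
            "memory_generations": self.memory,
            "r_squared": self.r_squared,
            "resid_log_sd": self.resid_log_sd,
            "n_points": self.n_points,
            "n_masked": self.n_masked,
            "underdetermined": self.underdetermined,
            "label": self.model.label,
        }
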