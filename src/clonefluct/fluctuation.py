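"""Fluctuation statistics on clone-survival tables.

The observable is a table of per-clone, per-passage suspension-survival
fractions.  The fluctuation test asks whether the clone-to-clone spread of
survival (the interclonal coefficient of variation, CV = SD/mean) is
compatible with a model's prediction; the companion statistics are a
percentile-bootstrap 95 % CI on the CV, inter-passage regression of clonal
survival (memory of clonal state across passages), and the per-clone
effective-growth-rate summary.

``FluctuationAnalysis`` is the model object built from a table;
``fit()`` returns a ``FluctuationResults`` carrying the estimates, their
bootstrap uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .state_model import effective_growth_rate

__all__ = [
    "REQUIRED_COLUMNS",
    "cv",
    "bootstrap_cv_ci",
    "passage_correlation",
    "growth_rate_summary",
    "compare_predicted_observed",
    "read_table",
    "write_table",
    "validate_table",
    "FluctuationAnalysis",
    "FluctuationResults",
]

REQUIRED_COLUMNS = ("clone_id", "passage", "n_plated", "n_live", "survival_fraction")

#: growth rate above which a clone counts as "doubling in suspension"
#: (doubling time <= 45 h, i.e. rate >= ln2/45 per hour)
DOUBLING_RATE = math.log(2.0) / 45.0


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over mean.

    Raises
    ------
    ValueError
        If fewer than two values, or the mean is zero (CV undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"CV needs >= 2 values, got {x.size}")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined: mean is zero")
    return float(x.std(ddof=1) / m)


def bootstrap_cv_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    *,
    method: str = "percentile",
) -> tuple[float, float, float, float]:
    """CV with a bootstrap confidence interval over clone resampling.

    Clones are resampled with replacement ``n_boot`` times; the interval is
    the percentile interval of the resampled CVs (``method="bca"`` uses the
    bias-corrected accelerated interval instead).  Returns
    ``(cv, ci_low, ci_high, half_width)`` with
    ``half_width = (ci_high - ci_low)/2`` — the "± x" the CV is reported
    with.  Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float)
    point = cv(x)
    if np.all(x == x[0]):
        # degenerate: no variation, zero-width interval
        return point, point, point, 0.0
    rng = np.random.default_rng(seed)
    if method == "bca":
        res = stats.bootstrap(
            (x,),
            lambda s, axis=-1: s.std(ddof=1, axis=axis) / s.mean(axis=axis),
            n_resamples=n_boot,
            confidence_level=1 - alpha,
            method="BCa",
            rng=rng,
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    elif method == "percentile":
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        samples = x[idx]
        cvs = samples.std(axis=1, ddof=1) / samples.mean(axis=1)
        lo, hi = np.quantile(cvs, [alpha / 2, 1 - alpha / 2])
        lo, hi = float(lo), float(hi)
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")
    return point, lo, hi, (hi - lo) / 2.0


def passage_correlation(
    surv_a: Sequence[float], surv_b: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS regression and Pearson correlation of paired per-clone survivals.

    Returns ``(slope, intercept, r, p)`` with a two-sided p-value; used to
    test whether clonal survival at one passage predicts survival at a
    later passage (a significant slope would indicate fixed clonal states).

    Raises
    ------
    ValueError
        With fewer than 3 pairs, mismatched lengths, or zero variance in
        either vector (correlation undefined).
    """
    a = np.asarray(surv_a, dtype=float)
    b = np.asarray(surv_b, dtype=float)
    if a.size != b.size:
        raise ValueError(f"paired vectors differ in length: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError(f"need >= 3 paired clones, got {a.size}")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance in one vector")
    fit = stats.linregress(a, b)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue)


@dataclass(frozen=True)
class GrowthRateSummary:
    """Cohort statistics of per-clone effective growth rates in suspension."""

    rates: np.ndarray  # finite rates only, per hour
    mean: float
    sd: float
    cv: float  # |SD / mean|
    fraction_negative: float
    fraction_positive: float
    n_doubling: int  # rate >= ln2/45 per hour
    n_extinct: int  # clones with zero survivors (rate -inf, excluded from moments)

    def to_dict(self) -> dict:
        return {
            "mean_per_hr": self.mean,
            "sd_per_hr": self.sd,
            "cv": self.cv,
            "fraction_negative": self.fraction_negative,
            "fraction_positive": self.fraction_positive,
            "n_doubling": self.n_doubling,
            "n_extinct": self.n_extinct,
            "n": int(self.rates.size),
        }


def growth_rate_summary(
    table: pd.DataFrame, T: float = 24.0, passage: str | None = None
) -> GrowthRateSummary:
    """Per-clone effective growth rates ln(n_live/n_plated)/T and cohort moments.

    Clones with zero survivors have rate -inf; they are counted in
    ``n_extinct`` and excluded from the moments.  The CV is reported as
    |SD/mean| (the mean is typically negative).
    """
    df = table if passage is None else table[table["passage"] == passage]
    if df.empty:
        raise ValueError(f"no rows{f' for passage {passage!r}' if passage else ''}")
    rates = np.array(
        [
            effective_growth_rate(n0, nt, T)
            for n0, nt in zip(df["n_plated"], df["n_live"])
        ]
    )
    finite = rates[np.isfinite(rates)]
    n_extinct = int(rates.size - finite.size)
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
    return GrowthRateSummary(
        rates=finite,
        mean=mean,
        sd=sd,
        cv=abs(sd / mean) if mean != 0 else float("inf"),
        fraction_negative=float((finite < 0).mean()),
        fraction_positive=float((finite > 0).mean()),
        n_doubling=int((finite >= DOUBLING_RATE).sum()),
        n_extinct=n_extinct,
    )


def compare_predicted_observed(observed_cv: float, predicted_cv: float) -> float:
    """Fold-ratio observed/predicted CV.

    The fluctuation test's verdict statistic: a ratio near 1 means the model
    accounts for the observed interclonal spread; a large ratio (the study
    finds >= 30 for the two-state model) rejects it.
    """
    if predicted_cv < 0 or observed_cv < 0:
        raise ValueError("CVs must be >= 0")
    if predicted_cv == 0:
        raise ValueError("predicted CV is 0: fold ratio infinite/undefined")
    return observed_cv / predicted_cv


# ---------------------------------------------------------------------------
# table I/O


def validate_table(df: pd.DataFrame, *, rtol: float = 1e-9) -> pd.DataFrame:
    """Validate the clone-survival table schema; returns the (typed) table.

    Requires the five schema columns; where both counts are present,
    survival_fraction must equal n_live/n_plated to within ``rtol``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table missing required columns: {missing}")
    df = df.copy()
    df["n_plated"] = df["n_plated"].astype(np.int64)
    df["n_live"] = df["n_live"].astype(np.int64)
    df["survival_fraction"] = df["survival_fraction"].astype(float)
    if (df["n_plated"] <= 0).any():
        bad = df.index[df["n_plated"] <= 0].tolist()
        raise ValueError(f"n_plated must be positive (rows {bad[:5]})")
    if (df["n_live"] < 0).any() or (df["survival_fraction"] < 0).any():
        raise ValueError("n_live and survival_fraction must be >= 0")
    implied = df["n_live"] / df["n_plated"]
    off = ~np.isclose(df["survival_fraction"], implied, rtol=rtol, atol=1e-12)
    if off.any():
        rows = df.index[off].tolist()
        raise ValueError(
            f"survival_fraction inconsistent with n_live/n_plated at rows {rows[:5]}"
        )
    return df


def read_table(path, *, percent: bool = False) -> pd.DataFrame:
    """Read a clone-survival CSV (header required, UTF-8, '.' decimal).

    ``percent=True`` divides the survival column by 100 on input.
    """
    df = pd.read_csv(path)
    if percent and "survival_fraction" in df.columns:
        df["survival_fraction"] = df["survival_fraction"] / 100.0
        df["n_live"] = np.rint(df["survival_fraction"] * df["n_plated"]).astype(np.int64)
    return validate_table(df)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a clone-survival table as CSV with the canonical column order."""
    validate_table(df)[list(REQUIRED_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# model / results objects


class FluctuationAnalysis:
    """Fluctuation analysis of a clone-survival table.

    Parameters
    ----------
    table : DataFrame in the clone-survival schema
        (clone_id, passage, n_plated, n_live, survival_fraction).
    T : suspension-assay duration in hours (for growth rates).

    Examples
    --------
    >>> res = FluctuationAnalysis(table).fit(seed=0)
    >>> res.cv_["P1"], res.cv_halfwidth_["P1"]
    """

    def __init__(self, table: pd.DataFrame, T: float = 24.0):
        self.table = validate_table(table)
        self.T = float(T)
        self.passages = list(dict.fromkeys(self.table["passage"]))

    @classmethod
    def from_csv(cls, path, T: float = 24.0, *, percent: bool = False) -> "FluctuationAnalysis":
        return cls(read_table(path, percent=percent), T=T)

    def survival(self, passage: str) -> np.ndarray:
        vals = self.table.loc[self.table["passage"] == passage, "survival_fraction"]
        if vals.empty:
            raise ValueError(f"no rows for passage {passage!r}")
        return vals.to_numpy()

    def _paired(self, pa: str, pb: str) -> tuple[np.ndarray, np.ndarray]:
        a = self.table[self.table["passage"] == pa].set_index("clone_id")["survival_fraction"]
        b = self.table[self.table["passage"] == pb].set_index("clone_id")["survival_fraction"]
        common = a.index.intersection(b.index)
        return a.loc[common].to_numpy(), b.loc[common].to_numpy()

    def fit(
        self,
        n_boot: int = 10_000,
        alpha: float = 0.05,
        seed: int | None = None,
        *,
        bootstrap_method: str = "percentile",
        predicted_cv: float | None = None,
    ) -> "FluctuationResults":
        """Compute all fluctuation statistics; deterministic given ``seed``.

        ``predicted_cv``, when supplied (e.g. from
        :func:`clonefluct.simulate.predicted_cv`), adds the
        observed/predicted fold-ratio per passage.
        """
        rng = np.random.default_rng(seed)
        cv_, lo_, hi_, hw_, mean_ = {}, {}, {}, {}, {}
        for p in self.passages:
            vals = self.survival(p)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            c, lo, hi, hw = bootstrap_cv_ci(
                vals, n_boot=n_boot, alpha=alpha, seed=sub_seed, method=bootstrap_method
            )
            cv_[p], lo_[p], hi_[p], hw_[p] = c, lo, hi, hw
            mean_[p] = float(vals.mean())

        correlations: dict[tuple[str, str], dict] = {}
        first = self.passages[0] if self.passages else None
        for p in self.passages[1:]:
            a, b = self._paired(first, p)
            if a.size >= 3 and a.std() > 0 and b.std() > 0:
                slope, intercept, r, pval = passage_correlation(a, b)
                correlations[(first, p)] = {
                    "slope": slope,
                    "intercept": intercept,
                    "r": r,
                    "p": pval,
                    "n": int(a.size),
                }

        growth = None
        if first is not None:
            growth = growth_rate_summary(self.table, T=self.T, passage=first)

        fold = None
        if predicted_cv is not None:
            fold = {p: compare_predicted_observed(cv_[p], predicted_cv) for p in self.passages}

        return FluctuationResults(
            model=self,
            mean_survival=mean_,
            cv_=cv_,
            cv_ci_low_=lo_,
            cv_ci_high_=hi_,
            cv_halfwidth_=hw_,
            correlations_=correlations,
            growth_=growth,
            predicted_cv=predicted_cv,
            fold_ratio_=fold,
            n_boot=n_boot,
            alpha=alpha,
            seed=seed,
        )


@dataclass
class FluctuationResults:
    """Fitted fluctuation statistics; see :class:`FluctuationAnalysis`."""

    model: FluctuationAnalysis
    mean_survival: dict
    cv_: dict
    cv_ci_low_: dict
    cv_ci_high_: dict
    cv_halfwidth_: dict
    correlations_: dict
    growth_: GrowthRateSummary | None
    predicted_cv: float | None
    fold_ratio_: dict | None
    n_boot: int
    alpha: float
    seed: int | None

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = ["Fluctuation analysis", "=" * 64]
        lines.append(
            f"{'passage':<10}{'n':>5}{'mean surv':>12}{'CV':>9}{'95% CI':>20}"
        )
        for p in self.model.passages:
            n = self.model.survival(p).size
            lines.append(
                f"{p:<10}{n:>5}{self.mean_survival[p]:>12.3f}{self.cv_[p]:>9.3f}"
                f"   [{self.cv_ci_low_[p]:.3f}, {self.cv_ci_high_[p]:.3f}] "
                f"(+/- {self.cv_halfwidth_[p]:.3f})"
            )
        if self.correlations_:
            lines.append("-" * 64)
            lines.append("inter-passage regression (first passage vs later):")
            for (pa, pb), d in self.correlations_.items():
                lines.append(
                    f"  {pa} vs {pb}: slope={d['slope']:+.3f}  r={d['r']:+.3f}  "
                    f"p={d['p']:.3g}  (n={d['n']})"
                )
        if self.growth_ is not None:
            g = self.growth_
            lines.append("-" * 64)
            lines.append(
                f"growth rates (first passage): mean={g.mean:+.4f}/hr  SD={g.sd:.4f}  "
                f"CV={g.cv * 100:.0f}%"
            )
            lines.append(
                f"  negative: {g.fraction_negative * 100:.0f}%  positive: "
                f"{g.fraction_positive * 100:.0f}%  doubling (T_d <= 45 h): "
                f"{g.n_doubling}  extinct: {g.n_extinct}"
            )
        if self.fold_ratio_ is not None:
            lines.append("-" * 64)
            lines.append(f"model-predicted CV: {self.predicted_cv:.4g}")
            for p, ratio in self.fold_ratio_.items():
                lines.append(f"  observed/predicted ({p}): {ratio:.1f}-fold")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable summary (stable field names)."""
        out = {
            "passages": {
                p: {
                    "n": int(self.model.survival(p).size),
                    "mean_survival": self.mean_survival[p],
                    "cv": self.cv_[p],
                    "cv_ci_low": self.cv_ci_low_[p],
                    "cv_ci_high": self.cv_ci_high_[p],
                    "cv_ci_halfwidth": self.cv_halfwidth_[p],
                }
                for p in self.model.passages
            },
            "correlations": [
                {"passage_a": pa, "passage_b": pb, **d}
                for (pa, pb), d in self.correlations_.items()
            ],
            "growth_rates": self.growth_.to_dict() if self.growth_ else None,
            "predicted_cv": self.predicted_cv,
            "fold_ratio": self.fold_ratio_,
            "n_boot": self.n_boot,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        return out
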