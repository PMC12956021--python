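"""Synthetic clone-survival data generators.

Two generative models are shipped:

* a **heritable continuum** model — each clone carries a latent suspension
  growth rate drawn once at founding from Normal(mu_g, sigma_g^2) per hour,
  evolving across passages as a first-order autoregressive process with
  coefficient ``rho`` (``rho = 0``: no inter-passage memory, matching the
  observed absence of passage-to-passage correlation).  Observed survival is
  ``exp(g*T)`` times unit-mean lognormal measurement noise.  This model
  reproduces the observed interclonal fluctuations (CV ~ 0.28) and
  growth-rate spread (mean ~ -0.004/hr, CV ~ 300 %) that the two-state
  switching model cannot.
* the **two-state** model — a thin wrapper over
  :func:`clonefluct.simulate.fluctuation_experiment`, emitting tables in the
  same schema, used as the null model the fluctuation test rejects.

Named presets (parameter sets as packaged YAML) pin the study conditions;
see ``preset_names()``.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .simulate import fluctuation_experiment
from .state_model import AssayProtocol, SwitchingModel

__all__ = [
    "ContinuumParams",
    "load_preset",
    "preset_names",
    "continuum_params_from_preset",
    "continuum_survival_moments",
    "generate_continuum_table",
    "generate_parental_replicates",
    "generate_two_state_table",
    "write_with_provenance",
]

_PASSAGE_RE = re.compile(r"^P(\d+)$")


@dataclass(frozen=True)
class ContinuumParams:
    """Parameters of the heritable-continuum generator.

    Parameters
    ----------
    mu_g : mean latent suspension growth rate, per hour.
    sigma_g : SD of founder latent growth rates across clones, per hour.
    rho : per-passage autocorrelation of the latent value in [-1, 1];
        0 means each passage redraws independently (memoryless).
    meas_cv : CV of multiplicative lognormal measurement noise (unit mean).
    T : suspension assay duration, hours.
    N0 : cells plated per assay.
    n_clones : clones per table.
    passages : passage labels; labels of the form ``P<k>`` contribute
        ``|k_b - k_a|`` AR steps between consecutive listed passages,
        otherwise one step each.
    link : latent-to-survival link; only ``"exp_growth"``
        (survival = exp(g*T)) is defined.
    """

    mu_g: float = -0.004
    sigma_g: float = 0.012
    rho: float = 0.0
    meas_cv: float = 0.05
    T: float = 24.0
    N0: int = 250_000
    n_clones: int = 60
    passages: tuple[str, ...] = ("P1", "P3", "P6")
    link: str = "exp_growth"

    def __post_init__(self) -> None:
        if self.sigma_g < 0:
            raise ValueError("sigma_g must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")
        if self.meas_cv < 0:
            raise ValueError("meas_cv must be >= 0")
        if self.link != "exp_growth":
            raise ValueError(f"unknown link {self.link!r}")
        if self.T <= 0 or self.N0 < 1 or self.n_clones < 1 or not self.passages:
            raise ValueError("T > 0, N0 >= 1, n_clones >= 1 and >= 1 passage required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passages"] = list(self.passages)
        return d


def _preset_dir():
    return importlib.resources.files("clonefluct") / "presets"


def preset_names() -> list[str]:
    """Names of the packaged parameter presets."""
    return sorted(
        p.name.removesuffix(".yaml") for p in _preset_dir().iterdir() if p.name.endswith(".yaml")
    )


def load_preset(name: str) -> dict:
    """Load a named preset's parameter dictionary."""
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"no preset {name!r}; available: {preset_names()}") from None
    return yaml.safe_load(text)


def continuum_params_from_preset(name: str = "ov90-clones", **overrides) -> ContinuumParams:
    """Build :class:`ContinuumParams` from a preset, with keyword overrides."""
    cfg = load_preset(name)
    if cfg.get("kind") != "continuum":
        raise ValueError(f"preset {name!r} is not a continuum preset")
    params = {k: v for k, v in cfg.items() if k not in ("kind", "description", "version")}
    params.update(overrides)
    if "passages" in params:
        params["passages"] = tuple(params["passages"])
    return ContinuumParams(**params)


def continuum_survival_moments(params: ContinuumParams) -> tuple[float, float]:
    """Analytic (mean, CV) of survival under the continuum model.

    ``ln S`` is Normal with variance ``(sigma_g*T)^2 + ln(1+meas_cv^2)``,
    so survival is lognormal with closed-form moments.
    """
    v = (params.sigma_g * params.T) ** 2 + math.log1p(params.meas_cv**2)
    mean = math.exp(params.mu_g * params.T + v / 2.0)
    cv = math.sqrt(math.expm1(v))
    return mean, cv


def _passage_lags(passages: tuple[str, ...]) -> list[int]:
    """AR steps between consecutive listed passages (0 for the first)."""
    nums = [_PASSAGE_RE.match(p) for p in passages]
    if all(m is not None for m in nums):
        ks = [int(m.group(1)) for m in nums]
        return [0] + [abs(b - a) for a, b in zip(ks, ks[1:])]
    return [0] + [1] * (len(passages) - 1)


def generate_continuum_table(
    params: ContinuumParams, seed: int | None = None
) -> pd.DataFrame:
    """Generate a clone-survival table under the heritable-continuum model.

    Deterministic given ``seed``.  Counts are emitted with ``N0`` plated and
    ``n_live`` rounded from the continuous survival fraction; the table's
    ``survival_fraction`` column is the count ratio, keeping the schema
    self-consistent.
    """
    rng = np.random.default_rng(seed)
    n = params.n_clones
    width = len(str(n))
    sln = math.sqrt(math.log1p(params.meas_cv**2))
    g = rng.normal(params.mu_g, params.sigma_g, size=n)
    frames = []
    for lag, passage in zip(_passage_lags(params.passages), params.passages):
        if lag > 0:
            a = params.rho**lag
            innovation_sd = params.sigma_g * math.sqrt(max(0.0, 1.0 - a**2))
            g = (
                params.mu_g
                + a * (g - params.mu_g)
                + rng.normal(0.0, innovation_sd, size=n)
            )
        noise = (
            rng.lognormal(-(sln**2) / 2.0, sln, size=n) if sln > 0 else np.ones(n)
        )
        survival = np.exp(g * params.T) * noise
        n_live = np.rint(survival * params.N0).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "clone_id": [f"clone{i + 1:0{width}d}" for i in range(n)],
                    "passage": passage,
                    "n_plated": params.N0,
                    "n_live": n_live,
                    "survival_fraction": n_live / params.N0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_parental_replicates(
    n: int = 11,
    preset: str | dict = "ov90-parental",
    seed: int | None = None,
) -> np.ndarray:
    """Replicate population-level survival measurements (no clonal term).

    Each replicate is ``mean_survival`` times unit-mean lognormal noise with
    CV ``noise_cv`` — technical/biological measurement spread only, the
    baseline the interclonal fluctuations are compared against.
    """
    if n < 2:
        raise ValueError("need >= 2 replicates")
    cfg = load_preset(preset) if isinstance(preset, str) else dict(preset)
    mean_survival = float(cfg["mean_survival"])
    noise_cv = float(cfg["noise_cv"])
    rng = np.random.default_rng(seed)
    if noise_cv == 0:
        return np.full(n, mean_survival)
    sln = math.sqrt(math.log1p(noise_cv**2))
    return mean_survival * rng.lognormal(-(sln**2) / 2.0, sln, size=n)


def generate_two_state_table(
    model: SwitchingModel | None = None,
    protocol: AssayProtocol | None = None,
    seed: int | None = None,
    *,
    passages: tuple[str, ...] = ("P1",),
    mode: str = "aggregate",
) -> pd.DataFrame:
    """Clone-survival table simulated under the two-state switching model.

    Defaults to the study parameterization (preset ``two-state-default``:
    equilibrium fraction from the survival balance 0.9 over 24 h at
    T_d = 100 h, memory 10.5 generations, G = 20, N0 = 250,000, 60 clones).
    Each passage is an independently re-equilibrated assay of the same
    clones (the two-state model has relaxed to equilibrium by P3/P6).
    """
    if model is None or protocol is None:
        cfg = load_preset("two-state-default")
        if model is None:
            model = SwitchingModel.from_survival_balance(
                cfg["S_mean"],
                cfg["T"],
                M=cfg["M"],
                T_d_susp=cfg["T_d_susp"],
                T_d_2D=cfg["T_d_2D"],
            )
        if protocol is None:
            protocol = AssayProtocol(
                T=cfg["T"], N0=cfg["N0"], G=cfg["G"], n_clones=cfg["n_clones"]
            )
    rng = np.random.default_rng(seed)
    frames = []
    for passage in passages:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = fluctuation_experiment(model, protocol, seed=sub_seed, mode=mode)
        frames.append(res.to_table(passage=passage))
    return pd.concat(frames, ignore_index=True)


def write_with_provenance(
    table: pd.DataFrame, csv_path, params: dict, seed: int | None
) -> None:
    """Write a table plus a JSON sidecar recording generator parameters/seed."""
    from .fluctuation import write_table

    write_table(table, csv_path)
    sidecar = str(csv_path) + ".json"
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump({"params": params, "seed": seed}, fh, indent=2, default=str)
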