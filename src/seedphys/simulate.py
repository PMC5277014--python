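"""Synthetic generators for every input the seed-development pipeline consumes.

The raw field records behind the bundled summary tables are not public, so
this module emulates the four input kinds with the statistical structure the
analysis assumes:

* **weather** — a year of daily radiation/temperature driven by seasonal
  sinusoids with Gaussian noise (temperate East-Asian coastal climate by
  default);
* **growth** — logistic 100-embryo-weight curves sampled every 7 days from
  10 DAA with replicate-level Gaussian noise, truth recorded for recovery
  tests;
* **plots** — the 2 years x 2 fertility x 3 managements x 3 replicates
  harvest design around configured treatment-mean yields (the bundled trial
  means by default) with replicate noise at a stated CV;
* **biochem** — an n = 96 sample table of carbohydrate-metabolism variables
  with a strictly ordered effect ladder against 100-seed weight.

The biochemistry generator mimics the stage structure of the real sampling
campaign: every sample carries a latent developmental stage, each node
reports that stage with a node-specific fidelity (the effect ladder), and the
target is a weighted sum of the node signals plus noise.  Samples are exactly
balanced over stages and node corruption is assigned by a single shared,
stage-stratified order (the assays are taken on the same physical samples),
a variance-reduction device that makes the generating information ladder
identifiable at n = 96.

All generators are deterministic under a fixed scenario seed.  Gaussian noise
is truncated at physical bounds by resampling (never clipping) to avoid point
masses at the bound.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .exceptions import InvalidInputError

__all__ = [
    "WeatherParams",
    "GrowthParams",
    "YieldParams",
    "BiochemParams",
    "SyntheticScenario",
    "gen_weather",
    "gen_growth",
    "gen_plots",
    "gen_biochem",
    "write_all",
]


def _resample_truncated(rng, draw, value, lower, strict=True):
    """Redraw entries at or below ``lower`` until all pass (resampling, not clipping)."""
    value = np.asarray(value, dtype=float)
    for _ in range(1000):
        bad = value <= lower if strict else value < lower
        if not bad.any():
            return value
        value = np.where(bad, draw(rng), value)
    raise InvalidInputError("truncation resampling failed to converge")


@dataclass(frozen=True)
class WeatherParams:
    """Seasonal-sinusoid weather model (defaults: temperate coastal site)."""

    mean_temp: float = 15.5  # annual mean air temperature, degC
    seasonal_amplitude: float = 12.0  # half peak-to-trough of the annual cycle, degC
    diurnal_range: float = 9.0  # tmax - tmin, degC
    srad_mean: float = 14.0  # annual mean solar radiation, MJ m^-2 d^-1
    srad_amplitude: float = 7.0  # seasonal amplitude of srad, MJ m^-2 d^-1
    temp_noise_sd: float = 1.8  # day-to-day noise on the daily mean, degC
    srad_noise_sd: float = 3.0  # day-to-day noise on srad, MJ m^-2 d^-1
    peak_doy: int = 200  # day of year of the warmest/brightest day


@dataclass(frozen=True)
class GrowthParams:
    """Logistic truth per group plus the sampling design and noise level."""

    groups: dict = field(
        default_factory=lambda: {"default": (6.0, 0.2, 27.0)}
    )  # group -> (w_asym g, k 1/d, t_m d)
    noise_sd: float = 0.3  # g per 100 embryos (5% of the default asymptote)
    sampling_daa: tuple = (10, 17, 24, 31, 38, 45)  # every 7 d from 10 DAA
    replicates: int = 3


@dataclass(frozen=True)
class YieldParams:
    """Treatment-mean yields/composition (bundled trial values by default)."""

    treatment_means: pd.DataFrame | None = None  # year,fertility,management,yield_kg_ha
    composition: pd.DataFrame | None = None  # fertility,management,year,contents
    seeds_per_boll: float = 28.0
    seed_weight_100: float = 11.0  # g per 100 seeds
    embryo_fraction: float = 0.58
    replicates: int = 3
    replicate_cv: float = 0.05  # CV of boll density across replicate plots


@dataclass(frozen=True)
class BiochemParams:
    """Stage-fidelity effect ladder for the n = 96 biochemistry table.

    ``fidelity`` maps each node to the fraction of samples on which it reports
    the true developmental stage (strictly decreasing = the effect ladder);
    ``target_weights`` are the weights of the node signals in the target.
    """

    n: int = 96
    nodes: tuple = (
        "susy",
        "d_fructose",
        "c_inv",
        "sps",
        "d_glucose",
        "pepc",
        "h_atpase",
        "sucrose",
    )
    fidelity: tuple = (1.00, 0.89, 0.78, 0.67, 0.56, 0.43, 0.29, 0.00)
    target_weights: tuple = (1.0, 0.06, 0.05, 0.04, 0.035, 0.03, 0.025, 0.02)
    stage_jitter: float = 0.10  # within-stage spread of a node signal (stage units)
    target_noise_sd: float = 0.03  # noise added to the target score
    target_mean: float = 10.5  # g per 100 seeds at the middle stage
    target_scale: float = 1.6  # g per unit of target score
    node_scales: dict = field(
        default_factory=lambda: {
            "susy": 20.0,
            "d_fructose": 10.0,
            "c_inv": 8.0,
            "sps": 6.0,
            "d_glucose": 12.0,
            "pepc": 4.0,
            "h_atpase": 25.0,
            "sucrose": 30.0,
        }
    )

    def __post_init__(self):
        k = len(self.nodes)
        if len(self.fidelity) != k or len(self.target_weights) != k:
            raise InvalidInputError("fidelity and target_weights must match nodes")
        if any(np.diff(self.fidelity) >= 0):
            raise InvalidInputError("effect ladder (fidelity) must be strictly decreasing")
        if any(w < 0 for w in self.target_weights):
            raise InvalidInputError("target_weights must be non-negative")


@dataclass(frozen=True)
class SyntheticScenario:
    """Master parameter bundle; a fixed seed yields byte-identical outputs."""

    seed: int = 0
    weather: WeatherParams = field(default_factory=WeatherParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    yields: YieldParams = field(default_factory=YieldParams)
    biochem: BiochemParams = field(default_factory=BiochemParams)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticScenario":
        """Build a scenario from a YAML mapping of (nested) field overrides."""
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for name, sub in (
            ("weather", WeatherParams),
            ("growth", GrowthParams),
            ("yields", YieldParams),
            ("biochem", BiochemParams),
        ):
            if name in cfg:
                kwargs[name] = sub(**cfg.pop(name))
        return cls(**cfg, **kwargs)


def _rng(scenario: SyntheticScenario, stream: str):
    # independent, reproducible stream per generator (crc32 is process-stable)
    return np.random.default_rng([scenario.seed, zlib.crc32(stream.encode()) % 2**31])


def gen_weather(scenario: SyntheticScenario, year: int) -> pd.DataFrame:
    """365 daily weather records for one calendar year.

    Daily mean temperature and solar radiation follow seasonal sinusoids with
    additive Gaussian noise; tmax/tmin sit half a diurnal range above/below
    the mean, so tavg is exactly the tmax/tmin midpoint before any downstream
    imputation; srad is truncated at 0 by resampling.
    """
    p = scenario.weather
    rng = np.random.default_rng([scenario.seed, int(year) % 2**31, 7])
    doy = np.arange(1, 366)
    phase = 2.0 * np.pi * (doy - p.peak_doy) / 365.0
    center = p.mean_temp + p.seasonal_amplitude * np.cos(phase)
    if p.temp_noise_sd > 0:
        center = center + rng.normal(0.0, p.temp_noise_sd, size=365)
    srad_clean = p.srad_mean + p.srad_amplitude * np.cos(phase)
    if p.srad_noise_sd > 0:
        srad = srad_clean + rng.normal(0.0, p.srad_noise_sd, size=365)
        srad = _resample_truncated(
            rng,
            lambda r: srad_clean + r.normal(0.0, p.srad_noise_sd, size=365),
            srad,
            0.0,
        )
    else:
        srad = np.maximum(srad_clean, 0.0)
    return pd.DataFrame(
        {
            "date": pd.date_range(f"{year}-01-01", periods=365, freq="D"),
            "srad": srad,
            "tmax": center + p.diurnal_range / 2.0,
            "tmin": center - p.diurnal_range / 2.0,
            "tavg": center,
        }
    )


def gen_growth(scenario: SyntheticScenario, group: str = "default") -> pd.DataFrame:
    """Replicated logistic growth observations for one group.

    Columns ``group``, ``daa``, ``weight_g_per_100``; weights are the exact
    logistic mean plus i.i.d. Gaussian noise, resampled to stay positive.
    """
    p = scenario.growth
    if group not in p.groups:
        raise InvalidInputError(f"unknown growth group {group!r}")
    w_asym, k, t_m = p.groups[group]
    rng = np.random.default_rng(
        [scenario.seed, zlib.crc32(f"growth/{group}".encode()) % 2**31]
    )
    daa = np.repeat(np.asarray(p.sampling_daa, dtype=float), p.replicates)
    mean = w_asym / (1.0 + np.exp(-k * (daa - t_m)))
    if p.noise_sd > 0:
        weight = mean + rng.normal(0.0, p.noise_sd, size=len(daa))
        weight = _resample_truncated(
            rng,
            lambda r: mean + r.normal(0.0, p.noise_sd, size=len(daa)),
            weight,
            0.0,
        )
    else:
        weight = mean
    return pd.DataFrame({"group": group, "daa": daa.astype(int), "weight_g_per_100": weight})


def gen_plots(scenario: SyntheticScenario) -> pd.DataFrame:
    """Plot-level harvest + composition records for the full factorial design.

    One row per year x fertility x management x replicate.  Boll density is
    back-solved so the plot's cottonseed yield reproduces the configured
    treatment mean, then perturbed across replicates at the configured CV.
    """
    p = scenario.yields
    means = p.treatment_means if p.treatment_means is not None else datasets.cottonseed_yields()
    comp = p.composition if p.composition is not None else datasets.embryo_composition()
    comp = comp.set_index(["year", "fertility", "management"])
    rng = _rng(scenario, "plots")
    rows = []
    for _, m in means.iterrows():
        # bd [bolls/ha] * spb * (sw/100) [g/seed] / 1000 = yield [kg/ha]
        bd_mean = m["yield_kg_ha"] * 1e5 / (p.seeds_per_boll * p.seed_weight_100)
        key = (m["year"], m["fertility"], m["management"])
        c = comp.loc[key] if key in comp.index else None
        for rep in range(1, p.replicates + 1):
            if p.replicate_cv > 0:
                bd = float(
                    _resample_truncated(
                        rng,
                        lambda r: bd_mean * (1.0 + p.replicate_cv * r.normal(size=1)),
                        bd_mean * (1.0 + p.replicate_cv * rng.normal(size=1)),
                        0.0,
                    )[0]
                )
            else:
                bd = bd_mean
            rows.append(
                {
                    "year": m["year"],
                    "fertility": m["fertility"],
                    "management": m["management"],
                    "replicate": rep,
                    "boll_density": bd,
                    "seeds_per_boll": p.seeds_per_boll,
                    "seed_weight_100": p.seed_weight_100,
                    "embryo_fraction": p.embryo_fraction,
                    "oil_content": (c["oil_content_pct"] / 100.0) if c is not None else np.nan,
                    "protein_content": (c["protein_content_pct"] / 100.0)
                    if c is not None
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def gen_biochem(scenario: SyntheticScenario) -> pd.DataFrame:
    """n-sample biochemistry table with a strictly ordered effect ladder.

    Latent developmental stages are exactly balanced over samples; node i
    reports the true stage on a ``fidelity[i]`` fraction of samples and an
    independent (balanced) decoy stage on the rest, with corruption assigned
    by one shared stage-stratified order.  The target score is the weighted
    sum of the node signals plus Gaussian noise, mapped affinely to a
    100-seed weight in grams; node signals are mapped through a positive
    log-scale onto realistic assay units (monotone, so discretization and MI
    are unaffected).
    """
    p = scenario.biochem
    n, k = p.n, len(p.nodes)
    rng = _rng(scenario, "biochem")

    combos = np.array([(s, g) for s in range(3) for g in range(3)])
    reps = np.full(9, n // 9)
    reps[: n % 9] += 1
    sg = np.repeat(combos, reps, axis=0)
    sg = sg[rng.permutation(n)]
    stage, decoy = sg[:, 0], sg[:, 1]

    # one corruption order shared by all nodes, cycling through the 9
    # (stage, decoy) strata so every corruption prefix stays balanced
    order = np.empty(n, dtype=int)
    pools = [
        list(rng.permutation(np.flatnonzero((stage == s) & (decoy == g))))
        for s, g in combos
    ]
    cycle = rng.permutation(9)
    pos = 0
    while pos < n:
        for j in cycle:
            if pools[j]:
                order[pos] = pools[j].pop()
                pos += 1
    u = np.empty(n)
    u[order] = (np.arange(n) + 0.5) / n

    signals = np.empty((n, k))
    for i, fid in enumerate(p.fidelity):
        reported = np.where(u < 1.0 - fid, decoy, stage)
        signals[:, i] = (reported - 1) + p.stage_jitter * rng.normal(size=n)

    w = np.asarray(p.target_weights, dtype=float)
    score = signals @ w
    if p.target_noise_sd > 0:
        score = score + rng.normal(0.0, p.target_noise_sd, size=n)
    denom = np.linalg.norm(w) if np.linalg.norm(w) > 0 else 1.0
    out = {"seed_weight_100": p.target_mean + p.target_scale * score / denom}
    for i, node in enumerate(p.nodes):
        scale = p.node_scales.get(node, 1.0)
        out[node] = scale * np.exp(0.4 * signals[:, i])
    return pd.DataFrame(out)


def _truth(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {
        key: (val.to_dict(orient="list") if isinstance(val, pd.DataFrame) else val)
        for key, val in d.items()
    }


def write_all(scenario: SyntheticScenario, outdir, years=(2012, 2013)) -> dict[str, Path]:
    """Write weather/growth/plots/biochem CSVs plus ground-truth sidecars.

    Each ``<name>.csv`` is accompanied by ``<name>.truth.json`` recording the
    generating parameters, so downstream recovery tests can compare against
    truth without re-deriving it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    weather = pd.concat([gen_weather(scenario, y) for y in years], ignore_index=True)
    weather = weather.rename(
        columns={"srad": "srad_mj_m2", "tmax": "tmax_c", "tmin": "tmin_c", "tavg": "tavg_c"}
    )
    growth = pd.concat(
        [gen_growth(scenario, g) for g in scenario.growth.groups], ignore_index=True
    )
    frames = {
        "weather": (weather, {"seed": scenario.seed, **_truth(scenario.weather)}),
        "growth": (growth, {"seed": scenario.seed, **_truth(scenario.growth)}),
        "plots": (gen_plots(scenario), {"seed": scenario.seed, **_truth(scenario.yields)}),
        "biochem": (gen_biochem(scenario), {"seed": scenario.seed, **_truth(scenario.biochem)}),
    }
    for name, (frame, truth) in frames.items():
        csv_path = outdir / f"{name}.csv"
        frame.to_csv(csv_path, index=False)
        (outdir / f"{name}.truth.json").write_text(json.dumps(truth, indent=2, default=str))
        written[name] = csv_path
    return written
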