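"""Experiment orchestration: configs, burn-in, replicates, summaries.

An experiment follows a fixed protocol: start every population from the
maximal-diversity state (each individual carries its own variant), run a
burn-in of unbiased transmission until the variant spectrum is at
innovation-drift equilibrium (default ``4 * N`` generations, the population
turnover timescale with margin), then record a number of generations
(default 300) under the configured transmission dynamic, storing one
:class:`GenerationRecord` row per generation and population.

Replicates are independent: replicate ``r`` of an experiment with master
seed ``s`` uses ``numpy.random.default_rng([s, r])``, so any single
replicate is reproducible in isolation and identical (config, seed) pairs
produce bit-identical output tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import connectedness, networks, transmission
from .population import Population, unbiased_step, variant_counts
from .stats import (InfluenceMoments, influence_moments, inbreeding_ne,
                    simple_ne, simpson_index, summarize, unique_count,
                    variance_ne)

__all__ = [
    "MODES",
    "ExperimentConfig",
    "burn_in",
    "burn_in_series",
    "stationarity_check",
    "run_experiment",
    "replicate_summary",
    "experiment_summary",
    "generation_summary",
    "sweep",
]

MODES = (
    "unbiased",
    "one_to_many",
    "frequency_dependent",
    "migration",
    "exchange",
    "influx",
    "network_er",
    "network_ba",
    "network_ws",
)

RECORD_COLUMNS = ["replicate", "pop", "t", "k_bar", "sigma2", "pool_size",
                  "offspring_size", "nei", "nev", "ne_simple", "simpson", "unique"]

SUMMARY_STATS = ("nei", "nev", "ne_simple", "simpson", "unique")


@dataclass
class ExperimentConfig:
    """Full specification of one simulation experiment.

    Only the parameters of the chosen ``mode`` need to be set; ``validate``
    reports missing or out-of-domain fields by name. ``burn_in=None``
    selects the default of four census turnovers (``4 * N``).
    """

    mode: str
    N: int = 1000
    mu: float = 1e-4
    R: int | None = None              # one_to_many
    theta: float | None = None        # frequency_dependent
    m: float | None = None            # migration
    e: float | None = None            # exchange
    influx_count: int | None = None   # influx
    source_N: int = 10000             # influx source census size
    p: float | None = None            # network_er
    pi_power: float | None = None     # network_ba
    K: int | None = None              # network_ws
    p_r: float | None = None          # network_ws
    burn_in: int | None = None
    generations: int = 300
    replicates: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.burn_in is not None and self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        required = {
            "one_to_many": ("R",),
            "frequency_dependent": ("theta",),
            "migration": ("m",),
            "exchange": ("e",),
            "influx": ("influx_count",),
            "network_er": ("p",),
            "network_ba": ("pi_power",),
            "network_ws": ("K", "p_r"),
        }.get(self.mode, ())
        for name in required:
            if getattr(self, name) is None:
                raise ValueError(f"mode {self.mode!r} requires parameter {name!r}")
        if self.mode == "one_to_many" and not 1 <= self.R <= self.N:
            raise ValueError("R must satisfy 1 <= R <= N")
        if self.mode == "frequency_dependent" and not self.theta > 0:
            raise ValueError("theta must be > 0")

    @property
    def burn_in_generations(self) -> int:
        return 4 * self.N if self.burn_in is None else self.burn_in

    def to_dict(self) -> dict:
        return asdict(self)


def burn_in(state, generations: int, mu: float, rng: np.random.Generator,
            graph: networks.Graph | None = None):
    """Equilibrate a population (or metapopulation) before recording.

    Runs ``generations`` of unbiased transmission — or network-constrained
    unbiased transmission when ``graph`` is given, since a network is the
    population's permanent structure. A metapopulation burns in as two
    isolated populations (coupling mechanisms act only during recording).
    """
    if generations < 0:
        raise ValueError("burn-in generations must be >= 0")
    if isinstance(state, connectedness.Metapopulation):
        for _ in range(generations):
            state, _counts = connectedness.migration_step(state, 0.0, mu, rng)
        return state
    pop = state
    for _ in range(generations):
        if graph is not None:
            pop, _counts = networks.network_step(pop, graph, mu, rng)
        else:
            pop, _counts = unbiased_step(pop, mu, rng)
    return pop


def burn_in_series(pop: Population, generations: int, mu: float,
                   rng: np.random.Generator,
                   graph: networks.Graph | None = None
                   ) -> tuple[Population, np.ndarray]:
    """Burn-in that also tracks the unique-variant count per generation.

    Used with :func:`stationarity_check` as a diagnostic that the default
    burn-in length suffices: at equilibrium the unique-variant series is
    trend-stationary.
    """
    uniques = np.empty(generations, dtype=np.int64)
    for g in range(generations):
        if graph is not None:
            pop, _counts = networks.network_step(pop, graph, mu, rng)
        else:
            pop, _counts = unbiased_step(pop, mu, rng)
        uniques[g] = np.unique(pop.variants).size
    return pop, uniques


def stationarity_check(series, frac: float = 0.25,
                       n_blocks: int = 10) -> tuple[float, float, float]:
    """Trend diagnostic: slope of block means over the trailing window.

    Splits the last ``frac`` of ``series`` into ``n_blocks`` consecutive
    blocks (block averaging absorbs the strong autocorrelation of the raw
    per-generation series), regresses the block means on block index and
    returns ``(slope, lower, upper)`` with a 95% confidence interval.
    The series is judged trend-stationary when the interval covers zero.
    """
    from scipy import stats as sps

    series = np.asarray(series, dtype=float)
    window = series[int(len(series) * (1 - frac)):]
    if len(window) < 2 * n_blocks:
        raise ValueError("series too short for the requested blocking")
    blocks = np.array_split(window, n_blocks)
    means = np.array([b.mean() for b in blocks])
    res = sps.linregress(np.arange(n_blocks), means)
    half = sps.t.ppf(0.975, n_blocks - 2) * res.stderr
    return float(res.slope), float(res.slope - half), float(res.slope + half)


def _record(rows: list, rep: int, which: str, t: int, oc, pop: Population) -> None:
    m = influence_moments(oc)
    vc = variant_counts(pop)
    ne = (m.pool_size - 1) / m.sigma2 if m.sigma2 > 0 else np.nan
    rows.append((rep, which, t, m.k_bar, m.sigma2, m.pool_size, m.offspring_size,
                 inbreeding_ne(m), variance_ne(m), ne,
                 simpson_index(vc), unique_count(vc.counts)))


def _run_replicate(cfg: ExperimentConfig, rep: int, rows: list) -> None:
    rng = np.random.default_rng([cfg.seed, rep])
    mode = cfg.mode
    burn = cfg.burn_in_generations

    if mode in ("migration", "exchange"):
        meta = connectedness.Metapopulation.independent(cfg.N)
        meta = burn_in(meta, burn, cfg.mu, rng)
        step = (connectedness.migration_step if mode == "migration"
                else connectedness.exchange_step)
        rate = cfg.m if mode == "migration" else cfg.e
        for t in range(cfg.generations):
            meta, (oc_a, oc_b) = step(meta, rate, cfg.mu, rng)
            _record(rows, rep, "a", t, oc_a, meta.pop_a)
            _record(rows, rep, "b", t, oc_b, meta.pop_b)
        return

    if mode == "influx":
        source = Population.all_distinct(cfg.source_N)
        src_burn = 4 * cfg.source_N if cfg.burn_in is None else cfg.burn_in
        source = burn_in(source, src_burn, cfg.mu, rng)
        focal = Population(np.arange(cfg.N) + source.next_label,
                           source.next_label + cfg.N)
        source = Population(source.variants, focal.next_label)
        focal = burn_in(focal, burn, cfg.mu, rng)
        source = Population(source.variants, focal.next_label)
        for t in range(cfg.generations):
            source, focal, oc = connectedness.influx_step(
                source, focal, cfg.influx_count, cfg.mu, rng)
            _record(rows, rep, "a", t, oc, focal)
        return

    if mode.startswith("network_"):
        if mode == "network_er":
            graph = networks.erdos_renyi(cfg.N, cfg.p, rng)
        elif mode == "network_ba":
            graph = networks.barabasi_albert(cfg.N, cfg.pi_power, rng)
        else:
            graph = networks.watts_strogatz(cfg.N, cfg.K, cfg.p_r, rng)
        pop = Population.all_distinct(cfg.N)
        pop = burn_in(pop, burn, cfg.mu, rng, graph=graph)
        for t in range(cfg.generations):
            pop, oc = networks.network_step(pop, graph, cfg.mu, rng)
            _record(rows, rep, "a", t, oc, pop)
        return

    pop = Population.all_distinct(cfg.N)
    pop = burn_in(pop, burn, cfg.mu, rng)
    for t in range(cfg.generations):
        if mode == "unbiased":
            pop, oc = unbiased_step(pop, cfg.mu, rng)
        elif mode == "one_to_many":
            pop, oc = transmission.one_to_many_step(pop, cfg.R, cfg.mu, rng)
        else:  # frequency_dependent; t = 0 is the first post-switch generation
            pop, oc = transmission.frequency_dependent_step(pop, cfg.theta, cfg.mu, rng)
        _record(rows, rep, "a", t, oc, pop)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run all replicates of an experiment; one row per recorded generation.

    Deterministic given (config, seed): identical inputs yield
    bit-identical tables.
    """
    config.validate()
    rows: list = []
    for rep in range(config.replicates):
        _run_replicate(config, rep, rows)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def replicate_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate estimates from moments pooled across recorded generations.

    The offspring-count moments are averaged over the recorded window
    first and the effective-size formulas applied to the pooled moments
    (ratio of means). This avoids the upward Jensen bias of averaging
    per-generation ``(N-1)/sigma2`` ratios, which is substantial whenever
    per-generation ``sigma2`` is noisy (e.g. one-to-many with small R).
    """
    out = []
    for (rep, which), g in records.groupby(["replicate", "pop"], sort=True):
        mom = InfluenceMoments(g["k_bar"].mean(), g["sigma2"].mean(),
                               g["pool_size"].mean(), g["offspring_size"].mean())
        out.append({
            "replicate": rep,
            "pop": which,
            "k_bar": mom.k_bar,
            "sigma2": mom.sigma2,
            "nei": inbreeding_ne(mom),
            "nev": variance_ne(mom),
            "ne_simple": (mom.pool_size - 1) / mom.sigma2 if mom.sigma2 > 0 else np.nan,
            "simpson": g["simpson"].mean(),
            "unique": g["unique"].mean(),
        })
    return pd.DataFrame(out)


def experiment_summary(records: pd.DataFrame,
                       stats: Sequence[str] = SUMMARY_STATS) -> pd.DataFrame:
    """Across-replicate mean and 90% prediction interval per statistic."""
    reps = replicate_summary(records)
    out = []
    for which, g in reps.groupby("pop", sort=True):
        for stat in stats:
            s = summarize(g[stat].to_numpy())
            out.append({"pop": which, "stat": stat, "mean": s.mean,
                        "lower": s.lower, "upper": s.upper})
    return pd.DataFrame(out)


def generation_summary(records: pd.DataFrame, stat: str = "ne_simple",
                       pop: str = "a") -> pd.DataFrame:
    """Across-replicate time series (mean + 90% PI) of one statistic."""
    g = records[records["pop"] == pop]
    out = []
    for t, gt in g.groupby("t", sort=True):
        s = summarize(gt[stat].to_numpy())
        out.append({"t": t, "mean": s.mean, "lower": s.lower, "upper": s.upper})
    return pd.DataFrame(out)


def sweep(base: ExperimentConfig, param: str, values: Iterable) -> pd.DataFrame:
    """Run an experiment per parameter value; concatenated summary table."""
    frames = []
    for v in values:
        cfg = ExperimentConfig(**{**base.to_dict(), param: v})
        summary = experiment_summary(run_experiment(cfg))
        summary.insert(0, param, v)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)
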