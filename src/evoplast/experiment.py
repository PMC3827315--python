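"""Study orchestration at configurable scale.

A *cell* of the study is (encoding, training-set size); a run samples an
evolutionary training set, evolves a population, and measures the
champion's General Learning Abilities score on all 256 association sets
and its automorphism count.  ``run_series`` sweeps a grid of cells with
replicates and aggregates per-cell statistics (GLA quartiles, fractions of
regular champions).

The ``desk`` preset (population 100, at most 500 generations, 5
replicates, training sets of size 1-3) is sized for a workstation; the
``full`` preset mirrors the published study scale (400 individuals, 4000
generations, sizes 1-7) and is intended for a cluster.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .encodings import DirectEncoding, HnnEncoding, MapEncoding, MutationRates
from .evolution import EvolutionConfig, EvolveResult, NoveltyParams, evolve
from .network import PlasticNetwork
from .regularity import network_automorphisms
from .task import TaskConfig, enumerate_global_set, gla_score, sample_training_set

logger = logging.getLogger("evoplast")

ENCODINGS = ("direct", "map", "hnn")


def make_encoding(name: str, rates: Optional[MutationRates] = None):
    if name == "direct":
        return DirectEncoding(rates=rates)
    if name == "map":
        return MapEncoding(rates=rates)
    if name == "hnn":
        return HnnEncoding(rates=rates)
    raise ValueError(f"unknown encoding {name!r}; choose from {ENCODINGS}")


@dataclass
class RunRecord:
    encoding: str
    n_train: int
    seed: int
    generations: int
    converged: bool
    champion_fitness: float
    champion_gla: float
    champion_gla_assoc: float
    champion_automorphisms: int
    training_set: List[str] = field(default_factory=list)
    champion_network: Optional[dict] = None

    def __post_init__(self):
        assert 0.0 <= self.champion_gla <= 1.0
        assert self.champion_automorphisms >= 1


@dataclass
class SeriesConfig:
    encodings: Tuple[str, ...] = ("direct", "map", "hnn")
    n_train_values: Tuple[int, ...] = (1, 2, 3)
    replicates: int = 5
    population_size: int = 100
    max_generations: int = 500
    base_seed: int = 1
    gla_repeats: int = 5

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def preset(cls, name: str, base_seed: int = 1) -> "SeriesConfig":
        if name == "desk":
            return cls(base_seed=base_seed)
        if name == "full":
            return cls(
                n_train_values=tuple(range(1, 8)),
                replicates=20,
                population_size=400,
                max_generations=4000,
                base_seed=base_seed,
            )
        raise ValueError(f"unknown preset {name!r}")


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_experiment(
    encoding_name: str,
    n_train: int,
    seed: int,
    population_size: int = 100,
    max_generations: int = 500,
    task_config: Optional[TaskConfig] = None,
    gla_repeats: int = 5,
    rates: Optional[MutationRates] = None,
    keep_network: bool = False,
    progress=None,
) -> RunRecord:
    """One evolutionary run plus champion measurement."""
    task_config = task_config if task_config is not None else TaskConfig()
    encoding = make_encoding(encoding_name, rates)
    global_set = enumerate_global_set(task_config.n_stimuli, task_config.n_actions)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E7]))
    training_set = sample_training_set(global_set, n_train, rng)

    config = EvolutionConfig(
        population_size=population_size,
        max_generations=max_generations,
        seed=seed,
    )
    result = evolve(training_set, encoding, config, task_config, progress=progress)

    best = result.best
    champion = encoding.develop(best.genotype) if not best.error else None
    if champion is not None:
        gla = gla_score(
            champion,
            global_set,
            task_config,
            np.random.default_rng(np.random.SeedSequence([seed, 0x61A])),
            n_repeats=gla_repeats,
        )
        autos = network_automorphisms(champion)
        gla_set, gla_assoc = gla.set_level, gla.association_level
    else:  # degenerate champion (development failure)
        gla_set = gla_assoc = 0.0
        autos = 1
    record = RunRecord(
        encoding=encoding_name,
        n_train=n_train,
        seed=seed,
        generations=result.generations,
        converged=result.converged,
        champion_fitness=best.fitness,
        champion_gla=gla_set,
        champion_gla_assoc=gla_assoc,
        champion_automorphisms=autos,
        training_set=[s.to_text() for s in training_set],
        champion_network=champion.to_dict() if keep_network else None,
    )
    logger.info(
        "run %s n_train=%d seed=%d: fitness=%.3f gla=%.3f automorphisms=%d "
        "(%d generations, converged=%s)",
        encoding_name, n_train, seed, best.fitness, gla_set, autos,
        result.generations, result.converged,
    )
    return record


def run_series(
    config: SeriesConfig,
    out_dir: Optional[str] = None,
    task_config: Optional[TaskConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Grid of runs; returns (per-run table, per-cell aggregate table)."""
    rows = []
    for enc_i, enc in enumerate(config.encodings):
        for n_train in config.n_train_values:
            for rep in range(config.replicates):
                seed = _derived_seed(config.base_seed, enc_i, n_train, rep)
                try:
                    rec = run_experiment(
                        enc,
                        n_train,
                        seed,
                        population_size=config.population_size,
                        max_generations=config.max_generations,
                        task_config=task_config,
                        gla_repeats=config.gla_repeats,
                    )
                except Exception:
                    logger.exception("cell %s n_train=%d rep=%d failed", enc, n_train, rep)
                    continue
                row = asdict(rec)
                row.pop("champion_network")
                row.pop("training_set")
                row["replicate"] = rep
                rows.append(row)
    runs = pd.DataFrame(rows)
    agg = aggregate_series(runs)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        runs.to_csv(os.path.join(out_dir, "runs.csv"), index=False)
        agg.to_csv(os.path.join(out_dir, "cells.csv"), index=False)
    return runs, agg


def aggregate_series(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-cell medians/quartiles of GLA and regularity fractions."""
    if runs.empty:
        return pd.DataFrame()
    out = []
    for (enc, n_train), cell in runs.groupby(["encoding", "n_train"]):
        gla = cell["champion_gla"]
        autos = cell["champion_automorphisms"]
        out.append(
            {
                "encoding": enc,
                "n_train": n_train,
                "n_runs": len(cell),
                "gla_median": gla.median(),
                "gla_q1": gla.quantile(0.25),
                "gla_q3": gla.quantile(0.75),
                "automorphisms_median": autos.median(),
                "frac_regular": float((autos > 1).mean()),
                "frac_over_3_automorphisms": float((autos > 3).mean()),
                "frac_at_least_10_automorphisms": float((autos >= 10).mean()),
                "frac_converged": float(cell["converged"].mean()),
            }
        )
    return pd.DataFrame(out)


def compare_cells(
    runs: pd.DataFrame,
    cell_a: Tuple[str, int],
    cell_b: Tuple[str, int],
    column: str = "champion_gla",
):
    """Mann-Whitney U between two cells' champion statistics."""
    from scipy.stats import mannwhitneyu

    a = runs.query("encoding == @cell_a[0] and n_train == @cell_a[1]")[column]
    b = runs.query("encoding == @cell_b[0] and n_train == @cell_b[1]")[column]
    return mannwhitneyu(a, b, alternative="two-sided")


def save_champion(record: RunRecord, out_dir: str) -> None:
    """Archive a champion as JSON + DOT for inspection."""
    if record.champion_network is None:
        raise ValueError("record was created without keep_network=True")
    os.makedirs(out_dir, exist_ok=True)
    stem = f"{record.encoding}_n{record.n_train}_s{record.seed}"
    net = PlasticNetwork.from_dict(record.champion_network)
    net.to_json(os.path.join(out_dir, stem + ".json"))
    with open(os.path.join(out_dir, stem + ".dot"), "w") as fh:
        fh.write(net.to_dot())
    with open(os.path.join(out_dir, stem + ".meta.json"), "w") as fh:
        meta = asdict(record)
        meta.pop("champion_network")
        json.dump(meta, fh, indent=2)
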