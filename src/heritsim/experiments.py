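"""Parameter-sweep drivers: heritability ratio surfaces over noise grids.

Three studies are supported, all built on the same primitive — grow a
clonal population, pool its pedigree, and regress offspring on parent at
the cell and collective level:

* a sigma x sigma' sweep at fixed collective size (ratio surfaces for any
  trait map);
* a collective-size series at a handful of noise levels;
* a sigma x CV_N sweep for the volume trait with variable cells per
  collective.

Every (parameter combination, replicate) cell runs with its own derived
seed, so replicates are independent and results do not depend on execution
order.  Degenerate combinations (no parental variance) are recorded as
missing rows, never dropped.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .errors import DegenerateVarianceError, InvalidInputError, ParameterError
from .growth_model import SimulationParams, grow_population
from .heritability import relative_heritability
from .trait_maps import TRAIT_MAPS

#: The sweeps' visual floor for noise SDs (true zeros are degenerate for
#: the regression estimator and are accepted only in the core model).
NOISE_FLOOR = 1e-4

#: Noise levels of the collective-size series.
SERIES_LEVELS = (1e-4, 0.0625, 0.125, 0.1875, 0.25)

RESULT_COLUMNS = (
    "trait_map", "sigma", "sigma_env", "cv_n", "n_cells", "replicate",
    "slope_cell", "slope_collective", "ratio",
)

GROUP_COLUMNS = ("trait_map", "sigma", "sigma_env", "cv_n", "n_cells")


def noise_grid(n: int = 32, low: float = NOISE_FLOOR,
               high: float = 0.25) -> list[float]:
    """``n`` evenly spaced noise SD values on [low, high]."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if n == 1:
        return [float(low)]
    return [float(v) for v in np.linspace(low, high, n)]


@dataclass(frozen=True)
class SweepGrid:
    """Axes and bookkeeping of one sweep."""

    sigma_values: tuple[float, ...] = tuple(noise_grid())
    sigma_env_values: tuple[float, ...] = tuple(noise_grid())
    cv_n_values: tuple[float, ...] = (0.0,)
    collective_sizes: tuple[int, ...] = (32,)
    replicates: int = 10
    generations: int = 7
    trait_map: str = "volume"
    seed: int = 0
    n_genotypes: int = 10
    genetic_mean_range: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if self.trait_map not in TRAIT_MAPS:
            raise InvalidInputError(
                f"unknown trait map {self.trait_map!r}")


@dataclass
class SweepResult:
    """Per-(combination, replicate) rows plus the configuration that made them."""

    rows: pd.DataFrame
    config: dict
    derived_seeds: list[int] = field(default_factory=list)

    def aggregate(self) -> pd.DataFrame:
        """Per-combination means over replicates (missing rows excluded)."""
        grouped = self.rows.groupby(list(GROUP_COLUMNS), as_index=False).agg(
            slope_cell=("slope_cell", "mean"),
            slope_collective=("slope_collective", "mean"),
            ratio=("ratio", "mean"),
            n_replicates=("replicate", "size"),
            n_missing=("ratio", lambda s: int(s.isna().sum())),
        )
        return grouped


def derive_seed(master_seed: int, combo_index: int, replicate: int) -> int:
    """Deterministic per-(combination, replicate) child seed."""
    ss = np.random.SeedSequence([int(master_seed), combo_index, replicate])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _run_cell(
    trait_map: str, sigma: float, sigma_env: float, cv_n: float,
    n_cells: int, replicate: int, seed: int, grid: SweepGrid,
) -> tuple:
    params = SimulationParams(
        sigma=sigma, sigma_env=sigma_env, cv_n=cv_n, n_bar=n_cells,
        generations=grid.generations, n_genotypes=grid.n_genotypes,
        genetic_mean_range=grid.genetic_mean_range, seed=seed)
    _, pedigree = grow_population(params)
    try:
        s_cell, s_coll, ratio = relative_heritability(pedigree, trait_map)
    except DegenerateVarianceError:
        s_cell = s_coll = ratio = np.nan
    return (trait_map, sigma, sigma_env, cv_n, n_cells, replicate,
            s_cell, s_coll, ratio)


def _run_combos(
    combos: Sequence[tuple[float, float, float, int]], grid: SweepGrid,
) -> SweepResult:
    """combos: (sigma, sigma_env, cv_n, n_cells) tuples, in grid order."""
    rows = []
    seeds = []
    for combo_index, (sg, se, cv, n_cells) in enumerate(combos):
        for rep in range(grid.replicates):
            seed = derive_seed(grid.seed, combo_index, rep)
            seeds.append(seed)
            rows.append(_run_cell(
                grid.trait_map, sg, se, cv, n_cells, rep, seed, grid))
    frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    config = asdict(grid)
    return SweepResult(rows=frame, config=config, derived_seeds=seeds)


def run_sigma_sweep(grid: SweepGrid) -> SweepResult:
    """Ratio surface over (sigma, sigma') at fixed collective size, cv_n = 0."""
    n_cells = grid.collective_sizes[0]
    combos = [
        (sg, se, 0.0, n_cells)
        for sg, se in itertools.product(
            grid.sigma_values, grid.sigma_env_values)
    ]
    return _run_combos(combos, grid)


def run_size_series(grid: SweepGrid) -> SweepResult:
    """Ratio as a function of collective size at each noise combination.

    Hold one of sigma / sigma' at a single value and let the other take
    the series levels; every combination is crossed with every collective
    size in ``grid.collective_sizes``.
    """
    combos = [
        (sg, se, 0.0, n_cells)
        for n_cells, sg, se in itertools.product(
            grid.collective_sizes, grid.sigma_values, grid.sigma_env_values)
    ]
    return _run_combos(combos, grid)


def run_cvn_sweep(grid: SweepGrid) -> SweepResult:
    """Ratio surface over (sigma, CV_N) with sigma' held at its single value.

    The default grid holds sigma' = 0 during this sweep (configurable via
    ``sigma_env_values``); the CV_N = 0 column reduces to the fixed-size
    model.
    """
    sigma_env = grid.sigma_env_values[0]
    n_cells = grid.collective_sizes[0]
    combos = [
        (sg, sigma_env, cv, n_cells)
        for sg, cv in itertools.product(grid.sigma_values, grid.cv_n_values)
    ]
    return _run_combos(combos, grid)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.10g"


def export_results(result: SweepResult, out_dir) -> dict[str, Path]:
    """Write results CSV, aggregate CSV and a JSON run manifest.

    Output is deterministic: fixed column order, fixed float formatting,
    sorted manifest keys — the same seed and config produce byte-identical
    files.
    """
    if result.rows.empty:
        raise InvalidInputError("nothing to export")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "results.csv",
        "aggregate": out / "aggregate.csv",
        "manifest": out / "manifest.json",
    }
    result.rows.to_csv(paths["results"], index=False,
                       float_format=FLOAT_FORMAT)
    result.aggregate().to_csv(paths["aggregate"], index=False,
                              float_format=FLOAT_FORMAT)
    manifest = {
        "package": "heritsim",
        "version": _version,
        "config": result.config,
        "master_seed": result.config.get("seed"),
        "derived_seeds": result.derived_seeds,
        "n_rows": int(len(result.rows)),
    }
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_jsonable))
    return paths


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def load_results(path) -> pd.DataFrame:
    """Re-read an exported results CSV with the canonical column order."""
    frame = pd.read_csv(path)
    missing = set(RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    return frame[list(RESULT_COLUMNS)]
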