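"""Agent-based clonal growth model for multilevel heritability studies.

Particles ("cells", with a single positive size phenotype) grow inside
collectives; each collective reproduces by splitting into two offspring
collectives every generation.  Two non-genetic noise sources perturb cell
phenotype:

* developmental instability: a daughter cell's size is drawn from a normal
  distribution centred on its genotype's genetic mean with standard
  deviation ``sigma`` (not on the parent cell's realized size — there is no
  cell-level inheritance of the deviation);
* environmental heterogeneity: every collective receives its own
  multiplicative size modifier, drawn from Normal(1, ``sigma_env``), applied
  identically to all of its member cells.

Optionally the number of cells per collective is itself a random variable
with genetic mean ``n_bar`` and coefficient of variation ``cv_n``.

The model is deliberately selection-free: every collective reproduces
exactly once per generation, so after ``g`` generations each founder clone
has produced ``2**g - 1`` collective-level reproductive events.  Pedigree
pairs at both levels are recorded for parent-offspring regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidStateError, ParameterError

logger = logging.getLogger(__name__)

#: Positivity floor for truncated-normal draws of sizes and modifiers.
EPS = 1e-6

#: Noise levels above this are outside the regime the default sweeps study.
NOISE_CEILING = 0.25


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeSpec:
    """A clone's fixed genetic values (no mutation over a run)."""

    id: int
    genetic_mean_size: float
    genetic_mean_count: float

    def __post_init__(self) -> None:
        if self.genetic_mean_size <= 0:
            raise ParameterError("genetic_mean_size must be positive")
        if self.genetic_mean_count <= 0:
            raise ParameterError("genetic_mean_count must be positive")


@dataclass(frozen=True)
class SimulationParams:
    """All generative knobs of a single run.

    Parameters
    ----------
    sigma:
        Developmental-instability standard deviation of cell size (size
        units, same scale as the genetic means).
    sigma_env:
        Standard deviation of the per-collective multiplicative
        environmental modifier (dimensionless, centred on 1).
    cv_n:
        Coefficient of variation of cells per collective; 0 gives the
        fixed-size model in which every collective has round(n_bar) cells.
    n_bar:
        Genetic mean number of cells per collective.
    generations:
        Number of doubling generations grown after founding.
    n_genotypes:
        Number of genetically distinct founder clones.
    genetic_mean_range:
        (low, high); founder genetic mean sizes are spaced evenly across
        this closed interval.
    seed:
        Master seed; each genotype lineage gets an independent child stream.
    """

    sigma: float
    sigma_env: float
    cv_n: float = 0.0
    n_bar: float = 32.0
    generations: int = 7
    n_genotypes: int = 10
    genetic_mean_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.sigma_env < 0 or self.cv_n < 0:
            raise ParameterError("sigma, sigma_env and cv_n must be >= 0")
        if self.n_bar < 1:
            raise ParameterError("n_bar must be >= 1")
        if self.generations < 0:
            raise ParameterError("generations must be >= 0")
        if self.n_genotypes < 1:
            raise ParameterError("n_genotypes must be >= 1")
        low, high = self.genetic_mean_range
        if low <= 0:
            raise ParameterError("genetic means must be positive")
        if self.n_genotypes > 1 and not low < high:
            raise ParameterError("genetic_mean_range must satisfy low < high")
        for name in ("sigma", "sigma_env", "cv_n"):
            value = getattr(self, name)
            if value > NOISE_CEILING:
                logger.warning(
                    "%s = %g exceeds the reference regime [0, %g]",
                    name, value, NOISE_CEILING,
                )


@dataclass
class CollectiveRecord:
    """One collective: who it is, its environment, and its member cells.

    ``cell_phenotypes`` are realized (post-modifier) sizes; dividing them by
    ``env_modifier`` recovers the pre-modifier developmental draws.
    """

    id: int
    genotype_id: int
    generation: int
    env_modifier: float
    cell_phenotypes: np.ndarray
    parent_id: int | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_phenotypes)


@dataclass
class PedigreeTable:
    """Parent-offspring value pairs recorded at both levels of a run.

    Cell-level pairs carry realized phenotypes directly.  Collective-level
    pairs carry the parent and offspring records; their trait values are
    filled in later by whichever trait map the analysis chooses
    (:meth:`collective_trait_pairs`).
    """

    cell_parent_values: list[float] = field(default_factory=list)
    cell_offspring_values: list[float] = field(default_factory=list)
    collective_links: list[tuple[CollectiveRecord, CollectiveRecord]] = field(
        default_factory=list)
    n_collective_events: int = 0
    n_cell_events: int = 0

    @property
    def cell_pairs(self) -> np.ndarray:
        """(n, 2) array of (parent phenotype, offspring phenotype)."""
        return np.column_stack([
            np.asarray(self.cell_parent_values, dtype=float),
            np.asarray(self.cell_offspring_values, dtype=float),
        ]) if self.cell_parent_values else np.empty((0, 2))

    def collective_trait_pairs(
        self, trait_map: Callable[[np.ndarray], float],
    ) -> np.ndarray:
        """(m, 2) array of (parent trait, offspring trait) under ``trait_map``."""
        if not self.collective_links:
            return np.empty((0, 2))
        return np.array([
            (trait_map(p.cell_phenotypes), trait_map(o.cell_phenotypes))
            for p, o in self.collective_links
        ], dtype=float)

    def extend(self, other: "PedigreeTable") -> None:
        self.cell_parent_values.extend(other.cell_parent_values)
        self.cell_offspring_values.extend(other.cell_offspring_values)
        self.collective_links.extend(other.collective_links)
        self.n_collective_events += other.n_collective_events
        self.n_cell_events += other.n_cell_events


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------

def _positive_normal(
    mean: float, sd: float, rng: np.random.Generator, size: int | None = None,
) -> float | np.ndarray:
    """Normal(mean, sd) resampled until every draw exceeds ``EPS``.

    At the reference parameter ranges (means >= 1, sd <= 0.25) the
    truncation probability is below 1e-4 of a standard deviation tail, so
    this is a vanishing perturbation of the stated distribution.
    """
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    out = rng.normal(mean, sd, size=size)
    if size is None:
        while out <= EPS:
            out = rng.normal(mean, sd)
        return float(out)
    bad = out <= EPS
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= EPS
    return out


def draw_cell_size(
    genetic_mean: float, sigma: float, rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Developmental draw of cell size around the *genetic* mean.

    The draw is centred on the genotype's genetic mean, not on the parent
    cell's realized phenotype: developmental deviations are not themselves
    inherited.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if genetic_mean <= 0:
        raise ParameterError("genetic_mean must be positive")
    return _positive_normal(genetic_mean, sigma, rng, size)


def draw_env_modifier(sigma_env: float, rng: np.random.Generator) -> float:
    """Per-collective multiplicative environmental modifier ~ Normal(1, sigma_env)."""
    if sigma_env < 0:
        raise ParameterError("sigma_env must be >= 0")
    value = _positive_normal(1.0, sigma_env, rng)
    return float(value)


def draw_cell_count(n_bar: float, cv_n: float, rng: np.random.Generator) -> int:
    """Cells per collective ~ Normal(n_bar, cv_n * n_bar), rounded, floored at 1."""
    if cv_n < 0:
        raise ParameterError("cv_n must be >= 0")
    if n_bar < 1:
        raise ParameterError("n_bar must be >= 1")
    if cv_n == 0:
        return max(1, int(round(n_bar)))
    draw = rng.normal(n_bar, cv_n * n_bar)
    return max(1, int(round(draw)))


# ---------------------------------------------------------------------------
# population construction and growth
# ---------------------------------------------------------------------------

def genotype_specs(params: SimulationParams) -> list[GenotypeSpec]:
    """Founder genotypes with mean sizes evenly spaced over the stated range.

    With a single genotype the (degenerate) convention is to use the lower
    bound of the range.
    """
    low, high = params.genetic_mean_range
    if params.n_genotypes == 1:
        means = np.array([low])
    else:
        means = np.linspace(low, high, params.n_genotypes)
    return [
        GenotypeSpec(id=i, genetic_mean_size=float(m),
                     genetic_mean_count=params.n_bar)
        for i, m in enumerate(means)
    ]


def _make_founder(
    genotype: GenotypeSpec, params: SimulationParams,
    rng: np.random.Generator, collective_id: int,
) -> CollectiveRecord:
    # Founders get an env modifier like any later collective so that
    # generation 0 has the same noise structure as the rest of the run.
    n = draw_cell_count(genotype.genetic_mean_count, params.cv_n, rng)
    modifier = draw_env_modifier(params.sigma_env, rng)
    base = draw_cell_size(genotype.genetic_mean_size, params.sigma, rng, size=n)
    return CollectiveRecord(
        id=collective_id,
        genotype_id=genotype.id,
        generation=0,
        env_modifier=modifier,
        cell_phenotypes=np.asarray(base, dtype=float) * modifier,
    )


def init_population(
    params: SimulationParams, rng: np.random.Generator,
) -> list[CollectiveRecord]:
    """One founder collective per genotype, drawn from a single stream."""
    return [
        _make_founder(g, params, rng, collective_id=i)
        for i, g in enumerate(genotype_specs(params))
    ]


def _offspring(
    parent: CollectiveRecord, genotype: GenotypeSpec,
    params: SimulationParams, rng: np.random.Generator,
    collective_id: int,
) -> tuple[CollectiveRecord, np.ndarray]:
    """One offspring collective plus the parent-cell index of each daughter."""
    n_parent = parent.n_cells
    if params.cv_n == 0:
        # fixed-size model: "each with as many particles as its parent"
        n_off = n_parent
        parent_idx = np.arange(n_parent)
    else:
        n_off = draw_cell_count(genotype.genetic_mean_count, params.cv_n, rng)
        perm = rng.permutation(n_parent)
        parent_idx = perm[np.arange(n_off) % n_parent]
    modifier = draw_env_modifier(params.sigma_env, rng)
    base = draw_cell_size(
        genotype.genetic_mean_size, params.sigma, rng, size=n_off)
    child = CollectiveRecord(
        id=collective_id,
        genotype_id=genotype.id,
        generation=parent.generation + 1,
        env_modifier=modifier,
        cell_phenotypes=np.asarray(base, dtype=float) * modifier,
        parent_id=parent.id,
    )
    return child, parent_idx


def reproduce_collective(
    parent: CollectiveRecord, genotype: GenotypeSpec,
    params: SimulationParams, rng: np.random.Generator,
    id_start: int = 0,
) -> tuple[CollectiveRecord, CollectiveRecord, PedigreeTable]:
    """Split one collective into two offspring and record pedigree rows.

    Each parent cell divides once, contributing one daughter to *each*
    offspring collective; both daughters form (parent, daughter) regression
    pairs.  With ``cv_n > 0`` offspring cell slots are matched to parent
    cells by cycling through a random permutation of the parent cells, so a
    surplus of slots reuses parents and a deficit leaves some unpaired.

    One call is one collective-level reproductive event; with ``cv_n = 0``
    it is also ``n_parent`` cell-level division events.
    """
    if parent.n_cells < 1:
        raise InvalidStateError("cannot reproduce an empty collective")
    if genotype.id != parent.genotype_id:
        raise InvalidStateError("genotype does not match parent's genotype_id")
    rows = PedigreeTable()
    children = []
    used_parents: set[int] = set()
    for k in range(2):
        child, parent_idx = _offspring(
            parent, genotype, params, rng, collective_id=id_start + k)
        rows.cell_parent_values.extend(parent.cell_phenotypes[parent_idx])
        rows.cell_offspring_values.extend(child.cell_phenotypes)
        rows.collective_links.append((parent, child))
        used_parents.update(parent_idx.tolist())
        children.append(child)
    rows.n_collective_events = 1
    rows.n_cell_events = len(used_parents)
    return children[0], children[1], rows


def grow_population(
    params: SimulationParams,
    seed_sequence: np.random.SeedSequence | None = None,
) -> tuple[list[list[CollectiveRecord]], PedigreeTable]:
    """Grow every founder clone for ``params.generations`` doublings.

    Returns the generation-indexed populations (``populations[g]`` is the
    list of all collectives alive at generation ``g``) and the pooled
    pedigree of all generations.  Each genotype lineage consumes its own
    child RNG stream spawned from the master seed, so lineages are
    independent and insensitive to execution order.
    """
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(params.seed)
    specs = genotype_specs(params)
    streams = seed_sequence.spawn(len(specs))
    populations: list[list[CollectiveRecord]] = [
        [] for _ in range(params.generations + 1)]
    pedigree = PedigreeTable()
    next_id = 0
    for genotype, stream in zip(specs, streams):
        rng = np.random.default_rng(stream)
        current = [_make_founder(genotype, params, rng, collective_id=next_id)]
        next_id += 1
        populations[0].extend(current)
        for g in range(params.generations):
            offspring: list[CollectiveRecord] = []
            for parent in current:
                a, b, rows = reproduce_collective(
                    parent, genotype, params, rng, id_start=next_id)
                next_id += 2
                offspring.extend((a, b))
                pedigree.extend(rows)
            current = offspring
            populations[g + 1].extend(current)
    return populations, pedigree


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

LONG_COLUMNS = ("level", "id", "parent_id", "genotype", "generation", "value")


def population_to_frame(populations: Sequence[Sequence[CollectiveRecord]]):
    """Long-format table of a run for inspection.

    One row per collective (``level == 'collective'``, value = env modifier)
    and one per member cell (``level == 'cell'``, id = enclosing collective,
    value = realized phenotype).  Column order is fixed to ``LONG_COLUMNS``.
    """
    import pandas as pd

    rows = []
    for generation in populations:
        for rec in generation:
            rows.append(("collective", rec.id, rec.parent_id,
                         rec.genotype_id, rec.generation, rec.env_modifier))
            rows.extend(
                ("cell", rec.id, rec.parent_id,
                 rec.genotype_id, rec.generation, float(v))
                for v in rec.cell_phenotypes
            )
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))
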