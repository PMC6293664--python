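"""Broad-sense heritability estimators at two hierarchical levels.

Two estimation routes are provided:

* a nested-ANOVA sums-of-squares route for balanced clonal designs
  (``a`` clones x ``b`` collectives per clone x ``c`` particles per
  collective), in which particle-level heritability is approximated by
  SSA / SST and collective-level heritability by SSa / (SSa + SS(b/a)),
  yielding the ratio

      H2_z / H2_y  ~=  (SSA + SS(B/A) + SS(C/B)) / (SSA + SS(B/A)),

  which is >= 1 for any linear collective trait with fixed particle number
  and equals 1 exactly when particles within every collective share one
  phenotype;

* a parent-offspring regression route for simulation output, in which the
  heritability of a trait at either level is the OLS slope of offspring
  value on parent value, pooled over all recorded reproductive events.

Heritability here is broad-sense (clonal reproduction): the fraction of
phenotypic variance attributable to all genetic differences among clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, InvalidInputError
from .growth_model import CollectiveRecord, PedigreeTable
from .trait_maps import get_trait_map

LONG_COLUMNS = ("clone", "collective", "particle", "value")


# ---------------------------------------------------------------------------
# nested phenotype tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NestedPhenotypeTable:
    """Balanced nested phenotypes, shape (clones, collectives, particles)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3 or arr.size == 0:
            raise InvalidInputError(
                "values must be a nonempty (a, b, c) array; unbalanced "
                "designs are not supported")
        if not np.isfinite(arr).all():
            raise InvalidInputError("values must be finite")
        object.__setattr__(self, "values", arr)

    @property
    def a(self) -> int:
        return self.values.shape[0]

    @property
    def b(self) -> int:
        return self.values.shape[1]

    @property
    def c(self) -> int:
        return self.values.shape[2]

    def collective_means(self) -> np.ndarray:
        """Within-collective mean phenotypes, shape (a, b)."""
        return self.values.mean(axis=2)

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "NestedPhenotypeTable":
        """Build from a long table with columns clone/collective/particle/value.

        The design must be balanced: every clone the same number of
        collectives and every collective the same number of particles.
        Labels are ordered by first appearance within their parent group.
        """
        missing = set(LONG_COLUMNS) - set(frame.columns)
        if missing:
            raise InvalidInputError(f"missing columns: {sorted(missing)}")
        if frame.empty:
            raise InvalidInputError("empty table")
        blocks = []
        width = None
        depth = None
        for _, clone_df in frame.groupby("clone", sort=True):
            rows = []
            for _, coll_df in clone_df.groupby("collective", sort=True):
                vals = coll_df["value"].to_numpy(dtype=float)
                if depth is None:
                    depth = len(vals)
                elif len(vals) != depth:
                    raise InvalidInputError(
                        "unbalanced design: unequal particles per collective")
                rows.append(vals)
            if width is None:
                width = len(rows)
            elif len(rows) != width:
                raise InvalidInputError(
                    "unbalanced design: unequal collectives per clone")
            blocks.append(rows)
        return cls(np.array(blocks, dtype=float))

    @classmethod
    def read_csv(cls, path) -> "NestedPhenotypeTable":
        return cls.from_long(pd.read_csv(path))

    def to_long_frame(self) -> pd.DataFrame:
        a, b, c = self.values.shape
        clone, coll, part = np.meshgrid(
            np.arange(a), np.arange(b), np.arange(c), indexing="ij")
        return pd.DataFrame({
            "clone": clone.ravel(),
            "collective": coll.ravel(),
            "particle": part.ravel(),
            "value": self.values.ravel(),
        })


def simulate_nested_table(
    a: int, b: int, c: int,
    var_a: float, var_b: float, var_c: float,
    mean: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NestedPhenotypeTable:
    """Generate a balanced table with known additive variance components.

    Phenotypes follow y_ijk = m + A_i + B_j(i) + C_k(ij) with independent
    zero-mean normal effects of variance ``var_a`` (among clones),
    ``var_b`` (among collectives within clones) and ``var_c`` (among
    particles within collectives).
    """
    if rng is None:
        rng = np.random.default_rng()
    if min(var_a, var_b, var_c) < 0:
        raise InvalidInputError("variance components must be >= 0")
    A = rng.normal(0.0, np.sqrt(var_a), size=(a, 1, 1))
    B = rng.normal(0.0, np.sqrt(var_b), size=(a, b, 1))
    C = rng.normal(0.0, np.sqrt(var_c), size=(a, b, c))
    return NestedPhenotypeTable(mean + A + B + C)


def population_to_nested_table(
    populations: Sequence[Sequence[CollectiveRecord]],
    generation: int = -1,
) -> NestedPhenotypeTable:
    """Arrange one generation of a fixed-size run as a balanced nested table.

    Clones index the first axis, that genotype's collectives the second,
    member cells the third.  Requires a balanced generation (equal
    collectives per genotype and cells per collective, i.e. ``cv_n = 0``).
    """
    gen = populations[generation]
    if not gen:
        raise InvalidInputError("empty generation")
    by_clone: dict[int, list[np.ndarray]] = {}
    for rec in gen:
        by_clone.setdefault(rec.genotype_id, []).append(rec.cell_phenotypes)
    rows = [by_clone[k] for k in sorted(by_clone)]
    try:
        return NestedPhenotypeTable(np.array(rows, dtype=float))
    except ValueError as exc:  # ragged
        raise InvalidInputError(
            "generation is unbalanced (variable collective or cell counts)"
        ) from exc


# ---------------------------------------------------------------------------
# sums of squares
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSComponents:
    """Nested sums of squares at the particle and/or collective level.

    Particle-level components (from a clone x collective x particle table):
    ``ssa`` among clones, ``ss_b_a`` among collectives within clones,
    ``ss_c_b`` among particles within collectives, ``sst`` their total.
    Collective-level analogues (from collective trait values z_ij):
    ``ss_alpha``, ``ss_beta_alpha``, ``sst_z``.  Fields not produced by the
    originating computation are ``None``.
    """

    ssa: float | None = None
    ss_b_a: float | None = None
    ss_c_b: float | None = None
    sst: float | None = None
    ss_alpha: float | None = None
    ss_beta_alpha: float | None = None
    sst_z: float | None = None


def nested_ss(table: NestedPhenotypeTable) -> SSComponents:
    """Partition particle phenotypic variation into nested sums of squares.

    SSA        = b c sum_i (ybar_i.. - ybar_...)^2
    SS(B/A)    = c sum_ij (ybar_ij. - ybar_i..)^2
    SS(C/B)    = sum_ijk (y_ijk - ybar_ij.)^2
    SST        = SSA + SS(B/A) + SS(C/B)
    """
    y = table.values
    a, b, c = y.shape
    grand = y.mean()
    clone_means = y.mean(axis=(1, 2))
    coll_means = y.mean(axis=2)
    ssa = b * c * float(((clone_means - grand) ** 2).sum())
    ss_b_a = c * float(((coll_means - clone_means[:, None]) ** 2).sum())
    ss_c_b = float(((y - coll_means[:, :, None]) ** 2).sum())
    return SSComponents(ssa=ssa, ss_b_a=ss_b_a, ss_c_b=ss_c_b,
                        sst=ssa + ss_b_a + ss_c_b)


def collective_ss(z_values) -> SSComponents:
    """Sums of squares of collective trait values z_ij (shape (a, b)).

    SSa        = b sum_i (zbar_i. - zbar_..)^2
    SS(b/a)    = sum_ij (z_ij - zbar_i.)^2
    SST_z      = SSa + SS(b/a)
    """
    z = np.asarray(z_values, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise InvalidInputError(
            "z_values must be a nonempty (a, b) array; unbalanced designs "
            "are not supported")
    b = z.shape[1]
    grand = z.mean()
    clone_means = z.mean(axis=1)
    ss_alpha = b * float(((clone_means - grand) ** 2).sum())
    ss_beta_alpha = float(((z - clone_means[:, None]) ** 2).sum())
    return SSComponents(ss_alpha=ss_alpha, ss_beta_alpha=ss_beta_alpha,
                        sst_z=ss_alpha + ss_beta_alpha)


# ---------------------------------------------------------------------------
# heritability estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeritabilityEstimate:
    """A single heritability estimate and the route that produced it.

    ``ss_ratio`` estimates lie in [0, 1] by construction; regression slopes
    (``po_regression``) may stochastically fall outside [0, 1] and are
    reported unclipped.
    """

    h2: float
    method: str


def particle_H2(ss: SSComponents) -> HeritabilityEstimate:
    """Particle-level broad-sense heritability, SSA / SST."""
    if ss.ssa is None or ss.sst is None:
        raise InvalidInputError("particle-level sums of squares required")
    if ss.sst == 0:
        raise DegenerateVarianceError("no phenotypic variance among particles")
    return HeritabilityEstimate(h2=ss.ssa / ss.sst, method="ss_ratio")


def collective_H2(ss: SSComponents) -> HeritabilityEstimate:
    """Collective-level broad-sense heritability, SSa / (SSa + SS(b/a))."""
    if ss.ss_alpha is None or ss.sst_z is None:
        raise InvalidInputError("collective-level sums of squares required")
    if ss.sst_z == 0:
        raise DegenerateVarianceError(
            "no phenotypic variance among collectives")
    return HeritabilityEstimate(h2=ss.ss_alpha / ss.sst_z, method="ss_ratio")


def heritability_ratio(ss: SSComponents) -> float:
    """Collective-to-particle heritability ratio from particle-level SS.

    For a linear collective trait with fixed particle number the ratio is
    (SSA + SS(B/A) + SS(C/B)) / (SSA + SS(B/A)): never below 1, and equal
    to 1 only when SS(C/B) = 0.
    """
    if None in (ss.ssa, ss.ss_b_a, ss.ss_c_b):
        raise InvalidInputError("particle-level sums of squares required")
    denom = ss.ssa + ss.ss_b_a
    if denom == 0:
        raise DegenerateVarianceError(
            "SSA + SS(B/A) = 0: ratio undefined (no among-collective "
            "variation)")
    return (ss.ssa + ss.ss_b_a + ss.ss_c_b) / denom


def po_slope(pairs) -> float:
    """OLS slope of offspring value on parent value."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InvalidInputError("need at least two (parent, offspring) pairs")
    parent, offspring = arr[:, 0], arr[:, 1]
    if np.ptp(parent) == 0:
        raise DegenerateVarianceError(
            "parent values have zero variance (degenerate population, "
            "e.g. sigma = sigma_env = 0)")
    return float(stats.linregress(parent, offspring).slope)


def relative_heritability(
    pedigree: PedigreeTable,
    trait_map: str | Callable[[np.ndarray], float],
) -> tuple[float, float, float]:
    """Cell-level slope, collective-level slope, and their ratio.

    The trait map (name or callable) converts each collective's member-cell
    phenotypes into its trait value; both regressions pool all recorded
    reproductive events of the run.
    """
    if isinstance(trait_map, str):
        trait_map = get_trait_map(trait_map)
    slope_cell = po_slope(pedigree.cell_pairs)
    slope_collective = po_slope(pedigree.collective_trait_pairs(trait_map))
    return slope_cell, slope_collective, slope_collective / slope_cell


# ---------------------------------------------------------------------------
# sums-of-squares vs variance-ratio approximation error
# ---------------------------------------------------------------------------

def expected_nested_ss(
    var_a: float, var_b: float, var_c: float, a: int, b: int, c: int,
) -> SSComponents:
    """Closed-form expectations of the nested SS in a balanced random-effects design.

    E[SSA]     = (a-1) (s2_C + c s2_B + b c s2_A)
    E[SS(B/A)] = a (b-1) (s2_C + c s2_B)
    E[SS(C/B)] = a b (c-1) s2_C
    """
    if min(a, b, c) < 1:
        raise InvalidInputError("a, b, c must be >= 1")
    if min(var_a, var_b, var_c) < 0:
        raise InvalidInputError("variance components must be >= 0")
    e_ssa = (a - 1) * (var_c + c * var_b + b * c * var_a)
    e_ssb = a * (b - 1) * (var_c + c * var_b)
    e_ssc = a * b * (c - 1) * var_c
    return SSComponents(ssa=e_ssa, ss_b_a=e_ssb, ss_c_b=e_ssc,
                        sst=e_ssa + e_ssb + e_ssc)


def ss_vs_variance_error(
    var_a: float, var_b: float, var_c: float, a: int, b: int, c: int,
) -> float:
    """Relative error (percent) of the SS-ratio heritability ratio.

    Compares, for a balanced design with known variance components, (i) the
    exact variance-ratio definition of the collective-to-particle
    heritability ratio with the collective trait taken as the
    within-collective mean,

        (s2_A + s2_B + s2_C) / (s2_A + s2_B + s2_C / c),

    against (ii) the same ratio computed from the closed-form *expected*
    sums of squares, so the comparison is deterministic.  The discrepancy
    is a finite-sample (degrees-of-freedom) effect that vanishes as a and b
    grow.
    """
    if var_a + var_b + var_c == 0:
        raise DegenerateVarianceError("all variance components are zero")
    true_ratio = (var_a + var_b + var_c) / (var_a + var_b + var_c / c)
    ess = expected_nested_ss(var_a, var_b, var_c, a, b, c)
    denom = ess.ssa + ess.ss_b_a
    if denom == 0:
        raise DegenerateVarianceError(
            "expected SSA + SS(B/A) = 0 for this design")
    ss_ratio = ess.sst / denom
    return abs(ss_ratio - true_ratio) / true_ratio * 100.0
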