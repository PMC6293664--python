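"""Maps from a collective's member-cell phenotypes to one collective trait.

Four biologically motivated traits are provided:

``volume``
    Collective volume, the sum of member cell sizes (sizes read as volumes).
``diameter``
    Diameter of the sphere the cells would form if pressed tightly
    together, d = 2 (3V / 4 pi)^(1/3).
``swim``
    Upward swimming speed of an undifferentiated flagellated colony.  With
    cell swimming force independent of cell size, heavier (larger) cells
    make the colony more negatively buoyant, so speed declines
    monotonically with mean cell radius:
    V_up = (f N^0.5 / 3 pi eta_w) r^-1 - (g dRho_c (4/3) N^2 / 3 eta_w) r^2.
    The default mode uses the literature's simplified numeric form
    V_up = (0.02/pi) r^-1 - (400/3) r^2; the general mode takes explicit
    physical constants.
``survival``
    Survival rate against a gape-limited predator, a logistic function of
    collective radius: 1 / (1 + exp(-0.5 (0.5 r N^0.5 - 25))).

Phenotype semantics: the growth model produces a generic positive "cell
size".  The volume map reads it as a cell *volume* (collective volume is
the plain sum, the canonical linear trait).  The diameter, swim and
survival maps read it as a cell *radius*: the diameter trait treats each
cell as a sphere of volume (4 pi / 3) s^3 before applying the printed
diameter formula, and swim/survival use the within-collective mean radius.
The radius reading keeps the environmental modifier acting linearly on the
diameter trait, which is what makes collective diameter heritability
dominate cell-level heritability across the whole noise plane; reading the
sizes as volumes there would push the ratio slightly below 1 where
environmental noise dominates developmental noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, ParameterError

__all__ = [
    "SwimParams", "PredationParams",
    "collective_volume", "collective_diameter",
    "upward_swim_speed", "survival_rate", "mean_cell_radius",
    "TRAIT_MAPS", "get_trait_map",
]


@dataclass(frozen=True)
class SwimParams:
    """Physical constants of the general upward-swimming-speed model (CGS units)."""

    f: float = 2.4e-7           # per-cell upward swimming force, g*cm/s^2
    eta_w: float = 0.01         # water viscosity, g/(cm*s)
    delta_rho_c: float = 0.047  # cell-water density difference, g/cm^3
    g_accel: float = 980.665    # gravitational acceleration, cm/s^2
    N: int = 32                 # cells per collective

    def __post_init__(self) -> None:
        for name in ("f", "eta_w", "delta_rho_c", "g_accel", "N"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class PredationParams:
    """Logistic predation-survival curve parameters."""

    steepness: float = 0.5
    radius_coeff: float = 0.5
    offset: float = 25.0
    N: int = 32

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ParameterError("N must be >= 1")


def _as_sizes(cell_sizes) -> np.ndarray:
    arr = np.asarray(cell_sizes, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cell_sizes must be nonempty")
    return arr


def collective_volume(cell_sizes) -> float:
    """Sum of member cell volumes."""
    return float(_as_sizes(cell_sizes).sum())


def collective_diameter(cell_sizes) -> float:
    """Diameter of a sphere of volume equal to the summed cell volumes."""
    v = collective_volume(cell_sizes)
    return 2.0 * (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)


def mean_cell_radius(cell_sizes) -> float:
    """Arithmetic mean of member sizes, read as the average cell radius r."""
    return float(_as_sizes(cell_sizes).mean())


def upward_swim_speed(
    mean_cell_radius: float, params: SwimParams | None = None,
) -> float:
    """Upward swimming speed at the given mean cell radius (may be negative).

    With ``params=None`` evaluates the simplified numeric form
    (0.02/pi) / r - (400/3) r^2, the default model.  With explicit
    :class:`SwimParams` evaluates the general physical form.  The two share
    the shape c1/r - c2 r^2; no numerical equivalence between the default
    coefficients and any particular parameter set is asserted.
    """
    r = float(mean_cell_radius)
    if r <= 0:
        raise InvalidInputError("mean_cell_radius must be positive")
    if params is None:
        return (0.02 / math.pi) / r - (400.0 / 3.0) * r * r
    buoyancy = (params.g_accel * params.delta_rho_c * (4.0 / 3.0)
                * params.N ** 2) / (3.0 * params.eta_w)
    thrust = (params.f * params.N ** 0.5) / (3.0 * math.pi * params.eta_w)
    return thrust / r - buoyancy * r * r


def survival_rate(
    mean_cell_radius: float, params: PredationParams | None = None,
) -> float:
    """Predation survival in (0, 1), logistic in collective radius.

    The argument of the logistic is steepness * (radius_coeff * r * sqrt(N)
    - offset); with the defaults the half-survival point sits where
    0.5 r sqrt(N) = 25.
    """
    if params is None:
        params = PredationParams()
    r = float(mean_cell_radius)
    if r < 0:
        raise InvalidInputError("mean_cell_radius must be >= 0")
    x = params.steepness * (params.radius_coeff * r * math.sqrt(params.N)
                            - params.offset)
    # scipy.special.expit semantics, kept local to avoid overflow warnings
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# registry: name -> map from a collective's cell sizes to its trait value
# ---------------------------------------------------------------------------

def _diameter_map(cell_sizes) -> float:
    # sizes read as radii: each cell a sphere of volume (4 pi / 3) s^3
    sizes = _as_sizes(cell_sizes)
    return collective_diameter((4.0 * math.pi / 3.0) * sizes ** 3)


def _swim_map(cell_sizes) -> float:
    return upward_swim_speed(mean_cell_radius(cell_sizes))


def _survival_map(cell_sizes) -> float:
    sizes = _as_sizes(cell_sizes)
    params = PredationParams(N=sizes.size)
    return survival_rate(float(sizes.mean()), params)


TRAIT_MAPS = {
    "volume": collective_volume,
    "diameter": _diameter_map,
    "swim": _swim_map,
    "survival": _survival_map,
}


def get_trait_map(name: str):
    """Resolve a trait map by its registry name."""
    try:
        return TRAIT_MAPS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown trait map {name!r}; choose from {sorted(TRAIT_MAPS)}"
        ) from None
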