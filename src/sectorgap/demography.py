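"""Per-year demographic transitions: growth, mortality, recruitment.

Growth is potential-times-limitation: the dbh increment is the species'
potential increment scaled by the resource limitation factor
``lambda = S * W`` (multiplicative) or ``min(S, W)`` (Liebig's law of
the minimum). Crown sector radii expand by ``rho`` metres per cm of dbh
increment, starting from the realized (competition-limited) radii.

Mortality combines a species-specific light-limitation probability —
``P_L`` scaled by a convex function of the light deficit,
``P_L * (1 - S)**q`` with shape exponent q = 5, so a fully overtopped
tree dies at a rate of order its tabulated understory mortality
(0.62 * P_L at the 9% transparency floor) while moderately crowded
canopy trees face only a small fraction of it — with a
species-independent water-limitation probability
``P_W = P_max * (1 - W)``, combined either additively
(``1 - (1 - P_L)(1 - P_W)``) or capped (``max(P_L, P_W)``). Crowding
itself is therefore lethal: a canopy tree whose realized crown is far
smaller than its allometric potential carries elevated mortality, which
is what keeps gap dynamics alive with no extra background rate.

Recruitment adds a Poisson number of saplings per year (rate ``nu`` per
hectare) at uniform random positions, with dbh drawn uniformly between
3 and 5 cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import SpeciesParams, make_species_pair
from .stand import StandState, Tree, new_sapling

__all__ = [
    "MechanismConfig",
    "growth_modifier",
    "potential_increment",
    "grow",
    "light_mortality",
    "water_mortality",
    "mortality_probability",
    "apply_mortality",
    "recruit",
]


@dataclass
class MechanismConfig:
    """Mechanism switches and demographic rates.

    growth_mechanism: 'multiplicative' (lambda = S*W) or 'liebig'
        (lambda = min(S, W)).
    mortality_mechanism: 'additive' or 'capped' combination of the light
        and water mortality probabilities.
    P_max: maximal water-limitation mortality (at W = 0).
    background_mortality: optional floor on the annual death probability
        of every tree (0 by default; light and water limitation already
        sustain turnover).
    light_mortality_exponent: shape q of the shade-mortality response
        P_L * (1 - S)**q; larger q confines light-limitation deaths to
        strongly suppressed trees.
    recruitment_rate: saplings per hectare per year (nu).
    pri_variant: 'constant' potential increment (b1 cm/yr) or
        'saturating' (b1 * (1 - dbh / b2)).
    """

    growth_mechanism: str = "multiplicative"
    mortality_mechanism: str = "capped"
    P_max: float = 0.20
    background_mortality: float = 0.0
    light_mortality_exponent: float = 5.0
    recruitment_rate: float = 40.0
    pri_variant: str = "saturating"

    def __post_init__(self) -> None:
        if self.growth_mechanism not in ("multiplicative", "liebig"):
            raise ValueError(f"unknown growth mechanism {self.growth_mechanism!r}")
        if self.mortality_mechanism not in ("additive", "capped"):
            raise ValueError(f"unknown mortality mechanism {self.mortality_mechanism!r}")
        if not 0.0 <= self.P_max <= 1.0:
            raise ValueError("P_max must be in [0,1]")
        if self.recruitment_rate < 0:
            raise ValueError("recruitment rate must be non-negative")


def growth_modifier(S: float, W: float, mechanism: str = "multiplicative") -> float:
    """Resource limitation factor lambda from the light and water ratios."""
    S, W = float(S), float(W)
    if not (0.0 <= S <= 1.0 and 0.0 <= W <= 1.0):
        raise ValueError("S and W must be in [0,1]")
    if mechanism == "multiplicative":
        return S * W
    if mechanism == "liebig":
        return min(S, W)
    raise ValueError(f"unknown growth mechanism {mechanism!r}")


def potential_increment(dbh: float, sp: SpeciesParams, variant: str = "constant") -> float:
    """Potential (unlimited) annual dbh increment, cm/yr."""
    if variant == "constant":
        return sp.b1
    if variant == "saturating":
        return sp.b1 * max(0.0, 1.0 - dbh / sp.b2)
    raise ValueError(f"unknown potential-increment variant {variant!r}")


def grow(tree: Tree, lam: float, *, pri_variant: str = "constant") -> None:
    """Advance one tree by a year of resource-limited growth.

    dbh increases by ``lam * PRI(dbh)``; every sector radius increases by
    ``rho`` times the dbh increment (on top of this year's realized
    radius); age increments even under full suppression (lam = 0).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0,1]")
    inc = lam * potential_increment(tree.dbh, tree.species, pri_variant)
    tree.dbh += inc
    tree.sector_radii = tree.sector_radii + tree.species.rho_crown * inc
    tree.age += 1


def light_mortality(tree: Tree, background: float = 0.0, exponent: float = 5.0) -> float:
    """Effective light-limitation mortality for this year.

    The species' shade-intolerance mortality ``P_L`` scaled by a convex
    power of the light deficit, ``(1 - S)**exponent``: a fully overtopped
    tree (S at the transparency floor) dies at ~0.62 * P_L per year, an
    unrestricted tree (S = 1) not at all, and a moderately crowded
    canopy tree at only a small fraction of P_L; ``background`` is an
    optional floor.
    """
    return max(tree.species.P_L * (1.0 - tree.S) ** exponent, background)


def water_mortality(W: float, P_max: float) -> float:
    """Water-limitation mortality P_W = P_max * (1 - W), species independent."""
    return P_max * (1.0 - float(W))


def mortality_probability(P_L_eff: float, P_W: float, mechanism: str = "capped") -> float:
    """Combine the two mortality sources.

    'additive' is the probability of failing to survive both hazards,
    ``1 - (1 - P_L)(1 - P_W)``; 'capped' is the most threatening single
    hazard, ``max(P_L, P_W)``. Additive >= capped always.
    """
    if mechanism == "additive":
        return 1.0 - (1.0 - P_L_eff) * (1.0 - P_W)
    if mechanism == "capped":
        return max(P_L_eff, P_W)
    raise ValueError(f"unknown mortality mechanism {mechanism!r}")


def apply_mortality(stand: StandState, mech: MechanismConfig) -> list[Tree]:
    """Draw survival for every tree (one uniform per tree, id order).

    Dead trees are removed from the stand immediately, releasing their
    light and water from the next allocation on. Returns the casualties.
    """
    dead: list[Tree] = []
    survivors: list[Tree] = []
    for tree in sorted(stand.trees, key=lambda t: t.id):
        p_l = light_mortality(
            tree, mech.background_mortality, mech.light_mortality_exponent
        )
        p_w = water_mortality(tree.W, mech.P_max)
        p = mortality_probability(p_l, p_w, mech.mortality_mechanism)
        if stand.rng.random() < p:
            dead.append(tree)
        else:
            survivors.append(tree)
    stand.trees = survivors
    return dead


def recruit(
    stand: StandState,
    nu: float,
    rng: np.random.Generator | None = None,
    species: tuple[SpeciesParams, ...] | None = None,
    probs=None,
    species_sampler=None,
) -> list[Tree]:
    """Add this year's saplings: Poisson(nu * area_ha) uniform recruits.

    Species are drawn with equal probability among ``species`` (the two
    prototypes by default) unless ``probs`` is given; alternatively a
    ``species_sampler(rng) -> SpeciesParams`` callable draws each
    recruit's parameterization (used for the continuum-of-species
    experiments).
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    if rng is None:
        rng = stand.rng
    if species is None:
        species = make_species_pair()
    n = rng.poisson(nu * stand.area_ha)
    recruits: list[Tree] = []
    for _ in range(n):
        x = rng.uniform(0.0, stand.plot_width)
        y = rng.uniform(0.0, stand.plot_height)
        if species_sampler is not None:
            sp = species_sampler(rng)
        else:
            sp = species[rng.choice(len(species), p=probs)]
        sapling = new_sapling(x, y, sp, rng, tree_id=stand.take_id())
        stand.add_tree(sapling)
        recruits.append(sapling)
    return recruits
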