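"""Species parameterization and dbh-height allometry.

Two prototype conifers with contrasting shade tolerance are built in:
a fast-growing, shade-intolerant white pine (*Pinus strobus*) and a
slow-growing, shade-tolerant eastern hemlock (*Tsuga canadensis*).
The shade-tolerance trade-off is purely demographic — it emerges from
the growth coefficient ``b1`` and the understory mortality ``P_L`` —
there is no physiological shade/drought trade-off anywhere in the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpeciesParams",
    "make_species_pair",
    "tree_height",
    "interpolate_species",
]

#: Breast height (m): dbh is measured here, so allometric height starts at it.
BREAST_HEIGHT = 1.35


@dataclass(frozen=True)
class SpeciesParams:
    """All per-species constants.

    Parameters
    ----------
    name : str
        Species label used in tree tables.
    b1 : float
        Potential growth coefficient (cm/yr): the annual dbh increment a
        tree achieves with no resource limitation (constant-increment
        potential growth; see ``demography.potential_increment``).
    b2 : float
        Asymptotic dbh (cm) of the optional saturating growth variant.
    b3 : float
        Reserved auxiliary growth constant (unused by the default form).
    gamma : float
        Crown shape exponent of the sector profile; 0.5 gives the
        square-root crown outline used for both prototypes.
    rho_crown : float
        Crown-radius increment per unit dbh increment (m/cm).
    alpha_root : float
        Root-system radial extent per unit dbh (m/cm).
    P_L : float
        Annual light-limitation (understory) mortality probability.
    tol_rank : float
        Shade-tolerance ranking in [0, 1]; 0 = intolerant, 1 = tolerant.
    h_max : float
        Asymptotic height (m) of the dbh-height allometry.
    h_k : float
        Allometry curvature (1/cm).
    """

    name: str
    b1: float
    P_L: float
    tol_rank: float
    h_max: float
    b2: float = 150.0
    b3: float = 0.0
    gamma: float = 0.5
    rho_crown: float = 0.1
    alpha_root: float = 0.07
    h_k: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.P_L <= 1.0:
            raise ValueError(f"P_L must be in [0,1], got {self.P_L}")
        if not 0.0 <= self.tol_rank <= 1.0:
            raise ValueError(f"tol_rank must be in [0,1], got {self.tol_rank}")
        if self.b1 <= 0:
            raise ValueError(f"b1 must be positive, got {self.b1}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def make_species_pair() -> tuple[SpeciesParams, SpeciesParams]:
    """Return the two default parameterizations (white pine, eastern hemlock).

    Growth coefficients and understory mortalities follow the published
    calibration of this species pair (b1 = 0.77134 vs 0.3498 cm/yr;
    P_L = 20% vs 1%); crown/root scaling and allometry constants are
    package defaults chosen so that pine outgrows hemlock at full
    resources, adult crowns span several metres, and adult root systems
    of neighbours overlap at closed-canopy densities.
    """
    white_pine = SpeciesParams(
        name="white_pine",
        b1=0.77134,
        P_L=0.20,
        tol_rank=0.0,
        h_max=40.0,
        b2=150.0,
    )
    eastern_hemlock = SpeciesParams(
        name="eastern_hemlock",
        b1=0.3498,
        P_L=0.01,
        tol_rank=1.0,
        h_max=30.0,
        b2=120.0,
    )
    return white_pine, eastern_hemlock


def tree_height(dbh: float, sp: SpeciesParams) -> float:
    """Tree height (m) from dbh (cm) by a saturating allometry.

    height = 1.35 + (h_max - 1.35) * (1 - exp(-k * dbh)); strictly
    increasing in dbh and bounded above by ``sp.h_max``.
    """
    dbh = np.asarray(dbh, dtype=float) if not np.isscalar(dbh) else dbh
    if np.any(np.asarray(dbh) <= 0):
        raise ValueError("dbh must be positive")
    return BREAST_HEIGHT + (sp.h_max - BREAST_HEIGHT) * (1.0 - np.exp(-sp.h_k * dbh))


_INTERP_FIELDS = (
    "b1", "b2", "b3", "gamma", "rho_crown", "alpha_root",
    "P_L", "tol_rank", "h_max", "h_k",
)


def interpolate_species(
    alpha: float,
    pair: tuple[SpeciesParams, SpeciesParams] | None = None,
    *,
    pine_at_one: bool = True,
) -> SpeciesParams:
    """Componentwise linear blend of the two prototype parameter vectors.

    With the default orientation ``alpha = 1`` returns the white-pine
    vector and ``alpha = 0`` the eastern-hemlock vector, so the blended
    shade-tolerance rank is ``1 - alpha``. The opposite orientation
    (pine at 0) is exposed because the two conventions coexist in the
    literature on this parameterization; ``alpha = 0.5`` is identical
    under both.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    pine, hemlock = pair if pair is not None else make_species_pair()
    hi, lo = (pine, hemlock) if pine_at_one else (hemlock, pine)
    blended = {
        f: alpha * getattr(hi, f) + (1.0 - alpha) * getattr(lo, f)
        for f in _INTERP_FIELDS
    }
    return SpeciesParams(name=f"alpha_{alpha:.4f}", **blended)
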