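"""Individual trees, the stand container, and tree-table serialization.

A stand is a toroidal rectangular plot rasterised at a fixed pixel
resolution (default 10 cm). Stems live at continuous coordinates; the
pixel grid is half-open, pixel (i, j) covering
[i*px, (i+1)*px) x [j*px, (j+1)*px). Toroidal wrap-around keeps edge
trees under full competition instead of releasing them at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import SpeciesParams, make_species_pair, tree_height

__all__ = ["Tree", "StandState", "new_sapling", "write_stand", "read_stand"]

N_SECTORS = 8


@dataclass
class Tree:
    """One individual: stem position, size, and the 8-sector crown state."""

    id: int
    species: SpeciesParams
    x: float
    y: float
    dbh: float
    age: int = 0
    sector_radii: np.ndarray = None  # type: ignore[assignment]
    live_crown_ratios: np.ndarray = None  # type: ignore[assignment]
    S: float = 1.0
    S_growth: float = 1.0
    W: float = 1.0
    canopy_flag: bool = False

    def __post_init__(self) -> None:
        if self.dbh <= 0:
            raise ValueError(f"dbh must be positive, got {self.dbh}")
        if self.sector_radii is None:
            self.sector_radii = np.full(N_SECTORS, self.species.rho_crown * self.dbh)
        else:
            self.sector_radii = np.asarray(self.sector_radii, dtype=float)
        if self.live_crown_ratios is None:
            self.live_crown_ratios = np.ones(N_SECTORS)
        else:
            self.live_crown_ratios = np.asarray(self.live_crown_ratios, dtype=float)
        if np.any(self.sector_radii < 0):
            raise ValueError("sector radii must be non-negative")
        if np.any((self.live_crown_ratios < 0) | (self.live_crown_ratios > 1)):
            raise ValueError("live crown ratios must be in [0,1]")

    @property
    def height(self) -> float:
        """Height (m) from the species allometry."""
        return float(tree_height(self.dbh, self.species))

    @property
    def root_extent(self) -> float:
        """Radial extent (m) of the circular root system, alpha * dbh."""
        return self.species.alpha_root * self.dbh

    @property
    def basal_area(self) -> float:
        """Stem cross-section (m^2), pi * (dbh/200)^2."""
        return float(np.pi * (self.dbh / 200.0) ** 2)


@dataclass
class StandState:
    """Plot geometry, the living trees, and the stand RNG stream."""

    plot_width: float = 50.0
    plot_height: float = 50.0
    pixel: float = 0.1
    water_content: float = 6.0  # units of water per pixel, c in [0, 6]
    trees: list[Tree] = field(default_factory=list)
    year: int = 0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0)
    )
    _next_id: int = 0

    def __post_init__(self) -> None:
        if self.pixel <= 0:
            raise ValueError("pixel must be positive")
        for name, dim in (("plot_width", self.plot_width), ("plot_height", self.plot_height)):
            n = dim / self.pixel
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of pixel")

    @property
    def nx(self) -> int:
        return round(self.plot_width / self.pixel)

    @property
    def ny(self) -> int:
        return round(self.plot_height / self.pixel)

    @property
    def area_ha(self) -> float:
        return self.plot_width * self.plot_height / 10_000.0

    def take_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add_tree(self, tree: Tree) -> None:
        if not (0 <= tree.x < self.plot_width and 0 <= tree.y < self.plot_height):
            raise ValueError(f"stem ({tree.x}, {tree.y}) outside plot")
        self.trees.append(tree)
        self._next_id = max(self._next_id, tree.id + 1)


def new_sapling(
    x: float,
    y: float,
    species: SpeciesParams,
    rng: np.random.Generator,
    *,
    tree_id: int = 0,
) -> Tree:
    """Create a recruit: dbh ~ Uniform(3, 5) cm, age 0, full live crown.

    Sector radii start at rho * dbh, consistent with integrating the
    crown-radius growth rule from zero size.
    """
    dbh = rng.uniform(3.0, 5.0)
    return Tree(id=tree_id, species=species, x=x, y=y, dbh=dbh, age=0)


# -- serialization ----------------------------------------------------------

_COLUMNS = (
    ["id", "species", "x", "y", "dbh", "age"]
    + [f"r_{i}" for i in range(1, 9)]
    + [f"beta_{i}" for i in range(1, 9)]
    + ["S", "W", "canopy_flag"]
)


def stand_to_frame(stand: StandState) -> pd.DataFrame:
    rows = []
    for t in stand.trees:
        row = {
            "id": t.id, "species": t.species.name, "x": t.x, "y": t.y,
            "dbh": t.dbh, "age": t.age, "S": t.S, "W": t.W,
            "canopy_flag": t.canopy_flag,
        }
        for i in range(N_SECTORS):
            row[f"r_{i + 1}"] = t.sector_radii[i]
            row[f"beta_{i + 1}"] = t.live_crown_ratios[i]
        rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_stand(stand: StandState, path) -> None:
    """Write the tree table as UTF-8 CSV (header-only when the stand is empty).

    Floats use 17 significant digits so a write/read round trip is
    bit-lossless.
    """
    stand_to_frame(stand).to_csv(path, index=False, float_format="%.17g")


def read_stand(
    path,
    species: dict[str, SpeciesParams] | None = None,
    *,
    plot_width: float = 50.0,
    plot_height: float = 50.0,
    pixel: float = 0.1,
    water_content: float = 6.0,
    rng: np.random.Generator | None = None,
) -> StandState:
    """Read a tree table written by :func:`write_stand` into a fresh stand.

    Raises ``ValueError`` with the offending row index for malformed rows
    (non-positive dbh, unknown species label).
    """
    if species is None:
        species = {sp.name: sp for sp in make_species_pair()}
    df = pd.read_csv(path, float_precision="round_trip")
    stand = StandState(
        plot_width=plot_width, plot_height=plot_height, pixel=pixel,
        water_content=water_content,
        rng=rng if rng is not None else np.random.default_rng(0),
    )
    for idx, row in df.iterrows():
        if row["species"] not in species:
            raise ValueError(f"row {idx}: unknown species {row['species']!r}")
        if row["dbh"] <= 0:
            raise ValueError(f"row {idx}: dbh must be positive, got {row['dbh']}")
        tree = Tree(
            id=int(row["id"]),
            species=species[row["species"]],
            x=float(row["x"]), y=float(row["y"]),
            dbh=float(row["dbh"]), age=int(row["age"]),
            sector_radii=np.array([row[f"r_{i}"] for i in range(1, 9)], dtype=float),
            live_crown_ratios=np.array(
                [row[f"beta_{i}"] for i in range(1, 9)], dtype=float
            ),
            S=float(row.get("S", 1.0)), W=float(row.get("W", 1.0)),
            canopy_flag=bool(row.get("canopy_flag", False)),
        )
        stand.add_tree(tree)
    return stand
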