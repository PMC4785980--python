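"""Below-ground competition: overlapping circular root systems.

Each tree forages in a circular zone of influence of radial extent
``alpha * dbh`` centred on the stem. Unlike light, water is shared:
every pixel holds ``c`` units of water (the aridity index maps linearly
onto c in [0, 6]) and splits them among all trees whose root systems
reach it, proportionally to claim strength ``s = 1 - x_r / d_r`` (1 at
the stem, 0 at the root edge). A tree's uptake ``u_j`` sums its shares
over its whole root disc; the water uptake ratio ``W`` compares it with
the uptake the same tree would achieve alone at the base water content
of one unit per pixel, clipped at 1 so abundant water confers no
super-growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import SpeciesParams
from .stand import StandState, Tree
from .light import _window_axes

__all__ = [
    "WaterField",
    "root_extent",
    "claim_strength",
    "aridity_to_content",
    "allocate_water",
    "water_field",
    "water_ratio",
]


@dataclass
class WaterField:
    """Per-pixel view of the below-ground competition.

    ``content`` is the uniform water content c per pixel;
    ``strength_sum`` the summed claim strengths of all root systems at
    each pixel (0 where no roots reach); ``claimants`` the number of
    overlapping root systems per pixel.
    """

    content: float
    strength_sum: np.ndarray
    claimants: np.ndarray


def root_extent(dbh: float, sp: SpeciesParams) -> float:
    """Radial extent (m) of the root system: ``alpha * dbh``, linear in dbh."""
    if np.any(np.asarray(dbh) <= 0):
        raise ValueError("dbh must be positive")
    return sp.alpha_root * dbh


def claim_strength(x_r, d_r: float):
    """Water claim strength ``s = 1 - x_r / d_r`` at stem distance ``x_r``.

    1 at the stem, 0 at the root-system edge; claims outside the extent
    are an error (the tree has no roots there).
    """
    if d_r <= 0:
        raise ValueError("root extent must be positive")
    x_r = np.asarray(x_r, dtype=float)
    if np.any(x_r < 0) or np.any(x_r > d_r):
        raise ValueError("x_r must lie in [0, d_r]")
    s = np.clip(1.0 - x_r / d_r, 0.0, 1.0)
    return float(s) if s.ndim == 0 else s


def aridity_to_content(aridity_index: float) -> float:
    """Map the [0, 1] aridity index linearly to water content c in [0, 6].

    0 is very xeric (no vegetation can be sustained), indices above 0.5
    are mesic; at 1, up to six trees can share a pixel on average.
    """
    if not 0.0 <= aridity_index <= 1.0:
        raise ValueError(f"aridity index must be in [0,1], got {aridity_index}")
    return 6.0 * aridity_index


def _root_strengths(stand: StandState, tree: Tree, variant: str):
    """Claim-strength field of one tree on its local window (None if empty)."""
    R = tree.root_extent
    if R <= 0:
        return None
    ix, iy, dxv, dyv = _window_axes(stand, tree, R)
    dist = np.hypot(dxv[None, :], dyv[:, None])
    inside = dist <= R
    if not inside.any():
        return None
    s = np.where(inside, np.clip(1.0 - dist / R, 0.0, 1.0), 0.0)
    if variant == "distance_diameter":
        s = s * tree.dbh
    elif variant != "distance":
        raise ValueError(f"unknown claim variant {variant!r}")
    return ix, iy, inside, s


def allocate_water(
    stand: StandState,
    c: float | None = None,
    *,
    variant: str = "distance",
):
    """Partition per-pixel water among overlapping root systems.

    Returns ``(u, W)`` arrays aligned with ``stand.trees``: ``u[k]`` the
    realized uptake (water units) and ``W[k]`` the uptake ratio, also
    stored on each tree. ``c`` defaults to the stand's water content.
    Pixels reached by no root system keep their water unallocated.
    """
    if c is None:
        c = stand.water_content
    if c < 0:
        raise ValueError("water content must be non-negative")
    n = len(stand.trees)
    u = np.zeros(n)
    demand = np.zeros(n)
    strength_sum = np.zeros((stand.ny, stand.nx))

    fields = []
    for tree in stand.trees:
        f = _root_strengths(stand, tree, variant)
        fields.append(f)
        if f is not None:
            ix, iy, inside, s = f
            strength_sum[np.ix_(iy, ix)] += s

    for k, (tree, f) in enumerate(zip(stand.trees, fields)):
        if f is None:
            tree.W = 0.0
            continue
        ix, iy, inside, s = f
        ssum = strength_sum[np.ix_(iy, ix)]
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(ssum > 0, s / np.where(ssum > 0, ssum, 1.0), 0.0)
        u[k] = c * float(share.sum())
        demand[k] = int(inside.sum())  # uptake alone at base content c = 1
        tree.W = water_ratio_value(u[k], demand[k])
    W = np.array([t.W for t in stand.trees]) if n else np.zeros(0)
    return u, W


def water_field(
    stand: StandState,
    c: float | None = None,
    *,
    variant: str = "distance",
) -> WaterField:
    """Rasterise the summed claim strengths and overlap counts."""
    if c is None:
        c = stand.water_content
    strength_sum = np.zeros((stand.ny, stand.nx))
    claimants = np.zeros((stand.ny, stand.nx), dtype=np.int32)
    for tree in stand.trees:
        f = _root_strengths(stand, tree, variant)
        if f is not None:
            ix, iy, inside, s = f
            sub = np.ix_(iy, ix)
            strength_sum[sub] += s
            claimants[sub] += inside
    return WaterField(content=float(c), strength_sum=strength_sum,
                      claimants=claimants)


def water_ratio_value(u_j: float, demand: float) -> float:
    """W = u_j / demand, clipped to [0, 1]."""
    if demand <= 0:
        raise ValueError("zero-extent root system has no water demand")
    return float(np.clip(u_j / demand, 0.0, 1.0))


def water_ratio(tree: Tree, u_j: float, stand: StandState) -> float:
    """Water uptake ratio of one tree given its realized uptake ``u_j``.

    Demand is the uptake the tree would achieve with no competitors at
    the base water content of 1 unit per pixel, i.e. the pixel count of
    its root disc.
    """
    f = _root_strengths(stand, tree, "distance")
    if f is None:
        raise ValueError("zero-extent root system")
    return water_ratio_value(u_j, float(f[2].sum()))
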