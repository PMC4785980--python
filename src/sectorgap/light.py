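"""Above-ground competition: winner-takes-all per-pixel light capture.

Each crown is divided into eight independently sized sectors. A sector of
radius ``r_i`` and live-crown ratio ``beta_i`` claims, at stem distance
``x <= r_i``, an elevation of ``h * (1 - beta_i * (x / r_i)**gamma)``
(the square-root crown outline when gamma = 0.5). Every 10 cm pixel of
the plot gives its unit of direct sunlight to the single tree claiming
the highest elevation there, ties broken at random from the stand RNG.
Crowns are plastic: after allocation each sector radius is shrunk to the
"mean estimate" of how far the tree actually remains unshaded, so a tree
released by a neighbour's death regrows into the gap gradually instead
of reoccupying it instantly.

Two light ratios are measured per tree. The light uptake ratio ``S``
compares what the tree captured with the light it would have received
in the absence of competition, i.e. over its maximal crown extent — the
full allometric crown of radius ``rho * dbh`` that the incremental
radius rule integrates to when no neighbour ever shaves it; it is a
continuous crowding/suppression signal and drives light-limitation
mortality. The growth ratio ``S_growth`` is the fraction of the
realized to the (current, plastic) potential crown: how much of the
crown the tree actually carries is lit; it drives the growth modifier,
so an uncrowded canopy tree keeps growing at full speed even if its
crown is smaller than its allometric potential. Understory trees are
not fully dark: crown transparency passes ``c_t = 9%`` of sunlight
through the canopy, so both ratios credit shaded crown area with c_t
and equal c_t for a fully overtopped tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stand import StandState, Tree

__all__ = [
    "TRANSPARENCY",
    "ClaimMap",
    "crown_profile_fraction",
    "sector_of",
    "allocate_light",
    "update_realized_sectors",
]

#: Fraction of sunlight transmitted through a canopy crown.
TRANSPARENCY = 0.09

_GROUND = -1


@dataclass
class ClaimMap:
    """Per-pixel outcome of the light competition.

    ``winner`` holds the index (into the stand's tree list) of the tree
    with the highest elevation claim, or -1 for ground; ``elevation`` the
    winning claim in metres (-inf for ground); ``covered_any`` the union
    of the current (plastic) crown projections; ``max_covered_any`` the
    union of the maximal allometric crown projections (the canopy-cover
    metric — realized crowns tile without overlap and so always leave
    interstitial pores, which the potential projections bridge);
    ``covered`` / ``max_covered`` / ``won`` the per-tree pixel counts.
    """

    winner: np.ndarray
    elevation: np.ndarray
    covered_any: np.ndarray
    max_covered_any: np.ndarray
    covered: np.ndarray
    max_covered: np.ndarray
    won: np.ndarray
    tree_ids: np.ndarray

    @property
    def ground_pixels(self) -> int:
        return int(np.sum(self.winner == _GROUND))


def crown_profile_fraction(x, r_i: float, beta_i: float, gamma: float):
    """Crown outline at stem distance ``x`` as a fraction of tree height.

    Returns ``1 - beta_i * (x / r_i)**gamma``: 1.0 at the stem, and
    ``1 - beta_i`` (the bole top) at the sector edge ``x = r_i``.
    """
    if r_i <= 0:
        raise ValueError("sector radius must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > r_i):
        raise ValueError("x must lie in [0, r_i]")
    out = 1.0 - beta_i * (x / r_i) ** gamma
    return float(out) if out.ndim == 0 else out


def sector_of(dx, dy, n_sectors: int = 8):
    """Index of the angular sector containing direction (dx, dy).

    Sector 0 starts at angle 0 (due east), counting counter-clockwise;
    ``n_sectors`` must be a power of two.
    """
    if n_sectors < 1 or (n_sectors & (n_sectors - 1)) != 0:
        raise ValueError(f"n_sectors must be a power of two, got {n_sectors}")
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if np.any((dx == 0) & (dy == 0)):
        raise ValueError("direction (0, 0) has no sector")
    angle = np.arctan2(dy, dx) % (2.0 * np.pi)
    idx = (angle / (2.0 * np.pi / n_sectors)).astype(np.int64) % n_sectors
    return int(idx) if idx.ndim == 0 else idx


def _window_axes(stand: StandState, tree: Tree, reach: float):
    """Toroidal pixel-index and centre-displacement axes covering ``reach``."""
    px = stand.pixel
    nx, ny = stand.nx, stand.ny
    half = int(np.ceil(reach / px)) + 1
    i0 = int(tree.x // px)
    j0 = int(tree.y // px)
    wx = min(2 * half + 1, nx)
    wy = min(2 * half + 1, ny)
    ix = (i0 - half + np.arange(wx)) % nx if wx < nx else np.arange(nx)
    iy = (j0 - half + np.arange(wy)) % ny if wy < ny else np.arange(ny)
    W, H = stand.plot_width, stand.plot_height
    dx = ((ix + 0.5) * px - tree.x + W / 2.0) % W - W / 2.0
    dy = ((iy + 0.5) * px - tree.y + H / 2.0) % H - H / 2.0
    return ix, iy, dx, dy


def _crown_claims(stand: StandState, tree: Tree):
    """Covered mask and elevation claims of one tree on its local window."""
    radii = tree.sector_radii
    rmax = float(radii.max())
    if rmax <= 0:
        return None
    ix, iy, dxv, dyv = _window_axes(stand, tree, rmax)
    dx = dxv[None, :]
    dy = dyv[:, None]
    dist = np.hypot(dx, dy)
    angle = np.arctan2(dy, dx) % (2.0 * np.pi)
    sec = (angle / (2.0 * np.pi / len(radii))).astype(np.int64) % len(radii)
    r_sec = radii[sec]
    covered = (dist <= r_sec) & (r_sec > 0)
    if not covered.any():
        return None
    beta_sec = tree.live_crown_ratios[sec]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - beta_sec * (dist / np.where(r_sec > 0, r_sec, 1.0)) ** tree.species.gamma
    elev = np.where(covered, tree.height * frac, -np.inf)
    return ix, iy, covered, elev


def allocate_light(stand: StandState, transparency: float = TRANSPARENCY):
    """Run the winner-takes-all light competition for the current year.

    Returns ``(ClaimMap, S)`` where ``S[k]`` is the light uptake ratio of
    ``stand.trees[k]`` — won pixels plus the transparency credit on the
    rest of the maximal (allometric, radius rho*dbh) crown footprint,
    over that footprint — also stored on each tree together with the
    canopy flag (won at least one pixel of direct light). Exact
    elevation ties are resolved with draws from the stand RNG, so a
    fixed seed gives a reproducible map.
    """
    ny, nx = stand.ny, stand.nx
    winner = np.full((ny, nx), _GROUND, dtype=np.int32)
    elevation = np.full((ny, nx), -np.inf)
    covered_any = np.zeros((ny, nx), dtype=bool)
    max_covered_any = np.zeros((ny, nx), dtype=bool)
    n = len(stand.trees)
    covered_count = np.zeros(n, dtype=np.int64)
    max_count = np.zeros(n, dtype=np.int64)

    for k, tree in enumerate(stand.trees):
        disc = _max_crown_disc(stand, tree)
        if disc is not None:
            dix, diy, dmask = disc
            max_count[k] = int(dmask.sum())
            max_covered_any[np.ix_(diy, dix)] |= dmask
        claims = _crown_claims(stand, tree)
        if claims is None:
            continue
        ix, iy, covered, elev = claims
        sub = np.ix_(iy, ix)
        covered_count[k] = int(covered.sum())
        covered_any[sub] |= covered

        best = elevation[sub]
        beats = covered & (elev > best)
        ties = covered & (elev == best) & np.isfinite(best)
        if ties.any():
            beats = beats | (ties & (stand.rng.random(ties.shape) < 0.5))
        if beats.any():
            elevation[sub] = np.where(beats, elev, best)
            w = winner[sub]
            winner[sub] = np.where(beats, np.int32(k), w)

    won = (
        np.bincount(winner[winner >= 0].ravel(), minlength=n)
        if n else np.zeros(0, dtype=np.int64)
    )
    denom = np.maximum(max_count, covered_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(
            denom > 0,
            (won + transparency * (denom - won)) / np.maximum(denom, 1),
            transparency,
        )
        S_growth = np.where(
            covered_count > 0,
            (won + transparency * (covered_count - won))
            / np.maximum(covered_count, 1),
            transparency,
        )
    if n:
        S = np.clip(S, transparency, 1.0)
        S_growth = np.clip(S_growth, transparency, 1.0)
    for k, tree in enumerate(stand.trees):
        tree.S = float(S[k])
        tree.S_growth = float(S_growth[k])
        tree.canopy_flag = bool(won[k] > 0)
    ids = np.array([t.id for t in stand.trees], dtype=np.int64)
    claim_map = ClaimMap(
        winner, elevation, covered_any, max_covered_any,
        covered_count, max_count, won, ids,
    )
    return claim_map, S


def _max_crown_disc(stand: StandState, tree: Tree):
    """Window mask of the maximal (allometric) crown disc of radius rho*dbh."""
    R = tree.species.rho_crown * tree.dbh
    if R <= 0:
        return None
    ix, iy, dxv, dyv = _window_axes(stand, tree, R)
    dist2 = dxv[None, :] ** 2 + dyv[:, None] ** 2
    return ix, iy, dist2 <= R * R


def _sector_realized(stand, claims, k, tree, sector, n_rays):
    """Mean/min/max ray estimate of one sector's realized radius."""
    r = float(tree.sector_radii[sector])
    if r <= 0:
        return np.zeros(n_rays)
    px = stand.pixel
    width = 2.0 * np.pi / len(tree.sector_radii)
    theta = sector * width + (np.arange(n_rays) + 0.5) / n_rays * width
    n_steps = int(r // px) + 1
    d = r - px * np.arange(n_steps)  # descending, r first
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    X = (tree.x + d[None, :] * cos_t[:, None]) % stand.plot_width
    Y = (tree.y + d[None, :] * sin_t[:, None]) % stand.plot_height
    ii = np.minimum((X / px).astype(np.int64), stand.nx - 1)
    jj = np.minimum((Y / px).astype(np.int64), stand.ny - 1)
    w = claims.winner[jj, ii]
    e_w = claims.elevation[jj, ii]
    beta = tree.live_crown_ratios[sector]
    e_self = tree.height * (1.0 - beta * (d / r) ** tree.species.gamma)
    unshaded = (w == k) | (e_w <= e_self[None, :] + 1e-9)
    dmax = np.where(unshaded, d[None, :], -np.inf).max(axis=1)
    return np.clip(dmax, 0.0, r)


def update_realized_sectors(
    stand: StandState,
    claims: ClaimMap,
    *,
    estimate: str = "mean",
    n_rays: int = 9,
) -> None:
    """Shrink each sector radius to its realized (competition-limited) value.

    For every sector a fan of ``n_rays`` equally spaced rays is cast from
    the stem; along each ray the farthest sampled distance at which the
    tree still wins its pixel, or at which no competing claim exceeds the
    tree's own potential elevation, is recorded. The sector's realized
    radius is the mean of the ray distances (``estimate`` may also select
    the more biased min or max), never exceeding the potential radius.
    An isolated tree keeps its full potential crown.

    Radii are floored at sapling scale (rho * 3 cm): a living tree keeps
    at least a sapling-sized branch skeleton, so full overtopping
    suppresses the crown without erasing it — the suppressed tree can
    still seize a gap opening above it.
    """
    if estimate not in ("mean", "min", "max"):
        raise ValueError(f"unknown estimate {estimate!r}")
    reduce_fn = {"mean": np.mean, "min": np.min, "max": np.max}[estimate]
    for k, tree in enumerate(stand.trees):
        new_radii = np.array([
            reduce_fn(_sector_realized(stand, claims, k, tree, s, n_rays))
            for s in range(len(tree.sector_radii))
        ])
        floor = tree.species.rho_crown * 3.0
        tree.sector_radii = np.maximum(
            np.minimum(new_radii, tree.sector_radii),
            np.minimum(floor, tree.sector_radii),
        )
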