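"""Shared fixtures: species, small deterministic stands, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from sectorgap import SpeciesParams, StandState, Tree, make_species_pair


@pytest.fixture(scope="session")
def species_pair():
    return make_species_pair()


@pytest.fixture()
def small_stand():
    """Empty 2 m x 2 m stand (20 x 20 pixels) with a seeded RNG."""
    return StandState(
        plot_width=2.0, plot_height=2.0, pixel=0.1,
        water_content=1.0, rng=np.random.default_rng(42),
    )


def make_tree(tree_id, sp, x, y, dbh, radii=None, betas=None):
    return Tree(
        id=tree_id, species=sp, x=x, y=y, dbh=dbh,
        sector_radii=None if radii is None else np.asarray(radii, float),
        live_crown_ratios=None if betas is None else np.asarray(betas, float),
    )


@pytest.fixture()
def two_tree_stand(species_pair):
    """A tall pine beside a shorter hemlock on a 2 m plot; no exact ties."""
    pine, hemlock = species_pair
    stand = StandState(
        plot_width=2.0, plot_height=2.0, pixel=0.1,
        water_content=1.0, rng=np.random.default_rng(7),
    )
    stand.add_tree(make_tree(0, pine, 0.7, 1.0, 8.0, radii=[0.6] * 8))
    stand.add_tree(make_tree(1, hemlock, 1.3, 1.0, 5.0, radii=[0.5] * 8))
    return stand


# -- independent oracles ----------------------------------------------------

def _wrap(d, span):
    return (d + span / 2.0) % span - span / 2.0


def brute_force_light(stand):
    """Exhaustive per-pixel winner computation, independent of the package.

    Loops every pixel and every tree sector; returns (winner, elevation)
    arrays with -1 / -inf for ground. Assumes no exact elevation ties.
    """
    nx, ny = stand.nx, stand.ny
    px = stand.pixel
    winner = np.full((ny, nx), -1, dtype=int)
    elev = np.full((ny, nx), -np.inf)
    for j in range(ny):
        for i in range(nx):
            cx, cy = (i + 0.5) * px, (j + 0.5) * px
            for k, t in enumerate(stand.trees):
                dx = _wrap(cx - t.x, stand.plot_width)
                dy = _wrap(cy - t.y, stand.plot_height)
                dist = float(np.hypot(dx, dy))
                ang = float(np.arctan2(dy, dx)) % (2 * np.pi)
                sec = int(ang // (2 * np.pi / 8)) % 8
                r = float(t.sector_radii[sec])
                if r <= 0 or dist > r:
                    continue
                beta = float(t.live_crown_ratios[sec])
                e = t.height * (1 - beta * (dist / r) ** t.species.gamma)
                if e > elev[j, i]:
                    elev[j, i] = e
                    winner[j, i] = k
    return winner, elev


def brute_force_water(stand, c):
    """Exhaustive per-pixel proportional water split; returns per-tree uptake."""
    nx, ny = stand.nx, stand.ny
    px = stand.pixel
    u = np.zeros(len(stand.trees))
    for j in range(ny):
        for i in range(nx):
            cx, cy = (i + 0.5) * px, (j + 0.5) * px
            strengths = {}
            for k, t in enumerate(stand.trees):
                dx = _wrap(cx - t.x, stand.plot_width)
                dy = _wrap(cy - t.y, stand.plot_height)
                dist = float(np.hypot(dx, dy))
                R = t.root_extent
                if R > 0 and dist <= R:
                    strengths[k] = 1.0 - dist / R
            total = sum(strengths.values())
            if total > 0:
                for k, s in strengths.items():
                    u[k] += c * s / total
    return u
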