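"""The annual simulation loop.

Each simulated year runs, in order: light competition, realized-crown
update, water competition, resource-limited growth, mortality, and
recruitment. The annual record is taken right after the two competition
steps, so the reported S/W ratios, strata and cover describe the stand
as it stood and competed that year. A run starts from an empty plot
(the state after a major disturbance) and is bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .demography import MechanismConfig, apply_mortality, grow, growth_modifier, recruit
from .light import TRANSPARENCY, allocate_light, update_realized_sectors
from .metrics import annual_record, records_to_frame
from .stand import StandState
from .water import allocate_water, aridity_to_content

__all__ = ["SimulationConfig", "make_stand", "annual_step", "run"]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulation."""

    plot_width: float = 50.0
    plot_height: float = 50.0
    pixel: float = 0.1
    years: int = 1500
    aridity: float = 0.5
    seed: int = 0
    mechanisms: MechanismConfig = field(default_factory=MechanismConfig)
    transparency: float = TRANSPARENCY
    crown_estimate: str = "mean"
    n_rays: int = 9
    claim_variant: str = "distance"
    record_every: int = 1
    species_sampler: object = None  # callable(rng) -> SpeciesParams, optional

    def __post_init__(self) -> None:
        if self.years < 0:
            raise ValueError("years must be >= 0")
        if not 0.0 <= self.aridity <= 1.0:
            raise ValueError("aridity index must be in [0,1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("species_sampler")
        return d


def make_stand(config: SimulationConfig) -> StandState:
    """Empty post-disturbance stand with a seeded RNG stream."""
    return StandState(
        plot_width=config.plot_width,
        plot_height=config.plot_height,
        pixel=config.pixel,
        water_content=aridity_to_content(config.aridity),
        rng=np.random.default_rng(config.seed),
    )


def annual_step(stand: StandState, config: SimulationConfig) -> dict:
    """Advance the stand by one year; returns the year's annual record."""
    mech = config.mechanisms
    claims, S = allocate_light(stand, config.transparency)
    update_realized_sectors(
        stand, claims, estimate=config.crown_estimate, n_rays=config.n_rays
    )
    _, W = allocate_water(stand, variant=config.claim_variant)
    record = annual_record(stand, claims)
    for tree in stand.trees:
        lam = growth_modifier(tree.S_growth, tree.W, mech.growth_mechanism)
        grow(tree, lam, pri_variant=mech.pri_variant)
    apply_mortality(stand, mech)
    recruit(
        stand,
        mech.recruitment_rate,
        species_sampler=config.species_sampler,
    )
    stand.year += 1
    return record


def run(config: SimulationConfig) -> tuple[pd.DataFrame, StandState]:
    """Simulate ``config.years`` annual steps from an empty plot.

    Returns the annual records (one row per recorded year) and the final
    stand state.
    """
    stand = make_stand(config)
    records: list[dict] = []
    for y in range(config.years):
        rec = annual_step(stand, config)
        if y % config.record_every == 0:
            records.append(rec)
    return records_to_frame(records), stand
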