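"""Experiment designs: aridity sweeps, mortality sensitivity grids,
succession analysis, and the continuum-of-species sampler.

All drivers spawn per-cell child seeds from a single master seed via
``numpy.random.SeedSequence``, record them in the output tables, and are
therefore reproducible end to end.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .engine import SimulationConfig, run
from .metrics import equilibrium_summary
from .species import interpolate_species

__all__ = [
    "crossover_year",
    "stabilization_year",
    "succession_runs",
    "aridity_sweep",
    "sensitivity_grid",
    "sample_alpha",
    "species_continuum_sampler",
]


# -- succession timing ------------------------------------------------------

def _guild_series(records: pd.DataFrame, window: int):
    """Rolling-mean smoothed tolerant/intolerant basal-area series."""
    tol = records["ba_shade_tolerant"].rolling(window, center=True, min_periods=1).mean()
    intol = records["ba_shade_intolerant"].rolling(window, center=True, min_periods=1).mean()
    return tol.to_numpy(), intol.to_numpy(), records["year"].to_numpy()


def crossover_year(records: pd.DataFrame, window: int = 25) -> float:
    """First year shade-tolerant basal area overtakes the shade-intolerant.

    Both guild series are smoothed with a centred ``window``-year rolling
    mean so the demographic noise of the first sapling cohorts does not
    register as a crossing. The crossover is the first smoothed year at
    which the tolerant guild exceeds the intolerant one after the
    intolerant guild has led (the early-domination phase); NaN if no
    takeover happens.
    """
    tol, intol, years = _guild_series(records, window)
    led = np.flatnonzero(intol > tol)
    if led.size == 0:
        return float("nan")
    after = np.flatnonzero((tol > intol) & (np.arange(len(tol)) > led[0]))
    return float(years[after[0]]) if after.size else float("nan")


def stabilization_year(records: pd.DataFrame, window: int = 25) -> float:
    """Year after which shade-tolerant prevalence shows no further sign flip.

    The year following the last smoothed record with shade-intolerant
    basal area >= shade-tolerant basal area; NaN if the tolerant guild
    does not end the run in the lead.
    """
    tol, intol, years = _guild_series(records, window)
    if tol.size == 0 or tol[-1] <= intol[-1]:
        return float("nan")
    behind = np.flatnonzero(tol <= intol)
    if behind.size == 0:
        return float(years[0])
    if behind[-1] + 1 >= len(years):
        return float("nan")
    return float(years[behind[-1] + 1])


def succession_runs(
    base: SimulationConfig,
    n_seeds: int = 5,
    master_seed: int = 0,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Replicate succession runs; returns per-seed records and a timing table."""
    children = np.random.SeedSequence(master_seed).spawn(n_seeds)
    all_records, rows = [], []
    for ss in children:
        seed = int(ss.generate_state(1)[0] % 2**31)
        rec, _ = run(replace(base, seed=seed))
        all_records.append(rec)
        rows.append({
            "seed": seed,
            "crossover_year": crossover_year(rec),
            "stabilization_year": stabilization_year(rec),
        })
    return all_records, pd.DataFrame(rows)


# -- grids ------------------------------------------------------------------

def _equilibrium_row(records: pd.DataFrame) -> dict:
    summ = equilibrium_summary(records)
    row = {}
    for metric in summ.index:
        row[f"{metric}_mean"] = summ.loc[metric, "mean"]
        row[f"{metric}_sd"] = summ.loc[metric, "sd"]
    return row


def aridity_sweep(
    base: SimulationConfig,
    aridity_values,
    reps: int = 1,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Equilibrium summaries along an aridity gradient (one row per run)."""
    aridity_values = sorted(aridity_values)
    rows = []
    ss_root = np.random.SeedSequence(master_seed)
    for a, ss in zip(aridity_values, ss_root.spawn(len(aridity_values))):
        for rep_ss in ss.spawn(reps):
            seed = int(rep_ss.generate_state(1)[0] % 2**31)
            rec, _ = run(replace(base, aridity=a, seed=seed))
            row = {"aridity": a, "seed": seed}
            row.update(_equilibrium_row(rec))
            rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_grid(
    base: SimulationConfig,
    aridity_values,
    pw_values,
    reps: int = 1,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Full factorial aridity x P_max grid of equilibrium summaries.

    Mirrors the water-limitation mortality sensitivity design: for every
    grid cell the equilibrium mean +- sd of the shade tolerance index
    (and the other stand metrics) over the second half of the run.
    """
    aridity_values = sorted(aridity_values)
    pw_values = sorted(pw_values)
    rows = []
    ss_root = np.random.SeedSequence(master_seed)
    cells = [(a, p) for a in aridity_values for p in pw_values]
    for (a, p), ss in zip(cells, ss_root.spawn(len(cells))):
        for rep_ss in ss.spawn(reps):
            seed = int(rep_ss.generate_state(1)[0] % 2**31)
            cfg = replace(
                base, aridity=a, seed=seed,
                mechanisms=replace(base.mechanisms, P_max=p),
            )
            rec, _ = run(cfg)
            row = {"aridity": a, "P_max": p, "seed": seed}
            row.update(_equilibrium_row(rec))
            rows.append(row)
    return pd.DataFrame(rows)


# -- continuum of species ---------------------------------------------------

def sample_alpha(
    rng: np.random.Generator,
    eta_m: float = 5.0,
    centres: tuple[float, float] = (0.05, 0.95),
) -> float:
    """Draw a species-blend coordinate by polynomial mutation.

    The standard operator from evolutionary multi-objective optimization:
    with u ~ U(0,1), the perturbation is ``delta = (2u)^(1/(eta_m+1)) - 1``
    for u < 0.5 and ``1 - (2(1-u))^(1/(eta_m+1))`` otherwise, applied over
    the unit range around one of the two centres (chosen with equal
    probability) and clipped to [0, 1]. The result is a symmetric bimodal
    distribution with modes at the centres; larger ``eta_m`` concentrates
    draws onto them.
    """
    if eta_m <= 0:
        raise ValueError("eta_m must be positive")
    centre = centres[int(rng.random() < 0.5)]
    u = rng.random()
    if u < 0.5:
        delta = (2.0 * u) ** (1.0 / (eta_m + 1.0)) - 1.0
    else:
        delta = 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta_m + 1.0))
    return float(np.clip(centre + delta, 0.0, 1.0))


def species_continuum_sampler(eta_m: float = 5.0, *, pine_at_one: bool = True):
    """Recruit-species sampler drawing an interpolated parameter vector.

    Returns a callable suitable for ``SimulationConfig.species_sampler``:
    each recruit receives ``p(alpha)``, the componentwise blend of the two
    prototype vectors at a polynomial-mutation draw of alpha.
    """
    def sampler(rng: np.random.Generator):
        return interpolate_species(sample_alpha(rng, eta_m), pine_at_one=pine_at_one)

    return sampler
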