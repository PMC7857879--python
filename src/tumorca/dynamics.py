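"""Stochastic state-transition rules of the tumor automaton.

Each iteration a cell first answers to its microenvironment (oxygen,
glucose, pH against the critical thresholds: necrosis conditions are the
halved thresholds and the lower pH bound, quiescence conditions the full
thresholds), and then the state machinery runs: proliferating cells (PCs)
attempt stochastic mitosis into an empty-or-normal Moore neighbor,
quiescent cells (QCs) necrose inside the geometric core radius or recover
at the rim / under sufficient nutrients, and necrosis is absorbing.

Two PC phenotypes exist.  A mutant PC divides independently of its
surroundings with probability p0*(1 - r/Rmax); a nonmutant PC needs free
(normal/empty) neighbors: phi0*(n_free/8)*(1 - r/Rmax).  A mutant parent's
daughter is nonmutant with probability Nmm -- the model's bifurcation
parameter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .model import (
    CellGrid,
    MetabolicFields,
    ModelParams,
    NORMAL,
    PROLIFERATIVE,
    QUIESCENT,
    NECROTIC,
    ph_from_h,
)

MOORE_OFFSETS = tuple((dr, dc)
                      for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                      if (dr, dc) != (0, 0))


class Verdict(enum.IntEnum):
    PROLIFERATION_PERMITTED = 0
    QUIESCENCE_TRIGGER = 1
    NECROSIS_TRIGGER = 2


@dataclass(frozen=True)
class MicroResponse:
    verdict: Verdict
    anaerobic: bool


@dataclass
class RngStreams:
    """Named random streams so refactoring one consumer leaves the rest."""

    shuffle: np.random.Generator
    mitosis: np.random.Generator
    neighbor: np.random.Generator
    phenotype: np.random.Generator
    init: np.random.Generator

    @classmethod
    def from_seed(cls, seed) -> "RngStreams":
        children = np.random.SeedSequence(seed).spawn(5)
        return cls(*(np.random.default_rng(s) for s in children))


def classify_microenvironment(o2: float, gl: float, ph: float,
                              p: ModelParams) -> MicroResponse:
    """Cell response to local (O2, glucose, pH).

    Necrosis conditions (half-thresholds, lower pH bound) are checked
    first, then quiescence conditions; otherwise proliferation is
    permitted.  The anaerobic switch follows the oxygen threshold alone.
    """
    if o2 < 0 or gl < 0:
        raise ValueError("concentrations must be non-negative")
    anaerobic = o2 < p.o2_thre
    if o2 < p.o2_necrosis or gl < p.gl_necrosis or ph < p.ph_thre_ne:
        verdict = Verdict.NECROSIS_TRIGGER
    elif o2 < p.o2_thre or gl < p.gl_thre or ph < p.ph_thre_q:
        verdict = Verdict.QUIESCENCE_TRIGGER
    else:
        verdict = Verdict.PROLIFERATION_PERMITTED
    return MicroResponse(verdict, anaerobic)


def classify_lattice(fields: MetabolicFields, p: ModelParams) -> np.ndarray:
    """Vectorized verdict lattice (values of :class:`Verdict`)."""
    ph = ph_from_h(fields.h)
    nec = ((fields.o2 < p.o2_necrosis) | (fields.gl < p.gl_necrosis)
           | (ph < p.ph_thre_ne))
    qui = ((fields.o2 < p.o2_thre) | (fields.gl < p.gl_thre)
           | (ph < p.ph_thre_q))
    out = np.where(nec, int(Verdict.NECROSIS_TRIGGER),
                   np.where(qui, int(Verdict.QUIESCENCE_TRIGGER),
                            int(Verdict.PROLIFERATION_PERMITTED)))
    return out.astype(np.int8)


def division_probability(is_mutant: bool, r: float, n_normal_neighbors: int,
                         p: ModelParams) -> float:
    """Division probability of a PC at lattice distance r from the seed.

    Zero at and beyond Rmax (pressure-limited saturation); the nonmutant
    neighbor count is normalized by the Moore maximum of 8 so the result
    stays a probability.
    """
    if r < 0:
        raise ValueError("radial distance must be non-negative")
    if not 0 <= n_normal_neighbors <= 8:
        raise ValueError("neighbor count must lie in 0..8")
    radial = 1.0 - r / p.rmax
    if radial <= 0.0:
        return 0.0
    if is_mutant:
        prob = p.p0 * radial
    else:
        prob = p.phi0 * (n_normal_neighbors / 8.0) * radial
    return float(min(max(prob, 0.0), 1.0))


def _free_neighbors(grid: CellGrid, site: tuple[int, int]) -> list[tuple[int, int]]:
    n = grid.ncell
    i, j = site
    out = []
    for dr, dc in MOORE_OFFSETS:
        r, c = (i + dr) % n, (j + dc) % n
        if grid.states[r, c] == NORMAL:
            out.append((r, c))
    return out


def stall_allowance(p: ModelParams, t: int = 0) -> float:
    """Consecutive failures a PC tolerates before quiescing at iteration t.

    Grows with the iteration count (the tolerance to crowding is a function
    of the number of elapsed time steps): max(stall_limit, stall_growth*t).
    """
    return max(float(p.stall_limit), p.stall_growth * t)


def attempt_mitosis(site: tuple[int, int], grid: CellGrid, rng: RngStreams,
                    p: ModelParams, r: float | None = None,
                    t: int = 0) -> CellGrid:
    """One PC's mitosis attempt; mutates and returns the grid.

    On success a daughter PC replaces a uniformly chosen empty-or-normal
    Moore neighbor (the parent stays put) and the stall counter resets; a
    mutant parent's daughter is nonmutant with probability Nmm.  On failure
    (no free neighbor, or the probability draw fails) the stall counter
    increments, and once it reaches the iteration-dependent stalling
    allowance the PC turns quiescent.
    """
    i, j = site
    if grid.states[i, j] != PROLIFERATIVE:
        raise ValueError(f"attempt_mitosis called on a non-PC site {site}")
    if r is None:
        ci, cj = grid.center
        r = float(np.hypot(i - ci, j - cj))
    free = _free_neighbors(grid, site)
    divided = False
    if free:
        prob = division_probability(bool(grid.mutant[i, j]), r, len(free), p)
        if prob > 0.0 and rng.mitosis.random() < prob:
            di, dj = free[rng.neighbor.integers(len(free))]
            grid.states[di, dj] = PROLIFERATIVE
            grid.empty[di, dj] = False
            grid.stall[di, dj] = 0
            if grid.mutant[i, j]:
                grid.mutant[di, dj] = rng.phenotype.random() >= p.nmm
            else:
                grid.mutant[di, dj] = False
            grid.stall[i, j] = 0
            divided = True
    if not divided:
        grid.stall[i, j] += 1
        if grid.stall[i, j] >= stall_allowance(p, t):
            grid.states[i, j] = QUIESCENT
            grid.stall[i, j] = 0
    return grid


def update_quiescent(site: tuple[int, int], grid: CellGrid,
                     fields: MetabolicFields, geometry, p: ModelParams) -> int:
    """One QC's fate given the tumor geometry computed for this iteration.

    Inside the necrotic-core radius the QC dies; within the proliferative
    rim (r >= Rt - Wp) or with all three nutrient conditions satisfied it
    recovers to PC with its pre-quiescence phenotype; otherwise it stays
    quiescent.  Returns the new state code.
    """
    i, j = site
    if grid.states[i, j] != QUIESCENT:
        raise ValueError(f"update_quiescent called on a non-QC site {site}")
    ci, cj = grid.center
    r = float(np.hypot(i - ci, j - cj))
    if r < geometry.rn:
        grid.states[i, j] = NECROTIC
        return NECROTIC
    sufficient = (fields.o2[i, j] >= p.o2_thre
                  and fields.gl[i, j] >= p.gl_thre
                  and ph_from_h(fields.h[i, j]) >= p.ph_thre_q)
    if r >= geometry.rt - geometry.wp or sufficient:
        grid.states[i, j] = PROLIFERATIVE
        grid.stall[i, j] = 0
        return PROLIFERATIVE
    return QUIESCENT


def apply_necrosis(grid: CellGrid, fields: MetabolicFields,
                   p: ModelParams) -> CellGrid:
    """Kill every tumor cell whose microenvironment triggers necrosis.

    Necrosis is absorbing: NeC sites are never modified by any rule.
    Living normal cells under lethal conditions leave an empty space
    (apoptosis) by default, or necrose if ``normal_death='necrotic'``.
    """
    verdict = classify_lattice(fields, p)
    lethal = verdict == int(Verdict.NECROSIS_TRIGGER)
    tumor_live = (grid.states == PROLIFERATIVE) | (grid.states == QUIESCENT)
    dying = tumor_live & lethal
    grid.states[dying] = NECROTIC
    grid.stall[dying] = 0
    normal_live = (grid.states == NORMAL) & ~grid.empty
    gone = normal_live & lethal
    if p.normal_death == "empty":
        grid.empty[gone] = True
    else:
        grid.states[gone] = NECROTIC
    return grid
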