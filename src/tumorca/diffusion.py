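"""Block-cellular-automata diffusion of the five metabolic fields.

Transport is modeled by partitioning the lattice into 3x3 blocks, replacing
every site of a block by the block mean, and shifting the partition origin
down one row and right one column each iteration.  A field value then
relaxes toward its block average with a per-field mixing weight alpha_i in
(0,1) that stands in for the physical diffusion coefficient:

    u_i(t+1) = alpha_i * A(t) + (1 - alpha_i) * u_i(t) + delta_i(t)

where A is the shifting-block mean and delta_i the signed per-site
consumption/production increment of the resident cell.  Boundaries are
periodic; when the lattice side is not a multiple of 3 the wrap-around
defines smaller partial blocks, so the partition is still exact and the
scheme still conserves mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    CellGrid,
    MetabolicFields,
    ModelParams,
    FIELD_NAMES,
    NORMAL,
    PROLIFERATIVE,
    QUIESCENT,
    NECROTIC,
)


@dataclass(frozen=True)
class BlockSchedule:
    """Shifting non-overlapping block partition with periodic wrap."""

    block_size: int = 3

    def offset(self, t: int) -> tuple[int, int]:
        """Top-left shift of the partition at iteration t: (+1, +1) per step."""
        return (t % self.block_size, t % self.block_size)


def _group_sizes(n: int, b: int) -> np.ndarray:
    """Sizes of the periodic partition of n sites into runs of length b."""
    k, rem = divmod(n, b)
    sizes = [b] * k
    if rem:
        sizes.append(rem)
    return np.asarray(sizes)


def block_average(field: np.ndarray, schedule: BlockSchedule = BlockSchedule(),
                  t: int = 0) -> np.ndarray:
    """Replace every site by the mean of its block at iteration t.

    The partition origin is ``schedule.offset(t)``; blocks wrap periodically
    and partition the lattice exactly, so the global sum is unchanged up to
    floating rounding.
    """
    if field.ndim != 2:
        raise ValueError("block_average expects a 2-D field")
    n0, n1 = field.shape
    b = schedule.block_size
    if n0 < b or n1 < b:
        raise ValueError(f"field smaller than one {b}x{b} block")
    off0, off1 = schedule.offset(t)
    rolled = np.roll(field, (-off0, -off1), axis=(0, 1))
    rsz, csz = _group_sizes(n0, b), _group_sizes(n1, b)
    ridx = np.concatenate([[0], np.cumsum(rsz)[:-1]])
    cidx = np.concatenate([[0], np.cumsum(csz)[:-1]])
    sums = np.add.reduceat(np.add.reduceat(rolled, ridx, axis=0), cidx, axis=1)
    means = sums / np.outer(rsz, csz)
    expanded = np.repeat(np.repeat(means, rsz, axis=0), csz, axis=1)
    return np.roll(expanded, (off0, off1), axis=(0, 1))


def cell_metabolism(grid: CellGrid, fields: MetabolicFields,
                    p: ModelParams) -> dict[str, np.ndarray]:
    """Signed per-site concentration increments from resident cells.

    Aerobic PCs consume O2 and glucose and export protons; below the oxygen
    threshold the anaerobic (glycolytic) branch multiplies glucose uptake
    and proton export and cuts O2 uptake.  QCs run the same branch at the
    quiescent_factor; NeCs only export protons; living normal cells take up
    O2/glucose at a reduced rate; empty sites are inert.  Uptake is
    truncated to the locally available amount so no field can be driven
    negative by consumption.
    """
    st = grid.states
    pc = st == PROLIFERATIVE
    qc = st == QUIESCENT
    nec = st == NECROTIC
    normal = (st == NORMAL) & ~grid.empty
    anaer = fields.o2 < p.o2_thre

    s_o2 = p.rate_scale * p.cr_o2
    s_gl = p.rate_scale * p.cr_gl
    # h is carried in mol/L (pH scale); 1e-3 converts the mMol-scale
    # increment, and proton_buffering is the free-H+ yield after tissue
    # buffering of the exported acid.
    s_h = p.rate_scale * p.cr_h * 1e-3 * p.proton_buffering

    # Branch multipliers per site (aerobic = 1).
    m_o2 = np.where(anaer, p.k_o2_anaerobic, 1.0)
    m_gl = np.where(anaer, p.k_gl_anaerobic, 1.0)
    m_h = np.where(anaer, p.k_h_anaerobic, 1.0)

    tumor_live = pc + p.quiescent_factor * qc  # 0/1/qf weight lattice
    o2_cons = s_o2 * m_o2 * tumor_live + s_o2 * p.modulation_normal * normal
    gl_cons = s_gl * m_gl * tumor_live + s_gl * p.modulation_normal * normal
    h_prod = s_h * m_h * tumor_live + s_h * nec

    gf_cons = p.factor_scale * p.cr_gf * tumor_live
    if_prod = p.factor_scale * p.cr_if * tumor_live

    return {
        "o2": -np.minimum(o2_cons, fields.o2),
        "gl": -np.minimum(gl_cons, fields.gl),
        "h": h_prod,
        "gf": -np.minimum(gf_cons, fields.gf),
        "if_": if_prod,
    }


def diffusion_step(fields: MetabolicFields, grid: CellGrid, p: ModelParams,
                   t: int, schedule: BlockSchedule = BlockSchedule(),
                   increments: dict[str, np.ndarray] | None = None,
                   ) -> MetabolicFields:
    """One shifting-block diffusion step with metabolic sources/sinks.

    Results are clamped at zero; with all-zero increments the step conserves
    each field's global sum exactly (block averaging is redistributive).
    """
    alphas = p.alphas()
    for name, a in alphas.items():
        if not 0.0 < a < 1.0:
            raise ValueError(f"alpha[{name}] = {a} outside (0, 1)")
    if increments is None:
        increments = cell_metabolism(grid, fields, p)
    out = {}
    for name in FIELD_NAMES:
        u = getattr(fields, name)
        if u.shape != grid.states.shape:
            raise ValueError(f"field {name!r} shape differs from the grid")
        a = alphas[name]
        mixed = a * block_average(u, schedule, t) + (1.0 - a) * u
        out[name] = np.maximum(mixed + increments[name], 0.0)
    return MetabolicFields(**out)


def replenish_medium(fields: MetabolicFields, grid: CellGrid,
                     p: ModelParams) -> MetabolicFields:
    """Restore medium sites toward fresh-medium concentrations.

    The vasculature outside the tumor keeps nutrient levels from dropping
    more than 5% below the fresh medium and clears exported acid, so at
    every non-tumor site O2 and glucose are raised to at least
    medium_floor_frac * background and H+ is capped near its background.
    Tumor-occupied sites are untouched.  ``replenish_mode='boundary'``
    restricts the effect to the lattice border instead.
    """
    if p.replenish_mode == "boundary":
        mask = np.zeros_like(grid.states, dtype=bool)
        mask[0, :] = mask[-1, :] = True
        mask[:, 0] = mask[:, -1] = True
        mask &= grid.states == NORMAL
    else:
        mask = grid.states == NORMAL
    out = fields.copy()
    frac = p.medium_floor_frac
    out.o2[mask] = np.maximum(out.o2[mask], frac * p.c0)
    out.gl[mask] = np.maximum(out.gl[mask], frac * p.g0)
    out.h[mask] = np.minimum(out.h[mask], p.h0 / frac)
    return out
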