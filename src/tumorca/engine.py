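"""Simulation orchestration: initialization, the iteration loop, replicate
runs and the Nmm bifurcation sweep.

Each iteration executes, in order: (1) block-CA diffusion with metabolic
sources/sinks, (2) medium replenishment, (3) environmental necrosis,
(4) one geometry computation (Rt, Rn, Wp), (5) quiescent-cell updates
against that geometry, and (6) mitosis attempts for every PC in a freshly
shuffled random order.  All randomness flows from one root seed through
named streams, so a (seed, params) pair determines every output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CellGrid,
    MetabolicFields,
    ModelParams,
    FIELD_NAMES,
    PROLIFERATIVE,
    QUIESCENT,
    validate_params,
)
from .diffusion import BlockSchedule, diffusion_step, replenish_medium
from .dynamics import (
    RngStreams,
    Verdict,
    apply_necrosis,
    attempt_mitosis,
    classify_lattice,
    update_quiescent,
)
from .metrics import (
    SimulationRecord,
    compute_geometry,
    compute_radius,
    distance_from_center,
)


@dataclass
class RunSpec:
    """A replicate experiment: parameters, seeds, Nmm grid and outputs."""

    params: ModelParams
    replicate_seeds: tuple[int, ...] = (0,)
    nmm_grid: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(11))
    out_dir: Path | None = None
    snapshot_iters: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.replicate_seeds) == 0:
            raise ValueError("replicate_seeds must be non-empty")
        if any(not 0.0 <= v <= 1.0 for v in self.nmm_grid):
            raise ValueError("nmm_grid values must lie in [0, 1]")


def initialize(p: ModelParams, rng: RngStreams | None = None
               ) -> tuple[CellGrid, MetabolicFields]:
    """All-normal tissue with one mutant PC at the seed site and uniform
    background concentrations (optionally jittered uniformly)."""
    validate_params(p)
    grid = CellGrid.blank(p.ncell, p.center_site)
    ci, cj = grid.center
    grid.states[ci, cj] = PROLIFERATIVE
    grid.mutant[ci, cj] = True
    fields = MetabolicFields.uniform(p.ncell, p)
    if p.init_jitter > 0:
        if rng is None:
            rng = RngStreams.from_seed(p.seed)
        for name in FIELD_NAMES:
            arr = getattr(fields, name)
            jitter = rng.init.uniform(1.0 - p.init_jitter,
                                      1.0 + p.init_jitter, size=arr.shape)
            np.multiply(arr, jitter, out=arr)
    return grid, fields


def step(grid: CellGrid, fields: MetabolicFields, p: ModelParams, t: int,
         rng: RngStreams, schedule: BlockSchedule = BlockSchedule(),
         ) -> tuple[CellGrid, MetabolicFields]:
    """Advance the coupled system by one iteration (mutates both arguments)."""
    fields = diffusion_step(fields, grid, p, t, schedule)
    fields = replenish_medium(fields, grid, p)
    grid = apply_necrosis(grid, fields, p)

    geom = compute_geometry(compute_radius(grid), p)

    qc_sites = np.argwhere(grid.states == QUIESCENT)
    for i, j in qc_sites:
        update_quiescent((int(i), int(j)), grid, fields, geom, p)

    # PCs below the quiescence thresholds stop cycling before any attempt.
    verdict = classify_lattice(fields, p)
    pc_mask = grid.states == PROLIFERATIVE
    demote = pc_mask & (verdict == int(Verdict.QUIESCENCE_TRIGGER))
    grid.states[demote] = QUIESCENT
    grid.stall[demote] = 0

    dist = distance_from_center(grid)
    pc_sites = np.argwhere(grid.states == PROLIFERATIVE)
    if len(pc_sites):
        order = rng.shuffle.permutation(len(pc_sites))
        for k in order:
            i, j = int(pc_sites[k, 0]), int(pc_sites[k, 1])
            attempt_mitosis((i, j), grid, rng, p, r=float(dist[i, j]), t=t)
    return grid, fields


def run_single(p: ModelParams, seed: int | None = None,
               snapshot_iters: tuple[int, ...] = (),
               ) -> SimulationRecord:
    """One full simulation of ``p.n_iter`` iterations under one seed."""
    if seed is not None:
        p = p.replace(seed=int(seed))
    rng = RngStreams.from_seed(p.seed)
    grid, fields = initialize(p, rng)
    schedule = BlockSchedule()
    record = SimulationRecord()
    record.append(0, grid, fields, p)
    if 0 in snapshot_iters:
        record.snapshots[0] = _snapshot(grid, fields)
    for t in range(1, p.n_iter + 1):
        grid, fields = step(grid, fields, p, t - 1, rng, schedule)
        record.append(t, grid, fields, p)
        if t in snapshot_iters:
            record.snapshots[t] = _snapshot(grid, fields)
    return record


def _snapshot(grid: CellGrid, fields: MetabolicFields) -> dict[str, np.ndarray]:
    snap = {name: arr.copy() for name, arr in fields.as_dict().items()}
    snap["states"] = grid.states.copy()
    snap["mutant"] = grid.mutant.copy()
    return snap


def run_simulation(spec: RunSpec) -> list[SimulationRecord]:
    """One record per replicate seed; writes outputs if out_dir is set."""
    records = []
    for seed in spec.replicate_seeds:
        rec = run_single(spec.params, seed, spec.snapshot_iters)
        records.append(rec)
        if spec.out_dir is not None:
            _write_run(spec, seed, rec)
    return records


def _write_run(spec: RunSpec, seed: int, rec: SimulationRecord) -> None:
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec.to_dataframe().to_csv(out / f"timeseries_seed{seed}.csv", index=False)
    for t, snap in rec.snapshots.items():
        for name, arr in snap.items():
            np.savetxt(out / f"snapshot_seed{seed}_iter{t}_{name}.csv",
                       arr, delimiter=",", fmt="%.10g")
    manifest = {
        "seed": seed,
        "n_iter": spec.params.n_iter,
        "nmm": spec.params.nmm,
        "params": spec.params.to_dict(),
    }
    (out / f"run_manifest_seed{seed}.json").write_text(
        json.dumps(manifest, indent=2))


def sweep_nmm(spec: RunSpec, keep_lattices: bool = False
              ) -> tuple[pd.DataFrame, dict]:
    """End-state metrics across the Nmm grid with paired seeds.

    Every Nmm value is run under every replicate seed; for each run the
    final counts, fractions, volume, pH-layer occupancies and the
    oxygen/pH difference lattices against the Nmm = 0 run of the same seed
    are computed.  Returns a tidy DataFrame and a dict of per-(nmm, seed)
    difference lattices (kept only if requested; mean difference lattices
    per Nmm are always returned under 'mean').
    """
    from .metrics import LayerBins, stratify_layers
    from .model import ph_from_h

    grid_vals = list(spec.nmm_grid)
    if 0.0 not in grid_vals:
        grid_vals = [0.0] + grid_vals
    # The Nmm = 0 reference of each seed must run before its comparisons.
    grid_vals.sort()
    rows = []
    diffs: dict = {"mean": {}}
    accum: dict[float, dict[str, np.ndarray]] = {}
    ph_bins = LayerBins.ph()
    ox_bins = LayerBins.oxygen_difference()
    for seed in spec.replicate_seeds:
        finals = {}
        for nmm in grid_vals:
            p = spec.params.replace(nmm=float(nmm))
            rec = run_single(p, seed, snapshot_iters=(p.n_iter,))
            snap = rec.snapshots[p.n_iter]
            finals[nmm] = snap
            ph_lat = ph_from_h(np.maximum(snap["h"], 1e-300))
            o2_diff = snap["o2"] - finals[0.0]["o2"]
            ph_frac = stratify_layers(ph_lat, ph_bins)
            ox_frac = stratify_layers(o2_diff, ox_bins)
            row = {
                "nmm": nmm,
                "seed": seed,
                "pc": int(rec.column("pc")[-1]),
                "pc_nonmutant": int(rec.column("pc_nonmutant")[-1]),
                "qc": int(rec.column("qc")[-1]),
                "nec": int(rec.column("nec")[-1]),
                "gf": float(rec.column("gf")[-1]),
                "nf": float(rec.column("nf")[-1]),
                "rt": float(rec.column("rt")[-1]),
                "volume": float(rec.column("volume")[-1]),
            }
            for k, v in enumerate(ph_frac, start=1):
                row[f"ph_layer{k}"] = float(v)
            for k, v in enumerate(ox_frac, start=1):
                row[f"ox_layer{k}"] = float(v)
            rows.append(row)
            if keep_lattices:
                diffs[(nmm, seed)] = {"o2": o2_diff,
                                      "ph": ph_lat - ph_from_h(
                                          np.maximum(finals[0.0]["h"], 1e-300))}
            bucket = accum.setdefault(nmm, {})
            bucket["o2"] = bucket.get("o2", 0.0) + o2_diff
            bucket["ph"] = bucket.get("ph", 0.0) + (
                ph_lat - ph_from_h(np.maximum(finals[0.0]["h"], 1e-300)))
    nrep = len(spec.replicate_seeds)
    for nmm, bucket in accum.items():
        diffs["mean"][nmm] = {k: v / nrep for k, v in bucket.items()}
    df = pd.DataFrame(rows)
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep_summary.csv", index=False)
    return df, diffs
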