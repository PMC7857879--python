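"""Tumor geometry, population metrics and spatial stratification.

The tumor is summarized by its mean radius Rt (average Euclidean distance
from the seed to the boundary cells), from which the proliferative-rim
thickness and necrotic-core radius follow the empirical power law

    Wp = b * Rt^(2/3),        Rn = max(0, Rt - (a + b * Rt^(2/3))),

and by the growth fraction GF = PC/tumor and necrotic fraction
NF = NeC/tumor.  The critical point is the first iteration at which the
necrotic population catches the proliferating one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .model import CellGrid, MetabolicFields, ModelParams, NORMAL, ph_from_h
from .dynamics import MOORE_OFFSETS


@dataclass(frozen=True)
class TumorGeometry:
    rt: float
    rn: float
    wp: float


@dataclass(frozen=True)
class LayerBins:
    """Descending bin edges partitioning the real line.

    ``edges = (e0, e1, ..., ek)`` yields k+2 bins: >= e0, [e1, e0), ...,
    < ek.  Defaults carry the pH stratification (7.2 / 7.0 / 6.8); use
    :meth:`oxygen_difference` for the relative-oxygen bins.
    """

    edges: tuple[float, ...] = (7.2, 7.0, 6.8)

    def __post_init__(self):
        if list(self.edges) != sorted(self.edges, reverse=True):
            raise ValueError("edges must be strictly descending")

    @classmethod
    def ph(cls) -> "LayerBins":
        return cls((7.2, 7.0, 6.8))

    @classmethod
    def oxygen_difference(cls) -> "LayerBins":
        # Bins on the (Nmm run minus Nmm=0 run) oxygen difference lattice.
        return cls((-0.4e-8, -0.8e-8))


@lru_cache(maxsize=8)
def _distance_lattice(n: int, center: tuple[int, int]) -> np.ndarray:
    rows = np.arange(n)[:, None] - center[0]
    cols = np.arange(n)[None, :] - center[1]
    return np.hypot(rows, cols)


def distance_from_center(grid: CellGrid) -> np.ndarray:
    """Euclidean distance of every site from the tumor seed, in lattice units."""
    return _distance_lattice(grid.ncell, grid.center)


def boundary_tumor_mask(grid: CellGrid) -> np.ndarray:
    """Tumor cells with at least one non-tumor Moore neighbor (periodic)."""
    tumor = grid.tumor_mask()
    non_tumor_nb = np.zeros(tumor.shape, dtype=int)
    for dr, dc in MOORE_OFFSETS:
        non_tumor_nb += ~np.roll(tumor, (dr, dc), axis=(0, 1))
    return tumor & (non_tumor_nb > 0)


def compute_radius(grid: CellGrid) -> float:
    """Mean distance from the seed to the tumor's external edge."""
    boundary = boundary_tumor_mask(grid)
    if not boundary.any():
        raise ValueError("no tumor cells: radius undefined")
    return float(distance_from_center(grid)[boundary].mean())


def compute_geometry(rt: float, p: ModelParams) -> TumorGeometry:
    """Rim thickness and necrotic-core radius from the mean radius."""
    if rt < 0:
        raise ValueError("radius must be non-negative")
    wp = p.b * rt ** (2.0 / 3.0)
    rn = max(0.0, rt - (p.a + wp))
    return TumorGeometry(rt=rt, rn=rn, wp=wp)


def compute_fractions(pc: int, qc: int, nec: int) -> tuple[float, float]:
    """Growth fraction PC/total and necrotic fraction NeC/total."""
    total = pc + qc + nec
    if total <= 0:
        raise ValueError("no tumor cells: fractions undefined")
    return pc / total, nec / total


def tumor_volume(rt) -> np.ndarray | float:
    """Spherical-approximation volume, proportional to Rt**3."""
    return np.asarray(rt, dtype=float) ** 3 if np.ndim(rt) else float(rt) ** 3


def normalize_series(series: np.ndarray) -> np.ndarray:
    """Scale a time series to end at 1.0 (reporting convention)."""
    series = np.asarray(series, dtype=float)
    final = series[-1]
    return series / final if final > 0 else series.copy()


def stratify_layers(field_values: np.ndarray, bins: LayerBins) -> np.ndarray:
    """Fraction of lattice sites per layer, ordered from the >= e0 bin down.

    The bins partition the line, so the fractions sum to 1.
    """
    flat = np.asarray(field_values, dtype=float).ravel()
    edges = np.asarray(bins.edges, dtype=float)
    counts = [np.count_nonzero(flat >= edges[0])]
    for hi, lo in zip(edges[:-1], edges[1:]):
        counts.append(np.count_nonzero((flat >= lo) & (flat < hi)))
    counts.append(np.count_nonzero(flat < edges[-1]))
    return np.asarray(counts, dtype=float) / flat.size


def center_edge_profile(fields: MetabolicFields, grid: CellGrid
                        ) -> dict[str, tuple[float, float]]:
    """Per-field (seed-site value, mean over boundary tumor cells)."""
    boundary = boundary_tumor_mask(grid)
    if not boundary.any():
        raise ValueError("no tumor cells: profile undefined")
    ci, cj = grid.center
    out = {}
    for name, arr in fields.as_dict().items():
        out[name] = (float(arr[ci, cj]), float(arr[boundary].mean()))
    return out


@dataclass
class SimulationRecord:
    """Per-iteration time series of a run (row 0 is the initial state)."""

    data: dict[str, list] = field(default_factory=dict)
    snapshots: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)

    COLUMNS = (
        "iteration", "pc", "pc_mutant", "pc_nonmutant", "qc", "nec", "tumor",
        "gf", "nf", "rt", "rn", "wp", "volume",
        "mean_o2", "mean_gl", "mean_ph", "min_ph",
        "tumor_o2", "tumor_gl", "tumor_ph",
        "center_o2", "edge_o2", "center_gl", "edge_gl",
        "center_ph", "edge_ph",
    )

    def append(self, t: int, grid: CellGrid, fields: MetabolicFields,
               p: ModelParams) -> None:
        counts = grid.counts()
        tumor = counts["pc"] + counts["qc"] + counts["nec"]
        gf, nf = compute_fractions(counts["pc"], counts["qc"], counts["nec"])
        rt = compute_radius(grid)
        geom = compute_geometry(rt, p)
        n_tumor = max(tumor, 1)
        # Reporting convention: lattice sum of each factor per tumor cell.
        mean_h = float(fields.h.sum()) / n_tumor
        # Plain spatial means over tumor-occupied sites.
        tmask = grid.tumor_mask()
        profile = center_edge_profile(fields, grid)
        row = {
            "iteration": t,
            **counts,
            "tumor": tumor,
            "gf": gf,
            "nf": nf,
            "rt": rt,
            "rn": geom.rn,
            "wp": geom.wp,
            "volume": tumor_volume(rt),
            "mean_o2": float(fields.o2.sum()) / n_tumor,
            "mean_gl": float(fields.gl.sum()) / n_tumor,
            "mean_ph": ph_from_h(mean_h),
            "min_ph": ph_from_h(float(fields.h.max())),
            "tumor_o2": float(fields.o2[tmask].mean()),
            "tumor_gl": float(fields.gl[tmask].mean()),
            "tumor_ph": ph_from_h(float(fields.h[tmask].mean())),
            "center_o2": profile["o2"][0],
            "edge_o2": profile["o2"][1],
            "center_gl": profile["gl"][0],
            "edge_gl": profile["gl"][1],
            "center_ph": ph_from_h(max(profile["h"][0], 1e-300)),
            "edge_ph": ph_from_h(max(profile["h"][1], 1e-300)),
        }
        for key, val in row.items():
            self.data.setdefault(key, []).append(val)

    def __len__(self) -> int:
        return len(self.data.get("iteration", ()))

    def column(self, name: str) -> np.ndarray:
        return np.asarray(self.data[name])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({k: self.data[k] for k in self.COLUMNS})

    # -- derived summaries -------------------------------------------------
    def first_necrosis(self) -> int | None:
        """First iteration with a positive necrotic count."""
        nec = self.column("nec")
        idx = np.flatnonzero(nec > 0)
        return int(self.column("iteration")[idx[0]]) if idx.size else None

    def rt_at_first_necrosis(self) -> float | None:
        t = self.first_necrosis()
        if t is None:
            return None
        pos = int(np.flatnonzero(self.column("iteration") == t)[0])
        return float(self.column("rt")[pos])

    def plateau_pc(self, window: int = 20) -> float:
        """Mean PC count over the final ``window`` recorded iterations."""
        return float(self.column("pc")[-window:].mean())

    def normalized_volume(self) -> np.ndarray:
        return normalize_series(self.column("volume"))


def detect_cp(record: SimulationRecord) -> int | None:
    """Critical point: first iteration with NeC count >= PC count.

    Requires a positive PC count at some earlier iteration; returns None if
    the populations never cross.
    """
    if len(record) == 0:
        raise ValueError("empty record")
    pc = record.column("pc")
    nec = record.column("nec")
    seen_pc = False
    for i in range(len(pc)):
        if seen_pc and nec[i] >= pc[i]:
            return int(record.column("iteration")[i])
        seen_pc = seen_pc or pc[i] > 0
    return None
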