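"""Core domain types for the avascular tumor cellular automaton.

The model couples a 2-D lattice of cells in four states -- normal/empty (0),
proliferating tumor (1, "PC"), quiescent tumor (2, "QC") and necrotic
(3, "NeC") -- to five co-registered concentration fields (oxygen, glucose,
protons, growth factor, inhibitory factor).  This module holds the lattice
containers, the parameter set with validation and derived quantities, the
pH <-> [H+] conversion, and structured-config round-tripping.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

# Cell state codes (lattice values).
NORMAL = 0          # living normal cell or empty space (see CellGrid.empty)
PROLIFERATIVE = 1   # proliferating tumor cell (PC)
QUIESCENT = 2       # quiescent tumor cell (QC)
NECROTIC = 3        # necrotic cell (NeC); absorbing

STATE_CODES = (NORMAL, PROLIFERATIVE, QUIESCENT, NECROTIC)

FIELD_NAMES = ("o2", "gl", "h", "gf", "if_")

# Seconds per iteration at the default 0.1-day time step.
SECONDS_PER_DAY = 86400.0


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants.

    Attributes
    ----------
    fields : list of str
        Names of the offending parameters.
    """

    def __init__(self, problems: dict[str, str]):
        self.fields = sorted(problems)
        msg = "; ".join(f"{k}: {v}" for k, v in sorted(problems.items()))
        super().__init__(f"invalid parameters -- {msg}")
        self.problems = problems


def ph_from_h(h):
    """pH = -log10([H+]) for a proton concentration in mol/L.

    Accepts scalars or arrays; every entry must be strictly positive.
    """
    arr = np.asarray(h, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("proton concentration must be strictly positive")
    out = -np.log10(arr)
    return float(out) if np.isscalar(h) or arr.ndim == 0 else out


def h_from_ph(ph):
    """Inverse of :func:`ph_from_h`: [H+] = 10**(-pH) in mol/L."""
    arr = np.asarray(ph, dtype=float)
    out = np.power(10.0, -arr)
    return float(out) if np.isscalar(ph) or arr.ndim == 0 else out


@dataclass(frozen=True)
class CellState:
    """Scalar cell state: a code in {0,1,2,3} plus an empty-space flag.

    Code 0 covers both living normal tissue and empty space left behind by
    apoptosis; ``empty_flag`` separates the two because living normal cells
    consume nutrients while empty sites are inert.
    """

    code: int
    empty_flag: bool = False

    def __post_init__(self):
        if self.code not in STATE_CODES:
            raise ValueError(f"cell state code must be one of {STATE_CODES}")
        if self.empty_flag and self.code != NORMAL:
            raise ValueError("empty_flag is only meaningful for state 0")


@dataclass
class CellGrid:
    """Square lattice of cell states with per-cell phenotype and stall data.

    Attributes
    ----------
    states : (n, n) int8 array of codes in {0,1,2,3}
    mutant : (n, n) bool, meaningful only where states == 1
    empty : (n, n) bool, meaningful only where states == 0
    stall : (n, n) int16, consecutive failed mitosis attempts of a PC
    center : (row, col) of the tumor seed, 0-based
    """

    states: np.ndarray
    mutant: np.ndarray
    empty: np.ndarray
    stall: np.ndarray
    center: tuple[int, int]

    @property
    def ncell(self) -> int:
        return self.states.shape[0]

    @classmethod
    def blank(cls, ncell: int, center: tuple[int, int] | None = None) -> "CellGrid":
        """All-normal lattice (no tumor, no empty space)."""
        if center is None:
            center = (ncell // 2, ncell // 2)
        shape = (ncell, ncell)
        grid = cls(
            states=np.zeros(shape, dtype=np.int8),
            mutant=np.zeros(shape, dtype=bool),
            empty=np.zeros(shape, dtype=bool),
            stall=np.zeros(shape, dtype=np.int16),
            center=tuple(int(c) for c in center),
        )
        grid.check()
        return grid

    def copy(self) -> "CellGrid":
        return CellGrid(self.states.copy(), self.mutant.copy(),
                        self.empty.copy(), self.stall.copy(), self.center)

    def check(self) -> None:
        """Raise ValueError on any structural invariant violation."""
        n = self.ncell
        if self.states.shape != (n, n):
            raise ValueError("states must be square")
        for name in ("mutant", "empty", "stall"):
            if getattr(self, name).shape != (n, n):
                raise ValueError(f"{name} shape differs from states")
        if not np.all(np.isin(self.states, STATE_CODES)):
            raise ValueError("states contain codes outside {0,1,2,3}")
        if np.any(self.empty & (self.states != NORMAL)):
            raise ValueError("empty flag set on a non-state-0 site")
        if np.any(self.stall[self.states != PROLIFERATIVE] != 0):
            raise ValueError("stall counter nonzero outside PC sites")
        r, c = self.center
        if not (0 <= r < n and 0 <= c < n):
            raise ValueError("center outside the lattice")

    def tumor_mask(self) -> np.ndarray:
        return self.states != NORMAL

    def counts(self) -> dict[str, int]:
        """Population counts, with PCs split by phenotype."""
        pc = self.states == PROLIFERATIVE
        return {
            "pc": int(pc.sum()),
            "pc_mutant": int((pc & self.mutant).sum()),
            "pc_nonmutant": int((pc & ~self.mutant).sum()),
            "qc": int((self.states == QUIESCENT).sum()),
            "nec": int((self.states == NECROTIC).sum()),
        }


@dataclass
class MetabolicFields:
    """Five non-negative concentration lattices co-registered with a CellGrid.

    o2 and gl are in mMol; h is in mol/L so that pH = -log10(h); gf and if_
    are dimensionless fractions of the medium supply.
    """

    o2: np.ndarray
    gl: np.ndarray
    h: np.ndarray
    gf: np.ndarray
    if_: np.ndarray

    @classmethod
    def uniform(cls, ncell: int, p: "ModelParams") -> "MetabolicFields":
        shape = (ncell, ncell)
        return cls(
            o2=np.full(shape, p.c0, dtype=float),
            gl=np.full(shape, p.g0, dtype=float),
            h=np.full(shape, h_from_ph(p.ph0), dtype=float),
            gf=np.full(shape, p.gf0, dtype=float),
            if_=np.full(shape, p.if0, dtype=float),
        )

    def copy(self) -> "MetabolicFields":
        return MetabolicFields(*(getattr(self, f).copy() for f in FIELD_NAMES))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f: getattr(self, f) for f in FIELD_NAMES}

    def check(self) -> None:
        shapes = {getattr(self, f).shape for f in FIELD_NAMES}
        if len(shapes) != 1:
            raise ValueError("field shapes differ")
        for f in FIELD_NAMES:
            if np.any(getattr(self, f) < 0):
                raise ValueError(f"negative concentration in field {f!r}")


@dataclass
class ModelParams:
    """Every named constant of the model plus the gap-filling parameters.

    Thresholds, diffusion coefficients and base rates follow the published
    control-parameter table; the remaining entries (rate_scale,
    proton_buffering, anaerobic multipliers, quiescent_factor, stall_limit,
    alpha_max, factor_scale) close gaps the source tables leave open and are
    calibrated once, then frozen as these defaults.
    """

    # --- microenvironment thresholds ---
    ph_thre_q: float = 6.4       # pH below which a PC quiesces
    ph_thre_ne: float = 6.0      # pH below which a tumor cell necroses
    o2_thre: float = 0.02        # mMol; PC -> QC and the anaerobic switch
    gl_thre: float = 0.06        # mMol; PC -> QC
    o2_thre2: float | None = None  # mMol; necrosis threshold, default o2_thre/2
    gl_thre2: float | None = None  # mMol; necrosis threshold, default gl_thre/2

    # --- physical diffusion coefficients ---
    d_o2: float = 1.82e-5        # cm^2/s
    d_gl: float = 9.1e-5         # cm^2/s
    d_gf: float = 1e-6 / 3600.0  # cm^2/s (published as 1e-6 cm^2/h)
    d_if: float = 1e-6 / 3600.0  # cm^2/s
    d_h: float = 1.1e-5          # cm^2/s
    alpha_max: float = 0.9       # mixing weight of the fastest field
    alpha: dict[str, float] | None = None  # per-field overrides; else derived

    # --- base per-cell consumption/production rates ---
    cr_o2: float = 2.3e-16       # Mol cell^-1 s^-1
    cr_gl: float = 3.8e-17       # Mol cell^-1 s^-1
    cr_gf: float = 0.5           # cm^3 h^-1 (dimensionless fraction here)
    cr_if: float = 1.0           # cm^3 h^-1
    cr_h: float = 1.5e-18        # Mol cell^-1 s^-1
    # Conversion from per-cell rates to per-site mMol per iteration; absorbs
    # the unstated site volume and cells-per-site.
    rate_scale: float = 5.75e13
    # Fraction of produced acid that persists as free H+ (tissue buffering).
    proton_buffering: float = 5e-3
    # Scale for the dimensionless growth/inhibitory factor turnover.
    factor_scale: float = 0.01
    # O2/gl uptake of a living normal cell relative to an aerobic PC.
    modulation_normal: float = 0.5

    # --- growth / division ---
    p0: float = 0.7              # base division probability, mutant PC
    phi0: float = 0.6            # base division probability, nonmutant PC
    a: float = 0.42              # necrotic-core geometry offset
    b: float = 0.11              # proliferative-rim thickness coefficient
    rmax: float = 37.5           # lattice units; division probability 0 beyond
    nmm: float = 0.2             # P(mutant PC's daughter is nonmutant)
    stall_limit: int = 26        # failed mitosis attempts before PC -> QC
    # The stalling allowance grows with the iteration count: a PC quiesces
    # once its consecutive failures exceed max(stall_limit,
    # stall_growth * t).  0 recovers a constant allowance.
    stall_growth: float = 0.4

    # --- anaerobic metabolism multipliers (active where o2 < o2_thre) ---
    k_gl_anaerobic: float = 5.0
    k_h_anaerobic: float = 2.0
    k_o2_anaerobic: float = 0.1

    # --- quiescent metabolism relative to PC ---
    quiescent_factor: float = 0.2

    # --- medium / background concentrations ---
    c0: float = 0.8              # mMol oxygen
    g0: float = 5.5              # mMol glucose
    ph0: float = 7.4             # medium pH
    gf0: float = 1.0             # medium growth-factor fraction
    if0: float = 0.0             # medium inhibitory-factor fraction
    medium_floor_frac: float = 0.95
    replenish_mode: str = "all_state0"  # or "boundary"
    normal_death: str = "empty"  # fate of a normal cell under lethal conditions

    # --- run control ---
    ncell: int = 101
    center: tuple[int, int] | None = None
    n_iter: int = 200
    seed: int = 0
    dt_days: float = 0.1
    init_jitter: float = 0.0     # relative uniform jitter on initial fields

    def __post_init__(self):
        self.validate()

    # -- derived quantities ------------------------------------------------
    def diffusion_coefficients(self) -> dict[str, float]:
        return {"o2": self.d_o2, "gl": self.d_gl, "h": self.d_h,
                "gf": self.d_gf, "if_": self.d_if}

    def alphas(self) -> dict[str, float]:
        """Per-field mixing weights.

        Unless overridden, alpha_i = alpha_max * D_i / max_j D_j, which keeps
        the stated monotone link between diffusion coefficient and mixing.
        """
        if self.alpha is not None:
            return dict(self.alpha)
        d = self.diffusion_coefficients()
        dmax = max(d.values())
        return {k: self.alpha_max * v / dmax for k, v in d.items()}

    @property
    def o2_necrosis(self) -> float:
        return self.o2_thre / 2.0 if self.o2_thre2 is None else self.o2_thre2

    @property
    def gl_necrosis(self) -> float:
        return self.gl_thre / 2.0 if self.gl_thre2 is None else self.gl_thre2

    @property
    def center_site(self) -> tuple[int, int]:
        if self.center is None:
            return (self.ncell // 2, self.ncell // 2)
        return tuple(int(c) for c in self.center)

    @property
    def h0(self) -> float:
        return h_from_ph(self.ph0)

    def validate(self) -> "ModelParams":
        """Check all invariants; raise ParameterError listing offenders."""
        bad: dict[str, str] = {}

        def req(cond, name, why):
            if not cond:
                bad[name] = why

        for name in ("p0", "phi0", "nmm", "medium_floor_frac",
                     "k_o2_anaerobic", "proton_buffering"):
            v = getattr(self, name)
            req(0.0 <= v <= 1.0, name, f"{v} outside [0, 1]")
        req(0.0 < self.quiescent_factor < 1.0,
            "quiescent_factor", "must lie in (0, 1)")
        for name in ("ph_thre_q", "ph_thre_ne", "o2_thre", "gl_thre",
                     "c0", "g0", "ph0", "gf0", "rmax", "rate_scale",
                     "cr_o2", "cr_gl", "cr_h", "cr_gf", "cr_if",
                     "d_o2", "d_gl", "d_h", "d_gf", "d_if", "dt_days"):
            v = getattr(self, name)
            req(v > 0, name, f"{v} must be positive")
        for name in ("if0", "factor_scale", "modulation_normal",
                     "init_jitter"):
            req(getattr(self, name) >= 0, name, "must be non-negative")
        for name in ("k_gl_anaerobic", "k_h_anaerobic"):
            req(getattr(self, name) >= 1.0, name, "must be >= 1")
        for name, v in (("o2_thre2", self.o2_thre2), ("gl_thre2", self.gl_thre2)):
            if v is not None:
                req(v > 0, name, "must be positive when overridden")
        req(self.stall_limit >= 1, "stall_limit", "must be a positive integer")
        req(self.stall_growth >= 0, "stall_growth", "must be non-negative")
        req(self.ncell >= 3, "ncell", "lattice side must be >= 3")
        req(self.n_iter >= 0, "n_iter", "must be non-negative")
        req(self.replenish_mode in ("all_state0", "boundary"),
            "replenish_mode", f"unknown mode {self.replenish_mode!r}")
        req(self.normal_death in ("empty", "necrotic"),
            "normal_death", f"unknown fate {self.normal_death!r}")
        req(0.0 < self.alpha_max < 1.0, "alpha_max", "must lie in (0, 1)")
        if self.alpha is not None:
            for k, v in self.alpha.items():
                req(k in FIELD_NAMES, f"alpha[{k}]", "unknown field")
                req(0.0 < v < 1.0, f"alpha[{k}]", f"{v} outside (0, 1)")
        if self.center is not None:
            r, c = self.center
            req(0 <= r < self.ncell and 0 <= c < self.ncell,
                "center", "outside the lattice")
        if bad:
            raise ParameterError(bad)
        return self

    # -- config round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["center"] is not None:
            d["center"] = list(d["center"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError({k: "unknown parameter" for k in unknown})
        d = dict(d)
        if d.get("center") is not None:
            d["center"] = tuple(d["center"])
        return cls(**d)

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def validate_params(p: ModelParams) -> ModelParams:
    """Validate a parameter set and return it (derived fields are lazy)."""
    return p.validate()
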