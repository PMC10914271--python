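"""Stochastic on-lattice agent-based model of evolution under a drug field.

Each lattice site holds at most one cell, identified by its genotype index.
Per hourly time step, cells are visited in a fresh random order; each cell

1. dies with probability ``death_rate * dt`` (drug-independent),
2. otherwise attempts division with probability ``g(genotype, local conc) * dt``
   clamped to [0, 1] — forced to zero where the local concentration exceeds
   the net-loss threshold in empirical mode,
3. on division places a daughter in a uniformly chosen empty neighbor site
   (Moore 8-neighborhood by default); the daughter mutates with probability
   ``n_sites * mutation_rate`` to a uniformly chosen Hamming-1 neighbor
   genotype (back-mutation allowed).

The drug field is either a fixed spatial profile gated on/off by a
:class:`TreatmentSchedule`, or co-integrated with the population through the
explicit reaction-diffusion solver (vessels clamped to a constant supply
concentration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numba import njit

from .diffusion import DrugField, PkParams, VesselLayout, pde_step
from .seascape import FitnessSeascape, HillCurve, LogisticCurve

__all__ = [
    "EMPTY",
    "SimParams",
    "SimState",
    "PdeConfig",
    "TreatmentSchedule",
    "init_population",
    "step",
    "run",
    "resistant_fraction",
    "counts_from_lattice",
    "write_lattice",
    "read_lattice",
]

#: lattice value for an unoccupied site
EMPTY = -1


@dataclass
class SimParams:
    """Agent-based simulation parameters (rates per hour, lengths in lattice units)."""

    mutation_rate: float = 1e-4  # per site per division
    init_mutant_prob: float = 0.01
    death_rate: float = 0.1
    init_density: float = 1.0
    init_shape: str = "circle"  # "circle" or "square"
    init_radius: float = 10.0  # circle radius
    init_side: int = 100  # square side
    vessel_conc: float = 1e3
    diffusion_rate: float = 0.1
    n_steps: int = 1000
    dt: float = 1.0
    rng_seed: int = 0
    neighborhood: str = "moore"  # "moore" (8) or "von_neumann" (4)
    net_loss_threshold: Optional[float] = None  # empirical mode if set

    def __post_init__(self) -> None:
        for p in ("mutation_rate", "init_mutant_prob", "init_density"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{p} must be in [0, 1], got {v}")
        if self.death_rate < 0 or self.dt <= 0:
            raise ValueError("death_rate must be >= 0 and dt > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ValueError("neighborhood must be 'moore' or 'von_neumann'")


@dataclass
class SimState:
    """Lattice occupancy (genotype index per site, :data:`EMPTY` for none) plus clock."""

    lattice: np.ndarray
    time: float = 0.0
    n_sites: int = 2
    drug: Optional[np.ndarray] = None  # current drug field values
    births: int = 0
    deaths: int = 0

    @property
    def cell_count(self) -> int:
        return int(np.count_nonzero(self.lattice >= 0))


@dataclass
class PdeConfig:
    """Drug-field co-integration settings for :func:`run`.

    ``init`` selects the initial field: ``"zero"`` (drug introduced at t=0)
    or ``"steady"`` (field pre-relaxed to the reaction-diffusion steady state,
    the long-term repeated-dosing regime); ``u0`` supplies an explicit
    initial field and overrides ``init``.
    """

    layout: VesselLayout
    params: PkParams
    n_substeps: int = 1
    init: str = "zero"
    u0: Optional[np.ndarray] = None

    def initial_field(self, grid_shape: Tuple[int, int]) -> np.ndarray:
        from .diffusion import solve_pde

        if self.u0 is not None:
            return np.array(self.u0, dtype=float)
        if self.init == "steady":
            return solve_pde(
                self.layout, self.params, grid_shape, steady_tol=1e-7
            ).values
        if self.init != "zero":
            raise ValueError(f"unknown pde init {self.init!r}")
        return np.zeros(grid_shape, dtype=float)


@dataclass
class TreatmentSchedule:
    """Ordered, non-overlapping on/off intervals covering [0, duration)."""

    intervals: List[Tuple[float, float, bool]]

    def __post_init__(self) -> None:
        iv = sorted(self.intervals)
        for (a, b, _), (c, d, _) in zip(iv[:-1], iv[1:]):
            if b > c:
                raise ValueError("schedule intervals overlap")
            if b < c:
                raise ValueError("schedule intervals leave a gap")
        for a, b, _ in iv:
            if b <= a:
                raise ValueError("empty schedule interval")
        self.intervals = iv

    @property
    def duration(self) -> float:
        return self.intervals[-1][1] - self.intervals[0][0]

    def is_on(self, t: float) -> bool:
        for a, b, on in self.intervals:
            if a <= t < b:
                return on
        return False  # outside the schedule: no drug

    @classmethod
    def always_on(cls, duration: float) -> "TreatmentSchedule":
        return cls([(0.0, float(duration), True)])

    @classmethod
    def always_off(cls, duration: float) -> "TreatmentSchedule":
        return cls([(0.0, float(duration), False)])

    @classmethod
    def cyclic(
        cls,
        n_cycles: int = 4,
        on_hours: float = 168.0,
        off_hours: float = 168.0,
        tail_off_hours: float = 672.0,
    ) -> "TreatmentSchedule":
        """N cycles of drug-on/drug-off followed by a final drug-free period.

        Defaults give the four-cycle one-week-on / one-week-off regimen with
        a four-week drug holiday (2016 h total).
        """
        t = 0.0
        intervals: List[Tuple[float, float, bool]] = []
        for _ in range(n_cycles):
            intervals.append((t, t + on_hours, True))
            t += on_hours
            intervals.append((t, t + off_hours, False))
            t += off_hours
        if tail_off_hours > 0:
            intervals.append((t, t + tail_off_hours, False))
        return cls(intervals)


def _curve_arrays(seascape: FitnessSeascape) -> Tuple[np.ndarray, np.ndarray]:
    """Pack per-genotype curve parameters into numba-friendly arrays."""
    n = 2**seascape.n_sites
    models = np.zeros(n, dtype=np.int64)
    params = np.zeros((n, 4), dtype=np.float64)
    for g, curve in seascape.curves.items():
        if isinstance(curve, LogisticCurve):
            models[g.index] = 0
            params[g.index] = (curve.g_drugless, curve.ic50, curve.nu, 0.0)
        elif isinstance(curve, HillCurve):
            models[g.index] = 1
            params[g.index] = (curve.g_max, curve.g_min, curve.ic50, curve.nu)
        else:  # pragma: no cover - seascape enforces curve types
            raise TypeError(f"unsupported curve type {type(curve)}")
    return models, params


@njit(cache=True)
def _seed_kernel_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _growth_nb(gi, c, models, params):
    if models[gi] == 0:  # logistic
        z = (params[gi, 1] - c) / params[gi, 2]
        if z > 500.0:
            return 0.0
        return params[gi, 0] / (1.0 + np.exp(z))
    # hill
    gmax = params[gi, 0]
    gmin = params[gi, 1]
    ic50 = params[gi, 2]
    nu = params[gi, 3]
    if c <= 0.0:
        return gmax
    t = (ic50 / c) ** nu
    if t > 1e300:
        return gmax
    return gmax + (gmin - gmax) / (1.0 + t)


@njit(cache=True)
def _step_kernel(
    lat,
    conc,
    models,
    params,
    death_p,
    dt,
    mut_p,
    n_sites,
    net_loss_thresh,  # negative => disabled (growth-rate criterion only)
    drug_on,
    moore,
):
    H, W = lat.shape
    n = 0
    for i in range(H):
        for j in range(W):
            if lat[i, j] >= 0:
                n += 1
    xs = np.empty(n, np.int64)
    ys = np.empty(n, np.int64)
    idx = 0
    for i in range(H):
        for j in range(W):
            if lat[i, j] >= 0:
                xs[idx] = i
                ys[idx] = j
                idx += 1
    # Fisher-Yates shuffle: fresh random visiting order each step
    for a in range(n - 1, 0, -1):
        b = np.random.randint(0, a + 1)
        xs[a], xs[b] = xs[b], xs[a]
        ys[a], ys[b] = ys[b], ys[a]
    births = 0
    deaths = 0
    exi = np.empty(8, np.int64)
    eyj = np.empty(8, np.int64)
    for m in range(n):
        i = xs[m]
        j = ys[m]
        gi = lat[i, j]
        if gi < 0:
            continue
        if np.random.random() < death_p:
            lat[i, j] = EMPTY
            deaths += 1
            continue
        c = conc[i, j] if drug_on else 0.0
        if net_loss_thresh >= 0.0 and c > net_loss_thresh:
            continue  # net-loss regime: division probability zero
        p = _growth_nb(gi, c, models, params) * dt
        if p <= 0.0:
            continue
        if p > 1.0:
            p = 1.0
        if np.random.random() < p:
            cnt = 0
            for di in range(-1, 2):
                for dj in range(-1, 2):
                    if di == 0 and dj == 0:
                        continue
                    if not moore and di != 0 and dj != 0:
                        continue
                    ii = i + di
                    jj = j + dj
                    if 0 <= ii < H and 0 <= jj < W and lat[ii, jj] < 0:
                        exi[cnt] = ii
                        eyj[cnt] = jj
                        cnt += 1
            if cnt == 0:
                continue  # contact inhibition: no empty adjacent site
            s = np.random.randint(0, cnt)
            child = gi
            if mut_p > 0.0 and np.random.random() < mut_p:
                bit = np.random.randint(0, n_sites)
                child = gi ^ (1 << (n_sites - 1 - bit))  # leftmost char = site 0
            lat[exi[s], eyj[s]] = child
            births += 1
    return births, deaths


def init_population(
    params: SimParams,
    seascape: FitnessSeascape,
    grid_shape: Tuple[int, int],
    rng: Optional[np.random.Generator] = None,
) -> SimState:
    """Seed the lattice with an initial population.

    Sites inside the initial geometry (circle of ``init_radius`` or square of
    ``init_side``, centered) are occupied with probability ``init_density``;
    each initial cell is wild-type with probability ``1 - init_mutant_prob``
    and otherwise a uniform draw over the non-wild-type genotypes.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    H, W = grid_shape
    ci, cj = H // 2, W // 2
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    if params.init_shape == "circle":
        if params.init_radius > min(ci, cj, H - 1 - ci, W - 1 - cj):
            raise ValueError("initial circle does not fit in the grid")
        inside = (ii - ci) ** 2 + (jj - cj) ** 2 <= params.init_radius**2
    elif params.init_shape == "square":
        half = params.init_side / 2.0
        if params.init_side > min(H, W):
            raise ValueError("initial square does not fit in the grid")
        inside = (np.abs(ii - ci) < half) & (np.abs(jj - cj) < half)
        if params.init_side >= min(H, W):
            inside[:] = True
    else:
        raise ValueError(f"unknown init_shape {params.init_shape!r}")
    lattice = np.full(grid_shape, EMPTY, dtype=np.int64)
    occupied = inside & (rng.random(grid_shape) < params.init_density)
    n_genotypes = 2**seascape.n_sites
    n_cells = int(occupied.sum())
    genos = np.zeros(n_cells, dtype=np.int64)
    mutant = rng.random(n_cells) < params.init_mutant_prob
    genos[mutant] = rng.integers(1, n_genotypes, size=int(mutant.sum()))
    lattice[occupied] = genos
    return SimState(lattice=lattice, time=0.0, n_sites=seascape.n_sites)


def step(
    state: SimState,
    seascape: FitnessSeascape,
    field: Union[DrugField, np.ndarray],
    params: SimParams,
    schedule: Optional[TreatmentSchedule] = None,
) -> SimState:
    """Advance the population by one time step (mutates ``state`` in place).

    The kernel RNG must have been seeded (``run`` does this); for standalone
    stepping call ``numba_seed(seed)`` first via :func:`seed_kernel`.
    """
    conc = np.asarray(getattr(field, "values", field), dtype=float)
    if conc.shape != state.lattice.shape:
        raise ValueError("drug field shape does not match lattice shape")
    drug_on = schedule.is_on(state.time) if schedule is not None else True
    thresh = -1.0 if params.net_loss_threshold is None else float(params.net_loss_threshold)
    models, curve_params = _curve_arrays(seascape)
    births, deaths = _step_kernel(
        state.lattice,
        conc,
        models,
        curve_params,
        params.death_rate * params.dt,
        params.dt,
        seascape.n_sites * params.mutation_rate,
        seascape.n_sites,
        thresh,
        drug_on,
        params.neighborhood == "moore",
    )
    state.time += params.dt
    state.births += births
    state.deaths += deaths
    state.drug = conc
    return state


def seed_kernel(seed: int) -> None:
    """Seed the numba-internal RNG used by the step kernel."""
    _seed_kernel_rng(int(seed) % 2**31)


def counts_from_lattice(lattice: np.ndarray, n_sites: int) -> np.ndarray:
    """Per-genotype cell counts (length ``2**n_sites``)."""
    occ = lattice[lattice >= 0]
    return np.bincount(occ, minlength=2**n_sites)


def resistant_fraction(counts) -> float:
    """Fraction of cells that are not wild-type; an empty population gives 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    return float((total - counts[0]) / total)


def run(
    params: SimParams,
    seascape: FitnessSeascape,
    field: Optional[Union[DrugField, np.ndarray]] = None,
    pde: Optional[PdeConfig] = None,
    schedule: Optional[TreatmentSchedule] = None,
    grid_shape: Tuple[int, int] = (100, 100),
    record_every: int = 1,
) -> Tuple[pd.DataFrame, SimState]:
    """Run a full simulation; returns (per-genotype count time series, final state).

    Exactly one of ``field`` (a fixed drug profile, gated by ``schedule``) or
    ``pde`` (a co-integrated reaction-diffusion field from clamped vessels)
    must be given; with neither, the drug concentration is zero everywhere.
    Deterministic for a fixed ``params.rng_seed``.
    """
    if field is not None and pde is not None:
        raise ValueError("give either a fixed field or a PDE config, not both")
    ss = np.random.SeedSequence(params.rng_seed)
    init_seed, kernel_seed = (int(s) % 2**31 for s in ss.generate_state(2))
    rng = np.random.default_rng(init_seed)
    seed_kernel(kernel_seed)

    state = init_population(params, seascape, grid_shape, rng)
    if field is not None:
        conc = np.asarray(getattr(field, "values", field), dtype=float)
        if conc.shape != grid_shape:
            raise ValueError("field shape does not match grid shape")
    elif pde is not None:
        pde.layout.validate_in_grid(grid_shape)
        conc = pde.initial_field(grid_shape)
    else:
        conc = np.zeros(grid_shape, dtype=float)

    n_genotypes = 2**seascape.n_sites
    records = []

    def record(t: float) -> None:
        counts = counts_from_lattice(state.lattice, seascape.n_sites)
        for g in range(n_genotypes):
            records.append({"time": t, "genotype": g, "count": int(counts[g])})

    record(0.0)
    for k in range(params.n_steps):
        if pde is not None:
            conc = pde_step(conc, pde.layout, pde.params, params.dt, n_substeps=pde.n_substeps)
        step(state, seascape, conc, params, schedule)
        if (k + 1) % record_every == 0 or k == params.n_steps - 1:
            record(state.time)
    state.drug = conc
    return pd.DataFrame.from_records(records), state


def write_lattice(state: SimState, path) -> None:
    """Final lattice as integer CSV grid (-1 = empty)."""
    np.savetxt(path, state.lattice, fmt="%d", delimiter=",")


def read_lattice(path, n_sites: int = 2) -> SimState:
    lattice = np.loadtxt(path, dtype=np.int64, delimiter=",", ndmin=2)
    return SimState(lattice=lattice, n_sites=n_sites)
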