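"""Seeded, scalable in-silico experiment recipes.

Three scripted experiments compose the simulator:

* :func:`gamma_sweep` — synthetic two-allele seascape, two clamped vessels,
  co-integrated reaction-diffusion drug field; sweeps the drug elimination
  rate γ and relates selection-window structure to the evolved population
  (Altieri entropies; window area vs final genotype count).
* :func:`sensitivity_grid` — varies mutation rate, initial mutant
  probability, and vessel separation; reports the normalized entropy
  difference between the selection-window map and the final population.
* :func:`therapy` — empirical NSCLC/gefitinib seascape under a cyclic
  drug schedule with a static exponential-penetration field; reports tumor
  size and resistant fraction over time for each penetration length L.

Every output row carries the seed, a config hash, and the package version so
runs are reproducible bit-for-bit from (config, seed list).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .abm import PdeConfig, SimParams, TreatmentSchedule, counts_from_lattice, resistant_fraction, run
from .datasets import GEFITINIB_NET_LOSS_UM, gefitinib_pc9_seascape, gefitinib_um_to_ug_ml
from .diffusion import PkParams, VesselLayout, exp_decay_field
from .entropy import altieri_entropy, entropy_difference
from .msw import NET_LOSS, predicted_counts, selection_map, window_areas
from .seascape import FitnessSeascape, generate_tradeoff_seascape

__all__ = [
    "ExperimentSpec",
    "GammaSweepResult",
    "TherapyResult",
    "gamma_sweep",
    "sensitivity_grid",
    "therapy",
]

DEFAULT_VESSELS = ((50, 25), (50, 75))
DEFAULT_GAMMAS = (1e-4, 1e-3, 1e-2, 1e-1, 0.5)
DEFAULT_LENGTH_SCALES = (2, 4, 8, 16)


@dataclass
class ExperimentSpec:
    """Declarative description of one experiment run."""

    name: str  # gamma_sweep | sensitivity | therapy
    replicates: int = 5
    seed: int = 0
    base_params: Optional[SimParams] = None
    grid: Dict[str, Sequence] = field(default_factory=dict)
    grid_shape: Tuple[int, int] = (100, 100)
    vessels: Sequence[Tuple[int, int]] = DEFAULT_VESSELS
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.name not in ("gamma_sweep", "sensitivity", "therapy"):
            raise ValueError(f"unknown experiment {self.name!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for key, values in self.grid.items():
            if len(list(values)) == 0:
                raise ValueError(f"empty grid for {key!r}")


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _tag(df: pd.DataFrame, seed: int, cfg_hash: str) -> pd.DataFrame:
    df["seed"] = seed
    df["config_hash"] = cfg_hash
    df["version"] = __version__
    return df


def _replicate_seeds(seed: int, n: int) -> List[int]:
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass
class GammaSweepResult:
    runs: pd.DataFrame  # per (gamma, replicate): entropies, totals
    genotype_rows: pd.DataFrame  # per (gamma, replicate, genotype): area/count
    r2_entropy: float
    r2_area_count: float


def synthetic_sim_params(seed: int = 0, **overrides) -> SimParams:
    """Synthetic-experiment defaults: mutation 1e-4/site/division, death 0.1/hr,
    full-density circle of radius 10, vessel concentration 1e3, 1000 hourly steps."""
    base = dict(
        mutation_rate=1e-4,
        init_mutant_prob=0.01,
        death_rate=0.1,
        init_density=1.0,
        init_shape="circle",
        init_radius=10.0,
        vessel_conc=1e3,
        diffusion_rate=0.1,
        n_steps=1000,
        rng_seed=seed,
    )
    base.update(overrides)
    return SimParams(**base)


def empirical_sim_params(seed: int = 0, **overrides) -> SimParams:
    """Empirical-experiment defaults: mutation 1e-3/site/division, death
    0.025/hr, density 0.1 over the full square, vessel concentration 10,
    initial mutant probability 0.1, 2016 hourly steps, cytostatic net-loss
    threshold at the gefitinib cutoff (1.8 μM in μg/mL)."""
    base = dict(
        mutation_rate=1e-3,
        init_mutant_prob=0.1,
        death_rate=0.025,
        init_density=0.1,
        init_shape="square",
        init_side=100,
        vessel_conc=10.0,
        n_steps=2016,
        rng_seed=seed,
        net_loss_threshold=gefitinib_um_to_ug_ml(GEFITINIB_NET_LOSS_UM),
    )
    base.update(overrides)
    return SimParams(**base)


def _entropy_pair(final_lattice, swmap, entropy_kwargs) -> Tuple[float, float]:
    e_msw = altieri_entropy(swmap.labels, **entropy_kwargs).total_pair_entropy
    e_pop = altieri_entropy(final_lattice, exclude_label=-1, **entropy_kwargs).total_pair_entropy
    return e_msw, e_pop


def gamma_sweep(
    seascape: Optional[FitnessSeascape] = None,
    gammas: Sequence[float] = DEFAULT_GAMMAS,
    replicates: int = 5,
    seed: int = 0,
    grid_shape: Tuple[int, int] = (100, 100),
    vessels: Sequence[Tuple[int, int]] = DEFAULT_VESSELS,
    params: Optional[SimParams] = None,
    entropy_max_pairs: int = 200_000,
    out_dir=None,
) -> GammaSweepResult:
    """Drug-elimination-rate sweep with co-integrated drug diffusion.

    For each γ and replicate: run the agent-based model with the PDE drug
    field, derive the final selection-window map from the final field, and
    record window areas, MSW-predicted counts, final genotype counts, and the
    Altieri entropies of the window map (all sites) and of the occupied-cell
    genotype map. Summary R² values regress population entropy on window-map
    entropy and final count on window area.
    """
    if seascape is None:
        seascape = generate_tradeoff_seascape(n_sites=2, rng_seed=seed)
    if params is None:
        params = synthetic_sim_params(seed)
    cfg_hash = _config_hash(
        dict(gammas=list(gammas), replicates=replicates, seed=seed, params=asdict(params))
    )
    entropy_kwargs = dict(max_pairs=entropy_max_pairs, rng_seed=seed)
    layout = VesselLayout(positions=list(vessels), strengths=[params.vessel_conc] * len(vessels))
    run_rows, geno_rows = [], []
    rep_seeds = _replicate_seeds(seed, replicates * len(list(gammas)))
    si = 0
    n_genotypes = 2**seascape.n_sites
    for gamma in gammas:
        pk = PkParams(D=params.diffusion_rate, gamma=gamma, k=params.vessel_conc)
        for rep in range(replicates):
            rseed = rep_seeds[si]
            si += 1
            p = replace(params, rng_seed=rseed)
            _, state = run(
                p, seascape, pde=PdeConfig(layout=layout, params=pk),
                grid_shape=grid_shape, record_every=max(1, params.n_steps),
            )
            swmap = selection_map(seascape, state.drug, death_rate=params.death_rate)
            areas = window_areas(swmap)
            pred = predicted_counts(swmap)
            counts = counts_from_lattice(state.lattice, seascape.n_sites)
            e_msw, e_pop = _entropy_pair(state.lattice, swmap, entropy_kwargs)
            run_rows.append(
                dict(
                    gamma=gamma,
                    replicate=rep,
                    run_seed=rseed,
                    e_msw=e_msw,
                    e_population=e_pop,
                    net_loss_area=areas.get(NET_LOSS, 0),
                    total_cells=int(counts.sum()),
                )
            )
            for g in range(n_genotypes):
                geno_rows.append(
                    dict(
                        gamma=gamma,
                        replicate=rep,
                        run_seed=rseed,
                        genotype=g,
                        window_area=pred[g],
                        predicted_count=pred[g],
                        final_count=int(counts[g]),
                    )
                )
    runs = pd.DataFrame(run_rows)
    genos = pd.DataFrame(geno_rows)
    ok = runs[["e_msw", "e_population"]].notna().all(axis=1) & (runs["total_cells"] > 0)

    def _r2(x, y) -> float:
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        if len(x) < 3 or np.ptp(x) == 0:
            return float("nan")  # degenerate design (e.g. single condition)
        return float(stats.linregress(x, y).rvalue ** 2)

    r2_entropy = _r2(runs.loc[ok, "e_msw"], runs.loc[ok, "e_population"])
    r2_area = _r2(genos["window_area"], genos["final_count"])
    _tag(runs, seed, cfg_hash)
    _tag(genos, seed, cfg_hash)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        runs.to_csv(out / "gamma_sweep_runs.csv", index=False)
        genos.to_csv(out / "gamma_sweep_genotypes.csv", index=False)
    return GammaSweepResult(
        runs=runs, genotype_rows=genos, r2_entropy=r2_entropy, r2_area_count=r2_area
    )


def sensitivity_grid(
    mutation_rates: Sequence[float] = (1e-4, 1e-3, 1e-2, 1e-1),
    init_mutant_probs: Sequence[float] = (0.0, 0.01, 0.1),
    vessel_separations: Sequence[int] = (10, 30, 50, 80),
    gamma: float = 0.01,
    replicates: int = 3,
    seed: int = 0,
    seascape: Optional[FitnessSeascape] = None,
    grid_shape: Tuple[int, int] = (100, 100),
    params: Optional[SimParams] = None,
    entropy_max_pairs: int = 100_000,
    out_dir=None,
) -> pd.DataFrame:
    """Sensitivity of the normalized entropy difference to model parameters.

    Each condition varies exactly one of (mutation rate, initial mutant
    probability, vessel separation) from the base configuration; the
    normalized entropy difference Δ = (e_MSW − e_pop)² / e_MSW is averaged
    over replicates. Vessels sit at x = 50, y = 50 ± separation/2.
    """
    if seascape is None:
        seascape = generate_tradeoff_seascape(n_sites=2, rng_seed=seed)
    if params is None:
        params = synthetic_sim_params(seed)
    conditions = (
        [("mutation_rate", m) for m in mutation_rates]
        + [("init_mutant_prob", p) for p in init_mutant_probs]
        + [("vessel_separation", s) for s in vessel_separations]
    )
    cfg_hash = _config_hash(dict(conditions=conditions, replicates=replicates, seed=seed))
    entropy_kwargs = dict(max_pairs=entropy_max_pairs, rng_seed=seed)
    rep_seeds = _replicate_seeds(seed, replicates * len(conditions))
    rows = []
    si = 0
    for varied, value in conditions:
        if varied == "vessel_separation":
            sep = int(value)
            vessels = [(50, 50 - sep // 2), (50, 50 + sep - sep // 2)]
            p_base = params
        else:
            vessels = list(DEFAULT_VESSELS)
            p_base = replace(params, **{varied: value})
        layout = VesselLayout(
            positions=vessels, strengths=[p_base.vessel_conc] * len(vessels)
        )
        pk = PkParams(D=p_base.diffusion_rate, gamma=gamma, k=p_base.vessel_conc)
        deltas = []
        for rep in range(replicates):
            rseed = rep_seeds[si]
            si += 1
            p = replace(p_base, rng_seed=rseed)
            _, state = run(
                p, seascape, pde=PdeConfig(layout=layout, params=pk),
                grid_shape=grid_shape, record_every=max(1, p.n_steps),
            )
            swmap = selection_map(seascape, state.drug, death_rate=p.death_rate)
            try:
                e_msw, e_pop = _entropy_pair(state.lattice, swmap, entropy_kwargs)
                deltas.append(entropy_difference(e_msw, e_pop))
            except ValueError:  # extinct population or degenerate map
                deltas.append(np.nan)
        rows.append(
            dict(
                varied=varied,
                value=value,
                delta_entropy=float(np.nanmean(deltas)),
                n_replicates=replicates,
            )
        )
    df = _tag(pd.DataFrame(rows), seed, cfg_hash)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sensitivity_grid.csv", index=False)
    return df


@dataclass
class TherapyResult:
    timeseries: pd.DataFrame  # per (L, replicate, time): total and resistant cells
    summary: pd.DataFrame  # per L: mean final counts / resistant fraction
    final_lattices: Dict[Tuple[float, int], np.ndarray]


def therapy(
    length_scales: Sequence[float] = DEFAULT_LENGTH_SCALES,
    replicates: int = 5,
    seed: int = 0,
    seascape: Optional[FitnessSeascape] = None,
    grid_shape: Tuple[int, int] = (100, 100),
    vessels: Sequence[Tuple[int, int]] = DEFAULT_VESSELS,
    params: Optional[SimParams] = None,
    schedule: Optional[TreatmentSchedule] = None,
    record_every: int = 24,
    out_dir=None,
) -> TherapyResult:
    """Cyclic-therapy tumor simulations over drug penetration length scales.

    For each characteristic penetration length L, a static two-vessel
    exponential-decay field is applied during drug-on periods of the cyclic
    schedule (four one-week-on/one-week-off cycles then four weeks off by
    default); drug-off means zero concentration everywhere. Sites above the
    cytostatic net-loss threshold have division probability zero.
    """
    if seascape is None:
        seascape = gefitinib_pc9_seascape()
    if params is None:
        params = empirical_sim_params(seed)
    if schedule is None:
        schedule = TreatmentSchedule.cyclic()
    cfg_hash = _config_hash(
        dict(Ls=list(length_scales), replicates=replicates, seed=seed, params=asdict(params))
    )
    layout = VesselLayout(positions=list(vessels))
    rep_seeds = _replicate_seeds(seed, replicates * len(list(length_scales)))
    rows = []
    lattices: Dict[Tuple[float, int], np.ndarray] = {}
    si = 0
    n_wt = 0  # wild-type genotype index
    for L in length_scales:
        drug = exp_decay_field(layout, k=params.vessel_conc, L=float(L), grid_shape=grid_shape)
        for rep in range(replicates):
            rseed = rep_seeds[si]
            si += 1
            p = replace(params, rng_seed=rseed)
            ts, state = run(
                p, seascape, field=drug, schedule=schedule, grid_shape=grid_shape,
                record_every=record_every,
            )
            wide = ts.pivot(index="time", columns="genotype", values="count")
            total = wide.sum(axis=1)
            resistant = total - wide[n_wt]
            for t, tot, res in zip(wide.index, total, resistant):
                rows.append(
                    dict(
                        L=L,
                        replicate=rep,
                        run_seed=rseed,
                        time=float(t),
                        total=int(tot),
                        resistant=int(res),
                    )
                )
            lattices[(L, rep)] = state.lattice.copy()
    ts_df = _tag(pd.DataFrame(rows), seed, cfg_hash)
    final = ts_df.loc[ts_df.groupby(["L", "replicate"])["time"].idxmax()]
    summary = (
        final.assign(
            resistant_fraction=lambda d: np.where(d["total"] > 0, d["resistant"] / d["total"], 0.0)
        )
        .groupby("L")
        .agg(
            mean_final_total=("total", "mean"),
            mean_final_resistant=("resistant", "mean"),
            mean_resistant_fraction=("resistant_fraction", "mean"),
            extinct_replicates=("total", lambda s: int((s == 0).sum())),
            n_replicates=("total", "size"),
        )
        .reset_index()
    )
    summary = _tag(summary, seed, cfg_hash)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ts_df.to_csv(out / "therapy_timeseries.csv", index=False)
        summary.to_csv(out / "therapy_summary.csv", index=False)
        for (L, rep), lat in lattices.items():
            np.savetxt(out / f"therapy_lattice_L{L}_rep{rep}.csv", lat, fmt="%d", delimiter=",")
    return TherapyResult(timeseries=ts_df, summary=summary, final_lattices=lattices)
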