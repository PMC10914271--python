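"""Mutant selection windows: pairwise window computation and spatial maps.

A mutant selection window (MSW) is the range of drug concentrations over
which a resistant mutant out-competes a reference genotype without its own
net replication being negative. For a reference/mutant pair the scanned
concentration range partitions into:

* *reference selection* — the reference genotype grows faster,
* *mutant selection* — the mutant grows faster,
* *net loss* — both genotypes have net replication rate below zero
  (growth rate minus the death rate), or, in "empirical" mode, the
  concentration exceeds a cytostatic threshold.

An N-site seascape embeds ``N * 2**N`` ordered reference-vs-neighbor
comparisons (``N * 2**(N-1)`` unordered). Applied per lattice site to a
spatial drug field, the same comparison yields a :class:`SelectionWindowMap`
labelling each site with the locally selected genotype or net loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .seascape import FitnessSeascape, Genotype, growth_rate, neighbors

__all__ = [
    "NET_LOSS",
    "WindowSet",
    "SelectionWindowMap",
    "selection_coefficient",
    "windows_from_curves",
    "compute_windows",
    "enumerate_comparisons",
    "selection_map",
    "window_areas",
    "predicted_counts",
    "write_windows",
    "write_selection_map",
    "read_selection_map",
]

#: label used for lattice sites where every genotype has negative net replication
NET_LOSS = -1

Interval = Tuple[float, float]


def selection_coefficient(seascape: FitnessSeascape, genotype_i, genotype_j, conc) -> float:
    """Selection coefficient ``s_ij = g_fitter / g_less_fit`` at ``conc``.

    Symmetric in its genotype arguments and always >= 1; equals 1 exactly
    when the two growth rates coincide. A zero denominator with a non-zero
    numerator returns ``inf`` with a warning.
    """
    gi = growth_rate(seascape, genotype_i, conc)
    gj = growth_rate(seascape, genotype_j, conc)
    hi, lo = max(gi, gj), min(gi, gj)
    if hi == lo:
        return 1.0
    if lo == 0.0:
        warnings.warn("selection_coefficient: zero growth rate in denominator; returning inf")
        return float("inf")
    return float(hi / lo)


@dataclass
class WindowSet:
    """Partition of a concentration range into selection and net-loss windows."""

    reference_windows: List[Interval]
    mutant_windows: List[Interval]
    net_loss_windows: List[Interval]
    death_rate: float
    conc_range: Interval
    tie_in_reference: bool = False  # exact-tie regions are reported as reference

    def total_coverage(self) -> float:
        return sum(
            hi - lo
            for windows in (self.reference_windows, self.mutant_windows, self.net_loss_windows)
            for lo, hi in windows
        )


def _scan_grid(lo: float, hi: float, resolution: int) -> np.ndarray:
    # log spacing when the range spans more than two decades (and lo > 0)
    if lo > 0 and hi / lo > 100.0:
        return np.geomspace(lo, hi, resolution)
    return np.linspace(lo, hi, resolution)


def _bisect(f: Callable[[float], float], a: float, b: float, tol: float) -> float:
    fa, fb = f(a), f(b)
    if fa == 0.0:
        return a
    if fb == 0.0:
        return b
    if fa * fb > 0:  # no sign change; fall back to midpoint
        return 0.5 * (a + b)
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            return m
        if fa * fm < 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def windows_from_curves(
    g_ref: Callable,
    g_mut: Callable,
    death_rate: float,
    conc_range: Interval,
    resolution: int = 512,
) -> WindowSet:
    """Compute selection/net-loss windows for two arbitrary dose-response callables.

    The range is scanned on a uniform grid (log-spaced beyond two decades),
    each point is classified, and every boundary between classes is refined
    by bisection on the relevant continuous function (``g_ref - g_mut`` for
    selection boundaries, ``max(g) - death_rate`` for net-loss boundaries)
    to a tolerance of ``1e-9`` times the range width.
    """
    lo, hi = conc_range
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError(f"invalid concentration range {conc_range}")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    grid = _scan_grid(lo, hi, resolution)
    tol = 1e-9 * (hi - lo)

    REF, MUT, LOSS = 0, 1, 2

    def classify(c: float) -> int:
        gr, gm = float(g_ref(c)), float(g_mut(c))
        if gr - death_rate < 0 and gm - death_rate < 0:
            return LOSS
        return REF if gr >= gm else MUT  # exact ties -> reference by convention

    labels = np.array([classify(c) for c in grid])
    boundaries: List[float] = []
    for a, b, la, lb in zip(grid[:-1], grid[1:], labels[:-1], labels[1:]):
        if la == lb:
            continue
        if LOSS in (la, lb):
            f = lambda c: max(float(g_ref(c)), float(g_mut(c))) - death_rate
        else:
            f = lambda c: float(g_ref(c)) - float(g_mut(c))
        boundaries.append(_bisect(f, float(a), float(b), tol))

    edges = [lo] + boundaries + [hi]
    out: Dict[int, List[Interval]] = {REF: [], MUT: [], LOSS: []}
    tie = False
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        mid = 0.5 * (a + b)
        lab = classify(mid)
        if lab == REF and abs(float(g_ref(mid)) - float(g_mut(mid))) == 0.0:
            tie = True
        if out[lab] and out[lab][-1][1] >= a - tol:  # merge touching intervals
            out[lab][-1] = (out[lab][-1][0], b)
        else:
            out[lab].append((a, b))
    return WindowSet(
        reference_windows=out[REF],
        mutant_windows=out[MUT],
        net_loss_windows=out[LOSS],
        death_rate=death_rate,
        conc_range=(lo, hi),
        tie_in_reference=tie,
    )


def compute_windows(
    seascape: FitnessSeascape,
    reference,
    mutant,
    death_rate: float,
    conc_range: Interval,
    resolution: int = 512,
    allow_any_pair: bool = False,
) -> WindowSet:
    """Selection/net-loss windows for a reference genotype vs a mutant neighbor."""
    ref = reference if isinstance(reference, Genotype) else Genotype(str(reference))
    mut = mutant if isinstance(mutant, Genotype) else Genotype(str(mutant))
    if not allow_any_pair and mut not in neighbors(ref):
        raise ValueError(
            f"{mut} is not a Hamming-1 neighbor of {ref}; pass allow_any_pair=True to override"
        )
    return windows_from_curves(
        seascape.curve(ref).rate, seascape.curve(mut).rate, death_rate, conc_range, resolution
    )


def enumerate_comparisons(n_sites: int, unique: bool = False):
    """All (reference, mutant-neighbor) MSW comparisons of an N-site seascape.

    Returns ``(count, pairs)``. Ordered comparisons number ``N * 2**N``;
    with ``unique=True`` mirror pairs are collapsed to ``N * 2**(N-1)``.
    The listing is deterministic: reference genotypes by index, neighbors in
    bit-flip order.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    pairs: List[Tuple[Genotype, Genotype]] = []
    for i in range(2**n_sites):
        ref = Genotype.from_index(i, n_sites)
        for mut in neighbors(ref):
            if unique and mut.index < ref.index:
                continue
            pairs.append((ref, mut))
    return len(pairs), pairs


@dataclass
class SelectionWindowMap:
    """Per-lattice-site selected genotype (or :data:`NET_LOSS`) labels."""

    labels: np.ndarray  # integer array; genotype index or NET_LOSS
    spacing: float = 1.0
    n_sites: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def shape(self):
        return self.labels.shape


def selection_map(
    seascape: FitnessSeascape,
    field,
    death_rate: float,
    net_loss_threshold: Optional[float] = None,
    spacing: float = 1.0,
) -> SelectionWindowMap:
    """Label every site of a drug field with its locally selected genotype.

    A site is :data:`NET_LOSS` when every genotype has ``g - death_rate < 0``
    — or, if ``net_loss_threshold`` is given (empirical mode), when the local
    concentration exceeds that threshold. Otherwise the site is labelled with
    the growth-rate argmax genotype; ties go to the lowest genotype index.
    """
    values = np.asarray(getattr(field, "values", field), dtype=float)
    if np.any(values < 0):
        raise ValueError("drug field values must be >= 0")
    rates = seascape.rate_table(values)  # (n_genotypes, *shape)
    labels = np.argmax(rates, axis=0)  # argmax takes the first (lowest index) on ties
    if net_loss_threshold is not None:
        loss = values > net_loss_threshold
    else:
        loss = np.all(rates - death_rate < 0, axis=0)
    labels = np.where(loss, NET_LOSS, labels)
    sp = getattr(field, "spacing", spacing)
    return SelectionWindowMap(labels=labels, spacing=sp, n_sites=seascape.n_sites)


def window_areas(swmap: SelectionWindowMap) -> Dict[int, int]:
    """Number of lattice sites carrying each label (incl. :data:`NET_LOSS`)."""
    labels, counts = np.unique(swmap.labels, return_counts=True)
    return {int(l): int(c) for l, c in zip(labels, counts)}


def predicted_counts(swmap: SelectionWindowMap) -> Dict[int, int]:
    """MSW-predicted steady-state cell count per genotype.

    The prediction for a genotype is simply the number of sites where it is
    the selected label; net-loss sites predict zero cells for every genotype.
    """
    n_sites = swmap.n_sites
    if n_sites is None:
        n_genotypes = int(swmap.labels.max()) + 1 if swmap.labels.size else 0
    else:
        n_genotypes = 2**n_sites
    areas = window_areas(swmap)
    return {g: areas.get(g, 0) for g in range(n_genotypes)}


def write_windows(windows: WindowSet, reference, mutant, path) -> None:
    """Serialize a :class:`WindowSet` to CSV (`reference,mutant,window_type,conc_lo,conc_hi`)."""
    rows = []
    for wtype, intervals in (
        ("reference", windows.reference_windows),
        ("mutant", windows.mutant_windows),
        ("net_loss", windows.net_loss_windows),
    ):
        for lo, hi in intervals:
            rows.append(
                {
                    "reference": str(reference),
                    "mutant": str(mutant),
                    "window_type": wtype,
                    "conc_lo": lo,
                    "conc_hi": hi,
                }
            )
    pd.DataFrame(rows, columns=["reference", "mutant", "window_type", "conc_lo", "conc_hi"]).to_csv(
        path, index=False
    )


def write_selection_map(swmap: SelectionWindowMap, grid_path, meta_path=None) -> None:
    """Write a label grid as row-major integer CSV plus a YAML metadata sidecar."""
    np.savetxt(grid_path, swmap.labels, fmt="%d", delimiter=",")
    if meta_path is not None:
        legend = {NET_LOSS: "net_loss"}
        if swmap.n_sites is not None:
            for i in range(2**swmap.n_sites):
                legend[i] = format(i, f"0{swmap.n_sites}b")
        meta = {
            "shape": list(swmap.labels.shape),
            "spacing": float(swmap.spacing),
            "n_sites": swmap.n_sites,
            "legend": {int(k): v for k, v in legend.items()},
        }
        with open(meta_path, "w") as fh:
            yaml.safe_dump(meta, fh)


def read_selection_map(grid_path, meta_path=None) -> SelectionWindowMap:
    labels = np.loadtxt(grid_path, dtype=int, delimiter=",", ndmin=2)
    spacing, n_sites = 1.0, None
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        spacing = float(meta.get("spacing", 1.0))
        n_sites = meta.get("n_sites")
    return SelectionWindowMap(labels=labels, spacing=spacing, n_sites=n_sites)
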