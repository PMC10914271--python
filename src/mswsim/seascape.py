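"""Genotype space, dose-response curves, and fitness seascapes.

A *fitness seascape* maps genotype **and** environment (drug concentration)
to fitness: it is a concentration-indexed family of fitness landscapes,
represented here as a combinatorially complete collection of genotype-specific
dose-response curves. Genotypes are binary strings of length ``N`` (one bit
per resistance-conferring mutation); the leftmost character is site 0.

Two curve models are supported:

* :class:`LogisticCurve` — ``g(c) = g_drugless / (1 + exp((ic50 - c) / nu))``.
  The shape parameter ``nu`` is sign-free; with ``nu < 0`` the curve decreases
  with concentration (the biologically oriented case emitted by the synthetic
  generator).
* :class:`HillCurve` — the four-parameter Hill form
  ``g(c) = g_max + (g_min - g_max) * c^nu / (ic50^nu + c^nu)`` with
  ``g(0) = g_max`` exactly and ``g(ic50) = (g_max + g_min) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "LogisticCurve",
    "HillCurve",
    "FitnessSeascape",
    "growth_rate",
    "rank_landscape",
    "neighbors",
    "generate_tradeoff_seascape",
    "read_seascape",
    "write_seascape",
]


@dataclass(frozen=True, order=True)
class Genotype:
    """A binary genotype of ``n_sites`` biallelic mutational sites.

    ``bits`` is an ordered binary string; the leftmost character is site 0,
    so ``index = int(bits, 2)`` reads the string as a binary number.
    """

    sort_index: int = field(init=False, repr=False, compare=True)
    bits: str = field(compare=True)

    def __post_init__(self) -> None:
        if not self.bits or any(ch not in "01" for ch in self.bits):
            raise ValueError(f"genotype bits must be a non-empty 0/1 string, got {self.bits!r}")
        object.__setattr__(self, "sort_index", int(self.bits, 2))

    @property
    def n_sites(self) -> int:
        return len(self.bits)

    @property
    def index(self) -> int:
        return self.sort_index

    @property
    def n_mutations(self) -> int:
        return self.bits.count("1")

    @classmethod
    def from_index(cls, index: int, n_sites: int) -> "Genotype":
        if not 0 <= index < 2**n_sites:
            raise ValueError(f"index {index} out of range for {n_sites} sites")
        return cls(format(index, f"0{n_sites}b"))

    def flip(self, site: int) -> "Genotype":
        """Return the genotype with the bit at ``site`` (0 = leftmost) flipped."""
        if not 0 <= site < self.n_sites:
            raise ValueError(f"site {site} out of range")
        b = list(self.bits)
        b[site] = "1" if b[site] == "0" else "0"
        return Genotype("".join(b))

    def __str__(self) -> str:
        return self.bits


def neighbors(genotype: Genotype) -> List[Genotype]:
    """All genotypes at Hamming distance 1, in bit-flip order (site 0..N-1)."""
    return [genotype.flip(i) for i in range(genotype.n_sites)]


@dataclass(frozen=True)
class LogisticCurve:
    """Logistic dose-response curve ``g_drugless / (1 + exp((ic50 - c)/nu))``.

    ``nu`` is sign-free; negative ``nu`` gives a curve that decreases with
    concentration.
    """

    g_drugless: float
    ic50: float
    nu: float

    def __post_init__(self) -> None:
        if self.g_drugless < 0:
            raise ValueError("g_drugless must be >= 0")
        if self.nu == 0:
            raise ValueError("nu must be non-zero")

    def rate(self, conc):
        conc = np.asarray(conc, dtype=float)
        # exp overflow is benign: g -> 0 (or g_drugless) in the saturated tail
        with np.errstate(over="ignore"):
            out = self.g_drugless / (1.0 + np.exp((self.ic50 - conc) / self.nu))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class HillCurve:
    """Four-parameter Hill dose-response curve.

    ``g(c) = g_max + (g_min - g_max) * c^nu / (ic50^nu + c^nu)``; exactly
    ``g_max`` at zero drug, saturating at ``g_min``, with the half-way point
    at ``ic50``.
    """

    g_max: float
    g_min: float
    ic50: float
    nu: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")
        if self.nu <= 0:
            raise ValueError("Hill coefficient nu must be > 0")

    def rate(self, conc):
        conc = np.asarray(conc, dtype=float)
        zero = conc <= 0.0
        c = np.where(zero, 1.0, conc)
        # (ic50/c)^nu form saturates cleanly to 0/1 at large nu instead of inf/inf
        with np.errstate(over="ignore"):
            frac = 1.0 / (1.0 + (self.ic50 / c) ** self.nu)
        out = self.g_max + (self.g_min - self.g_max) * frac
        out = np.where(zero, self.g_max, out)
        return out if out.ndim else float(out)


Curve = Union[LogisticCurve, HillCurve]


class FitnessSeascape:
    """Combinatorially complete map from genotype to dose-response curve.

    Parameters
    ----------
    curves
        Mapping from :class:`Genotype` (or bits string) to a curve; must
        contain all ``2**n_sites`` genotypes.
    concentration_unit
        Label for the drug concentration axis shared by all curves.
    """

    def __init__(self, curves: Dict, concentration_unit: str = "ug/mL"):
        norm: Dict[Genotype, Curve] = {}
        for k, v in curves.items():
            g = k if isinstance(k, Genotype) else Genotype(str(k))
            norm[g] = v
        if not norm:
            raise ValueError("empty seascape")
        n_sites = next(iter(norm)).n_sites
        if any(g.n_sites != n_sites for g in norm):
            raise ValueError("all genotypes must have the same number of sites")
        expected = {Genotype.from_index(i, n_sites) for i in range(2**n_sites)}
        missing = expected - set(norm)
        if missing:
            raise ValueError(
                f"seascape is not combinatorially complete; missing {sorted(str(g) for g in missing)}"
            )
        self.n_sites = n_sites
        self.curves = dict(sorted(norm.items(), key=lambda kv: kv[0].index))
        self.concentration_unit = concentration_unit

    @property
    def genotypes(self) -> List[Genotype]:
        return list(self.curves)

    def curve(self, genotype) -> Curve:
        g = genotype if isinstance(genotype, Genotype) else Genotype(str(genotype))
        try:
            return self.curves[g]
        except KeyError:
            raise KeyError(f"genotype {g} not in seascape") from None

    def growth_rate(self, genotype, conc):
        return growth_rate(self, genotype, conc)

    def rate_table(self, conc) -> np.ndarray:
        """Growth rate of every genotype (ordered by index) at ``conc``.

        ``conc`` may be a scalar or an array; the genotype axis is prepended.
        """
        return np.stack([self.curve(g).rate(np.asarray(conc, dtype=float)) for g in self.genotypes])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FitnessSeascape)
            and self.n_sites == other.n_sites
            and self.concentration_unit == other.concentration_unit
            and self.curves == other.curves
        )

    def __repr__(self) -> str:
        return f"FitnessSeascape(n_sites={self.n_sites}, unit={self.concentration_unit!r})"


def growth_rate(seascape: FitnessSeascape, genotype, conc):
    """Genotype-specific growth rate (per hour) at drug concentration ``conc``."""
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0):
        raise ValueError("concentration must be >= 0")
    return seascape.curve(genotype).rate(conc)


def rank_landscape(seascape: FitnessSeascape, conc: float) -> List[Genotype]:
    """Rank-order fitness landscape at a fixed concentration (fittest first).

    Ties are broken by ascending genotype index so the ordering is
    deterministic.
    """
    rates = {g: growth_rate(seascape, g, conc) for g in seascape.genotypes}
    return sorted(seascape.genotypes, key=lambda g: (-rates[g], g.index))


def generate_tradeoff_seascape(
    n_sites: int,
    rng_seed: int,
    g_drugless_range: Tuple[float, float] = (0.2, 0.3),
    ic50_range: Tuple[float, float] = (0.1, 100.0),
    nu_scale_range: Tuple[float, float] = (0.3, 0.8),
    concentration_unit: str = "ug/mL",
) -> FitnessSeascape:
    """Random two-or-more-allele seascape with resistance/growth tradeoffs.

    The *realized* drug-free growth rate ``g(0)`` strictly decreases with the
    number of mutations while IC50 strictly increases with it, so the wild
    type is fittest without drug and the fully mutated genotype is the most
    resistant. Curves are logistic with ``nu = -scale * ic50 < 0`` (decreasing
    in concentration); scaling the shape parameter to IC50 keeps the
    transition resolvable when IC50s span decades. Because the logistic form
    does not reach its plateau exactly at zero concentration, ``g_drugless``
    is back-solved so that ``g(0)`` equals the drawn target rate.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    for name, (lo, hi) in (
        ("g_drugless_range", g_drugless_range),
        ("ic50_range", ic50_range),
        ("nu_scale_range", nu_scale_range),
    ):
        if not (0 < lo < hi):
            raise ValueError(f"invalid {name}: {(lo, hi)}")
    rng = np.random.default_rng(rng_seed)
    n_genotypes = 2**n_sites
    genotypes = [Genotype.from_index(i, n_sites) for i in range(n_genotypes)]
    # order genotypes by mutation count (random tiebreak within a count class);
    # assigning sorted parameter draws in this order makes the tradeoff
    # orderings hold across mutation counts for every seed
    order = sorted(genotypes, key=lambda g: (g.n_mutations, rng.random()))
    g_draws = np.sort(rng.uniform(*g_drugless_range, size=n_genotypes))[::-1]
    log_lo, log_hi = np.log10(ic50_range[0]), np.log10(ic50_range[1])
    ic50_draws = np.sort(10.0 ** rng.uniform(log_lo, log_hi, size=n_genotypes))
    scales = rng.uniform(*nu_scale_range, size=n_genotypes)
    curves = {}
    for g, g0, ic, s in zip(order, g_draws, ic50_draws, scales):
        nu = -s * ic
        # g(0) = g_drugless / (1 + e^{ic50/nu}); solve for g_drugless so the
        # realized drug-free rate equals the drawn target
        g_dl = g0 * (1.0 + np.exp(ic / nu))
        curves[g] = LogisticCurve(g_drugless=float(g_dl), ic50=float(ic), nu=float(nu))
    return FitnessSeascape(curves, concentration_unit=concentration_unit)


_CSV_COLUMNS = ["genotype", "model", "g_drugless", "g_max", "g_min", "ic50", "nu", "unit"]


def write_seascape(seascape: FitnessSeascape, path) -> None:
    """Serialize a seascape to CSV (one row per genotype, header required)."""
    rows = []
    for g, c in seascape.curves.items():
        row = {"genotype": g.bits, "ic50": c.ic50, "nu": c.nu, "unit": seascape.concentration_unit}
        if isinstance(c, LogisticCurve):
            row.update(model="logistic", g_drugless=c.g_drugless, g_max="", g_min="")
        else:
            row.update(model="hill", g_drugless="", g_max=c.g_max, g_min=c.g_min)
        rows.append(row)
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_seascape(path) -> FitnessSeascape:
    """Read a seascape CSV written by :func:`write_seascape`.

    Rejects duplicate genotypes, unknown models, and combinatorially
    incomplete genotype sets.
    """
    df = pd.read_csv(path, dtype={"genotype": str}, float_precision="round_trip")
    missing_cols = {"genotype", "model", "ic50", "nu"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"seascape CSV missing columns: {sorted(missing_cols)}")
    if df["genotype"].duplicated().any():
        dups = df.loc[df["genotype"].duplicated(), "genotype"].tolist()
        raise ValueError(f"duplicate genotype rows: {dups}")
    curves: Dict[Genotype, Curve] = {}
    unit = "ug/mL"
    for _, row in df.iterrows():
        model = str(row["model"]).strip().lower()
        if model == "logistic":
            curve: Curve = LogisticCurve(
                g_drugless=float(row["g_drugless"]), ic50=float(row["ic50"]), nu=float(row["nu"])
            )
        elif model == "hill":
            curve = HillCurve(
                g_max=float(row["g_max"]),
                g_min=float(row["g_min"]),
                ic50=float(row["ic50"]),
                nu=float(row["nu"]),
            )
        else:
            raise ValueError(f"unknown dose-response model {row['model']!r}")
        curves[Genotype(str(row["genotype"]))] = curve
        if "unit" in df.columns and isinstance(row["unit"], str):
            unit = row["unit"]
    return FitnessSeascape(curves, concentration_unit=unit)
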