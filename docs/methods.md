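# Methods

This note records the models implemented in `mswsim`, the defaults chosen
where the design was genuinely open, the numerical choices, and what the
synthetic generators do and do not emulate. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Dose-response curves and seascapes

Genotypes are binary strings of length N; the leftmost character is site 0,
and a genotype's integer index reads the string as a binary number. Two curve
families are supported.

*Logistic*: `g(c) = g_drugless / (1 + exp((IC50 − c)/ν))`. The form is
evaluated verbatim with a sign-free shape parameter ν; with ν < 0 the curve
decreases with concentration, which is the biologically oriented case the
synthetic generator emits. Note `g(0)` is slightly below `g_drugless`
(exactly `g_drugless/(1+e^{IC50/ν})`); where the drug-free rate matters the
package works with the realized `g(0)`.

*Hill (four-parameter)*: `g(c) = g_max + (g_min − g_max)·c^ν/(IC50^ν + c^ν)`
with ν > 0; `g(0) = g_max` exactly and `g(IC50)` is the midpoint
`(g_max+g_min)/2`. Evaluation uses the `(IC50/c)^ν` form so large Hill
coefficients saturate cleanly instead of overflowing.

Concentrations are treated on a linear axis everywhere; log spacing is
purely a sampling/plotting concern. A seascape must be combinatorially
complete (all 2^N genotypes), and rank landscapes break fitness ties by
ascending genotype index so orderings are deterministic.

### Synthetic tradeoff seascapes

`generate_tradeoff_seascape` emulates the canonical resistance tradeoff: the
realized drug-free growth rate strictly decreases, and IC50 strictly
increases, with mutation count — the wild type is fittest without drug, the
fully mutated genotype is the most resistant. Defaults (chosen once,
documented here):

- drug-free growth 0.2–0.3 hr⁻¹. The synthetic experiments use a death rate
  of 0.1 hr⁻¹; every genotype must be viable (able to expand when selected)
  for the population to track its selection windows within the ~6-week
  simulations, which requires growth comfortably above death. Draws barely
  above the death rate produce resistant lineages that cannot escape founder
  drift, a regime the synthetic experiments are not meant to probe.
- IC50 log-uniform over 0.1–100 μg/mL, the two-decade window in which the
  example seascapes' dose-response transitions live.
- ν = −(0.3–0.8)·IC50: negative (decreasing curves), magnitude scaled to
  IC50 so that transitions occupy a similar width on a log axis whether the
  IC50 is 0.1 or 100.
- `g_drugless` is back-solved so the *realized* `g(0)` equals the drawn
  target; ordering the raw parameter instead can invert the drug-free
  ranking when IC50 ≈ |ν|.

The generator emulates tradeoff structure and reproducible randomness. It
does not emulate: epistasis beyond the monotone orderings, correlated noise
between genotypes, multi-drug response, or measurement error. A green test
against generated seascapes therefore establishes the machinery, not any
claim about a particular empirical system.

## Mutant selection windows

`compute_windows` scans the concentration range on a 512-point grid
(log-spaced when the range spans more than two decades), classifies each
point as reference / mutant / net-loss, and refines every class boundary by
bisection to 1e-9 of the range width — on `g_ref − g_mut` for selection
boundaries and `max(g) − death` for net-loss boundaries. Multiple crossings
are supported; exact ties are reported as reference selection and flagged.
The net-replication criterion uses the simulation death rate as the loss
term (`g − d < 0` for both genotypes); "empirical" mode instead marks any
site above a cytostatic concentration threshold as net loss.

`selection_map` applies the same rule per lattice site: net loss if every
genotype has negative net replication (or the threshold is exceeded),
otherwise the growth-rate argmax with ties to the lowest genotype index.
Window areas (site counts per label) double as the MSW prediction of
steady-state genotype abundances, with net-loss sites predicting zero.

## Drug diffusion

The pharmacokinetic model is linear reaction-diffusion,
`∂u/∂t = D∇²u − γu + source`, with closed-form point-source steady states in
1D (exponential) and 2D (modified Bessel K₀ kernel). The K₀ kernel diverges
at the origin, so concentrations inside a finite vessel radius (default 0.5
lattice units, half a cell diameter) are capped at the boundary value. The
transient solutions are kept as quadrature oracles (QUADPACK oscillatory
rules for the cosine/Hankel transforms) used to validate the closed forms
and the finite-difference solver; they are not used in simulations.

The numerical solver is forward-time centered-space with Dirichlet-zero
outer boundaries and vessel sites clamped to their supply concentration each
step. Stability: the default time step is `0.9/(4D/dx² + γ)`, the positivity
bound including the decay term; a user-supplied step is rejected when
`D·dt/dx² > 0.25`. Note the pure diffusion bound `D·dt/dx² = 0.25` is
*marginally unstable* once γ > 0 (the checkerboard mode's amplification is
−1 − γ·dt), which motivates the stricter default.

Multi-vessel steady states superpose the (linear) kernel per source —
mathematically identical to convolving the discretized kernel with the
source indicator map. The empirical perivascular model `u = k·2^(−d/L)` uses
the Euclidean distance to the *nearest* vessel by default, because it is an
empirical single-vessel fit rather than a solution of a linear PDE;
sum-superposition is available as an option.

Dimensional notes: the ratio √(γ/D) — an inverse length — is the natural
decay parameter; lattice spacing is nominally one cell diameter (~15 μm),
with L = 2 lattice units corresponding to ~20–40 μm penetration.

## Agent-based model

On a 100×100 lattice (one cell per site), each hourly step visits the cells
present at the step start in a fresh random order. Each cell: dies with
probability `death_rate·dt` (drug-independent); otherwise attempts division
with probability `g(genotype, local conc)·dt` clamped to [0,1], forced to
zero above the net-loss threshold in empirical mode; a division places the
daughter in a uniformly chosen empty Moore neighbor (configurable to von
Neumann), and the daughter mutates with probability N·μ to a uniformly
chosen Hamming-1 genotype (back-mutation allowed). Contact inhibition is
purely geometric: no empty neighbor, no division.

Design choices where the underlying description is silent: Moore
neighborhood (the common on-lattice default); asynchronous update in fresh
random order (avoids update-order artifacts); growth-rate→division
probability mapping `p = g·dt` with dt = 1 h (rates are per hour); death is
drug-independent, with drug acting only through division. The drug field is
either a fixed spatial profile gated by a treatment schedule (off = zero
everywhere) or co-integrated with the population via the explicit solver,
starting from zero drug by default (`PdeConfig(init="steady")` or an
explicit `u0` select the pre-equilibrated regime instead). With the shipped
diffusivity (0.1 lattice²/hr) the co-integrated field is still spreading at
the end of a 1000-h run; this transient regime is the one under which the
shipped synthetic experiments reproduce their reference behavior — a fully
pre-equilibrated field at low γ places the centrally seeded tumor entirely
in net loss and extinguishes it.

Determinism: a single integer seed derives (via `SeedSequence`) the
initialization RNG and the numba kernel RNG; identical seeds give bit-equal
trajectories.

The empirical (NSCLC/gefitinib) configuration uses the measured four-genotype
Hill seascape, death 0.025 hr⁻¹, mutation 10⁻³ per site per division, vessel
concentration 10 μg/mL, a 2016-h cyclic schedule, and a cytostatic net-loss
threshold of 1.8 μM gefitinib converted to 0.804 μg/mL (molar mass
446.9 g/mol). Initial conditions default to 10% occupancy of the full square
(0.1 is the log-midpoint of the plausible 0.01–1 occupancy range) and 10%
initial mutants (the therapy experiments are described with ~10%
pre-existing heterogeneity; the parameter table's 0.01 is available via
config).

## Altieri spatial entropy

For a categorical lattice map, consider unordered site pairs: Z is the
unordered pair of categories, W the distance class of the pair (defaults
[1,2), [2,5), [5,10), [10,20) lattice units; pairs beyond the last class are
ignored). The decomposition is exact:

    H(Z) = MI(Z,W) + H(Z|W)

with MI computed as the p(w)-weighted KL divergence of p(Z|w) from p(Z). All
entropies are in nats. When the number of within-range pairs exceeds
`max_pairs` (default 200 000), a seeded uniform subsample of site pairs is
used; on a 100×100 grid the residual subsampling error is well below the
effect sizes analyzed. Population maps are scored over occupied sites only
(empty sites carry no category); selection-window maps are scored over all
sites with net loss as a category. The scalar used as "the" spatial entropy
in regressions is the total pair entropy H(Z); the full decomposition is
always reported.

The normalized entropy difference `Δ = (e_MSW − e_pop)²/e_MSW` quantifies
how far the population departs from the MSW prediction; it is undefined for
a zero-entropy window map.

## Fitting

Growth rates are ordinary least-squares slopes of ln(count) vs time; zero
counts are dropped with a warning (no pseudocounts), and at least three
positive counts are required. Hill fits run bounded nonlinear least squares
in (g_max, g_min, log IC50, log ν) from a multi-start grid (5 log-spaced
IC50 initials × ν ∈ {0.5, 2, 8, 32}); ν is bounded to [0.1, 50] (empirical
seascapes contain ν ≈ 17) and IC50 to the sampled concentration range scaled
by [0.1, 10]. Flat responses and out-of-range IC50s are flagged as
unidentifiable/extrapolated. Parameter recovery depends on the sampling
design: concentrations must bracket the transition; with points spanning
IC50/4–4·IC50 recovery from noiseless rates is exact to machine precision.

## Experiments and their scaling

- **γ-sweep**: 5 elimination rates {1e-4, 1e-3, 1e-2, 1e-1, 0.5} × N
  replicates, 1000 hourly steps, two vessels at (50,25)/(50,75), circle
  radius 10 at full density, mutation 1e-4, death 0.1. Outputs per-run
  entropies and per-genotype window areas vs final counts, with summary R²
  values. Default 5 replicates in tests/acceptance (10 in the shipped
  config) to stay within CI budgets; the R² statistics are insensitive to
  this choice compared to the seascape draw (see limitations).
- **Sensitivity grid**: varies one of mutation rate, initial mutant
  probability, vessel separation (vessels at y = 50 ± sep/2) per condition
  and reports the mean normalized entropy difference.
- **Therapy**: static exponential-penetration fields for each L, cyclic
  schedule (4 × [168 h on + 168 h off] + 672 h off = 2016 h), empirical
  parameters above. Reports total and resistant cells over time and final
  resistant fractions.

Every experiment CSV row carries the seed, a config hash and the package
version; identical (config, seed) reruns are bit-identical.

## Known limitations

- The synthetic seascape is random by design; the strength of the
  entropy-entropy association across γ depends on the draw. Draws whose
  IC50s cluster at the low end of the axis yield thin selection windows and
  weakly heterogeneous populations, lowering the R² well below the typical
  ~0.9. The acceptance script reports whatever the seeded draw produces.
- No cell migration, no 3-D geometry, no resource competition beyond lattice
  exclusion, no time-varying systemic pharmacokinetics, and drug consumption
  is spatially uniform (constant γ).
- The co-integrated drug field uses one explicit update per hour; the
  effective transient regime therefore depends on the diffusivity and run
  length, as discussed above.
- The mapping `p = g·dt` treats growth rates as division probabilities per
  hour; it is accurate for g·dt ≪ 1 (all shipped parameter sets) but
  saturates for hypothetical rates above 1/dt.
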