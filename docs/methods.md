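# Methods

This note documents the models, numerical choices and limitations behind each
indolekit module, and what the synthetic-data generators do and do not
emulate.

## Stoichiometric accounting

All molar accounting rests on two constants: MW(Trp) = 204.23 g mol⁻¹ and
MW(indole) = 117.15 g mol⁻¹. Because tryptophanase is strictly 1:1 on a molar
basis, mol-% conversion is `100·(c_indole/117.15)/(c_Trp,supplied/204.23)`,
with the **total Trp supplied up to the sampling time** as the basis — split
feeds are summed, so 0.94 g/L indole against 2+2 g/L doses is 41 mol-%.

Reported values are presentation-rounded half away from zero (mol-% to
integers, titers to one decimal, space-time yields to two decimals); raw
values are always returned by the library functions and never overwritten by
the rounding layer. Two published table entries are known to disagree with
this arithmetic by one unit (0.37 g/L per 1 g/L computes to 65, printed 66;
0.19 g/L per 1 g/L computes to 33, printed 34). The package computes the
arithmetic value and does not special-case either entry.

Two-phase ISPR bookkeeping treats "20% (v/v)" overlays as organic volume =
0.2 × medium volume, so a product that partitions essentially completely into
the overlay is 5-fold concentrated there; `normalize_overlay` divides the
total solute mass by the medium volume. Extraction capacity is the organic
phase's share of total mass. Both are invariant under joint scaling of the
two volumes. Off-gas losses integrate a constant µg h⁻¹ stripping rate over
the culture volume; at the rates measured for indole (a few µg h⁻¹ in 0.75 L)
this is < 0.1% of a 0.2 g/L titer and included only for closure accounting.

Mass-balance closure compares supplied Trp (mol) with residual Trp + indole
present + integrated off-gas, flagging an unexplained gap above 5%.

## Coupled-assay model and Michaelis–Menten fitting

The readout couples TNA to an excess of NADH-dependent lactate dehydrogenase:
each Trp turned over consumes exactly one NADH, followed at 340 nm. The
simulator and the rate extractor both assume **quasi-steady coupling** — the
indicator reaction is treated as instantaneous, so the NADH oxidation rate
equals the TNA rate. No LDH kinetics, substrate depletion curvature, product
inhibition or PLP/K⁺ dependence is modelled: a noise-free trace is linear at
`v(S₀) = k_cat·[E]·S₀/(K_M+S₀)` from A₀ = ε·l·[NADH]₀ until min([NADH]₀, S₀)
is consumed, then flat. ε defaults to 6.22 AU mM⁻¹ cm⁻¹ and l to 1 cm
(standard values for NADH at 340 nm).

`trace_to_rate` fits a least-squares line over a window; the default window is
the first 10% of the trace, and `linear_window` widens it to the full
pre-exhaustion linear region, which is the unbiased choice under this trace
model and is what the recovery studies use. Rates are floored at zero (the
assay consumes NADH) and a fit with R² < 0.2 carries a warning flag.

`fit_mm` runs bounded nonlinear least squares on `v = v_max·S/(K_M+S)`,
initialized at v_max⁰ = max observed rate and K_M⁰ = the substrate at
half-max by linear interpolation; standard errors come from the
Jacobian-based covariance. k_cat = v_max/(60·[E]) with [E] in mM. Designs
with fewer than four distinct substrate levels are rejected as
unidentifiable. Catalytic efficiency k_cat/K_M carries either a
per-replicate-ratio SD (when replicate fits are supplied) or first-order
propagation; neither is claimed to reproduce published ± values, whose method
is not documented.

The default substrate design is a two-fold series from 6.25 µM topped off at
10 mM (12 levels). "5% noise" in the recovery studies means Gaussian
absorbance noise with sd = 5% of each trace's noise-free dynamic range; the
reference truth (K_M 0.14 mM, k_cat 1.65 s⁻¹) is then recovered with ~1%
median K_M error over ten seeds of triplicate series, comfortably inside the
15% target.

## Constraint-based modelling

Models are stored as plain JSON (metabolites with formulas, reactions with
stoichiometry/bounds/GPR strings, one objective); the community COBRA JSON
dialect is also read. FBA solves the LP with scipy's HiGHS backend;
infeasible and unbounded outcomes raise distinct errors, and degenerate
optima return whichever optimal vertex the solver reports (no lexicographic
tie-breaking is guaranteed).

GPR rules are parsed by a small recursive-descent parser (identifiers,
`and`/`or`, parentheses; case-insensitive operators) and evaluated against a
deletion set: AND requires all operands, OR any, the empty rule means no gene
dependence. `reduce_model` removes reactions whose rule evaluates inactive,
warns on genes absent from the model, refuses to remove the objective, and is
idempotent.

The grafted tryptophanase reaction `trp_c + h2o_c → indole_c + pyr_c + nh4_c`
is element-balanced (C11H12N2O2 + H2O → C8H7N + C3H4O3 + NH3) and
irreversible; missing metabolites are created with their formulas and
reported. Medium setup gives free components (salts, O₂, water, ammonium) a
lower bound of −1000, the carbon source and Trp −10 mmol gDW⁻¹ h⁻¹, and
closes all other uptakes unless whitelisted.

**ACHR sampling.** Warm-up points are the 2·n flux-variability extreme points
(per-reaction maxima/minima). Each iteration draws a direction from a random
warm-up point minus the running center, computes the feasible chord from the
box bounds, and steps uniformly along it; the center is the running mean of
visited points. Defaults: burn-in 1000 iterations, thinning 10, bounds capped
at ±1000 so the polytope is bounded. Numerical drift off `S·v = 0` is damped
by periodic re-projection onto the null space; every retained sample
satisfies `‖S·v‖∞ < 10⁻⁶` and the bounds to 10⁻⁶. A zero-volume polytope
returns the single feasible point repeated, with a warning.

**Producer decomposition.** A reaction contributes to a metabolite's
production when `coefficient × flux > 0`, i.e. reversible reactions count by
their realized direction (gross accounting; a net option averages signed
contributions instead). For sample sets, per-sample positive contributions
are averaged before normalizing. Fractions sum to one whenever total
production is positive; zero production is an explicit error, not a NaN.

The bundled toy models are deliberately small: a 4-reaction linear chain and
a 5-reaction two-path model whose FBA optima are verified against brute-force
vertex enumeration, a 2-reaction model whose polytope is a segment (sampler
calibration: the free flux on [0, 10] must average 5), and a ~15-reaction
core model with PTS glucose uptake (pyruvate co-producing), non-PTS gluconate
uptake, pyruvate kinase, a malate-shunt alternative producer, and a biomass
sink — enough structure for reduction, grafting, medium, sampling and
decomposition tests. The genome-scale model of the production organism is not
bundled; pipelines against it run through the same functions via the COBRA
JSON reader.

## Sequence bioprospecting

Global alignment is Needleman–Wunsch with configurable linear-gap scoring
(default match +1, mismatch −1, gap −1) and a fixed traceback preference
(diagonal, then gap-in-second, then gap-in-first) so results are
reproducible. Scores are verified against an exhaustive all-alignments
oracle for short sequences. Percent identity uses identical columns over
**all** alignment columns, gaps included — one of several conventions in use,
stated here explicitly. Exact reproduction of any particular external
aligner's identity values is a non-goal.

Hierarchical clustering on `1 − identity` is an explicit agglomerative loop
(complete linkage by default; single and average available) with ties broken
by the smallest pair of cluster indices — the reason it is hand-written
rather than delegated is that this tie-break is part of the contract; merge
heights are cross-checked against scipy's implementation in the tests. Trees
cut by count k (replay n−k merges) or by height, with flat labels numbered by
first member in input order.

Species deduplication keeps the longest sequence per species, ties broken by
lexicographically smaller id. Theoretical protein mass uses average residue
masses (from Biopython's tables) plus one water; `X` counts as the mean
residue. Candidate filters apply length bounds, a mass window and annotation
flags in that order, recording the first violated rule. Representative
selection is greedy: per cluster, the admissible record maximizing mean
distance to the already-selected set (ties by id).

## Synthetic families: what they are and are not

Family generation plants one independent uniform-random seed sequence per
family (length ~ N(471, 34) by default, matching a tryptophanase mining set)
and derives members by substitution-only point mutations at uniformly chosen
positions, hitting the requested member-to-seed identity exactly; an optional
indel rate is off by default. Member-to-member identity is consequently
about `1 − 2(1 − w)` for within-identity `w`. Separation between families is
statistical: independent random 20-letter sequences align at far below any
sensible between-family cap, the spec validates `within > between_max`, and a
cheap position-wise check guards seed draws. This is **not** phylogenetically
realistic evolution — no substitution matrices, rate heterogeneity, domain
structure or alignment-aware indels — so recovery tests demonstrate the
pipeline's correctness on well-separated families, not its performance on
real databases, where cluster boundaries are softer and cluster counts are a
judgment call.

The fermentation simulator uses explicit forward steps (default 0.1 h):
first-order Trp consumption, 1:1 molar indole formation, an optional constant
late-stage indole loss after a configurable onset (emulating the post-peak
decline seen in vivo), and constant off-gas stripping. It keeps exact
cumulative loss books, so closure tests have machine-precision ground truth.
It does not model growth, uptake saturation, product toxicity feedback or pH.

Noise magnitudes everywhere are free parameters (no published values exist
for these measurements); defaults are zero, with the magnitudes used by the
recovery studies stated alongside them.

## Problem sizes and determinism

Recovery and sampling studies run at deliberately modest sizes chosen for
tight, fast tests: planted-family recovery uses 3–4 families × 5–6 members at
seed length 40–60 (the recovery property is scale-free; all-vs-all alignment
cost grows as n²L²), ACHR calibration uses 10,000 samples as in the study
design, and Michaelis–Menten recovery uses the full 12-level substrate design
in triplicate over ten seeds. Every stochastic routine takes an explicit
seed and is bit-reproducible given it; different seeds change only noise
realizations, never deterministic structure.
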