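# indolekit

Computational companion toolkit for engineering whole-cell **l-tryptophan →
indole** bioconversion in *Corynebacterium glutamicum*. Bacterial
tryptophanases (TNA, EC 4.1.99.1) cleave Trp in a β-elimination:

    Trp + H2O  →  indole + pyruvate + NH3          (1:1:1:1 molar)

indolekit implements the four computational workflows such a metabolic
engineering campaign runs, plus seeded generators for every input they need:

1. **Bioprospecting** (`indolekit.bioprospecting`) — deduplicate candidate
   enzyme sequences per species, compute an all-vs-all percent-identity matrix
   by Needleman–Wunsch global alignment, cluster hierarchically on the
   distance `1 − identity`, cut the tree into *k* families, filter on length /
   theoretical mass / host annotations, and pick one diverse representative
   per cluster.
2. **Constraint-based flux analysis** (`indolekit.flux_analysis`) — reduce a
   genome-scale model to a gene-deleted chassis via its GPR boolean rules,
   graft in the TNA reaction and an indole exchange, configure the medium
   through exchange bounds (salts/O₂ at −1000, carbon source and Trp at −10
   mmol gDW⁻¹ h⁻¹), solve FBA (`max cᵀv` s.t. `S·v = 0`, `lb ≤ v ≤ ub`),
   sample the flux polytope with artificial-centering hit-and-run (ACHR,
   default 10,000 points), and decompose which reactions produce a metabolite
   such as pyruvate and in what shares.
3. **Enzyme kinetics** (`indolekit.kinetics`) — extract initial rates from
   coupled TNA–LDH/NADH assay traces (`v = −(dA₃₄₀/dt)/(ε·l)`), fit
   `v = v_max·S/(K_M + S)` by nonlinear least squares, and derive `k_cat`,
   `k_cat/K_M` and specific activity (1 U = 1 µmol min⁻¹).
4. **Bioconversion accounting** (`indolekit.bioconversion`) — mol-%
   conversion `100·(indole/117.15)/(Trp/204.23)`, theoretical titers,
   space-time yield, two-phase in-situ-product-recovery (ISPR) normalization
   and extraction capacity, and molar mass-balance closure including off-gas
   losses.

`indolekit.synthetic_data` generates sequence families with planted cluster
structure, assay traces, fermentation time courses, two-phase equilibria, and
a set of toy metabolic models (PTS/non-PTS carbon uptake, several
pyruvate-forming reactions) — all deterministic given a seed.

## Worked example

Simulate a coupled-assay substrate series at a known enzyme (K_M 0.14 mM,
k_cat 1.65 s⁻¹, design 6.25 µM – 10 mM Trp), re-estimate the parameters, and
report process numbers:

```python
from indolekit import bioconversion as bc, kinetics as kn, synthetic_data as sd

spec = sd.AssaySimSpec()          # truth: K_M 0.14 mM, k_cat 1.65 1/s
rates = [
    (tr.substrate_mm,
     kn.trace_to_rate(tr, window=kn.linear_window(tr)).initial_rate_mm_per_min)
    for tr in sd.simulate_assay_series(spec)
]
fit = kn.fit_mm(rates, spec.enzyme_molar_mm)
print(f"K_M  = {fit.km_mm:.3f} mM")
print(f"k_cat = {fit.kcat_per_s:.3f} 1/s")
print(f"k_cat/K_M = {kn.efficiency(fit).rounded} 1/(mM s)")

print("conversion:", bc.mol_conversion_rounded(0.51, 1.0), "mol-%")
print("max titer from 10 g/L Trp:", bc.theoretical_titer_rounded(10.0), "g/L")

overlay = bc.TwoPhaseState(v_aq=1.0, v_org=0.2, c_aq=0.0, c_org=28.0)
print("medium-normalized ISPR titer:", round(bc.normalize_overlay(overlay), 1), "g/L")
```

prints

```
K_M  = 0.140 mM
k_cat = 1.650 1/s
k_cat/K_M = 11.8 1/(mM s)
conversion: 89 mol-%
max titer from 10 g/L Trp: 5.7 g/L
medium-normalized ISPR titer: 5.6 g/L
```

The fit recovers the generating constants exactly on noise-free traces; the
efficiency 11.8 mM⁻¹ s⁻¹ is the quotient of the fitted constants. A titer of
0.51 g/L indole from 1 g/L Trp is an 89 mol-% conversion; complete conversion
of 10 g/L Trp tops out at 5.7 g/L indole; and 28 g/L indole in a 20% (v/v)
solvent overlay corresponds to 5.6 g/L on the medium volume.

A thin CLI mirrors the library (`indolekit synth|prospect|flux|kinetics|convert
--help`), reading and writing FASTA, CSV and JSON.

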