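"""Seeded generators for every input the pipeline consumes.

Four simulators and a set of toy metabolic models:

* protein sequence families with planted cluster structure, for testing the
  bioprospecting pipeline's ability to recover known family labels;
* coupled tryptophanase–LDH assay traces (absorbance at 340 nm vs time), for
  testing Michaelis–Menten parameter recovery;
* fed-batch biotransformation time courses with exact molar bookkeeping, for
  testing conversion and mass-balance accounting;
* two-phase (aqueous/organic) equilibria for in situ product recovery.

All randomness flows through one ``numpy`` generator per call, seeded from the
spec, so outputs are bit-reproducible.  Deterministic structure (lengths at a
given seed, dose schedules, equilibrium formulas) is unaffected by the noise
realization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bioconversion import MW_INDOLE, MW_TRP, CultureSample, TwoPhaseState
from .bioprospecting import AA_ALPHABET, SequenceRecord
from .flux_analysis import MetabolicModel, Metabolite, Reaction
from .kinetics import EPSILON_NADH, PATH_LENGTH_CM, KineticTrace


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilySpec:
    """Planted-structure protein family generator settings.

    Each family grows from an independent uniform-random seed sequence whose
    length is drawn from N(seed_length_mean, seed_length_sd); members are
    substitution-only point-mutated copies hitting ``within_family_identity``
    relative to the seed.  Defaults emulate a bacterial tryptophanase mining
    set: ~400 sequences in 14 families, mean length 471 +- 34 aa.
    """

    n_families: int = 14
    members_per_family: int | tuple[int, int] = (20, 40)
    seed_length_mean: float = 471.0
    seed_length_sd: float = 34.0
    within_family_identity: float = 0.9
    between_family_identity_max: float = 0.5
    indel_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0 < self.within_family_identity <= 1:
            raise ValueError("within_family_identity must be in (0, 1]")
        if self.within_family_identity <= self.between_family_identity_max:
            raise ValueError(
                "separation infeasible: within_family_identity must exceed "
                "between_family_identity_max")
        if self.seed_length_mean < 1:
            raise ValueError("seed_length_mean must be >= 1")


def _draw_members(spec: FamilySpec, rng: np.random.Generator) -> int:
    m = spec.members_per_family
    if isinstance(m, int):
        return m
    lo, hi = m
    return int(rng.integers(lo, hi + 1))


def _positionwise_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x == y) / max(len(a), len(b))


def generate_sequence_families(spec: FamilySpec
                               ) -> tuple[list[SequenceRecord], list[int]]:
    """Generate records with planted family structure and their truth labels.

    Seed sequences are redrawn (up to 50 attempts) if a cheap position-wise
    identity check finds two seeds above ``between_family_identity_max``;
    independent random sequences over 20 letters sit near 5% so this
    essentially never triggers for sane settings.
    """
    rng = np.random.default_rng(spec.rng_seed)
    letters = np.array(list(AA_ALPHABET))

    seeds: list[str] = []
    for _ in range(spec.n_families):
        for attempt in range(50):
            length = max(1, int(round(rng.normal(spec.seed_length_mean,
                                                 spec.seed_length_sd))))
            cand = "".join(rng.choice(letters, size=length))
            if all(_positionwise_identity(cand, s) <= spec.between_family_identity_max
                   for s in seeds):
                seeds.append(cand)
                break
        else:
            raise RuntimeError(
                "could not draw sufficiently separated family seeds for "
                f"between_family_identity_max={spec.between_family_identity_max}")

    records: list[SequenceRecord] = []
    labels: list[int] = []
    counter = 0
    for fam, seed in enumerate(seeds):
        n_members = _draw_members(spec, rng)
        length = len(seed)
        n_mut = int(round((1.0 - spec.within_family_identity) * length))
        for _ in range(n_members):
            seq = list(seed)
            if n_mut > 0:
                pos = rng.choice(length, size=n_mut, replace=False)
                for p in pos:
                    choices = [c for c in AA_ALPHABET if c != seq[p]]
                    seq[p] = choices[int(rng.integers(len(choices)))]
            if spec.indel_rate > 0:
                kept = [c for c in seq if rng.random() > spec.indel_rate]
                seq = kept if kept else seq
            counter += 1
            records.append(SequenceRecord(
                id=f"syn{counter:05d}",
                species=f"Synthbacter fam{fam}_sp{counter}",
                sequence="".join(seq),
                annotations={"family": fam, "pfam_pf01212_present": True,
                             "pathogenic_host": False,
                             "rng_seed": spec.rng_seed}))
            labels.append(fam)
    return records, labels


# ---------------------------------------------------------------------------
# coupled-assay traces
# ---------------------------------------------------------------------------

def _default_substrate_levels() -> tuple[float, ...]:
    # two-fold series from 6.25 uM, topped off at 10 mM
    levels = [6.25e-3 * 2 ** k for k in range(11)]
    return tuple(levels + [10.0])


@dataclass(frozen=True)
class AssaySimSpec:
    """Ground truth and instrument settings for the coupled TNA-LDH assay.

    The simulator assumes quasi-steady coupling: NADH is oxidized at exactly
    the tryptophanase rate for the trace's initial substrate concentration,
    v = kcat*[E]*S0/(KM+S0), until min(NADH0, S0) is consumed — one NADH per
    Trp turned over — after which the absorbance is flat.
    """

    km_true_mm: float = 0.14
    kcat_true_per_s: float = 1.65
    enzyme_molar_mm: float = 1e-4
    enzyme_mg_per_ml: float = 5e-3  # ~50 kDa subunit at 1e-4 mM
    substrate_levels_mm: tuple[float, ...] = field(
        default_factory=_default_substrate_levels)
    nadh0_mm: float = 0.2
    epsilon_nadh: float = EPSILON_NADH
    path_length_cm: float = PATH_LENGTH_CM
    noise_sd_au: float = 0.0
    #: extra noise as a fraction of each trace's noise-free dynamic range;
    #: "5% noise" = 0.05 here (the absolute and relative sds add)
    noise_relative_frac: float = 0.0
    duration_s: float = 120.0
    sampling_interval_s: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("km_true_mm", "kcat_true_per_s", "enzyme_molar_mm",
                     "nadh0_mm", "epsilon_nadh", "path_length_cm",
                     "duration_s", "sampling_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_au < 0 or self.noise_relative_frac < 0:
            raise ValueError("noise settings must be >= 0")
        lv = self.substrate_levels_mm
        if any(s <= 0 for s in lv) or any(a >= b for a, b in zip(lv, lv[1:])):
            raise ValueError("substrate_levels_mm must be positive and ascending")

    @property
    def vmax_mm_per_min(self) -> float:
        return self.kcat_true_per_s * self.enzyme_molar_mm * 60.0


def simulate_assay_trace(spec: AssaySimSpec, substrate_mm: float,
                         rng: Optional[np.random.Generator] = None) -> KineticTrace:
    """One absorbance-vs-time trace at the given substrate concentration.

    Noise-free absorbance falls linearly from epsilon*l*NADH0 at slope
    -epsilon*l*v(S0) until the coupled readout is exhausted.  Gaussian noise
    of sd ``noise_sd_au`` is added per sample.  If exhaustion precedes the
    first post-zero sample the trace is flagged via ``exhausted_at_s``.
    """
    if substrate_mm <= 0:
        raise ValueError("substrate_mm must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    v = (spec.vmax_mm_per_min * substrate_mm
         / (spec.km_true_mm + substrate_mm)) / 60.0  # mM/s
    el = spec.epsilon_nadh * spec.path_length_cm
    budget_mm = min(spec.nadh0_mm, substrate_mm)  # one NADH per Trp
    t_exhaust = budget_mm / v if v > 0 else math.inf

    t = np.arange(0.0, spec.duration_s + 1e-9, spec.sampling_interval_s)
    nadh = spec.nadh0_mm - v * np.minimum(t, t_exhaust)
    a = el * nadh
    sd = spec.noise_sd_au + spec.noise_relative_frac * float(a.max() - a.min())
    if sd > 0:
        a = a + rng.normal(0.0, sd, size=a.shape)
    exhausted = float(t_exhaust) if t_exhaust <= spec.duration_s else None
    if exhausted is not None and exhausted < spec.sampling_interval_s:
        exhausted = 0.0  # NADH gone before the first sample: unusable trace
    return KineticTrace(
        time_s=t, absorbance=a, substrate_mm=substrate_mm,
        conditions={"epsilon_nadh": spec.epsilon_nadh,
                    "path_length_cm": spec.path_length_cm,
                    "enzyme_molar_mm": spec.enzyme_molar_mm,
                    "enzyme_mg_per_ml": spec.enzyme_mg_per_ml,
                    "nadh0_mm": spec.nadh0_mm,
                    "rng_seed": spec.rng_seed},
        exhausted_at_s=exhausted)


def simulate_assay_series(spec: AssaySimSpec) -> list[KineticTrace]:
    """Traces over the full substrate design, one shared seeded generator."""
    rng = np.random.default_rng(spec.rng_seed)
    return [simulate_assay_trace(spec, s, rng=rng)
            for s in spec.substrate_levels_mm]


# ---------------------------------------------------------------------------
# fermentation time courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FermentationSpec:
    """Discrete-time whole-cell biotransformation simulator settings.

    Trp is consumed first-order at ``conversion_rate_per_h``; each gram of Trp
    consumed yields MW_indole/MW_trp grams of indole (1:1 molar).  After
    ``loss_onset_h`` an optional constant ``late_loss_rate`` removes indole
    (emulating late-stage product disappearance) and a constant off-gas rate
    strips a little more.  Every step keeps exact molar books, so the
    simulation's mass balance closes to numerical precision.
    """

    trp_doses: tuple[tuple[float, float], ...] = ((0.0, 1.0),)  # (time h, g/L)
    conversion_rate_per_h: float = 0.3
    late_loss_rate_g_per_l_h: float = 0.0
    loss_onset_h: float = 24.0
    offgas_loss_rate_ug_per_h: float = 0.0
    working_volume_l: float = 0.75
    sample_times_h: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)
    noise_sd_g_per_l: float = 0.0
    dt_h: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 0 or t < 0 for t, g in self.trp_doses):
            raise ValueError("doses must be non-negative with non-negative times")
        if self.conversion_rate_per_h < 0 or self.late_loss_rate_g_per_l_h < 0:
            raise ValueError("rates must be non-negative")
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if self.noise_sd_g_per_l < 0:
            raise ValueError("noise_sd_g_per_l must be >= 0")
        times = self.sample_times_h
        if any(a >= b for a, b in zip(times, times[1:])):
            raise ValueError("sample_times_h must be strictly increasing")


@dataclass
class FermentationResult:
    samples: list[CultureSample]
    #: exact (noise-free) cumulative indole losses in g/L at the final sample
    losses_g_per_l: float
    #: exact supplied Trp in g/L up to the final sample
    supplied_g_per_l: float
    rng_seed: int = 0


def simulate_fermentation(spec: FermentationSpec) -> FermentationResult:
    """Explicit forward simulation on a fixed grid, sampled at sample_times_h.

    Molar conservation holds at every step: Trp consumed (mol) equals indole
    present plus cumulative losses (mol), within floating-point tolerance.
    """
    rng = np.random.default_rng(spec.rng_seed)
    t_end = spec.sample_times_h[-1]
    n_steps = int(round(t_end / spec.dt_h))
    doses = sorted(spec.trp_doses)

    trp = 0.0
    indole = 0.0
    losses = 0.0
    dosed = 0.0
    results: dict[float, tuple[float, float]] = {}
    sample_iter = iter(spec.sample_times_h)
    next_sample = next(sample_iter, None)

    def record(time_h: float) -> None:
        results[time_h] = (trp, indole)

    for step in range(n_steps + 1):
        t = step * spec.dt_h
        for dt_, dg in doses:
            if t - spec.dt_h < dt_ <= t or (step == 0 and dt_ == 0.0):
                trp += dg
                dosed += dg
        while next_sample is not None and next_sample <= t + 1e-9:
            record(next_sample)
            next_sample = next(sample_iter, None)
        if step == n_steps:
            break
        consumed = trp * (1.0 - math.exp(-spec.conversion_rate_per_h * spec.dt_h))
        trp -= consumed
        indole += consumed * MW_INDOLE / MW_TRP
        if t + spec.dt_h > spec.loss_onset_h and spec.late_loss_rate_g_per_l_h > 0:
            loss = min(indole, spec.late_loss_rate_g_per_l_h * spec.dt_h)
            indole -= loss
            losses += loss
        if spec.offgas_loss_rate_ug_per_h > 0:
            loss = min(indole, spec.offgas_loss_rate_ug_per_h * 1e-6 * spec.dt_h
                       / spec.working_volume_l)
            indole -= loss
            losses += loss

    samples = []
    for t in spec.sample_times_h:
        trp_t, ind_t = results[t]
        if spec.noise_sd_g_per_l > 0:
            trp_t = max(0.0, trp_t + rng.normal(0, spec.noise_sd_g_per_l))
            ind_t = max(0.0, ind_t + rng.normal(0, spec.noise_sd_g_per_l))
        samples.append(CultureSample(time_h=t, trp_g_per_l=trp_t,
                                     indole_g_per_l=ind_t))
    return FermentationResult(samples=samples, losses_g_per_l=losses,
                              supplied_g_per_l=dosed, rng_seed=spec.rng_seed)


# ---------------------------------------------------------------------------
# two-phase equilibrium
# ---------------------------------------------------------------------------

def simulate_two_phase(c_total_g_per_l: float, v_aq_l: float, v_org_l: float,
                       partition_coefficient: float,
                       solvent: str = "") -> TwoPhaseState:
    """Equilibrium split of a solute between aqueous and organic phases.

    ``c_total_g_per_l`` is the overall concentration on the combined volume.
    Equilibrium satisfies c_org = K * c_aq and mass conservation, giving
    c_aq = M / (v_aq + K*v_org) with M the total mass.
    """
    if v_aq_l <= 0 or v_org_l <= 0:
        raise ValueError("phase volumes must be positive")
    if partition_coefficient < 0:
        raise ValueError("partition_coefficient must be >= 0")
    if c_total_g_per_l < 0:
        raise ValueError("c_total_g_per_l must be >= 0")
    mass = c_total_g_per_l * (v_aq_l + v_org_l)
    c_aq = mass / (v_aq_l + partition_coefficient * v_org_l)
    c_org = partition_coefficient * c_aq
    return TwoPhaseState(v_aq=v_aq_l, v_org=v_org_l, c_aq=c_aq, c_org=c_org,
                         solvent=solvent)


def partition_coefficient_for_capacity(extraction_pct: float, v_aq_l: float,
                                       v_org_l: float) -> float:
    """Invert the equilibrium: the K giving a target extraction capacity.

    extraction = 100*K*v_org/(v_aq + K*v_org)  =>  K = e*v_aq/((100-e)*v_org).
    """
    if not 0 <= extraction_pct < 100:
        raise ValueError("extraction_pct must be in [0, 100)")
    return extraction_pct * v_aq_l / ((100.0 - extraction_pct) * v_org_l)


# ---------------------------------------------------------------------------
# toy metabolic models
# ---------------------------------------------------------------------------

def toy_linear_chain() -> MetabolicModel:
    """A -> B -> C chain with uptake capped at 10; export objective optimum 10."""
    mets = {m: Metabolite(id=m) for m in ("A", "B", "C")}
    rxns = [
        Reaction("EX_A", {"A": -1.0}, lower_bound=-10.0, upper_bound=0.0),
        Reaction("R_AB", {"A": -1.0, "B": 1.0}),
        Reaction("R_BC", {"B": -1.0, "C": 1.0}),
        Reaction("EX_C", {"C": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    ]
    return MetabolicModel(id="toy_chain", metabolites=mets, reactions=rxns,
                          objective="EX_C")


def toy_two_path() -> MetabolicModel:
    """Two parallel routes A -> P, one capacity-limited; 5 reactions."""
    mets = {m: Metabolite(id=m) for m in ("A", "B", "P")}
    rxns = [
        Reaction("EX_A", {"A": -1.0}, lower_bound=-10.0, upper_bound=0.0),
        Reaction("R1", {"A": -1.0, "P": 1.0}, upper_bound=6.0),
        Reaction("R2", {"A": -1.0, "B": 1.0}),
        Reaction("R3", {"B": -1.0, "P": 1.0}),
        Reaction("EX_P", {"P": -1.0}, lower_bound=0.0, upper_bound=1000.0),
    ]
    return MetabolicModel(id="toy_two_path", metabolites=mets, reactions=rxns,
                          objective="EX_P")


def toy_free_segment() -> MetabolicModel:
    """A polytope that is a single segment: one flux free on [0, 10]."""
    mets = {"A": Metabolite(id="A")}
    rxns = [
        Reaction("EX_in", {"A": -1.0}, lower_bound=-10.0, upper_bound=0.0),
        Reaction("EX_out", {"A": -1.0}, lower_bound=0.0, upper_bound=10.0),
    ]
    return MetabolicModel(id="toy_segment", metabolites=mets, reactions=rxns,
                          objective="EX_out")


def toy_core_model() -> MetabolicModel:
    """PTS/non-PTS carbon uptake toy with several pyruvate-forming reactions.

    Glucose enters via a PEP-dependent phosphotransferase (PTS, co-producing
    pyruvate), gluconate via a non-PTS permease; pyruvate kinase and a lumped
    malate shunt (PEP -> OAA -> MAL -> PYR) both form pyruvate downstream, and
    a biomass sink consumes precursor pools.  Genes on each catalytic step
    support GPR-based reduction tests; tryptophanase and the indole exchange
    are *not* pre-installed — add them with ``add_tna_reaction`` /
    ``add_exchange`` as the study pipeline would.
    """
    met_ids = ["glc_e", "glcn_e", "g6p_c", "pep_c", "pyr_c", "oaa_c", "mal_c",
               "co2_c", "trp_e", "trp_c", "h2o_c", "nh4_c"]
    formulas = {"glc_e": "C6H12O6", "glcn_e": "C6H12O7", "g6p_c": "C6H13O9P",
                "pep_c": "C3H5O6P", "pyr_c": "C3H4O3", "oaa_c": "C4H4O5",
                "mal_c": "C4H6O5", "co2_c": "CO2", "trp_e": "C11H12N2O2",
                "trp_c": "C11H12N2O2", "h2o_c": "H2O", "nh4_c": "NH3"}
    mets = {m: Metabolite(id=m, formula=formulas[m],
                          compartment="e" if m.endswith("_e") else "c")
            for m in met_ids}
    rxns = [
        Reaction("EX_glc", {"glc_e": -1.0}, lower_bound=-10.0, upper_bound=0.0),
        Reaction("EX_glcn", {"glcn_e": -1.0}, lower_bound=0.0, upper_bound=0.0),
        Reaction("EX_trp", {"trp_e": -1.0}, lower_bound=0.0, upper_bound=0.0),
        Reaction("EX_h2o", {"h2o_c": -1.0}, lower_bound=-1000.0, upper_bound=1000.0),
        Reaction("EX_nh4", {"nh4_c": -1.0}, lower_bound=-1000.0, upper_bound=1000.0),
        Reaction("EX_co2", {"co2_c": -1.0}, lower_bound=0.0, upper_bound=1000.0),
        Reaction("PTS_glc", {"glc_e": -1.0, "pep_c": -1.0, "g6p_c": 1.0,
                             "pyr_c": 1.0}, gpr="ptsG", name="PTS glucose uptake"),
        Reaction("GLCNt", {"glcn_e": -1.0, "g6p_c": 1.0}, gpr="gntP",
                 name="gluconate uptake (non-PTS, lumped)"),
        Reaction("GLYC", {"g6p_c": -1.0, "pep_c": 2.0}, gpr="gapA and pgk",
                 name="lumped glycolysis"),
        Reaction("PYK", {"pep_c": -1.0, "pyr_c": 1.0}, gpr="pyk",
                 name="pyruvate kinase"),
        Reaction("PPC", {"pep_c": -1.0, "co2_c": -1.0, "oaa_c": 1.0}, gpr="ppc",
                 name="PEP carboxylase"),
        Reaction("MDH", {"oaa_c": -1.0, "mal_c": 1.0}, gpr="mdh",
                 name="malate dehydrogenase (lumped)"),
        Reaction("MEZ", {"mal_c": -1.0, "pyr_c": 1.0, "co2_c": 1.0}, gpr="malE",
                 name="malic enzyme"),
        Reaction("TRPt", {"trp_e": -1.0, "trp_c": 1.0}, gpr="aroP",
                 name="aromatic amino acid permease"),
        Reaction("BIOMASS", {"g6p_c": -1.0, "pyr_c": -3.0, "pep_c": -0.5},
                 name="biomass sink"),
    ]
    model = MetabolicModel(
        id="toy_core", metabolites=mets, reactions=rxns, objective="BIOMASS",
        genes={"ptsG", "gntP", "gapA", "pgk", "pyk", "ppc", "mdh", "malE",
               "aroP"})
    model.validate()
    return model
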