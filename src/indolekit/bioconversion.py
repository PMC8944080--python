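"""Stoichiometric and process accounting for whole-cell Trp-to-indole bioconversion.

Tryptophanase cleaves one mole of l-tryptophan into one mole each of indole,
pyruvate and ammonia, so process performance is naturally expressed on a molar
basis: mol-% conversion, the theoretical indole titer at complete conversion,
space-time yield, and — for cultivations run with a hydrophobic solvent overlay
(in situ product recovery, ISPR) — two-phase partitioning and medium-normalized
titers.  All functions return raw (unrounded) numbers; the reporting helpers
apply the presentation rounding used in the field (mol-% to the nearest integer,
titers to one decimal, space-time yields to two decimals, half away from zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

#: Molecular weights, g/mol.  Standard physical constants; override only via
#: the explicit keyword arguments of the functions below.
MW_TRP = 204.23
MW_INDOLE = 117.15


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (so 64.5 -> 65, -0.5 -> -1).

    Python's built-in round() uses banker's rounding; printed tables in this
    domain use the conventional half-away rule.
    """
    factor = 10.0 ** ndigits
    scaled = x * factor
    # nudge by a few ulps so values that are exactly representable halves
    # (e.g. 0.5, 2.5) round away from zero rather than to even
    return math.floor(abs(scaled) + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CultureSample:
    """One sampling point of a biotransformation culture."""

    time_h: float
    trp_g_per_l: float
    indole_g_per_l: float
    biomass_od600: Optional[float] = None
    phase: str = "aqueous"

    def __post_init__(self) -> None:
        if self.trp_g_per_l < 0 or self.indole_g_per_l < 0:
            raise ValueError("concentrations must be non-negative")
        if self.phase not in ("aqueous", "organic"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class TwoPhaseState:
    """Aqueous/organic volumes and concentrations of one solute at equilibrium."""

    v_aq: float
    v_org: float
    c_aq: float
    c_org: float
    solvent: str = ""

    def __post_init__(self) -> None:
        if self.v_aq <= 0 or self.v_org <= 0:
            raise ValueError("phase volumes must be positive")
        for c in (self.c_aq, self.c_org):
            if not math.isfinite(c) or c < 0:
                raise ValueError("concentrations must be finite and non-negative")

    @property
    def total_mass(self) -> float:
        return self.c_aq * self.v_aq + self.c_org * self.v_org


@dataclass
class ConversionReport:
    """Summary of a biotransformation run on a molar basis."""

    mol_pct: float
    mol_pct_rounded: float
    titer_g_per_l: float
    theoretical_max_titer_g_per_l: float
    space_time_yield_g_per_l_h: Optional[float] = None
    balance_closure: Optional[float] = None
    losses_g_per_l: float = 0.0
    unexplained_gap: Optional[float] = None
    flags: list[str] = field(default_factory=list)


def mol_conversion(indole_g_per_l: float, trp_supplied_g_per_l: float,
                   *, mw_trp: float = MW_TRP, mw_indole: float = MW_INDOLE) -> float:
    """Molar conversion of supplied Trp to indole, in percent (raw, unrounded).

    100 * (indole / MW_indole) / (trp_supplied / MW_trp).  The conversion basis
    is the total Trp supplied up to the sampling time; with split feeding the
    doses are summed before calling this.
    """
    if trp_supplied_g_per_l <= 0:
        raise ValueError("trp_supplied_g_per_l must be positive")
    if indole_g_per_l < 0:
        raise ValueError("indole_g_per_l must be non-negative")
    return 100.0 * (indole_g_per_l / mw_indole) / (trp_supplied_g_per_l / mw_trp)


def mol_conversion_rounded(indole_g_per_l: float, trp_supplied_g_per_l: float,
                           **kw) -> int:
    """mol-% conversion rounded to the nearest integer, half away from zero."""
    return int(round_half_away(mol_conversion(indole_g_per_l, trp_supplied_g_per_l, **kw)))


def theoretical_titer(trp_g_per_l: float, *, mw_trp: float = MW_TRP,
                      mw_indole: float = MW_INDOLE) -> float:
    """Indole titer (g/L, raw) at 100% molar conversion of the given Trp dose."""
    if trp_g_per_l < 0:
        raise ValueError("trp_g_per_l must be non-negative")
    return trp_g_per_l * mw_indole / mw_trp


def theoretical_titer_rounded(trp_g_per_l: float, **kw) -> float:
    """Theoretical titer reported to one decimal."""
    return round_half_away(theoretical_titer(trp_g_per_l, **kw), 1)


def space_time_yield(titer_g_per_l: float, elapsed_h: float) -> float:
    """Volumetric productivity titer/time in g L^-1 h^-1 (raw)."""
    if elapsed_h <= 0:
        raise ValueError("elapsed_h must be positive")
    return titer_g_per_l / elapsed_h


def space_time_yield_rounded(titer_g_per_l: float, elapsed_h: float) -> float:
    """Space-time yield reported to two decimals."""
    return round_half_away(space_time_yield(titer_g_per_l, elapsed_h), 2)


def normalize_overlay(state: TwoPhaseState) -> float:
    """Total solute mass expressed as a concentration on the medium volume.

    (c_org*v_org + c_aq*v_aq) / v_aq.  For a 20% (v/v, relative to medium)
    overlay that holds essentially all of the product, this is c_org / 5 —
    the convention used when quoting ISPR titers against the aqueous phase.
    """
    return state.total_mass / state.v_aq


def extraction_capacity(state: TwoPhaseState) -> float:
    """Percent of the solute's total mass residing in the organic phase."""
    total = state.total_mass
    if total <= 0:
        raise ValueError("total mass is zero; extraction capacity undefined")
    return 100.0 * state.c_org * state.v_org / total


def offgas_loss_g_per_l(rate_ug_per_h: float, duration_h: float,
                        working_volume_l: float) -> float:
    """Integrated off-gas product loss expressed as a culture concentration."""
    if working_volume_l <= 0:
        raise ValueError("working_volume_l must be positive")
    if rate_ug_per_h < 0 or duration_h < 0:
        raise ValueError("rate and duration must be non-negative")
    return rate_ug_per_h * 1e-6 * duration_h / working_volume_l


def mass_balance(timecourse: Sequence[CultureSample],
                 trp_doses: Sequence[tuple[float, float]],
                 offgas_rate_ug_per_h: float = 0.0,
                 working_volume_l: float = 0.75,
                 *, gap_flag_threshold: float = 0.05,
                 mw_trp: float = MW_TRP, mw_indole: float = MW_INDOLE) -> ConversionReport:
    """Molar closure of a biotransformation time course.

    Supplied Trp (all doses up to the final sample, mol/L) is compared with
    residual Trp + indole present + integrated off-gas loss; any remainder is
    the unexplained gap.  A gap above ``gap_flag_threshold`` (fraction of
    supplied moles) is flagged.

    Parameters
    ----------
    timecourse:
        At least two samples in increasing time order.
    trp_doses:
        (time_h, g_per_l) pairs; doses at or before the final sample time count.
    offgas_rate_ug_per_h:
        Constant indole loss rate to the gas phase, integrated over the course.
    """
    if len(timecourse) < 2:
        raise ValueError("need at least two samples")
    times = [s.time_h for s in timecourse]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("samples must be strictly increasing in time")
    final = timecourse[-1]
    duration = final.time_h - timecourse[0].time_h

    supplied_g = sum(g for t, g in trp_doses if t <= final.time_h)
    if supplied_g <= 0:
        raise ValueError("no Trp supplied up to the final sample")
    supplied_mol = supplied_g / mw_trp

    offgas_g = offgas_loss_g_per_l(offgas_rate_ug_per_h, duration, working_volume_l)
    residual_mol = final.trp_g_per_l / mw_trp
    indole_mol = final.indole_g_per_l / mw_indole
    offgas_mol = offgas_g / mw_indole

    closure = (residual_mol + indole_mol + offgas_mol) / supplied_mol
    gap = 1.0 - closure

    flags: list[str] = []
    if gap > gap_flag_threshold:
        flags.append(f"unexplained molar gap {100*gap:.1f}% exceeds "
                     f"{100*gap_flag_threshold:.0f}%")
    if closure > 1.0 + 1e-9:
        flags.append("closure exceeds 100%: inputs inconsistent")

    converted_basis = supplied_g - final.trp_g_per_l  # g/L of Trp consumed
    raw_pct = mol_conversion(final.indole_g_per_l, supplied_g,
                             mw_trp=mw_trp, mw_indole=mw_indole)
    return ConversionReport(
        mol_pct=raw_pct,
        mol_pct_rounded=round_half_away(raw_pct),
        titer_g_per_l=final.indole_g_per_l,
        theoretical_max_titer_g_per_l=theoretical_titer(
            supplied_g, mw_trp=mw_trp, mw_indole=mw_indole),
        space_time_yield_g_per_l_h=(space_time_yield(final.indole_g_per_l, duration)
                                    if duration > 0 else None),
        balance_closure=closure,
        losses_g_per_l=offgas_g + max(0.0, converted_basis * mw_indole / mw_trp
                                      - final.indole_g_per_l - offgas_g),
        unexplained_gap=gap,
        flags=flags,
    )
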