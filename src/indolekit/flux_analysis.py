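"""Constraint-based metabolic modelling for the indole-producing chassis.

Covers the model-handling steps of a flux-enforcement study: reduce a model to
a gene-deleted chassis via its gene–protein–reaction (GPR) rules, graft in the
tryptophanase reaction (trp + h2o -> indole + pyruvate + ammonium) and an
indole exchange, configure the growth medium through exchange-reaction bounds,
solve flux balance analysis (FBA) as a linear program, sample the feasible
flux polytope with artificial-centering hit-and-run (ACHR), and decompose
which reactions produce a metabolite of interest (e.g. pyruvate) and in what
proportions.

Models are plain JSON (documented schema below); the widespread COBRA JSON
convention is also read.  Flux units are mmol gDW^-1 h^-1 throughout.
"""

from __future__ import annotations

import copy
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linprog

FEASIBILITY_TOL = 1e-6   # absolute tolerance on S.v
BOUND_TOL = 1e-9
_BOUND_CAP = 1000.0


class InfeasibleError(RuntimeError):
    """The LP has no feasible flux distribution."""


class UnboundedError(RuntimeError):
    """The LP objective is unbounded under the given constraints."""


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds and an optional GPR rule.

    Stoichiometry maps metabolite id -> coefficient (negative = consumed).
    An empty stoichiometry is only legal for declared exchange placeholders;
    conventional exchanges carry a single metabolite with coefficient -1.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = _BOUND_CAP
    gpr: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"reaction {self.id!r}: lower_bound > upper_bound")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound,
                        self.upper_bound, self.gpr, self.name)


@dataclass
class MetabolicModel:
    id: str
    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    objective: str
    genes: set[str] = field(default_factory=set)

    def validate(self) -> None:
        errors = []
        if not self.objective:
            errors.append("no objective reaction declared")
        elif self.objective not in {r.id for r in self.reactions}:
            errors.append(f"objective {self.objective!r} is not a reaction")
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                errors.append(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            for met in r.stoichiometry:
                if met not in self.metabolites:
                    errors.append(f"reaction {r.id!r}: unknown metabolite {met!r}")
        if errors:
            raise ValueError("invalid model: " + "; ".join(errors))

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S (metabolites x reactions) plus its row/column id orderings."""
        met_ids = sorted(self.metabolites)
        row = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, coef in r.stoichiometry.items():
                S[row[m], j] = coef
        return S, met_ids, self.reaction_ids

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]


# ---------------------------------------------------------------------------
# JSON I/O (native schema + COBRA JSON convention)
# ---------------------------------------------------------------------------

def read_model(path) -> MetabolicModel:
    """Load a model from native JSON or the community COBRA JSON dialect.

    Native schema::

        {"id": ..., "objective": "<rxn id>",
         "metabolites": {"<id>": {"name":..., "formula":..., "compartment":...}},
         "genes": [...],
         "reactions": [{"id":..., "stoichiometry": {"<met>": coef, ...},
                        "lower_bound":..., "upper_bound":..., "gpr":...}]}
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data.get("metabolites"), list):
        model = _from_cobra_json(data)
    else:
        model = _from_native_json(data)
    model.validate()
    return model


def _from_native_json(data: dict) -> MetabolicModel:
    mets = {mid: Metabolite(id=mid, **{k: v for k, v in (m or {}).items()
                                       if k in ("name", "formula", "compartment")})
            for mid, m in data.get("metabolites", {}).items()}
    rxns = [Reaction(id=r["id"], stoichiometry={k: float(v) for k, v in
                                                r.get("stoichiometry", {}).items()},
                     lower_bound=float(r.get("lower_bound", 0.0)),
                     upper_bound=float(r.get("upper_bound", _BOUND_CAP)),
                     gpr=r.get("gpr", ""), name=r.get("name", ""))
            for r in data.get("reactions", [])]
    return MetabolicModel(id=data.get("id", "model"), metabolites=mets,
                          reactions=rxns, objective=data.get("objective", ""),
                          genes=set(data.get("genes", [])))


def _from_cobra_json(data: dict) -> MetabolicModel:
    mets = {m["id"]: Metabolite(id=m["id"], name=m.get("name", ""),
                                formula=m.get("formula", "") or "",
                                compartment=m.get("compartment", "c"))
            for m in data["metabolites"]}
    rxns = []
    objective = ""
    for r in data["reactions"]:
        rxns.append(Reaction(
            id=r["id"], stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
            lower_bound=float(r.get("lower_bound", -_BOUND_CAP)),
            upper_bound=float(r.get("upper_bound", _BOUND_CAP)),
            gpr=r.get("gene_reaction_rule", ""), name=r.get("name", "")))
        if r.get("objective_coefficient", 0):
            objective = r["id"]
    genes = {g["id"] for g in data.get("genes", [])}
    return MetabolicModel(id=data.get("id", "model"), metabolites=mets,
                          reactions=rxns, objective=objective, genes=genes)


def write_model(model: MetabolicModel, path) -> None:
    model.validate()
    data = {
        "id": model.id,
        "objective": model.objective,
        "genes": sorted(model.genes),
        "metabolites": {m.id: {"name": m.name, "formula": m.formula,
                               "compartment": m.compartment}
                        for m in model.metabolites.values()},
        "reactions": [{"id": r.id, "name": r.name,
                       "stoichiometry": r.stoichiometry,
                       "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
                       "gpr": r.gpr}
                      for r in model.reactions],
    }
    Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# GPR evaluation and model reduction
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|\b[Aa][Nn][Dd]\b|\b[Oo][Rr]\b|[^\s()]+)")


def _tokenize_gpr(expr: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            raise ValueError(f"GPR parse error at position {pos}: {expr[pos:]!r}")
        tok = m.group(1)
        kind = tok.lower() if tok.lower() in ("and", "or") else (
            tok if tok in "()" else "gene:" + tok)
        tokens.append((kind, m.start(1)))
        pos = m.end()
    return tokens


def evaluate_gpr(expr: str, deleted_genes: Iterable[str]) -> bool:
    """Evaluate a boolean AND/OR/parentheses gene rule against a deletion set.

    A gene is active unless deleted; AND needs all operands active, OR any.
    The empty rule means no gene dependence and evaluates active.
    """
    expr = expr.strip()
    if not expr:
        return True
    deleted = set(deleted_genes)
    tokens = _tokenize_gpr(expr)
    idx = 0

    def error(msg: str) -> ValueError:
        pos = tokens[idx][1] if idx < len(tokens) else len(expr)
        return ValueError(f"GPR parse error at position {pos}: {msg}")

    def parse_or() -> bool:
        nonlocal idx
        val = parse_and()
        while idx < len(tokens) and tokens[idx][0] == "or":
            idx += 1
            val = parse_and() or val
        return val

    def parse_and() -> bool:
        nonlocal idx
        val = parse_atom()
        while idx < len(tokens) and tokens[idx][0] == "and":
            idx += 1
            val = parse_atom() and val
        return val

    def parse_atom() -> bool:
        nonlocal idx
        if idx >= len(tokens):
            raise error("unexpected end of expression")
        kind, _ = tokens[idx]
        if kind == "(":
            idx += 1
            val = parse_or()
            if idx >= len(tokens) or tokens[idx][0] != ")":
                raise error("missing closing parenthesis")
            idx += 1
            return val
        if kind.startswith("gene:"):
            idx += 1
            return kind[5:] not in deleted
        raise error(f"unexpected token {kind!r}")

    result = parse_or()
    if idx != len(tokens):
        raise error(f"trailing tokens {tokens[idx:]}")
    return result


@dataclass
class ReductionReport:
    removed: list[str]
    unknown_genes: list[str]


def reduce_model(model: MetabolicModel, deleted_genes: Iterable[str]
                 ) -> tuple[MetabolicModel, ReductionReport]:
    """Remove reactions whose GPR evaluates inactive under the deletions.

    Genes absent from the model are warned about, not fatal.  Removing the
    objective reaction is an explicit error.  Idempotent for a fixed gene set.
    """
    deleted = set(deleted_genes)
    unknown = sorted(deleted - model.genes)
    if unknown:
        warnings.warn(f"deleted genes not in model: {unknown}", stacklevel=2)
    out = model.copy()
    removed = [r.id for r in out.reactions if not evaluate_gpr(r.gpr, deleted)]
    if model.objective in removed:
        raise ValueError(f"reduction would remove the objective reaction "
                         f"{model.objective!r}")
    out.reactions = [r for r in out.reactions if r.id not in set(removed)]
    return out, ReductionReport(removed=removed, unknown_genes=unknown)


# ---------------------------------------------------------------------------
# model editing: tryptophanase, exchanges, medium
# ---------------------------------------------------------------------------

#: default metabolite ids for the grafted tryptophanase reaction
TNA_METABOLITES = {
    "trp": ("trp_c", "L-tryptophan", "C11H12N2O2"),
    "h2o": ("h2o_c", "water", "H2O"),
    "indole": ("indole_c", "indole", "C8H7N"),
    "pyr": ("pyr_c", "pyruvate", "C3H4O3"),
    "nh4": ("nh4_c", "ammonium", "NH3"),
}

TNA_REACTION_ID = "TNA"


def add_tna_reaction(model: MetabolicModel, *,
                     metabolite_ids: Optional[dict[str, str]] = None,
                     reaction_id: str = TNA_REACTION_ID
                     ) -> tuple[MetabolicModel, list[str]]:
    """Add the irreversible tryptophanase reaction trp + h2o -> indole + pyr + nh3.

    The reaction is element-balanced (C11H12N2O2 + H2O -> C8H7N + C3H4O3 + NH3).
    Missing metabolites are created with their formulas and reported.
    """
    if reaction_id in {r.id for r in model.reactions}:
        raise ValueError(f"reaction {reaction_id!r} already present")
    out = model.copy()
    ids = {}
    created = []
    for role, (default_id, name, formula) in TNA_METABOLITES.items():
        mid = (metabolite_ids or {}).get(role, default_id)
        ids[role] = mid
        if mid not in out.metabolites:
            out.metabolites[mid] = Metabolite(id=mid, name=name, formula=formula)
            created.append(mid)
    out.reactions.append(Reaction(
        id=reaction_id, name="tryptophanase",
        stoichiometry={ids["trp"]: -1.0, ids["h2o"]: -1.0, ids["indole"]: 1.0,
                       ids["pyr"]: 1.0, ids["nh4"]: 1.0},
        lower_bound=0.0, upper_bound=_BOUND_CAP))
    return out, created


_FORMULA = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for el, n in _FORMULA.findall(formula):
        if el:
            counts[el] = counts.get(el, 0) + (int(n) if n else 1)
    return counts


def element_balance(model: MetabolicModel, reaction_id: str) -> dict[str, float]:
    """Net element production of a reaction (all zeros means balanced).

    Metabolites with no formula contribute nothing and make the check vacuous
    for their elements.
    """
    rxn = model.reaction(reaction_id)
    net: dict[str, float] = {}
    for mid, coef in rxn.stoichiometry.items():
        for el, cnt in parse_formula(model.metabolites[mid].formula).items():
            net[el] = net.get(el, 0.0) + coef * cnt
    return {el: v for el, v in net.items()}


def add_exchange(model: MetabolicModel, metabolite: str,
                 lower_bound: float = 0.0, upper_bound: float = _BOUND_CAP
                 ) -> MetabolicModel:
    """Add a single-metabolite exchange reaction ``EX_<met>`` with given bounds."""
    if metabolite not in model.metabolites:
        raise KeyError(f"metabolite {metabolite!r} not in model")
    rid = f"EX_{metabolite}"
    if rid in {r.id for r in model.reactions}:
        raise ValueError(f"exchange {rid!r} already present")
    out = model.copy()
    out.reactions.append(Reaction(id=rid, name=f"{metabolite} exchange",
                                  stoichiometry={metabolite: -1.0},
                                  lower_bound=lower_bound, upper_bound=upper_bound))
    return out


@dataclass(frozen=True)
class MediumSpec:
    """Growth-medium configuration applied to exchange reactions.

    ``free_exchanges`` (salts, minerals, oxygen, water, ammonium ...) get a
    lower bound of -1000 to model unlimited availability; the carbon source
    and Trp are limited to -10; every other exchange has uptake closed
    (lower bound 0) unless whitelisted in ``keep_open``.
    """

    carbon_exchange: str
    trp_exchange: Optional[str] = None
    free_exchanges: tuple[str, ...] = ()
    keep_open: tuple[str, ...] = ()
    carbon_uptake: float = -10.0
    trp_uptake: float = -10.0
    free_uptake: float = -1000.0


def set_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Apply a medium specification to the model's exchange reactions."""
    out = model.copy()
    ex = {r.id: r for r in out.exchanges()}
    named = [medium.carbon_exchange, *([medium.trp_exchange] if medium.trp_exchange else []),
             *medium.free_exchanges]
    for rid in named:
        if rid not in ex:
            raise KeyError(f"exchange reaction {rid!r} not in model")
    for r in ex.values():
        if r.id == medium.carbon_exchange:
            r.lower_bound = medium.carbon_uptake
        elif medium.trp_exchange and r.id == medium.trp_exchange:
            r.lower_bound = medium.trp_uptake
        elif r.id in medium.free_exchanges:
            r.lower_bound = medium.free_uptake
        elif r.id in medium.keep_open:
            pass
        else:
            r.lower_bound = max(r.lower_bound, 0.0)
    return out


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

@dataclass
class FluxVector:
    fluxes: dict[str, float]
    objective_value: float
    objective_id: str

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in order])


def _lp_bounds(model: MetabolicModel, cap: float = _BOUND_CAP
               ) -> list[tuple[float, float]]:
    return [(max(r.lower_bound, -cap), min(r.upper_bound, cap))
            for r in model.reactions]


def fba(model: MetabolicModel, objective: Optional[str] = None,
        direction: str = "max") -> FluxVector:
    """Flux balance analysis: optimize c.v subject to S.v = 0, lb <= v <= ub."""
    model.validate()
    obj = objective or model.objective
    rids = model.reaction_ids
    if obj not in rids:
        raise KeyError(f"objective reaction {obj!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    S, _, _ = model.stoichiometric_matrix()
    c = np.zeros(len(rids))
    c[rids.index(obj)] = -1.0 if direction == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=[(r.lower_bound, r.upper_bound) for r in model.reactions],
                  method="highs")
    if res.status == 2:
        raise InfeasibleError("FBA problem is infeasible")
    if res.status == 3:
        raise UnboundedError("FBA objective is unbounded")
    if not res.success:  # pragma: no cover - solver failure
        raise RuntimeError(f"LP solve failed: {res.message}")
    v = res.x
    value = float(-res.fun if direction == "max" else res.fun)
    return FluxVector(fluxes=dict(zip(rids, map(float, v))),
                      objective_value=value, objective_id=obj)


# ---------------------------------------------------------------------------
# ACHR sampling
# ---------------------------------------------------------------------------

@dataclass
class FluxSampleSet:
    samples: np.ndarray  # n_samples x n_reactions
    reaction_ids: list[str]
    seed: Optional[int]
    n_samples: int

    def mean(self) -> dict[str, float]:
        m = self.samples.mean(axis=0)
        return dict(zip(self.reaction_ids, map(float, m)))

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.samples, columns=self.reaction_ids).to_csv(path, index=False)


def _fva_warmup(model: MetabolicModel) -> np.ndarray:
    """Per-reaction max/min flux vectors (the ACHR warm-up extreme points)."""
    points = []
    for rid in model.reaction_ids:
        for direction in ("max", "min"):
            sol = fba(model, objective=rid, direction=direction)
            points.append(sol.as_array(model.reaction_ids))
    return np.array(points)


def check_feasible(model: MetabolicModel, v: np.ndarray,
                   tol_sv: float = FEASIBILITY_TOL,
                   tol_bounds: float = 1e-6) -> bool:
    S, _, _ = model.stoichiometric_matrix()
    if np.max(np.abs(S @ v)) > tol_sv:
        return False
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return bool(np.all(v >= lb - tol_bounds) and np.all(v <= ub + tol_bounds))


def achr_sample(model: MetabolicModel, n: int = 10_000,
                seed: Optional[int] = None, burn_in: int = 1000,
                thinning: int = 10) -> FluxSampleSet:
    """Artificial-centering hit-and-run sampling of the flux polytope.

    Warm-up points are the flux-variability extreme points (per-reaction
    optima).  Each iteration moves the current point along the chord through
    a random (warm-up point - running center) direction, drawing the step
    uniformly from the feasible segment; the center is the running mean of
    all visited points.  ``burn_in`` iterations are discarded, then every
    ``thinning``-th point is retained until ``n`` samples are collected.

    A degenerate (zero-volume) polytope yields the single feasible point
    repeated, with a warning.
    """
    model.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    # cap bounds at +-1000 so the polytope is bounded for sampling
    model = model.copy()
    for r in model.reactions:
        r.lower_bound = max(r.lower_bound, -_BOUND_CAP)
        r.upper_bound = min(r.upper_bound, _BOUND_CAP)
    rids = model.reaction_ids
    S, _, _ = model.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])

    warmup = _fva_warmup(model)
    center = warmup.mean(axis=0)
    spread = warmup.max(axis=0) - warmup.min(axis=0)
    if np.max(spread) < 1e-9:
        warnings.warn("flux polytope is a single point; returning it repeatedly",
                      stacklevel=2)
        samples = np.tile(center, (n, 1))
        return FluxSampleSet(samples=samples, reaction_ids=rids, seed=seed,
                             n_samples=n)

    # null-space projector to damp numerical drift off S.v = 0
    from scipy.linalg import null_space
    N = null_space(S)

    x = center.copy()
    samples = np.empty((n, len(rids)))
    collected = 0
    it = 0
    visited = 1.0
    while collected < n:
        d = warmup[rng.integers(len(warmup))] - center
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d = d / norm
        # chord limits from the box bounds
        with np.errstate(divide="ignore", invalid="ignore"):
            lo_steps = (lb - x) / d
            hi_steps = (ub - x) / d
        pos = np.where(d > 1e-12, hi_steps, np.where(d < -1e-12, lo_steps, np.inf))
        neg = np.where(d > 1e-12, lo_steps, np.where(d < -1e-12, hi_steps, -np.inf))
        alpha_max = float(np.min(pos))
        alpha_min = float(np.max(neg))
        if alpha_max <= alpha_min:
            continue
        x = x + rng.uniform(alpha_min, alpha_max) * d
        np.clip(x, lb, ub, out=x)
        it += 1
        visited += 1.0
        center = center + (x - center) / visited
        if it % 200 == 0 and np.max(np.abs(S @ x)) > FEASIBILITY_TOL / 10:
            x = N @ (N.T @ x)  # re-project onto the steady-state subspace
            np.clip(x, lb, ub, out=x)
        if it > burn_in and (it - burn_in) % thinning == 0:
            samples[collected] = x
            collected += 1
    return FluxSampleSet(samples=samples, reaction_ids=rids, seed=seed, n_samples=n)


# ---------------------------------------------------------------------------
# producer decomposition
# ---------------------------------------------------------------------------

@dataclass
class ProducerBreakdown:
    """Fractional contribution of each producing reaction to a metabolite's
    total (gross) production; fractions sum to 1 when production is nonzero."""

    metabolite: str
    fractions: dict[str, float]
    total_production: float
    basis: str  # "flux_vector" | "sample_mean"
    accounting: str = "gross"


def producer_breakdown(flux_source: Union[FluxVector, FluxSampleSet],
                       model: MetabolicModel, metabolite: str,
                       accounting: str = "gross") -> ProducerBreakdown:
    """Decompose which reactions produce ``metabolite`` and in what shares.

    A reaction contributes coefficient*flux whenever that signed product is
    positive — reversible reactions count by their realized direction.  With
    a sample set, per-sample positive contributions are averaged before
    normalizing (``accounting="gross"``); ``"net"`` instead signs each
    reaction's average coefficient*flux and keeps positive means only.
    """
    if metabolite not in model.metabolites:
        raise KeyError(f"metabolite {metabolite!r} not in model")
    if accounting not in ("gross", "net"):
        raise ValueError("accounting must be 'gross' or 'net'")
    producers = [(r.id, r.stoichiometry[metabolite])
                 for r in model.reactions if metabolite in r.stoichiometry]

    contributions: dict[str, float] = {}
    if isinstance(flux_source, FluxVector):
        basis = "flux_vector"
        for rid, coef in producers:
            prod = coef * flux_source.fluxes[rid]
            if prod > 0:
                contributions[rid] = prod
    else:
        basis = "sample_mean"
        for rid, coef in producers:
            col = coef * flux_source.column(rid)
            mean = float(np.mean(np.clip(col, 0.0, None)) if accounting == "gross"
                         else np.mean(col))
            if mean > 0:
                contributions[rid] = mean

    total = sum(contributions.values())
    if total <= 0:
        raise ValueError(f"no production of {metabolite!r} in the given fluxes; "
                         "breakdown undefined")
    fractions = {rid: c / total for rid, c in contributions.items()}
    return ProducerBreakdown(metabolite=metabolite, fractions=fractions,
                             total_production=total, basis=basis,
                             accounting=accounting)
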