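"""Flux-balance-analysis yield features under experiment-matched constraints.

Each strain-design record is mapped onto a stoichiometric model: carbon
sources set exchange uptake bounds, the aeration regime bounds oxygen uptake,
gene knockouts silence reactions through the gene-reaction (GPR) rules, and
pathway overexpression raises a reaction's lower bound to 10% of its
theoretical maximum flux. Four linear programs on the constrained model then
summarise the network's metabolic capacity:

1. max biomass                         -> vb*, carbon uptake vc*
2. max product                         -> vp*, vc_p
3. max biomass s.t. product = 0.5 vp*  -> vb50p, vc50p
4. max product s.t. biomass = 0.5 vb*  -> vp50b, vc50b

and the four yields (flux per unit carbon-uptake flux)

    yb_max = vb*/vc*,  yp_max = vp*/vc_p,
    yb50p = vb50p/vc50p,  yp50b = vp50b/vc50b

are appended to the ML feature matrix as ``cobra_`` columns. FBA optima can
be degenerate in the uptake flux; a secondary LP minimises total carbon
uptake at the fixed optimal objective so the yield features are
deterministic.

cobrapy (with the GLPK solver via optlang) provides model I/O, GPR
evaluation and the LP backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import cobra
from cobra.io import load_json_model, read_sbml_model

from .schema import DesignRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicModel",
    "ModificationSpec",
    "FluxFeatureSet",
    "FBAResult",
    "ConfigurationError",
    "load_model",
    "wrap_model",
    "apply_modifications",
    "fba",
    "compute_flux_features",
    "spec_from_record",
    "flux_feature_frame",
]

SOLVER_TOLERANCE = 1e-9
_UPTAKE_EPS = 1e-9


class ConfigurationError(ValueError):
    """Model designations (biomass/product/carbon/oxygen) unresolved."""


@dataclass
class MetabolicModel:
    """A cobra model plus the designated objective/exchange reactions.

    ``biomass_id`` and ``product_id`` play the role of the biomass and
    product objective unit vectors; ``carbon_ids`` are the candidate
    carbon-source exchange reactions (uptake = negative flux) and
    ``oxygen_id`` the oxygen exchange.
    """

    cobra_model: cobra.Model
    biomass_id: str
    product_id: str
    carbon_ids: tuple[str, ...]
    oxygen_id: str | None = None
    default_o2_uptake: float = 20.0   # mmol/gDW/h, aerobic baseline
    solver_cap: float = 1000.0        # bound used for "unbounded" uptake

    def __post_init__(self):
        rxns = {r.id for r in self.cobra_model.reactions}
        for name, rid in [("biomass", self.biomass_id), ("product", self.product_id)]:
            if rid not in rxns:
                raise ConfigurationError(f"designated {name} reaction {rid!r} not in model")
        for rid in self.carbon_ids:
            if rid not in rxns:
                raise ConfigurationError(f"designated carbon exchange {rid!r} not in model")
        if self.oxygen_id is not None and self.oxygen_id not in rxns:
            raise ConfigurationError(f"designated oxygen exchange {self.oxygen_id!r} not in model")
        self.cobra_model.solver.configuration.tolerances.feasibility = SOLVER_TOLERANCE

    def copy(self) -> "MetabolicModel":
        return replace(self, cobra_model=self.cobra_model.copy())

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {r.id: r.bounds for r in self.cobra_model.reactions}


def wrap_model(model: cobra.Model, *, biomass_id: str, product_id: str,
               carbon_ids: Sequence[str], oxygen_id: str | None = None,
               default_o2_uptake: float = 20.0) -> MetabolicModel:
    """Designate objective/exchange reactions on an in-memory cobra model."""
    return MetabolicModel(model, biomass_id, product_id, tuple(carbon_ids),
                          oxygen_id, default_o2_uptake)


def load_model(path, *, biomass_id: str, product_id: str,
               carbon_ids: Sequence[str], oxygen_id: str | None = None,
               default_o2_uptake: float = 20.0) -> MetabolicModel:
    """Load SBML (Level 3 + FBC) or cobrapy-JSON and resolve designations.

    The JSON dialect is cobrapy's model schema: top-level ``reactions``
    (with ``metabolites`` stoichiometry maps, ``lower_bound``/``upper_bound``
    and ``gene_reaction_rule``), ``metabolites`` and ``genes`` arrays.
    """
    spath = str(path)
    if spath.endswith(".json"):
        model = load_json_model(spath)
    elif spath.endswith((".xml", ".sbml", ".xml.gz")):
        try:
            model = read_sbml_model(spath)
        except Exception as exc:  # cobra raises CobraSBMLError on bad FBC
            raise ConfigurationError(
                f"could not parse {spath} as SBML Level 3 + FBC: {exc}") from exc
    else:
        raise ConfigurationError(f"unrecognised model format: {spath}")
    return wrap_model(model, biomass_id=biomass_id, product_id=product_id,
                      carbon_ids=carbon_ids, oxygen_id=oxygen_id,
                      default_o2_uptake=default_o2_uptake)


@dataclass(frozen=True)
class ModificationSpec:
    """Experiment-matched interventions applied to the model.

    ``carbon_uptake`` maps exchange-reaction ids to maximum uptake rates
    (mmol/gDW/h, positive numbers); designated carbon exchanges not listed
    are closed. ``overexpress`` lists reaction ids whose lower bound is
    raised to 10% of their theoretical maximum. ``growth_rate`` (1/h), when
    measured, becomes a lower bound on biomass flux in the product-side LPs.
    """

    knockouts: tuple[str, ...] = ()
    overexpress: tuple[str, ...] = ()
    carbon_uptake: Mapping[str, float] = field(default_factory=dict)
    oxygen: str | None = None
    growth_rate: float | None = None

    def __post_init__(self):
        overlap = set(self.knockouts) & set(self.overexpress)
        if overlap:
            raise ValueError(f"genes/reactions both knocked out and overexpressed: {sorted(overlap)}")
        object.__setattr__(self, "carbon_uptake", dict(self.carbon_uptake))

    def cache_key(self) -> tuple:
        return (tuple(sorted(self.knockouts)), tuple(sorted(self.overexpress)),
                tuple(sorted(self.carbon_uptake.items())), self.oxygen,
                self.growth_rate)


@dataclass(frozen=True)
class FluxFeatureSet:
    """The four FBA yield features plus the optimal fluxes behind them."""

    feasible: bool
    vb_star: float = 0.0
    vp_star: float = 0.0
    yb_max: float = 0.0
    yp_max: float = 0.0
    yb50p: float = 0.0
    yp50b: float = 0.0
    vc_star: float = 0.0
    vc_p: float = 0.0
    vc50p: float = 0.0
    vc50b: float = 0.0
    errors: tuple[str, ...] = ()

    def as_features(self) -> dict[str, float]:
        return {
            "cobra_feasible": float(self.feasible),
            "cobra_vb_star": self.vb_star,
            "cobra_vp_star": self.vp_star,
            "cobra_yb_max": self.yb_max,
            "cobra_yp_max": self.yp_max,
            "cobra_yb50p": self.yb50p,
            "cobra_yp50b": self.yp50b,
        }


@dataclass(frozen=True)
class FBAResult:
    status: str            # optimal | infeasible | unbounded | <solver status>
    objective_value: float # NaN unless optimal
    fluxes: pd.Series | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _oxygen_bounds(m: MetabolicModel, regime: str) -> float:
    """Maximum O2 uptake for a named aeration regime."""
    levels = {
        "anaerobic": 0.0,
        "microaerobic": 0.2 * m.default_o2_uptake,
        "aerobic": m.default_o2_uptake,
        "extra-aerobic": m.solver_cap,
    }
    if regime not in levels:
        raise ValueError(f"unknown aeration regime {regime!r}")
    return levels[regime]


def apply_modifications(m: MetabolicModel, spec: ModificationSpec) -> MetabolicModel:
    """Return a constrained copy of the model; the input is untouched.

    Order of operations: bioprocess environment first (carbon-source uptake
    bounds, unavailable substrates closed, aeration), then genetic
    interventions. The "theoretical maximum" used by the 10% overexpression
    rule is computed on the environment-constrained model *before* the
    knockouts/overexpressions of the same spec are applied.
    """
    out = m.copy()
    model = out.cobra_model

    # --- environment ---
    for rid in out.carbon_ids:
        rxn = model.reactions.get_by_id(rid)
        uptake = spec.carbon_uptake.get(rid, 0.0)
        rxn.lower_bound = -abs(uptake)
    for rid, uptake in spec.carbon_uptake.items():
        if rid not in out.carbon_ids:
            model.reactions.get_by_id(rid).lower_bound = -abs(uptake)
    if spec.oxygen is not None:
        if out.oxygen_id is None:
            raise ConfigurationError("aeration regime given but no oxygen exchange designated")
        model.reactions.get_by_id(out.oxygen_id).lower_bound = -_oxygen_bounds(out, spec.oxygen)

    # --- overexpression maxima on the environment-constrained model ---
    ovr_bounds: dict[str, float] = {}
    for rid in spec.overexpress:
        res = fba(out, rid)
        if res.optimal and res.objective_value > _UPTAKE_EPS:
            ovr_bounds[rid] = 0.10 * res.objective_value
        else:
            logger.info("overexpression target %s has zero theoretical maximum; bound untouched", rid)

    # --- genetic interventions ---
    for gid in spec.knockouts:
        try:
            gene = model.genes.get_by_id(gid)
        except KeyError as exc:
            raise KeyError(f"knockout gene {gid!r} not in model") from exc
        gene.knock_out()  # zeroes every reaction whose GPR evaluates false
    for rid, lb in ovr_bounds.items():
        model.reactions.get_by_id(rid).lower_bound = lb
    return out


def fba(m: MetabolicModel, objective: str,
        extra_constraints: Iterable[tuple[Mapping[str, float], str, float]] = (),
        *, minimize: bool = False) -> FBAResult:
    """Solve max (or min) of one reaction's flux over the flux polytope.

    ``extra_constraints`` are (coefficient-map, relation, value) triples with
    relation one of ``eq``/``le``/``ge``, applied on top of S v = 0 and the
    model bounds. Fixed solver settings make the optimum deterministic;
    an unbounded status is reported explicitly (it signals a missing
    exchange bound).
    """
    model = m.cobra_model
    with model:
        model.objective = model.reactions.get_by_id(objective)
        model.objective_direction = "min" if minimize else "max"
        added = []
        for coeffs, rel, value in extra_constraints:
            expr = sum(c * model.reactions.get_by_id(rid).flux_expression
                       for rid, c in coeffs.items())
            if rel == "eq":
                cons = model.problem.Constraint(expr, lb=value, ub=value)
            elif rel == "le":
                cons = model.problem.Constraint(expr, ub=value)
            elif rel == "ge":
                cons = model.problem.Constraint(expr, lb=value)
            else:
                raise ValueError(f"unknown relation {rel!r}")
            added.append(cons)
        if added:
            model.add_cons_vars(added)
        model.slim_optimize(error_value=float("nan"))
        status = str(model.solver.status)
        if status != "optimal":
            return FBAResult(status, float("nan"))
        fluxes = pd.Series({r.id: r.flux for r in model.reactions})
        return FBAResult("optimal", float(fluxes[objective]), fluxes)


def _carbon_uptake(m: MetabolicModel, fluxes: pd.Series) -> float:
    return float(sum(max(0.0, -fluxes[rid]) for rid in m.carbon_ids))


def _optimum_with_min_uptake(m: MetabolicModel, objective: str,
                             extras: list) -> tuple[float, float] | None:
    """Maximise ``objective``; break uptake degeneracy at the optimum.

    Returns (optimal objective flux, carbon uptake at the minimal-uptake
    optimum), or None if the primary LP is not optimal.
    """
    res = fba(m, objective, extras)
    if not res.optimal:
        return None
    vstar = res.objective_value
    uptake = _carbon_uptake(m, res.fluxes)
    if uptake <= _UPTAKE_EPS:
        return vstar, 0.0
    # secondary LP: pin the objective flux at its optimum (with a 1e-9
    # feasibility slack), then minimise total carbon uptake. Exchange fluxes
    # are negative for uptake, so maximising their sum minimises uptake.
    pin = [({objective: 1.0}, "ge", vstar - 1e-9)] + extras
    model = m.cobra_model
    with model:
        expr = sum(model.reactions.get_by_id(rid).flux_expression for rid in m.carbon_ids)
        model.objective = model.problem.Objective(expr, direction="max")
        added = []
        for coeffs, rel, value in pin:
            cexpr = sum(c * model.reactions.get_by_id(rid).flux_expression
                        for rid, c in coeffs.items())
            lb = value if rel in ("eq", "ge") else None
            ub = value if rel in ("eq", "le") else None
            added.append(model.problem.Constraint(cexpr, lb=lb, ub=ub))
        model.add_cons_vars(added)
        model.slim_optimize(error_value=float("nan"))
        if str(model.solver.status) == "optimal":
            fluxes = pd.Series({r.id: r.flux for r in model.reactions})
            uptake = _carbon_uptake(m, fluxes)
    return vstar, uptake


def _yield(flux: float, uptake: float) -> float:
    return 0.0 if uptake <= _UPTAKE_EPS else flux / uptake


def compute_flux_features(m: MetabolicModel, spec: ModificationSpec) -> FluxFeatureSet:
    """Run the four-LP procedure on the modified model.

    Infeasibility of the growth LP (step 1) marks the design infeasible with
    zero-filled features. Failures in the later LPs are recorded in
    ``errors`` (with zeroed features for that LP) rather than raised.
    """
    mm = apply_modifications(m, spec)
    errors: list[str] = []

    r1 = _optimum_with_min_uptake(mm, mm.biomass_id, [])
    if r1 is None:
        return FluxFeatureSet(feasible=False, errors=("growth LP not optimal",))
    vb_star, vc_star = r1

    growth_floor = []
    if spec.growth_rate is not None:
        growth_floor = [({mm.biomass_id: 1.0}, "ge", min(spec.growth_rate, vb_star))]

    r2 = _optimum_with_min_uptake(mm, mm.product_id, list(growth_floor))
    if r2 is None:
        errors.append("product LP not optimal")
        vp_star, vc_p = 0.0, 0.0
    else:
        vp_star, vc_p = r2

    r3 = _optimum_with_min_uptake(
        mm, mm.biomass_id,
        [({mm.product_id: 1.0}, "eq", 0.5 * vp_star)] + list(growth_floor))
    if r3 is None:
        errors.append("biomass-at-half-product LP not optimal")
        vb50p, vc50p = 0.0, 0.0
    else:
        vb50p, vc50p = r3

    r4 = _optimum_with_min_uptake(
        mm, mm.product_id,
        [({mm.biomass_id: 1.0}, "eq", 0.5 * vb_star)] + list(growth_floor))
    if r4 is None:
        errors.append("product-at-half-growth LP not optimal")
        vp50b, vc50b = 0.0, 0.0
    else:
        vp50b, vc50b = r4

    return FluxFeatureSet(
        feasible=True,
        vb_star=vb_star, vp_star=vp_star,
        yb_max=_yield(vb_star, vc_star), yp_max=_yield(vp_star, vc_p),
        yb50p=_yield(vb50p, vc50p), yp50b=_yield(vp50b, vc50b),
        vc_star=vc_star, vc_p=vc_p, vc50p=vc50p, vc50b=vc50b,
        errors=tuple(errors),
    )


def spec_from_record(r: DesignRecord, m: MetabolicModel,
                     carbon_exchange_map: Mapping[str, str],
                     default_uptake: float = 10.0) -> ModificationSpec:
    """Translate a design record into model interventions.

    - genes flagged deleted whose ids exist in the model become knockouts;
    - genes flagged overexpressed map (via the GPR rules) to the reactions
      they catalyse, which receive the 10%-of-maximum lower bound;
    - carbon-source names map to exchange ids through
      ``carbon_exchange_map`` (unknown substrates are skipped with a log
      message, as are genes absent from the model — e.g. heterologous genes
      a genome-scale reconstruction does not carry);
    - the record's aeration regime and measured growth rate carry over.
    """
    model_genes = {g.id for g in m.cobra_model.genes}
    knockouts, overexpress = [], []
    for gene, deleted, over in zip(r.gene_mod, r.gene_del, r.gene_ovr):
        if gene not in model_genes:
            logger.debug("record %s: gene %s not in model, skipped", r.record_id, gene)
            continue
        if deleted:
            knockouts.append(gene)
        elif over:
            for rxn in m.cobra_model.genes.get_by_id(gene).reactions:
                if rxn.id not in overexpress:
                    overexpress.append(rxn.id)
    uptake = {}
    for cs in r.carbon_sources:
        rid = carbon_exchange_map.get(cs.name)
        if rid is None:
            logger.debug("record %s: no exchange mapped for substrate %s", r.record_id, cs.name)
            continue
        uptake[rid] = default_uptake
    ko_rxns = set()
    for g in knockouts:
        ko_rxns.update(rx.id for rx in m.cobra_model.genes.get_by_id(g).reactions)
    overexpress = [rid for rid in overexpress if rid not in ko_rxns]
    return ModificationSpec(
        knockouts=tuple(knockouts), overexpress=tuple(overexpress),
        carbon_uptake=uptake, oxygen=r.oxygen, growth_rate=r.bio_grw_rate,
    )


def flux_feature_frame(records: Sequence[DesignRecord], m: MetabolicModel,
                       carbon_exchange_map: Mapping[str, str],
                       default_uptake: float = 10.0) -> pd.DataFrame:
    """Per-record ``cobra_`` feature table; identical specs solved once."""
    cache: dict[tuple, FluxFeatureSet] = {}
    rows = {}
    for r in records:
        spec = spec_from_record(r, m, carbon_exchange_map, default_uptake)
        key = spec.cache_key()
        if key not in cache:
            cache[key] = compute_flux_features(m, spec)
        rows[r.record_id] = cache[key].as_features()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "record_id"
    return df
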