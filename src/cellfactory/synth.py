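"""Synthetic study generator: toy metabolic network + strain-design datasets.

Real curated strain-design databases are assembled by hand from literature;
this module emulates one so the whole pipeline is testable offline:

* :func:`make_toy_model` builds a 13-reaction stoichiometric network
  (substrate -> precursor -> {product, biomass}, with respiratory and
  fermentative ATP branches and gene-reaction rules) whose maximal yields
  have closed forms, standing in for a genome-scale reconstruction at desk
  scale.
* :func:`simulate_designs` samples design records in the 45-field template,
  computes each design's flux features on the toy network, and draws
  ground-truth titer/rate/yield from documented response functions plus
  multiplicative log-normal noise and per-metric missingness. A sidecar
  table with the noise-free targets makes attainable prediction ceilings
  computable exactly.
* :func:`fixture_record` returns the template's worked sample record
  (an isobutanol fed-batch study) used in worked-example tests.

Toy network closed forms (defaults: uptake cap U = 10 mmol glucose/gDW/h,
2 precursors per glucose, 1 product per precursor, biomass = 2 precursor +
2 ATP, respiration 2 ATP per precursor at 3 O2, fermentation 1 ATP):

    vp* = 2U = 20            yp_max = 2          (mol product / mol glucose)
    vb* = 2U/3 (aerobic)     yb_max = 2/3        (ATP precursor overhead 1)
    vb* = 2U/4 (anaerobic)   yb_max = 1/2
    yp50b = yp_max/2,  yb50p = yb_max/2          (single linear resource)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import cobra
from cobra import Metabolite, Reaction

from .flux import MetabolicModel, flux_feature_frame, wrap_model
from .schema import CarbonSource, DesignRecord, write_records

__all__ = [
    "ToyNetworkSpec",
    "SyntheticStudyParams",
    "make_toy_model",
    "toy_analytic_yields",
    "simulate_designs",
    "fixture_record",
    "CARBON_EXCHANGES",
    "TOY_KNOCKOUT_POOL",
]

#: substrate name -> exchange reaction id on the toy model
CARBON_EXCHANGES = {"glucose": "EX_glc", "glycerol": "EX_glyc"}

#: model genes the generator may knock out (with sampling probabilities)
TOY_KNOCKOUT_POOL = {"gF": 0.12, "gR": 0.12, "gP2": 0.10, "gGLY": 0.06, "gSPL": 0.05}

_SUBSTRATES = {
    "glucose": {"mw": 180.0, "c": 6, "h": 12, "o": 6},
    "glycerol": {"mw": 92.0, "c": 3, "h": 8, "o": 3},
}

_BACKGROUND_POOL = (
    "lacI", "ldhA", "adhE", "pta", "poxB", "frdA", "ackA", "pflB",
    "mgsA", "tdcD", "mdh", "ptsG", "zwf", "sthA", "atpFH",
)


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Parameters of the toy network (all fluxes in mmol/gDW/h).

    The elemental bookkeeping (C per metabolite) must balance every internal
    reaction; :func:`make_toy_model` raises on an unbalanced spec.
    """

    uptake_cap: float = 10.0          # glucose uptake bound
    o2_cap: float = 20.0              # aerobic O2 uptake baseline
    split_stoich: float = 2.0         # precursors (C3) per glucose (C6)
    product_per_prec: float = 1.0     # product (C3) per precursor
    biomass_prec: float = 2.0         # precursors per unit growth
    biomass_atp: float = 2.0          # ATP per unit growth
    atp_per_resp: float = 2.0         # ATP per precursor respired
    o2_per_resp: float = 3.0          # O2 per precursor respired
    atp_per_ferm: float = 1.0         # ATP per precursor fermented
    gene_rules: dict = field(default_factory=lambda: {
        "PTS": "gPTS1 and gPTS2",
        "GLYCUP": "gGLY",
        "SPLIT": "gSPL",
        "PRODSYN": "gP1 or gP2",
        "RESP": "gR",
        "FERM": "gF",
    })


def _carbon_check(spec: ToyNetworkSpec) -> None:
    # C3 precursor/product/byproduct, C6 glucose/g6p, C1 co2
    checks = {
        "SPLIT": 6.0 - spec.split_stoich * 3.0,
        "PRODSYN": 3.0 - spec.product_per_prec * 3.0,
        "RESP": 3.0 - spec.o2_per_resp * 1.0,
    }
    bad = {rid: d for rid, d in checks.items() if abs(d) > 1e-9}
    if bad:
        raise ValueError(f"toy network spec is not carbon balanced: {bad}")


def make_toy_model(spec: ToyNetworkSpec | None = None,
                   out_dir: str | Path | None = None) -> MetabolicModel:
    """Build the toy network; optionally write JSON + SBML copies.

    Files (``toy_model.json``, ``toy_model.xml``) are written when
    ``out_dir`` is given.
    """
    spec = spec or ToyNetworkSpec()
    _carbon_check(spec)

    model = cobra.Model("toy_cell_factory")
    mets = {mid: Metabolite(mid, compartment="c", formula=f)
            for mid, f in [
                ("glc_e", "C6H12O6"), ("glyc_e", "C3H8O3"), ("g6p_c", "C6H13O9P"),
                ("prec_c", "C3H4O3"), ("prod_c", "C3H8O"), ("o2_e", "O2"),
                ("co2_e", "CO2"), ("byp_e", "C3H6O3"), ("atp_c", ""),
            ]}

    def rxn(rid, stoich, lb, ub, gpr=""):
        r = Reaction(rid)
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        r.bounds = (lb, ub)
        if gpr:
            r.gene_reaction_rule = gpr
        return r

    g = spec.gene_rules
    cap = 1000.0
    reactions = [
        rxn("EX_glc", {"glc_e": -1}, -spec.uptake_cap, cap),
        rxn("EX_glyc", {"glyc_e": -1}, 0.0, cap),
        rxn("EX_o2", {"o2_e": -1}, -spec.o2_cap, cap),
        rxn("EX_co2", {"co2_e": -1}, 0.0, cap),
        rxn("EX_byp", {"byp_e": -1}, 0.0, cap),
        rxn("EX_prod", {"prod_c": -1}, 0.0, cap),
        rxn("PTS", {"glc_e": -1, "g6p_c": 1}, 0.0, cap, g["PTS"]),
        rxn("GLYCUP", {"glyc_e": -1, "prec_c": 1}, 0.0, cap, g["GLYCUP"]),
        rxn("SPLIT", {"g6p_c": -1, "prec_c": spec.split_stoich}, 0.0, cap, g["SPLIT"]),
        rxn("PRODSYN", {"prec_c": -1, "prod_c": spec.product_per_prec}, 0.0, cap, g["PRODSYN"]),
        rxn("RESP", {"prec_c": -1, "o2_e": -spec.o2_per_resp,
                     "co2_e": spec.o2_per_resp, "atp_c": spec.atp_per_resp}, 0.0, cap, g["RESP"]),
        rxn("FERM", {"prec_c": -1, "byp_e": 1, "atp_c": spec.atp_per_ferm}, 0.0, cap, g["FERM"]),
        rxn("BIOMASS", {"prec_c": -spec.biomass_prec, "atp_c": -spec.biomass_atp}, 0.0, cap),
    ]
    model.add_reactions(reactions)

    wrapped = wrap_model(model, biomass_id="BIOMASS", product_id="EX_prod",
                         carbon_ids=("EX_glc", "EX_glyc"), oxygen_id="EX_o2",
                         default_o2_uptake=spec.o2_cap)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cobra.io.save_json_model(model, str(out / "toy_model.json"))
        cobra.io.write_sbml_model(model, str(out / "toy_model.xml"))
    return wrapped


def toy_analytic_yields(spec: ToyNetworkSpec | None = None) -> dict[str, float]:
    """Closed-form optima of the default-bound toy network (ample O2)."""
    spec = spec or ToyNetworkSpec()
    u, s = spec.uptake_cap, spec.split_stoich
    prec_cost_aerobic = spec.biomass_prec + spec.biomass_atp / spec.atp_per_resp
    prec_cost_anaerobic = spec.biomass_prec + spec.biomass_atp / spec.atp_per_ferm
    vp = u * s * spec.product_per_prec
    vb = u * s / prec_cost_aerobic
    return {
        "vp_max": vp,
        "yp_max": s * spec.product_per_prec,
        "vb_max_aerobic": vb,
        "yb_max_aerobic": s / prec_cost_aerobic,
        "vb_max_anaerobic": u * s / prec_cost_anaerobic,
        "yb_max_anaerobic": s / prec_cost_anaerobic,
        "yp50b": s * spec.product_per_prec / 2.0,
        "yb50p": s / prec_cost_aerobic / 2.0,
    }


# ---------------------------------------------------------------------------
# design-record simulation

@dataclass(frozen=True)
class SyntheticStudyParams:
    """Conditions of the emulated curated study.

    Defaults mirror a literature-curated strain-design database: ~1200
    records over 25 products (native and heterologous), production metrics
    clustered at low and high values with a sparse middle, and substantial
    missingness in the rate/yield fields. ``noise_sd`` is the standard
    deviation of the multiplicative log-normal reporting noise.
    """

    n_records: int = 1200
    n_products: int = 25
    noise_sd: float = 0.1
    missing_titer: float = 0.03
    missing_rate: float = 0.35
    missing_yield1: float = 0.30
    missing_yield2: float = 0.90
    missing_yield3: float = 0.45
    missing_bio: float = 0.40
    titer_saturation: float = 18.0    # g/L scale of product-inhibition roll-off
    rate_peak_titer: float = 8.0      # g/L titer of maximal productivity (mid 6-10 band)
    rate_peak_value: float = 1.0      # g/L/h productivity at the peak
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 50:
            raise ValueError("n_records must be >= 50")
        for f in ("noise_sd", "missing_titer", "missing_rate", "missing_yield1",
                  "missing_yield2", "missing_yield3", "missing_bio"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


#: documented ground-truth response coefficients (logit scale for the
#: process-quality term u; see docs/methods.md)
TRUE_COEFFICIENTS = {
    "intercept": -1.6,
    "mod_path_opt": 2.4,
    "dir_evo": 0.8,
    "oxygen_match": 1.1,
    "media_rich": 0.7,
    "native": 0.5,
    "temp_quadratic": -0.05,   # * (temp - 37)^2
    "n_gene_ovr": 0.25,        # per overexpressed native (non-heterologous) gene
    "growth_factor_floor": 0.25,  # h = floor + (1-floor) * yb_max / yb_ref
    "yb_ref": 2.0 / 3.0,
    # volumetric-productivity process factor q: continuous operation sustains
    # the highest rates, fed-batch intermediate; rich media boost rates
    "rate_reactor": {"batch": 1.0, "fed-batch": 1.3, "continuous": 1.7},
    "rate_media_rich": 0.25,   # log-scale bump for rich media
}

_RICH_MEDIA = {"LB", "TB", "M9+YE", "other rich media"}
_OXYGEN_LEVELS = ("anaerobic", "microaerobic", "aerobic", "extra-aerobic")


def _product_catalog(n_products: int, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(n_products):
        native = bool(rng.random() < 0.4)
        c = int(rng.integers(2, 8))
        h = int(rng.integers(4, 2 * c + 3))
        o = int(rng.integers(0, 4))
        n = int(rng.random() < 0.15)
        rows.append({
            "prod_name": f"prod_{i:02d}",
            "native": native,
            "no_C": c, "no_H": h, "no_O": o, "no_N": n,
            "mw": 12 * c + h + 16 * o + 14 * n,
            "precursor": str(rng.integers(1, 7)),
            "enz_steps": int(rng.integers(1, 6) if native else rng.integers(4, 13)),
            "atp_cost": int(rng.integers(0, 5)),
            "na_cost": int(rng.integers(0, 5)),
            "preferred_oxygen": _OXYGEN_LEVELS[rng.integers(0, 4)],
            "het_genes": () if native else tuple(f"het_{i:02d}_{k}" for k in range(rng.integers(1, 4))),
        })
    return pd.DataFrame(rows)


def _draw_record(i: int, prod: pd.Series, rng: np.random.Generator) -> tuple[DesignRecord, dict]:
    """Sample one design; returns the (metric-less) record and its latent draws."""
    good = bool(rng.random() < 0.5)  # bimodal design-quality mixture
    mod_path_opt = int(rng.random() < (0.85 if good else 0.10))
    dir_evo = int(rng.random() < (0.30 if good else 0.05))
    oxygen = (prod.preferred_oxygen if rng.random() < (0.85 if good else 0.35)
              else _OXYGEN_LEVELS[rng.integers(0, 4)])
    media = (str(rng.choice(["LB", "TB", "M9+YE"])) if (good and rng.random() < 0.7)
             else str(rng.choice(["M9", "AM1", "AM2", "NBS", "LB", "other rich media"])))
    temp = float(np.round(np.clip(rng.normal(37.0, 2.5), 25.0, 42.0), 1))
    reactor_type = str(rng.choice(["batch", "fed-batch", "continuous"], p=[0.6, 0.3, 0.1]))
    time = float(np.round(np.clip(np.exp(rng.normal(np.log(36.0), 0.4)), 6.0, 120.0), 1))

    sources = [("glucose" if rng.random() < 0.8 else "glycerol",
                float(np.round(rng.uniform(50, 200), 1)))]
    if rng.random() < 0.05:
        other = "glycerol" if sources[0][0] == "glucose" else "glucose"
        sources.append((other, float(np.round(rng.uniform(20, 100), 1))))
    carbon_sources = tuple(
        CarbonSource(name=nm, mw=_SUBSTRATES[nm]["mw"], conc_mm=conc,
                     c=_SUBSTRATES[nm]["c"], h=_SUBSTRATES[nm]["h"],
                     o=_SUBSTRATES[nm]["o"])
        for nm, conc in sources)

    knockouts = [gid for gid, p in TOY_KNOCKOUT_POOL.items() if rng.random() < p]
    over = []
    if rng.random() < 0.5:
        over.append("gP1")
    if rng.random() < 0.2:
        over.append("gSPL")
    over = [gg for gg in over if gg not in knockouts]

    genes = knockouts + over + list(prod.het_genes)
    gene_del = [1] * len(knockouts) + [0] * (len(over) + len(prod.het_genes))
    gene_ovr = [0] * len(knockouts) + [1] * (len(over) + len(prod.het_genes))
    het = [0] * (len(knockouts) + len(over)) + [1] * len(prod.het_genes)
    rep = [0.0] * len(knockouts) + [float(rng.choice([1, 5, 10]))
                                    for _ in range(len(over) + len(prod.het_genes))]
    codon = [0] * (len(knockouts) + len(over)) + [int(rng.random() < 0.3)
                                                  for _ in prod.het_genes]
    zeros = [0] * len(genes)

    n_bg = int(rng.integers(0, 7))
    bg = tuple(str(g) for g in rng.choice(_BACKGROUND_POOL, size=n_bg, replace=False)) if n_bg else ()
    bg_ins = tuple(int(rng.random() < 0.2) for _ in bg)

    rec = DesignRecord(
        record_id=f"synth{i:05d}",
        carbon_sources=carbon_sources,
        reactor_type=reactor_type,
        rxt_volume=float(rng.choice([0.05, 0.25, 1.0, 2.0, 5.0])),
        media=media, temp=temp, time=time, oxygen=oxygen,
        sbg_ref=f"strain_{rng.integers(1, 40):02d}",
        background_genes=bg, background_ins=bg_ins,
        gene_mod=tuple(genes), gene_del=tuple(gene_del), gene_ovr=tuple(gene_ovr),
        het_gene=tuple(het), rep_origin=tuple(rep), codon_opt=tuple(codon),
        sen_reg=tuple(int(rng.random() < 0.05) for _ in genes),
        enz_design=tuple(int(rng.random() < 0.05) for _ in genes),
        protein_scaffold=tuple(int(rng.random() < 0.03) for _ in genes),
        dir_evo=dir_evo, mod_path_opt=mod_path_opt,
        prod_name=prod.prod_name, no_C=float(prod.no_C), no_H=float(prod.no_H),
        no_O=float(prod.no_O), no_N=float(prod.no_N), mw=float(prod.mw),
        precursor=prod.precursor, enz_steps=float(prod.enz_steps),
        atp_cost=float(prod.atp_cost), na_cost=float(prod.na_cost),
        bio_grw_rate=float(np.round(rng.uniform(0.05, 0.65), 2)),
        titer=None, gen_info=1, env_info=1,
    )
    latent = {"good": good, "oxygen_match": float(oxygen == prod.preferred_oxygen),
              "media_rich": float(media in _RICH_MEDIA), "native": float(prod.native)}
    return rec, latent


def simulate_designs(params: SyntheticStudyParams | None = None,
                     model: MetabolicModel | None = None,
                     out_dir: str | Path | None = None,
                     ) -> tuple[list[DesignRecord], pd.DataFrame, dict]:
    """Generate a synthetic curated dataset in the 45-field template.

    Ground-truth targets (documented closed forms, coefficients in
    ``TRUE_COEFFICIENTS``):

    - process quality  u = sigmoid(linear score of design factors), drawn
      bimodal through a good/poor design mixture;
    - growth factor    h from the design's FBA maximum biomass yield;
    - yield (g/g fed)  = yp_max_gg * u * h, with yp_max_gg the FBA maximum
      product yield converted to grams;
    - titer (g/L)      = Tmax * tanh(yield * substrate_fed / Tmax)
      (saturating product inhibition);
    - rate (g/L/h)     = peak_value * (titer/titer_peak) *
      exp(1 - titer/titer_peak) * q, a concave link of titer maximal at
      mid-range titers, scaled by the process factor q (reactor mode and
      media richness).

    Reported metrics are the truths times log-normal noise, thinned by
    per-metric missingness. Returns ``(records, sidecar, truth)`` where the
    sidecar holds the noise-free targets; with ``out_dir`` also writes
    ``designs.tsv``, ``ground_truth.tsv`` and ``coefficients.json``.
    """
    params = params or SyntheticStudyParams()
    model = model or make_toy_model()
    rng = np.random.default_rng(params.seed)
    catalog = _product_catalog(params.n_products, rng)

    drafts, latents = [], []
    for i in range(params.n_records):
        prod = catalog.iloc[int(rng.integers(0, len(catalog)))]
        rec, latent = _draw_record(i, prod, rng)
        drafts.append(rec)
        latents.append(latent)

    flux = flux_feature_frame(drafts, model, CARBON_EXCHANGES)
    coef = TRUE_COEFFICIENTS

    records: list[DesignRecord] = []
    side_rows = []
    for rec, latent in zip(drafts, latents):
        fx = flux.loc[rec.record_id]
        mw_cs = float(np.average(
            [cs.mw for cs in rec.carbon_sources],
            weights=[cs.conc_mm for cs in rec.carbon_sources]))
        fed = sum(cs.conc_mm * cs.mw / 1000.0 for cs in rec.carbon_sources)  # g/L

        score = (coef["intercept"]
                 + coef["mod_path_opt"] * rec.mod_path_opt
                 + coef["dir_evo"] * rec.dir_evo
                 + coef["oxygen_match"] * latent["oxygen_match"]
                 + coef["media_rich"] * latent["media_rich"]
                 + coef["native"] * latent["native"]
                 + coef["temp_quadratic"] * (rec.temp - 37.0) ** 2
                 + coef["n_gene_ovr"] * sum(
                     o for o, het in zip(rec.gene_ovr, rec.het_gene) if not het))
        u = 1.0 / (1.0 + np.exp(-score))
        floor = coef["growth_factor_floor"]
        h = floor + (1 - floor) * min(1.0, fx["cobra_yb_max"] / coef["yb_ref"])
        yp_max_gg = fx["cobra_yp_max"] * rec.mw / mw_cs
        yield_true = yp_max_gg * u * h
        tmax = params.titer_saturation
        titer_true = tmax * np.tanh(yield_true * fed / tmax)
        # maximum productivity: concave link of titer (rising to the
        # mid-range peak, depressed at high titer by product inhibition and
        # the carbon/energy trade-off) scaled by an observable process
        # factor q (reactor operation mode, media richness)
        tp = params.rate_peak_titer
        q = coef["rate_reactor"][rec.reactor_type] \
            * np.exp(coef["rate_media_rich"] * latent["media_rich"])
        rate_true = params.rate_peak_value * (titer_true / tp) \
            * np.exp(1.0 - titer_true / tp) * q

        def noisy(x):
            return float(x * np.exp(rng.normal(0.0, params.noise_sd)))

        bio_titre = float(np.round(rng.uniform(0.8, 5.0) * (0.3 + 0.7 * h), 3))
        titer = noisy(titer_true)
        vals = {
            "titer": None if rng.random() < params.missing_titer else round(titer, 4),
            "rate": None if rng.random() < params.missing_rate else round(noisy(rate_true), 5),
            "yield_1": None if rng.random() < params.missing_yield1 else round(noisy(yield_true), 5),
        }
        yield_2 = vals["yield_1"] * rng.uniform(1.05, 1.3) if vals["yield_1"] is not None else None
        vals["yield_2"] = None if (yield_2 is None or rng.random() < params.missing_yield2) \
            else round(yield_2, 5)
        vals["yield_3"] = None if rng.random() < params.missing_yield3 \
            else round(titer / bio_titre, 5)
        if all(v is None for v in vals.values()):
            vals["titer"] = round(titer, 4)  # template requires >= 1 metric
        keep_bio = rng.random() >= params.missing_bio
        rec = DesignRecord(**{
            **rec.__dict__, **vals,
            "bio_titre": bio_titre if keep_bio else None,
            "bio_grw_rate": rec.bio_grw_rate if keep_bio else None,
        })
        records.append(rec)
        side_rows.append({
            "record_id": rec.record_id, "titer_true": titer_true,
            "rate_true": rate_true, "yield_true": yield_true,
            "u": u, "h": h, "good": latent["good"],
            "native": latent["native"], "yp_max": fx["cobra_yp_max"],
            "yb_max": fx["cobra_yb_max"], "feasible": fx["cobra_feasible"],
        })

    sidecar = pd.DataFrame(side_rows).set_index("record_id")
    truth = {"coefficients": dict(coef), "params": params.__dict__.copy()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(records, out / "designs.tsv")
        sidecar.to_csv(out / "ground_truth.tsv", sep="\t")
        with open(out / "coefficients.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return records, sidecar, truth


def fixture_record() -> DesignRecord:
    """The template's worked sample record (isobutanol fed from glucose)."""
    return DesignRecord(
        record_id="table1_sample",
        carbon_sources=(CarbonSource("glucose", mw=180.0, conc_mm=111.0,
                                     c=6.0, h=12.0, o=6.0),),
        reactor_type="batch", rxt_volume=2.0, media="other rich media",
        temp=37.0, time=36.0, oxygen="microaerobic",
        sbg_ref="BFA7.001(DE3) PCT01",
        background_genes=("lacI", "rrnB", "lacZ", "hsdR514", "araBAD", "rhaBAD",
                          "zwf", "mdh", "frdA", "ndh", "pta", "poxB", "ldhA",
                          "T7 RNA polymerase"),
        background_ins=(0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1),
        gene_mod=("alsS", "ilvC", "ilvD"),
        gene_del=(0, 0, 0), gene_ovr=(1, 1, 1), het_gene=(1, 0, 0),
        rep_origin=(5.0, 5.0, 5.0), codon_opt=(0, 0, 0), sen_reg=(0, 0, 0),
        enz_design=(0, 0, 0), protein_scaffold=(0, 0, 0),
        dir_evo=0, mod_path_opt=0,
        prod_name="Isobutanol", no_C=4.0, no_H=10.0, no_O=1.0, no_N=0.0,
        mw=74.0, precursor="6", enz_steps=5.0, atp_cost=0.0, na_cost=2.0,
        yield_1=0.0405, yield_2=None, yield_3=0.623, titer=0.81, rate=0.0225,
        bio_titre=1.3, bio_grw_rate=0.45, gen_info=1, env_info=1,
    )
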