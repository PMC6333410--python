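"""Strain-design record template: validation, I/O, derived metrics, encoding.

A metabolic-engineering design record captures one experimentally realised
cell factory in six blocks: carbon source(s), bioprocess conditions, genetic
modifications, product characterisation, production metrics (titer, rate,
yield — "TRY"), and completeness flags. Gene-level fields are parallel lists:
``gene_mod`` names the modified genes and ``gene_del`` / ``gene_ovr`` /
``het_gene`` / ... carry one 0/1 flag (or copy number, for ``rep_origin``)
per gene, serialised as comma-joined cells inside the delimited file.

The canonical template has 45 named columns (one carbon-source block);
records with two or three carbon sources use the optional ``cs2*`` / ``cs3*``
column blocks. A machine-readable copy of the template ships as
``cellfactory/data/template_schema.json``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "CarbonSource",
    "DesignRecord",
    "FeatureMatrix",
    "Rejection",
    "SchemaError",
    "read_records",
    "write_records",
    "records_to_frame",
    "derive_metrics",
    "validate_record",
    "targets_frame",
    "StrainDesignEncoder",
    "encode_features",
    "template_columns",
    "load_template_schema",
]

# Integer atomic masses reproduce the template's printed molecular weights
# (e.g. C4H10O -> 74) exactly.
ATOMIC_MASS = {"C": 12.0, "H": 1.0, "O": 16.0, "N": 14.0}

REACTOR_TYPES = ("batch", "fed-batch", "continuous")
REACTOR_CODES = {"1": "batch", "2": "fed-batch", "3": "continuous"}

OXYGEN_LEVELS = ("anaerobic", "microaerobic", "aerobic", "extra-aerobic")
OXYGEN_CODES = {"1": "anaerobic", "2": "microaerobic", "3": "aerobic", "4": "extra-aerobic"}

MEDIA_CATEGORIES = (
    "M9", "AM1", "AM2", "M9+YE", "LB", "NBS", "TB", "other rich media",
)
_MEDIA_ALIASES = {
    "m9": "M9", "am1": "AM1", "am2": "AM2",
    "m9+ye": "M9+YE", "m9 + yeast extract": "M9+YE", "m9+ yeast extract": "M9+YE",
    "lb": "LB", "nbs": "NBS", "tb": "TB",
    "other rich media": "other rich media",
}

METRIC_FIELDS = ("yield_1", "yield_2", "yield_3", "titer", "rate", "bio_titre", "bio_grw_rate")

# Gene-parallel flag fields (same length as gene_mod).
GENE_FLAG_FIELDS = ("gene_del", "gene_ovr", "het_gene", "rep_origin",
                    "codon_opt", "sen_reg", "enz_design", "protein_scaffold")

_CS_BLOCK = ("cs{i}", "cs{i}_mw", "cs_conc{i}", "CS_C{i}", "CS_H{i}", "CS_O{i}")

CORE_COLUMNS = (
    [c.format(i=1) for c in _CS_BLOCK]
    + ["reactor_type", "rxt_volume", "media", "temp", "time", "oxygen",
       "sbg_ref", "s_ref_gen", "s_gen_mod",
       "gene_mod", "gene_del", "gene_ovr", "het_gene", "rep_origin",
       "codon_opt", "sen_reg", "enz_design", "protein_scaffold",
       "dir_evo", "mod_path_opt",
       "prod_name", "no_C", "no_H", "no_O", "no_N", "mw",
       "precursor", "enz_steps", "atp_cost", "na_cost",
       "yield_1", "yield_2", "yield_3", "titer", "rate",
       "bio_titre", "bio_grw_rate", "gen_info", "env_info"]
)

OPTIONAL_COLUMNS = [c.format(i=i) for i in (2, 3) for c in _CS_BLOCK]


def template_columns(n_carbon_sources: int = 3) -> list[str]:
    """Column names of the on-disk template (``record_id`` prepended)."""
    cols = ["record_id"] + list(CORE_COLUMNS)
    for i in range(2, n_carbon_sources + 1):
        cols += [c.format(i=i) for c in _CS_BLOCK]
    return cols


def load_template_schema() -> dict:
    """Machine-readable template schema shipped with the package."""
    with resources.files("cellfactory.data").joinpath("template_schema.json").open() as fh:
        return json.load(fh)


class SchemaError(ValueError):
    """Input file does not follow the design-record template."""


@dataclass(frozen=True)
class Rejection:
    """A row that could not become a valid record, with the reason."""

    record_id: str
    reason: str


@dataclass(frozen=True)
class CarbonSource:
    name: str
    mw: float | None = None          # g/mol
    conc_mm: float | None = None     # mM
    c: float | None = None           # mol C per molecule
    h: float | None = None
    o: float | None = None


@dataclass(frozen=True)
class DesignRecord:
    """One experimentally realised cell factory (45-field template)."""

    record_id: str
    carbon_sources: tuple[CarbonSource, ...] = ()
    # bioprocess
    reactor_type: str | None = None
    rxt_volume: float | None = None   # L
    media: str | None = None
    temp: float | None = None         # degC
    time: float | None = None         # h
    oxygen: str | None = None
    # genetic background
    sbg_ref: str | None = None
    background_genes: tuple[str, ...] = ()
    background_ins: tuple[int, ...] = ()      # 1 = insertion, 0 = deletion
    # design modifications (gene-parallel)
    gene_mod: tuple[str, ...] = ()
    gene_del: tuple[int, ...] = ()
    gene_ovr: tuple[int, ...] = ()
    het_gene: tuple[int, ...] = ()
    rep_origin: tuple[float, ...] = ()        # plasmid copy numbers
    codon_opt: tuple[int, ...] = ()
    sen_reg: tuple[int, ...] = ()
    enz_design: tuple[int, ...] = ()
    protein_scaffold: tuple[int, ...] = ()
    dir_evo: int | None = None
    mod_path_opt: int | None = None
    # product
    prod_name: str | None = None
    no_C: float | None = None
    no_H: float | None = None
    no_O: float | None = None
    no_N: float | None = None
    mw: float | None = None           # g/mol
    precursor: str | None = None      # central-metabolism precursor code
    enz_steps: float | None = None
    atp_cost: float | None = None
    na_cost: float | None = None
    # production metrics (nullable)
    yield_1: float | None = None      # g product / g substrate fed
    yield_2: float | None = None      # g product / g substrate consumed
    yield_3: float | None = None      # g product / g biomass
    titer: float | None = None        # g/L
    rate: float | None = None         # g/L/h
    bio_titre: float | None = None    # g/L
    bio_grw_rate: float | None = None # 1/h
    # completeness flags
    gen_info: int | None = None
    env_info: int | None = None
    # provenance: metric fields filled by derive_metrics rather than reported
    estimated: frozenset = frozenset()


NONNEG_FIELDS = ("rxt_volume", "time", "mw", "no_C", "no_H", "no_O", "no_N",
                 "enz_steps", "atp_cost", "na_cost") + METRIC_FIELDS


def validate_record(r: DesignRecord) -> list[str]:
    """Return the list of invariant violations (empty = valid)."""
    problems: list[str] = []
    n = len(r.gene_mod)
    for f in GENE_FLAG_FIELDS:
        vals = getattr(r, f)
        if len(vals) != n:
            problems.append(f"{f} length {len(vals)} != gene_mod length {n}")
    if len(r.background_ins) not in (0, len(r.background_genes)):
        problems.append("s_gen_mod length mismatch with s_ref_gen")
    for f in NONNEG_FIELDS:
        v = getattr(r, f)
        if v is not None and v < 0:
            problems.append(f"{f} negative ({v})")
    for cs in r.carbon_sources:
        for f in ("mw", "conc_mm", "c", "h", "o"):
            v = getattr(cs, f)
            if v is not None and v < 0:
                problems.append(f"carbon source {cs.name}: {f} negative")
    if r.reactor_type is not None and r.reactor_type not in REACTOR_TYPES:
        problems.append(f"reactor_type {r.reactor_type!r} not in {REACTOR_TYPES}")
    if r.oxygen is not None and r.oxygen not in OXYGEN_LEVELS:
        problems.append(f"oxygen {r.oxygen!r} not in {OXYGEN_LEVELS}")
    if r.media is not None and r.media not in MEDIA_CATEGORIES:
        problems.append(f"media {r.media!r} not a template category")
    if all(getattr(r, m) is None for m in ("titer", "rate", "yield_1", "yield_2", "yield_3")):
        problems.append("no production metric reported (need one of titer/rate/yield)")
    return problems


# ---------------------------------------------------------------------------
# parsing helpers

def _is_na(cell) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    s = str(cell).strip()
    return s == "" or s.upper() in {"NA", "NAN", "NONE", "NULL"}


def _float(cell, col: str) -> float | None:
    if _is_na(cell):
        return None
    try:
        return float(str(cell).strip())
    except ValueError as exc:
        raise ValueError(f"unparseable numeric cell {cell!r} in column {col}") from exc


def _int01(cell, col: str) -> int | None:
    v = _float(cell, col)
    if v is None:
        return None
    if v not in (0.0, 1.0):
        raise ValueError(f"flag column {col} must be 0/1, got {cell!r}")
    return int(v)


def _split_list(cell) -> list[str]:
    if _is_na(cell):
        return []
    return [tok.strip() for tok in str(cell).split(",") if tok.strip() != ""]


def _flag_list(cell, col: str) -> tuple[int, ...]:
    out = []
    for tok in _split_list(cell):
        try:
            v = float(tok)
        except ValueError as exc:
            raise ValueError(f"unparseable entry {tok!r} in list column {col}") from exc
        if v not in (0.0, 1.0):
            raise ValueError(f"list column {col} entries must be 0/1, got {tok!r}")
        out.append(int(v))
    return tuple(out)


def _num_list(cell, col: str) -> tuple[float, ...]:
    out = []
    for tok in _split_list(cell):
        try:
            out.append(float(tok))
        except ValueError as exc:
            raise ValueError(f"unparseable entry {tok!r} in list column {col}") from exc
    return tuple(out)


def _reactor(cell) -> str | None:
    if _is_na(cell):
        return None
    s = str(cell).strip().lower()
    s = REACTOR_CODES.get(s.rstrip(".0") if s.replace(".", "").isdigit() else s, s)
    if s in ("fedbatch", "fed batch"):
        s = "fed-batch"
    return s


def _oxygen(cell) -> str | None:
    if _is_na(cell):
        return None
    s = str(cell).strip().lower()
    if s.replace(".", "").isdigit():
        return OXYGEN_CODES.get(str(int(float(s))), s)
    s = s.replace("extra aerobic", "extra-aerobic")
    return s


def _media(cell) -> str | None:
    """Map free-text media to the 8 template categories.

    Unrecognised strings (e.g. undefined rich media) fall back to
    "other rich media".
    """
    if _is_na(cell):
        return None
    return _MEDIA_ALIASES.get(str(cell).strip().lower(), "other rich media")


def _row_to_record(row: pd.Series, record_id: str) -> DesignRecord:
    sources = []
    for i in (1, 2, 3):
        name_col = f"cs{i}"
        if name_col not in row.index or _is_na(row.get(name_col)):
            continue
        sources.append(CarbonSource(
            name=str(row[name_col]).strip(),
            mw=_float(row.get(f"cs{i}_mw"), f"cs{i}_mw"),
            conc_mm=_float(row.get(f"cs_conc{i}"), f"cs_conc{i}"),
            c=_float(row.get(f"CS_C{i}"), f"CS_C{i}"),
            h=_float(row.get(f"CS_H{i}"), f"CS_H{i}"),
            o=_float(row.get(f"CS_O{i}"), f"CS_O{i}"),
        ))
    return DesignRecord(
        record_id=record_id,
        carbon_sources=tuple(sources),
        reactor_type=_reactor(row.get("reactor_type")),
        rxt_volume=_float(row.get("rxt_volume"), "rxt_volume"),
        media=_media(row.get("media")),
        temp=_float(row.get("temp"), "temp"),
        time=_float(row.get("time"), "time"),
        oxygen=_oxygen(row.get("oxygen")),
        sbg_ref=None if _is_na(row.get("sbg_ref")) else str(row["sbg_ref"]).strip(),
        background_genes=tuple(_split_list(row.get("s_ref_gen"))),
        background_ins=_flag_list(row.get("s_gen_mod"), "s_gen_mod"),
        gene_mod=tuple(_split_list(row.get("gene_mod"))),
        gene_del=_flag_list(row.get("gene_del"), "gene_del"),
        gene_ovr=_flag_list(row.get("gene_ovr"), "gene_ovr"),
        het_gene=_flag_list(row.get("het_gene"), "het_gene"),
        rep_origin=_num_list(row.get("rep_origin"), "rep_origin"),
        codon_opt=_flag_list(row.get("codon_opt"), "codon_opt"),
        sen_reg=_flag_list(row.get("sen_reg"), "sen_reg"),
        enz_design=_flag_list(row.get("enz_design"), "enz_design"),
        protein_scaffold=_flag_list(row.get("protein_scaffold"), "protein_scaffold"),
        dir_evo=_int01(row.get("dir_evo"), "dir_evo"),
        mod_path_opt=_int01(row.get("mod_path_opt"), "mod_path_opt"),
        prod_name=None if _is_na(row.get("prod_name")) else str(row["prod_name"]).strip(),
        no_C=_float(row.get("no_C"), "no_C"),
        no_H=_float(row.get("no_H"), "no_H"),
        no_O=_float(row.get("no_O"), "no_O"),
        no_N=_float(row.get("no_N"), "no_N"),
        mw=_float(row.get("mw"), "mw"),
        precursor=None if _is_na(row.get("precursor")) else str(row["precursor"]).strip(),
        enz_steps=_float(row.get("enz_steps"), "enz_steps"),
        atp_cost=_float(row.get("atp_cost"), "atp_cost"),
        na_cost=_float(row.get("na_cost"), "na_cost"),
        yield_1=_float(row.get("yield_1"), "yield_1"),
        yield_2=_float(row.get("yield_2"), "yield_2"),
        yield_3=_float(row.get("yield_3"), "yield_3"),
        titer=_float(row.get("titer"), "titer"),
        rate=_float(row.get("rate"), "rate"),
        bio_titre=_float(row.get("bio_titre"), "bio_titre"),
        bio_grw_rate=_float(row.get("bio_grw_rate"), "bio_grw_rate"),
        gen_info=_int01(row.get("gen_info"), "gen_info"),
        env_info=_int01(row.get("env_info"), "env_info"),
    )


def read_records(path, sep: str | None = None) -> tuple[list[DesignRecord], list[Rejection]]:
    """Read template-format TSV/CSV into records.

    Header must contain the 45 core template columns (order-insensitive);
    ``record_id`` and the carbon-source-2/3 blocks are optional. Rows that
    fail to parse or violate record invariants are returned as
    :class:`Rejection` entries, never raised.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = set(CORE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory template columns: {sorted(missing)}")
    records: list[DesignRecord] = []
    rejections: list[Rejection] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        rid = str(row["record_id"]) if "record_id" in df.columns and not _is_na(row.get("record_id")) else f"row{pos}"
        try:
            rec = _row_to_record(row, rid)
        except ValueError as exc:
            rejections.append(Rejection(rid, str(exc)))
            continue
        problems = validate_record(rec)
        if problems:
            rejections.append(Rejection(rid, "; ".join(problems)))
        else:
            records.append(rec)
    return records, rejections


def _join(vals: Sequence) -> str:
    return ",".join(_fmt(v) for v in vals)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float) and float(v).is_integer():
        return str(int(v))
    return str(v)


def records_to_frame(records: Iterable[DesignRecord]) -> pd.DataFrame:
    """Serialise records into the on-disk template layout."""
    rows = []
    for r in records:
        row: dict[str, str] = {"record_id": r.record_id}
        for i in (1, 2, 3):
            cs = r.carbon_sources[i - 1] if len(r.carbon_sources) >= i else None
            row[f"cs{i}"] = cs.name if cs else ""
            row[f"cs{i}_mw"] = _fmt(cs.mw) if cs else ""
            row[f"cs_conc{i}"] = _fmt(cs.conc_mm) if cs else ""
            row[f"CS_C{i}"] = _fmt(cs.c) if cs else ""
            row[f"CS_H{i}"] = _fmt(cs.h) if cs else ""
            row[f"CS_O{i}"] = _fmt(cs.o) if cs else ""
        row.update(
            reactor_type=_fmt(r.reactor_type), rxt_volume=_fmt(r.rxt_volume),
            media=_fmt(r.media), temp=_fmt(r.temp), time=_fmt(r.time),
            oxygen=_fmt(r.oxygen), sbg_ref=_fmt(r.sbg_ref),
            s_ref_gen=_join(r.background_genes), s_gen_mod=_join(r.background_ins),
            gene_mod=_join(r.gene_mod), gene_del=_join(r.gene_del),
            gene_ovr=_join(r.gene_ovr), het_gene=_join(r.het_gene),
            rep_origin=_join(r.rep_origin), codon_opt=_join(r.codon_opt),
            sen_reg=_join(r.sen_reg), enz_design=_join(r.enz_design),
            protein_scaffold=_join(r.protein_scaffold),
            dir_evo=_fmt(r.dir_evo), mod_path_opt=_fmt(r.mod_path_opt),
            prod_name=_fmt(r.prod_name), no_C=_fmt(r.no_C), no_H=_fmt(r.no_H),
            no_O=_fmt(r.no_O), no_N=_fmt(r.no_N), mw=_fmt(r.mw),
            precursor=_fmt(r.precursor), enz_steps=_fmt(r.enz_steps),
            atp_cost=_fmt(r.atp_cost), na_cost=_fmt(r.na_cost),
            yield_1=_fmt(r.yield_1), yield_2=_fmt(r.yield_2), yield_3=_fmt(r.yield_3),
            titer=_fmt(r.titer), rate=_fmt(r.rate), bio_titre=_fmt(r.bio_titre),
            bio_grw_rate=_fmt(r.bio_grw_rate), gen_info=_fmt(r.gen_info),
            env_info=_fmt(r.env_info),
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=template_columns())


def write_records(records: Iterable[DesignRecord], path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# derived metrics

def derive_metrics(r: DesignRecord) -> DesignRecord:
    """Fill derivable null metrics; never overwrite reported values.

    - yield_1 (g/g fed)   = titer / sum_i(conc_i[mM] * mw_i / 1000)
    - yield_3 (g/g X)     = titer / bio_titre
    - rate (g/L/h)        = titer / time  (an *average* productivity; the
      template's reported rate is a maximum, so derived values are flagged
      in ``estimated``)
    - product mw          = 12 C + 1 H + 16 O + 14 N

    Zero denominators leave the field null with a logged warning. The
    operation is idempotent.
    """
    updates: dict = {}
    est = set(r.estimated)

    if r.mw is None and None not in (r.no_C, r.no_H, r.no_O, r.no_N):
        updates["mw"] = (ATOMIC_MASS["C"] * r.no_C + ATOMIC_MASS["H"] * r.no_H
                         + ATOMIC_MASS["O"] * r.no_O + ATOMIC_MASS["N"] * r.no_N)
        est.add("mw")

    if r.titer is not None:
        if r.yield_1 is None and r.carbon_sources:
            concs = [(cs.conc_mm, cs.mw) for cs in r.carbon_sources]
            if all(c is not None and m is not None for c, m in concs):
                fed = sum(c * m / 1000.0 for c, m in concs)  # g/L substrate fed
                if fed > 0:
                    updates["yield_1"] = r.titer / fed
                    est.add("yield_1")
                else:
                    logger.warning("record %s: zero substrate fed, yield_1 left null", r.record_id)
        if r.yield_3 is None and r.bio_titre is not None:
            if r.bio_titre > 0:
                updates["yield_3"] = r.titer / r.bio_titre
                est.add("yield_3")
            else:
                logger.warning("record %s: zero biomass titer, yield_3 left null", r.record_id)
        if r.rate is None and r.time is not None:
            if r.time > 0:
                updates["rate"] = r.titer / r.time
                est.add("rate")
            else:
                logger.warning("record %s: zero fermentation time, rate left null", r.record_id)

    if not updates:
        return r
    return replace(r, estimated=frozenset(est), **updates)


def targets_frame(records: Sequence[DesignRecord]) -> pd.DataFrame:
    """Production-metric table (one row per record) with provenance flags."""
    rows = {}
    for r in records:
        row = {m: getattr(r, m) for m in METRIC_FIELDS}
        row.update({f"{m}_estimated": (m in r.estimated) for m in METRIC_FIELDS})
        row["prod_name"] = r.prod_name
        rows[r.record_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "record_id"
    for m in METRIC_FIELDS:
        df[m] = pd.to_numeric(df[m])
    return df


# ---------------------------------------------------------------------------
# feature encoding

@dataclass
class FeatureMatrix:
    """Dense numeric design matrix plus per-column role metadata.

    Roles are ``continuous``, ``categorical`` (0/1 indicator) or ``cobra``
    (flux-derived feature appended later).
    """

    frame: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.frame.columns if self.roles.get(c) == role]

    @property
    def continuous_columns(self) -> list[str]:
        return self.columns_with_role("continuous")

    @property
    def categorical_columns(self) -> list[str]:
        return self.columns_with_role("categorical")

    @property
    def cobra_columns(self) -> list[str]:
        return self.columns_with_role("cobra")

    def with_cobra(self, cobra_frame: pd.DataFrame) -> "FeatureMatrix":
        """Append flux-derived columns (must be prefixed ``cobra_``)."""
        bad = [c for c in cobra_frame.columns if not c.startswith("cobra_")]
        if bad:
            raise ValueError(f"cobra feature columns must be prefixed 'cobra_': {bad}")
        frame = self.frame.join(cobra_frame, how="left")
        if frame[cobra_frame.columns].isna().any().any():
            raise ValueError("cobra features missing for some records")
        roles = dict(self.roles, **{c: "cobra" for c in cobra_frame.columns})
        return FeatureMatrix(frame, roles)

    def drop_cobra(self) -> "FeatureMatrix":
        keep = [c for c in self.frame.columns if self.roles.get(c) != "cobra"]
        return FeatureMatrix(self.frame[keep].copy(),
                             {c: r for c, r in self.roles.items() if r != "cobra"})


_CONT_RECORD_FIELDS = ("rxt_volume", "temp", "time", "no_C", "no_H", "no_O",
                       "no_N", "mw", "enz_steps", "atp_cost", "na_cost")
_FLAG_RECORD_FIELDS = ("dir_evo", "mod_path_opt", "gen_info", "env_info")
_CAT_RECORD_FIELDS = ("reactor_type", "media", "oxygen", "precursor", "prod_name")


def _aggregate_row(r: DesignRecord) -> dict[str, float]:
    """Numeric feature dict for one record (before imputation/indicators)."""
    row: dict[str, float] = {}
    for i in (1, 2, 3):
        cs = r.carbon_sources[i - 1] if len(r.carbon_sources) >= i else None
        # absent carbon sources contribute zeros, present-but-unreported
        # numeric fields stay NaN for imputation
        for suffix, attr in (("mw", "mw"), ("conc", "conc_mm"), ("C", "c"),
                             ("H", "h"), ("O", "o")):
            val = getattr(cs, attr) if cs is not None else 0.0
            row[f"cs{i}_{suffix}"] = np.nan if (cs is not None and val is None) else float(val)
    for f in _CONT_RECORD_FIELDS:
        v = getattr(r, f)
        row[f] = np.nan if v is None else float(v)
    for f in _FLAG_RECORD_FIELDS:
        v = getattr(r, f)
        row[f] = np.nan if v is None else float(v)
    # variable-length gene lists collapse to fixed aggregates
    row["n_gene_mod"] = float(len(r.gene_mod))
    row["n_gene_del"] = float(sum(r.gene_del))
    row["n_gene_ovr"] = float(sum(r.gene_ovr))
    row["n_het_gene"] = float(sum(r.het_gene))
    row["n_codon_opt"] = float(sum(r.codon_opt))
    row["n_sen_reg"] = float(sum(r.sen_reg))
    row["n_enz_design"] = float(sum(r.enz_design))
    row["n_protein_scaffold"] = float(sum(r.protein_scaffold))
    row["mean_copy_number"] = float(np.mean(r.rep_origin)) if r.rep_origin else 0.0
    row["n_background_mod"] = float(len(r.background_genes))
    row["n_background_ins"] = float(sum(r.background_ins))
    return row


class StrainDesignEncoder(TransformerMixin, BaseEstimator):
    """Encode design records into a dense numeric :class:`FeatureMatrix`.

    Continuous fields pass through (missing values imputed with the
    training-set median learned in :meth:`fit`); enumerated fields expand to
    0/1 indicator columns with a dedicated ``unknown`` level; gene lists
    collapse to per-record aggregate counts; absent carbon sources 2/3
    contribute all-zero numeric blocks.
    """

    def __init__(self, include_product_name: bool = True):
        self.include_product_name = include_product_name

    def fit(self, records: Sequence[DesignRecord], y=None):
        for r in records:
            problems = validate_record(r)
            if problems:
                raise ValueError(f"record {r.record_id}: {'; '.join(problems)}")
        raw = pd.DataFrame([_aggregate_row(r) for r in records],
                           index=[r.record_id for r in records])
        self.continuous_columns_ = list(raw.columns)
        med = raw.median()
        self.medians_ = med.fillna(0.0).to_dict()
        self.categories_ = {}
        for f in self._cat_fields():
            levels = sorted({getattr(r, f) for r in records if getattr(r, f) is not None})
            self.categories_[f] = levels
        return self

    def _cat_fields(self) -> tuple[str, ...]:
        if self.include_product_name:
            return _CAT_RECORD_FIELDS
        return tuple(f for f in _CAT_RECORD_FIELDS if f != "prod_name")

    def transform(self, records: Sequence[DesignRecord]) -> FeatureMatrix:
        for r in records:
            problems = validate_record(r)
            if problems:
                raise ValueError(f"record {r.record_id}: {'; '.join(problems)}")
        ids = [r.record_id for r in records]
        raw = pd.DataFrame([_aggregate_row(r) for r in records], index=ids,
                           columns=self.continuous_columns_)
        raw = raw.fillna(self.medians_)
        roles = {c: "continuous" for c in raw.columns}
        blocks = [raw]
        for f in self._cat_fields():
            levels = self.categories_[f]
            cols = {}
            values = [getattr(r, f) for r in records]
            for lv in levels:
                cols[f"{f}={lv}"] = [1.0 if v == lv else 0.0 for v in values]
            cols[f"{f}=unknown"] = [1.0 if (v is None or v not in levels) else 0.0
                                    for v in values]
            block = pd.DataFrame(cols, index=ids)
            roles.update({c: "categorical" for c in block.columns})
            blocks.append(block)
        frame = pd.concat(blocks, axis=1)
        frame.index.name = "record_id"
        return FeatureMatrix(frame, roles)


def encode_features(records: Sequence[DesignRecord],
                    encoder: StrainDesignEncoder | None = None) -> FeatureMatrix:
    """Fit-and-transform convenience wrapper over :class:`StrainDesignEncoder`."""
    enc = encoder or StrainDesignEncoder()
    return enc.fit(records).transform(records)
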