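"""Build signaling models from reaction tables, plus canonical submodels.

Reaction-table TSV dialect
--------------------------
Tab-separated, one header line, columns::

    reaction_id  reactants  products  reversible  kf  kr  notes

``reactants``/``products`` are " + "-separated case-sensitive species
tokens; a coefficient prefix ("2 EGFR_EGF" or "2*EGFR_EGF") gives a
stoichiometry above one.  ``reversible`` accepts 1/0, true/false, yes/no,
rev/irr or the arrows "⇄"/"->".  ``kr`` must be non-empty exactly for
reversible rows.  First-order constants are s⁻¹, second-order μM⁻¹s⁻¹.

Species-table TSV dialect (companion file)::

    species_id  name  initial_uM  boundary  tags

``tags`` is ";"-separated (e.g. ``observable:ppERK``); ``boundary`` marks
clamped inputs such as the tamoxifen dose.

The packaged files ``data/sm1_reactions_synthetic.tsv`` and
``data/sm1_species_synthetic.tsv`` hold a synthetic transcription of the
full GPR30/EGFR/PI3K/MAPK/STAT network (see :func:`full_model`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .reaction_network import (
    Model,
    RateConstant,
    Reaction,
    Rule,
    Species,
    StructuralError,
)

__all__ = [
    "ReactionTableRow",
    "SpeciesInfo",
    "ConditionSpec",
    "FormatError",
    "parse_reaction_table",
    "parse_species_table",
    "assemble_model",
    "full_model",
    "build_submodel",
    "SUBMODEL_NAMES",
    "TREATED_TAMOXIFEN_UM",
]

#: Tamoxifen dose used for the treated condition, μM (the experimental LC50).
TREATED_TAMOXIFEN_UM = 250.0

REACTION_COLUMNS = ["reaction_id", "reactants", "products", "reversible", "kf", "kr", "notes"]
SPECIES_COLUMNS = ["species_id", "name", "initial_uM", "boundary", "tags"]

_TRUE = {"1", "true", "yes", "rev", "reversible", "⇄", "<->", "<=>"}
_FALSE = {"0", "false", "no", "irr", "irreversible", "->", "=>", ""}


class FormatError(Exception):
    """Malformed table file; message lists offending line numbers."""


@dataclass
class ReactionTableRow:
    reaction_id: str
    reactants: dict  # species id -> stoichiometry
    products: dict
    reversible: bool
    kf_value: float
    kr_value: float | None = None
    notes: str = ""


@dataclass
class SpeciesInfo:
    species_id: str
    name: str = ""
    initial_uM: float = 0.0
    boundary: bool = False
    tags: set = field(default_factory=set)


@dataclass
class ConditionSpec:
    """Experimental condition: which ligand inputs are set, and to what.

    ``ligand_settings`` maps species id → initial concentration (μM); for
    the treated condition the tamoxifen input is positive, for the
    untreated condition it is zero.  Only initial conditions differ between
    conditions — the reaction network itself is shared.
    """

    condition_label: str
    ligand_settings: dict = field(default_factory=dict)


def _parse_side(text: str) -> dict:
    out: dict = {}
    text = text.strip()
    if not text or text in ("-", "∅", "null"):
        return out
    for token in text.split("+"):
        token = token.strip()
        if not token:
            raise ValueError("empty species token")
        coef = 1
        if "*" in token:
            pre, _, rest = token.partition("*")
            coef, token = int(pre.strip()), rest.strip()
        else:
            parts = token.split()
            if len(parts) == 2 and parts[0].isdigit():
                coef, token = int(parts[0]), parts[1]
            elif len(parts) != 1:
                raise ValueError(f"unparsable token {token!r}")
        if coef < 1:
            raise ValueError(f"non-positive stoichiometry in {token!r}")
        out[token] = out.get(token, 0) + coef
    return out


def _parse_bool(text: str, line_no: int) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"line {line_no}: unrecognized reversibility flag {text!r}")


def _read_tsv(path) -> list:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln for ln in lines]


def parse_reaction_table(path, dialect: str = "tsv") -> list:
    """Parse a reaction-table TSV into :class:`ReactionTableRow` records.

    Malformed rows are collected and reported together with their line
    numbers in a :class:`FormatError`; an empty table yields an empty list
    and a warning.
    """
    if dialect != "tsv":
        raise FormatError(f"unknown dialect {dialect!r}")
    lines = _read_tsv(path)
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not body:
        warnings.warn(f"reaction table {path} is empty", UserWarning)
        return []
    header_no, header = body[0]
    cols = header.rstrip("\n").split("\t")
    if [c.strip() for c in cols[: len(REACTION_COLUMNS)]] != REACTION_COLUMNS:
        raise FormatError(
            f"line {header_no}: header {cols!r} does not match {REACTION_COLUMNS}"
        )
    rows, errors = [], []
    for line_no, ln in body[1:]:
        fields = ln.split("\t")
        if len(fields) < 6:
            errors.append(f"line {line_no}: expected ≥6 tab-separated fields, got {len(fields)}")
            continue
        fields += [""] * (7 - len(fields))
        rid, reac, prod, rev, kf, kr, notes = fields[:7]
        try:
            reversible = _parse_bool(rev, line_no)
            kf_value = float(kf)
            kr_text = kr.strip()
            if reversible and not kr_text:
                raise ValueError(f"line {line_no}: reversible reaction without kr")
            if not reversible and kr_text:
                raise ValueError(f"line {line_no}: kr given for irreversible reaction")
            kr_value = float(kr_text) if kr_text else None
            row = ReactionTableRow(
                reaction_id=rid.strip(),
                reactants=_parse_side(reac),
                products=_parse_side(prod),
                reversible=reversible,
                kf_value=kf_value,
                kr_value=kr_value,
                notes=notes.strip(),
            )
            if not row.reaction_id:
                raise ValueError(f"line {line_no}: empty reaction_id")
            if kf_value < 0 or (kr_value is not None and kr_value < 0):
                raise ValueError(f"line {line_no}: negative rate constant")
        except ValueError as exc:
            msg = str(exc)
            errors.append(msg if msg.startswith("line") else f"line {line_no}: {msg}")
            continue
        rows.append(row)
    if errors:
        raise FormatError("malformed reaction table:\n  " + "\n  ".join(errors))
    return rows


def parse_species_table(path) -> dict:
    """Parse the companion species TSV into {id: SpeciesInfo}, insertion-ordered."""
    lines = _read_tsv(path)
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not body:
        warnings.warn(f"species table {path} is empty", UserWarning)
        return {}
    header_no, header = body[0]
    cols = [c.strip() for c in header.split("\t")]
    if cols[: len(SPECIES_COLUMNS)] != SPECIES_COLUMNS:
        raise FormatError(f"line {header_no}: header {cols!r} does not match {SPECIES_COLUMNS}")
    out: dict = {}
    errors = []
    for line_no, ln in body[1:]:
        fields = ln.split("\t")
        fields += [""] * (5 - len(fields))
        sid, name, initial, boundary, tags = fields[:5]
        sid = sid.strip()
        try:
            info = SpeciesInfo(
                species_id=sid,
                name=name.strip(),
                initial_uM=float(initial) if initial.strip() else 0.0,
                boundary=_parse_bool(boundary, line_no),
                tags={t.strip() for t in tags.split(";") if t.strip()},
            )
            if not sid:
                raise ValueError(f"line {line_no}: empty species_id")
            if sid in out:
                raise ValueError(f"line {line_no}: duplicate species_id {sid!r}")
            if info.initial_uM < 0:
                raise ValueError(f"line {line_no}: negative initial concentration")
        except ValueError as exc:
            msg = str(exc)
            errors.append(msg if msg.startswith("line") else f"line {line_no}: {msg}")
            continue
        out[sid] = info
    if errors:
        raise FormatError("malformed species table:\n  " + "\n  ".join(errors))
    return out


def assemble_model(
    rows,
    condition: ConditionSpec,
    species_info: dict | None = None,
    name: str = "assembled",
    rules=(),
) -> Model:
    """Assemble a :class:`Model` from parsed rows under one condition.

    Species are the union of all reaction tokens (ordered by first
    appearance) unless ``species_info`` is given, in which case the species
    table's order, initial concentrations, boundary flags and tags are
    authoritative and every reaction token must appear in it.  The
    condition's ``ligand_settings`` override initial concentrations last.
    """
    rids = [r.reaction_id for r in rows]
    if len(set(rids)) != len(rids):
        dupes = sorted({i for i in rids if rids.count(i) > 1})
        raise StructuralError(f"duplicate reaction ids: {dupes}")
    if species_info is not None:
        order = list(species_info)
        declared = set(order)
        for row in rows:
            for sid in list(row.reactants) + list(row.products):
                if sid not in declared:
                    raise StructuralError(
                        f"reaction {row.reaction_id}: species {sid!r} not in species table"
                    )
        species = [
            Species(
                id=sid,
                name=species_info[sid].name,
                initial_concentration=species_info[sid].initial_uM,
                is_boundary=species_info[sid].boundary,
                tags=set(species_info[sid].tags),
            )
            for sid in order
        ]
    else:
        order = []
        seen = set()
        for row in rows:
            for sid in list(row.reactants) + list(row.products):
                if sid not in seen:
                    seen.add(sid)
                    order.append(sid)
        species = [Species(id=sid, name=sid) for sid in order]
    sp_by_id = {s.id: s for s in species}
    for sid, conc in condition.ligand_settings.items():
        if sid not in sp_by_id:
            raise StructuralError(f"condition references undeclared species {sid!r}")
        sp_by_id[sid].initial_concentration = float(conc)
    reactions = []
    for row in rows:
        r_order = sum(row.reactants.values())
        kf = RateConstant(id=f"{row.reaction_id}_kf", value=row.kf_value, order=r_order)
        kr = None
        if row.reversible:
            p_order = sum(row.products.values())
            kr = RateConstant(id=f"{row.reaction_id}_kr", value=row.kr_value, order=p_order)
        reactions.append(
            Reaction(
                id=row.reaction_id,
                reactants=dict(row.reactants),
                products=dict(row.products),
                kf=kf,
                kr=kr,
                reversible=row.reversible,
            )
        )
    return Model(
        name=name,
        species=species,
        reactions=reactions,
        rules=list(rules),
        condition_label=condition.condition_label,
    )


# ---------------------------------------------------------------------------
# Packaged full network
# ---------------------------------------------------------------------------

def _data_path(fname: str):
    return resources.files("gpersim").joinpath("data", fname)


def condition_spec(condition_label: str) -> ConditionSpec:
    """The two study conditions: tamoxifen at 250 μM (treated) or absent."""
    if condition_label == "treated":
        return ConditionSpec("treated", {"TAM": TREATED_TAMOXIFEN_UM})
    if condition_label == "untreated":
        return ConditionSpec("untreated", {"TAM": 0.0})
    raise ValueError(f"unknown condition {condition_label!r}")


def full_model(condition_label: str = "treated") -> Model:
    """The full GPR30/EGFR/PI3K/MAPK/STAT network under one condition.

    Built from the packaged synthetic transcription of the signaling
    reaction table (128 species, 143 reactions, 213 rate constants) plus
    the model's single rule — an assignment rule collecting every
    doubly-phosphorylated-ERK pool into the readout species ``ppERK_total``.
    Treated and untreated variants share structure and differ only in the
    clamped tamoxifen input (250 μM vs 0).
    """
    rows = parse_reaction_table(_data_path("sm1_reactions_synthetic.tsv"))
    info = parse_species_table(_data_path("sm1_species_synthetic.tsv"))
    rule = Rule(
        id="rule_ppERK_total",
        kind="assignment",
        target="ppERK_total",
        expression="ppERK + ppERK_nuc + ppERK_Elk1 + ppERK_p53 + MKP_ppERK",
    )
    return assemble_model(
        rows,
        condition_spec(condition_label),
        species_info=info,
        name=f"gper_signaling_{condition_label}",
        rules=[rule],
    )


# ---------------------------------------------------------------------------
# Canonical pathway submodels (for property testing and fitting)
# ---------------------------------------------------------------------------

def _m(name, condition, species, reactions, tags=None, boundary=(), initials=None):
    tags = tags or {}
    initials = initials or {}
    sp = [
        Species(
            id=s,
            name=s,
            initial_concentration=initials.get(s, 0.0),
            is_boundary=s in boundary,
            tags=set(tags.get(s, ())),
        )
        for s in species
    ]
    rx = []
    for rid, reac, prod, kf, kr in reactions:
        r_order = sum(reac.values())
        rx.append(
            Reaction(
                id=rid,
                reactants=reac,
                products=prod,
                kf=RateConstant(f"{rid}_kf", kf, order=r_order),
                kr=(
                    RateConstant(f"{rid}_kr", kr, order=sum(prod.values()))
                    if kr is not None
                    else None
                ),
                reversible=kr is not None,
            )
        )
    return Model(name=name, species=sp, reactions=rx, condition_label=condition)


def _egfr_activation():
    # ligand binding, dimerisation (2nd-order self-interaction), autophosphorylation
    return _m(
        "egfr_activation", "generic",
        ["EGF", "EGFR", "EGFR_EGF", "EGFR2", "EGFR2_p"],
        [
            ("r1", {"EGF": 1, "EGFR": 1}, {"EGFR_EGF": 1}, 0.1, 0.01),
            ("r2", {"EGFR_EGF": 2}, {"EGFR2": 1}, 0.05, 0.01),
            ("r3", {"EGFR2": 1}, {"EGFR2_p": 1}, 0.5, None),
            ("r4", {"EGFR2_p": 1}, {"EGFR2": 1}, 0.05, None),
        ],
        tags={"EGFR2_p": {"observable:EGFR_active"}},
        boundary={"EGF"},
        initials={"EGF": 0.1, "EGFR": 1.0},
    )


def _ras_raf_mek_erk():
    # decaying EGF-like input drives a distributive dual-phosphorylation cascade
    return _m(
        "ras_raf_mek_erk", "generic",
        ["input_active", "Raf1", "Raf1_act", "MEK", "MEK_p", "ppMEK",
         "ERK", "ERK_p", "ppERK"],
        [
            ("r_input_decay", {"input_active": 1}, {}, 0.002, None),
            ("r_raf_act", {"input_active": 1, "Raf1": 1},
             {"input_active": 1, "Raf1_act": 1}, 0.2, None),
            ("r_raf_deact", {"Raf1_act": 1}, {"Raf1": 1}, 0.02, None),
            ("r_mek_p1", {"Raf1_act": 1, "MEK": 1},
             {"Raf1_act": 1, "MEK_p": 1}, 0.1, None),
            ("r_mek_p2", {"Raf1_act": 1, "MEK_p": 1},
             {"Raf1_act": 1, "ppMEK": 1}, 0.1, None),
            ("r_mek_dp2", {"ppMEK": 1}, {"MEK_p": 1}, 0.02, None),
            ("r_mek_dp1", {"MEK_p": 1}, {"MEK": 1}, 0.02, None),
            ("r_erk_p1", {"ppMEK": 1, "ERK": 1}, {"ppMEK": 1, "ERK_p": 1}, 0.1, None),
            ("r_erk_p2", {"ppMEK": 1, "ERK_p": 1}, {"ppMEK": 1, "ppERK": 1}, 0.1, None),
            ("r_erk_dp2", {"ppERK": 1}, {"ERK_p": 1}, 0.02, None),
            ("r_erk_dp1", {"ERK_p": 1}, {"ERK": 1}, 0.02, None),
        ],
        tags={
            "Raf1_act": {"observable:Raf1_active"},
            "ppMEK": {"observable:ppMEK"},
            "ppERK": {"observable:ppERK"},
        },
        initials={"input_active": 0.1, "Raf1": 0.5, "MEK": 1.0, "ERK": 1.0},
    )


def _pi3k_akt_pten():
    # lipid turnover with fast reversible Akt recruitment (the reversible
    # Akt + PIP3 ⇄ Aktm step)
    return _m(
        "pi3k_akt_pten", "generic",
        ["PI3K_act", "PIP2", "PIP3", "PTEN", "Akt", "Aktm"],
        [
            ("r_pi3k", {"PI3K_act": 1, "PIP2": 1}, {"PI3K_act": 1, "PIP3": 1}, 0.05, None),
            ("r_pten", {"PTEN": 1, "PIP3": 1}, {"PTEN": 1, "PIP2": 1}, 0.1, None),
            ("r_akt_m", {"Akt": 1, "PIP3": 1}, {"Aktm": 1}, 1.0, 1.0),
        ],
        tags={"PIP3": {"observable:PIP3"}, "Aktm": {"observable:PIP3"}},
        boundary={"PI3K_act"},
        initials={"PI3K_act": 0.1, "PIP2": 2.0, "PTEN": 0.5, "Akt": 1.0},
    )


def _jak_stat():
    return _m(
        "jak_stat", "generic",
        ["R_act", "JAK", "JAK_act", "STAT", "STAT_p", "STAT_dim"],
        [
            ("r_jak_act", {"R_act": 1, "JAK": 1}, {"R_act": 1, "JAK_act": 1}, 0.1, None),
            ("r_jak_deact", {"JAK_act": 1}, {"JAK": 1}, 0.01, None),
            ("r_stat_p", {"JAK_act": 1, "STAT": 1}, {"JAK_act": 1, "STAT_p": 1}, 0.1, None),
            ("r_stat_dp", {"STAT_p": 1}, {"STAT": 1}, 0.01, None),
            ("r_dim", {"STAT_p": 2}, {"STAT_dim": 1}, 0.5, 0.05),
            ("r_dim_dp", {"STAT_dim": 1}, {"STAT": 2}, 0.005, None),
        ],
        tags={"STAT_dim": {"observable:STAT_dimer"}},
        boundary={"R_act"},
        initials={"R_act": 0.1, "JAK": 0.5, "STAT": 1.0},
    )


def _gpr30_plc_pkc():
    return _m(
        "gpr30_plc_pkc", "generic",
        ["TAM", "GPR30", "TAM_GPR30", "PLC", "PLC_act", "PIP2",
         "IP3", "DAG", "PKC", "PKC_IP3", "PKC_DAG"],
        [
            ("r_bind", {"TAM": 1, "GPR30": 1}, {"TAM_GPR30": 1}, 0.1, 0.01),
            ("r_plc_act", {"TAM_GPR30": 1, "PLC": 1},
             {"TAM_GPR30": 1, "PLC_act": 1}, 0.1, None),
            ("r_plc_deact", {"PLC_act": 1}, {"PLC": 1}, 0.01, None),
            ("r_cleave", {"PLC_act": 1, "PIP2": 1},
             {"PLC_act": 1, "IP3": 1, "DAG": 1}, 0.05, None),
            ("r_ip3_deg", {"IP3": 1}, {}, 0.01, None),
            ("r_dag_deg", {"DAG": 1}, {}, 0.01, None),
            ("r_pkc_ip3", {"IP3": 1, "PKC": 1}, {"PKC_IP3": 1}, 0.2, 0.05),
            ("r_pkc_dag", {"DAG": 1, "PKC": 1}, {"PKC_DAG": 1}, 0.2, 0.05),
        ],
        tags={"PKC_IP3": {"observable:PKC_active"}, "PKC_DAG": {"observable:PKC_active"}},
        boundary={"TAM"},
        initials={"TAM": 1.0, "GPR30": 0.5, "PLC": 0.5, "PIP2": 2.0, "PKC": 1.0},
    )


def _src_mmp_hbegf():
    return _m(
        "src_mmp_hbegf", "generic",
        ["Gbg", "Src", "Src_act", "MMP", "MMP_act", "proHBEGF", "EGF"],
        [
            ("r_src_act", {"Gbg": 1, "Src": 1}, {"Gbg": 1, "Src_act": 1}, 0.1, None),
            ("r_src_deact", {"Src_act": 1}, {"Src": 1}, 0.01, None),
            ("r_mmp_act", {"Src_act": 1, "MMP": 1}, {"Src_act": 1, "MMP_act": 1}, 0.1, None),
            ("r_mmp_deact", {"MMP_act": 1}, {"MMP": 1}, 0.01, None),
            ("r_shed", {"MMP_act": 1, "proHBEGF": 1}, {"MMP_act": 1, "EGF": 1}, 0.05, None),
            ("r_egf_deg", {"EGF": 1}, {}, 0.005, None),
        ],
        tags={"EGF": {"observable:EGF"}},
        boundary={"Gbg"},
        initials={"Gbg": 0.1, "Src": 0.5, "MMP": 0.5, "proHBEGF": 2.0},
    )


def _gpcr_internalization():
    # closed receptor cycle: membrane → phosphorylated → arrestin-bound →
    # internalised → recycled; total receptor is a conserved moiety
    return _m(
        "gpcr_internalization", "generic",
        ["R", "R_p", "bArr", "R_p_bArr", "R_int"],
        [
            ("r_grk", {"R": 1}, {"R_p": 1}, 0.05, None),
            ("r_arr_bind", {"R_p": 1, "bArr": 1}, {"R_p_bArr": 1}, 0.2, 0.02),
            ("r_internalize", {"R_p_bArr": 1}, {"R_int": 1, "bArr": 1}, 0.05, None),
            ("r_recycle", {"R_int": 1}, {"R": 1}, 0.02, None),
        ],
        tags={"R_int": {"observable:internalized_receptor"}},
        initials={"R": 1.0, "bArr": 0.5},
    )


_SUBMODEL_BUILDERS = {
    "egfr_activation": _egfr_activation,
    "ras_raf_mek_erk": _ras_raf_mek_erk,
    "pi3k_akt_pten": _pi3k_akt_pten,
    "jak_stat": _jak_stat,
    "gpr30_plc_pkc": _gpr30_plc_pkc,
    "src_mmp_hbegf": _src_mmp_hbegf,
    "gpcr_internalization": _gpcr_internalization,
}

SUBMODEL_NAMES = tuple(_SUBMODEL_BUILDERS)


def build_submodel(name: str) -> Model:
    """A self-contained, simulable model of one canonical pathway motif.

    Default rate constants are order-of-magnitude choices consistent with
    the package's unit convention (first-order 10⁻³–1 s⁻¹, second-order
    10⁻³–1 μM⁻¹s⁻¹); the submodels exist for property testing and
    parameter-recovery studies, not quantitative prediction.
    """
    try:
        builder = _SUBMODEL_BUILDERS[name]
    except KeyError:
        raise LookupError(
            f"unknown submodel {name!r}; known: {sorted(_SUBMODEL_BUILDERS)}"
        ) from None
    return builder()
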