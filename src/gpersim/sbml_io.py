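"""Minimal SBML reader/writer for mass-action models.

Scope is deliberately narrow — exactly what this package's models contain:
a single dimensionless compartment, species with initial concentrations
and boundary flags, global parameters (rate constants), reactions whose
kinetic laws are explicit mass-action expressions (kf·∏reactants, minus
kr·∏products when reversible, written as one reaction with a two-term
law), and assignment/rate rules over polynomial arithmetic.  Documents are
emitted as SBML Level 3 Version 1; on input both Level 2 and Level 3 core
are accepted (namespaces are matched by local name).  Anything outside
this fragment — e.g. a Michaelis–Menten kinetic law — is rejected with an
:class:`UnsupportedFeatureError` naming the reaction and expression.

Species tags (observable labels) ride along in a small custom annotation
element so a written model round-trips completely.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from xml.etree import ElementTree as ET

from .reaction_network import (
    Model,
    RateConstant,
    Reaction,
    Rule,
    Species,
    validate_model,
)

__all__ = [
    "SbmlDocumentInfo",
    "SbmlError",
    "UnsupportedFeatureError",
    "read_sbml",
    "write_sbml",
]

SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
GPERSIM_NS = "https://gpersim.invalid/annotations"


class SbmlError(Exception):
    """Malformed or unreadable SBML document."""


class UnsupportedFeatureError(SbmlError):
    """The document uses SBML features outside the mass-action fragment."""


@dataclass
class SbmlDocumentInfo:
    level: int
    version: int
    model_name: str
    n_species: int
    n_reactions: int
    n_parameters: int
    n_rules: int


# ---------------------------------------------------------------------------
# expression <-> MathML
# ---------------------------------------------------------------------------

def _expr_to_mathml(expr: str, parent: ET.Element) -> None:
    """Append the MathML rendering of a +,-,*,/,** arithmetic expression."""

    def build(node, into):
        if isinstance(node, ast.Expression):
            build(node.body, into)
        elif isinstance(node, ast.BinOp):
            ops = {
                ast.Add: "plus",
                ast.Sub: "minus",
                ast.Mult: "times",
                ast.Div: "divide",
                ast.Pow: "power",
            }
            opname = ops.get(type(node.op))
            if opname is None:
                raise UnsupportedFeatureError(f"operator {node.op!r} in {expr!r}")
            apply_el = ET.SubElement(into, f"{{{MATHML_NS}}}apply")
            ET.SubElement(apply_el, f"{{{MATHML_NS}}}{opname}")
            build(node.left, apply_el)
            build(node.right, apply_el)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
            apply_el = ET.SubElement(into, f"{{{MATHML_NS}}}apply")
            ET.SubElement(apply_el, f"{{{MATHML_NS}}}minus")
            build(node.operand, apply_el)
        elif isinstance(node, ast.Name):
            ci = ET.SubElement(into, f"{{{MATHML_NS}}}ci")
            ci.text = f" {node.id} "
        elif isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
            cn = ET.SubElement(into, f"{{{MATHML_NS}}}cn")
            cn.text = f" {node.value} "
        else:
            raise UnsupportedFeatureError(f"unsupported syntax in expression {expr!r}")

    math_el = ET.SubElement(parent, f"{{{MATHML_NS}}}math")
    build(ast.parse(expr, mode="eval"), math_el)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _mathml_to_ast(el):
    """MathML element -> nested tuples: ('ci', name) | ('cn', value) |
    (op, arg, ...)."""
    tag = _local(el.tag)
    if tag == "math":
        children = list(el)
        if len(children) != 1:
            raise UnsupportedFeatureError("math element must have one child")
        return _mathml_to_ast(children[0])
    if tag == "ci":
        return ("ci", el.text.strip())
    if tag == "cn":
        txt = el.text.strip() if el.text else "0"
        if el.get("type") == "integer":
            return ("cn", int(txt))
        return ("cn", float(txt))
    if tag == "apply":
        children = list(el)
        op = _local(children[0].tag)
        args = [_mathml_to_ast(c) for c in children[1:]]
        return (op, *args)
    raise UnsupportedFeatureError(f"unsupported MathML element <{tag}>")


def _ast_to_expr(node) -> str:
    kind = node[0]
    if kind == "ci":
        return node[1]
    if kind == "cn":
        return repr(node[1])
    ops = {"plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "**"}
    if kind in ops:
        args = [_ast_to_expr(a) for a in node[1:]]
        if kind == "minus" and len(args) == 1:
            return f"(-{args[0]})"
        return "(" + f" {ops[kind]} ".join(args) + ")"
    raise UnsupportedFeatureError(f"unsupported MathML operator {kind!r}")


def _flatten_product(node, out):
    """Collect factors of a ('times', ...) tree into ``out``; powers expand
    to repeated factors when the exponent is a small positive integer."""
    kind = node[0]
    if kind == "times":
        for child in node[1:]:
            _flatten_product(child, out)
    elif kind == "power":
        base, expo = node[1], node[2]
        if expo[0] != "cn" or int(expo[1]) != expo[1] or not (1 <= expo[1] <= 4):
            raise UnsupportedFeatureError(f"non-integer power {expo!r}")
        for _ in range(int(expo[1])):
            _flatten_product(base, out)
    elif kind in ("ci", "cn"):
        out.append(node)
    else:
        raise UnsupportedFeatureError(f"non-polynomial factor {node!r}")


def _match_half(factors, side, params, rxn_id, text):
    """Match product factors against one reaction side; return the rate
    constant value.  Exactly one factor must be a parameter/number; the
    species factors must reproduce the side's stoichiometry."""
    k_val = None
    counts: dict = {}
    for f in factors:
        if f[0] == "cn":
            if k_val is not None:
                raise UnsupportedFeatureError(
                    f"reaction {rxn_id!r}: kinetic law {text!r} has multiple constants"
                )
            k_val = float(f[1])
        else:
            name = f[1]
            if name in params:
                if k_val is not None:
                    raise UnsupportedFeatureError(
                        f"reaction {rxn_id!r}: kinetic law {text!r} has multiple constants"
                    )
                k_val = params[name]
            else:
                counts[name] = counts.get(name, 0) + 1
    if k_val is None or counts != dict(side):
        raise UnsupportedFeatureError(
            f"reaction {rxn_id!r}: kinetic law {text!r} is not mass-action "
            f"for stoichiometry {dict(side)}"
        )
    return k_val


# ---------------------------------------------------------------------------
# write
# ---------------------------------------------------------------------------

def write_sbml(model: Model, path, level_version: tuple = (3, 1)) -> None:
    """Write ``model`` as an SBML document (Level 3 Version 1).

    The model must validate; every reaction gets one explicit mass-action
    kineticLaw referencing global kf/kr parameters.
    """
    if level_version != (3, 1):
        raise ValueError("only SBML Level 3 Version 1 output is supported")
    rep = validate_model(model)
    if not rep.ok:
        raise SbmlError("model does not validate: " + "; ".join(rep.all_messages()))
    ET.register_namespace("", SBML_L3V1_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(f"{{{SBML_L3V1_NS}}}sbml", {"level": "3", "version": "1"})
    m = ET.SubElement(root, f"{{{SBML_L3V1_NS}}}model",
                      {"id": model.name, "name": model.name})
    m.set("metaid", f"condition_{model.condition_label}")
    lc = ET.SubElement(m, f"{{{SBML_L3V1_NS}}}listOfCompartments")
    ET.SubElement(lc, f"{{{SBML_L3V1_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true",
                   "spatialDimensions": "3"})
    ls = ET.SubElement(m, f"{{{SBML_L3V1_NS}}}listOfSpecies")
    for sp in model.species:
        el = ET.SubElement(ls, f"{{{SBML_L3V1_NS}}}species", {
            "id": sp.id,
            "name": sp.name or sp.id,
            "compartment": "cell",
            "initialConcentration": repr(float(sp.initial_concentration)),
            "boundaryCondition": "true" if sp.is_boundary else "false",
            "hasOnlySubstanceUnits": "false",
            "constant": "false",
        })
        if sp.tags:
            ann = ET.SubElement(el, f"{{{SBML_L3V1_NS}}}annotation")
            tags_el = ET.SubElement(ann, f"{{{GPERSIM_NS}}}tags")
            tags_el.text = ";".join(sorted(sp.tags))
    lp = ET.SubElement(m, f"{{{SBML_L3V1_NS}}}listOfParameters")
    for rxn in model.reactions:
        for k in (rxn.kf, rxn.kr):
            if k is not None:
                ET.SubElement(lp, f"{{{SBML_L3V1_NS}}}parameter",
                              {"id": k.id, "value": repr(float(k.value)),
                               "constant": "true"})
    if model.rules:
        lr = ET.SubElement(m, f"{{{SBML_L3V1_NS}}}listOfRules")
        for ru in model.rules:
            tag = "assignmentRule" if ru.kind == "assignment" else "rateRule"
            rel = ET.SubElement(lr, f"{{{SBML_L3V1_NS}}}{tag}",
                                {"variable": ru.target, "metaid": ru.id})
            _expr_to_mathml(ru.expression, rel)
    lx = ET.SubElement(m, f"{{{SBML_L3V1_NS}}}listOfReactions")
    for rxn in model.reactions:
        rel = ET.SubElement(lx, f"{{{SBML_L3V1_NS}}}reaction", {
            "id": rxn.id,
            "reversible": "true" if rxn.reversible else "false",
            "fast": "false",
        })
        if rxn.reactants:
            lre = ET.SubElement(rel, f"{{{SBML_L3V1_NS}}}listOfReactants")
            for sid, coef in rxn.reactants.items():
                ET.SubElement(lre, f"{{{SBML_L3V1_NS}}}speciesReference",
                              {"species": sid, "stoichiometry": str(coef),
                               "constant": "true"})
        if rxn.products:
            lpr = ET.SubElement(rel, f"{{{SBML_L3V1_NS}}}listOfProducts")
            for sid, coef in rxn.products.items():
                ET.SubElement(lpr, f"{{{SBML_L3V1_NS}}}speciesReference",
                              {"species": sid, "stoichiometry": str(coef),
                               "constant": "true"})
        kl = ET.SubElement(rel, f"{{{SBML_L3V1_NS}}}kineticLaw")
        fwd = " * ".join(
            [rxn.kf.id] + [sid if c == 1 else f"{sid}**{c}"
                           for sid, c in rxn.reactants.items()]
        )
        if rxn.reversible:
            rev = " * ".join(
                [rxn.kr.id] + [sid if c == 1 else f"{sid}**{c}"
                               for sid, c in rxn.products.items()]
            )
            law = f"{fwd} - {rev}"
        else:
            law = fwd
        _expr_to_mathml(law, kl)
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# read
# ---------------------------------------------------------------------------

def _find(el, name):
    for child in el:
        if _local(child.tag) == name:
            return child
    return None


def _findall(el, name):
    return [c for c in el if _local(c.tag) == name]


def read_sbml(path):
    """Read an SBML Level 2/3 document into a (:class:`Model`,
    :class:`SbmlDocumentInfo`) pair.

    Kinetic laws must be explicit mass-action (see module docstring);
    anything else raises :class:`UnsupportedFeatureError` with the
    offending reaction id and expression.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SbmlError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlError(f"{path}: root element is <{_local(root.tag)}>, not <sbml>")
    level = int(root.get("level", "0"))
    version = int(root.get("version", "0"))
    if level not in (2, 3):
        raise UnsupportedFeatureError(f"SBML level {level} not supported (need 2 or 3)")
    mel = _find(root, "model")
    if mel is None:
        raise SbmlError(f"{path}: no <model> element")
    name = mel.get("name") or mel.get("id") or "sbml_model"
    condition = "other"
    metaid = mel.get("metaid", "")
    if metaid.startswith("condition_"):
        condition = metaid[len("condition_"):]

    species = []
    ls = _find(mel, "listOfSpecies")
    for el in (_findall(ls, "species") if ls is not None else []):
        init = el.get("initialConcentration")
        if init is None:
            init = el.get("initialAmount", "0")  # size-1 compartment: equal
        tags: set = set()
        ann = _find(el, "annotation")
        if ann is not None:
            tags_el = _find(ann, "tags")
            if tags_el is not None and tags_el.text:
                tags = {t for t in tags_el.text.split(";") if t}
        species.append(
            Species(
                id=el.get("id"),
                name=el.get("name", "") or "",
                initial_concentration=float(init),
                is_boundary=el.get("boundaryCondition", "false") == "true",
                tags=tags,
            )
        )

    params = {}
    lp = _find(mel, "listOfParameters")
    for el in (_findall(lp, "parameter") if lp is not None else []):
        params[el.get("id")] = float(el.get("value", "nan"))

    rules = []
    lr = _find(mel, "listOfRules")
    for i, el in enumerate(_findall(lr, "assignmentRule") + _findall(lr, "rateRule")
                           if lr is not None else []):
        kind = "assignment" if _local(el.tag) == "assignmentRule" else "rate"
        math_el = _find(el, "math")
        if math_el is None:
            raise SbmlError(f"rule for {el.get('variable')!r} has no math")
        expr = _ast_to_expr(_mathml_to_ast(math_el))
        rules.append(
            Rule(
                id=el.get("metaid") or f"rule_{i}",
                kind=kind,
                target=el.get("variable"),
                expression=expr,
            )
        )

    reactions = []
    lx = _find(mel, "listOfReactions")
    for el in (_findall(lx, "reaction") if lx is not None else []):
        rid = el.get("id")
        reversible = el.get("reversible", "true" if level == 2 else "false") == "true"

        def side(list_name):
            out: dict = {}
            lst = _find(el, list_name)
            for ref in (_findall(lst, "speciesReference") if lst is not None else []):
                coef = float(ref.get("stoichiometry", "1"))
                if coef != int(coef) or coef < 1:
                    raise UnsupportedFeatureError(
                        f"reaction {rid!r}: non-integer stoichiometry {coef}"
                    )
                out[ref.get("species")] = out.get(ref.get("species"), 0) + int(coef)
            return out

        reactants = side("listOfReactants")
        products = side("listOfProducts")
        kl = _find(el, "kineticLaw")
        if kl is None:
            raise UnsupportedFeatureError(f"reaction {rid!r} has no kineticLaw")
        local_params = dict(params)
        for lpl_name in ("listOfLocalParameters", "listOfParameters"):
            lpl = _find(kl, lpl_name)
            if lpl is not None:
                for pel in list(lpl):
                    local_params[pel.get("id")] = float(pel.get("value", "nan"))
        math_el = _find(kl, "math")
        if math_el is None:
            raise UnsupportedFeatureError(f"reaction {rid!r}: kineticLaw has no math")
        node = _mathml_to_ast(math_el)
        text = _ast_to_expr(node)
        if node[0] == "minus" and len(node) == 3:
            fwd_node, rev_node = node[1], node[2]
        else:
            fwd_node, rev_node = node, None
        try:
            fwd_factors: list = []
            _flatten_product(fwd_node, fwd_factors)
            kf_val = _match_half(fwd_factors, reactants, local_params, rid, text)
            kf = RateConstant(f"{rid}_kf", kf_val, order=sum(reactants.values()))
            kr = None
            if rev_node is not None:
                rev_factors: list = []
                _flatten_product(rev_node, rev_factors)
                kr_val = _match_half(rev_factors, products, local_params, rid, text)
                kr = RateConstant(f"{rid}_kr", kr_val, order=sum(products.values()))
                reversible = True
            elif reversible:
                # declared reversible but one-term law: treat as irreversible
                reversible = False
        except UnsupportedFeatureError as exc:
            raise UnsupportedFeatureError(
                f"reaction {rid!r}: kinetic law {text!r} is not mass-action ({exc})"
            ) from None
        reactions.append(
            Reaction(
                id=rid,
                reactants=reactants,
                products=products,
                kf=kf,
                kr=kr,
                reversible=reversible,
            )
        )

    model = Model(
        name=name,
        species=species,
        reactions=reactions,
        rules=rules,
        condition_label=condition,
    )
    info = SbmlDocumentInfo(
        level=level,
        version=version,
        model_name=name,
        n_species=model.n_species,
        n_reactions=model.n_reactions,
        n_parameters=model.n_parameters,
        n_rules=model.n_rules,
    )
    return model, info
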