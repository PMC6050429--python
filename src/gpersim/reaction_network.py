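"""Core domain types and mass-action ODE machinery.

A signaling network is represented as a :class:`Model`: an ordered list of
:class:`Species`, an ordered list of :class:`Reaction` objects with pure
mass-action kinetics (first or second order, optionally reversible), and an
optional list of :class:`Rule` objects (SBML-style assignment or rate rules).

Units are fixed throughout the package: concentrations in μM, time in
seconds, first-order rate constants in s⁻¹ and second-order rate constants
in μM⁻¹s⁻¹.  Boundary species (clamped model inputs such as a ligand dose)
stay in the state vector but receive a zero derivative, so treated and
untreated variants of a model share one state layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "RateConstant",
    "Reaction",
    "Rule",
    "Model",
    "StoichiometryMatrix",
    "ValidationReport",
    "ModelError",
    "StructuralError",
    "DomainError",
    "UnitsError",
    "mass_action_flux",
    "stoichiometry_matrix",
    "ode_rhs",
    "conserved_moieties",
    "validate_model",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ModelError(Exception):
    """Base class for model construction and evaluation errors."""


class StructuralError(ModelError):
    """A reference to an undeclared id, a duplicate id, or a shape mismatch."""


class DomainError(ModelError):
    """A value outside its mathematical domain (negative concentration...)."""


class UnitsError(ModelError):
    """A rate-constant order inconsistent with the reaction stoichiometry."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Species:
    """A chemical species.

    Parameters
    ----------
    id : str
        Unique token within a model (e.g. ``"ppERK"``).
    name : str
        Free-text description.
    initial_concentration : float
        Initial concentration in μM; must be non-negative.
    is_boundary : bool
        If True the concentration is clamped (zero derivative) — used for
        model inputs such as the tamoxifen dose.
    tags : set of str
        Free-form labels, e.g. ``"observable:ppERK"``.
    """

    id: str
    name: str = ""
    initial_concentration: float = 0.0
    is_boundary: bool = False
    tags: set = field(default_factory=set)

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise DomainError(
                f"species {self.id!r}: negative initial concentration "
                f"{self.initial_concentration}"
            )


@dataclass
class RateConstant:
    """A mass-action rate constant.

    ``order`` 1 means units of s⁻¹, order 2 means μM⁻¹s⁻¹; the order must
    match the total stoichiometry of the half-reaction it governs.
    """

    id: str
    value: float
    order: int = 1

    def __post_init__(self):
        if self.value < 0:
            raise DomainError(f"rate constant {self.id!r}: negative value {self.value}")
        if self.order not in (1, 2):
            raise UnitsError(f"rate constant {self.id!r}: order must be 1 or 2, got {self.order}")

    @property
    def units(self) -> str:
        return "1/s" if self.order == 1 else "1/(uM*s)"


@dataclass
class Reaction:
    """A uni- or bimolecular mass-action reaction, optionally reversible.

    ``reactants`` and ``products`` map species id → positive integer
    stoichiometry.  The net flux is

        v = kf·∏[reactant]^stoich − (kr·∏[product]^stoich if reversible)

    in μM/s.
    """

    id: str
    reactants: dict
    products: dict
    kf: RateConstant
    kr: RateConstant | None = None
    reversible: bool = False

    def __post_init__(self):
        if self.reversible and self.kr is None:
            raise StructuralError(f"reaction {self.id!r}: reversible but no kr")
        if not self.reversible and self.kr is not None:
            raise StructuralError(f"reaction {self.id!r}: kr given but not reversible")
        for side, name in ((self.reactants, "reactant"), (self.products, "product")):
            for sid, coef in side.items():
                if not (isinstance(coef, (int, np.integer)) and coef > 0):
                    raise StructuralError(
                        f"reaction {self.id!r}: {name} {sid!r} stoichiometry "
                        f"{coef!r} is not a positive integer"
                    )

    @property
    def reactant_order(self) -> int:
        return sum(self.reactants.values())

    @property
    def product_order(self) -> int:
        return sum(self.products.values())


@dataclass
class Rule:
    """An SBML-style rule.

    kind "assignment": the target's value is set to ``expression`` before
    fluxes are evaluated at every RHS call.  kind "rate": the target's time
    derivative is set to ``expression`` (overriding the stoichiometric RHS).
    Expressions are arithmetic over declared species ids, evaluated with a
    restricted ``eval`` (no builtins).
    """

    id: str
    kind: str  # "assignment" | "rate"
    target: str
    expression: str

    def __post_init__(self):
        if self.kind not in ("assignment", "rate"):
            raise StructuralError(f"rule {self.id!r}: unknown kind {self.kind!r}")


@dataclass
class StoichiometryMatrix:
    """Integer net-stoichiometry matrix, species × reactions, model order."""

    matrix: np.ndarray
    species_ids: list
    reaction_ids: list


@dataclass
class ValidationReport:
    """Problems found by :func:`validate_model`, grouped by category."""

    structural: list = field(default_factory=list)
    domain: list = field(default_factory=list)
    units: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.structural or self.domain or self.units)

    def all_messages(self) -> list:
        return list(self.structural) + list(self.domain) + list(self.units)


class Model:
    """A named reaction network for one experimental condition."""

    def __init__(
        self,
        name: str,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        rules: Sequence[Rule] = (),
        condition_label: str = "untreated",
    ):
        self.name = name
        self.condition_label = condition_label
        self.species = list(species)
        self.reactions = list(reactions)
        self.rules = list(rules)
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StructuralError(f"duplicate species ids: {dupes}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({i for i in rids if rids.count(i) > 1})
            raise StructuralError(f"duplicate reaction ids: {dupes}")
        self._index = {s.id: i for i, s in enumerate(self.species)}
        self._compiled_rules = [
            (ru, compile(ru.expression, f"<rule {ru.id}>", "eval")) for ru in self.rules
        ]

    # -- structure queries ---------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_parameters(self) -> int:
        """Count of rate constants (one kf per reaction, plus kr if reversible)."""
        return sum(2 if r.reversible else 1 for r in self.reactions)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def structure_counts(self) -> tuple:
        """(species, reactions, parameters, rules)."""
        return (self.n_species, self.n_reactions, self.n_parameters, self.n_rules)

    def species_index(self, sid: str) -> int:
        try:
            return self._index[sid]
        except KeyError:
            raise StructuralError(f"unknown species id {sid!r}") from None

    def get_species(self, sid: str) -> Species:
        return self.species[self.species_index(sid)]

    def find_rate_constant(self, kid: str) -> RateConstant:
        for r in self.reactions:
            if r.kf.id == kid:
                return r.kf
            if r.kr is not None and r.kr.id == kid:
                return r.kr
        raise StructuralError(f"unknown rate constant id {kid!r}")

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], dtype=float)

    def species_by_tag(self, tag: str) -> list:
        return [s.id for s in self.species if tag in s.tags]

    def boundary_mask(self) -> np.ndarray:
        return np.array([s.is_boundary for s in self.species], dtype=bool)

    def copy(self) -> "Model":
        import copy as _copy

        return _copy.deepcopy(self)

    # -- rule machinery -------------------------------------------------------
    def _rule_env(self, state: np.ndarray, t: float) -> dict:
        env = {sid: state[i] for sid, i in self._index.items()}
        env["t"] = t
        return env

    def apply_assignment_rules(self, state: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Return a copy of ``state`` with assignment rules applied."""
        if not self.rules:
            return state
        out = np.array(state, dtype=float, copy=True)
        env = self._rule_env(out, t)
        for ru, code in self._compiled_rules:
            if ru.kind != "assignment":
                continue
            val = eval(code, {"__builtins__": {}}, env)
            out[self.species_index(ru.target)] = val
            env[ru.target] = val
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        s, r, p, ru = self.structure_counts()
        return (
            f"<Model {self.name!r} [{self.condition_label}] "
            f"{s} species, {r} reactions, {p} parameters, {ru} rules>"
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def mass_action_flux(reaction: Reaction, state: Mapping[str, float]) -> float:
    """Net mass-action flux of one reaction at the given state, μM/s.

    ``state`` maps species id → concentration (μM).  Stoichiometric
    coefficients above 1 raise the concentration to that power.
    """
    fwd = reaction.kf.value
    for sid, coef in reaction.reactants.items():
        if sid not in state:
            raise StructuralError(f"reaction {reaction.id!r}: species {sid!r} missing from state")
        c = state[sid]
        if c < 0:
            raise DomainError(f"negative concentration for {sid!r}: {c}")
        fwd *= c ** coef
    rev = 0.0
    if reaction.reversible:
        rev = reaction.kr.value
        for sid, coef in reaction.products.items():
            if sid not in state:
                raise StructuralError(
                    f"reaction {reaction.id!r}: species {sid!r} missing from state"
                )
            c = state[sid]
            if c < 0:
                raise DomainError(f"negative concentration for {sid!r}: {c}")
            rev *= c ** coef
    return fwd - rev


def stoichiometry_matrix(model: Model) -> StoichiometryMatrix:
    """Net stoichiometry matrix N with N[i, j] = products − reactants of
    species i in reaction j, in model ordering."""
    n = np.zeros((model.n_species, model.n_reactions), dtype=int)
    for j, rxn in enumerate(model.reactions):
        for sid, coef in rxn.reactants.items():
            n[model.species_index(sid), j] -= coef
        for sid, coef in rxn.products.items():
            n[model.species_index(sid), j] += coef
    return StoichiometryMatrix(
        matrix=n,
        species_ids=[s.id for s in model.species],
        reaction_ids=[r.id for r in model.reactions],
    )


def _flux_vector(model: Model, state: np.ndarray) -> np.ndarray:
    """All net reaction fluxes at ``state`` (no domain checks; internal)."""
    v = np.empty(model.n_reactions)
    for j, rxn in enumerate(model.reactions):
        fwd = rxn.kf.value
        for sid, coef in rxn.reactants.items():
            c = state[model._index[sid]]
            fwd *= c if coef == 1 else c ** coef
        rev = 0.0
        if rxn.reversible:
            rev = rxn.kr.value
            for sid, coef in rxn.products.items():
                c = state[model._index[sid]]
                rev *= c if coef == 1 else c ** coef
        v[j] = fwd - rev
    return v


def ode_rhs(model: Model, state: np.ndarray, time: float = 0.0) -> np.ndarray:
    """Right-hand side dx/dt = N·v(x), μM/s.

    Assignment rules are applied before flux evaluation; rate rules override
    the stoichiometric derivative of their target; boundary species get a
    zero derivative.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_species,):
        raise StructuralError(
            f"state length {state.shape} does not match species count {model.n_species}"
        )
    if not np.all(np.isfinite(state)):
        raise DomainError("non-finite state passed to ode_rhs")
    x = model.apply_assignment_rules(state, time)
    n = stoichiometry_matrix(model).matrix
    dx = n @ _flux_vector(model, x)
    for ru, code in model._compiled_rules:
        if ru.kind == "rate":
            env = model._rule_env(x, time)
            dx[model.species_index(ru.target)] = eval(code, {"__builtins__": {}}, env)
    for i, sp in enumerate(model.species):
        if sp.is_boundary:
            dx[i] = 0.0
        elif any(ru.kind == "assignment" and ru.target == sp.id for ru in model.rules):
            # assignment-ruled species are algebraic, not integrated
            dx[i] = 0.0
    return dx


def conserved_moieties(model: Model) -> list:
    """Integer basis of conservation vectors c with cᵀN = 0.

    Computed over the exact rational null space of Nᵀ (sympy), restricted to
    non-boundary, non-rule-targeted species; each basis vector is scaled to
    coprime integers.  Species held fixed by a boundary flag or rule are
    excluded because their clamped dynamics break the algebraic conservation.
    """
    import sympy

    n = stoichiometry_matrix(model).matrix
    ruled = {ru.target for ru in model.rules}
    free_idx = [
        i for i, s in enumerate(model.species) if not s.is_boundary and s.id not in ruled
    ]
    if not free_idx:
        return []
    sub = sympy.Matrix(n[free_idx, :])
    basis = sub.T.nullspace()
    out = []
    for vec in basis:
        fracs = [Fraction(sympy.Rational(v).p, sympy.Rational(v).q) for v in vec]
        lcm = 1
        for f in fracs:
            lcm = lcm * f.denominator // math.gcd(lcm, f.denominator)
        ints = [int(f * lcm) for f in fracs]
        g = 0
        for v in ints:
            g = math.gcd(g, abs(v))
        if g > 1:
            ints = [v // g for v in ints]
        if sum(ints) < 0:  # canonical sign
            ints = [-v for v in ints]
        full = np.zeros(model.n_species, dtype=int)
        for k, i in enumerate(free_idx):
            full[i] = ints[k]
        out.append(full)
    return out


def validate_model(model: Model) -> ValidationReport:
    """Check structural consistency, value domains and rate-constant units.

    Returns a report; an empty report means the model is usable.  Model
    construction already rejects duplicate ids, so this focuses on
    references, values and orders.
    """
    rep = ValidationReport()
    declared = set(model._index)
    for sp in model.species:
        if sp.initial_concentration < 0:
            rep.domain.append(
                f"species {sp.id}: negative initial concentration {sp.initial_concentration}"
            )
    for rxn in model.reactions:
        for sid in list(rxn.reactants) + list(rxn.products):
            if sid not in declared:
                rep.structural.append(f"reaction {rxn.id}: undeclared species {sid!r}")
        order = rxn.reactant_order
        if order not in (1, 2):
            rep.structural.append(
                f"reaction {rxn.id}: total reactant stoichiometry {order} not in {{1, 2}}"
            )
        if rxn.kf.order != order:
            rep.units.append(
                f"reaction {rxn.id}: kf order {rxn.kf.order} != reactant order {order}"
            )
        if rxn.kf.value < 0:
            rep.domain.append(f"reaction {rxn.id}: negative kf {rxn.kf.value}")
        if rxn.reversible:
            porder = rxn.product_order
            if rxn.kr.order != porder:
                rep.units.append(
                    f"reaction {rxn.id}: kr order {rxn.kr.order} != product order {porder}"
                )
            if rxn.kr.value < 0:
                rep.domain.append(f"reaction {rxn.id}: negative kr {rxn.kr.value}")
    for ru in model.rules:
        if ru.target not in declared:
            rep.structural.append(f"rule {ru.id}: undeclared target {ru.target!r}")
        try:
            code = compile(ru.expression, "<rule>", "eval")
        except SyntaxError:
            rep.structural.append(f"rule {ru.id}: unparsable expression {ru.expression!r}")
            continue
        for name in code.co_names:
            if name not in declared and name != "t":
                rep.structural.append(f"rule {ru.id}: undeclared symbol {name!r} in expression")
    return rep
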