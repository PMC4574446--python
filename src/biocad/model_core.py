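"""Constraint-based metabolic model core: representation, FBA, I/O, fixtures.

A :class:`MetabolicModel` holds the stoichiometric matrix ``S`` (metabolites x
reactions), per-reaction flux bounds and reversibility flags.  Steady-state
flux distributions satisfy ``S v = 0`` with ``lb <= v <= ub``; flux balance
analysis (FBA) picks the distribution maximising (or minimising) a linear
objective over reactions.  Fluxes are in umol min^-1 gDW^-1.

Sign convention for exchange reactions: the exchanged metabolite carries a
coefficient of -1, so a negative flux is an uptake and a positive flux is a
production (export).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "ModelValidationError",
    "MetabolicModel",
    "FluxDistribution",
    "read_model",
    "write_tabular",
    "write_sbml",
    "solve_fba",
    "add_exchange_reaction",
    "composite_objective",
    "make_toy_mitochondrion",
    "MASS_BALANCE_TOL",
]

#: absolute tolerance on the steady-state residual ``S v``
MASS_BALANCE_TOL = 1e-6


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass(frozen=True)
class MetabolicModel:
    """Immutable constraint-based model.

    Parameters
    ----------
    stoichiometry : ndarray, shape (n_metabolites, n_reactions)
        Dimensionless stoichiometric coefficients.
    lower_bounds, upper_bounds : ndarray
        Per-reaction flux bounds.
    reversible : ndarray of bool
        ``False`` implies ``lower_bound >= 0`` for that reaction.
    reaction_ids, metabolite_ids : tuple of str
        Unique identifiers.
    compartments : tuple of str
        One label per metabolite (e.g. ``matrix``, ``intermembrane``,
        ``external``).
    is_exchange : ndarray of bool
        Flags boundary pseudo-reactions.
    named_sets : dict
        Named reaction groups, e.g. ``{"biomass": [...], "inputs": [...]}``.
    """

    stoichiometry: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    reversible: np.ndarray
    reaction_ids: tuple
    metabolite_ids: tuple
    compartments: tuple
    is_exchange: np.ndarray
    named_sets: dict = field(default_factory=dict)
    #: (lb, ub) of the unscaled wild-type configuration; set by bound-scaling
    #: transforms so that repeated scaling always refers back to wild type.
    wild_type_bounds: tuple | None = None

    def __post_init__(self):
        S = np.asarray(self.stoichiometry, dtype=float)
        object.__setattr__(self, "stoichiometry", S)
        for name in ("lower_bounds", "upper_bounds"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("reversible", "is_exchange"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=bool))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "compartments", tuple(self.compartments))
        self._validate()

    def _validate(self):
        m, n = self.stoichiometry.shape
        if len(self.metabolite_ids) != m or len(self.compartments) != m:
            raise ModelValidationError("metabolite annotations do not match matrix rows")
        for vec, name in (
            (self.lower_bounds, "lower_bounds"),
            (self.upper_bounds, "upper_bounds"),
            (self.reversible, "reversible"),
            (self.is_exchange, "is_exchange"),
        ):
            if vec.shape != (n,):
                raise ModelValidationError(f"{name} does not match matrix columns")
        if len(self.reaction_ids) != n:
            raise ModelValidationError("reaction_ids do not match matrix columns")
        if len(set(self.reaction_ids)) != n:
            raise ModelValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != m:
            raise ModelValidationError("duplicate metabolite ids")
        bad = np.where(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            raise ModelValidationError(
                f"lower bound exceeds upper bound for reaction {self.reaction_ids[bad[0]]!r}"
            )
        bad = np.where(~self.reversible & (self.lower_bounds < 0))[0]
        if bad.size:
            raise ModelValidationError(
                f"irreversible reaction {self.reaction_ids[bad[0]]!r} has negative lower bound"
            )
        for set_name, ids in self.named_sets.items():
            for rid in ids:
                if rid not in self.reaction_ids:
                    raise ModelValidationError(
                        f"named set {set_name!r} references unknown reaction {rid!r}"
                    )

    # -- convenience -------------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.stoichiometry.shape[0]

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def metabolite_index(self, metabolite_id: str) -> int:
        try:
            return self.metabolite_ids.index(metabolite_id)
        except ValueError:
            raise KeyError(f"unknown metabolite {metabolite_id!r}") from None

    def with_bounds(self, lower_bounds, upper_bounds) -> "MetabolicModel":
        """Return a copy with replaced bound vectors (all else shared)."""
        return replace(
            self,
            lower_bounds=np.asarray(lower_bounds, float).copy(),
            upper_bounds=np.asarray(upper_bounds, float).copy(),
        )

    def exchange_ids(self) -> list:
        return [r for r, ex in zip(self.reaction_ids, self.is_exchange) if ex]


@dataclass(frozen=True)
class FluxDistribution:
    """One steady-state solution: flux vector, objective value and status."""

    fluxes: np.ndarray
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def __post_init__(self):
        object.__setattr__(self, "fluxes", np.asarray(self.fluxes, dtype=float))

    def to_csv(self, path, model: MetabolicModel):
        with open(path, "w") as fh:
            fh.write("reaction_id,flux\n")
            for rid, v in zip(model.reaction_ids, self.fluxes):
                fh.write(f"{rid},{float(v)!r}\n")

    def to_json(self, path, model: MetabolicModel):
        payload = {
            "status": self.status,
            "objective_value": self.objective_value,
            "fluxes": dict(zip(model.reaction_ids, map(float, self.fluxes))),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# FBA


def solve_fba(model: MetabolicModel, objective: dict, sense: str = "max") -> FluxDistribution:
    """Solve ``opt w'v  s.t.  S v = 0, lb <= v <= ub`` with the HiGHS LP solver.

    Parameters
    ----------
    objective : dict
        Mapping ``reaction_id -> weight``.
    sense : {"max", "min"}

    Returns
    -------
    FluxDistribution
        ``status`` is ``"optimal"``, ``"infeasible"`` or ``"unbounded"``;
        non-optimal results carry NaN fluxes, never silent zeros.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    n = model.n_reactions
    c = np.zeros(n)
    for rid, w in objective.items():
        c[model.reaction_index(rid)] = w
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=model.stoichiometry,
        b_eq=np.zeros(model.n_metabolites),
        bounds=list(zip(model.lower_bounds, model.upper_bounds)),
        method="highs",
    )
    if res.status == 0:
        return FluxDistribution(res.x, float(sign * res.fun), "optimal")
    status = "infeasible" if res.status == 2 else "unbounded" if res.status == 3 else "infeasible"
    return FluxDistribution(np.full(n, np.nan), float("nan"), status)


def add_exchange_reaction(
    model: MetabolicModel, metabolite_id: str, lb: float, ub: float
) -> MetabolicModel:
    """Return a new model with an exchange reaction for *metabolite_id*.

    The new column has a single ``-1`` coefficient on the metabolite, so a
    positive flux exports it.  Adding a second exchange for a metabolite that
    already has one is an error.
    """
    mi = model.metabolite_index(metabolite_id)
    for j in np.where(model.is_exchange)[0]:
        col = model.stoichiometry[:, j]
        if col[mi] != 0:
            raise ModelValidationError(
                f"metabolite {metabolite_id!r} already has exchange "
                f"{model.reaction_ids[j]!r}"
            )
    rid = f"EX_{metabolite_id}"
    if rid in model.reaction_ids:
        rid = f"EX_{metabolite_id}_b"
    col = np.zeros((model.n_metabolites, 1))
    col[mi, 0] = -1.0
    return MetabolicModel(
        stoichiometry=np.hstack([model.stoichiometry, col]),
        lower_bounds=np.append(model.lower_bounds, lb),
        upper_bounds=np.append(model.upper_bounds, ub),
        reversible=np.append(model.reversible, lb < 0),
        reaction_ids=model.reaction_ids + (rid,),
        metabolite_ids=model.metabolite_ids,
        compartments=model.compartments,
        is_exchange=np.append(model.is_exchange, True),
        named_sets=dict(model.named_sets),
    )


def composite_objective(model: MetabolicModel, reaction_ids, exclude=()) -> dict:
    """Unit-weight objective over *reaction_ids* minus *exclude*.

    Expresses composite targets such as "biomass = sum of the biomass
    component fluxes except ATP".
    """
    for rid in list(reaction_ids) + list(exclude):
        model.reaction_index(rid)  # raises KeyError on unknown ids
    kept = [rid for rid in reaction_ids if rid not in set(exclude)]
    if not kept:
        raise ValueError("composite objective excludes every reaction")
    return {rid: 1.0 for rid in kept}


# ---------------------------------------------------------------------------
# Tabular dialect
#
# One reaction per line: `id TAB formula TAB lb TAB ub` with formulas like
# `2 A + B -> C` (`<->` marks reversibility, empty sides are allowed for
# boundary reactions).


def _parse_side(text: str):
    terms = []
    text = text.strip()
    if not text:
        return terms
    for chunk in text.split("+"):
        parts = chunk.split()
        if not parts:
            raise ModelValidationError(f"empty term in formula side {text!r}")
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            coef, met = float(parts[0]), parts[1]
        else:
            raise ModelValidationError(f"cannot parse formula term {chunk!r}")
        terms.append((met, coef))
    return terms


def _format_side(terms):
    out = []
    for met, coef in terms:
        out.append(met if coef == 1 else f"{coef:g} {met}")
    return " + ".join(out)


def _read_tabular(path) -> MetabolicModel:
    reactions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ModelValidationError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            rid, formula, lb_s, ub_s = fields
            rid = rid.strip()
            lb, ub = float(lb_s), float(ub_s)
            if lb > ub:
                raise ModelValidationError(
                    f"{path}:{lineno}: reaction {rid!r} has lb={lb} > ub={ub}"
                )
            if "<->" in formula:
                left, right = formula.split("<->")
                rev = True
            elif "->" in formula:
                left, right = formula.split("->")
                rev = lb < 0  # directionality inferred from bounds
            else:
                raise ModelValidationError(f"{path}:{lineno}: formula lacks an arrow")
            subs = _parse_side(left)
            prods = _parse_side(right)
            reactions.append((rid, subs, prods, lb, ub, rev))

    met_ids = []
    for _, subs, prods, *_ in reactions:
        for met, _ in subs + prods:
            if met not in met_ids:
                met_ids.append(met)
    S = np.zeros((len(met_ids), len(reactions)))
    lbs, ubs, revs, rids, is_ex = [], [], [], [], []
    for j, (rid, subs, prods, lb, ub, rev) in enumerate(reactions):
        for met, coef in subs:
            S[met_ids.index(met), j] -= coef
        for met, coef in prods:
            S[met_ids.index(met), j] += coef
        lbs.append(lb)
        ubs.append(ub)
        revs.append(rev)
        rids.append(rid)
        is_ex.append(np.count_nonzero(S[:, j]) == 1)
    return MetabolicModel(
        stoichiometry=S,
        lower_bounds=lbs,
        upper_bounds=ubs,
        reversible=revs,
        reaction_ids=rids,
        metabolite_ids=met_ids,
        compartments=["matrix"] * len(met_ids),
        is_exchange=is_ex,
    )


def write_tabular(model: MetabolicModel, path):
    """Write the model in the flat tabular dialect (named sets are lost)."""
    with open(path, "w") as fh:
        for j, rid in enumerate(model.reaction_ids):
            col = model.stoichiometry[:, j]
            subs = [(model.metabolite_ids[i], -col[i]) for i in np.where(col < 0)[0]]
            prods = [(model.metabolite_ids[i], col[i]) for i in np.where(col > 0)[0]]
            arrow = "<->" if model.reversible[j] else "->"
            fh.write(
                f"{rid}\t{_format_side(subs)} {arrow} {_format_side(prods)}"
                f"\t{float(model.lower_bounds[j])!r}\t{float(model.upper_bounds[j])!r}\n"
            )


# ---------------------------------------------------------------------------
# SBML (through cobrapy, used for serialization only)


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (for SBML serialization or cross-checks)."""
    import cobra

    cm = cobra.Model("biocad_model")
    mets = [
        cobra.Metabolite(mid, compartment=comp)
        for mid, comp in zip(model.metabolite_ids, model.compartments)
    ]
    met_by_id = {m.id: m for m in mets}
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        r = cobra.Reaction(rid)
        r.lower_bound = float(model.lower_bounds[j])
        r.upper_bound = float(model.upper_bounds[j])
        rxns.append(r)
    cm.add_reactions(rxns)
    for j, r in enumerate(rxns):
        col = model.stoichiometry[:, j]
        r.add_metabolites(
            {met_by_id[model.metabolite_ids[i]]: float(col[i]) for i in np.nonzero(col)[0]}
        )
    return cm


def from_cobra(cm) -> MetabolicModel:
    met_ids = [m.id for m in cm.metabolites]
    comps = [m.compartment or "matrix" for m in cm.metabolites]
    n = len(cm.reactions)
    S = np.zeros((len(met_ids), n))
    lbs = np.zeros(n)
    ubs = np.zeros(n)
    rids = []
    for j, r in enumerate(cm.reactions):
        rids.append(r.id)
        lbs[j], ubs[j] = r.lower_bound, r.upper_bound
        for met, coef in r.metabolites.items():
            S[met_ids.index(met.id), j] = coef
    is_ex = np.array([np.count_nonzero(S[:, j]) == 1 for j in range(n)])
    return MetabolicModel(
        stoichiometry=S,
        lower_bounds=lbs,
        upper_bounds=ubs,
        reversible=lbs < 0,
        reaction_ids=rids,
        metabolite_ids=met_ids,
        compartments=comps,
        is_exchange=is_ex,
    )


def write_sbml(model: MetabolicModel, path):
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


def read_model(path, format: str = "tabular") -> MetabolicModel:
    """Read a model from *path* in the ``tabular`` or ``sbml`` format.

    Reaction directionality is inferred from the bounds when explicit
    reversibility markers are absent (``lb < 0`` implies reversible).
    """
    if format == "tabular":
        return _read_tabular(path)
    if format == "sbml":
        from cobra.io import read_sbml_model

        return from_cobra(read_sbml_model(str(path)))
    raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Toy mitochondrion fixture


_TOY_EXCHANGES = [
    # id, metabolite, lb, ub (pre-jitter nominal capacities)
    ("EX_glc", "glc", -10.0, 0.0),
    ("EX_o2", "o2", -200.0, 0.0),
    ("EX_aa1", "aa1", -5.0, 0.0),
    ("EX_aa2", "aa2", -5.0, 0.0),
    ("EX_hb", "hb", -5.0, 0.0),
    ("EX_lac", "lac", -5.0, 5.0),
    ("EX_co2", "co2", 0.0, 10000.0),
]

_TOY_CORE = [
    # id, substrates, products, lb, ub
    ("GLYC", [("glc", 1)], [("pyr", 2), ("nadh", 2), ("atp", 2)], 0.0, 10000.0),
    ("LDH", [("pyr", 1), ("nadh", 1)], [("lac", 1)], -10000.0, 10000.0),
    ("PDH", [("pyr", 1)], [("accoa", 1), ("nadh", 1), ("co2", 1)], 0.0, 10000.0),
    ("TCA", [("accoa", 1)], [("nadh", 4), ("co2", 2)], 0.0, 10000.0),
    ("ETC", [("nadh", 1), ("o2", 0.5)], [("atp", 2.5)], 0.0, 10000.0),
    ("AA1CAT", [("aa1", 1)], [("pyr", 1), ("nadh", 1)], 0.0, 10000.0),
    ("AA2CAT", [("aa2", 1)], [("accoa", 1), ("nadh", 1)], 0.0, 10000.0),
    ("HBCAT", [("hb", 1)], [("accoa", 2), ("nadh", 1)], 0.0, 10000.0),
    ("BIO_AA", [("aa1", 1), ("atp", 2)], [], 0.0, 10000.0),
    ("BIO_LIP", [("accoa", 1), ("atp", 1)], [], 0.0, 10000.0),
    ("ATP_DRAIN", [("atp", 1)], [], 0.0, 10000.0),
]

_TOY_COMPARTMENTS = {"o2": "intermembrane", "co2": "intermembrane"}


def make_toy_mitochondrion(seed: int, include_nadh_exchange: bool = True) -> MetabolicModel:
    """Deterministic desk-scale mitochondrion stand-in (synthetic).

    An 18/19-reaction network with lumped glycolysis, pyruvate oxidation, a
    TCA-like NADH factory, an O2-consuming electron-transport reaction
    producing ATP, amino-acid and ketone-body catabolism, two biomass
    component reactions and an ATP drain.  Substrate uptake capacities are
    jittered +-10% by *seed* (the network topology is fixed), so the same
    seed always yields a bitwise-identical model.

    By construction wild-type max-ATP is strictly positive, O2 availability
    is the single most influential uptake bound for ATP production, and
    closing the O2 exchange strictly lowers the ATP optimum.
    """
    rng = np.random.default_rng(seed)
    met_ids, comps = [], []

    def ensure(met):
        if met not in met_ids:
            met_ids.append(met)
            comps.append(_TOY_COMPARTMENTS.get(met, "matrix"))

    reactions = []
    for rid, met, lb, ub in _TOY_EXCHANGES:
        jit = 1.0 + 0.1 * (2.0 * rng.random() - 1.0)
        reactions.append((rid, [(met, 1)], [], lb * jit if lb < 0 else lb, ub * jit if ub > 0 else ub, True))
    if include_nadh_exchange:
        # export-only: the inner membrane is impermeable to NADH, so the
        # exchange measures NADH availability (production), never uptake;
        # the cap sits above the attainable supply so redox budget, not the
        # bound, limits export
        jit = 1.0 + 0.1 * (2.0 * rng.random() - 1.0)
        reactions.append(("EX_nadh", [("nadh", 1)], [], 0.0, 300.0 * jit, True))
    for rid, subs, prods, lb, ub in _TOY_CORE:
        reactions.append((rid, subs, prods, lb, ub, False))

    for _, subs, prods, *_ in reactions:
        for met, _ in subs + prods:
            ensure(met)

    S = np.zeros((len(met_ids), len(reactions)))
    lbs, ubs, revs, rids, is_ex = [], [], [], [], []
    for j, (rid, subs, prods, lb, ub, ex) in enumerate(reactions):
        for met, coef in subs:
            S[met_ids.index(met), j] -= coef
        for met, coef in prods:
            S[met_ids.index(met), j] += coef
        rids.append(rid)
        lbs.append(lb)
        ubs.append(ub)
        revs.append(lb < 0)
        is_ex.append(ex)

    named_sets = {
        "biomass": ["BIO_AA", "BIO_LIP"],
        "atp_demand": ["ATP_DRAIN"],
        "inputs": ["EX_glc", "EX_o2", "EX_aa1", "EX_aa2", "EX_hb", "EX_lac"],
    }
    if include_nadh_exchange:
        named_sets["nadh_exchange"] = ["EX_nadh"]
    return MetabolicModel(
        stoichiometry=S,
        lower_bounds=lbs,
        upper_bounds=ubs,
        reversible=revs,
        reaction_ids=rids,
        metabolite_ids=met_ids,
        compartments=comps,
        is_exchange=is_ex,
        named_sets=named_sets,
    )
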