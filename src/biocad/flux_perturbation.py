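"""Decision-vector encodings over model fluxes.

Two modes are supported.  ``input_fluxes`` optimizes the environment: each
decision variable is the uptake capacity (or, for pinned targets, the exact
flux) of an exchange reaction, and every candidate is scored by an inner FBA
solve.  ``internal_fluxes`` treats a full steady-state flux vector as the
candidate itself; its companion mutation operator perturbs up to ``C``
fluxes, repairs the rest by an LP feasibility solve, and retries up to ``N``
times before falling back to the parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_core import MASS_BALANCE_TOL, MetabolicModel, solve_fba
from .pareto import ObjectiveSpec

__all__ = ["FluxDecision", "evaluator_for", "mutate_internal_fluxes", "MAX_UPTAKE"]

#: default cap on any uptake magnitude (umol min^-1 gDW^-1)
MAX_UPTAKE = 1000.0


@dataclass(frozen=True)
class FluxDecision:
    """What the decision vector means in terms of the model.

    Parameters
    ----------
    mode : {"input_fluxes", "internal_fluxes"}
    targets : tuple of str
        Reaction ids the decision vector controls.  In input mode these must
        be exchange reactions; in internal mode an empty tuple means "every
        reaction" (the decision vector is a full flux vector).
    pinned : tuple of str
        Input-mode targets whose exchange flux is fixed at the decision
        value (``lb = ub = x``) instead of being capped (``lb = -x``).
    max_uptake : float
        Upper limit on any uptake magnitude.
    """

    mode: str
    targets: tuple = ()
    pinned: tuple = ()
    max_uptake: float = MAX_UPTAKE

    def __post_init__(self):
        if self.mode not in ("input_fluxes", "internal_fluxes"):
            raise ValueError(f"unknown decision mode {self.mode!r}")
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "pinned", tuple(self.pinned))

    def validate(self, model: MetabolicModel):
        for rid in self.targets + self.pinned:
            j = model.reaction_index(rid)
            if self.mode == "input_fluxes" and not model.is_exchange[j]:
                raise ValueError(f"input-flux target {rid!r} is not an exchange reaction")
        for rid in self.pinned:
            if rid not in self.targets:
                raise ValueError(f"pinned id {rid!r} is not among the targets")

    def bounds_for(self, model: MetabolicModel):
        """Decision box: capped targets get [0, min(|wt lb|, cap)], pinned
        targets keep their wild-type flux range."""
        self.validate(model)
        box = []
        for rid in self.targets:
            j = model.reaction_index(rid)
            if rid in self.pinned:
                box.append((model.lower_bounds[j], model.upper_bounds[j]))
            else:
                cap = min(abs(model.lower_bounds[j]), self.max_uptake)
                box.append((0.0, cap))
        return box


def _inner_objective(model: MetabolicModel, spec: ObjectiveSpec, decision: FluxDecision):
    """Weights for the inner FBA solve: the declared objectives that are not
    already pinned by the decision vector, signed by their sense."""
    weights = {}
    for name, sense in zip(spec.names, spec.senses):
        if decision.mode == "input_fluxes" and name in decision.pinned:
            continue
        weights[name] = 1.0 if sense == "max" else -1.0
    if not weights:  # every objective pinned: any feasible vertex will do
        weights = {spec.names[0]: 1.0}
    return weights


def evaluator_for(decision: FluxDecision, model: MetabolicModel, spec: ObjectiveSpec):
    """Build an ``x -> (objectives, constraint value)`` adapter for the optimizer.

    Input mode: map the decision vector to exchange bounds (uptake
    magnitudes are clipped to the cap), run FBA maximizing the non-pinned
    objectives, and read the objective fluxes off the solution; an
    infeasible FBA yields ``(None, None)`` (maximal violation).

    Internal mode: the candidate *is* a flux vector; objectives are read
    directly and the constraint value is the steady-state residual norm
    (plus any bound excess), so the feasibility threshold acts on mass
    balance.
    """
    decision.validate(model)
    for name in spec.names:
        model.reaction_index(name)
    obj_idx = [model.reaction_index(name) for name in spec.names]

    if decision.mode == "input_fluxes":
        from ._glpk import ReusableFBA

        inner = _inner_objective(model, spec, decision)
        tgt_idx = [model.reaction_index(r) for r in decision.targets]
        pinned_mask = [r in decision.pinned for r in decision.targets]
        lp = ReusableFBA(model)
        lp.set_objective(inner, "max")

        def evaluate(x):
            x = np.asarray(x, dtype=float)
            lbs = model.lower_bounds.copy()
            ubs = model.upper_bounds.copy()
            for xi, j, pin in zip(x, tgt_idx, pinned_mask):
                if pin:
                    lbs[j] = ubs[j] = np.clip(xi, model.lower_bounds[j], model.upper_bounds[j])
                else:
                    mag = min(max(xi, 0.0), decision.max_uptake)
                    lbs[j] = -mag
            status, _, fluxes = lp.solve(lbs, ubs)
            if status != "optimal":
                return None, None
            return tuple(float(fluxes[j]) for j in obj_idx), 0.0

        return evaluate

    # internal_fluxes
    def evaluate(v):
        v = np.asarray(v, dtype=float)
        if v.shape != (model.n_reactions,):
            raise ValueError("internal-flux candidate must be a full flux vector")
        residual = float(np.abs(model.stoichiometry @ v).max())
        excess = float(
            np.maximum(
                np.maximum(model.lower_bounds - v, v - model.upper_bounds), 0.0
            ).max()
        )
        return tuple(float(v[j]) for j in obj_idx), max(residual, excess)

    return evaluate


def _steady_state_ok(model: MetabolicModel, v: np.ndarray, tol: float) -> bool:
    scale = max(1.0, float(np.abs(v).max()))
    if np.abs(model.stoichiometry @ v).max() > tol * scale:
        return False
    slack = tol * scale
    return bool(
        np.all(v >= model.lower_bounds - slack) and np.all(v <= model.upper_bounds + slack)
    )


def mutate_internal_fluxes(
    v,
    model: MetabolicModel,
    C: int,
    N: int,
    rng: np.random.Generator,
    targets=None,
    tol: float = MASS_BALANCE_TOL,
):
    """Perturb up to *C* fluxes of a feasible flux vector and repair the rest.

    Picks ``k ~ Uniform{1..C}`` target fluxes, redraws each uniformly inside
    its own bounds (an irreversible reaction can never receive a negative
    value because its lower bound is non-negative), fixes them as equality
    constraints and solves an LP feasibility problem for the remaining
    fluxes.  On infeasibility the draw is repeated, up to *N* trials; after
    *N* failures the parent vector is returned unchanged.
    """
    if C < 1 or N < 1:
        raise ValueError("C and N must both be >= 1")
    v = np.asarray(v, dtype=float)
    if not _steady_state_ok(model, v, tol):
        raise ValueError("parent flux vector is not steady-state feasible")
    if targets is None:
        cand = np.arange(model.n_reactions)
    else:
        cand = np.array([model.reaction_index(r) for r in targets])
    for _ in range(N):
        k = int(rng.integers(1, C + 1))
        k = min(k, cand.size)
        chosen = rng.choice(cand, size=k, replace=False)
        lbs = model.lower_bounds.copy()
        ubs = model.upper_bounds.copy()
        for j in chosen:
            val = rng.uniform(model.lower_bounds[j], model.upper_bounds[j])
            lbs[j] = ubs[j] = val
        res = linprog(
            np.zeros(model.n_reactions),
            A_eq=model.stoichiometry,
            b_eq=np.zeros(model.n_metabolites),
            bounds=list(zip(lbs, ubs)),
            method="highs",
        )
        if res.status == 0:
            return res.x
    return v.copy()
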