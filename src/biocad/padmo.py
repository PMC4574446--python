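"""Protein-Abundance Design through Multi-objective Optimization (PADMO).

A protein abundance ``y_i >= 0`` (dimensionless, wild type = 1) controls the
flux bounds of the reaction it catalyses through the piecewise logarithmic
multiplier

    f(y) = 1 + ln(y)          for y > 1
    f(y) = 1 / (1 + |ln(y)|)  for 0 < y < 1
    f(1) = 1                  (removable discontinuity)
    f(0) = 0                  (limit: a knockout)

Both bounds of the controlled reaction are scaled: ``lb = LB_wt * f(y)``,
``ub = UB_wt * f(y)``, always from the stored wild-type bounds.  The
logarithmic damping keeps the evolutionary search from drifting to
implausibly large abundances; the ``y -> 0`` limit closes the reaction, so a
pure knockout design is the binary special case of the abundance design.

The optimization itself runs through :func:`biocad.optbiocad.run_optbiocad`
with the abundance array as the decision vector; each Pareto point therefore
carries a concrete protein-abundance profile, not only an objective vector.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import MetabolicModel, solve_fba
from .optbiocad import OptConfig, RunResult, run_optbiocad
from .pareto import ObjectiveSpec

__all__ = [
    "AbundanceProfile",
    "abundance_multiplier",
    "apply_abundances",
    "run_padmo",
    "read_profile_csv",
    "write_profile_csv",
]


def abundance_multiplier(y):
    """Flux-bound multiplier f(y) for a protein abundance ``y >= 0``.

    Accepts scalars or arrays; raises for negative abundances.
    """
    arr = np.asarray(y, dtype=float)
    if np.any(arr < 0):
        raise ValueError("protein abundance must be non-negative")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.empty_like(arr)
    with np.errstate(divide="ignore"):
        logs = np.where(arr > 0, np.log(np.where(arr > 0, arr, 1.0)), 0.0)
    out[arr > 1] = 1.0 + logs[arr > 1]
    inner = (arr > 0) & (arr < 1)
    out[inner] = 1.0 / (1.0 + np.abs(logs[inner]))
    out[arr == 1] = 1.0
    out[arr == 0] = 0.0
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class AbundanceProfile:
    """Abundances for a set of controlled reactions (wild type = 1)."""

    reaction_ids: tuple
    y: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if y.shape != (len(self.reaction_ids),):
            raise ValueError("one abundance per controlled reaction required")
        if np.any(y < 0):
            raise ValueError("abundances must be non-negative")

    def knockouts(self) -> list:
        return [rid for rid, yi in zip(self.reaction_ids, self.y) if yi == 0]


def apply_abundances(model: MetabolicModel, profile: AbundanceProfile) -> MetabolicModel:
    """Scale the bounds of the controlled reactions by ``f(y_i)``.

    The scaling always starts from the wild-type bounds (stored on the model
    the first time it is scaled), so applying the same profile twice equals
    applying it once; ``y_i = 0`` closes reaction *i* entirely.
    """
    if model.wild_type_bounds is not None:
        wt_lb, wt_ub = model.wild_type_bounds
    else:
        wt_lb, wt_ub = model.lower_bounds, model.upper_bounds
    lbs = wt_lb.copy()
    ubs = wt_ub.copy()
    for rid, yi in zip(profile.reaction_ids, profile.y):
        j = model.reaction_index(rid)
        fy = abundance_multiplier(yi)
        lbs[j] = wt_lb[j] * fy
        ubs[j] = wt_ub[j] * fy
    return replace(
        model,
        lower_bounds=lbs,
        upper_bounds=ubs,
        wild_type_bounds=(wt_lb.copy(), wt_ub.copy()),
    )


def _objective_weights(model: MetabolicModel, spec: ObjectiveSpec):
    """Resolve each objective name to FBA weights: a reaction id or the name
    of a reaction set in ``model.named_sets`` (summed with unit weights)."""
    weight_sets = []
    for name in spec.names:
        if name in model.named_sets:
            weight_sets.append({rid: 1.0 for rid in model.named_sets[name]})
        else:
            model.reaction_index(name)
            weight_sets.append({name: 1.0})
    return weight_sets


def wild_type_point(model: MetabolicModel, spec: ObjectiveSpec) -> np.ndarray:
    """Objective vector of the unscaled model, one FBA solve per objective."""
    out = []
    for weights, sense in zip(_objective_weights(model, spec), spec.senses):
        sol = solve_fba(model, weights, sense)
        if sol.status != "optimal":
            raise RuntimeError("wild-type model does not solve to optimality")
        out.append(sol.objective_value)
    return np.array(out)


def run_padmo(
    model: MetabolicModel,
    spec: ObjectiveSpec,
    config: OptConfig,
    controlled=None,
    y_max: float = 100.0,
    y_min: float = 0.0,
    binary: bool = False,
    max_knockouts: int | None = None,
) -> RunResult:
    """Optimize protein abundances (the decision vector is ``y``).

    Parameters
    ----------
    controlled : sequence of reaction ids, optional
        Reactions under abundance control; defaults to all non-exchange
        reactions.
    y_max : float
        Search-box ceiling for each abundance.
    binary : bool
        Restrict abundances to {0, 1} (decision values are thresholded at
        0.5), which reduces PADMO to a knockout search.
    max_knockouts : int, optional
        Feasibility constraint on the number of closed reactions.

    Each objective name is either a reaction id or a key of
    ``model.named_sets`` (e.g. ``"biomass"``), in which case the member
    fluxes are summed.  Every objective is scored by its own FBA solve on
    the abundance-scaled model.
    """
    if controlled is None:
        controlled = [
            rid for rid, ex in zip(model.reaction_ids, model.is_exchange) if not ex
        ]
    controlled = tuple(controlled)
    weight_sets = _objective_weights(model, spec)

    def evaluate(x):
        y = np.where(np.asarray(x) >= 0.5, 1.0, 0.0) if binary else np.asarray(x, float)
        profile = AbundanceProfile(controlled, y)
        scaled = apply_abundances(model, profile)
        objs = []
        for weights, sense in zip(weight_sets, spec.senses):
            sol = solve_fba(scaled, weights, sense)
            if sol.status != "optimal":
                return None, None
            objs.append(sol.objective_value)
        g = 0.0
        if max_knockouts is not None:
            g = float(len(profile.knockouts()) - max_knockouts)
        return tuple(objs), g

    hi = 1.0 if binary else y_max
    bounds = [(0.0 if binary else y_min, hi)] * len(controlled)
    result = run_optbiocad(evaluate, bounds, spec, config)
    if binary:
        result.cumulative_front = type(result.cumulative_front).from_points(
            result.cumulative_front.objectives,
            np.where(result.cumulative_front.decisions >= 0.5, 1.0, 0.0),
            spec,
            generation=result.cumulative_front.generation,
        )
    return result


def write_profile_csv(profile: AbundanceProfile, path):
    with open(path, "w") as fh:
        fh.write("reaction_id,abundance\n")
        for rid, yi in zip(profile.reaction_ids, profile.y):
            fh.write(f"{rid},{float(yi)!r}\n")


def read_profile_csv(path) -> AbundanceProfile:
    rids, ys = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("reaction_id"):
            raise ValueError("profile CSV must start with a reaction_id,abundance header")
        for line in fh:
            if not line.strip():
                continue
            rid, val = line.rsplit(",", 1)
            rids.append(rid.strip())
            ys.append(float(val))
    return AbundanceProfile(tuple(rids), np.array(ys))
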