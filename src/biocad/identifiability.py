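"""Identifiability analysis: ACE transformations, MOTA grouping, disease scans.

A flux is *structurally non-identifiable* when it is tied to other fluxes by
a functional relation, so no unique value can be inferred for it.  To detect
such relations we collect many optimal flux distributions (columns of a scan
matrix, one per pinned value of a disease-associated reaction) and look for
variables whose values can be predicted from other variables after optimal
nonlinear transformation.

The ACE (alternating conditional expectations) algorithm estimates the
transformations: given a response ``x_i`` and predictors ``x_j`` it
alternates the conditional-expectation updates

    beta_j <- E[ alpha - sum_{l != j} beta_l | x_j ]
    alpha  <- E[ sum_j beta_j | x_i ] / || . ||

(with a scatterplot smoother standing in for the conditional expectations)
until the squared residual of ``alpha(x_i) = sum_j beta_j(x_j)`` stops
improving.  ``r^2 = 1 - SS_res / Var(alpha)`` measures how much of the
transformed response the predictors explain; for jointly Gaussian/linear
data the square root equals the absolute Pearson correlation.

MOTA (mean optimal transformation approach) runs ACE once per variable as
response, ranks the predictors by the variance of their fitted
transformations, and reports a functional group whenever a small predictor
set reaches the ``r^2`` threshold.  A group recovered from two or more of
its own members as response is flagged *strong*.  The coefficient of
variation ``cv = std/mean`` of each member is attached as a practical
identifiability annotation.

Disease characterization pins the flux of the impaired reaction over a grid
spanning ``[0, wild-type optimum]``, recomputes the FBA optimum at every
pinned value, classifies each column into healthy / inflammation / disease
by its ATP output (or by explicit flux breakpoints) and reports the
functional groups stage by stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_core import MetabolicModel, solve_fba

__all__ = [
    "ScanMatrix",
    "TransformationSet",
    "FunctionalGroup",
    "disease_scan",
    "classify_stage",
    "ace",
    "mota_groups",
    "characterize_disease",
    "write_group_report",
]

STAGES = ("healthy", "inflammation", "disease")


def _is_constant(col: np.ndarray, rtol: float = 1e-9) -> bool:
    """Numerically constant columns carry no identifiability information."""
    return float(np.std(col)) <= rtol * max(1.0, float(np.abs(col).max()))


# ---------------------------------------------------------------------------
# Fixed-flux scans and stage classification


@dataclass(frozen=True)
class ScanMatrix:
    """Optimal flux distributions under a range of pinned flux values.

    ``V`` has one row per reaction and one column per grid value; columns
    where the pinned problem is infeasible are all-NaN and flagged in
    ``feasible``.
    """

    V: np.ndarray
    reaction_id: str
    grid: np.ndarray
    objective: dict
    objective_values: np.ndarray
    feasible: np.ndarray
    reaction_ids: tuple

    def row(self, reaction_id: str) -> np.ndarray:
        return self.V[self.reaction_ids.index(reaction_id)]


def disease_scan(model: MetabolicModel, reaction_id: str, grid, objective: dict) -> ScanMatrix:
    """Pin ``lb = ub = g`` on *reaction_id* for every grid value and re-solve.

    Grid values must lie within the reaction's wild-type bounds.  Each
    feasible column is a full optimal flux vector for *objective* (maximized).
    """
    j = model.reaction_index(reaction_id)
    grid = np.asarray(grid, dtype=float)
    lo, hi = model.lower_bounds[j], model.upper_bounds[j]
    if np.any(grid < lo) or np.any(grid > hi):
        raise ValueError(
            f"grid values outside the wild-type bounds [{lo}, {hi}] of {reaction_id!r}"
        )
    V = np.full((model.n_reactions, grid.size), np.nan)
    obj_vals = np.full(grid.size, np.nan)
    feas = np.zeros(grid.size, dtype=bool)
    for k, g in enumerate(grid):
        lbs = model.lower_bounds.copy()
        ubs = model.upper_bounds.copy()
        lbs[j] = ubs[j] = g
        sol = solve_fba(model.with_bounds(lbs, ubs), objective, "max")
        if sol.status == "optimal":
            V[:, k] = sol.fluxes
            obj_vals[k] = sol.objective_value
            feas[k] = True
    return ScanMatrix(
        V=V,
        reaction_id=reaction_id,
        grid=grid,
        objective=dict(objective),
        objective_values=obj_vals,
        feasible=feas,
        reaction_ids=model.reaction_ids,
    )


def classify_stage(atp: float, atp_normal: float) -> str:
    """Label a condition by its ATP output relative to the healthy optimum.

    ``ratio <= 0.33`` is *disease*, ``0.33 < ratio <= 0.66`` is
    *inflammation*, anything above is *healthy*; both thresholds are
    inclusive on the lower side.  Total on [0, inf).
    """
    if atp_normal <= 0:
        raise ValueError("reference ATP production must be positive")
    if atp < 0:
        raise ValueError("ATP production cannot be negative")
    ratio = atp / atp_normal
    if ratio <= 0.33:
        return "disease"
    if ratio <= 0.66:
        return "inflammation"
    return "healthy"


# ---------------------------------------------------------------------------
# ACE


def _local_linear_matrix(x: np.ndarray, bandwidth: float) -> np.ndarray:
    """Linear smoother matrix W so that ``W y`` is the local-linear fit of y
    on x, evaluated at the sample points themselves."""
    d = x[None, :] - x[:, None]  # d[t, i] = x_i - x_t
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    s0 = w.sum(axis=1, keepdims=True)
    s1 = (w * d).sum(axis=1, keepdims=True)
    s2 = (w * d * d).sum(axis=1, keepdims=True)
    denom = s2 * s0 - s1**2
    # fall back to the kernel mean when the local design is degenerate
    bad = np.abs(denom) < 1e-300
    L = w * (s2 - d * s1)
    L = np.where(bad, w, L / np.where(bad, 1.0, denom))
    return L / L.sum(axis=1, keepdims=True)


def _default_bandwidth(x: np.ndarray) -> float:
    n = x.size
    s = np.std(x)
    if s == 0:
        return 1.0
    return 1.06 * s * n ** (-1.0 / 5.0)


@dataclass(frozen=True)
class TransformationSet:
    """ACE result: tabulated optimal transformations and diagnostics."""

    response: int
    predictors: tuple
    alpha: np.ndarray  # alpha-hat(x_response) at the sample points, unit variance
    betas: np.ndarray  # (n_predictors, n_samples)
    r_squared: float
    max_correlation: float
    beta_variances: np.ndarray
    iterations: int
    converged: bool
    sse_history: tuple = ()


def ace(
    K,
    response: int,
    predictors,
    bandwidth: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> TransformationSet:
    """Estimate optimal transformations for one response against predictors.

    Parameters
    ----------
    K : array, shape (n_samples, n_variables)
        At least 20 samples; the used columns must not be constant.
    bandwidth : float, optional
        Kernel bandwidth on standardized columns; defaults to the normal
        rule of thumb ``1.06 sigma n^{-1/5}`` per column.

    Non-convergence within *max_iter* returns the last iterate flagged
    ``converged=False``.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if n < 20:
        raise ValueError("ACE needs at least 20 samples")
    predictors = tuple(predictors)
    if response in predictors:
        raise ValueError("the response cannot be among the predictors")
    used = (response,) + predictors
    for c in used:
        if _is_constant(K[:, c]):
            raise ValueError(f"column {c} is constant; it carries no information")

    xi = K[:, response]
    smoothers = {}
    for c in used:
        bw = bandwidth if bandwidth is not None else _default_bandwidth(K[:, c])
        smoothers[c] = _local_linear_matrix(K[:, c], bw)

    # printed starting point: alpha = x_i / ||x_i||, all betas zero
    alpha = xi / np.linalg.norm(xi)
    alpha = alpha - alpha.mean()
    sd = alpha.std()
    if sd > 0:
        alpha = alpha / sd
    betas = np.zeros((len(predictors), n))

    prev_sse = np.inf
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for jj in range(len(predictors)):
            partial = alpha - betas.sum(axis=0) + betas[jj]
            betas[jj] = smoothers[predictors[jj]] @ partial
            betas[jj] -= betas[jj].mean()
        fit = betas.sum(axis=0)
        alpha = smoothers[response] @ fit
        alpha -= alpha.mean()
        sd = alpha.std()
        if sd > 0:
            alpha /= sd
        sse = float(np.mean((alpha - fit) ** 2))
        history.append(sse)
        if np.isfinite(prev_sse) and abs(prev_sse - sse) <= tol * max(prev_sse, 1e-12):
            converged = True
            break
        prev_sse = sse

    fit = betas.sum(axis=0)
    resid = alpha - fit
    var_alpha = float(np.var(alpha))
    r2 = 1.0 - float(np.mean(resid**2)) / var_alpha if var_alpha > 0 else 0.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    if fit.std() > 0 and alpha.std() > 0:
        mc = float(np.corrcoef(alpha, fit)[0, 1])
    else:
        mc = 0.0
    return TransformationSet(
        response=response,
        predictors=predictors,
        alpha=alpha,
        betas=betas,
        r_squared=r2,
        max_correlation=mc,
        beta_variances=np.var(betas, axis=1),
        iterations=it,
        converged=converged,
        sse_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# MOTA grouping


@dataclass(frozen=True)
class FunctionalGroup:
    """A set of mutually related (non-identifiable) variables."""

    members: tuple  # column indices, sorted
    responses: tuple  # responses from which the group was recovered
    r_squared: float  # best r^2 over the recovering responses
    strong: bool  # recovered from >= 2 of its members
    cv: dict = field(default_factory=dict)  # member -> std/mean annotation


def _cv(col: np.ndarray) -> float:
    m = col.mean()
    return float(col.std() / m) if m != 0 else float("inf")


def mota_groups(
    K,
    max_group_size: int = 10,
    r2_threshold: float = 0.8,
    min_samples: int = 30,
    bandwidth: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list:
    """Detect functional groups by repeated ACE fits.

    Every non-constant variable is taken once as response.  Its predictors
    from a full ACE fit are ranked by the variance of their fitted
    transformations; the smallest top-ranked prefix whose ACE fit reaches
    ``r2_threshold`` forms a group with the response (capped at
    ``max_group_size`` members).  Groups recovered from two or more member
    responses are flagged strong.
    """
    K = np.asarray(K, dtype=float)
    if K.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {K.shape[0]}")
    live = [c for c in range(K.shape[1]) if not _is_constant(K[:, c])]
    if len(live) < 2:
        return []

    found: dict = {}  # members -> (responses, best r2)
    for resp in live:
        preds = tuple(c for c in live if c != resp)
        full = ace(K, resp, preds, bandwidth=bandwidth, max_iter=max_iter, tol=tol)
        order = [preds[i] for i in np.argsort(-full.beta_variances)]
        limit = min(max_group_size - 1, len(order))
        for k in range(1, limit + 1):
            sub = ace(K, resp, tuple(order[:k]), bandwidth=bandwidth, max_iter=max_iter, tol=tol)
            if sub.r_squared >= r2_threshold:
                members = tuple(sorted((resp,) + tuple(order[:k])))
                resps, best = found.get(members, ((), 0.0))
                found[members] = (resps + (resp,), max(best, sub.r_squared))
                break

    groups = []
    for members, (resps, r2) in sorted(found.items()):
        groups.append(
            FunctionalGroup(
                members=members,
                responses=tuple(sorted(set(resps))),
                r_squared=r2,
                strong=len(set(resps)) >= 2,
                cv={c: _cv(K[:, c]) for c in members},
            )
        )
    return groups


# ---------------------------------------------------------------------------
# Stage-resolved disease characterization


def _stage_of_column(g: float, atp: float, atp_normal: float, stage_breaks):
    if stage_breaks is not None:
        b1, b2 = stage_breaks
        if b1 <= b2:
            raise ValueError("stage breaks must satisfy b1 > b2 (descending flux)")
        if g > b1:
            return "healthy"
        if g > b2:
            return "inflammation"
        return "disease"
    return classify_stage(atp, atp_normal)


def characterize_disease(
    model: MetabolicModel,
    reaction_id: str,
    grid,
    objective: dict,
    stage_breaks=None,
    matrix_reactions=None,
    min_samples: int = 30,
    **mota_kwargs,
) -> dict:
    """Stage-resolved functional-group report for one impaired reaction.

    Builds the scan matrix, restricts the rows to *matrix_reactions* (the
    compartment of interest; defaults to all non-exchange reactions other
    than the scanned one), assigns each feasible column to a stage — either
    by explicit flux breakpoints ``(b1, b2)`` with the descending half-open
    convention ``healthy (b1, inf)``, ``inflammation (b2, b1]``,
    ``disease [min, b2]``, or by the ATP-ratio classifier against the
    unpinned optimum — and runs the MOTA grouping separately per stage.

    Stages with fewer than *min_samples* feasible columns are reported empty
    with a warning.  Returns ``{stage: (groups, reaction_ids_used)}``.
    """
    scan = disease_scan(model, reaction_id, grid, objective)
    if matrix_reactions is None:
        matrix_reactions = [
            rid
            for rid, ex in zip(model.reaction_ids, model.is_exchange)
            if not ex and rid != reaction_id
        ]
    rows = [model.reaction_index(rid) for rid in matrix_reactions]

    normal = solve_fba(model, objective, "max")
    if normal.status != "optimal":
        raise RuntimeError("wild-type model does not solve to optimality")

    stage_cols = {s: [] for s in STAGES}
    for k in range(scan.grid.size):
        if not scan.feasible[k]:
            continue
        stage = _stage_of_column(
            float(scan.grid[k]), float(scan.objective_values[k]), normal.objective_value, stage_breaks
        )
        stage_cols[stage].append(k)

    report = {}
    for stage in STAGES:
        cols = stage_cols[stage]
        if len(cols) < min_samples:
            if cols:
                warnings.warn(
                    f"stage {stage!r} has only {len(cols)} scan columns; reported empty"
                )
            report[stage] = ([], tuple(matrix_reactions))
            continue
        K = scan.V[np.ix_(rows, cols)].T  # samples x variables
        groups = mota_groups(K, min_samples=min_samples, **mota_kwargs)
        report[stage] = (groups, tuple(matrix_reactions))
    return report


def write_group_report(report: dict, path):
    """CSV mirror of the stage-resolved group tables."""
    with open(path, "w") as fh:
        fh.write("stage,response_ids,member_ids,r2,strong,cv_members\n")
        for stage, (groups, rids) in report.items():
            for grp in groups:
                members = ";".join(rids[c] for c in grp.members)
                resps = ";".join(rids[c] for c in grp.responses)
                cvs = ";".join(f"{rids[c]}={grp.cv[c]:.4g}" for c in grp.members)
                fh.write(f"{stage},{resps},{members},{grp.r_squared:.6f},{grp.strong},{cvs}\n")
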