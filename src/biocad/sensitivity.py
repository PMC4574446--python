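"""Global and local sensitivity screening over any scalar model evaluator.

Morris elementary-effects screening perturbs one input at a time along
randomized trajectories on a p-level grid; the elementary effect of input i
is the finite-difference quotient of the output over a step ``delta`` on the
unit-scaled input.  The mean ``mu``, absolute mean ``mu*`` and standard
deviation ``sigma`` of the r effects summarize, respectively, the signed and
overall influence of the input and how much that influence depends on where
in the input space the step is taken.  Inputs are unit-scaled before
stepping so that effects are comparable across inputs with different
physical ranges.

Also provided: a one-at-a-time local robustness probe (share of small
perturbations that leave the output within a tolerance band) and first-order
Sobol indices through the standard pick-freeze estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElementaryEffectSummary",
    "morris_screening",
    "rank_inputs",
    "local_robustness",
    "sobol_first_order",
]


@dataclass(frozen=True)
class ElementaryEffectSummary:
    """Per-input Morris statistics over r trajectories."""

    mu: np.ndarray
    mu_star: np.ndarray
    sigma: np.ndarray
    effects: np.ndarray  # (r, n_inputs) raw elementary effects
    r: int
    p: int
    delta: float
    input_names: tuple = ()


def _as_box(bounds):
    arr = np.asarray(bounds, dtype=float)
    lo, hi = arr[:, 0], arr[:, 1]
    if np.any(hi <= lo):
        raise ValueError("each input needs lo < hi")
    return lo, hi


def _call(evaluator, lo, hi, u):
    y = evaluator(lo + u * (hi - lo))
    y = float(y)
    if not np.isfinite(y):
        raise FloatingPointError("evaluator returned a non-finite output")
    return y


def morris_screening(
    evaluator,
    bounds,
    r: int = 20,
    p: int = 4,
    delta: float | None = None,
    rng: np.random.Generator | None = None,
) -> ElementaryEffectSummary:
    """Morris elementary-effects screening.

    Parameters
    ----------
    evaluator : callable
        Maps an input vector (original units) to a scalar output.
    bounds : sequence of (lo, hi)
    r : int
        Number of randomized trajectories.
    p : int
        Number of grid levels (must be even).
    delta : float, optional
        Step on the unit-scaled inputs; defaults to ``p / (2 (p - 1))``.

    A trajectory on which the evaluator fails is discarded and resampled,
    up to ``3 r`` attempts in total.
    """
    if p % 2:
        raise ValueError("the number of levels p must be even")
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = _as_box(bounds)
    n = lo.size
    if delta is None:
        delta = p / (2.0 * (p - 1.0))
    levels = np.arange(p) / (p - 1.0)
    starts = levels[levels <= 1.0 - delta + 1e-12]

    effects = np.empty((r, n))
    done = 0
    attempts = 0
    while done < r:
        if attempts >= 3 * r:
            raise RuntimeError("too many failed Morris trajectories")
        attempts += 1
        x = starts[rng.integers(starts.size, size=n)].astype(float)
        try:
            y = _call(evaluator, lo, hi, x)
            ee = np.empty(n)
            for i in rng.permutation(n):
                up_ok = x[i] + delta <= 1.0 + 1e-12
                down_ok = x[i] - delta >= -1e-12
                if up_ok and (not down_ok or rng.random() < 0.5):
                    step = delta
                else:
                    step = -delta
                x[i] = min(max(x[i] + step, 0.0), 1.0)
                y_new = _call(evaluator, lo, hi, x)
                ee[i] = (y_new - y) / step
                y = y_new
            effects[done] = ee
            done += 1
        except (FloatingPointError, ArithmeticError, ValueError, TypeError):
            continue
    mu = effects.mean(axis=0)
    mu_star = np.abs(effects).mean(axis=0)
    sigma = effects.std(axis=0, ddof=1) if r > 1 else np.zeros(n)
    names = tuple(getattr(bounds, "names", ()) or ())
    return ElementaryEffectSummary(
        mu=mu, mu_star=mu_star, sigma=sigma, effects=effects, r=r, p=p, delta=delta,
        input_names=names,
    )


def rank_inputs(summary: ElementaryEffectSummary) -> list:
    """Input indices ordered by decreasing ``mu*``; ties broken by higher
    ``sigma``, then by input order."""
    n = summary.mu_star.size
    return sorted(range(n), key=lambda i: (-summary.mu_star[i], -summary.sigma[i], i))


def local_robustness(
    evaluator,
    nominal,
    relative_step: float = 0.1,
    samples_per_input: int = 100,
    tolerance: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One-at-a-time robustness: per input, the fraction of uniform
    perturbations within ``+- relative_step`` that keep the output within
    ``tolerance * |y_nominal|`` of the nominal output (absolute tolerance
    when the nominal output is zero)."""
    if rng is None:
        rng = np.random.default_rng()
    nominal = np.asarray(nominal, dtype=float)
    y0 = float(evaluator(nominal))
    band = tolerance * abs(y0) if y0 != 0 else tolerance
    fractions = np.empty(nominal.size)
    for i in range(nominal.size):
        hits = 0
        for _ in range(samples_per_input):
            x = nominal.copy()
            x[i] = x[i] * (1.0 + rng.uniform(-relative_step, relative_step))
            if abs(float(evaluator(x)) - y0) <= band:
                hits += 1
        fractions[i] = hits / samples_per_input
    return fractions


def sobol_first_order(
    evaluator,
    bounds,
    n: int = 4096,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """First-order Sobol indices by the pick-freeze estimator.

    Base matrices A and B are the two halves of a scrambled Sobol sequence
    in 2k dimensions (quasi-Monte Carlo keeps the estimator error well below
    the plain-MC rate); for input i the hybrid matrix AB_i takes column i
    from B.  The index is ``S1_i = mean(y_B (y_ABi - y_A)) / Var(y)``,
    clamped to [-0.05, 1].  Zero output variance yields all-zero indices
    with a warning.
    """
    if n < 256:
        raise ValueError("need at least 256 base samples")
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = _as_box(bounds)
    k = lo.size
    from scipy.stats import qmc

    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-two n
        base = sampler.random(n)
    A, B = base[:, :k], base[:, k:]

    def batch(M):
        return np.array([float(evaluator(lo + row * (hi - lo))) for row in M])

    yA = batch(A)
    yB = batch(B)
    var = np.var(np.concatenate([yA, yB]))
    if var == 0:
        warnings.warn("output variance is zero; Sobol indices undefined, returning 0")
        return np.zeros(k)
    s1 = np.empty(k)
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        yABi = batch(ABi)
        s1[i] = np.mean(yB * (yABi - yA)) / var
    return np.clip(s1, -0.05, 1.0)
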