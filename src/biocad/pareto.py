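"""Dominance relations, Pareto-front extraction and epsilon-dominance.

Two dominance modes are exposed.  ``standard`` is the textbook weak-Pareto
relation: *a* dominates *b* iff *a* is at least as good in every objective
and strictly better in at least one.  ``paper_strict`` requires *a* to be
strictly better in every objective; it admits weakly-dominated points into
the front and is kept for fidelity with the strict-in-all-coordinates
definition some authors print.

Epsilon-dominance relaxes the front membership test: a point ``y*`` is
epsilon-non-dominated when no other point exceeds it by at least ``eps_i``
in every objective.  Every Pareto-optimal point is epsilon-non-dominated, so
the epsilon set is always a superset of the front; it grows monotonically
with ``eps``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "ParetoFront",
    "dominates",
    "pareto_front",
    "epsilon_nondominated",
    "write_front_csv",
    "write_front_json",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective identifiers with per-objective optimization sense."""

    names: tuple
    senses: tuple  # each "max" or "min"

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "senses", tuple(self.senses))
        if len(self.names) != len(self.senses) or not self.names:
            raise ValueError("need >= 1 objective with one sense each")
        for s in self.senses:
            if s not in ("max", "min"):
                raise ValueError(f"bad sense {s!r}")

    @property
    def r(self) -> int:
        return len(self.names)

    def sign_vector(self) -> np.ndarray:
        """+1 for maximized, -1 for minimized objectives."""
        return np.array([1.0 if s == "max" else -1.0 for s in self.senses])

    @classmethod
    def parse(cls, text: str) -> "ObjectiveSpec":
        """Parse ``"max:ATP,min:EX_nadh"``-style objective strings."""
        names, senses = [], []
        for part in text.split(","):
            sense, _, name = part.strip().partition(":")
            if sense not in ("max", "min") or not name:
                raise ValueError(f"cannot parse objective {part!r}")
            names.append(name)
            senses.append(sense)
        return cls(tuple(names), tuple(senses))


def _oriented(points, spec: ObjectiveSpec) -> np.ndarray:
    """Map points so every objective is maximized."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != spec.r:
        raise ValueError(f"points have {pts.shape[1]} objectives, spec has {spec.r}")
    return pts * spec.sign_vector()


def dominates(a, b, spec: ObjectiveSpec, mode: str = "standard") -> bool:
    """True iff *a* dominates *b* under *mode* (senses taken from *spec*)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.shape != (spec.r,):
        raise ValueError("objective vectors do not match the spec length")
    sg = spec.sign_vector()
    a, b = a * sg, b * sg
    if mode == "paper_strict":
        return bool(np.all(a > b))
    if mode == "standard":
        return bool(np.all(a >= b) and np.any(a > b))
    raise ValueError(f"unknown dominance mode {mode!r}")


def pareto_front(points, spec: ObjectiveSpec, mode: str = "standard") -> list:
    """Indices of the non-dominated points (duplicates all retained)."""
    pts = _oriented(points, spec)
    n = pts.shape[0]
    if n == 0:
        raise ValueError("empty point set")
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        diff = pts - pts[i]  # rows: candidate dominators
        if mode == "paper_strict":
            dominated = np.any(np.all(diff > 0, axis=1))
        else:
            dominated = np.any(np.all(diff >= 0, axis=1) & np.any(diff > 0, axis=1))
        keep[i] = not dominated
    return [int(i) for i in np.where(keep)[0]]


def epsilon_nondominated(points, eps, spec: ObjectiveSpec) -> list:
    """Indices of the epsilon-non-dominated points.

    ``eps`` must be strictly positive in every coordinate.  A point ``y*``
    stays when no point reaches ``y* + eps`` in all objectives, hence the
    result is a superset of the Pareto front.
    """
    eps = np.asarray(eps, dtype=float)
    if eps.shape == ():
        eps = np.full(spec.r, float(eps))
    if eps.shape != (spec.r,):
        raise ValueError("eps length does not match objective count")
    if np.any(eps <= 0):
        raise ValueError("eps must be strictly positive in every coordinate")
    pts = _oriented(points, spec)
    keep = []
    for i in range(pts.shape[0]):
        if not np.any(np.all(pts - pts[i] >= eps, axis=1)):
            keep.append(i)
    return keep


@dataclass(frozen=True)
class ParetoFront:
    """Mutually non-dominated objective points paired with decision vectors."""

    objectives: np.ndarray  # (k, r)
    decisions: np.ndarray  # (k, n)
    spec: ObjectiveSpec
    dominance_mode: str = "standard"
    generation: int = -1

    def __post_init__(self):
        obj = np.atleast_2d(np.asarray(self.objectives, dtype=float))
        dec = np.atleast_2d(np.asarray(self.decisions, dtype=float))
        if obj.shape[0] != dec.shape[0]:
            raise ValueError("objectives and decisions are not paired 1:1")
        object.__setattr__(self, "objectives", obj)
        object.__setattr__(self, "decisions", dec)
        idx = pareto_front(obj, self.spec, self.dominance_mode)
        if len(idx) != obj.shape[0]:
            raise ValueError("front contains dominated members")

    @classmethod
    def from_points(cls, objectives, decisions, spec, mode="standard", generation=-1):
        """Filter arbitrary evaluated points down to their non-dominated set."""
        obj = np.atleast_2d(np.asarray(objectives, dtype=float))
        dec = np.atleast_2d(np.asarray(decisions, dtype=float))
        idx = pareto_front(obj, spec, mode)
        return cls(obj[idx], dec[idx], spec, mode, generation)

    def __len__(self):
        return self.objectives.shape[0]


def write_front_csv(front: ParetoFront, path):
    r = front.spec.r
    n = front.decisions.shape[1]
    with open(path, "w") as fh:
        cols = [f"obj_{i + 1}" for i in range(r)] + [f"x_{i + 1}" for i in range(n)]
        fh.write(",".join(cols + ["generation"]) + "\n")
        for obj, dec in zip(front.objectives, front.decisions):
            vals = [repr(float(v)) for v in obj] + [repr(float(v)) for v in dec]
            fh.write(",".join(vals + [str(front.generation)]) + "\n")


def write_front_json(front: ParetoFront, path):
    payload = {
        "objectives": front.objectives.tolist(),
        "decisions": front.decisions.tolist(),
        "senses": list(front.spec.senses),
        "names": list(front.spec.names),
        "dominance_mode": front.dominance_mode,
        "generation": front.generation,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
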