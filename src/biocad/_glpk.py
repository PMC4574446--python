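"""Reusable GLPK problem for repeated FBA solves with changing bounds.

The evolutionary optimizer and the scan routines solve thousands of LPs that
differ only in their bound vectors; rebuilding the problem each time
dominates the runtime.  This helper loads the stoichiometry once and
re-solves with a warm simplex basis.  :func:`biocad.model_core.solve_fba`
(scipy/HiGHS) remains the reference path; both are cross-checked in the
test suite.
"""

from __future__ import annotations

import numpy as np
import swiglpk as glp

__all__ = ["ReusableFBA"]


class ReusableFBA:
    """``S v = 0`` LP with mutable bounds and objective."""

    def __init__(self, model):
        self._model = model
        m, n = model.stoichiometry.shape
        self._n = n
        lp = glp.glp_create_prob()
        glp.glp_add_rows(lp, m)
        for i in range(m):
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, 0.0, 0.0)
        glp.glp_add_cols(lp, n)
        S = model.stoichiometry
        rows, cols = np.nonzero(S)
        nnz = rows.size
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for k in range(nnz):
            ia[k + 1] = int(rows[k]) + 1
            ja[k + 1] = int(cols[k]) + 1
            ar[k + 1] = float(S[rows[k], cols[k]])
        glp.glp_load_matrix(lp, nnz, ia, ja, ar)
        self._lp = lp
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF
        self.set_bounds(model.lower_bounds, model.upper_bounds)

    def set_bounds(self, lb, ub):
        lp = self._lp
        for j in range(self._n):
            lo, hi = float(lb[j]), float(ub[j])
            kind = glp.GLP_FX if lo == hi else glp.GLP_DB
            glp.glp_set_col_bnds(lp, j + 1, kind, lo, hi)

    def set_objective(self, weights: dict, sense: str = "max"):
        lp = self._lp
        idx = {rid: j for j, rid in enumerate(self._model.reaction_ids)}
        for j in range(self._n):
            glp.glp_set_obj_coef(lp, j + 1, 0.0)
        for rid, w in weights.items():
            glp.glp_set_obj_coef(lp, idx[rid] + 1, float(w))
        glp.glp_set_obj_dir(lp, glp.GLP_MAX if sense == "max" else glp.GLP_MIN)

    def solve(self, lb=None, ub=None):
        """Re-solve; returns ``(status, objective_value, fluxes)``."""
        if lb is not None:
            self.set_bounds(lb, ub)
        lp = self._lp
        ret = glp.glp_simplex(lp, self._parm)
        if ret != 0:  # numerical trouble: retry from a fresh basis
            glp.glp_std_basis(lp)
            ret = glp.glp_simplex(lp, self._parm)
            if ret != 0:
                return "infeasible", float("nan"), np.full(self._n, np.nan)
        status = glp.glp_get_status(lp)
        if status == glp.GLP_OPT:
            v = np.array([glp.glp_get_col_prim(lp, j + 1) for j in range(self._n)])
            return "optimal", float(glp.glp_get_obj_val(lp)), v
        if status == glp.GLP_UNBND:
            return "unbounded", float("nan"), np.full(self._n, np.nan)
        return "infeasible", float("nan"), np.full(self._n, np.nan)

    def __del__(self):
        try:
            glp.glp_delete_prob(self._lp)
        except Exception:
            pass
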