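"""Internal helpers around statsmodels MixedLM.

Centralizes quiet fitting with optimizer fallbacks and the degrees-of-freedom
approximation used for all fixed-effect inference (residual-style
``n_obs - n_groups - n_fixed``, flagged as ``df_method="residual"`` in every
fit result).
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

DF_METHOD = "residual"

_OPTIMIZERS = ("bfgs", "powell", "cg")


def fit_mixedlm(formula: str, data, groups, re_formula: str | None = None,
                reml: bool = True):
    """Fit a linear mixed model, falling back across optimizers.

    A fit counts as clean when it emits no convergence warning and has
    finite fixed-effect standard errors; the first clean fit wins,
    otherwise the candidate with the best likelihood is returned with
    ``converged=False``.  Raises only if every optimizer fails outright.
    """
    model = sm.MixedLM.from_formula(formula, data=data, groups=groups,
                                    re_formula=re_formula)
    best, spare, last_err = None, None, None
    for method in _OPTIMIZERS:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                cand = model.fit(reml=reml, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
                last_err = err
                continue
        if not np.all(np.isfinite(cand.bse_fe)):
            spare = cand  # degenerate (e.g. zero residual variance)
            continue
        warned = any(issubclass(w.category, (ConvergenceWarning, UserWarning))
                     for w in caught)
        if not warned:
            return cand, True
        if best is None or float(cand.llf) > float(best.llf):
            best = cand
    if best is None:
        best = spare
    if best is None:  # pragma: no cover
        raise last_err if last_err else RuntimeError("mixed model fit failed")
    return best, False


def residual_df(n_obs: int, n_groups: int, n_fixed: int) -> float:
    """Residual-style denominator df for fixed-effect t tests."""
    return float(max(n_obs - n_groups - n_fixed, 1))
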