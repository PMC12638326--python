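"""Independent normal-equations OLS oracle for cross-checking models.

Deliberately minimal and self-contained: solves X'X b = X'y directly
and derives classical t-based inference, with no reliance on the
package's regression stack.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_oracle(X, y, add_intercept: bool = True, alpha: float = 0.05) -> dict:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    tvals = beta / se
    return {
        "beta": beta,
        "se": se,
        "ci_low": beta - tcrit * se,
        "ci_high": beta + tcrit * se,
        "p": 2.0 * stats.t.sf(np.abs(tvals), dof),
        "dof": dof,
    }
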