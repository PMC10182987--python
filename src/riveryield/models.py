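"""Registry of the nine LOADEST rating-curve model forms.

Each model regresses ln(instantaneous load) on a subset of the covariates
built from centered ln-streamflow (``lnQ``) and centered decimal time
(``dtime``):

====  =========================================================
 ID   linear predictor
====  =========================================================
 1    a0 + a1*lnQ
 2    a0 + a1*lnQ + a2*lnQ^2
 3    a0 + a1*lnQ + a2*dtime
 4    a0 + a1*lnQ + a2*sin(2*pi*dtime) + a3*cos(2*pi*dtime)
 5    a0 + a1*lnQ + a2*lnQ^2 + a3*dtime
 6    a0 + a1*lnQ + a2*lnQ^2 + a3*sin(..) + a4*cos(..)
 7    a0 + a1*lnQ + a2*sin(..) + a3*cos(..) + a4*dtime
 8    a0 + a1*lnQ + a2*lnQ^2 + a3*sin(..) + a4*cos(..) + a5*dtime
 9    model 8 + a6*dtime^2
====  =========================================================

Coefficients are positional: ``a_k`` is the k-th term of the model's own
term list (intercept first), so e.g. in model 4 ``a2`` multiplies the sine
term while in model 5 it multiplies ``lnQ^2``.
"""

from __future__ import annotations

import numpy as np

# covariate term codes
LNQ = "lnQ"
LNQ2 = "lnQ2"
SIN = "sin2pi_dtime"
COS = "cos2pi_dtime"
DTIME = "dtime"
DTIME2 = "dtime2"

#: term list per model id, intercept excluded
MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: (LNQ,),
    2: (LNQ, LNQ2),
    3: (LNQ, DTIME),
    4: (LNQ, SIN, COS),
    5: (LNQ, LNQ2, DTIME),
    6: (LNQ, LNQ2, SIN, COS),
    7: (LNQ, SIN, COS, DTIME),
    8: (LNQ, LNQ2, SIN, COS, DTIME),
    9: (LNQ, LNQ2, SIN, COS, DTIME, DTIME2),
}

MODEL_IDS = tuple(sorted(MODEL_TERMS))
MAX_COEFFICIENTS = 7  # model 9: a0..a6


def n_coefficients(model_id: int) -> int:
    """Number of regression coefficients (intercept included)."""
    return len(MODEL_TERMS[model_id]) + 1


def _term_column(term: str, lnq_c: np.ndarray, dtime_c: np.ndarray) -> np.ndarray:
    if term == LNQ:
        return lnq_c
    if term == LNQ2:
        return lnq_c**2
    if term == SIN:
        return np.sin(2.0 * np.pi * dtime_c)
    if term == COS:
        return np.cos(2.0 * np.pi * dtime_c)
    if term == DTIME:
        return dtime_c
    if term == DTIME2:
        return dtime_c**2
    raise ValueError(f"unknown term {term!r}")


def design_matrix(model_id: int, lnq_c: np.ndarray, dtime_c: np.ndarray) -> np.ndarray:
    """Build the (n, p) design matrix for a model from centered covariates.

    Parameters
    ----------
    model_id
        Rating-curve model id, 1-9.
    lnq_c
        ln(streamflow) minus its decorrelating center.
    dtime_c
        decimal time minus its decorrelating center.
    """
    if model_id not in MODEL_TERMS:
        raise ValueError(f"model_id must be in 1..9, got {model_id}")
    lnq_c = np.asarray(lnq_c, dtype=float)
    dtime_c = np.asarray(dtime_c, dtype=float)
    cols = [np.ones_like(lnq_c)]
    cols.extend(_term_column(t, lnq_c, dtime_c) for t in MODEL_TERMS[model_id])
    return np.column_stack(cols)


def linear_predictor(
    model_id: int,
    coefficients: np.ndarray,
    lnq_c: np.ndarray,
    dtime_c: np.ndarray,
) -> np.ndarray:
    """Evaluate a model's linear predictor at centered covariates."""
    X = design_matrix(model_id, lnq_c, dtime_c)
    beta = np.asarray(coefficients, dtype=float)[: X.shape[1]]
    return X @ beta
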