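"""The sorption-deformation-percolation (SDP) tortuosity model.

The normalized diffusion coefficient xi_inv = D_mu / D_bulk (the reciprocal
apparent tortuosity) is modelled as a product of exponential factors in three
experimentally accessible material descriptors:

    xi_inv = exp(a_0 + a_Q * x_Q + a_E * x_E + a_p * x_p)

with features x_Q = Q_ad / (R T)  (sorption; heat of adsorption in thermal
units), x_E = sqrt(E / E_0) with E_0 = 1 GPa (deformation; via the
persistence-length scaling ln D ~ l_p^(1/2)), and x_p = p_p (percolation
probability).  The model is linear in the weights on the log scale, so the
weights are fitted by ordinary least squares of ln xi_inv on (1, x_Q, x_E,
x_p), and each weight is the partial derivative a_i = d ln(xi_inv) / d x_i.

``REFERENCE_WEIGHTS`` ships the published wood-polymer fit (a_0 = -0.572,
a_Q = -3.051, a_E = -1.243, a_p = 0.466) for prediction.  These are
dataset-specific: the feature normalization behind them cannot be verified
independently, so treat them as opaque constants rather than transferable
physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .materials import GAS_CONSTANT_KJ, records_to_frame
from .msd import D_BULK_WATER

__all__ = [
    "E0_GPA",
    "DEFAULT_TEMPERATURE",
    "SDPFeatures",
    "SDPWeights",
    "REFERENCE_WEIGHTS",
    "RankDeficiencyError",
    "features_from_records",
    "sdp_predict",
    "sdp_fit",
    "sensitivity_analysis",
]

#: modulus normalization making (E/E0)^(1/2) dimensionless
E0_GPA = 1.0
#: default temperature (K) for converting Q_ad to thermal units
DEFAULT_TEMPERATURE = 300.0

_FACTOR_NAMES = ("Q", "E", "p")


class RankDeficiencyError(ValueError):
    pass


@dataclass
class SDPFeatures:
    """Dimensionless SDP features; scalars or aligned arrays."""

    x_Q: np.ndarray
    x_E: np.ndarray
    x_p: np.ndarray

    def __post_init__(self) -> None:
        self.x_Q = np.atleast_1d(np.asarray(self.x_Q, dtype=float))
        self.x_E = np.atleast_1d(np.asarray(self.x_E, dtype=float))
        self.x_p = np.atleast_1d(np.asarray(self.x_p, dtype=float))
        if not (self.x_Q.shape == self.x_E.shape == self.x_p.shape):
            raise ValueError("feature arrays must have matching shapes")
        if np.any(self.x_E < 0):
            raise ValueError("x_E = sqrt(E/E0) must be non-negative")
        if np.any((self.x_p < 0) | (self.x_p > 1)):
            raise ValueError("x_p is a probability and must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x_Q)

    def design_matrix(self, factors=("Q", "E", "p")) -> np.ndarray:
        cols = [np.ones(len(self))]
        lookup = {"Q": self.x_Q, "E": self.x_E, "p": self.x_p}
        cols.extend(lookup[f] for f in factors)
        return np.column_stack(cols)


@dataclass
class SDPWeights:
    a_0: float
    a_Q: float
    a_E: float
    a_p: float
    stderr: dict | None = None
    r_squared: float | None = None
    n_obs: int | None = None
    residuals: np.ndarray | None = field(repr=False, default=None)

    def as_array(self) -> np.ndarray:
        return np.array([self.a_0, self.a_Q, self.a_E, self.a_p])


#: published wood-polymer fit of the SDP weights (dataset-specific; see module docstring)
REFERENCE_WEIGHTS = SDPWeights(a_0=-0.572, a_Q=-3.051, a_E=-1.243, a_p=0.466)


def features_from_records(
    records, T: float = DEFAULT_TEMPERATURE, E0: float = E0_GPA
) -> SDPFeatures:
    """Build (x_Q, x_E, x_p) from material records with Q_ad (kJ/mol), E (GPa), p_p."""
    df = records_to_frame(records)
    return SDPFeatures(
        x_Q=df["Q_ad"].to_numpy(dtype=float) / (GAS_CONSTANT_KJ * T),
        x_E=np.sqrt(df["E"].to_numpy(dtype=float) / E0),
        x_p=df["p_p"].to_numpy(dtype=float),
    )


def sdp_predict(
    features: SDPFeatures,
    weights: SDPWeights = REFERENCE_WEIGHTS,
    D_bulk: float | None = None,
):
    """Predict xi_inv = exp(a_0 + a_Q x_Q + a_E x_E + a_p x_p).

    Evaluated in log space, so extreme feature values degrade gracefully.
    When ``D_bulk`` is given, returns (xi_inv, D_mu = xi_inv * D_bulk).
    """
    log_xi_inv = (
        weights.a_0
        + weights.a_Q * features.x_Q
        + weights.a_E * features.x_E
        + weights.a_p * features.x_p
    )
    xi_inv = np.exp(log_xi_inv)
    if xi_inv.size == 1:
        xi_inv = float(xi_inv[0])
    if D_bulk is not None:
        return xi_inv, np.multiply(xi_inv, D_bulk)
    return xi_inv


def _response(df: pd.DataFrame, D_bulk: float) -> np.ndarray:
    d_mu = df["D_mu"].to_numpy(dtype=float)
    return np.log(d_mu / D_bulk)


def _validated_frame(records, D_bulk: float) -> pd.DataFrame:
    df = records_to_frame(records)
    df = df[df["D_mu"] > 0]
    if len(df) < 5:
        raise ValueError(f"need at least 5 records with D_mu > 0, got {len(df)}")
    return df


def _check_rank(X: np.ndarray, factor_cols: tuple) -> None:
    for k, name in enumerate(factor_cols, start=1):
        if np.ptp(X[:, k]) < 1e-12 * max(1.0, abs(X[:, k]).max()):
            raise RankDeficiencyError(
                f"feature x_{name} is constant across records; "
                "the design matrix is rank deficient"
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient (collinear features)")


def sdp_fit(
    records,
    T: float = DEFAULT_TEMPERATURE,
    D_bulk: float = D_BULK_WATER,
) -> SDPWeights:
    """Fit the SDP weights by OLS of ln(D_mu / D_bulk) on (1, x_Q, x_E, x_p)."""
    df = _validated_frame(records, D_bulk)
    feats = features_from_records(df, T=T)
    X = feats.design_matrix()
    _check_rank(X, _FACTOR_NAMES)
    y = _response(df, D_bulk)
    model = sm.OLS(y, X).fit()
    a0, aQ, aE, ap = model.params
    se = model.bse
    return SDPWeights(
        a_0=float(a0), a_Q=float(aQ), a_E=float(aE), a_p=float(ap),
        stderr={"a_0": float(se[0]), "a_Q": float(se[1]),
                "a_E": float(se[2]), "a_p": float(se[3])},
        r_squared=float(model.rsquared),
        n_obs=int(model.nobs),
        residuals=np.asarray(model.resid),
    )


def sensitivity_analysis(
    records,
    T: float = DEFAULT_TEMPERATURE,
    D_bulk: float = D_BULK_WATER,
) -> pd.DataFrame:
    """Refit the model for every subset of {Q, E, p} factors.

    Returns one row per subset (8 rows, intercept-only included) with the
    in-sample R^2 and RMSE of the predicted vs measured ln xi_inv.  Nested
    OLS guarantees the full model attains the maximal R^2.
    """
    df = _validated_frame(records, D_bulk)
    feats = features_from_records(df, T=T)
    y = _response(df, D_bulk)
    rows = []
    for r in range(len(_FACTOR_NAMES) + 1):
        for subset in combinations(_FACTOR_NAMES, r):
            X = feats.design_matrix(subset)
            if subset:
                _check_rank(X, subset)
            model = sm.OLS(y, X).fit()
            pred = model.predict(X)
            rows.append(
                {
                    "factors": "+".join(subset) if subset else "none",
                    "n_factors": len(subset),
                    "r_squared": float(model.rsquared),
                    "rmse": float(np.sqrt(np.mean((pred - y) ** 2))),
                    "full_model": subset == _FACTOR_NAMES,
                }
            )
    return pd.DataFrame(rows)
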