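"""Spectral-tuning regression: λ_max as a function of HBN geometry.

The absorption maximum of an SWS1 pigment is modelled as a linear
function of its hydrogen-bond-network signature,

    λ_max = β0 + β1 · (A/B) + β2 · B,

fitted by ordinary least squares to pigments with both an in-vitro
λ_max and a modelled HBN geometry.  λ_max falls as the A/B ratio grows
and as area B shrinks, tracking the UV → violet transition.

Fitting uses the tabulated A/B column as the predictor (the ratio as
reported for each structural model), not a ratio recomputed from A and
B at full precision; the two differ in the third decimal and the model
coefficients are sensitive to that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


class ModelSource(str, Enum):
    """Provenance of an HBN structural model: raw homology model (SWISS)
    or the geometry-optimised refinement (AMBER)."""

    AMBER = "AMBER"
    SWISS = "SWISS"


@dataclass
class PigmentRecord:
    """One pigment's observed λ_max and HBN geometry under one model source."""

    name: str
    model_source: ModelSource
    area_A: float
    area_B: float
    ab: float
    lambda_obs: Optional[float] = None
    lambda_pred: Optional[float] = None

    def __post_init__(self) -> None:
        self.model_source = ModelSource(self.model_source)
        if self.area_B > 0 and abs(self.ab - self.area_A / self.area_B) > 5e-4:
            raise ValueError(
                f"{self.name}: ab={self.ab} inconsistent with A/B="
                f"{self.area_A / self.area_B:.6f}"
            )
        if self.lambda_obs is not None and not 350 <= self.lambda_obs <= 450:
            raise ValueError(f"{self.name}: lambda_obs {self.lambda_obs} outside [350, 450] nm")


@dataclass
class SpectralModel:
    """Fitted λ_max model and its fit diagnostics.

    ``s`` is the residual standard error sqrt(SSE / (n − 3)), the
    denominator counting the three estimated coefficients; ``mae`` is the
    mean absolute residual on the training records.
    """

    beta0: float
    beta1: float
    beta2: float
    r2: float
    s: float
    mae: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 {self.r2} outside [0, 1]")
        if self.s < 0 or self.mae < 0:
            raise ValueError("s and mae must be non-negative")


class SingularFitError(ValueError):
    """The design matrix is rank deficient (collinear predictors)."""


def _design(records: Sequence[PigmentRecord]) -> tuple[np.ndarray, np.ndarray]:
    ab = np.array([r.ab for r in records], float)
    b = np.array([r.area_B for r in records], float)
    y = np.array([r.lambda_obs for r in records], float)
    return sm.add_constant(np.column_stack([ab, b]), has_constant="add"), y


def fit_spectral_model(records: Sequence[PigmentRecord]) -> SpectralModel:
    """OLS fit of λ_max on (A/B, B) with intercept.

    Requires at least four records (three coefficients plus one residual
    degree of freedom) and a full-rank design.
    """
    records = [r for r in records if r.lambda_obs is not None]
    if len(records) < 4:
        raise ValueError(f"need >= 4 records with observed λ_max, got {len(records)}")
    X, y = _design(records)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("design matrix is rank deficient; predictors collinear")
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    sse = float(resid @ resid)
    n = len(records)
    return SpectralModel(
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        beta2=float(fit.params[2]),
        r2=float(fit.rsquared),
        s=math.sqrt(sse / (n - 3)),
        mae=float(np.abs(resid).mean()),
        n=n,
    )


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (the rounding
    used for whole-nm predicted values)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def predict_lambda(model: SpectralModel, ab: float, area_B: float) -> tuple[float, int]:
    """Predicted λ_max in nm: ``(exact, rounded-to-whole-nm)``."""
    value = model.beta0 + model.beta1 * ab + model.beta2 * area_B
    return value, round_half_away(value)


def model_diagnostics(model: SpectralModel, records: Sequence[PigmentRecord]) -> pd.DataFrame:
    """Per-record predictions and residuals for a fitted model.

    Residuals sum to ~0 and their mean absolute value equals ``model.mae``
    when ``records`` are the training set; on other records the table is
    still valid but those identities need not hold.
    """
    rows = []
    for r in records:
        pred, pred_round = predict_lambda(model, r.ab, r.area_B)
        rows.append(
            {
                "name": r.name,
                "model_source": r.model_source.value,
                "ab": r.ab,
                "area_B": r.area_B,
                "lambda_obs": r.lambda_obs,
                "lambda_pred": pred,
                "lambda_pred_round": pred_round,
                "residual": None if r.lambda_obs is None else r.lambda_obs - pred,
            }
        )
    return pd.DataFrame(rows)
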