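"""Minimal-generation-time predictor built on codon-usage bias.

The two selection indices ΔENC′ and S are z-standardised and combined into
their first principal component F (the composite codon-bias strength).  A
Box-Cox transform Φ_λ(d) of the minimal doubling time d (hours) is regressed
linearly on F, optionally with an optimal-growth-temperature (OGT) term:

    Φ_λ(d) = a + b·F (+ c·OGT)

The published mesophilic fit is Φ(d) = 0.8741 − 0.6496·F with Φ in its
log limit (λ → 0), so predictions back-transform as d = exp(Φ).  Predicted
times discretise into four growth classes: very fast (d < 1 h), fast
(1–2 h), intermediate (2–5 h) and slow (d ≥ 5 h).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

PUBLISHED_INTERCEPT = 0.8741
PUBLISHED_SLOPE_F = -0.6496
PUBLISHED_LAMBDA = 0.0

GROWTH_CLASSES = ("very_fast", "fast", "intermediate", "slow")
#: Right-open class boundaries in hours; d >= 5 h is slow (inclusive).
CLASS_BOUNDS = (1.0, 2.0, 5.0)

#: Mesophile gate for the OGT-free published model (°C).
MESOPHILE_OGT_RANGE = (15.0, 60.0)


def box_cox(d, lambda_: float):
    """Box-Cox transform Φ_λ(d) = (d^λ − 1)/λ, or ln d in the λ = 0 limit."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("Box-Cox transform requires d > 0")
    # expm1 keeps the transform accurate in the lambda -> 0 limit
    out = np.log(d) if lambda_ == 0 else np.expm1(lambda_ * np.log(d)) / lambda_
    return float(out) if out.ndim == 0 else out


def inverse_box_cox(phi, lambda_: float):
    """Inverse of :func:`box_cox`; round-trips within 1e-9 relative."""
    phi = np.asarray(phi, dtype=float)
    if lambda_ == 0:
        out = np.exp(phi)
    else:
        if np.any(lambda_ * phi <= -1.0):
            raise ValueError("inverse Box-Cox outside the transform's domain")
        out = np.exp(np.log1p(lambda_ * phi) / lambda_)
    return float(out) if out.ndim == 0 else out


@dataclass
class Composite:
    """Standardisation + first-principal-component loadings defining F."""

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    explained_ratio: float

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if abs(np.linalg.norm(self.loadings) - 1.0) > 1e-8:
            raise ValueError("loadings must have unit Euclidean norm")

    def transform(self, delta_enc, s):
        """Composite score F = loadings · z-scores of (ΔENC′, S)."""
        z = (np.stack(
            [np.asarray(delta_enc, dtype=float), np.asarray(s, dtype=float)], axis=-1
        ) - self.mean) / self.scale
        out = z @ self.loadings
        return float(out) if out.ndim == 0 else out


def fit_composite(index_table) -> Composite:
    """Fit the composite F on a table of (ΔENC′, S) pairs.

    z-standardises both indices (sample standard deviation, ddof=1),
    extracts the first principal component of the 2×2 correlation matrix and
    orients it so that larger indices (stronger selection, hence faster
    growth) increase F.
    """
    x = np.asarray(index_table, dtype=float)
    if isinstance(index_table, pd.DataFrame):
        x = index_table[["delta_enc", "s"]].to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("index_table must have two columns (delta_enc, s)")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows to fit the composite")
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    if np.any(scale <= 0):
        raise ValueError("zero variance in an index column")
    z = (x - mean) / scale
    r = float(np.corrcoef(z, rowvar=False)[0, 1])
    corr = np.array([[1.0, r], [r, 1.0]])
    evals, evecs = np.linalg.eigh(corr)
    loadings = evecs[:, int(np.argmax(evals))]
    if loadings.sum() < 0 or (loadings.sum() == 0 and loadings[0] < 0):
        loadings = -loadings
    return Composite(
        mean=mean, scale=scale, loadings=loadings,
        explained_ratio=float(evals.max() / evals.sum()),
    )


@dataclass
class PredictorModel:
    """Box-Cox / linear predictor of minimal generation time.

    ``provenance`` is ``"published"`` for the printed mesophilic
    coefficients (intercept 0.8741, slope −0.6496, λ = 0) or ``"refit"``
    for a model estimated from a training table.  The composite (PCA
    standardisation and loadings) is not printed in the original fit, so a
    published-coefficient model can only map raw indices to F once a
    composite has been attached (fit on a training index table); it always
    accepts F directly.
    """

    lambda_: float
    intercept: float
    slope_f: float
    slope_ogt: float | None = None
    composite: Composite | None = None
    provenance: str = "refit"
    training_n: int = 0
    r2: float | None = None

    def compose_f(self, delta_enc, s):
        if self.composite is None:
            raise ValueError(
                "model has no composite (standardisation/loadings); fit one with "
                "fit_composite or pass F directly"
            )
        return self.composite.transform(delta_enc, s)

    def predict_phi(self, f, ogt=None):
        if self.slope_ogt is not None:
            if ogt is None:
                raise ValueError("model includes an OGT term; ogt is required")
            return self.intercept + self.slope_f * np.asarray(f, float) \
                + self.slope_ogt * np.asarray(ogt, float)
        if ogt is not None and self.provenance == "published":
            raise ValueError(
                "published mode has no OGT term and refuses OGT predictions; "
                "use the mesophilic model (omit ogt) or refit with include_ogt"
            )
        return self.intercept + self.slope_f * np.asarray(f, float)

    def predict_d(self, f=None, delta_enc=None, s=None, ogt=None):
        """Predicted minimal generation time in hours (strictly positive)."""
        if f is None:
            if delta_enc is None or s is None:
                raise ValueError("pass either f or both delta_enc and s")
            f = self.compose_f(delta_enc, s)
        phi = self.predict_phi(f, ogt)
        return inverse_box_cox(phi, self.lambda_)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "lambda": self.lambda_,
            "intercept": self.intercept,
            "slope_f": self.slope_f,
            "slope_ogt": self.slope_ogt,
            "provenance": self.provenance,
            "training_n": self.training_n,
            "r2": self.r2,
        }
        if self.composite is not None:
            d["composite"] = {
                "mean": self.composite.mean.tolist(),
                "scale": self.composite.scale.tolist(),
                "loadings": self.composite.loadings.tolist(),
                "explained_ratio": self.composite.explained_ratio,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorModel":
        comp = None
        if d.get("composite"):
            c = d["composite"]
            comp = Composite(
                mean=c["mean"], scale=c["scale"], loadings=c["loadings"],
                explained_ratio=c.get("explained_ratio", float("nan")),
            )
        return cls(
            lambda_=d["lambda"], intercept=d["intercept"], slope_f=d["slope_f"],
            slope_ogt=d.get("slope_ogt"), composite=comp,
            provenance=d.get("provenance", "refit"),
            training_n=d.get("training_n", 0), r2=d.get("r2"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PredictorModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def published_model(composite: Composite | None = None) -> PredictorModel:
    """The printed mesophilic model: Φ(d) = 0.8741 − 0.6496·F, λ = 0."""
    return PredictorModel(
        lambda_=PUBLISHED_LAMBDA,
        intercept=PUBLISHED_INTERCEPT,
        slope_f=PUBLISHED_SLOPE_F,
        composite=composite,
        provenance="published",
        training_n=214,
        r2=0.47,
    )


def compose_F(delta_enc, s, model: PredictorModel):
    """Composite codon-bias strength F for index values under ``model``."""
    return model.compose_f(delta_enc, s)


def predict_d(f, ogt=None, model: PredictorModel | None = None):
    """Predict d (hours) from F (and OGT if the model carries a term)."""
    model = model if model is not None else published_model()
    return model.predict_d(f=f, ogt=ogt)


def fit_predictor(
    training: pd.DataFrame,
    include_ogt: bool = False,
    lambda_mode: str = "mle",
) -> PredictorModel:
    """Fit the Box-Cox / linear predictor on a training table.

    ``training`` needs columns ``delta_enc``, ``s``, ``d`` (hours, > 0) and
    ``ogt`` when ``include_ogt``.  λ is estimated by profile likelihood
    (``lambda_mode="mle"``) or fixed to the log limit (``"log"``).  The
    composite is fit on the same table; ordinary least squares (statsmodels)
    estimates the Φ-scale coefficients.
    """
    required = {"delta_enc", "s", "d"} | ({"ogt"} if include_ogt else set())
    missing = required - set(training.columns)
    if missing:
        raise ValueError(f"training table lacks columns: {sorted(missing)}")
    n = len(training)
    if n < 5:
        raise ValueError(f"need at least 5 training rows, got {n}")
    d = training["d"].to_numpy(dtype=float)
    if np.any(d <= 0):
        raise ValueError("all training d must be > 0")

    composite = fit_composite(training[["delta_enc", "s"]])
    f = composite.transform(
        training["delta_enc"].to_numpy(float), training["s"].to_numpy(float)
    )

    if lambda_mode == "log":
        lam = 0.0
    elif lambda_mode == "mle":
        lam = float(scipy.stats.boxcox_normmax(d, method="mle"))
    else:
        raise ValueError(f"unknown lambda_mode: {lambda_mode!r}")
    phi = box_cox(d, lam)

    cols = [f] + ([training["ogt"].to_numpy(float)] if include_ogt else [])
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(phi, X).fit()
    params = fit.params
    return PredictorModel(
        lambda_=lam,
        intercept=float(params[0]),
        slope_f=float(params[1]),
        slope_ogt=float(params[2]) if include_ogt else None,
        composite=composite,
        provenance="refit",
        training_n=n,
        r2=float(fit.rsquared),
    )


def classify(d: float) -> str:
    """Discrete growth class of a doubling time (hours).

    Boundaries are right-open: [0,1) very_fast, [1,2) fast,
    [2,5) intermediate, [5,∞) slow.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    for label, bound in zip(GROWTH_CLASSES, CLASS_BOUNDS):
        if d < bound:
            return label
    return GROWTH_CLASSES[-1]


def null_classification_expectations(
    class_sizes: Sequence[int],
) -> tuple[float, float, float]:
    """Expected accuracy (%) of a uniformly random class prediction.

    Given observed class sizes (very fast, fast, intermediate, slow),
    returns (expected exact, expected exact-or-adjacent, expected gross
    misclassification), where a gross error predicts a slow grower as fast
    or very fast, or vice versa.
    """
    sizes = np.asarray(class_sizes, dtype=float)
    if sizes.shape != (4,) or np.any(sizes <= 0):
        raise ValueError("class_sizes must be four positive integers")
    total = sizes.sum()
    k = len(GROWTH_CLASSES)
    # acceptable[i, j]: predicting class j for observed class i counts as
    # exact-or-adjacent; gross[i, j]: counts as a gross error.
    acceptable = np.array(
        [[1 if abs(i - j) <= 1 else 0 for j in range(k)] for i in range(k)]
    )
    gross = np.zeros((k, k), dtype=int)
    slow = GROWTH_CLASSES.index("slow")
    fastish = [GROWTH_CLASSES.index("very_fast"), GROWTH_CLASSES.index("fast")]
    for j in fastish:
        gross[slow, j] = 1
        gross[j, slow] = 1
    exact = 100.0 * total / (k * total)
    approx = 100.0 * float(sizes @ acceptable.sum(axis=1)) / (k * total)
    wrong = 100.0 * float(sizes @ gross.sum(axis=1)) / (k * total)
    return exact, approx, wrong


def pairwise_relative_differences(
    values: Sequence[float], lambda_: float | None = None
) -> np.ndarray:
    """Pairwise |differences| normalised by the maximum over all pairs.

    Optionally Box-Cox-transforms the values first (as done for doubling
    times).  The maximising pair maps to exactly 1, the diagonal to 0.  All
    values identical yields an all-zero matrix with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least two values")
    t = box_cox(v, lambda_) if lambda_ is not None else v
    diff = np.abs(t[:, None] - t[None, :])
    m = diff.max()
    if m == 0:
        logger.warning("all values identical: degenerate normalisation, all zeros")
        return diff
    return diff / m
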