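"""Biomass regression and diagnostics.

Implements the statistical side of impedance-based biomass estimation:
layer-wise feature extraction from two-pole impedance tables, ordinary least
squares Ŷ = ω₀ + Σ ωᵢ Z_fᵢ with the usual t/F diagnostics, ridge regression
min ‖y − Zω‖² + α‖ω‖² with an unpenalized intercept, collinearity screening
(tolerance value TV = 1 − R², VIF = 1/TV), wrapper backward elimination on
individual t-tests, the published field-calibrated models, and Table-style
validation reports (per-sample absolute error %).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .acquisition import ImpedanceTable

__all__ = [
    "FeatureTable",
    "RegressionModel",
    "extract_layer_features",
    "fit_ols",
    "fit_ridge",
    "select_ridge_alpha",
    "collinearity_diagnostics",
    "backward_eliminate",
    "PUBLISHED_MODELS",
    "predict_published",
    "published_model",
    "validation_report",
    "correlate_spectrum",
    "RankDeficientError",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Raised when an OLS design is rank deficient; ridge handles these."""


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

LAYER_FEATURES = ["Znl1m", "Znl1SD", "Znl2m", "Znl2SD", "Znl3m", "Znl3SD"]


@dataclass
class FeatureTable:
    """Samples × features table with optional biomass response."""

    data: pd.DataFrame
    response: str | None = "weight_g"

    def X(self, features: list[str] | None = None) -> np.ndarray:
        cols = features or [c for c in self.data.columns if c not in (self.response, "sample_id", "frequency_hz")]
        return self.data[cols].to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        if self.response is None or self.response not in self.data.columns:
            raise ValueError("feature table has no response column")
        return self.data[self.response].to_numpy(dtype=float)


def extract_layer_features(
    table: ImpedanceTable,
    normalization: str = "sample_max",
    frequencies: list[float] | None = None,
    biomass: pd.DataFrame | None = None,
    n_layers: int = 3,
) -> FeatureTable:
    """Layer-wise mean/SD features of (normalized) impedances.

    For each sample and frequency the impedances are normalized — by default
    dividing by the sample's maximum over the analyzed spectrum, giving values
    in (0, 1] — and the per-layer mean and standard deviation are taken,
    six features for a three-layer array.
    """
    if normalization not in ("sample_max", "none"):
        raise ValueError(f"unknown normalization '{normalization}'")
    df = table.data
    freqs = sorted(frequencies or df["frequency_hz"].unique())
    layers = list(range(n_layers))
    missing = set(layers) - set(df["layer"].unique())
    if missing:
        raise ValueError(f"impedance table is missing layer(s) {sorted(missing)}")
    recs = []
    for sample, sdf in df.groupby("sample_id", sort=True):
        sdf = sdf[sdf["frequency_hz"].isin(freqs)]
        scale = sdf["impedance_ohm"].max() if normalization == "sample_max" else 1.0
        for f in freqs:
            fdf = sdf[np.isclose(sdf["frequency_hz"], f)]
            rec = {"sample_id": sample, "frequency_hz": f}
            for li, layer in enumerate(layers, start=1):
                vals = fdf.loc[fdf["layer"] == layer, "impedance_ohm"].to_numpy() / scale
                if vals.size == 0:
                    raise ValueError(f"sample {sample}: missing layer {layer} at {f} Hz")
                rec[f"Znl{li}m"] = float(vals.mean())
                rec[f"Znl{li}SD"] = float(vals.std(ddof=0))
            recs.append(rec)
    data = pd.DataFrame.from_records(recs)
    if biomass is not None:
        data = data.merge(biomass[["sample_id", "weight_g"]], on="sample_id", how="left")
        if data["weight_g"].isna().any():
            raise ValueError("biomass table does not cover all samples")
    return FeatureTable(data=data, response="weight_g" if biomass is not None else None)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class RegressionModel:
    """Linear model Ŷ = ω₀ + Σ ωᵢ·featureᵢ with fit diagnostics."""

    intercept: float
    coefficients: np.ndarray
    feature_names: list[str]
    r_squared: float = float("nan")
    adj_r_squared: float = float("nan")
    rmse: float = float("nan")
    t_values: np.ndarray | None = None
    p_values: np.ndarray | None = None
    f_pvalue: float = float("nan")
    alpha: float = 0.0
    provenance: str = "fitted"
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficient/feature-name length mismatch")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.coefficients):
            raise ValueError(
                f"model expects {len(self.coefficients)} features, got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients

    def to_json(self) -> str:
        d = asdict(self)
        d["coefficients"] = [repr(float(c)) for c in self.coefficients]
        d["intercept"] = repr(float(self.intercept))
        for k in ("t_values", "p_values"):
            if d[k] is not None:
                d[k] = [float(v) for v in d[k]]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RegressionModel":
        d = json.loads(text)
        d["coefficients"] = np.array([float(c) for c in d["coefficients"]])
        d["intercept"] = float(d["intercept"])
        for k in ("t_values", "p_values"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _rmse(resid: np.ndarray, n: int, k: int, divisor: str) -> float:
    if divisor == "n":
        return float(np.sqrt(np.sum(resid**2) / n))
    if divisor == "n-k-1":
        return float(np.sqrt(np.sum(resid**2) / max(n - k - 1, 1)))
    raise ValueError(f"unknown RMSE divisor '{divisor}'")


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    rmse_divisor: str = "n",
) -> RegressionModel:
    """Ordinary least squares with t/p per coefficient and the overall F-test."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k+1 samples (n={n}, k={k})")
    names = feature_names or [f"x{i + 1}" for i in range(k)]
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < k + 1:
        raise RankDeficientError(
            "design matrix is rank deficient; use fit_ridge for collinear features"
        )
    res = sm.OLS(y, design).fit()
    return RegressionModel(
        intercept=float(res.params[0]),
        coefficients=res.params[1:],
        feature_names=list(names),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        rmse=_rmse(res.resid, n, k, rmse_divisor),
        t_values=res.tvalues[1:],
        p_values=res.pvalues[1:],
        f_pvalue=float(res.f_pvalue),
        alpha=0.0,
    )


def fit_ridge(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    feature_names: list[str] | None = None,
    rmse_divisor: str = "n",
) -> RegressionModel:
    """Ridge regression with centered features and an unpenalized intercept.

    Minimizes ‖y − ω₀ − X_c ω‖² + α‖ω‖² where X_c is the centered design;
    at α = 0 this coincides with OLS on full-rank designs.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = feature_names or [f"x{i + 1}" for i in range(k)]
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    coef = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(k), Xc.T @ (y - ym))
    intercept = float(ym - xm @ coef)
    pred = intercept + X @ coef
    resid = y - pred
    tss = np.sum((y - ym) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else float("nan")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n > k + 1 else float("nan")
    return RegressionModel(
        intercept=intercept,
        coefficients=coef,
        feature_names=list(names),
        r_squared=float(r2),
        adj_r_squared=float(adj),
        rmse=_rmse(resid, n, k, rmse_divisor),
        alpha=float(alpha),
    )


def select_ridge_alpha(
    X: np.ndarray, y: np.ndarray, alphas: np.ndarray | None = None
) -> float:
    """Generalized cross-validation over a log grid of penalties."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if alphas is None:
        alphas = np.logspace(-6, 4, 41)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    best_alpha, best_gcv = float(alphas[0]), np.inf
    for a in alphas:
        H = Xc @ np.linalg.solve(Xc.T @ Xc + a * np.eye(k), Xc.T)
        resid = yc - H @ yc
        tr = 1.0 + np.trace(H)  # +1 for the unpenalized intercept
        gcv = n * np.sum(resid**2) / (n - tr) ** 2
        if gcv < best_gcv:
            best_gcv, best_alpha = gcv, float(a)
    return best_alpha


# ---------------------------------------------------------------------------
# Collinearity and selection
# ---------------------------------------------------------------------------


def collinearity_diagnostics(
    X: np.ndarray, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature R², tolerance value TV = 1 − R², VIF = 1/TV, and flags.

    A feature is flagged when TV < 0.1 (equivalently VIF > 10). Pairs with
    |Pearson r| > 0.95 are listed in the ``high_corr_with`` column as
    candidates for removal.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if n <= k:
        raise ValueError("need more samples than features for VIF")
    names = feature_names or [f"x{i + 1}" for i in range(k)]
    recs = []
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False) if k > 1 else np.ones((1, 1))
    for j in range(k):
        xj = X[:, j]
        if np.allclose(xj, xj[0]):
            r2, tv, vif = float("nan"), 0.0, float("inf")
        elif k == 1:
            r2, tv, vif = 0.0, 1.0, 1.0
        else:
            others = np.delete(X, j, axis=1)
            design = sm.add_constant(others, has_constant="add")
            res = sm.OLS(xj, design).fit()
            r2 = float(min(max(res.rsquared, 0.0), 1.0))
            tv = 1.0 - r2
            vif = 1.0 / tv if tv > 0 else float("inf")
        partners = [
            names[m]
            for m in range(k)
            if m != j and np.isfinite(corr[j, m]) and abs(corr[j, m]) > 0.95
        ]
        recs.append(
            {
                "feature": names[j],
                "r_squared": r2,
                "TV": tv,
                "VIF": vif,
                "flag": (tv < 0.1) or (vif > 10),
                "high_corr_with": ",".join(partners),
            }
        )
    return pd.DataFrame.from_records(recs)


def backward_eliminate(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    p_threshold: float = 0.05,
) -> tuple[list[str], RegressionModel]:
    """Wrapper backward elimination on individual coefficient t-tests.

    Iteratively refits OLS and drops the highest-p coefficient above the
    threshold until all remaining coefficients satisfy p ≤ threshold or a
    single feature remains. If the final model fails the overall F-test at
    the same threshold, a warning is attached to the model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = list(feature_names or [f"x{i + 1}" for i in range(X.shape[1])])
    if not names:
        raise ValueError("need at least one feature")
    selected = list(range(X.shape[1]))
    while True:
        model = fit_ols(X[:, selected], y, [names[i] for i in selected])
        pv = model.p_values
        worst = int(np.argmax(pv))
        if pv[worst] <= p_threshold or len(selected) == 1:
            break
        del selected[worst]
    if not (model.f_pvalue <= p_threshold):
        msg = (
            f"final model fails the overall F-test at p ≤ {p_threshold} "
            f"(p = {model.f_pvalue:.3g})"
        )
        model.warnings_.append(msg)
        warnings.warn(msg)
    return [names[i] for i in selected], model


# ---------------------------------------------------------------------------
# Published field-calibrated models
# ---------------------------------------------------------------------------

def _published(intercept: float, names: list[str], coefs: list[float]) -> RegressionModel:
    return RegressionModel(
        intercept=intercept,
        coefficients=np.array(coefs),
        feature_names=names,
        provenance="published",
    )


_LAYER = LAYER_FEATURES

#: Field-calibrated carrot biomass models (grams) from the sensor study:
#: eq1/eq2 select the 15 and 80 kHz features (raw and normalized impedance);
#: eq3–eq9 are per-frequency ridge models on layer-wise mean/SD features.
PUBLISHED_MODELS: dict[str, RegressionModel] = {
    "eq1_fresh_Z": _published(134.398, ["Z15kHz", "Z80kHz"], [-0.0446, 0.03822]),
    "eq2_fresh_Zn": _published(243.513, ["Zn15kHz", "Zn80kHz"], [-2836.9, 2037.23]),
    "eq3_5kHz": _published(
        -96.087, _LAYER, [-233.21, -128.67, 49.9868, -129.91, 1450.2, -1368.9]
    ),
    "eq4_15kHz": _published(
        -55.906, _LAYER, [-169.66, -206.4, 51.861, -150.46, 1159.67, -1298.9]
    ),
    "eq5_25kHz": _published(
        -33.322, _LAYER, [-279.12, -201.35, 67.6375, -159.93, 1112.1, -1301.1]
    ),
    "eq6_40kHz": _published(
        126.109, _LAYER, [26.5157, -11.87, 73.5124, -135.26, -133.24, -780.57]
    ),
    "eq7_60kHz": _published(
        98.7354, _LAYER, [-126.86, -49.358, 38.4318, -120.8, 209.306, -966.06]
    ),
    "eq8_80kHz": _published(
        120.781, _LAYER, [17.849, -43.993, 3.395, -98.86, -18.32, -838.4]
    ),
    "eq9_100kHz": _published(
        110.897, _LAYER, [126.187, -89.055, -3.9723, -94.445, -61.193, -885.88]
    ),
}


def published_model(model_id: str) -> RegressionModel:
    try:
        return PUBLISHED_MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id '{model_id}'; expected one of {sorted(PUBLISHED_MODELS)}"
        ) from None


def predict_published(model_id: str, features) -> float | np.ndarray:
    """Evaluate a published model at a feature vector (or matrix)."""
    model = published_model(model_id)
    features = np.asarray(features, dtype=float)
    single = features.ndim == 1
    out = model.predict(features)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Validation and correlation
# ---------------------------------------------------------------------------


def validation_report(actual, predicted) -> pd.DataFrame:
    """Per-sample absolute error % (round-half-even to 2 decimals) + summary.

    error_i = 100·|actual_i − predicted_i| / actual_i; accuracy_i = 100 −
    error_i. Attributes ``min_accuracy``/``max_error`` summarize the run.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if np.any(actual <= 0):
        raise ValueError("actual values must be positive")
    err = np.array([round(e, 2) for e in 100.0 * np.abs(actual - predicted) / actual])
    report = pd.DataFrame(
        {
            "sample": np.arange(1, len(actual) + 1),
            "actual_g": actual,
            "predicted_g": predicted,
            "abs_error_pct": err,
            "accuracy_pct": 100.0 - err,
        }
    )
    report.attrs["min_accuracy"] = float((100.0 - err).min())
    report.attrs["max_error"] = float(err.max())
    return report


def correlate_spectrum(
    impedances: pd.DataFrame, size: np.ndarray, value_col: str = "impedance_ohm"
) -> pd.DataFrame:
    """Pearson r (and simple-fit R²) between mean impedance and root size.

    ``impedances`` must carry ``sample_id`` and ``frequency_hz`` columns; the
    mean of ``value_col`` per sample/frequency is correlated against ``size``
    (one value per sample, aligned with sorted sample ids).
    """
    size = np.asarray(size, dtype=float)
    if size.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.allclose(size, size[0]):
        raise ValueError("size variable has zero variance")
    recs = []
    for f, fdf in impedances.groupby("frequency_hz", sort=True):
        means = fdf.groupby("sample_id", sort=True)[value_col].mean().to_numpy()
        if means.size != size.size:
            raise ValueError("size vector does not match sample count")
        if np.allclose(means, means[0]):
            raise ValueError(f"zero-variance impedance at {f} Hz")
        r, _ = scipy.stats.pearsonr(means, size)
        recs.append({"frequency_hz": float(f), "pearson_r": float(r), "r_squared": float(r * r)})
    return pd.DataFrame.from_records(recs)
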