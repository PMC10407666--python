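"""Per-landscape logistic stability models and the Ecological Stability Index.

The probability that a landscape pixel stays in its steady state is modelled
as a logistic function of the normalized environmental factors,

    log(P / (1 - P)) = beta0 + beta1*Z1 + ... + betan*Zn,

fitted by maximum likelihood (iteratively reweighted least squares with
step-halving, so the Bernoulli log-likelihood is non-decreasing across
iterations).  The fitted probability surface is the Ecological Stability
Index (ESI) of that landscape,

    ESI = P = exp(eta) / (1 + exp(eta)),   eta = beta0 + sum_i betai * Zi,

a value in (0, 1) where larger means more stable.  Because every Z lies in
[0, 1], the coefficient magnitudes are directly comparable across factors
and serve as the factor-contribution measure; odds ratios exp(beta) are
available as an alternative view.

Standard errors come from the observed information at the optimum.  Complete
or quasi-complete separation (a factor that splits the labels perfectly)
makes the MLE diverge; it is detected by a coefficient-magnitude guard and
reported as an error naming the offending factor rather than returning a
meaningless fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .raster import RasterGrid, RasterStack
from .sampling import FactorSpec, SampleTable

__all__ = [
    "StabilityModel",
    "ESILayer",
    "SeparationError",
    "fit_logistic",
    "fit_all_landscapes",
    "predict_esi",
    "factor_contributions",
]

#: |beta| beyond this on the Z scale is taken as evidence of separation
#: (odds ratio > e^15 across the unit interval is not a finite MLE).
SEPARATION_BETA_MAX = 15.0


class SeparationError(RuntimeError):
    """Raised when the MLE diverges due to (quasi-)complete separation."""


@dataclass
class StabilityModel:
    """Fitted logistic stability model for one landscape."""

    landscape_id: int
    beta0: float
    beta: np.ndarray  # (n_factors,), aligned with factor_specs
    se: np.ndarray  # (n_factors + 1,), intercept first
    loglik: float
    converged: bool
    n_samples: int
    n_iter: int
    factor_specs: list[FactorSpec] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.beta0], self.beta])

    def linear_predictor(self, z: np.ndarray) -> np.ndarray:
        """eta = beta0 + Z @ beta for Z of shape (n, n_factors)."""
        return self.beta0 + np.asarray(z) @ self.beta

    def predict_proba(self, z: np.ndarray) -> np.ndarray:
        return expit(self.linear_predictor(z))

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def to_dict(self) -> dict:
        return {
            "landscape_id": self.landscape_id,
            "beta0": self.beta0,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_samples": self.n_samples,
            "n_iter": self.n_iter,
            "factor_specs": [
                {"code": s.code, "name": s.name, "label": s.label, "vmin": s.vmin, "vmax": s.vmax}
                for s in self.factor_specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StabilityModel":
        return cls(
            landscape_id=int(d["landscape_id"]),
            beta0=float(d["beta0"]),
            beta=np.asarray(d["beta"], dtype=float),
            se=np.asarray(d["se"], dtype=float),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_samples=int(d["n_samples"]),
            n_iter=int(d.get("n_iter", 0)),
            factor_specs=[FactorSpec(**s) for s in d.get("factor_specs", [])],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "StabilityModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ESILayer:
    """Per-landscape ESI probability surface for one factor year."""

    landscape_id: int
    year: str
    values: RasterGrid  # float layer, NaN outside the landscape


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*log(p) + (1-y)*log(1-p), written overflow-free
    return float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta)))


def fit_logistic(
    z: np.ndarray,
    y: np.ndarray,
    landscape_id: int = 0,
    factor_specs: list[FactorSpec] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> StabilityModel:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    Parameters
    ----------
    z
        (n, n_factors) matrix of normalized covariates (an intercept column
        is added internally); may be empty (n, 0) for an intercept-only fit.
    y
        Binary labels in {0, 1}; both classes must be present.
    tol
        Convergence when max|step| < tol or the log-likelihood improves by
        less than tol.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z.reshape(-1, 1)
    y = np.asarray(y, dtype=float).ravel()
    n, k = z.shape
    if n != len(y):
        raise ValueError("z and y lengths differ")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if set(classes) <= {0.0, 1.0}:
            raise ValueError("both labels (0 and 1) must be present to fit")
        raise ValueError("labels must be binary {0,1}")
    if n <= k + 1:
        raise ValueError(f"need more than n_factors+1 = {k + 1} samples, got {n}")

    x = np.column_stack([np.ones(n), z])
    # rank check catches perfectly collinear Z before IRLS produces NaNs
    if np.linalg.matrix_rank(x) < k + 1:
        raise np.linalg.LinAlgError("singular design: collinear covariates")

    beta = np.zeros(k + 1)
    ll = _bernoulli_loglik(y, x @ beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = x @ beta
        p = expit(eta)
        w = p * (1 - p)
        # Newton/IRLS step on the observed information
        xtw = x.T * w
        try:
            step = np.linalg.solve(xtw @ x, x.T @ (y - p))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"singular design during IRLS: {exc}") from exc
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _bernoulli_loglik(y, x @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll_new = _bernoulli_loglik(y, x @ beta)
        trace.append(ll_new)
        if np.max(np.abs(beta)) > SEPARATION_BETA_MAX:
            j = int(np.argmax(np.abs(beta)))
            name = "intercept" if j == 0 else (
                factor_specs[j - 1].code if factor_specs else f"Z{j}"
            )
            raise SeparationError(
                f"complete or quasi-complete separation detected: |beta[{name}]| "
                f"= {abs(beta[j]):.2f} exceeds {SEPARATION_BETA_MAX} on the Z scale"
            )
        if np.max(np.abs(scale * step)) < tol or abs(ll_new - ll) < tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new

    p = expit(x @ beta)
    w = p * (1 - p)
    info = (x.T * w) @ x
    se = np.sqrt(np.diag(np.linalg.inv(info)))

    return StabilityModel(
        landscape_id=landscape_id,
        beta0=float(beta[0]),
        beta=beta[1:].copy(),
        se=se,
        loglik=float(ll),
        converged=converged,
        n_samples=n,
        n_iter=it,
        factor_specs=list(factor_specs or []),
        loglik_trace=trace,
    )


def fit_from_samples(
    samples: SampleTable,
    landscape_id: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> StabilityModel:
    """Fit one landscape's model from a sample table."""
    sub = samples.for_landscape(landscape_id)
    if sub.empty:
        raise ValueError(f"no samples for landscape {landscape_id}")
    z = sub[samples.z_columns].to_numpy(dtype=float)
    y = sub["label"].to_numpy()
    return fit_logistic(
        z, y, landscape_id=landscape_id, factor_specs=samples.specs[landscape_id],
        tol=tol, max_iter=max_iter,
    )


def fit_all_landscapes(
    samples: SampleTable, tol: float = 1e-8, max_iter: int = 100
) -> dict[int, StabilityModel]:
    """Fit every landscape with two label classes; degenerate ones are skipped."""
    models: dict[int, StabilityModel] = {}
    for lid in sorted(samples.specs):
        if "degenerate labels" in samples.flags.get(lid, []):
            continue
        models[lid] = fit_from_samples(samples, lid, tol=tol, max_iter=max_iter)
    return models


def predict_esi(
    model: StabilityModel,
    factors: RasterStack,
    landscape_mask: RasterGrid,
    year: str = "",
) -> ESILayer:
    """Map the fitted probability surface over one landscape.

    Raw factor layers are normalized with the model's own FactorSpec (so
    prediction is self-contained), the linear predictor is evaluated per
    pixel and squashed through a numerically stable logistic; output values
    are clamped to the open interval (0, 1) at float resolution.
    """
    if not model.factor_specs:
        raise ValueError("model carries no FactorSpec; cannot normalize raw factors")
    for spec in model.factor_specs:
        if spec.label not in factors.labels:
            raise KeyError(f"factor layer {spec.label!r} missing from the stack")
    cube = factors.subset([s.label for s in model.factor_specs]).as_array()
    # landscape domain: valid cells with a nonzero membership value
    mask = landscape_mask.valid_mask() & (landscape_mask.values != 0)
    z = np.stack([spec.apply(cube[i]) for i, spec in enumerate(model.factor_specs)])
    eta = model.beta0 + np.tensordot(model.beta, z, axes=1)
    p = expit(eta)
    tiny = np.finfo(float).tiny
    eps = np.finfo(float).epsneg
    p = np.clip(p, tiny, 1.0 - eps)
    out = np.full(landscape_mask.shape, np.nan)
    out[mask] = p[mask]
    grid = landscape_mask.with_values(out, nodata=None)
    return ESILayer(landscape_id=model.landscape_id, year=year, values=grid)


def factor_contributions(model: StabilityModel, metric: str = "coefficient") -> pd.DataFrame:
    """Rank the drivers of stability for one landscape.

    Contribution = the fitted coefficient on the normalized (Z in [0,1])
    scale, sorted by magnitude, ties broken by factor code; ``metric=
    'odds_ratio'`` adds the exp(beta) view.
    """
    if not model.converged:
        raise ValueError("factor contributions require a converged model")
    if metric not in ("coefficient", "odds_ratio"):
        raise ValueError(f"unknown metric {metric!r}")
    codes = [s.code for s in model.factor_specs] or [f"Z{i+1}" for i in range(len(model.beta))]
    df = pd.DataFrame(
        {
            "factor": codes,
            "coefficient": model.beta,
            "se": model.se[1:],
            "sign": np.sign(model.beta).astype(int),
        }
    )
    if metric == "odds_ratio":
        df["odds_ratio"] = np.exp(model.beta)
    order = sorted(range(len(df)), key=lambda i: (-abs(model.beta[i]), codes[i]))
    return df.iloc[order].reset_index(drop=True)
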