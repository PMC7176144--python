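"""Maximum-likelihood detection functions for line-transect distances.

Perpendicular detection distances x within a truncation distance w are
modelled by a key function g(x), half-normal ``exp(-x^2 / 2 sigma^2)`` or
hazard-rate ``1 - exp(-(x/sigma)^-b)``, optionally with covariates entering
the scale log-linearly (multiple-covariate distance sampling): group size is
log-transformed, platform is a stern indicator.  The conditional likelihood
of the observed distances is

    L = prod_i  g(x_i | z_i) / integral_0^w g(u | z_i) du

maximized over the scale intercept, covariate coefficients and (hazard-rate)
shape.  The per-observation integral is the effective (half) strip width
ESW; its average over observations is the Horvitz-Thompson-consistent
covariate-averaged ESW, f(0) = 1/ESW, and the average detection probability
is ESW / w.  Model ranking uses AICc; ESW uncertainty is a delta-method CV
through the inverse observed information.

No cosine/polynomial adjustment terms: the candidate set is key + covariates
only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import survey_data as sd

KEYS = ("half_normal", "hazard_rate")
COVARIATES = ("group_size", "platform")
DEFAULT_CANDIDATES = ("hr", "hr+gs", "hr+pt", "hr+gs+pt", "hn", "hn+gs", "hn+pt", "hn+gs+pt")

_GL_NODES = 96  # Gauss-Legendre order for the hazard-rate ESW integral
_KEY_SHORT = {"hr": "hazard_rate", "hn": "half_normal"}
_COV_SHORT = {"gs": "group_size", "pt": "platform"}


class DetectionFitError(RuntimeError):
    """Fit failure: too few observations, degenerate data, or non-convergence."""


def parse_candidate(name: str) -> tuple[str, tuple[str, ...]]:
    """Parse a short model name like ``"hr+gs+pt"`` into (key, covariates)."""
    parts = [p.strip() for p in name.split("+")]
    if parts[0] not in _KEY_SHORT:
        raise DetectionFitError(f"unknown key {parts[0]!r} in candidate {name!r}")
    covs = []
    for p in parts[1:]:
        if p not in _COV_SHORT:
            raise DetectionFitError(f"unknown covariate {p!r} in candidate {name!r}")
        covs.append(_COV_SHORT[p])
    return _KEY_SHORT[parts[0]], tuple(covs)


def _g_halfnormal(x: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    return np.exp(-(x * x) / (2.0 * sigma * sigma))


def _g_hazard(x: np.ndarray, sigma: np.ndarray, b: float) -> np.ndarray:
    out = np.ones(np.broadcast_shapes(np.shape(x), np.shape(sigma)))
    x, sigma = np.broadcast_arrays(x, sigma)
    pos = x > 0
    with np.errstate(over="ignore"):
        u = np.exp(np.minimum(-b * np.log(x[pos] / sigma[pos]), 700.0))
    out[pos] = -np.expm1(-u)
    return out


def _esw_halfnormal(sigma: np.ndarray, w: float) -> np.ndarray:
    # closed form: integral_0^w exp(-x^2/2s^2) dx = s sqrt(pi/2) erf(w / s sqrt(2))
    sigma = np.asarray(sigma, dtype=float)
    if math.isinf(w):
        return sigma * math.sqrt(math.pi / 2.0)
    return sigma * math.sqrt(math.pi / 2.0) * special.erf(w / (sigma * math.sqrt(2.0)))


def _esw_hazard(sigma: np.ndarray, b: float, w: float) -> np.ndarray:
    if math.isinf(w):
        raise DetectionFitError("hazard-rate key needs a finite truncation distance")
    nodes, weights = np.polynomial.legendre.leggauss(_GL_NODES)
    t = 0.5 * w * (nodes + 1.0)  # map [-1,1] -> [0,w]
    wt = 0.5 * w * weights
    g = _g_hazard(t[:, None], np.asarray(sigma, dtype=float)[None, :], b)
    return g.T @ wt


@dataclass(frozen=True)
class DetectionFit:
    """A fitted detection function with selection and precision summaries."""

    key: str
    covariates: tuple[str, ...]
    params: np.ndarray  # [log sigma0, beta..., log b (hazard-rate)]
    loglik: float
    n_obs: int
    n_params: int
    aicc: float
    esw_m: float
    f0_per_km: float
    p_avg: float
    cv_esw: float
    truncation_m: float
    vcov: np.ndarray | None = None
    sigmas_m: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    esw_per_obs_m: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    design: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def scale_m(self) -> float:
        """Baseline scale sigma (bow platform, unit group) in meters."""
        return math.exp(self.params[0])

    @property
    def shape(self) -> float | None:
        if self.key != "hazard_rate":
            return None
        return math.exp(self.params[-1])

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Covariate-averaged density of detection distances on [0, w]."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.key == "half_normal":
            g = _g_halfnormal(x[:, None], self.sigmas_m[None, :])
        else:
            g = _g_hazard(x[:, None], self.sigmas_m[None, :], self.shape)
        return (g / self.esw_per_obs_m[None, :]).mean(axis=1)


def _design_matrix(
    gs: np.ndarray, pt: np.ndarray, covariates: Sequence[str]
) -> np.ndarray:
    cols = []
    for c in covariates:
        if c == "group_size":
            cols.append(np.log(gs))
        elif c == "platform":
            cols.append(pt)
        else:
            raise DetectionFitError(f"unknown covariate {c!r}")
    if not cols:
        return np.zeros((len(gs), 0))
    return np.column_stack(cols)


def _extract_arrays(
    sightings: Sequence[sd.SightingRecord] | pd.DataFrame, truncation_m: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(sightings, pd.DataFrame):
        frame = sightings
        x = frame["perp_distance_m"].to_numpy(dtype=float)
        gs = (
            frame["group_size"].to_numpy(dtype=float)
            if "group_size" in frame
            else np.ones_like(x)
        )
        pt = (
            (frame["platform"] == "stern").to_numpy(dtype=float)
            if "platform" in frame
            else np.zeros_like(x)
        )
    else:
        records = sd.unique_groups(list(sightings))
        x = np.array([s.perp_distance_m for s in records], dtype=float)
        gs = np.array([s.group_size for s in records], dtype=float)
        pt = np.array([1.0 if s.platform == "stern" else 0.0 for s in records])
    keep = x <= truncation_m
    return x[keep], gs[keep], pt[keep]


def _negloglik(
    p: np.ndarray, x: np.ndarray, Z: np.ndarray, key: str, w: float
) -> float:
    log_sigma = p[0] + (Z @ p[1 : 1 + Z.shape[1]] if Z.shape[1] else np.zeros(len(x)))
    if np.any(log_sigma > 25) or np.any(log_sigma < -10):
        return 1e12
    sigma = np.exp(log_sigma)
    if key == "half_normal":
        g = _g_halfnormal(x, sigma)
        mu = _esw_halfnormal(sigma, w)
    else:
        b = math.exp(p[-1])
        if not 0.05 < b < 50:
            return 1e12
        g = _g_hazard(x, sigma, b)
        mu = _esw_hazard(sigma, b, w)
    if np.any(g <= 0) or np.any(mu <= 0):
        return 1e12
    val = -(np.sum(np.log(g)) - np.sum(np.log(mu)))
    return float(val) if np.isfinite(val) else 1e12


def _hessian(fun, p: np.ndarray, h_scale: float = 1e-4) -> np.ndarray:
    n = len(p)
    h = h_scale * (1.0 + np.abs(p))
    H = np.empty((n, n))
    f0 = fun(p)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        for j in range(i, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(p + ei) - 2.0 * f0 + fun(p - ei)) / (h[i] * h[i])
            else:
                H[i, j] = H[j, i] = (
                    fun(p + ei + ej) - fun(p + ei - ej) - fun(p - ei + ej) + fun(p - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def _gradient(fun, p: np.ndarray, h_scale: float = 1e-5) -> np.ndarray:
    n = len(p)
    h = h_scale * (1.0 + np.abs(p))
    g = np.empty(n)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        g[i] = (fun(p + ei) - fun(p - ei)) / (2.0 * h[i])
    return g


def fit_detection(
    sightings: Sequence[sd.SightingRecord] | pd.DataFrame,
    key: str = "hazard_rate",
    covariates: Sequence[str] = (),
    truncation_m: float = 300.0,
    min_n: int = 10,
    n_restarts: int = 5,
    seed: int = 0,
) -> DetectionFit:
    """Fit one detection model to line-transect perpendicular distances.

    ``sightings`` may be SightingRecords (deduplicated to unique groups) or a
    DataFrame with ``perp_distance_m`` and optional ``group_size``/``platform``
    columns.  Optimization is multi-start L-BFGS-B from moment-style initial
    values (sigma0 = sd of distances, b0 = 2) with seeded jitter.
    """
    if key not in KEYS:
        raise DetectionFitError(f"unknown key {key!r}")
    for c in covariates:
        if c not in COVARIATES:
            raise DetectionFitError(f"unknown covariate {c!r}")
    x, gs, pt = _extract_arrays(sightings, truncation_m)
    n = len(x)
    if n < min_n:
        raise DetectionFitError(
            f"need >= {min_n} sightings within {truncation_m} m, got {n}"
        )
    if np.any(x < 0):
        raise DetectionFitError("negative perpendicular distances")
    if float(np.std(x)) == 0.0:
        raise DetectionFitError("all distances identical; detection scale unidentifiable")
    Z = _design_matrix(gs, pt, covariates)

    def nll(p: np.ndarray) -> float:
        return _negloglik(p, x, Z, key, truncation_m)

    n_beta = Z.shape[1]
    k = 1 + n_beta + (1 if key == "hazard_rate" else 0)
    p0 = np.zeros(k)
    p0[0] = math.log(max(float(np.std(x)), 1e-6))
    if key == "hazard_rate":
        p0[-1] = math.log(2.0)

    rng = np.random.default_rng(seed)
    best = None
    starts = [p0] + [p0 + rng.normal(0.0, 0.5, size=k) for _ in range(max(n_restarts - 1, 0))]
    for start in starts:
        try:
            res = optimize.minimize(
                nll, start, method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500}
            )
        except Exception:  # noqa: BLE001 - keep trying other starts
            continue
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise DetectionFitError(
            f"detection fit did not converge for key={key} covariates={covariates} "
            f"after {len(starts)} starts"
        )

    p_hat = best.x
    loglik = -float(best.fun)
    log_sigma = p_hat[0] + (Z @ p_hat[1 : 1 + n_beta] if n_beta else np.zeros(n))
    sigmas = np.exp(log_sigma)
    if key == "half_normal":
        esw_per_obs = _esw_halfnormal(sigmas, truncation_m)
    else:
        esw_per_obs = _esw_hazard(sigmas, math.exp(p_hat[-1]), truncation_m)
    esw = float(np.mean(esw_per_obs))
    p_avg = esw / truncation_m if math.isfinite(truncation_m) else math.nan

    if n - k - 1 > 0:
        aicc = 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1) / (n - k - 1)
    else:
        warnings.warn(f"AICc undefined at n={n}, k={k}; reporting +inf", stacklevel=2)
        aicc = math.inf

    # delta-method CV of the covariate-averaged ESW
    vcov = None
    cv_esw = math.nan
    H = _hessian(nll, p_hat)
    try:
        vcov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov = None
    if vcov is not None and np.all(np.isfinite(vcov)) and np.all(np.diag(vcov) > 0):

        def esw_of(p: np.ndarray) -> float:
            ls = p[0] + (Z @ p[1 : 1 + n_beta] if n_beta else np.zeros(n))
            s = np.exp(ls)
            if key == "half_normal":
                return float(np.mean(_esw_halfnormal(s, truncation_m)))
            return float(np.mean(_esw_hazard(s, math.exp(p[-1]), truncation_m)))

        grad = _gradient(esw_of, p_hat)
        var_esw = float(grad @ vcov @ grad)
        if var_esw > 0:
            cv_esw = math.sqrt(var_esw) / esw
    else:
        vcov = None

    return DetectionFit(
        key=key,
        covariates=tuple(covariates),
        params=p_hat,
        loglik=loglik,
        n_obs=n,
        n_params=k,
        aicc=aicc,
        esw_m=esw,
        f0_per_km=1000.0 / esw,
        p_avg=p_avg,
        cv_esw=cv_esw,
        truncation_m=truncation_m,
        vcov=vcov,
        sigmas_m=sigmas,
        esw_per_obs_m=esw_per_obs,
        design=Z,
    )


def esw_cv(fit: DetectionFit) -> float:
    """Delta-method CV of the effective strip width from the inverse observed
    information; raises when the information matrix was singular."""
    if fit.vcov is None or not math.isfinite(fit.cv_esw):
        raise DetectionFitError(
            "observed information is singular; ESW CV unavailable — "
            "consider a simpler detection model"
        )
    return fit.cv_esw


@dataclass(frozen=True)
class RankedModel:
    name: str
    fit: DetectionFit
    delta_aicc: float


def select_model(
    sightings: Sequence[sd.SightingRecord] | pd.DataFrame,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    truncation_m: float = 300.0,
    **fit_kwargs,
) -> list[RankedModel]:
    """Fit every candidate model and rank by AICc ascending.

    Candidates failing to fit are excluded with a warning; ties in AICc
    break toward fewer parameters.
    """
    if len(candidates) < 2:
        raise DetectionFitError("need >= 2 candidate models to rank")
    fits: list[tuple[str, DetectionFit]] = []
    for name in candidates:
        key, covs = parse_candidate(name)
        try:
            fits.append((name, fit_detection(sightings, key, covs, truncation_m, **fit_kwargs)))
        except DetectionFitError as exc:
            warnings.warn(f"candidate {name!r} excluded: {exc}", stacklevel=2)
    if not fits:
        raise DetectionFitError("every candidate model failed to fit")
    fits.sort(key=lambda item: (item[1].aicc, item[1].n_params))
    best_aicc = fits[0][1].aicc
    return [RankedModel(name, fit, fit.aicc - best_aicc) for name, fit in fits]


def fit_report(ranked: Sequence[RankedModel]) -> pd.DataFrame:
    """Model-selection report: model, AICc, delta AICc, average detection
    probability P and CV of the effective strip width."""
    rows = [
        {
            "model": r.name,
            "AICc": round(r.fit.aicc, 2),
            "dAICc": round(r.delta_aicc, 2),
            "P": round(r.fit.p_avg, 2),
            "CV": round(r.fit.cv_esw, 2) if math.isfinite(r.fit.cv_esw) else math.nan,
        }
        for r in ranked
    ]
    return pd.DataFrame(rows, columns=["model", "AICc", "dAICc", "P", "CV"])
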