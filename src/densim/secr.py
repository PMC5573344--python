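"""Maximum-likelihood spatially explicit capture-recapture (SECR).

Binary proximity detectors, homogeneous Poisson activity centers and a
half-normal detection function

    p(s, k) = g0 * exp(-||s - x_k||^2 / (2 sigma^2)),

with optional site-specific behavioral ("bk") and detector-type effects on
g0 (additive on the logit scale).  The full likelihood integrates each
observed individual's history over a discrete habitat mask and models the
number observed as Poisson(D * effective sampled area):

    ln L = -D a(theta) + n ln D + sum_i ln integral Pr(omega_i | s) ds - ln n!

where a(theta) = integral of p.(s), the probability of at least one
detection, over the mask.  Animals removed at a corral trap contribute
occasions only up to their removal (their later occasions carry no Bernoulli
terms); never-detected animals were never removed, so the p.(s) thinning
term runs over the full effort.  Parameters are estimated on link scales
(log D, logit g0, log sigma) by quasi-Newton search with multiple jittered
starts; Wald SEs come from the inverse numerical Hessian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln, logit, logsumexp
from sklearn.base import BaseEstimator

from .types import CAMERA, TRAP, DetectorArray, EncounterHistory, SECRFit

__all__ = ["HabitatMask", "SECRModelSpec", "build_mask", "secr_loglik",
           "fit_secr", "aicc_table", "SECREstimator", "DEFAULT_MODEL_SET"]


# ---------------------------------------------------------------------------
# habitat mask

@dataclass
class HabitatMask:
    """Discrete grid of candidate activity-center locations."""

    points: np.ndarray  # (M, 2) km
    spacing_km: float
    buffer_km: float

    @property
    def cell_area(self) -> float:
        return self.spacing_km ** 2

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        return self.n_points * self.cell_area

    def extent(self) -> tuple[float, float, float, float]:
        p = self.points
        h = self.spacing_km / 2
        return (p[:, 0].min() - h, p[:, 1].min() - h,
                p[:, 0].max() + h, p[:, 1].max() + h)


def build_mask(detectors: DetectorArray, buffer_km: float,
               spacing_km: float) -> HabitatMask:
    """Rectangular mask covering the detector hull plus a buffer.

    Cell centers on a square lattice; a buffer of at least twice the
    expected sigma is recommended so that truncation of the activity-center
    integral is negligible.
    """
    if spacing_km <= 0:
        raise ValueError("spacing_km must be > 0")
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    c = detectors.coords()
    x0, x1 = c[:, 0].min() - buffer_km, c[:, 0].max() + buffer_km
    y0, y1 = c[:, 1].min() - buffer_km, c[:, 1].max() + buffer_km
    nx = max(1, math.ceil((x1 - x0) / spacing_km))
    ny = max(1, math.ceil((y1 - y0) / spacing_km))
    xs = x0 + spacing_km * (np.arange(nx) + 0.5)
    ys = y0 + spacing_km * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if len(pts) == 0:
        raise ValueError("empty habitat mask")
    return HabitatMask(pts, spacing_km, buffer_km)


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class SECRModelSpec:
    """Which effects enter g0: site-specific behavioral response ("bk") and a
    camera-vs-trap detector-type effect.  sigma and D are always shared."""

    behavior: bool = False
    type_effect: bool = False

    @property
    def name(self) -> str:
        parts = [p for p, on in (("bk", self.behavior),
                                 ("type", self.type_effect)) if on]
        return "g0~" + ("+".join(parts) if parts else "1")

    @property
    def n_params(self) -> int:
        return 3 + self.behavior + self.type_effect


DEFAULT_MODEL_SET: tuple[SECRModelSpec, ...] = (
    SECRModelSpec(),
    SECRModelSpec(behavior=True),
    SECRModelSpec(type_effect=True),
    SECRModelSpec(behavior=True, type_effect=True),
)


# ---------------------------------------------------------------------------
# sufficient statistics

@dataclass
class _SECRData:
    """History collapsed to per-(individual, detector) Bernoulli counts.

    With a behavioral effect the occasions at each detector split at the
    first detection there: 'naive' occasions before/at it, 'experienced'
    after.  Without it everything is naive.
    """

    d2: np.ndarray          # (M, K) squared mask-detector distances
    is_trap: np.ndarray     # (K,) float 0/1
    hits_naive: np.ndarray  # (n, K)
    miss_naive: np.ndarray
    hits_exp: np.ndarray
    miss_exp: np.ndarray
    t_full: np.ndarray      # (K,) active occasions per detector, full study
    cell_area: float
    n: int


def _collapse_history(history: EncounterHistory, detectors: pd.DataFrame,
                      mask: HabitatMask, behavior: bool) -> _SECRData:
    ncam = history.n_camera_occasions
    last = history.n_occasions - 1
    det_ids = detectors["id"].to_numpy()
    det_type = detectors["type"].to_numpy()
    is_trap = (det_type == TRAP).astype(float)
    k_of = {d: k for k, d in enumerate(det_ids)}
    K = len(det_ids)

    rec = history.records
    rec = rec[rec["detector_id"].isin(k_of)]
    if len(rec) == 0:
        raise ValueError("no detections: SECR likelihood undefined")
    inds = sorted(rec["individual_id"].unique())
    i_of = {a: i for i, a in enumerate(inds)}
    n = len(inds)

    # last at-risk occasion per individual (removal truncation)
    r_last = np.full(n, last)
    removed = rec[rec["removed_flag"]]
    for aid, occ in zip(removed["individual_id"], removed["occasion"]):
        r_last[i_of[aid]] = min(r_last[i_of[aid]], occ)

    # active occasions of detector k while individual i is at risk
    def t_ik(r_last_i: np.ndarray) -> np.ndarray:
        cam_t = np.minimum(r_last_i, ncam - 1) + 1 if ncam > 0 else \
            np.zeros_like(r_last_i)
        trap_t = np.maximum(0, np.minimum(r_last_i, last) - ncam + 1)
        return np.where(is_trap[None, :] > 0, trap_t[:, None],
                        np.maximum(0, cam_t)[:, None]).astype(float)

    T = t_ik(r_last)  # (n, K)
    y = np.zeros((n, K))
    first = np.full((n, K), -1)
    grouped = rec.groupby(["individual_id", "detector_id"])["occasion"]
    for (aid, did), occs in grouped:
        i, k = i_of[aid], k_of[did]
        y[i, k] = len(occs)
        first[i, k] = occs.min()

    if behavior:
        # occasions up to and including the first detection are naive
        pos = np.where(first >= 0,
                       np.where(is_trap[None, :] > 0, first - ncam + 1,
                                first + 1), 0).astype(float)
        hits_naive = (first >= 0).astype(float)
        miss_naive = np.where(first >= 0, pos - 1, T)
        exp_occ = np.where(first >= 0, T - pos, 0.0)
        hits_exp = np.where(first >= 0, y - 1, 0.0)
        miss_exp = exp_occ - hits_exp
    else:
        hits_naive, miss_naive = y, T - y
        hits_exp = np.zeros_like(y)
        miss_exp = np.zeros_like(y)
    if (miss_naive < -1e-9).any() or (miss_exp < -1e-9).any():
        raise ValueError("inconsistent encounter history (more detections "
                         "than at-risk occasions)")

    det_xy = detectors[["x_km", "y_km"]].to_numpy(float)
    diff = mask.points[:, None, :] - det_xy[None, :, :]
    d2 = np.einsum("mkc,mkc->mk", diff, diff)
    t_full = np.where(is_trap > 0, float(history.n_trap_occasions),
                      float(ncam))
    return _SECRData(d2=d2, is_trap=is_trap, hits_naive=hits_naive,
                     miss_naive=np.maximum(miss_naive, 0.0),
                     hits_exp=hits_exp, miss_exp=np.maximum(miss_exp, 0.0),
                     t_full=t_full, cell_area=mask.cell_area, n=n)


def _theta_unpack(theta: np.ndarray, spec: SECRModelSpec):
    log_d, logit_g0 = theta[0], theta[1]
    i = 2
    beta_bk = theta[i] if spec.behavior else 0.0
    i += spec.behavior
    beta_type = theta[i] if spec.type_effect else 0.0
    i += spec.type_effect
    log_sigma = theta[i]
    return log_d, logit_g0, beta_bk, beta_type, log_sigma


def _loglik_core(theta: np.ndarray, data: _SECRData,
                 spec: SECRModelSpec) -> float:
    log_d, logit_g0, beta_bk, beta_type, log_sigma = _theta_unpack(theta,
                                                                   spec)
    sigma = math.exp(log_sigma)
    d_dens = math.exp(log_d)
    hn = np.exp(-data.d2 / (2.0 * sigma ** 2))       # (M, K)
    g0_naive = expit(logit_g0 + beta_type * data.is_trap)   # (K,)
    with np.errstate(divide="ignore"):
        p_n = np.clip(g0_naive[None, :] * hn, 1e-300, 1 - 1e-12)
        l1n, l0n = np.log(p_n), np.log1p(-p_n)
        # per-individual mask log-likelihood surface  (M, n)
        surf = (l1n @ data.hits_naive.T) + (l0n @ data.miss_naive.T)
        if spec.behavior:
            g0_exp = expit(logit_g0 + beta_bk + beta_type * data.is_trap)
            p_e = np.clip(g0_exp[None, :] * hn, 1e-300, 1 - 1e-12)
            surf += (np.log(p_e) @ data.hits_exp.T
                     + np.log1p(-p_e) @ data.miss_exp.T)
    log_a_i = logsumexp(surf, axis=0) + math.log(data.cell_area)
    # overall detection probability p.(s), naive state, full effort
    log_miss_all = l0n @ data.t_full
    a_theta = data.cell_area * float(np.sum(-np.expm1(log_miss_all)))
    n = data.n
    return (-d_dens * a_theta + n * log_d + float(np.sum(log_a_i))
            - gammaln(n + 1))


def secr_loglik(history: EncounterHistory, detectors: DetectorArray | pd.DataFrame,
                mask: HabitatMask, params: dict,
                model_spec: SECRModelSpec = SECRModelSpec()) -> float:
    """Full SECR log-likelihood at natural-scale ``params``.

    ``params`` keys: density (animals/km^2), g0, sigma (km), and optionally
    beta_bk / beta_type (log-odds effects) when the model includes them.
    """
    det = detectors.detectors if isinstance(detectors, DetectorArray) else \
        detectors
    data = _collapse_history(history, det, mask, model_spec.behavior)
    theta = [math.log(params["density"]), logit(params["g0"])]
    if model_spec.behavior:
        theta.append(params.get("beta_bk", 0.0))
    if model_spec.type_effect:
        theta.append(params.get("beta_type", 0.0))
    theta.append(math.log(params["sigma"]))
    return float(_loglik_core(np.asarray(theta, float), data, model_spec))


# ---------------------------------------------------------------------------
# fitting

def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar ``f`` at ``x``."""
    k = len(x)
    h = np.maximum(eps, eps * np.abs(x))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                4 * h[i] * h[j])
    return hess


def _spatial_recaptures(history: EncounterHistory) -> int:
    """Number of individuals detected at >= 2 distinct detectors."""
    g = history.records.groupby("individual_id")["detector_id"].nunique()
    return int((g >= 2).sum())


def _start_values(history: EncounterHistory, detectors: pd.DataFrame,
                  data: _SECRData, spec: SECRModelSpec,
                  mask: HabitatMask) -> np.ndarray:
    rec = history.records.merge(
        detectors[["id", "x_km", "y_km"]], left_on="detector_id",
        right_on="id")
    # pooled spatial spread of within-individual detection locations
    devs = []
    for _, grp in rec.groupby("individual_id"):
        if len(grp) >= 2:
            devs.append(grp["x_km"] - grp["x_km"].mean())
            devs.append(grp["y_km"] - grp["y_km"].mean())
    if devs:
        pooled = float(np.sqrt(np.mean(np.concatenate(devs) ** 2)))
    else:
        pooled = 0.0
    sigma0 = pooled if pooled > 1e-3 else 0.5
    g0_0 = 0.2
    theta = [0.0, float(logit(g0_0))]
    if spec.behavior:
        theta.append(0.0)
    if spec.type_effect:
        theta.append(0.0)
    theta.append(math.log(sigma0))
    theta = np.asarray(theta, float)
    # crude density start: n over effective area at the start kernel
    probe = theta.copy()
    ll0 = _loglik_core(probe, data, spec)  # noqa: F841  (warms caches)
    hn = np.exp(-data.d2 / (2 * sigma0 ** 2))
    pdot = -np.expm1(np.log1p(-np.clip(g0_0 * hn, 0, 1 - 1e-12))
                     @ data.t_full)
    a0 = data.cell_area * float(pdot.sum())
    if a0 > 0:
        theta[0] = math.log(max(data.n / a0, 1e-3))
    return theta


def fit_secr(history: EncounterHistory,
             detectors: DetectorArray | pd.DataFrame,
             mask: HabitatMask,
             model_spec: SECRModelSpec = SECRModelSpec(),
             start: Optional[np.ndarray] = None,
             n_starts: int = 3, seed: int = 0,
             tol: float = 1e-8) -> SECRFit:
    """Maximize the SECR likelihood; failures are flagged, not raised.

    Multi-start quasi-Newton (BFGS) on the link scale.  The fit is flagged
    non-converged when no individual was detected at two distinct detectors
    (sigma unidentifiable), when the optimizer fails from every start, or
    when the Hessian is not positive definite.
    """
    det = detectors.detectors if isinstance(detectors, DetectorArray) else \
        detectors

    def _failed(msg: str, n_ind: int = 0) -> SECRFit:
        return SECRFit(density=float("nan"), g0={}, sigma=float("nan"),
                       se_density=float("nan"), se_log_density=float("nan"),
                       loglik=float("nan"), n_params=model_spec.n_params,
                       aicc=float("inf"), converged=False, message=msg,
                       model=model_spec.name, n_individuals=n_ind)

    try:
        data = _collapse_history(history, det, mask, model_spec.behavior)
    except ValueError as e:
        return _failed(str(e))
    if _spatial_recaptures(history) == 0:
        return _failed("no spatial recaptures: sigma unidentifiable", data.n)

    if start is None:
        start = _start_values(history, det, data, model_spec, mask)
    start = np.asarray(start, float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def nll(theta: np.ndarray) -> float:
        val = _loglik_core(theta, data, model_spec)
        return -val if np.isfinite(val) else 1e12

    best = None
    for s in range(max(1, n_starts)):
        x0 = start if s == 0 else start + rng.normal(0, 0.3, len(start))
        try:
            res = optimize.minimize(nll, x0, method="BFGS",
                                    options={"gtol": 1e-6, "maxiter": 500})
        except Exception:
            continue
        if best is None or res.fun < best.fun - tol:
            best = res
        # further jittered starts only rescue a failed search
        if res.success and np.isfinite(res.fun) and res.fun < 1e11:
            break
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        return _failed("optimizer failed from every start", data.n)

    theta = best.x
    log_d, logit_g0, beta_bk, beta_type, log_sigma = _theta_unpack(
        theta, model_spec)
    hess = _numerical_hessian(nll, theta)
    converged = True
    message = "ok"
    try:
        eigs = np.linalg.eigvalsh(hess)
        if eigs.min() <= 0:
            converged = False
            message = "Hessian not positive definite"
            cov = None
        else:
            cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        converged, message, cov = False, "singular Hessian", None

    density = math.exp(log_d)
    sigma = math.exp(log_sigma)
    g0 = {
        "camera": float(expit(logit_g0)),
        "camera_bk": float(expit(logit_g0 + beta_bk)),
        "trap": float(expit(logit_g0 + beta_type)),
        "trap_bk": float(expit(logit_g0 + beta_bk + beta_type)),
    }
    if cov is not None and cov[0, 0] > 0:
        se_log_d = float(np.sqrt(cov[0, 0]))
    else:
        se_log_d = float("nan")
        converged = False
        if message == "ok":
            message = "non-positive variance for log D"
    se_d = density * se_log_d
    z = 1.959963984540054
    ci_low = density * math.exp(-z * se_log_d) if np.isfinite(se_log_d) \
        else float("nan")
    ci_high = density * math.exp(z * se_log_d) if np.isfinite(se_log_d) \
        else float("nan")
    loglik = -best.fun
    k = model_spec.n_params
    n = data.n
    aicc = (-2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            if n > k + 1 else float("inf"))
    return SECRFit(density=density, g0=g0, sigma=sigma, se_density=se_d,
                   se_log_density=se_log_d, loglik=loglik, n_params=k,
                   aicc=aicc, converged=converged, message=message,
                   params=theta, cov=cov, model=model_spec.name,
                   n_individuals=n, ci_low=ci_low, ci_high=ci_high)


# ---------------------------------------------------------------------------
# model comparison

def aicc_table(fits: Sequence[SECRFit], n_individuals: int) -> pd.DataFrame:
    """AICc ranking with Akaike weights and model-averaged density.

    AICc = -2 ln L + 2K + 2K(K+1)/(n - K - 1).  Weights are normalized over
    converged fits; when several models sit within delta AICc < 2 of the
    best, the returned table's ``attrs['d_hat']`` is their weight-averaged
    density, otherwise the best model's.
    """
    ok = [f for f in fits if f.converged and np.isfinite(f.loglik)]
    if not ok:
        raise ValueError("no converged fit to rank")
    for f in ok:
        if n_individuals <= f.n_params + 1:
            raise ValueError(
                f"sample size n={n_individuals} too small for K="
                f"{f.n_params} (need n > K+1)")
    aicc = np.array([-2 * f.loglik + 2 * f.n_params
                     + 2 * f.n_params * (f.n_params + 1)
                     / (n_individuals - f.n_params - 1) for f in ok])
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()
    order = np.argsort(aicc)
    table = pd.DataFrame({
        "model": [ok[i].model for i in order],
        "K": [ok[i].n_params for i in order],
        "loglik": [ok[i].loglik for i in order],
        "aicc": aicc[order],
        "delta_aicc": delta[order],
        "weight": w[order],
        "d_hat": [ok[i].density for i in order],
        "se_d_hat": [ok[i].se_density for i in order],
    })
    close = table["delta_aicc"] < 2
    if close.sum() > 1:
        ww = table.loc[close, "weight"]
        table.attrs["d_hat"] = float(
            (table.loc[close, "d_hat"] * ww).sum() / ww.sum())
        table.attrs["averaged"] = True
    else:
        table.attrs["d_hat"] = float(table["d_hat"].iloc[0])
        table.attrs["averaged"] = False
    return table


# ---------------------------------------------------------------------------
# estimator facade

class SECREstimator(BaseEstimator):
    """Spatially explicit capture-recapture density estimator.

    Parameters
    ----------
    detectors_used : {"camera", "all"}
        "camera" fits the camera phase only; "all" adds the corral-trap
        occasions (the trap-SECR variant).
    behavior, type_effect : bool
        Effects on g0 for the single fitted model (ignored when
        ``model_set`` is given).
    model_set : sequence of SECRModelSpec, optional
        Fit every model and select/average by AICc.
    buffer_km : float, optional
        Mask buffer; default is four times a data-driven sigma guess.
    spacing_km : float, optional
        Mask cell side; default sigma-guess / 3 (bounded to [0.1, 0.5]).
    n_starts, seed, alpha : optimizer restarts, jitter seed, CI level.

    Attributes (after fit)
    ----------------------
    fit_ : SECRFit for the selected model
    fits_ : list of SECRFit (one per model in the set)
    table_ : AICc table when a model set was fitted
    density_, sigma_, g0_, se_density_ : float / dict
    mask_ : HabitatMask used
    """

    def __init__(self, detectors_used: str = "camera",
                 behavior: bool = False, type_effect: bool = False,
                 model_set: Optional[Sequence[SECRModelSpec]] = None,
                 buffer_km: Optional[float] = None,
                 spacing_km: Optional[float] = None,
                 n_starts: int = 3, seed: int = 0, alpha: float = 0.05):
        self.detectors_used = detectors_used
        self.behavior = behavior
        self.type_effect = type_effect
        self.model_set = model_set
        self.buffer_km = buffer_km
        self.spacing_km = spacing_km
        self.n_starts = n_starts
        self.seed = seed
        self.alpha = alpha

    def _subset(self, history: EncounterHistory,
                detectors: DetectorArray) -> tuple[EncounterHistory,
                                                   pd.DataFrame]:
        if self.detectors_used == "camera":
            det = detectors.cameras
            hist = history.phase(CAMERA)
            hist = EncounterHistory(hist.records, history.n_camera_occasions,
                                    0)
        elif self.detectors_used == "all":
            det = detectors.detectors
            hist = history
        else:
            raise ValueError("detectors_used must be 'camera' or 'all'")
        return hist, det.reset_index(drop=True)

    def _guess_sigma(self, history: EncounterHistory,
                     detectors: pd.DataFrame) -> float:
        rec = history.records.merge(detectors[["id", "x_km", "y_km"]],
                                    left_on="detector_id", right_on="id")
        devs = []
        for _, grp in rec.groupby("individual_id"):
            if len(grp) >= 2:
                devs.append(grp["x_km"] - grp["x_km"].mean())
                devs.append(grp["y_km"] - grp["y_km"].mean())
        if devs:
            s = float(np.sqrt(np.mean(np.concatenate(devs) ** 2)))
            if s > 1e-3:
                return s
        return 0.5

    def fit(self, history: EncounterHistory,
            detectors: DetectorArray) -> "SECREstimator":
        hist, det = self._subset(history, detectors)
        sig0 = self._guess_sigma(hist, det)
        buffer_km = self.buffer_km if self.buffer_km is not None else \
            min(max(4 * sig0, 1.0), 6.0)
        spacing = self.spacing_km if self.spacing_km is not None else \
            min(max(sig0 / 3, 0.1), 0.5)
        self.mask_ = build_mask(DetectorArray(det), buffer_km, spacing)
        specs = tuple(self.model_set) if self.model_set is not None else (
            SECRModelSpec(behavior=self.behavior,
                          type_effect=self.type_effect),)
        self.fits_ = [fit_secr(hist, det, self.mask_, spec,
                               n_starts=self.n_starts, seed=self.seed)
                      for spec in specs]
        ok = [f for f in self.fits_ if f.converged]
        if len(specs) > 1 and ok:
            n = max(f.n_individuals for f in ok)
            usable = [f for f in ok if n > f.n_params + 1]
            if usable:
                self.table_ = aicc_table(usable, n)
                best_name = self.table_["model"].iloc[0]
                self.fit_ = next(f for f in usable if f.model == best_name)
            else:
                self.table_ = None
                self.fit_ = ok[0]
        else:
            self.table_ = None
            self.fit_ = ok[0] if ok else self.fits_[0]
        self.converged_ = self.fit_.converged
        self.density_ = self.fit_.density
        self.sigma_ = self.fit_.sigma
        self.g0_ = self.fit_.g0
        self.se_density_ = self.fit_.se_density
        return self

    def predict(self) -> float:
        """Fitted density (animals/km^2)."""
        return self.density_
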