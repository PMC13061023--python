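"""EMG envelope extraction, burst statistics, and task-demand tuning.

Muscle activation amplitude is estimated by a centered sliding
root-mean-square (RMS) envelope.  Under the amplitude-modulated-noise
signal model ``s(t) = env(t) * n(t)`` with ``n ~ N(0, 1)``, the windowed
RMS is an asymptotically unbiased estimator of the envelope, which gives
the burst statistics an analytic test surface.

Distance tuning of the pre-takeoff extensor burst is quantified with a
random-intercept linear model fitted by restricted maximum likelihood,
profiling the single variance ratio ``lambda = sigma_u^2 / sigma_e^2``:

    y_ij = beta0 + beta1 * d_ij + u_i + e_ij,
    u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

with a Wald z test on the distance slope ``beta1`` (no small-sample
degrees-of-freedom correction; the z approximation is documented).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError
from .kinematics import PhaseSegmentation
from .records import EMGRecording, StimEpoch

DEFAULT_RMS_WINDOW_MS = 20.0
FLEXOR_PREFLIGHT_EXTENSION_MS = 30.0


@dataclass
class RMSEnvelope:
    """Sliding-RMS envelope aligned to the EMG time axis."""

    muscle: str
    envelope: np.ndarray
    time_ms: np.ndarray
    window_ms: float
    sampling_rate: float
    trial_id: str = ""

    def window_mean(self, lo_ms: float, hi_ms: float) -> float:
        m = (self.time_ms >= lo_ms) & (self.time_ms < hi_ms)
        if not m.any():
            raise ValueError(f"window [{lo_ms}, {hi_ms}) ms outside envelope")
        return float(self.envelope[m].mean())


def rms_envelope(rec: EMGRecording, window_ms: float = DEFAULT_RMS_WINDOW_MS) -> RMSEnvelope:
    """Centered sliding RMS with truncated windows at the edges."""
    w = int(round(window_ms * rec.sampling_rate / 1000.0))
    if w < 3:
        raise ValueError(f"window of {w} samples too short (need >= 3)")
    if w > rec.signal.size:
        raise ValueError("window longer than the signal")
    # average the squared signal over the actual in-bounds window so the
    # edges are honestly truncated rather than padded
    sq = rec.signal ** 2
    n = sq.size
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    half_lo = (w - 1) // 2
    half_hi = w // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    mean_sq = (csum[hi] - csum[lo]) / (hi - lo)
    return RMSEnvelope(
        muscle=rec.muscle,
        envelope=np.sqrt(mean_sq),
        time_ms=rec.time_ms,
        window_ms=window_ms,
        sampling_rate=rec.sampling_rate,
        trial_id=rec.trial_id,
    )


def zscore(env: RMSEnvelope, baseline_window_ms: tuple[float, float]) -> RMSEnvelope:
    """(env - mu_baseline) / sigma_baseline against a baseline window."""
    lo, hi = baseline_window_ms
    m = (env.time_ms >= lo) & (env.time_ms < hi)
    if not m.any():
        raise ValueError("baseline window outside recording")
    mu = env.envelope[m].mean()
    sd = env.envelope[m].std()
    if sd == 0:
        raise ZeroDivisionError(
            f"zero baseline variance for {env.muscle} (trial {env.trial_id})"
        )
    return RMSEnvelope(
        muscle=env.muscle,
        envelope=(env.envelope - mu) / sd,
        time_ms=env.time_ms,
        window_ms=env.window_ms,
        sampling_rate=env.sampling_rate,
        trial_id=env.trial_id,
    )


@dataclass
class BurstStats:
    """Peak and half-peak crossings of a burst within a phase window."""

    muscle: str
    phase: str
    peak: float
    peak_time_ms: float | None
    onset_ms: float | None
    offset_ms: float | None


def phase_peak(
    env: RMSEnvelope,
    seg: PhaseSegmentation,
    phase: str,
    role: str,
    frame_rate: float,
    flexor_extension_ms: float = FLEXOR_PREFLIGHT_EXTENSION_MS,
) -> BurstStats:
    """Peak envelope within the phase window, with half-peak crossings.

    Windows follow the muscle role: the extensor window ends at takeoff
    (propulsion convention), while the flexor flight window is extended
    ``flexor_extension_ms`` before flight onset to capture the
    co-activation burst that precedes flight.
    """
    to_ms = 1000.0 / frame_rate
    b1, b2, b3 = seg.boundaries
    frame_to_rel = lambda f: (f - b2) * to_ms  # noqa: E731
    windows = {
        "preparation": (frame_to_rel(0), frame_to_rel(b1)),
        "propulsion": (frame_to_rel(b1), frame_to_rel(b2)),
        "flight": (frame_to_rel(b2), frame_to_rel(b3)),
        "landing": (frame_to_rel(b3), frame_to_rel(seg.n_frames)),
    }
    lo, hi = windows[phase]
    if phase == "flight" and role == "flexor":
        lo -= flexor_extension_ms
    m = (env.time_ms >= lo) & (env.time_ms < hi)
    if not m.any():
        return BurstStats(env.muscle, phase, np.nan, None, None, None)
    sub = env.envelope[m]
    t = env.time_ms[m]
    i_peak = int(np.argmax(sub))
    peak = float(sub[i_peak])
    if peak <= 0:
        return BurstStats(env.muscle, phase, peak, None, None, None)
    half = peak / 2.0
    onset = offset = None
    before = np.flatnonzero(sub[: i_peak + 1] < half)
    if before.size:
        onset = float(t[before[-1] + 1]) if before[-1] + 1 <= i_peak else None
    after = np.flatnonzero(sub[i_peak:] < half)
    if after.size:
        offset = float(t[i_peak + after[0] - 1])
    return BurstStats(
        muscle=env.muscle, phase=phase, peak=peak,
        peak_time_ms=float(t[i_peak]), onset_ms=onset, offset_ms=offset,
    )


# ---------------------------------------------------------------------------
# random-intercept mixed model


@dataclass
class MixedModelFit:
    beta0: float
    beta1: float
    se_beta1: float
    sigma_u: float
    sigma_e: float
    wald_z: float
    p_value: float
    n_animals: int
    n_obs: int
    converged: bool
    reml_loglik: float

    def wald_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        return self.beta1 - z * self.se_beta1, self.beta1 + z * self.se_beta1


class RandomInterceptLM(BaseEstimator, RegressorMixin):
    """REML random-intercept regression via 1-D profiling of sigma_u^2/sigma_e^2.

    For fixed lambda the per-group covariance ``V_i = I + lambda 11'`` has
    the closed-form inverse ``I - lambda/(1+lambda n_i) 11'``, so the GLS
    estimate, the profiled residual variance, and the REML criterion are
    all cheap; the scalar profile is minimized over log10(lambda).
    """

    def __init__(self, lam_bounds: tuple[float, float] = (-8.0, 8.0)):
        self.lam_bounds = lam_bounds

    @staticmethod
    def _group_stats(X, y, groups):
        gs = []
        for g in np.unique(groups):
            m = groups == g
            gs.append((X[m], y[m]))
        return gs

    @staticmethod
    def _profile(lam: float, gs, n_obs: int, p: int):
        xtvx = 0.0
        xtvy = 0.0
        logdet = 0.0
        for xg, yg in gs:
            ni = yg.size
            shrink = lam / (1.0 + lam * ni)
            sx = xg.sum(axis=0)
            sy = yg.sum()
            xtvx = xtvx + xg.T @ xg - shrink * np.outer(sx, sx)
            xtvy = xtvy + xg.T @ yg - shrink * sx * sy
            logdet += np.log1p(lam * ni)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = 0.0
        for xg, yg in gs:
            r = yg - xg @ beta
            ni = r.size
            shrink = lam / (1.0 + lam * ni)
            rss += r @ r - shrink * r.sum() ** 2
        sigma2 = rss / (n_obs - p)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            raise FitError("singular fixed-effects design")
        neg2_reml = (n_obs - p) * np.log(sigma2) + logdet + logdet_x
        return neg2_reml, beta, sigma2, xtvx

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = np.column_stack([np.ones_like(X), X])
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if uniq.size < 2:
            # single group: collapses to OLS with lambda = 0
            gs = self._group_stats(X, y, groups)
            crit, beta, sigma2, xtvx = self._profile(0.0, gs, y.size, X.shape[1])
            lam_hat = 0.0
        else:
            gs = self._group_stats(X, y, groups)
            n, p = y.size, X.shape[1]

            def objective(log_lam):
                return self._profile(10.0 ** log_lam, gs, n, p)[0]

            res = minimize_scalar(
                objective, bounds=self.lam_bounds, method="bounded",
                options={"xatol": 1e-8},
            )
            # compare against the boundary lambda -> 0 (no animal variance)
            crit0 = self._profile(0.0, gs, n, p)[0]
            lam_hat = 10.0 ** res.x if res.fun < crit0 else 0.0
            crit, beta, sigma2, xtvx = self._profile(lam_hat, gs, n, p)
            self.converged_ = bool(getattr(res, "success", True))
        self.lambda_ = lam_hat
        self.coef_ = beta
        self.sigma_e_ = float(np.sqrt(sigma2))
        self.sigma_u_ = float(np.sqrt(lam_hat * sigma2))
        cov = sigma2 * np.linalg.inv(xtvx)
        self.se_ = np.sqrt(np.diag(cov))
        self.reml_criterion_ = float(crit)
        self.n_groups_ = uniq.size
        self.n_obs_ = y.size
        if not hasattr(self, "converged_"):
            self.converged_ = True
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = np.column_stack([np.ones_like(X), X])
        return X @ self.coef_

    def summary(self) -> MixedModelFit:
        z = self.coef_[1] / self.se_[1]
        return MixedModelFit(
            beta0=float(self.coef_[0]),
            beta1=float(self.coef_[1]),
            se_beta1=float(self.se_[1]),
            sigma_u=self.sigma_u_,
            sigma_e=self.sigma_e_,
            wald_z=float(z),
            p_value=float(2.0 * norm.sf(abs(z))),
            n_animals=self.n_groups_,
            n_obs=self.n_obs_,
            converged=self.converged_,
            reml_loglik=-0.5 * self.reml_criterion_,
        )


def distance_modulation_fit(
    peaks: np.ndarray, distances: np.ndarray, animals: np.ndarray
) -> MixedModelFit:
    """Random-intercept fit of burst peaks on gap distance (cm)."""
    peaks = np.asarray(peaks, dtype=float)
    distances = np.asarray(distances, dtype=float)
    animals = np.asarray(animals)
    if np.unique(distances).size < 2:
        raise FitError("need at least two distinct gap distances")
    model = RandomInterceptLM().fit(distances, peaks, animals)
    return model.summary()


def suppression_index(
    zenv: RMSEnvelope,
    epoch: StimEpoch,
    control_window_ms: tuple[float, float],
) -> float:
    """SI = 1 - mean(epoch)/mean(control); 1 denotes complete suppression."""
    epoch_mean = zenv.window_mean(epoch.onset_ms, epoch.offset_ms)
    ctrl_mean = zenv.window_mean(*control_window_ms)
    if ctrl_mean == 0:
        raise ZeroDivisionError(
            f"zero control-window envelope for {zenv.muscle}; SI undefined"
        )
    return min(1.0, 1.0 - epoch_mean / ctrl_mean)
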