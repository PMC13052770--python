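"""MSD estimation, random-walk model fitting, and AICc-based classification.

Per-track mean squared displacement is estimated with overlapping time
intervals.  Three candidate models are fitted to the leading 40% of the lag
curve and ranked by the small-sample corrected Akaike information criterion:

- constrained:  MSD(tau) = R^2 (1 - exp(-4 Dc tau / R^2))
- brownian:     MSD(tau) = 4 D tau
- prw:          MSD(tau) = 2 v^2 tp^2 (tau/tp - (1 - exp(-tau/tp)))

A generalized power law MSD(tau) = A tau^alpha is available as a descriptive
fit but takes no part in model selection.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigError, DegenerateInputError
from .track_io import Track

logger = logging.getLogger(__name__)

#: Candidate models entering AICc selection, in tie-break order.
SELECTION_MODELS = ("brownian", "constrained", "prw")

#: Minimum number of fitted MSD points: k_max + 2 keeps the AICc denominator
#: positive for the largest candidate model (k = 2).
MIN_FIT_POINTS = 4


@dataclass(frozen=True)
class ModelSpec:
    """One MSD model: parameter names and positive box bounds."""

    name: str
    param_names: tuple
    lower: tuple
    upper: tuple

    def __post_init__(self):
        if not (len(self.param_names) == len(self.lower) == len(self.upper)):
            raise ConfigError(f"model {self.name}: inconsistent parameter lists")
        if any(lo <= 0 for lo in self.lower):
            raise ConfigError(f"model {self.name}: lower bounds must be positive")

    @property
    def k(self) -> int:
        return len(self.param_names)


MODELS = {
    "brownian": ModelSpec("brownian", ("D",), (1e-12,), (1e12,)),
    "constrained": ModelSpec("constrained", ("Dc", "R"), (1e-12, 1e-6), (1e12, 1e9)),
    "prw": ModelSpec("prw", ("v", "tau_p"), (1e-9, 1e-6), (1e9, 1e12)),
    "powerlaw": ModelSpec("powerlaw", ("A", "alpha"), (1e-12, 1e-6), (1e12, 2.0)),
}


@dataclass
class MSDCurve:
    """Per-track MSD estimate on the lag grid tau = k * frame_interval."""

    track_id: str
    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    fitted_window: int | None = None

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if not (len(self.lags) == len(self.msd) == len(self.n_pairs)):
            raise ConfigError("lags/msd/n_pairs length mismatch")
        if np.any(np.diff(self.lags) <= 0) or np.any(self.lags <= 0):
            raise ConfigError("lags must be strictly increasing and positive")
        if np.any(self.msd < 0):
            raise ConfigError("msd values must be non-negative")
        if np.any(self.n_pairs < 1):
            raise ConfigError("n_pairs must be >= 1")
        if self.fitted_window is not None and self.fitted_window > len(self.lags):
            raise ConfigError("fitted_window exceeds number of lags")


@dataclass
class FitResult:
    """Outcome of fitting one model to one MSD curve."""

    track_id: str
    model: str
    params: dict
    rss: float
    n_points: int
    aicc: float
    converged: bool
    n_starts_used: int = 0
    exact_fit: bool = False


@dataclass
class TrackClassification:
    """Winning model for one track plus derived motility parameters."""

    track_id: str
    best_model: str
    delta_aicc: dict
    params_best: dict
    fits: dict = field(default_factory=dict)
    persistence_speed: float | None = None
    persistence_time: float | None = None
    rmc: float | None = None


# ---------------------------------------------------------------------------
# MSD estimation
# ---------------------------------------------------------------------------

def compute_msd(track: Track, max_lag_fraction: float = 1.0) -> MSDCurve:
    """Overlapping-interval MSD: msd(k*dt) = mean_i |r(i+k) - r(i)|^2.

    Requires uniform sampling (apply filters first) and >= 3 points.
    ``n_pairs[k-1] = n - k`` counts the overlapping pairs per lag.
    """
    if track.n_points < 3:
        raise DegenerateInputError(
            f"track {track.track_id!r}: need >= 3 points for MSD"
        )
    if not track.is_uniform:
        raise DegenerateInputError(
            f"track {track.track_id!r}: has gaps; interpolate or split first"
        )
    n = track.n_points
    if not 0 < max_lag_fraction <= 1:
        raise ConfigError("max_lag_fraction must be in (0, 1]")
    k_max = max(1, int(math.floor(max_lag_fraction * (n - 1))))
    pos = track.positions
    lags = np.empty(k_max)
    msd = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=int)
    for k in range(1, k_max + 1):
        diffs = pos[k:] - pos[:-k]
        sq = (diffs**2).sum(axis=1)
        lags[k - 1] = k * track.frame_interval
        msd[k - 1] = np.mean(sq)
        n_pairs[k - 1] = n - k
    return MSDCurve(track_id=track.track_id, lags=lags, msd=msd, n_pairs=n_pairs)


def truncate_for_fit(curve: MSDCurve, fraction: float = 0.4) -> MSDCurve:
    """Mark the leading ``max(4, floor(fraction*K))`` lags as the fit window."""
    K = len(curve.lags)
    if K < MIN_FIT_POINTS:
        raise DegenerateInputError(
            f"curve {curve.track_id!r}: only {K} lags; need >= {MIN_FIT_POINTS}"
        )
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    window = max(MIN_FIT_POINTS, int(math.floor(fraction * K)))
    window = min(window, K)
    return replace(curve, fitted_window=window)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def eval_model(name: str, params, lags) -> np.ndarray:
    """Evaluate a model's closed-form MSD at the given lags (minutes).

    ``params`` is a dict keyed by parameter name or a sequence in the order
    of :attr:`ModelSpec.param_names`.  Stable for exponent arguments spanning
    [1e-6, 1e6] (expm1/series evaluation).
    """
    spec = MODELS.get(name)
    if spec is None:
        raise ConfigError(f"unknown model {name!r}")
    if isinstance(params, dict):
        values = [params[p] for p in spec.param_names]
    else:
        values = list(params)
    if len(values) != spec.k:
        raise ConfigError(f"model {name}: expected {spec.k} parameters")
    if any(v <= 0 for v in values):
        raise ConfigError(f"model {name}: parameters must be positive, got {values}")
    lags = np.asarray(lags, dtype=float)
    if np.any(lags <= 0):
        raise ConfigError("lags must be positive")

    if name == "brownian":
        (D,) = values
        return 4.0 * D * lags
    if name == "constrained":
        Dc, R = values
        return R**2 * (-np.expm1(-4.0 * Dc * lags / R**2))
    if name == "prw":
        v, tau_p = values
        x = lags / tau_p
        # x + expm1(-x) loses precision only for x << 1; series there.
        core = np.where(
            x < 1e-4,
            x * x / 2.0 - x**3 / 6.0 + x**4 / 24.0,
            x + np.expm1(-x),
        )
        return 2.0 * v**2 * tau_p**2 * core
    if name == "powerlaw":
        A, alpha = values
        if alpha > 2.0:
            raise ConfigError("alpha must be in (0, 2]")
        return A * lags**alpha
    raise ConfigError(f"unknown model {name!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# AICc
# ---------------------------------------------------------------------------

def aicc(rss: float, n_points: int, k: int) -> float:
    """Small-sample corrected AIC: n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1).

    ``rss = 0`` (an exact fit) maps to ``-inf``; ``n_points <= k + 1`` is an
    error (non-positive correction denominator).
    """
    if n_points <= k + 1:
        raise DegenerateInputError(
            f"AICc undefined: n={n_points} <= k+1={k + 1} (denominator <= 0)"
        )
    if rss < 0:
        raise ConfigError("rss must be non-negative")
    if rss == 0:
        return -math.inf
    n = float(n_points)
    return n * math.log(rss / n) + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _model_jacobian(name: str, theta, lags: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the model MSD w.r.t. its parameters."""
    if name == "brownian":
        return 4.0 * lags[:, None]
    if name == "constrained":
        Dc, R = theta
        u = 4.0 * Dc * lags / R**2
        eu = np.exp(-u)
        dDc = 4.0 * lags * eu
        dR = 2.0 * R * (1.0 - eu) - (8.0 * Dc * lags / R) * eu
        return np.column_stack([dDc, dR])
    if name == "prw":
        v, tau_p = theta
        x = lags / tau_p
        ex = np.exp(-x)
        core = np.where(x < 1e-4, x * x / 2.0 - x**3 / 6.0 + x**4 / 24.0, x + ex - 1.0)
        dv = 4.0 * v * tau_p**2 * core
        dtp = 2.0 * v**2 * (lags * (1.0 + ex) + 2.0 * tau_p * (ex - 1.0))
        return np.column_stack([dv, dtp])
    if name == "powerlaw":
        A, alpha = theta
        ta = lags**alpha
        return np.column_stack([ta, A * ta * np.log(lags)])
    raise ConfigError(f"unknown model {name!r}")


def _initial_guesses(name: str, lags: np.ndarray, y: np.ndarray) -> list:
    """Deterministic data-driven multi-start initializers (>= 3 per model)."""
    dt = lags[0]
    slope1 = max(y[0] / lags[0], 1e-9)
    d0 = slope1 / 4.0
    if name == "brownian":
        # closed-form OLS optimum of the linear model as the first start
        d_star = max(float(np.dot(y, lags) / (4.0 * np.dot(lags, lags))), 1e-12)
        return [[d_star], [d0], [5.0 * d0]]
    if name == "constrained":
        r0 = math.sqrt(max(y.max(), 1e-9))
        return [[d0, r0], [d0, 2.0 * r0], [5.0 * d0, r0]]
    if name == "prw":
        v0 = math.sqrt(max(y[0], 1e-12)) / dt
        return [[v0, dt], [v0, 5.0 * dt], [v0, 25.0 * dt]]
    if name == "powerlaw":
        # log-log regression start
        coef = np.polyfit(np.log(lags), np.log(np.maximum(y, 1e-300)), 1)
        alpha0 = float(np.clip(coef[0], 0.05, 2.0))
        a0 = float(np.exp(np.clip(coef[1], -200, 200)))
        return [[a0, alpha0], [slope1, 1.0], [max(y[0], 1e-9) / dt**2, 2.0]]
    raise ConfigError(f"unknown model {name!r}")


def fit_model(
    curve: MSDCurve,
    spec: ModelSpec | str,
    weighted: bool = False,
) -> FitResult:
    """Bounded nonlinear least squares of one model on the fit window.

    Unweighted, in linear MSD space, from >= 3 deterministic data-driven
    starts; the best (lowest-RSS) start wins.  ``weighted=True`` weights
    residuals by sqrt(n_pairs) (off by default).
    """
    if isinstance(spec, str):
        spec = MODELS[spec]
    window = curve.fitted_window if curve.fitted_window is not None else len(curve.lags)
    if window < spec.k + 2:
        raise DegenerateInputError(
            f"fit window {window} too small for model {spec.name} (k={spec.k})"
        )
    lags = curve.lags[:window]
    y = curve.msd[:window]
    w = np.sqrt(curve.n_pairs[:window]) if weighted else np.ones(window)

    def residuals(theta):
        return (eval_model(spec.name, theta, lags) - y) * w

    def jac(theta):
        return _model_jacobian(spec.name, theta, lags) * w[:, None]

    best = None
    n_used = 0
    for x0 in _initial_guesses(spec.name, lags, y):
        x0 = np.clip(x0, spec.lower, spec.upper)
        n_used += 1
        try:
            sol = least_squares(
                residuals,
                x0,
                jac=jac,
                bounds=(spec.lower, spec.upper),
                method="trf",
                xtol=1e-13,
                ftol=1e-13,
                gtol=1e-13,
                max_nfev=200,
            )
        except Exception:  # noqa: BLE001 - optimizer failure handled as non-convergence
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)

    if best is None:
        return FitResult(
            track_id=curve.track_id,
            model=spec.name,
            params={},
            rss=math.inf,
            n_points=window,
            aicc=math.inf,
            converged=False,
            n_starts_used=n_used,
        )

    rss, theta = best
    scale = max(float(np.max(y)), 1e-300)
    exact = rss <= 100.0 * window * (np.finfo(float).eps * scale) ** 2
    value = -math.inf if exact else aicc(rss, window, spec.k)
    return FitResult(
        track_id=curve.track_id,
        model=spec.name,
        params=dict(zip(spec.param_names, (float(t) for t in theta))),
        rss=rss,
        n_points=window,
        aicc=value,
        converged=True,
        n_starts_used=n_used,
        exact_fit=exact,
    )


def fit_power_law(curve: MSDCurve) -> FitResult:
    """Descriptive A, alpha fit (Eq.-4 style); not part of model selection."""
    return fit_model(curve, MODELS["powerlaw"])


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

_AICC_TIE_TOL = 1e-9


def classify_track(curve: MSDCurve, fraction: float = 0.4) -> TrackClassification:
    """Fit the three candidate models and pick the AICc minimum.

    Exact ties (within 1e-9) break toward fewer parameters, then toward the
    fixed order brownian < constrained < prw.  If every fit fails the track
    is returned as ``unclassified``.
    """
    if curve.fitted_window is None:
        curve = truncate_for_fit(curve, fraction)
    fits = {name: fit_model(curve, MODELS[name]) for name in SELECTION_MODELS}
    usable = {n: f for n, f in fits.items() if f.converged and not math.isnan(f.aicc)}
    if not usable:
        logger.warning("track %s: all model fits failed", curve.track_id)
        return TrackClassification(
            track_id=curve.track_id,
            best_model="unclassified",
            delta_aicc={},
            params_best={},
            fits=fits,
        )
    best_aicc = min(f.aicc for f in usable.values())
    if math.isinf(best_aicc):  # one or more exact fits
        candidates = [n for n, f in usable.items() if math.isinf(f.aicc)]
    else:
        candidates = [
            n for n, f in usable.items() if f.aicc - best_aicc <= _AICC_TIE_TOL
        ]
    candidates.sort(key=lambda n: (MODELS[n].k, SELECTION_MODELS.index(n)))
    best = candidates[0]
    delta = {}
    for name, f in fits.items():
        if not f.converged:
            delta[name] = math.inf
        elif math.isinf(best_aicc) and math.isinf(f.aicc):
            delta[name] = 0.0 if name in candidates else math.inf
        elif math.isinf(best_aicc):
            delta[name] = math.inf
        else:
            delta[name] = f.aicc - best_aicc
    delta[best] = 0.0

    cls = TrackClassification(
        track_id=curve.track_id,
        best_model=best,
        delta_aicc=delta,
        params_best=dict(fits[best].params),
        fits=fits,
    )
    if best == "prw":
        cls.persistence_speed = fits[best].params["v"]
        cls.persistence_time = fits[best].params["tau_p"]
    if fits["brownian"].converged:
        cls.rmc = fits["brownian"].params["D"]
    return cls


@dataclass
class MotilityRecord:
    """Motility coefficients derived from a classification."""

    track_id: str
    best_model: str
    rmc: float | None
    effective_coefficient: float | None
    flags: frozenset = frozenset()


def derive_motility(classification: TrackClassification) -> MotilityRecord:
    """Random motility coefficient (always the Brownian-fit D) plus a
    model-specific effective coefficient: prw -> v^2 tp / 2 (long-lag slope
    of the PRW MSD is 2 v^2 tp = 4 D_eff in 2D), constrained -> Dc,
    brownian -> D."""
    flags = set()
    rmc = classification.rmc
    if rmc is None:
        flags.add("missing_brownian_fit")
    best = classification.best_model
    p = classification.params_best
    effective: float | None = None
    if best == "brownian" and "D" in p:
        effective = p["D"]
    elif best == "constrained" and "Dc" in p:
        effective = p["Dc"]
    elif best == "prw" and "v" in p and "tau_p" in p:
        effective = p["v"] ** 2 * p["tau_p"] / 2.0
    else:
        flags.add("missing_best_fit")
    return MotilityRecord(
        track_id=classification.track_id,
        best_model=best,
        rmc=rmc,
        effective_coefficient=effective,
        flags=frozenset(flags),
    )
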