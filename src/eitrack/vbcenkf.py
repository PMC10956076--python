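"""Variational-Bayesian noise-adaptive constrained Ensemble Kalman Filter.

Joint sample-by-sample estimation of the 11-dimensional augmented state
``x = [v0..v5, A, a, B, b, p]`` of the Jansen-Rit neural-mass model from a
single observed EEG channel.  Three ingredients on top of the stochastic
(perturbed-observation) EnKF:

* the parameter block rides along as a random walk inside the state
  transition ``f(x) = [v + RK4(g(v, theta), dt); theta]``;
* the observation-noise covariance is ``R / eta`` with a gamma posterior
  ``eta ~ G(alpha, beta)`` updated variationally each sample, so the
  filter adapts to unknown / nonstationary noise power;
* interval constraints on the parameters are enforced after each update
  by projecting violating components onto their bounds (the oblique
  covariance-weighted projection, which on the constrained components
  coincides with clamping them to the bound).

Observation model: ``y = H x + w``, ``H = [0, 1, -1, 0, ..., 0]`` (the
EEG-like output is ``v1 - v2``), ``w ~ N(0, R/eta)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nm_model import BLOWUP_GUARD, NMParameters, _vector_field

__all__ = [
    "H_ROW",
    "AugmentedState",
    "EnsembleState",
    "NoisePosterior",
    "ConstraintSet",
    "FilterConfig",
    "FilterResult",
    "FilterDivergenceError",
    "init_filter",
    "predict_step",
    "vb_update_step",
    "apply_constraints",
    "run_filter",
]

NX = 11           # six model states + five parameters
PARAM_SLICE = slice(6, 11)
PARAM_NAMES = ("A", "a", "B", "b", "p")

#: observation row: y = v1 - v2
H_ROW = np.array([0.0, 1.0, -1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])

# small diagonal jitter used when inverting near-singular matrices
_JITTER = 1e-10


class FilterDivergenceError(RuntimeError):
    """Filter collapse at a given sample; carries the valid result prefix."""

    def __init__(self, msg: str, sample: int, partial: "FilterResult | None" = None):
        super().__init__(msg)
        self.sample = sample
        self.partial = partial


@dataclass
class AugmentedState:
    """An 11-vector ``[v0..v5, A, a, B, b, p]`` with fixed ordering."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (NX,):
            raise ValueError(f"augmented state must have length {NX}")

    @property
    def v(self) -> np.ndarray:
        return self.x[:6]

    @property
    def theta(self) -> np.ndarray:
        return self.x[PARAM_SLICE]


@dataclass
class EnsembleState:
    """Ensemble of augmented states with its sample mean and covariance.

    The covariance uses the 1/(N_ens - 1) normalization.
    """

    members: np.ndarray          # (n_ens, 11)
    mean: np.ndarray             # (11,)
    cov: np.ndarray              # (11, 11)

    @classmethod
    def from_members(cls, members: np.ndarray, extra_cov: np.ndarray | None = None):
        members = np.asarray(members, dtype=float)
        mean = members.mean(axis=0)
        dev = members - mean
        cov = dev.T @ dev / (members.shape[0] - 1)
        if extra_cov is not None:
            cov = cov + extra_cov
        cov = 0.5 * (cov + cov.T)
        return cls(members=members, mean=mean, cov=cov)

    @property
    def n_ens(self) -> int:
        return self.members.shape[0]


@dataclass
class NoisePosterior:
    """Gamma posterior G(alpha, beta) over the noise scaling factor eta.

    The effective observation covariance is ``R / <eta>`` with
    ``<eta> = alpha / beta``.  ``alpha`` grows by N/2 per update (N = 1
    observation dimension here); ``beta`` accumulates the innovation
    energy scaled by the base covariance R.
    """

    alpha: float
    beta: float
    R: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.R <= 0:
            raise ValueError("alpha, beta and R must be positive")

    @property
    def eta_mean(self) -> float:
        return self.alpha / self.beta

    @property
    def effective_R(self) -> float:
        return self.R / self.eta_mean


@dataclass(frozen=True)
class ConstraintSet:
    """Interval constraints d_L <= D x <= d_U on selected components.

    ``indices`` are the constrained components of the augmented state
    (each index defines one selection row of D).
    """

    indices: tuple[int, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if not (len(self.indices) == lower.size == upper.size):
            raise ValueError("indices, lower and upper must have equal length")
        if np.any(lower >= upper):
            raise ValueError("each lower bound must be below its upper bound")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def default(cls) -> "ConstraintSet":
        """Parameter-block constraints: A in [1, 10], a in [5, 200],
        B in [1, 50], b in [5, 200], p in [120, 320]; the v-block is
        unconstrained."""
        return cls(
            indices=(6, 7, 8, 9, 10),
            lower=np.array([1.0, 5.0, 1.0, 5.0, 120.0]),
            upper=np.array([10.0, 200.0, 50.0, 200.0, 320.0]),
        )

    @property
    def D(self) -> np.ndarray:
        D = np.zeros((len(self.indices), NX))
        D[np.arange(len(self.indices)), list(self.indices)] = 1.0
        return D

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        out = np.array(x, dtype=float, copy=True)
        idx = list(self.indices)
        out[..., idx] = np.clip(out[..., idx], self.lower, self.upper)
        return out

    def satisfied(self, x: np.ndarray) -> bool:
        idx = list(self.indices)
        x = np.asarray(x)
        return bool(
            np.all(x[..., idx] >= self.lower - 1e-12)
            and np.all(x[..., idx] <= self.upper + 1e-12)
        )


def _default_Q(dt: float, preset: str) -> np.ndarray:
    if preset == "simulation":
        v_diag = dt * 1e-2
    elif preset == "eeg":
        v_diag = dt
    else:
        raise ValueError(f"unknown Q preset {preset!r}")
    return np.diag(np.r_[np.full(6, v_diag), np.full(5, 1e-3)])


@dataclass
class FilterConfig:
    """Filter settings; defaults follow the simulation study.

    ``Q`` defaults to the preset named by ``q_preset``:
    ``"simulation"`` -> diag([dt*1e-2]*6 + [1e-3]*5), used for synthetic
    data; ``"eeg"`` -> diag([dt]*6 + [1e-3]*5), used for real recordings.
    ``P0`` defaults to diag(1) on the v-block and (interval width / 8)^2
    on each constrained parameter.  ``theta0`` is the parameter-prior
    center, defaulting to the canonical Jansen-Rit values
    (A = 3.25, a = 100, B = 22, b = 50, p = 220); it is used wherever an
    ``x0`` parameter entry lies outside its constraint interval (the
    all-zero default ``x0`` always does).  ``forgetting`` < 1
    exponentially discounts the gamma posterior for nonstationary noise
    (an extension; 1.0 disables it).
    """

    n_ens: int = 200
    dt: float = 0.01
    R: float = 50.0
    alpha0: float = 1.0
    beta0: float = 0.5
    q_preset: str = "simulation"
    Q: np.ndarray | None = None
    x0: np.ndarray | None = None
    P0: np.ndarray | None = None
    theta0: np.ndarray | None = None
    forgetting: float = 1.0
    guard: float = BLOWUP_GUARD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ens < 2:
            raise ValueError("n_ens must be at least 2")
        if self.R <= 0 or self.dt <= 0:
            raise ValueError("R and dt must be positive")
        if not (0.0 < self.forgetting <= 1.0):
            raise ValueError("forgetting factor must be in (0, 1]")

    @classmethod
    def simulation(cls, **kw) -> "FilterConfig":
        return cls(q_preset="simulation", **kw)

    @classmethod
    def eeg(cls, **kw) -> "FilterConfig":
        return cls(q_preset="eeg", **kw)

    def resolved_Q(self) -> np.ndarray:
        Q = self.Q if self.Q is not None else _default_Q(self.dt, self.q_preset)
        Q = np.asarray(Q, dtype=float)
        if Q.shape != (NX, NX):
            raise ValueError(f"Q must be {NX}x{NX}")
        return Q

    def resolved_x0(self) -> np.ndarray:
        x0 = np.zeros(NX) if self.x0 is None else np.asarray(self.x0, dtype=float)
        if x0.shape != (NX,):
            raise ValueError(f"x0 must have length {NX}")
        return x0

    def resolved_P0(self, constraints: ConstraintSet) -> np.ndarray:
        if self.P0 is not None:
            P0 = np.asarray(self.P0, dtype=float)
            if P0.shape != (NX, NX):
                raise ValueError(f"P0 must be {NX}x{NX}")
            return P0
        diag = np.ones(NX)
        diag[list(constraints.indices)] = (constraints.widths() / 8.0) ** 2
        return np.diag(diag)

    def resolved_theta0(self) -> np.ndarray:
        if self.theta0 is None:
            return NMParameters().as_array()
        theta0 = np.asarray(self.theta0, dtype=float)
        if theta0.shape != (5,):
            raise ValueError("theta0 must hold the five parameters [A, a, B, b, p]")
        return theta0

    def to_dict(self) -> dict:
        d = {
            "n_ens": self.n_ens, "dt": self.dt, "R": self.R,
            "alpha0": self.alpha0, "beta0": self.beta0,
            "q_preset": self.q_preset, "forgetting": self.forgetting,
            "guard": self.guard, "seed": self.seed,
        }
        if self.Q is not None:
            d["Q"] = np.asarray(self.Q).tolist()
        if self.x0 is not None:
            d["x0"] = np.asarray(self.x0).tolist()
        if self.P0 is not None:
            d["P0"] = np.asarray(self.P0).tolist()
        return d


@dataclass
class FilterResult:
    """Per-sample output of :func:`run_filter`.

    ``y_pred`` is the one-step (prior, pre-update) predicted observation
    ``H x_t``; ``x_hat`` the constrained posterior mean; ``r_eff`` the
    effective observation covariance R/<eta> after each update.
    """

    t: np.ndarray
    x_hat: np.ndarray            # (T, 11)
    P_diag: np.ndarray           # (T, 11)
    y_pred: np.ndarray           # (T,)
    r_eff: np.ndarray            # (T,)
    alpha: np.ndarray            # (T,)
    beta: np.ndarray             # (T,)
    n_resampled: int
    config: FilterConfig
    seed: int

    @property
    def A_hat(self) -> np.ndarray:
        return self.x_hat[:, 6]

    @property
    def B_hat(self) -> np.ndarray:
        return self.x_hat[:, 8]

    @property
    def mei(self) -> np.ndarray:
        """Model-based E/I ratio A/(A+B) per sample."""
        return self.A_hat / (self.A_hat + self.B_hat)

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.t}
        names = [f"v{i}" for i in range(6)] + list(PARAM_NAMES)
        for j, name in enumerate(names):
            cols[f"xhat_{name}"] = self.x_hat[:, j]
        cols.update(
            y_pred=self.y_pred, R_eff=self.r_eff,
            alpha=self.alpha, beta=self.beta, mEI=self.mei,
        )
        return pd.DataFrame(cols)

    def to_csv(self, path, manifest: bool = True) -> None:
        self.to_frame().to_csv(path, index=False)
        if manifest:
            meta = {"config": self.config.to_dict(), "seed": self.seed,
                    "n_resampled": self.n_resampled}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# core steps

def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent child streams (init, process noise, obs perturbations)."""
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


def init_filter(
    config: FilterConfig,
    constraints: ConstraintSet | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EnsembleState, NoisePosterior]:
    """Draw the initial ensemble and noise posterior.

    Members are sampled from N(center, P0) and then projected into the
    feasible region.  The sampling center is ``x0`` except on parameter
    components whose ``x0`` entry violates its bounds, which take the
    ``theta0`` prior center (canonical Jansen-Rit values by default,
    clipped into the feasible interval); with the all-zero default
    ``x0`` this yields a weakly informative parameter prior around the
    canonical operating point rather than an ensemble piled up on a
    bound.
    """
    constraints = constraints or ConstraintSet.default()
    rng = rng or _streams(config.seed)[0]
    P0 = config.resolved_P0(constraints)
    P0 = 0.5 * (P0 + P0.T)
    try:
        L = np.linalg.cholesky(P0 + _JITTER * np.eye(NX))
    except np.linalg.LinAlgError as exc:
        raise ValueError("P0 must be positive semidefinite") from exc

    center = config.resolved_x0()
    theta0_full = np.full(NX, np.nan)
    theta0_full[PARAM_SLICE] = config.resolved_theta0()
    idx = np.array(constraints.indices)
    viol = (center[idx] < constraints.lower) | (center[idx] > constraints.upper)
    fallback = np.where(
        np.isnan(theta0_full[idx]), constraints.midpoints(), theta0_full[idx]
    )
    center[idx[viol]] = np.clip(fallback, constraints.lower, constraints.upper)[viol]

    members = center + rng.standard_normal((config.n_ens, NX)) @ L.T
    P_ens = EnsembleState.from_members(members).cov
    members = np.array(
        [apply_constraints(m, P_ens, constraints) for m in members]
    )
    ensemble = EnsembleState.from_members(members)
    posterior = NoisePosterior(alpha=config.alpha0, beta=config.beta0, R=config.R)
    return ensemble, posterior


def _propagate(members: np.ndarray, dt: float, guard: float) -> tuple[np.ndarray, np.ndarray]:
    """RK4-advance the v-block of each member with its own parameters.

    Returns the advanced members and a boolean mask of members that blew
    up (non-finite or beyond the guard)."""
    v = members[:, :6]
    th = members[:, PARAM_SLICE]
    params = tuple(th[:, j] for j in range(5))

    def deriv(state):
        return _vector_field(state, *params)

    with np.errstate(over="ignore", invalid="ignore"):
        k1 = deriv(v)
        k2 = deriv(v + 0.5 * dt * k1)
        k3 = deriv(v + 0.5 * dt * k2)
        k4 = deriv(v + dt * k3)
        v_new = v + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    out = members.copy()
    out[:, :6] = v_new
    with np.errstate(invalid="ignore"):
        bad = ~np.all(np.isfinite(out), axis=1) | np.any(np.abs(out) > guard, axis=1)
    return out, bad


def predict_step(
    ensemble: EnsembleState,
    config: FilterConfig,
    rng: np.random.Generator,
) -> tuple[EnsembleState, int]:
    """Propagate every member through f and add N(0, Q) noise.

    The parameter block is a random walk: carried unchanged through f,
    perturbed only by Q.  The predicted covariance is the ensemble
    covariance plus Q.  Members that blow up are re-sampled from the
    statistics of the surviving members; the count is returned.
    """
    members, bad = _propagate(ensemble.members, config.dt, config.guard)
    n_bad = int(bad.sum())
    if n_bad:
        good = members[~bad]
        if good.shape[0] < 2:
            raise FilterDivergenceError("ensemble collapsed: all members diverged", -1)
        mean = good.mean(axis=0)
        dev = good - mean
        cov = dev.T @ dev / (good.shape[0] - 1) + _JITTER * np.eye(NX)
        L = np.linalg.cholesky(0.5 * (cov + cov.T) + _JITTER * np.eye(NX))
        members[bad] = mean + rng.standard_normal((n_bad, NX)) @ L.T
    Q = config.resolved_Q()
    if np.any(Q):
        Lq = np.linalg.cholesky(Q + _JITTER * np.eye(NX))
        members = members + rng.standard_normal((ensemble.n_ens, NX)) @ Lq.T
    return EnsembleState.from_members(members, extra_cov=Q), n_bad


def vb_update_step(
    ensemble: EnsembleState,
    posterior: NoisePosterior,
    y_obs: float,
    config: FilterConfig,
    rng: np.random.Generator | None = None,
    perturbations: np.ndarray | None = None,
) -> tuple[EnsembleState, NoisePosterior]:
    """One variational-Bayes stochastic-EnKF measurement update.

    Order of operations: (i) alpha += N/2 (N = 1) and <eta> = alpha/beta;
    (ii) ensemble observations and P_YY (which includes the R/<eta>
    term) and P_XY; (iii) per-member update with perturbed observations
    w_i ~ N(0, R/<eta>); (iv) posterior mean from the members and
    covariance P - K P_YY K^T; (v) beta incremented with the expected
    squared residual under the *posterior*,
    (||y - H x||^2 + H P H^T) / (2 R), which is the exact
    variational-Bayes update for the gamma factor and makes the adapted
    covariance R/<eta> converge to the true observation-noise variance
    when the ensemble spread is calibrated.

    ``perturbations`` overrides the w_i draws (one per member); otherwise
    they come from ``rng``.
    """
    N_obs = 1.0
    rho = config.forgetting
    alpha = rho * posterior.alpha + N_obs / 2.0
    beta = rho * posterior.beta
    eta = alpha / beta
    R_eff = posterior.R / eta

    members = ensemble.members
    x_pred = ensemble.mean
    P_pred = ensemble.cov

    Y = members @ H_ROW                       # (n_ens,)
    y_mean = Y.mean()
    dev_y = Y - y_mean
    P_yy = dev_y @ dev_y / (ensemble.n_ens - 1) + R_eff
    if not np.isfinite(P_yy) or P_yy <= 0:
        raise FilterDivergenceError("non-positive innovation covariance", -1)
    dev_x = members - x_pred
    P_xy = dev_x.T @ dev_y / (ensemble.n_ens - 1)   # (11,)

    K = P_xy / P_yy                            # (11,) gain column
    if perturbations is None:
        if rng is None:
            raise ValueError("either rng or explicit perturbations required")
        w = rng.normal(0.0, np.sqrt(R_eff), size=ensemble.n_ens)
    else:
        w = np.asarray(perturbations, dtype=float)
    innov = y_obs + w - Y                      # (n_ens,)
    new_members = members + innov[:, None] * K[None, :]

    mean = new_members.mean(axis=0)
    P_post = P_pred - P_yy * np.outer(K, K)
    P_post = 0.5 * (P_post + P_post.T)
    updated = EnsembleState(members=new_members, mean=mean, cov=P_post)

    resid = y_obs - mean @ H_ROW
    beta = beta + 0.5 * (resid**2 + H_ROW @ P_post @ H_ROW) / posterior.R
    return updated, NoisePosterior(alpha=alpha, beta=beta, R=posterior.R)


def apply_constraints(x, P, constraints: ConstraintSet):
    """Project bound-violating components of ``x`` onto their bounds.

    Implements the covariance-weighted (oblique) projection
    ``x_L = x - P D^T (D P D^T)^{-1} (D x - d_L)`` (same form with d_U),
    replacing only the components that violate their bound.  Because D is
    a selection matrix, the projected value of an active component equals
    its bound exactly; non-violating components keep their values.  If
    ``D P D^T`` is numerically singular the projection degenerates to
    componentwise clamping (equivalent under diagonal P).
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    idx = np.array(constraints.indices)
    sub = x[idx]
    below = sub < constraints.lower
    above = sub > constraints.upper
    if not (below.any() or above.any()):
        return out

    D = constraints.D
    P = np.asarray(P, dtype=float)
    DPD = D @ P @ D.T
    try:
        S = P @ D.T @ np.linalg.inv(DPD + _JITTER * np.eye(len(idx)))
        x_L = x - S @ (sub - constraints.lower)
        x_U = x - S @ (sub - constraints.upper)
        out[idx[below]] = x_L[idx[below]]
        out[idx[above]] = x_U[idx[above]]
    except np.linalg.LinAlgError:
        out[idx] = np.clip(sub, constraints.lower, constraints.upper)
    # numerical safety: the oblique projection puts active components on
    # their bound up to round-off; snap them inside the closed interval
    out[idx] = np.clip(out[idx], constraints.lower, constraints.upper)
    return out


def run_filter(
    eeg,
    config: FilterConfig | None = None,
    constraints: ConstraintSet | None = None,
    constrain_members: bool = True,
) -> FilterResult:
    """Run the predict -> update -> constrain loop over an EEG series.

    Parameters
    ----------
    eeg : array_like
        Observed single-channel series, one sample per ``config.dt``.
    config, constraints
        Filter settings; defaults reproduce the simulation-study setup.
    constrain_members : bool
        Also project each ensemble member into the feasible box after
        the update (keeps the neural-mass integration of every member in
        its stable parameter regime); the posterior mean is constrained
        regardless.

    Returns
    -------
    FilterResult
        Per-sample constrained posterior mean, covariance diagonal,
        one-step prediction, effective noise covariance and gamma trace.
    """
    y = np.asarray(eeg, dtype=float)
    if y.ndim != 1:
        raise ValueError("eeg must be a 1-D series")
    if not np.all(np.isfinite(y)):
        raise ValueError("eeg contains non-finite samples")
    config = config or FilterConfig()
    constraints = constraints or ConstraintSet.default()

    rng_init, rng_q, rng_obs = _streams(config.seed)
    ensemble, posterior = init_filter(config, constraints, rng_init)

    T = y.size
    res = FilterResult(
        t=np.arange(T) * config.dt,
        x_hat=np.empty((T, NX)), P_diag=np.empty((T, NX)),
        y_pred=np.empty(T), r_eff=np.empty(T),
        alpha=np.empty(T), beta=np.empty(T),
        n_resampled=0, config=config, seed=config.seed,
    )
    n_resampled = 0
    idx = list(constraints.indices)
    for t in range(T):
        try:
            ensemble, n_bad = predict_step(ensemble, config, rng_q)
            n_resampled += n_bad
            res.y_pred[t] = ensemble.mean @ H_ROW
            ensemble, posterior = vb_update_step(
                ensemble, posterior, y[t], config, rng_obs
            )
        except FilterDivergenceError as exc:
            prefix = _truncate(res, t)
            prefix.n_resampled = n_resampled
            raise FilterDivergenceError(
                f"filter diverged at sample {t}: {exc}", t, prefix
            ) from exc
        x_hat = apply_constraints(ensemble.mean, ensemble.cov, constraints)
        if constrain_members:
            # per-member projection: with a selection matrix D the
            # projected value of each violating component is exactly its
            # bound, so the vectorized clip is the same operation
            members = constraints.clip(ensemble.members)
            ensemble = EnsembleState(
                members=members, mean=members.mean(axis=0), cov=ensemble.cov
            )
        res.x_hat[t] = x_hat
        res.P_diag[t] = np.diag(ensemble.cov)
        res.r_eff[t] = posterior.effective_R
        res.alpha[t] = posterior.alpha
        res.beta[t] = posterior.beta
    res.n_resampled = n_resampled
    return res


def _truncate(res: FilterResult, t: int) -> FilterResult:
    return FilterResult(
        t=res.t[:t], x_hat=res.x_hat[:t], P_diag=res.P_diag[:t],
        y_pred=res.y_pred[:t], r_eff=res.r_eff[:t],
        alpha=res.alpha[:t], beta=res.beta[:t],
        n_resampled=res.n_resampled, config=res.config, seed=res.seed,
    )
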