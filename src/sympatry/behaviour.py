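"""Expectation-maximization binary clustering of track kinematics.

Each interior fix of a trip yields a speed/turning-angle pair (v, theta).
A four-component bivariate Gaussian mixture, initialised from the four
quadrants defined by the per-variable medians, is fitted by EM; after
convergence a per-variable delimiter is placed where the adjacent marginal
components intersect and each component is labelled Low/High per variable,
giving the four behavioural states HL, HH, LL and LH (velocity letter
first). HL — fast and straight — is interpreted as commuting flight to and
from the colony and removed before any habitat analysis; the remaining
states cover searching, foraging and resting. No smoothing is applied
before or after clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "compute_kinematics",
    "fit_embc",
    "fit_embc_groups",
    "annotate_and_drop_commuting",
    "BehaviourModel",
]

STATES = ("HL", "HH", "LL", "LH")


class DegenerateDataError(ValueError):
    pass


def compute_kinematics(track: pd.DataFrame) -> pd.DataFrame:
    """Speed and absolute turning angle at each interior fix.

    For fix i (0-based), ``v_i = |x_{i+1} - x_i| / dt_i`` (forward speed,
    m/s) and ``theta_i`` is the absolute angle in [0, pi] between the
    incoming and outgoing displacement vectors. Only interior fixes
    (1 .. n-2) have both quantities; zero-dt pairs are dropped.
    Returns a frame with columns (idx, v, theta, dt).
    """
    if len(track) < 3:
        warnings.warn("fewer than 3 fixes; no kinematics computed")
        return pd.DataFrame(columns=["idx", "v", "theta", "dt"])
    x = track["x"].to_numpy(float)
    y = track["y"].to_numpy(float)
    t = pd.to_datetime(track["timestamp"]).astype("int64").to_numpy() / 1e9
    dx = np.diff(x)
    dy = np.diff(y)
    dt = np.diff(t)
    idx = np.arange(1, len(track) - 1)
    ok = (dt[idx - 1] > 0) & (dt[idx] > 0)
    idx = idx[ok]
    v = np.hypot(dx[idx], dy[idx]) / dt[idx]
    a_in = np.arctan2(dy[idx - 1], dx[idx - 1])
    a_out = np.arctan2(dy[idx], dx[idx])
    theta = np.abs((a_out - a_in + np.pi) % (2 * np.pi) - np.pi)
    return pd.DataFrame({"idx": idx, "v": v, "theta": theta, "dt": dt[idx]})


@dataclass
class BehaviourModel:
    """Fitted 4-component (v, theta) mixture with binary-state labels."""

    weights: np.ndarray           # (4,)
    means: np.ndarray             # (4, 2) on the original (v, theta) scale
    covariances: np.ndarray       # (4, 2, 2) on the original scale
    labels: tuple[str, ...]       # component -> state, a bijection onto STATES
    delimiters: tuple[float, float]  # (v, theta) split values, original scale
    converged: bool
    n_iter: int
    log_likelihood: float
    ll_history: np.ndarray = field(repr=False, default=None)
    _scale_mean: np.ndarray = field(repr=False, default=None)
    _scale_std: np.ndarray = field(repr=False, default=None)

    def _standardise(self, vtheta: np.ndarray) -> np.ndarray:
        return (vtheta - self._scale_mean) / self._scale_std

    def _z_params(self):
        mu = (self.means - self._scale_mean) / self._scale_std
        s = self._scale_std
        cov = self.covariances / np.outer(s, s)[None, :, :]
        return mu, cov

    def posterior(self, vtheta: np.ndarray) -> np.ndarray:
        z = self._standardise(np.atleast_2d(vtheta))
        mu, cov = self._z_params()
        logp = _log_gauss(z, mu, cov) + np.log(self.weights)[None, :]
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict_states(self, vtheta: np.ndarray) -> np.ndarray:
        comp = np.argmax(self.posterior(vtheta), axis=1)
        return np.asarray(self.labels)[comp]

    def summary(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "labels": list(self.labels),
            "delimiters": list(self.delimiters),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_likelihood": self.log_likelihood,
        }


def _log_gauss(z: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of each row of z under each bivariate Gaussian (n, K)."""
    n, K = len(z), len(mu)
    out = np.empty((n, K))
    for k in range(K):
        c = cov[k]
        det = c[0, 0] * c[1, 1] - c[0, 1] * c[1, 0]
        inv = np.array([[c[1, 1], -c[0, 1]], [-c[1, 0], c[0, 0]]]) / det
        d = z - mu[k]
        q = d[:, 0] ** 2 * inv[0, 0] + 2 * d[:, 0] * d[:, 1] * inv[0, 1] + d[:, 1] ** 2 * inv[1, 1]
        out[:, k] = -0.5 * (q + np.log(det)) - np.log(2 * np.pi)
    return out


def _marginal_delimiter(weights, mus, sigmas) -> float:
    """Split value for one variable: intersection of the adjacent marginals.

    Components are pooled into the two lowest-mean and two highest-mean
    groups; the delimiter is the crossing point of the two nearest
    single-Gaussian marginals (closed-form quadratic), falling back to the
    midpoint when the quadratic degenerates.
    """
    order = np.argsort(mus)
    i, j = order[1], order[2]  # adjacent components across the split
    w1, m1, s1 = weights[i], mus[i], max(sigmas[i], 1e-9)
    w2, m2, s2 = weights[j], mus[j], max(sigmas[j], 1e-9)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 - 2.0 * np.log((w1 * s2) / (w2 * s1))
    mid = 0.5 * (m1 + m2)
    if abs(a) < 1e-12:
        return mid if abs(b) < 1e-12 else float(-c / b)
    disc = b * b - 4 * a * c
    if disc < 0:
        return mid
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots >= min(m1, m2)) & (roots <= max(m1, m2))]
    if len(inside):
        return float(inside[np.argmin(np.abs(inside - mid))])
    return mid


def fit_embc(
    points: pd.DataFrame | np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
    min_points: int = 50,
) -> BehaviourModel:
    """Fit the 4-state speed/turn mixture to one group's kinematic points.

    (v, theta) are standardised to z-scores before EM (theta's [0, pi]
    range is far narrower than speeds in m/s); means, covariances and
    delimiters are reported back on the original scale. The fit is
    deterministic given the data: initialisation uses the median quadrants,
    not random draws, and `seed` only breaks exact ties.
    """
    if isinstance(points, pd.DataFrame):
        Z0 = points[["v", "theta"]].to_numpy(float)
    else:
        Z0 = np.atleast_2d(np.asarray(points, float))
    n = len(Z0)
    if n < min_points:
        raise ValueError(f"need at least {min_points} kinematic points, got {n}")
    mean = Z0.mean(axis=0)
    std = Z0.std(axis=0)
    if np.any(std < 1e-12):
        raise DegenerateDataError("no variance in speed or turning angle")
    Z = (Z0 - mean) / std

    # quadrant initialisation from per-variable medians
    med = np.median(Z, axis=0)
    quad = (Z[:, 0] > med[0]).astype(int) * 2 + (Z[:, 1] > med[1]).astype(int)
    K = 4
    w = np.empty(K)
    mu = np.empty((K, 2))
    cov = np.empty((K, 2, 2))
    rng = np.random.default_rng(seed)
    for k in range(K):
        pts = Z[quad == k]
        if len(pts) < 3:  # empty quadrant: seed near the quadrant corner
            corner = med + np.array([(k // 2) * 2 - 1, (k % 2) * 2 - 1]) * 0.5
            pts = Z[np.argsort(((Z - corner) ** 2).sum(axis=1))[:5]]
        w[k] = max(len(pts) / n, 0.05)
        mu[k] = pts.mean(axis=0)
        cov[k] = np.cov(pts.T) + 1e-4 * np.eye(2)
    w /= w.sum()

    ll_hist = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = _log_gauss(Z, mu, cov) + np.log(w)[None, :]
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        ll_hist.append(ll)
        r = np.exp(logp - lse[:, None])
        nk = r.sum(axis=0) + 1e-12
        w = nk / n
        mu = (r.T @ Z) / nk[:, None]
        for k in range(K):
            d = Z - mu[k]
            cov[k] = (r[:, k][:, None] * d).T @ d / nk[k] + 1e-6 * np.eye(2)
        if len(ll_hist) > 1 and abs(ll_hist[-1] - ll_hist[-2]) < tol * (abs(ll_hist[-2]) + 1e-12):
            converged = True
            break
    if not converged:
        warnings.warn("EM did not converge; returning the best model so far")

    sig = np.sqrt(cov[:, [0, 1], [0, 1]])
    delim_z = (
        _marginal_delimiter(w, mu[:, 0], sig[:, 0]),
        _marginal_delimiter(w, mu[:, 1], sig[:, 1]),
    )
    # label each component L/H per variable against the delimiters; if the
    # raw comparison is not a bijection, resolve by optimal assignment of
    # component means to the four quadrant sign patterns
    raw = ["".join(["H" if mu[k, d] > delim_z[d] else "L" for d in range(2)]) for k in range(4)]
    if len(set(raw)) == 4:
        labels = tuple(raw)
    else:
        signs = {"HL": (1, -1), "HH": (1, 1), "LL": (-1, -1), "LH": (-1, 1)}
        score = np.zeros((4, 4))
        for k in range(4):
            for qi, st in enumerate(STATES):
                sv, st_ = signs[st]
                score[k, qi] = sv * (mu[k, 0] - delim_z[0]) + st_ * (mu[k, 1] - delim_z[1])
        rowi, coli = linear_sum_assignment(-score)
        labels = tuple(STATES[coli[np.where(rowi == k)[0][0]]] for k in range(4))

    return BehaviourModel(
        weights=w,
        means=mu * std + mean,
        covariances=cov * np.outer(std, std)[None, :, :],
        labels=labels,
        delimiters=tuple(np.asarray(delim_z) * std + mean),
        converged=converged,
        n_iter=it,
        log_likelihood=ll_hist[-1],
        ll_history=np.asarray(ll_hist),
        _scale_mean=mean,
        _scale_std=std,
    )


def fit_embc_groups(
    kin_by_group: dict, min_group_size: int = 50, **kwargs
) -> dict:
    """One model per (species x trip-type) group, pooled-species fallback.

    Groups with fewer than `min_group_size` points are fitted from the
    pooled points of their species (key ``(species, None)``), mirroring how
    sparse trip types borrow strength from the species-level data.
    """
    models: dict = {}
    pooled: dict[str, list] = {}
    for (species, _ttype), kin in kin_by_group.items():
        pooled.setdefault(species, []).append(kin)
    pooled_models = {}
    for species, frames in pooled.items():
        allk = pd.concat(frames, ignore_index=True)
        if len(allk) >= min_group_size:
            pooled_models[species] = fit_embc(allk, min_points=min_group_size, **kwargs)
    for key, kin in kin_by_group.items():
        species = key[0]
        if len(kin) >= min_group_size:
            models[key] = fit_embc(kin, min_points=min_group_size, **kwargs)
        elif species in pooled_models:
            warnings.warn(f"group {key} below {min_group_size} points; using pooled model")
            models[key] = pooled_models[species]
    return models


def annotate_and_drop_commuting(
    track: pd.DataFrame, model: BehaviourModel, kin: pd.DataFrame | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label every fix with its behavioural state and drop HL (commuting).

    Interior fixes take the maximum-posterior state of their kinematic
    point; boundary fixes with undefined turning angle inherit the state of
    the nearest labelled fix. Returns ``(labels, track_without_HL)``.
    """
    if model is None:
        raise KeyError("no behaviour model available for this track's group")
    if kin is None:
        kin = compute_kinematics(track)
    labels = np.array([""] * len(track), dtype=object)
    if len(kin):
        states = model.predict_states(kin[["v", "theta"]].to_numpy(float))
        labels[kin["idx"].to_numpy(int)] = states
        filled = np.where(labels != "")[0]
        for i in np.where(labels == "")[0]:
            j = filled[np.argmin(np.abs(filled - i))]
            labels[i] = labels[j]
    else:
        labels[:] = "LL"  # too short to classify: treat as stationary
    keep = labels != "HL"
    return labels, track[keep].reset_index(drop=True)
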