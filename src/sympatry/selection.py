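"""Habitat selection: population-level RSFs and individual-level iSSFs.

The resource selection function (RSF) contrasts used fixes against random
available fixes drawn inside each bird's minimum convex polygon (20 per use
fix, weighted 1:20), in a logistic regression with a per-bird random
intercept, habitat treatment-coded against agriculture, and optionally a
habitat x group (species or year) interaction. The mixed model is fitted by
maximising the Laplace-approximated marginal likelihood; a fixed-effects
fit with cluster-robust standard errors is the fallback when the intercept
variance collapses.

The integrated step-selection function (iSSF) works at the scale of single
movement steps: each observed step is paired with 20 random steps sharing
its start point, with lengths from a gamma fit and turns from a von Mises
fit to the bird's own steps, and a conditional logistic model (one stratum
per observed step) estimates per-habitat selection against agriculture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from shapely import contains_xy
from shapely.geometry import MultiPoint

from .habitat import extract_habitat
from .raster import Raster

__all__ = [
    "build_rsf_design",
    "fit_rsf",
    "marginal_means_contrasts",
    "fit_metrics",
    "build_issf_design",
    "fit_issf",
    "SelectionFit",
    "mcp",
]

REFERENCE_HABITAT = "agricultural"


def mcp(x, y):
    """Minimum convex polygon of a point set (availability domain)."""
    hull = MultiPoint(np.column_stack([np.asarray(x, float), np.asarray(y, float)])).convex_hull
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise ValueError("degenerate MCP (collinear or too few fixes)")
    return hull


def _uniform_in_polygon(poly, n, rng):
    """Uniform points inside a polygon by bounding-box rejection."""
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(int((n - len(out)) * 2.5), 32)
        cand = np.column_stack([rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)])
        cand = cand[contains_xy(poly, cand[:, 0], cand[:, 1])]
        out = np.vstack([out, cand])
    return out[:n]


def build_rsf_design(
    tracks: pd.DataFrame | dict,
    habitat_raster: Raster,
    n_avail: int = 20,
    seed: int = 0,
    min_fixes: int = 100,
    available_weight: float = 20.0,
    availability=None,
) -> pd.DataFrame:
    """Use/available table for the RSF.

    `tracks` holds the retained (post-commuting-removal, non-colony) fixes,
    either tidy with a bird_id column or as a dict of per-bird frames.
    Birds with fewer than `min_fixes` fixes, or a degenerate MCP, are
    excluded. Per bird, `n_avail` random fixes are drawn uniformly inside
    its availability domain for each use fix; used rows get weight 1 and
    available rows `available_weight`. The domain defaults to the bird's
    minimum convex polygon; pass a shapely polygon (or a bird_id -> polygon
    mapping) as `availability` when the true domain is known, e.g. in
    simulation studies. Deterministic given `seed`.
    """
    if isinstance(tracks, dict):
        tracks = pd.concat(tracks.values(), ignore_index=True)
    rng = np.random.default_rng(seed)
    rows = []
    for bird, sub in tracks.groupby("bird_id", sort=True):
        if len(sub) < min_fixes:
            warnings.warn(f"{bird}: {len(sub)} fixes < {min_fixes}; excluded from RSF")
            continue
        x = sub["x"].to_numpy(float)
        y = sub["y"].to_numpy(float)
        try:
            if availability is None:
                hull = mcp(x, y)
            elif isinstance(availability, dict):
                hull = availability[bird]
            else:
                hull = availability
        except ValueError:
            warnings.warn(f"{bird}: degenerate MCP; excluded from RSF")
            continue
        avail = _uniform_in_polygon(hull, n_avail * len(sub), rng)
        species = sub["species"].iloc[0] if "species" in sub.columns else ""
        year = (
            pd.to_datetime(sub["timestamp"]).dt.year.iloc[0]
            if "timestamp" in sub.columns
            else None
        )
        use_hab = extract_habitat(habitat_raster, x, y)
        av_hab = extract_habitat(habitat_raster, avail[:, 0], avail[:, 1])
        rows.append(pd.DataFrame({
            "bird_id": bird, "species": species, "year": year,
            "habitat": use_hab, "used": 1, "weight": 1.0, "x": x, "y": y,
        }))
        rows.append(pd.DataFrame({
            "bird_id": bird, "species": species, "year": year,
            "habitat": av_hab, "used": 0, "weight": float(available_weight),
            "x": avail[:, 0], "y": avail[:, 1],
        }))
    if not rows:
        raise ValueError("no birds passed the RSF inclusion rules")
    return pd.concat(rows, ignore_index=True)


@dataclass
class SelectionFit:
    """Fitted RSF: fixed effects with covariance plus the intercept variance."""

    params: pd.Series
    cov: pd.DataFrame
    sigma2_alpha: float
    loglik: float
    converged: bool
    method: str                      # "laplace" or "glm-cluster-robust"
    design_info: dict = field(default_factory=dict)
    random_effects: pd.Series | None = None
    df: float | None = None          # t degrees of freedom (few-cluster robust)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        # cluster-robust covariances from few clusters call for t(G-1)
        # critical values rather than normal ones
        if self.df is not None and np.isfinite(self.df):
            z = stats.t.ppf(1 - alpha / 2, self.df)
        else:
            z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lo": self.params - z * self.se, "hi": self.params + z * self.se}
        )


def _design_matrix(table: pd.DataFrame, group_col: str | None, reference: str):
    """Treatment-coded design: intercept + habitat + group + habitat:group."""
    hab = pd.Categorical(table["habitat"])
    hab_levels = [reference] + [l for l in hab.categories if l != reference]
    hab = pd.Categorical(table["habitat"], categories=hab_levels)
    cols = {"(Intercept)": np.ones(len(table))}
    for l in hab_levels[1:]:
        cols[f"habitat[{l}]"] = (hab == l).astype(float)
    grp_levels = []
    if group_col is not None:
        grp = pd.Categorical(table[group_col].astype(str))
        grp_levels = list(grp.categories)
        for g in grp_levels[1:]:
            cols[f"{group_col}[{g}]"] = (grp == g).astype(float)
        for l in hab_levels[1:]:
            for g in grp_levels[1:]:
                cols[f"habitat[{l}]:{group_col}[{g}]"] = (
                    (hab == l) & (grp == g)
                ).astype(float)
    X = pd.DataFrame(cols, index=table.index)
    info = {"habitat_levels": hab_levels, "group_levels": grp_levels, "group_col": group_col,
            "reference": reference}
    return X, info


def _check_separation(table: pd.DataFrame) -> list[str]:
    out = []
    for h, sub in table.groupby("habitat", observed=True):
        if sub["used"].nunique() == 1:
            out.append(str(h))
    return out


def fit_rsf(
    table: pd.DataFrame,
    group_col: str | None = None,
    reference: str = REFERENCE_HABITAT,
    random_intercept: bool = True,
    max_iter: int = 200,
) -> SelectionFit:
    """Weighted logistic RSF with a per-bird random intercept (Laplace).

    The weighted log-likelihood ``sum_r w_r [y_r log p_r + (1-y_r)
    log(1-p_r)]`` with ``logit p_r = x_r' beta + alpha_bird`` and
    ``alpha ~ N(0, sigma2)`` is maximised over (beta, log sigma) with the
    per-cluster integrals replaced by their Laplace approximations. When
    the intercept variance collapses (or `random_intercept` is False) the
    model degrades to a weighted GLM with cluster-robust covariance.
    """
    X, info = _design_matrix(table, group_col, reference)
    sep = _check_separation(table)
    if sep:
        warnings.warn(f"complete separation in habitats {sep}; their SEs are unreliable")
    y = table["used"].to_numpy(float)
    w = table["weight"].to_numpy(float)
    Xm = X.to_numpy(float)
    clusters, cl_idx = np.unique(table["bird_id"].to_numpy(), return_inverse=True)
    n_cl = len(clusters)

    import statsmodels.api as sm

    glm = sm.GLM(y, Xm, family=sm.families.Binomial(), freq_weights=w)
    glm_fit = glm.fit()
    beta0 = glm_fit.params

    if not random_intercept or n_cl < 2:
        if n_cl >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = glm.fit(cov_type="cluster", cov_kwds={"groups": cl_idx})
        else:
            res = glm_fit
        return SelectionFit(
            params=pd.Series(res.params, index=X.columns),
            cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
            sigma2_alpha=0.0, loglik=float(res.llf), converged=True,
            method="glm-cluster-robust", design_info=info,
            df=(n_cl - 1) if n_cl >= 2 else None,
        )

    alpha_state = np.zeros(n_cl)

    def inner_mode(beta, sigma2, alpha):
        """Newton iterations for the per-cluster intercept modes."""
        xb = Xm @ beta
        for _ in range(50):
            eta = xb + alpha[cl_idx]
            p = special.expit(eta)
            g = np.bincount(cl_idx, weights=w * (y - p), minlength=n_cl) - alpha / sigma2
            h = np.bincount(cl_idx, weights=w * p * (1 - p), minlength=n_cl) + 1.0 / sigma2
            step = g / h
            alpha = alpha + np.clip(step, -4, 4)
            if np.max(np.abs(step)) < 1e-9:
                break
        return alpha, xb

    def neg_marginal_ll(theta):
        beta = theta[:-1]
        sigma2 = np.exp(2.0 * theta[-1])
        alpha, xb = inner_mode(beta, sigma2, alpha_state.copy())
        alpha_state[:] = alpha
        eta = xb + alpha[cl_idx]
        p = special.expit(eta)
        ll_data = np.sum(w * (y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300)))
        h = np.bincount(cl_idx, weights=w * p * (1 - p), minlength=n_cl) + 1.0 / sigma2
        ll = ll_data - np.sum(alpha**2) / (2 * sigma2) - 0.5 * n_cl * np.log(sigma2) \
            - 0.5 * np.sum(np.log(h))
        return -ll

    theta0 = np.concatenate([beta0, [np.log(0.5)]])
    opt = optimize.minimize(
        neg_marginal_ll, theta0, method="L-BFGS-B",
        bounds=[(None, None)] * len(beta0) + [(-6.0, 3.0)],
        options={"maxiter": max_iter, "ftol": 1e-10},
    )
    beta = opt.x[:-1]
    sigma2 = float(np.exp(2.0 * opt.x[-1]))

    if sigma2 < 1e-5:
        warnings.warn("random-intercept variance collapsed; cluster-robust GLM fallback")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(cov_type="cluster", cov_kwds={"groups": cl_idx})
        return SelectionFit(
            params=pd.Series(res.params, index=X.columns),
            cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
            sigma2_alpha=0.0, loglik=float(res.llf), converged=bool(opt.success),
            method="glm-cluster-robust", design_info=info, df=n_cl - 1,
        )

    # covariance of beta from the joint observed information at the mode,
    # profiling out the cluster intercepts (Schur complement)
    alpha, xb = inner_mode(beta, sigma2, alpha_state.copy())
    p = special.expit(xb + alpha[cl_idx])
    W = w * p * (1 - p)
    XtWX = (Xm * W[:, None]).T @ Xm
    ZtWZ = np.bincount(cl_idx, weights=W, minlength=n_cl) + 1.0 / sigma2
    XtWZ = np.zeros((Xm.shape[1], n_cl))
    for j in range(Xm.shape[1]):
        XtWZ[j] = np.bincount(cl_idx, weights=W * Xm[:, j], minlength=n_cl)
    info_beta = XtWX - XtWZ @ (XtWZ / ZtWZ[None, :]).T
    cov = np.linalg.pinv(info_beta)

    return SelectionFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        sigma2_alpha=sigma2,
        loglik=float(-opt.fun),
        converged=bool(opt.success),
        method="laplace",
        design_info=info,
        random_effects=pd.Series(alpha, index=clusters),
    )


def _cell_design_row(fit: SelectionFit, habitat: str, group) -> np.ndarray:
    cols = fit.params.index
    row = np.zeros(len(cols))
    info = fit.design_info
    gc = info["group_col"]
    for i, c in enumerate(cols):
        if c == "(Intercept)":
            row[i] = 1.0
        elif c == f"habitat[{habitat}]":
            row[i] = 1.0
        elif gc and c == f"{gc}[{group}]":
            row[i] = 1.0
        elif gc and c == f"habitat[{habitat}]:{gc}[{group}]":
            row[i] = 1.0
    return row


def marginal_means_contrasts(fit: SelectionFit, adjust: str = "tukey") -> dict:
    """Cell marginal means and pairwise contrasts from the fitted RSF.

    For every habitat x group cell the linear predictor (random effects at
    zero) and its delta-method interval are reported on the response scale
    (extent of selection); pairwise differences are computed on the link
    scale within each habitat (between groups) and within each group
    (between habitats), with Tukey studentized-range adjustment by default
    (``adjust``: "tukey", "bonferroni" or "none").
    """
    info = fit.design_info
    habitats = info["habitat_levels"]
    groups = info["group_levels"] or [None]
    covm = fit.cov.to_numpy()
    beta = fit.params.to_numpy()

    cells = []
    for h in habitats:
        for g in groups:
            L = _cell_design_row(fit, h, g)
            eta = float(L @ beta)
            se = float(np.sqrt(L @ covm @ L))
            cells.append({
                "habitat": h, "group": g, "eta": eta, "se_eta": se,
                "response": float(special.expit(eta)),
                "response_lo": float(special.expit(eta - 1.96 * se)),
                "response_hi": float(special.expit(eta + 1.96 * se)),
                "_L": L,
            })
    cells_df = pd.DataFrame(cells)

    def pairwise(sub: pd.DataFrame, label_col: str, family_k: int):
        out = []
        recs = sub.to_dict("records")
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                L = recs[i]["_L"] - recs[j]["_L"]
                est = float(L @ beta)
                se = float(np.sqrt(L @ covm @ L))
                z = est / se if se > 0 else np.inf
                if adjust == "tukey" and family_k > 1:
                    p = float(stats.studentized_range.sf(abs(z) * np.sqrt(2), family_k, 1e6))
                elif adjust == "bonferroni":
                    m = family_k * (family_k - 1) / 2
                    p = min(2 * stats.norm.sf(abs(z)) * m, 1.0)
                else:
                    p = 2 * stats.norm.sf(abs(z))
                out.append({
                    "contrast": f"{recs[i][label_col]} - {recs[j][label_col]}",
                    "estimate": est, "se": se, "z": z, "p": p,
                })
        return out

    between_group = []
    if info["group_levels"]:
        for h in habitats:
            sub = cells_df[cells_df.habitat == h]
            for r in pairwise(sub, "group", len(groups)):
                r["habitat"] = h
                between_group.append(r)
    between_habitat = []
    for g in groups:
        sub = cells_df[cells_df.group == g] if g is not None else cells_df
        for r in pairwise(sub, "habitat", len(habitats)):
            r["group"] = g
            between_habitat.append(r)
    return {
        "means": cells_df.drop(columns=["_L"]),
        "between_group": pd.DataFrame(between_group),
        "between_habitat": pd.DataFrame(between_habitat),
    }


def fit_metrics(fit: SelectionFit, table: pd.DataFrame) -> dict:
    """AUC of used-vs-available discrimination and Nakagawa R-squared.

    AUC is the rank statistic of the fitted probabilities (fixed effects
    plus random intercepts). ``R2_marginal = var_f / (var_f + sigma2_alpha
    + pi^2/3)`` and ``R2_conditional = (var_f + sigma2_alpha) / (...)``
    with var_f the variance of the fixed-effect linear predictor and
    pi^2/3 the logit-link distribution-specific variance.
    """
    from sklearn.metrics import roc_auc_score

    X, _ = _design_matrix(table, fit.design_info["group_col"], fit.design_info["reference"])
    eta = X.to_numpy(float) @ fit.params.to_numpy()
    if fit.random_effects is not None:
        re = fit.random_effects.reindex(table["bird_id"]).to_numpy()
        score = eta + np.nan_to_num(re)
    else:
        score = eta
    y = table["used"].to_numpy(int)
    if y.min() == y.max():
        raise ValueError("AUC undefined: only one response class present")
    auc = float(roc_auc_score(y, score))
    var_f = float(np.var(eta))
    denom = var_f + fit.sigma2_alpha + np.pi**2 / 3.0
    return {
        "auc": auc,
        "r2_marginal": var_f / denom,
        "r2_conditional": (var_f + fit.sigma2_alpha) / denom,
    }


# --------------------------------------------------------------------------
# iSSF
# --------------------------------------------------------------------------

def build_issf_design(
    track: pd.DataFrame,
    habitat_raster: Raster,
    n_steps: int = 20,
    seed: int = 0,
    min_steps: int = 30,
) -> pd.DataFrame:
    """Observed + random step table (strata of 21) for one bird.

    Step lengths of the random steps follow a gamma distribution fitted to
    the bird's observed step lengths and turning angles a von Mises fitted
    to its observed turns (uniform when the concentration estimate falls
    below 0.1). Random steps share the observed step's start point; the
    habitat at each end point is extracted from the overlay raster.
    """
    track = track.sort_values("timestamp").reset_index(drop=True)
    x = track["x"].to_numpy(float)
    y = track["y"].to_numpy(float)
    dx = np.diff(x)
    dy = np.diff(y)
    lengths = np.hypot(dx, dy)
    bearings = np.arctan2(dx, dy)
    turns = (np.diff(bearings) + np.pi) % (2 * np.pi) - np.pi
    # observed step i: from fix i to i+1, previous bearing from step i-1
    n_obs = len(lengths) - 1
    if n_obs < min_steps:
        warnings.warn(f"only {n_obs} observed steps (< {min_steps}); bird excluded from iSSF")
        return pd.DataFrame()
    pos_lengths = lengths[lengths > 0]
    shape, _loc, scale = stats.gamma.fit(pos_lengths, floc=0)
    kappa, _loc, _scale = stats.vonmises.fit(turns, fscale=1)
    rng = np.random.default_rng(seed)
    rows = []
    bird = str(track["bird_id"].iloc[0]) if "bird_id" in track else ""
    for s in range(n_obs):
        # stratum s: observed step runs fix s+1 -> s+2; the previous
        # displacement (fix s -> s+1) supplies the reference bearing
        start = np.array([x[s + 1], y[s + 1]])
        obs_end = np.array([x[s + 2], y[s + 2]])
        prev_bearing = bearings[s]
        rnd_len = rng.gamma(shape, scale, size=n_steps)
        if kappa >= 0.1:
            rnd_turn = rng.vonmises(0.0, kappa, size=n_steps)
        else:
            rnd_turn = rng.uniform(-np.pi, np.pi, size=n_steps)
        head = prev_bearing + rnd_turn
        ends = np.vstack([
            obs_end,
            start[None, :] + np.column_stack([rnd_len * np.sin(head), rnd_len * np.cos(head)]),
        ])
        habs = extract_habitat(habitat_raster, ends[:, 0], ends[:, 1])
        used = np.zeros(n_steps + 1, int)
        used[0] = 1
        step_len = np.hypot(ends[:, 0] - start[0], ends[:, 1] - start[1])
        rows.append(pd.DataFrame({
            "bird_id": bird, "stratum": s, "used": used, "habitat": habs,
            "x": ends[:, 0], "y": ends[:, 1], "step_length": step_len,
        }))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["gamma_shape"] = float(shape)
    out.attrs["gamma_scale"] = float(scale)
    out.attrs["vonmises_kappa"] = float(kappa)
    return out


def fit_issf(
    step_table: pd.DataFrame,
    reference: str = REFERENCE_HABITAT,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> dict:
    """Conditional logistic fit of habitat selection within strata.

    Maximises ``sum_s [x_obs' beta - log sum_j exp(x_j' beta)]`` by
    Newton-Raphson with step halving. Habitats absent from every stratum
    yield no coefficient and are reported in ``absent``; habitats whose
    coefficient diverges (monotone likelihood: the habitat appears only as
    used or only as available) are flagged ``unstable``.
    """
    if len(step_table) == 0:
        raise ValueError("empty step table")
    habs = pd.Categorical(step_table["habitat"])
    levels = [reference] + [l for l in habs.categories if l != reference]
    present = [l for l in levels[1:]]
    all_cols = [f"habitat[{l}]" for l in present]
    Xfull = (
        np.column_stack([(habs == l).astype(float) for l in present])
        if present
        else np.zeros((len(step_table), 0))
    )
    y = step_table["used"].to_numpy(float)
    strata, s_idx = np.unique(step_table["stratum"].to_numpy(), return_inverse=True)
    n_s = len(strata)
    # a dummy constant within every stratum carries no information in the
    # conditional likelihood: exclude it from the optimisation and report a
    # zero coefficient with infinite variance
    degenerate = []
    keep_cols = []
    for j in range(Xfull.shape[1]):
        smean = np.bincount(s_idx, weights=Xfull[:, j], minlength=n_s)
        smean = smean / np.bincount(s_idx, minlength=n_s)
        if np.max(np.abs(Xfull[:, j] - smean[s_idx])) < 1e-12:
            degenerate.append(j)
        else:
            keep_cols.append(j)
    X = Xfull[:, keep_cols]
    cols = [all_cols[j] for j in keep_cols]
    k = X.shape[1]
    beta = np.zeros(k)

    def loglik_grad_hess(beta):
        eta = X @ beta
        # per-stratum softmax
        m = np.full(n_s, -np.inf)
        np.maximum.at(m, s_idx, eta)
        ex = np.exp(eta - m[s_idx])
        denom = np.bincount(s_idx, weights=ex, minlength=n_s)
        p = ex / denom[s_idx]
        ll = float(np.sum(y * (eta - (m + np.log(denom))[s_idx])))
        g = X.T @ (y - p)
        A = np.zeros((n_s, k))
        for j in range(k):
            A[:, j] = np.bincount(s_idx, weights=p * X[:, j], minlength=n_s)
        H = -((X * p[:, None]).T @ X - A.T @ A)
        return ll, g, H

    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, g, H = loglik_grad_hess(beta)
        if k == 0:
            converged = True
            break
        try:
            step = np.linalg.solve(H - 1e-10 * np.eye(k), -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        # step halving to keep the likelihood non-decreasing
        t = 1.0
        for _h in range(30):
            ll_new, _, _ = loglik_grad_hess(beta + t * step)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
        ll_old = ll_new

    unstable = [cols[i].split("[")[1].rstrip("]") for i in range(k) if abs(beta[i]) > 12]
    if k:
        cov = np.linalg.pinv(-H)
        se_vals = np.sqrt(np.clip(np.diag(cov), 0, None))
    else:
        se_vals = np.zeros(0)
    params = pd.Series(beta, index=cols)
    se = pd.Series(se_vals, index=cols)
    for j in degenerate:
        params[all_cols[j]] = 0.0
        se[all_cols[j]] = np.inf
    params = params.reindex(all_cols)
    se = se.reindex(all_cols)
    ci = pd.DataFrame({"lo": params - 1.96 * se, "hi": params + 1.96 * se})
    absent = [l for l in ("marine", "coastal", "urban", "other", "landfill", "harbour")
              if l not in habs.categories]
    return {
        "params": params, "se": se, "conf_int": ci, "loglik": float(ll),
        "converged": converged, "absent": absent, "unstable": unstable,
        "n_strata": int(n_s), "reference": reference,
    }
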