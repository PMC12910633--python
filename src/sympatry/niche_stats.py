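"""Individual specialisation and niche-overlap statistics.

Habitat-use profiles (per-individual proportions p_ij against pooled
population proportions q_j) feed three indices:

* proportional similarity ``PS_i = 1 - 0.5 * sum_j |p_ij - q_j|`` — 0 is an
  absolute specialist, 1 an absolute generalist; the population mean PS is
  tested against a Monte Carlo null in which each individual's fixes are
  multinomial draws from q (999 replicates, one-sided towards
  specialisation, with the +1 correction);
* Pianka's overlap ``O = sum p_a p_b / sqrt(sum p_a^2 sum p_b^2)`` between
  two species' pooled profiles, banded low (0.00-0.39), intermediate
  (0.40-0.60) or high (0.61-1.00);
* a Kruskal-Wallis test of PS_i across species.

Also here: the foraging-range mixed model (species fixed effect, bird
random intercept, contrasts in km) and the harbour-visits vs fishery
landings regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HabitatUseProfile",
    "habitat_use_profile",
    "proportional_similarity",
    "pianka_overlap",
    "compare_specialization",
    "foraging_range_model",
    "harbour_landings_model",
]


@dataclass
class HabitatUseProfile:
    """Per-individual habitat-use counts, proportions, and pooled q."""

    counts: pd.DataFrame        # individuals x categories, integer counts
    proportions: pd.DataFrame   # row-normalised counts (p_ij)
    q: pd.Series                # population proportions (count-pooled)

    @property
    def individuals(self):
        return list(self.counts.index)

    @property
    def categories(self):
        return list(self.counts.columns)


def habitat_use_profile(
    use_fixes: pd.DataFrame,
    habitat_col: str = "habitat",
    bird_col: str = "bird_id",
    q_method: str = "pooled",
) -> HabitatUseProfile:
    """Profiles from the retained use fixes of one species.

    `use_fixes` must already exclude at-colony and commuting fixes. The
    population proportions q_j pool fix counts across individuals (matching
    the multinomial resampling null); ``q_method="mean"`` averages the
    individual proportion vectors instead.
    """
    counts = use_fixes.groupby([bird_col, habitat_col], observed=True).size().unstack(fill_value=0)
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"excluding individuals with no retained fixes: {list(counts.index[empty])}")
        counts = counts[~empty]
    props = counts.div(counts.sum(axis=1), axis=0)
    if q_method == "pooled":
        q = counts.sum(axis=0) / counts.to_numpy().sum()
    elif q_method == "mean":
        q = props.mean(axis=0)
    else:
        raise ValueError("q_method must be 'pooled' or 'mean'")
    return HabitatUseProfile(counts=counts, proportions=props, q=q)


def ps_index(p: np.ndarray, q: np.ndarray) -> float:
    """Proportional similarity of one individual to the population."""
    return float(1.0 - 0.5 * np.abs(np.asarray(p, float) - np.asarray(q, float)).sum())


def proportional_similarity(
    profile: HabitatUseProfile, n_replicates: int = 999, seed: int = 0
) -> dict:
    """PS_i per individual with a Monte Carlo specialisation test.

    The null resamples each individual's n_i fixes from Multinomial(n_i, q)
    and recomputes the mean PS; the one-sided p-value is
    ``(1 + #{null mean PS <= observed mean PS}) / (n_replicates + 1)``
    (specialisation shows up as a *lower* mean PS than the null).
    """
    counts = profile.counts.to_numpy(float)
    if counts.shape[1] < 2:
        warnings.warn("single habitat category: PS_i degenerate (all 1)")
        psi = pd.Series(1.0, index=profile.counts.index)
        return {"psi": psi, "mean_ps": 1.0, "p_value": np.nan, "n_replicates": n_replicates}
    q = profile.q.to_numpy(float)
    n_i = counts.sum(axis=1)
    p = counts / n_i[:, None]
    psi = np.array([ps_index(p[i], q) for i in range(len(p))])
    obs_mean = psi.mean()
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_replicates)
    for r in range(n_replicates):
        sim = np.array([rng.multinomial(int(n), q) for n in n_i], float)
        simp = sim / sim.sum(axis=1)[:, None]
        # recompute the pooled population vector from the resampled counts,
        # exactly as the observed statistic does — otherwise the null is
        # mis-centred and the test badly conservative
        q_rep = sim.sum(axis=0) / sim.sum()
        null_means[r] = np.mean(1.0 - 0.5 * np.abs(simp - q_rep[None, :]).sum(axis=1))
    p_val = (1.0 + np.sum(null_means <= obs_mean)) / (n_replicates + 1.0)
    return {
        "psi": pd.Series(psi, index=profile.counts.index),
        "mean_ps": float(obs_mean),
        "p_value": float(p_val),
        "n_replicates": n_replicates,
        "null_means": null_means,
    }


PIANKA_BANDS = ((0.40, "low"), (0.61, "intermediate"), (np.inf, "high"))


def pianka_band(o: float) -> str:
    """Band an overlap value: [0,0.40) low, [0.40,0.61) intermediate, rest high."""
    for edge, name in PIANKA_BANDS:
        if o < edge:
            return name
    return "high"


def pianka_overlap(p_a, p_b) -> tuple[float, str]:
    """Pianka's symmetric niche-overlap index with its category band."""
    a = np.asarray(p_a, float)
    b = np.asarray(p_b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the same category set")
    na = np.sqrt((a**2).sum())
    nb = np.sqrt((b**2).sum())
    if na == 0 or nb == 0:
        raise ValueError("zero-vector habitat profile")
    o = float((a * b).sum() / (na * nb))
    return o, pianka_band(o)


def compare_specialization(psi_by_species: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis test of PS_i across species (tie-corrected)."""
    groups = [np.asarray(v, float) for v in psi_by_species.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return {"H": 0.0, "df": len(groups) - 1, "p_value": 1.0}
    H, p = stats.kruskal(*groups)
    return {"H": float(H), "df": len(groups) - 1, "p_value": float(p)}


def foraging_range_model(trip_table: pd.DataFrame) -> dict:
    """Species differences in foraging range (km), bird as random intercept.

    Fits a linear mixed model by REML on complete trips only and reports
    pairwise species contrasts on the response scale with a between-bird
    degrees-of-freedom approximation (df = n_birds - n_species). Falls
    back to OLS with a warning when the grouping is degenerate.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    tab = trip_table[trip_table["complete"] & trip_table["d_max_km"].notna()].copy()
    species = sorted(tab["species"].unique())
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    birds_per_sp = tab.groupby("species")["bird_id"].nunique()
    mixed_ok = (birds_per_sp > 1).all()
    fit = None
    sigma2_bird = 0.0
    if mixed_ok:
        try:
            md = smf.mixedlm("d_max_km ~ C(species)", tab, groups=tab["bird_id"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = md.fit(reml=True)
            params = fit.params
            cov = fit.cov_params()
            sigma2_bird = float(fit.cov_re.iloc[0, 0])
        except (np.linalg.LinAlgError, ValueError):
            fit = None
    if fit is None:
        warnings.warn("bird-level variance inestimable; fixed-effects fallback")
        fit = smf.ols("d_max_km ~ C(species)", tab).fit()
        params = fit.params
        cov = fit.cov_params()
        sigma2_bird = 0.0
    # cell means and pairwise contrasts on the km scale
    names = list(params.index)
    rows = []
    df_approx = max(tab["bird_id"].nunique() - len(species), 1)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            L = np.zeros(len(names))
            for j, nm in enumerate(names):
                if nm == f"C(species)[T.{a}]":
                    L[j] += 1
                if nm == f"C(species)[T.{b}]":
                    L[j] -= 1
            est = float(L @ params.to_numpy())
            se = float(np.sqrt(L @ np.asarray(cov)[: len(L), : len(L)] @ L))
            t = est / se if se > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), df_approx)
            rows.append({"contrast": f"{a} - {b}", "estimate_km": est, "se": se,
                         "t": t, "df": df_approx, "p": float(p)})
    means = tab.groupby("species")["d_max_km"].agg(["mean", "std", "count"])
    return {
        "model": fit,
        "sigma2_bird": sigma2_bird,
        "contrasts": pd.DataFrame(rows),
        "species_means": means,
    }


def harbour_landings_model(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-species OLS of monthly harbour visits on fishery landings.

    `visits` needs columns (species, harbour, month, n_fixes, landings_kg);
    rows with missing landings are dropped. Returns slope, SE, t and p per
    species.
    """
    import statsmodels.api as sm

    out = []
    for sp, sub in visits.dropna(subset=["landings_kg"]).groupby("species"):
        if len(sub) < 3:
            raise ValueError(f"{sp}: fewer than 3 paired observations")
        X = sm.add_constant(sub["landings_kg"].to_numpy(float))
        res = sm.OLS(sub["n_fixes"].to_numpy(float), X).fit()
        out.append({
            "species": sp, "slope": float(res.params[1]), "se": float(res.bse[1]),
            "t": float(res.tvalues[1]), "p": float(res.pvalues[1]), "n": len(sub),
        })
    return pd.DataFrame(out)
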