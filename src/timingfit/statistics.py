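"""Map-level aggregation and statistical comparisons of model fits.

The analysis unit throughout is the *measurement*: one hemisphere of one
participant in one cross-validation split contributes one median (or
mean) variance-explained value per map and model.  Model-vs-model
comparisons within maps use paired two-sided Wilcoxon signed-rank tests
with Benjamini-Hochberg FDR correction and effect size r = Z/sqrt(n),
preceded by a fixed-effects ANOVA (Type III sums of squares) and a
Jarque-Bera normality gate; medians carry bootstrap percentile
confidence intervals.  Eccentricity analyses bin voxels at 0.2-degree
resolution and compare near (<1 deg) against far (>2, <5.6 deg)
visual-field representations.

A Bayes-factor column is carried as a placeholder (NaN) so output tables
keep the full published column layout; Bayesian paired comparisons are
out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------------------
# elementary tests


def wilcoxon_signed_rank(x, y=None, method: str = "auto") -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped (classical convention).  ``method``:
    ``"approx"`` uses the normal approximation with tie correction and a
    0.5 continuity correction; ``"exact"`` enumerates the null
    distribution of the rank sum (untied ranks only); ``"auto"`` picks
    exact for n <= 12 without ties — the discrete small-n null deviates
    from any normal approximation by more than is acceptable there —
    and the approximation otherwise.  Returns (Z, p); Z comes from the
    approximation in every case (it feeds the effect size r = Z/sqrt(n))
    and is > 0 when x tends to exceed y.  All-zero differences give
    (0, 1) by convention.
    """
    d = np.asarray(x, float) - (0 if y is None else np.asarray(y, float))
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    has_ties = (counts > 1).any()
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        return 0.0, 1.0
    z = np.sign(w_pos - mu) * max(abs(w_pos - mu) - 0.5, 0.0) / np.sqrt(var)
    z = float(z)
    if method == "exact" and has_ties:
        raise ValueError("exact method requires untied ranks")
    use_exact = method == "exact" or (method == "auto" and n <= 12 and not has_ties)
    if use_exact:
        # null distribution of W+ over all 2^n sign assignments, by DP
        dist = np.zeros(n * (n + 1) // 2 + 1)
        dist[0] = 1.0
        for r in range(1, n + 1):
            dist[r:] += dist[:-r]
        dist /= dist.sum()
        w_all = np.arange(dist.size)
        p = float(dist[np.abs(w_all - mu) >= abs(w_pos - mu) - 1e-12].sum())
    elif method in ("approx", "auto"):
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    return z, min(p, 1.0)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone)."""
    p = np.asarray(p_values, float)
    return multipletests(p, method="fdr_bh")[1]


def effect_size_r(z: float, n: int) -> float:
    if n <= 0:
        raise ValueError("n must be positive")
    return z / np.sqrt(n)


def bootstrap_median_ci(
    values, n_iter: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile CI of the median from resamples with replacement."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("values must be nonempty")
    rng = np.random.default_rng(seed)
    meds = np.median(v[rng.integers(v.size, size=(n_iter, v.size))], axis=1)
    alpha = (1 - level) / 2
    return float(np.quantile(meds, alpha)), float(np.quantile(meds, 1 - alpha))


def jarque_bera(values) -> tuple[float, float]:
    res = stats.jarque_bera(np.asarray(values, float))
    return float(res.statistic), float(res.pvalue)


def anova_nfactor(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    interactions: list[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Fixed-effects n-factor ANOVA with Type III sums of squares.

    Returns one row per term with F, p and partial eta squared
    (SS_effect / (SS_effect + SS_error)).
    """
    import statsmodels.api as smapi
    import statsmodels.formula.api as smf

    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    terms = [f"C({f}, Sum)" for f in factors]
    terms += [f"C({a}, Sum):C({b}, Sum)" for a, b in interactions]
    formula = f"{response} ~ " + " + ".join(terms)
    data = table.copy()
    if data[response].nunique() == 1:
        # constant response: every F is 0 by definition
        rows = [
            dict(term=t, df=np.nan, F=0.0, p=1.0, partial_eta_sq=0.0)
            for t in factors + [f"{a}:{b}" for a, b in interactions]
        ]
        return pd.DataFrame(rows)
    model = smf.ols(formula, data=data).fit()
    tbl = smapi.stats.anova_lm(model, typ=3)
    ss_err = tbl.loc["Residual", "sum_sq"]
    rows = []
    names = factors + [f"{a}:{b}" for a, b in interactions]
    keys = terms
    for name, key in zip(names, keys):
        ss = tbl.loc[key, "sum_sq"]
        rows.append(
            dict(
                term=name,
                df=tbl.loc[key, "df"],
                F=tbl.loc[key, "F"],
                p=tbl.loc[key, "PR(>F)"],
                partial_eta_sq=ss / (ss + ss_err),
            )
        )
    return pd.DataFrame(rows)


def dunn_holm_sidak(groups) -> pd.DataFrame:
    """Dunn's rank-based pairwise test with Holm-Sidak adjustment.

    ``groups`` maps group label -> 1-D samples (or is a list of
    samples).  Returns one row per pair with z, raw and adjusted p.
    """
    if not isinstance(groups, dict):
        groups = {i: g for i, g in enumerate(groups)}
    labels = list(groups)
    samples = [np.asarray(groups[k], float) for k in labels]
    if len(samples) < 2 or any(s.size < 1 for s in samples):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    pos = 0
    for s in samples:
        mean_ranks.append(ranks[pos : pos + s.size].mean())
        sizes.append(s.size)
        pos += s.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            rows.append(
                dict(
                    group_a=labels[i],
                    group_b=labels[j],
                    z=z,
                    p_raw=2 * stats.norm.sf(abs(z)),
                )
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_sidak(out.p_raw.values)
    return out


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjustment."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p)
    # step-down: running maximum over the sorted sequence, capped at 1
    adj_sorted = np.maximum.accumulate(1.0 - (1.0 - p[order]) ** (m - np.arange(m)))
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


# ---------------------------------------------------------------------------
# map-level summaries


def _passing_mask(fits: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Voxel x split selection: some model's training VE above threshold."""
    tr = fits.pivot_table(
        index=["voxel_id", "split"], columns="model", values="ve_train"
    )
    keep = tr.max(axis=1) > threshold
    return keep.rename("passes").reset_index()


def map_median_ve(
    fits: pd.DataFrame, annotations: pd.DataFrame, threshold: float = 0.2
) -> pd.DataFrame:
    """Median cross-validated VE per map x hemisphere x split x model.

    Voxels pass a (split-specific) selection when either model explains
    more than ``threshold`` of the training variance; a cell with no
    passing voxel is absent from the output.
    """
    keep = _passing_mask(fits, threshold)
    df = fits.merge(keep, on=["voxel_id", "split"]).query("passes")
    df = df.merge(
        annotations[
            ["voxel_id", "participant_id", "hemisphere_id", "visual_field_map"]
        ],
        on="voxel_id",
    )
    out = (
        df.groupby(
            ["visual_field_map", "participant_id", "hemisphere_id", "split", "model"],
            observed=True,
        )
        .agg(median_ve=("ve_cv", "median"), n_voxels=("ve_cv", "size"))
        .reset_index()
    )
    return out


def compare_models_by_map(
    fits: pd.DataFrame,
    annotations: pd.DataFrame,
    threshold: float = 0.2,
    n_boot: int = 1000,
    seed: int = 0,
    map_order=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-map tuned-vs-monotonic comparison across measurements.

    Returns ``(table, anova)``.  ``table`` mirrors the published layout:
    per map the median fits of both models with bootstrap CIs, the
    Wilcoxon Z, effect size r, raw and FDR-adjusted p, a Jarque-Bera
    normality p for the paired differences, and a Bayes-factor
    placeholder.  ``anova`` is the 3-factor fixed-effects ANOVA
    (participant, map, model; interaction map x model) on the
    measurement-level medians.
    """
    med = map_median_ve(fits, annotations, threshold)
    wide = med.pivot_table(
        index=["visual_field_map", "participant_id", "hemisphere_id", "split"],
        columns="model",
        values="median_ve",
    ).dropna()
    anova = anova_nfactor(
        med.rename(columns=dict(median_ve="ve")),
        "ve",
        ["participant_id", "visual_field_map", "model"],
        interactions=[("visual_field_map", "model")],
    )
    rows = []
    maps = map_order or sorted(wide.index.get_level_values(0).unique())
    for m in maps:
        if m not in wide.index.get_level_values(0):
            continue
        sub = wide.xs(m, level="visual_field_map")
        mono, tuned = sub["monotonic"].values, sub["tuned"].values
        z, p = wilcoxon_signed_rank(tuned, mono)
        jb_p = jarque_bera(tuned - mono)[1] if len(sub) >= 8 else np.nan
        ci_m = bootstrap_median_ci(mono, n_boot, seed=seed)
        ci_t = bootstrap_median_ci(tuned, n_boot, seed=seed + 1)
        rows.append(
            dict(
                map=m,
                n=len(sub),
                median_monotonic=np.median(mono),
                ci_monotonic_lo=ci_m[0],
                ci_monotonic_hi=ci_m[1],
                median_tuned=np.median(tuned),
                ci_tuned_lo=ci_t[0],
                ci_tuned_hi=ci_t[1],
                median_difference=np.median(tuned - mono),
                Z=z,
                effect_size_r=effect_size_r(z, len(sub)),
                p=p,
                jarque_bera_p=jb_p,
                bayes_factor=np.nan,
            )
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = fdr_bh(table.p.values)
    return table, anova


def hierarchy_progression(
    fits: pd.DataFrame,
    annotations: pd.DataFrame,
    threshold: float = 0.2,
) -> tuple[pd.DataFrame, float]:
    """Tuned-minus-monotonic median-VE difference along the hierarchy.

    Returns a per-map frame (hierarchy index, median difference across
    measurements) and the Spearman rank correlation of that difference
    with the hierarchy index.
    """
    med = map_median_ve(fits, annotations, threshold)
    wide = med.pivot_table(
        index=["visual_field_map", "participant_id", "hemisphere_id", "split"],
        columns="model",
        values="median_ve",
    ).dropna()
    diff = (
        (wide["tuned"] - wide["monotonic"])
        .groupby("visual_field_map")
        .median()
        .rename("median_difference")
        .reset_index()
    )
    ranks = annotations[["visual_field_map", "hierarchy_index"]].drop_duplicates()
    out = diff.merge(ranks, on="visual_field_map").sort_values("hierarchy_index")
    rho = stats.spearmanr(out.hierarchy_index, out.median_difference).statistic
    return out.reset_index(drop=True), float(rho)


def map_median_params(
    fits: pd.DataFrame,
    annotations: pd.DataFrame,
    param: str,
    model: str,
    threshold: float = 0.2,
) -> pd.DataFrame:
    """Median parameter per map x hemisphere x split (per-model gate).

    The selection here is per model: a voxel contributes only when *this*
    model's training VE in that split exceeds the threshold.  For the
    monotonic amplitude ratio, voxels with a zero or infinite ratio
    (one component absent) are excluded.
    """
    df = fits[fits.model == model].query("ve_train > @threshold").copy()
    if param == "amplitude_ratio":
        df = df[np.isfinite(df.amplitude_ratio) & (df.amplitude_ratio > 0)]
    df = df.merge(
        annotations[
            ["voxel_id", "participant_id", "hemisphere_id", "visual_field_map"]
        ],
        on="voxel_id",
    )
    return (
        df.groupby(
            ["visual_field_map", "participant_id", "hemisphere_id", "split"],
            observed=True,
        )[param]
        .median()
        .rename("median_value")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# eccentricity analyses


def eccentricity_bins(
    fits: pd.DataFrame,
    annotations: pd.DataFrame,
    bin_width: float = 0.2,
    center_min: float = 0.1,
    center_max: float = 5.5,
    min_count: int = 50,
    ve_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-map eccentricity-binned mean cross-validated VE (+SEM).

    Voxels (pooled across hemispheres and splits) enter a half-open bin
    [center - w/2, center + w/2); bins with fewer than ``min_count``
    entries are dropped.  Voxel x split entries where neither model
    exceeds ``ve_floor`` training VE are excluded.
    """
    keep = _passing_mask(fits, ve_floor)
    wide = (
        fits.merge(keep, on=["voxel_id", "split"])
        .query("passes")
        .pivot_table(index=["voxel_id", "split"], columns="model", values="ve_cv")
        .dropna()
        .reset_index()
        .merge(annotations[["voxel_id", "visual_field_map", "eccentricity_deg"]], on="voxel_id")
    )
    centers = np.round(np.arange(center_min, center_max + 1e-9, bin_width), 10)
    edges = np.concatenate([centers - bin_width / 2, [centers[-1] + bin_width / 2]])
    wide["bin_center"] = pd.cut(
        wide.eccentricity_deg, bins=edges, labels=centers, right=False
    ).astype(float)
    wide["difference"] = wide["tuned"] - wide["monotonic"]
    out = (
        wide.dropna(subset=["bin_center"])
        .groupby(["visual_field_map", "bin_center"], observed=True)
        .agg(
            n=("monotonic", "size"),
            mean_monotonic=("monotonic", "mean"),
            sem_monotonic=("monotonic", "sem"),
            mean_tuned=("tuned", "mean"),
            sem_tuned=("tuned", "sem"),
            mean_difference=("difference", "mean"),
            sem_difference=("difference", "sem"),
        )
        .reset_index()
    )
    return out[out.n >= min_count].reset_index(drop=True)


def _sigmoid(x, inflection, slope, maximum, minimum):
    return minimum + (maximum - minimum) * stats.norm.cdf(slope * (x - inflection))


def fit_eccentricity_progression(
    bin_centers,
    bin_means,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Fit a cumulative-Gaussian sigmoid and a quadratic to bin means.

    The displayed curve is the one whose fitted values correlate best
    with the bin means (ties, including constant data, go to the
    quadratic).  The sigmoid CI is a bootstrap percentile band over bin
    resamples; the quadratic CI comes from the analytic parameter
    covariance.
    """
    x = np.asarray(bin_centers, float)
    y = np.asarray(bin_means, float)
    if x.size < 5:
        raise ValueError("need at least 5 bins")

    quad_coef, quad_cov = np.polyfit(x, y, 2, cov=True)
    quad_pred = np.polyval(quad_coef, x)
    quad_se = np.sqrt(np.diag(quad_cov))
    tcrit = stats.t.ppf(0.5 + level / 2, x.size - 3)
    result = dict(
        quadratic=dict(
            coefficients=quad_coef,
            ci=np.stack([quad_coef - tcrit * quad_se, quad_coef + tcrit * quad_se]),
        )
    )

    def corr(pred):
        if np.std(pred) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(pred, y)[0, 1])

    import warnings

    sig_params, converged = None, False
    p0 = [x.mean(), -1.0 if y[-1] < y[0] else 1.0, y.max(), y.min()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            sig_params, _ = optimize.curve_fit(_sigmoid, x, y, p0=p0, maxfev=5000)
            converged = True
        except RuntimeError:
            pass

    if converged:
        rng = np.random.default_rng(seed)
        boots = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            for _ in range(n_boot):
                idx = rng.integers(x.size, size=x.size)
                try:
                    bp, _ = optimize.curve_fit(
                        _sigmoid, x[idx], y[idx], p0=sig_params, maxfev=2000
                    )
                    boots.append(bp)
                except RuntimeError:
                    continue
        if boots:
            bq = np.quantile(np.array(boots), [(1 - level) / 2, 0.5 + level / 2], axis=0)
        else:
            bq = np.stack([sig_params, sig_params])
        result["sigmoid"] = dict(
            inflection=sig_params[0],
            slope=sig_params[1],
            maximum=sig_params[2],
            minimum=sig_params[3],
            ci=bq,
        )
        sig_corr = corr(_sigmoid(x, *sig_params))
    else:
        sig_corr = -np.inf

    chosen = "sigmoid" if sig_corr > corr(quad_pred) else "quadratic"
    result["chosen"] = chosen
    result["sigmoid_converged"] = converged
    return result


def near_far_compare(
    fits: pd.DataFrame,
    annotations: pd.DataFrame,
    near_max: float = 1.0,
    far_min: float = 2.0,
    far_max: float = 5.6,
    ve_floor: float = 0.0,
    map_order=None,
) -> dict:
    """Near (<1 deg) vs far (>2, <5.6 deg) eccentricity-range comparison.

    Builds per participant x hemisphere x split x map mean cross-validated
    VE in each eccentricity range (voxels pass when either model's
    training VE exceeds ``ve_floor``), then for each of the monotonic VE,
    tuned VE and their difference: a 3-factor ANOVA (participant, map,
    eccentricity range; interaction map x range) and per-map paired
    Wilcoxon tests with FDR correction.
    """
    keep = _passing_mask(fits, ve_floor)
    wide = (
        fits.merge(keep, on=["voxel_id", "split"])
        .query("passes")
        .pivot_table(index=["voxel_id", "split"], columns="model", values="ve_cv")
        .dropna()
        .reset_index()
        .merge(
            annotations[
                [
                    "voxel_id",
                    "participant_id",
                    "hemisphere_id",
                    "visual_field_map",
                    "eccentricity_deg",
                ]
            ],
            on="voxel_id",
        )
    )
    wide["difference"] = wide["tuned"] - wide["monotonic"]
    wide["range"] = np.where(
        wide.eccentricity_deg < near_max,
        "near",
        np.where(
            (wide.eccentricity_deg > far_min) & (wide.eccentricity_deg < far_max),
            "far",
            "other",
        ),
    )
    cells = (
        wide[wide["range"] != "other"]
        .groupby(
            ["participant_id", "hemisphere_id", "split", "visual_field_map", "range"],
            observed=True,
        )[["monotonic", "tuned", "difference"]]
        .mean()
        .reset_index()
    )
    out = {"cells": cells}
    for measure in ("monotonic", "tuned", "difference"):
        try:
            anova = anova_nfactor(
                cells.rename(columns={measure: "ve"}),
                "ve",
                ["participant_id", "visual_field_map", "range"],
                interactions=[("visual_field_map", "range")],
            )
        except ValueError:
            anova = None
        paired = cells.pivot_table(
            index=["participant_id", "hemisphere_id", "split", "visual_field_map"],
            columns="range",
            values=measure,
        ).dropna()
        rows = []
        maps = map_order or sorted(paired.index.get_level_values("visual_field_map").unique())
        for m in maps:
            if m not in paired.index.get_level_values("visual_field_map"):
                continue
            sub = paired.xs(m, level="visual_field_map")
            z, p = wilcoxon_signed_rank(sub["near"], sub["far"])
            rows.append(
                dict(
                    map=m,
                    n=len(sub),
                    mean_near=sub["near"].mean(),
                    mean_far=sub["far"].mean(),
                    Z=z,
                    effect_size_r=effect_size_r(z, len(sub)),
                    p=p,
                    bayes_factor=np.nan,
                )
            )
        table = pd.DataFrame(rows)
        if len(table):
            table["p_adj"] = fdr_bh(table.p.values)
        out[measure] = dict(anova=anova, table=table)
    return out
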