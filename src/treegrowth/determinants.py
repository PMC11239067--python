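"""Determinants of growth: standardized OLS, collinearity, group tests.

The response is the per-tree growth rate (in/yr). Continuous predictors are
standardized by subtracting the mean and dividing by *twice* the sample
standard deviation, which puts their coefficients on the same footing as
binary indicators (a 2-SD change is comparable to flipping an indicator).
Categorical predictors enter as treatment-coded indicators against declared
reference levels; the species factor keeps the ``top_k`` most abundant
species distinct and pools the rest into the reference level "other".

Collinearity is screened with the generalized variance inflation factor
(GVIF), the determinant-ratio construction that treats a multi-column
categorical term as one block; ``GVIF^(1/(2 df))`` is reported alongside so
terms of different dimension are comparable. For a single-column term the
GVIF reduces to the classical VIF ``1/(1 - R^2)``.

Group comparisons use a two-sample t-test for two levels and one-way ANOVA
with Tukey's HSD for three or more, summarized as a compact letter display
(levels sharing no letter differ at ``alpha``) built by the insert–absorb
algorithm.

The social-vulnerability analysis deliberately keeps SVI *out* of the model:
the model is refit without the borough factor, tree-level residuals are
averaged by zone, and the zone-mean residual is regressed on zone-mean SVI —
a positive slope means trees grow faster than the urban form predicts in more
vulnerable areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ModelSpec",
    "FitResult",
    "GroupComparison",
    "ResidualAnalysis",
    "standardize_2sd",
    "build_design",
    "fit_ols",
    "gvif",
    "group_compare",
    "compact_letter_display",
    "pearson_screen",
    "residuals_vs_svi",
]


@dataclass(frozen=True)
class ModelSpec:
    """What goes into the growth-rate OLS, and how.

    ``categorical`` maps factor column -> reference level (``None`` = first
    level alphabetically). SVI is never a model term; it is reserved for the
    residual comparison.
    """

    response: str = "rate_in_per_yr"
    species_col: str = "species_norm"
    species_reference: str = "other"
    top_k_species: int = 15
    categorical: dict = field(
        default_factory=lambda: {
            "health": None,
            "curb_loc": None,
            "steward": None,
            "guards": "Harmful",
            "sidewalk": None,
            "root_blocked": None,
            "trunk_altered": None,
            "branch_problems": None,
            "roadside_location": None,
            "land_use": None,
            "user_type": "NYC Parks Staff",
        }
    )
    continuous: tuple = ("dbh_in_05", "builtFAR", "pop_density", "st_width")
    borough_col: str = "borough"
    include_borough: bool = True

    def __post_init__(self) -> None:
        banned = {"svi", "SVI", "svi_vulnerability"}
        if set(self.continuous) & banned or set(self.categorical) & banned:
            raise ValueError("SVI must not be a model term")


def standardize_2sd(values) -> np.ndarray:
    """Center and scale by twice the sample SD: output has mean 0, SD 0.5."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / (2.0 * x.std(ddof=1))


def _species_factor(series: pd.Series, top_k: int, reference: str) -> pd.Series:
    top = series.value_counts().index[:top_k]
    return series.where(series.isin(top), reference)


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Assemble the standardized design matrix.

    Complete cases only. Returns ``(X, y, term_map)`` where ``X`` includes the
    intercept column ``const`` and ``term_map`` maps each model term to its
    design columns (for the GVIF block structure).
    """
    factors = dict(spec.categorical)
    if spec.include_borough and spec.borough_col in data.columns:
        factors[spec.borough_col] = None
    used_cols = (
        [spec.response, spec.species_col]
        + [c for c in factors if c in data.columns]
        + [c for c in spec.continuous if c in data.columns]
    )
    missing_cont = [c for c in spec.continuous if c not in data.columns]
    if missing_cont:
        raise KeyError(f"continuous terms absent from data: {missing_cont}")
    rows = data[used_cols].dropna()
    if len(rows) == 0:
        raise ValueError("no complete cases")

    X = pd.DataFrame(index=rows.index)
    term_map: dict[str, list[str]] = {}

    for col in spec.continuous:
        name = col
        X[name] = standardize_2sd(rows[col])
        term_map[col] = [name]

    species = _species_factor(
        rows[spec.species_col].astype(str), spec.top_k_species, spec.species_reference
    )
    if (species == spec.species_reference).sum() == 0:
        # no species fell into the pooled reference (fewer species than top_k):
        # use the most abundant species as the reference instead
        ref = species.value_counts().index[0]
        species = species.where(species != ref, spec.species_reference)
    levels = sorted(set(species) - {spec.species_reference})
    cols = []
    for lev in levels:
        name = f"species[{lev}]"
        X[name] = (species == lev).astype(float)
        cols.append(name)
    if cols:
        term_map["species"] = cols

    for factor, ref in factors.items():
        if factor not in rows.columns:
            continue
        vals = rows[factor].astype(str)
        lvls = sorted(vals.unique())
        if len(lvls) < 2:
            continue
        reference = ref if ref in lvls else lvls[0]
        cols = []
        for lev in lvls:
            if lev == reference:
                continue
            name = f"{factor}[{lev}]"
            X[name] = (vals == lev).astype(float)
            cols.append(name)
        term_map[factor] = cols

    constant = [c for c in X.columns if X[c].nunique() < 2]
    if constant:
        raise ValueError(f"constant design columns: {constant}")
    X.insert(0, "const", 1.0)
    y = rows[spec.response].astype(float)
    return X, y, term_map


@dataclass
class FitResult:
    """Standardized OLS output: effects, uncertainty, fit quality, GVIFs."""

    table: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p
    gvif_table: pd.DataFrame  # term, df, gvif, gvif_adj
    adj_r2: float
    rmse: float
    n_used: int
    residuals: pd.Series = field(repr=False)
    fitted: pd.Series = field(repr=False)
    term_map: dict = field(repr=False, default_factory=dict)


def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit the standardized growth-rate OLS with conventional inference."""
    X, y, term_map = build_design(data, spec)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.drop(columns="const").values, rowvar=False)
        raise ValueError(
            "design matrix is rank deficient "
            f"(rank {rank} < {X.shape[1]}); check collinear terms "
            f"(max |corr| = {np.abs(corr - np.eye(len(corr))).max():.3f})"
        )
    if len(y) <= X.shape[1]:
        raise ValueError("fewer rows than design columns")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.values,
            "se": res.bse.values,
            "ci_low": ci[0].values,
            "ci_high": ci[1].values,
            "p": res.pvalues.values,
        }
    )
    resid = pd.Series(res.resid, index=y.index, name="residual")
    rmse = float(np.sqrt(np.mean(res.resid**2)))
    gvif_table = gvif(X, term_map)
    return FitResult(
        table=table,
        gvif_table=gvif_table,
        adj_r2=float(res.rsquared_adj),
        rmse=rmse,
        n_used=int(res.nobs),
        residuals=resid,
        fitted=pd.Series(res.fittedvalues, index=y.index, name="fitted"),
        term_map=term_map,
    )


def gvif(X: pd.DataFrame, term_map: dict[str, list[str]]) -> pd.DataFrame:
    """Generalized VIF per term (determinant-ratio construction).

    ``X`` may include the intercept; it is excluded from the correlation
    matrix. For a one-column term this equals the classical ``1/(1 - R^2)``.
    """
    cols = [c for c in X.columns if c != "const"]
    R = np.atleast_2d(np.corrcoef(X[cols].values, rowvar=False))
    if np.linalg.matrix_rank(R) < len(cols):
        raise ValueError("singular correlation matrix; terms are collinear")
    det_R = np.linalg.det(R)
    idx = {c: i for i, c in enumerate(cols)}
    rows = []
    for term, members in term_map.items():
        i1 = [idx[c] for c in members]
        i2 = [i for i in range(len(cols)) if i not in i1]
        det1 = np.linalg.det(R[np.ix_(i1, i1)])
        det2 = np.linalg.det(R[np.ix_(i2, i2)]) if i2 else 1.0
        g = det1 * det2 / det_R
        df = len(i1)
        rows.append((term, df, g, g ** (1.0 / (2.0 * df))))
    return pd.DataFrame(rows, columns=["term", "df", "gvif", "gvif_adj"])


def compact_letter_display(
    levels: list[str], significant_pairs: list[tuple[str, str]]
) -> dict[str, str]:
    """Letters such that two levels share a letter iff they are *not* separated.

    Insert–absorb: start from one group of all levels; for every significant
    pair split each group containing both; absorb groups that became subsets
    of others. Letters are assigned to groups in a deterministic order.
    """
    groups: list[set] = [set(levels)]
    for a, b in significant_pairs:
        for grp in [g for g in groups if a in g and b in g]:
            groups.remove(grp)
            for child in (grp - {a}, grp - {b}):
                if child and not any(child <= g for g in groups):
                    groups.append(child)
            groups = [
                g
                for i, g in enumerate(groups)
                if not any(g < o or (g == o and i > j) for j, o in enumerate(groups) if j != i)
            ]
    groups.sort(key=lambda g: (min(g), -len(g)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lev: "" for lev in levels}
    for letter, grp in zip(alphabet, groups):
        for lev in grp:
            out[lev] += letter
    return {lev: "".join(sorted(s)) for lev, s in out.items()}


@dataclass
class GroupComparison:
    """Per-level summary plus the significance structure of one factor."""

    factor: str
    test: str  # "t-test" or "anova+tukey"
    alpha: float
    p_overall: float
    table: pd.DataFrame  # level, n, mean, q25, q75, letters


def group_compare(
    data: pd.DataFrame,
    factor: str,
    value_col: str = "rate_in_per_yr",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare mean rates across the levels of one categorical factor."""
    rows = data[[factor, value_col]].dropna()
    counts = rows[factor].value_counts()
    thin = counts[counts < 2].index.tolist()
    if thin:
        warnings.warn(f"levels with <2 observations excluded from {factor}: {thin}")
        rows = rows[~rows[factor].isin(thin)]
    levels = sorted(rows[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than two usable levels")
    samples = [rows.loc[rows[factor] == lev, value_col].values for lev in levels]

    if len(levels) == 2:
        test = "t-test"
        _, p = stats.ttest_ind(samples[0], samples[1])
        sig_pairs = [(levels[0], levels[1])] if p < alpha else []
        p_overall = float(p)
    else:
        test = "anova+tukey"
        _, p_overall = stats.f_oneway(*samples)
        hsd = pairwise_tukeyhsd(
            rows[value_col].values, rows[factor].values, alpha=alpha
        )
        pair_order = list(combinations(hsd.groupsunique, 2))
        sig_pairs = [
            (str(a), str(b)) for (a, b), rej in zip(pair_order, hsd.reject) if rej
        ]
        p_overall = float(p_overall)

    letters = compact_letter_display(levels, sig_pairs)
    table = pd.DataFrame(
        {
            "level": levels,
            "n": [len(s) for s in samples],
            "mean": [float(np.mean(s)) for s in samples],
            "q25": [float(np.percentile(s, 25)) for s in samples],
            "q75": [float(np.percentile(s, 75)) for s in samples],
            "letters": [letters[lev] for lev in levels],
        }
    )
    return GroupComparison(factor, test, alpha, p_overall, table)


def pearson_screen(
    data: pd.DataFrame,
    covariates: tuple = ("dbh_in_05", "builtFAR", "pop_density", "st_width"),
    value_col: str = "rate_in_per_yr",
) -> pd.DataFrame:
    """Pearson r (and p) of the growth rate against each continuous covariate."""
    rows = []
    for cov in covariates:
        sub = data[[value_col, cov]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 complete pairs for {cov!r}")
        if sub[cov].nunique() < 2:
            rows.append((cov, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(sub[value_col], sub[cov])
        rows.append((cov, float(r), float(p)))
    return pd.DataFrame(rows, columns=["parameter", "r", "p"])


@dataclass
class ResidualAnalysis:
    """Zone-level comparison of model residuals against social vulnerability."""

    slope: float
    intercept: float
    p_value: float
    zone_table: pd.DataFrame  # zone_id, n_trees, mean_residual, mean_svi
    tree_residuals: pd.Series = field(repr=False)
    n_zones: int = 0
    weighted: bool = False


def residuals_vs_svi(
    spec: ModelSpec,
    data: pd.DataFrame,
    zone_col: str = "zip",
    svi_col: str = "svi",
    min_n: int = 100,
    exclude: tuple = (),
    weighted: bool = False,
) -> ResidualAnalysis:
    """Regress zone-mean model residuals on zone-mean SVI.

    The model is refit *without* the borough factor (the arbitrary spatial
    correction would soak up exactly the geographic signal being probed).
    Zones with fewer than ``min_n`` trees or in ``exclude`` are dropped.
    """
    spec_nb = ModelSpec(
        response=spec.response,
        species_col=spec.species_col,
        species_reference=spec.species_reference,
        top_k_species=spec.top_k_species,
        categorical=dict(spec.categorical),
        continuous=spec.continuous,
        borough_col=spec.borough_col,
        include_borough=False,
    )
    fit = fit_ols(spec_nb, data)
    sub = data.loc[fit.residuals.index, [zone_col, svi_col]].copy()
    sub["residual"] = fit.residuals
    sub = sub.dropna(subset=[zone_col, svi_col])
    zone = (
        sub.groupby(zone_col)
        .agg(
            n_trees=("residual", "size"),
            mean_residual=("residual", "mean"),
            mean_svi=(svi_col, "mean"),
        )
        .reset_index()
        .rename(columns={zone_col: "zone_id"})
    )
    zone = zone[~zone["zone_id"].isin(exclude)]
    zone = zone[zone["n_trees"] >= min_n].reset_index(drop=True)
    if len(zone) < 3:
        raise ValueError("fewer than 3 zones survive the filters")
    X = sm.add_constant(zone["mean_svi"].values)
    if weighted:
        model = sm.WLS(zone["mean_residual"].values, X, weights=zone["n_trees"].values)
    else:
        model = sm.OLS(zone["mean_residual"].values, X)
    res = model.fit()
    return ResidualAnalysis(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        zone_table=zone,
        tree_residuals=fit.residuals,
        n_zones=len(zone),
        weighted=weighted,
    )
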