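"""Statistical layer: mixed ANCOVA, the 3 dB margin, survey ANOVA, CCA.

The acoustic features are compared with a linear mixed model — fixed
effects year x protection, a random intercept per location couplet, and
the moon-phase fraction as covariate — fit by REML, with type-II Wald
chi-square tests per fixed term: each term is tested after all other
terms of its order, with higher-order terms that contain it excluded.
Because the recording chains differ between years, a group difference in
level only counts as significant when it is both statistically significant
at alpha = 0.05 and larger than the 3 dB instrumentation error margin.

Community-composition analysis is a canonical correspondence analysis in
the ter Braak formulation: the chi-square-standardized community matrix is
regressed on the (row-weighted) constraining variables and the fitted
values are decomposed by SVD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

import statsmodels.formula.api as smf

__all__ = [
    "TermTest",
    "AncovaResult",
    "CcaResult",
    "EffectCall",
    "GroupDifferenceSummary",
    "fit_ancova",
    "fit_survey_anova",
    "apply_3db_rule",
    "run_cca",
    "summarize_group_differences",
]

ALPHA = 0.05
DB_MARGIN = 3.0


@dataclass
class TermTest:
    chi2: float
    df: int
    p: float


@dataclass
class AncovaResult:
    terms: dict[str, TermTest]
    location_variance: float
    residual_variance: float
    group_means: pd.Series
    converged: bool = True
    boundary_fit: bool = False

    def to_dict(self) -> dict:
        return {
            "terms": {
                k: {"chi2": t.chi2, "df": t.df, "p": t.p} for k, t in self.terms.items()
            },
            "location_variance": self.location_variance,
            "residual_variance": self.residual_variance,
            "group_means": {str(k): v for k, v in self.group_means.items()},
            "converged": self.converged,
            "boundary_fit": self.boundary_fit,
        }


@dataclass
class EffectCall:
    response: str
    difference_db: float
    p: float
    verdict: str
    margin_db: float = DB_MARGIN
    alpha: float = ALPHA

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "difference_db": self.difference_db,
            "p": self.p,
            "verdict": self.verdict,
            "margin_db": self.margin_db,
            "alpha": self.alpha,
        }


def _term_factors(term: str) -> frozenset[str]:
    return frozenset(term.split(":"))


def _term_patsy(term: str, data: pd.DataFrame) -> str:
    parts = []
    for f in term.split(":"):
        if data[f].dtype.kind in "OUSb" or isinstance(data[f].dtype, pd.CategoricalDtype):
            parts.append(f"C({f})")
        else:
            parts.append(f)
    return ":".join(parts)


def _fit_mixed(formula: str, data: pd.DataFrame, groups: pd.Series):
    """REML mixed-model fit with a boundary-tolerant fallback chain."""
    boundary = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data, groups=groups)
        res = None
        for method in ("bfgs", "powell", "lbfgs"):
            try:
                res = model.fit(reml=True, method=method)
            except Exception:
                continue
            if getattr(res, "converged", True):
                break
        if res is None:
            res = model.fit(reml=True, method="nm")
        for w in caught:
            if "boundary" in str(w.message).lower() or "singular" in str(w.message).lower():
                boundary = True
    return res, boundary


def _wald_for_slice(res, names: list[str]) -> TermTest:
    fe = res.fe_params
    idx = [list(fe.index).index(n) for n in names]
    beta = fe.values[idx]
    cov = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    # pinv guards exact-zero-variance degenerate fits
    stat = float(beta @ linalg.pinvh(cov) @ beta)
    df = len(idx)
    return TermTest(chi2=stat, df=df, p=float(chi2.sf(stat, df)))


def _column_names_for_term(res, data: pd.DataFrame, term: str) -> list[str]:
    design_info = res.model.data.design_info
    patsy_term = _term_patsy(term, data)
    for name, sl in design_info.term_name_slices.items():
        if name == patsy_term:
            return design_info.column_names[sl]
    raise KeyError(f"term {term!r} not found in the fitted design")


def fit_ancova(
    table: pd.DataFrame,
    response: str,
    fixed: tuple[str, ...] = ("protection", "year", "protection:year"),
    random: str = "location",
    covariate: str | None = "moon_phase",
) -> AncovaResult:
    """Linear mixed ANCOVA with a random intercept per `random` group.

    Fit by restricted maximum likelihood; each fixed term gets a type-II
    Wald chi-square: the model is refit without any term that contains the
    tested term (e.g. main effects are tested in the model without the
    interaction), and the term's coefficients are tested jointly in that
    fit. A boundary (zero random-variance) fit is reported, not raised.
    """
    data = table.dropna(subset=[response]).copy()
    terms = list(fixed) + ([covariate] if covariate else [])
    for t in terms:
        for f in _term_factors(t):
            if f not in data.columns:
                raise KeyError(f"column {f!r} missing from the feature table")
    factor_terms = [t for t in terms if ":" not in t and data[t].dtype.kind in "OUSb"]
    for t in factor_terms:
        if data[t].nunique() < 2:
            raise ValueError(f"fixed factor {t!r} needs >= 2 levels")
    if data[random].nunique() < 2:
        raise ValueError("need >= 2 random-effect groups")

    def formula_for(term_subset: list[str]) -> str:
        rhs = " + ".join(_term_patsy(t, data) for t in term_subset) or "1"
        return f"{response} ~ {rhs}"

    full_res, boundary = _fit_mixed(formula_for(terms), data, data[random])

    tests: dict[str, TermTest] = {}
    fit_cache = {formula_for(terms): full_res}
    for term in terms:
        tf = _term_factors(term)
        keep = [t for t in terms if t == term or not (_term_factors(t) > tf)]
        formula = formula_for(keep)
        if formula not in fit_cache:
            res, b2 = _fit_mixed(formula, data, data[random])
            boundary = boundary or b2
            fit_cache[formula] = res
        res = fit_cache[formula]
        names = _column_names_for_term(res, data, term)
        tests[term] = _wald_for_slice(res, names)

    group_cols = sorted({f for t in fixed for f in _term_factors(t)})
    group_means = data.groupby(group_cols, observed=True)[response].mean()
    try:
        loc_var = float(np.asarray(full_res.cov_re)[0, 0])
    except Exception:
        loc_var = float("nan")
    return AncovaResult(
        terms=tests,
        location_variance=loc_var,
        residual_variance=float(full_res.scale),
        group_means=group_means,
        converged=bool(getattr(full_res, "converged", True)),
        boundary_fit=boundary,
    )


_SURVEY_METRIC_ALIASES = {
    "abundance": "abundance",
    "richness": "richness",
    "coral": "coral_cover",
    "coral_cover": "coral_cover",
    "algae": "algae_cover",
    "algae_cover": "algae_cover",
}


def fit_survey_anova(
    survey: pd.DataFrame, metric: str, random: str = "location"
) -> TermTest:
    """Mixed one-factor comparison of a survey metric between MPA and nMPA.

    Same type-II Wald contract as :func:`fit_ancova` (with a single factor,
    type II coincides with the ordinary joint Wald test).
    """
    col = _SURVEY_METRIC_ALIASES.get(metric, metric)
    if col not in survey.columns:
        raise KeyError(f"survey metric {metric!r} not found")
    if survey["protection"].nunique() < 2:
        raise ValueError("need both protection groups")
    data = survey.rename(columns={col: "_metric"})
    res = fit_ancova(
        data, "_metric", fixed=("protection",), random=random, covariate=None
    )
    return res.terms["protection"]


def apply_3db_rule(
    difference_db: float,
    p: float,
    margin: float = DB_MARGIN,
    alpha: float = ALPHA,
    response: str = "",
) -> EffectCall:
    """Conjunction rule: significant iff p < alpha AND |difference| > margin.

    The margin (default |3| dB) absorbs the level error between the two
    recording chains, so a statistically significant but small level change
    is still called non-significant.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    verdict = "significant" if (p < alpha and abs(difference_db) > margin) else "non-significant"
    return EffectCall(
        response=response,
        difference_db=float(difference_db),
        p=float(p),
        verdict=verdict,
        margin_db=margin,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# canonical correspondence analysis (ter Braak)
# ---------------------------------------------------------------------------


@dataclass
class CcaResult:
    eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    dropped_sites: list = field(default_factory=list)
    dropped_taxa: list = field(default_factory=list)
    dropped_constraints: list = field(default_factory=list)

    @property
    def proportion_constrained(self) -> float:
        return float(self.eigenvalues.sum() / self.total_inertia)


def run_cca(
    community: pd.DataFrame | np.ndarray,
    constraints: pd.DataFrame | np.ndarray,
    *,
    tol: float = 1e-10,
) -> CcaResult:
    """Canonical correspondence analysis, ter Braak formulation.

    The community matrix (sites x taxa, non-negative counts or relative
    abundances) is converted to the chi-square-standardized residual matrix
    Q = D_r^{-1/2} (P - r c^T) D_c^{-1/2}; the constraints are centered and
    weighted by the site masses r, Q is projected onto their column space,
    and the fitted matrix is decomposed by SVD. Constrained eigenvalues are
    the squared singular values; residual (unconstrained) axes come from the
    complementary projection. All-zero site rows / taxon columns and aliased
    (collinear) constraint columns are dropped with a warning.
    """
    comm = pd.DataFrame(community).copy()
    cons = pd.DataFrame(constraints).copy()
    if comm.shape[0] != cons.shape[0]:
        raise ValueError("community and constraints must have matching site rows")
    Y = comm.to_numpy(dtype=float)
    if np.any(Y < 0):
        raise ValueError("community matrix must be non-negative")

    row_zero = Y.sum(axis=1) <= 0
    col_zero = Y.sum(axis=0) <= 0
    dropped_sites = list(comm.index[row_zero])
    dropped_taxa = list(comm.columns[col_zero])
    if dropped_sites or dropped_taxa:
        warnings.warn(
            f"dropping {len(dropped_sites)} all-zero site(s) and "
            f"{len(dropped_taxa)} all-zero taxon column(s)",
            stacklevel=2,
        )
    comm = comm.loc[~row_zero, ~col_zero]
    cons = cons.loc[~row_zero]
    Y = comm.to_numpy(dtype=float)
    X = cons.to_numpy(dtype=float)

    P = Y / Y.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    total_inertia = float((Q**2).sum())

    # weighted centering and row weighting of the constraints
    Xc = X - r @ X
    Xw = np.sqrt(r)[:, None] * Xc

    # drop aliased columns via pivoted QR
    q_, r_, piv = linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r_))
    rank = int(np.sum(diag > max(diag.max(), 1.0) * max(Xw.shape) * np.finfo(float).eps * 10)) if diag.size else 0
    keep = sorted(piv[:rank])
    dropped_constraints = [cons.columns[i] for i in range(X.shape[1]) if i not in keep]
    if dropped_constraints:
        warnings.warn(
            f"dropping aliased constraint column(s): {dropped_constraints}", stacklevel=2
        )
    Xw = Xw[:, keep]

    # project Q onto the constraint space
    beta, *_ = linalg.lstsq(Xw, Q)
    Qfit = Xw @ beta
    u, s, vt = linalg.svd(Qfit, full_matrices=False)
    pos = s**2 > tol
    n_axes = min(int(pos.sum()), Xw.shape[1])
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    eigenvalues = s**2

    ru, rs, _ = linalg.svd(Q - Qfit, full_matrices=False)
    unconstrained = rs[rs**2 > tol] ** 2

    # scores: sites (linear-combination) and species in chi-square space
    site_scores = u / np.sqrt(r)[:, None]
    species_scores = (vt.T / np.sqrt(c)[:, None]) * s
    axes = [f"CCA{i+1}" for i in range(n_axes)]
    site_df = pd.DataFrame(site_scores, index=comm.index, columns=axes)
    spec_df = pd.DataFrame(species_scores, index=comm.columns, columns=axes)

    # biplot arrows: weighted correlation of the constraints with site scores
    Xk = Xc[:, keep]
    wstd = np.sqrt(np.sum(r[:, None] * Xk**2, axis=0))
    wstd[wstd == 0] = 1.0
    site_w = u  # already orthonormal in the weighted metric
    bip = (np.sqrt(r)[:, None] * (Xk / wstd)).T @ site_w
    bip_df = pd.DataFrame(bip, index=[cons.columns[i] for i in keep], columns=axes)

    return CcaResult(
        eigenvalues=eigenvalues,
        unconstrained_eigenvalues=unconstrained,
        total_inertia=total_inertia,
        site_scores=site_df,
        species_scores=spec_df,
        biplot_scores=bip_df,
        dropped_sites=dropped_sites,
        dropped_taxa=dropped_taxa,
        dropped_constraints=dropped_constraints,
    )


# ---------------------------------------------------------------------------
# group-difference summaries
# ---------------------------------------------------------------------------


@dataclass
class GroupDifferenceSummary:
    """Per-cell dB means with Jensen audits, and per-unit differences."""

    cell_table: pd.DataFrame
    differences: pd.DataFrame
    overall_difference: float
    contrast: tuple[str, str]


def summarize_group_differences(
    table: pd.DataFrame,
    value_col: str,
    contrast_col: str,
    by: tuple[str, ...] = ("site",),
) -> GroupDifferenceSummary:
    """Arithmetic dB means per cell with the linear-vs-dB averaging audit.

    ``contrast_col`` must have exactly two levels; the reported difference
    is mean(level 2) - mean(level 1) with levels in sorted order, per ``by``
    cell and overall (grand mean of cell means per level). Empty cells are
    simply absent from the output.
    """
    from reefpam.spectral import average_db_audit

    levels = sorted(table[contrast_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{contrast_col!r} must have exactly 2 levels, got {levels}")
    grouped = table.groupby([*by, contrast_col], observed=True)[value_col]
    cells = grouped.agg(
        mean_db="mean",
        delta_audit_db=average_db_audit,
        n="count",
    ).reset_index()
    wide = cells.pivot_table(index=list(by), columns=contrast_col, values="mean_db")
    wide = wide.dropna()
    diffs = (wide[levels[1]] - wide[levels[0]]).rename("difference_db").reset_index()
    overall = float(
        cells.groupby(contrast_col, observed=True)["mean_db"].mean().loc[levels[1]]
        - cells.groupby(contrast_col, observed=True)["mean_db"].mean().loc[levels[0]]
    )
    return GroupDifferenceSummary(
        cell_table=cells,
        differences=diffs,
        overall_difference=overall,
        contrast=(str(levels[0]), str(levels[1])),
    )
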