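"""Group-comparison statistics for cohort tables.

Multivariate responses (wave amplitudes/latencies, audiogram thresholds, DN1
series) are analysed with linear mixed-effects models: sex, genotype, litter
and condition (wave, frequency or ITD) as fixed effects and animal as a
random intercept, fitted by REML.  Pairwise group comparisons use estimated
marginal means (model-adjusted cell means averaged over nuisance factors)
with Tukey adjustment within a contrast family; morphological measures use
two-way ANOVA (sex x genotype) with Tukey post hoc tests.

Degrees of freedom for marginal-mean contrasts are between-within style:
``df = n_animals - rank(animal-level fixed design)``, which is exact for
between-animal contrasts in balanced designs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
from scipy import stats as spstats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DEFAULT_FIXED = "sex * genotype * condition + litter"


def significance_stars(p: float) -> str:
    """Reporting tiers: * p<0.05, ** p<0.01, *** p<0.0001."""
    if p < 1e-4:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    aliased = []
    r_prev = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == r_prev:
            aliased.append(names[j])
        r_prev = r
    raise ValueError(
        "rank-deficient fixed-effects design; aliased terms: "
        + ", ".join(aliased)
    )


@dataclass
class MixedFit:
    """A fitted mixed model plus the metadata contrasts need."""

    result: "sm.regression.mixed_linear_model.MixedLMResults"
    formula: str
    data: pd.DataFrame
    group: str
    factors: Dict[str, List[str]]  # categorical factor -> levels
    singular: bool
    df_between: float
    converged: bool

    @property
    def params(self) -> pd.Series:
        return self.result.fe_params

    def summary(self):
        return self.result.summary()

    @property
    def random_intercept_var(self) -> float:
        return float(np.asarray(self.result.cov_re).ravel()[0])


def fit_mixed_model(table: pd.DataFrame, response: str,
                    fixed: str = DEFAULT_FIXED,
                    group: str = "animal") -> MixedFit:
    """Fit ``response ~ fixed`` with a random intercept per ``group``.

    Raises on rank-deficient designs (naming the aliased terms).  A
    boundary fit with a near-zero random-intercept variance is flagged as
    ``singular``, not hidden.
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    data = table.dropna(subset=[response]).copy()
    formula = f"{response} ~ {fixed}"
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    _check_full_rank(X.values, list(X.columns))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[group])
        result = None
        for method in (None, "lbfgs", "powell"):
            kw = {} if method is None else {"method": method}
            try:
                candidate = model.fit(reml=True, **kw)
            except Exception:  # noqa: BLE001 - try the next optimizer
                continue
            result = candidate
            if getattr(candidate, "converged", True):
                break
        if result is None:
            raise RuntimeError("mixed-model optimization failed outright")

    # between-animal df: animals minus the rank of the animal-averaged design
    groups = data[group].to_numpy()
    Xv = X.to_numpy()
    uniq = pd.unique(groups)
    Xbar = np.vstack([Xv[groups == g].mean(axis=0) for g in uniq])
    df_between = float(len(uniq) - np.linalg.matrix_rank(Xbar))

    # boundary (singular) fit: intercept SD below 1% of the residual SD
    # (the optimizer stops slightly off an exact-zero boundary)
    resid_var = float(result.scale)
    re_var = float(np.asarray(result.cov_re).ravel()[0])
    singular = re_var < 1e-4 * max(resid_var, 1e-300)

    factors = {
        c: sorted(map(str, data[c].unique()))
        for c in data.columns
        if c in formula and (data[c].dtype == object or str(data[c].dtype) == "category")
    }
    return MixedFit(
        result=result,
        formula=formula,
        data=data,
        group=group,
        factors=factors,
        singular=singular,
        df_between=df_between,
        converged=bool(getattr(result, "converged", True)),
    )


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise marginal-mean contrast."""

    contrast: str
    by: Tuple[Tuple[str, str], ...]  # ((factor, level), ...)
    estimate: float
    se: float
    df: float
    t: float
    p_raw: float
    p_adjusted: float
    adjust: str

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted)


def _reference_grid(fit: MixedFit, at: Mapping[str, str]) -> pd.DataFrame:
    """All combinations of factor levels, with ``at`` factors pinned."""
    cols = {}
    for fac, levels in fit.factors.items():
        cols[fac] = [str(at[fac])] if fac in at else levels
    combos = list(product(*cols.values()))
    grid = pd.DataFrame(combos, columns=list(cols.keys()))
    # numeric covariates (if any) held at their mean
    for c in fit.data.columns:
        if c not in grid.columns and c in fit.formula and \
                pd.api.types.is_numeric_dtype(fit.data[c]):
            grid[c] = float(fit.data[c].mean())
    return grid


def _emmean_vector(fit: MixedFit, grid: pd.DataFrame,
                   cell: Mapping[str, str]) -> np.ndarray:
    """Design-row vector of the marginal mean for ``cell`` (equal weights)."""
    mask = np.ones(len(grid), dtype=bool)
    for fac, level in cell.items():
        mask &= grid[fac].astype(str) == str(level)
    if not mask.any():
        raise ValueError(f"no reference-grid rows for cell {dict(cell)}")
    design_info = fit.result.model.data.design_info
    (X,) = patsy.build_design_matrices([design_info], grid[mask])
    return np.asarray(X).mean(axis=0)


def emmeans(fit: MixedFit, factors: Sequence[str],
            at: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Estimated marginal means over the levels of ``factors``."""
    at = dict(at or {})
    grid = _reference_grid(fit, at)
    beta = fit.params.to_numpy()
    V = fit.result.cov_params().to_numpy()[: beta.size, : beta.size]
    rows = []
    levels = [sorted(grid[f].astype(str).unique()) for f in factors]
    for combo in product(*levels):
        cell = dict(zip(factors, combo))
        c = _emmean_vector(fit, grid, cell)
        est = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        rows.append({**cell, "emmean": est, "se": se})
    return pd.DataFrame(rows)


def pairwise_emmeans(fit: MixedFit, factor: str,
                     by: Sequence[str] = (),
                     at: Optional[Mapping[str, str]] = None,
                     adjust: str = "tukey") -> List[ContrastResult]:
    """All pairwise contrasts of ``factor`` marginal means, within ``by`` cells.

    ``at`` pins additional factors (e.g. ``{"condition": "IV"}``).  Raw and
    Tukey-adjusted p-values are both reported; the Tukey p uses the
    studentized range over the ``factor`` level count with between-animal df.
    """
    if not fit.converged:
        raise RuntimeError("mixed model did not converge; contrasts unavailable")
    if factor not in fit.factors:
        raise ValueError(f"{factor!r} is not a categorical factor of the model")
    at = dict(at or {})
    grid = _reference_grid(fit, at)
    beta = fit.params.to_numpy()
    V = fit.result.cov_params().to_numpy()[: beta.size, : beta.size]
    df = max(fit.df_between, 1.0)

    by_levels = [sorted(grid[b].astype(str).unique()) for b in by]
    results: List[ContrastResult] = []
    for by_combo in product(*by_levels) if by else [()]:
        by_cell = dict(zip(by, by_combo))
        levels = sorted(grid[factor].astype(str).unique())
        k = len(levels)
        vectors = {
            lv: _emmean_vector(fit, grid, {**by_cell, factor: lv})
            for lv in levels
        }
        for a, b in combinations(levels, 2):
            c = vectors[b] - vectors[a]
            est = float(c @ beta)
            se = float(np.sqrt(c @ V @ c))
            tval = est / se if se > 0 else np.inf * np.sign(est)
            p_raw = 2.0 * float(spstats.t.sf(abs(tval), df))
            if adjust == "tukey" and k > 2:
                p_adj = float(
                    spstats.studentized_range.sf(abs(tval) * np.sqrt(2.0), k, df)
                )
            elif adjust == "bonferroni":
                p_adj = min(1.0, p_raw * (k * (k - 1) // 2))
            else:  # 'none' or two levels
                p_adj = p_raw
            results.append(
                ContrastResult(
                    contrast=f"{b} - {a} [{factor}]",
                    by=tuple(sorted(by_cell.items())),
                    estimate=est,
                    se=se,
                    df=df,
                    t=tval,
                    p_raw=p_raw,
                    p_adjusted=p_adj,
                    adjust=adjust if k > 2 or adjust != "tukey" else "none",
                )
            )
    return results


def contrasts_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"contrast": r.contrast}
        row.update({f"by_{f}": lv for f, lv in r.by})
        row.update({
            "estimate": r.estimate, "se": r.se, "df": r.df, "t": r.t,
            "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
            "adjust": r.adjust, "stars": r.stars,
        })
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus Tukey post hoc comparisons."""

    table: pd.DataFrame
    tukey: Dict[str, pd.DataFrame] = field(default_factory=dict)


def anova_two_way(data: pd.DataFrame, response: str,
                  factors: Tuple[str, str] = ("sex", "genotype"),
                  posthoc: bool = True) -> AnovaResult:
    """Two-way ANOVA with interaction and Tukey-adjusted post hoc contrasts.

    Requires at least two observations in every ``factors`` cell; empty cells
    raise an explicit error.  ``posthoc=False`` skips the Tukey tables (e.g.
    inside permutation loops).
    """
    fa, fb = factors
    data = data.dropna(subset=[response, fa, fb])
    counts = data.groupby([fa, fb], observed=True).size()
    full = set(product(data[fa].unique(), data[fb].unique()))
    empty = full - set(counts.index)
    if empty:
        raise ValueError(f"empty design cells: {sorted(empty)}")
    if (counts < 2).any():
        thin = counts[counts < 2].index.tolist()
        raise ValueError(f"cells with fewer than two observations: {thin}")
    formula = f"{response} ~ C({fa}) * C({fb})"
    fit = smf.ols(formula, data).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    tukey: Dict[str, pd.DataFrame] = {}
    if not posthoc:
        return AnovaResult(table=table, tukey=tukey)
    for fac in factors:
        if data[fac].nunique() < 2:
            continue
        res = pairwise_tukeyhsd(data[response], data[fac])
        tukey[fac] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    cells = data[fa].astype(str) + ":" + data[fb].astype(str)
    if cells.nunique() > 1:
        res = pairwise_tukeyhsd(data[response], cells)
        tukey[f"{fa}x{fb}"] = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return AnovaResult(table=table, tukey=tukey)
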