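"""Statistical comparisons used by the pipeline.

Covers the contingency analysis of interval-modulated neuron counts
(Pearson chi-square without continuity correction), the paired
shuffled-versus-real decoder comparison (Wilcoxon signed rank plus Cohen's
d), and mixed/generalized linear model fits with post hoc estimated
marginal means under Tukey's family-wise adjustment.

Model fitting delegates to statsmodels: gaussian outcomes with random
effects use a linear mixed model with the first random-effect factor as the
grouping variable; Poisson outcomes use a GLM, with cluster-robust
covariance over the first random-effect factor when one is declared (a
pragmatic stand-in for a Poisson GLMM, adequate for the Wald tests reported
here).  Per-term tests are large-sample Wald statistics reported as
F = W/df_num with a chi-square reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps

from .exceptions import DegenerateDataError, ValidationError


# ---------------------------------------------------------------------------
# Contingency analysis
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    """2x2 counts: rows are areas, columns are modulated / not modulated."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("MFC", "DMS")
    col_labels: tuple[str, str] = ("modulated", "not_modulated")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2):
            raise ValidationError("contingency table must be 2x2")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValidationError("counts must be nonnegative with positive total")


def chi_square_2x2(table: ContingencyTable2x2 | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (statistic, df=1, p)."""
    counts = table.counts if isinstance(table, ContingencyTable2x2) else np.asarray(table, float)
    if counts.shape != (2, 2):
        raise ValidationError("chi_square_2x2 requires a 2x2 table")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateDataError("chi-square undefined: a margin is zero")
    expected = np.outer(row, col) / n
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, 1, float(sps.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# Paired rank test with effect size
# ---------------------------------------------------------------------------

@dataclass
class SignedRankResult:
    statistic: float
    p_value: float
    cohens_d: float
    d_capped: bool = False
    n: int = 0


def signed_rank_and_d(x, y, alternative: str = "two-sided") -> SignedRankResult:
    """Wilcoxon signed-rank test on paired samples plus Cohen's d of x - y.

    Zero differences are dropped (Wilcoxon convention), ties get mid-ranks,
    and the normal approximation is used beyond n = 25 pairs.  A constant
    nonzero difference has undefined d (zero SD); it is reported as signed
    infinity with ``d_capped`` set.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValidationError("paired samples must have equal length >= 5")
    d = x - y
    if np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    sd = d.std(ddof=1)
    if sd == 0:
        cohens_d, capped = math.copysign(math.inf, d.mean()), True
    else:
        cohens_d, capped = float(d.mean() / sd), False
    nonzero = d[d != 0]
    method = "exact" if (nonzero.size <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size) else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative=alternative, method=method)
    return SignedRankResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        cohens_d=cohens_d,
        d_capped=capped,
        n=int(nonzero.size),
    )


# ---------------------------------------------------------------------------
# (Generalized) linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative model specification.

    ``predictors`` are formula terms (use ``C(col)`` for categoricals and
    ``*`` for interactions inside a term string).  ``random_effects`` lists
    grouping columns; the first is used as the mixed-model grouping factor.
    ``offset`` optionally names an exposure column (seconds) for Poisson
    rates.
    """

    outcome: str
    predictors: list[str]
    random_effects: list[str] = field(default_factory=list)
    family: str = "gaussian"
    offset: str | None = None

    def validate(self) -> None:
        if self.outcome in self.predictors:
            raise ValidationError("outcome cannot appear among predictors")
        if self.family not in ("gaussian", "poisson"):
            raise ValidationError(f"unknown family {self.family!r}")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.predictors) if self.predictors else "1"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class FitModelResult:
    spec: ModelSpec
    kind: str  # "ols", "mixedlm", or "glm"
    result: object
    params: pd.Series
    cov_params: pd.DataFrame
    term_tests: pd.DataFrame
    random_effect_variance: float | None
    data: pd.DataFrame
    design_info: object
    singular: bool = False
    df_resid: float = np.inf

    def summary(self) -> str:
        lines = [
            f"Model: {self.spec.formula}  [{self.kind}, family={self.spec.family}]",
            f"Random effects: {self.spec.random_effects or 'none'}"
            + (f"  (group variance {self.random_effect_variance:.4g})"
               if self.random_effect_variance is not None else ""),
            "",
            self.term_tests.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.singular:
            lines.append("WARNING: singular mixed fit; fixed-effects-only fallback was used")
        return "\n".join(lines)


def _term_wald_tests(params, cov, design_info, df_resid=np.inf) -> pd.DataFrame:
    """Large-sample Wald test per formula term (Intercept skipped)."""
    rows = []
    names = list(design_info.column_names)
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = [names.index(c) for c in names[sl]]
        b = np.asarray(params)[idx]
        V = np.asarray(cov)[np.ix_(idx, idx)]
        r = len(idx)
        try:
            w = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            w = float(b @ np.linalg.pinv(V) @ b)
        f = w / r
        p = float(sps.chi2.sf(w, r))
        rows.append({"term": term, "F": f, "df_num": r, "p": p})
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "p"])


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitModelResult:
    """Fit the declared model; returns estimates, per-term Wald tests, variances.

    Deterministic given the data (fixed optimizer settings).  A singular
    mixed fit falls back to fixed effects only, with a warning recorded on
    the result.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    spec.validate()
    for col in [spec.outcome] + spec.random_effects + ([spec.offset] if spec.offset else []):
        if col not in data.columns:
            raise ValidationError(f"data is missing column {col!r}")
    for g in spec.random_effects:
        if data[g].nunique() < 2:
            raise ValidationError(f"grouping factor {g!r} needs >= 2 levels")

    singular = False
    re_var: float | None = None
    if spec.family == "gaussian":
        if spec.random_effects:
            group = spec.random_effects[0]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(spec.formula, data, groups=data[group])
                    res = model.fit(reml=True)
                if not np.all(np.isfinite(np.asarray(res.bse_fe))):
                    raise np.linalg.LinAlgError("non-finite standard errors")
                kind = "mixedlm"
                params = res.fe_params
                k = len(params)
                cov = pd.DataFrame(
                    np.asarray(res.cov_params())[:k, :k], index=params.index, columns=params.index
                )
                re_var = float(np.asarray(res.cov_re).ravel()[0])
                df_resid = float(res.df_resid)
            except (np.linalg.LinAlgError, ValueError):
                warnings.warn("singular mixed fit; falling back to fixed effects only")
                singular = True
                res = smf.ols(spec.formula, data).fit()
                kind = "ols"
                params = res.params
                cov = res.cov_params()
                df_resid = float(res.df_resid)
        else:
            res = smf.ols(spec.formula, data).fit()
            kind = "ols"
            params = res.params
            cov = res.cov_params()
            df_resid = float(res.df_resid)
        design_info = res.model.data.design_info
    else:
        kwargs = {}
        if spec.offset is not None:
            kwargs["exposure"] = np.asarray(data[spec.offset], float)
        model = smf.glm(spec.formula, data, family=sm.families.Poisson(), **kwargs)
        if spec.random_effects:
            groups = data[spec.random_effects[0]]
            res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
        else:
            res = model.fit()
        kind = "glm"
        params = res.params
        cov = res.cov_params()
        df_resid = float(res.df_resid)
        design_info = res.model.data.design_info

    term_tests = _term_wald_tests(params, cov, design_info, df_resid)
    return FitModelResult(
        spec=spec,
        kind=kind,
        result=res,
        params=pd.Series(np.asarray(params), index=list(params.index)),
        cov_params=pd.DataFrame(np.asarray(cov), index=list(params.index), columns=list(params.index)),
        term_tests=term_tests,
        random_effect_variance=re_var,
        data=data,
        design_info=design_info,
        singular=singular,
        df_resid=df_resid,
    )


def posthoc_marginal_means(
    fit: FitModelResult, factor: str, method: str = "tukey"
) -> pd.DataFrame:
    """Pairwise contrasts of estimated marginal means for ``factor``.

    Marginal means are model predictions (link scale) with the factor column
    set to each level in turn, averaged over the observed covariate
    distribution.  P-values use Tukey's studentized-range adjustment over
    the level family (for two levels this equals the unadjusted test).
    """
    if method != "tukey":
        raise ValueError("only Tukey's method is implemented")
    if factor not in fit.data.columns:
        raise ValidationError(f"factor {factor!r} not in the model data")
    levels = sorted(pd.unique(fit.data[factor]))
    if len(levels) < 2:
        raise ValidationError(f"factor {factor!r} has a single level")

    rows_x = {}
    for lev in levels:
        new = fit.data.copy()
        new[factor] = lev
        dm = patsy.build_design_matrices([fit.design_info], new)[0]
        rows_x[lev] = np.asarray(dm).mean(axis=0)

    b = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    k = len(levels)
    df = fit.df_resid if np.isfinite(fit.df_resid) and fit.df_resid > 2 else 1e6
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            c = rows_x[levels[i]] - rows_x[levels[j]]
            est = float(c @ b)
            se = float(np.sqrt(c @ V @ c))
            t = est / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            out.append(
                {
                    "contrast": f"{levels[i]} - {levels[j]}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_adj": min(1.0, p),
                }
            )
    return pd.DataFrame(out, columns=["contrast", "estimate", "se", "t", "p_adj"])


# ---------------------------------------------------------------------------
# Named model specifications for the pipeline's standard analyses
# ---------------------------------------------------------------------------

MODEL_SPECS = {
    # response time vs temporal context (one- vs two-interval sessions), FI12 only
    "response_context": ModelSpec(
        outcome="response_time", predictors=["C(context)"], random_effects=["animal_id"]
    ),
    # response time across days of two-interval performance
    "response_day": ModelSpec(
        outcome="response_time", predictors=["C(day)"], random_effects=["animal_id"]
    ),
    # ramping strength vs context and area
    "pc1_context_area": ModelSpec(
        outcome="abs_score",
        predictors=["C(context) * C(area)"],
        random_effects=["animal_id"],
    ),
    # trial-by-trial firing rate binned at 0.1 s
    "firing_trialwise": ModelSpec(
        outcome="count",
        predictors=["time", "C(area)", "time:C(area)"],
        random_effects=["unit_id"],
        family="poisson",
        offset="exposure",
    ),
    # |slope| vs interval and day
    "slope_interval": ModelSpec(
        outcome="abs_slope",
        predictors=["C(interval_type)", "C(day)"],
        random_effects=["unit_id"],
    ),
}


def model_spec(name: str) -> ModelSpec:
    """A fresh copy of a named standard model specification."""
    spec = MODEL_SPECS[name]
    return ModelSpec(
        outcome=spec.outcome,
        predictors=list(spec.predictors),
        random_effects=list(spec.random_effects),
        family=spec.family,
        offset=spec.offset,
    )
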