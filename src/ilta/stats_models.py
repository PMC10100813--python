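"""The statistical battery for leaf-trait and herbivory analysis.

Univariate: Shapiro-Wilk normality screening, Mann-Whitney two-sample
comparisons (the W reported is the first-sample U with ½-weighting of
ties), and Kruskal-Wallis with a Fisher-LSD-on-mean-ranks post hoc
summarised as a compact letter display (groups sharing a letter are not
significantly different).

Multivariate: correlation-matrix PCA of the five quantitative leaf traits
(LM_A, leaf size, width, length, length/width ratio) with per-axis variable
contributions, and a generalized-linear-model suite.  The trait and damage
models use a Gamma error with identity link (responses are positive and
effects are read additively on the original scale); the damage
presence/absence model is binomial with logit link.  Model selection is
greedy bidirectional stepwise on AIC; term significance comes from type-II
likelihood-ratio ANOVA; explanatory power is Nagelkerke's R² (Tjur's R²
additionally for binomial models).

Single-model fitting is delegated to statsmodels; the selection loop, the
type-II table, the R² measures, the post-hoc letters and the W convention
are authored here.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "mann_whitney",
    "shapiro_wilk",
    "kruskal_letters",
    "PCAResult",
    "pca_traits",
    "ModelFormula",
    "ModelResult",
    "fit_glm",
    "stepwise_aic",
    "anova_type2",
    "r2_measures",
]


def mann_whitney(x, y) -> dict[str, float]:
    """Mann-Whitney test with the first-sample W convention.

    ``W = #{(i, j): x_i > y_j} + ½ #{ties}`` — the U statistic of the
    first sample, computed via rank sums.  The two-sided p-value follows
    the usual exact/normal-approximation switch (exact for small untied
    samples, tie-corrected normal otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    return {"W": float(res.statistic), "p": float(res.pvalue)}


def shapiro_wilk(x) -> dict[str, float]:
    """Shapiro-Wilk normality test (3 <= n <= 5000, non-constant input)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = scipy.stats.shapiro(x)
    return {"W": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Kruskal-Wallis post hoc with compact letter display


def kruskal_letters(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis post hoc with Fisher-LSD comparisons on mean ranks.

    All observations are ranked jointly (midranks for ties).  Pairs of
    groups are compared by the t-type criterion on mean-rank differences
    with the pooled rank variance adjusted by the Kruskal-Wallis statistic;
    letters are then assigned by the standard sweep over groups sorted by
    mean rank, such that two groups share a letter iff their pairwise
    difference is non-significant at ``alpha``.

    Returns a frame indexed by group with columns ``n``, ``mean_rank`` and
    ``letters``.  Empty groups are dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("at least two groups are required")

    big_n = values.size
    ranks = scipy.stats.rankdata(values)
    stats_rows = {
        lab: (int((groups == lab).sum()),
              float(ranks[groups == lab].mean()))
        for lab in labels
    }
    # Kruskal-Wallis H (tie-corrected) for the variance adjustment
    h_stat = scipy.stats.kruskal(
        *[values[groups == lab] for lab in labels]
    ).statistic
    # pooled variance of the joint ranks
    s2 = (np.sum(ranks**2) - big_n * (big_n + 1) ** 2 / 4) / (big_n - 1)
    k = len(labels)
    df = big_n - k
    t_crit = scipy.stats.t.ppf(1 - alpha / 2, df)

    def differ(a: str, b: str) -> bool:
        n_a, r_a = stats_rows[a]
        n_b, r_b = stats_rows[b]
        se = np.sqrt(
            s2 * ((big_n - 1 - h_stat) / df) * (1 / n_a + 1 / n_b)
        )
        if se == 0:
            return False
        return abs(r_a - r_b) > t_crit * se

    ordered = sorted(labels, key=lambda lab: stats_rows[lab][1])
    # maximal runs (in mean-rank order) of mutually non-different groups,
    # one letter per run that is not contained in an earlier run
    intervals: list[tuple[int, int]] = []
    for i in range(len(ordered)):
        j = i
        while j + 1 < len(ordered) and not any(
            differ(ordered[m], ordered[j + 1]) for m in range(i, j + 1)
        ):
            j += 1
        if not intervals or j > intervals[-1][1]:
            intervals.append((i, j))
    letters = {lab: "" for lab in ordered}
    for letter, (i, j) in zip(string.ascii_lowercase, intervals):
        for m in range(i, j + 1):
            letters[ordered[m]] += letter

    out = pd.DataFrame(
        {
            "n": [stats_rows[lab][0] for lab in ordered],
            "mean_rank": [stats_rows[lab][1] for lab in ordered],
            "letters": [letters[lab] for lab in ordered],
        },
        index=pd.Index(ordered, name="group"),
    )
    out.attrs["H"] = float(h_stat)
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# PCA on the five quantitative traits


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # percent, sums to 100
    scores: pd.DataFrame
    loadings: pd.DataFrame          # variables x axes
    contributions: pd.DataFrame     # percent, each axis sums to 100


TRAIT_COLUMNS = (
    "lma_gm2", "leaf_area_mm2", "leaf_width_mm", "leaf_length_mm",
    "length_width_ratio",
)


def pca_traits(data: pd.DataFrame, columns=TRAIT_COLUMNS) -> PCAResult:
    """Correlation-matrix PCA of quantitative leaf traits.

    Variables are centred and scaled to unit variance, so eigenvalues sum
    to the number of variables.  The contribution of variable v to axis k
    is ``100 · loading²(v, k) / Σ_v loading²(v, k)`` — the share of the
    axis carried by that variable.  Requires complete cases and at least
    6 rows; a constant column is rejected by name.
    """
    frame = data.loc[:, list(columns)].astype(float)
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"PCA requires complete cases; NAs in {bad}")
    if len(frame) < 6:
        raise ValueError(f"PCA requires at least 6 rows, got {len(frame)}")
    sd = frame.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s): {constant}")

    z = (frame - frame.mean()) / sd
    n = len(z)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    var_explained = 100.0 * eigenvalues / eigenvalues.sum()
    axes = [f"PC{k + 1}" for k in range(len(eigenvalues))]
    loadings = pd.DataFrame(vt.T, index=frame.columns, columns=axes)
    scores = pd.DataFrame(u * s, index=frame.index, columns=axes)
    sq = loadings**2
    contributions = 100.0 * sq / sq.sum(axis=0)
    return PCAResult(
        eigenvalues=eigenvalues,
        variance_explained=var_explained,
        scores=scores,
        loadings=loadings,
        contributions=contributions,
    )


# ---------------------------------------------------------------------------
# GLM suite


@dataclass(frozen=True)
class ModelFormula:
    """A GLM specification: ``response ~ term + term`` plus a family flag
    (``gamma_identity`` or ``binomial_logit``)."""

    response: str
    terms: tuple[str, ...]
    family: str = "gamma_identity"

    def __post_init__(self):
        if self.family not in ("gamma_identity", "binomial_logit"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def without(self, term: str) -> "ModelFormula":
        return ModelFormula(
            self.response,
            tuple(t for t in self.terms if t != term),
            self.family,
        )

    def adding(self, term: str) -> "ModelFormula":
        return ModelFormula(
            self.response, (*self.terms, term), self.family,
        )

    @classmethod
    def parse(cls, text: str, family: str = "gamma_identity") -> "ModelFormula":
        lhs, rhs = text.split("~")
        terms = tuple(
            t.strip() for t in rhs.split("+") if t.strip() and t.strip() != "1"
        )
        return cls(lhs.strip(), terms, family)


@dataclass
class ModelResult:
    formula: ModelFormula
    fitted: object                      # statsmodels GLMResults
    coefficients: pd.Series = field(init=False)
    loglik: float = field(init=False)
    aic: float = field(init=False)
    selection_trace: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        self.coefficients = self.fitted.params
        self.loglik = float(self.fitted.llf)
        self.aic = float(self.fitted.aic)


def _family(name: str):
    if name == "gamma_identity":
        return sm.families.Gamma(link=sm.families.links.Identity())
    return sm.families.Binomial(link=sm.families.links.Logit())


def fit_glm(f: ModelFormula, data: pd.DataFrame) -> ModelResult:
    """Fit one GLM by IRLS.

    Gamma/identity fits start from an OLS solution clipped to positive
    fitted means (statsmodels' default starting values already guarantee
    a valid identity-link start for positive responses); binomial models
    with complete separation converge to the boundary with a warning from
    the backend rather than an error.
    """
    y = data[f.response]
    if y.dropna().empty:
        raise ValueError(
            f"no observations with a {f.response!r} value to fit on"
        )
    if f.family == "gamma_identity" and (y <= 0).any():
        raise ValueError(
            f"gamma_identity requires a strictly positive response; "
            f"{int((y <= 0).sum())} non-positive value(s) in {f.response!r}"
        )
    if f.family == "binomial_logit":
        uniques = set(pd.unique(y.dropna()))
        if not uniques <= {0, 1, 0.0, 1.0, True, False}:
            raise ValueError(
                f"binomial_logit requires a 0/1 response, got {uniques}"
            )
    import warnings

    with warnings.catch_warnings():
        # identity link on Gamma is the intended parametrisation here
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.DomainWarning)
        model = sm.GLM.from_formula(
            f.formula, data=data, family=_family(f.family)
        )
        fitted = model.fit(maxiter=200)
    if not fitted.converged:
        raise RuntimeError(
            f"GLM did not converge for {f.formula!r}; "
            f"last deviance {fitted.deviance:.6g}"
        )
    return ModelResult(f, fitted)


def stepwise_aic(
    full: ModelFormula, data: pd.DataFrame, trace: bool = True,
) -> ModelResult:
    """Greedy bidirectional stepwise selection on AIC.

    Starts from the full model; at each step evaluates every single-term
    deletion and every re-addition of a previously removed term, and takes
    the move with the lowest AIC if it improves on the current model
    (strictly, beyond a 1e-10 tie guard — AIC ties keep the current
    model).  Stops at a local minimum; the returned result carries the
    selection trace and never has a higher AIC than the full model.

    When the full model itself fails to converge (identity-link gamma
    fits can, on small samples with collinear factors), selection starts
    from the best-AIC fittable submodel instead; only if no model fits —
    not even the intercept-only one — does the error propagate.
    """

    def try_fit(f: ModelFormula) -> ModelResult | None:
        try:
            return fit_glm(f, data)
        except (ValueError, RuntimeError):
            return None

    start = full
    current = try_fit(start)
    while current is None:
        if not start.terms:
            return fit_glm(start, data)  # re-raise the null-model error
        fittable = [
            (res.aic, cand)
            for term in start.terms
            if (res := try_fit(cand := start.without(term))) is not None
        ]
        if fittable:
            _, start = min(fittable, key=lambda c: (c[0], c[1].formula))
            current = try_fit(start)
        else:  # no single-term deletion fits either; shrink and retry
            start = start.without(start.terms[0])
            current = try_fit(start)
    current.selection_trace = [(start.formula, current.aic)]
    removed: set[str] = set(full.terms) - set(start.terms)
    while True:
        candidates: list[tuple[float, ModelFormula, str]] = []
        for term in current.formula.terms:
            cand = current.formula.without(term)
            try:
                res = fit_glm(cand, data)
            except (ValueError, RuntimeError):
                continue
            candidates.append((res.aic, cand, term))
        for term in sorted(removed):
            cand = current.formula.adding(term)
            try:
                res = fit_glm(cand, data)
            except (ValueError, RuntimeError):
                continue
            candidates.append((res.aic, cand, term))
        if not candidates:
            break
        best_aic, best_formula, moved = min(
            candidates, key=lambda c: (c[0], c[1].formula)
        )
        if best_aic >= current.aic - 1e-10:
            break
        trace_list = current.selection_trace
        current = fit_glm(best_formula, data)
        current.selection_trace = trace_list + [
            (best_formula.formula, current.aic)
        ]
        removed = set(full.terms) - set(best_formula.terms)
    return current


def anova_type2(m: ModelResult, data: pd.DataFrame) -> pd.DataFrame:
    """Type-II ANOVA by likelihood-ratio tests.

    For each term, the model without that term (all other terms retained;
    there are no interactions in this suite, so marginality is trivial) is
    refitted and compared by ``LR χ² = 2 (logLik_full − logLik_reduced)``
    with df = number of parameters removed.  A refit failure yields an NA
    row with a warning.
    """
    import warnings

    rows = []
    if not m.formula.terms:
        return pd.DataFrame(
            columns=["lr_chisq", "df", "p"],
            index=pd.Index([], name="term"),
        )
    for term in m.formula.terms:
        reduced_formula = m.formula.without(term)
        try:
            reduced = fit_glm(reduced_formula, data)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"refit without {term!r} failed: {exc}",
                          stacklevel=2)
            rows.append({"term": term, "lr_chisq": np.nan,
                         "df": np.nan, "p": np.nan})
            continue
        lr = 2.0 * (m.loglik - reduced.loglik)
        lr = max(lr, 0.0)
        df = int(m.fitted.df_model - reduced.fitted.df_model)
        df = max(df, 1)
        p = float(scipy.stats.chi2.sf(lr, df))
        rows.append({"term": term, "lr_chisq": lr, "df": df, "p": p})
    return pd.DataFrame(rows).set_index("term")


def r2_measures(m: ModelResult, data: pd.DataFrame) -> dict[str, float]:
    """Nagelkerke's R² (all families) and Tjur's R² (binomial only).

    Nagelkerke: ``[1 − (L0/L1)^(2/n)] / [1 − L0^(2/n)]`` with L0 the
    likelihood of the intercept-only model.  Tjur: mean fitted probability
    among successes minus mean among failures.
    """
    n = int(m.fitted.nobs)
    null_formula = ModelFormula(m.formula.response, (), m.formula.family)
    null = fit_glm(null_formula, data)
    cox_snell = 1.0 - np.exp((2.0 / n) * (null.loglik - m.loglik))
    max_r2 = 1.0 - np.exp((2.0 / n) * null.loglik)
    out = {"nagelkerke": float(cox_snell / max_r2) if max_r2 > 0 else np.nan}
    if m.formula.family == "binomial_logit":
        y = np.asarray(data[m.formula.response], dtype=float)
        mu = np.asarray(m.fitted.fittedvalues, dtype=float)
        ones = mu[y == 1]
        zeros = mu[y == 0]
        out["tjur"] = (
            float(ones.mean() - zeros.mean())
            if ones.size and zeros.size
            else np.nan
        )
    return out
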