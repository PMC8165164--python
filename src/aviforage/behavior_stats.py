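"""Ethogram and repeated-measures statistics.

Covers the manual-scoring side of the analysis: Table-style behavior
summaries, inter-rater reliability (Cohen's kappa), two-way
repeated-measures ANOVA with partial eta-squared and Tukey post-hocs,
and mixed-model likelihood-ratio tests for the per-session scalars
(latency, activity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .config import BODY_ORIENTED
from .errors import InputError

__all__ = [
    "TestResult",
    "summarize_ethogram",
    "cohens_kappa",
    "rm_anova",
    "rm_anova_within",
    "lmm_lrt",
]


@dataclass
class TestResult:
    """A named test statistic with df, p, effect size and post-hoc table."""

    name: str
    terms: pd.DataFrame  # term, statistic, df, p, effect_size
    posthoc: pd.DataFrame | None = None
    notes: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        rows = self.terms.loc[self.terms["term"] == name]
        if rows.empty:
            raise KeyError(f"no term {name!r} in {self.name}")
        return rows.iloc[0]


# --------------------------------------------------------------------------
# ethogram summaries
# --------------------------------------------------------------------------


def summarize_ethogram(
    tab: pd.DataFrame, rater: str | None = "R1"
) -> pd.DataFrame:
    """Per-behavior, per-condition sum, mean and SEM of session counts.

    The mean divides the condition total by the number of bird x session
    observations (48 in the full design); the SEM is computed across
    those observations.
    """
    df = tab
    if rater is not None and "rater" in df.columns:
        df = df[df["rater"] == rater]
    if df.empty:
        raise InputError("empty ethogram table")
    out = (
        df.groupby(["behavior", "condition"], sort=False)["count"]
        .agg(sum="sum", n="size", mean="mean", sem=lambda c: c.sem(ddof=1))
        .reset_index()
    )
    out["sem"] = out["sem"].fillna(0.0)
    return out


# --------------------------------------------------------------------------
# inter-rater reliability
# --------------------------------------------------------------------------


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Returns NaN (with a warning) when both raters are constant on the
    same label, where chance agreement is 1 and kappa is undefined.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InputError("label vectors must be 1-d, equal length >= 2")
    if len(np.unique(a)) == 1 and np.array_equal(np.unique(a), np.unique(b)):
        warnings.warn("both raters constant on one label; kappa undefined")
        return float("nan")
    return float(cohen_kappa_score(a, b))


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------


def _check_balanced(df, subject, factors):
    sizes = df.groupby([subject, *factors], sort=False).size()
    n_expected = df[subject].nunique()
    for f in factors:
        n_expected *= df[f].nunique()
    if sizes.nunique() != 1 or len(sizes) != n_expected:
        raise InputError(
            "unbalanced within-subject design; each subject needs every "
            f"{' x '.join(factors)} cell (no silent imputation)"
        )


def rm_anova(
    tab: pd.DataFrame,
    behaviors=BODY_ORIENTED,
    subject: str = "bird_id",
    rater: str | None = "R1",
) -> TestResult:
    """Two-way repeated-measures ANOVA (condition x day) on behavior counts.

    Counts of the selected behaviors are summed per bird x condition x
    session; both factors are within-subject.  Reports F, df, p and
    partial eta-squared per term, plus a Tukey test over the three
    condition pairs using the condition x subject error term.
    """
    import pingouin as pg

    df = tab
    if rater is not None and "rater" in df.columns:
        df = df[df["rater"] == rater]
    df = df[df["behavior"].isin(behaviors)]
    if df.empty:
        raise InputError(f"no rows for behaviors {list(behaviors)}")
    agg = (
        df.groupby([subject, "condition", "session"], sort=False)["count"]
        .sum()
        .reset_index(name="y")
    )
    _check_balanced(agg, subject, ["condition", "session"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(
            data=agg,
            dv="y",
            within=["condition", "session"],
            subject=subject,
            detailed=True,
        )
    terms = []
    for _, row in aov.iterrows():
        # recover the error SS from F = (SS/df1) / (SS_err/df2)
        ss_err = row["SS"] * row["ddof2"] / (row["ddof1"] * row["F"]) if row["F"] > 0 else np.nan
        np2 = row["SS"] / (row["SS"] + ss_err) if np.isfinite(ss_err) else 0.0
        terms.append(
            {
                "term": str(row["Source"]).replace(" * ", ":"),
                "statistic": row["F"],
                "df": f"({int(row['ddof1'])}, {int(row['ddof2'])})",
                "p": row["p_unc"],
                "effect_size": np2,
            }
        )
    posthoc = _tukey_within(agg, subject, "condition", "y")
    return TestResult(
        name="rm_anova", terms=pd.DataFrame(terms), posthoc=posthoc
    )


def _tukey_within(agg, subject, factor, dv) -> pd.DataFrame:
    """Tukey HSD over factor levels in a within-subject design.

    Collapses over the remaining factors, then uses the factor x subject
    interaction mean square as the error term (df = (k-1)(n-1)).
    """
    cell = agg.groupby([subject, factor], sort=False)[dv].mean().unstack(factor)
    n, k = cell.shape
    grand = cell.to_numpy().mean()
    subj_means = cell.mean(axis=1).to_numpy()
    lvl_means = cell.mean(axis=0)
    resid = (
        cell.to_numpy()
        - subj_means[:, None]
        - lvl_means.to_numpy()[None, :]
        + grand
    )
    df_err = (k - 1) * (n - 1)
    ms_err = float((resid**2).sum()) / df_err
    se = np.sqrt(ms_err / n)
    rows = []
    levels = list(cell.columns)
    for i in range(k):
        for j in range(i + 1, k):
            diff = lvl_means.iloc[j] - lvl_means.iloc[i]
            q = abs(diff) / se if se > 0 else np.inf
            p = float(stats.studentized_range.sf(q, k, df_err)) if se > 0 else 0.0
            rows.append(
                {
                    "comparison": f"{levels[j]}-{levels[i]}",
                    "estimate": diff,
                    "se": se,
                    "q": q,
                    "p_corrected": p,
                }
            )
    return pd.DataFrame(rows)


def rm_anova_within(
    tab: pd.DataFrame,
    condition: str,
    behaviors=BODY_ORIENTED,
    subject: str = "bird_id",
    rater: str | None = "R1",
) -> TestResult:
    """One-way repeated-measures ANOVA of the session effect inside one condition."""
    import pingouin as pg

    df = tab
    if rater is not None and "rater" in df.columns:
        df = df[df["rater"] == rater]
    df = df[(df["behavior"].isin(behaviors)) & (df["condition"] == condition)]
    if df.empty:
        raise InputError(f"no rows for condition {condition!r}")
    agg = (
        df.groupby([subject, "session"], sort=False)["count"].sum().reset_index(name="y")
    )
    _check_balanced(agg, subject, ["session"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(data=agg, dv="y", within="session", subject=subject, detailed=True)
    row = aov.iloc[0]
    err = aov.iloc[1]
    np2 = row["SS"] / (row["SS"] + err["SS"])
    terms = pd.DataFrame(
        [
            {
                "term": f"session|{condition}",
                "statistic": row["F"],
                "df": f"({int(row['DF'])}, {int(err['DF'])})",
                "p": row["p_unc"],
                "effect_size": np2,
            }
        ]
    )
    return TestResult(name="rm_anova_within", terms=terms)


# --------------------------------------------------------------------------
# linear mixed model with likelihood-ratio tests
# --------------------------------------------------------------------------


def lmm_lrt(
    data: pd.DataFrame,
    outcome: str,
    subject: str = "bird_id",
    condition: str = "condition",
    session: str = "session",
    censored: str | None = "censored",
) -> TestResult:
    """Mixed-model LRTs for condition, session and their interaction.

    Fits nested linear mixed models (random bird intercept, maximum
    likelihood) and tests each term with a chi-square likelihood-ratio
    test: condition and session against the additive model, the
    interaction against the full model.  Censored sessions (no feeding
    episode) are excluded and their count reported.  Pairwise condition
    contrasts are Tukey-adjusted via the studentized range.

    A singular random-effects fit falls back to ordinary least squares
    for all nested fits, flagged in ``notes``.
    """
    import statsmodels.formula.api as smf

    df = data.copy()
    n_censored = 0
    if censored is not None and censored in df.columns:
        n_censored = int(df[censored].sum())
        df = df[~df[censored].astype(bool)]
    df = df.dropna(subset=[outcome])
    if df[subject].nunique() < 2:
        raise InputError("need at least 2 subjects")
    for col in (condition, session):
        if df[col].nunique() < 2:
            raise InputError(f"factor {col!r} needs at least 2 levels")
    df["_y"] = df[outcome].astype(float)
    df["_cond"] = df[condition].astype(str)
    df["_sess"] = df[session].astype(str)

    formulas = {
        "full": "_y ~ C(_cond) * C(_sess)",
        "additive": "_y ~ C(_cond) + C(_sess)",
        "no_condition": "_y ~ C(_sess)",
        "no_session": "_y ~ C(_cond)",
    }

    def fit_ml(formula, use_ols):
        if use_ols:
            res = smf.ols(formula, df).fit()
            return res, res.llf, res.df_model + 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, df, groups=df[subject]).fit(reml=False)
        k = res.k_fe + 1  # fixed effects + random-intercept variance
        return res, res.llf, k

    singular = False
    fits = {}
    try:
        for key, f in formulas.items():
            fits[key] = fit_ml(f, use_ols=False)
        # near-zero random-effect variance => singular fit
        if float(fits["full"][0].cov_re.iloc[0, 0]) < 1e-8:
            singular = True
    except Exception:
        singular = True
    if singular:
        fits = {key: fit_ml(f, use_ols=True) for key, f in formulas.items()}

    n = len(df)

    def lrt(full_key, reduced_key, term):
        llf_f, k_f = fits[full_key][1], fits[full_key][2]
        llf_r, k_r = fits[reduced_key][1], fits[reduced_key][2]
        chi2 = max(2 * (llf_f - llf_r), 0.0)
        dof = int(k_f - k_r)
        p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else np.nan
        # likelihood-based pseudo effect size (partial eta-squared analog)
        eta = float(1 - np.exp(-chi2 / n))
        return {"term": term, "statistic": chi2, "df": dof, "p": p, "effect_size": eta}

    terms = pd.DataFrame(
        [
            lrt("additive", "no_condition", "condition"),
            lrt("additive", "no_session", "session"),
            lrt("full", "additive", "condition:session"),
        ]
    )

    posthoc = _tukey_lmm(fits["additive"][0], df, singular)
    return TestResult(
        name=f"lmm_lrt[{outcome}]",
        terms=terms,
        posthoc=posthoc,
        notes={"n": n, "n_censored": n_censored, "singular_fallback_ols": singular},
    )


def _tukey_lmm(res, df, is_ols) -> pd.DataFrame:
    """Tukey-adjusted pairwise condition contrasts from the additive fit."""
    levels = sorted(df["_cond"].unique())
    k = len(levels)
    params = res.params
    cov = res.cov_params()
    names = list(params.index)

    def coef_name(level):
        return f"C(_cond)[T.{level}]"

    # effect of each non-reference level relative to the first
    idx = {levels[0]: None}
    for lv in levels[1:]:
        idx[lv] = names.index(coef_name(lv))
    dof = len(df) - (res.df_model + 1 if is_ols else res.k_fe)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            vec = np.zeros(len(names))
            if idx[b] is not None:
                vec[idx[b]] += 1
            if idx[a] is not None:
                vec[idx[a]] -= 1
            est = float(vec @ params.to_numpy())
            se = float(np.sqrt(vec @ np.asarray(cov) @ vec))
            z = est / se if se > 0 else np.inf
            q = abs(z) * np.sqrt(2)
            p = float(stats.studentized_range.sf(q, k, max(dof, 1)))
            rows.append(
                {
                    "comparison": f"{b}-{a}",
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p_corrected": p,
                }
            )
    return pd.DataFrame(rows)
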