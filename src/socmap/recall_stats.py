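"""Scoring and statistical battery for 3AFC recall outcomes.

Implements the analyses applied to the recall data: per-condition accuracy
summaries (chance = 1/3), deviation-from-grand-mean ANOVAs with sum-to-zero
effect coding, a repeated-measures ANOVA with Bonferroni-corrected paired
t post-hocs, regressions and (partial) correlations of friendship recall on
context/trait recall, and a trial-level mixed-effects logistic model with
participant random intercepts for trait-valence, centrality and bridge
effects on friendship recall.

Partial correlations use the residual-correlation definition: correlate the
residuals of x ~ covariates with those of y ~ covariates, with two-sided
p-values on n - 2 - #covariates degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from socmap.design import CONDITIONS, SocialNetwork
from socmap.exceptions import ConfigurationError, StructuralError

CHANCE_3AFC = 1.0 / 3.0


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_3afc(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracy per condition and overall.

    Expects a tidy trial table with columns ``participant_id``,
    ``condition`` and ``correct`` (0/1); rows with a missing ``response``
    are excluded (their count is reported in the ``n_missing`` column).
    Overall accuracy is the trial-count-weighted mean of the conditions.
    """
    df = records.copy()
    if "response" in df.columns:
        missing = df["response"].isna() | (df["response"] == "")
    else:
        missing = pd.Series(False, index=df.index)
    n_missing = (
        df[missing].groupby("participant_id").size()
        if missing.any()
        else pd.Series(dtype=int)
    )
    df = df[~missing]
    acc = (
        df.pivot_table(
            index="participant_id", columns="condition", values="correct",
            aggfunc="mean",
        )
        .reindex(columns=list(CONDITIONS))
    )
    acc["overall"] = df.groupby("participant_id")["correct"].mean()
    counts = df.groupby("participant_id").size()
    acc["n_trials"] = counts
    acc["n_missing"] = n_missing.reindex(acc.index).fillna(0).astype(int)
    if "group" in records.columns:
        acc["group"] = records.groupby("participant_id")["group"].first()
    return acc.reset_index()


# ---------------------------------------------------------------------------
# deviation ANOVAs
# ---------------------------------------------------------------------------

@dataclass
class AnovaReport:
    deviations: pd.DataFrame          # per condition: estimate, F, p
    rm_anova: Dict[str, float]        # repeated-measures F, p, dfs
    posthoc: pd.DataFrame             # Bonferroni-corrected paired t-tests
    interaction: Optional[Dict[str, float]] = None
    flagged: bool = False


def _deviation_tests(long: pd.DataFrame) -> pd.DataFrame:
    """Per-condition deviation from the grand mean via sum-to-zero coding.

    Fits OLS with Sum contrasts and recovers all three deviation
    coefficients (the omitted level's deviation is minus the sum of the
    others, with variance from the coefficient covariance).  F = t^2 with
    one numerator degree of freedom, matching a per-condition
    "different from the mean" test.
    """
    import statsmodels.formula.api as smf

    levels = list(CONDITIONS)
    model = smf.ols(
        "acc ~ C(condition, Sum(omit='%s'))" % levels[-1], data=long
    ).fit()
    names = [
        "C(condition, Sum(omit='%s'))[S.%s]" % (levels[-1], l) for l in levels[:-1]
    ]
    est = np.array([model.params[n] for n in names])
    cov = model.cov_params().loc[names, names].to_numpy()
    # omitted level: deviation = -(sum of others)
    est_all = np.append(est, -est.sum())
    var_all = np.append(np.diag(cov), np.ones(len(est)) @ cov @ np.ones(len(est)))
    se_all = np.sqrt(var_all)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = est_all / se_all
    tvals[(est_all == 0)] = 0.0  # exact ties: no deviation from the mean
    dfres = model.df_resid
    pvals = 2 * stats.t.sf(np.abs(tvals), dfres)
    return pd.DataFrame(
        {
            "condition": levels,
            "deviation": est_all,
            "se": se_all,
            "F": tvals ** 2,
            "p": pvals,
        }
    )


def condition_anovas(
    summaries: pd.DataFrame,
    design: str = "one_way",
) -> AnovaReport:
    """Condition-vs-mean ANOVAs plus repeated-measures ANOVA and post-hocs.

    ``summaries`` is the output of :func:`score_3afc` (requires a ``group``
    column for the ``two_way`` design, which adds the between-subject
    network-regime factor and its interaction with condition).
    """
    from statsmodels.stats.anova import AnovaRM, anova_lm
    import statsmodels.formula.api as smf

    if design not in ("one_way", "two_way"):
        raise ConfigurationError(f"unknown design {design!r}")
    long = summaries.melt(
        id_vars=[c for c in ("participant_id", "group") if c in summaries.columns],
        value_vars=list(CONDITIONS),
        var_name="condition",
        value_name="acc",
    ).dropna(subset=["acc"])
    counts = long.groupby("condition")["acc"].count()
    if counts.min() < 2:
        raise ConfigurationError("need >= 2 participants per condition")
    flagged = counts.nunique() > 1  # unbalanced cells

    deviations = _deviation_tests(long)

    interaction = None
    if design == "two_way":
        if "group" not in long.columns:
            raise ConfigurationError("two_way design requires a 'group' column")
        m = smf.ols(
            "acc ~ C(condition, Sum) * C(group, Sum)", data=long
        ).fit()
        an = anova_lm(m, typ=2)
        interaction = {
            "F_group": float(an.loc["C(group, Sum)", "F"]),
            "p_group": float(an.loc["C(group, Sum)", "PR(>F)"]),
            "F_interaction": float(
                an.loc["C(condition, Sum):C(group, Sum)", "F"]
            ),
            "p_interaction": float(
                an.loc["C(condition, Sum):C(group, Sum)", "PR(>F)"]
            ),
        }

    wide_acc = long.pivot_table(index="participant_id", columns="condition",
                                values="acc")
    n_subj = len(wide_acc)
    if np.allclose(wide_acc.max(axis=1), wide_acc.min(axis=1)):
        # no within-subject variation at all: F is 0 by definition
        rm_anova = {"F": 0.0, "df_num": 2.0, "df_den": 2.0 * (n_subj - 1),
                    "p": 1.0}
    else:
        rm = AnovaRM(
            long, depvar="acc", subject="participant_id", within=["condition"]
        ).fit()
        row = rm.anova_table.iloc[0]
        rm_anova = {
            "F": float(row["F Value"]),
            "df_num": float(row["Num DF"]),
            "df_den": float(row["Den DF"]),
            "p": float(row["Pr > F"]),
        }

    wide = summaries.set_index("participant_id")
    pairs = [(a, b) for i, a in enumerate(CONDITIONS) for b in CONDITIONS[i + 1:]]
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_rel(wide[a], wide[b])
        rows.append(
            {
                "pair": f"{a}-{b}",
                "t": float(t),
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * len(pairs))),
            }
        )
    posthoc = pd.DataFrame(rows)
    return AnovaReport(
        deviations=deviations, rm_anova=rm_anova, posthoc=posthoc,
        interaction=interaction, flagged=bool(flagged),
    )


# ---------------------------------------------------------------------------
# recall-recall regression and correlations
# ---------------------------------------------------------------------------

def partial_corr(
    x: np.ndarray, y: np.ndarray, covar: np.ndarray
) -> Dict[str, float]:
    """Partial correlation of x and y controlling for covariates.

    Residual-correlation definition; two-sided p on n - 2 - k df.  Returns
    NaN (flagged) when either residual vector is degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(len(x)), np.atleast_2d(covar).T
                         if np.ndim(covar) == 1 else covar])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    if np.allclose(rx.std(), 0) or np.allclose(ry.std(), 0):
        return {"r": float("nan"), "p": float("nan"), "flagged": True}
    r = float(np.corrcoef(rx, ry)[0, 1])
    k = Z.shape[1] - 1
    df = len(x) - 2 - k
    if df <= 0 or abs(r) >= 1:
        return {"r": r, "p": float("nan"), "flagged": True}
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), df)
    return {"r": r, "p": float(p), "flagged": False}


@dataclass
class RegressionReport:
    terms: pd.DataFrame                 # term, F, p
    correlations: Dict[str, Dict[str, float]]
    partials: Dict[str, Dict[str, float]]
    flagged: bool = False


def recall_regression(
    summaries: pd.DataFrame,
    design: str = "one_way",
) -> RegressionReport:
    """Does context or trait recall (or their interaction) predict friendship
    recall?

    Fits ``friendship ~ context * trait`` (plus the network-regime factor in
    the ``two_way`` design), reports per-term F/p, the zero-order Pearson
    correlations of context and trait recall with friendship recall, and the
    partial correlations with the other predictor controlled.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    need = {"friendship", "trait", "context"}
    if not need.issubset(summaries.columns):
        raise StructuralError("summaries must contain per-condition accuracies")
    df = summaries.dropna(subset=list(need)).copy()
    if (
        len(df) < 6  # fewer participants than model df + residual df
        or df["friendship"].std() == 0
        or df["context"].std() == 0
    ):
        return RegressionReport(pd.DataFrame(), {}, {}, flagged=True)

    formula = "friendship ~ context * trait"
    if design == "two_way":
        if "group" not in df.columns:
            raise ConfigurationError("two_way design requires a 'group' column")
        formula += " + C(group, Sum)"
    model = smf.ols(formula, data=df).fit()
    an = anova_lm(model, typ=2)
    terms = pd.DataFrame(
        {
            "term": [t for t in an.index if t != "Residual"],
            "F": [float(an.loc[t, "F"]) for t in an.index if t != "Residual"],
            "p": [float(an.loc[t, "PR(>F)"]) for t in an.index if t != "Residual"],
        }
    )
    correlations = {}
    for pred in ("context", "trait"):
        if df[pred].std() == 0:
            correlations[pred] = {"r": float("nan"), "p": float("nan")}
            continue
        r, p = stats.pearsonr(df[pred], df["friendship"])
        correlations[pred] = {"r": float(r), "p": float(p)}
    partials = {
        "context": partial_corr(df["context"], df["friendship"], df["trait"]),
        "trait": partial_corr(df["trait"], df["friendship"], df["context"]),
    }
    return RegressionReport(
        terms=terms, correlations=correlations, partials=partials,
    )


# ---------------------------------------------------------------------------
# mixed-effects logistic model
# ---------------------------------------------------------------------------

@dataclass
class GlmmReport:
    coefficients: pd.DataFrame   # term, estimate, se, z, p
    random_intercept_sd: float
    backend: str
    flagged: bool = False


def _glmm_design(
    records: pd.DataFrame, net: SocialNetwork, predictors: Iterable[str]
) -> pd.DataFrame:
    df = records.copy()
    if "valence_class" not in df.columns:
        df["valence_class"] = df["cue"].map(lambda v: net.valence_class(v))
    if "central" not in df.columns:
        df["central"] = df["cue"].map(lambda v: int(v in net.central_nodes))
    if "bridge" not in df.columns:
        df["bridge"] = df["cue"].map(lambda v: int(v == net.bridge_node))
    X = pd.DataFrame(index=df.index)
    preds = set(predictors)
    if "valence" in preds:
        X["negative"] = (df["valence_class"] == "negative").astype(float)
        X["both"] = (df["valence_class"] == "both").astype(float)
    if "centrality" in preds:
        X["central"] = df["central"].astype(float)
        if "valence" in preds:
            X["central_x_negative"] = X["central"] * X["negative"]
    if "bridge" in preds:
        X["bridge"] = df["bridge"].astype(float)
    return X


def valence_glmm(
    records: pd.DataFrame,
    net: SocialNetwork,
    predictors: Iterable[str] = ("valence",),
    condition: str = "friendship",
) -> GlmmReport:
    """Mixed-effects logistic regression of trial-level recall outcomes.

    Random intercept per participant; fixed effects assembled from the
    requested predictor blocks: ``valence`` (negative / both dummies,
    positive as reference), ``centrality`` (indicator, plus its interaction
    with the negative dummy when valence is present) and ``bridge``.  The
    backend is a variational Bayesian binomial mixed GLM (statsmodels);
    posterior mean/sd give Z and two-sided p per coefficient.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    df = records[records["condition"] == condition].reset_index(drop=True)
    if df.empty:
        raise StructuralError(f"no trials for condition {condition!r}")
    X = _glmm_design(df, net, predictors)
    dropped = [c for c in X.columns if X[c].std() == 0]
    X = X.drop(columns=dropped)
    exog = np.column_stack([np.ones(len(df)), X.to_numpy()])
    names = ["intercept"] + list(X.columns)

    participants = pd.Categorical(df["participant_id"])
    vc = pd.get_dummies(participants).to_numpy(dtype=float)
    import scipy.sparse as sp

    model = BinomialBayesMixedGLM(
        endog=df["correct"].to_numpy(dtype=float),
        exog=exog,
        exog_vc=sp.csr_matrix(vc),
        ident=np.zeros(vc.shape[1], dtype=int),
        vcp_p=2.0,
        fe_p=2.0,
    )
    flagged = False
    # the VB objective uses Monte-Carlo draws from the global numpy RNG;
    # pin the state locally so reports are reproducible
    state = np.random.get_state()
    np.random.seed(1234567)
    try:
        res = model.fit_vb()
    except Exception:  # separation or non-convergence: flag and retry MAP
        flagged = True
        res = model.fit_map()
    finally:
        np.random.set_state(state)
    k = len(names)
    est = res.fe_mean[:k]
    sd = res.fe_sd[:k]
    z = est / sd
    p = 2 * stats.norm.sf(np.abs(z))
    coefs = pd.DataFrame(
        {"term": names, "estimate": est, "se": sd, "z": z, "p": p}
    )
    for c in dropped:
        flagged = True
        coefs = pd.concat(
            [coefs, pd.DataFrame([{"term": c, "estimate": np.nan,
                                   "se": np.nan, "z": np.nan, "p": np.nan}])],
            ignore_index=True,
        )
    re_sd = float(np.exp(res.vcp_mean[0])) if len(res.vcp_mean) else float("nan")
    return GlmmReport(
        coefficients=coefs,
        random_intercept_sd=re_sd,
        backend="statsmodels-BinomialBayesMixedGLM-VB",
        flagged=flagged,
    )
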