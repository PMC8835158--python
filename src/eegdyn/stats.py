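"""Group-level statistics for microstate and omega feature tables.

The battery mirrors common practice for two-group EEG studies: mixed
repeated-measures ANOVA (between factor: group; within factor: microstate
class, transition pair, or scalp region) with Greenhouse-Geisser
correction when Mauchly's test rejects sphericity, Bonferroni-corrected
post hoc t-tests with Cohen's d, independent t-tests for global measures,
a rank-sum fallback for non-normal data, and Spearman correlations with
the symptom score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "mixed_anova",
    "posthoc_tests",
    "cohens_d",
    "spearman_corr",
    "wilcoxon_fallback",
    "independent_ttest",
    "group_battery",
]


def mixed_anova(data: pd.DataFrame, dv: str, within: str, subject: str,
                between: str, gg_alpha: float = 0.05) -> pd.DataFrame:
    """Two-way mixed repeated-measures ANOVA.

    Returns one row per effect (between, within, interaction) with F,
    degrees of freedom, the p-value (Greenhouse-Geisser corrected for the
    within and interaction effects whenever Mauchly's sphericity p <
    ``gg_alpha``), partial eta squared, and the correction metadata.

    Every subject must have exactly one observation per within level.
    """
    counts = data.groupby([subject, within], observed=True)[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("each subject needs exactly one value per within level")

    with np.errstate(invalid="ignore", divide="ignore"):
        res = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                             between=between, correction=True)
    n_levels = data[within].nunique()
    eps = 1.0
    spher_p = np.nan
    if n_levels > 2:
        spher = pg.sphericity(data, dv=dv, within=within, subject=subject)
        spher_p = float(spher.pval)
        eps_row = res.loc[res["Source"] == within, "eps"]
        if not eps_row.empty and np.isfinite(eps_row.iloc[0]):
            eps = float(eps_row.iloc[0])
    correct = n_levels > 2 and spher_p < gg_alpha

    rows = []
    for _, r in res.iterrows():
        effect = r["Source"]
        df1, df2 = float(r["DF1"]), float(r["DF2"])
        f = float(r["F"])
        p = float(r["p_unc"])
        if not np.isfinite(f):
            # degenerate 0/0 effect (e.g. a dv that sums to a constant per
            # subject has no between-subject variance at all): no evidence
            f, p = 0.0, 1.0
        elif correct and effect != between:
            p = float(sps.f.sf(f, eps * df1, eps * df2))
        np2 = float(r["np2"])
        rows.append({"effect": effect, "F": f, "df1": df1, "df2": df2,
                     "p": p, "p_unc": float(r["p_unc"]),
                     "partial_eta_sq": np2 if np.isfinite(np2) else 0.0,
                     "gg_applied": bool(correct and effect != between),
                     "eps": eps if effect != between else np.nan,
                     "sphericity_p": spher_p})
    return pd.DataFrame(rows)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d for two independent samples, pooled-SD form."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def independent_ttest(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-sided independent-samples t-test with effect size."""
    t, p = sps.ttest_ind(x, y)
    return {"t": float(t), "df": len(x) + len(y) - 2, "p": float(p),
            "cohens_d": cohens_d(x, y)}


def posthoc_tests(comparisons: list[tuple[np.ndarray, np.ndarray]],
                  names: list[str] | None = None,
                  correction: str = "bonferroni") -> pd.DataFrame:
    """Independent two-sample t-tests with multiplicity correction.

    ``p_adj = min(1, m * p)`` under Bonferroni over the ``m`` comparisons.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    m = len(comparisons)
    rows = []
    for i, (x, y) in enumerate(comparisons):
        r = independent_ttest(x, y)
        p_adj = min(1.0, m * r["p"]) if correction == "bonferroni" else r["p"]
        rows.append({"comparison": names[i] if names else str(i), **r,
                     "p_adj": p_adj})
    return pd.DataFrame(rows)


def spearman_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties); (rho, p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of at least 3")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def wilcoxon_fallback(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample rank-sum test for non-normal data; (statistic, p).

    Exact enumeration for small tie-free samples (both n <= 25), otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = max(x.size, y.size) <= 25
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# full battery on a cohort feature table

def _long(table: pd.DataFrame, cols: list[str], value: str,
          within: str) -> pd.DataFrame:
    out = table.melt(id_vars=["subject", "group"], value_vars=cols,
                     var_name=within, value_name=value)
    return out


def group_battery(features: pd.DataFrame, classes=("A", "B", "C", "D"),
                  bands=("delta", "theta", "alpha1", "alpha2",
                         "beta1", "beta2", "gamma")) -> dict[str, pd.DataFrame]:
    """The full statistical battery on a subject-by-feature table.

    Expects columns ``subject``, ``group``, ``score`` plus the feature
    columns produced by :mod:`eegdyn.features`.  Returns a dict of tidy
    result tables:

    - ``anova``: mixed ANOVAs for duration/occurrence/contribution over
      classes, transition probability over the 12 ordered pairs, and
      omega over scalp region per band;
    - ``global_omega``: independent t-tests per band on global omega;
    - ``posthoc``: Bonferroni-corrected per-class group comparisons;
    - ``score_corr``: Spearman correlations of each feature with the
      symptom score.
    """
    groups = features["group"].unique()
    if groups.size != 2:
        raise ValueError("feature table must contain exactly two groups")
    g1 = features[features["group"] == groups[0]]
    g2 = features[features["group"] == groups[1]]

    anova_rows = []
    for measure, prefix in (("duration", "dur"), ("occurrence", "occ"),
                            ("contribution", "contrib")):
        cols = [f"{prefix}_{c}" for c in classes]
        long = _long(features, cols, measure, "class")
        res = mixed_anova(long, dv=measure, within="class", subject="subject",
                          between="group")
        res.insert(0, "measure", measure)
        anova_rows.append(res)
    tcols = [c for c in features.columns if c.startswith("t_")]
    if tcols:
        long = _long(features, tcols, "prob", "pair")
        res = mixed_anova(long, dv="prob", within="pair", subject="subject",
                          between="group")
        res.insert(0, "measure", "transition")
        anova_rows.append(res)
    for band in bands:
        cols = [f"omega_anterior_{band}", f"omega_posterior_{band}"]
        if not all(c in features.columns for c in cols):
            continue
        long = _long(features, cols, "omega", "region")
        res = mixed_anova(long, dv="omega", within="region", subject="subject",
                          between="group")
        res.insert(0, "measure", f"omega_{band}")
        anova_rows.append(res)
    anova = pd.concat(anova_rows, ignore_index=True)

    glob_rows = []
    for band in bands:
        col = f"omega_global_{band}"
        if col not in features.columns:
            continue
        r = independent_ttest(g1[col].to_numpy(), g2[col].to_numpy())
        glob_rows.append({"band": band, **r})
    global_omega = pd.DataFrame(glob_rows)

    ph_cols = ([f"occ_{c}" for c in classes] + [f"dur_{c}" for c in classes]
               + [f"contrib_{c}" for c in classes])
    comparisons = [(g1[c].to_numpy(), g2[c].to_numpy()) for c in ph_cols]
    posthoc = posthoc_tests(comparisons, names=ph_cols)

    corr_rows = []
    feature_cols = [c for c in features.columns
                    if c not in ("subject", "group", "score")]
    for c in feature_cols:
        rho, p = spearman_corr(features[c].to_numpy(), features["score"].to_numpy())
        corr_rows.append({"feature": c, "rho": rho, "p": p})
    score_corr = pd.DataFrame(corr_rows)

    return {"anova": anova, "global_omega": global_omega, "posthoc": posthoc,
            "score_corr": score_corr}
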