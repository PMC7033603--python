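"""Group-comparison statistics with Bonferroni control.

Training-set condition contrasts use Welch independent t-tests (no
equal-variance assumption); testing-set contrasts use paired t-tests on the
within-participant condition pairs.  With ``r`` retained features that makes
``m = 2 r`` comparisons, each judged at ``alpha / m``.  Cohort descriptives
are compared across protocol groups with one-way ANOVAs, and the
both-environments group's speeds with a paired t-test.  Normality is
reported (Shapiro-Wilk p) but does not trigger any automatic fallback.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ConfigError, DatasetError


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-comparison significance threshold ``alpha / m``."""
    if m < 1:
        raise ConfigError("number of comparisons must be >= 1")
    return alpha / m


def welch_t(a, b) -> tuple[float, float]:
    """Welch's independent-samples t-test; degenerate inputs give t=0, p=1."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = sstats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def paired_t(a, b) -> tuple[float, float]:
    """Paired t-test; identical vectors give t=0, p=1."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = sstats.ttest_rel(a, b)
    return float(t), float(p)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA; zero within- and between-variance gives F=0, p=1."""
    arrs = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ConfigError("every group needs at least 2 observations")
    allv = np.concatenate(arrs)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    f, p = sstats.f_oneway(*arrs)
    return float(f), float(p)


def compare_selected_features(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    retained: list[str],
    alpha: float = 0.05,
    conditions: tuple[str, str] = ("treadmill", "sidewalk"),
) -> pd.DataFrame:
    """Condition contrasts for every retained feature in both datasets.

    Returns one row per (feature, dataset) with group means/SDs, the test
    statistic, p-value, and a significance flag at the Bonferroni-adjusted
    threshold ``alpha / (2 * len(retained))``.
    """
    if not retained:
        raise ConfigError("retained feature set is empty")
    c0, c1 = conditions
    m = 2 * len(retained)
    thr = bonferroni_threshold(alpha, m)

    test_piv = {}
    for feat in retained:
        piv = test_table.pivot(index="participant", columns="condition",
                               values=feat)
        if piv.isna().any().any() or not {c0, c1} <= set(piv.columns):
            raise DatasetError("testing rows are not pairable by participant")
        test_piv[feat] = piv

    rows = []
    for feat in retained:
        a = train_table.loc[train_table["condition"] == c0, feat].to_numpy()
        b = train_table.loc[train_table["condition"] == c1, feat].to_numpy()
        t, p = welch_t(a, b)
        rows.append(dict(
            feature=feat, dataset="training",
            **{f"mean_{c0}": a.mean(), f"sd_{c0}": a.std(ddof=1),
               f"mean_{c1}": b.mean(), f"sd_{c1}": b.std(ddof=1)},
            statistic=t, p_value=p, significant=p < thr))
        piv = test_piv[feat]
        t, p = paired_t(piv[c0].to_numpy(), piv[c1].to_numpy())
        rows.append(dict(
            feature=feat, dataset="testing",
            **{f"mean_{c0}": piv[c0].mean(), f"sd_{c0}": piv[c0].std(ddof=1),
               f"mean_{c1}": piv[c1].mean(), f"sd_{c1}": piv[c1].std(ddof=1)},
            statistic=t, p_value=p, significant=p < thr))
    out = pd.DataFrame(rows)
    out.attrs["n_comparisons"] = m
    out.attrs["adjusted_threshold"] = thr
    return out


def cohort_descriptives(manifest: pd.DataFrame, runs=None) -> dict:
    """Protocol-level descriptive summary with ANOVA and paired speed test.

    ``manifest`` needs participant/protocol plus demographic columns;
    ``runs`` (optional) supplies per-run speeds for the speed comparisons.
    Returns a dict with a mean (SD) summary table, ANOVA p-values per
    variable, Shapiro-Wilk normality p-values, and the paired
    treadmill-vs-sidewalk speed test within the both-environments protocol.
    """
    protocols = sorted(manifest["protocol"].unique())
    if len(protocols) < 2 or any(
            (manifest["protocol"] == p).sum() < 2 for p in protocols):
        raise ConfigError("need >= 2 protocols with >= 2 participants each")
    demo_vars = [c for c in ("height_m", "mass_kg", "age_yr")
                 if c in manifest.columns]
    summary_rows, anova_p, shapiro_p = [], {}, {}
    for var in demo_vars:
        groups = [manifest.loc[manifest["protocol"] == p, var].to_numpy()
                  for p in protocols]
        _, p_val = one_way_anova(*groups)
        anova_p[var] = p_val
        shapiro_p[var] = float(sstats.shapiro(manifest[var]).pvalue)
        summary_rows.append(
            {"variable": var,
             **{f"protocol_{p}": f"{g.mean():.2f} ({g.std(ddof=1):.2f})"
                for p, g in zip(protocols, groups)},
             "anova_p": p_val})
    out = dict(summary=pd.DataFrame(summary_rows), anova_p=anova_p,
               shapiro_p=shapiro_p)

    if runs is not None:
        speed = pd.DataFrame(
            [dict(participant=r.participant, condition=r.condition,
                  speed=r.speed_mps) for r in runs])
        speed = speed.merge(manifest[["participant", "protocol"]],
                            on="participant")
        for cond in sorted(speed["condition"].unique()):
            sub = speed[speed["condition"] == cond]
            groups = [sub.loc[sub["protocol"] == p, "speed"].to_numpy()
                      for p in sorted(sub["protocol"].unique())
                      if (sub["protocol"] == p).sum() >= 2]
            if len(groups) >= 2:
                _, p_val = one_way_anova(*groups)
                anova_p[f"speed_{cond}"] = p_val
        both = speed[speed["protocol"] == max(protocols)]
        piv = both.pivot(index="participant", columns="condition",
                         values="speed").dropna()
        if piv.shape[1] == 2 and len(piv) >= 2:
            cols = list(piv.columns)
            t, p_val = paired_t(piv[cols[0]], piv[cols[1]])
            out["paired_speed"] = dict(
                conditions=cols, t=t, p=p_val,
                means={c: float(piv[c].mean()) for c in cols})
    return out
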