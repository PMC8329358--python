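"""The inference battery: mixed-design ANOVA with generalized eta squared,
Welch t with Holm correction, Levene (Brown–Forsythe) and rank-based
confirmations, and the Spearman correlation battery.

The mixed ANOVA handles one between-subjects factor (2 or 3 groups, sizes
may differ) crossed with up to two 2-level within-subject factors.  The
univariate sums-of-squares partition uses orthonormal within-subject
contrasts: the between-subjects stratum is a one-way ANOVA on subject
means; each within effect and its Group interaction live in the stratum of
the corresponding contrast scores, with subjects-within-group as the error
term.  With unequal group sizes, within-subject main effects test the
unweighted average of group means (sum-to-zero / Type III estimable
functions, the convention of the R packages conventionally used for this
design).  Two-level within factors need no sphericity correction.

Generalized eta squared puts every error stratum in the denominator:
η²_G = SS_effect / (SS_effect + Σ all error SS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from efaa.asymmetry import remove_outliers


@dataclass
class EffectRow:
    effect: str
    ss: float
    df_num: int
    df_den: int
    ss_err: float
    f: float
    p: float
    ges: float
    note: str = ""


@dataclass
class AnovaResult:
    design: str
    effects: list[EffectRow]

    def __getitem__(self, effect: str) -> EffectRow:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])


def _one_way_ss(values: np.ndarray, groups: np.ndarray
                ) -> tuple[float, float, list]:
    """Between-group SS, pooled within-group SS, group labels (sorted)."""
    labels = sorted(set(groups))
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in labels:
        v = values[groups == g]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    return ss_b, ss_w, labels


def _f_and_p(ss: float, df_n: int, ss_err: float, df_d: int
             ) -> tuple[float, float, str]:
    ms_err = ss_err / df_d if df_d > 0 else 0.0
    if ms_err <= 0:
        if ss <= 1e-24:
            return 0.0, 1.0, "degenerate-variance"
        return float("inf"), 0.0, "degenerate-variance"
    f = (ss / df_n) / ms_err
    return f, float(sps.f.sf(f, df_n, df_d)), ""


def mixed_anova(data: pd.DataFrame, dv: str, subject: str, between: str,
                within: list[str]) -> AnovaResult:
    """Mixed-design ANOVA on a long-format table.

    ``within`` lists one or two 2-level within-subject factor columns; every
    subject must have a value in every within cell.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("supports one or two within-subject factors")
    for w in within:
        if data[w].nunique() != 2:
            raise ValueError(f"within factor {w!r} must have exactly 2 levels")

    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv, sort=True)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing within-cells for subjects {missing}")
    y = wide.to_numpy()                      # subjects × cells
    groups = np.array([ix[1] for ix in wide.index])
    n_sub, q = y.shape
    labels = sorted(set(groups))
    a = len(labels)
    n_g = np.array([(groups == g).sum() for g in labels])
    if (n_g < 2).any():
        raise ValueError("every group needs at least 2 subjects")

    # ---- between stratum: subject means, scaled so SS is on the cell scale
    m = y.mean(axis=1) * np.sqrt(q)
    ss_grp, ss_sub_err, _ = _one_way_ss(m, groups)
    df_grp, df_sub = a - 1, n_sub - a

    # ---- within strata via orthonormal contrasts over the cell axis
    # cell columns are sorted lexicographically by pivot_table
    if len(within) == 1:
        contrasts = {within[0]: np.array([1.0, -1.0]) / np.sqrt(2.0)}
    else:
        cB = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
        cC = np.array([1.0, -1.0, 1.0, -1.0]) / 2.0
        contrasts = {
            within[0]: cB,
            within[1]: cC,
            f"{within[0]}:{within[1]}": cB * cC * 2.0,
        }

    strata: list[tuple[str, float, int, str, float, int, str, float]] = []
    err_total = ss_sub_err
    per_stratum = []
    for name, c in contrasts.items():
        s = y @ c
        gmeans = np.array([s[groups == g].mean() for g in labels])
        # Type III main effect: unweighted mean of group means
        ubar = gmeans.mean()
        n_eff = a * a / (1.0 / n_g).sum()
        ss_main = n_eff * ubar ** 2
        ss_int, ss_err, _ = _one_way_ss(s, groups)
        per_stratum.append((name, ss_main, ss_int, ss_err))
        err_total += ss_err

    effects: list[EffectRow] = []

    def add(effect: str, ss: float, df_n: int, ss_err: float, df_d: int):
        f, p, note = _f_and_p(ss, df_n, ss_err, df_d)
        ges = ss / (ss + err_total) if (ss + err_total) > 0 else 0.0
        effects.append(EffectRow(effect, ss, df_n, df_d, ss_err, f, p, ges, note))

    add(between, ss_grp, df_grp, ss_sub_err, df_sub)
    for name, ss_main, ss_int, ss_err in per_stratum:
        add(name, ss_main, 1, ss_err, df_sub)
        add(f"{between}:{name}", ss_int, df_grp, ss_err, df_sub)

    design = (f"{between} ({a} levels, n={list(n_g)}) × "
              + " × ".join(f"{w} (2)" for w in within))
    return AnovaResult(design=design, effects=effects)


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def welch_t(values_a, values_b) -> tuple[float, float, float]:
    """Unequal-variance t with Welch–Satterthwaite df; two-sided p.

    Returns (t, df, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate variance in both groups")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in the original order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def levene_median(*groups) -> tuple[float, float]:
    """Brown–Forsythe homogeneity test (deviations from group medians)."""
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least 2 values")
    with np.errstate(divide="ignore", invalid="ignore"):
        # tiny groups can have zero within-group deviation spread
        w, p = sps.levene(*groups, center="median")
    return float(w), float(p)


def rank_tests(groups: list[np.ndarray]) -> dict:
    """Wilcoxon rank-sum for 2 groups, Kruskal–Wallis for 3+.

    Two-group p uses exact enumeration for small samples (n ≤ 20 per group,
    no ties), the tie-corrected normal approximation otherwise.
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    if len(groups) == 2:
        a, b = np.asarray(groups[0], float), np.asarray(groups[1], float)
        small = max(len(a), len(b)) <= 20
        method = "exact" if small else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return {"test": "wilcoxon-rank-sum", "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    h, p = sps.kruskal(*groups)
    return {"test": "kruskal-wallis", "statistic": float(h), "p": float(p)}


def spearman(x, y) -> dict:
    """Spearman rank correlation (midranks for ties), t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero rank variance")
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": int(len(x))}


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

#: Spearman battery: eFAA against these columns, all groups pooled
CORRELATES_ALL = ["bdi", "rpq", "rpq_emotional", "brief_gec", "brief_ec", "age"]
#: clinical covariates available for MTBI subjects only
CORRELATES_MTBI = ["pta_hours", "months_post_injury"]

BDI_CUTOFF = 10  # mild depressive symptoms: 10 or more points


@dataclass
class InferenceConfig:
    outlier_k: float = 2.5
    alpha: float = 0.05
    bdi_cutoff: int = BDI_CUTOFF


def _faa_long(scores: pd.DataFrame, group_col: str) -> pd.DataFrame:
    rows = []
    for _, r in scores.iterrows():
        for emo in ("threat", "neutral"):
            for rel in ("relevant", "irrelevant"):
                rows.append((r["subject_id"], r[group_col],
                             emo, rel, r[f"faa_{emo}_{rel}"]))
    return pd.DataFrame(rows, columns=["subject_id", "group_level",
                                       "emotion", "relevance", "faa"])


def _anova_dict(res: AnovaResult) -> dict:
    return {
        "design": res.design,
        "effects": {e.effect: {"F": e.f, "df": [e.df_num, e.df_den],
                               "p": e.p, "ges": e.ges, "note": e.note}
                    for e in res.effects},
    }


def _pairwise_welch(scores: pd.DataFrame, value: str) -> list[dict]:
    labels = sorted(scores["group"].unique())
    rows = []
    for ga, gb in combinations(labels, 2):
        t, df, p = welch_t(scores.loc[scores["group"] == ga, value],
                           scores.loc[scores["group"] == gb, value])
        rows.append({"pair": f"{ga} vs {gb}", "t": t, "df": df, "p": p})
    adj = holm_adjust([r["p"] for r in rows])
    for r, pa in zip(rows, adj):
        r["p_holm"] = float(pa)
    return rows


def run_full_inference(scores: pd.DataFrame,
                       config: InferenceConfig | None = None) -> dict:
    """Execute the whole battery on per-subject scores.

    Steps, in order: (1) two-group FAA ANOVA (MTBI pooled vs Control) after
    overall-FAA outlier removal; (2) the same with BDI ≥ cutoff subjects
    excluded; (3) three-group FAA ANOVA, with per-emotion follow-ups when
    Group × Emotion interacts; (4) eFAA ANOVA (3 groups × Relevance) after
    eFAA outlier removal, with Holm-corrected pairwise Welch post-hocs;
    (5) Levene and rank-test confirmations; (6) the Spearman battery with
    the pairwise outlier rule.

    Returns a JSON-serialisable report dict; every exclusion lists ids.
    """
    cfg = config or InferenceConfig()
    report: dict = {"exclusions": {}}

    scores = scores.copy()
    scores["group2"] = np.where(scores["group"] == "Control", "Control", "MTBI")

    # (1) two-group FAA ANOVA
    kept, removed = remove_outliers(scores, "faa_overall", k=cfg.outlier_k)
    report["exclusions"]["faa_outliers"] = removed["subject_id"].tolist()
    if kept.groupby("group2").size().min() < 2 or kept["group2"].nunique() < 2:
        raise ValueError("outlier rule removed too many subjects for ANOVA")
    long2 = _faa_long(kept, "group2")
    report["faa_two_group"] = _anova_dict(mixed_anova(
        long2, dv="faa", subject="subject_id", between="group_level",
        within=["emotion", "relevance"]))
    report["faa_two_group"]["group_means"] = \
        kept.groupby("group2")["faa_overall"].mean().to_dict()

    # (2) depression-exclusion re-analysis
    dep = kept["bdi"] >= cfg.bdi_cutoff
    report["exclusions"]["bdi_depression"] = \
        kept.loc[dep, "subject_id"].tolist()
    nodep = kept.loc[~dep]
    if nodep["group2"].nunique() == 2 and nodep.groupby("group2").size().min() >= 2:
        report["faa_two_group_no_depression"] = _anova_dict(mixed_anova(
            _faa_long(nodep, "group2"), dv="faa", subject="subject_id",
            between="group_level", within=["emotion", "relevance"]))

    # (3) three-group FAA ANOVA with per-emotion follow-ups
    long3 = _faa_long(kept, "group")
    res3 = mixed_anova(long3, dv="faa", subject="subject_id",
                       between="group_level", within=["emotion", "relevance"])
    report["faa_three_group"] = _anova_dict(res3)
    if res3["group_level:emotion"].p < cfg.alpha:
        follow = {}
        for emo, chunk in long3.groupby("emotion"):
            follow[emo] = _anova_dict(mixed_anova(
                chunk, dv="faa", subject="subject_id",
                between="group_level", within=["relevance"]))
        report["faa_three_group"]["per_emotion"] = follow

    # (4) eFAA ANOVA + post-hocs
    ekept, eremoved = remove_outliers(scores, "efaa", k=cfg.outlier_k)
    report["exclusions"]["efaa_outliers"] = eremoved["subject_id"].tolist()
    elong = ekept.melt(
        id_vars=["subject_id", "group"],
        value_vars=["efaa_relevant", "efaa_irrelevant"],
        var_name="relevance", value_name="efaa_val")
    elong["relevance"] = elong["relevance"].str.removeprefix("efaa_")
    report["efaa_anova"] = _anova_dict(mixed_anova(
        elong, dv="efaa_val", subject="subject_id", between="group",
        within=["relevance"]))
    report["efaa_anova"]["group_means"] = \
        ekept.groupby("group")["efaa"].mean().to_dict()
    report["efaa_posthoc"] = _pairwise_welch(ekept, "efaa")

    # (5) confirmations on the original (outliers-in) data
    by_group2 = [scores.loc[scores["group2"] == g, "faa_overall"].to_numpy()
                 for g in sorted(scores["group2"].unique())]
    by_group3e = [scores.loc[scores["group"] == g, "efaa"].to_numpy()
                  for g in sorted(scores["group"].unique())]
    w, p = levene_median(*[scores.loc[scores["group"] == g, "faa_overall"]
                           for g in sorted(scores["group"].unique())])
    report["levene_faa"] = {"W": w, "p": p}
    report["rank_faa_two_group"] = rank_tests(by_group2)
    report["rank_efaa_three_group"] = rank_tests(by_group3e)

    # (6) Spearman battery with the pairwise outlier rule
    corr: dict[str, dict] = {}
    for col, frame in ([(c, scores) for c in CORRELATES_ALL]
                       + [(c, scores[scores["group"] != "Control"])
                          for c in CORRELATES_MTBI]):
        sub = frame[["subject_id", "efaa", col]].dropna()
        if len(sub) < 3:
            continue
        kept_c, removed_c = remove_outliers(sub, ["efaa", col], k=cfg.outlier_k)
        if len(kept_c) < 3:
            continue
        res = spearman(kept_c["efaa"], kept_c[col])
        res["outliers_removed"] = removed_c["subject_id"].tolist()
        corr[f"efaa_vs_{col}"] = res
    report["spearman"] = corr
    return report
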