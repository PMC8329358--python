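"""Frontal alpha asymmetry (FAA), its emotional modulation (eFAA), the
outlier rule and the group summary surface.

FAA = ln(alpha power at F4) − ln(alpha power at F3): more negative values
mean relatively greater right-frontal cortical activity (alpha power is
inversely related to activity).  eFAA = FAA in threat trials − FAA in
neutral trials, isolating the effect of emotional content.

Outliers are screened with the mean ± k·SD rule (k = 2.5 by default) on the
pooled sample across groups; values strictly outside the bounds are removed
in a single pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from efaa.preprocess import EMOTIONS, RELEVANCES

DEFAULT_PAIR = ("F4", "F3")  # right, left


def compute_faa(alpha_f4: float, alpha_f3: float) -> float:
    """ln(right-frontal alpha power) − ln(left-frontal alpha power)."""
    if alpha_f4 <= 0 or alpha_f3 <= 0:
        raise ValueError("alpha power must be positive")
    return math.log(alpha_f4) - math.log(alpha_f3)


def compute_efaa(faa_threat: float, faa_neutral: float) -> float:
    """FAA in the threat condition minus FAA in the neutral condition."""
    if not (np.isfinite(faa_threat) and np.isfinite(faa_neutral)):
        raise ValueError("FAA inputs must be finite")
    return faa_threat - faa_neutral


@dataclass
class OutlierRule:
    """mean ± k·SD screening bounds."""

    k: float
    center: float
    spread: float

    @property
    def lower(self) -> float:
        return self.center - self.k * self.spread

    @property
    def upper(self) -> float:
        return self.center + self.k * self.spread

    def outside(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values strictly outside the bounds."""
        v = np.asarray(values, dtype=float)
        return (v < self.lower) | (v > self.upper)

    @classmethod
    def from_moments(cls, center: float, spread: float, k: float = 2.5
                     ) -> "OutlierRule":
        if spread < 0:
            raise ValueError("spread must be nonnegative")
        return cls(k=k, center=center, spread=spread)


def outlier_bounds(values, k: float = 2.5) -> OutlierRule:
    """Estimate mean and sample SD (n−1) from the pooled values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for an outlier rule")
    return OutlierRule(k=k, center=float(v.mean()), spread=float(v.std(ddof=1)))


def remove_outliers(scores: pd.DataFrame, fields, k: float = 2.5
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass mean ± k·SD removal on one or more columns.

    Bounds come from the pooled distribution across all groups; a subject is
    removed when strictly outside the bounds on any listed field (for
    correlation pairs the rule is applied to both variables).  Returns
    (kept, removed); ``removed`` carries a ``removed_on`` column.
    """
    if isinstance(fields, str):
        fields = [fields]
    mask = np.zeros(len(scores), dtype=bool)
    reason = np.array([""] * len(scores), dtype=object)
    for f in fields:
        vals = scores[f].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            continue
        rule = outlier_bounds(vals[ok], k=k)
        out = np.zeros(len(scores), dtype=bool)
        out[ok] = rule.outside(vals[ok])
        reason[out & ~mask] = f
        mask |= out
    removed = scores.loc[mask].copy()
    removed["removed_on"] = reason[mask]
    return scores.loc[~mask].copy(), removed


# ---------------------------------------------------------------------------
# subject scores
# ---------------------------------------------------------------------------

def subject_scores(alpha_table: pd.DataFrame,
                   scores_table: pd.DataFrame | None = None,
                   pair: tuple[str, str] = DEFAULT_PAIR) -> pd.DataFrame:
    """Per-subject FAA per cell, per emotion, overall, and eFAA.

    ``alpha_table`` is the long table from
    :func:`efaa.spectral.condition_alpha_table` (already pooled over
    response type).  If a questionnaire/clinical scores table is given it is
    merged on subject id.

    Column layout (wide): faa_<emotion>_<relevance> for the four cells,
    faa_<emotion>, faa_overall, efaa_<relevance>, efaa.
    """
    right, left = pair
    wide = alpha_table.pivot_table(
        index="subject", columns=["electrode", "emotion", "relevance"],
        values="auc", sort=True,
    )
    rows = []
    for subject, r in wide.iterrows():
        rec: dict[str, float | str] = {"subject_id": subject}
        cells = {}
        for emo in EMOTIONS:
            for rel in RELEVANCES:
                try:
                    p_r, p_l = r[(right, emo, rel)], r[(left, emo, rel)]
                except KeyError:
                    p_r = p_l = np.nan
                cells[(emo, rel)] = (
                    compute_faa(p_r, p_l)
                    if np.isfinite(p_r) and np.isfinite(p_l) else np.nan
                )
                rec[f"faa_{emo}_{rel}"] = cells[(emo, rel)]
        for emo in EMOTIONS:
            rec[f"faa_{emo}"] = float(np.mean([cells[(emo, rel)]
                                               for rel in RELEVANCES]))
        rec["faa_overall"] = float(np.mean(list(cells.values())))
        for rel in RELEVANCES:
            rec[f"efaa_{rel}"] = cells[("threat", rel)] - cells[("neutral", rel)]
        rec["efaa"] = float(np.mean([rec[f"efaa_{rel}"] for rel in RELEVANCES]))
        rows.append(rec)
    df = pd.DataFrame(rows)
    if scores_table is not None:
        df = df.merge(scores_table, on="subject_id", how="left")
    return df


def group_summary_table(scores: pd.DataFrame,
                        alpha_table: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Group × emotion summary in the layout of a published FAA table:
    per group and emotion the mean/SD of F4 and F3 alpha power, their logs
    and FAA; per group the mean/SD of eFAA and overall FAA.

    The arithmetic identities mean(FAA) = mean(lnF4) − mean(lnF3) and
    mean(eFAA) = mean(FAA_threat) − mean(FAA_neutral) hold exactly because
    every column is a plain mean of per-subject values.
    """
    if "group" not in scores.columns:
        raise ValueError("scores must carry a 'group' column")
    if scores.empty:
        raise ValueError("empty scores table")

    power = None
    if alpha_table is not None:
        merged = alpha_table.merge(
            scores[["subject_id", "group"]], left_on="subject",
            right_on="subject_id",
        )
        power = merged.groupby(["group", "electrode", "emotion"]) \
            .agg(auc_mean=("auc", "mean"), auc_sd=("auc", "std"),
                 ln_mean=("ln_auc", "mean"), ln_sd=("ln_auc", "std"))

    rows = []
    for group, chunk in scores.groupby("group", sort=True):
        base = {
            "group": group,
            "n": len(chunk),
            "efaa_mean": chunk["efaa"].mean(),
            "efaa_sd": chunk["efaa"].std(ddof=1),
            "faa_overall_mean": chunk["faa_overall"].mean(),
            "faa_overall_sd": chunk["faa_overall"].std(ddof=1),
        }
        for emo in EMOTIONS:
            row = dict(base)
            row["emotion"] = emo
            row["faa_mean"] = chunk[f"faa_{emo}"].mean()
            row["faa_sd"] = chunk[f"faa_{emo}"].std(ddof=1)
            if power is not None:
                # per-subject cell AUCs averaged over relevance, as tabulated
                for elec, tag in (("F4", "f4"), ("F3", "f3")):
                    p = power.loc[(group, elec, emo)]
                    row[f"{tag}_mean"] = p["auc_mean"]
                    row[f"{tag}_sd"] = p["auc_sd"]
                    row[f"ln_{tag}_mean"] = p["ln_mean"]
                    row[f"ln_{tag}_sd"] = p["ln_sd"]
            rows.append(row)
    out = pd.DataFrame(rows)

    # linearity identity, asserted on every produced table
    for group, chunk in out.groupby("group"):
        threat = chunk.loc[chunk["emotion"] == "threat", "faa_mean"].iloc[0]
        neutral = chunk.loc[chunk["emotion"] == "neutral", "faa_mean"].iloc[0]
        efaa = chunk["efaa_mean"].iloc[0]
        if not math.isclose(threat - neutral, efaa, abs_tol=1e-9):
            raise AssertionError(
                f"summary identity violated for group {group}: "
                f"{threat} − {neutral} != {efaa}"
            )
    return out
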