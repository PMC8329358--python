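"""Independent oracles for the statistical routines.

The mixed-ANOVA oracle takes a completely different route from the
implementation: per-subject condition-subset means are regressed on
effect-coded group dummies with statsmodels OLS, and each ANOVA F value is
obtained from statsmodels' general linear hypothesis machinery (f_test)
rather than from sums-of-squares formulas.
"""

import numpy as np
import pandas as pd
import statsmodels.api as sm


def mixed_anova_oracle(data: pd.DataFrame, dv: str, subject: str,
                       between: str, within: list[str]) -> dict:
    """F and p per effect via OLS projections / linear hypotheses."""
    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv, sort=True)
    y = wide.to_numpy()
    groups = np.array([ix[1] for ix in wide.index])
    labels = sorted(set(groups))
    a = len(labels)

    # effect (sum-to-zero) coding for the between factor
    codes = np.zeros((len(groups), a - 1))
    for j, lab in enumerate(labels[:-1]):
        codes[groups == lab, j] = 1.0
    codes[groups == labels[-1], :] = -1.0
    X = sm.add_constant(codes)

    def glh_f(response: np.ndarray) -> dict:
        fit = sm.OLS(response, X).fit()
        r = {}
        # between-coefficients hypothesis (a-1 rows)
        L_grp = np.zeros((a - 1, a))
        L_grp[:, 1:] = np.eye(a - 1)
        t = fit.f_test(L_grp)
        r["group"] = (float(t.fvalue), float(t.pvalue))
        # intercept hypothesis: unweighted mean of group means
        t = fit.f_test(np.eye(a)[:1])
        r["mean"] = (float(t.fvalue), float(t.pvalue))
        return r

    out = {}
    sub_means = y.mean(axis=1)
    out[between] = glh_f(sub_means)["group"]

    if len(within) == 1:
        half = y.shape[1] // 2
        scores = {within[0]: y[:, :half].mean(axis=1) - y[:, half:].mean(axis=1)}
    else:
        # cells sorted lexicographically: (B1C1, B1C2, B2C1, B2C2)
        scores = {
            within[0]: y[:, :2].mean(axis=1) - y[:, 2:].mean(axis=1),
            within[1]: y[:, [0, 2]].mean(axis=1) - y[:, [1, 3]].mean(axis=1),
            f"{within[0]}:{within[1]}": (y[:, 0] - y[:, 1]
                                         - y[:, 2] + y[:, 3]),
        }
    for name, s in scores.items():
        r = glh_f(s)
        out[name] = r["mean"]
        out[f"{between}:{name}"] = r["group"]
    return out


def welch_oracle(a, b):
    """Plain textbook evaluation of the Welch statistic and df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    return t, df


def levene_median_oracle(*groups):
    """Brown–Forsythe as a one-way ANOVA on |x − median| by hand."""
    devs = [np.abs(np.asarray(g, float) - np.median(g)) for g in groups]
    allv = np.concatenate(devs)
    grand = allv.mean()
    ss_b = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
    ss_w = sum(((d - d.mean()) ** 2).sum() for d in devs)
    k = len(groups)
    n = len(allv)
    return (ss_b / (k - 1)) / (ss_w / (n - k))
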