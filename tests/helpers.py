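"""Independent oracles used across the test suite.

The split-plot sums-of-squares oracle below is written as plain nested
loops over cell/marginal means, deliberately independent of the vectorized
implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sst


def splitplot_oracle(df: pd.DataFrame, dv="diff", within="region", between="group", subject="subject"):
    """Brute-force split-plot ANOVA: explicit sums of squares from means.

    Returns dict of effect -> (F, df1, df2, p_uncorrected).
    """
    groups = sorted(df[between].unique())
    levels = sorted(df[within].unique())
    subjects = sorted(df[subject].unique())
    g, k = len(groups), len(levels)
    n = len(subjects) // g
    N = g * n

    def val(s, w):
        rows = df[(df[subject] == s) & (df[within] == w)]
        assert len(rows) == 1
        return float(rows[dv].iloc[0])

    def group_of(s):
        return df[df[subject] == s][between].iloc[0]

    grand = np.mean([val(s, w) for s in subjects for w in levels])
    ss_total = sum((val(s, w) - grand) ** 2 for s in subjects for w in levels)
    subj_mean = {s: np.mean([val(s, w) for w in levels]) for s in subjects}
    grp_mean = {
        gr: np.mean([val(s, w) for s in subjects if group_of(s) == gr for w in levels])
        for gr in groups
    }
    lev_mean = {w: np.mean([val(s, w) for s in subjects]) for w in levels}
    cell_mean = {
        (gr, w): np.mean([val(s, w) for s in subjects if group_of(s) == gr])
        for gr in groups
        for w in levels
    }

    ss_between_subj = k * sum((subj_mean[s] - grand) ** 2 for s in subjects)
    ss_group = n * k * sum((grp_mean[gr] - grand) ** 2 for gr in groups)
    ss_subj_w = ss_between_subj - ss_group
    ss_level = N * sum((lev_mean[w] - grand) ** 2 for w in levels)
    ss_inter = n * sum(
        (cell_mean[(gr, w)] - grp_mean[gr] - lev_mean[w] + grand) ** 2
        for gr in groups
        for w in levels
    )
    ss_err = ss_total - ss_between_subj - ss_level - ss_inter

    out = {}
    for name, ss_eff, df1, ss_e, df2 in [
        ("group", ss_group, g - 1, ss_subj_w, N - g),
        ("channel", ss_level, k - 1, ss_err, (N - g) * (k - 1)),
        ("group*channel", ss_inter, (g - 1) * (k - 1), ss_err, (N - g) * (k - 1)),
    ]:
        F = (ss_eff / df1) / (ss_e / df2)
        out[name] = (F, df1, df2, float(sst.f.sf(F, df1, df2)))
    return out


def random_balanced_design(rng, max_n=4, max_k=4):
    """Random balanced split-plot dataset: 2 groups x <=4 subjects x <=4 levels."""
    n = int(rng.integers(2, max_n + 1))
    k = int(rng.integers(2, max_k + 1))
    rows = []
    for gi, gr in enumerate(("g1", "g2")):
        for i in range(n):
            base = rng.normal(0, 1)
            for j in range(k):
                rows.append(
                    {
                        "subject": f"{gr}s{i}",
                        "group": gr,
                        "region": f"r{j}",
                        "diff": base + 0.4 * j * gi + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


def fit_loglog_slope(x: np.ndarray, fs: float, fmin: float, fmax: float) -> float:
    """Independent periodogram-based spectral slope estimate (log-log LS fit)."""
    n = len(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    pxx = np.abs(np.fft.rfft(x)) ** 2
    m = (freqs >= fmin) & (freqs <= fmax)
    return float(np.polyfit(np.log(freqs[m]), np.log(pxx[m]), 1)[0])
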