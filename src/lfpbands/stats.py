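"""Statistical engine: split-plot repeated-measures ANOVA and the
assumption-driven two-group test cascade.

The ANOVA is the classical balanced split-plot (mixed) decomposition with
one between-subject factor (group) and one within-subject factor (brain
region / channel).  Sphericity of the within-subject covariance is tested
with Mauchly's W on the pooled within-group covariance; when violated at
alpha = 0.05 the Greenhouse-Geisser epsilon (eigenvalue form, computed
from the doubly-centred covariance) multiplies the within-effect degrees
of freedom for the reported p value.  F statistics themselves are never
altered by the correction.  Post hoc comparisons are Fisher's LSD using
the ANOVA's own pooled error mean square and error df, unadjusted.

Two-group endpoint comparisons follow a fixed cascade: Shapiro-Wilk
normality per group and Levene homogeneity across groups; on violation the
data are re-tested after log (positive data) then square-root
(non-negative data) transforms; if assumptions are met a pooled-variance
independent t-test is used, otherwise the Mann-Whitney U test with a
tie-corrected, continuity-corrected normal Z (exact p for small untied
samples).  p < 0.05 is significant; 0.05 <= p < 0.1 marginally significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sst

from .synth import DEFAULT_REGIONS

SPHERICITY_ALPHA = 0.05

# canonical rendering order for region labels in LSD ordering strings
_CANONICAL_ORDER = tuple(reversed(DEFAULT_REGIONS))  # PPN, SNc, STN, CPu, M1


# ---------------------------------------------------------------------------
# elementary identities
# ---------------------------------------------------------------------------

def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """Partial eta-squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


def f_pvalue(F: float, df1: float, df2: float) -> float:
    """Upper-tail probability of the F distribution."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(sst.f.sf(F, df1, df2))


def classify_significance(p: float) -> str:
    """'significant' (p < 0.05), 'marginal' (0.05 <= p < 0.1), else 'ns'."""
    if not 0 <= p <= 1:
        raise ValueError(f"p value {p} outside [0, 1]")
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "marginal"
    return "ns"


def round3(x: float) -> float:
    """Round to 3 decimals, half away from zero (report-rendering convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------

def gg_epsilon(within_covariance: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a within-subject covariance matrix.

    epsilon = (sum lambda)^2 / ((k-1) * sum lambda^2) where lambda are the
    eigenvalues of the doubly-centred covariance; bounded in [1/(k-1), 1].
    """
    S = np.asarray(within_covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need k >= 2 within-subject levels")
    J = np.eye(k) - np.ones((k, k)) / k
    D = J @ S @ J
    lam = np.linalg.eigvalsh(D)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * np.sum(lam**2)
    if denom == 0:
        return 1.0
    eps = float(np.sum(lam) ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mauchly_test(within_covariance: np.ndarray, n_error: int) -> tuple[float, float]:
    """Mauchly's sphericity test on a (pooled) within-subject covariance.

    ``n_error`` is the df of the covariance estimate (N - g for a pooled
    estimate over g groups).  Returns (W, p) via the standard chi-square
    approximation; with k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    S = np.asarray(within_covariance, dtype=float)
    k = S.shape[0]
    if k == 2:
        return 1.0, 1.0
    q = k - 1
    # orthonormal contrast basis
    C = np.linalg.qr(np.eye(k) - np.ones((k, k)) / k)[0][:, :q].T
    T = C @ S @ C.T
    tr = np.trace(T)
    if tr <= 0:
        return 0.0, 0.0
    det = np.linalg.det(T)
    W = float(det / (tr / q) ** q)
    W = min(max(W, 0.0), 1.0)
    if W == 0.0:
        return 0.0, 0.0
    f = n_error - (2 * q**2 + q + 2) / (6.0 * q)
    chi2 = -f * np.log(W)
    ddof = k * (k - 1) // 2 - 1
    return W, float(sst.chi2.sf(chi2, ddof))


# ---------------------------------------------------------------------------
# split-plot ANOVA
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    name: str
    F: float
    df1: int
    df2: int
    p_uncorrected: float
    p_reported: float
    partial_eta_sq: float
    df1_reported: float = 0.0
    df2_reported: float = 0.0


@dataclass
class PairwiseComparison:
    a: str
    b: str
    mean_a: float
    mean_b: float
    t: float
    p: float


@dataclass
class AnovaResult:
    band: str
    effects: dict[str, EffectResult]
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    correction_applied: bool
    lsd: dict[str, list[PairwiseComparison]] = field(default_factory=dict)
    lsd_strings: dict[str, str] = field(default_factory=dict)
    # fit context needed by lsd_posthoc
    _context: dict = field(default_factory=dict, repr=False)


def _check_balanced(df: pd.DataFrame, subject: str, within: str, between: str) -> None:
    counts = df.groupby([subject, within]).size()
    if (counts != 1).any():
        raise ValueError("design error: duplicate or missing cells per subject x level")
    levels = df[within].nunique()
    per_subject = df.groupby(subject)[within].nunique()
    if (per_subject != levels).any():
        raise ValueError("design error: incomplete within-subject data (no silent drop)")
    group_sizes = df.groupby(between)[subject].nunique()
    if group_sizes.nunique() != 1:
        raise ValueError("design error: unbalanced group sizes")
    if group_sizes.iloc[0] < 2:
        raise ValueError("design error: need at least 2 subjects per group")
    subj_groups = df.groupby(subject)[between].nunique()
    if (subj_groups != 1).any():
        raise ValueError("design error: subject assigned to multiple groups")


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "diff",
    within: str = "region",
    between: str = "group",
    subject: str = "subject",
    band: str = "",
    sphericity_alpha: float = SPHERICITY_ALPHA,
    run_lsd: bool = True,
) -> AnovaResult:
    """Two-way mixed (split-plot) repeated-measures ANOVA on a long table.

    Between-subject effect tested against subjects-within-groups; within
    effect and interaction against the channel x subjects-within-groups
    residual.  Requires a balanced complete design.
    """
    data = df[[subject, between, within, dv]].copy()
    if data[dv].isna().any():
        raise ValueError("design error: missing values")
    _check_balanced(data, subject, within, between)

    g_levels = sorted(data[between].unique())
    w_levels = list(pd.unique(data[within]))
    g, k = len(g_levels), len(w_levels)
    n = data.groupby(between)[subject].nunique().iloc[0]
    N = g * n

    grand = data[dv].mean()
    y = data
    ss_total = ((y[dv] - grand) ** 2).sum()
    subj_mean = y.groupby(subject)[dv].mean()
    ss_between_subj = k * ((subj_mean - grand) ** 2).sum()
    group_mean = y.groupby(between)[dv].mean()
    ss_group = n * k * ((group_mean - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    chan_mean = y.groupby(within)[dv].mean()
    ss_chan = N * ((chan_mean - grand) ** 2).sum()
    cell_mean = y.groupby([between, within])[dv].mean()
    ss_cells = n * ((cell_mean - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_chan
    ss_err_within = ss_total - ss_between_subj - ss_chan - ss_inter

    df_group, df_subj_w = g - 1, N - g
    df_chan = k - 1
    df_inter = (g - 1) * (k - 1)
    df_err_w = (N - g) * (k - 1)

    ms_group = ss_group / df_group
    ms_subj_w = ss_subj_within / df_subj_w
    ms_chan = ss_chan / df_chan
    ms_inter = ss_inter / df_inter
    ms_err_w = max(ss_err_within, 0.0) / df_err_w

    def _F(ms_eff: float, ms_err: float) -> float:
        return float(ms_eff / ms_err) if ms_err > 0 else 0.0

    # sphericity on the pooled within-group covariance of the k measures
    wide = data.pivot_table(index=[subject, between], columns=within, values=dv)
    wide = wide[w_levels]
    pooled = np.zeros((k, k))
    for gl in g_levels:
        sub = wide.xs(gl, level=between).to_numpy()
        pooled += (sub.shape[0] - 1) * np.cov(sub, rowvar=False)
    pooled /= N - g
    W, mauchly_p = mauchly_test(pooled, N - g)
    eps = gg_epsilon(pooled)
    correct = mauchly_p < sphericity_alpha

    effects: dict[str, EffectResult] = {}
    for name, F, d1, d2, within_effect in [
        ("group", _F(ms_group, ms_subj_w), df_group, df_subj_w, False),
        ("channel", _F(ms_chan, ms_err_w), df_chan, df_err_w, True),
        ("group*channel", _F(ms_inter, ms_err_w), df_inter, df_err_w, True),
    ]:
        p_unc = f_pvalue(F, d1, d2)
        if within_effect and correct:
            d1r, d2r = eps * d1, eps * d2
            p_rep = f_pvalue(F, d1r, d2r)
        else:
            d1r, d2r = float(d1), float(d2)
            p_rep = p_unc
        effects[name] = EffectResult(
            name, F, d1, d2, p_unc, p_rep, partial_eta_squared(F, d1, d2), d1r, d2r
        )

    result = AnovaResult(
        band=band,
        effects=effects,
        mauchly_W=W,
        mauchly_p=mauchly_p,
        gg_epsilon=eps,
        correction_applied=bool(correct),
        _context={
            "chan_means": {lv: float(chan_mean[lv]) for lv in w_levels},
            "group_means": {lv: float(group_mean[lv]) for lv in g_levels},
            "ms_err_within": float(ms_err_w),
            "df_err_within": df_err_w,
            "ms_subj_within": float(ms_subj_w),
            "df_subj_within": df_subj_w,
            "n_per_group": int(n),
            "n_subjects": int(N),
            "k": k,
        },
    )
    if run_lsd:
        for eff in ("channel", "group"):
            result.lsd[eff] = lsd_posthoc(result, eff)
            result.lsd_strings[eff] = ordering_string(
                result.lsd[eff], gate_p=result.effects[eff].p_reported
            )
    return result


def lsd_posthoc(fit: AnovaResult, effect: str) -> list[PairwiseComparison]:
    """Fisher LSD pairwise comparisons for 'channel' or 'group' marginal means.

    Uses the ANOVA's pooled error mean square and error df for the requested
    stratum; per-pair two-sided p, no multiplicity adjustment.
    """
    ctx = fit._context
    if not ctx:
        raise ValueError("AnovaResult carries no fit context")
    if effect == "channel":
        means = ctx["chan_means"]
        se = np.sqrt(2 * ctx["ms_err_within"] / ctx["n_subjects"])
        dof = ctx["df_err_within"]
    elif effect == "group":
        means = ctx["group_means"]
        se = np.sqrt(2 * ctx["ms_subj_within"] / (ctx["n_per_group"] * ctx["k"]))
        dof = ctx["df_subj_within"]
    else:
        raise ValueError(f"no such effect {effect!r}")
    levels = list(means)
    out = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            d = means[a] - means[b]
            t = d / se if se > 0 else 0.0
            p = 2 * float(sst.t.sf(abs(t), dof)) if se > 0 else 1.0
            out.append(PairwiseComparison(a, b, means[a], means[b], t, p))
    return out


def ordering_string(
    pairs: list[PairwiseComparison], gate_p: float = 0.0, alpha: float = 0.05
) -> str:
    """Render significant pairwise differences as 'A/B > C; D > E' or 'NA'.

    Shown only when the omnibus p (``gate_p``) is below 0.1 (significant or
    marginal).  Pairs enter at p < alpha.  Greater members sharing an
    identical set of lesser members are merged; members are listed in the
    canonical region order (PPN, SNc, STN, CPu, M1) when applicable,
    otherwise by descending marginal mean.
    """
    if gate_p >= 0.1:
        return "NA"
    greater_to_lesser: dict[str, set[str]] = {}
    means: dict[str, float] = {}
    for pc in pairs:
        means[pc.a], means[pc.b] = pc.mean_a, pc.mean_b
        if pc.p < alpha:
            hi, lo = (pc.a, pc.b) if pc.mean_a >= pc.mean_b else (pc.b, pc.a)
            greater_to_lesser.setdefault(hi, set()).add(lo)
    if not greater_to_lesser:
        return "NA"

    labels = set(means)
    if labels <= set(_CANONICAL_ORDER):
        order = {lab: i for i, lab in enumerate(_CANONICAL_ORDER)}
        key = lambda lab: order[lab]
    else:
        key = lambda lab: (-means[lab], lab)

    # merge greaters with identical lesser-sets
    merged: dict[frozenset, list[str]] = {}
    for hi, lows in greater_to_lesser.items():
        merged.setdefault(frozenset(lows), []).append(hi)
    parts = []
    for lows, his in merged.items():
        parts.append(
            ("/".join(sorted(his, key=key)), "/".join(sorted(lows, key=key)))
        )
    parts.sort(key=lambda ab: key(ab[0].split("/")[0]))
    return "; ".join(f"{a} > {b}" for a, b in parts)


# ---------------------------------------------------------------------------
# two-group test cascade
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    endpoint: str
    test_used: str  # 't' | 'mann_whitney'
    transform_used: str  # 'none' | 'log' | 'sqrt'
    statistic: float  # t or Z
    p: float
    significance_class: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.significance_class:
            self.significance_class = classify_significance(self.p)


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant sample")
    res = sst.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def levene(*groups: np.ndarray, center: str = "mean") -> tuple[float, float]:
    """Levene's test on absolute deviations from the group means (original form)."""
    if all(np.ptp(np.asarray(g, dtype=float)) == 0 for g in groups):
        return 0.0, 1.0
    res = sst.levene(*groups, center=center)
    return float(res.statistic), float(res.pvalue)


def independent_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2)."""
    res = sst.ttest_ind(x, y, equal_var=True)
    if np.isnan(res.statistic):  # both samples constant and equal
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected, continuity-corrected normal Z.

    Returns (U, Z, p).  p is exact for small untied samples (enumeration of
    rank assignments), otherwise the two-sided normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sst.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    U = float(res.statistic)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0
    allv = np.concatenate([x, y])
    nt = len(allv)
    _, counts = np.unique(allv, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term / (nt * (nt - 1)))
    if var <= 0:
        return U, 0.0, 1.0
    num = U - mu
    z = (num - 0.5 * np.sign(num)) / np.sqrt(var) if num != 0 else 0.0
    return U, float(z), float(res.pvalue)


def _assumptions_met(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> bool:
    try:
        _, p1 = shapiro_wilk(x)
        _, p2 = shapiro_wilk(y)
    except ValueError:
        return False
    _, pl = levene(x, y)
    return p1 >= alpha and p2 >= alpha and pl >= alpha


def select_and_run_test(
    x: np.ndarray, y: np.ndarray, endpoint: str = "", alpha: float = 0.05
) -> TestResult:
    """Assumption-driven choice between pooled t and Mann-Whitney U.

    Cascade: test normality (Shapiro-Wilk per group) and variance
    homogeneity (Levene); if violated, retest after log (positive data
    only) then sqrt (non-negative data only) transforms; run the pooled t
    on the first scale passing, else fall back to Mann-Whitney on the
    original data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    notes = []
    candidates: list[tuple[str, np.ndarray, np.ndarray]] = [("none", x, y)]
    if np.all(x > 0) and np.all(y > 0):
        candidates.append(("log", np.log(x), np.log(y)))
    else:
        notes.append("log transform skipped (non-positive values)")
    if np.all(x >= 0) and np.all(y >= 0):
        candidates.append(("sqrt", np.sqrt(x), np.sqrt(y)))
    else:
        notes.append("sqrt transform skipped (negative values)")
    for transform, xt, yt in candidates:
        if _assumptions_met(xt, yt, alpha):
            t, p = independent_t(xt, yt)
            return TestResult(endpoint, "t", transform, t, p, notes="; ".join(notes))
    _, z, p = mann_whitney(x, y)
    notes.append("assumptions not met on any scale; Mann-Whitney used")
    return TestResult(endpoint, "mann_whitney", "none", z, p, notes="; ".join(notes))
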