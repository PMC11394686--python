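"""Behavioral endpoints: cylinder asymmetry, gait support percentages,
and group summaries with assumption-driven testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, select_and_run_test
from .synth import GAIT_CLASSES


@dataclass
class CylinderCounts:
    """Forelimb wall-touch counts from one rearing-cylinder trial."""

    touches_injection_side: int
    touches_non_injection_side: int
    touches_both: int

    def __post_init__(self) -> None:
        if min(self.touches_injection_side, self.touches_non_injection_side, self.touches_both) < 0:
            raise ValueError("touch counts must be >= 0")


def asymmetry_ratio(c: CylinderCounts) -> float:
    """Forelimb-use asymmetry in percent:
    (injection - non_injection) / (injection + non_injection + both) * 100.

    Positive values mean a preference for the injection-side forelimb.
    """
    total = c.touches_injection_side + c.touches_non_injection_side + c.touches_both
    if total == 0:
        raise ValueError("asymmetry ratio undefined: no touches recorded")
    return 100.0 * (c.touches_injection_side - c.touches_non_injection_side) / total


def support_percentages(frames: list[str] | np.ndarray | pd.Series) -> dict[str, float]:
    """Per-class percentage of video frames; classes partition the frames,
    so the percentages sum to 100 exactly."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames supplied")
    unknown = set(frames) - set(GAIT_CLASSES)
    if unknown:
        raise ValueError(f"unknown gait classes {sorted(unknown)}")
    n = len(frames)
    return {c: 100.0 * frames.count(c) / n for c in GAIT_CLASSES}


def cylinder_table_to_ratios(cylinder: pd.DataFrame) -> pd.DataFrame:
    """Per-subject asymmetry ratios from a cylinder-count table."""
    out = cylinder[["subject", "group"]].copy()
    out["asymmetry_pct"] = [
        asymmetry_ratio(
            CylinderCounts(r.touches_injection, r.touches_non_injection, r.touches_both)
        )
        for r in cylinder.itertuples()
    ]
    return out


def gait_table_to_percentages(gait: pd.DataFrame) -> pd.DataFrame:
    """Per-subject support percentages from frame-count columns."""
    out = gait[["subject", "group"]].copy()
    counts = gait[[f"frames_{c}" for c in GAIT_CLASSES]].to_numpy(dtype=float)
    total = counts.sum(axis=1)
    if np.any(total == 0):
        raise ValueError("subject with zero gait frames")
    pct = 100.0 * counts / total[:, None]
    for j, c in enumerate(GAIT_CLASSES):
        out[f"{c}_pct"] = pct[:, j]
    return out


def summarize_endpoints(
    tables: dict[str, pd.DataFrame], group_col: str = "group"
) -> pd.DataFrame:
    """Group mean +/- SD and the selected two-group test for every endpoint.

    ``tables`` is the dict produced by the synthetic generator (or any
    tables with the same schemas): 'endpoints' (one numeric column per
    endpoint), optional 'cylinder' and 'gait' raw-count tables, which are
    reduced to asymmetry and support percentages first.  Multi-trial
    endpoints are assumed already aggregated to one row per subject.
    """
    frames: list[pd.DataFrame] = []
    if "endpoints" in tables:
        frames.append(tables["endpoints"])
    if "cylinder" in tables:
        frames.append(cylinder_table_to_ratios(tables["cylinder"]))
    if "gait" in tables:
        g = gait_table_to_percentages(tables["gait"])
        # 'other' support classes are reported but not tested
        frames.append(g[["subject", "group", "diagonal_pct", "three_limb_pct"]])
    if not frames:
        raise ValueError("no endpoint tables supplied")
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on=["subject", group_col], how="outer")

    rows = []
    for col in merged.columns:
        if col in ("subject", group_col):
            continue
        sub = merged[[group_col, col]].dropna()
        groups = {g: v[col].to_numpy(dtype=float) for g, v in sub.groupby(group_col)}
        if len(groups) != 2 or any(len(v) < 2 for v in groups.values()):
            raise ValueError(f"endpoint {col!r}: need two groups with >= 2 subjects each")
        if set(groups) == {"lesion", "sham"}:  # sign convention: lesion - sham
            (g1, x), (g2, y) = ("lesion", groups["lesion"]), ("sham", groups["sham"])
        else:
            (g1, x), (g2, y) = sorted(groups.items())
        res: TestResult = select_and_run_test(x, y, endpoint=col)
        rows.append(
            {
                "endpoint": col,
                f"{g1}_mean": x.mean(),
                f"{g1}_sd": x.std(ddof=1),
                f"{g2}_mean": y.mean(),
                f"{g2}_sd": y.std(ddof=1),
                "test_used": res.test_used,
                "transform_used": res.transform_used,
                "statistic": res.statistic,
                "p": res.p,
                "significance": res.significance_class,
            }
        )
    return pd.DataFrame(rows)
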