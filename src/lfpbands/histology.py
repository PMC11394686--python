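"""TH+ neuron density, percent loss vs sham, and group comparison.

Density is the area-normalized count (cells/mm^2) per slice; a subject's
density is the mean over its (typically three) slices, and percent loss is
computed on the group means relative to sham.
"""

from __future__ import annotations

import pandas as pd

from .stats import TestResult, select_and_run_test

SIDES = ("injection", "non_injection")


def subject_density(slices: pd.DataFrame) -> float:
    """Mean per-slice density (count/area) for one subject x side."""
    if slices.empty:
        raise ValueError("no slices supplied")
    if slices["subject"].nunique() != 1 or slices["side"].nunique() != 1:
        raise ValueError("slices must come from a single subject and side")
    if (slices["area_mm2"] <= 0).any():
        raise ValueError("slice area must be positive")
    return float((slices["th_count"] / slices["area_mm2"]).mean())


def density_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per subject x side mean density from a slice-level count table."""
    dens = counts.assign(density=counts["th_count"] / counts["area_mm2"])
    if (counts["area_mm2"] <= 0).any():
        raise ValueError("slice area must be positive")
    return (
        dens.groupby(["subject", "group", "side"], as_index=False)["density"]
        .mean()
        .rename(columns={"density": "density_per_mm2"})
    )


def percent_loss(lesion_mean: float, sham_mean: float) -> float:
    """(1 - lesion/sham) * 100 — dopaminergic-neuron loss relative to sham."""
    if sham_mean <= 0:
        raise ValueError("sham mean density must be positive")
    return 100.0 * (1.0 - lesion_mean / sham_mean)


def compare_groups(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-side percent loss and lesion-vs-sham test on subject densities."""
    dens = density_table(counts)
    rows = []
    for side in SIDES:
        sub = dens[dens["side"] == side]
        lesion = sub[sub["group"] == "lesion"]["density_per_mm2"].to_numpy()
        sham = sub[sub["group"] == "sham"]["density_per_mm2"].to_numpy()
        if len(lesion) < 3 or len(sham) < 3:
            raise ValueError(f"side {side!r}: need >= 3 subjects per group")
        res: TestResult = select_and_run_test(lesion, sham, endpoint=f"th_density_{side}")
        rows.append(
            {
                "side": side,
                "sham_mean": sham.mean(),
                "lesion_mean": lesion.mean(),
                "percent_loss": percent_loss(lesion.mean(), sham.mean()),
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p": res.p,
                "significance": res.significance_class,
            }
        )
    return pd.DataFrame(rows)
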