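"""Robust-miRNA selection: positive-call rate and two-cohort concentration
linearity.

A miRNA is robust when its positive-call rate in the exploratory set exceeds
the call-rate threshold, its log2 signal is linear against the Int-con
signal (a proxy for total serum miRNA concentration) with Pearson rsq > 0.5
in both cohorts, and the regression slopes of the two cohorts differ by less
than 0.1. All inequalities are strict except where noted. The two cohorts
are independent healthy populations (exploratory healthy vs a reference
set); consistent unit slope against Int-con across populations is the
robustness signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import DataError


@dataclass
class RobustSet:
    """miRNAs passing all robustness criteria, with the per-miRNA table."""

    mirna_ids: list
    table: pd.DataFrame  # call_rate, slope/rsq per cohort, slope_difference, robust


def call_rate(calls: pd.DataFrame, sample_ids=None) -> pd.Series:
    """Fraction of positive calls per miRNA over the given samples."""
    block = calls if sample_ids is None else calls[list(sample_ids)]
    if block.shape[1] == 0:
        raise DataError("call rate over an empty sample set")
    return block.mean(axis=1).rename("call_rate")


def linearity(log2_signals: pd.DataFrame, intcon: pd.Series) -> pd.DataFrame:
    """Per-miRNA OLS of log2 signal (y) on Int-con (x): slope and Pearson rsq.

    A constant y gives slope 0 and rsq 0 by convention; constant x is an
    error (no concentration spread to regress against).
    """
    x = intcon.loc[log2_signals.columns].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise DataError("linearity requires >= 3 samples")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DataError("Int-con has zero variance; cannot assess linearity")
    Y = log2_signals.to_numpy(dtype=float)
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxy = yc @ xc
    syy = np.einsum("ij,ij->i", yc, yc)
    slope = sxy / sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        rsq = np.where(syy > 0, (sxy**2) / (sxx * syy), 0.0)
    slope = np.where(syy > 0, slope, 0.0)
    return pd.DataFrame({"slope": slope, "rsq": rsq}, index=log2_signals.index)


def select_robust(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    rates: pd.Series,
    rate_threshold: float = 0.90,
    rsq_threshold: float = 0.5,
    slope_diff_threshold: float = 0.1,
) -> RobustSet:
    """Combine the two cohorts' linearity statistics and call rates.

    Membership: rate > rate_threshold AND rsq > rsq_threshold in both
    cohorts AND |slope_a - slope_b| < slope_diff_threshold.
    """
    if set(stats_a.index) != set(stats_b.index):
        only = set(stats_a.index) ^ set(stats_b.index)
        raise DataError(f"miRNA(s) present in one cohort only: {sorted(only)}")
    b = stats_b.loc[stats_a.index]
    table = pd.DataFrame(
        {
            "call_rate": rates.loc[stats_a.index],
            "slope_a": stats_a["slope"],
            "rsq_a": stats_a["rsq"],
            "slope_b": b["slope"],
            "rsq_b": b["rsq"],
        }
    )
    table["slope_difference"] = (table["slope_a"] - table["slope_b"]).abs()
    table["robust"] = (
        (table["call_rate"] > rate_threshold)
        & (table["rsq_a"] > rsq_threshold)
        & (table["rsq_b"] > rsq_threshold)
        & (table["slope_difference"] < slope_diff_threshold)
    )
    return RobustSet(mirna_ids=list(table.index[table["robust"]]), table=table)
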