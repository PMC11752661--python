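"""Raw signals -> normalized expression: positive calls, imputation,
internal-control normalization.

The positive-call threshold for a sample is mean + 2 x SD (n-1 denominator)
of that sample's negative-control signals after removing exactly the highest
and the lowest one. Missing values are imputed with the miRNA's mean signal
over non-missing samples of the same analysis set, on the raw linear scale.
Each log2 signal is then normalized by subtracting the per-sample mean of
the three log2 internal-control signals (Int-con); per-sample multiplicative
rescaling of all signals therefore leaves normalized values exactly
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import DataError, NormalizedMatrix, SignalMatrix


@dataclass
class CallMatrix:
    """Per-probe boolean positive calls with the per-sample threshold used."""

    calls: pd.DataFrame  # target probe x sample booleans
    thresholds: pd.Series  # per-sample linear-scale threshold

    def __post_init__(self) -> None:
        if not np.isfinite(self.thresholds).all():
            raise DataError("non-finite positive-call threshold")


def detect_positive_calls(matrix: SignalMatrix) -> CallMatrix:
    """Positive call = linear signal strictly above the trimmed
    negative-control threshold; a missing signal is never a call."""
    neg = matrix.values.loc[matrix.negative_control_ids]
    thresholds = {}
    for sample in matrix.values.columns:
        vals = neg[sample].dropna().to_numpy()
        if vals.size < 4:
            raise DataError(
                f"sample {sample!r} has {vals.size} negative-control signals; >= 4 required to trim one extreme each"
            )
        trimmed = np.sort(vals)[1:-1]
        thresholds[sample] = trimmed.mean() + 2.0 * trimmed.std(ddof=1)
    thresholds = pd.Series(thresholds, name="threshold")
    targets = matrix.values.loc[matrix.target_ids]
    calls = targets.gt(thresholds, axis=1) & targets.notna()
    return CallMatrix(calls=calls, thresholds=thresholds)


def impute_missing(matrix: SignalMatrix) -> SignalMatrix:
    """Replace missing signals by the miRNA's mean over non-missing samples
    of the same analysis set (raw linear scale); observed values untouched."""
    values = matrix.values.copy()
    if matrix.metadata is not None and "analysis_set" in matrix.metadata.columns:
        groups = matrix.metadata["analysis_set"]
    else:
        groups = pd.Series("all", index=values.columns)
    for _, cols in values.columns.to_series().groupby(groups.to_numpy()):
        block = values[cols.index]
        means = block.mean(axis=1)
        all_missing = block.isna().all(axis=1)
        if all_missing.any():
            bad = values.index[all_missing].tolist()
            raise DataError(f"miRNA(s) with all values missing in a set: {bad}")
        filled = block.apply(lambda col: col.fillna(means))
        values[cols.index] = filled
    return SignalMatrix(values=values, annotation=matrix.annotation.copy(), metadata=matrix.metadata)


def normalize_to_internal_controls(matrix: SignalMatrix) -> NormalizedMatrix:
    """log2-transform and subtract the per-sample Int-con mean; control
    probes are dropped from the output value block."""
    ic = matrix.values.loc[matrix.internal_control_ids]
    if ic.isna().any().any() or (ic <= 0).any().any():
        bad = ic.columns[(ic.isna() | (ic <= 0)).any(axis=0)].tolist()
        raise DataError(f"internal-control signal missing or <= 0 in sample(s): {bad}")
    intcon = np.log2(ic).mean(axis=0)
    intcon.name = "intcon"
    targets = matrix.values.loc[matrix.target_ids]
    if targets.isna().any().any():
        raise DataError("missing target signals remain; impute before normalization")
    if (targets <= 0).any().any():
        raise DataError("non-positive target signals cannot be log2-transformed")
    values = np.log2(targets).sub(intcon, axis=1)
    return NormalizedMatrix(values=values, intcon=intcon, metadata=matrix.metadata)


def log2_target_signals(matrix: SignalMatrix) -> pd.DataFrame:
    """log2 of the (imputed) raw target signals, for concentration-linearity
    checks against the Int-con signal."""
    targets = matrix.values.loc[matrix.target_ids]
    if targets.isna().any().any() or (targets <= 0).any().any():
        raise DataError("log2 target signals require imputed, positive values")
    return np.log2(targets)


def preprocess(matrix: SignalMatrix) -> tuple[CallMatrix, NormalizedMatrix]:
    """Convenience driver: calls -> imputation -> normalization."""
    calls = detect_positive_calls(matrix)
    imputed = impute_missing(matrix)
    return calls, normalize_to_internal_controls(imputed)
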