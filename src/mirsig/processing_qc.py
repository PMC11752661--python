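"""Pre-analytic QC: storage time-course summaries and embedding-based
group-separation scoring.

The time-course summary reports, per comparison time vs baseline, each
miRNA's subject-averaged change in normalized level (log2 units) and the
mean +/- SD of those changes across miRNAs — the variation statistic used
to define stable serum processing. The embedding stage maps a marker panel
to 2-D with t-SNE and replaces visual inspection of group overlap by the
mean silhouette of the group labels in the embedding (score in [-1, 1];
~0 means inseparable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .dataio import DataError, NormalizedMatrix

#: default silhouette above which groups are reported as separated
DEFAULT_SEPARATION_THRESHOLD = 0.25


@dataclass
class TimecourseSummary:
    deltas: pd.DataFrame  # miRNA x time, subject-averaged change vs baseline
    summary: pd.DataFrame  # per time: mean and SD of deltas across miRNAs
    baseline_time: float


@dataclass
class EmbeddingReport:
    coordinates: pd.DataFrame  # sample x (x, y)
    labels: pd.Series
    separation_score: float


def summarize_timecourse(series: dict, baseline_time: float | None = None) -> TimecourseSummary:
    """Per-miRNA drift vs baseline across a {time: NormalizedMatrix} series.

    All time points must cover the same miRNAs and subjects; the baseline
    defaults to the earliest time.
    """
    if not series:
        raise DataError("empty time-course series")
    times = sorted(series)
    baseline_time = times[0] if baseline_time is None else float(baseline_time)
    if baseline_time not in series:
        raise DataError(f"baseline time {baseline_time} not in series")
    base = series[baseline_time]
    for t in times:
        m = series[t]
        if list(m.values.index) != list(base.values.index) or list(m.values.columns) != list(base.values.columns):
            raise DataError(f"miRNA/subject mismatch between t={t} and baseline")
    deltas = pd.DataFrame(
        {t: (series[t].values - base.values).mean(axis=1) for t in times}
    )
    summary = pd.DataFrame({"mean": deltas.mean(axis=0), "sd": deltas.std(axis=0, ddof=1)})
    summary.index.name = "time_min"
    return TimecourseSummary(deltas=deltas, summary=summary, baseline_time=baseline_time)


def embed_and_score(
    normalized: NormalizedMatrix | pd.DataFrame,
    labels: pd.Series,
    panel=None,
    perplexity: float = 30.0,
    seed: int = 0,
) -> EmbeddingReport:
    """2-D t-SNE of the (panel-restricted) expression with a silhouette
    separation score for the given group labels."""
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    if panel is not None:
        missing = [m for m in panel if m not in values.index]
        if missing:
            raise DataError(f"panel miRNA(s) absent: {missing}")
        values = values.loc[list(panel)]
    if values.shape[0] < 2:
        raise DataError("panel must contain at least 2 miRNAs")
    labels = labels.loc[values.columns]
    counts = labels.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise DataError(f"label(s) with < 2 samples: {small}")
    n = values.shape[1]
    if n <= 3 * perplexity:
        raise DataError("need n samples > 3 x perplexity")
    emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca").fit_transform(
        values.T.to_numpy(dtype=float)
    )
    coords = pd.DataFrame(emb, index=values.columns, columns=["x", "y"])
    score = float(silhouette_score(emb, labels.to_numpy()))
    return EmbeddingReport(coordinates=coords, labels=labels, separation_score=score)
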