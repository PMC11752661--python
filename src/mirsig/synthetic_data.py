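"""Synthetic serum-miRNA cohorts with the structure the pipeline assumes.

The generator emulates, on the log2 scale: a per-sample total-concentration
factor tracked by three internal-control probes; block-correlated miRNA
modules driven by shared latent factors; disease effects on designated
modules (one up-, one down-regulated by default); a storage-time degradation
drift on designated modules beyond a 120-min room-temperature lag;
negative-control probes that are pure linear-scale noise; signal censoring
below a detection threshold; and clinical traits (CA19-9, CEA, cT/cN/cM,
platelets) correlated with disease status.

Signals are generated in log2 space and exponentiated to linear scale for
the :class:`~mirsig.dataio.SignalMatrix`, matching microarray convention:
the positive-call rule downstream operates on linear signals.

The miRNA-level parameters (baseline offsets, module membership, loadings)
are a deterministic function of the seed, so cohorts generated for different
analysis sets share the same probes and planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import DEFAULT_INTERNAL_CONTROLS, SignalMatrix, make_annotation

#: room-temperature serum storage beyond this lag (minutes) degrades signals
DEGRADATION_LAG_MIN = 120.0

_SET_STREAMS = {"exploratory": 1, "validation": 2, "independent_validation": 3, "timecourse": 4}
_SET_PREFIX = {"exploratory": "EXP", "validation": "VAL", "independent_validation": "IVL", "timecourse": "REF"}


@dataclass
class TraitModel:
    """Effect sizes linking disease status to the clinical traits.

    CA19-9 and CEA are log2-normal; healthy mean/SD plus an additive disease
    effect (log2 units). Tumor scores are categorical among cases, 0 for
    healthy. Defaults give a synthetic CA19-9 AUC near the cohort's reported
    value (~0.83).
    """

    log_ca199_mean: float = 3.8
    log_ca199_sd: float = 1.1
    log_ca199_effect: float = 1.5
    log_cea_mean: float = 1.0
    log_cea_sd: float = 0.8
    log_cea_effect: float = 0.7
    ct_probs: tuple = (0.15, 0.35, 0.35, 0.15)  # cT 1..4 among cases
    cn_probs: tuple = (0.5, 0.5)  # cN 1..2 among cases
    cm_probs: tuple = (0.8, 0.2)  # cM 1..2 among cases
    platelet_mean: float = 25.0
    platelet_sd: float = 5.0


@dataclass
class SyntheticConfig:
    """Cohort-scale defaults: 150 healthy + 134 PBca, 600 miRNAs in 12
    modules (sizes 20-80), one up- and one down-regulated disease module,
    one storage-degradation module."""

    n_healthy: int = 150
    n_pbca: int = 134
    n_mirna: int = 600
    module_sizes: tuple = (80, 70, 65, 60, 55, 50, 50, 45, 40, 35, 30, 20)
    disease_modules: dict = field(default_factory=lambda: {8: 0.9, 9: -0.9})
    disturbance_modules: dict = field(default_factory=lambda: {10: 0.02})
    within_module_corr: float = 0.7
    noise_sd: float = 0.4
    concentration_sd: float = 2.0
    mirna_baseline_sd: float = 1.0
    intcon_sd: float = 0.1
    intcon_base: float = 10.0
    detection_threshold: float = 4.0  # linear signal; well below the call threshold
    base_signal: float = 9.0  # log2
    n_negative_controls: int = 20
    negctrl_mean: float = 20.0  # linear
    negctrl_sd: float = 5.0
    storage_min_range: tuple = (15.0, 180.0)
    blood_processing_range: tuple = (20.0, 120.0)
    trait_model: TraitModel = field(default_factory=TraitModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna <= 0 or self.n_healthy < 0 or self.n_pbca < 0:
            raise ValueError("counts must be positive")
        if sum(self.module_sizes) > self.n_mirna:
            raise ValueError("sum(module_sizes) exceeds n_mirna")
        for idx in list(self.disease_modules) + list(self.disturbance_modules):
            if not 0 <= idx < len(self.module_sizes):
                raise ValueError(f"module index {idx} out of range")
        if not 0 < self.within_module_corr < 1:
            raise ValueError("within_module_corr must lie in (0, 1)")


def module_loading(within_module_corr: float, noise_sd: float) -> float:
    """Latent-factor loading giving the requested within-module pairwise
    correlation: lambda^2 / (lambda^2 + noise_sd^2) = rho."""
    rho = within_module_corr
    return noise_sd * np.sqrt(rho / (1.0 - rho))


def planted_structure(config: SyntheticConfig) -> pd.DataFrame:
    """Per-miRNA planted truth: module id (1-based, 0 = none), baseline
    offset, disease effect (log2), and degradation slope (log2/min)."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_mirna
    ids = [f"miR-synth-{i:04d}" for i in range(n)]
    module = np.zeros(n, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        module[pos : pos + size] = m + 1
        pos += size
    offsets = rng.normal(0.0, config.mirna_baseline_sd, size=n)
    effect = np.zeros(n)
    for m, eff in config.disease_modules.items():
        effect[module == m + 1] = eff
    slope = np.zeros(n)
    for m, s in config.disturbance_modules.items():
        slope[module == m + 1] = s
    lam = np.where(module > 0, module_loading(config.within_module_corr, config.noise_sd), 0.0)
    return pd.DataFrame(
        {"module": module, "offset": offsets, "disease_effect": effect, "drift_slope": slope, "loading": lam},
        index=pd.Index(ids, name="mirna_id"),
    )


def _draw_metadata(config, rng, n_healthy, n_pbca, prefix, analysis_set):
    tm = config.trait_model
    n = n_healthy + n_pbca
    y = np.r_[np.zeros(n_healthy, dtype=int), np.ones(n_pbca, dtype=int)]
    ids = [f"{prefix}{i:04d}" for i in range(n)]
    log_ca199 = rng.normal(tm.log_ca199_mean + tm.log_ca199_effect * y, tm.log_ca199_sd)
    log_cea = rng.normal(tm.log_cea_mean + tm.log_cea_effect * y, tm.log_cea_sd)
    ct = np.where(y == 1, rng.choice(np.arange(1, 5), size=n, p=tm.ct_probs), 0)
    cn = np.where(y == 1, rng.choice(np.arange(1, 3), size=n, p=tm.cn_probs), 0)
    cm = np.where(y == 1, rng.choice(np.arange(1, 3), size=n, p=tm.cm_probs), 0)
    storage = rng.uniform(*config.storage_min_range, size=n)
    blood = rng.uniform(*config.blood_processing_range, size=n)
    platelet = rng.normal(tm.platelet_mean, tm.platelet_sd, size=n)
    meta = pd.DataFrame(
        {
            "cohort": np.where(y == 1, "pbca", "healthy"),
            "analysis_set": analysis_set,
            "disease_score": y,
            "log_cea": log_cea,
            "log_ca199": log_ca199,
            "ca199_linear": np.exp2(log_ca199),
            "ct_score": ct,
            "cn_score": cn,
            "cm_score": cm,
            "serum_storage_min": storage,
            "blood_processing_min": blood,
            "platelet_count": platelet,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return meta


def _assemble(config, truth, meta, rng, storage_override=None):
    """Draw the probe x sample linear signal matrix for the given samples."""
    n = len(meta)
    y = meta["disease_score"].to_numpy()
    storage = meta["serum_storage_min"].to_numpy() if storage_override is None else storage_override
    conc = rng.normal(0.0, config.concentration_sd, size=n)
    n_modules = len(config.module_sizes)
    factors = rng.normal(0.0, 1.0, size=(n_modules + 1, n))  # row 0 unused
    drift_time = np.maximum(0.0, storage - DEGRADATION_LAG_MIN)
    log2_target = (
        config.base_signal
        + truth["offset"].to_numpy()[:, None]
        + conc[None, :]
        + truth["loading"].to_numpy()[:, None] * factors[truth["module"].to_numpy(), :]
        + truth["disease_effect"].to_numpy()[:, None] * y[None, :]
        + truth["drift_slope"].to_numpy()[:, None] * drift_time[None, :]
        + rng.normal(0.0, config.noise_sd, size=(len(truth), n))
    )
    target_linear = np.exp2(log2_target)
    target_linear[target_linear < config.detection_threshold] = np.nan  # censored

    intcon_log2 = config.intcon_base + conc[None, :] + rng.normal(0.0, config.intcon_sd, size=(3, n))
    negctrl = np.clip(rng.normal(config.negctrl_mean, config.negctrl_sd, size=(config.n_negative_controls, n)), 0.0, None)

    neg_ids = [f"NC-{i:02d}" for i in range(config.n_negative_controls)]
    values = pd.DataFrame(
        np.vstack([target_linear, negctrl, np.exp2(intcon_log2)]),
        index=list(truth.index) + neg_ids + list(DEFAULT_INTERNAL_CONTROLS),
        columns=meta.index,
    )
    annotation = make_annotation(list(truth.index), neg_ids, DEFAULT_INTERNAL_CONTROLS)
    return SignalMatrix(values=values, annotation=annotation, metadata=meta)


def generate_dataset(
    config: SyntheticConfig,
    analysis_set: str = "exploratory",
    n_healthy: int | None = None,
    n_pbca: int | None = None,
) -> SignalMatrix:
    """Generate one cohort as a raw :class:`SignalMatrix`.

    The same config and seed give byte-identical output; different analysis
    sets use independent sample streams but share the planted miRNA
    structure.
    """
    if analysis_set not in _SET_STREAMS:
        raise ValueError(f"unknown analysis_set {analysis_set!r}")
    n_healthy = config.n_healthy if n_healthy is None else n_healthy
    n_pbca = config.n_pbca if n_pbca is None else n_pbca
    if n_healthy + n_pbca <= 0:
        raise ValueError("cohort must contain at least one sample")
    truth = planted_structure(config)
    rng = np.random.default_rng([config.seed, _SET_STREAMS[analysis_set]])
    meta = _draw_metadata(config, rng, n_healthy, n_pbca, _SET_PREFIX[analysis_set], analysis_set)
    return _assemble(config, truth, meta, rng)


def generate_timecourse(config: SyntheticConfig, times_min, n_subjects: int) -> dict:
    """Serum storage time-course: the same subjects measured at each time.

    Subject-level latents (concentration, module factors, traits) are drawn
    once; measurement noise is fresh per time point. Disturbance-module
    miRNAs drift by slope x (t - 120 min) for t > 120 min; all other miRNAs
    are stable. Returns ``{time: SignalMatrix}``.
    """
    times = sorted(float(t) for t in times_min)
    if not times:
        raise ValueError("times_min must be non-empty")
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    truth = planted_structure(config)
    rng = np.random.default_rng([config.seed, _SET_STREAMS["timecourse"], 1])
    meta = _draw_metadata(config, rng, n_subjects, 0, "TC", "timecourse")
    # freeze subject latents by re-using one rng stream per time point but
    # drawing conc/factors once
    n = n_subjects
    conc = rng.normal(0.0, config.concentration_sd, size=n)
    factors = rng.normal(0.0, 1.0, size=(len(config.module_sizes) + 1, n))
    out = {}
    for t in times:
        noise_rng = np.random.default_rng([config.seed, _SET_STREAMS["timecourse"], 2, int(round(t * 1000))])
        meta_t = meta.copy()
        meta_t["serum_storage_min"] = t
        drift = max(0.0, t - DEGRADATION_LAG_MIN)
        log2_target = (
            config.base_signal
            + truth["offset"].to_numpy()[:, None]
            + conc[None, :]
            + truth["loading"].to_numpy()[:, None] * factors[truth["module"].to_numpy(), :]
            + truth["drift_slope"].to_numpy()[:, None] * drift
            + noise_rng.normal(0.0, config.noise_sd, size=(len(truth), n))
        )
        target_linear = np.exp2(log2_target)
        target_linear[target_linear < config.detection_threshold] = np.nan
        intcon_log2 = config.intcon_base + conc[None, :] + noise_rng.normal(0.0, config.intcon_sd, size=(3, n))
        negctrl = np.clip(
            noise_rng.normal(config.negctrl_mean, config.negctrl_sd, size=(config.n_negative_controls, n)), 0.0, None
        )
        neg_ids = [f"NC-{i:02d}" for i in range(config.n_negative_controls)]
        values = pd.DataFrame(
            np.vstack([target_linear, negctrl, np.exp2(intcon_log2)]),
            index=list(truth.index) + neg_ids + list(DEFAULT_INTERNAL_CONTROLS),
            columns=meta_t.index,
        )
        annotation = make_annotation(list(truth.index), neg_ids, DEFAULT_INTERNAL_CONTROLS)
        out[t] = SignalMatrix(values=values, annotation=annotation, metadata=meta_t)
    return out
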