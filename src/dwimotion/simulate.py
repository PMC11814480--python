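"""Synthetic data with the statistical structure the analyses assume.

The real study cohorts are controlled-access; this module generates
stand-ins for every input the pipelines consume:

- per-volume rigid motion traces: a Gaussian random-walk drift plus
  sparse persistent jumps, with anterior–posterior translation and
  left–right-axis rotation dominant (the directions least constrained
  by head padding);
- lifespan cohorts with a U-shaped age–motion curve (elevated in
  childhood, flat through adulthood, rising in old age, more outliers
  with age) and motion offsets increasing across the CN < CI < AD
  diagnostic spectrum;
- paired scan–rescan bundle feature tables with a shared per-subject
  latent value, independent within-subject noise, and an injectable
  multiplicative motion bias on the more-motion scan;
- random symmetric 84-node weighted connectomes per scan.

Every generator is a pure function of (config, seed): repeated calls
are byte-identical. Substreams are derived per operation name so adding
a generator never perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eddy_io import AcquisitionMeta, MotionTrace, RMSSeries
from .errors import ValidationError
from .graph_metrics import METRIC_NAMES, Connectome, global_metrics
from .motion_descriptors import MotionSummary, summarize_scan
from .rigid_kinematics import BrainMask, make_spherical_mask, trace_to_rms_series

__all__ = [
    "TraceSimConfig",
    "CohortSimConfig",
    "FeatureSimConfig",
    "DEFAULT_BUNDLES",
    "MICRO_MEASURES",
    "MACRO_MEASURES",
    "simulate_motion_trace",
    "simulate_scan",
    "simulate_cohort",
    "simulate_paired_features",
    "simulate_paired_matrices",
    "default_mask",
]

# 25 bilateral white-matter pathway names (TractSeg nomenclature),
# left/right expanded to the 50-bundle default analysis set.
_BILATERAL = (
    "AF", "ATR", "CG", "CST", "FPT", "ICP", "IFO", "ILF", "MLF", "OR",
    "POPT", "SCP", "SLF_I", "SLF_II", "SLF_III", "STR", "UF",
    "T_PREF", "T_PREM", "T_PREC", "T_POSTC", "T_PAR", "T_OCC",
    "ST_FO", "ST_PREF",
)
DEFAULT_BUNDLES: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _BILATERAL for side in ("left", "right")
)

MICRO_MEASURES = ("FA", "MD", "AD", "RD")
MACRO_MEASURES = (
    "volume",
    "endpoint_volume",
    "mean_length",
    "std_length",
    "min_length",
    "max_length",
    "mean_curvature",
)

# Population means and (between-subject sd, within-subject scan-rescan sd)
# for each measure. Diffusivities in um^2/ms, volumes in mm^3, lengths in
# mm. Within-subject sds sit near 1%-2% of the mean — typical same-session
# scan-rescan repeatability of tractometry features.
FEATURE_POPULATIONS: dict[str, tuple[float, float, float]] = {
    "FA": (0.45, 0.03, 0.005),
    "MD": (0.80, 0.05, 0.008),
    "AD": (1.20, 0.07, 0.010),
    "RD": (0.60, 0.05, 0.008),
    "volume": (15000.0, 3000.0, 150.0),
    "endpoint_volume": (4000.0, 800.0, 60.0),
    "mean_length": (80.0, 8.0, 0.8),
    "std_length": (15.0, 3.0, 0.4),
    "min_length": (20.0, 5.0, 0.8),
    "max_length": (150.0, 15.0, 1.5),
    "mean_curvature": (0.05, 0.008, 0.0008),
}


def _rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic substream: mixes the global seed with a CRC of the
    operation name so streams are independent and stable."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class TraceSimConfig:
    """Per-scan motion trace generator settings.

    The defaults are calibrated so a typical adult scan (40 volumes,
    TR 4 s, 80 mm mask) lands near 0.1 mm/vol ≈ 1.5 mm/min — the middle
    of the adult range reported across large consortium cohorts.
    ``anisotropy_*`` multiply the per-axis step sds; the defaults make
    AP (y) translation and LR-axis (x) rotation dominant.
    """

    n_volumes: int = 40
    tr_seconds: float = 4.0
    drift_sd_trans: float = 0.030  # mm per volume per axis, before anisotropy
    drift_sd_rot: float = 0.00045  # rad per volume per axis, before anisotropy
    jump_rate: float = 0.03  # probability per volume of a persistent jump
    jump_scale_trans: float = 0.35  # mm, jump offset sd before anisotropy
    jump_scale_rot: float = 0.0045  # rad
    anisotropy_trans: tuple[float, float, float] = (1.0, 2.0, 1.0)
    anisotropy_rot: tuple[float, float, float] = (2.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jump_rate <= 1.0:
            raise ValidationError("jump_rate must lie in [0, 1]")
        if min(self.drift_sd_trans, self.drift_sd_rot, self.jump_scale_trans,
               self.jump_scale_rot) < 0:
            raise ValidationError("scales must be non-negative")
        if self.n_volumes < 2:
            raise ValidationError("n_volumes must be at least 2")

    def scaled(self, factor: float) -> "TraceSimConfig":
        """A config with all motion amplitudes multiplied by ``factor``
        (jump probability unchanged)."""
        return replace(
            self,
            drift_sd_trans=self.drift_sd_trans * factor,
            drift_sd_rot=self.drift_sd_rot * factor,
            jump_scale_trans=self.jump_scale_trans * factor,
            jump_scale_rot=self.jump_scale_rot * factor,
        )


@dataclass(frozen=True)
class CohortSimConfig:
    """Lifespan cohort generator settings.

    The age–motion curve is piecewise: exponential childhood decay of
    amplitude ``child_amp`` and time-scale ``child_tau`` (years) down to
    an adult floor, plus a linear increase of ``elderly_slope`` per year
    past ``elderly_onset``. Diagnosis offsets multiply the motion level
    (CN reference). ``outlier_rate`` subjects (increasing with age) get
    a large motion multiplier.
    """

    n_subjects: int = 200
    age_range: tuple[float, float] = (0.5, 95.0)
    child_amp: float = 2.0
    child_tau: float = 5.0
    elderly_onset: float = 60.0
    elderly_slope: float = 0.01  # fractional increase per year past onset
    dx_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 1.0, "CI": 1.15, "AD": 1.35, "LD": 1.5}
    )
    dx_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.75, "CI": 0.15, "AD": 0.10}
    )
    frailty_sd: float = 0.3  # lognormal sigma of the subject motion level
    within_subject_sd: float = 0.2  # lognormal sigma of per-scan level jitter
    outlier_rate: float = 0.02
    outlier_factor: float = 4.0
    scan_rescan: bool = False
    sessions_per_subject: int = 1
    cohort_id: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValidationError("outlier_rate must lie in [0, 1]")

    def lifespan_curve(self, age: np.ndarray | float) -> np.ndarray | float:
        """Motion multiplier vs. age (1.0 = adult floor)."""
        age = np.asarray(age, dtype=float)
        curve = (
            1.0
            + self.child_amp * np.exp(-age / self.child_tau)
            + self.elderly_slope * np.maximum(0.0, age - self.elderly_onset)
        )
        return curve if curve.ndim else float(curve)


@dataclass(frozen=True)
class FeatureSimConfig:
    """Paired scan–rescan feature table generator settings.

    ``injected_bias`` maps a measure name (e.g. ``"FA"``) or a
    ``(measure, bundle)`` pair to a multiplicative factor applied to the
    more-motion scan's latent value; unlisted features get 1.0 (no
    bias). ``conn_*`` control the random connectome generator.
    """

    n_subjects: int = 120
    bundles: tuple[str, ...] = DEFAULT_BUNDLES
    injected_bias: Mapping = field(default_factory=dict)
    populations: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(FEATURE_POPULATIONS)
    )
    domains: tuple[str, ...] = ("micro", "macro", "conn")
    conn_nodes: int = 84
    conn_density: float = 0.3
    conn_weight_sigma: float = 0.5  # lognormal sigma of latent edge weights
    conn_within_sigma: float = 0.02  # per-scan lognormal edge jitter
    conn_bias: float = 1.0  # multiplicative edge-weight bias on more-motion scan
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for key, factor in dict(self.injected_bias).items():
            if not factor > 0:
                raise ValidationError(f"bias factor for {key!r} must be positive")


_DEFAULT_MASK: BrainMask | None = None


def default_mask() -> BrainMask:
    """The package's default brain-scale mask (sphere, r=80 mm, 4 mm grid),
    built once and cached."""
    global _DEFAULT_MASK
    if _DEFAULT_MASK is None:
        _DEFAULT_MASK = make_spherical_mask(radius=80.0, spacing=4.0)
    return _DEFAULT_MASK


def simulate_motion_trace(cfg: TraceSimConfig) -> MotionTrace:
    """Draw one motion trace: cumulative Gaussian drift plus sparse
    persistent jumps; the first volume is the all-zero reference."""
    rng = _rng(cfg.seed, "trace")
    n = cfg.n_volumes
    sd_t = cfg.drift_sd_trans * np.asarray(cfg.anisotropy_trans)
    sd_r = cfg.drift_sd_rot * np.asarray(cfg.anisotropy_rot)
    steps_t = rng.normal(0.0, 1.0, size=(n - 1, 3)) * sd_t
    steps_r = rng.normal(0.0, 1.0, size=(n - 1, 3)) * sd_r
    jumps = rng.random(n - 1) < cfg.jump_rate
    jump_t = rng.normal(0.0, 1.0, size=(n - 1, 3)) * (
        cfg.jump_scale_trans * np.asarray(cfg.anisotropy_trans)
    )
    jump_r = rng.normal(0.0, 1.0, size=(n - 1, 3)) * (
        cfg.jump_scale_rot * np.asarray(cfg.anisotropy_rot)
    )
    steps_t += jumps[:, None] * jump_t
    steps_r += jumps[:, None] * jump_r
    trans = np.vstack([np.zeros(3), np.cumsum(steps_t, axis=0)])
    rot = np.vstack([np.zeros(3), np.cumsum(steps_r, axis=0)])
    return MotionTrace(trans=trans, rot=rot, tr_seconds=cfg.tr_seconds)


def simulate_scan(
    cfg: TraceSimConfig, mask: BrainMask | None = None
) -> tuple[MotionTrace, RMSSeries, MotionSummary]:
    """Simulate one scan end to end: trace → ground-truth RMS series
    (via the rigid-kinematics oracle) → descriptor summary."""
    mask = mask if mask is not None else default_mask()
    trace = simulate_motion_trace(cfg)
    rms = trace_to_rms_series(trace, mask)
    meta = AcquisitionMeta(tr_seconds=cfg.tr_seconds, n_volumes=cfg.n_volumes)
    return trace, rms, summarize_scan(rms, trace, meta)


def simulate_cohort(
    cfg: CohortSimConfig,
    trace_cfg_base: TraceSimConfig | None = None,
    mask: BrainMask | None = None,
) -> list:
    """Simulate a lifespan cohort of :class:`~dwimotion.pipelines.ScanRecord`.

    Per subject: age ~ Uniform(age_range); motion level = lifespan
    curve(age) × dx offset × lognormal frailty, with rare age-weighted
    outliers; each scan scales the base trace config by the level times
    an independent lognormal per-scan jitter. ``scan_rescan`` adds a
    second scan per session sharing the subject level.
    """
    from .pipelines import ScanRecord  # deferred: pipelines imports this module

    base = trace_cfg_base if trace_cfg_base is not None else TraceSimConfig()
    mask = mask if mask is not None else default_mask()
    rng = _rng(cfg.seed, "cohort")

    ages = rng.uniform(*cfg.age_range, size=cfg.n_subjects)
    sexes = rng.choice(["F", "M"], size=cfg.n_subjects)
    dx_names = list(cfg.dx_fractions)
    dx_probs = np.asarray([cfg.dx_fractions[k] for k in dx_names], dtype=float)
    dx_probs = dx_probs / dx_probs.sum()
    dxs = rng.choice(dx_names, size=cfg.n_subjects, p=dx_probs)
    frailty = np.exp(rng.normal(0.0, cfg.frailty_sd, size=cfg.n_subjects))
    # outlier probability grows linearly with age
    out_p = cfg.outlier_rate * (0.5 + ages / np.mean(cfg.age_range))
    outliers = rng.random(cfg.n_subjects) < np.clip(out_p, 0.0, 1.0)

    records: list = []
    n_scans = 2 if cfg.scan_rescan else 1
    for i in range(cfg.n_subjects):
        level = (
            float(cfg.lifespan_curve(ages[i]))
            * cfg.dx_offsets.get(str(dxs[i]), 1.0)
            * frailty[i]
            * (cfg.outlier_factor if outliers[i] else 1.0)
        )
        for sess in range(1, cfg.sessions_per_subject + 1):
            for scan_idx in range(1, n_scans + 1):
                jitter = float(np.exp(rng.normal(0.0, cfg.within_subject_sd)))
                scan_seed = int(rng.integers(0, 2**31 - 1))
                scan_cfg = replace(base.scaled(level * jitter), seed=scan_seed)
                _, _, summary = simulate_scan(scan_cfg, mask)
                records.append(
                    ScanRecord(
                        subject=f"sub-{i:04d}",
                        session=f"ses-{sess}",
                        scan_index=scan_idx,
                        cohort=cfg.cohort_id,
                        age=float(ages[i]),
                        sex=str(sexes[i]),
                        dx=str(dxs[i]),
                        summary=summary,
                    )
                )
    return records


def _bias_factor(cfg: FeatureSimConfig, measure: str, bundle: str) -> float:
    bias = dict(cfg.injected_bias)
    if (measure, bundle) in bias:
        return float(bias[(measure, bundle)])
    return float(bias.get(measure, 1.0))


def _random_connectome(rng: np.random.Generator, cfg: FeatureSimConfig) -> np.ndarray:
    n = cfg.conn_nodes
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < cfg.conn_density
    w = np.exp(rng.normal(0.0, cfg.conn_weight_sigma, size=iu[0].size)) * present
    W = np.zeros((n, n))
    W[iu] = w
    return W + W.T


def _jitter_connectome(
    W: np.ndarray, rng: np.random.Generator, sigma: float, factor: float = 1.0
) -> np.ndarray:
    iu = np.triu_indices(W.shape[0], k=1)
    jit = np.exp(rng.normal(0.0, sigma, size=iu[0].size))
    out = np.zeros_like(W)
    out[iu] = W[iu] * jit * factor
    return out + out.T


def simulate_paired_matrices(
    cfg: FeatureSimConfig,
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Paired bundle-feature matrices: (feature keys, less, more).

    Keys are (measure, bundle) pairs for the micro/macro measures in
    ``cfg.domains``; the matrices are (n_subjects, n_features). Per
    subject and feature: latent ~ N(mean, between_sd); less = latent +
    N(0, within_sd); more = latent × bias + N(0, within_sd). This is
    the matrix core of :func:`simulate_paired_features` and is also
    usable directly for large replicate suites.
    """
    rng = _rng(cfg.seed, "paired_features")
    bundle_measures = []
    if "micro" in cfg.domains:
        bundle_measures += list(MICRO_MEASURES)
    if "macro" in cfg.domains:
        bundle_measures += list(MACRO_MEASURES)
    if not bundle_measures:
        return [], np.empty((cfg.n_subjects, 0)), np.empty((cfg.n_subjects, 0))
    n_feat = len(cfg.bundles) * len(bundle_measures)
    means = np.empty(n_feat)
    between = np.empty(n_feat)
    within = np.empty(n_feat)
    bias = np.empty(n_feat)
    keys: list[tuple[str, str]] = []
    k = 0
    for measure in bundle_measures:
        mu, bsd, wsd = cfg.populations[measure]
        for bundle in cfg.bundles:
            means[k], between[k], within[k] = mu, bsd, wsd
            bias[k] = _bias_factor(cfg, measure, bundle)
            keys.append((measure, bundle))
            k += 1
    latent = means + rng.normal(size=(cfg.n_subjects, n_feat)) * between
    less = latent + rng.normal(size=(cfg.n_subjects, n_feat)) * within
    more = latent * bias + rng.normal(size=(cfg.n_subjects, n_feat)) * within
    return keys, less, more


def simulate_paired_features(
    cfg: FeatureSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired less-/more-motion feature tables.

    Returns two long-format DataFrames (columns: subject, session, scan,
    bundle, measure, value). Bundle features come from
    :func:`simulate_paired_matrices`. Connectome rows (bundle
    ``"connectome"``) are the five global metrics of per-scan jittered
    copies of a per-subject random 84-node network.
    """
    rng = _rng(cfg.seed, "paired_conn")
    subjects = [f"sub-{i:04d}" for i in range(cfg.n_subjects)]

    rows_less: list[tuple] = []
    rows_more: list[tuple] = []

    keys, less, more = simulate_paired_matrices(cfg)
    for si, subj in enumerate(subjects):
        for ki, (measure, bundle) in enumerate(keys):
            rows_less.append((subj, "ses-1", "scan-less", bundle, measure, less[si, ki]))
            rows_more.append((subj, "ses-1", "scan-more", bundle, measure, more[si, ki]))

    if "conn" in cfg.domains:
        for subj in subjects:
            W = _random_connectome(rng, cfg)
            W_less = _jitter_connectome(W, rng, cfg.conn_within_sigma)
            W_more = _jitter_connectome(W, rng, cfg.conn_within_sigma, cfg.conn_bias)
            m_less = global_metrics(Connectome(W_less)).as_dict()
            m_more = global_metrics(Connectome(W_more)).as_dict()
            for name in METRIC_NAMES:
                rows_less.append((subj, "ses-1", "scan-less", "connectome", name, m_less[name]))
                rows_more.append((subj, "ses-1", "scan-more", "connectome", name, m_more[name]))

    columns = ["subject", "session", "scan", "bundle", "measure", "value"]
    return (
        pd.DataFrame(rows_less, columns=columns),
        pd.DataFrame(rows_more, columns=columns),
    )
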