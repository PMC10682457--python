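"""Synthetic parcellations, sessions, and staged cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at parcel/bin resolution:

* a global low-frequency event signal shared across parcels, each event a
  raised-cosine bump, expressed locally according to a per-parcel presence
  weight;
* a CSF-inflow signal that is the (sign-flipped) global signal at a fixed
  positive lag, mixed with an independent component controlled by a
  per-subject coupling strength;
* propagation: each event reaches a parcel with a delay linear in its
  principal-gradient rank (bottom-up) or reversed (top-down);
* a staged cohort whose CSF A-beta-42 / SUVR values straddle the clinical
  cut-offs, with configurable monotone associations between coupling
  strength and the biomarkers, amplitude-mediated connectivity effects, and
  a DMN-weighted attenuation of the global signal that concentrates 2-year
  amyloid accumulation in higher-order parcels.

Everything is driven by one integer seed; identical (config, seed) pairs
produce bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .hierarchy import NETWORKS, Parcellation
from .preprocess import (
    BoldSession,
    framewise_displacement,
    write_bold_tsv,
    write_motion_tsv,
    write_series_tsv,
)
from .stats import STAGE_ORDER, SubjectRecord, classify_stage

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "generate_parcellation",
    "generate_session",
    "generate_cohort",
    "write_cohort",
]

# Table-1 defaults for the staged cohort: (S1, S2, S3)
DEFAULT_STAGE_COUNTS = (50, 23, 71)
DEFAULT_FOLLOWUP_COUNTS = (40, 19, 53)  # 112 subjects with 2-year PET, 19 of them in S2
STAGE_AGE = {"S1": (71.7, 8.0), "S2": (70.5, 7.3), "S3": (73.9, 7.0)}
STAGE_FEMALE_COUNT = {"S1": 28, "S2": 7, "S3": 38}
STAGE_TOTAL = {"S1": 50, "S2": 23, "S3": 71}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generator.

    Session-level fields control one subject's signals; the cohort fields
    control stage structure and the monotone biomarker associations. Effect
    sizes are target Spearman magnitudes in [-1, 1].
    """

    n_parcels: int = 140
    n_bins: int = 70
    n_volumes: int = 140
    tr: float = 3.0
    seed: int = 0
    event_rate: float = 3.0  # events / minute: quasi-periodic at ~0.05 Hz
    event_amplitude: float = 1.0
    noise_sd: float = 0.2  # measurement noise, as a fraction of event_amplitude
    kernel_width: float = 12.0  # seconds, raised-cosine event support
    csf_lag: float = 3.0  # seconds; CSF examines the global signal this much earlier
    csf_polarity: int = -1
    wave_speed: float = 35.0  # bins / second (70 bins traversed in ~2 s)
    direction_mix: float = 0.7  # fraction of events propagating bottom-up
    presence_profile: np.ndarray | None = None  # per-parcel weights in [0, 1]
    coupling_strength: float = 1.0  # fraction of CSF variance locked to the global signal
    sync_amplitude: float = 0.0  # amplitude of the synchronous (non-propagating) global component
    network_signal_sd: float = 0.0  # intrinsic per-network fluctuation amplitude (this session)
    target_mean_fd: float = 0.15  # mm, session-mean framewise displacement
    # cohort structure
    stage_counts: tuple[int, int, int] = DEFAULT_STAGE_COUNTS
    followup_counts: tuple[int, int, int] = DEFAULT_FOLLOWUP_COUNTS
    stage_coupling_means: Mapping[str, float] = field(
        default_factory=lambda: {"S1": 0.65, "S2": 0.55, "S3": 0.45}
    )
    coupling_sd: float = 0.20
    # effect sizes (target Spearman magnitudes)
    marker_rho: float = 0.65  # coupling strength vs each biomarker, within stage
    fc_amp_rho: float = 0.8  # ln A-beta-42 vs synchronous global-signal amplitude
    attenuation_rho: float = 0.8  # ln A-beta-42 vs higher-order attenuation
    attenuation_max: float = 0.6  # maximal fractional presence loss at the top-PG end
    sync_base: float = 1.0  # cohort baseline of the synchronous component amplitude
    sync_spread: float = 0.6  # fractional range of the synchronous amplitude across subjects
    cohort_network_sd: float = 0.3  # intrinsic network fluctuation amplitude in cohort sessions

    def __post_init__(self) -> None:
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed 10")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must lie in [0, 1]")
        if self.presence_profile is not None:
            prof = np.asarray(self.presence_profile, dtype=float)
            if prof.shape[0] != self.n_parcels:
                raise ValueError("presence_profile length must equal n_parcels")
            self.presence_profile = prof
        for name in ("marker_rho", "fc_amp_rho", "attenuation_rho"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValueError(f"effect size {name}={v} outside [-1, 1]")
        if not 0 < self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually injected into one session."""

    event_times: np.ndarray
    event_directions: list[str]
    true_presence: np.ndarray
    true_lag: float
    coupling_strength: float
    amplitude: float
    sync_amplitude: float = 0.0
    stage: str | None = None
    attenuation: float = 0.0


@dataclass
class Cohort:
    """A staged synthetic cohort: subject table, sessions, and per-subject truth."""

    parcellation: Parcellation
    records: list[SubjectRecord]
    sessions: dict[str, BoldSession]
    truth: dict[str, GroundTruth]
    suvr_change_maps: dict[str, pd.Series]  # per-parcel 2-year SUVR change (follow-up subjects)
    config: SimulationConfig


def _spearman_to_pearson(rho: float) -> float:
    """Bivariate-normal Pearson correlation giving the target Spearman rho."""
    return 2 * np.sin(rho * np.pi / 6)


def _copula_partner(z: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """A standard-normal vector whose Spearman correlation with z targets rho."""
    r = _spearman_to_pearson(rho)
    return r * z + np.sqrt(max(0.0, 1 - r * r)) * rng.standard_normal(z.shape)


def generate_parcellation(n_parcels: int, seed: int) -> Parcellation:
    """Random parcellation with PG values, network labels, and overlap fractions.

    PG values increase strictly with parcel index; dominant networks occupy
    contiguous PG blocks from visual/somatomotor at the sensory end to
    DMN/FPN at the associative end, with every network represented. Each
    parcel's vertex-overlap fractions sum to exactly 1, with the dominant
    network holding a strict majority.
    """
    if n_parcels < 8:
        raise ValueError("need at least 8 parcels to populate all networks")
    rng = np.random.default_rng(seed)
    pg = np.sort(rng.uniform(0.0, 1.0, n_parcels))
    # largest-remainder allocation over the PG-ordered network blocks
    fractions = {"visual": 0.15, "somatomotor": 0.20, "other": 0.25, "DMN": 0.25, "FPN": 0.15}
    counts = {k: max(1, int(np.floor(v * n_parcels))) for k, v in fractions.items()}
    while sum(counts.values()) < n_parcels:
        k = max(fractions, key=lambda k: fractions[k] * n_parcels - counts[k])
        counts[k] += 1
    while sum(counts.values()) > n_parcels:
        k = max(counts, key=lambda k: counts[k] - fractions[k] * n_parcels)
        counts[k] -= 1
    dominant: list[str] = []
    for net in ("visual", "somatomotor", "other", "DMN", "FPN"):
        dominant.extend([net] * counts[net])
    ids = [f"p{i:03d}" for i in range(n_parcels)]
    overlaps = np.zeros((n_parcels, len(NETWORKS)))
    net_index = {n: i for i, n in enumerate(NETWORKS)}
    for i, dom in enumerate(dominant):
        share = rng.uniform(0.55, 0.9)
        rest = rng.dirichlet(np.ones(len(NETWORKS) - 1)) * (1 - share)
        row = np.empty(len(NETWORKS))
        j = net_index[dom]
        others = [k for k in range(len(NETWORKS)) if k != j]
        row[j] = share
        row[others] = rest
        overlaps[i] = row
    df = pd.DataFrame(overlaps, index=ids, columns=list(NETWORKS))
    return Parcellation(parcel_ids=ids, pg=pg, overlaps=df, meta={"seed": seed})


def _raised_cosine(t: np.ndarray, width: float) -> np.ndarray:
    """Unit-height raised-cosine bump supported on [-width/2, width/2]."""
    out = np.zeros_like(t)
    inside = np.abs(t) <= width / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * t[inside] / width))
    return out


def _event_train(
    times: np.ndarray,
    event_times: np.ndarray,
    delays: np.ndarray,
    width: float,
) -> np.ndarray:
    """Noise-free per-parcel signal: sum of delayed kernels, evaluated exactly.

    ``delays`` has shape (n_parcels, n_events); returns (n_parcels, len(times)).
    """
    n_parcels = delays.shape[0]
    out = np.zeros((n_parcels, times.size))
    for e, t_e in enumerate(event_times):
        out += _raised_cosine(times[None, :] - t_e - delays[:, e : e + 1], width)
    return out


def _draw_event_times(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Quasi-periodic event times: a jittered grid at the configured rate.

    The jittered grid keeps events separated by roughly the mean interval, so
    the global signal stays pseudo-periodic (as infra-slow activity is) and
    trough segmentation is well posed.
    """
    if config.event_rate <= 0:
        return np.empty(0)
    duration = config.n_volumes * config.tr
    spacing = 60.0 / config.event_rate
    margin = config.kernel_width / 2
    anchors = np.arange(margin + spacing / 2, duration - margin, spacing)
    jitter = rng.uniform(-0.25, 0.25, anchors.size) * spacing
    return anchors + jitter


def _propagation_delays(
    frac_rank: np.ndarray, directions: list[str], config: SimulationConfig
) -> np.ndarray:
    """(n_parcels, n_events) delay of each event at each parcel.

    The delay is linear in PG rank: a bottom-up event reaches the highest-PG
    parcel ``(n_bins - 1) / wave_speed`` seconds after the lowest-PG parcel;
    top-down events traverse in the opposite direction.
    """
    span = (config.n_bins - 1) / config.wave_speed
    cols = []
    for d in directions:
        cols.append(frac_rank * span if d == "bottom_up" else (1 - frac_rank) * span)
    if not cols:
        return np.zeros((frac_rank.size, 0))
    return np.column_stack(cols)


def _motion_trace(
    rng: np.random.Generator, n_volumes: int, target_mean_fd: float
) -> np.ndarray:
    """Random-walk motion whose session-mean FD equals the target exactly."""
    incr = rng.standard_normal((n_volumes - 1, 6))
    incr[:, 3:] /= 50.0  # balance rotational and translational contributions
    motion = np.vstack([np.zeros(6), np.cumsum(incr, axis=0)])
    fd_mean = framewise_displacement(motion).mean()
    if fd_mean > 0 and target_mean_fd >= 0:
        motion *= target_mean_fd / fd_mean
    return motion


def generate_session(
    config: SimulationConfig,
    parcellation: Parcellation | None = None,
    overrides: Mapping | None = None,
    seed: int | None = None,
) -> tuple[BoldSession, GroundTruth]:
    """One subject's session plus the ground truth that generated it.

    ``overrides`` may pin any of: ``event_times``, ``event_directions``,
    ``presence`` (per-parcel weights), ``coupling_strength``, ``amplitude``,
    ``attenuation``, ``target_mean_fd``, ``stage``, ``subject_id``.
    """
    overrides = dict(overrides or {})
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if parcellation is None:
        parcellation = generate_parcellation(
            config.n_parcels, seed=int(rng.integers(2**31))
        )
    if parcellation.n_parcels != config.n_parcels:
        raise ValueError("parcellation size does not match config.n_parcels")

    lag = float(config.csf_lag)
    n_steps = lag / config.tr
    if not np.isclose(n_steps, round(n_steps), atol=1e-9):
        lag = round(n_steps) * config.tr
        warnings.warn(
            f"csf_lag {config.csf_lag} s is not a multiple of the sampling "
            f"interval {config.tr} s; rounded to {lag} s",
            stacklevel=2,
        )

    event_times = np.asarray(
        overrides.get("event_times", _draw_event_times(rng, config)), dtype=float
    )
    if "event_directions" in overrides:
        directions = list(overrides["event_directions"])
    else:
        directions = [
            "bottom_up" if u < config.direction_mix else "top_down"
            for u in rng.uniform(size=event_times.size)
        ]
    if len(directions) != event_times.size:
        raise ValueError("one direction per event required")

    frac_rank = (
        parcellation.pg_rank() / max(1, config.n_parcels - 1)
    ).astype(float)
    if "presence" in overrides:
        presence = np.asarray(overrides["presence"], dtype=float)
    elif config.presence_profile is not None:
        presence = config.presence_profile
    else:
        # sensory-dominant default: full expression at the sensory-motor end,
        # tapering toward the DMN end of the gradient
        presence = 1.0 - 0.5 * frac_rank
    if presence.shape[0] != config.n_parcels:
        raise ValueError("presence profile length must equal n_parcels")
    attenuation = float(overrides.get("attenuation", 0.0))
    if attenuation:
        presence = presence * (1 - attenuation * frac_rank)

    amplitude = float(overrides.get("amplitude", config.event_amplitude))
    c = float(overrides.get("coupling_strength", config.coupling_strength))
    if not 0 <= c <= 1:
        raise ValueError("coupling_strength must lie in [0, 1]")
    sync_amp = float(overrides.get("sync_amplitude", config.sync_amplitude))
    # synchronous global component: its own event train, expressed with zero
    # delay at every parcel through the same presence weights as the waves
    sync_times = _draw_event_times(rng, config) if sync_amp else np.empty(0)

    times = np.arange(config.n_volumes) * config.tr
    delays = _propagation_delays(frac_rank, directions, config)

    def sync_signal(at: np.ndarray) -> np.ndarray:
        if not sync_times.size:
            return np.zeros(at.size)
        return sync_amp * _event_train(at, sync_times,
                                       np.zeros((1, sync_times.size)),
                                       config.kernel_width)[0]

    def noise_free(at: np.ndarray) -> np.ndarray:
        wave = amplitude * _event_train(at, event_times, delays, config.kernel_width)
        return presence[:, None] * (wave + sync_signal(at)[None, :])

    clean = noise_free(times)
    # the noise-free global signal, lag-shifted by exact evaluation
    g_shift = noise_free(times - lag).mean(axis=0)
    g_sd = g_shift.std()
    g_norm = (g_shift - g_shift.mean()) / g_sd if g_sd > 0 else np.zeros_like(g_shift)
    decoupled = rng.standard_normal(times.size)
    csf_clean = config.csf_polarity * (c * g_norm + np.sqrt(1 - c * c) * decoupled)

    noise_scale = config.noise_sd * config.event_amplitude
    bold = clean + noise_scale * rng.standard_normal(clean.shape)
    if config.network_signal_sd > 0:
        # intrinsic (non-global) connectivity: each parcel loads onto latent
        # per-network fluctuations through its vertex-overlap fractions,
        # row-normalized so every parcel carries the same intrinsic variance
        loadings = parcellation.overlaps.to_numpy()
        loadings = loadings / np.linalg.norm(loadings, axis=1, keepdims=True)
        latent = rng.standard_normal((loadings.shape[1], times.size))
        bold = bold + config.network_signal_sd * config.event_amplitude * (loadings @ latent)
    csf = csf_clean + noise_scale * rng.standard_normal(times.size)
    motion = _motion_trace(
        rng, config.n_volumes, float(overrides.get("target_mean_fd", config.target_mean_fd))
    )

    session = BoldSession(
        bold=bold,
        csf=csf,
        motion=motion,
        tr=config.tr,
        parcel_ids=list(parcellation.parcel_ids),
        meta={"subject_id": overrides.get("subject_id", "sub-000"), "synthetic": True},
    )
    truth = GroundTruth(
        event_times=event_times,
        event_directions=directions,
        true_presence=presence,
        true_lag=lag,
        coupling_strength=c,
        amplitude=amplitude,
        sync_amplitude=sync_amp,
        stage=overrides.get("stage"),
        attenuation=attenuation,
    )
    return session, truth


def _stage_marker_values(
    stage: str, z: np.ndarray, marker: str
) -> np.ndarray:
    """Map standard-normal scores to stage-consistent marker ranges (monotone).

    Ranges straddle the clinical cut-offs strictly: A-beta-42 above 192 ng/L
    for S1 and below for S2/S3; SUVR below 0.872 for S1/S2 and above for S3.
    """
    u = norm.cdf(z)
    if marker == "ab42":
        return 196.0 + 124.0 * u if stage == "S1" else 80.0 + 108.0 * u
    if marker == "suvr":
        return (0.88 + 0.20 * u) if stage == "S3" else (0.70 + 0.16 * u)
    if marker == "ttau":
        return 40.0 + 110.0 * u
    if marker == "ptau":
        return 15.0 + 55.0 * u
    raise ValueError(marker)


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """A staged cohort with sessions, biomarkers, and injected associations.

    Within each stage, a latent coupling score anchors the biomarker copula:
    each marker targets a Spearman magnitude of ``config.marker_rho`` against
    the subject's coupling strength, signed so that weaker coupling goes with
    lower A-beta-42, higher tau, and more amyloid. Global-signal amplitude
    and higher-order attenuation are tied to A-beta-42, which induces the
    connectivity and propagating-wave group effects downstream.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = tuple(config.stage_counts)
    if any(c < 3 for c in counts):
        raise ValueError("need at least 3 subjects per stage")
    # cohort sessions carry the intrinsic network fluctuations; the
    # synchronous-component amplitude is set per subject below
    import dataclasses

    config = dataclasses.replace(config, network_signal_sd=config.cohort_network_sd)
    parcellation = generate_parcellation(config.n_parcels, seed=int(rng.integers(2**31)))
    frac_rank = (parcellation.pg_rank() / max(1, config.n_parcels - 1)).astype(float)
    base_presence = (
        config.presence_profile
        if config.presence_profile is not None
        else 1.0 - 0.5 * frac_rank
    )
    higher_weight = frac_rank  # attenuation ramp toward the DMN end

    records: list[SubjectRecord] = []
    sessions: dict[str, BoldSession] = {}
    truth: dict[str, GroundTruth] = {}
    change_maps: dict[str, pd.Series] = {}
    sub_idx = 0
    for stage, n_stage, n_follow in zip(STAGE_ORDER, counts, config.followup_counts):
        mean_c = config.stage_coupling_means[stage]
        z_c = rng.standard_normal(n_stage)
        c_vals = np.clip(mean_c + config.coupling_sd * z_c, 0.05, 0.98)
        # biomarkers: copula partners of the coupling score, signed per marker
        z_ab = _copula_partner(z_c, config.marker_rho, rng)  # weaker coupling -> lower ab42
        z_suvr = _copula_partner(-z_c, config.marker_rho, rng)
        z_ttau = _copula_partner(-z_c, config.marker_rho, rng)
        z_ptau = _copula_partner(-z_c, config.marker_rho, rng)
        ab42 = _stage_marker_values(stage, z_ab, "ab42")
        suvr = _stage_marker_values(stage, z_suvr, "suvr")
        ttau = _stage_marker_values(stage, z_ttau, "ttau")
        ptau = _stage_marker_values(stage, z_ptau, "ptau")
        # the synchronous-component amplitude and the higher-order attenuation
        # both follow A-beta-42: these induce the connectivity and wave effects
        z_amp = _copula_partner(z_ab, config.fc_amp_rho, rng)
        z_att = _copula_partner(-z_ab, config.attenuation_rho, rng)
        sync = config.sync_base * (1 + config.sync_spread * (2 * norm.cdf(z_amp) - 1))
        att = config.attenuation_max * norm.cdf(z_att)

        ages = STAGE_AGE[stage][0] + STAGE_AGE[stage][1] * rng.standard_normal(n_stage)
        n_female = int(round(STAGE_FEMALE_COUNT[stage] * n_stage / STAGE_TOTAL[stage]))
        sexes = np.array(["F"] * n_female + ["M"] * (n_stage - n_female))
        rng.shuffle(sexes)
        follow_idx = set(rng.choice(n_stage, size=min(n_follow, n_stage), replace=False))

        for i in range(n_stage):
            sid = f"sub-{sub_idx:03d}"
            sub_idx += 1
            session, gt = generate_session(
                config,
                parcellation=parcellation,
                overrides={
                    "coupling_strength": float(c_vals[i]),
                    "attenuation": float(att[i]),
                    "sync_amplitude": float(sync[i]),
                    "stage": stage,
                    "subject_id": sid,
                },
                seed=int(rng.integers(2**31)),
            )
            suvr_2y = None
            if i in follow_idx:
                # 2-year accumulation concentrated where this subject's global
                # signal dropped out: proportional to the presence-deficit
                # profile, i.e. inversely weighted by the subject's remaining
                # higher-order presence
                deficit_profile = base_presence - gt.true_presence
                delta = 0.005 + 0.12 * deficit_profile + 0.004 * rng.standard_normal(
                    config.n_parcels
                )
                change_maps[sid] = pd.Series(
                    delta, index=parcellation.parcel_ids, name="suvr_change_2y"
                )
                suvr_2y = float(suvr[i] + delta.mean())
            rec = SubjectRecord(
                id=sid,
                age=float(ages[i]),
                sex=str(sexes[i]),
                csf_ab42=float(ab42[i]),
                csf_ttau=float(ttau[i]),
                csf_ptau=float(ptau[i]),
                suvr_baseline=float(suvr[i]),
                suvr_2y=suvr_2y,
                stage=classify_stage(float(ab42[i]), float(suvr[i])),
            )
            if rec.stage != stage:
                raise RuntimeError("generated markers violate the stage cut-offs")
            records.append(rec)
            sessions[sid] = session
            truth[sid] = gt
    return Cohort(
        parcellation=parcellation,
        records=records,
        sessions=sessions,
        truth=truth,
        suvr_change_maps=change_maps,
        config=config,
    )



# ---------------------------------------------------------------------------
# Plain-text export (round-trips through the preprocess readers)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort as TSV/CSV/JSON: one directory per subject plus tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        rows.append(
            {
                "id": rec.id,
                "age": rec.age,
                "sex": rec.sex,
                "csf_ab42": rec.csf_ab42,
                "csf_ttau": rec.csf_ttau,
                "csf_ptau": rec.csf_ptau,
                "suvr_baseline": rec.suvr_baseline,
                "suvr_2y": rec.suvr_2y,
                "stage": rec.stage,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "subjects.csv", index=False)
    parc = cohort.parcellation
    parc_df = parc.overlaps.copy()
    parc_df.insert(0, "pg", parc.pg)
    parc_df.to_csv(outdir / "parcellation.tsv", sep="\t", index_label="parcel_id")
    gt_json = {}
    for sid, gt in cohort.truth.items():
        sdir = outdir / sid
        sdir.mkdir(exist_ok=True)
        sess = cohort.sessions[sid]
        write_bold_tsv(sdir / "bold.tsv", sess.bold, sess.parcel_ids)
        write_series_tsv(sdir / "csf.tsv", sess.csf, name="csf")
        write_motion_tsv(sdir / "motion.tsv", sess.motion)
        gt_json[sid] = {
            "event_times": gt.event_times.tolist(),
            "event_directions": gt.event_directions,
            "true_presence": gt.true_presence.tolist(),
            "true_lag": gt.true_lag,
            "coupling_strength": gt.coupling_strength,
            "amplitude": gt.amplitude,
            "stage": gt.stage,
            "attenuation": gt.attenuation,
        }
    (outdir / "ground_truth.json").write_text(json.dumps(gt_json, indent=1))
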