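"""Forward simulators for lineage forests and toy clustered expression data.

The forest simulator draws, per cell, a discrete state from its mother via a
transition matrix, a log-normal division time modulated by a latent factor
shared within sibships (and, attenuated, between cousin sibships, but never
passed mother to daughter), a death event with a state-specific probability,
and a per-frame reporter trace from the state's intensity band. All times are
quantized up to the acquisition frame grid. Outputs always pass
:mod:`lineagedyn.tracks_io` validation, so every downstream estimator can be
exercised against known generative parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster_align import ClusteredMatrix
from .errors import ConfigError
from .tracks_io import FRAME_INTERVAL_H, CellTrack, LineageForest


def lognormal_from_median_sd(median: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and standard deviation.

    Uses median = exp(mu) and Var = m^2 u (u - 1) with u = exp(sigma^2),
    solved in closed form.
    """
    if median <= 0 or sd < 0:
        raise ConfigError("median must be > 0 and sd >= 0")
    if sd == 0:
        return math.log(median), 0.0
    ratio2 = (sd / median) ** 2
    u = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * ratio2))
    return math.log(median), math.sqrt(math.log(u))


@dataclass(frozen=True)
class StateParams:
    """Generative parameters of one discrete cell state."""

    division_median_h: float
    division_sd_h: float
    death_prob: float  # per generation
    intensity_mean: float
    intensity_sd: float
    g1_fraction_mean: float = 0.15
    g1_fraction_sd: float = 0.05


@dataclass
class ForestSimConfig:
    """Configuration of :func:`simulate_forest`."""

    states: dict[str, StateParams]
    transition: dict[str, dict[str, float]]  # mother state -> daughter state dist
    n_roots: int = 10
    duration_h: float = 120.0
    frame_interval_h: float = FRAME_INTERVAL_H
    initial_state_probs: dict[str, float] | None = None
    frame_noise_sd: float = 0.005
    kin_rho: float = 0.0  # variance share of the sibship-shared latent factor
    cousin_lambda: float = 0.5  # attenuation of the factor between cousin sibships
    include_phase: bool = False
    phase_noise_sd: float = 0.03
    seed: int = 0
    cell_cap: int = 100_000
    condition_label: str = "sim"

    def __post_init__(self) -> None:
        for s, row in self.transition.items():
            if s not in self.states:
                raise ConfigError(f"transition row for unknown state {s!r}")
            total = sum(row.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigError(f"transition row {s!r} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ConfigError("negative transition probability")
        for s, sp in self.states.items():
            if not 0.0 <= sp.death_prob <= 1.0:
                raise ConfigError(f"state {s!r}: death_prob outside [0, 1]")
            if sp.division_median_h <= self.frame_interval_h:
                raise ConfigError(
                    f"state {s!r}: division median must exceed the frame interval"
                )
        if not 0.0 <= self.kin_rho < 1.0:
            raise ConfigError("kin_rho must be in [0, 1)")


@dataclass
class _Pending:
    cell_id: str
    parent_id: str | None
    state: str
    birth_time: float
    # latent factors: u is drawn at this cell's birth division (shared with
    # its sister); v_grand is the v drawn at the mother's birth division
    # (shared with cousins). Each division draws a fresh (u, v) pair; v is
    # expressed only one generation later, which keeps mother and daughter
    # cycles uncorrelated while sisters share rho and cousins rho*lambda.
    sib_u: float = 0.0
    gran_v: float = 0.0
    own_v: float = 0.0  # the v of this cell's birth division, passed to kids


def _quantize_up(t: float, dt: float) -> float:
    """Round a duration up to the next frame multiple (at least one frame)."""
    return max(1, math.ceil(t / dt - 1e-9)) * dt


def simulate_forest(config: ForestSimConfig, true_states_out: dict | None = None) -> LineageForest:
    """Forward-simulate a lineage forest.

    If ``true_states_out`` is a dict it is filled with the generative state of
    every cell (cell_id -> state), for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_h
    state_names = sorted(config.states)
    init = config.initial_state_probs or {s: 1.0 / len(state_names) for s in state_names}
    init_names = sorted(init)
    init_p = np.array([init[s] for s in init_names])
    init_p = init_p / init_p.sum()

    tracks: dict[str, CellTrack] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"c{counter:06d}"

    queue: list[_Pending] = []
    for _ in range(config.n_roots):
        s = str(rng.choice(init_names, p=init_p))
        queue.append(
            _Pending(
                cell_id=next_id(),
                parent_id=None,
                state=s,
                birth_time=0.0,
                sib_u=float(rng.standard_normal()),
                gran_v=float(rng.standard_normal()),
                own_v=float(rng.standard_normal()),
            )
        )

    rho, lam = config.kin_rho, config.cousin_lambda
    truncated = False
    while queue:
        cell = queue.pop(0)
        if len(tracks) >= config.cell_cap:
            truncated = True
            break
        sp = config.states[cell.state]
        mu, sigma = lognormal_from_median_sd(sp.division_median_h, sp.division_sd_h)
        shared = math.sqrt(lam) * cell.gran_v + math.sqrt(1.0 - lam) * cell.sib_u
        z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * rng.standard_normal()
        cycle = _quantize_up(math.exp(mu + sigma * z), dt)

        dies = rng.random() < sp.death_prob
        if dies:
            end = cell.birth_time + _quantize_up(rng.uniform(0.3, 0.9) * cycle, dt)
            fate = "died"
        else:
            end = cell.birth_time + cycle
            fate = "divided"
        # division must leave room for a first daughter frame inside the movie
        horizon = config.duration_h - (dt if fate == "divided" else 0.0)
        if end > horizon + 1e-9:
            end = cell.birth_time + math.floor(
                (config.duration_h - cell.birth_time) / dt + 1e-9
            ) * dt
            fate = "censored"

        n_frames = int(round((end - cell.birth_time) / dt)) + 1
        times = cell.birth_time + dt * np.arange(n_frames)
        base = rng.normal(sp.intensity_mean, sp.intensity_sd)
        trace = base + rng.normal(0.0, config.frame_noise_sd, size=n_frames)
        trace = np.maximum(trace, 1e-6)

        phase = None
        if config.include_phase:
            g1_frac = float(
                np.clip(rng.normal(sp.g1_fraction_mean, sp.g1_fraction_sd), 0.03, 0.9)
            )
            g1_end = cell.birth_time + g1_frac * (end - cell.birth_time)
            raw = np.where(times <= g1_end + 1e-9, 1.0, 0.0)
            phase = tuple(raw + rng.normal(0.0, config.phase_noise_sd, size=n_frames))

        tracks[cell.cell_id] = CellTrack(
            cell_id=cell.cell_id,
            parent_id=cell.parent_id,
            frame_times=tuple(times),
            intensity_trace=tuple(trace),
            fate=fate,
            phase_trace=phase,
        )
        if true_states_out is not None:
            true_states_out[cell.cell_id] = cell.state

        if fate == "divided":
            row = config.transition[cell.state]
            kid_names = sorted(row)
            kid_p = np.array([row[s] for s in kid_names])
            u = float(rng.standard_normal())  # shared by the two daughters
            v = float(rng.standard_normal())  # expressed in the granddaughters
            for _ in range(2):
                queue.append(
                    _Pending(
                        cell_id=next_id(),
                        parent_id=cell.cell_id,
                        state=str(rng.choice(kid_names, p=kid_p)),
                        birth_time=end + dt,
                        sib_u=u,
                        gran_v=cell.own_v,
                        own_v=v,
                    )
                )
    if truncated:
        warnings.warn(
            f"simulation truncated at cell cap {config.cell_cap}", RuntimeWarning
        )
        tracks = _demote_childless_divided(tracks)
    return LineageForest(
        tracks,
        condition_label=config.condition_label,
        frame_interval_h=dt,
    )


def _demote_childless_divided(tracks: dict[str, CellTrack]) -> dict[str, CellTrack]:
    """After cap truncation, divided cells whose daughters were never
    materialized are re-flagged as censored."""
    from dataclasses import replace

    n_children: dict[str, int] = {}
    for tr in tracks.values():
        if tr.parent_id is not None:
            n_children[tr.parent_id] = n_children.get(tr.parent_id, 0) + 1
    return {
        cid: (
            replace(tr, fate="censored")
            if tr.fate == "divided" and n_children.get(cid, 0) == 0
            else tr
        )
        for cid, tr in tracks.items()
    }


def nacl_like_config(**overrides) -> ForestSimConfig:
    """Steady-state three-compartment defaults.

    Division-time medians (17.3/16.3/14.7 h for High/Mid/Low), death
    probabilities (0.09/0.12/0.21) and a near-symmetric transition matrix
    mirror the measured steady-state compartment table; intensity bands are
    placed so quartile thresholds land near the published cut points
    (0.1376, 0.1648).
    """
    states = {
        "High": StateParams(17.3, 6.0, 0.09, 0.180, 0.010),
        "Mid": StateParams(16.3, 6.0, 0.12, 0.151, 0.008),
        "Low": StateParams(14.7, 5.0, 0.21, 0.125, 0.010),
    }
    transition = {
        "High": {"High": 0.62, "Mid": 0.36, "Low": 0.02},
        "Mid": {"High": 0.18, "Mid": 0.64, "Low": 0.18},
        "Low": {"High": 0.02, "Mid": 0.36, "Low": 0.62},
    }
    cfg = dict(
        states=states,
        transition=transition,
        n_roots=12,
        duration_h=120.0,
        initial_state_probs={"High": 0.25, "Mid": 0.50, "Low": 0.25},
        condition_label="NACL",
    )
    cfg.update(overrides)
    return ForestSimConfig(**cfg)


def pd03_like_config(**overrides) -> ForestSimConfig:
    """MEK-inhibited variant: intensities shifted down, cycles shortened,
    High state destabilized, kin correlation off by default."""
    states = {
        "High": StateParams(15.8, 5.0, 0.23, 0.172, 0.010),
        "Mid": StateParams(14.0, 4.0, 0.22, 0.145, 0.008),
        "Low": StateParams(13.7, 4.0, 0.18, 0.120, 0.010),
    }
    transition = {
        "High": {"High": 0.35, "Mid": 0.55, "Low": 0.10},
        "Mid": {"High": 0.08, "Mid": 0.62, "Low": 0.30},
        "Low": {"High": 0.01, "Mid": 0.24, "Low": 0.75},
    }
    cfg = dict(
        states=states,
        transition=transition,
        n_roots=12,
        duration_h=120.0,
        initial_state_probs={"High": 0.10, "Mid": 0.40, "Low": 0.50},
        condition_label="PD03",
    )
    cfg.update(overrides)
    return ForestSimConfig(**cfg)


@dataclass
class DifferentiationConfig:
    """Configuration of :func:`simulate_differentiation_forest`.

    Conversion from the undifferentiated to the differentiated state is
    allowed at per-generation probability ``conv_pre`` before ``cutoff_h``
    and ``conv_post`` after. Division-time medians and survival follow
    day-indexed schedules (day 1 = first 24 h).
    """

    conv_pre: float = 0.126
    conv_post: float = 0.019
    cutoff_h: float = 72.0
    n_roots: int = 40
    duration_h: float = 120.0
    frame_interval_h: float = FRAME_INTERVAL_H
    # day -> (division median h, sd h, survival probability)
    nediff_schedule: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: {
            1: (16.3, 4.0, 0.73),
            2: (18.0, 7.0, 0.49),
            3: (20.0, 6.0, 0.70),
            4: (17.0, 7.0, 0.51),
            5: (22.0, 7.0, 0.27),
        }
    )
    pre_schedule: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: {
            1: (13.3, 4.0, 0.83),
            2: (13.3, 4.0, 0.83),
            3: (11.0, 3.0, 0.89),
            4: (13.0, 4.0, 0.94),
            5: (17.3, 4.0, 0.90),
        }
    )
    nediff_intensity: tuple[float, float] = (0.15, 0.02)
    pre_intensity_base: tuple[float, float] = (0.22, 0.03)
    pre_intensity_ramp_per_day: float = 0.04  # upward drift along PrE lineages
    frame_noise_sd: float = 0.008
    seed: int = 0
    cell_cap: int = 100_000
    condition_label: str = "RACL"


def _day_of(time_h: float) -> int:
    return int(math.floor(time_h / 24.0)) + 1


def _schedule_get(schedule: dict[int, tuple[float, float, float]], day: int):
    if day in schedule:
        return schedule[day]
    return schedule[max(schedule)] if day > max(schedule) else schedule[min(schedule)]


def simulate_differentiation_forest(
    config: DifferentiationConfig, true_states_out: dict | None = None
) -> LineageForest:
    """Simulate a PrE-differentiation forest with day-dependent rates."""
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval_h
    tracks: dict[str, CellTrack] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"d{counter:06d}"

    queue: list[tuple[str, str | None, str, float]] = [
        (next_id(), None, "NEDiff", 0.0) for _ in range(config.n_roots)
    ]
    truncated = False
    while queue:
        cid, parent, state, birth = queue.pop(0)
        if len(tracks) >= config.cell_cap:
            truncated = True
            break
        day = _day_of(birth)
        schedule = config.pre_schedule if state == "PrE" else config.nediff_schedule
        med, sd, survival = _schedule_get(schedule, day)
        mu, sigma = lognormal_from_median_sd(med, sd)
        cycle = _quantize_up(float(rng.lognormal(mu, sigma)), dt)

        dies = rng.random() > survival
        if dies:
            end = birth + _quantize_up(rng.uniform(0.3, 0.9) * cycle, dt)
            fate = "died"
        else:
            end = birth + cycle
            fate = "divided"
        horizon = config.duration_h - (dt if fate == "divided" else 0.0)
        if end > horizon + 1e-9:
            end = birth + math.floor((config.duration_h - birth) / dt + 1e-9) * dt
            fate = "censored"

        n_frames = int(round((end - birth) / dt)) + 1
        times = birth + dt * np.arange(n_frames)
        if state == "PrE":
            m0, s0 = config.pre_intensity_base
            base = rng.normal(m0 + config.pre_intensity_ramp_per_day * max(0, day - 2), s0)
        else:
            base = rng.normal(*config.nediff_intensity)
        trace = np.maximum(base + rng.normal(0.0, config.frame_noise_sd, n_frames), 1e-6)

        tracks[cid] = CellTrack(
            cell_id=cid,
            parent_id=parent,
            frame_times=tuple(times),
            intensity_trace=tuple(trace),
            fate=fate,
        )
        if true_states_out is not None:
            true_states_out[cid] = state

        if fate == "divided":
            conv = config.conv_pre if end < config.cutoff_h else config.conv_post
            for _ in range(2):
                kid_state = state
                if state == "NEDiff" and rng.random() < conv:
                    kid_state = "PrE"
                queue.append((next_id(), cid, kid_state, end + dt))
    if truncated:
        warnings.warn(
            f"simulation truncated at cell cap {config.cell_cap}", RuntimeWarning
        )
        tracks = _demote_childless_divided(tracks)
    return LineageForest(
        tracks, condition_label=config.condition_label, frame_interval_h=dt
    )


def simulate_expression_clusters(
    n_genes: int,
    cluster_means: dict[str, np.ndarray],
    n_cells_per_cluster: int | dict[str, int],
    dispersion: float = 0.3,
    seed: int = 0,
) -> ClusteredMatrix:
    """Count-like clustered matrix from per-cluster mean profiles.

    Counts are log-normal-Poisson: per cell, rates are the cluster's mean
    profile perturbed on the log scale by N(0, dispersion) noise.
    """
    if len(cluster_means) < 2:
        raise ConfigError("need >= 2 clusters")
    rng = np.random.default_rng(seed)
    if isinstance(n_cells_per_cluster, int):
        n_cells_per_cluster = {k: n_cells_per_cluster for k in cluster_means}
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    cols = []
    cell_ids = []
    labels = {}
    for cname in sorted(cluster_means):
        profile = np.asarray(cluster_means[cname], dtype=float)
        if profile.shape != (n_genes,):
            raise ConfigError(f"cluster {cname!r}: profile length != n_genes")
        for j in range(n_cells_per_cluster[cname]):
            rate = profile * np.exp(rng.normal(0.0, dispersion, size=n_genes))
            cols.append(rng.poisson(rate))
            cid = f"{cname}_{j:04d}"
            cell_ids.append(cid)
            labels[cid] = cname
    return ClusteredMatrix(
        values=np.column_stack(cols).astype(float),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cluster_labels=labels,
    )


def make_profile_family(
    n_genes: int,
    n_clusters: int,
    base_expression: float = 5.0,
    n_marker_genes: int = 30,
    marker_fold: float = 8.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Distinct mean profiles sharing a backbone, one marker block each."""
    rng = np.random.default_rng(seed)
    backbone = rng.gamma(2.0, base_expression / 2.0, size=n_genes)
    profiles = {}
    for k in range(n_clusters):
        p = backbone.copy()
        lo = k * n_marker_genes
        p[lo:lo + n_marker_genes] *= marker_fold
        profiles[f"cl{k}"] = p
    return profiles
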