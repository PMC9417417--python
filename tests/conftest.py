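"""Shared fixtures: hand-built toy forests and simulated forests."""

from __future__ import annotations

import numpy as np
import pytest

from lineagedyn.tracks_io import FRAME_INTERVAL_H, CellTrack, LineageForest


def make_track(
    cell_id: str,
    parent_id: str | None,
    birth: float,
    end: float,
    fate: str,
    intensity: float = 0.15,
    dt: float = FRAME_INTERVAL_H,
    phase: list[float] | None = None,
) -> CellTrack:
    """Track with constant intensity on a regular frame grid from birth to end."""
    n = int(round((end - birth) / dt)) + 1
    times = tuple(birth + dt * i for i in range(n))
    return CellTrack(
        cell_id=cell_id,
        parent_id=parent_id,
        frame_times=times,
        intensity_trace=tuple([intensity] * n),
        fate=fate,
        phase_trace=tuple(phase) if phase is not None else None,
    )


def chain_forest(intensities_and_fates, dt: float = FRAME_INTERVAL_H,
                 cycle_h: float = 16.0) -> LineageForest:
    """Single-lineage forest: each cell has one child (last is censored)."""
    tracks = {}
    birth = 0.0
    parent = None
    for i, (intensity, fate) in enumerate(intensities_and_fates):
        cid = f"n{i}"
        tracks[cid] = make_track(cid, parent, birth, birth + cycle_h, fate,
                                 intensity=intensity, dt=dt)
        parent = cid
        birth = birth + cycle_h + dt
    return LineageForest(tracks, check_divided_children=False)


@pytest.fixture
def trio_forest() -> LineageForest:
    """Mother P (divided) with daughters A, B (both censored)."""
    tracks = {
        "P": make_track("P", None, 0.0, 16.0, "divided"),
        "A": make_track("A", "P", 16.0 + FRAME_INTERVAL_H, 30.0, "censored"),
        "B": make_track("B", "P", 16.0 + FRAME_INTERVAL_H, 30.0, "censored"),
    }
    return LineageForest(tracks)


@pytest.fixture
def three_generation_forest() -> LineageForest:
    """Root -> 2 divided -> 4 censored leaves: pruning keeps the middle two."""
    dt = FRAME_INTERVAL_H
    tracks = {"R": make_track("R", None, 0.0, 16.0, "divided")}
    for i, name in enumerate(["M0", "M1"]):
        tracks[name] = make_track(name, "R", 16.0 + dt, 32.0 + dt, "divided")
        for j in range(2):
            leaf = f"L{i}{j}"
            tracks[leaf] = make_track(leaf, name, 32.0 + 2 * dt, 40.0, "censored")
    return LineageForest(tracks)


def full_binary_forest(depth: int, cycle_h: float = 15.0,
                       dt: float = FRAME_INTERVAL_H,
                       intensity: float = 0.15) -> LineageForest:
    """Complete binary tree; all internal cells divided, leaves censored."""
    tracks = {}

    def build(cid: str, parent: str | None, birth: float, level: int) -> None:
        if level == depth:
            tracks[cid] = make_track(cid, parent, birth, birth + cycle_h,
                                     "censored", intensity, dt)
            return
        tracks[cid] = make_track(cid, parent, birth, birth + cycle_h,
                                 "divided", intensity, dt)
        for tag in ("a", "b"):
            build(cid + tag, cid, birth + cycle_h + dt, level + 1)

    build("r", None, 0.0, 0)
    return LineageForest(tracks)


@pytest.fixture(scope="session")
def nacl_forest_with_states():
    """Medium simulated steady-state forest plus its generative states."""
    from lineagedyn.synthetic_data import simulate_forest, nacl_like_config

    states: dict[str, str] = {}
    forest = simulate_forest(
        nacl_like_config(seed=11, n_roots=14, duration_h=115, frame_interval_h=1.0),
        true_states_out=states,
    )
    return forest, states
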