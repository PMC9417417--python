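"""Population statistics over labelled lineage forests.

All operations expect a forest already pruned to complete-cycle cells
(:func:`lineagedyn.tracks_io.prune_incomplete`) and, where relevant, a
:class:`lineagedyn.compartments.StateLabeling` covering those cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .compartments import StateLabeling
from .errors import DataError, NotApplicableError
from .tracks_io import CellTrack, LineageForest, division_time

logger = logging.getLogger(__name__)


def day_of_birth(track: CellTrack, day_offset: int = 1) -> int:
    """Day bin of a cell: the day containing its birth (day 1 = first 24 h)."""
    return int(math.floor(track.birth_time / 24.0)) + day_offset


# ---------------------------------------------------------------------------
# survival / death
# ---------------------------------------------------------------------------

def survival_table(
    forest: LineageForest,
    labeling: StateLabeling | None = None,
    by_day: bool = False,
    day_offset: int = 1,
) -> pd.DataFrame:
    """Survival/death counts and rates per group.

    A cell counts as surviving if it divided and as dying if it died; the
    forest must be pruned so censored cells are absent. Groups are the
    assigned state, the day of birth, or their cross. Division-time medians
    (divided cells only) come with the distribution SD.
    """
    rows = []
    for cid, tr in forest.tracks.items():
        if tr.fate not in ("divided", "died"):
            raise DataError(
                f"cell {cid} has fate {tr.fate!r}; prune the forest first"
            )
        state = labeling[cid] if labeling is not None and cid in labeling else "all"
        rows.append(
            {
                "cell_id": cid,
                "state": state,
                "day": day_of_birth(tr, day_offset),
                "survived": tr.fate == "divided",
                "division_time": division_time(tr) if tr.fate == "divided" else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    keys = []
    if labeling is not None:
        keys.append("state")
    if by_day:
        keys.append("day")
    if not keys:
        df["group"] = "all"
        keys = ["group"]

    out = []
    if df.empty:
        return pd.DataFrame(
            columns=keys + ["n_survive", "n_die", "n_total", "survival_rate",
                            "death_rate", "division_time_median", "division_time_sd"]
        )
    for key_vals, grp in df.groupby(keys):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        n_survive = int(grp["survived"].sum())
        n_total = len(grp)
        n_die = n_total - n_survive
        divs = grp["division_time"].dropna()
        rec = dict(zip(keys, key_vals))
        rec.update(
            n_survive=n_survive,
            n_die=n_die,
            n_total=n_total,
            survival_rate=n_survive / n_total if n_total else np.nan,
            death_rate=n_die / n_total if n_total else np.nan,
            division_time_median=float(divs.median()) if len(divs) else np.nan,
            division_time_sd=float(divs.std(ddof=1)) if len(divs) > 1 else np.nan,
        )
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

@dataclass
class TransitionSummary:
    """Mother->daughter compartment moves and derived rates."""

    counts: pd.DataFrame  # integer counts, mother state x daughter state
    probabilities: pd.DataFrame  # row-normalized
    per24h: pd.DataFrame | None = None  # expected transitions per 24 h
    residence: pd.DataFrame | None = None  # per-state run-length summary
    n_excluded: int = 0


def _mother_daughter_pairs(forest: LineageForest, labeling: StateLabeling):
    """(mother id, daughter id) pairs where both members are labelled."""
    n_excluded = 0
    pairs = []
    for cid, tr in forest.tracks.items():
        if tr.parent_id is None:
            continue
        if cid not in labeling:
            continue
        if tr.parent_id not in labeling:
            n_excluded += 1
            continue
        pairs.append((tr.parent_id, cid))
    if n_excluded:
        logger.info("excluded %d daughters without a labelled mother", n_excluded)
    return pairs, n_excluded


def transition_matrix(forest: LineageForest, labeling: StateLabeling) -> TransitionSummary:
    """Per-generation transition counts and row-normalized probabilities.

    Each labelled daughter contributes one observation of its mother's state
    moving (or not) to its own.
    """
    states = list(labeling.states())
    counts = pd.DataFrame(0, index=states, columns=states, dtype=int)
    pairs, n_excluded = _mother_daughter_pairs(forest, labeling)
    for mother, daughter in pairs:
        counts.loc[labeling[mother], labeling[daughter]] += 1
    row_sums = counts.sum(axis=1)
    probs = counts.div(row_sums.replace(0, np.nan), axis=0)
    return TransitionSummary(counts=counts, probabilities=probs, n_excluded=n_excluded)


def transitions_per_day(
    forest: LineageForest,
    labeling: StateLabeling,
    weight_clip: float = 2.0,
) -> TransitionSummary:
    """Transition rates rescaled to a 24-h unit by the mother's division time.

    Each mother->daughter observation is weighted by ``24/division_time`` of
    the mother (clipped at ``weight_clip``: one observed division cannot
    evidence more transitions than clip allows). Entry (i, j) is the expected
    number of i->j daughter outcomes per state-i cell per 24 h.
    """
    states = list(labeling.states())
    weighted = pd.DataFrame(0.0, index=states, columns=states)
    n_obs = pd.Series(0.0, index=states)
    pairs, n_excluded = _mother_daughter_pairs(forest, labeling)
    n_clipped = 0
    for mother, daughter in pairs:
        d = division_time(forest.tracks[mother])
        w = 24.0 / d
        if w > weight_clip:
            w = weight_clip
            n_clipped += 1
        weighted.loc[labeling[mother], labeling[daughter]] += w
        n_obs[labeling[mother]] += 1
    if n_clipped:
        logger.info("clipped %d per-24h weights at %.1f", n_clipped, weight_clip)
    per24h = weighted.div(n_obs.replace(0, np.nan), axis=0)
    counts = transition_matrix(forest, labeling)
    return TransitionSummary(
        counts=counts.counts,
        probabilities=counts.probabilities,
        per24h=per24h,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# residence times
# ---------------------------------------------------------------------------

def _state_runs(forest: LineageForest, labeling: StateLabeling):
    """Maximal same-state downward chains (deduplicated across leaf paths).

    A run starts at a labelled cell whose mother is unlabelled or in a
    different state, and follows each downward path while the state persists;
    every leaf of that same-state subtree yields one run. Returns tuples
    (state, n_generations, hours, truncated) where truncated means the run
    ended at the tree boundary rather than at an observed state switch.
    """
    runs = []
    for cid, tr in forest.tracks.items():
        if cid not in labeling:
            continue
        state = labeling[cid]
        parent = tr.parent_id
        if parent is not None and parent in labeling and labeling[parent] == state:
            continue  # interior of a run
        # DFS over the same-state subtree rooted at cid
        stack = [(cid, 1, forest.tracks[cid].lifespan)]
        while stack:
            cur, length, hours = stack.pop()
            same_kids = [
                k
                for k in forest.children.get(cur, [])
                if k in labeling and labeling[k] == state
            ]
            if same_kids:
                for k in same_kids:
                    stack.append((k, length + 1, hours + forest.tracks[k].lifespan))
            else:
                any_labeled_kid = any(
                    k in labeling for k in forest.children.get(cur, [])
                )
                runs.append((state, length, hours, not any_labeled_kid))
    return runs


def residence_times(
    forest: LineageForest,
    labeling: StateLabeling,
    include_truncated: bool = True,
) -> pd.DataFrame:
    """Mean +/- SD residence per state, in generations and in hours.

    Residence is the length of a maximal same-state run along a lineage
    path. Runs cut short by the tree boundary are included by default
    (excluding them biases residence short); pass ``include_truncated=False``
    to keep only runs ending in an observed switch.
    """
    runs = _state_runs(forest, labeling)
    if not include_truncated:
        runs = [r for r in runs if not r[3]]
    rows = []
    for state in labeling.states():
        sruns = [r for r in runs if r[0] == state]
        gens = np.array([r[1] for r in sruns], dtype=float)
        hours = np.array([r[2] for r in sruns], dtype=float)
        rows.append(
            {
                "state": state,
                "n_runs": len(sruns),
                "residence_generations_mean": gens.mean() if len(gens) else np.nan,
                "residence_generations_sd": gens.std(ddof=1) if len(gens) > 1 else np.nan,
                "residence_hours_mean": hours.mean() if len(hours) else np.nan,
                "residence_hours_sd": hours.std(ddof=1) if len(hours) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fate conversion and prospective fate
# ---------------------------------------------------------------------------

def _tree_of(forest: LineageForest, cid: str) -> str:
    while forest.tracks[cid].parent_id is not None:
        cid = forest.tracks[cid].parent_id
    return cid


def conversion_fraction(
    forest: LineageForest,
    labeling: StateLabeling,
    cutoff_h: float = 72.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Fraction of cells converting NEDiff->PrE before vs after ``cutoff_h``.

    A conversion is a PrE-labelled cell with a NEDiff-labelled mother; the
    denominator is the at-risk population, i.e. cells with a NEDiff-labelled
    mother born in the window. Uncertainty is a per-tree bootstrap SD (the
    paper's +/- procedure is unstated).
    """
    pairs, _ = _mother_daughter_pairs(forest, labeling)
    obs = []  # (tree id, window 'pre'|'post', converted)
    for mother, daughter in pairs:
        if labeling[mother] != "NEDiff":
            continue
        window = "pre" if forest.tracks[daughter].birth_time < cutoff_h else "post"
        obs.append((_tree_of(forest, daughter), window, labeling[daughter] == "PrE"))

    def frac(observations, window):
        sub = [c for t, w, c in observations if w == window]
        return sum(sub) / len(sub) if sub else np.nan

    rng = np.random.default_rng(seed)
    trees = sorted(set(t for t, _, _ in obs))
    boot = {"pre": [], "post": []}
    for _ in range(n_boot):
        chosen = rng.choice(trees, size=len(trees), replace=True) if trees else []
        resampled = [o for t in chosen for o in obs if o[0] == t]
        for w in ("pre", "post"):
            boot[w].append(frac(resampled, w))
    out = {}
    for w in ("pre", "post"):
        vals = np.array([v for v in boot[w] if not np.isnan(v)])
        out[f"{w}_fraction"] = frac(obs, w)
        out[f"{w}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        out[f"{w}_n"] = sum(1 for _, ww, _ in obs if ww == w)
    out["cutoff_h"] = cutoff_h
    return out


def _descendants(forest: LineageForest, cid: str):
    stack = list(forest.children.get(cid, []))
    while stack:
        cur = stack.pop()
        yield cur
        stack.extend(forest.children.get(cur, []))


def prospective_fate_comparison(
    forest: LineageForest,
    labeling: StateLabeling,
    at_day: int = 2,
    day_offset: int = 1,
) -> dict:
    """Compare intensities of same-day NEDiff cells by their clonal future.

    Day-``at_day`` NEDiff cells are split into those with at least one
    PrE-labelled descendant (prospective PrE fate) and those without; the
    groups are compared with a two-sided Mann-Whitney test on mean cycle
    intensity.
    """
    from .tracks_io import mean_cell_intensity

    groups: dict[str, list[float]] = {"PrE_fate": [], "NEDiff_fate": []}
    counts = {"PrE_fate": 0, "NEDiff_fate": 0}
    for cid, tr in forest.tracks.items():
        if cid not in labeling or labeling[cid] != "NEDiff":
            continue
        if day_of_birth(tr, day_offset) != at_day:
            continue
        has_pre = any(
            d in labeling and labeling[d] == "PrE" for d in _descendants(forest, cid)
        )
        key = "PrE_fate" if has_pre else "NEDiff_fate"
        groups[key].append(mean_cell_intensity(tr))
        counts[key] += 1

    out = {"at_day": at_day}
    for key, vals in groups.items():
        arr = np.array(vals)
        out[f"{key}_n"] = len(arr)
        out[f"{key}_median"] = float(np.median(arr)) if len(arr) else np.nan
        out[f"{key}_sd"] = float(arr.std(ddof=1)) if len(arr) > 1 else np.nan
    if counts["PrE_fate"] > 0 and counts["NEDiff_fate"] > 0:
        stat, p = sps.mannwhitneyu(
            groups["PrE_fate"], groups["NEDiff_fate"], alternative="two-sided"
        )
        out["p_value"] = float(p)
        out["test"] = "mann-whitney two-sided"
    else:
        out["p_value"] = np.nan
        out["test"] = "not computed (empty group)"
    return out


# ---------------------------------------------------------------------------
# G1 metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class G1Metrics:
    cell_id: str
    division_time: float
    g1_length: float
    g1_ratio: float
    short_g1_flag: bool = False


def g1_metrics(
    track: CellTrack,
    phase_threshold: float = 0.5,
    hysteresis_frames: int = 2,
) -> G1Metrics:
    """G1 duration from the phase-reporter trace of a divided cell.

    The reporter is min-max normalized per cell; G1 runs from birth while the
    normalized signal stays above ``phase_threshold``, ending at the first
    frame of a below-threshold stretch at least ``hysteresis_frames`` long.
    If the reporter is already below threshold at birth, G1 is floored at one
    frame and flagged.
    """
    if track.phase_trace is None:
        raise NotApplicableError(f"cell {track.cell_id}: no phase trace")
    if track.fate != "divided":
        raise NotApplicableError(
            f"cell {track.cell_id}: G1 metrics need fate=divided"
        )
    d = division_time(track)
    phase = np.asarray(track.phase_trace, dtype=float)
    lo, hi = phase.min(), phase.max()
    norm = np.zeros_like(phase) if hi == lo else (phase - lo) / (hi - lo)
    times = np.asarray(track.frame_times)
    dt_frame = times[1] - times[0] if len(times) > 1 else d

    below = norm <= phase_threshold
    end_idx = len(times) - 1
    flagged = False
    i = 0
    while i < len(below):
        if below[i]:
            j = i
            while j < len(below) and below[j]:
                j += 1
            if j - i >= hysteresis_frames or j == len(below):
                end_idx = i
                break
            i = j
        else:
            i += 1
    if end_idx == 0:
        g1 = dt_frame  # reporter below threshold at birth: floor at one frame
        flagged = True
    else:
        g1 = times[end_idx] - times[0]
    g1 = min(g1, d)
    if g1 <= 0 or g1 > d:
        raise DataError(f"cell {track.cell_id}: invalid G1 length {g1}")
    return G1Metrics(
        cell_id=track.cell_id,
        division_time=d,
        g1_length=float(g1),
        g1_ratio=float(g1 / d),
        short_g1_flag=flagged,
    )


def g1_table(
    forest: LineageForest,
    phase_threshold: float = 0.5,
    hysteresis_frames: int = 2,
) -> pd.DataFrame:
    """Per-cell G1 metrics for every divided cell with a phase trace."""
    rows = []
    for cid, tr in forest.tracks.items():
        if tr.fate != "divided" or tr.phase_trace is None:
            continue
        m = g1_metrics(tr, phase_threshold, hysteresis_frames)
        rows.append(
            {
                "cell_id": cid,
                "division_time": m.division_time,
                "g1_length": m.g1_length,
                "g1_ratio": m.g1_ratio,
                "short_g1_flag": m.short_g1_flag,
            }
        )
    return pd.DataFrame(rows)
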