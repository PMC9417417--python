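"""Track-table I/O and the lineage-forest data model.

Track tables are long-format delimited text with one row per (cell, frame):
columns ``cell_id, parent_id, time_h, intensity[, phase], fate``. Cells are
assembled into rooted trees; every structural invariant (unique ids, <=2
children, child birth after mother's end within one frame of tolerance) is
checked at construction time so downstream statistics can assume a valid
forest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, NotApplicableError, SchemaError, TopologyError

#: nominal frame spacing, hours (20-minute acquisition interval)
FRAME_INTERVAL_H = 1.0 / 3.0

#: allowed fate flags
FATES = ("divided", "died", "censored")

DEFAULT_SCHEMA = {
    "cell_id": "cell_id",
    "parent_id": "parent_id",
    "time_h": "time_h",
    "intensity": "intensity",
    "phase": "phase",
    "fate": "fate",
}


@dataclass(frozen=True)
class CellTrack:
    """One tracked cell: identity, parentage, timed intensity trace, fate.

    ``frame_times`` are hours, strictly increasing; ``intensity_trace`` holds
    one reporter value per frame (each value is already the median over the
    measured nuclear region). ``phase_trace`` optionally carries a cell-cycle
    phase reporter for G1 analyses.
    """

    cell_id: str
    parent_id: str | None
    frame_times: tuple[float, ...]
    intensity_trace: tuple[float, ...]
    fate: str
    phase_trace: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.frame_times) == 0:
            raise DataError(f"cell {self.cell_id}: empty track")
        if len(self.intensity_trace) != len(self.frame_times):
            raise DataError(
                f"cell {self.cell_id}: intensity trace length "
                f"{len(self.intensity_trace)} != {len(self.frame_times)} frames"
            )
        if self.phase_trace is not None and len(self.phase_trace) != len(self.frame_times):
            raise DataError(f"cell {self.cell_id}: phase trace length mismatch")
        times = np.asarray(self.frame_times)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise DataError(f"cell {self.cell_id}: frame times not strictly increasing")
        if self.fate not in FATES:
            raise DataError(f"cell {self.cell_id}: unknown fate {self.fate!r}")

    @property
    def birth_time(self) -> float:
        return self.frame_times[0]

    @property
    def end_time(self) -> float:
        return self.frame_times[-1]

    @property
    def lifespan(self) -> float:
        """Observed duration in hours (end - birth)."""
        return self.end_time - self.birth_time


def mean_cell_intensity(track: CellTrack) -> float:
    """Arithmetic mean of the per-frame intensities over the observed cycle."""
    if len(track.intensity_trace) == 0:
        raise DataError(f"cell {track.cell_id}: empty intensity trace")
    return float(np.mean(track.intensity_trace))


def division_time(track: CellTrack) -> float:
    """Cell-cycle length in hours for a cell that divided.

    Resolution is limited by the frame interval; the division frame is
    attributed to the mother, so the cycle runs birth frame to last frame.
    """
    if track.fate != "divided":
        raise NotApplicableError(
            f"cell {track.cell_id}: division_time undefined for fate={track.fate!r}"
        )
    return track.end_time - track.birth_time


@dataclass
class LineageForest:
    """A set of rooted trees over :class:`CellTrack` with validated timing."""

    tracks: dict[str, CellTrack]
    condition_label: str = ""
    frame_interval_h: float = FRAME_INTERVAL_H
    #: enforce "divided => 1-2 children"; False for pruned/subset forests,
    #: where a divided cell's daughters may have been dropped as censored
    check_divided_children: bool = True
    #: roots whose birth was observed before their parent was subset away;
    #: these still count as complete-cycle cells when pruning
    complete_roots: frozenset = frozenset()
    #: original parent id of each severed root, preserved so kinship
    #: (sisters/cousins across a dropped ancestor) survives subsetting
    external_parents: dict = field(default_factory=dict)
    children: dict[str, list[str]] = field(init=False)
    roots: list[str] = field(init=False)
    generation: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self._rebuild_topology()
        self._validate()

    def _rebuild_topology(self) -> None:
        self.children = {cid: [] for cid in self.tracks}
        self.roots = []
        for cid, tr in self.tracks.items():
            if tr.parent_id is None:
                self.roots.append(cid)
            else:
                if tr.parent_id not in self.tracks:
                    raise TopologyError(f"cell {cid}: parent {tr.parent_id!r} not in forest")
                self.children[tr.parent_id].append(cid)
        for kids in self.children.values():
            kids.sort()
        self.roots.sort()
        # BFS depth from roots; also detects unreachable cells (cycles)
        self.generation = {}
        queue = [(r, 0) for r in self.roots]
        while queue:
            cid, g = queue.pop()
            self.generation[cid] = g
            queue.extend((k, g + 1) for k in self.children[cid])
        if len(self.generation) != len(self.tracks):
            raise TopologyError("forest contains cells unreachable from any root (cycle?)")

    def _validate(self) -> None:
        tol = self.frame_interval_h + 1e-9
        for cid, kids in self.children.items():
            if len(kids) > 2:
                raise TopologyError(f"cell {cid} has {len(kids)} children (max 2)")
            parent = self.tracks[cid]
            for k in kids:
                child = self.tracks[k]
                if child.birth_time < parent.end_time - tol:
                    raise TopologyError(
                        f"cell {k} born at {child.birth_time:.3f} h before parent "
                        f"{cid} ended at {parent.end_time:.3f} h"
                    )
            if (
                self.check_divided_children
                and parent.fate == "divided"
                and len(kids) not in (1, 2)
            ):
                raise TopologyError(f"cell {cid} divided but has {len(kids)} children")

    def __len__(self) -> int:
        return len(self.tracks)

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self.tracks

    def subtree_size(self, root: str) -> int:
        size = 0
        stack = [root]
        while stack:
            cid = stack.pop()
            size += 1
            stack.extend(self.children[cid])
        return size

    def subset(self, keep: Iterable[str]) -> "LineageForest":
        """Forest restricted to ``keep``; severed cells become roots."""
        keep = set(keep)
        new_tracks = {}
        severed: dict[str, str] = {}
        for cid in keep:
            tr = self.tracks[cid]
            if tr.parent_id is not None and tr.parent_id not in keep:
                severed[cid] = tr.parent_id
                tr = replace(tr, parent_id=None)
            new_tracks[cid] = tr
        complete = (self.complete_roots & keep) | set(severed)
        ext = {c: p for c, p in self.external_parents.items() if c in keep}
        ext.update(severed)
        return LineageForest(new_tracks, condition_label=self.condition_label,
                             frame_interval_h=self.frame_interval_h,
                             check_divided_children=False,
                             complete_roots=frozenset(complete),
                             external_parents=ext)

    def parent_of(self, cell_id: str) -> str | None:
        """Parent id, falling back to the pre-subset parent of severed roots."""
        p = self.tracks[cell_id].parent_id
        if p is not None:
            return p
        return self.external_parents.get(cell_id)


def prune_incomplete(forest: LineageForest) -> LineageForest:
    """Restrict a forest to cells with complete cell-cycle information.

    Drops every root-generation cell (birth not observed) and every
    right-censored cell (alive at movie end). The result contains only cells
    with fate ``divided`` or ``died``; division-time statistics additionally
    use only the ``divided`` subset.
    """
    keep = [
        cid
        for cid, tr in forest.tracks.items()
        if (forest.generation[cid] > 0 or cid in forest.complete_roots)
        and tr.fate in ("divided", "died")
    ]
    return forest.subset(keep)


def _resolve_schema(columns: Sequence[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    for key in ("cell_id", "parent_id", "time_h", "intensity", "fate"):
        if mapping[key] not in columns:
            raise SchemaError(f"required column {mapping[key]!r} (for {key}) not found")
    if mapping["phase"] not in columns:
        mapping["phase"] = None  # type: ignore[assignment]
    return mapping


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() in ("", "NA", "none", "None", "root")


def read_tracks(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    condition_label: str = "",
    frame_interval_h: float = FRAME_INTERVAL_H,
) -> LineageForest:
    """Read a long-format track table (CSV or TSV by extension) into a forest."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = _resolve_schema(list(df.columns), schema)

    dup = df.duplicated(subset=[cols["cell_id"], cols["time_h"]])
    if dup.any():
        bad = df.loc[dup, cols["cell_id"]].iloc[0]
        raise DataError(f"duplicated (cell_id, time) rows, e.g. cell {bad!r}")

    tracks: dict[str, CellTrack] = {}
    for cid, grp in df.groupby(cols["cell_id"], sort=False):
        grp = grp.sort_values(cols["time_h"])
        parent_raw = grp[cols["parent_id"]].iloc[0]
        parent = None if _is_missing(parent_raw) else str(parent_raw)
        fates = grp[cols["fate"]].unique()
        if len(fates) != 1:
            raise DataError(f"cell {cid}: inconsistent fate flags {fates}")
        phase = None
        if cols["phase"] is not None and not grp[cols["phase"]].isna().all():
            phase = tuple(float(v) for v in grp[cols["phase"]])
        tracks[str(cid)] = CellTrack(
            cell_id=str(cid),
            parent_id=parent,
            frame_times=tuple(float(t) for t in grp[cols["time_h"]]),
            intensity_trace=tuple(float(v) for v in grp[cols["intensity"]]),
            fate=str(fates[0]),
            phase_trace=phase,
        )
    return LineageForest(tracks, condition_label=condition_label,
                         frame_interval_h=frame_interval_h)


def write_tracks(forest: LineageForest, path: str | Path) -> None:
    """Write a forest back to the long-format track table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    rows = []
    has_phase = any(tr.phase_trace is not None for tr in forest.tracks.values())
    for cid in sorted(forest.tracks):
        tr = forest.tracks[cid]
        for i, t in enumerate(tr.frame_times):
            row = {
                "cell_id": cid,
                "parent_id": tr.parent_id if tr.parent_id is not None else "",
                "time_h": t,
                "intensity": tr.intensity_trace[i],
                "fate": tr.fate,
            }
            if has_phase:
                row["phase"] = tr.phase_trace[i] if tr.phase_trace is not None else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def forest_to_json(forest: LineageForest) -> dict:
    """JSON-serializable representation of a forest (documented schema)."""
    return {
        "condition_label": forest.condition_label,
        "frame_interval_h": forest.frame_interval_h,
        "cells": [
            {
                "cell_id": cid,
                "parent_id": tr.parent_id,
                "frame_times": list(tr.frame_times),
                "intensity_trace": list(tr.intensity_trace),
                "phase_trace": list(tr.phase_trace) if tr.phase_trace is not None else None,
                "fate": tr.fate,
            }
            for cid, tr in sorted(forest.tracks.items())
        ],
    }


def forest_from_json(obj: dict) -> LineageForest:
    tracks = {
        c["cell_id"]: CellTrack(
            cell_id=c["cell_id"],
            parent_id=c["parent_id"],
            frame_times=tuple(c["frame_times"]),
            intensity_trace=tuple(c["intensity_trace"]),
            fate=c["fate"],
            phase_trace=tuple(c["phase_trace"]) if c.get("phase_trace") else None,
        )
        for c in obj["cells"]
    }
    return LineageForest(
        tracks,
        condition_label=obj.get("condition_label", ""),
        frame_interval_h=obj.get("frame_interval_h", FRAME_INTERVAL_H),
    )


def save_forest(forest: LineageForest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(forest_to_json(forest)))


def load_forest(path: str | Path) -> LineageForest:
    return forest_from_json(json.loads(Path(path).read_text()))
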