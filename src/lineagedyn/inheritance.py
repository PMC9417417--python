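"""Cell-cycle length inheritance across kin relations.

Pairs of divided cells related as sisters (shared mother), cousins (shared
grandmother, different mothers) or mother-daughter are extracted from a
pruned forest. Correlation is Pearson on symmetrized pairs, with a
permutation p-value (family-level for mother-daughter pairs, which are
clustered) and a pair-bootstrap confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, InsufficientDataError
from .tracks_io import LineageForest, division_time

RELATIONS = ("sister", "cousin", "mother_daughter")


@dataclass
class KinPairSet:
    relation: str
    pairs: list[tuple[float, float]]
    cell_ids: list[tuple[str, str]] = field(default_factory=list)
    #: family key per pair (shared ancestor id), used for clustered permutation
    families: list[str] = field(default_factory=list)
    condition_label: str = ""

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class CorrelationResult:
    relation: str
    r: float
    n_pairs: int
    p_value: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_perm: int


def _divided_cells(forest: LineageForest) -> dict[str, float]:
    return {
        cid: division_time(tr)
        for cid, tr in forest.tracks.items()
        if tr.fate == "divided"
    }


def extract_kin_pairs(
    forest: LineageForest,
    relation: str,
    seed: int = 0,
    max_birth_h: float | None = None,
) -> KinPairSet:
    """All kin pairs of the requested relation with both cycles observed.

    Sister and cousin pairs are unordered; each is entered once with its
    member order randomized under the seed so symmetrization is unbiased.
    Mother-daughter pairs are ordered (mother first), one per daughter.
    Kinship across ancestors removed by pruning is preserved via the
    forest's severed-parent records.

    ``max_birth_h`` restricts pairs to cells born before that time. Near the
    movie end only fast-cycling cells complete, and sisters share a birth
    time, so this joint selection induces a spurious positive cycle
    correlation; a margin of roughly three median cycle lengths removes it.
    """
    if relation not in RELATIONS:
        raise ConfigError(f"unknown relation {relation!r}")
    cycles = _divided_cells(forest)
    if max_birth_h is not None:
        cycles = {
            c: v for c, v in cycles.items()
            if forest.tracks[c].birth_time < max_birth_h
        }
    rng = np.random.default_rng(seed)
    pairs: list[tuple[float, float]] = []
    ids: list[tuple[str, str]] = []
    fams: list[str] = []

    def add_unordered(a: str, b: str, family: str) -> None:
        if rng.random() < 0.5:
            a, b = b, a
        pairs.append((cycles[a], cycles[b]))
        ids.append((a, b))
        fams.append(family)

    # sibships over complete-cycle cells, keyed by (possibly severed) mother
    sibships: dict[str, list[str]] = {}
    for cid in sorted(cycles):
        mother = forest.parent_of(cid)
        if mother is not None:
            sibships.setdefault(mother, []).append(cid)

    if relation == "sister":
        for mother, kids in sorted(sibships.items()):
            if len(kids) == 2:
                add_unordered(kids[0], kids[1], mother)
    elif relation == "cousin":
        # mothers that are sisters themselves, grouped by the grandmother
        mother_sibships: dict[str, list[str]] = {}
        for cid in sorted(forest.tracks):
            granny = forest.parent_of(cid)
            if granny is not None:
                mother_sibships.setdefault(granny, []).append(cid)
        for granny, mothers in sorted(mother_sibships.items()):
            if len(mothers) != 2:
                continue
            side_a = sibships.get(mothers[0], [])
            side_b = sibships.get(mothers[1], [])
            for a in side_a:
                for b in side_b:
                    add_unordered(a, b, granny)
    else:  # mother_daughter
        for mother, kids in sorted(sibships.items()):
            if mother not in cycles:
                continue
            for k in kids:
                pairs.append((cycles[mother], cycles[k]))
                ids.append((mother, k))
                fams.append(mother)
    return KinPairSet(
        relation=relation,
        pairs=pairs,
        cell_ids=ids,
        families=fams,
        condition_label=forest.condition_label,
    )


def _symmetrized_r(x: np.ndarray, y: np.ndarray, symmetric: bool) -> float:
    if symmetric:
        xs = np.concatenate([x, y])
        ys = np.concatenate([y, x])
    else:
        xs, ys = x, y
    if xs.std() == 0 or ys.std() == 0:
        raise DataError("zero variance in a pair margin; r undefined")
    return float(np.corrcoef(xs, ys)[0, 1])


def kin_correlation(
    pair_set: KinPairSet,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation of cycle lengths within kin pairs.

    Unordered relations are symmetrized (each pair contributes both
    orderings; n is still the pair count). The p-value permutes pair
    memberships — at the family level for mother-daughter sets, where the
    same mother appears in up to two pairs — and the CI is a percentile pair
    bootstrap.
    """
    if len(pair_set) < 3:
        raise InsufficientDataError(
            f"need >= 3 pairs, got {len(pair_set)} for {pair_set.relation}"
        )
    x = np.array([p[0] for p in pair_set.pairs])
    y = np.array([p[1] for p in pair_set.pairs])
    symmetric = pair_set.relation != "mother_daughter"
    r_obs = _symmetrized_r(x, y, symmetric)
    rng = np.random.default_rng(seed)

    # permutation null: shuffle the second margin against the first, by family
    fams = np.array(pair_set.families)
    unique_fams = np.unique(fams)
    fam_to_rows = {f: np.where(fams == f)[0] for f in unique_fams}
    count_ge = 0
    n_valid = 0
    for _ in range(n_perm):
        perm_fams = rng.permutation(unique_fams)
        y_perm = np.empty_like(y)
        pos = 0
        for f in perm_fams:
            rows = fam_to_rows[f]
            take = y[rows]
            y_perm[pos:pos + len(rows)] = rng.permutation(take)
            pos += len(rows)
        try:
            r_null = _symmetrized_r(x, y_perm, symmetric)
        except DataError:
            continue
        n_valid += 1
        if abs(r_null) >= abs(r_obs) - 1e-12:
            count_ge += 1
    p = (count_ge + 1) / (n_valid + 1) if n_valid else float("nan")

    boot_rs = []
    idx = np.arange(len(pair_set))
    for _ in range(n_boot):
        take = rng.choice(idx, size=len(idx), replace=True)
        try:
            boot_rs.append(_symmetrized_r(x[take], y[take], symmetric))
        except DataError:
            continue
    if boot_rs:
        ci_low, ci_high = np.percentile(boot_rs, [2.5, 97.5])
    else:
        ci_low = ci_high = float("nan")
    return CorrelationResult(
        relation=pair_set.relation,
        r=r_obs,
        n_pairs=len(pair_set),
        p_value=float(p),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        n_perm=n_perm,
    )


def permutation_null_band(
    pair_set: KinPairSet, n_perm: int = 10_000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """(lower, upper) quantiles of the permutation null distribution of r."""
    x = np.array([p[0] for p in pair_set.pairs])
    y = np.array([p[1] for p in pair_set.pairs])
    symmetric = pair_set.relation != "mother_daughter"
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        try:
            rs.append(_symmetrized_r(x, y_perm, symmetric))
        except DataError:
            continue
    lo, hi = np.percentile(rs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def bootstrap_median_diff(
    group_a,
    group_b,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Difference of medians (a - b) with a percentile bootstrap CI.

    Significance is the CI excluding zero. Degenerate single-element groups
    produce a flagged zero-width CI.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} < 100 gives an unstable CI", UserWarning)
    rng = np.random.default_rng(seed)
    diff = float(np.median(a) - np.median(b))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.median(rng.choice(a, a.size, replace=True)) - np.median(
            rng.choice(b, b.size, replace=True)
        )
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    degenerate = a.size == 1 and b.size == 1
    return {
        "median_diff": diff,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "significant": bool(lo > 0 or hi < 0) and not degenerate,
        "degenerate": degenerate,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "n_boot": n_boot,
    }
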