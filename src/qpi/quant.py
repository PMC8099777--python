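"""Positional-isomer stoichiometry from ladder intensities.

Fragment pairs are always formed within one ion kind at one cleavage
(ion-type efficiencies cancel only within a type); stretch-level ratios use
the median over pairs with an SEM over the pair population. Candidate
isomers and per-(stretch, level) intensity fractions define a linear
system whose non-negative, sum-to-one solution is the isomer stoichiometry;
indistinguishable isomers are reported as groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.stats import ttest_ind

from .ladder import PTMLadder, Stretch, stretches_for

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentPair",
    "StretchRatios",
    "IsomerSystem",
    "QuantResult",
    "IsomerGroup",
    "collect_pairs",
    "count_pair_positions",
    "stretch_ratio",
    "compare_stretches",
    "detect_occupancy",
    "prune_candidates",
    "build_system",
    "solve_abundances",
    "group_isomers",
]

#: Below this many pairs a stretch ratio is flagged unreliable.
MIN_PAIRS = 3
#: SEM floor used when building solver weights.
SEM_FLOOR = 1e-4
#: Results with SEM above this fraction are flagged "treat with caution".
SEM_CAUTION = 0.10


@dataclass(frozen=True)
class FragmentPair:
    """Intensities of one ion kind at one cleavage observed at two adjacent
    modification levels; the ratio I(m+1)/I(m) reflects isomer abundance."""

    terminus: str
    cleavage: int
    ion_kind: tuple[str, str]
    intensity_low: float
    intensity_high: float

    @property
    def ratio(self) -> float:
        return self.intensity_high / self.intensity_low


def collect_pairs(ladder: PTMLadder, stretch: Stretch, m: int) -> list[FragmentPair]:
    """All (cleavage, ion kind) pairs within a stretch where BOTH level m
    and level m+1 are present. Positions with only one level are skipped
    (they still count toward :func:`count_pair_positions`)."""
    pairs: list[FragmentPair] = []
    for c in stretch.cleavages():
        low = ladder.cell(c, m)
        high = ladder.cell(c, m + 1)
        for kind in sorted(set(low) & set(high)):
            pairs.append(
                FragmentPair(ladder.terminus, c, kind, low[kind], high[kind])
            )
    return pairs


def count_pair_positions(ladder: PTMLadder, stretch: Stretch, m: int) -> int:
    """Number of (cleavage, ion kind) positions where at least one of the
    two levels is present — the denominator for pair-completeness."""
    n = 0
    for c in stretch.cleavages():
        n += len(set(ladder.cell(c, m)) | set(ladder.cell(c, m + 1)))
    return n


@dataclass(frozen=True)
class StretchRatios:
    stretch: Stretch
    pairs: tuple[FragmentPair, ...]
    median_ratio: float
    sem: float
    n_pairs: int
    n_possible: int
    reliable: bool


def stretch_ratio(
    pairs: Sequence[FragmentPair],
    stretch: Stretch | None = None,
    n_possible: int | None = None,
    min_pairs: int = MIN_PAIRS,
) -> StretchRatios:
    """Median and SEM (sample SD / sqrt(n)) of the pair ratios of a stretch.

    Stretches with fewer than ``min_pairs`` pairs are flagged unreliable and
    excluded from abundance solving unless forced.
    """
    ratios = np.array([p.ratio for p in pairs])
    n = len(ratios)
    if n == 0:
        median_r, sem = math.nan, math.nan
    else:
        median_r = float(np.median(ratios))
        sem = float(np.std(ratios, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return StretchRatios(
        stretch=stretch,
        pairs=tuple(pairs),
        median_ratio=median_r,
        sem=sem,
        n_pairs=n,
        n_possible=n_possible if n_possible is not None else n,
        reliable=n >= min_pairs,
    )


def compare_stretches(a: StretchRatios, b: StretchRatios) -> float:
    """Two-sided equal-variance Student's t-test on the pair-ratio samples
    of two stretches; p < 0.05 indicates the boundary site between them is
    modified in some isomer."""
    xa = np.array([p.ratio for p in a.pairs])
    xb = np.array([p.ratio for p in b.pairs])
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("both stretches need at least 2 pairs")
    if np.var(xa) == 0 and np.var(xb) == 0:
        return 1.0 if np.mean(xa) == np.mean(xb) else 0.0
    return float(ttest_ind(xa, xb, equal_var=True).pvalue)


def _nearest_flank_levels(
    ladder: PTMLadder, cleavages: Iterable[int], min_evidence: int
) -> tuple[set[int], int]:
    """Levels present on the occupied cleavages nearest to a boundary,
    walking outward until at least ``min_evidence`` cells were seen."""
    levels: set[int] = set()
    total = 0
    for c in cleavages:
        found = False
        for m in range(ladder.n_max + 1):
            k = len(ladder.cell(c, m))
            if k:
                levels.add(m)
                total += k
                found = True
        if found and total >= min_evidence:
            break
    return levels, total


def _occupancy_one_ladder(ladder: PTMLadder, site: int, min_evidence: int) -> str:
    if ladder.terminus == "N":
        pre_walk = range(site - 1, 0, -1)
        post_walk = range(site, ladder.L)
    else:
        # C-ladder levels step up when moving toward the N terminus.
        pre_walk = range(site, ladder.L)
        post_walk = range(site - 1, 0, -1)
    pre, n_pre = _nearest_flank_levels(ladder, pre_walk, min_evidence)
    post, n_post = _nearest_flank_levels(ladder, post_walk, min_evidence)
    if n_pre < min_evidence or n_post < min_evidence:
        return "undetermined"
    if min(post) == min(pre):
        return "partial" if max(post) > max(pre) else "unmodified"
    if min(post) == min(pre) + 1:
        return "full"
    return "undetermined"


def detect_occupancy(
    ladders: Mapping[str, PTMLadder] | PTMLadder,
    site: int,
    min_evidence: int = 3,
) -> str:
    """Classify the occupancy of ``site`` from the level step across its
    boundary, combining the evidence of both ladders.

    ``full``: the lowest modification level present just before the site
    disappears entirely past it (a clean step with no level overlap);
    ``partial``: the pre-site level persists while a higher one appears;
    ``unmodified``: no step; ``undetermined``: insufficient flanking
    evidence. A site buried behind another modified site is invisible to
    one terminus' ladder, which is why both are consulted.
    """
    if isinstance(ladders, PTMLadder):
        ladders = {ladders.terminus: ladders}
    statuses = {
        _occupancy_one_ladder(ladder, site, min_evidence)
        for ladder in ladders.values()
    }
    if "partial" in statuses or {"full", "unmodified"} <= statuses:
        return "partial"
    if "full" in statuses:
        return "full"
    if "unmodified" in statuses:
        return "unmodified"
    return "undetermined"


def _isomer_level(sites: Sequence[int], stretch: Stretch, n_mods: int) -> int:
    """Modification level an isomer's fragments carry over a stretch."""
    n_before = sum(1 for s in sites if s <= stretch.end)
    return n_before if stretch.terminus == "N" else n_mods - n_before


def prune_candidates(
    candidates: Sequence[tuple[int, ...]],
    ladders: Mapping[str, PTMLadder],
    min_evidence: int = 3,
) -> list[tuple[int, ...]]:
    """Drop isomers that require a (stretch, level) cell class with zero
    accepted fragments while that stretch holds at least ``min_evidence``
    fragments at other levels (the data positively excludes them)."""
    if not candidates:
        return []
    pool = sorted({s for combo in candidates for s in combo})
    n_mods = len(candidates[0])
    kept = []
    for combo in candidates:
        excluded = False
        for terminus, ladder in ladders.items():
            for stretch in stretches_for(pool, terminus, ladder.L):
                level = _isomer_level(combo, stretch, n_mods)
                own = ladder.count_matched(stretch.start, stretch.end, level)
                others = sum(
                    ladder.count_matched(stretch.start, stretch.end, m)
                    for m in range(ladder.n_max + 1)
                    if m != level
                )
                if own == 0 and others >= min_evidence:
                    excluded = True
                    break
            if excluded:
                break
        if not excluded:
            kept.append(tuple(combo))
    return kept


@dataclass
class SystemRow:
    terminus: str
    stretch: Stretch
    level: int
    fraction: float
    sem: float
    n_positions: int


@dataclass
class IsomerSystem:
    """Design matrix linking isomer abundances to per-(stretch, level)
    intensity fractions.

    ``A[row, i] = 1`` iff isomer ``i`` carries that row's level over that
    row's stretch; within one stretch each isomer column sums to 1 and the
    observed fractions sum to 1.
    """

    isomers: tuple[tuple[int, ...], ...]
    rows: list[SystemRow]
    A: np.ndarray
    b: np.ndarray
    weights: np.ndarray

    @property
    def n_isomers(self) -> int:
        return len(self.isomers)

    def column_rank(self) -> int:
        return int(np.linalg.matrix_rank(self.A)) if self.A.size else 0

    def is_rank_deficient(self) -> bool:
        return self.column_rank() < self.n_isomers


def build_system(
    candidates: Sequence[tuple[int, ...]],
    ladders: Mapping[str, PTMLadder],
    min_pairs: int = MIN_PAIRS,
    min_evidence: int = 3,
    prune: bool = True,
) -> IsomerSystem:
    """Build the abundance system from candidate isomers and both ladders.

    Observed fractions per stretch come from the per-position normalized
    intensity vectors over the levels the candidates imply (median across
    positions, renormalized); weights are 1/SEM^2. Stretches with fewer
    than ``min_pairs`` usable positions are dropped.
    """
    candidates = [tuple(sorted(c)) for c in candidates]
    if not candidates:
        raise ValueError("no candidate isomers")
    n_mods = len(candidates[0])
    if any(len(c) != n_mods for c in candidates):
        raise ValueError("all candidates must carry the same modification count")
    if prune:
        pruned = prune_candidates(candidates, ladders, min_evidence)
        if pruned:
            candidates = pruned
        else:
            logger.warning("pruning removed every candidate; keeping the full list")

    pool = sorted({s for combo in candidates for s in combo})
    rows: list[SystemRow] = []
    a_rows: list[list[float]] = []
    for terminus, ladder in ladders.items():
        for stretch in stretches_for(pool, terminus, ladder.L):
            levels = sorted({_isomer_level(c, stretch, n_mods) for c in candidates})
            # Per-position normalized intensity vectors over these levels.
            fractions: dict[int, list[float]] = {lv: [] for lv in levels}
            n_positions = 0
            for c in stretch.cleavages():
                kinds = set()
                for lv in levels:
                    kinds |= set(ladder.cell(c, lv))
                for kind in kinds:
                    vec = np.array(
                        [ladder.cell(c, lv).get(kind, 0.0) for lv in levels]
                    )
                    total = vec.sum()
                    if total <= 0:
                        continue
                    n_positions += 1
                    for lv, frac in zip(levels, vec / total):
                        fractions[lv].append(float(frac))
            if n_positions < min_pairs:
                if n_positions:
                    logger.warning(
                        "stretch %s-%d..%d dropped: only %d usable positions",
                        terminus, stretch.start, stretch.end, n_positions,
                    )
                continue
            # Single-level stretches stay in: they only restate sum-to-one
            # but keep trivial (e.g. one-isomer) systems solvable.
            medians = np.array([np.median(fractions[lv]) for lv in levels])
            if medians.sum() <= 0:
                continue
            medians = medians / medians.sum()
            for lv, med in zip(levels, medians):
                vals = np.array(fractions[lv])
                sem = (
                    float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                    if len(vals) > 1
                    else 0.0
                )
                rows.append(
                    SystemRow(terminus, stretch, lv, float(med), sem, n_positions)
                )
                a_rows.append(
                    [
                        1.0 if _isomer_level(c, stretch, n_mods) == lv else 0.0
                        for c in candidates
                    ]
                )
    if not rows:
        raise ValueError("no usable stretches: cannot build an abundance system")
    A = np.array(a_rows)
    b = np.array([r.fraction for r in rows])
    weights = np.array([1.0 / max(r.sem, SEM_FLOOR) ** 2 for r in rows])
    return IsomerSystem(tuple(candidates), rows, A, b, weights)


@dataclass(frozen=True)
class IsomerGroup:
    """Isomers the observed stretches cannot distinguish (identical design
    columns); reported with a summed abundance."""

    members: tuple[tuple[int, ...], ...]
    shared_sites: tuple[int, ...]
    alternative_sites: tuple[tuple[int, ...], ...]

    @property
    def label(self) -> str:
        shared = "+".join(f"s{s}" for s in self.shared_sites) or "-"
        if len(self.members) == 1:
            return "+".join(f"s{s}" for s in self.members[0])
        alts = "|".join(
            ",".join(f"s{s}" for s in alt) or "-" for alt in self.alternative_sites
        )
        return f"{shared}+({alts})"


def group_isomers(system: IsomerSystem) -> list[IsomerGroup]:
    """Partition isomers into equivalence classes of identical design-matrix
    columns, deterministically ordered by first member."""
    by_column: dict[tuple, list[int]] = {}
    for i in range(system.n_isomers):
        key = tuple(system.A[:, i]) if system.A.size else ()
        by_column.setdefault(key, []).append(i)
    groups = []
    for indices in by_column.values():
        members = tuple(system.isomers[i] for i in indices)
        shared = set(members[0])
        for m in members[1:]:
            shared &= set(m)
        alternatives = tuple(
            tuple(sorted(set(m) - shared)) for m in members
        )
        groups.append(
            IsomerGroup(members, tuple(sorted(shared)), alternatives)
        )
    groups.sort(key=lambda g: g.members[0])
    return groups


@dataclass(frozen=True)
class QuantResult:
    groups: tuple[IsomerGroup, ...]
    abundances: tuple[float, ...]
    sems: tuple[float, ...]
    residual_norm: float
    grouped: bool
    caution: bool

    def abundance_by_sites(self) -> dict[str, float]:
        return {g.label: a for g, a in zip(self.groups, self.abundances)}


def solve_abundances(system: IsomerSystem) -> QuantResult:
    """Weighted non-negative least squares on the simplex.

    Isomers with identical design columns are merged into groups and the
    group sums are solved for; abundances are normalized to sum exactly 1.
    Per-estimate SEMs come from first-order propagation of the row SEMs.
    """
    if system.A.size == 0 or not np.any(system.b > 0):
        raise ValueError("infeasible system: no informative observations")
    groups = group_isomers(system)
    G = np.column_stack(
        [system.A[:, system.isomers.index(g.members[0])] for g in groups]
    )
    w_sqrt = np.sqrt(system.weights)
    A_w = G * w_sqrt[:, None]
    b_w = system.b * w_sqrt
    # Sum-to-one as a heavily weighted extra row, then exact renormalization.
    lam = 10.0 * float(np.max(w_sqrt)) * max(1.0, float(np.max(np.abs(b_w))))
    A_aug = np.vstack([A_w, lam * np.ones((1, G.shape[1]))])
    b_aug = np.concatenate([b_w, [lam]])
    alpha, _ = nnls(A_aug, b_aug)
    total = alpha.sum()
    if total <= 0:
        raise ValueError("solver returned an all-zero abundance vector")
    alpha = alpha / total
    residual = float(np.linalg.norm(A_w @ alpha - b_w))

    # First-order error propagation through the weighted normal equations.
    W = np.diag(system.weights)
    cov = np.linalg.pinv(G.T @ W @ G)
    sems = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    caution = bool(np.any(sems > SEM_CAUTION))
    if caution:
        logger.warning("abundance SEM exceeds %.0f%%: treat with caution", SEM_CAUTION * 100)
    return QuantResult(
        groups=tuple(groups),
        abundances=tuple(float(a) for a in alpha),
        sems=tuple(float(s) for s in sems),
        residual_norm=residual,
        grouped=any(len(g.members) > 1 for g in groups),
        caution=caution,
    )
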