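"""PTM ladders and site-localization scoring.

A ladder arranges accepted fragments of one terminus family on a grid of
cleavage position x modification count. Both ladders are indexed by
N-terminal cleavage coordinates (cleavage ``c`` sits after residue ``c``),
so a C-terminal fragment with ``j`` residues lands at ``c = L - j``.

For a candidate site combination the cleavages split into stretches of
constant expected modification count; each stretch is scored with a
binomial chance-match probability and the per-stretch p-values are
combined in log10 space, correcting each stretch by the previous one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import binom

from .chem import ConstraintSet, Modification, enumerate_isomers
from .fragments import ION_TYPES
from .assignment import VotedFragment

LN10 = math.log(10.0)

__all__ = [
    "PTMLadder",
    "Stretch",
    "StretchScore",
    "CombinationScore",
    "build_ladder",
    "stretches_for",
    "stretch_probability",
    "stretch_log10_probability",
    "score_combination",
    "localize",
]

#: Candidate-explosion guard for localize().
MAX_CANDIDATES = 10**6


class PTMLadder:
    """Per-terminus matrix of matched evidence indexed by cleavage position
    and modification count; each cell keeps its contributing (ion kind,
    intensity) entries."""

    def __init__(self, terminus: str, L: int, n_max: int,
                 ion_kinds: Sequence[tuple[str, str]]):
        if terminus not in ("N", "C"):
            raise ValueError("terminus must be 'N' or 'C'")
        self.terminus = terminus
        self.L = L
        self.n_max = n_max
        #: (ion_type, loss) kinds that were searched for this terminus family
        self.ion_kinds = tuple(sorted(ion_kinds))
        #: (cleavage, mod_count) -> {(ion_type, loss): intensity}
        self.cells: dict[tuple[int, int], dict[tuple[str, str], float]] = {}

    def add(self, cleavage: int, mod_count: int, ion_kind: tuple[str, str],
            intensity: float) -> None:
        if mod_count > self.n_max:
            raise ValueError(
                f"fragment carries {mod_count} modifications but the ladder "
                f"allows at most {self.n_max}"
            )
        if not 1 <= cleavage <= self.L - 1:
            raise ValueError(f"cleavage {cleavage} outside 1..{self.L - 1}")
        cell = self.cells.setdefault((cleavage, mod_count), {})
        cell[ion_kind] = cell.get(ion_kind, 0.0) + intensity

    def intensity(self, cleavage: int, mod_count: int) -> float:
        return sum(self.cells.get((cleavage, mod_count), {}).values())

    def cell(self, cleavage: int, mod_count: int) -> dict[tuple[str, str], float]:
        return self.cells.get((cleavage, mod_count), {})

    def matrix(self) -> dict[tuple[int, int], float]:
        """Summed-intensity view for TSV export."""
        return {key: sum(kinds.values()) for key, kinds in self.cells.items()}

    def count_matched(self, start: int, end: int, mod_count: int) -> int:
        """Distinct (cleavage, ion kind) entries at a level within a span."""
        return sum(
            len(self.cells.get((c, mod_count), {})) for c in range(start, end + 1)
        )


def build_ladder(
    fragments: Iterable[VotedFragment],
    terminus: str,
    L: int,
    n_max: int,
    ion_kinds: Sequence[tuple[str, str]] | None = None,
) -> PTMLadder:
    """Arrange accepted fragments of one terminus family on the ladder grid;
    intensities of fragments sharing a (cleavage, level, ion kind) cell sum."""
    fragments = [
        f for f in fragments if ION_TYPES[f.fragment.ion_type].terminus == terminus
    ]
    if ion_kinds is None:
        ion_kinds = sorted({(f.fragment.ion_type, f.fragment.loss) for f in fragments})
    ladder = PTMLadder(terminus, L, n_max, ion_kinds)
    for f in fragments:
        frag = f.fragment
        cleavage = frag.cleavage_index if terminus == "N" else L - frag.cleavage_index
        ladder.add(cleavage, frag.mod_count, (frag.ion_type, frag.loss), f.intensity)
    return ladder


@dataclass(frozen=True)
class Stretch:
    """A run of cleavages over which the expected modification count of one
    terminus' fragments is constant (bounds inclusive, N-coordinates)."""

    terminus: str
    start: int
    end: int
    mod_count: int

    @property
    def n_cleavages(self) -> int:
        return self.end - self.start + 1

    def cleavages(self) -> range:
        return range(self.start, self.end + 1)


def stretches_for(sites: Sequence[int], terminus: str, L: int) -> list[Stretch]:
    """Tile cleavages 1..L-1 into stretches of constant expected level for
    the given site combination.

    N-terminal fragments at cleavage c carry ``#{sites <= c}`` modifications;
    C-terminal fragments carry the complement. Empty spans (a site at
    residue 1, or two adjacent sites) produce no stretch; the emitted
    stretches still tile 1..L-1 exactly.
    """
    sites = sorted(sites)
    n = len(sites)
    stretches: list[Stretch] = []
    for m in range(n + 1):
        start = 1 if m == 0 else sites[m - 1]
        end = (sites[m] - 1) if m < n else L - 1
        start, end = max(start, 1), min(end, L - 1)
        if start > end:
            continue
        level = m if terminus == "N" else n - m
        stretches.append(Stretch(terminus, start, end, level))
    if terminus == "C":
        stretches.reverse()  # read from the C terminus: ascending level
    return stretches


def stretch_log10_probability(n_matched: int, n_theoretical: int, q: float) -> float:
    """log10 of the binomial upper tail P(X >= n_matched | n_theoretical, q).

    Zero matches (or a zero-theoretical stretch) contribute p = 1.
    """
    if not 0 <= n_matched <= n_theoretical:
        raise ValueError("need 0 <= n_matched <= n_theoretical")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if n_matched == 0 or n_theoretical == 0:
        return 0.0
    return float(binom.logsf(n_matched - 1, n_theoretical, q)) / LN10


def stretch_probability(n_matched: int, n_theoretical: int, q: float) -> float:
    """Linear-space version of :func:`stretch_log10_probability` (may
    underflow to 0 for very long, fully matched stretches)."""
    return 10.0 ** stretch_log10_probability(n_matched, n_theoretical, q)


@dataclass(frozen=True)
class StretchScore:
    stretch: Stretch
    n_matched: int
    n_theoretical: int
    log10_p: float
    log10_p_corrected: float


@dataclass(frozen=True)
class CombinationScore:
    """Score of one candidate site combination, kept in log10 space.

    ``log10_corrected`` applies the previous-stretch correction (each
    stretch's p divided by the preceding stretch's p, reading each ladder
    from its own terminus); ``log10_plain`` is the uncorrected product.
    """

    sites: tuple[int, ...]
    stretch_scores: tuple[StretchScore, ...]
    log10_corrected: float
    log10_plain: float

    def score(self, variant: str = "corrected") -> float:
        if variant == "corrected":
            return self.log10_corrected
        if variant == "plain":
            return self.log10_plain
        raise ValueError(f"unknown score variant {variant!r}")

    @property
    def n_stretches(self) -> int:
        return len(self.stretch_scores)


def score_combination(
    ladders: Mapping[str, PTMLadder],
    sites: Sequence[int],
    q: float,
) -> CombinationScore:
    """Score one site combination against both ladders.

    Per ladder and per stretch, the matched count is the number of occupied
    (cleavage, ion kind) cells at the stretch's expected level; the
    theoretical count is cleavages x searched ion kinds. Fragments at other
    levels inside the span are ignored — they belong to other isomers.
    """
    sites = tuple(sorted(sites))
    scores: list[StretchScore] = []
    log10_plain = 0.0
    log10_corrected = 0.0
    for terminus in ("N", "C"):
        ladder = ladders.get(terminus)
        if ladder is None:
            continue
        prev_log10 = 0.0
        for stretch in stretches_for(sites, terminus, ladder.L):
            n_theo = stretch.n_cleavages * len(ladder.ion_kinds)
            n_match = ladder.count_matched(stretch.start, stretch.end, stretch.mod_count)
            n_match = min(n_match, n_theo)
            lp = stretch_log10_probability(n_match, n_theo, q)
            lp_corr = lp - prev_log10
            scores.append(StretchScore(stretch, n_match, n_theo, lp, lp_corr))
            log10_plain += lp
            log10_corrected += lp_corr
            prev_log10 = lp
    return CombinationScore(sites, tuple(scores), log10_corrected, log10_plain)


def localize(
    ladders: Mapping[str, PTMLadder],
    sequence: str,
    n_mods: int,
    mod: Modification,
    q: float,
    constraints: ConstraintSet | None = None,
    score_variant: str = "plain",
) -> list[CombinationScore]:
    """Enumerate candidate site combinations over the acceptor positions,
    score them all, and return them ranked (best = most negative log10
    first). Ties break by fewer stretches, then lexicographic site order.

    Ranking defaults to the plain product of per-stretch p-values: the
    previous-stretch correction telescopes to the final stretch's p within
    each ladder, which makes all candidates sharing the same terminal
    stretches tie. The corrected value is still computed and reported on
    every :class:`CombinationScore` for auditability.
    """
    if n_mods < 1:
        raise ValueError("n_mods must be >= 1")
    pool = mod.acceptor_positions(sequence)
    if math.comb(len(pool), n_mods) > MAX_CANDIDATES and (
        constraints is None or not constraints.fixed_sites
    ):
        raise ValueError(
            f"{math.comb(len(pool), n_mods)} candidate combinations exceed the "
            f"{MAX_CANDIDATES} guard; supply constraints or a site short-list"
        )
    candidates = enumerate_isomers(pool, n_mods, constraints)
    scored = [score_combination(ladders, combo, q) for combo in candidates]
    scored.sort(key=lambda s: (s.score(score_variant), s.n_stretches, s.sites))
    return scored
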