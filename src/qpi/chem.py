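"""Amino-acid and modification mass bookkeeping, decoy scrambling and
candidate-isomer combinatorics.

All residue indexing is 1-based (site 64 means the 64th residue of the
sequence). Cleavage indices count residues on the N-terminal side of a
backbone bond, so a protein of length ``L`` has cleavages ``1 .. L-1``.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "WATER",
    "AMMONIA",
    "CARBON_MONOXIDE",
    "HYDROGEN",
    "PROTON",
    "RESIDUE_MASSES",
    "Modification",
    "Proteoform",
    "ConstraintSet",
    "PHOSPHO",
    "HEAVY_VAL",
    "BUILTIN_MODIFICATIONS",
    "validate_sequence",
    "protein_neutral_mass",
    "infer_mod_count",
    "scramble_sequence",
    "enumerate_isomers",
    "count_modifiable_pairs",
]

# Monoisotopic constants (Da)
WATER = 18.010565
AMMONIA = 17.026549
CARBON_MONOXIDE = 27.994915
HYDROGEN = 1.007825
PROTON = 1.007276

#: Monoisotopic residue masses of the 20 standard amino acids (Da).
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}


@dataclass(frozen=True)
class Modification:
    """A single covalent modification type.

    Parameters
    ----------
    name :
        Human-readable label, e.g. ``"phospho"``.
    delta_mass :
        Monoisotopic mass shift in Da; must be non-zero.
    acceptor_residues :
        Residue letters that can carry the modification.
    """

    name: str
    delta_mass: float
    acceptor_residues: frozenset[str]

    def __post_init__(self) -> None:
        if self.delta_mass == 0:
            raise ValueError("modification delta_mass must be non-zero")
        if not self.acceptor_residues:
            raise ValueError("modification needs at least one acceptor residue")
        object.__setattr__(self, "acceptor_residues", frozenset(self.acceptor_residues))

    def acceptor_positions(self, sequence: str) -> list[int]:
        """1-based positions of acceptor residues in ``sequence``."""
        return [i + 1 for i, aa in enumerate(sequence) if aa in self.acceptor_residues]


PHOSPHO = Modification("phospho", 79.96633, frozenset("STY"))
#: 13C5,15N-valine used in the synthetic-ubiquitin benchmark; reusing the
#: Modification machinery keeps the whole PTM pipeline unchanged.
HEAVY_VAL = Modification("heavy-Val", 6.013810, frozenset("V"))

BUILTIN_MODIFICATIONS: dict[str, Modification] = {
    "phospho": PHOSPHO,
    "heavy-Val": HEAVY_VAL,
}


@dataclass(frozen=True)
class Proteoform:
    """A sequence plus an ordered set of modified site indices for one
    modification type."""

    sequence: str
    modification: Modification
    sites: tuple[int, ...]
    abundance_label: str | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        sites = tuple(self.sites)
        object.__setattr__(self, "sites", sites)
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise ValueError("modification sites must be strictly increasing")
        for s in sites:
            if not 1 <= s <= len(self.sequence):
                raise ValueError(f"site {s} outside sequence of length {len(self.sequence)}")
            if self.sequence[s - 1] not in self.modification.acceptor_residues:
                raise ValueError(
                    f"site {s} ({self.sequence[s - 1]}) is not an acceptor for "
                    f"{self.modification.name}"
                )

    @property
    def n_mods(self) -> int:
        return len(self.sites)

    def neutral_mass(self) -> float:
        return protein_neutral_mass(self.sequence, self.n_mods, self.modification)


@dataclass(frozen=True)
class ConstraintSet:
    """Site-occupancy constraints used to prune candidate isomers.

    ``fixed_sites`` are sites with 100% occupancy (must be present in every
    candidate); ``mutually_exclusive_pairs`` are unordered pairs that can
    never co-occur.
    """

    fixed_sites: frozenset[int] = frozenset()
    mutually_exclusive_pairs: frozenset[frozenset[int]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_sites", frozenset(self.fixed_sites))
        pairs = frozenset(frozenset(p) for p in self.mutually_exclusive_pairs)
        if any(len(p) != 2 for p in pairs):
            raise ValueError("mutually exclusive pairs must contain two distinct sites")
        object.__setattr__(self, "mutually_exclusive_pairs", pairs)

    def allows(self, sites: Iterable[int]) -> bool:
        s = set(sites)
        if not self.fixed_sites <= s:
            return False
        return not any(p <= s for p in self.mutually_exclusive_pairs)


def validate_sequence(sequence: str) -> str:
    """Validate a residue string, rejecting empty input and any letter
    outside the 20-residue table (including B, Z, X, U, O — silent mass
    approximations would corrupt downstream calibration)."""
    if not sequence:
        raise ValueError("empty sequence")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
    return sequence


def protein_neutral_mass(
    sequence: str, n_mods: int = 0, mod: Modification | None = None
) -> float:
    """Neutral monoisotopic mass of an intact protein carrying ``n_mods``
    copies of ``mod``: sum of residue masses + water + n_mods * delta."""
    validate_sequence(sequence)
    if n_mods < 0:
        raise ValueError("n_mods must be >= 0")
    if n_mods > 0 and mod is None:
        raise ValueError("a Modification is required when n_mods > 0")
    # fsum: exactly-rounded, so permuted sequences give identical masses
    mass = math.fsum(RESIDUE_MASSES[aa] for aa in sequence) + WATER
    if n_mods:
        mass += n_mods * mod.delta_mass
    return mass


def infer_mod_count(
    observed_precursor_mass: float,
    sequence: str,
    mod: Modification,
    tolerance_ppm: float = 5.0,
) -> int:
    """Infer the number of modifications from the observed precursor mass.

    Returns ``n = round((M_obs - M_unmod) / delta)`` provided the residual
    after rounding is within ``tolerance_ppm`` of the observed mass.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    unmod = protein_neutral_mass(sequence)
    n = round((observed_precursor_mass - unmod) / mod.delta_mass)
    if n < 0:
        raise ValueError(
            f"observed mass {observed_precursor_mass:.4f} is below the "
            f"unmodified mass {unmod:.4f}"
        )
    residual = observed_precursor_mass - (unmod + n * mod.delta_mass)
    if abs(residual) > tolerance_ppm * 1e-6 * observed_precursor_mass:
        raise ValueError(
            "precursor inconsistent with modification count: residual "
            f"{residual:+.4f} Da after assuming {n} x {mod.name}"
        )
    return n


def scramble_sequence(sequence: str, seed: int) -> str:
    """Composition-preserving Fisher–Yates shuffle of ``sequence``.

    Deterministic for a given seed; the scrambled decoy has the identical
    residue multiset and therefore the identical precursor mass.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2 to scramble")
    rng = random.Random(seed)
    chars = list(sequence)
    for i in range(len(chars) - 1, 0, -1):
        j = rng.randint(0, i)
        chars[i], chars[j] = chars[j], chars[i]
    return "".join(chars)


def enumerate_isomers(
    site_pool: Sequence[int],
    n_mods: int,
    constraints: ConstraintSet | None = None,
) -> list[tuple[int, ...]]:
    """Enumerate every size-``n_mods`` subset of ``site_pool`` satisfying the
    constraints, in deterministic lexicographic order."""
    pool = sorted(site_pool)
    if len(set(pool)) != len(pool):
        raise ValueError("site_pool contains duplicates")
    if n_mods > len(pool):
        raise ValueError(f"n_mods={n_mods} exceeds pool size {len(pool)}")
    constraints = constraints or ConstraintSet()
    if not set(constraints.fixed_sites) <= set(pool):
        raise ValueError("fixed sites must be members of the site pool")
    if len(constraints.fixed_sites) > n_mods:
        raise ValueError(
            f"{len(constraints.fixed_sites)} fixed sites cannot fit in "
            f"{n_mods} modifications"
        )
    return [
        combo
        for combo in itertools.combinations(pool, n_mods)
        if constraints.allows(combo)
    ]


def count_modifiable_pairs(sequence: str, mod: Modification) -> int:
    """Number of unordered pairs of acceptor residues in ``sequence``:
    C(k, 2) for k acceptors."""
    k = len(mod.acceptor_positions(sequence))
    return k * (k - 1) // 2
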