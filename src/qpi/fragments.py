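"""Theoretical neutral monoisotopic fragment masses on the modification grid.

All masses are neutral; charge is the deconvolution layer's concern. The
radical ETD species are expressed relative to the even-electron c/z ions:
``c-1`` is c minus one hydrogen atom and ``z+1`` is z plus one hydrogen
atom (z-dot).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .chem import (
    AMMONIA,
    CARBON_MONOXIDE,
    HYDROGEN,
    RESIDUE_MASSES,
    WATER,
    Modification,
    protein_neutral_mass,
    validate_sequence,
)

__all__ = [
    "ION_TYPES",
    "NEUTRAL_LOSSES",
    "ETD_DEFAULT_ION_TYPES",
    "ALL_ION_TYPES",
    "IonType",
    "FragmentIon",
    "FragmentTable",
    "generate_fragments",
    "complement_mass_check",
]


@dataclass(frozen=True)
class IonType:
    name: str
    terminus: str  # "N" or "C"
    offset: float  # Da added to the residue-mass sum of the fragment's side


# Offsets relative to the plain residue-mass sum of the fragment's own side.
ION_TYPES: dict[str, IonType] = {
    "b": IonType("b", "N", 0.0),
    "a": IonType("a", "N", -CARBON_MONOXIDE),
    "c": IonType("c", "N", AMMONIA),
    "c-1": IonType("c-1", "N", AMMONIA - HYDROGEN),
    "y": IonType("y", "C", WATER),
    "x": IonType("x", "C", WATER + CARBON_MONOXIDE - 2 * HYDROGEN),
    "z": IonType("z", "C", WATER - AMMONIA),
    "z+1": IonType("z+1", "C", WATER - AMMONIA + HYDROGEN),
}

NEUTRAL_LOSSES: dict[str, float] = {
    "none": 0.0,
    "water": -WATER,
    "ammonia": -AMMONIA,
    "hydrogen": -HYDROGEN,
}

#: Ion types significantly generated by ETD of intact proteins.
ETD_DEFAULT_ION_TYPES: tuple[str, ...] = ("c", "c-1", "y", "z", "z+1")
ALL_ION_TYPES: tuple[str, ...] = tuple(ION_TYPES)


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment: ion type, neutral loss, cleavage index
    (residues on the fragment's own terminus side), modification count and
    neutral monoisotopic mass."""

    ion_type: str
    loss: str
    cleavage_index: int
    mod_count: int
    neutral_mass: float

    @property
    def terminus(self) -> str:
        return ION_TYPES[self.ion_type].terminus

    @property
    def key(self) -> tuple[str, int, str, str, int]:
        t = ION_TYPES[self.ion_type]
        return (t.terminus, self.cleavage_index, self.ion_type, self.loss, self.mod_count)


class FragmentTable:
    """All theoretical fragments for one sequence, sorted by neutral mass,
    with exact lookup by (terminus, cleavage_index, ion_type, loss, mod_count)."""

    def __init__(self, sequence: str, fragments: Iterable[FragmentIon]):
        self.sequence = sequence
        self.fragments: list[FragmentIon] = sorted(
            fragments, key=lambda f: (f.neutral_mass, f.key)
        )
        self._by_key: dict[tuple, FragmentIon] = {}
        for frag in self.fragments:
            if frag.key in self._by_key:
                raise ValueError(f"duplicate fragment key {frag.key}")
            self._by_key[frag.key] = frag
        self.masses = [f.neutral_mass for f in self.fragments]

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[FragmentIon]:
        return iter(self.fragments)

    def lookup(
        self, terminus: str, cleavage_index: int, ion_type: str, loss: str, mod_count: int
    ) -> FragmentIon | None:
        return self._by_key.get((terminus, cleavage_index, ion_type, loss, mod_count))

    def ion_kinds(self, terminus: str | None = None) -> list[tuple[str, str]]:
        """Distinct (ion_type, loss) combinations present, optionally
        restricted to one terminus family."""
        kinds = {
            (f.ion_type, f.loss)
            for f in self.fragments
            if terminus is None or f.terminus == terminus
        }
        return sorted(kinds)


def generate_fragments(
    sequence: str,
    ion_types: Sequence[str] = ETD_DEFAULT_ION_TYPES,
    losses: Sequence[str] = ("none",),
    max_mods: int = 0,
    mod: Modification | None = None,
) -> FragmentTable:
    """Build the full theoretical fragment grid for ``sequence``.

    For every cleavage index ``i in 1..L-1``, every selected ion type and
    loss, and every modification count ``m in 0..max_mods`` one fragment is
    produced with mass ``sum(side residues) + type offset + loss + m*delta``.
    """
    validate_sequence(sequence)
    if not ion_types:
        raise ValueError("ion_types must be nonempty")
    if max_mods < 0:
        raise ValueError("max_mods must be >= 0")
    if max_mods > 0 and mod is None:
        raise ValueError("a Modification is required when max_mods > 0")
    unknown = [t for t in ion_types if t not in ION_TYPES]
    if unknown:
        raise ValueError(f"unknown ion types: {unknown}")
    unknown_losses = [l for l in losses if l not in NEUTRAL_LOSSES]
    if unknown_losses:
        raise ValueError(f"unknown losses: {unknown_losses}")

    L = len(sequence)
    prefix = [0.0] * (L + 1)
    for i, aa in enumerate(sequence):
        prefix[i + 1] = prefix[i] + RESIDUE_MASSES[aa]
    total = prefix[L]

    delta = mod.delta_mass if mod is not None else 0.0
    fragments: list[FragmentIon] = []
    for i in range(1, L):
        for name in ion_types:
            ion = ION_TYPES[name]
            side_sum = prefix[i] if ion.terminus == "N" else total - prefix[L - i]
            base = side_sum + ion.offset
            for loss_name in losses:
                for m in range(max_mods + 1):
                    fragments.append(
                        FragmentIon(
                            ion_type=name,
                            loss=loss_name,
                            cleavage_index=i,
                            mod_count=m,
                            neutral_mass=base + NEUTRAL_LOSSES[loss_name] + m * delta,
                        )
                    )
    return FragmentTable(sequence, fragments)


def complement_mass_check(
    table: FragmentTable,
    sequence: str,
    mod_count: int = 0,
    mod: Modification | None = None,
    atol: float = 1e-6,
) -> bool:
    """Validate the complementarity identities ``c_i(m) + z_{L-i}(n-m) = M``
    and ``b_i(m) + y_{L-i}(n-m) = M`` for every cleavage present in the
    table (no-loss fragments only). Vacuously true when a pair's members are
    absent."""
    L = len(sequence)
    M = protein_neutral_mass(sequence, mod_count, mod)
    for n_type, c_type in (("c", "z"), ("b", "y")):
        for i in range(1, L):
            for m in range(mod_count + 1):
                left = table.lookup("N", i, n_type, "none", m)
                right = table.lookup("C", L - i, c_type, "none", mod_count - m)
                if left is None or right is None:
                    continue
                if abs(left.neutral_mass + right.neutral_mass - M) > atol:
                    return False
    return True
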