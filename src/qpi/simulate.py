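"""Seeded simulator for deconvoluted ETD spectrum sets of proteoform
mixtures, with full ground truth.

The central modeling assumption mirrors what the quantification rests on:
the per-cleavage base fragmentation intensity is SHARED across all isomers
(and replicates), so the expected modified/unmodified pair ratio on a
discriminating stretch equals the isomer abundance ratio exactly. An
optional site-suppression knob breaks that assumption on purpose to test
robustness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem import Modification, Proteoform, protein_neutral_mass
from .fragments import ION_TYPES, generate_fragments
from .peaklists import DeconvolutedSpectrum, SpectrumSet, write_peaklist

__all__ = ["SimulationConfig", "GroundTruth", "simulate_spectrum_set", "write_fixture"]

DEFAULT_EFFICIENCIES: dict[str, float] = {
    "c": 1.0,
    "c-1": 0.35,
    "y": 0.7,
    "z": 0.9,
    "z+1": 0.45,
}

DECOY_MASS_FLOOR = 150.0


@dataclass
class SimulationConfig:
    """Everything needed to generate one replicate-grouped spectrum set."""

    sequence: str
    modification: Modification
    #: (sites, abundance) per proteoform; abundances must sum to 1.
    proteoforms: Sequence[tuple[tuple[int, ...], float]]
    ion_efficiencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFICIENCIES)
    )
    base_intensity_median: float = 1e4
    base_intensity_sigma_log10: float = 0.4
    noise_cv: float = 0.0  # multiplicative, per replicate
    ppm_bias: float = 0.0
    ppm_sd: float = 0.0
    dropout: float = 0.0  # i.i.d. per fragment per replicate
    decoy_density: float = 0.0  # decoy peaks per 100 Da
    decoy_intensity_scale: float = 0.1
    n_replicates: int = 3
    seed: int = 0
    #: Optional (factor, window) intensity suppression near modified sites.
    site_suppression: tuple[float, int] | None = None

    def __post_init__(self) -> None:
        abundances = [a for _, a in self.proteoforms]
        if not abundances or any(a <= 0 for a in abundances):
            raise ValueError("proteoform abundances must be positive")
        if abs(sum(abundances) - 1.0) > 1e-9:
            raise ValueError("proteoform abundances must sum to 1")
        if self.noise_cv < 0 or self.dropout < 0 or self.decoy_density < 0:
            raise ValueError("noise_cv, dropout and decoy_density must be >= 0")
        for sites, _ in self.proteoforms:
            Proteoform(self.sequence, self.modification, tuple(sites))

    @property
    def n_mods(self) -> int:
        return len(self.proteoforms[0][0])


@dataclass
class GroundTruth:
    """Traceability record: every emitted peak is either a fragment class or
    a registered decoy."""

    #: key (terminus, cleavage, ion_type, mod_count) -> (mass, true intensity)
    classes: dict[tuple[str, int, str, int], tuple[float, float]]
    #: per replicate: keys that survived dropout
    emitted: list[set[tuple[str, int, str, int]]]
    #: per replicate: list of (mass, intensity) decoy peaks
    decoys: list[list[tuple[float, float]]]
    abundances: dict[tuple[int, ...], float]
    base_intensities: dict[int, float]

    def to_jsonable(self) -> dict:
        return {
            "classes": [
                {"terminus": t, "cleavage": c, "ion_type": ion, "mod_count": m,
                 "mass": mass, "intensity": inten}
                for (t, c, ion, m), (mass, inten) in sorted(self.classes.items())
            ],
            "emitted": [sorted(map(list, keys)) for keys in self.emitted],
            "decoys": self.decoys,
            "abundances": {
                "+".join(map(str, sites)): a for sites, a in self.abundances.items()
            },
            "base_intensities": self.base_intensities,
        }


def _mod_level(sites: Sequence[int], terminus: str, cleavage_index: int, L: int) -> int:
    """Modifications carried by a fragment with ``cleavage_index`` residues
    on its own terminus side."""
    if terminus == "N":
        return sum(1 for s in sites if s <= cleavage_index)
    return sum(1 for s in sites if s > L - cleavage_index)


def simulate_spectrum_set(
    config: SimulationConfig,
) -> tuple[SpectrumSet, GroundTruth]:
    """Generate ``n_replicates`` deconvoluted spectra plus ground truth.

    Deterministic for a given seed (byte-identical peak lists).
    """
    rng = np.random.default_rng(config.seed)
    seq = config.sequence
    L = len(seq)
    n_mods = config.n_mods
    mod = config.modification
    ion_types = sorted(config.ion_efficiencies)
    table = generate_fragments(seq, ion_types, ("none",), n_mods, mod)

    # One base intensity per cleavage, shared by all isomers and replicates.
    sigma_ln = config.base_intensity_sigma_log10 * math.log(10.0)
    base = {
        c: float(
            config.base_intensity_median * math.exp(sigma_ln * rng.standard_normal())
        )
        for c in range(1, L)
    }

    suppression = config.site_suppression
    classes: dict[tuple[str, int, str, int], tuple[float, float]] = {}
    for sites, abundance in config.proteoforms:
        for ion in ion_types:
            terminus = ION_TYPES[ion].terminus
            eff = config.ion_efficiencies[ion]
            for ci in range(1, L):
                m = _mod_level(sites, terminus, ci, L)
                cleavage_pos = ci if terminus == "N" else L - ci
                intensity = abundance * base[cleavage_pos] * eff
                if suppression is not None:
                    factor, window = suppression
                    if any(abs(cleavage_pos - s) <= window for s in sites):
                        intensity *= factor
                frag = table.lookup(terminus, ci, ion, "none", m)
                key = (terminus, ci, ion, m)
                mass = frag.neutral_mass
                prev = classes.get(key)
                classes[key] = (mass, (prev[1] if prev else 0.0) + intensity)

    precursor = protein_neutral_mass(seq, n_mods, mod if n_mods else None)
    sigma_noise = (
        math.sqrt(math.log(1.0 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    )

    spectra: SpectrumSet = []
    emitted: list[set] = []
    decoy_registry: list[list[tuple[float, float]]] = []
    ordered_keys = sorted(classes)
    for rep in range(config.n_replicates):
        masses: list[float] = []
        intensities: list[float] = []
        kept: set = set()
        for key in ordered_keys:
            mass, inten = classes[key]
            if config.dropout > 0 and rng.random() < config.dropout:
                continue
            kept.add(key)
            if sigma_noise > 0:
                # E[noise]=1 for a log-normal with mu=-sigma^2/2
                inten *= math.exp(
                    sigma_noise * rng.standard_normal() - 0.5 * sigma_noise**2
                )
            ppm = config.ppm_bias + config.ppm_sd * rng.standard_normal()
            masses.append(mass * (1.0 + ppm * 1e-6))
            intensities.append(inten)
        emitted.append(kept)

        decoys: list[tuple[float, float]] = []
        if config.decoy_density > 0:
            span = max(precursor - DECOY_MASS_FLOOR, 0.0)
            n_decoys = int(rng.poisson(config.decoy_density * span / 100.0))
            for _ in range(n_decoys):
                dm = float(DECOY_MASS_FLOOR + span * rng.random())
                di = float(
                    config.base_intensity_median
                    * config.decoy_intensity_scale
                    * math.exp(sigma_ln * rng.standard_normal())
                )
                decoys.append((dm, di))
                masses.append(dm)
                intensities.append(di)
        decoy_registry.append(decoys)
        spectra.append(
            DeconvolutedSpectrum(
                masses,
                intensities,
                replicate_id=f"rep{rep + 1}",
                precursor_mass=precursor,
            )
        )

    truth = GroundTruth(
        classes=classes,
        emitted=emitted,
        decoys=decoy_registry,
        abundances={tuple(sites): a for sites, a in config.proteoforms},
        base_intensities=base,
    )
    return spectra, truth


def write_fixture(
    spectra: SpectrumSet, truth: GroundTruth, directory: str | Path
) -> list[Path]:
    """Write peak lists (one TSV per replicate) and a ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for spectrum in spectra:
        path = directory / f"{spectrum.replicate_id}.tsv"
        write_peaklist(spectrum, path)
        paths.append(path)
    truth_path = directory / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=2)
    paths.append(truth_path)
    return paths
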