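"""Fragment-to-peak matching, data-driven mass calibration, frequent-flyer
ion-type selection, scrambled-decoy fragment-level FDR, and replicate
majority voting.

No intensity threshold is ever applied during matching: false-positive
assignments show no substantial intensity dependence, so intensity cutoffs
cost real fragments without buying specificity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chem import Modification, scramble_sequence
from .fragments import (
    ALL_ION_TYPES,
    ION_TYPES,
    FragmentIon,
    FragmentTable,
    generate_fragments,
)
from .peaklists import DeconvolutedSpectrum, SpectrumSet

logger = logging.getLogger(__name__)

__all__ = [
    "Assignment",
    "VotedFragment",
    "CalibrationModel",
    "IonTypeSelection",
    "FDRReport",
    "SearchParams",
    "match_fragments",
    "calibrate",
    "select_ion_types",
    "sequence_coverage",
    "majority_vote",
    "estimate_fdr",
    "search_and_vote",
]


@dataclass(frozen=True)
class Assignment:
    """One theoretical fragment matched to one observed peak."""

    fragment: FragmentIon
    observed_mass: float
    intensity: float
    ppm_error: float
    replicate_id: str = ""

    @property
    def key(self):
        return self.fragment.key


@dataclass(frozen=True)
class VotedFragment:
    """A fragment accepted by majority voting; intensity is the median over
    the replicates in which it was assigned."""

    fragment: FragmentIon
    intensity: float
    n_replicates_present: int
    ppm_error: float


def match_fragments(
    spectrum: DeconvolutedSpectrum,
    table: FragmentTable,
    tolerance_ppm: float,
) -> list[Assignment]:
    """Match each theoretical fragment to its single nearest peak within
    ``tolerance_ppm`` (ties broken by smaller |ppm|, then higher intensity).

    A peak may serve multiple theoretical fragments: positional-isomer
    spectra are highly multiplexed and shared peaks are expected.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    if len(table) == 0:
        raise ValueError("fragment table is empty")
    if len(spectrum) == 0:
        return []

    masses = spectrum.masses
    intensities = spectrum.intensities
    theo = np.array(table.masses)
    idx = np.searchsorted(masses, theo)
    left = np.clip(idx - 1, 0, len(masses) - 1)
    right = np.clip(idx, 0, len(masses) - 1)

    assignments: list[Assignment] = []
    for frag, t, li, ri in zip(table.fragments, theo, left, right):
        best = None  # (abs_ppm, -intensity, observed_mass)
        for pi in {int(li), int(ri)}:
            ppm = (masses[pi] - t) / t * 1e6
            if abs(ppm) <= tolerance_ppm:
                cand = (abs(ppm), -intensities[pi], pi)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            pi = best[2]
            assignments.append(
                Assignment(
                    fragment=frag,
                    observed_mass=float(masses[pi]),
                    intensity=float(intensities[pi]),
                    ppm_error=float((masses[pi] - t) / t * 1e6),
                    replicate_id=spectrum.replicate_id,
                )
            )
    return assignments


@dataclass(frozen=True)
class CalibrationModel:
    """Systematic ppm shift and dispersion of the assignment population.

    Applying the model multiplies observed masses by ``1 - shift_ppm*1e-6``,
    bringing the median residual to ~0; the post-calibration matching
    tolerance is ``3 * sigma_ppm``.
    """

    shift_ppm: float
    sigma_ppm: float

    @property
    def tolerance_ppm(self) -> float:
        return 3.0 * self.sigma_ppm

    def apply(self, spectrum: DeconvolutedSpectrum) -> DeconvolutedSpectrum:
        return spectrum.with_masses(spectrum.masses * (1.0 - self.shift_ppm * 1e-6))

    def apply_all(self, spectra: SpectrumSet) -> SpectrumSet:
        return [self.apply(s) for s in spectra]


def calibrate(
    assignments: Sequence[Assignment], min_assignments: int = 20
) -> CalibrationModel:
    """Estimate the systematic mass shift (median ppm error) and dispersion
    of a broad-tolerance assignment population.

    Outliers beyond 4 robust sigmas (1.4826*MAD) from the median are removed
    before taking the standard deviation; tolerance is 3 sigma.
    """
    if len(assignments) < min_assignments:
        raise ValueError(
            f"only {len(assignments)} assignments; need >= {min_assignments}. "
            "Re-run the first pass with a wider tolerance."
        )
    errors = np.array([a.ppm_error for a in assignments])
    shift = float(np.median(errors))
    mad = float(np.median(np.abs(errors - shift)))
    robust_sigma = 1.4826 * mad
    if robust_sigma > 0:
        kept = errors[np.abs(errors - shift) <= 4.0 * robust_sigma]
    else:
        kept = errors
    sigma = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
    if sigma <= 0:
        sigma = max(robust_sigma, 1e-3)
    return CalibrationModel(shift_ppm=shift, sigma_ppm=sigma)


@dataclass(frozen=True)
class IonTypeSelection:
    """Outcome of the frequent-flyer ion-type test."""

    counts: dict[str, int]
    decoy_mean_counts: dict[str, float]
    p_values: dict[str, float]
    selected: tuple[str, ...]
    fallback: bool = False


def _significance_a_right(value: float, population: np.ndarray) -> float:
    """Right-tail outlier probability from a percentile-based robust z:
    z = (value - median) / (P84.13 - median)."""
    med = float(np.median(population))
    p8413 = float(np.percentile(population, 84.13))
    sigma = p8413 - med
    if sigma <= 0:
        return 0.0 if value > med else 1.0
    z = (value - med) / sigma
    if z <= 0:
        return 1.0
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def select_ion_types(
    spectra: SpectrumSet,
    sequence: str,
    candidates: Sequence[str] = ALL_ION_TYPES,
    losses: Sequence[str] = ("none",),
    broad_tolerance_ppm: float = 10.0,
    alpha: float = 0.01,
    max_mods: int = 0,
    mod: Modification | None = None,
    n_decoys: int = 20,
    seed: int = 0,
) -> IonTypeSelection:
    """Select the ion types significantly present in the spectra.

    Per candidate type, matched-fragment counts against the target sequence
    are compared with counts from scrambled decoy sequences; a type is kept
    when its count is a significant right-tail outlier of the combined
    count distribution (threshold ``alpha``). An empty selection falls back
    to all candidates with a warning.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")

    def _counts(seq: str) -> dict[str, int]:
        table = generate_fragments(seq, candidates, losses, max_mods, mod)
        counts = {t: 0 for t in candidates}
        for spectrum in spectra:
            for a in match_fragments(spectrum, table, broad_tolerance_ppm):
                counts[a.fragment.ion_type] += 1
        return counts

    target_counts = _counts(sequence)
    decoy_counts: dict[str, list[int]] = {t: [] for t in candidates}
    for d in range(n_decoys):
        dc = _counts(scramble_sequence(sequence, seed + d))
        for t in candidates:
            decoy_counts[t].append(dc[t])

    population = np.array(
        [c for counts in decoy_counts.values() for c in counts]
        + list(target_counts.values()),
        dtype=float,
    )
    p_values = {
        t: _significance_a_right(target_counts[t], population) for t in candidates
    }
    selected = tuple(t for t in candidates if p_values[t] < alpha)
    fallback = False
    if not selected:
        warnings.warn(
            "no ion type was significantly present; falling back to all candidates",
            stacklevel=2,
        )
        selected, fallback = tuple(candidates), True
    return IonTypeSelection(
        counts=target_counts,
        decoy_mean_counts={t: float(np.mean(decoy_counts[t])) for t in candidates},
        p_values=p_values,
        selected=selected,
        fallback=fallback,
    )


def _covered_cleavages(items: Iterable, sequence_length: int) -> set[int]:
    covered: set[int] = set()
    for item in items:
        frag = item.fragment if hasattr(item, "fragment") else item
        terminus = ION_TYPES[frag.ion_type].terminus
        cleavage = (
            frag.cleavage_index
            if terminus == "N"
            else sequence_length - frag.cleavage_index
        )
        if 1 <= cleavage <= sequence_length - 1:
            covered.add(cleavage)
    return covered


def sequence_coverage(assignments: Iterable, sequence_length: int) -> float:
    """Fraction of the L-1 backbone cleavages supported by >= 1 assignment.

    An N-terminal fragment with cleavage index i covers cleavage i; a
    C-terminal fragment with index j covers cleavage L-j.
    """
    if sequence_length < 2:
        raise ValueError("sequence_length must be >= 2")
    return len(_covered_cleavages(assignments, sequence_length)) / (sequence_length - 1)


def majority_vote(
    replicate_assignments: Mapping[str, Sequence[Assignment]],
    k_required: int,
) -> list[VotedFragment]:
    """Accept a fragment iff it was assigned in at least ``k_required``
    replicates; accepted intensity (and ppm) is the median across the
    replicates where the fragment is present."""
    n = len(replicate_assignments)
    if not 1 <= k_required <= n:
        raise ValueError(f"k_required must be in 1..{n}")
    by_key: dict[tuple, list[Assignment]] = {}
    for rep_assignments in replicate_assignments.values():
        seen_in_rep: set[tuple] = set()
        for a in rep_assignments:
            if a.key in seen_in_rep:
                continue  # one vote per replicate
            seen_in_rep.add(a.key)
            by_key.setdefault(a.key, []).append(a)
    voted = [
        VotedFragment(
            fragment=group[0].fragment,
            intensity=median(a.intensity for a in group),
            n_replicates_present=len(group),
            ppm_error=median(a.ppm_error for a in group),
        )
        for group in by_key.values()
        if len(group) >= k_required
    ]
    voted.sort(key=lambda v: v.fragment.key)
    return voted


@dataclass(frozen=True)
class SearchParams:
    """Everything needed to repeat a search against a different sequence."""

    ion_types: tuple[str, ...]
    losses: tuple[str, ...] = ("none",)
    tolerance_ppm: float = 10.0
    max_mods: int = 0
    mod: Modification | None = None
    vote_k: int = 2


def search_and_vote(
    spectra: SpectrumSet, sequence: str, params: SearchParams
) -> list[VotedFragment]:
    """The core search: match every replicate, then majority-vote."""
    table = generate_fragments(
        sequence, params.ion_types, params.losses, params.max_mods, params.mod
    )
    per_replicate = {
        s.replicate_id or f"rep{i}": match_fragments(s, table, params.tolerance_ppm)
        for i, s in enumerate(spectra)
    }
    k = min(params.vote_k, len(spectra))
    return majority_vote(per_replicate, k)


@dataclass(frozen=True)
class FDRReport:
    """Fragment-level FDR: the median fraction of cleavages that scrambled
    decoy sequences can explain, next to the target's own coverage."""

    target_coverage: float
    decoy_coverages: tuple[float, ...]
    fdr: float
    n_scrambles: int


def estimate_fdr(
    spectra: SpectrumSet,
    sequence: str,
    params: SearchParams,
    n_scrambles: int = 200,
    seed: int = 0,
) -> FDRReport:
    """Run the identical search pipeline (same ion types, tolerance and
    voting, same calibrated spectra) against ``n_scrambles`` scrambled
    sequences; the FDR is the median decoy coverage."""
    if n_scrambles < 2:
        raise ValueError("n_scrambles must be >= 2")
    L = len(sequence)
    target = search_and_vote(spectra, sequence, params)
    target_cov = sequence_coverage(target, L)
    decoy_covs = []
    for d in range(n_scrambles):
        decoy_seq = scramble_sequence(sequence, seed + d)
        decoy = search_and_vote(spectra, decoy_seq, params)
        decoy_covs.append(sequence_coverage(decoy, L))
    fdr = float(np.median(decoy_covs))
    logger.info(
        "FDR estimate: target coverage %.3f, median decoy coverage %.4f (%d scrambles)",
        target_cov,
        fdr,
        n_scrambles,
    )
    return FDRReport(
        target_coverage=target_cov,
        decoy_coverages=tuple(decoy_covs),
        fdr=fdr,
        n_scrambles=n_scrambles,
    )
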