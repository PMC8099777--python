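"""End-to-end pipeline: match(broad) -> calibrate -> select ion types ->
match(tight) -> vote -> FDR -> ladders -> localize -> quantify, with file
outputs and provenance."""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .assignment import (
    SearchParams,
    calibrate,
    estimate_fdr,
    match_fragments,
    search_and_vote,
    select_ion_types,
    sequence_coverage,
)
from .chem import (
    BUILTIN_MODIFICATIONS,
    ConstraintSet,
    Modification,
    enumerate_isomers,
    infer_mod_count,
)
from .fragments import ALL_ION_TYPES, generate_fragments, ION_TYPES
from .ladder import build_ladder, localize
from .peaklists import (
    compute_spectrum_stats,
    read_fasta,
    read_peaklist,
    write_ladder_tsv,
    write_report,
)
from .quant import build_system, prune_candidates, solve_abundances

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "DataError",
    "ConvergenceError",
    "run_full",
    "resolve_modification",
]

#: Candidate guard for the quantification enumeration.
MAX_QUANT_CANDIDATES = 10**5


class ConfigError(Exception):
    """Invalid configuration (missing files, bad parameters). Exit code 2."""


class DataError(Exception):
    """Input data cannot support the requested analysis. Exit code 3."""


class ConvergenceError(Exception):
    """A numerical stage failed to produce a usable result. Exit code 4."""


def resolve_modification(spec) -> Modification:
    """Accept a built-in name, a mapping with name/delta_mass/acceptor_residues,
    or a ready Modification."""
    if isinstance(spec, Modification):
        return spec
    if isinstance(spec, str):
        if spec not in BUILTIN_MODIFICATIONS:
            raise ConfigError(
                f"unknown modification {spec!r}; built-ins: "
                f"{sorted(BUILTIN_MODIFICATIONS)}"
            )
        return BUILTIN_MODIFICATIONS[spec]
    if isinstance(spec, dict):
        try:
            return Modification(
                spec["name"],
                float(spec["delta_mass"]),
                frozenset(spec["acceptor_residues"]),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"bad modification definition: {exc}") from None
    raise ConfigError(f"cannot interpret modification {spec!r}")


@dataclass
class RunConfig:
    fasta: str
    peaklists: Sequence[str]
    modification: object = "phospho"
    precursor_mass: float | None = None
    n_mods: int | None = None
    first_pass_tolerance_ppm: float = 10.0
    tolerance_ppm: float | None = None  # explicit override of the tight pass
    ion_types: Sequence[str] | None = None  # None = auto (frequent flyer)
    losses: Sequence[str] = ("none",)
    vote_k: int = 2
    n_scrambles: int = 200
    seed: int = 0
    no_calibration: bool = False
    mass_offset: float = 0.0
    score_variant: str = "plain"
    fixed_sites: Sequence[int] = ()
    mutually_exclusive: Sequence[tuple[int, int]] = ()
    out_dir: str = "qpi_out"
    stage: str = "full"  # assign | localize | quantify | full


def run_full(config: RunConfig) -> dict:
    """Execute the pipeline up to ``config.stage``; write reports into
    ``config.out_dir`` and return the in-memory result bundle."""
    t0 = time.time()

    # --- inputs -----------------------------------------------------------
    fasta = Path(config.fasta)
    if not fasta.exists():
        raise ConfigError(f"FASTA file not found: {fasta}")
    for p in config.peaklists:
        if not Path(p).exists():
            raise ConfigError(f"peak list not found: {p}")
    if not config.peaklists:
        raise ConfigError("at least one peak list is required")
    mod = resolve_modification(config.modification)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sequence = read_fasta(fasta)[0][1]
    L = len(sequence)
    spectra = [read_peaklist(p, mass_offset=config.mass_offset) for p in config.peaklists]
    logger.info("loaded %d replicates, %s peaks", len(spectra),
                [len(s) for s in spectra])

    if config.precursor_mass is not None:
        try:
            n_mods = infer_mod_count(config.precursor_mass, sequence, mod)
        except ValueError as exc:
            raise DataError(str(exc)) from None
    elif config.n_mods is not None:
        n_mods = config.n_mods
    else:
        n_mods = 0

    # --- broad pass + calibration ----------------------------------------
    broad_table = generate_fragments(sequence, ALL_ION_TYPES, config.losses, n_mods, mod)
    broad = [
        a
        for s in spectra
        for a in match_fragments(s, broad_table, config.first_pass_tolerance_ppm)
    ]
    logger.info("broad pass: %d assignments at %.1f ppm", len(broad),
                config.first_pass_tolerance_ppm)
    calibration = None
    if not config.no_calibration:
        try:
            calibration = calibrate(broad)
        except ValueError as exc:
            raise DataError(f"calibration failed: {exc}") from None
        spectra = calibration.apply_all(spectra)
        logger.info("calibration: shift %.3f ppm, sigma %.3f ppm",
                    calibration.shift_ppm, calibration.sigma_ppm)

    # --- ion-type policy ---------------------------------------------------
    if config.ion_types is not None:
        selected_types = tuple(config.ion_types)
        selection = None
    else:
        selection = select_ion_types(
            spectra,
            sequence,
            candidates=ALL_ION_TYPES,
            losses=config.losses,
            broad_tolerance_ppm=config.first_pass_tolerance_ppm,
            max_mods=n_mods,
            mod=mod,
            seed=config.seed,
        )
        selected_types = selection.selected
        logger.info("ion types selected: %s", selected_types)

    if config.tolerance_ppm is not None:
        tight = config.tolerance_ppm
    elif calibration is not None:
        tight = min(calibration.tolerance_ppm, config.first_pass_tolerance_ppm)
    else:
        tight = config.first_pass_tolerance_ppm

    params = SearchParams(
        ion_types=selected_types,
        losses=tuple(config.losses),
        tolerance_ppm=tight,
        max_mods=n_mods,
        mod=mod,
        vote_k=config.vote_k,
    )

    # --- tight search + voting + FDR --------------------------------------
    voted = search_and_vote(spectra, sequence, params)
    coverage = sequence_coverage(voted, L)
    logger.info("accepted %d fragments after %d/%d voting; coverage %.1f%%",
                len(voted), config.vote_k, len(spectra), 100 * coverage)
    fdr = estimate_fdr(spectra, sequence, params,
                       n_scrambles=config.n_scrambles, seed=config.seed)

    results: dict = {
        "sequence_length": L,
        "n_mods": n_mods,
        "calibration": calibration,
        "ion_type_selection": selection,
        "params": params,
        "voted_fragments": voted,
        "coverage": coverage,
        "fdr": fdr,
    }
    _write_assign_outputs(out_dir, config, results)
    if config.stage == "assign":
        return results

    # --- ladders + localization -------------------------------------------
    n_kinds = [
        (t, l) for t in selected_types for l in config.losses
        if ION_TYPES[t].terminus == "N"
    ]
    c_kinds = [
        (t, l) for t in selected_types for l in config.losses
        if ION_TYPES[t].terminus == "C"
    ]
    ladders = {
        "N": build_ladder(voted, "N", L, n_mods, n_kinds),
        "C": build_ladder(voted, "C", L, n_mods, c_kinds),
    }
    q = float(np.mean([compute_spectrum_stats(s).chance_probability for s in spectra]))
    results["ladders"] = ladders
    results["q"] = q
    for terminus, ladder in ladders.items():
        write_ladder_tsv(ladder.matrix(), L, n_mods, out_dir / f"ladder_{terminus}.tsv")

    constraints = ConstraintSet(
        frozenset(config.fixed_sites),
        frozenset(frozenset(p) for p in config.mutually_exclusive),
    )
    if n_mods >= 1:
        ranked = localize(ladders, sequence, n_mods, mod, q,
                          constraints=constraints, score_variant=config.score_variant)
        results["localization"] = ranked
        write_report(
            [
                {
                    "rank": i + 1,
                    "sites": "+".join(map(str, r.sites)),
                    "log10_corrected": r.log10_corrected,
                    "log10_plain": r.log10_plain,
                }
                for i, r in enumerate(ranked)
            ],
            out_dir / "localization.tsv",
            format="tsv",
        )
    if config.stage == "localize":
        return results

    # --- quantification ----------------------------------------------------
    if n_mods >= 1:
        pool = mod.acceptor_positions(sequence)
        if math.comb(len(pool), n_mods) > MAX_QUANT_CANDIDATES:
            raise DataError(
                "candidate explosion in quantification; supply constraints"
            )
        candidates = enumerate_isomers(pool, n_mods, constraints)
        candidates = prune_candidates(candidates, ladders)
        if not candidates:
            raise DataError("no candidate isomer is consistent with the ladders")
        try:
            system = build_system(candidates, ladders, prune=False)
            quant = solve_abundances(system)
        except ValueError as exc:
            raise ConvergenceError(str(exc)) from None
        results["system"] = system
        results["quant"] = quant
        write_report(
            {
                "groups": [
                    {
                        "label": g.label,
                        "members": ["+".join(map(str, m)) for m in g.members],
                        "abundance": a,
                        "sem": s,
                    }
                    for g, a, s in zip(quant.groups, quant.abundances, quant.sems)
                ],
                "residual_norm": quant.residual_norm,
                "grouped": quant.grouped,
                "caution": quant.caution,
            },
            out_dir / "quant.json",
        )

    _write_provenance(out_dir, config, results, time.time() - t0)
    return results


def _write_assign_outputs(out_dir: Path, config: RunConfig, results: dict) -> None:
    voted = results["voted_fragments"]
    write_report(
        [
            {
                "terminus": v.fragment.terminus,
                "cleavage_index": v.fragment.cleavage_index,
                "ion_type": v.fragment.ion_type,
                "loss": v.fragment.loss,
                "mod_count": v.fragment.mod_count,
                "neutral_mass": v.fragment.neutral_mass,
                "intensity": v.intensity,
                "n_replicates": v.n_replicates_present,
                "ppm_error": v.ppm_error,
            }
            for v in voted
        ],
        out_dir / "assignments.tsv",
        format="tsv",
    )
    fdr = results["fdr"]
    write_report(
        {
            "target_coverage": fdr.target_coverage,
            "fdr": fdr.fdr,
            "n_scrambles": fdr.n_scrambles,
            "decoy_coverages": list(fdr.decoy_coverages),
        },
        out_dir / "fdr.json",
    )


def _write_provenance(out_dir: Path, config: RunConfig, results: dict,
                      elapsed: float) -> None:
    cal = results.get("calibration")
    provenance = {
        "qpi_version": __version__,
        "seed": config.seed,
        "parameters": {
            "first_pass_tolerance_ppm": config.first_pass_tolerance_ppm,
            "tolerance_ppm": results["params"].tolerance_ppm,
            "ion_types": list(results["params"].ion_types),
            "losses": list(results["params"].losses),
            "vote_k": config.vote_k,
            "n_scrambles": config.n_scrambles,
            "score_variant": config.score_variant,
            "mass_offset": config.mass_offset,
        },
        "calibration": None
        if cal is None
        else {"shift_ppm": cal.shift_ppm, "sigma_ppm": cal.sigma_ppm},
        "n_mods": results["n_mods"],
        "coverage": results["coverage"],
        "fdr": results["fdr"].fdr,
    }
    timing = {"elapsed_seconds": elapsed}
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump({"provenance": provenance, "timing": timing}, fh, indent=2)
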