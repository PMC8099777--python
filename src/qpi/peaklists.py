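"""Reading protein sequences and deconvoluted peak lists, spectrum summary
statistics, and delimited/JSON report writing.

Peak lists are delimited text (comma or tab, auto-detected) with at least a
mass and an intensity column, emulating exported deisotoping results.
Masses are NEUTRAL monoisotopic by default; a ``mass_offset`` (e.g.
``-1.007276`` for MH+ lists) converts other dialects on read.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Peak",
    "DeconvolutedSpectrum",
    "SpectrumSet",
    "SpectrumStats",
    "read_fasta",
    "read_peaklist",
    "write_peaklist",
    "compute_spectrum_stats",
    "write_report",
    "write_ladder_tsv",
    "read_ladder_tsv",
]

#: Peaks closer than this (Da) are merged on read.
MERGE_TOLERANCE_DA = 1e-4


@dataclass(frozen=True)
class Peak:
    neutral_mass: float
    intensity: float


class DeconvolutedSpectrum:
    """A neutral monoisotopic peak list with intensities.

    Peaks are stored sorted by mass; near-duplicates (< 1e-4 Da apart) are
    merged with intensity-weighted mean mass and summed intensity.
    """

    def __init__(
        self,
        masses: Sequence[float],
        intensities: Sequence[float],
        replicate_id: str = "",
        precursor_mass: float | None = None,
        metadata: dict | None = None,
    ):
        masses = np.asarray(masses, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        if masses.shape != intensities.shape:
            raise ValueError("masses and intensities must have equal length")
        if np.any(masses <= 0):
            raise ValueError("neutral masses must be positive")
        if np.any(intensities <= 0):
            raise ValueError("intensities must be positive")
        order = np.argsort(masses, kind="stable")
        masses, intensities = masses[order], intensities[order]
        self.masses, self.intensities = _merge_close(masses, intensities)
        self.replicate_id = replicate_id
        self.precursor_mass = precursor_mass
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.masses, self.intensities)]

    def with_masses(self, masses: np.ndarray) -> "DeconvolutedSpectrum":
        """Copy with replaced masses (used by calibration)."""
        return DeconvolutedSpectrum(
            masses,
            self.intensities,
            replicate_id=self.replicate_id,
            precursor_mass=self.precursor_mass,
            metadata=self.metadata,
        )


#: Replicate-grouped spectra of one precursor.
SpectrumSet = list[DeconvolutedSpectrum]


def _merge_close(masses: np.ndarray, intensities: np.ndarray):
    if len(masses) == 0:
        return masses, intensities
    out_m: list[float] = []
    out_i: list[float] = []
    cur_m, cur_i = masses[0], intensities[0]
    for m, i in zip(masses[1:], intensities[1:]):
        if m - cur_m < MERGE_TOLERANCE_DA:
            new_i = cur_i + i
            cur_m = (cur_m * cur_i + m * i) / new_i
            cur_i = new_i
        else:
            out_m.append(cur_m)
            out_i.append(cur_i)
            cur_m, cur_i = m, i
    out_m.append(cur_m)
    out_i.append(cur_i)
    return np.array(out_m), np.array(out_i)


@dataclass(frozen=True)
class SpectrumStats:
    """Peak-density summary: X is the average number of peaks per 100 Da of
    observed mass range and q = X/100 is the chance-match probability."""

    peak_count: int
    mass_range: float
    peaks_per_100da: float
    chance_probability: float


def compute_spectrum_stats(spectrum: DeconvolutedSpectrum) -> SpectrumStats:
    if len(spectrum) < 2:
        raise ValueError("need at least 2 peaks to compute spectrum statistics")
    mass_range = float(spectrum.masses[-1] - spectrum.masses[0])
    effective_range = max(mass_range, 100.0)  # degenerate ranges floored to 100 Da
    x = len(spectrum) / (effective_range / 100.0)
    q = min(max(x / 100.0, 1e-6), 0.99)
    return SpectrumStats(len(spectrum), mass_range, x, q)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, residue string); whitespace and digits are
    stripped and the sequence uppercased."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = re.sub(r"[\s\d]", "", str(rec.seq)).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        bad = sorted(set(seq) - set("ACDEFGHIKLMNPQRSTVWY"))
        if bad:
            raise ValueError(f"record {rec.id!r} contains illegal characters {bad}")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_peaklist(
    path: str | Path,
    mass_offset: float = 0.0,
    replicate_id: str | None = None,
) -> DeconvolutedSpectrum:
    """Read a delimited peak list with at least mass and intensity columns.

    The header row is auto-detected (non-numeric first row); without a
    header the first two columns are taken as mass and intensity.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty peak list")
    delim = _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))

    header = rows[0]
    has_header = not all(_is_number(tok) for tok in header if tok.strip())
    if has_header:
        lowered = [h.strip().lower() for h in header]
        mass_col = next(
            (i for i, h in enumerate(lowered) if "mass" in h or "m/z" in h), None
        )
        int_col = next(
            (i for i, h in enumerate(lowered) if "intens" in h or "abundance" in h),
            None,
        )
        if mass_col is None or int_col is None:
            raise ValueError(
                f"{path}: could not find mass/intensity columns in header {header}"
            )
        data_rows = rows[1:]
        first_data_row = 2
    else:
        mass_col, int_col = 0, 1
        data_rows = rows
        first_data_row = 1

    masses: list[float] = []
    intensities: list[float] = []
    for offset, row in enumerate(data_rows):
        rownum = first_data_row + offset
        if len(row) <= max(mass_col, int_col):
            raise ValueError(f"{path}:{rownum}: expected at least 2 columns, got {len(row)}")
        try:
            m = float(row[mass_col]) + mass_offset
            inten = float(row[int_col])
        except ValueError as exc:
            raise ValueError(f"{path}:{rownum}: non-numeric value ({exc})") from None
        if m <= 0 or inten <= 0:
            raise ValueError(f"{path}:{rownum}: non-positive mass or intensity")
        masses.append(m)
        intensities.append(inten)
    return DeconvolutedSpectrum(
        masses, intensities, replicate_id=replicate_id or path.stem
    )


def write_peaklist(spectrum: DeconvolutedSpectrum, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("mass\tintensity\n")
        for m, i in zip(spectrum.masses, spectrum.intensities):
            fh.write(f"{m:.12g}\t{i:.12g}\n")


def write_report(results, path: str | Path, format: str = "json") -> None:
    """Write a result object (dict / dataclass tree) to JSON or TSV.

    TSV expects ``results`` to be a list of flat dicts with identical keys.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, default=_jsonify)
            fh.write("\n")
    elif format == "tsv":
        rows = list(results)
        if not rows:
            path.write_text("")
            return
        keys = list(rows[0].keys())
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys, delimiter="\t")
            writer.writeheader()
            for row in rows:
                writer.writerow({k: _format_cell(row[k]) for k in keys})
    else:
        raise ValueError(f"unknown report format {format!r}")


def _jsonify(obj):
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def _format_cell(value):
    if isinstance(value, float):
        return f"{value:.12g}"
    return value


def write_ladder_tsv(matrix: dict[tuple[int, int], float], L: int, n_max: int,
                     path: str | Path) -> None:
    """Write a ladder intensity matrix: rows = cleavage positions 1..L-1,
    columns = modification counts 0..n_max; empty cells are blank."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("cleavage\t" + "\t".join(f"m{m}" for m in range(n_max + 1)) + "\n")
        for c in range(1, L):
            cells = [
                f"{matrix[(c, m)]:.12g}" if (c, m) in matrix else ""
                for m in range(n_max + 1)
            ]
            fh.write(f"{c}\t" + "\t".join(cells) + "\n")


def read_ladder_tsv(path: str | Path) -> dict[tuple[int, int], float]:
    matrix: dict[tuple[int, int], float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        mods = [int(h[1:]) for h in header[1:]]
        for row in reader:
            c = int(row[0])
            for m, cell in zip(mods, row[1:]):
                if cell:
                    matrix[(c, m)] = float(cell)
    return matrix
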