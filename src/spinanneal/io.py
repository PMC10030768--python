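"""Readers and writers for peak lists, sequences, shift predictions and results.

Peak lists use a whitespace-delimited Sparky-style dialect: an optional
assignment-label first column (ignored), one numeric column per spectral
dimension, and an optional trailing intensity ("Data Height") column.  Lines
that are blank, start with ``#`` or look like a Sparky header row are skipped.

Residue numbering is 1-based throughout the package; the (i-1) resonances of a
spin system rooted at residue n refer to residue n-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .spectra import RESONANCES, SpectrumDefinition

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Global per-resonance prediction errors (ppm) for structure-based
#: prediction tables (typical predictor RMSDs): H, N, CA, CB, CO.
STRUCTURE_PREDICTION_ERRORS = {"H": 0.45, "N": 2.4, "CA": 0.8, "CB": 0.95, "CO": 0.9}

#: Global per-resonance prediction errors (ppm) for sequence-specific
#: random-coil prediction tables (intrinsically disordered proteins).
RANDOM_COIL_PREDICTION_ERRORS = {"H": 0.16, "N": 1.0, "CA": 0.42, "CB": 0.37, "CO": 0.43}

PREDICTION_ERROR_SETS = {
    "structure": STRUCTURE_PREDICTION_ERRORS,
    "random_coil": RANDOM_COIL_PREDICTION_ERRORS,
}


class PeakListFormatError(ValueError):
    pass


@dataclass
class CrossPeak:
    """One multidimensional crosspeak.

    ``candidates`` is the set of resonance-type tuples the peak could still
    represent; spin-system assembly narrows it, and a single surviving tuple
    means the peak's types are resolved.
    """

    id: str
    spectrum: SpectrumDefinition
    shifts: tuple[float, ...]
    intensity: float | None = None
    candidates: tuple[tuple[str, ...], ...] = ()
    cache_eligible: bool = False

    def __post_init__(self):
        if not self.candidates:
            self.candidates = self.spectrum.candidate_peak_types
        if len(self.shifts) != self.spectrum.ndim:
            raise PeakListFormatError(
                f"peak {self.id}: {len(self.shifts)} shifts for "
                f"{self.spectrum.ndim}-dimensional {self.spectrum.name}"
            )
        if not all(math.isfinite(s) for s in self.shifts):
            raise PeakListFormatError(f"peak {self.id}: non-finite shift")

    @property
    def resolved_types(self) -> tuple[str, ...] | None:
        """The unique resonance-type tuple, or None while still ambiguous."""
        return self.candidates[0] if len(self.candidates) == 1 else None

    @property
    def amide_shifts(self) -> tuple[float, float]:
        return self.shifts[self.spectrum.h_dim], self.shifts[self.spectrum.n_dim]


@dataclass(frozen=True)
class ShiftPrediction:
    """Predicted chemical shift for one resonance of one residue."""

    residue_index: int  # 1-based
    resonance: str  # H, N, CA, CB or CO
    delta_pred: float  # ppm
    sigma: float  # ppm, prediction error
    source: str = "residue_stats"  # structure | random_coil | residue_stats

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"prediction sigma must be > 0 (got {self.sigma})")
        if self.resonance not in RESONANCES:
            raise ValueError(f"unknown resonance {self.resonance!r}")


class ResidueTypeStats:
    """Mean/SD of each backbone resonance per amino-acid type (BMRB-like)."""

    def __init__(self, table: dict[tuple[str, str], tuple[float, float]]):
        self._table = dict(table)
        for (aa, res), (_, sd) in self._table.items():
            if sd <= 0:
                raise ValueError(f"SD must be positive for ({aa}, {res})")
        for aa in AMINO_ACIDS:
            for res in RESONANCES:
                if not self.has(aa, res) and not _chemically_absent(aa, res):
                    raise ValueError(f"statistics missing for ({aa}, {res})")

    def has(self, aa: str, resonance: str) -> bool:
        return (aa, resonance) in self._table

    def mean(self, aa: str, resonance: str) -> float:
        return self._table[(aa, resonance)][0]

    def sd(self, aa: str, resonance: str) -> float:
        return self._table[(aa, resonance)][1]

    @classmethod
    def from_tsv(cls, path) -> "ResidueTypeStats":
        df = pd.read_csv(path, sep="\t", comment="#")
        table = {
            (row.aa, row.resonance): (float(row["mean"]), float(row.sd))
            for _, row in df.iterrows()
        }
        return cls(table)

    @classmethod
    def packaged(cls) -> "ResidueTypeStats":
        """The residue-type statistics table shipped with the package."""
        ref = resources.files("spinanneal.data") / "residue_type_stats.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def _chemically_absent(aa: str, resonance: str) -> bool:
    """True where a backbone resonance does not exist for an amino acid."""
    if aa == "G" and resonance == "CB":
        return True
    if aa == "P" and resonance in ("H", "N"):
        return True
    return False


# ---------------------------------------------------------------------------
# peak lists


def _is_header(tokens: list[str]) -> bool:
    return tokens[0].lower() in ("assignment", "label")


def _parse_float(tok: str, lineno: int, path) -> float:
    try:
        return float(tok)
    except ValueError:
        raise PeakListFormatError(
            f"{path}, line {lineno}: malformed numeric field {tok!r}"
        ) from None


def read_peak_list(path, spectrum: SpectrumDefinition) -> list[CrossPeak]:
    """Parse a Sparky-style peak list into crosspeaks of ``spectrum``.

    Each data row must have ``spectrum.ndim`` shift columns plus an optional
    trailing intensity column; an optional leading non-numeric assignment
    label is ignored.
    """
    path = Path(path)
    peaks: list[CrossPeak] = []
    ndim = spectrum.ndim
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#") or _is_header(tokens):
                continue
            label = None
            try:
                float(tokens[0])
            except ValueError:
                label = tokens[0]
                tokens = tokens[1:]
            if len(tokens) not in (ndim, ndim + 1):
                raise PeakListFormatError(
                    f"{path}, line {lineno}: expected {ndim} shift columns "
                    f"(+ optional intensity) for {spectrum.name}, got {len(tokens)}"
                )
            values = [_parse_float(t, lineno, path) for t in tokens]
            shifts = tuple(values[:ndim])
            intensity = values[ndim] if len(values) > ndim else None
            pid = label or f"{spectrum.name}:{len(peaks) + 1}"
            peaks.append(CrossPeak(pid, spectrum, shifts, intensity))
    if not peaks:
        logger.warning("peak list %s (%s) contained no peaks", path, spectrum.name)
    return peaks


def write_peak_list(peaks: list[CrossPeak], path) -> None:
    """Write crosspeaks back out in the Sparky-style dialect (6 decimals)."""
    with open(path, "w") as fh:
        for p in peaks:
            cols = [f"{s:.6f}" for s in p.shifts]
            if p.intensity is not None:
                cols.append(f"{p.intensity:.6g}")
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------------------
# sequences


def read_sequence(path) -> str:
    """Read a single-record FASTA into an upper-case one-letter sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    bad = sorted(set(seq) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(f"{path}: illegal sequence characters {bad}")
    return seq


def write_sequence(sequence: str, path, name: str = "protein") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# shift predictions


def predictions_from_stats(sequence: str, stats: ResidueTypeStats) -> list[ShiftPrediction]:
    """Per-residue predictions from residue-type statistics (mean, SD)."""
    preds = []
    for n, aa in enumerate(sequence, start=1):
        for res in RESONANCES:
            if _chemically_absent(aa, res) or not stats.has(aa, res):
                continue
            preds.append(
                ShiftPrediction(n, res, stats.mean(aa, res), stats.sd(aa, res), "residue_stats")
            )
    return preds


def read_shift_predictions(
    path,
    sequence: str,
    stats: ResidueTypeStats,
    mode: str = "table",
    errors: dict[str, float] | str | None = None,
) -> list[ShiftPrediction]:
    """Load per-residue predicted shifts with per-resonance errors.

    In ``table`` mode a TSV with columns (residue_index, aa, resonance,
    delta_pred[, sigma]) is parsed; rows without a sigma receive the global
    per-resonance error (``errors`` may be a dict, ``"structure"`` or
    ``"random_coil"``; default structure-based errors).  Residues absent from
    the table fall back to the residue-type statistics.  In ``residue_stats``
    mode the table is ignored entirely.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if mode == "residue_stats":
        return predictions_from_stats(sequence, stats)
    if mode != "table":
        raise ValueError(f"unknown prediction mode {mode!r}")

    if errors is None:
        errors = STRUCTURE_PREDICTION_ERRORS
        source = "structure"
    elif isinstance(errors, str):
        source = errors
        errors = PREDICTION_ERROR_SETS[errors]
    else:
        source = "structure"

    df = pd.read_csv(path, sep="\t", comment="#")
    preds: list[ShiftPrediction] = []
    seen_residues: set[int] = set()
    for _, row in df.iterrows():
        n = int(row.residue_index)
        if not 1 <= n <= len(sequence):
            raise IndexError(f"residue index {n} outside sequence of length {len(sequence)}")
        aa = sequence[n - 1]
        if "aa" in df.columns and str(row.aa).upper() != aa:
            raise ValueError(f"residue {n}: table says {row.aa}, sequence says {aa}")
        res = str(row.resonance)
        if res not in RESONANCES:
            raise ValueError(f"residue {n}: unknown resonance {res!r}")
        if _chemically_absent(aa, res):
            logger.warning("dropping prediction for chemically absent (%s%d, %s)", aa, n, res)
            continue
        sigma = float(row.sigma) if "sigma" in df.columns and pd.notna(row.get("sigma")) else errors[res]
        preds.append(ShiftPrediction(n, res, float(row.delta_pred), sigma, source))
        seen_residues.add(n)

    # residues with no table entry fall back to residue-type statistics
    for n, aa in enumerate(sequence, start=1):
        if n in seen_residues:
            continue
        for res in RESONANCES:
            if _chemically_absent(aa, res) or not stats.has(aa, res):
                continue
            preds.append(
                ShiftPrediction(n, res, stats.mean(aa, res), stats.sd(aa, res), "residue_stats")
            )

    dup = {}
    for p in preds:
        key = (p.residue_index, p.resonance)
        if key in dup:
            raise ValueError(f"duplicate prediction for residue {key[0]} {key[1]}")
        dup[key] = p
    return preds


def write_shift_predictions(preds: list[ShiftPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("residue_index\tresonance\tdelta_pred\tsigma\n")
        for p in preds:
            fh.write(f"{p.residue_index}\t{p.resonance}\t{p.delta_pred:.4f}\t{p.sigma:.4f}\n")


# ---------------------------------------------------------------------------
# assignment output


def write_assignment_table(result, path) -> None:
    """Write a curated consensus assignment as a tab-separated table."""
    cols = (
        "residue\taa\tstatus\tspin_system\tvote_fraction\tposterior\tconnectivities\t"
        + "\t".join(RESONANCES)
    )
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        for rec in result.records:
            shifts = [
                f"{rec.mean_shifts[r]:.4f}" if rec.mean_shifts and r in rec.mean_shifts else "."
                for r in RESONANCES
            ]
            fh.write(
                f"{rec.residue}\t{rec.aa}\t{rec.status}\t"
                f"{rec.spin_system if rec.spin_system is not None else '.'}\t"
                f"{rec.vote_fraction:.3f}\t"
                f"{rec.posterior:.6g}\t{rec.connectivities}\t" + "\t".join(shifts) + "\n"
            )


def read_assignment_table(path) -> dict[int, dict]:
    """Read back an assignment table as residue -> record dict."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        shifts = {
            r: float(row[r]) for r in RESONANCES if str(row[r]) != "."
        }
        out[int(row.residue)] = {
            "aa": row.aa,
            "status": row.status,
            "spin_system": None if str(row.spin_system) == "." else str(row.spin_system),
            "vote_fraction": float(row.vote_fraction),
            "posterior": float(row.posterior),
            "connectivities": int(row.connectivities),
            "mean_shifts": shifts,
        }
    return out


def write_nmrstar_shifts(result, sequence: str, path, entry_id: str = "assignment") -> None:
    """Minimal NMR-STAR 3.1 chemical-shift loop for assigned residues."""
    atom_name = {"H": "H", "N": "N", "CA": "CA", "CB": "CB", "CO": "C"}
    atom_type = {"H": "H", "N": "N", "CA": "C", "CB": "C", "CO": "C"}
    rows = []
    idx = 1
    for rec in result.records:
        if rec.status != "assigned" or not rec.mean_shifts:
            continue
        own = {r: v for r, v in rec.mean_shifts.items() if r in atom_name}
        for res, shift in sorted(own.items()):
            rows.append(
                f"{idx} {rec.residue} {rec.aa} {atom_name[res]} {atom_type[res]} {shift:.3f}"
            )
            idx += 1
    with open(path, "w") as fh:
        fh.write(f"data_{entry_id}\n\nsave_assigned_chemical_shifts\n")
        fh.write("loop_\n")
        for tag in (
            "_Atom_chem_shift.ID",
            "_Atom_chem_shift.Seq_ID",
            "_Atom_chem_shift.Comp_ID",
            "_Atom_chem_shift.Atom_ID",
            "_Atom_chem_shift.Atom_type",
            "_Atom_chem_shift.Val",
        ):
            fh.write(f"  {tag}\n")
        for row in rows:
            fh.write(f"  {row}\n")
        fh.write("stop_\nsave_\n")
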