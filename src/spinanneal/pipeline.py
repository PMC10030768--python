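"""End-to-end orchestration: assemble → ensemble anneal → consensus → curate.

`assign` is the in-memory entry point; `run_pipeline` drives a full run from
a YAML configuration, writing the assignment table, an optional score report
and a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .annealing import AnnealingParams, AssignmentProblem, run_annealing
from .consensus import (
    AssignmentScore,
    ConsensusResult,
    build_consensus,
    curate,
    run_ensemble,
    score_against_reference,
)
from .energy import EnergyParams
from .io import (
    ResidueTypeStats,
    read_assignment_table,
    read_peak_list,
    read_sequence,
    read_shift_predictions,
    write_assignment_table,
)
from .spectra import DEFAULT_TOLERANCES, get_spectrum

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one assignment run."""

    sequence_path: str
    peak_lists: dict[str, str]  # spectrum name -> path
    output_dir: str = "."
    prediction_mode: str = "residue_stats"  # or "table"
    prediction_path: str | None = None
    prediction_errors: str | dict | None = None  # "structure" | "random_coil" | dict
    reference_path: str | None = None
    n_runs: int = 20
    seed: int = 0
    tolerances: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TOLERANCES)
    )
    energy: dict = dataclasses.field(default_factory=dict)
    annealing: dict = dataclasses.field(default_factory=dict)
    cache_low_intensity: bool = False

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        for path in [self.sequence_path, *self.peak_lists.values()]:
            if not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def rel(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        raw["sequence_path"] = rel(raw["sequence_path"])
        raw["peak_lists"] = {k: rel(v) for k, v in raw["peak_lists"].items()}
        if raw.get("prediction_path"):
            raw["prediction_path"] = rel(raw["prediction_path"])
        if raw.get("reference_path"):
            raw["reference_path"] = rel(raw["reference_path"])
        return cls(**raw)

    def energy_params(self) -> EnergyParams:
        return EnergyParams(**self.energy)

    def annealing_params(self) -> AnnealingParams:
        return AnnealingParams(**self.annealing)


def assign(
    peaks,
    sequence: str,
    predictions,
    n_runs: int = 20,
    base_seed: int = 0,
    energy_params: EnergyParams | None = None,
    anneal_params: AnnealingParams | None = None,
    tolerances: dict[str, float] | None = None,
    cache_low_intensity: bool = False,
) -> ConsensusResult:
    """Assemble, anneal an ensemble, and return the curated consensus."""
    problem = AssignmentProblem.from_peaks(
        peaks,
        sequence,
        predictions,
        energy_params or EnergyParams(),
        tolerances,
        cache_low_intensity,
    )
    runs = run_ensemble(problem, n_runs, anneal_params or AnnealingParams(), base_seed)
    return curate(build_consensus(runs))


def reference_from_table(path) -> dict[int, tuple[float, float] | None]:
    """Amide (H, N) reference map from a written assignment table."""
    table = read_assignment_table(path)
    ref: dict[int, tuple[float, float] | None] = {}
    for n, rec in table.items():
        shifts = rec["mean_shifts"]
        if rec["status"] == "assigned" and "H" in shifts and "N" in shifts:
            ref[n] = (shifts["H"], shifts["N"])
        else:
            ref[n] = None
    return ref


def run_pipeline(config: RunConfig) -> ConsensusResult:
    """Execute the full pipeline described by ``config``.

    Writes ``assignment.tsv``, a ``manifest.json`` with config, seeds and
    version, and ``score.json`` when a reference table is supplied.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sequence = read_sequence(config.sequence_path)
    peaks = []
    for name, path in config.peak_lists.items():
        spectrum = get_spectrum(name)
        peaks.extend(read_peak_list(path, spectrum))
    stats = ResidueTypeStats.packaged()
    predictions = read_shift_predictions(
        config.prediction_path,
        sequence,
        stats,
        mode=config.prediction_mode,
        errors=config.prediction_errors,
    )

    result = assign(
        peaks,
        sequence,
        predictions,
        n_runs=config.n_runs,
        base_seed=config.seed,
        energy_params=config.energy_params(),
        anneal_params=config.annealing_params(),
        tolerances=config.tolerances,
        cache_low_intensity=config.cache_low_intensity,
    )

    write_assignment_table(result, out_dir / "assignment.tsv")
    manifest = {
        "spinanneal_version": __version__,
        "config": dataclasses.asdict(config),
        "run_seeds": [config.seed + i for i in range(config.n_runs)],
        "n_peaks": len(peaks),
        "n_residues": len(sequence),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if config.reference_path:
        reference = reference_from_table(config.reference_path)
        score = score_against_reference(result, reference, config.tolerances)
        (out_dir / "score.json").write_text(
            json.dumps(
                {
                    "matched": score.matched,
                    "mismatched": score.mismatched,
                    "missing": score.missing,
                    "n_scored": score.n_scored,
                },
                indent=2,
            )
        )
        logger.info(
            "score vs reference: matched %.3f mismatched %.3f missing %.3f",
            score.matched,
            score.mismatched,
            score.missing,
        )
    return result
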