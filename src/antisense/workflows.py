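"""End-to-end antisense design pipeline and fixture generation.

``design_pipeline`` chains the three design stages — epitope profiling
(when a whole protein is given), antisense enumeration, and paratope
consensus ranking against an antibody reference FASTA — writing a region
table, a candidate FASTA, a ranking JSON and a reproducibility manifest.
Binding evaluation (stage 3 of the overall method) operates on measured
titration data and is exposed through the ``fit``/``simulate``/``species``
commands rather than this pipeline.

All coordinates in outputs are 1-based inclusive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from .binding import (BindingModel1to1, DilutionLadder, mst_model, serial_dilution,
                      simulate_spectra, simulate_titration)
from .epitope import consensus_regions, profile_suite
from .genetic_code import ReadingDirection, enumerate_antisense, validate_peptide
from .io import read_fasta, write_fasta, write_spectra_csv, write_titration_csv
from .paratope import DEFAULT_MIN_SCORE, rank_candidates

__all__ = ["DesignRun", "RunManifest", "design_pipeline", "make_fixtures"]


@dataclass
class DesignRun:
    """Configuration of one design pipeline run."""

    out_dir: Path
    protein: Optional[str] = None       # full protein sequence (alternative input)
    epitope: Optional[str] = None       # epitope peptide (alternative input)
    direction: str = "3to5"
    methods: Sequence[str] = ("kd", "parker", "emini", "turn", "eiip")
    window: int = 9
    vote_threshold: float = 0.5
    min_length: int = 5
    references: Optional[Path] = None   # antibody FASTA for paratope ranking
    k: int = 4
    min_score: float = DEFAULT_MIN_SCORE
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.protein is None) == (self.epitope is None):
            raise ValueError("provide exactly one of protein or epitope")


@dataclass
class RunManifest:
    version: str
    config: Dict
    input_checksums: Dict[str, str]
    chosen_epitope: str
    ensemble_count: int
    top_candidate: Optional[str]
    outputs: List[str] = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def design_pipeline(run: DesignRun) -> RunManifest:
    """Run epitope selection, antisense enumeration and paratope ranking."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}
    outputs: List[str] = []

    if run.protein is not None:
        protein = validate_peptide(run.protein)
        profiles = profile_suite(protein, run.methods, run.window)
        calls = consensus_regions(profiles, run.vote_threshold, run.min_length)
        region_path = out / "epitope_regions.tsv"
        with open(region_path, "w") as fh:
            fh.write("# coordinates are 1-based inclusive\n")
            fh.write("start\tend\tmean_vote\tmean_score\tpeptide\n")
            for c in calls:
                fh.write(f"{c.start}\t{c.end}\t{c.mean_vote:.4f}\t{c.mean_score:.4f}\t{c.sequence}\n")
        outputs.append(str(region_path))
        if not calls:
            raise ValueError("no consensus epitope region found in the protein")
        epitope = calls[0].sequence
    else:
        epitope = validate_peptide(run.epitope)

    direction = ReadingDirection.parse(run.direction)
    ensemble = enumerate_antisense(epitope, direction)
    fasta_path = out / "antisense_candidates.fasta"
    write_fasta(fasta_path, {f"anti_{i + 1:04d}": c for i, c in enumerate(ensemble.candidates)})
    outputs.append(str(fasta_path))

    top = None
    if run.references is not None:
        refs = read_fasta(run.references)
        checksums[str(run.references)] = _sha256(Path(run.references))
        rankings = rank_candidates(ensemble, refs, k=run.k, min_score=run.min_score)
        top = rankings[0].candidate
        ranking_path = out / "candidate_ranking.json"
        ranking_path.write_text(json.dumps(
            [
                {
                    "candidate": r.candidate,
                    "covered_motifs": r.covered_motifs,
                    "total_score": r.total_score,
                    "per_motif_best": list(r.per_motif_best),
                }
                for r in rankings
            ],
            indent=1,
        ))
        outputs.append(str(ranking_path))
        top_path = out / "top_candidate.fasta"
        write_fasta(top_path, {"consensus_antisense": top})
        outputs.append(str(top_path))

    manifest = RunManifest(
        version=__version__,
        config={**{k: str(v) for k, v in asdict(run).items()}, "direction": direction.value},
        input_checksums=checksums,
        chosen_epitope=epitope,
        ensemble_count=ensemble.count,
        top_candidate=top,
        outputs=outputs,
    )
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=1))
    return manifest


# Demonstration antibody references: framework-like stretches carrying the
# four AVRDKVG paratope motifs, used by tests and the worked example.
DEMO_ANTIBODY_SEGMENTS = {
    "demo_heavy_1": "EVQLVESGGGLVQPGGSAVRDKVGSLRLSCAAS",
    "demo_heavy_2": "GFTFSSYAMSWVRQVRDKAPGKGLEWVS",
    "demo_light_1": "DIQMTQSPSSLSASVGDKVGRVTITC",
    "demo_light_2": "QSISSYLNWYQQKPAVRDGKAPKLLIY",
}


def make_fixtures(seed: int, out_dir: "str | Path") -> List[Path]:
    """Write demonstration inputs: antibody FASTA, titrations, spectra.

    Deterministic for a fixed seed.  Produces one titration CSV per signal
    mode on its literature concentration design and a two-species spectral
    titration CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    fasta = out / "demo_antibodies.fasta"
    write_fasta(fasta, DEMO_ANTIBODY_SEGMENTS)
    written.append(fasta)

    wide = serial_dilution(DilutionLadder(2800.0, 2.0, 16))
    narrow = serial_dilution(DilutionLadder(70.0, 2.0, 7))
    designs = {
        "fluorescence": (BindingModel1to1(kd=2.6, s_free=0.05, s_complex=1.0, baseline=0.02),
                         1.0, wide),
        "mst": (mst_model(kd=24.3, labeled_total=1.0),
                1.0, wide),
        "mpeia": (BindingModel1to1(kd=24.6, s_free=0.0, s_complex=1.2, baseline=0.05),
                  1.0, narrow),
    }
    for i, (mode, (model, labeled, t)) in enumerate(designs.items()):
        series = simulate_titration(model, labeled, t, noise_cv=0.02,
                                    seed=seed + i, mode=mode)
        path = out / f"titration_{mode}.csv"
        write_titration_csv(path, series)
        written.append(path)

    spectra = simulate_spectra(BindingModel1to1(kd=2.6), labeled_total=1.0,
                               titrant_totals=wide[::-1], noise_sd=0.002,
                               seed=seed + 10, two_species=True)
    spath = out / "spectra_two_species.csv"
    write_spectra_csv(spath, spectra)
    written.append(spath)
    return written
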