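"""End-to-end pipelines: FASTQ in, tables out, with read-fate accounting.

``run_ribo_pipeline`` composes adapter trimming, best-match mapping to the
mature mRNA transcripts, A-site assignment and the codon-occupancy
statistic; ``run_mpat_pipeline`` composes anchor trimming, padded-reference
mapping and 3'-end classification into per-gene end profiles and
summaries.  Both return a result object and can serialise everything to a
directory as plain TSV/JSON.  Every input read is accounted for exactly
once (trimmed-away, unmapped, rejected-by-reason or counted), and a run is
fully determined by its inputs and the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import mpat as _mpat
from .annotation import (
    MitoAnnotation,
    build_overlap_exclusion_mask,
    build_padded_reference,
    codon_frequency_table,
    load_annotation,
)
from .mapping import MappingParams, ReferenceAligner, trim_three_prime_adapter
from .mpat import (
    EndProfile,
    ThreePrimeCall,
    classify_three_prime_end,
    end_profile_relative_to_db,
    gene_end_model,
)
from .ribo import (
    ASiteParams,
    GeneProfile,
    OccupancyTable,
    assign_all,
    codon_occupancy,
    gene_profile,
)
from .simulate import READ_ADAPTER, read_fastq

logger = logging.getLogger("mitostall")

__all__ = [
    "RunConfig",
    "RiboResult",
    "MpatResult",
    "run_ribo_pipeline",
    "run_mpat_pipeline",
]


@dataclass
class RunConfig:
    """Serializable run configuration.

    Defaults are the standard analysis parameters: footprint window 31-35 nt,
    A-site at read nt 16-18 / 17-19 (frame 1/3), start/stop margins 15/45
    nt, at most two mismatches with best-match reporting, a 30 nt uncalled
    pad on the 3'-end reference, and reads above 20 nt after trimming.
    """

    genome: str = ""
    features: str = ""
    reads: str = ""
    output_dir: str = "mitostall_out"
    adapter: str = READ_ADAPTER
    min_len: int = 31
    max_len: int = 35
    offset_frame1: int = 16  # 1-based first A-site nt of the read
    offset_frame3: int = 17
    start_margin: int = 15
    stop_margin: int = 45
    max_mismatches: int = 2
    min_read_length: int = 20
    pad: int = 30
    min_anchor: int = 15
    profile_offset: int = 17
    smoothing_window: int = 3
    genotype_label: str = ""
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def asite_params(self) -> ASiteParams:
        return ASiteParams(
            min_length=self.min_len,
            max_length=self.max_len,
            offset_frame1=self.offset_frame1 - 1,
            offset_frame3=self.offset_frame3 - 1,
            start_margin_nt=self.start_margin,
            stop_margin_nt=self.stop_margin,
        )

    def mapping_params(self) -> MappingParams:
        return MappingParams(
            max_mismatches=self.max_mismatches,
            min_read_length=self.min_read_length,
            min_anchor=self.min_anchor,
        )


def _load(config: RunConfig) -> MitoAnnotation:
    for path in (config.genome, config.features):
        if not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    return load_annotation(config.genome, config.features)


def _trim_all(
    reads: Iterable[tuple[str, str]], adapter: str, min_length: int
) -> tuple[list[tuple[str, str]], dict]:
    kept: list[tuple[str, str]] = []
    fates = {"input": 0, "trimmed": 0, "untrimmed": 0, "discarded_short": 0}
    for rid, seq in reads:
        fates["input"] += 1
        res = trim_three_prime_adapter(rid, seq, adapter, min_length)
        if res.discarded:
            fates["discarded_short"] += 1
            continue
        fates["trimmed" if res.trimmed else "untrimmed"] += 1
        kept.append((rid, res.sequence))
    return kept, fates


@dataclass
class RiboResult:
    occupancy: OccupancyTable
    profiles: dict[str, GeneProfile]
    qc: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.occupancy.to_tsv(out / "codon_occupancy.tsv")
        for name, prof in self.profiles.items():
            prof.to_dataframe().to_csv(
                out / f"profile_{name}.tsv", sep="\t", index=False
            )
        (out / "qc.json").write_text(json.dumps(self.qc, indent=2) + "\n")


def run_ribo_pipeline(
    config: RunConfig,
    annotation: MitoAnnotation | None = None,
    reads: Sequence[tuple[str, str]] | None = None,
    trim: bool = False,
) -> RiboResult:
    """Footprints -> codon occupancy table + per-gene profiles + QC.

    ``annotation``/``reads`` may be passed in-memory; otherwise they are
    loaded from the config paths.  ``trim`` enables 3'-adapter trimming
    (off by default: footprint protocols vary and simulated reads are
    emitted insert-only).
    """
    ann = annotation if annotation is not None else _load(config)
    if reads is None:
        reads = read_fastq(config.reads)
    if trim:
        reads, fates = _trim_all(reads, config.adapter, config.min_read_length)
    else:
        fates = {"input": len(reads)}
    transcripts = {name: ann.transcript(name) for name in ann.cds_names}
    aligner = ReferenceAligner(transcripts, params=config.mapping_params())
    alignments, n_unmapped = aligner.map_reads(reads)
    mask = build_overlap_exclusion_mask(ann, config.start_margin, config.stop_margin)
    accepted, reasons = assign_all(alignments, ann, mask, config.asite_params())
    occupancy = codon_occupancy(accepted, ann, mask)
    profiles = {
        name: gene_profile(
            alignments, ann, name, config.profile_offset, config.smoothing_window
        )
        for name in ann.cds_names
    }
    qc = {
        "read_fates": {
            **fates,
            "unmapped": n_unmapped,
            "rejected": dict(reasons),
            "accepted": len(accepted),
        },
        "config": asdict(config),
    }
    total = n_unmapped + sum(reasons.values()) + len(accepted)
    assert total + fates.get("discarded_short", 0) == fates["input"], (
        "read-fate accounting does not sum to the input read count"
    )
    return RiboResult(occupancy=occupancy, profiles=profiles, qc=qc)


@dataclass
class MpatResult:
    profiles: dict[str, EndProfile]
    calls: dict[str, list[ThreePrimeCall]]
    summary: pd.DataFrame
    qc: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / "end_summary.tsv", sep="\t", index=False)
        for name, prof in self.profiles.items():
            prof.to_dataframe().to_csv(
                out / f"end_profile_{name}.tsv", sep="\t", index=False
            )
        (out / "qc.json").write_text(json.dumps(self.qc, indent=2) + "\n")


def run_mpat_pipeline(
    config: RunConfig,
    annotation: MitoAnnotation | None = None,
    reads: Sequence[tuple[str, str]] | None = None,
) -> MpatResult:
    """MPAT-Seq reads -> per-gene 3'-end profiles + summary + QC."""
    ann = annotation if annotation is not None else _load(config)
    if reads is None:
        reads = read_fastq(config.reads)
    reads, fates = _trim_all(reads, config.adapter, config.min_read_length)
    padded = build_padded_reference(ann, config.pad)
    aligner = ReferenceAligner(padded, params=config.mapping_params(), padded=True)
    models = {name: gene_end_model(ann, name) for name in padded}
    calls: dict[str, list[ThreePrimeCall]] = {name: [] for name in padded}
    n_unmapped = 0
    for rid, seq in reads:
        aln = aligner.map_read(rid, seq)
        if aln is None:
            n_unmapped += 1
            continue
        calls[aln.target].append(classify_three_prime_end(aln, models[aln.target]))
    profiles = {
        name: end_profile_relative_to_db(c) for name, c in calls.items() if c
    }
    rows = []
    for name, prof in profiles.items():
        gene_calls = calls[name]
        ext_calls = [
            c for c in gene_calls if c.state is _mpat.EndState.EXTENDED
        ]
        a_fraction = None
        if ext_calls:
            comp = _mpat.extension_composition(gene_calls)
            a_fraction = comp.attrs["overall_A_fraction"]
        rows.append(
            {
                "gene": name,
                "n": prof.n_calls,
                "percent_extended": prof.percent_extended_beyond_cca,
                "modal_extension": prof.modal_extension,
                "A_fraction": a_fraction,
                "genotype": config.genotype_label,
            }
        )
    summary = pd.DataFrame(rows)
    n_called = sum(len(c) for c in calls.values())
    qc = {
        "read_fates": {
            **fates,
            "unmapped": n_unmapped,
            "classified": n_called,
        },
        "config": asdict(config),
    }
    assert n_unmapped + n_called + fates.get("discarded_short", 0) == fates["input"]
    return MpatResult(profiles=profiles, calls=calls, summary=summary, qc=qc)
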