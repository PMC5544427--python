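"""Mitochondrial genome annotation: features, transcripts, codon statistics.

The human mitochondrial genome is a ~16.6 kb circular molecule encoding 13
protein-coding genes (CDS), 22 tRNAs and 2 rRNAs.  This module loads the
genome plus a feature annotation (GFF3 or GenBank), derives transcript and
ORF sequences on the coding strand, computes codon-usage statistics under
the vertebrate mitochondrial genetic code (translation table 2), builds the
codon-level exclusion masks used by the ribosome-profiling occupancy
statistic, and constructs the N-padded 3'-end reference used for mapping
reads that carry non-templated 3' extensions.

Coordinate conventions: features are stored with 1-based inclusive
``start``/``end`` (the convention of GFF3/GenBank and of positions quoted
as e.g. "m.7,846"); all internal arithmetic uses the 0-based half-open
``start0``/``end0`` properties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "MitoAnnotation",
    "CodonUsageTable",
    "ExclusionMask",
    "AnnotationError",
    "load_annotation",
    "extract_orf_codons",
    "count_codon_occurrences",
    "codon_frequency_table",
    "build_overlap_exclusion_mask",
    "build_padded_reference",
    "MITO_TABLE_ID",
    "MITO_STOPS",
    "amino_acid_groups",
    "write_fasta",
    "write_gff3",
]

#: NCBI translation table for vertebrate mitochondria.
MITO_TABLE_ID = 2

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[MITO_TABLE_ID]
#: Stop codons of the vertebrate mitochondrial code (includes AGA/AGG).
MITO_STOPS = frozenset(_MITO_TABLE.stop_codons)

_VALID_KINDS = ("CDS", "tRNA", "rRNA")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent genome annotations."""


@dataclass(frozen=True)
class Feature:
    """A single annotated gene on the mitochondrial genome.

    Parameters
    ----------
    name : short gene symbol (``ND4``, ``TK`` ...), unique per annotation.
    kind : one of ``CDS``, ``tRNA``, ``rRNA``.
    start, end : 1-based inclusive genome coordinates (end may exceed the
        genome length only for origin-wrapping features, see ``wraps``).
    strand : ``+`` or ``-``; minus-strand transcripts are the reverse
        complement of the genomic slice.
    db_offset : tRNA only — position of the discriminator base relative to
        the predominant 3' processing site.  0 for a tRNA whose processing
        leaves the discriminator base in place; +1 for mt-tRNA-Tyr, whose
        discriminator base is shared with the 5' end of mt-tRNA-Cys and is
        absent from the directly processed molecule.
    completion_by_polyadenylation : CDS only — the stop codon is completed
        by 3' polyadenylation, so the templated ORF length is not a
        multiple of three.
    wraps : the interval crosses the origin of the circular genome.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str
    db_offset: int = 0
    completion_by_polyadenylation: bool = False
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise AnnotationError(f"{self.name}: unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.name}: strand must be '+' or '-'")
        if self.start < 1 or (self.end < self.start and not self.wraps):
            raise AnnotationError(f"{self.name}: bad interval {self.start}..{self.end}")

    @property
    def start0(self) -> int:
        return self.start - 1

    @property
    def end0(self) -> int:
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitoAnnotation:
    """A circular genome sequence plus its CDS/tRNA/rRNA features."""

    genome_sequence: str
    features: list[Feature]
    genetic_code_id: int = MITO_TABLE_ID
    circular: bool = True

    def __post_init__(self) -> None:
        self.genome_sequence = self.genome_sequence.upper().replace("U", "T")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationError(f"duplicate feature names: {dup}")
        for f in self.features:
            if f.start > self.genome_length:
                raise AnnotationError(
                    f"{f.name}: start {f.start} outside genome of "
                    f"length {self.genome_length}"
                )
            if f.end > self.genome_length and not (self.circular and f.wraps):
                raise AnnotationError(
                    f"{f.name}: end {f.end} exceeds genome length "
                    f"{self.genome_length} and feature is not flagged as "
                    "wrapping the origin"
                )
        self._by_name = {f.name: f for f in self.features}
        self._transcript_cache: dict[str, str] = {}

    @property
    def genome_length(self) -> int:
        return len(self.genome_sequence)

    def __getitem__(self, name: str) -> Feature:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no feature named {name!r} in annotation") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def cds_names(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "CDS"]

    def genomic_slice(self, start0: int, end0: int) -> str:
        """Plus-strand genomic sequence over [start0, end0), unwrapping the
        circular origin when end0 exceeds the genome length."""
        g = self.genome_sequence
        if end0 <= self.genome_length:
            return g[start0:end0]
        if not self.circular:
            raise AnnotationError("interval beyond a linear genome")
        return g[start0:] + g[: end0 - self.genome_length]

    def transcript(self, name: str) -> str:
        """Coding-strand (mature orientation) sequence of a feature."""
        cached = self._transcript_cache.get(name)
        if cached is not None:
            return cached
        f = self[name]
        seq = self.genomic_slice(f.start0, f.end0)
        if f.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        self._transcript_cache[name] = seq
        return seq

    def downstream_feature(self, name: str) -> Feature | None:
        """The immediately distal feature in transcript orientation: the
        annotated feature whose 5' end abuts (or overlaps by one base) the
        3' end of ``name`` on the same strand."""
        f = self[name]
        if f.strand == "+":
            tp = f.end  # genomic coordinate of the 3' end
            candidates = [
                g for g in self.features
                if g is not f and g.strand == "+" and g.start >= tp - 1
            ]
            if not candidates:
                return None
            return min(candidates, key=lambda g: g.start)
        tp = f.start
        candidates = [
            g for g in self.features
            if g is not f and g.strand == "-" and g.end <= tp + 1
        ]
        if not candidates:
            return None
        return max(candidates, key=lambda g: g.end)


# ---------------------------------------------------------------------------
# codon machinery


def amino_acid_groups() -> dict[str, frozenset[str]]:
    """Codon families under translation table 2, with the two-box splits
    conventional for mitochondrial work: Ser is split into Ser(AGY) and
    Ser(UCN), Leu into Leu(UUR) and Leu(CUN).  Stop codons form one group.
    """
    groups: dict[str, set[str]] = {}
    for codon, aa in _MITO_TABLE.forward_table.items():
        if aa == "S":
            label = "Ser(AGY)" if codon.startswith("AG") else "Ser(UCN)"
        elif aa == "L":
            label = "Leu(UUR)" if codon.startswith("TT") else "Leu(CUN)"
        else:
            label = {
                "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
                "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
                "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro", "T": "Thr",
                "W": "Trp", "Y": "Tyr", "V": "Val",
            }[aa]
        groups.setdefault(label, set()).add(codon)
    groups["Stop"] = set(MITO_STOPS)
    return {k: frozenset(v) for k, v in groups.items()}


_GROUPS = amino_acid_groups()
_CODON_TO_GROUP = {c: g for g, cs in _GROUPS.items() for c in cs}


def _normalize_codon(codon: str) -> str:
    c = codon.upper().replace("U", "T")
    if len(c) != 3 or any(b not in "ACGT" for b in c):
        raise AnnotationError(f"invalid codon {codon!r}")
    return c


def extract_orf_codons(
    annotation: MitoAnnotation, cds_name: str
) -> tuple[list[str], str | None]:
    """Codons of a CDS read in translation frame on the coding strand.

    Returns ``(codons, partial)`` where ``partial`` is the trailing
    incomplete codon (one or two templated nucleotides of a stop codon
    completed by polyadenylation) or ``None``.  Partial codons are excluded
    from all codon statistics.
    """
    f = annotation[cds_name]
    if f.kind != "CDS":
        raise KeyError(f"{cds_name} is a {f.kind}, not a CDS")
    seq = annotation.transcript(cds_name)
    n_full = len(seq) // 3
    codons = [seq[3 * i : 3 * i + 3] for i in range(n_full)]
    partial = seq[3 * n_full :] or None
    if partial and not f.completion_by_polyadenylation:
        warnings.warn(
            f"{cds_name}: length {len(seq)} is not a multiple of 3 but the "
            "CDS is not flagged as polyadenylation-completed",
            stacklevel=2,
        )
    return codons, partial


def count_codon_occurrences(
    annotation: MitoAnnotation, cds_name: str, codon_set: Iterable[str]
) -> int:
    """Number of complete codons of the ORF belonging to ``codon_set``."""
    wanted = {_normalize_codon(c) for c in codon_set}
    if not wanted:
        raise AnnotationError("codon_set must be non-empty")
    codons, _ = extract_orf_codons(annotation, cds_name)
    return sum(1 for c in codons if c in wanted)


@dataclass
class CodonUsageTable:
    """Pooled codon usage over the mtDNA-encoded ORFs.

    ``frequencies`` are percentages of all complete coding triplets (stop
    codons included, polyadenylation-completed partial codons excluded).
    """

    counts: dict[str, int]
    frequencies: dict[str, float]
    amino_acid_groups: dict[str, frozenset[str]] = field(
        default_factory=amino_acid_groups
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def group_count(self, label: str) -> int:
        return sum(self.counts.get(c, 0) for c in self.amino_acid_groups[label])

    def group_frequency(self, label: str) -> float:
        """Percent of all coding triplets in an amino-acid family."""
        return 100.0 * self.group_count(label) / self.total

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "codon": c,
                "amino_acid": _CODON_TO_GROUP[c],
                "count": n,
                "percent": self.frequencies[c],
            }
            for c, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def codon_frequency_table(annotation: MitoAnnotation) -> CodonUsageTable:
    """Codon counts and percent frequencies pooled over all CDS features."""
    cds = annotation.cds_names
    if not cds:
        raise AnnotationError("annotation contains no CDS features")
    counts: dict[str, int] = {}
    for name in cds:
        codons, _ = extract_orf_codons(annotation, name)
        for c in codons:
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    freqs = {c: 100.0 * n / total for c, n in counts.items()}
    return CodonUsageTable(counts=counts, frequencies=freqs)


# ---------------------------------------------------------------------------
# exclusion mask


@dataclass
class ExclusionMask:
    """Per-CDS boolean masks over codon indices (True = excluded) together
    with the reason each codon was masked.

    A codon is excluded from the occupancy statistic when the 5' end of any
    footprint that would place its ribosomal A-site on that codon falls
    within ``start_margin_nt`` of the start codon or ``stop_margin_nt`` of
    the stop codon, or when the codon lies in a region where two CDS
    overlap on the genome (ambiguous CDS assignment).
    """

    masks: dict[str, np.ndarray]
    reasons: dict[str, dict[int, str]]
    start_margin_nt: int = 15
    stop_margin_nt: int = 45

    def is_masked(self, cds_name: str, codon_index: int) -> bool:
        m = self.masks[cds_name]
        if codon_index < 0 or codon_index >= len(m):
            return True
        return bool(m[codon_index])

    def reason(self, cds_name: str, codon_index: int) -> str | None:
        return self.reasons[cds_name].get(codon_index)

    def unmasked_indices(self, cds_name: str) -> np.ndarray:
        return np.flatnonzero(~self.masks[cds_name])


# 0-based read offsets of the A-site first nucleotide for footprints whose
# 5' end falls on codon position 1 / position 3 (read nt 16-18 and 17-19).
ASITE_OFFSET_FRAME1 = 15
ASITE_OFFSET_FRAME3 = 16


def _genomic_codon_interval(f: Feature, codon_index: int) -> tuple[int, int]:
    """0-based half-open genomic interval of one codon of a CDS."""
    if f.strand == "+":
        s = f.start0 + 3 * codon_index
        return s, s + 3
    e = f.end0 - 3 * codon_index
    return e - 3, e


def build_overlap_exclusion_mask(
    annotation: MitoAnnotation,
    start_margin_nt: int = 15,
    stop_margin_nt: int = 45,
) -> ExclusionMask:
    """Derive the deterministic codon exclusion mask from the annotation.

    ``near_start`` / ``near_stop``: a codon is masked if a footprint 5' end
    generating it under the A-site rule (5' end at ``3*c - 15`` for frame-1
    reads or ``3*c - 16`` for frame-3 reads) would lie within the start or
    stop margin.  ``overlap_region``: the codon's genomic interval
    intersects another CDS feature.
    """
    if start_margin_nt < 0 or stop_margin_nt < 0:
        raise AnnotationError("margins must be non-negative")
    cds_feats = annotation.features_of_kind("CDS")
    masks: dict[str, np.ndarray] = {}
    reasons: dict[str, dict[int, str]] = {}
    for f in cds_feats:
        n_codons = len(annotation.transcript(f.name)) // 3
        cds_len = f.length
        mask = np.zeros(n_codons, dtype=bool)
        why: dict[int, str] = {}
        if start_margin_nt + stop_margin_nt >= cds_len:
            warnings.warn(
                f"{f.name}: margins ({start_margin_nt}+{stop_margin_nt} nt) "
                f"cover the whole CDS ({cds_len} nt); every codon masked",
                stacklevel=2,
            )
        for c in range(n_codons):
            # frame-1 5' end = 3c-15; frame-3 5' end = 3c-16; a zero margin
            # masks nothing (only margin-caused exclusions are encoded)
            p1, p3 = 3 * c - 15, 3 * c - 16
            if start_margin_nt > 0 and min(p1, p3) < start_margin_nt:
                mask[c] = True
                why[c] = "near_start"
            elif stop_margin_nt > 0 and max(p1, p3) >= cds_len - stop_margin_nt:
                mask[c] = True
                why[c] = "near_stop"
        # CDS-CDS genomic overlap (e.g. ATP8/ATP6 and ND4L/ND4)
        others = [g for g in cds_feats if g.name != f.name]
        for c in range(n_codons):
            cs, ce = _genomic_codon_interval(f, c)
            for g in others:
                if cs < g.end0 and g.start0 < ce:
                    mask[c] = True
                    why[c] = "overlap_region"
                    break
        masks[f.name] = mask
        reasons[f.name] = why
    return ExclusionMask(
        masks=masks,
        reasons=reasons,
        start_margin_nt=start_margin_nt,
        stop_margin_nt=stop_margin_nt,
    )


# ---------------------------------------------------------------------------
# padded 3'-end reference


def build_padded_reference(
    annotation: MitoAnnotation, pad_length: int = 30
) -> dict[str, str]:
    """tRNA and rRNA gene sequences (coding strand, mature orientation)
    followed by ``pad_length`` uncalled ``N`` symbols.

    Reads whose 3' ends carry non-templated nucleotides (CCA, oligo(A)
    extensions) align over the pad without penalty, so every 3' end maps.
    CDS genes are not padded and are not part of this reference.
    """
    if pad_length <= 0:
        raise AnnotationError("pad_length must be positive")
    ref: dict[str, str] = {}
    for f in annotation.features:
        if f.kind in ("tRNA", "rRNA"):
            ref[f.name] = annotation.transcript(f.name) + "N" * pad_length
    return ref


# ---------------------------------------------------------------------------
# file I/O

#: Default alias map normalising long locus names to the short gene symbols
#: used throughout ("MT-ND4" -> "ND4").  User-extendable via load_annotation.
DEFAULT_ALIASES = {
    "MT-ND1": "ND1", "MT-ND2": "ND2", "MT-ND3": "ND3", "MT-ND4": "ND4",
    "MT-ND4L": "ND4L", "MT-ND5": "ND5", "MT-ND6": "ND6", "MT-CYB": "CYTB",
    "MT-CO1": "COI", "MT-CO2": "COII", "MT-CO3": "COIII", "MT-ATP6": "ATP6",
    "MT-ATP8": "ATP8", "MT-RNR1": "RNR1", "MT-RNR2": "RNR2",
    "MT-TF": "TF", "MT-TV": "TV", "MT-TL1": "TL1", "MT-TI": "TI",
    "MT-TQ": "TQ", "MT-TM": "TM", "MT-TW": "TW", "MT-TA": "TA",
    "MT-TN": "TN", "MT-TC": "TC", "MT-TY": "TY", "MT-TS1": "TS1",
    "MT-TD": "TD", "MT-TK": "TK", "MT-TG": "TG", "MT-TR": "TR",
    "MT-TH": "TH", "MT-TS2": "TS2", "MT-TL2": "TL2", "MT-TE": "TE",
    "MT-TT": "TT", "MT-TP": "TP",
}


def _read_single_fasta(path: str | Path) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(
            f"{path}: expected exactly one genome record, found {len(records)}"
        )
    return str(records[0].seq).upper()


def _attr_bool(value: str) -> bool:
    return value.lower() in ("1", "true", "yes")


def _features_from_gff3(path: str | Path, aliases: Mapping[str, str]) -> list[Feature]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", force=True
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"{path}: failed to parse GFF3 ({exc})") from exc
    feats: list[Feature] = []
    for rec in db.all_features():
        if rec.featuretype not in _VALID_KINDS:
            continue
        name = rec.attributes.get("Name", rec.attributes.get("ID", [rec.id]))[0]
        name = aliases.get(name, name)
        db_offset = int(rec.attributes.get("db_offset", ["0"])[0])
        partial = _attr_bool(rec.attributes.get("partial_stop", ["false"])[0])
        wraps = _attr_bool(rec.attributes.get("wraps_origin", ["false"])[0])
        feats.append(
            Feature(
                name=name,
                kind=rec.featuretype,
                start=rec.start,
                end=rec.end,
                strand=rec.strand,
                db_offset=db_offset,
                completion_by_polyadenylation=partial,
                wraps=wraps,
            )
        )
    return feats


def _features_from_genbank(record, aliases: Mapping[str, str]) -> list[Feature]:
    feats: list[Feature] = []
    seen: set[str] = set()
    for sf in record.features:
        if sf.type not in _VALID_KINDS:
            continue
        quals = sf.qualifiers
        name = quals.get("gene", quals.get("product", ["?"]))[0]
        name = aliases.get(name, name)
        if name in seen:  # GenBank repeats gene/CDS pairs; keep first typed one
            continue
        seen.add(name)
        start = int(sf.location.start) + 1
        end = int(sf.location.end)
        strand = "+" if (sf.location.strand or 1) >= 0 else "-"
        partial = "transl_except" in quals or (end - start + 1) % 3 != 0
        feats.append(
            Feature(
                name=name,
                kind=sf.type,
                start=start,
                end=end,
                strand=strand,
                completion_by_polyadenylation=partial if sf.type == "CDS" else False,
            )
        )
    return feats


def load_annotation(
    genome_file: str | Path,
    features_file: str | Path,
    aliases: Mapping[str, str] | None = None,
    circular: bool = True,
) -> MitoAnnotation:
    """Load a genome FASTA plus a GFF3 or GenBank feature annotation.

    The features file dialect is chosen by extension (``.gff``/``.gff3`` vs
    ``.gb``/``.gbk``/``.genbank``).  For GenBank input the genome FASTA may
    be the same GenBank file.  Gene names are normalised through ``aliases``
    (defaults to the MT-* alias map).
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update(aliases)
    fpath = Path(features_file)
    suffix = fpath.suffix.lower()
    if suffix in (".gb", ".gbk", ".genbank"):
        record = SeqIO.read(str(fpath), "genbank")
        features = _features_from_genbank(record, alias_map)
        genome = (
            str(record.seq).upper()
            if str(genome_file) == str(features_file)
            else _read_single_fasta(genome_file)
        )
    elif suffix in (".gff", ".gff3"):
        genome = _read_single_fasta(genome_file)
        features = _features_from_gff3(fpath, alias_map)
    else:
        raise AnnotationError(
            f"{fpath}: unrecognised annotation dialect {suffix!r} "
            "(expected GFF3 or GenBank)"
        )
    if not features:
        raise AnnotationError(f"{fpath}: no CDS/tRNA/rRNA features found")
    return MitoAnnotation(genome_sequence=genome, features=features, circular=circular)


def write_fasta(annotation: MitoAnnotation, path: str | Path, name: str = "mtDNA") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        seq = annotation.genome_sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_gff3(annotation: MitoAnnotation, path: str | Path, seqid: str = "mtDNA") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.genome_length}\n")
        for f in annotation.features:
            attrs = [f"ID={f.name}", f"Name={f.name}"]
            if f.db_offset:
                attrs.append(f"db_offset={f.db_offset}")
            if f.completion_by_polyadenylation:
                attrs.append("partial_stop=true")
            if f.wraps:
                attrs.append("wraps_origin=true")
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "mitostall",
                        f.kind,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
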