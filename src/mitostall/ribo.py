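"""A-site assignment and codon-occupancy (stalling) statistics.

A mitoribosome protects a ~31-35 nt mRNA fragment.  For footprints whose
5' end falls on the first position of a codon the A-site codon occupies
read nucleotides 16-18; for 5' ends on the third codon position it
occupies nucleotides 17-19.  Only footprints of length 31-35 nt with 5'
ends in frame 1 or 3 are used for the occupancy statistic; frame-2 reads
and reads with 5' ends within 15 nt of the start codon or 45 nt of the
stop codon are rejected, as are reads in CDS-CDS overlap regions
(ambiguous gene assignment) and multi-mapped reads.

The occupancy statistic: within each CDS, the histogram of A-site counts
per codon is scaled by the mean count over that CDS's unmasked codons
(so a uniformly translated gene has scaled density 1 everywhere).  The
scaled density at each A-site codon is then summed over all occurrences of
that codon species across the examined CDS regions and divided by the
number of occurrences — i.e. the occupancy of a codon species is the mean
scaled A-site density over its occurrences, with 1.0 the no-stalling
baseline and values above 1 indicating ribosomes dwelling with that codon
in the A-site (awaiting the cognate aminoacyl-tRNA).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    ASITE_OFFSET_FRAME1,
    ASITE_OFFSET_FRAME3,
    ExclusionMask,
    MitoAnnotation,
    amino_acid_groups,
    extract_orf_codons,
)
from .mapping import Alignment

__all__ = [
    "ASiteParams",
    "ASiteAssignment",
    "Rejection",
    "assign_asite",
    "assign_all",
    "GeneProfile",
    "gene_profile",
    "OccupancyTable",
    "codon_occupancy",
]

_CODON_TO_GROUP = {c: g for g, cs in amino_acid_groups().items() for c in cs}


@dataclass(frozen=True)
class ASiteParams:
    """Footprint acceptance window and A-site offsets (0-based read offset
    of the first A-site nucleotide, per 5'-end frame)."""

    min_length: int = 31
    max_length: int = 35
    offset_frame1: int = ASITE_OFFSET_FRAME1  # read nt 16-18
    offset_frame3: int = ASITE_OFFSET_FRAME3  # read nt 17-19
    start_margin_nt: int = 15
    stop_margin_nt: int = 45


@dataclass(frozen=True)
class ASiteAssignment:
    read_id: str
    cds: str
    a_site_codon_index: int
    codon: str
    read_length: int
    frame_of_5prime: int  # 1 or 3


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # length | frame | near_start | near_stop | overlap_region |
    #              multimapped | off_cds


def assign_asite(
    alignment: Alignment,
    annotation: MitoAnnotation,
    mask: ExclusionMask,
    params: ASiteParams | None = None,
) -> ASiteAssignment | Rejection:
    """Infer the A-site codon of one footprint alignment, or reject it.

    The alignment must be on a CDS transcript (plus strand of the mature
    mRNA); its ``start`` is the 5'-end position on the transcript.
    """
    p = params or ASiteParams()
    if alignment.target not in annotation or annotation[alignment.target].kind != "CDS":
        return Rejection(alignment.read_id, "off_cds")
    if alignment.multi_mapped:
        return Rejection(alignment.read_id, "multimapped")
    if alignment.strand != "+":
        return Rejection(alignment.read_id, "off_cds")
    L = alignment.read_length
    if not (p.min_length <= L <= p.max_length):
        return Rejection(alignment.read_id, "length")
    pos = alignment.start
    frame = pos % 3  # 0 -> codon position 1, 2 -> codon position 3
    if frame == 1:
        return Rejection(alignment.read_id, "frame")
    cds_len = len(annotation.transcript(alignment.target))
    if pos < p.start_margin_nt:
        return Rejection(alignment.read_id, "near_start")
    if pos >= cds_len - p.stop_margin_nt:
        return Rejection(alignment.read_id, "near_stop")
    a_start = pos + (p.offset_frame1 if frame == 0 else p.offset_frame3)
    codon_index = a_start // 3
    if a_start + 3 > cds_len:
        return Rejection(alignment.read_id, "near_stop")
    if mask.is_masked(alignment.target, codon_index):
        return Rejection(
            alignment.read_id, mask.reason(alignment.target, codon_index) or "masked"
        )
    codon = annotation.transcript(alignment.target)[a_start : a_start + 3]
    return ASiteAssignment(
        read_id=alignment.read_id,
        cds=alignment.target,
        a_site_codon_index=codon_index,
        codon=codon,
        read_length=L,
        frame_of_5prime=1 if frame == 0 else 3,
    )


def assign_all(
    alignments: Iterable[Alignment],
    annotation: MitoAnnotation,
    mask: ExclusionMask,
    params: ASiteParams | None = None,
) -> tuple[list[ASiteAssignment], Counter]:
    """Assign every alignment; returns accepted assignments and a counter
    of rejection reasons."""
    accepted: list[ASiteAssignment] = []
    reasons: Counter = Counter()
    # memoise transcripts: assign_asite re-derives them per read otherwise
    for aln in alignments:
        res = assign_asite(aln, annotation, mask, params)
        if isinstance(res, ASiteAssignment):
            accepted.append(res)
        else:
            reasons[res.reason] += 1
    return accepted, reasons


# ---------------------------------------------------------------------------
# per-gene profiles


@dataclass
class GeneProfile:
    """Per-nucleotide 5'-end histogram of one CDS, shifted by a fixed
    offset to approximate the A-site, plus its running-mean smoothing."""

    cds: str
    counts: np.ndarray
    smoothed: np.ndarray
    offset_nt: int = 17
    smoothing_window: int = 3

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(len(self.counts)),
                "count": self.counts,
                "smoothed": self.smoothed,
            }
        )


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean; the window shrinks at the vector edges so the
    output has the same length as the input."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = len(x)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def gene_profile(
    alignments: Iterable[Alignment],
    annotation: MitoAnnotation,
    cds_name: str,
    offset_nt: int = 17,
    window: int = 3,
) -> GeneProfile:
    """Histogram of footprint 5' ends shifted by ``offset_nt`` (the
    approximate A-site), smoothed with a ``window``-nt running mean.

    All mapped footprint lengths contribute (the strict 31-35 nt / frame
    filter applies to the occupancy statistic, not to profiles).
    """
    n = len(annotation.transcript(cds_name))
    counts = np.zeros(n, dtype=float)
    for aln in alignments:
        if aln.target != cds_name or aln.strand != "+":
            continue
        pos = aln.start + offset_nt
        if 0 <= pos < n:
            counts[pos] += 1
    return GeneProfile(
        cds=cds_name,
        counts=counts,
        smoothed=_running_mean(counts, window),
        offset_nt=offset_nt,
        smoothing_window=window,
    )


# ---------------------------------------------------------------------------
# codon occupancy


@dataclass
class OccupancyTable:
    """Mean scaled A-site density per codon species."""

    occupancy: dict[str, float]
    n_occurrences: dict[str, int]
    n_reads: dict[str, int]
    cds_mean_density: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": _CODON_TO_GROUP.get(c, "?"),
                "occupancy": self.occupancy[c],
                "n_occurrences": self.n_occurrences[c],
                "n_reads": self.n_reads[c],
            }
            for c in sorted(self.occupancy)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def top_codons(self, n: int = 2) -> list[str]:
        return sorted(self.occupancy, key=self.occupancy.get, reverse=True)[:n]


def codon_occupancy(
    assignments: Sequence[ASiteAssignment],
    annotation: MitoAnnotation,
    mask: ExclusionMask,
) -> OccupancyTable:
    """Pool accepted A-site assignments into the per-codon-species
    occupancy statistic (see module docstring for the definition)."""
    if not assignments:
        raise ValueError("no accepted A-site assignments")
    by_cds: dict[str, Counter] = {}
    for a in assignments:
        by_cds.setdefault(a.cds, Counter())[a.a_site_codon_index] += 1

    scaled: dict[str, np.ndarray] = {}
    cds_mean: dict[str, float] = {}
    examined: list[str] = []
    for cds_name in annotation.cds_names:
        unmasked = mask.unmasked_indices(cds_name)
        if cds_name not in by_cds or len(unmasked) == 0:
            if cds_name in by_cds or len(unmasked) > 0:
                import warnings

                warnings.warn(
                    f"{cds_name}: no accepted footprints, excluded from "
                    "occupancy scaling",
                    stacklevel=2,
                )
            continue
        counts = by_cds[cds_name]
        n_codons = len(mask.masks[cds_name])
        dens = np.zeros(n_codons, dtype=float)
        for idx, c in counts.items():
            dens[idx] = c
        mean = dens[unmasked].mean()
        if mean == 0:
            continue
        scaled[cds_name] = dens / mean
        cds_mean[cds_name] = float(mean)
        examined.append(cds_name)

    occ_sum: dict[str, float] = {}
    occ_n: dict[str, int] = {}
    reads: dict[str, int] = {}
    for cds_name in examined:
        codons, _ = extract_orf_codons(annotation, cds_name)
        unmasked = set(mask.unmasked_indices(cds_name).tolist())
        vec = scaled[cds_name]
        counts = by_cds[cds_name]
        for idx in unmasked:
            sp = codons[idx]
            occ_sum[sp] = occ_sum.get(sp, 0.0) + vec[idx]
            occ_n[sp] = occ_n.get(sp, 0) + 1
            reads[sp] = reads.get(sp, 0) + counts.get(idx, 0)
    occupancy = {sp: occ_sum[sp] / occ_n[sp] for sp in occ_sum}
    return OccupancyTable(
        occupancy=occupancy,
        n_occurrences=occ_n,
        n_reads=reads,
        cds_mean_density=cds_mean,
    )
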