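"""3'-end state classification of mt-tRNAs and mt-rRNAs from MPAT-Seq.

MPAT-Seq ligates an anchor oligo to RNA 3' ends; after RT and PCR, each
read is the 3' region of a gene followed by any non-templated nucleotides
and the (reverse-complemented) anchor.  After anchor trimming and mapping
against the N-padded gene reference, this module classifies each read's 3'
end relative to the tRNA discriminator base (DB, position 0; the
non-templated CCA occupies +1..+3), profiles end positions per gene,
computes the fraction of CCA-complete molecules extended beyond the CCA,
analyses extension nucleotide composition, detects 16S rRNA 3' ends
carrying templated nucleotides of the immediately distal mt-tRNA-Leu(UUR)
(alternative processing rather than adenylation), resolves the special
mt-tRNA-Tyr 3'-end states (its DB is shared with mt-tRNA-Cys), and carries
the small calculus of the nested MPAT PCR amplicon (50 bp for an
unmodified end) and of circularisation RT-PCR junction clones.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Feature, MitoAnnotation
from .mapping import Alignment

__all__ = [
    "EndState",
    "ThreePrimeCall",
    "classify_three_prime_end",
    "EndProfile",
    "end_profile_relative_to_db",
    "percent_extended_beyond_cca",
    "extension_composition",
    "detect_templated_overlap",
    "TyrState",
    "classify_tyr_state",
    "amplicon_length",
    "parse_crtpcr_junction",
    "CrtPcrParseError",
    "compare_groups",
    "GeneEndModel",
    "gene_end_model",
]

#: Length of the nested MPAT PCR product for an unmodified, exactly
#: processed 3' end under the Fw2/ANTI-LIGN primer design rule.
BASE_AMPLICON_BP = 50


class EndState(str, enum.Enum):
    PRE_DB = "pre_DB"
    AT_DB = "at_DB"
    WITHIN_CCA = "within_CCA"
    MATURE_CCA = "mature_CCA"
    EXTENDED = "extended"


@dataclass(frozen=True)
class GeneEndModel:
    """3'-end reference frame of one tRNA or rRNA gene.

    ``db_index`` is the 0-based index, on the padded gene axis, of the tRNA
    discriminator base (for rRNA: of the last templated nucleotide, the
    DB-analog).  ``templated_length`` is the length of the annotated gene
    sequence (the non-pad prefix of the padded reference).
    """

    gene: str
    kind: str  # tRNA | rRNA
    templated_length: int
    db_index: int
    downstream_5prime: str | None = None  # 5' terminus of the distal feature


def gene_end_model(
    annotation: MitoAnnotation, gene: str, downstream_nt: int = 10
) -> GeneEndModel:
    """Build the 3'-end frame for a gene from the annotation.

    For every tRNA the annotated interval includes the discriminator base
    as its last position, so ``db_index = templated_length - 1``; the
    ``db_offset`` feature field records how the predominant processing site
    relates to the DB (mt-tRNA-Tyr, db_offset 1, is processed one base
    short of it) but does not move the DB itself.  For rRNAs the DB-analog
    is the annotated last nucleotide.
    """
    f = annotation[gene]
    if f.kind not in ("tRNA", "rRNA"):
        raise ValueError(f"{gene} is a {f.kind}; 3'-end analysis applies to tRNA/rRNA")
    t_len = len(annotation.transcript(gene))
    down = annotation.downstream_feature(gene)
    down_seq = (
        annotation.transcript(down.name)[:downstream_nt] if down is not None else None
    )
    return GeneEndModel(
        gene=gene,
        kind=f.kind,
        templated_length=t_len,
        db_index=t_len - 1,
        downstream_5prime=down_seq,
    )


@dataclass(frozen=True)
class ThreePrimeCall:
    """Classified 3' end of one read."""

    read_id: str
    gene: str
    kind: str  # tRNA | rRNA
    end_position_relative_to_db: int  # DB = 0; CCA occupies +1..+3
    state: EndState
    extension_length: int  # nt beyond the CCA (tRNA) / beyond the terminus (rRNA)
    extension_sequence: str
    post_db_sequence: str  # all read bases past the DB (CCA + extension for tRNA)
    templated: str = "n/a"  # rRNA only: yes | no | ambiguous | n/a
    censored: bool = False  # extension ran past the pad (length is a lower bound)


def classify_three_prime_end(
    alignment: Alignment,
    model: GeneEndModel,
    max_k_templated: int = 5,
) -> ThreePrimeCall:
    """Classify one padded-reference alignment into a 3'-end call.

    CCA is positional — the three pad positions +1..+3 after the DB — not
    a sequence search, so a templated 3' end that happens to read "CCA"
    cannot be mistaken for the non-templated addition.  For rRNA genes any
    overhang past the annotated terminus counts as extension, except that
    ends matching the downstream feature's 5' terminus (>= 4 nt, tested
    before composition) are flagged templated (alternative processing).
    """
    if alignment.target != model.gene:
        raise ValueError(
            f"alignment is on {alignment.target}, model is for {model.gene}"
        )
    last = alignment.end - 1  # padded-axis index of the last aligned base
    rel = last - model.db_index
    aligned_len = len(alignment.read_sequence) - alignment.overflow
    post_db = (
        alignment.read_sequence[aligned_len - rel : aligned_len] if rel > 0 else ""
    )
    censored = alignment.overflow > 0

    if model.kind == "rRNA":
        ext = post_db
        templated = "n/a"
        if rel > 0 and model.downstream_5prime is not None:
            templated, k = _templated_overlap(
                ext, model.downstream_5prime, max_k=max_k_templated
            )
            if templated == "yes":
                # alternative processing: the templated prefix is not an
                # extension; only what follows it is
                ext = ext[k:]
        state = (
            EndState.EXTENDED
            if ext
            else (EndState.AT_DB if rel >= 0 else EndState.PRE_DB)
        )
        return ThreePrimeCall(
            read_id=alignment.read_id,
            gene=model.gene,
            kind="rRNA",
            end_position_relative_to_db=rel,
            state=state,
            extension_length=len(ext),
            extension_sequence=ext,
            post_db_sequence=post_db,
            templated=templated,
            censored=censored,
        )

    # tRNA
    if rel < 0:
        state, ext = EndState.PRE_DB, ""
    elif rel == 0:
        state, ext = EndState.AT_DB, ""
    elif rel <= 2:
        state, ext = EndState.WITHIN_CCA, ""
    elif rel == 3:
        state, ext = EndState.MATURE_CCA, ""
    else:
        state, ext = EndState.EXTENDED, post_db[3:]
    return ThreePrimeCall(
        read_id=alignment.read_id,
        gene=model.gene,
        kind="tRNA",
        end_position_relative_to_db=rel,
        state=state,
        extension_length=len(ext),
        extension_sequence=ext,
        post_db_sequence=post_db,
        censored=censored,
    )


# ---------------------------------------------------------------------------
# per-gene profiles and summaries


@dataclass
class EndProfile:
    """Distribution of 3'-end calls for one gene, DB-relative."""

    gene: str
    counts: dict[int, int]  # end position (rel DB) -> read count
    normalized: dict[int, float] | None  # counts / count at DB (None if DB empty)
    percent_extended_beyond_cca: float | None
    extension_lengths: Counter
    n_calls: int
    db_count: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pos in sorted(self.counts):
            rows.append(
                {
                    "position_rel_DB": pos,
                    "count": self.counts[pos],
                    "normalized": (
                        self.normalized[pos] if self.normalized is not None else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)

    @property
    def modal_extension(self) -> int | None:
        if not self.extension_lengths:
            return None
        return self.extension_lengths.most_common(1)[0][0]


def end_profile_relative_to_db(calls: Sequence[ThreePrimeCall]) -> EndProfile:
    """Aggregate calls of one gene into a DB-relative end profile.

    Counts at each position are normalised to the discriminator-base count;
    when no read ends exactly at the DB the raw counts are kept and the
    normalised profile flagged undefined (None).
    """
    if not calls:
        raise ValueError("no 3'-end calls supplied")
    genes = {c.gene for c in calls}
    if len(genes) != 1:
        raise ValueError(f"calls span multiple genes: {sorted(genes)}")
    counts: Counter = Counter(c.end_position_relative_to_db for c in calls)
    db_count = counts.get(0, 0)
    normalized = (
        {pos: n / db_count for pos, n in counts.items()} if db_count > 0 else None
    )
    ext_lengths = Counter(
        c.extension_length for c in calls if c.state is EndState.EXTENDED
    )
    return EndProfile(
        gene=calls[0].gene,
        counts=dict(counts),
        normalized=normalized,
        percent_extended_beyond_cca=percent_extended_beyond_cca(calls, strict=False),
        extension_lengths=ext_lengths,
        n_calls=len(calls),
        db_count=db_count,
    )


def percent_extended_beyond_cca(
    calls: Sequence[ThreePrimeCall], strict: bool = True
) -> float | None:
    """100 x extended / (mature_CCA + extended).

    Only CCA-complete molecules enter the denominator; pre-CCA
    intermediates are reported separately in the end profile.  For rRNA
    genes (no CCA) the denominator is at-terminus + extended, and
    templated-overlap ends count as at-terminus (alternative processing,
    not extension).  Returns None (or raises when ``strict``) for an empty
    denominator.
    """
    mature = extended = 0
    for c in calls:
        if c.state is EndState.EXTENDED:
            extended += 1
        elif c.state is EndState.MATURE_CCA or (
            c.kind == "rRNA" and c.state is EndState.AT_DB
        ):
            mature += 1
    if mature + extended == 0:
        if strict:
            raise ValueError("no CCA-complete molecules among calls")
        return None
    return 100.0 * extended / (mature + extended)


def extension_composition(calls: Sequence[ThreePrimeCall]) -> pd.DataFrame:
    """Per-position nucleotide fractions over all extended calls.

    Returns a DataFrame indexed by extension position (1-based) with
    columns A/C/G/U fractions and n; the overall A fraction is available
    as ``df.attrs['overall_A_fraction']``.
    """
    ext = [c.extension_sequence for c in calls if c.state is EndState.EXTENDED]
    if not ext:
        raise ValueError("no extended calls supplied")
    max_len = max(len(e) for e in ext)
    rows = []
    total_a = total_n = 0
    for pos in range(max_len):
        bases = Counter(e[pos] for e in ext if len(e) > pos)
        n = sum(bases.values())
        total_a += bases.get("A", 0)
        total_n += n
        rows.append(
            {
                "position": pos + 1,
                "A": bases.get("A", 0) / n,
                "C": bases.get("C", 0) / n,
                "G": bases.get("G", 0) / n,
                "U": bases.get("T", 0) / n,
                "n": n,
            }
        )
    df = pd.DataFrame(rows).set_index("position")
    df.attrs["overall_A_fraction"] = total_a / total_n
    return df


def _templated_overlap(
    extension: str, downstream_5prime: str, max_k: int = 5, min_k: int = 4
) -> tuple[str, int]:
    if downstream_5prime is None or downstream_5prime == "":
        raise ValueError("downstream 5' sequence is required")
    k = 0
    for a, b in zip(extension, downstream_5prime[:max_k]):
        if a != b:
            break
        k += 1
    if k < min_k:
        return "no", k
    if set(downstream_5prime[:k]) == {"A"}:
        return "ambiguous", k
    return "yes", k


def detect_templated_overlap(
    extension: str, downstream_5prime: str, max_k: int = 5, min_k: int = 4
) -> str:
    """Does a 3' overhang match the 5' terminus of the downstream gene?

    ``yes`` when the first k (min_k <= k <= max_k) overhang nucleotides
    equal the downstream 5' terminus; ``ambiguous`` when they match but the
    downstream prefix is poly(A), so non-templated adenylation explains the
    data equally well; ``no`` otherwise.
    """
    return _templated_overlap(extension, downstream_5prime, max_k, min_k)[0]


# ---------------------------------------------------------------------------
# mt-tRNA-Tyr state machine


class TyrState(str, enum.Enum):
    """3'-end states of mt-tRNA-Tyr.

    The Tyr discriminator base (an A) is shared with the 5' end of
    mt-tRNA-Cys; processing predominantly yields mt-tRNA-Tyr(-1), which is
    repaired by adding the DB before CCA addition.
    """

    MINUS1 = "Tyr_minus1"  # ends one base short of the DB
    MINUS1_A = "Tyr_minus1A"  # DB (single A) added, no CCA yet
    MINUS1_ACCA = "Tyr_minus1ACCA"  # mature: DB + CCA
    MINUS1_AN = "Tyr_minus1_An"  # >= 2 A's past -1, no CCA
    BEYOND_CCA = "beyond_CCA_adenylated"  # DB + CCA + additional A's
    OTHER = "other_3prime"  # partial CCA or non-canonical tail


def classify_tyr_state(call: ThreePrimeCall, model: GeneEndModel) -> TyrState:
    """Deterministic, total classification of a mt-tRNA-Tyr 3'-end call.

    The call must come from the Tyr gene model (annotated interval includes
    the shared DB, so the processed -1 form ends at DB-relative -1).  The
    non-templated suffix past -1 is read off the call: position 0 is the DB
    'A' itself, +1..+3 the CCA, beyond that any adenylate tail.  Ends not
    matching one of the five canonical patterns (e.g. an incomplete CCA or
    a mixed-composition tail) fall in ``OTHER``.
    """
    if call.gene != model.gene:
        raise ValueError("call and gene model disagree")
    rel = call.end_position_relative_to_db
    if rel <= -1:
        return TyrState.MINUS1
    if rel == 0:
        return TyrState.MINUS1_A
    tail = call.post_db_sequence  # bases at +1.. (after the DB)
    if rel == 3 and tail == "CCA":
        return TyrState.MINUS1_ACCA
    if rel > 3 and tail.startswith("CCA") and set(tail[3:]) == {"A"}:
        return TyrState.BEYOND_CCA
    if rel >= 1 and set(tail) == {"A"}:
        return TyrState.MINUS1_AN
    return TyrState.OTHER


# ---------------------------------------------------------------------------
# amplicon calculus and cRT-PCR parsing


def amplicon_length(extension_length: int) -> int:
    """Nested MPAT PCR product size for a 3' end carrying
    ``extension_length`` non-templated nucleotides.

    The gene-specific Fw2 primer and the anchor-complement primer are
    designed so that an exactly processed, unmodified 3' end yields a 50 bp
    product; each non-templated nucleotide adds one bp.
    """
    if extension_length < 0:
        raise ValueError("extension_length must be >= 0")
    return BASE_AMPLICON_BP + int(extension_length)


class CrtPcrParseError(ValueError):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def parse_crtpcr_junction(
    clone: str, gene_sequence: str, min_anchor: int = 12
) -> tuple[int, int, int, str]:
    """Parse a circularisation RT-PCR clone spanning the 3'-5' junction.

    The clone reads [gene 3' terminus + tail][gene 5' terminus].  The
    maximal clone prefix matching a suffix of the gene is the 3' side, the
    maximal clone suffix matching a prefix of the gene is the 5' side, and
    the unmatched middle is the (poly(A)) tail.  When the tail's last bases
    coincide with the gene's first bases the split is ambiguous; the
    convention here maximises the templated 3' side first, then the 5'
    side.  Returns ``(three_prime_matched, five_prime_matched, tail_length,
    tail_sequence)``; both matched lengths must reach ``min_anchor``.
    """
    clone = clone.upper().replace("U", "T")
    gene = gene_sequence.upper().replace("U", "T")
    k = 0  # maximal clone prefix == gene suffix
    max_k = min(len(clone), len(gene))
    for i in range(max_k, 0, -1):
        if clone[:i] == gene[-i:]:
            k = i
            break
    if k < min_anchor:
        raise CrtPcrParseError("three_prime_anchor_too_short")
    rest = clone[k:]
    j = 0  # maximal clone suffix == gene prefix (within the remainder)
    for i in range(min(len(rest), len(gene)), 0, -1):
        if rest[-i:] == gene[:i]:
            j = i
            break
    if j < min_anchor:
        raise CrtPcrParseError("five_prime_anchor_too_short")
    tail = rest[: len(rest) - j]
    return k, j, len(tail), tail


# ---------------------------------------------------------------------------
# group comparison


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> dict:
    """Two-sample Student t-test (pooled variance; Welch by flag) on
    per-gene percent-extended values, with box-plot summary numbers."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate and np.allclose(a.mean(), b.mean()):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    summary = {
        name: {
            "median": float(np.median(x)),
            "q1": float(np.percentile(x, 25)),
            "q3": float(np.percentile(x, 75)),
            "n": int(len(x)),
        }
        for name, x in (("A", a), ("B", b))
    }
    return {
        "t": float(t),
        "p": float(p),
        "welch": welch,
        "degenerate_variance": bool(degenerate),
        "summary": summary,
    }
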