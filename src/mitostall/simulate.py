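"""Synthetic data generators: annotation, footprints, MPAT-Seq reads.

Three generators emulate the statistical structure the two analyses
assume, each emitting reads together with machine-readable ground truth so
that parameter recovery can be tested end to end:

* :func:`simulate_footprints` — ribosome-protected fragments under a
  codon-stalling model.  The A-site codon is sampled first (with
  probability proportional to its stall factor), then the read length and
  5'-end frame, and the 5' end is back-computed so the generative model is
  the exact inverse of the A-site assignment rule.
* :func:`simulate_mpat_reads` — anchor-ligated 3'-end reads under per-gene
  3'-state models (pre-CCA, mature CCA, oligoadenylate extensions), with
  genotype presets emulating a PDE12-proficient control (WT), the PDE12
  knock-out (KO, mt-tRNA-Lys shifted to 6-9 nt A-extensions and longer
  16S extensions) and mtPAP overexpression in either background.
* :func:`simulate_crtpcr_clones` — circularisation RT-PCR junction clones
  with sampled poly(A) tails (mt-mRNA tails average 45-55 nt).

:func:`synthetic_human_mito_annotation` builds a SYNTHETIC stand-in for
the human mitochondrial genome annotation: the real gene complement
(13 CDS, 22 tRNA, 2 rRNA), gene order, strands and approximate lengths,
the ATP8/ATP6 and ND4L/ND4 CDS overlaps, the mt-tRNA-Tyr/Cys shared
discriminator base, seven polyadenylation-completed stop codons, and a
codon composition constructed to the published codon-usage statistics of
the human mtDNA ORFs (11 Lys codons in ND4, none in ND4L; Lys 2.5% and
Ser(AGY) 1.4% of all coding triplets).  The nucleotide sequence itself is
simulated, not the rCRS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import (
    Feature,
    MitoAnnotation,
    MITO_STOPS,
    build_overlap_exclusion_mask,
    extract_orf_codons,
)
from .mapping import reverse_complement

__all__ = [
    "LIGN_ANCHOR",
    "READ_ADAPTER",
    "synthetic_human_mito_annotation",
    "toy_annotation",
    "StallModel",
    "simulate_footprints",
    "ExtensionModel",
    "GeneEndSpec",
    "extension_model_for_genotype",
    "simulate_mpat_reads",
    "simulate_crtpcr_clones",
    "write_fastq",
    "read_fastq",
    "write_truth_jsonl",
    "GENOTYPES",
]

#: The 3'-ligated anchor oligo (5'->3'); its 3' Spacer C3 analog is the
#: guarantee of one anchor per read (no concatemers).
LIGN_ANCHOR = "TGGAATTCTCGGGTGCCAAG"
#: What appears at the 3' end of a sequencing read: the anchor complement.
READ_ADAPTER = reverse_complement(LIGN_ANCHOR)

GENOTYPES = ("WT", "KO", "WT+mtPAP", "KO+mtPAP")

_BASES = np.array(list("ACGT"))
# heavy-strand-like base composition for simulated sequence
_BASE_P = np.array([0.31, 0.31, 0.13, 0.25])


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_BASE_P))


# ---------------------------------------------------------------------------
# synthetic human-mtDNA-like annotation

_LYS = ("AAA", "AAG")
_AGY = ("AGT", "AGC")


def _codon_pool() -> tuple[list[str], np.ndarray]:
    """Codons available for ORF body sampling: everything except stops,
    Lys and Ser(AGY) codons (those are placed in exact numbers)."""
    pool, w = [], []
    pb = dict(zip("ACGT", _BASE_P))
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                codon = a + b + c
                if codon in MITO_STOPS or codon in _LYS or codon in _AGY:
                    continue
                pool.append(codon)
                w.append(pb[a] * pb[b] * pb[c])
    w = np.array(w)
    return pool, w / w.sum()


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Integer allocation of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base.tolist()


def _make_orf(
    rng: np.random.Generator,
    n_codons: int,
    n_lys: int,
    n_agy: int,
    partial: str = "",
    forced: Mapping[int, str] | None = None,
) -> str:
    """An ORF of ``n_codons`` complete codons (stop included unless
    ``partial`` is set, in which case the templated sequence ends with the
    given partial stop) carrying exactly the requested numbers of Lys and
    Ser(AGY) codons."""
    pool, pw = _codon_pool()
    codons = ["ATG"] + list(rng.choice(pool, size=n_codons - 1, p=pw))
    forced = dict(forced or {})
    if not partial:
        forced.setdefault(n_codons - 1, "TAA")
    for idx, codon in forced.items():
        codons[idx] = codon
    free = [i for i in range(1, n_codons - (0 if partial else 1)) if i not in forced]
    chosen = rng.choice(len(free), size=n_lys + n_agy, replace=False)
    for j in chosen[:n_lys]:
        codons[free[j]] = _LYS[0] if rng.random() < 0.75 else _LYS[1]
    for j in chosen[n_lys:]:
        codons[free[j]] = _AGY[0] if rng.random() < 0.5 else _AGY[1]
    return "".join(codons) + partial


def _orf_frame_codons(seq: str, offset: int) -> list[str]:
    return [seq[i : i + 3] for i in range(offset, len(seq) - 2, 3)]


def _make_atp6_head(rng: np.random.Generator) -> str:
    """First 46 nt of ATP6 == last 46 nt of ATP8 (the CDS overlap).

    ATP6 frame: ATG + 14 codons + the first base ('A') of codon 15.
    ATP8 frame (shifted by one): 15 codons ending in its TAA stop; the
    search rejects draws that put a stop, Lys or Ser(AGY) codon in either
    frame so the genome-wide codon counts stay exact.
    """
    pool, pw = _codon_pool()
    bad = set(MITO_STOPS) | set(_LYS) | set(_AGY)
    while True:
        c = list(rng.choice(pool, size=13, p=pw))
        head = "ATG" + "".join(c) + "CTA" + "A"
        assert len(head) == 46
        atp8_frame = _orf_frame_codons(head, 1)  # 15 codons
        if atp8_frame[-1] != "TAA":
            continue
        if any(x in bad for x in atp8_frame[:-1]):
            continue
        return head


# (complete-codon count, Lys count fixed?, partial stop) per ORF; partial
# stops are completed by polyadenylation (paper set: ND1, ND2, ND3, ND4,
# CYTB, COIII, ATP6)
_ORF_PLAN: list[tuple[str, int, str]] = [
    ("ND1", 318, "TA"),
    ("ND2", 347, "TA"),
    ("COI", 513, ""),
    ("COII", 227, ""),
    ("ATP8", 69, ""),
    ("ATP6", 226, "TA"),
    ("COIII", 261, "TA"),
    ("ND3", 115, "TA"),
    ("ND4L", 99, ""),
    ("ND4", 459, "TA"),
    ("ND5", 603, ""),
    ("ND6", 174, ""),
    ("CYTB", 380, "TA"),
]

_TRNA_ORDER: list[tuple[str, str]] = [
    # (name, strand) in genome order interleaved with rRNA/CDS below
    ("TF", "+"), ("TV", "+"), ("TL1", "+"), ("TI", "+"), ("TQ", "-"),
    ("TM", "+"), ("TW", "+"), ("TA", "-"), ("TN", "-"), ("TC", "-"),
    ("TY", "-"), ("TS1", "-"), ("TD", "+"), ("TK", "+"), ("TG", "+"),
    ("TR", "+"), ("TH", "+"), ("TS2", "+"), ("TL2", "+"), ("TE", "-"),
    ("TT", "+"), ("TP", "-"),
]

_LYS_TARGET_PERCENT = 2.5
_AGY_TARGET_PERCENT = 1.4


@lru_cache(maxsize=4)
def synthetic_human_mito_annotation(seed: int = 101) -> MitoAnnotation:
    """SYNTHETIC human-mtDNA-like annotation (see module docstring).

    Deterministic for a given seed; the default is the package's reference
    emulation used by the examples and the test-suite.
    """
    rng = np.random.default_rng(seed)
    total_codons = sum(n for _, n, _ in _ORF_PLAN)
    lys_total = round(_LYS_TARGET_PERCENT / 100 * total_codons)
    agy_total = round(_AGY_TARGET_PERCENT / 100 * total_codons)

    # Lys allocation: ND4 carries exactly 11, ND4L none, the rest spread
    # proportionally to ORF length
    fixed_lys = {"ND4": 11, "ND4L": 0}
    others = [(n, c) for n, c, _ in _ORF_PLAN if n not in fixed_lys]
    spread = _largest_remainder(
        lys_total - sum(fixed_lys.values()), [c for _, c in others]
    )
    lys_alloc = dict(fixed_lys, **{n: k for (n, _), k in zip(others, spread)})
    agy_alloc = dict(
        zip(
            [n for n, _, _ in _ORF_PLAN],
            _largest_remainder(agy_total, [c for _, c, _ in _ORF_PLAN]),
        )
    )

    # ORF sequences, honouring the two CDS-CDS overlap constraints
    orf_seq: dict[str, str] = {}
    for name, n_codons, partial in _ORF_PLAN:
        forced: dict[int, str] = {}
        if name == "ND4L":
            # last 7 nt must read ATGCTAA = the first 7 nt of ND4
            forced = {96: "CGA", 97: "TGC", 98: "TAA"}
        if name == "ND4":
            forced = {1: "CTA", 2: "ACA"}
        if name == "ATP6":
            head = _make_atp6_head(rng)
            forced = {i: head[3 * i : 3 * i + 3] for i in range(1, 15)}
            forced[15] = "ACC"  # keeps head[45] == 'A'
        orf_seq[name] = _make_orf(
            rng, n_codons, lys_alloc[name], agy_alloc[name], partial, forced
        )
    assert orf_seq["ND4L"][-7:] == orf_seq["ND4"][:7]
    atp6_head = orf_seq["ATP6"][:46]

    # ATP8 tail must equal the ATP6 head; rebuild ATP8 with its last 16
    # codons forced from the overlap (codon 53 third base = head[0])
    tail = "CC" + atp6_head  # codon53 = 'CC'+head[0]='CCA'
    forced8 = {53 + i: tail[3 * i : 3 * i + 3] for i in range(16)}
    orf_seq["ATP8"] = _make_orf(rng, 69, lys_alloc["ATP8"], agy_alloc["ATP8"], "", forced8)
    assert orf_seq["ATP8"][-46:] == atp6_head
    assert orf_seq["ATP8"][-3:] == "TAA"

    # non-coding genes
    trna_len = {name: int(rng.integers(64, 73)) for name, _ in _TRNA_ORDER}
    trna_seq = {name: _rand_seq(rng, trna_len[name]) for name, _ in _TRNA_ORDER}
    # Tyr ends in its discriminator base (A), shared with the Cys 5' end
    trna_seq["TY"] = trna_seq["TY"][:-1] + "A"
    trna_seq["TC"] = "A" + trna_seq["TC"][1:]
    # Leu(UUR) 5' terminus is the templated overlap carried by ~50% of 16S
    # 3' ends; keep it distinctive (not poly-A)
    trna_seq["TL1"] = "GTTAAG" + trna_seq["TL1"][6:]
    rrna_seq = {"RNR1": _rand_seq(rng, 954), "RNR2": _rand_seq(rng, 1559)}

    # genome assembly, following the human gene order; offsets are the gap
    # to the previous feature (negative = overlap)
    layout: list[tuple[str, str, str, int]] = [
        # (name, kind, strand, gap_to_previous)
        ("TF", "tRNA", "+", 0),
        ("RNR1", "rRNA", "+", 0),
        ("TV", "tRNA", "+", 0),
        ("RNR2", "rRNA", "+", 0),
        ("TL1", "tRNA", "+", 0),
        ("ND1", "CDS", "+", 2),
        ("TI", "tRNA", "+", 0),
        ("TQ", "tRNA", "-", 0),
        ("TM", "tRNA", "+", 1),
        ("ND2", "CDS", "+", 0),
        ("TW", "tRNA", "+", 0),
        ("TA", "tRNA", "-", 1),
        ("TN", "tRNA", "-", 1),
        ("TC", "tRNA", "-", 30),
        ("TY", "tRNA", "-", -1),  # shares the discriminator base with TC
        ("COI", "CDS", "+", 12),
        ("TS1", "tRNA", "-", 0),
        ("TD", "tRNA", "+", 4),
        ("COII", "CDS", "+", 2),
        ("TK", "tRNA", "+", 0),
        ("ATP8", "CDS", "+", 1),
        ("ATP6", "CDS", "+", -46),
        ("COIII", "CDS", "+", 0),
        ("TG", "tRNA", "+", 0),
        ("ND3", "CDS", "+", 0),
        ("TR", "tRNA", "+", 0),
        ("ND4L", "CDS", "+", 0),
        ("ND4", "CDS", "+", -7),
        ("TH", "tRNA", "+", 0),
        ("TS2", "tRNA", "+", 0),
        ("TL2", "tRNA", "+", 0),
        ("ND5", "CDS", "+", 0),
        ("ND6", "CDS", "-", 0),
        ("TE", "tRNA", "-", 0),
        ("CYTB", "CDS", "+", 2),
        ("TT", "tRNA", "+", 0),
        ("TP", "tRNA", "-", 0),
    ]
    dloop = _rand_seq(rng, 1000)
    genome: list[str | None] = list(dloop)
    features: list[Feature] = []
    cursor = len(dloop)  # 0-based position where the next feature starts

    def transcript_of(name: str, kind: str) -> str:
        if kind == "CDS":
            return orf_seq[name]
        if kind == "rRNA":
            return rrna_seq[name]
        return trna_seq[name]

    for name, kind, strand, gap in layout:
        start0 = cursor + gap
        t = transcript_of(name, kind)
        plus = t if strand == "+" else reverse_complement(t)
        end0 = start0 + len(t)
        while len(genome) < end0:
            genome.append(None)
        for i, base in enumerate(plus):
            existing = genome[start0 + i] if start0 + i < len(genome) else None
            if existing is not None and existing != base:
                raise AssertionError(
                    f"overlap inconsistency at {start0 + i} placing {name}"
                )
            genome[start0 + i] = base
        features.append(
            Feature(
                name=name,
                kind=kind,
                start=start0 + 1,
                end=end0,
                strand=strand,
                db_offset=1 if name == "TY" else 0,
                completion_by_polyadenylation=(
                    kind == "CDS" and len(t) % 3 != 0
                ),
            )
        )
        cursor = end0
    # trailing spacer back to the origin; intergenic gaps get random sequence
    genome.extend(_rand_seq(rng, 60))
    gap_fill = iter(_rand_seq(rng, sum(b is None for b in genome)))
    filled = [b if b is not None else next(gap_fill) for b in genome]
    return MitoAnnotation(genome_sequence="".join(filled), features=features)


def toy_annotation(
    cds: Mapping[str, str] | None = None,
    trna: Mapping[str, str] | None = None,
    rrna: Mapping[str, str] | None = None,
    spacer: int = 20,
    seed: int = 7,
) -> MitoAnnotation:
    """Small single-strand annotation from explicit transcript sequences,
    laid head to tail with random spacers (unit-test construction kit)."""
    rng = np.random.default_rng(seed)
    parts: list[str] = [_rand_seq(rng, spacer)]
    features: list[Feature] = []
    cursor = spacer
    for kind, genes in (("CDS", cds), ("tRNA", trna), ("rRNA", rrna)):
        for name, seq in (genes or {}).items():
            seq = seq.upper().replace("U", "T")
            features.append(
                Feature(
                    name=name,
                    kind=kind,
                    start=cursor + 1,
                    end=cursor + len(seq),
                    strand="+",
                    completion_by_polyadenylation=(kind == "CDS" and len(seq) % 3 != 0),
                )
            )
            parts.append(seq)
            cursor += len(seq)
            parts.append(_rand_seq(rng, spacer))
            cursor += spacer
    return MitoAnnotation(genome_sequence="".join(parts), features=features)


# ---------------------------------------------------------------------------
# footprint simulation


def _default_length_probs() -> dict[int, float]:
    # 80% of the mass uniform on 31-35 nt, 20% on 25-30 nt, so the length
    # filter is exercised
    d = {n: 0.8 / 5 for n in range(31, 36)}
    d.update({n: 0.2 / 6 for n in range(25, 31)})
    return d


@dataclass
class StallModel:
    """Generative codon-stalling model for ribosome footprints.

    ``stall_factors`` maps codon -> relative A-site dwell time (1.0 =
    baseline); ``coverage`` is the mean number of footprints per eligible
    codon.  Frame probabilities refer to the codon position of the 5' end
    (1/2/3); frame-2 reads are generated so the downstream frame filter is
    exercised, but carry no A-site.
    """

    stall_factors: dict[str, float] = field(default_factory=dict)
    coverage: float = 50.0
    length_probs: dict[int, float] = field(default_factory=_default_length_probs)
    frame_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.10, 3: 0.45}
    )
    mismatch_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for name, dist in (("length", self.length_probs), ("frame", self.frame_probs)):
            tot = sum(dist.values())
            if not np.isclose(tot, 1.0):
                raise ValueError(f"{name} distribution sums to {tot}, not 1")
        if any(v <= 0 for v in self.stall_factors.values()):
            raise ValueError("stall factors must be positive")

    def factor(self, codon: str) -> float:
        return self.stall_factors.get(codon, 1.0)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def expected_occupancy(
    annotation: MitoAnnotation, model: StallModel
) -> dict[str, float]:
    """Exact expected occupancy per codon species under the stalling model,
    computed over the unmasked codons the analysis pools (the analytic
    truth against which recovery is checked)."""
    mask = build_overlap_exclusion_mask(annotation)
    num: dict[str, float] = {}
    den: dict[str, int] = {}
    for cds_name in annotation.cds_names:
        codons, _ = extract_orf_codons(annotation, cds_name)
        unmasked = mask.unmasked_indices(cds_name)
        if len(unmasked) == 0:
            continue
        sf = np.array([model.factor(codons[i]) for i in unmasked])
        scaled = sf / sf.mean()
        for i, s in zip(unmasked, scaled):
            sp = codons[i]
            num[sp] = num.get(sp, 0.0) + s
            den[sp] = den.get(sp, 0) + 1
    return {sp: num[sp] / den[sp] for sp in num}


def simulate_footprints(
    annotation: MitoAnnotation, model: StallModel
) -> tuple[list[tuple[str, str]], list[dict], dict]:
    """Simulate ribosome footprints; returns (reads, truth records, summary).

    Reads are ``(read_id, sequence)``; use :func:`write_fastq` to emit
    FASTQ.  Each truth record names the source CDS, the true A-site codon
    index and species, the read length and the 5'-end frame.  The summary
    carries the analytic expected occupancy per species.
    """
    rng = np.random.default_rng(model.seed)
    max_len = max(model.length_probs)
    sites: list[tuple[str, int, str]] = []  # (cds, codon_index, codon)
    weights: list[float] = []
    for cds_name in annotation.cds_names:
        t = annotation.transcript(cds_name)
        codons, _ = extract_orf_codons(annotation, cds_name)
        # eligibility: every frame's 5' end and 3' end must fit the CDS
        # every unmasked codon must be reachable: the latest 5' end is at
        # 3c-14 (frame 2) and the read must fit, so 3c <= L - max_len + 14;
        # the stricter bound below also keeps frame-2 reads inside the CDS
        c_lo = 6
        c_hi = (len(t) - 21) // 3
        for c in range(c_lo, c_hi + 1):
            sites.append((cds_name, c, codons[c]))
            weights.append(model.factor(codons[c]))
    if not sites:
        raise ValueError("no codon is eligible for footprint placement")
    w = np.asarray(weights)
    n_reads = int(round(model.coverage * len(sites)))
    idx = rng.choice(len(sites), size=n_reads, p=w / w.sum())
    lengths = rng.choice(
        list(model.length_probs), size=n_reads, p=list(model.length_probs.values())
    )
    frames = rng.choice(
        list(model.frame_probs), size=n_reads, p=list(model.frame_probs.values())
    )
    transcripts = {name: annotation.transcript(name) for name in annotation.cds_names}
    reads: list[tuple[str, str]] = []
    truths: list[dict] = []
    offset_by_frame = {1: -15, 2: -14, 3: -16}
    for i in range(n_reads):
        cds_name, c, codon = sites[idx[i]]
        L = int(lengths[i])
        frame = int(frames[i])
        p = 3 * c + offset_by_frame[frame]
        seq = transcripts[cds_name][p : p + L]
        seq = _mutate(rng, seq, model.mismatch_rate)
        rid = f"fp{i:07d}"
        reads.append((rid, seq))
        truths.append(
            {
                "read": rid,
                "cds": cds_name,
                "codon_index": c,
                "codon": codon,
                "length": L,
                "frame": frame,
            }
        )
    summary = {
        "n_reads": n_reads,
        "n_sites": len(sites),
        "expected_occupancy": expected_occupancy(annotation, model),
    }
    return reads, truths, summary


# ---------------------------------------------------------------------------
# MPAT-Seq simulation


@dataclass
class GeneEndSpec:
    """Per-gene 3'-state distribution.

    ``pre_cca`` + ``extended`` + mature = 1; ``length_probs`` is the
    extension-length distribution conditional on being extended.  For
    rRNAs ``pre_cca`` is reinterpreted as ending short of the annotated
    terminus.
    """

    pre_cca: float
    extended: float
    length_probs: dict[int, float]

    def __post_init__(self) -> None:
        if not 0 <= self.pre_cca + self.extended <= 1:
            raise ValueError("state probabilities must sum to <= 1")
        if self.length_probs and not np.isclose(sum(self.length_probs.values()), 1.0):
            raise ValueError("extension length distribution must sum to 1")

    @property
    def mature(self) -> float:
        return 1.0 - self.pre_cca - self.extended


@dataclass
class ExtensionModel:
    """Per-gene 3'-end models plus global composition parameters."""

    genes: dict[str, GeneEndSpec]
    a_fraction: float = 0.95  # P(A) per extension position, rest spread C/G/U
    templated_overlap_prob: float = 0.5  # 16S alternative-processing fraction
    templated_k_probs: dict[int, float] = field(
        default_factory=lambda: {4: 0.5, 5: 0.5}
    )
    reads_per_gene: int = 2000
    body_length: int = 25  # templated gene nt carried by each read
    seed: int = 0
    max_ext: int = 30

    def __post_init__(self) -> None:
        for g, spec in self.genes.items():
            if spec.length_probs and max(spec.length_probs) > self.max_ext:
                raise ValueError(f"{g}: extension longer than the reference pad")


def _uniform(lo: int, hi: int) -> dict[int, float]:
    n = hi - lo + 1
    return {k: 1.0 / n for k in range(lo, hi + 1)}


def extension_model_for_genotype(
    annotation: MitoAnnotation,
    genotype: str,
    seed: int = 0,
    reads_per_gene: int = 2000,
) -> ExtensionModel:
    """Genotype presets for the four experimental conditions.

    The quantitative anchors follow the characteristic phenotypes of
    PDE12-deficient cells: in the KO, mt-tRNA-Lys carries 6-9 nt all-A
    extensions on a large fraction of molecules and 16S extensions
    lengthen, while control 16S extensions are 4-5 nt; mtPAP
    overexpression raises the extended fraction genome-wide, most
    strongly on the KO background.  Per-tRNA baseline fractions are free
    parameters chosen once (deterministic spread in 0.05-0.15), since
    per-tRNA extension levels are typically observed only as gel
    profiles.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; choose from {GENOTYPES}")
    trnas = [f.name for f in annotation.features_of_kind("tRNA")]
    genes: dict[str, GeneEndSpec] = {}
    short = {1: 0.5, 2: 0.3, 3: 0.2}
    mid = _uniform(2, 6)
    for i, g in enumerate(sorted(trnas)):
        wt_frac = 0.05 + 0.10 * i / max(len(trnas) - 1, 1)
        if genotype == "WT":
            frac, lengths = wt_frac, short
        elif genotype == "WT+mtPAP":
            frac, lengths = (0.50, mid) if g == "TK" else (wt_frac + 0.20, mid)
        elif genotype == "KO":
            if g == "TK":
                frac, lengths = 0.80, _uniform(6, 9)
            elif g in ("TS2", "TH"):
                frac, lengths = 0.50, mid
            else:
                frac, lengths = wt_frac + 0.20, mid
        else:  # KO+mtPAP
            if g == "TK":
                # near-complete adenylation; the pre-CCA pool shrinks too
                genes[g] = GeneEndSpec(
                    pre_cca=0.03, extended=0.95, length_probs=_uniform(6, 12)
                )
                continue
            elif g in ("TS2", "TH"):
                frac, lengths = 0.65, _uniform(4, 10)
            else:
                frac, lengths = wt_frac + 0.35, _uniform(4, 10)
        genes[g] = GeneEndSpec(pre_cca=0.10, extended=frac, length_probs=lengths)
    # rRNAs: 12S is insensitive to the genotype; 16S extensions lengthen in
    # the KO and further under mtPAP overexpression on that background
    if genotype in ("WT", "WT+mtPAP"):
        genes["RNR2"] = GeneEndSpec(0.0, 0.85, {3: 0.05, 4: 0.45, 5: 0.45, 6: 0.05})
    elif genotype == "KO":
        genes["RNR2"] = GeneEndSpec(0.0, 0.90, _uniform(6, 15))
    else:
        genes["RNR2"] = GeneEndSpec(0.0, 0.95, _uniform(10, 20))
    genes["RNR1"] = GeneEndSpec(0.0, 0.30, _uniform(1, 4))
    return ExtensionModel(
        genes=genes, seed=seed, reads_per_gene=reads_per_gene
    )


def _sample_extension(rng: np.random.Generator, k: int, a_fraction: float) -> str:
    other = (1 - a_fraction) / 3
    return "".join(
        rng.choice(_BASES, size=k, p=[a_fraction, other, other, other])
    )


def simulate_mpat_reads(
    annotation: MitoAnnotation,
    model: ExtensionModel | None = None,
    genotype: str = "WT",
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], list[dict], dict]:
    """Simulate MPAT-Seq reads; returns (reads, truth records, summary).

    Each read is the last ``body_length`` nt of the mature gene sequence
    (cut at the state-dependent 3' end), any non-templated nucleotides
    (CCA and/or extension), then the reverse-complemented anchor.  For the
    mt-tRNA-Tyr gene the discriminator base itself is non-templated on the
    processed molecule, so its pre-CCA state ends at -1 and all other
    states begin with the repaired DB adenosine.
    """
    if model is None:
        model = extension_model_for_genotype(
            annotation, genotype, seed=seed if seed is not None else 0
        )
    rng = np.random.default_rng(model.seed if seed is None else seed)
    reads: list[tuple[str, str]] = []
    truths: list[dict] = []
    per_gene_truth: dict[str, dict] = {}
    counter = 0
    for gene, spec in model.genes.items():
        f = annotation[gene]
        t = annotation.transcript(gene)
        processed = t[: len(t) - f.db_offset]  # Tyr: ends one short of the DB
        db_repair = "A" * f.db_offset
        is_rrna = f.kind == "rRNA"
        down = annotation.downstream_feature(gene)
        down5 = annotation.transcript(down.name) if down is not None else ""
        lengths = list(spec.length_probs) or [0]
        length_p = list(spec.length_probs.values()) or [1.0]
        n = model.reads_per_gene
        u = rng.random(n)
        ext_k = rng.choice(lengths, size=n, p=length_p)
        n_ext = n_mat = n_pre = 0
        for i in range(n):
            if u[i] < spec.pre_cca:
                state, k = "pre_CCA", 0
                n_pre += 1
            elif u[i] < spec.pre_cca + spec.extended:
                state, k = "extended", int(ext_k[i])
                n_ext += 1
            else:
                state, k = "mature", 0
                n_mat += 1
            templated = False
            if is_rrna:
                tpl = ""
                if (
                    gene == "RNR2"
                    and state != "pre_CCA"
                    and rng.random() < model.templated_overlap_prob
                ):
                    kk = int(
                        rng.choice(
                            list(model.templated_k_probs),
                            p=list(model.templated_k_probs.values()),
                        )
                    )
                    tpl = down5[:kk]
                    templated = True
                ext = _sample_extension(rng, k, model.a_fraction) if state == "extended" else ""
                if state == "pre_CCA":  # short of the terminus by 1 nt
                    body = processed[:-1][-model.body_length :]
                else:
                    body = processed[-model.body_length :]
                insert = body + tpl + ext
            else:
                body_src = processed
                if state == "pre_CCA":
                    nontemplated = ""
                else:
                    ext = (
                        _sample_extension(rng, k, model.a_fraction)
                        if state == "extended"
                        else ""
                    )
                    nontemplated = db_repair + "CCA" + ext
                body = body_src[-model.body_length :]
                insert = body + nontemplated
            rid = f"mp{counter:07d}"
            counter += 1
            reads.append((rid, insert + READ_ADAPTER))
            truths.append(
                {
                    "read": rid,
                    "gene": gene,
                    "state": state,
                    "extension_length": k if state == "extended" else 0,
                    "templated": templated,
                }
            )
        per_gene_truth[gene] = {
            "pre_cca": n_pre,
            "mature": n_mat,
            "extended": n_ext,
            # generating fraction among CCA-complete molecules, the quantity
            # percent_extended_beyond_cca estimates
            "true_extended_fraction": spec.extended / (spec.extended + spec.mature),
            "empirical_extended_fraction": n_ext / max(n_ext + n_mat, 1),
        }
    summary = {"genotype": genotype, "per_gene": per_gene_truth, "n_reads": counter}
    return reads, truths, summary


# ---------------------------------------------------------------------------
# cRT-PCR clones


def simulate_crtpcr_clones(
    annotation: MitoAnnotation,
    gene: str,
    n: int,
    tail_mean: float = 50.0,
    tail_sd: float = 8.0,
    flank: int = 20,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Circularisation RT-PCR junction clones for one gene.

    Each clone reads [gene 3' terminus (``flank`` nt) + poly(A) tail]
    [gene 5' terminus (``flank`` nt)]; tail lengths are normal(tail_mean,
    tail_sd) rounded and clipped at zero (mt-mRNA tails average 45-55 nt).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    t = annotation.transcript(gene)
    rng = np.random.default_rng(seed)
    tails = np.clip(np.rint(rng.normal(tail_mean, tail_sd, size=n)), 0, None).astype(int)
    clones: list[tuple[str, str]] = []
    truths: list[dict] = []
    for i, k in enumerate(tails):
        cid = f"clone{i:05d}"
        clones.append((cid, t[-flank:] + "A" * int(k) + t[:flank]))
        truths.append({"clone": cid, "gene": gene, "tail_length": int(k)})
    return clones, truths


# ---------------------------------------------------------------------------
# FASTQ / truth I/O


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTQ with constant 'I' qualities
    (neither analysis uses base qualities)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_truth_jsonl(truths: Iterable[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in truths:
            fh.write(json.dumps(rec) + "\n")
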