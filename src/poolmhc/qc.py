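"""Read cleaning and allele (variant) calling for pooled amplicon data.

The cascade mirrors established practice for validating alleles from
pooled-barcode 454 amplicon runs:

1. drop reads shorter than 180 bp (incomplete amplicons),
2. assign each read to a locus by pairwise alignment against the two
   reference amplicons, dropping reads below 70% identity to both,
3. collapse reads to variants at 100% sequence identity,
4. remove variants seen only once within a barcode (presumptive errors),
5. drop reads with fewer than 80% of bases at Phred >= 20 (and variants
   left with no backing reads),
6. remove variants whose alignment to the reference carries a net indel
   that is not a multiple of three (frameshifts; homopolymer artefacts).

Thresholds follow a strict-less-than reading ("under 180 bp", "under 80%
quality"): boundary values are retained. Reads are checked in both
orientations and normalized to the reference strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import reverse_complement

__all__ = [
    "Read",
    "AlignmentResult",
    "Variant",
    "FilterReport",
    "QCParams",
    "filter_length",
    "assign_locus",
    "dereplicate",
    "drop_singletons",
    "filter_quality",
    "filter_frameshift",
    "run_qc_pipeline",
]


@dataclass
class Read:
    """One amplicon read: id, barcode, bases, and per-base Phred scores."""

    id: str
    barcode: str
    bases: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(f"read {self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentResult:
    """Best-reference alignment of a read: locus call and identity."""

    locus: str | None
    identity: float
    net_indel_length: int
    aligned_span: tuple[int, int]
    strand: str = "+"
    oriented_bases: str = ""


@dataclass
class Variant:
    """A distinct retained sequence (candidate allele) with per-barcode counts."""

    sequence: str
    locus: str
    counts: dict[str, int] = field(default_factory=dict)
    read_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class QCParams:
    min_length: int = 180
    min_identity: float = 0.70
    min_fraction_hq: float = 0.80
    hq_phred: int = 20
    singleton_scope: str = "per-barcode"  # or "global"
    quality_first: bool = False
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0


def _make_aligner(params: QCParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_score
    aligner.extend_gap_score = params.gap_score
    # free end gaps: whole-read similarity, no penalty for terminal overhang
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _alignment_stats(alignment) -> tuple[float, int, tuple[int, int]]:
    """(identity, net internal indel length, reference span) of one alignment.

    Identity counts matches over all alignment columns, end-gap columns
    included. The net indel is insertions minus deletions strictly inside
    the aligned region (terminal overhangs are truncation, not indels).
    """
    counts = alignment.counts()
    columns = alignment.length
    identity = counts.identities / columns if columns else 0.0
    tblocks, qblocks = alignment.aligned
    if len(tblocks) == 0:
        return identity, 0, (0, 0)
    insertions = deletions = 0
    for i in range(1, len(tblocks)):
        deletions += tblocks[i][0] - tblocks[i - 1][1]
        insertions += qblocks[i][0] - qblocks[i - 1][1]
    span = (int(tblocks[0][0]), int(tblocks[-1][1]))
    return identity, insertions - deletions, span


def filter_length(reads: list[Read], min_length: int = 180) -> list[Read]:
    """Retain reads of length >= min_length (drop 'under 180 bp')."""
    return [r for r in reads if len(r) >= min_length]


def assign_locus(
    read: Read | str,
    references: dict[str, str],
    min_identity: float = 0.70,
    params: QCParams | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Align a read to every reference (both strands), call the best locus.

    The best-scoring reference/strand wins when its identity (matches over
    alignment columns) reaches ``min_identity``; otherwise locus is None.
    """
    bases = read.bases if isinstance(read, Read) else read
    if not bases:
        raise ValueError("empty read")
    if aligner is None:
        aligner = _make_aligner(params or QCParams(min_identity=min_identity))
    best = None
    for locus, ref in references.items():
        for strand, seq in (("+", bases), ("-", reverse_complement(bases))):
            aln = aligner.align(ref, seq)[0]
            identity, net_indel, span = _alignment_stats(aln)
            cand = (identity, locus, strand, net_indel, span, seq)
            if best is None or cand[0] > best[0]:
                best = cand
    identity, locus, strand, net_indel, span, seq = best
    if identity < min_identity:
        return AlignmentResult(None, identity, net_indel, span, strand, seq)
    return AlignmentResult(locus, identity, net_indel, span, strand, seq)


def dereplicate(reads_by_locus: list[tuple[Read, str, str]]) -> list[Variant]:
    """Collapse locus-assigned reads to variants at 100% identity.

    Input triples are (read, locus, oriented_sequence). Output is ordered
    by descending total count, ties broken lexicographically by sequence.
    """
    table: dict[tuple[str, str], Variant] = {}
    for read, locus, seq in reads_by_locus:
        key = (locus, seq)
        v = table.get(key)
        if v is None:
            v = table[key] = Variant(sequence=seq, locus=locus)
        v.counts[read.barcode] = v.counts.get(read.barcode, 0) + 1
        v.read_ids.setdefault(read.barcode, []).append(read.id)
    return sorted(table.values(), key=lambda v: (-v.total_count, v.sequence))


def drop_singletons(variants: list[Variant], scope: str = "per-barcode") -> list[Variant]:
    """Remove count-1 occurrences ('occurred only once in each barcode').

    Per-barcode scope deletes a variant's entry in every barcode where its
    count is 1; the variant survives wherever it has count >= 2. Global
    scope removes only variants whose total count is 1.
    """
    out = []
    for v in variants:
        if scope == "global":
            if v.total_count > 1:
                out.append(v)
            continue
        if scope != "per-barcode":
            raise ValueError(f"unknown scope {scope!r}")
        counts = {b: c for b, c in v.counts.items() if c > 1}
        if counts:
            out.append(
                Variant(
                    v.sequence,
                    v.locus,
                    counts,
                    {b: ids for b, ids in v.read_ids.items() if b in counts},
                )
            )
    return out


def read_hq_fraction(read: Read, hq_phred: int = 20) -> float:
    if read.qualities is None:
        raise ValueError(f"read {read.id} has no qualities")
    q = np.asarray(read.qualities)
    return float(np.mean(q >= hq_phred))


def filter_quality(
    reads: list[Read],
    min_fraction_hq: float = 0.80,
    hq_phred: int = 20,
    allow_missing: bool = False,
) -> list[Read]:
    """Retain reads with >= 80% of bases at Phred >= 20 (drop 'under 80%')."""
    out = []
    for r in reads:
        if r.qualities is None:
            if allow_missing:
                warnings.warn(f"read {r.id}: no qualities, passing through")
                out.append(r)
                continue
            raise ValueError(f"read {r.id} has no qualities (FASTA input? set allow_missing)")
        if read_hq_fraction(r, hq_phred) >= min_fraction_hq:
            out.append(r)
    return out


def filter_frameshift(
    variants: list[Variant],
    references: dict[str, str],
    params: QCParams | None = None,
) -> list[Variant]:
    """Drop variants whose net indel versus their reference is not 0 mod 3.

    In-frame (multiple-of-three) insertions and deletions are retained;
    single-base homopolymer slips are removed here if they survived the
    singleton filter. Both the net internal indel and the total length
    offset against the reference must be codon multiples: a single-base
    gain or loss in a terminal homopolymer run shows up as an end overhang
    rather than an internal gap under free-end-gap alignment, and is just
    as much a frameshift artefact.
    """
    params = params or QCParams()
    aligner = _make_aligner(params)
    out = []
    for v in variants:
        ref = references[v.locus]
        if (len(v.sequence) - len(ref)) % 3 != 0:
            continue
        aln = aligner.align(ref, v.sequence)[0]
        _, net_indel, _ = _alignment_stats(aln)
        if net_indel % 3 == 0:
            out.append(v)
    return out


@dataclass
class FilterReport:
    """Per-stage retention counts; reads for read stages, variants after."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, unit: str, per_barcode: dict[str, int]) -> None:
        self.stages.append(
            {"stage": stage, "unit": unit, **per_barcode, "total": sum(per_barcode.values())}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    @property
    def retained_fraction(self) -> float:
        reads = [s for s in self.stages if s["unit"] == "reads"]
        if not reads:
            return float("nan")
        return reads[-1]["total"] / reads[0]["total"] if reads[0]["total"] else float("nan")


def _count_reads(reads: list[Read]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in reads:
        out[r.barcode] = out.get(r.barcode, 0) + 1
    return out


def _count_variants(variants: list[Variant]) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in variants:
        for b in v.counts:
            out[b] = out.get(b, 0) + 1
    return out


def run_qc_pipeline(
    reads: list[Read],
    references: dict[str, str],
    manifest_barcodes: set[str] | None = None,
    params: QCParams | None = None,
) -> tuple[list[Variant], FilterReport]:
    """Full cascade: length -> locus -> dereplicate -> singletons -> quality
    -> frameshift. Returns retained variants and the per-stage report.
    """
    params = params or QCParams()
    if not reads:
        raise ValueError("no reads supplied")
    if manifest_barcodes is not None:
        unknown = {r.barcode for r in reads} - set(manifest_barcodes)
        if unknown:
            raise ValueError(f"barcodes absent from manifest: {sorted(unknown)}")
    report = FilterReport()
    report.record("input", "reads", _count_reads(reads))

    reads1 = filter_length(reads, params.min_length)
    report.record("length>=%d" % params.min_length, "reads", _count_reads(reads1))

    if params.quality_first:
        reads1 = filter_quality(reads1, params.min_fraction_hq, params.hq_phred)
        report.record("quality", "reads", _count_reads(reads1))

    aligner = _make_aligner(params)
    assigned: list[tuple[Read, str, str]] = []
    quality_pass: dict[str, bool] = {}
    cache: dict[str, AlignmentResult] = {}  # locus call depends only on bases
    for r in reads1:
        res = cache.get(r.bases)
        if res is None:
            res = assign_locus(r, references, params.min_identity, aligner=aligner)
            cache[r.bases] = res
        if res.locus is not None:
            assigned.append((r, res.locus, res.oriented_bases))
            if r.qualities is not None:
                quality_pass[r.id] = (
                    read_hq_fraction(r, params.hq_phred) >= params.min_fraction_hq
                )
            else:
                quality_pass[r.id] = True
    report.record("locus>=%.0f%%" % (100 * params.min_identity), "reads",
                  _count_reads([t[0] for t in assigned]))

    variants = dereplicate(assigned)
    report.record("dereplicate", "variants", _count_variants(variants))

    variants = drop_singletons(variants, params.singleton_scope)
    report.record("drop_singletons", "variants", _count_variants(variants))

    if not params.quality_first:
        pruned = []
        for v in variants:
            counts: dict[str, int] = {}
            ids: dict[str, list[str]] = {}
            for b, rid_list in v.read_ids.items():
                keep = [rid for rid in rid_list if quality_pass.get(rid, True)]
                if keep:
                    counts[b] = len(keep)
                    ids[b] = keep
            if counts:
                pruned.append(Variant(v.sequence, v.locus, counts, ids))
        variants = pruned
        report.record("quality", "variants", _count_variants(variants))

    variants = filter_frameshift(variants, references, params)
    report.record("frameshift", "variants", _count_variants(variants))

    retained_reads: dict[str, int] = {}
    for v in variants:
        for b, c in v.counts.items():
            retained_reads[b] = retained_reads.get(b, 0) + c
    report.record("retained", "reads", retained_reads)
    return variants, report
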