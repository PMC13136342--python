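"""Hierarchical small-RNA read classification.

Reads are assigned by sequential alignment with class priority: a read is
given to the FIRST class in the configured order (default rRNA, miRNA, tRNA,
piRNA) with at least one best-stratum alignment. Reads surviving the class
stages are aligned to the genome; genome-mapping reads that overlap a
transcript are called mRNA fragments (sense) or endo-siRNAs (antisense),
genome hits outside any transcript stay "genome_only", and reads mapping
nowhere are "unassigned".

Within one class, equally good (minimal-mismatch) alignments to several
features split the read as fractional 1/n weights, so per-feature counts
and class totals stay conserved.

The internal aligner is a deliberately simple exhaustive matcher for small
reference sets and test fixtures; production alignments arrive as SAM/BAM
and are ingested via :func:`alignments_from_sam`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

from .annotations import AnnotationBundle, GenomicInterval, Transcript

__all__ = [
    "ReadRecord",
    "Alignment",
    "ReadAssignment",
    "ClassCountTable",
    "trim_adapter",
    "size_select",
    "toy_align",
    "sequential_classify",
    "tabulate",
    "extract_22g",
    "read_fastq",
    "write_fastq",
    "alignments_from_sam",
]

DEFAULT_CLASS_ORDER = ("rRNA", "miRNA", "tRNA", "piRNA")
CLASS_LABELS = (
    "rRNA",
    "miRNA",
    "tRNA",
    "piRNA",
    "mRNA_fragment",
    "endo_siRNA",
    "genome_only",
    "unassigned",
)

MIN_READ_LEN = 18
MAX_READ_LEN = 40

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One small-RNA read after trimming."""

    read_id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def first_nt(self) -> str:
        return self.seq[0]


@dataclass(frozen=True)
class Alignment:
    read_id: str
    target_class: str  # rRNA | miRNA | tRNA | piRNA | genome
    target_id: str
    target_start: int  # 0-based
    target_end: int  # exclusive
    antisense: bool = False
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.target_start >= self.target_end:
            raise ValueError("alignment start must precede end")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    cls: str
    feature_id: str = ""
    weight: float = 1.0
    alignment: Alignment | None = None

    def __post_init__(self) -> None:
        if self.cls not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.cls!r}")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError("weight must be in (0, 1]")


# ---------------------------------------------------------------------------
# preprocessing


def trim_adapter(
    read: ReadRecord, adapter: str, k: int = 8
) -> ReadRecord | None:
    """Remove the 3' adapter from a read; None if trimming leaves nothing.

    The suffix starting at the leftmost exact match of the adapter's first
    ``k`` nucleotides is removed; if no exact match exists, the leftmost
    window with at most one mismatch is used. Reads without a match are
    returned unchanged. An adapter match at position 0 leaves an empty
    insert, which is flagged as discarded by returning None.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    key = adapter[: max(1, k)]
    pos = read.seq.find(key)
    if pos == -1:
        klen = len(key)
        for i in range(len(read.seq) - klen + 1):
            window = read.seq[i : i + klen]
            if sum(a != b for a, b in zip(window, key)) <= 1:
                pos = i
                break
    if pos == -1:
        return read
    if pos == 0:
        return None
    return ReadRecord(read.read_id, read.seq[:pos])


def size_select(
    reads: Iterable[ReadRecord],
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
) -> list[ReadRecord]:
    """Keep reads with min_len <= length <= max_len (default 18-40 nt)."""
    return [r for r in reads if min_len <= r.length <= max_len]


# ---------------------------------------------------------------------------
# alignment


def _exact_hits(read_seq: str, ref: str) -> list[int]:
    hits, start = [], ref.find(read_seq)
    while start != -1:
        hits.append(start)
        start = ref.find(read_seq, start + 1)
    return hits


def _mismatch_hits(read_seq: str, ref: str, max_mm: int) -> list[tuple[int, int]]:
    # exhaustive Hamming scan; only used at max_mismatch >= 1 on fixtures
    n, m = len(ref), len(read_seq)
    out = []
    for i in range(n - m + 1):
        mm = 0
        window = ref[i : i + m]
        for a, b in zip(window, read_seq):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            out.append((i, mm))
    return out


def toy_align(
    read: ReadRecord,
    references: Mapping[str, str],
    max_mismatch: int = 0,
    target_class: str = "genome",
) -> list[Alignment]:
    """Exhaustively align a read (both strands) against small references.

    Returns all best-stratum alignments: every placement achieving the
    minimal mismatch count, provided it is <= ``max_mismatch``. Reverse-
    complement placements carry ``antisense=True``. An empty list means no
    hit.
    """
    if not references:
        raise ValueError("references must be non-empty")
    m = read.length
    candidates: list[tuple[int, Alignment]] = []
    for antisense, seq in ((False, read.seq), (True, revcomp(read.seq))):
        for ref_id, ref_seq in references.items():
            if max_mismatch == 0:
                placements = [(p, 0) for p in _exact_hits(seq, ref_seq)]
            else:
                placements = _mismatch_hits(seq, ref_seq, max_mismatch)
            for pos, mm in placements:
                candidates.append(
                    (
                        mm,
                        Alignment(
                            read_id=read.read_id,
                            target_class=target_class,
                            target_id=ref_id,
                            target_start=pos,
                            target_end=pos + m,
                            antisense=antisense,
                            mismatches=mm,
                        ),
                    )
                )
    if not candidates:
        return []
    best = min(mm for mm, _ in candidates)
    return [aln for mm, aln in candidates if mm == best]


# ---------------------------------------------------------------------------
# sequential classification


def _overlapping_transcript(
    chrom: str, start: int, end: int, transcripts: Sequence[Transcript]
) -> Transcript | None:
    for t in transcripts:
        span = t.span
        if span.chrom == chrom and start < span.end and span.start < end:
            return t
    return None


def sequential_classify(
    reads: Iterable[ReadRecord],
    bundle: AnnotationBundle,
    order: Sequence[str] = DEFAULT_CLASS_ORDER,
    max_mismatch: int = 0,
) -> list[ReadAssignment]:
    """Assign reads by class priority, then genome / transcriptome.

    A read goes to the first class in ``order`` with a best-stratum
    alignment; otherwise to the genome stage, where sense transcript overlap
    yields mRNA_fragment and antisense overlap endo-siRNA. Sense is decided
    against the transcript strand: a read aligned to the genome minus strand
    over a minus-strand gene is sense to that gene.
    """
    for cls in order:
        if cls not in ("rRNA", "miRNA", "tRNA", "piRNA"):
            raise ValueError(f"unknown class in order: {cls!r}")
    stage_refs = [(cls, bundle.class_references(cls)) for cls in order]
    assignments: list[ReadAssignment] = []
    for read in reads:
        hits: list[Alignment] = []
        hit_cls = None
        for cls, refs in stage_refs:
            if not refs:
                continue
            hits = toy_align(read, refs, max_mismatch, target_class=cls)
            if hits:
                hit_cls = cls
                break
        if hit_cls is not None:
            w = 1.0 / len(hits)
            assignments.extend(
                ReadAssignment(read.read_id, hit_cls, h.target_id, w, h)
                for h in hits
            )
            continue
        genome_hits = toy_align(
            read, bundle.genome, max_mismatch, target_class="genome"
        )
        if not genome_hits:
            assignments.append(ReadAssignment(read.read_id, "unassigned"))
            continue
        w = 1.0 / len(genome_hits)
        for h in genome_hits:
            t = _overlapping_transcript(
                h.target_id, h.target_start, h.target_end, bundle.transcripts
            )
            if t is None:
                assignments.append(
                    ReadAssignment(read.read_id, "genome_only", "", w, h)
                )
            else:
                read_strand_minus = h.antisense
                gene_strand_minus = t.strand == "-"
                sense = read_strand_minus == gene_strand_minus
                cls = "mRNA_fragment" if sense else "endo_siRNA"
                assignments.append(
                    ReadAssignment(read.read_id, cls, t.gene_id, w, h)
                )
    return assignments


# ---------------------------------------------------------------------------
# tabulation


@dataclass
class ClassCountTable:
    """Per-sample fractional counts by (class, feature) with denominators."""

    sample_id: str
    counts: dict[tuple[str, str], float] = field(default_factory=dict)
    totals: dict[str, float] = field(default_factory=dict)

    def class_total(self, cls: str) -> float:
        return self.totals.get(f"class:{cls}", 0.0)

    def class_percentages(self, include_unassigned: bool = False) -> dict[str, float]:
        """Class totals as percent of total genome-mapping reads."""
        denom = self.totals["total_genome"]
        classes = [c for c in CLASS_LABELS if c != "unassigned"]
        pct = {c: 100.0 * self.class_total(c) / denom for c in classes}
        if include_unassigned:
            total_all = denom + self.class_total("unassigned")
            pct = {
                c: 100.0 * self.class_total(c) / total_all
                for c in CLASS_LABELS
            }
        return pct

    def to_frame(self):
        import pandas as pd

        rows = [
            {"sample_id": self.sample_id, "cls": cls, "feature_id": feat, "count": n}
            for (cls, feat), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["sample_id", "cls", "feature_id", "count"])


def tabulate(
    assignments: Iterable[ReadAssignment], sample_id: str = "sample"
) -> ClassCountTable:
    """Aggregate assignments of one sample into a count table.

    ``total_genome`` counts every read assigned anywhere on the genome or a
    class reference (i.e. everything except "unassigned"), matching the
    "total genome mapping reads" denominator; ``genome_minus_rRNA``
    subtracts the rRNA class total.
    """
    table = ClassCountTable(sample_id=sample_id)
    class_totals: dict[str, float] = {c: 0.0 for c in CLASS_LABELS}
    for a in assignments:
        key = (a.cls, a.feature_id)
        table.counts[key] = table.counts.get(key, 0.0) + a.weight
        class_totals[a.cls] += a.weight
    assigned = sum(v for c, v in class_totals.items() if c != "unassigned")
    if assigned == 0:
        raise ValueError(f"{sample_id}: no assigned reads (empty library)")
    for cls, total in class_totals.items():
        table.totals[f"class:{cls}"] = total
    table.totals["total_genome"] = assigned
    table.totals["genome_minus_rRNA"] = assigned - class_totals["rRNA"]
    return table


# ---------------------------------------------------------------------------
# 22G-RNA extraction


def extract_22g(
    assignments: Iterable[ReadAssignment],
    reads_by_id: Mapping[str, ReadRecord],
    gene_id: str,
    bundle: AnnotationBundle,
) -> tuple[float, list[ReadAssignment]]:
    """Count 22G-RNAs against one gene locus.

    A qualifying read (i) has a genome-stage alignment overlapping the
    gene's span, (ii) is antisense to the gene, (iii) is exactly 22 nt, and
    (iv) starts with G. Returns the fractional count and the qualifying
    assignments.
    """
    gene = bundle.transcript(gene_id)  # raises KeyError if unknown
    span = gene.span
    gene_minus = gene.strand == "-"
    total = 0.0
    kept: list[ReadAssignment] = []
    for a in assignments:
        aln = a.alignment
        if aln is None or aln.target_class != "genome":
            continue
        if aln.target_id != span.chrom:
            continue
        if not (aln.target_start < span.end and span.start < aln.target_end):
            continue
        if aln.antisense == gene_minus:  # sense to the gene
            continue
        read = reads_by_id.get(a.read_id)
        if read is None or read.length != 22 or read.first_nt != "G":
            continue
        total += a.weight
        kept.append(a)
    return total, kept


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path: str | Path) -> list[ReadRecord]:
    return [
        ReadRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * r.length}\n")


def alignments_from_sam(
    path: str | Path, target_class: str
) -> list[Alignment]:
    """Ingest externally produced SAM/BAM hits for one class stage.

    Mismatch counts come from the NM tag when present (0 otherwise); the
    upstream aligner's settings are accepted as-is.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                Alignment(
                    read_id=rec.query_name,
                    target_class=target_class,
                    target_id=rec.reference_name,
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    antisense=rec.is_reverse,
                    mismatches=int(nm),
                )
            )
    return out


def assignments_from_sam_stages(
    stage_files: Mapping[str, str | Path],
    bundle: AnnotationBundle,
    all_read_ids: Iterable[str],
) -> list[ReadAssignment]:
    """Replicate the sequential priority over per-stage SAM/BAM files.

    ``stage_files`` maps class names (and optionally "genome") to SAM/BAM
    paths, in priority order; a read is assigned to the first stage in which
    it has an alignment, splitting weight across that stage's hits.
    """
    remaining = set(all_read_ids)
    assignments: list[ReadAssignment] = []
    for cls, path in stage_files.items():
        hits_by_read: dict[str, list[Alignment]] = {}
        for aln in alignments_from_sam(path, cls):
            if aln.read_id in remaining:
                hits_by_read.setdefault(aln.read_id, []).append(aln)
        for read_id, hits in hits_by_read.items():
            best = min(h.mismatches for h in hits)
            hits = [h for h in hits if h.mismatches == best]
            w = 1.0 / len(hits)
            for h in hits:
                if cls == "genome":
                    t = _overlapping_transcript(
                        h.target_id, h.target_start, h.target_end, bundle.transcripts
                    )
                    if t is None:
                        assignments.append(
                            ReadAssignment(read_id, "genome_only", "", w, h)
                        )
                    else:
                        sense = h.antisense == (t.strand == "-")
                        assignments.append(
                            ReadAssignment(
                                read_id,
                                "mRNA_fragment" if sense else "endo_siRNA",
                                t.gene_id,
                                w,
                                h,
                            )
                        )
                else:
                    assignments.append(
                        ReadAssignment(read_id, cls, h.target_id, w, h)
                    )
            remaining.discard(read_id)
    assignments.extend(ReadAssignment(rid, "unassigned") for rid in sorted(remaining))
    return assignments
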