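"""Reference annotation bundle: genome, small-RNA class references, mature tRNA models.

A bundle collects every reference the classifier needs: the genome, rRNA /
miRNA / piRNA sequences, mature tRNA models (with anticodon coordinates and
3' CCA handling), and transcript models for the mRNA-fragment / endo-siRNA
stage. Coordinates are 0-based half-open throughout; 1-based GFF coordinates
are converted at the I/O boundary only.

Mature tRNA sequences are consumed pre-spliced (intron-free) from FASTA;
no intron splicing from genomic coordinates is attempted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "TrnaModel",
    "Transcript",
    "AnnotationBundle",
    "parse_trna_name",
    "locate_anticodon",
    "finalize_trna",
    "load_bundle",
    "write_bundle",
]

# Canonical anticodon position in the mature tRNA body (0-based); used only
# when the annotation does not supply an explicit anticodon offset.
CANONICAL_ANTICODON_OFFSET = 34

_TRNA_NAME_RE = re.compile(
    r"^tRNA-(?P<aa>[A-Za-z]{3}|iMet|SeC|Sup|Und)-(?P<ac>[ACGTN]{3})"
    r"(?:-(?P<iso>\d+))?(?:-(?P<copy>\d+))?$"
)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based, stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def parse_trna_name(name: str) -> tuple[str, str, str, str]:
    """Split a tRNA record name into (amino_acid, anticodon, isoacceptor, isodecoder).

    Names follow the GtRNAdb-style convention ``tRNA-Gly-GCC-1-1`` where the
    trailing integers are the isodecoder (sequence variant) and gene-copy
    numbers.

    Raises
    ------
    ValueError
        If the name cannot be parsed.
    """
    m = _TRNA_NAME_RE.match(name.strip())
    if m is None:
        raise ValueError(
            f"cannot parse tRNA record name {name!r}: expected "
            "'tRNA-<AminoAcid>-<Anticodon>[-<isodecoder>[-<copy>]]'"
        )
    aa, ac = m.group("aa"), m.group("ac").upper()
    isoacceptor = f"{aa}-{ac}"
    iso_num = m.group("iso")
    isodecoder = f"{isoacceptor}-{iso_num}" if iso_num else isoacceptor
    return aa, ac, isoacceptor, isodecoder


@dataclass
class TrnaModel:
    """A mature tRNA sequence with anticodon coordinates.

    ``anticodon_start`` is the 0-based offset of the anticodon 3-mer within
    ``mature_seq``; it is unaffected by 3' CCA addition.
    """

    name: str
    amino_acid: str
    anticodon: str
    isoacceptor_id: str
    isodecoder_id: str
    mature_seq: str
    anticodon_start: int
    cca_appended: bool = False

    @classmethod
    def from_fasta_record(
        cls, name: str, seq: str, anticodon_start: int | None = None
    ) -> "TrnaModel":
        aa, ac, isoacceptor, isodecoder = parse_trna_name(name)
        start = locate_anticodon(seq, ac, provided=anticodon_start)
        return cls(
            name=name,
            amino_acid=aa,
            anticodon=ac,
            isoacceptor_id=isoacceptor,
            isodecoder_id=isodecoder,
            mature_seq=seq.upper(),
            anticodon_start=start,
        )

    def validate(self) -> None:
        seq = self.mature_seq
        if not (60 <= len(seq) <= 100):
            raise ValueError(
                f"{self.name}: mature tRNA length {len(seq)} outside [60, 100]"
            )
        window = seq[self.anticodon_start : self.anticodon_start + 3]
        if window != self.anticodon:
            raise ValueError(
                f"{self.name}: anticodon {self.anticodon} not found at offset "
                f"{self.anticodon_start} (sequence has {window!r})"
            )
        if self.cca_appended and not seq.endswith("CCA"):
            raise ValueError(f"{self.name}: cca_appended set but sequence lacks 3' CCA")

    def __len__(self) -> int:
        return len(self.mature_seq)


def locate_anticodon(
    seq: str, anticodon: str, provided: int | None = None
) -> int:
    """Return the anticodon start offset within a mature tRNA sequence.

    An explicitly annotated offset is passed through (after checking the
    3-mer actually sits there). Otherwise every occurrence of the anticodon
    3-mer is found and the one whose start is closest to the canonical
    offset 34 wins; on an exact distance tie the 5'-most occurrence is used.
    """
    seq = seq.upper()
    anticodon = anticodon.upper()
    if provided is not None:
        if seq[provided : provided + 3] != anticodon:
            raise ValueError(
                f"annotated anticodon offset {provided} does not contain "
                f"{anticodon} (found {seq[provided:provided + 3]!r})"
            )
        return provided
    hits = [m.start() for m in re.finditer(f"(?={re.escape(anticodon)})", seq)]
    if not hits:
        raise ValueError(f"anticodon {anticodon} absent from mature sequence")
    return min(hits, key=lambda p: (abs(p - CANONICAL_ANTICODON_OFFSET), p))


def finalize_trna(model: TrnaModel, append_cca: bool = True) -> TrnaModel:
    """Append the post-transcriptional 3' CCA to a mature tRNA model.

    3' tDRs carry the CCA tail in vivo, so mature models must include it for
    3'-anchored fragments to align within the model. The anticodon offset is
    unchanged. Appending twice is refused.
    """
    if not append_cca:
        return model
    if model.cca_appended:
        raise ValueError(f"{model.name}: CCA already appended")
    out = replace(model, mature_seq=model.mature_seq + "CCA", cca_appended=True)
    out.validate()
    return out


@dataclass
class Transcript:
    gene_id: str
    intervals: list[GenomicInterval]
    strand: str

    @property
    def chrom(self) -> str:
        return self.intervals[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(iv.start for iv in self.intervals),
            max(iv.end for iv in self.intervals),
            self.strand,
        )


@dataclass
class AnnotationBundle:
    """All references consumed by the classifier, keyed by class."""

    genome: dict[str, str]
    rrna: dict[str, str] = field(default_factory=dict)
    mirna: dict[str, str] = field(default_factory=dict)
    trna: list[TrnaModel] = field(default_factory=list)
    pirna: dict[str, str] = field(default_factory=dict)
    transcripts: list[Transcript] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def validate(self, enabled: Iterable[str] | None = None) -> None:
        enabled = set(
            enabled
            if enabled is not None
            else ("rRNA", "miRNA", "tRNA", "piRNA", "mRNA")
        )
        empties = {
            "rRNA": not self.rrna,
            "miRNA": not self.mirna,
            "tRNA": not self.trna,
            "piRNA": not self.pirna,
            "mRNA": not self.transcripts,
        }
        for cls in enabled:
            if empties.get(cls, False):
                raise ValueError(f"class {cls} is enabled but has no references")
        gene_ids = [t.gene_id for t in self.transcripts]
        if len(gene_ids) != len(set(gene_ids)):
            raise ValueError("transcript gene_ids are not unique")
        for model in self.trna:
            model.validate()

    def trna_by_name(self) -> dict[str, TrnaModel]:
        return {m.name: m for m in self.trna}

    def transcript(self, gene_id: str) -> Transcript:
        for t in self.transcripts:
            if t.gene_id == gene_id:
                return t
        raise KeyError(f"unknown gene_id {gene_id!r}")

    def class_references(self, cls: str) -> dict[str, str]:
        """Reference sequences for one alignment stage."""
        if cls == "rRNA":
            return self.rrna
        if cls == "miRNA":
            return self.mirna
        if cls == "tRNA":
            return {m.name: m.mature_seq for m in self.trna}
        if cls == "piRNA":
            return self.pirna
        if cls == "genome":
            return self.genome
        raise ValueError(f"unknown reference class {cls!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationBundle):
            return NotImplemented
        return (
            self.genome == other.genome
            and self.rrna == other.rrna
            and self.mirna == other.mirna
            and self.trna == other.trna
            and self.pirna == other.pirna
            and self.transcripts == other.transcripts
        )


# ---------------------------------------------------------------------------
# I/O


def _read_fasta(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


_ANTICODON_ATTR_RE = re.compile(r"anticodon_start=(\d+)")


def _read_trna_fasta(path: Path, append_cca: bool) -> list[TrnaModel]:
    models: list[TrnaModel] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _ANTICODON_ATTR_RE.search(rec.description)
        offset = int(m.group(1)) if m else None
        try:
            model = TrnaModel.from_fasta_record(rec.id, str(rec.seq), offset)
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
        if append_cca:
            model = finalize_trna(model, append_cca=True)
        model.validate()
        models.append(model)
    if not models:
        raise ValueError(f"{path}: no tRNA records")
    return models


def _read_transcripts_gff(path: Path) -> list[Transcript]:
    """Parse gene/exon features from a GFF3 file into transcripts.

    Each ``gene`` (falling back to ``mRNA``/``transcript``) feature becomes
    one Transcript; ``exon`` children (via Parent=) define its intervals,
    and genes without exons use the full gene span. GFF is 1-based
    inclusive; output is 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    top_types = ("gene",)
    if not any(True for _ in db.features_of_type("gene")):
        top_types = ("mRNA", "transcript")
    transcripts: list[Transcript] = []
    for feat in db.features_of_type(top_types):
        gene_id = feat.attributes.get("gene_id", [None])[0] or feat.id
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        intervals = exons or [
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        ]
        transcripts.append(Transcript(gene_id, intervals, feat.strand))
    return transcripts


def load_bundle(manifest: str | Path | Mapping) -> AnnotationBundle:
    """Load an annotation bundle from a manifest (YAML/JSON path or mapping).

    Manifest keys: ``genome``, ``rrna``, ``mirna``, ``trna``, ``pirna``
    (FASTA paths), ``transcripts`` (GFF3 path), plus options ``append_cca``
    (default true) and ``enabled_classes``. Relative paths resolve against
    the manifest's directory. Free-form ``provenance`` is carried through to
    ``bundle.meta``.
    """
    base = Path(".")
    if isinstance(manifest, (str, Path)):
        path = Path(manifest)
        base = path.parent
        with open(path) as fh:
            manifest = yaml.safe_load(fh)
    if not isinstance(manifest, Mapping):
        raise ValueError("manifest must be a mapping or a path to one")

    def resolve(key: str) -> Path | None:
        val = manifest.get(key)
        return None if val is None else base / val

    append_cca = bool(manifest.get("append_cca", True))
    enabled = manifest.get("enabled_classes")

    genome_path = resolve("genome")
    if genome_path is None:
        raise ValueError("manifest must name a genome FASTA")
    bundle = AnnotationBundle(
        genome=_read_fasta(genome_path),
        rrna=_read_fasta(resolve("rrna")) if manifest.get("rrna") else {},
        mirna=_read_fasta(resolve("mirna")) if manifest.get("mirna") else {},
        trna=_read_trna_fasta(resolve("trna"), append_cca)
        if manifest.get("trna")
        else [],
        pirna=_read_fasta(resolve("pirna")) if manifest.get("pirna") else {},
        transcripts=_read_transcripts_gff(resolve("transcripts"))
        if manifest.get("transcripts")
        else [],
        meta={
            "append_cca": append_cca,
            "provenance": manifest.get("provenance", {}),
        },
    )
    bundle.validate(enabled)
    return bundle


def _write_fasta(records: Mapping[str, str], path: Path, descriptions=None) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description=(descriptions or {}).get(name, ""))
        for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_bundle(bundle: AnnotationBundle, outdir: str | Path) -> Path:
    """Write a bundle to FASTA/GFF files plus a manifest; returns manifest path.

    ``load_bundle(write_bundle(b, d))`` reproduces ``b`` field for field.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fasta(bundle.genome, outdir / "genome.fa")
    manifest: dict = {"genome": "genome.fa"}
    if bundle.rrna:
        _write_fasta(bundle.rrna, outdir / "rrna.fa")
        manifest["rrna"] = "rrna.fa"
    if bundle.mirna:
        _write_fasta(bundle.mirna, outdir / "mirna.fa")
        manifest["mirna"] = "mirna.fa"
    if bundle.pirna:
        _write_fasta(bundle.pirna, outdir / "pirna.fa")
        manifest["pirna"] = "pirna.fa"
    if bundle.trna:
        seqs, descs = {}, {}
        for m in bundle.trna:
            # persist the CCA-stripped body so reloading with append_cca
            # reconstructs the identical model
            body = m.mature_seq[:-3] if m.cca_appended else m.mature_seq
            seqs[m.name] = body
            descs[m.name] = f"anticodon_start={m.anticodon_start}"
        _write_fasta(seqs, outdir / "trna.fa", descs)
        manifest["trna"] = "trna.fa"
        manifest["append_cca"] = all(m.cca_appended for m in bundle.trna)
    if bundle.transcripts:
        with open(outdir / "transcripts.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for t in bundle.transcripts:
                span = t.span
                fh.write(
                    f"{span.chrom}\ttdrprof\tgene\t{span.start + 1}\t{span.end}\t.\t"
                    f"{t.strand}\t.\tID={t.gene_id};gene_id={t.gene_id}\n"
                )
                if len(t.intervals) > 1 or t.intervals[0] != span:
                    for iv in t.intervals:
                        fh.write(
                            f"{iv.chrom}\ttdrprof\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                            f"{t.strand}\t.\tParent={t.gene_id}\n"
                        )
        manifest["transcripts"] = "transcripts.gff3"
    manifest["enabled_classes"] = [
        c
        for c, present in (
            ("rRNA", bundle.rrna),
            ("miRNA", bundle.mirna),
            ("tRNA", bundle.trna),
            ("piRNA", bundle.pirna),
            ("mRNA", bundle.transcripts),
        )
        if present
    ]
    manifest["provenance"] = bundle.meta.get("provenance", {})
    manifest_path = outdir / "bundle.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
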