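"""Readers and writers for the external formats the pipeline consumes.

Supported formats: GFF3 transcript models (with ``identity=``/``coverage=``
attributes), RepeatMasker ``.out``, BED6 repeats, FASTA, and two-column TSV
gene→term maps.  Internal coordinates are always 0-based half-open;
conversion from GFF3's 1-based inclusive convention happens here and only
here.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    GenomicInterval,
    ParseError,
    RepeatFeature,
    TermAnnotationMap,
    TranscriptModel,
)

_TRANSCRIPT_TYPES = {"transcript", "mRNA"}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into a chrom → uppercase sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3 transcript models
# ---------------------------------------------------------------------------

def _validate_gff3_lines(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise ParseError(
                    f"{path}: line {lineno}: invalid 1-based range {start}..{end}"
                )


def read_transcripts_gff3(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript/mRNA + exon features into TranscriptModel objects.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    ``identity``/``coverage`` attributes on the transcript feature default to
    1.0 when absent (curated input).  Exons lacking a parent transcript are
    an error.
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype in _TRANSCRIPT_TYPES:
            tid = feat.id
            transcripts[tid] = {
                "gene_id": feat.attributes.get("gene_id", [None])[0]
                or (feat.attributes.get("Parent", [None])[0]),
                "identity": float(feat.attributes.get("identity", ["1.0"])[0]),
                "coverage": float(feat.attributes.get("coverage", ["1.0"])[0]),
                "exons": [],
                "strand": feat.strand,
                "chrom": feat.seqid,
            }
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent", [])
        if not parents:
            raise ParseError(f"{path}: exon at {feat.seqid}:{feat.start} has no Parent")
        for parent in parents:
            if parent not in transcripts:
                raise ParseError(
                    f"{path}: exon parent {parent!r} is not a transcript/mRNA feature"
                )
            transcripts[parent]["exons"].append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
    out = []
    for tid, rec in transcripts.items():
        if not rec["exons"]:
            raise ParseError(f"{path}: transcript {tid} has no exon features")
        out.append(
            TranscriptModel(
                transcript_id=tid,
                exons=rec["exons"],
                gene_id=rec["gene_id"],
                identity=rec["identity"],
                coverage=rec["coverage"],
            )
        )
    return out


def write_transcripts_gff3(
    transcripts: Iterable[TranscriptModel], path: str | os.PathLike
) -> None:
    """Write transcript + exon features; coordinates converted to 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            attrs = f"ID={t.transcript_id}"
            if t.gene_id:
                attrs += f";gene_id={t.gene_id}"
            attrs += f";identity={t.identity:.4f};coverage={t.coverage:.4f}"
            fh.write(
                f"{t.chrom}\tisoscape\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for i, e in enumerate(t.exons, start=1):
                fh.write(
                    f"{e.chrom}\tisoscape\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tID={t.transcript_id}.exon{i};"
                    f"Parent={t.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out and BED6 repeats
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(
    path: str | os.PathLike,
    transposase_families: Optional[set[str]] = None,
) -> list[RepeatFeature]:
    """Parse a standard RepeatMasker .out file (3 header lines, 15 columns).

    Query coordinates (1-based inclusive) become 0-based half-open;
    orientation ``C`` maps to strand ``-``.  ``transposase_families`` flags
    families whose consensus encodes a transposase (library metadata).
    """
    transposase_families = transposase_families or set()
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ParseError(
                    f"{path}: line {lineno}: truncated RepeatMasker record "
                    f"({len(fields)} fields)"
                )
            try:
                chrom = fields[4]
                begin, end = int(fields[5]), int(fields[6])
                orientation = fields[8]
                family = fields[9]
                te_class = fields[10]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from exc
            strand = "-" if orientation == "C" else "+"
            feats.append(
                RepeatFeature(
                    interval=GenomicInterval(chrom, begin - 1, end, strand),
                    family=family,
                    te_class=te_class,
                    is_transposase_family=family in transposase_families,
                )
            )
    return feats


def write_repeatmasker_out(
    feats: Iterable[RepeatFeature], path: str | os.PathLike
) -> None:
    """Write repeats in the standard .out column layout (used by the simulator)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, f in enumerate(feats, start=1):
            orientation = "C" if f.interval.strand == "-" else "+"
            length = len(f.interval)
            fh.write(
                f"{1000:>5} {1.0:5.1f} {0.0:4.1f} {0.0:4.1f}  "
                f"{f.interval.chrom:<10} {f.interval.start + 1:>8} "
                f"{f.interval.end:>8} (0) {orientation} {f.family:<18} "
                f"{f.te_class:<18} 1 {length} (0) {i}\n"
            )


def read_repeats_bed(
    path: str | os.PathLike,
    transposase_families: Optional[set[str]] = None,
) -> list[RepeatFeature]:
    """BED6 alternative repeat input: name column holds ``family#class``."""
    transposase_families = transposase_families or set()
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            family, _, te_class = name.partition("#")
            feats.append(
                RepeatFeature(
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                    family=family,
                    te_class=te_class or "Unknown",
                    is_transposase_family=family in transposase_families,
                )
            )
    return feats


def read_repeat_library_tsv(path: str | os.PathLike) -> dict[str, dict]:
    """Read family metadata TSV: family, te_class, is_transposase (0/1)."""
    lib: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            lib[row["family"]] = {
                "te_class": row.get("te_class", "Unknown"),
                "is_transposase": row.get("is_transposase", "0") == "1",
            }
    return lib


# ---------------------------------------------------------------------------
# Term annotation map
# ---------------------------------------------------------------------------

def read_term_map(path: str | os.PathLike) -> TermAnnotationMap:
    """Two-or-three-column TSV: gene_id, term_id[, term_name]."""
    gene_to_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: term map rows need >=2 columns")
            gene, term = fields[0], fields[1]
            gene_to_terms.setdefault(gene, set()).add(term)
            if len(fields) > 2:
                term_names[term] = fields[2]
    return TermAnnotationMap(gene_to_terms=gene_to_terms, term_names=term_names)


# ---------------------------------------------------------------------------
# Sequence extraction
# ---------------------------------------------------------------------------

def extract_spliced_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence, 5'→3' in transcript sense.

    Exon sequences are concatenated in genomic order and the whole string is
    reverse-complemented for minus-strand transcripts.
    """
    if t.chrom not in genome:
        raise KeyError(f"chromosome {t.chrom!r} not in genome")
    chrom_seq = genome[t.chrom]
    if t.end > len(chrom_seq):
        raise IndexError(
            f"{t.transcript_id}: exon end {t.end} beyond chromosome "
            f"{t.chrom} length {len(chrom_seq)}"
        )
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq
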