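"""Transposable-element exonization annotation and summary statistics.

Genomic repeat annotations are projected into spliced-transcript
coordinates; a transcript counts as TE-exonized when a repeat covers at
least ``min_overlap`` bp of its exons.  For protein-coding transcripts the
projected fragments are localized to 5'UTR / ORF / 3'UTR (a fragment
spanning a boundary contributes to every region it touches); lncRNA
fragments are labelled NONCODING_EXON.  Coding TE-transcripts are further
split into transposase-coding transcripts (the ORF itself is TE-derived)
and fragment carriers.  The module also provides the two statistics used to
summarize exonization: the pooled two-sample proportion z-test and
hypergeometric term enrichment with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import bisect
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coding import CodingVerdict, OrfAnnotation
from .models import GenomicInterval, RepeatFeature, TermAnnotationMap, TranscriptModel

REGIONS = ("FIVE_UTR", "ORF", "THREE_UTR", "NONCODING_EXON")
DEFAULT_MIN_OVERLAP = 10
DEFAULT_TRANSPOSASE_ORF_FRACTION = 0.5


@dataclass
class TeOverlapRecord:
    transcript_id: str
    family: str
    overlap_bp: int
    tx_start: int
    tx_end: int
    regions: set[str]
    orf_overlap_fraction: float = 0.0
    is_transposase_family: bool = False
    covers_orf_start: bool = False

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("TE overlap record needs >=1 region label")
        if not 0.0 <= self.orf_overlap_fraction <= 1.0:
            raise ValueError("orf_overlap_fraction must be in [0,1]")


@dataclass
class ExonizationSummary:
    n_total: int = 0
    n_te_transcripts: int = 0
    n_coding: int = 0
    n_coding_te: int = 0
    n_lnc: int = 0
    n_lnc_te: int = 0
    n_transposase: int = 0
    n_fragment_carriers: int = 0
    region_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_te_transcripts": self.n_te_transcripts,
            "n_coding": self.n_coding,
            "n_coding_te": self.n_coding_te,
            "n_lnc": self.n_lnc,
            "n_lnc_te": self.n_lnc_te,
            "n_transposase": self.n_transposase,
            "n_fragment_carriers": self.n_fragment_carriers,
            "region_counts": dict(self.region_counts),
        }


# ---------------------------------------------------------------------------
# coordinate projection
# ---------------------------------------------------------------------------

def project_to_transcript(
    t: TranscriptModel, feature: GenomicInterval
) -> list[tuple[int, int]]:
    """Exonic overlap of a genomic feature in spliced-transcript coordinates.

    Returns half-open (tx_start, tx_end) fragments running 5'→3' in
    transcript sense (minus-strand transcripts are mirrored); abutting
    fragments (a feature bridging a splice junction) are merged.  Purely
    intronic or off-chromosome features yield [].
    """
    if feature.chrom != t.chrom:
        return []
    frags: list[tuple[int, int]] = []
    off = 0
    for e in t.exons:
        s, x = max(e.start, feature.start), min(e.end, feature.end)
        if x > s:
            frags.append((off + s - e.start, off + x - e.start))
        off += len(e)
    if t.strand == "-":
        total = t.length
        frags = [(total - b, total - a) for a, b in frags]
    frags.sort()
    merged: list[list[int]] = []
    for a, b in frags:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


# ---------------------------------------------------------------------------
# TE overlap annotation
# ---------------------------------------------------------------------------

def _verdict_map(verdicts) -> dict[str, bool]:
    """transcript id → is_lncRNA, from CodingVerdicts or a ready-made map."""
    if isinstance(verdicts, dict):
        return {k: bool(v.is_lncRNA if isinstance(v, CodingVerdict) else v)
                for k, v in verdicts.items()}
    return {v.transcript_id: v.is_lncRNA for v in verdicts}


class _RepeatIndex:
    def __init__(self, repeats: Sequence[RepeatFeature]):
        self.by_chrom: dict[str, list[RepeatFeature]] = defaultdict(list)
        for r in repeats:
            self.by_chrom[r.interval.chrom].append(r)
        self.starts: dict[str, list[int]] = {}
        for chrom, feats in self.by_chrom.items():
            feats.sort(key=lambda r: r.interval.start)
            self.starts[chrom] = [r.interval.start for r in feats]

    def overlapping(self, chrom: str, start: int, end: int) -> list[RepeatFeature]:
        feats = self.by_chrom.get(chrom, [])
        if not feats:
            return []
        hi = bisect.bisect_left(self.starts[chrom], end)
        return [r for r in feats[:hi] if r.interval.end > start]


def annotate_te_overlaps(
    transcripts: Sequence[TranscriptModel],
    verdicts,
    orfs: dict[str, OrfAnnotation],
    repeats: Sequence[RepeatFeature],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    transposase_threshold: float = DEFAULT_TRANSPOSASE_ORF_FRACTION,
) -> tuple[list[TeOverlapRecord], ExonizationSummary]:
    """TE overlap records per (transcript, repeat feature) plus the tallies.

    A record is emitted when a repeat's exonic overlap with the transcript
    reaches ``min_overlap`` bp; a transcript is TE-exonized iff it has >=1
    record.  Coding transcripts must come with an ORF annotation.
    """
    is_lnc = _verdict_map(verdicts)
    missing = [t.transcript_id for t in transcripts
               if t.transcript_id not in is_lnc]
    if missing:
        raise ValueError(f"transcripts without coding verdict: {missing[:3]}")
    index = _RepeatIndex(repeats)
    records: list[TeOverlapRecord] = []
    for t in transcripts:
        tid = t.transcript_id
        lnc = is_lnc[tid]
        orf = orfs.get(tid)
        if not lnc and orf is None:
            raise ValueError(f"coding transcript {tid} lacks an ORF annotation")
        for rep in index.overlapping(t.chrom, t.start, t.end):
            frags = project_to_transcript(t, rep.interval)
            total = sum(b - a for a, b in frags)
            if total < min_overlap:
                continue
            regions: set[str] = set()
            orf_overlap = 0
            covers_start = False
            if lnc:
                regions.add("NONCODING_EXON")
            else:
                o_s, o_e = orf.start, orf.end
                for a, b in frags:
                    if a < o_s:
                        regions.add("FIVE_UTR")
                    if b > o_e:
                        regions.add("THREE_UTR")
                    ov = min(b, o_e) - max(a, o_s)
                    if ov > 0:
                        regions.add("ORF")
                        orf_overlap += ov
                    if a <= o_s < b:
                        covers_start = True
            records.append(
                TeOverlapRecord(
                    transcript_id=tid,
                    family=rep.family,
                    overlap_bp=total,
                    tx_start=min(a for a, _ in frags),
                    tx_end=max(b for _, b in frags),
                    regions=regions,
                    orf_overlap_fraction=(
                        orf_overlap / (orf.end - orf.start) if not lnc else 0.0
                    ),
                    is_transposase_family=rep.is_transposase_family,
                    covers_orf_start=covers_start,
                )
            )
    summary = build_summary(records, is_lnc, transposase_threshold)
    return records, summary


def classify_transposase(
    records: Sequence[TeOverlapRecord],
    orfs: Optional[dict[str, OrfAnnotation]] = None,
    threshold: float = DEFAULT_TRANSPOSASE_ORF_FRACTION,
) -> dict[str, set[str]]:
    """Partition coding TE-transcripts into transposase coders vs carriers.

    A coding TE-transcript is transposase-coding iff some record covers at
    least ``threshold`` of its ORF, or a transposase-family fragment covers
    the ORF start.  ``orfs`` is accepted for interface symmetry; the records
    already carry the ORF-derived quantities.
    """
    coding_tids = {
        r.transcript_id for r in records if "NONCODING_EXON" not in r.regions
    }
    transposase: set[str] = set()
    for r in records:
        if r.transcript_id not in coding_tids:
            continue
        if r.orf_overlap_fraction >= threshold or (
            r.is_transposase_family and r.covers_orf_start
        ):
            transposase.add(r.transcript_id)
    return {
        "transposase_coding": transposase,
        "fragment_carrier": coding_tids - transposase,
    }


def build_summary(
    records: Sequence[TeOverlapRecord],
    is_lnc: dict[str, bool],
    transposase_threshold: float = DEFAULT_TRANSPOSASE_ORF_FRACTION,
) -> ExonizationSummary:
    """Exonization tallies; UTR/ORF region counts exclude transposase
    transcripts (they are reported separately)."""
    te_tids = {r.transcript_id for r in records}
    parts = classify_transposase(records, threshold=transposase_threshold)
    n_lnc = sum(1 for v in is_lnc.values() if v)
    lnc_te = {tid for tid in te_tids if is_lnc[tid]}
    region_counts = {r: 0 for r in REGIONS}
    by_tid: dict[str, set[str]] = defaultdict(set)
    for r in records:
        if r.transcript_id in parts["transposase_coding"]:
            continue
        by_tid[r.transcript_id] |= r.regions
    for regions in by_tid.values():
        for region in regions:
            region_counts[region] += 1
    return ExonizationSummary(
        n_total=len(is_lnc),
        n_te_transcripts=len(te_tids),
        n_coding=len(is_lnc) - n_lnc,
        n_coding_te=len(te_tids) - len(lnc_te),
        n_lnc=n_lnc,
        n_lnc_te=len(lnc_te),
        n_transposase=len(parts["transposase_coding"]),
        n_fragment_carriers=len(parts["fragment_carrier"]),
        region_counts=region_counts,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class ProportionTestResult:
    p1: float
    p2: float
    z: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0,1]")


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Pooled-variance two-sample proportion z-test (two-sided).

    z = (p1 - p2) / sqrt(p̂ (1-p̂) (1/n1 + 1/n2)) with p̂ = (x1+x2)/(n1+n2).
    Degenerate pooled proportions (0 or 1) return z=0, p=1.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("need 0 <= x <= n and n >= 1 for both samples")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(p1=p1, p2=p2, z=0.0, p_value=1.0)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p_value = 2 * stats.norm.sf(abs(z))
    return ProportionTestResult(p1=p1, p2=p2, z=z, p_value=float(min(p_value, 1.0)))


@dataclass
class EnrichmentResult:
    term: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")


def hypergeom_enrichment(
    study: set[str],
    universe: set[str],
    annot: TermAnnotationMap,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment per term, BH-adjusted.

    p = P[X >= k] with population N = |universe|, K genes annotated to the
    term, n = |study|.  Terms with zero study hits are skipped.  Results are
    sorted by p-value.
    """
    study, universe = set(study), set(universe)
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    N, n = len(universe), len(study)
    rows: list[tuple[str, int, int, float]] = []
    for term in sorted(annot.all_terms()):
        annotated = annot.genes_with_term(term) & universe
        K = len(annotated)
        k = len(annotated & study)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(p, 1.0)))
    if not rows:
        return []
    pvals = [p for _, _, _, p in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(term=term, k=k, K=K, n=n, N=N,
                         p_value=p, q_value=float(max(q, p)))
        for (term, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
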