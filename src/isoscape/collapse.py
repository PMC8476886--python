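"""Alignment-quality filtering and 5'-tolerant redundancy collapse.

Mapped isoforms are first filtered on alignment identity and trimmed
coverage (defaults 0.90 / 0.85).  Survivors are then merged into
non-redundant groups: two multi-exon transcripts are redundant iff they sit
on the same chromosome and strand, have identical intron chains, identical
3' termini (within an optional tolerance) and differ at most in the 5'
boundary of the 5'-terminal exon — the signature of 5'-degraded cDNA
copies.  Single-exon transcripts merge iff they share the 3' terminus and
overlap.  Grouping is the transitive closure of this pairwise relation, so
it is order-invariant; the representative is the member reaching furthest
5'.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .models import GenomicInterval, TranscriptModel


@dataclass
class CollapseConfig:
    min_identity: float = 0.90
    min_coverage: float = 0.85
    end3_tolerance: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity <= 1 and 0 <= self.min_coverage <= 1):
            raise ValueError("identity/coverage thresholds must be in [0,1]")
        if self.end3_tolerance < 0:
            raise ValueError("end3_tolerance must be >= 0")


@dataclass
class CollapseGroup:
    representative: str
    members: set[str]
    shared_intron_chain: list[GenomicInterval]
    representative_model: TranscriptModel = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a group member")


def filter_alignments(
    transcripts: list[TranscriptModel], cfg: CollapseConfig | None = None
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Partition into (kept, discarded) on identity >= min AND coverage >= min."""
    cfg = cfg or CollapseConfig()
    kept, discarded = [], []
    for t in transcripts:
        if t.identity >= cfg.min_identity and t.coverage >= cfg.min_coverage:
            kept.append(t)
        else:
            discarded.append(t)
    return kept, discarded


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _merge_key(t: TranscriptModel) -> tuple:
    """Everything that must match exactly apart from the 3' coordinate."""
    if t.n_exons == 1:
        return (t.chrom, t.strand, "single")
    chain = t.intron_chain()
    # all exon boundaries except the 5' terminus and the 3' terminus are
    # fixed by the intron chain
    return (t.chrom, t.strand, chain)


def collapse_redundant(
    transcripts: list[TranscriptModel], cfg: CollapseConfig | None = None
) -> list[CollapseGroup]:
    """Merge 5'-degraded redundant isoforms into non-redundant groups."""
    cfg = cfg or CollapseConfig()
    order = sorted(range(len(transcripts)),
                   key=lambda i: transcripts[i].transcript_id)
    uf = _UnionFind(len(transcripts))

    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i in order:
        buckets[_merge_key(transcripts[i])].append(i)

    for key, idxs in buckets.items():
        single = key[-1] == "single"
        # sort by 3' terminus; within tolerance → same chain of unions
        idxs = sorted(idxs, key=lambda i: transcripts[i].three_prime())
        for a, b in zip(idxs, idxs[1:]):
            ta, tb = transcripts[a], transcripts[b]
            if abs(ta.three_prime() - tb.three_prime()) > cfg.end3_tolerance:
                continue
            # single-exon transcripts additionally need span overlap (always
            # true at tolerance 0, where they share the 3' coordinate)
            if single and not ta.exons[0].overlaps(tb.exons[0]):
                continue
            uf.union(a, b)

    groups_idx: dict[int, list[int]] = defaultdict(list)
    for i in range(len(transcripts)):
        groups_idx[uf.find(i)].append(i)

    groups: list[CollapseGroup] = []
    for idxs in groups_idx.values():
        members = [transcripts[i] for i in idxs]
        strand = members[0].strand
        # representative: reaches furthest 5' (ties: longest, then id)
        def _rep_key(t: TranscriptModel):
            reach = -t.start if strand == "+" else t.end
            return (reach, t.length, t.transcript_id)
        rep = max(members, key=_rep_key)
        groups.append(
            CollapseGroup(
                representative=rep.transcript_id,
                members={m.transcript_id for m in members},
                shared_intron_chain=rep.introns(),
                representative_model=rep,
            )
        )
    groups.sort(key=lambda g: (g.representative_model.chrom,
                               g.representative_model.start,
                               g.representative))
    return groups


def assign_loci(groups: list[CollapseGroup]) -> dict[str, str]:
    """Group → locus id, by gene_id when present, else by single-linkage
    clustering of same-strand exon-overlapping representatives."""
    reps = [g.representative_model for g in groups]
    if all(t.gene_id for t in reps):
        return {g.representative: reps[i].gene_id for i, g in enumerate(groups)}
    # single-linkage over (chrom, strand) spans using exon overlap
    uf = _UnionFind(len(reps))
    by_cs: dict[tuple, list[int]] = defaultdict(list)
    for i, t in enumerate(reps):
        by_cs[(t.chrom, t.strand)].append(i)
    for idxs in by_cs.values():
        idxs = sorted(idxs, key=lambda i: reps[i].start)
        for a, b in zip(idxs, idxs[1:]):
            if reps[b].start < reps[a].end and any(
                ea.overlaps(eb) for ea in reps[a].exons for eb in reps[b].exons
            ):
                uf.union(a, b)
    return {
        g.representative: f"locus_{uf.find(i)}" for i, g in enumerate(groups)
    }


def count_isoforms_per_locus(groups: list[CollapseGroup]) -> dict[str, int]:
    """Isoform count per locus; values sum to the number of groups."""
    loci = assign_loci(groups)
    counts: dict[str, int] = defaultdict(int)
    for g in groups:
        counts[loci[g.representative]] += 1
    return dict(counts)
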