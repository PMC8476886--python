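"""Synthetic genome/transcriptome generator with ground-truth tables.

The simulator emulates the input a long-read isoform pipeline sees after
genome mapping: multi-exon gene loci with GT-AG introns, redundant
5'-degraded isoform copies, one planted alternative-splicing event per
derived isoform (ES / IR / A5S / A3S / MEE), coding transcripts carrying a
single planted ATG→stop ORF with biased codon usage, noncoding transcripts
produced by a dinucleotide-preserving shuffle, AATAAA polyadenylation
signals near the 3' terminus, and transposable-element insertions copied
(with 1% substitution noise) from a small consensus library into exons and
introns.  Every planted feature is recorded in a truth table so each
downstream stage can be scored exactly.

Construction happens in a gene-local plus-strand frame; minus-strand loci
are reverse-complemented as a whole, which guarantees that splice motifs
and ORFs remain correct on the transcribed strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .coding import find_longest_orf
from .io_formats import (
    reverse_complement,
    write_fasta,
    write_repeatmasker_out,
    write_transcripts_gff3,
)
from .models import ConfigError, GenomicInterval, RepeatFeature, TranscriptModel

EVENT_TYPES = ("ES", "IR", "A5S", "A3S", "MEE")

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
# biased usage (GC-ending codons preferred) so coding hexamer statistics are
# separable from shuffled background
_CODON_P = np.array([4.0 if c[2] in "GC" else 1.0 for c in _CODONS])
_CODON_P /= _CODON_P.sum()

_TE_CLASSES = ("LINE", "LTR", "DNA", "SINE", "Helitron", "Unknown")

# region mix for TE fragments landing in coding transcripts (5'UTR / 3'UTR /
# ORF interior), matching the observed dominance of UTR insertions
_CODING_REGION_P = {"FIVE_UTR": 0.26, "THREE_UTR": 0.69, "ORF": 0.05}
_P_TRANSPOSASE_GENE = 0.05  # coding TE gene whose ORF is itself a TE copy
_P_EXONIC = 0.7             # remaining insertions land in introns


@dataclass
class SimulationConfig:
    """Stated world for the simulator; defaults are seconds-scale."""

    seed: int = 0
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_len: tuple[int, int] = (80, 400)
    intron_len: tuple[int, int] = (60, 2000)
    n_te_families: int = 6
    te_len: tuple[int, int] = (100, 600)
    te_insertion_rate: float = 0.8
    p_coding: float = 0.6
    planted_events: dict[str, int] = field(
        default_factory=lambda: {t: 5 for t in EVENT_TYPES}
    )
    p_degraded_copy: float = 0.5
    p_polya_signal: float = 0.8
    orf_min_codons: int = 100

    def __post_init__(self) -> None:
        for name in ("te_insertion_rate",):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("p_coding", "p_degraded_copy", "p_polya_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} not in [0,1]")
        for name in ("exons_per_gene", "exon_len", "intron_len", "te_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"{name} range ({lo},{hi}) is empty or invalid")
        if self.n_genes < 0 or self.n_te_families < 0 or self.orf_min_codons < 1:
            raise ConfigError("counts must be non-negative")
        bad = set(self.planted_events) - set(EVENT_TYPES)
        if bad:
            raise ConfigError(f"unknown event types {bad}")
        if any(v < 0 for v in self.planted_events.values()):
            raise ConfigError("planted event counts must be >= 0")
        if self.intron_len[0] < 30:
            raise ConfigError("introns shorter than 30 bp cannot host GT..AG edits")


@dataclass
class TruthTables:
    """Ground truth emitted alongside the synthetic dataset."""

    redundancy_groups: list[list[str]]
    event_truth: list[tuple[str, str, tuple[str, str]]]
    coding_truth: dict[str, str]
    te_truth: dict[str, list[tuple[str, str]]]
    polya_truth: dict[str, bool]
    te_intronic: list[tuple[str, str, int, int]]

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        with open(os.path.join(outdir, "truth_redundancy.tsv"), "w") as fh:
            fh.write("group_id\ttranscript_id\n")
            for i, group in enumerate(self.redundancy_groups):
                for tid in sorted(group):
                    fh.write(f"G{i:05d}\t{tid}\n")
        with open(os.path.join(outdir, "truth_events.tsv"), "w") as fh:
            fh.write("event_type\tgene_id\ttranscript_a\ttranscript_b\n")
            for etype, gid, (a, b) in self.event_truth:
                fh.write(f"{etype}\t{gid}\t{a}\t{b}\n")
        with open(os.path.join(outdir, "truth_coding.tsv"), "w") as fh:
            fh.write("transcript_id\tlabel\n")
            for tid in sorted(self.coding_truth):
                fh.write(f"{tid}\t{self.coding_truth[tid]}\n")
        with open(os.path.join(outdir, "truth_te.tsv"), "w") as fh:
            fh.write("transcript_id\tfamily\tregion\n")
            for tid in sorted(self.te_truth):
                for fam, region in self.te_truth[tid]:
                    fh.write(f"{tid}\t{fam}\t{region}\n")
        with open(os.path.join(outdir, "truth_polya.tsv"), "w") as fh:
            fh.write("transcript_id\thas_signal\n")
            for tid in sorted(self.polya_truth):
                fh.write(f"{tid}\t{int(self.polya_truth[tid])}\n")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    repeats: list[RepeatFeature]
    truth: TruthTables
    transposase_families: set[str]
    te_classes: dict[str, str]

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        write_transcripts_gff3(
            self.transcripts, os.path.join(outdir, "transcripts.gff3")
        )
        write_repeatmasker_out(self.repeats, os.path.join(outdir, "repeats.out"))
        with open(os.path.join(outdir, "te_families.tsv"), "w") as fh:
            fh.write("family\tte_class\tis_transposase\n")
            for fam in sorted(self.te_classes):
                fh.write(
                    f"{fam}\t{self.te_classes[fam]}\t"
                    f"{int(fam in self.transposase_families)}\n"
                )
        self.truth.write(outdir)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _coding_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.choice(len(_CODONS), size=n, p=_CODON_P)
    return "".join(_CODONS[i] for i in idx)


def _orf_seq(rng: np.random.Generator, protein_len: int) -> str:
    """ATG + (protein_len - 1) sense codons + stop; nt length 3*protein_len+3."""
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + _coding_codons(rng, protein_len - 1) + stop


def _scrub_motif(seq: str, motif: str, start: int = 0, end: Optional[int] = None) -> str:
    """Destroy every occurrence of ``motif`` in seq[start:end] by one substitution."""
    end = len(seq) if end is None else end
    buf = bytearray(seq, "ascii")
    i = seq.find(motif, start)
    while i != -1 and i + len(motif) <= end:
        mid = i + len(motif) // 2
        buf[mid] = ord("C") if chr(buf[mid]) != "C" else ord("G")
        seq = buf.decode("ascii")
        i = seq.find(motif, i + 1)
    return seq


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    buf = list(seq)
    n_mut = rng.binomial(len(seq), rate)
    for pos in rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False):
        alts = [b for b in "ACGT" if b != buf[pos]]
        buf[pos] = alts[rng.integers(0, 3)]
    return "".join(buf)


def _recode_frame_stops(orf: str) -> str:
    """Remove internal in-frame stops (3rd base → C); keeps the final stop."""
    codons = [orf[i : i + 3] for i in range(0, len(orf) - 3, 3)]
    fixed = [c[:2] + "C" if c in _STOPS else c for c in codons]
    return "".join(fixed) + orf[-3:]


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul–Erickson Euler-path shuffle)
# ---------------------------------------------------------------------------

def shuffle_preserving_dinucleotides(seq: str, seed: int) -> str:
    """Random permutation of ``seq`` with identical dinucleotide counts.

    Builds the dinucleotide transition multigraph and samples a uniform-ish
    Eulerian path from the original start to the original end vertex: last
    outgoing edges are drawn until they form an arborescence into the end
    vertex, remaining edges are shuffled freely, and the path is walked.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT characters in sequence: {set(seq) - set('ACGT')}")
    rng = np.random.default_rng(seed)
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    start, end = seq[0], seq[-1]
    vertices = sorted(set(seq))
    if len(vertices) == 1:
        return seq

    def _arborescence_ok(last: dict[str, str]) -> bool:
        for v in vertices:
            if v == end or v not in adj:
                continue
            seen, cur = {v}, v
            while cur != end:
                cur = last.get(cur)
                if cur is None or cur in seen:
                    return False
                seen.add(cur)
        return True

    while True:
        last = {
            v: adj[v][rng.integers(0, len(adj[v]))]
            for v in vertices
            if v != end and v in adj and adj[v]
        }
        if _arborescence_ok(last):
            break

    ordered: dict[str, list[str]] = {}
    for v in vertices:
        if v not in adj:
            continue
        edges = list(adj[v])
        if v in last:
            edges.remove(last[v])
        rng.shuffle(edges)
        if v in last:
            edges.append(last[v])
        ordered[v] = edges

    out = [start]
    ptr = {v: 0 for v in ordered}
    cur = start
    for _ in range(len(seq) - 1):
        nxt = ordered[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

@dataclass
class _GeneDraft:
    """A gene locus in its local plus-strand frame."""

    gene_id: str
    strand: str
    local_seq: str = ""
    # transcript_id -> local exon list [(s, e), ...]
    isoforms: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    coding: dict[str, str] = field(default_factory=dict)
    polya: dict[str, bool] = field(default_factory=dict)
    te_records: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    te_local: list[tuple[str, int, int]] = field(default_factory=list)
    te_intronic_local: list[tuple[str, int, int]] = field(default_factory=list)
    groups: list[list[str]] = field(default_factory=list)
    event: Optional[tuple[str, tuple[str, str]]] = None


class _TeLibrary:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.consensus: dict[str, str] = {}
        self.te_class: dict[str, str] = {}
        self.transposase: set[str] = set()
        n_transposase = min(2, cfg.n_te_families) if cfg.n_te_families else 0
        min_tp_len = 3 * cfg.orf_min_codons + 6
        for i in range(cfg.n_te_families):
            fam = f"TEfam{i + 1}"
            self.te_class[fam] = _TE_CLASSES[i % len(_TE_CLASSES)]
            if i < n_transposase:
                # transposase family: the consensus is one long ORF
                lo = max(cfg.te_len[0], min_tp_len)
                hi = max(cfg.te_len[1], lo + 60)
                n_aa = int(rng.integers(lo, hi + 1)) // 3
                self.consensus[fam] = _orf_seq(rng, n_aa)
                self.transposase.add(fam)
            else:
                length = int(rng.integers(cfg.te_len[0], cfg.te_len[1] + 1))
                self.consensus[fam] = _rand_seq(rng, length)
        self.fragment_families = [
            f for f in sorted(self.consensus) if f not in self.transposase
        ] or sorted(self.consensus)


def _feasibility_check(cfg: SimulationConfig, n_noncoding: int) -> None:
    total_events = sum(cfg.planted_events.values())
    if total_events > n_noncoding:
        raise ConfigError(
            f"{total_events} planted events need {total_events} noncoding "
            f"multi-exon host genes but only {n_noncoding} are available"
        )
    k_max = cfg.exons_per_gene[1]
    need3 = {t for t in ("ES", "MEE") if cfg.planted_events.get(t, 0) > 0}
    need2 = {t for t in ("IR", "A5S", "A3S") if cfg.planted_events.get(t, 0) > 0}
    if need3 and k_max < 3:
        raise ConfigError(f"events {need3} need >=3 exons; exons_per_gene max is {k_max}")
    if need2 and k_max < 2:
        raise ConfigError(f"events {need2} need >=2 exons; exons_per_gene max is {k_max}")


def _sample_exon_intron_lens(
    rng: np.random.Generator, cfg: SimulationConfig, k: int, min_total: int
) -> tuple[list[int], list[int]]:
    lo, hi = cfg.exon_len
    for _ in range(60):
        exons = [int(rng.integers(lo, hi + 1)) for _ in range(k)]
        if sum(exons) >= min_total:
            break
    deficit = min_total - sum(exons)
    if deficit > 0:
        exons[-1] += deficit
    introns = [
        int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
        for _ in range(k - 1)
    ]
    return exons, introns


def _place_te_fragment(
    rng: np.random.Generator,
    tx: str,
    exon_tx_bounds: list[tuple[int, int]],
    target: tuple[int, int],
    consensus: str,
) -> Optional[tuple[str, int, int]]:
    """Overwrite tx with a consensus fragment inside one exon ∩ target.

    Returns (new_tx, tx_start, tx_end) or None when no window fits.
    """
    windows = []
    for es, ee in exon_tx_bounds:
        s, e = max(es, target[0]), min(ee, target[1])
        if e - s >= 60:
            windows.append((s, e))
    if not windows:
        return None
    s, e = windows[rng.integers(0, len(windows))]
    max_len = min(e - s - 10, len(consensus), 250)
    if max_len < 50:
        return None
    flen = int(rng.integers(50, max_len + 1))
    off = int(rng.integers(0, len(consensus) - flen + 1))
    pos = int(rng.integers(s, e - flen + 1))
    frag = _mutate(consensus[off : off + flen], 0.01, rng)
    return tx[:pos] + frag + tx[pos + flen :], pos, pos + flen


def _build_gene(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    lib: _TeLibrary,
    gene_idx: int,
    coding: bool,
    event_type: Optional[str],
    n_exonic_te: int,
    n_intronic_te: int,
    transposase_gene: bool,
) -> _GeneDraft:
    gene_id = f"G{gene_idx + 1:04d}"
    strand = "+" if rng.random() < 0.5 else "-"
    draft = _GeneDraft(gene_id=gene_id, strand=strand)

    # --- architecture -----------------------------------------------------
    k_lo, k_hi = cfg.exons_per_gene
    k = int(rng.integers(k_lo, k_hi + 1))
    if event_type in ("ES", "MEE"):
        k = max(k, 3)
    elif event_type in ("IR", "A5S", "A3S"):
        k = max(k, 2)

    orf_min_nt = 3 * cfg.orf_min_codons + 3
    if coding and not transposase_gene:
        min_total = 130 + orf_min_nt + 130
    else:
        min_total = 0
    if transposase_gene:
        tp_family = _pick_transposase(rng, lib)
        tp_consensus = lib.consensus[tp_family]
        utr5 = int(rng.integers(60, 201))
        pad = int(rng.integers(20, 61))
        exon_lens = [utr5 + len(tp_consensus) + pad, int(rng.integers(100, 251))]
        intron_lens = [int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))]
        k = 2
    else:
        exon_lens, intron_lens = _sample_exon_intron_lens(rng, cfg, k, min_total)

    # --- event geometry ---------------------------------------------------
    ev: dict = {}
    if event_type == "ES":
        ev["x"] = int(rng.integers(1, k - 1))
    elif event_type == "IR":
        ev["m"] = int(rng.integers(0, k - 1))
    elif event_type in ("A5S", "A3S"):
        m = int(rng.integers(0, k - 1))
        intron_lens[m] = max(intron_lens[m], 45)
        delta = int(rng.integers(9, min(31, intron_lens[m] - 29)))
        ev["m"], ev["delta"] = m, delta
    elif event_type == "MEE":
        x = int(rng.integers(1, k - 1))
        y_len = int(rng.integers(70, 121))
        intron_lens[x] = max(intron_lens[x], y_len + 60)
        y_off = int(rng.integers(20, intron_lens[x] - y_len - 21))
        ev.update(x=x, y_len=y_len, y_off=y_off)

    L = sum(exon_lens)
    base_id = f"{gene_id}.I1"

    # --- transcript sequence (with validation retries) --------------------
    orf_bounds: Optional[tuple[int, int]] = None
    for _attempt in range(40):
        te_placed: list[tuple[str, str, int, int]] = []  # family, region, s, e
        if transposase_gene:
            utr5_seq = _scrub_motif(_rand_seq(rng, utr5), "ATG")
            copy = _recode_frame_stops(
                "ATG" + _mutate(tp_consensus, 0.01, rng)[3:-3] + tp_consensus[-3:]
            )
            tail = _rand_seq(rng, L - utr5 - len(copy))
            tx = utr5_seq + copy + tail
            orf_bounds = (utr5, utr5 + len(copy))
            te_placed.append((tp_family, "ORF", utr5, utr5 + len(copy)))
        elif coding:
            utr5 = int(rng.integers(60, min(251, L - orf_min_nt - 129)))
            utr3 = int(rng.integers(60, min(251, L - orf_min_nt - utr5 + 1)))
            orf_nt = L - utr5 - utr3
            utr3 += orf_nt % 3
            orf_nt -= orf_nt % 3
            protein_len = orf_nt // 3 - 1
            tx = (
                _scrub_motif(_rand_seq(rng, utr5), "ATG")
                + _orf_seq(rng, protein_len)
                + _rand_seq(rng, utr3)
            )
            orf_bounds = (utr5, utr5 + orf_nt)
        else:
            # dinucleotide-preserving shuffle of a coding-like proto: the
            # noncoding class keeps coding composition but loses frame and
            # position structure
            if L >= orf_min_nt + 140:
                u5 = int(rng.integers(60, min(251, L - orf_min_nt - 69)))
                u3 = max(0, L - u5 - orf_min_nt)
                u3 -= (L - u5 - u3) % 3
                proto = (
                    _rand_seq(rng, u5)
                    + _orf_seq(rng, (L - u5 - u3) // 3 - 1)
                    + _rand_seq(rng, u3)
                )
            else:
                proto = _rand_seq(rng, L)
            tx = shuffle_preserving_dinucleotides(
                proto, int(rng.integers(0, 2**31 - 1))
            )
            orf_bounds = None

        # exon bounds in transcript coordinates
        bounds, pos = [], 0
        for el in exon_lens:
            bounds.append((pos, pos + el))
            pos += el

        # TE fragments (transposase copy already placed above)
        ok = True
        for _ in range(n_exonic_te):
            fam = lib.fragment_families[rng.integers(0, len(lib.fragment_families))]
            if coding:
                regions = list(_CODING_REGION_P)
                probs = np.array([_CODING_REGION_P[r] for r in regions])
                region = regions[rng.choice(len(regions), p=probs / probs.sum())]
                o_s, o_e = orf_bounds
                target = {
                    "FIVE_UTR": (10, o_s - 10),
                    "ORF": (o_s + 20, o_e - 20),
                    "THREE_UTR": (o_e + 10, L - 60),
                }[region]
            else:
                region, target = "NONCODING_EXON", (10, L - 60)
            placed = _place_te_fragment(rng, tx, bounds, target, lib.consensus[fam])
            if placed is None:
                continue
            tx, s, e = placed
            te_placed.append((fam, region, s, e))

        if orf_bounds is not None:
            o_s, o_e = orf_bounds
            # repair TE damage: no upstream starts, no internal stops
            tx = _scrub_motif(tx, "ATG", 0, o_s)
            tx = tx[:o_s] + _recode_frame_stops(tx[o_s:o_e]) + tx[o_e:]

        # polyA signal handling in the 3'-terminal window
        has_polya = rng.random() < cfg.p_polya_signal
        if has_polya:
            tx = tx[: L - 30] + "AATAAA" + tx[L - 24 :]
        else:
            tx = _scrub_motif(tx, "AATAAA", max(0, L - 55), L)

        if orf_bounds is None:
            # planted-noncoding transcripts must not carry a stop-terminated
            # ORF above the coding floor, or the truth label would be wrong
            spurious = find_longest_orf(tx, min_codons=cfg.orf_min_codons)
            if spurious is not None and spurious.has_stop:
                continue
        else:
            found = find_longest_orf(tx, min_codons=1)
            if found is None or (found.start, found.end) != orf_bounds:
                continue

        # --- locus assembly in local plus-strand frame --------------------
        parts: list[str] = []
        exon_local: list[tuple[int, int]] = []
        intron_local: list[tuple[int, int]] = []
        pos = 0
        tx_pos = 0
        tx_to_local: list[tuple[int, int, int]] = []  # (tx_s, tx_e, local_s)
        for j, el in enumerate(exon_lens):
            parts.append(tx[tx_pos : tx_pos + el])
            exon_local.append((pos, pos + el))
            tx_to_local.append((tx_pos, tx_pos + el, pos))
            tx_pos += el
            pos += el
            if j < len(intron_lens):
                il = intron_lens[j]
                fill = bytearray(("GT" + _rand_seq(rng, il - 4) + "AG").encode())
                if event_type == "A5S" and ev["m"] == j:
                    d = ev["delta"]
                    fill[d : d + 2] = b"GT"
                if event_type == "A3S" and ev["m"] == j:
                    d = ev["delta"]
                    fill[il - d - 2 : il - d] = b"AG"
                if event_type == "MEE" and ev["x"] == j:
                    yo, yl = ev["y_off"], ev["y_len"]
                    fill[yo - 2 : yo] = b"AG"
                    fill[yo : yo + yl] = _rand_seq(rng, yl).encode()
                    fill[yo + yl : yo + yl + 2] = b"GT"
                parts.append(fill.decode())
                intron_local.append((pos, pos + il))
                pos += il
        local_seq = "".join(parts)

        # --- derived isoform for the planted AS event ---------------------
        alt: Optional[list[tuple[int, int]]] = None
        if event_type is not None:
            exons = list(exon_local)
            if event_type == "ES":
                alt = exons[: ev["x"]] + exons[ev["x"] + 1 :]
            elif event_type == "IR":
                m = ev["m"]
                alt = exons[:m] + [(exons[m][0], exons[m + 1][1])] + exons[m + 2 :]
            elif event_type == "A5S":
                m = ev["m"]
                alt = list(exons)
                alt[m] = (alt[m][0], alt[m][1] + ev["delta"])
            elif event_type == "A3S":
                m = ev["m"]
                alt = list(exons)
                alt[m + 1] = (alt[m + 1][0] - ev["delta"], alt[m + 1][1])
            else:  # MEE
                x = ev["x"]
                i_s = intron_local[x][0]
                y = (i_s + ev["y_off"], i_s + ev["y_off"] + ev["y_len"])
                alt = exons[:x] + [y] + exons[x + 1 :]
            # derived isoforms splice in intron-derived sequence (or new
            # junctions); they carry the host's noncoding label, so they
            # must not gain a qualifying ORF either
            alt_seq = "".join(local_seq[s:e] for s, e in alt)
            spurious = find_longest_orf(alt_seq, min_codons=cfg.orf_min_codons)
            if spurious is not None and spurious.has_stop:
                continue
        break
    else:
        raise ConfigError(
            f"{gene_id}: could not realize sequences consistent with the "
            "planted coding labels"
        )

    draft.local_seq = local_seq
    draft.isoforms[base_id] = list(exon_local)
    draft.coding[base_id] = "coding" if orf_bounds is not None else "noncoding"
    draft.polya[base_id] = has_polya
    draft.te_records[base_id] = [(fam, region) for fam, region, _, _ in te_placed]

    # exonic TE records → local genomic coordinates (each is inside one exon)
    for fam, region, s, e in te_placed:
        for txs, txe, ls in tx_to_local:
            if txs <= s and e <= txe:
                draft.te_local.append((fam, ls + (s - txs), ls + (e - txs)))
                break

    # intronic TE insertions: recorded in the .out, absent from exonic truth;
    # they stay clear of splice boundaries and only occur in event-free genes,
    # so no isoform's spliced sequence changes
    for _ in range(n_intronic_te):
        if not intron_local:
            break
        fam = lib.fragment_families[rng.integers(0, len(lib.fragment_families))]
        cands = [iv for iv in intron_local if iv[1] - iv[0] >= 120]
        if not cands:
            continue
        i_s, i_e = cands[rng.integers(0, len(cands))]
        max_len = min(250, len(lib.consensus[fam]), i_e - i_s - 60)
        if max_len < 50:
            continue
        flen = int(rng.integers(50, max_len + 1))
        off = int(rng.integers(0, len(lib.consensus[fam]) - flen + 1))
        p0 = int(rng.integers(i_s + 25, i_e - flen - 25))
        frag = _mutate(lib.consensus[fam][off : off + flen], 0.01, rng)
        draft.local_seq = (
            draft.local_seq[:p0] + frag + draft.local_seq[p0 + flen :]
        )
        draft.te_intronic_local.append((fam, p0, p0 + flen))

    if alt is not None:
        alt_id = f"{gene_id}.I2"
        draft.isoforms[alt_id] = alt
        draft.coding[alt_id] = draft.coding[base_id]
        draft.polya[alt_id] = draft.polya[base_id]
        draft.te_records[alt_id] = []
        draft.event = (event_type, (base_id, alt_id))

    # --- 5'-degraded redundant copies --------------------------------------
    for iso_id in list(draft.isoforms):
        group = [iso_id]
        if rng.random() < cfg.p_degraded_copy:
            exons = draft.isoforms[iso_id]
            first_len = exons[0][1] - exons[0][0]
            cap = first_len - 30
            te_min = min(
                (s for _, _, s, e in te_placed), default=10**9
            ) if iso_id == base_id else 10**9
            cap = min(cap, 40, te_min - 10)
            if draft.coding[iso_id] == "coding" and orf_bounds is not None:
                cap = min(cap, orf_bounds[0] - 10)
            if cap >= 10:
                delta = int(rng.integers(10, cap + 1))
                copy_id = f"{iso_id}.D1"
                trimmed = [(exons[0][0] + delta, exons[0][1])] + exons[1:]
                draft.isoforms[copy_id] = trimmed
                draft.coding[copy_id] = draft.coding[iso_id]
                draft.polya[copy_id] = draft.polya[iso_id]
                draft.te_records[copy_id] = list(draft.te_records[iso_id])
                group.append(copy_id)
        draft.groups.append(group)
    return draft


def _pick_transposase(rng: np.random.Generator, lib: _TeLibrary) -> str:
    fams = sorted(lib.transposase)
    if not fams:
        raise ConfigError("transposase gene requested but no transposase family exists")
    return fams[rng.integers(0, len(fams))]


# ---------------------------------------------------------------------------
# top-level simulate
# ---------------------------------------------------------------------------

def simulate(
    config: SimulationConfig, outdir: Optional[str | os.PathLike] = None
) -> SimulatedDataset:
    """Generate genome, transcripts, repeats and truth tables.

    Identical seed → identical in-memory objects and byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    lib = _TeLibrary(config, rng)

    n_coding = int(round(config.p_coding * config.n_genes))
    coding_flags = np.zeros(config.n_genes, dtype=bool)
    coding_flags[:n_coding] = True
    rng.shuffle(coding_flags)
    noncoding_idx = [i for i in range(config.n_genes) if not coding_flags[i]]
    _feasibility_check(config, len(noncoding_idx))

    event_for_gene: dict[int, str] = {}
    cursor = 0
    for etype in EVENT_TYPES:
        for _ in range(config.planted_events.get(etype, 0)):
            event_for_gene[noncoding_idx[cursor]] = etype
            cursor += 1

    drafts: list[_GeneDraft] = []
    for gi in range(config.n_genes):
        etype = event_for_gene.get(gi)
        if etype is not None or config.n_te_families == 0:
            n_te = 0
        else:
            n_te = int(rng.poisson(config.te_insertion_rate))
        n_exonic = int(rng.binomial(n_te, _P_EXONIC)) if n_te else 0
        n_intronic = n_te - n_exonic
        transposase_gene = (
            bool(coding_flags[gi])
            and n_exonic > 0
            and bool(lib.transposase)
            and rng.random() < _P_TRANSPOSASE_GENE
        )
        if transposase_gene:
            n_exonic -= 1  # the ORF copy replaces one fragment insertion
        drafts.append(
            _build_gene(
                rng,
                config,
                lib,
                gi,
                coding=bool(coding_flags[gi]),
                event_type=etype,
                n_exonic_te=n_exonic,
                n_intronic_te=n_intronic,
                transposase_gene=transposase_gene,
            )
        )

    # --- place loci on chromosomes ----------------------------------------
    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    repeats: list[RepeatFeature] = []
    truth = TruthTables(
        redundancy_groups=[],
        event_truth=[],
        coding_truth={},
        te_truth={},
        polya_truth={},
        te_intronic=[],
    )
    genes_per_chrom = 50
    chrom_parts: list[str] = []
    chrom_name = ""
    offset = 0
    for gi, draft in enumerate(drafts):
        if gi % genes_per_chrom == 0:
            if chrom_parts:
                genome[chrom_name] = "".join(chrom_parts)
            chrom_name = f"chr{gi // genes_per_chrom + 1}"
            chrom_parts, offset = [], 0
        spacer = _rand_seq(rng, int(rng.integers(200, 801)))
        chrom_parts.append(spacer)
        offset += len(spacer)

        loc_len = len(draft.local_seq)
        seq = draft.local_seq
        if draft.strand == "-":
            seq = reverse_complement(seq)

        def _to_global(s: int, e: int) -> tuple[int, int]:
            if draft.strand == "-":
                return offset + loc_len - e, offset + loc_len - s
            return offset + s, offset + e

        chrom_parts.append(seq)

        for iso_id, exons_local in draft.isoforms.items():
            exons = [
                GenomicInterval(chrom_name, *_to_global(s, e), draft.strand)
                for s, e in exons_local
            ]
            transcripts.append(
                TranscriptModel(
                    transcript_id=iso_id,
                    exons=exons,
                    gene_id=draft.gene_id,
                    identity=1.0,
                    coverage=1.0,
                )
            )
            truth.coding_truth[iso_id] = draft.coding[iso_id]
            truth.polya_truth[iso_id] = draft.polya[iso_id]
            truth.te_truth[iso_id] = list(draft.te_records[iso_id])
        truth.redundancy_groups.extend(draft.groups)
        if draft.event is not None:
            etype, pair = draft.event
            truth.event_truth.append((etype, draft.gene_id, pair))

        for fam, s, e in draft.te_local:
            gs, ge = _to_global(s, e)
            repeats.append(
                RepeatFeature(
                    interval=GenomicInterval(chrom_name, gs, ge, draft.strand),
                    family=fam,
                    te_class=lib.te_class[fam],
                    is_transposase_family=fam in lib.transposase,
                )
            )
        for fam, s, e in draft.te_intronic_local:
            gs, ge = _to_global(s, e)
            repeats.append(
                RepeatFeature(
                    interval=GenomicInterval(chrom_name, gs, ge, draft.strand),
                    family=fam,
                    te_class=lib.te_class[fam],
                    is_transposase_family=fam in lib.transposase,
                )
            )
            truth.te_intronic.append((fam, chrom_name, gs, ge))
        offset += loc_len
    if chrom_parts:
        genome[chrom_name] = "".join(chrom_parts)

    # attach spliced sequences (single source of truth: the genome)
    from .io_formats import extract_spliced_sequence

    for t in transcripts:
        t.sequence = extract_spliced_sequence(t, genome)

    dataset = SimulatedDataset(
        config=config,
        genome=genome,
        transcripts=transcripts,
        repeats=repeats,
        truth=truth,
        transposase_families=set(lib.transposase),
        te_classes=dict(lib.te_class),
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
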