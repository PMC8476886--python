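"""Alternative-splicing event classification and consensus-motif matrices.

Events are extracted pairwise between isoforms as "bubbles": maximal regions
bounded by splice sites common to both transcripts (transcript termini count
as pseudo-flanks only when they coincide exactly) inside which the
exon-intron structures differ.  Each bubble is classified as one of the five
canonical types — exon skipping (ES), intron retention (IR), alternative 5'
or 3' splice site (A5S/A3S, donor/acceptor defined on the transcribed
strand) or mutually exclusive exons (MEE) — or as COMPLEX when the interior
matches none of them; COMPLEX regions are excluded from the five-type tally.

The motif side builds position frequency matrices anchored at annotated
splice junctions (donor: first intron base is offset +1; acceptor: last
intron base is offset -1) in transcribed-strand orientation, and ranks
polyadenylation-signal hexamers in the 3'-terminal window.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import reverse_complement
from .models import TranscriptModel

EVENT_TYPES = ("ES", "IR", "A5S", "A3S", "MEE")
COMPLEX = "COMPLEX"

#: canonical polyadenylation-signal hexamers, most common variants first
CANONICAL_PAS_HEXAMERS = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AATACA", "CATAAA",
    "AATATA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA", "AATAGA",
)


@dataclass(frozen=True)
class ASEvent:
    event_type: str
    chrom: str
    strand: str
    flank_left: int
    flank_right: int
    variant_coords: tuple[int, ...]
    transcript_pair: tuple[str, str]

    def key(self) -> tuple:
        """Deduplication key: ignores which transcript pair exhibited it."""
        return (
            self.event_type,
            self.chrom,
            self.strand,
            self.flank_left,
            self.flank_right,
            self.variant_coords,
        )


# ---------------------------------------------------------------------------
# pairwise classification
# ---------------------------------------------------------------------------

def _internal_sites(t: TranscriptModel) -> list[tuple[int, str]]:
    """Internal exon boundaries as (pos, kind); kind 'E' = exon end (donor
    side on +), 'S' = exon start (acceptor side on +)."""
    sites: list[tuple[int, str]] = []
    for i, e in enumerate(t.exons):
        if i > 0:
            sites.append((e.start, "S"))
        if i < t.n_exons - 1:
            sites.append((e.end, "E"))
    return sites


def _classify_region(
    strand: str,
    kL: str,
    kR: str,
    b1: list[tuple[int, str]],
    b2: list[tuple[int, str]],
) -> str:
    """Classify one differing bubble from the two interior boundary lists."""

    def _is_exon_chain(b: list[tuple[int, str]]) -> bool:
        kinds = [k for _, k in b]
        return (
            len(b) >= 2
            and len(b) % 2 == 0
            and kinds == ["S", "E"] * (len(b) // 2)
        )

    def _is_intron_chain(b: list[tuple[int, str]]) -> bool:
        kinds = [k for _, k in b]
        return (
            len(b) >= 2
            and len(b) % 2 == 0
            and kinds == ["E", "S"] * (len(b) // 2)
        )

    if not b1 or not b2:
        full, = [b for b in (b1, b2) if b]
        if kL == "E" and kR == "S" and _is_exon_chain(full):
            return "ES"
        if kL == "S" and kR == "E" and _is_intron_chain(full):
            return "IR" if len(full) == 2 else COMPLEX
        return COMPLEX
    if len(b1) == 1 and len(b2) == 1 and b1[0][1] == b2[0][1]:
        kind = b1[0][1]
        if kind == "E":  # differing donor on +, differing acceptor on -
            return "A5S" if strand == "+" else "A3S"
        return "A3S" if strand == "+" else "A5S"
    if (
        len(b1) == 2
        and len(b2) == 2
        and _is_exon_chain(b1)
        and _is_exon_chain(b2)
    ):
        (s1, _), (e1, _) = b1
        (s2, _), (e2, _) = b2
        if e1 <= s2 or e2 <= s1:  # non-overlapping alternative exons
            return "MEE"
    return COMPLEX


def classify_pair(t1: TranscriptModel, t2: TranscriptModel) -> list[ASEvent]:
    """All AS events between two isoforms on the same chromosome and strand.

    Symmetric in its arguments; returns an empty list for identical chains
    or non-overlapping transcripts.
    """
    if t1.chrom != t2.chrom or t1.strand != t2.strand:
        raise ValueError(
            f"{t1.transcript_id} and {t2.transcript_id} are on different "
            "chromosomes or strands"
        )
    if min(t1.end, t2.end) <= max(t1.start, t2.start):
        return []

    s1 = set(_internal_sites(t1))
    s2 = set(_internal_sites(t2))
    anchors = s1 & s2
    if t1.start == t2.start:
        anchors.add((t1.start, "S"))
    if t1.end == t2.end:
        anchors.add((t1.end, "E"))
    if len(anchors) < 2:
        return []
    ordered = sorted(anchors)

    pair = tuple(sorted((t1.transcript_id, t2.transcript_id)))
    events: list[ASEvent] = []
    for (pL, kL), (pR, kR) in zip(ordered, ordered[1:]):
        b1 = sorted(x for x in s1 if pL < x[0] < pR)
        b2 = sorted(x for x in s2 if pL < x[0] < pR)
        if b1 == b2:
            continue
        etype = _classify_region(t1.strand, kL, kR, b1, b2)
        variant = tuple(sorted({p for p, _ in b1} | {p for p, _ in b2}))
        events.append(
            ASEvent(
                event_type=etype,
                chrom=t1.chrom,
                strand=t1.strand,
                flank_left=pL,
                flank_right=pR,
                variant_coords=variant,
                transcript_pair=pair,
            )
        )
    return events


def collect_events(
    transcripts: Sequence[TranscriptModel],
) -> tuple[list[ASEvent], dict[str, int]]:
    """Deduplicated events over all same-locus isoform pairs + per-type tally.

    Pairs are compared when they share chromosome, strand and >=1 bp of
    exonic overlap.  COMPLEX regions are listed but excluded from the
    five-type counts.
    """
    seen: dict[tuple, ASEvent] = {}
    by_cs: dict[tuple, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_cs[(t.chrom, t.strand)].append(t)
    for group in by_cs.values():
        group = sorted(group, key=lambda t: (t.start, t.transcript_id))
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.start >= a.end:
                    break
                if not any(
                    ea.overlaps(eb) for ea in a.exons for eb in b.exons
                ):
                    continue
                for ev in classify_pair(a, b):
                    seen.setdefault(ev.key(), ev)
    events = sorted(
        seen.values(),
        key=lambda e: (e.chrom, e.flank_left, e.flank_right, e.event_type),
    )
    counts = {t: 0 for t in EVENT_TYPES}
    for e in events:
        if e.event_type in counts:
            counts[e.event_type] += 1
    return events, counts


def events_to_frame(events: Iterable[ASEvent]) -> pd.DataFrame:
    rows = [
        {
            "event_type": e.event_type,
            "chrom": e.chrom,
            "strand": e.strand,
            "flank_left": e.flank_left,
            "flank_right": e.flank_right,
            "variant_coords": ",".join(map(str, e.variant_coords)),
            "transcript_a": e.transcript_pair[0],
            "transcript_b": e.transcript_pair[1],
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_type", "chrom", "strand", "flank_left", "flank_right",
            "variant_coords", "transcript_a", "transcript_b",
        ],
    )


# ---------------------------------------------------------------------------
# position frequency matrices
# ---------------------------------------------------------------------------

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PositionFrequencyMatrix:
    """Per-position A/C/G/T counts around an anchored site.

    Offsets are junction-relative in transcribed-strand orientation and skip
    zero: +k is the k-th base downstream of the junction point, -k the k-th
    base upstream.  For a donor site the junction sits at the exon|intron
    boundary (+1 = first intron base); for an acceptor at the intron|exon
    boundary (-1 = last intron base).
    """

    window: tuple[int, int]
    counts: np.ndarray  # shape (4, width), rows A/C/G/T
    n_sites: int = 0
    n_skipped: int = 0

    @staticmethod
    def offsets(window: tuple[int, int]) -> list[int]:
        return [o for o in range(window[0], window[1] + 1) if o != 0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=list("ACGT"),
            columns=self.offsets(self.window),
        )

    def frequencies(self) -> np.ndarray:
        sums = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.counts / sums, 0.0)


def _window_sequence(
    chrom_seq: str, junction: int, strand: str, window: tuple[int, int]
) -> Optional[str]:
    """Bases at junction-relative offsets (skipping 0), transcribed sense."""
    offs = PositionFrequencyMatrix.offsets(window)
    if strand == "+":
        positions = [junction + o - 1 if o > 0 else junction + o for o in offs]
    else:
        positions = [junction - o if o > 0 else junction - o - 1 for o in offs]
    if min(positions) < 0 or max(positions) >= len(chrom_seq):
        return None
    bases = "".join(chrom_seq[p] for p in positions)
    return reverse_complement(bases)[::-1] if strand == "-" else bases


def junction_motif_matrix(
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, str],
    site: str,
    window: Optional[tuple[int, int]] = None,
) -> PositionFrequencyMatrix:
    """PFM over all annotated introns, anchored at donor or acceptor.

    Minus-strand introns are reverse-complemented so that every window reads
    5'→3' on the transcribed strand; out-of-bounds windows are skipped and
    counted in ``n_skipped``.
    """
    if site not in ("donor", "acceptor"):
        raise ValueError("site must be 'donor' or 'acceptor'")
    if window is None:
        window = (-3, 6) if site == "donor" else (-10, 3)
    width = len(PositionFrequencyMatrix.offsets(window))
    pfm = PositionFrequencyMatrix(window=window, counts=np.zeros((4, width), int))
    for t in transcripts:
        chrom_seq = genome.get(t.chrom)
        if chrom_seq is None:
            raise KeyError(f"chromosome {t.chrom} missing from genome")
        for intron in t.introns():
            if t.strand == "+":
                junction = intron.start if site == "donor" else intron.end
            else:
                junction = intron.end if site == "donor" else intron.start
            seq = _window_sequence(chrom_seq, junction, t.strand, window)
            if seq is None:
                pfm.n_skipped += 1
                continue
            for col, base in enumerate(seq):
                if base in _BASE_ROW:
                    pfm.counts[_BASE_ROW[base], col] += 1
            pfm.n_sites += 1
    return pfm


def tss_motif_matrix(
    transcripts: Sequence[TranscriptModel],
    genome: dict[str, str],
    window: tuple[int, int] = (-30, 10),
) -> PositionFrequencyMatrix:
    """PFM anchored at transcript 5' termini (junction = TSS); exploratory —
    the window is caller-chosen and no consensus claim is attached."""
    width = len(PositionFrequencyMatrix.offsets(window))
    pfm = PositionFrequencyMatrix(window=window, counts=np.zeros((4, width), int))
    for t in transcripts:
        chrom_seq = genome.get(t.chrom)
        if chrom_seq is None:
            raise KeyError(f"chromosome {t.chrom} missing from genome")
        junction = t.five_prime()
        seq = _window_sequence(chrom_seq, junction, t.strand, window)
        if seq is None:
            pfm.n_skipped += 1
            continue
        for col, base in enumerate(seq):
            if base in _BASE_ROW:
                pfm.counts[_BASE_ROW[base], col] += 1
        pfm.n_sites += 1
    return pfm


def plot_pfm_logo(pfm: PositionFrequencyMatrix, path: str, title: str = "") -> None:
    """Render a simple stacked-bar frequency logo of a PFM to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freq = pfm.frequencies()
    offsets = PositionFrequencyMatrix.offsets(pfm.window)
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(offsets)), 2.5))
    bottom = np.zeros(len(offsets))
    for i, base in enumerate("ACGT"):
        ax.bar(range(len(offsets)), freq[i], bottom=bottom,
               color=colors[base], label=base, width=0.85)
        bottom += freq[i]
    ax.set_xticks(range(len(offsets)))
    ax.set_xticklabels([f"{o:+d}" for o in offsets], fontsize=7)
    ax.set_ylabel("frequency")
    ax.set_title(title or f"n={pfm.n_sites}")
    ax.legend(ncol=4, fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# polyadenylation signal ranking
# ---------------------------------------------------------------------------

def polya_signal_rank(
    transcripts: Sequence[TranscriptModel],
    window_upstream: int = 50,
    hexamer_set: Sequence[str] = CANONICAL_PAS_HEXAMERS,
) -> pd.Series:
    """Frequency of each PAS hexamer in the 3'-terminal window.

    Each transcript contributes its single 3'-most match (scanning 3'→5');
    transcripts with no match count under ``none``.  Returned sorted by
    frequency, descending.
    """
    hexset = set(h.upper() for h in hexamer_set)
    counts: Counter = Counter()
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"{t.transcript_id}: sequence not attached")
        s = t.sequence.upper()
        tail = s[-window_upstream:] if len(s) > window_upstream else s
        hit = None
        for i in range(len(tail) - 6, -1, -1):
            if tail[i : i + 6] in hexset:
                hit = tail[i : i + 6]
                break
        counts[hit if hit is not None else "none"] += 1
    order = sorted(h for h in counts if h != "none")
    ser = pd.Series({h: counts[h] for h in order}, dtype=int)
    ser = ser.sort_values(ascending=False, kind="stable")
    if counts["none"]:
        ser = pd.concat([ser, pd.Series({"none": counts["none"]})])
    ser.name = "n_transcripts"
    return ser


# ---------------------------------------------------------------------------
# junction verification
# ---------------------------------------------------------------------------

def verify_against_junction_set(
    transcripts_or_junctions,
    reference: set[tuple[str, str, int, int]],
) -> tuple[float, list[tuple[tuple[str, str, int, int], bool]]]:
    """Fraction of introns present in a reference junction set.

    Accepts TranscriptModels (their introns are used) or raw
    ``(chrom, strand, intron_start, intron_end)`` tuples.  Returns
    (supported fraction, per-junction flags); 0.0 for an empty query.
    """
    junctions: list[tuple[str, str, int, int]] = []
    for item in transcripts_or_junctions:
        if isinstance(item, TranscriptModel):
            junctions.extend(
                (i.chrom, i.strand, i.start, i.end) for i in item.introns()
            )
        else:
            junctions.append(tuple(item))
    flags = [(j, j in reference) for j in junctions]
    if not junctions:
        return 0.0, []
    return sum(ok for _, ok in flags) / len(junctions), flags
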