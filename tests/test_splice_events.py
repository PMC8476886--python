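"""AS-event classification, motif matrices, polyA ranking, junction checks."""

from collections import Counter

import numpy as np
import pytest

from isoscape import splice_events as se
from isoscape.models import GenomicInterval, TranscriptModel

from conftest import make_transcript


def _types(events):
    return sorted(e.event_type for e in events)


# ---------------------------------------------------------------------------
# classify_pair: canonical examples
# ---------------------------------------------------------------------------

def test_exon_skipping():
    t1 = make_transcript([(0, 100), (200, 300), (400, 500)], tid="a")
    t2 = make_transcript([(0, 100), (400, 500)], tid="b")
    (ev,) = se.classify_pair(t1, t2)
    assert ev.event_type == "ES"
    assert (ev.flank_left, ev.flank_right) == (100, 400)
    assert ev.variant_coords == (200, 300)


def test_intron_retention():
    t1 = make_transcript([(0, 100), (200, 300)], tid="a")
    t2 = make_transcript([(0, 300)], tid="b")
    (ev,) = se.classify_pair(t1, t2)
    assert ev.event_type == "IR"
    assert (ev.flank_left, ev.flank_right) == (0, 300)


def test_alternative_donor_and_strand_flip():
    plus1 = make_transcript([(0, 100), (200, 300)], tid="a")
    plus2 = make_transcript([(0, 120), (200, 300)], tid="b")
    (ev,) = se.classify_pair(plus1, plus2)
    assert ev.event_type == "A5S"
    # identical coordinates on the minus strand: donor and acceptor swap
    minus1 = make_transcript([(0, 100), (200, 300)], tid="a", strand="-")
    minus2 = make_transcript([(0, 120), (200, 300)], tid="b", strand="-")
    (ev_m,) = se.classify_pair(minus1, minus2)
    assert ev_m.event_type == "A3S"


def test_alternative_acceptor():
    t1 = make_transcript([(0, 100), (200, 300)], tid="a")
    t2 = make_transcript([(0, 100), (180, 300)], tid="b")
    (ev,) = se.classify_pair(t1, t2)
    assert ev.event_type == "A3S"


def test_mutually_exclusive_exons():
    t1 = make_transcript([(0, 100), (150, 250), (400, 500)], tid="a")
    t2 = make_transcript([(0, 100), (300, 380), (400, 500)], tid="b")
    (ev,) = se.classify_pair(t1, t2)
    assert ev.event_type == "MEE"
    assert ev.variant_coords == (150, 250, 300, 380)


def test_identical_chains_no_events():
    t1 = make_transcript([(0, 100), (200, 300)], tid="a")
    t2 = make_transcript([(0, 100), (200, 300)], tid="b")
    assert se.classify_pair(t1, t2) == []


def test_overlapping_alternative_exons_are_complex():
    t1 = make_transcript([(0, 100), (150, 250), (400, 500)], tid="a")
    t2 = make_transcript([(0, 100), (200, 300), (400, 500)], tid="b")
    (ev,) = se.classify_pair(t1, t2)
    assert ev.event_type == se.COMPLEX


def test_different_strand_is_an_error():
    t1 = make_transcript([(0, 100)], tid="a", strand="+")
    t2 = make_transcript([(0, 100)], tid="b", strand="-")
    with pytest.raises(ValueError):
        se.classify_pair(t1, t2)


def test_termini_only_anchor_when_coinciding():
    # different 5' starts: the A5S-like difference has no left anchor, so
    # no event is called (truncation artifacts are not AS)
    t1 = make_transcript([(0, 100), (200, 300)], tid="a")
    t2 = make_transcript([(50, 120), (200, 300)], tid="b")
    assert se.classify_pair(t1, t2) == []
    # with coinciding 5' termini the same structure is a real A5S
    t3 = make_transcript([(0, 120), (200, 300)], tid="c")
    assert _types(se.classify_pair(t1, t3)) == ["A5S"]


def test_classify_pair_is_symmetric(dataset):
    by_id = {t.transcript_id: t for t in dataset.transcripts}
    for etype, _, (a, b) in dataset.truth.event_truth:
        e1 = se.classify_pair(by_id[a], by_id[b])
        e2 = se.classify_pair(by_id[b], by_id[a])
        assert [ev.key() for ev in e1] == [ev.key() for ev in e2]
        assert _types(e1) == [etype]


def test_strand_equivariance(dataset):
    """Flipping strand at fixed coordinates swaps A5S<->A3S and preserves
    ES/IR/MEE; mirroring coordinates AND flipping strand leaves the
    transcribed structure — hence every event type — unchanged."""
    swap = {"A5S": "A3S", "A3S": "A5S", "ES": "ES", "IR": "IR", "MEE": "MEE"}
    by_id = {t.transcript_id: t for t in dataset.transcripts}
    M = 10_000_000

    def flip(t):
        return TranscriptModel(
            transcript_id=t.transcript_id,
            exons=[
                GenomicInterval(e.chrom, e.start, e.end,
                                "-" if e.strand == "+" else "+")
                for e in t.exons
            ],
        )

    def mirror_flip(t):
        return TranscriptModel(
            transcript_id=t.transcript_id,
            exons=[
                GenomicInterval(e.chrom, M - e.end, M - e.start,
                                "-" if e.strand == "+" else "+")
                for e in t.exons
            ],
        )

    for etype, _, (a, b) in dataset.truth.event_truth:
        (flipped,) = se.classify_pair(flip(by_id[a]), flip(by_id[b]))
        assert flipped.event_type == swap[etype]
        (mirrored,) = se.classify_pair(mirror_flip(by_id[a]),
                                       mirror_flip(by_id[b]))
        assert mirrored.event_type == etype


# ---------------------------------------------------------------------------
# collect_events
# ---------------------------------------------------------------------------

def test_collect_events_deduplicates_shared_events():
    # three isoform pairs exhibiting the same skipping event
    t1 = make_transcript([(0, 100), (200, 300), (400, 500)], tid="a")
    t2 = make_transcript([(0, 100), (400, 500)], tid="b")
    t3 = make_transcript([(0, 100), (200, 300), (400, 500), (600, 700)], tid="c")
    events, counts = se.collect_events([t1, t2, t3])
    assert counts["ES"] == 1
    assert sum(counts.values()) == 1


def test_collect_events_no_multi_isoform_loci(sim_cache):
    ds = sim_cache(3, n_genes=40, p_degraded_copy=0.0, planted_events={})
    events, counts = se.collect_events(ds.transcripts)
    assert events == [] and sum(counts.values()) == 0


def test_collect_events_recovers_planted_counts(dataset, representatives):
    _, counts = se.collect_events(representatives)
    planted = Counter(e for e, _, _ in dataset.truth.event_truth)
    assert counts == dict(planted)


# ---------------------------------------------------------------------------
# motif matrices
# ---------------------------------------------------------------------------

def test_donor_acceptor_matrices_are_canonical(dataset, representatives):
    donor = se.junction_motif_matrix(representatives, dataset.genome, "donor")
    acceptor = se.junction_motif_matrix(representatives, dataset.genome,
                                        "acceptor")
    offs_d = se.PositionFrequencyMatrix.offsets(donor.window)
    offs_a = se.PositionFrequencyMatrix.offsets(acceptor.window)
    fd, fa = donor.frequencies(), acceptor.frequencies()
    # GT at intron positions +1/+2; AG at -2/-1 (rows A,C,G,T)
    assert fd[2, offs_d.index(1)] == 1.0 and fd[3, offs_d.index(2)] == 1.0
    assert fa[0, offs_a.index(-2)] == 1.0 and fa[2, offs_a.index(-1)] == 1.0
    assert donor.n_sites > 0 and donor.n_skipped == 0
    # conservation: every column sums to n_sites
    assert (donor.counts.sum(axis=0) == donor.n_sites).all()
    assert (acceptor.counts.sum(axis=0) == acceptor.n_sites).all()


def test_motif_matrix_zero_introns():
    t = make_transcript([(10, 60)], tid="mono")
    pfm = se.junction_motif_matrix([t], {"chr1": "A" * 100}, "donor")
    assert pfm.n_sites == 0 and pfm.counts.sum() == 0


def test_motif_window_beyond_chromosome_is_skipped():
    t = make_transcript([(0, 4), (8, 12)], tid="edge")
    pfm = se.junction_motif_matrix([t], {"chr1": "A" * 12}, "acceptor",
                                   window=(-10, 3))
    assert pfm.n_skipped == 1 and pfm.n_sites == 0


def test_tss_matrix_counts(dataset, representatives):
    pfm = se.tss_motif_matrix(representatives, dataset.genome, window=(-5, 5))
    assert pfm.n_sites + pfm.n_skipped == len(representatives)
    assert (pfm.counts.sum(axis=0) == pfm.n_sites).all()


# ---------------------------------------------------------------------------
# polyA signal ranking
# ---------------------------------------------------------------------------

def test_polya_rank_recovers_planted_signal(dataset, representatives):
    rank = se.polya_signal_rank(representatives)
    assert rank.index[0] == "AATAAA"
    planted = sum(
        dataset.truth.polya_truth[t.transcript_id] for t in representatives
    )
    assert rank.iloc[0] >= 0.9 * planted
    # each transcript contributes at most one hexamer
    assert rank.sum() <= len(representatives) + rank.get("none", 0)


def test_polya_no_match_counts_none():
    t = make_transcript([(0, 60)], tid="x", sequence="C" * 60)
    rank = se.polya_signal_rank([t])
    assert rank.get("none", 0) == 1


def test_polya_short_transcript_scanned_in_full():
    t = make_transcript([(0, 20)], tid="x", sequence="CCCCCCAATAAACCCCCCCC")
    rank = se.polya_signal_rank([t], window_upstream=50)
    assert rank.index[0] == "AATAAA"


# ---------------------------------------------------------------------------
# junction verification
# ---------------------------------------------------------------------------

def test_verify_against_junction_set():
    t = make_transcript([(0, 100), (200, 300), (400, 500)], tid="a")
    juncs = [("chr1", "+", 100, 200), ("chr1", "+", 300, 400)]
    frac, flags = se.verify_against_junction_set([t], set(juncs))
    assert frac == 1.0
    frac_half, _ = se.verify_against_junction_set([t], {juncs[0]})
    assert frac_half == 0.5
    frac_none, flags = se.verify_against_junction_set([t], set())
    assert frac_none == 0.0 and all(ok is False for _, ok in flags)
    assert se.verify_against_junction_set([], set()) == (0.0, [])
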