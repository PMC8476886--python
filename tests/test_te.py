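"""TE projection/annotation, transposase split, proportion test, enrichment."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from isoscape import coding, te as tm
from isoscape.coding import OrfAnnotation
from isoscape.models import GenomicInterval, RepeatFeature, TermAnnotationMap

from conftest import make_transcript


def _interval(s, e, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, s, e, strand)


# ---------------------------------------------------------------------------
# project_to_transcript
# ---------------------------------------------------------------------------

def test_projection_plus_strand_single_exon():
    t = make_transcript([(100, 200)])
    assert tm.project_to_transcript(t, _interval(150, 180)) == [(50, 80)]


def test_projection_minus_strand_single_exon():
    t = make_transcript([(100, 200)], strand="-")
    assert tm.project_to_transcript(t, _interval(150, 180)) == [(20, 50)]


def test_projection_intronic_feature_is_empty():
    t = make_transcript([(0, 100), (200, 300)])
    assert tm.project_to_transcript(t, _interval(120, 180)) == []
    assert tm.project_to_transcript(t, _interval(120, 180, chrom="chr2")) == []


def test_projection_bridging_feature_merges_fragments():
    t = make_transcript([(0, 100), (200, 300)])
    # spans the intron: 40 bp in exon 1 + 30 bp in exon 2, adjacent in tx
    assert tm.project_to_transcript(t, _interval(60, 230)) == [(60, 130)]


def test_projection_agrees_with_per_base_oracle():
    """Brute-force oracle: walk every transcript base and mark overlap."""
    rng = np.random.default_rng(3)
    for trial in range(40):
        n_ex = int(rng.integers(1, 5))
        pos, exons = 0, []
        for _ in range(n_ex):
            pos += int(rng.integers(10, 200))
            length = int(rng.integers(20, 300))
            exons.append((pos, pos + length))
            pos += length
        strand = "+" if trial % 2 == 0 else "-"
        t = make_transcript(exons, strand=strand)
        f_start = int(rng.integers(0, pos))
        feature = _interval(f_start, f_start + int(rng.integers(5, 400)))
        # oracle: per-base genomic→transcript walk
        tx_positions = []
        genome_order = []
        for e in exons:
            genome_order.extend(range(e[0], e[1]))
        if strand == "-":
            genome_order = genome_order[::-1]
        covered = sorted(
            i for i, g in enumerate(genome_order)
            if feature.start <= g < feature.end
        )
        expected = []
        for i in covered:
            if expected and expected[-1][1] == i:
                expected[-1] = (expected[-1][0], i + 1)
            else:
                expected.append((i, i + 1))
        got = tm.project_to_transcript(t, feature)
        assert got == [tuple(x) for x in expected]


# ---------------------------------------------------------------------------
# annotate_te_overlaps
# ---------------------------------------------------------------------------

def _repeat(s, e, family="FamA", **kw):
    return RepeatFeature(interval=_interval(s, e), family=family, **kw)


def test_lncRNA_overlap_is_noncoding_exon():
    t = make_transcript([(0, 500)], tid="lnc1")
    records, summary = tm.annotate_te_overlaps(
        [t], {"lnc1": True}, {}, [_repeat(100, 150)], min_overlap=10
    )
    (r,) = records
    assert r.regions == {"NONCODING_EXON"}
    assert r.overlap_bp == 50 and r.orf_overlap_fraction == 0.0
    assert summary.n_lnc_te == 1 and summary.n_te_transcripts == 1


def test_coding_region_localization_by_hand():
    t = make_transcript([(0, 600)], tid="cod1")
    orf = OrfAnnotation(start=100, end=400, frame=0, protein="M" * 99,
                        transcript_id="cod1")
    records, _ = tm.annotate_te_overlaps(
        [t], {"cod1": False}, {"cod1": orf},
        [_repeat(420, 480, family="F3"), _repeat(80, 120, family="F5")],
        min_overlap=10,
    )
    by_fam = {r.family: r for r in records}
    assert by_fam["F3"].regions == {"THREE_UTR"}
    # fragment spanning the ORF start contributes to both regions
    assert by_fam["F5"].regions == {"FIVE_UTR", "ORF"}
    assert by_fam["F5"].covers_orf_start
    assert by_fam["F5"].orf_overlap_fraction == pytest.approx(20 / 300)


def test_min_overlap_gate():
    t = make_transcript([(0, 500)], tid="lnc1")
    records, summary = tm.annotate_te_overlaps(
        [t], {"lnc1": True}, {}, [_repeat(100, 108)], min_overlap=10
    )
    assert records == [] and summary.n_te_transcripts == 0


def test_coding_without_orf_errors():
    t = make_transcript([(0, 500)], tid="c1")
    with pytest.raises(ValueError, match="lacks an ORF"):
        tm.annotate_te_overlaps([t], {"c1": False}, {}, [], 10)


def test_annotation_recovers_simulator_truth(dataset, representatives):
    truth_lnc = {
        t.transcript_id: dataset.truth.coding_truth[t.transcript_id]
        == "noncoding"
        for t in representatives
    }
    orfs = coding.annotate_orfs(
        [t for t in representatives if not truth_lnc[t.transcript_id]],
        min_codons=1,
    )
    records, summary = tm.annotate_te_overlaps(
        representatives, truth_lnc, orfs, dataset.repeats, min_overlap=10
    )
    got: dict[str, list] = {}
    for r in records:
        got.setdefault(r.transcript_id, []).extend(
            (r.family, reg) for reg in r.regions
        )
    rep_ids = {t.transcript_id for t in representatives}
    expected = {
        tid: sorted(v)
        for tid, v in dataset.truth.te_truth.items()
        if v and tid in rep_ids
    }
    assert {tid: sorted(v) for tid, v in got.items()} == expected
    # conservation: lncRNA + coding TE carriers = all TE transcripts
    assert summary.n_lnc_te + summary.n_coding_te == summary.n_te_transcripts
    assert summary.n_transposase + summary.n_fragment_carriers == summary.n_coding_te


def test_intronic_insertions_do_not_exonize(dataset, representatives):
    """TEs recorded in the .out but landing in introns yield no records."""
    truth_lnc = {
        t.transcript_id: dataset.truth.coding_truth[t.transcript_id]
        == "noncoding"
        for t in representatives
    }
    orfs = coding.annotate_orfs(
        [t for t in representatives if not truth_lnc[t.transcript_id]],
        min_codons=1,
    )
    intronic_only = [
        RepeatFeature(interval=GenomicInterval(chrom, s, e), family=fam)
        for fam, chrom, s, e in dataset.truth.te_intronic
    ]
    assert len(intronic_only) > 0
    records, _ = tm.annotate_te_overlaps(
        representatives, truth_lnc, orfs, intronic_only, min_overlap=10
    )
    assert records == []


# ---------------------------------------------------------------------------
# transposase classification
# ---------------------------------------------------------------------------

def test_transposase_by_orf_coverage():
    r_hi = tm.TeOverlapRecord("t1", "F", 300, 100, 400, {"ORF"},
                              orf_overlap_fraction=0.9)
    r_lo = tm.TeOverlapRecord("t2", "F", 60, 420, 480, {"THREE_UTR"},
                              orf_overlap_fraction=0.0)
    parts = tm.classify_transposase([r_hi, r_lo])
    assert parts["transposase_coding"] == {"t1"}
    assert parts["fragment_carrier"] == {"t2"}


def test_transposase_by_family_flag_at_orf_start():
    r = tm.TeOverlapRecord("t1", "TP", 80, 90, 170, {"FIVE_UTR", "ORF"},
                           orf_overlap_fraction=0.2,
                           is_transposase_family=True, covers_orf_start=True)
    parts = tm.classify_transposase([r])
    assert parts["transposase_coding"] == {"t1"}


def test_transposase_simulator_truth(dataset, representatives):
    truth_lnc = {
        t.transcript_id: dataset.truth.coding_truth[t.transcript_id]
        == "noncoding"
        for t in representatives
    }
    orfs = coding.annotate_orfs(
        [t for t in representatives if not truth_lnc[t.transcript_id]],
        min_codons=1,
    )
    records, _ = tm.annotate_te_overlaps(
        representatives, truth_lnc, orfs, dataset.repeats, min_overlap=10
    )
    parts = tm.classify_transposase(records)
    expected = {
        tid
        for tid, recs in dataset.truth.te_truth.items()
        if any(fam in dataset.transposase_families and reg == "ORF"
               for fam, reg in recs)
        and tid in {t.transcript_id for t in representatives}
    }
    assert parts["transposase_coding"] == expected


# ---------------------------------------------------------------------------
# two-proportion z-test
# ---------------------------------------------------------------------------

def test_ztest_headline_proportions_significant():
    res = tm.two_proportion_ztest(5691, 7253, 5980, 18717)
    assert res.p1 == pytest.approx(0.785, abs=0.001)
    assert res.p2 == pytest.approx(0.319, abs=0.001)
    assert res.p_value < 0.01


def test_ztest_null_identity():
    res = tm.two_proportion_ztest(5, 10, 50, 100)
    assert res.z == 0.0 and res.p_value == 1.0


def test_ztest_degenerate_pooled_proportion():
    assert tm.two_proportion_ztest(0, 10, 0, 20).p_value == 1.0
    assert tm.two_proportion_ztest(10, 10, 20, 20).z == 0.0


def test_ztest_invalid_counts_error():
    with pytest.raises(ValueError):
        tm.two_proportion_ztest(11, 10, 1, 10)


@pytest.mark.parametrize(
    "x1,n1,x2,n2",
    [(8, 10, 2, 10), (5691, 7253, 5980, 18717), (1, 7, 3, 9), (40, 80, 41, 81)],
)
def test_ztest_squared_equals_chi_square(x1, n1, x2, n2):
    """z² must equal the Pearson chi-square statistic (no continuity corr.)."""
    res = tm.two_proportion_ztest(x1, n1, x2, n2)
    table = [[x1, n1 - x1], [x2, n2 - x2]]
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    assert res.z**2 == pytest.approx(chi2, abs=1e-9)


def test_ztest_matches_statsmodels():
    from statsmodels.stats.proportion import proportions_ztest

    z, p = proportions_ztest([8, 2], [10, 10])
    res = tm.two_proportion_ztest(8, 10, 2, 10)
    assert res.z == pytest.approx(z) and res.p_value == pytest.approx(p)


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def _enumeration_pvalue(N, K, n, k):
    """P[X >= k] by exhaustive counting over all C(N, n) study sets."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return hits / total


def test_enrichment_matches_exhaustive_enumeration():
    universe = {f"g{i}" for i in range(12)}
    annot = TermAnnotationMap(
        gene_to_terms={f"g{i}": {"T"} for i in range(5)}
    )
    for study_genes in [{"g0", "g1", "g2"}, {"g0", "g5", "g6", "g7"},
                        {"g0", "g1", "g2", "g3", "g4"}]:
        results = tm.hypergeom_enrichment(study_genes, universe, annot)
        (res,) = results
        k = len(study_genes & {f"g{i}" for i in range(5)})
        assert res.p_value == pytest.approx(
            _enumeration_pvalue(12, 5, len(study_genes), k), abs=1e-12
        )


def test_enrichment_universal_term_p_is_one():
    universe = {f"g{i}" for i in range(8)}
    annot = TermAnnotationMap(gene_to_terms={g: {"ALL"} for g in universe})
    (res,) = tm.hypergeom_enrichment({"g0", "g1"}, universe, annot)
    assert res.p_value == pytest.approx(1.0)


def test_enrichment_bh_properties():
    rng = np.random.default_rng(1)
    universe = {f"g{i}" for i in range(40)}
    gene_to_terms = {}
    for i, g in enumerate(sorted(universe)):
        gene_to_terms[g] = {f"T{j}" for j in rng.choice(8, 3, replace=False)}
    annot = TermAnnotationMap(gene_to_terms=gene_to_terms)
    study = set(sorted(universe)[:10])
    results = tm.hypergeom_enrichment(study, universe, annot)
    assert results, "expected at least one tested term"
    # q >= p everywhere, and q non-decreasing in p-rank order
    assert all(r.q_value >= r.p_value for r in results)
    qs = [r.q_value for r in results]  # results sorted by p
    assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
    assert all(r.k <= min(r.K, r.n) for r in results)


def test_enrichment_study_outside_universe_errors():
    annot = TermAnnotationMap(gene_to_terms={"g1": {"T"}})
    with pytest.raises(ValueError):
        tm.hypergeom_enrichment({"gX"}, {"g1"}, annot)
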