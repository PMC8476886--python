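"""End-to-end orchestration: simulate/load → filter+collapse → events/motifs
→ lncRNA calling → TE exonization → summary & report.

Every stage logs its in/out counts; ``run_all`` is deterministic given the
seed and writes a fixed set of artifacts into the output directory
(nr.gff3, events.tsv, motifs/, verdicts.tsv, orfs.tsv, te_report.tsv,
summary.json, report.txt).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import coding, collapse as collapse_mod, splice_events, te as te_mod
from .io_formats import (
    extract_spliced_sequence,
    read_fasta,
    read_repeat_library_tsv,
    read_repeatmasker_out,
    read_transcripts_gff3,
    write_transcripts_gff3,
)
from .models import IsoscapeError, TranscriptModel
from .simulate import SimulatedDataset, SimulationConfig, simulate

logger = logging.getLogger("isoscape")

ALL_STAGES = ("collapse", "events", "motifs", "classify", "te")
_LEN_BINS = (("<1kb", 0, 1000), ("1-2kb", 1000, 2000), ("2-3kb", 2000, 3000),
             ("3-6kb", 3000, 6000), (">6kb", 6000, float("inf")))


@dataclass
class PipelineConfig:
    outdir: str = "isoscape_out"
    seed: int = 0
    # inputs: either simulate=True or explicit paths
    simulate: bool = False
    sim_config: Optional[SimulationConfig] = None
    gff: Optional[str] = None
    genome_fasta: Optional[str] = None
    repeats_out: Optional[str] = None
    repeat_library: Optional[str] = None
    # stage parameters
    collapse: collapse_mod.CollapseConfig = field(
        default_factory=collapse_mod.CollapseConfig
    )
    orf_min_codons: int = coding.DEFAULT_ORF_MIN_CODONS
    fickett_threshold: float = coding.DEFAULT_FICKETT_THRESHOLD
    hexamer_threshold: float = 0.0
    min_lnc_len: int = coding.DEFAULT_MIN_LNC_LEN
    min_overlap: int = te_mod.DEFAULT_MIN_OVERLAP
    transposase_threshold: float = te_mod.DEFAULT_TRANSPOSASE_ORF_FRACTION
    polya_window: int = 50
    stages: tuple[str, ...] = ALL_STAGES


def _length_histogram(transcripts) -> dict[str, int]:
    hist = {name: 0 for name, _, _ in _LEN_BINS}
    for t in transcripts:
        for name, lo, hi in _LEN_BINS:
            if lo <= t.length < hi:
                hist[name] += 1
                break
    return hist


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        sim_cfg = cfg.sim_config or SimulationConfig(seed=cfg.seed)
        dataset: SimulatedDataset = simulate(
            sim_cfg, outdir=os.path.join(cfg.outdir, "sim")
        )
        return dataset.transcripts, dataset.genome, dataset.repeats
    if not (cfg.gff and cfg.genome_fasta):
        raise IsoscapeError("need --gff and --fasta (or simulate=True)")
    transcripts = read_transcripts_gff3(cfg.gff)
    genome = read_fasta(cfg.genome_fasta)
    for t in transcripts:
        t.sequence = extract_spliced_sequence(t, genome)
    repeats = []
    if cfg.repeats_out:
        transposase = set()
        if cfg.repeat_library:
            lib = read_repeat_library_tsv(cfg.repeat_library)
            transposase = {f for f, meta in lib.items() if meta["is_transposase"]}
        repeats = read_repeatmasker_out(cfg.repeats_out, transposase)
    return transcripts, genome, repeats


def run_all(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the summary dict (also written as
    summary.json).  Any stage failure aborts with the stage name; artifacts
    written by earlier stages are preserved."""
    os.makedirs(cfg.outdir, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    stage = "load"
    try:
        transcripts, genome, repeats = _load_inputs(cfg)
        logger.info("loaded %d transcripts, %d repeats", len(transcripts),
                    len(repeats))
        summary["n_input_transcripts"] = len(transcripts)

        stage = "collapse"
        kept, discarded = collapse_mod.filter_alignments(transcripts, cfg.collapse)
        summary["n_filtered_out"] = len(discarded)
        groups = collapse_mod.collapse_redundant(kept, cfg.collapse)
        reps = [g.representative_model for g in groups]
        logger.info("collapse: %d → %d non-redundant isoforms", len(kept),
                    len(groups))
        summary["n_nrhqci"] = len(groups)
        summary["length_histogram"] = _length_histogram(reps)
        summary["isoforms_per_locus"] = _locus_histogram(groups)
        if "collapse" in cfg.stages:
            write_transcripts_gff3(reps, os.path.join(cfg.outdir, "nr.gff3"))
            pd.DataFrame(
                [
                    {"representative": g.representative,
                     "n_members": len(g.members),
                     "members": ",".join(sorted(g.members))}
                    for g in groups
                ]
            ).to_csv(os.path.join(cfg.outdir, "collapse.tsv"), sep="\t",
                     index=False)

        if "events" in cfg.stages:
            stage = "events"
            events, counts = splice_events.collect_events(reps)
            splice_events.events_to_frame(events).to_csv(
                os.path.join(cfg.outdir, "events.tsv"), sep="\t", index=False
            )
            n_complex = sum(1 for e in events if e.event_type ==
                            splice_events.COMPLEX)
            summary["as_event_counts"] = {**counts, "COMPLEX": n_complex}
            logger.info("events: %d (complex: %d)", len(events), n_complex)

        if "motifs" in cfg.stages:
            stage = "motifs"
            motif_dir = os.path.join(cfg.outdir, "motifs")
            os.makedirs(motif_dir, exist_ok=True)
            consensus = {}
            for site in ("donor", "acceptor"):
                pfm = splice_events.junction_motif_matrix(reps, genome, site)
                df = pfm.to_dataframe()
                df.to_csv(os.path.join(motif_dir, f"{site}_pfm.tsv"), sep="\t")
                if pfm.n_sites:
                    freq = pfm.frequencies()
                    consensus[site] = "".join(
                        "ACGT"[i] for i in freq.argmax(axis=0)
                    )
            rank = splice_events.polya_signal_rank(
                reps, window_upstream=cfg.polya_window
            )
            rank.to_csv(os.path.join(motif_dir, "polya_hexamers.tsv"), sep="\t")
            summary["motifs"] = {
                "consensus": consensus,
                "polya_top": rank.index[0] if len(rank) else None,
            }

        verdicts = None
        orfs = None
        if "classify" in cfg.stages or "te" in cfg.stages:
            stage = "classify"
            caller = coding.LncRnaCaller(
                orf_min_codons=cfg.orf_min_codons,
                fickett_threshold=cfg.fickett_threshold,
                hexamer_threshold=cfg.hexamer_threshold,
                min_lnc_len=cfg.min_lnc_len,
            )
            verdicts = coding.call_lncRNA(reps, caller=caller)
            orfs = coding.annotate_orfs(reps, min_codons=1)
            n_lnc = sum(v.is_lncRNA for v in verdicts)
            summary["n_lncRNA"] = n_lnc
            summary["n_coding"] = len(verdicts) - n_lnc
            logger.info("classify: %d lncRNA / %d coding", n_lnc,
                        len(verdicts) - n_lnc)
            pd.DataFrame(
                [
                    {"transcript_id": v.transcript_id,
                     "is_lncRNA": int(v.is_lncRNA),
                     **{f"scorer_{k}": s for k, s in v.per_scorer.items()}}
                    for v in verdicts
                ]
            ).to_csv(os.path.join(cfg.outdir, "verdicts.tsv"), sep="\t",
                     index=False)
            pd.DataFrame(
                [
                    {"transcript_id": tid, "start": o.start, "end": o.end,
                     "frame": o.frame, "has_stop": int(o.has_stop),
                     "protein_length": len(o.protein)}
                    for tid, o in sorted(orfs.items())
                ]
            ).to_csv(os.path.join(cfg.outdir, "orfs.tsv"), sep="\t", index=False)

        if "te" in cfg.stages:
            stage = "te"
            # coding-classified transcripts without any ORF cannot be
            # region-localized; they are excluded and counted
            vmap = {v.transcript_id: v for v in verdicts}
            usable = [
                t for t in reps
                if vmap[t.transcript_id].is_lncRNA or t.transcript_id in orfs
            ]
            summary["n_coding_without_orf"] = len(reps) - len(usable)
            records, exo = te_mod.annotate_te_overlaps(
                usable,
                {t.transcript_id: vmap[t.transcript_id] for t in usable},
                orfs,
                repeats,
                min_overlap=cfg.min_overlap,
                transposase_threshold=cfg.transposase_threshold,
            )
            pd.DataFrame(
                [
                    {"transcript_id": r.transcript_id, "family": r.family,
                     "overlap_bp": r.overlap_bp, "tx_start": r.tx_start,
                     "tx_end": r.tx_end,
                     "regions": ",".join(sorted(r.regions)),
                     "orf_overlap_fraction": round(r.orf_overlap_fraction, 4)}
                    for r in records
                ]
            ).to_csv(os.path.join(cfg.outdir, "te_report.tsv"), sep="\t",
                     index=False)
            summary["exonization"] = exo.to_dict()
            if exo.n_lnc and exo.n_coding:
                test = te_mod.two_proportion_ztest(
                    exo.n_lnc_te, exo.n_lnc, exo.n_coding_te, exo.n_coding
                )
                summary["te_proportion_test"] = {
                    "p_lnc": round(test.p1, 6), "p_coding": round(test.p2, 6),
                    "z": round(test.z, 6), "p_value": float(f"{test.p_value:.6g}"),
                }
            logger.info("te: %d/%d transcripts TE-exonized",
                        exo.n_te_transcripts, exo.n_total)
    except Exception as exc:
        raise IsoscapeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    report = make_report(summary)
    with open(os.path.join(cfg.outdir, "report.txt"), "w") as fh:
        fh.write(report)
    return summary


def _locus_histogram(groups) -> dict[str, int]:
    per_locus = collapse_mod.count_isoforms_per_locus(groups)
    hist: dict[str, int] = {}
    for n in per_locus.values():
        hist[str(n)] = hist.get(str(n), 0) + 1
    return hist


def make_report(summary: dict | str) -> str:
    """Human-readable tables from a summary dict or summary.json path.

    Idempotent: regenerating from the same summary yields the same text.
    """
    if isinstance(summary, str):
        with open(summary) as fh:
            summary = json.load(fh)
    lines = ["isoscape pipeline report", "=" * 30, ""]
    if "n_nrhqci" in summary:
        lines += [
            f"input transcripts       : {summary.get('n_input_transcripts', '?')}",
            f"failed identity/coverage: {summary.get('n_filtered_out', '?')}",
            f"non-redundant isoforms  : {summary['n_nrhqci']}",
            "",
            "length distribution:",
        ]
        hist = summary.get("length_histogram", {})
        for name, _, _ in _LEN_BINS:  # canonical bin order, not dict order
            if name in hist:
                lines.append(f"  {name:>6}: {hist[name]}")
        lines.append("")
    if "isoforms_per_locus" in summary:
        lines.append("isoforms per locus:")
        for k in sorted(summary["isoforms_per_locus"], key=int):
            lines.append(f"  {k} isoform(s): {summary['isoforms_per_locus'][k]} loci")
        lines.append("")
    if "as_event_counts" in summary:
        counts = summary["as_event_counts"]
        total5 = sum(v for k, v in counts.items() if k != "COMPLEX")
        lines.append(f"AS events ({total5} in the five types):")
        for etype in (*splice_events.EVENT_TYPES, "COMPLEX"):
            n = counts.get(etype, 0)
            frac = f"{100 * n / total5:5.1f}%" if total5 and etype != "COMPLEX" \
                else "    —"
            lines.append(f"  {etype:>7}: {n:5d} {frac}")
        lines.append("")
    if "n_lncRNA" in summary:
        lines += [
            f"lncRNA        : {summary['n_lncRNA']}",
            f"protein-coding: {summary['n_coding']}",
            "",
        ]
    if "exonization" in summary:
        exo = summary["exonization"]
        lines.append("TE exonization:")
        lines.append(f"  TE transcripts : {exo['n_te_transcripts']}"
                     f" / {exo['n_total']}")
        if exo["n_lnc"]:
            lines.append(
                f"  lncRNA with TE : {exo['n_lnc_te']} / {exo['n_lnc']} "
                f"({100 * exo['n_lnc_te'] / exo['n_lnc']:.1f}%)"
            )
        else:
            lines.append("  lncRNA with TE : undefined (no lncRNAs)")
        if exo["n_coding"]:
            lines.append(
                f"  coding with TE : {exo['n_coding_te']} / {exo['n_coding']} "
                f"({100 * exo['n_coding_te'] / exo['n_coding']:.1f}%)"
            )
        lines.append(f"  transposase coding  : {exo['n_transposase']}")
        lines.append(f"  TE-fragment carriers: {exo['n_fragment_carriers']}")
        lines.append("  region counts (fragment carriers / lncRNA):")
        rc = exo.get("region_counts", {})
        for region in te_mod.REGIONS:
            if region in rc:
                lines.append(f"    {region:>14}: {rc[region]}")
        if "te_proportion_test" in summary:
            t = summary["te_proportion_test"]
            lines.append(
                f"  lncRNA vs coding TE proportion: z={t['z']:.3f}, "
                f"p={t['p_value']:.3g}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
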