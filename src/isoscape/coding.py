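"""Coding-potential scoring and lncRNA calling.

Three independent in-repo scorers replace the external coding-potential
tools while keeping their decision logic: (1) an ORF-length rule, (2) the
Fickett TESTCODE statistic computed from the published position/composition
lookup tables, and (3) a log-ratio hexamer score trained on coding ORFs vs
noncoding background.  A transcript is called lncRNA iff *every* configured
scorer calls it noncoding and it passes the community length floor
(default 200 nt) — the intersection rule.

The trainable parts are exposed as scikit-learn compatible estimators
(:class:`HexamerCodingModel`, :class:`LncRnaCaller`); the module-level
functions are thin wrappers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from sklearn.base import BaseEstimator, ClassifierMixin

from .models import TranscriptModel

_STOP_CODONS = ("TAA", "TAG", "TGA")
_VALID = set("ACGTN")

DEFAULT_MIN_LNC_LEN = 200
DEFAULT_ORF_MIN_CODONS = 100
DEFAULT_FICKETT_THRESHOLD = 0.95
#: hexamer means are noisy on very short ORFs; ORFs below this floor score 0
HEXAMER_SCORING_MIN_CODONS = 25


@dataclass
class OrfAnnotation:
    """An open reading frame in transcript coordinates (0-based half-open)."""

    start: int
    end: int
    frame: int
    protein: str
    has_start: bool = True
    has_stop: bool = True
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")

    @property
    def nt_length(self) -> int:
        return self.end - self.start


@dataclass
class CodingVerdict:
    transcript_id: str
    per_scorer: dict[str, str]
    is_lncRNA: bool


def _check_sequence(seq: str, allow_n: bool = True) -> str:
    s = seq.upper()
    alphabet = _VALID if allow_n else set("ACGT")
    bad = set(s) - alphabet
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def find_longest_orf(
    seq: str, min_codons: int = DEFAULT_ORF_MIN_CODONS
) -> Optional[OrfAnnotation]:
    """Longest ATG→stop ORF over the three forward frames.

    ``min_codons`` is the minimum protein length (amino acids, including the
    initial Met).  Ties go to the 5'-most start.  If no stop-terminated ORF
    qualifies, the longest open (stop-less) ORF reaching the final complete
    codon is returned with ``has_stop=False``; otherwise None.  Codons
    containing N never act as start or stop.
    """
    s = _check_sequence(seq)
    best: Optional[tuple[int, int, int]] = None       # (nt_len, -start, frame)
    best_coords: Optional[tuple[int, int, int]] = None
    best_open: Optional[tuple[int, int, int]] = None
    best_open_coords: Optional[tuple[int, int, int]] = None
    for frame in range(3):
        open_start: Optional[int] = None
        i = frame
        while i + 3 <= len(s):
            codon = s[i : i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in _STOP_CODONS:
                end = i + 3
                protein_len = (end - open_start) // 3 - 1
                if protein_len >= min_codons:
                    key = (end - open_start, -open_start, frame)
                    if best is None or key > best:
                        best, best_coords = key, (open_start, end, frame)
                open_start = None
            i += 3
        if open_start is not None:
            end = frame + 3 * ((len(s) - frame) // 3)
            protein_len = (end - open_start) // 3
            if protein_len >= min_codons:
                key = (end - open_start, -open_start, frame)
                if best_open is None or key > best_open:
                    best_open, best_open_coords = key, (open_start, end, frame)
    if best_coords is not None:
        start, end, frame = best_coords
        protein = str(Seq(s[start : end - 3]).translate())
        return OrfAnnotation(start, end, frame, protein, True, True)
    if best_open_coords is not None:
        start, end, frame = best_open_coords
        protein = str(Seq(s[start:end]).translate())
        return OrfAnnotation(start, end, frame, protein, True, False)
    return None


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------
# Published TESTCODE lookup tables: 10 probability bins per base for the
# position asymmetry parameter and the composition parameter, plus weights.

_POS_THRESHOLDS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_POS_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POS_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

_CONT_THRESHOLDS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)
_CONT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.61, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, thresholds: Sequence[float], probs: Sequence[float]) -> float:
    for t, p in zip(thresholds, probs):
        if value >= t:
            return p
    return probs[-1]


def fickett_testcode(seq: str) -> float:
    """Fickett TESTCODE statistic: 8 weighted lookups (4 position, 4 content).

    The position parameter for base B is max/(min+1) over the three codon
    positions; the content parameter is B's overall fraction.
    """
    s = _check_sequence(seq)
    if not s:
        raise ValueError("empty sequence")
    score = 0.0
    n = len(s)
    for base in "ACGT":
        by_pos = [s[p::3].count(base) for p in range(3)]
        position = max(by_pos) / (min(by_pos) + 1.0)
        content = s.count(base) / n
        score += _lookup(position, _POS_THRESHOLDS, _POS_PROB[base]) * _POS_WEIGHT[base]
        score += _lookup(content, _CONT_THRESHOLDS, _CONT_PROB[base]) * _CONT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

_HEXAMERS = ["".join(h) for h in itertools.product("ACGT", repeat=6)]
_HEXAMER_INDEX = {h: i for i, h in enumerate(_HEXAMERS)}


@dataclass
class HexamerTable:
    """log(f_coding / f_noncoding) per hexamer, pseudocount 1 per class."""

    log_ratio: dict[str, float]
    trained_on: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if len(self.log_ratio) != 4096:
            raise ValueError("hexamer table must have exactly 4096 entries")
        if not all(np.isfinite(list(self.log_ratio.values()))):
            raise ValueError("hexamer log-ratios must be finite")


def _count_hexamers(seqs: Sequence[str], step: int) -> np.ndarray:
    counts = np.zeros(4096, dtype=np.int64)
    for seq in seqs:
        s = seq.upper()
        for i in range(0, len(s) - 5, step):
            idx = _HEXAMER_INDEX.get(s[i : i + 6])
            if idx is not None:  # skip N-containing hexamers
                counts[idx] += 1
    return counts


def train_hexamer_table(
    coding_seqs: Sequence[str], noncoding_seqs: Sequence[str]
) -> HexamerTable:
    """In-frame (step 3) hexamer frequencies of coding ORFs vs all-frame
    (step 1) frequencies of noncoding sequences, pseudocount 1."""
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both training classes must be non-empty")
    c = _count_hexamers(coding_seqs, step=3) + 1
    n = _count_hexamers(noncoding_seqs, step=1) + 1
    log_ratio = np.log(c / c.sum()) - np.log(n / n.sum())
    return HexamerTable(
        log_ratio=dict(zip(_HEXAMERS, log_ratio.tolist())),
        trained_on=(len(coding_seqs), len(noncoding_seqs)),
    )


def hexamer_score(
    seq: str,
    table: HexamerTable,
    scoring_min_codons: int = HEXAMER_SCORING_MIN_CODONS,
) -> float:
    """Mean log-ratio over in-frame hexamers of the longest ORF; 0 if none."""
    orf = find_longest_orf(seq, min_codons=scoring_min_codons)
    if orf is None:
        return 0.0
    s = seq.upper()[orf.start : orf.end]
    vals = [
        table.log_ratio[s[i : i + 6]]
        for i in range(0, len(s) - 5, 3)
        if s[i : i + 6] in table.log_ratio
    ]
    return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

def _as_sequences(X) -> list[str]:
    if hasattr(X, "tolist"):
        X = X.tolist()
    return [_check_sequence(x) for x in X]


class HexamerCodingModel(BaseEstimator, ClassifierMixin):
    """Hexamer-usage classifier: coding iff the mean in-frame log-ratio of
    the longest ORF exceeds ``threshold``.

    Parameters
    ----------
    threshold : float
        Decision boundary on the mean log-ratio (default 0.0).
    scoring_min_codons : int
        Shortest ORF (protein length) that is scored; shorter → score 0.
    """

    def __init__(
        self,
        threshold: float = 0.0,
        scoring_min_codons: int = HEXAMER_SCORING_MIN_CODONS,
    ):
        self.threshold = threshold
        self.scoring_min_codons = scoring_min_codons

    def fit(self, X, y):
        seqs = _as_sequences(X)
        y = list(y)
        if len(seqs) != len(y):
            raise ValueError("X and y length mismatch")
        labels = [
            "coding" if v in (1, True, "coding") else "noncoding" for v in y
        ]
        labels = np.asarray(labels)
        coding_orfs = []
        for s, lab in zip(seqs, labels):
            if lab != "coding":
                continue
            orf = find_longest_orf(s, min_codons=self.scoring_min_codons)
            if orf is not None:
                coding_orfs.append(s[orf.start : orf.end])
        noncoding = [s for s, lab in zip(seqs, labels) if lab == "noncoding"]
        self.table_ = train_hexamer_table(coding_orfs, noncoding)
        self.classes_ = np.array(["noncoding", "coding"])
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "table_"):
            raise AttributeError("HexamerCodingModel is not fitted")
        return np.array(
            [hexamer_score(s, self.table_, self.scoring_min_codons)
             for s in _as_sequences(X)]
        )

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d > self.threshold, "coding", "noncoding")


class LncRnaCaller(BaseEstimator, ClassifierMixin):
    """Intersection-rule lncRNA caller over independent coding scorers.

    A transcript is lncRNA iff its length is >= ``min_lnc_len`` AND all
    configured scorers call it noncoding; everything else is protein-coding,
    so the two sets partition the input.  ``fit`` with ``y=None`` bootstraps
    hexamer training labels from the ORF-length rule (transcripts with an
    ORF of >= ``orf_min_codons`` codons form the provisional coding class).
    """

    def __init__(
        self,
        orf_min_codons: int = DEFAULT_ORF_MIN_CODONS,
        fickett_threshold: float = DEFAULT_FICKETT_THRESHOLD,
        hexamer_threshold: float = 0.0,
        min_lnc_len: int = DEFAULT_MIN_LNC_LEN,
        use_fickett: bool = True,
        use_hexamer: bool = True,
        extra_scorers: Optional[dict[str, Callable[[str], str]]] = None,
    ):
        self.orf_min_codons = orf_min_codons
        self.fickett_threshold = fickett_threshold
        self.hexamer_threshold = hexamer_threshold
        self.min_lnc_len = min_lnc_len
        self.use_fickett = use_fickett
        self.use_hexamer = use_hexamer
        self.extra_scorers = extra_scorers

    # -- scorer assembly ---------------------------------------------------
    def _orf_scorer(self, seq: str) -> str:
        orf = find_longest_orf(seq, min_codons=self.orf_min_codons)
        return "coding" if orf is not None and orf.has_stop else "noncoding"

    def _fickett_scorer(self, seq: str) -> str:
        return (
            "coding" if fickett_testcode(seq) >= self.fickett_threshold
            else "noncoding"
        )

    def fit(self, X, y=None):
        seqs = _as_sequences(X)
        self.scorers_: dict[str, Callable[[str], str]] = {
            "orf_length": self._orf_scorer
        }
        if self.use_fickett:
            self.scorers_["fickett"] = self._fickett_scorer
        if self.use_hexamer:
            model = HexamerCodingModel(
                threshold=self.hexamer_threshold
            )
            if y is None:
                labels = np.array([self._orf_scorer(s) for s in seqs])
                if (labels == "coding").sum() == 0 or (labels == "noncoding").sum() == 0:
                    # degenerate bootstrap: hexamer scorer cannot be trained
                    self.use_hexamer_ = False
                else:
                    model.fit(seqs, labels)
                    self.hexamer_model_ = model
                    self.scorers_["hexamer"] = (
                        lambda s: "coding"
                        if hexamer_score(s, self.hexamer_model_.table_)
                        > self.hexamer_threshold
                        else "noncoding"
                    )
            else:
                model.fit(seqs, y)
                self.hexamer_model_ = model
                self.scorers_["hexamer"] = (
                    lambda s: "coding"
                    if hexamer_score(s, self.hexamer_model_.table_)
                    > self.hexamer_threshold
                    else "noncoding"
                )
        if self.extra_scorers:
            self.scorers_.update(self.extra_scorers)
        self.classes_ = np.array(["coding", "lncRNA"])
        return self

    def _verdict(self, tid: str, seq: str) -> CodingVerdict:
        per_scorer = {name: fn(seq) for name, fn in self.scorers_.items()}
        is_lnc = len(seq) >= self.min_lnc_len and all(
            v == "noncoding" for v in per_scorer.values()
        )
        return CodingVerdict(transcript_id=tid, per_scorer=per_scorer,
                             is_lncRNA=is_lnc)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "scorers_"):
            raise AttributeError("LncRnaCaller is not fitted")
        return np.array(
            [
                "lncRNA" if self._verdict(str(i), s).is_lncRNA else "coding"
                for i, s in enumerate(_as_sequences(X))
            ]
        )

    def verdicts(
        self, X, ids: Optional[Sequence[str]] = None
    ) -> list[CodingVerdict]:
        seqs = _as_sequences(X)
        if ids is None:
            ids = [str(i) for i in range(len(seqs))]
        return [self._verdict(tid, s) for tid, s in zip(ids, seqs)]


# ---------------------------------------------------------------------------
# module-level convenience wrappers
# ---------------------------------------------------------------------------

def call_lncRNA(
    transcripts: Sequence[TranscriptModel],
    caller: Optional[LncRnaCaller] = None,
    min_lnc_len: int = DEFAULT_MIN_LNC_LEN,
) -> list[CodingVerdict]:
    """Fit an :class:`LncRnaCaller` on the transcripts' sequences and return
    per-transcript verdicts.  Transcript sequences must be attached."""
    missing = [t.transcript_id for t in transcripts if t.sequence is None]
    if missing:
        raise ValueError(f"transcripts without sequence: {missing[:3]} ...")
    caller = caller or LncRnaCaller(min_lnc_len=min_lnc_len)
    seqs = [t.sequence for t in transcripts]
    caller.fit(seqs)
    return caller.verdicts(seqs, ids=[t.transcript_id for t in transcripts])


def annotate_orfs(
    transcripts: Sequence[TranscriptModel],
    min_codons: int = 1,
) -> dict[str, OrfAnnotation]:
    """Longest-ORF annotation per transcript (transcripts without any ORF
    are omitted)."""
    out: dict[str, OrfAnnotation] = {}
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"{t.transcript_id}: sequence not attached")
        orf = find_longest_orf(t.sequence, min_codons=min_codons)
        if orf is not None:
            orf.transcript_id = t.transcript_id
            out[t.transcript_id] = orf
    return out
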