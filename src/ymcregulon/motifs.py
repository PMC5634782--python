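"""Position weight matrices and log-odds motif scanning.

A PWM is a ``w x 4`` matrix of per-position base probabilities (columns
A, C, G, T). Windows are scored on both strands as

    score = sum_i log2( p'_i(base_i) / bg(base_i) )   [bits]

where ``p'`` is the matrix after adding a pseudocount and renormalising.
The default site threshold is a fixed fraction of the PWM's maximum
achievable score, which keeps thresholds comparable across motif widths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SITE_COLS = ["tf_id", "chrom", "start", "end", "strand", "score"]


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else -> 4 (scored neutrally)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[arr]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    tf_id: str
    matrix: np.ndarray  # (w, 4) probabilities, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (w, 4)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(w, 5) log2-odds lookup; column 4 (non-ACGT) scores 0."""
        p = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        lo = np.zeros((self.width, 5))
        with np.errstate(divide="ignore"):  # pseudocount 0 gives -inf, legal
            lo[:, :4] = np.log2(p / self.background[None, :])
        return lo

    @property
    def max_score(self) -> float:
        return float(self.log_odds()[:, :4].max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            tf_id=self.tf_id,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )

    def score_windows(self, encoded: np.ndarray) -> np.ndarray:
        """Plus-strand score of every window of an encoded sequence."""
        w = self.width
        n = encoded.size - w + 1
        if n <= 0:
            return np.empty(0)
        lo = self.log_odds()
        scores = np.zeros(n)
        for i in range(w):
            scores += lo[i, encoded[i : i + n]]
        return scores


def scan_motifs(
    sequences: dict[str, str],
    pwm: PWM,
    regions: pd.DataFrame,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
) -> pd.DataFrame:
    """Scan a PWM over regions of a genome on both strands.

    A site is reported where the log-odds score reaches ``threshold`` bits
    (default ``threshold_frac * pwm.max_score``) and the window lies wholly
    inside a region. Overlapping same-strand hits are collapsed to the
    best-scoring window (ties: leftmost).
    """
    if threshold is None:
        threshold = threshold_frac * pwm.max_score
    if not np.isfinite(threshold):
        raise ValueError("scan threshold must be finite")
    w = pwm.width
    rc = pwm.reverse_complement()
    hits: list[tuple] = []
    for _, reg in regions.iterrows():
        chrom = reg["chrom"]
        seq = sequences[chrom]
        start, end = int(max(0, reg["start"])), int(min(len(seq), reg["end"]))
        if end - start < w:
            continue  # window wider than region
        enc = encode_sequence(seq[start:end])
        for strand, mat in (("+", pwm), ("-", rc)):
            scores = mat.score_windows(enc)
            for off in np.flatnonzero(scores >= threshold):
                hits.append((pwm.tf_id, chrom, start + int(off), start + int(off) + w, strand, float(scores[off])))
    sites = pd.DataFrame(hits, columns=SITE_COLS)
    if sites.empty:
        return sites
    # regions may overlap; a given window is one site
    sites = sites.drop_duplicates(subset=["chrom", "start", "strand"])
    return collapse_overlapping_sites(sites)


def collapse_overlapping_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Greedy best-score-then-leftmost collapse of overlapping same-strand hits."""
    kept: list[int] = []
    sites = sites.sort_values(
        ["score", "start"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    occupied: dict[tuple, list[tuple[int, int]]] = {}
    for i, row in sites.iterrows():
        key = (row["chrom"], row["strand"])
        slots = occupied.setdefault(key, [])
        if any(row["start"] < e and row["end"] > s for s, e in slots):
            continue
        slots.append((row["start"], row["end"]))
        kept.append(i)
    out = sites.loc[kept].sort_values(["chrom", "start", "strand"]).reset_index(drop=True)
    return out


def random_pwm(
    tf_id: str, width: int, rng: np.random.Generator, info: float = 0.85
) -> PWM:
    """An informative PWM around a random consensus (consensus base prob ``info``)."""
    consensus = rng.integers(0, 4, size=width)
    mat = np.full((width, 4), (1.0 - info) / 3.0)
    mat[np.arange(width), consensus] = info
    return PWM(tf_id=tf_id, matrix=mat)
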