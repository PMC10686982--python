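"""Variant-centered sequence windows, ETS-core offsets and PWM scanning.

The ETS core is the 4-mer GGAA (reverse complement TTCC). Offsets are
strand-normalized: when the nearest core occurrence is on the minus strand
the window is reverse-complemented first, so the reported offset (variant
index minus motif start) always refers to a GGAA-reading orientation.
Offsets 0..3 mean the variant lies inside the core.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from regspot.io import Interval
from regspot.regions import RegionSet

__all__ = [
    "SequenceWindow",
    "OrientedOffset",
    "PWM",
    "revcomp",
    "extract_window",
    "nearest_ets_offset",
    "offset_histogram",
    "consensus_counts",
    "consensus_from_counts",
    "pwm_from_consensus",
    "scan_pwm",
]

ETS_CORE = "GGAA"
ETS_CORE_RC = "TTCC"
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class SequenceWindow:
    """A variant-centered window of genomic sequence."""

    chrom: str
    window_start: int  # 0-based
    seq: str
    variant_offset: int  # 0-based index of the variant within seq
    allele: str = "WT"  # WT or MUT

    def __post_init__(self) -> None:
        if not 0 <= self.variant_offset < len(self.seq):
            raise ValueError(
                f"variant_offset {self.variant_offset} outside window of "
                f"length {len(self.seq)}"
            )


@dataclass(frozen=True, slots=True)
class OrientedOffset:
    """Strand-normalized offset of a variant relative to the nearest core."""

    found: bool
    offset: int = 0
    strand: str = "+"
    motif_start: int = 0


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Substring [start, end) from a dict of strings or a pyfaidx Fasta."""
    seq = genome[chrom]
    if isinstance(seq, str):
        if end > len(seq):
            raise ValueError(f"window [{start},{end}) off end of {chrom}")
        return seq[start:end].upper()
    piece = seq[start:end]  # pyfaidx-style sequence object
    out = str(piece).upper()
    if len(out) != end - start:
        raise ValueError(f"window [{start},{end}) off end of {chrom}")
    return out


def extract_window(
    genome,
    chrom: str,
    pos1: int,
    length: int = 11,
    anchor_index: int = 6,
    alt: Optional[str] = None,
) -> SequenceWindow:
    """Window of ``length`` bp with the variant at 1-based ``anchor_index``.

    The defaults give 11 bp windows centered on the variant; 20 bp windows
    use ``anchor_index=10``. Passing ``alt`` substitutes the alternate
    allele (same-length alleles only), producing a MUT window. Windows
    running off either chromosome end raise (no clipping).
    """
    if not 1 <= anchor_index <= length:
        raise ValueError(f"anchor_index {anchor_index} outside window length {length}")
    start = (pos1 - 1) - (anchor_index - 1)
    if start < 0:
        raise ValueError(f"window for {chrom}:{pos1} starts before the chromosome")
    seq = _fetch(genome, chrom, start, start + length)
    offset = anchor_index - 1
    allele = "WT"
    if alt is not None:
        alt = alt.upper()
        if offset + len(alt) > length:
            raise ValueError("alt allele extends past the window")
        seq = seq[:offset] + alt + seq[offset + len(alt):]
        allele = "MUT"
    return SequenceWindow(chrom, start, seq, offset, allele)


def _core_distance(variant_idx: int, motif_start: int) -> int:
    """0 if the variant lies inside the 4-mer, else gap to the nearer edge."""
    if motif_start <= variant_idx <= motif_start + 3:
        return 0
    return min(abs(variant_idx - motif_start), abs(variant_idx - (motif_start + 3)))


def _find_all(seq: str, pat: str) -> list[int]:
    hits, i = [], seq.find(pat)
    while i != -1:
        hits.append(i)
        i = seq.find(pat, i + 1)
    return hits


def nearest_ets_offset(window: SequenceWindow) -> OrientedOffset:
    """Offset of the variant from the nearest ETS core, strand-normalized.

    All GGAA and TTCC occurrences compete on unsigned distance (inside the
    core counts as 0). When the winner is a TTCC, the window is
    reverse-complemented before the offset is measured, so the motif always
    reads GGAA. Distance ties are broken by the smaller resulting offset,
    then by preferring the plus strand; because each occurrence's
    strand-normalized offset is invariant under reverse complement, this
    keeps nearest_ets_offset strand-involutive.
    """
    seq = window.seq.upper()
    v = window.variant_offset
    n = len(seq)
    # (distance, oriented offset, strand order, oriented motif start, strand)
    candidates: list[tuple[int, int, int, int, str]] = []
    for s in _find_all(seq, ETS_CORE):
        candidates.append((_core_distance(v, s), v - s, 0, s, "+"))
    for s in _find_all(seq, ETS_CORE_RC):
        # TTCC at s reads GGAA at n-4-s on the reverse strand
        v_rc, s_rc = n - 1 - v, n - 4 - s
        candidates.append((_core_distance(v, s), v_rc - s_rc, 1, s_rc, "-"))
    if not candidates:
        return OrientedOffset(found=False)
    _, offset, _, motif_start, strand = min(candidates)
    return OrientedOffset(True, offset=offset, strand=strand, motif_start=motif_start)


def offset_histogram(
    windows: Iterable[SequenceWindow],
) -> tuple[Counter, int]:
    """Counts of strand-normalized offsets; second value = windows w/o motif."""
    counts: Counter = Counter()
    n_missing = 0
    for w in windows:
        res = nearest_ets_offset(w)
        if res.found:
            counts[res.offset] += 1
        else:
            n_missing += 1
    return counts, n_missing


def consensus_counts(
    windows: Iterable[SequenceWindow],
    align_g_at: int = 5,
    length: int = 11,
) -> np.ndarray:
    """4 x ``length`` base-count matrix of motif-aligned windows.

    Each window is oriented so its nearest core reads GGAA and shifted so
    the first G sits at 1-based position ``align_g_at``; bases falling
    outside the frame are dropped, and windows without a core are skipped.
    Rows are A, C, G, T (WebLogo-ready).
    """
    counts = np.zeros((4, length), dtype=np.int64)
    target = align_g_at - 1
    for w in windows:
        res = nearest_ets_offset(w)
        if not res.found:
            continue
        seq = w.seq.upper() if res.strand == "+" else revcomp(w.seq.upper())
        shift = target - res.motif_start
        for i, base in enumerate(seq):
            j = i + shift
            if 0 <= j < length and base in _BASE_INDEX:
                counts[_BASE_INDEX[base], j] += 1
    return counts


def consensus_from_counts(counts: np.ndarray) -> str:
    """Majority base per column (ties broken alphabetically; empty -> N)."""
    out = []
    for j in range(counts.shape[1]):
        col = counts[:, j]
        out.append("N" if col.sum() == 0 else BASES[int(np.argmax(col))])
    return "".join(out)


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide probability matrix (rows A, C, G, T)."""

    probs: np.ndarray
    consensus: str
    p_consensus: float

    def __post_init__(self) -> None:
        if self.probs.shape != (4, len(self.consensus)):
            raise ValueError("probs must be 4 x len(consensus)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        for j, base in enumerate(self.consensus):
            if BASES[int(np.argmax(self.probs[:, j]))] != base:
                raise ValueError(f"column {j} argmax does not match consensus")

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / 0.25) per cell, uniform background."""
        return np.log2(self.probs / 0.25)

    @property
    def self_score(self) -> float:
        """Score of the consensus itself: L * log2(p_consensus / 0.25)."""
        return len(self) * math.log2(self.p_consensus / 0.25)

    def score(self, seq: str) -> float:
        """Log-odds score of a sequence of the PWM's length."""
        if len(seq) != len(self):
            raise ValueError("sequence length must match PWM length")
        lo = self.log_odds
        total = 0.0
        for j, base in enumerate(seq.upper()):
            if base not in _BASE_INDEX:
                return float("-inf")
            total += lo[_BASE_INDEX[base], j]
        return total


def pwm_from_consensus(consensus: str, p_consensus: float = 0.997) -> PWM:
    """Zero-mismatch-style PWM: p_consensus on the consensus base per
    column, (1 - p_consensus)/3 on each other base."""
    consensus = consensus.upper()
    if any(b not in _BASE_INDEX for b in consensus):
        raise ValueError(f"consensus contains non-ACGT characters: {consensus}")
    if not 0.25 < p_consensus < 1:
        raise ValueError("p_consensus must lie in (0.25, 1)")
    off = (1.0 - p_consensus) / 3.0
    probs = np.full((4, len(consensus)), off, dtype=float)
    for j, base in enumerate(consensus):
        probs[_BASE_INDEX[base], j] = p_consensus
    return PWM(probs=probs, consensus=consensus, p_consensus=p_consensus)


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _scan_sequence(lo: np.ndarray, seq: str) -> np.ndarray:
    """Log-odds score at every start position; -inf where non-ACGT."""
    L = lo.shape[1]
    arr = _encode(seq.upper())
    n = len(arr) - L + 1
    if n <= 0:
        return np.empty(0)
    lo_ext = np.vstack([lo, np.full(L, -np.inf)])  # row 4 = non-ACGT
    scores = np.zeros(n)
    for j in range(L):
        scores += lo_ext[arr[j : j + n], j]
    return scores


def scan_pwm(
    pwm: PWM,
    regions: RegionSet,
    genome,
    threshold_bits: Optional[float] = None,
    max_instances: int = 50_000,
    seed: Optional[int] = None,
) -> list[tuple[Interval, str, float]]:
    """Slide the PWM over both strands of every region.

    Hits with log-odds >= ``threshold_bits`` (default: consensus self-score
    minus 1 bit) are reported as (interval, strand, bits) on forward-strand
    coordinates. If more than ``max_instances`` hits are found they are
    uniformly subsampled with ``seed``.
    """
    if threshold_bits is None:
        threshold_bits = pwm.self_score - 1.0
    L = len(pwm)
    lo_fwd = pwm.log_odds
    lo_rev = lo_fwd[::-1, ::-1]  # scanning the - strand == scanning the rc PWM
    hits: list[tuple[Interval, str, float]] = []
    for region in regions.intervals():
        seq = _fetch(genome, region.chrom, region.start, region.end)
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            scores = _scan_sequence(lo, seq)
            for i in np.flatnonzero(scores >= threshold_bits):
                hits.append(
                    (
                        Interval(region.chrom, region.start + int(i), region.start + int(i) + L),
                        strand,
                        float(scores[i]),
                    )
                )
    if len(hits) > max_instances:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(hits), size=max_instances, replace=False)
        hits = [hits[i] for i in sorted(keep)]
    return hits


def write_hits_bed(hits: Sequence[tuple[Interval, str, float]], path) -> None:
    """BED6 with score = bits x 100 rounded to int."""
    with open(path, "w") as fh:
        for i, (iv, strand, bits) in enumerate(hits):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\thit{i}\t{round(bits * 100)}\t{strand}\n"
            )
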