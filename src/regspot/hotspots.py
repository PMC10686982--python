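"""Merge variant records into hotspots and compute recurrence scores.

Merging is single-linkage chaining on variant start positions: two records
join one cluster iff their 1-based start positions differ by at most the
window (default 25 bp), applied transitively, so a cluster may span more
than one window. Clusters with fewer than ``min_count`` records (default 3)
are discarded as isolated variants.

The donor score of a hotspot is D^2/G where D is the number of variant
records and G the number of distinct mutated start positions; the hotspot
score is the donor score times the mean per-variant functional weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from regspot.io import Interval, ScoreTrack, VariantRecord

__all__ = ["MergeConfig", "Hotspot", "merge_variants", "attach_funseq", "donor_score"]


@dataclass(frozen=True, slots=True)
class MergeConfig:
    """Parameters of the merge step.

    ``count_donors`` switches D from counting records (default, matching
    the worked example where per-position donor counts are summed) to
    counting distinct donor ids. ``expand_mnv_positions`` makes an MNV of
    reference length L contribute L mutated positions to G instead of 1.
    """

    window: int = 25
    min_count: int = 3
    count_donors: bool = False
    expand_mnv_positions: bool = False

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError(f"window must be >= 0, got {self.window}")
        if self.min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {self.min_count}")


@dataclass(slots=True)
class Hotspot:
    """A merged cluster of variant records with its scores."""

    span: Interval
    variants: list[VariantRecord]
    D: int
    G: int
    mean_funseq: float = 0.0
    n_missing_funseq: int = 0
    compartment: str = "unassigned"
    p_value: Optional[float] = None
    q_value: Optional[float] = None

    @property
    def donor_score(self) -> float:
        """D^2 / G."""
        return self.D * self.D / self.G

    @property
    def hotspot_score(self) -> float:
        """donor_score x mean functional weight."""
        return self.donor_score * self.mean_funseq


def donor_score(hotspot: Hotspot) -> float:
    """D^2/G for a populated hotspot (e.g. D=10, G=4 -> 25.0)."""
    return hotspot.donor_score


def merge_variants(
    variants: Iterable[VariantRecord], config: MergeConfig = MergeConfig()
) -> list[Hotspot]:
    """Chain variants within ``config.window`` bp into hotspots.

    Input order is irrelevant; output is sorted by (chrom, start). Gaps are
    measured between 1-based start positions; indel footprints do not
    extend the chaining reach.
    """
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    hotspots: list[Hotspot] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda v: (v.pos1, v.donor_id, v.alt))
        cluster: list[VariantRecord] = []
        for v in recs:
            if cluster and v.pos1 - cluster[-1].pos1 > config.window:
                hs = _finalize(cluster, config)
                if hs is not None:
                    hotspots.append(hs)
                cluster = []
            cluster.append(v)
        hs = _finalize(cluster, config)
        if hs is not None:
            hotspots.append(hs)
    return hotspots


def _finalize(cluster: list[VariantRecord], config: MergeConfig) -> Optional[Hotspot]:
    if not cluster:
        return None
    if config.count_donors:
        d = len({v.donor_id for v in cluster})
    else:
        d = len(cluster)
    if d < config.min_count:
        return None
    if config.expand_mnv_positions:
        positions = {
            p for v in cluster for p in range(v.pos1, v.pos1 + len(v.ref))
        }
    else:
        positions = {v.pos1 for v in cluster}
    span = Interval(
        cluster[0].chrom,
        min(v.start0 for v in cluster),
        max(v.end0 for v in cluster),
    )
    return Hotspot(span=span, variants=list(cluster), D=d, G=len(positions))


def attach_funseq(hotspots: Iterable[Hotspot], track: ScoreTrack) -> list[Hotspot]:
    """Attach per-variant weights from ``track`` and set each mean.

    Each variant gets the track score at its start position. Missing scores
    are imputed as 0 and counted in ``n_missing_funseq``; the mean is taken
    over all records of the hotspot.
    """
    out = []
    for h in hotspots:
        total = 0.0
        missing = 0
        for v in h.variants:
            score = track.lookup(v.chrom, v.pos1)
            if score is None:
                v.funseq = 0.0
                missing += 1
            else:
                v.funseq = score
                total += score
        n = len(h.variants)
        h.mean_funseq = total / n if n else 0.0
        h.n_missing_funseq = missing
        out.append(h)
    return out
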