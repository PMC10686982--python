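"""Compartment assignment, empirical p-values, FDR and summaries.

Hotspots inside the regulatory-region set form the test compartment; those
outside form the empirical null. The p-value of a test hotspot is the
proportion of null hotspot scores greater than or equal to its score
(ties count; p may be exactly 0), adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from regspot.hotspots import Hotspot
from regspot.io import Interval, VariantRecord
from regspot.regions import RegionSet

__all__ = [
    "CompartmentSummary",
    "assign_compartments",
    "empirical_pvalues",
    "bh_fdr",
    "score_significance",
    "significant_hotspots",
    "compartment_summary",
    "cohort_mutation_summary",
]


def assign_compartments(
    hotspots: Iterable[Hotspot],
    pmrr: RegionSet,
    exons: Optional[RegionSet] = None,
    excluded: Optional[RegionSet] = None,
    literal_null: bool = False,
) -> list[Hotspot]:
    """Label each hotspot test / null / excluded by span overlap (>=1 bp).

    A hotspot overlapping exons or the exclusion list is removed from BOTH
    compartments by default; ``literal_null=True`` restores the literal
    reading (null = everything outside the regulatory set, exons and all).
    """
    out = []
    for h in hotspots:
        in_bad = False
        if not literal_null:
            for bad in (exons, excluded):
                if bad is not None and bad.overlaps(h.span):
                    in_bad = True
                    break
        if in_bad:
            h.compartment = "excluded"
        elif pmrr.overlaps(h.span):
            h.compartment = "test"
        else:
            h.compartment = "null"
        out.append(h)
    return out


def empirical_pvalues(
    test_scores: Sequence[float], null_scores: Sequence[float]
) -> np.ndarray:
    """p_i = |{s in null : s >= t_i}| / |null|.

    Sorts the null once and binary-searches each test score. p can be
    exactly 0 when a test score exceeds the null maximum.
    """
    null = np.sort(np.asarray(null_scores, dtype=float))
    if null.size == 0:
        raise ValueError(
            "empty null compartment: enlarge the simulated genome or region set"
        )
    t = np.asarray(test_scores, dtype=float)
    n_ge = null.size - np.searchsorted(null, t, side="left")
    return n_ge / null.size


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def score_significance(hotspots: Iterable[Hotspot]) -> list[Hotspot]:
    """Set p and q on test-compartment hotspots from the null scores.

    Null and excluded hotspots keep p = q = None.
    """
    hotspots = list(hotspots)
    test = [h for h in hotspots if h.compartment == "test"]
    null_scores = [h.hotspot_score for h in hotspots if h.compartment == "null"]
    if test:
        p = empirical_pvalues([h.hotspot_score for h in test], null_scores)
        q = bh_fdr(p)
        for h, pi, qi in zip(test, p, q):
            h.p_value = float(pi)
            h.q_value = float(qi)
    return hotspots


def significant_hotspots(hotspots: Iterable[Hotspot], alpha: float = 0.05) -> list[Hotspot]:
    """Hotspots with q < alpha, sorted by descending hotspot score."""
    sig = [h for h in hotspots if h.q_value is not None and h.q_value < alpha]
    return sorted(sig, key=lambda h: -h.hotspot_score)


@dataclass(frozen=True, slots=True)
class CompartmentSummary:
    """Test/null fold enrichment over the top-N hotspots per compartment."""

    n_test: int
    n_null: int
    top_n: int
    fold_donor: Optional[float]
    fold_funseq: Optional[float]
    fold_hotspot: Optional[float]


def compartment_summary(
    hotspots: Iterable[Hotspot], top_n: int = 10_000
) -> CompartmentSummary:
    """Fold ratios of mean donor / functional / hotspot scores, test vs null.

    Each compartment contributes its ``top_n`` hotspots by hotspot score;
    folds are None when either compartment is empty.
    """
    hotspots = list(hotspots)
    test = sorted(
        (h for h in hotspots if h.compartment == "test"),
        key=lambda h: -h.hotspot_score,
    )[:top_n]
    null = sorted(
        (h for h in hotspots if h.compartment == "null"),
        key=lambda h: -h.hotspot_score,
    )[:top_n]

    def fold(metric) -> Optional[float]:
        if not test or not null:
            return None
        denom = float(np.mean([metric(h) for h in null]))
        if denom == 0:
            return None
        return float(np.mean([metric(h) for h in test])) / denom

    return CompartmentSummary(
        n_test=len(test),
        n_null=len(null),
        top_n=top_n,
        fold_donor=fold(lambda h: h.donor_score),
        fold_funseq=fold(lambda h: h.mean_funseq),
        fold_hotspot=fold(lambda h: h.hotspot_score),
    )


def cohort_mutation_summary(
    variants: Iterable[VariantRecord],
    span: Interval,
    donor_groups: Mapping[str, str],
) -> dict[str, dict[str, float]]:
    """Per-group donor mutation rates within a genomic span.

    ``donor_groups`` maps every cohort donor id to a subtype label. For
    each group, reports the number of donors carrying >=1 variant whose
    footprint overlaps ``span``, the group size, and the percentage
    rounded to one decimal (e.g. 1 of 35 -> 2.9).
    """
    mutated: set[str] = set()
    for v in variants:
        if v.interval.overlaps(span) and v.donor_id in donor_groups:
            mutated.add(v.donor_id)
    groups: dict[str, dict[str, float]] = {}
    for donor, group in donor_groups.items():
        g = groups.setdefault(group, {"n_mutated": 0, "n_donors": 0})
        g["n_donors"] += 1
        if donor in mutated:
            g["n_mutated"] += 1
    for g in groups.values():
        g["pct_mutated"] = round(100.0 * g["n_mutated"] / g["n_donors"], 1)
    return groups
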