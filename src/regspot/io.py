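"""Readers and writers for variant tables, BED intervals, score tracks and
hotspot tables.

Internal coordinates are 0-based half-open everywhere; 1-based coordinates
appear only at the VCF/TSV boundary. Chromosome names are passed through
verbatim — no "chr" normalization is ever applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "Interval",
    "VariantRecord",
    "ScoreTrack",
    "read_variants",
    "write_variants",
    "read_bed",
    "write_bed",
    "read_score_track",
    "write_hotspot_table",
    "read_hotspot_table",
]

_DNA = frozenset("ACGTN")

SSM_COLUMNS = ("donor_id", "chrom", "pos1", "ref", "alt")

HOTSPOT_COLUMNS = (
    "chrom",
    "start",
    "end",
    "n_variants",
    "n_positions",
    "donor_score",
    "mean_funseq",
    "hotspot_score",
    "compartment",
    "p_value",
    "q_value",
)


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


def classify_alleles(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as SNV, MNV, INS or DEL."""
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(ref) == len(alt):
        return "MNV"
    if len(ref) < len(alt):
        return "INS"
    return "DEL"


@dataclass(frozen=True, slots=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(slots=True)
class VariantRecord:
    """One somatic variant call from one donor.

    ``pos1`` is the 1-based position of the first altered base. ``funseq``
    is an optional non-negative functional-impact weight; ``gerp`` is a
    display-only passthrough.
    """

    donor_id: str
    chrom: str
    pos1: int
    ref: str
    alt: str
    variant_class: str = field(default="")
    funseq: Optional[float] = None
    gerp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos1 < 1:
            raise ValueError(f"pos1 must be >= 1, got {self.pos1}")
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not self.ref or not self.alt:
            raise ValueError("empty ref or alt allele")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos1}")
        inferred = classify_alleles(self.ref, self.alt)
        if not self.variant_class:
            self.variant_class = inferred
        elif self.variant_class != inferred:
            raise ValueError(
                f"variant_class {self.variant_class} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {inferred})"
            )
        if self.funseq is not None and self.funseq < 0:
            raise ValueError(f"funseq must be non-negative, got {self.funseq}")

    @property
    def start0(self) -> int:
        """0-based start of the reference footprint."""
        return self.pos1 - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the reference footprint."""
        return self.pos1 - 1 + len(self.ref)

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start0, self.end0)


class ScoreTrack:
    """Sorted, non-overlapping (interval, score) entries with point lookup.

    Emulates a pre-computed per-position functional score track
    (chrom, start, end, score) with 0-based half-open intervals.
    """

    def __init__(self, entries: Iterable[tuple[Interval, float]]) -> None:
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, score in entries:
            if score < 0:
                raise ValueError(
                    f"negative score {score} at {iv.chrom}:{iv.start}-{iv.end}"
                )
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, score))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._scores: dict[str, np.ndarray] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            for (s0, e0, _), (s1, _, _) in zip(rows, rows[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"overlapping score entries on {chrom}: "
                        f"[{s0},{e0}) and starting at {s1}"
                    )
            self._starts[chrom] = np.array([r[0] for r in rows], dtype=np.int64)
            self._ends[chrom] = np.array([r[1] for r in rows], dtype=np.int64)
            self._scores[chrom] = np.array([r[2] for r in rows], dtype=float)

    def lookup(self, chrom: str, pos1: int) -> Optional[float]:
        """Score covering 1-based position ``pos1``, or None if uncovered."""
        starts = self._starts.get(chrom)
        if starts is None:
            return None
        pos0 = pos1 - 1
        idx = int(np.searchsorted(starts, pos0, side="right")) - 1
        if idx >= 0 and pos0 < self._ends[chrom][idx]:
            return float(self._scores[chrom][idx])
        return None

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def entries(self) -> Iterable[tuple[Interval, float]]:
        for chrom in sorted(self._starts):
            for s, e, v in zip(
                self._starts[chrom], self._ends[chrom], self._scores[chrom]
            ):
                yield Interval(chrom, int(s), int(e)), float(v)


# ---------------------------------------------------------------------------
# variant tables


def read_variants(path: str | Path, dialect: str) -> list[VariantRecord]:
    """Read somatic variant calls from ``path``.

    ``dialect`` must be ``"ssm_tsv"`` (tab-separated with a header naming at
    least donor_id, chrom, pos1, ref, alt; optional funseq/gerp columns) or
    ``"vcf"``. Multi-allelic VCF rows are split into one record per alt.
    """
    if dialect == "ssm_tsv":
        return _read_ssm_tsv(Path(path))
    if dialect == "vcf":
        return _read_vcf(Path(path))
    raise ValueError(f"unknown variant dialect: {dialect!r} (expected vcf or ssm_tsv)")


def _read_ssm_tsv(path: Path) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: missing header line")
        header = [c.strip() for c in header_line.rstrip("\n").split("\t")]
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in SSM_COLUMNS if c not in col]
        if missing:
            raise ParseError(f"{path}: header missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            try:
                funseq = _opt_float(fields, col.get("funseq"))
                gerp = _opt_float(fields, col.get("gerp"))
                records.append(
                    VariantRecord(
                        donor_id=fields[col["donor_id"]],
                        chrom=fields[col["chrom"]],
                        pos1=int(fields[col["pos1"]]),
                        ref=fields[col["ref"]],
                        alt=fields[col["alt"]],
                        funseq=funseq,
                        gerp=gerp,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return records


def _opt_float(fields: Sequence[str], idx: Optional[int]) -> Optional[float]:
    if idx is None or idx >= len(fields):
        return None
    raw = fields[idx]
    if raw in ("", ".", "NA", "nan"):
        return None
    return float(raw)


def _read_vcf(path: Path) -> list[VariantRecord]:
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        fallback = Path(path).stem
        for rec in vcf:
            if rec.alts is None:
                continue
            donor = rec.info.get("DONOR") if "DONOR" in rec.info else None
            if donor is None:
                donor = samples[0] if len(samples) == 1 else fallback
            if isinstance(donor, tuple):
                donor = donor[0]
            for alt in rec.alts:
                if alt is None or alt.startswith("<"):
                    continue
                records.append(
                    VariantRecord(
                        donor_id=str(donor),
                        chrom=rec.chrom,
                        pos1=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                    )
                )
    return records


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    """Write an ssm_tsv variant table (round-trips through read_variants)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SSM_COLUMNS + ("funseq", "gerp")) + "\n")
        for v in variants:
            fh.write(
                "\t".join(
                    [
                        v.donor_id,
                        v.chrom,
                        str(v.pos1),
                        v.ref,
                        v.alt,
                        _fmt_opt(v.funseq),
                        _fmt_opt(v.gerp),
                    ]
                )
                + "\n"
            )


def _fmt_opt(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


# ---------------------------------------------------------------------------
# BED and score tracks


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ intervals in file order; extra columns are ignored."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative start {start}")
            intervals.append(Interval(fields[0], start, end))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_score_track(path: str | Path) -> ScoreTrack:
    """Read a 4-column BED-graph-like score track.

    Entries must be non-overlapping and scores non-negative; violations
    raise an error naming the offending line.
    """
    entries: list[tuple[Interval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, score = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed row") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            if score < 0:
                raise ParseError(f"{path}:{lineno}: negative score {score}")
            entries.append((Interval(fields[0], start, end), score))
    try:
        return ScoreTrack(entries)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# hotspot tables


def write_hotspot_table(hotspots, path: str | Path, extra_columns=()) -> None:
    """Write scored hotspots as a BED-sortable TSV.

    ``extra_columns`` is a sequence of (name, getter) pairs appended after
    the standard columns (used by annotation).
    """
    names = HOTSPOT_COLUMNS + tuple(name for name, _ in extra_columns)
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for h in hotspots:
            row = [
                h.span.chrom,
                str(h.span.start),
                str(h.span.end),
                str(h.D),
                str(h.G),
                repr(float(h.donor_score)),
                repr(float(h.mean_funseq)),
                repr(float(h.hotspot_score)),
                h.compartment,
                _fmt_opt(h.p_value),
                _fmt_opt(h.q_value),
            ]
            row.extend(str(getter(h)) for _, getter in extra_columns)
            fh.write("\t".join(row) + "\n")


def read_hotspot_table(path: str | Path):
    """Read a hotspot TSV written by :func:`write_hotspot_table`.

    Returned hotspots carry no variant records (the table stores only
    summary fields).
    """
    from regspot.hotspots import Hotspot

    hotspots = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        missing = [c for c in HOTSPOT_COLUMNS if c not in col]
        if missing:
            raise ParseError(f"{path}: header missing columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                p = f[col["p_value"]]
                q = f[col["q_value"]]
                hotspots.append(
                    Hotspot(
                        span=Interval(
                            f[col["chrom"]],
                            int(f[col["start"]]),
                            int(f[col["end"]]),
                        ),
                        variants=[],
                        D=int(f[col["n_variants"]]),
                        G=int(f[col["n_positions"]]),
                        mean_funseq=float(f[col["mean_funseq"]]),
                        compartment=f[col["compartment"]],
                        p_value=None if p == "" else float(p),
                        q_value=None if q == "" else float(q),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row: {exc}") from exc
            expected = hotspots[-1].donor_score
            got = float(f[col["donor_score"]])
            if not math.isclose(expected, got, rel_tol=1e-9):
                raise ParseError(
                    f"{path}:{lineno}: donor_score {got} != D^2/G = {expected}"
                )
    return hotspots
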