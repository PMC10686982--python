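"""Genomic feature labels and nearest-gene assignment for hotspots.

Labels follow a fixed precedence: Promoter > Exon > Intron > Downstream >
Distal Intergenic, with the promoter window +/-3 kb of the TSS
(strand-oriented) and Downstream meaning within 3 kb past the gene end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from regspot.io import Interval, ParseError

__all__ = [
    "Gene",
    "GeneModel",
    "read_gene_model",
    "annotate",
    "nearest_gene",
    "annotation_frequencies",
    "LABELS",
]

LABELS = ("Promoter", "Exon", "Intron", "Downstream", "Distal Intergenic")


@dataclass(frozen=True, slots=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int  # 0-based
    tx_end: int  # exclusive
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.gene_id}: tx_start >= tx_end")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside tx")

    @property
    def tss(self) -> int:
        """0-based transcription start: tx_start on +, tx_end-1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


class GeneModel:
    """A collection of genes indexed by chromosome."""

    def __init__(self, genes: Iterable[Gene]) -> None:
        self.genes = list(genes)
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.tx_start, g.tx_end, g.gene_id))

    def on_chrom(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    def __len__(self) -> int:
        return len(self.genes)


def read_gene_model(path: str | Path) -> GeneModel:
    """Read genes from BED12 (.bed) or a 6-column TSV.

    The TSV columns are gene_id, chrom, strand, tx_start, tx_end, exons
    where exons is a comma-separated list of start-end pairs
    (e.g. "100-200,300-400"), all 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed12(path)
    return _read_gene_tsv(path)


def _read_bed12(path: Path) -> GeneModel:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED12 row") from exc
            exons = tuple(
                (start + o, start + o + s) for o, s in zip(offsets, sizes)
            )
            genes.append(Gene(name, chrom, strand, start, end, exons))
    return GeneModel(genes)


def _read_gene_tsv(path: Path) -> GeneModel:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 TSV columns")
            try:
                exons = tuple(
                    tuple(int(x) for x in block.split("-"))
                    for block in f[5].split(",")
                    if block
                )
                genes.append(
                    Gene(f[0], f[1], f[2], int(f[3]), int(f[4]), exons)  # type: ignore[arg-type]
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed gene row: {exc}") from exc
    return GeneModel(genes)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Write the 6-column TSV accepted by :func:`read_gene_model`."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttx_start\ttx_end\texons\n")
        for g in model.genes:
            blocks = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{blocks}\n"
            )


def _promoter_interval(g: Gene, up: int, down: int) -> tuple[int, int]:
    if g.strand == "+":
        return max(0, g.tss - up), g.tss + down + 1
    return max(0, g.tss - down), g.tss + up + 1


def _downstream_interval(g: Gene, reach: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.tx_end, g.tx_end + reach
    return max(0, g.tx_start - reach), g.tx_start


def _hits(interval: Interval, start: int, end: int) -> bool:
    return interval.start < end and start < interval.end


def annotate(
    interval: Interval,
    gene_model: GeneModel,
    promoter_up: int = 3000,
    promoter_down: int = 3000,
    downstream_reach: int = 3000,
) -> str:
    """First matching label by precedence for one interval."""
    genes = gene_model.on_chrom(interval.chrom)
    if any(_hits(interval, *_promoter_interval(g, promoter_up, promoter_down)) for g in genes):
        return "Promoter"
    if any(_hits(interval, s, e) for g in genes for s, e in g.exons):
        return "Exon"
    if any(_hits(interval, g.tx_start, g.tx_end) for g in genes):
        return "Intron"
    if any(_hits(interval, *_downstream_interval(g, downstream_reach)) for g in genes):
        return "Downstream"
    return "Distal Intergenic"


def nearest_gene(
    interval: Interval, gene_model: GeneModel
) -> Optional[tuple[str, int]]:
    """Gene whose TSS is closest to the interval midpoint.

    Distance is signed by the gene's strand: negative means the midpoint
    lies upstream of the TSS. Returns None when the chromosome has no
    genes. Ties prefer the smaller absolute distance, then gene order.
    """
    genes = gene_model.on_chrom(interval.chrom)
    if not genes:
        return None
    mid = (interval.start + interval.end) // 2
    best = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
    signed = mid - best.tss if best.strand == "+" else best.tss - mid
    return best.gene_id, signed


def annotation_frequencies(
    intervals: Iterable[Interval],
    gene_model: GeneModel,
    promoter_up: int = 3000,
    promoter_down: int = 3000,
) -> dict[str, float]:
    """Fraction of intervals per label; sums to 1 over non-empty input."""
    counts = Counter(
        annotate(iv, gene_model, promoter_up, promoter_down) for iv in intervals
    )
    total = sum(counts.values())
    if total == 0:
        return {}
    return {label: counts[label] / total for label in LABELS if counts[label]}
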