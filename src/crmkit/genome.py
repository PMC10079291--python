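"""Genome coordinate universe: chromosome layouts and gene models.

All coordinates are 0-based half-open (BED convention). GTF-style 1-based
closed input is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class GenomeError(ValueError):
    """Raised for malformed or inconsistent genomic inputs."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered mapping of chromosome name to length in bp.

    Parameters
    ----------
    lengths
        Mapping of unique chromosome names to positive lengths.
    """

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.lengths) == 0:
            raise GenomeError("genome layout has no chromosomes")
        for name, length in self.lengths.items():
            if length <= 0:
                raise GenomeError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    @classmethod
    def read(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column chromosome-sizes file (name<TAB>length)."""
        lengths: dict[str, int] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise GenomeError(f"{path}:{lineno}: expected 'name length', got {line!r}")
            name = fields[0]
            if name in lengths:
                raise GenomeError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            try:
                lengths[name] = int(fields[1])
            except ValueError as exc:
                raise GenomeError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
        return cls(lengths)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{length}\n" for name, length in self.lengths.items())
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, span, and exon structure.

    TSS is ``start`` on the + strand and ``end - 1`` on the − strand; the
    transcription termination site (TTS) is the opposite terminus. Exons are
    non-overlapping, sorted, and contained in the gene span.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise GenomeError(f"gene {self.gene_id!r}: invalid span [{self.start}, {self.end})")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise GenomeError(
                    f"gene {self.gene_id!r}: exons must be sorted, disjoint and within span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start site as a single bp position."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site as a single bp position."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gene_models(path: str | Path, layout: GenomeLayout | None = None) -> list[GeneModel]:
    """Read gene models from a BED12 file.

    Columns: chrom, start, end, name, score, strand, thickStart, thickEnd,
    rgb, blockCount, blockSizes, blockStarts. Blocks become exons.
    """
    genes: list[GeneModel] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise GenomeError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(fields)}")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        strand = fields[5]
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise GenomeError(f"{path}:{lineno}: block count mismatch")
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
        if layout is not None:
            if chrom not in layout:
                raise GenomeError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > layout[chrom]:
                raise GenomeError(f"{path}:{lineno}: gene {name!r} exceeds chromosome length")
        genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12."""
    lines = []
    for g in genes:
        exons = g.exons if g.exons else ((g.start, g.end),)
        sizes = ",".join(str(e - s) for s, e in exons)
        offsets = ",".join(str(s - g.start) for s, e in exons)
        lines.append(
            f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
            f"\t{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
        )
    Path(path).write_text("".join(lines))


def read_gtf_lite(path: str | Path) -> list[GeneModel]:
    """Read a minimal GTF: exon features with gene_id attributes.

    GTF 1-based closed coordinates are converted to 0-based half-open.
    """
    by_gene: dict[str, dict] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GenomeError(f"{path}:{lineno}: GTF needs 9 columns")
        chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
        if feature != "exon":
            continue
        gene_id = None
        for attr in attrs.split(";"):
            attr = attr.strip()
            if attr.startswith("gene_id"):
                gene_id = attr.split(None, 1)[1].strip().strip('"')
                break
        if gene_id is None:
            raise GenomeError(f"{path}:{lineno}: exon without gene_id attribute")
        rec = by_gene.setdefault(gene_id, {"chrom": chrom, "strand": strand, "exons": []})
        rec["exons"].append((int(start) - 1, int(end)))
    genes = []
    for gene_id, rec in by_gene.items():
        exons = tuple(sorted(rec["exons"]))
        genes.append(
            GeneModel(gene_id, rec["chrom"], rec["strand"], exons[0][0], exons[-1][1], exons)
        )
    return genes


def iter_genes_by_chromosome(genes: Iterable[GeneModel]) -> Iterator[tuple[str, list[GeneModel]]]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, gs in by_chrom.items():
        yield chrom, sorted(gs, key=lambda g: (g.start, g.end, g.gene_id))
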