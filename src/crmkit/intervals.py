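"""Genomic interval primitives: peaks, overlap algebra, annotation.

Every operation uses 0-based half-open coordinates and the ≥1-shared-bp
overlap predicate. Sorted-array binary search backs the overlap queries;
the test suite checks all of them against brute-force all-pairs oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .genome import GeneModel, GenomeError, GenomeLayout, iter_genes_by_chromosome

FEATURE_PRIORITY = ("promoter", "TTS", "exon", "intron", "intergenic")

PROMOTER_UPSTREAM = 1000  # bp upstream of the TSS included in the promoter
PROMOTER_DOWNSTREAM = 100  # bp downstream of the TSS included in the promoter
TTS_UPSTREAM = 100  # bp upstream of the TTS included in the TTS window
TTS_DOWNSTREAM = 1000  # bp downstream of the TTS included in the TTS window


class PeakParseError(ValueError):
    """Raised when a peak file line does not parse under its dialect."""


@dataclass(frozen=True)
class Peak:
    """A named genomic interval with optional summit and enrichment score."""

    chromosome: str
    start: int
    end: int
    id: str = ""
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise GenomeError(f"peak {self.id!r}: invalid interval [{self.start}, {self.end})")
        if self.summit_offset is not None and not 0 <= self.summit_offset < self.end - self.start:
            raise GenomeError(f"peak {self.id!r}: summit offset outside interval")
        if self.score is not None and self.score < 0:
            raise GenomeError(f"peak {self.id!r}: negative score")

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint (floor) when absent."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


class PeakSet:
    """Ordered collection of peaks with a provenance label."""

    def __init__(
        self,
        peaks: Iterable[Peak],
        label: str = "",
        layout: GenomeLayout | None = None,
    ) -> None:
        self.peaks: list[Peak] = list(peaks)
        self.label = label
        self.layout = layout
        if layout is not None:
            for p in self.peaks:
                if p.chromosome not in layout:
                    raise GenomeError(
                        f"peak {p.id!r} on unknown chromosome {p.chromosome!r}"
                    )
                if p.end > layout[p.chromosome]:
                    raise GenomeError(
                        f"peak {p.id!r} [{p.start}, {p.end}) exceeds "
                        f"{p.chromosome} length {layout[p.chromosome]}"
                    )
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PeakSet) and self.peaks == other.peaks

    def summits(self) -> np.ndarray:
        return np.array([p.summit for p in self.peaks], dtype=np.int64)

    def scores(self) -> np.ndarray:
        """Scores as a float array; raises if any peak lacks one."""
        out = np.empty(len(self.peaks))
        for i, p in enumerate(self.peaks):
            if p.score is None:
                raise ValueError(f"peak {p.id!r} has no score")
            out[i] = p.score
        return out

    def _overlap_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (sorted starts, running max of ends) for overlap queries."""
        if self._index is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for p in self.peaks:
                by_chrom.setdefault(p.chromosome, []).append((p.start, p.end))
            index = {}
            for chrom, ivs in by_chrom.items():
                ivs.sort()
                starts = np.array([s for s, _ in ivs], dtype=np.int64)
                ends = np.maximum.accumulate(np.array([e for _, e in ivs], dtype=np.int64))
                index[chrom] = (starts, ends)
            self._index = index
        return self._index

    def overlaps_point(self, chromosome: str, pos: int) -> bool:
        return self.overlaps_interval(chromosome, pos, pos + 1)

    def overlaps_interval(self, chromosome: str, start: int, end: int) -> bool:
        index = self._overlap_index()
        if chromosome not in index:
            return False
        starts, max_ends = index[chromosome]
        k = int(np.searchsorted(starts, end, side="left"))
        return k > 0 and max_ends[k - 1] > start


def read_peaks(
    path: str | Path,
    dialect: str = "narrowPeak",
    layout: GenomeLayout | None = None,
    label: str | None = None,
) -> PeakSet:
    """Read a peak file in BED3, BED6, or narrowPeak dialect.

    narrowPeak column 10 populates ``summit_offset``; −1 there means absent.
    Malformed lines raise :class:`PeakParseError` naming the line.
    """
    min_cols = {"BED3": 3, "BED6": 6, "narrowPeak": 10}
    if dialect not in min_cols:
        raise ValueError(f"unknown dialect {dialect!r}")
    need = min_cols[dialect]
    peaks = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < need:
            raise PeakParseError(
                f"{path}:{lineno}: {dialect} needs {need} columns, got {len(fields)}"
            )
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise PeakParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise PeakParseError(f"{path}:{lineno}: empty interval [{start}, {end})")
        name = fields[3] if need >= 6 else f"peak_{lineno}"
        score: float | None = None
        summit: int | None = None
        if dialect == "narrowPeak":
            score = float(fields[6])  # signalValue column
            summit = int(fields[9])
            if summit == -1:
                summit = None
        elif dialect == "BED6" and fields[4] not in (".", ""):
            score = float(fields[4])
        try:
            peaks.append(Peak(chrom, start, end, name, score, summit))
        except GenomeError as exc:
            raise PeakParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(peaks, label or Path(path).stem, layout)


def write_peaks(peaks: PeakSet, path: str | Path, dialect: str = "narrowPeak") -> None:
    lines = []
    for p in peaks:
        if dialect == "BED3":
            lines.append(f"{p.chromosome}\t{p.start}\t{p.end}\n")
        elif dialect == "BED6":
            score = "." if p.score is None else f"{p.score:g}"
            lines.append(f"{p.chromosome}\t{p.start}\t{p.end}\t{p.id}\t{score}\t.\n")
        elif dialect == "narrowPeak":
            score = 0.0 if p.score is None else p.score
            summit = -1 if p.summit_offset is None else p.summit_offset
            lines.append(
                f"{p.chromosome}\t{p.start}\t{p.end}\t{p.id}\t0\t.\t{score:g}\t-1\t-1\t{summit}\n"
            )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("".join(lines))


def overlap_any(query: PeakSet, subject: PeakSet) -> np.ndarray:
    """Per-query booleans: does each query peak share ≥1 bp with any subject peak?"""
    return np.array(
        [subject.overlaps_interval(p.chromosome, p.start, p.end) for p in query],
        dtype=bool,
    )


def partition_by_marks(crm: PeakSet, k27ac: PeakSet, k27me3: PeakSet) -> np.ndarray:
    """Label each CRM peak by histone-mark context.

    I: overlaps both H3K27ac and H3K27me3 (heterogeneous CRMs);
    II: only H3K27me3 (repressive); III: only H3K27ac (active);
    IV: neither. The labels partition the input exactly.
    """
    has_ac = overlap_any(crm, k27ac)
    has_me3 = overlap_any(crm, k27me3)
    labels = np.where(
        has_ac & has_me3, "I", np.where(has_me3, "II", np.where(has_ac, "III", "IV"))
    )
    return labels.astype("U3")


def venn_two(a: PeakSet, b: PeakSet) -> tuple[np.ndarray, np.ndarray]:
    """Two-set Venn labels over two peak lists.

    Returns per-peak labels for ``a`` (``shared`` / ``a_only``) and for ``b``
    (``shared`` / ``b_only``). Reciprocally overlapping peaks are each counted
    once in their own list; shared regions are not re-merged.
    """
    in_b = overlap_any(a, b)
    in_a = overlap_any(b, a)
    labels_a = np.where(in_b, "shared", "a_only").astype("U6")
    labels_b = np.where(in_a, "shared", "b_only").astype("U6")
    return labels_a, labels_b


def merge_union(sets: Sequence[PeakSet], label: str = "merged") -> PeakSet:
    """Collapse overlapping or book-ended intervals across peak sets.

    The merged peak inherits the summit of its highest-score constituent
    (leftmost summit when no constituent has a score) and the maximum score.
    """
    all_peaks = [p for s in sets for p in s]
    by_chrom: dict[str, list[Peak]] = {}
    for p in all_peaks:
        by_chrom.setdefault(p.chromosome, []).append(p)
    layout = next((s.layout for s in sets if s.layout is not None), None)
    merged: list[Peak] = []
    for chrom in sorted(by_chrom):
        peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end, p.id))
        group: list[Peak] = []
        group_end = -1
        for p in peaks + [None]:  # sentinel flushes the last group
            if p is not None and (not group or p.start <= group_end):
                group.append(p)
                group_end = max(group_end, p.end)
                continue
            if group:
                start = group[0].start
                end = group_end
                scored = [q for q in group if q.score is not None]
                if scored:
                    best = max(scored, key=lambda q: (q.score, -q.start, q.id))
                else:
                    best = min(group, key=lambda q: q.summit)
                score = max((q.score for q in scored), default=None)
                merged.append(
                    Peak(
                        chrom,
                        start,
                        end,
                        f"{label}_{len(merged) + 1}",
                        score,
                        best.summit - start,
                    )
                )
            if p is not None:
                group = [p]
                group_end = p.end
    return PeakSet(merged, label, layout)


def _point_to_gene_distance(pos: int, gene: GeneModel) -> int:
    """bp gap from a point to a gene span; 0 when the point lies inside."""
    if gene.start <= pos < gene.end:
        return 0
    if pos < gene.start:
        return gene.start - pos
    return pos - (gene.end - 1)


def nearest_gene(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> list[str | None]:
    """Assign each peak to the nearest gene within ``max_distance`` of its summit.

    Distance is zero when the summit lies inside the gene span, else the bp
    gap from the summit to the nearer gene terminus. Ties break on smallest
    distance, then lexicographically smallest gene id. Peaks farther than
    ``max_distance`` from every gene are unassigned (None).
    """
    if not genes:
        raise ValueError("nearest_gene requires a non-empty gene collection")
    by_chrom = {chrom: gs for chrom, gs in iter_genes_by_chromosome(genes)}
    assignments: list[str | None] = []
    for p in peaks:
        candidates = by_chrom.get(p.chromosome, [])
        best: tuple[int, str] | None = None
        for g in candidates:
            d = _point_to_gene_distance(p.summit, g)
            if d > max_distance:
                continue
            key = (d, g.gene_id)
            if best is None or key < best:
                best = key
        assignments.append(best[1] if best else None)
    return assignments


def annotate_features(peaks: PeakSet, genes: Sequence[GeneModel]) -> list[str]:
    """Classify each peak summit into a genomic-feature category.

    The promoter window spans −1 kb to +100 bp around the TSS and the TTS
    window −100 bp to +1 kb around the TTS, both strand-aware. A summit in
    multiple features takes the highest-priority label
    (promoter > TTS > exon > intron > intergenic).
    """
    by_chrom = {chrom: gs for chrom, gs in iter_genes_by_chromosome(genes)}
    rank = {f: i for i, f in enumerate(FEATURE_PRIORITY)}
    labels = []
    for p in peaks:
        pos = p.summit
        best = "intergenic"
        for g in by_chrom.get(p.chromosome, []):
            d_tss = pos - g.tss if g.strand == "+" else g.tss - pos
            if -PROMOTER_UPSTREAM <= d_tss <= PROMOTER_DOWNSTREAM:
                best = "promoter"
                break  # highest priority; no better label possible
            d_tts = pos - g.tts if g.strand == "+" else g.tts - pos
            if -TTS_UPSTREAM <= d_tts <= TTS_DOWNSTREAM:
                candidate = "TTS"
            elif g.start <= pos < g.end:
                candidate = "exon" if any(s <= pos < e for s, e in g.exons) else "intron"
            else:
                continue
            if rank[candidate] < rank[best]:
                best = candidate
        labels.append(best)
    return labels


def random_regions(
    layout: GenomeLayout,
    lengths: Sequence[int],
    seed: int,
    label: str = "random",
) -> PeakSet:
    """Place intervals of the requested lengths uniformly over the genome.

    Each interval keeps its requested length; the chromosome is drawn with
    probability proportional to the number of valid start positions for that
    length, then the start uniformly among them. Fixed seed → identical output.
    """
    chroms = layout.chromosomes
    if not chroms:
        raise GenomeError("empty genome layout")
    chrom_lengths = np.array([layout[c] for c in chroms], dtype=np.int64)
    rng = np.random.default_rng(seed)
    peaks = []
    for i, length in enumerate(lengths):
        valid = chrom_lengths - length + 1
        valid = np.maximum(valid, 0)
        total = int(valid.sum())
        if total <= 0:
            raise GenomeError(f"length {length} exceeds every chromosome")
        ci = rng.choice(len(chroms), p=valid / total)
        start = int(rng.integers(0, valid[ci]))
        peaks.append(Peak(chroms[ci], start, start + length, f"{label}_{i + 1}"))
    return PeakSet(peaks, label, layout)


def shift_peaks(peaks: PeakSet, offset: int) -> PeakSet:
    """Translate every peak by a fixed offset (utility for tests/simulation)."""
    return PeakSet(
        [replace(p, start=p.start + offset, end=p.end + offset) for p in peaks],
        peaks.label,
    )
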