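"""Fixed-bin coverage tracks and region-level quantification.

A :class:`SignalTrack` stores, per chromosome, the mean per-bp fragment depth
within each fixed-size bin, so quantification has per-bp semantics regardless
of bin size. Normalizations follow the coverage-tool conventions: BPM rescales
so all bin values sum to 10^6; RPGC rescales so the genome-wide mean per-bp
coverage is 1 (effective genome size = sum of chromosome lengths).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GeneModel, GenomeLayout
from .intervals import Peak, PeakSet

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("raw", "RPGC", "BPM", "spikein-scaled")


@dataclass
class SignalTrack:
    """Fixed-bin per-chromosome coverage with a declared normalization."""

    bin_size: int
    values: dict[str, np.ndarray]
    layout: GenomeLayout
    normalization: str = "raw"
    total_mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for chrom in self.layout.chromosomes:
            n_bins = math.ceil(self.layout[chrom] / self.bin_size)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n_bins)
            elif len(self.values[chrom]) != n_bins:
                raise ValueError(
                    f"{chrom}: expected {n_bins} bins, got {len(self.values[chrom])}"
                )

    def bin_widths(self, chrom: str) -> np.ndarray:
        """Actual bp width of each bin (the last bin may be partial)."""
        length = self.layout[chrom]
        n_bins = len(self.values[chrom])
        widths = np.full(n_bins, self.bin_size, dtype=np.int64)
        widths[-1] = length - (n_bins - 1) * self.bin_size
        return widths

    def scaled(self, factor: float, normalization: str) -> "SignalTrack":
        return SignalTrack(
            self.bin_size,
            {c: v * factor for c, v in self.values.items()},
            self.layout,
            normalization,
            self.total_mapped_reads,
        )

    def copy(self) -> "SignalTrack":
        return self.scaled(1.0, self.normalization)


def binned_coverage(
    fragments: PeakSet,
    layout: GenomeLayout,
    bin_size: int = 50,
    mode: str = "raw",
) -> SignalTrack:
    """Build a fixed-bin coverage track from fragment intervals.

    Raw bin values are the mean per-bp fragment depth within the bin, so a
    uniform 1× fragment tiling yields bins of 1.0. BPM and RPGC rescale as
    described in the module docstring.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if mode not in ("raw", "RPGC", "BPM"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    # per-bp depth via difference arrays, then per-bin sums
    diffs = {c: np.zeros(layout[c] + 1) for c in layout.chromosomes}
    for frag in fragments:
        d = diffs.get(frag.chromosome)
        if d is None:
            continue
        s = max(0, frag.start)
        e = min(layout[frag.chromosome], frag.end)
        if s < e:
            d[s] += 1.0
            d[e] -= 1.0
    values: dict[str, np.ndarray] = {}
    total_bp = 0.0
    for chrom in layout.chromosomes:
        depth = np.cumsum(diffs[chrom][:-1])
        n_bins = math.ceil(layout[chrom] / bin_size)
        edges = np.arange(n_bins) * bin_size
        sums = np.add.reduceat(depth, edges)
        widths = np.full(n_bins, bin_size, dtype=np.int64)
        widths[-1] = layout[chrom] - edges[-1]
        values[chrom] = sums / widths
        total_bp += float(sums.sum())
    track = SignalTrack(bin_size, values, layout, "raw", len(fragments))
    if mode == "raw":
        return track
    if total_bp == 0:
        raise ValueError(f"cannot {mode}-normalize a track with zero total signal")
    if mode == "BPM":
        bin_total = sum(float(v.sum()) for v in values.values())
        return track.scaled(1e6 / bin_total, "BPM")
    # RPGC: genome-wide mean per-bp coverage -> 1
    return track.scaled(layout.total_length / total_bp, "RPGC")


def _window_values(track: SignalTrack, chrom: str, start: int, window: int) -> np.ndarray:
    """Per-bp track values over [start, start + window); zero outside bounds."""
    out = np.zeros(window)
    if chrom not in track.values:
        return out
    length = track.layout[chrom]
    lo = max(start, 0)
    hi = min(start + window, length)
    if lo < hi:
        pos = np.arange(lo, hi)
        out[lo - start : hi - start] = track.values[chrom][pos // track.bin_size]
    return out


def matrix_at_summits(
    track: SignalTrack,
    peaks: PeakSet,
    window: int = 5000,
    bin: int = 50,
) -> "SignalMatrix":
    """Summit-centered signal matrix: one row per peak, ``window/bin`` columns."""
    if window % bin != 0:
        raise ValueError("window must be divisible by bin")
    if bin % track.bin_size != 0:
        raise ValueError("track bin size must divide the matrix bin")
    n_cols = window // bin
    rows = np.empty((len(peaks), n_cols))
    for i, p in enumerate(peaks):
        per_bp = _window_values(track, p.chromosome, p.summit - window // 2, window)
        rows[i] = per_bp.reshape(n_cols, bin).mean(axis=1)
    return SignalMatrix(rows, [p.id for p in peaks], window, bin)


@dataclass
class SignalMatrix:
    """Region × bin signal values (rows ordered as the input regions)."""

    values: np.ndarray
    region_ids: list[str]
    window: int
    bin_size: int

    def to_tsv(self, path: str | Path) -> None:
        n_cols = self.values.shape[1]
        header = "region\t" + "\t".join(
            str(-self.window // 2 + j * self.bin_size) for j in range(n_cols)
        )
        body = "\n".join(
            rid + "\t" + "\t".join(f"{v:.6g}" for v in row)
            for rid, row in zip(self.region_ids, self.values)
        )
        Path(path).write_text(header + "\n" + body + "\n")


def metagene_profile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    flank: int = 5000,
    body_bins: int = 100,
    flank_bin: int = 50,
) -> np.ndarray:
    """Length-normalized gene-body profile with fixed-width flanks.

    Each gene contributes a strand-oriented (5'→3') vector: the upstream
    flank rebinned at ``flank_bin`` bp, the gene body rescaled to
    ``body_bins`` bins, and the downstream flank. The profile is the
    per-column mean over genes. Genes shorter than one bp per body bin are
    skipped with a warning.
    """
    if not genes:
        raise ValueError("metagene_profile requires genes")
    if flank % flank_bin != 0:
        raise ValueError("flank must be divisible by flank_bin")
    n_flank = flank // flank_bin
    vectors = []
    for g in genes:
        if g.length < body_bins:
            logger.warning("gene %s shorter than %d bp; skipped", g.gene_id, body_bins)
            continue
        per_bp = _window_values(track, g.chromosome, g.start - flank, g.length + 2 * flank)
        if g.strand == "-":
            per_bp = per_bp[::-1]
        up = per_bp[:flank].reshape(n_flank, flank_bin).mean(axis=1)
        down = per_bp[flank + g.length :].reshape(n_flank, flank_bin).mean(axis=1)
        body_bp = per_bp[flank : flank + g.length]
        edges = np.floor(np.linspace(0, g.length, body_bins + 1)).astype(int)
        csum = np.concatenate([[0.0], np.cumsum(body_bp)])
        body = (csum[edges[1:]] - csum[edges[:-1]]) / np.diff(edges)
        vectors.append(np.concatenate([up, body, down]))
    if not vectors:
        raise ValueError("no gene long enough for the requested body bins")
    return np.mean(vectors, axis=0)


def quantify_regions(
    track: SignalTrack,
    regions: PeakSet,
    statistic: str = "mean",
) -> np.ndarray:
    """Per-region mean or sum of the per-bp track signal (order preserved).

    Partial bins are weighted by their bp overlap with the region.
    """
    if statistic not in ("mean", "sum"):
        raise ValueError(f"unknown statistic {statistic!r}")
    bs = track.bin_size
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        vals = track.values[r.chromosome]
        length = track.layout[r.chromosome]
        s, e = max(0, r.start), min(length, r.end)
        if s >= e:
            out[i] = 0.0
            continue
        b0, b1 = s // bs, (e - 1) // bs
        idx = np.arange(b0, b1 + 1)
        bin_starts = idx * bs
        bin_ends = np.minimum(bin_starts + bs, length)
        overlap = np.minimum(e, bin_ends) - np.maximum(s, bin_starts)
        total = float(np.dot(vals[idx], overlap))
        out[i] = total / (r.end - r.start) if statistic == "mean" else total
    return out


def top_fraction(peaks: PeakSet, fraction: float) -> PeakSet:
    """Peaks with score at or above the (1 − fraction) score quantile.

    Ties at the threshold are all included, so the output may slightly exceed
    the requested fraction.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    scores = peaks.scores()
    if fraction == 1:
        return PeakSet(list(peaks), peaks.label, peaks.layout)
    threshold = np.quantile(scores, 1 - fraction)
    kept = [p for p, s in zip(peaks, scores) if s >= threshold]
    return PeakSet(kept, f"{peaks.label}_top{fraction:g}", peaks.layout)


def pearson_at_regions(
    track_a: SignalTrack,
    track_b: SignalTrack,
    regions: PeakSet,
) -> float:
    """Pearson r over paired per-region mean signals of two tracks."""
    if track_a.bin_size != track_b.bin_size:
        raise ValueError("tracks must share a bin size")
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    x = quantify_regions(track_a, regions, "mean")
    y = quantify_regions(track_b, regions, "mean")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined: zero variance at regions")
    return float(np.corrcoef(x, y)[0, 1])


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write the track as bedGraph, merging runs of equal-valued bins."""
    lines = []
    for chrom in track.layout.chromosomes:
        vals = track.values[chrom]
        length = track.layout[chrom]
        run_start = 0
        for b in range(1, len(vals) + 1):
            if b == len(vals) or vals[b] != vals[run_start]:
                if vals[run_start] != 0.0:
                    start_bp = run_start * track.bin_size
                    end_bp = min(b * track.bin_size, length)
                    lines.append(f"{chrom}\t{start_bp}\t{end_bp}\t{vals[run_start]:.6g}\n")
                run_start = b
    Path(path).write_text("".join(lines))


def read_bedgraph(
    path: str | Path,
    layout: GenomeLayout,
    bin_size: int,
    normalization: str = "raw",
) -> SignalTrack:
    """Read a bedGraph into a fixed-bin track (per-bp semantics, rebinned)."""
    per_bp = {c: np.zeros(layout[c]) for c in layout.chromosomes}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if chrom not in per_bp:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        per_bp[chrom][start:end] = value
    values = {}
    for chrom in layout.chromosomes:
        n_bins = math.ceil(layout[chrom] / bin_size)
        edges = np.arange(n_bins) * bin_size
        sums = np.add.reduceat(per_bp[chrom], edges)
        widths = np.full(n_bins, bin_size, dtype=np.int64)
        widths[-1] = layout[chrom] - edges[-1]
        values[chrom] = sums / widths
    return SignalTrack(bin_size, values, layout, normalization)


def fragments_from_bed(path: str | Path, layout: GenomeLayout) -> PeakSet:
    """Read fragment intervals from a BED3 file (thin wrapper for pipelines)."""
    from .intervals import read_peaks

    return read_peaks(path, "BED3", layout)
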