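"""Spike-in (ChIP-Rx) normalization and differential-signal quantities.

Exogenous chromatin added at a fixed mass ratio lets between-sample ChIP
signal be compared on an absolute scale: reads mapping to spike-in peaks
estimate per-sample recovery, and scaling each sample by
reference-count / sample-count removes recovery and depth differences that
within-sample normalizations (BPM/RPGC) cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import PeakSet, overlap_any
from .signal import SignalTrack

TISSUES = ("AC", "VG", "WE")
TREATMENTS = ("DMSO", "TSA")


@dataclass
class SampleLibrary:
    """One sequencing library: experimental + spike-in fragments and labels."""

    sample_id: str
    experimental: PeakSet
    spikein: PeakSet
    tissue: str = "WE"
    treatment: str = "DMSO"
    replicate: int = 1


@dataclass(frozen=True)
class NormalizationFactor:
    """Per-sample spike-in scaling factor (reference count / sample count)."""

    sample_id: str
    spikein_peak_reads: int
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError(f"{self.sample_id}: non-positive factor")


def spikein_factors(
    libraries: Sequence[SampleLibrary],
    spikein_peaks: PeakSet,
    reference: str = "min",
) -> dict[str, NormalizationFactor]:
    """Compute per-sample spike-in normalization factors.

    ``n_i`` is the number of spike-in fragments overlapping the spike-in
    peak set; ``factor_i = n_ref / n_i``. ``reference="min"`` uses the
    smallest count across samples so every factor is ≤ 1; otherwise the
    named sample's count is the reference (its own factor is exactly 1).
    """
    counts: dict[str, int] = {}
    for lib in libraries:
        n = int(overlap_any(lib.spikein, spikein_peaks).sum())
        if n == 0:
            raise ValueError(f"sample {lib.sample_id!r} has no spike-in reads in peaks")
        counts[lib.sample_id] = n
    if reference == "min":
        n_ref = min(counts.values())
    else:
        if reference not in counts:
            raise ValueError(f"reference sample {reference!r} not among libraries")
        n_ref = counts[reference]
    return {
        sid: NormalizationFactor(sid, n, n_ref / n) for sid, n in counts.items()
    }


def write_factors(factors: Iterable[NormalizationFactor], path: str | Path) -> None:
    lines = ["sample_id\tspikein_peak_reads\tfactor\n"]
    for f in factors:
        lines.append(f"{f.sample_id}\t{f.spikein_peak_reads}\t{f.factor:.6g}\n")
    Path(path).write_text("".join(lines))


def apply_factor(track: SignalTrack, factor: NormalizationFactor) -> SignalTrack:
    """Scale a raw coverage track by a spike-in factor."""
    if track.normalization != "raw":
        raise ValueError(
            f"refusing to spike-in-scale a {track.normalization!r} track; "
            "factors apply to raw coverage only"
        )
    return track.scaled(factor.factor, "spikein-scaled")


def downsample_reads(
    library: SampleLibrary,
    fraction: float,
    seed: int,
    exact: bool = False,
) -> SampleLibrary:
    """Randomly subsample a library's fragments (experimental and spike-in).

    Default is Bernoulli per fragment with probability ``fraction``;
    ``exact=True`` keeps exactly ``round(fraction * n)`` fragments.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return library
    rng = np.random.default_rng(seed)

    def subsample(peaks: PeakSet) -> PeakSet:
        n = len(peaks)
        if exact:
            k = int(round(fraction * n))
            keep = np.zeros(n, dtype=bool)
            keep[rng.choice(n, size=k, replace=False)] = True
        else:
            keep = rng.random(n) < fraction
        return PeakSet([p for p, k in zip(peaks, keep) if k], peaks.label, peaks.layout)

    return replace(
        library,
        experimental=subsample(library.experimental),
        spikein=subsample(library.spikein),
    )


def region_fold_change(
    control: np.ndarray,
    treated: np.ndarray,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-region log2 fold change of treated over control scaled signal."""
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.shape != treated.shape:
        raise ValueError("control and treated must be paired, equal-length vectors")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (control < 0).any() or (treated < 0).any():
        raise ValueError("negative signal values")
    return np.log2(treated + pseudocount) - np.log2(control + pseudocount)


def delta_bar(
    control: np.ndarray,
    treated: np.ndarray,
    pseudocount: float = 1.0,
    method: str = "mean_log_ratio",
) -> float:
    """Log2-scale average difference between two per-region signal vectors.

    ``mean_log_ratio`` (default) averages the per-region log2 differences,
    i.e. the mean of :func:`region_fold_change`. ``log_ratio_of_means``
    instead takes log2 of the ratio of the two region means.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size == 0:
        raise ValueError("empty region set")
    if method == "mean_log_ratio":
        return float(np.mean(region_fold_change(control, treated, pseudocount)))
    if method == "log_ratio_of_means":
        if (control < 0).any() or (treated < 0).any():
            raise ValueError("negative signal values")
        return float(
            np.log2(treated.mean() + pseudocount) - np.log2(control.mean() + pseudocount)
        )
    raise ValueError(f"unknown method {method!r}")
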