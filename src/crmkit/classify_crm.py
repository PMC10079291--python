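"""CRM-level categorization: localization and germ-layer spatial class.

Localization asks whether an Hdac1-bound CRM sits under germ-layer-specific
pan-H3K acetylation (LC), under acetylation shared between animal-cap and
vegetal-mass explants (NL), or under no acetylation peak at all (NP). The
spatial class compares spike-in-scaled pan-H3Kac signal between the two
explants at a fold threshold (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import PeakSet, overlap_any

LOCALIZATION_LABELS = ("LC", "NL", "NP")
SPATIAL_LABELS = ("AC", "VG", "ubiquitous")


@dataclass
class CrmAnnotation:
    """Per-CRM record combining every categorical call."""

    peak_id: str
    cluster: str
    localization: str = "NP"
    spatial: str = "NA"
    nearest_gene: str | None = None
    ac_signal: float = 0.0
    vg_signal: float = 0.0


def localization_category(
    crm: PeakSet,
    ac_peaks: PeakSet,
    vg_peaks: PeakSet,
    venn_ac_labels: np.ndarray,
    venn_vg_labels: np.ndarray,
) -> np.ndarray:
    """Classify each CRM as LC (localized), NL (non-localized), or NP.

    ``venn_*_labels`` are the per-peak labels from
    :func:`crmkit.intervals.venn_two` over the AC and VG pan-H3Kac peak sets.
    A CRM overlapping any AC-only or VG-only acetylation peak is LC; one
    overlapping only shared peaks is NL; one overlapping none is NP. LC takes
    precedence when a CRM touches both specific and shared peaks.
    """
    ac_specific = PeakSet(
        [p for p, lab in zip(ac_peaks, venn_ac_labels) if lab == "a_only"], "AC_specific"
    )
    vg_specific = PeakSet(
        [p for p, lab in zip(vg_peaks, venn_vg_labels) if lab == "b_only"], "VG_specific"
    )
    shared = PeakSet(
        [p for p, lab in zip(ac_peaks, venn_ac_labels) if lab == "shared"]
        + [p for p, lab in zip(vg_peaks, venn_vg_labels) if lab == "shared"],
        "shared",
    )
    hits_specific = overlap_any(crm, ac_specific) | overlap_any(crm, vg_specific)
    hits_shared = overlap_any(crm, shared)
    return np.where(hits_specific, "LC", np.where(hits_shared, "NL", "NP")).astype("U2")


def spatial_crm_category(
    ac_signal: Sequence[float],
    vg_signal: Sequence[float],
    fold: float = 2.0,
) -> np.ndarray:
    """Assign AC / VG / ubiquitous by the fold difference of explant signals.

    AC when the animal-cap signal is at least ``fold`` times the vegetal
    signal, VG symmetrically; anything not exceeding the fold threshold in
    either direction is ubiquitous. Regions with zero signal in both explants
    are ubiquitous (degenerate case).
    """
    ac = np.asarray(ac_signal, dtype=float)
    vg = np.asarray(vg_signal, dtype=float)
    if ac.shape != vg.shape:
        raise ValueError("signal vectors must be paired")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if (ac < 0).any() or (vg < 0).any():
        raise ValueError("negative signals")
    both_zero = (ac == 0) & (vg == 0)
    labels = np.where(
        ac >= fold * vg, "AC", np.where(vg >= fold * ac, "VG", "ubiquitous")
    )
    labels = np.where(both_zero, "ubiquitous", labels)
    return labels.astype("U10")


def annotations_to_tsv(annotations: Iterable[CrmAnnotation], crm: PeakSet, path: str | Path) -> None:
    """Write one row per CRM: BED coordinates plus every category column."""
    by_id = {p.id: p for p in crm}
    lines = [
        "chrom\tstart\tend\tpeak_id\tcluster\tlocalization\tspatial"
        "\tnearest_gene\tac_signal\tvg_signal\n"
    ]
    for ann in annotations:
        p = by_id[ann.peak_id]
        gene = ann.nearest_gene if ann.nearest_gene is not None else "."
        lines.append(
            f"{p.chromosome}\t{p.start}\t{p.end}\t{ann.peak_id}\t{ann.cluster}"
            f"\t{ann.localization}\t{ann.spatial}\t{gene}"
            f"\t{ann.ac_signal:.6g}\t{ann.vg_signal:.6g}\n"
        )
    Path(path).write_text("".join(lines))
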