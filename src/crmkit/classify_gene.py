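"""Gene-level categorization: CRM-derived gene classes, zygotic filtering,
temporal trends, germ-layer expression categories, DE thresholding.

Expression tables are pandas DataFrames indexed by gene id. Time-course
columns are hours post-fertilization (floats); spatial tables carry the five
dissected-tissue columns AC, DMZ, LMZ, VMZ, VG.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel
from .intervals import PeakSet, nearest_gene

logger = logging.getLogger(__name__)

MESODERM_TISSUES = ("DMZ", "LMZ", "VMZ")
SPATIAL_GENE_LABELS = ("AC", "MZ", "VG", "NL", "NE")


def read_expression_table(path: str | Path, time_columns: bool = False) -> pd.DataFrame:
    """Read a genes × samples TPM table (TSV, header row, gene id first)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cells in expression table")
    if time_columns:
        df.columns = [float(c) for c in df.columns]
    return df


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table: gene, log2FC, FDR."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"log2FC", "FDR"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: DE table needs columns {sorted(required)}")
    if ((df["FDR"] < 0) | (df["FDR"] > 1)).any():
        raise ValueError(f"{path}: FDR outside [0, 1]")
    return df


def gene_classes(
    cluster_peaks: dict[str, PeakSet],
    genes: Sequence[GeneModel],
    max_distance: int = 10_000,
) -> pd.Series:
    """Map genes to classes 1–3 from the per-cluster nearest-gene sets.

    With G(X) the set of genes nearest to cluster-X CRMs (within
    ``max_distance``): Class 1 = G(I) ∪ (G(II) ∩ G(III)); Class 2 =
    G(II) \\ Class 1; Class 3 = G(III) \\ Class 1. Genes in no class are
    'unclassified'. Classes 1–3 are pairwise disjoint by construction and
    asserted on every run.
    """
    for key in ("I", "II", "III"):
        if key not in cluster_peaks:
            raise ValueError(f"missing cluster {key!r} peak set")
    g = {
        key: {gid for gid in nearest_gene(cluster_peaks[key], genes, max_distance) if gid}
        for key in ("I", "II", "III")
    }
    class1 = g["I"] | (g["II"] & g["III"])
    class2 = g["II"] - class1
    class3 = g["III"] - class1
    assert not (class1 & class2) and not (class1 & class3) and not (class2 & class3)
    labels = pd.Series("unclassified", index=[gm.gene_id for gm in genes], name="gene_class")
    labels[labels.index.isin(class1)] = "1"
    labels[labels.index.isin(class2)] = "2"
    labels[labels.index.isin(class3)] = "3"
    return labels


def zygotic_filter(
    timecourse: pd.DataFrame,
    maternal_window_hpf: float = 2.0,
    tpm_threshold: float = 1.0,
    horizon_hpf: float = 23.0,
) -> set[str]:
    """Strictly zygotic genes from a time-course TPM table.

    Removes (1) genes above ``tpm_threshold`` at any time point within the
    first ``maternal_window_hpf`` hours (residual maternal transcript), and
    (2) genes never reaching ``tpm_threshold`` up to ``horizon_hpf`` (never
    expressed). The remainder is the strictly zygotic set.
    """
    times = np.array([float(c) for c in timecourse.columns])
    early = times <= maternal_window_hpf
    if not early.any():
        raise ValueError("no time point within the maternal window")
    within = times <= horizon_hpf
    vals = timecourse.to_numpy(dtype=float)
    maternal_ok = (vals[:, early] <= tpm_threshold).all(axis=1)
    expressed = vals[:, within].max(axis=1) >= tpm_threshold
    keep = maternal_ok & expressed
    return set(timecourse.index[keep])


def class_trend(timecourse: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Per-class mean TPM at each time point (classes × time points)."""
    rows = {}
    for label in ("1", "2", "3"):
        members = classes.index[classes == label]
        members = timecourse.index.intersection(members)
        if len(members) == 0:
            logger.warning("gene class %s empty; trend omitted", label)
            continue
        rows[label] = timecourse.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T


def spatial_gene_category(
    tissues: pd.DataFrame,
    tpm_threshold: float = 1.0,
    cv_threshold: float = 0.1,
    literal_any_tissue_ne: bool = False,
) -> pd.Series:
    """Assign each gene a germ-layer expression category.

    The three mesoderm dissections (DMZ, LMZ, VMZ) are averaged into a single
    MZ value, giving a per-gene triple (AC, MZ, VG). A gene below
    ``tpm_threshold`` in all three collapsed values is NE (not expressed);
    with the ``literal_any_tissue_ne`` flag, any single raw dissected tissue
    below threshold makes the gene NE instead. An expressed gene whose triple
    has coefficient of variation (population sd / mean) below ``cv_threshold``
    is NL (evenly expressed); otherwise the gene takes the germ layer of its
    maximum value.
    """
    required = ("AC",) + MESODERM_TISSUES + ("VG",)
    missing = [c for c in required if c not in tissues.columns]
    if missing:
        raise ValueError(f"missing tissue columns: {missing}")
    ac = tissues["AC"].to_numpy(dtype=float)
    mz = tissues[list(MESODERM_TISSUES)].to_numpy(dtype=float).mean(axis=1)
    vg = tissues["VG"].to_numpy(dtype=float)
    triple = np.column_stack([ac, mz, vg])
    if literal_any_tissue_ne:
        ne = (tissues[list(required)].to_numpy(dtype=float) < tpm_threshold).any(axis=1)
    else:
        ne = (triple < tpm_threshold).all(axis=1)
    mean = triple.mean(axis=1)
    sd = triple.std(axis=1, ddof=0)
    cv = np.divide(sd, mean, out=np.zeros_like(sd), where=mean > 0)
    layer = np.array(["AC", "MZ", "VG"])[triple.argmax(axis=1)]
    labels = np.where(ne, "NE", np.where(cv < cv_threshold, "NL", layer))
    return pd.Series(labels, index=tissues.index, name="spatial_category")


def de_threshold_filter(
    de: pd.DataFrame,
    min_fold: float = 2.0,
    max_fdr: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets at strict fold/FDR cutoffs.

    up: log2FC > log2(min_fold) and FDR < max_fdr; down symmetric.
    """
    cut = np.log2(min_fold)
    sig = de["FDR"] < max_fdr
    up = set(de.index[sig & (de["log2FC"] > cut)])
    down = set(de.index[sig & (de["log2FC"] < -cut)])
    return up, down


def premature_activation_fraction(class2_genes: set[str], up_set: set[str]) -> float:
    """Fraction of Class 2 genes found in the HDAC-inhibition up-set."""
    if not class2_genes:
        raise ValueError("empty Class 2 gene set")
    return len(class2_genes & up_set) / len(class2_genes)
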