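"""End-to-end orchestration: from a dataset directory to report tables.

The pipeline reproduces the post-alignment analysis stages in order: CRM
partition by histone marks, localization and spatial categorization under
spike-in-scaled pan-H3Kac signal, differential-acetylation statistics, gene
classes with temporal trends, and spatial-category × DE-direction enrichment
tests. A ``score`` step compares every classification against the planted
ground truth of a synthetic dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify_crm, classify_gene, spikein, stats
from .genome import GenomeLayout, read_gene_models
from .intervals import (
    PeakSet,
    merge_union,
    nearest_gene,
    partition_by_marks,
    random_regions,
    read_peaks,
    venn_two,
)
from .signal import binned_coverage, quantify_regions, top_fraction
from .spikein import SampleLibrary, apply_factor, delta_bar, region_fold_change, spikein_factors
from .synthetic import GroundTruth, SimulatedDataset

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "crm_clusters.tsv",
    "localization_by_cluster.tsv",
    "spikein_signal_delta.tsv",
    "fold_change_stats.tsv",
    "gene_classes.tsv",
    "spatial_enrichment.tsv",
)


@dataclass
class PipelineConfig:
    """Analysis thresholds; the defaults are the study's printed values."""

    fold: float = 2.0
    tpm_threshold: float = 1.0
    cv_threshold: float = 0.1
    nearest_gene_distance: int = 10_000
    top_fraction: float = 0.30
    de_min_fold: float = 2.0
    de_max_fdr: float = 0.05
    maternal_window_hpf: float = 2.0
    horizon_hpf: float = 23.0
    reference: str = "min"
    pseudocount: float = 1.0
    delta_bar_method: str = "mean_log_ratio"
    merge_combined_stages: bool = True
    bin_size: int = 50
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_dataset_inputs(datadir: str | Path) -> SimulatedDataset:
    """Re-read an emitted dataset directory through the public file readers."""
    from .synthetic import SimulationConfig

    d = Path(datadir)
    config = SimulationConfig.from_yaml(d / "config.yaml")
    layout = GenomeLayout.read(d / "genome.sizes")
    spike_layout = GenomeLayout.read(d / "spike.sizes")
    genes = read_gene_models(d / "genes.bed12", layout)
    crm = read_peaks(d / "hdac1_crm.narrowPeak", "narrowPeak", layout)
    k27ac = read_peaks(d / "h3k27ac.narrowPeak", "narrowPeak", layout)
    k27me3 = read_peaks(d / "h3k27me3.narrowPeak", "narrowPeak", layout)
    pan_ac = read_peaks(d / "pan_h3kac_AC.narrowPeak", "narrowPeak", layout)
    pan_vg = read_peaks(d / "pan_h3kac_VG.narrowPeak", "narrowPeak", layout)
    spike_peaks = read_peaks(d / "spike_h2av.narrowPeak", "narrowPeak", spike_layout)
    libraries = []
    for tissue in ("AC", "VG"):
        for treatment in ("DMSO", "TSA"):
            for rep in (1, 2):
                sid = f"{tissue}_{treatment}_rep{rep}"
                libraries.append(
                    SampleLibrary(
                        sid,
                        read_peaks(d / f"frags_{sid}.bed", "BED3", layout),
                        read_peaks(d / f"spike_frags_{sid}.bed", "BED3", spike_layout),
                        tissue,
                        treatment,
                        rep,
                    )
                )
    timecourse = classify_gene.read_expression_table(d / "timecourse_tpm.tsv", time_columns=True)
    tissues = classify_gene.read_expression_table(d / "tissue_tpm.tsv")
    de_tables = {
        name: classify_gene.read_de_table(d / f"de_{name}.tsv") for name in ("AC", "VG")
    }
    truth = GroundTruth.read(d)
    return SimulatedDataset(
        config,
        layout,
        spike_layout,
        genes,
        crm,
        k27ac,
        k27me3,
        pan_ac,
        pan_vg,
        spike_peaks,
        libraries,
        timecourse,
        tissues,
        de_tables,
        truth,
    )


def _scaled_region_signal(
    ds: SimulatedDataset, config: PipelineConfig, regions: PeakSet
) -> tuple[dict[tuple[str, str], np.ndarray], dict[str, spikein.NormalizationFactor]]:
    """Replicate-averaged spike-in-scaled mean signal per region and condition."""
    factors = spikein_factors(ds.libraries, ds.spike_peaks, config.reference)
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    for lib in ds.libraries:
        track = binned_coverage(lib.experimental, ds.layout, config.bin_size, "raw")
        scaled = apply_factor(track, factors[lib.sample_id])
        sig = quantify_regions(scaled, regions, "mean")
        pooled.setdefault((lib.tissue, lib.treatment), []).append(sig)
    averaged = {key: np.mean(vals, axis=0) for key, vals in pooled.items()}
    return averaged, factors


@dataclass
class PipelineResult:
    clusters: pd.DataFrame
    localization: pd.DataFrame
    signal_delta: pd.DataFrame
    fold_stats: pd.DataFrame
    gene_classes: pd.DataFrame
    enrichment: pd.DataFrame
    annotations: pd.DataFrame
    trends: pd.DataFrame
    top_peak_expression: pd.DataFrame
    premature_fraction: dict[str, float]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.clusters.to_csv(out / "crm_clusters.tsv", sep="\t", index=False)
        self.localization.to_csv(out / "localization_by_cluster.tsv", sep="\t")
        self.signal_delta.to_csv(out / "spikein_signal_delta.tsv", sep="\t", index=False)
        self.fold_stats.to_csv(out / "fold_change_stats.tsv", sep="\t", index=False)
        self.gene_classes.to_csv(out / "gene_classes.tsv", sep="\t")
        self.enrichment.to_csv(out / "spatial_enrichment.tsv", sep="\t", index=False)
        self.annotations.to_csv(out / "crm_annotations.tsv", sep="\t", index=False)
        self.trends.to_csv(out / "class_trends.tsv", sep="\t")
        self.top_peak_expression.to_csv(out / "top_peak_expression.tsv", sep="\t", index=False)
        pd.Series(self.premature_fraction).rename("fraction").to_csv(
            out / "premature_activation.tsv", sep="\t"
        )


def run_pipeline(ds: SimulatedDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every analysis stage on a dataset and return the report tables."""
    config = config or PipelineConfig()
    crm = ds.crm
    n_crm = len(crm)
    logger.info("stage clusters: %d CRMs", n_crm)
    cluster_labels = partition_by_marks(crm, ds.k27ac, ds.k27me3)
    assert len(cluster_labels) == n_crm
    clusters = pd.DataFrame(
        {
            "peak_id": [p.id for p in crm],
            "chrom": [p.chromosome for p in crm],
            "start": [p.start for p in crm],
            "end": [p.end for p in crm],
            "cluster": cluster_labels,
        }
    )

    logger.info("stage localization")
    venn_ac, venn_vg = venn_two(ds.pan_kac_ac, ds.pan_kac_vg)
    loc_labels = classify_crm.localization_category(
        crm, ds.pan_kac_ac, ds.pan_kac_vg, venn_ac, venn_vg
    )
    localization = (
        pd.crosstab(cluster_labels, loc_labels, normalize="index")
        .rename_axis(index="cluster", columns="localization")
    )

    logger.info("stage spike-in signal (seed %d for randomized control)", config.seed)
    scaled, factors = _scaled_region_signal(ds, config, crm)
    rand = random_regions(ds.layout, [p.length for p in crm], config.seed)
    scaled_rand, _ = _scaled_region_signal(ds, config, rand)
    rows = []
    for name, mask in [("all", np.ones(n_crm, dtype=bool))] + [
        (c, cluster_labels == c) for c in ("I", "II", "III", "IV")
    ]:
        dmso = scaled[("AC", "DMSO")][mask]
        tsa = scaled[("AC", "TSA")][mask]
        rows.append(
            {
                "regions": f"cluster_{name}" if name != "all" else "all_crm",
                "n": int(mask.sum()),
                "mean_dmso": dmso.mean(),
                "mean_tsa": tsa.mean(),
                "delta_bar": delta_bar(dmso, tsa, config.pseudocount, config.delta_bar_method),
            }
        )
    rows.append(
        {
            "regions": "randomized",
            "n": len(rand),
            "mean_dmso": scaled_rand[("AC", "DMSO")].mean(),
            "mean_tsa": scaled_rand[("AC", "TSA")].mean(),
            "delta_bar": delta_bar(
                scaled_rand[("AC", "DMSO")],
                scaled_rand[("AC", "TSA")],
                config.pseudocount,
                config.delta_bar_method,
            ),
        }
    )
    signal_delta = pd.DataFrame(rows)

    logger.info("stage spatial CRM categories and fold-change statistics")
    ac_sig = scaled[("AC", "DMSO")]
    vg_sig = scaled[("VG", "DMSO")]
    spatial_labels = classify_crm.spatial_crm_category(ac_sig, vg_sig, config.fold)
    fc = region_fold_change(scaled[("AC", "DMSO")], scaled[("AC", "TSA")], config.pseudocount)
    fc_rows = []
    for cl in ("I", "II", "III", "IV"):
        cmask = cluster_labels == cl
        groups = [("all", cmask)] + [
            (sp, cmask & (spatial_labels == sp)) for sp in ("AC", "VG", "ubiquitous")
        ]
        for sp, mask in groups:
            if mask.sum() < 2:
                continue
            w = stats.welch_t(scaled[("AC", "TSA")][mask], scaled[("AC", "DMSO")][mask])
            d = stats.cohens_d(scaled[("AC", "TSA")][mask], scaled[("AC", "DMSO")][mask])
            fc_rows.append(
                {
                    "cluster": cl,
                    "spatial": sp,
                    "n": int(mask.sum()),
                    "mean_log2fc": fc[mask].mean(),
                    "welch_t": w.t,
                    "welch_df": w.df,
                    "welch_p": w.p,
                    "cohens_d": d,
                }
            )
    fold_stats = pd.DataFrame(fc_rows)

    logger.info("stage gene classes")
    cluster_sets = {
        c: PeakSet([p for p, lab in zip(crm, cluster_labels) if lab == c], f"cluster_{c}", ds.layout)
        for c in ("I", "II", "III")
    }
    classes = classify_gene.gene_classes(cluster_sets, ds.genes, config.nearest_gene_distance)
    zygotic = classify_gene.zygotic_filter(
        ds.timecourse, config.maternal_window_hpf, config.tpm_threshold, config.horizon_hpf
    )
    zygotic_classes = classes[classes.index.isin(zygotic)]
    trends = classify_gene.class_trend(ds.timecourse, zygotic_classes)
    gene_table = pd.DataFrame(
        {"gene_class": classes, "strictly_zygotic": classes.index.isin(zygotic)}
    ).rename_axis(index="gene")

    logger.info("stage nearest genes / annotations")
    nearest = nearest_gene(crm, ds.genes, config.nearest_gene_distance)
    annotations = pd.DataFrame(
        {
            "chrom": [p.chromosome for p in crm],
            "start": [p.start for p in crm],
            "end": [p.end for p in crm],
            "peak_id": [p.id for p in crm],
            "cluster": cluster_labels,
            "localization": loc_labels,
            "spatial": spatial_labels,
            "nearest_gene": [g if g else "." for g in nearest],
            "ac_signal": ac_sig,
            "vg_signal": vg_sig,
        }
    )

    logger.info("stage top pan-H3Kac peak expression")
    top_rows = []
    for label, peaks, venn_labels, only in (
        ("AC", ds.pan_kac_ac, venn_ac, "a_only"),
        ("VG", ds.pan_kac_vg, venn_vg, "b_only"),
    ):
        specific = PeakSet(
            [p for p, lab in zip(peaks, venn_labels) if lab == only], f"{label}_specific", ds.layout
        )
        if len(specific) == 0:
            continue
        top = top_fraction(specific, config.top_fraction)
        genes_near = {g for g in nearest_gene(top, ds.genes, config.nearest_gene_distance) if g}
        genes_near &= set(ds.tissues.index)
        if not genes_near:
            continue
        sub = ds.tissues.loc[sorted(genes_near)]
        top_rows.append(
            {
                "specific_to": label,
                "n_top_peaks": len(top),
                "n_genes": len(genes_near),
                "mean_tpm_AC": sub["AC"].mean(),
                "mean_tpm_VG": sub["VG"].mean(),
            }
        )
    top_peak_expression = pd.DataFrame(top_rows)

    logger.info("stage spatial enrichment")
    spatial_genes = classify_gene.spatial_gene_category(
        ds.tissues, config.tpm_threshold, config.cv_threshold
    )
    class2 = set(classes.index[classes == "2"])
    enr_rows = []
    premature = {}
    for name, de in ds.de_tables.items():
        up, down = classify_gene.de_threshold_filter(de, config.de_min_fold, config.de_max_fdr)
        premature[name] = classify_gene.premature_activation_fraction(class2, up)
        for direction, de_set in (("up", up), ("down", down)):
            pvals = []
            for cat in classify_gene.SPATIAL_GENE_LABELS:
                cat_genes = set(spatial_genes.index[spatial_genes == cat])
                universe = set(spatial_genes.index)
                a = len(cat_genes & de_set)
                b = len(cat_genes - de_set)
                c = len(de_set - cat_genes)
                dd = len(universe - cat_genes - de_set)
                p = stats.fisher_greater(stats.ContingencyTable2x2(a, b, c, dd))
                pvals.append(p)
                enr_rows.append(
                    {
                        "explant": name,
                        "direction": direction,
                        "category": cat,
                        "in_category_and_de": a,
                        "in_category_only": b,
                        "de_only": c,
                        "neither": dd,
                        "fisher_p": p,
                    }
                )
            adjusted = stats.benjamini_hochberg(pvals)
            for row, padj in zip(enr_rows[-len(pvals):], adjusted):
                row["fisher_p_bh"] = padj
    enrichment = pd.DataFrame(enr_rows)

    return PipelineResult(
        clusters,
        localization,
        signal_delta,
        fold_stats,
        gene_table,
        enrichment,
        annotations,
        trends,
        top_peak_expression,
        premature,
    )


def score_against_truth(result: PipelineResult, truth: GroundTruth) -> pd.DataFrame:
    """Per-classifier recovery rates against the generator's planted labels."""
    crm_truth = truth.crm.set_index("peak_id")
    ann = result.annotations.set_index("peak_id")
    rows = []

    def add(name: str, recovered: float, threshold: float) -> None:
        rows.append(
            {
                "metric": name,
                "recovery": recovered,
                "threshold": threshold,
                "passed": bool(recovered >= threshold),
            }
        )

    add("crm_cluster", float((ann["cluster"] == crm_truth["cluster"]).mean()), 0.99)
    add("crm_spatial", float((ann["spatial"] == crm_truth["spatial"]).mean()), 0.95)
    # localization truth is implied by cluster + spatial class:
    # acetylated CRMs (clusters I/III) are LC when germ-layer-specific,
    # NL when shared; unacetylated CRMs are NP
    acet = crm_truth["cluster"].isin(["I", "III"])
    true_loc = np.where(
        acet & crm_truth["spatial"].isin(["AC", "VG"]),
        "LC",
        np.where(acet, "NL", "NP"),
    )
    add("crm_localization", float((ann["localization"] == true_loc).mean()), 0.95)
    gene_truth = truth.gene.set_index("gene_id")
    pred = result.gene_classes["gene_class"].astype(str)
    true_cls = gene_truth["gene_class"].astype(str).reindex(pred.index)
    add("gene_class", float((pred == true_cls).mean()), 0.95)
    zyg_pred = result.gene_classes["strictly_zygotic"]
    zyg_true = gene_truth["temporal"] == "zygotic"
    add("zygotic_filter", float((zyg_pred == zyg_true.loc[zyg_pred.index]).mean()), 0.99)
    return pd.DataFrame(rows)
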