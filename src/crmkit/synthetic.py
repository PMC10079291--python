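"""Synthetic dataset generator with known ground truth.

Emulates the statistical structure of an explant ChIP-Rx / RNA-seq study of
HDAC-bound cis-regulatory modules (CRMs) in an early embryo:

* a multi-chromosome genome with non-overlapping exon-bearing gene models;
* CRMs planted with an epigenetic cluster (I heterogeneous / II repressive /
  III active / IV unmarked) and a germ-layer spatial class (AC / VG /
  ubiquitous) expressed as an animal-cap : vegetal-mass signal ratio;
* H3K27ac / H3K27me3 peak sets consistent with the planted clusters, and
  explant-specific pan-H3Kac peak sets consistent with the spatial classes;
* fragment-level ChIP libraries (AC/VG × DMSO/TSA × 2 replicates) with
  multiplicative lognormal region noise and a spike-in chromosome admixed at
  a fixed mass ratio with constant recovery across treatments — HDAC
  inhibition (TSA) raises experimental ChIP yield genome-wide, which only a
  spike-in normalization can see;
* maternal/zygotic TPM time courses, a five-tissue spatial TPM table, and
  TSA-vs-control differential-expression tables with a controllable
  premature-activation probability for repressed (Class-2-like) genes.

All randomness flows from a single integer seed through independent
``numpy`` generator streams, so a fixed seed reproduces every file byte for
byte.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import GeneModel, GenomeLayout, write_gene_models
from .intervals import Peak, PeakSet, write_peaks
from .spikein import SampleLibrary

CLUSTERS = ("I", "II", "III", "IV")
SPATIAL_CLASSES = ("AC", "VG", "ubiquitous")
GENE_LAYER_LABELS = ("AC", "MZ", "VG", "NL", "NE")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 1
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 1_500_000 for i in range(1, 5)}
    )
    spike_chromosome_length: int = 200_000
    n_spike_peaks: int = 50
    spike_peak_width: int = 400
    n_genes: int = 800
    gene_length_median: float = 2000.0
    gene_length_sigma: float = 0.5
    max_exons: int = 8
    # CRM counts per epigenetic cluster: proportions follow the four-way
    # partition of 23,442 Hdac1 peaks (3548/1389/13,669/4836) scaled to 2,000
    cluster_counts: dict[str, int] = field(
        default_factory=lambda: {"I": 300, "II": 120, "III": 1170, "IV": 410}
    )
    crm_min_width: int = 300
    crm_max_width: int = 800
    crm_min_gap: int = 300
    # germ-layer spatial classes (~37% AC-specific, ~38% VG-specific, rest shared)
    spatial_fractions: dict[str, float] = field(
        default_factory=lambda: {"AC": 0.37, "VG": 0.38, "ubiquitous": 0.25}
    )
    ac_vg_ratio: float = 4.0
    cluster_enrichment: dict[str, float] = field(
        default_factory=lambda: {"I": 1.0, "II": 0.4, "III": 1.0, "IV": 0.25}
    )
    base_enrichment: float = 1.0
    background_fraction: float = 0.3
    noise_sigma: float = 0.2
    spike_mass_ratio: float = 35.0  # experimental : spike-in chromatin, 35 : 1
    reads_per_library: int = 200_000
    fragment_length: int = 200
    tsa_multiplier: float = 3.0
    replicates: int = 2
    # expression
    time_grid_hpf: tuple[float, ...] = tuple(float(t) for t in range(24))
    zga_onset_hpf: float = 4.0
    class2_onset_hpf: float = 13.0
    maternal_fraction: float = 0.4
    tissue_fold_separation: float = 5.0
    gene_layer_fractions: dict[str, float] = field(
        default_factory=lambda: {"AC": 0.2, "MZ": 0.2, "VG": 0.2, "NL": 0.2, "NE": 0.2}
    )
    class2_activation_prob: float = 0.9
    expression_noise_sigma: float = 0.2

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["time_grid_hpf"] = list(self.time_grid_hpf)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "time_grid_hpf" in data:
            data["time_grid_hpf"] = tuple(float(t) for t in data["time_grid_hpf"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted labels sufficient to score every classifier in the pipeline."""

    crm: pd.DataFrame  # peak_id, cluster, spatial, gene (or '')
    gene: pd.DataFrame  # gene_id, temporal, gene_class, germ_layer, activated_ac, activated_vg

    def write(self, outdir: Path) -> None:
        self.crm.to_csv(outdir / "truth_crm.tsv", sep="\t", index=False)
        self.gene.to_csv(outdir / "truth_gene.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, outdir: Path) -> "GroundTruth":
        return cls(
            pd.read_csv(outdir / "truth_crm.tsv", sep="\t", keep_default_na=False),
            pd.read_csv(outdir / "truth_gene.tsv", sep="\t", keep_default_na=False),
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    layout: GenomeLayout
    spike_layout: GenomeLayout
    genes: list[GeneModel]
    crm: PeakSet
    k27ac: PeakSet
    k27me3: PeakSet
    pan_kac_ac: PeakSet
    pan_kac_vg: PeakSet
    spike_peaks: PeakSet
    libraries: list[SampleLibrary]
    timecourse: pd.DataFrame
    tissues: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.layout.write(out / "genome.sizes")
        self.spike_layout.write(out / "spike.sizes")
        write_gene_models(self.genes, out / "genes.bed12")
        write_peaks(self.crm, out / "hdac1_crm.narrowPeak")
        write_peaks(self.k27ac, out / "h3k27ac.narrowPeak")
        write_peaks(self.k27me3, out / "h3k27me3.narrowPeak")
        write_peaks(self.pan_kac_ac, out / "pan_h3kac_AC.narrowPeak")
        write_peaks(self.pan_kac_vg, out / "pan_h3kac_VG.narrowPeak")
        write_peaks(self.spike_peaks, out / "spike_h2av.narrowPeak")
        for lib in self.libraries:
            write_peaks(lib.experimental, out / f"frags_{lib.sample_id}.bed", "BED3")
            write_peaks(lib.spikein, out / f"spike_frags_{lib.sample_id}.bed", "BED3")
        self.timecourse.to_csv(out / "timecourse_tpm.tsv", sep="\t")
        self.tissues.to_csv(out / "tissue_tpm.tsv", sep="\t")
        for name, de in self.de_tables.items():
            de.to_csv(out / f"de_{name}.tsv", sep="\t")
        self.truth.write(out)
        self.config.to_yaml(out / "config.yaml")


# ---------------------------------------------------------------------------
# genome


def _place_non_overlapping(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    widths: Sequence[int],
    min_gap: int,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    max_tries: int = 200,
) -> list[tuple[str, int, int]]:
    """Uniformly place intervals that keep ``min_gap`` bp from one another."""
    chroms = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    occ = {c: sorted(occupied.get(c, [])) if occupied else [] for c in chroms}
    placed = []
    for w in widths:
        for _ in range(max_tries):
            ci = rng.choice(len(chroms), p=lens / lens.sum())
            chrom = chroms[ci]
            limit = chrom_lengths[chrom] - w
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            ivs = occ[chrom]
            i = bisect.bisect_left(ivs, (start, start + w))
            ok = True
            if i > 0 and ivs[i - 1][1] + min_gap > start:
                ok = False
            if ok and i < len(ivs) and start + w + min_gap > ivs[i][0]:
                ok = False
            if ok:
                ivs.insert(i, (start, start + w))
                placed.append((chrom, start, start + w))
                break
        else:
            raise ValueError("could not place intervals at the requested density")
    return placed


def make_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeLayout, list[GeneModel]]:
    """Build the chromosome layout and non-overlapping gene models."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    layout = GenomeLayout(dict(config.chromosome_lengths))
    lengths = np.maximum(
        rng.lognormal(math.log(config.gene_length_median), config.gene_length_sigma, config.n_genes),
        200,
    ).astype(int)
    spans = _place_non_overlapping(
        rng, dict(config.chromosome_lengths), lengths.tolist(), min_gap=100
    )
    genes = []
    order = sorted(range(len(spans)), key=lambda i: (spans[i][0], spans[i][1]))
    for rank, i in enumerate(order):
        chrom, start, end = spans[i]
        gene_len = end - start
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(1, config.max_exons + 1))
        k = min(k, max(1, gene_len // 100))
        if k == 1:
            exons = ((start, end),)
        else:
            cuts = np.sort(rng.choice(np.arange(1, gene_len), size=2 * (k - 1), replace=False))
            bounds = np.concatenate([[0], cuts, [gene_len]])
            exons = tuple(
                (start + int(bounds[2 * j]), start + int(bounds[2 * j + 1]))
                for j in range(k)
            )
        genes.append(GeneModel(f"gene{rank + 1:04d}", chrom, strand, start, end, exons))
    return layout, genes


# ---------------------------------------------------------------------------
# ChIP


def _nearest_gene_bruteforce(
    summit: int, chrom: str, genes: Sequence[GeneModel], max_distance: int = 10_000
) -> str:
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chromosome != chrom:
            continue
        if g.start <= summit < g.end:
            d = 0
        elif summit < g.start:
            d = g.start - summit
        else:
            d = summit - (g.end - 1)
        if d <= max_distance and (best is None or (d, g.gene_id) < best):
            best = (d, g.gene_id)
    return best[1] if best else ""


def _jittered_peak(
    rng: np.random.Generator, p: Peak, layout: GenomeLayout, name: str, score: float
) -> Peak:
    start = max(0, p.start - int(rng.integers(0, 100)))
    end = min(layout[p.chromosome], p.end + int(rng.integers(0, 100)))
    return Peak(p.chromosome, start, end, name, score, (p.summit - start))


def plant_crms(
    config: SimulationConfig,
    layout: GenomeLayout,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> tuple[PeakSet, PeakSet, PeakSet, PeakSet, PeakSet, pd.DataFrame]:
    """Place CRMs with cluster/spatial labels and emit consistent mark peaks."""
    n_crm = sum(config.cluster_counts.values())
    widths = rng.integers(config.crm_min_width, config.crm_max_width, n_crm)
    spans = _place_non_overlapping(
        rng, dict(config.chromosome_lengths), widths.tolist(), config.crm_min_gap
    )
    spans.sort()
    clusters = np.repeat(
        list(config.cluster_counts), list(config.cluster_counts.values())
    )
    rng.shuffle(clusters)
    frac = config.spatial_fractions
    spatial = rng.choice(
        SPATIAL_CLASSES, size=n_crm, p=[frac[c] for c in SPATIAL_CLASSES]
    )
    crm_peaks, k27ac, k27me3, pan_ac, pan_vg = [], [], [], [], []
    records = []
    for i, ((chrom, start, end), cluster, spat) in enumerate(zip(spans, clusters, spatial)):
        pid = f"crm{i + 1:05d}"
        score = float(rng.lognormal(math.log(10), 0.5))
        peak = Peak(chrom, start, end, pid, score, (end - start) // 2)
        crm_peaks.append(peak)
        if cluster in ("I", "III"):
            k27ac.append(_jittered_peak(rng, peak, layout, f"k27ac_{pid}", score))
        if cluster in ("I", "II"):
            k27me3.append(_jittered_peak(rng, peak, layout, f"k27me3_{pid}", score))
        # pan-H3Kac peaks exist where the CRM is acetylated; explant-specific
        # presence encodes the spatial class. Shared (ubiquitous) regions carry
        # higher enrichment, as observed for AC/VG-shared acetylation.
        if cluster in ("I", "III"):
            kac_score = score * (2.0 if spat == "ubiquitous" else 1.0)
            if spat in ("AC", "ubiquitous"):
                pan_ac.append(_jittered_peak(rng, peak, layout, f"kac_ac_{pid}", kac_score))
            if spat in ("VG", "ubiquitous"):
                pan_vg.append(_jittered_peak(rng, peak, layout, f"kac_vg_{pid}", kac_score))
        records.append(
            {
                "peak_id": pid,
                "chrom": chrom,
                "start": start,
                "end": end,
                "cluster": cluster,
                "spatial": spat,
                "gene": _nearest_gene_bruteforce((start + end) // 2, chrom, genes),
            }
        )
    truth = pd.DataFrame(records)
    crm = PeakSet(crm_peaks, "hdac1_crm", layout)
    return (
        crm,
        PeakSet(k27ac, "h3k27ac", layout),
        PeakSet(k27me3, "h3k27me3", layout),
        PeakSet(pan_ac, "pan_h3kac_AC", layout),
        PeakSet(pan_vg, "pan_h3kac_VG", layout),
        truth,
    )


def _tissue_factor(spatial: str, tissue: str, ratio: float) -> float:
    r = math.sqrt(ratio)
    if spatial == "ubiquitous":
        return 1.0
    if spatial == tissue:
        return r
    return 1.0 / r


def simulate_chip(
    config: SimulationConfig,
    layout: GenomeLayout,
    crm_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[list[SampleLibrary], PeakSet, GenomeLayout]:
    """Draw fragment-level ChIP libraries for AC/VG × DMSO/TSA × replicates.

    Per-CRM fragment rates are background plus cluster- and spatial-scaled
    enrichment with multiplicative lognormal noise. The spike-in chromosome
    receives a constant chromatin mass (1 : ``spike_mass_ratio`` relative to
    the untreated experimental mass) with constant recovery, so the TSA-driven
    genome-wide gain dilutes spike-in reads rather than changing their yield.
    """
    spike_layout = GenomeLayout({"chrSpike": config.spike_chromosome_length})
    spike_widths = [config.spike_peak_width] * config.n_spike_peaks
    spike_spans = _place_non_overlapping(
        rng, {"chrSpike": config.spike_chromosome_length}, spike_widths, 200
    )
    spike_spans.sort()
    spike_peaks = PeakSet(
        [
            Peak(c, s, e, f"h2av{i + 1:03d}", 10.0)
            for i, (c, s, e) in enumerate(spike_spans)
        ],
        "spike_h2av",
        spike_layout,
    )
    chroms = layout.chromosomes
    chrom_lens = np.array([layout[c] for c in chroms], dtype=float)
    n_crm = len(crm_truth)
    base_w = np.array(
        [
            config.base_enrichment
            * config.cluster_enrichment[row.cluster]
            * (row.end - row.start)
            / 550.0
            for row in crm_truth.itertuples()
        ]
    )
    mean_exp_mass_dmso = base_w.sum() / (1 - config.background_fraction)
    spike_mass = mean_exp_mass_dmso / config.spike_mass_ratio
    frag = config.fragment_length
    half = frag // 2
    libraries = []
    spike_starts_arr = np.array([p.start for p in spike_peaks])
    spike_widths_arr = np.array([p.length for p in spike_peaks])
    for tissue in ("AC", "VG"):
        tissue_f = np.array(
            [
                _tissue_factor(row.spatial, tissue, config.ac_vg_ratio)
                for row in crm_truth.itertuples()
            ]
        )
        # equal ChIP efficiency per explant: unit mass-weighted mean factor
        tissue_f *= base_w.sum() / (base_w * tissue_f).sum()
        for treatment in ("DMSO", "TSA"):
            mult = config.tsa_multiplier if treatment == "TSA" else 1.0
            for rep in (1, 2):
                sid = f"{tissue}_{treatment}_rep{rep}"
                noise = rng.lognormal(0.0, config.noise_sigma, n_crm)
                w = base_w * tissue_f * noise
                exp_mass = mult * (
                    w.sum() + config.background_fraction * mean_exp_mass_dmso
                )
                n_reads = config.reads_per_library
                n_spike = rng.binomial(n_reads, spike_mass / (spike_mass + exp_mass))
                n_exp = n_reads - n_spike
                bg_mass = mult * config.background_fraction * mean_exp_mass_dmso
                probs = np.concatenate([mult * w, [bg_mass]])
                probs /= probs.sum()
                counts = rng.multinomial(n_exp, probs)
                frags = []
                for ci, row in enumerate(crm_truth.itertuples()):
                    k = counts[ci]
                    if k == 0:
                        continue
                    centers = rng.normal(
                        (row.start + row.end) / 2, (row.end - row.start) / 4, k
                    ).astype(int)
                    limit = layout[row.chrom]
                    centers = np.clip(centers, half, limit - half - 1)
                    for c in centers:
                        frags.append(Peak(row.chrom, int(c) - half, int(c) - half + frag))
                n_bg = counts[-1]
                bg_chrom = rng.choice(len(chroms), size=n_bg, p=chrom_lens / chrom_lens.sum())
                for ci in bg_chrom:
                    limit = int(chrom_lens[ci]) - frag
                    s = int(rng.integers(0, limit))
                    frags.append(Peak(chroms[ci], s, s + frag))
                # spike-in fragments: 80% inside H2Av peaks, 20% background
                in_peak = rng.random(n_spike) < 0.8
                sfrags = []
                pk = rng.integers(0, len(spike_peaks), n_spike)
                for j in range(n_spike):
                    if in_peak[j]:
                        s = spike_starts_arr[pk[j]] + int(
                            rng.integers(0, max(1, spike_widths_arr[pk[j]] - frag))
                        )
                    else:
                        s = int(rng.integers(0, config.spike_chromosome_length - frag))
                    sfrags.append(Peak("chrSpike", s, s + frag))
                libraries.append(
                    SampleLibrary(
                        sid,
                        PeakSet(frags, f"exp_{sid}", layout),
                        PeakSet(sfrags, f"spike_{sid}", spike_layout),
                        tissue,
                        treatment,
                        rep,
                    )
                )
    return libraries, spike_peaks, spike_layout


# ---------------------------------------------------------------------------
# expression


def _true_gene_classes(crm_truth: pd.DataFrame) -> pd.Series:
    """Planted gene classes from the CRM-gene associations (set algebra)."""
    g = {
        c: set(crm_truth.loc[(crm_truth["cluster"] == c) & (crm_truth["gene"] != ""), "gene"])
        for c in ("I", "II", "III")
    }
    class1 = g["I"] | (g["II"] & g["III"])
    class2 = g["II"] - class1
    class3 = g["III"] - class1
    out = {}
    for gid in class1:
        out[gid] = "1"
    for gid in class2:
        out[gid] = "2"
    for gid in class3:
        out[gid] = "3"
    return pd.Series(out, name="gene_class")


def simulate_de(
    class2_genes: Sequence[str],
    other_genes: Sequence[str],
    activation_prob: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, set[str]]:
    """DE table (log2FC, FDR) with planted premature activation.

    Each Class-2-like gene is activated with probability ``activation_prob``
    (strong positive fold change, tiny FDR); everything else gets null-like
    statistics. Returns the table and the activated gene set.
    """
    rows = []
    activated = set()
    for gid in class2_genes:
        if rng.random() < activation_prob:
            activated.add(gid)
            rows.append((gid, 2.0 + rng.exponential(0.5), rng.uniform(1e-4, 0.01)))
        else:
            rows.append((gid, rng.normal(0.0, 0.3), rng.uniform(0.2, 1.0)))
    for gid in other_genes:
        rows.append((gid, rng.normal(0.0, 0.4), rng.uniform(0.05, 1.0)))
    de = pd.DataFrame(rows, columns=["gene", "log2FC", "FDR"]).set_index("gene")
    return de, activated


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    crm_truth: pd.DataFrame,
    rng: np.random.Generator,
    noise_sigma: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Time-course, five-tissue, and DE tables plus the per-gene truth table."""
    if noise_sigma is None:
        noise_sigma = config.expression_noise_sigma
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    gene_class = _true_gene_classes(crm_truth)
    temporal = np.where(rng.random(n) < config.maternal_fraction, "maternal", "zygotic")
    # repressed (Class-2-like) genes are zygotic with a late onset
    class2_mask = np.array([gene_class.get(gid) == "2" for gid in gene_ids])
    temporal[class2_mask] = "zygotic"
    times = np.array(config.time_grid_hpf)
    m0 = np.maximum(rng.lognormal(math.log(50), 1.0, n), 5.0)
    plateau = np.maximum(rng.lognormal(math.log(30), 1.0, n), 5.0)
    onset = np.where(class2_mask, config.class2_onset_hpf, config.zga_onset_hpf)
    tc = np.empty((n, len(times)))
    for i in range(n):
        if temporal[i] == "maternal":
            tc[i] = m0[i] * np.exp(-times / 6.0)
        else:
            ramp = np.clip((times - onset[i]) / 4.0, 0.0, 1.0)
            tc[i] = 0.05 + plateau[i] * ramp
    if noise_sigma > 0:
        tc *= rng.lognormal(0.0, noise_sigma, tc.shape)
    timecourse = pd.DataFrame(tc, index=pd.Index(gene_ids, name="gene"), columns=times)
    # five-tissue table with planted germ-layer labels
    frac = config.gene_layer_fractions
    layers = rng.choice(
        GENE_LAYER_LABELS, size=n, p=[frac[c] for c in GENE_LAYER_LABELS]
    )
    base = np.maximum(rng.lognormal(math.log(20), 0.7, n), 2.0)
    cols = ("AC", "DMZ", "LMZ", "VMZ", "VG")
    tissue_vals = np.empty((n, 5))
    fold = config.tissue_fold_separation
    for i, lab in enumerate(layers):
        if lab == "NE":
            tissue_vals[i] = rng.uniform(0.0, 0.5, 5)
            continue
        vals = {"AC": base[i], "MZ": base[i], "VG": base[i]}
        if lab in ("AC", "MZ", "VG"):
            vals[lab] = fold * base[i]
        tissue_vals[i] = [vals["AC"], vals["MZ"], vals["MZ"], vals["MZ"], vals["VG"]]
    if noise_sigma > 0:
        ne = layers == "NE"
        tissue_vals[~ne] *= rng.lognormal(0.0, noise_sigma, (int((~ne).sum()), 5))
    tissues = pd.DataFrame(tissue_vals, index=pd.Index(gene_ids, name="gene"), columns=cols)
    # DE tables per explant
    class2 = [gid for gid, m in zip(gene_ids, class2_mask) if m]
    others = [gid for gid, m in zip(gene_ids, class2_mask) if not m]
    de_tables = {}
    activated = {}
    for name in ("AC", "VG"):
        de, act = simulate_de(class2, others, config.class2_activation_prob, rng)
        de_tables[name] = de.loc[gene_ids]
        activated[name] = act
    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "temporal": temporal,
            "gene_class": [gene_class.get(gid, "unclassified") for gid in gene_ids],
            "germ_layer": layers,
            "activated_ac": [gid in activated["AC"] for gid in gene_ids],
            "activated_vg": [gid in activated["VG"] for gid in gene_ids],
        }
    )
    return timecourse, tissues, de_tables, gene_truth


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator under the config's seed."""
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(4)
    ]
    genome_rng, crm_rng, chip_rng, expr_rng = streams
    layout, genes = make_genome(config, genome_rng)
    crm, k27ac, k27me3, pan_ac, pan_vg, crm_truth = plant_crms(
        config, layout, genes, crm_rng
    )
    libraries, spike_peaks, spike_layout = simulate_chip(config, layout, crm_truth, chip_rng)
    timecourse, tissues, de_tables, gene_truth = simulate_expression(
        config, genes, crm_truth, expr_rng
    )
    truth = GroundTruth(crm_truth, gene_truth)
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
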