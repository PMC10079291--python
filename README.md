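# crmkit

Tools for the post-alignment analysis of HDAC-bound cis-regulatory modules
(CRMs) in early vertebrate embryos: classifying ChIP peaks by their histone
modification context, quantifying spike-in-normalized (ChIP-Rx) changes in
pan-H3K acetylation between germ layers and HDAC-inhibited conditions, and
mapping CRMs to temporally and spatially categorized gene classes.

The package is aimed at developmental epigenomics analyses of the explant
design used in *Xenopus* embryos: animal cap (AC, presumptive ectoderm) and
vegetal mass (VG, presumptive endoderm) explants profiled by pan-H3Kac
ChIP-seq with a *Drosophila*-style spike-in, alongside H3K27ac / H3K27me3
peak sets, maternal-to-zygotic expression time courses, and dissected-tissue
RNA-seq. A fully deterministic synthetic-data generator emulates this design
with known ground truth, so every classifier in the pipeline can be scored.

## What it computes

**CRM epigenetic clusters.** Each CRM (an Hdac1 ChIP peak) is placed in a
four-way partition by overlap (≥1 bp, half-open coordinates) with H3K27ac
and H3K27me3 peaks: cluster I overlaps both marks (heterogeneous), II only
H3K27me3 (repressive), III only H3K27ac (active), IV neither.

**Localization and spatial class.** From a two-set Venn of AC and VG
pan-H3Kac peaks, a CRM is LC (localized) if it overlaps a germ-layer-specific
acetylation peak, NL if it overlaps only shared peaks, NP if it overlaps
none. Independently, with spike-in-scaled signals *s*<sub>AC</sub> and
*s*<sub>VG</sub>, a CRM is AC-specific when
*s*<sub>AC</sub> ≥ 2·*s*<sub>VG</sub>, VG-specific symmetrically, and
ubiquitous otherwise.

**Spike-in (ChIP-Rx) normalization.** For library *i* with *n*<sub>i</sub>
spike-in reads in spike-in peaks, the scaling factor is
*f*<sub>i</sub> = *n*<sub>ref</sub> / *n*<sub>i</sub> (reference = smallest
count by default). Differential acetylation is summarized per region as
log2((treated + c)/(control + c)) with pseudocount *c*, and as
Δ̄ = mean over regions of the per-region log2 differences.

**Gene classes.** With G(X) the genes nearest (≤10 kb from the peak summit)
to cluster-X CRMs: Class 1 = G(I) ∪ (G(II) ∩ G(III)),
Class 2 = G(II) \ Class 1, Class 3 = G(III) \ Class 1. Strictly zygotic
genes are those ≤1 TPM at every time point within the first 2 hpf that reach
≥1 TPM by 23 hpf. Spatial gene categories collapse the three mesoderm
dissections to their mean, call genes below 1 TPM in all germ layers NE,
genes with coefficient of variation <0.1 NL, and label the rest by the
maximal germ layer.

**Statistics.** Welch two-sample t (two-sided, Welch–Satterthwaite df),
Cohen's d (pooled n−1-weighted sd), one-sided Fisher exact
(hypergeometric upper tail) with Benjamini–Hochberg adjustment, and
ChIP-qPCR percent input, 100·2^(adjusted input Ct − mean IP Ct), with
quadrature error propagation over replicate spreads.

## Worked example

Simulate the default study conditions (2,000 CRMs in the published cluster
proportions, 4-fold AC:VG signal separation, 1:35 spike-in mass ratio, a
3-fold genome-wide acetylation gain under the HDAC inhibitor TSA) and run
the full pipeline:

```bash
crmkit simulate --seed 1 --out data/
crmkit run-all --data data/ --out reports/
crmkit score --data data/ --out reports/
```

`reports/spikein_signal_delta.tsv` then contains the spike-in-scaled
pan-H3Kac signal at CRMs in DMSO- versus TSA-treated AC explants:

```
regions       n     mean_dmso  mean_tsa   delta_bar
all_crm       2000  8.230365   24.546666  1.418912
cluster_I     300   9.893485   29.357439  1.444948
cluster_II    120   4.456188   13.392869  1.332243
cluster_III   1170  10.080721  30.022881  1.466750
cluster_IV    410   2.837802   8.663868   1.288713
randomized    2000  2.113987   6.386119   0.979519
```

Every cluster gains acetylation under HDAC inhibition (Δ̄ ≈ 1.3–1.5, i.e.
a ~2.5–2.8-fold increase; the planted genome-wide gain is 3-fold, slightly
attenuated by the pseudocount at weakly covered regions), and randomized
control regions — dominated by background coverage — show a smaller but
still genome-wide gain, exactly the behaviour a within-sample normalization
would erase. `crmkit score` prints the ground-truth recovery of every
classifier; on this dataset the cluster, localization, gene-class and
zygotic calls are recovered at 100% and the spatial CRM labels at 97.95%
under the default lognormal signal noise (σ = 0.2).

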