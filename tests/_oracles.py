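"""Independent brute-force oracles used only by the test suite.

Everything here is all-pairs / exhaustive and shares no code path with the
implementation under test (numpy broadcasting is used purely to make the
all-pairs scans fast enough).
"""

import numpy as np


def overlap_matrix(query, subject):
    """All-pairs boolean overlap matrix under half-open ≥1 bp semantics."""
    if len(query) == 0 or len(subject) == 0:
        return np.zeros((len(query), len(subject)), dtype=bool)
    qc = np.array([p.chromosome for p in query])
    sc = np.array([p.chromosome for p in subject])
    qs = np.array([p.start for p in query])
    qe = np.array([p.end for p in query])
    ss = np.array([p.start for p in subject])
    se = np.array([p.end for p in subject])
    return (
        (qc[:, None] == sc[None, :])
        & (qs[:, None] < se[None, :])
        & (ss[None, :] < qe[:, None])
    )


def brute_overlap_any(query, subject):
    return overlap_matrix(query, subject).any(axis=1)


def brute_partition(crm, k27ac, k27me3):
    ac = brute_overlap_any(crm, k27ac)
    me3 = brute_overlap_any(crm, k27me3)
    out = []
    for a, m in zip(ac, me3):
        out.append("I" if a and m else "II" if m else "III" if a else "IV")
    return np.array(out)


def brute_merge(peaks_lists):
    """Sweep-line union of intervals (book-ended intervals merge)."""
    by_chrom = {}
    for peaks in peaks_lists:
        for p in peaks:
            by_chrom.setdefault(p.chromosome, []).append((p.start, p.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = [tuple(iv) for iv in out]
    return merged


def point_gene_distance(pos, gene):
    if gene.start <= pos < gene.end:
        return 0
    return gene.start - pos if pos < gene.start else pos - (gene.end - 1)


def brute_nearest(peaks, genes, max_distance):
    out = []
    for p in peaks:
        cands = [
            (point_gene_distance(p.summit, g), g.gene_id)
            for g in genes
            if g.chromosome == p.chromosome
            and point_gene_distance(p.summit, g) <= max_distance
        ]
        out.append(min(cands)[1] if cands else None)
    return out


def brute_annotate(peaks, genes):
    priority = ["promoter", "TTS", "exon", "intron", "intergenic"]
    out = []
    for p in peaks:
        pos = p.summit
        found = {"intergenic"}
        for g in genes:
            if g.chromosome != p.chromosome:
                continue
            tss = g.start if g.strand == "+" else g.end - 1
            tts = g.end - 1 if g.strand == "+" else g.start
            d_tss = pos - tss if g.strand == "+" else tss - pos
            d_tts = pos - tts if g.strand == "+" else tts - pos
            if -1000 <= d_tss <= 100:
                found.add("promoter")
            if -100 <= d_tts <= 1000:
                found.add("TTS")
            if g.start <= pos < g.end:
                found.add("exon" if any(s <= pos < e for s, e in g.exons) else "intron")
        out.append(next(f for f in priority if f in found))
    return out


def hypergeom_tail_enumeration(a, b, c, d):
    """P(X >= a) by explicit enumeration over all tables with fixed margins."""
    from math import comb

    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    total = 0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        if x >= a:
            total += comb(row1, x) * comb(n - row1, col1 - x)
    return total / denom
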