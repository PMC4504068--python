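# isoratio

Quantification of an **alternate-start transcript variant** relative to its
full-length transcript from exon-level RNA-seq read counts, plus the cohort
statistics used to evaluate such a variant as a tumor biomarker.

## The problem

Some genes express, alongside the canonical full-length mRNA, a shorter
transcript initiated inside an intron that shares only the 3' exons. A
well-studied example is a variant of the peroxisomal oxidase gene *ACOX2*:
a 15-exon gene whose variant starts just upstream of exon 10 and comprises
exons 10–15. Standard gene-level expression cannot separate the two
isoforms, but exon-level raw read counts can: exons upstream of the variant
start belong exclusively to the full-length transcript, while downstream
exons receive reads from both.

## The estimator

Assume reads per nucleotide are uniform within each transcript and that the
two isoforms are the only transcripts at the locus. With

- `L0` — summed exon length of exons 1..n (the full transcript),
- `L1` — summed exon length of the shared exons k..n,
- `r0` — raw reads on the exclusive exons 1..k−1,
- `r1` — raw reads on the shared exons k..n,

the reads assignable to each transcript and their abundance ratio follow in
closed form:

```
F0 = r0 · L0 / (L0 − L1)
F1 = r1 − F0 · L1 / L0
R  = (F1 / L1) / (F0 / L0)
```

`R` estimates the variant : full-length mRNA ratio and recovers the true
per-nucleotide coverage ratio `b/a` exactly on noiseless data. Counts must
be **raw integers** — not RPKM, not log-transformed. Negative `F1` (sampling
noise when the variant is absent) is clipped to zero and flagged; `r0 = 0`
with variant reads present yields an infinite-ratio sentinel.

Around the estimator the package provides exon read counting from SAM/BAM
(pysam), per-exon RPKM profiles, a binary positivity call (`R ≥ threshold`,
a sequencing surrogate for a PCR band assay), paired tumor/normal
log2-ratio differences, Wilcoxon rank-sum subgroup tests, exact Fisher
2×2/2×3 association tests, Kaplan–Meier / log-rank survival stratified by
positivity (lifelines), and a fully seeded synthetic-data generator.

## Worked example

```python
import numpy as np
from isoratio import SimConfig, build_gene_model, ExonCounts, estimate_isoform_ratio

model = build_gene_model(SimConfig())   # 15 exons x 100 bp, variant starts at exon 10
print(model.L0, model.L1)
counts = ExonCounts("sample1", np.array([100] * 9 + [300] * 6))
est = estimate_isoform_ratio(counts, model)
print(f"F0={est.f0:.0f} F1={est.f1:.0f} R={est.R:.2f}")
```

prints

```
1500 600
F0=1500 F1=1200 R=2.00
```

Each exclusive exon carries 100 reads (full-length coverage 1 read/bp) and
each shared exon 300 (combined coverage 3 reads/bp), so the variant is
twice as abundant as the full-length transcript: `R = 2`.

The same analysis end-to-end from the shell, on a simulated 87-pair
tumor/normal cohort:

```
isoratio simulate --seed 7 --out-dir demo
isoratio quantify --annotation demo/gene.gtf --gene-id SYNGENE \
    --variant-start-exon 10 --counts demo/exon_counts.tsv --out demo/estimates.tsv
isoratio cohort --estimates demo/estimates.tsv --sheet demo/sample_sheet.tsv \
    --out-dir demo/report
```

which ends with the cohort summary (abridged):

```
Paired tumor/normal: 87 pairs analyzed, 0 skipped; log2-ratio difference > 1 in 82 of 87 pairs.
Wilcoxon ER+/Her2- (n=49) vs ER-/Her2- (n=22): W=2256.0, p=9.88e-10 (asymptotic)
Fisher exact, positivity vs er: p=0.000456, OR=inf
Log-rank (all): chi2=2.08, p=0.15; n per stratum {'negative': 6, 'positive': 81}
```

The variant is strongly tumor-enriched (the log2-ratio difference exceeds 1
in 82 of 87 pairs), higher in ER+/Her2− than ER−/Her2− tumors, and
positivity associates with ER status — the structure the generator encodes.

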