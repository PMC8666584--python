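# tracseq

Analysis toolkit for **m7G tRNA modification and its downstream effect on
mRNA translation**, built around chemical cleavage sequencing (TRAC-seq:
NaBH4 reduction of N7-methylguanosine followed by aniline scission of the
tRNA backbone) and polysome-profiling mRNA-seq. It is aimed at
transcriptomics researchers who want to call m7G sites on mature tRNAs,
quantify tRNA expression from ALKB-treated small-RNA libraries, and test
whether translation-efficiency changes track the frequency of codons
decoded by m7G-modified tRNAs — together with a synthetic-data generator
that reproduces the statistical structure of all three experiments, so the
whole pipeline runs and is testable at desk scale.

## The statistics at the core

**Site calling.** Reads are aligned to mature tRNA sequences (introns
spliced out, `CCA` appended to the 3' end). Cleavage at an m7G leaves the
downstream fragment starting exactly at the modified base, so for each
1-based position *i* on a mature tRNA:

```
cleavage ratio_i  = s_i / d_i                    (read starts / read depth)
cleavage score_i  = log2( ratio_treated,i / ratio_non-treated,i )
```

A position in the variable-loop window **46–48** with **score > 4** and
treated-arm **ratio > 0.1** (both strict) is called m7G-modified. A
per-tRNA methylation level is the maximum score over the window, and
paired condition contrasts (e.g. methyltransferase knockdown vs control)
use the Wilcoxon signed-rank test, exact by sign-flip enumeration for
small panels.

**Expression.** Reads are counted with an exclusive-mapping rule (ties
between genomic loci and mature tRNAs resolve to the mature tRNA; ties
among k mature tRNAs split 1/k), normalized as RPKM, filtered at
RPKM > 10,000, and compared as fold change knockdown/control per m7G
class.

**Translation.** Per gene, TE = FPKM(polysome) / FPKM(input);
translation ratio TR = TE(knockdown) / TE(control). Each CDS gets an
m7G-codon frequency *f* — the fraction of its codons decoded by
m7G-modified tRNAs (codon = reverse complement of the anticodon; e.g.
tRNA-Lys-CTT decodes AAG). The package reports Pearson r between *f* and
log2 TR, Mann–Whitney comparisons of low-*f* vs high-*f* quartile groups,
TE classes at |log2 TR| ≥ log2(1.5), and the ranked codon profile of
TE-decreased genes.

## Worked example

```python
from tracseq.pipeline import RunConfig, run_pipeline, report_summary

report = run_pipeline(RunConfig(seed=1), "out/")
print(report_summary(report))
```

prints

```
tracseq run (config d2a81c0b614b1a26)
  m7G-modified tRNAs called: 17
  m7G codon set: AAC, ACA, CCC, CCG, CGT, CTA, CTG, GTT, TAT, TGG, TGT, TTA, TTT
  methylation control vs knockdown: W=151.0, p=0.00046
  median expression fold change (m7G: 0.623, non-m7G: 1.044)
  Pearson r(f, log2 TR) = -0.283 (model closed form -0.288), p = 4.63e-147
  low-f vs high-f translation ratio: U=2823936, p=1.03e-112 (a>b)
  TE classes: decreased=2286, increased=2145, other=3569
```

Reading this: the simulated repertoire implants m7G sites in 17 of 300
tRNA species and the caller recovers exactly those 17; their codon set is
the union of the codons those tRNAs decode. Halving the cleavage
probability (the knockdown condition) lowers every per-tRNA methylation
level (signed-rank p = 4.6e-4). Scaling modified-tRNA abundances by 0.6
in the knockdown expression library yields a median fold change of 0.62
for the m7G class and ~1 for the rest. In the 8000-gene translation
experiment, genes rich in m7G codons lose translation efficiency under
knockdown: the measured correlation (−0.283) matches the generative
model's closed form (−0.288), the low-*f* quartile translates better than
the high-*f* quartile, and TE-decreased genes are m7G-codon-rich.

The same pipeline runs from the shell (`tracseq run --outdir out --seed 1`),
and the individual stages are exposed as subcommands (`tracseq simulate`,
`tracseq build-ref`, `tracseq trac-call`, `tracseq trna-expr`,
`tracseq te-analyze`, `tracseq report`) for use with real alignment
tables, SAM/BAM files, count tables and CDS FASTA.

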