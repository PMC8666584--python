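# Methods

## Mature tRNA reference

tRNA gene models carry 1-based, closed intron intervals on the unspliced
sequence (`>id|isotype|anticodon|introns=a-b[,c-d]`). A mature tRNA is the
spliced sequence with `CCA` appended; all downstream coordinates are
1-based positions on this mature sequence (not Sprinzl numbering), and the
m7G window "46–48" is taken as sequence positions. `U` is normalized to
`T` on input so every sequence space is DNA-alphabet. Identical mature
sequences from distinct loci are collapsed into one entry with a
multi-locus id list (reversible via `collapse_duplicates=False`); the
reference table records both gene- and anticodon-level identity so either
roll-up of "number of m7G tRNAs" is computable.

Codon decoding is strict Watson–Crick by default: the decoded codon is the
reverse complement of the anticodon (Lys-CTT → AAG). An optional wobble
expansion admits additional codon third bases by the anticodon-34 pairing
table (G→{C,T}, T→{A,G}, A→{T}, C→{G}); it is off by default because the
biologically motivating case (AAG/Lys-CTT) is Watson–Crick. Decoded stop
codons (possible only for suppressor-like anticodons) are excluded from
the codon set and flagged separately.

## TRAC-seq statistics

Pileups count, per mature position, the reads overlapping it (depth d_i)
and the reads whose alignment begins exactly there (starts s_i), from
either a SAM/BAM (primary alignments only; the reported alignment start is
used as-is, soft clips do not shift it) or a plain alignment table.

* **Cleavage ratio** r_i = s_i/d_i, masked (NA, never 0) where
  d_i < `min_depth` (default 20 reads per site per arm; the floor keeps
  single-read artifacts from producing extreme ratios at this depth).
* **Cleavage score** = log2(max(r_treated, ε)/max(r_non-treated, ε)) with
  pseudo-ratio ε = 1e-4, below any ratio observable at the depth floor, so
  it prevents division by zero without perturbing real signal. An
  alternative "ratio of logs" reading, log2(r_t)/log2(r_c), is available
  behind `literal_formula`/`--literal-score-formula`; it is not the
  default because its value is bounded near [0, 1] for enriched sites
  (0.3 vs 0.01 gives 0.26) and therefore can never clear the >4 calling
  threshold, whereas the quotient reading gives 4.9 for the same site.
* **Calls**: positions 46–48 with score > 4 and treated ratio > 0.1, both
  strict; the ratio threshold is applied to the treated arm only. The
  46–48 window also absorbs the ±1 ambiguity of where the scission
  chemistry places the first base of the downstream fragment.
* **Methylation level** (this package's per-tRNA summary; the assays it
  mirrors report only a global signal): the maximum cleavage score over
  46–48. Paired condition comparisons use the Wilcoxon signed-rank test —
  zero differences dropped, midranks for ties, exact null by enumeration
  of all 2^n sign assignments for n ≤ 15, normal approximation with
  continuity correction beyond.
* **Motif**: base-frequency matrix over ±flank around called sites;
  columns at sequence edges renormalize over the calls that cover them.

## Expression quantification

Hit tables carry per-read candidate alignments (target, score, class ∈
{mature, genomic}; an upstream aligner policy reporting best alignments
with at most 50 hits is assumed). Per read: sub-best hits are discarded;
if best-score hits include a mature tRNA, genomic hits are dropped
(exclusive mapping); a read tied across k mature tRNAs adds 1/k to each,
which conserves total counts and is seed-independent. RPKM =
count/(length/1000 × total/1e6); "expressed" means RPKM > 10,000,
strictly. Fold change is the RPKM ratio knockdown/control, computed on
the analysis set defined by the **control** condition's expressed flag so
knockdown-induced losses are not filtered away.

Bench formulas: 2^-ΔΔCt with ΔCt = Ct(target) − Ct(reference) and
ΔΔCt = ΔCt(test) − ΔCt(calibrator) — the same routine serves qRT-PCR
(β-actin reference) and MeRIP-qPCR enrichment (U6 reference, input sample
as calibrator) — and the LC-MS modification percentage,
100 × area(mod)/Σ area(all nucleosides).

## Translation analysis

FPKM = count/(length_kb × total/1e6) per library; TE = FPKM_poly /
FPKM_input, masked where input FPKM < 1 (an expression floor that
stabilizes the ratio; configurable). Translation ratio TR = TE_kd /
TE_ctrl. The m7G-codon frequency f of a CDS is counted in frame 0 with
the terminal stop codon excluded from numerator and denominator; internal
stops are counted but logged. TE classes use |log2 TR| ≥ log2(1.5)
(boundary inclusive toward the extreme classes; the cutoff is exposed as
`--te-threshold`), and the low/high-f split takes the bottom and top
quartiles (q = 0.25, ties broken by gene-id order, equal sizes by
construction). Group contrasts use the two-sided Mann–Whitney U test —
exact by enumeration of all C(n_a+n_b, n_a) assignments when
n_a + n_b ≤ 12 (ties counted 1/2), tie-corrected normal approximation
otherwise. Codon frequencies weight all codons uniformly (no weighting by
cognate tRNA abundance).

## Synthetic-data generators

All generators are pure functions of (config, seed); every consumer of
randomness derives its own stream from the seed plus a fixed stream id.

**tRNA panel.** `n_trnas` mature sequences of 70–90 nt (CCA included),
random anticodons at positions 34–36, a designated G implanted at a
position drawn from {46,47,48} for each modified tRNA. Defaults emulate
the repertoire scale of a human cell line — 300 distinct mature species,
17 of them m7G-modified — so that the modified class is a minority of
total tRNA abundance, as it is in real repertoires; this matters because
RPKM fold changes are compositional, and the renormalization shift equals
1/(1 − 0.4 × abundance share of the modified class). A 20-species,
half-modified panel is used as the caller-validation condition.

**TRAC libraries.** Each molecule of a modified tRNA is cleaved with
per-arm probability p (`p_cleave_treated` = 0.3 in the treated arm,
`p_cleave_background` = 0.01 otherwise — plausible placeholders, surfaced
in config, since no empirical per-molecule cleavage efficiency for
NaBH4/aniline at m7G46 is established); a cleaved molecule emits the
downstream fragment, whose read starts at the modified position, an
uncleaved one a full-length read starting at position 1. Unmodified tRNAs
cleave at background rate at a uniformly random internal position. ALKB
treatment is modelled implicitly: reads are reverse-transcribable
end-to-end, with no hard-stop modifications besides the cleavage event.
FASTQ qualities are constant (the pipeline does not use them), and each
library ships a ready alignment table so the analysis stack is testable
without an external aligner.

**Expression libraries.** Per-tRNA abundances are log-normal(0, 1),
shared between conditions; knockdown scales modified-tRNA abundances by
0.6. Reads are multinomial over abundances; 5% of reads carry an
equal-score genomic-locus hit to exercise the exclusivity rule.

**Translation experiment.** Per gene: CDS length uniform in 100–500
codons; a target f drawn uniform on [0, 0.5] is realized exactly by
placing round(f·n) codons from the m7G codon set and the rest from
non-set sense codons, so the measured f equals the truth table
codon-for-codon. True log2 TR = −beta·f + N(0, sigma) with beta = 2,
sigma = 0.2. Input count means are library-size-scaled
abundance×length weights (abundance log-normal(0,1), library size 2e7);
polysome means are the input means times the condition's TE; counts are
negative-binomial with dispersion φ = 0.1 (Poisson at φ = 0).

**Closed-form correlation.** Under this model the measured log2 TR is
−beta·f + e + m, where m sums the log-count noise of the four libraries.
For NB counts, Var[log2 X] ≈ (ψ′(1/φ) + E[1/μ])/ln²2 (Gamma–Poisson
mixture; delta method for the Poisson layer), so

r = −beta·sd(f) / sqrt(beta²·var(f) + sigma² + 4(ψ′(1/φ) + E[1/μ])/ln²2),

with var(f) = (range)²/12 and E[1/μ] = e·n_genes/library_size for the
log-normal weights. At the defaults this gives r ≈ −0.288; the count
noise term dominates sigma, which is why it must appear in the reference
value. The acceptance suite checks the measured r against this closed
form to ±0.05.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: sequencing error, adapter contamination and PCR
duplication; position-dependent cleavage efficiency and RT fall-off;
multi-mapping structure among near-identical isodecoders (expression
ties are exercised synthetically, not derived from sequence similarity);
other tRNA modifications co-occurring with m7G; and biological covariance
between codon content, CDS length and expression level. Results on real
libraries additionally depend on the upstream aligner's scoring policy.

## Pipeline and reproducibility

Stages run in dependency order (simulate → TRAC → expression →
translation) with a plan check before any computation. The knockdown
TRAC condition halves the cleavage probability; the translation stage by
default uses the codon set *discovered* by the caller (falling back to a
skip marker if no sites were called), so an end-to-end run exercises
discovery feeding measurement. Reports are JSON; wall-times go to the
log so outputs are byte-identical across reruns of one config; every
table carries the config hash, and tabular outputs are TSV with
'#'-prefixed headers and 1-based inclusive coordinates. Problem sizes
throughout (300-species panel, 2000 reads/tRNA, 8000 genes, five-seed
caller sweeps, ten-seed recovery checks) were chosen so any single check
completes in seconds on one CPU while keeping binomial/NB sampling error
well inside the asserted tolerances.

## Known limitations

* The caller is restricted to the 46–48 window by design; m7G outside the
  variable loop (or other aniline-labile modifications) is out of scope.
* Methylation "level" is a score-based summary, not a stoichiometry; it
  saturates once cleavage is complete and compresses near the epsilon
  floor.
* RPKM fold changes are compositional (see above); with a large modified
  abundance share, the unmodified class drifts above 1 even when its
  absolute abundances are unchanged.
* The Mann–Whitney exact branch enumerates assignments and is limited to
  n_a + n_b ≤ 12; beyond that the tie-corrected normal approximation is
  used (and likewise the signed-rank test beyond n = 15).
* qPCR quantification assumes perfect doubling efficiency (plain
  2^-ΔΔCt).
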