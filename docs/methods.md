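# Methods

`anomito` re-implements, as a tested pipeline, the comparative mitogenomic
workflow used to study adaptation and carcinization in anomuran crustaceans:
composition and strand-skew statistics, gene-order rearrangement typing,
depth-matched Ka/Ks selection analysis, control-region architecture
(tandem repeats, motif blocks, secondary-structure free energy), and the
family-wise association between control-region ΔG and habitat depth.  A
synthetic-data generator supplies genomes with known ground truth so every
stage is validated against what was planted rather than against itself.

## Genome model and coordinates

A mitogenome is a circular DNA sequence (the deposited plus strand, treated
as the heavy strand unless overridden) with typed features drawn from a
closed 38-symbol vocabulary: 13 protein-coding genes (PCGs), 22 tRNAs with
trnL1/trnL2 and trnS1/trnS2 disambiguated by anticodon, two rRNAs and the
control region (CR).  Coordinates are 1-based inclusive; features spanning
the origin carry a wrap flag.  Heterogeneous GenBank labels are mapped by an
editable synonym table (`data/gene_synonyms.yaml`).  Translation uses the
invertebrate mitochondrial code (NCBI table 5); incomplete stop codons are
trimmed, not padded.

The CR is located as the longest circular inter-feature gap (an explicit
D-loop/CR annotation takes precedence); gaps under 50 bp are reported "too
compact", a threshold chosen to keep the shortest reported CR (63 bp) while
rejecting the compact records.

## Composition and skews

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C), per strand (Perna & Kocher
convention).  Because the two strands are complementary, skew(s) =
−skew(revcomp(s)); the strand a printed number refers to therefore matters.
The whole-genome skews printed for these taxa are reproducible only as the
heavy-strand AT skew paired with the light-strand GC skew — verified
arithmetically from the printed per-strand compositions — so a "paper-style"
report emits that mixed pair while the pure per-strand values are always
also emitted.  Report rounding is half-away-from-zero (1 decimal for
percentages, 3 for skews), matching the printed precision.  Codon usage
reports counts, frequencies per thousand and RSCU per synonymous family.

## Gene orders

An arrangement is a circular sequence of signed gene symbols.  Canonical
form rotates the circle to start at +cox1, reflecting first when cox1 lies
on the minus strand, so circular/orientation equivalence is tuple equality.
Arrangement types are equivalence classes of canonical orders over the 37
genes (CR excluded; duplicated genes expand the alphabet as `gene_copy2`).
Diffs against a reference report a gene as *translocated* when both of its
circular adjacencies are absent from the reference and *inverted* when its
unsigned neighbourhood is conserved but its strand differs; genes at a
single breakpoint boundary are deliberately not called translocated.  The
breakpoint distance counts signed circular adjacencies of one order absent
from the other (orientation-normalized, so it is rotation- and
reflection-invariant); the triangle inequality is not asserted.

Two references ship with the package: the 32-gene pancrustacean
ground-pattern string as printed in the comparative literature (strands
unspecified, taken as plus) and a complete signed 37-gene pancrustacean
(Drosophila-like) order.  The choice is a config switch since the printed
string omits five genes and orders a few tRNAs unusually.

## Ka/Ks estimation

Counting is NG86 under the mito code: per codon, each position contributes
the fraction of its three mutations that are synonymous; mutations creating
stops count as nonsynonymous, which keeps L_A + L_S = 3 sites per codon
exactly.  Codon pairs differing at several positions average synonymous /
nonsynonymous difference counts over all minimal substitution pathways,
excluding pathways through stops (all pathways when every one is blocked).
Proportions are Jukes–Cantor corrected; p ≥ 0.75 raises a saturation error.
ω = Ka/Ks, reported as 0 when Ka = 0 and Ks > 0 and flagged undefined when
Ks = 0.  Interpretation bands: ω < 1 purifying, |ω − 1| ≤ 0.05 neutral,
ω > 1 positive.

This is a deliberate substitution for the γ-MYN estimator used by the
original study: γ-MYN's rate-variation machinery belongs to a different
method family, while NG86 preserves the S_A/L_A and S_S/L_S definitions the
study quotes.  Consequently only estimator-robust facts are asserted
against the published per-gene table (all ω < 1 for purifying pairs; Ka = 0
rows give ω = 0), never its exact decimals.  The deviation is recorded in
output metadata.

Alignment is translation-guided: proteins aligned globally (BLOSUM62,
gap open −10 / extend −0.5) and back-threaded onto codons; gap and stop
columns are masked but kept.  The per-gene Fisher exact test uses the 2×2
table [[S_A, L_A−S_A], [S_S, L_S−S_S]] with counts rounded
half-away-from-zero (the KaKs_Calculator-style single-p-per-gene
convention).  Sliding windows are 52 codons at step 12 — codon units keep
reading frames intact; the published window length is unitless, so this is
a documented choice, with partial terminal windows dropped and Ks = 0
windows flagged rather than removed.

## Control-region architecture

*Tandem repeats* are found TRF-style with the tool's documented default
weights (match +2, mismatch −7, indel −7): exact k-mer (k = 7) recurrence
distances propose candidate periods; a lag-p match scan delimits
high-scoring regions; X-drop extension against the rolling consensus
refines boundaries; wraparound dynamic programming against the consensus
scores the final report.  Copy number = aligned span / period (1 decimal);
repeats under 1.9 copies are suppressed.  The minimum report score is 20
(ten matched bases) rather than TRF's 50 so that short perfect repeats of a
few copies — the dinucleotide-scale events the reference behaviour expects —
are reported.  Copy-to-copy divergence is modelled as substitutions in the
scan; the wraparound alignment tolerates indels when scoring.

*SSRs* are maximal perfect runs of primitive 1–6 bp units, left-greedy,
with minimum copies {1:12, 2:6, 3:4, 4:3, 5:3, 6:3}.  *Inverted repeats*
come from gapless local alignment of the sequence against its reverse
complement with einverted-style scores (+3/−4, gap −12), arm ≥ 10 bp,
≤ 25% mismatches, loop ≥ 3 nt; the score threshold is 30 (= 3 × min arm)
so that a perfect 10–14 bp arm is reportable.  *Motif blocks*: GA blocks
are ≥ 6 nt purine runs containing ≥ 2 G (5′/3′ subtype assigned relative to
the longest tandem repeat), poly-T is ≥ 5 T, [TA(A)]n is ≥ 3 consecutive
TA/TAA units.  These thresholds are config defaults — the study reports the
blocks without stating cutoffs.

## Secondary structure and ΔG

Folding is Zuker-style nearest-neighbour dynamic programming over a
packaged Turner-style parameter table: Watson–Crick stack (ΔG37, ΔH) pairs
with GU wobble handled as a penalized analogue, and purely entropic
hairpin/bulge/internal-loop size penalties, so any temperature is reached
via ΔG(T) = ΔH − TΔS (default 27 °C = 300.15 K).  Multibranch loops use the
affine a + b·unpaired + c·branches model (3.4 / 0.0 / 0.4 kcal/mol at
37 °C).  Minimum hairpin loop 3 nt; interior loops are capped at 30
unpaired nt during the search (the standard Zuker heuristic — the
standalone structure evaluator has no cap); no pseudoknots, dangles or
terminal-mismatch terms.  Suboptimal structures come from a Wuchty-style
best-first traceback over an unambiguous grammar, so up to 20 structures
within 1 kcal/mol arrive in nondecreasing energy order with the MFE first.

DNA control regions are folded as RNA (T read as U), reproducing the
study's procedure of submitting CR DNA to an RNA-folding server; a
SantaLucia-style DNA stack table is a config option.  Published ΔG values
are treated as qualitative anchors only — they depend on the external
server's exact parameter set — and numeric validation instead uses
exhaustive enumeration with the package's own table (agreement to
1e-6 kcal/mol on short sequences).

tRNA folds are classified *cloverleaf* when the MFE structure has a single
exterior (acceptor) helix of ≥ 4 stacked pairs and exactly three hairpin
loops, else *atypical*.

## Depth association

Each species' ΔG is summarized as the midpoint of its reported range, depth
as the midpoint of its depth range (ranges are all the study publishes).
Depth categories: Terrestrial (flag), Intertidal [0, 30), Shallow
[30, 200), Upper bathyal [200, 1000), Deep sea [1000, ∞) by midpoint.
Family trends are Spearman rank correlations rho(depth midpoint, ΔG
midpoint) with a seeded two-sided permutation p (≥ 10,000 shuffles);
"ΔG decreases with depth" means rho < 0.  The source narrative contains a
sign ambiguity ("positive correlation" beside "i.e. become more negative");
this package follows the parenthetical and the table arithmetic.  Families
need ≥ 4 usable rows by default; the packaged Diogenidae has only 3, so the
reported Diogenidae trend uses an explicit min_n = 3.  "Too compact" CRs
are excluded; hydrothermal-vent taxa (Munidopsidae) carry a vent flag.
Carcinized families default to {Lithodidae, Porcellanidae, Lomisidae}
(editable; only the first two are named in the source).  The contrast
output is descriptive — no phylogenetically independent contrasts.

One transcription note: the packaged habitat table carries 49 species rows
(42 anomurans, 3 brachyurans, and one each from four outgroup orders);
Clibanarius infraspinatus is kept as a 0–1 m marine record rather than
terrestrial, since a depth range is reported for it.

## Synthetic data

All generators are pure functions of their spec, seeded through numpy's
PCG64.  Genomes follow a configurable signed gene order (default: the
37-gene pancrustacean order with the CR between rrnS and trnI) with PCGs as
random ORFs, tRNAs of 60–75 nt, rRNAs of 1300/800 nt and 0–5 bp spacers.
Base composition targets the study's heavy strand (A 31.7 / T 41.8 /
C 9.8 / G 16.7 %); codons are sampled from a sense-codon distribution fit
by iterative proportional fitting so the base marginal matches the target
(naive stop-exclusion would distort T by over a percentage point), and
minus-strand genes are sampled at the complementary composition so the plus
strand stays on target (within ±1% at ≥ 10 kb).

Control regions (default 1313 bp at the printed CR composition) plant a
47 bp × 3.6-copy repeat mutated at 5% per base per copy, poly-T runs, GA
blocks, [TA(A)]n blocks and GC-enriched hairpins at recorded coordinates.

Codon pairs evolve from a random sense-codon ancestor by a continuous-time
process: uniform nucleotide proposals with a kappa transition bias,
synonymous changes at relative rate 1, nonsynonymous at rate ω,
stop-generating changes rejected.  The clock is scaled so one time unit is
one synonymous substitution per NG86 synonymous site of the ancestor; a
pair at divergence t runs each branch for t/2.  Default kappa = 1 — the
mutational assumption of NG86 counting, so estimator validation measures
counting and correction error rather than a deliberate model mismatch;
kappa is configurable for sensitivity analyses.  Realized substitution
counts are recorded as truth.

What the generator does not emulate: real rRNA/tRNA sequence structure,
indels in coding sequences, codon-frequency bias beyond the base marginal,
among-site rate variation, and gene-length variation between taxa.  Passing
recovery tests therefore demonstrates correctness of the detectors under
the planted model, not performance on diverged real annotations.

## Problem sizes and numerics

Validation sizes used by the tests and the acceptance script: 500 random
sequences ≤ 30 nt for the folding oracle (structures enumerated
exhaustively; sequences with > 40,000 structures are resampled to keep the
oracle tractable), 100 replicate 500-codon pairs for ω recovery at ω = 0.2
(mean |ω̂ − ω| < 0.05), 50 seeded backgrounds for 47 bp repeat recovery
(≥ 90% at period ± 1, copies ± 0.3), and 200 random signed circles ≤ 15
genes for the breakpoint/typing oracle.  Long CRs are folded on their first
600 nt inside the pipeline (configurable; the acceptance script folds a
full 1313 nt synthetic CR).  Energies are float64; oracle comparisons use
1e-6 kcal/mol; count identities use 1e-9.  Permutation p-values are
bit-reproducible for a fixed seed.

## Known limitations

* The folding parameter table is Turner-style but not Turner-complete (no
  dangles, terminal mismatches, special hairpins, or coaxial stacking);
  absolute ΔG values are comparable within this package only.
* NG86 underestimates ω when the true mutation process is strongly
  transition-biased; the published per-gene values (γ-MYN) are not
  reproduced numerically.
* Gene-order typing treats annotation-level duplications literally; a
  mis-annotated duplicate creates a new type.
* The depth association inherits all limitations of range midpoints and
  of comparing non-independent (phylogenetically related) families.
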