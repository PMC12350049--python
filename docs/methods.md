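# Methods

This note documents the models, conventions and design choices behind
`mitochar`, in the spirit of the methods appendices that accompany
comparative-mitogenomics toolkits.

## Data model and coordinates

Annotations are ordered lists of features (`PCG`, `tRNA`, `rRNA`, `CR`)
with 1-based inclusive coordinates on the heavy strand and an `H`/`L`
strand flag; 0-based half-open conversion happens only inside format
readers. Features are sorted by start, ties broken by end then name.
Duplicated tRNA names receive the isoacceptor tags used in mitogenome
tables — Ser(S1)/(S2), Leu(L1)/(L2) — resolved by anticodon (TGA→S2,
GCT→S1, TAA→L2, TAG→L1). "D-loop"/"control region" names are normalized to
`CR`. Wraparound features are not supported: the standard vertebrate gene
order starts with tRNA-Phe at position 1 and ends with the CR at the
genome's last base, so none are needed.

The spacer/overlap ledger assigns each consecutive pair the signed
intergenic count `IN = start_next − end_prev − 1`. The pair that closes the
circle (CR back to tRNA-Phe) is reported separately and excluded from the
linear ledger, matching the tabular convention in genome reports. For the
bundled *C. repasson* table the conservation identity
`Σ sizes + Σ IN = 16,571` holds exactly. The bundled table contains 12
positive IN entries and 7 overlaps; published prose for the same genome
counts "11" spacers — the package reports the arithmetic result and never
reconciles such discrepancies silently. Similarly, the published
composition table prints the rRNA partition as 2,587 bp while the gene
table's rRNA sizes sum to 2,634 bp, and the printed whole-genome base
percentages are not exactly the size-weighted mixture of the printed
partition rows; coordinate-derived values are used wherever the two
disagree.

## Composition and skews

Counts run over unambiguous residues only (N excluded, tallied). Skews are
`(A−T)/(A+T)` and `(G−C)/(G+C)`; a zero denominator yields a missing value
at report level, never an exception. Partition composition concatenates
annotated spans in genome order **without** reverse-complementing L-strand
genes — the convention that keeps partition skews commensurate with the
whole-genome skew (published partition skews for this genome are consistent
with it); `strand_oriented=True` switches to coding-strand counting for
sensitivity checks. Overlapping bases belong to every feature containing
them, so partition totals may exceed the union length.

## Codon usage

Codons are read in frame from each strand-oriented PCG; a trailing 1–2 nt
incomplete codon is dropped, and complete terminal stops are tallied
separately and excluded from RSCU and amino-acid percentages. Translation
is the vertebrate mitochondrial code throughout (stops TAA/TAG/AGA/AGG,
ATA = Met, TGA = Trp). Two RSCU family partitions are provided because
published RSCU figures conventionally display AUG and UGG at exactly 1:
the default `report` mode splits ATG and TGG (and consequently ATA and
TGA) into single-codon families, while `table2` mode uses the exact
synonymous sets of the mitochondrial code (Met = {ATA, ATG},
Trp = {TGA, TGG}). Amino-acid percentages merge the two Leu and two Ser
families by the shared amino acid.

## Distances, diversity and Ka/Ks

Gap or ambiguity in either sequence removes a site from a pair (complete
pairwise deletion), the common default of desk tools. K2P uses the closed
form `−½ ln((1−2P−Q)√(1−2Q))`; F84 uses the standard closed form with
`A = πAπG/πR + πCπT/πY`, `B = πAπG + πCπT`, `C = πRπY`, base frequencies
estimated from the pooled pair by default. Both return a missing value
with a diagnostic when a log argument is non-positive (saturation), and
both were verified to nine decimals against an independent implementation
(`ape::dist.dna`) on simulated pairs; at equal base frequencies F84
reduces to K2P analytically and numerically. Distances are reported as
percentages (100·d) in report surfaces.

π is the average over row pairs of (differences / compared sites) per
window — the uncorrected average-pairwise estimator; the n/(n−1)-corrected
variant is available by flag since desk tools do not agree on the
convention. Windows default to 200 bp stepped by 25 bp; a final partial
window is kept and flagged truncated.

Ka/Ks follows Nei–Gojobori (1986): per-codon synonymous site fractions
count the synonymous share of the three one-step changes at each position
(stop-creating changes count as nonsynonymous); observed differences in
multi-hit codons are averaged with equal weight over all orderings of the
changed positions; Jukes–Cantor correction (`−¾ ln(1−4p/3)`) maps
proportions to rates, undefined at p ≥ 3/4. Codons with a gap, ambiguity
or stop in either sequence are skipped pairwise. The implementation
reproduces `Bio.codonalign`'s NG86 to 1e-9 on simulated data. NG86 with
equal path weights compresses the Ka/Ks ratio below the generating ω when
the transition/transversion ratio exceeds 1 (transitions are
disproportionately synonymous); recovery tests therefore use
simulation-calibrated bands rather than asserting ω itself.

## Control-region features

CSB consensus calling is majority rule over alignment seed windows (ties
broken alphabetically, all-gap columns yield N); scanning a CR reports the
best ungapped Hamming match per block, in block order, with an explicit
absence record when the best match exceeds `max_mismatch` (default 4). The
shipped seed motifs are synthetic fixtures at the canonical block lengths
(18/21/18/20 bp for CSB-D/1/2/3); empirical consensus sequences should be
built from a real alignment.

The tandem-repeat detector is a deterministic seed-and-verify procedure,
not a reimplementation of Tandem Repeats Finder's probabilistic model: for
each candidate period p, positively scoring runs in the lag-p
self-comparison (match +2, mismatch −7, Kadane walk) seed candidate
arrays, each verified by scoring the full array against its periodic
majority consensus; arrays need ≥1.5 copies and a verification score of
≥20 by default, and overlapping reports are merged keeping the higher
score (ties to the shorter period). Copy numbers are reported to one
decimal. On random 900-bp sequences the false-positive rate for
period ≥ 10, copies ≥ 1.9 arrays is below 5%.

## Neighbor joining

Standard Q-criterion agglomeration; negative branch estimates are clamped
to zero with the total deficit recorded on the tree. Newick output uses
six decimals and deterministic child ordering (by smallest descendant
label), so identical matrices give byte-identical trees. On additive
matrices the algorithm recovers path lengths to 1e-9. Bootstrap support
(site resampling, seeded) is provided for alignment-based use; rooting is
display-only.

## Synthetic data

The generator's defaults emulate the bundled genome: its exact gene order,
strands, sizes and anticodons; per-partition base composition from the
published percentages; valid start codons (ATG, GTG for COI) and the
annotated complete/incomplete terminal stops; no internal stops. PCG
bodies are sampled codon-wise from the 60 sense codons with probabilities
fitted (iterative proportional fitting) so that the base-composition
marginal equals the partition target exactly — naive per-base sampling
with stop rejection would bias composition, since the four stops are
A/G-rich. Codons straddling gene overlaps are filled by constrained
rejection against already-fixed positions. Anticodon triplets are
implanted in each tRNA; the CR can carry the CSB motifs and a tandem
repeat (defaults: a 17-mer at 2.2 copies when enabled). Composition is hit
in expectation; single realizations of sub-kilobase partitions deviate by
binomial sampling noise (~1.5% SE per base on the CR), and the implanted
motifs carry their own composition.

Divergence is an event process: Poisson(branch length × sites) candidate
substitutions per lineage, transitions favoured κ:1 per alternative
(default κ = 4, a typical mitochondrial value). Inside PCGs a candidate
creating an internal stop is rejected and an amino-acid-changing candidate
is accepted with per-gene probability ω; defaults place all 13 genes under
strong purifying selection (0.0093 for ND4L up to 0.0687 for Cytb,
matching the span of published congeneric estimates, 0.015–0.05 for the
rest). Indels are not simulated, so alignments of simulated sets are
positional. Every dataset carries a truth bundle (per-gene syn/nonsyn
fixations, candidate and accepted event counts, implant coordinates) and
is byte-reproducible from its seed.

## Problem sizes and limitations

Validation runs at desk scale: 20–50 replicates of 500-codon or 582-bp to
10-kb sequence pairs, 4-taxon genome sets, 24-row CR alignments — sizes at
which the whole suite completes in seconds while keeping Monte-Carlo
standard errors a few percent of the measured values. Known limitations:
the generator's codons are independent draws, so it reproduces base
composition but not real codon-bias rankings beyond the broad Leu/Ser/Thr
dominance; saturation behaviour is reported (missing values), not
modelled; the CSB motifs shipped are placeholders for real consensus
building; and passing tests on synthetic data show estimator correctness
under the simulated process, not the fidelity of any particular published
annotation.
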