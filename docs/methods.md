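# Methods

## Motif model and scanning

A domain motif is an ordered list of residue classes over the 20
proteinogenic amino acids; a singleton class is a fixed catalytic residue,
a larger class records tolerated substitutions. The built-in patterns are
the type-I PKS ketosynthase catalytic centre `GP[ACQS]{5}TA[CQSY][ST][AS]`
(anchor `GPXXXXXTACSS`) and the NRPS condensation-domain centre
`HH[A-Z]{3}DG`. The condensation pattern is kept in its double-histidine
form by default even though the underlying HxxxDG catalytic box has a
single conserved histidine; `c_motif("relaxed")` gives `H[A-Z]{4}DG` for
users who prefer the single-H reading. `[A-Z]` is deliberately narrowed to
the 20 amino-acid letters: stop (`*`) and unknown (`X`) translations are
not catalytic residues, which also guarantees that no match ever spans a
stop codon or an N-containing codon.

Contigs are translated in all six frames with the standard genetic code;
codons containing N translate to `X`, trailing partial codons are dropped.
Coordinates are 0-based half-open internally and 1-based inclusive
forward-strand in every output, with orientation in a separate strand
field; a hit's nucleotide span is always exactly three times its
amino-acid span, and the mapping between peptide and contig positions is
invertible (property-tested). Overlapping motif occurrences are all
reported (the scanner resumes one residue after each match start);
deduplication by locus happens only at aggregation time.

### Pattern derivation from alignments

`derive_motif` locates an anchor (fixed residues + `X` wildcards) as the
window of aligned columns maximizing the number of rows whose fixed
columns match exactly, then assigns each wildcard column the set of
residues at column frequency ≥ `min_freq` (default 0.05 — the admission
rule for "common variations" is otherwise under-determined) **unioned
with** the residues contributed by anchor-matching rows. The union term is
a design choice: thresholding alone cannot guarantee that every row
matching the fixed anchor also matches the derived pattern (a residue
unique to one matching row can sit below any frequency cut), and we treat
that guarantee as the more important contract.

### Chance-match statistics

For an i.i.d. residue model the per-position match probability is the
product of class probabilities; for uniform residues the condensation
pattern's rate is (1/20)² · 1³ · (1/20)² = 6.25×10⁻⁶ and the ketosynthase
pattern's ≈ 4×10⁻¹², i.e. essentially zero at metagenome scale. Because
six-frame-translated background is *not* uniform in amino acids,
`translated_aa_probs(gc)` computes the exact residue distribution induced
by i.i.d. nucleotides at a given GC fraction through the codon table, and
the false-positive suites test observed chance-hit counts against that
analytic rate within 3 binomial standard deviations.

## Alignment confirmation and search

Motif hits are noisy; each is therefore re-examined by Smith–Waterman
local alignment (BLOSUM62, affine gaps open 11 / extend 1 — BLAST's
protein defaults, via Biopython's `PairwiseAligner`) of the hit peptide
extended by 50 aa of frame context on each side (truncated at stops)
against all reference domain proteins of the same class. Confirmation
requires identity ≥ 60 % over ≥ 15 aligned amino-acid columns — thresholds
borrowed from common metagenome-annotation practice since the confirmation
step itself does not prescribe any; identity is counted BLAST-style as
identities / alignment columns including gaps. Confirmation is a *flag*:
no hit is deleted, so downstream counting can be run on confirmed-only or
all hits, and confirmed counts are monotone in the reference set.

`align_search` is the alignment-only route (and the only route for
adenylation domains): stop-delimited peptides ≥ 15 aa from all six frames
are aligned against each reference class, keeping at most one hit per
(peptide, class) — the best-scoring reference, ties to the lowest
reference id — mirroring a best-hit BLAST configuration. Hit coordinates
cover the locally aligned query region, so a hit may extend beyond a
planted domain when flanking background happens to align; count-based
truth comparisons are used in tests for that reason.

## Aggregation

Hits identical in (sample, contig, class, nucleotide span) are counted
once, with the alignment route taking precedence over the motif route for
the retained record. "Shared" between domain hits and an external cluster
predictor's regions is operationalized as ≥ 1 base of nucleotide overlap
on the same contig of the same sample (the weakest defensible criterion;
`min_overlap` is exposed). Group totals are computed fieldwise, never
copied: the bundled seven-sample reference count table has a printed
C-domain grand total (120) and overall domain total (1122) that do not
equal their own row-wise sums (128 and 1119); the pipeline reports the
computed sums.

## Dereplication

Monoisotopic masses are sums over a fixed table of most-abundant-isotope
masses (C 12, H 1.0078250319, N 14.0030740, O 15.9949146, Na 22.9897693,
Cl 34.96885268, S, P, …; proton 1.00727646), cross-checked against an
independent isotope-table implementation in the tests. Adducts are singly
charged: [M+H]⁺/[M−H]⁻ add/subtract the proton mass; [M+Na]⁺ adds the
*neutral* sodium atom mass by default, because that convention reproduces
the reference annotation table's printed ppm values (e.g. Salinosporamide
B −1.2, Soraphen A +1.5, Erythronolide A +3.5); `builtin_adducts("strict")`
switches to electron-corrected ion masses (Na⁺ 22.989218) for users who
want physical ion masses. Reporting rounds half-up — masses to 4 decimals,
m/z to 3, ppm to 1 — while all arithmetic is full precision.

Known irreproducibilities in the reference table, all still within the
5 ppm annotation rule and therefore not load-bearing: Jamaicamide C's ppm
reproduces in magnitude only (printed 2.3, computed −2.3 under the signed
convention (obs − theo)/theo); Actiphenol (printed 3.6, computed 1.9 from
the printed observed m/z) and Secocycloheximide A (printed 0.1, computed
−1.5) do not reproduce under either adduct convention, most plausibly
because the printed observed m/z values are truncated. Tests assert the
exact printed value only where it reproduces, and |ppm| < 5 elsewhere.

`dereplicate` emits, per ion, every polarity-matching (compound, adduct)
pair within tolerance, sorted by |ppm| with ties broken by compound name;
lowering the tolerance can only remove hits.

## Molecular networking

The modified cosine allows a fragment pair to match either directly or
shifted by the precursor mass difference (fragment tolerance 0.02 Da).
Intensities are √-scaled before the cosine (GNPS-style; `intensity_power`
is exposed), and a one-to-one peak matching is built greedily by
descending pair score with deterministic index tie-breaks. Greedy matching
can in principle be suboptimal relative to the exhaustive maximum-weight
assignment; the test suite quantifies this with a brute-force oracle on
≤ 6-peak spectra and asserts equality on conflict-free constructions where
greedy is provably optimal. An independent reference implementation
(matchms) is used as a cross-check, never as the implementation.

Network assembly: all pairwise similarities; candidate edges need cosine
≥ 0.70 and ≥ 4 matched ions; an edge survives only if each endpoint is in
the other's top-10 scores (mutual rank filter); while any connected
component exceeds 100 nodes its weakest edge is removed (ties: largest
absolute precursor delta, then lexicographic id pair), so the result is
deterministic for a fixed input. The "maximum connected components = 100"
workflow parameter is read as a maximum component *size*, matching the
semantics of the feature-based networking workflow it comes from. The
precursor tolerance (0.01 Da) plays no role in edge formation; it is
retained as a parameter for duplicate-feature merging and shift
annotation. Family statistics bin component sizes as 1 / 2 / 3 / >3, so
either the ">3 nodes" or the "≥3 nodes" reading of "chemical family" can
be derived.

Published network statistics from the original communities (60 families of
more than three nodes, 98 pairs, 984 singletons) depend on unreleased raw
spectra and are not desk-reproducible; the planted-family property suites
stand in for them.

## Synthetic data

`simulate_contigs` draws i.i.d. background nucleotides at a configurable
GC fraction (default 0.5) and inserts reverse-translated plant peptides
with uniformly random synonymous codons at uniform non-overlapping
positions on the requested strand, recording exact coordinates, frame and
peptide as truth. No codon-usage bias and no k-mer structure are modelled:
the scanner is codon-agnostic and the false-positive analysis assumes
i.i.d. residues, so passing tests demonstrate correct recovery and
calibrated chance-match rates under that null — not performance on real
assemblies, where repeat structure and composition bias can change the
background rate. Default problem sizes (50 contigs of 2–10 kb, 5–20
plants) keep a full property run at a few seconds per seed.

`simulate_spectra` gives each family a template peak set on its own
disjoint 100 Da m/z block (peaks ≥ 1 Da apart, 8 peaks by default), then
perturbs members with bounded uniform m/z jitter (default ±0.005 Da, i.e.
≤ half the fragment tolerance between two members) and lognormal intensity
noise (CV 0.2); an optional per-member precursor offset shifts precursor
and fragments together to exercise the shifted-match path. Disjoint
supports make the planted partition unambiguous; real spectra share
fragments across families, so family recovery there is necessarily
approximate in ways these tests do not measure.

Both generators are driven by a single seeded NumPy generator and emit
byte-identical FASTA/MGF for identical configurations.

## Degenerate inputs and numerical choices

Empty FASTA/MGF files, duplicate ids, non-nucleotide characters, inverted
cluster intervals, unknown elements, zero formula counts and empty
reference classes all raise early with the offending record named.
Zero-intensity peaks are dropped on MGF read and peaks re-sorted. Cosines
are clipped to [0, 1] against floating-point overshoot. All report
rounding is decimal half-up.
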