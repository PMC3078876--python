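# Methods

## Scope and model of the experiment

`srnapipe` implements the desk-side analysis of a two-condition small-RNA
sequencing experiment with one pooled library per condition (here labelled
FP and SP, for first- and second-year plantings of a perennial crop). The
pipeline stages are: read collapsing to unique 18–30 nt tags, a
prioritized annotation waterfall, novel-miRNA hairpin screening,
two-library differential expression, miRNA target prediction, GO
tabulation and qRT-PCR quantification. Because such studies rarely deposit
raw reads, the package ships a synthetic-data generator with planted
ground truth; every stage is tested against that truth and against
independent oracles.

## Tag collapsing and overlap statistics

Reads are validated over {A,C,G,U/T} (U is canonicalized to T, since
miRNA FASTA sources mix RNA and DNA conventions), length-filtered to
18–30 nt — the gel size-selection window of small-RNA protocols and the
only read filter applied — and collapsed to unique tags with per-library
counts. The overlap summary partitions tags into common, FP-specific and
SP-specific classes; percentages are taken against the pooled unique-tag
and read totals and the mean frequency (reads per unique tag) is reported
to 2 decimals, matching the conventional table layout.

## Annotation waterfall

Categories are assigned in strict priority: rRNA/tRNA/snRNA/snoRNA >
known miRNA > genome-matched > other; a tag reaches a tier only if every
higher tier rejected it, so the assignment is a partition. Matching is
deliberately deterministic rather than BLAST-based:

* ncRNA tier — exact substring of a reference;
* known-miRNA tier — full-length alignment of the tag within a mature
  reference with at most 2 substitutions and no indels (the tolerance
  reflects that conserved families are recognized across species with a
  couple of nucleotide variants); best hit = fewest mismatches, ties
  broken by lexicographic family then reference id;
* genome tier — exact full-length match to either strand.

For 18–30 nt queries substring/bounded-Hamming matching is both adequate
and database-version free. Family abundances aggregate best-hit counts and
are reported as shares of the conserved-miRNA read pool.

## Hairpin screening

Genome-matched, otherwise unannotated tags are screened for novel miRNA
precursors. Candidate windows around each genomic hit are the
left-extended, right-extended and symmetric windows at a flank extent
(default 150 nt in `extract_windows`); because precursor boundaries are
unknown a priori, `screen_novel` probes a grid of extents
(25/50/100/150 nt) and keeps the best-passing window. The grid matters:
the stability criterion compares a fold score against dinucleotide
shuffles, and a true hairpin diluted in 100+ nt of random flank loses most
of its margin (the flank folds equally well shuffled or not).

Folding is a weighted base-pair-maximization dynamic program — GC = 3,
AU = 2, GU = 1, minimum hairpin loop 3 nt, nested structures only,
deterministic outermost-first traceback — compiled with numba. It is a
geometric model, not a thermodynamic one: the screening criteria need the
stem-loop architecture plus a relative stability proxy, not free
energies. The backend is pluggable; `vienna_fold_backend()` adapts
ViennaRNA's MFE fold to the same interface and is cross-checked in the
test suite. The fold is verified against an exhaustive enumeration of all
nested structures for short sequences.

A candidate passes when all four flags hold:

1. **mature_in_one_arm** — no mature base pairs with another mature base
   (which would mean the mature straddles the terminal loop) and all
   partners lie on one side;
2. **duplex_pairing_ok** — ≥ 75% of mature bases paired, ≤ 4 unpaired,
   and no internal bulge longer than 2 nt in the mature duplex;
3. **loop_ok** — precursor length within [60, 300] nt;
4. **stability_ok** — weighted pair sum ≥ 15% above the mean of 100
   dinucleotide-shuffled versions of the precursor (exact Euler-walk
   shuffle, preserving dinucleotide counts and hence composition and
   stacking bias).

The thresholds are concrete renderings of the community's "strict
criteria" for plant miRNA loci; each is a config key. Candidates with
fewer than 40 total reads are flagged low-abundance — such candidates
typically need RT-PCR confirmation, which is outside computational scope
and representable as a user-supplied `validated` column.

## Differential expression

With one pooled library per condition no dispersion can be estimated, so
the appropriate test is the Audic–Claverie exact test: conditional on the
pooled count n = x + y, the second-library count is Binomial(n, q) with
q = N₂/(N₁+N₂) under the null of equal relative abundance (N₁, N₂ the
clean-read totals). The two-sided p doubles the smaller tail, capped at 1,
and is computed via log-space binomial tails so counts of order 10⁵ do
not underflow intermediates. Counts are normalized to reads per million;
a zero count is floored at 0.01 RPM so log2 fold-changes stay finite.
Significance marks are `**` (p < 0.01) and `*` (p < 0.05); a
differential-expression *call* additionally requires |log2 FC| ≥ 1. No
multiple-testing correction is applied by default (single-table
presentation convention); a Benjamini–Hochberg column via statsmodels is
available opt-in.

## Target prediction

Plant miRNAs act through near-perfect complementarity, so targets are
found by sliding the reverse complement of the miRNA along each
transcript and scoring an expectation penalty: mismatch 1.0, G:U wobble
0.5, gap 2.0, doubled at seed positions 2–13 (miRNA numbered 5′→3′), at
most 2 G:U in the seed, and a single gap explored by bounded extension
(site length within ±1 of the miRNA). Sites with expectation ≤ the
cutoff (default 3.0, the midpoint of the commonly used 1–5 range) are
reported; overlapping hits reduce to the best one deterministically. Any
non-match at positions 9–11 — the slicing site — classifies the
interaction as translational inhibition rather than cleavage. All
penalties are config-exposed (`ScoringParams`).

## qPCR and GO

Relative expression is 2^(−ΔΔCT): replicate CTs are averaged
arithmetically, normalized within sample against a reference gene
(default `18S_rRNA`), and the treated sample is referenced to the
control. The computation is invariant to a global CT shift. GO
tabulation consumes a user- or generator-supplied 3-column mapping
(gene, hierarchy, term) restricted to the three GO hierarchies; genes
with no mapping are tallied as `unannotated`.

## Synthetic data: what it emulates, and what it does not

The generator plants: 25 conserved families with 2–5 one-substitution
member variants each (≈ 90 mature sequences), 6 novel hairpin loci
embedded in a toy genome as inverted repeats (stem 30 bp = 21 nt mature +
9 nt extension, loop 8 nt, 68 nt precursor, separated by 150 nt random
spacers), ncRNA contamination as fragments of random rRNA/tRNA/snRNA/
snoRNA references, and uniform-random noise tags (rejected on any
reference collision so truth labels stay unambiguous) whose length
profile peaks at 24 nt with a 21 nt shoulder, as in real plant libraries.
Each planted miRNA also receives one transcript carrying a
complementarity site of known penalty (perfect, central mismatch at
position 10, or off-seed G:U, cycled), plus GO terms.

Default library depth is 10⁵ reads — a desk-scale rendering of
multi-million-read libraries that preserves the count-statistics
structure. The conserved-miRNA read fraction (0.44) is deliberately
inflated relative to the ~2% of real libraries so that per-miRNA expected
counts at this depth span the same range as deep sequencing; the noise
fraction (0.50) stands in for the dominant unannotated fraction, ncRNA is
0.04 and novel loci 0.02. About 30% of conserved members receive a true
fold-change drawn from {4, ¼, 2, ½}; half the novel loci are changed
4-fold. Libraries are multinomial draws from per-library tag
probabilities; per-library probabilities renormalize, so planted fold
changes are *compositional*, exactly as RPM-normalized sequencing is: a
change planted on a minor pool member is realized almost exactly, while a
global change is unidentifiable in principle. Identical seeds give
byte-identical outputs; sequence content, fold-change assignment and
abundance draws use independent RNG streams so varying one leaves the
others fixed.

Not emulated: sequencing error and quality profiles, adapters (reads are
emitted pre-trimmed; size selection and ligation are wet-lab steps),
cross-species genome alignment artifacts, and isomiR end-variation.
Passing tests therefore demonstrate the statistics and algorithms, not
robustness to instrument noise or to reference incompleteness.

## Numerical and procedural choices

* Exact test in log space via `scipy.stats.binom.logcdf/logsf`; verified
  against a pure-Python exact-coefficient tail summation to relative
  error < 10⁻¹⁰ on the full x, y ≤ 50 grid.
* Fold traceback prefers pairing the left end with its outermost
  admissible partner; ties are thereby deterministic.
* Dinucleotide shuffling uses rejection-sampled Euler walks (exact
  preservation; acceptance probability is high for nucleotide alphabets).
* Stability shuffles are seeded deterministically from the candidate
  length and a config seed, so screening is reproducible.
* Degenerate inputs: empty libraries, zero library totals, zero-unique
  categories, empty transcript sets and missing reference genes raise
  typed errors rather than propagating NaNs; a zero-count RPM floors at
  0.01; a category with 0 unique tags reports mean frequency 0.
* Simulation scale in the test suite and acceptance script: 20 seeds ×
  10⁵-read libraries for calibration/power, 100 shuffles for stability
  and false-pass rates, x, y ≤ 50 for the oracle grid — chosen so the
  whole suite completes in well under a minute of compute per stage while
  keeping binomial standard errors far below the asserted margins.

## Known limitations

* The fold model ignores stacking thermodynamics; scores are comparable
  only within a sequence and its shuffles, and the 15% stability margin
  is calibrated for the pair-maximization backend (an MFE backend shifts
  score scales, though the geometric flags transfer).
* The annotation waterfall's bounded-Hamming tier does not model indels
  or isomiR length variants.
* One library per condition means the exact test captures only sampling
  noise, not biological variance; p-values at very high counts are
  anti-conservative in the presence of overdispersion — the |log2 FC| ≥ 1
  requirement on calls is the practical guard.
* The target scanner explores at most one gap and does not model site
  accessibility.
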