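# Methods

## Model and procedure

`strandsym` quantifies strand (second-parity-rule) symmetry of the k-mer
spectrum of DNA sequences. For a sequence set, overlapping k-mers are
counted per record on the forward strand (windows advance by one position,
no wraparound; windows containing any non-ACGT letter are scanned but not
counted) and per-record tables are summed into one genome table per order.
Counting never crosses record (chromosome/contig) boundaries. Raw integer
counts are used throughout: every downstream quantity is invariant under
rescaling of the spectrum, so relative frequencies are never formed.

**Symmetry indexes.** S1 = 1 − Σ|f−f′|/Σ(f+f′) and
S2 = 1 − (1/M)·Σ|f−f′|/(f+f′) are computed over all ordered word entries
whose word differs from its own reverse complement and whose pair is not
entirely absent (f = f′ = 0). Each unordered pair enters twice; the double
counting cancels in both formulas and M (the ordered-entry count) is
always even. If no eligible pair exists — e.g. a spectrum containing only
palindromic words — the result is flagged undefined and reported as NaN
with a warning, never silently as 0 or 1.

**Word symmetry distances.** Arrangement A1 lists all 4^k words (including
zero-count words) by descending count; A2 makes complementary pairs
adjacent, pairs ordered by their larger frequency, self-complementary
words as singleton units. The rearrangement processes pairs in A2 order:
a pair whose members are not adjacent has its later member removed and
reinserted immediately after the earlier one, recording as *step* the
number of words strictly between them just before the move. WSD1 is the
move count, WSD2 the step sum; WSD2 ≥ WSD1 since every recorded move has
step ≥ 1. Closed-form maxima normalize both:

- max moves: (4^k − 2)/2 for odd k, (4^k − 4^{k/2})/2 for even k
  (palindromic words never move);
- max WSD2: 4^k(4^k − 2)/4 for odd k, (4^k + 4^{k/2} − 2)(4^k − 4^{k/2})/4
  for even k.

**Null model.** Controls are exact-composition shuffles: each record is
permuted uniformly at random (seeded Fisher–Yates via numpy's PCG64),
independently per record, so every control record has byte-identical
length and A/C/G/T (and ambiguity-letter) counts to its source. Shuffling
per record rather than from pooled genome-wide composition preserves each
chromosome's own composition; either choice preserves genome-level
mononucleotide counts. Control sets derive substream seeds as seed + index
for auditability.

**Statistics.** Groups (each genome vs. its one control) use the Wilcoxon
signed-rank test on paired per-order values: zero differences dropped,
tied absolute differences mid-ranked, exact null for ≤ 25 untied nonzero
differences, normal approximation with continuity correction otherwise,
and an undefined flag below 5 nonzero differences. Individual genomes use
a one-sample t test of the ≥ 2 (canonically 30) control values against the
genome's fixed value; small p_less means the genome sits significantly
below its controls. Both one-sided p-values and the two-sided p-value are
always reported, since directional conclusions are drawn. The extent of
symmetry is the largest k such that the genomic distances are
significantly smaller at *every* order 2..k (a failure at order 2 gives
extent 1 — mononucleotide symmetry only); a contiguous-run rule is used
when an intermediate order fails but a higher one passes. No
multiple-testing correction is applied across orders. Default
alpha = 0.05; default extent metric WSD2 (for groups, WSD2 and nWSD2 give
identical decisions since the normalizer is constant within an order).
Covariate grouping uses half-open bins [e_i, e_{i+1}) with the final bin
closed.

## Tie-breaking (a genuinely open design point)

The published sorting rule — equal-count words ordered by the counts of
their reverse complements — is circular when those counts also tie. The
full A1 key used here is: descending count(w), then descending
count(revcomp(w)), then ascending canonical pair key (lexicographic min of
{w, revcomp(w)}), then pair leader before follower. Consequences: exactly
tied complementary pairs land adjacent and contribute zero distance (the
right reading of "same frequency" as perfect symmetry for that pair), and
A1/A2 are mutually consistent, so the rearrangement provably terminates at
A2 — the implementation asserts this on every run. The reference worked
example contains no ties, so these conventions do not affect its values.
A2 is derived from A1 positions alone (units ordered by their earliest
member's A1 position), which is equivalent to the larger-frequency rule
under these tie conventions and is the only form applicable to a printed
arrangement given without counts.

WSD1 is defined operationally as the greedy move count of this procedure.
Whether the greedy count always equals the true minimal (Ulam) move count
is not proven; the package exposes the proven lower bound
n − LCS(A1, A2) (`ulam_lower_bound`) for audit, and the two agree on the
reference example (16 − 13 = 3) and are never violated on randomized
cross-checks.

## Numerical and performance choices

- Words are encoded base-4 (A=0 < C=1 < G=2 < T=3), so numeric code order
  is lexicographic word order; arrangements are integer arrays.
- The move procedure tracks surviving A1 positions and moved words
  "riding" behind their anchors in two Fenwick trees, giving
  O((n + moves)·log n) per order. This rests on two invariants of the
  procedure: anchors never move, and a moved word stays adjacent to its
  anchor forever after. A literal quadratic list simulation is retained as
  an independent test oracle and agrees move-for-move on randomized tables
  at k ≤ 3. At k = 8 a full profile of a random table takes ~0.3 s;
  k ≤ 10 is supported, k = 11–12 allowed with a memory warning.
- Undefined statistics (no eligible pairs, zero control spread, < 5
  nonzero differences) carry an explicit flag; downstream extent decisions
  treat them as "none" direction.

## Synthetic data

`generate_symmetric(core)` returns core + revcomp(core): a sequence equal
to its own reverse complement, hence exactly symmetric at every order — a
positive control with known extent k_max. `generate_mixture(length,
symmetric_fraction, gc, seed)` concatenates (in seeded random order) a
symmetric block of ≈ fraction·length and an i.i.d. block with the stated
GC, giving a tunable symmetry signal; fraction 0 is pure i.i.d. (a genome
statistically exchangeable with its own shuffles, expected extent ≈ 1) and
fraction 1 is fully symmetric. Defaults used in the recovery study:
length 20,000 nt, GC 0.5, orders 2–6, 30 controls per genome, 10 seeds per
fraction — sizes at which per-word counts at the top order (4^6 = 4,096
words) are small but informative, mirroring the high-order regime of real
genomes at desk scale.

What these fixtures emulate is the *signal structure* (a tunable excess of
reverse-complement-matched counts over a composition-matched null); what
they do not emulate is real genomic texture — skewed word composition,
repeats, coding constraints, replication-strand asymmetries, megabase
length, or ambiguity-letter runs. Passing recovery tests therefore shows
the estimator responds monotonically to symmetry strength and is unbiased
under the null, not that any particular real genome has a given extent.

## Known limitations

- Very short or extreme-GC inputs leave high-order spectra almost empty;
  indexes go undefined and WSD values lose resolution (the small-genome
  regime is explicitly out of scope).
- The Wilcoxon exact path is skipped in the presence of tied absolute
  differences (normal approximation with continuity correction is used
  instead), which is conservative for tiny groups with many ties.
- The greedy move count is reported as WSD1 without a minimality proof
  (see above); WSD2 is unaffected, being defined by the same procedure
  that produces it.
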