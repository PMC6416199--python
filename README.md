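# strandsym

Strand symmetry — Chargaff's second parity rule — is the observation that
within a single strand of genomic DNA, each word (k-mer) occurs about as
often as its reverse complement (e.g. GTCA vs. TGAC). The symmetry is
strong for short words and decays with increasing order k; *where* it stops
persisting is a quantitative question about genome composition that simple
similarity indexes cannot answer on their own.

`strandsym` is a toolkit for answering that question on any DNA sequence
set. It computes, per order k:

- **Symmetry indexes.** With f_i the count of word i and f_i′ that of its
  reverse complement, over all words that differ from their own reverse
  complement and whose pair is not entirely absent:

  S1 = 1 − Σ|f_i − f_i′| / Σ(f_i + f_i′)
  S2 = 1 − (1/M) Σ |f_i − f_i′| / (f_i + f_i′)

  S1 weights pairs by total frequency; S2 weights every pair equally
  (M = number of entries used). Both are 1 under perfect symmetry.

- **Word symmetry distances.** All 4^k words are sorted by descending
  frequency (arrangement A1) and reorganized so each complementary pair is
  adjacent, pairs ordered by their larger frequency (arrangement A2).
  Pair by pair, the later member is moved next to the earlier one; **WSD1**
  counts the moves (an Ulam-style permutation distance), and **WSD2** sums
  each move's *step* — the number of words between the pair just before
  the move — so that strongly asymmetric pairs weigh more. Both are
  normalized by closed-form maxima (nWSD1, nWSD2).

- **Statistical extent.** Each sequence is compared against shuffled
  controls with exactly its mononucleotide composition: groups of genomes
  (one control each) with the Wilcoxon signed-rank test, individual
  genomes (30 controls) with a one-sample t test. Strand symmetry
  *persists* at order k while the genomic distances are significantly
  smaller than the controls'; the extent is the highest such k, and orders
  where the genomic values become significantly larger mark the breakdown.

## Worked example

The reference dinucleotide rearrangement is built in as a permanent
self-check:

```bash
$ strandsym worked-example
      A2: AG CT AT GC AA TT CA TG GT AC CG TC GA CC GG TA  [PASS]
   steps: [8, 1, 1]  [PASS]
    WSD1: 3  [PASS]
    WSD2: 10  [PASS]
max_ulam: 6  [PASS]
max_WSD2: 54  [PASS]
   nWSD1: 0.5  [PASS]
   nWSD2: 0.185  [PASS]
```

Starting from the frequency arrangement A1(2) =
[AG CT AT GC AA CA TG GT CG AC TC CC GA TT GG TA], pairing produces A2(2);
three moves are needed (TT next to AA with step 8, then AC and GA each with
step 1), so WSD1 = 3 and WSD2 = 10. With the dinucleotide maxima 6 and 54,
the normalized distances are nWSD1 = 0.500 and nWSD2 = 0.185.

A full synthetic run, end to end:

```bash
$ strandsym simulate --mixture 0.8 --length 20000 --n 1 --seed 7 --out fixtures
$ strandsym analyze fixtures/mixture_0.fasta --kmax 6 --controls 30 --seed 1 --out out
extent of strand symmetry (WSD2): 6
reports written to out
```

`out/profiles.tsv` holds per-order S1/S2/WSD values for the genome and each
control; `out/individual_report.tsv` holds the per-order t tests. The
extent line says the genome's WSD2 stayed significantly below its controls
at every order 2–6 — expected for a sequence that is 80% a
self-reverse-complement block. `strandsym group` runs the paired
Wilcoxon workflow over a manifest of genomes, optionally binned by GC
content or mononucleotide S1.

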