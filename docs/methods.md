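# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic world does and does not
emulate, and the numerical conventions a user re-implementing or auditing
the pipeline would need.

## Study design and data model

The analysis assumes the paired-subclone design of the *Botryllus
schlosseri* blastogenetic-cycle experiment: each of 5 colonies is split
into genetically identical subclones, one sampled per phase (MC, preTO,
TO), one sequencing library per subclone — 15 libraries in total. A phase
comparison within a colony is therefore a paired contrast between two
libraries of the same genotype, and colonies are the biological replicates.
Counts are analyzed on library-total proportions only (c/N with N the
column sum); no between-sample scaling factor (TMM, median-of-ratios) is
applied, because the per-colony two-library tests below are defined on the
raw (count, total) pairs.

Comparisons are oriented later-phase-first — (preTO vs MC), (TO vs preTO),
(MC vs TO) — so "up" always means higher relative abundance in the phase
the cycle has just entered.

## Pairwise tests

**Fisher exact test.** Two-sided under the probability-mass rule: the
p-value is the sum of hypergeometric probabilities of all tables sharing
the observed margins whose probability does not exceed the observed one. A
relative tolerance of 1e-7 absorbs floating-point ties; this matches the
widely used convention (scipy's two-sided test agrees to ~1e-12 on random
tables). The implementation works in log space via `gammaln`, so
million-read libraries cost one vectorized pass over the hypergeometric
support instead of big-integer arithmetic; the test suite checks it against
exact integer enumeration on all tables with totals ≤ 30.

**Likelihood-ratio test.** The G statistic is the Poisson-rate likelihood
ratio: with pooled rate p̂ = (c_A+c_B)/(N_A+N_B) and expectations
E_i = N_i·p̂,

    G = 2·[c_A ln(c_A/E_A) + c_B ln(c_B/E_B)],  0·ln 0 := 0,

referred to χ² with 1 df. This is the exact maximized-likelihood form for
Poisson counts with fixed totals (the linear terms cancel at the MLE); the
binomial LRT would add complement terms of order c²/N that are negligible
at RNA-seq proportions but not identically zero, so the Poisson form is the
one the closed formula represents and the one the oracle test maximizes
numerically. The empty pair c_A = c_B = 0 returns (G, p) = (0, 1) rather
than an error.

**Combination rule.** The two tests are combined conservatively: a gene is
significant only when *both* reject at α (default 0.05, raw p-values, no
multiple-testing correction — matching the published procedure; a
Benjamini–Hochberg layer can be added by the caller on the stored
p-values). `mode` can relax this to `either`, `fisher_only` or `lrt_only`.
Direction is read off the normalized proportions; an exactly equal pair is
never directional regardless of significance.

## Replicate consensus

A consensus call for (gene, comparison) is `up` when at least `min_clues`
colonies call it up *and* up strictly outnumbers down (symmetrically for
`down`), else `ns`. The strict-majority clause means a direction-mixed gene
(e.g. 3 up / 3 down in a 6-replicate design) is never reported as coherent
DE. Colonies missing one of the two phases are skipped with a warning and
reduce `n_replicates` for that gene rather than aborting the run. Default
`min_clues` = 3 against 5 replicates.

## GO-category dynamics

Consensus calls are tallied per GO term and comparison into (D, U); a gene
annotated to several terms counts once in each, unannotated genes are
ignored, and all-ns terms are reported with D = U = 0 rather than dropped.
For an ordered pair of comparisons, GRV and GNV (see README for the
formulas) are computed by integer arithmetic with a single final division,
so they are exact to one rounding. An empty quadruple (D1+U1+D2+U2 = 0)
yields NaN metrics and `selected = False` — degenerate categories stay in
the output for auditability.

**Selection rule.** The published criterion "GRV and GNV > |0.9|" cannot be
a conjunction: the reported flagship category (ATPase activity, 39/0 →
1/51) has |GRV| = 89/91 ≈ 0.98 but |GNV| = 13/91 ≈ 0.14. The default is
therefore |GRV| > τ OR |GNV| > τ with τ = 0.9 (strict inequality), with
`rule="and"` available. "Most represented" ordering is by total DE-gene
count D1+U1+D2+U2 descending, ties by GO code.

## Transcript recovery

**Candidate definition.** Within each reading frame, stop codons split the
frame into segments. Each segment containing an ATG yields one
start-anchored candidate from its *first* ATG to the bounding stop
(`complete`) or to the 3′ terminus (`open3`). Startless segments that begin
at the 5′ terminus are candidates only as a *fallback*, when no
start-anchored candidate anywhere reaches `min_aa`: they classify as
`open5` (terminated by a stop) or `open_both` (no boundary codon at
either end). A startless segment preceded by a stop is never a candidate.
This precedence keeps the constructed single-ORF example unambiguous and
mirrors the behavior of start-preferring ORF callers; its known cost is
that a genuinely 5′-truncated ORF containing an internal in-frame ATG will
be reported from that ATG (and so may classify `complete`). Coordinates
are 0-based half-open on the scanned strand, include the stop codon when
present, and always span whole codons; `aa_length` excludes the stop.

**Coding-potential proxy.** The published workflow delegates coding
potential to an external predictor; here the dominant criterion of such
predictors — minimum ORF length — stands in, with `min_aa` = 100 codons by
default. The best candidate is the longest; ties break toward smaller
start, then lower frame, then forward strand. Only the forward strand is
scanned by default (assembled transcripts are oriented); `both_strands=True`
scans the reverse complement and reports `-`-strand coordinates on the
reverse-complemented sequence.

**Taxonomy inheritance.** Hits above `evalue_max` (default 1e-5) are
discarded; each transcript inherits the taxon of its lowest-e-value
surviving hit, ties broken by higher bitscore then first occurrence.
Malformed rows are counted and skipped with a warning, not fatal. The
summary reports per-taxon counts, exact proportions, and whole-percent
shares for tables.

## Synthetic world

Counts for gene g in sample s are Poisson with mean
N · θ_g · 2^{φ(g, phase)} · ε(g, colony), where

- θ is log-normal across genes (σ = 1.0), normalized to sum to 1 — the
  standard heavy-tailed RNA-seq abundance shape; per-sample expected totals
  are then ≈ `library_size` (10⁶ by default) up to the DE and colony
  effects;
- φ shifts exactly one phase of an affected gene by ±δ, δ ~ U(0.5, 2.5) in
  log2; the per-gene effects over the three cyclic transitions therefore
  sum to zero, encoding that the cycle returns to the same state each week.
  Genes are affected with probability de_fraction·3/2 so that the non-null
  count per transition is exactly Binomial(n_genes, de_fraction), with
  de_fraction = 0.1 by default;
- ε is a mild log-normal colony effect (σ = 0.1) shared by all phases of a
  colony, so it cancels in within-colony contrasts — the overdispersion
  lives *between* replicates, as in real paired subclones.

GO terms (100 by default) are assigned 1–4 per gene; 30% of terms are
"coherent": they accept DE members only from genes sharing one
(phase, sign) profile, so their DE members agree in direction within every
comparison, and a term whose profile is "suppressed in preTO" flips from
all-down to all-up across the (preTO vs MC, TO vs preTO) pair — the
GRV ≈ 1 scenario. Toy transcripts are built per completeness class from
sense codons that exclude ATG, with stop-bearing blocker motifs every 25
codons capping spurious cross-frame open runs below `min_aa`, so the
designed class is provably the only retainable candidate; best-hit tables
draw 1–4 hits per complete transcript with log-uniform e-values over
[1e-30, 1], Ascidiacea-weighted taxa, and some insignificant rows.

**What a green test does not establish.** The generator emulates Poisson
sampling with paired colony effects; it does not emulate within-subclone
technical overdispersion, mapping/quantification error (counts stand in
for RSEM output), isoform ambiguity, GC or length bias, or real GO
topology (terms are flat labels, no DAG propagation). One real effect it
*does* reproduce: because 10% of genes shift composition, the shares of
highly abundant null genes genuinely change slightly between phases, so
the consensus false-call rate on null genes is composition-dependent —
about 10⁻³ at the default seed, occasionally higher on unlucky draws —
rather than the ~3·10⁻⁴ that independent per-colony errors would give.
Proportion-based truth would count those as true positives; rate-based
truth (used here) counts them as false calls.

## Numerical conventions and degenerate inputs

- Fisher tie tolerance 1e-7 (relative, part of the p-value definition);
  log-space evaluation; p clipped at 1.
- G clipped at 0 against floating-point jitter; χ² survival function from
  scipy.
- GRV/GNV: NaN sentinel for empty quadruples, never an exception.
- Empty datasets write valid headers with zero rows; an all-zero gene is
  `ns` everywhere; `min_clues` above the replicate count yields all-`ns`
  tables, not an error.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; transcripts and hit tables use spawned
  sub-seeds so the count matrix is invariant to transcript settings.

## Known limitations

- No multiple-testing correction by default (fidelity to the published
  procedure); at 2000 genes and α = 0.05 the per-colony false-positive
  load is carried by the consensus filter instead.
- The two-test "both" rule is conservative; its joint size is below α and
  not calibrated.
- ORF classification reports a single best ORF per transcript; nested or
  polycistronic arrangements are out of scope.
- The optional `min_count` filter (default 0 = off) drops genes whose
  maximum count is below threshold before testing; it mirrors the
  platform's "expression level threshold" and is deliberately blunt.
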