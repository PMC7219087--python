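# Methods

This note records the models, defaults and numerical choices behind
`promotif`, and what the synthetic validation does and does not show.

## Promoter definition

A promoter is the window `[TSS − w, TSS)` on the gene's strand, `w = 500`
by default, read 5'→3' toward the TSS. The TSS base itself is excluded;
"from the TSS to 500 bp upstream" is ambiguous by one base, so the
alternative is available via `include_tss_base`. Coordinates are 0-based
half-open internally; GFF3 (1-based inclusive) is converted on read.
Windows are clipped at chromosome edges, so promoters may be shorter than
`w`; every returned sequence has length `min(w, available bases)`. One
promoter per input record; duplicate gene ids are rejected rather than
silently reconciled, because transcript selection is the caller's decision.

## Scoring model

A JASPAR count matrix `c` (rows A, C, G, T) becomes a log2-odds weight
matrix against a background `q`:

    w(b, j) = log2[ (c(b,j) + s_j q_b) / (Σ_b c(b,j) + s_j) / q_b ]

The default background is uniform (0.25 each); an empirical background
computed from the scanned universe is available, since both conventions are
standard. The default pseudocount mass is `s_j = 0.01 · column sum`,
enough to keep sparse JASPAR columns finite without visibly distorting
well-populated ones. A zero pseudocount is rejected whenever any count is
zero (it would yield −∞ weights).

A window scores the sum of its per-position weights. Each promoter is
scanned at every offset on both strands (the reverse strand via the
reverse-complemented matrix); windows containing N are skipped entirely
rather than penalised, which avoids composition artifacts at assembly gaps.
The best hit per (gene, motif) is kept, with ties broken by smaller offset,
then by the + strand. The reverse-strand accumulation deliberately sums
columns right-to-left so that a palindromic window produces bit-identical
forward and reverse scores and the tie-break is exact, not
rounding-dependent.

Scores are reported raw and normalised, `(x − min) / (max − min)` over the
matrix's theoretical extremes. Downstream fitting and calling use the
normalised score by default: its [0, 1] support makes distributions
comparable across matrices of different widths and information content.
Raw-score fitting is available behind a flag.

## Set-vs-genome enrichment and archetype selection

For a gene set of size `n` the statistic is the set-mean z-test used by
promoter-scanning enrichment tools:

    z = (x̄_set − μ_pop) / (σ_pop / √n),   p = 1 − Φ(z)

with the population moments taken from *all* scanned genes — they are
known, not estimated, which is why a z-test rather than a two-sample t-test
is appropriate. Benjamini–Hochberg adjustment is applied across the motifs
tested in one call; raw p-values are always reported alongside. The
finite-population correction for sampling without replacement
(factor √((N−n)/(N−1)) ≈ 0.99 at N = 5000, n = 100) is deliberately
omitted, matching the plain form of the statistic; its effect is below the
Monte-Carlo resolution of the calibration tests.

Per element family (G-box, MADS-box/CArG, W-box, …) the matrix with the
smallest enrichment p is selected as the family archetype and used for
genome-wide calling; exact ties go to the lexicographically smaller motif
id with a logged warning.

## Mixture model and bona fide calls

The genome-wide best-score distribution of an archetype is modelled as a
two-component univariate Gaussian mixture fit by EM:

- E-step: responsibilities `γ_i = π_h φ(x_i; μ_h, σ_h) / Σ_c π_c φ(x_i; μ_c, σ_c)`,
  computed in log-space.
- M-step: standard weighted moments, with a variance floor
  `max(1e-6, 1e-4 · Var(x))` that prevents singular collapse onto
  duplicated scores.
- Initialisation is deterministic: means at the 25th/75th percentiles,
  equal weights, pooled standard deviation. Random restarts (initial means
  drawn from data pairs) run only when requested and require a seed, so
  pipelines are reproducible by default.
- Convergence: absolute log-likelihood change < 1e-8, cap 500 iterations;
  non-convergence returns the model flagged with a warning rather than
  failing the run. The log-likelihood trace is retained and is
  nondecreasing by construction of EM (asserted in tests).

Components are relabelled so `μ_low ≤ μ_high`; "high-scoring" means the
larger-mean component regardless of its mixing weight. A promoter is
called a **bona fide element** when the posterior probability of the
high component at its score strictly exceeds the confidence level
(default 0.95). With equal component variances the posterior is monotone
in the score and the calls are exactly an upper score set; the implied
threshold (the posterior-crossing point, found by Brent's method) is then
reported. With unequal variances the posterior can be non-monotone at the
extremes; calls still follow the posterior rule pointwise and the report
flags the case instead of forcing a single threshold. A collapsed fit
(`μ_low = μ_high`) refuses to call anything. Genes without a scoreable
window are never called.

The choice of *posterior responsibility* as the ">95% confidence" quantity
is the natural probabilistic reading; it is applied per gene, not as a
family-wise certainty.

## Over-representation and co-occurrence

With `N` scored promoters, `K` called, and a gene set with `n` members in
the scored universe of which `k` are called, the enrichment p-value is the
hypergeometric upper tail `P(X ≥ k)`, one-sided for over-representation
(depletion available behind a flag). The universe is the scored-promoter
population for that motif — the same population the mixture was fit to —
so `(N, K, n, k)` are mutually consistent and every reported proportion
`k/n` is auditable against its background `K/N`. Set members outside the
universe are dropped with a logged count; duplicates are de-duplicated.
Cross-family co-occurrence reports, per unordered family pair, the genes
of a set called for both families.

## Synthetic data

The generator emulates the shape of a genome-scale promoter study at desk
scale, and its defaults are the study conditions used throughout the
tests:

- 5,000 promoters × 500 bp, i.i.d. bases at GC = 0.36 (the Arabidopsis
  genome-wide composition);
- DEG sets of 31 up / 171 down genes, disjoint, sampled without
  replacement;
- planting rates 0.4 within a regulated set versus 0.05 background;
- three sharply peaked archetype matrices (94% consensus base per column,
  ≈ 16 bits over 10 bp) around G-box, W-box and CArG-box consensus cores.

Planted sites are sampled column-wise from the pseudocounted probability
matrix (so a minority carry mutations, as real sites do), placed at a
uniform offset on a uniform strand, and overwrite the background sequence,
keeping all promoters at fixed length. At most one instance per (motif,
gene) keeps truth bookkeeping and best-match semantics unambiguous. All
randomness flows from one seed through `numpy.random.SeedSequence.spawn`,
one child stream per stage, so each stage is individually reproducible.

What the simulations do *not* emulate: positional bias of real TFBSs
toward the TSS, dinucleotide composition and repeats, co-occurring or
overlapping sites, and annotation noise. Passing the planted-signal tests
therefore demonstrates that the machinery recovers a known signal at
realistic rates, not that any particular biological dataset will show one.

## Validation experiment sizes

The test suite and `scripts/acceptance.py` use: 200 random
(promoter ≤ 60 bp, motif ≤ 12 bp) pairs against exhaustive enumeration;
all feasible hypergeometric arguments at N ≤ 25 (tests) / N ≤ 20 (script)
against exact rational combinatorics; EM recovery on 5,000 draws from
π = (0.7, 0.3), μ = (0.55, 0.85), σ = (0.06, 0.06); null calibration with
2,000 random 100-gene sets on a 5,000-promoter universe; and 20 seeded
end-to-end planted-signal runs at full generator defaults. These sizes
give Monte-Carlo standard errors small enough for the stated bands while
keeping a full validation run around a minute.

One calibration caveat, measured honestly: the best-score distribution of
a sharp motif is right-skewed and heavy-tailed (a maximum over ~10³
windows), so the *conditional* null rejection rate of the z-test given one
simulated universe scatters by roughly ±0.007 around 0.05 between
universes (measured 0.044–0.058 across universes at 20,000 replicates).
A 2,000-replicate estimate adds ±0.005 binomial noise on top; individual
runs can therefore land slightly outside a ±0.01 band around the nominal
level even though the test is calibrated on average.

## Known limitations

- Only A/C/G/T/N are handled; other ambiguity codes are rejected on input.
- No per-hit p-values or suboptimal-hit enumeration; the analysis is
  built on one best hit per promoter, matching the mixture model's input.
- The mixture is always exactly two Gaussian components; no model-order
  selection.
- DE calling, GO enrichment and read processing are out of scope: the
  pipeline consumes a finished DEG table.
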