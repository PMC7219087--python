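# promotif

Promoter motif scanning, Gaussian-mixture thresholding and gene-set
enrichment for regulatory genomics.

## The problem

Given a list of differentially expressed genes (DEGs) from an RNA-seq
contrast — say, genes mis-regulated when a set of MADS-domain and bHLH
transcription factors is knocked out — a recurring question is whether the
promoters of those genes are enriched for the binding elements of specific
transcription-factor families (G-box for bHLH, CArG-box for MADS, W-box for
WRKY), and *which* genes carry a credible element, making them candidate
direct targets.

`promotif` implements that analysis as a tested, reusable pipeline over
standard file formats (JASPAR PFM, FASTA, GFF3/BED, TSV):

1. **Promoter definition** — the window from the TSS to 500 bp upstream,
   extracted strand-aware from a genome + annotation, or supplied directly
   as FASTA.
2. **PWM scanning** — each promoter is scored on both strands with the
   log2-odds matrix
   `w(b,j) = log2[(c(b,j) + s·q_b) / (Σ_b c(b,j) + s) / q_b]`,
   and the best window per (gene, motif) is kept, normalised to [0, 1]
   between the matrix's score extremes.
3. **Set-vs-genome enrichment** — a Pscan-style z-test per motif:
   `z = (x̄_set − μ_pop) / (σ_pop / √n)` over best scores, with the whole
   scanned universe as the population, one-sided upper-tail p and
   Benjamini–Hochberg adjustment; the best-enriched matrix per element
   family becomes that family's *archetype*.
4. **Mixture thresholding** — for each archetype the genome-wide best-score
   distribution is fit with a two-component Gaussian mixture
   `f(x) = π_lo N(μ_lo, σ_lo²) + π_hi N(μ_hi, σ_hi²)` by EM; a promoter is
   called a **bona fide element** when the posterior probability of the
   high-scoring component at its score exceeds 0.95.
5. **Over-representation** — bona fide calls are tested in each DEG set by
   the hypergeometric upper tail `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`,
   with cross-family co-occurrence reported per gene set.

A first-class synthetic-data module generates promoter universes with
motif instances planted at controlled rates and full ground truth, so every
stage is validated end to end without any external downloads.

## Worked example

Simulate a study shaped like a typical DEG contrast (5,000 promoters of
500 bp, 31 up / 171 down genes, a G-box planted in 40% of the up set versus
a 5% background), then run the full analysis:

```python
from promotif import (SimulationConfig, example_motifs, simulate_study,
                      build_weight_matrix, scan_universe, zscore_enrichment,
                      fit_two_component_em, call_bona_fide, enrich_set)

motifs = example_motifs()                 # G-box, W-box, CArG-box archetypes
gbox = motifs[0]
config = SimulationConfig(
    n_promoters=5000, promoter_length=500, motifs=motifs,
    set_sizes={"up": 31, "down": 171},
    planting={
        gbox.motif_id: {"up": 0.4, "background": 0.05},
        motifs[1].motif_id: {"down": 0.4, "background": 0.05},
        motifs[2].motif_id: {"down": 0.4, "background": 0.05},
    },
    seed=42,
)
universe, deg, truth = simulate_study(config)
wms = [build_weight_matrix(m) for m in motifs]
table = scan_universe(wms, universe)

up = deg.gene_set("up")
for e in zscore_enrichment(table, up, "up"):
    print(f"{e.motif_id}: z = {e.z:.2f}, p = {e.p:.2e}")

scores = table.norm_scores(gbox.motif_id).to_numpy()
model = fit_two_component_em(scores, seed=0, motif_id=gbox.motif_id)
print(f"mixture: mu = ({model.mu_low:.3f}, {model.mu_high:.3f}), "
      f"pi_high = {model.pi_high:.3f}, converged = {model.converged}")

calls = call_bona_fide(model, table, confidence=0.95)
print(f"bona fide G-box promoters: {calls.K} of {calls.N}")
rec = enrich_set(calls, up, universe, "up", table=table)
print(f"up-set enrichment: k/n = {rec.k}/{rec.n} "
      f"({100*rec.proportion:.0f}%), hypergeometric p = {rec.p:.1e}")
```

Output:

```
SYN_GBOX: z = 7.93, p = 1.08e-15
SYN_WBOX: z = -0.69, p = 7.55e-01
SYN_CARG: z = -1.49, p = 9.31e-01
mixture: mu = (0.631, 0.847), pi_high = 0.109, converged = True
bona fide G-box promoters: 249 of 5000
up-set enrichment: k/n = 14/31 (45%), hypergeometric p = 5.0e-11
```

Reading it: only the planted family is enriched in the up set (z = 7.9);
the mixture separates a high-scoring component containing ~11% of
promoters; 249 promoters genome-wide carry a confident G-box, and 14 of
the 31 upregulated genes do — a 45% proportion against a 5% background,
hypergeometric p ≈ 5×10⁻¹¹.

The same pipeline runs from the shell over files:

```sh
promotif simulate --n-promoters 5000 --seed 42 --out-dir study/
promotif run --config config.json --seed 42     # scan → enrich → fit → call
```

`promotif run` writes z-score and hypergeometric enrichment TSVs, the
mixture report, BED6 files of called elements, a co-occurrence table and a
JSON manifest into the run directory; identical inputs + seed give
byte-identical outputs.

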