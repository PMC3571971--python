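# omegascreen

Detection of rapidly evolving genes in expression-defined gene categories,
after the study design used for sex-associated genes in *Neurospora*:
two-channel microarray hybridizations between sexual and vegetative tissue
define **sexual**, **vegetative** and **constitutive** gene categories, and
codon-model maximum likelihood on multi-species alignments asks whether the
sex-associated genes evolve faster and whether positive selection drives
individual codons.

The package implements the full inference chain, exercisable end to end on
synthetic data:

* **expression** — normalization of dye-swap two-channel intensities and a
  Bayesian posterior for each gene's relative expression (Normal model with
  Jeffreys prior; closed-form Student-t posterior with a Gibbs-sampler
  cross-check), three-way categorization at *P* < 0.05 and a stringent
  *Q* < 0.10 sexual subcategory (Storey q-values);
* **alignprep** — fragment consensus merging, frame-restoring insert
  removal, stop/incomplete-codon masking, and the all-taxa gapless codon
  filter that produces clean alignments;
* **codonmodel** — a Goldman–Yang rate matrix (κ, ω, π; 61 sense codons),
  Felsenstein pruning with pattern compression, the one-ratio (M0),
  two-ratio branch, and site-mixture models M1a/M2a/M7/M8, dN/dS
  decomposition, likelihood-ratio tests, and Bayes empirical Bayes (BEB)
  site posteriors for positive selection;
* **screen** — the genome screen: per gene, free ω versus ω fixed at the
  all-genes concatenation mean (χ²₁ LRT), per-branch two-ratio variants on
  a star phylogeny, Storey FDR within each scope, and a directional filter
  so only *accelerated* genes are called rapid;
* **categorystats** — bootstrap concatenation of 10-gene resamples per
  category with Wilcoxon rank-sum contrasts, Fisher-exact enrichment with
  observed/expected tables, RSCU codon-usage correspondence analysis, and
  expression–rate regressions;
* **synthgen** — simulators for codon alignments under single-ratio,
  branch-specific, and site-mixture ω regimes, and for the 4-array
  dye-swap microarray experiment, with truth tables kept separate from
  pipeline inputs.

The scientific core is the ratio ω = dN/dS of nonsynonymous to synonymous
substitutions per site: ω < 1 indicates purifying selection, ω = 1
neutrality, ω > 1 positive selection. The screen's null fixes a gene's ω
at the category-wide mean m̂ (estimated from a concatenated fit), so
2(lnL_free − lnL_fixed) ~ χ²₁ tests whether the gene's rate ratio deviates
from m̂, and ω̂ > m̂ makes the deviation an acceleration.

## Worked example

Simulate a small study and screen it:

```python
import numpy as np
from omegascreen.synthgen import CodonSimScenario, simulate_codon_alignment
from omegascreen.screen import estimate_mean_omega, screen_gene, adjust_screen_fdr
from omegascreen.trees import star_tree

tree = star_tree(["crassa", "discreta", "intermedia", "tetrasperma"], 0.3)

# ten background genes at omega = 0.11, one accelerated gene at 0.45
alns = [
    simulate_codon_alignment(
        CodonSimScenario(tree=tree, omega_mode=0.11, n_codons=300, seed=s),
        gene_id=f"bg{s}",
    ).alignment
    for s in range(10)
]
fast = simulate_codon_alignment(
    CodonSimScenario(tree=tree, omega_mode=0.45, n_codons=300, seed=99),
    gene_id="fast",
).alignment

mean = estimate_mean_omega(alns + [fast], tree)
print(f"concatenation mean omega = {mean.global_mean:.4f}")

results = adjust_screen_fdr(
    [screen_gene(a, tree, mean.global_mean) for a in alns + [fast]]
)
for r in results:
    if r.rapid:
        print(f"{r.gene_id}: omega_free={r.omega_free:.3f} "
              f"vs mean={r.omega_fixed_mean:.3f}, p={r.p_value:.2e}, q={r.q_value:.2e}")
```

prints

```
concatenation mean omega = 0.1325
fast: omega_free=0.521 vs mean=0.132, p=1.50e-31, q=9.00e-31
```

— the concatenation mean lands near the simulated background (0.11 pulled
up by the planted fast gene), and the screen recovers exactly the
accelerated gene: its free estimate 0.52 against the mean-fixed null gives
a χ²₁ p-value of 1.5×10⁻³¹, which survives the within-scope FDR adjustment
(q ≈ 9×10⁻³¹ < 0.05) and passes the directional filter (0.52 > 0.13).

The same machinery drives the command line:

```sh
omegascreen simulate --genes 100 --out study/
omegascreen run --alignments study/ --tree study/tree.nwk \
    --intensities study/intensities.tsv --metadata study/metadata.tsv \
    --out study/results
omegascreen sites study/SIM00000.fasta --tree study/tree.nwk --pair M1a
```

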