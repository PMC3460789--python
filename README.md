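# e3miner

Mining and expression characterization of E3 ubiquitin ligases.

E3 ligases confer substrate specificity in the ubiquitination cascade, and a
large fraction of them are deployed during spermatogenesis — meiosis and
spermatid morphogenesis consume proteins at a rate that demands dedicated,
often testis-specific, degradation machinery. `e3miner` implements, as a
tested and reusable pipeline, the informatic half of cataloguing these
enzymes and profiling their expression:

1. **Domain-based mining** — parse HMMER per-domain tabular output
   (`--domtblout`), keep hits with full-sequence E-value ≤ 0.1, and build an
   exclusive per-gene catalogue over the three classical E3 families: RING
   (Pfam `zf-C3HC4`), HECT and U-box. Multi-domain genes take the family of
   their best-E-value hit (tie precedence RING > HECT > U-box).
2. **Cross-species homology** — map ortholog groups (HomoloGene-style
   tables) between two species and summarize the overlap as
   *n*<sub>shared</sub> / (*n*<sub>A</sub> + *n*<sub>B</sub> −
   *n*<sub>shared</sub>), with an exact one-sided binomial tail
   P(X ≥ k), X ~ Bin(n, p₀), for enrichment over the genome background.
3. **Tissue-specificity rating** — per dataset, convert a gene's expression
   across tissues to z-scores, z<sub>t</sub> = (x<sub>t</sub> − μ)/s, and
   assign one of five ordinal levels per tissue:
   A (absent, by MAS5 P/A call), P (present),
   HP (z<sub>t</sub> ≥ 1), MS (z<sub>t</sub> ≥ 1.96),
   SP (z<sub>t</sub> ≥ 2.58 with all other tissues ≤ 1.96) — most specific
   satisfied level wins. Multiple datasets (microarray voters plus an EST
   count voter) are combined by ballot: a level needs ≥ 2 supporting
   datasets; ties resolve to the less specific level.
4. **Stage grouping** — classify developmental profiles (SG-A → pacSC →
   rST → eST cell types, or days-postpartum series) as MI (high at the
   mitotic stage), ME (rises at meiosis) or PM (rises post-meiotically)
   using a ≥ 3-fold differential filter and a deterministic half-max onset
   rule, again aggregated by 2-of-3 voting.

A synthetic-data module generates every input kind with planted ground truth
(specificity classes, stage groups, domain families, homology structure), so
the whole chain is testable end to end without any external download.

## Worked example

Simulate the five-voter study condition (4 arrays with P/A calls + 1 EST
count voter, 10 tissues including testis), rate every gene and ballot:

```python
from e3miner.synthetic_data import PanelConfig, generate_full_panel
from e3miner.tissue_rating import rate_all

config = PanelConfig(n_genes=500, seed=1)       # defaults: noise 0.2 log2, 2% call flips
voters, truth = generate_full_panel(config)
ratings = rate_all(voters)
print(ratings.final["testis"].value_counts().to_dict())
```

```
{'P': 336, 'A': 75, 'HP': 48, 'SP': 37, 'MS': 4}
```

Each gene gets one final level in the testis; under the default noise the
ballot recovers 98.8% of the planted labels (100% at zero noise). The
homology summary works directly from published-scale counts — 398 mouse and
411 human catalogue genes sharing 335 ortholog groups:

```python
from e3miner.homology import homolog_fraction, enrichment_test

print(round(100 * homolog_fraction(398, 411, 335), 1))   # 70.7  (% of the union)
print(f"{enrichment_test(335, 474, 15952/33868):.2e}")   # 2.38e-25
```

70.7% of the union of the two E3 sets is shared, versus a genome-wide
background of 47.1% (15952 of 33868 union genes) — the binomial tail above
is the probability of an overlap at least that large under the background
rate.

The same flows are available from a shell:

```console
e3miner simulate panel --seed 1 --out panel/
e3miner mine --domtbl hits.domtblout --gene-map map.tsv --out catalog.tsv
e3miner homology --table homologene.tsv --set-a mouse.tsv:10090 --set-b human.tsv:9606
e3miner rate --datasets panel/array1.tsv,panel/array2.tsv --est panel/est.tsv --out ratings.tsv
e3miner run --config run.yaml          # full pipeline + report bundle
```

`e3miner run` writes a report bundle: catalogue TSV, homology summary,
per-gene ratings, a family × level cross-tab for the chosen tissue, stage
groups, a group × level cross-tab, and a manifest whose content hash makes
reruns provably identical.

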