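# polylink

Single-dose marker linkage mapping, homology-group assembly and
chromosome-pairing analysis for autopolyploids.

## The problem

Highly polyploid, heterozygous crops (sugarcane is the motivating case:
aneu-polyploid cultivars with ~110 chromosomes in 8 basic homology
groups) cannot be mapped with the designs used in diploids. The
workable strategy is the **pseudo-testcross**: score dominant
presence/absence markers in an F1 between two heterozygous parents and
map only the **single-dose (SD)** markers of one parent — markers
present on exactly one homologue, which segregate 1:1 in the progeny
regardless of ploidy. Each linkage group (LG) then represents one
homologue; LGs are tied back into **homology groups (HGs)** through
multi-allelic SSR/SNP anchor loci whose alleles map to different
homologous LGs. Because repulsion-phase linkage between SD markers on
different homologues is only detectable when those homologues pair
preferentially at meiosis, repulsion analysis doubles as a test for
(partial) disomy.

`polylink` implements that entire workflow as a tested Python library,
with a polysomic meiosis simulator that generates populations with
known truth, so every stage can be validated by parameter recovery.

## The statistics

* **Dosage classification.** A dose-*k* dominant marker at even ploidy
  *m* is absent from a progeny with probability
  C(m−k, m/2) / C(m, m/2) under random chromosomal segregation —
  1:1 present:absent for SD, 55:15 for DD and 65:5 for TD at m = 8.
  Markers are classified by χ² (1 df) at α = 0.05; significantly
  distorted markers are retained as *skewed SD* as long as the 1:1 fit
  still beats the DD fit.
* **Two-point linkage.** For coupling-phase SD markers each informative
  progeny is one meiosis, so r̂ = R/n (R = discordant progeny) and
  LOD = R·log₁₀ r̂ + (n−R)·log₁₀(1−r̂) + n·log₁₀ 2.
  Groups form by transitive closure over pairs with LOD ≥ 10 and
  r ≤ 0.35; orders minimise the sum of adjacent recombination fractions
  (greedy seriation with 2-opt/or-opt refinement); positions are
  cumulative Haldane cM, d = −50·ln(1−2r). Maps are built in two
  stages: a framework from fully scored markers, then single insertion
  of panel-restricted markers.
* **Homology groups.** LGs join when they share ≥ 2 distinct
  multi-allelic locus families; HGs are the connected components.
* **Repulsion / pairing.** The segregation matrix is phase-inverted and
  two-point analysis run between original and inverted markers
  (repulsion LOD of (a, b) ≡ coupling LOD of (a, complement of b)).
  An LG pair is accepted as in repulsion at LOD ≥ 5 when ≥ 3 marker
  pairs agree and span ≥ 30% of both LGs.
* **Difference ratio.** For the shared (anchor-defined) marker
  intervals between a HG's most densely mapped LG and another LG,
  ratio = Σₖ |LGmax_k − LGi_k| / (LGmax + LGi); 0 means identical
  interval structure.

## Worked example

`examples/05_chromosome_pairing.py` simulates one octoploid HG (8
homologues, 10 SD markers each, 227 progeny) twice — under strict
disomy (partner pairs always form bivalents together) and under fully
polysomic random pairing — maps it, and runs repulsion detection:

```
strict disomy: 8 LGs, 4 accepted repulsion links
  LG1 -- LG2: best LOD 65.3, 186 marker pairs
  LG3 -- LG4: best LOD 65.6, 170 marker pairs
  LG5 -- LG6: best LOD 65.6, 171 marker pairs
  LG7 -- LG8: best LOD 65.6, 177 marker pairs
  mean difference ratio vs densest LG: 0.07

full polysomy: 8 LGs, 0 accepted repulsion links
  mean difference ratio vs densest LG: 0.06
```

Both pairing regimes recover one LG per homologue; only the disomic
genome shows repulsion, and it is exactly the four true partner pairs.
Under full polysomy at ploidy 8 the residual marker association
(joint-absence 15/70 against 1/4 under independence) stays below the
acceptance rule — absence of repulsion is evidence of polysomy, not of
missing data. The other examples cover simulation
(`01_simulate_population.py`), dosage classification (`02…`), map
building (`03…`), HG assembly (`04…`) and the full pipeline driver with
its TSV/JSON report bundle (`06_full_pipeline.py`).

A thin CLI wraps the same library:

```bash
polylink simulate --seed 1
polylink all --genotypes genotypes.csv --metadata metadata.tsv --outdir out --seed 1
```

## Layout

| path | contents |
| --- | --- |
| `src/polylink/simulate.py` | polysomic meiosis simulator with truth tables |
| `src/polylink/scoring.py` | dosage classification, skew, duplicates, QC |
| `src/polylink/linkage.py` | two-point LOD/rf, grouping, SARF ordering, two-stage maps |
| `src/polylink/homology.py` | anchor families, HG assembly, summaries, clustering |
| `src/polylink/pairing.py` | matrix inversion, repulsion links, difference ratios |
| `src/polylink/io.py`, `pipeline.py`, `cli.py` | formats, driver, CLI |
| `docs/methods.md` | model assumptions, parameter choices, limitations |
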