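# Methods

This note records the models, parameter choices and known limitations
behind `polylink`, in the spirit of the methods documentation shipped
with simulation and statistics packages.

## The mapping model

All mapped markers are dominant, coupling-phase, single-dose (SD)
markers of one informative parent in a pseudo-testcross: present on
exactly one homologue of that parent and absent from the other parent,
so each informative progeny is a direct observation of one meiosis.
The recombination fraction between two SD markers on the same homologue
is estimated as the discordance rate r̂ = R/n over progeny scored for
both markers, and the two-point LOD is the likelihood ratio of linkage
at r̂ against free recombination,

    LOD = R log10(r) + (n − R) log10(1 − r) + n log10 2,

with the r = 0 limit n·log10 2 handled exactly. Repulsion-phase
configurations are never estimated directly: they are handled by
phase-inverting the matrix (see below), mirroring how the analysis is
done in practice with CP-population mapping software.

Map distances use the Haldane function d = −50 ln(1 − 2r), which
assumes crossovers occur without interference — the same assumption the
simulator makes (Poisson crossover counts), so simulator and estimator
are mutually consistent by construction.

### Grouping, ordering, two-stage build

Marker groups are single-linkage connected components over edges with
LOD ≥ 10 and r ≤ 0.35, both inclusive, with a floor of 30 shared
informative progeny per pair (pairs below the floor are excluded, not
down-weighted). Ordering minimises the sum of adjacent recombination
fractions (SARF): greedy insertion seriation refined by alternating
2-opt (segment reversal) and or-opt (relocation of 1–3 marker segments,
optionally reversed) passes until neither improves. Pure 2-opt was
found to miss the global SARF optimum on a few percent of random 4–8
marker instances; with or-opt added the refiner agreed with an
exhaustive permutation search on 300/300 random instances. All
tie-breaks are lexicographic on marker names, and each LG is oriented
so its lexicographically smaller terminal marker comes first, making
orders deterministic and reversal-invariant.

The map is built in two stages: markers scored on ≥ 188 progeny form
the framework; markers scored on fewer (the 94-progeny panel markers)
are inserted one at a time into the LG holding their best framework
linkage, at the slot minimising the SARF increase, without reordering
the framework. An adjacent r at or above 0.5 cannot be mapped to a
Haldane distance; adjacent fractions are capped at 0.49 (a ~196 cM
interval) rather than erroring, which in practice only triggers on
pathological inputs since grouping already requires r ≤ 0.35.

### Dosage classification

At even ploidy m, a dose-k dominant marker is absent from a gamete with
probability C(m−k, m/2)/C(m, m/2) under random chromosomal segregation.
Classification against the 1:1 (SD), DD and TD ratios uses χ² with 1 df
at α = 0.05 (complete-case counts): SD when 1:1 is not rejected;
*skewed SD* when 1:1 is rejected but its χ² is still strictly below the
χ² against the DD ratio — this operationalises "keep moderate
segregation distortion, exclude likely double dose"; DD or TD when the
respective χ² is minimal and non-significant; otherwise unclassified.
The significance gate deliberately sends an α-tail of genuinely
multi-dose markers to "unclassified" rather than risking their
inclusion in the SD map; accuracy should therefore be judged as
discrimination (SD never called DD/TD and vice versa), which the test
suite verifies at ≥ 95%. Markers flagged as present in both parents
are tested against 3:1 and always excluded from SD mapping.

Duplicate markers (the same clone assayed under several restriction
enzymes) are collapsed when identical wherever both are scored, with a
floor of 50 shared scored progeny to prevent spurious merges among
94-progeny panel markers; the representative is the member with the
highest call rate. Marker QC keeps quality strictly above 80 and call
rate at least 0.8, where call rate is scored calls over *assayed*
progeny when a panel restriction is recorded — a marker deliberately
assayed on 94 progeny is not penalised for the 133 never attempted.

## Homology groups and pairing

Two LGs join when they share at least two **distinct** multi-allelic
locus families; requiring two families (not two alleles of one family)
guards against single duplicated loci bridging unrelated chromosomes,
which is the classic mis-assembly mode for multi-locus SSRs in
polyploids. HGs are connected components, so membership can chain
through intermediate LGs; components held together by a single
articulation LG are flagged for review rather than split. Sequence-
similarity evidence and repulsion evidence are reported alongside but
never merge components automatically.

Repulsion detection runs two-point analysis between every mapped
marker and the phase-inverted copy of every marker on another LG; the
repulsion LOD of (a, b) is identically the coupling LOD of a with the
complement of b, which the tests verify directly. A LG pair is
accepted at LOD ≥ 5 only when ≥ 3 supporting marker pairs exist and
the involved markers span ≥ 30% of each LG's length — artefactual
repulsion tends to involve isolated marker pairs, genuine preferential
pairing involves whole homologues. Both acceptance parameters are
exposed on the API and CLI; the quantification of "large parts of the
LG" as (3 pairs, 30%) is this package's choice. At ploidy 8 a fully
polysomic genome leaves only weak repulsion signal (joint absence
15/70 ≈ 0.214 against 0.25 under independence), far below LOD 5 at
n = 227; at ploidy 4 that residual signal is strong enough to clear
LOD 5 even under random pairing, so repulsion-based pairing inference
is only meaningful at higher ploidies — the test suite encodes the
octoploid control.

The difference ratio between a HG's most marker-dense LG and another
member LG is Σ|LGmax_k − LGi_k| / (LGmax + LGi) over shared marker
intervals, where shared markers are locus families with exactly one
mapped allele on each LG (homologous LGs never share an SD marker
itself) and intervals run between consecutive shared markers in
reference order. The compared LG is flipped when its shared markers
run backwards overall; intervals still conflicting after that are
skipped and counted. Values are kept at full precision internally and
rounded to one decimal only in reports. The per-HG pairing summary
reports LGs in accepted repulsion (percentage over all member LGs) and
the mean difference ratio, plus a cross-HG least-squares R² between the
two once at least three HGs carry both statistics.

## The simulator

The generator emulates the study design the pipeline is built for: a
cross between an aneu-polyploid informative parent and a second parent
contributing no segregating alleles, n = 227 progeny, dominant markers
scored present/absent.

* **Genome.** 8 HGs with 13–23 homologues each (defaults
  17, 23, 20, 18, 13, 18, 16, 22, mirroring observed per-HG LG counts);
  100 cM homologues with evenly spaced marker grids; dosage mixture
  (0.78, 0.16, 0.06) for SD/DD/TD, matching the dominant-marker mix
  reported for such crosses. Anchor families (SSR/SNP-like) place SD
  alleles at a homologous position on several homologues,
  least-anchored homologues first so anchor evidence accumulates
  evenly; 20% of families also drop an allele into a second HG,
  emulating the multi-locus SSR rate observed in sugarcane.
* **Meiosis.** Within each HG homologues are partitioned into
  bivalents — uniformly at random (polysomy) or, with probability
  `pairing_preference`, within designated partner sets. With an odd
  homologue count one unpaired homologue is dropped at random per
  meiosis, so aneuploid HGs transmit slightly fewer copies, as in real
  aneu-polyploids. Crossovers per bivalent are Poisson(L/100) with
  uniform positions (no interference, consistent with Haldane
  distances); one chromatid per bivalent is transmitted. Under random
  pairing this model reproduces random chromosomal segregation exactly:
  the transmitted subset is uniform over all m/2-subsets, giving the
  C(m−k, m/2)/C(m, m/2) absence probabilities the classifier assumes
  (verified against the combinatorial oracle in the tests).
* **Segregation distortion.** A fraction (default 0.25) of homologues
  carries a hidden viability locus at a random position; the carrier
  strand is transmitted there with probability 0.5 + δ (default
  δ = 0.15). Linked markers skew with exponential decay away from the
  locus, and homologues paired against a carrier are correspondingly
  under-transmitted — yielding the "moderate, heterogeneous" distortion
  pattern real maps show, rather than a uniform bias.
* **Missingness.** A configurable fraction (default 0.33) of DArT
  markers is assayed only on the first 94 progeny, reproducing the
  framework/insertion two-stage design; random missingness (default
  0.03) is added on top.
* **Structural divergence.** `partner_set_divergence` shifts anchor
  positions per partner set (emulating two ancestral subgenomes), which
  is what makes difference ratios larger between subsets than within;
  it defaults to 0.
* **Reproducibility.** Every operation draws from an independent
  child stream of the master seed (CRC-keyed SeedSequence spawns), so a
  fixed seed reproduces the matrix bit-for-bit and stages are
  individually replayable.

### What the simulator does not model

Sequence-level variation, hybridisation intensities, genotyping error
(beyond missingness), crossover interference, double reduction,
translocated/fused chromosomes between ancestral genomes, and 3:1
markers from selfed designs. Passing recovery tests therefore show the
pipeline is correct under polysomic/disomic bivalent meiosis with
independent errors; they do not certify behaviour under structural
rearrangement or systematic genotyping artefacts.

## Problem sizes in tests and the acceptance script

Recovery suites use sizes chosen to make the statistical claims sharp
while staying cheap: 1,000 markers per dosage class at n = 227; 1,000
replicate populations for the r = 0.2 bias check (3 standard errors of
the mean ≈ 0.0025); 60 replicates of an 8-HG × 4-homologue genome with
fully scored 10-marker homologues for LG-count recovery (the published
panel-restriction default can open framework gaps beyond the LOD-10
linkage range, ~27 cM at n = 227, which is correct behaviour but
outside the stated spacing condition); and a full aneuploid 8-HG
genome with ≥ 3 anchor families per homologue for HG recovery.

## Known limitations

* Ordering is heuristic (SARF local search); it matches exhaustive
  search on small groups but carries no global guarantee for large LGs
  — the same trade-off every seriation-based mapper makes.
* The repulsion acceptance rule's parameters (3 pairs, 30% span) are
  pragmatic; very short LGs (2 markers) trivially span 100% and rely on
  the support count alone.
* Difference ratios depend on shared anchor density; with a single
  shared interval the statistic is symmetric in its arguments and
  carries little information, so records report k alongside the ratio.
* HG percentages in repulsion use the HG's full LG count as the
  denominator; published tables computed by other conventions can
  differ slightly.
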