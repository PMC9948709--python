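# Methods

This note documents the models, rules and numerical choices behind
`mehg-guild`, and what its synthetic benchmarks do and do not demonstrate.

## Marker screening

Candidate marker proteins are found with an additive position-specific
log-odds profile per family (HgcA, HgcB, MerB, MerA, MerP, MerT, MerR).
The profile is built from a reference alignment with pseudocount 0.5 per
residue against a uniform background (1/20 per residue); a protein's score
is its best ungapped window of the profile's length. The score threshold is
calibrated from the reference set itself: the minimum reference self-score
minus a stringency margin. Two tiers are exposed — stringent
(`margin = 4.0`, applied to hgcA) and permissive (`margin = 8.0`, applied to
everything else) — mirroring the two-tier stringency of HMM screening
pipelines, where the first-pass marker is held to a much harder cutoff than
the companion genes screened afterwards. The margins are in log-odds units:
4.0 comfortably absorbs a single residue substitution (which costs ~2.8
units at a conserved column under these pseudocounts) while rejecting
shuffled sequences, whose expected score sits hundreds of units lower for
alignment lengths ≥ 90.

Profile scores only nominate candidates; the calls that matter are gated on
the conserved features that define each family:

- **hgcA**: the cap-helix motif `G(I/V)NVWCA(A/G)` must occur verbatim.
- **hgcB**: at least two non-overlapping `CX2CX2CX3C` ferredoxin motifs.
- **merB**: the candidate is globally aligned to a numbering reference
  (BLOSUM62, gap open −11, extend −1) and must place cysteine at the
  columns aligned to reference positions 96 and 159; a gap over either
  column fails with reason "gapped". The aligned-position tolerance is
  zero — the conserved positions are exact.

merA/merP/merT/merR carry no positional gate and are called on score alone.
A MAG is a putative MeHg producer iff it has ≥1 hgcA call and ≥1 hgcB call
anywhere in the genome (the pair is jointly required for methylation but
need not be contiguous), and a putative degrader iff it has ≥1 merB call;
both can hold at once. Genome-quality tiers use strict inequalities:
good-quality = completeness > 75% and contamination < 10%; high-quality =
> 90% and < 5%.

The bundled reference families are synthetic: deterministic pseudo-random
protein families built around exactly the conserved features above
(~92% column conservation elsewhere). They make the screening rules fully
testable and self-contained; swapping in curated reference alignments is a
one-argument change to `Profile.build` / `check_merb_cysteines`.

## Guild rules

Sulfate-reducing bacteria (SRB): all six core genes present (aprA, aprB,
sat, dsrA, dsrB, dsrD), dsrAB typed *reductive*, and none of
dsrE/dsrF/dsrH (which mark oxidative use of the dsr machinery). An
equivocal dsrAB typing ("untyped") does not qualify — ambiguity is
surfaced, not guessed. Iron-reducing bacteria (IRB): omcF **or** omcS
present. The OR reading is the default because omcF-only genomes behave as
iron-reduction-capable in practice; a strict AND is available via
`require_both=True`. dsrAB typing assigns the label of the best-scoring
labelled reference under global alignment and records the margin to the
second-best type; simulation shows queries 10% diverged from a reference
type correctly as long as the types are ≥30% divergent from each other.

Per-lineage gene-repertoire percentages count a MAG as carrying a gene
group only when **all** genes of the group are present (multi-gene pathways
such as nifHDK+nifNEX count as a unit) and report
`100 × carriers / lineage size` to 2 decimals.

## Abundance

A MAG's coverage in a sample is the length-weighted mean of its scaffold
coverages, `Σ(lengthᵢ·covᵢ)/Σ lengthᵢ`; its relative abundance divides that
by the summed coverage of all MAGs in the sample — i.e. abundance is
relative to the binned fraction of the community, not the whole metagenome,
because that is what the coverage table describes. Occurrence is strict
positivity with a numerical floor of 1e−12 treated as zero. Taxon-by-site
aggregates sum member MAGs per sample and average over each site's samples.
MeHg/THg fractions convert ng/kg MeHg against µg/kg THg
(`100·(MeHg/1000)/THg`); a zero THg yields a missing value. Read-mapping
parameters are upstream provenance, not computed here.

## HGT counting

Both trees are rooted and leaf-labelled by genome, with a leaf→taxon map
(phylum, or class within Proteobacteria). The species tree must have every
taxon monophyletic, else the pair is rejected. In the gene tree each taxon
forms one or more maximal same-taxon clades ("clusters"); same-taxon
children of a mixed polytomy are merged into a single cluster rather than
counted apart (conservative treatment of unresolved nodes).

The event count is the **minimum number of clusters that must be pruned to
restore taxon monophyly**, with candidates restricted to clusters of
currently non-monophyletic taxa; each pruned cluster is one independent
acquisition attributed to its taxon, and a transferred multi-leaf clade
counts as one event. Two edge cases motivate this definition over naive
excess-cluster counting: a leaf transplanted *into* a host clade also
splits the host into two clusters (naive counting would charge the host an
event), and a leaf grafted *at the boundary* of an adjacent clade could be
"resolved" most cheaply by deleting the host clade wholesale (attributing
the event to the wrong taxon). Minimal pruning over non-monophyletic taxa
counts every single transplant as exactly one event, attributed to the
donor — verified exhaustively over all single-leaf transplants of a 9-leaf,
3-taxon tree.

The minimum is found by iterative-deepening search with the greedy pruning
sequence (remove the cluster whose removal most reduces the total cluster
count) as depth cap and fallback; the exact search is used up to 200 leaves,
which covers marker-gene trees at the scale this package targets. Rooting
is the caller's responsibility (an outgroup-rerooting utility is provided);
no bootstrap filtering is applied.

## Attribution chain

All variables enter on the log10 scale; raw zeros (e.g. absent lineages)
are offset by half the smallest positive value in their column and flagged.
The chain is:

1. **Pearson screen.** Product-moment r against log10(MeHg); two-sided p
   from the t transform with n−2 df; retain p < α (default 0.05).
   Zero-variance columns are skipped with a warning.
2. **Best-subsets OLS under AIC.** Every non-empty subset of the retained
   factors (exhaustive, capped at 15) is fitted; the score is the
   profile-Gaussian `AIC = n ln(RSS/n) + 2(k+1)` (the error variance counts
   as a parameter; constant offsets cancel in comparisons). AICc is
   available by flag. Ties break toward fewer predictors, and an RSS below
   `1e−12 × TSS` is treated as an exact fit so that all supersets of a
   perfectly fitting subset tie and the tie-break decides — without this
   floor, rounding-level RSS differences between exact fits would be
   amplified by the logarithm into arbitrary selections. Rank-deficient
   subsets are skipped with a note.
3. **Johnson relative weights.** Computed on the correlation scale:
   `Λ = R_xx^{1/2}` (via eigendecomposition), `β = Λ⁻¹ r_xy`, and weight
   `εⱼ = Σₖ Λⱼₖ² βₖ²`. The weights sum to R² exactly and are invariant to
   affine rescaling of predictors; shares are reported as `100·εⱼ/R²`.
4. **Variance partitioning.** Ezekiel-adjusted R² of the microbial set, the
   environmental set and their union give `unique₁ = adjR²(∪) − adjR²(2)`,
   `unique₂` symmetrically, `shared = adjR²(1) + adjR²(2) − adjR²(∪)`,
   `unexplained = 1 − adjR²(∪)`. Negative fractions (possible with
   adjusted R²) are reported as-is with a flag, never truncated.

`MehgAttribution.fit()` runs the four stages and returns a results object;
stage-level failures (e.g. an empty factor set at the partition step) are
recorded in `results.errors` while earlier stages remain available. THg may
be offered as a candidate predictor but is off by default.

A note on selection consistency: with one redundant screened candidate, the
probability that AIC admits it is scale-free in the noise level (roughly
15–25% at n = 20 for any σ > 0 — the classic AIC overfit rate), so exact
recovery of the generating subset is a noiseless-limit property; the
benchmark exercises it at σ = 0 where the tie-break logic decides. At
realistic noise the selected subset is near-optimal in AIC but not always
the generating one, which is expected behaviour of best-subsets AIC, not a
defect.

## Synthetic-data generators

All generators are deterministic in their seed (identical seeds give
byte-identical artifacts) and expose the planted truth for closed-loop
tests.

- **Proteomes.** Background proteins are uniform-random over the 20-letter
  alphabet, length 150–500 — only the motif/profile contrast matters for
  the screening rules, not compositional realism. Planted markers are
  reference-family members with random flanks; decoys are the same with one
  mandatory motif residue broken (`GLNVWCAA` for HgcA, a lost leading
  cysteine for HgcB, Cys96→Ala for MerB) — the hardest near-miss, scoring
  within one substitution of a true family member but failing the gate.
- **Gene content.** SRB-labelled MAGs satisfy the six-present/three-absent
  rule exactly; non-SRB MAGs violate it in a seeded random way (a missing
  core gene or a planted dsrE/F/H); IRB MAGs carry omcF and/or omcS.
- **Coverage.** Per (MAG, sample) abundance weights are lognormal(0, 1)
  with 15% structural zeros (every sample keeps ≥1 MAG); scaffold counts
  default to 50/MAG with lognormal length (~20 kb median, ≥2 kb) and
  mean-preserving lognormal coverage noise (σ = 0.3). At these settings the
  recovered abundances correlate with truth at r > 0.99.
- **Sites.** `log10(MeHg) = β₀ + Σβⱼxⱼ + ε`, ε ~ N(0, σ²), with defaults
  n = 20 sites (the study scale), β = (0.5, 0.3, −0.4, 0.4, 0.3) over
  (Deltaproteobacteria-like producers, Firmicutes-like producers,
  Acidithiobacillia-like degraders, TC, Fe²⁺/Fe³⁺) and σ = 0.3. The five
  predictors share one latent site-condition axis with sign-matched
  loadings (producers, carbon and the redox ratio rise together across
  sites while degraders decline), giving marginal correlations of
  |r| ≈ 0.65–0.76 with the response — without this inter-factor structure,
  the weaker factors would be marginally unscreenable at n = 20 no matter
  how small σ is, which contradicts how such factor sets behave in field
  data. The population R² of the full model at σ = 0.3 is ≈ 0.8.
- **Tree pairs.** Species trees have random binary topology with each taxon
  monophyletic; transfers prune one leaf (never reducing a taxon below one
  un-moved leaf, never reusing a moved leaf) and regraft it as sister to an
  un-moved leaf of a foreign taxon. Each planted move therefore creates one
  recoverable discordant cluster; the counter recovers the planted number
  in ≥95% of pairs over transfer levels 0–4 (nested moves can in principle
  interact, hence the tolerance).

## What the synthetic benchmarks do not show

The generators probe the rules, not biology: uniform-composition proteins
carry no real phylogenetic or compositional signal, the profile/motif
contrast is planted rather than evolved, tree pairs contain clean
transplants rather than duplication/loss noise, and the site model is
exactly log-linear. Passing benchmarks demonstrates that the
implementation computes the stated quantities correctly and recovers
planted truth under the stated conditions — not that the screening
thresholds or the regression model are well-calibrated for any particular
real metagenome. Applying the package to real data requires curated
reference alignments, upstream gene prediction, read mapping and tree
inference, all of which are deliberately out of scope.

## Problem sizes used in the benchmarks

Fixture tallies use the published breakdowns (46 producers, 93 degraders
split 81 over lineages). Marker benchmarks scan 140 MAGs (~1,470 proteins,
420 decoys). The SRB rule is checked against all 512 gene combinations.
Transfer recovery uses 3 taxa × 4 leaves over 20 seeds × 5 levels.
Calibration checks use 1,000 null simulations (screen type-I), 200
noiseless selections (best-subsets), and 20-site attribution runs — sizes
chosen to give stable rates while keeping the whole suite fast on one CPU.
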