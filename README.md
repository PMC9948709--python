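# mehg-guild

Genome-resolved accounting of microbial methylmercury (MeHg) producers and
degraders, built for acid-mine-drainage (AMD) sediment metagenomes and fully
exercisable on synthetic data with known ground truth.

Methylmercury is a potent neurotoxin whose environmental accumulation is set
by the balance between microbial methylation and demethylation. Producers
carry the gene pair *hgcA*/*hgcB* (a corrinoid methyl-carrier plus a
2[4Fe-4S] ferredoxin); degraders carry *merB* (organomercury lyase, which
cleaves MeHg) usually alongside *merA* (mercuric reductase). This package
takes the standard genome-resolved inputs — per-MAG protein FASTAs, gene
annotation tables, scaffold coverage tables, taxon-labelled gene/species
trees, and site chemistry — and computes:

- **Marker screening** (`mehg_guild.markers`): candidate HgcA/HgcB/MerB/MerA
  and mer-operon accessory proteins by position-specific log-odds profile
  score, gated on the conserved features of each family — the HgcA cap-helix
  motif `G(I/V)NVWCA(A/G)`, two non-overlapping `CX2CX2CX3C` motifs in HgcB,
  and cysteines at the residues aligned to MerB reference positions 96/159.
  A MAG is a putative producer iff it carries both hgcA and hgcB (adjacency
  not required), a putative degrader iff it carries merB.
- **Guild rules** (`mehg_guild.guilds`): sulfate reducers by the six-core
  rule (aprA, aprB, sat, reductive dsrA/dsrB, dsrD present; dsrE/dsrF/dsrH
  absent), iron reducers by omcF/omcS, dsrAB reductive/oxidative typing by
  nearest labelled reference, and per-lineage gene-repertoire percentages.
- **Abundance** (`mehg_guild.abundance`): length-weighted scaffold coverage
  per MAG, relative abundance normalised to the binned community per sample,
  occurrence frequencies, taxon-by-site aggregates, MeHg/THg fractions.
- **HGT counting** (`mehg_guild.hgt`): independent horizontal-transfer
  events of a marker gene per taxon, defined as the minimum number of
  same-taxon clades that must be pruned from the gene tree to restore the
  species tree's taxon monophyly.
- **Attribution** (`mehg_guild.attribution`): a statsmodels-style model of
  site-level MeHg accumulation. `MehgAttribution(...).fit()` runs a Pearson
  screen (two-sided t test, n−2 df), exhaustive best-subsets OLS under
  `AIC = n ln(RSS/n) + 2(k+1)`, Johnson relative weights (an SVD-based
  decomposition of R² into per-predictor shares), and two-set variance
  partitioning on adjusted R² (unique microbial, unique environmental,
  shared, unexplained), all on log10-transformed data.
- **Synthetic data** (`mehg_guild.synthdata`): generators for proteomes with
  planted markers and single-residue decoys, guild-labelled gene tables,
  lognormal coverage tables, log-linear site tables, and tree pairs with a
  known number of planted cross-taxon transfers — every downstream result is
  checkable against planted truth.

## Worked example

Plant one MAG per role (producer / degrader / both / neither) with a decoy
motif in every genome, scan, and assign roles:

```python
from mehg_guild import assign_roles, default_profiles, scan_mag
from mehg_guild import synthdata as sd

spec = sd.PlantingSpec(roles=["producer", "degrader", "both", "neither"],
                       decoy_rate=1.0, seed=1)
proteomes, truth = sd.generate_proteomes(spec)
profiles = default_profiles()
calls = {m: scan_mag(recs, profiles, mag_id=m) for m, recs in proteomes.items()}
for role in assign_roles(calls):
    print(role)
```

```
RoleAssignment(mag_id='MAG001', is_producer=True, is_degrader=False)
RoleAssignment(mag_id='MAG002', is_producer=False, is_degrader=True)
RoleAssignment(mag_id='MAG003', is_producer=True, is_degrader=True)
RoleAssignment(mag_id='MAG004', is_producer=False, is_degrader=False)
```

Every planted marker is recovered, every decoy (e.g. `GLNVWCAA`, one residue
off the cap-helix motif) is rejected by the motif gate, and MAG003 shows the
dual producer/degrader genotype.

Attribute site-level MeHg to microbial and abiotic factors on a generated
20-site table:

```python
from mehg_guild import MehgAttribution
sites, beta = sd.generate_sites(sd.SiteModelSpec(seed=3))
fit = MehgAttribution(sites,
                      microbial=list(sd.SITE_FACTORS[:3]),
                      environmental=["TC", "Fe2_Fe3"]).fit()
print(fit.summary())
```

```
MeHg attribution results
========================================
sites: 20   alpha: 0.05   criterion: AIC

Pearson screen (vs log10_MeHg):
                     factor       r       p  retained
            delta_producers  0.7740  0.0001      True
       firmicutes_producers  0.7668  0.0001      True
acidithiobacillia_degraders -0.8393  0.0000      True
                         TC  0.6586  0.0016      True
                    Fe2_Fe3  0.8258  0.0000      True

selected subset: delta_producers, firmicutes_producers, acidithiobacillia_degraders, Fe2_Fe3
model R^2: 0.899  (adjusted: 0.871)

relative weights (share of explained variance):
                     factor  weight  share_pct
            delta_producers  0.2000    22.2570
       firmicutes_producers  0.2000    22.2582
acidithiobacillia_degraders  0.2720    30.2686
                    Fe2_Fe3  0.2266    25.2162

variance partition (adjusted R^2 scale):
  unique microbial:       0.207
  unique environmental:   0.022
  shared:                 0.642
  unexplained:            0.129
```

All five generated factors pass the screen with correlation signs matching
their generating coefficients (producers and the abiotic factors positive,
degraders negative); best-subsets keeps four of them; the relative weights
sum exactly to the model R² (0.899); and the partition splits the adjusted
R² into unique and shared contributions of the microbial vs environmental
sets.

A full pipeline run (`mehg-guild run --out rundir --seed 1`, or
`mehg_guild.run_pipeline`) simulates all inputs, executes every stage, and
writes the intermediate tables (`calls.tsv`, `roles.tsv`, `guilds.tsv`,
`abundance.tsv`, `hgt.tsv`, `attribution.json`, `tally.json`) plus a
structured provenance log; reruns with the same seed are byte-identical.

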