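"""Synthetic inputs with known ground truth for every pipeline stage.

Five generators emulate the pipeline's inputs so the whole analysis is
testable without any download:

* :func:`generate_proteomes` — per-MAG protein FASTA sets with marker
  proteins planted according to a producer/degrader role plan, plus
  near-miss decoys (single mandatory-residue breakages of each motif);
* :func:`generate_gene_content` — presence/absence gene tables with known
  SRB/IRB guild labels;
* :func:`generate_coverage` — scaffold coverage tables drawn around known
  MAG relative abundances (lognormal scaffold noise, sparse zeros);
* :func:`generate_sites` — site tables whose log10(MeHg) follows a stated
  log-linear model of microbial and abiotic predictors;
* :func:`generate_tree_pair` — species/gene tree pairs with a known number
  of planted cross-taxon transfers.

All generators are deterministic in their seed: identical seeds produce
byte-identical artifacts.  Background proteins use near-uniform residue
frequencies and lengths of 150-500; only the motif/profile contrast matters
for the screening rules, not sequence realism.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .references import (
    HGCA_MOTIF_START,
    HGCB_MOTIF_STARTS,
    MERB_CYS_POSITIONS,
    AA_ALPHABET,
    reference_alignment,
)

ROLES = ("producer", "degrader", "both", "neither")

#: the five generating factors of the site model: producer abundance of a
#: Deltaproteobacteria-like and a Firmicutes-like lineage, degrader abundance
#: of an Acidithiobacillia-like lineage, total carbon, and the Fe2+/Fe3+
#: redox ratio (all on log10 scale)
SITE_FACTORS = (
    "delta_producers",
    "firmicutes_producers",
    "acidithiobacillia_degraders",
    "TC",
    "Fe2_Fe3",
)

#: default generating coefficients on the log10 scale
DEFAULT_BETA = (0.5, 0.3, -0.4, 0.4, 0.3)


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------


@dataclass
class PlantingSpec:
    """Role plan for proteome generation.

    ``roles`` assigns each MAG exactly one of producer / degrader / both /
    neither; ``decoy_rate`` is the per-MAG, per-motif probability of planting
    a near-miss decoy (a single mandatory-residue substitution of the motif).
    """

    roles: list[str]
    decoy_rate: float = 0.0
    n_background: int = 30
    background: tuple[float, ...] | None = None
    seed: int = 0

    @property
    def n_mags(self) -> int:
        return len(self.roles)

    def validate(self) -> None:
        if self.n_mags == 0:
            raise ValueError("zero MAGs requested")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValueError("decoy_rate must be in [0, 1]")


def _background_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _planted_copy(rng: np.random.Generator, marker: str) -> str:
    """A marker protein: one reference family member with random flanks."""
    refs = reference_alignment(marker)
    core = refs[rng.integers(len(refs))]
    left = _background_protein(rng, int(rng.integers(10, 40)))
    right = _background_protein(rng, int(rng.integers(10, 40)))
    return left + core + right


_DECOY_BREAKS = {
    # marker -> (0-based position within the reference, replacement residue)
    "hgcA": (HGCA_MOTIF_START + 1, "L"),  # G[IV]NVWCA[AG] -> GLNVWCAA
    "hgcB": (HGCB_MOTIF_STARTS[0], "A"),  # first motif loses its leading Cys
    "merB": (MERB_CYS_POSITIONS[0] - 1, "A"),  # Cys96 -> Ala
}


def _decoy_copy(rng: np.random.Generator, marker: str) -> str:
    """A near-miss decoy: profile-passing copy with one broken motif residue."""
    refs = reference_alignment(marker)
    core = list(refs[rng.integers(len(refs))])
    pos, repl = _DECOY_BREAKS[marker]
    core[pos] = repl
    left = _background_protein(rng, int(rng.integers(10, 40)))
    right = _background_protein(rng, int(rng.integers(10, 40)))
    return left + "".join(core) + right


def generate_proteomes(
    spec: PlantingSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Generate per-MAG proteomes and the planting truth table.

    Producer-role MAGs receive one hgcA-family and one hgcB-family protein
    (motifs intact); degrader-role MAGs receive a merB-family protein (with
    both catalytic cysteines) and a merA-family protein; ``both`` receives
    all four.  Decoys are single mandatory-residue breakages of each gated
    motif, planted with probability ``decoy_rate`` per MAG and motif.

    Returns ``(proteomes, truth)`` where ``proteomes`` maps MAG id to
    ``(protein_id, sequence)`` pairs and ``truth`` lists every planted or
    decoy sequence (columns: mag, protein, marker, kind, role).  If
    ``out_dir`` is given, writes one FASTA per MAG (headers ``mag|protein``)
    and a sidecar ``truth.tsv``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    proteomes: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []
    for m, role in enumerate(spec.roles):
        mag_id = f"MAG{m + 1:03d}"
        counter = 0

        def next_id() -> str:
            nonlocal counter
            counter += 1
            return f"{mag_id}_{counter:05d}"

        records: list[tuple[str, str]] = []
        for _ in range(spec.n_background):
            length = int(rng.integers(150, 501))
            records.append((next_id(), _background_protein(rng, length)))
        planted = []
        if role in ("producer", "both"):
            planted += [("hgcA", _planted_copy(rng, "hgcA")), ("hgcB", _planted_copy(rng, "hgcB"))]
        if role in ("degrader", "both"):
            planted += [("merB", _planted_copy(rng, "merB")), ("merA", _planted_copy(rng, "merA"))]
        for marker, seq in planted:
            pid = next_id()
            records.append((pid, seq))
            truth_rows.append(dict(mag=mag_id, protein=pid, marker=marker, kind="planted", role=role))
        for marker in _DECOY_BREAKS:
            if rng.random() < spec.decoy_rate:
                pid = next_id()
                records.append((pid, _decoy_copy(rng, marker)))
                truth_rows.append(dict(mag=mag_id, protein=pid, marker=marker, kind="decoy", role=role))
        proteomes[mag_id] = records
    truth = pd.DataFrame(truth_rows, columns=["mag", "protein", "marker", "kind", "role"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for mag_id, records in proteomes.items():
            with open(out_dir / f"{mag_id}.faa", "w") as fh:
                for pid, seq in records:
                    fh.write(f">{mag_id}|{pid}\n")
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i : i + 60] + "\n")
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return proteomes, truth


# ---------------------------------------------------------------------------
# gene content
# ---------------------------------------------------------------------------

SRB_CORE = ("aprA", "aprB", "sat", "dsrA", "dsrB", "dsrD")
SRB_EXCLUDE = ("dsrE", "dsrF", "dsrH")
GENE_VOCABULARY = SRB_CORE + SRB_EXCLUDE + (
    "omcF", "omcS",
    "merA", "merB", "merP", "merT", "merR",
    "nifH", "nifD", "nifK", "nifN", "nifE", "nifX",
    "copA", "czcA", "arsB",
    # methanol dehydrogenase (non-merB demethylation): annotation-table
    # lookup only, never profile-scanned
    "xoxF", "mxaF",
)


def generate_gene_content(
    guild_plan: dict[str, str],
    accessories: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene presence/absence table honouring a guild plan.

    ``guild_plan`` maps MAG id to ``"SRB"``, ``"IRB"`` or ``"neither"``.
    SRB MAGs carry the six core sulfate-reduction genes (aprA aprB sat dsrA
    dsrB dsrD, dsrAB typed reductive) and none of dsrE/dsrF/dsrH; non-SRB
    MAGs violate the rule in a seeded random way (a missing core gene or a
    planted dsrE/dsrF/dsrH); IRB MAGs carry omcF and/or omcS.  ``accessories``
    optionally adds further genes (mer operon, nif, metal resistance) per MAG.

    Returns ``(table, labels)``: a boolean MAG x gene table with a
    ``dsrAB_type`` column, and the guild truth labels.
    """
    rng = np.random.default_rng(seed)
    accessories = accessories or {}
    rows = {}
    dsr_type = {}
    labels = {}
    for mag_id, guild in guild_plan.items():
        if guild not in ("SRB", "IRB", "neither"):
            raise ValueError(f"unknown guild {guild!r} for {mag_id}")
        present: set[str] = set()
        if guild == "SRB":
            present |= set(SRB_CORE)
            dsr_type[mag_id] = "reductive"
        elif guild == "IRB":
            present.add("omcF" if rng.random() < 0.5 else "omcS")
            if rng.random() < 0.3:
                present |= {"omcF", "omcS"}
            dsr_type[mag_id] = "absent"
        if guild != "SRB":
            # carry a perturbed sulfate-reduction repertoire that fails the rule
            present |= set(SRB_CORE)
            if rng.random() < 0.5:
                present.discard(SRB_CORE[rng.integers(len(SRB_CORE))])
            else:
                present.add(SRB_EXCLUDE[rng.integers(len(SRB_EXCLUDE))])
            dsr_type.setdefault(
                mag_id, "reductive" if {"dsrA", "dsrB"} <= present else "absent"
            )
        present |= set(accessories.get(mag_id, []))
        rows[mag_id] = {g: g in present for g in GENE_VOCABULARY}
        labels[mag_id] = guild
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(GENE_VOCABULARY))
    table["dsrAB_type"] = pd.Series(dsr_type)
    return table, pd.Series(labels, name="guild")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def generate_coverage(
    n_mags: int,
    n_samples: int,
    seed: int = 0,
    scaffolds_per_mag: int = 50,
    absence_rate: float = 0.15,
    depth_scale: float = 100.0,
    noise_sigma: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scaffold coverage tables around known MAG relative abundances.

    Per (MAG, sample) an abundance weight is drawn lognormal and zeroed with
    probability ``absence_rate`` (at least one MAG stays present per sample);
    scaffold coverages are the MAG's depth perturbed by lognormal noise, so
    occurrence frequencies fall below 1 for some MAGs.  Returns the coverage
    table (sample, mag, scaffold, length_bp, coverage) and the true relative
    abundance matrix (MAG x sample).
    """
    if n_mags < 1 or n_samples < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    mags = [f"MAG{i + 1:03d}" for i in range(n_mags)]
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=(n_mags, n_samples))
    present = rng.random((n_mags, n_samples)) >= absence_rate
    for j in range(n_samples):  # keep every sample non-empty
        if not present[:, j].any():
            present[rng.integers(n_mags), j] = True
    weights = weights * present
    truth = weights / weights.sum(axis=0, keepdims=True)
    lengths = {
        mag: np.maximum(
            rng.lognormal(mean=np.log(2e4), sigma=0.5, size=scaffolds_per_mag), 2000
        ).astype(int)
        for mag in mags
    }
    rows = []
    for j, sample in enumerate(samples):
        for i, mag in enumerate(mags):
            depth = weights[i, j] * depth_scale
            noise = rng.lognormal(mean=-(noise_sigma**2) / 2, sigma=noise_sigma,
                                  size=scaffolds_per_mag)
            covs = depth * noise if depth > 0 else np.zeros(scaffolds_per_mag)
            for k in range(scaffolds_per_mag):
                rows.append(
                    dict(
                        sample=sample,
                        mag=mag,
                        scaffold=f"{mag}_sc{k + 1:04d}",
                        length_bp=int(lengths[mag][k]),
                        coverage=float(covs[k]),
                    )
                )
    table = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth, index=mags, columns=samples)
    return table, truth_df


# ---------------------------------------------------------------------------
# sites
# ---------------------------------------------------------------------------


@dataclass
class SiteModelSpec:
    """Log-linear generating model for site-level MeHg.

    ``log10(MeHg) = beta0 + X beta + eps`` with ``eps ~ N(0, sigma^2)``;
    predictors default to the five retained factors (two producer lineages,
    one degrader lineage, TC, Fe2+/Fe3+), all on log10 scale.
    """

    beta: tuple[float, ...] = DEFAULT_BETA
    beta0: float = 1.5
    sigma: float = 0.3
    n_sites: int = 20
    samples_per_site: int = 4
    factors: tuple[str, ...] = SITE_FACTORS
    seed: int = 0

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if len(self.beta) != len(self.factors):
            raise ValueError("beta length must match number of factors")
        if self.n_sites < 1:
            raise ValueError("need at least one site")


def generate_sites(
    spec: SiteModelSpec, predictors: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Site table with MeHg generated from the stated log-linear model.

    ``predictors`` (sites x factors, log10 scale) may be supplied — e.g. from
    aggregated abundances — or are drawn here: lineage abundances lognormal
    around ~1% relative abundance, TC and Fe2+/Fe3+ around field-typical
    values.  Returns the site table (site, log10 predictors, log10_MeHg,
    MeHg_ng_kg) and the generating coefficients (incl. intercept) for
    recovery tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sites = [f"SITE{i + 1:02d}" for i in range(spec.n_sites)]
    if predictors is None:
        # predictors share a latent site-condition axis (the redox /
        # productivity gradient along which producer lineages, carbon and
        # Fe2+/Fe3+ rise together while degraders decline), giving the
        # inter-factor correlations seen in field data; unnamed extra
        # factors are independent noise
        latent = rng.normal(0.0, 1.0, spec.n_sites)
        plan = {
            "delta_producers": (-2.0, 0.35, 0.35),
            "firmicutes_producers": (-2.0, 0.35, 0.35),
            "acidithiobacillia_degraders": (-2.0, -0.35, 0.35),
            "TC": (0.7, 0.2, 0.2),
            "Fe2_Fe3": (0.0, 0.25, 0.25),
        }
        cols = {}
        for name in spec.factors:
            mean, load, unique = plan.get(name, (0.0, 0.0, 0.3))
            cols[name] = mean + load * latent + unique * rng.normal(
                0.0, 1.0, spec.n_sites
            )
        predictors = pd.DataFrame(cols, index=sites)
    else:
        predictors = predictors.loc[:, list(spec.factors)].copy()
        predictors.index = sites[: len(predictors)]
    x = predictors.to_numpy(float)
    eps = rng.normal(0.0, spec.sigma, len(predictors)) if spec.sigma > 0 else 0.0
    log_mehg = spec.beta0 + x @ np.asarray(spec.beta) + eps
    table = predictors.copy()
    table.insert(0, "site", predictors.index)
    table["log10_MeHg"] = log_mehg
    table["MeHg_ng_kg"] = 10.0**log_mehg
    table = table.reset_index(drop=True)
    beta = pd.Series(
        [spec.beta0, *spec.beta], index=["intercept", *spec.factors], name="beta"
    )
    return table, beta


# ---------------------------------------------------------------------------
# tree pairs
# ---------------------------------------------------------------------------


@dataclass
class TransferSpec:
    """Plan for a species/gene tree pair with planted cross-taxon transfers."""

    n_taxa: int = 3
    leaves_per_taxon: int = 3
    n_transfers: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 1 or self.leaves_per_taxon < 1:
            raise ValueError("need at least one taxon and one leaf per taxon")
        if self.n_transfers > 0 and self.n_taxa < 2:
            raise ValueError("transfers require at least two taxa")
        if self.n_transfers > self.n_taxa * (self.leaves_per_taxon - 1):
            raise ValueError("n_transfers exceeds feasible moves")


@dataclass
class TreePair:
    """A taxon-labelled gene tree and species tree over the same genomes."""

    gene_tree: dendropy.Tree
    species_tree: dendropy.Tree
    taxon_map: dict[str, str]
    n_planted: int = 0

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.species_tree.write(path=str(out_dir / "species.nwk"), schema="newick")
        self.gene_tree.write(path=str(out_dir / "gene.nwk"), schema="newick")
        pd.DataFrame(
            sorted(self.taxon_map.items()), columns=["leaf", "taxon"]
        ).to_csv(out_dir / "taxa.tsv", sep="\t", index=False)


def _random_binary_join(
    rng: np.random.Generator, nodes: list[dendropy.Node]
) -> dendropy.Node:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    return nodes[0]


def generate_tree_pair(spec: TransferSpec) -> TreePair:
    """Species tree with monophyletic taxa + gene tree with planted transfers.

    Each transfer prunes one leaf from its home clade (never emptying it
    below two leaves, never reusing a moved leaf) and regrafts it as sister
    to an unmoved leaf of a different taxon, so each planted move produces
    one discordant cluster.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ns = dendropy.TaxonNamespace()
    taxon_map: dict[str, str] = {}
    species = dendropy.Tree(taxon_namespace=ns)
    clade_roots = []
    for t in range(spec.n_taxa):
        taxon_name = f"T{t + 1}"
        leaves = []
        for k in range(spec.leaves_per_taxon):
            label = f"{taxon_name}_g{k + 1}"
            taxon_map[label] = taxon_name
            taxon = ns.new_taxon(label)
            node = dendropy.Node(taxon=taxon)
            leaves.append(node)
        clade_roots.append(
            _random_binary_join(rng, leaves) if len(leaves) > 1 else leaves[0]
        )
    species.seed_node = (
        _random_binary_join(rng, clade_roots) if len(clade_roots) > 1 else clade_roots[0]
    )
    species.update_bipartitions(suppress_unifurcations=True)

    gene = dendropy.Tree(species)  # deep clone sharing the taxon namespace
    moved: set[str] = set()
    for _ in range(spec.n_transfers):
        unmoved_per_taxon: dict[str, int] = {}
        for label, taxon in taxon_map.items():
            if label not in moved:
                unmoved_per_taxon[taxon] = unmoved_per_taxon.get(taxon, 0) + 1
        donors = [
            leaf
            for leaf in gene.leaf_node_iter()
            if leaf.taxon.label not in moved
            and unmoved_per_taxon[taxon_map[leaf.taxon.label]] > 1
        ]
        if not donors:
            raise ValueError("no feasible transfer moves remain")
        donor = donors[rng.integers(len(donors))]
        donor_taxon = taxon_map[donor.taxon.label]
        recipients = [
            leaf
            for leaf in gene.leaf_node_iter()
            if taxon_map[leaf.taxon.label] != donor_taxon
            and leaf.taxon.label not in moved
        ]
        recipient = recipients[rng.integers(len(recipients))]
        _prune_leaf(gene, donor)
        _graft_as_sister(gene, donor, recipient)
        moved.add(donor.taxon.label)
    gene.update_bipartitions(suppress_unifurcations=True)
    return TreePair(gene_tree=gene, species_tree=species, taxon_map=taxon_map,
                    n_planted=spec.n_transfers)


def _prune_leaf(tree: dendropy.Tree, leaf: dendropy.Node) -> None:
    parent = leaf.parent_node
    parent.remove_child(leaf)
    if parent.num_child_nodes() == 1:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        if grand is None:
            tree.seed_node = only
            only.parent_node = None
        else:
            grand.remove_child(parent)
            grand.add_child(only)


def _graft_as_sister(tree: dendropy.Tree, mover: dendropy.Node,
                     sibling: dendropy.Node) -> None:
    parent = sibling.parent_node
    joint = dendropy.Node()
    if parent is None:
        tree.seed_node = joint
    else:
        parent.remove_child(sibling)
        parent.add_child(joint)
    joint.add_child(sibling)
    joint.add_child(mover)
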