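"""Horizontal-gene-transfer event counting from gene/species tree discordance.

A marker-gene tree is compared against the species tree over the same
genomes, with every leaf labelled by taxon (phylum, or class within
Proteobacteria).  The species tree must have each taxon monophyletic; in the
gene tree a taxon may fragment into several maximal same-taxon clades
("clusters").  Each branch conflicting with taxon monophyly marks an
independent acquisition, and the event count is the *minimum* number of
clusters that must be pruned from the gene tree to restore taxon monophyly;
each pruned cluster is one HGT event attributed to its taxon.  This
resolves the host-splitting ambiguity of naive excess-cluster counting: a
single leaf transplanted into the middle of a foreign clade splits the host
into two clusters, but one pruning (of the transplanted leaf) restores
monophyly, so exactly one event is counted, attributed to the donor taxon.

Polytomies are treated conservatively: same-taxon children of a mixed
multifurcation are merged into a single cluster rather than counted apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import dendropy
import pandas as pd

Nested = Union[str, tuple]


@dataclass
class Cluster:
    """One maximal same-taxon clade in a tree."""

    taxon: str
    leaves: frozenset
    sister_taxa: frozenset


@dataclass
class HgtReport:
    """Per-taxon HGT event counts plus the pruned discordant clades."""

    events: dict[str, int]
    total: int
    discordant: list[Cluster] = field(default_factory=list)
    gene_clusters: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(taxon=t, events=self.events.get(t, 0),
                 gene_clusters=self.gene_clusters.get(t, 0))
            for t in sorted(self.gene_clusters)
        ]
        return pd.DataFrame(rows, columns=["taxon", "events", "gene_clusters"])


# ---------------------------------------------------------------------------
# tree plumbing
# ---------------------------------------------------------------------------


def _to_nested(tree: dendropy.Tree) -> Nested:
    def convert(node: dendropy.Node) -> Nested:
        if node.is_leaf():
            return node.taxon.label
        return tuple(convert(c) for c in node.child_nodes())
    return convert(tree.seed_node)


def _leaves(node: Nested) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    out: set = set()
    for child in node:
        out |= _leaves(child)
    return frozenset(out)


def _prune(node: Nested, drop: frozenset) -> Nested | None:
    if isinstance(node, str):
        return None if node in drop else node
    kept = [c for c in (_prune(child, drop) for child in node) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return tuple(kept)


def _collect_clusters(
    node: Nested, taxon_map: Mapping[str, str], out: list[Cluster]
) -> tuple[frozenset, frozenset]:
    """Post-order cluster collection; returns (leaves, taxa) of ``node``."""
    if isinstance(node, str):
        try:
            return frozenset([node]), frozenset([taxon_map[node]])
        except KeyError:
            raise ValueError(f"leaf {node!r} has no taxon assignment") from None
    child_info = [_collect_clusters(c, taxon_map, out) for c in node]
    leaves = frozenset().union(*(lv for lv, _ in child_info))
    taxa = frozenset().union(*(tx for _, tx in child_info))
    if len(taxa) > 1:
        # group pure children by taxon; same-taxon children of a
        # multifurcation merge into one cluster (conservative polytomies)
        groups: dict[str, list[frozenset]] = {}
        other_taxa: dict[str, set] = {}
        for lv, tx in child_info:
            if len(tx) == 1:
                groups.setdefault(next(iter(tx)), []).append(lv)
        for taxon, lvs in groups.items():
            sisters = set()
            for lv, tx in child_info:
                if not (len(tx) == 1 and next(iter(tx)) == taxon):
                    sisters |= tx
            out.append(
                Cluster(
                    taxon=taxon,
                    leaves=frozenset().union(*lvs),
                    sister_taxa=frozenset(sisters),
                )
            )
    return leaves, taxa


def _clusters(nested: Nested, taxon_map: Mapping[str, str]) -> list[Cluster]:
    out: list[Cluster] = []
    leaves, taxa = _collect_clusters(nested, taxon_map, out)
    if len(taxa) == 1:
        out.append(
            Cluster(taxon=next(iter(taxa)), leaves=leaves, sister_taxa=frozenset())
        )
    return out


def taxon_clusters(
    tree: dendropy.Tree, taxon_map: Mapping[str, str]
) -> dict[str, int]:
    """Count maximal monophyletic same-taxon clades per taxon.

    A taxon with k > 1 clusters is non-monophyletic in ``tree``.
    """
    counts: dict[str, int] = {}
    for cluster in _clusters(_to_nested(tree), taxon_map):
        counts[cluster.taxon] = counts.get(cluster.taxon, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# event counting
# ---------------------------------------------------------------------------


def _sort_key(cluster: Cluster) -> tuple:
    return (len(cluster.leaves), tuple(sorted(cluster.leaves)))


def _is_concordant(clusters: list[Cluster]) -> bool:
    seen: set[str] = set()
    for c in clusters:
        if c.taxon in seen:
            return False
        seen.add(c.taxon)
    return True


def _prunable(clusters: list[Cluster], all_leaves: frozenset) -> list[Cluster]:
    """Prune candidates: clusters of currently non-monophyletic taxa only.

    A taxon already monophyletic needs no pruning, and removing its only
    cluster would delete the taxon wholesale (e.g. pruning a host clade to
    'resolve' a transplant grafted as its sister) — that would count the
    event against the wrong taxon.
    """
    counts: dict[str, int] = {}
    for c in clusters:
        counts[c.taxon] = counts.get(c.taxon, 0) + 1
    return [
        c for c in clusters if counts[c.taxon] > 1 and c.leaves != all_leaves
    ]


def _greedy_prunes(nested: Nested, taxon_map: Mapping[str, str]) -> list[Cluster]:
    """Greedy pruning sequence: at each step remove the cluster whose
    removal most reduces the total cluster count (upper bound on the
    minimum; used as fallback and as the search budget cap)."""
    pruned: list[Cluster] = []
    while True:
        clusters = _clusters(nested, taxon_map)
        if _is_concordant(clusters):
            return pruned
        all_leaves = _leaves(nested)
        best = None
        best_score = None
        for cand in sorted(_prunable(clusters, all_leaves), key=_sort_key):
            remaining = _prune(nested, cand.leaves)
            n_after = len(_clusters(remaining, taxon_map))
            score = (n_after, len(cand.leaves), tuple(sorted(cand.leaves)))
            if best_score is None or score < best_score:
                best, best_score = cand, score
        nested = _prune(nested, best.leaves)
        pruned.append(best)


def _min_prunes(
    nested: Nested, taxon_map: Mapping[str, str], budget_cap: int
) -> list[Cluster] | None:
    """Iterative-deepening search for a minimum pruning sequence.

    No useful per-prune lower bound exists (one prune can chain-merge many
    fragments of a host taxon), so deepening starts at 1; the greedy
    sequence length caps the search depth.
    """

    def search(node: Nested, budget: int, seen: set) -> list[Cluster] | None:
        clusters = _clusters(node, taxon_map)
        if _is_concordant(clusters):
            return []
        if budget <= 0:
            return None
        if (node, budget) in seen:
            return None
        seen.add((node, budget))
        all_leaves = _leaves(node)
        ranked = []
        for cand in _prunable(clusters, all_leaves):
            remaining = _prune(node, cand.leaves)
            n_after = len(_clusters(remaining, taxon_map))
            ranked.append((n_after, _sort_key(cand), cand, remaining))
        for _, _, cand, remaining in sorted(ranked, key=lambda t: (t[0], t[1])):
            sub = search(remaining, budget - 1, seen)
            if sub is not None:
                return [cand] + sub
        return None

    for budget in range(1, budget_cap + 1):
        result = search(nested, budget, set())
        if result is not None:
            return result
    return None


#: above this leaf count the exact search is skipped in favour of the greedy
EXACT_SEARCH_MAX_LEAVES = 200


def count_hgt_events(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    taxon_map: Mapping[str, str],
    method: str = "exact",
) -> HgtReport:
    """Count independent HGT events from gene/species tree discordance.

    The species tree must be taxon-monophyletic (one cluster per taxon),
    otherwise the pair is rejected with a diagnostic.  Events are the
    minimum number of same-taxon clusters whose pruning restores taxon
    monophyly in the gene tree (module docstring); each pruned cluster is
    one event attributed to its taxon.  ``method="exact"`` (default) finds
    the minimum by iterative-deepening search, falling back to the greedy
    sequence on trees above ~200 leaves; ``method="greedy"`` always uses
    the greedy sequence.
    """
    if method not in ("exact", "greedy"):
        raise ValueError("method must be 'exact' or 'greedy'")
    gene_leaves = {leaf.taxon.label for leaf in gene_tree.leaf_node_iter()}
    sp_leaves = {leaf.taxon.label for leaf in species_tree.leaf_node_iter()}
    if gene_leaves != sp_leaves:
        raise ValueError(
            "gene and species trees have different leaf sets: "
            f"{sorted(gene_leaves ^ sp_leaves)[:5]}"
        )
    sp_counts = taxon_clusters(species_tree, taxon_map)
    bad = {t: k for t, k in sp_counts.items() if k != 1}
    if bad:
        raise ValueError(f"taxa non-monophyletic in species tree: {bad}")

    nested = _to_nested(gene_tree)
    gene_counts: dict[str, int] = {}
    for cluster in _clusters(nested, taxon_map):
        gene_counts[cluster.taxon] = gene_counts.get(cluster.taxon, 0) + 1

    pruned = _greedy_prunes(nested, taxon_map)
    if method == "exact" and pruned and len(gene_leaves) <= EXACT_SEARCH_MAX_LEAVES:
        exact = _min_prunes(nested, taxon_map, budget_cap=len(pruned))
        if exact is not None:
            pruned = exact
    events: dict[str, int] = {t: 0 for t in gene_counts}
    for cluster in pruned:
        events[cluster.taxon] = events.get(cluster.taxon, 0) + 1
    return HgtReport(
        events=events,
        total=len(pruned),
        discordant=pruned,
        gene_clusters=gene_counts,
    )


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Leaf -> taxon map from a two-column TSV (leaf, taxon)."""
    frame = pd.read_csv(path, sep="\t")
    if not {"leaf", "taxon"} <= set(frame.columns):
        raise ValueError("taxon map TSV needs 'leaf' and 'taxon' columns")
    return dict(zip(frame["leaf"].astype(str), frame["taxon"].astype(str)))


def read_tree(path: str | Path,
              taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        taxon_namespace=taxon_namespace,
    )


def reroot_with_outgroup(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Reroot on the edge above the MRCA of the outgroup leaves.

    Rooting choice is otherwise the caller's responsibility — trees are
    consumed as pre-rooted.
    """
    taxa = [tree.taxon_namespace.get_taxon(lbl) for lbl in outgroup_labels]
    if any(t is None for t in taxa):
        raise ValueError("outgroup labels not found in tree")
    tree.is_rooted = True
    mrca = tree.mrca(taxa=taxa)
    tree.reroot_at_edge(mrca.edge, update_bipartitions=True)
    return tree
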