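"""Metabolic guild classification and lineage gene-repertoire percentages.

Sulfate-reducing bacteria (SRB) are recognised by a strict gene-set rule:
all six core genes (aprA, aprB, sat, reductive dsrA and dsrB, dsrD) must be
present and none of dsrE/dsrF/dsrH (which mark the reverse, oxidative use of
the dsr machinery).  Iron-reducing bacteria (IRB) are recognised by outer-
membrane cytochromes omcF/omcS.  dsrAB sequences are typed reductive or
oxidative by nearest labelled reference under global alignment.  Lineage
gene-repertoire percentages summarise, per taxonomic lineage, the share of
MAGs carrying a full gene group (e.g. the nitrogen-fixation set
nifHDK+nifNEX).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .references import dsrab_references

SRB_CORE = frozenset({"aprA", "aprB", "sat", "dsrA", "dsrB", "dsrD"})
SRB_EXCLUDE = frozenset({"dsrE", "dsrF", "dsrH"})
IRB_GENES = frozenset({"omcF", "omcS"})
MER_ACCESSORIES = ("merA", "merP", "merT", "merR")


@dataclass
class GeneContent:
    """Gene presence for one MAG plus its dsrAB type annotation."""

    mag_id: str
    genes: frozenset[str]
    dsrab_type: str = "absent"  # reductive | oxidative | absent | untyped

    def __post_init__(self):
        if self.dsrab_type not in ("reductive", "oxidative", "absent", "untyped"):
            raise ValueError(f"invalid dsrAB type {self.dsrab_type!r}")


@dataclass
class GuildLabel:
    mag_id: str
    is_srb: bool
    is_irb: bool
    mer_accessories: list[str] = field(default_factory=list)


def classify_srb(content: GeneContent) -> bool:
    """Six-core-present / three-absent SRB rule.

    True iff {aprA, aprB, sat, dsrA, dsrB, dsrD} are all present, the dsrAB
    type is reductive, and none of dsrE/dsrF/dsrH is present.  An equivocal
    ("untyped") dsrAB does not qualify.
    """
    return (
        SRB_CORE <= content.genes
        and content.dsrab_type == "reductive"
        and not (SRB_EXCLUDE & content.genes)
    )


def classify_irb(content: GeneContent, require_both: bool = False) -> bool:
    """IRB rule on omcF/omcS.

    Default is OR (omcF-only genomes count as iron-reduction capable);
    ``require_both=True`` switches to the stricter AND reading.
    """
    hits = IRB_GENES & content.genes
    return hits == IRB_GENES if require_both else bool(hits)


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def type_dsrab(
    sequence: str,
    references: Mapping[str, str | Sequence[str]] | None = None,
) -> tuple[str, float]:
    """Type a dsrAB sequence by its nearest labelled reference.

    ``references`` maps type labels (``reductive``/``oxidative``) to one or
    more reference sequences.  Returns ``(best type, margin)`` where margin
    is the alignment-score gap between the best and second-best type.
    """
    refs = references if references is not None else dsrab_references()
    if not refs:
        raise ValueError("empty reference set")
    aligner = _global_aligner()
    best: dict[str, float] = {}
    for label, seqs in refs.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        if not seqs:
            raise ValueError(f"no references for type {label!r}")
        best[label] = max(aligner.score(ref, sequence) for ref in seqs)
    ranked = sorted(best.items(), key=lambda kv: -kv[1])
    margin = ranked[0][1] - ranked[1][1] if len(ranked) > 1 else float("inf")
    return ranked[0][0], float(margin)


def mer_operon_profile(contents: Iterable[GeneContent]) -> pd.DataFrame:
    """Which mer-operon genes accompany merB in each merB-carrying MAG.

    Reports merA separately (the reductase completing the demethylation
    pathway) from the transport/regulatory accessories merP/merT/merR.
    """
    rows = []
    for content in contents:
        if "merB" not in content.genes:
            continue
        accessories = [g for g in ("merP", "merT", "merR") if g in content.genes]
        rows.append(
            dict(
                mag=content.mag_id,
                merA="merA" in content.genes,
                accessories=";".join(accessories) if accessories else "none",
            )
        )
    return pd.DataFrame(rows, columns=["mag", "merA", "accessories"])


def classify_guilds(
    contents: Iterable[GeneContent], require_both_irb: bool = False
) -> list[GuildLabel]:
    return [
        GuildLabel(
            mag_id=c.mag_id,
            is_srb=classify_srb(c),
            is_irb=classify_irb(c, require_both=require_both_irb),
            mer_accessories=[g for g in MER_ACCESSORIES if g in c.genes],
        )
        for c in contents
    ]


def contents_from_table(table: pd.DataFrame) -> list[GeneContent]:
    """Build :class:`GeneContent` records from a boolean MAG x gene table.

    An optional ``dsrAB_type`` column supplies the typing annotation;
    otherwise MAGs with dsrA+dsrB are marked ``untyped``.
    """
    contents = []
    gene_cols = [c for c in table.columns if c != "dsrAB_type"]
    for mag_id, row in table.iterrows():
        genes = frozenset(g for g in gene_cols if bool(row[g]))
        if "dsrAB_type" in table.columns and pd.notna(row.get("dsrAB_type")):
            dsr = str(row["dsrAB_type"])
        else:
            dsr = "untyped" if {"dsrA", "dsrB"} <= genes else "absent"
        contents.append(GeneContent(mag_id=str(mag_id), genes=genes, dsrab_type=dsr))
    return contents


def lineage_gene_percentage(
    table: pd.DataFrame,
    lineages: Mapping[str, str],
    gene_groups: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-lineage percentage of MAGs carrying *all* genes of each group.

    ``table`` is a boolean MAG x gene table, ``lineages`` maps each MAG to
    exactly one lineage, and each gene group is satisfied only when every
    member gene is present (multi-gene pathways count as a unit).  Values are
    rounded to 2 decimals; an empty lineage yields NaN.
    """
    missing = set(table.index) - set(lineages)
    if missing:
        raise ValueError(f"MAGs without lineage assignment: {sorted(missing)[:5]}")
    lineage_series = pd.Series({m: lineages[m] for m in table.index})
    out = {}
    for group_name, genes in gene_groups.items():
        genes = list(genes)
        absent = [g for g in genes if g not in table.columns]
        if absent:
            raise KeyError(f"genes not in table: {absent}")
        has_all = table[genes].all(axis=1)
        pct = has_all.groupby(lineage_series).mean() * 100.0
        out[group_name] = pct.round(2)
    result = pd.DataFrame(out)
    result.index.name = "lineage"
    return result
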