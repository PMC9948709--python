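"""End-to-end orchestration: simulate/scan/classify/count/attribute.

``run_pipeline`` executes the stages in order — marker scanning, guild
classification, abundance accounting, HGT counting, attribution — writing
every intermediate table under the run directory together with a structured
provenance log (one JSON line per stage event, no wall-clock fields so reruns
are byte-identical).  Stages with missing inputs are reported as skipped;
a stage failure halts the run with the stage name and cause while earlier
outputs are retained.

``tally_by_lineage`` produces the summary tallies: producer/degrader counts
per taxonomic lineage, where lineages are phyla except Proteobacteria, which
is split by class.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import abundance as abundance_mod
from . import attribution as attribution_mod
from . import guilds as guilds_mod
from . import hgt as hgt_mod
from . import markers as markers_mod
from . import synthdata

#: phyla whose members are tallied at class level instead
CLASS_SPLIT_PHYLA = ("Proteobacteria",)

_RANK_PREFIXES = {"d": "domain", "p": "phylum", "c": "class", "o": "order",
                  "f": "family", "g": "genus", "s": "species"}
_RANK_ORDER = ("domain", "phylum", "class", "order", "family", "genus", "species")


def parse_taxonomy(taxonomy: str) -> dict[str, str]:
    """Parse a ranked taxonomy string into a rank -> name map.

    Accepts GTDB-style prefixes (``d__Bacteria;p__Proteobacteria;...``) or a
    plain semicolon-separated list in conventional rank order.
    """
    ranks: dict[str, str] = {}
    parts = [p.strip() for p in taxonomy.split(";") if p.strip()]
    for i, part in enumerate(parts):
        if len(part) > 3 and part[1:3] == "__" and part[0] in _RANK_PREFIXES:
            name = part[3:]
            if name:
                ranks[_RANK_PREFIXES[part[0]]] = name
        elif i < len(_RANK_ORDER):
            ranks[_RANK_ORDER[i]] = part
    return ranks


def lineage_of(
    taxonomy: str, class_split: Sequence[str] = CLASS_SPLIT_PHYLA
) -> tuple[str, bool]:
    """Lineage label under the phylum-except-Proteobacteria convention.

    Returns ``(lineage, flagged)``; a MAG without a phylum is counted under
    ``"unclassified"`` and flagged.
    """
    ranks = parse_taxonomy(taxonomy)
    phylum = ranks.get("phylum")
    if not phylum:
        return "unclassified", True
    if phylum in class_split:
        return ranks.get("class", phylum), False
    return phylum, False


@dataclass
class SummaryTally:
    """Producer/degrader counts per lineage plus the role totals.

    ``producer_lineage_sum``/``degrader_lineage_sum`` restate the sum over
    lineages so that any discrepancy against the input totals surfaces
    instead of being silently reconciled.
    """

    producer_counts: dict[str, int]
    degrader_counts: dict[str, int]
    producer_total: int
    degrader_total: int
    dual_role: list[str]
    flagged_unclassified: list[str] = field(default_factory=list)

    @property
    def producer_lineage_sum(self) -> int:
        return sum(self.producer_counts.values())

    @property
    def degrader_lineage_sum(self) -> int:
        return sum(self.degrader_counts.values())

    def to_dict(self) -> dict:
        return dict(
            producer_counts=dict(sorted(self.producer_counts.items())),
            degrader_counts=dict(sorted(self.degrader_counts.items())),
            producer_total=self.producer_total,
            degrader_total=self.degrader_total,
            producer_lineage_sum=self.producer_lineage_sum,
            degrader_lineage_sum=self.degrader_lineage_sum,
            dual_role=self.dual_role,
            flagged_unclassified=self.flagged_unclassified,
        )


def tally_by_lineage(
    roles: Sequence[markers_mod.RoleAssignment],
    taxonomy: Mapping[str, str],
    class_split: Sequence[str] = CLASS_SPLIT_PHYLA,
) -> SummaryTally:
    """Tally producers and degraders per lineage (class within Proteobacteria)."""
    producer_counts: Counter = Counter()
    degrader_counts: Counter = Counter()
    dual = []
    flagged = []
    producer_total = 0
    degrader_total = 0
    for role in roles:
        lineage, was_flagged = lineage_of(taxonomy.get(role.mag_id, ""), class_split)
        if was_flagged:
            flagged.append(role.mag_id)
        if role.is_producer:
            producer_counts[lineage] += 1
            producer_total += 1
        if role.is_degrader:
            degrader_counts[lineage] += 1
            degrader_total += 1
        if role.is_producer and role.is_degrader:
            dual.append(role.mag_id)
    return SummaryTally(
        producer_counts=dict(producer_counts),
        degrader_counts=dict(degrader_counts),
        producer_total=producer_total,
        degrader_total=degrader_total,
        dual_role=sorted(dual),
        flagged_unclassified=sorted(set(flagged)),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_LINEAGE_CYCLE = (
    "d__Bacteria;p__Proteobacteria;c__Deltaproteobacteria",
    "d__Bacteria;p__Nitrospirae;c__Nitrospiria",
    "d__Bacteria;p__Firmicutes;c__Clostridia",
    "d__Bacteria;p__Proteobacteria;c__Acidithiobacillia",
    "d__Bacteria;p__Actinobacteria;c__Actinomycetia",
    "d__Bacteria;p__Chloroflexi;c__Anaerolineae",
    "d__Bacteria;p__Spirochaetes;c__Spirochaetia",
    "d__Bacteria;p__Elusimicrobia;c__Elusimicrobia",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: inputs, thresholds, seed."""

    out_dir: str
    seed: int = 0
    quality_tier: str = "good"
    alpha: float = 0.05
    criterion: str = "aic"
    margin_stringent: float = markers_mod.MARGIN_STRINGENT
    margin_permissive: float = markers_mod.MARGIN_PERMISSIVE
    # simulation block (used when simulate is true)
    simulate: bool = True
    n_mags: int = 20
    n_samples: int = 9
    n_sample_sites: int = 3
    n_model_sites: int = 20
    decoy_rate: float = 0.3
    n_taxa: int = 3
    leaves_per_taxon: int = 4
    n_transfers: int = 2
    # external inputs (used when simulate is false)
    proteome_dir: str | None = None
    gene_content_path: str | None = None
    coverage_path: str | None = None
    taxonomy_path: str | None = None
    site_map_path: str | None = None
    gene_tree_path: str | None = None
    species_tree_path: str | None = None
    taxa_path: str | None = None
    sites_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(log_path: Path, event: dict) -> None:
    with open(log_path, "a") as fh:
        fh.write(json.dumps(event, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a result bundle with per-stage status."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "provenance.jsonl"
    log_path.write_text("")
    _log(log_path, dict(event="start", version=__version__, seed=config.seed,
                        tier=config.quality_tier, alpha=config.alpha,
                        margins=[config.margin_stringent, config.margin_permissive]))
    config.to_yaml(out_dir / "config.yaml")
    result: dict = {"stages": {}, "truth": {}}

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        inputs = out_dir / "inputs"
        roles = [synthdata.ROLES[i % 4] for i in range(config.n_mags)]
        spec = synthdata.PlantingSpec(
            roles=roles, decoy_rate=config.decoy_rate, seed=config.seed
        )
        proteomes, proteome_truth = synthdata.generate_proteomes(spec, out_dir=inputs)
        guild_plan = {
            f"MAG{i + 1:03d}": ("SRB", "IRB", "neither", "neither")[i % 4]
            for i in range(config.n_mags)
        }
        accessories = {
            f"MAG{i + 1:03d}": ["merA", "merB", "merP"] if roles[i] in ("degrader", "both") else []
            for i in range(config.n_mags)
        }
        gene_content, guild_truth = synthdata.generate_gene_content(
            guild_plan, accessories=accessories, seed=config.seed + 1
        )
        gene_content.to_csv(inputs / "gene_content.tsv", sep="\t")
        coverage, abundance_truth = synthdata.generate_coverage(
            config.n_mags, config.n_samples, seed=config.seed + 2
        )
        coverage.to_csv(inputs / "coverage.tsv", sep="\t", index=False)
        taxonomy = {
            f"MAG{i + 1:03d}": _LINEAGE_CYCLE[i % len(_LINEAGE_CYCLE)]
            for i in range(config.n_mags)
        }
        pd.Series(taxonomy, name="taxonomy").rename_axis("mag").to_csv(
            inputs / "taxonomy.tsv", sep="\t"
        )
        site_map = {
            f"S{j + 1:03d}": f"SITE{(j % config.n_sample_sites) + 1:02d}"
            for j in range(config.n_samples)
        }
        pair = synthdata.generate_tree_pair(
            synthdata.TransferSpec(
                n_taxa=config.n_taxa,
                leaves_per_taxon=config.leaves_per_taxon,
                n_transfers=config.n_transfers,
                seed=config.seed + 3,
            )
        )
        pair.write(inputs / "trees")
        site_spec = synthdata.SiteModelSpec(n_sites=config.n_model_sites,
                                           seed=config.seed + 4)
        sites, beta_truth = synthdata.generate_sites(site_spec)
        sites.to_csv(inputs / "sites.tsv", sep="\t", index=False)
        result["truth"] = dict(
            proteomes=proteome_truth,
            guilds=guild_truth,
            abundance=abundance_truth,
            n_transfers=pair.n_planted,
            beta=beta_truth,
        )
        gene_tree, species_tree, taxon_map = pair.gene_tree, pair.species_tree, pair.taxon_map
    else:
        proteomes = None
        if config.proteome_dir:
            proteomes = {
                p.stem: None for p in sorted(Path(config.proteome_dir).glob("*.faa"))
            }
        gene_content = (
            pd.read_csv(config.gene_content_path, sep="\t", index_col=0)
            if config.gene_content_path
            else None
        )
        coverage = (
            pd.read_csv(config.coverage_path, sep="\t")
            if config.coverage_path
            else None
        )
        taxonomy = (
            pd.read_csv(config.taxonomy_path, sep="\t", index_col=0)["taxonomy"].to_dict()
            if config.taxonomy_path
            else {}
        )
        site_map = (
            pd.read_csv(config.site_map_path, sep="\t", index_col=0)["site"].to_dict()
            if config.site_map_path
            else None
        )
        if config.gene_tree_path and config.species_tree_path and config.taxa_path:
            import dendropy

            ns = dendropy.TaxonNamespace()
            gene_tree = hgt_mod.read_tree(config.gene_tree_path, ns)
            species_tree = hgt_mod.read_tree(config.species_tree_path, ns)
            taxon_map = hgt_mod.read_taxon_map(config.taxa_path)
        else:
            gene_tree = species_tree = taxon_map = None
        sites = (
            pd.read_csv(config.sites_path, sep="\t") if config.sites_path else None
        )

    # ---- markers ---------------------------------------------------------
    try:
        profiles = markers_mod.default_profiles()
        all_calls = []
        if config.simulate:
            for mag_id, records in proteomes.items():
                all_calls += markers_mod.scan_mag(
                    records, profiles, mag_id=mag_id,
                    margin_stringent=config.margin_stringent,
                    margin_permissive=config.margin_permissive,
                )
        elif config.proteome_dir:
            for path in sorted(Path(config.proteome_dir).glob("*.faa")):
                all_calls += markers_mod.scan_mag(
                    path, profiles,
                    margin_stringent=config.margin_stringent,
                    margin_permissive=config.margin_permissive,
                )
        else:
            result["stages"]["markers"] = "skipped"
            all_calls = []
        if all_calls or proteomes:
            calls_frame = markers_mod.calls_to_frame(all_calls)
            calls_frame.to_csv(out_dir / "calls.tsv", sep="\t", index=False)
            roles_assigned = markers_mod.assign_roles(
                {m: markers_mod.group_calls(all_calls).get(m, [])
                 for m in (proteomes or markers_mod.group_calls(all_calls))}
            )
            roles_frame = pd.DataFrame(
                [dataclasses.asdict(r) for r in roles_assigned]
            )
            roles_frame.to_csv(out_dir / "roles.tsv", sep="\t", index=False)
            result["calls"] = calls_frame
            result["roles"] = roles_assigned
            result["stages"]["markers"] = "ok"
            tally = tally_by_lineage(roles_assigned, taxonomy)
            (out_dir / "tally.json").write_text(
                json.dumps(tally.to_dict(), sort_keys=True, indent=1)
            )
            result["tally"] = tally
        _log(log_path, dict(event="markers", status=result["stages"].get("markers")))
    except Exception as exc:  # noqa: BLE001 — re-raised with stage context
        raise StageError("markers", exc) from exc

    # ---- guilds ----------------------------------------------------------
    try:
        if gene_content is not None:
            contents = guilds_mod.contents_from_table(gene_content)
            labels = guilds_mod.classify_guilds(contents)
            guild_frame = pd.DataFrame(
                [
                    dict(mag=l.mag_id, is_srb=l.is_srb, is_irb=l.is_irb,
                         mer_accessories=";".join(l.mer_accessories))
                    for l in labels
                ]
            )
            guild_frame.to_csv(out_dir / "guilds.tsv", sep="\t", index=False)
            guilds_mod.mer_operon_profile(contents).to_csv(
                out_dir / "mer_operon.tsv", sep="\t", index=False
            )
            result["guilds"] = labels
            result["stages"]["guilds"] = "ok"
        else:
            result["stages"]["guilds"] = "skipped"
        _log(log_path, dict(event="guilds", status=result["stages"]["guilds"]))
    except Exception as exc:
        raise StageError("guilds", exc) from exc

    # ---- abundance -------------------------------------------------------
    try:
        if coverage is not None:
            rel = abundance_mod.relative_abundance(coverage)
            rel.to_csv(out_dir / "abundance.tsv", sep="\t")
            per_mag, per_taxon = abundance_mod.occurrence_frequency(
                rel, taxonomy if taxonomy else None
            )
            per_mag.rename_axis("mag").to_csv(out_dir / "occurrence.tsv", sep="\t")
            if taxonomy and site_map:
                lineages = {m: lineage_of(t)[0] for m, t in taxonomy.items()}
                agg = abundance_mod.aggregate_taxon_site(rel, lineages, site_map)
                agg.to_csv(out_dir / "taxon_site_abundance.tsv", sep="\t")
                result["taxon_site"] = agg
            result["abundance"] = rel
            result["stages"]["abundance"] = "ok"
        else:
            result["stages"]["abundance"] = "skipped"
        _log(log_path, dict(event="abundance", status=result["stages"]["abundance"]))
    except Exception as exc:
        raise StageError("abundance", exc) from exc

    # ---- hgt -------------------------------------------------------------
    try:
        if gene_tree is not None:
            report = hgt_mod.count_hgt_events(gene_tree, species_tree, taxon_map)
            report.to_frame().to_csv(out_dir / "hgt.tsv", sep="\t", index=False)
            (out_dir / "hgt.json").write_text(
                json.dumps(
                    dict(events=report.events, total=report.total), sort_keys=True
                )
            )
            result["hgt"] = report
            result["stages"]["hgt"] = "ok"
        else:
            result["stages"]["hgt"] = "skipped"
        _log(log_path, dict(event="hgt", status=result["stages"]["hgt"]))
    except Exception as exc:
        raise StageError("hgt", exc) from exc

    # ---- attribution -----------------------------------------------------
    try:
        if sites is not None:
            factors = [c for c in synthdata.SITE_FACTORS if c in sites.columns]
            microbial = [f for f in factors if f not in ("TC", "Fe2_Fe3")]
            environmental = [f for f in factors if f in ("TC", "Fe2_Fe3")]
            fit = attribution_mod.MehgAttribution(
                sites, microbial=microbial, environmental=environmental
            ).fit(alpha=config.alpha, criterion=config.criterion)
            (out_dir / "attribution.json").write_text(
                json.dumps(fit.to_dict(), sort_keys=True, indent=1, default=str)
            )
            (out_dir / "attribution_report.txt").write_text(fit.summary() + "\n")
            result["attribution"] = fit
            result["stages"]["attribution"] = "ok"
        else:
            result["stages"]["attribution"] = "skipped"
        _log(log_path, dict(event="attribution", status=result["stages"]["attribution"]))
    except Exception as exc:
        raise StageError("attribution", exc) from exc

    _log(log_path, dict(event="done", stages=result["stages"]))
    return result
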