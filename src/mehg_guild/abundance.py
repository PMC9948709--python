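"""MAG abundance accounting from scaffold coverage tables.

A MAG's coverage in a sample is the length-weighted mean of its scaffold
coverages; its relative abundance is that coverage divided by the summed
coverage of all MAGs in the sample (abundance is relative to the binned
fraction of the community, not the whole metagenome).  Occurrence frequency
is the share of samples where a MAG's abundance is strictly positive; a
taxon's frequency is the unweighted mean over its member MAGs.  Site-level
aggregates sum member-MAG abundances per taxon and average over each site's
samples.  MeHg/THg fractions convert ng/kg MeHg against ug/kg THg.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: coverages below this are numerically zero for occurrence purposes
ZERO_TOL = 1e-12

REQUIRED_COLUMNS = ("sample", "mag", "scaffold", "length_bp", "coverage")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    if (table["length_bp"] <= 0).any():
        raise ValueError("scaffold lengths must be > 0")
    if (table["coverage"] < 0).any():
        raise ValueError("coverages must be >= 0")
    owners = table.groupby("scaffold")["mag"].nunique()
    shared = owners[owners > 1]
    if not shared.empty:
        raise ValueError(f"scaffolds assigned to multiple MAGs: {list(shared.index[:5])}")
    return table


def mag_coverage(lengths, coverages) -> float:
    """Length-weighted mean coverage of one MAG's scaffolds in one sample."""
    lengths = np.asarray(lengths, float)
    coverages = np.asarray(coverages, float)
    if lengths.size == 0:
        raise ValueError("need at least one scaffold")
    total = lengths.sum()
    if total <= 0:
        raise ValueError("zero total scaffold length")
    return float((lengths * coverages).sum() / total)


def coverage_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """MAG x sample length-weighted coverages from a scaffold table."""
    table = _validate_table(table)
    def _wmean(group: pd.DataFrame) -> float:
        return mag_coverage(group["length_bp"], group["coverage"])
    cov = (
        table.groupby(["mag", "sample"])[["length_bp", "coverage"]]
        .apply(_wmean)
        .unstack("sample", fill_value=0.0)
    )
    return cov.sort_index(axis=0).sort_index(axis=1)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """MAG x sample relative abundances (each sample column sums to 1).

    A sample whose MAGs all have zero coverage yields an all-zero column
    with a logged warning.
    """
    cov = coverage_matrix(table)
    totals = cov.sum(axis=0)
    empty = totals[totals <= 0].index
    for sample in empty:
        logger.warning("sample %s has zero total MAG coverage", sample)
    safe = totals.replace(0.0, np.nan)
    rel = cov.div(safe, axis=1).fillna(0.0)
    return rel


def occurrence_frequency(
    abundance: pd.DataFrame, taxonomy: Mapping[str, str] | None = None
) -> tuple[pd.Series, pd.Series | None]:
    """Per-MAG (and optionally per-taxon) occurrence frequencies.

    A MAG occurs in a sample when its relative abundance exceeds the
    numerical zero tolerance; a taxon's frequency is the unweighted mean of
    its member MAG frequencies.
    """
    if abundance.shape[1] < 1:
        raise ValueError("need at least one sample")
    per_mag = (abundance > ZERO_TOL).mean(axis=1)
    per_mag.name = "occurrence"
    if taxonomy is None:
        return per_mag, None
    tax = pd.Series({m: taxonomy[m] for m in abundance.index})
    per_taxon = per_mag.groupby(tax).mean()
    per_taxon.name = "occurrence"
    return per_mag, per_taxon


def aggregate_taxon_site(
    abundance: pd.DataFrame,
    taxonomy: Mapping[str, str],
    site_map: Mapping[str, str],
) -> pd.DataFrame:
    """Taxon x site mean relative abundances.

    Per sample, a taxon's total is the sum of its member MAGs' abundances;
    per site, the value is the mean over that site's samples.  Every sample
    column must be mapped to a site.
    """
    unknown = [s for s in abundance.columns if s not in site_map]
    if unknown:
        raise ValueError(f"samples without site assignment: {unknown[:5]}")
    tax = pd.Series({m: taxonomy[m] for m in abundance.index})
    taxon_sample = abundance.groupby(tax).sum()
    sites = pd.Series({s: site_map[s] for s in abundance.columns})
    return taxon_sample.T.groupby(sites).mean().T


def mehg_fraction(thg_ug_kg: float, mehg_ng_kg: float) -> float:
    """MeHg as a percentage of THg (MeHg in ng/kg, THg in ug/kg).

    Returns NaN (reported missing) when THg is zero.
    """
    if thg_ug_kg < 0 or mehg_ng_kg < 0:
        raise ValueError("concentrations must be >= 0")
    if thg_ug_kg == 0:
        return float("nan")
    return 100.0 * (mehg_ng_kg / 1000.0) / thg_ug_kg


def mehg_fraction_table(chem: pd.DataFrame) -> pd.Series:
    """Row-wise MeHg/THg percentages for a chemistry table.

    Expects columns ``THg_ug_kg`` and ``MeHg_ng_kg``.
    """
    return pd.Series(
        [
            mehg_fraction(row["THg_ug_kg"], row["MeHg_ng_kg"])
            for _, row in chem.iterrows()
        ],
        index=chem.index,
        name="MeHg_pct_of_THg",
    )
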