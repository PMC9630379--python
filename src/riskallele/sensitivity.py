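"""Sensitivity re-analyses: locus removal, outlier removal, LD variants.

Each re-analysis removes records (by cytoband/position region or by an
explicit rsID list) and/or switches the LD-collapsing mode, then re-runs the
aggregation and inference stages.  A null spec (no removal, LD off)
reproduces the primary analysis exactly; the suite never mutates its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .aggregate import aggregate_catalog, catalog_or_max
from .catalog import SnpCatalog
from .ld import build_ld_groups, collapse_catalog, decide_groups
from .stats import compare_populations, deming_regression, extract_frequency_vectors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    """A genomic region named by cytoband prefix and/or position interval."""

    cytoband: str = ""
    chromosome: str = ""
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if not self.cytoband and not (self.chromosome and self.start is not None and self.end is not None):
            raise ValueError("region needs a cytoband or a chromosome plus position interval")

    def contains(self, record) -> bool:
        if self.cytoband and record.cytoband.startswith(self.cytoband):
            return True
        if (
            self.chromosome
            and self.start is not None
            and self.end is not None
            and record.chromosome == self.chromosome
            and record.position is not None
            and self.start <= record.position <= self.end
        ):
            return True
        return False


@dataclass(frozen=True)
class SensitivitySpec:
    name: str
    removal: str = "none"               # none | by_region | by_rsid_list
    region: Region | None = None
    rsids: tuple[str, ...] = ()
    ld_mode: str = "off"                # off | full_rules | ignore_locations
    deming: bool = True

    def __post_init__(self) -> None:
        if self.removal not in ("none", "by_region", "by_rsid_list"):
            raise ValueError(f"unknown removal mode {self.removal!r}")
        if self.ld_mode not in ("off", "full_rules", "ignore_locations"):
            raise ValueError(f"unknown ld_mode {self.ld_mode!r}")
        if self.removal == "by_region" and self.region is None:
            raise ValueError("by_region removal requires a region")
        if self.removal == "by_rsid_list" and not self.rsids:
            raise ValueError("by_rsid_list removal requires a non-empty rsid list")


def remove_by_region(catalog: SnpCatalog, region: Region) -> tuple[SnpCatalog, int]:
    """Drop records inside a region; returns (catalog, removed count)."""
    kept = [rec for rec in catalog.records if not region.contains(rec)]
    removed = len(catalog.records) - len(kept)
    if removed == 0:
        logger.warning("region %s matched no catalog records", region)
        return catalog, 0
    return catalog.with_records(kept), removed


def remove_by_rsids(catalog: SnpCatalog, rsids) -> tuple[SnpCatalog, int]:
    """Drop the listed rsIDs; unknown rsIDs are warned about, not errors."""
    targets = set(rsids)
    unknown = targets - set(catalog.rsids)
    for rsid in sorted(unknown):
        logger.warning("rsid %s not present in catalog", rsid)
    kept = [rec for rec in catalog.records if rec.rsid not in targets]
    return catalog.with_records(kept), len(catalog.records) - len(kept)


def run_sensitivity_suite(
    catalog: SnpCatalog,
    ld_pairs,
    specs,
    pop_a: str = "afr",
    pop_b: str = "eur",
    use_weighted: bool = True,
    direction: str = "greater",
    variant: str = "paired",
    pooling: str = "weighted",
    r2_threshold: float = 0.8,
    recompute_or_max: bool = False,
) -> pd.DataFrame:
    """Run each spec against a fresh view of the catalog.

    Returns one row per spec with the unit count, per-population means, the
    one-tailed t-test and (optionally) the Deming slope and its p-value
    against the identity line.  OR_max defaults to the full-catalog value so
    weighted frequencies stay comparable across subsets
    (``recompute_or_max=True`` recomputes it within each subset).
    """
    full_or_max = catalog_or_max(catalog)
    rows = []
    for spec in specs:
        sub = catalog
        n_removed = 0
        if spec.removal == "by_region":
            sub, n_removed = remove_by_region(sub, spec.region)
        elif spec.removal == "by_rsid_list":
            sub, n_removed = remove_by_rsids(sub, spec.rsids)

        if spec.ld_mode != "off":
            groups = build_ld_groups(sub, ld_pairs, r2_threshold)
            groups = decide_groups(
                groups,
                sub,
                pop_a=pop_a,
                pop_b=pop_b,
                ignore_locations=(spec.ld_mode == "ignore_locations"),
                pooling=pooling,
            )
            sub = collapse_catalog(sub, groups, pooling=pooling)

        or_max = None if recompute_or_max else full_or_max
        _, units = aggregate_catalog(sub, pooling=pooling, or_max=or_max)
        comp = compare_populations(
            units, pop_a, pop_b, use_weighted=use_weighted, direction=direction, variant=variant
        )
        row = {
            "name": spec.name,
            "n_units": len(units),
            "n_removed": n_removed,
            f"mean_{pop_a}": comp.mean_a,
            f"mean_{pop_b}": comp.mean_b,
            "t": comp.ttest.statistic,
            "df": comp.ttest.df,
            "p_one_tailed": comp.ttest.p_one_tailed,
        }
        if spec.deming:
            x, y = extract_frequency_vectors(units, pop_b, pop_a, use_weighted=False)
            fit = deming_regression(x, y)  # x = reference population, y = comparison
            row.update(
                {
                    "deming_slope": fit.slope,
                    "deming_intercept": fit.intercept,
                    "deming_slope_se": fit.slope_se,
                    "p_slope_vs_1": fit.p_slope_vs_one,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
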