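"""Pooled (F) and OR-weighted (F_w) risk-allele frequencies.

For each variant and population the frequency reports from the reference
databases are pooled into a single estimate F.  The default pooling is the
sample-size-weighted mean with weights equal to allele counts (2n), which is
the maximum-likelihood pooled estimate under binomial sampling; an
unweighted mean is available for comparison.

To reflect each allele's relative attributable risk, the weighted frequency
is F_w = F * OR / OR_max, where OR_max is the largest odds ratio in the
catalog.  F_w <= F always, with equality exactly when OR = OR_max.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import FrequencyObservation, SnpCatalog


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class AggregatedSnp:
    """Pooled and weighted frequencies for one analysis unit.

    A unit is a single SNP or an LD-collapsed group of SNPs.
    """

    unit_id: str
    odds_ratio: float
    pooled: dict[str, float]        # population -> F
    weighted: dict[str, float]      # population -> F_w
    n_databases: dict[str, int]     # population -> databases pooled


@dataclass(frozen=True)
class DatasetSummary:
    cancer_label: str
    or_max: float
    n_units: int


def pooled_frequency(observations, weighted: bool = True) -> float:
    """Pool database frequency reports into one estimate.

    Weighted pooling uses allele counts (2 x individuals) as weights; the
    factor 2 cancels in the mean but is kept for clarity.  The result always
    lies within [min f, max f] of the inputs.
    """
    obs = list(observations)
    if not obs:
        raise AggregationError("no frequency observations to pool")
    if weighted:
        total = sum(ob.allele_count for ob in obs)
        return sum(ob.frequency * ob.allele_count for ob in obs) / total
    return sum(ob.frequency for ob in obs) / len(obs)


def weighted_frequency(f: float, odds_ratio: float, or_max: float) -> float:
    """F_w = F * OR / OR_max."""
    if odds_ratio > or_max:
        raise AggregationError(
            f"odds ratio {odds_ratio} exceeds OR_max {or_max}; "
            "OR_max was computed on a different catalog"
        )
    return f * odds_ratio / or_max


def catalog_or_max(catalog: SnpCatalog) -> float:
    if not catalog.records:
        raise AggregationError("empty catalog has no OR_max")
    return max(rec.odds_ratio for rec in catalog.records)


def aggregate_catalog(
    catalog: SnpCatalog,
    pooling: str = "weighted",
    or_max: float | None = None,
) -> tuple[DatasetSummary, list[AggregatedSnp]]:
    """Compute F and F_w for every record and population of a catalog.

    Parameters
    ----------
    catalog : SnpCatalog
        A harmonized catalog (all OR >= 1).
    pooling : {"weighted", "unweighted"}
        Database pooling rule for F.
    or_max : float, optional
        Externally fixed OR_max (e.g. from the full pre-subset catalog so
        that F_w stays comparable across sensitivity runs).  Defaults to the
        catalog-wide maximum.
    """
    if pooling not in ("weighted", "unweighted"):
        raise AggregationError(f"unknown pooling rule {pooling!r}")
    omax = catalog_or_max(catalog) if or_max is None else or_max
    units: list[AggregatedSnp] = []
    for rec in catalog.records:
        pooled: dict[str, float] = {}
        weighted: dict[str, float] = {}
        ndb: dict[str, int] = {}
        for pop in catalog.populations:
            obs = rec.observations.get(pop, ())
            if not obs:
                raise AggregationError(
                    f"unit {rec.rsid}: no frequency observation for population {pop!r}"
                )
            f = pooled_frequency(obs, weighted=(pooling == "weighted"))
            pooled[pop] = f
            weighted[pop] = weighted_frequency(f, rec.odds_ratio, omax)
            ndb[pop] = len(obs)
        units.append(
            AggregatedSnp(
                unit_id=rec.rsid,
                odds_ratio=rec.odds_ratio,
                pooled=pooled,
                weighted=weighted,
                n_databases=ndb,
            )
        )
    summary = DatasetSummary(cancer_label=catalog.cancer_label, or_max=omax, n_units=len(units))
    return summary, units


def aggregated_to_frame(units):
    """Tabulate aggregated units: unit_id, or_value, <pop>_F, <pop>_Fw."""
    import pandas as pd

    rows = []
    for u in units:
        row = {"unit_id": u.unit_id, "or_value": u.odds_ratio}
        for pop in u.pooled:
            row[f"{pop}_F"] = round(u.pooled[pop], 6)
            row[f"{pop}_Fw"] = round(u.weighted[pop], 6)
        rows.append(row)
    return pd.DataFrame(rows)
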