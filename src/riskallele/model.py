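"""Model/Results interface tying the pipeline together.

:class:`DisparityModel` holds a harmonized catalog (and optionally its LD
pairs) for one disease and two populations; :meth:`DisparityModel.fit` runs
the aggregation, optional LD collapsing, the one-tailed mean comparison and
the Deming regression against the identity line, returning a
:class:`DisparityResults` with the estimates, their uncertainties and a
``summary()`` table.  Sensitivity re-analyses hang off the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import sensitivity as _sens
from .aggregate import AggregatedSnp, DatasetSummary, aggregate_catalog, catalog_or_max
from .catalog import LdPair, SnpCatalog, harmonize_risk_alleles, read_catalog, read_ld_pairs
from .ld import build_ld_groups, collapse_catalog, decide_groups
from .stats import (
    ComparisonResult,
    DemingFit,
    compare_populations,
    deming_regression,
    extract_frequency_vectors,
)


class DisparityModel:
    """Cross-population risk-allele frequency disparity model.

    Parameters
    ----------
    catalog : SnpCatalog
        The curated catalog; it is harmonized on construction (every OR is
        recoded to >= 1 by flipping alleles where needed).
    ld_pairs : list of LdPair, optional
        Pairwise r² reports for same-chromosome catalog SNPs; required only
        for LD-collapsed fits.
    pop_a, pop_b : str
        Population labels; the comparison and the regression treat
        ``pop_a`` as the comparison group (y axis) and ``pop_b`` as the
        reference group (x axis).
    """

    def __init__(
        self,
        catalog: SnpCatalog,
        ld_pairs: list[LdPair] | None = None,
        pop_a: str = "afr",
        pop_b: str = "eur",
    ) -> None:
        for pop in (pop_a, pop_b):
            if pop not in catalog.populations:
                raise ValueError(f"population {pop!r} not present in catalog")
        self.catalog = harmonize_risk_alleles(catalog)
        self.ld_pairs = list(ld_pairs) if ld_pairs else []
        self.pop_a = pop_a
        self.pop_b = pop_b

    @classmethod
    def from_files(
        cls,
        catalog_path,
        ld_pairs_path=None,
        pop_a: str = "afr",
        pop_b: str = "eur",
    ) -> "DisparityModel":
        catalog = read_catalog(catalog_path, populations=[pop_a, pop_b])
        pairs = read_ld_pairs(ld_pairs_path, catalog) if ld_pairs_path else None
        return cls(catalog, pairs, pop_a, pop_b)

    def fit(
        self,
        use_weighted: bool = True,
        direction: str = "greater",
        variant: str = "paired",
        ld_mode: str = "off",
        pooling: str = "weighted",
        r2_threshold: float = 0.8,
        lam: float = 1.0,
    ) -> "DisparityResults":
        """Run the full analysis and return a results object.

        ``ld_mode`` is ``"off"`` (per-SNP analysis), ``"full_rules"``
        (collapse LD groups unless a gene/functional-region/direction rule
        fires) or ``"ignore_locations"`` (only the direction rule applies).
        """
        catalog = self.catalog
        groups = []
        if ld_mode != "off":
            groups = build_ld_groups(catalog, self.ld_pairs, r2_threshold)
            groups = decide_groups(
                groups,
                catalog,
                pop_a=self.pop_a,
                pop_b=self.pop_b,
                ignore_locations=(ld_mode == "ignore_locations"),
                pooling=pooling,
            )
            catalog = collapse_catalog(catalog, groups, pooling=pooling)

        # OR_max from the pre-collapse catalog keeps F_w comparable.
        summary, units = aggregate_catalog(
            catalog, pooling=pooling, or_max=catalog_or_max(self.catalog)
        )
        comparison = compare_populations(
            units, self.pop_a, self.pop_b,
            use_weighted=use_weighted, direction=direction, variant=variant,
        )
        x, y = extract_frequency_vectors(units, self.pop_b, self.pop_a, use_weighted=False)
        deming = deming_regression(x, y, lam=lam, reference=1.0)
        return DisparityResults(
            model=self,
            dataset=summary,
            units=units,
            comparison=comparison,
            deming=deming,
            ld_groups=groups,
            options={
                "use_weighted": use_weighted,
                "direction": direction,
                "variant": variant,
                "ld_mode": ld_mode,
                "pooling": pooling,
                "r2_threshold": r2_threshold,
                "lambda": lam,
            },
        )

    def run_sensitivity(self, specs, **kwargs) -> pd.DataFrame:
        """Run a suite of sensitivity re-analyses (one row per spec)."""
        return _sens.run_sensitivity_suite(
            self.catalog, self.ld_pairs, specs, pop_a=self.pop_a, pop_b=self.pop_b, **kwargs
        )


@dataclass
class DisparityResults:
    """Fitted disparity analysis: means, t-test, Deming line, bookkeeping."""

    model: DisparityModel
    dataset: DatasetSummary
    units: list[AggregatedSnp]
    comparison: ComparisonResult
    deming: DemingFit
    ld_groups: list
    options: dict

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def mean_a(self) -> float:
        return self.comparison.mean_a

    @property
    def mean_b(self) -> float:
        return self.comparison.mean_b

    @property
    def p_value(self) -> float:
        return self.comparison.ttest.p_one_tailed

    @property
    def slope(self) -> float:
        return self.deming.slope

    def to_frame(self) -> pd.DataFrame:
        from .aggregate import aggregated_to_frame

        return aggregated_to_frame(self.units)

    def summary(self) -> str:
        tt = self.comparison.ttest
        d = self.deming
        pa, pb = self.model.pop_a, self.model.pop_b
        freq_kind = "weighted (F_w)" if self.comparison.use_weighted else "pooled (F)"
        lines = [
            "Risk-allele frequency disparity analysis",
            "=" * 56,
            f"Dataset:            {self.dataset.cancer_label}",
            f"Analysis units:     {self.n_units}   (OR_max = {self.dataset.or_max:.3f})",
            f"LD mode:            {self.options['ld_mode']}",
            f"Frequency compared: {freq_kind}",
            "-" * 56,
            f"mean[{pa}]          {tt.mean_a:.4f}",
            f"mean[{pb}]          {tt.mean_b:.4f}",
            f"t ({tt.variant}, one-tailed {tt.direction})"
            f"   t = {tt.statistic:.4f}, df = {tt.df:.1f}, p = {tt.p_one_tailed:.4g}",
            "-" * 56,
            f"Deming ({pa} on {pb}, lambda = {self.options['lambda']:g})",
            f"  slope     {d.slope:.4f}  (SE {d.slope_se:.4f})",
            f"  intercept {d.intercept:.4f}",
            f"  H0 slope = 1:  p = {d.p_slope_vs_one:.4g}",
            f"  H0 slope = 0:  p = {d.p_slope_vs_zero:.4g}",
            "=" * 56,
        ]
        return "\n".join(lines)
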