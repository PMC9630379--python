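"""LD grouping and collapsing of linked risk variants.

Same-chromosome SNPs linked at r² above a threshold (default 0.8) are
grouped by graph connected components and, unless an exclusion rule fires,
collapsed to one unit whose per-population frequency is the unweighted mean
of member pooled frequencies.  A group is kept separate (members analysed
individually) when:

1. its members lie in different protein-coding genes,
2. any member lies in an annotated functional region (e.g. a 3'-UTR), or
3. the direction of the between-population frequency difference is opposite
   between members (higher in one population for one SNP, lower for another).

Rules are checked in that order only to make the recorded reason
deterministic; any one of them prevents collapsing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import networkx as nx

from .aggregate import pooled_frequency
from .catalog import FrequencyObservation, LdPair, SnpCatalog, SnpRecord

logger = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.8


class Decision(str, Enum):
    UNDECIDED = "undecided"
    COLLAPSED = "collapsed"
    KEPT_SEPARATE = "kept_separate"


class Reason(str, Enum):
    NONE = "none"
    DIFFERENT_CODING_GENES = "different_coding_genes"
    FUNCTIONAL_REGION = "functional_region"
    OPPOSITE_DIRECTION = "opposite_direction"


class LdError(ValueError):
    pass


@dataclass(frozen=True)
class LdGroup:
    group_id: str
    member_rsids: frozenset[str]
    chromosome: str
    decision: Decision = Decision.UNDECIDED
    reason: Reason = Reason.NONE

    def __post_init__(self) -> None:
        if len(self.member_rsids) < 2:
            raise LdError(f"group {self.group_id} needs >= 2 members")
        if self.decision is Decision.COLLAPSED and self.reason is not Reason.NONE:
            raise LdError("collapsed group cannot carry a keep-separate reason")
        if self.decision is Decision.KEPT_SEPARATE and self.reason is Reason.NONE:
            raise LdError("kept_separate group must carry a reason")


def build_ld_groups(
    catalog: SnpCatalog,
    pairs: list[LdPair],
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> list[LdGroup]:
    """Partition linked SNPs into groups (connected components).

    Edges are catalog pairs with r² strictly greater than ``r2_threshold``;
    singletons are not reported.  A pair whose two members sit on different
    chromosomes is inconsistent input and raises :class:`LdError` (LD as
    used here is an intra-chromosomal notion).
    """
    if not 0.0 < r2_threshold < 1.0:
        raise LdError(f"r² threshold must be in (0, 1), got {r2_threshold}")
    chrom = {rec.rsid: rec.chromosome for rec in catalog.records}
    graph = nx.Graph()
    for pair in pairs:
        if pair.rsid_a not in chrom or pair.rsid_b not in chrom:
            continue  # flagged at read time; cannot group unknown variants
        if pair.r_squared <= r2_threshold:
            continue
        ca, cb = chrom[pair.rsid_a], chrom[pair.rsid_b]
        if ca != cb:
            raise LdError(
                f"LD pair {pair.rsid_a}-{pair.rsid_b} spans chromosomes {ca} and {cb}"
            )
        graph.add_edge(pair.rsid_a, pair.rsid_b)

    groups: list[LdGroup] = []
    order = {rsid: i for i, rsid in enumerate(catalog.rsids)}
    components = sorted(nx.connected_components(graph), key=lambda c: min(order[r] for r in c))
    for i, comp in enumerate(components, start=1):
        members = frozenset(comp)
        any_member = next(iter(members))
        groups.append(
            LdGroup(
                group_id=f"ld{i:03d}_chr{chrom[any_member]}",
                member_rsids=members,
                chromosome=chrom[any_member],
            )
        )
    return groups


def apply_collapse_rules(
    group: LdGroup,
    catalog: SnpCatalog,
    pop_a: str = "afr",
    pop_b: str = "eur",
    ignore_locations: bool = False,
    pooling: str = "weighted",
) -> LdGroup:
    """Decide whether a group may be collapsed.

    ``ignore_locations`` disables the gene and functional-region rules,
    leaving only the opposite-direction rule (the location-blind variant of
    the analysis).  Rule 3 compares the sign of the pooled-frequency
    difference F(pop_a) - F(pop_b) across members; an exact zero difference
    is compatible with either sign.
    """
    members = [catalog.get(rsid) for rsid in sorted(group.member_rsids)]

    if not ignore_locations:
        genes = {m.gene for m in members if m.gene}
        if len(genes) >= 2:
            return replace(
                group, decision=Decision.KEPT_SEPARATE, reason=Reason.DIFFERENT_CODING_GENES
            )
        if any(m.functional_region for m in members):
            return replace(
                group, decision=Decision.KEPT_SEPARATE, reason=Reason.FUNCTIONAL_REGION
            )

    weighted = pooling == "weighted"
    signs = set()
    for m in members:
        fa = pooled_frequency(m.observations[pop_a], weighted=weighted)
        fb = pooled_frequency(m.observations[pop_b], weighted=weighted)
        diff = fa - fb
        if diff != 0.0:
            signs.add(diff > 0)
    if len(signs) == 2:
        return replace(group, decision=Decision.KEPT_SEPARATE, reason=Reason.OPPOSITE_DIRECTION)

    return replace(group, decision=Decision.COLLAPSED, reason=Reason.NONE)


def decide_groups(
    groups: list[LdGroup],
    catalog: SnpCatalog,
    pop_a: str = "afr",
    pop_b: str = "eur",
    ignore_locations: bool = False,
    pooling: str = "weighted",
) -> list[LdGroup]:
    return [
        apply_collapse_rules(g, catalog, pop_a, pop_b, ignore_locations, pooling) for g in groups
    ]


def collapse_catalog(
    catalog: SnpCatalog,
    groups: list[LdGroup],
    or_rule: str = "max",
    pooling: str = "weighted",
) -> SnpCatalog:
    """Replace each collapsed group by one frequency-averaged unit.

    The unit frequency per population is the unweighted mean of member
    pooled frequencies F; the unit odds ratio is the maximum (default) or
    mean of member ORs.  Kept-separate groups and ungrouped SNPs pass
    through unchanged.  Output unit count = input count minus
    sum(|group| - 1) over collapsed groups.
    """
    if or_rule not in ("max", "mean"):
        raise LdError(f"unknown OR rule {or_rule!r}")
    for g in groups:
        if g.decision is Decision.UNDECIDED:
            raise LdError(f"group {g.group_id} is undecided; run apply_collapse_rules first")

    collapsed = [g for g in groups if g.decision is Decision.COLLAPSED]
    member_to_group: dict[str, LdGroup] = {}
    for g in collapsed:
        for rsid in g.member_rsids:
            if rsid in member_to_group:
                raise LdError(f"rsid {rsid} appears in more than one group")
            member_to_group[rsid] = g

    weighted = pooling == "weighted"
    out: list[SnpRecord] = []
    emitted: set[str] = set()
    for rec in catalog.records:
        group = member_to_group.get(rec.rsid)
        if group is None:
            out.append(rec)
            continue
        if group.group_id in emitted:
            continue
        emitted.add(group.group_id)
        members = [catalog.get(rsid) for rsid in sorted(group.member_rsids)]
        obs: dict[str, tuple[FrequencyObservation, ...]] = {}
        for pop in catalog.populations:
            fs = []
            n_total = 0
            for m in members:
                pop_obs = m.observations.get(pop, ())
                if not pop_obs:
                    raise LdError(
                        f"group {group.group_id}: member {m.rsid} lacks population {pop!r}"
                    )
                fs.append(pooled_frequency(pop_obs, weighted=weighted))
                n_total += sum(ob.sample_size for ob in pop_obs)
            obs[pop] = (
                FrequencyObservation("collapsed", sum(fs) / len(fs), max(n_total, 1)),
            )
        ors = [m.odds_ratio for m in members]
        unit_or = max(ors) if or_rule == "max" else sum(ors) / len(ors)
        genes = {m.gene for m in members if m.gene}
        out.append(
            SnpRecord(
                rsid="+".join(sorted(group.member_rsids)),
                chromosome=group.chromosome,
                risk_allele="",
                ref_allele="",
                odds_ratio=unit_or,
                gene=genes.pop() if len(genes) == 1 else "",
                observations=obs,
            )
        )
        logger.info("collapsed group %s (%d members) into one unit", group.group_id, len(members))
    return catalog.with_records(out)


def groups_to_frame(groups):
    """Audit table: group_id, members, decision, reason."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "group_id": g.group_id,
                "members": ",".join(sorted(g.member_rsids)),
                "decision": g.decision.value,
                "reason": g.reason.value,
            }
            for g in groups
        ]
    )
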