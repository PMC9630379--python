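"""SNP catalog types and TSV input/output.

A catalog is one curated table of disease risk variants: one row per SNP with
its risk/reference alleles, odds ratio, optional annotation (position,
cytoband, gene symbol, functional region), and risk-allele frequency
observations per population and per reference database.

The on-disk dialect is UTF-8 tab-separated text with one header row.
Mandatory columns: ``rsid, chromosome, risk_allele, ref_allele, or_value``.
Optional columns: ``position, cytoband, gene, functional_region, ci_low,
ci_high, p_value``.  Frequency observations follow the column pattern
``<pop>_freq_<db>`` and ``<pop>_n_<db>`` (e.g. ``afr_freq_1kg``,
``afr_n_1kg``); a blank cell is a missing observation.  Sample sizes are
numbers of individuals; internal weights use allele counts (2n, diploid
autosomal convention).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("rsid", "chromosome", "risk_allele", "ref_allele", "or_value")
OPTIONAL_COLUMNS = (
    "position",
    "cytoband",
    "gene",
    "functional_region",
    "ci_low",
    "ci_high",
    "p_value",
)

_FREQ_RE = re.compile(r"^(?P<pop>[a-z0-9]+)_freq_(?P<db>[a-z0-9]+)$")
_N_RE = re.compile(r"^(?P<pop>[a-z0-9]+)_n_(?P<db>[a-z0-9]+)$")


class CatalogError(ValueError):
    """Base class for catalog problems."""


class CatalogFormatError(CatalogError):
    """The file does not follow the documented TSV dialect."""


class CatalogValidationError(CatalogError):
    """A row violates a typed invariant (frequency range, sample size, ...)."""


@dataclass(frozen=True)
class FrequencyObservation:
    """One database's risk-allele frequency estimate for one population.

    ``sample_size`` is the number of individuals contributing to the
    estimate; the corresponding allele count is ``2 * sample_size``.
    """

    database: str
    frequency: float
    sample_size: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise CatalogValidationError(
                f"frequency {self.frequency} outside [0, 1] for database {self.database}"
            )
        if self.sample_size <= 0:
            raise CatalogValidationError(
                f"non-positive sample size {self.sample_size} for database {self.database}"
            )

    @property
    def allele_count(self) -> int:
        return 2 * self.sample_size


@dataclass(frozen=True)
class SnpRecord:
    """One curated risk variant.

    ``observations`` maps a population label (e.g. ``"afr"``, ``"eur"``) to
    the list of per-database frequency observations available for it.
    """

    rsid: str
    chromosome: str
    risk_allele: str
    ref_allele: str
    odds_ratio: float
    position: int | None = None
    cytoband: str = ""
    gene: str = ""
    functional_region: str = ""
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    observations: dict[str, tuple[FrequencyObservation, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.odds_ratio is None or self.odds_ratio <= 0:
            raise CatalogValidationError(
                f"{self.rsid}: odds ratio must be positive, got {self.odds_ratio}"
            )
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise CatalogValidationError(
                f"{self.rsid}: p-value {self.p_value} outside (0, 1]"
            )


@dataclass(frozen=True)
class SnpCatalog:
    """An ordered collection of :class:`SnpRecord` for one disease."""

    cancer_label: str
    records: tuple[SnpRecord, ...]
    populations: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.populations:
            raise CatalogValidationError("catalog must declare at least one population")
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise CatalogValidationError(f"duplicate rsid {rec.rsid} in catalog")
            seen.add(rec.rsid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rsid: str) -> SnpRecord:
        for rec in self.records:
            if rec.rsid == rsid:
                return rec
        raise KeyError(rsid)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(r.rsid for r in self.records)

    def with_records(self, records) -> "SnpCatalog":
        return replace(self, records=tuple(records))


@dataclass(frozen=True)
class LdPair:
    """A pairwise linkage-disequilibrium report between two variants."""

    rsid_a: str
    rsid_b: str
    r_squared: float
    in_catalog: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise CatalogValidationError(
                f"r² {self.r_squared} outside [0, 1] for pair {self.rsid_a}-{self.rsid_b}"
            )
        if self.rsid_a == self.rsid_b:
            raise CatalogValidationError(f"self-pair {self.rsid_a}")


def _parse_float(value: str, row: int, column: str, rsid: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise CatalogValidationError(
            f"row {row} ({rsid}): column {column!r} is not numeric: {value!r}"
        ) from None


def read_catalog(path, populations=None, cancer_label=None) -> SnpCatalog:
    """Read a catalog TSV.

    Parameters
    ----------
    path : path-like
        Catalog file in the documented dialect.
    populations : sequence of str, optional
        Population labels to load.  Defaults to every population named by a
        ``<pop>_freq_<db>`` column.
    cancer_label : str, optional
        Dataset name; defaults to the file stem.

    Raises
    ------
    CatalogFormatError
        If a mandatory column is missing.
    CatalogValidationError
        If any row violates a typed invariant; the message names the row
        number, rsid and offending column.
    """
    path = str(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing:
            raise CatalogFormatError(f"{path}: missing mandatory column(s) {missing}")

        freq_cols: dict[tuple[str, str], str] = {}
        n_cols: dict[tuple[str, str], str] = {}
        for col in header:
            m = _FREQ_RE.match(col)
            if m:
                freq_cols[(m["pop"], m["db"])] = col
            m = _N_RE.match(col)
            if m:
                n_cols[(m["pop"], m["db"])] = col
        file_pops = sorted({pop for pop, _ in freq_cols})
        pops = list(populations) if populations is not None else file_pops
        unknown = [p for p in pops if p not in file_pops]
        if unknown:
            raise CatalogFormatError(
                f"{path}: requested population(s) {unknown} have no frequency columns"
            )

        records: list[SnpRecord] = []
        for rownum, row in enumerate(reader, start=2):  # header is line 1
            rsid = (row.get("rsid") or "").strip()
            if not rsid:
                raise CatalogValidationError(f"row {rownum}: empty rsid")
            obs: dict[str, tuple[FrequencyObservation, ...]] = {}
            for pop in pops:
                pop_obs = []
                for (p, db), col in sorted(freq_cols.items()):
                    if p != pop:
                        continue
                    raw_f = (row.get(col) or "").strip()
                    ncol = n_cols.get((p, db))
                    raw_n = (row.get(ncol) or "").strip() if ncol else ""
                    if not raw_f and not raw_n:
                        continue
                    if not raw_f or not raw_n:
                        raise CatalogValidationError(
                            f"row {rownum} ({rsid}): population {pop!r} database {db!r} "
                            "has frequency without sample size (or vice versa)"
                        )
                    f = _parse_float(raw_f, rownum, col, rsid)
                    n = _parse_float(raw_n, rownum, ncol, rsid)
                    if not 0.0 <= f <= 1.0:
                        raise CatalogValidationError(
                            f"row {rownum} ({rsid}): column {col!r} frequency {f} outside [0, 1]"
                        )
                    if n <= 0 or int(n) != n:
                        raise CatalogValidationError(
                            f"row {rownum} ({rsid}): column {ncol!r} sample size {raw_n!r} "
                            "is not a positive integer"
                        )
                    pop_obs.append(FrequencyObservation(db, f, int(n)))
                obs[pop] = tuple(pop_obs)

            def opt_float(col: str) -> float | None:
                raw = (row.get(col) or "").strip()
                return _parse_float(raw, rownum, col, rsid) if raw else None

            raw_pos = (row.get("position") or "").strip()
            try:
                records.append(
                    SnpRecord(
                        rsid=rsid,
                        chromosome=(row.get("chromosome") or "").strip(),
                        risk_allele=(row.get("risk_allele") or "").strip(),
                        ref_allele=(row.get("ref_allele") or "").strip(),
                        odds_ratio=_parse_float(
                            (row.get("or_value") or "").strip(), rownum, "or_value", rsid
                        ),
                        position=int(raw_pos) if raw_pos else None,
                        cytoband=(row.get("cytoband") or "").strip(),
                        gene=(row.get("gene") or "").strip(),
                        functional_region=(row.get("functional_region") or "").strip(),
                        ci_low=opt_float("ci_low"),
                        ci_high=opt_float("ci_high"),
                        p_value=opt_float("p_value"),
                        observations=obs,
                    )
                )
            except CatalogValidationError as exc:
                raise CatalogValidationError(f"row {rownum}: {exc}") from None

    label = cancer_label if cancer_label is not None else path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return SnpCatalog(cancer_label=label, records=tuple(records), populations=tuple(pops))


def write_catalog(catalog: SnpCatalog, path) -> None:
    """Write a catalog back to the TSV dialect (round-trip safe)."""
    dbs: list[str] = []
    for rec in catalog.records:
        for pop in catalog.populations:
            for ob in rec.observations.get(pop, ()):
                if ob.database not in dbs:
                    dbs.append(ob.database)
    dbs = sorted(dbs) or ["1kg", "alfa", "gnomad"]

    header = list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS)
    for pop in catalog.populations:
        for db in dbs:
            header += [f"{pop}_freq_{db}", f"{pop}_n_{db}"]

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with open(str(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for rec in catalog.records:
            row = [
                rec.rsid,
                rec.chromosome,
                rec.risk_allele,
                rec.ref_allele,
                fmt(rec.odds_ratio),
                fmt(rec.position),
                rec.cytoband,
                rec.gene,
                rec.functional_region,
                fmt(rec.ci_low),
                fmt(rec.ci_high),
                fmt(rec.p_value),
            ]
            for pop in catalog.populations:
                by_db = {ob.database: ob for ob in rec.observations.get(pop, ())}
                for db in dbs:
                    ob = by_db.get(db)
                    row += [fmt(ob.frequency) if ob else "", fmt(ob.sample_size) if ob else ""]
            writer.writerow(row)


def harmonize_risk_alleles(catalog: SnpCatalog) -> SnpCatalog:
    """Recode every record so the risk allele has OR >= 1.

    A record with OR < 1 has its alleles swapped, OR inverted, confidence
    bounds inverted and swapped, and every frequency f replaced by 1 - f.
    Idempotent; each flip is logged.
    """
    out: list[SnpRecord] = []
    for rec in catalog.records:
        if rec.odds_ratio >= 1.0:
            out.append(rec)
            continue
        flipped_obs = {
            pop: tuple(
                FrequencyObservation(ob.database, 1.0 - ob.frequency, ob.sample_size)
                for ob in obs
            )
            for pop, obs in rec.observations.items()
        }
        ci_low = 1.0 / rec.ci_high if rec.ci_high else None
        ci_high = 1.0 / rec.ci_low if rec.ci_low else None
        logger.info(
            "harmonize: flipped %s (OR %.4g -> %.4g, risk allele %s -> %s)",
            rec.rsid, rec.odds_ratio, 1.0 / rec.odds_ratio, rec.risk_allele, rec.ref_allele,
        )
        out.append(
            replace(
                rec,
                risk_allele=rec.ref_allele,
                ref_allele=rec.risk_allele,
                odds_ratio=1.0 / rec.odds_ratio,
                ci_low=ci_low,
                ci_high=ci_high,
                observations=flipped_obs,
            )
        )
    return catalog.with_records(out)


def read_ld_pairs(path, catalog: SnpCatalog | None = None) -> list[LdPair]:
    """Read an LD-pairs TSV with columns ``rsid_a, rsid_b, r2``.

    Pairs that reference rsIDs absent from the companion catalog are kept
    but flagged (``in_catalog=False``) and logged.
    """
    known = set(catalog.rsids) if catalog is not None else None
    pairs: list[LdPair] = []
    with open(str(path), newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in ("rsid_a", "rsid_b", "r2") if c not in header]
        if missing:
            raise CatalogFormatError(f"{path}: missing LD column(s) {missing}")
        for rownum, row in enumerate(reader, start=2):
            a = (row.get("rsid_a") or "").strip()
            b = (row.get("rsid_b") or "").strip()
            r2 = _parse_float((row.get("r2") or "").strip(), rownum, "r2", f"{a}-{b}")
            if not 0.0 <= r2 <= 1.0:
                raise CatalogValidationError(
                    f"row {rownum}: r² {r2} outside [0, 1] for pair {a}-{b}"
                )
            in_cat = True
            if known is not None and (a not in known or b not in known):
                in_cat = False
                logger.warning("LD pair %s-%s references rsID(s) absent from catalog", a, b)
            pairs.append(LdPair(a, b, r2, in_catalog=in_cat))
    return pairs
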