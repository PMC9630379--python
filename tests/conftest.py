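import pytest

from riskallele import FrequencyObservation, SnpCatalog, SnpRecord


def make_record(
    rsid,
    chromosome="1",
    odds_ratio=1.5,
    f_afr=0.4,
    f_eur=0.3,
    gene="",
    functional_region="",
    cytoband="",
    position=None,
    db_sizes=((("1kg", 661), ("alfa", 50_000), ("gnomad", 8_000))),
    f_afr_by_db=None,
    f_eur_by_db=None,
):
    """Build a SnpRecord with one observation per database.

    By default every database reports the same frequency; per-database
    overrides let tests exercise the pooling arithmetic.
    """
    obs = {}
    for pop, f, by_db in (("afr", f_afr, f_afr_by_db), ("eur", f_eur, f_eur_by_db)):
        pop_obs = []
        for db, n in db_sizes:
            freq = by_db[db] if by_db and db in by_db else f
            pop_obs.append(FrequencyObservation(db, freq, n))
        obs[pop] = tuple(pop_obs)
    return SnpRecord(
        rsid=rsid,
        chromosome=chromosome,
        risk_allele="A",
        ref_allele="G",
        odds_ratio=odds_ratio,
        gene=gene,
        functional_region=functional_region,
        cytoband=cytoband,
        position=position,
        observations=obs,
    )


def make_catalog(records, label="fixture"):
    return SnpCatalog(cancer_label=label, records=tuple(records), populations=("afr", "eur"))


@pytest.fixture
def three_snp_catalog():
    return make_catalog(
        [
            make_record("rs1", "1", 1.5, f_afr=0.4, f_eur=0.3),
            make_record("rs2", "2", 2.0, f_afr=0.6, f_eur=0.5, gene="KITLG"),
            make_record("rs3", "8", 1.2, f_afr=0.2, f_eur=0.25, cytoband="8q24.21"),
        ]
    )
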