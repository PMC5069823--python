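import pytest

from somatrack.fixtures import (
    reference_manifest,
    reference_ras_calls,
    reference_recurrent_calls,
)
from somatrack.model import (
    Case,
    Consequence,
    FilterConfig,
    Specimen,
    Tissue,
    Variant,
    VariantCall,
    YearMonth,
)
from somatrack.simulate import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def default_config():
    return FilterConfig()


@pytest.fixture(scope="session")
def ref_manifest():
    return reference_manifest()


@pytest.fixture(scope="session")
def ras_calls():
    return reference_ras_calls()


@pytest.fixture(scope="session")
def recurrent_calls():
    return reference_recurrent_calls()


@pytest.fixture(scope="session")
def sim_result():
    """One small deterministic simulated cohort shared by read-only tests."""
    return simulate_cohort(SimParams(n_cases=5, seed=11))


def make_variant(gene="KRAS", hgvs_p="p.G12D", consequence=Consequence.MISSENSE,
                 **kwargs):
    return Variant(gene=gene, hgvs_p=hgvs_p, consequence=consequence, **kwargs)


def make_call(specimen_id, gene="KRAS", hgvs_p="p.G12D", af=50.0,
              consequence=Consequence.MISSENSE, **kwargs):
    return VariantCall(
        variant=make_variant(gene=gene, hgvs_p=hgvs_p, consequence=consequence,
                             **kwargs),
        specimen_id=specimen_id,
        allele_fraction=af,
    )


def make_case(case_id="X", n_mets=2, met_tissue=Tissue.LIVER_MET,
              met_months=(2, 12)):
    """Minimal valid case: normal + primary + n metastases."""
    pdate = YearMonth(2010, 1)
    specimens = [
        Specimen(f"{case_id}_N", case_id, Tissue.NORMAL),
        Specimen(f"{case_id}_PT", case_id, Tissue.PRIMARY, resection_date=pdate),
    ]
    for i in range(n_mets):
        months = met_months[i % len(met_months)]
        year, month = 2010 + (months // 12), 1 + months % 12
        if month > 12:
            year, month = year + 1, month - 12
        specimens.append(
            Specimen(
                f"{case_id}_M{i + 1}",
                case_id,
                met_tissue,
                resection_date=YearMonth(year, month),
            )
        )
    case = Case(case_id=case_id, specimens=specimens)
    case.validate()
    return case
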