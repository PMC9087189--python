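import textwrap

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100,
                          deadline=None)
settings.load_profile("ci")


FIXTURE_CSV = textwrap.dedent(
    """\
    drug_name,modality_class,molecular_weight_kda,nonclin_dose_value,nonclin_dose_unit,nonclin_n_admin_day1,nonclin_species,nonclin_route,nonclin_model,nonclin_response_metric,nonclin_response_value,clin_dose_low,clin_dose_high,clin_dose_unit,clin_route,indication,flags,reference
    drugA,SM_PO,0.45,37,mg_per_kg,1,mouse,PO,HT-29 xenograft,TGI_percent,72,3,,mg_per_kg,PO,colorectal cancer,,Smith 2001
    drugB,mAb,150,2,mg_per_kg,1,mouse,IV,Raji xenograft,regression,,2,,mg_per_kg,IV,lymphoma,,Jones 2005
    drugC,SM_IV,0.6,10,mg_per_kg,2,mouse,IV,A549 xenograft,TGI_percent,65,100,200,mg,IV,NSCLC,,Lee 2010
    drugD,SM_IV,,5,mg_per_kg,1,mouse,IP,HCT-116 xenograft,TGI_percent,88,1,,mg_per_kg,IV,colorectal cancer,mtd_only,Kim 2012
    drugE,ADC,152,3,mg_per_kg,1,mouse,IV,MDA-MB-231 xenograft,stasis,,1.8,,mg_per_kg,IV,breast cancer,syngeneic_model,Park 2015
    """
)


@pytest.fixture
def fixture_csv(tmp_path):
    """A small, hand-written drug table covering doses, ranges, units and flags."""
    path = tmp_path / "drugs.csv"
    path.write_text(FIXTURE_CSV)
    return path
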