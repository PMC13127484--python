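import pytest

import hetchrom as hc


@pytest.fixture(scope="session")
def planted_family():
    """Ortholog family with planted strata: 40 records, 12 with extensions,
    7 longer than 20 aa, 5 basic (3 reference-similar, 2 distinct)."""
    records, aln, truth = hc.gen_ortholog_family(
        n_total=40,
        n_with_extension=12,
        n_long=7,
        n_basic=5,
        n_similar=3,
        seed=11,
    )
    return records, aln, truth


@pytest.fixture(scope="session")
def survey_result(planted_family):
    records, aln, _ = planted_family
    return hc.run_survey(
        records, aln, ref_start=("SYN-REF1", 1), truncate_at=("SYN-REF2", 81)
    )
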