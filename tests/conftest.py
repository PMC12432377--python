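import pandas as pd
import pytest

from tcrtrack.models import CLONOTYPE_COLUMNS, RepertoireTable


def make_table(rows, sample_id="s1", patient_id="p1", compartment="other"):
    """rows: list of (chain, v, j, cdr3, count) tuples."""
    df = pd.DataFrame(rows, columns=CLONOTYPE_COLUMNS)
    return RepertoireTable(sample_id, patient_id, compartment, df)


@pytest.fixture
def trb_table():
    return make_table(
        [
            ("TRB", "TRBV27", "TRBJ2-1", "CASSLGQETQYF", 10),
            ("TRB", "TRBV9", "TRBJ2-5", "CASSKGASGNEQFF", 5),
            ("TRB", "TRBV2", "TRBJ1-1", "CASSPLGPQETQYF", 5),
        ]
    )
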