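import numpy as np
import pandas as pd
import pytest

from apms.io_model import DatasetMeta, PeptideRecord, PVMatrix


@pytest.fixture
def tiny_pv_tsv(tmp_path):
    """Hand-written 3-peptide, 2-dataset PV table with one missing cell."""
    text = (
        "protein_id\tsequence\tAP_1\tAP_2\n"
        "GluA1\tACDEFGHIK\t1000\t500\n"
        "GluA1\tLMNPQRSTV\t2000\t\n"
        "FRRS1l\tWYACDEFGH\t300\t150\n"
    )
    path = tmp_path / "pv.tsv"
    path.write_text(text)
    return path


def make_pv(values: dict[str, dict[str, list[float]]], dataset_ids: list[str]):
    """Build a PVMatrix from {protein: {sequence: [pv per dataset]}}."""
    peptides = []
    rows = {}
    for protein, peps in values.items():
        for seq, pv in peps.items():
            peptides.append(PeptideRecord(protein, seq))
            rows[seq] = pv
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=dataset_ids)
    return PVMatrix(peptides, frame)


@pytest.fixture
def simple_matrix():
    return make_pv(
        {
            "P1": {"AAAA": [10.0, 5.0, np.nan], "CCCC": [20.0, 10.0, 2.0]},
            "P2": {"DDDD": [7.0, 7.0, 7.0]},
        },
        ["d1", "d2", "d3"],
    )


@pytest.fixture
def glua_meta():
    glua = frozenset({"GluA1", "GluA2", "GluA3", "GluA4"})
    return [
        DatasetMeta("AP_1", glua, antibody_id="AB1"),
        DatasetMeta("AP_2", glua, antibody_id="AB2"),
    ]
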