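import numpy as np
import pytest

from uroquant.itraq import ProteinQuantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_record(
    accession="P1",
    n_peptides=5,
    ratio=2.0,
    p=0.01,
    ef=1.2,
    name=None,
):
    return ProteinQuantRecord(
        accession=accession,
        protein_name=name or accession,
        n_unique_peptides=n_peptides,
        ratio_ma_na=ratio,
        p_value=p,
        ef=ef,
    )


def random_quant_table(rng, n_rows):
    """Random table exercising every filter gate, including undefined stats."""
    rows = []
    for i in range(n_rows):
        if rng.random() < 0.15:
            p, ef = None, None
            npep = 1
        else:
            p = float(rng.uniform(0.0, 0.2))
            ef = float(rng.uniform(1.0, 3.0))
            npep = int(rng.integers(1, 8))
        rows.append(
            make_record(
                accession=f"P{i:04d}",
                n_peptides=npep,
                ratio=float(np.exp(rng.normal(0.0, 0.6))),
                p=p,
                ef=ef,
            )
        )
    return rows
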