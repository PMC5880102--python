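import numpy as np
import pandas as pd
import pytest

from spatialprot.core import PSM_META_COLUMNS, PsmTable
from spatialprot.preprocess import NormalizationFit


def build_psm(rows, channels):
    """Build a PsmTable from (peptide, protein, proteotypic, contaminant,
    decoy, [intensities...]) tuples."""
    records = []
    for pep, prot, typ, cont, dec, inten in rows:
        rec = {
            "peptide_id": pep,
            "protein_group": prot,
            "proteotypic": typ,
            "is_contaminant": cont,
            "is_decoy": dec,
        }
        rec.update(dict(zip(channels, inten)))
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=list(PSM_META_COLUMNS) + channels)
    return PsmTable(df=df, channels=channels)


@pytest.fixture
def toy_channels():
    return ["c1", "c2"]


@pytest.fixture
def toy_psm(toy_channels):
    """Hand-countable toy table.

    Filter at min_intensity=1000 on both channels removes: the P2 row with
    999.9, both P4 contaminant rows, the P5 decoy row, and the P6 row sitting
    exactly at 1000 (strict threshold).  Survivors: 3 P1 rows, 1 P2 row,
    2 P3 rows (one non-proteotypic), 1 P6 row = 7 rows.  After the
    >= 2-proteotypic-peptide rule only P1 remains in the protein matrix.
    """
    rows = [
        ("p1a", "P1", True, False, False, [5000.0, 6000.0]),
        ("p1b", "P1", True, False, False, [4000.0, 3000.0]),
        ("p1c", "P1", True, False, False, [2000.0, 2500.0]),
        ("p2a", "P2", True, False, False, [999.9, 5000.0]),
        ("p2b", "P2", True, False, False, [3000.0, 3000.0]),
        ("p3a", "P3", True, False, False, [2000.0, 2000.0]),
        ("p3b", "P3", False, False, False, [2500.0, 2500.0]),
        ("p4a", "P4", True, True, False, [1e6, 1e6]),
        ("p4b", "P4", True, True, False, [1e6, 1e6]),
        ("p5a", "P5", True, False, True, [1e6, 1e6]),
        ("p6a", "P6", True, False, False, [1000.0, 4000.0]),
        ("p6b", "P6", True, False, False, [1500.0, 1500.0]),
    ]
    return build_psm(rows, ["c1", "c2"])


@pytest.fixture
def identity_fit(toy_channels):
    return NormalizationFit.identity(toy_channels)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
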