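import pandas as pd
import pytest
from hypothesis import settings

from cyclomet import CyclicPeptide

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

ELLISIIAMIDE_A = "cyclo(NMePhe-Ala-Ile-Leu-Pro)"
ELLISIIAMIDE_B = "cyclo(NMePhe-Val-Val-Leu-Pro)"
ELLISIIAMIDE_C = "cyclo(NMePhe-Ile-Ile-Leu-Pro)"


@pytest.fixture
def ellisiiamide_a():
    return CyclicPeptide.from_string(ELLISIIAMIDE_A)


@pytest.fixture
def ellisiiamide_b():
    return CyclicPeptide.from_string(ELLISIIAMIDE_B)


@pytest.fixture
def ellisiiamide_c():
    return CyclicPeptide.from_string(ELLISIIAMIDE_C)


@pytest.fixture
def small_table_csvs(tmp_path):
    """A 4-feature, 4-sample feature table on disk (2 filtrate, 2 mycelium)."""
    features = pd.DataFrame(
        {
            "feature_id": ["F1", "F2", "F3", "F4"],
            "mz": [550.3973, 237.1094, 300.1, 412.2],
            "rt_min": [15.97, 10.84, 26.3, 5.0],
            "isotope_flag": [False, False, False, True],
            "s1": [50000.0, 9999.0, 20000.0, 30000.0],
            "s2": [60000.0, 8000.0, 25000.0, 35000.0],
            "s3": [55000.0, 7000.0, 21000.0, 31000.0],
            "s4": [52000.0, 10000.0, 22000.0, 33000.0],
        }
    )
    metadata = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "strain": ["HB01", "HB01", "WB01", "WB01"],
            "host": ["highbush", "highbush", "wild", "wild"],
            "medium": ["ML", "PDB", "ML", "PDB"],
            "matrix": ["filtrate", "filtrate", "mycelium", "mycelium"],
        }
    )
    fpath, mpath = tmp_path / "features.csv", tmp_path / "metadata.csv"
    features.to_csv(fpath, index=False)
    metadata.to_csv(mpath, index=False)
    return fpath, mpath
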