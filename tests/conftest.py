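import pandas as pd
import pytest

from befa.feature_io import FeatureTable


@pytest.fixture
def small_manifest() -> pd.DataFrame:
    rows = [
        ("wt_1", "WT", 1), ("wt_2", "WT", 2),
        ("mut_1", "mut", 1), ("mut_2", "mut", 2),
        ("blank_1", "blank", 1),
    ]
    return pd.DataFrame(rows, columns=["sample_id", "group", "experiment"]).set_index("sample_id")


@pytest.fixture
def small_table(small_manifest) -> FeatureTable:
    features = {
        "fa": {"mz": 183.1391, "rt": 300.0, "ion_mode": "neg"},
        "fb": {"mz": 215.1289, "rt": 500.0, "ion_mode": "neg"},
        "fc": {"mz": 400.0000, "rt": 800.0, "ion_mode": "neg"},
    }
    intensities = {
        "fa": {"wt_1": 50_000.0, "wt_2": 55_000.0, "mut_1": 48_000.0, "mut_2": 52_000.0, "blank_1": 100.0},
        "fb": {"wt_1": 20_000.0, "wt_2": 22_000.0, "mut_1": 90_000.0, "mut_2": 95_000.0, "blank_1": 0.0},
        "fc": {"wt_1": 15_000.0, "wt_2": 14_000.0, "mut_1": 15_500.0, "mut_2": 14_500.0, "blank_1": 200.0},
    }
    f = pd.DataFrame(features).T
    f.index.name = "feature_id"
    f[["mz", "rt"]] = f[["mz", "rt"]].astype(float)
    x = pd.DataFrame(intensities).T.astype(float)
    return FeatureTable(features=f, intensities=x, manifest=small_manifest)
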