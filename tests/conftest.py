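import numpy as np
import pandas as pd
import pytest

from innatome_miner.catalog import GeneCatalog
from innatome_miner.degcall import Contrast, signed_fc_array
from innatome_miner.resources import build_innatome_catalog, housekeeping_catalog


@pytest.fixture(scope="session")
def innatome():
    return build_innatome_catalog()


@pytest.fixture(scope="session")
def housekeeping():
    return housekeeping_catalog()


def contrast_from_fc(fc_map: dict[str, float], dataset_id: str = "test") -> Contrast:
    """Build a gene-level contrast directly from a symbol -> signed_fc map."""
    frame = pd.DataFrame(
        {"symbol": list(fc_map), "signed_fc": list(fc_map.values())}
    )
    return Contrast(dataset_id=dataset_id, species="agnostic", frame=frame)


def contrast_from_means(rows: list[tuple[str, float, float]], dataset_id: str = "test") -> Contrast:
    frame = pd.DataFrame(rows, columns=["symbol", "treat_mean", "control_mean"])
    frame["signed_fc"] = signed_fc_array(
        frame["treat_mean"].to_numpy(), frame["control_mean"].to_numpy()
    )
    return Contrast(dataset_id=dataset_id, species="agnostic", frame=frame)


@pytest.fixture
def small_catalog():
    genes = {f"G{i}" for i in range(1, 11)}
    annotations = {
        f"G{i}": {
            "location_class": "cytoplasm" if i <= 6 else "nucleus",
            "function_class": "kinase" if i <= 3 else "enzyme",
        }
        for i in range(1, 11)
    }
    return GeneCatalog(name="small", species="agnostic", genes=genes, annotations=annotations)
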