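from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bpscan

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

REPO_ROOT = Path(__file__).resolve().parents[1]
SUPPLEMENTARY_DIR = REPO_ROOT / "data" / "supplementary"

#: Expected on-disk names for the published evaluation data (see
#: data/supplementary/README.md for how to prepare them).
SUPPLEMENTARY_FILES = {
    "dataset_s1": "Dataset_S1.fa",
    "dataset_s2": "Dataset_S2.fa",
    "table_s4": "Table_S4.tsv",
    "table_s5": "Table_S5.tsv",
    "table_s6": "Table_S6.tsv",
}


def supplementary_status(*keys: str) -> tuple[dict[str, Path], list[str]]:
    """Resolve requested supplementary files; also report the missing ones."""
    found, missing = {}, []
    for key in keys:
        p = SUPPLEMENTARY_DIR / SUPPLEMENTARY_FILES[key]
        if p.exists():
            found[key] = p
        else:
            missing.append(str(p))
    return found, missing


def require_supplementary(*keys: str) -> dict[str, Path]:
    found, missing = supplementary_status(*keys)
    if missing:
        pytest.skip(
            "published evaluation data not present in this checkout; "
            "place the files listed in data/supplementary/README.md to enable "
            "this check. Missing: " + ", ".join(missing)
        )
    return found


@pytest.fixture(scope="session")
def nn_table() -> bpscan.EnergyTable:
    return bpscan.build_energy_table("nn")


@pytest.fixture(scope="session")
def cofold_table() -> bpscan.EnergyTable:
    return bpscan.build_energy_table("cofold")


@pytest.fixture(scope="session")
def tna_matrix() -> bpscan.FrequencyMatrix:
    return bpscan.bundled_matrix("tna-strict")


@pytest.fixture(scope="session")
def degenerate_matrix() -> bpscan.FrequencyMatrix:
    return bpscan.bundled_matrix("degenerate")


@pytest.fixture(scope="session")
def uniform_matrix() -> bpscan.FrequencyMatrix:
    return bpscan.FrequencyMatrix(f=np.full((4, 7), 0.25), source="uniform")


@pytest.fixture(scope="session")
def zero_table() -> bpscan.EnergyTable:
    return bpscan.EnergyTable(
        energies={h: 0.0 for h in bpscan.energy.all_hexamers()},
        backend_label="zero",
    )
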