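
import numpy as np
import pandas as pd
import pytest

from hybridcline import SimulationConfig, simulate_all


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def specimen_csv(tmp_path):
    """Factory: write a specimen CSV from a list of row dicts."""

    def make(rows, name="specimens.csv"):
        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return make


@pytest.fixture()
def fasta_file(tmp_path):
    """Factory: write a FASTA from an id -> sequence dict (in order)."""

    def make(seqs, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, s in seqs.items():
                fh.write(f">{sid}\n{s}\n")
        return path

    return make


@pytest.fixture(scope="session")
def default_bundle():
    """One default simulated dataset, shared across tests (read-only)."""
    return simulate_all(SimulationConfig.default(), out_dir=None, seed=2021)


def straight_line_points(n=12, lat0=3.9, lon0=-77.0, slope=-0.6, span=1.0):
    """Collinear lat/lon points for exact-regression tests."""
    lon = np.linspace(lon0, lon0 + span, n)
    lat = lat0 + slope * (lon - lon0)
    return pd.DataFrame({"longitude": lon, "latitude": lat})
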