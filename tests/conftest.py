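import numpy as np
import pytest

from qspr.descriptors import compute_descriptors
from qspr.synthetic import toy_molecule_panel


@pytest.fixture(scope="session")
def panel_descriptors():
    """Descriptor vectors for the ten-molecule toy panel (computed once:
    embedding + SASA quadrature dominate the cost)."""
    out = {}
    for entry in toy_molecule_panel():
        out[entry["name"]] = compute_descriptors(entry["smiles"])
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20180607)


def make_compound_csv(path, rows, header="id,name,smiles,tc_K,pc_MPa,omega,rel_err_tc,rel_err_pc"):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path
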