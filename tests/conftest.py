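import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, occ, b, element,
                   altloc=" "):
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5d} {name:<4s}{altloc}{resname:<3s} {chain}{resseq:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_atom_pdb(tmp_path):
    """Hand-written 3-atom PDB fixture with B = 10.0 / 12.5 / 15.0."""
    lines = [
        "CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1",
        _pdb_atom_line(1, " SG ", "CYS", "A", 12, (1.0, 2.0, 3.0), 1.00, 10.0, "S"),
        _pdb_atom_line(2, " SD ", "MET", "A", 20, (4.0, 5.0, 6.0), 1.00, 12.5, "S"),
        _pdb_atom_line(3, "FE  ", "HEM", "B", 101, (7.0, 8.0, 9.0), 0.80, 15.0, "FE"),
        "END",
    ]
    path = tmp_path / "sites.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230704)
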