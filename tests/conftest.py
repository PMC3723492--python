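import numpy as np
import pytest

from memscale import fixtures as fx
from memscale.mapping import map_protein, load_lipid_templates
from memscale.engine import load_forcefield
from memscale.structure_io import Structure


@pytest.fixture(scope="session")
def anchor_helix():
    return fx.build_amphipathic_anchor()


@pytest.fixture(scope="session")
def anchor_cg(anchor_helix):
    return map_protein(anchor_helix)


@pytest.fixture(scope="session")
def toy_ff():
    return load_forcefield()


@pytest.fixture(scope="session")
def lipid_templates():
    return load_lipid_templates()


@pytest.fixture(scope="session")
def small_bilayer():
    return fx.build_bilayer(fx.BilayerSpec(nx=6, ny=6))


def make_aa_toy_lipids(n, spacing=8.0, res_name="TOY4"):
    """Atomistic toy lipids matching the TOY4/TOY3 template parent atoms."""
    names = ["N1", "O1", "C1", "C2", "C3", "C4", "C5", "C6"]
    if res_name == "TOY3":
        names = names[:6]
    rows = {"names": [], "resn": [], "rid": [], "xyz": []}
    per = int(np.ceil(np.sqrt(n)))
    for li in range(n):
        base = np.array([(li % per) * spacing, (li // per) * spacing, 0.0])
        for k, nm in enumerate(names):
            rows["names"].append(nm)
            rows["resn"].append(res_name)
            rows["rid"].append(li + 1)
            rows["xyz"].append(base + [0.3 * k, 0.2 * (k % 2), 1.9 * k])
    n_at = len(rows["names"])
    return Structure(rows["names"], rows["resn"], rows["rid"], ["L"] * n_at,
                     np.array(rows["xyz"]))
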