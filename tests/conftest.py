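import numpy as np
import pandas as pd
import pytest

from dmsort import design as design_mod
from dmsort import simulate as sim_mod
from dmsort import workflows

NON_SINGLE_CODON = "ACDEFGHIKLNPQRSTVY"  # standard residues minus M and W


@pytest.fixture(scope="session")
def usage():
    return design_mod.load_codon_usage()


@pytest.fixture(scope="session")
def small_library():
    """~500 missense variants + 20 synonymous control positions."""
    return workflows.demo_library(seed=7)


@pytest.fixture(scope="session")
def tiny_library():
    """A 5-position library for shape-level tests."""
    rng = np.random.default_rng(11)
    seq = "M" + "".join(rng.choice(list(NON_SINGLE_CODON), 6))
    lib = design_mod.enumerate_missense(seq, (2, 6), rng_seed=3)
    return design_mod.add_synonymous_controls(lib, [2, 3], rng_seed=4)


@pytest.fixture(scope="session")
def surface_experiment(small_library):
    """One simulated bimodal surface experiment at 100x depth, seed-fixed."""
    return sim_mod.simulate_experiment(
        small_library,
        sim_mod.surface_model(),
        sim_mod.surface_sort_spec(),
        depth_per_bin=100 * len(small_library.variants),
        unexpected_rate=0.005,
        seed=1,
    )


def make_pdb(atoms) -> str:
    """Render synthetic ATOM records.

    ``atoms``: iterable of (chain, resseq, resname, atom_name, element,
    (x, y, z)) or with a trailing (altloc, occupancy) tuple.
    """
    lines = []
    for serial, spec in enumerate(atoms, start=1):
        chain, resseq, resname, name, element, xyz = spec[:6]
        altloc, occ = spec[6] if len(spec) > 6 else (" ", 1.00)
        x, y, z = xyz
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{20.0:6.2f}"
            f"          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def pdb_writer(tmp_path):
    def _write(atoms, name="synthetic.pdb"):
        path = tmp_path / name
        path.write_text(make_pdb(atoms))
        return path

    return _write
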