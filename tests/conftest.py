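import numpy as np
import pytest

from andis import build_chain, default_table, derive_from_chains
from andis.structure import AtomRecord, ProteinChain, Residue
from andis.synthetic import make_training_corpus


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def hairpin_chain():
    """One 50-residue hairpin with all four default residue types."""
    rng = np.random.default_rng(123)
    seq = [["ALA", "GLY", "LEU", "SER"][int(i)]
           for i in rng.integers(0, 4, size=50)]
    return build_chain(seq, backbone="hairpin", rng=rng, dihedral_jitter=4.0)


@pytest.fixture(scope="session")
def small_potential():
    """Potential derived once from a 20-chain synthetic corpus."""
    chains = make_training_corpus(20, seed=5)
    return derive_from_chains(chains, mode="weighted")


def make_manual_chain(residue_specs, table=None):
    """Build a ProteinChain from explicit coordinates.

    ``residue_specs``: list of (residue_name, {atom_name: (x, y, z)}).
    """
    table = table or default_table()
    chain = ProteinChain(chain_id="A")
    for idx, (name, atoms) in enumerate(residue_specs, start=1):
        res = Residue(name=name, index=idx)
        for atom_name, xyz in atoms.items():
            res.atoms.append(AtomRecord(
                residue_name=name, atom_name=atom_name, residue_index=idx,
                coords=np.asarray(xyz, dtype=float),
                type_index=table.index(name, atom_name)))
        chain.residues.append(res)
    return chain


def three_pair_toy_chain():
    """Chain with exactly three scoring pairs below 7 A: residue 1's N
    against residue 9's N, CA and C; every other atom is far away."""
    overrides = {
        1: {"N": (0.0, 0.0, 0.0), "CA": (40.0, 0.0, 0.0),
            "C": (40.0, 1.5, 0.0), "O": (41.0, 2.0, 0.0)},
        9: {"N": (3.05, 0.0, 0.0), "CA": (3.05, 1.4, 0.0),
            "C": (4.45, 1.4, 0.0), "O": (4.95, 6.0, 0.0)},
    }
    return spaced_gly_chain(n_residues=15, spacing=300.0,
                            overrides=overrides)


def spaced_gly_chain(n_residues=15, spacing=100.0, overrides=None):
    """GLY chain whose residues sit on well-separated clusters, with
    optional per-residue coordinate overrides (1-based index)."""
    overrides = overrides or {}
    specs = []
    for k in range(1, n_residues + 1):
        if k in overrides:
            specs.append(("GLY", overrides[k]))
        else:
            z = spacing * k
            specs.append(("GLY", {"N": (0.0, 0.0, z),
                                  "CA": (1.5, 0.0, z),
                                  "C": (1.5, 1.5, z),
                                  "O": (2.5, 1.5, z + 1.0)}))
    return make_manual_chain(specs)
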