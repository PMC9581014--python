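import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from loopcraft import (MotifSpec, assemble_descriptor, build_peptide,
                       extract_loop_features, generate_motif_family,
                       write_structure)
from loopcraft.synthetic import HELIX_PHI_PSI, STRAND_PHI_PSI

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: a 30-position glycine-rich loop signature (fixed letters + free positions)
SIGNATURE = "xxxxxGAGLLGxxxxxxxxxxxxxxxxxxx"
TEMPLATE = ([STRAND_PHI_PSI] * 8 + [(-70.0, 150.0)] * 6
            + [HELIX_PHI_PSI] * 16)


def make_family(family_size=12, jitter=5.0, seed=42, flank_length=15):
    spec = MotifSpec(length=30, signature=SIGNATURE, template=TEMPLATE,
                     jitter=jitter, family_size=family_size,
                     flank_length=flank_length, seed=seed)
    return generate_motif_family(spec)


@pytest.fixture(scope="session")
def family():
    """(structures, true motif offsets) of a 12-member planted family."""
    return make_family()


@pytest.fixture(scope="session")
def family_instances(family):
    structures, offsets = family
    return [extract_loop_features(s, "A", off, 30)
            for s, off in zip(structures, offsets)]


@pytest.fixture(scope="session")
def family_descriptor(family_instances):
    return assemble_descriptor(family_instances, name="gly-rich", seed=0)


@pytest.fixture(scope="session")
def family_library(family):
    structures, _ = family
    return {s.id: s for s in structures}


@pytest.fixture
def helix():
    return build_peptide([HELIX_PHI_PSI] * 12, "A" * 12, structure_id="helix")


@pytest.fixture
def poly_ala_pdb(helix):
    """PDB text of a 3-residue poly-ALA peptide (15 ATOM records)."""
    short = build_peptide([HELIX_PHI_PSI] * 3, "AAA", structure_id="ala3")
    return write_structure(short)


def random_residue_structure(rng, n_residues=50, atoms_per_residue=4,
                             box=20.0, structure_id="random"):
    """Random-coordinate single-chain structure with backbone-named atoms
    (used for oracle-equivalence contact tests)."""
    from loopcraft import Atom, Residue, Structure
    names3 = ["ALA", "SER", "GLY", "LEU", "PRO", "THR", "VAL", "ASP"]
    chain = []
    for i in range(n_residues):
        r = Residue(name3=names3[int(rng.integers(0, len(names3)))],
                    chain_id="A", seq_index=i + 1)
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))[
                :atoms_per_residue]:
            r.atoms.append(Atom(name=name, element=element,
                                position=rng.uniform(0.0, box, size=3)))
        chain.append(r)
    return Structure(id=structure_id, chains={"A": chain})
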