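"""Shared fixtures: in-memory structures and toy peak lists."""

from __future__ import annotations

import gemmi
import pytest

from premap import PREParameters, StructureHandle


def build_structure(chains: dict[str, dict[int, tuple[str, dict[str, tuple[float, float, float]]]]],
                    name: str = "TOY") -> gemmi.Structure:
    """Assemble a gemmi structure from nested plain data.

    ``chains`` maps chain id -> {residue_number: (residue_name,
    {atom_name: (x, y, z)})}.
    """
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for chain_id, residues in chains.items():
        chain = gemmi.Chain(chain_id)
        for resnum in sorted(residues):
            resname, atoms = residues[resnum]
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            for atom_name, pos in atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.pos = gemmi.Position(*pos)
                atom.element = gemmi.Element(atom_name[0])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


@pytest.fixture
def toy_chains() -> dict:
    """Observed chain A with amides at known geometry; labeled chain B
    with one anchor C-alpha at the origin.

    Residue 1 sits at (3, 4, 0) — a 3-4-5 triangle with the anchor;
    residue 2 coincides with the anchor; residue 3 has no amide N
    modeled; residue 4 is a proline (excluded from amide references).
    """
    return {
        "A": {
            1: ("GLY", {"N": (3.0, 4.0, 0.0), "CA": (4.0, 4.0, 0.0)}),
            2: ("ALA", {"N": (0.0, 0.0, 0.0), "CA": (1.0, 0.0, 0.0)}),
            3: ("LEU", {"CA": (7.0, 0.0, 0.0)}),
            4: ("PRO", {"N": (0.0, 8.0, 0.0), "CA": (1.0, 8.0, 0.0)}),
        },
        "B": {
            151: ("ILE", {"CA": (0.0, 0.0, 0.0)}),
        },
    }


@pytest.fixture
def toy_handle(toy_chains) -> StructureHandle:
    st = build_structure(toy_chains)
    return StructureHandle(st, {"observed": "A", "labeled": "B"})


@pytest.fixture
def toy_pdb(tmp_path, toy_chains):
    path = tmp_path / "toy.pdb"
    build_structure(toy_chains).write_pdb(str(path))
    return path


@pytest.fixture
def params() -> PREParameters:
    return PREParameters()


TOY_PEAKLIST = """\
# toy paramagnetic list
  Assignment   w1      w2     Data Height   lw (hz)
    G42N-H   110.20   8.31     1.5e6         12.4
    A43N-HN  118.05   7.95     8.0e5         14.0
    L44N-H   121.40   8.77     2.2e6
"""


@pytest.fixture
def toy_peaklist_file(tmp_path):
    path = tmp_path / "toy.list"
    path.write_text(TOY_PEAKLIST)
    return path
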