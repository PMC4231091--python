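"""Crystal-structure reference distances for spin-label experiments.

Given a structure of the complex (PDB or mmCIF, parsed with gemmi), the
spin-label anchor is taken as the C-alpha atom of the labeled residue and
the reporter as the backbone amide nitrogen of each observed-chain
residue — the only proton-free convention available for an X-ray model.
Author residue numbering is preserved throughout so distances line up
with peak-list assignments.

Region averaging supports Table-style summaries (mean label-to-residue
distance over a helix, averaged over label sites).  Helix bounds for
cardiac troponin C (author numbering) are provided as an editable default
table; the exact residue sets behind any published average may differ, so
every region is overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import pandas as pd

from .core import DistanceEstimate, DistanceWindow

__all__ = [
    "LabelSite",
    "RegionDef",
    "ReferenceDistanceSet",
    "StructureHandle",
    "DEFAULT_TNC_REGIONS",
    "load_structure",
    "reference_distances",
    "region_average",
    "read_region_table",
    "write_reference_table",
    "amide_coordinates",
]

#: Cardiac troponin C helix bounds, author numbering, inclusive.  The
#: central linker range is the published 85-93; the helix bounds are the
#: canonical TnC assignments and are meant to be user-edited per study.
DEFAULT_TNC_REGIONS: dict[str, tuple[int, int]] = {
    "helixN": (3, 11),
    "helixA": (14, 28),
    "helixB": (38, 48),
    "helixC": (54, 64),
    "helixD": (74, 84),
    "central_linker": (85, 93),
    "helixE": (95, 104),
    "helixF": (105, 115),
    "helixG": (131, 141),
    "helixH": (151, 158),
}


@dataclass(frozen=True)
class LabelSite:
    """Anchor of a spin label: a residue on the labeled chain."""

    residue_id: int
    chain_role: str = "labeled"
    anchor_atom: str = "CA"


@dataclass(frozen=True)
class RegionDef:
    """A named inclusive residue interval on the observed chain."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"region {self.name}: empty range "
                             f"[{self.start}, {self.end}]")

    def __contains__(self, residue_id: int) -> bool:
        return self.start <= residue_id <= self.end


@dataclass
class StructureHandle:
    """A parsed structure plus the chain-role mapping in force."""

    structure: gemmi.Structure
    chain_map: dict[str, str]   # role ("observed"/"labeled") -> chain id

    def chain(self, role: str) -> gemmi.Chain:
        chain_id = self.chain_map[role]
        chain = self.structure[0].find_chain(chain_id)
        if chain is None:  # pragma: no cover - guarded at load time
            raise KeyError(chain_id)
        return chain

    def residue(self, role: str, residue_id: int) -> gemmi.Residue | None:
        for res in self.chain(role):
            if res.seqid.num == residue_id:
                return res
        return None

    def atom_position(self, role: str, residue_id: int,
                      atom_name: str) -> tuple[float, float, float] | None:
        res = self.residue(role, residue_id)
        if res is None:
            return None
        atom = res.find_atom(atom_name, "*")
        if atom is None:
            return None
        return (atom.pos.x, atom.pos.y, atom.pos.z)


@dataclass
class ReferenceDistanceSet:
    """Label-site to amide distances measured on one structure.

    ``entries`` holds (label_site, residue_id, distance in Angstrom)
    triples; residues whose amide atom is absent (prolines, chain breaks)
    are listed in ``skipped_residues`` and label sites missing from the
    model in ``unresolved_sites`` — absence is always explicit.
    """

    structure_id: str
    copy_selector: dict[str, str]
    entries: pd.DataFrame    # columns: label_site, residue_id, distance
    skipped_residues: list[int] = field(default_factory=list)
    unresolved_sites: list[int] = field(default_factory=list)

    def distances(self, label_site: int) -> dict[int, float]:
        sub = self.entries[self.entries["label_site"] == label_site]
        return dict(zip(sub["residue_id"], sub["distance"]))


def load_structure(path: str | Path,
                   chain_map: Mapping[str, str] | None = None,
                   ) -> StructureHandle:
    """Parse a PDB or mmCIF file and bind chain roles.

    ``chain_map`` maps ``observed`` (the isotope-labeled, NMR-visible
    chain) and ``labeled`` (the spin-label-carrying chain) to chain ids.
    Defaults to the first two chains of the first model, in file order —
    for multi-copy crystals only the mapped chains are ever used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    available = [ch.name for ch in model]
    if chain_map is None:
        if len(available) < 2:
            raise ValueError(
                f"{path.name}: need at least two chains to assign roles, "
                f"found {available}")
        chain_map = {"observed": available[0], "labeled": available[1]}
    chain_map = dict(chain_map)
    for role, chain_id in chain_map.items():
        if model.find_chain(chain_id) is None:
            raise ValueError(
                f"chain {chain_id!r} (role {role!r}) not in structure; "
                f"available chains: {available}")
    return StructureHandle(structure, chain_map)


def amide_coordinates(handle: StructureHandle, atom_name: str = "N",
                      role: str = "observed", skip_proline: bool = True
                      ) -> dict[int, tuple[float, float, float]]:
    """Coordinates of the chosen backbone atom for every residue of a
    chain, keyed by author residue number.

    Prolines are skipped by default: they carry a backbone nitrogen but
    no amide proton, hence no peak to reference.
    """
    coords: dict[int, tuple[float, float, float]] = {}
    for res in handle.chain(role):
        if skip_proline and res.name == "PRO":
            continue
        atom = res.find_atom(atom_name, "*")
        if atom is not None:
            coords[res.seqid.num] = (atom.pos.x, atom.pos.y, atom.pos.z)
    return coords


def _dist(a: Sequence[float], b: Sequence[float]) -> float:
    return math.dist(a, b)


def reference_distances(handle: StructureHandle,
                        sites: Sequence[LabelSite],
                        amide_atom: str = "N") -> ReferenceDistanceSet:
    """Distances from each label anchor to every observed-chain amide.

    Observed-chain residues lacking the amide atom are skipped but
    recorded; a label-site residue absent from the model (disordered
    segment) is reported in ``unresolved_sites`` rather than silently
    dropped.
    """
    rows: list[dict] = []
    skipped: set[int] = set()
    unresolved: list[int] = []
    amides = amide_coordinates(handle, amide_atom)
    for res in handle.chain("observed"):
        if res.seqid.num not in amides:
            skipped.add(res.seqid.num)
    for site in sites:
        anchor = handle.atom_position(site.chain_role, site.residue_id,
                                      site.anchor_atom)
        if anchor is None:
            unresolved.append(site.residue_id)
            continue
        for rid, pos in amides.items():
            rows.append({"label_site": site.residue_id,
                         "residue_id": rid,
                         "distance": _dist(anchor, pos)})
    entries = pd.DataFrame(rows, columns=["label_site", "residue_id",
                                          "distance"])
    return ReferenceDistanceSet(
        structure_id=handle.structure.name or "structure",
        copy_selector=dict(handle.chain_map),
        entries=entries,
        skipped_residues=sorted(skipped),
        unresolved_sites=unresolved,
    )


def region_average(dset: ReferenceDistanceSet | Sequence[DistanceEstimate],
                   region: RegionDef,
                   sites: Sequence[int] | None = None,
                   include_nonquantifiable: bool = False) -> float:
    """Arithmetic mean distance over all (site, residue) pairs in a region.

    Works on a crystal-reference set or on a list of experimental
    distance estimates.  For estimates, members flagged outside the
    quantifiable window are excluded unless explicitly included.
    Permutation-invariant by construction.
    """
    values: list[float] = []
    if isinstance(dset, ReferenceDistanceSet):
        sub = dset.entries
        if sites is not None:
            sub = sub[sub["label_site"].isin(sites)]
        sub = sub[(sub["residue_id"] >= region.start)
                  & (sub["residue_id"] <= region.end)]
        values = list(sub["distance"])
    else:
        for est in dset:
            if est.residue_id not in region:
                continue
            if (est.window is not DistanceWindow.quantifiable
                    and not include_nonquantifiable):
                continue
            if math.isfinite(est.r):
                values.append(est.r)
    if not values:
        raise ValueError(f"region {region.name}: no usable distances")
    return float(sum(values) / len(values))


def read_region_table(path: str | Path) -> list[RegionDef]:
    """Read regions from TSV columns (name, start, end); '#' comments."""
    regions: list[RegionDef] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if fields[0].lower() == "name":
            continue
        if len(fields) != 3:
            raise ValueError(f"region table line {lineno}: expected "
                             f"3 columns, got {len(fields)}")
        regions.append(RegionDef(fields[0], int(fields[1]), int(fields[2])))
    if not regions:
        raise ValueError("region table is empty")
    return regions


def default_regions() -> list[RegionDef]:
    return [RegionDef(name, lo, hi)
            for name, (lo, hi) in DEFAULT_TNC_REGIONS.items()]


def write_reference_table(dset: ReferenceDistanceSet,
                          path: str | Path,
                          header: Iterable[str] = ()) -> None:
    """Write the distance set as TSV (structure_id, site, residue, A)."""
    lines = [f"# {h}" for h in header]
    lines.append("structure_id\tlabel_site\tresidue_id\tdistance_A")
    for row in dset.entries.itertuples(index=False):
        lines.append(f"{dset.structure_id}\t{row.label_site}\t"
                     f"{row.residue_id}\t{row.distance:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")
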