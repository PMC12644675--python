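"""Interface metrics for homo-trimer coordinate models.

Contacts between peptide chains (intercatenane) and within one chain
(intracatenane) are classified by simple geometric criteria: van der Waals
contacts as carbon-carbon pairs within a distance cutoff, hydrogen bonds as
donor-acceptor heavy-atom pairs, and salt bridges as carboxylate to basic
nitrogen pairs.  Per-residue interchain C-alpha distance statistics and a
numerical solvent-accessible surface area complete the picture of how
tightly the three chains pack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "ContactCriteria",
    "Contact",
    "ContactTable",
    "CaDistanceStats",
    "read_structure",
    "write_structure",
    "classify_contacts",
    "ca_distance_stats",
    "sasa",
]


@dataclass
class StructureModel:
    """A coordinate model backed by an atom array with chain annotations."""

    atoms: struc.AtomArray
    name: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("structure contains non-finite coordinates")

    @property
    def chains(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    def chain(self, chain_id: str) -> struc.AtomArray:
        return self.atoms[self.atoms.chain_id == chain_id]

    def __len__(self) -> int:
        return self.atoms.array_length()

    def require_trimer(self):
        if len(self.chains) != 3:
            raise ValueError(
                f"trimer operation needs exactly 3 chains, found {self.chains}")


def read_structure(path, model: int = 1, keep_water: bool = False,
                   name: str | None = None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Multi-model files (NMR ensembles) yield the requested model; alternate
    locations resolve to the highest-occupancy atom; waters are excluded by
    default.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="occupancy")
    if not keep_water:
        atoms = atoms[~struc.filter_solvent(atoms)]
    atoms = atoms[atoms.element != "H"] if "H" in atoms.element else atoms
    return StructureModel(atoms=atoms, name=name or path.stem)


def write_structure(model: StructureModel, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))


@dataclass(frozen=True)
class ContactCriteria:
    """Distance cutoffs (Angstrom) per interaction type.

    ``intercatenane_cutoff`` caps the distance accepted for between-chain
    contacts of every type; by default it coincides with the per-type
    cutoffs so a single <= 4 A criterion governs interchain contacts.
    """

    vdw_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    saltbridge_cutoff: float = 4.0
    intercatenane_cutoff: float = 4.0

    def __post_init__(self):
        if min(self.vdw_cutoff, self.hbond_cutoff, self.saltbridge_cutoff,
               self.intercatenane_cutoff) <= 0:
            raise ValueError("all cutoffs must be positive")


@dataclass(frozen=True)
class Contact:
    force_type: str
    chain_i: str
    chain_j: str
    res_i: int
    res_j: int
    atom_i: str
    atom_j: str
    distance: float

    @property
    def intercatenane(self) -> bool:
        return self.chain_i != self.chain_j


@dataclass
class ContactTable:
    """Intra/inter counts per force type plus the contributing atom pairs."""

    contacts: list[Contact] = field(default_factory=list)

    def counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for c in self.contacts:
            row = out.setdefault(c.force_type,
                                 {"intra": 0, "inter": 0, "total": 0})
            row["inter" if c.intercatenane else "intra"] += 1
            row["total"] += 1
        return out

    def to_records(self) -> list[dict]:
        return [
            dict(force_type=c.force_type,
                 location="inter" if c.intercatenane else "intra",
                 chain_i=c.chain_i, chain_j=c.chain_j,
                 res_i=c.res_i, res_j=c.res_j,
                 atom_i=c.atom_i, atom_j=c.atom_j,
                 distance=round(c.distance, 3))
            for c in self.contacts
        ]


_ACIDIC = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASIC = {("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
          ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}
_HYDROXYL_O = {"OG", "OG1", "OH"}


def _pairs_within(coords_a, coords_b, cutoff, same_set):
    """Index pairs within cutoff; unordered-unique when both sets coincide."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return []
    tree_b = cKDTree(coords_b)
    pairs = []
    for i, neighbors in enumerate(cKDTree(coords_a).query_ball_tree(tree_b, cutoff)):
        for j in neighbors:
            if same_set and j <= i:
                continue
            pairs.append((i, j))
    return pairs


def _make_contacts(atoms, idx_a, idx_b, cutoff, force_type, same_set,
                   inter_cutoff, exclude):
    coords_a = atoms.coord[idx_a]
    coords_b = atoms.coord[idx_b]
    contacts = []
    for i, j in _pairs_within(coords_a, coords_b, cutoff, same_set):
        ia, jb = idx_a[i], idx_b[j]
        if ia == jb:
            continue
        if exclude(ia, jb):
            continue
        d = float(np.linalg.norm(atoms.coord[ia] - atoms.coord[jb]))
        inter = atoms.chain_id[ia] != atoms.chain_id[jb]
        if inter and d > inter_cutoff:
            continue
        contacts.append(Contact(
            force_type=force_type,
            chain_i=str(atoms.chain_id[ia]), chain_j=str(atoms.chain_id[jb]),
            res_i=int(atoms.res_id[ia]), res_j=int(atoms.res_id[jb]),
            atom_i=str(atoms.atom_name[ia]), atom_j=str(atoms.atom_name[jb]),
            distance=d))
    return contacts


def classify_contacts(model: StructureModel,
                      criteria: ContactCriteria | None = None) -> ContactTable:
    """Classify vdW, hydrogen-bond and salt-bridge contacts as intra/inter.

    Conventions (all distances between heavy atoms):

    * van der Waals: carbon-carbon pairs within ``vdw_cutoff``; pairs inside
      one residue or between sequence-adjacent residues of the same chain
      are excluded as covalent/1-3 neighbours.
    * hydrogen bonds: donor (any N, or hydroxyl O) to acceptor (any O) pairs
      within ``hbond_cutoff``; same-residue pairs and the backbone peptide
      N(i+1)-O(i) pair are excluded.
    * salt bridges: Asp/Glu carboxylate O to Arg/Lys/His basic N within
      ``saltbridge_cutoff``.

    Between-chain pairs must additionally satisfy ``intercatenane_cutoff``.
    """
    criteria = criteria or ContactCriteria()
    atoms = model.atoms
    n = atoms.array_length()
    chain = atoms.chain_id
    res = atoms.res_id

    def covalent_neighbors(ia, jb):
        return (chain[ia] == chain[jb]) and abs(int(res[ia]) - int(res[jb])) <= 1

    def same_residue(ia, jb):
        return chain[ia] == chain[jb] and res[ia] == res[jb]

    def peptide_no(ia, jb):
        if chain[ia] != chain[jb]:
            return False
        names = {atoms.atom_name[ia], atoms.atom_name[jb]}
        return names == {"N", "O"} and abs(int(res[ia]) - int(res[jb])) == 1

    contacts: list[Contact] = []

    carbon = np.nonzero(atoms.element == "C")[0]
    contacts += _make_contacts(
        atoms, carbon, carbon, criteria.vdw_cutoff, "vdW", True,
        criteria.intercatenane_cutoff, covalent_neighbors)

    is_n = atoms.element == "N"
    is_hydroxyl = np.isin(atoms.atom_name, sorted(_HYDROXYL_O))
    donors = np.nonzero(is_n | is_hydroxyl)[0]
    acceptors = np.nonzero(atoms.element == "O")[0]
    contacts += _make_contacts(
        atoms, donors, acceptors, criteria.hbond_cutoff, "hydrogen bond",
        False, criteria.intercatenane_cutoff,
        lambda ia, jb: same_residue(ia, jb) or peptide_no(ia, jb))

    key = [(str(r), str(a)) for r, a in zip(atoms.res_name, atoms.atom_name)]
    acidic = np.nonzero([k in _ACIDIC for k in key])[0]
    basic = np.nonzero([k in _BASIC for k in key])[0]
    contacts += _make_contacts(
        atoms, acidic, basic, criteria.saltbridge_cutoff, "salt bridge",
        False, criteria.intercatenane_cutoff, lambda ia, jb: False)

    return ContactTable(contacts=contacts)


@dataclass
class CaDistanceStats:
    """Interchain C-alpha distances per matched residue position.

    ``distances`` maps position (1-based after per-chain renumbering) to the
    three pairwise chain-chain distances; ``total`` sums every distance over
    all positions and chain pairs.
    """

    positions: list[int]
    residue_names: dict[int, str]
    distances: dict[int, np.ndarray]
    mean: dict[int, float]
    sd: dict[int, float]
    total: float


def ca_distance_stats(model: StructureModel) -> CaDistanceStats:
    """Distances between the C-alpha atoms of the same residue in all chains.

    Chains are matched by residue position after renumbering each chain from
    its first resolved residue; unmatched positions raise with the list of
    offending (chain, position) pairs.
    """
    model.require_trimer()
    atoms = model.atoms
    per_chain: dict[str, dict[int, np.ndarray]] = {}
    names: dict[int, str] = {}
    for cid in model.chains:
        ca = atoms[(atoms.chain_id == cid) & (atoms.atom_name == "CA")]
        if ca.array_length() == 0:
            raise ValueError(f"chain {cid} has no C-alpha atoms")
        start = int(ca.res_id.min())
        chain_map = {}
        for k in range(ca.array_length()):
            pos = int(ca.res_id[k]) - start + 1
            chain_map[pos] = ca.coord[k]
            names.setdefault(pos, str(ca.res_name[k]))
        per_chain[cid] = chain_map

    all_pos = sorted(set().union(*[set(m) for m in per_chain.values()]))
    unpaired = [(cid, p) for cid, m in per_chain.items()
                for p in all_pos if p not in m]
    if unpaired:
        raise ValueError(f"residue positions unmatched across chains: {unpaired}")

    c1, c2, c3 = (per_chain[cid] for cid in model.chains)
    distances, mean, sd = {}, {}, {}
    total = 0.0
    for pos in all_pos:
        a, b, c = c1[pos], c2[pos], c3[pos]
        d = np.array([np.linalg.norm(a - b), np.linalg.norm(a - c),
                      np.linalg.norm(b - c)])
        distances[pos] = d
        mean[pos] = float(d.mean())
        sd[pos] = float(d.std(ddof=0))
        total += float(d.sum())
    return CaDistanceStats(positions=all_pos, residue_names=names,
                           distances=distances, mean=mean, sd=sd, total=total)


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 1000,
    radii="ProtOr",
) -> tuple[float, dict[tuple[str, int], float]]:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Returns the total area and per-residue areas keyed by (chain, res_id).
    ``radii`` selects the van der Waals radius set ("ProtOr" group radii,
    "Single" element radii, or an explicit per-atom array); the result is
    deterministic for a fixed number of sphere points.
    """
    atoms = model.atoms
    try:
        per_atom = struc.sasa(atoms, probe_radius=probe_radius,
                              point_number=n_sphere_points, vdw_radii=radii)
    except Exception as exc:  # radius lookup failures name the atom
        raise ValueError(f"SASA radius assignment failed: {exc}") from exc
    bad = ~np.isfinite(per_atom)
    if np.any(bad):
        i = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"no radius for atom {atoms.atom_name[i]} "
            f"({atoms.res_name[i]} {atoms.res_id[i]}, chain {atoms.chain_id[i]})")
    per_residue: dict[tuple[str, int], float] = {}
    for k in range(atoms.array_length()):
        key = (str(atoms.chain_id[k]), int(atoms.res_id[k]))
        per_residue[key] = per_residue.get(key, 0.0) + float(per_atom[k])
    return float(per_atom.sum()), per_residue
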