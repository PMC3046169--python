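"""Reading protein-protein complexes and locating candidate interface residues.

A complex is read from PDB text together with a user-supplied chain split
defining the two sides of the interface. Atoms are reduced to a heavy-atom
model, each carrying physics parameters from a :class:`~hotspots.params.ParameterTable`.
Candidate residues for alanine mutation are interface residues (any heavy
atom within a cutoff of the partner side) excluding Ala, Gly and Pro.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from ._topology import (
    NON_MUTABLE,
    SIDE_CHAIN_ATOMS,
    STUB_ATOMS,
    THREE_TO_ONE,
    atom_element,
)
from .params import AtomParameters, ParameterTable

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 5.0  # Angstrom, heavy-atom interface definition


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: str  # PDB numbering; insertion code kept as suffix
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""


@dataclass(frozen=True)
class ResidueSite:
    """A candidate interface residue (alanine-mutable, with a beta carbon)."""

    chain_id: str
    residue_number: str
    wild_type: str  # 1-letter code
    cbeta_coords: np.ndarray

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.residue_number)


def _res_sort_key(resnum: str) -> tuple[int, str]:
    digits = ""
    for ch in resnum.lstrip("-"):
        if ch.isdigit():
            digits += ch
        else:
            break
    sign = -1 if resnum.startswith("-") else 1
    num = sign * int(digits) if digits else 0
    return (num, resnum[len(digits) + (sign < 0):])


@dataclass
class TypedComplex:
    """Heavy-atom two-sided complex with per-atom physics parameters.

    Parameters are exposed both per-atom (``params``) and as flat numpy
    arrays for vectorised energy evaluation.
    """

    atoms: list[AtomRecord]
    params: list[AtomParameters]
    side1_chains: frozenset[str]
    side2_chains: frozenset[str]

    coords: np.ndarray = field(init=False)
    rmin: np.ndarray = field(init=False)
    epsilon: np.ndarray = field(init=False)
    charge: np.ndarray = field(init=False)
    dg_free: np.ndarray = field(init=False)
    lam: np.ndarray = field(init=False)
    volume: np.ndarray = field(init=False)
    donor: np.ndarray = field(init=False)
    acceptor: np.ndarray = field(init=False)
    side: np.ndarray = field(init=False)  # 1 or 2 per atom
    residue_index: dict = field(init=False)

    def __post_init__(self) -> None:
        if self.side1_chains & self.side2_chains:
            both = sorted(self.side1_chains & self.side2_chains)
            raise ValueError(f"chains on both sides of the interface: {both}")
        if len(self.atoms) != len(self.params):
            raise ValueError("every atom must have parameters assigned")
        n = len(self.atoms)
        self.coords = np.array([a.coords for a in self.atoms], dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        p = self.params
        self.rmin = np.array([q.vdw_rmin for q in p])
        self.epsilon = np.array([q.vdw_epsilon for q in p])
        self.charge = np.array([q.partial_charge for q in p])
        self.dg_free = np.array([q.solv_dG_free for q in p])
        self.lam = np.array([q.solv_lambda for q in p])
        self.volume = np.array([q.solv_volume for q in p])
        self.donor = np.array([q.is_donor_heavy for q in p], dtype=bool)
        self.acceptor = np.array([q.is_acceptor for q in p], dtype=bool)
        self.side = np.empty(n, dtype=np.int8)
        self.residue_index = {}
        for i, a in enumerate(self.atoms):
            if a.chain_id in self.side1_chains:
                self.side[i] = 1
            elif a.chain_id in self.side2_chains:
                self.side[i] = 2
            else:
                raise ValueError(f"atom chain {a.chain_id!r} not assigned to a side")
            self.residue_index.setdefault((a.chain_id, a.residue_number), []).append(i)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_atoms(self, chain_id: str, residue_number: str) -> list[int]:
        key = (chain_id, str(residue_number))
        if key not in self.residue_index:
            raise KeyError(f"residue {key} not in complex")
        return self.residue_index[key]

    def atom_side(self, chain_id: str) -> int:
        return 1 if chain_id in self.side1_chains else 2


def read_complex(
    pdb_text: str,
    side1: set[str],
    side2: set[str],
    parameter_table: ParameterTable | None = None,
) -> TypedComplex:
    """Parse PDB text into a parameterised heavy-atom complex.

    Only the first model is used; altloc 'A' or blank atoms are kept;
    HETATM records, waters and hydrogens are dropped. Atoms with names
    absent from the parameter table receive element-based fallback
    parameters (with a logged warning).
    """
    side1, side2 = frozenset(side1), frozenset(side2)
    if side1 & side2:
        raise ValueError(f"chains on both sides: {sorted(side1 & side2)}")
    if parameter_table is None:
        parameter_table = ParameterTable.default()

    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]
    present = {chain.name for chain in model}
    for cid in sorted((side1 | side2) - present):
        raise ValueError(f"chain {cid} not found in PDB input")

    atoms: list[AtomRecord] = []
    params: list[AtomParameters] = []
    for chain in model:
        if chain.name not in side1 | side2:
            continue
        for res in chain:
            if res.het_flag == "H" or res.is_water():
                continue
            resnum = str(res.seqid.num) + (res.seqid.icode.strip() or "")
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                if atom.altloc not in ("", "A", "\0"):
                    continue
                elem = atom.element.name.upper() or atom_element(atom.name)
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=elem,
                        residue_name=res.name,
                        chain_id=chain.name,
                        residue_number=resnum,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        altloc=atom.altloc.strip("\0"),
                    )
                )
                params.append(parameter_table.lookup(res.name, atom.name))
    if not atoms:
        raise ValueError("no heavy atoms left after filtering")
    return TypedComplex(atoms, params, side1, side2)


def _candidate_site(complex: TypedComplex, chain_id: str, resnum: str) -> ResidueSite | None:
    """Build a ResidueSite if the residue is a valid mutation candidate."""
    idx = complex.residue_index[(chain_id, resnum)]
    res_name = complex.atoms[idx[0]].residue_name
    one = THREE_TO_ONE.get(res_name)
    if one is None or one in NON_MUTABLE:
        return None
    names = {complex.atoms[i].name: i for i in idx}
    if "CB" not in names:
        logger.warning("residue %s/%s has no CB; skipped", chain_id, resnum)
        return None
    expected = set(SIDE_CHAIN_ATOMS[res_name])
    missing = expected - set(names)
    if len(missing) > 2:
        logger.warning(
            "residue %s/%s missing %d side-chain atoms; skipped",
            chain_id, resnum, len(missing),
        )
        return None
    return ResidueSite(chain_id, resnum, one, complex.coords[names["CB"]].copy())


def find_interface_residues(
    complex: TypedComplex, contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> list[ResidueSite]:
    """Candidate residues with >=1 heavy atom within cutoff of the other side.

    Gly, Pro and Ala are excluded (no alanine mutation is possible), as are
    residues lacking a beta carbon or with more than two missing side-chain
    heavy atoms. The result is sorted by chain then residue number and is
    symmetric under relabelling of the two sides.
    """
    if not contact_cutoff > 0:
        raise ValueError("contact_cutoff must be positive")
    m1 = complex.side == 1
    m2 = complex.side == 2
    if not m1.any() or not m2.any():
        return []
    idx1 = np.flatnonzero(m1)
    idx2 = np.flatnonzero(m2)
    tree2 = cKDTree(complex.coords[idx2])
    pairs = cKDTree(complex.coords[idx1]).query_ball_tree(tree2, r=contact_cutoff)

    contact_keys: set[tuple[str, str]] = set()
    for local1, hits in enumerate(pairs):
        if not hits:
            continue
        a1 = complex.atoms[idx1[local1]]
        contact_keys.add((a1.chain_id, a1.residue_number))
        for local2 in hits:
            a2 = complex.atoms[idx2[local2]]
            contact_keys.add((a2.chain_id, a2.residue_number))

    sites = []
    for chain_id, resnum in contact_keys:
        site = _candidate_site(complex, chain_id, resnum)
        if site is not None:
            sites.append(site)
    sites.sort(key=lambda s: (s.chain_id, _res_sort_key(s.residue_number)))
    return sites


def side_chain_atoms(complex: TypedComplex, site: ResidueSite) -> np.ndarray:
    """Indices of the residue's heavy atoms beyond CB (removed by Ala mutation)."""
    idx = complex.residue_atoms(site.chain_id, site.residue_number)
    return np.array(
        [i for i in idx if complex.atoms[i].name not in STUB_ATOMS], dtype=int
    )
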