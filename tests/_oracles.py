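"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's vectorised code paths: energies
are summed atom pair by atom pair with the scalar potentials, and region
membership is decided by explicit predicates.
"""

from __future__ import annotations

import numpy as np

from hotspots._topology import STUB_ATOMS
from hotspots.energetics import (
    EnergyConfig,
    coulomb_pair,
    desolv_pair,
    hbond_pair,
    lj_pair,
)
from hotspots.params import AtomParameters
from hotspots.structure import AtomRecord, TypedComplex


def pair_energy(complex: TypedComplex, i: int, j: int, term: str,
                config: EnergyConfig) -> float:
    pi, pj = complex.params[i], complex.params[j]
    r = float(np.linalg.norm(complex.coords[i] - complex.coords[j]))
    if term == "vdw":
        return lj_pair(pi, pj, r, config)
    if term == "coulomb":
        return coulomb_pair(pi, pj, r, config)
    if term == "desolv":
        return desolv_pair(pi, pj, r, config)
    if term == "hbond":
        # both donor->acceptor orientations
        return hbond_pair(pi, pj, r, config) + hbond_pair(pj, pi, r, config)
    raise ValueError(term)


def brute_force_region_energy(complex: TypedComplex, set_a, set_b, term,
                              config=EnergyConfig()) -> float:
    total = 0.0
    for i in set_a:
        for j in set_b:
            total += pair_energy(complex, int(i), int(j), term, config)
    return total


def brute_force_regions(complex: TypedComplex, site, shell_radius):
    """Region membership by explicit predicates (indices a, b, c)."""
    cb = site.cbeta_coords
    own = set(complex.residue_atoms(site.chain_id, site.residue_number))
    own_side = complex.atom_side(site.chain_id)
    a, b, c = [], [], []
    for i, atom in enumerate(complex.atoms):
        d = float(np.linalg.norm(complex.coords[i] - cb))
        if i in own:
            if atom.name not in STUB_ATOMS:
                a.append(i)
            continue
        if d > shell_radius:
            continue
        (b if complex.side[i] == own_side else c).append(i)
    return a, b, c


def brute_force_energy_vector(complex: TypedComplex, site, shell_radius,
                              config=EnergyConfig()) -> dict:
    """Monolithic recomputation of the 12 features from membership predicates."""
    a, b, c = brute_force_regions(complex, site, shell_radius)
    out = {}
    for pairing, (sa, sb) in (("sc_inter", (a, c)), ("env_inter", (b, c)),
                              ("sc_intra", (a, b))):
        for term in ("vdw", "hbond", "coulomb", "desolv"):
            out[f"{term}_{pairing}"] = brute_force_region_energy(
                complex, sa, sb, term, config
            )
    return out


def random_typed_complex(n_atoms: int, seed: int, box: float = 12.0) -> TypedComplex:
    """A random two-sided complex with random physics parameters."""
    rng = np.random.default_rng(seed)
    atoms, params = [], []
    half = n_atoms // 2
    for i in range(n_atoms):
        chain = "A" if i < half else "B"
        atoms.append(AtomRecord(
            serial=i + 1, name="X", element="C", residue_name="UNK",
            chain_id=chain, residue_number=str(i + 1),
            coords=rng.uniform(0.0, box, 3),
        ))
        params.append(AtomParameters(
            vdw_rmin=rng.uniform(1.5, 2.1),
            vdw_epsilon=rng.uniform(0.05, 0.5),
            partial_charge=rng.uniform(-0.6, 0.6),
            solv_dG_free=rng.uniform(-10.0, 1.0),
            solv_lambda=float(rng.choice([3.5, 6.0])),
            solv_volume=rng.uniform(5.0, 25.0),
            is_donor_heavy=bool(rng.random() < 0.4),
            is_acceptor=bool(rng.random() < 0.4),
        ))
    return TypedComplex(atoms, params, frozenset("A"), frozenset("B"))


def random_rotation(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A uniform random rotation matrix and a random translation."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-20.0, 20.0, 3)


def transform_complex(complex: TypedComplex, rot: np.ndarray, trans: np.ndarray) -> TypedComplex:
    atoms = [
        AtomRecord(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                   a.residue_number, rot @ a.coords + trans, a.occupancy, a.altloc)
        for a in complex.atoms
    ]
    return TypedComplex(atoms, list(complex.params),
                        complex.side1_chains, complex.side2_chains)
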