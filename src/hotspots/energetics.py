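"""Pairwise energy terms over the three structural regions of a mutation site.

For a candidate residue, atoms are partitioned into: (a) the mutated
side chain beyond CB, (b) same-side atoms within a shell of the site's CB,
and (c) partner-side atoms within that shell. Four pairwise molecular-
mechanics terms (Lennard-Jones, hydrogen bond, Coulomb, desolvation) are
summed over the three region pairings a*c (side-chain inter-molecular),
b*c (environment inter-molecular) and a*b (side-chain intra-molecular),
giving 12 energy features per residue. The environment term deliberately
excludes the mutated side chain, so it measures the interface context the
mutation leaves behind.

Functional forms (all constants in :class:`EnergyConfig`):

* 12-6 Lennard-Jones, ``eps_ij = sqrt(eps_i eps_j)``,
  ``rmin_ij = rmin_i + rmin_j``, each pair capped at +10 kcal/mol so a
  single modelled clash cannot dominate a feature;
* 12-10 hydrogen-bond well on heavy-atom donor-acceptor distance
  (depth 2.0 kcal/mol at 2.9 A, zero outside [2.0, 3.5] A);
* Coulomb with distance-dependent dielectric ``eps(r) = 4r``;
* symmetric Gaussian solvent-exclusion desolvation with a 9 A cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AtomParameters
from .structure import ResidueSite, TypedComplex, side_chain_atoms

TERMS = ("vdw", "hbond", "coulomb", "desolv")
PAIRINGS = ("sc_inter", "env_inter", "sc_intra")
#: Canonical order of the 12 energy features (region-major, matching the
#: scoring-function weight tables).
FEATURE_NAMES = tuple(f"{t}_{p}" for p in PAIRINGS for t in TERMS)

DEFAULT_SHELL_RADIUS = 10.0  # Angstrom


@dataclass(frozen=True)
class EnergyConfig:
    shell_radius: float = DEFAULT_SHELL_RADIUS
    lj_cap: float = 10.0            # kcal/mol, per-pair clash cap
    hb_epsilon: float = 2.0         # kcal/mol, well depth
    hb_r0: float = 2.9              # Angstrom, well minimum
    hb_rmin: float = 2.0            # Angstrom, lower distance window
    hb_rmax: float = 3.5            # Angstrom, upper distance window
    coulomb_k: float = 332.0637     # kcal*A/(mol*e^2)
    dielectric_slope: float = 4.0   # eps(r) = slope * r
    desolv_cutoff: float = 9.0      # Angstrom


DEFAULT_CONFIG = EnergyConfig()


# ---------------------------------------------------------------------------
# Scalar pair potentials (the reference forms; vectorised sums below).

def lj_pair(pi: AtomParameters, pj: AtomParameters, r: float,
            config: EnergyConfig = DEFAULT_CONFIG) -> float:
    """12-6 Lennard-Jones energy of one atom pair, kcal/mol."""
    if r <= 0:
        raise ValueError("zero interatomic distance (clashing duplicate atom)")
    eps = np.sqrt(pi.vdw_epsilon * pj.vdw_epsilon)
    rmin = pi.vdw_rmin + pj.vdw_rmin
    x6 = (rmin / r) ** 6
    return min(eps * (x6 * x6 - 2.0 * x6), config.lj_cap)


def hbond_pair(donor: AtomParameters, acceptor: AtomParameters, r: float,
               config: EnergyConfig = DEFAULT_CONFIG) -> float:
    """12-10 hydrogen-bond energy for a donor->acceptor heavy-atom pair."""
    if not (donor.is_donor_heavy and acceptor.is_acceptor):
        return 0.0
    if r > config.hb_rmax or r < config.hb_rmin:
        return 0.0
    x = config.hb_r0 / r
    return config.hb_epsilon * (5.0 * x**12 - 6.0 * x**10)


def coulomb_pair(pi: AtomParameters, pj: AtomParameters, r: float,
                 config: EnergyConfig = DEFAULT_CONFIG) -> float:
    """Coulomb energy with distance-dependent dielectric eps(r) = 4r."""
    if r <= 0:
        raise ValueError("zero interatomic distance")
    return (config.coulomb_k * pi.partial_charge * pj.partial_charge
            / (config.dielectric_slope * r * r))


def desolv_pair(pi: AtomParameters, pj: AtomParameters, r: float,
                config: EnergyConfig = DEFAULT_CONFIG) -> float:
    """Symmetric Gaussian solvent-exclusion desolvation energy, kcal/mol."""
    if r <= 0:
        raise ValueError("zero interatomic distance")
    if r > config.desolv_cutoff:
        return 0.0

    def f(pa: AtomParameters, pb: AtomParameters) -> float:
        pref = pa.solv_dG_free / (2.0 * np.pi ** 1.5 * pa.solv_lambda * r * r)
        return pref * np.exp(-(((r - pa.vdw_rmin) / pa.solv_lambda) ** 2)) * pb.solv_volume

    return -f(pi, pj) - f(pj, pi)


# ---------------------------------------------------------------------------
# Vectorised region sums.

def _check_disjoint(set_a: np.ndarray, set_b: np.ndarray) -> None:
    if np.intersect1d(set_a, set_b).size:
        raise ValueError("overlapping atom sets in region energy")


def _pair_distances(complex: TypedComplex, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    d = complex.coords[ia][:, None, :] - complex.coords[ib][None, :, :]
    r = np.sqrt((d * d).sum(axis=2))
    if np.any(r <= 0):
        raise ValueError("zero interatomic distance between regions")
    return r


def region_energy(complex: TypedComplex, set_a: np.ndarray, set_b: np.ndarray,
                  term: str, config: EnergyConfig = DEFAULT_CONFIG) -> float:
    """Sum of one pair potential over all cross pairs of two disjoint atom sets.

    For the hydrogen-bond term both donor/acceptor orientations are summed,
    which makes every term symmetric in its two arguments.
    """
    ia = np.asarray(set_a, dtype=int)
    ib = np.asarray(set_b, dtype=int)
    if ia.size == 0 or ib.size == 0:
        return 0.0
    _check_disjoint(ia, ib)
    r = _pair_distances(complex, ia, ib)

    if term == "vdw":
        eps = np.sqrt(np.outer(complex.epsilon[ia], complex.epsilon[ib]))
        rmin = complex.rmin[ia][:, None] + complex.rmin[ib][None, :]
        x6 = (rmin / r) ** 6
        e = np.minimum(eps * (x6 * x6 - 2.0 * x6), config.lj_cap)
        return float(e.sum())
    if term == "hbond":
        window = (r >= config.hb_rmin) & (r <= config.hb_rmax)
        if not window.any():
            return 0.0
        x = np.where(window, config.hb_r0 / np.where(window, r, 1.0), 0.0)
        well = config.hb_epsilon * (5.0 * x**12 - 6.0 * x**10)
        orient = (
            np.outer(complex.donor[ia], complex.acceptor[ib]).astype(float)
            + np.outer(complex.acceptor[ia], complex.donor[ib]).astype(float)
        )
        return float((well * orient * window).sum())
    if term == "coulomb":
        qq = np.outer(complex.charge[ia], complex.charge[ib])
        return float((config.coulomb_k * qq / (config.dielectric_slope * r * r)).sum())
    if term == "desolv":
        mask = r <= config.desolv_cutoff
        if not mask.any():
            return 0.0

        def f(da, lam_a, rmin_a, vol_b, rr):
            pref = da[:, None] / (2.0 * np.pi ** 1.5 * lam_a[:, None] * rr * rr)
            gauss = np.exp(-(((rr - rmin_a[:, None]) / lam_a[:, None]) ** 2))
            return pref * gauss * vol_b[None, :]

        e = -(
            f(complex.dg_free[ia], complex.lam[ia], complex.rmin[ia],
              complex.volume[ib], r)
            + f(complex.dg_free[ib], complex.lam[ib], complex.rmin[ib],
                complex.volume[ia], r.T).T
        )
        return float((e * mask).sum())
    raise ValueError(f"unknown energy term {term!r}")


# ---------------------------------------------------------------------------
# Region partition and the 12-feature vector.

@dataclass(frozen=True)
class RegionPartition:
    """The three atom sets around a mutation site (indices into the complex)."""

    region_a: np.ndarray  # mutated side chain beyond CB
    region_b: np.ndarray  # same-side shell, minus a and the site's stub
    region_c: np.ndarray  # partner-side shell
    shell_radius: float


def partition_regions(
    complex: TypedComplex, site: ResidueSite,
    shell_radius: float = DEFAULT_SHELL_RADIUS,
) -> RegionPartition:
    if not shell_radius > 0:
        raise ValueError("shell_radius must be positive")
    cb = np.asarray(site.cbeta_coords, dtype=float)
    if cb.shape != (3,) or not np.all(np.isfinite(cb)):
        raise ValueError(f"site {site.key} has no usable CB coordinates")
    region_a = side_chain_atoms(complex, site)
    own = set(complex.residue_atoms(site.chain_id, site.residue_number))

    dist = np.linalg.norm(complex.coords - cb, axis=1)
    in_shell = dist <= shell_radius
    own_side = complex.atom_side(site.chain_id)
    same_side = complex.side == own_side

    b_mask = in_shell & same_side
    b_idx = np.array(
        [i for i in np.flatnonzero(b_mask) if i not in own], dtype=int
    )
    c_idx = np.flatnonzero(in_shell & ~same_side).astype(int)
    return RegionPartition(region_a, b_idx, c_idx, shell_radius)


def energy_vector(
    complex: TypedComplex, site: ResidueSite,
    shell_radius: float = DEFAULT_SHELL_RADIUS,
    config: EnergyConfig | None = None,
) -> pd.Series:
    """The 12 per-residue energy features, kcal/mol, in canonical order."""
    if config is None:
        config = EnergyConfig(shell_radius=shell_radius)
    part = partition_regions(complex, site, shell_radius)
    regions = {
        "sc_inter": (part.region_a, part.region_c),
        "env_inter": (part.region_b, part.region_c),
        "sc_intra": (part.region_a, part.region_b),
    }
    values = {
        f"{term}_{pairing}": region_energy(complex, sa, sb, term, config)
        for pairing, (sa, sb) in regions.items()
        for term in TERMS
    }
    return pd.Series([values[name] for name in FEATURE_NAMES],
                     index=list(FEATURE_NAMES), dtype=float)
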