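"""Per-atom physics parameters.

A parameter table assigns every heavy atom of a standard residue its
Lennard-Jones radius and well depth, a simplified partial charge, Gaussian
solvent-exclusion (EEF1-style) solvation parameters, and hydrogen-bond
donor/acceptor flags. The bundled default table is a whitespace-delimited
text file (``data/atom_params.tsv``) so users can substitute their own
parameter set with the same columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from ._topology import atom_element

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AtomParameters:
    """Physics parameters carried by one heavy atom.

    vdw_rmin is the per-atom contribution to the pair minimum-energy
    distance (Angstrom, combined additively); vdw_epsilon the well depth
    (kcal/mol, combined geometrically). Solvation parameters follow the
    Gaussian solvent-exclusion model: dG_free (kcal/mol), correlation
    length lambda (Angstrom) and excluded volume (Angstrom^3).
    """

    vdw_rmin: float
    vdw_epsilon: float
    partial_charge: float
    solv_dG_free: float
    solv_lambda: float
    solv_volume: float
    is_donor_heavy: bool
    is_acceptor: bool

    def __post_init__(self) -> None:
        if not self.vdw_rmin > 0:
            raise ValueError("vdw_rmin must be positive")
        if self.vdw_epsilon < 0:
            raise ValueError("vdw_epsilon must be non-negative")
        if not self.solv_lambda > 0:
            raise ValueError("solv_lambda must be positive")
        if self.solv_volume < 0:
            raise ValueError("solv_volume must be non-negative")


# Fallback parameters for atoms missing from the table, keyed by element.
# Neutral, non-H-bonding, element-typical vdW and mild solvation.
_ELEMENT_FALLBACK = {
    "C": AtomParameters(1.95, 0.07, 0.0, 0.0, 3.5, 15.0, False, False),
    "N": AtomParameters(1.75, 0.17, 0.0, -5.0, 3.5, 5.0, False, False),
    "O": AtomParameters(1.70, 0.12, 0.0, -5.0, 3.5, 12.0, False, False),
    "S": AtomParameters(2.00, 0.45, 0.0, -3.0, 3.5, 21.0, False, False),
}
_GENERIC_FALLBACK = AtomParameters(1.90, 0.10, 0.0, 0.0, 3.5, 15.0, False, False)


class ParameterTable:
    """Lookup of AtomParameters by (residue_name, atom_name)."""

    def __init__(self, entries: dict[tuple[str, str], AtomParameters]):
        self._entries = dict(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterTable":
        df = pd.read_csv(path, sep=r"\s+")
        required = {
            "residue", "atom", "vdw_rmin", "vdw_epsilon", "charge",
            "solv_dg_free", "solv_lambda", "solv_volume", "donor", "acceptor",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"parameter table missing columns: {sorted(missing)}")
        entries = {}
        for row in df.itertuples(index=False):
            entries[(row.residue, row.atom)] = AtomParameters(
                vdw_rmin=float(row.vdw_rmin),
                vdw_epsilon=float(row.vdw_epsilon),
                partial_charge=float(row.charge),
                solv_dG_free=float(row.solv_dg_free),
                solv_lambda=float(row.solv_lambda),
                solv_volume=float(row.solv_volume),
                is_donor_heavy=bool(row.donor),
                is_acceptor=bool(row.acceptor),
            )
        return cls(entries)

    @classmethod
    def default(cls) -> "ParameterTable":
        with resources.as_file(
            resources.files("hotspots.data").joinpath("atom_params.tsv")
        ) as path:
            return cls.from_file(path)

    def lookup(self, residue_name: str, atom_name: str) -> AtomParameters:
        """Parameters for an atom; element-based fallback with a warning."""
        try:
            return self._entries[(residue_name, atom_name)]
        except KeyError:
            try:
                elem = atom_element(atom_name)
            except ValueError:
                elem = ""
            params = _ELEMENT_FALLBACK.get(elem, _GENERIC_FALLBACK)
            logger.warning(
                "no parameters for atom %s/%s; using element fallback (%s)",
                residue_name, atom_name, elem or "generic",
            )
            return params

    def __len__(self) -> int:
        return len(self._entries)
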