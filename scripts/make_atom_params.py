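#!/usr/bin/env python
"""Regenerate the bundled atom-parameter table.

Writes ``src/hotspots/data/atom_params.tsv``: per-(residue, atom) LJ
radius/depth, simplified partial charges on polar and charged groups,
EEF1-style solvation parameters and hydrogen-bond donor/acceptor flags.
Edit the dictionaries below to derive an alternative parameter set.
"""

from pathlib import Path

from hotspots._topology import SIDE_CHAIN_ATOMS, atom_element, residue_heavy_atoms

OUT = Path(__file__).resolve().parent.parent / "src/hotspots/data/atom_params.tsv"

AROMATIC = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}
SP2_C = {  # carbonyl / carboxyl / guanidinium carbons
    ("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"), ("GLN", "CD"), ("ARG", "CZ"),
}
CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
CARBOXYL_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
HYDROXYL_O = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}

CHARGES = {
    ("*", "N"): -0.30, ("*", "CA"): 0.10, ("*", "C"): 0.40, ("*", "O"): -0.45,
    ("ASP", "CG"): 0.10, ("ASP", "OD1"): -0.55, ("ASP", "OD2"): -0.55,
    ("GLU", "CD"): 0.10, ("GLU", "OE1"): -0.55, ("GLU", "OE2"): -0.55,
    ("LYS", "CE"): 0.10, ("LYS", "NZ"): 0.90,
    ("ARG", "CZ"): 0.20, ("ARG", "NE"): 0.10,
    ("ARG", "NH1"): 0.35, ("ARG", "NH2"): 0.35,
    ("HIS", "ND1"): -0.05, ("HIS", "NE2"): -0.05,
    ("SER", "OG"): -0.35, ("THR", "OG1"): -0.35, ("TYR", "OH"): -0.35,
    ("ASN", "OD1"): -0.45, ("ASN", "ND2"): -0.25,
    ("GLN", "OE1"): -0.45, ("GLN", "NE2"): -0.25,
    ("TRP", "NE1"): -0.15, ("CYS", "SG"): -0.10, ("MET", "SD"): -0.05,
}

DONORS = {("*", "N")} | CHARGED_N | HYDROXYL_O | {
    ("ASN", "ND2"), ("GLN", "NE2"), ("HIS", "ND1"), ("HIS", "NE2"),
    ("TRP", "NE1"),
}
ACCEPTORS = {("*", "O")} | CARBOXYL_O | HYDROXYL_O | {
    ("ASN", "OD1"), ("GLN", "OE1"), ("HIS", "ND1"), ("HIS", "NE2"),
}

# per-element LJ: (rmin contribution in A, well depth kcal/mol)
VDW = {"C": (1.95, 0.07), "N": (1.75, 0.17), "O": (1.70, 0.12), "S": (2.00, 0.45)}


def solvation(res: str, atom: str, elem: str) -> tuple[float, float, float]:
    """(dG_free kcal/mol, lambda A, volume A^3) by coarse atom class."""
    if elem == "C":
        if atom in AROMATIC.get(res, ()):
            return (0.08, 3.5, 18.0)
        if (res, atom) in SP2_C or atom == "C":
            return (0.00, 3.5, 10.0)
        return (0.52, 3.5, 20.0)
    if elem == "N":
        if (res, atom) in CHARGED_N:
            return (-10.00, 6.0, 8.0)
        return (-5.95, 3.5, 5.0)
    if elem == "O":
        if (res, atom) in CARBOXYL_O:
            return (-10.00, 6.0, 11.0)
        if (res, atom) in HYDROXYL_O:
            return (-6.70, 3.5, 11.0)
        return (-5.33, 3.5, 12.0)
    if elem == "S":
        return (-3.24, 3.5, 21.0)
    raise ValueError(elem)


def main() -> None:
    rows = []
    for res in sorted(SIDE_CHAIN_ATOMS):
        for atom in residue_heavy_atoms(res):
            elem = atom_element(atom)
            rmin, eps = VDW[elem]
            q = CHARGES.get((res, atom), CHARGES.get(("*", atom), 0.0))
            dg, lam, vol = solvation(res, atom, elem)
            donor = int(
                (res, atom) in DONORS
                or (("*", atom) in DONORS and not (res == "PRO" and atom == "N"))
            )
            acc = int((res, atom) in ACCEPTORS or ("*", atom) in ACCEPTORS)
            rows.append((res, atom, rmin, eps, q, dg, lam, vol, donor, acc))

    with open(OUT, "w") as fh:
        fh.write("residue\tatom\tvdw_rmin\tvdw_epsilon\tcharge\tsolv_dg_free"
                 "\tsolv_lambda\tsolv_volume\tdonor\tacceptor\n")
        for r in rows:
            fh.write("{}\t{}\t{:.2f}\t{:.3f}\t{:+.2f}\t{:+.2f}\t{:.1f}\t{:.1f}"
                     "\t{}\t{}\n".format(*r))
    print(f"wrote {len(rows)} rows to {OUT}")


if __name__ == "__main__":
    main()
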