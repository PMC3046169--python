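"""Synthetic complexes and feature datasets with known ground truth.

Two generators make every pipeline stage testable without structure
downloads:

* :func:`generate_toy_complex` builds an idealized two-chain complex in
  PDB text. Chains run along parallel axes; "planted" residues have
  their side chains oriented across the gap so they make close
  inter-chain contacts, everything else points away. The geometry is
  deliberately cartoonish — the energy terms only need finite,
  contact-bearing coordinates, not physical conformations.

* :func:`generate_feature_dataset` draws energy-feature rows from a
  seeded multivariate normal and derives ddG from a known linear scoring
  function, ``ddg = a (w* . x - b) + noise``, so weight recovery and
  classifier performance can be checked against planted truth. Label
  prevalence is calibrated to ~22% hot spots, the minority-class regime
  of real alanine-scanning compilations. Per-amino-acid weight overrides
  allow planting signal that a single general classifier cannot capture.

Both generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._topology import ONE_TO_THREE, SIDE_CHAIN_ATOMS, atom_element
from .energetics import FEATURE_NAMES
from .features import DEFAULT_DDG_THRESHOLD, META_COLUMNS, MutationRecord, label_hotspots

# Distance from a planted side-chain tip to the partner chain axis. The
# facing partner residue's CB reaches 1.5 A inward, so the closest
# cross-side contact sits near 3.8 A — inside the 4 A "planted contact"
# guarantee and close to the Lennard-Jones minimum (favorable, not clashing).
DEFAULT_PLANT_GAP = 5.3


@dataclass(frozen=True)
class ToyComplexSpec:
    """Blueprint for an idealized two-chain complex."""

    chains: dict  # chain id -> 1-letter sequence (exactly two chains)
    separation: float = 10.0  # Angstrom between the two chain axes
    planted: dict = field(default_factory=dict)  # chain -> {res index: tip gap}
    jitter_sd: float = 0.05  # Angstrom, Gaussian coordinate jitter
    seed: int = 0
    spacing: float = 3.8  # Angstrom between consecutive CA atoms

    def __post_init__(self) -> None:
        if len(self.chains) != 2:
            raise ValueError("a toy complex has exactly two chains")
        for cid, seq in self.chains.items():
            if not seq:
                raise ValueError(f"chain {cid} has an empty sequence")
            for aa in seq:
                if aa not in ONE_TO_THREE:
                    raise ValueError(f"invalid amino-acid letter {aa!r} in chain {cid}")
        if not self.separation > 0:
            raise ValueError("separation must be positive")
        for cid, idxs in self.planted.items():
            if cid not in self.chains:
                raise ValueError(f"planted chain {cid!r} not in complex")
            for i in idxs:
                if not 0 <= i < len(self.chains[cid]):
                    raise ValueError(f"planted index {i} outside chain {cid}")


def _pdb_line(serial, name, res3, chain, resnum, xyz, element) -> str:
    return (
        f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def generate_toy_complex(spec: ToyComplexSpec) -> tuple[str, dict]:
    """Emit deterministic PDB text plus a truth record of planted contacts."""
    rng = np.random.default_rng(spec.seed)
    chain_ids = sorted(spec.chains)
    axis_y = {chain_ids[0]: 0.0, chain_ids[1]: spec.separation}
    inward = {chain_ids[0]: 1.0, chain_ids[1]: -1.0}

    lines = []
    serial = 0
    planted_truth = []
    for cid in chain_ids:
        seq = spec.chains[cid]
        y0, d = axis_y[cid], inward[cid]
        y_partner = axis_y[chain_ids[1]] if cid == chain_ids[0] else axis_y[chain_ids[0]]
        plant = {int(k): float(v) if v is not None else DEFAULT_PLANT_GAP
                 for k, v in spec.planted.get(cid, {}).items()}
        for i, aa in enumerate(seq):
            res3 = ONE_TO_THREE[aa]
            x = i * spec.spacing
            positions = {
                "N": (x - 0.6, y0, -0.6),
                "CA": (x, y0, 0.0),
                "C": (x + 0.8, y0, 0.6),
                "O": (x + 1.4, y0 - d * 0.4, 1.3),
            }
            side_atoms = SIDE_CHAIN_ATOMS[res3]
            if res3 != "GLY":
                cb = np.array([x, y0 + d * 1.5, 0.3])
                positions["CB"] = tuple(cb)
                if i in plant and side_atoms:
                    tip = np.array([x, y_partner - d * plant[i], 0.0])
                    m = len(side_atoms)
                    for k, name in enumerate(side_atoms):
                        t = (k + 1) / m
                        pos = cb + t * (tip - cb)
                        # stagger z so successive atoms never coincide
                        positions[name] = (pos[0] + 0.15 * ((k % 2) - 0.5),
                                           pos[1], pos[2] + 0.05 * k)
                    planted_truth.append((cid, str(i + 1), aa))
                else:
                    for k, name in enumerate(side_atoms):
                        positions[name] = (
                            x + 0.3 * ((k % 2) - 0.5),
                            y0 - d * (1.0 + 1.4 * (k + 1)),
                            0.3 + 0.05 * k,
                        )
            for name in ("N", "CA", "C", "O", "CB", *side_atoms):
                if name not in positions:
                    continue
                serial += 1
                xyz = np.asarray(positions[name]) + rng.normal(0.0, spec.jitter_sd, 3)
                lines.append(
                    _pdb_line(serial, name, res3, cid, i + 1, xyz, atom_element(name))
                )
        lines.append(f"TER   {serial + 1:5d}      {ONE_TO_THREE[seq[-1]]:>3s} "
                     f"{cid}{len(seq):4d}\n")
    lines.append("END\n")
    truth = {
        "planted": planted_truth,
        "side1": {chain_ids[0]}, "side2": {chain_ids[1]},
        "sequences": dict(spec.chains),
    }
    return "".join(lines), truth


def demo_training_set(n_complexes: int = 6, seed: int = 0):
    """Toy complexes with planted hot spots plus matching mutation records.

    Each complex is its own homology cluster. Planted residues (strong
    cross-interface contacts) receive hot-spot ddG values (2.5-4 kcal/mol),
    the remaining interface residues cold ones (0-1 kcal/mol); rotating the
    sequences across complexes sweeps the planted positions through the
    amino-acid types, so Arg and Glu occur both hot and cold.
    Returns ``(complexes, records)`` where ``complexes`` maps complex id to
    PDB text (sides are always chain A vs chain B).
    """
    from .structure import find_interface_residues, read_complex

    rng = np.random.default_rng(seed)
    aa_pool = "RENKDWYTSQLF"
    complexes: dict[str, str] = {}
    records: list[MutationRecord] = []
    for k in range(n_complexes):
        seq_a = "".join(aa_pool[(k + i) % len(aa_pool)] for i in range(12))
        seq_b = "".join(aa_pool[(k + 5 + i) % len(aa_pool)] for i in range(12))
        spec = ToyComplexSpec(
            chains={"A": seq_a, "B": seq_b},
            separation=10.0,
            planted={"A": {2: None, 5: None, 8: None}, "B": {4: None, 7: None}},
            jitter_sd=0.05,
            seed=seed * 1000 + k,
        )
        pdb_text, truth = generate_toy_complex(spec)
        cid = f"toy{k}"
        complexes[cid] = pdb_text
        cx = read_complex(pdb_text, {"A"}, {"B"})
        planted_keys = {(c, r) for c, r, _ in truth["planted"]}
        for site in find_interface_residues(cx):
            hot = site.key in planted_keys
            ddg = rng.uniform(2.5, 4.0) if hot else rng.uniform(0.0, 1.0)
            records.append(MutationRecord(
                cid, site.chain_id, site.residue_number, site.wild_type,
                float(ddg), f"c{k}",
            ))
    return complexes, records


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Blueprint for a planted-signal feature dataset."""

    n_rows: int = 500
    true_weights: dict = field(default_factory=lambda: {
        "vdw_sc_inter": -1.0, "hbond_sc_inter": -0.7, "desolv_sc_inter": -0.5,
        "vdw_env_inter": -0.4, "vdw_sc_intra": -0.3,
    })
    threshold: float | None = None  # decision offset b; None -> calibrated
    label_noise: float = 0.05
    ddg_noise_sd: float = 0.5  # kcal/mol
    ddg_scale: float = 1.5  # a in ddg = a*(w.x - b) + noise
    ddg_threshold: float = DEFAULT_DDG_THRESHOLD
    hotspot_prevalence: float = 0.225  # used only when threshold is None
    aa_composition: dict = field(default_factory=lambda: {
        "R": 0.14, "E": 0.14, "K": 0.10, "D": 0.09, "N": 0.09, "W": 0.08,
        "Y": 0.08, "S": 0.07, "T": 0.07, "L": 0.05, "I": 0.05, "F": 0.04,
    })
    aa_true_weights: dict = field(default_factory=dict)  # aa -> weight dict
    n_clusters: int = 8
    covariance: tuple | None = None  # 12x12, row-major; None -> identity
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        unknown = set(self.true_weights) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names in true_weights: {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    table: pd.DataFrame
    records: list
    truth: dict


def _weight_vector(weights: dict) -> np.ndarray:
    return np.array([weights.get(f, 0.0) for f in FEATURE_NAMES])


def generate_feature_dataset(spec: SyntheticFeatureSpec) -> SyntheticDataset:
    """Draw a labelled feature table from a known linear ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows

    if spec.covariance is None:
        cov = np.eye(len(FEATURE_NAMES))
    else:
        cov = np.asarray(spec.covariance, dtype=float).reshape(
            len(FEATURE_NAMES), len(FEATURE_NAMES)
        )
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("requested covariance is singular or indefinite") from exc
    x = rng.multivariate_normal(np.zeros(len(FEATURE_NAMES)), cov, size=n,
                                method="cholesky")

    aas, probs = zip(*sorted(spec.aa_composition.items()))
    probs = np.asarray(probs, dtype=float)
    codes = rng.choice(aas, size=n, p=probs / probs.sum())

    w_global = _weight_vector(spec.true_weights)
    w_rows = np.tile(w_global, (n, 1))
    for aa, weights in spec.aa_true_weights.items():
        w_rows[codes == aa] = _weight_vector(weights)

    if spec.threshold is None:
        sigma2 = float(w_global @ cov @ w_global)
        z = norm.ppf(1.0 - spec.hotspot_prevalence)
        total_sd = np.sqrt(spec.ddg_scale**2 * sigma2 + spec.ddg_noise_sd**2)
        b = (z * total_sd - spec.ddg_threshold) / spec.ddg_scale
    else:
        b = spec.threshold

    latent = (w_rows * x).sum(axis=1) - b
    ddg = spec.ddg_scale * latent + rng.normal(0.0, spec.ddg_noise_sd, n)
    labels = label_hotspots(ddg, spec.ddg_threshold)
    flip = rng.random(n) < spec.label_noise
    labels = np.where(flip, -labels, labels)

    clusters = np.array([f"c{i % spec.n_clusters}" for i in range(n)])
    records = [
        MutationRecord(f"cplx{clusters[i][1:]}", "A", str(i + 1), codes[i],
                       float(ddg[i]), clusters[i])
        for i in range(n)
    ]
    table = pd.DataFrame(x, columns=list(FEATURE_NAMES))
    table.insert(0, "complex_id", [m.complex_id for m in records])
    table.insert(1, "chain", "A")
    table.insert(2, "resnum", [m.residue_number for m in records])
    table.insert(3, "wt_aa", codes)
    table.insert(4, "ddg", ddg)
    table.insert(5, "cluster_id", clusters)
    table.insert(6, "label", labels)
    table = table[list(META_COLUMNS) + list(FEATURE_NAMES)]
    truth = {
        "weights": w_global, "threshold": b, "flipped": flip,
        "prevalence": float((labels == 1).mean()),
    }
    return SyntheticDataset(table=table, records=records, truth=truth)
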