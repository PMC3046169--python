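"""Labelled per-residue feature tables.

A feature table has one row per alanine mutation: identifying metadata
(complex, chain, residue, wild type, homology cluster), the 12 energy
features, the experimental ddG (kcal/mol) and the hot-spot label
(+1 if ddG >= threshold, -1 otherwise). Tables round-trip through
tab-separated text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .energetics import DEFAULT_SHELL_RADIUS, EnergyConfig, FEATURE_NAMES, energy_vector
from .structure import DEFAULT_CONTACT_CUTOFF, TypedComplex, find_interface_residues

logger = logging.getLogger(__name__)

DEFAULT_DDG_THRESHOLD = 2.0  # kcal/mol; the conventional hot-spot definition

META_COLUMNS = ("complex_id", "chain", "resnum", "wt_aa", "ddg", "cluster_id", "label")


@dataclass(frozen=True)
class MutationRecord:
    """One alanine mutation with its measured binding free-energy change."""

    complex_id: str
    chain_id: str
    residue_number: str
    wild_type: str  # 1-letter code, not A/G/P
    ddg: float      # kcal/mol, positive = destabilising
    cluster_id: str

    def __post_init__(self) -> None:
        if self.wild_type in {"A", "G", "P"}:
            raise ValueError(f"wild type {self.wild_type} cannot be alanine-scanned")
        if not np.isfinite(self.ddg):
            raise ValueError("ddg must be finite")


def label_hotspots(ddg: Iterable[float], ddg_threshold: float = DEFAULT_DDG_THRESHOLD) -> np.ndarray:
    """+1 where ddG >= threshold (inclusive), else -1."""
    if not ddg_threshold > 0:
        raise ValueError("ddg_threshold must be positive")
    arr = np.asarray(list(ddg) if not isinstance(ddg, np.ndarray) else ddg, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("missing or non-finite ddg values")
    return np.where(arr >= ddg_threshold, 1, -1)


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "resnum": str, "cluster_id": str})
    required = {"complex_id", "chain", "resnum", "wt_aa", "ddg", "cluster_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    return [
        MutationRecord(r.complex_id, r.chain, str(r.resnum), r.wt_aa, float(r.ddg), str(r.cluster_id))
        for r in df.itertuples(index=False)
    ]


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.complex_id, m.chain_id, m.residue_number, m.wild_type, m.ddg, m.cluster_id)
         for m in records],
        columns=["complex_id", "chain", "resnum", "wt_aa", "ddg", "cluster_id"],
    )
    df.to_csv(path, sep="\t", index=False)


def build_feature_table(
    complexes: Mapping[str, TypedComplex],
    mutations: Iterable[MutationRecord],
    shell_radius: float = DEFAULT_SHELL_RADIUS,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    ddg_threshold: float = DEFAULT_DDG_THRESHOLD,
    energy_config: EnergyConfig | None = None,
) -> pd.DataFrame:
    """Join mutations with their complexes into a labelled feature table.

    Mutations at non-interface residues are dropped with a warning (only
    interface mutations are retained); unresolvable mutations — wrong
    chain/number or wild-type mismatch — are a hard error listing every
    offender. Rows are keyed uniquely by (complex_id, chain, resnum).
    """
    mutations = list(mutations)
    site_maps: dict[str, dict] = {}
    for cid in {m.complex_id for m in mutations}:
        if cid not in complexes:
            raise ValueError(f"complex {cid!r} not provided")
        site_maps[cid] = {
            s.key: s for s in find_interface_residues(complexes[cid], contact_cutoff)
        }

    offenders: list[str] = []
    rows = []
    seen: set[tuple[str, str, str]] = set()
    for m in mutations:
        key = (m.complex_id, m.chain_id, m.residue_number)
        if key in seen:
            raise ValueError(f"duplicate mutation row {key}")
        seen.add(key)
        cx = complexes[m.complex_id]
        try:
            idx = cx.residue_atoms(m.chain_id, m.residue_number)
        except KeyError:
            offenders.append(f"{m.complex_id}/{m.chain_id}/{m.residue_number}: residue not found")
            continue
        from ._topology import THREE_TO_ONE

        actual = THREE_TO_ONE.get(cx.atoms[idx[0]].residue_name, "?")
        if actual != m.wild_type:
            offenders.append(
                f"{m.complex_id}/{m.chain_id}/{m.residue_number}: "
                f"wild type mismatch (structure {actual}, record {m.wild_type})"
            )
            continue
        site = site_maps[m.complex_id].get((m.chain_id, m.residue_number))
        if site is None:
            logger.warning(
                "mutation %s/%s/%s is not at the interface; dropped",
                m.complex_id, m.chain_id, m.residue_number,
            )
            continue
        ev = energy_vector(cx, site, shell_radius, energy_config)
        rows.append(
            {"complex_id": m.complex_id, "chain": m.chain_id, "resnum": m.residue_number,
             "wt_aa": m.wild_type, "ddg": m.ddg, "cluster_id": m.cluster_id,
             **ev.to_dict()}
        )
    if offenders:
        raise ValueError("unresolvable mutations:\n  " + "\n  ".join(offenders))

    table = pd.DataFrame(rows, columns=list(META_COLUMNS[:-1]) + list(FEATURE_NAMES))
    table["label"] = label_hotspots(table["ddg"].to_numpy(), ddg_threshold) if len(table) else []
    return table[list(META_COLUMNS) + list(FEATURE_NAMES)] if len(table) else table


def _is_degenerate_sd(sd: pd.Series, mean: pd.Series) -> pd.Series:
    # a constant column's sample sd comes out as rounding noise, not exact 0
    return sd <= 1e-12 * (mean.abs() + 1.0)


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature mean and standard deviation for z-scoring."""

    mean: pd.Series
    sd: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        sd = self.sd.mask(_is_degenerate_sd(self.sd, self.mean), 1.0)
        out[list(self.mean.index)] = (out[list(self.mean.index)] - self.mean) / sd
        return out


def standardize(
    table: pd.DataFrame,
    stats: FeatureStats | str = "fit",
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> tuple[pd.DataFrame, FeatureStats]:
    """Z-score the feature columns.

    With ``stats="fit"`` the mean/sd are computed on this table and
    returned for reuse on held-out folds (never re-fit on test data).
    Zero-variance features are left unscaled with a warning.
    """
    cols = list(feature_names)
    if isinstance(stats, str):
        if stats != "fit":
            raise ValueError("stats must be a FeatureStats or 'fit'")
        mean = table[cols].mean()
        sd = table[cols].std(ddof=0)
        for name in sd.index[_is_degenerate_sd(sd, mean)]:
            logger.warning("feature %s has zero variance; left unscaled", name)
        stats = FeatureStats(mean=mean, sd=sd)
    return stats.apply(table), stats


def feature_ddg_correlation(
    table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> pd.Series:
    """Absolute Pearson correlation of each feature with the observed ddG."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation estimate")
    ddg = table["ddg"].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = table[list(feature_names)].apply(lambda col: col.corr(ddg))
    return corr.abs().fillna(0.0)  # constant features -> no information


def feature_correlation_matrix(
    table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> pd.DataFrame:
    """Absolute feature-feature Pearson correlation matrix (unit diagonal)."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation estimate")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = table[list(feature_names)].corr().abs().fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "resnum": str, "cluster_id": str})
    if "label" in df.columns:
        df["label"] = df["label"].astype(int)
    return df
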