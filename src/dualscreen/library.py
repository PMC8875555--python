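"""Reading, standardising and curating potency-annotated molecule libraries.

The curation workflow mirrors common practice for assembling a ligand-based
training set from a potency database export: parse and canonicalise SMILES
(keeping the largest covalent fragment), convert potencies to nM, keep
molecules below a molecular-weight ceiling and above a potency floor, cluster
the survivors at a Tanimoto cutoff and keep the single most potent member of
each cluster as the representative active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .similarity import butina_cluster, fingerprints

logger = logging.getLogger(__name__)

#: potency unit -> factor converting to nM
_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "m": 1e9, "mm": 1e6, "pm": 1e-3}

ROLES = ("active", "inactive", "query", "candidate")


@dataclass(frozen=True)
class MoleculeRecord:
    """One library entry: an identified molecule with optional potency annotation."""

    molecule_id: str
    smiles: str
    target_id: str = ""
    potency_type: str = "none"  # Ki | IC50 | none
    potency_nM: float | None = None
    role: str = "candidate"

    def __post_init__(self) -> None:
        if self.potency_nM is not None and not self.potency_nM > 0:
            raise ValueError(f"potency_nM must be > 0, got {self.potency_nM}")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.potency_type not in ("Ki", "IC50", "none"):
            raise ValueError(f"bad potency_type {self.potency_type!r}")


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds for active-set curation.

    mw_max
        molecular-weight ceiling in Da; molecules must be strictly smaller.
    potency_max_nM
        potency ceiling in nM; molecules must be strictly more potent.
    cluster_tc_cutoff
        Tanimoto cutoff for the representative-selection clustering.
    fingerprint_kind
        fingerprint used for that clustering.
    """

    mw_max: float = 500.0
    potency_max_nM: float = 500.0
    cluster_tc_cutoff: float = 0.6
    fingerprint_kind: str = "ECFP4"

    def __post_init__(self) -> None:
        if self.mw_max <= 0 or self.potency_max_nM <= 0:
            raise ValueError("thresholds must be strictly positive")
        if not 0.0 <= self.cluster_tc_cutoff <= 1.0:
            raise ValueError("cluster_tc_cutoff must be in [0, 1]")


def to_nM(value: float, unit: str) -> float:
    """Convert a potency value in the given unit (nM/uM/mM/M/pM) to nM."""
    key = unit.strip().lower()
    if key not in _UNIT_TO_NM:
        raise ValueError(f"unknown potency unit {unit!r}")
    return float(value) * _UNIT_TO_NM[key]


def standardize_smiles(smiles: str) -> str | None:
    """Canonical SMILES of the largest covalent fragment, or None if unparseable.

    Salt stripping keeps the fragment with the most heavy atoms (ties broken
    by canonical-SMILES order for determinism); no neutralisation is applied,
    since formal charge matters downstream for decoy property matching.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return Chem.MolToSmiles(mol)


@dataclass
class ReadReport:
    """Bookkeeping from read_library: how many rows were kept or skipped."""

    n_rows: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    n_merged_duplicates: int = 0
    skipped_ids: list[str] = field(default_factory=list)


_REQUIRED_COLUMNS = ("molecule_id", "smiles")
_DEFAULT_COLUMNS = {
    "molecule_id": "molecule_id",
    "smiles": "smiles",
    "target_id": "target_id",
    "potency_type": "potency_type",
    "potency_value": "potency_value",
    "potency_unit": "potency_unit",
}


def _records_from_frame(
    df: pd.DataFrame, columns: dict[str, str], report: ReadReport
) -> list[MoleculeRecord]:
    records: list[MoleculeRecord] = []
    for _, row in df.iterrows():
        report.n_rows += 1
        mid = str(row[columns["molecule_id"]])
        smiles = standardize_smiles(str(row[columns["smiles"]]))
        if smiles is None:
            report.n_skipped += 1
            report.skipped_ids.append(mid)
            continue
        target = ""
        if columns["target_id"] in row.index and pd.notna(row[columns["target_id"]]):
            target = str(row[columns["target_id"]])
        ptype, pot = "none", None
        vcol, ucol = columns["potency_value"], columns["potency_unit"]
        if vcol in row.index and pd.notna(row[vcol]) and str(row[vcol]).strip() != "":
            unit = str(row[ucol]) if ucol in row.index and pd.notna(row[ucol]) else "nM"
            pot = to_nM(float(row[vcol]), unit)
            tcol = columns["potency_type"]
            raw = str(row[tcol]) if tcol in row.index and pd.notna(row[tcol]) else "none"
            ptype = {"ki": "Ki", "ic50": "IC50"}.get(raw.strip().lower(), "none")
        report.n_parsed += 1
        records.append(
            MoleculeRecord(
                molecule_id=mid, smiles=smiles, target_id=target,
                potency_type=ptype, potency_nM=pot,
            )
        )
    return records


def _records_from_sdf(path: Path, report: ReadReport) -> list[MoleculeRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records: list[MoleculeRecord] = []
    for i, mol in enumerate(supplier):
        report.n_rows += 1
        if mol is None:
            report.n_skipped += 1
            report.skipped_ids.append(f"sdf_record_{i}")
            continue
        props = mol.GetPropsAsDict()
        mid = str(props.get("molecule_id", mol.GetProp("_Name") if mol.HasProp("_Name") else "")) or f"sdf_record_{i}"
        smiles = standardize_smiles(Chem.MolToSmiles(mol))
        ptype, pot = "none", None
        if "potency_value" in props:
            pot = to_nM(float(props["potency_value"]), str(props.get("potency_unit", "nM")))
            ptype = {"ki": "Ki", "ic50": "IC50"}.get(
                str(props.get("potency_type", "none")).strip().lower(), "none"
            )
        report.n_parsed += 1
        records.append(
            MoleculeRecord(
                molecule_id=mid, smiles=smiles,
                target_id=str(props.get("target_id", "")),
                potency_type=ptype, potency_nM=pot,
            )
        )
    return records


def _merge_duplicates(records: list[MoleculeRecord], report: ReadReport) -> list[MoleculeRecord]:
    # Multiple measurements for one molecule_id collapse to the most potent
    # (minimum nM) annotation, Ki/IC50 treated interchangeably.
    by_id: dict[str, MoleculeRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.molecule_id not in by_id:
            by_id[rec.molecule_id] = rec
            order.append(rec.molecule_id)
            continue
        report.n_merged_duplicates += 1
        prev = by_id[rec.molecule_id]
        if rec.potency_nM is not None and (
            prev.potency_nM is None or rec.potency_nM < prev.potency_nM
        ):
            by_id[rec.molecule_id] = replace(
                prev, potency_nM=rec.potency_nM, potency_type=rec.potency_type
            )
    return [by_id[mid] for mid in order]


def read_library(
    path: str | Path,
    format: str = "smiles-table",
    columns: dict[str, str] | None = None,
    delimiter: str | None = None,
) -> tuple[list[MoleculeRecord], ReadReport]:
    """Read a molecule library from a delimited SMILES table or an SDF.

    SMILES are canonicalised and salt-stripped; potencies are converted to nM;
    unparseable rows are skipped and counted in the returned report; duplicate
    molecule_ids are merged keeping the minimum (most potent) annotation.

    Raises if the file is missing, a required column is absent, or no row
    parses at all.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = ReadReport()
    if format == "smiles-table":
        cols = dict(_DEFAULT_COLUMNS)
        if columns:
            cols.update(columns)
        sep = delimiter
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        for req in _REQUIRED_COLUMNS:
            if cols[req] not in df.columns:
                raise ValueError(f"missing required column {cols[req]!r} in {path}")
        records = _records_from_frame(df, cols, report)
    elif format == "sdf":
        records = _records_from_sdf(path, report)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not records:
        raise ValueError(f"no parseable molecules in {path}")
    records = _merge_duplicates(records, report)
    logger.info(
        "read %d rows from %s: %d parsed, %d skipped, %d duplicates merged",
        report.n_rows, path, report.n_parsed, report.n_skipped,
        report.n_merged_duplicates,
    )
    return records, report


def write_library(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    """Write records as a smiles-table (CSV, potencies in nM)."""
    df = pd.DataFrame(
        {
            "molecule_id": [r.molecule_id for r in records],
            "smiles": [r.smiles for r in records],
            "target_id": [r.target_id for r in records],
            "potency_type": [r.potency_type for r in records],
            "potency_value": [r.potency_nM for r in records],
            "potency_unit": ["nM" if r.potency_nM is not None else "" for r in records],
            "role": [r.role for r in records],
        }
    )
    df.to_csv(path, index=False)


def molecular_weight(smiles: str) -> float:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Descriptors.MolWt(mol)


def filter_library(
    records: Iterable[MoleculeRecord], config: CurationConfig = CurationConfig()
) -> list[MoleculeRecord]:
    """Keep molecules strictly below the MW ceiling and strictly more potent
    than the potency ceiling; order is preserved.

    Both comparisons are strict, so boundary values (exactly 500 Da or exactly
    500 nM under the defaults) are excluded, as are molecules with no potency
    annotation.
    """
    records = list(records)
    kept = []
    for rec in records:
        if rec.potency_nM is None or not rec.potency_nM < config.potency_max_nM:
            continue
        if not molecular_weight(rec.smiles) < config.mw_max:
            continue
        kept.append(rec)
    logger.info("filter_library: %d in, %d kept", len(records), len(kept))
    return kept


def select_representative_actives(
    records: Sequence[MoleculeRecord], config: CurationConfig = CurationConfig()
) -> list[MoleculeRecord]:
    """One representative active per similarity cluster: the most potent member.

    Clusters come from sphere-exclusion clustering at ``cluster_tc_cutoff``;
    within a cluster the minimum-potency_nM record wins, potency ties broken
    by lexicographically smallest molecule_id.  Returned records carry
    role="active", in cluster order.
    """
    if not records:
        raise ValueError("no records to select representatives from")
    for rec in records:
        if rec.potency_nM is None:
            raise ValueError(f"record {rec.molecule_id} lacks a potency annotation")
    fps = fingerprints([r.smiles for r in records], config.fingerprint_kind)
    clusters = butina_cluster(fps, config.cluster_tc_cutoff)
    representatives = []
    for members in clusters:
        best = min(members, key=lambda i: (records[i].potency_nM, records[i].molecule_id))
        representatives.append(replace(records[best], role="active"))
    logger.info(
        "select_representative_actives: %d molecules -> %d clusters",
        len(records), len(clusters),
    )
    return representatives
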