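"""Property-matched, topologically dissimilar decoy generation.

For each active, candidates from a pool are ranked by closeness in six
physicochemical properties (molecular weight, cLogP, rotatable bonds,
H-bond acceptors, H-bond donors, net charge at physiological pH) and selected
greedily under two hard topology constraints: no decoy may reach TC >= 0.6 to
ANY active, and no two selected decoys may reach TC >= 0.8 to each other.
When a property window yields too few candidates the windows relax stepwise;
the similarity constraints are never relaxed.  This follows the
property-matching / topology-exclusion recipe popularised by the DUD-E
benchmark, applied to a file-based candidate pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .library import MoleculeRecord
from .similarity import FingerprintVector, fingerprints, tanimoto_matrix

logger = logging.getLogger(__name__)

PROPERTY_NAMES = ("mw", "clogp", "rotatable_bonds", "hba", "hbd", "net_charge")

#: default matching windows, one per property, in property units
DEFAULT_WINDOWS = {
    "mw": 25.0,
    "clogp": 1.0,
    "rotatable_bonds": 2.0,
    "hba": 1.0,
    "hbd": 1.0,
    "net_charge": 0.0,  # exact charge match initially
}
RELAX_FACTOR = 1.5
MAX_RELAX_ROUNDS = 3

_CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_BASIC_AMINE = Chem.MolFromSmarts(
    "[NX3+0;H2,H1,H0;!$(N-[a]);!$(N-C=[O,N,S]);!$(N-S(=O));!$(N=*);!$(N-[O,N])]"
)


@dataclass(frozen=True)
class PropertyVector:
    """Six physicochemical properties used for decoy matching."""

    mw: float
    clogp: float
    rotatable_bonds: int
    hba: int
    hbd: int
    net_charge: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mw, self.clogp, self.rotatable_bonds, self.hba, self.hbd, self.net_charge],
            dtype=float,
        )


def net_charge(mol: Chem.Mol) -> int:
    """Rule-based net charge at physiological pH.

    Starts from the formal charge and deprotonates neutral carboxylic acids
    (-1 each) / protonates neutral basic aliphatic amines (+1 each).
    """
    charge = Chem.GetFormalCharge(mol)
    charge -= len(mol.GetSubstructMatches(_CARBOXYLIC_ACID))
    charge += len(mol.GetSubstructMatches(_BASIC_AMINE))
    return charge


def property_vector(smiles: str) -> PropertyVector:
    """Compute the six-property matching vector for a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return PropertyVector(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        hba=Lipinski.NumHAcceptors(mol),
        hbd=Lipinski.NumHDonors(mol),
        net_charge=net_charge(mol),
    )


@dataclass
class DecoyAudit:
    """Constraint evidence recorded for one selected decoy."""

    decoy_id: str
    active_id: str
    max_tc_to_actives: float
    max_tc_to_decoys: float  # vs decoys selected before this one; 0 if first
    property_deltas: dict[str, float]
    relax_round: int


@dataclass
class DecoySet:
    """Active -> decoys assignment with a per-decoy constraint audit."""

    assignments: dict[str, list[MoleculeRecord]]
    audit: list[DecoyAudit]
    shortfalls: dict[str, int] = field(default_factory=dict)
    tc_active_max: float = 0.6
    tc_decoy_max: float = 0.8

    def all_decoys(self) -> list[MoleculeRecord]:
        return [d for decs in self.assignments.values() for d in decs]

    def decoy_ids_for(self, active_id: str) -> set[str]:
        return {d.molecule_id for d in self.assignments.get(active_id, [])}


def _window_arrays(windows: Mapping[str, float], round_: int) -> np.ndarray:
    base = np.array([windows[name] for name in PROPERTY_NAMES], dtype=float)
    w = base * (RELAX_FACTOR ** round_)
    # exact-match properties (window 0) relax to +/-1 only on the final round
    if round_ >= MAX_RELAX_ROUNDS:
        w = np.where(base == 0.0, 1.0, w)
    return w


def _norm_scales(windows: Mapping[str, float]) -> np.ndarray:
    base = np.array([windows[name] for name in PROPERTY_NAMES], dtype=float)
    return np.where(base > 0, base, 1.0)


def generate_decoys(
    actives: Sequence[MoleculeRecord],
    pool: Sequence[MoleculeRecord],
    n_per_active: int = 40,
    tc_active_max: float = 0.6,
    tc_decoy_max: float = 0.8,
    windows: Mapping[str, float] | None = None,
    fingerprint_kind: str = "ECFP4",
) -> DecoySet:
    """Select property-matched, topology-excluded decoys for each active.

    Actives are processed in input order.  For each, pool candidates inside
    the property windows are ranked by normalised property distance (ties by
    id) and accepted greedily, subject to TC < tc_active_max against every
    active and TC < tc_decoy_max against every decoy already selected across
    the whole set.  If fewer than ``n_per_active`` candidates fit, the windows
    relax by x1.5 up to 3 rounds; exact-match windows open to +/-1 on the last
    round; the similarity constraints never relax.  Shortfalls are recorded,
    not fatal.  Each candidate is used at most once across the whole set.
    """
    if not actives:
        raise ValueError("actives must be non-empty")
    if not pool:
        raise ValueError("candidate pool is empty")
    windows = dict(DEFAULT_WINDOWS, **(windows or {}))
    active_ids = {a.molecule_id for a in actives}
    overlap = active_ids & {c.molecule_id for c in pool}
    if overlap:
        raise ValueError(f"pool overlaps actives by molecule_id: {sorted(overlap)[:5]}")

    active_fps = fingerprints([a.smiles for a in actives], fingerprint_kind)
    pool_fps = fingerprints([c.smiles for c in pool], fingerprint_kind)
    active_props = np.stack([property_vector(a.smiles).as_array() for a in actives])
    pool_props = np.stack([property_vector(c.smiles).as_array() for c in pool])

    # max TC of each candidate to any active: computed once, a hard veto
    tc_to_actives = tanimoto_matrix(pool_fps, active_fps).max(axis=1)
    scales = _norm_scales(windows)

    available = np.ones(len(pool), dtype=bool)
    available &= tc_to_actives < tc_active_max

    assignments: dict[str, list[MoleculeRecord]] = {}
    audit: list[DecoyAudit] = []
    shortfalls: dict[str, int] = {}
    selected_fps: list[FingerprintVector] = []

    for ai, active in enumerate(actives):
        deltas = np.abs(pool_props - active_props[ai])
        distance = (deltas / scales).sum(axis=1)
        chosen: list[int] = []
        for round_ in range(MAX_RELAX_ROUNDS + 1):
            w = _window_arrays(windows, round_)
            in_window = (deltas <= w).all(axis=1)
            cand = np.flatnonzero(in_window & available)
            order = sorted(cand, key=lambda j: (distance[j], pool[j].molecule_id))
            for j in order:
                if len(chosen) >= n_per_active:
                    break
                max_tc_dec = 0.0
                if selected_fps:
                    max_tc_dec = float(
                        tanimoto_matrix([pool_fps[j]], selected_fps).max()
                    )
                    if max_tc_dec >= tc_decoy_max:
                        continue
                chosen.append(j)
                available[j] = False
                selected_fps.append(pool_fps[j])
                audit.append(
                    DecoyAudit(
                        decoy_id=pool[j].molecule_id,
                        active_id=active.molecule_id,
                        max_tc_to_actives=float(tc_to_actives[j]),
                        max_tc_to_decoys=max_tc_dec,
                        property_deltas=dict(zip(PROPERTY_NAMES, deltas[j])),
                        relax_round=round_,
                    )
                )
            if len(chosen) >= n_per_active:
                break
        assignments[active.molecule_id] = [
            MoleculeRecord(
                molecule_id=pool[j].molecule_id,
                smiles=pool[j].smiles,
                target_id=pool[j].target_id,
                role="inactive",
            )
            for j in chosen
        ]
        if len(chosen) < n_per_active:
            shortfalls[active.molecule_id] = n_per_active - len(chosen)
            logger.warning(
                "active %s: only %d/%d decoys found",
                active.molecule_id, len(chosen), n_per_active,
            )
    return DecoySet(
        assignments=assignments,
        audit=audit,
        shortfalls=shortfalls,
        tc_active_max=tc_active_max,
        tc_decoy_max=tc_decoy_max,
    )


@dataclass
class AuditResult:
    n_decoys: int
    n_violations: int
    violations: list[str]

    @property
    def all_pass(self) -> bool:
        return self.n_violations == 0


def verify_decoy_set(
    decoy_set: DecoySet,
    actives: Sequence[MoleculeRecord],
    fingerprint_kind: str = "ECFP4",
) -> AuditResult:
    """Independently re-check every constraint on an emitted decoy set.

    Recomputes fingerprints from SMILES and verifies TC < tc_active_max to
    every active, pairwise decoy TC < tc_decoy_max, and per-active counts.
    """
    decoys = decoy_set.all_decoys()
    violations: list[str] = []
    if decoys:
        dec_fps = fingerprints([d.smiles for d in decoys], fingerprint_kind)
        act_fps = fingerprints([a.smiles for a in actives], fingerprint_kind)
        tc_da = tanimoto_matrix(dec_fps, act_fps)
        for i, d in enumerate(decoys):
            if tc_da[i].max() >= decoy_set.tc_active_max:
                violations.append(
                    f"{d.molecule_id}: TC {tc_da[i].max():.3f} to an active"
                )
        tc_dd = tanimoto_matrix(dec_fps)
        iu = np.triu_indices(len(decoys), k=1)
        for i, j in zip(*iu):
            if tc_dd[i, j] >= decoy_set.tc_decoy_max:
                violations.append(
                    f"{decoys[i].molecule_id}/{decoys[j].molecule_id}: "
                    f"pairwise TC {tc_dd[i, j]:.3f}"
                )
    seen: set[str] = set()
    for active_id, decs in decoy_set.assignments.items():
        ids = [d.molecule_id for d in decs]
        if len(ids) != len(set(ids)) or seen & set(ids):
            violations.append(f"{active_id}: duplicate decoys")
        seen |= set(ids)
    return AuditResult(
        n_decoys=len(decoys), n_violations=len(violations), violations=violations
    )
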