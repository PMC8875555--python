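"""Fingerprints and Tanimoto-similarity machinery.

Molecules are compared as fixed-length bit vectors: circular (Morgan)
fingerprints of bond radius 2 or 3 folded to 1024 bits (the common ECFP4 and
ECFP6 approximations) and the 166 MACCS structural keys.  On top of the bit
vectors this module provides the Tanimoto coefficient (TC), sphere-exclusion
(Butina) clustering, nearest-neighbour lookup against a labelled reference
set, and the pairwise-TC distributions used for similarity-ensemble (SEA)
style comparisons of two ligand sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

FINGERPRINT_KINDS = ("ECFP4", "ECFP6", "MACCS")

_N_BITS = {"ECFP4": 1024, "ECFP6": 1024, "MACCS": 166}


@dataclass(frozen=True)
class FingerprintVector:
    """A molecular fingerprint: a fixed-length bit vector plus its kind tag."""

    kind: str
    bits: np.ndarray  # uint8 0/1, length fixed by kind

    def __post_init__(self) -> None:
        if self.kind not in _N_BITS:
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.shape[0] != _N_BITS[self.kind]:
            raise ValueError(
                f"{self.kind} fingerprint must have {_N_BITS[self.kind]} bits, "
                f"got shape {bits.shape}"
            )
        object.__setattr__(self, "bits", bits)

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    def popcount(self) -> int:
        return int(self.bits.sum())

    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


_MORGAN_GENS: dict[int, object] = {}


def _morgan_bits(mol: Chem.Mol, radius: int) -> np.ndarray:
    if radius not in _MORGAN_GENS:
        _MORGAN_GENS[radius] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=1024
        )
    gen = _MORGAN_GENS[radius]
    return np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)


def _maccs_bits(mol: Chem.Mol) -> np.ndarray:
    # RDKit returns 167 bits with bit 0 never set; drop it to get the 166 keys.
    bv = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(167, dtype=np.uint8)
    for idx in bv.GetOnBits():
        arr[idx] = 1
    return arr[1:]


_BACKENDS: dict[str, Callable[[Chem.Mol], np.ndarray]] = {
    "ECFP4": lambda mol: _morgan_bits(mol, radius=2),
    "ECFP6": lambda mol: _morgan_bits(mol, radius=3),
    "MACCS": _maccs_bits,
}


def register_backend(kind: str, n_bits: int, fn: Callable[[Chem.Mol], np.ndarray]) -> None:
    """Register an alternative fingerprint backend under a new kind tag."""
    _N_BITS[kind] = n_bits
    _BACKENDS[kind] = fn


def fingerprint(smiles: str, kind: str = "ECFP4") -> FingerprintVector:
    """Compute a fingerprint bit vector for a SMILES string.

    ECFP4/ECFP6 are Morgan circular fingerprints of bond radius 2/3 folded to
    1024 bits; MACCS are the 166 predefined substructure keys.  Deterministic
    for a given canonical SMILES and backend version.
    """
    if kind not in _BACKENDS:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    mol = _mol_from_smiles(smiles)
    return FingerprintVector(kind=kind, bits=_BACKENDS[kind](mol))


def fingerprints(smiles_list: Sequence[str], kind: str = "ECFP4") -> list[FingerprintVector]:
    return [fingerprint(s, kind) for s in smiles_list]


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|; 0 when both vectors are empty."""
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 0.0
    return inter / union


def _bit_matrix(fps: Sequence[FingerprintVector]) -> np.ndarray:
    kinds = {fp.kind for fp in fps}
    if len(kinds) > 1:
        raise ValueError(f"mixed fingerprint kinds: {sorted(kinds)}")
    return np.stack([fp.bits for fp in fps]).astype(np.uint8)


def tanimoto_matrix(
    fps_a: Sequence[FingerprintVector],
    fps_b: Sequence[FingerprintVector] | None = None,
) -> np.ndarray:
    """Pairwise Tanimoto matrix between two fingerprint sets (or within one).

    Vectorised over the bit matrices; all-zero/all-zero pairs score 0.
    """
    A = _bit_matrix(fps_a)
    B = A if fps_b is None else _bit_matrix(fps_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    inter = A.astype(np.int32) @ B.T.astype(np.int32)
    pa = A.sum(axis=1).astype(np.int32)
    pb = B.sum(axis=1).astype(np.int32)
    union = pa[:, None] + pb[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return tc


def butina_cluster(fps: Sequence[FingerprintVector], cutoff: float) -> list[list[int]]:
    """Sphere-exclusion (Butina) clustering of fingerprints at a TC cutoff.

    Candidate centroids are ordered by descending neighbour count (neighbours
    are molecules with TC >= cutoff), ties by ascending index.  Each molecule
    joins the first centroid it is within the cutoff of; leftover molecules
    become singletons.  Returns a partition of indices, clusters in centroid
    order, each cluster led by its centroid.
    """
    if len(fps) == 0:
        raise ValueError("cannot cluster an empty fingerprint list")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    return butina_cluster_matrix(tanimoto_matrix(fps), cutoff)


def butina_cluster_matrix(sim: np.ndarray, cutoff: float) -> list[list[int]]:
    """Butina clustering from a precomputed symmetric similarity matrix."""
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if n == 0:
        raise ValueError("cannot cluster an empty similarity matrix")
    neighbor = sim >= cutoff
    np.fill_diagonal(neighbor, False)
    counts = neighbor.sum(axis=1)
    order = sorted(range(n), key=lambda i: (-counts[i], i))
    assigned = np.zeros(n, dtype=bool)
    clusters: list[list[int]] = []
    for centroid in order:
        if assigned[centroid]:
            continue
        members = [centroid]
        assigned[centroid] = True
        for j in np.flatnonzero(neighbor[centroid] & ~assigned):
            members.append(int(j))
            assigned[j] = True
        clusters.append(members)
    return clusters


def nearest_neighbor(
    query: FingerprintVector, refs: Mapping[str, FingerprintVector]
) -> tuple[str, float]:
    """Label and TC of the most similar reference; ties to the smaller label."""
    if not refs:
        raise ValueError("empty reference set")
    best_label, best_tc = None, -1.0
    for label in sorted(refs):
        tc = tanimoto(query, refs[label])
        if tc > best_tc:
            best_label, best_tc = label, tc
    return best_label, best_tc


@dataclass
class SimilarityDistribution:
    """Histogram of pairwise Tanimoto coefficients between (or within) ligand sets."""

    pair_tcs: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    label: str = ""

    @property
    def n_pairs(self) -> int:
        return int(self.pair_tcs.shape[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def tc_distribution(
    fps_a: Sequence[FingerprintVector],
    fps_b: Sequence[FingerprintVector] | None = None,
    n_bins: int = 20,
    label: str = "",
) -> SimilarityDistribution:
    """Distribution of pairwise TCs, within one set or across two sets.

    Within-set mode uses all unordered pairs without self-pairs (C(n, 2)
    values); cross mode uses the full a x b product.  The histogram spans
    [0, 1] with ``n_bins`` equal bins; counts conserve the pair count.
    """
    if len(fps_a) == 0:
        raise ValueError("set_a is empty")
    tc = tanimoto_matrix(fps_a, fps_b)
    if fps_b is None:
        if len(fps_a) < 2:
            raise ValueError("within-set distribution needs at least 2 molecules")
        iu = np.triu_indices(len(fps_a), k=1)
        pair_tcs = tc[iu]
    else:
        pair_tcs = tc.ravel()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(pair_tcs, bins=edges)
    return SimilarityDistribution(
        pair_tcs=pair_tcs, bin_edges=edges, counts=counts, label=label
    )
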