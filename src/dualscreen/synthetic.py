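"""Synthetic chemical libraries and assay curves with controlled structure.

Every stage of the screening pipeline can be exercised without database
downloads: actives are built combinatorially by decorating a shared scaffold
(by default a benzenesulfonamide, the canonical zinc-binding pharmacophore of
carbonic-anhydrase inhibitors) so they share elevated pairwise Tanimoto
similarity and a common substructure; background molecules come from distinct
scaffold families; dose–response and melt curves are simulated from the exact
models the fitters assume, plus seeded noise.  Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .assay import DoseResponseDataset, MeltCurve
from .library import MoleculeRecord

#: branch-SMILES substituent vocabulary; ring closures use digits 8/9 so they
#: never collide with the scaffold templates (which use 1/2)
DEFAULT_SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "CO", "CN", "CCO",
    "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C(F)(F)F", "C#N", "C(=O)OC", "C(=O)NC",
    "c9ccccc9", "Oc9ccccc9", "N9CCOCC9", "N9CCCCC9",
)

#: primary benzenesulfonamide scaffold with three decoration slots
#: ({a}/{b} render as parenthesised branches, {c} as a plain suffix)
DEFAULT_SCAFFOLD = "NS(=O)(=O)c1cc{a}c{b}cc1{c}"

#: background scaffold families: sulfonamide-free heteroaromatics and
#: aliphatics, two decoration slots each
BACKGROUND_SCAFFOLDS = (
    "c1ccnc{a}c1{c}",                    # pyridine
    "c1cnc{a}nc1{c}",                    # pyrimidine
    "c1cc{a}oc1{c}",                     # furan
    "c1cc{a}sc1{c}",                     # thiophene
    "C1CCC{a}CC1{c}",                    # cyclohexane
    "C1CCN{a}CC1{c}",                    # piperidine
    "c1cc{a}c2cc{b}ccc2c1",              # naphthalene
    "c1ccc(-c2cc{a}ccc2{c})cc1",         # biphenyl
    "O=C(Nc1cc{a}ccc1{c})C2CCCC2",       # cyclopentyl benzamide
    "O=C(N1CCC{a}CC1)c1ccc{b}cc1",       # aroyl piperidine
)


def render_scaffold(template: str, subs: Sequence[str | None]) -> str:
    """Fill a scaffold template's {a}/{b}/{c} slots with branch substituents.

    {a} and {b} are interior ring positions (rendered as ``(X)``); {c} is a
    terminal suffix appended verbatim.  None/empty leaves a slot bare.
    """
    def branch(x):
        return f"({x})" if x else ""

    a, b, c = (list(subs) + [None, None, None])[:3]
    return template.format(a=branch(a), b=branch(b), c=c or "")


def _canonical_or_none(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of a synthetic screening benchmark.

    Potencies are sampled log-uniformly between the bounds (nM); the defaults
    keep every active inside the 500 Da / 500 nM curation gate.
    """

    n_actives: int = 60
    n_background: int = 500
    scaffold_smiles: str = DEFAULT_SCAFFOLD
    substituents: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    potency_low_nM: float = 1.0
    potency_high_nM: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_actives <= 0 or self.n_background <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.potency_low_nM < self.potency_high_nM:
            raise ValueError("potency bounds must be positive and ordered")
        if Chem.MolFromSmiles(render_scaffold(self.scaffold_smiles, [])) is None:
            raise ValueError("scaffold template does not parse bare")


def _sample_decorations(
    rng: np.random.Generator, vocab: Sequence[str], n_slots: int = 3
) -> list[str | None]:
    # 1..n_slots substituents; empty slots allowed so sizes vary
    subs: list[str | None] = []
    for _ in range(n_slots):
        if rng.random() < 0.6:
            subs.append(str(vocab[rng.integers(len(vocab))]))
        else:
            subs.append(None)
    if all(s is None for s in subs):
        subs[0] = str(vocab[rng.integers(len(vocab))])
    return subs


def _generate_unique(
    rng: np.random.Generator,
    n: int,
    make_smiles,
    max_tries_per_mol: int = 400,
    taken: set[str] | None = None,
) -> list[str]:
    seen: set[str] = set(taken or ())
    out: list[str] = []
    misses = 0
    while len(out) < n:
        if misses > max_tries_per_mol:  # consecutive failures: space exhausted
            raise ValueError(
                f"could not generate {n} unique molecules "
                f"(got {len(out)}); vocabulary too small for the request"
            )
        smi = _canonical_or_none(make_smiles())
        if smi is None or smi in seen:
            misses += 1
            continue
        misses = 0
        seen.add(smi)
        out.append(smi)
    return out


def generate_screening_benchmark(
    spec: BenchmarkSpec,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord], dict[str, bool]]:
    """Scaffold-derived actives, a diverse background library, truth labels.

    Actives share the scaffold (elevated pairwise TC, common substructure);
    background molecules are drawn from unrelated scaffold families.  Returns
    (actives, background, truth) where truth maps every molecule_id to
    whether it is a planted active.
    """
    rng = np.random.default_rng(spec.seed)
    active_smiles = _generate_unique(
        rng, spec.n_actives,
        lambda: render_scaffold(
            spec.scaffold_smiles, _sample_decorations(rng, spec.substituents)
        ),
    )
    taken = set(active_smiles)
    bg_smiles = _generate_unique(
        rng, spec.n_background,
        lambda: render_scaffold(
            str(BACKGROUND_SCAFFOLDS[rng.integers(len(BACKGROUND_SCAFFOLDS))]),
            _sample_decorations(rng, spec.substituents),
        ),
        taken=taken,
    )
    log_lo, log_hi = np.log10(spec.potency_low_nM), np.log10(spec.potency_high_nM)
    potencies = 10.0 ** rng.uniform(log_lo, log_hi, size=spec.n_actives)
    actives = [
        MoleculeRecord(
            molecule_id=f"ACT{i:05d}", smiles=s, target_id="SYN_TARGET",
            potency_type="Ki" if i % 2 == 0 else "IC50",
            potency_nM=float(potencies[i]), role="active",
        )
        for i, s in enumerate(active_smiles)
    ]
    background = [
        MoleculeRecord(molecule_id=f"BG{i:06d}", smiles=s, role="candidate")
        for i, s in enumerate(bg_smiles)
    ]
    truth = {r.molecule_id: True for r in actives}
    truth.update({r.molecule_id: False for r in background})
    return actives, background, truth


def generate_decoy_pool(
    n: int,
    property_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    substituents: Sequence[str] = DEFAULT_SUBSTITUENTS,
) -> list[MoleculeRecord]:
    """A structurally diverse, sulfonamide-free candidate pool for decoys.

    ``property_ranges`` optionally constrains properties by name (e.g.
    ``{"mw": (250, 350)}``); molecules outside any range are rejected during
    sampling.  Raises when the requested ranges are infeasible under the
    scaffold vocabulary.  Deterministic under seed.
    """
    from .decoys import property_vector  # local import to avoid a cycle

    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    ranges = dict(property_ranges or {})

    def make() -> str:
        template = str(BACKGROUND_SCAFFOLDS[rng.integers(len(BACKGROUND_SCAFFOLDS))])
        return render_scaffold(template, _sample_decorations(rng, substituents))

    seen: set[str] = set()
    out: list[str] = []
    misses = 0
    while len(out) < n:
        if misses > 2000:  # consecutive rejections: ranges look infeasible
            raise ValueError(
                f"requested property ranges look infeasible: "
                f"only {len(out)}/{n} candidates found"
            )
        misses += 1
        smi = _canonical_or_none(make())
        if smi is None or smi in seen:
            continue
        if ranges:
            props = property_vector(smi)
            ok = all(
                lo <= getattr(props, name) <= hi for name, (lo, hi) in ranges.items()
            )
            if not ok:
                continue
        misses = 0
        seen.add(smi)
        out.append(smi)
    return [
        MoleculeRecord(molecule_id=f"POOL{i:06d}", smiles=s, role="candidate")
        for i, s in enumerate(out)
    ]


def simulate_dose_response(
    true_ic50: float,
    hill: float = 1.0,
    concentrations: Sequence[float] | None = None,
    rel_noise: float = 0.05,
    seed: int = 0,
) -> DoseResponseDataset:
    """Logistic inhibition curve with multiplicative Gaussian noise.

    responses = 1 / (1 + ([I]/IC50)^h) * (1 + N(0, rel_noise)).  Default
    concentrations: 8 points log-spaced over 3 decades centred on IC50.
    """
    if true_ic50 <= 0:
        raise ValueError("true_ic50 must be > 0")
    if concentrations is None:
        concentrations = np.logspace(
            np.log10(true_ic50) - 1.5, np.log10(true_ic50) + 1.5, 8
        )
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    clean = 1.0 / (1.0 + (conc / true_ic50) ** hill)
    noisy = clean * (1.0 + rng.normal(0.0, rel_noise, size=conc.shape))
    return DoseResponseDataset(concentrations_M=conc, responses=noisy)


def simulate_melt_curve(
    true_tm: float = 55.0,
    slope: float = 2.0,
    plateau_low: float = 100.0,
    plateau_high: float = 1000.0,
    temperatures: Sequence[float] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """Boltzmann-shaped DSF melt curve on a 30-90 degC grid plus noise.

    ``noise`` is the Gaussian SD expressed as a fraction of the plateau
    amplitude (plateau_high - plateau_low).
    """
    if temperatures is None:
        temperatures = np.arange(30.0, 90.0 + 1e-9, 1.0)
    T = np.asarray(temperatures, dtype=float)
    rng = np.random.default_rng(seed)
    F = plateau_low + (plateau_high - plateau_low) / (
        1.0 + np.exp((true_tm - T) / slope)
    )
    if noise > 0:
        F = F + rng.normal(0.0, noise * (plateau_high - plateau_low), size=T.shape)
    return MeltCurve(temperatures_C=T, fluorescence=F)
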