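# Methods

This note records the models, conventions and design choices behind
`dualscreen`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and what the synthetic benchmarks do
and do not demonstrate.

## Curation

Input libraries are delimited SMILES tables (or SDF). Each SMILES is parsed
with RDKit, reduced to its largest covalent fragment by heavy-atom count
(salt stripping; ties broken by canonical-SMILES order) and canonicalised.
No neutralisation is applied: formal charge is a matched property in decoy
generation, so charge states are preserved as annotated. Potencies are
converted to nM; Ki and IC50 annotations are treated interchangeably for
selection purposes, and duplicate molecule ids are merged keeping the
minimum (most potent) value — potency databases report multiple assays per
compound and the curation rule is a potency *ceiling*, so the most
optimistic measurement is the operative one.

The curation gate keeps molecules with MW strictly below 500 Da and potency
strictly below 500 nM. Both inequalities are strict; boundary values are
excluded. Records with no potency annotation cannot satisfy a potency
ceiling and are excluded by the filter. Survivors are clustered at TC 0.6
(ECFP4 by default) and the minimum-potency member represents each cluster,
with potency ties broken by lexicographically smallest id for determinism.
This de-biases the chemical space of the positive class before training.

## Fingerprints and similarity

ECFP4/ECFP6 are Morgan circular fingerprints of bond radius 2/3 folded to
1024 bits; MACCS are the 166 predefined substructure keys (RDKit's 167-bit
vector with its permanently unset bit 0 dropped). The backend is a registry
keyed by kind, so alternative generators can be plugged in; determinism is
guaranteed by pinning the toolkit version. The Tanimoto coefficient is
|A∩B|/|A∪B| on the bit sets, defined as 0 when both vectors are empty (the
natural continuous extension that avoids a 0/0).

Clustering is Butina sphere exclusion: candidate centroids ordered by
descending neighbour count (neighbours = TC ≥ cutoff), ties by index; each
centroid absorbs all still-unassigned neighbours; leftovers become
singletons. The field's usage rarely names the exact variant, so this
package fixes one and verifies it against an exhaustive literal
re-implementation on small random similarity matrices. Nearest-neighbour
lookups break TC ties by lexicographic label.

SEA-style comparisons histogram all pairwise TCs within one ligand set
(unordered pairs, no self-pairs) or across two sets, over [0, 1]; a
distribution massed near 0 indicates chemotype novelty relative to the
reference set.

## Decoy generation

Negatives are presumed-inactive decoys matched on six properties — MW,
cLogP, rotatable bonds, H-bond acceptors, H-bond donors, and net charge at
physiological pH — but topologically excluded: TC < 0.6 to *every* active
and pairwise TC < 0.8 among all selected decoys. The net charge is
rule-based (formal charge, minus one per neutral carboxylic acid, plus one
per neutral basic aliphatic amine; aromatic, amide and sulfonamide nitrogens
are not basic), a deliberate simplification of pKa prediction that is
deterministic and adequate for matching.

Selection is greedy and deterministic: actives in input order; candidates
inside the property windows ranked by window-normalised absolute property
distance, ties by id; each accepted candidate is checked against all actives
and all decoys selected so far across the whole set, and is consumed (one
global decoy set, as the pairwise-TC constraint implies). Default windows
are ±25 Da, ±1.0 cLogP, ±2 rotatable bonds, ±1 HBA, ±1 HBD, exact charge;
when an active cannot fill its quota (40 by default) the windows relax by
×1.5 for up to 3 rounds (the exact-charge window opens to ±1 only on the
final round). The similarity constraints never relax; shortfalls are
recorded rather than patched. `verify_decoy_set` re-derives every constraint
from SMILES after the fact, independently of the selection bookkeeping.

## Classification and screening

Fingerprint matrices with labels 1 (active) / 0 (decoy) feed seven classifier
families at framework defaults: KNN, Bernoulli naive Bayes (the natural
variant for binary bit features), logistic regression, decision tree,
random forest, MLP, and XGBoost. The only default deviations are raised
iteration caps (logistic 1000, MLP 400) so fits converge on 1024-bit inputs;
all resolved settings are written to the model manifest.

Cross-validation is stratified 5-fold repeated over 5 independent
reshufflings (25 fold evaluations). Stratification matters because the
design prevalence is ~2.4% positives (1 active : 40 decoys); unstratified
folds would occasionally starve a fold of actives. Per-fold ACC and MCC come
from the confusion counts (MCC set to 0 when any marginal is empty); AUC is
the rank statistic P(score⁺ > score⁻) with ties counted ½, computed on the
held-out fold only. Model selection maximises mean MCC — ACC and AUC
saturate near 1 under heavy imbalance and discriminate little — with exact
ties resolved toward the simpler family (NB < Logit < KNN < DT < RF <
XGBoost < MLP by effective parameter count). LogAUC integrates TPR over
log10(FPR) from 0.001 to 1, normalised by the 3-decade range, ×100; its
random-scorer baseline is (1−0.001)/(3 ln 10) × 100 ≈ 14.5%.

The final model refits on all data; screening reports every library molecule
with positive-class probability ≥ the threshold (≥, so exactly-threshold
molecules are hits), sorted by probability then id, each annotated with the
nearest training active (max TC, ties to the smaller id) — the analyst's
first question about a hit is always "what known active does this resemble,
and how much?". External validation removes training actives with max
TC ≥ 0.6 to any external molecule *and exactly their linked decoys*, then
retrains and tabulates TP/FP at p ≥ 0.5 against the provided annotations;
removing the actives but keeping their decoys would silently shift the class
balance.

## Assay analysis

**Dose–response.** Normalised activity is fit to v = 1/(1 + ([I]/IC50)^h)
with asymptotes fixed at 1 and 0 — the inputs are defined as activities
scaled to the uninhibited control, so floating the asymptotes would let the
normalisation be refit as two extra parameters. IC50 is optimised in log
space with multi-start initialisation over a log-spaced grid spanning the
measured range ±1 decade (7 starts), Hill slope free in [0.1, 10] and
reported. The convergence flag reflects the optimiser's own status.

**Cheng–Prusoff.** Ki = IC50/(1 + [S]/Km), the competitive-inhibition
relation. Km is a required per-enzyme input: no default is defensible, and a
silent assumption would corrupt every downstream Ki, so its absence is an
explicit error.

**Monte-Carlo uncertainty.** 100 cycles by default; each perturbs every
response with Gaussian noise of SD = max(rel_noise·|response|, replicate SD)
— at least 5% relative uncertainty — refits, and converts to Ki; the
reported value is the mean ± SD over converged cycles, erroring if more than
half fail. Zero noise degenerates exactly to the point estimate with SD 0.

**DSF.** Melt curves are restricted to 40–68 °C (below aggregation and
probe-quench artifacts), min–max normalised within the window, and fit to
F(T) = B + (A−B)/(1 + exp((Tm−T)/s)) with Tm bounded to the window, s > 0,
and plateaus loosely bounded around 0 and 1 on the normalised scale. A Tm
within 0.5 °C of the window edge is flagged. ΔTm versus a reference is
called significant when |ΔTm| > 3 × SD of ≥3 reference replicates (sample
SD, n−1); identical replicates give SD 0, so any nonzero shift is then
significant — the correct degenerate limit.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes, not
medicinal-chemistry realism. Actives decorate a shared scaffold (default: a
primary benzenesulfonamide, the canonical CA zinc-binding pharmacophore)
with 1–3 substituents from a 24-fragment vocabulary, giving elevated
within-class TC and a common substructure; potencies are log-uniform in
[1, 400] nM so every active passes the curation gate. Background and decoy
pools draw from ten sulfonamide-free scaffold families (heteroaromatics,
aliphatics, amide-linked bicycles) with the same vocabulary; invalid or
duplicate SMILES are rejected and resampled, and generation fails loudly
when a request exhausts the combinatorial space or the requested property
ranges. Every generator is a pure function of its spec and seed.

Simulated dose–response curves apply multiplicative Gaussian noise
(default 5% relative, 8 points log-spaced over 3 decades around the true
IC50); melt curves are Boltzmann sigmoids on a 30–90 °C, 1 °C grid with
additive noise scaled to the plateau amplitude. Because these are exactly
the fitters' model families plus noise, recovery tests demonstrate estimator
correctness and calibration — not robustness to model misspecification
(cooperative binding, drifting baselines, aggregation artifacts), which real
data can exhibit.

Consequently the benchmark classification task is *easy by construction*:
scaffold-derived actives against topology-excluded decoys are nearly
separable, and cross-validated MCC/AUC near 1.0 with planted-active recall
of 100% show the pipeline's plumbing and bookkeeping are correct, not that
comparable figures would be achieved on a real potency database.

## Problem sizes and determinism

The shipped verification runs use desk-scale sizes chosen to exercise every
code path with comfortable statistics: 1,000 random confusion matrices and
200 score sets for the metric oracles; a 5,000-candidate pool with 20
actives for the decoy audit; 60 training actives (+20 held out) with up to
40 decoys each (~2,400 negatives) for the CV/screening benchmark; 100
simulated curves each for IC50 and Tm recovery; 200 random matrices of ≤8
molecules for the clustering oracle. One global seed is expanded
deterministically (SHA-256) into per-stage seeds, so every pipeline run,
test and acceptance quantity is reproducible bit-for-bit given the seed and
pinned library versions.

## Known limitations

- Net charge is rule-based, not a pKa model; zwitterions and unusual
  ionisable groups are handled only through their formal charges.
- Exact published TC values, CV tables and candidate counts from any given
  database snapshot are not reproducible without that snapshot; the package
  promises the procedures, constraints and conventions, verified on
  synthetic ground truth.
- The dose–response model fixes both asymptotes; data with incomplete
  inhibition plateaus need the normalisation revisited upstream.
- Decoy generation is O(actives × pool) in Tanimoto evaluations; it is
  vectorised but intended for desk-scale pools (10³–10⁵), not full ZINC.
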