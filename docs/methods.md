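# Methods

## Targeted MSA column masking

A3M semantics: uppercase letters and `-` are match states, lowercase
letters are insertions relative to the query; the first record is the
query, which must contain neither gaps nor insertions, so the number of
match columns equals the query length. The parser indexes match columns
from the query and preserves insertions verbatim, and writing is an
exact inverse (byte-identical round trip).

Masking operates on files, not on a predictor's feature pipeline: the
match-state character at each selected column is replaced with `X`
(configurable), which AlphaFold-class predictors treat as an unknown
residue, and a JSON sidecar records `{region, p, seed, masked_columns,
mask_char, include_query}` so an integrator who prefers to mask in
feature space can replay the exact plan. Masking is applied to whole
columns — the same positions in every homolog row — because the point is
to hide a column's coevolutionary signal, not individual cells. The
query row is left unmasked by default (`include_query=False`): at file
level the query defines residue identity, and whether masking it helps
is an open question for the inference engine, so it is a flag rather
than a behaviour.

Columns are drawn independently with probability *p* inside a declared
binding-site region supplied as an explicit 1-based residue list or
range spec (for class-A GPCRs this is typically the extracellular
transmembrane region down to one helical turn below the Pro–Ile–Phe
microswitch, plus the stretch of extracellular loop 2 between the
conserved cysteine and TM5 — the kit consumes such lists, it does not
derive them). Sampling uses `numpy.random.default_rng(seed)`, so a plan
is a pure function of (region, p, seed); masked counts are
Binomial(|region|, p) by construction.

Ensemble planning enumerates (masking level, state, replicate) jobs.
Defaults follow the recommended protocol: levels 0/10/20/30 %, 250
models per level — 1,000 jobs per receptor — split equally between the
active state (receptor co-folded with the G-protein α/β/γ sequences)
and the inactive state (receptor alone), which forces an even per-level
count when both states are requested. Each entry gets a derived seed,
`(base_seed + CRC32(level|state|replicate)) mod 2^31`, with a
deterministic +1 probe on the (astronomically rare) collision, so job
seeds are reproducible without a shared counter. Entries carry a
`dropout` flag (default on, matching the ensemble protocol in which all
masked levels, including 0 %, run with inference-time dropout); enabling
dropout is the inference engine's job, the manifest only records it.

## Binding-site metrics

**Site definition.** A residue belongs to the binding site iff any of
its atoms lies within 5 Å (default) of any ligand atom; multiple
ligands contribute their union. Distances use a k-d tree; an empty site
is allowed with a warning (apo case, misplaced ligand).

**Superposition.** Atoms are paired by (chain, residue number, atom
name); the least-squares rigid fit (Kabsch, proper rotation) runs in
float64 via `scipy.spatial.transform.Rotation.align_vectors`. At least
three non-collinear pairs are required. Coordinates themselves are
stored float32 (the container's native width; coordinate files carry
three decimals, ~10⁻³ Å), so identity fits recover RMSD ≈ 10⁻⁷ Å, far
below any structural signal.

**Apo ligand transfer.** For apo references the site is defined by
superposing the holo structure onto the apo on the holo site's backbone,
carrying the ligand through the transform, and deleting ligand atoms
with any receptor atom within 2.5 Å.

**Symmetry-aware RMSD.** Computed over site atoms of one class —
side-chain heavy atoms from CB outward (no OXT, no hydrogens; whether
published side-chain RMSDs include hydrogens is rarely stated, and heavy
atoms are the robust choice) or backbone N/CA/C/O. The alignment frame
is fixed first (backbone Kabsch on the site), so the sum of squared
deviations decomposes over residues, and the minimum over chemically
equivalent label swaps can be taken residue by residue — this equals the
global minimum over all 2^k label permutations, which the test suite
verifies against an explicit enumeration oracle at 10⁻⁹ Å. The default
swap table covers true chemical equivalences only: Asp OD1/OD2, Glu
OE1/OE2, Arg NH1/NH2, and the Phe/Tyr ring flip (CD1↔CD2 with CE1↔CE2,
one coupled swap). Prochiral Leu CD1/CD2 and Val CG1/CG2 are available
behind `include_prochiral` but off by default, since those labels are
distinguishable by CIP rules. Ties between swapped and unswapped
labellings keep the unswapped one. Residues whose type differs between
model and reference (engineered mutations) are skipped with a warning;
analyses of mutated pockets should exclude such references entirely.

**Capture curves.** From a (reference structures × models) RMSD table, a
reference counts as reproduced at threshold t if *any* model is within t
(min over models — the ensemble framing: one good model suffices). The
threshold grid is 1.0–2.0 Å in 0.05 Å steps (the span is standard; the
step is this kit's choice, fine enough that halving it moves the AUC by
< 10⁻³ on smooth tables). The AUC is the trapezoid integral divided by
the 1 Å span, so AUC ∈ [0, 1].

**Ensemble RMSF.** Models are aligned on the site backbone in two
passes — to the first model, then to the resulting mean structure (the
usual iterative-mean convention; a reference structure would bias the
fluctuations toward it). Per-atom RMSF_a = √(mean_m |x_a,m − x̄_a|²);
per-residue values are the RMS over the residue's class atoms (a plain
mean is available via `aggregate="mean"`; RMS is the default so that
per-residue² remains an average of per-atom², consistent with the
trajectory-analysis convention). For i.i.d. Gaussian coordinate noise of
scale σ the per-atom RMSF converges to σ√3·√(1−1/n), which the fixture
tests recover within 10 % at n = 1000. RMSF profiles are compared by
Pearson r over shared residues (≥ 3 required, zero-variance profiles
rejected).

**Confidence.** Per-model pLDDT is the mean over residues of the
per-residue value stored in the B-factor column (values outside [0, 100]
warn); per-model PAE is the mean of the off-diagonal entries of the
predicted-aligned-error matrix (the matrix is plotted in full elsewhere;
a scalar is needed for ensemble boxplots and the off-diagonal mean is
the natural one since the diagonal is ~0 by construction). Ensemble
medians of both are reported; useful reference lines are pLDDT 80 and
PAE 5.

## Enrichment metrics

Scores follow the docking-energy convention (lower is better; a flag
inverts). The ROC advances tied-score blocks as single steps, so curves
are deterministic and permutation-symmetric; the plain ROC area equals
the Mann–Whitney pair statistic with ties counted ½ (oracle-tested).

LogAUC integrates TPR over log10(FPR) on [λ, 1], λ = 0.001 (the
docking-community convention for early enrichment; the integral is
normalised by log10(1/λ) and expressed in percent). The integral is
evaluated exactly per ROC segment — for a segment with TPR linear in
FPR, ∫ y d(ln x) = (y₁ − m·x₁)·ln(x₂/x₁) + m·(x₂ − x₁) — rather than by
trapezoid on log-spaced vertices, which would be wrong for sparse vertex
sets (the all-tied diagonal has only two vertices but must yield the
random area, (1−λ)/(ln10·log10(1/λ)) ≈ 14.462 %). aLogAUC subtracts that
random area, so 0 means no discrimination.

EF1 % uses the library-fraction definition: top-N cut at
N = round(0.01·library), round half up, minimum 1; a tied block
straddling the cut contributes its pro-rata active share (this makes the
permutation-null mean exactly 1 and avoids order dependence); the
enrichment factor is (actives in top N / all actives)/(N / library). A
ROC-based variant (TPR at 1 % FPR divided by 1 %) is available behind
`roc_based=True` for comparison with that convention; the
library-fraction form is the default.

Model ranking sorts descending on aLogAUC (default; EF1 % optional),
breaking ties by the other metric and then model id, and selects
ceil(top_fraction·n) ≥ 1 models (default top 1 %). Per-receptor
summaries report the median and maximum of aLogAUC and EF1 % over a
receptor's models, and cross-receptor means of those medians/maxima;
medians of even-sized sets are the mean of the central pair.

## Ligand curation

Inputs are SMILES with activities already converted to −log10 molar
(pKi/pKd/pIC50/pEC50). Standardisation uses RDKit `rdMolStandardize`:
largest-fragment (salt/solvent stripping), uncharging, canonical
tautomer — pinned with `tautomerRemoveSp3Stereo=False` and
`tautomerRemoveBondStereo=False`, because the stereocentre filter runs
afterwards and the default canonicaliser erases sp3 stereo. The original
published workflows used a proprietary standardisation pipeline whose
exact settings are not reproducible; this kit documents its own instead.

Filters run in a fixed order — activity ≥ 6.0 (≤ 1 µM), heavy atoms
< 25, largest ring ≤ 7, stereocentres < 2 — and every removed compound
is attributed to the first stage it fails, so stage counts are
non-increasing and removals sum exactly. Stereocentres count assigned
plus unassigned tetrahedral centres (conservative: an unannotated centre
is still a docking ambiguity).

Survivors are clustered with a leader (sphere-exclusion) pass on Morgan
fingerprints (radius 2, 2048 bits) at Tanimoto ≥ 0.5, visiting compounds
in descending activity with lexicographic id tie-breaks; each cluster's
leader — its most potent member — is the representative. The published
description names only the fingerprints and threshold; leader clustering
with activity-ordered visiting is this kit's concrete choice, chosen so
the retained representative is always the most potent member and the
result is order-independent.

## Synthetic fixtures

The generators exist to give every metric a known ground truth at desk
scale:

- toy MSAs with a conservation parameter (match the query with
  probability c, else a uniform different residue or gap);
- a synthetic peptide with correct PDB atom naming (including
  Asp/Glu/Arg/Phe/Tyr side chains so the full symmetry table is
  exercised) on a helix-like curve — the geometry is generic, not a real
  fold;
- Gaussian structure ensembles (per-residue σ, anchored residues at
  σ = 0 so the alignment frame is well-posed) with closed-form RMSF;
- Gaussian score tables (decoys N(0,1), actives N(−δ,1)) with known
  expected enrichment behaviour, and label-permutation nulls;
- label-swap structures for symmetry-RMSD ground truth (an involution);
- deliberately broken A3M variants for parser error paths.

What the fixtures do *not* emulate: real fold geometry, correlated
conformational modes (noise is i.i.d.), realistic docking score
distributions (real energies are heavy-tailed and correlated with
compound properties), or property-matched decoys. Passing tests
therefore demonstrate that the *metrics and bookkeeping* are correct,
not that masked-MSA ensembles improve any particular receptor —
that conclusion requires running the external predictors and docking
engines this kit feeds.

## Workflow

`run_workflow` executes the stages whose inputs exist — (A) masking and
planning from an A3M + region file, (B/C) enrichment evaluation and
top-fraction selection from a labeled per-model score CSV, plus site
evaluation when a model directory and reference structure are supplied —
and logs an explicit skip notice for the rest, since prediction and
docking typically run elsewhere, days apart. Configs are YAML,
schema-validated with strict unknown-key rejection; percent-form masking
levels ("0,10,20,30") are normalised to fractions; defaults: λ = 0.001,
top_fraction = 0.01, site cutoff 5 Å, thresholds 1–2 Å step 0.05.
Ensembles below 250 models, fewer than 10 actives, or fewer than 50
decoys per active draw warnings, not errors. Reports carry a config
hash, the seed and the package version; timestamps live in a separate
field so two runs from identical inputs are otherwise byte-identical,
and the report's selection is by construction exactly `rank_models`
applied to the per-model metrics.

## Problem sizes used in the checks

The verification suite uses desk-scale problems chosen for statistical
adequacy: 50 random structures for the symmetry oracle (≤ 2⁶
permutations each), 10,000 label shuffles for the permutation nulls
(SEM small enough to resolve a 0.1 bias), 1,000 models for RMSF
recovery (sampling error ~2 %, well inside the 10 % band), 2,000 seeds
for per-column masking frequencies (99 % CI halfwidth ~±0.026 at
p = 0.3), and 100-model score sets for end-to-end selection. Headline
numbers from full-scale studies (capture AUCs on 119 experimental
structures, enrichment over trillions of docked poses) require the
external GPU/docking pipelines and are out of scope here.

## Known limitations

- A3M `#`-prefixed header lines (some aligners emit them) are not
  special-cased; strip them before reading.
- The symmetry table is heavy-atom and residue-type driven; modified
  residues and ligand symmetry are out of scope.
- Per-model PAE summarisation assumes the AlphaFold JSON dialect
  (`{"predicted_aligned_error": [[...]]}`, optionally list-wrapped).
- Binding-site volume, state classification from TM6 geometry, decoy
  generation and docking itself are intentionally not implemented; the
  kit consumes their outputs.
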