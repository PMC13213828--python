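"""Active-compound curation for docking benchmarks.

Known ligands exported from a bioactivity database arrive as SMILES
with an activity value already on the −log10 molar scale (pKi, pKd,
pIC50 or pEC50).  Curation keeps potent, small, dockable compounds:

1. activity: p-activity >= 6.0 (i.e. <= 1 µM);
2. size: fewer than 25 heavy atoms;
3. rings: no ring larger than seven members;
4. stereo: fewer than two stereocentres (unassigned centres count).

Survivors are clustered on Morgan fingerprints (radius 2) with a
leader-style sphere-exclusion pass at Tanimoto 0.5, visiting compounds
in descending activity so each cluster is represented by its most
potent member.  Every removed compound is attributed to exactly one
stage — the first filter it fails — in the curation report.

Input standardisation (salt stripping, charge neutralisation, canonical
tautomer) uses RDKit's ``rdMolStandardize`` with one pinned deviation
from the defaults: tautomer canonicalisation is configured to preserve
sp3 and double-bond stereochemistry, since the stereocentre filter runs
afterwards.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit import DataStructs
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit parse chatter is reported via the report

__all__ = [
    "CompoundRecord",
    "CurationReport",
    "filter_actives",
    "cluster_actives",
    "standardize_smiles",
    "curate",
]

STAGES = ("input", "parse", "activity", "heavy_atoms", "ring_size",
          "stereocenters", "clustering")

MIN_P_ACTIVITY = 6.0
MAX_HEAVY_ATOMS = 25   # exclusive: retain < 25
MAX_RING_SIZE = 7      # inclusive: retain rings <= 7
MAX_STEREOCENTERS = 2  # exclusive: retain < 2
FP_RADIUS = 2
TANIMOTO_CUTOFF = 0.5


@dataclass(frozen=True)
class CompoundRecord:
    """One ligand: SMILES plus −log10 molar activity (pKi/pKd/pIC50/pEC50)."""

    compound_id: str
    smiles: str
    p_activity: float
    source: str = ""


@dataclass
class CurationReport:
    """Stage-by-stage attrition; each removal attributed to one stage."""

    counts: dict[str, int] = field(default_factory=dict)
    retained_ids: dict[str, list[str]] = field(default_factory=dict)
    removed: dict[str, str] = field(default_factory=dict)  # id -> failing stage

    def record(self, stage: str, retained: Sequence[CompoundRecord],
               removed_ids: Sequence[str]) -> None:
        self.counts[stage] = len(retained)
        self.retained_ids[stage] = [r.compound_id for r in retained]
        for cid in removed_ids:
            self.removed.setdefault(cid, stage)

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "retained_ids": self.retained_ids,
             "removed": self.removed},
            indent=2,
        )


def _tautomer_enumerator() -> rdMolStandardize.TautomerEnumerator:
    # pinned so canonicalisation does not erase sp3/double-bond stereo
    params = rdMolStandardize.CleanupParameters()
    params.tautomerRemoveSp3Stereo = False
    params.tautomerRemoveBondStereo = False
    return rdMolStandardize.TautomerEnumerator(params)


def standardize_smiles(smiles: str) -> Chem.Mol | None:
    """Parse and standardise: largest fragment, neutralised, canonical tautomer."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        mol = rdMolStandardize.FragmentParent(mol)   # salt/solvent stripping
        mol = rdMolStandardize.Uncharger().uncharge(mol)
        mol = _tautomer_enumerator().Canonicalize(mol)
    except Exception:
        return None
    return mol


def _n_stereocenters(mol: Chem.Mol) -> int:
    """Assigned plus unassigned tetrahedral stereocentres (conservative)."""
    mol = Chem.Mol(mol)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return len(Chem.FindMolChiralCenters(mol, includeUnassigned=True,
                                         useLegacyImplementation=False))


def _max_ring_size(mol: Chem.Mol) -> int:
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def filter_actives(
    records: Sequence[CompoundRecord],
    min_p_activity: float = MIN_P_ACTIVITY,
    max_heavy_atoms: int = MAX_HEAVY_ATOMS,
    max_ring_size: int = MAX_RING_SIZE,
    max_stereocenters: int = MAX_STEREOCENTERS,
    standardize: bool = True,
) -> tuple[list[CompoundRecord], dict[str, Chem.Mol], CurationReport]:
    """Apply the activity/size/ring/stereo filters in order.

    Returns the retained records, their standardised molecules, and a
    report attributing every removal to its first failing stage.
    Compounds whose SMILES fail to parse are dropped at the parse stage.
    """
    if not records:
        raise ValueError("no compound records supplied")
    report = CurationReport()
    report.counts["input"] = len(records)
    report.retained_ids["input"] = [r.compound_id for r in records]

    mols: dict[str, Chem.Mol] = {}
    parsed, failed = [], []
    for r in records:
        if not math.isfinite(r.p_activity):
            failed.append(r.compound_id)
            continue
        mol = standardize_smiles(r.smiles) if standardize else \
            Chem.MolFromSmiles(r.smiles)
        if mol is None:
            failed.append(r.compound_id)
            continue
        mols[r.compound_id] = mol
        parsed.append(r)
    if failed:
        warnings.warn(f"{len(failed)} compounds failed to parse/standardise",
                      stacklevel=2)
    report.record("parse", parsed, failed)

    stage_filters = [
        ("activity", lambda r: r.p_activity >= min_p_activity),
        ("heavy_atoms",
         lambda r: mols[r.compound_id].GetNumHeavyAtoms() < max_heavy_atoms),
        ("ring_size",
         lambda r: _max_ring_size(mols[r.compound_id]) <= max_ring_size),
        ("stereocenters",
         lambda r: _n_stereocenters(mols[r.compound_id]) < max_stereocenters),
    ]
    retained = parsed
    for stage, keep in stage_filters:
        kept = [r for r in retained if keep(r)]
        removed = [r.compound_id for r in retained if not keep(r)]
        report.record(stage, kept, removed)
        retained = kept
    return retained, {r.compound_id: mols[r.compound_id] for r in retained}, report


def _fingerprint(mol: Chem.Mol, radius: int):
    from rdkit.Chem import rdFingerprintGenerator

    fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=2048)
    return fpgen.GetFingerprint(mol)


def cluster_actives(
    retained: Sequence[CompoundRecord],
    mols: dict[str, Chem.Mol],
    radius: int = FP_RADIUS,
    cutoff: float = TANIMOTO_CUTOFF,
) -> tuple[list[CompoundRecord], list[list[str]]]:
    """Leader-style (sphere-exclusion) clustering at a Tanimoto threshold.

    Compounds are visited in descending activity (ties by id); a compound
    joins the first existing cluster whose leader it matches at Tanimoto
    >= cutoff, otherwise founds a new one.  The leader — the most potent
    member — represents the cluster.  Returns (representatives, clusters).
    """
    if not retained:
        raise ValueError("no compounds to cluster")
    order = sorted(retained, key=lambda r: (-r.p_activity, r.compound_id))
    fps = {r.compound_id: _fingerprint(mols[r.compound_id], radius) for r in order}
    leaders: list[CompoundRecord] = []
    clusters: list[list[str]] = []
    for r in order:
        placed = False
        for leader, members in zip(leaders, clusters):
            sim = DataStructs.TanimotoSimilarity(fps[leader.compound_id],
                                                 fps[r.compound_id])
            if sim >= cutoff:
                members.append(r.compound_id)
                placed = True
                break
        if not placed:
            leaders.append(r)
            clusters.append([r.compound_id])
    return leaders, clusters


def curate(
    records: Sequence[CompoundRecord],
    min_p_activity: float = MIN_P_ACTIVITY,
    radius: int = FP_RADIUS,
    cutoff: float = TANIMOTO_CUTOFF,
) -> tuple[list[CompoundRecord], CurationReport]:
    """Full curation: filters then clustering; report covers both."""
    retained, mols, report = filter_actives(records, min_p_activity=min_p_activity)
    if not retained:
        report.record("clustering", [], [])
        return [], report
    reps, clusters = cluster_actives(retained, mols, radius=radius, cutoff=cutoff)
    rep_ids = {r.compound_id for r in reps}
    removed = [r.compound_id for r in retained if r.compound_id not in rep_ids]
    report.record("clustering", reps, removed)
    return reps, report


def read_compounds(
    path: str | Path,
    id_col: str = "compound_id",
    smiles_col: str = "smiles",
    activity_col: str = "p_activity",
    sep: str | None = None,
) -> list[CompoundRecord]:
    """Read compounds from CSV/TSV with SMILES + activity columns."""
    import pandas as pd

    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in (id_col, smiles_col, activity_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        CompoundRecord(str(i), str(s), float(a), source=str(path))
        for i, s, a in zip(df[id_col], df[smiles_col], df[activity_col])
    ]
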