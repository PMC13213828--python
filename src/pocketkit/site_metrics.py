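"""Binding-site accuracy and plasticity metrics for structure ensembles.

The central accuracy measure is a symmetry-aware side-chain RMSD over
the orthosteric-site residues: for side-chain groups whose atom labels
are chemically interchangeable (carboxylate oxygens of Asp/Glu, the
two guanidinium NH nitrogens of Arg, and the ring CD/CE pairs of
Phe/Tyr, which flip together), the per-residue squared deviation is
minimised over label swaps.  Because the superposition frame is fixed
beforehand (Kabsch fit on the binding-site backbone), the global
minimum decomposes residue by residue, so no combinatorial search
across residues is needed.

Ensemble-level measures follow: the capture curve (fraction of
experimental structures reproduced within an RMSD threshold, swept
from 1 to 2 Å, summarised by its normalised AUC), per-residue RMSF
about the iteratively aligned ensemble mean, and per-model confidence
summaries (mean pLDDT, mean off-diagonal PAE).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .structures import (
    BACKBONE_ATOMS,
    BindingSite,
    StructureModel,
    backbone_selection,
    superpose,
)

__all__ = [
    "RMSDResult",
    "CaptureCurve",
    "RMSFProfile",
    "ConfidenceSummary",
    "SYMMETRY_GROUPS",
    "PROCHIRAL_GROUPS",
    "symmetry_rmsd",
    "align_to_reference",
    "capture_curve",
    "ensemble_rmsf",
    "rmsf_correlation",
    "confidence_summary",
    "read_pae_json",
    "default_thresholds",
]

# Chemically equivalent heavy-atom label swaps, per residue type.  Each
# group is a list of (name_a, name_b) pairs swapped together: the Phe/Tyr
# ring flip exchanges CD1<->CD2 and CE1<->CE2 simultaneously.
SYMMETRY_GROUPS: dict[str, list[list[tuple[str, str]]]] = {
    "ASP": [[("OD1", "OD2")]],
    "GLU": [[("OE1", "OE2")]],
    "ARG": [[("NH1", "NH2")]],
    "PHE": [[("CD1", "CD2"), ("CE1", "CE2")]],
    "TYR": [[("CD1", "CD2"), ("CE1", "CE2")]],
}

# Prochiral methyl pairs are not strictly equivalent; off by default.
PROCHIRAL_GROUPS: dict[str, list[list[tuple[str, str]]]] = {
    "LEU": [[("CD1", "CD2")]],
    "VAL": [[("CG1", "CG2")]],
}

_BACKBONE_SET = set(BACKBONE_ATOMS)


def _class_atoms(
    atoms, index_of: Mapping[tuple[str, int, str], int], key: tuple[str, int],
    atom_class: str,
) -> dict[str, np.ndarray]:
    """Heavy atoms of one residue in the requested class, name -> coord."""
    out: dict[str, np.ndarray] = {}
    for (ch, num, name), i in index_of.items():
        if (ch, num) != key:
            continue
        if str(atoms.element[i]).upper() in {"H", "D"}:
            continue
        if atom_class == "backbone":
            if name in _BACKBONE_SET:
                out[name] = np.asarray(atoms.coord[i], dtype=np.float64)
        else:  # sidechain: heavy atoms from CB outward
            if name not in _BACKBONE_SET and name != "OXT":
                out[name] = np.asarray(atoms.coord[i], dtype=np.float64)
    return out


@dataclass(frozen=True)
class RMSDResult:
    value: float
    atom_class: str
    n_atoms: int
    swaps_applied: int
    naive_value: float

    def __post_init__(self) -> None:
        assert self.value >= 0.0
        assert self.value <= self.naive_value + 1e-12


def _residue_ss(
    model_atoms: dict[str, np.ndarray],
    ref_atoms: dict[str, np.ndarray],
    groups: list[list[tuple[str, str]]],
) -> tuple[float, float, int, int]:
    """(min squared-dev sum, naive sum, n atoms, 1 if a swap was used)."""
    names = sorted(set(model_atoms) & set(ref_atoms))
    if not names:
        return 0.0, 0.0, 0, 0
    # only groups whose atoms are all present can be swapped
    usable = [
        g for g in groups
        if all(a in names and b in names for a, b in g)
    ]
    def ss(mapping: dict[str, str]) -> float:
        total = 0.0
        for n in names:
            d = model_atoms[n] - ref_atoms[mapping.get(n, n)]
            total += float(d @ d)
        return total
    naive = ss({})
    best, best_swapped = naive, 0
    for flags in itertools.product((False, True), repeat=len(usable)):
        if not any(flags):
            continue
        mapping: dict[str, str] = {}
        for g, on in zip(usable, flags):
            if on:
                for a, b in g:
                    mapping[a] = b
                    mapping[b] = a
        val = ss(mapping)
        if val < best - 1e-15:  # ties keep the unswapped labelling
            best, best_swapped = val, 1
    return best, naive, len(names), best_swapped


def symmetry_rmsd(
    model: StructureModel,
    ref: StructureModel,
    site: BindingSite,
    atom_class: str = "sidechain",
    include_prochiral: bool = False,
) -> RMSDResult:
    """Symmetry-aware RMSD over binding-site atoms of one class.

    The model must already be superposed onto the reference (use
    :func:`align_to_reference`); the superposition is held fixed, so the
    swap minimisation is exact per residue.  Backbone class (N, CA, C, O)
    has no symmetric atoms.  Residues whose type differs between model
    and reference are skipped with a warning.
    """
    if atom_class not in {"sidechain", "backbone"}:
        raise ValueError(f"unknown atom class {atom_class!r}")
    groups_table = dict(SYMMETRY_GROUPS)
    if include_prochiral:
        for k, v in PROCHIRAL_GROUPS.items():
            groups_table.setdefault(k, []).extend(v)
    m_map = model.atom_map(site.residues)
    r_map = ref.atom_map(site.residues)

    def res_name(m: StructureModel, key: tuple[str, int]) -> str | None:
        a = m.atoms
        hit = (a.chain_id == key[0]) & (a.res_id == key[1])
        return str(a.res_name[hit][0]) if hit.any() else None

    total_ss = naive_ss = 0.0
    n_atoms = swaps = 0
    for key in site.sorted():
        mname, rname = res_name(model, key), res_name(ref, key)
        if mname is None or rname is None:
            warnings.warn(f"site residue {key} missing from model or reference",
                          stacklevel=2)
            continue
        if mname != rname:
            warnings.warn(
                f"residue type mismatch at {key}: {mname} vs {rname}; skipped",
                stacklevel=2,
            )
            continue
        m_atoms = _class_atoms(model.atoms, m_map, key, atom_class)
        r_atoms = _class_atoms(ref.atoms, r_map, key, atom_class)
        groups = groups_table.get(mname, []) if atom_class == "sidechain" else []
        ss, naive, n, swapped = _residue_ss(m_atoms, r_atoms, groups)
        total_ss += ss
        naive_ss += naive
        n_atoms += n
        swaps += swapped
    if n_atoms == 0:
        raise ValueError("no shared binding-site atoms between model and reference")
    return RMSDResult(
        value=float(np.sqrt(total_ss / n_atoms)),
        atom_class=atom_class,
        n_atoms=n_atoms,
        swaps_applied=swaps,
        naive_value=float(np.sqrt(naive_ss / n_atoms)),
    )


def align_to_reference(
    model: StructureModel, ref: StructureModel, site: BindingSite
) -> StructureModel:
    """Superpose a model onto the reference on the binding-site backbone."""
    tr, _ = superpose(model, ref, backbone_selection(site))
    atoms = model.atoms.copy()
    atoms.coord = tr.apply(atoms.coord)
    return StructureModel(atoms=atoms, model_id=model.model_id,
                          plddt_available=model.plddt_available)


# --- capture curves --------------------------------------------------------


def default_thresholds(start: float = 1.0, stop: float = 2.0,
                       step: float = 0.05) -> np.ndarray:
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass(frozen=True)
class CaptureCurve:
    """Fraction of experimental structures captured vs RMSD threshold."""

    thresholds: np.ndarray
    fractions: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.fractions) >= -1e-12)
        assert 0.0 <= self.auc <= 1.0 + 1e-12


def capture_curve(
    rmsd_table: np.ndarray | Sequence[Sequence[float]],
    thresholds: np.ndarray | None = None,
) -> CaptureCurve:
    """Capture curve from a (structures x models) RMSD table.

    An experimental structure counts as captured at threshold t if ANY
    model in the ensemble reproduces it within t (min over models).  The
    AUC is the trapezoid integral normalised by the threshold span, so a
    curve pinned at 1 gives AUC 1.
    """
    table = np.asarray(rmsd_table, dtype=float)
    if table.ndim == 1:
        table = table[:, None]
    if table.size == 0:
        raise ValueError("empty RMSD table")
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)
    best = table.min(axis=1)  # min over models, per structure
    fractions = (best[:, None] <= thresholds[None, :]).mean(axis=0)
    span = thresholds[-1] - thresholds[0]
    auc = float(np.trapezoid(fractions, thresholds) / span)
    return CaptureCurve(thresholds=thresholds, fractions=fractions, auc=auc)


# --- ensemble RMSF ---------------------------------------------------------


@dataclass
class RMSFProfile:
    """Per-residue (and per-atom) fluctuation about the aligned ensemble mean."""

    per_residue: dict[tuple[str, int], float]
    per_atom: dict[tuple[str, int, str], float]
    atom_class: str
    n_models: int

    @property
    def median(self) -> float:
        return float(np.median(list(self.per_residue.values())))


def ensemble_rmsf(
    models: Sequence[StructureModel],
    site: BindingSite,
    atom_class: str = "sidechain",
    aggregate: str = "rms",
) -> RMSFProfile:
    """Per-residue RMSF of binding-site atoms across an ensemble.

    Models are aligned on the binding-site backbone in two passes (align
    to the first model, recompute the mean structure, re-align to the
    mean), then per-atom RMSF_a = sqrt(mean_m |x_a,m - mean_a|^2).  The
    residue value is the RMS over its class atoms ('rms', default) or
    the plain mean ('mean').
    """
    if len(models) < 2:
        raise ValueError("RMSF needs at least 2 models")
    if aggregate not in {"rms", "mean"}:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    residues = site.sorted()

    # atoms of the requested class present in every model
    maps = [m.atom_map(site.residues) for m in models]
    common: list[tuple[str, int, str]] = []
    for key in residues:
        names = None
        for m, amap in zip(models, maps):
            atoms = _class_atoms(m.atoms, amap, key, atom_class)
            names = set(atoms) if names is None else names & set(atoms)
        if not names:
            warnings.warn(f"residue {key} has no shared {atom_class} atoms; skipped",
                          stacklevel=2)
            continue
        common.extend((key[0], key[1], n) for n in sorted(names))
    if not common:
        raise ValueError("no shared binding-site atoms across the ensemble")

    def stacked(ref: StructureModel) -> np.ndarray:
        out = np.empty((len(models), len(common), 3))
        for i, m in enumerate(models):
            aligned = align_to_reference(m, ref, site)
            a_map = aligned.atom_map(site.residues)
            for j, key in enumerate(common):
                out[i, j] = aligned.atoms.coord[a_map[key]]
        return out

    # pass 1: align everything to the first model
    coords = stacked(models[0])
    # pass 2: write the pass-1 mean into a template and re-align to it
    mean1 = coords.mean(axis=0)
    tmpl = models[0].atoms.copy()
    amap0 = models[0].atom_map(site.residues)
    for j, key in enumerate(common):
        tmpl.coord[amap0[key]] = mean1[j]
    mean_struct = StructureModel(atoms=tmpl, model_id="__ensemble_mean__")
    coords = stacked(mean_struct)

    mean = coords.mean(axis=0)
    per_atom_vals = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    per_atom = {key: float(v) for key, v in zip(common, per_atom_vals)}
    per_residue: dict[tuple[str, int], float] = {}
    for key in residues:
        vals = [v for (ch, num, _), v in per_atom.items() if (ch, num) == key]
        if not vals:
            continue
        if aggregate == "rms":
            per_residue[key] = float(np.sqrt(np.mean(np.square(vals))))
        else:
            per_residue[key] = float(np.mean(vals))
    return RMSFProfile(per_residue=per_residue, per_atom=per_atom,
                       atom_class=atom_class, n_models=len(models))


def rmsf_correlation(a: RMSFProfile, b: RMSFProfile) -> float:
    """Pearson r between two RMSF profiles over their shared residues."""
    shared = sorted(set(a.per_residue) & set(b.per_residue))
    if len(shared) < 3:
        raise ValueError(f"profiles share only {len(shared)} residues (need >= 3)")
    xa = np.array([a.per_residue[k] for k in shared])
    xb = np.array([b.per_residue[k] for k in shared])
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("zero variance in an RMSF profile")
    return float(stats.pearsonr(xa, xb).statistic)


# --- model confidence ------------------------------------------------------


@dataclass(frozen=True)
class ConfidenceSummary:
    per_model_plddt: tuple[float, ...]
    per_model_pae: tuple[float, ...]
    median_plddt: float
    median_pae: float


def read_pae_json(path: str | Path) -> np.ndarray:
    """Read a predicted-aligned-error matrix from AlphaFold-style JSON."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        data = data[0]
    matrix = np.asarray(data["predicted_aligned_error"], dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{path}: PAE matrix is not square: {matrix.shape}")
    return matrix


def _per_residue_plddt(model: StructureModel) -> np.ndarray:
    """pLDDT per residue: the B-factor value shared by the residue's atoms."""
    prot = model.protein()
    vals = []
    seen: set[tuple[str, int]] = set()
    for i in range(prot.array_length()):
        key = (str(prot.chain_id[i]), int(prot.res_id[i]))
        if key in seen:
            continue
        seen.add(key)
        vals.append(float(prot.b_factor[i]))
    return np.asarray(vals)


def confidence_summary(
    models: Sequence[StructureModel],
    pae_matrices: Sequence[np.ndarray] | None = None,
) -> ConfidenceSummary:
    """Per-model mean pLDDT / mean off-diagonal PAE and their ensemble medians."""
    plddts = []
    for m in models:
        vals = _per_residue_plddt(m)
        if vals.min() < 0 or vals.max() > 100:
            warnings.warn(
                f"{m.model_id!r}: pLDDT outside [0, 100] "
                f"(min {vals.min():.1f}, max {vals.max():.1f})",
                stacklevel=2,
            )
        plddts.append(float(vals.mean()))
    paes: list[float] = []
    if pae_matrices is not None:
        for mat in pae_matrices:
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError(f"PAE matrix is not square: {mat.shape}")
            n = mat.shape[0]
            off = (mat.sum() - np.trace(mat)) / (n * (n - 1)) if n > 1 else 0.0
            paes.append(float(off))
    return ConfidenceSummary(
        per_model_plddt=tuple(plddts),
        per_model_pae=tuple(paes),
        median_plddt=float(np.median(plddts)) if plddts else float("nan"),
        median_pae=float(np.median(paes)) if paes else float("nan"),
    )
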