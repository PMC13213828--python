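"""Synthetic desk-scale inputs with known ground truth.

Everything downstream — masking, superposition, symmetry RMSD, RMSF,
enrichment — can be exercised on fixtures generated here, with closed
forms available for the expected answers: Gaussian coordinate noise of
scale σ gives a per-atom RMSF of σ√3 (E|Δr|² = 3σ²), and Gaussian
score tables with class separation δ have a known ROC in expectation.

All geometry is synthetic: the toy protein has proper residue/atom
names (including Asp/Glu/Phe/Tyr/Arg side chains for the symmetry
table) but its coordinates are a generic helix-like curve, not a real
fold.  Every fixture is reproducible from its parameters and seed.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc

from .msa import MSA
from .enrichment import ScoreRecord, ScoreTable
from .site_metrics import PROCHIRAL_GROUPS, SYMMETRY_GROUPS
from .structures import StructureModel

__all__ = [
    "AMINO_ALPHABET",
    "make_toy_msa",
    "make_broken_a3m",
    "make_toy_protein",
    "make_toy_ensemble",
    "make_scores",
    "make_swap_fixture",
]

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def make_toy_msa(n_rows: int, length: int, conservation: float, seed: int) -> MSA:
    """Query plus homolog rows matching the query with the given probability.

    Non-matching positions become a uniformly chosen different residue or
    a gap.  Output is a valid A3M alignment (no insertions).
    """
    if n_rows < 1 or length < 1:
        raise ValueError("n_rows and length must be >= 1")
    if not 0.0 <= conservation <= 1.0:
        raise ValueError("conservation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ALPHABET))
    query = "".join(rng.choice(letters, size=length))
    rows = [("query", query)]
    for i in range(1, n_rows):
        chars = []
        for qc in query:
            if rng.random() < conservation:
                chars.append(qc)
            else:
                others = [c for c in AMINO_ALPHABET if c != qc] + ["-"]
                chars.append(others[rng.integers(len(others))])
        rows.append((f"homolog_{i}", "".join(chars)))
    return MSA(rows=rows, query_index=0)


def make_broken_a3m(kind: str) -> str:
    """Deliberately malformed A3M text to exercise parser error paths."""
    variants = {
        "empty": "",
        "ragged": ">query\nMKT\n>homolog_1\nMKTA\n",
        "query_gap": ">query\nM-KT\n>homolog_1\nMAKT\n",
        "query_insertion": ">query\nMaKT\n>homolog_1\nMKT\n",
    }
    if kind not in variants:
        raise ValueError(f"unknown broken-A3M kind {kind!r}: {sorted(variants)}")
    return variants[kind]


# --- toy structures --------------------------------------------------------

# Local side-chain geometry (Å offsets from CA); names follow PDB
# conventions so the symmetry table applies.  Synthetic, not real geometry.
_SIDECHAINS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "GLY": [],
    "ALA": [("CB", (0.0, 1.5, 0.5))],
    "SER": [("CB", (0.0, 1.5, 0.5)), ("OG", (0.0, 2.4, 1.6))],
    "VAL": [("CB", (0.0, 1.5, 0.5)), ("CG1", (-0.9, 2.4, 1.2)),
            ("CG2", (0.9, 2.4, 1.2))],
    "LEU": [("CB", (0.0, 1.5, 0.5)), ("CG", (0.0, 2.6, 1.4)),
            ("CD1", (-1.0, 3.4, 1.9)), ("CD2", (1.0, 3.4, 1.9))],
    "ASP": [("CB", (0.0, 1.5, 0.5)), ("CG", (0.0, 2.7, 1.3)),
            ("OD1", (-1.0, 3.4, 1.6)), ("OD2", (1.0, 3.4, 1.6))],
    "GLU": [("CB", (0.0, 1.5, 0.5)), ("CG", (0.0, 2.7, 1.3)),
            ("CD", (0.0, 3.9, 2.1)), ("OE1", (-1.0, 4.6, 2.4)),
            ("OE2", (1.0, 4.6, 2.4))],
    "ARG": [("CB", (0.0, 1.5, 0.5)), ("CG", (0.0, 2.7, 1.3)),
            ("CD", (0.0, 3.9, 2.1)), ("NE", (0.0, 5.0, 2.9)),
            ("CZ", (0.0, 6.1, 3.4)), ("NH1", (-1.1, 6.8, 3.6)),
            ("NH2", (1.1, 6.8, 3.6))],
    "PHE": [("CB", (0.0, 1.5, 0.5)), ("CG", (0.0, 2.8, 1.2)),
            ("CD1", (-1.2, 3.5, 1.5)), ("CD2", (1.2, 3.5, 1.5)),
            ("CE1", (-1.2, 4.9, 1.9)), ("CE2", (1.2, 4.9, 1.9)),
            ("CZ", (0.0, 5.6, 2.1))],
    "TYR": [("CB", (0.0, 1.5, 0.5)), ("CG", (0.0, 2.8, 1.2)),
            ("CD1", (-1.2, 3.5, 1.5)), ("CD2", (1.2, 3.5, 1.5)),
            ("CE1", (-1.2, 4.9, 1.9)), ("CE2", (1.2, 4.9, 1.9)),
            ("CZ", (0.0, 5.6, 2.1)), ("OH", (0.0, 6.9, 2.5))],
}

_THREE = {
    "A": "ALA", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "L": "LEU", "R": "ARG", "S": "SER", "V": "VAL", "Y": "TYR",
}

_BACKBONE = [("N", (-1.45, 0.0, 0.0)), ("CA", (0.0, 0.0, 0.0)),
             ("C", (1.52, 0.0, 0.0)), ("O", (2.15, 1.05, 0.0))]


def make_toy_protein(
    sequence: str = "ADERFYLVSG",
    chain: str = "A",
    start_res: int = 1,
    bfactor: float = 80.0,
    model_id: str = "toy",
) -> StructureModel:
    """A synthetic peptide with PDB-style atom naming on a helix-like curve.

    Sequence letters are restricted to {A,D,E,F,G,L,R,S,V,Y}, which covers
    every residue type in the atom-symmetry table.
    """
    atoms: list[struc.Atom] = []
    for i, letter in enumerate(sequence):
        if letter not in _THREE:
            raise ValueError(f"unsupported toy residue {letter!r}")
        res_name = _THREE[letter]
        # CA path: gentle helix so backbones are never collinear
        t = i * 0.8
        origin = np.array([3.8 * i, 2.3 * np.sin(t), 2.3 * np.cos(t)])
        for name, offset in _BACKBONE + _SIDECHAINS[res_name]:
            atoms.append(
                struc.Atom(
                    coord=origin + np.asarray(offset),
                    chain_id=chain,
                    res_id=start_res + i,
                    res_name=res_name,
                    atom_name=name,
                    element=name[0],
                    hetero=False,
                    b_factor=bfactor,
                    occupancy=1.0,
                )
            )
    arr = struc.array(atoms)
    return StructureModel(atoms=arr, model_id=model_id)


def make_toy_ensemble(
    base: StructureModel,
    sigma_profile: dict[tuple[str, int], float],
    n_models: int,
    seed: int,
    anchor: set[tuple[str, int]] | None = None,
) -> list[StructureModel]:
    """Base structure plus i.i.d. Gaussian per-coordinate noise per residue.

    ``sigma_profile`` maps (chain, residue number) to the noise scale in Å;
    residues absent from the profile, and all ``anchor`` residues, get σ=0
    so the alignment frame is well-posed.  Per-atom RMSF then converges to
    σ√3 for large ensembles.
    """
    if any(s < 0 for s in sigma_profile.values()):
        raise ValueError("negative sigma in profile")
    anchor = anchor or set()
    rng = np.random.default_rng(seed)
    a = base.atoms
    sigmas = np.zeros(a.array_length())
    for i in range(a.array_length()):
        key = (str(a.chain_id[i]), int(a.res_id[i]))
        if key not in anchor:
            sigmas[i] = sigma_profile.get(key, 0.0)
    models = []
    for k in range(n_models):
        atoms = a.copy()
        noise = rng.normal(size=(a.array_length(), 3)) * sigmas[:, None]
        atoms.coord = atoms.coord + noise
        models.append(StructureModel(atoms=atoms, model_id=f"{base.model_id}_{k}",
                                     plddt_available=base.plddt_available))
    return models


def make_scores(
    n_actives: int,
    n_decoys: int,
    delta: float,
    seed: int,
    model_id: str = "synthetic",
    receptor_id: str = "toy_receptor",
) -> ScoreTable:
    """Gaussian score table: decoys ~ N(0,1), actives ~ N(−δ,1); lower = better."""
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    records = [
        ScoreRecord(f"A{i:05d}", float(s), "active")
        for i, s in enumerate(rng.normal(-delta, 1.0, n_actives))
    ] + [
        ScoreRecord(f"D{i:05d}", float(s), "decoy")
        for i, s in enumerate(rng.normal(0.0, 1.0, n_decoys))
    ]
    return ScoreTable(records=records, model_id=model_id, receptor_id=receptor_id)


def make_swap_fixture(
    structure: StructureModel,
    residues: set[tuple[str, int]],
    include_prochiral: bool = False,
) -> StructureModel:
    """Copy with chemically equivalent atom labels swapped, coordinates untouched.

    Applying it twice restores the original labels.  Raises if a requested
    residue has no symmetric atom pair.
    """
    table = dict(SYMMETRY_GROUPS)
    if include_prochiral:
        for k, v in PROCHIRAL_GROUPS.items():
            table.setdefault(k, []).extend(v)
    atoms = structure.atoms.copy()
    names = atoms.atom_name.astype("U6").copy()
    for key in sorted(residues):
        mask = (atoms.chain_id == key[0]) & (atoms.res_id == key[1])
        if not mask.any():
            raise ValueError(f"residue {key} not in structure")
        res_name = str(atoms.res_name[mask][0])
        groups = table.get(res_name)
        if not groups:
            raise ValueError(f"residue {key} ({res_name}) has no symmetric atoms")
        idx = np.nonzero(mask)[0]
        for group in groups:
            for a, b in group:
                ia = [i for i in idx if names[i] == a]
                ib = [i for i in idx if names[i] == b]
                if ia and ib:
                    names[ia[0]], names[ib[0]] = b, a
    atoms.atom_name = names
    return StructureModel(atoms=atoms, model_id=structure.model_id + "_swapped",
                         plddt_available=structure.plddt_available)
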