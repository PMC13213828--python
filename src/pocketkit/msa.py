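"""A3M alignment handling and targeted binding-site column masking.

An A3M file is a FASTA-shaped multiple sequence alignment in which
uppercase letters and ``-`` are match states (columns of the alignment)
and lowercase letters are insertions relative to the query.  The first
record is the query, which by construction contains only match states
and no gaps, so the number of match columns equals the query length.

Masking replaces the match-state character at selected columns with an
"unknown residue" character (default ``X``) in every non-query row.
Hiding a column this way attenuates the coevolutionary signal a
structure predictor can extract from it, which diversifies the
conformations sampled for the corresponding residues.  Columns are
drawn independently within a declared binding-site region with a fixed
probability and seed, so a masking plan is fully reproducible.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "MSA",
    "MaskRegion",
    "MaskPlan",
    "ManifestEntry",
    "EnsembleManifest",
    "A3MParseError",
    "read_a3m",
    "write_a3m",
    "load_region",
    "sample_mask",
    "apply_mask",
    "build_ensemble_manifest",
]


class A3MParseError(ValueError):
    """Raised when an A3M file violates the format invariants."""


def _match_states(seq: str) -> str:
    """Match-state string of an aligned row (uppercase + '-', insertions dropped)."""
    return "".join(c for c in seq if not c.islower())


@dataclass
class MSA:
    """An A3M-style alignment: ordered (header, aligned sequence) rows.

    ``query_index`` marks the row holding the target sequence;
    ``n_match_columns`` equals the query length.
    """

    rows: list[tuple[str, str]]
    query_index: int = 0
    n_match_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise A3MParseError("alignment has no rows")
        header, qseq = self.rows[self.query_index]
        if "-" in qseq or any(c.islower() for c in qseq):
            raise A3MParseError(
                f"query row {header!r} contains gaps or insertions"
            )
        self.n_match_columns = len(qseq)
        for h, seq in self.rows:
            n = len(_match_states(seq))
            if n != self.n_match_columns:
                raise A3MParseError(
                    f"row {h!r} has {n} match states, expected {self.n_match_columns}"
                )

    @property
    def query(self) -> str:
        return self.rows[self.query_index][1]


def read_a3m(path: str | Path) -> MSA:
    """Read an A3M alignment; the first record is taken as the query."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise A3MParseError(f"{path}: empty alignment file")
    rows = [(r.description, str(r.seq)) for r in records]
    return MSA(rows=rows, query_index=0)


def write_a3m(msa: MSA, path: str | Path) -> Path:
    """Write an alignment to A3M, preserving headers and case verbatim."""
    path = Path(path)
    with open(path, "w") as fh:
        for header, seq in msa.rows:
            fh.write(f">{header}\n{seq}\n")
    return path


@dataclass(frozen=True)
class MaskRegion:
    """1-based query-sequence positions eligible for masking."""

    residue_indices: frozenset[int]
    label: str = "region"

    def __post_init__(self) -> None:
        if not self.residue_indices:
            raise ValueError("mask region is empty")
        if min(self.residue_indices) < 1:
            raise ValueError("residue indices are 1-based; got index < 1")


_RANGE_RE = re.compile(r"^(\d+)(?:\s*-\s*(\d+))?$")


def load_region(
    spec: str | Iterable[int | str],
    query_length: int | None = None,
    label: str = "region",
) -> MaskRegion:
    """Expand a residue-index/range spec ("40-42, 45" or a list) into a region.

    Indices are 1-based; ranges are closed.  If ``query_length`` is given,
    indices beyond it are rejected.
    """
    if isinstance(spec, str):
        tokens: list[str] = [t for t in re.split(r"[,\s]+", spec.strip()) if t]
    else:
        tokens = []
        for item in spec:
            tokens.extend(t for t in re.split(r"[,\s]+", str(item).strip()) if t)
    if not tokens:
        raise ValueError("empty region spec")
    indices: set[int] = set()
    for tok in tokens:
        m = _RANGE_RE.match(tok)
        if not m:
            raise ValueError(f"cannot parse region token {tok!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if lo < 1:
            raise ValueError(f"residue index {lo} out of range (1-based)")
        if hi < lo:
            raise ValueError(f"inverted range {tok!r}")
        indices.update(range(lo, hi + 1))
    if query_length is not None and max(indices) > query_length:
        raise ValueError(
            f"region index {max(indices)} exceeds query length {query_length}"
        )
    return MaskRegion(frozenset(indices), label=label)


def load_region_file(path: str | Path, query_length: int | None = None) -> MaskRegion:
    """Read a region spec from a text file of indices/ranges (comments with '#')."""
    text = Path(path).read_text()
    lines = [ln.split("#", 1)[0] for ln in text.splitlines()]
    return load_region(" ".join(lines), query_length=query_length,
                       label=Path(path).stem)


@dataclass(frozen=True)
class MaskPlan:
    """The sampled set of masked columns for one model job.

    ``masked_columns`` are 1-based match-column indices, always a subset of
    the region the plan was drawn from.  The same (region, p, seed) always
    reproduces the same plan.
    """

    masked_columns: frozenset[int]
    region: MaskRegion
    probability: float
    seed: int
    mask_char: str = "X"
    include_query: bool = False

    def __post_init__(self) -> None:
        if not self.masked_columns <= self.region.residue_indices:
            raise ValueError("masked columns outside the declared region")

    def to_json(self) -> str:
        return json.dumps(
            {
                "region": sorted(self.region.residue_indices),
                "region_label": self.region.label,
                "p": self.probability,
                "seed": self.seed,
                "masked_columns": sorted(self.masked_columns),
                "mask_char": self.mask_char,
                "include_query": self.include_query,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaskPlan":
        d = json.loads(text)
        region = MaskRegion(frozenset(d["region"]), d.get("region_label", "region"))
        return cls(
            masked_columns=frozenset(d["masked_columns"]),
            region=region,
            probability=d["p"],
            seed=d["seed"],
            mask_char=d.get("mask_char", "X"),
            include_query=d.get("include_query", False),
        )


def sample_mask(
    region: MaskRegion,
    p: float,
    seed: int,
    mask_char: str = "X",
    include_query: bool = False,
) -> MaskPlan:
    """Draw each region column independently with probability ``p`` (seeded)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"masking probability {p} outside [0, 1]")
    columns = np.array(sorted(region.residue_indices))
    rng = np.random.default_rng(seed)
    chosen = columns[rng.random(columns.size) < p]
    return MaskPlan(
        masked_columns=frozenset(int(c) for c in chosen),
        region=region,
        probability=p,
        seed=seed,
        mask_char=mask_char,
        include_query=include_query,
    )


def apply_mask(msa: MSA, plan: MaskPlan) -> MSA:
    """Replace match states at masked columns with the mask character.

    All non-query rows are masked at the same columns (column masking);
    the query row is masked only if the plan says so.  Insertions
    (lowercase) and unmasked columns are untouched.
    """
    if plan.masked_columns and max(plan.masked_columns) > msa.n_match_columns:
        raise ValueError(
            f"masked column {max(plan.masked_columns)} beyond "
            f"{msa.n_match_columns} match columns"
        )
    masked = plan.masked_columns
    out_rows: list[tuple[str, str]] = []
    for i, (header, seq) in enumerate(msa.rows):
        if i == msa.query_index and not plan.include_query:
            out_rows.append((header, seq))
            continue
        chars = list(seq)
        col = 0
        for j, c in enumerate(chars):
            if c.islower():
                continue
            col += 1
            if col in masked:
                chars[j] = plan.mask_char
        out_rows.append((header, "".join(chars)))
    return MSA(rows=out_rows, query_index=msa.query_index)


# --- ensemble planning -----------------------------------------------------

STATES = ("active", "inactive")


@dataclass(frozen=True)
class ManifestEntry:
    masking_level: float
    state: str
    replicate: int
    seed: int
    dropout: bool = True


@dataclass
class EnsembleManifest:
    """The planned set of (masking level, state, replicate) model jobs."""

    receptor_id: str
    entries: list[ManifestEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def count(self, state: str | None = None, level: float | None = None) -> int:
        n = 0
        for e in self.entries:
            if state is not None and e.state != state:
                continue
            if level is not None and e.masking_level != level:
                continue
            n += 1
        return n

    def to_json(self) -> str:
        return json.dumps(
            {
                "receptor_id": self.receptor_id,
                "entries": [
                    {
                        "masking_level": e.masking_level,
                        "state": e.state,
                        "replicate": e.replicate,
                        "seed": e.seed,
                        "dropout": e.dropout,
                    }
                    for e in self.entries
                ],
            },
            indent=2,
        )


def _entry_seed(base_seed: int, level: float, state: str, replicate: int) -> int:
    # stable across runs/platforms: CRC32 of a canonical key string
    key = f"{level:.6f}|{state}|{replicate}".encode()
    return (base_seed + zlib.crc32(key)) % (2**31)


def build_ensemble_manifest(
    receptor_id: str,
    levels: Sequence[float],
    per_level: int,
    states: Sequence[str] = STATES,
    base_seed: int = 0,
    dropout: bool = True,
) -> EnsembleManifest:
    """Plan one model job per (level, state, replicate) with derived seeds.

    With both receptor states requested, replicates are split equally
    between them, so ``per_level`` must be even.  The recommended ensemble
    is 250 models at each of the 0/10/20/30% masking levels, i.e. 1,000
    jobs with a 500/500 active/inactive split.
    """
    if per_level < 1:
        raise ValueError("per_level must be >= 1")
    if len(set(levels)) != len(levels):
        raise ValueError("duplicate masking levels")
    states = list(states)
    if not states or any(s not in STATES for s in states):
        raise ValueError(f"states must be drawn from {STATES}")
    if len(states) == 2 and per_level % 2:
        raise ValueError("per_level must be even to split states equally")
    per_state = per_level // len(states)
    entries: list[ManifestEntry] = []
    used_seeds: set[int] = set()
    for level in levels:
        for state in states:
            for rep in range(per_state):
                seed = _entry_seed(base_seed, float(level), state, rep)
                while seed in used_seeds:  # CRC collisions: resolve deterministically
                    seed = (seed + 1) % (2**31)
                used_seeds.add(seed)
                entries.append(
                    ManifestEntry(
                        masking_level=float(level),
                        state=state,
                        replicate=rep,
                        seed=seed,
                        dropout=dropout,
                    )
                )
    return EnsembleManifest(receptor_id=receptor_id, entries=entries)
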