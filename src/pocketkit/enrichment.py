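"""Semilog-ROC virtual-screening metrics for labeled docking score tables.

Early enrichment — pulling true ligands to the very top of a ranked
library of actives and property-matched decoys — is what matters in a
prospective screen, so the ROC area is computed on a log10-scaled
false-positive axis (LogAUC).  The false-positive rate is clamped below
at λ (default 0.001) and the area is normalised by log10(1/λ), giving a
percentage in [0, 100]; a random ranking scores (1−λ)/(ln10·log10(1/λ))
≈ 14.462% at λ=0.001, and the adjusted LogAUC (aLogAUC) subtracts that
random area so 0 means no discrimination.  The enrichment factor at 1%
(EF1%) is the fraction of actives recovered in the top 1% of the ranked
library divided by the actives' fraction of the whole library.

Scores follow the docking-energy convention: lower is better (a flag
inverts this for score-like inputs).  Ties are handled as blocks: the
ROC advances through a tied block in a single step and the EF cut takes
the tied block's pro-rata active share, so all metrics are deterministic
and permutation-symmetric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreRecord",
    "ScoreTable",
    "EnrichmentResult",
    "EnsembleSummary",
    "read_scores",
    "read_two_file_scores",
    "roc",
    "roc_auc",
    "logauc",
    "random_logauc",
    "alogauc",
    "ef_at",
    "evaluate",
    "rank_models",
    "aggregate_receptors",
]

DEFAULT_LAMBDA = 0.001


@dataclass(frozen=True)
class ScoreRecord:
    compound_id: str
    score: float
    label: str  # "active" | "decoy"


@dataclass
class ScoreTable:
    """Labeled docking scores for one model of one receptor (lower = better)."""

    records: list[ScoreRecord]
    model_id: str = ""
    receptor_id: str = ""

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dup[:5]}")
        for r in self.records:
            if r.label not in {"active", "decoy"}:
                raise ValueError(f"unknown label {r.label!r} for {r.compound_id}")

    @property
    def n_actives(self) -> int:
        return sum(r.label == "active" for r in self.records)

    @property
    def n_decoys(self) -> int:
        return sum(r.label == "decoy" for r in self.records)

    def require_both_classes(self) -> None:
        if self.n_actives == 0 or self.n_decoys == 0:
            raise ValueError(
                f"score table {self.model_id!r} needs >= 1 active and >= 1 decoy "
                f"(got {self.n_actives} actives, {self.n_decoys} decoys)"
            )

    def arrays(self, higher_is_better: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(scores, is_active) with scores oriented so lower is better."""
        scores = np.array([r.score for r in self.records], dtype=float)
        if higher_is_better:
            scores = -scores
        is_active = np.array([r.label == "active" for r in self.records])
        return scores, is_active


def read_scores(
    path: str | Path,
    id_col: str = "compound_id",
    score_col: str = "score",
    label_col: str = "label",
    sep: str | None = None,
    model_id: str = "",
    receptor_id: str = "",
) -> ScoreTable:
    """Read a delimited score table with id/score/label columns.

    The delimiter is sniffed from the suffix (.tsv → tab) unless given.
    Rows whose score fails to parse are reported and dropped.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in (id_col, score_col, label_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    scores = pd.to_numeric(df[score_col], errors="coerce")
    bad = scores.isna()
    if bad.any():
        warnings.warn(
            f"{path}: dropped {int(bad.sum())} unparseable rows "
            f"(ids: {list(df.loc[bad, id_col].astype(str)[:3])}...)",
            stacklevel=2,
        )
    df = df[~bad]
    records = [
        ScoreRecord(str(i), float(s), str(l).strip().lower())
        for i, s, l in zip(df[id_col], df[score_col], df[label_col])
    ]
    table = ScoreTable(records=records, model_id=model_id or path.stem,
                       receptor_id=receptor_id)
    table.require_both_classes()
    return table


def read_two_file_scores(
    actives_path: str | Path,
    decoys_path: str | Path,
    model_id: str = "",
    receptor_id: str = "",
) -> ScoreTable:
    """DOCK-style dialect: one "id score" line per compound, one file per class."""

    def parse(path: Path, label: str) -> list[ScoreRecord]:
        recs = []
        for ln in path.read_text().splitlines():
            parts = ln.split()
            if len(parts) < 2 or parts[0].startswith("#"):
                continue
            recs.append(ScoreRecord(parts[0], float(parts[1]), label))
        return recs

    records = parse(Path(actives_path), "active") + parse(Path(decoys_path), "decoy")
    table = ScoreTable(records=records,
                       model_id=model_id or Path(actives_path).stem,
                       receptor_id=receptor_id)
    table.require_both_classes()
    return table


# --- ROC -------------------------------------------------------------------


def roc(table: ScoreTable, higher_is_better: bool = False) -> np.ndarray:
    """ROC points (FPR, TPR) from best to worst score, ties as one block.

    Returns an (n+1, 2) array starting at (0, 0) and ending at (1, 1);
    each tied-score block contributes a single vertex.
    """
    table.require_both_classes()
    scores, is_active = table.arrays(higher_is_better)
    order = np.argsort(scores, kind="stable")
    scores, is_active = scores[order], is_active[order]
    n_act, n_dec = is_active.sum(), (~is_active).sum()
    # block boundaries: last index of each distinct score
    boundaries = np.nonzero(np.diff(scores))[0]
    ends = np.append(boundaries, len(scores) - 1)
    cum_act = np.cumsum(is_active)[ends]
    cum_dec = np.cumsum(~is_active)[ends]
    pts = np.column_stack([cum_dec / n_dec, cum_act / n_act])
    return np.vstack([[0.0, 0.0], pts])


def roc_auc(rocpts: np.ndarray) -> float:
    """Plain (linear-axis) area under a block-step ROC, trapezoid rule."""
    x, y = rocpts[:, 0], rocpts[:, 1]
    return float(np.trapezoid(y, x))


def logauc(rocpts: np.ndarray, lam: float = DEFAULT_LAMBDA) -> float:
    """Semilog ROC area, in percent.

    Integrates TPR d(log10 FPR) over [λ, 1] exactly on the piecewise-linear
    ROC (FPR clamped below at λ), normalised by log10(1/λ).  A perfect
    classifier gives 100; worst case 0.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda {lam} outside (0, 1)")
    pts = np.asarray(rocpts, dtype=float)
    total = 0.0
    for (x1, y1), (x2, y2) in zip(pts[:-1], pts[1:]):
        if x2 <= lam or x2 <= x1:
            continue  # below the clamp, or a vertical step (no x-extent)
        lo = max(x1, lam)
        m = (y2 - y1) / (x2 - x1)
        a = y1 - m * x1
        # ∫ y d(ln x) for y = a + m x over [lo, x2]
        total += a * math.log(x2 / lo) + m * (x2 - lo)
    return total / math.log(10) / math.log10(1.0 / lam) * 100.0


def random_logauc(lam: float = DEFAULT_LAMBDA) -> float:
    """Semilog area of the diagonal (random) ROC, in percent."""
    return (1.0 - lam) / math.log(10) / math.log10(1.0 / lam) * 100.0


def alogauc(rocpts: np.ndarray, lam: float = DEFAULT_LAMBDA) -> float:
    """Adjusted LogAUC: semilog area minus the random-curve area (percent)."""
    return logauc(rocpts, lam) - random_logauc(lam)


def ef_at(
    table: ScoreTable,
    fraction: float = 0.01,
    higher_is_better: bool = False,
    roc_based: bool = False,
) -> float:
    """Enrichment factor at a top fraction of the ranked library (default 1%).

    Library-fraction form: (actives in top N / total actives) divided by
    (N / library size), with N = round(fraction x library size), minimum 1
    (round half up).  A tied block straddling the cut contributes its
    pro-rata active share.  With ``roc_based=True`` the alternative
    TPR-at-fraction-FPR / fraction form is used instead.
    """
    table.require_both_classes()
    if roc_based:
        pts = roc(table, higher_is_better)
        tpr = float(np.interp(fraction, pts[:, 0], pts[:, 1]))
        return tpr / fraction
    scores, is_active = table.arrays(higher_is_better)
    size = len(scores)
    if size < 1.0 / fraction:
        warnings.warn(
            f"library size {size} below 1/fraction = {1 / fraction:.0f}; "
            "the top cut is a single compound",
            stacklevel=2,
        )
    n_top = max(1, math.floor(fraction * size + 0.5))  # round half up
    order = np.argsort(scores, kind="stable")
    scores, is_active = scores[order], is_active[order]
    cut_score = scores[n_top - 1]
    before = scores < cut_score  # fully included, above the tied block
    block = scores == cut_score
    n_before = int(before.sum())
    block_size = int(block.sum())
    block_actives = int(is_active[block].sum())
    actives_top = float(is_active[before].sum())
    actives_top += block_actives * (n_top - n_before) / block_size
    n_act = int(is_active.sum())
    return actives_top * size / (n_top * n_act)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-model early-enrichment metrics (percent scales for LogAUC/aLogAUC)."""

    model_id: str
    receptor_id: str
    logauc: float
    alogauc: float
    ef1: float
    auc: float
    n_actives: int
    n_decoys: int
    lam: float = DEFAULT_LAMBDA


def evaluate(
    table: ScoreTable,
    lam: float = DEFAULT_LAMBDA,
    ef_fraction: float = 0.01,
    higher_is_better: bool = False,
) -> EnrichmentResult:
    """All enrichment metrics for one labeled score table."""
    pts = roc(table, higher_is_better)
    la = logauc(pts, lam)
    return EnrichmentResult(
        model_id=table.model_id,
        receptor_id=table.receptor_id,
        logauc=la,
        alogauc=la - random_logauc(lam),
        ef1=ef_at(table, ef_fraction, higher_is_better),
        auc=roc_auc(pts),
        n_actives=table.n_actives,
        n_decoys=table.n_decoys,
        lam=lam,
    )


# --- ranking & aggregation -------------------------------------------------


def rank_models(
    results: Sequence[EnrichmentResult],
    metric: str = "alogauc",
    top_fraction: float = 0.01,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult]]:
    """Rank models by an enrichment metric; select the top fraction.

    Sorted descending by the chosen metric, ties broken by the other
    metric (descending) and then model id.  The selection keeps
    ceil(top_fraction x n) models, at least one.  Returns
    (selected, full_ranking).
    """
    if not results:
        raise ValueError("no results to rank")
    if metric not in {"alogauc", "ef1"}:
        raise ValueError(f"unknown ranking metric {metric!r}")
    other = "ef1" if metric == "alogauc" else "alogauc"
    ranking = sorted(
        results,
        key=lambda r: (-getattr(r, metric), -getattr(r, other), r.model_id),
    )
    n_top = max(1, math.ceil(top_fraction * len(ranking)))
    return ranking[:n_top], ranking


@dataclass(frozen=True)
class ReceptorSummary:
    receptor_id: str
    median_alogauc: float
    max_alogauc: float
    median_ef1: float
    max_ef1: float
    n_models: int


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-receptor medians/maxima and their cross-receptor means."""

    per_receptor: tuple[ReceptorSummary, ...]
    mean_median_alogauc: float
    mean_max_alogauc: float
    mean_median_ef1: float
    mean_max_ef1: float


def aggregate_receptors(
    grouped: Mapping[str, Sequence[EnrichmentResult]],
) -> EnsembleSummary:
    """Median and maximum per receptor, then arithmetic means across receptors."""
    if not grouped:
        raise ValueError("no receptor groups")
    summaries = []
    for receptor_id, results in grouped.items():
        if not results:
            raise ValueError(f"empty result group for receptor {receptor_id!r}")
        al = np.array([r.alogauc for r in results])
        ef = np.array([r.ef1 for r in results])
        summaries.append(
            ReceptorSummary(
                receptor_id=receptor_id,
                median_alogauc=float(np.median(al)),
                max_alogauc=float(al.max()),
                median_ef1=float(np.median(ef)),
                max_ef1=float(ef.max()),
                n_models=len(results),
            )
        )
    return EnsembleSummary(
        per_receptor=tuple(summaries),
        mean_median_alogauc=float(np.mean([s.median_alogauc for s in summaries])),
        mean_max_alogauc=float(np.mean([s.max_alogauc for s in summaries])),
        mean_median_ef1=float(np.mean([s.median_ef1 for s in summaries])),
        mean_max_ef1=float(np.mean([s.max_ef1 for s in summaries])),
    )


def results_dataframe(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Per-model metrics as a tidy DataFrame (for CSV export)."""
    return pd.DataFrame(
        [
            {
                "model_id": r.model_id,
                "receptor_id": r.receptor_id,
                "logauc": r.logauc,
                "alogauc": r.alogauc,
                "ef1": r.ef1,
                "auc": r.auc,
                "n_actives": r.n_actives,
                "n_decoys": r.n_decoys,
            }
            for r in results
        ]
    )


def plot_roc(
    tables: Sequence[ScoreTable],
    path: str | Path,
    lam: float = DEFAULT_LAMBDA,
    higher_is_better: bool = False,
):
    """Semilog ROC plot for one or more score tables (PNG/PDF by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    xs = np.logspace(math.log10(lam), 0, 200)
    ax.plot(xs, xs, ls="--", c="grey", lw=1, label="random")
    for t in tables:
        pts = roc(t, higher_is_better)
        x = np.clip(pts[:, 0], lam, None)
        ax.plot(x, pts[:, 1], lw=1.2,
                label=f"{t.model_id} (aLogAUC {alogauc(pts, lam):.1f})")
    ax.set_xscale("log")
    ax.set_xlim(lam, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
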