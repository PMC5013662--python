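"""Additive expression-score computation and sample stratification.

The score for a sample is the unweighted sum of log2 expression over a fixed
gene panel.  Stratification supports population-quantile tertiles,
equal-width (range) tertiles, a binary top-tertile-vs-rest split, quartiles,
and a fixed cut point; a minimal-p cut-point scan over a survival cohort is
also provided (its p-value is reported as uncorrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePanel

MODES = (
    "quantile_tertile",
    "range_tertile",
    "top_tertile_vs_rest",
    "quartile",
    "fixed_cutpoint",
)

_LABELS = {
    "quantile_tertile": ("low", "intermediate", "high"),
    "range_tertile": ("low", "intermediate", "high"),
    "top_tertile_vs_rest": ("low", "high"),
    "quartile": ("Q1", "Q2", "Q3", "Q4"),
    "fixed_cutpoint": ("low", "high"),
}

COHORT_FLOOR = 30  # minimum cohort size for data-driven cut-point scans


class MissingPanelGenesError(ValueError):
    """Panel genes absent from the matrix without an explicit override."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(f"panel genes missing from matrix: {missing}")


class DegenerateStratificationError(ValueError):
    """Scores cannot support the requested stratification (e.g. all equal)."""


class CutpointScanError(ValueError):
    """No admissible cut point in the scan grid."""


@dataclass
class CESResult:
    """Per-sample additive log2-expression score over a panel."""

    scores: pd.Series
    panel_name: str
    n_genes_used: int
    panel_size: int
    rescaled_for_missing: bool = False
    missing_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.scores.index, "ces": self.scores.to_numpy()}
        )


@dataclass
class StrataAssignment:
    """Per-sample stratum labels with the mode and boundaries that made them."""

    labels: pd.Series
    mode: str
    boundaries: tuple[float, ...]

    def samples_in(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.labels.index, "stratum": self.labels.to_numpy()}
        )


def compute_ces(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    allow_missing: bool = False,
) -> CESResult:
    """Sum log2 expression over the panel genes, per sample.

    Linear-scale input is converted via log2(x + 1) first.  If panel genes are
    absent and ``allow_missing`` is set, the score is rescaled by
    ``panel_size / n_available`` to remain comparable; otherwise an error
    lists the missing genes.
    """
    missing = [g for g in panel.genes if g not in matrix.values.index]
    if missing and not allow_missing:
        raise MissingPanelGenesError(missing)
    available = [g for g in panel.genes if g not in missing]
    if not available:
        raise MissingPanelGenesError(missing)
    log2 = matrix.to_log2()
    scores = log2.values.loc[available].sum(axis=0)
    rescaled = False
    if missing:
        scores = scores * (len(panel) / len(available))
        rescaled = True
    return CESResult(
        scores=scores.astype(float),
        panel_name=panel.name,
        n_genes_used=len(available),
        panel_size=len(panel),
        rescaled_for_missing=rescaled,
        missing_genes=missing,
    )


def _assign(scores: pd.Series, boundaries: np.ndarray, labels: tuple[str, ...]) -> pd.Series:
    # boundary ties go to the lower stratum: searchsorted(side="left")
    idx = np.searchsorted(boundaries, scores.to_numpy(), side="left")
    return pd.Series([labels[i] for i in idx], index=scores.index, name="stratum")


def stratify(
    result: CESResult | pd.Series,
    mode: str = "quantile_tertile",
    cutpoint: float | None = None,
) -> StrataAssignment:
    """Assign each sample to a stratum of its score distribution.

    ``quantile_tertile`` cuts at the empirical 1/3 and 2/3 quantiles;
    ``range_tertile`` cuts the observed [min, max] range into equal-width
    thirds; ``top_tertile_vs_rest`` is binary (high = top quantile tertile);
    ``quartile`` uses the three quartile boundaries; ``fixed_cutpoint``
    requires ``cutpoint``.  Samples exactly on a boundary go to the lower
    stratum.
    """
    if mode not in MODES:
        raise ValueError(f"unknown stratification mode {mode!r}; one of {MODES}")
    scores = result.scores if isinstance(result, CESResult) else pd.Series(result)
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    distinct = np.unique(vals)

    if mode == "fixed_cutpoint":
        if cutpoint is None:
            raise ValueError("fixed_cutpoint mode requires a cutpoint")
        boundaries = np.array([float(cutpoint)])
    else:
        if distinct.size == 1:
            raise DegenerateStratificationError(
                "all scores identical; cannot stratify"
            )
        if mode == "quantile_tertile":
            needed = 3
        elif mode == "quartile":
            needed = 4
        elif mode == "top_tertile_vs_rest":
            needed = 2
        else:
            needed = 2
        if distinct.size < needed:
            raise DegenerateStratificationError(
                f"need ≥{needed} distinct scores for mode {mode!r}, got {distinct.size}"
            )
        if mode == "quantile_tertile":
            boundaries = np.quantile(vals, [1 / 3, 2 / 3])
        elif mode == "range_tertile":
            lo, hi = vals.min(), vals.max()
            boundaries = np.array([lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3])
        elif mode == "top_tertile_vs_rest":
            boundaries = np.quantile(vals, [2 / 3])
        else:  # quartile
            boundaries = np.quantile(vals, [0.25, 0.5, 0.75])
    if np.unique(boundaries).size != boundaries.size:
        raise DegenerateStratificationError(
            f"degenerate boundaries {boundaries.tolist()} for mode {mode!r}"
        )
    labels = _assign(scores, boundaries, _LABELS[mode])
    return StrataAssignment(labels=labels, mode=mode, boundaries=tuple(boundaries))


@dataclass
class CutpointScan:
    """Result of a minimal-p two-group log-rank cut-point scan."""

    cutpoint: float
    p_value: float
    statistic: float
    labels: pd.Series
    grid: tuple[float, ...]
    minimal_p_uncorrected: bool = True  # the reported p is a scan minimum


def best_cutpoint(
    result: CESResult | pd.Series,
    survival: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
) -> CutpointScan:
    """Scan interior score cut points for the most significant two-group split.

    Candidate cut points are the unique observed scores clipped to the
    [P10, P90] percentile window; a candidate is admissible only if both
    sides contain at least one event.  The returned p-value is the scan
    minimum and is NOT corrected for the multiplicity of the scan.
    Cohorts below the n ≥ 30 floor are rejected.
    """
    from .survival import logrank_test  # local import to avoid a cycle

    scores = result.scores if isinstance(result, CESResult) else pd.Series(result)
    common = scores.index.intersection(survival.index)
    scores = scores.loc[common]
    survival = survival.loc[common]
    n = len(scores)
    if n < COHORT_FLOOR:
        raise ValueError(f"cohort size {n} below the n ≥ {COHORT_FLOOR} floor")
    vals = scores.to_numpy(dtype=float)
    p10, p90 = np.quantile(vals, [0.10, 0.90])
    grid = np.unique(vals)
    grid = grid[(grid >= p10) & (grid <= p90)]
    if grid.size == 0:
        raise CutpointScanError("empty cut-point grid")

    best: tuple[float, float, float, pd.Series] | None = None
    time = survival[time_col].to_numpy(dtype=float)
    event = survival[event_col].to_numpy(dtype=int)
    for c in grid:
        low_mask = vals <= c
        if low_mask.all() or not low_mask.any():
            continue
        if event[low_mask].sum() < 1 or event[~low_mask].sum() < 1:
            continue
        groups = pd.Series(np.where(low_mask, "low", "high"), index=scores.index)
        res = logrank_test(time, event, groups.to_numpy())
        if best is None or res.p_value < best[1]:
            best = (float(c), float(res.p_value), float(res.statistic), groups)
    if best is None:
        raise CutpointScanError("no admissible cut point (events on one side only)")
    c, p, stat, groups = best
    return CutpointScan(
        cutpoint=c, p_value=p, statistic=stat, labels=groups, grid=tuple(grid)
    )
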