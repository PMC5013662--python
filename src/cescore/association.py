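"""Association analyses: Spearman correlation tables with joint FDR, rank
tests, categorical enrichment across strata, co-expression networks, a
pairwise-difference robust scale (Qn) estimator, and drug-sensitivity
comparisons with robust one-sided outlier exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .scoring import CESResult, StrataAssignment, stratify


class DegenerateInputError(ValueError):
    """Statistic undefined for a constant or too-small input."""


# ---------------------------------------------------------------------------
# Robust scale (Qn)
# ---------------------------------------------------------------------------

# Asymptotic consistency constant for the standard normal, and finite-sample
# correction factors (small-n table, then parity-dependent asymptotic form).
QN_CONSISTENCY = 2.2219
_QN_SMALL_N = {2: 0.399, 3: 0.994, 4: 0.512, 5: 0.844, 6: 0.611, 7: 0.857, 8: 0.669, 9: 0.872}

# brute-force pair enumeration is used up to this n; above it, an
# O(n log n)-per-step counting selection avoids materializing all pairs
_QN_BRUTE_LIMIT = 2000


@dataclass
class QnResult:
    raw_kernel: float     # k-th order statistic of pairwise |x_i - x_j|
    estimate: float       # consistency constant × finite-sample factor × kernel
    n: int
    k: int


def _qn_kernel_brute(x: np.ndarray, k: int) -> float:
    diffs = np.abs(x[:, None] - x[None, :])[np.triu_indices(x.size, 1)]
    return float(np.partition(diffs, k - 1)[k - 1])


def _count_pairs_le(xs: np.ndarray, t: float) -> int:
    """Number of pairs i<j (of sorted xs) with xs[j] - xs[i] <= t."""
    idx = np.searchsorted(xs, xs + t, side="right")
    return int((idx - np.arange(1, xs.size + 1)).sum())


def _qn_kernel_large(x: np.ndarray, k: int) -> float:
    """Select the k-th smallest pairwise difference by bisection + counting."""
    xs = np.sort(x)
    lo, hi = 0.0, float(xs[-1] - xs[0])
    if hi == 0.0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if _count_pairs_le(xs, mid) >= k:
            hi = mid
        else:
            lo = mid
    # exact value: enumerate the (few) pair differences in (lo, hi]
    starts = np.searchsorted(xs, xs + lo, side="right")
    ends = np.searchsorted(xs, xs + hi, side="right")
    cands: list[float] = []
    for i in range(xs.size):
        for j in range(max(starts[i], i + 1), ends[i]):
            cands.append(float(xs[j] - xs[i]))
    if not cands:
        return hi
    cands.sort()
    rank_needed = k - _count_pairs_le(xs, lo)
    rank_needed = min(max(rank_needed, 1), len(cands))
    return cands[rank_needed - 1]


def qn_finite_sample_factor(n: int) -> float:
    if n in _QN_SMALL_N:
        return _QN_SMALL_N[n]
    if n % 2 == 1:
        return n / (n + 1.4)
    return n / (n + 3.8)


def qn_scale(values: Sequence[float]) -> QnResult:
    """Location-free robust scale from pairwise absolute differences.

    The raw kernel is the k-th order statistic of {|x_i − x_j| : i < j} with
    h = floor(n/2) + 1 and k = C(h, 2); the estimate multiplies the kernel by
    the normal-consistency constant (2.2219) and a finite-sample correction.
    Both are reported so the constant choice can never silently change
    downstream exclusions.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError(f"qn_scale needs n >= 2, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError("qn_scale requires finite values")
    n = x.size
    h = n // 2 + 1
    k = h * (h - 1) // 2
    if n <= _QN_BRUTE_LIMIT:
        kernel = _qn_kernel_brute(x, k)
    else:
        kernel = _qn_kernel_large(x, k)
    est = QN_CONSISTENCY * qn_finite_sample_factor(n) * kernel
    return QnResult(raw_kernel=kernel, estimate=est, n=n, k=k)


# ---------------------------------------------------------------------------
# Correlation tables
# ---------------------------------------------------------------------------

@dataclass
class AssociationTable:
    """Spearman correlations per group/metric with a joint BH-FDR column."""

    table: pd.DataFrame            # group, metric, rs, p, q, n
    notes: list[str] = field(default_factory=list)


def spearman_with_fdr(
    tables: Mapping[str, tuple[Sequence[float], Sequence[float]]]
    | Mapping[str, Mapping[str, tuple[Sequence[float], Sequence[float]]]],
) -> AssociationTable:
    """Spearman r_s (average-rank ties) with two-tailed p per row and BH q
    computed jointly across all rows of the table.

    ``tables`` maps a group label either to a single ``(score, metric)`` pair
    or to a ``{metric_name: (score, metric)}`` mapping.  Rows with a constant
    vector are excluded from the FDR family with a note.
    """
    rows = []
    notes: list[str] = []
    flat: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    for group, entry in tables.items():
        if isinstance(entry, Mapping):
            for metric, (x, y) in entry.items():
                flat.append((group, metric, np.asarray(x, float), np.asarray(y, float)))
        else:
            x, y = entry
            flat.append((group, "metric", np.asarray(x, float), np.asarray(y, float)))
    for group, metric, x, y in flat:
        if x.size != y.size:
            raise ValueError(f"{group}/{metric}: length mismatch")
        if x.size < 3:
            notes.append(f"{group}/{metric}: n < 3, skipped")
            continue
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            notes.append(f"{group}/{metric}: constant vector, excluded from FDR family")
            continue
        rs, p = stats.spearmanr(x, y)
        rows.append({"group": group, "metric": metric, "rs": float(rs), "p": float(p), "n": int(x.size)})
    if not rows:
        raise DegenerateInputError("no valid rows for correlation table")
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return AssociationTable(table=df, notes=notes)


def rank_test(
    scores: Sequence[float], groups: Sequence, mode: str = "two_group"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (normal approximation with tie correction) for two
    groups, Kruskal–Wallis for k groups.  Returns (statistic, p)."""
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    samples = [s[g == lab] for lab in labels]
    if len(samples) < 2 or any(len(x) < 2 for x in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if mode == "two_group":
        if len(samples) != 2:
            raise ValueError(f"two_group mode requires 2 groups, got {len(samples)}")
        res = stats.mannwhitneyu(
            samples[0], samples[1], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        return float(res.statistic), float(res.pvalue)
    if mode == "k_group":
        stat, p = stats.kruskal(*samples)
        return float(stat), float(p)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Categorical enrichment
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    table: pd.DataFrame     # factor levels × strata counts
    test: str               # "chi_square" or "fisher_exact"
    statistic: float
    p_value: float


def categorical_enrichment(
    strata: StrataAssignment | pd.Series,
    factor: pd.Series,
    test_policy: str = "auto",
) -> ContingencyResult:
    """Cross-tabulate a categorical factor against score strata and test
    independence.  Chi-square (no continuity correction) by default; Fisher's
    exact is used for 2×2 tables with any expected cell < 5 (policy recorded
    in the result)."""
    labels = strata.labels if isinstance(strata, StrataAssignment) else strata
    common = labels.index.intersection(factor.index)
    if len(common) == 0:
        raise ValueError("no shared sample ids between strata and factor")
    tab = pd.crosstab(factor.loc[common], labels.loc[common])
    obs = tab.to_numpy()
    use_fisher = False
    if test_policy == "fisher":
        use_fisher = True
    elif test_policy == "auto" and obs.shape == (2, 2):
        expected = stats.contingency.expected_freq(obs)
        use_fisher = (expected < 5).any()
    if use_fisher:
        if obs.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2×2 table")
        odds, p = stats.fisher_exact(obs)
        return ContingencyResult(table=tab, test="fisher_exact", statistic=float(odds), p_value=float(p))
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(table=tab, test="chi_square", statistic=float(stat), p_value=float(p))


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

@dataclass
class NetworkResult:
    edges: pd.DataFrame           # gene_a, gene_b, r
    degrees: pd.DataFrame         # gene, degree
    excluded_constant: list[str] = field(default_factory=list)


def coexpression_network(matrix: ExpressionMatrix, threshold: float = 0.4) -> NetworkResult:
    """All-pairs Pearson correlation across samples; pairs with r ≥ threshold
    become undirected edges.  Constant genes are excluded with a note."""
    if matrix.n_samples < 3:
        raise ValueError("need >= 3 samples for a correlation network")
    vals = matrix.values
    sds = vals.std(axis=1, ddof=1)
    constant = list(vals.index[sds == 0])
    kept = vals.loc[sds > 0]
    genes = list(kept.index)
    corr = np.corrcoef(kept.to_numpy())
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = float(corr[i, j])
            if r >= threshold:
                rows.append({"gene_a": genes[i], "gene_b": genes[j], "r": r})
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])
    degree = {g: 0 for g in genes}
    for _, row in edges.iterrows():
        degree[row["gene_a"]] += 1
        degree[row["gene_b"]] += 1
    degrees = pd.DataFrame(
        {"gene": list(degree.keys()), "degree": list(degree.values())}
    )
    return NetworkResult(edges=edges, degrees=degrees, excluded_constant=constant)


# ---------------------------------------------------------------------------
# Drug sensitivity
# ---------------------------------------------------------------------------

@dataclass
class DrugSensitivityResult:
    quartile_statistic: float
    quartile_p: float
    spearman: AssociationTable     # overall + per-tissue rows
    flagged_outliers: list[str]
    n_used: int
    quartiles: StrataAssignment
    notes: list[str] = field(default_factory=list)


def flag_extreme_ic50(
    ic50: pd.Series,
    multiplier: float = 3.0,
    two_sided: bool = False,
    log_scale: bool = True,
) -> pd.Series:
    """Flag IC50 values more than ``multiplier`` robust scales (Qn) above the
    median — one-sided by default, exactly as the exclusion rule is worded.

    IC50s are analyzed on the log scale, so the rule is applied to log values
    by default (``log_scale=False`` applies it to raw concentrations).
    """
    x = ic50.to_numpy(dtype=float)
    if log_scale:
        if (x <= 0).any():
            raise ValueError("IC50 values must be positive for log-scale flagging")
        x = np.log(x)
    qn = qn_scale(x).estimate
    med = float(np.median(x))
    upper = x > med + multiplier * qn
    if two_sided:
        flags = upper | (x < med - multiplier * qn)
    else:
        flags = upper
    return pd.Series(flags, index=ic50.index)


def drug_sensitivity_analysis(
    ces: CESResult | pd.Series,
    drugs: pd.DataFrame,
    ic50_col: str = "ic50",
    tissue_col: str = "tissue",
    exclude_extremes: bool = True,
) -> DrugSensitivityResult:
    """Relate score values to drug response across cell lines.

    Steps: (i) optionally flag and drop lines with IC50 above
    median + 3×Qn; (ii) bin remaining lines into score quartiles and compare
    IC50 between top and bottom quartiles by Wilcoxon rank-sum; (iii) Spearman
    r_s between score and IC50 overall and per tissue group (groups with
    n < 3 are skipped with a note).
    """
    scores = ces.scores if isinstance(ces, CESResult) else pd.Series(ces)
    common = scores.index.intersection(drugs.index)
    if len(common) < 8:
        raise ValueError(f"need >= 8 matched cell lines, got {len(common)}")
    scores = scores.loc[common]
    drugs = drugs.loc[common]
    if (drugs[ic50_col] <= 0).any():
        raise ValueError("IC50 values must be positive")

    notes: list[str] = []
    flagged: list[str] = []
    if exclude_extremes:
        flags = flag_extreme_ic50(drugs[ic50_col])
        flagged = list(flags.index[flags])
        if flagged:
            notes.append(f"excluded {len(flagged)} extreme IC50 value(s)")
        drugs = drugs.loc[~flags]
        scores = scores.loc[drugs.index]

    quartiles = stratify(scores, mode="quartile")
    top = drugs.loc[quartiles.labels == "Q4", ic50_col]
    bottom = drugs.loc[quartiles.labels == "Q1", ic50_col]
    log_top = np.log(top.to_numpy())
    log_bottom = np.log(bottom.to_numpy())
    q_stat, q_p = rank_test(
        np.concatenate([log_top, log_bottom]),
        np.array(["top"] * log_top.size + ["bottom"] * log_bottom.size),
        mode="two_group",
    )

    corr_input: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "pooled": (scores.to_numpy(), np.log(drugs[ic50_col].to_numpy()))
    }
    if tissue_col in drugs.columns:
        for tissue, sub in drugs.groupby(tissue_col):
            if len(sub) < 3:
                notes.append(f"tissue {tissue!r}: n < 3, skipped")
                continue
            corr_input[str(tissue)] = (
                scores.loc[sub.index].to_numpy(),
                np.log(sub[ic50_col].to_numpy()),
            )
    spearman = spearman_with_fdr(corr_input)
    spearman.notes.extend(notes)

    return DrugSensitivityResult(
        quartile_statistic=q_stat,
        quartile_p=q_p,
        spearman=spearman,
        flagged_outliers=flagged,
        n_used=int(len(drugs)),
        quartiles=quartiles,
        notes=notes,
    )
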