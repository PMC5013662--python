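"""Differential-expression screening across tumour/normal datasets, a
permutation overexpression test, a cross-dataset prevalence filter, and panel
derivation by intersecting upregulation with prognostic evidence.

Fold changes are differences of log2 means (ratios of geometric means).  The
default engine is a Welch two-sample test on log2 values with per-dataset
Benjamini–Hochberg adjustment; a moderated d-statistic with a
variance-stabilizing offset and permutation p-values is available for
sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ROLE_NORMAL, ROLE_TUMOUR, ExpressionMatrix, GenePanel


class DegenerateGeneWarning(UserWarning):
    pass


def _class_arrays(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    log2 = matrix.to_log2()
    normals = matrix.samples_with_role(ROLE_NORMAL)
    tumours = matrix.samples_with_role(ROLE_TUMOUR)
    if len(normals) < 2 or len(tumours) < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {len(normals)} normal / {len(tumours)} tumour"
        )
    return (
        log2.values[normals].to_numpy(dtype=float),
        log2.values[tumours].to_numpy(dtype=float),
    )


def differential_expression(
    matrix: ExpressionMatrix,
    method: str = "welch_log2",
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene tumour-vs-normal differential expression for one dataset.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean log2
    tumour − mean log2 normal), ``p``, ``q`` (BH within dataset) and
    ``direction``.
    """
    if method not in ("welch_log2", "moderated"):
        raise ValueError(f"unknown method {method!r}")
    normal, tumour = _class_arrays(matrix)
    log2fc = tumour.mean(axis=1) - normal.mean(axis=1)

    if method == "welch_log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(tumour, normal, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    else:
        p = _moderated_p(normal, tumour, n_permutations, seed)

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat")),
        },
        index=matrix.gene_ids,
    )


def _d_stat(normal: np.ndarray, tumour: np.ndarray, s0: float) -> np.ndarray:
    nn, nt = normal.shape[1], tumour.shape[1]
    se = np.sqrt(normal.var(axis=1, ddof=1) / nn + tumour.var(axis=1, ddof=1) / nt)
    return (tumour.mean(axis=1) - normal.mean(axis=1)) / (se + s0)


def _moderated_p(
    normal: np.ndarray, tumour: np.ndarray, n_permutations: int, seed: int
) -> np.ndarray:
    """Moderated d-statistic: mean difference over (se + s0), s0 = median of
    per-gene standard errors; two-sided p from label permutations with the
    permuted statistics pooled across genes for resolution."""
    nn, nt = normal.shape[1], tumour.shape[1]
    pooled = np.concatenate([normal, tumour], axis=1)
    se = np.sqrt(normal.var(axis=1, ddof=1) / nn + tumour.var(axis=1, ddof=1) / nt)
    s0 = float(np.median(se))
    d_obs = np.abs(_d_stat(normal, tumour, s0))
    rng = np.random.default_rng(seed)
    null_pool = np.empty((n_permutations, d_obs.size))
    for b in range(n_permutations):
        perm = rng.permutation(nn + nt)
        pn, pt = pooled[:, perm[:nn]], pooled[:, perm[nn:]]
        null_pool[b] = np.abs(_d_stat(pn, pt, s0))
    flat = np.sort(null_pool.ravel())
    exceed = flat.size - np.searchsorted(flat, d_obs, side="left")
    return (1.0 + exceed) / (flat.size + 1.0)


def cross_dataset_filter(
    results: Sequence[pd.DataFrame],
    q_max: float = 0.05,
    min_fold: float = 2.0,
    prevalence: float = 0.5,
) -> set[str]:
    """Genes upregulated with q ≤ q_max and fold change ≥ min_fold in at least
    ceil(prevalence × n_datasets) datasets.

    ``min_fold`` is a linear fold change; the comparison is made as
    log2fc ≥ log2(min_fold).  Prevalence rounding uses the ceiling, so a gene
    must pass in a strict majority when n is odd.
    """
    if not results:
        raise ValueError("need at least one DE result")
    n = len(results)
    needed = math.ceil(prevalence * n - 1e-12)
    min_log2fc = math.log2(min_fold)
    counts: dict[str, int] = {}
    for res in results:
        passed = res.index[
            (res["q"] <= q_max)
            & (res["log2fc"] >= min_log2fc)
            & (res["direction"] == "up")
        ]
        for g in passed:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= needed}


@dataclass
class PermutationResult:
    gene: str
    observed_log2fc: float
    n_permutations: int
    p_perm: float


def permutation_overexpression_test(
    matrix: ExpressionMatrix, gene: str, n_permutations: int = 999, seed: int = 0
) -> PermutationResult:
    """Label-permutation test of a gene's observed tumour-vs-normal log2 fold
    change, with the add-one estimator
    p = (1 + #{permuted log2FC ≥ observed}) / (B + 1)."""
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    normal, tumour = _class_arrays(matrix)
    gi = matrix.gene_ids.index(gene)
    xn, xt = normal[gi], tumour[gi]
    observed = float(xt.mean() - xn.mean())
    pooled = np.concatenate([xn, xt])
    if np.unique(pooled).size == 1:
        warnings.warn(f"gene {gene!r} is constant; p set to 1", DegenerateGeneWarning)
        return PermutationResult(gene, observed, n_permutations, 1.0)
    rng = np.random.default_rng(seed)
    nn = xn.size
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if perm[nn:].mean() - perm[:nn].mean() >= observed:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return PermutationResult(gene, observed, n_permutations, p)


class EmptyPanelError(ValueError):
    """No upregulated gene carries any prognostic evidence."""


@dataclass
class DerivedPanel:
    panel: GenePanel
    provenance: dict[str, list[str]]  # gene -> evidence sources that include it


def derive_panel(
    upregulated: set[str],
    prognostic_evidence: Mapping[str, set[str]],
    name: str = "derived",
) -> DerivedPanel:
    """Core panel = upregulated genes supported by at least one prognostic
    evidence set; per-gene provenance records which sets supported it."""
    if not upregulated:
        raise ValueError("upregulated set is empty")
    provenance: dict[str, list[str]] = {}
    for gene in sorted(upregulated):
        sources = [src for src, genes in prognostic_evidence.items() if gene in genes]
        if sources:
            provenance[gene] = sources
    if not provenance:
        raise EmptyPanelError("no upregulated gene has prognostic evidence")
    panel = GenePanel(name=name, genes=tuple(sorted(provenance)))
    return DerivedPanel(panel=panel, provenance=provenance)
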