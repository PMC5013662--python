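"""Synthetic multi-dataset cohorts with known ground truth.

Generates (i) tumour/normal expression matrices with planted log2 fold
changes on a log-normal (Normal-on-log2) noise model, (ii) survival cohorts
from an exponential proportional-hazards process with uniform censoring and
an optional treatment×stratum interaction, (iii) genomic-instability metrics
coupled to the score through a Gaussian-copula-style monotone link, and
(iv) cell-line expression plus log-IC50 drug response with injected extreme
outliers.  One global seed is expanded into independent per-stream
substreams so each component can be regenerated on its own.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .io import (
    ROLE_CELL_LINE,
    ROLE_NORMAL,
    ROLE_TUMOUR,
    SCALE_LOG2,
    ExpressionMatrix,
    GenePanel,
    load_gene_panel,
)
from .scoring import compute_ces, stratify

_STREAMS = {"expression": 0, "survival": 1, "instability": 2, "drug": 3, "covariate": 4}


class SimConfigError(ValueError):
    pass


def _default_panel_genes() -> tuple[str, ...]:
    return load_gene_panel("ces14").genes


@dataclass
class SimConfig:
    """Parameters for all synthetic-data streams (one seed, substreamed)."""

    n_datasets: int = 4
    n_normal: int = 30
    n_tumour: int = 30
    n_genes_background: int = 200
    panel_genes: tuple[str, ...] = field(default_factory=_default_panel_genes)
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    gene_sd: float = 0.5
    hazard_beta: float = 0.0
    treat_beta: float = 0.0
    treat_main: float = 0.0
    baseline_hazard: float = 0.1
    censor_horizon: float = 10.0
    assoc_slope: float = 0.0
    covariate_links: dict[str, float] = field(
        default_factory=lambda: {"grade": 1.0, "er_negative": 1.0, "scc": 1.0}
    )
    ic50_slope: float = 0.0
    ic50_noise_sd: float = 0.5
    n_outliers: int = 0
    n_celllines: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        self.panel_genes = tuple(self.panel_genes)
        for name in ("n_datasets", "n_normal", "n_tumour", "n_celllines"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        if self.n_genes_background < 0:
            raise SimConfigError("n_genes_background must be >= 0")
        if self.gene_sd < 0:
            raise SimConfigError("gene_sd must be >= 0")
        if self.baseline_hazard <= 0:
            raise SimConfigError("baseline_hazard must be > 0")
        if self.censor_horizon <= 0:
            raise SimConfigError("censor_horizon must be > 0")
        if self.n_outliers < 0 or self.n_outliers > self.n_celllines:
            raise SimConfigError("n_outliers must be in [0, n_celllines]")
        unknown = set(self.planted_log2fc) - self.gene_universe
        if unknown:
            raise SimConfigError(f"planted_log2fc for genes outside universe: {sorted(unknown)}")

    @property
    def background_genes(self) -> tuple[str, ...]:
        return tuple(f"BG{i:04d}" for i in range(self.n_genes_background))

    @property
    def gene_universe(self) -> set[str]:
        return set(self.panel_genes) | set(self.background_genes)

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream], extra))
        )


@dataclass
class SimTruth:
    """Generator ground truth for parameter-recovery tests."""

    planted_up_genes: set[str] = field(default_factory=set)
    realized_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    hazard_beta: float = 0.0
    treat_beta: float = 0.0
    target_rs: float | None = None
    outlier_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_up_genes": sorted(self.planted_up_genes),
            "realized_log2fc": self.realized_log2fc,
            "hazard_beta": self.hazard_beta,
            "treat_beta": self.treat_beta,
            "target_rs": self.target_rs,
            "outlier_ids": list(self.outlier_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def slope_for_spearman(target_rs: float) -> float:
    """Latent-slope value whose Gaussian-copula link yields the requested
    Spearman correlation (rho = 2·sin(π·r_s/6); slope = rho/sqrt(1−rho²))."""
    if not -1 < target_rs < 1:
        raise ValueError("target Spearman must be in (-1, 1)")
    rho = 2.0 * math.sin(math.pi * target_rs / 6.0)
    return rho / math.sqrt(1.0 - rho * rho)


def simulate_expression_datasets(
    config: SimConfig,
) -> tuple[list[ExpressionMatrix], SimTruth]:
    """Per-dataset tumour/normal log2 expression with planted fold changes.

    Each gene gets a dataset-specific baseline log2 mean; tumour samples for a
    planted gene are shifted up by its planted log2 fold change; background
    genes have zero planted shift.  Noise is independent Normal on the log2
    scale.
    """
    genes = list(config.panel_genes) + list(config.background_genes)
    fc = np.array([config.planted_log2fc.get(g, 0.0) for g in genes])
    truth = SimTruth(
        planted_up_genes={g for g, v in config.planted_log2fc.items() if v > 0}
    )
    matrices: list[ExpressionMatrix] = []
    for d in range(config.n_datasets):
        rng = config.rng("expression", d)
        baseline = rng.uniform(5.0, 9.0, size=len(genes))
        normal = rng.normal(
            baseline[:, None], config.gene_sd, size=(len(genes), config.n_normal)
        )
        tumour = rng.normal(
            (baseline + fc)[:, None],
            config.gene_sd,
            size=(len(genes), config.n_tumour),
        )
        sample_ids = [f"D{d}_N{i:03d}" for i in range(config.n_normal)] + [
            f"D{d}_T{i:03d}" for i in range(config.n_tumour)
        ]
        roles = [ROLE_NORMAL] * config.n_normal + [ROLE_TUMOUR] * config.n_tumour
        values = pd.DataFrame(
            np.concatenate([normal, tumour], axis=1), index=genes, columns=sample_ids
        )
        mat = ExpressionMatrix(
            values=values,
            scale=SCALE_LOG2,
            sample_roles=pd.Series(roles, index=sample_ids),
        )
        matrices.append(mat)
        realized = tumour.mean(axis=1) - normal.mean(axis=1)
        truth.realized_log2fc[f"dataset_{d}"] = {
            g: float(realized[i])
            for i, g in enumerate(genes)
            if g in config.planted_log2fc
        }
    return matrices, truth


def _standardize(ces: pd.Series) -> np.ndarray:
    z = ces.to_numpy(dtype=float)
    sd = z.std()
    return np.zeros_like(z) if sd == 0 else (z - z.mean()) / sd


def simulate_cohort(config: SimConfig, ces: pd.Series) -> pd.DataFrame:
    """Clinical/survival table for tumour samples with the given scores.

    Survival times follow an exponential proportional-hazards process
    h = baseline · exp(hazard_beta·z + treat_main·treated +
    treat_beta·treated·1[high stratum]) with z the standardized score; an
    independent Uniform(0, horizon) censoring time applies.  Ordinal/binary
    covariates are drawn with success probabilities monotone in z; the
    treatment flag is randomized 1:1.
    """
    ces = pd.Series(ces)
    if ces.index.duplicated().any():
        raise ValueError("duplicate sample ids in scores")
    n = len(ces)
    if n == 0:
        raise ValueError("empty score vector")
    z = _standardize(ces)
    try:
        strata = stratify(ces, mode="top_tertile_vs_rest")
        high = (strata.labels == "high").to_numpy().astype(int)
    except Exception:
        high = np.zeros(n, dtype=int)

    rng = config.rng("survival")
    treated = rng.integers(0, 2, size=n)
    log_h = (
        math.log(config.baseline_hazard)
        + config.hazard_beta * z
        + config.treat_main * treated
        + config.treat_beta * treated * high
    )
    t_event = rng.exponential(1.0 / np.exp(log_h))
    t_censor = rng.uniform(0.0, config.censor_horizon, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    crng = config.rng("covariate")
    links = config.covariate_links
    grade = 1 + crng.binomial(2, expit(links.get("grade", 1.0) * z))
    er_negative = crng.binomial(1, expit(links.get("er_negative", 1.0) * z))
    scc = crng.binomial(1, expit(links.get("scc", 1.0) * z))

    return pd.DataFrame(
        {
            "ces": ces.to_numpy(),
            "z": z,
            "stratum": np.where(high == 1, "high", "low"),
            "treated": treated,
            "grade": grade,
            "er_status": np.where(er_negative == 1, "negative", "positive"),
            "histology": np.where(scc == 1, "SCC", "ADC"),
            "time": time,
            "event": event,
            "endpoint": "OS",
        },
        index=ces.index.rename("sample_id"),
    )


def simulate_instability(ces: pd.Series, config: SimConfig) -> pd.DataFrame:
    """Per-sample CNA fraction (in [0,1]) and mutation frequency (≥ 0) coupled
    to the score through a rank-based Gaussian-copula monotone link whose
    Spearman correlation rises with ``assoc_slope`` (0 ⇒ independence)."""
    ces = pd.Series(ces)
    x = ces.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    n = x.size
    # normal scores of the score ranks: a strictly monotone transform, so the
    # planted Spearman correlation is insensitive to the score distribution
    ranks = stats_rankdata(x)
    zr = ndtri((ranks - 0.5) / n) if np.unique(x).size > 1 else np.zeros(n)
    rng = config.rng("instability")
    s = config.assoc_slope
    denom = math.sqrt(1.0 + s * s)
    latent_cna = (s * zr + rng.normal(size=n)) / denom
    latent_mut = (s * zr + rng.normal(size=n)) / denom
    return pd.DataFrame(
        {
            "cna_fraction": expit(latent_cna),
            "mutation_frequency": np.exp(0.8 * latent_mut + 1.0),
        },
        index=ces.index.rename("sample_id"),
    )


def stats_rankdata(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def simulate_celllines(
    config: SimConfig, panel: GenePanel | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Cell-line expression plus a drug-response table.

    log IC50 = intercept − ic50_slope·z + Normal(0, ic50_noise_sd) with z the
    standardized score over the panel genes; ``n_outliers`` lines then get
    their IC50 inflated far above the bulk (recorded in the truth object).
    """
    rng = config.rng("drug")
    genes = list(config.panel_genes) + list(config.background_genes)
    n = config.n_celllines
    ids = [f"CL{i:04d}" for i in range(n)]
    baseline = rng.uniform(5.0, 9.0, size=len(genes))
    spread = rng.normal(0.0, 1.0, size=n)  # per-line panel-wide shift drives score spread
    vals = rng.normal(baseline[:, None], max(config.gene_sd, 1e-12), size=(len(genes), n))
    panel_set = set(config.panel_genes)
    for i, g in enumerate(genes):
        if g in panel_set:
            vals[i] += 0.5 * spread
    matrix = ExpressionMatrix(
        values=pd.DataFrame(vals, index=genes, columns=ids),
        scale=SCALE_LOG2,
        sample_roles=pd.Series(ROLE_CELL_LINE, index=ids),
    )
    if panel is None:
        panel = GenePanel(name="sim_panel", genes=tuple(config.panel_genes))
    scores = compute_ces(matrix, panel).scores
    z = _standardize(scores)
    log_ic50 = 1.0 - config.ic50_slope * z + rng.normal(0.0, config.ic50_noise_sd, size=n)
    ic50 = np.exp(log_ic50)

    truth = SimTruth(
        hazard_beta=config.hazard_beta,
        treat_beta=config.treat_beta,
    )
    if config.n_outliers > 0:
        out_idx = rng.choice(n, size=config.n_outliers, replace=False)
        bulk = np.delete(ic50, out_idx)
        scale = max(float(np.median(bulk)), float(bulk.max() - bulk.min()), 1e-9)
        ic50[out_idx] = float(np.median(bulk)) + 100.0 * scale
        truth.outlier_ids = [ids[i] for i in sorted(out_idx)]

    tissues = ["breast", "lung", "ovary", "skin", "cns"]
    drug = pd.DataFrame(
        {
            "ic50": ic50,
            "tissue": [tissues[i % len(tissues)] for i in range(n)],
        },
        index=pd.Index(ids, name="cell_line"),
    )
    return matrix, drug, truth
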