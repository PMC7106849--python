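"""Synthetic multi-platform expression study generator.

Generates a probe panel of multi-isoform genes with a configurable
isoform-count category mix, ground-truth isoform expressions with tissue
structure, probe-capture intensities (y = A.x with multiplicative noise,
background and technical replicates), additional platform views with
distinct measurement biases (a count-like sampled view with within-gene
read ambiguity; an array-like view with an additive background floor that
compresses the low-expression range), and per-isoform qPCR cycle
thresholds.  Every stage of the quantification and concordance pipeline can
therefore be exercised end to end with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import GeneModel, Probe, design_max_probe_panel
from .quantify import (
    DEFAULT_HOUSEKEEPING,
    ExpressionMatrix,
    ProbeCountMatrix,
    collapse_replicates,
    housekeeping_normalize,
    quantify_panel,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_panel",
    "simulate_truth",
    "simulate_probe_counts",
    "simulate_platform_views",
    "simulate_ct",
    "simulate_study",
    "gene_view",
]

#: Panel-like default tissue mix (ovary-heavy cancer cell line cohort).
DEFAULT_TISSUES = ("ovary", "lung", "colon", "breast", "pancreas", "prostate")


@dataclass
class SimulationConfig:
    """All knobs of the generator.  A fixed seed gives byte-identical output.

    The default panel composition follows the custom cancer panel the
    pipeline models: 155 multi-isoform genes mixed 79:37:18:21 across the
    2/3/4/>4 isoform categories (the >4 category is generated with 5
    isoforms), 10 single-isoform housekeeping genes and 14 spike-in control
    probes.
    """

    # panel
    n_genes: int = 155
    category_weights: dict[int, float] = field(
        default_factory=lambda: {2: 79.0, 3: 37.0, 4: 18.0, 5: 21.0}
    )
    allocation: str = "proportional"  # "proportional" | "multinomial"
    n_housekeeping: int = 10
    n_spike_in: int = 14
    # cohort
    n_samples: int = 46
    tissue_weights: tuple[float, ...] = (12, 12, 11, 10, 4, 2)
    # true expression (natural-log log-normal)
    log_mean: float = 4.0
    log_sd: float = 1.5
    biological_sd: float = 0.5  # per isoform x sample multiplicative spread
    de_fraction: float = 0.2
    de_effect: float = 1.0  # log2-scale tissue shift for DE genes
    housekeeping_level: float = 800.0
    # probe capture measurement
    noise_sd: float = 0.2  # multiplicative log-normal sd per measurement
    background: float = 0.0  # additive probe background counts
    sample_scale_sd: float = 0.3  # per-sample global scale (removed by normalization)
    n_replicates: int = 2
    replicate_sd: float = 0.1  # extra per-replicate scale jitter
    spike_in_level: float = 500.0
    # platform views
    seq_depth: float = 10.0  # Poisson counts per expression unit
    ambiguity: float = 0.0  # within-gene read-assignment mixing rate in [0,1]
    array_background: float = 50.0
    array_noise_sd: float = 0.1
    # qPCR
    ct_offset: float = 20.0
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be non-negative")
        if sum(self.category_weights.values()) <= 0:
            raise ValueError("category weights must have positive sum")
        for name in ("biological_sd", "noise_sd", "sample_scale_sd",
                     "replicate_sd", "array_noise_sd", "ct_noise_sd", "log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ambiguity <= 1:
            raise ValueError("ambiguity must lie in [0, 1]")
        if self.allocation not in ("proportional", "multinomial"):
            raise ValueError(f"unknown allocation mode {self.allocation!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category_weights"] = {int(k): float(v) for k, v in self.category_weights.items()}
        d["tissue_weights"] = list(self.tissue_weights)
        return d


@dataclass
class GroundTruth:
    """True expressions and study structure behind a simulated cohort."""

    genes: list[GeneModel]  # endogenous panel genes
    housekeeping: list[GeneModel]
    expression: ExpressionMatrix  # isoform level, raw; includes housekeeping
    labels: pd.Series  # sample_id -> tissue
    de_genes: dict[str, str]  # gene_id -> shifted tissue
    annotation: dict[str, str]  # isoform_id -> gene_id


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Deterministic proportional allocation of ``total`` items to weights."""
    weights = np.asarray(weights, dtype=float)
    quota = weights / weights.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    # ties broken by position for determinism
    for i in np.argsort(-remainder, kind="stable")[: total - counts.sum()]:
        counts[i] += 1
    return counts


def simulate_panel(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], list[Probe]]:
    """Draw the gene panel and its max-probe design.

    Endogenous genes get isoform counts from the category mix (exactly
    proportional in "proportional" mode, multinomially sampled otherwise),
    each with one gene-level max probe and n-1 singleton probes.
    Housekeeping genes are single-isoform with one housekeeping-class probe;
    spike-in probes carry no target.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cats = sorted(cfg.category_weights)
    weights = np.array([cfg.category_weights[c] for c in cats], dtype=float)
    if cfg.allocation == "proportional":
        counts = _largest_remainder(weights, cfg.n_genes)
    else:
        counts = rng.multinomial(cfg.n_genes, weights / weights.sum())
    sizes = np.repeat(cats, counts)

    genes: list[GeneModel] = []
    probes: list[Probe] = []
    for gi, size in enumerate(sizes, start=1):
        gid = f"G{gi:04d}"
        gene = GeneModel(gid, tuple(f"{gid}.{k}" for k in range(1, size + 1)))
        genes.append(gene)
        probes.extend(design_max_probe_panel(gene))

    housekeeping: list[GeneModel] = []
    hk_names = list(DEFAULT_HOUSEKEEPING[: cfg.n_housekeeping])
    hk_names += [f"HK{k}" for k in range(len(hk_names) + 1, cfg.n_housekeeping + 1)]
    for name in hk_names:
        g = GeneModel(name, (f"{name}.1",))
        housekeeping.append(g)
        probes.append(Probe(f"{name}_hk", name, g.isoform_ids, "housekeeping"))
    for k in range(1, cfg.n_spike_in + 1):
        probes.append(Probe(f"SPIKE_{k:02d}", "SPIKEIN", (), "spike_in"))
    return genes + housekeeping, probes


def _tissue_labels(cfg: SimulationConfig) -> pd.Series:
    names = list(DEFAULT_TISSUES[: len(cfg.tissue_weights)])
    names += [f"tissue_{k}" for k in range(len(names) + 1, len(cfg.tissue_weights) + 1)]
    counts = _largest_remainder(np.asarray(cfg.tissue_weights), cfg.n_samples)
    labels = {}
    si = 0
    for name, c in zip(names, counts):
        for _ in range(c):
            si += 1
            labels[f"S{si:03d}"] = name
    return pd.Series(labels, name="tissue")


def simulate_truth(
    genes: list[GeneModel],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Draw ground-truth isoform expressions for the cohort.

    Per-isoform log-normal baselines with per-sample multiplicative
    biological spread; a configured fraction of endogenous genes carries a
    tissue-specific 2**de_effect mean shift (all isoforms of the gene
    shifted together); housekeeping genes are constant across samples.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = _tissue_labels(cfg)
    samples = list(labels.index)
    endo = [g for g in genes if not _is_housekeeping(g)]
    hk = [g for g in genes if _is_housekeeping(g)]

    rows: dict[str, np.ndarray] = {}
    annotation: dict[str, str] = {}
    n_samples = len(samples)
    de_genes: dict[str, str] = {}
    tissues = sorted(labels.unique())
    n_de = int(round(cfg.de_fraction * len(endo)))
    if n_de:
        de_idx = rng.choice(len(endo), size=n_de, replace=False)
        for i in de_idx:
            de_genes[endo[i].gene_id] = tissues[rng.integers(len(tissues))]

    for gene in endo:
        shift_tissue = de_genes.get(gene.gene_id)
        tissue_mask = (labels.to_numpy() == shift_tissue) if shift_tissue else None
        for iso in gene.isoform_ids:
            base = rng.lognormal(cfg.log_mean, cfg.log_sd)
            x = base * rng.lognormal(0.0, cfg.biological_sd, size=n_samples)
            if tissue_mask is not None:
                x = np.where(tissue_mask, x * 2.0**cfg.de_effect, x)
            rows[iso] = x
            annotation[iso] = gene.gene_id
    for gene in hk:
        base = cfg.housekeeping_level * rng.lognormal(0.0, 0.1)
        for iso in gene.isoform_ids:
            rows[iso] = np.full(n_samples, base)
            annotation[iso] = gene.gene_id

    expr = ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", dtype=float).set_axis(samples, axis=1),
        level="isoform",
        transform="raw",
    )
    return GroundTruth(
        genes=endo, housekeeping=hk, expression=expr,
        labels=labels, de_genes=de_genes, annotation=annotation,
    )


def _is_housekeeping(gene: GeneModel) -> bool:
    return gene.gene_id in DEFAULT_HOUSEKEEPING or (
        gene.gene_id.startswith("HK") and gene.gene_id[2:].isdigit()
    )


def simulate_probe_counts(
    truth: GroundTruth,
    probes: list[Probe],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ProbeCountMatrix, dict[str, str]]:
    """Forward-simulate raw probe intensities y = A.x with noise.

    Each replicate column gets a per-sample global scale factor (shared by
    replicates of the same sample; what housekeeping normalization is meant
    to remove), a per-replicate scale jitter, per-measurement multiplicative
    log-normal noise, and an additive background floor.  Returns the raw
    count matrix and the replicate-column -> sample map.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    samples = list(truth.expression.sample_ids)
    expr = truth.expression.values
    scale = rng.lognormal(0.0, cfg.sample_scale_sd, size=len(samples))

    columns: dict[str, np.ndarray] = {}
    replicate_map: dict[str, str] = {}
    n_probes = len(probes)
    signals = np.zeros((n_probes, len(samples)))
    for j, probe in enumerate(probes):
        if probe.probe_class == "spike_in":
            signals[j] = cfg.spike_in_level
        else:
            signals[j] = expr.loc[list(probe.targets)].to_numpy().sum(axis=0)
    for r in range(1, cfg.n_replicates + 1):
        rep_jitter = rng.lognormal(0.0, cfg.replicate_sd, size=len(samples))
        noise = rng.lognormal(0.0, cfg.noise_sd, size=signals.shape)
        vals = signals * (scale * rep_jitter)[None, :] * noise + cfg.background
        for si, s in enumerate(samples):
            col = s if cfg.n_replicates == 1 else f"{s}:rep{r}"
            columns[col] = vals[:, si]
            replicate_map[col] = s
    counts = pd.DataFrame(columns, index=[p.probe_id for p in probes], dtype=float)
    return ProbeCountMatrix(counts, normalized=False), replicate_map


def probe_capture_view(
    truth: GroundTruth,
    probes: list[Probe],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Full probe-capture pipeline: simulate counts, normalize by the
    housekeeping geometric mean, average technical replicates, deconvolve.
    Returns raw-scale isoform and gene matrices for the panel genes."""
    raw, rep_map = simulate_probe_counts(truth, probes, cfg, rng)
    hk_ids = tuple(g.gene_id for g in truth.housekeeping)
    normalized = housekeeping_normalize(raw, probes, hk_ids)
    collapsed = collapse_replicates(normalized, rep_map)
    return quantify_panel(collapsed, truth.genes, probes)


def _mix_within_gene(truth: GroundTruth, ambiguity: float) -> pd.DataFrame:
    """Blend each isoform toward its gene's mean expression.

    Models ambiguous read assignment in shared exon regions: a fraction
    ``ambiguity`` of each gene's signal is distributed uniformly over its
    isoforms.  Gene totals are preserved exactly.
    """
    expr = truth.expression.values.copy()
    for gene in truth.genes:
        isos = list(gene.isoform_ids)
        block = expr.loc[isos].to_numpy()
        mixed = (1 - ambiguity) * block + ambiguity * block.mean(axis=0, keepdims=True)
        expr.loc[isos] = mixed
    return expr


def simulate_platform_views(
    truth: GroundTruth,
    probes: list[Probe],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, ExpressionMatrix]:
    """Emit isoform-level raw expression views of the panel genes on three
    platforms with distinct biases.

    - ``seq``: Poisson-sampled counts at ``seq_depth`` reads per expression
      unit, after within-gene ambiguity mixing at rate ``ambiguity``.
    - ``array``: truth plus an additive ``array_background`` floor with
      multiplicative noise — the floor compresses the low-expression range.
    - ``probe``: the probe-capture pipeline (simulate, normalize,
      deconvolve).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    panel_isos = [iso for g in truth.genes for iso in g.isoform_ids]
    samples = truth.expression.sample_ids

    mixed = _mix_within_gene(truth, cfg.ambiguity).loc[panel_isos]
    lam = np.maximum(mixed.to_numpy() * cfg.seq_depth, 0.0)
    seq_vals = rng.poisson(lam).astype(float) / cfg.seq_depth
    seq = ExpressionMatrix(
        pd.DataFrame(seq_vals, index=panel_isos, columns=samples),
        level="isoform", transform="raw",
    )

    base = truth.expression.values.loc[panel_isos].to_numpy()
    arr_vals = (base + cfg.array_background) * rng.lognormal(
        0.0, cfg.array_noise_sd, size=base.shape
    )
    array = ExpressionMatrix(
        pd.DataFrame(arr_vals, index=panel_isos, columns=samples),
        level="isoform", transform="raw",
    )

    probe_iso, _ = probe_capture_view(truth, probes, cfg, rng)
    return {"seq": seq, "array": array, "probe": probe_iso}


def gene_view(M: ExpressionMatrix, annotation: dict[str, str]) -> ExpressionMatrix:
    """Aggregate a raw isoform matrix to gene level by summing isoforms."""
    if M.level != "isoform" or M.transform != "raw":
        raise ValueError("gene aggregation needs a raw isoform-level matrix")
    grouped = M.values.groupby(
        pd.Index([annotation[i] for i in M.feature_ids], name="gene_id")
    ).sum()
    return ExpressionMatrix(grouped, level="gene", transform="raw")


def simulate_ct(
    truth: GroundTruth,
    gene_ids: list[str],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-isoform qPCR cycle thresholds for selected genes.

    Ct = ct_offset - log2(x_true) + Gaussian noise; a zero-expression
    isoform yields a missing (NaN) Ct.  Tidy output: gene_id, isoform_id,
    sample_id, ct.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if samples is None:
        samples = list(truth.expression.sample_ids)
    by_id = {g.gene_id: g for g in truth.genes + truth.housekeeping}
    records = []
    for gid in gene_ids:
        if gid not in by_id:
            raise KeyError(f"unknown gene {gid!r}")
        for iso in by_id[gid].isoform_ids:
            x = truth.expression.values.loc[iso, samples].to_numpy(dtype=float)
            with np.errstate(divide="ignore"):
                ct = cfg.ct_offset - np.log2(x) + rng.normal(0.0, cfg.ct_noise_sd, len(samples))
            ct = np.where(x > 0, ct, np.nan)
            for s, v in zip(samples, ct):
                records.append((gid, iso, s, v))
    return pd.DataFrame(records, columns=["gene_id", "isoform_id", "sample_id", "ct"])


def simulate_study(cfg: SimulationConfig):
    """One-call study generator used by the CLI and analysis drivers.

    Returns (genes, probes, truth, views, gene_views) where views/gene_views
    are isoform- and gene-level raw matrices per platform, all driven by
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, probes = simulate_panel(cfg, rng)
    truth = simulate_truth(genes, cfg, rng)
    views = simulate_platform_views(truth, probes, cfg, rng)
    gene_views = {name: gene_view(M, truth.annotation) for name, M in views.items()}
    return genes, probes, truth, views, gene_views
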