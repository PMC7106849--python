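"""Housekeeping normalization and non-negative isoform deconvolution.

Probe counts for one sample restricted to one gene form an intensity vector
``y``; with the gene's probe–isoform incidence matrix ``A`` the isoform
expression vector ``x`` is the non-negative least-squares minimiser of
``||y - A x||^2``.  Gene expression is the sum of its isoform expressions.
Between-sample normalization rescales each sample so that the geometric mean
of its housekeeping-gene signals matches the cohort-wide geometric mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .panel import GeneModel, IdentifiabilityReport, IncidenceMatrix, Probe, build_incidence_matrix, check_identifiability

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "ProbeCountMatrix",
    "IsoformExpressionVector",
    "ExpressionMatrix",
    "NormalizationError",
    "housekeeping_normalize",
    "collapse_replicates",
    "deconvolve_gene",
    "gene_expression_from_isoforms",
    "log_transform",
    "quantify_panel",
]

#: The ten housekeeping genes used for geometric-mean normalization.
DEFAULT_HOUSEKEEPING = (
    "TAF5L", "HPS6", "DNTTIP2", "GNRHR", "ZNF407",
    "KCNK7", "KIAA1539", "RBM12", "DGCR14", "KHDRBS1",
)


class NormalizationError(ValueError):
    pass


@dataclass
class ProbeCountMatrix:
    """Probe-by-sample count matrix (raw or housekeeping-normalized)."""

    counts: pd.DataFrame  # probes in rows, samples in columns
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate probe id {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("probe counts must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class IsoformExpressionVector:
    """Deconvolved isoform expressions for one gene in one sample.

    When the design is not fully identifiable, only the expression *sums* of
    indistinguishable isoform groups are constrained: ``group_values`` holds
    those sums and ``values`` carries NaN for isoforms inside a multi-member
    group (not-estimable rather than an arbitrary split).
    """

    isoform_ids: list[str]
    values: np.ndarray  # NaN where not estimable
    groups: list[tuple[str, ...]]
    group_values: np.ndarray
    identifiability: IdentifiabilityReport
    objective: float  # residual ||y - A x||^2 at the solution

    @property
    def identifiable(self) -> bool:
        return self.identifiability.identifiable

    @property
    def total(self) -> float:
        """Gene expression: the sum over estimable groups."""
        return float(np.sum(self.group_values))


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression matrix with level and transform tags."""

    values: pd.DataFrame
    level: str  # "isoform" | "gene"
    transform: str = "raw"  # "raw" | "log1p"

    def __post_init__(self) -> None:
        if self.level not in ("isoform", "gene"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.transform not in ("raw", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _geomean(a: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(a))))


def housekeeping_normalize(
    raw: ProbeCountMatrix,
    probes: list[Probe],
    housekeeping_gene_ids: tuple[str, ...] = DEFAULT_HOUSEKEEPING,
) -> ProbeCountMatrix:
    """Scale each sample by its housekeeping geometric mean.

    Per sample the geometric mean of the housekeeping probe counts is taken;
    the scale factor is (cohort geometric mean of those per-sample geomeans)
    / (the sample's geomean), so the across-sample geometric mean of
    housekeeping signal is preserved while sample-specific global scale is
    removed.

    Raises
    ------
    NormalizationError
        On already-normalized input, a housekeeping gene with no probe, or a
        zero housekeeping count (geometric mean undefined).
    """
    if raw.normalized:
        raise NormalizationError("input is already normalized; refusing to renormalize")
    by_gene: dict[str, list[str]] = {}
    for p in probes:
        if p.probe_id in raw.counts.index:
            by_gene.setdefault(p.gene_id, []).append(p.probe_id)
    hk_probe_ids: list[str] = []
    for g in housekeeping_gene_ids:
        if g not in by_gene:
            raise NormalizationError(f"housekeeping gene {g!r} has no probe in the count matrix")
        hk_probe_ids.extend(by_gene[g])

    hk = raw.counts.loc[hk_probe_ids]
    for sample in raw.sample_ids:
        col = hk[sample]
        if (col <= 0).any():
            gene = next(p.gene_id for p in probes if p.probe_id == col.index[(col <= 0).argmax()])
            raise NormalizationError(
                f"zero housekeeping count in sample {sample!r} (gene {gene!r})"
            )
    sample_geomeans = np.exp(np.log(hk.to_numpy(dtype=float)).mean(axis=0))
    reference = _geomean(sample_geomeans)
    factors = reference / sample_geomeans
    scaled = raw.counts * factors
    return ProbeCountMatrix(scaled, normalized=True)


def collapse_replicates(
    counts: ProbeCountMatrix, replicate_map: dict[str, str]
) -> ProbeCountMatrix:
    """Average technical replicate columns (arithmetic mean of normalized
    counts), mapping each replicate column to its sample id."""
    missing = [c for c in counts.sample_ids if c not in replicate_map]
    if missing:
        raise ValueError(f"columns without a replicate mapping: {missing}")
    collapsed = counts.counts.T.groupby(
        [replicate_map[c] for c in counts.sample_ids]
    ).mean().T
    return ProbeCountMatrix(collapsed, normalized=counts.normalized)


def deconvolve_gene(y: np.ndarray, im: IncidenceMatrix) -> IsoformExpressionVector:
    """Estimate isoform expressions from one gene's probe intensities.

    Minimises ``||y - A x||^2`` subject to ``x >= 0``.  Indistinguishable
    isoforms (identical columns of A) are collapsed before solving, so the
    solver works on distinct columns only; their shared coefficient is a
    group expression sum.  The solution is the unique minimiser whenever the
    collapsed design has full column rank.
    """
    y = np.asarray(y, dtype=float)
    m, n = im.shape
    if y.shape != (m,):
        raise ValueError(f"intensity vector has length {y.shape}, expected {m}")
    if (y < 0).any():
        raise ValueError("probe intensities must be non-negative")

    report = check_identifiability(im)
    groups = report.indistinguishable_groups
    iso_index = {iso: i for i, iso in enumerate(im.isoform_ids)}

    # one representative column per group; a group's coefficient is the sum
    # of its members' expressions
    estimable = [g for g in groups if not set(g) <= set(report.untargeted)]
    A_grp = np.column_stack([im.A[:, iso_index[g[0]]] for g in estimable]).astype(float)
    x_grp, rnorm = nnls(A_grp, y)
    if report.partially_identifiable:
        logger.debug(
            "gene design is rank-deficient beyond duplicate columns; "
            "returned minimizer is not unique"
        )

    values = np.full(n, np.nan)
    group_values = np.zeros(len(estimable))
    for k, g in enumerate(estimable):
        group_values[k] = x_grp[k]
        if len(g) == 1:
            values[iso_index[g[0]]] = x_grp[k]
    return IsoformExpressionVector(
        isoform_ids=list(im.isoform_ids),
        values=values,
        groups=list(estimable),
        group_values=group_values,
        identifiability=report,
        objective=float(rnorm**2),
    )


def gene_expression_from_isoforms(x: IsoformExpressionVector | np.ndarray) -> float:
    """Total gene expression: the sum of isoform expressions."""
    if isinstance(x, IsoformExpressionVector):
        return x.total
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("isoform expressions must be non-negative")
    return float(arr.sum())


def log_transform(M: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Entrywise log(x + 1) in the given base (default 2).

    A monotone bijection on [0, inf); downstream rank statistics are
    invariant to the base choice.
    """
    if M.transform != "raw":
        raise ValueError("matrix is already log-transformed")
    arr = M.values.to_numpy(dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("negative entries cannot be log(x+1)-transformed")
    out = pd.DataFrame(
        np.log1p(arr) / np.log(base), index=M.values.index, columns=M.values.columns
    )
    return ExpressionMatrix(out, level=M.level, transform="log1p")


def quantify_panel(
    counts: ProbeCountMatrix,
    genes: list[GeneModel],
    probes: list[Probe],
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Deconvolve every panel gene in every sample.

    Returns raw-scale (pre-log) isoform and gene expression matrices.  Gene
    values equal the column sums of their isoform group values, exactly.
    Isoforms inside indistinguishable multi-member groups appear as NaN rows
    (not-estimable); spike-in probes are ignored; genes without probes are
    skipped with a warning.
    """
    if not counts.normalized:
        raise ValueError("counts must be housekeeping-normalized before deconvolution")
    probes_by_gene: dict[str, list[Probe]] = {}
    for p in probes:
        if p.probe_class == "endogenous":
            probes_by_gene.setdefault(p.gene_id, []).append(p)

    iso_rows: dict[str, dict[str, float]] = {}
    gene_rows: dict[str, dict[str, float]] = {}
    samples = counts.sample_ids
    for gene in genes:
        gprobes = probes_by_gene.get(gene.gene_id)
        if not gprobes:
            warnings.warn(f"gene {gene.gene_id!r} has no endogenous probes; skipped")
            continue
        im = build_incidence_matrix(gene, gprobes)
        Y = counts.counts.loc[[p.probe_id for p in gprobes]].to_numpy(dtype=float)
        gene_rows[gene.gene_id] = {}
        for iso in gene.isoform_ids:
            iso_rows[iso] = {}
        for si, sample in enumerate(samples):
            vec = deconvolve_gene(Y[:, si], im)
            gene_rows[gene.gene_id][sample] = vec.total
            for iso, v in zip(vec.isoform_ids, vec.values):
                iso_rows[iso][sample] = v

    iso_df = pd.DataFrame.from_dict(iso_rows, orient="index", dtype=float)
    gene_df = pd.DataFrame.from_dict(gene_rows, orient="index", dtype=float)
    if samples:
        iso_df = iso_df.reindex(columns=samples)
        gene_df = gene_df.reindex(columns=samples)
    else:  # keep feature metadata even with no samples
        iso_df = pd.DataFrame(index=list(iso_rows), dtype=float)
        gene_df = pd.DataFrame(index=list(gene_rows), dtype=float)
    return (
        ExpressionMatrix(iso_df, level="isoform", transform="raw"),
        ExpressionMatrix(gene_df, level="gene", transform="raw"),
    )
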