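"""Within-gene isoform proportions and the cross-platform proportion
difference statistic.

For gene *i* with m_i isoforms measured on platform *a*, the proportion of
isoform *j* is p^a_ij = x_ij / sum_j x_ij.  Two platforms are compared by

    d = (1/n) * sum_i [ (1/m_i) * sum_j | p^a_ij - p^b_ij | ]

over the n genes estimable on both platforms.  d lies in [0, 1]: it is 0 iff
the proportion tables agree and 1 only when every gene's mass sits on
disjoint isoforms.  RT-qPCR cycle thresholds reach the same representation
through the comparative-Ct route: relative quantity 2^(-Ct), normalised
within the gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import ExpressionMatrix

__all__ = [
    "ProportionTable",
    "ProportionDifference",
    "isoform_proportions",
    "proportion_difference",
    "proportion_difference_per_sample",
    "collapse_to_groups",
    "ct_to_proportions",
    "rank_sum_compare",
]

PROPORTION_COLUMNS = ["gene_id", "isoform_id", "sample_id", "proportion"]


@dataclass
class ProportionTable:
    """Tidy per-gene, per-sample isoform proportions.

    ``data`` has columns gene_id, isoform_id, sample_id, proportion; within
    every (gene, sample) the proportions sum to 1.  Genes whose total
    expression is zero in a sample are excluded and recorded in
    ``excluded``.
    """

    data: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (gene, sample)

    def __post_init__(self) -> None:
        missing = [c for c in PROPORTION_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"proportion table missing columns {missing}")
        if len(self.data):
            sums = self.data.groupby(["gene_id", "sample_id"])["proportion"].sum()
            bad = sums[(sums - 1.0).abs() > 1e-9]
            if len(bad):
                g, s = bad.index[0]
                raise ValueError(
                    f"proportions for gene {g!r} sample {s!r} sum to {bad.iloc[0]:.12g}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())


@dataclass
class ProportionDifference:
    """The proportion-difference statistic d for one shared sample."""

    d: float
    n_genes_used: int
    excluded_genes: list[str] = field(default_factory=list)


def isoform_proportions(
    M: ExpressionMatrix, annotation: dict[str, str]
) -> ProportionTable:
    """Convert a raw-scale isoform expression matrix to proportions.

    ``annotation`` maps isoform_id -> gene_id.  NaN expressions
    (not-estimable isoforms) and zero-total genes are excluded and recorded.
    """
    if M.level != "isoform":
        raise ValueError("proportions are defined on isoform-level matrices")
    if M.transform != "raw":
        raise ValueError("proportions must be computed on the raw (pre-log) scale")
    unmapped = [f for f in M.feature_ids if f not in annotation]
    if unmapped:
        raise KeyError(f"isoform {unmapped[0]!r} has no gene annotation")

    records: list[tuple[str, str, str, float]] = []
    excluded: list[tuple[str, str]] = []
    genes: dict[str, list[str]] = {}
    for iso in M.feature_ids:
        genes.setdefault(annotation[iso], []).append(iso)
    vals = M.values
    for gene_id, isos in genes.items():
        block = vals.loc[isos]
        for sample in M.sample_ids:
            x = block[sample].to_numpy(dtype=float)
            if np.isnan(x).any():
                excluded.append((gene_id, sample))
                continue
            total = x.sum()
            if total <= 0:
                excluded.append((gene_id, sample))
                continue
            for iso, p in zip(isos, x / total):
                records.append((gene_id, iso, sample, p))
    data = pd.DataFrame(records, columns=PROPORTION_COLUMNS)
    return ProportionTable(data, excluded=excluded)


def _pivot(P: ProportionTable, sample: str) -> pd.Series:
    sub = P.data[P.data["sample_id"] == sample]
    return sub.set_index(["gene_id", "isoform_id"])["proportion"]


def proportion_difference(
    P_a: ProportionTable, P_b: ProportionTable, sample_id: str | None = None
) -> ProportionDifference:
    """The mean-over-genes average absolute proportion difference d between
    two platforms, for one shared sample.

    Only genes present in both tables for that sample enter; each gene must
    expose the same isoform set on both platforms (collapse with
    :func:`collapse_to_groups` first if the designs differ in resolution).
    """
    if sample_id is None:
        shared = sorted(set(P_a.sample_ids) & set(P_b.sample_ids))
        if len(shared) != 1:
            raise ValueError(
                f"tables share {len(shared)} samples; pass sample_id explicitly "
                "or use proportion_difference_per_sample"
            )
        sample_id = shared[0]

    a = _pivot(P_a, sample_id)
    b = _pivot(P_b, sample_id)
    genes_a = set(a.index.get_level_values(0))
    genes_b = set(b.index.get_level_values(0))
    common = sorted(genes_a & genes_b)
    if not common:
        raise ValueError(f"no genes shared between platforms in sample {sample_id!r}")
    excluded = sorted((genes_a | genes_b) - set(common))

    terms = []
    for gene in common:
        pa = a.loc[gene]
        pb = b.loc[gene].reindex(pa.index)
        if pb.isna().any():
            raise ValueError(
                f"gene {gene!r}: isoform sets differ between platforms in "
                f"sample {sample_id!r}; collapse to shared groups first"
            )
        terms.append(float(np.abs(pa.to_numpy() - pb.to_numpy()).mean()))
    return ProportionDifference(
        d=float(np.mean(terms)), n_genes_used=len(common), excluded_genes=excluded
    )


def proportion_difference_per_sample(
    P_a: ProportionTable, P_b: ProportionTable
) -> pd.Series:
    """d for every sample shared by the two tables (one value per sample)."""
    shared = sorted(set(P_a.sample_ids) & set(P_b.sample_ids))
    if not shared:
        raise ValueError("tables share no samples")
    return pd.Series(
        {s: proportion_difference(P_a, P_b, s).d for s in shared}, name="d"
    )


def collapse_to_groups(
    P: ProportionTable, groups_by_gene: dict[str, list[tuple[str, ...]]]
) -> ProportionTable:
    """Collapse a proportion table to indistinguishable-group resolution.

    Each group's proportion is the sum of its members'; the group is renamed
    by joining member ids with '+'.  Platforms with full-resolution
    estimates are collapsed to the coarser design's groups so the
    cross-platform comparison stays well-defined.
    """
    frames = []
    for gene_id, groups in groups_by_gene.items():
        sub = P.data[P.data["gene_id"] == gene_id]
        if sub.empty:
            continue
        member_to_group = {m: "+".join(g) for g in groups for m in g}
        sub = sub.assign(isoform_id=sub["isoform_id"].map(member_to_group))
        if sub["isoform_id"].isna().any():
            raise KeyError(f"gene {gene_id!r}: isoform missing from group map")
        frames.append(
            sub.groupby(["gene_id", "isoform_id", "sample_id"], as_index=False)[
                "proportion"
            ].sum()
        )
    untouched = P.data[~P.data["gene_id"].isin(groups_by_gene)]
    data = pd.concat([untouched, *frames], ignore_index=True)
    return ProportionTable(data[PROPORTION_COLUMNS], excluded=list(P.excluded))


def ct_to_proportions(
    ct_values: np.ndarray | pd.Series, efficiency: float = 2.0
) -> np.ndarray:
    """Comparative-Ct proportions for one gene's isoforms in one sample.

    Each cycle threshold unit corresponds to an ``efficiency``-fold (default
    two-fold) abundance difference: relative quantity q_j =
    efficiency^(-Ct_j), normalised to sum to 1.  Missing (undetermined) Ct
    values drop their isoform with a warning; adding a constant to all Ct
    values of the gene leaves the proportions unchanged.
    """
    ct = np.asarray(ct_values, dtype=float)
    mask = np.isfinite(ct)
    if not mask.any():
        raise ValueError("all Ct values are missing")
    if not mask.all():
        warnings.warn(f"{(~mask).sum()} isoform(s) with undetermined Ct dropped")
    # subtract the min Ct for numerical stability; proportions are invariant
    q = np.where(mask, efficiency ** -(ct - np.nanmin(ct)), 0.0)
    return q / q.sum()


def rank_sum_compare(
    d_values_a: np.ndarray | list, d_values_b: np.ndarray | list
) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two sets of d values.

    Exact enumeration for combined n <= 20 (no ties), normal approximation
    with tie correction otherwise.  Degenerate all-tied input returns 1.
    """
    a = np.asarray(d_values_a, dtype=float)
    b = np.asarray(d_values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied; rank-sum test is uninformative")
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
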