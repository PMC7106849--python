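"""Cross-platform concordance battery.

Per-sample and pooled Spearman rank correlations between two platforms'
expression matrices, the bottom-third low-expression subset, tissue
fold-change pairs, and one-way ANOVA differential-expression ranking across
tissue types.  All rank statistics are invariant to monotone transforms, so
they do not depend on the log base used upstream.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .proportions import ProportionTable, proportion_difference_per_sample
from .quantify import ExpressionMatrix

__all__ = [
    "SampleCorrelationSet",
    "DEResult",
    "ConcordanceReport",
    "spearman_per_sample",
    "pooled_correlation",
    "low_expression_subset",
    "fold_change_pairs",
    "anova_de",
    "platform_agreement_report",
]


@dataclass
class SampleCorrelationSet:
    """Per-sample Spearman coefficients between two platforms."""

    coefficients: pd.Series  # indexed by sample id; NaN where undefined
    level: str
    platforms: tuple[str, str] = ("a", "b")

    @property
    def mean(self) -> float:
        return float(self.coefficients.mean())

    @property
    def median(self) -> float:
        return float(self.coefficients.median())


@dataclass
class DEResult:
    """Per-gene one-way ANOVA F statistics and the ranked top genes."""

    table: pd.DataFrame  # gene_id index; columns F, pvalue, qvalue, rank
    top: list[str]
    groups_used: list[str]


def _align(M_a: ExpressionMatrix, M_b: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    features = [f for f in M_a.feature_ids if f in set(M_b.feature_ids)]
    samples = [s for s in M_a.sample_ids if s in set(M_b.sample_ids)]
    if len(features) < 3:
        raise ValueError(f"platforms share only {len(features)} features; need >= 3")
    if len(samples) < 1:
        raise ValueError("platforms share no samples")
    return M_a.values.loc[features, samples], M_b.values.loc[features, samples]


def spearman_per_sample(
    M_a: ExpressionMatrix,
    M_b: ExpressionMatrix,
    platforms: tuple[str, str] = ("a", "b"),
) -> SampleCorrelationSet:
    """Spearman correlation of the two platforms' shared features, sample by
    sample (average-rank tie handling).  Constant vectors yield NaN with a
    warning."""
    if M_a.level != M_b.level:
        raise ValueError("matrices are at different feature levels")
    va, vb = _align(M_a, M_b)
    coeffs = {}
    for sample in va.columns:
        x, y = va[sample].to_numpy(), vb[sample].to_numpy()
        ok = ~(np.isnan(x) | np.isnan(y))
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            warnings.warn(f"constant expression vector in sample {sample!r}; correlation undefined")
            coeffs[sample] = np.nan
            continue
        coeffs[sample] = stats.spearmanr(x[ok], y[ok]).statistic
    return SampleCorrelationSet(
        pd.Series(coeffs, name="spearman"), level=M_a.level, platforms=platforms
    )


def pooled_correlation(M_a: ExpressionMatrix, M_b: ExpressionMatrix) -> float:
    """One Spearman coefficient over all (feature, sample) pairs pooled."""
    va, vb = _align(M_a, M_b)
    x = va.to_numpy().ravel()
    y = vb.to_numpy().ravel()
    ok = ~(np.isnan(x) | np.isnan(y))
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        warnings.warn("constant pooled vector; correlation undefined")
        return float("nan")
    return float(stats.spearmanr(x[ok], y[ok]).statistic)


def low_expression_subset(M_a: ExpressionMatrix, M_b: ExpressionMatrix) -> list[str]:
    """Features in the bottom one-third by mean expression on *both*
    platforms.

    Each platform ranks its shared features by mean expression across
    samples and takes the bottom floor(N/3); the intersection is returned
    (possibly empty), sorted for determinism.
    """
    va, vb = _align(M_a, M_b)
    k = len(va) // 3
    bottom_a = set(va.mean(axis=1).nsmallest(k, keep="first").index)
    bottom_b = set(vb.mean(axis=1).nsmallest(k, keep="first").index)
    return sorted(bottom_a & bottom_b)


def fold_change_pairs(
    M: ExpressionMatrix,
    labels: pd.Series,
    target_tissue: str,
    raw_ratio: bool = False,
) -> pd.DataFrame:
    """Log fold-changes of every gene between each target-tissue sample and
    each sample outside the tissue.

    ``M`` is expected on the log(x+1) scale, so the fold-change is the
    difference of log expressions.  With ``raw_ratio`` the back-transformed
    ratio (x_t + 1)/(x_o + 1) is reported instead.  The result is tidy:
    columns gene_id, target_sample, other_sample, fold_change, with exactly
    |target| x |non-target| x genes rows.
    """
    missing = [s for s in M.sample_ids if s not in labels.index]
    if missing:
        raise KeyError(f"samples without tissue labels: {missing}")
    target = [s for s in M.sample_ids if labels[s] == target_tissue]
    other = [s for s in M.sample_ids if labels[s] != target_tissue]
    if not target or not other:
        raise ValueError(
            f"need samples inside and outside tissue {target_tissue!r} "
            f"(got {len(target)} / {len(other)})"
        )
    records = []
    vals = M.values
    for t, o in itertools.product(target, other):
        diff = vals[t] - vals[o]
        fc = np.exp2(diff) if raw_ratio and M.transform == "log1p" else diff
        for gene, v in fc.items():
            records.append((gene, t, o, float(v)))
    return pd.DataFrame(
        records, columns=["gene_id", "target_sample", "other_sample", "fold_change"]
    )


def anova_de(
    M: ExpressionMatrix, tissue_labels: pd.Series, k_top: int = 10
) -> DEResult:
    """One-way fixed-effects ANOVA of each gene across tissue types.

    Tissues with fewer than two samples are dropped with a warning.  Genes
    are ranked by ascending p-value with a lexicographic gene-id tie-break;
    the top ``k_top`` gene ids are returned.  A Benjamini-Hochberg q-value
    column is attached as supplementary output.
    """
    labels = tissue_labels.reindex(M.sample_ids)
    if labels.isna().any():
        raise KeyError(
            f"samples without tissue labels: {list(labels[labels.isna()].index)}"
        )
    counts = labels.value_counts()
    usable = sorted(counts[counts >= 2].index)
    dropped = sorted(counts[counts < 2].index)
    if dropped:
        warnings.warn(f"tissues with a single sample dropped from ANOVA: {dropped}")
    if len(usable) < 2:
        raise ValueError("ANOVA needs at least two tissues with >= 2 samples")

    groups = [
        M.values[[s for s in M.sample_ids if labels[s] == t]].to_numpy()
        for t in usable
    ]
    with warnings.catch_warnings():
        # genes constant within every group produce a 0/0 F statistic
        warnings.simplefilter("ignore", category=RuntimeWarning)
        res = stats.f_oneway(*groups, axis=1)
    F = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # a zero between-group sum of squares is no evidence of an effect
    F = np.where(np.isnan(F), 0.0, F)
    p = np.where(np.isnan(p), 1.0, p)

    table = pd.DataFrame({"F": F, "pvalue": p}, index=pd.Index(M.feature_ids, name="gene_id"))
    table["qvalue"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    table = table.sort_values(["pvalue", "gene_id"], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return DEResult(table=table, top=list(table.index[:k_top]), groups_used=usable)


@dataclass
class ConcordanceReport:
    """Bundle of pairwise concordance results across >= 2 platforms."""

    per_sample: dict[tuple[str, str], SampleCorrelationSet] = field(default_factory=dict)
    per_sample_gene: dict[tuple[str, str], SampleCorrelationSet] = field(default_factory=dict)
    pooled: dict[tuple[str, str], float] = field(default_factory=dict)
    pooled_gene: dict[tuple[str, str], float] = field(default_factory=dict)
    proportion_diff: dict[tuple[str, str], pd.Series] = field(default_factory=dict)
    low_expression: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    low_expression_corr: dict[tuple[str, str], float] = field(default_factory=dict)
    fold_changes: dict[str, pd.DataFrame] = field(default_factory=dict)
    de: dict[str, DEResult] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Serialize the report as one TSV per analysis per platform pair."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def pair_frames(d, value_name):
            rows = []
            for (a, b), val in d.items():
                if isinstance(val, SampleCorrelationSet):
                    for s, v in val.coefficients.items():
                        rows.append((a, b, s, v))
                elif isinstance(val, pd.Series):
                    for s, v in val.items():
                        rows.append((a, b, s, v))
                else:
                    rows.append((a, b, "", val))
            return pd.DataFrame(
                rows, columns=["platform_a", "platform_b", "sample_id", value_name]
            )

        pair_frames(self.per_sample, "spearman").to_csv(
            outdir / "spearman_per_sample.tsv", sep="\t", index=False)
        pair_frames(self.per_sample_gene, "spearman").to_csv(
            outdir / "spearman_per_sample_gene.tsv", sep="\t", index=False)
        pooled_rows = [
            (a, b, "isoform", v) for (a, b), v in self.pooled.items()
        ] + [(a, b, "gene", v) for (a, b), v in self.pooled_gene.items()]
        pd.DataFrame(
            pooled_rows, columns=["platform_a", "platform_b", "level", "spearman"]
        ).to_csv(outdir / "pooled.tsv", sep="\t", index=False)
        pair_frames(self.proportion_diff, "d").to_csv(
            outdir / "proportion_diff.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(a, b, g) for (a, b), genes in self.low_expression.items() for g in genes],
            columns=["platform_a", "platform_b", "gene_id"],
        ).to_csv(outdir / "low_expr_genes.tsv", sep="\t", index=False)
        frames = []
        for platform, fc in self.fold_changes.items():
            frames.append(fc.assign(platform=platform))
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "fold_changes.tsv", sep="\t", index=False)
        de_frames = []
        for platform, de in self.de.items():
            de_frames.append(de.table.reset_index().assign(platform=platform))
        if de_frames:
            pd.concat(de_frames, ignore_index=True).to_csv(
                outdir / "anova.tsv", sep="\t", index=False)


def platform_agreement_report(
    isoform_matrices: dict[str, ExpressionMatrix],
    gene_matrices: dict[str, ExpressionMatrix],
    proportion_tables: dict[str, ProportionTable] | None = None,
    labels: pd.Series | None = None,
    target_tissue: str | None = None,
    k_top: int = 10,
    outdir: str | Path | None = None,
) -> ConcordanceReport:
    """Run the full pairwise concordance battery over >= 2 platforms.

    Expression matrices should be on the log(x+1) scale (rank statistics do
    not care, but fold-changes do).  Fold-change and ANOVA results are
    produced per platform when ``labels`` (and ``target_tissue`` for
    fold-changes) are given.
    """
    names = sorted(isoform_matrices)
    if len(names) < 2:
        raise ValueError("need at least two platforms to compare")
    report = ConcordanceReport()
    for a, b in itertools.combinations(names, 2):
        Ma, Mb = isoform_matrices[a], isoform_matrices[b]
        report.per_sample[(a, b)] = spearman_per_sample(Ma, Mb, platforms=(a, b))
        report.pooled[(a, b)] = pooled_correlation(Ma, Mb)
        Ga, Gb = gene_matrices[a], gene_matrices[b]
        report.per_sample_gene[(a, b)] = spearman_per_sample(Ga, Gb, platforms=(a, b))
        report.pooled_gene[(a, b)] = pooled_correlation(Ga, Gb)
        low = low_expression_subset(Ga, Gb)
        report.low_expression[(a, b)] = low
        if len(low) >= 3:
            sub_a = ExpressionMatrix(Ga.values.loc[low], level="gene", transform=Ga.transform)
            sub_b = ExpressionMatrix(Gb.values.loc[low], level="gene", transform=Gb.transform)
            report.low_expression_corr[(a, b)] = pooled_correlation(sub_a, sub_b)
        if proportion_tables and a in proportion_tables and b in proportion_tables:
            report.proportion_diff[(a, b)] = proportion_difference_per_sample(
                proportion_tables[a], proportion_tables[b]
            )
    if labels is not None:
        for name, G in gene_matrices.items():
            if target_tissue is not None:
                report.fold_changes[name] = fold_change_pairs(G, labels, target_tissue)
            report.de[name] = anova_de(G, labels, k_top=k_top)
    if outdir is not None:
        report.write(outdir)
    return report
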