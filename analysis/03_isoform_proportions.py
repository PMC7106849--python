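"""Within-gene isoform proportions and cross-platform proportion
differences, including the qPCR comparative-Ct route.

For each platform view the raw isoform matrix is converted to proportions;
the pairwise proportion-difference statistic d is computed per sample.  The
Ct tables of four genes are converted to proportions through the
comparative-Ct method and compared against each platform's proportions for
the same genes, with a rank-sum test on the per-sample d values.

Reads results/study, writes results/proportions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from isopanel import (
    ProportionTable,
    ct_to_proportions,
    io,
    isoform_proportions,
    proportion_difference_per_sample,
    rank_sum_compare,
)

STUDY = Path("results/study")
OUT = Path("results/proportions")
PLATFORMS = ("seq", "array", "probe")


def ct_proportion_table(ct: pd.DataFrame) -> ProportionTable:
    """Comparative-Ct proportions, gene by gene and sample by sample."""
    records = []
    for (gene, sample), sub in ct.groupby(["gene_id", "sample_id"]):
        p = ct_to_proportions(sub["ct"].to_numpy())
        records += [
            (gene, iso, sample, v) for iso, v in zip(sub["isoform_id"], p)
        ]
    return ProportionTable(
        pd.DataFrame(records, columns=["gene_id", "isoform_id", "sample_id", "proportion"])
    )


def main() -> None:
    ann = io.read_annotation(STUDY / "annotation.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    tables = {}
    for name in PLATFORMS:
        M = io.read_expression_matrix(STUDY / f"{name}_isoform.tsv")
        tables[name] = isoform_proportions(M, ann)
        io.write_proportions(tables[name], OUT / f"{name}_proportions.tsv")

    rows = []
    for i, a in enumerate(PLATFORMS):
        for b in PLATFORMS[i + 1:]:
            d = proportion_difference_per_sample(tables[a], tables[b])
            rows += [(a, b, s, v) for s, v in d.items()]
            print(f"{a} vs {b}: median proportion difference d = {d.median():.4f}")
    pd.DataFrame(rows, columns=["platform_a", "platform_b", "sample_id", "d"]).to_csv(
        OUT / "pairwise_d.tsv", sep="\t", index=False
    )

    ct = io.read_ct_table(STUDY / "ct.tsv").dropna(subset=["ct"])
    qpcr = ct_proportion_table(ct)
    qpcr_genes = set(qpcr.data["gene_id"])
    d_vs_qpcr = {}
    for name in PLATFORMS:
        restricted = ProportionTable(
            tables[name].data[tables[name].data["gene_id"].isin(qpcr_genes)].reset_index(drop=True)
        )
        d_vs_qpcr[name] = proportion_difference_per_sample(qpcr, restricted)
        print(f"qPCR vs {name}: median d = {d_vs_qpcr[name].median():.4f}")
    for a, b in (("probe", "seq"), ("probe", "array")):
        p = rank_sum_compare(d_vs_qpcr[a].to_numpy(), d_vs_qpcr[b].to_numpy())
        print(f"rank-sum test, qPCR disagreement {a} vs {b}: p = {p:.3g}")
    pd.DataFrame(
        [(n, s, v) for n, d in d_vs_qpcr.items() for s, v in d.items()],
        columns=["platform", "sample_id", "d"],
    ).to_csv(OUT / "qpcr_d.tsv", sep="\t", index=False)
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
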