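"""Differential expression across tissues on each platform view.

Runs the one-way ANOVA ranking of gene expression across the six tissue
groups for every platform and reports the top-10 lists and their overlap;
also summarises the breast-versus-rest fold-change tables.  Reads
results/study and results/concordance (runs 01 and 04 first); writes
results/de.
"""

from pathlib import Path

import pandas as pd

from isopanel import anova_de, fold_change_pairs, io, log_transform

STUDY = Path("results/study")
OUT = Path("results/de")
PLATFORMS = ("seq", "array", "probe")


def main() -> None:
    labels = io.read_labels(STUDY / "labels.tsv")
    OUT.mkdir(parents=True, exist_ok=True)
    tops = {}
    frames = []
    for name in PLATFORMS:
        G = log_transform(io.read_expression_matrix(STUDY / f"{name}_gene.tsv"))
        res = anova_de(G, labels, k_top=10)
        tops[name] = res.top
        frames.append(res.table.reset_index().assign(platform=name))
        fc = fold_change_pairs(G, labels, "breast")
        fc.to_csv(OUT / f"fold_changes_{name}.tsv", sep="\t", index=False)
        print(f"{name}: top-10 DE genes {', '.join(res.top)}")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "anova.tsv", sep="\t", index=False)

    common_all = set.intersection(*(set(t) for t in tops.values()))
    print(f"genes in every platform's top-10: {sorted(common_all) or 'none'}")
    for i, a in enumerate(PLATFORMS):
        for b in PLATFORMS[i + 1:]:
            shared = sorted(set(tops[a]) & set(tops[b]))
            print(f"top-10 overlap {a}/{b}: {len(shared)}")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
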