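"""Readers and writers for the interchange formats.

Canonical interchange is tab-separated text.  Expression matrices carry a
``# level=... transform=...`` comment header so level and transform survive
a round trip; probe definitions, annotations (two-column TSV or GTF
transcript records), proportion tables, Ct tables and tissue labels are
plain TSVs with fixed headers.  A simplified RCC-style CSV (CodeClass,
Name, Accession, Count; one file per sample) is accepted read-only for raw
probe counts.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd

from .panel import GeneModel, Probe
from .proportions import PROPORTION_COLUMNS, ProportionTable
from .quantify import ExpressionMatrix, ProbeCountMatrix

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_definitions",
    "write_probe_definitions",
    "read_annotation",
    "write_annotation",
    "read_probe_counts",
    "read_rcc_files",
    "write_probe_counts",
    "read_proportions",
    "write_proportions",
    "read_labels",
    "write_labels",
    "read_ct_table",
    "write_ct_table",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless round trips in practice


class ParseError(ValueError):
    pass


def write_expression_matrix(M: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# level={M.level} transform={M.transform}\n")
        M.values.rename_axis("feature_id").to_csv(
            fh, sep="\t", float_format=_FLOAT_FMT
        )


def read_expression_matrix(
    path: str | Path, level: str | None = None, transform: str | None = None
) -> ExpressionMatrix:
    """Read a feature-by-sample TSV; level/transform come from the comment
    header unless overridden by the arguments."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            meta = dict(
                kv.split("=", 1) for kv in first.lstrip("#").split() if "=" in kv
            )
            header_line = 1
        else:
            header_line = 0
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    df.index.name = None
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate feature id {dup!r}")
    non_numeric = df.columns[[df[c].dtype == object for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        line = df.index.get_loc(bad.index[0]) + header_line + 2
        raise ParseError(f"{path}: non-numeric value {bad.iloc[0]!r} at line {line}")
    return ExpressionMatrix(
        df.astype(float),
        level=level or meta.get("level", "gene"),
        transform=transform or meta.get("transform", "raw"),
    )


def write_probe_definitions(probes: list[Probe], path: str | Path) -> None:
    rows = [
        (p.probe_id, p.gene_id, ",".join(p.targets), p.probe_class) for p in probes
    ]
    pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "isoform_ids", "probe_class"]
    ).to_csv(path, sep="\t", index=False)


def read_probe_definitions(
    path: str | Path, annotation: dict[str, str] | None = None
) -> tuple[list[GeneModel], list[Probe]]:
    """Read a probe-definition TSV and group probes into gene models.

    Gene isoform sets are the union of the gene's probe targets, in
    first-seen order, optionally checked against an isoform -> gene
    annotation.  Returns (genes, probes); an empty file yields an empty
    panel with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["probe_id", "gene_id", "isoform_ids", "probe_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: no probes defined; empty panel")
        return [], []
    probes: list[Probe] = []
    iso_by_gene: dict[str, list[str]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        targets = tuple(t for t in row.isoform_ids.split(",") if t)
        if row.probe_class != "spike_in" and not targets:
            raise ParseError(
                f"{path}:{lineno}: probe {row.probe_id!r} has a malformed or "
                f"empty isoform list {row.isoform_ids!r}"
            )
        try:
            probe = Probe(row.probe_id, row.gene_id, targets, row.probe_class)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        probes.append(probe)
        if probe.probe_class == "spike_in":
            continue
        bucket = iso_by_gene.setdefault(probe.gene_id, [])
        for iso in targets:
            if annotation is not None and annotation.get(iso) != probe.gene_id:
                raise ParseError(
                    f"{path}:{lineno}: isoform {iso!r} not annotated to gene "
                    f"{probe.gene_id!r}"
                )
            if iso not in bucket:
                bucket.append(iso)
    genes = [GeneModel(gid, tuple(isos)) for gid, isos in iso_by_gene.items()]
    return genes, probes


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read an isoform -> gene map from a two-column TSV (isoform_id,
    gene_id) or from GTF transcript records (only the transcript_id and
    gene_id attributes are read; coordinates are ignored)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 9:  # GTF record
                attrs = dict(_GTF_ATTR.findall(fields[8]))
                if fields[2] != "transcript":
                    continue
                if "transcript_id" not in attrs or "gene_id" not in attrs:
                    raise ParseError(
                        f"{path}:{lineno}: transcript record without "
                        "transcript_id/gene_id attributes"
                    )
                mapping[attrs["transcript_id"]] = attrs["gene_id"]
            elif len(fields) == 2:
                if fields[0] == "isoform_id":  # optional header
                    continue
                mapping[fields[0]] = fields[1]
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 2-column TSV or GTF record"
                )
    return mapping


def write_annotation(annotation: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(annotation.items()), columns=["isoform_id", "gene_id"]
    ).to_csv(path, sep="\t", index=False)


def write_probe_counts(counts: ProbeCountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# normalized={str(counts.normalized).lower()}\n")
        counts.counts.rename_axis("probe_id").to_csv(
            fh, sep="\t", float_format=_FLOAT_FMT
        )


def read_probe_counts(path: str | Path) -> ProbeCountMatrix:
    with open(path) as fh:
        first = fh.readline()
    normalized = first.startswith("#") and "normalized=true" in first
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = None
    return ProbeCountMatrix(df.astype(float), normalized=normalized)


def read_rcc_files(paths: dict[str, str | Path]) -> tuple[ProbeCountMatrix, pd.DataFrame]:
    """Read simplified RCC-style CSVs, one per sample.

    ``paths`` maps sample_id -> file.  Each file has columns CodeClass,
    Name, Accession, Count; Name is the probe id.  Returns the raw count
    matrix plus the probe metadata table (CodeClass/Accession) from the
    first file.
    """
    columns = {}
    meta = None
    for sample, p in paths.items():
        df = pd.read_csv(p)
        required = ["CodeClass", "Name", "Accession", "Count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"{p}: missing RCC columns {missing}")
        df = df.set_index("Name")
        columns[sample] = df["Count"].astype(float)
        if meta is None:
            meta = df[["CodeClass", "Accession"]]
    counts = pd.DataFrame(columns)
    return ProbeCountMatrix(counts, normalized=False), meta


def write_proportions(P: ProportionTable, path: str | Path) -> None:
    P.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_proportions(path: str | Path) -> ProportionTable:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in PROPORTION_COLUMNS[:3]})
    missing = [c for c in PROPORTION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["proportion"] = df["proportion"].astype(float)
    return ProportionTable(df[PROPORTION_COLUMNS])


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename_axis("sample_id").rename("tissue").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "tissue"]:
        raise ParseError(f"{path}: expected columns sample_id, tissue")
    return df.set_index("sample_id")["tissue"]


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "isoform_id": str, "sample_id": str})
    required = ["gene_id", "isoform_id", "sample_id", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df
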