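"""Multi-isoform gene panels, probe designs and identifiability diagnostics.

A capture panel measures a gene's isoforms through probes, each of which
hybridises to a sequence region shared by one or more isoforms of the gene.
The design is summarised by a 0/1 probe-by-isoform incidence matrix ``A``:
``A[j, i] = 1`` iff probe ``j`` targets isoform ``i``.  Whether the isoform
expressions can be recovered from probe intensities is a question about the
column rank of ``A``: the design is *identifiable* when rank(A) equals the
number of isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "GeneModel",
    "Probe",
    "IncidenceMatrix",
    "IdentifiabilityReport",
    "PROBE_CLASSES",
    "AnnotationMismatchError",
    "DesignError",
    "build_incidence_matrix",
    "check_identifiability",
    "design_max_probe_panel",
    "exact_rank",
]

PROBE_CLASSES = ("endogenous", "housekeeping", "spike_in")


class AnnotationMismatchError(ValueError):
    """A probe references an isoform that does not belong to its gene."""


class DesignError(ValueError):
    """A probe design request that does not apply to the gene."""


@dataclass(frozen=True)
class GeneModel:
    """A gene and its ordered isoform (transcript) identifiers."""

    gene_id: str
    isoform_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "isoform_ids", tuple(self.isoform_ids))
        if len(self.isoform_ids) < 1:
            raise ValueError(f"gene {self.gene_id!r} has no isoforms")
        if len(set(self.isoform_ids)) != len(self.isoform_ids):
            raise ValueError(f"gene {self.gene_id!r} has duplicate isoform ids")

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_ids)


@dataclass(frozen=True)
class Probe:
    """A capture probe targeting a subset of one gene's isoforms.

    ``targets`` must be non-empty for endogenous probes; spike-in control
    probes carry no biological target.
    """

    probe_id: str
    gene_id: str
    targets: tuple[str, ...]
    probe_class: str = "endogenous"

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(
                f"probe {self.probe_id!r}: unknown probe_class {self.probe_class!r}; "
                f"expected one of {PROBE_CLASSES}"
            )
        if self.probe_class != "spike_in" and not self.targets:
            raise ValueError(f"probe {self.probe_id!r} has an empty target set")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"probe {self.probe_id!r} lists a target twice")


@dataclass
class IncidenceMatrix:
    """The 0/1 probe-by-isoform matrix A for one gene.

    Rows follow the input probe order, columns the gene's isoform order.
    """

    A: np.ndarray
    probe_ids: list[str]
    isoform_ids: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=int)
        if self.A.ndim != 2:
            raise ValueError("A must be two-dimensional")
        if self.A.shape != (len(self.probe_ids), len(self.isoform_ids)):
            raise ValueError("A shape does not match probe/isoform id lists")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A entries must be 0 or 1")
        if self.A.shape[0] >= 1 and (self.A.sum(axis=1) == 0).any():
            raise ValueError("A contains an all-zero row (probe with no target)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape


@dataclass
class IdentifiabilityReport:
    """Rank diagnosis of a probe design.

    ``indistinguishable_groups`` partitions the isoforms into groups whose
    columns of A are identical — only the expression *sum* within such a
    group is constrained by the data.  ``partially_identifiable`` flags rank
    deficiency that duplicate columns alone do not explain.
    ``untargeted`` lists isoforms no probe covers at all; their expression is
    not estimable (rather than zero).
    """

    rank: int
    identifiable: bool
    indistinguishable_groups: list[tuple[str, ...]]
    partially_identifiable: bool = False
    untargeted: tuple[str, ...] = field(default_factory=tuple)


def build_incidence_matrix(gene: GeneModel, probes: list[Probe]) -> IncidenceMatrix:
    """Build the 0/1 incidence matrix of ``probes`` over ``gene``'s isoforms.

    Raises
    ------
    AnnotationMismatchError
        If a probe targets an isoform absent from the gene, or belongs to a
        different gene.
    """
    if not probes:
        raise ValueError(f"gene {gene.gene_id!r}: no probes given")
    iso_index = {iso: i for i, iso in enumerate(gene.isoform_ids)}
    A = np.zeros((len(probes), gene.n_isoforms), dtype=int)
    for j, probe in enumerate(probes):
        if probe.gene_id != gene.gene_id:
            raise AnnotationMismatchError(
                f"probe {probe.probe_id!r} belongs to gene {probe.gene_id!r}, "
                f"not {gene.gene_id!r}"
            )
        for iso in probe.targets:
            if iso not in iso_index:
                raise AnnotationMismatchError(
                    f"probe {probe.probe_id!r} targets isoform {iso!r} "
                    f"which is not annotated to gene {gene.gene_id!r}"
                )
            A[j, iso_index[iso]] = 1
    return IncidenceMatrix(A, [p.probe_id for p in probes], list(gene.isoform_ids))


def exact_rank(A: np.ndarray) -> int:
    """Rank of an integer matrix by exact fraction-free Gaussian elimination.

    Works over the rationals, so small 0/1 matrices never suffer
    floating-point rank ambiguity.
    """
    M = [[Fraction(int(v)) for v in row] for row in np.asarray(A)]
    n_rows = len(M)
    n_cols = len(M[0]) if n_rows else 0
    rank = 0
    row = 0
    for col in range(n_cols):
        pivot = next((r for r in range(row, n_rows) if M[r][col] != 0), None)
        if pivot is None:
            continue
        M[row], M[pivot] = M[pivot], M[row]
        pv = M[row][col]
        for r in range(row + 1, n_rows):
            if M[r][col] != 0:
                factor = M[r][col] / pv
                M[r] = [a - factor * b for a, b in zip(M[r], M[row])]
        rank += 1
        row += 1
        if row == n_rows:
            break
    return rank


def check_identifiability(im: IncidenceMatrix) -> IdentifiabilityReport:
    """Diagnose which isoforms a probe design can distinguish.

    The design is identifiable iff rank(A) equals the number of isoforms.
    Isoforms with identical columns form indistinguishable groups; residual
    rank deficiency (linear dependence among distinct columns) is flagged as
    partial identifiability.
    """
    rank = exact_rank(im.A)
    n = len(im.isoform_ids)

    untargeted = tuple(
        iso for i, iso in enumerate(im.isoform_ids) if not im.A[:, i].any()
    )

    # group isoforms by identical columns, preserving first-seen order
    seen: dict[bytes, list[str]] = {}
    for i, iso in enumerate(im.isoform_ids):
        seen.setdefault(im.A[:, i].tobytes(), []).append(iso)
    groups = [tuple(v) for v in seen.values()]

    n_distinct = len(groups)
    return IdentifiabilityReport(
        rank=rank,
        identifiable=(rank == n),
        indistinguishable_groups=groups,
        partially_identifiable=(rank < n_distinct),
        untargeted=untargeted,
    )


def design_max_probe_panel(gene: GeneModel) -> list[Probe]:
    """Design the max-probe layout: one gene-level probe covering every
    isoform plus one singleton probe per isoform except the last.

    The last isoform's expression is recovered as the max probe's signal
    minus the singleton signals, so n probes suffice for n isoforms and the
    incidence matrix has full column rank.
    """
    if gene.n_isoforms < 2:
        raise DesignError(
            f"gene {gene.gene_id!r} has a single isoform; one probe measures "
            "it directly and no max-probe design is needed"
        )
    probes = [
        Probe(f"{gene.gene_id}_max", gene.gene_id, gene.isoform_ids, "endogenous")
    ]
    for k, iso in enumerate(gene.isoform_ids[:-1], start=1):
        probes.append(Probe(f"{gene.gene_id}_p{k}", gene.gene_id, (iso,), "endogenous"))
    return probes
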