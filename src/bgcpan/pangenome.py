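"""Per-genus pan-genome statistics on a gene presence/absence matrix.

Given a Roary-style matrix and genome metadata, this module computes
gene-family prevalence within one genus, extracts the conserved-gene list
(families present in at least half the genus's genomes, by default), and
bins families into the usual pan-genome categories (core / soft core /
shell / cloud).  It also provides a greedy protein clustering so fully
synthetic datasets can be run end to end without an external pan-genome
tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cluster_compare import AlignmentParams, protein_identity
from .formats import GenomeMetadata, PresenceAbsenceMatrix

__all__ = [
    "PrevalenceTable",
    "PangenomeBins",
    "ClusteringParams",
    "compute_prevalence",
    "conserved_families",
    "classify_bins",
    "cluster_proteins",
]


@dataclass
class PrevalenceTable:
    """Fraction of one genus's genomes carrying each gene family.

    Families absent from every genome of the genus are omitted, so all
    stored prevalences are in (0, 1].
    """

    genus: str
    n_genomes: int
    prevalence: dict[str, float]


@dataclass
class PangenomeBins:
    """Families partitioned by prevalence into core/soft-core/shell/cloud."""

    core: list[str]
    soft_core: list[str]
    shell: list[str]
    cloud: list[str]
    bounds: tuple[float, float, float]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "core": len(self.core),
            "soft_core": len(self.soft_core),
            "shell": len(self.shell),
            "cloud": len(self.cloud),
        }

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ClusteringParams:
    """Thresholds and scoring for greedy protein family clustering."""

    min_identity: float = 0.7
    min_coverage: float = 0.8
    scoring: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")


def compute_prevalence(
    matrix: PresenceAbsenceMatrix,
    metadata: list[GenomeMetadata],
    genus: str,
) -> PrevalenceTable:
    """Family prevalence over exactly the genomes of one genus."""
    meta_ids = {m.genome_id for m in metadata}
    unknown = [g for g in matrix.genome_ids if g not in meta_ids]
    if unknown:
        raise ValueError(f"matrix genomes missing from metadata: {unknown}")
    genus_genomes = [
        m.genome_id for m in metadata if m.genus == genus and m.genome_id in set(matrix.genome_ids)
    ]
    if not genus_genomes:
        raise ValueError(f"genus {genus!r} has no genomes in the matrix")
    n = len(genus_genomes)
    prevalence = {}
    for fam in matrix.family_ids:
        k = sum(1 for g in genus_genomes if matrix.tags(fam, g))
        if k:
            prevalence[fam] = k / n
    return PrevalenceTable(genus=genus, n_genomes=n, prevalence=prevalence)


def conserved_families(
    prev: PrevalenceTable, min_prevalence: float = 0.5
) -> set[str]:
    """Families present in at least ``min_prevalence`` of the genus genomes.

    The comparison is >= on exact fractions: a family in exactly half the
    genomes qualifies at the default threshold.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    return {f for f, p in prev.prevalence.items() if p >= min_prevalence}


def classify_bins(
    prev: PrevalenceTable,
    bounds: tuple[float, float, float] = (0.99, 0.95, 0.15),
) -> PangenomeBins:
    """Partition families by prevalence: core >= 99%, soft core >= 95%,
    shell >= 15%, cloud below (Roary's reporting conventions)."""
    core_b, soft_b, shell_b = bounds
    if not core_b > soft_b > shell_b > 0:
        raise ValueError("bounds must be strictly decreasing positive fractions")
    bins = PangenomeBins([], [], [], [], bounds)
    for fam in sorted(prev.prevalence):
        p = prev.prevalence[fam]
        if p >= core_b:
            bins.core.append(fam)
        elif p >= soft_b:
            bins.soft_core.append(fam)
        elif p >= shell_b:
            bins.shell.append(fam)
        else:
            bins.cloud.append(fam)
    return bins


def cluster_proteins(
    proteins: list[tuple[str, str, str]],
    params: ClusteringParams = ClusteringParams(),
) -> PresenceAbsenceMatrix:
    """Greedy incremental centroid clustering of proteins into families.

    Input triples are (genome_id, locus_tag, translation).  Proteins are
    processed longest-first (ties by genome then tag, so results do not
    depend on input order); each joins the first existing centroid it
    matches at ``min_identity`` global identity with coverage at least
    ``min_coverage`` of *both* sequences, else founds a new family.  Family
    ids are assigned in founding order ("fam00001", ...).
    """
    for g, t, seq in proteins:
        if not seq:
            raise ValueError(f"empty translation for {g}:{t}")
    ordered = sorted(proteins, key=lambda p: (-len(p[2]), p[0], p[1]))

    centroids: list[tuple[str, str]] = []  # (family_id, sequence)
    assignment: dict[tuple[str, str], str] = {}
    for genome_id, tag, seq in ordered:
        placed = None
        for fam_id, centroid_seq in centroids:
            identity, cov_short = protein_identity(seq, centroid_seq, params.scoring)
            # coverage must hold for BOTH sequences, not just the shorter
            aligned_both = cov_short * min(len(seq), len(centroid_seq))
            cov_a = aligned_both / len(seq)
            cov_b = aligned_both / len(centroid_seq)
            if (
                identity >= params.min_identity
                and cov_a >= params.min_coverage
                and cov_b >= params.min_coverage
            ):
                placed = fam_id
                break
        if placed is None:
            placed = f"fam{len(centroids) + 1:05d}"
            centroids.append((placed, seq))
        assignment[(genome_id, tag)] = placed

    genome_ids = sorted({g for g, _, _ in proteins})
    family_ids = [fid for fid, _ in centroids]
    cells: dict[tuple[str, str], list[str]] = {}
    for genome_id, tag, _ in sorted(proteins, key=lambda p: (p[0], p[1])):
        fam = assignment[(genome_id, tag)]
        cells.setdefault((fam, genome_id), []).append(tag)
    return PresenceAbsenceMatrix(family_ids, genome_ids, cells)
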