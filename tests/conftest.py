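"""Shared fixtures: tiny hand-built matrices and regions, plus a seeded
default simulation reused by the slower end-to-end tests."""

from __future__ import annotations

import pytest

from bgcpan import (
    BgcRegion,
    CdsFeature,
    GenomeMetadata,
    PresenceAbsenceMatrix,
    SimParams,
    simulate_dataset,
)


def make_region(
    genome_id: str,
    tags_translations: list[tuple[str, str]],
    contig: str | None = None,
    gene_len: int = 300,
    gap: int = 50,
    product_classes: list[str] | None = None,
) -> BgcRegion:
    """A synthetic region with evenly laid-out CDS (translations supplied)."""
    contig = contig or f"{genome_id}_c1"
    cds = []
    pos = 1
    for tag, translation in tags_translations:
        cds.append(
            CdsFeature(
                locus_tag=tag,
                contig_id=contig,
                start=pos,
                end=pos + gene_len - 1,
                strand="+",
                translation=translation,
            )
        )
        pos += gene_len + gap
    end = pos - gap - 1 if cds else 1
    return BgcRegion(
        region_id=f"{genome_id}|{contig}|1-{end}",
        genome_id=genome_id,
        contig_id=contig,
        start=1,
        end=end,
        product_classes=product_classes or ["other"],
        cds=cds,
    )


def make_matrix(
    cells: dict[tuple[str, str], list[str]],
    family_ids: list[str] | None = None,
    genome_ids: list[str] | None = None,
) -> PresenceAbsenceMatrix:
    fams = family_ids or sorted({f for f, _ in cells})
    genomes = genome_ids or sorted({g for _, g in cells})
    return PresenceAbsenceMatrix(fams, genomes, dict(cells))


@pytest.fixture
def small_metadata() -> list[GenomeMetadata]:
    return [
        GenomeMetadata("g1", "Alpha"),
        GenomeMetadata("g2", "Alpha"),
        GenomeMetadata("g3", "Alpha"),
        GenomeMetadata("g4", "Alpha"),
        GenomeMetadata("h1", "Beta"),
        GenomeMetadata("h2", "Beta"),
    ]


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions, simulated once per session."""
    return simulate_dataset(SimParams(seed=11))
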