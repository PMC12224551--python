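"""Conservation calling for biosynthetic gene clusters.

The core inference: conserved gene families (from the per-genus pan-genome)
are mapped into annotated BGC regions; regions sharing conserved gene
content are grouped into genus-level BGC families; a family is called
conserved in its genus when it occurs in at least half the genus's genomes
AND carries at least two distinct conserved gene families.  Conserved
families are then linked across genera through protein-level mutual-best
hits between representative regions, and a group is called phylum-conserved
when it spans enough genera (seven of eleven by default).  Finally, genomes
from genera too sparsely sequenced for pan-genome analysis can be screened
for presence/absence of each conserved cluster profile.

The within- and across-genus grouping procedures are explicit, parameterized
graph constructions (shared-content single linkage); published analyses of
this kind typically group clusters by similarity scores plus manual
inspection, so the rules here are deliberately simple and fully declared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .cluster_compare import AlignmentParams, DEFAULT_PARAMS, best_bidirectional_hits, protein_identity
from .formats import BgcRegion, CdsFeature, PresenceAbsenceMatrix, TableFixture

log = logging.getLogger("bgcpan")

__all__ = [
    "RegionFamilyContent",
    "BgcFamily",
    "GenusConservationCall",
    "PhylumGroup",
    "BgcProfile",
    "ScreenResult",
    "map_families_to_regions",
    "build_bgc_families",
    "call_genus_conservation",
    "link_across_genera",
    "call_phylum_conservation",
    "screen_genome",
    "screen_table",
    "phylum_groups_from_fixture",
    "screen_results_from_fixture",
    "profiles_from_groups",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RegionFamilyContent:
    """Gene families mapped onto one region's CDS."""

    region_id: str
    families_all: set[str]
    families_conserved: set[str]
    unmapped_tags: list[str]

    def __post_init__(self) -> None:
        if not self.families_conserved <= self.families_all:
            raise ValueError("families_conserved must be a subset of families_all")


@dataclass
class BgcFamily:
    """A genus-level group of regions sharing conserved gene content."""

    family_id: str
    genus: str
    member_regions: dict[str, list[str]]  # genome_id -> region_ids
    defining_families: set[str]

    @property
    def n_genomes_with(self) -> int:
        return len(self.member_regions)

    @property
    def region_ids(self) -> list[str]:
        return sorted(r for rs in self.member_regions.values() for r in rs)


@dataclass
class GenusConservationCall:
    bgc_family: BgcFamily
    n_genomes_total: int
    genome_fraction: float
    n_conserved_genes: int
    is_conserved: bool


@dataclass
class PhylumGroup:
    """Cross-genus linkage of genus-level BGC families."""

    group_id: str
    members: list[tuple[str, BgcFamily]]  # (genus, family)
    label: str | None = None

    @property
    def genera_present(self) -> set[str]:
        return {genus for genus, _ in self.members}


@dataclass
class BgcProfile:
    """Reference gene set used to screen genomes for one conserved cluster."""

    profile_id: str
    reference_genes: list[tuple[str, str]]  # (gene_label, translation)
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.reference_genes) < 2:
            raise ValueError("a profile needs at least 2 reference genes")
        if any(not t for _, t in self.reference_genes):
            raise ValueError("reference translations must be non-empty")


@dataclass
class ScreenResult:
    """Presence/absence calls of each profile in one screened genome."""

    genome_id: str
    calls: dict[str, bool]  # profile_id -> present
    evidence: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)

    @property
    def per_genome_total(self) -> int:
        return sum(self.calls.values())


# ---------------------------------------------------------------------------
# Mapping conserved families into regions
# ---------------------------------------------------------------------------


def _reciprocal_overlap(
    a: tuple[str, int, int], b: tuple[str, int, int], min_frac: float = 0.5
) -> bool:
    """Reciprocal coordinate overlap of two 1-based inclusive intervals."""
    if a[0] != b[0]:
        return False
    ov = min(a[2], b[2]) - max(a[1], b[1]) + 1
    if ov <= 0:
        return False
    len_a = a[2] - a[1] + 1
    len_b = b[2] - b[1] + 1
    return ov / len_a >= min_frac and ov / len_b >= min_frac


def map_families_to_regions(
    matrix: PresenceAbsenceMatrix,
    regions: Sequence[BgcRegion],
    conserved: set[str] | None = None,
    fallback_coordinates: Mapping[tuple[str, str], tuple[str, int, int]] | None = None,
    min_overlap: float = 0.5,
) -> list[RegionFamilyContent]:
    """Assign each region CDS to a gene family of its genome, by locus tag.

    Primary mapping is exact locus_tag equality within the same genome.
    When ``fallback_coordinates`` is supplied (a sidecar mapping
    (genome_id, matrix locus_tag) -> (contig, start, end)), a CDS whose tag
    matches nothing is assigned to the family of any matrix tag overlapping
    it reciprocally by at least ``min_overlap`` — this covers annotation
    runs whose locus tags are disjoint from the pan-genome's.
    """
    conserved = conserved or set()
    matrix_genomes = set(matrix.genome_ids)
    out: list[RegionFamilyContent] = []
    for region in regions:
        if region.genome_id not in matrix_genomes:
            raise ValueError(f"region {region.region_id} from unknown genome {region.genome_id}")
        idx = matrix.tag_index(region.genome_id)
        families: set[str] = set()
        unmapped: list[str] = []
        for cds in region.cds:
            fam = idx.get(cds.locus_tag)
            if fam is None and fallback_coordinates is not None:
                fam = _coordinate_fallback(
                    cds, region.genome_id, idx, fallback_coordinates, min_overlap
                )
            if fam is None:
                unmapped.append(cds.locus_tag)
            else:
                families.add(fam)
        if not families and region.cds:
            log.warning(
                "region %s: no CDS tag matched the matrix (disjoint tag universes?)",
                region.region_id,
            )
        out.append(
            RegionFamilyContent(
                region_id=region.region_id,
                families_all=families,
                families_conserved=families & conserved,
                unmapped_tags=unmapped,
            )
        )
    return out


def _coordinate_fallback(
    cds: CdsFeature,
    genome_id: str,
    tag_to_family: Mapping[str, str],
    coordinates: Mapping[tuple[str, str], tuple[str, int, int]],
    min_overlap: float,
) -> str | None:
    cds_iv = (cds.contig_id, cds.start, cds.end)
    hits = []
    for tag, fam in tag_to_family.items():
        coords = coordinates.get((genome_id, tag))
        if coords is not None and _reciprocal_overlap(cds_iv, coords, min_overlap):
            hits.append((tag, fam))
    if not hits:
        return None
    hits.sort()  # deterministic when several tags overlap
    return hits[0][1]


# ---------------------------------------------------------------------------
# Grouping regions into genus-level BGC families
# ---------------------------------------------------------------------------


def build_bgc_families(
    contents: Sequence[RegionFamilyContent],
    conserved: set[str],
    regions: Mapping[str, BgcRegion],
    genus: str,
    min_shared: int = 2,
) -> list[BgcFamily]:
    """Group regions sharing conserved gene content into BGC families.

    Graph construction: nodes are regions carrying at least ``min_shared``
    conserved families in total; an edge joins two regions sharing at least
    ``min_shared`` conserved families.  Each connected component (including
    singletons) is one BgcFamily; regions below ``min_shared`` form no
    family.  Family ids are assigned in order of smallest member region_id.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    eligible = [c for c in contents if len(c.families_conserved & conserved) >= min_shared]
    g = nx.Graph()
    for c in eligible:
        g.add_node(c.region_id)
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            shared = (a.families_conserved & b.families_conserved) & conserved
            if len(shared) >= min_shared:
                g.add_edge(a.region_id, b.region_id)

    by_id = {c.region_id: c for c in contents}
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(g)), key=lambda c: c[0]
    )
    families: list[BgcFamily] = []
    for k, comp in enumerate(components, start=1):
        member_regions: dict[str, list[str]] = {}
        defining: set[str] = set()
        for rid in comp:
            genome = regions[rid].genome_id
            member_regions.setdefault(genome, []).append(rid)
            defining |= by_id[rid].families_conserved & conserved
        for rs in member_regions.values():
            rs.sort()
        families.append(
            BgcFamily(
                family_id=f"{genus}:bgcfam{k:03d}",
                genus=genus,
                member_regions=member_regions,
                defining_families=defining,
            )
        )
    return families


def call_genus_conservation(
    families: Sequence[BgcFamily],
    n_genomes_total: int,
    min_genome_frac: float = 0.5,
    min_conserved_genes: int = 2,
) -> list[GenusConservationCall]:
    """Call each BGC family conserved or not within its genus.

    Conserved means present in at least ``min_genome_frac`` of the genus's
    genomes AND defined by at least ``min_conserved_genes`` distinct
    conserved gene families; both comparisons are >= on exact fractions.
    """
    if n_genomes_total < 1:
        raise ValueError("n_genomes_total must be >= 1")
    calls = []
    for fam in families:
        frac = fam.n_genomes_with / n_genomes_total
        n_genes = len(fam.defining_families)
        calls.append(
            GenusConservationCall(
                bgc_family=fam,
                n_genomes_total=n_genomes_total,
                genome_fraction=frac,
                n_conserved_genes=n_genes,
                is_conserved=frac >= min_genome_frac and n_genes >= min_conserved_genes,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Cross-genus aggregation
# ---------------------------------------------------------------------------


def representative_region(
    family: BgcFamily,
    regions: Mapping[str, BgcRegion],
    contents: Mapping[str, RegionFamilyContent],
) -> BgcRegion:
    """The member region from the genome with the most conserved families
    mapped (ties broken by lexicographic genome_id, then region_id)."""
    best: tuple[int, str, str] | None = None
    for genome_id in sorted(family.member_regions):
        for rid in family.member_regions[genome_id]:
            n = len(contents[rid].families_conserved)
            key = (-n, genome_id, rid)
            if best is None or key < best:
                best = key
    assert best is not None
    return regions[best[2]]


def link_across_genera(
    families: Sequence[BgcFamily],
    regions: Mapping[str, BgcRegion],
    contents: Mapping[str, RegionFamilyContent],
    min_shared_genes: int = 2,
    min_identity: float = 0.4,
    min_coverage: float = 0.6,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[PhylumGroup]:
    """Link genus-level conserved families across genera into phylum groups.

    Each family contributes one representative region; two families are
    linked when their representatives share at least ``min_shared_genes``
    mutual-best protein pairs at the identity/coverage cutoffs.  Connected
    components become PhylumGroups; a group's label is the first
    known-cluster annotation seen among member representatives, if any.
    """
    reps = {f.family_id: representative_region(f, regions, contents) for f in families}
    g = nx.Graph()
    for f in families:
        g.add_node(f.family_id)
    fams = sorted(families, key=lambda f: f.family_id)
    for i, fa in enumerate(fams):
        for fb in fams[i + 1 :]:
            hits = best_bidirectional_hits(
                reps[fa.family_id], reps[fb.family_id], min_identity, min_coverage, params
            )
            if len(hits) >= min_shared_genes:
                g.add_edge(fa.family_id, fb.family_id)

    by_id = {f.family_id: f for f in families}
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(g)), key=lambda c: c[0]
    )
    groups = []
    for k, comp in enumerate(components, start=1):
        members = [(by_id[fid].genus, by_id[fid]) for fid in comp]
        label = None
        for fid in comp:
            kc = reps[fid].known_cluster
            if kc is not None:
                label = kc[0]
                break
        groups.append(PhylumGroup(group_id=f"group{k:03d}", members=members, label=label))
    return groups


def call_phylum_conservation(
    groups: Sequence[PhylumGroup],
    n_genera_total: int,
    min_genera: int = 7,
) -> list[tuple[PhylumGroup, bool]]:
    """A group is phylum-conserved when it spans at least ``min_genera`` genera."""
    if min_genera < 1:
        raise ValueError("min_genera must be >= 1")
    if n_genera_total < 1:
        raise ValueError("n_genera_total must be >= 1")
    return [(grp, len(grp.genera_present) >= min_genera) for grp in groups]


# ---------------------------------------------------------------------------
# Screening additional genomes
# ---------------------------------------------------------------------------


def screen_genome(
    profiles: Sequence[BgcProfile],
    regions: Sequence[BgcRegion],
    genome_id: str,
    min_matched_genes: int = 2,
    min_identity: float = 0.4,
    min_coverage: float = 0.6,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> ScreenResult:
    """Presence/absence of each cluster profile in one genome's regions.

    A profile is present when some *single* region contains at least
    ``min_matched_genes`` distinct CDS that are mutual-best partners of
    distinct profile reference genes at the cutoffs — matches spread over
    several regions do not count, since a BGC is by definition colocated.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    calls: dict[str, bool] = {}
    evidence: dict[str, list[tuple[str, str, float]]] = {}
    for profile in profiles:
        best_ev: list[tuple[str, str, float]] = []
        for region in regions:
            ev = _profile_region_matches(profile, region, min_identity, min_coverage, params)
            if len(ev) > len(best_ev):
                best_ev = ev
        calls[profile.profile_id] = len(best_ev) >= min_matched_genes
        evidence[profile.profile_id] = best_ev if calls[profile.profile_id] else []
    return ScreenResult(genome_id=genome_id, calls=calls, evidence=evidence)


def _profile_region_matches(
    profile: BgcProfile,
    region: BgcRegion,
    min_identity: float,
    min_coverage: float,
    params: AlignmentParams,
) -> list[tuple[str, str, float]]:
    """Mutual-best pairs between profile reference genes and region CDS."""
    cds = [c for c in region.cds if c.translation]
    if not cds:
        return []
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for label, ref_seq in profile.reference_genes:
        for c in cds:
            scores[(label, c.locus_tag)] = protein_identity(ref_seq, c.translation, params)
    ref_labels = sorted(label for label, _ in profile.reference_genes)
    cds_tags = sorted(c.locus_tag for c in cds)
    matches = []
    for label in ref_labels:
        best_cds = min(cds_tags, key=lambda t: (-scores[(label, t)][0], t))
        back = min(ref_labels, key=lambda l: (-scores[(l, best_cds)][0], l))
        if back != label:
            continue
        identity, coverage = scores[(label, best_cds)]
        if identity >= min_identity and coverage >= min_coverage:
            matches.append((label, best_cds, identity))
    return matches


def screen_table(results: Sequence[ScreenResult]) -> list[dict[str, object]]:
    """Tabulate screen results: one row per genome plus a recomputed totals row.

    Per-genome totals are "k/P" (P = number of profiles) and the final
    "total" row carries per-profile counts "m/N" (N = number of genomes).
    All totals are recomputed from the +/- grid, never copied in.
    """
    if not results:
        raise ValueError("no screen results")
    profile_ids = list(results[0].calls.keys())
    for r in results:
        if list(r.calls.keys()) != profile_ids:
            raise ValueError(
                f"inconsistent profile sets: {list(r.calls.keys())} vs {profile_ids}"
            )
    rows: list[dict[str, object]] = []
    for r in results:
        row: dict[str, object] = {"genome": r.genome_id}
        for p in profile_ids:
            row[p] = "+" if r.calls[p] else "-"
        row["total"] = f"{r.per_genome_total}/{len(profile_ids)}"
        rows.append(row)
    totals: dict[str, object] = {"genome": "total"}
    for p in profile_ids:
        m = sum(1 for r in results if r.calls[p])
        totals[p] = f"{m}/{len(results)}"
    totals["total"] = ""
    rows.append(totals)
    return rows


# ---------------------------------------------------------------------------
# Fixture adapters (replay of published presence/absence tables)
# ---------------------------------------------------------------------------


def phylum_groups_from_fixture(fixture: TableFixture) -> list[PhylumGroup]:
    """Encode a BGC x genus presence table as PhylumGroups.

    Each row becomes one group whose members are placeholder genus-level
    families for exactly the genera marked present.
    """
    groups = []
    for k, bgc in enumerate(fixture.row_labels, start=1):
        members = []
        for genus in fixture.col_labels:
            if fixture.present(bgc, genus):
                members.append(
                    (
                        genus,
                        BgcFamily(
                            family_id=f"{genus}:{bgc}",
                            genus=genus,
                            member_regions={},
                            defining_families=set(),
                        ),
                    )
                )
        groups.append(PhylumGroup(group_id=f"group{k:03d}", members=members, label=bgc))
    return groups


def screen_results_from_fixture(fixture: TableFixture) -> list[ScreenResult]:
    """Encode a strain x BGC presence table as ScreenResults for tabulation."""
    return [
        ScreenResult(
            genome_id=strain,
            calls={bgc: fixture.present(strain, bgc) for bgc in fixture.col_labels},
        )
        for strain in fixture.row_labels
    ]


def profiles_from_groups(
    groups: Sequence[PhylumGroup],
    regions: Mapping[str, BgcRegion],
    contents: Mapping[str, RegionFamilyContent],
    max_genes: int = 8,
) -> list[BgcProfile]:
    """Derive screening profiles from phylum groups' representative regions."""
    profiles = []
    for grp in groups:
        if not grp.members:
            continue
        genus, fam = min(grp.members, key=lambda m: m[1].family_id)
        rep = representative_region(fam, regions, contents)
        genes = [(c.locus_tag, c.translation) for c in rep.cds if c.translation]
        genes = genes[:max_genes]
        if len(genes) < 2:
            continue
        profiles.append(
            BgcProfile(
                profile_id=grp.label or grp.group_id,
                reference_genes=genes,
                source=grp.group_id,
            )
        )
    return profiles
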