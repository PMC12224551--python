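"""Conservation calling: family-to-region mapping (with coordinate
fallback), region grouping vs component oracles, the double conservation
rule, cross-genus linkage, and genome screening."""

from __future__ import annotations

import pytest

from bgcpan import (
    BgcFamily,
    BgcProfile,
    RegionFamilyContent,
    build_bgc_families,
    call_genus_conservation,
    call_phylum_conservation,
    link_across_genera,
    load_fixture,
    map_families_to_regions,
    phylum_groups_from_fixture,
    screen_genome,
    screen_results_from_fixture,
    screen_table,
)
from bgcpan.bgc_conservation import representative_region

from conftest import make_matrix, make_region
from oracles import connected_components, interval_overlap_pairs


class TestMapping:
    def test_exact_tag_mapping_with_unmapped_leftover(self):
        matrix = make_matrix({("f1", "g1"): ["A"], ("f2", "g1"): ["B"]})
        region = make_region("g1", [("A", "MK"), ("B", "MA"), ("C", "MC")])
        [content] = map_families_to_regions(matrix, [region])
        assert content.families_all == {"f1", "f2"}
        assert content.unmapped_tags == ["C"]

    def test_disjoint_tag_universes_all_unmapped(self, caplog):
        matrix = make_matrix({("f1", "g1"): ["X1"]})
        region = make_region("g1", [("A", "MK"), ("B", "MA")])
        with caplog.at_level("WARNING", logger="bgcpan"):
            [content] = map_families_to_regions(matrix, [region])
        assert content.families_all == set()
        assert content.unmapped_tags == ["A", "B"]
        assert any("disjoint" in r.message for r in caplog.records)

    def test_coordinate_fallback_recovers_families(self):
        matrix = make_matrix({("f1", "g1"): ["X1"], ("f2", "g1"): ["X2"]})
        region = make_region("g1", [("A", "MK"), ("B", "MA")], gene_len=300, gap=50)
        contig = region.contig_id
        # sidecar coordinates for the matrix's tags, overlapping the CDS
        coords = {
            ("g1", "X1"): (contig, 1, 300),
            ("g1", "X2"): (contig, 351, 650),
        }
        [content] = map_families_to_regions(
            matrix, [region], fallback_coordinates=coords
        )
        assert content.families_all == {"f1", "f2"}
        assert content.unmapped_tags == []
        # cross-check the overlap rule against brute force over all pairs
        cds_ivs = {c.locus_tag: (c.contig_id, c.start, c.end) for c in region.cds}
        tag_ivs = {t: coords[("g1", t)] for t in ["X1", "X2"]}
        assert interval_overlap_pairs(cds_ivs, tag_ivs) == {("A", "X1"), ("B", "X2")}

    def test_partial_overlap_below_half_not_mapped(self):
        matrix = make_matrix({("f1", "g1"): ["X1"]})
        region = make_region("g1", [("A", "MK")], gene_len=300)
        contig = region.contig_id
        coords = {("g1", "X1"): (contig, 250, 549)}  # 51/300 overlap
        [content] = map_families_to_regions(matrix, [region], fallback_coordinates=coords)
        assert content.families_all == set()
        assert interval_overlap_pairs(
            {"A": (contig, 1, 300)}, {"X1": coords[("g1", "X1")]}
        ) == set()

    def test_region_from_unknown_genome_rejected(self):
        matrix = make_matrix({("f1", "g1"): ["A"]})
        region = make_region("zz", [("A", "MK")])
        with pytest.raises(ValueError):
            map_families_to_regions(matrix, [region])


def _content(region_id, conserved, extra=()):
    fams = set(conserved) | set(extra)
    return RegionFamilyContent(region_id, fams, set(conserved), [])


def _regions_for(contents, genome_of):
    return {
        c.region_id: make_region(genome_of[c.region_id], [("t", "MK")])
        for c in contents
    }


class TestBuildFamilies:
    def test_two_regions_sharing_two_families_group(self):
        contents = [_content("r1", {"f1", "f2"}), _content("r2", {"f1", "f2"})]
        regions = {}
        for c, g in zip(contents, ["g1", "g2"]):
            r = make_region(g, [("t", "MK")])
            regions[c.region_id] = r
        fams = build_bgc_families(contents, {"f1", "f2"}, regions, "Alpha")
        assert len(fams) == 1
        assert fams[0].defining_families >= {"f1", "f2"}
        assert fams[0].n_genomes_with == 2

    def test_single_shared_family_insufficient(self):
        contents = [_content("r1", {"f1", "f3"}), _content("r2", {"f1", "f4"})]
        regions = {c.region_id: make_region(g, [("t", "MK")])
                   for c, g in zip(contents, ["g1", "g2"])}
        fams = build_bgc_families(contents, {"f1", "f3", "f4"}, regions, "Alpha")
        # each region has >= 2 conserved families so each forms a singleton
        assert len(fams) == 2
        assert all(f.n_genomes_with == 1 for f in fams)

    def test_region_below_min_shared_forms_no_family(self):
        contents = [_content("r1", {"f1"})]
        regions = {"r1": make_region("g1", [("t", "MK")])}
        assert build_bgc_families(contents, {"f1"}, regions, "Alpha") == []

    def test_chain_matches_component_oracle(self):
        contents = [
            _content("r1", {"f1", "f2"}),
            _content("r2", {"f1", "f2", "f3"}),
            _content("r3", {"f2", "f3"}),
            _content("r4", {"f8", "f9"}),
        ]
        conserved = {"f1", "f2", "f3", "f8", "f9"}
        regions = {c.region_id: make_region(f"g{i}", [("t", "MK")])
                   for i, c in enumerate(contents, 1)}
        fams = build_bgc_families(contents, conserved, regions, "Alpha")
        # oracle: set-merging components on the same edge rule
        nodes = [c.region_id for c in contents]
        edges = [
            (a.region_id, b.region_id)
            for i, a in enumerate(contents)
            for b in contents[i + 1 :]
            if len(a.families_conserved & b.families_conserved) >= 2
        ]
        expected = {frozenset(c) for c in connected_components(nodes, edges)}
        got = {frozenset(f.region_ids) for f in fams}
        assert got == expected
        assert {frozenset({"r1", "r2", "r3"}), frozenset({"r4"})} == got

    def test_family_ids_deterministic(self):
        contents = [_content("r2", {"f1", "f2"}), _content("r1", {"f1", "f2"})]
        regions = {c.region_id: make_region(g, [("t", "MK")])
                   for c, g in zip(contents, ["g2", "g1"])}
        fams1 = build_bgc_families(contents, {"f1", "f2"}, regions, "Alpha")
        fams2 = build_bgc_families(list(reversed(contents)), {"f1", "f2"}, regions, "Alpha")
        assert [f.family_id for f in fams1] == [f.family_id for f in fams2]


def _family(genus, n_genomes, n_genes):
    return BgcFamily(
        family_id=f"{genus}:x",
        genus=genus,
        member_regions={f"g{i}": [f"r{i}"] for i in range(n_genomes)},
        defining_families={f"f{i}" for i in range(n_genes)},
    )


class TestGenusConservationRule:
    @pytest.mark.parametrize("n_with,n_genes,expected", [
        (2, 2, True),   # exactly half with two conserved genes
        (2, 1, False),  # half but only one conserved gene
        (1, 5, False),  # many genes but only a quarter of genomes
        (3, 1, False),  # three quarters but one gene
        (4, 2, True),
    ])
    def test_double_rule_on_four_genomes(self, n_with, n_genes, expected):
        [call] = call_genus_conservation([_family("Alpha", n_with, n_genes)], 4)
        assert call.is_conserved is expected

    def test_five_of_eleven_does_not_reach_half(self):
        [call] = call_genus_conservation([_family("Alpha", 5, 3)], 11)
        assert call.is_conserved is False

    def test_adding_evidence_never_unconserves(self):
        base = _family("Alpha", 2, 2)
        [c0] = call_genus_conservation([base], 4)
        more_genomes = _family("Alpha", 3, 2)
        more_genes = _family("Alpha", 2, 3)
        [c1] = call_genus_conservation([more_genomes], 4)
        [c2] = call_genus_conservation([more_genes], 4)
        assert c0.is_conserved and c1.is_conserved and c2.is_conserved


class TestLinkAcrossGenera:
    def _setup(self, seqs_by_genus):
        families, regions, contents = [], {}, {}
        for genus, seqs in seqs_by_genus.items():
            gid = f"{genus}_g1"
            region = make_region(gid, seqs)
            rid = region.region_id
            regions[rid] = region
            contents[rid] = RegionFamilyContent(rid, {"f1", "f2"}, {"f1", "f2"}, [])
            families.append(
                BgcFamily(
                    family_id=f"{genus}:bgcfam001",
                    genus=genus,
                    member_regions={gid: [rid]},
                    defining_families={"f1", "f2"},
                )
            )
        return families, regions, contents

    def test_identical_representatives_link(self):
        seqs = [("a1", "MKLVANDE"), ("a2", "MWYYCPHG")]
        fams, regions, contents = self._setup({"Alpha": seqs, "Beta": seqs})
        groups = link_across_genera(fams, regions, contents)
        assert len(groups) == 1
        assert groups[0].genera_present == {"Alpha", "Beta"}

    def test_unrelated_representatives_stay_separate(self):
        fams, regions, contents = self._setup({
            "Alpha": [("a1", "MKLVANDE"), ("a2", "MWYYCPHG")],
            "Beta": [("b1", "MDDEEKKR"), ("b2", "MSTSTSTS")],
        })
        groups = link_across_genera(fams, regions, contents)
        assert len(groups) == 2

    def test_transitive_linkage_matches_component_oracle(self):
        # A links B, B links C, A and C share nothing directly
        fams, regions, contents = self._setup({
            "Alpha": [("a1", "MKLVANDE"), ("a2", "MWYYCPHG")],
            "Beta": [("b1", "MKLVANDE"), ("b2", "MWYYCPHG"),
                     ("b3", "MDDEEKKR"), ("b4", "MSTSTSTS")],
            "Gamma": [("c1", "MDDEEKKR"), ("c2", "MSTSTSTS")],
        })
        groups = link_across_genera(fams, regions, contents)
        assert len(groups) == 1
        assert groups[0].genera_present == {"Alpha", "Beta", "Gamma"}
        nodes = [f.family_id for f in fams]
        edges = [("Alpha:bgcfam001", "Beta:bgcfam001"),
                 ("Beta:bgcfam001", "Gamma:bgcfam001")]
        assert {frozenset(c) for c in connected_components(nodes, edges)} == {
            frozenset(nodes)
        }

    def test_representative_is_region_with_most_conserved_content(self):
        region_big = make_region("g2", [("b1", "MK"), ("b2", "MA")])
        region_small = make_region("g1", [("a1", "MK")])
        contents = {
            region_big.region_id: RegionFamilyContent(
                region_big.region_id, {"f1", "f2"}, {"f1", "f2"}, []),
            region_small.region_id: RegionFamilyContent(
                region_small.region_id, {"f1"}, {"f1"}, []),
        }
        fam = BgcFamily(
            family_id="Alpha:bgcfam001", genus="Alpha",
            member_regions={"g1": [region_small.region_id], "g2": [region_big.region_id]},
            defining_families={"f1", "f2"},
        )
        rep = representative_region(
            fam,
            {r.region_id: r for r in [region_big, region_small]},
            contents,
        )
        assert rep.region_id == region_big.region_id


class TestPhylumCall:
    def test_table2_groups_all_conserved_at_seven(self):
        groups = phylum_groups_from_fixture(load_fixture("table2"))
        flagged = call_phylum_conservation(groups, 11, 7)
        assert sum(1 for _, f in flagged if f) == 5

    def test_no_group_spans_all_eleven(self):
        groups = phylum_groups_from_fixture(load_fixture("table2"))
        flagged = call_phylum_conservation(groups, 11, 11)
        assert sum(1 for _, f in flagged if f) == 0

    def test_single_genus_group_at_min_one(self):
        fam = _family("Alpha", 1, 2)
        from bgcpan import PhylumGroup

        grp = PhylumGroup("group001", [("Alpha", fam)])
        [(g, flag)] = call_phylum_conservation([grp], 1, 1)
        assert flag is True

    def test_genera_present_recomputed_from_members(self):
        groups = phylum_groups_from_fixture(load_fixture("table2"))
        for g in groups:
            assert g.genera_present == {genus for genus, _ in g.members}


class TestScreening:
    PROFILES = [
        BgcProfile("p1", [("x1", "MKLVANDE"), ("x2", "MWYYCPHG")]),
        BgcProfile("p2", [("y1", "MDDEEKKR"), ("y2", "MSTSTSTS")]),
    ]

    def test_no_regions_means_all_absent(self):
        res = screen_genome(self.PROFILES, [], "gX")
        assert res.per_genome_total == 0
        assert all(not v for v in res.calls.values())

    def test_exact_copies_in_one_region_present(self):
        region = make_region("gX", [("t1", "MKLVANDE"), ("t2", "MWYYCPHG")])
        res = screen_genome(self.PROFILES, [region], "gX")
        assert res.calls == {"p1": True, "p2": False}
        assert res.per_genome_total == 1
        assert {tag for _, tag, _ in res.evidence["p1"]} == {"t1", "t2"}

    def test_matches_split_across_regions_absent(self):
        r1 = make_region("gX", [("t1", "MKLVANDE")], contig="c1")
        r2 = make_region("gX", [("t2", "MWYYCPHG")], contig="c2")
        res = screen_genome(self.PROFILES, [r1, r2], "gX")
        assert res.calls["p1"] is False

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            screen_genome([], [], "gX")


class TestScreenTable:
    def test_fixture_replay_recomputes_published_totals(self):
        rows = screen_table(screen_results_from_fixture(load_fixture("table3")))
        totals = rows[-1]
        assert totals["genome"] == "total"
        assert totals["geosmin"] == "7/11"
        assert totals["carotenoid"] == "9/11"
        assert totals["VEPE/AEPE/TG-1"] == "8/11"
        assert totals["alkylpyrone"] == "9/11"
        assert totals["myxochelin"] == "5/11"

    def test_row_and_column_sums_consistent(self):
        rows = screen_table(screen_results_from_fixture(load_fixture("table3")))
        body, totals = rows[:-1], rows[-1]
        profiles = [c for c in rows[0] if c not in ("genome", "total")]
        for p in profiles:
            m = sum(1 for r in body if r[p] == "+")
            assert totals[p] == f"{m}/{len(body)}"
        for r in body:
            k = sum(1 for p in profiles if r[p] == "+")
            assert r["total"] == f"{k}/{len(profiles)}"

    def test_minimum_per_strain_total_is_two(self):
        rows = screen_table(screen_results_from_fixture(load_fixture("table3")))
        per_strain = [int(r["total"].split("/")[0]) for r in rows[:-1]]
        assert min(per_strain) == 2

    def test_inconsistent_profile_sets_rejected(self):
        from bgcpan import ScreenResult

        r1 = ScreenResult("g1", {"p1": True})
        r2 = ScreenResult("g2", {"p2": True})
        with pytest.raises(ValueError):
            screen_table([r1, r2])
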