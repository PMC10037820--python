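import numpy as np
import pytest

from founderera.taxonomy import (
    Lineage,
    LineageLevel,
    TaxonomyError,
    collapse_levels,
    divergence_level,
    focal_lineage,
    load_taxonomy,
)


def write_tsv(path, rows):
    path.write_text("".join(f"{t}\t{p}\t{r}\t{n}\n" for t, p, r, n in rows))
    return path


class TestLoadTaxonomy:
    def test_minimal_three_node_chain(self, tmp_path):
        db = load_taxonomy(write_tsv(tmp_path / "tax.tsv", [
            (1, 2, "species", "sp"), (2, 3, "kingdom", "kg"), (3, 3, "no rank", "root"),
        ]))
        assert len(db) == 3
        assert db.root == 3

    def test_dangling_parent_names_offender(self, tmp_path):
        path = write_tsv(tmp_path / "tax.tsv", [
            (5, 99, "species", "sp"), (3, 3, "no rank", "root"),
        ])
        with pytest.raises(TaxonomyError, match="99"):
            load_taxonomy(path)

    def test_cycle_detected(self, tmp_path):
        path = write_tsv(tmp_path / "tax.tsv", [
            (1, 2, "a", "x"), (2, 1, "b", "y"), (3, 3, "no rank", "root"),
        ])
        with pytest.raises(TaxonomyError):
            load_taxonomy(path)

    def test_multiple_roots_rejected(self, tmp_path):
        path = write_tsv(tmp_path / "tax.tsv", [
            (1, 1, "no rank", "r1"), (2, 2, "no rank", "r2"),
        ])
        with pytest.raises(TaxonomyError, match="one root"):
            load_taxonomy(path)

    def test_random_taxonomy_single_fixed_point(self, tmp_path):
        # oracle: an independent parent-chain walk from every node must
        # terminate at one and the same fixed point
        rng = np.random.default_rng(0)
        rows = [(1, 1, "no rank", "root")]
        ranks = ["phylum", "class", "order", "family"]
        for t in range(2, 31):
            rows.append((t, int(rng.integers(1, t)), ranks[t % 4], f"n{t}"))
        db = load_taxonomy(write_tsv(tmp_path / "tax.tsv", rows))
        parents = {t: p for t, p, _, _ in rows}
        fixed_points = set()
        for t in parents:
            seen = set()
            while parents[t] != t:
                assert t not in seen
                seen.add(t)
                t = parents[t]
            fixed_points.add(t)
        assert fixed_points == {db.root} == {1}

    def test_taxdump_dialect(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t1\t|\tno rank\t|\n9606\t|\t9605\t|\tspecies\t|\n9605\t|\t1\t|\tgenus\t|\n"
        )
        (tmp_path / "names.dmp").write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "9606\t|\tHomo sapiens\t|\t\t|\tscientific name\t|\n"
            "9606\t|\thuman\t|\t\t|\tgenbank common name\t|\n"
            "9605\t|\tHomo\t|\t\t|\tscientific name\t|\n"
        )
        db = load_taxonomy(tmp_path / "nodes.dmp", tmp_path / "names.dmp")
        assert db[9606].name == "Homo sapiens"
        assert db[9606].rank == "species"
        assert db.root == 1


class TestFocalLineage:
    def test_four_level_chain(self, chain_db):
        lin = focal_lineage(chain_db, 1)
        assert len(lin) == 4
        assert [lv.taxid for lv in lin.levels] == [1, 2, 3, 4]
        assert lin.level(1).name == "focal"
        assert lin.level(4).name == "root"

    def test_root_as_focal_is_degenerate(self, chain_db):
        lin = focal_lineage(chain_db, 4)
        assert len(lin) == 1

    def test_unknown_focal_raises(self, chain_db):
        with pytest.raises(KeyError):
            focal_lineage(chain_db, 12345)

    def test_simulated_lineage_strictly_nested(self, noiseless_bundle):
        # oracle: the simulator's truth of ring membership; the species set
        # contained by each level must strictly grow with the index
        b = noiseless_bundle
        db = load_taxonomy(b.nodes_path, b.names_path)
        lin = focal_lineage(db, b.focal_taxid)
        assert len(lin) == b.config.n_levels
        members = []
        for lv in lin.levels:
            contained = {t for t in (s for ring in b.ring_taxids.values() for s in ring)
                         if lv.taxid in db.ancestors(t)}
            members.append(contained)
        for young, old in zip(members, members[1:]):
            assert young < old  # strict superset going older


class TestDivergenceLevel:
    def test_focal_itself_is_level_one(self, chain_db, chain_lineage):
        assert divergence_level(chain_lineage, chain_db, 1) == 1

    def test_root_only_subject_is_level_n(self, chain_db, chain_lineage):
        assert divergence_level(chain_lineage, chain_db, 41) == 4

    def test_intermediate_subjects(self, chain_db, chain_lineage):
        assert divergence_level(chain_lineage, chain_db, 21) == 2
        assert divergence_level(chain_lineage, chain_db, 31) == 3

    def test_simulated_rings_match_lca_oracle(self, noiseless_bundle):
        b = noiseless_bundle
        db = load_taxonomy(b.nodes_path, b.names_path)
        lin = focal_lineage(db, b.focal_taxid)
        focal_anc = db.ancestors(b.focal_taxid)
        for level, ring in b.ring_taxids.items():
            for taxid in ring:
                # oracle: lowest common ancestor by explicit ancestor-set intersection
                lca = next(a for a in focal_anc if a in set(db.ancestors(taxid)))
                lca_index = focal_anc.index(lca) + 1
                assert divergence_level(lin, db, taxid) == lca_index == level

    def test_subject_outside_truncated_lineage_unmappable(self, chain_db):
        truncated = Lineage(focal_taxid=1, levels=(
            LineageLevel(1, 1, "focal", "species"), LineageLevel(2, 2, "genus_A", "genus"),
        ))
        assert divergence_level(truncated, chain_db, 41) is None

    def test_order_preserving_for_nested_subjects(self, chain_db, chain_lineage):
        # genus (ancestor of sib_genus member) diverges no younger than its members
        assert divergence_level(chain_lineage, chain_db, 21) <= divergence_level(
            chain_lineage, chain_db, 31
        )


class TestCollapseLevels:
    def test_all_levels_supported_is_identity(self, chain_db, chain_lineage):
        fracs = {21: 0.5, 31: 0.5, 41: 0.5}
        collapsed, index_map = collapse_levels(chain_lineage, chain_db, fracs)
        assert collapsed == chain_lineage
        assert index_map == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_unsupported_level_removed_and_renumbered(self, chain_db, chain_lineage):
        fracs = {21: 0.5, 31: 0.05, 41: 0.5}  # family ring under-sampled
        collapsed, index_map = collapse_levels(chain_lineage, chain_db, fracs)
        assert [lv.taxid for lv in collapsed.levels] == [1, 2, 4]
        assert index_map == {1: 1, 2: 2, 4: 3}

    def test_boundary_fraction_is_strict(self, chain_db, chain_lineage):
        # exactly 10% does not retain: the rule is strictly "more than"
        fracs = {21: 0.10, 31: 0.5, 41: 0.5}
        collapsed, _ = collapse_levels(chain_lineage, chain_db, fracs)
        assert [lv.taxid for lv in collapsed.levels] == [1, 3, 4]

    def test_species_and_root_always_retained(self, chain_db, chain_lineage):
        collapsed, _ = collapse_levels(chain_lineage, chain_db, {})
        assert [lv.taxid for lv in collapsed.levels] == [1, 4]

    def test_explicit_name_exclusion(self, chain_db, chain_lineage):
        fracs = {21: 0.5, 31: 0.5, 41: 0.5}
        collapsed, _ = collapse_levels(
            chain_lineage, chain_db, fracs, excluded_level_names=["genus_A"]
        )
        assert [lv.name for lv in collapsed.levels] == ["focal", "family_A", "root"]

    def test_idempotent(self, chain_db, chain_lineage):
        fracs = {21: 0.5, 31: 0.02, 41: 0.3}
        once, _ = collapse_levels(chain_lineage, chain_db, fracs)
        twice, _ = collapse_levels(once, chain_db, fracs)
        assert once == twice

    def test_reindexing_preserves_relative_order(self, chain_db, chain_lineage):
        fracs = {21: 0.01, 31: 0.5, 41: 0.5}
        collapsed, index_map = collapse_levels(chain_lineage, chain_db, fracs)
        olds = sorted(index_map)
        assert [index_map[o] for o in olds] == sorted(index_map[o] for o in olds)

    def test_bad_fraction_rejected(self, chain_db, chain_lineage):
        with pytest.raises(ValueError):
            collapse_levels(chain_lineage, chain_db, {21: 1.5})
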