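"""Ward-D2 linkage, centroid identity assignment, regions, newick export."""

import numpy as np
import pytest

from biooilms.dataset_io import StandardCompound
from biooilms.formula_core import VKPoint, parse_formula, vk_point
from biooilms.standard_matching import (
    DEFAULT_REGIONS,
    Dendrogram,
    assign_identities,
    fixed_region_classify,
    load_regions_table,
    to_newick,
    ward_linkage,
)
from biooilms.vk_clustering import kmeans_fit


def cophenetic_matrix(tree: Dendrogram) -> np.ndarray:
    """Pairwise merge heights of the smallest clade containing each pair."""
    n = tree.n_leaves
    coph = np.zeros((n, n))
    sets = {i: {i} for i in range(n)}
    for a, b, height, new_id in tree.merges:
        for x in sets[a]:
            for y in sets[b]:
                coph[x, y] = coph[y, x] = height
        sets[new_id] = sets[a] | sets[b]
    return coph


def standard(name, formula=None, oc=None, hc=None):
    if formula is not None:
        comp = parse_formula(formula)
        return StandardCompound(name=name, vk=vk_point(comp), composition=comp)
    return StandardCompound(name=name, vk=VKPoint(oc, hc))


class TestWardLinkage:
    def test_collinear_nearest_pair_merges_first(self):
        points = np.array([[0.0, 1.0], [0.1, 1.0], [0.5, 1.0]])
        tree = ward_linkage(points, ["a", "b", "c"])
        first = tree.merges[0]
        assert {first[0], first[1]} == {0, 1}

    def test_coincident_points_merge_at_zero_height(self):
        points = np.array([[0.3, 1.0], [0.3, 1.0], [0.9, 2.0]])
        tree = ward_linkage(points, ["a", "b", "c"])
        assert tree.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(31)
        for trial in range(5):
            points = rng.uniform(0, 2, size=(12, 2))
            tree = ward_linkage(points, [f"p{i}" for i in range(12)])
            heights = [merge[2] for merge in tree.merges]
            assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))

    def test_agrees_with_scipy_ward(self):
        """Independent oracle: identical cophenetic structure to
        scipy's ward linkage on small random sets."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        for trial in range(8):
            n = int(rng.integers(4, 7))
            points = rng.uniform(0, 2, size=(n, 2))
            tree = ward_linkage(points, [f"p{i}" for i in range(n)])
            ours = cophenetic_matrix(tree)
            ref = squareform(cophenet(linkage(points, method="ward")))
            assert np.allclose(ours, ref, atol=1e-9)

    def test_duplicate_labels_rejected(self):
        points = np.array([[0.0, 1.0], [0.5, 1.0]])
        with pytest.raises(ValueError, match="duplicate labels"):
            ward_linkage(points, ["x", "x"])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ward_linkage(np.array([[0.1, 1.0]]), ["only"])


class TestNewick:
    def test_two_leaf_tree(self):
        points = np.array([[0.0, 1.0], [0.0, 2.0]])
        tree = ward_linkage(points, ["A", "B"])
        height = tree.merges[0][2]
        assert to_newick(tree) == f"(A:{height / 2:.10g},B:{height / 2:.10g});"

    def test_zero_height_tree(self):
        points = np.array([[0.3, 1.0], [0.3, 1.0]])
        tree = ward_linkage(points, ["A", "B"])
        assert to_newick(tree) == "(A:0,B:0);"

    def test_reserved_characters_are_quoted(self):
        points = np.array([[0.0, 1.0], [0.0, 2.0]])
        tree = ward_linkage(points, ["p-cresol (ortho)", "B"])
        assert "'p-cresol (ortho)'" in to_newick(tree)

    def test_roundtrip_topology_via_dendropy(self):
        import dendropy

        rng = np.random.default_rng(12)
        for trial in range(5):
            n = int(rng.integers(4, 9))
            points = rng.uniform(0, 2, size=(n, 2))
            labels = [f"leaf{i}" for i in range(n)]
            tree = ward_linkage(points, labels)
            parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
            taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
            assert taxa == set(labels)
            # every internal clade of ours appears in the parsed tree
            parsed_clades = {
                frozenset(leaf.taxon.label for leaf in node.leaf_iter())
                for node in parsed.preorder_node_iter()
                if not node.is_leaf()
            }
            sets = tree.leaf_sets()
            for _, _, _, new_id in tree.merges:
                clade = frozenset(labels[i] for i in sets[new_id])
                assert clade in parsed_clades


class TestAssignIdentities:
    STANDARDS = [
        standard("levoglucosan", "C6H10O5"),
        standard("butanedial", "C4H6O2"),
        standard("oleic acid", "C18H34O2"),
    ]

    def fit(self, points, k):
        return kmeans_fit(np.asarray(points, dtype=float), k, n_starts=5, seed=0)

    def test_coincident_centroid_has_zero_distance(self):
        model = self.fit([[5 / 6, 10 / 6], [5 / 6 + 1e-3, 10 / 6], [0.1, 1.9]], 2)
        identities, _ = assign_identities(model, self.STANDARDS)
        by_size = {tuple(np.round(model.centroids[i.cluster_id], 2)): i for i in identities}
        lev = [i for i in identities if i.nearest_standard == "levoglucosan"]
        assert lev and min(i.distance for i in lev) < 1e-2

    def test_nearest_by_plain_euclidean(self):
        model = self.fit([[0.5, 1.5], [0.5, 1.5], [0.11, 1.89]], 2)
        identities, _ = assign_identities(model, self.STANDARDS)
        names = {i.cluster_id: i.nearest_standard for i in identities}
        centroid_names = {
            tuple(np.round(model.centroids[cid], 3)): name for cid, name in names.items()
        }
        assert centroid_names[(0.5, 1.5)] == "butanedial"

    def test_equidistant_tie_breaks_lexicographically(self):
        standards = [standard("beta", oc=0.2, hc=1.0), standard("alpha", oc=0.4, hc=1.0)]
        model = self.fit([[0.3, 1.0], [0.3, 1.0], [0.3, 1.01]], 1)
        identities, _ = assign_identities(model, standards)
        assert identities[0].nearest_standard == "alpha"
        assert identities[0].tied

    def test_invariant_to_standard_ordering(self):
        model = self.fit([[0.5, 1.5], [0.8, 1.6], [0.1, 1.85]], 3)
        a, _ = assign_identities(model, self.STANDARDS)
        b, _ = assign_identities(model, list(reversed(self.STANDARDS)))
        assert [x.nearest_standard for x in a] == [x.nearest_standard for x in b]

    def test_clade_contains_nearest_standard_for_well_separated_case(self):
        model = self.fit([[0.84, 1.66], [0.83, 1.68], [0.12, 1.88]], 2)
        identities, tree = assign_identities(model, self.STANDARDS)
        for ident in identities:
            assert ident.clade_standards  # some standard shares a clade
        assert tree.n_leaves == 2 + len(self.STANDARDS)

    def test_empty_standards_rejected(self):
        model = self.fit([[0.5, 1.5], [0.1, 1.9]], 2)
        with pytest.raises(ValueError):
            assign_identities(model, [])


class TestFixedRegions:
    @pytest.mark.parametrize(
        "oc, hc, expected",
        [
            (0.2, 1.2, "pyrolytic lignin-like"),
            (0.05, 1.8, "zone 1"),
            (0.95, 0.2, "unclassified"),
            (0.0, 1.8, "unclassified"),  # zone 1 is open at O/C = 0
            (0.3, 1.5, "zone 1"),  # boundary hit, priority order decides
        ],
    )
    def test_shipped_regions(self, oc, hc, expected):
        assert fixed_region_classify(VKPoint(oc, hc)) == expected

    def test_multimatch_reported_without_priority(self):
        matches = fixed_region_classify(VKPoint(0.3, 1.5), priority=False)
        assert matches == ["zone 1", "pyrolytic lignin-like"]

    def test_user_region_table(self, tmp_path):
        path = tmp_path / "regions.csv"
        path.write_text(
            "name,oc_min,oc_max,hc_min,hc_max,oc_min_inclusive\n"
            "carbs,0.7,1.2,1.4,2.4,True\n"
        )
        regions = load_regions_table(path)
        assert fixed_region_classify(VKPoint(0.83, 1.67), regions) == "carbs"
        assert fixed_region_classify(VKPoint(0.2, 1.2), regions) == "unclassified"
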