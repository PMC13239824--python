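import numpy as np
import pytest

from refugia.diversity import diversity_change, faith_pd, load_tree, species_richness
from refugia.grid import RasterGrid, Transform
from refugia.synthetic import generate_phylogeny


def grids(stack):
    t = Transform(86.0, 48.0, 0.1)
    return [RasterGrid(np.asarray(b, dtype=float), t) for b in stack]


def brute_force_pd(tree, present, rooted=True):
    """Edge-union enumeration: walk each present tip to the root and sum the
    union of traversed edge lengths (shared root path dropped if unrooted)."""
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    paths = {}
    for sp in present:
        edges = []
        node = tips[sp]
        while node is not tree.seed_node:
            edges.append(node.edge)
            node = node.parent_node
        paths[sp] = edges
    union = {id(e): e for edges in paths.values() for e in edges}
    if not rooted and paths:
        shared = set.intersection(*[{id(e) for e in edges} for edges in paths.values()])
        union = {k: v for k, v in union.items() if k not in shared}
    return sum(e.length or 0.0 for e in union.values())


class TestSpeciesRichness:
    def test_counts_presences(self):
        sr = species_richness(grids([[[1, 0]], [[1, 1]], [[1, 0]]]))
        np.testing.assert_array_equal(sr.values, [[3, 1]])

    def test_empty_cell_is_zero(self):
        sr = species_richness(grids([[[0, 0]], [[0, 0]]]))
        np.testing.assert_array_equal(sr.values, [[0, 0]])

    def test_sum_exchange_identity(self):
        rng = np.random.default_rng(0)
        stack = [rng.integers(0, 2, size=(7, 9)) for _ in range(5)]
        sr = species_richness(grids(stack))
        assert sr.values.sum() == sum(b.sum() for b in stack)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            species_richness([])


class TestFaithPD:
    def test_all_species_give_total_tree_length(self):
        species = [f"s{i}" for i in range(6)]
        tree = generate_phylogeny(species, seed=1)
        # the root's own subtending edge carries no shared history
        total = sum(
            e.length or 0.0
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        )
        pd_grid = faith_pd(grids([[[1]]] * 6), tree, species)
        assert pd_grid.values[0, 0] == pytest.approx(total)

    def test_single_species_is_root_path(self):
        species = ["a", "b", "c", "d"]
        tree = generate_phylogeny(species, seed=2)
        maps = grids([[[1]], [[0]], [[0]], [[0]]])
        pd_grid = faith_pd(maps, tree, species)
        assert pd_grid.values[0, 0] == pytest.approx(brute_force_pd(tree, ["a"]))
        assert pd_grid.values[0, 0] > 0

    def test_empty_cell_pd_zero(self):
        species = ["a", "b"]
        tree = generate_phylogeny(species, seed=3)
        pd_grid = faith_pd(grids([[[0]], [[0]]]), tree, species)
        assert pd_grid.values[0, 0] == 0.0

    def test_missing_species_named(self):
        tree = generate_phylogeny(["a", "b"], seed=4)
        with pytest.raises(KeyError, match="ghost"):
            faith_pd(grids([[[1]], [[1]]]), tree, ["a", "ghost"])

    @pytest.mark.parametrize("rooted", [True, False])
    @pytest.mark.parametrize("seed", range(5))
    def test_random_communities_match_brute_force(self, seed, rooted):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(3, 13))
        species = [f"s{i}" for i in range(n_tips)]
        tree = generate_phylogeny(species, seed=seed)
        stack = [rng.integers(0, 2, size=(4, 10)) for _ in species]
        pd_grid = faith_pd(grids(stack), tree, species, rooted=rooted)
        for r in range(4):
            for c in range(10):
                present = [sp for sp, b in zip(species, stack) if b[r, c]]
                assert pd_grid.values[r, c] == pytest.approx(
                    brute_force_pd(tree, present, rooted) if present else 0.0
                ), (r, c, present)

    def test_monotone_in_species_addition(self):
        rng = np.random.default_rng(9)
        species = [f"s{i}" for i in range(8)]
        tree = generate_phylogeny(species, seed=9)
        stack = [rng.integers(0, 2, size=(5, 5)) for _ in species]
        base = faith_pd(grids(stack), tree, species).values
        stack2 = [s.copy() for s in stack]
        stack2[3][:] = 1  # species 3 now everywhere
        grown = faith_pd(grids(stack2), tree, species).values
        assert np.all(grown >= base - 1e-12)

    def test_matches_picante_reference(self, tmp_path):
        """Cross-check rooted PD against the R picante implementation."""
        import subprocess

        rng = np.random.default_rng(5)
        species = [f"s{i}" for i in range(7)]
        tree = generate_phylogeny(species, seed=5)
        stack = [rng.integers(0, 2, size=(1, 6)) for _ in species]
        pd_grid = faith_pd(grids(stack), tree, species, rooted=True)
        (tmp_path / "tree.nwk").write_text(tree.as_string(schema="newick"))
        comm = "\n".join(
            ",".join(str(stack[s][0, c]) for s in range(len(species))) for c in range(6)
        )
        (tmp_path / "comm.csv").write_text(",".join(species) + "\n" + comm + "\n")
        script = (
            "suppressMessages(library(picante));"
            f"tr <- read.tree('{tmp_path}/tree.nwk');"
            f"cm <- as.matrix(read.csv('{tmp_path}/comm.csv', check.names=FALSE));"
            "res <- pd(cm, tr, include.root=TRUE);"
            "cat(res$PD, sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        ref = [float(v) if v != "NA" else 0.0 for v in out.stdout.strip().split(",")]
        # tolerance limited by Rscript's printed precision
        np.testing.assert_allclose(pd_grid.values[0], ref, atol=1e-5)


class TestDiversityChange:
    def _mask(self, shape, mountain_rows):
        m = np.zeros(shape)
        m[:mountain_rows] = 1
        return RasterGrid(m, Transform(86.0, 48.0, 0.1))

    def test_identical_layers_all_unchanged(self):
        g = grids([np.random.default_rng(0).integers(0, 5, (6, 6))])[0]
        out = diversity_change(g, g, self._mask((6, 6), 3))
        assert (out.fractions["unchanged"] == 1.0).all()

    def test_basinwide_loss_classed_decrease(self):
        cur = grids([np.ones((4, 4))])[0]
        fut = grids([np.zeros((4, 4))])[0]
        out = diversity_change(cur, fut, self._mask((4, 4), 2))
        assert (out.change.values == -1).all()
        assert (out.fractions["decrease"] == 1.0).all()

    def test_stratified_fractions_match_direct_count(self):
        rng = np.random.default_rng(1)
        cur = grids([rng.integers(0, 4, (10, 10))])[0]
        fut = grids([rng.integers(0, 4, (10, 10))])[0]
        mask = self._mask((10, 10), 4)
        out = diversity_change(cur, fut, mask)
        delta = fut.values - cur.values
        mnt = mask.values > 0
        for stratum, sel in (("mountain", mnt), ("non_mountain", ~mnt)):
            n = sel.sum()
            assert out.fractions.loc[stratum, "increase"] == pytest.approx(
                (delta[sel] > 0).sum() / n
            )
            assert out.fractions.loc[stratum, "decrease"] == pytest.approx(
                (delta[sel] < 0).sum() / n
            )
        row_sums = out.fractions.sum(axis=1)
        np.testing.assert_allclose(row_sums, 1.0)


class TestLoadTree:
    def test_newick_string_and_file_round_trip(self, tmp_path):
        tree = generate_phylogeny(["x", "y", "z"], seed=0)
        newick = tree.as_string(schema="newick")
        t1 = load_tree(newick)
        p = tmp_path / "t.nwk"
        p.write_text(newick)
        t2 = load_tree(str(p))
        labels = lambda t: sorted(l.taxon.label for l in t.leaf_node_iter())
        assert labels(t1) == labels(t2) == ["x", "y", "z"]
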