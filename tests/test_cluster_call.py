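import numpy as np
import pytest

from oracles import average_linkage_trace
from riboscreen.cluster_call import (
    CORE_QUERIES,
    best_hits,
    build_distribution_matrix,
    call_rib_cluster,
    hcluster_order,
)
from riboscreen.homology import HomologyHit, align_local
from riboscreen.io_formats import Gene, GenomeRecord
from riboscreen.synthetic_data import (
    GeneratorConfig,
    make_pangenome,
    scatter_cluster,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n=80):
    return "".join(rng.choice(list(AA), size=n))


def _genome(proteins, contig="c1", genome_id="g1"):
    genes = [
        Gene(f"{genome_id}_{i:02d}", contig if isinstance(contig, str) else contig[i],
             1 + 400 * i, 400 * i + 3 * len(p), "+", p)
        for i, p in enumerate(proteins)
    ]
    return GenomeRecord(genome_id=genome_id, genes=genes)


@pytest.fixture(scope="module")
def queries():
    rng = np.random.default_rng(21)
    return {name: _random_protein(rng, 90) for name in CORE_QUERIES}


class TestBestHits:
    def test_exact_copies_hit_at_full_identity(self, queries):
        genome = _genome(list(queries.values()))
        hits = best_hits(genome, queries)
        assert all(h is not None and h.pct_identity == 100.0 for h in hits.values())

    def test_unrelated_genome_has_no_hits(self, queries):
        rng = np.random.default_rng(99)
        genome = _genome([_random_protein(rng) for _ in range(4)])
        assert all(h is None for h in best_hits(genome, queries).values())

    def test_equal_paralogs_tie_break_by_locus_tag(self, queries):
        q = {"ribD": queries["ribD"]}
        genome = _genome([queries["ribD"], queries["ribD"]])
        hit = best_hits(genome, q)["ribD"]
        assert hit.subject_locus == "g1_00"

    def test_empty_genome_returns_all_none(self, queries):
        genome = GenomeRecord(genome_id="empty")
        assert all(h is None for h in best_hits(genome, queries).values())


def _passing_hit(query, locus, similarity=90.0):
    return HomologyHit(query, locus, 200.0, similarity, similarity, 100.0, 1e-30)


class TestCallRibCluster:
    def test_four_adjacent_copies_are_present(self, queries):
        genome = _genome(list(queries.values()))
        call = call_rib_cluster(genome, best_hits(genome, queries))
        assert call.present and call.colocated
        assert call.avg_similarity == pytest.approx(100.0)

    def test_split_contigs_are_absent(self, queries):
        proteins = list(queries.values())
        contigs = ["c2", "c1", "c1", "c1"]
        genome = _genome(proteins, contig=contigs)
        call = call_rib_cluster(genome, best_hits(genome, queries))
        assert not call.present and not call.colocated

    def test_three_of_four_hits_is_absent(self):
        hits = {q: _passing_hit(q, f"l{i}") for i, q in enumerate(CORE_QUERIES[:3])}
        hits["ribH"] = None
        genome = _genome(["MKT" * 30])
        assert not call_rib_cluster(genome, hits).present

    def test_average_similarity_at_or_below_40_is_absent(self, queries):
        genome = _genome(list(queries.values()))
        hits = {
            q: _passing_hit(q, f"g1_{i:02d}", similarity=s)
            for i, (q, s) in enumerate(zip(CORE_QUERIES, (41.0, 39.0, 40.0, 38.0)))
        }
        call = call_rib_cluster(genome, hits)
        assert call.avg_similarity == pytest.approx(39.5)
        assert not call.present

    def test_wide_separation_on_one_contig_breaks_colocation(self, queries):
        rng = np.random.default_rng(5)
        proteins = [queries["ribD"]] + [
            _random_protein(rng) for _ in range(12)
        ] + [queries["ribE"], queries["ribAB"], queries["ribH"]]
        genome = _genome(proteins)
        call = call_rib_cluster(genome, best_hits(genome, queries))
        assert not call.colocated and not call.present


class TestDistributionMatrix:
    def test_query_source_genome_scores_100_everywhere(self, queries):
        genome = _genome(list(queries.values()))
        matrix, niche, _ = build_distribution_matrix([genome], queries)
        assert (matrix.loc["g1"] == 100.0).all()

    def test_genome_without_rib_genes_gives_zero_row(self, queries):
        rng = np.random.default_rng(31)
        genome = _genome([_random_protein(rng) for _ in range(3)])
        matrix, _, _ = build_distribution_matrix([genome], queries)
        assert (matrix.loc["g1"] == 0.0).all()

    def test_duplicate_genome_id_rejected(self, queries):
        genome = _genome(list(queries.values()))
        with pytest.raises(ValueError, match="duplicate"):
            build_distribution_matrix([genome, genome], queries)

    def test_cells_equal_per_pair_realignment(self, queries, small_panel):
        panel, _, panel_queries = small_panel
        sub = panel[:3]
        matrix, _, hits = build_distribution_matrix(sub, panel_queries)
        for genome in sub:
            for qname, hit in hits[genome.genome_id].items():
                if hit is None:
                    continue
                subject = genome.gene(hit.subject_locus).protein
                recomputed = align_local(panel_queries[qname], subject)
                assert matrix.loc[genome.genome_id, qname] == pytest.approx(
                    recomputed.pct_identity
                )


class TestHclusterOrder:
    def test_identical_rows_merge_first_at_height_zero(self):
        import pandas as pd

        m = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
            index=["r1", "r2", "r3"],
            columns=["q1", "q2"],
        )
        link, order = hcluster_order(m, "rows")
        assert link[0, 2] == 0.0  # first merge height
        assert abs(order.index("r1") - order.index("r2")) == 1  # adjacent leaves

    def test_merge_trace_matches_manual_average_linkage(self):
        import pandas as pd

        rows = [(0.0, 0.0), (0.0, 1.0), (4.0, 0.0), (10.0, 10.0)]
        labels = ["a", "b", "c", "d"]
        m = pd.DataFrame(rows, index=labels, columns=["x", "y"])
        link, _ = hcluster_order(m, "rows")
        expected = average_linkage_trace(rows)
        assert [h for _, _, h in expected] == pytest.approx(sorted(link[:, 2]))
        # first manual merge is {a,b}; the first linkage row joins leaves 0,1
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_row_permutation_leaves_leaf_order_unchanged(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        m = pd.DataFrame(
            rng.uniform(0, 100, size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=list("wxyz"),
        )
        _, order1 = hcluster_order(m, "rows")
        _, order2 = hcluster_order(m.sample(frac=1, random_state=1), "rows")
        assert order1 == order2

    def test_single_item_axis_is_trivial(self):
        import pandas as pd

        m = pd.DataFrame([[1.0, 2.0]], index=["only"], columns=["q1", "q2"])
        link, order = hcluster_order(m, "rows")
        assert link is None and order == ["only"]


class TestPlantedTruthRecovery:
    def test_default_panel_recovers_exactly_the_planted_carriers(self):
        """The headline screen: 83 species, 16 planted carriers, exact calls."""
        panel, truth, queries = make_pangenome(GeneratorConfig(seed=1))
        q4 = {k: queries[k] for k in CORE_QUERIES}
        predicted = set()
        for genome in panel:
            call = call_rib_cluster(genome, best_hits(genome, q4))
            if call.present:
                predicted.add(genome.genome_id)
        assert predicted == set(truth.index[truth.present])

    def test_pushing_divergence_below_threshold_flips_calls_to_absent(self):
        config = GeneratorConfig(
            seed=5,
            panel_size=6,
            n_carriers=3,
            carrier_identity_range=(0.08, 0.12),
            conservative_prob=0.0,
        )
        panel, truth, queries = make_pangenome(config)
        q4 = {k: queries[k] for k in CORE_QUERIES}
        for genome in panel:
            assert not call_rib_cluster(genome, best_hits(genome, q4)).present

    def test_scattering_a_carrier_always_flips_present_to_absent(self, small_panel):
        panel, truth, queries = small_panel
        q4 = {k: queries[k] for k in CORE_QUERIES}
        carriers = [g for g in panel if truth.loc[g.genome_id, "present"]]
        for genome in carriers:
            assert call_rib_cluster(genome, best_hits(genome, q4)).present
            scattered = scatter_cluster(genome)
            assert not call_rib_cluster(scattered, best_hits(scattered, q4)).present
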