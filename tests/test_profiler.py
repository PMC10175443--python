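import numpy as np
import pandas as pd
import pytest

from microvar.config import SimulationConfig
from microvar.lineage import Lineage
from microvar.profiler import (
    OtuTable,
    ProfilerError,
    apply_filters,
    assign_lineage,
    build_function_tables,
    build_taxa_table,
    collapse_asvs_by_taxonomy,
    genome_length_normalize,
    minimum_otu_count,
    resolve_ties_capitalist,
    tabulate_assignments,
    to_relative_abundance,
)
from microvar.synth import Modality, simulate_dataset

from conftest import make_refdb


def hits_frame(rows):
    """rows of (sample, tie_ids, position[, gene_id])"""
    return pd.DataFrame(
        [
            {
                "sample_id": r[0],
                "read_id": f"r{i}",
                "tied_genome_ids": r[1],
                "position": r[2],
                "gene_id": r[3] if len(r) > 3 else "-",
            }
            for i, r in enumerate(rows)
        ]
    )


class TestCapitalist:
    def test_star_instance_uses_single_otu(self):
        hits = hits_frame([("s", "G1;G2", 0), ("s", "G1", 0), ("s", "G1;G3", 0)])
        out = resolve_ties_capitalist(hits)
        assert set(out["chosen_genome"]) == {"G1"}
        sets = [frozenset(t.split(";")) for t in hits["tied_genome_ids"]]
        assert minimum_otu_count(sets) == 1

    def test_chain_instance_picks_shared_genome(self):
        hits = hits_frame([("s", "G1;G2", 0), ("s", "G2;G3", 0)])
        out = resolve_ties_capitalist(hits)
        assert list(out["chosen_genome"]) == ["G2", "G2"]

    def test_singleton(self):
        out = resolve_ties_capitalist(hits_frame([("s", "G5", 7)]))
        assert list(out["chosen_genome"]) == ["G5"]

    def test_empty_tie_set_rejected(self):
        with pytest.raises(ProfilerError):
            resolve_ties_capitalist(hits_frame([("s", "", 0)]))

    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_within_one_of_exhaustive_minimum(self, seed):
        """On random instances (<=12 reads, <=6 genomes) the greedy OTU count
        is sandwiched between the exact minimum and minimum + 1."""
        rng = np.random.default_rng(seed)
        genomes = [f"G{i}" for i in range(1, int(rng.integers(2, 7)) + 1)]
        n_reads = int(rng.integers(1, 13))
        rows = []
        for _ in range(n_reads):
            k = int(rng.integers(1, min(4, len(genomes)) + 1))
            ties = rng.choice(genomes, size=k, replace=False)
            rows.append(("s", ";".join(sorted(ties)), 0))
        hits = hits_frame(rows)
        out = resolve_ties_capitalist(hits)
        greedy = out["chosen_genome"].nunique()
        exact = minimum_otu_count(
            [frozenset(t.split(";")) for t in hits["tied_genome_ids"]]
        )
        assert exact <= greedy <= exact + 1


class TestLCA:
    def test_exact_80_percent_boundary_is_inclusive(self, enterics_refdb):
        # 4 of 5 tied genomes are E. coli -> 0.8 support, species accepted
        lin = assign_lineage({"E1", "E2", "E3", "E4", "E5"}, enterics_refdb)
        assert lin.at_rank("species") == "Escherichia coli"
        assert lin.deepest_rank == "species"

    def test_unanimous_strains_collapse_to_species(self, enterics_refdb):
        lin = assign_lineage({"E1", "E2"}, enterics_refdb)
        assert lin.deepest_rank == "species"
        assert lin.at_rank("species") == "Escherichia coli"

    def test_split_genus_falls_back_to_family(self, enterics_refdb):
        # 2 Escherichia + 1 Salmonella: genus support 2/3 < 0.8
        lin = assign_lineage({"E1", "E5", "S1"}, enterics_refdb)
        assert lin.deepest_rank == "family"
        assert lin.at_rank("family") == "Enterobacteriaceae"

    def test_threshold_monotonicity(self, enterics_refdb):
        """Lowering the threshold never yields a shallower assignment."""
        tie_sets = [
            {"E1", "E5", "S1"}, {"E1", "E2", "E3", "E4", "E5"},
            {"E1", "S1"}, {"E3", "E5"}, {"E1", "E2", "S1"},
        ]
        for ties in tie_sets:
            depths = [
                assign_lineage(ties, enterics_refdb, threshold=t).depth
                for t in (1.0, 0.8, 0.6, 0.4)
            ]
            assert depths == sorted(depths)

    def test_missing_genome_rejected(self, enterics_refdb):
        with pytest.raises(KeyError):
            assign_lineage({"E1", "NOPE"}, enterics_refdb)


class TestTabulation:
    def test_coverage_single_read(self, enterics_refdb):
        hits = resolve_ties_capitalist(hits_frame([("s1", "E1", 0)]))
        otu = tabulate_assignments(hits, enterics_refdb)
        assert otu.raw.loc["E1", "s1"] == 1
        assert otu.coverage.loc["E1", "genome_cov"] == pytest.approx(100 / 10_000)

    def test_overlapping_reads_union_semantics(self, enterics_refdb):
        hits = resolve_ties_capitalist(
            hits_frame([("s1", "E1", 50), ("s1", "E1", 50), ("s2", "E1", 100)])
        )
        otu = tabulate_assignments(hits, enterics_refdb)
        # union of [50,150) x2 and [100,200) = [50,200): 150 bp pooled
        assert otu.coverage.loc["E1", "genome_cov"] == pytest.approx(150 / 10_000)
        # unique region [0,1000): fully inside
        assert otu.coverage.loc["E1", "unique_cov"] == pytest.approx(150 / 1_000)

    def test_read_conservation(self, tiny_config):
        ds = simulate_dataset(tiny_config)
        otu = tabulate_assignments(resolve_ties_capitalist(ds.hits), ds.refdb)
        per_sample_hits = ds.hits.groupby("sample_id").size()
        totals = otu.raw.sum(axis=0)
        for sid, n in per_sample_hits.items():
            assert totals[sid] == n

    def test_position_outside_genome_rejected(self, enterics_refdb):
        hits = resolve_ties_capitalist(hits_frame([("s1", "E1", 9_950)]))
        with pytest.raises(ProfilerError):
            tabulate_assignments(hits, enterics_refdb)


class TestNormalization:
    def _otu(self, counts, refdb):
        return OtuTable(
            raw=counts,
            lineages=pd.Series({g: "" for g in counts.index}),
            coverage=pd.DataFrame(
                {"genome_cov": 1.0, "unique_cov": 1.0}, index=counts.index
            ),
        )

    def test_hand_example(self):
        db = make_refdb({"G1": "k__B", "G2": "k__B"})
        object.__setattr__(db.genomes["G1"], "length", 1_000_000)
        object.__setattr__(db.genomes["G2"], "length", 2_000_000)
        counts = pd.DataFrame({"s1": [10, 10]}, index=["G1", "G2"])
        out = genome_length_normalize(self._otu(counts, db), db)
        np.testing.assert_allclose(out.normalized["s1"], [15.0, 7.5])

    def test_equal_lengths_identity(self):
        db = make_refdb({"G1": "k__B", "G2": "k__B"}, length=5_000)
        counts = pd.DataFrame({"s1": [3, 9], "s2": [1, 0]}, index=["G1", "G2"])
        out = genome_length_normalize(self._otu(counts, db), db)
        np.testing.assert_allclose(out.normalized.to_numpy(), counts.to_numpy())

    def test_single_otu_sample_unchanged(self):
        db = make_refdb({"G1": "k__B", "G2": "k__B"})
        object.__setattr__(db.genomes["G2"], "length", 99_999)
        counts = pd.DataFrame({"s1": [7, 0]}, index=["G1", "G2"])
        out = genome_length_normalize(self._otu(counts, db), db)
        assert out.normalized.loc["G1", "s1"] == pytest.approx(7.0)


class TestFilters:
    def _table(self, raw, coverage):
        return OtuTable(
            raw=raw,
            lineages=pd.Series({g: "" for g in raw.index}),
            coverage=coverage,
            normalized=raw.astype(float),
        )

    def test_shallow_sample_dropped(self):
        raw = pd.DataFrame({"ok": [6_000, 6_000], "shallow": [5_000, 4_999]},
                           index=["G1", "G2"])
        cov = pd.DataFrame({"genome_cov": [1.0, 1.0], "unique_cov": [1.0, 1.0]},
                           index=["G1", "G2"])
        out, log = apply_filters(self._table(raw, cov))
        assert list(out.raw.columns) == ["ok"]
        assert any(r["rule"] == "min_sample_depth" and r["entity"] == "shallow"
                   for r in log)

    def test_coverage_filter_is_conjunctive(self):
        # unique 0.02% passes the 0.01% clause -> retained despite genome 0.5%
        raw = pd.DataFrame({"s": [20_000, 20_000]}, index=["keep", "drop"])
        cov = pd.DataFrame(
            {"genome_cov": [0.005, 0.005], "unique_cov": [0.0002, 0.00005]},
            index=["keep", "drop"],
        )
        out, log = apply_filters(self._table(raw, cov))
        assert list(out.raw.index) == ["keep"]
        assert log[0]["rule"] == "min_coverage" and log[0]["entity"] == "drop"

    def test_rare_otu_dropped(self):
        raw = pd.DataFrame({"s": [10_000_000, 1]}, index=["big", "rare"])
        cov = pd.DataFrame({"genome_cov": [1.0, 1.0], "unique_cov": [1.0, 1.0]},
                           index=["big", "rare"])
        out, log = apply_filters(self._table(raw, cov))
        assert list(out.raw.index) == ["big"]
        assert log[0]["rule"] == "min_frac"

    def test_idempotent(self):
        raw = pd.DataFrame({"a": [30_000, 2], "b": [11_000, 9_000]},
                           index=["G1", "G2"])
        cov = pd.DataFrame({"genome_cov": [0.5, 0.001], "unique_cov": [0.5, 0.00001]},
                           index=["G1", "G2"])
        once, _ = apply_filters(self._table(raw, cov))
        twice, log2 = apply_filters(once)
        pd.testing.assert_frame_equal(once.raw, twice.raw)
        assert log2 == []


class TestRelativeAbundance:
    def test_columns_sum_to_one(self):
        rel = to_relative_abundance(pd.DataFrame({"s1": [30, 70], "s2": [1, 0]}))
        np.testing.assert_allclose(rel.sum(), 1.0)
        np.testing.assert_allclose(rel["s1"], [0.3, 0.7])

    def test_zero_column_rejected(self):
        with pytest.raises(ProfilerError):
            to_relative_abundance(pd.DataFrame({"s1": [0, 0]}))


class TestFunctionTables:
    def test_ko_collapse_to_shared_enzyme(self):
        db = make_refdb(
            {"G1": "k__B", "G2": "k__B"},
            kos={"G1": "KO1", "G2": "KO2"},
            ko_to_enzymes={"KO1": frozenset({"EC_a"}), "KO2": frozenset({"EC_a"})},
        )
        hits = hits_frame(
            [("s", "G1", 0, "G1_g1")] * 6 + [("s", "G2", 0, "G2_g1")] * 4
        )
        ko, enz = build_function_tables(hits, db)
        assert ko.loc["KO1", "s"] == pytest.approx(0.6)
        assert enz.loc["EC_a", "s"] == pytest.approx(1.0)

    def test_multi_enzyme_ko_counts_fully_to_each(self):
        db = make_refdb(
            {"G1": "k__B"}, kos={"G1": "KO1"},
            ko_to_enzymes={"KO1": frozenset({"EC_a", "EC_b"})},
        )
        hits = hits_frame([("s", "G1", 0, "G1_g1")] * 10)
        ko, enz = build_function_tables(hits, db, relative=False)
        assert enz.loc["EC_a", "s"] == 10
        assert enz.loc["EC_b", "s"] == 10

    def test_no_gene_hits_warns_and_returns_empty(self):
        db = make_refdb({"G1": "k__B"})
        hits = hits_frame([("s", "G1", 5_000)])
        with pytest.warns(UserWarning):
            ko, enz = build_function_tables(hits, db)
        assert ko.empty and enz.empty

    def test_unknown_gene_rejected(self):
        db = make_refdb({"G1": "k__B"})
        hits = hits_frame([("s", "G1", 0, "MYSTERY")])
        with pytest.raises(ProfilerError):
            build_function_tables(hits, db)


class TestAsvCollapse:
    def test_identical_assignments_summed(self):
        table = pd.DataFrame({"s1": [5, 7], "s2": [1, 2]}, index=["A1", "A2"])
        lineages = pd.Series({"A1": "k__B;p__X", "A2": "k__B;p__X"})
        out = collapse_asvs_by_taxonomy(table, lineages)
        assert out.shape == (1, 2)
        assert list(out.loc["k__B;p__X"]) == [12, 3]

    def test_distinct_lineages_preserved_and_totals_conserved(self):
        table = pd.DataFrame({"s1": [5, 7, 2]}, index=["A1", "A2", "A3"])
        lineages = pd.Series({"A1": "k__B;p__X", "A2": "k__B;p__Y", "A3": "k__B"})
        out = collapse_asvs_by_taxonomy(table, lineages)
        assert out.shape[0] == 3
        assert out["s1"].sum() == table["s1"].sum()

    def test_missing_lineage_rejected(self):
        table = pd.DataFrame({"s1": [5]}, index=["A1"])
        with pytest.raises(ProfilerError):
            collapse_asvs_by_taxonomy(table, pd.Series(dtype=object))


class TestEndToEnd:
    def test_profile_converges_to_latent_at_high_depth(self):
        """With no ties, equal genome lengths and passing filters, the OTU
        relative-abundance profile approaches the latent composition."""
        cfg = SimulationConfig(
            n_subjects=1, days=(1,), n_extractions=1, n_libpreps=1,
            n_taxa=20, p_tie=0.0, read_depth_shotgun=10 ** 6,
            genome_length_range=(50_000, 50_000), seed=5,
        )
        ds = simulate_dataset(cfg)
        otu = tabulate_assignments(resolve_ties_capitalist(ds.hits), ds.refdb)
        otu = genome_length_normalize(otu, ds.refdb)
        otu, _ = apply_filters(otu, ds.refdb)
        rel = to_relative_abundance(otu.normalized)
        latent = {p.sample_id: p.composition for p in ds.latent}[ds.latent[0].sample_id]
        taxon_of = {v: k for k, v in ds.refdb.taxon_to_genome.items()}
        taxa = sorted(ds.shotgun_counts.index)
        est = np.zeros(len(taxa))
        for gid in rel.index:
            est[taxa.index(taxon_of[gid])] = rel.iloc[:, 0][gid]
        assert np.abs(est - latent).sum() < 0.02

    def test_taxa_table_resolution_reflects_ties(self, tiny_config):
        ds = simulate_dataset(tiny_config.replace(p_tie=1.0))
        taxa = build_taxa_table(ds.hits, ds.refdb)
        depths = [Lineage.parse(str(f)).depth for f in taxa.index]
        # genus-tied reads truncate below species; untied singleton genera stay deep
        assert min(depths) < 7
        assert taxa.to_numpy().sum() == len(ds.hits)
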