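"""Catalog deduplication and mean-expression enrichment with permutation null."""

import numpy as np
import pytest
from scipy import stats

from stemdis import synthetic
from stemdis.de import DEResult
from stemdis.enrichment import (
    Module,
    ModuleCatalog,
    dedupe_catalog,
    module_scores,
    module_significance,
    read_gmt,
    top_modules,
    write_gmt,
)


def de_table(log2fcs, prefix="g"):
    return [
        DEResult(gene=f"{prefix}{i}", log2fc=float(fc), p=0.5, q=0.5, label="ns")
        for i, fc in enumerate(log2fcs)
    ]


def mod(name, genes):
    return Module(name=name, description="", genes=frozenset(genes))


class TestDedupe:
    def test_unites_set_identical_entries(self):
        cat = ModuleCatalog([mod("A", "vwxyz"), mod("B", "zyxwv")])
        out = dedupe_catalog(cat)
        assert len(out) == 1
        assert out.modules[0].name == "A|B"

    def test_keeps_distinct_entries(self):
        cat = ModuleCatalog([mod("A", "abc"), mod("B", "abd")])
        assert len(dedupe_catalog(cat)) == 2

    def test_idempotent(self):
        cat = ModuleCatalog([mod("A", "abc"), mod("B", "abc"), mod("C", "xy")])
        once = dedupe_catalog(cat)
        twice = dedupe_catalog(once)
        assert [m.name for m in once.modules] == [m.name for m in twice.modules]

    def test_generator_duplicates_collapse_to_unique_count(self):
        universe = [f"g{i}" for i in range(100)]
        rows, truth = synthetic.gen_module_catalog(
            universe, n_modules=10, duplicate_fraction=0.5, seed=6
        )
        cat = ModuleCatalog([mod(n, gs) for n, _, gs in rows])
        assert len(cat) == 10
        assert len(dedupe_catalog(cat)) == 5
        assert (truth.planted_label == "duplicate").sum() == 5

    def test_gmt_round_trip(self, tmp_path):
        cat = ModuleCatalog([mod("A", "abc"), mod("B", "de")])
        path = tmp_path / "c.gmt"
        write_gmt(cat, path)
        back = read_gmt(path)
        assert [(m.name, m.genes) for m in back.modules] == [
            (m.name, m.genes) for m in cat.modules
        ]


class TestScores:
    def test_mean_of_members(self):
        de = de_table([2.0, 4.0, 1.0, 1.0, 1.0, 1.0])
        cat = ModuleCatalog([mod("M", ["g0", "g1"])])
        scores = module_scores(cat, de, min_genes=2)
        assert scores["M"] == (pytest.approx(3.0), 2)

    def test_unmapped_module_skipped(self, caplog):
        de = de_table([1.0] * 10)
        cat = ModuleCatalog([mod("ghost", ["zz1", "zz2"]), mod("ok", [f"g{i}" for i in range(5)])])
        with caplog.at_level("INFO", logger="stemdis.enrichment"):
            scores = module_scores(cat, de, min_genes=2)
        assert "ghost" not in scores and "ok" in scores
        assert any("ghost" in r.message for r in caplog.records)

    def test_all_gene_module_equals_transcriptome_mean(self):
        fcs = np.linspace(-3, 3, 50)
        de = de_table(fcs)
        cat = ModuleCatalog([mod("all", [f"g{i}" for i in range(50)])])
        scores = module_scores(cat, de, min_genes=2)
        assert scores["all"][0] == pytest.approx(float(np.mean(fcs)))

    def test_score_linearity(self):
        fcs = np.linspace(-2, 2, 30)
        cat = ModuleCatalog([mod("M", ["g3", "g7", "g11"])])
        s1 = module_scores(cat, de_table(fcs), min_genes=2)["M"][0]
        s2 = module_scores(cat, de_table(2 * fcs), min_genes=2)["M"][0]
        assert s2 == pytest.approx(2 * s1)


class TestSignificance:
    def test_planted_module_hits_minimal_p(self):
        rng = np.random.default_rng(8)
        fcs = rng.normal(0, 0.3, 500)
        fcs[:20] = 4.0
        de = de_table(fcs)
        cat = ModuleCatalog([mod("planted", [f"g{i}" for i in range(20)]),
                             mod("noise", [f"g{i}" for i in range(100, 120)])])
        scores = module_scores(cat, de, min_genes=5)
        results = {r.module: r for r in module_significance(scores, de, 10_000, seed=1)}
        assert results["planted"].p == pytest.approx(1 / 10_001)
        assert results["planted"].q < 0.05
        assert results["planted"].direction == "up"

    def test_p_bounds(self):
        rng = np.random.default_rng(9)
        de = de_table(rng.normal(0, 1, 200))
        cat = ModuleCatalog([mod(f"M{i}", [f"g{j}" for j in range(i, i + 10)])
                             for i in range(0, 50, 10)])
        scores = module_scores(cat, de, min_genes=5)
        for r in module_significance(scores, de, 200, seed=2):
            assert 1 / 201 <= r.p <= 1.0

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(10)
        de = de_table(rng.normal(0, 1, 100))
        cat = ModuleCatalog([mod("M", [f"g{i}" for i in range(8)])])
        scores = module_scores(cat, de, min_genes=5)
        a = module_significance(scores, de, 500, seed=4)
        b = module_significance(scores, de, 500, seed=4)
        assert [(r.module, r.p) for r in a] == [(r.module, r.p) for r in b]

    def test_null_modules_give_roughly_uniform_p(self):
        """Random gene sets against a null DE table: KS sanity check."""
        rng = np.random.default_rng(11)
        de = de_table(rng.normal(0, 1, 400))
        mods = []
        for i in range(60):
            genes = rng.choice(400, size=15, replace=False)
            mods.append(mod(f"M{i}", [f"g{j}" for j in genes]))
        scores = module_scores(ModuleCatalog(mods), de, min_genes=5)
        results = module_significance(scores, de, 2000, seed=5)
        pvals = [r.p for r in results]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTopModules:
    def _results(self):
        from stemdis.enrichment import EnrichmentResult

        return [
            EnrichmentResult("a", 2.0, 10, 0.001, 0.01, "up"),
            EnrichmentResult("b", 3.0, 10, 0.001, 0.01, "up"),
            EnrichmentResult("c", 1.0, 10, 0.02, 0.04, "up"),
            EnrichmentResult("d", -2.0, 10, 0.001, 0.01, "down"),
        ]

    def test_ranking_and_tiebreak(self):
        top = top_modules(self._results(), n=60, direction="up")
        assert [r.module for r in top] == ["b", "a", "c"]  # tie: larger |score| first

    def test_n_one(self):
        assert top_modules(self._results(), n=1, direction="down")[0].module == "d"
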