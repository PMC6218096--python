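"""TAD model, contact enrichment, Mantel, odds ratios, MITEs, 6mA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from patchwork import linkage as lk
from patchwork import synthetic as syn
from patchwork.io_formats import GenomeSequence
from tests_helpers_matrix import matrix_from_dense


def _grid_genes(n, spacing=2_000, glen=1_000, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * spacing,
            "end": np.arange(n) * spacing + glen,
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
        }
    )


def _grid_tads(n_tads, span, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_tads) * span,
            "end": (np.arange(n_tads) + 1) * span,
            "tad_id": [f"{chrom}.{i}" for i in range(n_tads)],
            "label": "TAD",
        }
    )


class TestTadModel:
    def test_planted_effects_recovered(self):
        genes = _grid_genes(300)
        tads = _grid_tads(20, 30_000)
        p = syn.ExpressionSimParams(tad_effect_sd=1.0, residual_sd=0.1, seed=3)
        sim = syn.simulate_expression(genes, tads, None, p)
        res = lk.tad_coregulation_model(sim.table)
        assert res.delta_aic > 0
        est = res.table.set_index("tad_id")["estimate"]
        common = est.index.intersection(sim.tad_effects.index)
        r = np.corrcoef(est[common], sim.tad_effects[common])[0, 1]
        assert r > 0.9

    def test_delta_aic_invariant_to_lfc_shift(self):
        genes = _grid_genes(200)
        tads = _grid_tads(10, 40_000)
        p = syn.ExpressionSimParams(tad_effect_sd=0.5, residual_sd=0.5, seed=5)
        tab = syn.simulate_expression(genes, tads, None, p).table
        a = lk.tad_coregulation_model(tab).delta_aic
        tab2 = tab.copy()
        tab2["lfc"] = tab2["lfc"] + 17.3
        b = lk.tad_coregulation_model(tab2).delta_aic
        assert a == pytest.approx(b, abs=1e-6)

    def test_single_tad_unidentifiable(self):
        genes = _grid_genes(50)
        tads = _grid_tads(1, 200_000)
        tab = syn.simulate_expression(
            genes, tads, None, syn.ExpressionSimParams(seed=1)
        ).table
        with pytest.raises(ValueError, match="unidentifiable"):
            lk.tad_coregulation_model(tab)

    def test_small_tads_dropped_and_flagged(self):
        genes = _grid_genes(41)
        # one TAD holds a single gene
        tads = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [0, 2_000, 42_000],
                "end": [2_000, 42_000, 82_000],
                "tad_id": ["chr1.0", "chr1.1", "chr1.2"],
                "label": "TAD",
            }
        )
        tab = syn.simulate_expression(
            genes, tads, None, syn.ExpressionSimParams(seed=2)
        ).table
        res = lk.tad_coregulation_model(tab)
        assert "chr1.0" in res.dropped_tads
        assert "chr1.0" not in set(res.table["tad_id"])

    def test_null_false_positive_rate_at_fdr(self):
        """Without planted effects, ~1% of TADs are flagged at FDR 0.01."""
        genes = _grid_genes(300)
        tads = _grid_tads(20, 30_000)
        n_sig = 0
        n_tads = 0
        for seed in range(60):
            p = syn.ExpressionSimParams(tad_effect_sd=0.0, residual_sd=1.0, seed=seed)
            tab = syn.simulate_expression(genes, tads, None, p).table
            res = lk.tad_coregulation_model(tab, fdr=0.01)
            n_sig += int(res.table["significant"].sum())
            n_tads += len(res.table)
        # binomial(1200, 0.01): mean 12, sd ~3.4; stay within ~4 sd
        assert n_sig / n_tads < 0.025


class TestEnrichment:
    def _uniform_setup(self, n_genes=60, seed=0):
        rng = np.random.default_rng(seed)
        genes = _grid_genes(n_genes, spacing=5_000, glen=2_000)
        n_bins = int(genes["end"].max() // 5_000 + 1)
        dense = np.full((n_bins, n_bins), 4.0)
        mat = matrix_from_dense(dense, {"chr1": n_bins * 5_000}, 5_000)
        expr = pd.DataFrame(
            {"gene_id": genes["gene_id"], "mean_expr": rng.lognormal(2, 1, n_genes)}
        )
        return mat, genes, expr

    def test_whole_gene_universe_has_zero_excess(self):
        mat, genes, expr = self._uniform_setup()
        res = lk.gene_set_contact_enrichment(
            mat, genes, expr, fraction=1.0, n_perm=50, seed=1
        )
        ok = res.table["defined"]
        assert np.allclose(res.table.loc[ok, "excess"], 0.0, atol=1e-12)

    def test_uniform_contacts_calibrated(self):
        """Random sets on a uniform map stay inside the 95% envelope ~95% of
        the time (pooled over seeds and defined bins)."""
        inside = 0
        total = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            genes = _grid_genes(60, spacing=5_000, glen=2_000)
            n_bins = int(genes["end"].max() // 5_000 + 1)
            upper = np.triu(rng.poisson(6, (n_bins, n_bins)).astype(float))
            dense = upper + np.triu(upper, 1).T
            mat = matrix_from_dense(dense, {"chr1": n_bins * 5_000}, 5_000)
            expr = pd.DataFrame(
                {"gene_id": genes["gene_id"], "mean_expr": rng.lognormal(2, 1, 60)}
            )
            res = lk.gene_set_contact_enrichment(
                mat, genes, expr, fraction=0.2, n_perm=150, seed=seed
            )
            t = res.table[res.table["defined"]]
            inside += int(
                ((t["observed"] >= t["envelope_low"]) & (t["observed"] <= t["envelope_high"])).sum()
            )
            total += len(t)
        assert 0.90 <= inside / total <= 0.99

    def test_planted_trans_boost_detected(self):
        """Extra trans contacts among a marked set push the trans bin outside
        the envelope while mid-range cis bins stay inside."""
        rng = np.random.default_rng(10)
        genes = pd.concat(
            [
                _grid_genes(40, spacing=5_000, glen=2_000, chrom="chr1"),
                _grid_genes(40, spacing=5_000, glen=2_000, chrom="chr2").assign(
                    gene_id=lambda d: "h" + d["gene_id"]
                ),
            ],
            ignore_index=True,
        )
        n_per = 40
        lengths = {"chr1": n_per * 5_000, "chr2": n_per * 5_000}
        n = 2 * n_per
        upper = np.triu(rng.poisson(5, (n, n)).astype(float))
        dense = upper + np.triu(upper, 1).T
        marked = rng.choice(len(genes), size=16, replace=False)
        marked_ids = genes["gene_id"].iloc[marked]
        bins = (genes["start"].to_numpy() + 1_000) // 5_000 + np.where(
            genes["chrom"] == "chr2", n_per, 0
        )
        for a, b in itertools.combinations(sorted(marked), 2):
            if genes["chrom"].iloc[a] != genes["chrom"].iloc[b]:
                i, j = int(bins[a]), int(bins[b])
                dense[i, j] += 40
                dense[j, i] += 40
        mat = matrix_from_dense(dense, lengths, 5_000)
        expr = pd.DataFrame(
            {"gene_id": genes["gene_id"], "mean_expr": rng.lognormal(2, 1, len(genes))}
        )
        res = lk.gene_set_contact_enrichment(
            mat, genes, expr, n_perm=300, seed=2, gene_set=pd.Index(marked_ids)
        )
        t = res.table.set_index("distance_bin")
        assert t.loc["trans", "observed"] > t.loc["trans", "envelope_high"]
        # mid-range cis distances carry no planted signal
        mid = t.loc["cis_20_200kb"]
        assert mid["envelope_low"] <= mid["observed"] <= mid["envelope_high"]

    def test_small_fraction_rejected(self):
        mat, genes, expr = self._uniform_setup()
        with pytest.raises(ValueError, match="fewer than 10"):
            lk.gene_set_contact_enrichment(mat, genes, expr, fraction=0.01)


class TestMantel:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        res = lk.mantel_test(d, d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_exact_p_matches_brute_force(self):
        """Monte-Carlo-free mode equals an independently coded enumeration."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            a = rng.uniform(size=(6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = rng.uniform(size=(6, 6))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            res = lk.mantel_test(a, b, exact=True)
            iu = np.triu_indices(6, 1)
            v2 = b[iu]
            r_obs = np.corrcoef(a[iu], v2)[0, 1]
            count = 0
            total = 0
            for perm in itertools.permutations(range(6)):
                p = np.asarray(perm)
                rp = np.corrcoef(a[np.ix_(p, p)][iu], v2)[0, 1]
                count += abs(rp) >= abs(r_obs) - 1e-12
                total += 1
            assert res.pvalue == pytest.approx(count / total)
            assert res.n_permutations == 720

    def test_constant_matrix_undefined(self):
        d = np.zeros((5, 5))
        res = lk.mantel_test(d, d, n_perm=9)
        assert not res.defined and np.isnan(res.r)

    def test_null_p_calibration(self):
        """Independent random matrices: P(p <= 0.05) ~ 0.05 over seeds."""
        hits = 0
        n_seeds = 400
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            a = rng.uniform(size=(7, 7))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = rng.uniform(size=(7, 7))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            res = lk.mantel_test(a, b, n_perm=199, seed=seed)
            hits += res.pvalue <= 0.05
        assert 0.02 <= hits / n_seeds <= 0.08

    def test_repeat_contact_wrapper(self, medium_genome):
        from patchwork import hic

        params = syn.HiCSimParams(n_pairs=100_000, trans_fraction=0.15, seed=3)
        pairs = syn.simulate_hic_pairs(medium_genome.blocks, medium_genome.genome, params)
        mat = hic.build_contact_matrix(pairs, medium_genome.genome)
        res = lk.mantel_repeat_contacts(
            medium_genome.blocks, mat, medium_genome.repeats, n_perm=199, seed=4
        )
        assert res.defined and abs(res.r) <= 1

    def test_too_few_regions_rejected(self):
        blocks = pd.DataFrame(
            [{"chrom": "c", "start": 0, "end": 100, "kind": "AT"}] * 3
        )
        with pytest.raises(ValueError, match="4 AT-rich"):
            lk.mantel_repeat_contacts(blocks, None, None)


class TestProximityOddsRatio:
    BLOCKS = pd.DataFrame(
        [{"chrom": "chr1", "start": 100_000, "end": 130_000, "kind": "AT"},
         {"chrom": "chr1", "start": 0, "end": 100_000, "kind": "GC"},
         {"chrom": "chr1", "start": 130_000, "end": 1_200_000, "kind": "GC"}]
    )

    def _genes_with_counts(self, a, b, c, d):
        """a near/class, b far/class, c near/other, d far/other."""
        rows = []
        gid = 0

        def add(near, is_class, n):
            nonlocal gid
            for _ in range(n):
                start = 95_000 if near else 500_000 + gid * 100
                rows.append(
                    {
                        "gene_id": f"g{gid}", "chrom": "chr1",
                        "start": start, "end": start + 50,
                        "strand": "+", "is_class": is_class,
                    }
                )
                gid += 1

        add(True, True, a)
        add(False, True, b)
        add(True, False, c)
        add(False, False, d)
        return pd.DataFrame(rows)

    def test_closed_form_hand_example(self):
        genes = self._genes_with_counts(20, 80, 10, 90)
        res = lk.proximity_odds_ratio(genes, genes["is_class"], self.BLOCKS)
        assert res.odds_ratio == pytest.approx((20 * 90) / (80 * 10), abs=1e-6)
        assert res.counts == {"class_near": 20, "class_far": 80,
                              "other_near": 10, "other_far": 90}
        assert res.ci_low < 2.25 < res.ci_high

    def test_logistic_equals_cross_product_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a, b, c, d = rng.integers(5, 60, size=4)
            genes = self._genes_with_counts(int(a), int(b), int(c), int(d))
            res = lk.proximity_odds_ratio(genes, genes["is_class"], self.BLOCKS)
            assert res.odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_degenerate_table_corrected(self):
        genes = self._genes_with_counts(15, 0, 10, 90)
        res = lk.proximity_odds_ratio(genes, genes["is_class"], self.BLOCKS)
        assert res.corrected and np.isfinite(res.odds_ratio)

    def test_null_coverage_of_ci(self):
        """Class independent of proximity: the 95% CI covers 1 in ~95% of seeds."""
        cover = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            near = rng.random(400) < 0.3
            is_class = rng.random(400) < 0.25
            genes = pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(400)],
                    "chrom": "chr1",
                    "start": np.where(near, 95_000, 500_000 + np.arange(400) * 10),
                    "end": np.where(near, 95_050, 500_050 + np.arange(400) * 10),
                    "strand": "+",
                }
            )
            res = lk.proximity_odds_ratio(genes, is_class, self.BLOCKS)
            cover += res.ci_low <= 1.0 <= res.ci_high
        assert 0.90 <= cover / n_seeds <= 0.99


class TestMiteEnrichment:
    def test_planted_threefold_recovered(self):
        plan = syn.default_block_plan(n_chromosomes=4, genome_size=10_000_000, seed=41)
        g = syn.generate_blocky_genome(plan, seed=41, mite_near_gene_rate=0.2)
        mites = g.repeats[g.repeats["repeat_class"] == "MITE"]
        assert len(g.genes) >= 2_000
        p = syn.ExpressionSimParams(
            tad_effect_sd=0.0, residual_sd=1.0, n_de_fraction=0.2,
            mite_fold=3.0, seed=42,
        )
        sim = syn.simulate_expression(g.genes, None, mites, p)
        res = lk.mite_enrichment(mites, g.genes, sim.table, top_fraction=0.2)
        assert 2.5 <= res.pooled_fold <= 3.5

    def test_no_mites_undefined(self):
        genes = _grid_genes(30)
        expr = pd.DataFrame({"gene_id": genes["gene_id"], "lfc": np.linspace(-1, 1, 30)})
        empty = pd.DataFrame(columns=["chrom", "start", "end", "family", "repeat_class"])
        res = lk.mite_enrichment(empty, genes, expr)
        assert len(res.family_table) == 0
        assert np.isnan(res.pooled_fold) or res.pooled_fold == 0

    def test_minus_strand_mite_registers_upstream(self):
        # gene on minus strand, MITE 500 bp 3' of its TSS coordinate -> -500
        genes = pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "start": 10_000, "end": 12_000,
              "strand": "-"},
             {"gene_id": "g2", "chrom": "chr1", "start": 30_000, "end": 32_000,
              "strand": "+"}]
        )
        # TSS of g1 is 11_999; MITE mid at 12_499 -> rel = -(12_499-11_999) = -500
        mites = pd.DataFrame(
            [{"chrom": "chr1", "start": 12_449, "end": 12_549, "family": "M",
              "repeat_class": "MITE"}]
        )
        expr = pd.DataFrame({"gene_id": ["g1", "g2"], "lfc": [2.0, -1.0]})
        res = lk.mite_enrichment(mites, genes, expr, quantiles=2, top_fraction=0.5)
        top_profile = res.profile[(res.profile["quantile"] == 1)]
        row = top_profile[(top_profile["pos_low"] <= -500) & (top_profile["pos_high"] > -500)]
        assert row["density_quantile"].iloc[0] == 1.0

    def test_gene_without_strand_excluded(self):
        genes = pd.DataFrame(
            [{"gene_id": "g1", "chrom": "chr1", "start": 0, "end": 100, "strand": "."},
             {"gene_id": "g2", "chrom": "chr1", "start": 200, "end": 300, "strand": "+"}]
        )
        expr = pd.DataFrame({"gene_id": ["g1", "g2"], "lfc": [1.0, 0.0]})
        mites = pd.DataFrame(columns=["chrom", "start", "end", "family", "repeat_class"])
        res = lk.mite_enrichment(mites, genes, expr)
        assert res.n_excluded_no_strand == 1


class TestMethylationSummary:
    def test_hand_built_toy(self):
        # 100 bp with known adenine count; 2 passing + 1 failing call
        seq = ("A" * 20 + "C" * 30 + "T" * 20 + "G" * 30)
        genome = GenomeSequence({"chr1": seq})
        blocks = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100, "kind": "AT"}])
        calls = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 0, "strand": "+", "modqv": 30.0},
                {"chrom": "chr1", "pos": 55, "strand": "-", "modqv": 25.0},
                {"chrom": "chr1", "pos": 1, "strand": "+", "modqv": 10.0},
            ]
        )
        out = lk.methylation_summary(calls, blocks, None, genome)
        assert out["n_adenines"]["AT"] == 40
        assert out["n_calls_passing"]["AT"] == 2
        assert out["fraction_modified"]["AT"] == pytest.approx(0.05)

    def test_zero_calls(self):
        genome = GenomeSequence({"chr1": "ACGT" * 25})
        blocks = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100, "kind": "GC"}])
        out = lk.methylation_summary(
            pd.DataFrame(columns=["chrom", "pos", "strand", "modqv"]), blocks, None, genome
        )
        assert out["fraction_modified"]["GC"] == 0.0

    def test_non_adenine_call_rejected(self):
        genome = GenomeSequence({"chr1": "CCCC"})
        blocks = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 4, "kind": "GC"}])
        calls = pd.DataFrame([{"chrom": "chr1", "pos": 1, "strand": "+", "modqv": 40.0}])
        with pytest.raises(ValueError, match="chr1:1"):
            lk.methylation_summary(calls, blocks, None, genome)

    def test_uniform_simulation_even_between_compartments(self, medium_genome):
        calls = syn.simulate_mod_calls(
            medium_genome.genome, medium_genome.blocks,
            rate_at=2e-3, rate_gc=2e-3, seed=6,
        )
        out = lk.methylation_summary(calls, medium_genome.blocks, None, medium_genome.genome)
        f_at, f_gc = out["fraction_modified"]["AT"], out["fraction_modified"]["GC"]
        n = min(out["n_adenines"]["AT"], out["n_adenines"]["GC"])
        sd = np.sqrt(2e-3 / n) * 2
        assert abs(f_at - f_gc) < 4 * np.sqrt(2e-3 * (1 - 2e-3) * (1 / out["n_adenines"]["AT"] + 1 / out["n_adenines"]["GC"]))

    def test_apg_context_readout(self):
        genome = GenomeSequence({"chr1": "AAGT" + "C" * 20})
        blocks = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 24, "kind": "GC"}])
        calls = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 1, "strand": "+", "modqv": 40.0},  # ApG
                {"chrom": "chr1", "pos": 3, "strand": "-", "modqv": 40.0},  # A on -, next is comp(G)=C
            ]
        )
        out = lk.methylation_summary(calls, blocks, None, genome)
        ctx = out["context_breakdown"].set_index("context")["n"].to_dict()
        assert ctx.get("ApG") == 1 and ctx.get("ApC") == 1
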