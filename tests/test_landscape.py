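import numpy as np
import pandas as pd
import pytest

from txscape import landscape as land
from txscape.model import Feature, FeatureTable, Genome, TxscapeError, jaccard
from txscape.quantify import ExpressionTable


def expr_table(tpms, ids=None):
    ids = ids or [f"G{i}" for i in range(len(tpms))]
    return ExpressionTable(
        pd.DataFrame(
            {
                "feature_id": ids,
                "length": [900] * len(tpms),
                "count": [max(0, int(t)) for t in tpms],
                "tpm": tpms,
                "is_cds": True,
            }
        )
    )


def gene_row(n, glen=900, gap=100, ids=None, hyp=None, arcog=None):
    feats = []
    pos = 0
    for i in range(n):
        feats.append(
            Feature(
                (ids or [f"G{i}" for i in range(n)])[i],
                "CDS",
                pos,
                pos + glen,
                "+",
                "hypothetical protein" if hyp and hyp[i] else "protein",
                bool(hyp[i]) if hyp else False,
                arcog[i] if arcog else None,
            )
        )
        pos += glen + gap
    return FeatureTable(feats)


class TestGcTrack:
    def test_uniform_genome_no_deviants(self):
        g = Genome(id="u", sequence="ACGT" * 5000)
        track = land.gc_track(g, window=1000, step=200)
        assert all(w.value == 0.5 for w in track)
        assert all(w.z == 0.0 for w in track)
        assert land.call_deviant_regions(track) == []

    def test_window_equal_to_genome(self):
        g = Genome(id="u", sequence="ACGT" * 100)
        track = land.gc_track(g, window=400, step=100)
        assert len(track) == 1
        assert land.call_deviant_regions(track) == []

    def test_window_too_small_rejected(self):
        g = Genome(id="u", sequence="ACGT" * 100)
        with pytest.raises(TxscapeError, match="50"):
            land.gc_track(g, window=20)

    def test_window_beyond_genome_rejected(self):
        g = Genome(id="u", sequence="ACGT" * 10)
        with pytest.raises(TxscapeError):
            land.gc_track(g, window=100)

    def test_n_bases_excluded(self):
        g = Genome(id="u", sequence="GCGC" + "N" * 96 + "AT" * 200)
        track = land.gc_track(g, window=100, step=100)
        assert track[0].value == pytest.approx(1.0)  # 4 GC over 4 non-N bases

    def test_planted_island_windows_flagged(self):
        # +15-point island of 10 kb in a 300-kb background
        rng = np.random.default_rng(123)
        L, s, e = 300_000, 150_000, 160_000
        p = np.full(L, 0.45)
        p[s:e] += 0.15
        seq = np.where(rng.random(L) < p, "G", "A")
        g = Genome(id="p", sequence="".join(seq))
        track = land.gc_track(g)
        inside = [w for w in track if w.start >= s and w.end <= e]
        assert inside and all(w.z > 2.5 for w in inside)
        calls = land.call_deviant_regions(track)
        assert jaccard([(c.start, c.end) for c in calls], [(s, e)]) >= 0.8

    def test_adjacent_flagged_windows_merge(self):
        from txscape.model import WindowStat

        track = [
            WindowStat(0, 5000, 0.5, 0.1),
            WindowStat(1000, 6000, 0.6, 3.0),
            WindowStat(2000, 7000, 0.6, 2.8),
            WindowStat(3000, 8000, 0.5, 0.2),
            WindowStat(20000, 25000, 0.7, 4.0),
        ]
        calls = land.call_deviant_regions(track)
        assert len(calls) == 2
        assert calls[0].start == 3500 and calls[0].end == 4500  # center span
        assert calls[0].score == 3.0


class TestHypotheticalDensity:
    def test_all_hypothetical_is_hundred(self):
        t = gene_row(30, hyp=[True] * 30)
        track = land.hypothetical_density(t, gene_window=10)
        assert all(w.value == 100.0 for w in track)

    def test_alternation_is_fifty(self):
        t = gene_row(30, hyp=[i % 2 == 0 for i in range(30)])
        track = land.hypothetical_density(t, gene_window=10)
        assert all(w.value == 50.0 for w in track)

    def test_fewer_genes_than_window_single_window(self):
        t = gene_row(7, hyp=[True, False, True, False, False, False, True])
        track = land.hypothetical_density(t, gene_window=100)
        assert len(track) == 1
        assert track[0].value == pytest.approx(100 * 3 / 7)

    def test_planted_enrichment_visible(self, sim, small_config):
        track = land.hypothetical_density(sim.features, gene_window=15)
        block = sim.truth.low_expression_blocks[0]
        inside = [
            w for w in track if w.start >= block["start"] and w.end <= block["end"]
        ]
        background = np.median([w.value for w in track])
        assert inside
        assert np.median([w.value for w in inside]) > background + 20


class TestLowExpressionRegions:
    def test_uniform_expression_no_regions(self):
        t = gene_row(300)
        table = expr_table([50.0] * 300)
        assert land.low_expression_regions(table, t) == []

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(9)
        n = 2000
        tpms = rng.lognormal(3, 0.6, size=n)
        tpms[900:1100] *= 0.02
        t = gene_row(n)
        calls = land.low_expression_regions(expr_table(list(tpms)), t)
        assert len(calls) == 1
        truth = (t[900].start, t[1099].end)
        called = (calls[0].start, calls[0].end)
        ov = max(0, min(truth[1], called[1]) - max(truth[0], called[0]))
        assert ov / (truth[1] - truth[0]) >= 0.9

    def test_two_blocks_two_regions(self):
        rng = np.random.default_rng(10)
        n = 3000
        tpms = rng.lognormal(3, 0.6, size=n)
        tpms[700:850] *= 0.02
        tpms[2000:2150] *= 0.02
        t = gene_row(n)
        calls = land.low_expression_regions(expr_table(list(tpms)), t)
        assert len(calls) == 2


class TestPositionalShares:
    def test_uniform_even_split(self):
        t = gene_row(40)
        L = t[39].end + 100
        shares = land.positional_shares(expr_table([10.0] * 40), t, 4, L)
        assert shares == pytest.approx([25, 25, 25, 25], abs=0.5)

    def test_concentrated_first_quarter(self):
        t = gene_row(40)
        L = t[39].end + 100
        tpms = [0.0] * 40
        tpms[2] = 1e6
        shares = land.positional_shares(expr_table(tpms), t, 4, L)
        assert shares == pytest.approx([100, 0, 0, 0])

    def test_shares_sum_conserved(self):
        rng = np.random.default_rng(3)
        t = gene_row(57)
        L = t[56].end + 100
        tpms = list(rng.exponential(30, size=57))
        shares = land.positional_shares(expr_table(tpms), t, 4, L)
        assert sum(shares) == pytest.approx(100, abs=1e-9)

    def test_exclude_top_changes_shares(self):
        t = gene_row(40)
        L = t[39].end + 100
        tpms = [1.0] * 40
        tpms[0] = 1000.0
        full = land.positional_shares(expr_table(tpms), t, 2, L)
        trimmed = land.positional_shares(expr_table(tpms), t, 2, L, exclude_top=1)
        assert full[0] > 90
        assert trimmed == pytest.approx([50, 50], abs=2)

    def test_parts_validation(self):
        t = gene_row(5)
        with pytest.raises(TxscapeError):
            land.positional_shares(expr_table([1.0] * 5), t, 1, 10_000)


class TestArcogSummary:
    def test_hand_built_medians(self):
        t = gene_row(6, arcog=["C", "C", "C", "J", "J", "J"])
        table = expr_table([10.0, 100.0, 1000.0, 1.0, 1.0, 1.0])
        out = land.arcog_summary(table, t, pseudocount=0.0)
        by = out.set_index("arcog")
        assert by.loc["C", "median"] == pytest.approx(np.log10(100.0))
        assert by.loc["C", "n"] == 3
        assert by.loc["J", "median"] == pytest.approx(0.0)

    def test_single_category_median_is_global(self):
        t = gene_row(5, arcog=["M"] * 5)
        table = expr_table([1.0, 2.0, 3.0, 4.0, 5.0])
        out = land.arcog_summary(table, t, pseudocount=0.1)
        assert out.loc[0, "median"] == pytest.approx(np.log10(3.1))

    def test_top_n_drops_small_categories(self):
        t = gene_row(8, arcog=["C"] * 5 + ["J"] * 3)
        table = expr_table([100, 90, 80, 70, 60, 50, 2, 1])
        out = land.arcog_summary(table, t, top_n=6)
        assert list(out["arcog"]) == ["C"]  # J has only 1 gene in the top 6

    def test_requires_annotations(self):
        t = gene_row(4)
        with pytest.raises(TxscapeError, match="arCOG"):
            land.arcog_summary(expr_table([1.0] * 4), t)
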