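import numpy as np
import pytest

from txscape.model import CoverageTrack, Feature, FeatureTable, RegionCall
from txscape.units import call_islands, infer_units, unit_evidence_table


def cluster(gaps, start=1000, glen=600, strand=None):
    """Build consecutive CDS separated by the given gaps (may be negative)."""
    feats = []
    pos = start
    for i in range(len(gaps) + 1):
        feats.append(
            Feature(f"g{i + 1}", "CDS", pos, pos + glen,
                    (strand[i] if strand else "+"))
        )
        pos += glen + (gaps[i] if i < len(gaps) else 0)
    return FeatureTable(feats)


def coverage_for(table, depths, L=20_000):
    vals = np.zeros(L, dtype=np.int64)
    for f, d in zip(table.cds, depths):
        vals[f.start: f.end] = d
    return CoverageTrack(vals)


class TestInferUnits:
    def test_atp_like_cluster_adjacency_only(self):
        # gaps -3, -13, 2, 24 within the cluster, then a 250-nt spacer
        table = cluster([-3, -13, 2, 24, 250])
        units = infer_units(table)
        members = [u.members for u in units]
        assert members == [("g1", "g2", "g3", "g4", "g5"), ("g6",)]

    def test_atp_like_cluster_coverage_split(self):
        # the first gene is ~10x the rest: the -3-linked terminal pair is
        # split off as a monocistronic unit, giving three units in total
        table = cluster([-3, -13, 2, 24, 250])
        cov = coverage_for(table, [100, 10, 10, 10, 10, 10])
        units = infer_units(table, cov)
        members = [u.members for u in units]
        assert members == [("g1",), ("g2", "g3", "g4", "g5"), ("g6",)]

    def test_opposite_strands_never_merge(self):
        table = cluster([0, 0], strand=["+", "-", "+"])
        units = infer_units(table)
        assert [len(u.members) for u in units] == [1, 1, 1]

    def test_gap_exactly_gap_max_merges(self):
        table = cluster([30])
        assert len(infer_units(table, gap_max=30)) == 1
        assert len(infer_units(cluster([31]), gap_max=30)) == 2

    def test_even_coverage_not_split(self):
        table = cluster([5, 5, 5])
        cov = coverage_for(table, [10, 11, 9, 10])
        assert len(infer_units(table, cov)) == 1

    def test_units_partition_cds(self, sim):
        units = infer_units(sim.features)
        seen = [m for u in units for m in u.members]
        cds_ids = [f.feature_id for f in sim.features.cds]
        assert sorted(seen) == sorted(cds_ids)
        assert len(seen) == len(set(seen))

    def test_generator_operons_recovered(self, sim):
        from txscape.simulate import _coverage_of

        cov = _coverage_of(sim.fragments["light"], sim.genome.length)
        units = infer_units(sim.features, cov)
        inferred = {u.members for u in units}
        truth = {tuple(m) for m in sim.truth.units}
        agree = len(inferred & truth) / len(truth)
        assert agree >= 0.95

    def test_evidence_table_shape(self, sim):
        units = infer_units(sim.features)
        df = unit_evidence_table(units, sim.features, None)
        assert len(df) == len(units)
        assert df["n_genes"].sum() == len(sim.features.cds)


class TestCallIslands:
    def _features(self):
        return FeatureTable(
            [
                Feature("A", "CDS", 1000, 2000, "+"),
                Feature("B", "CDS", 9000, 9900, "+"),
            ]
        )

    def test_zero_coverage_warns_empty(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = call_islands(
                CoverageTrack(np.zeros(20_000, dtype=np.int64)), self._features()
            )
        assert out == []

    def test_planted_island_exact_bounds(self):
        vals = np.zeros(20_000, dtype=np.int64)
        vals[1000:2000] = 10  # expressed CDS A
        vals[9000:9900] = 10  # expressed CDS B -> median CDS depth 10
        vals[5000:5080] = 500  # 80-nt island at 50x
        calls = call_islands(CoverageTrack(vals), self._features())
        assert len(calls) == 1
        assert abs(calls[0].start - 5000) <= 2 and abs(calls[0].end - 5080) <= 2
        assert calls[0].score == pytest.approx(500)

    def test_short_island_filtered(self):
        vals = np.zeros(20_000, dtype=np.int64)
        vals[1000:2000] = 10
        vals[9000:9900] = 10
        vals[5000:5020] = 500  # 20 nt < min_len
        assert call_islands(CoverageTrack(vals), self._features()) == []

    def test_long_island_filtered(self):
        vals = np.zeros(20_000, dtype=np.int64)
        vals[1000:2000] = 10
        vals[9000:9900] = 10
        vals[4000:4700] = 500  # 700 nt > max_len
        assert call_islands(CoverageTrack(vals), self._features()) == []

    def test_covered_utr_excluded(self):
        vals = np.zeros(20_000, dtype=np.int64)
        vals[1000:2000] = 10
        vals[9000:9900] = 10
        vals[2000:2100] = 200  # hot 3' UTR of A
        utr = [RegionCall("utr", 2000, 2100, 200.0)]
        assert call_islands(CoverageTrack(vals), self._features(), utr) == []

    def test_continuation_of_covered_signal_dropped(self):
        # run flush against an annotated gene whose boundary is still hot:
        # a clipped tail, not a detached island
        feats = FeatureTable(
            [
                Feature("A", "CDS", 1000, 2000, "+"),
                Feature("B", "CDS", 9000, 9900, "+"),
                Feature("C", "CDS", 15000, 15900, "+"),
            ]
        )
        vals = np.zeros(20_000, dtype=np.int64)
        vals[1000:2000] = 400  # gene A very hot
        vals[2000:2090] = 400  # tail continuing past its end
        vals[9000:9900] = 10
        vals[15000:15900] = 10  # median CDS depth 10 -> threshold 50
        assert call_islands(CoverageTrack(vals), feats) == []

    def test_islands_never_overlap_annotation(self, sim):
        from txscape.simulate import _coverage_of

        cov = _coverage_of(sim.fragments["light"], sim.genome.length)
        calls = call_islands(cov, sim.features)
        for c in calls:
            for f in sim.features:
                assert c.end <= f.start or c.start >= f.end

    def test_planted_islands_recovered(self, sim):
        from txscape.simulate import _coverage_of

        cov = _coverage_of(sim.fragments["light"], sim.genome.length)
        calls = call_islands(cov, sim.features)
        hit = 0
        for s, e in sim.truth.island_coords:
            if any(c.start < e and c.end > s for c in calls):
                hit += 1
        assert hit == len(sim.truth.island_coords)
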