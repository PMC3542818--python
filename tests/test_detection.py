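import numpy as np
import pytest

from nucleoscan.center_model import beta_offset_pmf
from nucleoscan.detection import (
    NStatTrack,
    candidates,
    detect_chromosome,
    detect_genome,
    group_reads,
    n_statistic,
    plan_chunks,
)
from nucleoscan.formats_io import GenomeTable
from nucleoscan.synthetic import genome_for
from nucleoscan.triangle import TriangleTrack, WindowPartition


def track_of(values, chrom="c", start=1):
    return TriangleTrack(
        chrom=chrom, start_offset=start, t_values=np.asarray(values, dtype=float)
    )


def brute_force_n(t, t_c):
    """Shifted-array evaluation of the N-statistic product formula.

    Independent of the implementation's sparse candidate loop: every
    indicator factor is materialized as a full boolean array.
    """
    t = np.asarray(t, dtype=float)
    n = len(t)
    pad = np.concatenate([np.zeros(78), t, np.zeros(78)])
    ok = t >= t_c
    for d in range(1, 26):  # left factors, strict
        ok &= pad[78 - d : 78 - d + n] < t
    for d in range(1, 27):  # right factors, non-strict
        ok &= t >= pad[78 + d : 78 + d + n]
    ins_r = np.zeros(n)
    for d in range(69, 79):
        ins_r += pad[78 + d : 78 + d + n]
    ins_l = np.zeros(n)
    for d in range(68, 78):
        ins_l += pad[78 - d : 78 - d + n]
    ok &= ins_r <= 10.0
    ok &= ins_l <= 10.0
    return ok.astype(np.uint8)


class TestNStatistic:
    def test_single_strict_maximum(self):
        t = np.full(300, 0.1)
        t[150] = 2.0
        n = n_statistic(track_of(t), 1.7).n_values
        assert n[150] == 1
        assert n.sum() == 1

    def test_equal_adjacent_maxima_leftmost_wins(self):
        t = np.full(300, 0.1)
        t[150] = t[151] = 2.0
        n = n_statistic(track_of(t), 1.7).n_values
        assert n[150] == 1
        assert n[151] == 0
        assert n.sum() == 1

    def test_all_below_cutoff(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 1.69, size=500)
        n = n_statistic(track_of(t), 1.7).n_values
        assert n.sum() == 0

    def test_insurance_sum_blocks_call(self):
        # a qualifying peak with a big clump of statistics 72 windows right:
        # sum over offsets +69..+78 exceeds 10, so the peak must not fire
        t = np.full(400, 0.1)
        t[200] = 2.0
        t[200 + 72] = 1.5  # within [i+69, i+78]
        t[200 + 73] = 9.0
        assert brute_force_n(t, 1.7)[200] == 0
        n = n_statistic(track_of(t), 1.7).n_values
        assert n[200] == 0

    def test_insurance_sum_below_threshold_allows_call(self):
        t = np.full(400, 0.1)
        t[200] = 2.0
        t[200 + 72] = 1.5
        assert brute_force_n(t, 1.7)[200] == 1
        n = n_statistic(track_of(t), 1.7).n_values
        assert n[200] == 1

    def test_peak_at_track_edge_still_callable(self):
        t = np.full(100, 0.1)
        t[0] = 2.0
        n = n_statistic(track_of(t), 1.7).n_values
        assert n[0] == 1
        t = np.full(100, 0.1)
        t[99] = 2.0
        n = n_statistic(track_of(t), 1.7).n_values
        assert n[99] == 1

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            n_statistic(track_of([1.0]), 0.0)

    def test_empty_track(self):
        n = n_statistic(track_of([]), 1.7).n_values
        assert len(n) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            t = rng.uniform(0, 2.2, size=160)
            spikes = rng.random(160) < 0.02
            t[spikes] *= 4
            expected = brute_force_n(t, 1.7)
            got = n_statistic(track_of(t), 1.7).n_values
            assert np.array_equal(got, expected)

    def test_fires_at_least_26_windows_apart(self):
        # two calls closer than 26 are impossible: the left call's
        # right-hand span enforces t_i >= t_j while the right call's
        # left-hand span enforces t_i < t_j
        rng = np.random.default_rng(77)
        for _ in range(200):
            t = rng.uniform(0, 2.5, size=300)
            n = n_statistic(track_of(t), 1.7).n_values
            fired = np.nonzero(n)[0]
            assert all(b - a >= 26 for a, b in zip(fired, fired[1:]))

    def test_plateau_fires_exactly_leftmost(self):
        t = np.full(300, 0.1)
        t[140:160] = 3.0  # 20-wide plateau
        n = n_statistic(track_of(t), 1.7).n_values
        assert np.nonzero(n)[0].tolist() == [140]


class TestCandidates:
    def test_center_convention(self):
        t = np.zeros(1000)
        t[900] = 2.0  # window start coordinate 901
        track = track_of(t)
        nstat = NStatTrack(chrom="c", n_values=(t >= 1.7).astype(np.uint8))
        out = candidates(track, nstat, WindowPartition())
        assert len(out) == 1
        assert out[0].center == 1001
        assert out[0].t_stat == 2.0

    def test_no_nonzero_n(self):
        track = track_of(np.zeros(100))
        nstat = NStatTrack(chrom="c", n_values=np.zeros(100, dtype=np.uint8))
        assert candidates(track, nstat) == []

    def test_two_calls_keep_spacing(self):
        t = np.zeros(500)
        nv = np.zeros(500, dtype=np.uint8)
        t[100] = t[160] = 2.0
        nv[100] = nv[160] = 1
        out = candidates(track_of(t), NStatTrack(chrom="c", n_values=nv))
        assert [c.center for c in out] == [201, 261]

    def test_misaligned_tracks_rejected(self):
        with pytest.raises(ValueError):
            candidates(
                track_of(np.zeros(10)),
                NStatTrack(chrom="c", n_values=np.zeros(9, dtype=np.uint8)),
            )


class TestPlanChunks:
    def test_two_core_tiling(self):
        genome = GenomeTable([("c", 10_000)])
        plan = plan_chunks(genome, target_interval=5_000)
        chunks = plan.for_chrom("c")
        assert len(chunks) == 2
        assert chunks[0].core_start == 1
        assert chunks[0].core_end == 5_000
        assert chunks[1].core_start == 5_001
        assert chunks[1].core_end == 10_000
        # flanks of at least W + 103 where in-bounds
        assert chunks[0].start == 1
        assert chunks[0].end == 5_000 + 303
        assert chunks[1].start == 5_001 - 303
        assert chunks[1].end == 10_000

    def test_short_chromosome_single_chunk(self):
        genome = GenomeTable([("c", 2_000)])
        plan = plan_chunks(genome, target_interval=5_000)
        chunks = plan.for_chrom("c")
        assert len(chunks) == 1
        assert (chunks[0].core_start, chunks[0].core_end) == (1, 2_000)

    def test_cores_tile_without_gaps(self):
        genome = GenomeTable([("c", 123_457)])
        plan = plan_chunks(genome, target_interval=10_000)
        chunks = plan.for_chrom("c")
        assert chunks[0].core_start == 1
        assert chunks[-1].core_end == 123_457
        for a, b in zip(chunks, chunks[1:]):
            assert b.core_start == a.core_end + 1

    def test_target_interval_validated(self):
        genome = GenomeTable([("c", 10_000)])
        with pytest.raises(ValueError):
            plan_chunks(genome, target_interval=100)


class TestChunkedEqualsSerial:
    def test_planted_fixture(self, planted, planted_genome, default_pmf):
        spec, reads, _ = planted
        part = WindowPartition()
        serial = detect_chromosome(
            reads, spec.chrom, spec.chrom_length, default_pmf, part, 1.7
        )
        by = group_reads(reads)
        for target in (5_000, 13_333, 50_000):
            chunked = detect_genome(
                by,
                planted_genome,
                default_pmf,
                part,
                t_c=1.7,
                threads=1,
                target_interval=target,
            )
            assert [c.center for c in chunked] == [c.center for c in serial]
            assert np.allclose(
                [c.t_stat for c in chunked],
                [c.t_stat for c in serial],
                rtol=1e-9,
            )

    def test_parallel_equals_single_worker(self, planted, planted_genome, default_pmf):
        _, reads, _ = planted
        by = group_reads(reads)
        runs = [
            detect_genome(
                by,
                planted_genome,
                default_pmf,
                t_c=1.7,
                threads=T,
                target_interval=5_000,
            )
            for T in (1, 4)
        ]
        assert [(c.center, c.t_stat) for c in runs[0]] == [
            (c.center, c.t_stat) for c in runs[1]
        ]

    def test_candidate_spacing_at_least_26(self, planted, planted_genome, default_pmf):
        _, reads, _ = planted
        by = group_reads(reads)
        cands = detect_genome(
            by, planted_genome, default_pmf, t_c=1.7, threads=1,
            target_interval=20_000,
        )
        centers = [c.center for c in cands]
        assert all(b - a >= 26 for a, b in zip(centers, centers[1:]))

    def test_random_reads_chunked_equals_serial(self, default_pmf):
        rng = np.random.default_rng(31)
        from nucleoscan.formats_io import ReadAlignment

        L = 30_000
        reads = [
            ReadAlignment("c", int(p), "+" if s else "-")
            for p, s in zip(
                rng.integers(100, L - 100, 3_000), rng.integers(0, 2, 3_000)
            )
        ]
        genome = GenomeTable([("c", L)])
        serial = detect_chromosome(reads, "c", L, default_pmf)
        chunked = detect_genome(
            group_reads(reads), genome, default_pmf, t_c=1.7, threads=3,
            target_interval=4_000,
        )
        assert [c.center for c in chunked] == [c.center for c in serial]
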