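import numpy as np
import pytest

from patchywave.circular import fisher_lee_corr, wrap_angle
from patchywave.motifs import (
    define_motifs,
    embed_and_score,
    psi,
    similarity_matrix,
    DISTANCE_RATIO_CAP,
)
from patchywave.phase import PhasePattern


def brute_force_motifs(C, S, R):
    """Independent set-based implementation of the repetition algorithm."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    B = np.zeros((n, n), dtype=bool)
    for j in range(n):
        for k in range(n):
            if j != k and np.isfinite(C[j, k]) and C[j, k] >= S:
                B[j, k] = True
    r = [sum(B[j]) for j in range(n)]
    r_mean = sum(r) / n
    if r_mean == 0:
        return []
    motifs = []
    members_so_far = set()
    for j in range(n):
        if r[j] / r_mean > R and j not in members_so_far:
            m = {j} | {k for k in range(n) if B[j, k]}
            motifs.append(sorted(m))
            members_so_far |= m
    return motifs


def rand_pattern(rng, n_ch=64):
    side = int(round(np.sqrt(n_ch)))
    ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    grid = np.column_stack([ii.ravel(), jj.ravel()])
    return PhasePattern(
        phase=rng.uniform(-np.pi, np.pi, n_ch), valid=np.ones(n_ch, bool),
        channel_grid=grid, test_time=0.0,
    )


class TestPSI:
    def test_identity_is_one(self):
        rng = np.random.default_rng(0)
        p = rand_pattern(rng)
        assert psi(p, p) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        rng = np.random.default_rng(1)
        p = rand_pattern(rng)
        q = rand_pattern(rng)
        q.phase = wrap_angle(-p.phase)
        assert psi(p, q) == pytest.approx(-1.0)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        p = rand_pattern(rng)
        q = rand_pattern(rng)
        val = psi(p, q)
        p.phase = wrap_angle(p.phase + 0.9)
        q.phase = wrap_angle(q.phase + 0.9)
        assert psi(p, q) == pytest.approx(val, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        p, q = rand_pattern(rng), rand_pattern(rng)
        assert psi(p, q) == pytest.approx(psi(q, p))

    def test_independent_maps_near_zero(self):
        """Monte-Carlo null: random 64-channel pairs rarely exceed |0.35|."""
        rng = np.random.default_rng(4)
        vals = [
            fisher_lee_corr(
                rng.uniform(-np.pi, np.pi, 64), rng.uniform(-np.pi, np.pi, 64)
            )
            for _ in range(1500)
        ]
        assert np.mean(np.abs(vals) < 0.35) >= 0.95

    def test_too_few_shared_channels_masked(self):
        rng = np.random.default_rng(5)
        p, q = rand_pattern(rng), rand_pattern(rng)
        p.valid[:] = False
        p.valid[:5] = True
        assert np.isnan(psi(p, q))


class TestSimilarityMatrix:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(6)
        pats = [rand_pattern(rng) for _ in range(6)]
        C = similarity_matrix(pats)
        assert np.allclose(C.values, C.values.T)
        assert np.allclose(np.diag(C.values), 1.0)

    def test_duplicated_pattern_block(self):
        rng = np.random.default_rng(7)
        p = rand_pattern(rng)
        C = similarity_matrix([p, p, p])
        assert np.allclose(C.values, 1.0)

    def test_pair_count(self):
        rng = np.random.default_rng(8)
        pats = [rand_pattern(rng) for _ in range(7)]
        C = similarity_matrix(pats)
        iu = np.triu_indices(7, k=1)
        assert iu[0].size == 7 * 6 // 2
        assert np.isfinite(C.values[iu]).all()


class TestDefineMotifs:
    def test_hand_traced_example(self):
        # patterns 0,1,2 mutually similar; 3,4 below threshold to everyone
        C = np.eye(5)
        for a in (0, 1, 2):
            for b in (0, 1, 2):
                if a != b:
                    C[a, b] = 0.9
        ms = define_motifs(C, S=0.55, R=1.2)
        assert ms.motifs == [[0, 1, 2]]

    def test_all_below_threshold(self):
        C = np.eye(4) * 1.0
        ms = define_motifs(C, S=0.55, R=3.0)
        assert ms.n_motifs == 0

    def test_anchor_in_own_motif_and_overlap_allowed(self):
        # 0-1-2 clique; 3 similar to 2 and 4 only
        C = np.eye(5)
        for a, b in [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]:
            C[a, b] = C[b, a] = 0.9
        ms = define_motifs(C, S=0.5, R=1.01)
        for anchor, members in zip(ms.anchors, ms.motifs):
            assert anchor in members

    def test_invalid_thresholds_rejected(self):
        C = np.eye(3)
        with pytest.raises(ValueError):
            define_motifs(C, S=1.5, R=3.0)
        with pytest.raises(ValueError):
            define_motifs(C, S=0.5, R=0.9)

    @pytest.mark.parametrize("S", [0.55, 0.8])
    @pytest.mark.parametrize("R", [1.5, 3.0])
    def test_matches_brute_force_small(self, S, R):
        rng = np.random.default_rng(int(S * 100) + int(R))
        for _ in range(100):
            n = rng.integers(3, 10)
            M = rng.uniform(-1, 1, (n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 1.0)
            ms = define_motifs(M, S=S, R=R)
            assert ms.motifs == brute_force_motifs(M, S, R)


class TestEmbedding:
    def _two_families(self, n_per=10, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        side = 8
        ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        grid = np.column_stack([ii.ravel(), jj.ravel()])
        base1 = rng.uniform(-np.pi, np.pi, 64)
        base2 = rng.uniform(-np.pi, np.pi, 64)
        pats = []
        for b in (base1, base2):
            for _ in range(n_per):
                pats.append(
                    PhasePattern(
                        phase=wrap_angle(b + noise * rng.standard_normal(64)),
                        valid=np.ones(64, bool), channel_grid=grid, test_time=0.0,
                    )
                )
        return pats

    def test_two_families_strongly_separated(self):
        rng = np.random.default_rng(20)
        pats = self._two_families() + [rand_pattern(rng) for _ in range(20)]
        C = similarity_matrix(pats)
        ms = define_motifs(C, S=0.55, R=1.2)
        assert ms.n_motifs == 2
        emb = embed_and_score(C, ms)
        assert emb.distance_ratio > 5.0

    def test_identical_patterns_hit_cap(self):
        rng = np.random.default_rng(9)
        p = rand_pattern(rng)
        pats = [p] * 6
        C = similarity_matrix(pats)
        ms = define_motifs(C, S=0.5, R=1.01)
        # every pattern repeats equally: r_j / mean(r) == 1, no high-repetition
        # patterns; force two degenerate motifs to exercise the cap
        from patchywave.motifs import MotifSet

        forced = MotifSet([[0, 1, 2], [3, 4, 5]], [0, 3], np.zeros(6), 0.5, 1.01, 0.0)
        emb = embed_and_score(C, forced)
        assert emb.capped and emb.distance_ratio == DISTANCE_RATIO_CAP

    def test_single_motif_ratio_undefined(self):
        pats = self._two_families(n_per=5)
        C = similarity_matrix(pats[:5] + pats[10:12])
        ms = define_motifs(C, S=0.55, R=1.2)
        if ms.n_motifs < 2:
            emb = embed_and_score(C, ms)
            assert np.isnan(emb.distance_ratio)

    def test_eigenvalues_sorted_descending(self):
        pats = self._two_families()
        C = similarity_matrix(pats)
        ms = define_motifs(C, S=0.55, R=1.2)
        emb = embed_and_score(C, ms)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)


class TestShuffleControl:
    def test_channel_shuffle_destroys_motifs(self):
        """Permuting channel positions of every pattern kills similarity."""
        rng = np.random.default_rng(10)
        pats = TestEmbedding()._two_families(n_per=8, noise=0.05, seed=11)
        for p in pats:
            p.phase = rng.permutation(p.phase)
        C = similarity_matrix(pats)
        ms = define_motifs(C, S=0.8, R=3.0, min_repeats=4)
        assert ms.n_motifs == 0
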