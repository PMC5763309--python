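import numpy as np
import pandas as pd
import pytest

from cpredictor3 import IntegrityError, spectral_clusters


def _frame(matrix, labels):
    return pd.DataFrame(matrix, index=labels, columns=labels)


def _random_sim(rng, n):
    """A random symmetric similarity matrix with unit diagonal in [0, 1]."""
    raw = rng.random((n, n))
    sym = (raw + raw.T) / 2
    np.fill_diagonal(sym, 1.0)
    return _frame(sym, [f"p{i}" for i in range(n)])


class TestSpectralClusters:
    def test_k_one_is_single_cluster(self):
        rng = np.random.default_rng(0)
        sim = _random_sim(rng, 7)
        out = spectral_clusters(sim, 1, seed=0)
        assert out.as_sets() == {frozenset(sim.index)}

    def test_two_blocks_recovered_exactly(self):
        labels = list("abcdef")
        block = np.zeros((6, 6))
        block[:3, :3] = 1.0
        block[3:, 3:] = 1.0
        out = spectral_clusters(_frame(block, labels), 2, seed=1)
        assert out.as_sets() == {frozenset("abc"), frozenset("def")}

    def test_two_noisy_blocks_recovered(self):
        rng = np.random.default_rng(4)
        n = 12
        sim = np.where(np.add.outer(np.arange(n) < 6, np.arange(n) < 6) % 2 == 0,
                       0.9, 0.05) + rng.random((n, n)) * 0.05
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        out = spectral_clusters(_frame(sim, [f"p{i}" for i in range(n)]), 2, seed=0)
        assert out.as_sets() == {
            frozenset(f"p{i}" for i in range(6)),
            frozenset(f"p{i}" for i in range(6, 12)),
        }

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(2)
        sim = _random_sim(rng, 5) * 0.5
        vals = sim.to_numpy()
        np.fill_diagonal(vals, 1.0)
        out = spectral_clusters(_frame(vals, sim.index), 5, seed=0)
        assert out.as_sets() == {frozenset({p}) for p in sim.index}

    def test_partition_property_on_random_matrices(self):
        rng = np.random.default_rng(6)
        for trial in range(15):
            n = int(rng.integers(4, 20))
            k = int(rng.integers(1, n + 1))
            sim = _random_sim(rng, n)
            out = spectral_clusters(sim, k, seed=trial)
            members = [p for c in out.clusters for p in c]
            assert len(members) == n  # disjoint
            assert set(members) == set(sim.index)  # cover
            assert 1 <= len(out.nonempty()) <= k

    def test_deterministic_for_fixed_inputs(self):
        rng = np.random.default_rng(8)
        sim = _random_sim(rng, 15)
        first = spectral_clusters(sim, 4, seed=3).as_sets()
        second = spectral_clusters(sim, 4, seed=3).as_sets()
        assert first == second

    def test_permutation_consistency(self):
        # well-separated blocks: permuting the protein order must permute
        # membership, not change the partition
        rng = np.random.default_rng(10)
        n, labels = 12, [f"p{i}" for i in range(12)]
        base = np.full((n, n), 0.05)
        for lo, hi in ((0, 4), (4, 8), (8, 12)):
            base[lo:hi, lo:hi] = 0.95
        base += rng.random((n, n)) * 0.02
        base = (base + base.T) / 2
        np.fill_diagonal(base, 1.0)
        sim = _frame(base, labels)
        perm = list(rng.permutation(n))
        shuffled = sim.iloc[perm, perm]
        assert (spectral_clusters(sim, 3, seed=0).as_sets()
                == spectral_clusters(shuffled, 3, seed=0).as_sets())

    def test_more_components_than_k_groups_whole_components(self):
        # 4 disconnected cliques, k=2: components must never be split
        n, labels = 8, list("abcdefgh")
        sim = np.zeros((n, n))
        comps = [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")]
        index = {l: i for i, l in enumerate(labels)}
        for x, y in comps:
            sim[index[x], index[y]] = sim[index[y], index[x]] = 1.0
        np.fill_diagonal(sim, 1.0)
        out = spectral_clusters(_frame(sim, labels), 2, seed=0)
        for x, y in comps:
            assert any(x in c and y in c for c in out.clusters)

    def test_k_larger_than_n_rejected(self):
        sim = _frame(np.eye(3), list("abc"))
        with pytest.raises(ValueError):
            spectral_clusters(sim, 4, seed=0)

    def test_asymmetric_matrix_rejected(self):
        mat = np.eye(3)
        mat[0, 1] = 0.5
        with pytest.raises(IntegrityError):
            spectral_clusters(_frame(mat, list("abc")), 2, seed=0)
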