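"""Oracle semantics and cycle structure of the dual-source loop."""

import numpy as np
import pytest

from barrierbo import (
    NoiseModel,
    run_optimization,
    virtual_computation,
    virtual_experiment,
)
from barrierbo.dual_source_loop import LoopConfig, LoopError, RunRecord
from barrierbo.substrate_space import DatasetError


class TestOracles:
    def test_experiment_is_exact_and_repeatable(self, tiny):
        _, _, landscape = tiny
        s = landscape.substrates[4]
        v = virtual_experiment(s, landscape)
        assert v == landscape.barriers[4]
        assert virtual_experiment(s, landscape) == v

    def test_experiment_unknown_substrate_raises(self, tiny):
        _, _, landscape = tiny
        with pytest.raises(DatasetError):
            virtual_experiment(("nope", "nope"), landscape)

    def test_computation_degenerate_noise(self, tiny, rng):
        _, _, landscape = tiny
        s = landscape.substrates[0]
        exact = landscape.barriers[0]
        assert virtual_computation(s, landscape, NoiseModel(0.0, 0.0), rng) == exact
        assert virtual_computation(s, landscape, NoiseModel(10.0, 0.0), rng) == exact + 10.0

    def test_computation_moments_match_noise_model(self, tiny):
        _, _, landscape = tiny
        s = landscape.substrates[0]
        exact = landscape.barriers[0]
        rng = np.random.default_rng(2024)
        draws = np.array(
            [virtual_computation(s, landscape, NoiseModel(0.0, 5.0), rng)
             for _ in range(10_000)]
        ) - exact
        assert abs(draws.mean()) < 0.15
        assert abs(draws.std() - 5.0) < 0.15

    def test_negative_sigma_rejected(self):
        with pytest.raises(LoopError):
            NoiseModel(0.0, -1.0)


class TestRunStructure:
    def test_single_random_batch_when_budget_equals_n(self, tiny):
        _, table, landscape = tiny
        rec = run_optimization(
            landscape, table, n=4, m=0, noise=NoiseModel(), budget=4, seed=0
        )
        assert len(rec.experimental) == 4
        assert rec.computational == []
        assert rec.experimental_batch_ends == [4]
        for s, v in rec.experimental:
            assert v == landscape.barrier(s)

    def test_batch_count_and_uniqueness(self, small):
        _, table, landscape = small
        rec = run_optimization(
            landscape, table, n=5, m=0, noise=NoiseModel(), budget=40, seed=3
        )
        assert rec.n_batches == 8
        subs = [s for s, _ in rec.experimental]
        assert len(set(subs)) == len(subs) == 40

    def test_oracle_call_counts_with_and_without_final_computations(self, small):
        _, table, landscape = small
        kw = dict(n=5, m=3, noise=NoiseModel(0.0, 2.0), budget=20, seed=9)
        rec_skip = run_optimization(landscape, table, **kw)
        assert len(rec_skip.experimental) == 20
        assert len(rec_skip.computational) == (20 // 5 - 1) * 3
        rec_full = run_optimization(
            landscape, table,
            loop_config=LoopConfig(skip_final_computation=False), **kw,
        )
        assert len(rec_full.computational) == (20 // 5) * 3

    def test_asymmetric_exclusion(self, small):
        """Computed substrates may be experimented later, never the reverse;
        neither list contains internal duplicates."""
        _, table, landscape = small
        rec = run_optimization(
            landscape, table, n=5, m=10, noise=NoiseModel(), budget=30, seed=5
        )
        exp = [s for s, _ in rec.experimental]
        comp = [s for s, _ in rec.computational]
        assert len(set(exp)) == len(exp)
        assert len(set(comp)) == len(comp)
        promoted = set(exp) & set(comp)
        for s in promoted:  # computation must precede the experiment
            comp_batch = next(
                b for b, end in enumerate(rec.computational_batch_ends, 1)
                if comp.index(s) < end
            )
            exp_batch = next(
                b for b, end in enumerate(rec.experimental_batch_ends, 1)
                if exp.index(s) < end
            )
            assert comp_batch < exp_batch

    def test_same_seed_is_bitwise_identical(self, small):
        _, table, landscape = small
        kw = dict(n=5, m=4, noise=NoiseModel(-10.0, 5.0), budget=20, seed=77)
        a = run_optimization(landscape, table, **kw)
        b = run_optimization(landscape, table, **kw)
        assert a.to_json() == b.to_json()

    def test_noise_paired_across_m_settings(self, small):
        """Shared master seed gives identical initial batches regardless of
        m, mu, sigma, so grid points are comparable pairwise."""
        _, table, landscape = small
        recs = [
            run_optimization(
                landscape, table, n=5, m=m, noise=NoiseModel(mu, sigma),
                budget=10, seed=123,
            )
            for m, mu, sigma in [(0, 0.0, 0.0), (3, 20.0, 5.0), (5, -10.0, 0.0)]
        ]
        first_batches = [r.experimental[:5] for r in recs]
        assert first_batches[0] == first_batches[1] == first_batches[2]

    def test_truncates_on_pool_exhaustion(self, tiny):
        _, table, landscape = tiny  # 9 substrates
        rec = run_optimization(
            landscape, table, n=2, m=6, noise=NoiseModel(), budget=8, seed=1
        )
        assert rec.truncated

    @pytest.mark.parametrize(
        "kw,msg",
        [
            (dict(n=0, m=0, budget=5), "n must be"),
            (dict(n=5, m=-1, budget=5), "m must be"),
            (dict(n=5, m=0, budget=7), "multiple"),
            (dict(n=5, m=200, budget=5), "pool"),
        ],
    )
    def test_invalid_configs_rejected(self, tiny, kw, msg):
        _, table, landscape = tiny
        with pytest.raises(LoopError, match=msg):
            run_optimization(landscape, table, noise=NoiseModel(), seed=0, **kw)

    def test_missing_barriers_rejected(self, tiny):
        from barrierbo import BarrierLandscape

        _, table, landscape = tiny
        barriers = landscape.barriers.copy()
        barriers[0] = np.nan
        holey = BarrierLandscape(list(landscape.substrates), barriers)
        with pytest.raises(DatasetError, match="imputed"):
            run_optimization(holey, table, n=2, m=0, noise=NoiseModel(), budget=2, seed=0)


def test_record_json_roundtrip(tmp_path, tiny):
    _, table, landscape = tiny
    rec = run_optimization(
        landscape, table, n=2, m=2, noise=NoiseModel(5.0, 1.0), budget=4, seed=2
    )
    path = tmp_path / "record.json"
    rec.to_json(path)
    back = RunRecord.from_json(path)
    assert back.to_json() == rec.to_json()
    assert back.experimental == rec.experimental
    assert back.best_experimental() == rec.best_experimental()
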