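"""The FSBRR selector: rules, ordering, invariants, oracle equivalence."""

import numpy as np
import pytest

from fsbrr import (
    BinningSpec,
    DiscreteVector,
    FSBRRConfig,
    fsbrr_select,
    normalized_relevance,
    relevance_profile,
    select_from_table,
    sweep,
)
from fsbrr.core import RULE_IRRELEVANT, RULE_REDUNDANCY_1, RULE_REDUNDANCY_2
from fsbrr.infotheory import DiscretizedTable

from conftest import random_coded_table
from oracles import naive_fsbrr, relevance_oracle


def dv(codes):
    return DiscreteVector.from_codes(codes)


def coded_table(columns, class_codes, ids=None):
    ids = ids or [f"f{k}" for k in range(len(columns))]
    return DiscretizedTable(
        feature_ids=ids,
        features=[dv(c) for c in columns],
        class_codes=dv(class_codes),
    )


NO_REMOVAL = dict(delta=-1.0, alpha=0.0)  # rule 1 gap and rule 2 window both empty


class TestRelevanceProfile:
    def test_feature_identical_to_class(self):
        t = coded_table([[0, 1, 0, 1]], [0, 1, 0, 1])
        prof = relevance_profile(t, FSBRRConfig())
        assert prof.scores == {"f0": 1.0}
        assert prof.r_max == prof.r_bar == 1.0

    def test_tau_drops_independent_feature(self):
        t = coded_table([[0, 1, 0, 1], [0, 0, 1, 1]], [0, 1, 0, 1])
        prof = relevance_profile(t, FSBRRConfig(tau=0.5))
        assert set(prof.scores) == {"f0"}
        assert prof.dropped[0].removed == "f1"
        assert prof.dropped[0].rule == RULE_IRRELEVANT

    def test_r_bar_matches_oracle_mean(self, rng):
        t = random_coded_table(rng, n_features=10, n_instances=100)
        prof = relevance_profile(t, FSBRRConfig())
        oracle_scores = [
            relevance_oracle(f.codes.tolist(), t.class_codes.codes.tolist())
            for f in t.features
        ]
        assert prof.r_bar == pytest.approx(np.mean(oracle_scores), abs=1e-12)

    def test_all_dropped_is_error(self):
        t = coded_table([[0, 0, 1, 1]], [0, 1, 0, 1])
        with pytest.raises(ValueError, match="empty after irrelevance filter"):
            relevance_profile(t, FSBRRConfig(tau=0.9))

    def test_single_class_is_error(self):
        t = coded_table([[0, 1, 0, 1]], [0, 0, 0, 0])
        with pytest.raises(ValueError, match="class"):
            relevance_profile(t, FSBRRConfig())

    def test_constant_feature_warns_and_is_retained(self):
        t = coded_table([[0, 0, 0, 0], [0, 1, 0, 1]], [0, 1, 0, 1])
        with pytest.warns(UserWarning, match="constant"):
            result = fsbrr_select(t, FSBRRConfig())
        assert "f0" in result.selected  # R=0 passes tau=0 (>= comparison)


class TestConfigValidation:
    def test_defaults_are_silent(self, recwarn):
        FSBRRConfig()
        assert not recwarn.list

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(delta=0.3), "delta"),
            (dict(delta=0.01), "delta"),
            (dict(alpha=0.9), "alpha"),
            (dict(delta=0.12, alpha=0.1), "alpha"),
        ],
    )
    def test_out_of_range_warns_but_constructs(self, kwargs, match):
        with pytest.warns(UserWarning, match=match):
            FSBRRConfig(**kwargs)

    def test_negative_tau_is_error(self):
        with pytest.raises(ValueError):
            FSBRRConfig(tau=-0.1)


class TestSelection:
    def test_single_feature(self):
        t = coded_table([[0, 1, 0, 1]], [0, 1, 0, 1])
        result = fsbrr_select(t, FSBRRConfig())
        assert result.selected == ["f0"]
        assert result.pair_evaluations == 0

    def test_exact_duplicate_removed_by_rule_1(self):
        c = [0, 1, 0, 1, 0, 1, 1, 0]
        f1 = [0, 1, 1, 1, 0, 1, 0, 0]  # informative but not a class copy
        t = coded_table([f1, list(f1)], c)
        result = fsbrr_select(t, FSBRRConfig())
        assert result.selected == ["f0"]
        (rec,) = result.removal_log
        assert rec.rule == RULE_REDUNDANCY_1
        assert rec.pivot == "f0" and rec.removed == "f1"
        assert rec.r_pair == 1.0

    def test_selected_ordered_by_descending_relevance(self, rng):
        t = random_coded_table(rng, n_features=20, n_instances=150)
        result = fsbrr_select(t, FSBRRConfig())
        scores = [result.scores[f] for f in result.selected]
        assert scores == sorted(scores, reverse=True)

    def test_tie_break_ascending_original_index(self):
        # two identical non-adjacent columns: the earlier index is the pivot
        c = [0, 0, 1, 1, 0, 1]
        f = [0, 1, 0, 1, 1, 0]
        t = coded_table([f, [0, 0, 0, 1, 1, 1], list(f)], c)
        result = fsbrr_select(t, FSBRRConfig())
        assert "f2" not in result.selected
        rec = [r for r in result.removal_log if r.removed == "f2"][0]
        assert rec.pivot == "f0"

    def test_partition_of_input(self, rng):
        t = random_coded_table(rng, n_features=25, n_instances=100)
        result = fsbrr_select(t, FSBRRConfig())
        removed = {r.removed for r in result.removal_log}
        assert removed.isdisjoint(result.selected)
        assert removed | set(result.selected) == set(t.feature_ids)

    def test_determinism(self, rng):
        t = random_coded_table(rng, n_features=15, n_instances=120)
        r1 = fsbrr_select(t, FSBRRConfig())
        r2 = fsbrr_select(t, FSBRRConfig())
        assert r1.selected == r2.selected
        assert r1.removal_log == r2.removal_log
        assert r1.pair_evaluations == r2.pair_evaluations


class TestComplexityContract:
    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_all_duplicates_is_linear(self, rng, n):
        base = rng.integers(0, 4, 100)
        cls = (base > 1).astype(int)
        t = coded_table([base.tolist()] * n, cls.tolist())
        result = fsbrr_select(t, FSBRRConfig())
        assert result.pair_evaluations == n - 1
        assert len(result.selected) == 1

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_nothing_removed_is_quadratic(self, rng, n):
        t = random_coded_table(rng, n_features=n, n_instances=60)
        with pytest.warns(UserWarning):
            config = FSBRRConfig(**NO_REMOVAL)
        result = fsbrr_select(t, config)
        assert result.pair_evaluations == n * (n - 1) // 2
        assert len(result.selected) == n


class TestCriterion2Invariant:
    """Weak pairwise correlation protects a feature from removal."""

    def test_exactly_independent_victim_retained(self):
        # victim balanced within every (pivot, class) cell: R_pivot,victim = 0
        cls = [0, 0, 0, 0, 1, 1, 1, 1]
        pivot = list(cls)  # R = 1
        victim = [0, 1, 0, 1, 0, 1, 0, 1]  # R with class and pivot exactly 0
        t = coded_table([pivot, victim], cls)
        result = fsbrr_select(t, FSBRRConfig())
        assert "f1" in result.selected

    def test_low_correlation_features_never_removed(self, rng):
        """Any feature whose R_i,j with every stronger feature is below both
        rule thresholds appears in the selected set."""
        config = FSBRRConfig()
        for _ in range(20):
            t = random_coded_table(rng, n_features=12, n_instances=80)
            result = fsbrr_select(t, config)
            scores = {
                fid: normalized_relevance(f, t.class_codes)
                for fid, f in zip(t.feature_ids, t.features)
            }
            r_bar = np.mean(list(scores.values()))
            cols = dict(zip(t.feature_ids, t.features))
            for fj, r_jc in scores.items():
                protected = True
                for fi, r_ic in scores.items():
                    if fi == fj or r_ic < r_jc:
                        continue
                    r_ij = normalized_relevance(cols[fi], cols[fj])
                    if r_ij >= r_ic or r_ij > (r_bar + r_jc) / 2:
                        protected = False
                        break
                if protected:
                    assert fj in result.selected


class TestOracleEquivalence:
    def test_matches_naive_transcription_on_random_tables(self, rng):
        """Optimized selector == literal transcription: same selected sets
        and same removal logs, across 50 random tables and parameter draws."""
        for trial in range(50):
            n_features = int(rng.integers(2, 31))
            n_instances = int(rng.integers(20, 201))
            t = random_coded_table(rng, n_features, n_instances)
            tau = float(rng.choice([0.0, 0.0, 0.02]))
            delta = float(rng.uniform(0.05, 0.13))
            alpha = float(rng.uniform(0.60, 0.66))
            config = FSBRRConfig(tau=tau, delta=delta, alpha=alpha)

            columns = [f.codes.tolist() for f in t.features]
            cls = t.class_codes.codes.tolist()
            try:
                result = fsbrr_select(t, config)
            except ValueError:
                # every feature fell below tau: the transcription must agree
                with pytest.raises(ValueError):
                    naive_fsbrr(columns, cls, tau, delta, alpha)
                continue
            sel_idx, log_idx = naive_fsbrr(columns, cls, tau, delta, alpha)

            idx_to_id = dict(enumerate(t.feature_ids))
            assert result.selected == [idx_to_id[i] for i in sel_idx], f"trial {trial}"
            got_log = [
                (r.pivot, r.removed, r.rule) for r in result.removal_log
            ]
            want_log = [
                (None if p is None else idx_to_id[p], idx_to_id[j], rule)
                for p, j, rule in log_idx
            ]
            assert got_log == want_log, f"trial {trial}"

    def test_eight_feature_synthetic_matches_naive(self, eight_feature_table):
        table, _ = eight_feature_table
        config = FSBRRConfig()
        result = select_from_table(table, config)

        from fsbrr.infotheory import discretize_table

        disc = discretize_table(table, config.binning)
        columns = [f.codes.tolist() for f in disc.features]
        cls = disc.class_codes.codes.tolist()
        sel_idx, _ = naive_fsbrr(columns, cls, 0.0, 0.08, 0.64)
        assert result.selected == [disc.feature_ids[i] for i in sel_idx]


class TestSweep:
    def test_singleton_grid_equals_single_call(self, rng):
        t = random_coded_table(rng, n_features=10, n_instances=100)
        config = FSBRRConfig()
        df = sweep(t, [0.08], [0.64], config, evaluator=None)
        assert len(df) == 1
        assert df.loc[0, "n_selected"] == len(fsbrr_select(t, config).selected)

    def test_all_duplicates_size_one_everywhere(self, rng):
        base = rng.integers(0, 3, 80)
        cls = (base > 0).astype(int)
        t = coded_table([base.tolist()] * 6, cls.tolist())
        df = sweep(t, [0.0, 0.1, 0.2], [0.64], FSBRRConfig(), evaluator=None)
        assert (df["n_selected"] == 1).all()

    def test_grid_matches_pointwise_calls(self, eight_feature_table):
        from fsbrr.infotheory import discretize_table

        table, _ = eight_feature_table
        config = FSBRRConfig()
        disc = discretize_table(table, config.binning)
        grid = np.round(np.arange(0, 0.21, 0.01), 2).tolist()
        df = sweep(disc, grid, [0.64], config, evaluator=None)
        assert len(df) == 21
        import warnings

        for row in df.itertuples():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                single = fsbrr_select(
                    disc, FSBRRConfig(delta=row.delta, alpha=0.64)
                )
            assert row.n_selected == len(single.selected)

    def test_empty_grid_rejected(self, rng):
        t = random_coded_table(rng, 5, 50)
        with pytest.raises(ValueError):
            sweep(t, [], [0.64], FSBRRConfig(), None)
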