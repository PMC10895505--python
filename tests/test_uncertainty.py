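"""Cluster bootstrap and bias-corrected percentile intervals."""

from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intervmed.effects import EffectDecomposition
from intervmed.schema import TrialDataset
from intervmed.synthetic_data import GeneratorConfig, generate_trial
from intervmed.uncertainty import BootstrapConfig, bc_interval, cluster_bootstrap


def _bc_oracle(point, reps, alpha):
    """Independent step-by-step evaluation of the BC formula using only the
    standard library for the normal quantile and a hand-rolled
    linear-interpolation quantile."""
    nd = NormalDist()
    reps = sorted(reps)
    b = len(reps)
    frac = (sum(r < point for r in reps) + 0.5 * sum(r == point for r in reps)) / b
    z0 = nd.inv_cdf(frac)

    def quantile(q):
        h = (b - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, b - 1)
        return reps[lo] + (h - lo) * (reps[hi] - reps[lo])

    lo_level = nd.cdf(2 * z0 + nd.inv_cdf(alpha / 2))
    hi_level = nd.cdf(2 * z0 + nd.inv_cdf(1 - alpha / 2))
    return quantile(lo_level), quantile(hi_level)


def test_bc_interval_matches_independent_oracle():
    rng = np.random.default_rng(100)
    reps = rng.normal(1.2, 0.5, 1000)
    lo, hi = bc_interval(1.0, reps, alpha=0.05)
    olo, ohi = _bc_oracle(1.0, reps, 0.05)
    assert lo == pytest.approx(olo, abs=1e-10)
    assert hi == pytest.approx(ohi, abs=1e-10)


def test_bc_reduces_to_percentile_when_median_centred():
    """With exactly half the replicates strictly below the point the bias
    factor is zero and BC bounds equal plain percentile bounds."""
    rng = np.random.default_rng(101)
    for _ in range(50):
        vals = rng.normal(size=2 * rng.integers(20, 200))
        point = float(np.median(vals))  # even count: exactly half below
        lo, hi = bc_interval(point, vals, alpha=0.05)
        assert lo == pytest.approx(np.quantile(vals, 0.025))
        assert hi == pytest.approx(np.quantile(vals, 0.975))


def test_bc_degenerate_replicates():
    with pytest.warns(UserWarning, match="degenerate"):
        lo, hi = bc_interval(2.0, np.full(100, 2.0))
    assert (lo, hi) == (2.0, 2.0)


def test_bc_one_sided_replicates_clamped():
    reps = np.linspace(5.0, 6.0, 200)  # all above the point
    lo, hi = bc_interval(1.0, reps, alpha=0.05)
    assert np.isfinite(lo) and np.isfinite(hi) and lo <= hi


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000))
def test_bc_interval_properties(seed):
    """Bounds stay inside the replicate range, are ordered, and never widen
    when alpha grows."""
    rng = np.random.default_rng(seed)
    reps = rng.normal(rng.normal(), 1.0 + rng.random(), 250)
    point = float(rng.normal())
    lo5, hi5 = bc_interval(point, reps, alpha=0.05)
    lo10, hi10 = bc_interval(point, reps, alpha=0.10)
    assert reps.min() <= lo5 <= hi5 <= reps.max()
    assert lo5 <= lo10 and hi10 <= hi5


# -- bootstrap machinery -----------------------------------------------------


def _mean_pipeline(record=None):
    """Cheap stand-in estimator: decomposition built from arm means."""

    def pipeline(ds: TrialDataset, rng) -> EffectDecomposition:
        if record is not None:
            record.append(ds)
        df = ds.df
        total = float(df.loc[df.arm == 1, "phq9_12m"].mean() - df.loc[df.arm == 0, "phq9_12m"].mean())
        return EffectDecomposition(
            total=total, direct=total,
            indirect={"sessions": 0.0, "activation": 0.0, "response": 0.0},
            m_copies=1, seed=0,
        )

    return pipeline


@pytest.fixture(scope="module")
def trial(default_truth):
    ds, _ = generate_trial(GeneratorConfig(seed=33, n_subjects=200, n_clusters=8),
                           truth=default_truth)
    return ds


def test_resampling_preserves_cluster_membership(trial):
    seen = []
    cluster_sets = {
        c: sorted(g["subject_id"]) for c, g in trial.df.groupby("cluster_id")
    }
    res = cluster_bootstrap(trial, _mean_pipeline(seen), BootstrapConfig(n_resamples=5, seed=1))
    for boot in seen[1:]:  # first call is the point estimate on original data
        assert boot.df["cluster_id"].nunique() == trial.n_clusters
        for _, grp in boot.df.groupby("cluster_id"):
            assert sorted(grp["subject_id"]) in cluster_sets.values()
    assert res.n_failed == 0


def test_bootstrap_reproducible_and_lengths(trial):
    cfg = BootstrapConfig(n_resamples=12, seed=7)
    r1 = cluster_bootstrap(trial, _mean_pipeline(), cfg)
    r2 = cluster_bootstrap(trial, _mean_pipeline(), cfg)
    assert np.array_equal(r1.replicates["total"], r2.replicates["total"])
    assert len(r1.replicates["total"]) == 12
    one = cluster_bootstrap(trial, _mean_pipeline(), BootstrapConfig(n_resamples=1, seed=0))
    assert len(one.replicates["total"]) == 1
    for lo, hi in r1.intervals.values():
        assert lo <= hi


def test_single_cluster_degenerate(trial):
    df = trial.df.copy()
    df["cluster_id"] = 1
    single = TrialDataset(df=df)
    with pytest.warns(UserWarning, match="one cluster"):
        res = cluster_bootstrap(single, _mean_pipeline(), BootstrapConfig(n_resamples=6, seed=2))
    assert np.allclose(res.replicates["total"], res.point.total)


def test_failed_resamples_are_dropped_not_retried(trial):
    calls = {"n": 0}

    def flaky(ds, rng):
        calls["n"] += 1
        if calls["n"] > 1 and calls["n"] % 3 == 0:
            raise RuntimeError("synthetic failure")
        return _mean_pipeline()(ds, rng)

    res = cluster_bootstrap(trial, flaky, BootstrapConfig(n_resamples=9, seed=3))
    assert res.n_failed == 3
    assert len(res.replicates["total"]) == 6

    def always_fail(ds, rng):
        if calls["n"] >= 0:
            raise RuntimeError("nope")

    calls["n"] = -10_000
    with pytest.raises(RuntimeError, match="all bootstrap"):
        # point estimate must still succeed, so fail only on resamples
        def fail_after_first(ds, rng):
            calls["n"] += 1
            if calls["n"] > 1:
                raise RuntimeError("nope")
            return _mean_pipeline()(ds, rng)

        calls["n"] = 0
        cluster_bootstrap(trial, fail_after_first, BootstrapConfig(n_resamples=4, seed=4))


def test_subject_resampling_unit(trial):
    res = cluster_bootstrap(
        trial, _mean_pipeline(), BootstrapConfig(n_resamples=5, seed=5, resample_unit="subject")
    )
    assert len(res.replicates["total"]) == 5


def test_bootstrap_config_validation():
    with pytest.raises(ValueError):
        BootstrapConfig(n_resamples=0)
    with pytest.raises(ValueError):
        BootstrapConfig(alpha=1.5)
    with pytest.raises(ValueError):
        BootstrapConfig(resample_unit="clinic")
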