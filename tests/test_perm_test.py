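import numpy as np
import pytest
from scipy import stats

from c14pop import (DemographicCurve, calibrate, make_bins, perm_test,
                    permute_labels, simulate_dates, sum_spd,
                    toy_identity_curve, two_region_scenario)


@pytest.fixture(scope="module")
def curve():
    return toy_identity_curve(8000, 2000, 0.0)


def test_permute_labels_preserves_counts():
    labels = np.array(["Kanto"] * 87 + ["Aomori"] * 128 + ["Hokkaido"] * 186)
    rng = np.random.default_rng(0)
    for _ in range(10):
        p = permute_labels(labels, rng)
        lab, cnt = np.unique(p, return_counts=True)
        assert dict(zip(lab.tolist(), cnt.tolist())) == {
            "Kanto": 87, "Aomori": 128, "Hokkaido": 186}


def test_permute_labels_two_bins_uniform():
    labels = np.array(["A", "B"])
    rng = np.random.default_rng(1)
    n = 4000
    counts = {"AB": 0, "BA": 0}
    for _ in range(n):
        p = permute_labels(labels, rng)
        counts["".join(p)] += 1
    chi2 = sum((c - n / 2) ** 2 / (n / 2) for c in counts.values())
    assert stats.chi2.sf(chi2, df=1) > 0.001


def test_permute_labels_reproducible():
    labels = np.array(["A"] * 5 + ["B"] * 5)
    a = permute_labels(labels, np.random.default_rng(3))
    b = permute_labels(labels, np.random.default_rng(3))
    assert np.array_equal(a, b)


def test_permute_labels_needs_two_labels():
    with pytest.raises(ValueError):
        permute_labels(np.array(["A", "A"]), np.random.default_rng(0))


def test_self_comparison_not_significant(curve):
    """Two literal copies of the same bins should rarely reject."""
    dem = DemographicCurve("rise_fall", (7000, 3000))
    nonreject_a = nonreject_b = 0
    reps = 20
    for rep in range(reps):
        a = simulate_dates(dem, 50, curve, sites=50, set_label="A",
                           seed=300 + rep)
        b = [d.__class__(**{**vars(d), "set_label": "B",
                            "site_id": d.site_id + "x"}) for d in a]
        res = perm_test(a + b, curve, nsim=200, seed=400 + rep)
        nonreject_a += res.sets["A"].pvalue > 0.05
        nonreject_b += res.sets["B"].pvalue > 0.05
    assert nonreject_a >= reps * 0.8
    assert nonreject_b >= reps * 0.8


def test_detects_gap_divergence(curve):
    dem = DemographicCurve("rise_fall", (7000, 3000))
    a, b = two_region_scenario(dem, {"window": (5500, 5000), "multiplier": 0.0},
                               400, curve, sites_per_region=40, seed=10)
    res = perm_test(a + b, curve, nsim=500, seed=11)
    assert res.sets["B"].pvalue < 0.05
    # a negative interval for B overlapping the carved gap
    assert any(old >= 5000 and young <= 5500
               for old, young in res.sets["B"].neg_intervals)


def test_two_set_significant_years_are_mirror_signed(curve):
    dem = DemographicCurve("rise_fall", (7000, 3000))
    a, b = two_region_scenario(dem, {"window": (5500, 5000), "multiplier": 0.0},
                               400, curve, sites_per_region=40, seed=12)
    res = perm_test(a + b, curve, nsim=300, seed=13)

    def years(intervals):
        return {y for old, young in intervals
                for y in range(int(young), int(old) + 1)}

    assert not (years(res.sets["A"].pos_intervals)
                & years(res.sets["B"].pos_intervals))
    assert not (years(res.sets["A"].neg_intervals)
                & years(res.sets["B"].neg_intervals))


def test_exchangeability_under_relabelling(curve):
    dem = DemographicCurve("rise_fall", (7000, 3000))
    a, b = two_region_scenario(dem, {"window": (5500, 5000), "multiplier": 0.5},
                               100, curve, sites_per_region=20, seed=14)
    swapped = ([d.__class__(**{**vars(d), "set_label": "B"}) for d in a]
               + [d.__class__(**{**vars(d), "set_label": "A"}) for d in b])
    r1 = perm_test(a + b, curve, nsim=200, seed=15)
    r2 = perm_test(swapped, curve, nsim=200, seed=15)
    assert r1.sets["A"].pvalue == r2.sets["B"].pvalue
    assert r1.sets["B"].pvalue == r2.sets["A"].pvalue
    assert np.array_equal(r1.sets["A"].obs_z, r2.sets["B"].obs_z)


def test_aggregate_spd_invariant_under_permutation(curve):
    dem = DemographicCurve("rise_fall", (7000, 3000))
    a = simulate_dates(dem, 40, curve, sites=8, set_label="A", seed=20)
    b = simulate_dates(dem, 40, curve, sites=8, set_label="B", seed=21)
    table = a + b
    bs = make_bins(table, 200)
    dens = {i: calibrate(d.cra, d.error, curve) for i, d in enumerate(table)}
    total = sum_spd(bs, dens, (7000, 3000)).density
    rng = np.random.default_rng(22)
    new_labels = permute_labels(bs.labels(), rng)
    relabelled = bs.__class__(
        [bn.__class__(bn.bin_id, bn.site_id, lbl, bn.members)
         for bn, lbl in zip(bs.bins, new_labels)], bs.h)
    per_set = sum(sum_spd(relabelled, dens, (7000, 3000), set_label=s).density
                  for s in ("A", "B"))
    assert np.max(np.abs(per_set - total)) < 1e-12


def test_three_set_mode_runs(curve):
    dem = DemographicCurve("uniform", (7000, 3000))
    table = []
    for i, lbl in enumerate(("A", "B", "C")):
        table += simulate_dates(dem, 30, curve, sites=6, set_label=lbl,
                                seed=30 + i)
    res = perm_test(table, curve, nsim=100, seed=33)
    assert set(res.sets) == {"A", "B", "C"}
    for r in res.sets.values():
        assert 1 / 101 <= r.pvalue <= 1.0


def test_single_set_rejected(curve):
    dem = DemographicCurve("uniform", (7000, 3000))
    table = simulate_dates(dem, 10, curve, sites=2, set_label="A", seed=40)
    with pytest.raises(ValueError):
        perm_test(table, curve, nsim=10, seed=41)


def test_range_clipping_changes_scope(curve):
    dem = DemographicCurve("rise_fall", (7000, 3000))
    a, b = two_region_scenario(dem, {"window": (6500, 6000), "multiplier": 0.0},
                               200, curve, sites_per_region=20, seed=50)
    full = perm_test(a + b, curve, nsim=200, seed=51)
    clipped = perm_test(a + b, curve, nsim=200, seed=51, range_=(7000, 4420))
    assert clipped.sets["B"].calbp[0] == 7000
    assert clipped.sets["B"].calbp[-1] == 4420
    # divergence sits inside the clipped window, so it must still be seen
    assert clipped.sets["B"].pvalue <= full.sets["B"].pvalue + 0.1
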