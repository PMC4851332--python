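import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c14pop import (analysis_grid, bin_density, calibrate, make_bins,
                    rolling_mean, sum_spd, toy_identity_curve)
from c14pop.spd import SPD

from conftest import make_date
from oracles import naive_complete_linkage


def test_hand_computed_complete_linkage():
    # merge 5000/5100 at height 100; adding 5350 would need height 350 > 200
    t = [make_date(c, site="s1") for c in (5000, 5100, 5350)]
    bs = make_bins(t, h=200)
    groups = sorted(tuple(sorted(round(t[i].cra) for i in b.members))
                    for b in bs.bins)
    assert groups == [(5000, 5100), (5350,)]


def test_single_date_single_bin():
    bs = make_bins([make_date(5000)], h=200)
    assert len(bs.bins) == 1 and bs.bins[0].members == (0,)


def test_bins_never_cross_sites_or_sets():
    t = [make_date(5000, site="s1"), make_date(5001, site="s2"),
         make_date(5000, site="s1", label="B")]
    bs = make_bins(t, h=200)
    assert len(bs.bins) == 3
    for b in bs.bins:
        assert len({t[i].site_id for i in b.members}) == 1
        assert len({t[i].set_label for i in b.members}) == 1


@given(st.lists(st.floats(3000, 7000), min_size=1, max_size=10))
@settings(max_examples=40, deadline=None)
def test_h_extremes(cras):
    table = [make_date(c, site="s1") for c in cras]
    zero = make_bins(table, h=0)
    assert len(zero.bins) == len({d.cra for d in table})
    inf = make_bins(table, h=np.inf)
    assert len(inf.bins) == 1


def test_bins_match_naive_agglomeration_small():
    rng = np.random.default_rng(2)
    for _ in range(20):
        cras = rng.uniform(3000, 7000, size=rng.integers(2, 8))
        table = [make_date(c, site="s1") for c in cras]
        bs = make_bins(table, h=200)
        ours = sorted(tuple(sorted(table[i].cra for i in b.members))
                      for b in bs.bins)
        assert ours == naive_complete_linkage(cras, 200)


@pytest.fixture(scope="module")
def curve():
    return toy_identity_curve(8000, 2000, 0.0)


def test_bin_density_identity_and_mean(curve):
    grid = analysis_grid((7000, 3000))
    d = calibrate(5000, 20, curve)
    one = bin_density([d], grid)
    assert abs(one.prob.sum() - 1.0) < 1e-9
    two = bin_density([d, d], grid)
    assert np.allclose(one.prob, two.prob)
    # disjoint unit-mass members -> bimodal with half mass each
    far = calibrate(4000, 20, curve)
    mix = bin_density([d, far], grid)
    assert abs(mix.prob[(mix.calbp > 4800) & (mix.calbp < 5200)].sum() - 0.5) < 1e-6
    assert abs(mix.prob.sum() - 1.0) < 1e-9


def test_bin_density_empty_raises():
    with pytest.raises(ValueError):
        bin_density([], analysis_grid((7000, 3000)))


def test_sum_spd_conservation_and_identity(curve):
    table = [make_date(5000, site="s1", lab_id="a"),
             make_date(5000, site="s1", lab_id="b"),
             make_date(4000, site="s2")]
    bs = make_bins(table, h=200)
    dens = {i: calibrate(d.cra, d.error, curve) for i, d in enumerate(table)}
    spd = sum_spd(bs, dens, (7000, 3000))
    assert spd.n_bins == 2 and spd.n_dates == 3
    assert abs(spd.density.sum() - 2.0) < 1e-6  # k bins wholly inside range
    # one bin of two identical dates == the single calibrated density
    single = sum_spd(make_bins(table[:2], h=200), dens, (7000, 3000))
    ref = calibrate(5000, 30, curve)
    on_grid = np.zeros(single.calbp.size)
    off = int(single.calbp[0] - ref.calbp[0])
    on_grid[off:off + ref.prob.size] = ref.prob
    assert np.allclose(single.density, on_grid)
    # disjoint supports each integrate to 1
    m1 = (spd.calbp > 4800) & (spd.calbp < 5200)
    m2 = (spd.calbp > 3800) & (spd.calbp < 4200)
    assert abs(spd.density[m1].sum() - 1.0) < 1e-6
    assert abs(spd.density[m2].sum() - 1.0) < 1e-6


def test_spd_order_invariance_and_additivity(curve):
    rng = np.random.default_rng(9)
    table = [make_date(c, site=f"s{int(i) % 4}", label="A" if i % 2 else "B",
                       lab_id=f"L{i}")
             for i, c in enumerate(rng.uniform(3500, 6500, 30))]
    dens = {i: calibrate(d.cra, d.error, curve) for i, d in enumerate(table)}
    spd = sum_spd(make_bins(table, 200), dens, (7000, 3000))

    order = rng.permutation(len(table))
    shuffled = [table[i] for i in order]
    dens2 = {i: calibrate(d.cra, d.error, curve) for i, d in enumerate(shuffled)}
    spd2 = sum_spd(make_bins(shuffled, 200), dens2, (7000, 3000))
    assert np.allclose(spd.density, spd2.density)

    bs = make_bins(table, 200)
    a = sum_spd(bs, dens, (7000, 3000), set_label="A")
    b = sum_spd(bs, dens, (7000, 3000), set_label="B")
    assert np.allclose(a.density + b.density, spd.density)


def test_rolling_mean_constant_window1_and_spike():
    grid = analysis_grid((7000, 3000))
    const = SPD(grid, np.full(grid.size, 0.3))
    assert np.allclose(rolling_mean(const, 200).density, 0.3)
    spike = np.zeros(grid.size)
    spike[2000] = 1.0
    s = SPD(grid, spike)
    assert np.array_equal(rolling_mean(s, 1).density, spike)
    sm = rolling_mean(s, 201).density
    assert np.allclose(sm[1900:2101], 1 / 201)
    assert sm[1899] == 0 and sm[2101] == 0
    with pytest.raises(ValueError):
        rolling_mean(s, 0)
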