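import itertools

import numpy as np
import pytest

from broadcall import (ConfigurationError, SimulationConfig,
                       make_fixed_width_peak_sets, make_fixed_width_peaks,
                       make_grid, n_reads, simulate_dataset)
from broadcall.simulate import (GRID_NOISE_COVERAGES, GRID_PEAK_COVERAGES,
                                GRID_PEAK_WIDTHS, read_config)


# ---------------------------------------------------------------------------
# truth peak construction


def test_fixed_width_peaks_basic():
    fw = make_fixed_width_peaks([0, 1000], 500, 10_000)
    assert fw.intervals.intervals() == [("chrS", 0, 500), ("chrS", 1000, 1500)]
    assert fw.kept_indices == (0, 1)


def test_fixed_width_peaks_drop_overlapping():
    fw = make_fixed_width_peaks([0, 300], 500, 10_000)
    assert fw.intervals.intervals() == [("chrS", 0, 500)]
    assert fw.kept_indices == (0,)


def test_fixed_width_peaks_drop_past_genome_end():
    fw = make_fixed_width_peaks([0, 9800], 500, 10_000)
    assert fw.kept_indices == (0,)


def test_cross_width_drop_rule():
    """A template dropped at any width is dropped at every width."""
    sets = make_fixed_width_peak_sets([0, 300], [100, 500], 10_000)
    assert sets[100].intervals() == [("chrS", 0, 100)]
    assert sets[500].intervals() == [("chrS", 0, 500)]


def test_no_surviving_peaks_is_an_error():
    with pytest.raises(ConfigurationError):
        make_fixed_width_peaks([9900], 500, 10_000)


# ---------------------------------------------------------------------------
# read-count arithmetic


@pytest.mark.parametrize("coverage, span, rlen, expected", [
    (1, 1_000_000, 100, 10_000),
    (5, 1000 * 157, 100, 7850),
    (0, 1_000_000, 100, 0),
])
def test_n_reads_formula(coverage, span, rlen, expected):
    assert n_reads(coverage, span, rlen) == expected


def test_total_read_count_is_exact():
    cfg = SimulationConfig(genome_size=100_000, template_starts=(10_000, 40_000),
                           peak_width=5000, peak_coverage=4, noise_coverage=1, seed=3)
    ds = simulate_dataset(cfg)
    assert len(ds.reads) == n_reads(1, 100_000, 100) + n_reads(4, 5000 * 2, 100)


# ---------------------------------------------------------------------------
# coverage identities


def _coverage_split(ds):
    mask = np.zeros(ds.config.genome_size, dtype=bool)
    for _, s, e in ds.truth.intervals():
        mask[s:e] = True
    cov = ds.per_base_coverage()
    return cov[mask].mean(), cov[~mask].mean()


def test_peak_coverage_is_x_plus_y():
    """Mean per-base depth over peak regions approximates x + y."""
    cfg = SimulationConfig(genome_size=1_000_000,
                           template_starts=tuple(range(20_000, 980_000, 48_000)),
                           peak_width=5000, peak_coverage=5, noise_coverage=1, seed=11)
    ds = simulate_dataset(cfg)
    assert len(ds.truth.intervals()) == 20
    peak_mean, bg_mean = _coverage_split(ds)
    assert peak_mean == pytest.approx(6.0, rel=0.10)
    assert bg_mean == pytest.approx(1.0, rel=0.10)


def test_zero_enrichment_is_flat():
    """y = 0: peak regions look like background (within 3 standard errors)."""
    cfg = SimulationConfig(genome_size=500_000,
                           template_starts=tuple(range(20_000, 450_000, 40_000)),
                           peak_width=5000, peak_coverage=0, noise_coverage=2, seed=4)
    ds = simulate_dataset(cfg)
    peak_mean, bg_mean = _coverage_split(ds)
    peak_bp = sum(e - s for _, s, e in ds.truth.intervals())
    # per-base depths are correlated over ~read_length, so SE uses bp/read_length draws
    se = np.sqrt(2.0 * cfg.read_length / peak_bp)
    assert abs(peak_mean - bg_mean) < 3 * se


def test_windows_in_peaks_are_enriched():
    cfg = SimulationConfig(genome_size=500_000,
                           template_starts=tuple(range(20_000, 450_000, 40_000)),
                           peak_width=8000, peak_coverage=3, noise_coverage=1, seed=9)
    ds = simulate_dataset(cfg)
    peak_mean, bg_mean = _coverage_split(ds)
    assert peak_mean > bg_mean


def test_same_seed_is_bit_identical():
    cfg = SimulationConfig(genome_size=200_000, template_starts=(10_000, 60_000),
                           peak_width=4000, peak_coverage=3, noise_coverage=1, seed=42)
    ds1, ds2 = simulate_dataset(cfg), simulate_dataset(cfg)
    np.testing.assert_array_equal(ds1.reads, ds2.reads)
    assert ds1.truth.intervals() == ds2.truth.intervals()


# ---------------------------------------------------------------------------
# the simulation grid


def test_grid_cardinalities():
    """Default axes: 18 peak-width sets x (7 x 6) = 42 variants per width."""
    configs = make_grid()
    assert len(GRID_PEAK_WIDTHS) == 18
    by_width = {w: [c for c in configs if c.peak_width == w] for w in GRID_PEAK_WIDTHS}
    assert len(by_width) == 18
    assert all(len(v) == 42 for v in by_width.values())
    assert len(configs) == 18 * 42


def test_grid_is_width_major():
    configs = make_grid()
    widths = [c.peak_width for c in configs]
    assert widths == sorted(widths, key=lambda w: GRID_PEAK_WIDTHS.index(w))
    first = configs[:42]
    assert [(c.peak_coverage, c.noise_coverage) for c in first] == [
        (float(y), float(x)) for y, x in
        itertools.product(GRID_PEAK_COVERAGES, GRID_NOISE_COVERAGES)]


def test_single_point_axes():
    configs = make_grid(peak_widths=[1000], peak_coverages=[5], noise_coverages=[1])
    assert len(configs) == 1
    with pytest.raises(ConfigurationError):
        make_grid(peak_widths=[])


def test_config_file_roundtrip(tmp_path):
    cfg = SimulationConfig(genome_size=200_000, template_starts=(10_000, 60_000),
                           peak_width=4000, peak_coverage=3.5, noise_coverage=0.5,
                           seed=13)
    ds = simulate_dataset(cfg)
    path = tmp_path / "cfg.txt"
    ds.write_config(str(path))
    assert read_config(str(path)) == cfg


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimulationConfig(genome_size=10_000, template_starts=(9000,),
                         peak_width=2000, peak_coverage=1, noise_coverage=1)
    with pytest.raises(ConfigurationError):
        SimulationConfig(genome_size=10_000, template_starts=(),
                         peak_width=200, peak_coverage=1, noise_coverage=1)
    with pytest.raises(ConfigurationError):
        SimulationConfig(genome_size=10_000, template_starts=(0,),
                         peak_width=200, peak_coverage=-1, noise_coverage=1)
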