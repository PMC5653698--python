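"""Synthetic-data generator: banding, T-RFLP noise, qPCR, degradation."""

import numpy as np
import pytest

from siptrflp.errors import ConfigurationError, NotReachedError
from siptrflp.sequences import build_amplicon
from siptrflp.shift import fit_standard_curve
from siptrflp.simulate import (
    CompoundKinetics,
    SimulatorParams,
    Taxon,
    band_masses,
    max_interval_rate,
    sampling_day,
    simulate_degradation,
    simulate_experiment,
    simulate_gradient,
    simulate_qpcr_dilution_series,
    simulate_trflp,
    taxon_band_center,
)
from siptrflp.study import TAXON_TABLE, taxon_sequences
from siptrflp.trflp import HHAI, MSPI, terminal_fragment_length


def lone(gc=0.5, atom=0.0, trfs=None):
    return Taxon(
        "t",
        gc_fraction=gc,
        relative_abundance=1.0,
        atom_frac_13C=atom,
        true_trfs=trfs or {"HhaI": 341, "MspI": 403},
    )


class TestBandCenter:
    @pytest.mark.parametrize(
        "gc, atom, expected",
        [
            (0.5, 0.0, 1.709),
            (0.684, 0.0, 1.727032),
            (0.684, 0.61, 1.748992),
        ],
    )
    def test_examples(self, gc, atom, expected):
        center = taxon_band_center(lone(gc, atom), SimulatorParams())
        assert center == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Taxon("t", gc_fraction=1.5, relative_abundance=1.0)
        with pytest.raises(ValueError):
            Taxon("t", gc_fraction=0.5, relative_abundance=1.0, atom_frac_13C=-0.1)

    def test_gc_derived_from_sequence(self):
        taxon = Taxon("t", sequence="GGCCAATT", relative_abundance=1.0)
        assert taxon.gc_fraction == pytest.approx(0.5)


class TestGradient:
    def test_mass_conserved_per_taxon(self):
        community = [
            Taxon("a", gc_fraction=0.45, relative_abundance=0.3,
                  true_trfs={"HhaI": 100, "MspI": 200}),
            Taxon("b", gc_fraction=0.65, relative_abundance=0.7,
                  true_trfs={"HhaI": 300, "MspI": 400}),
        ]
        _, masses = band_masses(community, SimulatorParams())
        assert masses[0].sum() == pytest.approx(0.3, abs=1e-9)
        assert masses[1].sum() == pytest.approx(0.7, abs=1e-9)

    def test_unnormalized_community_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_gradient(
                [Taxon("a", gc_fraction=0.5, relative_abundance=0.5)],
                SimulatorParams(),
            )

    def test_degenerate_band_lands_in_nearest_fraction(self):
        params = SimulatorParams(band_sigma=1e-12, qpcr_lognormal_sd=0.0)
        _, masses = band_masses([lone(gc=0.684)], params)
        assert (masses > 0).sum() == 1

    def test_heaviest_first_ordering(self):
        series = simulate_gradient([lone()], SimulatorParams(seed=5))
        rhos = [f.buoyant_density for f in series.fractions]
        assert rhos == sorted(rhos, reverse=True)
        assert series.fractions[0].index == 1

    def test_deterministic_given_seed(self):
        a = simulate_experiment([lone()], SimulatorParams(seed=9), "c")
        b = simulate_experiment([lone()], SimulatorParams(seed=9), "c")
        assert [f.buoyant_density for f in a.fractions] == [
            f.buoyant_density for f in b.fractions
        ]
        assert [f.peaks for f in a.fractions] == [f.peaks for f in b.fractions]

    def test_band_center_outside_grid_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            band_masses([lone(gc=0.05)], SimulatorParams())


class TestTrflp:
    def test_zero_length_error_reproduces_true_lengths(self):
        params = SimulatorParams(seed=2, len_error_sd=0.0)
        series = simulate_experiment([lone()], params, "c")
        lengths = {
            p.length_bp for f in series.fractions for p in f.peaks["HhaI"]
        }
        assert lengths == {341}

    def test_length_error_clipped_at_four(self):
        params = SimulatorParams(seed=3, len_error_sd=10.0)
        series = simulate_experiment([lone()], params, "c")
        lengths = {
            p.length_bp for f in series.fractions for p in f.peaks["MspI"]
        }
        assert lengths and all(abs(L - 403) <= 4 for L in lengths)

    def test_comigrating_taxa_merge_fluorescence(self):
        community = [
            Taxon("a", gc_fraction=0.6, relative_abundance=0.5,
                  true_trfs={"HhaI": 341}),
            Taxon("b", gc_fraction=0.6, relative_abundance=0.5,
                  true_trfs={"HhaI": 341}),
        ]
        params = SimulatorParams(seed=0, len_error_sd=0.0, qpcr_lognormal_sd=0.0)
        series = simulate_gradient(community, params, "c")
        simulate_trflp(series, community, [HHAI], params)
        for frac in series.fractions:
            assert len(frac.peaks["HhaI"]) <= 1
        total = sum(p.fluorescence for f in series.fractions for p in f.peaks["HhaI"])
        assert total == pytest.approx(params.fluorescence_scale, rel=1e-9)

    def test_missing_trf_is_configuration_error(self):
        community = [Taxon("a", gc_fraction=0.5, relative_abundance=1.0)]
        params = SimulatorParams(seed=0)
        series = simulate_gradient(community, params, "c")
        with pytest.raises(ConfigurationError):
            simulate_trflp(series, community, [HHAI], params)


class TestQpcr:
    def test_noiseless_series_recovers_calibration(self):
        params = SimulatorParams(cq_noise_sd=0.0)
        pts = simulate_qpcr_dilution_series(1e8, 5, params)
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(params.qpcr_slope, abs=1e-9)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)

    def test_noisy_series_recovers_slope(self):
        slopes = []
        for seed in range(100):
            pts = simulate_qpcr_dilution_series(
                1e8, 6, SimulatorParams(seed=seed, cq_noise_sd=0.1)
            )
            slopes.append(fit_standard_curve(pts).slope)
        assert np.mean(slopes) == pytest.approx(-3.3219, abs=0.1)

    def test_two_levels_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr_dilution_series(1e8, 2, SimulatorParams())


DCM = CompoundKinetics(initial_mg_L=30.0, lag_days=2.0, rate_per_day=0.5)


class TestDegradation:
    def test_initial_concentration(self):
        df = simulate_degradation({"DCM": DCM}, [0, 1, 2])
        assert df["DCM"].iloc[0] == 30.0

    def test_zero_rate_is_constant(self):
        k = CompoundKinetics(initial_mg_L=30.0, lag_days=0.0, rate_per_day=0.0)
        df = simulate_degradation({"x": k}, [0, 2, 5, 9])
        assert (df["x"] == 30.0).all()

    def test_first_order_after_lag(self):
        df = simulate_degradation({"DCM": DCM}, [0, 2, 4])
        assert df["DCM"].iloc[2] == pytest.approx(30 * np.exp(-1), abs=1e-9)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_degradation({"DCM": DCM}, [-1, 0, 1])

    def test_times_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            simulate_degradation({"DCM": DCM}, [1, 2, 3])


class TestRateSummaries:
    def test_constant_series_rate_zero_with_warning(self):
        with pytest.warns(UserWarning):
            rate, _ = max_interval_rate([0, 1, 2], [30.0, 30.0, 30.0])
        assert rate == 0.0

    def test_constructed_maximum_rate(self):
        rate, interval = max_interval_rate(
            [0, 1, 2, 3, 4], [30.0, 30.0, 30.0, 30.0, 18.1]
        )
        assert rate == pytest.approx(11.9)
        assert interval == (3.0, 4.0)

    def test_increasing_series_warns_negative(self):
        with pytest.warns(UserWarning):
            rate, _ = max_interval_rate([0, 1], [10.0, 20.0])
        assert rate == -10.0

    def test_one_point_rejected(self):
        with pytest.raises(ValueError):
            max_interval_rate([0], [30.0])


class TestSamplingDay:
    def test_day_within_window(self):
        # 75% degraded on day 4
        day = sampling_day([0, 1, 2, 3, 4], [30, 30, 28, 19.4, 7.5])
        assert day == 4.0

    def test_wide_open_target_returns_first_day_after_start(self):
        day = sampling_day([0, 1, 2], [30, 29, 20], target_fraction_range=(0.0, 1.0))
        assert day == 1.0

    def test_skipped_window_warns_and_returns_next_day(self):
        with pytest.warns(UserWarning, match="skipped"):
            day = sampling_day([0, 1, 2], [30.0, 18.0, 4.5])
        assert day == 2.0

    def test_never_reached(self):
        with pytest.raises(NotReachedError):
            sampling_day([0, 1, 2], [30.0, 29.0, 28.0])


class TestAmpliconBuilder:
    @pytest.mark.parametrize("ident, gc_count, trfs", [
        (t[0], t[2], t[3]) for t in TAXON_TABLE
    ])
    def test_default_community_sequences(self, ident, gc_count, trfs):
        seq = taxon_sequences()[ident]
        assert len(seq) == 980
        assert sum(b in "GC" for b in seq) == gc_count
        assert terminal_fragment_length(seq, HHAI) == trfs["HhaI"]
        assert terminal_fragment_length(seq, MSPI) == trfs["MspI"]

    @pytest.mark.parametrize("seed", range(5))
    def test_arbitrary_specs(self, seed):
        rng = np.random.default_rng(seed)
        h, m = sorted(rng.choice(np.arange(60, 900, 17), 2, replace=False))
        trfs = {"HhaI": int(h), "MspI": int(m)}
        gc = int(rng.integers(350, 700))
        seq = build_amplicon(trfs, gc, length=980, seed=seed)
        assert sum(b in "GC" for b in seq) == gc
        assert terminal_fragment_length(seq, HHAI) == trfs["HhaI"]
        assert terminal_fragment_length(seq, MSPI) == trfs["MspI"]

    def test_deterministic(self):
        a = build_amplicon({"HhaI": 341, "MspI": 403}, 650, seed=4)
        b = build_amplicon({"HhaI": 341, "MspI": 403}, 650, seed=4)
        assert a == b

    def test_overlapping_sites_rejected(self):
        with pytest.raises(ValueError):
            build_amplicon({"HhaI": 100, "MspI": 99}, 500)
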