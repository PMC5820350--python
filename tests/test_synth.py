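"""Synthetic-data generators: spectrum closed forms, read simulation and
ledger conservation, OD curves."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy import stats

from escapewatch.fitting import fit_stability
from escapewatch.isscan.align import align_to_reference
from escapewatch.isscan.breakpoints import InsertionEvent
from escapewatch.popmodel import ModelParams, producer_fraction
from escapewatch.growth import estimate_growth
from escapewatch import synth


def spectrum_of(load, rates):
    modes = tuple(
        synth.EscapeMode(
            label=f"m{i}",
            rate=r,
            event=InsertionEvent(position=1000 + 500 * i, subgroup="IS10",
                                 orientation="+", tsd_length=5),
        )
        for i, r in enumerate(rates)
    )
    return synth.EscapeSpectrum(load=load, modes=modes)


class TestSpectrumFrequencies:
    def test_single_mode_reduces_to_two_state_model(self):
        spec = spectrum_of(0.3, [1e-7])
        grid = np.linspace(0, 80, 9)
        truth = synth.simulate_spectrum_frequencies(spec, grid)
        np.testing.assert_allclose(
            truth.intact, producer_fraction(ModelParams(0.3, 1e-7), grid), rtol=1e-12
        )
        np.testing.assert_allclose(truth.mode_freqs["m0"], 1.0 - truth.intact, rtol=1e-9)

    def test_equal_rates_give_equal_frequencies(self):
        truth = synth.simulate_spectrum_frequencies(spectrum_of(0.3, [1e-6, 1e-6]), [10, 40, 70])
        np.testing.assert_allclose(truth.mode_freqs["m0"], truth.mode_freqs["m1"], rtol=1e-12)

    def test_rate_ratio_preserved_at_all_generations(self):
        truth = synth.simulate_spectrum_frequencies(spectrum_of(0.3, [1e-6, 1e-7]), [5, 30, 60, 90])
        ratio = truth.mode_freqs["m0"] / truth.mode_freqs["m1"]
        np.testing.assert_allclose(ratio, 10.0, rtol=1e-9)

    def test_matches_ode_integration(self):
        c, k1, k2 = 0.25, 3e-4, 1e-4
        spec = spectrum_of(c, [k1, k2])
        g_end = 25.0

        def rhs(t, y):
            P, n1, n2 = y
            return [(1 - c - k1 - k2) * P, n1 + k1 * P, n2 + k2 * P]

        sol = solve_ivp(rhs, (0, g_end), [1.0, 0.0, 0.0], rtol=1e-11, atol=1e-300)
        P, n1, n2 = sol.y[:, -1]
        truth = synth.simulate_spectrum_frequencies(spec, [g_end])
        assert truth.mode_freqs["m0"][0] == pytest.approx(n1 / (P + n1 + n2), rel=1e-7)
        assert truth.mode_freqs["m1"][0] == pytest.approx(n2 / (P + n1 + n2), rel=1e-7)

    def test_conservation_and_aggregate(self):
        spec = spectrum_of(0.281, [1e-7, 5e-8, 3e-8])
        grid = np.linspace(0, 100, 11)
        truth = synth.simulate_spectrum_frequencies(spec, grid)
        total = truth.intact + sum(truth.mode_freqs.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        np.testing.assert_allclose(
            truth.intact,
            producer_fraction(ModelParams(0.281, 1.8e-7), grid),
            rtol=1e-9,
        )

    def test_empty_spectrum_is_pure_producer(self):
        truth = synth.simulate_spectrum_frequencies(
            synth.EscapeSpectrum(load=0.3, modes=()), [0, 50]
        )
        np.testing.assert_array_equal(truth.intact, 1.0)


class TestStabilitySeriesGenerator:
    def test_zero_noise_is_exact_model_curve(self):
        grid = np.linspace(10, 80, 8)
        s = synth.simulate_stability_series(ModelParams(0.3, 1e-7), grid, noise_sd=0.0)
        params = ModelParams(0.3, 1e-7)
        expected = producer_fraction(params, grid) / producer_fraction(params, 10.0)
        np.testing.assert_allclose(s.values, expected, rtol=1e-12)

    def test_round_trip_fit_recovers_generator(self):
        grid = np.linspace(14, 80, 10)
        s = synth.simulate_stability_series(ModelParams(0.281, 2.1e-7), grid, noise_sd=0.0)
        fit = fit_stability(s)
        assert fit.estimates["load"] == pytest.approx(0.281, rel=1e-3)
        assert fit.estimates["escape_rate"] == pytest.approx(2.1e-7, rel=1e-3)

    def test_seed_determinism(self):
        grid = np.linspace(10, 70, 7)
        a = synth.simulate_stability_series(ModelParams(0.3, 1e-7), grid, 0.05, seed=9)
        b = synth.simulate_stability_series(ModelParams(0.3, 1e-7), grid, 0.05, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.sem, b.sem)


class TestReadSimulator:
    def test_intact_only_reads_align_cleanly(self, reference, catalog, spectrum):
        reads, ledger = synth.simulate_reads(
            reference, {"intact": 1.0}, catalog, spectrum, depth=120, seed=3
        )
        alns = align_to_reference(reads, reference)
        aligned = [a for a in alns if a is not None]
        assert len(aligned) / len(reads) > 0.99
        long_clips = [
            a for a in aligned if len(a.left_clip) >= 20 or len(a.right_clip) >= 20
        ]
        assert len(long_clips) == 0

    def test_ledger_conserves_fragments(self, reference, catalog, spectrum, planted_truth, readset):
        reads, ledger = readset
        counts = ledger["molecule_fragments"]
        assert sum(counts.values()) == ledger["n_pairs"]
        assert len(reads) == 2 * ledger["n_pairs"]

    def test_junction_fragment_count_binomial(self, reference, catalog, spectrum, readset):
        """Fragments attributed to the 10% insertion molecule are binomial
        around the mass-weighted expectation."""
        reads, ledger = readset
        n = ledger["n_pairs"]
        p = ledger["fragment_sampling_probabilities"]["IS10@1200"]
        obs = ledger["molecule_fragments"]["IS10@1200"]
        lo, hi = stats.binom.interval(0.999, n, p)
        assert lo <= obs <= hi

    def test_seed_determinism(self, reference, catalog, spectrum):
        a, _ = synth.simulate_reads(reference, {"intact": 1.0}, catalog, spectrum, depth=30, seed=5)
        b, _ = synth.simulate_reads(reference, {"intact": 1.0}, catalog, spectrum, depth=30, seed=5)
        assert a.seqs == b.seqs and a.names == b.names

    def test_event_outside_reference_rejected(self, reference, catalog):
        bad = synth.EscapeSpectrum(
            load=0.3,
            modes=(
                synth.EscapeMode(
                    label="bad",
                    rate=1e-7,
                    event=InsertionEvent(
                        position=len(reference) + 10, subgroup="IS10",
                        orientation="+", tsd_length=5,
                    ),
                ),
            ),
        )
        with pytest.raises(ValueError):
            synth.simulate_reads(reference, {"intact": 0.5, "bad": 0.5}, catalog, bad, depth=10, seed=0)

    def test_provenance_labels(self, readset):
        reads, _ = readset
        labels = set(reads.labels)
        assert "intact" in labels and "IS10@1200" in labels


class TestODGenerator:
    def test_noise_free_rate_recovery_exact_when_capacity_dwarfs_band(self):
        od = synth.simulate_od(0.5, carrying_capacity=1e5, noise_sd=0.0, seed=0)
        est = estimate_growth(od)
        assert est.mean_rate == pytest.approx(0.5, rel=1e-3)

    def test_emulated_study_rate(self):
        od = synth.simulate_od(0.84, noise_sd=0.0, seed=1)
        assert estimate_growth(od).mean_rate == pytest.approx(0.84, rel=0.02)

    def test_seed_determinism(self):
        a = synth.simulate_od(0.84, seed=4)
        b = synth.simulate_od(0.84, seed=4)
        np.testing.assert_array_equal(a.od_raw, b.od_raw)
        np.testing.assert_array_equal(a.blanks, b.blanks)

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            synth.simulate_od(0.0)
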