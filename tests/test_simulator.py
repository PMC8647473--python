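"""Process-simulator contracts: conservation, inhibition, transfer, recovery."""

import numpy as np
import pandas as pd
import pytest

import caproflux as cf
from caproflux.simulator import REACTIONS, SPECIES


def ledger_selectivity(out, t0, t1):
    """Ground-truth electron selectivities from the integrated reaction ledger."""
    led = out.ledger
    t = led["time_d"].to_numpy()
    i0, i1 = np.searchsorted(t, [t0, t1])
    reg = cf.Registry.default()
    rates = {}
    for s in SPECIES:
        d = led[f"cumprod_{s}_mmol_per_L"].iloc[i1] - led[f"cumprod_{s}_mmol_per_L"].iloc[i0]
        rates[s] = d / (t1 - t0) * reg[s].electron_eq
    dh2 = led["cum_h2_mmol_per_L"].iloc[i1] - led["cum_h2_mmol_per_L"].iloc[i0]
    rates["H2"] = dh2 / (t1 - t0) * 2
    return cf.electron_selectivity(rates)


class TestReactionBasis:
    def test_every_route_conserves_electrons_and_carbon(self, registry):
        for rxn in REACTIONS.values():
            rxn.check_balanced(registry)  # raises on imbalance

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cf.SimParams(inhib_start_mM=37.0, inhib_stop_mM=26.0)


class TestConservation:
    def test_electron_ledger_closes_on_biotic_run(self, nonextractive_run):
        assert cf.conservation_error(nonextractive_run) < 1e-6

    def test_electron_ledger_closes_with_extraction(self):
        cfg = cf.ReactorConfig(v_org=0.24)
        out = cf.simulate_cstr(cf.SimParams(), cfg, t_end=30.0)
        assert cf.conservation_error(out) < 1e-6

    def test_batch_without_reactions_conserves_mass_exactly(self, abiotic_batch_run):
        ts = abiotic_batch_run.timeseries
        total = ts.aq("n-caproate") * 0.04 + ts.org("n-caproate") * 0.008
        assert total == pytest.approx(total[0], rel=1e-9)


class TestTwoPhaseTransfer:
    def test_abiotic_mode_extracts_only_extractables(self):
        """With the synthetic-effluent feed, only MCC appear in the oil."""
        feed = {"lactate": 11.0, "acetate": 2.6, "n-butyrate": 1.3, "n-caproate": 6.1}
        cfg = cf.ReactorConfig(v_org=0.24, feed=feed)
        out = cf.simulate_cstr(cf.SimParams(x0_emeq_per_L=0.0), cfg, t_end=12.0)
        ts = out.timeseries
        assert ts.org("n-caproate")[-1] > 1.0
        for name in ("lactate", "acetate", "n-butyrate"):
            assert np.all(ts.org(name) == 0.0)

    def test_zero_kd_equals_single_phase_model(self):
        params = cf.SimParams(kd={})
        cfg2 = cf.ReactorConfig(v_org=0.24)
        cfg1 = cf.ReactorConfig(v_org=0.0)
        two = cf.simulate_cstr(params, cfg2, t_end=20.0)
        one = cf.simulate_cstr(params, cfg1, t_end=20.0)
        np.testing.assert_allclose(
            two.timeseries.aq("n-caproate"), one.timeseries.aq("n-caproate"),
            rtol=1e-6,
        )
        assert np.all(two.timeseries.org("n-caproate") == 0.0)

    def test_batch_equilibrium_recovery_matches_closed_form(self, abiotic_batch_run):
        ts = abiotic_batch_run.timeseries
        rec = cf.recovery(ts.org("n-caproate")[-1] * 0.008, ts.aq("n-caproate")[-1] * 0.04)
        assert rec == pytest.approx(cf.equilibrium_recovery(2.5, 0.2), abs=1e-9)

    def test_no_substrate_batch_stays_flat(self):
        params = cf.SimParams(x0_emeq_per_L=10.0, kd={})
        out = cf.simulate_batch(
            params, v_aq=0.04, v_org=0.008, t_end=5.0,
            initial_mM={"acetate": 50.0},
        )
        ace = out.timeseries.aq("acetate")
        assert ace == pytest.approx(np.full_like(ace, ace[0]), rel=1e-9)


class TestInhibition:
    @staticmethod
    def _initial_rate(nc6_mM):
        params = cf.SimParams(x0_emeq_per_L=100.0)
        out = cf.simulate_batch(
            params, v_aq=0.04, v_org=0.0001, t_end=0.2, dt_out=0.1,
            initial_mM={"lactate": 300.0, "acetate": 50.0, "n-caproate": nc6_mM},
        )
        led = out.ledger
        return (
            led["cumprod_n-caproate_mmol_per_L"].iloc[-1]
            - led["cumprod_n-caproate_mmol_per_L"].iloc[0]
        ) / 0.2

    def test_production_non_increasing_in_undissociated_acid(self):
        # pH 5.0, pKa 4.88: total nC6 of 0/65/75/95 mM spans the 26-37 mM
        # undissociated ramp (f_HA ~ 0.431).
        rates = [self._initial_rate(c) for c in (0.0, 65.0, 75.0, 95.0)]
        assert all(a >= b - 1e-9 for a, b in zip(rates, rates[1:]))
        assert rates[1] < rates[0]

    def test_production_ceases_above_stop_threshold(self):
        assert self._initial_rate(95.0) <= 0.0 + 1e-9  # HA ~ 41 mM > 37

    def test_extraction_relieves_inhibition(self):
        """Cumulative nC6 with solvent >= without, under active inhibition."""
        params = cf.SimParams()
        t_end = 60.0
        on = cf.simulate_cstr(params, cf.ReactorConfig(v_org=0.24), t_end=t_end)
        off = cf.simulate_cstr(params, cf.ReactorConfig(v_org=0.0), t_end=t_end)
        # steady state sits inside the attenuation ramp (inhibition active)
        ha = off.timeseries.aq("n-caproate")[-1] / 116.16 * 1000 * cf.undissociated_fraction(5.0, 4.88)
        assert ha > 26.0
        cum_on = on.ledger["cumprod_n-caproate_mmol_per_L"].iloc[-1]
        cum_off = off.ledger["cumprod_n-caproate_mmol_per_L"].iloc[-1]
        assert cum_on >= cum_off


class TestSelectivityRecovery:
    def test_performance_module_recovers_imposed_split(self, nonextractive_run, registry):
        """Accounting on sampled output matches the generator's own ledger."""
        out = nonextractive_run
        period = (60.0, 80.0)
        s = cf.build_period_summary(out.timeseries, out.config, period, registry)
        truth = ledger_selectivity(out, *period)
        for name, expected in truth.items():
            assert s.electron_selectivity_pct[name] == pytest.approx(expected, abs=0.5)


class TestNoiseAndDeterminism:
    def test_zero_sd_is_identity(self, nonextractive_run):
        ts = nonextractive_run.timeseries
        same = cf.add_measurement_noise(ts, 0.0, seed=3)
        pd.testing.assert_frame_equal(ts.data, same.data)

    def test_same_seed_reproduces(self, nonextractive_run):
        ts = nonextractive_run.timeseries
        a = cf.add_measurement_noise(ts, 0.05, seed=11)
        b = cf.add_measurement_noise(ts, 0.05, seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = cf.add_measurement_noise(ts, 0.05, seed=12)
        assert not a.data.equals(c.data)

    def test_empirical_cv_matches_sd(self):
        rows = 10_000
        data = pd.DataFrame(
            {"time_d": np.arange(rows, dtype=float), "pH": 5.0,
             "n-caproate_aq_g_per_L": 10.0}
        )
        noisy = cf.add_measurement_noise(cf.ReactorTimeSeries(data), 0.05, seed=5)
        vals = noisy.aq("n-caproate")
        cv = vals.std() / vals.mean()
        assert cv == pytest.approx(0.05, abs=0.005)

    def test_seeded_simulations_bit_identical(self):
        params = cf.SimParams(noise_sd=0.05, seed=21)
        cfg = cf.ReactorConfig()
        a = cf.simulate_cstr(params, cfg, t_end=10.0)
        b = cf.simulate_cstr(params, cfg, t_end=10.0)
        pd.testing.assert_frame_equal(a.timeseries.data, b.timeseries.data)


class TestKdFit:
    def test_noiseless_recovery_within_2_percent(self, abiotic_batch_run):
        fit = cf.fit_kd(abiotic_batch_run.timeseries, "n-caproate")
        assert fit.kd == pytest.approx(2.5, rel=0.02)

    def test_noisy_recovery_within_10_percent(self, abiotic_batch_run):
        ts = abiotic_batch_run.timeseries.window(
            abiotic_batch_run.timeseries.time[-30], 1e9
        )
        noisy = cf.add_measurement_noise(ts, 0.05, seed=4)
        fit = cf.fit_kd(noisy, "n-caproate", tail_fraction=1.0)
        assert fit.n_points == 30
        assert fit.kd == pytest.approx(2.5, rel=0.10)

    def test_kd_zero_estimates_zero(self):
        params = cf.SimParams(x0_emeq_per_L=0.0, kd={"n-caproate": 0.0})
        out = cf.simulate_batch(
            params, v_aq=0.04, v_org=0.008, t_end=5.0,
            initial_mM={"n-caproate": 50.0},
        )
        assert cf.fit_kd(out.timeseries, "n-caproate").kd == 0.0

    def test_too_few_points_rejected(self, abiotic_batch_run):
        short = cf.ReactorTimeSeries(abiotic_batch_run.timeseries.data.iloc[:2])
        with pytest.raises(ValueError):
            cf.fit_kd(short, "n-caproate")
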