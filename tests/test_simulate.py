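"""Telegraph simulator: p53 dynamics, k_on modulation, exactness."""

import numpy as np
import pandas as pd
import pytest

from burstquant import (
    ExperimentDesign,
    GeneModel,
    TelegraphParams,
    p53_profile,
    kon_modulation,
    sample_population,
    simulate_allele,
    steady_state_moments,
)
from burstquant.io import write_population
from burstquant.simulate import (
    _simulate_population,
    constant_kon,
    gillespie_telegraph,
    p_on_trajectory,
)


class TestP53Profile:
    def test_pulsatile_normalised_to_first_peak(self):
        prof = p53_profile("pulsatile", [0, 3, 6, 9])
        levels = dict(zip(prof.times_h, prof.p53_level))
        assert levels[3.0] == pytest.approx(1.0, abs=1e-3)
        assert levels[9.0] == pytest.approx(1.0, abs=1e-3)
        assert levels[6.0] < 0.25  # trough between the pulses
        assert levels[0.0] == 0.0  # pre-damage basal

    def test_transient_decays_after_single_pulse(self):
        prof = p53_profile("transient", [3, 9])
        assert prof.p53_level[0] == pytest.approx(1.0, abs=1e-3)
        assert prof.p53_level[1] <= 0.2

    def test_sustained_plateau_at_peak_level(self):
        prof = p53_profile("sustained", [3, 6, 9])
        assert all(v >= 1.0 - 1e-9 for v in prof.p53_level)

    def test_unknown_mode_and_out_of_range_times_rejected(self):
        with pytest.raises(ValueError):
            p53_profile("oscillatory", [0, 3])
        with pytest.raises(ValueError):
            p53_profile("pulsatile", [0, 15])


class TestKonModulation:
    def setup_method(self):
        self.profile = p53_profile("pulsatile", [0, 3, 6, 9])

    def test_never_below_basal(self):
        for arch in ("transient", "pulsatile", "sustained"):
            kon = kon_modulation(TelegraphParams(archetype=arch), self.profile)
            t = np.linspace(0, 12, 121)
            assert np.all(kon(t) >= TelegraphParams().k_on_basal - 1e-12)
            assert np.all(kon(t) <= kon.max_rate + 1e-12)

    def test_no_p53_gives_constant_basal(self):
        kon = kon_modulation(TelegraphParams(archetype="pulsatile"), None)
        assert np.allclose(kon([0.0, 3.0, 9.0]), TelegraphParams().k_on_basal)

    def test_sustained_latches_at_first_peak(self):
        kon = kon_modulation(TelegraphParams(archetype="sustained"), self.profile)
        assert kon(9.0) == pytest.approx(float(kon(3.0)), rel=1e-3)
        assert kon(6.0) >= float(kon(3.0)) * 0.999

    def test_transient_does_not_rerise_at_second_peak(self):
        kon = kon_modulation(TelegraphParams(archetype="transient"), self.profile)
        assert float(kon(9.0)) < float(kon(3.0))
        # relaxed most of the way back to basal by the second peak
        basal = TelegraphParams().k_on_basal
        assert float(kon(9.0)) < basal + 0.2 * (float(kon(3.0)) - basal)

    def test_pulsatile_tracks_both_peaks(self):
        kon = kon_modulation(TelegraphParams(archetype="pulsatile"), self.profile)
        assert float(kon(9.0)) == pytest.approx(float(kon(3.0)), rel=1e-3)
        assert float(kon(6.0)) < 0.4 * float(kon(3.0))


class TestSimulateAllele:
    def setup_method(self):
        self.gene = GeneModel("g", 6000, 1, tuple(range(200, 5800, 200)))

    def test_absorbing_empty_state(self):
        params = TelegraphParams(k_on_basal=0.0, k_off=1.0, init_rate=50.0,
                                 deg_rate=1.0, export_rate=5.0)
        snap = simulate_allele(self.gene, params, 0.0, t_end=10.0, seed=1,
                               initial_state="off")
        assert snap.nuclear_count == 0 and snap.cytoplasmic_count == 0
        assert snap.nascent_positions_nt.size == 0
        assert not snap.promoter_on

    def test_same_seed_same_trajectory(self):
        params = TelegraphParams()
        a = simulate_allele(self.gene, params, 0.5, t_end=8.0, seed=7, t_start=-10.0)
        b = simulate_allele(self.gene, params, 0.5, t_end=8.0, seed=7, t_start=-10.0)
        assert a.promoter_on == b.promoter_on
        assert a.nuclear_count == b.nuclear_count
        assert a.cytoplasmic_count == b.cytoplasmic_count
        assert np.array_equal(a.nascent_positions_nt, b.nascent_positions_nt)

    def test_constitutive_birth_death_mean(self):
        # k_off = 0: mature count is a simple birth-death, mean r/d
        params = TelegraphParams(k_on_basal=1.0, k_off=0.0, init_rate=30.0,
                                 deg_rate=1.0, export_rate=6.0)
        rng = np.random.default_rng(11)
        sim = _simulate_population(self.gene, params, constant_kon(1.0),
                                   -12.0, 0.0, 10_000, rng, initial_state="on")
        tot = sim["nuc_count"] + sim["cyt_count"]
        se = tot.std(ddof=1) / np.sqrt(tot.size)
        assert abs(tot.mean() - 30.0) < 3 * se


class TestSteadyStateMoments:
    def test_closed_form_example(self):
        params = TelegraphParams(k_on_basal=1.0, k_off=9.0, init_rate=100.0,
                                 deg_rate=1.0, export_rate=6.0)
        m = steady_state_moments(params, n_alleles=1)
        assert m["mean"] == pytest.approx(10.0)
        assert m["fano"] == pytest.approx(1.0 + 900.0 / 110.0)

    def test_constitutive_is_poisson(self):
        params = TelegraphParams(k_on_basal=1.0, k_off=0.0, init_rate=50.0,
                                 deg_rate=2.0, export_rate=6.0)
        assert steady_state_moments(params)["fano"] == 1.0

    def test_alleles_are_additive(self):
        params = TelegraphParams()
        one = steady_state_moments(params, 1)
        two = steady_state_moments(params, 2)
        assert two["mean"] == pytest.approx(2 * one["mean"])
        assert two["fano"] == pytest.approx(one["fano"])

    def test_no_steady_state_without_degradation(self):
        with pytest.raises(ValueError):
            steady_state_moments(TelegraphParams(deg_rate=0.0))

    def test_ssa_cross_check(self):
        # independent classical Gillespie agrees with the closed form
        params = TelegraphParams(k_on_basal=1.0, k_off=9.0, init_rate=100.0,
                                 deg_rate=1.0, export_rate=6.0)
        x = gillespie_telegraph(params, 5_000, 15.0, np.random.default_rng(3))
        ref = steady_state_moments(params)
        se = x.std(ddof=1) / np.sqrt(x.size)
        assert abs(x.mean() - ref["mean"]) < 3 * se


class TestSamplePopulation:
    def test_truth_p_on_matches_rates(self, basal_population, bursty_params):
        sample, _ = basal_population
        p_on = bursty_params.p_on_basal
        assert sample.truth["f_true"].iloc[0] == pytest.approx(p_on, abs=1e-6)
        n_alleles = sample.truth["n_alleles_on"].sum()
        total = 4 * len(sample.truth)
        se = np.sqrt(p_on * (1 - p_on) / total)
        assert abs(n_alleles / total - p_on) < 3 * se

    def test_tss_rows_only_for_nascent_alleles(self, basal_population):
        sample, _ = basal_population
        tss = sample.spots[sample.spots["spot_type"] == "TSS"]
        per_cell = tss.groupby("cell_id").size()
        truth = sample.truth.set_index("cell_id")
        # a cell can never show more TSS rows than nascent-bearing alleles
        assert (per_cell <= truth.loc[per_cell.index, "nascent_total"]).all()
        # cells without nascent transcripts emit no TSS row
        idle = truth[truth["nascent_total"] == 0].index
        assert not tss["cell_id"].isin(idle).any()

    def test_tss_intensity_counts_polymerases(self, gene10k, basal_population,
                                              bursty_params):
        # population mean of Int_TSS/(kappa*eta*mInt) recovers the mean
        # nascent load per active allele - the identity inference inverts
        sample, _ = basal_population
        tss = sample.spots[sample.spots["spot_type"] == "TSS"]
        occup = tss["intensity"] / (gene10k.kappa * gene10k.eta * 1.0)
        # every nascent-bearing allele emits exactly one TSS row, so the
        # mean load per active allele is total nascent / #TSS rows
        mean_load = sample.truth["nascent_total"].sum() / len(tss)
        assert occup.mean() == pytest.approx(mean_load, rel=0.05)

    def test_nuclear_cytoplasmic_ratio_is_deg_over_export(self, basal_population,
                                                          bursty_params):
        sample, _ = basal_population
        ratio = sample.truth["nuc_count"].mean() / sample.truth["cyt_count"].mean()
        expected = bursty_params.deg_rate / bursty_params.export_rate
        assert ratio == pytest.approx(expected, rel=0.2)

    def test_seed_determinism_byte_identical_tables(self, gene10k, bursty_params,
                                                    tmp_path):
        design = ExperimentDesign(timepoints_h=(0.0, 3.0), treatment="IR_pulsatile",
                                  n_cells_per_timepoint=50, seed=5)
        pa = write_population(sample_population(gene10k, bursty_params, design),
                              tmp_path / "a")
        pb = write_population(sample_population(gene10k, bursty_params, design),
                              tmp_path / "b")
        for key in ("spots", "cells", "truth"):
            assert pa[key].read_bytes() == pb[key].read_bytes()


def test_p_on_trajectory_constant_rates_is_stationary():
    params = TelegraphParams(k_on_basal=0.5, k_off=1.5, init_rate=10.0,
                             deg_rate=1.0, export_rate=6.0)
    p = p_on_trajectory(params, constant_kon(0.5), -10.0, [0.0, 5.0])
    assert np.allclose(p, 0.25, atol=1e-6)
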