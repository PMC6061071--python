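import numpy as np
import pytest

from telprop.closed_forms import (binomial_decay, closed_forms,
                                  poisson_immigration_death)
from telprop.fsp import FSPConfig, fsp_propagate
from telprop.params import (ChiSpec, ModelAParams, ModelBParams, Regulation,
                            RegulationB, chi_markov)
from telprop.ssa import (TransitionSeries, empirical_propagator, ssa_simulate,
                         synth_series)


class TestClosedForms:
    def test_poisson_limit_mean(self):
        pmf = poisson_immigration_death(3.0, 50.0, 60)
        assert np.dot(np.arange(61), pmf) == pytest.approx(3.0, rel=1e-6)

    def test_binomial_point_mass_at_zero_molecules(self):
        assert binomial_decay(0, 1.0)[0] == 1.0

    @pytest.mark.parametrize("kind,params", [
        ("poisson_immigration_death", {"lam": 2.5, "n_max": 60}),
        ("binomial_decay", {"n0": 7}),
    ])
    def test_pmfs_normalised(self, kind, params):
        pmf = closed_forms(kind, params, 0.8)
        assert abs(pmf.sum() - 1) < 1e-14


class TestFSP:
    def test_initial_delta_distribution(self, telegraph_a):
        tab = fsp_propagate("A", telegraph_a, 4, 0.5, 0.0)
        assert tab.P[4] == pytest.approx(1.0)
        assert tab.mass == pytest.approx(1.0, abs=1e-12)

    def test_permanently_active_is_poisson(self):
        p = ModelAParams(0.0, 0.0, 2.0)
        tab = fsp_propagate("A", p, 0, 0.0, 1.2)
        ref = poisson_immigration_death(2.0, 1.2, len(tab.P) - 1)
        assert np.max(np.abs(tab.P - ref)) < 1e-8

    @pytest.mark.parametrize("t", [0.1, 1.0, 3.0])
    def test_probability_conserved(self, telegraph_a, t):
        tab = fsp_propagate("A", telegraph_a, 5, 0.4, t)
        assert abs(tab.mass - 1) < 1e-10

    def test_linearity_in_initial_gene_split(self, telegraph_a):
        chi = 0.3
        mix = fsp_propagate("A", telegraph_a, 3, chi, 0.8).P
        off = fsp_propagate("A", telegraph_a, 3, 1.0, 0.8).P
        on = fsp_propagate("A", telegraph_a, 3, 0.0, 0.8).P
        assert np.max(np.abs(mix - (chi * off + (1 - chi) * on))) < 1e-12

    def test_model_b_joint_mass(self, telegraph_b):
        tab = fsp_propagate("B", telegraph_b, (1, 4), 0.5, 0.5)
        assert abs(tab.mass - 1) < 1e-9
        assert tab.P.ndim == 2


class TestSSA:
    def test_frozen_system_stays_put(self):
        # no production, no switching, nothing to decay: trajectories are
        # constant (protein decay itself is fixed at rate n by the time unit)
        p = ModelAParams(0.0, 0.0, 0.0)
        run = ssa_simulate("A", p, 0, 1.0, 1.0, 50, seed=1,
                           record_times=[0.0, 1.0])
        assert np.all(run.counts[:, :, 1] == 0)
        assert np.all(run.counts[:, :, 0] == 0)

    def test_identical_seeds_identical_paths(self, telegraph_a):
        kw = dict(record_times=[0.5, 1.0])
        a = ssa_simulate("A", telegraph_a, 3, 0.5, 1.0, 100, seed=7, **kw)
        b = ssa_simulate("A", telegraph_a, 3, 0.5, 1.0, 100, seed=7, **kw)
        assert np.array_equal(a.counts, b.counts)
        c = ssa_simulate("A", telegraph_a, 3, 0.5, 1.0, 100, seed=8, **kw)
        assert not np.array_equal(a.counts, c.counts)

    def test_immigration_death_mean_within_mc_error(self):
        p = ModelAParams(0.0, 0.0, 3.0)
        n_paths = 10000
        run = ssa_simulate("A", p, 0, 0.0, 1.0, n_paths, seed=42,
                           record_times=[1.0])
        counts = run.counts[:, 0, 1]
        mean = 3.0 * (1 - np.exp(-1.0))
        stderr = np.sqrt(mean / n_paths)   # Poisson variance = mean
        assert abs(counts.mean() - mean) < 3 * stderr

    def test_empirical_propagator_matches_fsp(self, telegraph_a):
        n_paths = 20000
        run = ssa_simulate("A", telegraph_a, 3, 0.5, 1.0, n_paths, seed=11,
                           record_times=[1.0])
        emp = empirical_propagator(run, 1.0)
        assert emp.mass == pytest.approx(1.0)
        fsp = fsp_propagate("A", telegraph_a, 3, 0.5, 1.0)
        K = len(emp.P)
        tv = 0.5 * np.sum(np.abs(emp.P - fsp.P[:K])) + 0.5 * fsp.P[K:].sum()
        assert tv < 3 * np.sqrt(K / n_paths)

    def test_unrecorded_time_is_an_error(self, telegraph_a):
        run = ssa_simulate("A", telegraph_a, 3, 0.5, 1.0, 10, seed=2)
        with pytest.raises(ValueError):
            empirical_propagator(run, 0.123)


class TestSynthSeries:
    def test_single_sample_has_no_transitions(self, telegraph_a):
        s = synth_series("A", telegraph_a, 0.5, 3, 0.5, 1, seed=3)
        assert s.transitions == []

    def test_regular_grid_and_transition_count(self, telegraph_a):
        s = synth_series("A", telegraph_a, 0.5, 3, 0.25, 12, seed=3)
        assert len(s.counts) == 12
        assert len(s.transitions) == 11
        assert np.allclose(np.diff(s.times), 0.25)

    def test_stationary_distribution_of_permanently_active_model(self):
        # long immigration-death series should look Poisson(lam)
        p = ModelAParams(0.0, 0.0, 4.0)
        s = synth_series("A", p, 0.0, 4, 0.5, 3000, seed=9)
        counts = np.asarray(s.counts[100:])
        assert counts.mean() == pytest.approx(4.0, abs=0.3)
        assert counts.var() == pytest.approx(4.0, abs=0.8)

    def test_tsv_round_trip(self, telegraph_a):
        s = synth_series("A", telegraph_a, 0.5, 3, 0.5, 8, seed=3)
        back = TransitionSeries.from_tsv(s.to_tsv())
        assert back.dt == s.dt
        assert np.array_equal(back.counts, s.counts)


@pytest.mark.parametrize("reg,kw", [
    (Regulation.AUTOACTIVATION, {"alpha": 1.0}),
    (Regulation.AUTOREPRESSION, {"rho": 1.0}),
])
def test_ssa_vs_fsp_with_feedback_channels_a(reg, kw):
    p = ModelAParams(1.0, 1.0, 2.0, reg, delta=0.3, **kw)
    chi0 = chi_markov(p, None, 3)
    n_paths = 10000
    run = ssa_simulate("A", p, 3, chi0, 1.0, n_paths, seed=5,
                       record_times=[1.0])
    emp = empirical_propagator(run, 1.0)
    fsp = fsp_propagate("A", p, 3, chi0, 1.0)
    K = len(emp.P)
    tv = 0.5 * np.sum(np.abs(emp.P - fsp.P[:K])) + 0.5 * fsp.P[K:].sum()
    assert tv < 3 * np.sqrt(K / n_paths)


def test_ssa_vs_fsp_model_b_mrna_feedback():
    p = ModelBParams(1.0, 1.0, 2.0, 1.0, 0.1, RegulationB.MRNA_ACT,
                     delta=0.3, reg_coeff=1.0)
    chi0 = chi_markov(p, 1, 3)
    n_paths = 10000
    run = ssa_simulate("B", p, (1, 3), chi0, 1.0, n_paths, seed=6,
                       record_times=[1.0])
    emp = empirical_propagator(run, 1.0)
    prot = fsp_propagate("B", p, (1, 3), chi0, 1.0).P.sum(axis=0)
    K = len(emp.P)
    tv = 0.5 * np.sum(np.abs(emp.P - prot[:K])) + 0.5 * prot[K:].sum()
    assert tv < 3 * np.sqrt(K / n_paths)
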