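"""Expected-SFS engine: closed forms, symmetries, degeneracies, residuals."""

import numpy as np
import pytest

from sfsflow.demography import get_model
from sfsflow.engine import (DEFAULT_CONFIG, EngineConfig, EngineError,
                            equilibrium_1d, expected_sfs, integrate_1d,
                            jackknife_matrix, mixture_sfs, residuals)
from sfsflow.sfs import JointSFS, project_sfs

CFG = EngineConfig(dt_fac=0.02, order_buffer=5)


class TestOneDimensional:
    def test_equilibrium_is_theta_over_i(self):
        """Integrating from an empty spectrum converges to xi_i = theta/i."""
        n = 20
        phi = integrate_1d(np.zeros(n + 1), nu=1.0, T=30.0, config=CFG)
        i = np.arange(1, n)
        assert np.max(np.abs(phi[1:n] * i - 1.0)) < 1e-2

    def test_transient_tightens_under_step_refinement(self):
        """Mid-relaxation spectra converge as the step shrinks (the
        equilibrium itself is a fixed point of the scheme at any step)."""
        n = 12
        ref = integrate_1d(np.zeros(n + 1), 1.0, 0.5, EngineConfig(dt_fac=0.001))
        errs = []
        for dtf in (0.25, 0.025):
            phi = integrate_1d(np.zeros(n + 1), 1.0, 0.5, EngineConfig(dt_fac=dtf))
            errs.append(np.max(np.abs(phi[1:n] - ref[1:n])))
        assert errs[1] < errs[0] / 10

    def test_heterozygosity_decay_rate(self):
        """With n=2 the singleton class decays as exp(-t/nu)."""
        phi = np.array([0.0, 1.0, 0.0])
        for nu in (0.5, 2.0):
            out = integrate_1d(phi.copy(), nu, 0.4, CFG)
            # subtract the mutation-influx equilibrium component
            eq = equilibrium_1d(2) * nu
            expected = eq[1] + (1 - eq[1]) * np.exp(-0.4 / nu)
            assert out[1] == pytest.approx(expected, rel=1e-3)


class TestJackknife:
    def test_projection_consistency(self):
        """The closure reproduces the lower-order spectrum exactly under
        hypergeometric downward projection."""
        for n in (6, 11, 20):
            J = jackknife_matrix(n)
            P = np.zeros((n + 1, n + 2))
            for i in range(n + 1):
                P[i, i] = (n + 1 - i) / (n + 1)
                P[i, i + 1] = (i + 1) / (n + 1)
            np.testing.assert_allclose(P @ J, np.eye(n + 1), atol=1e-9)

    def test_exact_on_neutral_spectrum(self):
        """theta/i is sampling-consistent, so its extension is theta/i."""
        n = 14
        est = jackknife_matrix(n) @ equilibrium_1d(n)
        np.testing.assert_allclose(est[1:n + 1] * np.arange(1, n + 1), 1.0,
                                   atol=2e-2)


class TestExpectedSFS:
    def test_symmetric_model_symmetric_spectrum(self, im_model):
        sfs = expected_sfs(im_model, [0.3, 1.0, 1.0, 1.5], 10, 10, CFG)
        np.testing.assert_allclose(sfs.counts, sfs.counts.T, atol=1e-10)

    def test_asymmetry_direction(self):
        """More migration into pop 1 shifts shared variation toward pop 1
        resembling pop 2 (higher minor-allele sharing)."""
        m = get_model("e1ma")
        into1 = expected_sfs(m, [0.3, 1.0, 1.0, 4.0, 0.0], 8, 8, CFG)
        into2 = expected_sfs(m, [0.3, 1.0, 1.0, 0.0, 4.0], 8, 8, CFG)
        np.testing.assert_allclose(into1.counts, into2.counts.T, atol=1e-8)
        assert not np.allclose(into1.counts, into2.counts)

    def test_sample_size_validation(self, im_model):
        with pytest.raises(EngineError):
            expected_sfs(im_model, [0.3, 1, 1, 1.5], 1, 8, CFG)

    def test_projection_commutes(self, im_model):
        big = expected_sfs(im_model, [0.4, 1.5, 0.7, 0.8], 14, 12, CFG)
        small = expected_sfs(im_model, [0.4, 1.5, 0.7, 0.8], 8, 6, CFG)
        proj = project_sfs(big, 8, 6)
        rel = np.abs(proj.counts - small.counts)[small.mask] / \
            np.maximum(small.counts[small.mask], 1e-12)
        assert np.max(rel) < 1e-2

    def test_fst_decreases_with_migration(self, im_model):
        """Symmetric migration homogenizes the populations monotonically."""
        def fst(sfs):
            # Hudson-style from the spectrum: 1 - pi_within / pi_total
            n1, n2 = sfs.n1, sfs.n2
            i = np.arange(n1 + 1)[:, None]
            j = np.arange(n2 + 1)[None, :]
            p1, p2 = i / n1, j / n2
            w = sfs.counts
            pi_w = (w * (p1 * (1 - p1) + p2 * (1 - p2))).sum()
            pi_b = (w * (p1 * (1 - p2) + p2 * (1 - p1))).sum()
            return 1 - pi_w / pi_b
        vals = [fst(expected_sfs(im_model, [0.5, 1, 1, m], 8, 8, CFG))
                for m in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestDegeneracies:
    def test_zero_island_fraction_equals_plain_model(self):
        plain = get_model("e1ms")
        isl = get_model("e1msi")
        a = expected_sfs(plain, [0.3, 1.0, 1.0, 1.5], 10, 10, CFG)
        b = expected_sfs(isl, [0.3, 1.0, 1.0, 1.5, 0.0, 0.5], 10, 10, CFG)
        np.testing.assert_allclose(a.counts, b.counts, rtol=1e-6)

    def test_island_factor_one_equals_plain_model(self):
        plain = get_model("e1ms")
        isl = get_model("e1msi")
        a = expected_sfs(plain, [0.3, 1.0, 1.0, 1.5], 10, 10, CFG)
        b = expected_sfs(isl, [0.3, 1.0, 1.0, 1.5, 0.7, 1.0], 10, 10, CFG)
        np.testing.assert_allclose(a.counts, b.counts, rtol=1e-6)

    def test_full_island_zero_factor_equals_isolated_epoch(self):
        """P=1, b=0 in a contact epoch equals removing its migration."""
        isl = get_model("e1msi")
        iso = get_model("e1m0")
        a = expected_sfs(isl, [0.3, 1.0, 1.0, 1.5, 1.0, 0.0], 10, 10, CFG)
        b = expected_sfs(iso, [0.3, 1.0, 1.0], 10, 10, CFG)
        rel = np.abs(a.counts - b.counts)[a.mask] / np.maximum(b.counts[a.mask], 1e-12)
        assert np.max(rel) < 1e-6

    def test_middle_epoch_zero_duration_nests(self):
        """3-epoch model with T_mid = 0 equals the nested 2-epoch model."""
        m3 = get_model("e3ms0a")
        m2 = get_model("e2msa")
        v3 = [0.4, 1.0, 1.0, 0.6,       # epoch 1: symmetric
              0.0, 1.0, 1.0,            # middle isolation, zero duration
              0.2, 1.5, 0.8, 0.9, 0.1]  # epoch 3: asymmetric
        v2 = [0.4, 1.0, 1.0, 0.6, 0.2, 1.5, 0.8, 0.9, 0.1]
        a = expected_sfs(m3, v3, 10, 10, CFG)
        b = expected_sfs(m2, v2, 10, 10, CFG)
        rel = np.abs(a.counts - b.counts)[a.mask] / np.maximum(b.counts[a.mask], 1e-12)
        assert np.max(rel) < 1e-8

    def test_mixture_requires_islands(self, im_model):
        with pytest.raises(EngineError):
            mixture_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, CFG)

    def test_mixture_equals_expected_for_island_model(self):
        isl = get_model("e1msi")
        vals = [0.3, 1.0, 1.0, 1.5, 0.4, 0.1]
        a = mixture_sfs(isl, vals, 8, 8, CFG)
        b = expected_sfs(isl, vals, 8, 8, CFG)
        np.testing.assert_allclose(a.counts, b.counts)


class TestResiduals:
    def test_exact_fit_zero_residuals(self, im_model):
        m = expected_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, CFG)
        data = JointSFS(2.0 * m.counts)
        r = residuals(data, m, 2.0)
        assert np.nanmax(np.abs(r)) < 1e-12

    def test_unit_residual_definition(self, im_model):
        m = expected_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, CFG)
        c = 2.0 * m.counts + np.sqrt(2.0 * m.counts)
        r = residuals(JointSFS(c), m, 2.0)
        np.testing.assert_allclose(r[JointSFS(c).mask], 1.0, atol=1e-10)

    def test_poisson_residual_sd_near_one(self, im_model):
        m = expected_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, CFG)
        theta = 5000.0
        rng = np.random.default_rng(3)
        data = JointSFS(rng.poisson(theta * m.counts).astype(float))
        r = residuals(data, m, theta)
        assert abs(np.nanstd(r) - 1.0) < 0.1

    def test_zero_model_nonzero_data_is_inf(self, im_model):
        m = expected_sfs(im_model, [0.3, 1, 1, 1.5], 8, 8, CFG)
        mm = m.copy()
        mm.counts[1, 1] = 0.0
        data = JointSFS(np.ones_like(m.counts))
        r = residuals(data, mm, 1.0)
        assert np.isinf(r[1, 1])
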