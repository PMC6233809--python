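"""HRF, design matrices, and OLS ROI fits."""

import numpy as np
import pandas as pd
import pytest

from tastepe.glm import (HRFSpec, build_design_matrix, canonical_hrf,
                         extract_roi_panel, fit_glm)
from tastepe.reward_task import (PETrace, RWModel, compute_pe_trace,
                                 generate_trial_sequence)


class TestCanonicalHRF:
    def test_peak_near_five_seconds(self):
        t, h = canonical_hrf()
        assert t[np.argmax(h)] == pytest.approx(5.0, abs=0.2)

    def test_positive_net_response(self):
        t, h = canonical_hrf()
        assert np.trapezoid(h, t) > 0

    def test_unit_peak_and_truncation(self):
        t, h = canonical_hrf()
        assert h.max() == pytest.approx(1.0)
        assert t[-1] <= 32.0 + 1e-9

    def test_grid_refinement_keeps_peak(self):
        t1, h1 = canonical_hrf(HRFSpec(microtime_dt_s=0.1))
        t2, h2 = canonical_hrf(HRFSpec(microtime_dt_s=0.05))
        assert abs(t1[np.argmax(h1)] - t2[np.argmax(h2)]) <= 0.1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            HRFSpec(peak_delay_s=-1)


class TestDesignMatrix:
    def test_dct_drift_column_count(self, default_sequence, default_trace):
        # floor(2 * 300 * 2.1 / 128) = 9 cosine drift regressors
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        drift = [n for n in X.names if n.startswith("drift_")]
        assert len(drift) == 9

    def test_drift_periods_exceed_cutoff(self, default_sequence, default_trace):
        # the fastest drift regressor completes k full cycles over the run:
        # its period 2 * T / k must stay above the high-pass cutoff
        n_scans, tr = 300, 2.1
        X = build_design_matrix(default_sequence, default_trace, tr, n_scans)
        k = len([n for n in X.names if n.startswith("drift_")])
        assert 2 * n_scans * tr / k > 128.0
        assert 2 * n_scans * tr / (k + 1) <= 128.0

    def test_drift_columns_mutually_orthogonal(self, default_sequence,
                                               default_trace):
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        D = np.column_stack([X.column(n) for n in X.names
                             if n.startswith("drift_")])
        G = D.T @ D
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_drift_basis_is_a_high_pass_filter(self, default_sequence,
                                               default_trace):
        # slow fluctuations are strongly attenuated while in-band task
        # frequencies pass nearly untouched (worst case over phase)
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        D = np.column_stack([X.column(n) for n in X.names
                             if n.startswith("drift_") or n == "intercept"])
        P = D @ np.linalg.pinv(D)
        t = np.arange(300) * 2.1

        def worst_residual(period):
            return max(
                np.sqrt(np.mean((y - P @ y) ** 2) / 0.5)
                for y in (np.sin(2 * np.pi * t / period + ph)
                          for ph in (0.0, np.pi / 4, np.pi / 2)))

        assert worst_residual(630.0) < 0.15   # run-length drift: mostly gone
        assert worst_residual(21.0) > 0.95    # task-band signal: retained
        assert worst_residual(630.0) < worst_residual(200.0)

    def test_empty_sequence_gives_drift_and_intercept(self):
        seq = generate_trial_sequence(0, 0, 0, seed=0)
        X = build_design_matrix(seq, None, 2.1, 300)
        assert all(n.startswith("drift_") or n == "intercept"
                   for n in X.names)

    def test_constant_modulator_dropped_with_warning(self):
        seq = generate_trial_sequence(5, 0, 0, p_violation=0.0, seed=1)
        flat = PETrace(delta=np.ones(5), abs_delta=np.ones(5),
                       trial_indices=np.arange(5))
        with pytest.warns(UserWarning, match="constant"):
            X = build_design_matrix(seq, flat, 2.1, 100)
        assert "pe_mod" not in X.names

    def test_events_beyond_scan_window_rejected(self, default_sequence,
                                                default_trace):
        with pytest.raises(ValueError, match="beyond the scan window"):
            build_design_matrix(default_sequence, default_trace, 2.1, 50)

    def test_task_regressors_carry_derivatives(self, default_sequence,
                                               default_trace):
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        for base in ("cs_sucrose", "pe_mod"):
            assert f"{base}_tderiv" in X.names
            assert f"{base}_dderiv" in X.names

    def test_deterministic(self, default_sequence, default_trace):
        X1 = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        X2 = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        assert np.array_equal(X1.matrix, X2.matrix)


class TestFitGLM:
    def test_noiseless_recovery_is_exact(self, default_sequence, default_trace):
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        y = 2.0 * X.column("pe_mod")
        fit = fit_glm(y[:, None], X)[0]
        assert fit.beta["pe_mod"] == pytest.approx(2.0, abs=1e-9)

    def test_residuals_orthogonal_to_design(self, default_sequence,
                                            default_trace):
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        rng = np.random.default_rng(4)
        y = rng.standard_normal(300)
        fit = fit_glm(y[:, None], X)[0]
        resid = y - X.matrix @ fit.beta.to_numpy()
        assert np.abs(X.matrix.T @ resid).max() < 1e-8

    def test_df_resid_accounts_for_rank(self, default_sequence, default_trace):
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        fit = fit_glm(np.random.default_rng(0).standard_normal((300, 1)), X)[0]
        assert fit.df_resid == 300 - np.linalg.matrix_rank(X.matrix)

    def test_rank_deficient_design_warns_and_fits(self, default_sequence,
                                                  default_trace, caplog):
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        dup = X.column("drift_01")
        Xdup = build_design_matrix(default_sequence, default_trace, 2.1, 300,
                                   nuisance=dup[:, None])
        with caplog.at_level("WARNING"):
            fit = fit_glm(dup[:, None], Xdup)[0]
        assert "rank deficient" in caplog.text
        assert np.isfinite(fit.beta).all()


class TestExtractROIPanel:
    def _fit(self, name, value, default_sequence, default_trace):
        X = build_design_matrix(default_sequence, default_trace, 2.1, 300)
        y = value * X.column("pe_mod")
        fit = fit_glm(pd.DataFrame({name: y}), X)[0]
        return fit

    def test_single_fit_identity(self, default_sequence, default_trace):
        fits = {"s0": [self._fit("roiA", 1.5, default_sequence, default_trace)]}
        panel = extract_roi_panel(fits)
        assert panel.loc["s0", "roiA"] == pytest.approx(1.5, abs=1e-9)

    def test_voxel_mean_over_duplicate_rois(self, default_sequence,
                                            default_trace):
        f1 = self._fit("roiA", 1.0, default_sequence, default_trace)
        f2 = self._fit("roiA", 3.0, default_sequence, default_trace)
        panel = extract_roi_panel({"s0": [f1, f2]})
        assert panel.loc["s0", "roiA"] == pytest.approx(2.0, abs=1e-9)

    def test_missing_roi_raises(self, default_sequence, default_trace):
        fits = {"s0": [self._fit("roiA", 1.0, default_sequence, default_trace)],
                "s1": [self._fit("roiB", 1.0, default_sequence, default_trace)]}
        with pytest.raises(ValueError, match="missing ROI"):
            extract_roi_panel(fits, roi_names=["roiA", "roiB"])
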