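"""Linear-in-parameters calibration: regressors, OLS, decoded fits."""

import numpy as np
import pytest

import emgnms as E
from emgnms.data import Design
from emgnms.emg import activation
from emgnms.gravity import ArmAnthropometry, gravity_components
from emgnms.linear import RegressorMatrix, build_regressors, calibrate_linear, fit_linear
from emgnms.muscle import JointModel, MuscleTendonUnit


def _design(u, theta1, theta2, tau_sh, tau_el, channels=("BB", "TB", "AD", "PD")):
    n = u.shape[0]
    return Design(
        u=u, theta1=theta1, theta2=theta2,
        tau_m_sh=tau_sh, tau_m_el=tau_el,
        trial_index=np.zeros(n, dtype=int), trial_ids=("t0",),
        channel_names=channels, fs_effective=25.0,
    )


def _simple_elbow():
    bb = MuscleTendonUnit(name="BB", F_O=600, l_o=0.10, phi_o=0.0, A=-0.2,
                          sigma_A=0.45, coeff_l=(0.10, 0, 0, 0), coeff_r=(0.03, 0, 0, 0))
    tb = MuscleTendonUnit(name="TB", F_O=800, l_o=0.13, phi_o=0.2, A=-0.2,
                          sigma_A=0.45, coeff_l=(0.13, 0, 0, 0), coeff_r=(-0.02, 0, 0, 0))
    return JointModel(joint="elbow", muscles=(bb, tb))


@pytest.fixture
def anthro():
    return ArmAnthropometry(M_a=2.0, M_fh=1.6, L_1=0.31, l_1=0.155, l_2=0.24)


class TestBuildRegressors:
    def test_zero_excitation_gives_zero_muscle_columns(self, anthro):
        n = 40
        d = _design(np.zeros((n, 4)), np.full(n, 0.5), np.full(n, 0.8),
                    np.zeros(n), np.zeros(n))
        reg = build_regressors(_simple_elbow(), anthro, d)
        assert np.all(reg.A_cols == 0.0)

    def test_unit_force_regressor_by_hand(self, anthro):
        # a = 1, l~ = 1 (f_l = 1), phi = 0, r = 0.03 -> A_BB = 0.03
        n = 5
        u = np.zeros((n, 4))
        u[:, 0] = 1.0
        d = _design(u, np.full(n, 0.5), np.full(n, 0.8), np.zeros(n), np.zeros(n))
        reg = build_regressors(_simple_elbow(), anthro, d)
        assert np.allclose(reg.A_cols[:, 0], 0.03, rtol=1e-12)

    def test_regressors_invariant_to_default_forces(self, anthro):
        rng = np.random.default_rng(0)
        n = 30
        d = _design(rng.uniform(0, 1, (n, 4)), np.full(n, 0.5), np.full(n, 0.8),
                    rng.normal(size=n), rng.normal(size=n))
        model = _simple_elbow()
        reg1 = build_regressors(model, anthro, d)
        reg2 = build_regressors(model.with_forces([1.0, 1.0]), anthro, d)
        assert np.allclose(reg1.A_cols, reg2.A_cols, rtol=1e-14)

    def test_missing_channel_raises(self, anthro):
        n = 10
        d = _design(np.zeros((n, 2)), np.full(n, 0.5), np.full(n, 0.8),
                    np.zeros(n), np.zeros(n), channels=("AD", "PD"))
        with pytest.raises(ValueError, match="missing"):
            build_regressors(_simple_elbow(), anthro, d)


def _synthetic_regression(anthro, joint="elbow", n=200, seed=4, noise_sd=0.0):
    """Forward-simulate the linear model with known coefficients."""
    rng = np.random.default_rng(seed)
    models, _ = E.default_models()
    model = models[joint]
    u = rng.uniform(0, 0.8, (n, 4))
    theta1 = rng.uniform(0.2, 1.2, n)
    theta2 = rng.uniform(0.3, 1.6, n)
    zeros = np.zeros(n)
    d = _design(u, theta1, theta2, zeros, zeros)
    reg0 = build_regressors(model, anthro, d)
    p = reg0.matrix.shape[1]
    coef_true = np.concatenate([
        rng.uniform(300, 2000, len(reg0.muscle_names)),
        rng.uniform(0.7, 1.3, len(reg0.gravity_names)),
    ])
    target = reg0.matrix @ coef_true + rng.normal(0, noise_sd, n)
    tau_sh = target if joint == "shoulder" else zeros
    tau_el = target if joint == "elbow" else zeros
    d = _design(u, theta1, theta2, tau_sh, tau_el)
    return model, build_regressors(model, anthro, d), coef_true


class TestFitLinear:
    def test_exact_recovery_without_noise(self, anthro):
        for joint in ("elbow", "shoulder"):
            _, reg, coef_true = _synthetic_regression(anthro, joint)
            fit = fit_linear(reg)
            got = np.concatenate([fit.F_O_hat, fit.f_sc_hat])
            assert np.allclose(got, coef_true, rtol=1e-8)
            assert fit.residual_rms < 1e-10

    def test_zero_target_gives_null_fit(self, anthro):
        model, reg, _ = _synthetic_regression(anthro)
        reg = RegressorMatrix(
            A_cols=reg.A_cols, G_cols=reg.G_cols, target=np.zeros_like(reg.target),
            muscle_names=reg.muscle_names, gravity_names=reg.gravity_names,
            joint=reg.joint, trial_ids=reg.trial_ids,
        )
        fit = fit_linear(reg)
        assert np.allclose(fit.F_O_hat, 0.0, atol=1e-10)
        assert np.allclose(fit.f_sc_hat, 0.0, atol=1e-10)

    def test_ols_unbiased_under_additive_noise(self, anthro):
        """Coefficient averages over seeded Monte-Carlo replicates approach
        the truth, and residual RMS approaches the noise level."""
        sd = 0.5
        coefs, rms = [], []
        for rep in range(100):
            _, reg, coef_true = _synthetic_regression(anthro, seed=1000 + rep,
                                                      noise_sd=sd)
            fit = fit_linear(reg)
            coefs.append(np.concatenate([fit.F_O_hat, fit.f_sc_hat]) - coef_true)
            rms.append(fit.residual_rms)
        bias = np.mean(coefs, axis=0)
        spread = np.std(coefs, axis=0)
        assert np.all(np.abs(bias) < 0.5 * spread + 1e-9)
        assert np.mean(rms) == pytest.approx(sd, rel=0.05)

    def test_underdetermined_system_rejected(self, anthro):
        n = 2
        d = _design(np.zeros((n, 4)), np.full(n, 0.5), np.full(n, 0.8),
                    np.zeros(n), np.zeros(n))
        reg = build_regressors(_simple_elbow(), anthro, d)
        with pytest.raises(ValueError, match="samples"):
            fit_linear(reg)

    def test_collinear_columns_named(self, anthro):
        rng = np.random.default_rng(5)
        n = 50
        u = rng.uniform(0, 1, (n, 4))
        u[:, 1] = u[:, 0]  # identical excitations
        model = _simple_elbow()
        # make TB geometry identical to BB: exactly collinear columns
        tb = MuscleTendonUnit(name="TB", F_O=800, l_o=0.10, phi_o=0.0, A=-0.2,
                              sigma_A=0.45, coeff_l=(0.10, 0, 0, 0),
                              coeff_r=(0.03, 0, 0, 0))
        model = JointModel(joint="elbow", muscles=(model.muscles[0], tb))
        d = _design(u, np.full(n, 0.5), np.full(n, 0.8), np.zeros(n),
                    rng.normal(size=n))
        reg = build_regressors(model, anthro, d)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(reg)

    def test_negative_force_flagged(self, anthro):
        model, reg, coef_true = _synthetic_regression(anthro)
        target = reg.matrix @ np.array([-500.0, 800.0, 1.0])
        reg = RegressorMatrix(
            A_cols=reg.A_cols, G_cols=reg.G_cols, target=target,
            muscle_names=reg.muscle_names, gravity_names=reg.gravity_names,
            joint=reg.joint, trial_ids=reg.trial_ids,
        )
        with pytest.warns(UserWarning, match="negative"):
            fit_linear(reg)


class TestCalibrateOnProtocol:
    def test_decoded_fit_reproduces_ols_predictions(self, defaults,
                                                    noiseless_linear_case):
        """The calibrated joint model evaluated through the full torque
        path equals the OLS fitted values exactly: the muscle-model and
        linear-reformulation routes agree."""
        models, anthro0 = defaults
        train = noiseless_linear_case["train"]
        for joint in ("elbow", "shoulder"):
            reg = build_regressors(models[joint], anthro0, train)
            fit = fit_linear(reg)
            coef = np.concatenate([fit.F_O_hat, fit.f_sc_hat])
            ols_pred = reg.matrix @ coef
            cal = calibrate_linear(train, models[joint], anthro0)
            model_pred = E.predict_external_torque(cal.model, cal.anthro, train)
            assert np.allclose(model_pred, ols_pred, atol=1e-10)

    def test_train_error_never_worse_than_default_model(self, defaults,
                                                        noiseless_linear_case):
        models, anthro0 = defaults
        train = noiseless_linear_case["train"]
        for joint in ("elbow", "shoulder"):
            cal = calibrate_linear(train, models[joint], anthro0)
            fitted = E.evaluate_model(cal.model, cal.anthro, train)["e_rms"]
            raw = E.evaluate_model(models[joint], anthro0, train)["e_rms"]
            assert fitted <= raw + 1e-12

    def test_elbow_system_is_shoulder_system_restricted(self, defaults,
                                                        noiseless_linear_case):
        """Solving the elbow normal equations equals solving the 6-column
        shoulder-style stack restricted to the BB/TB columns and elbow
        gravity on elbow torque data."""
        models, anthro0 = defaults
        train = noiseless_linear_case["train"]
        reg = build_regressors(models["elbow"], anthro0, train)
        fit = fit_linear(reg)
        # manual restricted solve
        comp = gravity_components(anthro0, train.theta1, train.theta2)
        cols = []
        for mtu in models["elbow"].muscles:
            a = activation(train.u[:, train.channel_index(mtu.name)], mtu.A)
            cols.append(mtu.unit_force_torque(a, train.theta2))
        X = np.column_stack(cols + [-comp["elbow_fh"]])
        coef, *_ = np.linalg.lstsq(X, train.tau_m_el, rcond=None)
        assert np.allclose(np.concatenate([fit.F_O_hat, fit.f_sc_hat]), coef,
                           rtol=1e-10)
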