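import numpy as np
import pytest

from lvmech.materials import (ActiveParams, KinematicsError, PassiveParams,
                              active_fiber_stress, eca50, kinematics,
                              passive_energy, passive_stress, total_stress)

F0 = np.array([1.0, 0.0, 0.0])
S0 = np.array([0.0, 1.0, 0.0])


def _random_states(n, scale=0.15, seed=0):
    rng = np.random.default_rng(seed)
    Fs = np.eye(3) + scale * rng.standard_normal((n, 3, 3))
    keep = np.linalg.det(Fs) > 0.2
    return Fs[keep]


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def test_kinematics_identity():
    st = kinematics(np.eye(3), F0, S0)
    assert np.isclose(st.I1, 3.0)
    assert np.isclose(st.I4f, 1.0)
    assert np.isclose(st.I4s, 1.0)
    assert np.isclose(st.I8fs, 0.0)
    assert np.isclose(st.Eff, 0.0)


def test_kinematics_isochoric_uniaxial():
    lam = 1.1
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    st = kinematics(F, F0, S0)
    assert np.isclose(st.J, 1.0)
    assert np.isclose(st.I4f, lam ** 2)                 # 1.21
    assert np.isclose(st.I1, lam ** 2 + 2.0 / lam)      # 1.21 + 2/1.1


def test_kinematics_rotation_invariance():
    rng = np.random.default_rng(3)
    F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
    assert np.linalg.det(F) > 0
    Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    a, b = kinematics(F, F0, S0), kinematics(Q @ F, F0, S0)
    for n in ("I1", "I4f", "I4s", "I8fs", "Eff"):
        assert np.isclose(getattr(a, n), getattr(b, n), atol=1e-12)


def test_kinematics_rejects_inverted():
    with pytest.raises(KinematicsError):
        kinematics(-np.eye(3), F0, S0)


# --------------------------------------------------------------------------
# passive energy and stress
# --------------------------------------------------------------------------

def test_energy_zero_at_identity():
    st = kinematics(np.eye(3), F0, S0)
    assert abs(passive_energy(st, PassiveParams())) < 1e-14


def test_fiber_term_quadratic_limit():
    """With the fiber exponent null, the I4f term is (af/2)(I4f-1)^2."""
    lam = 1.1
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    st = kinematics(F, F0, S0)
    full = passive_energy(st, PassiveParams())
    iso = passive_energy(st, PassiveParams(af=0.0))
    # the tension-only switch is C1-smoothed over 1e-4 in I4, which shifts
    # the quadratic-limit energy by ~5e-5 absolute in the strain measure
    assert np.isclose(full - iso, 0.5 * 2.501 * (lam ** 2 - 1.0) ** 2,
                      rtol=1e-3)


def test_energy_monotone_in_i1():
    p = PassiveParams()
    st = kinematics(np.eye(3), F0, S0)
    vals = []
    for i1 in np.linspace(3.0, 4.0, 41):
        st.I1 = i1
        vals.append(float(passive_energy(st, p)))
    assert np.all(np.diff(vals) > 0)


def test_stress_free_reference():
    sig = passive_stress(np.eye(3), F0, S0, PassiveParams())
    assert np.abs(sig).max() < 1e-12


def test_stress_matches_energy_derivative():
    """Analytic Cauchy stress vs central differences of the energy via the
    first Piola transform, 100 random states, relative error < 1e-5."""
    p = PassiveParams(bf=1.5, a_s=1.0, b_s=0.8, afs=0.5, bfs=0.6)
    h = 1e-6
    for F in _random_states(120, seed=11)[:100]:
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                wp = passive_energy(kinematics(Fp, F0, S0), p)
                wm = passive_energy(kinematics(Fm, F0, S0), p)
                P[i, j] = (wp - wm) / (2 * h)
        J = np.linalg.det(F)
        sig_fd = P @ F.T / J
        sig = passive_stress(F, F0, S0, p)
        ref = max(np.abs(sig).max(), 1e-6)
        assert np.abs(sig - sig_fd).max() / ref < 1e-5


def test_isotropic_simple_shear_closed_form():
    """With af = 0 the law is one-term exponential isotropic; under simple
    shear sigma = a e^{b gamma^2} (B - I1/3 I)."""
    gamma = 0.1
    F = np.eye(3)
    F[0, 1] = gamma
    p = PassiveParams(af=0.0)
    sig = passive_stress(F, F0, S0, p)
    B = F @ F.T
    I1 = 3.0 + gamma ** 2
    expected = p.a * np.exp(p.b * gamma ** 2) * (B - I1 / 3.0 * np.eye(3))
    assert np.allclose(sig, expected, atol=1e-10)


def test_objectivity():
    """total_stress(QF) = Q total_stress(F) Q^T to 1e-9 kPa."""
    rng = np.random.default_rng(5)
    p, ap = PassiveParams(), ActiveParams()
    for _ in range(10):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        if not 0.7 < np.linalg.det(F) < 1.4:    # physiologic stress range
            continue
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        s1 = total_stress(Q @ F, F0, S0, 1.85, 0.2, p, ap)
        s2 = total_stress(F, F0, S0, 1.85, 0.2, p, ap)
        assert np.abs(s1 - Q @ s2 @ Q.T).max() < 1e-9


# --------------------------------------------------------------------------
# active law
# --------------------------------------------------------------------------

def test_eca50_printed_value():
    ap = ActiveParams()
    expected = 4.35 / np.sqrt(np.exp(4.750 * (1.85 - 1.58)) - 1.0)
    assert np.isclose(eca50(1.85, ap), expected, rtol=1e-12)


def test_eca50_monotone_decreasing():
    ap = ActiveParams()
    ls = np.linspace(1.70, 2.0, 50)
    vals = eca50(ls, ap)
    assert np.all(np.diff(vals) < 0)
    assert eca50(1.9, ap) < eca50(1.8, ap)


def test_eca50_clamp_kills_activation():
    """As l -> l0 the calcium factor Ca0^2/(Ca0^2+ECa50^2) tends to zero."""
    ap = ActiveParams()
    ec = eca50(ap.l0, ap)         # clamped, finite, huge
    gain = ap.ca0 ** 2 / (ap.ca0 ** 2 + ec ** 2)
    assert gain < 0.05


def test_twitch_zero_at_start_and_after_relaxation():
    ap = ActiveParams()
    assert active_fiber_stress(0.0, 0.0, 1.85, ap) == 0.0
    l = 1.85
    tr = ap.m * l + ap.b_tr
    assert active_fiber_stress(ap.t0 + tr + 1e-6, 0.0, l, ap) == 0.0


def test_twitch_peak_value():
    ap = ActiveParams()
    ec = eca50(1.85, ap)
    expected = ap.tmax * ap.ca0 ** 2 / (ap.ca0 ** 2 + ec ** 2)
    assert np.isclose(active_fiber_stress(ap.t0, 0.0, 1.85, ap), expected,
                      rtol=1e-12)


def test_twitch_continuity_at_phase_boundaries():
    ap = ActiveParams()
    l = 1.85
    tr = ap.m * l + ap.b_tr
    for t_star in (ap.t0, ap.t0 + tr):
        lo = active_fiber_stress(t_star - 1e-9, 0.0, l, ap)
        hi = active_fiber_stress(t_star + 1e-9, 0.0, l, ap)
        assert abs(hi - lo) < 1e-5


def test_twitch_increases_with_sarcomere_reference():
    ap = ActiveParams()
    lrs = np.linspace(1.78, 1.91, 14)
    vals = active_fiber_stress(ap.t0, 0.0, lrs, ap)
    assert np.all(np.diff(vals) > 0)


def test_twitch_rejects_nonphysical_fiber_state():
    with pytest.raises(KinematicsError):
        active_fiber_stress(0.1, -0.6, 1.85, ActiveParams())


def test_twitch_nonnegative():
    ap = ActiveParams()
    ts = np.linspace(0, ap.period, 200)
    vals = [active_fiber_stress(t, 0.02, 1.85, ap) for t in ts]
    assert min(vals) >= 0.0


# --------------------------------------------------------------------------
# combined stress
# --------------------------------------------------------------------------

def test_total_equals_passive_at_rest():
    rng = np.random.default_rng(8)
    F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    p, ap = PassiveParams(), ActiveParams()
    s_tot = total_stress(F, F0, S0, 1.85, 0.0, p, ap)
    s_pas = passive_stress(F, F0, S0, p)
    assert np.allclose(s_tot, s_pas, atol=1e-12)


def test_total_identity_at_peak_is_rank_one_active():
    p, ap = PassiveParams(), ActiveParams()
    sig = total_stress(np.eye(3), F0, S0, 1.85, ap.t0, p, ap)
    saf = active_fiber_stress(ap.t0, 0.0, 1.85, ap)
    expected = saf * np.outer(F0, F0)
    assert np.allclose(sig, expected, atol=1e-10)


def test_total_stress_symmetric():
    rng = np.random.default_rng(9)
    p, ap = PassiveParams(), ActiveParams()
    for _ in range(5):
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.2:
            continue
        sig = total_stress(F, F0, S0, 1.85, 0.18, p, ap)
        assert np.allclose(sig, sig.T, atol=1e-12)
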