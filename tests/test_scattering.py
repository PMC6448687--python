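"""Forward model: structure factor, form factors, powder average."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import argrelmax

from hexsaxs.composition import LatticeConfig, build_wedge, filler_sld, lamellar_slabs
from hexsaxs.scattering import (
    ForwardModel,
    ModelParams,
    PARAM_NAMES,
    QuadratureSettings,
    ShellProfile,
    _cross_section_cylinder,
    _interstice_integral,
    cylinder_form_factor,
    hex_structure_factor,
    interstice_form_factor,
    lamellar_form_factor,
    smear_form_factor,
)

A = 76.9
L = 2500.0
Q10 = 4 * math.pi / (math.sqrt(3) * A)


@pytest.fixture(scope="module")
def shells(dope):
    w = build_wedge(-0.0400, 2.16, 2.40, 1150.0, A, dope)
    return ShellProfile.from_wedge(w, A)


@pytest.fixture(scope="module")
def truth_params(dope_truth):
    return dope_truth[0]


# ---------------------------------------------------------------------------
# structure factor
# ---------------------------------------------------------------------------


def test_structure_factor_forward_limit():
    """S(q=0) = N_hex: all pair terms coherent."""
    lat = LatticeConfig(a=A, n=3, Delta=20.0)
    assert hex_structure_factor(0.0, math.pi / 2, lat) == pytest.approx(lat.n_hex)


def test_structure_factor_debye_waller_kills_interference():
    lat = LatticeConfig(a=A, n=3, Delta=1e6)
    s = hex_structure_factor(0.2, math.pi / 2, lat)
    assert s == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("n,rel_tol", [(1, 0.01), (6, 0.001)])
def test_structure_factor_peak_at_q10(n, rel_tol):
    """S(q) peaks at 4 pi / (sqrt(3) a); the 7-cell patch is finite-size
    broadened (peak shifted ~0.7% low), converging onto q10 as n grows."""
    lat = LatticeConfig(a=A, n=n, Delta=0.0)
    q = np.linspace(0.06, 0.12, 4001)
    s = hex_structure_factor(q, math.pi / 2, lat)
    q_peak = q[np.argmax(s)]
    assert q_peak == pytest.approx(Q10, rel=rel_tol)


def test_structure_factor_positive(truth_params):
    lat = LatticeConfig(a=A, n=8, Delta=12.0)
    q = np.linspace(0.03, 0.8, 400)
    s = hex_structure_factor(q, math.pi / 2, lat)
    assert np.all(s > 0)


# ---------------------------------------------------------------------------
# cylinder form factor
# ---------------------------------------------------------------------------


def test_cylinder_forward_scattering_is_excess_electrons(shells):
    """q -> 0: F -> L * pi * sum drho_k (r_k^2 - r_{k-1}^2)."""
    r = np.concatenate([[0.0], shells.radii])
    expected = L * math.pi * np.sum(
        np.asarray(shells.contrasts) * (r[1:] ** 2 - r[:-1] ** 2)
    )
    f = cylinder_form_factor(1e-12, math.pi / 2, shells, L)
    assert f == pytest.approx(expected, rel=1e-9)


def test_cylinder_zero_contrast_vanishes():
    sh = ShellProfile(radii=(10.0, 20.0), contrasts=(0.0, 0.0))
    q = np.linspace(0.01, 0.5, 50)
    assert np.allclose(cylinder_form_factor(q, math.pi / 2, sh, L), 0.0)


def test_cylinder_contrast_linearity(shells):
    q = np.linspace(0.02, 0.6, 100)
    f1 = cylinder_form_factor(q, math.pi / 2, shells, L)
    doubled = ShellProfile(
        radii=shells.radii, contrasts=tuple(2 * c for c in shells.contrasts)
    )
    f2 = cylinder_form_factor(q, math.pi / 2, doubled, L)
    assert np.allclose(f2, 2 * f1, rtol=1e-13)


def test_cylinder_cross_section_vs_2d_quadrature(shells):
    """Analytic core-shell amplitude vs brute-force 2D transform, <= 1e-6."""

    def brute(qs):
        total = 0.0
        r = np.concatenate([[0.0], shells.radii])
        # int rho(r) exp(i q.r) dA = sum_k drho_k int_r int_phi cos(q r cos phi)
        for k, c in enumerate(shells.contrasts):
            if c == 0.0:
                continue
            val, _ = quad(
                lambda rr: rr * quad(
                    lambda phi: math.cos(qs * rr * math.cos(phi)), 0, 2 * math.pi,
                    limit=200,
                )[0],
                r[k], r[k + 1], limit=200,
            )
            total += c * val
        return total

    for qs in (0.05, 0.15, 0.31):
        analytic = _cross_section_cylinder(
            np.array([qs]), shells.radii, shells.contrasts
        )[0]
        assert analytic == pytest.approx(brute(qs), rel=1e-6)


# ---------------------------------------------------------------------------
# boundary smearing
# ---------------------------------------------------------------------------


def test_smearing_identity_at_zero_width(shells):
    q = np.linspace(0.02, 0.6, 200)
    f0 = cylinder_form_factor(q, math.pi / 2, shells, L)
    fs = smear_form_factor(q, math.pi / 2, shells, L)
    assert np.array_equal(f0, fs)


def test_smearing_damps_high_q_envelope(shells):
    """The |F|^2 envelope maxima decrease monotonically with sigma_fluc."""
    q = np.linspace(0.2, 0.7, 2000)
    prev = None
    for sig in (0.0, 2.0, 4.0):
        sh = ShellProfile(shells.radii, shells.contrasts, sigma_fluc=sig)
        f2 = smear_form_factor(q, math.pi / 2, sh, L) ** 2
        peaks = f2[argrelmax(f2)[0]]
        height = peaks.max()
        if prev is not None:
            assert height < prev
        prev = height


def test_smearing_quadrature_refinement(shells):
    """15-node Gauss-Hermite vs 101-node dense rule: <= 1e-4 relative."""
    q = np.linspace(0.02, 0.7, 300)
    sh = ShellProfile(shells.radii, shells.contrasts, sigma_fluc=3.0)
    f15 = smear_form_factor(q, math.pi / 2, sh, L, order=15)
    f101 = smear_form_factor(q, math.pi / 2, sh, L, order=101)
    scale = np.max(np.abs(f101))
    assert np.max(np.abs(f15 - f101)) / scale < 1e-4


def test_smearing_clips_nodes_reaching_negative_radii(caplog):
    sh = ShellProfile(radii=(2.0, 30.0), contrasts=(0.1, -0.05), sigma_fluc=1.5)
    import logging

    with caplog.at_level(logging.WARNING, logger="hexsaxs.scattering"):
        smear_form_factor(np.array([0.1]), math.pi / 2, sh, L, order=15)
    assert any("clipped" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# interstice form factor
# ---------------------------------------------------------------------------


def test_interstice_forward_scattering_is_excess_volume():
    """q -> 0: F = drho * L * (2 sqrt(3) - pi) (a/2)^2 (hexagon minus disc)."""
    drho = -0.054
    expected = drho * L * (2 * math.sqrt(3) - math.pi) * (A / 2) ** 2
    f = interstice_form_factor(1e-12, math.pi / 2, A, drho, L)
    assert f == pytest.approx(expected, rel=1e-8)


def test_interstice_zero_contrast():
    q = np.linspace(0.01, 0.5, 20)
    assert np.allclose(interstice_form_factor(q, math.pi / 2, A, 0.0, L), 0.0)


def test_interstice_grid_refinement():
    """Doubling the 1/12-sector resolution changes the result <= 1e-4."""
    qs = np.linspace(0.0, 0.8, 300)
    g1 = _interstice_integral(qs, A, (24, 24))
    g2 = _interstice_integral(qs, A, (48, 48))
    assert np.max(np.abs(g1 - g2)) / np.max(np.abs(g2)) < 1e-4


# ---------------------------------------------------------------------------
# lamellar form factor
# ---------------------------------------------------------------------------


def test_lamellar_forward_scattering(dope):
    slabs = lamellar_slabs(65.0, 8.0, 1150.0, dope)
    expected = 2 * (slabs.drho_HC * slabs.d_C + slabs.drho_H * slabs.d_H_lam)
    assert lamellar_form_factor(1e-14, slabs) == pytest.approx(expected, rel=1e-10)


def test_lamellar_merged_slabs_reduce_to_uniform(dope):
    from hexsaxs.composition import LamellarSlabs

    c = 0.07
    slabs = LamellarSlabs(d_C=12.0, d_H_lam=6.0, drho_H=c, drho_HC=c)
    q = np.linspace(0.01, 0.6, 200)
    expected = 2 * c * np.sin(q * 18.0) / q
    assert np.allclose(lamellar_form_factor(q, slabs), expected, rtol=1e-12)


def test_lamellar_closed_form_vs_quadrature(dope):
    """Closed form equals the cosine transform of the slab profile, <= 1e-10."""
    slabs = lamellar_slabs(65.0, 8.0, 1150.0, dope)

    def profile(z):
        if abs(z) < slabs.d_C:
            return slabs.drho_HC
        if abs(z) < slabs.d_C + slabs.d_H_lam:
            return slabs.drho_H
        return 0.0

    for qv in (0.05, 0.21, 0.4):
        num, _ = quad(
            lambda z: 2 * profile(z) * math.cos(qv * z),
            0, slabs.d_C + slabs.d_H_lam, limit=400, epsabs=1e-14,
        )
        assert lamellar_form_factor(qv, slabs) == pytest.approx(num, abs=1e-10)


# ---------------------------------------------------------------------------
# powder intensity
# ---------------------------------------------------------------------------


def test_bragg_peaks_at_hexagonal_ratios(truth_params, dope):
    """Pure H_II pattern: the three dominant maxima at ratios 1 : sqrt3 : 2."""
    p = truth_params.replace(c_lam=0.0, Delta=5.0)
    q = np.linspace(0.03, 0.8, 600)
    i_mod = ForwardModel(q, A, dope).powder_intensity(p)
    idx = argrelmax(i_mod)[0]
    top = idx[np.argsort(i_mod[idx])[::-1][:3]]
    q_top = np.sort(q[top])
    dq = q[1] - q[0]
    for q_found, mult in zip(q_top, (1.0, math.sqrt(3), 2.0)):
        assert q_found == pytest.approx(Q10 * mult, abs=1.5 * dq)


def test_pure_lamellar_pattern_has_no_bragg_peaks(truth_params, dope):
    p = truth_params.replace(c_lam=1.0)
    q = np.linspace(0.03, 0.8, 600)
    fm = ForwardModel(q, A, dope)
    i_lam = fm.powder_intensity(p)
    # no local maximum anywhere near the strong hexagonal reflections
    idx = argrelmax(i_lam)[0]
    for mult in (1.0, math.sqrt(3), 2.0):
        assert np.all(np.abs(q[idx] - Q10 * mult) > 5 * (q[1] - q[0]))


def test_lamellar_term_fills_form_factor_minimum(truth_params, dope):
    """Diffuse bilayer scattering removes the deep minimum between 10 and 11."""
    q = np.linspace(0.03, 0.8, 600)
    fm = ForwardModel(q, A, dope)
    window = (q > Q10 * 1.05) & (q < Q10 * math.sqrt(3) * 0.95)
    i_hex = fm.powder_intensity(truth_params.replace(c_lam=0.0))
    i_mix = fm.powder_intensity(truth_params)
    depth_hex = i_hex[window].min() / i_hex.max()
    depth_mix = i_mix[window].min() / i_mix.max()
    assert depth_mix > 5 * depth_hex


def test_debye_waller_reduces_peak_to_background(truth_params, dope):
    """Increasing Delta monotonically lowers the 20-reflection contrast."""
    q = np.linspace(0.03, 0.8, 600)
    fm = ForwardModel(q, A, dope)
    q20 = 2 * Q10
    on = np.argmin(np.abs(q - q20))
    off = np.argmin(np.abs(q - q20 * 1.12))
    ratios = []
    for delta in (5.0, 15.0, 30.0):
        i_mod = fm.powder_intensity(truth_params.replace(c_lam=0.0, Delta=delta))
        ratios.append(i_mod[on] / i_mod[off])
    assert ratios[0] > ratios[1] > ratios[2]


def test_quadrature_refinement_converges(truth_params, dope):
    """Doubling the q_s resolution changes the curve < 0.1% (L2)."""
    q = np.linspace(0.03, 0.8, 600)
    i1 = ForwardModel(q, A, dope).powder_intensity(truth_params)
    i2 = ForwardModel(
        q, A, dope, QuadratureSettings(qs_oversample=4, low_qs_points=96)
    ).powder_intensity(truth_params)
    assert np.linalg.norm(i2 - i1) / np.linalg.norm(i1) < 1e-3


def test_length_insensitivity(truth_params, dope):
    """Doubling the prism length changes the curve < 1% (L2) at these radii."""
    q = np.linspace(0.05, 0.5, 400)
    i1 = ForwardModel(q, A, dope, L=2500.0).powder_intensity(truth_params)
    i2 = ForwardModel(q, A, dope, L=5000.0).powder_intensity(truth_params)
    assert np.linalg.norm(i2 - i1) / np.linalg.norm(i1) < 0.01


def test_long_rod_mode_agrees_at_peaks(truth_params, dope):
    """The decoupled 1/q cross-check matches near Bragg maxima (~1%)."""
    q = np.linspace(0.03, 0.8, 600)
    i1 = ForwardModel(q, A, dope).powder_intensity(truth_params)
    i2 = ForwardModel(
        q, A, dope, QuadratureSettings(method="long_rod")
    ).powder_intensity(truth_params)
    for mult in (1.0, math.sqrt(3), 2.0):
        i_pk = np.argmin(np.abs(q - Q10 * mult))
        assert i2[i_pk] == pytest.approx(i1[i_pk], rel=0.02)


def test_total_intensity_scaling(truth_params, dope):
    q = np.linspace(0.05, 0.5, 100)
    fm = ForwardModel(q, A, dope)
    p0 = truth_params.replace(Gamma=1.0, I_inc=0.0)
    base = fm.total_intensity(p0)
    assert np.allclose(
        fm.total_intensity(p0.replace(Gamma=2.0)), 2 * base, rtol=1e-13
    )
    assert np.allclose(
        fm.total_intensity(p0.replace(Gamma=1e-12, I_inc=3.3)), 3.3, atol=1e-6
    )


def test_lattice_polydispersity_hook_damps_peaks(truth_params, dope):
    """Optional Gaussian average over the lattice parameter (off by default)
    smooths the Bragg peaks without changing the diffuse level much."""
    from hexsaxs.composition import LatticeConfig
    from hexsaxs.scattering import powder_intensity

    lat = LatticeConfig(a=A, n=truth_params.n, Delta=truth_params.Delta)
    q = np.linspace(0.05, 0.5, 200)
    i0 = powder_intensity(q, truth_params, lat, dope)
    i1 = powder_intensity(q, truth_params, lat, dope, sigma_a=0.5)
    pk = np.argmin(np.abs(q - Q10))
    assert i1[pk] < i0[pk]  # peak height reduced by the spread
    assert np.median(np.abs(i1 - i0) / i0) < 0.05


def test_model_params_roundtrip():
    assert len(PARAM_NAMES) == 12
    p = ModelParams(
        Delta=12.0, n=8, sigma_fluc=2.5, C0=-0.04, d_H=2.2, d_BB=2.4,
        V_lipid=1150.0, c_lam=0.15, A_L=65.0, n_W_lam=8.0, Gamma=5e-4,
        I_inc=0.1,
    )
    assert ModelParams.from_array(p.as_array()) == p
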