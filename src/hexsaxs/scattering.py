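"""Forward scattering model for unoriented inverted hexagonal phases.

The measured 1D powder intensity is modeled as a bundle of long hexagonal
prisms (water core + lipid shells + filler-rich interstices) on a 2D
hexagonal lattice, plus a diffuse contribution from a coexisting planar
bilayer that fills the form-factor minimum between the 10 and 11
reflections:

    I_mod(q) = (1 - c_lam) * I_hex(q) + c_lam * I_lam(q)
    I(q)     = Gamma * I_mod(q) + I_inc

with

    I_hex(q) = integral_0^{pi/2} S(q, theta) |F_CS + F_int|^2 sin(theta) dtheta

where ``S`` is the hexagonal-lattice structure factor with Debye-Waller
damping, ``F_CS`` the analytic core-shell cylinder amplitude (with Gaussian
smearing of the shell boundaries), ``F_int`` the numerically integrated
amplitude of the hexagon-minus-disc interstitial region, and ``I_lam`` a
flat-sheet powder average ``|F_lam|^2 / q^2`` of a two-slab bilayer.

Orientational average
---------------------
The prisms are long (L = 2500 A), so the axial factor
``[2 sin(q L cos(theta) / 2) / (q cos(theta))]^2`` concentrates the
orientational integral sharply at theta = pi/2 while oscillating on the
scale 2 pi / L.  With ``u = q cos(theta)`` and the in-plane component
``q_s = q sin(theta)``, the integral splits into an exact part

    K(q, L) = integral_0^q 4 sin^2(uL/2)/u^2 du
            = 2 [L Si(qL) - (1 - cos qL)/q]

multiplying the integrand at u = 0 (theta = pi/2), plus the remainder

    2 integral_0^q [g(q_s) - g(q)] q_s (q^2 - q_s^2)^{-3/2} dq_s

where ``g = S |F_cross|^2`` carries the sharp Bragg oscillations of the
lattice sum.  The remainder is evaluated by product integration: ``g`` is
interpolated piecewise-linearly (in the variable ``phi = q^2 - q_s^2``,
which absorbs the integrable end-point singularity) on a dense shared
q_s grid, and the singular kernel is integrated analytically against each
hat function, yielding a precomputed weight matrix applied per parameter
set.  The rapidly oscillating residual coupling is O(1/(q L)) relative to
the remainder and is dropped.  A decoupled long-rod mode
(I ~ pi L S |F|^2 / q) is available as a cross-check.

The hexagonal and lamellar terms are each normalized per lipid (prism
intensity divided by the 2 pi L / A_u lipids of a unit cell, bilayer
intensity multiplied by A_L/2), so that ``c_lam`` is interpretable as a
lipid fraction; the absolute scale is absorbed by ``Gamma``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy.spatial.distance import pdist
from scipy.special import j0, j1, sici

from .composition import (
    LamellarSlabs,
    LatticeConfig,
    LipidSpec,
    WedgeStructure,
    build_wedge,
    filler_sld,
    lamellar_slabs,
)

__all__ = [
    "ModelParams",
    "PARAM_NAMES",
    "ShellProfile",
    "QuadratureSettings",
    "ForwardModel",
    "hex_structure_factor",
    "cylinder_form_factor",
    "smear_form_factor",
    "interstice_form_factor",
    "lamellar_form_factor",
    "powder_intensity",
    "total_intensity",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

#: The twelve adjustable model parameters, in canonical order.
PARAM_NAMES = (
    "Delta",
    "n",
    "sigma_fluc",
    "C0",
    "d_H",
    "d_BB",
    "V_lipid",
    "c_lam",
    "A_L",
    "n_W_lam",
    "Gamma",
    "I_inc",
)


@dataclass(frozen=True)
class ModelParams:
    """The 12 adjustable parameters of the global H_II model.

    Structure factor: ``Delta`` (lateral mean-square displacement, A^2) and
    ``n`` (hexagonal rings / domain size).  H_II form factor: ``sigma_fluc``
    (boundary smearing width, A), ``C0`` (intrinsic curvature, 1/A),
    ``d_H``/``d_BB`` (headgroup/backbone widths, A), ``V_lipid`` (A^3).
    Lamellar term: ``c_lam`` (lamellar fraction), ``A_L`` (area per lipid,
    A^2), ``n_W_lam`` (head-slab waters).  Signal scaling: ``Gamma``
    (instrumental constant) and ``I_inc`` (incoherent background).
    """

    Delta: float
    n: int
    sigma_fluc: float
    C0: float
    d_H: float
    d_BB: float
    V_lipid: float
    c_lam: float
    A_L: float
    n_W_lam: float
    Gamma: float
    I_inc: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "ModelParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got {x.shape}")
        kwargs = dict(zip(PARAM_NAMES, x))
        kwargs["n"] = int(round(kwargs["n"]))
        return cls(**kwargs)

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


assert len(fields(ModelParams)) == len(PARAM_NAMES)


@dataclass(frozen=True)
class ShellProfile:
    """Radial electron-density contrast profile of the prism cross-section.

    ``radii`` are the M shell boundaries (ascending, the implicit innermost
    boundary is r = 0, the last entry is a/2); ``contrasts[k]`` is the SLD
    relative to water of the shell ending at ``radii[k]``.  ``sigma_fluc``
    is the Gaussian width of the rigid boundary-displacement smearing.
    """

    radii: tuple[float, ...]
    contrasts: tuple[float, ...]
    sigma_fluc: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if r.size == 0 or np.any(np.diff(np.concatenate([[0.0], r])) <= 0):
            raise ValueError("shell radii must be strictly increasing and > 0")
        if len(self.contrasts) != len(self.radii):
            raise ValueError("need one contrast per shell")
        if self.sigma_fluc < 0:
            raise ValueError("sigma_fluc must be non-negative")

    @classmethod
    def from_wedge(cls, w: WedgeStructure, a: float, sigma_fluc: float = 0.0):
        return cls(
            radii=(w.R_W, w.r_H_out, w.r_BB_out, a / 2.0),
            contrasts=(0.0, w.sld["H"], w.sld["BB"], w.sld["HC"]),
            sigma_fluc=sigma_fluc,
        )


@dataclass(frozen=True)
class QuadratureSettings:
    """Numerical settings of the forward model.

    ``qs_oversample``: subdivision factor of the data q grid used for the
    orientational remainder integral (the convergence knob — doubling it
    refines the quadrature); ``low_qs_points``: extra grid points covering
    (0, q_min); ``n_smear``: Gauss-Hermite nodes of the boundary smearing;
    ``interstice_nodes``: (n_phi, n_r) Gauss-Legendre nodes of the 1/12
    hexagon-sector integral; ``method``: ``"product"`` (default) or
    ``"long_rod"`` (decoupled 1/q powder factor, cross-check mode).
    """

    qs_oversample: int = 2
    low_qs_points: int = 48
    n_smear: int = 15
    interstice_nodes: tuple[int, int] = (24, 24)
    method: str = "product"

    def __post_init__(self) -> None:
        if self.method not in ("product", "long_rod"):
            raise ValueError(f"unknown quadrature method {self.method!r}")
        if self.qs_oversample < 1 or self.low_qs_points < 8:
            raise ValueError("qs_oversample >= 1 and low_qs_points >= 8 required")


# ---------------------------------------------------------------------------
# structure factor
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _hex_pair_distances(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unique pair distances (units of a) and multiplicities of an n-ring patch."""
    pts = [
        (i + 0.5 * j, 0.5 * math.sqrt(3.0) * j)
        for i in range(-n, n + 1)
        for j in range(-n, n + 1)
        if max(abs(i), abs(j), abs(i + j)) <= n
    ]
    xy = np.array(pts)
    assert len(pts) == 1 + 3 * n * (n + 1)
    if len(pts) == 1:
        return np.empty(0), np.empty(0)
    d = np.round(pdist(xy), 9)
    dist, counts = np.unique(d, return_counts=True)
    return dist, 2.0 * counts  # pdist counts each unordered pair once


def _pair_sum(qs: np.ndarray, n: int, a: float) -> np.ndarray:
    """sum_{j != k} J0(qs |R_j - R_k|) on the n-ring hexagonal patch."""
    dist, counts = _hex_pair_distances(n)
    if dist.size == 0:
        return np.zeros_like(qs)
    qs = np.asarray(qs, dtype=float)
    return j0(np.multiply.outer(qs, dist * a)) @ counts


def hex_structure_factor(q, theta, lattice: LatticeConfig) -> np.ndarray:
    """Powder structure factor of the hexagonal prism bundle.

    ``S(q, theta) = 1 + exp(-q^2 Delta)/N_hex * sum_{j!=k} J0(q sin(theta)
    |R_j - R_k|)`` over all lattice-point pairs of the n-ring patch,
    averaged over in-plane orientations (hence the Bessel J0).  The
    ``exp(-q^2 Delta)`` Debye-Waller factor damps lattice interference by
    positional disorder.  Broadcasts over ``q`` and ``theta``.
    """
    q = np.asarray(q, dtype=float)
    theta = np.asarray(theta, dtype=float)
    qs = q * np.sin(theta)
    dw = np.exp(-(q**2) * lattice.Delta)
    return 1.0 + dw / lattice.n_hex * _pair_sum(qs, lattice.n, lattice.a)


# ---------------------------------------------------------------------------
# form factors
# ---------------------------------------------------------------------------


def _j1_over_x(x: np.ndarray) -> np.ndarray:
    """J1(x)/x, finite at x = 0 (-> 1/2)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-5
    xs = np.where(small, 1.0, x)
    out = np.where(small, 0.5 - x**2 / 16.0, j1(xs) / xs)
    return out


def _axial_factor(q, theta, L: float) -> np.ndarray:
    """2 sin(q L cos(theta)/2) / (q cos(theta)); -> L at theta = pi/2."""
    u = np.asarray(q, dtype=float) * np.cos(theta)
    return L * np.sinc(u * L / (2.0 * math.pi))


def _cross_section_cylinder(qs, radii, contrasts) -> np.ndarray:
    """In-plane (azimuthally averaged) core-shell amplitude.

    ``(2 pi / qs) sum_k drho_k [r_k J1(qs r_k) - r_{k-1} J1(qs r_{k-1})]``
    with the analytic qs -> 0 limit ``pi sum_k drho_k (r_k^2 - r_{k-1}^2)``.
    """
    qs = np.asarray(qs, dtype=float)
    r = np.concatenate([[0.0], np.asarray(radii, dtype=float)])
    rho = np.asarray(contrasts, dtype=float)
    # r_k J1(qs r_k)/qs = r_k^2 * (J1/x)(qs r_k)
    terms = r**2 * _j1_over_x(np.multiply.outer(qs, r))
    return 2.0 * math.pi * (terms[..., 1:] - terms[..., :-1]) @ rho


def cylinder_form_factor(q, theta, shells: ShellProfile, L: float) -> np.ndarray:
    """Analytic amplitude of the core-shell cylindrical part of the prism.

    Product of the axial factor and the azimuthally averaged radial
    transform.  Real-valued (centrosymmetric profile); ignores the shell
    smearing of ``shells.sigma_fluc`` (see :func:`smear_form_factor`).
    """
    q = np.asarray(q, dtype=float)
    qs = q * np.sin(theta)
    return _axial_factor(q, theta, L) * _cross_section_cylinder(
        qs, shells.radii, shells.contrasts
    )


def _smear_nodes(sigma: float, order: int) -> tuple[np.ndarray, np.ndarray]:
    t, w = hermgauss(order)
    return math.sqrt(2.0) * sigma * t, w / math.sqrt(math.pi)


def _cross_section_smeared(
    qs, shells: ShellProfile, order: int
) -> np.ndarray:
    """Boundary-smeared in-plane amplitude (Gauss-Hermite average)."""
    if shells.sigma_fluc == 0.0:
        return _cross_section_cylinder(qs, shells.radii, shells.contrasts)
    shifts, weights = _smear_nodes(shells.sigma_fluc, order)
    r = np.asarray(shells.radii, dtype=float)
    keep = r[0] + shifts > 0
    if not np.all(keep):
        log.warning(
            "smearing: clipped %d quadrature node(s) shifting innermost "
            "radius below zero",
            int(np.sum(~keep)),
        )
        shifts, weights = shifts[keep], weights[keep] / np.sum(weights[keep])
    qs = np.asarray(qs, dtype=float)
    rho = np.asarray(shells.contrasts, dtype=float)
    # shifted boundary sets: (S, M+1), innermost boundary 0 fixed
    rmat = np.concatenate(
        [np.zeros((len(shifts), 1)), r[None, :] + shifts[:, None]], axis=1
    )
    terms = rmat**2 * _j1_over_x(qs[..., None, None] * rmat)
    per_shift = 2.0 * math.pi * (terms[..., 1:] - terms[..., :-1]) @ rho
    return per_shift @ weights


def smear_form_factor(
    q, theta, shells: ShellProfile, L: float, *, order: int = 15
) -> np.ndarray:
    """Cylinder amplitude averaged over rigid Gaussian boundary shifts.

    Molecular fluctuations smear the sharp shell boundaries; all radii are
    translated by a common shift x ~ N(0, sigma_fluc^2) and the amplitude
    is averaged by Gauss-Hermite quadrature (``order`` nodes).  With
    ``sigma_fluc = 0`` this is exactly :func:`cylinder_form_factor`.
    Extreme nodes that would push the innermost radius below zero are
    clipped (with a log message) and the weights renormalized.
    """
    q = np.asarray(q, dtype=float)
    qs = q * np.sin(theta)
    return _axial_factor(q, theta, L) * _cross_section_smeared(qs, shells, order)


@lru_cache(maxsize=8)
def _sector_nodes(n_phi: int, n_r: int):
    tp, wp = leggauss(n_phi)
    tr, wr = leggauss(n_r)
    return tp, wp, tr, wr


def _interstice_integral(qs, a: float, nodes: tuple[int, int]) -> np.ndarray:
    """Azimuthally averaged transform of the hexagon-minus-disc region.

    ``G(qs) = 12 int_0^{pi/6} int_{a/2}^{a/(2 cos phi)} J0(qs r) r dr dphi``
    exploiting the 12-fold symmetry of the interstitial corners;
    ``G(0)`` equals the interstitial area ``(2 sqrt(3) - pi)(a/2)^2``.
    """
    n_phi, n_r = nodes
    tp, wp, tr, wr = _sector_nodes(n_phi, n_r)
    phi = (tp + 1.0) * (math.pi / 12.0)  # [0, pi/6]
    wphi = wp * (math.pi / 12.0)
    r_lo = a / 2.0
    r_hi = a / (2.0 * np.cos(phi))
    # r-nodes per phi: (n_phi, n_r)
    half = (r_hi - r_lo) / 2.0
    rmat = r_lo + np.multiply.outer(half, tr + 1.0)
    wmat = np.multiply.outer(half * wphi, wr) * rmat
    qs = np.asarray(qs, dtype=float)
    vals = j0(np.multiply.outer(qs, rmat))  # (..., n_phi, n_r)
    return 12.0 * np.einsum("...pr,pr->...", vals, wmat)


def interstice_form_factor(
    q,
    theta,
    a: float,
    drho_TC: float,
    L: float,
    *,
    nodes: tuple[int, int] = (24, 24),
) -> np.ndarray:
    """Amplitude of the filler-rich interstitial region of the unit cell.

    The region between the hexagon of apothem a/2 and the inscribed disc,
    with uniform contrast ``drho_TC``; evaluated numerically over 1/12 of
    the hexagon, multiplied by the same axial factor as the cylinder.
    """
    q = np.asarray(q, dtype=float)
    qs = q * np.sin(theta)
    return (
        _axial_factor(q, theta, L) * drho_TC * _interstice_integral(qs, a, nodes)
    )


def lamellar_form_factor(q, slabs: LamellarSlabs) -> np.ndarray:
    """Amplitude of a symmetric two-slab (head/tail) planar bilayer.

    ``F(q) = 2 [drho_HC sin(q d_C)/q +
              drho_H (sin(q (d_C + d_H)) - sin(q d_C))/q]``
    with the analytic q -> 0 limit ``2 (drho_HC d_C + drho_H d_H)``.
    """
    q = np.asarray(q, dtype=float)
    b = slabs.d_C + slabs.d_H_lam
    sin_dc = slabs.d_C * np.sinc(q * slabs.d_C / math.pi)
    sin_b = b * np.sinc(q * b / math.pi)
    return 2.0 * (slabs.drho_HC * sin_dc + slabs.drho_H * (sin_b - sin_dc))


# ---------------------------------------------------------------------------
# powder-averaged intensity
# ---------------------------------------------------------------------------


def _axial_kernel_integral(q: np.ndarray, L: float) -> np.ndarray:
    """K(q, L) = int_0^q 4 sin^2(uL/2)/u^2 du = 2 [L Si(qL) - (1 - cos qL)/q]."""
    si, _ = sici(q * L)
    return 2.0 * (L * si - (1.0 - np.cos(q * L)) / q)


def _correction_weights(s: np.ndarray, q_idx: np.ndarray) -> np.ndarray:
    """Product-integration weights of the singular orientational remainder.

    For each data point ``q_i = s[m_i]`` the remainder integral

        C_i = int_0^{q_i} [g(q_s) - g(q_i)] q_s (q_i^2 - q_s^2)^{-3/2} dq_s

    is computed from the values of ``g`` on the shared grid ``s`` by
    interpolating ``h = g - g(q_i)`` piecewise-linearly in
    ``phi = q_i^2 - q_s^2`` and integrating ``phi^{-3/2}`` analytically on
    each panel; the end-point singularity is integrable because ``h``
    vanishes linearly in ``phi``.  Returns ``W`` with
    ``C = W @ g - (W @ 1) * g0``.
    """
    W = np.zeros((len(q_idx), s.size))
    for row, m in enumerate(q_idx):
        qi = s[m]
        phi = qi * qi - s[: m + 1] ** 2  # phi[m] = 0
        pj, pj1 = phi[:-2], phi[1:-1]  # regular panels j = 0 .. m-2
        d = pj - pj1
        c1 = 1.0 / np.sqrt(pj1) - 1.0 / np.sqrt(pj)
        c2 = np.sqrt(pj) - np.sqrt(pj1)
        W[row, : m - 1] += c1 * (-pj1 / d) + c2 / d
        W[row, 1:m] += c1 * (pj / d) - c2 / d
        # last panel: h interpolated through (phi[m-1], h[m-1]) and (0, 0)
        W[row, m - 1] += 1.0 / math.sqrt(phi[m - 1])
    return W


class ForwardModel:
    """Cached evaluator of the model intensity on a fixed q grid.

    Precomputes everything that does not change between parameter sets of
    one data set (lattice parameter ``a``, filler contrast, interstice
    transform, orientational quadrature nodes, per-``n`` lattice pair
    sums), so that repeated evaluation inside an MCMC chain costs only the
    shell form factor and a few elementwise operations.
    """

    def __init__(
        self,
        q: np.ndarray,
        a: float,
        lipid: LipidSpec,
        settings: QuadratureSettings | None = None,
        *,
        L: float = 2500.0,
        strict: bool = True,
    ):
        self.q = np.asarray(q, dtype=float)
        if self.q.ndim != 1 or np.any(self.q <= 0):
            raise ValueError("q grid must be 1D with q > 0 (powder factors diverge)")
        self.a = float(a)
        self.lipid = lipid
        self.settings = settings or QuadratureSettings()
        self.L = float(L)
        self.strict = strict
        self.drho_tc = filler_sld(lipid)

        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        # shared q_s grid: 0, a low-q extension, the data grid and
        # oversampling midpoints between data points
        ov = self.settings.qs_oversample
        low = np.linspace(0.0, self.q[0], self.settings.low_qs_points,
                          endpoint=False)
        mids = [
            self.q[:-1] + (k / ov) * np.diff(self.q) for k in range(1, ov)
        ]
        grid = np.unique(np.concatenate([low, self.q, *mids]))
        self._s = grid
        self._q_idx = np.searchsorted(grid, self.q)
        assert np.allclose(grid[self._q_idx], self.q)
        self._W = _correction_weights(grid, self._q_idx)
        self._Wsum = self._W.sum(axis=1)
        self._K = _axial_kernel_integral(self.q, self.L)
        self._interstice_s = _interstice_integral(
            grid, self.a, self.settings.interstice_nodes
        )
        self._pair_sums: dict[int, np.ndarray] = {}

    def _pair_sum_for(self, n: int) -> np.ndarray:
        if n not in self._pair_sums:
            self._pair_sums[n] = _pair_sum(self._s, n, self.a)
        return self._pair_sums[n]

    # -- pieces ------------------------------------------------------------

    def wedge(self, p: ModelParams) -> WedgeStructure:
        return build_wedge(
            p.C0, p.d_H, p.d_BB, p.V_lipid, self.a, self.lipid,
            check_hydration=self.strict,
        )

    def hex_intensity(self, p: ModelParams) -> np.ndarray:
        """Orientationally averaged H_II intensity per lipid."""
        n_hex = 1 + 3 * p.n * (p.n + 1)
        dw = np.exp(-(self.q**2) * p.Delta)
        w = self.wedge(p)
        shells = ShellProfile.from_wedge(w, self.a, p.sigma_fluc)
        # in-plane amplitude and g = S * amp^2 on the shared q_s grid
        amp = (
            _cross_section_smeared(self._s, shells, self.settings.n_smear)
            + self.drho_tc * self._interstice_s
        )
        a2 = amp**2  # structure-factor-free part of g
        b = a2 * self._pair_sum_for(p.n) / n_hex  # lattice-sum part
        a2_q, b_q = a2[self._q_idx], b[self._q_idx]
        g0 = a2_q + dw * b_q  # g at theta = pi/2
        if self.settings.method == "long_rod":
            i_hex = math.pi * self.L / self.q * g0
        else:
            corr = (
                self._W @ a2
                - self._Wsum * a2_q
                + dw * (self._W @ b - self._Wsum * b_q)
            )
            i_hex = (g0 * self._K + 2.0 * corr) / self.q
        return i_hex * w.A_u / (2.0 * math.pi * self.L)

    def lamellar_intensity(self, p: ModelParams) -> np.ndarray:
        """Flat-sheet powder intensity of the bilayer term, per lipid."""
        slabs = lamellar_slabs(p.A_L, p.n_W_lam, p.V_lipid, self.lipid)
        f = lamellar_form_factor(self.q, slabs)
        return (p.A_L / 2.0) * f**2 / self.q**2

    def powder_intensity(self, p: ModelParams) -> np.ndarray:
        """I_mod(q): lamellar-fraction-weighted sum of both contributions."""
        i = (1.0 - p.c_lam) * self.hex_intensity(p)
        if p.c_lam > 0.0:
            i = i + p.c_lam * self.lamellar_intensity(p)
        return i

    def total_intensity(self, p: ModelParams) -> np.ndarray:
        """Gamma * I_mod(q) + I_inc."""
        return p.Gamma * self.powder_intensity(p) + p.I_inc


def powder_intensity(
    q,
    params: ModelParams,
    lattice: LatticeConfig,
    lipid: LipidSpec,
    settings: QuadratureSettings | None = None,
    *,
    sigma_a: float = 0.0,
    n_a_nodes: int = 7,
) -> np.ndarray:
    """Model intensity I_mod(q) for one parameter set.

    Convenience wrapper constructing a :class:`ForwardModel`; for repeated
    evaluation (fitting) build the model once and reuse it.  The lattice
    supplies ``a`` and ``L``; the fitted ``Delta`` and ``n`` are taken from
    ``params``.  ``sigma_a`` optionally averages over a Gaussian
    distribution of lattice parameters (off by default; it affects only
    low q).
    """
    if sigma_a > 0.0:
        t, w = hermgauss(n_a_nodes)
        a_nodes = lattice.a + math.sqrt(2.0) * sigma_a * t
        out = 0.0
        for a_i, w_i in zip(a_nodes, w / math.sqrt(math.pi)):
            # hydration constraints are a prior statement at the nominal
            # lattice; off-nominal nodes of the average relax them
            fm = ForwardModel(q, a_i, lipid, settings, L=lattice.L,
                              strict=False)
            out = out + w_i * fm.powder_intensity(params)
        return out
    fm = ForwardModel(q, lattice.a, lipid, settings, L=lattice.L)
    return fm.powder_intensity(params)


def total_intensity(
    q,
    params: ModelParams,
    lattice: LatticeConfig,
    lipid: LipidSpec,
    settings: QuadratureSettings | None = None,
    **kw,
) -> np.ndarray:
    """Measured-scale intensity ``Gamma * I_mod(q) + I_inc``."""
    return params.Gamma * powder_intensity(
        q, params, lattice, lipid, settings, **kw
    ) + params.I_inc
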