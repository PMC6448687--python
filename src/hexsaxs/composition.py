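"""Composition-specific structural modeling of inverted hexagonal (H_II) phases.

An H_II phase is a 2D hexagonal lattice of water cylinders coated by lipid
monolayers (headgroups facing the water core) with a hydrophobic filler
(here cis-9-tricosene) occupying the interstitial corners of each hexagonal
unit cell.  This module translates a molecular description of the lipid
(quasi-molecular fragments: headgroup H, glycerol backbone BB, hydrocarbon
chains HC, each with a formula and a volume) into the wedge geometry of a
single lipid unit cell and the electron densities of its shells.

The wedge is parametrized by the intrinsic monolayer curvature
``C0 = -1/R0`` (R0 = neutral-plane radius, assumed at the center of the
backbone shell), the headgroup width ``d_H``, the backbone width ``d_BB``
and the lipid molecular volume ``V_lipid``.  The hydrocarbon shell extends
from the backbone to the inscribed-circle radius ``a/2`` of the hexagon and
is assumed water-free, which closes the system of equations: the mantle
area per unit radius ``A_u`` follows from the HC volume, shell water
contents from the shell volumes, and electron densities from electron
counts over shell volumes.  All densities are expressed relative to water
(0.33 e/A^3 for X-rays).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ATOMIC_NUMBERS",
    "V_WATER",
    "RHO_WATER",
    "ConstraintError",
    "LipidSpec",
    "LatticeConfig",
    "WedgeStructure",
    "LamellarSlabs",
    "parse_formula",
    "electron_count",
    "hexagon_cell_count",
    "hexagonal_miller_sequence",
    "lattice_from_peaks",
    "build_wedge",
    "derived_structure",
    "filler_sld",
    "lamellar_slabs",
    "load_lipid",
    "available_lipids",
]

#: Atomic numbers of the elements occurring in phospholipids and alkenes.
ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15}

#: Molecular volume of water, A^3.
V_WATER = 30.0
#: Electron density of water, e/A^3 (X-rays).
RHO_WATER = 0.33
#: Electrons per water molecule.
_WATER_ELECTRONS = 10


class ConstraintError(ValueError):
    """A molecular/geometric constraint is violated.

    Raised when a parameter combination does not describe a physical wedge
    (unordered radii, non-positive water core, or a shell too small to
    accommodate its molecular fragment).  During Bayesian sampling this maps
    to zero prior probability.
    """


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse a molecular formula like ``'C23H46'`` into an element->count map.

    Accepts an already-parsed mapping unchanged (after validation).
    """
    if isinstance(formula, Mapping):
        counts = {str(k): int(v) for k, v in formula.items()}
    else:
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at {pos}")
            if not m.group(0):
                break
            pos = m.end()
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    for el, cnt in counts.items():
        if el not in ATOMIC_NUMBERS:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        if cnt < 0:
            raise ValueError(f"negative count for element {el!r}")
    return counts


def electron_count(formula: str | Mapping[str, int]) -> int:
    """Number of electrons of a (neutral) molecular fragment.

    >>> electron_count("C23H46")
    184
    """
    counts = parse_formula(formula)
    return sum(ATOMIC_NUMBERS[el] * cnt for el, cnt in counts.items())


def hexagon_cell_count(n: int) -> int:
    """Total number of unit cells in a hexagonal patch of ``n`` rings.

    ``N_hex = 1 + 3 n (n + 1)``; a single cell for ``n = 0``.
    """
    if n < 0 or int(n) != n:
        raise ValueError(f"ring count must be a non-negative integer, got {n!r}")
    n = int(n)
    return 1 + 3 * n * (n + 1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LipidSpec:
    """Molecular description of a phosphatidylethanolamine and its filler.

    Fragment formulas follow the standard quasi-molecular parsing:
    H = phosphate + ethanolamine, BB = glycerol + carbonyls, HC = all
    methyl/methine/methylene groups of the acyl chains.  ``filler_groups``
    gives the CH/CH2/CH3 decomposition of the filler molecule and
    ``filler_group_volumes`` the corresponding group volumes (A^3) used for
    the volume-averaged filler electron density.
    """

    name: str
    fragment_formulas: Mapping[str, str]
    V_H: float = 110.0
    V_BB: float = 135.0
    filler_formula: str = "C23H46"
    filler_groups: Mapping[str, int] = field(
        default_factory=lambda: {"CH3": 2, "CH2": 19, "CH": 2}
    )
    filler_group_volumes: Mapping[str, float] = field(
        default_factory=lambda: {"CH3": 53.6, "CH2": 27.1, "CH": 22.0}
    )

    def __post_init__(self) -> None:
        for key in ("H", "BB", "HC"):
            if key not in self.fragment_formulas:
                raise ValueError(f"lipid {self.name!r} misses fragment {key!r}")
        if self.V_H <= 0 or self.V_BB <= 0:
            raise ValueError("fragment volumes must be positive")

    def electrons(self, fragment: str) -> int:
        return electron_count(self.fragment_formulas[fragment])

    def v_hc(self, v_lipid: float) -> float:
        """Hydrocarbon volume ``V_HC = V_lipid - V_H - V_BB``."""
        v = v_lipid - self.V_H - self.V_BB
        if v <= 0:
            raise ConstraintError(
                f"V_lipid={v_lipid} leaves no hydrocarbon volume "
                f"(V_H={self.V_H}, V_BB={self.V_BB})"
            )
        return v


@dataclass(frozen=True)
class LatticeConfig:
    """Hexagonal lattice of the H_II bundle.

    Parameters
    ----------
    a : lattice parameter (A), known from Bragg peak positions.
    n : number of hexagonal rings; the bundle holds ``1 + 3n(n+1)`` cells.
    Delta : lateral mean-square displacement of the cell axes (A^2),
        entering the Debye-Waller factor ``exp(-q^2 Delta)``.
    L : prism length (A).  Scattering is insensitive to L above ~2500 A
        for the radii occurring here, so it is fixed rather than fitted.
    """

    a: float
    n: int = 8
    Delta: float = 10.0
    L: float = 2500.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("lattice parameter a must be positive")
        if self.Delta < 0:
            raise ValueError("Delta must be non-negative")
        if self.L <= 0:
            raise ValueError("prism length L must be positive")
        hexagon_cell_count(self.n)  # validates n

    @property
    def n_hex(self) -> int:
        return hexagon_cell_count(self.n)


@dataclass(frozen=True)
class WedgeStructure:
    """Geometry and electron densities of the lipid wedge unit cell.

    Radii are measured from the cylinder axis; the shells are
    water core [0, R_W], headgroup [R_W, r_H_out], backbone
    [r_H_out, r_BB_out] and hydrocarbon [r_BB_out, a/2].  ``A_u`` is the
    mantle area of a sector of unitary radius (the product of wedge opening
    angle and height), so the area per lipid at radius r is ``A_u * r``.
    ``sld`` maps shell name to electron density relative to water (e/A^3);
    ``n_W`` maps shell name to water molecules per lipid in that shell.
    """

    R_W: float
    r_H_out: float
    r_BB_out: float
    R_0: float
    A_u: float
    A_0: float
    n_W: Mapping[str, float]
    sld: Mapping[str, float]
    shell_volumes: Mapping[str, float]
    V_HC: float

    @property
    def radii(self) -> tuple[float, float, float]:
        return (self.R_W, self.r_H_out, self.r_BB_out)


@dataclass(frozen=True)
class LamellarSlabs:
    """Symmetric head/tail slab model of the coexisting planar bilayer."""

    d_C: float
    d_H_lam: float
    drho_H: float
    drho_HC: float

    def __post_init__(self) -> None:
        if self.d_C <= 0 or self.d_H_lam <= 0:
            raise ValueError("slab thicknesses must be positive")


# ---------------------------------------------------------------------------
# lattice determination from Bragg peaks
# ---------------------------------------------------------------------------


def hexagonal_miller_sequence(count: int) -> list[tuple[int, int]]:
    """First ``count`` hexagonal Miller pairs (k, l) ordered by peak position.

    Ordered by sqrt(k^2 + k l + l^2): (1,0), (1,1), (2,0), (2,1), (3,0), ...
    """
    pairs = [(k, l) for k in range(1, 16) for l in range(0, k + 1)]
    pairs.sort(key=lambda kl: (kl[0] ** 2 + kl[0] * kl[1] + kl[1] ** 2, kl))
    # drop duplicated moduli? distinct (k,l) kept: each is a distinct reflection
    return pairs[:count]


def _miller_modulus(k: int, l: int) -> float:
    m2 = k * k + k * l + l * l
    if m2 <= 0:
        raise ValueError(f"invalid hexagonal Miller pair ({k}, {l})")
    return math.sqrt(m2)


def lattice_from_peaks(
    peak_positions: Sequence[float],
    indices: Sequence[tuple[int, int]] | None = None,
) -> float:
    """Least-squares lattice parameter from hexagonal Bragg peak positions.

    Peak positions obey ``q_kl = (4 pi / (sqrt(3) a)) * sqrt(k^2 + kl + l^2)``.
    If ``indices`` is omitted, peaks (sorted ascending) are matched to the
    ordered reflection sequence (1,0), (1,1), (2,0), (2,1), (3,0), ...

    Returns the lattice parameter ``a`` in A.
    """
    q = np.asarray(peak_positions, dtype=float)
    if q.size == 0:
        raise ValueError("need at least one peak position")
    if np.any(q <= 0):
        raise ValueError("peak positions must be positive")
    if indices is None:
        q = np.sort(q)
        indices = hexagonal_miller_sequence(q.size)
    if len(indices) != q.size:
        raise ValueError("number of indices must match number of peaks")
    m = np.array([_miller_modulus(k, l) for k, l in indices])
    # q_i = c * m_i with c = 4 pi / (sqrt(3) a); least squares in c
    c = float(np.dot(m, q) / np.dot(m, m))
    return 4 * math.pi / (math.sqrt(3) * c)


# ---------------------------------------------------------------------------
# wedge construction
# ---------------------------------------------------------------------------


def build_wedge(
    C0: float,
    d_H: float,
    d_BB: float,
    V_lipid: float,
    a: float,
    lipid: LipidSpec,
    *,
    V_W: float = V_WATER,
    rho_W: float = RHO_WATER,
    check_hydration: bool = True,
) -> WedgeStructure:
    """Construct the wedge unit cell from the four molecular parameters.

    The neutral plane sits at the center of the backbone shell:
    ``R_0 = -1/C0``, ``r_H_out = R_0 - d_BB/2``, ``R_W = r_H_out - d_H``,
    ``r_BB_out = R_0 + d_BB/2``.  The hydrocarbon shell spans
    ``[r_BB_out, a/2]`` and is water-free, which fixes the sector mantle
    area per unit radius ``A_u = 2 V_HC / ((a/2)^2 - r_BB_out^2)``.  Shell
    water contents follow from ``n_W,k = (V_shell,k - V_k) / V_W`` and must
    be non-negative (the shell must accommodate its molecular group);
    electron densities are volume-weighted fragment + water densities,
    quoted relative to water.

    Raises :class:`ConstraintError` for unphysical geometries; with
    ``check_hydration=False`` negative water counts are tolerated (useful
    for probing the constraint boundary).
    """
    if C0 >= 0:
        raise ConstraintError(f"intrinsic curvature must be negative, got {C0}")
    if d_H <= 0 or d_BB <= 0:
        raise ConstraintError("shell widths d_H, d_BB must be positive")
    R_0 = -1.0 / C0
    r_H_out = R_0 - d_BB / 2.0
    r_BB_out = R_0 + d_BB / 2.0
    R_W = r_H_out - d_H
    half_a = a / 2.0
    if not (0.0 < R_W < r_H_out < r_BB_out < half_a):
        raise ConstraintError(
            f"unordered radii: R_W={R_W:.3f}, r_H={r_H_out:.3f}, "
            f"r_BB={r_BB_out:.3f}, a/2={half_a:.3f}"
        )
    V_HC = lipid.v_hc(V_lipid)
    A_u = 2.0 * V_HC / (half_a**2 - r_BB_out**2)
    vol = {
        "H": 0.5 * A_u * (r_H_out**2 - R_W**2),
        "BB": 0.5 * A_u * (r_BB_out**2 - r_H_out**2),
        "HC": 0.5 * A_u * (half_a**2 - r_BB_out**2),
    }
    frag_vol = {"H": lipid.V_H, "BB": lipid.V_BB, "HC": V_HC}
    n_W = {k: (vol[k] - frag_vol[k]) / V_W for k in vol}
    n_W["HC"] = 0.0  # water-free by construction (closes the system)
    if check_hydration and (n_W["H"] < 0 or n_W["BB"] < 0):
        raise ConstraintError(
            f"shell too small for molecular group: n_W,H={n_W['H']:.3f}, "
            f"n_W,BB={n_W['BB']:.3f}"
        )
    sld = {
        k: (lipid.electrons(k) + n_W[k] * _WATER_ELECTRONS) / vol[k] - rho_W
        for k in vol
    }
    return WedgeStructure(
        R_W=R_W,
        r_H_out=r_H_out,
        r_BB_out=r_BB_out,
        R_0=R_0,
        A_u=A_u,
        A_0=A_u * R_0,
        n_W=n_W,
        sld=sld,
        shell_volumes=vol,
        V_HC=V_HC,
    )


def derived_structure(w: WedgeStructure, a: float) -> dict[str, float]:
    """Derived structural parameters of a wedge.

    Returns hydrocarbon width ``d_HC = a/2 - r_BB_out``, head-to-headgroup
    length ``d_HH = a - 2 R_W``, water-core radius ``R_W``, neutral-plane
    area per lipid ``A_0`` and the molecular shape parameter
    ``s = V_HC / (A_0 * d_HC)`` (s = 1 for cylindrical, s > 1 for
    inverted-cone, H_II-forming molecules).
    """
    d_HC = a / 2.0 - w.r_BB_out
    d_HH = a - 2.0 * w.R_W
    return {
        "d_HC": d_HC,
        "d_HH": d_HH,
        "R_W": w.R_W,
        "R_0": w.R_0,
        "A_0": w.A_0,
        "V_HC": w.V_HC,
        "s": w.V_HC / (w.A_0 * d_HC),
        "C0": -1.0 / w.R_0,
    }


def filler_sld(lipid: LipidSpec, *, rho_W: float = RHO_WATER) -> float:
    """Electron density of the interstitial filler, relative to water.

    Computed by molecular averaging over the fractional group volumes:
    ``rho = n_e(filler) / sum(count_g * V_g)`` minus the water density.
    The group decomposition must be consistent with the molecular formula.
    """
    counts = parse_formula(lipid.filler_formula)
    n_e = electron_count(counts)
    total_v = 0.0
    group_atoms = {"C": 0, "H": 0}
    for group, cnt in lipid.filler_groups.items():
        if group not in lipid.filler_group_volumes:
            raise ValueError(f"missing volume for filler group {group!r}")
        total_v += cnt * lipid.filler_group_volumes[group]
        g = parse_formula(group)
        for el, n in g.items():
            group_atoms[el] = group_atoms.get(el, 0) + n * cnt
    if group_atoms != {el: counts.get(el, 0) for el in group_atoms} or set(
        counts
    ) != set(group_atoms):
        raise ValueError(
            f"filler group decomposition {dict(lipid.filler_groups)} does not "
            f"match formula {lipid.filler_formula!r}"
        )
    return n_e / total_v - rho_W


def lamellar_slabs(
    A_L: float,
    n_W_lam: float,
    V_lipid: float,
    lipid: LipidSpec,
    *,
    V_W: float = V_WATER,
    rho_W: float = RHO_WATER,
) -> LamellarSlabs:
    """Head/tail slab model of the coexisting planar bilayer.

    The hydrocarbon half-thickness is ``d_C = V_HC / A_L`` and the head
    slab thickness ``d_H_lam = (V_H + V_BB + n_W_lam V_W) / A_L``, with
    slab electron densities from electron counts over slab volumes,
    relative to water.  ``A_L`` is the area per lipid of the lamellar
    phase and ``n_W_lam`` the water molecules associated with the head
    slab — the only two structural parameters of the lamellar term.
    """
    if A_L <= 0:
        raise ValueError("area per lipid A_L must be positive")
    if n_W_lam < 0:
        raise ValueError("n_W_lam must be non-negative")
    V_HC = lipid.v_hc(V_lipid)
    V_head = lipid.V_H + lipid.V_BB + n_W_lam * V_W
    n_e_head = lipid.electrons("H") + lipid.electrons("BB") + n_W_lam * _WATER_ELECTRONS
    return LamellarSlabs(
        d_C=V_HC / A_L,
        d_H_lam=V_head / A_L,
        drho_H=n_e_head / V_head - rho_W,
        drho_HC=lipid.electrons("HC") / V_HC - rho_W,
    )


# ---------------------------------------------------------------------------
# lipid registry
# ---------------------------------------------------------------------------


def _registry() -> dict:
    with resources.files("hexsaxs.data").joinpath("lipids.yaml").open() as fh:
        return yaml.safe_load(fh)


def available_lipids() -> list[str]:
    """Names of the lipids shipped with the package."""
    return sorted(_registry()["lipids"])


def load_lipid(name: str, **overrides) -> LipidSpec:
    """Load a shipped lipid definition (DOPE, POPE, DMPE, diC16:1PE).

    Keyword overrides replace individual :class:`LipidSpec` fields.
    """
    reg = _registry()
    try:
        entry = dict(reg["lipids"][name])
    except KeyError:
        raise KeyError(
            f"unknown lipid {name!r}; available: {sorted(reg['lipids'])}"
        ) from None
    filler = reg["filler"]
    kwargs = dict(
        name=name,
        fragment_formulas=entry["fragments"],
        V_H=float(entry.get("V_H", 110.0)),
        V_BB=float(entry.get("V_BB", 135.0)),
        filler_formula=filler["formula"],
        filler_groups=filler["groups"],
        filler_group_volumes=filler["group_volumes"],
    )
    kwargs.update(overrides)
    return LipidSpec(**kwargs)
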