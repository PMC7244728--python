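"""Zernike and LD/HD polynomial bases on the pupil disk.

The ocular wavefront error W is expanded over the unit pupil disk in
ANSI/OSA-normalized Zernike modes Z_n^m.  The LD/HD ("low degree / high
degree") basis re-partitions the same polynomial space so that every
high-order mode (radial order n >= 3) contains *no* monomial of total degree
<= 2: its value, gradient and curvature at the pupil center all vanish.  The
low-order LD/HD modes coincide with the Zernike modes of order n <= 2, so the
low-order LD/HD coefficients alone carry the paraxial sphero-cylinder of the
wavefront.

All polynomials here are represented exactly by monomial coefficient tables
over (x, y) on the unit disk; inner products use the closed-form disk
integral of x^a y^b, so the change-of-basis matrix carries no quadrature
error.  Physical pupil coordinates are x_mm = r * x with r the pupil radius
in mm; a wavefront in um over a pupil of radius r mm yields curvature in
um/mm^2, read directly as diopters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ModeIndex",
    "WavefrontCoefficients",
    "BasisTransform",
    "modes_up_to",
    "zernike_mode_eval",
    "build_ldhd_transform",
    "zernike_to_ldhd",
    "ldhd_to_zernike",
    "wavefront_eval",
    "paraxial_curvature_refraction",
]

ZERNIKE = "zernike"
LDHD = "ldhd"


@dataclass(frozen=True, order=True)
class ModeIndex:
    """Double-index (n, m): radial order and meridional frequency."""

    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 0 or abs(self.m) > self.n or (self.n - abs(self.m)) % 2:
            raise IndexError(f"invalid Zernike mode index (n={self.n}, m={self.m})")

    def __str__(self) -> str:  # e.g. G4^-2 -> "4,-2"
        return f"{self.n},{self.m}"


def modes_up_to(max_order: int) -> list[ModeIndex]:
    """All valid modes with n <= max_order, ordered by ascending n then m.

    This ordering is the fixed mode ordering used by every coefficient vector
    and matrix in the package (28 modes for max_order 6).
    """
    return [
        ModeIndex(n, m)
        for n in range(max_order + 1)
        for m in range(-n, n + 1, 2)
    ]


# ---------------------------------------------------------------------------
# monomial machinery
# ---------------------------------------------------------------------------

def _monomial_basis(max_degree: int) -> list[tuple[int, int]]:
    """Exponent pairs (a, b) for x^a y^b with a+b <= max_degree."""
    return [(d - b, b) for d in range(max_degree + 1) for b in range(d + 1)]


def monomial_disk_average(a: int, b: int) -> float:
    """Disk-average (1/pi) * integral of x^a y^b over the unit disk (closed form)."""
    if a % 2 or b % 2:
        return 0.0
    p, q = a // 2, b // 2
    return (
        math.factorial(a)
        * math.factorial(b)
        / (4 ** (p + q) * math.factorial(p) * math.factorial(q) * math.factorial(p + q + 1))
    )


def _angular_monomials(m: int) -> dict[tuple[int, int], float]:
    """rho^|m| cos(m theta) (m>=0) or rho^|m| sin(|m| theta) (m<0) as monomials.

    Uses Re/Im of (x + iy)^|m|.
    """
    am = abs(m)
    if am == 0:
        return {(0, 0): 1.0}
    out: dict[tuple[int, int], float] = {}
    for t in range(am + 1):
        if m >= 0 and t % 2 == 0:
            out[(am - t, t)] = math.comb(am, t) * (-1.0) ** (t // 2)
        elif m < 0 and t % 2 == 1:
            out[(am - t, t)] = math.comb(am, t) * (-1.0) ** ((t - 1) // 2)
    return out


def _radial_coefficients(n: int, am: int) -> dict[int, float]:
    """Powers of rho in the radial polynomial R_n^|m|."""
    coeffs: dict[int, float] = {}
    for k in range((n - am) // 2 + 1):
        coeffs[n - 2 * k] = (
            (-1.0) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)
            )
        )
    return coeffs


def _zernike_norm(n: int, m: int) -> float:
    return math.sqrt(2.0 * (n + 1) / (1.0 + (m == 0)))


def _zernike_monomials(mode: ModeIndex) -> dict[tuple[int, int], float]:
    """ANSI/OSA-normalized Zernike mode as an (x, y) monomial table."""
    n, m = mode.n, mode.m
    am = abs(m)
    norm = _zernike_norm(n, m)
    angular = _angular_monomials(m)
    out: dict[tuple[int, int], float] = {}
    for power, rc in _radial_coefficients(n, am).items():
        s = (power - am) // 2  # rho^(2s) = (x^2+y^2)^s
        for j in range(s + 1):
            radial_coef = rc * math.comb(s, j)
            for (a, b), ac in angular.items():
                key = (a + 2 * (s - j), b + 2 * j)
                out[key] = out.get(key, 0.0) + norm * radial_coef * ac
    return {k: v for k, v in out.items() if v != 0.0}


def zernike_mode_eval(mode: ModeIndex, rho, theta):
    """Evaluate one ANSI/OSA-normalized Zernike mode at (rho, theta).

    Orthonormal under the disk-average inner product
    <f, g> = (1/pi) * integral over the unit disk of f*g.
    Implemented directly from the radial/angular definition, independently of
    the monomial tables used elsewhere (the two routes cross-check each other
    in tests).
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    n, m = mode.n, mode.m
    am = abs(m)
    radial = sum(c * rho**p for p, c in _radial_coefficients(n, am).items())
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(am * theta)
    else:
        ang = np.ones_like(rho * theta)
    return _zernike_norm(n, m) * radial * ang


# ---------------------------------------------------------------------------
# LD/HD construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisTransform:
    """Invertible linear map between Zernike and LD/HD coefficient vectors.

    ``to_ldhd @ c`` gives G coefficients from Zernike coefficients c; the
    monomial matrices hold each basis function's exact monomial expansion
    (column per mode, row per monomial of _monomial_basis(max_order)).
    """

    max_order: int
    modes: tuple[ModeIndex, ...]
    monomials: tuple[tuple[int, int], ...]
    zernike_monomial_matrix: np.ndarray  # (n_monomials, n_modes)
    ldhd_monomial_matrix: np.ndarray
    to_ldhd: np.ndarray  # (n_modes, n_modes)
    to_zernike: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def mode_position(self, mode: ModeIndex) -> int:
        return self.modes.index(mode)

    def to_frame(self):
        """Change-of-basis matrix as a DataFrame with mode-index labels."""
        import pandas as pd

        labels = [str(m) for m in self.modes]
        return pd.DataFrame(self.to_ldhd, index=labels, columns=labels)


def _gram_matrix(monomials: Iterable[tuple[int, int]]) -> np.ndarray:
    mono = list(monomials)
    g = np.empty((len(mono), len(mono)))
    for i, (a1, b1) in enumerate(mono):
        for j, (a2, b2) in enumerate(mono):
            g[i, j] = monomial_disk_average(a1 + a2, b1 + b2)
    return g


@lru_cache(maxsize=8)
def build_ldhd_transform(max_order: int = 6) -> BasisTransform:
    """Construct the LD/HD basis and the coefficient transform at max_order.

    High-order Zernike modes (n >= 3) are expanded in monomials, their terms
    of total degree <= 2 deleted, and the truncated set orthonormalized by
    classical Gram-Schmidt (one re-orthogonalization pass) in the fixed mode
    ordering under the disk-average inner product.  Each resulting mode's sign
    is fixed to have positive inner product with its parent truncated
    polynomial.  Low-order modes (n <= 2) are the Zernike modes themselves.
    The coefficient transform preserves the reconstructed wavefront exactly:
    the deleted low-degree content reappears in the low-order coefficients.
    """
    if max_order < 3:
        raise ValueError("max_order must be >= 3 for an LD/HD split")
    modes = modes_up_to(max_order)
    mono = _monomial_basis(max_order)
    mono_pos = {ab: i for i, ab in enumerate(mono)}
    gram = _gram_matrix(mono)

    def vec(table: Mapping[tuple[int, int], float]) -> np.ndarray:
        v = np.zeros(len(mono))
        for ab, c in table.items():
            v[mono_pos[ab]] = c
        return v

    def inner(u: np.ndarray, v: np.ndarray) -> float:
        return float(u @ gram @ v)

    z_cols = [vec(_zernike_monomials(mode)) for mode in modes]
    low_degree = np.array([a + b <= 2 for (a, b) in mono])

    g_cols: list[np.ndarray] = []
    ho_done: list[np.ndarray] = []
    for mode, z in zip(modes, z_cols):
        if mode.n <= 2:
            g_cols.append(z.copy())
            continue
        t = z.copy()
        t[low_degree] = 0.0  # delete paraxial (degree <= 2) content
        g = t.copy()
        for _ in range(2):  # classical GS, re-orthogonalized once
            for prev in ho_done:
                g = g - inner(g, prev) * prev
        nrm = math.sqrt(inner(g, g))
        if nrm < 1e-10:
            raise ArithmeticError(
                f"LD/HD construction degenerate at mode {mode}: near-zero residual"
            )
        g = g / nrm
        if inner(g, t) < 0:
            g = -g
        ho_done.append(g)
        g_cols.append(g)

    mz = np.column_stack(z_cols)
    mg = np.column_stack(g_cols)
    cond = np.linalg.cond(mg)
    if not np.isfinite(cond) or cond > 1e10:
        raise ArithmeticError(f"LD/HD monomial matrix ill-conditioned (cond={cond:.3g})")
    to_ldhd = np.linalg.solve(mg, mz)  # W = Mz c = Mg G  =>  G = Mg^-1 Mz c
    to_zernike = np.linalg.solve(mz, mg)
    return BasisTransform(
        max_order=max_order,
        modes=tuple(modes),
        monomials=tuple(mono),
        zernike_monomial_matrix=mz,
        ldhd_monomial_matrix=mg,
        to_ldhd=to_ldhd,
        to_zernike=to_zernike,
    )


# ---------------------------------------------------------------------------
# coefficient container
# ---------------------------------------------------------------------------

@dataclass
class WavefrontCoefficients:
    """Mode-indexed expansion coefficients (um) with pupil radius (mm).

    ``values`` is aligned with ``modes_up_to(max_order)``.
    """

    basis: str
    values: np.ndarray
    pupil_radius_mm: float
    max_order: int = 6
    _modes: tuple[ModeIndex, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.basis not in (ZERNIKE, LDHD):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.pupil_radius_mm <= 0:
            raise ValueError("pupil_radius_mm must be > 0")
        self._modes = tuple(modes_up_to(self.max_order))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self._modes),):
            raise ValueError(
                f"expected {len(self._modes)} coefficients for order {self.max_order}, "
                f"got shape {self.values.shape}"
            )

    @classmethod
    def from_dict(
        cls,
        basis: str,
        coeffs: Mapping[tuple[int, int], float],
        pupil_radius_mm: float,
        max_order: int = 6,
    ) -> "WavefrontCoefficients":
        modes = modes_up_to(max_order)
        pos = {(mode.n, mode.m): i for i, mode in enumerate(modes)}
        values = np.zeros(len(modes))
        for (n, m), v in coeffs.items():
            key = (ModeIndex(n, m).n, ModeIndex(n, m).m)  # validates
            values[pos[key]] = v
        return cls(basis=basis, values=values, pupil_radius_mm=pupil_radius_mm,
                   max_order=max_order)

    @property
    def modes(self) -> tuple[ModeIndex, ...]:
        return self._modes

    def __getitem__(self, nm: tuple[int, int]) -> float:
        mode = ModeIndex(*nm)
        return float(self.values[self._modes.index(mode)])


def _check_compatible(w: WavefrontCoefficients, t: BasisTransform) -> None:
    if w.max_order != t.max_order:
        raise ValueError(
            f"coefficient order {w.max_order} incompatible with transform order {t.max_order}"
        )


def zernike_to_ldhd(
    w: WavefrontCoefficients, t: BasisTransform | None = None
) -> WavefrontCoefficients:
    """Convert Zernike coefficients to LD/HD G coefficients (same wavefront)."""
    if w.basis != ZERNIKE:
        raise ValueError(f"expected zernike-basis coefficients, got {w.basis!r}")
    t = t or build_ldhd_transform(w.max_order)
    _check_compatible(w, t)
    return WavefrontCoefficients(
        basis=LDHD,
        values=t.to_ldhd @ w.values,
        pupil_radius_mm=w.pupil_radius_mm,
        max_order=w.max_order,
    )


def ldhd_to_zernike(
    w: WavefrontCoefficients, t: BasisTransform | None = None
) -> WavefrontCoefficients:
    """Convert LD/HD G coefficients back to Zernike coefficients."""
    if w.basis != LDHD:
        raise ValueError(f"expected ldhd-basis coefficients, got {w.basis!r}")
    t = t or build_ldhd_transform(w.max_order)
    _check_compatible(w, t)
    return WavefrontCoefficients(
        basis=ZERNIKE,
        values=t.to_zernike @ w.values,
        pupil_radius_mm=w.pupil_radius_mm,
        max_order=w.max_order,
    )


def wavefront_eval(w: WavefrontCoefficients, rho, theta):
    """Reconstruct the wavefront height (um) at unit-disk polar points."""
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    t = build_ldhd_transform(w.max_order)
    mono_matrix = (
        t.zernike_monomial_matrix if w.basis == ZERNIKE else t.ldhd_monomial_matrix
    )
    poly = mono_matrix @ w.values  # monomial coefficients of W
    x = rho * np.cos(theta)
    y = rho * np.sin(theta)
    out = np.zeros(np.broadcast(x, y).shape)
    for (a, b), c in zip(t.monomials, poly):
        if c != 0.0:
            out = out + c * x**a * y**b
    return out


def paraxial_curvature_refraction(w: WavefrontCoefficients) -> "PowerVector":
    """Power vector from the wavefront curvature at the pupil center.

    With W in um over physical pupil coordinates in mm,
    M = -(Wxx + Wyy)/2, J0 = -(Wxx - Wyy)/2, J45 = -Wxy, all at the origin;
    um/mm^2 reads directly as diopters.  The second derivatives come
    analytically from the monomial table (coefficients of x^2, y^2, xy), so
    this routine is an exact, quadrature-free oracle for paraxial matching.
    """
    from .power_vectors import PowerVector

    if w.basis != ZERNIKE:
        raise ValueError("curvature oracle expects zernike-basis coefficients")
    t = build_ldhd_transform(w.max_order)
    poly = t.zernike_monomial_matrix @ w.values
    pos = {ab: i for i, ab in enumerate(t.monomials)}
    r2 = w.pupil_radius_mm**2
    a20 = poly[pos[(2, 0)]]
    a02 = poly[pos[(0, 2)]]
    a11 = poly[pos[(1, 1)]]
    # d2W/dx_mm^2 = 2*a20 / r^2 etc.
    return PowerVector(
        M=-(a20 + a02) / r2,
        J0=-(a20 - a02) / r2,
        J45=-a11 / r2,
    )
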