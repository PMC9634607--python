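"""Limited-resolution Fourier-synthesis reference maps.

The independent oracle for the closed-form map engine: structure factors are
summed directly over atoms (never computed as the FFT of a sampled density,
which would bias the reference itself) for every reciprocal-lattice point
inside the resolution sphere ``|s| <= 1/d_min``, each atom damped by its own
``exp(-B_n s^2/4)``; the map is then the inverse FFT of that coefficient set.
Orthorhombic P1 only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .map_engine import AtomicModel, DensityMap, GridSpec
from .scattering import lookup_scattering, scattering_curve

__all__ = [
    "StructureFactorSet",
    "direct_structure_factors",
    "synthesize_map",
]


@dataclass(frozen=True)
class StructureFactorSet:
    """Complex Fourier coefficients inside a spherical resolution cutoff."""

    cell: tuple[float, float, float]
    hkl: np.ndarray  # (N, 3) int
    amplitudes: np.ndarray  # (N,) complex
    d_min: float

    def __post_init__(self) -> None:
        hkl = np.asarray(self.hkl, dtype=int)
        amp = np.asarray(self.amplitudes, dtype=complex)
        object.__setattr__(self, "hkl", hkl)
        object.__setattr__(self, "amplitudes", amp)
        if hkl.ndim != 2 or hkl.shape[1] != 3 or amp.shape != (hkl.shape[0],):
            raise ValueError("hkl must be (N, 3) and amplitudes (N,)")
        if not self.d_min > 0:
            raise ValueError("d_min must be > 0")

    def s_lengths(self) -> np.ndarray:
        inv = 1.0 / np.asarray(self.cell)
        return np.sqrt(((self.hkl * inv) ** 2).sum(axis=1))


def direct_structure_factors(
    model: AtomicModel, d_min: float, tables: str = "electron"
) -> StructureFactorSet:
    """F(h) = sum_n occ_n f_n(s) exp(-B_n s^2/4) exp(2 pi i h.x_n), |s| <= 1/d_min.

    The cutoff is strict and inclusive: reflexes exactly on the sphere
    boundary are kept.
    """
    if not d_min > 0:
        raise ValueError("d_min must be > 0")
    a, b, c = model.cell
    hmax = [int(np.floor(L / d_min)) for L in model.cell]
    h, k, l = np.meshgrid(
        np.arange(-hmax[0], hmax[0] + 1),
        np.arange(-hmax[1], hmax[1] + 1),
        np.arange(-hmax[2], hmax[2] + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    inv = np.array([1.0 / a, 1.0 / b, 1.0 / c])
    s = np.sqrt(((hkl * inv) ** 2).sum(axis=1))
    keep = s <= 1.0 / d_min + 1e-12
    hkl = hkl[keep]
    s = s[keep]

    curves = {
        el: scattering_curve(lookup_scattering(el, tables), s)
        for el in sorted({at.element for at in model.atoms})
    }
    s2 = s * s
    F = np.zeros(hkl.shape[0], dtype=complex)
    frac_factors = hkl * inv  # phase = 2 pi (h x/a + k y/b + l z/c)
    for at in model.atoms:
        phase = 2.0 * np.pi * (frac_factors @ np.asarray(at.position))
        F += (
            at.occupancy
            * curves[at.element]
            * np.exp(-at.b_iso * s2 / 4.0)
            * np.exp(1j * phase)
        )
    return StructureFactorSet(model.cell, hkl, F, d_min)


def synthesize_map(sf: StructureFactorSet, grid: GridSpec) -> DensityMap:
    """rho(r) = (1/V) sum_h F(h) exp(-2 pi i h.x) via inverse FFT.

    The grid must hold every reflex without wrapping (divisions per axis
    >= 2*h_max + 1); the synthesized map is real up to float round-off.
    """
    if tuple(grid.cell) != tuple(sf.cell):
        raise ValueError("grid cell must match the structure-factor cell")
    if tuple(grid.origin) != (0.0, 0.0, 0.0):
        raise ValueError("Fourier synthesis requires a grid origin at (0,0,0)")
    n = grid.divisions
    hmax = np.abs(sf.hkl).max(axis=0)
    if any(ni < 2 * hm + 1 for ni, hm in zip(n, hmax)):
        raise ValueError(
            f"grid {n} cannot represent reflexes up to {tuple(hmax)}; "
            "need divisions >= 2*h_max + 1 per axis (Nyquist)"
        )
    coef = np.zeros(n, dtype=complex)
    idx = tuple(sf.hkl[:, ax] % n[ax] for ax in range(3))
    coef[idx] = sf.amplitudes
    vol = float(np.prod(grid.cell))
    # forward FFT carries the e^{-2 pi i h.x} kernel of the synthesis
    rho = np.fft.fftn(coef) / vol
    imag_peak = float(np.max(np.abs(rho.imag)))
    real_peak = float(np.max(np.abs(rho.real)))
    if real_peak > 0 and imag_peak > 1e-8 * real_peak:
        raise ValueError(
            "synthesized map is not real; structure factors violate "
            "Friedel symmetry"
        )
    return DensityMap(grid, rho.real)
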