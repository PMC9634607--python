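"""Deterministic toy atomic models for tests and demos.

No structure downloads: the canonical test body is a protein-sized
"helix" preset — a solenoid of backbone-like C/N/O atoms with ~1.5 A bonded
spacing wound compactly inside the box — plus trivial single-atom, pair and
random-blob presets.  Displacement parameters are drawn uniformly from
[5, 60] A^2 (seeded), a realistic macromolecular range.  All presets are
bit-reproducible for a given (preset, n_atoms, box, seed).
"""

from __future__ import annotations

import numpy as np

from .map_engine import AtomicModel, AtomSite
from .model_io import ResolutionSidecar

__all__ = ["make_toy_model", "assign_radial_resolution"]

_B_RANGE = (5.0, 60.0)
_MIN_SEPARATION = 0.8  # A
_HELIX_ELEMENTS = ("N", "C", "C", "O")


def _min_pair_distance(xyz: np.ndarray) -> float:
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def make_toy_model(
    preset: str, n_atoms: int, box: float, seed: int = 0
) -> AtomicModel:
    """Generate a deterministic toy model in a cubic P1 box.

    Presets: ``single-atom`` (one immobile C at the box center), ``pair``
    (C and O 2 A apart, B = 5 and 15), ``helix`` (a compact solenoid of
    N/C/C/O atoms, bonded spacing ~1.5 A, B ~ U[5, 60]), ``blob``
    (uniform random atoms with minimum separation enforced by rejection).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if box <= 0:
        raise ValueError("box must be > 0")
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0)
    cell = (box, box, box)

    if preset == "single-atom":
        return AtomicModel(
            (AtomSite("C", tuple(center), b_iso=0.0, id=("A", 1, "", "C1", "")),),
            cell,
        )
    if preset == "pair":
        a = AtomSite("C", tuple(center - [1.0, 0, 0]), b_iso=5.0,
                     id=("A", 1, "", "C1", ""))
        b = AtomSite("O", tuple(center + [1.0, 0, 0]), b_iso=15.0,
                     id=("A", 1, "", "O1", ""))
        return AtomicModel((a, b), cell)

    if preset == "helix":
        # minor helix (r = 2.3 A, ~1.5 A chord) wound on a major circle so a
        # long chain stays compact, like a folded protein
        r_minor, dphi = 2.3, 0.6
        arc_rise = np.sqrt(1.5**2 - (2 * r_minor * np.sin(dphi / 2)) ** 2)
        r_major = max(6.0, n_atoms * arc_rise / (2 * np.pi) * 1.15)
        i = np.arange(n_atoms)
        phi = i * dphi
        theta = i * arc_rise / r_major
        rho = r_major + r_minor * np.cos(phi)
        xyz = np.stack(
            [rho * np.cos(theta), rho * np.sin(theta), r_minor * np.sin(phi)],
            axis=1,
        )
        xyz += center - xyz.mean(axis=0)
        elements = [_HELIX_ELEMENTS[j % 4] for j in range(n_atoms)]
    elif preset == "blob":
        xyz = np.empty((n_atoms, 3))
        placed = 0
        for _ in range(200 * n_atoms):
            cand = center + rng.uniform(-box / 4, box / 4, size=3)
            if placed == 0 or np.min(
                np.linalg.norm(xyz[:placed] - cand, axis=1)
            ) >= _MIN_SEPARATION:
                xyz[placed] = cand
                placed += 1
                if placed == n_atoms:
                    break
        if placed < n_atoms:
            raise ValueError(
                f"could not place {n_atoms} atoms at >= {_MIN_SEPARATION} A "
                f"separation in a {box} A box"
            )
        elements = rng.choice(["C", "N", "O"], size=n_atoms).tolist()
    else:
        raise ValueError(f"unknown preset {preset!r}")

    if np.any(xyz < 0) or np.any(xyz > box):
        raise ValueError(
            f"preset {preset!r} with n_atoms={n_atoms} does not fit in a "
            f"{box} A box"
        )
    if n_atoms > 1 and _min_pair_distance(xyz) < _MIN_SEPARATION:
        raise ValueError("generated atoms overlap closer than 0.8 A")

    b_vals = rng.uniform(*_B_RANGE, size=n_atoms)
    atoms = tuple(
        AtomSite(
            elements[j],
            tuple(xyz[j]),
            b_iso=float(b_vals[j]),
            id=("A", j + 1, "", f"{elements[j]}{j + 1}", ""),
        )
        for j in range(n_atoms)
    )
    return AtomicModel(atoms, cell)


def assign_radial_resolution(
    model: AtomicModel, d_center: float, d_edge: float
) -> ResolutionSidecar:
    """Linear per-atom resolution gradient from the model center outward.

    D_n interpolates linearly in distance from the center of geometry:
    ``d_center`` at the center, ``d_edge`` at the outermost atom, clamped to
    the [min, max] of the two values.
    """
    if not (d_center > 0 and d_edge > 0):
        raise ValueError("d_center and d_edge must be > 0")
    xyz = np.array([a.position for a in model.atoms])
    cog = xyz.mean(axis=0)
    dist = np.linalg.norm(xyz - cog, axis=1)
    rmax = dist.max() if dist.size and dist.max() > 0 else 1.0
    dn = d_center + (d_edge - d_center) * dist / rmax
    lo, hi = min(d_center, d_edge), max(d_center, d_edge)
    dn = np.clip(dn, lo, hi)
    entries = {a.id: float(d) for a, d in zip(model.atoms, dn)}
    return ResolutionSidecar(entries, default_resolution=d_center)
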