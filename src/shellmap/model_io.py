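"""File I/O: coordinate models, per-atom resolution sidecars, CCP4 maps.

Coordinate files (PDB / mmCIF) are read through gemmi; only orthorhombic P1
cells are accepted, since the map engine's periodic summation assumes them.
Per-atom resolutions have no deposition convention yet, so they travel in a
provisional CSV sidecar keyed by (chain, resseq, icode, atom, altloc).
Density maps are written as CCP4/MRC mode-2 files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .map_engine import AtomicModel, AtomSite, DensityMap, GridSpec

__all__ = [
    "ResolutionSidecar",
    "read_model",
    "apply_sidecar",
    "read_sidecar",
    "write_sidecar",
    "write_map",
    "read_map",
    "write_model_pdb",
]

_SIDECAR_COLUMNS = ["chain", "resseq", "icode", "atom", "altloc", "d_n"]


@dataclass(frozen=True)
class ResolutionSidecar:
    """Per-atom resolution assignments plus a fallback default (A)."""

    entries: dict[tuple, float] = field(default_factory=dict)
    default_resolution: float = 2.0

    def __post_init__(self) -> None:
        if not self.default_resolution > 0:
            raise ValueError("default_resolution must be > 0")
        for key, d in self.entries.items():
            if not d > 0:
                raise ValueError(f"D_n must be > 0 (got {d} for {key})")


def read_model(
    path,
    default_b: float | None = None,
    default_d: float = 2.0,
    box: tuple[float, float, float] | None = None,
    keep_altlocs: bool = False,
    drop_hydrogens: bool = False,
) -> AtomicModel:
    """Read a PDB or mmCIF file into an AtomicModel.

    B-factors and occupancies come from the file (``default_b`` overrides B
    for every atom if given); every atom gets ``default_d`` as its resolution
    until a sidecar is applied.  The cell must be orthorhombic P1; ``box``
    overrides a missing or placeholder cell.  By default only the
    highest-occupancy altloc conformer of each atom is kept.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    sg = (st.spacegroup_hm or "P 1").strip()
    if sg.replace(" ", "") != "P1":
        raise ValueError(f"{path}: only space group P1 is supported, got {sg!r}")

    cell = st.cell
    if box is not None:
        cell_edges = tuple(float(v) for v in box)
    else:
        if not cell.is_crystal() or (cell.a, cell.b, cell.c) == (1.0, 1.0, 1.0):
            raise ValueError(
                f"{path}: no usable unit cell (missing CRYST1?); pass an "
                "explicit box"
            )
        if not (
            abs(cell.alpha - 90) < 1e-6
            and abs(cell.beta - 90) < 1e-6
            and abs(cell.gamma - 90) < 1e-6
        ):
            raise ValueError(f"{path}: only orthorhombic cells are supported")
        cell_edges = (cell.a, cell.b, cell.c)

    atoms: list[AtomSite] = []
    best: dict[tuple, AtomSite] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                if drop_hydrogens and at.element.is_hydrogen:
                    continue
                el = at.element.name
                if not el or el == "X":
                    raise ValueError(
                        f"{path}: atom {chain.name}/{res.seqid.num}/{at.name} "
                        "has no element assignment"
                    )
                site = AtomSite(
                    element=el,
                    position=(at.pos.x, at.pos.y, at.pos.z),
                    b_iso=float(default_b if default_b is not None else at.b_iso),
                    resolution=default_d,
                    occupancy=float(at.occ),
                    id=(
                        chain.name,
                        res.seqid.num,
                        res.seqid.icode.strip(),
                        at.name,
                        at.altloc.strip(),
                    ),
                )
                if keep_altlocs:
                    atoms.append(site)
                else:
                    key = site.id[:4]
                    if key not in best or site.occupancy > best[key].occupancy:
                        best[key] = site
    if not keep_altlocs:
        atoms = list(best.values())
    return AtomicModel(tuple(atoms), cell_edges)


def apply_sidecar(
    model: AtomicModel, sidecar: ResolutionSidecar, strict: bool = False
) -> AtomicModel:
    """Assign per-atom resolutions from a sidecar; unmatched atoms get the
    default.  In strict mode a sidecar row matching no atom is an error."""
    model_ids = {a.id for a in model.atoms}
    unmatched = [k for k in sidecar.entries if k not in model_ids]
    if unmatched and strict:
        raise ValueError(f"sidecar rows match no atom: {unmatched[:5]}...")
    atoms = tuple(
        replace(
            a, resolution=sidecar.entries.get(a.id, sidecar.default_resolution)
        )
        for a in model.atoms
    )
    return replace(model, atoms=atoms)


def write_sidecar(sidecar: ResolutionSidecar, path) -> None:
    rows = [
        {
            "chain": k[0],
            "resseq": k[1],
            "icode": k[2],
            "atom": k[3],
            "altloc": k[4],
            "d_n": d,
        }
        for k, d in sidecar.entries.items()
    ]
    df = pd.DataFrame(rows, columns=_SIDECAR_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# default_resolution={sidecar.default_resolution!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_sidecar(path) -> ResolutionSidecar:
    default = 2.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# default_resolution="):
            default = float(first.split("=", 1)[1])
            df = pd.read_csv(fh, dtype={"icode": str, "altloc": str})
        else:
            fh.seek(0)
            df = pd.read_csv(fh, dtype={"icode": str, "altloc": str})
    missing = set(_SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sidecar is missing columns {sorted(missing)}")
    entries = {}
    for row in df.itertuples(index=False):
        icode = "" if pd.isna(row.icode) else str(row.icode)
        altloc = "" if pd.isna(row.altloc) else str(row.altloc)
        key = (str(row.chain), int(row.resseq), icode, str(row.atom), altloc)
        if key in entries:
            raise ValueError(f"{path}: duplicate sidecar id {key}")
        entries[key] = float(row.d_n)
    return ResolutionSidecar(entries, default)


def write_map(density: DensityMap, path) -> None:
    """Write a CCP4/MRC mode-2 (float32) map with cell and sampling set."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(density.values, dtype=np.float32))
    grid.set_unit_cell(gemmi.UnitCell(*density.grid.cell, 90, 90, 90))
    grid.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header(2, True)
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> DensityMap:
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"))
    grid = ccp4.grid
    values = np.array(grid, copy=True, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: map does not cover the full unit cell")
    cell = (grid.unit_cell.a, grid.unit_cell.b, grid.unit_cell.c)
    spec = GridSpec(cell=cell, divisions=values.shape)
    return DensityMap(spec, values)


def write_model_pdb(model: AtomicModel, path) -> None:
    """Write an AtomicModel as a single-chain P1 PDB file."""
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    md = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, a in enumerate(model.atoms, start=1):
        res = gemmi.Residue()
        res.name = "UNK"
        res.seqid = gemmi.SeqId(i, " ")
        at = gemmi.Atom()
        at.name = f"{a.element}{i % 100}"
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = a.b_iso
        res.add_atom(at)
        chain.add_residue(res)
    md.add_chain(chain)
    st.add_model(md)
    st.write_pdb(str(path))
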