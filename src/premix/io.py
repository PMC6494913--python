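"""Structure and sidecar-table I/O.

Coordinates travel as PDB files (via biotite): the fixed receptor frame as a
single-model PDB, structure pools as multi-model PDBs whose models share the
same atom layout (mobile-unit pseudo-atoms plus probe pseudo-atoms).  The
spin-label conformer centers, which have no natural PDB slot, travel in a
sidecar TSV (member, site_id, copy, conformer, x, y, z), and probe ids in an
index TSV so the methyl labels round-trip exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .forward import LabeledStructure

__all__ = [
    "write_coords_pdb",
    "read_coords_pdb",
    "write_pool",
    "read_pool",
]

_PROBE_RES = "PRB"
_MOBILE_RES = "MOB"


def _atom_array(coords: np.ndarray, res_name: str, start_res: int = 1) -> AtomArray:
    n = len(coords)
    arr = AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(start_res, start_res + n)
    arr.res_name = np.full(n, res_name)
    arr.atom_name = np.full(n, "C")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, True)
    return arr


def write_coords_pdb(coords: np.ndarray, path, res_name: str = _MOBILE_RES) -> None:
    """Write a bare coordinate set as pseudo-atoms in PDB format."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array(coords, res_name))
    pdb.write(str(path))


def read_coords_pdb(path) -> np.ndarray:
    arr = PDBFile.read(str(path)).get_structure(model=1)
    return np.asarray(arr.coord, dtype=float)


def write_pool(members: list[LabeledStructure], pdb_path, sidecar_path, index_path) -> None:
    """Write a structure pool: multi-model PDB + conformer sidecar + index TSV.

    Model m of the PDB holds member m's mobile-unit atoms (residue MOB)
    followed by its probe pseudo-atoms (residue PRB, in probe-id order).
    """
    if not members:
        raise ValueError("empty pool")
    n_atoms = 0 if members[0].atoms is None else len(members[0].atoms)
    n_probes = len(members[0].probe_ids)
    template = _atom_array(np.zeros((n_atoms + n_probes, 3)), _MOBILE_RES)
    template.res_name[n_atoms:] = _PROBE_RES
    coords = np.empty((len(members), n_atoms + n_probes, 3), dtype=np.float32)
    side_rows = []
    for m, st in enumerate(members):
        if len(st.probe_ids) != n_probes:
            raise ValueError("pool members disagree on probe count")
        if n_atoms:
            coords[m, :n_atoms] = st.atoms
        coords[m, n_atoms:] = st.probe_xyz
        for sid, conf in st.sites.items():
            for c in range(conf.shape[0]):
                for j in range(conf.shape[1]):
                    side_rows.append((m, sid, c, j, *conf[c, j]))
    stack = AtomArrayStack(len(members), n_atoms + n_probes)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(pdb_path))
    pd.DataFrame(
        side_rows, columns=["member", "site_id", "copy", "conformer", "x", "y", "z"]
    ).to_csv(sidecar_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "probe_order": np.arange(n_probes),
            "methyl_id": members[0].probe_ids,
        }
    ).to_csv(index_path, sep="\t", index=False)


def read_pool(pdb_path, sidecar_path, index_path) -> list[LabeledStructure]:
    """Read a pool written by :func:`write_pool`."""
    stack = PDBFile.read(str(pdb_path)).get_structure()
    probe_mask = stack.res_name == _PROBE_RES
    idx = pd.read_csv(index_path, sep="\t").sort_values("probe_order")
    probe_ids = [str(m) for m in idx["methyl_id"]]
    side = pd.read_csv(sidecar_path, sep="\t")
    members = []
    for m in range(stack.stack_depth()):
        coords = np.asarray(stack.coord[m], dtype=float)
        sites = {}
        sub = side[side["member"] == m]
        for sid, g in sub.groupby("site_id"):
            n_copies = g["copy"].max() + 1
            n_conf = g["conformer"].max() + 1
            arr = np.empty((n_copies, n_conf, 3))
            for _, _, c, j, x, y, z in g.itertuples(index=False, name=None):
                arr[int(c), int(j)] = (x, y, z)
            sites[str(sid)] = arr
        members.append(
            LabeledStructure(
                probe_ids=probe_ids,
                probe_xyz=coords[probe_mask],
                sites=sites,
                atoms=coords[~probe_mask] if np.any(~probe_mask) else None,
                meta={"member": m},
            )
        )
    return members
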