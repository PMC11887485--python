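"""In-memory trajectory container and PDB/DCD/JSON I/O.

A :class:`TrajectoryBundle` holds frames as a single (n_frames, n_atoms,
3) array in Angstrom plus named atom groups: the nanotube, the ssDNA
corona (with tagged backbone atoms P, O1P/OP1, O2P/OP2, O3', O4', O5'),
and one entry per analyte molecule with its aryl-ring and polar-group
atom subsets.  Group membership comes from a JSON side file rather than
from residue heuristics, since the systems here mix real and pseudo
atoms.  File reading/writing goes through MDAnalysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sasa import vdw_radii

__all__ = [
    "PolarGroup",
    "AnalyteMolecule",
    "TrajectoryBundle",
    "load_trajectory",
    "write_trajectory",
]

POLAR_CLASSES = ("hydroxy", "amine", "ammonium", "alkoxide")
#: classes whose surface distance gates binding-event segmentation
AMINE_CLASSES = ("amine", "ammonium")
BACKBONE_TAGS = ("P", "O1P", "O2P", "O3'", "O4'", "O5'")


@dataclass
class PolarGroup:
    name: str
    indices: np.ndarray
    group_class: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.group_class not in POLAR_CLASSES:
            raise ValueError(f"unknown polar-group class {self.group_class!r}")


@dataclass
class AnalyteMolecule:
    indices: np.ndarray
    aryl_ring: np.ndarray
    polar_groups: list[PolarGroup] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.aryl_ring = np.asarray(self.aryl_ring, dtype=np.int64)
        if not np.isin(self.aryl_ring, self.indices).all():
            raise ValueError("aryl-ring atoms are not a subset of the molecule")
        for g in self.polar_groups:
            if not np.isin(g.indices, self.indices).all():
                raise ValueError(f"polar group {g.name!r} not a subset of the molecule")

    def groups_of_class(self, classes) -> list[PolarGroup]:
        if isinstance(classes, str):
            classes = (classes,)
        return [g for g in self.polar_groups if g.group_class in classes]


@dataclass
class TrajectoryBundle:
    """Frames + group definitions for one simulated/loaded system."""

    coords: np.ndarray  # (n_frames, n_atoms, 3) Angstrom
    elements: np.ndarray  # (n_atoms,) element symbols
    swcnt: np.ndarray
    dna: np.ndarray
    analytes: list[AnalyteMolecule]
    box: np.ndarray  # (3,) orthorhombic lengths, Angstrom
    dt: float  # ns between stored frames
    dna_backbone: dict[str, np.ndarray] = field(default_factory=dict)
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates contain non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.swcnt = np.asarray(self.swcnt, dtype=np.int64)
        self.dna = np.asarray(self.dna, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        n = self.coords.shape[1]
        pools = [self.swcnt, self.dna] + [m.indices for m in self.analytes]
        nonempty = [p for p in pools if p.size]
        allidx = np.concatenate(nonempty) if nonempty else np.empty(0, dtype=np.int64)
        if allidx.size and (allidx.min() < 0 or allidx.max() >= n):
            raise ValueError("group indices out of range")
        if np.unique(allidx).size != allidx.size:
            raise ValueError("swcnt/dna/analyte groups are not disjoint")
        if self.radii is None:
            self.radii = vdw_radii(self.elements)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def conjugate(self) -> np.ndarray:
        """Atom indices of the ssDNA-SWCNT conjugate (nanotube + corona)."""
        return np.concatenate([self.swcnt, self.dna])

    def target_indices(self, target: str) -> np.ndarray:
        if target == "swcnt":
            return self.swcnt
        if target == "dna":
            return self.dna
        if target == "conjugate":
            return self.conjugate
        raise ValueError(f"unknown target {target!r} (swcnt|dna|conjugate)")

    def com(self, indices: np.ndarray, frame: int | None = None) -> np.ndarray:
        """Unweighted center of geometry of the atoms (all frames or one)."""
        if frame is None:
            return self.coords[:, indices, :].mean(axis=1)
        return self.coords[frame, indices, :].mean(axis=0)

    def with_stride(self, stride: int) -> "TrajectoryBundle":
        """Keep every stride-th frame; dt scales accordingly."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return TrajectoryBundle(
            coords=self.coords[::stride],
            elements=self.elements,
            swcnt=self.swcnt,
            dna=self.dna,
            analytes=self.analytes,
            box=self.box,
            dt=self.dt * stride,
            dna_backbone=self.dna_backbone,
            radii=self.radii,
        )


# ---------------------------------------------------------------------------
# Group-config JSON schema
# ---------------------------------------------------------------------------

def _groups_from_dict(cfg: dict) -> tuple:
    analytes = [
        AnalyteMolecule(
            indices=np.asarray(m["indices"], dtype=np.int64),
            aryl_ring=np.asarray(m["aryl_ring"], dtype=np.int64),
            polar_groups=[
                PolarGroup(
                    name=g["name"],
                    indices=np.asarray(g["indices"], dtype=np.int64),
                    group_class=g["class"],
                )
                for g in m.get("polar_groups", [])
            ],
        )
        for m in cfg.get("analytes", [])
    ]
    backbone = {
        tag: np.asarray(idx, dtype=np.int64)
        for tag, idx in cfg.get("dna_backbone", {}).items()
    }
    return (
        np.asarray(cfg["swcnt"], dtype=np.int64),
        np.asarray(cfg["dna"], dtype=np.int64),
        analytes,
        backbone,
        float(cfg.get("dt_ns", 1.0)),
    )


def groups_to_dict(bundle: TrajectoryBundle) -> dict:
    return {
        "swcnt": bundle.swcnt.tolist(),
        "dna": bundle.dna.tolist(),
        "dna_backbone": {t: v.tolist() for t, v in bundle.dna_backbone.items()},
        "analytes": [
            {
                "indices": m.indices.tolist(),
                "aryl_ring": m.aryl_ring.tolist(),
                "polar_groups": [
                    {
                        "name": g.name,
                        "indices": g.indices.tolist(),
                        "class": g.group_class,
                    }
                    for g in m.polar_groups
                ],
            }
            for m in bundle.analytes
        ],
        "dt_ns": bundle.dt,
    }


def load_trajectory(topology, frames, groups_json) -> TrajectoryBundle:
    """Build a bundle from a PDB topology, DCD/XTC frames and a groups JSON."""
    import MDAnalysis as mda

    with open(groups_json) as fh:
        cfg = json.load(fh)
    swcnt, dna, analytes, backbone, dt = _groups_from_dict(cfg)
    u = mda.Universe(str(topology), str(frames))
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float32)
    try:
        elements = np.array([a.element for a in u.atoms])
    except mda.exceptions.NoDataError:
        # fall back to the leading letter of the atom name
        elements = np.array([a.name.strip("0123456789'*")[:1].upper() for a in u.atoms])
    dims = u.dimensions
    box = np.asarray(dims[:3], dtype=float) if dims is not None else np.full(3, np.inf)
    return TrajectoryBundle(
        coords=coords,
        elements=elements,
        swcnt=swcnt,
        dna=dna,
        analytes=analytes,
        box=box,
        dt=dt,
        dna_backbone=backbone,
    )


def write_trajectory(bundle: TrajectoryBundle, out_dir, basename: str = "system"):
    """Write PDB + DCD + groups JSON; returns the three paths."""
    import MDAnalysis as mda

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_atoms = bundle.coords.shape[1]
    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.add_TopologyAttr("names", [f"{e}{i%100}" for i, e in enumerate(bundle.elements)])
    u.add_TopologyAttr("elements", list(bundle.elements))
    u.dimensions = [*bundle.box, 90.0, 90.0, 90.0]
    pdb = out / f"{basename}.pdb"
    dcd = out / f"{basename}.dcd"
    gjson = out / f"{basename}_groups.json"
    u.atoms.positions = bundle.coords[0]
    u.atoms.write(str(pdb))
    with mda.Writer(str(dcd), n_atoms) as w:
        for frame in bundle.coords:
            u.atoms.positions = frame
            w.write(u.atoms)
    with open(gjson, "w") as fh:
        json.dump(groups_to_dict(bundle), fh)
    return pdb, dcd, gjson
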