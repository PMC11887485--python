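"""Trajectory-derived binding metrics.

Implements, for a :class:`~nanosar.trajectory.TrajectoryBundle`:

* per-frame buried contact areas between each analyte molecule and the
  nanotube or the full ssDNA-SWCNT conjugate (buried-surface formula,
  see :mod:`nanosar.sasa`);
* the percentage of frames a molecule is bound (contact area above a
  proximity threshold, default 1 A^2);
* binding-event segmentation (contact area > 30 A^2, plus — for
  molecules carrying amine/ammonium groups — group COM within 10.5 A of
  the nanotube surface) and the pooled mean event duration, i.e. the
  residence time tau_R = sum_i t_i n_i / sum_j n_j = 1/k_off;
* stacking distances (aryl-ring COM to surface, conditional on < 10 A);
* polar-group distance distributions within 10 A and their area under
  the curve below 4 A;
* radial distribution functions g(r) and geometric hydrogen-bond counts;
* an operationalized per-molecule binding-mode classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import CylinderModel, fit_cylinder, surface_distance
from .sasa import (
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    contact_area as _contact_area_raw,
    sasa_per_atom,
    sasa_per_atom_partial,
)
from .trajectory import AMINE_CLASSES, TrajectoryBundle

__all__ = [
    "ContactSeries",
    "BindingEvent",
    "ResidenceTimeResult",
    "DistanceDistribution",
    "GofR",
    "contact_area",
    "contact_series",
    "bound_fraction",
    "segment_binding_events",
    "residence_time",
    "aryl_distance_series",
    "amine_distance_series",
    "stacking_distance",
    "polar_distance_distribution",
    "auc_below",
    "class_auc_sum",
    "radial_distribution",
    "count_hbonds",
    "classify_binding_mode",
    "swcnt_cylinder",
]

BOUND_AREA_THRESHOLD = 1.0  # A^2, proximity criterion for % bound
EVENT_AREA_THRESHOLD = 30.0  # A^2, binding-event criterion
AMINE_DISTANCE_CUTOFF = 10.5  # A, extra criterion for amine-bearing analytes
STACKING_CUTOFF = 10.0  # A, frames counted toward the stacking distance
POLAR_RMAX = 10.0  # A, polar-group distribution support
POLAR_AUC_X = 4.0  # A, close-interaction threshold
DEFAULT_BIN_WIDTH = 0.1  # A


def swcnt_cylinder(bundle: TrajectoryBundle, frame: int = 0) -> CylinderModel:
    """Cylinder fit of the nanotube from one frame's SWCNT coordinates."""
    return fit_cylinder(bundle.coords[frame, bundle.swcnt, :])


# ---------------------------------------------------------------------------
# Contact areas
# ---------------------------------------------------------------------------

@dataclass
class ContactSeries:
    """Per-frame, per-molecule buried contact areas against one target."""

    areas: np.ndarray  # (n_frames, n_molecules), A^2
    target: str
    dt: float  # ns between frames

    def __post_init__(self) -> None:
        self.areas = np.atleast_2d(np.asarray(self.areas, dtype=float))
        if np.any(self.areas < 0):
            raise ValueError("contact areas must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.areas.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.areas.shape[1]


def contact_area(
    bundle: TrajectoryBundle,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    frame: int,
    probe: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> float:
    """Buried contact area between two disjoint atom-index selections."""
    a = np.asarray(selection_a, dtype=np.int64)
    b = np.asarray(selection_b, dtype=np.int64)
    if np.intersect1d(a, b).size:
        raise ValueError("selections overlap: shared atom indices")
    return _contact_area_raw(
        bundle.coords[frame, a, :],
        bundle.radii[a],
        bundle.coords[frame, b, :],
        bundle.radii[b],
        probe=probe,
        n_sphere_points=n_sphere_points,
    )


class _StaticTargetSASA:
    """Cached per-atom SASA of a rigid target for fast frame-wise contacts.

    Only target atoms within occlusion range of the analyte change their
    accessibility in the union, so per frame we recompute SASA for the
    analyte atoms plus the affected target atoms (with their own target
    neighbors as occluding context) and patch the cached values.
    """

    def __init__(self, coords, radii, probe, n_points):
        self.coords = np.ascontiguousarray(coords, dtype=np.float64)
        self.radii = np.asarray(radii, dtype=np.float64)
        self.probe = probe
        self.n_points = n_points
        self.per_atom = sasa_per_atom(self.coords, self.radii, probe, n_points)
        self.total = float(self.per_atom.sum())
        self.R = self.radii + probe
        self.Rmax = float(self.R.max())
        self.tree = cKDTree(self.coords)
        # target-target occlusion neighbors (for context around affected atoms)
        self.ctx_lists = self.tree.query_ball_tree(self.tree, 2.0 * self.Rmax)

    def contact_with(self, coords_a, radii_a) -> float:
        Ra = np.asarray(radii_a, dtype=float) + self.probe
        cutoff = self.Rmax + float(Ra.max())
        hit = self.tree.query_ball_point(coords_a, cutoff)
        affected = np.unique(np.concatenate([np.asarray(h, dtype=np.int64) for h in hit])) \
            if any(len(h) for h in hit) else np.empty(0, dtype=np.int64)
        s_a_iso = float(
            sasa_per_atom(coords_a, radii_a, self.probe, self.n_points).sum()
        )
        if affected.size == 0:
            return 0.0
        ctx = np.unique(
            np.concatenate([np.asarray(self.ctx_lists[i], dtype=np.int64) for i in affected])
        )
        ctx_only = np.setdiff1d(ctx, affected, assume_unique=False)
        sub_coords = np.vstack(
            [coords_a, self.coords[affected], self.coords[ctx_only]]
        )
        sub_radii = np.concatenate(
            [radii_a, self.radii[affected], self.radii[ctx_only]]
        )
        na = len(coords_a)
        per = sasa_per_atom_partial(
            sub_coords, sub_radii, na + affected.size, self.probe, self.n_points
        )
        s_a_union = float(per[:na].sum())
        s_aff_union = float(per[na : na + affected.size].sum())
        s_ab = s_a_union + s_aff_union + (self.total - float(self.per_atom[affected].sum()))
        return max(0.0, 0.5 * (s_a_iso + self.total - s_ab))


def contact_series(
    bundle: TrajectoryBundle,
    target: str = "conjugate",
    probe: float = DEFAULT_PROBE,
    n_sphere_points: int = DEFAULT_N_POINTS,
    stride: int = 1,
) -> ContactSeries:
    """Per-frame contact areas of each analyte molecule with a target.

    ``target`` is ``swcnt``, ``dna`` or ``conjugate`` (nanotube + corona).
    If the target atoms do not move over the trajectory their per-atom
    SASA is cached and only the interface region is recomputed per frame.
    """
    if not bundle.analytes:
        raise ValueError("bundle defines no analyte molecules")
    tidx = bundle.target_indices(target)
    if tidx.size == 0:
        raise ValueError(f"target group {target!r} is empty")
    frames = range(0, bundle.n_frames, stride)
    n_mol = len(bundle.analytes)
    areas = np.zeros((len(frames), n_mol))

    static = np.array_equal(
        bundle.coords[0, tidx, :], bundle.coords[-1, tidx, :]
    )
    if static:
        cache = _StaticTargetSASA(
            bundle.coords[0, tidx, :], bundle.radii[tidx], probe, n_sphere_points
        )
        for fi, f in enumerate(frames):
            for mi, mol in enumerate(bundle.analytes):
                areas[fi, mi] = cache.contact_with(
                    np.asarray(bundle.coords[f, mol.indices, :], dtype=np.float64),
                    bundle.radii[mol.indices],
                )
    else:
        for fi, f in enumerate(frames):
            for mi, mol in enumerate(bundle.analytes):
                areas[fi, mi] = contact_area(
                    bundle, mol.indices, tidx, f, probe, n_sphere_points
                )
    return ContactSeries(areas=areas, target=target, dt=bundle.dt * stride)


# ---------------------------------------------------------------------------
# Bound fraction, events, residence time
# ---------------------------------------------------------------------------

def bound_fraction(
    series: ContactSeries,
    threshold: float = BOUND_AREA_THRESHOLD,
):
    """Percentage of frames with contact area above the threshold.

    Returns (per-molecule percentages, pooled percentage).
    """
    if series.n_frames < 1:
        raise ValueError("empty contact series")
    bound = series.areas > threshold
    per_mol = 100.0 * bound.mean(axis=0)
    return per_mol, float(100.0 * bound.mean())


@dataclass(frozen=True)
class BindingEvent:
    molecule: int
    target: str
    start_frame: int
    end_frame: int  # inclusive
    duration: float  # ns

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("event end before start")


def _runs(mask: np.ndarray):
    """(start, end_inclusive) index pairs of True runs in a boolean trace."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _fill_gaps(mask: np.ndarray, tol: int) -> np.ndarray:
    if tol <= 0:
        return mask
    filled = mask.copy()
    for start, end in _runs(~mask):
        if start > 0 and end < mask.size - 1 and (end - start + 1) <= tol:
            filled[start : end + 1] = True
    return filled


def segment_binding_events(
    series: ContactSeries,
    amine_distance: np.ndarray | None = None,
    area_threshold: float = EVENT_AREA_THRESHOLD,
    amine_cutoff: float = AMINE_DISTANCE_CUTOFF,
    dt: float | None = None,
    gap_tolerance: int = 0,
) -> list[BindingEvent]:
    """Maximal runs of frames satisfying the binding-event criteria.

    A frame belongs to an event when contact area > ``area_threshold``
    and — if ``amine_distance`` is provided for that molecule (non-NaN
    column) — the amine/ammonium group COM is within ``amine_cutoff`` of
    the nanotube surface.  Strict frame-wise predicates by default; a
    ``gap_tolerance`` of g frames bridges interior gaps of length <= g.
    """
    dt = series.dt if dt is None else dt
    if amine_distance is not None:
        amine_distance = np.atleast_2d(np.asarray(amine_distance, dtype=float))
        if amine_distance.shape != series.areas.shape:
            raise ValueError(
                f"amine-distance series {amine_distance.shape} misaligned with "
                f"contact series {series.areas.shape}"
            )
    events: list[BindingEvent] = []
    for m in range(series.n_molecules):
        mask = series.areas[:, m] > area_threshold
        if amine_distance is not None and not np.isnan(amine_distance[:, m]).all():
            mask = mask & (amine_distance[:, m] < amine_cutoff)
        mask = _fill_gaps(mask, gap_tolerance)
        for start, end in _runs(mask):
            events.append(
                BindingEvent(
                    molecule=m,
                    target=series.target,
                    start_frame=int(start),
                    end_frame=int(end),
                    duration=(end - start + 1) * dt,
                )
            )
    return events


@dataclass(frozen=True)
class ResidenceTimeResult:
    tau_R: float  # ns
    n_events: int
    durations: tuple[float, ...]


def residence_time(events: list[BindingEvent]) -> ResidenceTimeResult:
    """Mean binding-event duration pooled over molecules, tau_R = 1/k_off.

    Equivalent to sum_i t_i n_i / sum_j n_j over the histogram of event
    durations t_i with multiplicities n_i.
    """
    if not events:
        raise ValueError("no binding events: the analyte never bound the target")
    durations = tuple(e.duration for e in events)
    return ResidenceTimeResult(
        tau_R=float(np.mean(durations)),
        n_events=len(durations),
        durations=durations,
    )


# ---------------------------------------------------------------------------
# Surface-distance metrics
# ---------------------------------------------------------------------------

def aryl_distance_series(
    bundle: TrajectoryBundle, cylinder: CylinderModel
) -> np.ndarray:
    """(n_frames, n_molecules) surface distance of each aryl-ring COM."""
    out = np.empty((bundle.n_frames, len(bundle.analytes)))
    for mi, mol in enumerate(bundle.analytes):
        out[:, mi] = surface_distance(bundle.com(mol.aryl_ring), cylinder)
    return out


def amine_distance_series(
    bundle: TrajectoryBundle, cylinder: CylinderModel
) -> np.ndarray:
    """Surface distance of the nearest amine/ammonium COM per molecule.

    Columns for molecules without amine or ammonium groups are NaN, so
    the segmentation criterion is simply not applied to them.
    """
    out = np.full((bundle.n_frames, len(bundle.analytes)), np.nan)
    for mi, mol in enumerate(bundle.analytes):
        groups = mol.groups_of_class(AMINE_CLASSES)
        if not groups:
            continue
        d = np.stack(
            [surface_distance(bundle.com(g.indices), cylinder) for g in groups]
        )
        out[:, mi] = d.min(axis=0)
    return out


def stacking_distance(
    bundle: TrajectoryBundle,
    cylinder: CylinderModel,
    cutoff: float = STACKING_CUTOFF,
):
    """Mean aryl-COM surface distance over stacking frames (< cutoff).

    Returns (per-molecule means, grand mean over molecules with at least
    one qualifying frame).  Molecules that never come within the cutoff
    are NaN (undefined, distinct from 0).
    """
    dists = aryl_distance_series(bundle, cylinder)
    per_mol = np.full(dists.shape[1], np.nan)
    for m in range(dists.shape[1]):
        sel = dists[:, m][dists[:, m] < cutoff]
        if sel.size:
            per_mol[m] = sel.mean()
    pooled = float(np.nanmean(per_mol)) if not np.isnan(per_mol).all() else float("nan")
    return per_mol, pooled


@dataclass
class DistanceDistribution:
    """Normalized histogram of surface distances on [0, r_max]."""

    bin_edges: np.ndarray
    density: np.ndarray  # per-Angstrom probability density
    n_samples: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be >= 0")

    @property
    def empty(self) -> bool:
        return self.n_samples == 0


def polar_distance_distribution(
    bundle: TrajectoryBundle,
    group_selector,
    cylinder: CylinderModel,
    r_max: float = POLAR_RMAX,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DistanceDistribution:
    """Distribution of polar-group COM surface distances within r_max.

    ``group_selector`` is a polar-group name (e.g. ``"OH1"``) or class
    (``hydroxy``/``amine``/``ammonium``/``alkoxide``); samples are pooled
    over all molecules.  Distances are included at <= r_max (closed upper
    bound); the density integrates to 1 unless no frame qualifies.
    """
    samples = []
    for mol in bundle.analytes:
        for g in mol.polar_groups:
            if g.name == group_selector or g.group_class == group_selector:
                d = surface_distance(bundle.com(g.indices), cylinder)
                samples.append(d[(d >= 0) & (d <= r_max)])
    if not samples:
        data = np.empty(0)
    else:
        data = np.concatenate(samples)
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    if data.size == 0:
        return DistanceDistribution(edges, np.zeros(edges.size - 1), 0)
    counts, _ = np.histogram(data, bins=edges)
    density = counts / (data.size * bin_width)
    return DistanceDistribution(edges, density, int(data.size))


def auc_below(dist: DistanceDistribution, x: float = POLAR_AUC_X) -> float:
    """Integral of the distance density over [0, x]."""
    r_max = dist.bin_edges[-1]
    if x < 0 or x > r_max:
        raise ValueError(f"x = {x} outside the distribution support [0, {r_max}]")
    if dist.empty:
        return 0.0
    widths = np.diff(dist.bin_edges)
    covered = np.clip(x - dist.bin_edges[:-1], 0.0, widths)
    return float(np.sum(dist.density * covered))


def class_auc_sum(dists: list[DistanceDistribution], x: float = POLAR_AUC_X) -> float:
    """Sum of per-group AUCs for all groups of one polar class.

    Used when a molecule carries several groups of the same class (e.g.
    two hydroxys): the class value is the sum of the per-group AUCs.
    """
    return float(sum(auc_below(d, x) for d in dists))


# ---------------------------------------------------------------------------
# g(r) and hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class GofR:
    """Radial distribution function normalized to the ideal-gas density.

    Pair-distance counts between set A and set B are divided by
    n_frames * n_A * (shell volume) * rho_B with rho_B the B-set number
    density in the box, so an uncorrelated system gives g(r) = 1.
    """

    r_grid: np.ndarray  # bin centers
    g: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.g) < 0):
            raise ValueError("g(r) must be >= 0")


def radial_distribution(
    bundle: TrajectoryBundle,
    atoms_a,
    atoms_b,
    r_max: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> GofR:
    """g(r) between two atom-index sets with the minimum-image convention."""
    a = np.asarray(atoms_a, dtype=np.int64)
    b = np.asarray(atoms_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both atom sets must be nonempty")
    box = bundle.box
    if not np.isfinite(box).all():
        raise ValueError("g(r) requires a finite periodic box")
    if r_max >= box.min() / 2:
        raise ValueError(
            f"r_max = {r_max} must be < half the smallest box length ({box.min()/2})"
        )
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    shared = np.intersect1d(a, b)
    for f in range(bundle.n_frames):
        A = np.asarray(bundle.coords[f][a], dtype=float)
        B = np.asarray(bundle.coords[f][b], dtype=float)
        delta = A[:, None, :] - B[None, :, :]
        delta -= box * np.round(delta / box)
        dist = np.linalg.norm(delta, axis=-1)
        if shared.size:  # exclude self pairs when the sets overlap
            ia = {v: i for i, v in enumerate(a)}
            for v in shared:
                dist[ia[v], np.nonzero(b == v)[0]] = np.inf
        c, _ = np.histogram(dist.ravel(), bins=edges)
        counts += c
    volume = float(np.prod(box))
    rho_b = b.size / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = bundle.n_frames * a.size * shell * rho_b
    centers = 0.5 * (edges[1:] + edges[:-1])
    return GofR(r_grid=centers, g=counts / norm)


def count_hbonds(
    bundle: TrajectoryBundle,
    donors,
    acceptors,
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
) -> np.ndarray:
    """Per-frame geometric hydrogen-bond counts.

    ``donors`` is a sequence of (D, H) atom-index pairs; ``acceptors`` a
    sequence of acceptor atom indices.  A pair is counted when the D...A
    distance is <= d_cut and the D-H...A angle is within ``angle_cut``
    degrees of linear (i.e. angle >= 180 - angle_cut).
    """
    donors = np.asarray(donors, dtype=np.int64)
    if donors.ndim != 2 or donors.shape[1] != 2:
        raise ValueError(
            "donors must be (D, H) index pairs; donors without an attached "
            "hydrogen cannot form a directional bond"
        )
    acceptors = np.asarray(acceptors, dtype=np.int64)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("need at least one donor pair and one acceptor")
    min_angle = np.deg2rad(180.0 - angle_cut)
    counts = np.zeros(bundle.n_frames, dtype=np.int64)
    for f in range(bundle.n_frames):
        D = bundle.coords[f, donors[:, 0], :]
        H = bundle.coords[f, donors[:, 1], :]
        A = bundle.coords[f, acceptors, :]
        da = A[None, :, :] - D[:, None, :]
        d_da = np.linalg.norm(da, axis=-1)
        hd = D - H
        ha = A[None, :, :] - H[:, None, :]
        # D-H...A angle: angle at H between the H->D and H->A directions
        # (180 degrees when donor, hydrogen and acceptor are collinear)
        num = np.einsum("ij,iaj->ia", hd, ha)
        den = np.linalg.norm(hd, axis=-1)[:, None] * np.linalg.norm(ha, axis=-1)
        cosang = np.clip(num / np.where(den == 0, np.inf, den), -1.0, 1.0)
        dha = np.arccos(cosang)
        counts[f] = int(np.sum((d_da <= d_cut) & (dha >= min_angle)))
    return counts


# ---------------------------------------------------------------------------
# Binding-mode classification
# ---------------------------------------------------------------------------

BINDING_MODES = ("stack_dna", "stack_swcnt", "both", "insertion", "mixed", "unbound")


def classify_binding_mode(
    bundle: TrajectoryBundle,
    molecule: int,
    cylinder: CylinderModel,
    swcnt_series: ContactSeries | None = None,
    dna_series: ContactSeries | None = None,
    contact_threshold: float = EVENT_AREA_THRESHOLD,
    stack_cutoff: float = 5.0,
    dna_shell: float = 6.0,
    predominance: float = 0.5,
    n_sphere_points: int = DEFAULT_N_POINTS,
) -> str:
    """Predominant binding mode of one analyte molecule.

    Frame states: ``stack_swcnt`` when the aryl COM is within
    ``stack_cutoff`` of the surface and nanotube contact dominates;
    ``stack_dna`` when DNA contact dominates with the aryl ring farther
    out; ``insertion`` when the aryl ring sits on the surface under a
    contacted DNA strand while an ammonium group projects beyond the DNA
    shell.  The molecule's mode is the state occupying more than
    ``predominance`` of its bound frames; a stack_dna/stack_swcnt split
    is ``both``, any other split ``mixed``; never bound is ``unbound``.
    The assignment is an operationalization of a by-eye protocol and is
    validated against synthetic ground truth only.
    """
    if swcnt_series is None:
        swcnt_series = contact_series(bundle, "swcnt", n_sphere_points=n_sphere_points)
    if dna_series is None:
        dna_series = contact_series(bundle, "dna", n_sphere_points=n_sphere_points)
    if swcnt_series.n_frames != dna_series.n_frames:
        raise ValueError("swcnt and dna contact series are misaligned")
    mol = bundle.analytes[molecule]
    aryl = surface_distance(bundle.com(mol.aryl_ring), cylinder)
    amm_groups = mol.groups_of_class("ammonium")
    amm = (
        np.stack(
            [surface_distance(bundle.com(g.indices), cylinder) for g in amm_groups]
        ).min(axis=0)
        if amm_groups
        else None
    )
    sc = swcnt_series.areas[:, molecule]
    dc = dna_series.areas[:, molecule]
    bound = (sc > contact_threshold) | (dc > contact_threshold)
    if not bound.any():
        return "unbound"
    occ = {"stack_dna": 0, "stack_swcnt": 0, "insertion": 0}
    for f in np.nonzero(bound)[0]:
        aryl_close = aryl[f] < stack_cutoff
        if aryl_close:
            if dc[f] > contact_threshold and amm is not None and amm[f] > dna_shell:
                occ["insertion"] += 1
            elif sc[f] >= dc[f]:
                occ["stack_swcnt"] += 1
            else:
                occ["stack_dna"] += 1
        else:
            if dc[f] >= sc[f]:
                occ["stack_dna"] += 1
            else:
                occ["stack_swcnt"] += 1
    n_bound = int(bound.sum())
    top = max(occ, key=occ.get)
    if occ[top] / n_bound > predominance:
        return top
    ranked = sorted(occ, key=occ.get, reverse=True)
    if {ranked[0], ranked[1]} == {"stack_dna", "stack_swcnt"} and occ["insertion"] == 0:
        return "both"
    return "mixed"
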