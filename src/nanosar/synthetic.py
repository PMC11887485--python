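"""Synthetic study inputs with known ground truth.

Three generators, all seed-reproducible:

* a cylinder-world trajectory simulator: a rigid (9,4)-nanotube segment
  (40 A) wrapped by three helical ssDNA bead strands, with six analyte
  molecules whose binding/unbinding follows a continuous-time Markov
  chain of known rates.  Bound states place the aryl ring at a surface
  offset ~ N(3.4, 0.2) A; the free state samples the box shell at least
  12 A from the surface.  Positions are sampled conditional on the
  Markov state — these are kinematic stand-ins targeting the estimators,
  not physical MD;
* an emission-spectrum generator producing (F0, F) pairs of Gaussian
  multi-chirality peaks whose designated peaks scale by (1 + dF/F);
* a plate-dataset generator emitting triplicate wells, blanks and the
  dopamine reference in the exact CSV formats the screening module reads.

The default trajectory budget mirrors the study conditions: 10^5 stored
frames at dt = 0.06 ns (6 us total); any budget is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CylinderModel, chirality_radius
from .spectra import EmissionSpectrum
from .trajectory import AnalyteMolecule, PolarGroup, TrajectoryBundle

__all__ = [
    "KineticParams",
    "SyntheticWorld",
    "GroundTruth",
    "build_world",
    "simulate_trajectory",
    "generate_spectrum",
    "generate_screen_dataset",
    "DEFAULT_PEAKS",
    "PEAK94_WINDOW",
]

# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

#: Default emission peaks (nm): the modeled (9,4) species plus a second
#: chirality outside its window.  ``scaled`` marks peaks that respond to
#: the analyte.
DEFAULT_PEAKS = (
    {"center": 1101.0, "width": 12.0, "amplitude": 1.0, "name": "(9,4)", "scaled": True},
    {"center": 1205.0, "width": 14.0, "amplitude": 0.7, "name": "(8,6)", "scaled": True},
)

#: Integration window bracketing the synthetic (9,4) peak, nm.
PEAK94_WINDOW = (1053.0, 1149.0)

DEFAULT_GRID = np.arange(950.0, 1350.0 + 0.5, 1.0)


def generate_spectrum(
    peaks=DEFAULT_PEAKS,
    dff: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    wavelength_grid=DEFAULT_GRID,
) -> tuple[EmissionSpectrum, EmissionSpectrum]:
    """(F0, F) spectrum pair with designated peaks scaled by (1 + dff).

    Each peak is a Gaussian {center, width, amplitude, scaled}; noise is
    i.i.d. Gaussian, drawn independently for the two reads.
    """
    rng = np.random.default_rng(seed)
    wl = np.asarray(wavelength_grid, dtype=float)
    base = np.zeros_like(wl)
    scaled_part = np.zeros_like(wl)
    for p in peaks:
        if p["amplitude"] < 0:
            raise ValueError(f"negative peak amplitude for {p.get('name', p['center'])}")
        if p["width"] <= 0:
            raise ValueError("peak width must be positive")
        if not (wl[0] <= p["center"] <= wl[-1]):
            raise ValueError(f"peak center {p['center']} nm outside the grid")
        g = p["amplitude"] * np.exp(-0.5 * ((wl - p["center"]) / p["width"]) ** 2)
        if p.get("scaled", True):
            scaled_part += g
        else:
            base += g
    f0 = base + scaled_part + rng.normal(0.0, noise_sd, wl.size)
    f = base + (1.0 + dff) * scaled_part + rng.normal(0.0, noise_sd, wl.size)
    return EmissionSpectrum(wl, f0), EmissionSpectrum(wl, f)


def generate_screen_dataset(
    library: pd.DataFrame,
    true_normalized: dict[str, float],
    n_rep: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    da_dff: float = 0.25,
    timepoint: float = 30.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format plate CSV + plate map emulating one screening plate.

    Each compound in ``library`` (must include the DA reference with
    true normalized value 1.0) gets ``n_rep`` sample wells; two blank
    wells are added.  A compound's true dF/F is its true normalized
    response times the dopamine dF/F (default 0.25).  With zero noise
    the screening pipeline recovers the true values exactly.
    """
    ids = list(library["analyte_id"])
    if "DA" not in ids:
        raise ValueError("library must include the DA reference compound")
    if abs(true_normalized.get("DA", 1.0) - 1.0) > 1e-12:
        raise ValueError("DA true normalized value must be 1.0")
    rng = np.random.default_rng(seed)
    rows = []
    map_rows = []
    well_n = 0

    def add_well(analyte, role, dff):
        nonlocal well_n
        well_id = f"W{well_n:03d}"
        well_n += 1
        f0, f = generate_spectrum(
            dff=dff, noise_sd=noise_sd, seed=int(rng.integers(2**31))
        )
        for t, spec in ((0.0, f0), (timepoint, f)):
            for wl, it in zip(spec.wavelength, spec.intensity):
                rows.append((well_id, t, wl, it))
        map_rows.append((well_id, analyte, role))

    for analyte in ids:
        if analyte not in true_normalized:
            raise ValueError(f"no true normalized value for {analyte!r}")
        role = "reference" if analyte == "DA" else "sample"
        for _ in range(n_rep):
            add_well(analyte, role, true_normalized[analyte] * da_dff)
    for _ in range(2):
        well_id = f"W{well_n:03d}"
        well_n += 1
        wl = DEFAULT_GRID
        for t in (0.0, timepoint):
            blank = rng.normal(0.0, noise_sd, wl.size)
            for w, it in zip(wl, blank):
                rows.append((well_id, t, w, it))
        map_rows.append((well_id, "blank", "blank"))

    plate = pd.DataFrame(
        rows, columns=["well_id", "timepoint_min", "wavelength_nm", "intensity"]
    )
    pmap = pd.DataFrame(map_rows, columns=["well_id", "analyte_id", "role"])
    return plate, pmap


# ---------------------------------------------------------------------------
# Cylinder world
# ---------------------------------------------------------------------------

STATE_NAMES = ("free", "stack_dna", "stack_swcnt", "inserted")


@dataclass
class KineticParams:
    """Continuous-time Markov kinetics for the binding simulator.

    ``rates[(a, b)]`` is the a->b transition rate in 1/ns over the state
    subset actually used; the discrete chain uses p_ab = rate * dt, which
    requires dt * (fastest total exit rate) <= 0.1.
    """

    states: tuple[str, ...]
    rates: dict[tuple[str, str], float]
    dt: float = 0.06  # ns between stored frames
    n_frames: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.states:
            if s not in STATE_NAMES:
                raise ValueError(f"unknown state {s!r}")
        for (a, b), r in self.rates.items():
            if a not in self.states or b not in self.states:
                raise ValueError(f"rate {a}->{b} references unknown state")
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def generator_matrix(self) -> np.ndarray:
        """Q matrix (1/ns) over ``states``; rows sum to zero."""
        n = len(self.states)
        Q = np.zeros((n, n))
        idx = {s: i for i, s in enumerate(self.states)}
        for (a, b), r in self.rates.items():
            Q[idx[a], idx[b]] = r
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary_distribution(self) -> np.ndarray:
        Q = self.generator_matrix()
        n = Q.shape[0]
        A = np.vstack([Q.T, np.ones(n)])
        b = np.concatenate([np.zeros(n), [1.0]])
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return pi

    def mean_dwell(self, state: str) -> float:
        """Expected dwell time (ns) in a state = 1/(total exit rate)."""
        Q = self.generator_matrix()
        i = self.states.index(state)
        exit_rate = -Q[i, i]
        return np.inf if exit_rate == 0 else 1.0 / exit_rate

    @classmethod
    def two_state(
        cls, k_on: float, k_off: float, dt: float = 0.06,
        n_frames: int = 100_000, seed: int = 0, bound_state: str = "stack_swcnt",
    ) -> "KineticParams":
        return cls(
            states=("free", bound_state),
            rates={("free", bound_state): k_on, (bound_state, "free"): k_off},
            dt=dt, n_frames=n_frames, seed=seed,
        )


@dataclass
class SyntheticWorld:
    """Static scaffold geometry plus analyte templates."""

    cylinder: CylinderModel
    length: float
    swcnt_coords: np.ndarray
    dna_coords: np.ndarray  # (n_dna, 3)
    dna_tags: list[str]
    dna_strand_phase: np.ndarray  # azimuth (rad) of each strand at z=0
    dna_pitch: float  # A of axial rise per full helix turn
    dna_shell_offset: float  # A, radial offset of DNA beads above the wall
    box: np.ndarray
    n_molecules: int
    template: dict  # analyte pseudo-atom template
    seed: int

    @property
    def n_scaffold_atoms(self) -> int:
        return self.swcnt_coords.shape[0] + self.dna_coords.shape[0]


def _analyte_template(charged: bool = True) -> dict:
    """Catecholamine-like pseudo-molecule in its local frame.

    Aryl ring: hexagon of 6 C (radius 1.40 A) in the xy-plane.  Two
    vicinal hydroxy oxygens extend outward from adjacent ring carbons;
    an ethylamine-like nitrogen sits across the ring, lifted out of the
    ring plane so that, when the ring stacks flat on the surface, the
    polar group projects away from it.
    """
    ring_angles = np.deg2rad(np.arange(0, 360, 60))
    ring = np.column_stack(
        [1.40 * np.cos(ring_angles), 1.40 * np.sin(ring_angles), np.zeros(6)]
    )
    oh1 = 2.76 * np.array([np.cos(ring_angles[0]), np.sin(ring_angles[0]), 0.0])
    oh2 = 2.76 * np.array([np.cos(ring_angles[1]), np.sin(ring_angles[1]), 0.0])
    nitrogen = np.array(
        [2.5 * np.cos(ring_angles[3]), 2.5 * np.sin(ring_angles[3]), 1.8]
    )
    coords = np.vstack([ring, oh1, oh2, nitrogen])
    return {
        "coords": coords,
        "elements": ["C"] * 6 + ["O", "O", "N"],
        "aryl_ring": list(range(6)),
        "polar_groups": [
            {"name": "OH1", "indices": [6], "class": "hydroxy"},
            {"name": "OH2", "indices": [7], "class": "hydroxy"},
            {
                "name": "NH3" if charged else "NH2",
                "indices": [8],
                "class": "ammonium" if charged else "amine",
            },
        ],
    }


def build_world(
    chirality: tuple[int, int] = (9, 4),
    length: float = 40.0,
    seed: int = 0,
    n_molecules: int = 6,
    n_dna_strands: int = 3,
    charged_analyte: bool = True,
    box_margin: float = 28.0,
) -> SyntheticWorld:
    """Deterministic scaffold: nanotube lattice + helical DNA bead strands.

    Nanotube atoms sit on rings of the cylinder of the chirality's
    closed-form radius, spaced to approximate the graphene areal density;
    each DNA strand is a helix of backbone pseudo-atoms cycling through
    the tags P, O1P, O2P, O3', O4', O5'.
    """
    n, m = chirality
    radius = chirality_radius(n, m)  # raises on nonphysical chirality
    # rings every half row-spacing of graphene, alternating offset
    dz = 1.23
    n_rings = int(round(length / dz)) + 1
    circumference = 2 * np.pi * radius
    per_ring = max(8, int(round(circumference / 1.42)))
    zs = np.arange(n_rings) * dz - length / 2
    sw = []
    for ri, z in enumerate(zs):
        phase = (ri % 2) * np.pi / per_ring
        ang = 2 * np.pi * np.arange(per_ring) / per_ring + phase
        sw.append(
            np.column_stack(
                [radius * np.cos(ang), radius * np.sin(ang), np.full(per_ring, z)]
            )
        )
    swcnt_coords = np.vstack(sw)

    shell = 3.3  # DNA backbone beads ride this far above the wall
    # gentle wrap: strands stay near-axial so inter-strand wall lanes exist
    pitch = length * 8.0
    bead_spacing = 1.8  # arc spacing of backbone pseudo-atoms
    tags = ["P", "O1P", "O2P", "O3'", "O4'", "O5'"]
    dna_coords, dna_tags = [], []
    strand_phase = 2 * np.pi * np.arange(n_dna_strands) / n_dna_strands
    helix_r = radius + shell
    arc = np.hypot(length, 2 * np.pi * helix_r * length / pitch)
    n_beads = max(int(arc / bead_spacing), 10)
    ts = np.linspace(-length / 2, length / 2, n_beads)
    for phase in strand_phase:
        ang = phase + 2 * np.pi * ts / pitch
        for i, (z, a) in enumerate(zip(ts, ang)):
            dna_coords.append([helix_r * np.cos(a), helix_r * np.sin(a), z])
            dna_tags.append(tags[i % len(tags)])
    dna_coords = np.asarray(dna_coords)

    box = np.array(
        [2 * (radius + box_margin), 2 * (radius + box_margin), length + 20.0]
    )
    return SyntheticWorld(
        cylinder=CylinderModel(
            axis_point=np.zeros(3), axis_dir=np.array([0.0, 0.0, 1.0]), radius=radius
        ),
        length=length,
        swcnt_coords=swcnt_coords,
        dna_coords=dna_coords,
        dna_tags=dna_tags,
        dna_strand_phase=strand_phase,
        dna_pitch=pitch,
        dna_shell_offset=shell,
        box=box,
        n_molecules=n_molecules,
        template=_analyte_template(charged_analyte),
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the simulator actually did, for estimator validation."""

    states: tuple[str, ...]
    state_sequence: np.ndarray  # (n_molecules, n_frames) int8
    occupancy: np.ndarray  # stationary distribution over states
    mean_dwell_ns: dict[str, float]
    stacking_offset_mean: float
    stacking_offset_sd: float
    dt: float

    def bound_fraction_true(self) -> float:
        """Stationary probability of any bound (non-free) state, percent."""
        free = self.states.index("free")
        return float(100.0 * (1.0 - self.occupancy[free]))

    def residence_true_ns(self) -> float:
        """Expected bound-episode duration (ns) for a single bound state."""
        bound = [s for s in self.states if s != "free"]
        if len(bound) == 1:
            return self.mean_dwell_ns[bound[0]]
        raise ValueError("residence_true_ns is defined for two-state kinetics only")


# state-conditional placement offsets (A above the wall)
_ARYL_OFFSET_MEAN = 3.4
_ARYL_OFFSET_SD = 0.2
_FREE_MIN_DISTANCE = 12.0
_DNA_STACK_EXTRA = 3.2  # aryl sits this far above the DNA shell when on DNA
_INSERT_POLAR_OFFSET = 7.5  # ammonium projects beyond the DNA shell


def _rotation_to_surface_normal(normal: np.ndarray) -> np.ndarray:
    """Rotation taking the template +z axis onto the surface normal."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, normal)
    c = float(np.dot(z, normal))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def simulate_trajectory(
    world: SyntheticWorld,
    kinetics: KineticParams,
) -> tuple[TrajectoryBundle, GroundTruth]:
    """Markov-state trajectory of n_molecules analytes around the scaffold.

    Each molecule independently follows the discrete-time embedding of
    the kinetics' continuous-time chain.  Positions are drawn
    conditional on the state; an anchor (azimuth, axial position) is
    redrawn on each state entry and jittered within an event, so bound
    events are spatially coherent.
    """
    Q = kinetics.generator_matrix()
    exit_rates = -np.diag(Q)
    if kinetics.dt * exit_rates.max() > 0.1:
        raise ValueError(
            f"dt = {kinetics.dt} ns too coarse for the fastest rate "
            f"({exit_rates.max():.3g}/ns): dt*rate must be <= 0.1"
        )
    rng = np.random.default_rng(kinetics.seed)
    n_frames, n_mol = kinetics.n_frames, world.n_molecules
    states = kinetics.states
    n_states = len(states)
    P = np.eye(n_states) + Q * kinetics.dt

    # state sequences
    seq = np.empty((n_mol, n_frames), dtype=np.int8)
    pi = kinetics.stationary_distribution()
    for mi in range(n_mol):
        s = rng.choice(n_states, p=np.clip(pi, 0, None) / np.clip(pi, 0, None).sum())
        for f in range(n_frames):
            seq[mi, f] = s
            s = rng.choice(n_states, p=P[s])

    tpl = world.template
    tpl_coords = tpl["coords"]
    n_tpl = tpl_coords.shape[0]
    n_scaffold = world.n_scaffold_atoms
    n_atoms = n_scaffold + n_mol * n_tpl
    coords = np.empty((n_frames, n_atoms, 3), dtype=np.float32)
    coords[:, : world.swcnt_coords.shape[0], :] = world.swcnt_coords
    coords[:, world.swcnt_coords.shape[0] : n_scaffold, :] = world.dna_coords

    radius = world.cylinder.radius
    half_len = world.length / 2
    free_idx = states.index("free") if "free" in states else -1

    for mi in range(n_mol):
        anchor = None  # (azimuth, z)
        prev_state = -1
        base = n_scaffold + mi * n_tpl
        for f in range(n_frames):
            s = seq[mi, f]
            name = states[s]
            if name == "free":
                # uniform in the box shell >= 12 A from the wall
                while True:
                    pos = (rng.random(3) - 0.5) * (world.box - 4.0)
                    if np.hypot(pos[0], pos[1]) - radius >= _FREE_MIN_DISTANCE:
                        break
                Rm = _rotation_to_surface_normal(_random_unit(rng))
                coords[f, base : base + n_tpl, :] = tpl_coords @ Rm.T + pos
                anchor = None
                prev_state = s
                continue
            if s != prev_state or anchor is None:
                z = rng.uniform(-half_len * 0.8, half_len * 0.8)
                if name == "stack_swcnt":
                    # pick an azimuth well away from every DNA strand
                    az = _azimuth_between_strands(world, z, rng)
                else:
                    az = _azimuth_on_strand(world, z, rng)
                anchor = [az, z]
            else:
                anchor[0] += rng.normal(0.0, 0.02)
                anchor[1] = np.clip(
                    anchor[1] + rng.normal(0.0, 0.15), -half_len * 0.9, half_len * 0.9
                )
            az, z = anchor
            normal = np.array([np.cos(az), np.sin(az), 0.0])
            if name == "stack_swcnt" or name == "inserted":
                offset = rng.normal(_ARYL_OFFSET_MEAN, _ARYL_OFFSET_SD)
            else:  # stack_dna
                offset = world.dna_shell_offset + _DNA_STACK_EXTRA + rng.normal(
                    0.0, _ARYL_OFFSET_SD
                )
            ring_com = (radius + offset) * normal + np.array([0.0, 0.0, z])
            Rm = _rotation_to_surface_normal(normal)
            spin = rng.uniform(0, 2 * np.pi)
            cs, sn = np.cos(spin), np.sin(spin)
            Sz = np.array([[cs, -sn, 0.0], [sn, cs, 0.0], [0.0, 0.0, 1.0]])
            placed = tpl_coords @ Sz.T @ Rm.T
            placed -= placed[tpl["aryl_ring"]].mean(axis=0)
            placed += ring_com
            if name == "inserted":
                # push the ammonium pseudo-atom radially beyond the DNA shell
                for g in tpl["polar_groups"]:
                    if g["class"] == "ammonium":
                        for gi in g["indices"]:
                            placed[gi] = (radius + _INSERT_POLAR_OFFSET) * normal + [
                                0.0,
                                0.0,
                                z + 1.0,
                            ]
            coords[f, base : base + n_tpl, :] = placed
            prev_state = s

    sw_n = world.swcnt_coords.shape[0]
    backbone: dict[str, list[int]] = {}
    for i, tag in enumerate(world.dna_tags):
        backbone.setdefault(tag, []).append(sw_n + i)
    analytes = [
        AnalyteMolecule(
            indices=np.arange(n_scaffold + mi * n_tpl, n_scaffold + (mi + 1) * n_tpl),
            aryl_ring=np.asarray(tpl["aryl_ring"]) + n_scaffold + mi * n_tpl,
            polar_groups=[
                PolarGroup(
                    name=g["name"],
                    indices=np.asarray(g["indices"]) + n_scaffold + mi * n_tpl,
                    group_class=g["class"],
                )
                for g in tpl["polar_groups"]
            ],
        )
        for mi in range(n_mol)
    ]
    bundle = TrajectoryBundle(
        coords=coords,
        elements=np.array(
            ["C"] * sw_n
            + ["P" if t == "P" else "O" for t in world.dna_tags]
            + list(tpl["elements"]) * n_mol
        ),
        swcnt=np.arange(sw_n),
        dna=np.arange(sw_n, n_scaffold),
        analytes=analytes,
        box=world.box,
        dt=kinetics.dt,
        dna_backbone={t: np.asarray(v) for t, v in backbone.items()},
    )
    truth = GroundTruth(
        states=states,
        state_sequence=seq,
        occupancy=pi,
        mean_dwell_ns={s: kinetics.mean_dwell(s) for s in states},
        stacking_offset_mean=_ARYL_OFFSET_MEAN,
        stacking_offset_sd=_ARYL_OFFSET_SD,
        dt=kinetics.dt,
    )
    return bundle, truth


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _strand_azimuth_at(world: SyntheticWorld, phase: float, z: float) -> float:
    return phase + 2 * np.pi * z / world.dna_pitch


def _azimuth_on_strand(world: SyntheticWorld, z: float, rng) -> float:
    phase = rng.choice(world.dna_strand_phase)
    return _strand_azimuth_at(world, phase, z) + rng.normal(0.0, 0.05)


def _azimuth_between_strands(world: SyntheticWorld, z: float, rng) -> float:
    strand_az = np.array(
        [_strand_azimuth_at(world, p, z) for p in world.dna_strand_phase]
    )
    # midpoint between two adjacent strands, i.e. maximally exposed wall
    k = rng.integers(len(strand_az))
    gap = 2 * np.pi / len(strand_az)
    return strand_az[k] + gap / 2 + rng.normal(0.0, 0.08)
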