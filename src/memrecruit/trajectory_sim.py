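"""Synthetic protein/membrane/ion trajectories with planted contact statistics.

Emulates, at the coarsest useful resolution, a protein dimer hovering above a
planar bilayer patch of two lipid species (anionic PS, zwitterionic PC, 30/70
by default): lipids contribute one headgroup and one acyl particle each on a
jittered planar grid, each protein residue is a single particle that is placed
within contact range of a chosen lipid headgroup with its planted per-frame
contact probability, and cations sit in the solvent except during planted
coordination events, when the specified ion is held within coordination range
of its partner PS headgroup.  Contact statistics depend only on distances and
labels, so this is sufficient to exercise every analysis code path against
exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PlantedEvent",
    "TrajectorySimConfig",
    "Trajectory",
    "TrajGroundTruth",
    "generate_trajectory",
]

HEAD_Z = 2.0  # nm, bilayer headgroup plane
ACYL_Z = 1.0  # nm, acyl proxy below the headgroups
ION_Z_RANGE = (6.0, 8.0)  # solvent band, safely beyond any reporting distance
EVENT_DISTANCE = 0.30  # nm, ion-headgroup separation during a planted event


class TrajectoryConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedEvent:
    """A planted ion-lipid coordination interval (times in ns)."""

    ion_index: int
    lipid_index: int
    t_start: float
    duration: float


@dataclass
class TrajectorySimConfig:
    """Parameters of a synthetic trajectory.

    ``contact_prob`` is the per-sampled-frame probability that a residue sits
    within contact range of a lipid (scalar broadcast or one value per
    residue).  ``contact_cutoff`` must match the cutoff the analysis will use:
    in-contact placements land in [0.25, cutoff-0.02] nm and out-of-contact
    placements in [cutoff+0.3, 3] nm, keeping every frame unambiguous at the
    boundary.  ``ps_contact_prob`` optionally biases which species a contact
    touches (default: uniform over lipids, i.e. the PS fraction).
    """

    n_frames: int = 500
    dt: float = 0.1  # ns per frame
    box: tuple[float, float, float] = (14.0, 14.0, 10.0)  # nm
    periodic: bool = True
    n_residues: int = 20
    contact_prob: Union[float, Sequence[float]] = 0.3
    lipid_grid: tuple[int, int] = (8, 8)
    ps_fraction: float = 0.30
    n_ions: int = 2
    planted_events: tuple[PlantedEvent, ...] = ()
    contact_cutoff: float = 0.4  # nm
    ps_contact_prob: Optional[float] = None
    seed: int = 0

    def contact_probs(self) -> np.ndarray:
        p = np.broadcast_to(np.asarray(self.contact_prob, dtype=float),
                            (self.n_residues,)).copy()
        if ((p < 0) | (p > 1)).any():
            raise TrajectoryConfigError("contact_prob values must lie in [0, 1]")
        return p

    def validate(self) -> None:
        if not (0.0 <= self.ps_fraction <= 1.0):
            raise TrajectoryConfigError("ps_fraction must be in [0, 1]")
        if self.n_frames < 1 or self.dt <= 0:
            raise TrajectoryConfigError("need n_frames >= 1 and dt > 0")
        if any(L <= 0 for L in self.box):
            raise TrajectoryConfigError("box edges must be positive")
        self.contact_probs()
        total = self.n_frames * self.dt
        n_lipids = self.lipid_grid[0] * self.lipid_grid[1]
        spans: dict[int, list[tuple[int, int]]] = {}
        for ev in self.planted_events:
            if not (0 <= ev.ion_index < self.n_ions):
                raise TrajectoryConfigError(f"event ion index {ev.ion_index} out of range")
            if not (0 <= ev.lipid_index < n_lipids):
                raise TrajectoryConfigError(f"event lipid index {ev.lipid_index} out of range")
            if ev.t_start < 0 or ev.t_start + ev.duration > total + 1e-9:
                raise TrajectoryConfigError(
                    f"event [{ev.t_start}, {ev.t_start + ev.duration}] ns lies outside "
                    f"the trajectory span [0, {total}] ns")
            f0 = int(round(ev.t_start / self.dt))
            f1 = int(round((ev.t_start + ev.duration) / self.dt))
            for a, b in spans.get(ev.ion_index, []):
                if f0 < b and a < f1:
                    raise TrajectoryConfigError(
                        f"overlapping planted events for ion {ev.ion_index}")
            spans.setdefault(ev.ion_index, []).append((f0, f1))


@dataclass
class Trajectory:
    """Time-stamped particle coordinates plus the particle annotation table.

    ``particles`` has columns particle_id, kind (protein|lipid|ion),
    residue_index (protein, else -1), lipid_index (lipid, else -1),
    lipid_species (PS|PC|''), atom_class (headgroup|acyl|n/a).
    ``coords`` has shape (n_frames, n_particles, 3) in nm; positions are
    wrapped into the box when ``periodic``.
    """

    times: np.ndarray
    coords: np.ndarray
    particles: pd.DataFrame
    box: tuple[float, float, float]
    periodic: bool

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    @property
    def n_residues(self) -> int:
        prot = self.particles[self.particles.kind == "protein"]
        return int(prot.residue_index.nunique())


@dataclass
class TrajGroundTruth:
    contact_prob: np.ndarray  # per residue
    events: list[dict]  # ion_index, lipid_index, start_frame, n_frames, species
    ps_contact_share: float  # expected fraction of contact frames touching PS


def _wrap(x: np.ndarray, box, periodic: bool) -> np.ndarray:
    if not periodic:
        return x
    return np.mod(x, np.asarray(box, dtype=float))


def generate_trajectory(config: TrajectorySimConfig):
    """Build one trajectory and its exact ground truth.

    Returns ``(Trajectory, TrajGroundTruth)``.  Identical configs (including
    seed) produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nx, ny = config.lipid_grid
    n_lipids = nx * ny
    Lx, Ly, Lz = config.box
    probs = config.contact_probs()

    # --- lipid lattice (static): headgroup + acyl particle per lipid
    sx, sy = Lx / nx, Ly / ny
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    head_xy = np.column_stack([(ix.ravel() + 0.5) * sx, (iy.ravel() + 0.5) * sy])
    head_xy = head_xy + rng.uniform(-0.1, 0.1, size=head_xy.shape)
    head = np.column_stack([head_xy, np.full(n_lipids, HEAD_Z)])
    acyl = head.copy()
    acyl[:, 2] = ACYL_Z

    # --- species labels: exactly round(ps_fraction * n_lipids) PS lipids,
    # with planted-event partners forced into the PS set
    n_ps = int(round(config.ps_fraction * n_lipids))
    perm = rng.permutation(n_lipids)
    ps_set = set(perm[:n_ps].tolist())
    event_partners = {ev.lipid_index for ev in config.planted_events}
    if len(event_partners) > n_ps:
        raise TrajectoryConfigError("more distinct event partner lipids than PS lipids")
    for li in sorted(event_partners - ps_set):
        swap = next(j for j in perm[:n_ps] if j not in event_partners)
        ps_set.discard(int(swap))
        ps_set.add(li)
    species = np.array(["PS" if i in ps_set else "PC" for i in range(n_lipids)])
    ps_indices = np.flatnonzero(species == "PS")
    pc_indices = np.flatnonzero(species == "PC")

    # --- particle table: protein residues, lipid (head, acyl) pairs, ions
    rows = []
    pid = 0
    for ri in range(config.n_residues):
        rows.append((pid, "protein", ri, -1, "", "n/a")); pid += 1
    head_pid = np.empty(n_lipids, dtype=int)
    acyl_pid = np.empty(n_lipids, dtype=int)
    for li in range(n_lipids):
        head_pid[li] = pid
        rows.append((pid, "lipid", -1, li, species[li], "headgroup")); pid += 1
        acyl_pid[li] = pid
        rows.append((pid, "lipid", -1, li, species[li], "acyl")); pid += 1
    ion_pid = np.empty(config.n_ions, dtype=int)
    for ii in range(config.n_ions):
        ion_pid[ii] = pid
        rows.append((pid, "ion", -1, -1, "", "n/a")); pid += 1
    particles = pd.DataFrame(
        rows, columns=["particle_id", "kind", "residue_index", "lipid_index",
                       "lipid_species", "atom_class"])
    n_particles = pid

    # --- event frame spans
    event_frames = np.full((config.n_ions, config.n_frames), -1, dtype=int)
    truth_events = []
    for ev in config.planted_events:
        f0 = int(round(ev.t_start / config.dt))
        f1 = int(round((ev.t_start + ev.duration) / config.dt))
        f1 = min(f1, config.n_frames)
        event_frames[ev.ion_index, f0:f1] = ev.lipid_index
        truth_events.append(dict(ion_index=ev.ion_index, lipid_index=ev.lipid_index,
                                 start_frame=f0, n_frames=f1 - f0,
                                 species=str(species[ev.lipid_index])))

    # --- per-frame coordinates
    cutoff = config.contact_cutoff
    coords = np.empty((config.n_frames, n_particles, 3), dtype=float)
    # static lipid positions, interleaved (head, acyl) matching the table
    lipid_coords = np.empty((n_lipids * 2, 3))
    lipid_coords[0::2] = head
    lipid_coords[1::2] = acyl

    ion_default = np.column_stack([
        rng.uniform(0, Lx, size=config.n_ions),
        rng.uniform(0, Ly, size=config.n_ions),
        rng.uniform(*ION_Z_RANGE, size=config.n_ions),
    ])

    for f in range(config.n_frames):
        frame = np.empty((n_particles, 3))
        # residues
        in_contact = rng.random(config.n_residues) < probs
        for ri in range(config.n_residues):
            if in_contact[ri]:
                if config.ps_contact_prob is not None and len(ps_indices) and len(pc_indices):
                    pool = ps_indices if rng.random() < config.ps_contact_prob else pc_indices
                    li = int(pool[rng.integers(len(pool))])
                else:
                    li = int(rng.integers(n_lipids))
                d = rng.uniform(0.25, cutoff - 0.02)
            else:
                li = int(rng.integers(n_lipids))
                d = rng.uniform(max(cutoff + 0.3, 1.02), 3.0)
            frame[ri] = head[li] + np.array([0.0, 0.0, d])
        # lipids (static)
        frame[config.n_residues:config.n_residues + n_lipids * 2] = lipid_coords
        # ions: re-drawn in solvent each frame unless inside a planted event
        ion_xy = np.column_stack([
            rng.uniform(0, Lx, size=config.n_ions),
            rng.uniform(0, Ly, size=config.n_ions),
            rng.uniform(*ION_Z_RANGE, size=config.n_ions),
        ])
        for ii in range(config.n_ions):
            partner = event_frames[ii, f]
            if partner >= 0:
                frame[ion_pid[ii]] = head[partner] + np.array([0.0, 0.0, EVENT_DISTANCE])
            else:
                frame[ion_pid[ii]] = ion_xy[ii]
        coords[f] = _wrap(frame, config.box, config.periodic)

    times = np.arange(config.n_frames, dtype=float) * config.dt
    traj = Trajectory(times=times, coords=coords, particles=particles,
                      box=config.box, periodic=config.periodic)
    ps_share = (config.ps_contact_prob if config.ps_contact_prob is not None
                else len(ps_indices) / n_lipids)
    truth = TrajGroundTruth(contact_prob=probs, events=truth_events,
                            ps_contact_share=float(ps_share))
    return traj, truth
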