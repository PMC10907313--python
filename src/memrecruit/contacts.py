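"""Membrane-contact statistics on trajectories.

Implements the trajectory observables of the recruitment study: per-residue
lipid contact frequencies over a defined analysis window (percent of analysed
frames, sampled at a fixed stride), decomposed by lipid species (PS/PC) and
atom class (headgroup/acyl); the number of residues in membrane contact over
time with replicate aggregation; ion-lipid coordination event segmentation
under a strict distance cutoff; and one-tailed group comparison of
time-averaged contact levels.

All distances use the minimum-image convention when the trajectory is
periodic.  "Within cutoff" always means strictly less than the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .recruit_stats import ComparisonResult, compare_conditions
from .trajectory_sim import Trajectory

__all__ = [
    "ContactConfig",
    "ContactProfile",
    "ContactTimeSeries",
    "CoordinationEvent",
    "IonDistanceSummary",
    "pair_distance",
    "residue_contact_frequency",
    "compute_contact_profile",
    "residues_in_contact_series",
    "detect_coordination_events",
    "min_ion_lipid_distance",
    "compare_contact_levels",
]


class EmptySelectionError(ValueError):
    pass


class IncompatibleReplicatesError(ValueError):
    pass


@dataclass(frozen=True)
class ContactConfig:
    """Cutoffs and windowing of the contact analyses.

    All distances in nm, times in ns.  ``analysis_window`` is the trailing
    fraction of each trajectory that is analysed (0.5 = the final half);
    ``sample_stride`` is the sampling interval within that window.
    ``contact_cutoff`` governs protein-lipid contacts, ``coordination_cutoff``
    ion-lipid coordination, and ``encage_report_distance`` the encaged-ion
    reporting distance.  Events shorter than ``short_event_max`` are classed
    'short', all others 'persistent'.  ``gap_bridge`` frames above the cutoff
    may be bridged inside one event (default 0: any excursion ends the event).
    """

    contact_cutoff: float = 0.4
    coordination_cutoff: float = 0.35
    encage_report_distance: float = 0.5
    sample_stride: float = 2.0
    analysis_window: float = 0.5
    short_event_max: float = 2.0
    gap_bridge: int = 0

    def __post_init__(self):
        for name in ("contact_cutoff", "coordination_cutoff", "encage_report_distance",
                     "sample_stride", "short_event_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.analysis_window <= 1.0):
            raise ValueError("analysis_window must lie in (0, 1]")


@dataclass
class ContactProfile:
    """Per-residue contact frequencies (percent of analysed frames)."""

    residue_index: np.ndarray
    frequency: np.ndarray  # any lipid
    by_species: dict[str, np.ndarray] = field(default_factory=dict)
    by_class: dict[str, np.ndarray] = field(default_factory=dict)
    n_frames_analyzed: int = 0


@dataclass
class ContactTimeSeries:
    """Residues-in-contact counts over time, aggregated across replicates."""

    times: np.ndarray
    per_replicate: np.ndarray  # (n_replicates, n_frames)
    mean: np.ndarray
    se: Optional[np.ndarray]  # None for a single replicate
    replicate_window_means: np.ndarray  # time-average per replicate over the window
    window_mean: float
    window_sd: Optional[float]


@dataclass
class CoordinationEvent:
    """A contiguous run of frames with an ion within the coordination cutoff of
    one lipid headgroup."""

    ion_id: int
    lipid_id: int
    lipid_species: str
    t_start: float
    t_end: float
    duration: float
    event_class: str  # 'short' | 'persistent'


@dataclass
class IonDistanceSummary:
    ion_ids: np.ndarray
    distances: np.ndarray  # (n_ions, n_frames), nearest-lipid distance per frame
    fraction_beyond: np.ndarray  # per ion, fraction of frames beyond the report distance


# ---------------------------------------------------------------------------
# distances


def pair_distance(p, q, box=None, periodic: bool = False) -> float:
    """Euclidean distance, minimum-image per axis when periodic."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("coordinates must be finite")
    d = p - q
    if periodic:
        if box is None or any(L <= 0 for L in box):
            raise ValueError("periodic distance requires a box with positive edges")
        L = np.asarray(box, dtype=float)
        d = d - L * np.round(d / L)
    return float(np.linalg.norm(d))


def _displacement(a: np.ndarray, b: np.ndarray, box, periodic: bool) -> np.ndarray:
    """Pairwise min-image distance matrix between coordinate sets a (n,3) and b (m,3)."""
    d = a[:, None, :] - b[None, :, :]
    if periodic:
        L = np.asarray(box, dtype=float)
        d = d - L * np.round(d / L)
    return np.sqrt((d**2).sum(axis=-1))


def _contact_pairs_bruteforce(prot, lip, cutoff, box, periodic):
    """Boolean (n_prot, n_lip): strictly-within-cutoff pairs by all-pairs min image."""
    return _displacement(prot, lip, box, periodic) < cutoff


def _contact_any_fast(prot, lip, cutoff, box, periodic):
    """Per protein particle: any lipid strictly within cutoff (cKDTree fast path).

    The tree query is inclusive at the radius, so candidates are refiltered
    with the exact strict-< min-image distance; results equal brute force.
    """
    if periodic:
        L = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(lip, L), boxsize=L)
        query = np.mod(prot, L)
    else:
        tree = cKDTree(lip)
        query = prot
    out = np.zeros(len(prot), dtype=bool)
    neighbors = tree.query_ball_point(query, cutoff)
    for i, idx in enumerate(neighbors):
        if not idx:
            continue
        d = _displacement(prot[i:i + 1], lip[np.asarray(idx)], box, periodic)
        out[i] = bool((d < cutoff).any())
    return out


# ---------------------------------------------------------------------------
# windowing


def analysis_frames(times: np.ndarray, cfg: ContactConfig) -> np.ndarray:
    """Indices of analysed frames: trailing window, sampled every stride.

    The window opens at ``t_end - analysis_window * duration`` and the first
    frame at or after that time is included; thereafter every
    ``round(sample_stride / dt)``-th frame, endpoint included, giving
    ``floor(window_duration / stride) + 1`` frames on a regular grid.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 1:
        raise ValueError("empty trajectory")
    if len(times) == 1:
        return np.array([0])
    dt = float(times[1] - times[0])
    duration = float(times[-1] - times[0])
    window = cfg.analysis_window * duration
    if cfg.sample_stride > window:
        raise ValueError(
            f"sample_stride={cfg.sample_stride} ns exceeds the analysis window "
            f"({window:.6g} ns)")
    start_time = times[-1] - window
    start = int(np.searchsorted(times, start_time - 1e-9))
    stride = max(1, int(round(cfg.sample_stride / dt)))
    return np.arange(start, len(times), stride)


def _selection(traj: Trajectory, species=None, atom_class=None):
    part = traj.particles
    mask = (part.kind == "lipid").to_numpy()
    if species is not None:
        mask &= (part.lipid_species == species).to_numpy()
    if atom_class is not None:
        mask &= (part.atom_class == atom_class).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(
            f"no lipid particles match species={species!r}, atom_class={atom_class!r}")
    return idx


def _protein_layout(traj: Trajectory):
    part = traj.particles
    prot = part[part.kind == "protein"]
    residues = np.sort(prot.residue_index.unique())
    groups = [prot.index[prot.residue_index == r].to_numpy() for r in residues]
    return residues, groups


# ---------------------------------------------------------------------------
# contact frequency


def residue_contact_frequency(traj: Trajectory, cfg: ContactConfig | None = None,
                              species: Optional[str] = None,
                              atom_class: Optional[str] = None,
                              method: str = "fast"):
    """Percent of analysed frames in which each residue touches a selected lipid.

    A residue is in contact in a frame iff any of its particles lies strictly
    within ``contact_cutoff`` of any selected lipid particle.  Returns
    ``(frequencies, n_frames_analyzed)`` with frequencies in percent, ordered
    by residue index.  ``method`` is 'fast' (cell-tree) or 'bruteforce'
    (all-pairs min image); both give identical results.
    """
    cfg = cfg or ContactConfig()
    frames = analysis_frames(traj.times, cfg)
    lip_idx = _selection(traj, species, atom_class)
    residues, groups = _protein_layout(traj)
    prot_idx = np.concatenate(groups)
    # map particle rows -> residue slot
    slot = np.empty(len(prot_idx), dtype=int)
    pos = 0
    for si, g in enumerate(groups):
        slot[pos:pos + len(g)] = si
        pos += len(g)

    counts = np.zeros(len(residues), dtype=int)
    for f in frames:
        prot = traj.coords[f, prot_idx]
        lip = traj.coords[f, lip_idx]
        if method == "bruteforce":
            within = _contact_pairs_bruteforce(prot, lip, cfg.contact_cutoff,
                                               traj.box, traj.periodic).any(axis=1)
        elif method == "fast":
            within = _contact_any_fast(prot, lip, cfg.contact_cutoff,
                                       traj.box, traj.periodic)
        else:
            raise ValueError(f"unknown method {method!r}")
        in_contact = np.zeros(len(residues), dtype=bool)
        in_contact[slot[within]] = True
        counts += in_contact
    freq = 100.0 * counts / len(frames)
    return freq, len(frames)


def compute_contact_profile(traj: Trajectory, cfg: ContactConfig | None = None,
                            method: str = "fast") -> ContactProfile:
    """Full per-residue profile: any-lipid frequency plus species and
    atom-class decompositions."""
    cfg = cfg or ContactConfig()
    residues, _ = _protein_layout(traj)
    freq, n = residue_contact_frequency(traj, cfg, method=method)
    by_species = {}
    for sp in ("PS", "PC"):
        try:
            by_species[sp], _ = residue_contact_frequency(traj, cfg, species=sp,
                                                          method=method)
        except EmptySelectionError:
            by_species[sp] = np.zeros_like(freq)
    by_class = {}
    for cl in ("headgroup", "acyl"):
        try:
            by_class[cl], _ = residue_contact_frequency(traj, cfg, atom_class=cl,
                                                        method=method)
        except EmptySelectionError:
            by_class[cl] = np.zeros_like(freq)
    return ContactProfile(residue_index=residues, frequency=freq,
                          by_species=by_species, by_class=by_class,
                          n_frames_analyzed=n)


# ---------------------------------------------------------------------------
# residues-in-contact time series


def _counts_per_frame(traj: Trajectory, cfg: ContactConfig) -> np.ndarray:
    lip_idx = _selection(traj)
    residues, groups = _protein_layout(traj)
    prot_idx = np.concatenate(groups)
    slot = np.concatenate([np.full(len(g), si) for si, g in enumerate(groups)])
    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        within = _contact_any_fast(traj.coords[f, prot_idx], traj.coords[f, lip_idx],
                                   cfg.contact_cutoff, traj.box, traj.periodic)
        in_contact = np.zeros(len(residues), dtype=bool)
        in_contact[slot[within]] = True
        counts[f] = int(in_contact.sum())
    return counts


def residues_in_contact_series(trajs: Sequence[Trajectory],
                               cfg: ContactConfig | None = None) -> ContactTimeSeries:
    """Number of residues with >= 1 lipid contact, per frame and per replicate.

    Replicates must share the residue count and time grid.  The pointwise SE
    across replicates uses n = number of replicates; the scalar summary is the
    mean +/- SD across replicates of each replicate's time average over the
    analysis window (sampled at the configured stride).
    """
    cfg = cfg or ContactConfig()
    if not trajs:
        raise IncompatibleReplicatesError("no trajectories supplied")
    ref = trajs[0]
    for t in trajs[1:]:
        if t.n_residues != ref.n_residues:
            raise IncompatibleReplicatesError("replicates differ in residue count")
        if t.n_frames != ref.n_frames or not np.allclose(t.times, ref.times):
            raise IncompatibleReplicatesError("replicates differ in time grid")

    per_rep = np.stack([_counts_per_frame(t, cfg) for t in trajs])
    n_rep = per_rep.shape[0]
    mean = per_rep.mean(axis=0)
    se = (per_rep.std(axis=0, ddof=1) / np.sqrt(n_rep)) if n_rep > 1 else None

    frames = analysis_frames(ref.times, cfg)
    rep_means = per_rep[:, frames].mean(axis=1)
    window_sd = float(np.std(rep_means, ddof=1)) if n_rep > 1 else None
    return ContactTimeSeries(times=ref.times.copy(), per_replicate=per_rep,
                             mean=mean, se=se, replicate_window_means=rep_means,
                             window_mean=float(rep_means.mean()), window_sd=window_sd)


# ---------------------------------------------------------------------------
# ion-lipid coordination


def _runs(below: np.ndarray, gap_bridge: int):
    """Contiguous True runs, optionally bridging gaps of <= gap_bridge frames."""
    if gap_bridge > 0 and below.any():
        below = below.copy()
        idx = np.flatnonzero(below)
        for a, b in zip(idx[:-1], idx[1:]):
            if 1 < b - a <= gap_bridge + 1:
                below[a:b] = True
    runs = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(below)))
    return runs


def detect_coordination_events(traj: Trajectory, cfg: ContactConfig | None = None
                               ) -> list[CoordinationEvent]:
    """Segment ion-lipid coordination events.

    For every (ion, lipid headgroup) pair, contiguous runs of frames with
    min-image distance strictly below ``coordination_cutoff`` become events;
    duration is run length x dt.  Only headgroup particles of species PS and
    PC are considered, and the species is recorded per event.  Events with
    duration < ``short_event_max`` are 'short', others 'persistent'.
    """
    cfg = cfg or ContactConfig()
    part = traj.particles
    ions = part.index[part.kind == "ion"].to_numpy()
    heads = part.index[(part.kind == "lipid") & (part.atom_class == "headgroup")
                       & (part.lipid_species.isin(["PS", "PC"]))].to_numpy()
    if ions.size == 0 or heads.size == 0:
        return []
    dt = traj.dt if traj.n_frames > 1 else 1.0

    events: list[CoordinationEvent] = []
    for ion_row in ions:
        ion_xyz = traj.coords[:, ion_row, :]  # (n_frames, 3)
        head_xyz = traj.coords[:, heads, :]  # (n_frames, n_heads, 3)
        d = ion_xyz[:, None, :] - head_xyz
        if traj.periodic:
            L = np.asarray(traj.box, dtype=float)
            d = d - L * np.round(d / L)
        dist = np.sqrt((d**2).sum(axis=-1))  # (n_frames, n_heads)
        below = dist < cfg.coordination_cutoff
        for hi, head_row in enumerate(heads):
            if not below[:, hi].any():
                continue
            lipid_id = int(part.loc[head_row, "lipid_index"])
            species = str(part.loc[head_row, "lipid_species"])
            for a, b in _runs(below[:, hi], cfg.gap_bridge):
                duration = (b - a) * dt
                t_start = float(traj.times[a])
                events.append(CoordinationEvent(
                    ion_id=int(part.loc[ion_row, "particle_id"]),
                    lipid_id=lipid_id, lipid_species=species,
                    t_start=t_start, t_end=t_start + duration, duration=duration,
                    event_class="short" if duration < cfg.short_event_max
                    else "persistent"))
    events.sort(key=lambda e: (e.t_start, e.ion_id, e.lipid_id))
    return events


def min_ion_lipid_distance(traj: Trajectory, cfg: ContactConfig | None = None
                           ) -> IonDistanceSummary:
    """Each ion's per-frame distance to the nearest lipid particle (any class),
    and the fraction of frames beyond the encaged-ion reporting distance."""
    cfg = cfg or ContactConfig()
    part = traj.particles
    ions = part.index[part.kind == "ion"].to_numpy()
    lipids = part.index[part.kind == "lipid"].to_numpy()
    if ions.size == 0 or lipids.size == 0:
        return IonDistanceSummary(np.array([], dtype=int),
                                  np.empty((0, traj.n_frames)), np.array([]))
    dists = np.empty((ions.size, traj.n_frames))
    for k, ion_row in enumerate(ions):
        d = traj.coords[:, ion_row, None, :] - traj.coords[:, lipids, :]
        if traj.periodic:
            L = np.asarray(traj.box, dtype=float)
            d = d - L * np.round(d / L)
        dists[k] = np.sqrt((d**2).sum(axis=-1)).min(axis=1)
    frac = (dists > cfg.encage_report_distance).mean(axis=1)
    ion_ids = part.loc[ions, "particle_id"].to_numpy()
    return IonDistanceSummary(ion_ids=ion_ids, distances=dists, fraction_beyond=frac)


# ---------------------------------------------------------------------------
# group comparison


def compare_contact_levels(group_a: Sequence[float], group_b: Sequence[float]
                           ) -> ComparisonResult:
    """One-tailed two-sample Student's t test of the alternative that group B's
    mean time-averaged contact count is below group A's."""
    return compare_conditions([list(group_a), list(group_b)], test="one_tailed_t",
                              group_names=["group_a", "group_b"])
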