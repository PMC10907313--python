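"""End-to-end experiment orchestration and run manifests.

Ties the two pipelines together: for the vesicle assay, detect -> quantify ->
summarise -> compare across conditions; for trajectories, profiles -> time
series -> events -> group comparison.  Every run can write CSV outputs plus a
manifest (tool version, config snapshot, input digests, seeds, per-stage
counts) sufficient to reproduce the deterministic outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .contacts import (ContactConfig, compare_contact_levels, compute_contact_profile,
                       detect_coordination_events, residues_in_contact_series)
from .detection import DetectorParams, detect_guvs
from .imaging_sim import MultiChannelImage, read_image
from .puncta import PunctaPipelineConfig, analyze_guv
from .recruit_stats import (ComparisonResult, ReplicateResult, compare_conditions,
                            proportion_guvs_with_puncta, summarize_replicates)
from .trajectory_sim import Trajectory
from .trajio import read_trajectory

__all__ = ["ValidationError", "GUVExperimentResult", "ContactExperimentResult",
           "run_guv_experiment", "run_contact_experiment"]


class ValidationError(ValueError):
    pass


def _asdict(obj):
    return dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(config_snapshot: dict, inputs: list[Path], seeds, counts: dict) -> dict:
    return dict(
        tool="memrecruit",
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        config=config_snapshot,
        seeds=seeds,
        input_digests={str(p): _digest(p) for p in inputs},
        counts=counts,
    )


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str)
                                           + "\n")


# ---------------------------------------------------------------------------
# GUV assay experiment


@dataclass
class GUVExperimentResult:
    replicates: list[ReplicateResult]
    summary: pd.DataFrame  # condition, channel, mean, sd, n_replicates, pooled n
    comparison: Optional[ComparisonResult]
    manifest: dict
    failures: list[str] = field(default_factory=list)


ImageLike = Union[str, Path, MultiChannelImage]


def _load_image(entry: ImageLike) -> tuple[MultiChannelImage, Optional[Path]]:
    if isinstance(entry, MultiChannelImage):
        return entry, None
    path = Path(entry)
    return read_image(path), path


def run_guv_experiment(design: dict[str, Sequence[Sequence[ImageLike]]],
                       detector: DetectorParams | None = None,
                       pipeline: PunctaPipelineConfig | None = None,
                       channel: str = "A",
                       out_dir=None) -> GUVExperimentResult:
    """Run the full vesicle assay over a condition design.

    ``design`` maps condition label -> list of replicates, each replicate a
    list of images (paths to TIFFs or in-memory ``MultiChannelImage``).
    Border-flagged detections are excluded.  Per-image failures are recorded,
    not fatal.  With exactly two conditions the per-replicate proportions are
    compared by a two-tailed pooled-variance t test; with more, by one-way
    ANOVA.

    Raises
    ------
    ValidationError
        If a condition has no replicates or a replicate has no images.
    """
    detector = detector or DetectorParams()
    pipeline = pipeline or PunctaPipelineConfig()

    offenders = [c for c, reps in design.items()
                 if not reps or any(not rep for rep in reps)]
    if not design or offenders:
        raise ValidationError(
            "invalid design: conditions with no replicates or empty replicates: "
            + ", ".join(repr(c) for c in (offenders or ["<empty design>"])))

    replicates: list[ReplicateResult] = []
    failures: list[str] = []
    inputs: list[Path] = []
    n_images = n_guvs_total = n_puncta_total = 0

    for condition, reps in design.items():
        for ri, rep_images in enumerate(reps):
            records = []
            coloc_values = []
            for entry in rep_images:
                try:
                    image, path = _load_image(entry)
                    if path is not None:
                        inputs.append(path)
                    n_images += 1
                    dets = [d for d in detect_guvs(image["lipid"], detector)
                            if not d.border]
                    for det in dets:
                        rec = analyze_guv(image, det, pipeline)
                        records.append(rec)
                        if rec.coloc_fraction is not None:
                            coloc_values.append(rec.coloc_fraction)
                except Exception as exc:  # per-image failure is reported, not fatal
                    failures.append(f"{condition}/rep{ri}: {exc}")
            if not records:
                failures.append(f"{condition}/rep{ri}: no GUVs recognised")
                continue
            n_guvs_total += len(records)
            n_puncta_total += sum(sum(r.punctum_count.values()) for r in records)
            channels = sorted({ch for r in records for ch in r.punctum_count})
            props = {ch: proportion_guvs_with_puncta(records, ch) for ch in channels}
            replicates.append(ReplicateResult(
                condition=condition, replicate_id=f"rep{ri}",
                n_guvs=len(records),
                n_guvs_with_puncta={ch: sum(r.has_punctum[ch] for r in records)
                                    for ch in channels},
                proportion_with_puncta=props,
                coloc_proportion=(float(np.mean(coloc_values))
                                  if coloc_values else None),
            ))

    by_condition: dict[str, list[float]] = {}
    for rep in replicates:
        if channel in rep.proportion_with_puncta:
            by_condition.setdefault(rep.condition, []).append(
                float(rep.proportion_with_puncta[channel]))
    summaries = summarize_replicates(by_condition) if by_condition else []
    pooled_n = {c: sum(r.n_guvs for r in replicates if r.condition == c)
                for c in by_condition}
    summary = pd.DataFrame([
        dict(condition=s.condition, channel=channel, n_replicates=len(s.values),
             mean_proportion=s.mean,
             sd_proportion=s.sd if s.sd is not None else np.nan,
             pooled_n_guvs=pooled_n[s.condition])
        for s in summaries
    ])

    comparison = None
    groups = [v for v in by_condition.values() if len(v) >= 2]
    if len(groups) == len(by_condition) and len(groups) >= 2:
        test = "student_t" if len(groups) == 2 else "anova"
        comparison = compare_conditions(groups, test=test,
                                        group_names=list(by_condition))

    manifest = _manifest(
        config_snapshot=dict(detector=_asdict(detector), pipeline=_asdict(pipeline),
                             channel=channel),
        inputs=inputs, seeds=None,
        counts=dict(images=n_images, guvs=n_guvs_total, puncta=n_puncta_total,
                    replicates=len(replicates), failures=len(failures)),
    )

    result = GUVExperimentResult(replicates, summary, comparison, manifest, failures)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rep_rows = []
        for rep in replicates:
            for ch, prop in rep.proportion_with_puncta.items():
                rep_rows.append(dict(
                    condition=rep.condition, replicate_id=rep.replicate_id, channel=ch,
                    n_guvs=rep.n_guvs, n_with_puncta=rep.n_guvs_with_puncta[ch],
                    proportion=float(prop),
                    coloc_proportion=(rep.coloc_proportion
                                      if rep.coloc_proportion is not None else "")))
        pd.DataFrame(rep_rows).to_csv(out_dir / "replicates.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        if comparison is not None:
            pd.DataFrame([dataclasses.asdict(comparison)]).to_csv(
                out_dir / "comparison.csv", index=False)
        _write_manifest(manifest, out_dir)
    return result


# ---------------------------------------------------------------------------
# trajectory experiment


@dataclass
class ContactExperimentResult:
    profiles: dict[str, list]  # group label -> list of ContactProfile
    series: dict[str, object]  # group label -> ContactTimeSeries
    events: dict[str, list]  # group label -> flat list of CoordinationEvent
    comparison: Optional[ComparisonResult]
    manifest: dict


TrajLike = Union[str, Path, Trajectory]


def _load_traj(entry: TrajLike) -> tuple[Trajectory, Optional[Path]]:
    if isinstance(entry, Trajectory):
        return entry, None
    path = Path(entry)
    return read_trajectory(path), path


def run_contact_experiment(groups: dict[str, Sequence[TrajLike]],
                           cfg: ContactConfig | None = None,
                           out_dir=None) -> ContactExperimentResult:
    """Contact statistics over labelled trajectory groups.

    Computes per-trajectory contact profiles, the per-group residues-in-contact
    time series, coordination events, and (with >= 2 groups of >= 2 replicates)
    a one-tailed comparison of the first group against the second (alternative:
    the second binds less).
    """
    cfg = cfg or ContactConfig()
    if not groups or any(not trajs for trajs in groups.values()):
        raise ValidationError("every group needs at least one trajectory")

    inputs: list[Path] = []
    profiles: dict[str, list] = {}
    series: dict[str, object] = {}
    events: dict[str, list] = {}
    counts = dict(groups=len(groups), trajectories=0, events=0)

    for label, entries in groups.items():
        trajs = []
        for e in entries:
            traj, path = _load_traj(e)
            trajs.append(traj)
            if path is not None:
                inputs.append(path / "coords.csv")
        counts["trajectories"] += len(trajs)
        profiles[label] = [compute_contact_profile(t, cfg) for t in trajs]
        series[label] = residues_in_contact_series(trajs, cfg)
        ev = [e for t in trajs for e in detect_coordination_events(t, cfg)]
        events[label] = ev
        counts["events"] += len(ev)

    comparison = None
    labels = list(groups)
    if len(labels) >= 2:
        a = series[labels[0]].replicate_window_means
        b = series[labels[1]].replicate_window_means
        if len(a) >= 2 and len(b) >= 2:
            comparison = compare_contact_levels(a, b)

    manifest = _manifest(config_snapshot=_asdict(cfg), inputs=inputs, seeds=None,
                         counts=counts)
    result = ContactExperimentResult(profiles, series, events, comparison, manifest)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prof_rows = []
        for label, profs in profiles.items():
            for ti, prof in enumerate(profs):
                for i, res in enumerate(prof.residue_index):
                    prof_rows.append(dict(
                        group=label, trajectory=ti, residue_index=int(res),
                        any_pct=prof.frequency[i],
                        ps_pct=prof.by_species["PS"][i],
                        pc_pct=prof.by_species["PC"][i],
                        headgroup_pct=prof.by_class["headgroup"][i],
                        acyl_pct=prof.by_class["acyl"][i]))
        pd.DataFrame(prof_rows).to_csv(out_dir / "contact_profiles.csv", index=False)

        ts_rows = []
        for label, ts in series.items():
            for i, t in enumerate(ts.times):
                ts_rows.append(dict(group=label, time_ns=t, mean=ts.mean[i],
                                    se=ts.se[i] if ts.se is not None else ""))
        pd.DataFrame(ts_rows).to_csv(out_dir / "contact_series.csv", index=False)

        ev_rows = [dict(group=label, **dataclasses.asdict(e))
                   for label, evs in events.items() for e in evs]
        pd.DataFrame(ev_rows).to_csv(out_dir / "events.csv", index=False)
        if comparison is not None:
            pd.DataFrame([dataclasses.asdict(comparison)]).to_csv(
                out_dir / "comparison.csv", index=False)
        _write_manifest(manifest, out_dir)
    return result
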