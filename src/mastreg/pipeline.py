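"""End-to-end orchestration: simulate → project → detect → track → contacts.

`run_pipeline` executes every analysis stage on a simulated (or caller-
supplied) stack and produces a JSON-serializable summary with densities,
velocity statistics and contact-category counts; `compare_arms` sets a
control arm against a PCA arm (Treg density fold change, Welch velocity
comparison, side-by-side contact histograms).  Identical config + seed
give a byte-identical summary.

The module also houses the ground-truth correspondence helpers used to
score recovery: matching recovered mast-cell labels and Treg tracks back
to generator identities, and recovered contact events back to seeded
episodes.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import __version__
from .contacts import (
    ContactEvent,
    CorrelationParams,
    assign_contact_pairs,
    categorize_duration,
    classify_contacts,
    contact_mask,
    link_contact_events,
    local_correlation_map,
)
from .detect import (
    MC_SEGMENTATION,
    TREG_SEGMENTATION,
    Detection,
    SegmentationParams,
    characteristic_spacing,
    enumerate_density,
    fold_change,
    segment_cells,
)
from .imgproc import ProjectedStack, max_z_project
from .motility import Track, TrackStats, link_tracks, track_velocity
from .scenegen import GroundTruth, ScenarioConfig, SeededContact, simulate_scene
from .stackio import ImageStack, write_stack, write_table

__all__ = [
    "RunConfig",
    "AnalysisResult",
    "analyze_stack",
    "summarize",
    "run_pipeline",
    "compare_arms",
    "match_treg_tracks_to_truth",
    "match_mc_labels_to_truth",
    "score_contact_recovery",
]

#: matching radius (µm) when re-identifying sessile mast cells across frames
MC_MATCH_RADIUS_UM = 6.0


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run."""

    scenario: ScenarioConfig
    mc_segmentation: SegmentationParams = MC_SEGMENTATION
    treg_segmentation: SegmentationParams = TREG_SEGMENTATION
    correlation: CorrelationParams = field(default_factory=CorrelationParams)
    #: Treg linking gate; None → 3 × expected per-frame step length
    max_disp_um: float | None = None
    max_gap: int = 1
    #: contact events tolerate slightly longer mask dropouts than tracks do
    contact_max_gap: int = 2
    #: tracks shorter than this many points are excluded from velocity stats
    min_track_points: int = 3
    #: set False for velocity-only runs to skip the per-frame contact mapping
    contacts_enabled: bool = True
    outdir: str | None = None
    write_scene: bool = False

    @property
    def treg_gate_um(self) -> float:
        if self.max_disp_um is not None:
            return self.max_disp_um
        sc = self.scenario
        return 3.0 * sc.treg_speed_um_min * sc.meta.frame_interval_min


@dataclass
class AnalysisResult:
    """Everything one pipeline run measured on one stack."""

    projected: ProjectedStack
    mc_detections: list[list[Detection]]
    treg_detections: list[list[Detection]]
    mc_tracks: list[Track]
    treg_tracks: list[Track]
    mc_stats: list[TrackStats]
    treg_stats: list[TrackStats]
    contact_pairs: list[tuple[int, int, int]]
    events: list[ContactEvent]
    #: per-frame map (frame, detection label) -> stable MC id (frame-0 label)
    mc_stable_ids: dict[tuple[int, int], int]
    #: per-frame map (frame, detection label) -> Treg track id
    treg_track_ids: dict[tuple[int, int], int]


def _stable_mc_ids(mc_detections: list[list[Detection]]) -> dict[tuple[int, int], int]:
    """Identify each frame's mast cells with frame-0 labels (cells are sessile)."""
    ids: dict[tuple[int, int], int] = {}
    if not mc_detections or not mc_detections[0]:
        return ids
    ref = [(d.label, d.y_um, d.x_um) for d in mc_detections[0]]
    for dets in mc_detections:
        for d in dets:
            best, best_d = None, MC_MATCH_RADIUS_UM
            for lab, y, x in ref:
                dist = math.hypot(d.y_um - y, d.x_um - x)
                if dist < best_d:
                    best, best_d = lab, dist
            if best is not None:
                ids[(d.frame, d.label)] = best
    return ids


def _treg_track_ids(
    treg_detections: list[list[Detection]], tracks: list[Track]
) -> dict[tuple[int, int], int]:
    pos_to_tid = {
        (f, y, x): tr.id for tr in tracks for (f, y, x) in tr.points
    }
    out: dict[tuple[int, int], int] = {}
    for dets in treg_detections:
        for d in dets:
            tid = pos_to_tid.get((d.frame, d.y_um, d.x_um))
            if tid is not None:
                out[(d.frame, d.label)] = tid
    return out


def analyze_stack(stack: ImageStack, config: RunConfig) -> AnalysisResult:
    """Run projection, segmentation, tracking and contact mapping on a stack."""
    meta = stack.meta
    px = meta.pixel_size_um
    proj = max_z_project(stack)
    roles = meta.channel_roles
    red = proj.channel("red_tdt") if "red_tdt" in roles else None
    green = proj.channel("green_egfp") if "green_egfp" in roles else None
    blue = proj.channel("blue_auto") if "blue_auto" in roles else None

    mc_detections: list[list[Detection]] = []
    treg_detections: list[list[Detection]] = []
    for t in range(proj.n_frames):
        if red is not None:
            mc_detections.append(
                segment_cells(red[t], px, blue_plane=blue[t] if blue is not None else None,
                              params=config.mc_segmentation, frame=t, channel_role="red_tdt")
            )
        else:
            mc_detections.append([])
        if green is not None:
            treg_detections.append(
                segment_cells(green[t], px, params=config.treg_segmentation,
                              frame=t, channel_role="green_egfp")
            )
        else:
            treg_detections.append([])

    mc_tracks = link_tracks([d for f in mc_detections for d in f],
                            max_disp_um=MC_MATCH_RADIUS_UM, max_gap=config.max_gap)
    treg_tracks = link_tracks([d for f in treg_detections for d in f],
                              max_disp_um=config.treg_gate_um, max_gap=config.max_gap)
    dt = meta.frame_interval_min
    mc_stats = [s for tr in mc_tracks if tr.n_points >= config.min_track_points
                and (s := track_velocity(tr, dt)) is not None]
    treg_stats = [s for tr in treg_tracks if tr.n_points >= config.min_track_points
                  and (s := track_velocity(tr, dt)) is not None]

    mc_stable = _stable_mc_ids(mc_detections)
    treg_tids = _treg_track_ids(treg_detections, treg_tracks)

    pairs: list[tuple[int, int, int]] = []
    if config.contacts_enabled and red is not None and green is not None and proj.n_frames >= 2:
        for t in range(proj.n_frames):
            corr = local_correlation_map(red[t], green[t], config.correlation)
            mask = contact_mask(corr, red[t], green[t], config.correlation)
            for frame, mlab, tlab in assign_contact_pairs(
                mask, mc_detections[t], treg_detections[t]
            ):
                mid = mc_stable.get((frame, mlab))
                tid = treg_tids.get((frame, tlab))
                if mid is not None and tid is not None:
                    pairs.append((frame, mid, tid))
    pairs = sorted(set(pairs))
    events = link_contact_events(pairs, dt, max_gap=config.contact_max_gap)
    track_pos = {tr.id: {f: (y, x) for f, y, x in tr.points} for tr in treg_tracks}
    events = _stitch_events(events, track_pos, dt, config.contact_max_gap)

    return AnalysisResult(
        projected=proj,
        mc_detections=mc_detections,
        treg_detections=treg_detections,
        mc_tracks=mc_tracks,
        treg_tracks=treg_tracks,
        mc_stats=mc_stats,
        treg_stats=treg_stats,
        contact_pairs=pairs,
        events=events,
        mc_stable_ids=mc_stable,
        treg_track_ids=treg_tids,
    )


def _stitch_events(
    events: list[ContactEvent],
    track_pos: dict[int, dict[int, tuple[float, float]]],
    frame_interval_min: float,
    max_gap: int,
    junction_um: float = 12.0,
) -> list[ContactEvent]:
    """Merge contact events interrupted only by a Treg track re-identification.

    When a fast-moving Treg's track fragments, one physical contact can
    surface as two events on the same mast cell under different track
    ids.  Two events of one mast cell are merged when they are separated
    by at most ``max_gap`` frames and the two Treg tracks sit within
    ``junction_um`` of each other at the junction — i.e. they plainly
    describe the same cell holding the same contact.
    """
    events = sorted(events, key=lambda e: (e.mc_id, e.start_frame, e.end_frame))
    out: list[ContactEvent] = []
    for ev in events:
        if out:
            prev = out[-1]
            if (
                prev.mc_id == ev.mc_id
                and prev.treg_id != ev.treg_id
                and ev.start_frame - prev.end_frame - 1 <= max_gap
            ):
                p1 = track_pos.get(prev.treg_id, {}).get(min(prev.end_frame, ev.start_frame))
                p2 = track_pos.get(ev.treg_id, {}).get(ev.start_frame)
                if (
                    p1 is not None and p2 is not None
                    and math.hypot(p1[0] - p2[0], p1[1] - p2[1]) <= junction_um
                ):
                    end = max(prev.end_frame, ev.end_frame)
                    duration = (end - prev.start_frame + 1) * frame_interval_min
                    out[-1] = ContactEvent(
                        mc_id=prev.mc_id, treg_id=prev.treg_id,
                        start_frame=prev.start_frame, end_frame=end,
                        duration_min=duration,
                        category=categorize_duration(duration),
                    )
                    continue
        out.append(ev)
    return out


def summarize(analysis: AnalysisResult, config: RunConfig) -> dict:
    """JSON-serializable summary of one analyzed stack."""
    sc = config.scenario
    area_um2 = sc.field_size_um[0] * sc.field_size_um[1]
    dt = sc.meta.frame_interval_min

    def population(dets_by_frame, stats_list):
        n0 = len(dets_by_frame[0]) if dets_by_frame else 0
        dens = enumerate_density(n0, area_um2)
        speeds = sorted(round(s.mean_speed_um_min, 9) for s in stats_list)
        return {
            "n_frame0": n0,
            "density_per_mm2": dens.density_per_mm2,
            "spacing_um": characteristic_spacing(dens.density_per_mm2)
            if dens.density_per_mm2 > 0 else None,
            "n_tracks": len(stats_list),
            "mean_speed_um_min": float(np.mean(speeds)) if speeds else None,
            "speeds_um_min": speeds,
        }

    counts = classify_contacts(analysis.events)
    treg_pop = population(analysis.treg_detections, analysis.treg_stats)
    treg_pop["speeds_contiguous_um_min"] = sorted(
        round(v, 9) for v in contiguous_track_speeds(analysis, dt)
    )
    return {
        "version": __version__,
        "seed": sc.rng_seed,
        "arm": "pca" if sc.pca else "control",
        "frame_interval_min": dt,
        "area_um2": area_um2,
        "n_frames": sc.n_frames,
        "mc": population(analysis.mc_detections, analysis.mc_stats),
        "treg": treg_pop,
        "contacts": {
            "n_events": len(analysis.events),
            "counts": counts,
            "durations_min": sorted(round(e.duration_min, 9) for e in analysis.events),
        },
    }


def run_pipeline(config: RunConfig) -> dict:
    """Simulate the configured scenario, analyze it, optionally write outputs."""
    stack, truth = simulate_scene(config.scenario)
    analysis = analyze_stack(stack, config)
    summary = summarize(analysis, config)
    summary["seeded"] = {
        role: dens for role, dens in truth.densities_seeded.items()
    }
    summary["seeded"]["n_contacts"] = len(truth.contacts)
    if config.outdir:
        _write_outputs(config, stack, truth, analysis, summary)
    return summary


def _write_outputs(config, stack, truth, analysis, summary) -> None:
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    if config.write_scene:
        write_stack(stack, os.path.join(out, "scene.ome.tiff"))
    write_table(
        [d.record() for dets in analysis.mc_detections + analysis.treg_detections
         for d in dets],
        os.path.join(out, "detections.csv"),
        fieldnames=["frame", "channel", "label", "y_um", "x_um", "area_um2",
                    "mean_intensity"],
    )
    write_table(
        [{"track_id": tr.id, "channel": tr.channel_role, "frame": f,
          "y_um": y, "x_um": x}
         for tr in analysis.mc_tracks + analysis.treg_tracks
         for (f, y, x) in tr.points],
        os.path.join(out, "tracks.csv"),
        fieldnames=["track_id", "channel", "frame", "y_um", "x_um"],
    )
    write_table(
        analysis.mc_stats + analysis.treg_stats,
        os.path.join(out, "track_stats.csv"),
        fieldnames=["track_id", "mean_speed_um_min", "path_length_um", "n_steps",
                    "duration_min"],
    )
    write_table(
        analysis.events,
        os.path.join(out, "contacts.csv"),
        fieldnames=["mc_id", "treg_id", "start_frame", "end_frame", "duration_min",
                    "category"],
    )
    write_table(
        [{"mc_id": c.mc_id, "treg_id": c.treg_id, "start_frame": c.start_frame,
          "end_frame": c.end_frame} for c in truth.contacts],
        os.path.join(out, "truth_contacts.csv"),
        fieldnames=["mc_id", "treg_id", "start_frame", "end_frame"],
    )
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out, "config.json"), "w") as fh:
        json.dump(_config_record(config), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _config_record(config: RunConfig) -> dict:
    rec = dataclasses.asdict(config)
    return rec


def compare_arms(summary_control: dict, summary_pca: dict) -> dict:
    """Contrast a control arm with a PCA arm.

    Reports the Treg density fold change, a Welch two-sample comparison
    of per-track speeds (descriptive, α = 0.05), and side-by-side
    contact-category histograms.
    """
    for s in (summary_control, summary_pca):
        if "treg" not in s or "contacts" not in s:
            raise KeyError("summary lacks treg/contacts sections")
    d_ctrl = summary_control["treg"]["density_per_mm2"]
    d_pca = summary_pca["treg"]["density_per_mm2"]
    fc = fold_change(d_pca, d_ctrl)
    v_ctrl = (summary_control["treg"].get("speeds_contiguous_um_min")
              or summary_control["treg"]["speeds_um_min"])
    v_pca = (summary_pca["treg"].get("speeds_contiguous_um_min")
             or summary_pca["treg"]["speeds_um_min"])
    if len(v_ctrl) >= 2 and len(v_pca) >= 2:
        t_stat, p = stats.ttest_ind(v_pca, v_ctrl, equal_var=False)
        velocity = {
            "mean_control": float(np.mean(v_ctrl)),
            "mean_pca": float(np.mean(v_pca)),
            "difference": float(np.mean(v_pca) - np.mean(v_ctrl)),
            "welch_t": float(t_stat),
            "p_value": float(p),
            "significant_at_0.05": bool(p < 0.05),
        }
    else:
        velocity = {"p_value": None, "note": "too few tracks for a comparison"}
    return {
        "treg_fold_change": fc,
        "velocity": velocity,
        "contact_counts": {
            "control": summary_control["contacts"]["counts"],
            "pca": summary_pca["contacts"]["counts"],
        },
    }


def contiguous_track_speeds(
    analysis: AnalysisResult,
    frame_interval_min: float,
    min_points: int = 10,
) -> list[float]:
    """Mean speeds of gap-free Treg tracks, for between-arm comparisons.

    A step bridging a detection dropout (typically two touching cells
    merging into one blob for a frame) measures the chord of two walk
    steps and biases speed low; the bias scales with cell density and
    would masquerade as a between-arm velocity difference.  Restricting
    the comparison to contiguously detected tracks of at least
    ``min_points`` points removes it; the selection is blind to speed.
    """
    speeds = []
    for tr in analysis.treg_tracks:
        if tr.n_points < min_points:
            continue
        frames = [f for f, _, _ in tr.points]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            continue
        stats_ = track_velocity(tr, frame_interval_min)
        if stats_ is not None:
            speeds.append(stats_.mean_speed_um_min)
    return speeds


# ---------------------------------------------------------------------------
# ground-truth correspondence


def match_mc_labels_to_truth(
    analysis: AnalysisResult, truth: GroundTruth
) -> dict[int, list[int]]:
    """Map stable (frame-0) mast-cell labels to candidate generator cell ids.

    All generator cells within twice the re-identification radius are
    listed, so a detection that merged two touching cells remains
    associated with both members.
    """
    out: dict[int, list[int]] = {}
    if not analysis.mc_detections:
        return out
    for d in analysis.mc_detections[0]:
        cands = [
            (math.hypot(d.y_um - mc.y_um, d.x_um - mc.x_um), mc.id)
            for mc in truth.mc_cells
            if math.hypot(d.y_um - mc.y_um, d.x_um - mc.x_um) < 2.0 * MC_MATCH_RADIUS_UM
        ]
        if cands:
            out[d.label] = [mc_id for _, mc_id in sorted(cands)]
    return out


def match_treg_tracks_to_truth(
    analysis: AnalysisResult, truth: GroundTruth, max_mean_dist_um: float = 5.0
) -> dict[int, int]:
    """Map recovered Treg track ids to generator track ids by mean distance."""
    out: dict[int, int] = {}
    for tr in analysis.treg_tracks:
        best, best_d = None, max_mean_dist_um
        for gt in truth.treg_tracks:
            dists = [
                math.hypot(y - gt.positions_um[f, 0], x - gt.positions_um[f, 1])
                for (f, y, x) in tr.points
                if f < gt.positions_um.shape[0]
            ]
            if dists:
                d = float(np.mean(dists))
                if d < best_d:
                    best, best_d = gt.id, d
        if best is not None:
            out[tr.id] = best
    return out


def score_contact_recovery(
    analysis: AnalysisResult, truth: GroundTruth, frame_interval_min: float
) -> list[dict]:
    """For each seeded contact episode, the recovered events that match it.

    A recovered event matches a seeded episode when it involves the same
    ground-truth mast cell, overlaps the episode in time, and its Treg
    track runs alongside the seeded Treg's positions over the overlap
    (mean distance below 5 µm).  Matching Treg identity positionally per
    episode keeps the score meaningful even when the global track of a
    fast-walking Treg fragments outside its episodes.
    """
    mc_map = match_mc_labels_to_truth(analysis, truth)
    track_pos = {
        tr.id: {f: (y, x) for f, y, x in tr.points} for tr in analysis.treg_tracks
    }

    def treg_matches(ev: ContactEvent, seeded: SeededContact) -> bool:
        gt = truth.treg_tracks[seeded.treg_id].positions_um
        pos = track_pos.get(ev.treg_id, {})
        dists = [
            math.hypot(pos[f][0] - gt[f, 0], pos[f][1] - gt[f, 1])
            for f in range(max(ev.start_frame, seeded.start_frame),
                           min(ev.end_frame, seeded.end_frame) + 1)
            if f in pos and f < gt.shape[0]
        ]
        return bool(dists) and float(np.mean(dists)) < 5.0

    records = []
    for seeded in truth.contacts:
        matches = [
            ev for ev in analysis.events
            if seeded.mc_id in mc_map.get(ev.mc_id, [])
            and ev.start_frame <= seeded.end_frame + 1
            and ev.end_frame >= seeded.start_frame - 1
            and treg_matches(ev, seeded)
        ]
        seeded_duration = (seeded.end_frame - seeded.start_frame + 1) * frame_interval_min
        if matches:
            duration = sum(ev.duration_min for ev in matches)
            error = abs(duration - seeded_duration)
        else:
            duration, error = 0.0, seeded_duration
        records.append(
            {
                "seeded": seeded,
                "events": matches,
                "n_events": len(matches),
                "seeded_duration_min": seeded_duration,
                "recovered_duration_min": duration,
                "duration_error_min": error,
            }
        )
    return records
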