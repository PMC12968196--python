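"""End-to-end study orchestration on a synthetic cohort.

``run_study`` chains the full planning study: phantom cohort generation,
AC-PC quadrant parcellation, tensor fitting from synthesized DWI,
deterministic tractography and connection counting, target-segment
selection by motor connectivity, frontal/occipital trajectory safety
classification, GA infusion optimization per trajectory, and the paired
cohort statistics (contingency + mid-p McNemar on safety, paired t and
mean/CI on coverage).  Every stage's artifacts are written under the
output directory and the whole run is bit-reproducible from one seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .acpc import SEGMENT_CODES, SEGMENT_NAMES, build_acpc_frame, parcellate_putamen
from .infusion import GAConfig, optimize_injection
from .phantom import Phantom, PhantomSpec, attach_dwi, generate_phantom
from .stats import (PairedSample, build_contingency, midp_mcnemar, paired_t,
                    proportions, render_heatmap, summarize_mean_ci)
from .tractography import (TrackingCriteria, connection_present,
                           connectivity_counts, fit_tensor, track_from_segment)
from .trajectory import SafetyConfig, Trajectory, classify_safety, valid_centers
from .volume import distance_to_mask, write_volume

__all__ = ["StudyConfig", "run_study", "save_streamlines_tck"]


@dataclass
class StudyConfig:
    """One seeded, fully specified study run on a synthetic cohort."""

    n_subjects: int = 20
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(jitter_mm=1.5))
    tracking: TrackingCriteria = field(default_factory=TrackingCriteria)
    safety: SafetyConfig = field(default_factory=SafetyConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    motor_regions: tuple[str, ...] = ("SMA",)
    fit_from_dwi: bool = True
    write_nifti: bool = True
    write_png: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


def _sub_seed(global_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def save_streamlines_tck(streamlines, path) -> None:
    """Export streamlines (world-mm polylines) as a TCK file."""
    import nibabel as nib

    tractogram = nib.streamlines.Tractogram(
        [s.points for s in streamlines], affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(tractogram, str(path))


def _subject_phantom(cfg: StudyConfig, subject: int) -> Phantom:
    spec = replace(cfg.phantom, seed=_sub_seed(cfg.seed, 1, subject))
    ph = generate_phantom(spec)
    if cfg.fit_from_dwi:
        ph = attach_dwi(ph, seed=_sub_seed(cfg.seed, 2, subject))
    return ph


def run_study(cfg: StudyConfig, out_dir) -> dict:
    """Run the full study; returns the summary dict (also written as
    ``summary.json``).  Identical config + seed -> identical summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region_names = [r.name for r in cfg.phantom.cortical_rois]
    segment_names = list(SEGMENT_CODES)

    connection_matrices: list[pd.DataFrame] = []
    safety_rows: list[dict] = []
    per_hemi: list[dict] = []   # cached per-hemisphere state for the infusion stage

    for subject in range(cfg.n_subjects):
        ph = _subject_phantom(cfg, subject)
        frame = build_acpc_frame(**ph.landmarks)
        if cfg.fit_from_dwi:
            field_ = fit_tensor(ph.dwi_signal, ph.bvecs, ph.bvals, brain=ph.brain_mask)
        else:
            field_ = ph.tensor_field
        dmaps = {name: distance_to_mask(m) for name, m in ph.critical_masks.items()}

        for hemi in cfg.phantom.hemispheres:
            parc = parcellate_putamen(ph.putamen_masks[hemi], frame, hemisphere=hemi)
            if cfg.write_nifti and subject == 0:
                write_volume(parc.labels, out / f"parcellation_s{subject}_{hemi}.nii.gz")
                parc.to_frame().to_csv(out / f"segment_volumes_s{subject}_{hemi}.csv", index=False)

            streamlines = []
            for seg_name, code in SEGMENT_CODES.items():
                seg_mask = parc.segment_mask(code)
                streamlines += track_from_segment(
                    field_, seg_mask, cfg.tracking, ph.brain_mask, segment_code=code)
            conn = pd.DataFrame(False, index=region_names, columns=segment_names)
            for roi_name in region_names:
                roi = ph.roi_masks[(roi_name, hemi)]
                for seg_name, code in SEGMENT_CODES.items():
                    conn.loc[roi_name, seg_name] = connection_present(
                        streamlines, roi, parc.segment_mask(code))
            connection_matrices.append(conn)
            if subject == 0:
                save_streamlines_tck(streamlines, out / f"streamlines_s{subject}_{hemi}.tck")

            per_hemi.append(dict(subject=subject, hemi=hemi, parc=parc,
                                 phantom=ph, dmaps=dmaps))

    counts = connectivity_counts(connection_matrices)
    scale_max = 2 * cfg.n_subjects
    render_heatmap(counts, scale_max, out_png=(out / "connectivity_heatmap.png")
                   if cfg.write_png else None, out_csv=out / "connectivity_counts.csv")

    # target segment: highest presence count with the motor-associated regions
    motor = [r for r in cfg.motor_regions if r in counts.index]
    target_segment_name = counts.loc[motor].sum(axis=0).idxmax()
    target_code = SEGMENT_CODES[target_segment_name]

    coverage_pairs: dict[str, list[float]] = {"frontal": [], "occipital": []}
    safety_pairs: dict[str, list[int]] = {"frontal": [], "occipital": []}
    for state in per_hemi:
        ph, parc, hemi = state["phantom"], state["parc"], state["hemi"]
        seg = parc.segment_mask(target_code)
        for approach in ("frontal", "occipital"):
            tt = ph.trajectories[(hemi, approach)]
            traj = Trajectory(entry=tt["entry"], target=tt["target"],
                              approach=approach, hemisphere=hemi)
            verdict = classify_safety(traj, cfg.safety, state["dmaps"])
            centers = valid_centers(traj, seg)
            ga_cfg = replace(cfg.ga, seed=_sub_seed(cfg.seed, 3, state["subject"],
                                                    {"left": 0, "right": 1}[hemi],
                                                    {"frontal": 0, "occipital": 1}[approach]))
            res = optimize_injection(centers, seg, allowed_roi=seg, cfg=ga_cfg)
            safety_pairs[approach].append(int(verdict.safe))
            coverage_pairs[approach].append(res.coverage if res.feasible else np.nan)
            safety_rows.append(dict(
                subject=state["subject"], hemisphere=hemi, approach=approach,
                safe=int(verdict.safe), min_distance_mm=verdict.min_distance_mm,
                offending=verdict.offending_structure or "",
                n_valid_centers=len(centers),
                in_segment_length_mm=traj.in_segment_length(seg),
                feasible=res.feasible, coverage=res.coverage,
                n_spheres=len(res.plan.spheres) if res.feasible else 0,
            ))
            if cfg.write_nifti and state["subject"] == 0 and res.coverage_mask is not None:
                write_volume(res.coverage_mask, out / f"coverage_s0_{hemi}_{approach}.nii.gz")

    safety_df = pd.DataFrame(safety_rows)
    safety_df.to_csv(out / "trajectory_safety.csv", index=False)

    pairs_bin = PairedSample(np.array(safety_pairs["frontal"]),
                             np.array(safety_pairs["occipital"]))
    table = build_contingency(pairs_bin)
    props = proportions(table)
    p_mid = midp_mcnemar(table)

    cov_f = np.array(coverage_pairs["frontal"], dtype=float)
    cov_o = np.array(coverage_pairs["occipital"], dtype=float)
    both = ~np.isnan(cov_f) & ~np.isnan(cov_o)
    cov_stats: dict = {"n_paired": int(both.sum())}
    if both.sum() >= 2:
        t_res = paired_t(PairedSample(cov_f[both] * 100, cov_o[both] * 100))
        cov_stats.update(
            frontal=summarize_mean_ci(cov_f[both] * 100),
            occipital=summarize_mean_ci(cov_o[both] * 100),
            paired_t=t_res,
        )

    summary = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "n_hemispheres": len(per_hemi),
        "target_segment": target_segment_name,
        "connectivity_counts": {r: counts.loc[r].to_dict() for r in counts.index},
        "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d, "n": table.n},
        "proportions": props,
        "midp_mcnemar_p": p_mid,
        "coverage_percent": cov_stats,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
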