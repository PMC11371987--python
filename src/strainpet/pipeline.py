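"""End-to-end study orchestration.

Runs the full analysis — phantom generation (or loading of user-supplied
volumes), CT aeration, strain field, SUVR, iso-gravitational profiles
with their regression statistics, and linear mutual information — over a
cohort of subjects split into an injured (VILI-like) and a healthy-like
condition, at one or more transverse slice levels, and writes a
reproducible report (JSON + CSV tables).

Slice levels are given as fractional positions along the apico-basal
axis of the masked lung (for example 0.8 for a para-diaphragmatic
analogue and 0.5 for a mid-thoracic one), since absolute anatomical
distances are meaningless on phantoms.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .aeration import aeration_map
from .lmi import linear_mutual_information
from .phantom import Phantom, PhantomParams, generate_phantom, read_phantom, write_phantom
from .profiles import (
    DEFAULT_FIT_RANGE,
    DEFAULT_N_LAYERS,
    GravProfile,
    compare_regressions_F,
    fit_central_quartiles,
    group_profile,
    layer_profile,
    slope_z_test,
    suvr_vs_nongaseous_regression,
    wilcoxon_compare,
)
from .strain import DEFAULT_FLOOR_FRACTION, summarize_slice, vostrain_map
from .suvr import reference_concentration, suvr_map

__all__ = [
    "SubjectSpec",
    "StudyConfig",
    "StudyReport",
    "run_study",
    "select_analysis_slices",
    "default_demo_config",
    "VILI_LIKE_PARAMS",
    "HEALTHY_LIKE_PARAMS",
]

logger = logging.getLogger(__name__)

CONDITION_VILI = "VILI-like"
CONDITION_HEALTHY = "healthy-like"

#: Study conditions for the demo cohort. The injured condition combines
#: deep dependent atelectasis, inflation to (near) total capacity and
#: strong strain-activation coupling; the healthy condition shallow
#: atelectasis, moderate inflation and weak coupling.
VILI_LIKE_PARAMS = PhantomParams(
    atelectasis_depth_fraction=0.3,
    inflation_factor=4.0,
    coupling_kappa=0.9,
)
HEALTHY_LIKE_PARAMS = PhantomParams(
    atelectasis_depth_fraction=0.02,
    inflation_factor=2.0,
    coupling_kappa=0.1,
)


@dataclass
class SubjectSpec:
    """One study subject: either phantom parameters or NIfTI input paths.

    ``paths`` must provide ct_ref, ct_inflated, pet, lung_mask and
    ref_roi_mask as a phantom directory (see ``phantom.write_phantom``).
    """

    subject_id: str
    condition: str
    phantom_params: PhantomParams | None = None
    input_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.phantom_params is None) == (self.input_dir is None):
            raise ValueError(
                f"subject {self.subject_id}: give exactly one of phantom_params or input_dir"
            )


@dataclass
class StudyConfig:
    subjects: list[SubjectSpec]
    slice_levels: dict[str, float] = field(
        default_factory=lambda: {"para_diaphragmatic": 0.8, "mid_thoracic": 0.5}
    )
    slice_axis: int = 0
    floor_fraction: float = DEFAULT_FLOOR_FRACTION
    n_layers: int = DEFAULT_N_LAYERS
    fit_range: tuple[int, int] = DEFAULT_FIT_RANGE
    out_dir: str | Path = "study_out"
    seed: int = 0
    save_volumes: bool = False
    lmi_log_strain: bool = False

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("study needs at least one subject")
        for name, pos in self.slice_levels.items():
            if not 0.0 < pos <= 1.0:
                raise ValueError(f"slice level {name}: position {pos} outside (0, 1]")

    def canonical_dict(self) -> dict:
        return {
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "condition": s.condition,
                    "phantom_params": s.phantom_params.to_dict() if s.phantom_params else None,
                    "input_dir": s.input_dir,
                }
                for s in self.subjects
            ],
            "slice_levels": dict(sorted(self.slice_levels.items())),
            "slice_axis": self.slice_axis,
            "floor_fraction": self.floor_fraction,
            "n_layers": self.n_layers,
            "fit_range": list(self.fit_range),
            "seed": self.seed,
            "lmi_log_strain": self.lmi_log_strain,
        }


@dataclass
class StudyReport:
    """Everything the study computed, plus where it was written."""

    report: dict
    subject_table: pd.DataFrame
    profile_table: pd.DataFrame
    out_dir: Path


def default_demo_config(
    out_dir: str | Path = "study_out",
    seed: int = 0,
    n_vili: int = 7,
    n_healthy: int = 3,
) -> StudyConfig:
    """Demo cohort mirroring the study design: 7 injured vs 3 controls.

    Per-subject phantom seeds are derived deterministically from the
    study seed.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_vili + n_healthy) % (2**31)
    subjects = []
    for i in range(n_vili):
        subjects.append(
            SubjectSpec(
                subject_id=f"vili{i + 1:02d}",
                condition=CONDITION_VILI,
                phantom_params=VILI_LIKE_PARAMS.with_seed(int(child_seeds[i])),
            )
        )
    for j in range(n_healthy):
        subjects.append(
            SubjectSpec(
                subject_id=f"ctrl{j + 1:02d}",
                condition=CONDITION_HEALTHY,
                phantom_params=HEALTHY_LIKE_PARAMS.with_seed(int(child_seeds[n_vili + j])),
            )
        )
    return StudyConfig(subjects=subjects, out_dir=out_dir, seed=seed)


def select_analysis_slices(
    mask: np.ndarray, positions: Sequence[float], slice_axis: int = 0
) -> list[int]:
    """Convert fractional apico-basal positions into transverse slice
    indices within the masked lung extent.

    Position p in (0, 1] maps to the slice a fraction p of the way from
    the most cranial to the most caudal masked plane; p = 1 gives the
    most caudal masked slice.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    planes = np.any(mask, axis=tuple(a for a in range(mask.ndim) if a != slice_axis))
    lo = int(np.argmax(planes))
    hi = mask.shape[slice_axis] - 1 - int(np.argmax(planes[::-1]))
    extent = hi - lo + 1
    out = []
    for p in positions:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"slice position {p} outside (0, 1]")
        out.append(lo + min(int(p * extent), extent - 1))
    return out


def _load_subject(spec: SubjectSpec) -> Phantom:
    if spec.phantom_params is not None:
        return generate_phantom(spec.phantom_params)
    return read_phantom(spec.input_dir)


def _take2d(vol: np.ndarray, idx: int, axis: int) -> np.ndarray:
    return np.take(vol, idx, axis=axis)


def _fit_to_dict(fit) -> dict:
    d = {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "slope_se": fit.slope_se,
        "r_squared": fit.r_squared,
        "n": fit.n,
        "fit_range": list(fit.fit_range),
    }
    if fit.slope_through_origin is not None:
        d["slope_through_origin"] = fit.slope_through_origin
        d["slope_through_origin_se"] = fit.slope_through_origin_se
    return d


def run_study(config: StudyConfig) -> StudyReport:
    """Execute all analysis stages over the configured cohort.

    Identical config + seed gives byte-identical CSV/JSON outputs. Any
    stage failure aborts with an error labeled by subject and stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    subject_rows: list[dict] = []
    profile_rows: list[dict] = []
    # per (level, condition): lists of per-subject profiles / scalars
    prof_store: dict[tuple[str, str, str], list[GravProfile]] = {}
    scalar_store: dict[tuple[str, str, str], list[float]] = {}
    warnings_log: list[str] = []

    for spec in config.subjects:
        try:
            phantom = _load_subject(spec)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"[load] subject {spec.subject_id}: {exc}") from exc
        logger.info("subject %s (%s): volumes ready", spec.subject_id, spec.condition)

        if config.save_volumes and spec.phantom_params is not None:
            vol_dir = out_dir / "volumes" / spec.subject_id
            vol_dir.mkdir(parents=True, exist_ok=True)
            write_phantom(phantom, vol_dir)

        try:
            aer_ref = aeration_map(phantom.ct_ref, phantom.lung_mask)
            aer_inf = aeration_map(phantom.ct_inflated, phantom.lung_mask)
            if aer_ref.n_clamped or aer_inf.n_clamped:
                warnings_log.append(
                    f"{spec.subject_id}: clamped HU voxels ref={aer_ref.n_clamped} "
                    f"inflated={aer_inf.n_clamped}"
                )
            strain = vostrain_map(aer_ref, aer_inf, config.floor_fraction)
            if strain.n_floored:
                warnings_log.append(f"{spec.subject_id}: {strain.n_floored} floored voxels")
            c_ref = reference_concentration(phantom.pet, phantom.ref_roi_mask)
            suvr = suvr_map(phantom.pet, c_ref, phantom.lung_mask)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"[maps] subject {spec.subject_id}: {exc}") from exc

        gravity_axis = phantom.ct_ref.gravity_axis
        gravity_axis_2d = gravity_axis - 1 if config.slice_axis < gravity_axis else gravity_axis
        level_names = sorted(config.slice_levels)
        slice_idx = select_analysis_slices(
            phantom.lung_mask,
            [config.slice_levels[k] for k in level_names],
            config.slice_axis,
        )

        for level, idx in zip(level_names, slice_idx):
            try:
                mask2d = _take2d(phantom.lung_mask, idx, config.slice_axis)
                vostrain2d = _take2d(strain.vostrain, idx, config.slice_axis)
                suvr2d = _take2d(suvr.suvr, idx, config.slice_axis)
                nongas2d = _take2d(aer_ref.nongaseous_volume, idx, config.slice_axis)

                st_sum = summarize_slice(strain.vostrain, phantom.lung_mask, idx, config.slice_axis)
                sv_sum = summarize_slice(suvr.suvr, phantom.lung_mask, idx, config.slice_axis)

                maps2d = {"vostrain": vostrain2d, "suvr": suvr2d, "nongaseous": nongas2d}
                profs = {
                    src: layer_profile(arr, mask2d, gravity_axis_2d, config.n_layers, source=src)
                    for src, arr in maps2d.items()
                }
                lmi_x = np.log1p(np.clip(vostrain2d, 0, None)) if config.lmi_log_strain else vostrain2d
                lmi_res = linear_mutual_information(lmi_x, suvr2d, mask2d)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"[slice {level}] subject {spec.subject_id}: {exc}"
                ) from exc

            subject_rows.append(
                {
                    "subject": spec.subject_id,
                    "condition": spec.condition,
                    "level": level,
                    "slice_index": idx,
                    "vostrain_mean": st_sum.mean,
                    "vostrain_sd": st_sum.sd,
                    "vostrain_median": st_sum.median,
                    "vostrain_iqr": st_sum.iqr,
                    "vostrain_grav_max": profs["vostrain"].gravitational_max,
                    "suvr_mean": sv_sum.mean,
                    "suvr_sd": sv_sum.sd,
                    "suvr_median": sv_sum.median,
                    "suvr_iqr": sv_sum.iqr,
                    "suvr_grav_max": profs["suvr"].gravitational_max,
                    "c_ref": c_ref,
                    "lmi": lmi_res.lmi,
                    "n_voxels": st_sum.n_voxels,
                    "n_floored": strain.n_floored,
                }
            )
            for src, prof in profs.items():
                prof_store.setdefault((level, spec.condition, src), []).append(prof)
            for name, val in (
                ("vostrain_mean", st_sum.mean),
                ("vostrain_median", st_sum.median),
                ("suvr_mean", sv_sum.mean),
                ("suvr_median", sv_sum.median),
                ("lmi", lmi_res.lmi),
            ):
                scalar_store.setdefault((level, spec.condition, name), []).append(val)

    subject_table = pd.DataFrame(subject_rows)

    # ---- group stage -------------------------------------------------
    conditions = sorted({s.condition for s in config.subjects})
    two_groups = conditions == sorted([CONDITION_HEALTHY, CONDITION_VILI])
    levels = sorted(config.slice_levels)
    group: dict = {}
    for level in levels:
        level_report: dict = {"conditions": {}}
        gprofs: dict[tuple[str, str], GravProfile] = {}
        for cond in conditions:
            cond_rep: dict = {"profiles": {}, "fits": {}}
            for src in ("vostrain", "suvr", "nongaseous"):
                plist = prof_store.get((level, cond, src), [])
                if not plist:
                    continue
                gp = group_profile(plist, source=src)
                gprofs[(cond, src)] = gp
                cond_rep["profiles"][src] = {
                    "gravitational_max": gp.gravitational_max,
                    "n_subjects": len(plist),
                }
                for li, (m, se, n) in enumerate(
                    zip(gp.layer_mean, gp.layer_se, gp.layer_n), start=1
                ):
                    profile_rows.append(
                        {
                            "level": level,
                            "condition": cond,
                            "source": src,
                            "layer": li,
                            "mean": m,
                            "se": se,
                            "n_subjects": int(n),
                        }
                    )
                if src in ("vostrain", "suvr"):
                    cond_rep["fits"][src] = _fit_to_dict(
                        fit_central_quartiles(gp, config.fit_range)
                    )
            nongas = gprofs.get((cond, "nongaseous"))
            suvr_gp = gprofs.get((cond, "suvr"))
            if nongas is not None and suvr_gp is not None:
                cond_rep["fits"]["suvr_vs_nongaseous"] = _fit_to_dict(
                    suvr_vs_nongaseous_regression(suvr_gp, nongas, config.fit_range)
                )
            level_report["conditions"][cond] = cond_rep

        if two_groups:
            comp: dict = {}
            lo, hi = config.fit_range
            for src in ("vostrain", "suvr"):
                pts = {}
                for cond in conditions:
                    gp = gprofs[(cond, src)]
                    sel = (gp.layer_index >= lo) & (gp.layer_index <= hi) & (gp.layer_n > 0)
                    pts[cond] = (gp.layer_index[sel].astype(float), gp.layer_mean[sel])
                f_res = compare_regressions_F(
                    *pts[CONDITION_VILI], *pts[CONDITION_HEALTHY]
                )
                comp[f"{src}_regression_F"] = {
                    "F": f_res.statistic,
                    "p": f_res.p_value,
                    "df": list(f_res.df),
                }
            fits_v = level_report["conditions"][CONDITION_VILI]["fits"]["suvr_vs_nongaseous"]
            fits_h = level_report["conditions"][CONDITION_HEALTHY]["fits"]["suvr_vs_nongaseous"]
            z_res = slope_z_test(
                fits_v["slope"], fits_v["slope_se"], fits_h["slope"], fits_h["slope_se"]
            )
            comp["suvr_vs_nongaseous_slope_Z"] = {"Z": z_res.statistic, "p": z_res.p_value}
            for name in (
                "vostrain_mean",
                "vostrain_median",
                "suvr_mean",
                "suvr_median",
                "lmi",
            ):
                a = scalar_store[(level, CONDITION_VILI, name)]
                b = scalar_store[(level, CONDITION_HEALTHY, name)]
                w = wilcoxon_compare(a, b, paired=False)
                comp[f"{name}_ranksum"] = {
                    "statistic": w.statistic,
                    "p": w.p_value,
                    "mean_vili": float(np.mean(a)),
                    "mean_healthy": float(np.mean(b)),
                }
            level_report["comparisons"] = comp
        group[level] = level_report

    report: dict = {"levels": group}
    if two_groups:
        lmi_v = [v for lv in levels for v in scalar_store[(lv, CONDITION_VILI, "lmi")]]
        lmi_h = [v for lv in levels for v in scalar_store[(lv, CONDITION_HEALTHY, "lmi")]]
        w = wilcoxon_compare(lmi_v, lmi_h, paired=False)
        report["lmi_global"] = {
            "mean_vili": float(np.mean(lmi_v)),
            "sd_vili": float(np.std(lmi_v, ddof=1)),
            "mean_healthy": float(np.mean(lmi_h)),
            "sd_healthy": float(np.std(lmi_h, ddof=1)),
            "ranksum_p": w.p_value,
        }

    cfg = config.canonical_dict()
    report["provenance"] = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "strainpet_version": __version__,
        "numpy_version": np.__version__,
        "warnings": warnings_log,
    }

    profile_table = pd.DataFrame(profile_rows)
    subject_table.to_csv(out_dir / "subjects.csv", index=False)
    profile_table.to_csv(out_dir / "profiles.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return StudyReport(
        report=report,
        subject_table=subject_table,
        profile_table=profile_table,
        out_dir=out_dir,
    )
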