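"""End-to-end orchestration: phantom (or file bundle) -> input function ->
planar and SPECT quantification -> diagnostic report.

The processing order mirrors the acquisition protocol: the dynamic
first-pass series yields the input-function AUC, the static planar image
the H/M and planar uptake index, and the SPECT projections the polar-map
output function and SPECT uptake index.

Index scale convention: with ``scale="auto"`` (the default) both uptake
indices are normalized against a noiseless reference phantom of unit
myocardial concentration processed through the identical chain, so an
index value reads directly as a concentration in phantom units.  The
2D-3D conversion factor CF is estimated from the cohort's
(planar heart counts, SPECT polar-map counts) pairs — pooled over all
subjects by default, or from a designated calibration subset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import diagnostics, input_function, planar_quant, spect_quant
from .errors import FitFailed, MibgQuantError, NoBolusDetected, OneClassOnly
from .phantom import PhantomConfig, SubjectPhantom, make_cohort, make_dynamic_series, \
    make_myocardial_volume, make_planar_image, forward_project
from .spect_quant import CalibrationModel, ShortAxisGeometry

__all__ = ["RunConfig", "UptakeResult", "run_subject", "run_cohort", "reference_raw"]


@dataclass(frozen=True)
class RunConfig:
    """Cohort-run configuration; seeds and the config hash are embedded in
    every output for provenance."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_lbd: int = 37
    n_nonlbd: int = 40
    seed: int = 0
    subsets: int = 4
    iterations: int = 30
    rings: int = 10
    sectors: int = 36
    planar_scale: Union[str, float] = "auto"
    spect_scale: Union[str, float] = "auto"
    pooled_calibration: bool = True
    calibration_fraction: float = 0.5  # used when pooled_calibration is False


@dataclass
class UptakeResult:
    """Per-subject indices with provenance."""

    subject_id: str
    group: Optional[str] = None
    auc: Optional[float] = None
    hm: Optional[float] = None
    planar_index: Optional[float] = None
    spect_index: Optional[float] = None
    heart_mean: Optional[float] = None
    polar_mean: Optional[float] = None
    cf: Optional[float] = None
    planar_virtual: bool = False
    spect_virtual: bool = False
    error: Optional[str] = None


def _template_geometry(config: PhantomConfig) -> ShortAxisGeometry:
    c = config.myo_outer.center
    nz = config.volume_shape[0]
    return ShortAxisGeometry(
        center=tuple(float(v) for v in c),
        slice_range=(max(0, int(c[0]) - 14), min(nz - 1, int(c[0]) + 14)),
    )


def run_subject(
    subject: SubjectPhantom,
    config: RunConfig,
    calibration: Optional[CalibrationModel] = None,
    planar_scale: float = 1.0,
    spect_scale: float = 1.0,
) -> UptakeResult:
    """Quantify one subject: input function, then whichever of the planar
    and SPECT chains its image bundle supports.

    Missing modalities yield absent fields (never fabricated values).
    The SPECT index additionally requires a calibration model.  Input-
    function failures are re-raised with the subject id attached.
    """
    if subject.dynamic is None:
        raise ValueError(f"{subject.subject_id}: dynamic series required")
    res = UptakeResult(subject_id=subject.subject_id, group=subject.group)
    try:
        roi = input_function.detect_pa_roi(subject.dynamic)
        tac = input_function.extract_tac(subject.dynamic, roi)
        fit = input_function.fit_gamma_variate(tac)
    except (NoBolusDetected, FitFailed) as exc:
        raise type(exc)(f"{subject.subject_id}: {exc}") from exc
    res.auc = fit.auc

    if subject.planar is not None:
        rois = planar_quant.place_heart_roi(subject.planar)
        pq = planar_quant.planar_uptake_index(
            subject.planar, rois, res.auc, scale=planar_scale
        )
        res.hm = pq.hm
        res.heart_mean = pq.heart_mean
        res.planar_index = pq.index
        res.planar_virtual = pq.virtual

    if subject.projections is not None:
        recon = spect_quant.osem_reconstruct(
            subject.projections, subsets=config.subsets, iterations=config.iterations
        )
        sa, geom, virtual = spect_quant.reorient_short_axis(
            recon, template=_template_geometry(config.phantom)
        )
        pm = spect_quant.build_polar_map(sa, geom, rings=config.rings, sectors=config.sectors)
        res.polar_mean = pm.mean_counts
        res.spect_virtual = virtual
        if calibration is not None:
            sq = spect_quant.spect_uptake_index(
                pm, calibration, res.auc, scale=spect_scale, virtual=virtual
            )
            res.spect_index = sq.index
            res.cf = calibration.cf
    return res


def reference_raw(config: RunConfig) -> tuple[float, float]:
    """Raw planar and SPECT ratios of the noiseless unit-concentration
    reference phantom: (heart_mean / AUC, polar_mean / AUC).

    These normalize the index scales so a unit-concentration subject
    scores 1.0 on both indices.
    """
    ph_cfg = dataclasses.replace(config.phantom, noise=False)
    subj = SubjectPhantom(
        subject_id="REF",
        group="non-LBD",
        true_concentration=1.0,
        dynamic=make_dynamic_series(ph_cfg),
        planar=make_planar_image(ph_cfg, 1.0),
        projections=forward_project(
            make_myocardial_volume(ph_cfg, 1.0),
            n_views=ph_cfg.n_views,
            view_duration_s=ph_cfg.view_duration_s,
            count_scale=ph_cfg.projection_count_scale,
        ),
    )
    raw = run_subject(subj, config)
    return raw.heart_mean / raw.auc, raw.polar_mean / raw.auc


def run_cohort(
    config: RunConfig,
    subjects: Optional[Sequence[SubjectPhantom]] = None,
) -> tuple[diagnostics.CohortTable, diagnostics.DiagnosticReport, CalibrationModel]:
    """Simulate (or accept) a cohort, quantify every subject, calibrate CF,
    and evaluate diagnostic accuracy of H/M and both uptake indices.

    Subjects whose input-function fit fails are excluded from diagnostics
    and listed in the report.  Returns (table, report, calibration).
    """
    if subjects is None:
        subjects = make_cohort(
            config.n_lbd, config.n_nonlbd, seed=config.seed, config=config.phantom
        )
    raws: list[UptakeResult] = []
    excluded: list[str] = []
    for subj in subjects:
        try:
            raws.append(run_subject(subj, config))
        except (NoBolusDetected, FitFailed) as exc:
            excluded.append(f"{subj.subject_id}: {exc}")

    pairs = [
        (r.heart_mean, r.polar_mean)
        for r in raws
        if r.heart_mean is not None and r.polar_mean is not None
    ]
    if config.pooled_calibration:
        cal_pairs = pairs
    else:
        n_cal = max(3, int(len(pairs) * config.calibration_fraction))
        cal_pairs = pairs[:n_cal]
    calibration = spect_quant.calibrate_cf(
        [p[0] for p in cal_pairs], [p[1] for p in cal_pairs]
    )

    planar_ref, spect_ref = reference_raw(config)
    planar_scale = (
        1.0 / planar_ref if config.planar_scale == "auto" else float(config.planar_scale)
    )
    spect_scale = (
        calibration.cf / spect_ref
        if config.spect_scale == "auto"
        else float(config.spect_scale)
    )

    rows = []
    for r in raws:
        if r.heart_mean is not None:
            r.planar_index = planar_scale * r.heart_mean / r.auc
        if r.polar_mean is not None:
            r.spect_index = spect_scale * r.polar_mean / (calibration.cf * r.auc)
            r.cf = calibration.cf
        rows.append(
            {
                "subject": r.subject_id,
                "group": r.group,
                "hm": r.hm,
                "planar_index": r.planar_index,
                "spect_index": r.spect_index,
                "auc": r.auc,
                "planar_virtual": r.planar_virtual,
                "spect_virtual": r.spect_virtual,
            }
        )
    table = diagnostics.CohortTable(pd.DataFrame(rows))

    for group in (diagnostics.POSITIVE_GROUP, diagnostics.NEGATIVE_GROUP):
        if not (table.data["group"] == group).any():
            raise OneClassOnly(f"no subjects in group {group}")
    report = diagnostics.evaluate_cohort(table, excluded=excluded)
    return table, report, calibration
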