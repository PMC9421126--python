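"""End-to-end orchestration: cohort synthesis -> spectral preprocessing ->
baseline sweep and quantification -> hemodynamics -> linking statistics.

`run_pipeline` executes the stages in order under one master seed, returns
an in-memory result bundle, and (optionally) writes every report to an
output directory.  Stages communicate only through their returned
artifacts, so any stage can be re-run from written files.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.interpolate import CubicSpline

from . import hemodynamics as hemo
from . import io as mio
from . import lc_fit, mrs_prep, stats_link, synthetic
from .types import (
    AcquisitionSpec,
    BaselineConfig,
    BoldDesign,
    CohortSpec,
    DriftModel,
    SegmentScheme,
)

log = logging.getLogger("megabold")

__all__ = ["PipelineConfig", "run_pipeline", "validate_io_roundtrip"]


class PipelineConfig(BaseModel):
    """Everything the pipeline needs, in one validated structure."""

    cohort: CohortSpec = Field(default_factory=CohortSpec)
    acq: AcquisitionSpec = Field(default_factory=AcquisitionSpec)
    bold: BoldDesign = Field(default_factory=BoldDesign)
    voxel_grid: tuple[int, int, int] = (8, 8, 8)
    sweep: tuple[float | None, ...] = lc_fit.DEFAULT_SWEEP
    fit_window: tuple[float, float] = (1.9, 4.2)
    mrs_noise_sd: float = Field(default=100.0, ge=0)
    bold_noise_sd: float = Field(default=0.2, ge=0)
    voxel_p: float = Field(default=0.01, gt=0, lt=1)
    fwe_rate: float = Field(default=0.05, gt=0, lt=1)
    n_null: int = Field(default=500, ge=40)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    bonferroni_m: int = Field(default=3, ge=1)
    seed: int = 0
    out_dir: str | None = None


def _prep_subject(subject, basis, config):
    """Synthesize and preprocess one subject's spectra; returns the DIFF
    spectrum, water amplitude, and QC report."""
    series, water = synthetic.synthesize_megapress_fids(
        subject, basis, config.acq,
        drift_model=DriftModel(),
        noise_sd=config.mrs_noise_sd,
        seed=config.seed,
    )
    drift, corrected = mrs_prep.spectral_register(series)
    keep = mrs_prep.reject_transients(drift, edit_labels=series.edit_labels)
    diff, off_avg = mrs_prep.average_and_difference(corrected, keep)
    qc = mrs_prep.estimate_linewidth(
        off_avg, config.acq, n_rejected=diff.n_rejected
    )
    w_spec = mrs_prep.fid_to_spectrum(water.fids.mean(axis=0), config.acq)
    w_amp = lc_fit.water_amplitude(w_spec, mrs_prep.ppm_axis(config.acq))
    return diff, w_amp, qc


def _hrf_stage(subject, config):
    """Synthesize BOLD, deconvolve the 48-s HRF, and summarise it."""
    ds = synthetic.synthesize_bold_dataset(
        subject, config.bold,
        voxel_grid=config.voxel_grid,
        noise_sd=config.bold_noise_sd,
        seed=config.seed,
        coupling=config.cohort.coupling_coeffs,
    )
    taps, avg = hemo.deconvolve_hrf(
        ds.runs, list(ds.truth["stimulus"]), config.bold
    )
    avg = hemo.interpolate_hrf(avg)
    metrics = hemo.hrf_peak_metrics(avg)
    # per-voxel interpolation for segment energetics
    cs = CubicSpline(avg.times, taps, axis=0)
    fine_t = avg.fine_times
    curves = cs(fine_t).T                     # (V, 97)
    energetics = hemo.segment_energetics(curves, fine_t)
    return ds, taps, avg, metrics, energetics


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns the result bundle."""
    stage = "cohort"
    subj_id = None
    try:
        log.info("stage=cohort seed=%d", config.seed)
        cohort = synthetic.generate_cohort(
            config.cohort.model_copy(update={"seed": config.seed})
        )
        if len(cohort) < 4:
            raise ValueError("pipeline needs at least 2 subjects per group")
        basis = synthetic.generate_basis(config.acq)

        stage = "mrs_prep"
        diffs, water_amps, qcs = [], [], []
        for s in cohort:
            subj_id = s.subject_id
            diff, w_amp, qc = _prep_subject(s, basis, config)
            diffs.append(diff)
            water_amps.append(w_amp)
            qcs.append(qc)
        subj_id = None

        stage = "lc_fit"
        log.info("stage=lc_fit sweep=%s", list(config.sweep))
        sweep_table, selection = lc_fit.sweep_and_select(
            diffs, basis, configs=tuple(config.sweep),
            fit_window=config.fit_window,
        )
        chosen = selection["recommended"]
        chosen_cfg = BaselineConfig(
            dkntmn=None if chosen == "noBline" else float(chosen),
            fit_window=config.fit_window,
        )
        quantified = []
        for s, diff, w_amp in zip(cohort, diffs, water_amps):
            subj_id = s.subject_id
            fit = lc_fit.fit_linear_combination(diff, basis, chosen_cfg)
            quantified.append(lc_fit.quantify(fit, w_amp, s.f_csf))
        subj_id = None

        stage = "hemodynamics"
        log.info("stage=hemodynamics grid=%s", config.voxel_grid)
        rows, z_by_seg, cbf_maps = [], [[], [], []], []
        affine = None
        for s, q, qc in zip(cohort, quantified, qcs):
            subj_id = s.subject_id
            ds, taps, avg, metrics, energ = _hrf_stage(s, config)
            affine = ds.affine
            cbf_maps.append(ds.cbf.ravel())
            for k in range(3):
                z_by_seg[k].append(energ.z[k])
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "Age": s.age,
                    "GABA": q.gaba_h2o,
                    "Glx": q.glx_h2o,
                    "creatine_linewidth_hz": qc.creatine_linewidth,
                    "qc_pass": qc.passed,
                    "amplitude": metrics.amplitude,
                    "ttp": metrics.ttp,
                    "fwhm": metrics.fwhm,
                }
            )
        subj_id = None
        cbf_mat = np.array(cbf_maps)

        stage = "neurosensitize"
        seg_maps = {}
        for k in range(3):
            z = np.array(z_by_seg[k])
            sens, _ = hemo.neurosensitize(z, cbf_mat)
            seg_maps[k] = {"unsensitized": z, "neurosensitized": sens}
            for i, r in enumerate(rows):
                r[f"zauc_seg{k + 1}"] = float(z[i].mean())
                r[f"zauc_seg{k + 1}_ns"] = float(sens[i].mean())
        table = pd.DataFrame(rows)

        stage = "parcellate"
        groups = {g: table.index[table["group"] == g].to_numpy()
                  for g in ("young", "old")}
        parcellation = {}
        for k in range(3):
            for g, idx in groups.items():
                maps = seg_maps[k]["unsensitized"][idx].reshape(
                    (len(idx),) + tuple(config.voxel_grid)
                )
                res = hemo.parcellate(
                    maps, affine,
                    voxel_p=config.voxel_p,
                    fwe_rate=config.fwe_rate,
                    n_null=config.n_null,
                    seed=config.seed,
                )
                parcellation[f"seg{k + 1}-{g}"] = res

        stage = "stats"
        young = table[table["group"] == "young"]
        old = table[table["group"] == "old"]
        group_stats = {
            "GABA": stats_link.group_difference(young["GABA"], old["GABA"]),
            "Glx": stats_link.group_difference(young["Glx"], old["Glx"]),
        }
        responses = ["amplitude", "ttp", "fwhm"] + [
            c for c in table.columns if c.startswith("zauc_")
        ]
        # fit only the models this sample size supports (n >= p + 2)
        feasible = {
            name: terms
            for name, terms in stats_link.MODEL_TERMS.items()
            if len(table) >= len(terms) + 3
        }
        if not feasible:
            raise ValueError("cohort too small for any regression model")
        model_report = []
        for resp in responses:
            fits = stats_link.fit_model_suite(table, resp, models=feasible)
            best = fits[0]
            for _, row in best.params.iterrows():
                model_report.append(
                    {
                        "response": resp,
                        "best_model": best.name,
                        "R2": best.rsquared,
                        "adj_R2": best.rsquared_adj,
                        "F": best.fvalue,
                        "p": best.f_pvalue,
                        "model_flag": best.flag,
                        "term": row["term"],
                        "beta": row["beta"],
                        "t": row["t"],
                        "term_p": row["p"],
                    }
                )
        model_table = pd.DataFrame(model_report)
        corrected_alpha = stats_link.bonferroni_alpha(
            0.01, config.bonferroni_m
        )

        bundle = {
            "config": config.model_dump(),
            "cohort": table,
            "sweep_table": sweep_table,
            "selection": selection,
            "group_stats": group_stats,
            "model_table": model_table,
            "parcellation": {
                key: {
                    "n_clusters": len(res.clusters),
                    "extent_threshold": res.cluster_extent_threshold,
                    "clusters": [
                        {
                            "size": c.size,
                            "centroid_mm": list(c.centroid_mm),
                            "label": c.label,
                            "peak_t": c.peak_t,
                        }
                        for c in res.clusters
                    ],
                }
                for key, res in parcellation.items()
            },
            "corrected_alpha": corrected_alpha,
        }
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}"
            + (f" (subject {subj_id})" if subj_id else "")
        ) from err

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mio.write_table(out / "cohort.tsv", table)
        mio.write_table(out / "sweep.tsv", sweep_table)
        mio.write_table(out / "model_report.tsv", model_table)
        mio.write_json(out / "selection.json", selection)
        mio.write_json(out / "group_stats.json", group_stats)
        mio.write_json(out / "parcellation.json", bundle["parcellation"])
        mio.write_json(
            out / "config.json",
            config.model_dump(mode="json"),
        )
    return bundle


# ---------------------------------------------------------------------------
# round-trip validation
# ---------------------------------------------------------------------------

def _arrays_equal(a, b) -> bool:
    a = np.asarray(a)
    b = np.asarray(b)
    return a.shape == b.shape and np.array_equal(a, b)


def validate_io_roundtrip(paths: dict[str, str | Path]) -> dict:
    """Check every writer/reader pair: each file is parsed, re-written, and
    re-parsed; the two in-memory objects must be equal.

    ``paths`` maps a kind ("fid", "diff", "nifti", "table", "json") to a
    file of that kind.  Returns a per-file report; mismatches carry diffs.
    """
    report = {}
    with tempfile.TemporaryDirectory() as tmp:
        for kind, path in paths.items():
            path = Path(path)
            entry = {"path": str(path), "ok": False}
            try:
                if kind == "fid":
                    a = mio.read_fid_series(path)
                    mio.write_fid_series(Path(tmp) / "f.txt", a)
                    b = mio.read_fid_series(Path(tmp) / "f.txt")
                    entry["ok"] = (
                        _arrays_equal(a.fids, b.fids)
                        and list(a.edit_labels) == list(b.edit_labels)
                        and a.acq == b.acq
                    )
                elif kind == "diff":
                    a = mio.read_diff_spectrum(path)
                    mio.write_diff_spectrum(Path(tmp) / "d.txt", a)
                    b = mio.read_diff_spectrum(Path(tmp) / "d.txt")
                    entry["ok"] = (
                        _arrays_equal(a.values, b.values)
                        and a.n_kept == b.n_kept
                        and a.n_rejected == b.n_rejected
                    )
                elif kind == "nifti":
                    data, aff = mio.read_nifti(path)
                    mio.write_nifti(Path(tmp) / "v.nii", data, aff)
                    d2, a2 = mio.read_nifti(Path(tmp) / "v.nii")
                    entry["ok"] = _arrays_equal(data, d2) and \
                        _arrays_equal(aff, a2)
                elif kind == "table":
                    a = mio.read_table(path)
                    mio.write_table(Path(tmp) / "t.tsv", a)
                    b = mio.read_table(Path(tmp) / "t.tsv")
                    entry["ok"] = a.equals(b)
                    if not entry["ok"]:
                        entry["diff"] = str(a.compare(b))
                elif kind == "json":
                    a = mio.read_json(path)
                    mio.write_json(Path(tmp) / "j.json", a)
                    entry["ok"] = a == mio.read_json(Path(tmp) / "j.json")
                else:
                    entry["error"] = f"unknown kind {kind!r}"
            except Exception as err:   # report, don't abort the sweep
                entry["error"] = str(err)
            report[kind] = entry
    report["ok"] = all(e.get("ok") for e in report.values()
                       if isinstance(e, dict))
    return report
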