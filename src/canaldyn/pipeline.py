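"""End-to-end analysis driver: filter → average → PCA → align → statistics.

``run_pipeline`` reproduces the full per-cohort analysis: responsiveness
filtering, trial averaging, per-individual latent models, canonical mode
ordering of the control group, alignment of every other group to the
control reference, stereotypy statistics (trial-to-trial, leave-one-out /
reference correlations, within-group pairwise, group-average cross
correlations, pooled distributions), per-neuron tuning tables, and the
group-comparison tests, writing tidy CSV/JSON reports plus a structured
log of seeds and versions.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import RunConfig, read_cohort
from .latent import ModeSet, align_to_reference, canonical_order, fit_latent
from .stats import dunn_pairwise, dunnett_many_to_one
from .stereotypy import (
    StereotypyReport,
    group_average_and_compare,
    pairwise_within_group,
    pooled_distribution,
    reference_correlations,
    trial_consistency,
)
from .synthetic import TraceSet
from .traces import filter_responsive, trial_average
from .tuning import direction_histogram, tuning_table


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("analyze_group")
def analyze_group(cohort: list[TraceSet], config: RunConfig) -> dict:
    """Per-individual filter → trial average → latent model → trial-averaged modes."""
    out = {"fish_ids": [], "filtered": [], "models": [], "modesets": [], "tuning": []}
    for ts in sorted(cohort, key=lambda t: t.fish_id):
        fts = filter_responsive(ts, config.z_thresh)
        ta = trial_average(fts)
        model = fit_latent(ta, config.k)
        out["fish_ids"].append(ts.fish_id)
        out["filtered"].append(fts)
        out["models"].append(model)
        out["modesets"].append(
            ModeSet(modes=model.dynamics, fish_id=ts.fish_id, trial="trial-averaged")
        )
        out["tuning"].append(tuning_table(ta, dsi_threshold=config.dsi_threshold))
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis for a control cohort and any comparison groups.

    Returns a results dictionary and writes tidy CSV/JSON reports to
    ``out_dir`` (or ``config.out_dir``).
    """
    out_path = Path(out_dir if out_dir is not None else config.out_dir)
    out_path.mkdir(parents=True, exist_ok=True)

    try:
        control = read_cohort(config.control_path)
    except Exception as exc:
        raise PipelineError(f"stage 'read_control' failed: {exc}") from exc
    groups = {}
    for label, path in config.group_paths.items():
        try:
            groups[label] = read_cohort(path)
        except Exception as exc:
            raise PipelineError(f"stage 'read_group:{label}' failed: {exc}") from exc

    ctrl = analyze_group(control, config)
    aligned_ctrl, reference = canonical_order(ctrl["modesets"], config.reference_policy)

    reports: dict[str, StereotypyReport] = {}
    t2t = np.stack(
        [trial_consistency(f, m) for f, m in zip(ctrl["filtered"], ctrl["models"])]
    )
    ctrl_report = StereotypyReport(
        group="control",
        fish_ids=ctrl["fish_ids"],
        trial_to_trial_rbar=t2t,
        r_to_reference=reference_correlations(aligned_ctrl, loo=True),
        pairwise_r=pairwise_within_group(aligned_ctrl) if len(aligned_ctrl) > 1 else None,
        group_average=reference,
    )
    if ctrl_report.pairwise_r is not None:
        ctrl_report.pooled_r, _ = pooled_distribution(ctrl_report.pairwise_r)
    reports["control"] = ctrl_report

    tuning_frames = [pd.concat(ctrl["tuning"], ignore_index=True).assign(group="control")]
    for label, cohort in groups.items():
        res = analyze_group(cohort, config)
        aligned = align_to_reference(res["modesets"], reference)
        rep = StereotypyReport(
            group=label,
            fish_ids=res["fish_ids"],
            trial_to_trial_rbar=np.stack(
                [trial_consistency(f, m) for f, m in zip(res["filtered"], res["models"])]
            ),
            r_to_reference=reference_correlations(aligned, aligned_ctrl, loo=False),
            pairwise_r=pairwise_within_group(aligned) if len(aligned) > 1 else None,
        )
        _, _, rep.cross_group_r = group_average_and_compare(aligned_ctrl, aligned)
        if rep.pairwise_r is not None:
            rep.pooled_r, _ = pooled_distribution(rep.pairwise_r)
        reports[label] = rep
        tuning_frames.append(pd.concat(res["tuning"], ignore_index=True).assign(group=label))

    # group-comparison tests on pooled pairwise-r distributions
    tests = {}
    pooled = {g: r.pooled_r for g, r in reports.items() if r.pooled_r is not None}
    if len(pooled) >= 2 and "control" in pooled:
        labels = [g for g in pooled if g != "control"]
        dunnett = dunnett_many_to_one(
            [pooled[g] for g in labels], pooled["control"], labels=labels
        )
        dunn = dunn_pairwise(list(pooled.values()), labels=list(pooled.keys()))
        tests = {
            "dunnett": dict(
                comparisons=dunnett.comparisons,
                statistic=dunnett.statistic.tolist(),
                p_value=dunnett.p_value.tolist(),
            ),
            "dunn": dict(
                comparisons=dunn.comparisons,
                statistic=dunn.statistic.tolist(),
                p_value=dunn.p_value.tolist(),
                adjustment=dunn.adjustment,
            ),
        }

    # ---- reports on disk -------------------------------------------------
    stereo = pd.concat([r.to_frame() for r in reports.values()], ignore_index=True)
    stereo.to_csv(out_path / "stereotypy.csv", index=False, float_format="%.9g")
    tuning_all = pd.concat(tuning_frames, ignore_index=True)
    tuning_all.to_csv(out_path / "tuning.csv", index=False, float_format="%.9g")
    hist_rows = []
    protocol = control[0].protocol
    for label, frame in tuning_all.groupby("group"):
        h = direction_histogram(frame, np.asarray(protocol.directions_deg), group=label)
        for c, n, f in zip(h.bin_centers_deg, h.counts, h.fractions):
            hist_rows.append(dict(group=label, bin_center_deg=c, count=int(n), fraction=f))
    pd.DataFrame(hist_rows).to_csv(out_path / "direction_histograms.csv", index=False,
                                   float_format="%.9g")
    summary = {
        "groups": {
            g: {
                "n_fish": len(r.fish_ids),
                "mean_trial_to_trial_r": (
                    None if r.trial_to_trial_rbar is None
                    else r.trial_to_trial_rbar.mean(axis=0).tolist()
                ),
                "mean_r_to_reference": (
                    None if r.r_to_reference is None else r.r_to_reference.mean(axis=0).tolist()
                ),
                "pooled_median_r": (None if r.pooled_r is None else float(np.median(r.pooled_r))),
                "cross_group_r": (
                    None if r.cross_group_r is None else r.cross_group_r.tolist()
                ),
            }
            for g, r in reports.items()
        },
        "tests": tests,
    }
    (out_path / "summary.json").write_text(json.dumps(summary, indent=1))
    log = {
        "canaldyn_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
    }
    (out_path / "run_log.json").write_text(json.dumps(log, indent=1))
    return {"reports": reports, "reference": reference, "tests": tests, "summary": summary}
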