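"""End-to-end orchestration: simulate/ingest -> idealize -> summarize -> growth.

``run_pipeline`` executes the full chain for a genotype panel and writes the
per-genotype summary, growth fold changes, the WT-anchored classification,
correlation coefficients, and the multilinear growth model to ``out_dir``.
Every applied default (fit range, timepoint, feature) is logged.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as scio
from .chanparams import build_relations, summarize_channel
from .growthcorr import (
    classify_vs_wt,
    fold_change_summary,
    multilinear_r2,
    pearson_r,
    _replicate_folds,
    ttest_vs_wt,
)
from .gatingsim import make_panel
from .idealize import estimate_amplitude, estimate_baseline, hinkley_detect, open_probability

logger = logging.getLogger("singlechan")

_FEATURE_COLUMN = {
    "activity_meas": "activity_meas_pA",
    "activity_true": "activity_true_pA",
    "activity_p140": "activity_p140_pA",
    "i_meas": "i_meas_m140_pA",
    "po": "po_m140",
}


def idealize_recording(recording, detector) -> list[tuple[float, float, float]]:
    """Per-voltage (voltage, i_meas, P_O) from one recording."""
    results = []
    for voltage, trace in zip(recording.voltages, recording.traces):
        baseline = estimate_baseline(trace)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            events = hinkley_detect(trace, baseline, detector)
            if events.n_events == 0:
                po, i_meas = 0.0, float("nan")
            else:
                po = open_probability(events)
                i_meas = estimate_amplitude(trace, events, baseline, detector)
        results.append((voltage, i_meas, po))
    return results


def run_pipeline(config: scio.RunConfig) -> dict:
    """Execute all stages and return the analysis report (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info(
        "settings: fit range %g..%g mV, activity voltage %g mV, timepoint %g h, "
        "feature %s, welch=%s, holm=%s",
        config.fit_lo, config.fit_hi, config.activity_voltage,
        config.timepoint, config.feature, config.welch, config.holm,
    )
    out_dir = Path(config.out_dir)

    # stage 1: simulate the panel
    try:
        panel = make_panel(
            config.panel,
            config.protocol,
            config.acquisition,
            config.growth_model,
            seed=config.seed,
            activity_voltage=config.activity_voltage,
            n_replicates=config.n_replicates,
        )
    except Exception as err:
        raise RuntimeError(f"stage simulate failed: {err}") from err
    logger.info("simulated %d genotypes x %d voltages",
                len(panel.recordings), len(config.protocol.voltages))

    # stage 2+3: idealize and summarize
    summaries = []
    failed_fits: list[str] = []
    all_events = []
    try:
        for label, recording in panel.recordings.items():
            results = idealize_recording(recording, config.detector)
            iv, povr = build_relations(results)
            try:
                summaries.append(
                    summarize_channel(
                        label, iv, povr,
                        v_lo=config.fit_lo, v_hi=config.fit_hi,
                        activity_voltage=config.activity_voltage,
                    )
                )
            except (ValueError, KeyError) as err:
                # too few resolvable open events for an i/V fit (short record
                # or very low P_O): keep the genotype as a missing-value row
                logger.warning("no i/V fit for %s: %s", label, err)
                failed_fits.append(label)
            if config.write_traces:
                for voltage, trace in zip(recording.voltages, recording.traces):
                    baseline = estimate_baseline(trace)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        all_events.append(hinkley_detect(trace, baseline, config.detector))
    except Exception as err:
        raise RuntimeError(f"stage idealize/summarize failed: {err}") from err
    logger.info("summarized %d genotypes (%d without i/V fit)",
                len(summaries) + len(failed_fits), len(failed_fits))
    summary_frame = scio.summaries_to_frame(summaries)
    if failed_fits:
        nan_rows = pd.DataFrame(
            [
                {c: (label if c == "genotype" else np.nan)
                 for c in summary_frame.columns}
                for label in failed_fits
            ]
        )
        summary_frame = pd.concat([summary_frame, nan_rows], ignore_index=True)
    order = [e.model.genotype_label for e in config.panel]
    summary_frame = (
        summary_frame.set_index("genotype").loc[order].reset_index()
    )

    # stage 4: growth
    try:
        if config.growth_file is not None:
            growth_table = scio.read_growth_csv(config.growth_file)
        else:
            growth_table = panel.growth
        folds = fold_change_summary(growth_table, times=[24.0, 48.0])
    except Exception as err:
        raise RuntimeError(f"stage growth failed: {err}") from err

    # stage 5: correlation, t-tests, classification, multilinear model
    try:
        report = analyze(
            summary_frame,
            growth_table,
            folds,
            wt_label=panel.wt_label,
            timepoint=config.timepoint,
            feature=config.feature,
            welch=config.welch,
            holm=config.holm,
        )
    except Exception as err:
        raise RuntimeError(f"stage analysis failed: {err}") from err

    report["n_genotypes"] = len(summary_frame)
    report["genotypes_without_fit"] = failed_fits
    report["settings"] = {
        "seed": config.seed,
        "fit_range_mV": [config.fit_lo, config.fit_hi],
        "activity_voltage_mV": config.activity_voltage,
        "timepoint_h": config.timepoint,
        "feature": config.feature,
        "welch": config.welch,
        "holm": config.holm,
    }
    manifest = scio.write_outputs(
        out_dir,
        traces=[t for r in panel.recordings.values() for t in r.traces]
        if config.write_traces else (),
        events=all_events,
        growth=growth_table,
        report=report,
    )
    summary_frame.to_csv(out_dir / "summary.tsv", sep="\t", index=False,
                         float_format="%.6g")
    folds.table.to_csv(out_dir / "growth_folds.tsv", sep="\t", index=False,
                       float_format="%.6g")
    logger.info("wrote %d files to %s", len(manifest) + 1, out_dir)
    return report


def analyze(
    summary: pd.DataFrame,
    growth_table: pd.DataFrame,
    folds,
    wt_label: str,
    timepoint: float = 48.0,
    feature: str = "activity_meas",
    welch: bool = False,
    holm: bool = False,
) -> dict:
    """Correlation/classification/multilinear analysis of a summary table."""
    column = _FEATURE_COLUMN[feature]
    genotypes = list(summary["genotype"])
    features = dict(zip(genotypes, summary[column].astype(float)))
    growth = {g: folds.at(g, timepoint) for g in genotypes}

    # Pearson r between |feature| and growth across genotypes
    feats = np.array([abs(features[g]) for g in genotypes])
    folds_vec = np.array([growth[g] for g in genotypes])
    ok = np.isfinite(feats) & np.isfinite(folds_vec)
    r = pearson_r(feats[ok], folds_vec[ok]) if np.count_nonzero(ok) >= 3 else float("nan")

    # per-mutant t-tests against WT replicate fold changes
    wt_folds = _replicate_folds(growth_table, wt_label, timepoint)
    pvals, labels = [], []
    for g in genotypes:
        if g == wt_label:
            continue
        mut_folds = _replicate_folds(growth_table, g, timepoint)
        p, _ = ttest_vs_wt(mut_folds, wt_folds, welch=welch)
        pvals.append(p)
        labels.append(g)
    if holm and pvals:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(pvals, alpha=0.05, method="holm")
        significant = dict(zip(labels, (bool(x) for x in reject)))
        pvals_out = dict(zip(labels, (float(x) for x in p_adj)))
    else:
        significant = {g: p < 0.05 for g, p in zip(labels, pvals)}
        pvals_out = dict(zip(labels, (float(p) for p in pvals)))

    # genotypes without a usable feature value cannot be placed in a quadrant
    classifiable = {g: v for g, v in features.items() if np.isfinite(v)}
    if wt_label in classifiable:
        outcomes, counts = classify_vs_wt(classifiable, growth, wt_label,
                                          feature=feature)
    else:
        outcomes, counts = [], {"concordant": 0, "discordant": 0,
                                "tie-excluded": 0}

    # multilinear model of growth on (i, P_O, i x P_O)
    i_vec = summary["i_meas_m140_pA"].to_numpy(dtype=float)
    po_vec = summary["po_m140"].to_numpy(dtype=float)
    ok3 = np.isfinite(i_vec) & np.isfinite(po_vec) & np.isfinite(folds_vec)
    if np.count_nonzero(ok3) >= 5:
        fit = multilinear_r2(folds_vec[ok3], np.abs(i_vec[ok3]), po_vec[ok3])
        r2 = fit.r2
    else:
        r2 = float("nan")

    return {
        "wt_label": wt_label,
        "pearson_r": r,
        "timepoint_h": timepoint,
        "feature": feature,
        "classification": {
            o.genotype: {
                "feature_relation": o.feature_relation,
                "growth_relation": o.growth_relation,
                "call": o.call,
            }
            for o in outcomes
        },
        "classification_counts": counts,
        "t_test_p": pvals_out,
        "t_test_significant": significant,
        "multilinear_r2": r2,
    }
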