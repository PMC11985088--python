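"""Plain-text readers and writers for traces, events, summaries, and growth.

All formats are locale-independent TSV/CSV with period decimal separators
and fixed column order.  Currents are written with 6 significant digits and
probabilities with 6 decimals; writers never embed timestamps, so re-running
with identical inputs reproduces byte-identical files.

Trace TSV dialect::

    # genotype = WT
    # voltage_mV = -140
    # fs_hz = 5000
    # filter_hz = 1000
    time_s<TAB>current_pA
    0.000000<TAB>-0.12345

``fs_hz`` is required on read; the time column must be monotone and is
checked against the declared rate (warning above 0.1 % mismatch).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chanparams import ChannelSummary
from .gatingsim import (
    AcquisitionConfig,
    DwellSequence,
    GatingModel,
    GrowthModel,
    PanelEntry,
    VoltageProtocol,
    slow_gate_model,
    _WT_FLICKER,
)
from .idealize import DetectorConfig, EventTable
from .trace import Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "write_dwells",
    "read_growth_csv",
    "write_growth_csv",
    "write_summaries",
    "read_summaries",
    "write_outputs",
    "RunConfig",
    "load_config",
]

_FMT_CURRENT = "%.6g"
_FMT_PROB = "%.6f"


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def write_trace(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    if trace.genotype is not None:
        lines.append(f"# genotype = {trace.genotype}")
    if trace.voltage is not None:
        lines.append(f"# voltage_mV = {trace.voltage:g}")
    lines.append(f"# fs_hz = {trace.fs:g}")
    if trace.filter_cutoff is not None:
        lines.append(f"# filter_hz = {trace.filter_cutoff:g}")
    lines.append("time_s\tcurrent_pA")
    t = trace.times()
    for k in range(trace.n_samples):
        lines.append(f"{t[k]:.6f}\t{trace.samples[k]:.6g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_trace(path: str | Path) -> Trace:
    """Read a trace TSV written by :func:`write_trace` (or by hand)."""
    path = Path(path)
    header: list[str] = []
    times: list[float] = []
    currents: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                header.append(line)
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                currents.append(float(parts[1]))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric cell") from err
    meta = _parse_header(header)
    if "fs_hz" not in meta:
        raise ValueError(f"{path}: missing required metadata key fs_hz")
    fs = float(meta["fs_hz"])
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    if t.size >= 2:
        dt = float(np.median(np.diff(t)))
        if abs(dt * fs - 1.0) > 1e-3:
            warnings.warn(
                f"{path}: median time step {dt} s deviates >0.1% from 1/fs_hz",
                stacklevel=2,
            )
    extra = {
        k: float(v) if k == "filter_hz" else v
        for k, v in meta.items()
        if k not in {"genotype", "voltage_mV", "fs_hz"}
    }
    return Trace(
        np.asarray(currents),
        fs=fs,
        voltage=float(meta["voltage_mV"]) if "voltage_mV" in meta else None,
        genotype=meta.get("genotype"),
        meta=extra,
    )


# ---------------------------------------------------------------------------
# event tables and truth dwells
# ---------------------------------------------------------------------------


def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for key in (
        "genotype",
        "voltage_mV",
        "closed_level_pA",
        "noise_sd_pA",
        "open_level_pA",
        "order",
        "threshold_lambda",
        "dead_time_s",
        "edge_margin",
    ):
        if key in events.meta and events.meta[key] is not None:
            lines.append(f"# {key} = {events.meta[key]:g}" if isinstance(
                events.meta[key], float) else f"# {key} = {events.meta[key]}")
    lines.append(f"# t_total_s = {events.t_total:.6f}")
    for flag in events.flags:
        lines.append(f"# flag = {flag}")
    lines.append("event_index\tstate\tstart_s\tduration_s\tamplitude_pA")
    for k in range(events.n_events):
        state = "open" if events.states[k] else "closed"
        amp = "nan" if not np.isfinite(events.amplitudes[k]) else f"{events.amplitudes[k]:.6g}"
        lines.append(
            f"{k}\t{state}\t{events.starts[k]:.6f}\t{events.durations[k]:.6f}\t{amp}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_events(path: str | Path) -> EventTable:
    path = Path(path)
    header: list[str] = []
    rows: list[tuple[str, float, float, float]] = []
    flags: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("flag"):
                    flags.append(body.partition("=")[2].strip())
                else:
                    header.append(line)
                continue
            if line.startswith("event_index"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            rows.append((parts[1], float(parts[2]), float(parts[3]), float(parts[4])))
    meta_raw = _parse_header(header)
    meta: dict = {}
    for key, value in meta_raw.items():
        if key == "genotype":
            meta[key] = value
        else:
            try:
                meta[key] = float(value)
            except ValueError:
                meta[key] = value
    t_total = float(meta.pop("t_total_s", sum(r[2] for r in rows)))
    return EventTable(
        states=np.array([r[0] == "open" for r in rows], dtype=bool),
        starts=np.array([r[1] for r in rows]),
        durations=np.array([r[2] for r in rows]),
        t_total=t_total,
        amplitudes=np.array([r[3] for r in rows]),
        flags=flags,
        meta=meta,
    )


def write_dwells(dwells: DwellSequence, path: str | Path) -> Path:
    """Ground-truth dwell table: conducting_flag, start_s, duration_s."""
    path = Path(path)
    lines = [f"# total_duration_s = {dwells.total_duration:.6f}",
             "conducting_flag\tstart_s\tduration_s"]
    start = 0.0
    for k in range(dwells.states.size):
        lines.append(
            f"{int(dwells.states[k])}\t{start:.6f}\t{dwells.durations[k]:.6f}"
        )
        start += dwells.durations[k]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# growth tables and summaries
# ---------------------------------------------------------------------------


def write_growth_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6g")
    return path


def read_growth_csv(path: str | Path) -> pd.DataFrame:
    from .growthcorr import validate_growth_table

    table = pd.read_csv(path)
    return validate_growth_table(table)


_SUMMARY_COLUMNS = [
    "genotype",
    "g_pS",
    "fit_lo_mV",
    "fit_hi_mV",
    "mean_po",
    "po_m140",
    "i_meas_m140_pA",
    "i_true_m140_pA",
    "activity_meas_pA",
    "activity_true_pA",
    "activity_p140_pA",
    "n",
]


def summaries_to_frame(summaries: list[ChannelSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "genotype": s.genotype_label,
                "g_pS": s.g,
                "fit_lo_mV": s.fit_range[0],
                "fit_hi_mV": s.fit_range[1],
                "mean_po": s.mean_po,
                "po_m140": s.po_minus140,
                "i_meas_m140_pA": s.i_meas_minus140,
                "i_true_m140_pA": s.i_true_minus140,
                "activity_meas_pA": s.activity_meas,
                "activity_true_pA": s.activity_true,
                "activity_p140_pA": s.activity_pos,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def write_summaries(summaries: list[ChannelSummary], path: str | Path) -> Path:
    path = Path(path)
    summaries_to_frame(summaries).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    return path


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_outputs(
    out_dir: str | Path,
    traces: list[Trace] = (),
    events: list[EventTable] = (),
    summaries: list[ChannelSummary] = (),
    growth: pd.DataFrame | None = None,
    report: dict | None = None,
) -> list[Path]:
    """Write a set of result objects with deterministic file names.

    Returns the manifest of written paths; an empty input writes nothing.
    File contents carry no timestamps, so identical inputs overwrite
    byte-identically.
    """
    out_dir = Path(out_dir)
    manifest: list[Path] = []
    if traces or events or summaries or growth is not None or report is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for trace in traces:
        name = f"{trace.genotype or 'trace'}_{trace.voltage:+g}mV.trace.tsv"
        manifest.append(write_trace(trace, out_dir / name))
    for table in events:
        genotype = table.meta.get("genotype", "trace")
        voltage = table.meta.get("voltage_mV", 0.0)
        name = f"{genotype}_{voltage:+g}mV.events.tsv"
        manifest.append(write_events(table, out_dir / name))
    if summaries:
        manifest.append(write_summaries(list(summaries), out_dir / "summary.tsv"))
    if growth is not None:
        manifest.append(write_growth_csv(growth, out_dir / "growth.csv"))
    if report is not None:
        path = out_dir / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        manifest.append(path)
    return manifest


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated end-to-end pipeline configuration."""

    panel: list[PanelEntry]
    protocol: VoltageProtocol
    acquisition: AcquisitionConfig
    detector: DetectorConfig
    growth_model: GrowthModel
    seed: int = 0
    out_dir: str = "singlechan-out"
    log_level: str = "INFO"
    fit_lo: float = 0.0
    fit_hi: float = 100.0
    activity_voltage: float = -140.0
    timepoint: float = 48.0
    feature: str = "activity_meas"
    welch: bool = False
    holm: bool = False
    growth_file: str | None = None
    write_traces: bool = False
    n_replicates: int = 3

    def __post_init__(self) -> None:
        from .growthcorr import CURRENT_FEATURES

        if self.feature not in CURRENT_FEATURES | {"po"}:
            raise ValueError(
                f"unknown feature {self.feature!r}; choose one of "
                f"{sorted(CURRENT_FEATURES | {'po'})}"
            )
        if self.growth_file is not None and not Path(self.growth_file).exists():
            raise ValueError(f"growth file does not exist: {self.growth_file}")


def _panel_entry_from_dict(spec: dict) -> PanelEntry:
    for key in ("label", "g_pS", "po_m160"):
        if key not in spec:
            raise ValueError(f"panel entry misses required key {key!r}: {spec}")
    po_m160 = float(spec["po_m160"])
    po_p160 = float(spec.get("po_p160", min(0.9, po_m160 / 6.8)))
    model = slow_gate_model(
        str(spec["label"]),
        g_true=float(spec["g_pS"]),
        p_neg=po_m160,
        p_pos=po_p160,
        k_close0=float(spec.get("k_close0", 50.0)),
        flicker=_WT_FLICKER if spec.get("flicker", True) else None,
    )
    return PanelEntry(
        model,
        expression_factor=float(spec.get("expression_factor", 1.0)),
        is_wt=bool(spec.get("is_wt", False)),
    )


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load and validate a JSON run configuration.

    ``seed`` overrides the file's master seed (for CLI --seed).
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"config file does not exist: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ValueError(f"{path}: invalid JSON ({err})") from err
    if "panel" not in raw or not raw["panel"]:
        raise ValueError(f"{path}: config needs a non-empty 'panel' list")
    panel = [_panel_entry_from_dict(spec) for spec in raw["panel"]]
    protocol = VoltageProtocol(**raw.get("protocol", {}))
    acquisition = AcquisitionConfig(**raw.get("acquisition", {}))
    detector = DetectorConfig(**raw.get("detector", {}))
    growth_model = GrowthModel(
        **{k: (tuple(v) if k == "sample_times" else v)
           for k, v in raw.get("growth", {}).items()}
    )
    analysis = raw.get("analysis", {})
    fit = raw.get("fit", {})
    return RunConfig(
        panel=panel,
        protocol=protocol,
        acquisition=acquisition,
        detector=detector,
        growth_model=growth_model,
        seed=int(seed if seed is not None else raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "singlechan-out")),
        log_level=str(raw.get("log_level", "INFO")),
        fit_lo=float(fit.get("v_lo", 0.0)),
        fit_hi=float(fit.get("v_hi", 100.0)),
        activity_voltage=float(fit.get("activity_voltage", -140.0)),
        timepoint=float(analysis.get("timepoint", 48.0)),
        feature=str(analysis.get("feature", "activity_meas")),
        welch=bool(analysis.get("welch", False)),
        holm=bool(analysis.get("holm", False)),
        growth_file=raw.get("growth_file"),
        write_traces=bool(raw.get("write_traces", False)),
        n_replicates=int(raw.get("n_replicates", 3)),
    )
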