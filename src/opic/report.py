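"""Timeline rendering and report-bundle assembly.

The timeline is a Gantt-style summary of one coded night: one lane per
ethogram category, state events as horizontal bars, point events as markers,
and a clock-time axis — the visual summary a clinician would flick through
to grasp a bedtime routine at a glance. SVG is the canonical output because
it is deterministic byte-for-byte for fixed input (raster export optional).

The report bundle gathers everything one analysis produced — metrics,
agreement, parent-report discrepancies, timelines, and a plain-text summary
noting whether agreement met the sufficiency threshold — into one directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import cm

from .agreement import AgreementResult, NOT_ASSESSABLE
from .ethogram import Ethogram, EventType, default_opic_ethogram, _canon
from .events import CodedObservation, to_clock
from .metrics import DiscrepancyTable, SleepMetrics

__all__ = ["TimelineSpec", "render_timeline", "build_report"]


@dataclass(frozen=True)
class TimelineSpec:
    """Lane order, colors, and axis style for a timeline rendering."""

    lane_order: tuple[str, ...]
    color_map: Mapping[str, str]
    time_axis: str = "clock"  # "clock" | "elapsed"

    @classmethod
    def for_ethogram(cls, e: Ethogram | None = None, time_axis: str = "clock") -> "TimelineSpec":
        """Default spec: category lanes in ethogram order, one color per code."""
        e = e or default_opic_ethogram()
        palette = [matplotlib.colors.to_hex(cm.tab20(i / 20)) for i in range(20)]
        colors = {
            code.name: palette[i % len(palette)] for i, code in enumerate(e.codes)
        }
        return cls(lane_order=tuple(e.categories), color_map=colors, time_axis=time_axis)

    def color_for(self, code_name: str) -> str:
        key = _canon(code_name)
        for name, color in self.color_map.items():
            if _canon(name) == key:
                return color
        return "#808080"


def render_timeline(
    obs: CodedObservation,
    spec: TimelineSpec | None = None,
    path: str | Path = "timeline.svg",
    e: Ethogram | None = None,
) -> Path:
    """Render a deterministic SVG timeline of one observation.

    One lane per category (codes not in the ethogram share an "other" lane),
    state bars spanning [start, stop), point markers, hour ticks labeled as
    wall-clock or elapsed time. Each event's glyph carries a stable SVG id,
    so the glyph census equals the event census. An empty observation yields
    axes only.
    """
    e = e or default_opic_ethogram()
    spec = spec or TimelineSpec.for_ethogram(e)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    lanes = list(spec.lane_order)
    def lane_of(code_name: str) -> str:
        code = e.get(code_name)
        return code.category if code is not None else "other"
    if any(lane_of(ev.code) == "other" for ev in obs.events):
        lanes = lanes + ["other"]
    lane_y = {name: len(lanes) - 1 - i for i, name in enumerate(lanes)}

    with plt.rc_context({"svg.hashsalt": "opic-timeline"}):
        fig, ax = plt.subplots(figsize=(11, 0.6 * max(len(lanes), 3) + 1.2))
        for i, ev in enumerate(obs.sorted_events()):
            y = lane_y[lane_of(ev.code)]
            color = spec.color_for(ev.code)
            if ev.event_type is EventType.STATE:
                artist = ax.barh(
                    y, ev.duration_s / 3600.0, left=ev.start_s / 3600.0,
                    height=0.6, color=color, edgecolor="none",
                )[0]
            else:
                (artist,) = ax.plot(
                    ev.start_s / 3600.0, y, marker="v", markersize=7,
                    color=color, linestyle="none",
                )
            artist.set_gid(f"opic-glyph-{i}")

        ax.set_yticks([lane_y[name] for name in lanes])
        ax.set_yticklabels(lanes)
        ax.set_ylim(-0.6, len(lanes) - 0.4)
        hours = int(obs.recording_duration_s // 3600) + 1
        ticks = list(range(0, hours + 1))
        ax.set_xticks(ticks)
        if spec.time_axis == "clock":
            labels = [to_clock(obs, min(t * 3600.0, obs.recording_duration_s)) for t in ticks]
        else:
            labels = [f"{t}h" for t in ticks]
        ax.set_xticklabels(labels, fontsize=8)
        ax.set_xlim(0, obs.recording_duration_s / 3600.0)
        ax.set_xlabel("clock time" if spec.time_axis == "clock" else "elapsed time")
        ax.set_title(f"Observation {obs.observation_id}" +
                     (f" (coder {obs.coder_id})" if obs.coder_id else ""))
        fig.tight_layout()
        fig.savefig(path, format=path.suffix.lstrip(".") or "svg",
                    metadata={"Date": None} if path.suffix in ("", ".svg") else None)
        plt.close(fig)
    return path


def build_report(
    out_dir: str | Path,
    *,
    observations: Sequence[CodedObservation] = (),
    metrics: SleepMetrics | None = None,
    agreement: AgreementResult | None = None,
    discrepancies: DiscrepancyTable | None = None,
    e: Ethogram | None = None,
) -> dict[str, Path]:
    """Assemble a report bundle directory from whatever components exist.

    Writes metrics (JSON + CSV), the agreement report (JSON), the
    reported-vs-observed discrepancy table (CSV), one timeline SVG per
    observation, and a plain-text summary that flags whether agreement met
    the sufficiency threshold. Missing components are listed in the summary;
    a partial bundle is still written. Returns {artifact name: path}.
    """
    e = e or default_opic_ethogram()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary: list[str] = ["Overnight coding analysis report", ""]

    if metrics is not None:
        p = out / "sleep_metrics.json"
        p.write_text(json.dumps(metrics.to_dict(), indent=2) + "\n", encoding="utf-8")
        written["metrics_json"] = p
        rows = [{"variable": k, "value": v} for k, v in metrics.to_dict().items()]
        p = out / "sleep_metrics.csv"
        import pandas as pd

        pd.DataFrame(rows).to_csv(p, index=False)
        written["metrics_csv"] = p
        summary.append(
            f"Sleep schedule: onset {metrics.sleep_onset_clock}, "
            f"offset {metrics.sleep_offset_clock}."
        )
        summary.append(
            f"Sleep quality: {metrics.n_night_wakings} night waking(s) totalling "
            f"{metrics.total_night_waking_min:.1f} min."
        )
    else:
        summary.append("Sleep metrics: not computed.")

    if agreement is not None:
        p = out / "agreement.json"
        p.write_text(json.dumps(agreement.to_dict(), indent=2) + "\n", encoding="utf-8")
        written["agreement_json"] = p
        if agreement.overall_pct is None:
            summary.append("Inter-rater agreement: not assessable (no events).")
        else:
            verdict = ("meets" if agreement.meets_threshold else "below")
            summary.append(
                f"Inter-rater agreement: {agreement.overall_pct:.0f}% "
                f"({verdict} the {agreement.threshold_pct:.0f}% threshold)."
            )
    else:
        summary.append("Inter-rater agreement: not computed (single coder).")

    if discrepancies is not None:
        p = out / "parent_report_discrepancy.csv"
        discrepancies.to_dataframe().to_csv(p, index=False)
        written["discrepancy_csv"] = p
        n_under = sum(1 for r in discrepancies.rows if r.under_report)
        summary.append(
            f"Parent report: {n_under} sleep-quality variable(s) under-reported."
        )
    else:
        summary.append("Parent-report comparison: not computed.")

    for obs in observations:
        name = f"timeline_{obs.coder_id or obs.observation_id}".replace(" ", "_")
        p = render_timeline(obs, TimelineSpec.for_ethogram(e), out / f"{name}.svg", e)
        written[name] = p

    p = out / "summary.txt"
    p.write_text("\n".join(summary) + "\n", encoding="utf-8")
    written["summary"] = p
    return written
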