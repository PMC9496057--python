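"""End-to-end run analysis: normalize -> classify -> Ct or cause -> report.

Also provides the abnormal-cause lookup, positive-count risk binning, the
Pearson agreement check against a reference instrument, and HTML/JSON report
rendering.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
from scipy import stats

from . import ctcall
from .classify import predict_curve
from .preprocess import NormalizerState
from .simgen import CurveClass, FluorescenceCurve, Group

__all__ = [
    "CurveCallResult",
    "RunReport",
    "CtPairTable",
    "HBV_COMPARISON_PAIRS",
    "analyze_run",
    "anomaly_cause",
    "risk_level",
    "pearson_validate",
    "render_report",
    "report_from_json",
]

ABNORMAL_CAUSES = {
    CurveClass.D: "suspected cross-contamination of the template or low sample concentration",
    CurveClass.E: "severe evaporation of samples or probe degradation",
    CurveClass.F: "slight sample evaporation",
}

# Ct values for eight HBV standard-serum samples (A..H): the StepOnePlus
# commercial instrument vs. this 5PL/SDM caller, two decimals.
HBV_COMPARISON_PAIRS = {
    "samples": ["A", "B", "C", "D", "E", "F", "G", "H"],
    "reference_ct": [35.99, 30.12, 25.07, 34.97, 32.41, 35.21, 34.59, 35.92],
    "algorithm_ct": [35.70, 29.71, 24.52, 34.53, 31.61, 34.50, 33.96, 35.25],
}


@dataclass(frozen=True)
class CurveCallResult:
    """Per-well verdict: predicted class, group, and Ct or abnormal cause."""

    well_id: str
    label: CurveClass
    group: Group
    ct: float | None = None
    cause: str | None = None
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.group is Group.POSITIVE:
            has_ct = self.ct is not None
            uncallable = self.status == "positive-but-uncallable"
            if has_ct == uncallable:
                raise ValueError(
                    "positive result must carry a Ct XOR the uncallable status"
                )
            if self.cause is not None:
                raise ValueError("positive result must not carry a cause")
        elif self.group is Group.ABNORMAL:
            if self.cause is None or self.ct is not None:
                raise ValueError("abnormal result must carry a cause and no Ct")
        else:
            if self.ct is not None or self.cause is not None:
                raise ValueError("negative result carries neither Ct nor cause")

    def to_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "label": self.label.value,
            "group": self.group.value,
            "ct": self.ct,
            "cause": self.cause,
            "status": self.status,
        }


@dataclass(frozen=True)
class RunReport:
    """Ordered per-well results plus run metadata and group tallies."""

    results: tuple[CurveCallResult, ...]
    template_name: str = "default"
    instrument_id: str = "unknown"
    timestamp: str = ""
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tallies = {g.value: 0 for g in Group}
        for r in self.results:
            tallies[r.group.value] += 1
        object.__setattr__(self, "counts", tallies)

    def __len__(self) -> int:
        return len(self.results)

    def to_dict(self) -> dict:
        return {
            "template_name": self.template_name,
            "instrument_id": self.instrument_id,
            "timestamp": self.timestamp,
            "counts": self.counts,
            "results": [r.to_dict() for r in self.results],
        }


@dataclass(frozen=True)
class CtPairTable:
    """Paired Ct calls: reference instrument vs. this algorithm."""

    sample_ids: tuple[str, ...]
    reference_ct: np.ndarray
    algorithm_ct: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_ct, dtype=float)
        alg = np.asarray(self.algorithm_ct, dtype=float)
        object.__setattr__(self, "reference_ct", ref)
        object.__setattr__(self, "algorithm_ct", alg)
        if not (len(self.sample_ids) == len(ref) == len(alg)):
            raise ValueError("sample ids and both Ct columns must align")
        if len(ref) < 3:
            raise ValueError("need at least 3 Ct pairs")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(alg))):
            raise ValueError("Ct values must be finite")

    @classmethod
    def builtin_hbv(cls) -> "CtPairTable":
        d = HBV_COMPARISON_PAIRS
        return cls(
            sample_ids=tuple(d["samples"]),
            reference_ct=np.array(d["reference_ct"]),
            algorithm_ct=np.array(d["algorithm_ct"]),
        )


def anomaly_cause(label: CurveClass) -> str:
    """Preset cause string for an abnormal class (D, E or F)."""
    if label not in ABNORMAL_CAUSES:
        raise ValueError(f"{label.value} is not an abnormal class")
    return ABNORMAL_CAUSES[label]


def analyze_run(
    raw_curves: Sequence[FluorescenceCurve],
    model,
    normalizer: NormalizerState,
    template_name: str = "default",
    instrument_id: str = "unknown",
    timestamp: str | None = None,
) -> RunReport:
    """Classify each curve and branch: positive -> Ct, abnormal -> cause,
    negative -> pass-through. Per-curve failures are captured in that well's
    status and never abort the run.
    """
    results: list[CurveCallResult] = []
    for i, curve in enumerate(raw_curves):
        well_id = curve.well_id or f"well_{i + 1}"
        label, group = predict_curve(model, normalizer, curve)
        if group is Group.POSITIVE:
            try:
                ct_res = ctcall.call_ct(curve)
                results.append(
                    CurveCallResult(well_id=well_id, label=label, group=group, ct=ct_res.ct)
                )
            except ctcall.UncallableError:
                results.append(
                    CurveCallResult(
                        well_id=well_id,
                        label=label,
                        group=group,
                        status="positive-but-uncallable",
                    )
                )
        elif group is Group.ABNORMAL:
            results.append(
                CurveCallResult(
                    well_id=well_id, label=label, group=group, cause=anomaly_cause(label)
                )
            )
        else:
            results.append(CurveCallResult(well_id=well_id, label=label, group=group))
    if timestamp is None:
        timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return RunReport(
        results=tuple(results),
        template_name=template_name,
        instrument_id=instrument_id,
        timestamp=timestamp,
    )


def risk_level(positive_count: int, thresholds: Sequence[int] = (10, 50, 100)) -> int:
    """Map a positive-result count to a risk level 1..4.

    Level = 1 + number of thresholds strictly exceeded; monotone
    non-decreasing in the count.
    """
    if positive_count < 0:
        raise ValueError("positive_count must be non-negative")
    t = list(thresholds)
    if len(t) != 3 or not (t[0] < t[1] < t[2]):
        raise ValueError("thresholds must be 3 strictly ascending integers")
    return 1 + sum(positive_count > th for th in t)


def pearson_validate(pairs: CtPairTable) -> tuple[float, float]:
    """Pearson r (and two-sided p from the t-transform, n-2 df) between the
    reference and algorithm Ct columns."""
    ref, alg = pairs.reference_ct, pairs.algorithm_ct
    if np.std(ref) == 0 or np.std(alg) == 0:
        raise ValueError("zero variance in a Ct column; r undefined")
    r, p = stats.pearsonr(ref, alg)
    return float(r), float(p)


def _round_half_up(value: float, digits: int = 2) -> float:
    import decimal

    q = decimal.Decimal(10) ** -digits
    return float(
        decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def _curve_svg(curve: FluorescenceCurve) -> str:
    """Small inline SVG plot of one trace for the HTML report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 2.2), dpi=72)
    ax.plot(curve.cycles, curve.rfu, lw=1.2)
    ax.set_xlabel("cycle", fontsize=7)
    ax.set_ylabel("fluorescence", fontsize=7)
    ax.tick_params(labelsize=6)
    fig.tight_layout()
    buf = io.StringIO()
    fig.savefig(buf, format="svg")
    plt.close(fig)
    svg = buf.getvalue()
    return svg[svg.index("<svg") :]


def render_report(
    report: RunReport,
    path,
    fmt: str = "json",
    curves: Sequence[FluorescenceCurve] | None = None,
) -> None:
    """Write the run report as lossless JSON or as a human-readable HTML page
    with per-well verdicts, two-decimal Ct values and embedded curve plots."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        return
    if fmt != "html":
        raise ValueError("format must be 'json' or 'html'")
    by_well = {c.well_id: c for c in curves or [] if c.well_id}
    rows = []
    for r in report.results:
        ct_str = f"{_round_half_up(r.ct):.2f}" if r.ct is not None else "—"
        cause = r.cause or "—"
        plot = ""
        if r.well_id in by_well:
            plot = _curve_svg(by_well[r.well_id])
        rows.append(
            f"<tr><td>{r.well_id}</td><td>{r.label.value}</td>"
            f"<td>{r.group.value}</td><td>{ct_str}</td><td>{cause}</td>"
            f"<td>{r.status}</td><td>{plot}</td></tr>"
        )
    counts = ", ".join(f"{k}: {v}" for k, v in report.counts.items())
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Amplification run report</title>
<style>table{{border-collapse:collapse}}td,th{{border:1px solid #999;padding:4px 8px;font:12px sans-serif}}</style>
</head><body>
<h1>Amplification run report</h1>
<p>Template: {report.template_name} | Instrument: {report.instrument_id} | Time: {report.timestamp}</p>
<p>Counts — {counts}</p>
<table>
<tr><th>Well</th><th>Class</th><th>Group</th><th>Ct</th><th>Cause</th><th>Status</th><th>Curve</th></tr>
{''.join(rows)}
</table>
</body></html>
"""
    with open(path, "w") as fh:
        fh.write(html)


def report_from_json(path) -> RunReport:
    """Rebuild a :class:`RunReport` from its JSON rendering (round-trip)."""
    with open(path) as fh:
        d = json.load(fh)
    results = tuple(
        CurveCallResult(
            well_id=r["well_id"],
            label=CurveClass(r["label"]),
            group=Group(r["group"]),
            ct=r["ct"],
            cause=r["cause"],
            status=r["status"],
        )
        for r in d["results"]
    )
    return RunReport(
        results=results,
        template_name=d["template_name"],
        instrument_id=d["instrument_id"],
        timestamp=d["timestamp"],
    )
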