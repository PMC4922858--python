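"""End-to-end seeded runs and worked-example event fixtures.

``run_pipeline`` chains simulation -> trace rendering -> event detection
-> coincidence classification -> dwell-time fits and produces a
machine-readable report bundle (events CSV, tallies and fits as JSON,
run manifest with all seeds).  ``make_fixture`` builds small
deterministic event tables whose classification reproduces a requested
tally exactly — useful for worked examples and arithmetic checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as skio
from .detect import (DegenerateTraceError, DetectorConfig, EventInterval,
                     detect_events)
from .dwell import fit_mle
from .pathways import (Outcome, classify_outcomes, match_coincident,
                       multi_binding_summary, ordering_offsets,
                       randomized_control, rebinding_analysis)
from .simulate import (AcquisitionConfig, preset_scheme, render_traces,
                       simulate_molecules)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture",
           "validate_report"]

_SCHEMA_PATH = Path(__file__).resolve().parents[2] / "docs" \
    / "report.schema.json"

_JSON_TYPES = {"object": dict, "integer": int, "number": (int, float),
               "string": str, "null": type(None)}


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Check a report bundle against the published report schema.

    Covers the structural subset of JSON Schema the reports use
    (required keys, object nesting, primitive types); raises
    ``ValueError`` on the first violation.
    """
    if schema is None:
        import json
        schema = json.loads(_SCHEMA_PATH.read_text())

    def _check(obj, spec, path):
        types = spec.get("type")
        if types is not None:
            allowed: tuple = ()
            for name in [types] if isinstance(types, str) else types:
                t = _JSON_TYPES[name]
                allowed += t if isinstance(t, tuple) else (t,)
            if not isinstance(obj, allowed) or isinstance(obj, bool):
                raise ValueError(
                    f"{path}: expected {types}, got {type(obj).__name__}")
        if isinstance(obj, dict):
            for key in spec.get("required", []):
                if key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
            for key, sub in spec.get("properties", {}).items():
                if key in obj:
                    _check(obj[key], sub, f"{path}.{key}")

    _check(report, schema, "report")


@dataclass
class PipelineConfig:
    """Settings for one seeded end-to-end run."""

    preset: str = "2mM"
    n_molecules: int = 100
    seed: int = 0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    coincidence_tolerance_s: float | None = None  # default: 1 frame spacing
    fit_cohorts: bool = True
    n_boot: int = 0          # bootstrap resamples per fit (0 = skip)
    write_traces: bool = False
    out_dir: str | Path | None = None

    @property
    def tolerance(self) -> float:
        if self.coincidence_tolerance_s is not None:
            return self.coincidence_tolerance_s
        return self.acquisition.frame_spacing


def _fit_or_none(dwells, spec, t_m, t_max, seed):
    from .dwell import _N_FREE
    dwells = np.asarray(dwells, dtype=float)
    dwells = dwells[(dwells >= t_m) & (dwells <= t_max)]
    if dwells.size < 3 * _N_FREE[spec]:
        return None
    # detector dwells sit on the frame grid with atoms at t_m; the tau
    # floor keeps the truncated likelihood bounded there
    return fit_mle(dwells, spec, t_m, t_max, seed=seed, tau_min=t_m / 2)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> render -> detect -> classify -> fit and report.

    The returned bundle is a plain dict (JSON-serializable apart from the
    event list) and is bit-reproducible for identical config + seed.
    When ``config.out_dir`` is set, events, tallies, fits and a manifest
    are also written there.
    """
    acq = config.acquisition
    t_m = acq.frame_spacing
    report: dict = {
        "manifest": {
            "preset": config.preset,
            "n_molecules": config.n_molecules,
            "seed": config.seed,
            "frame_spacing_s": acq.frame_spacing,
            "frame_duration_s": acq.frame_duration,
            "t_max_s": acq.t_max,
            "tolerance_s": config.tolerance,
        },
    }
    if config.n_molecules == 0:
        report.update({
            "events": [], "tally": {"counts": {}, "total": 0,
                                    "percentages": {}},
            "multi_binding": {}, "rebinding": None, "ordering": None,
            "fits": {}})
        _write_bundle(report, [], config)
        return report

    scheme = preset_scheme(config.preset)
    truths = simulate_molecules(scheme, config.n_molecules, acq, config.seed)
    channels = sorted({c for chans in scheme.emission_map.values()
                       for c in chans})
    traces = render_traces(truths, acq, seed=config.seed + 1,
                           channels=channels)

    events: list[EventInterval] = []
    for trace in traces:
        try:
            events.extend(detect_events(trace, config.detector))
        except DegenerateTraceError:
            continue
    by_channel: dict[str, list[EventInterval]] = {}
    for ev in events:
        by_channel.setdefault(ev.channel, []).append(ev)

    tol = config.tolerance
    pairs, u4_only, u5_only = match_coincident(
        by_channel.get("U4", []), by_channel.get("U5", []), tol)
    tally = classify_outcomes(pairs, tol)
    multi = multi_binding_summary(pairs, config.n_molecules)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rebind = rebinding_analysis(pairs, by_channel.get("U4", []), tol)

    ordering = None
    if by_channel.get("NTC"):
        rec = ordering_offsets(by_channel["U4"], by_channel["NTC"])
        ctrl = randomized_control(by_channel["U4"], by_channel["NTC"],
                                  n_shuffles=20, seed=config.seed + 2)
        ordering = {
            "n_pairs": int(rec.deltas.size),
            "fraction_negative": rec.fraction_negative,
            "n_excluded": rec.n_excluded,
            "bin_edges": rec.bin_edges.tolist(),
            "histogram": rec.histogram.tolist(),
            "control_histogram": ctrl.histogram.tolist(),
        }

    fits: dict[str, dict] = {}
    if config.fit_cohorts:
        release = [0.5 * (p.u4.dwell + p.u5.dwell) for p in pairs
                   if p.outcome == Outcome.SIMULTANEOUS_LOSS]
        act_u4 = [p.u4.dwell for p in pairs
                  if p.outcome == Outcome.U4_FIRST]
        u5_after = [p.u5.t_end - p.u4.t_end for p in pairs
                    if p.outcome == Outcome.U4_FIRST and not p.u5.censored]
        spec_release = "exp3" if config.preset == "2mM" else "exp2"
        for name, dwells, spec in [
                ("release", release, spec_release),
                ("activation_u4", act_u4, "conv"),
                ("u5_after_u4", u5_after, "exp2")]:
            fit = _fit_or_none(dwells, spec, t_m, acq.t_max, config.seed)
            if fit is not None:
                if config.n_boot > 0:
                    from .dwell import bootstrap_errors
                    fit.bootstrap_sd = bootstrap_errors(
                        np.asarray(dwells)[
                            (np.asarray(dwells) >= t_m)
                            & (np.asarray(dwells) <= acq.t_max)],
                        spec, t_m, acq.t_max, n_boot=config.n_boot,
                        seed=config.seed)
                fits[name] = fit.to_dict()

    report.update({
        "events": events,
        "tally": {"counts": tally.counts, "total": tally.total,
                  "percentages": tally.percentages},
        "n_unmatched": {"U4_only": len(u4_only), "U5_only": len(u5_only)},
        "multi_binding": multi,
        "rebinding": {
            "n_eligible": rebind.n_eligible,
            "n_rebinding": rebind.n_rebinding,
            "percent": rebind.percent,
            "rate_per_min": rebind.rate_per_min,
        },
        "ordering": ordering,
        "fits": fits,
    })
    _write_bundle(report, traces if config.write_traces else [], config)
    return report


def _write_bundle(report: dict, traces, config: PipelineConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skio.write_events_csv(report["events"], out / "events.csv")
    if traces:
        skio.write_traces_csv(traces, out / "traces.csv", config.acquisition)
    serializable = {k: v for k, v in report.items() if k != "events"}
    skio.write_json(serializable, out / "report.json")


# ---------------------------------------------------------------------------
# worked-example fixtures
# ---------------------------------------------------------------------------

def _route_events(mol: int, route: str, t_max: float):
    """Deterministic U4/U5 interval pair realizing one outcome route."""
    t0 = 100.0
    if route == "U4_FIRST":
        u4 = EventInterval(mol, "U4", t0, t0 + 120.0)
        u5 = EventInterval(mol, "U5", t0, t0 + 400.0)
    elif route == "U5_FIRST":
        u4 = EventInterval(mol, "U4", t0, t0 + 400.0)
        u5 = EventInterval(mol, "U5", t0, t0 + 120.0)
    elif route == "SIMULTANEOUS_LOSS":
        u4 = EventInterval(mol, "U4", t0, t0 + 250.0)
        u5 = EventInterval(mol, "U5", t0, t0 + 250.0)
    elif route == "PERSIST":
        u4 = EventInterval(mol, "U4", t0, t_max, censored=True)
        u5 = EventInterval(mol, "U5", t0, t_max, censored=True)
    else:
        raise ValueError(f"unknown route {route!r}")
    return u4, u5


def make_fixture(kind: str, spec: dict, t_max: float = 3600.0) -> dict:
    """Deterministic event tables realizing printed summary counts.

    kind="routes": spec maps outcome route names (U4_FIRST, U5_FIRST,
        SIMULTANEOUS_LOSS, PERSIST) to counts; optional "total" is
        validated against their sum.
    kind="coincidence": spec {"paired", "only_a", "only_b"}; channel A
        is U5 and channel B is U4 (paired events share arrival times).
    kind="rebinding": spec {"eligible", "rebind"}; eligible U4-first
        pairs, of which ``rebind`` show a U4 reappearance during the
        remaining U5 dwell.
    kind="repeats": spec {"total", "repeat"}; molecules with >= 2
        activation rounds among ``total`` molecules (the rest get one).

    Returns {"events": {channel: [EventInterval, ...]}, "n_molecules": n}.
    """
    if any(v < 0 for v in spec.values()):
        raise ValueError("fixture counts must be non-negative")

    events: dict[str, list[EventInterval]] = {"U4": [], "U5": []}
    if kind == "routes":
        routes = {k: v for k, v in spec.items() if k != "total"}
        total = sum(routes.values())
        if "total" in spec and spec["total"] != total:
            raise ValueError("route counts do not sum to the stated total")
        mol = 0
        for route, count in routes.items():
            for _ in range(count):
                u4, u5 = _route_events(mol, route, t_max)
                events["U4"].append(u4)
                events["U5"].append(u5)
                mol += 1
        return {"events": events, "n_molecules": mol}

    if kind == "coincidence":
        paired = spec.get("paired", 0)
        only_a = spec.get("only_a", 0)
        only_b = spec.get("only_b", 0)
        mol = 0
        for _ in range(paired):
            events["U5"].append(EventInterval(mol, "U5", 100.0, 400.0))
            events["U4"].append(EventInterval(mol, "U4", 100.0, 400.0))
            mol += 1
        for _ in range(only_a):
            events["U5"].append(EventInterval(mol, "U5", 100.0, 150.0))
            mol += 1
        for _ in range(only_b):
            events["U4"].append(EventInterval(mol, "U4", 100.0, 150.0))
            mol += 1
        return {"events": events, "n_molecules": mol}

    if kind == "rebinding":
        eligible = spec["eligible"]
        rebind = spec.get("rebind", 0)
        if rebind > eligible:
            raise ValueError("rebind count exceeds eligible count")
        for mol in range(eligible):
            events["U4"].append(EventInterval(mol, "U4", 100.0, 220.0))
            events["U5"].append(EventInterval(mol, "U5", 100.0, 1000.0))
            if mol < rebind:
                events["U4"].append(EventInterval(mol, "U4", 500.0, 560.0))
        return {"events": events, "n_molecules": eligible}

    if kind == "repeats":
        total = spec["total"]
        repeat = spec.get("repeat", 0)
        if repeat > total:
            raise ValueError("repeat count exceeds total molecule count")
        for mol in range(total):
            u4, u5 = _route_events(mol, "U4_FIRST", t_max)
            events["U4"].append(u4)
            events["U5"].append(u5)
            if mol < repeat:
                events["U4"].append(
                    EventInterval(mol, "U4", 2000.0, 2120.0))
                events["U5"].append(
                    EventInterval(mol, "U5", 2000.0, 2400.0))
        return {"events": events, "n_molecules": total}

    raise ValueError(f"unknown fixture kind {kind!r}")
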