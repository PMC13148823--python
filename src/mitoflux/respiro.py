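"""High-resolution respirometry: traces -> per-state oxygen flux -> coupling.

A SUIT (substrate–uncoupler–inhibitor titration) run records chamber O2
concentration (µM) over time while substrates and inhibitors are injected.
Each injection starts a new respiratory state; within a state, O2 declines
linearly and the oxygen flux is

    JO2 = -slope(O2 vs t) * chamber_volume_ml * 1000 / amount

in pmol O2 s-1 per amount unit (mg wet weight or million cells), with O2
consumption positive.  Composite state labels accumulate substrate letters
(E -> PM -> PMD -> PMDG -> PMDGS, optionally -> PMDGSC with cytochrome c);
inhibitor injections open the states OMY (oligomycin), AMA (antimycin A)
and AMA_ROT (antimycin A followed by rotenone).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RespirometryTrace",
    "PROTOCOLS",
    "parse_trace",
    "write_trace",
    "segment_states",
    "estimate_jo2",
    "build_state_table",
    "coupling_metrics",
]

EVENT_VOCABULARY = {"E", "PM", "D", "G", "S", "PC", "M", "CC", "OMY", "AMA", "ROT"}

# Injection sequences per protocol id.  The pre-first-injection segment is
# always the endogenous state E.
PROTOCOLS: dict[str, tuple[str, ...]] = {
    "CI_CII": ("PM", "D", "G", "S"),
    "CI_CII_coupling": ("PM", "D", "G", "S", "OMY", "AMA", "ROT"),
    "LIPID": ("M", "D", "PC"),
}

# How each substrate event extends the composite state label.
_SUBSTRATE_SUFFIX = {"PM": "PM", "D": "D", "G": "G", "S": "S", "PC": "PC",
                     "M": "M", "CC": "C"}
_INHIBITORS = {"OMY", "AMA", "ROT"}

GROUPS = {"benign", "tumor", "control", "treated"}
AMOUNT_UNITS = {"mg_wet_weight", "million_cells"}


class TraceError(ValueError):
    """Raised for malformed traces or event annotations."""


@dataclass
class RespirometryTrace:
    sample_id: str
    group: str
    replicate_id: int
    time_s: np.ndarray
    o2_uM: np.ndarray
    events: list[tuple[float, str]]
    chamber_volume_ml: float = 2.0
    amount: float = 1.0
    amount_units: str = "mg_wet_weight"
    protocol: str | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_uM = np.asarray(self.o2_uM, dtype=float)
        self.validate()

    def validate(self) -> "RespirometryTrace":
        if self.time_s.shape != self.o2_uM.shape or self.time_s.ndim != 1:
            raise TraceError("time_s and o2_uM must be 1-d arrays of equal length")
        dt = np.diff(self.time_s)
        if len(dt) and not np.all(dt > 0):
            i = int(np.argmin(dt))
            raise TraceError(
                f"time_s must be strictly increasing (violated at row {i + 1}, "
                f"t={self.time_s[i + 1]!r})"
            )
        if not np.all(np.isfinite(self.o2_uM)):
            raise TraceError("o2_uM contains non-finite values")
        if self.group not in GROUPS:
            raise TraceError(f"unknown group '{self.group}' (expected one of {sorted(GROUPS)})")
        if self.amount_units not in AMOUNT_UNITS:
            raise TraceError(f"unknown amount_units '{self.amount_units}'")
        if self.chamber_volume_ml <= 0 or self.amount <= 0:
            raise TraceError("chamber_volume_ml and amount must be positive")
        last_t = -np.inf
        for row, (t, label) in enumerate(self.events):
            if label not in EVENT_VOCABULARY:
                raise TraceError(f"unknown event label '{label}' (events row {row})")
            if t < last_t:
                raise TraceError(f"events not time-ordered at row {row}")
            last_t = t
        return self


def write_trace(trace: RespirometryTrace, directory, stem: str | None = None) -> dict:
    """Write a trace as three text files: trace CSV, events CSV, metadata JSON.

    Returns the paths written, keyed by ``trace``/``events``/``metadata``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{trace.sample_id}_r{trace.replicate_id}"
    paths = {
        "trace": directory / f"{stem}.trace.csv",
        "events": directory / f"{stem}.events.csv",
        "metadata": directory / f"{stem}.meta.json",
    }
    # %.17g round-trips float64 exactly
    pd.DataFrame({"time_s": trace.time_s, "o2_uM": trace.o2_uM}).to_csv(
        paths["trace"], index=False, float_format="%.17g"
    )
    pd.DataFrame(trace.events, columns=["time_s", "label"]).to_csv(
        paths["events"], index=False
    )
    meta = {
        "sample_id": trace.sample_id,
        "group": trace.group,
        "replicate_id": trace.replicate_id,
        "chamber_volume_ml": trace.chamber_volume_ml,
        "amount": trace.amount,
        "amount_units": trace.amount_units,
        "protocol": trace.protocol,
    }
    paths["metadata"].write_text(json.dumps(meta, indent=1))
    return paths


def parse_trace(trace_file, events_file, metadata) -> RespirometryTrace:
    """Read a trace from its CSV/CSV/JSON file triple.

    ``metadata`` may be a mapping or a path to a JSON file.  Validation
    errors name the offending row.
    """
    df = pd.read_csv(trace_file, float_precision="round_trip")
    if list(df.columns[:2]) != ["time_s", "o2_uM"]:
        raise TraceError(f"trace file must have columns time_s,o2_uM; got {list(df.columns)}")
    ev = pd.read_csv(events_file, float_precision="round_trip")
    if list(ev.columns[:2]) != ["time_s", "label"]:
        raise TraceError(f"events file must have columns time_s,label; got {list(ev.columns)}")
    if not isinstance(metadata, dict):
        metadata = json.loads(Path(metadata).read_text())
    required = {"sample_id", "group", "replicate_id", "chamber_volume_ml",
                "amount", "amount_units"}
    missing = required - set(metadata)
    if missing:
        raise TraceError(f"metadata missing fields: {sorted(missing)}")
    return RespirometryTrace(
        sample_id=str(metadata["sample_id"]),
        group=metadata["group"],
        replicate_id=int(metadata["replicate_id"]),
        time_s=df["time_s"].to_numpy(),
        o2_uM=df["o2_uM"].to_numpy(),
        events=[(float(t), str(l)) for t, l in zip(ev["time_s"], ev["label"])],
        chamber_volume_ml=float(metadata["chamber_volume_ml"]),
        amount=float(metadata["amount"]),
        amount_units=metadata["amount_units"],
        protocol=metadata.get("protocol"),
    )


@dataclass
class StateSegment:
    state: str
    start: int          # index of first point in the analysis window
    stop: int           # exclusive
    missing: bool = False

    @property
    def n_points(self) -> int:
        return self.stop - self.start


def _composite_states(labels: Iterable[str]) -> list[str]:
    """Fold an injection sequence into composite state names."""
    states = []
    current = "E"
    for label in labels:
        if label in _INHIBITORS:
            if label == "ROT" and current == "AMA":
                current = "AMA_ROT"
            else:
                current = label
        elif label in _SUBSTRATE_SUFFIX:
            base = "" if current in ("E",) or current in _INHIBITORS or "_" in current else current
            current = base + _SUBSTRATE_SUFFIX[label]
        else:
            raise TraceError(f"unknown event label '{label}'")
        states.append(current)
    return states


def protocol_states(protocol: str, with_cc: bool = False) -> list[str]:
    """Composite state sequence (including E) produced by a protocol."""
    if protocol not in PROTOCOLS:
        raise TraceError(f"unknown protocol '{protocol}'")
    labels = list(PROTOCOLS[protocol])
    if with_cc:
        idx = labels.index("S") + 1 if "S" in labels else len(labels)
        labels.insert(idx, "CC")
    return ["E"] + _composite_states(labels)


def segment_states(
    trace: RespirometryTrace, discard_s: float = 30.0, window_s: float = 60.0
) -> list[StateSegment]:
    """Split a trace into steady-state analysis windows.

    Each inter-event interval yields a window starting ``discard_s`` after
    the injection (mixing/stabilization) and spanning at most ``window_s``,
    truncated at the next event.  The pre-first-event segment is the
    endogenous state E (its window also starts ``discard_s`` after trace
    start).  A state whose interval is entirely consumed by the discard is
    returned with ``missing=True`` rather than silently dropped.
    """
    if discard_s < 0:
        raise ValueError("discard_s must be >= 0")
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    t = trace.time_s
    boundaries = [t[0]] + [ev_t for ev_t, _ in trace.events] + [t[-1] + np.finfo(float).eps]
    states = ["E"] + _composite_states(label for _, label in trace.events)
    segments: list[StateSegment] = []
    for state, t_start, t_next in zip(states, boundaries, boundaries[1:]):
        w0 = t_start + discard_s
        w1 = min(w0 + window_s, t_next)
        start = int(np.searchsorted(t, w0, side="left"))
        stop = int(np.searchsorted(t, w1, side="right"))
        missing = w1 <= w0 or stop - start < 3
        segments.append(StateSegment(state=state, start=start, stop=stop, missing=missing))
    return segments


def estimate_jo2(trace: RespirometryTrace, index_range) -> float:
    """Oxygen flux for one analysis window, pmol O2 s-1 per amount unit.

    Ordinary least-squares slope of o2_uM against time_s over the window;
    consumption (declining O2) is positive.
    """
    if isinstance(index_range, StateSegment):
        start, stop = index_range.start, index_range.stop
    else:
        start, stop = index_range
    t = trace.time_s[start:stop]
    y = trace.o2_uM[start:stop]
    if len(t) < 3:
        raise ValueError(f"need >= 3 points in window, got {len(t)}")
    slope = np.polyfit(t, y, 1)[0]
    return float(-slope * trace.chamber_volume_ml * 1000.0 / trace.amount)


def build_state_table(
    traces: Sequence[RespirometryTrace],
    protocol: str | None = None,
    discard_s: float = 30.0,
    window_s: float = 60.0,
    analyte: str = "O2",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-state fluxes for a cohort of traces.

    Technical replicates of one biological sample are averaged
    (arithmetic mean) into a single biological row; the replicate-level
    table is returned alongside for audit.  Samples with a single replicate
    pass through with ``single_replicate=True``.  Negative fitted fluxes are
    retained and flagged (``negative_flux``) rather than clamped.

    Returns ``(biological, replicate)`` DataFrames.
    """
    if protocol is not None:
        protos = {tr.protocol for tr in traces if tr.protocol is not None}
        if protos and protos != {protocol}:
            raise TraceError(f"traces carry mismatched protocols {sorted(protos)}, expected {protocol}")
    rows = []
    for tr in traces:
        for seg in segment_states(tr, discard_s=discard_s, window_s=window_s):
            if seg.missing:
                jo2 = np.nan
            else:
                jo2 = estimate_jo2(tr, seg)
            rows.append(
                {
                    "sample_id": tr.sample_id,
                    "group": tr.group,
                    "replicate_id": tr.replicate_id,
                    "state": seg.state,
                    "jo2": jo2,
                    "analyte": analyte,
                    "units": f"pmol_s-1_per_{tr.amount_units}",
                    "missing": seg.missing,
                }
            )
    replicate = pd.DataFrame(rows)
    grouped = replicate.groupby(["sample_id", "group", "state", "analyte", "units"],
                                sort=False)
    biological = grouped.agg(
        jo2=("jo2", "mean"),
        n_replicates=("replicate_id", "nunique"),
    ).reset_index()
    biological["single_replicate"] = biological["n_replicates"] < 2
    biological["negative_flux"] = biological["jo2"] < 0
    return biological, replicate


def _sample_state_flux(df: pd.DataFrame, sample: str, state: str) -> float | None:
    sel = df.loc[(df["sample_id"] == sample) & (df["state"] == state), "jo2"]
    return float(sel.iloc[0]) if len(sel) else None


def coupling_metrics(state_table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample coupling summary from a biological state table.

    omy_inhibition_pct = 100 * (1 - J_OMY / J_max): percent of maximal
    CI+CII-supported respiration abolished by oligomycin, where J_max is the
    maximal pre-oligomycin composite state (PMDGSC when cytochrome c was
    added, else PMDGS).  residual_pct = 100 * J_AMA_ROT / J_max is the
    non-mitochondrial residual after antimycin A + rotenone.
    cc_response_pct = 100 * (J_PMDGSC - J_PMDGS) / J_PMDGS is the cytochrome
    c test (near zero for intact outer membranes); NaN when no CC state.
    """
    needed = {"PMDGS", "OMY"}
    present = set(state_table["state"])
    if not needed <= present and "PMDGSC" not in present:
        raise ValueError(f"state table must contain PMDGS and OMY states, has {sorted(present)}")
    out = []
    for sample, df in state_table.groupby("sample_id", sort=False):
        ref_state = "PMDGSC" if "PMDGSC" in set(df["state"]) else "PMDGS"
        j_max = _sample_state_flux(df, sample, ref_state)
        if j_max is None or not np.isfinite(j_max) or j_max <= 0:
            raise ValueError(f"sample {sample}: reference flux {ref_state} missing or <= 0")
        j_omy = _sample_state_flux(df, sample, "OMY")
        j_res = _sample_state_flux(df, sample, "AMA_ROT")
        j_pmdgs = _sample_state_flux(df, sample, "PMDGS")
        j_cc = _sample_state_flux(df, sample, "PMDGSC")
        cc_resp = (
            100.0 * (j_cc - j_pmdgs) / j_pmdgs
            if (j_cc is not None and j_pmdgs is not None and j_pmdgs != 0)
            else np.nan
        )
        out.append(
            {
                "sample_id": sample,
                "group": df["group"].iloc[0],
                "reference_state": ref_state,
                "omy_inhibition_pct": (
                    100.0 * (1.0 - j_omy / j_max) if j_omy is not None else np.nan
                ),
                "residual_pct": 100.0 * j_res / j_max if j_res is not None else np.nan,
                "cc_response_pct": cc_resp,
            }
        )
    return pd.DataFrame(out)
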