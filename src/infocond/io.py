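"""Readers, writers and the bundled protocol catalog.

Event logs travel as plain CSV with columns ``session_id,time_s,event``
(plus an optional leading ``subject_id`` for combined cohort files); times
carry one decimal (0.1-s recording resolution).  The protocol catalog —
the 28 published Pavlovian and operant parameter sets — ships with the
package and is the source for protocol lookup by id and for the derived
exposure/rate/informativeness report.
"""

from __future__ import annotations

import importlib.resources
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .protocols import (
    Contingency,
    Paradigm,
    ProtocolSpec,
    ToneKind,
    assign_credit,
    expected_exposures,
    informativeness,
)
from .simulate import Event, EventLog, EventLogError, validate_log

__all__ = [
    "load_catalog",
    "spec_for_protocol",
    "catalog_protocol_ids",
    "table1_report",
    "read_event_log_csv",
    "write_event_log_csv",
    "load_config",
]


# ---------------------------------------------------------------------------
# protocol catalog


def load_catalog() -> pd.DataFrame:
    """The bundled protocol catalog as a DataFrame (one row per protocol)."""
    with importlib.resources.files("infocond.data").joinpath("protocol_catalog.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"tone_values": "string"})
    return df


def catalog_protocol_ids(catalog: pd.DataFrame | None = None) -> list[int]:
    catalog = load_catalog() if catalog is None else catalog
    return [int(p) for p in catalog["protocol"]]


def _spec_from_row(row: pd.Series) -> ProtocolSpec:
    kind = ToneKind(row["tone_kind"])
    values = None
    if kind is ToneKind.MIXED:
        values = tuple(float(v) for v in str(row["tone_values"]).split("|"))
    return ProtocolSpec(
        paradigm=Paradigm(row["paradigm"]),
        contingency=Contingency(row["contingency"]),
        tone_duration_s=float(row["tone_s"]),
        tone_duration_kind=kind,
        iti_mean_s=float(row["iti_s"]),
        iri_mean_s=float(row["iri_s"]),
        tones_per_session=int(row["tones_per_session"]),
        tone_duration_values=values,
        label=f"protocol {int(row['protocol'])}",
    )


def spec_for_protocol(protocol_id: int, catalog: pd.DataFrame | None = None) -> ProtocolSpec:
    """Look up one catalog protocol by its id."""
    catalog = load_catalog() if catalog is None else catalog
    match = catalog[catalog["protocol"] == int(protocol_id)]
    if match.empty:
        valid = ", ".join(str(p) for p in catalog_protocol_ids(catalog))
        raise KeyError(f"unknown protocol id {protocol_id}; valid ids: {valid}")
    return _spec_from_row(match.iloc[0])


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def table1_report(catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Computed exposures, rates, informativeness and attributed rates for
    every catalog protocol, alongside the published values with match flags
    at the published rounding (two decimals for rates, one for iota)."""
    catalog = load_catalog() if catalog is None else catalog
    rows = []
    for _, row in catalog.iterrows():
        spec = _spec_from_row(row)
        exp = expected_exposures(spec)
        rep = informativeness(exp, signal="offset")
        credit = assign_credit(exp)
        rows.append(
            {
                "exp": int(row["exp"]),
                "protocol": int(row["protocol"]),
                "cum_c_min": exp.cum_context_s / 60.0,
                "cum_iti_min": exp.cum_no_tone_s / 60.0,
                "rewards_per_session": exp.n_rewards_context,
                "rate_tone_per_min": rep.rate_tone_per_min,
                "rate_context_per_min": rep.rate_context_per_min,
                "rate_iti_per_min": rep.rate_no_tone_per_min,
                "iota": rep.iota,
                "delta_H_bits": rep.delta_H_bits,
                "attributed_tone_per_min": credit.attributed_rate_tone_per_min,
                "attributed_iti_per_min": credit.attributed_rate_no_tone_per_min,
                "printed_rate_context_per_min": float(row["printed_rate_context"]),
                "printed_rate_iti_per_min": float(row["printed_rate_iti"]),
                "printed_iota": float(row["printed_iota"]),
                "match_rate_context": _round_half_up(rep.rate_context_per_min, 2)
                == float(row["printed_rate_context"]),
                "match_rate_iti": _round_half_up(rep.rate_no_tone_per_min, 2)
                == float(row["printed_rate_iti"]),
                "match_iota": _round_half_up(rep.iota, 1) == float(row["printed_iota"]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# event-log CSV dialect


def write_event_log_csv(
    path: str | Path, logs, subject_ids: list[str] | None = None
) -> None:
    """Write event logs to CSV, one decimal per timestamp.

    ``logs`` is one :class:`EventLog` or a list; with ``subject_ids`` a
    combined file gains a leading ``subject_id`` column (one id per log).
    """
    if isinstance(logs, EventLog):
        logs = [logs]
    lines = []
    if subject_ids is not None:
        if len(subject_ids) != len(logs):
            raise ValueError("need one subject_id per log")
        lines.append("subject_id,session_id,time_s,event")
        for sid, log in zip(subject_ids, logs):
            for t, kind in log.events:
                lines.append(f"{sid},{log.session_id},{t:.1f},{kind}")
    else:
        lines.append("session_id,time_s,event")
        for log in logs:
            for t, kind in log.events:
                lines.append(f"{log.session_id},{t:.1f},{kind}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_log_csv(path: str | Path, validate: bool = True):
    """Read an event-log CSV back into :class:`EventLog` objects.

    Returns a list of logs for the plain dialect, or a dict
    ``{subject_id: [logs]}`` when a ``subject_id`` column is present.
    Malformed rows raise :class:`EventLogError` with their line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        has_subject = header[0] == "subject_id"
        expected = (
            ["subject_id", "session_id", "time_s", "event"]
            if has_subject
            else ["session_id", "time_s", "event"]
        )
        if header != expected:
            raise EventLogError(f"{path}: unexpected header {header!r}")
        groups: dict[tuple[str, ...], EventLog] = {}
        order: list[tuple[str, ...]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(expected):
                raise EventLogError(f"{path}:{lineno}: expected {len(expected)} fields")
            try:
                t = float(parts[-2])
            except ValueError as exc:
                raise EventLogError(f"{path}:{lineno}: bad timestamp {parts[-2]!r}") from exc
            kind = parts[-1]
            key = tuple(parts[:-2])
            if key not in groups:
                groups[key] = EventLog(session_id=key[-1], events=[])
                order.append(key)
            groups[key].events.append(Event(t, kind))
    if validate:
        for log in groups.values():
            validate_log(log)
    if has_subject:
        out: dict[str, list[EventLog]] = {}
        for key in order:
            out.setdefault(key[0], []).append(groups[key])
        return out
    return [groups[k] for k in order]


# ---------------------------------------------------------------------------
# run configuration


def load_config(path: str | Path) -> dict:
    """Load a flat YAML run configuration (protocol, agent, seeds, output)."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    if "base_seed" not in cfg:
        raise ValueError(f"{path}: configuration must state base_seed (no wall-clock seeding)")
    return cfg
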