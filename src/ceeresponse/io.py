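"""File formats, manifests and detection-summary tables.

All tabular data are comma-separated text with a header row (UTF-8, '.'
decimal); fitted results and generating truths are JSON.  Readers are
strict: a missing column or a non-numeric cell is an error with row/column
context, unknown extra columns only warn.

Summary tables mirror the study's reporting: one row per CEE and response
metric with posterior phase means and detection markers, plus footer rows
giving detections/total (and a percentage) separately per CEE type and
phase comparison.  A CEE lacking usable data for a metric is excluded from
that metric's denominator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import CEE_TYPES, Ping, PingLog
from .latent import CeeResult
from .schedule import PHASES, PhaseSchedule, make_phase_schedule
from .simulate import CeeDataset

TRACK_COLUMNS = ("time_s", "x_m", "y_m")
BLOCK_COLUMNS = ("block_index", "phase", "value", "observed")
PING_COLUMNS = ("time_s", "range_m", "spl_db", "sel_db", "transmitted")

#: which data-availability flag gates each response metric
METRIC_FLAGS = {"whistles": "pam", "subgroups": "subgroup", "speed": "uas"}


# ----------------------------------------------------------------------
# low-level readers/writers


def _check_columns(
    df: pd.DataFrame,
    required: tuple[str, ...],
    path,
    optional: tuple[str, ...] = (),
) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required and c not in optional]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=3)


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
            f"{col!r}, row {row}"
        )
    return vals.to_numpy()


def read_track(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TRACK_COLUMNS, path)
    out = pd.DataFrame({c: _numeric(df, c, path) for c in TRACK_COLUMNS})
    t = out["time_s"].to_numpy()
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        bad = np.flatnonzero(np.diff(t) <= 0)
        row = int(bad[0]) + 1 if bad.size else 0
        raise ValueError(f"{path}: track times not strictly increasing (row {row})")
    return out


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, index=False)


def read_blocks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    # a combined per-CEE file carries an extra metric column
    _check_columns(df, BLOCK_COLUMNS, path, optional=("metric",))
    observed = df["observed"].astype(bool).to_numpy()
    value = _numeric(df, "value", path)
    bad = ~observed & ~np.isnan(value)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: row {row} has a value but observed = 0 "
            "(value must be present iff observed)"
        )
    bad = observed & np.isnan(value)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: row {row} observed but value missing")
    phase = df["phase"].astype(str)
    unknown = ~phase.isin(PHASES)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise ValueError(
            f"{path}: unknown phase {phase.iloc[row]!r} in row {row}"
        )
    return pd.DataFrame(
        {
            "block_index": _numeric(df, "block_index", path).astype(int),
            "phase": phase.to_numpy(dtype=object),
            "value": value,
            "observed": observed,
        }
    )


def write_blocks(blocks: pd.DataFrame, path) -> None:
    out = blocks.copy()
    out["observed"] = out["observed"].astype(int)
    out.to_csv(path, index=False)


def read_pings(path, source_level: float = 212.0,
               cee_type: str | None = None) -> PingLog:
    """Read a ping log; levels are taken as stored, not recomputed.

    The per-ping duration is recovered from the SPL/SEL pair
    (``duration = 10^((sel - spl)/10)``).  When ``cee_type`` is not given
    it is inferred from the transmitted flag (all 0 -> control).
    """
    df = pd.read_csv(path)
    _check_columns(df, PING_COLUMNS, path)
    cols = {c: _numeric(df, c, path) for c in PING_COLUMNS}
    if cee_type is None:
        cee_type = "mfas_sim" if np.any(cols["transmitted"] != 0) else "control"
    pings = [
        Ping(
            time=float(t), range=float(r), spl=float(spl), sel=float(sel),
            duration=float(10.0 ** ((sel - spl) / 10.0)),
        )
        for t, r, spl, sel in zip(
            cols["time_s"], cols["range_m"], cols["spl_db"], cols["sel_db"]
        )
    ]
    return PingLog(pings=pings, source_level=source_level, cee_type=cee_type)


def write_pings(pings: PingLog, path) -> None:
    pings.to_frame().to_csv(path, index=False)


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


# ----------------------------------------------------------------------
# manifests


@dataclass
class CeeManifest:
    """Catalogue entry for one CEE: identity, files, data availability."""

    cee_id: str
    subspecies: str
    cee_type: str
    schedule: PhaseSchedule
    track_path: str | None = None
    blocks_path: str | None = None
    pings_path: str | None = None
    flags: dict[str, bool] = field(
        default_factory=lambda: {"uas": True, "pam": True, "subgroup": True}
    )

    def __post_init__(self) -> None:
        if self.cee_type not in CEE_TYPES:
            raise ValueError(f"unknown cee_type {self.cee_type!r}")
        if self.subspecies not in ("short_beaked", "long_beaked"):
            raise ValueError(f"unknown subspecies {self.subspecies!r}")


def read_manifest(path) -> CeeManifest:
    """Read a JSON manifest and validate the files it references."""
    raw = json.loads(Path(path).read_text())
    base = Path(path).parent
    sched = raw["schedule"]
    schedule = make_phase_schedule(
        sched["pre_dur"], sched["exp_dur"], sched["post_dur"],
        sched.get("block_dur", 5.0),
    )
    manifest = CeeManifest(
        cee_id=raw["cee_id"],
        subspecies=raw["subspecies"],
        cee_type=raw["cee_type"],
        schedule=schedule,
        track_path=raw.get("track"),
        blocks_path=raw.get("blocks"),
        pings_path=raw.get("pings"),
        flags=raw.get("flags", {"uas": True, "pam": True, "subgroup": True}),
    )
    for attr, reader in (
        ("track_path", read_track),
        ("blocks_path", read_blocks),
        ("pings_path", read_pings),
    ):
        rel = getattr(manifest, attr)
        if rel is not None:
            p = base / rel
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
            reader(p)  # parse to validate
    return manifest


def write_cee_dataset(ds: CeeDataset, out_dir) -> Path:
    """Write a simulated CEE (track, blocks, pings, truth, manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_track(ds.track, out / "track.csv")
    blocks = []
    for metric, table in (("whistles", ds.whistles), ("subgroups", ds.subgroups)):
        t = table.copy()
        t.insert(2, "metric", metric)
        blocks.append(t)
    merged = pd.concat(blocks, ignore_index=True)
    merged["observed"] = merged["observed"].astype(int)
    merged.to_csv(out / "blocks.csv", index=False)
    write_pings(ds.pings, out / "pings.csv")
    write_truth(ds.truth, out / "truth.json")
    manifest = {
        "cee_id": ds.cee_id,
        "subspecies": ds.subspecies,
        "cee_type": ds.cee_type,
        "schedule": {
            "pre_dur": ds.schedule.pre_end - ds.schedule.pre_start,
            "exp_dur": ds.schedule.exp_end - ds.schedule.exp_start,
            "post_dur": ds.schedule.post_end - ds.schedule.post_start,
            "block_dur": ds.schedule.block_dur,
        },
        "track": "track.csv",
        "blocks": "blocks.csv",
        "pings": "pings.csv",
        "flags": {"uas": True, "pam": True, "subgroup": True},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def read_metric_blocks(path, metric: str) -> pd.DataFrame:
    """Read one metric's series from a combined blocks file."""
    df = pd.read_csv(path)
    if "metric" not in df.columns:
        raise ValueError(f"{path}: missing required column(s) ['metric']")
    sub = df[df["metric"] == metric].drop(columns=["metric"]).reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"{path}: no rows for metric {metric!r}")
    return pd.DataFrame(
        {
            "block_index": sub["block_index"].astype(int),
            "phase": sub["phase"].astype(str),
            "value": pd.to_numeric(sub["value"], errors="raise"),
            "observed": sub["observed"].astype(bool),
        }
    )


# ----------------------------------------------------------------------
# detection summaries


def detection_proportion(flags: list[bool]) -> tuple[int, int, float]:
    """Count detections and express them as a one-decimal percentage."""
    if len(flags) == 0:
        raise ValueError("detection proportion of an empty list is undefined")
    k = int(sum(bool(f) for f in flags))
    n = len(flags)
    return k, n, round(100.0 * k / n, 1)


@dataclass
class SummaryTable:
    """Per-CEE detection table plus footer proportions."""

    rows: pd.DataFrame
    footers: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.rows


def build_summary(
    results: list[tuple[str, CeeResult]],
    manifests: list[CeeManifest],
) -> SummaryTable:
    """Assemble the per-CEE detection table and footer proportions.

    ``results`` pairs each CEE id with one fitted metric summary (several
    entries per CEE, one per metric).  Footers report detections/total per
    (cee_type, metric, comparison), with denominators restricted to CEEs
    whose manifest flags the metric's data stream as available.
    """
    ids = [m.cee_id for m in manifests]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cee_id in manifests: {dup}")
    by_id = {m.cee_id: m for m in manifests}

    rows = []
    for cee_id, res in results:
        if cee_id not in by_id:
            raise ValueError(f"result for unknown cee_id {cee_id!r}")
        m = by_id[cee_id]
        row = {
            "cee_id": cee_id,
            "cee_type": m.cee_type,
            "subspecies": m.subspecies,
            "metric": res.metric,
        }
        for ph in PHASES:
            mean, sd = res.phase_means[ph]
            row[f"{ph}_mean"] = round(mean, 1)
            row[f"{ph}_sd"] = round(sd, 1)
        row["p_response"] = res.p_response
        row["response_direction"] = res.response_direction
        row["p_persistence"] = res.p_persistence
        row["persistence_direction"] = res.persistence_direction
        row["detected_exposure"] = res.detected_exposure
        row["detected_post"] = res.detected_post
        rows.append(row)
    rows_df = pd.DataFrame(rows)

    footers = []
    mfas_types = ("mfas_sim", "mfas_navy")
    for metric in sorted({r.metric for _, r in results}):
        flag = METRIC_FLAGS.get(metric)
        for label, types in (("mfas", mfas_types), ("control", ("control",))):
            for comparison, col in (
                ("exp_vs_pre", "detected_exposure"),
                ("post_vs_pre", "detected_post"),
            ):
                flags = [
                    bool(r[col])
                    for _, r in rows_df.iterrows()
                    if r["metric"] == metric
                    and r["cee_type"] in types
                    and (flag is None or by_id[r["cee_id"]].flags.get(flag, True))
                ]
                if not flags:
                    continue
                k, n, pct = detection_proportion(flags)
                footers.append(
                    {
                        "metric": metric,
                        "cee_type": label,
                        "comparison": comparison,
                        "detections": k,
                        "total": n,
                        "pct": pct,
                    }
                )
    return SummaryTable(rows=rows_df, footers=pd.DataFrame(footers))


def write_results(results: list[tuple[str, CeeResult]], path) -> None:
    payload = [{"cee_id": cid, **res.to_dict()} for cid, res in results]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_results(path) -> list[tuple[str, CeeResult]]:
    raw = json.loads(Path(path).read_text())
    out = []
    for item in raw:
        res = CeeResult(
            metric=item["metric"],
            family=item["family"],
            phase_means={k: tuple(v) for k, v in item["phase_means"].items()},
            p_response=item["p_response"],
            response_direction=item["response_direction"],
            p_persistence=item["p_persistence"],
            persistence_direction=item["persistence_direction"],
            detected_exposure=item["detected_exposure"],
            detected_post=item["detected_post"],
            psrf=item["psrf"],
        )
        out.append((item["cee_id"], res))
    return out
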