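"""Readers/writers: trace CSVs with JSON sidecars, configs and manifests.

The interchange format is a two-column CSV (``time_s, amplitude``) per
channel plus a JSON sidecar (same stem, ``.json``) carrying the channel,
condition, sampling rate and -- for synthetic data -- the ground truth and
generating profile.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .signals import SignalTrace
from .synthetic import GroundTruth, VirtualParticipantProfile

__version__ = "0.1.0"

#: tolerated sampling jitter relative to the median interval
MAX_JITTER = 0.01


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_trace(
    trace: SignalTrace,
    path,
    ground_truth: GroundTruth | None = None,
    profile: VirtualParticipantProfile | None = None,
) -> Path:
    """Write a trace CSV plus its JSON sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    times = trace.times()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "amplitude"])
        for t, a in zip(times, trace.samples):
            writer.writerow([f"{t:.9g}", f"{a:.9g}"])
    meta = {
        "channel": trace.channel,
        "condition": trace.condition,
        "sampling_rate": trace.sampling_rate,
        "n_samples": len(trace.samples),
    }
    if ground_truth is not None:
        meta["ground_truth"] = ground_truth.to_dict()
    if profile is not None:
        meta["profile"] = dataclasses.asdict(profile)
    with open(sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_trace(path) -> SignalTrace:
    """Read a trace CSV, validating shape, monotonicity and uniformity.

    Malformed rows, non-monotone times and sampling jitter above 1% are
    rejected with the offending line number.
    """
    path = Path(path)
    times, amps = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["time_s", "amplitude"]:
            raise ValueError(f"{path}: expected header 'time_s,amplitude'")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, found {len(row)}")
            try:
                t, a = float(row[0]), float(row[1])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({err})") from None
            if times and t <= times[-1]:
                raise ValueError(f"{path}:{lineno}: time not strictly increasing")
            times.append(t)
            amps.append(a)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(times)
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > MAX_JITTER * med:
        lineno = int(np.argmax(np.abs(dt - med))) + 3
        raise ValueError(f"{path}:{lineno}: sampling not uniform within 1%")
    meta: dict = {}
    channel, condition = "ppg", None
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = json.load(fh)
        channel = meta.get("channel", "ppg")
        condition = meta.get("condition")
    trace_meta = {}
    if "ground_truth" in meta:
        trace_meta["ground_truth"] = GroundTruth.from_dict(meta["ground_truth"])
    return SignalTrace(np.asarray(amps), 1.0 / med, channel=channel, condition=condition, meta=trace_meta)


# ---------------------------------------------------------------------- #
# configuration
# ---------------------------------------------------------------------- #


@dataclass
class RunConfig:
    """Top-level run configuration; YAML round-trip stable."""

    sampling_rate: float = 75.0
    seed: int = 0
    design: str = "study2"
    n_per_group: int = 27
    ref_bpm: float = 70.0
    range_bpm: float = 25.0
    death_enabled: bool = True
    filter_dialect: str = "normalized"
    filter_cutoff: float = 0.1
    profile: dict = field(default_factory=dict)
    out_dir: str = "results"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def config_hash(config: RunConfig | dict) -> str:
    d = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(out_dir, config, seed: int) -> Path:
    """Deterministic run manifest (config hash, seed, package version)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(config),
        "seed": seed,
        "package": "biofeedbacklab",
        "version": __version__,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def write_study_report(report, out_dir, seed: int = 0) -> None:
    """Tidy CSV outputs plus a manifest for a study run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.metrics.to_csv(out_dir / "metrics.csv", index=False)
    rows = []
    for name, res in report.stats.items():
        rows.append(
            {
                "effect_name": name, "statistic_kind": res.statistic_kind,
                "statistic_value": res.statistic_value,
                "df": str(res.df), "p_value": res.p_value, "n": res.n,
                "degenerate": res.degenerate, "note": res.note,
            }
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(out_dir / "stats.csv", index=False)
    report.exclusions.to_csv(out_dir / "exclusions.csv", index=False)
    with open(out_dir / "accounting.json", "w") as fh:
        json.dump({"design": report.design, "n_input": report.n_input, "tests": report.accounting}, fh, indent=1)
    write_manifest(out_dir, {"design": report.design, "seed": seed}, seed)
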