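"""Batch orchestration: run many knees from a manifest, with per-knee isolation.

A :class:`RunConfig` is a fully serializable description of a run (manifest,
per-knee parameters, statistics options, output directory); re-running the
same config with the same seeds reproduces all outputs.  One knee failing
never aborts the batch: failures are logged with the knee ID and cause, and
the run's exit status reflects whether any occurred.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .es_segmentation import ThresholdSpec, segment_effusion
from .hs_quantification import HoffaSliceScheme, compute_x_hoff, sample_reference
from .image_core import PolygonROI, SliceRange, read_volume

__all__ = ["RunConfig", "BatchResult", "run_batch", "timing_report"]


@dataclass
class RunConfig:
    """Serializable configuration for a batch run.

    The manifest is a list of per-knee entries.  ES entries need ``volume``,
    ``range`` ([first, last]) and threshold settings; HS entries need
    ``volume``, ``center_slice``, four ``rois`` and a ``ref_roi`` (paths to
    ROI JSON files), plus ``k``.
    """

    manifest: list = field(default_factory=list)
    icc_model: str = "two_way_random_absolute_single"
    bootstrap_replicates: int = 500
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        obj = json.loads(p.read_text())
        return cls(**obj)

    def to_json(self) -> str:
        return json.dumps(
            {
                "manifest": self.manifest,
                "icc_model": self.icc_model,
                "bootstrap_replicates": self.bootstrap_replicates,
                "seed": self.seed,
                "out_dir": self.out_dir,
            },
            sort_keys=True,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class BatchResult:
    results: pd.DataFrame
    failures: list[dict]
    log_path: Path

    @property
    def ok(self) -> bool:
        return not self.failures


def _process_entry(entry: dict) -> dict:
    knee_id = entry.get("knee_id", "unknown")
    kind = entry.get("kind", "es")
    volume = read_volume(entry["volume"])
    if kind == "es":
        rng = SliceRange(*entry["range"])
        spec = ThresholdSpec(
            mode=entry.get("threshold_mode", "otsu_within_range"),
            value=entry.get("threshold_value"),
            applies_to=rng,
        )
        res = segment_effusion(
            volume,
            rng,
            spec,
            connectivity=entry.get("connectivity", 8),
            min_area_mm2=entry.get("min_area_mm2", 0.0),
            rejections=[tuple(p) for p in entry.get("reject", [])],
            reject_flagged=entry.get("reject_flagged", False),
        )
        return {
            "knee_id": knee_id,
            "kind": "es",
            "threshold_used": res.threshold_used,
            "n_slices": rng.count,
            "v_eff_mm3": res.v_eff_mm3,
            "v_norm_mm3_per_slice": res.v_norm_mm3_per_slice,
        }
    if kind == "hs":
        scheme = HoffaSliceScheme(
            center_slice_i=entry["center_slice"],
            offsets=tuple(entry.get("offsets", (-3, -1, 1, 3))),
        )
        rois = [PolygonROI.load(p) for p in entry["rois"]]
        ref = sample_reference(volume, PolygonROI.load(entry["ref_roi"]), entry.get("k", 2.0))
        res = compute_x_hoff(volume, scheme, rois, ref)
        return {
            "knee_id": knee_id,
            "kind": "hs",
            "threshold_used": res.threshold,
            "x_hoff_mm3": res.x_hoff_mm3,
            **{f"roi{i}_mm3": v for i, v in enumerate(res.per_roi_volume_mm3)},
        }
    raise ValueError(f"unknown entry kind {kind!r}")


def run_batch(config: RunConfig) -> BatchResult:
    """Process every manifest entry; log progress; never abort on one knee."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    lines = [
        f"{_now()} synovolume {__version__} config_hash={config.config_hash()} "
        f"seed={config.seed}"
    ]
    rows: list[dict] = []
    failures: list[dict] = []
    for entry in config.manifest:
        knee_id = entry.get("knee_id", "unknown")
        t0 = time.monotonic()
        try:
            rows.append(_process_entry(entry))
            status = "ok"
        except Exception as exc:
            failures.append({"knee_id": knee_id, "error": f"{type(exc).__name__}: {exc}"})
            status = f"FAILED {type(exc).__name__}: {exc}"
        lines.append(f"{_now()} knee={knee_id} elapsed_s={time.monotonic() - t0:.3f} {status}")
    results = pd.DataFrame(rows)
    results.to_csv(out_dir / "results.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
    log_path.write_text("\n".join(lines) + "\n")
    return BatchResult(results=results, failures=failures, log_path=log_path)


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%S.%f%z")


def timing_report(log_path: str | Path) -> pd.DataFrame:
    """Per-knee and mean wall-clock summary parsed from a run log.

    Reported for workflow bookkeeping only; timings are hardware-dependent
    and never asserted against.
    """
    lines = Path(log_path).read_text().splitlines()
    rows = []
    for line in lines:
        parts = dict(
            p.split("=", 1) for p in line.split() if "=" in p and not p.startswith("20")
        )
        if "knee" in parts and "elapsed_s" in parts:
            rows.append({"knee_id": parts["knee"], "elapsed_s": float(parts["elapsed_s"])})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    mean_row = pd.DataFrame([{"knee_id": "__mean__", "elapsed_s": df["elapsed_s"].mean()}])
    return pd.concat([df, mean_row], ignore_index=True)
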