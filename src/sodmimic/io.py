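"""Plain-text readers and writers for traces, peak lists and manifests.

Instrument vendors ship proprietary formats; this package reads and
writes simple delimited text instead and leaves format adapters to the
caller.  Traces are two-column CSV with header ``time_s,absorbance``
(one file per replicate); peak lists are CSV with header
``mz,intensity``.  A campaign manifest is a YAML file binding trace
files to assay metadata (wavelength, extinction coefficient, optical
path, catalyst concentration per file, optional blank).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import DecayTrace
from .species import Assignment, PeakList, species_composition

__all__ = [
    "read_trace",
    "write_trace",
    "read_peaklist",
    "write_peaklist",
    "load_manifest",
    "write_campaign",
    "write_assignment_report",
    "write_json_report",
]


def _read_table(path, required: tuple[str, str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; header must be {','.join(required)}")
    bad = df[list(required)].isna().any(axis=1)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        rows = [int(i) + 2 for i in df.index[bad][:5]]
        raise ValueError(f"{path}: malformed/NaN values at line(s) {rows}")
    return df


def read_trace(source, **metadata) -> DecayTrace:
    """Read a ``time_s,absorbance`` CSV; metadata keywords (wavelength,
    epsilon, optical ``path``, ``b``, ...) are merged into the trace."""
    df = _read_table(source, ("time_s", "absorbance"))
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) >= 2 and np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise ValueError(f"{source}: time not strictly increasing at line {i + 3}")
    return DecayTrace(time=t, absorbance=df["absorbance"].to_numpy(dtype=float), **metadata)


def write_trace(trace: DecayTrace, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": trace.time, "absorbance": trace.absorbance}).to_csv(
        path, index=False, float_format="%.9g"
    )
    return path


def read_peaklist(path) -> PeakList:
    """Read an ``mz,intensity`` CSV; a header-only file yields an empty list."""
    df = _read_table(path, ("mz", "intensity"))
    return PeakList(mz=df["mz"].to_numpy(dtype=float), intensity=df["intensity"].to_numpy(dtype=float))


def write_peaklist(peaks: PeakList, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"mz": peaks.mz, "intensity": peaks.intensity}).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


# --------------------------------------------------------------------------
# Manifests and campaigns
# --------------------------------------------------------------------------


def load_manifest(path) -> dict:
    """Load and validate a campaign manifest (YAML).

    Required keys: ``epsilon`` (M^-1 cm^-1), ``traces`` (list of
    ``{file, b}``); optional: ``wavelength`` (nm, default 250),
    ``path_cm`` (default 1.0), ``blank`` (trace file subtracted from all
    runs).  File paths are resolved relative to the manifest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: manifest must be a mapping")
    for key in ("epsilon", "traces"):
        if key not in doc:
            raise ValueError(f"{path}: manifest missing required key {key!r}")
    if float(doc["epsilon"]) <= 0:
        raise ValueError(f"{path}: epsilon must be positive")
    doc.setdefault("wavelength", 250.0)
    doc.setdefault("path_cm", 1.0)
    root = path.parent
    for entry in doc["traces"]:
        if "file" not in entry or "b" not in entry:
            raise ValueError(f"{path}: each trace entry needs 'file' and 'b'")
        entry["file"] = str((root / entry["file"]).resolve())
        if not Path(entry["file"]).exists():
            raise FileNotFoundError(f"{path}: trace file not found: {entry['file']}")
        entry["b"] = float(entry["b"])
    if doc.get("blank"):
        doc["blank"] = str((root / doc["blank"]).resolve())
        if not Path(doc["blank"]).exists():
            raise FileNotFoundError(f"{path}: blank file not found: {doc['blank']}")
    return doc


def write_campaign(campaign, out_dir) -> Path:
    """Write an :class:`~sodmimic.simulate.ActivityCampaign` to disk.

    One CSV per trace plus a ``manifest.yaml``; returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tr in enumerate(campaign.background):
        f = f"background_{i}.csv"
        write_trace(tr, out / f)
        entries.append({"file": f, "b": 0.0, "replicate": tr.replicate})
    for b, reps in campaign.catalyzed.items():
        for i, tr in enumerate(reps):
            f = f"b{b*1e6:g}uM_{i}.csv"
            write_trace(tr, out / f)
            entries.append({"file": f, "b": float(b), "replicate": tr.replicate})
    any_trace = campaign.background[0]
    manifest = {
        "wavelength": float(any_trace.wavelength),
        "epsilon": float(any_trace.epsilon),
        "path_cm": float(any_trace.path),
        "traces": entries,
        "truth": campaign.truth,
    }
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------


def write_assignment_report(peaks: PeakList, assignments: list[list[Assignment]], path) -> Path:
    """Delimited annotation table: one row per (peak, candidate) match."""
    rows = []
    for i, matches in enumerate(assignments):
        if not matches:
            rows.append(
                {"mz": peaks.mz[i], "intensity": peaks.intensity[i], "z": "",
                 "species": "", "formula": "", "theo_mz": "", "ppm": "", "isotope_score": ""}
            )
        for rank, a in enumerate(matches):
            rows.append(
                {
                    "mz": peaks.mz[i],
                    "intensity": peaks.intensity[i],
                    "z": a.species.z,
                    "species": a.species.label,
                    "formula": species_composition(a.species).hill_formula(),
                    "theo_mz": f"{a.theoretical_mz:.5f}",
                    "ppm": f"{a.ppm_error:.3f}",
                    "isotope_score": "" if a.isotope_similarity is None else f"{a.isotope_similarity:.4f}",
                }
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_json_report(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
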