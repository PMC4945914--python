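"""Reading and writing recordings, connectivity matrices and reports.

The canonical on-disk recording format is a plain channels x samples CSV with
a JSON sidecar header (``<stem>.json``) holding fs_hz, channel labels,
subject id and group; it round-trips losslessly and needs no binary
dependencies.  EDF recordings can be *read* when ``mne`` is installed
(optional extra); EDF writing is not supported.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fconnet.connectivity import ConnectivityMatrix
from fconnet.preproc import Recording, ValidationError


class FormatError(ValueError):
    """Malformed on-disk recording."""


def write_recording(rec: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write a Recording as ``<stem>.csv`` + ``<stem>.json`` sidecar."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    np.savetxt(csv_path, rec.data, delimiter=",", fmt="%.17g")
    header = {
        "fs_hz": rec.fs_hz,
        "channel_labels": rec.channel_labels,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "units": "uV",
    }
    if rec.artifact_epochs is not None:
        header["artifact_epochs"] = [int(k) for k in rec.artifact_epochs]
    json_path.write_text(json.dumps(header, indent=1))
    return csv_path, json_path


def _read_csv_json(path: Path) -> Recording:
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    if not csv_path.exists():
        raise FormatError(f"missing CSV file: {csv_path}")
    if not json_path.exists():
        raise FormatError(f"missing JSON sidecar: {json_path}")
    try:
        header = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed JSON sidecar {json_path}: {exc}") from exc
    if "fs_hz" not in header:
        raise FormatError(f"fs_hz missing from sidecar {json_path}")
    try:
        data = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"ragged or non-numeric rows in {csv_path}: {exc}") from exc
    if "n_channels" in header and data.shape[0] != header["n_channels"]:
        raise FormatError(
            f"{csv_path}: {data.shape[0]} rows but header says "
            f"{header['n_channels']} channels"
        )
    art = header.get("artifact_epochs")
    return Recording(
        data=data,
        fs_hz=float(header["fs_hz"]),
        channel_labels=list(header.get("channel_labels", [])),
        subject_id=str(header.get("subject_id", path.stem)),
        group=str(header.get("group", "unknown")),
        artifact_epochs=None if art is None else np.asarray(art, dtype=int),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional extra
        raise FormatError(
            "EDF reading requires the optional 'mne' dependency (pip install fconnet[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; recordings are in uV
    return Recording(
        data=data,
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=path.stem,
        group="unknown",
    )


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a Recording from CSV+JSON (default) or EDF.

    A missing group label in the sidecar yields ``group="unknown"``; group
    statistics will refuse such subjects later.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv+json"
    if format == "csv+json":
        return _read_csv_json(path)
    if format == "edf":
        if not path.exists():
            raise FormatError(f"missing EDF file: {path}")
        return _read_edf(path)
    raise ValidationError(f"unknown format {format!r}; valid: csv+json, edf")


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> Path:
    """Square CSV with channel-label header row/column."""
    path = Path(path)
    df = pd.DataFrame(cm.weights, index=cm.channel_labels, columns=cm.channel_labels)
    df.to_csv(path, float_format="%.10g")
    return path


def connectivity_long_table(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Long-format table (subject, group, estimator, i, j, weight), i < j."""
    rows = []
    for cm in matrices:
        n = cm.n_channels
        iu, ju = np.triu_indices(n, 1)
        for i, j in zip(iu, ju):
            rows.append(
                {
                    "subject": cm.subject_id,
                    "group": cm.group,
                    "estimator": cm.estimator,
                    "i": cm.channel_labels[i],
                    "j": cm.channel_labels[j],
                    "weight": cm.weights[i, j],
                }
            )
    return pd.DataFrame(rows)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_results(
    report: dict,
    outdir: str | Path,
    config: dict | None = None,
    force: bool = False,
) -> list[Path]:
    """Write a report as JSON plus per-cell CSV tables, deterministically named
    ``{estimator}_{binarizer}_{metric}``.

    The config that produced the results (plus its hash) is embedded and also
    written alongside, for provenance.  Refuses to overwrite an existing
    non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    payload = dict(report)
    if config is not None:
        payload["config"] = config
        payload["run_hash"] = _config_hash(config)
        cfg_path = outdir / "config.json"
        cfg_path.write_text(json.dumps(config, indent=1, sort_keys=True, default=str))
        written.append(cfg_path)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    written.append(report_path)
    for cell in report.get("cells", []):
        name = f"{cell['estimator']}_{cell['binarizer']}_{cell['metric']}"
        rows = []
        for k, p in enumerate(cell["parameter_grid"]):
            row = {
                "parameter": p,
                "p_value": cell["p_values"][k],
                "significant": cell["significant"][k],
            }
            for g, d in cell["groups"].items():
                row[f"mean_{g}"] = d["mean"][k]
                row[f"sem_{g}"] = d["sem"][k]
                row[f"n_{g}"] = d["n"][k]
            rows.append(row)
        cell_path = outdir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(cell_path, index=False, float_format="%.10g")
        written.append(cell_path)
    return written
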