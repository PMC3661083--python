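"""Serialization: recordings, model specs, coupling tables, graphs, manifests.

Recordings travel either as European Data Format (EDF) files — read
through MNE when it is installed — or as plain delimited matrices
(channels x samples) with a one-line header ``# fs=<Hz>
channels=<comma-separated labels>``. VAR model specifications are YAML
with lag-indexed coefficient matrices. Coupling matrices are written as
labelled tab-separated tables (row = target, column = source), optionally
with the surrogate threshold in brackets next to each value.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .coupling import CouplingMatrix
from .selection import SelectionTrace
from .simulate import DataError, Recording, VarModelSpec

__all__ = [
    "read_recording",
    "write_recording",
    "read_model_spec",
    "write_model_spec",
    "coupling_table",
    "write_coupling_table",
    "selection_table",
    "write_fit_report",
    "write_graphml",
    "write_dot",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def write_recording(path, recording: Recording, fmt: str = "%.10g") -> None:
    """Write a recording as a delimited text matrix with a ``# fs=`` header."""
    path = Path(path)
    header = (
        f"fs={recording.sampling_rate:g} "
        f"channels={','.join(recording.channel_labels)}"
    )
    np.savetxt(path, recording.data, fmt=fmt, header=header)


def _read_text_recording(path: Path) -> Recording:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise DataError(
            f"{path}: missing '# fs=<Hz> channels=<labels>' header line"
        )
    fields = dict(
        tok.split("=", 1) for tok in first.lstrip("#").split() if "=" in tok
    )
    if "fs" not in fields:
        raise DataError(f"{path}: header does not declare fs=<Hz>")
    fs = float(fields["fs"])
    labels = fields.get("channels", "").split(",") if fields.get("channels") else None
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    if labels and len(labels) != data.shape[0]:
        raise DataError(
            f"{path}: {len(labels)} labels for {data.shape[0]} channel rows"
        )
    return Recording(data=data, sampling_rate=fs, channel_labels=labels or [])


def _read_edf_recording(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne optional
        raise DataError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install eipr[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data(),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def read_recording(path) -> Recording:
    """Read a recording from EDF (by extension) or a headered text matrix."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"recording file {path} does not exist")
    if path.stat().st_size == 0:
        raise DataError(f"recording file {path} is empty")
    if path.suffix.lower() == ".edf":
        return _read_edf_recording(path)
    return _read_text_recording(path)


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

def write_model_spec(path, spec: VarModelSpec) -> None:
    doc = {
        "n_channels": spec.n_channels,
        "order": spec.order,
        "coeffs": {
            f"lag_{j + 1}": spec.coeffs[j].tolist() for j in range(spec.order)
        },
        "noise_cov": spec.noise_cov.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model_spec(path) -> VarModelSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        p = int(doc["order"])
        K = int(doc["n_channels"])
        coeffs = np.array([doc["coeffs"][f"lag_{j + 1}"] for j in range(p)],
                          dtype=float)
        noise_cov = np.array(doc["noise_cov"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise DataError(f"malformed model spec {path}: {exc}") from exc
    if coeffs.shape != (p, K, K):
        raise DataError(
            f"model spec {path}: coefficient shape {coeffs.shape} "
            f"inconsistent with order={p}, n_channels={K}"
        )
    return VarModelSpec(coeffs=coeffs, noise_cov=noise_cov)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def coupling_table(matrix: CouplingMatrix, with_thresholds: bool = False) -> pd.DataFrame:
    """Coupling matrix as a labelled DataFrame (row = target, col = source).

    With ``with_thresholds`` each off-diagonal cell is rendered as
    ``value (threshold)`` — the familiar printed layout.
    """
    K = matrix.n_channels
    labels = matrix.channel_labels or [f"ch{k}" for k in range(K)]
    if not with_thresholds:
        return pd.DataFrame(matrix.values, index=labels, columns=labels)
    if matrix.thresholds is None:
        raise DataError("matrix has no thresholds to render")
    cells = []
    for k in range(K):
        row = []
        for l in range(K):
            if k == l:
                row.append(f"{matrix.values[k, l]:.5f}")
            else:
                row.append(
                    f"{matrix.values[k, l]:.5f} ({matrix.thresholds[k, l]:.5f})"
                )
        cells.append(row)
    return pd.DataFrame(cells, index=labels, columns=labels)


def write_coupling_table(path, matrix: CouplingMatrix,
                         with_thresholds: bool = False) -> None:
    coupling_table(matrix, with_thresholds=with_thresholds).to_csv(
        path, sep="\t", index_label="target\\source"
    )


def selection_table(trace: SelectionTrace, labels: Optional[list[str]] = None) -> pd.DataFrame:
    """Selection trace as a step-by-step table (one row per candidate)."""
    def name(k: int) -> str:
        return labels[k] if labels else f"ch{k}"

    rows = []
    for i, step in enumerate(trace.steps, start=1):
        for cand, value in sorted(step.candidates.items()):
            rows.append({
                "target": name(trace.target),
                "step": i,
                "candidate": name(cand),
                "bic": value,
                "chosen": name(step.chosen) if step.chosen is not None else "STOP",
            })
    return pd.DataFrame(rows)


def write_fit_report(path, fits) -> None:
    """Serialize equation fits (target, set, coefficients, rss, n_rows) as JSON."""
    doc = [
        {
            "target": f.target,
            "extrinsic_set": list(f.extrinsic_set),
            "order": f.order,
            "coefficients": {
                str(l): f.coefficients_for(l).tolist() for l in f.sources
            },
            "rss": f.rss,
            "n_rows": f.n_rows,
        }
        for f in fits
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Graphs
# ---------------------------------------------------------------------------

def write_graphml(path, graph: nx.DiGraph) -> None:
    g = graph.copy()
    for _, attrs in g.nodes(data=True):
        if "pos" in attrs:  # GraphML cannot store tuples
            attrs["x"], attrs["y"] = attrs.pop("pos")
    nx.write_graphml(g, path)


def write_dot(path, graph: nx.DiGraph) -> None:
    """Minimal DOT serialization (directed, weights as edge labels)."""
    lines = ["digraph coupling {"]
    for node in graph.nodes:
        lines.append(f'  "{node}";')
    for u, v, attrs in graph.edges(data=True):
        w = attrs.get("weight", 1.0)
        lines.append(f'  "{u}" -> "{v}" [label="{w:.4g}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, config: dict, seed: Optional[int] = None,
                   inputs: Optional[list] = None) -> None:
    """Record everything needed to re-run a command: config, seed, input digests."""
    from . import __version__

    def jsonable(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return asdict(obj)
        return str(obj)

    doc = {
        "command": command,
        "config": config,
        "seed": seed,
        "inputs": {str(p): _digest(p) for p in (inputs or []) if Path(p).exists()},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=jsonable)
        fh.write("\n")
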