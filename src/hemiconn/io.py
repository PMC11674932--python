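"""Plain-text cohort I/O.

Formats:

* matrices — whitespace-delimited square numeric text, one file per subject
  per matrix (``<id>_weights.txt``, ``<id>_lengths.txt``), full float
  precision so round trips are lossless;
* region sidecar — ``labels.tsv`` with columns label, hemisphere (L/R/M),
  cortical (0/1), shared by every subject of a cohort;
* subject table — ``subjects.csv`` with header, one row per subject;
* ground truth — ``ground_truth.json``;
* manifest — ``manifest.json`` listing subjects and files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, InvalidConnectomeError

__all__ = ["write_cohort", "read_cohort", "read_labels", "write_labels",
           "read_matrix", "write_matrix"]

_FLOAT_FMT = "%.17g"
MANIFEST_NAME = "manifest.json"


def write_matrix(path: Path, m: np.ndarray) -> None:
    np.savetxt(path, m, fmt=_FLOAT_FMT)


def read_matrix(path: Path) -> np.ndarray:
    m = np.loadtxt(path, ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({m.shape})")
    return m


def write_labels(path: Path, labels, hemisphere, cortical) -> None:
    df = pd.DataFrame({"label": list(labels),
                       "hemisphere": list(hemisphere),
                       "cortical": np.asarray(cortical, dtype=int)})
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: Path):
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "hemisphere": str})
    return (tuple(df["label"]), df["hemisphere"].to_numpy(dtype=object),
            df["cortical"].to_numpy(dtype=bool))


def write_cohort(cohort, directory: str | Path) -> dict:
    """Write connectomes + subject table + ground truth; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = list(cohort.records.index)
    subjects = []
    for sid, conn in zip(ids, cohort.connectomes):
        write_matrix(directory / f"{sid}_weights.txt", conn.weights)
        write_matrix(directory / f"{sid}_lengths.txt", conn.lengths)
        subjects.append(sid)
    if cohort.connectomes:
        c0 = cohort.connectomes[0]
        write_labels(directory / "labels.tsv", c0.labels, c0.hemisphere, c0.cortical)
    cohort.records.to_csv(directory / "subjects.csv")
    (directory / "ground_truth.json").write_text(json.dumps(cohort.ground_truth))
    manifest = {
        "format": "hemiconn-cohort-1",
        "n_subjects": len(subjects),
        "subjects": subjects,
        "files": {"labels": "labels.tsv", "records": "subjects.csv",
                  "ground_truth": "ground_truth.json"},
    }
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return manifest


def read_cohort(directory: str | Path):
    """Load a written cohort, validating every connectome.

    Returns ``(connectomes, records, ground_truth, errors)`` where
    ``errors`` maps subject id -> message for subjects whose matrices fail
    the connectome invariants (those subjects are excluded from the
    returned tables, mirroring a quality-control exclusion step).
    """
    directory = Path(directory)
    mpath = directory / MANIFEST_NAME
    if not mpath.exists():
        raise FileNotFoundError(f"no cohort manifest at {mpath}")
    manifest = json.loads(mpath.read_text())
    records = pd.read_csv(directory / "subjects.csv", index_col="id")
    gt_path = directory / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    if manifest["n_subjects"] == 0:
        return [], records, ground_truth, {}
    labels, hemis, cortical = read_labels(directory / "labels.tsv")
    connectomes, keep, errors = [], [], {}
    for sid in manifest["subjects"]:
        try:
            conn = Connectome(
                labels=labels, hemisphere=hemis, cortical=cortical,
                weights=read_matrix(directory / f"{sid}_weights.txt"),
                lengths=read_matrix(directory / f"{sid}_lengths.txt"),
            ).validate()
        except (InvalidConnectomeError, ValueError, OSError) as exc:
            errors[sid] = str(exc)
            continue
        connectomes.append(conn)
        keep.append(sid)
    records = records.loc[keep]
    return connectomes, records, ground_truth, errors
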