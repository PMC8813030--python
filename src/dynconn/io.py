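"""Reading and writing of pipeline artifacts.

Time courses and tables are delimited text (TSV); window stacks and state
models are binary array containers (``.npz``) with JSON sidecars carrying
their parameters; truth/QC/provenance records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TimecourseSet, ConnMatrix, WindowStack
from .states import StateModel

__all__ = [
    "write_timecourses",
    "read_timecourses",
    "write_metadata",
    "read_metadata",
    "write_conn_matrix",
    "read_conn_matrix",
    "save_window_stack",
    "load_window_stack",
    "save_state_model",
    "load_state_model",
    "write_json",
    "read_json",
]


def write_timecourses(ts: TimecourseSet, path) -> None:
    """One row per TR, one column per component; header line carries
    subject id and TR as a comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={ts.subject_id} tr_seconds={ts.tr_seconds}\n")
        fh.write("\t".join(ts.component_ids) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.10g")


def read_timecourses(path) -> TimecourseSet:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing metadata header line")
        fields = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").split()
        )
        component_ids = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return TimecourseSet(
        subject_id=fields["subject_id"],
        data=data,
        tr_seconds=float(fields["tr_seconds"]),
        component_ids=component_ids,
    )


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_conn_matrix(conn: ConnMatrix, path) -> None:
    df = pd.DataFrame(
        conn.values, index=conn.component_ids, columns=conn.component_ids
    )
    with open(path, "w") as fh:
        fh.write(f"# scale={conn.scale}\n")
        df.to_csv(fh, sep="\t")


def read_conn_matrix(path) -> ConnMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        scale = header.split("=", 1)[1] if "=" in header else "fisher_z"
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return ConnMatrix(
        values=df.to_numpy(float),
        scale=scale,
        component_ids=[str(c) for c in df.columns],
    )


def save_window_stack(stack: WindowStack, path) -> None:
    """``.npz`` array container plus a ``.json`` parameter sidecar."""
    path = Path(path)
    np.savez_compressed(path, windows=stack.windows, onsets=stack.onsets)
    sidecar = {
        "subject_id": stack.subject_id,
        "window_length_tr": stack.window_length_tr,
        "sigma_tr": stack.sigma_tr,
        "step_tr": stack.step_tr,
        "component_ids": stack.component_ids,
    }
    write_json(sidecar, path.with_suffix(".json"))


def load_window_stack(path) -> WindowStack:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = read_json(path.with_suffix(".json"))
    return WindowStack(
        windows=arrays["windows"],
        onsets=arrays["onsets"],
        window_length_tr=sidecar["window_length_tr"],
        sigma_tr=sidecar["sigma_tr"],
        step_tr=sidecar["step_tr"],
        component_ids=sidecar["component_ids"],
        subject_id=sidecar["subject_id"],
    )


def save_state_model(model: StateModel, path) -> None:
    path = Path(path)
    subject_ids = sorted(model.labels)
    np.savez_compressed(
        path,
        centroids=model.centroids,
        **{f"labels_{sid}": model.labels[sid] for sid in subject_ids},
    )
    write_json(
        {
            "k": model.k,
            "inertia": model.inertia,
            "silhouette_by_k": {str(k): v for k, v in model.silhouette_by_k.items()},
            "subject_ids": subject_ids,
        },
        path.with_suffix(".json"),
    )


def load_state_model(path) -> StateModel:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    sidecar = read_json(path.with_suffix(".json"))
    return StateModel(
        k=sidecar["k"],
        centroids=arrays["centroids"],
        labels={sid: arrays[f"labels_{sid}"] for sid in sidecar["subject_ids"]},
        inertia=sidecar["inertia"],
        silhouette_by_k={int(k): v for k, v in sidecar["silhouette_by_k"].items()},
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
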