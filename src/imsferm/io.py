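"""File formats: spectrum CSV + JSON sidecar, HDF5 cubes and models.

A raw spectrum CSV holds the drift axis (ms) in the first row, the retention
axis (s) in the first column and the intensity matrix in the body; sample
identity and acquisition metadata travel in a JSON sidecar next to it.
Preprocessed cubes and fitted models are stored as flat HDF5 containers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .decompose import NNMFModel, PCAModel
from .preprocess import AxisMap, GCIMSSpectrum, SpectrumCube

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "save_cube",
    "load_cube",
    "save_models",
    "load_models",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_spectrum_csv(spec: GCIMSSpectrum, path) -> None:
    path = Path(path)
    block = np.zeros((spec.intensity.shape[0] + 1, spec.intensity.shape[1] + 1))
    block[0, 1:] = spec.drift_axis
    block[1:, 0] = spec.retention_axis
    block[1:, 1:] = spec.intensity
    np.savetxt(path, block, delimiter=",", fmt="%.9g")
    meta = {
        "sample_id": spec.sample_id,
        "replicate_id": spec.replicate_id,
        "class_label": spec.class_label,
        "drift_units": spec.drift_units,
        "metadata": spec.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=float))


def read_spectrum_csv(path) -> GCIMSSpectrum:
    path = Path(path)
    block = np.loadtxt(path, delimiter=",")
    meta = json.loads(_sidecar(path).read_text())
    return GCIMSSpectrum(
        sample_id=meta["sample_id"],
        replicate_id=meta["replicate_id"],
        class_label=meta.get("class_label"),
        intensity=block[1:, 1:],
        retention_axis=block[1:, 0],
        drift_axis=block[0, 1:],
        drift_units=meta.get("drift_units", "ms"),
        metadata=meta.get("metadata", {}),
    )


def _write_strings(group: h5py.Group, name: str, values: list) -> None:
    group.create_dataset(
        name,
        data=np.array(
            ["" if v is None else str(v) for v in values], dtype=object
        ),
        dtype=h5py.string_dtype(),
    )


def _read_strings(group: h5py.Group, name: str) -> list[str]:
    return [
        v.decode() if isinstance(v, bytes) else str(v) for v in group[name][()]
    ]


def save_cube(cube: SpectrumCube, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=cube.intensity)
        f.create_dataset("retention_axis", data=cube.retention_axis)
        f.create_dataset("drift_axis", data=cube.drift_axis)
        _write_strings(f, "sample_ids", cube.sample_ids)
        _write_strings(f, "class_labels", cube.class_labels)


def load_cube(path) -> SpectrumCube:
    with h5py.File(path, "r") as f:
        labels = [lab or None for lab in _read_strings(f, "class_labels")]
        return SpectrumCube(
            intensity=f["intensity"][()],
            retention_axis=f["retention_axis"][()],
            drift_axis=f["drift_axis"][()],
            sample_ids=_read_strings(f, "sample_ids"),
            class_labels=labels,
        )


def save_models(
    path,
    axis_map: AxisMap,
    retention_axis: np.ndarray,
    drift_axis: np.ndarray,
    sample_ids: list[str],
    class_labels: list[str | None],
    pca: PCAModel | None = None,
    nnmf: NNMFModel | None = None,
) -> None:
    """One container for the fitted decomposition(s) plus the grid they refold to."""
    with h5py.File(path, "w") as f:
        f.attrs["n_retention"] = axis_map.n_retention
        f.attrs["n_drift"] = axis_map.n_drift
        f.create_dataset("retention_axis", data=retention_axis)
        f.create_dataset("drift_axis", data=drift_axis)
        _write_strings(f, "sample_ids", sample_ids)
        _write_strings(f, "class_labels", class_labels)
        if pca is not None:
            g = f.create_group("pca")
            g.create_dataset("mean_vector", data=pca.mean_vector)
            g.create_dataset("components", data=pca.components)
            g.create_dataset("scores", data=pca.scores)
            g.create_dataset(
                "explained_variance_pct", data=pca.explained_variance_pct
            )
        if nnmf is not None:
            g = f.create_group("nnmf")
            g.attrs["k"] = nnmf.k
            g.attrs["residual"] = nnmf.residual
            g.attrs["seed"] = nnmf.seed
            g.attrs["n_iterations"] = nnmf.n_iterations
            g.create_dataset("W", data=nnmf.W)
            g.create_dataset("H", data=nnmf.H)


def load_models(path) -> dict:
    """Load the model container back into PCAModel / NNMFModel plus grid info."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        out["axis_map"] = AxisMap(
            n_retention=int(f.attrs["n_retention"]),
            n_drift=int(f.attrs["n_drift"]),
        )
        out["retention_axis"] = f["retention_axis"][()]
        out["drift_axis"] = f["drift_axis"][()]
        out["sample_ids"] = _read_strings(f, "sample_ids")
        out["class_labels"] = [
            lab or None for lab in _read_strings(f, "class_labels")
        ]
        if "pca" in f:
            g = f["pca"]
            out["pca"] = PCAModel(
                mean_vector=g["mean_vector"][()],
                components=g["components"][()],
                scores=g["scores"][()],
                explained_variance_pct=g["explained_variance_pct"][()],
            )
        if "nnmf" in f:
            g = f["nnmf"]
            out["nnmf"] = NNMFModel(
                k=int(g.attrs["k"]),
                W=g["W"][()],
                H=g["H"][()],
                residual=float(g.attrs["residual"]),
                seed=int(g.attrs["seed"]),
                n_iterations=int(g.attrs["n_iterations"]),
            )
    return out
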