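"""HDF5 dataset archive: one schema for synthetic and ingested cohorts.

Layout::

    /ids                      (n,)  plan identifiers
    /mlpm                     (n, rows, cols)  normalized leaf position maps
    /labels                   (n, 9) GPR %  (criteria order in root attrs)
    /leaf_matrices            (n, 120, n_cp) raw leaf coordinates, mm
    /closed_references        (n, 60) per-pair closed coordinates, mm
    /mean_leaf_perturbation   (n,) mm
    /planes/<name>            (n, H, W) normalized dose planes

Root attributes carry the seed, normalization constants, excluded pairs and
criterion labels.  Datasets are written with ``track_times=False`` so a
fixed-seed generation produces a byte-identical file.
"""

from __future__ import annotations

import numpy as np
import h5py

from .errors import FormatError
from .gamma import NINE_CRITERIA
from .mlpm import LeafPositionMatrix
from .synthetic import SyntheticDataset

_OPTS = dict(track_times=False)


def save_dataset(dataset: SyntheticDataset, path) -> None:
    """Serialize a dataset; deterministic content for a fixed-seed dataset."""
    with h5py.File(path, "w", libver="earliest") as f:
        f.attrs["seed"] = dataset.seed
        f.attrs["plane_spacing_mm"] = dataset.plane_spacing
        f.attrs["mlpm_norm_mm"] = dataset.mlpm_norm_mm
        f.attrs["excluded_pairs"] = np.array(sorted(dataset.excluded_pairs), dtype=np.int64)
        f.attrs["degenerate_labels"] = dataset.degenerate_labels
        f.attrs["criteria"] = np.array([str(c) for c in NINE_CRITERIA], dtype="S16")

        f.create_dataset("ids", data=np.array(dataset.ids, dtype="S64"), **_OPTS)
        f.create_dataset("mlpm", data=dataset.mlpm, **_OPTS)
        f.create_dataset("labels", data=dataset.labels, **_OPTS)
        f.create_dataset(
            "leaf_matrices",
            data=np.stack([m.values for m in dataset.leaf_matrices]),
            **_OPTS,
        )
        f.create_dataset(
            "closed_references",
            data=np.stack([m.closed_reference for m in dataset.leaf_matrices]),
            **_OPTS,
        )
        f.create_dataset(
            "mean_leaf_perturbation", data=dataset.mean_leaf_perturbation_mm, **_OPTS
        )
        grp = f.create_group("planes")
        for name in sorted(dataset.planes):
            d = grp.create_dataset(name, data=dataset.planes[name], **_OPTS)
            d.attrs["norm"] = dataset.plane_norms[name]


def load_dataset(path) -> SyntheticDataset:
    """Load a dataset archive written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        for key in ("ids", "mlpm", "labels", "leaf_matrices", "closed_references"):
            if key not in f:
                raise FormatError(f"{path}: archive missing dataset {key!r}")
        ids = [s.decode() for s in f["ids"][...]]
        matrices = [
            LeafPositionMatrix(values=v, closed_reference=r, plan_id=pid)
            for v, r, pid in zip(f["leaf_matrices"][...], f["closed_references"][...], ids)
        ]
        planes = {}
        plane_norms = {}
        for name, d in f["planes"].items():
            planes[name] = d[...]
            plane_norms[name] = float(d.attrs["norm"])
        return SyntheticDataset(
            ids=ids,
            leaf_matrices=matrices,
            excluded_pairs=frozenset(int(p) for p in f.attrs["excluded_pairs"]),
            mlpm=f["mlpm"][...],
            mlpm_norm_mm=float(f.attrs["mlpm_norm_mm"]),
            planes=planes,
            plane_norms=plane_norms,
            plane_spacing=float(f.attrs["plane_spacing_mm"]),
            labels=f["labels"][...],
            mean_leaf_perturbation_mm=f["mean_leaf_perturbation"][...],
            seed=int(f.attrs["seed"]),
            degenerate_labels=bool(f.attrs["degenerate_labels"]),
        )
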