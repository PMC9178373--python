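"""File I/O: TIFF stacks, JSON sidecars, partitions, cohort tables.

Volumes travel as multipage TIFF (one page per proximodistal slice) with
the voxel size recorded in the ImageDescription tag; ground truth and
metadata as JSON sidecars; cohort manifests and tables as CSV.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
import tifffile

from .core import VoxelVolume
from .segmentation import RegionPartition


def write_tiff_stack(volume: VoxelVolume, path: str) -> str:
    """Write a volume as a multipage TIFF, voxel size in the description."""
    desc = json.dumps({"voxel_size_mm": volume.voxel_size})
    tifffile.imwrite(path, np.asarray(volume.data), description=desc,
                     photometric="minisblack")
    return path


def read_tiff_stack(path: str, voxel_size: float | None = None) -> VoxelVolume:
    """Read a multipage TIFF (or a directory of per-slice TIFFs) back.

    The voxel size is taken from the ImageDescription written by
    :func:`write_tiff_stack` unless given explicitly.
    """
    if os.path.isdir(path):
        files = sorted(f for f in os.listdir(path)
                       if f.lower().endswith((".tif", ".tiff")))
        if not files:
            raise ValueError(f"no TIFF slices in directory {path!r}")
        data = np.stack([tifffile.imread(os.path.join(path, f))
                         for f in files])
        if voxel_size is None:
            raise ValueError("voxel_size required for per-slice stacks")
        return VoxelVolume(data, voxel_size)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if voxel_size is None:
            desc = tf.pages[0].tags.get("ImageDescription")
            if desc is None:
                raise ValueError("no voxel size in file; pass voxel_size")
            voxel_size = json.loads(desc.value)["voxel_size_mm"]
    return VoxelVolume(data, float(voxel_size))


def write_partition(partition: RegionPartition, path: str) -> str:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in partition.intervals().items()}, fh,
                  indent=2)
    return path


def read_partition(path: str) -> RegionPartition:
    with open(path) as fh:
        iv = {k: tuple(v) for k, v in json.load(fh).items()}
    return RegionPartition(base=iv["base"], shaft=iv["shaft"],
                           metaphysis=iv["metaphysis"],
                           epiphysis=iv.get("epiphysis"))


def samples_to_dataframe(samples) -> pd.DataFrame:
    """Tabulate grid VOI samples (node coordinates in mm, BV/TV, fabric
    eigenstructure, validity) for CSV export."""
    rows = []
    for s in samples:
        row = {"z_mm": s.node[0], "y_mm": s.node[1], "x_mm": s.node[2],
               "bvtv": s.bvtv, "n_bone_voxels": s.n_bone_voxels,
               "valid": s.valid, "da": np.nan}
        if s.fabric is not None and s.fabric.valid:
            row["da"] = s.fabric.da
            for i in range(3):
                row[f"lambda{i + 1}"] = s.fabric.eigenvalues[i]
                for ax, name in enumerate(("z", "y", "x")):
                    row[f"evec{i + 1}_{name}"] = s.fabric.eigenvectors[ax, i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_samples(samples, path: str) -> str:
    samples_to_dataframe(samples).to_csv(path, index=False)
    return path


def write_cohort(table: pd.DataFrame, path: str) -> str:
    table.to_csv(path, index=False)
    return path


def read_cohort(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def export_specimen(specimen, out_dir: str) -> dict:
    """Write a synthetic specimen to disk: greyscale and label TIFF stacks
    plus a JSON sidecar with metadata, per-region ground truth, recorded
    region slices and the label code dictionary.  Returns the paths."""
    from dataclasses import asdict

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "volume": os.path.join(out_dir, "volume.tif"),
        "labels": os.path.join(out_dir, "labels.tif"),
        "sidecar": os.path.join(out_dir, "specimen.json"),
    }
    write_tiff_stack(specimen.volume, paths["volume"])
    write_tiff_stack(specimen.labels, paths["labels"])
    truth = {}
    for region, gt in specimen.truth.items():
        d = asdict(gt)
        if d.get("principal_axis") is not None:
            d["principal_axis"] = list(np.asarray(d["principal_axis"]))
        truth[region] = d
    sidecar = {
        "metadata": specimen.metadata,
        "truth": truth,
        "region_slices": {k: list(v)
                          for k, v in specimen.region_slices.items()},
        "gap_center": specimen.gap_center,
        "epiphysis_present": specimen.epiphysis_present,
        "gradient": specimen.gradient,
        "label_codes": {"background": 0, "cortex": 1,
                        "trabecular_bone": 2, "marrow": 3},
        "voxel_size_mm": specimen.volume.voxel_size,
    }
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return paths
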