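"""Plain-text TSV I/O for BOLD matrices, connectomes, region tables and studies.

Formats
-------
BOLD: a comment line ``# tr=<seconds>`` followed by a TSV with a
``region_id`` index column and one column per time point.

Adjacency: square TSV with region ids as both header and index.

Region table: columns ``region_id``, ``name``, ``volume_voxels``.

A study directory holds per-subject ``sub-XXX_bold.tsv`` /
``sub-XXX_connectome.tsv`` files, ``regions.tsv``, ``nuisance.tsv`` (subject
x time global signals), ``ground_truth.tsv`` and a ``manifest.yaml``
recording the full generating config and seed.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import ConnectomeMatrix
from .preprocess import BoldMatrix

__all__ = [
    "read_bold_tsv",
    "write_bold_tsv",
    "read_adjacency_tsv",
    "write_adjacency_tsv",
    "read_region_table",
    "write_region_table",
    "write_study",
    "load_study",
]


def write_bold_tsv(bold: BoldMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        bold.values,
        index=pd.Index(bold.region_ids, name="region_id"),
        columns=[f"t{j}" for j in range(bold.n_timepoints)],
    )
    with open(path, "w") as fh:
        fh.write(f"# tr={bold.tr!r}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g")


def read_bold_tsv(path) -> BoldMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# tr="):
            raise ValueError(f"{path}: missing '# tr=' header line")
        tr = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return BoldMatrix(df.values, tr=tr, region_ids=[str(r) for r in df.index])


def write_adjacency_tsv(matrix: ConnectomeMatrix | np.ndarray, path, region_ids=None) -> None:
    if isinstance(matrix, ConnectomeMatrix):
        region_ids = matrix.region_ids
        matrix = matrix.weights
    ids = region_ids or [f"region_{i:02d}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=pd.Index(ids, name="region_id"), columns=ids)
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_adjacency_tsv(path) -> ConnectomeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectomeMatrix(df.values, region_ids=[str(r) for r in df.index])


def write_region_table(region_ids, volumes, path, names=None) -> None:
    names = names or list(region_ids)
    pd.DataFrame(
        {"region_id": region_ids, "name": names, "volume_voxels": np.asarray(volumes)}
    ).to_csv(path, sep="\t", index=False)


def read_region_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "volume_voxels"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: region table needs columns {sorted(required)}")
    return df.set_index("region_id")


def write_study(study, out_dir) -> Path:
    """Write a synthetic study to a directory of TSVs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {"subjects": []}
    for s in range(study.config.n_subjects):
        bold_name = f"sub-{s:03d}_bold.tsv"
        conn_name = f"sub-{s:03d}_connectome.tsv"
        write_bold_tsv(study.subject_bold(s), out / bold_name)
        write_adjacency_tsv(study.subject_connectome(s), out / conn_name)
        files["subjects"].append({"bold": bold_name, "connectome": conn_name})
    write_region_table(study.region_ids, study.truth.volumes.astype(int), out / "regions.tsv")
    pd.DataFrame(
        study.global_signals,
        index=pd.Index([f"sub-{s:03d}" for s in range(study.config.n_subjects)], name="subject"),
        columns=[f"t{j}" for j in range(study.config.n_timepoints)],
    ).to_csv(out / "nuisance.tsv", sep="\t", float_format="%.6g")
    pd.DataFrame(
        {
            "region_id": study.region_ids,
            "tau_s": study.truth.tau,
            "phi": study.truth.phi,
            "volume_voxels": study.truth.volumes.astype(int),
        }
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    manifest = {
        "config": asdict(study.config),
        "seed": study.config.seed,
        "files": files,
        "format_version": 1,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def load_study(study_dir):
    """Load a study directory written by :func:`write_study`."""
    from .synthetic import GroundTruth, SyntheticStudy, SyntheticStudyConfig

    d = Path(study_dir)
    with open(d / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = SyntheticStudyConfig(**manifest["config"])
    bolds, conns = [], []
    for entry in manifest["files"]["subjects"]:
        bolds.append(read_bold_tsv(d / entry["bold"]).values)
        conns.append(read_adjacency_tsv(d / entry["connectome"]).weights)
    nuisance = pd.read_csv(d / "nuisance.tsv", sep="\t", index_col=0).values
    gt = pd.read_csv(d / "ground_truth.tsv", sep="\t")
    connectomes = np.stack(conns)
    truth = GroundTruth(
        tau=gt["tau_s"].values,
        phi=gt["phi"].values,
        strengths=connectomes.sum(axis=2),
        volumes=gt["volume_voxels"].values.astype(float),
    )
    return SyntheticStudy(
        config=config,
        truth=truth,
        connectomes=connectomes,
        bold=np.stack(bolds),
        global_signals=nuisance,
        region_ids=gt["region_id"].astype(str).tolist(),
    )
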