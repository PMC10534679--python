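"""File formats: PLY / XYZ point clouds, JSON transforms, detections,
dataset manifests, and YAML/JSON configuration.

PLY support covers the subset this pipeline uses — vertex properties
x, y, z and optionally nx, ny, nz (plus an integer ``label``) — in ASCII and
binary little-endian form; clouds are written as ASCII by default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .geometry import PointCloud, RigidTransform
from .keypoints import N_SLOTS, HandKeyPointSet

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_xyz",
    "write_xyz",
    "read_ply",
    "write_ply",
    "transform_to_json",
    "transform_from_json",
    "write_detections",
    "read_detections",
    "write_dataset",
    "load_dataset",
    "load_config",
]

_PLY_DTYPES = {
    "float": "<f4",
    "float32": "<f4",
    "double": "<f8",
    "float64": "<f8",
    "int": "<i4",
    "int32": "<i4",
    "uint": "<u4",
    "uchar": "u1",
    "uint8": "u1",
    "char": "i1",
    "short": "<i2",
    "ushort": "<u2",
}


def write_ply(path, cloud: PointCloud, binary: bool = False) -> None:
    path = Path(path)
    props = [("x", cloud.points[:, 0]), ("y", cloud.points[:, 1]), ("z", cloud.points[:, 2])]
    if cloud.normals is not None:
        props += [("nx", cloud.normals[:, 0]), ("ny", cloud.normals[:, 1]), ("nz", cloud.normals[:, 2])]
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property double {name}" for name, _ in props]
    if cloud.labels is not None:
        header.append("property int label")
    header.append("end_header")
    data = np.column_stack([v for _, v in props])
    if binary:
        fields = [(name, "<f8") for name, _ in props]
        if cloud.labels is not None:
            fields.append(("label", "<i4"))
        rec = np.zeros(len(cloud), dtype=fields)
        for name, v in props:
            rec[name] = v
        if cloud.labels is not None:
            rec["label"] = cloud.labels
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            rec.tofile(fh)
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for k in range(len(cloud)):
                row = " ".join(repr(float(x)) for x in data[k])
                if cloud.labels is not None:
                    row += f" {int(cloud.labels[k])}"
                fh.write(row + "\n")


def read_ply(path) -> PointCloud:
    with open(path, "rb") as fh:
        raw = fh.read()
    head_end = raw.find(b"end_header")
    if head_end < 0:
        raise ValueError("not a PLY file: missing end_header")
    head_end = raw.index(b"\n", head_end) + 1
    header = raw[:head_end].decode("ascii").splitlines()
    if header[0].strip() != "ply":
        raise ValueError("not a PLY file")
    fmt, n_vertex, names, dtypes = None, 0, [], []
    in_vertex = False
    for line in header[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise ValueError("list properties on vertices are not supported")
            names.append(tok[2])
            dtypes.append(_PLY_DTYPES[tok[1]])
    if fmt == "ascii":
        body = raw[head_end:].decode("ascii").split()
        table = np.array(body, dtype=float).reshape(n_vertex, len(names))
        cols = {name: table[:, k] for k, name in enumerate(names)}
    elif fmt == "binary_little_endian":
        rec = np.frombuffer(raw, dtype=list(zip(names, dtypes)), count=n_vertex, offset=head_end)
        cols = {name: rec[name].astype(float) for name in names}
    else:
        raise ValueError(f"unsupported PLY format: {fmt}")
    pts = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(k in cols for k in ("nx", "ny", "nz")):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        normals = normals / np.where(norms > 0, norms, 1.0)
    labels = cols["label"].astype(int) if "label" in cols else None
    return PointCloud(pts, normals, labels)


def write_xyz(path, cloud: PointCloud) -> None:
    cols = [cloud.points]
    if cloud.normals is not None:
        cols.append(cloud.normals)
    np.savetxt(path, np.column_stack(cols), fmt="%.8g")


def read_xyz(path) -> PointCloud:
    table = np.atleast_2d(np.loadtxt(path))
    if table.shape[1] < 3:
        raise ValueError("XYZ file must have at least 3 columns")
    normals = None
    if table.shape[1] >= 6:
        normals = table[:, 3:6]
        normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(table[:, :3], normals)


def read_point_cloud(path) -> PointCloud:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return read_ply(path)
    return read_xyz(path)


def write_point_cloud(path, cloud: PointCloud) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        write_ply(path, cloud)
    else:
        write_xyz(path, cloud)


def transform_to_json(transform: RigidTransform, frame_from: str = "", frame_to: str = "") -> dict:
    return {
        "matrix": transform.matrix.tolist(),
        "frame_from": frame_from,
        "frame_to": frame_to,
    }


def transform_from_json(obj: dict) -> RigidTransform:
    return RigidTransform.from_matrix(np.asarray(obj["matrix"]))


def _kp_to_list(kp: HandKeyPointSet | None):
    if kp is None:
        return None
    return [None if not kp.valid_mask[s] else [float(v) for v in kp.coords[s]] for s in range(N_SLOTS)]


def write_detections(path, detections) -> None:
    """Per-pose detections file: one record per sensor with score and 21 slots."""
    records = [
        {"sensor": kp.sensor_id, "score": kp.score, "keypoints": _kp_to_list(kp)}
        for kp in detections
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_detections(path) -> list:
    out = []
    for rec in json.loads(Path(path).read_text()):
        coords = np.full((N_SLOTS, 3), np.nan)
        width = 3
        for s, val in enumerate(rec["keypoints"]):
            if val is not None:
                width = len(val)
                coords[s, : len(val)] = val
        coords = coords[:, :width]
        out.append(HandKeyPointSet(coords, score=rec["score"], sensor_id=rec["sensor"]))
    return out


def write_dataset(out_dir, triplets, include_truth: bool = True) -> Path:
    """Write triplets as PLY files plus a JSON sidecar per pose and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    poses = []
    for t in triplets:
        entry = {"pose_id": t.pose_id, "clouds": [], "detections": f"pose_{t.pose_id:03d}.json"}
        for s, cloud in enumerate(t.clouds):
            name = f"pose_{t.pose_id:03d}_sensor{s}.ply"
            write_ply(out_dir / name, cloud)
            entry["clouds"].append(name)
        sidecar = {
            "pose_id": t.pose_id,
            "detections": [
                {"sensor": kp.sensor_id, "score": kp.score, "keypoints": _kp_to_list(kp)}
                for kp in t.detections
            ],
        }
        if include_truth and t.truth_transform is not None:
            sidecar["truth_transform"] = transform_to_json(
                t.truth_transform, f"pose_{t.pose_id}", "world"
            )
        (out_dir / entry["detections"]).write_text(json.dumps(sidecar, indent=1))
        poses.append(entry)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"poses": poses}, indent=1))
    return manifest


def load_dataset(manifest_path) -> list:
    """Load a dataset written by :func:`write_dataset` into Triplet objects."""
    from .simulate import Triplet

    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    triplets = []
    for entry in manifest["poses"]:
        clouds = [read_ply(root / name) for name in entry["clouds"]]
        sidecar = json.loads((root / entry["detections"]).read_text())
        detections = []
        for rec in sidecar["detections"]:
            coords = np.full((N_SLOTS, 3), np.nan)
            for s, val in enumerate(rec["keypoints"]):
                if val is not None:
                    coords[s] = val
            detections.append(HandKeyPointSet(coords, score=rec["score"], sensor_id=rec["sensor"]))
        truth = None
        if "truth_transform" in sidecar:
            truth = transform_from_json(sidecar["truth_transform"])
        triplets.append(Triplet(clouds, detections, sidecar["pose_id"], truth))
    return triplets


def load_config(path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
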