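"""Weighted point clouds from triangulated vascular surfaces.

A closed surface is represented as a weighted point cloud: one point per
triangle at its centroid, weighted by the normalized cell area, with the
per-cell outward unit normal attached.  The module also provides the
shared unit-cube normalization, rigid coherent-point-drift pre-alignment,
thin-plate-spline warping, and lossless cloud I/O (PLY with a custom
per-vertex ``weight`` property, ascii VTP, native ``.npz``).
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "SurfaceMesh",
    "WeightedPointCloud",
    "UnitCubeTransform",
    "RigidTransform",
    "DegenerateGeometryError",
    "mesh_to_weighted_cloud",
    "fit_unit_cube",
    "cpd_rigid",
    "tps_warp",
    "estimate_normals",
    "read_cloud",
    "write_cloud",
]

WEIGHT_SUM_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised for zero-area triangles or otherwise unusable geometry."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices in cm and consistently wound triangles."""

    vertices: np.ndarray  # (V, 3)
    triangles: np.ndarray  # (F, 3) int
    oriented: bool = True

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_count(self) -> int:
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        return len(np.unique(np.sort(e, axis=1), axis=0))

    def is_closed(self) -> bool:
        """Every edge shared by exactly two triangles."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        _, counts = np.unique(np.sort(e, axis=1), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def euler_characteristic(self) -> int:
        return len(self.vertices) - self.edge_count() + self.n_triangles


@dataclass
class WeightedPointCloud:
    """Points with positive weights summing to one and optional unit normals."""

    points: np.ndarray  # (M, 3)
    weights: np.ndarray  # (M,)
    normals: np.ndarray | None = None  # (M, 3)
    label: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (M, 3)")
        if self.weights.shape != (len(self.points),):
            raise ValueError("weights must align with points")
        if np.any(self.weights <= 0):
            raise ValueError("all weights must be positive")
        if abs(self.weights.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError("weights must sum to 1 within 1e-12")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            norms = np.linalg.norm(self.normals, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("normals must be unit vectors within 1e-9")

    def __len__(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray, label: str | None = None) -> "WeightedPointCloud":
        """Same weights/normals on new coordinates (e.g. after a mapping)."""
        return WeightedPointCloud(
            points=np.asarray(points, dtype=np.float64),
            weights=self.weights.copy(),
            normals=None if self.normals is None else self.normals.copy(),
            label=self.label if label is None else label,
        )

    def subsample(self, idx: np.ndarray) -> "WeightedPointCloud":
        w = self.weights[idx]
        return WeightedPointCloud(
            points=self.points[idx],
            weights=w / w.sum(),
            normals=None if self.normals is None else self.normals[idx],
            label=self.label,
        )


@dataclass
class UnitCubeTransform:
    """Shared anisotropic affine map x -> scale * x + translation into [0,1]^3."""

    scale: np.ndarray  # (3,) positive
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.scale = np.asarray(self.scale, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) * self.scale + self.translation

    def invert(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.translation) / self.scale

    def apply_cloud(self, cloud: WeightedPointCloud) -> WeightedPointCloud:
        return cloud.with_points(self.apply(cloud.points))

    def invert_cloud(self, cloud: WeightedPointCloud) -> WeightedPointCloud:
        return cloud.with_points(self.invert(cloud.points))

    def lengths_to_physical(self, d: np.ndarray, axis_isotropic: bool = True) -> np.ndarray:
        """Map unit-cube distances back to cm; exact only for isotropic scale."""
        return np.asarray(d) / np.mean(self.scale)


@dataclass
class RigidTransform:
    """Similarity transform x -> s * R x + t with det(R) = +1."""

    rotation: np.ndarray  # (3, 3)
    scale: float = 1.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if np.max(np.abs(self.rotation.T @ self.rotation - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be orthonormal within 1e-9")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must have det +1 within 1e-9")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points) @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# construction


def _triangle_geometry(mesh: SurfaceMesh):
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    cross = np.cross(b - a, c - a)
    double_area = np.linalg.norm(cross, axis=1)
    return (a + b + c) / 3.0, double_area / 2.0, cross, double_area


def mesh_to_weighted_cloud(mesh: SurfaceMesh, label: str = "") -> WeightedPointCloud:
    """Cell centroids weighted by normalized cell areas, with cell normals."""
    if mesh.n_triangles < 1:
        raise DegenerateGeometryError("mesh has no triangles")
    centroids, areas, cross, double_area = _triangle_geometry(mesh)
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise DegenerateGeometryError(f"zero-area triangle at index {bad[0]}")
    normals = cross / double_area[:, None]
    return WeightedPointCloud(
        points=centroids, weights=areas / areas.sum(), normals=normals, label=label
    )


def fit_unit_cube(
    clouds: list[WeightedPointCloud], margin: float = 0.05
) -> UnitCubeTransform:
    """Per-axis affine map sending the union of all points into [m, 1-m]^3.

    Fitted once over the whole cohort (template + sources) so every shape
    lives in a common coordinate frame.
    """
    if not clouds:
        raise ValueError("need at least one cloud")
    pts = np.concatenate([c.points for c in clouds], axis=0)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    extent = hi - lo
    scale = np.empty(3)
    translation = np.empty(3)
    for ax in range(3):
        if extent[ax] <= 0:
            warnings.warn(f"degenerate extent on axis {ax}; centring only")
            scale[ax] = 1.0
            translation[ax] = 0.5 - lo[ax]
        else:
            scale[ax] = (1.0 - 2.0 * margin) / extent[ax]
            translation[ax] = margin - lo[ax] * scale[ax]
    return UnitCubeTransform(scale=scale, translation=translation)


# ---------------------------------------------------------------------------
# rigid coherent point drift


def cpd_rigid(
    source: WeightedPointCloud,
    target: WeightedPointCloud,
    max_iter: int = 100,
    tol: float = 1e-8,
    outlier_weight: float = 0.1,
) -> tuple[RigidTransform, WeightedPointCloud, bool]:
    """Rigid (rotation + isotropic scale + translation) CPD EM alignment.

    The source points are centroids of a GMM fitted to the target under a
    uniform outlier component; the M-step has the standard closed form.
    Returns (transform, transformed source, converged flag).
    """
    X = np.asarray(target.points, dtype=np.float64)  # data
    Y = np.asarray(source.points, dtype=np.float64)  # centroids
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("clouds must be nonempty")
    N, M, D = len(X), len(Y), 3
    R, s, t = np.eye(D), 1.0, np.zeros(D)
    TY = Y.copy()
    sigma2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum() / (D * M * N)
    w = float(outlier_weight)
    prev_ll = None
    converged = False
    for _ in range(max_iter):
        # E-step: posteriors with uniform outlier channel
        d2 = ((X[:, None, :] - TY[None, :, :]) ** 2).sum(axis=2)  # (N, M)
        log_num = -d2 / (2 * sigma2)
        c = (
            np.log(w / (1 - w) + 1e-300)
            + (D / 2) * np.log(2 * np.pi * sigma2)
            + np.log(M / (N * _volume_guess(X)))
        )
        log_den = logsumexp(np.column_stack([log_num, np.full(N, c)]), axis=1)
        P = np.exp(log_num - log_den[:, None])  # (N, M)
        ll = float(log_den.sum())
        Np = P.sum()
        if Np < 1e-12:
            break
        # M-step (closed-form similarity transform)
        mu_x = (P.sum(axis=1) @ X) / Np
        mu_y = (P.sum(axis=0) @ Y) / Np
        Xh, Yh = X - mu_x, Y - mu_y
        A = Xh.T @ (P @ Yh)
        U, S, Vt = np.linalg.svd(A)
        Cc = np.eye(D)
        Cc[-1, -1] = np.linalg.det(U @ Vt)
        R = U @ Cc @ Vt
        denom = (P.sum(axis=0) * (Yh**2).sum(axis=1)).sum()
        s = np.trace(np.diag(S) @ Cc) / denom
        t = mu_x - s * R @ mu_y
        TY = s * Y @ R.T + t
        sigma2 = max(
            ((P.sum(axis=1) * (Xh**2).sum(axis=1)).sum() - s * np.trace(np.diag(S) @ Cc))
            / (Np * D),
            1e-12,
        )
        if prev_ll is not None and abs(ll - prev_ll) < tol * (1 + abs(ll)):
            converged = True
            break
        prev_ll = ll
    transform = RigidTransform(rotation=R, scale=float(s), translation=t)
    return transform, source.with_points(TY), converged


def _volume_guess(X: np.ndarray) -> float:
    extent = X.max(axis=0) - X.min(axis=0)
    return float(np.prod(np.maximum(extent, 1e-6)))


# ---------------------------------------------------------------------------
# thin-plate-spline warp


def tps_warp(
    control_src: np.ndarray,
    control_dst: np.ndarray,
    query: np.ndarray,
    stiffness: float = 0.0,
) -> np.ndarray:
    """3-D thin-plate-spline warp with biharmonic kernel U(r) = r.

    Exact interpolation of control displacements at stiffness 0; affine
    maps are reproduced exactly.  Requires >= 4 non-coplanar controls.
    """
    P = np.asarray(control_src, dtype=np.float64)
    Q = np.asarray(control_dst, dtype=np.float64)
    X = np.asarray(query, dtype=np.float64)
    n = len(P)
    if n < 4:
        raise ValueError("need at least 4 control points")
    K = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
    K += stiffness * np.eye(n)
    A = np.column_stack([np.ones(n), P])  # (n, 4)
    sys = np.zeros((n + 4, n + 4))
    sys[:n, :n] = K
    sys[:n, n:] = A
    sys[n:, :n] = A.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = Q
    try:
        sol = np.linalg.solve(sys, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system (coplanar or duplicate controls)") from exc
    cond = np.linalg.cond(sys)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular TPS system (coplanar or duplicate controls)")
    Wk, affine = sol[:n], sol[n:]
    Uq = np.linalg.norm(X[:, None, :] - P[None, :, :], axis=2)
    return Uq @ Wk + np.column_stack([np.ones(len(X)), X]) @ affine


# ---------------------------------------------------------------------------
# normals for bare clouds


def estimate_normals(points: np.ndarray, k: int = 12, viewpoint: np.ndarray | None = None):
    """Local-PCA normals oriented outward from an interior viewpoint.

    Used only for clouds loaded without a mesh; meshed clouds carry exact
    per-cell normals.
    """
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=np.float64)
    tree = cKDTree(pts)
    _, nn = tree.query(pts, k=min(k, len(pts)))
    normals = np.empty_like(pts)
    for i, idx in enumerate(nn):
        local = pts[idx] - pts[idx].mean(axis=0)
        _, _, Vt = np.linalg.svd(local, full_matrices=False)
        normals[i] = Vt[-1]
    vp = pts.mean(axis=0) if viewpoint is None else np.asarray(viewpoint)
    flip = np.einsum("ij,ij->i", normals, pts - vp) < 0
    normals[flip] *= -1
    return normals / np.linalg.norm(normals, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# I/O


def write_cloud(cloud: WeightedPointCloud, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "npz":
        arrays = {"points": cloud.points, "weights": cloud.weights, "label": cloud.label}
        if cloud.normals is not None:
            arrays["normals"] = cloud.normals
        np.savez_compressed(path, **arrays)
    elif fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "vtp":
        _write_vtp(cloud, path)
    else:
        raise ValueError(f"unknown cloud format: {fmt!r}")


def read_cloud(path, format: str | None = None) -> WeightedPointCloud:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as data:
            return WeightedPointCloud(
                points=data["points"],
                weights=data["weights"],
                normals=data["normals"] if "normals" in data else None,
                label=str(data["label"]) if "label" in data else "",
            )
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "vtp":
        return _read_vtp(path)
    raise ValueError(f"unknown cloud format: {fmt!r}")


def _write_ply(cloud: WeightedPointCloud, path: Path) -> None:
    has_n = cloud.normals is not None
    lines = ["ply", "format ascii 1.0", f"comment label {cloud.label}"]
    lines.append(f"element vertex {len(cloud)}")
    lines += ["property double x", "property double y", "property double z"]
    if has_n:
        lines += ["property double nx", "property double ny", "property double nz"]
    lines.append("property double weight")
    lines.append("end_header")
    rows = []
    for i in range(len(cloud)):
        vals = list(cloud.points[i])
        if has_n:
            vals += list(cloud.normals[i])
        vals.append(cloud.weights[i])
        rows.append(" ".join(f"{v:.17g}" for v in vals))
    path.write_text("\n".join(lines + rows) + "\n")


def _read_ply(path: Path) -> WeightedPointCloud:
    raw = Path(path).read_bytes()
    try:
        header_end = raw.index(b"end_header\n") + len(b"end_header\n")
    except ValueError as exc:
        raise ValueError(f"malformed PLY (no end_header): {path}") from exc
    header = raw[:header_end].decode("ascii", errors="replace").splitlines()
    if not header or header[0].strip() != "ply":
        raise ValueError(f"malformed PLY (missing 'ply' magic): {path}")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    label = ""
    in_vertex = False
    for line in header[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "comment" and len(tok) >= 2 and tok[1] == "label":
            label = " ".join(tok[2:])
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            if tok[1] == "list":
                raise ValueError(f"malformed PLY (list property on vertex): {path}")
            props.append((tok[2], tok[1]))
    if n_vertex is None:
        raise ValueError(f"malformed PLY (no vertex element): {path}")
    names = [p[0] for p in props]
    _np_types = {
        "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
        "uchar": "u1", "uint8": "u1", "int": "<i4", "int32": "<i4",
    }
    if fmt == "ascii":
        body = raw[header_end:].decode("ascii").split()
        vals = np.array(body, dtype=np.float64)
        if vals.size != n_vertex * len(props):
            raise ValueError(f"malformed PLY (vertex data size mismatch): {path}")
        table = vals.reshape(n_vertex, len(props))
        cols = {name: table[:, i] for i, (name, _) in enumerate(props)}
    elif fmt == "binary_little_endian":
        dtype = np.dtype([(name, _np_types[t]) for name, t in props])
        rec = np.frombuffer(raw[header_end:header_end + dtype.itemsize * n_vertex], dtype=dtype)
        cols = {name: rec[name].astype(np.float64) for name, _ in props}
    else:
        raise ValueError(f"unsupported PLY format {fmt!r}: {path}")
    for ax in "xyz":
        if ax not in cols:
            raise ValueError(f"malformed PLY (missing vertex property {ax!r}): {path}")
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(f"n{ax}" in names for ax in "xyz"):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
    if "weight" in names:
        weights = cols["weight"]
    else:
        warnings.warn(f"PLY without weight property; using uniform weights: {path}")
        weights = np.full(n_vertex, 1.0 / n_vertex)
    return WeightedPointCloud(points=points, weights=weights, normals=normals, label=label)


def _write_vtp(cloud: WeightedPointCloud, path: Path) -> None:
    def arr(name, data, comps):
        el = ET.Element(
            "DataArray",
            type="Float64",
            Name=name,
            NumberOfComponents=str(comps),
            format="ascii",
        )
        el.text = " ".join(f"{v:.17g}" for v in np.asarray(data).ravel())
        return el

    root = ET.Element("VTKFile", type="PolyData", version="0.1", byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        poly, "Piece", NumberOfPoints=str(len(cloud)), NumberOfVerts=str(len(cloud)),
        NumberOfLines="0", NumberOfStrips="0", NumberOfPolys="0",
    )
    pts = ET.SubElement(piece, "Points")
    pts.append(arr("Points", cloud.points, 3))
    pdata = ET.SubElement(piece, "PointData")
    pdata.append(arr("weight", cloud.weights, 1))
    if cloud.normals is not None:
        pdata.append(arr("Normals", cloud.normals, 3))
    verts = ET.SubElement(piece, "Verts")
    conn = ET.Element("DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = " ".join(str(i) for i in range(len(cloud)))
    offs = ET.Element("DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = " ".join(str(i + 1) for i in range(len(cloud)))
    verts.append(conn)
    verts.append(offs)
    if cloud.label:
        root.set("label", cloud.label)
    ET.ElementTree(root).write(path, xml_declaration=True)


def _read_vtp(path: Path) -> WeightedPointCloud:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VTP (XML parse error): {path}") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise ValueError(f"malformed VTP (no Piece element): {path}")
    pts_el = piece.find("./Points/DataArray")
    if pts_el is None or pts_el.text is None:
        raise ValueError(f"malformed VTP (no Points array): {path}")
    points = np.fromstring(pts_el.text, sep=" ").reshape(-1, 3)
    weights = None
    normals = None
    for el in piece.findall("./PointData/DataArray"):
        if el.get("Name") == "weight":
            weights = np.fromstring(el.text, sep=" ")
        elif el.get("Name") == "Normals":
            normals = np.fromstring(el.text, sep=" ").reshape(-1, 3)
    if weights is None:
        warnings.warn(f"VTP without weight array; using uniform weights: {path}")
        weights = np.full(len(points), 1.0 / len(points))
    return WeightedPointCloud(
        points=points, weights=weights, normals=normals, label=root.get("label", "")
    )
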