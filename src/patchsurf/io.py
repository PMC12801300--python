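"""Atom-file readers (xyzr, pqr), mesh writers (OFF, PLY) and the keyword
configuration dialect.

All coordinates and radii are in Angstrom throughout; no unit conversion is
performed anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger("patchsurf")

__all__ = [
    "AtomSet",
    "SurfaceConfig",
    "ParseError",
    "ConfigError",
    "read_xyzr",
    "read_pqr",
    "read_config",
    "write_mesh",
]


class ParseError(ValueError):
    """Malformed atom record."""


class ConfigError(ValueError):
    """Malformed configuration keyword or value."""


@dataclass(frozen=True)
class AtomSet:
    """Solute atoms: centers (n, 3) and positive radii (n,), Angstrom."""

    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        r = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if c.shape != (r.size, 3):
            raise ValueError(f"centers shape {c.shape} does not match {r.size} radii")
        if r.size < 1:
            raise ValueError("an AtomSet needs at least one atom")
        if not np.all(np.isfinite(c)) or not np.all(np.isfinite(r)):
            raise ValueError("atom coordinates and radii must be finite")
        if np.any(r <= 0.0):
            raise ValueError("all atom radii must be positive")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "radii", r)

    @property
    def count(self) -> int:
        return self.radii.size

    def subset(self, ids: np.ndarray) -> "AtomSet":
        ids = np.asarray(ids, dtype=int)
        return AtomSet(self.centers[ids], self.radii[ids])


@dataclass(frozen=True)
class SurfaceConfig:
    """Pipeline parameters.

    probe_radius        solvent probe, Angstrom (water ~ 1.4)
    grid_scale          s, grid points per Angstrom; spacing h = 1/s
    halo_thickness      slab halo band, Angstrom (conservative default 12)
    slab_count          requested Y-slab decomposition of the SES buildup
    skip_strategy       near entry/exit pair removal: one_point or two_point
    skip_eps            pair-gap threshold, Angstrom
    big_probe_radius    pocket-detection probe, Angstrom
    smoothing_iterations  Laplacian smoothing passes on the final mesh
    """

    probe_radius: float = 1.4
    grid_scale: float = 2.0
    halo_thickness: float = 12.0
    slab_count: int = 1
    skip_strategy: str = "two_point"
    skip_eps: float = 1e-7
    big_probe_radius: float = 3.0
    smoothing_iterations: int = 1

    def __post_init__(self) -> None:
        if self.probe_radius < 0.0:
            raise ValueError("probe_radius must be >= 0")
        if self.grid_scale <= 0.0:
            raise ValueError("grid_scale must be > 0")
        if self.halo_thickness < 2.0 * self.probe_radius:
            raise ValueError("halo_thickness must be >= 2 * probe_radius")
        if self.skip_eps <= 0.0:
            raise ValueError("skip_eps must be > 0")
        if self.skip_strategy not in ("one_point", "two_point"):
            raise ValueError(f"unknown skip_strategy {self.skip_strategy!r}")
        if self.slab_count < 1:
            raise ValueError("slab_count must be >= 1")
        if self.smoothing_iterations < 0:
            raise ValueError("smoothing_iterations must be >= 0")

    @property
    def spacing(self) -> float:
        return 1.0 / self.grid_scale

    def with_(self, **kw) -> "SurfaceConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# atom files


def read_xyzr(path: str | Path) -> AtomSet:
    """Read the plain ``x y z r`` one-record-per-line format."""
    centers, radii = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 fields, got {len(fields)}")
            try:
                x, y, z, r = (float(v) for v in fields)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric field: {exc}") from exc
            if r <= 0.0:
                raise ParseError(f"{path}: line {lineno}: non-positive radius {r}")
            centers.append((x, y, z))
            radii.append(r)
    if not centers:
        raise ParseError(f"{path}: no atom records found")
    return AtomSet(np.array(centers), np.array(radii))


def write_xyzr(atoms: AtomSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (x, y, z), r in zip(atoms.centers, atoms.radii):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {r:.6f}\n")


def read_pqr(path: str | Path) -> AtomSet:
    """Read PQR: ATOM/HETATM records, whitespace-tokenized, with
    ``x y z charge radius`` as the last five fields.  Charge is discarded.

    Whitespace tokenization (rather than fixed columns) matches common
    PDB2PQR output and is the robust choice for generated files.
    """
    centers, radii = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.startswith(("ATOM", "HETATM")):
                continue
            fields = raw.split()
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: too few fields for a PQR record")
            try:
                x, y, z, _charge, r = (float(v) for v in fields[-5:])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric field: {exc}") from exc
            if r <= 0.0:
                raise ParseError(f"{path}: line {lineno}: non-positive radius {r}")
            centers.append((x, y, z))
            radii.append(r)
    if not centers:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return AtomSet(np.array(centers), np.array(radii))


# ---------------------------------------------------------------------------
# configuration dialect

_CONFIG_TYPES = {
    "probe_radius": float,
    "grid_scale": float,
    "halo_thickness": float,
    "slab_count": int,
    "skip_strategy": str,
    "skip_eps": float,
    "big_probe_radius": float,
    "smoothing_iterations": int,
}


def read_config(path: str | Path) -> SurfaceConfig:
    """Parse ``keyword = value`` lines; ``#`` starts a comment.  Unknown
    keywords are logged and ignored; missing keywords take the
    :class:`SurfaceConfig` defaults.  Parsing is order-independent."""
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}: line {lineno}: expected 'keyword = value'")
            key, _, val = (s.strip() for s in line.partition("="))
            typ = _CONFIG_TYPES.get(key)
            if typ is None:
                log.warning("config %s line %d: unknown keyword %r ignored", path, lineno, key)
                continue
            try:
                values[key] = typ(val)
            except ValueError as exc:
                raise ConfigError(f"{path}: bad value for keyword {key!r}: {val!r}") from exc
    try:
        return SurfaceConfig(**values)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# mesh writers


def write_mesh(mesh, path: str | Path, format: str | None = None) -> None:
    """Write a triangle mesh as ASCII OFF or PLY (0-based vertex indices).

    ``format`` defaults from the file suffix.  Writing an empty mesh is
    refused: an empty surface is always an upstream error.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper() or "OFF"
    format = format.upper()
    if format not in ("OFF", "PLY"):
        raise ValueError(f"unsupported mesh format {format!r}")
    nv = len(mesh.vertices)
    nt = len(mesh.triangles)
    if nv == 0 or nt == 0:
        raise ValueError("refusing to write an empty mesh")
    with open(path, "w") as fh:
        if format == "OFF":
            fh.write(f"OFF\n{nv} {nt} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        else:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {nv}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("property float nx\nproperty float ny\nproperty float nz\n")
            fh.write(f"element face {nt}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            normals = mesh.normals if mesh.normals is not None else np.zeros((nv, 3))
            for v, n in zip(mesh.vertices, normals):
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
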