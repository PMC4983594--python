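"""Landmark and metadata I/O for 2D outline morphometrics.

Reads and writes TPS landmark files (the format used by the tpsDig/tpsUtil
family of digitizing tools), resamples digitized outline polylines to
equidistant semilandmarks, normalizes side orientation by reflection, and
joins landmark records onto a specimen classifier table.

Coordinate convention: y increases upward (TPS convention). The reader never
flips the image origin; any flip is the exporter's job.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OutlinePolyline",
    "LandmarkConfiguration",
    "SpecimenRecord",
    "TpsParseError",
    "read_tps",
    "write_tps",
    "resample_equidistant",
    "reflect",
    "read_specimen_table",
    "join_records",
]

HABITAT_CODES = frozenset({"f", "b", "m"})  # fresh, brackish, marine


class TpsParseError(ValueError):
    """Raised when a TPS file violates the LM=/coordinate-line structure."""


@dataclass(frozen=True)
class OutlinePolyline:
    """A digitized outline curve: ordered 2D points, optionally closed.

    Zero-length segments (consecutive duplicate points) are removed at
    construction; for a closed outline the implicit last->first segment is
    part of the perimeter.
    """

    points: np.ndarray
    closed: bool = True
    scale: float = 1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("outline coordinates must be finite")
        # drop consecutive duplicates (and the closing duplicate if closed)
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        pts = pts[keep]
        if self.closed and len(pts) > 1 and np.all(pts[0] == pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("outline needs at least 3 distinct points")
        object.__setattr__(self, "points", pts)

    @property
    def perimeter(self) -> float:
        segs = np.diff(self.points, axis=0)
        total = float(np.sum(np.hypot(segs[:, 0], segs[:, 1])))
        if self.closed:
            total += float(np.hypot(*(self.points[0] - self.points[-1])))
        return total


def _check_noncollinear(coords: np.ndarray) -> bool:
    c = coords - coords.mean(axis=0)
    return np.linalg.matrix_rank(c, tol=1e-12 * max(1.0, np.abs(c).max())) >= 2


@dataclass(frozen=True)
class LandmarkConfiguration:
    """k ordered 2D landmarks with one designated fixed (Type 2) landmark.

    The fixed landmark anchors the outline (a curvature maximum on the
    ventral anterior edge of the opercle); all other points are sliding
    semilandmarks. ``closed`` records whether the landmarks trace a closed
    outline (neighbors wrap around).
    """

    coords: np.ndarray
    fixed_index: int = 0
    side: str = "left"
    closed: bool = True

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if coords.shape[0] < 3:
            raise ValueError("a landmark configuration needs k >= 3 points")
        if not np.all(np.isfinite(coords)):
            raise ValueError("landmark coordinates must be finite")
        if not _check_noncollinear(coords):
            raise ValueError("landmarks are collinear (thin-plate spline undefined)")
        if not (0 <= self.fixed_index < coords.shape[0]):
            raise ValueError("fixed_index out of range")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return int(self.coords.shape[0])

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass(frozen=True)
class SpecimenRecord:
    """Classifier-table row: who a specimen is and where it was caught."""

    specimen_id: str
    species: str
    genus: str
    habitat: str
    locality: str
    sides_present: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.habitat not in HABITAT_CODES:
            raise ValueError(
                f"habitat {self.habitat!r} not one of {sorted(HABITAT_CODES)}"
            )
        if not self.sides_present:
            raise ValueError("sides_present must be non-empty")


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------

def read_tps(path) -> list[tuple[LandmarkConfiguration, dict]]:
    """Parse a TPS file into landmark configurations plus metadata maps.

    Each record starts with ``LM=<k>`` followed by k "x y" coordinate lines;
    optional ``ID=``, ``IMAGE=`` and ``SCALE=`` lines follow. Coordinates are
    multiplied by SCALE when present. Record order is preserved and ID/IMAGE
    are carried verbatim in the metadata map.
    """
    records: list[tuple[LandmarkConfiguration, dict]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    i = 0
    rec_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(
                f"line {i + 1}: expected LM= to start record {rec_no + 1}, got {line!r}"
            )
        rec_no += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(f"line {i + 1}: bad LM count {line!r}") from exc
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= len(lines) or lines[i].strip().upper().startswith(
                ("LM=", "ID=", "IMAGE=", "SCALE=")
            ):
                raise TpsParseError(
                    f"record {rec_no}: LM={k} but only {j} coordinate lines found"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"line {i + 1}: expected 'x y' coordinate pair, got {lines[i]!r}"
                )
            try:
                coords[j] = [float(parts[0]), float(parts[1])]
            except ValueError as exc:
                raise TpsParseError(
                    f"line {i + 1}: non-numeric coordinate {lines[i]!r}"
                ) from exc
            i += 1
        meta: dict = {}
        scale = 1.0
        while i < len(lines):
            s = lines[i].strip()
            if not s:
                i += 1
                continue
            if s.upper().startswith("LM="):
                break
            key, _, value = s.partition("=")
            key_u = key.strip().upper()
            if key_u == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise TpsParseError(f"line {i + 1}: bad SCALE {value!r}") from exc
            elif key_u in ("ID", "IMAGE"):
                meta[key_u] = value
            else:
                meta[key_u] = value
            i += 1
        coords *= scale
        records.append((LandmarkConfiguration(coords), meta))
    return records


def write_tps(configs, path) -> None:
    """Write configurations (with optional metadata) as a TPS file.

    ``configs`` is an iterable of ``LandmarkConfiguration`` or
    ``(LandmarkConfiguration, metadata_map)`` pairs. Coordinates are emitted
    at fixed 6-decimal precision; ID= and IMAGE= lines follow when present.
    """
    out_lines: list[str] = []
    for entry in configs:
        if isinstance(entry, LandmarkConfiguration):
            config, meta = entry, {}
        else:
            config, meta = entry
        if not np.all(np.isfinite(config.coords)):
            raise ValueError("refusing to write non-finite coordinates")
        out_lines.append(f"LM={config.k}")
        for x, y in config.coords:
            out_lines.append(f"{x:.6f} {y:.6f}")
        for key in ("IMAGE", "ID"):
            if key in meta:
                out_lines.append(f"{key}={meta[key]}")
    with open(path, "w", encoding="utf-8") as fh:
        if out_lines:
            fh.write("\n".join(out_lines) + "\n")


# ---------------------------------------------------------------------------
# Outline resampling
# ---------------------------------------------------------------------------

def resample_equidistant(
    outline: OutlinePolyline,
    k: int,
    start_point,
    direction: str = "ccw",
    density_warn_ratio: float = 1.0,
) -> LandmarkConfiguration:
    """Place k landmarks equally spaced by arc length along a closed outline.

    The start point is snapped to the nearest point on the curve and becomes
    landmark 0, the fixed landmark; the remaining k-1 points are sliding
    semilandmarks spaced perimeter/k apart in the requested traversal
    direction (the start point is both start and end of capture).
    """
    if not outline.closed:
        raise ValueError("resampling requires a closed outline")
    if k < 4:
        raise ValueError("k must be >= 4")
    if k > density_warn_ratio * len(outline.points):
        warnings.warn(
            f"requested k={k} exceeds input density ({len(outline.points)} points); "
            "landmark spacing may be inaccurate",
            stacklevel=2,
        )

    pts = outline.points
    if direction not in ("cw", "ccw"):
        raise ValueError("direction must be 'cw' or 'ccw'")
    # signed area: positive means the stored order is counter-clockwise
    x, y = pts[:, 0], pts[:, 1]
    area2 = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    stored_ccw = area2 > 0
    want_ccw = direction == "ccw"
    if stored_ccw != want_ccw:
        pts = pts[::-1]

    # snap start point to the nearest point ON the curve (segment projection)
    start = np.asarray(start_point, dtype=float)
    a = pts
    b = np.roll(pts, -1, axis=0)
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(
        np.einsum("ij,ij->i", start - a, ab) / np.where(seg_len2 > 0, seg_len2, 1.0),
        0.0,
        1.0,
    )
    proj = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", proj - start, proj - start)
    seg0 = int(np.argmin(d2))
    snapped = proj[seg0]

    # rebuild the closed polyline starting at the snapped point
    ring = np.vstack([[snapped], pts[seg0 + 1:], pts[: seg0 + 1]])
    keep = np.ones(len(ring), dtype=bool)
    keep[1:] = np.any(ring[1:] != ring[:-1], axis=1)
    ring = ring[keep]
    if np.all(ring[0] == ring[-1]):
        ring = ring[:-1]

    closed_ring = np.vstack([ring, ring[:1]])
    seg = np.diff(closed_ring, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    perimeter = cum[-1]
    targets = np.arange(k) * perimeter / k
    xs = np.interp(targets, cum, closed_ring[:, 0])
    ys = np.interp(targets, cum, closed_ring[:, 1])
    return LandmarkConfiguration(np.column_stack([xs, ys]), fixed_index=0)


# ---------------------------------------------------------------------------
# Side normalization
# ---------------------------------------------------------------------------

def reflect(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Mirror a configuration about the vertical axis through its centroid.

    After mirroring, the point order is reversed (keeping the fixed landmark
    at its position) so the traversal direction matches the left-side
    digitizing convention, and the side flag is flipped. Involution:
    reflect(reflect(c)) == c.
    """
    coords = config.coords.copy()
    cx = coords[:, 0].mean()
    coords[:, 0] = 2.0 * cx - coords[:, 0]
    # reverse traversal, keeping the fixed landmark first in the cycle
    idx = np.arange(config.k)
    rolled = np.roll(idx, -config.fixed_index)  # fixed landmark to front
    reversed_cycle = np.concatenate([rolled[:1], rolled[1:][::-1]])
    new_order = np.roll(reversed_cycle, config.fixed_index)
    coords = coords[new_order]
    return replace(
        config,
        coords=coords,
        side="right" if config.side == "left" else "left",
    )


# ---------------------------------------------------------------------------
# Classifier table
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ["specimen_id", "species", "genus", "side", "habitat", "locality"]


def read_specimen_table(path) -> list[SpecimenRecord]:
    """Read and validate the specimen classifier CSV.

    The file has one row per (specimen, side); rows are collapsed to one
    ``SpecimenRecord`` per specimen with ``sides_present`` accumulated.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"classifier table missing columns: {missing}")

    bad_rows = df.index[~df["habitat"].isin(HABITAT_CODES)].tolist()
    if bad_rows:
        raise ValueError(
            "invalid habitat code(s) in rows "
            + ", ".join(str(r + 2) for r in bad_rows)  # +2: header + 1-based
            + " (must be one of f, b, m)"
        )
    dup = df.duplicated(subset=["specimen_id", "side"])
    if dup.any():
        raise ValueError(
            f"duplicate (specimen_id, side) rows: {df.loc[dup, 'specimen_id'].tolist()}"
        )
    bad_side = df.index[~df["side"].isin(["left", "right"])].tolist()
    if bad_side:
        raise ValueError(
            "invalid side in rows " + ", ".join(str(r + 2) for r in bad_side)
        )

    records = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        first = grp.iloc[0]
        records.append(
            SpecimenRecord(
                specimen_id=str(sid),
                species=first["species"],
                genus=first["genus"],
                habitat=first["habitat"],
                locality=first["locality"],
                sides_present=frozenset(grp["side"]),
            )
        )
    return records


def join_records(tps_records, specimen_records):
    """Join TPS records onto the classifier by (specimen_id, side).

    TPS metadata IDs are expected to be ``<specimen_id>_<side>``. Returns
    ``(matched, tps_orphans, table_orphans)`` where ``matched`` is a list of
    (config, SpecimenRecord, side) triples; orphans are reported, not fatal.
    """
    by_id = {r.specimen_id: r for r in specimen_records}
    matched = []
    tps_orphans = []
    seen = set()
    for config, meta in tps_records:
        tps_id = meta.get("ID", "")
        sid, _, side = tps_id.rpartition("_")
        rec = by_id.get(sid)
        if rec is None or side not in rec.sides_present:
            tps_orphans.append(tps_id)
            continue
        matched.append((config, rec, side))
        seen.add((sid, side))
    table_orphans = [
        (r.specimen_id, side)
        for r in specimen_records
        for side in sorted(r.sides_present)
        if (r.specimen_id, side) not in seen
    ]
    return matched, tps_orphans, table_orphans
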