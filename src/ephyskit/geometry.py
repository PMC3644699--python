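"""Electrode-array geometries: definition, validation, and queries.

An :class:`ElectrodeArray` holds per-electrode positions in micrometres
(1D/2D/3D), human-facing 1-based electrode ids, and a bijective map from
electrode id to 0-based acquisition-channel index.  The geometry drives
channel bookkeeping and the grouping of electrodes into per-shank depth
columns for current-source-density estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ElectrodeArray",
    "GeometryError",
    "build_geometry",
    "load_geometry",
    "save_geometry",
]

#: planar coordinates are compared after rounding to this grid (µm);
#: positions originate in config files and may carry formatting noise
_PLANAR_TOL_UM = 0.1


class GeometryError(ValueError):
    """Invalid electrode-array definition or query."""


@dataclass(frozen=True)
class ElectrodeArray:
    """A validated electrode array.

    Parameters
    ----------
    name
        Human-readable array name.
    positions
        ``(n, 3)`` float array of (x, y, z) electrode positions in µm.
        Unused axes are fixed at 0.
    electrode_ids
        1-based integer labels, unique, one per electrode.
    pin_map
        Bijection electrode_id -> 0-based acquisition-channel index.
    shape_spec
        Optional ``(grid_dims, pitches_um)`` pair when the array was built
        from a regular grid description.
    depth_axis
        Index (0, 1, 2) of the axis treated as depth for CSD grouping.
    """

    name: str
    positions: np.ndarray
    electrode_ids: tuple[int, ...]
    pin_map: dict[int, int]
    shape_spec: tuple[tuple[int, int, int], tuple[float, float, float]] | None = None
    depth_axis: int = 2
    _inverse_pin_map: dict[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("positions must be an (n, 3) array")
        if not np.all(np.isfinite(pos)):
            raise GeometryError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        n = pos.shape[0]
        ids = tuple(int(i) for i in self.electrode_ids)
        if len(ids) != n:
            raise GeometryError("one electrode id per position required")
        if len(set(ids)) != n:
            raise GeometryError("duplicate electrode ids")
        object.__setattr__(self, "electrode_ids", ids)
        pm = {int(k): int(v) for k, v in self.pin_map.items()}
        if set(pm) != set(ids):
            raise GeometryError("pin_map keys must be exactly the electrode ids")
        if sorted(pm.values()) != list(range(n)):
            raise GeometryError("pin_map must be a bijection onto 0..N-1")
        object.__setattr__(self, "pin_map", pm)
        if self.shape_spec is not None:
            dims, pitches = self.shape_spec
            if int(np.prod(dims)) != n:
                raise GeometryError(
                    f"grid {dims} implies {int(np.prod(dims))} electrodes, got {n}"
                )
        if self.depth_axis not in (0, 1, 2):
            raise GeometryError("depth_axis must be 0, 1 or 2")
        object.__setattr__(
            self, "_inverse_pin_map", {v: k for k, v in pm.items()}
        )

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    @property
    def dimensionality(self) -> int:
        """Number of spatial axes with more than one distinct coordinate."""
        return int(
            sum(len(np.unique(np.round(self.positions[:, a] / _PLANAR_TOL_UM))) > 1
                for a in range(3))
        )

    def electrode_to_channel(self, electrode_id: int) -> int:
        """Acquisition-channel index (0-based) for a 1-based electrode id."""
        try:
            return self.pin_map[int(electrode_id)]
        except KeyError:
            raise GeometryError(
                f"unknown electrode id {electrode_id} on array '{self.name}'"
            ) from None

    def channel_to_electrode(self, channel: int) -> int:
        """Inverse of :meth:`electrode_to_channel`."""
        try:
            return self._inverse_pin_map[int(channel)]
        except KeyError:
            raise GeometryError(
                f"unknown channel {channel} on array '{self.name}'"
            ) from None

    def csd_groups(self) -> list[dict]:
        """Partition electrodes into per-shank depth columns.

        Electrodes sharing the same planar (non-depth) coordinates form one
        group, sorted by increasing depth.  Groups with fewer than 3
        electrodes cannot support a second spatial difference and are
        flagged ``csd_capable=False``.

        Returns
        -------
        list of dict
            Each with keys ``planar`` (tuple, µm), ``electrode_ids``
            (depth-ordered), ``depths_um`` and ``csd_capable``.
        """
        planar_axes = [a for a in range(3) if a != self.depth_axis]
        keys = np.round(self.positions[:, planar_axes] / _PLANAR_TOL_UM).astype(int)
        depth = self.positions[:, self.depth_axis]
        groups: dict[tuple, list[int]] = {}
        for idx, key in enumerate(map(tuple, keys)):
            groups.setdefault(key, []).append(idx)
        out = []
        for key in sorted(groups):
            members = sorted(groups[key], key=lambda i: (depth[i], i))
            out.append(
                {
                    "planar": tuple(k * _PLANAR_TOL_UM for k in key),
                    "electrode_ids": [self.electrode_ids[i] for i in members],
                    "depths_um": [float(depth[i]) for i in members],
                    "csd_capable": len(members) >= 3,
                }
            )
        return out


def _default_depth_axis(dims: Sequence[int]) -> int:
    nontrivial = [a for a, d in enumerate(dims) if d > 1]
    if len(nontrivial) >= 3:
        return 2  # z by convention for true 3D grids
    if len(nontrivial) == 2:
        # 2D: depth runs along the longer axis
        return max(nontrivial, key=lambda a: dims[a])
    return nontrivial[0] if nontrivial else 2


def build_geometry(
    spec: dict,
) -> ElectrodeArray:
    """Build a validated :class:`ElectrodeArray` from a description.

    ``spec`` is either a grid description::

        {"name": ..., "grid": [nx, ny, nz], "pitch_um": [px, py, pz],
         "pin_map": [...optional...], "depth_axis": ...optional...}

    or an explicit list of positions::

        {"name": ..., "positions": [[id, x, y, z], ...], "pin_map": [...]}

    Grid electrodes are numbered 1..N in x-fastest order.  ``pin_map`` is a
    list where entry i is the channel of electrode id i+1; omitted, the map
    is the identity (id k -> channel k-1).
    """
    name = spec.get("name", "array")
    if "grid" in spec:
        dims = [int(d) for d in spec["grid"]]
        while len(dims) < 3:
            dims.append(1)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise GeometryError(f"grid dims must be 3 integers >= 1, got {dims}")
        pitch = [float(p) for p in spec.get("pitch_um", [1.0, 1.0, 1.0])]
        while len(pitch) < 3:
            pitch.append(1.0)
        if any(p <= 0 for p in pitch):
            raise GeometryError(f"pitches must be positive, got {pitch}")
        nx, ny, nz = dims
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        # x-fastest electrode numbering: Fortran ravel varies ix fastest
        xs = (ix * pitch[0]).ravel(order="F")
        ys = (iy * pitch[1]).ravel(order="F")
        zs = (iz * pitch[2]).ravel(order="F")
        positions = np.column_stack([xs, ys, zs])
        n = nx * ny * nz
        ids = tuple(range(1, n + 1))
        shape_spec = ((nx, ny, nz), tuple(pitch))
        depth_axis = int(spec.get("depth_axis", _default_depth_axis(dims)))
    elif "positions" in spec:
        rows = spec["positions"]
        ids = tuple(int(r[0]) for r in rows)
        positions = np.array([[float(v) for v in r[1:4]] for r in rows])
        n = len(rows)
        shape_spec = None
        depth_axis = int(spec.get("depth_axis", 2))
    else:
        raise GeometryError("spec must contain 'grid' or 'positions'")

    if "pin_map" in spec and spec["pin_map"] is not None:
        pins = [int(p) for p in spec["pin_map"]]
        if len(pins) != n:
            raise GeometryError("pin_map length must equal electrode count")
        pin_map = dict(zip(ids, pins))
    else:
        pin_map = {eid: i for i, eid in enumerate(ids)}
    return ElectrodeArray(
        name=name,
        positions=positions,
        electrode_ids=ids,
        pin_map=pin_map,
        shape_spec=shape_spec,
        depth_axis=depth_axis,
    )


def save_geometry(array: ElectrodeArray) -> dict:
    """JSON-serializable document; round-trips through :func:`load_geometry`."""
    doc: dict = {"name": array.name, "depth_axis": array.depth_axis}
    if array.shape_spec is not None:
        dims, pitch = array.shape_spec
        doc["grid"] = list(dims)
        doc["pitch_um"] = list(pitch)
        doc["pin_map"] = [array.pin_map[eid] for eid in array.electrode_ids]
    else:
        doc["positions"] = [
            [eid, *map(float, array.positions[i])]
            for i, eid in enumerate(array.electrode_ids)
        ]
        doc["pin_map"] = [array.pin_map[eid] for eid in array.electrode_ids]
    return doc


def load_geometry(doc: dict | str) -> ElectrodeArray:
    """Load an array from a geometry document (dict or JSON text)."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    return build_geometry(doc)
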