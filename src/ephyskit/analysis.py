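"""Trial-aligned PSTH accumulation and per-shank current source density.

The PSTH is a running mean over remotely triggered trials, updated
incrementally as each trial arrives (the incremental result is identical to
recomputing over all trials in a batch).  Trial conditions are not
distinguished.

CSD is the classic three-point estimate: the negative second spatial
difference of the depth-resolved field potential along one shank, scaled by
tissue conductivity.  Electrodes sharing a planar location form a depth
column (see :mod:`ephyskit.geometry`); the two edge electrodes of each
column have no complete neighbourhood and are dropped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PSTH",
    "CSDProfile",
    "compute_csd",
    "lfp_depth_matrix",
    "DEFAULT_SIGMA_S_PER_M",
]

#: default tissue conductivity (S/m) for scaled CSD values
DEFAULT_SIGMA_S_PER_M = 0.3


@dataclass
class PSTH:
    """Running post-stimulus histogram (spike counts or LFP average).

    ``edges`` are bin edges in seconds relative to the trial trigger.
    ``values`` holds per-bin means over the accumulated trials: mean spike
    count per trial in ``spikes`` mode, mean voltage (µV) in ``lfp`` mode.
    """

    edges: np.ndarray
    mode: str = "spikes"  # 'spikes' | 'lfp'
    n_trials: int = 0
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.size < 2 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be increasing with >= 2 entries")
        if self.mode not in ("spikes", "lfp"):
            raise ValueError("mode must be 'spikes' or 'lfp'")
        if self.values is None:
            self.values = np.zeros(self.edges.size - 1)

    @classmethod
    def from_window(cls, t_start: float, t_stop: float, bin_s: float = 0.01,
                    mode: str = "spikes") -> "PSTH":
        """PSTH with uniform bins of ``bin_s`` seconds (default 10 ms)."""
        n = int(round((t_stop - t_start) / bin_s))
        return cls(edges=t_start + np.arange(n + 1) * bin_s, mode=mode)

    def accumulate(self, trial: np.ndarray) -> "PSTH":
        """Fold one trial into the running mean.

        In ``spikes`` mode ``trial`` is the array of spike times (s,
        trigger at 0); in ``lfp`` mode it is a per-bin trace whose length
        must equal the number of bins.
        """
        if self.mode == "spikes":
            counts, _ = np.histogram(np.asarray(trial, dtype=float), self.edges)
            contrib = counts.astype(float)
        else:
            contrib = np.asarray(trial, dtype=float)
            if contrib.shape != self.values.shape:
                raise ValueError(
                    f"lfp trace length {contrib.size} != {self.values.size} bins"
                )
        self.n_trials += 1
        # numerically exact running mean: identical to the batch mean
        self.values = self.values + (contrib - self.values) / self.n_trials
        return self

    def to_csv(self) -> str:
        """Two-row CSV: bin edges, then per-bin means."""
        buf = io.StringIO()
        buf.write(",".join(f"{e:.6f}" for e in self.edges) + "\n")
        buf.write(",".join(f"{v:.9g}" for v in self.values) + "\n")
        return buf.getvalue()


@dataclass
class CSDProfile:
    """CSD along one shank at the interior electrode depths.

    ``values`` are in µA/mm³ when conductivity-scaled, else raw second
    differences in µV/µm².
    """

    shank: tuple[float, ...]  # planar location (µm) identifying the shank
    depths_um: np.ndarray  # interior electrode depths
    values: np.ndarray  # (n_interior,) or (n_interior, n_samples)
    scaled: bool

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write(",".join(f"{d:.3f}" for d in self.depths_um) + "\n")
        vals = np.atleast_2d(self.values.T)
        for row in vals:
            buf.write(",".join(f"{v:.9g}" for v in row) + "\n")
        return buf.getvalue()


def lfp_depth_matrix(data, array, group) -> tuple[np.ndarray, np.ndarray]:
    """Depth-ordered LFP traces for one shank (depth x time, µV).

    ``group`` is one entry of :meth:`ElectrodeArray.csd_groups`; rows are
    ordered by increasing depth via the array's pin map.  This is the
    data behind a depth heat-map display and the input to
    :func:`compute_csd`.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    channels = [array.electrode_to_channel(eid) for eid in group["electrode_ids"]]
    return np.asarray(group["depths_um"], dtype=float), data[channels]


def compute_csd(
    lfp_by_depth: np.ndarray,
    spacing_um: float | None = None,
    depths_um: np.ndarray | None = None,
    sigma_s_per_m: float | None = DEFAULT_SIGMA_S_PER_M,
    shank: tuple[float, ...] = (0.0,),
) -> CSDProfile:
    """Current source density from depth-ordered field potentials.

    For interior electrode i::

        CSD_i = -sigma * (V_{i-1} - 2 V_i + V_{i+1}) / dz^2

    Parameters
    ----------
    lfp_by_depth
        ``(n_depths,)`` or ``(n_depths, n_samples)`` array of potentials in
        µV, ordered by increasing depth.
    spacing_um
        Uniform inter-electrode spacing.  May be omitted when
        ``depths_um`` is given; spacing uniformity is checked to 1%.
    sigma_s_per_m
        Tissue conductivity.  ``None`` returns the unscaled second
        difference in µV/µm².

    Returns
    -------
    CSDProfile
        Scaled values are in µA/mm³ (σ[S/m] · µV/µm² = µA/mm³, since
        S/m · V/m² = A/m³).
    """
    v = np.asarray(lfp_by_depth, dtype=float)
    squeeze = v.ndim == 1
    if squeeze:
        v = v.reshape(-1, 1)
    n = v.shape[0]
    if n < 3:
        raise ValueError(f"CSD needs >= 3 electrodes in a depth group, got {n}")
    if depths_um is not None:
        depths_um = np.asarray(depths_um, dtype=float)
        dz = np.diff(depths_um)
        if np.any(dz <= 0):
            raise ValueError("depths must be strictly increasing")
        if (dz.max() - dz.min()) > 0.01 * dz.mean():
            raise ValueError("electrode spacing non-uniform beyond 1%")
        spacing = float(dz.mean())
    else:
        if spacing_um is None:
            raise ValueError("either spacing_um or depths_um is required")
        spacing = float(spacing_um)
        depths_um = np.arange(n) * spacing
    if spacing <= 0:
        raise ValueError("spacing must be positive")

    second_diff = (v[:-2] - 2 * v[1:-1] + v[2:]) / spacing**2  # µV/µm²
    if sigma_s_per_m is None:
        values = second_diff
        scaled = False
    else:
        values = -sigma_s_per_m * second_diff
        scaled = True
    if squeeze:
        values = values[:, 0]
    return CSDProfile(
        shank=tuple(shank),
        depths_um=depths_um[1:-1],
        values=values,
        scaled=scaled,
    )
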