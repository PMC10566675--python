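"""Pair measured resonance peaks with simulated modes and score spatial agreement.

Measured peaks are matched order-preservingly against per-mode frequency
ranges spanned by a material sweep (optionally inflated by a tolerance).
Spatial agreement between an amplitude map and a mode's surface-normal
displacement is a Spearman rank correlation: radiated amplitude and surface
displacement are monotonically, not linearly, related.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from tpcvibe.geometry import SurfaceMesh
from tpcvibe.modal_fem import ModalSolution, NormalDisplacementField
from tpcvibe.tap_spectra import AmplitudeMap, PeakSet

__all__ = [
    "SurfacePointMap",
    "ModeMatchReport",
    "map_tap_locations",
    "spatial_correlation",
    "match_modes",
    "left_right_offset",
]


@dataclass(frozen=True)
class SurfacePointMap:
    """tap_location_id -> nearest surface vertex (index into surface arrays)."""

    table: pd.DataFrame  # columns: tap_location_id, vertex_id, distance_m

    def vertex_of(self, loc: int) -> int:
        row = self.table[self.table.tap_location_id == loc]
        if len(row) != 1:
            raise KeyError(f"tap location {loc} not mapped")
        return int(row.vertex_id.iloc[0])


@dataclass(frozen=True)
class ModeMatchReport:
    """Per-mode pairing of measured peaks with sweep frequency ranges."""

    matches: pd.DataFrame
    # columns: mode_index, peak_freq_hz, range_min_hz, range_max_hz,
    #          offset_hz (0 when the peak lies inside the inflated range)
    unmatched_peaks_hz: np.ndarray
    unmatched_modes: np.ndarray
    tolerance_pct: float

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tolerance_pct": self.tolerance_pct,
            "matches": self.matches.to_dict(orient="records"),
            "unmatched_peaks_hz": self.unmatched_peaks_hz.tolist(),
            "unmatched_modes": self.unmatched_modes.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_csv(self, path: str | Path) -> None:
        self.matches.to_csv(path, index=False)


def map_tap_locations(
    surface: SurfaceMesh,
    coords: pd.DataFrame,
    tolerance_m: float | None = None,
) -> SurfacePointMap:
    """Nearest-surface-vertex assignment for tap-location coordinates.

    ``coords`` needs columns ``tap_location_id, x, y, z`` (meters, mesh
    frame).  A warning is issued for any location farther than
    ``tolerance_m`` from the surface (default: twice the median edge
    length of the boundary triangulation).
    """
    if len(coords) == 0 or len(surface.vertices) == 0:
        raise ValueError("empty tap locations or surface")
    need = {"tap_location_id", "x", "y", "z"}
    if not need <= set(coords.columns):
        raise ValueError(f"coords must have columns {sorted(need)}")
    tree = cKDTree(surface.vertices)
    pts = coords[["x", "y", "z"]].to_numpy(dtype=float)
    dist, idx = tree.query(pts)
    if tolerance_m is None:
        tri = surface.vertices[surface.triangles]
        edges = np.linalg.norm(tri - np.roll(tri, 1, axis=1), axis=2)
        tolerance_m = 2.0 * float(np.median(edges))
    far = dist > tolerance_m
    if far.any():
        warnings.warn(
            f"{far.sum()} tap location(s) farther than {tolerance_m:.3g} m "
            "from the surface",
            stacklevel=2,
        )
    table = pd.DataFrame(
        {
            "tap_location_id": coords["tap_location_id"].to_numpy(),
            "vertex_id": idx,
            "distance_m": dist,
        }
    )
    return SurfacePointMap(table=table)


def spatial_correlation(
    amap: AmplitudeMap,
    field: NormalDisplacementField,
    pointmap: SurfacePointMap,
    mode: int,
    reduce: str = "max",
) -> float:
    """Spearman rank correlation between measured amplitudes and |u . n|.

    Measured amplitude per location is reduced over microphones (``max`` by
    default, ``mean`` optionally); the simulated value is the mode's normal
    displacement magnitude at the mapped surface vertex.
    """
    reduced = amap.reduced(reduce)
    locs = reduced.index.to_numpy()
    if len(locs) < 3:
        raise ValueError("need at least 3 tap locations for a correlation")
    mapped = pointmap.table.set_index("tap_location_id")
    missing = [l for l in locs if l not in mapped.index]
    if missing:
        raise ValueError(f"tap location(s) {missing[:5]} absent from the point map")
    verts = mapped.loc[locs, "vertex_id"].to_numpy(dtype=int)
    sim = field.values[mode, verts]
    rho = spearmanr(reduced.to_numpy(), sim).statistic
    return float(rho)


def match_modes(
    peaks: PeakSet,
    sweep: Sequence[ModalSolution],
    tolerance_pct: float = 10.0,
) -> ModeMatchReport:
    """Order-preserving assignment of ascending peaks to sweep mode ranges.

    Mode ``i``'s range is the (min, max) of the i-th ascending frequency
    across the sweep, inflated by ``tolerance_pct``; a peak matches the
    first unassigned mode whose inflated range contains it.  The result is
    independent of the ordering of the sweep list.
    """
    if len(peaks) == 0 or len(sweep) == 0:
        raise ValueError("need nonempty peaks and sweep")
    freqs = np.stack([np.sort(s.frequencies_hz) for s in sweep])
    n_modes = freqs.shape[1]
    lo = freqs.min(axis=0)
    hi = freqs.max(axis=0)
    tol = tolerance_pct / 100.0
    lo_i = lo * (1 - tol)
    hi_i = hi * (1 + tol)

    rows = []
    used_modes: set[int] = set()
    unmatched_peaks = []
    mode_cursor = 0
    for f in np.sort(peaks.frequencies_hz):
        matched = None
        for mi in range(mode_cursor, n_modes):
            if lo_i[mi] <= f <= hi_i[mi]:
                matched = mi
                break
            if f < lo_i[mi]:
                break
        if matched is None:
            unmatched_peaks.append(f)
            continue
        offset = 0.0 if lo[matched] <= f <= hi[matched] else float(
            min(abs(f - lo[matched]), abs(f - hi[matched]))
        )
        rows.append(
            {
                "mode_index": matched + 1,
                "peak_freq_hz": float(f),
                "range_min_hz": float(lo[matched]),
                "range_max_hz": float(hi[matched]),
                "offset_hz": offset,
            }
        )
        used_modes.add(matched)
        mode_cursor = matched + 1
    matches = pd.DataFrame(
        rows,
        columns=["mode_index", "peak_freq_hz", "range_min_hz", "range_max_hz", "offset_hz"],
    )
    return ModeMatchReport(
        matches=matches,
        unmatched_peaks_hz=np.asarray(unmatched_peaks),
        unmatched_modes=np.asarray(sorted(set(range(n_modes)) - used_modes)) + 1,
        tolerance_pct=tolerance_pct,
    )


def left_right_offset(
    left: PeakSet | np.ndarray, right: PeakSet | np.ndarray
) -> pd.DataFrame:
    """Per-mode left-minus-right frequency offsets in Hz and percent of right."""
    fl = left.frequencies_hz if isinstance(left, PeakSet) else np.asarray(left, float)
    fr = right.frequencies_hz if isinstance(right, PeakSet) else np.asarray(right, float)
    if len(fl) != len(fr):
        raise ValueError(f"peak lists differ in length ({len(fl)} vs {len(fr)})")
    return pd.DataFrame(
        {
            "mode_index": np.arange(1, len(fl) + 1),
            "left_hz": fl,
            "right_hz": fr,
            "offset_hz": fl - fr,
            "offset_pct": 100.0 * (fl - fr) / fr,
        }
    )
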