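"""Synthetic inputs with machine-readable ground truth.

Two mesh generators (a box beam for analytic checks, a multi-component toy
structure with hinge-like low modes) and a tap-recording synthesizer that
superposes exponentially damped sinusoids per mode, adds a short broadband
click per tap plus white noise, and emits WAV files, a manifest CSV and a
ground-truth JSON bundle.

Meshes are built from axis-aligned boxes on a shared integer lattice; each
cell is split into six tetrahedra with a face-consistent (Kuhn) pattern, so
touching boxes weld into a conforming mesh automatically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from tpcvibe.geometry import TetMesh, to_quadratic
from tpcvibe.tap_spectra import MIC_DIRECTIONS, Recording, write_recording

__all__ = [
    "ToyTPCParams",
    "SyntheticModeSpec",
    "make_beam_mesh",
    "make_toy_tpc",
    "toy_material_cards",
    "cosine_mic_gains",
    "synth_tap_recordings",
    "write_recording_set",
]

# six tetrahedra per lattice cell sharing the (0,0,0)-(1,1,1) diagonal;
# positively oriented, and face splits agree between adjacent cells
_KUHN = (
    ((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
    ((0, 0, 0), (1, 0, 0), (1, 1, 1), (1, 0, 1)),
    ((0, 0, 0), (0, 1, 0), (1, 1, 1), (1, 1, 0)),
    ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
    ((0, 0, 0), (0, 0, 1), (1, 1, 1), (0, 1, 1)),
)


class _LatticeMesher:
    """Accumulates labeled boxes on a global integer lattice and welds them."""

    def __init__(self, pitch):
        self.pitch = np.broadcast_to(np.asarray(pitch, dtype=float), 3).copy()
        self._nodes: dict[tuple[int, int, int], int] = {}
        self._elems: list[list[int]] = []
        self._comp: list[str] = []
        self._reg: list[str] = []

    def _node(self, key) -> int:
        if key not in self._nodes:
            self._nodes[key] = len(self._nodes)
        return self._nodes[key]

    def add_box(self, lo, hi, component: str, region: str) -> int:
        """Mesh the lattice box [lo, hi) cells; returns elements added."""
        lo = np.asarray(lo, int)
        hi = np.asarray(hi, int)
        if np.any(hi <= lo):
            raise ValueError(f"degenerate box {lo} .. {hi}")
        count = 0
        for ix in range(lo[0], hi[0]):
            for iy in range(lo[1], hi[1]):
                for iz in range(lo[2], hi[2]):
                    for tet in _KUHN:
                        conn = [
                            self._node((ix + dx, iy + dy, iz + dz))
                            for dx, dy, dz in tet
                        ]
                        self._elems.append(conn)
                        self._comp.append(component)
                        self._reg.append(region)
                        count += 1
        return count

    def build(self, order: int = 4) -> TetMesh:
        keys = np.array(list(self._nodes.keys()), dtype=float)
        mesh = TetMesh(
            nodes=keys * self.pitch,
            elements=np.array(self._elems, dtype=np.int64),
            component=np.array(self._comp, dtype=object),
            region=np.array(self._reg, dtype=object),
        )
        if order == 10:
            mesh = to_quadratic(mesh)
        elif order != 4:
            raise ValueError("order must be 4 or 10")
        return mesh

    def nodes_where(self, mesh: TetMesh, predicate) -> np.ndarray:
        return np.flatnonzero(predicate(mesh.nodes))


def _check_connected(mesh: TetMesh) -> None:
    m = mesh.n_elements
    rows = np.repeat(np.arange(m), mesh.order)
    cols = mesh.elements.ravel()
    inc = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, mesh.n_nodes)
    ).tocsr()
    adj = inc @ inc.T
    n, _ = connected_components(adj, directed=False)
    if n != 1:
        raise ValueError(f"generated mesh has {n} connected components")


def make_beam_mesh(
    length: float,
    width: float,
    height: float,
    divisions: tuple[int, int, int] = (20, 2, 2),
    order: int = 10,
) -> TetMesh:
    """Structured tet mesh of a box beam along x, single component/region.

    The ``x = 0`` face is the intended clamp; select it with a predicate
    like ``lambda p: p[:, 0] < 1e-12``.
    """
    if min(length, width, height) <= 0 or min(divisions) < 1:
        raise ValueError("dimensions and divisions must be positive")
    nx, ny, nz = divisions
    mesher = _LatticeMesher((length / nx, width / ny, height / nz))
    mesher.add_box((0, 0, 0), (nx, ny, nz), "beam", "stiff_bone")
    return mesher.build(order)


@dataclass(frozen=True)
class ToyTPCParams:
    """Lattice layout of the toy multi-component structure (cells of ``pitch`` m).

    A stiff fixed block ("periotic") hangs two slender flexible connectors
    (the pedicles) that carry a stiff shell block ("bulla", with an
    off-center ridge standing in for the sigmoid process).  A three-segment
    stiff appendage (malleus-incus-stapes) joined by soft ligament cells is
    attached to the side of the bulla.  Deliberately asymmetric so no modes
    are exactly degenerate.
    """

    pitch: float = 0.01
    bulla: tuple = ((0, 0, 0), (6, 4, 2))
    ridge: tuple = ((1, 4, 0), (3, 5, 2))
    anterior_pedicle: tuple = ((1, 1, 2), (2, 2, 5))
    posterior_pedicle: tuple = ((4, 2, 2), (5, 3, 5))
    periotic: tuple = ((0, 0, 5), (6, 4, 7))
    malleus: tuple = ((6, 1, 0), (7, 2, 2))
    ligament_mi: tuple = ((7, 1, 1), (8, 2, 2))
    incus: tuple = ((8, 1, 1), (9, 2, 2))
    ligament_is: tuple = ((9, 1, 1), (10, 2, 2))
    stapes: tuple = ((10, 1, 1), (11, 2, 2))

    def __post_init__(self):
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")


def toy_material_cards():
    """Default material cards for the toy structure.

    Bone values follow the stiff/flexible corner cards used throughout the
    analysis; the ligament card is deliberately stiffer than a physiological
    ligament so the appendage-chain modes land inside the measured band
    instead of crowding the spectrum below it.
    """
    from tpcvibe.geometry import MaterialCard

    return {
        "stiff_bone": MaterialCard(2400.0, 25e9, 0.3),
        "flexible_bone": MaterialCard(2000.0, 5e9, 0.3),
        "stiff_ligament": MaterialCard(1200.0, 1e8, 0.3),
        "flexible_ligament": MaterialCard(1200.0, 1e8, 0.45),
    }


#: component -> material region for the toy structure
TOY_REGIONS = {
    "periotic": "stiff_bone",
    "bulla": "stiff_bone",
    "anterior_pedicle": "flexible_bone",
    "posterior_pedicle": "flexible_bone",
    "malleus": "stiff_bone",
    "incus": "stiff_bone",
    "stapes": "stiff_bone",
    "ligament_mi": "stiff_ligament",
    "ligament_is": "stiff_ligament",
}


def make_toy_tpc(
    params: ToyTPCParams | None = None, seed: int = 0, order: int = 10
) -> tuple[TetMesh, dict]:
    """Toy fixed-base structure plus ground-truth tables.

    Returns ``(mesh, truth)`` where ``truth`` holds per-component element
    counts, the base node set (top face of the fixed block), tap-location
    coordinates on the shell underside, and the parameters used.
    """
    p = params or ToyTPCParams()
    mesher = _LatticeMesher(p.pitch)
    counts: dict[str, int] = {}
    # bulla ridge is part of the bulla component (a shape feature, not a part)
    counts["bulla"] = mesher.add_box(*p.bulla, "bulla", TOY_REGIONS["bulla"])
    counts["bulla"] += mesher.add_box(*p.ridge, "bulla", TOY_REGIONS["bulla"])
    for name in (
        "anterior_pedicle",
        "posterior_pedicle",
        "periotic",
        "malleus",
        "ligament_mi",
        "incus",
        "ligament_is",
        "stapes",
    ):
        counts[name] = mesher.add_box(*getattr(p, name), name, TOY_REGIONS[name])
    mesh = mesher.build(order)
    _check_connected(mesh)

    # base = top face of the fixed block
    ztop = p.periotic[1][2] * p.pitch
    peri_nodes = mesh.component_nodes("periotic")
    base = peri_nodes[np.abs(mesh.nodes[peri_nodes, 2] - ztop) < 1e-12 * max(1, ztop)]

    # tap locations: lattice nodes of the shell underside (z = 0)
    (bx0, by0, _), (bx1, by1, _) = p.bulla
    locs = []
    tid = 1
    for ix in range(bx0, bx1 + 1):
        for iy in range(by0, by1 + 1):
            locs.append(
                {
                    "tap_location_id": tid,
                    "x": ix * p.pitch,
                    "y": iy * p.pitch,
                    "z": 0.0,
                }
            )
            tid += 1
    truth = {
        "component_counts": counts,
        "base_nodes": np.sort(base),
        "tap_locations": pd.DataFrame(locs),
        "params": p,
        "seed": seed,
    }
    return mesh, truth


# ---------------------------------------------------------------------------
# tap-recording synthesis
# ---------------------------------------------------------------------------


@dataclass
class SyntheticModeSpec:
    """Forward model for tap recordings as damped-sinusoid mode superpositions.

    Channel ``m`` at tap location ``loc`` receives, per tap of strength
    ``s``:  ``sum_k  w[loc,k] g[loc,m] s  exp(-z_k w_k t) sin(w_k sqrt(1-z_k^2) t)``
    plus a short broadband click (so the high-frequency normalization bin
    carries deterministic tap energy) and white Gaussian noise at ``snr_db``
    relative to the first tap's peak amplitude.
    """

    frequencies_hz: np.ndarray
    weights: np.ndarray  # (n_locations, n_modes) excitation per location
    mic_gains: np.ndarray  # (n_locations, n_mics)
    zetas: np.ndarray | float = 0.01
    sample_rate: float = 48000.0
    taps_per_location: int = 20
    tap_interval_s: float = 0.6
    jitter_s: float = 0.02
    snr_db: float = 20.0
    click_level: float = 2.0
    click_freq_hz: float = 15000.0
    click_ms: float = 4.0
    seed: int = 0

    def __post_init__(self):
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.mic_gains = np.atleast_2d(np.asarray(self.mic_gains, dtype=float))
        z = np.asarray(self.zetas, dtype=float)
        if z.ndim == 0:
            z = np.full(len(self.frequencies_hz), float(z))
        self.zetas = z
        if np.any(self.frequencies_hz >= self.sample_rate / 2):
            raise ValueError("mode frequency at or above Nyquist (aliasing)")
        if np.any((self.zetas <= 0) | (self.zetas >= 1)):
            raise ValueError("damping ratios must lie in (0, 1)")
        if self.taps_per_location < 2:
            raise ValueError("need at least 2 taps per location")
        if self.weights.shape[1] != len(self.frequencies_hz):
            raise ValueError("weights must be (n_locations, n_modes)")
        if self.mic_gains.shape[0] != self.weights.shape[0]:
            raise ValueError("mic_gains and weights disagree on n_locations")


def cosine_mic_gains(
    normals: np.ndarray, mic_directions: list[str] | None = None, floor: float = 0.1
) -> np.ndarray:
    """Direction gains: cosine between mic direction and surface normal, floored."""
    if mic_directions is None:
        mic_directions = list(MIC_DIRECTIONS)
    dirs = np.stack([MIC_DIRECTIONS[d] for d in mic_directions])
    g = normals @ dirs.T
    return np.maximum(g, floor)


def _mode_segment(spec: SyntheticModeSpec, loc_idx: int, n: int) -> np.ndarray:
    """Clean per-mode superposition after one unit-strength tap, (mics, n)."""
    t = np.arange(n) / spec.sample_rate
    omega = 2 * np.pi * spec.frequencies_hz
    wd = omega * np.sqrt(1 - spec.zetas**2)
    modes = np.exp(-np.outer(spec.zetas * omega, t)) * np.sin(np.outer(wd, t))
    per_mode = spec.weights[loc_idx][:, None] * modes  # (modes, n)
    return spec.mic_gains[loc_idx][:, None] * per_mode.sum(axis=0)[None, :]


def _click(spec: SyntheticModeSpec) -> np.ndarray:
    """Tapping-tool contact ping: Hann-windowed tone burst at ``click_freq_hz``.

    Concentrates tap energy near the spectrum-normalization frequency, so
    the normalization bin is tap-dominated (not noise-dominated) as it is
    in a physical impact measurement.
    """
    n = max(8, int(round(spec.click_ms * 1e-3 * spec.sample_rate)))
    t = np.arange(n) / spec.sample_rate
    return np.hanning(n) * np.cos(2 * np.pi * spec.click_freq_hz * t)


def synth_tap_recordings(
    spec: SyntheticModeSpec,
    location_ids: list[int] | None = None,
    mic_ids: list[str] | None = None,
) -> tuple[dict[int, Recording], dict]:
    """Multichannel recordings per tap location plus the ground-truth bundle.

    Deterministic for a fixed ``spec.seed``.  The bundle records onsets,
    planted frequencies and damping, per-location weights and mic gains,
    per-location tap strengths and the noise levels used.
    """
    n_loc, n_modes = spec.weights.shape
    n_mics = spec.mic_gains.shape[1]
    if location_ids is None:
        location_ids = list(range(1, n_loc + 1))
    if mic_ids is None:
        mic_ids = list(MIC_DIRECTIONS)[:n_mics]
    if len(location_ids) != n_loc or len(mic_ids) != n_mics:
        raise ValueError("location/mic id lists disagree with spec shapes")

    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    seg_n = int(round(0.5 * fs))
    click = _click(spec)
    recordings: dict[int, Recording] = {}
    truth_onsets: dict[int, list[int]] = {}
    truth_strengths: dict[int, list[float]] = {}
    noise_sigmas: dict[int, float] = {}

    for li, loc in enumerate(location_ids):
        gaps = spec.tap_interval_s + spec.jitter_s * rng.uniform(
            -1, 1, spec.taps_per_location - 1
        )
        onsets = np.round(
            (0.5 + np.concatenate([[0.0], np.cumsum(gaps)])) * fs
        ).astype(int)
        total = onsets[-1] + seg_n + int(0.25 * fs)
        clean = np.zeros((n_mics, total))
        seg = _mode_segment(spec, li, seg_n)  # (mics, seg_n)
        loc_strength = rng.uniform(0.8, 1.2)
        strengths = loc_strength * rng.uniform(0.9, 1.1, spec.taps_per_location)
        for o, s in zip(onsets, strengths):
            clean[:, o : o + seg_n] += s * seg
            cl = s * spec.click_level * spec.mic_gains[li][:, None] * click[None, :]
            clean[:, o : o + len(click)] += cl
        # per-channel noise at the requested SNR vs that channel's first tap peak
        peak = np.abs(clean[:, onsets[0] : onsets[0] + seg_n]).max(axis=1)
        sigma = peak * 10 ** (-spec.snr_db / 20)
        samples = clean + sigma[:, None] * rng.standard_normal(clean.shape)
        recordings[loc] = Recording(
            samples=samples,
            rate=fs,
            mic_ids=list(mic_ids),
            mic_directions=list(mic_ids),
            tap_location_id=loc,
        )
        truth_onsets[loc] = onsets.tolist()
        truth_strengths[loc] = strengths.tolist()
        noise_sigmas[loc] = sigma.tolist()

    truth = {
        "frequencies_hz": spec.frequencies_hz.tolist(),
        "zetas": spec.zetas.tolist(),
        "weights": spec.weights.tolist(),
        "mic_gains": spec.mic_gains.tolist(),
        "location_ids": list(location_ids),
        "mic_ids": list(mic_ids),
        "onsets": truth_onsets,
        "tap_strengths": truth_strengths,
        "noise_sigmas": noise_sigmas,
        "sample_rate": fs,
        "snr_db": spec.snr_db,
        "seed": spec.seed,
    }
    return recordings, truth


def write_recording_set(
    out_dir: str | Path, recordings: dict[int, Recording], truth: dict
) -> Path:
    """Write WAVs, a manifest CSV and the ground-truth JSON; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for loc in sorted(recordings):
        rec = recordings[loc]
        fname = f"loc{loc:03d}.wav"
        write_recording(out / fname, rec)
        for mic, d in zip(rec.mic_ids, rec.mic_directions or rec.mic_ids):
            rows.append(
                {
                    "file": fname,
                    "tap_location_id": loc,
                    "mic_id": mic,
                    "mic_direction": d,
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return manifest
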