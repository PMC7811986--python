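"""Dose quantities: body current, impedance, heart fields, heart current factors.

From a solved field the pipeline measures

* I_Body -- total body current, the mean of the conduction-current flux
  through several cross-section planes transecting the current path (the
  spread across planes is a charge-conservation diagnostic);
* Z_Total = U_t / I_Body (Ohm's law; U_t is real by convention, the phase is
  carried by the current);
* E99Heart -- the 99th percentile of the field-magnitude distribution over the
  ventricular myocardium (the compliance-style robust maximum);
* E_Sam -- the trans-cardiac field estimated from three orthogonal line
  integrals across the heart at 1-mm sampling, imitating cadaver voltage
  probes: E_i = |integral E . dl| / L_i, combined as the Euclidean norm
  (the unique rotation-consistent combination of three orthogonal
  unidirectional estimates);

and the two heart-current-factor statistics, each normalised to the LH-BF
reference path at the same frequency:

    F(p, f) = [E(p, f) / |I_Body(p, f)|] * [|I_Body(ref, f)| / E(ref, f)]

with E = E99Heart (F99) or E = E_Sam (FSam).  By solver linearity the factors
are invariant to the touch voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .paths import REFERENCE_PATH
from .phantom import AIR, HEART_WALL, VoxelPhantom
from .solver import FieldSolution, _face_conductance

__all__ = [
    "BodyCurrent", "DoseReport", "HCFTable",
    "body_current", "total_impedance", "e99_heart", "sam_field",
    "percentile99", "hcf", "evaluate_solution",
]


@dataclass(frozen=True)
class BodyCurrent:
    """Plane-averaged total body current with its conservation diagnostic."""

    value: complex               # A
    per_plane: tuple[complex, ...]
    spread: float                # max pairwise |I_i - I_j| / |mean|


@dataclass(frozen=True)
class DoseReport:
    """All dose quantities of one (path, frequency, voltage) solve."""

    path_label: str
    frequency: float
    touch_voltage: float
    mode: str
    i_body: complex              # A
    z_total: complex             # Ohm
    e99_heart: float             # V/m (phasor magnitude)
    e_sam: float                 # V/m
    plane_spread: float
    residual: float
    f99_num: float | None = None
    f_sam_num: float | None = None


def _electrode_centroid(phantom: VoxelPhantom, sites: Iterable[str]) -> np.ndarray:
    pts = np.concatenate([phantom.electrodes[s].contact for s in sorted(sites)])
    return pts.mean(axis=0)


def body_current(
    solution: FieldSolution,
    n_planes: int = 4,
    axis: int | None = None,
    plane_indices: Sequence[int] | None = None,
) -> BodyCurrent:
    """Total body current through cross-section planes between source and sink.

    Each plane k cuts the grid between voxel slices k and k+1 along ``axis``
    (default: the dominant axis of the source-to-sink displacement).  The flux
    through a plane is the sum of the finite-volume face currents
    g_face * (phi_k - phi_{k+1}), i.e. the discrete surface integral of J.n
    consistent with the assembled operator, so the spread across planes
    measures pure solver error.  Planes are placed at even fractions of the
    gap between the electrode extents; a plane that does not intersect the
    body is an error.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    phantom = solution.phantom
    scen = solution.scenario
    src = _electrode_centroid(phantom, scen.path.source_sites)
    snk = _electrode_centroid(phantom, scen.path.sink_sites)
    delta = (snk - src) * phantom.spacing
    if axis is None:
        axis = int(np.argmax(np.abs(delta)))
    direction = 1 if delta[axis] >= 0 else -1

    if plane_indices is None:
        src_vox = np.concatenate(
            [phantom.electrodes[s].contact for s in sorted(scen.path.source_sites)])
        snk_vox = np.concatenate(
            [phantom.electrodes[s].contact for s in sorted(scen.path.sink_sites)])
        if direction > 0:
            lo = int(src_vox[:, axis].max())
            hi = int(snk_vox[:, axis].min())
        else:
            lo = int(snk_vox[:, axis].max())
            hi = int(src_vox[:, axis].min())
        if hi - lo < 2:
            raise ValueError(
                "source and sink electrodes overlap along the measurement axis; "
                "supply plane_indices explicitly")
        fracs = (np.arange(n_planes) + 1) / (n_planes + 1)
        plane_indices = sorted({int(round(lo + f * (hi - lo - 1))) for f in fracs})

    phi = solution.potential
    sig = solution.sigma_star
    g = _face_conductance(sig, axis, phantom.spacing)
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    currents = []
    for k in plane_indices:
        if not 0 <= k < phantom.labels.shape[axis] - 1:
            raise ValueError(f"plane index {k} outside the grid")
        sl_lo[axis] = k
        sl_hi[axis] = k + 1
        gk = g[tuple(sl_lo)]
        if not np.any(gk != 0):
            raise ValueError(f"cross-section plane at index {k} misses the body")
        flux = np.sum(gk * (phi[tuple(sl_lo)] - phi[tuple(sl_hi)]))
        currents.append(direction * flux)
    currents = np.array(currents)
    mean = currents.mean()
    if mean == 0:
        raise ValueError("zero net current through the measurement planes")
    spread = float(np.max(np.abs(currents[:, None] - currents[None, :])) / np.abs(mean))
    return BodyCurrent(value=complex(mean),
                       per_plane=tuple(complex(c) for c in currents),
                       spread=spread)


def total_impedance(touch_voltage: float, i_body: complex) -> complex:
    """Z = U_t / I_Body; the touch voltage is real by convention."""
    if i_body == 0:
        raise ValueError("zero body current")
    return touch_voltage / i_body


def percentile99(values: np.ndarray) -> float:
    """99th percentile with linear interpolation between closest order
    statistics (the convention is stated explicitly because compliance
    guidelines do not fix one)."""
    return float(np.percentile(np.asarray(values, dtype=float), 99.0,
                               method="linear"))


def e99_heart(solution: FieldSolution) -> float:
    """99th percentile of |E| over the ventricular myocardium.

    |E| is the phasor amplitude sqrt(|Ex|^2 + |Ey|^2 + |Ez|^2) per voxel.
    The domain is the myocardium shell only -- lumen blood and vessels are
    excluded.
    """
    if solution.e_field is None:
        raise ValueError("solution has no derived fields; call derive_fields first")
    sel = solution.phantom.labels == HEART_WALL
    if not np.any(sel):
        raise ValueError("phantom has no ventricular-myocardium voxels")
    mag = np.sqrt(np.sum(np.abs(solution.e_field[sel]) ** 2, axis=-1))
    return percentile99(mag)


def heart_field_magnitudes(solution: FieldSolution) -> np.ndarray:
    """|E| samples over the myocardium (for distribution diagnostics)."""
    sel = solution.phantom.labels == HEART_WALL
    return np.sqrt(np.sum(np.abs(solution.e_field[sel]) ** 2, axis=-1))


def sam_field(solution: FieldSolution, step_mm: float = 1.0,
              return_components: bool = False):
    """Trans-cardiac field from three orthogonal line integrals at 1-mm steps.

    For each heart axis i: V_i = integral of E . dl (trilinear interpolation
    of the complex field), E_i = |V_i| / L_i; returns sqrt(E1^2+E2^2+E3^2).
    An axis leaving the body is an error.
    """
    if solution.e_field is None:
        raise ValueError("solution has no derived fields; call derive_fields first")
    phantom = solution.phantom
    comps = []
    for seg in phantom.heart_axes:
        p0, p1 = seg
        length_mm = float(np.linalg.norm(p1 - p0))
        if length_mm == 0:
            raise ValueError("degenerate heart axis of zero length")
        n = max(2, int(np.ceil(length_mm / step_mm)) + 1)
        t = np.linspace(0.0, 1.0, n)
        pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
        idx = phantom.world_to_index(pts).T  # (3, n)
        labs = ndimage.map_coordinates(phantom.labels, idx, order=0, mode="constant",
                                       cval=AIR)
        if np.any(labs == AIR):
            raise ValueError("heart axis exits the phantom body")
        tang = (p1 - p0) / length_mm
        e_tan = np.zeros(n, dtype=complex)
        for a in range(3):
            re = ndimage.map_coordinates(solution.e_field[..., a].real, idx, order=1)
            im = ndimage.map_coordinates(solution.e_field[..., a].imag, idx, order=1)
            e_tan += (re + 1j * im) * tang[a]
        length_m = length_mm * 1e-3
        v = np.trapezoid(e_tan, dx=length_m / (n - 1))
        comps.append(abs(v) / length_m)
    e_sam = float(np.sqrt(sum(c**2 for c in comps)))
    if return_components:
        return e_sam, tuple(float(c) for c in comps)
    return e_sam


def evaluate_solution(solution: FieldSolution, n_planes: int = 4) -> DoseReport:
    """Post-process one solved scenario into a DoseReport."""
    cur = body_current(solution, n_planes=n_planes)
    scen = solution.scenario
    return DoseReport(
        path_label=scen.path.label,
        frequency=scen.frequency,
        touch_voltage=scen.touch_voltage,
        mode=scen.mode.value,
        i_body=cur.value,
        z_total=total_impedance(scen.touch_voltage, cur.value),
        e99_heart=e99_heart(solution),
        e_sam=sam_field(solution),
        plane_spread=cur.spread,
        residual=solution.residual,
    )


@dataclass(frozen=True)
class HCFTable:
    """Heart-current factors on the path x frequency grid.

    The reference-path row is 1.0 at every frequency exactly by construction
    (each column is divided by its reference entry).
    """

    frame: pd.DataFrame          # index: path labels, columns: frequencies
    statistic: str               # "F99" | "FSAM"
    reference_path: str = REFERENCE_PATH

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="path")


def hcf(doses: Iterable[DoseReport], statistic: str = "F99") -> HCFTable:
    """Heart current factors from per-scenario dose reports.

    ``statistic``: "F99" uses the myocardium 99th-percentile field, "FSAM" the
    trans-cardiac line-integral estimate.  The reference path LH-BF must be
    present at every frequency.
    """
    statistic = statistic.upper()
    if statistic not in ("F99", "FSAM"):
        raise ValueError(f"statistic must be F99 or FSAM, got {statistic!r}")
    rows = {}
    for d in doses:
        e = d.e99_heart if statistic == "F99" else d.e_sam
        rows[(d.path_label, d.frequency)] = e / abs(d.i_body)
    paths = sorted({p for p, _ in rows}, key=str)
    freqs = sorted({f for _, f in rows})
    for f in freqs:
        if (REFERENCE_PATH, f) not in rows:
            raise ValueError(
                f"reference path {REFERENCE_PATH} missing at {f} Hz; cannot normalise")
    data = {}
    for f in freqs:
        ref = rows[(REFERENCE_PATH, f)]
        data[f] = [rows[(p, f)] / ref if (p, f) in rows else np.nan for p in paths]
    frame = pd.DataFrame(data, index=paths)
    # put the reference path first, mirroring the usual table layout
    order = [REFERENCE_PATH] + [p for p in paths if p != REFERENCE_PATH]
    frame = frame.loc[[p for p in order if p in frame.index]]
    return HCFTable(frame=frame, statistic=statistic)
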