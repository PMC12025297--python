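"""Complete-electrode-model FEM forward solver.

First-order (linear triangle) finite elements with the complete electrode
model: each electrode is a boundary arc with a finite contact impedance, the
injected current is specified per electrode and the electrode potentials are
extra unknowns.  One recording frame drives each of the 16 opposite
electrode pairs in turn with 1 mA and reads the 12 adjacent-pair voltages
per drive, giving the 192-channel frame defined by the channel map.

The weak form assembled here is the standard one: for potentials u (nodal)
and U (electrode), with contact impedance z_l on electrode arc e_l,

    [K + A_z   -A_w] [u]   [0]
    [-A_w^T     A_d] [U] = [I]

where K is the sigma-weighted stiffness matrix, A_z, A_w, A_d are the
boundary mass integrals over the electrode arcs divided by z_l, and I is the
vector of injected electrode currents (summing to zero).  The floating
potential level is fixed by grounding one interior node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .datamodel import VoltageMatrix, build_channel_map
from .mesh import PhantomSpec

__all__ = ["FEMModel", "forward_frame", "forward_voltages", "measurement_jacobian"]

#: contact impedance in model units (Ohm * length); 100 Ohm*cm^2 on a
#: unit-radius 2-D section.
DEFAULT_CONTACT_IMPEDANCE = 0.01


@dataclass
class FEMModel:
    """Precomputed geometry factors for repeated solves on one phantom."""

    phantom: PhantomSpec
    z_contact: float
    rows: np.ndarray       # COO pattern of the stiffness matrix
    cols: np.ndarray
    kdata: np.ndarray      # per-entry unit-conductivity stiffness values
    entry_elem: np.ndarray  # element owning each COO entry
    bmat: sp.csr_matrix    # electrode-coupling block, fixed
    grad: np.ndarray       # (M, 2, 3) shape-function gradients per element
    areas: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.phantom.nodes.shape[0]

    @property
    def n_elec(self) -> int:
        return self.phantom.n_electrodes


def build_fem(phantom: PhantomSpec, z_contact: float = DEFAULT_CONTACT_IMPEDANCE) -> FEMModel:
    nodes = phantom.nodes
    elems = phantom.elements
    n = nodes.shape[0]
    ne = phantom.n_electrodes

    p = nodes[elems]                      # (M, 3, 2)
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    areas = 0.5 * np.abs(det)
    # gradients of the three linear shape functions on each triangle
    grad = np.empty((elems.shape[0], 2, 3))
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        grad[:, 0, i] = (p[:, j, 1] - p[:, k, 1]) / det
        grad[:, 1, i] = (p[:, k, 0] - p[:, j, 0]) / det

    # unit-sigma local stiffness: area * grad_i . grad_j
    local = np.einsum("mdi,mdj->mij", grad, grad) * areas[:, None, None]
    rows = np.repeat(elems, 3, axis=1).reshape(-1)          # i index
    cols = np.tile(elems, (1, 3)).reshape(-1)               # j index
    kdata = local.transpose(0, 2, 1).reshape(-1)            # matches repeat/tile order
    entry_elem = np.repeat(np.arange(elems.shape[0]), 9)

    # electrode blocks: boundary-arc integrals / z
    az = sp.lil_matrix((n, n))
    aw = sp.lil_matrix((n, ne))
    ad = np.zeros(ne)
    for l, edges in enumerate(phantom.electrode_edges):
        for a, b in edges:
            le = float(np.linalg.norm(nodes[a] - nodes[b]))
            az[a, a] += le / 3.0 / z_contact
            az[b, b] += le / 3.0 / z_contact
            az[a, b] += le / 6.0 / z_contact
            az[b, a] += le / 6.0 / z_contact
            aw[a, l] += le / 2.0 / z_contact
            aw[b, l] += le / 2.0 / z_contact
            ad[l] += le / z_contact
    bmat = sp.bmat(
        [[az.tocsr(), -aw.tocsr()], [-aw.T.tocsr(), sp.diags(ad)]]
    ).tocsr()

    return FEMModel(
        phantom=phantom, z_contact=z_contact, rows=rows, cols=cols,
        kdata=kdata, entry_elem=entry_elem, bmat=bmat, grad=grad, areas=areas,
    )


def _system(model: FEMModel, sigma: np.ndarray) -> sp.csc_matrix:
    n, ne = model.n_nodes, model.n_elec
    kvals = model.kdata * sigma[model.entry_elem]
    k = sp.coo_matrix((kvals, (model.rows, model.cols)), shape=(n, n)).tocsr()
    full = sp.bmat([[k, None], [None, sp.csr_matrix((ne, ne))]]).tocsr() + model.bmat
    # ground node 0 to remove the constant-potential nullspace
    full = full.tolil()
    full[0, :] = 0.0
    full[:, 0] = 0.0
    full[0, 0] = 1.0
    return full.tocsc()


def solve_patterns(
    model: FEMModel, sigma: np.ndarray, currents: np.ndarray
) -> np.ndarray:
    """Solve the CEM system for several current patterns.

    currents : (n_patterns, n_elec) injected current per electrode, each row
        summing to zero.
    Returns the electrode potentials, shape (n_patterns, n_elec).
    """
    n, ne = model.n_nodes, model.n_elec
    a = _system(model, sigma)
    lu = spla.splu(a)
    rhs = np.zeros((n + ne, currents.shape[0]))
    rhs[n:, :] = currents.T
    sol = lu.solve(rhs)
    return sol[n:, :].T


def solve_fields(
    model: FEMModel, sigma: np.ndarray, currents: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`solve_patterns` but also returns nodal potentials
    (n_patterns, n_nodes) for Jacobian assembly."""
    n, ne = model.n_nodes, model.n_elec
    a = _system(model, sigma)
    lu = spla.splu(a)
    rhs = np.zeros((n + ne, currents.shape[0]))
    rhs[n:, :] = currents.T
    sol = lu.solve(rhs)
    return sol[:n, :].T, sol[n:, :].T


def drive_currents(n_elec: int = 16, current: float = 1e-3) -> np.ndarray:
    """Opposite-pair drive patterns: +I at electrode k, -I at k + n/2."""
    pat = np.zeros((n_elec, n_elec))
    for k in range(n_elec):
        pat[k, k] = current
        pat[k, (k + n_elec // 2) % n_elec] = -current
    return pat


def frame_from_potentials(
    potentials: np.ndarray, n_elec: int = 16, signed: bool = False
) -> np.ndarray:
    """Assemble the 192-channel frame from per-drive electrode potentials
    following the package channel-ordering convention.

    Channels are demodulated voltage *amplitudes* ``|U_c - U_d|`` by default,
    matching what clinical acquisition systems record (the signed pair
    differences sum to zero around the ring and are never reported)."""
    cmap = build_channel_map(n_elec)
    out = np.empty(len(cmap))
    for e in cmap.entries:
        drive_idx = e.drive[0]
        c, d = e.measure
        out[e.channel] = potentials[drive_idx, c] - potentials[drive_idx, d]
    return out if signed else np.abs(out)


def forward_frame(
    model: FEMModel, sigma: np.ndarray, current_mA: float = 1.0,
    signed: bool = False,
) -> np.ndarray:
    u = solve_patterns(model, sigma, drive_currents(model.n_elec, current_mA * 1e-3))
    return frame_from_potentials(u, model.n_elec, signed=signed)


def forward_voltages(
    phantom: PhantomSpec,
    breathing,
    lung2_scale: float = 0.15,
    current_mA: float = 1.0,
    z_contact: float = DEFAULT_CONTACT_IMPEDANCE,
) -> VoltageMatrix:
    """Simulate a breathing recording.

    For frame t the "area 1" lung regions take conductivity ``w[t]`` and the
    "area 2" regions ``lung2_scale * w[t]`` (non-lung tissue stays at the
    phantom background, 1 S/m); the CEM forward problem is solved and the
    192-channel frame assembled.  Since the waveform is periodic, frames with
    an identical modulation value reuse one solve.

    Parameters
    ----------
    breathing : BreathingWaveform
        Normalised conductivity modulation in (0, 1].
    """
    w = np.asarray(breathing.values, dtype=float)
    model = build_fem(phantom, z_contact)
    cache: dict[float, np.ndarray] = {}
    frames = np.empty((192, w.size))
    for t, wt in enumerate(w):
        key = round(float(wt), 12)
        if key not in cache:
            sigma = phantom.conductivity_vector(wt, lung2_scale * wt)
            cache[key] = forward_frame(model, sigma, current_mA)
        frames[:, t] = cache[key]
    return VoltageMatrix(data=frames, frame_rate=breathing.frame_rate)


def measurement_jacobian(
    model: FEMModel, sigma: np.ndarray, current: float = 1e-3
) -> np.ndarray:
    """Sensitivity of each of the 192 channel voltages to each element's
    conductivity, by the adjoint method.

    For drive field u_d (actual drive current) and measurement field w_m
    (unit current through the measurement pair),

        d v_ch / d sigma_e = - integral_e  grad(u_d) . grad(w_m)  dA,

    sign-corrected per channel so the sensitivity refers to the recorded
    voltage *amplitude* ``|v_ch|`` (see :func:`frame_from_potentials`).
    """
    n_elec = model.n_elec
    drv = drive_currents(n_elec, current)
    meas = np.zeros((n_elec, n_elec))
    for c in range(n_elec):
        meas[c, c] = 1.0
        meas[c, (c + 1) % n_elec] = -1.0
    u_nodes, _ = solve_fields(model, sigma, drv)
    w_nodes, _ = solve_fields(model, sigma, meas)

    elems = model.phantom.elements
    # per-element constant gradients of every field: (patterns, M, 2)
    gu = np.einsum("pmk,mdk->pmd", u_nodes[:, elems], model.grad)
    gw = np.einsum("pmk,mdk->pmd", w_nodes[:, elems], model.grad)

    cmap = build_channel_map(n_elec)
    jac = np.empty((len(cmap), elems.shape[0]))
    for e in cmap.entries:
        d = e.drive[0]
        m = e.measure[0]
        jac[e.channel] = -np.einsum("md,md->m", gu[d], gw[m]) * model.areas
    baseline = forward_frame(model, sigma, current_mA=current / 1e-3, signed=True)
    return np.sign(baseline)[:, None] * jac
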