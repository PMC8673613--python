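"""Multi-compartment myelinated axon cable model under extracellular stimulation.

The fiber follows the standard myelinated-axon architecture for mammalian
motor/projection axons: excitable nodes of Ranvier carrying fast Na+,
persistent Na+, slow K+ and leak channels, separated by passive myelinated
internodes (MYSA attachment, FLUT paranode, STIN segments).  The myelin sheath
and internodal axolemma are combined in series into a single-cable RC wall,
which preserves the internodal space constant while keeping the state small.

Extracellular coupling uses the standard activating-function form: the static
potentials Ve interpolated at compartment centers are scaled by the stimulus
waveform and enter the cable equation through the axial difference operator,

    C dV/dt = A (V + Ve(t)) - I_ion(V),

where A is the tridiagonal axial-conductance operator.  A constant Ve along
the fiber therefore produces no drive; only its second spatial difference
excites the membrane.  Integration is semi-implicit Crank-Nicolson with
exponential (staggered) gate updates.

Units: geometry um/mm, membrane mV, ms, uF, mS, uA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
from scipy.linalg import solve_banded

from .config import FiberSpec, StimulusWaveform

COMP_NODE, COMP_MYSA, COMP_FLUT, COMP_STIN = 0, 1, 2, 3
_COMP_NAMES = {COMP_NODE: "node", COMP_MYSA: "mysa", COMP_FLUT: "flut", COMP_STIN: "stin"}


class PlacementError(ValueError):
    """A compartment lies outside the conductive tissue (inside the lead body)."""


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# morphology


@dataclass
class AxonInstance:
    """A straight axon: compartment geometry plus (optionally) attached
    static extracellular potentials at a reference stimulus current."""

    fiber: FiberSpec
    coords: np.ndarray          # (n, 3) mm, compartment centers
    comp_type: np.ndarray       # (n,) int
    lengths_um: np.ndarray      # (n,)
    diameters_um: np.ndarray    # (n,)
    ve_static_mV: Optional[np.ndarray] = None   # (n,), at i_ref_mA
    i_ref_mA: float = -1.0

    @property
    def n_comp(self) -> int:
        return len(self.coords)

    @property
    def node_index(self) -> np.ndarray:
        return np.nonzero(self.comp_type == COMP_NODE)[0]

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.coords[0] + self.coords[-1])


def build_axon(fiber: FiberSpec, start_point, direction, length_mm: float) -> AxonInstance:
    """Place a straight axon of ``fiber.n_nodes`` nodes from start_point along
    ``direction``; ``length_mm`` must span the full node chain."""
    start = np.asarray(start_point, dtype=float)
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / nd
    span_mm = (fiber.n_nodes - 1) * fiber.internode_length * 1e-3
    if length_mm <= 0:
        raise ValueError("axon length must be positive")
    if length_mm + 1e-9 < span_mm:
        raise ValueError(
            f"length {length_mm:.2f} mm cannot span {fiber.n_nodes} nodes at "
            f"{fiber.internode_length} um spacing ({span_mm:.2f} mm needed)"
        )

    stin_len = (fiber.internode_length - fiber.node_length
                - 2 * fiber.mysa_length - 2 * fiber.flut_length) / fiber.n_stin
    seq_types = ([COMP_MYSA, COMP_FLUT] + [COMP_STIN] * fiber.n_stin + [COMP_FLUT, COMP_MYSA])
    seq_lens = ([fiber.mysa_length, fiber.flut_length] + [stin_len] * fiber.n_stin
                + [fiber.flut_length, fiber.mysa_length])

    types: list[int] = []
    lens: list[float] = []
    for i in range(fiber.n_nodes):
        types.append(COMP_NODE)
        lens.append(fiber.node_length)
        if i < fiber.n_nodes - 1:
            types.extend(seq_types)
            lens.extend(seq_lens)
    lens_arr = np.array(lens)
    types_arr = np.array(types, dtype=np.int8)
    # compartment centers along the line, in mm
    edges = np.concatenate([[0.0], np.cumsum(lens_arr)]) * 1e-3
    centers = 0.5 * (edges[:-1] + edges[1:])
    coords = start[None, :] + centers[:, None] * d[None, :]

    diam = np.where(
        (types_arr == COMP_NODE) | (types_arr == COMP_MYSA),
        fiber.node_diameter, fiber.internode_diameter,
    ).astype(float)
    return AxonInstance(fiber=fiber, coords=coords, comp_type=types_arr,
                        lengths_um=lens_arr, diameters_um=diam)


def attach_field(axon: AxonInstance,
                 field_source: Union[Callable[[np.ndarray], np.ndarray], object],
                 i_ref_mA: float = -1.0) -> AxonInstance:
    """Interpolate extracellular potentials at compartment centers.

    ``field_source`` is either a callable points -> potentials (V) or an object
    with ``interpolate`` (FieldSolution / HomogeneousSolution).  Compartments
    inside the lead body or outside the meshed tissue raise PlacementError.
    """
    pts = axon.coords
    if callable(field_source):
        v = np.asarray(field_source(pts), dtype=float)
    else:
        mesh = getattr(field_source, "mesh", None)
        if mesh is not None:
            from .geometry import REGION_BRAIN, REGION_ENCAPSULATION

            tet_idx, _ = mesh.locate(pts)
            if np.any(tet_idx < 0):
                raise PlacementError("axon compartments lie outside the meshed tissue")
            reg = mesh.region[tet_idx]
            if not np.all((reg == REGION_BRAIN) | (reg == REGION_ENCAPSULATION)):
                raise PlacementError("axon compartments lie inside the lead body")
        v = np.asarray(field_source.interpolate(pts), dtype=float)
    if not np.all(np.isfinite(v)):
        raise PlacementError("non-finite extracellular potentials along the axon")
    return replace(axon, ve_static_mV=v * 1e3, i_ref_mA=i_ref_mA)


# ---------------------------------------------------------------------------
# membrane dynamics


def _gate_rates(V: np.ndarray) -> dict:
    """Opening/closing rates (1/ms) of m, h, p, s at node potential V (mV)."""
    def vtrap(x, y):
        # x / (exp(x/y) - 1), stable near x = 0; exp overflow in the far tail
        # correctly limits the rate to 0
        return np.where(np.abs(x / y) < 1e-6, y * (1 - x / y / 2),
                        x / np.expm1(np.clip(x / y, -700, 700)))

    with np.errstate(over="ignore", invalid="ignore"):
        am = 6.57 * vtrap(-(V + 20.4), 10.3)
        bm = 0.304 * vtrap(V + 25.7, 9.16)
        ah = 0.34 * vtrap(V + 114.0, 11.0)
        bh = 12.6 / (1.0 + np.exp(np.clip(-(V + 31.8) / 13.4, -700, 700)))
        ap = 0.0353 * vtrap(-(V + 27.0), 10.2)
        bp = 0.000883 * vtrap(V + 34.0, 10.0)
        a_s = 0.3 / (1.0 + np.exp(np.clip(-(V + 53.0) / 5.0, -700, 700)))
        b_s = 0.03 / (1.0 + np.exp(np.clip(-(V + 90.0) / 1.0, -700, 700)))
    return dict(m=(am, bm), h=(ah, bh), p=(ap, bp), s=(a_s, b_s))


@dataclass
class _Cable:
    """Precomputed electrical structure of one axon."""

    c_uF: np.ndarray            # (n,) membrane capacitance
    g_ax_mS: np.ndarray         # (n-1,) axial conductances between neighbors
    g_pas_mS: np.ndarray        # (n,) passive wall conductance (internodes; leak at nodes
                                # is handled with the active channels)
    node_idx: np.ndarray
    g_node_mS: dict             # absolute channel conductances per node: naf, nap, ks, lk
    e_leak_eff: float           # leak reversal balancing the node at rest (mV)
    v_rest: float


def _build_cable(axon: AxonInstance) -> _Cable:
    fib = axon.fiber
    L_cm = axon.lengths_um * 1e-4
    d_cm = axon.diameters_um * 1e-4
    area = np.pi * d_cm * L_cm                       # cm^2

    is_node = axon.comp_type == COMP_NODE
    c_myelin = fib.c_myelin_lamella / (2.0 * fib.n_lamellae)
    c_wall = fib.c_membrane * c_myelin / (fib.c_membrane + c_myelin)
    g_myelin = fib.g_myelin_lamella / (2.0 * fib.n_lamellae)
    g_wall = fib.g_internode_passive * g_myelin / (fib.g_internode_passive + g_myelin)

    c_uF = np.where(is_node, fib.c_membrane, c_wall) * area
    g_pas = np.where(is_node, 0.0, g_wall) * area * 1e3          # mS

    # axial conductances: half-compartment resistances in series
    r_half = fib.rho_axial * (L_cm / 2.0) / (np.pi * d_cm ** 2 / 4.0)   # Ohm
    g_ax = 1e3 / (r_half[:-1] + r_half[1:])                             # mS

    node_idx = np.nonzero(is_node)[0]
    a_node = area[node_idx]
    g_node = dict(
        naf=fib.g_naf * a_node * 1e3, nap=fib.g_nap * a_node * 1e3,
        ks=fib.g_ks * a_node * 1e3, lk=fib.g_leak * a_node * 1e3,
    )
    # steady-state gates at rest; shift the leak reversal so the node sits at
    # exactly v_rest with no stimulus
    V0 = fib.v_rest
    r = _gate_rates(np.array([V0]))
    m0 = r["m"][0] / (r["m"][0] + r["m"][1])
    h0 = r["h"][0] / (r["h"][0] + r["h"][1])
    p0 = r["p"][0] / (r["p"][0] + r["p"][1])
    s0 = r["s"][0] / (r["s"][0] + r["s"][1])
    i_other = (fib.g_naf * m0 ** 3 * h0 * (V0 - fib.e_na)
               + fib.g_nap * p0 ** 3 * (V0 - fib.e_na)
               + fib.g_ks * s0 * (V0 - fib.e_k))          # per cm^2, scalar
    e_leak_eff = float(V0 + np.asarray(i_other).ravel()[0] / fib.g_leak)
    return _Cable(c_uF=c_uF, g_ax_mS=g_ax, g_pas_mS=g_pas, node_idx=node_idx,
                  g_node_mS=g_node, e_leak_eff=e_leak_eff, v_rest=fib.v_rest)


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimResult:
    """Membrane response of one axon to one stimulus amplitude."""

    t_ms: np.ndarray
    detector_traces: np.ndarray     # (2, T) mV at the two detector nodes
    detector_nodes: tuple[int, int]
    activated: bool
    spike_times_ms: tuple[Optional[float], Optional[float]]
    v_peak_mV: float
    node_spike_times_ms: Optional[np.ndarray] = None   # (n_nodes,) NaN if no spike
    conduction_velocity_m_s: Optional[float] = None


def detect_propagation(traces: np.ndarray, t_ms: np.ndarray, onset_ms: float,
                       level_mV: float = 0.0) -> bool:
    """True iff the membrane potential crosses ``level_mV`` after stimulus onset
    at BOTH detector nodes (an AP that propagated through the axon)."""
    after = t_ms >= onset_ms
    return bool(np.all(np.any(traces[:, after] >= level_mV, axis=1)))


def simulate(axon: AxonInstance, waveform: StimulusWaveform,
             dt_ms: float = 0.002, detector_offset: int = 2,
             early_stop: bool = True) -> SimResult:
    """Integrate the cable equation for one stimulus pulse.

    The extracellular drive is ``waveform(t) * (amplitude / i_ref) * Ve_static``
    applied through the axial operator; detectors sit at the ``detector_offset``-th
    node from each end (default 2nd, avoiding end-node boundary artifacts).
    """
    if axon.ve_static_mV is None:
        raise ValueError("attach_field must be called before simulate")
    cab = _build_cable(axon)
    n = axon.n_comp
    fib = axon.fiber
    nt = int(round(waveform.total_time_ms / dt_ms))
    scale = waveform.amplitude_mA / axon.i_ref_mA
    ve = axon.ve_static_mV * scale
    onset = waveform.onset_delay_us * 1e-3
    t_off = onset + waveform.pulse_width_us * 1e-3

    node_idx = cab.node_idx
    det = (node_idx[detector_offset], node_idx[len(node_idx) - 1 - detector_offset])

    # banded Laplacian L = -A (positive semidefinite): ab[0]=super, ab[1]=diag, ab[2]=sub
    gax = cab.g_ax_mS
    Ldiag = np.zeros(n)
    Ldiag[:-1] += gax
    Ldiag[1:] += gax
    Loff = -gax

    V = np.full(n, fib.v_rest)
    r0 = _gate_rates(V[node_idx])
    gates = {k: a / (a + b) for k, (a, b) in r0.items()}

    gna, gnap, gks, glk = (cab.g_node_mS[k] for k in ("naf", "nap", "ks", "lk"))
    traces = np.empty((2, nt + 1))
    traces[:, 0] = V[list(det)]
    t_arr = np.arange(nt + 1) * dt_ms
    crossed = [None, None]
    node_spikes = np.full(len(node_idx), np.nan)
    v_peak = float(V.max())
    half = 0.5

    def applyL(x):
        y = Ldiag * x
        y[:-1] += Loff * x[1:]
        y[1:] += Loff * x[:-1]
        return y

    ab = np.zeros((3, n))
    steps_done = nt
    for it in range(1, nt + 1):
        t_mid = (it - half) * dt_ms
        # staggered exponential gate update at the current node potentials
        rates = _gate_rates(V[node_idx])
        for k, (a, b) in rates.items():
            tau = 1.0 / (a + b)
            inf = a * tau
            gates[k] = inf + (gates[k] - inf) * np.exp(-dt_ms / tau)

        g_ion = np.array(cab.g_pas_mS)
        ge = cab.g_pas_mS * cab.v_rest
        g_na_tot = gna * gates["m"] ** 3 * gates["h"]
        g_nap_tot = gnap * gates["p"] ** 3
        g_ks_tot = gks * gates["s"]
        g_node_sum = g_na_tot + g_nap_tot + g_ks_tot + glk
        e_node = (g_na_tot * fib.e_na + g_nap_tot * fib.e_na + g_ks_tot * fib.e_k
                  + glk * cab.e_leak_eff)
        g_ion[node_idx] += g_node_sum
        ge_full = ge.copy()
        ge_full[node_idx] += e_node

        ve_t = ve * waveform.value(t_mid)
        cdt = cab.c_uF / dt_ms
        rhs = cdt * V - half * applyL(V) - half * g_ion * V + ge_full - applyL(ve_t)
        ab[0, 1:] = half * Loff
        ab[1] = cdt + half * Ldiag + half * g_ion
        ab[2, :-1] = half * Loff
        V = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(V)):
            raise IntegrationError(f"cable integration diverged at dt={dt_ms} ms")

        traces[:, it] = V[list(det)]
        v_peak = max(v_peak, float(V.max()))
        t_now = it * dt_ms
        if t_now >= onset:
            new = np.isnan(node_spikes) & (V[node_idx] >= 0.0)
            node_spikes[new] = t_now
        for j in range(2):
            if crossed[j] is None and t_now >= onset and traces[j, it] >= 0.0:
                crossed[j] = t_now
        if early_stop:
            if crossed[0] is not None and crossed[1] is not None:
                steps_done = it
                break
            if t_now > t_off + 0.5 and np.max(np.abs(V - fib.v_rest)) < 1.0:
                steps_done = it
                break

    traces = traces[:, :steps_done + 1]
    t_arr = t_arr[:steps_done + 1]
    activated = detect_propagation(traces, t_arr, onset)
    velocity = None
    if activated:
        # conduction estimate: regress node spike time on distance along one limb
        # (initiation is usually at the center for perpendicular axons)
        first = int(np.nanargmin(node_spikes))
        side = node_spikes[first:]
        ok = ~np.isnan(side)
        if ok.sum() >= 3 and np.ptp(side[ok]) > dt_ms:
            dist = np.arange(len(side)) * axon.fiber.internode_length * 1e-3  # mm
            slope = np.polyfit(side[ok], dist[ok], 1)[0]                      # mm/ms
            if slope > 0:
                velocity = float(slope)  # mm/ms == m/s
    return SimResult(t_ms=t_arr, detector_traces=traces, detector_nodes=det,
                     activated=activated,
                     spike_times_ms=(crossed[0], crossed[1]),
                     v_peak_mV=v_peak, node_spike_times_ms=node_spikes,
                     conduction_velocity_m_s=velocity)


def simulate_batch(axons: list, waveform: StimulusWaveform, amplitudes_mA: np.ndarray,
                   dt_ms: float = 0.002, detector_offset: int = 2,
                   early_stop: bool = True) -> np.ndarray:
    """Activation decisions for many axons of the SAME fiber spec at once.

    Each axon b is driven by ``waveform`` at its own amplitude
    ``amplitudes_mA[b]``.  The tridiagonal systems are solved with a Thomas
    sweep vectorized over the batch, which makes population threshold searches
    roughly batch-size times faster than per-axon simulation.  Returns a
    boolean array: AP detected at both detector nodes.
    """
    if not axons:
        return np.zeros(0, dtype=bool)
    fib = axons[0].fiber
    for ax in axons[1:]:
        if ax.fiber != fib or ax.n_comp != axons[0].n_comp:
            raise ValueError("batched simulation requires identical fiber specs")
    if any(ax.ve_static_mV is None for ax in axons):
        raise ValueError("attach_field must be called on every axon")

    cab = _build_cable(axons[0])
    n = axons[0].n_comp
    B = len(axons)
    amplitudes = np.asarray(amplitudes_mA, dtype=float)
    ve = np.stack([ax.ve_static_mV * (amplitudes[b] / ax.i_ref_mA)
                   for b, ax in enumerate(axons)])            # (B, n)
    node_idx = cab.node_idx
    det = (node_idx[detector_offset], node_idx[len(node_idx) - 1 - detector_offset])
    onset = waveform.onset_delay_us * 1e-3
    t_off = onset + waveform.pulse_width_us * 1e-3
    nt = int(round(waveform.total_time_ms / dt_ms))

    gax = cab.g_ax_mS
    Ldiag = np.zeros(n)
    Ldiag[:-1] += gax
    Ldiag[1:] += gax
    Loff = -gax                                            # sub == super
    cdt = cab.c_uF / dt_ms
    half = 0.5

    V = np.full((B, n), fib.v_rest)
    r0 = _gate_rates(V[:, node_idx])
    gates = {k: a / (a + b) for k, (a, b) in r0.items()}
    gna, gnap, gks, glk = (cab.g_node_mS[k] for k in ("naf", "nap", "ks", "lk"))

    crossed = np.zeros((B, 2), dtype=bool)
    decided = np.zeros(B, dtype=bool)
    sup = half * Loff                                      # constant off-diagonals
    for it in range(1, nt + 1):
        t_mid = (it - half) * dt_ms
        rates = _gate_rates(V[:, node_idx])
        for k, (a, b) in rates.items():
            tau = 1.0 / (a + b)
            inf = a * tau
            gates[k] = inf + (gates[k] - inf) * np.exp(-dt_ms / tau)

        g_ion = np.broadcast_to(cab.g_pas_mS, (B, n)).copy()
        ge_full = cab.g_pas_mS * cab.v_rest + np.zeros((B, n))
        g_na_tot = gna * gates["m"] ** 3 * gates["h"]
        g_nap_tot = gnap * gates["p"] ** 3
        g_ks_tot = gks * gates["s"]
        g_ion[:, node_idx] += g_na_tot + g_nap_tot + g_ks_tot + glk
        ge_full[:, node_idx] += (g_na_tot * fib.e_na + g_nap_tot * fib.e_na
                                 + g_ks_tot * fib.e_k + glk * cab.e_leak_eff)

        w = waveform.value(t_mid)
        rhs = cdt * V - half * _applyL_batch(Ldiag, Loff, V) - half * g_ion * V + ge_full
        if w:
            rhs -= _applyL_batch(Ldiag, Loff, ve)
        diag = cdt + half * Ldiag + half * g_ion           # (B, n)
        V = _thomas_batch(sup, diag, rhs)
        if not np.all(np.isfinite(V)):
            raise IntegrationError(f"batched cable integration diverged at dt={dt_ms} ms")

        t_now = it * dt_ms
        if t_now >= onset:
            crossed[:, 0] |= V[:, det[0]] >= 0.0
            crossed[:, 1] |= V[:, det[1]] >= 0.0
        if early_stop:
            done = crossed.all(axis=1)
            if t_now > t_off + 0.5:
                quiet = np.max(np.abs(V - fib.v_rest), axis=1) < 1.0
                done = done | quiet
            decided |= done
            if decided.all():
                break
    return crossed.all(axis=1)


def _applyL_batch(Ldiag: np.ndarray, Loff: np.ndarray, X: np.ndarray) -> np.ndarray:
    Y = Ldiag * X
    Y[..., :-1] += Loff * X[..., 1:]
    Y[..., 1:] += Loff * X[..., :-1]
    return Y


def _thomas_batch(off: np.ndarray, diag: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve symmetric tridiagonal systems with constant off-diagonals ``off``
    ((n-1,)) and batched diagonals/rhs ((B, n)), one Thomas sweep per column."""
    B, n = rhs.shape
    w = np.empty((B, n - 1))
    g = np.empty((B, n))
    w[:, 0] = off[0] / diag[:, 0]
    g[:, 0] = rhs[:, 0] / diag[:, 0]
    for i in range(1, n - 1):
        denom = diag[:, i] - off[i - 1] * w[:, i - 1]
        w[:, i] = off[i] / denom
        g[:, i] = (rhs[:, i] - off[i - 1] * g[:, i - 1]) / denom
    denom = diag[:, n - 1] - off[n - 2] * w[:, n - 2]
    g[:, n - 1] = (rhs[:, n - 1] - off[n - 2] * g[:, n - 2]) / denom
    x = np.empty_like(g)
    x[:, n - 1] = g[:, n - 1]
    for i in range(n - 2, -1, -1):
        x[:, i] = g[:, i] - w[:, i] * x[:, i + 1]
    return x


# ---------------------------------------------------------------------------
# CSV I/O


def export_axon_csv(axon: AxonInstance, path: str | Path) -> None:
    """Write compartment morphology + attached potentials as CSV."""
    import pandas as pd

    df = pd.DataFrame({
        "index": np.arange(axon.n_comp),
        "x_mm": axon.coords[:, 0], "y_mm": axon.coords[:, 1], "z_mm": axon.coords[:, 2],
        "type": [_COMP_NAMES[int(t)] for t in axon.comp_type],
        "length_um": axon.lengths_um, "diameter_um": axon.diameters_um,
        "ve_static_mV": (axon.ve_static_mV if axon.ve_static_mV is not None
                         else np.full(axon.n_comp, np.nan)),
    })
    df.to_csv(path, index=False)


def import_axon_csv(path: str | Path, fiber: FiberSpec) -> AxonInstance:
    """Rebuild an AxonInstance from an exported CSV (inverse of export_axon_csv)."""
    import pandas as pd

    df = pd.read_csv(path)
    name_to_code = {v: k for k, v in _COMP_NAMES.items()}
    ve = df["ve_static_mV"].to_numpy()
    return AxonInstance(
        fiber=fiber,
        coords=df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        comp_type=np.array([name_to_code[t] for t in df["type"]], dtype=np.int8),
        lengths_um=df["length_um"].to_numpy(),
        diameters_um=df["diameter_um"].to_numpy(),
        ve_static_mV=None if np.all(np.isnan(ve)) else ve,
    )
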