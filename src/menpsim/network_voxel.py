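"""Layered cortical voxel: network construction, spiking surrogate, bursts.

The modeled tissue is a 200 x 200 um column spanning cortical layers II,
III and IV (150/350/200 um deep, 700 um total) with the reported
excitatory:inhibitory counts per layer (895:95, 988:188, 970:170).
Connectivity follows the stated rules: excitatory cells connect to all cell
classes with probability 0.1 and weight 25 * y_norm (y_norm = depth / 700 um
from the top of layer II); inhibitory cells connect only to excitatory cells
with distance-dependent probability 0.4 * exp(-d / 150 um) and weight 5.

Membrane dynamics are a leaky integrate-and-fire surrogate with
bi-exponential conductance synapses using the stated kinetics (tau values in
seconds as reported; a ``tau_units`` flag reinterprets them as ms).  Because
second-scale synaptic kinetics cannot by themselves produce fast population
bursts inside a 140 ms window, the default external drive supplies a shared
rectified slow oscillation with random phase — a stand-in for common
afferent up-state volleys — plus a shared Ornstein-Uhlenbeck modulation and
independent membrane noise; amplitudes were chosen once so the default
configuration fires at ~5-20 Hz with distinct burst epochs, and
spike-frequency adaptation terminates each burst.

Axes: x and z span the column (0..200 um); y is cortical depth (0 at the
top of layer II, 700 um at the bottom of layer IV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .neuro_fields import FieldGrid, MagnetizationField, biphasic_waveform

__all__ = [
    "LayerSpec",
    "SynapseParams",
    "DriveParams",
    "Network",
    "SpikeRaster",
    "VoxelSignal",
    "DEFAULT_LAYERS",
    "DEFAULT_EXC_SYNAPSE",
    "DEFAULT_INH_SYNAPSE",
    "grid_sites",
    "build_network",
    "simulate_network",
    "detect_bursts",
    "population_rate",
    "cell_source_currents",
    "network_potential",
    "voxel_signal",
]

COLUMN_XZ_UM = 200.0
TOTAL_DEPTH_UM = 700.0


@dataclass
class LayerSpec:
    """One cortical layer slab: thickness and cell counts."""

    name: str
    thickness_um: float
    n_excitatory: int
    n_inhibitory: int

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("layer thickness must be positive")
        if self.n_excitatory < 0 or self.n_inhibitory < 0:
            raise ValueError("cell counts must be non-negative")


DEFAULT_LAYERS = (
    LayerSpec("II", 150.0, 895, 95),
    LayerSpec("III", 350.0, 988, 188),
    LayerSpec("IV", 200.0, 970, 170),
)


@dataclass
class SynapseParams:
    """Bi-exponential synapse: rise tau1, decay tau2, reversal potential.

    tau values are stored as reported; ``tau_units`` ('s' or 'ms') sets how
    they are interpreted by the simulator.
    """

    tau1: float
    tau2: float
    v_rev_mV: float
    tau_units: str = "s"

    def __post_init__(self) -> None:
        if not 0 < self.tau1 < self.tau2:
            raise ValueError("require 0 < tau1 < tau2")
        if self.tau_units not in ("s", "ms"):
            raise ValueError("tau_units must be 's' or 'ms'")

    def taus_ms(self) -> tuple[float, float]:
        f = 1e3 if self.tau_units == "s" else 1.0
        return self.tau1 * f, self.tau2 * f


DEFAULT_EXC_SYNAPSE = SynapseParams(tau1=0.8, tau2=5.3, v_rev_mV=0.0)
DEFAULT_INH_SYNAPSE = SynapseParams(tau1=0.6, tau2=8.5, v_rev_mV=-75.0)


@dataclass
class DriveParams:
    """External drive: shared slow rhythm, OU modulation, membrane noise.

    The shared component emulates common afferent input: a rectified slow
    oscillation (``osc_amp_mV`` at ``osc_period_ms``, random phase per run)
    modeling up-state volleys, plus a zero-mean Ornstein-Uhlenbeck process
    (``common_amp_mV``, time constant ``common_tau_ms``), both injected
    identically into every cell.  ``noise_sigma_mV`` is per-cell independent
    voltage noise (SD per sqrt(ms)); ``mean_mV`` a constant bias.  Defaults
    were tuned once to yield distinct burst epochs at a few to ~20 Hz.
    """

    mean_mV: float = 0.0
    osc_amp_mV: float = 35.0
    osc_period_ms: float = 35.0
    common_amp_mV: float = 2.0
    common_tau_ms: float = 6.0
    noise_sigma_mV: float = 1.0


@dataclass
class Network:
    """Cell positions, classes and synaptic weight matrices.

    ``w_exc`` and ``w_inh`` are CSR matrices indexed [post, pre]; weights
    follow the connectivity rules (dimensionless couplings scaled by the
    simulator's ``g_scale``).
    """

    positions: np.ndarray  # (n, 3) um; y = depth
    is_excitatory: np.ndarray  # bool
    layer: np.ndarray  # str labels
    w_exc: sparse.csr_matrix
    w_inh: sparse.csr_matrix
    seed: int

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def y_norm(self) -> np.ndarray:
        return self.positions[:, 1] / TOTAL_DEPTH_UM


@dataclass
class SpikeRaster:
    """Spike times per cell, with class and layer labels."""

    cell: np.ndarray  # spike -> cell index
    time_ms: np.ndarray  # sorted
    n_cells: int
    duration_ms: float
    is_excitatory: np.ndarray
    layer: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.time_ms, kind="stable")
        self.time_ms = np.asarray(self.time_ms, float)[order]
        self.cell = np.asarray(self.cell, int)[order]

    @property
    def n_spikes(self) -> int:
        return len(self.time_ms)

    def mean_rate_hz(self, excitatory: Optional[bool] = None) -> float:
        if excitatory is None:
            mask = np.ones(self.n_spikes, bool)
            n = self.n_cells
        else:
            mask = self.is_excitatory[self.cell] == excitatory
            n = int((self.is_excitatory == excitatory).sum())
        if n == 0:
            return 0.0
        return float(mask.sum()) / n / (self.duration_ms * 1e-3)

    def to_text(self, path: str) -> None:
        np.savetxt(
            path,
            np.column_stack([self.cell, self.time_ms]),
            header="cell_id time_ms",
            fmt=["%d", "%.6f"],
        )


def grid_sites(dims_um: Sequence[float], spacing_um: float) -> np.ndarray:
    """Inclusive recording lattice over a box: (dim/spacing + 1) planes/axis.

    A 200 x 700 x 200 um^3 voxel at 5 um spacing yields 41 x 141 x 41 =
    237,021 sites.  Dimensions must be integer multiples of the spacing.
    """
    grid = FieldGrid.from_dims(dims_um, spacing_um, times_ms=np.array([0.0]))
    return grid.sites


def build_network(
    layers: Sequence[LayerSpec] = DEFAULT_LAYERS,
    seed: int = 0,
    p_exc: float = 0.1,
    exc_weight_scale: float = 25.0,
    p_inh_max: float = 0.4,
    inh_lambda_um: float = 150.0,
    inh_weight: float = 5.0,
) -> Network:
    """Place cells in layer slabs and draw synapses by the stated rules."""
    rng = np.random.default_rng(seed)
    positions, is_exc, labels = [], [], []
    y0 = 0.0
    for spec in layers:
        n = spec.n_excitatory + spec.n_inhibitory
        if n == 0:
            raise ValueError(f"layer {spec.name} has no cells")
        xyz = np.column_stack([
            rng.uniform(0.0, COLUMN_XZ_UM, n),
            rng.uniform(y0, y0 + spec.thickness_um, n),
            rng.uniform(0.0, COLUMN_XZ_UM, n),
        ])
        positions.append(xyz)
        is_exc.append(np.r_[np.ones(spec.n_excitatory, bool),
                            np.zeros(spec.n_inhibitory, bool)])
        labels.extend([spec.name] * n)
        y0 += spec.thickness_um
    positions = np.vstack(positions)
    is_exc = np.concatenate(is_exc)
    labels = np.array(labels)
    n = len(positions)
    y_norm = positions[:, 1] / TOTAL_DEPTH_UM

    exc_idx = np.flatnonzero(is_exc)
    inh_idx = np.flatnonzero(~is_exc)

    # E -> (E, I): Bernoulli p_exc, weight scaled by presynaptic depth.
    conn = rng.random((n, len(exc_idx))) < p_exc
    conn[exc_idx, np.arange(len(exc_idx))] = False  # no autapses
    post, pre_col = np.nonzero(conn)
    pre = exc_idx[pre_col]
    w_exc = sparse.csr_matrix(
        (exc_weight_scale * y_norm[pre], (post, pre)), shape=(n, n)
    )

    # I -> E only, with exponentially distance-dependent probability.
    d = np.linalg.norm(
        positions[exc_idx][:, None, :] - positions[inh_idx][None, :, :], axis=2
    )
    conn_i = rng.random(d.shape) < p_inh_max * np.exp(-d / inh_lambda_um)
    post_e, pre_col = np.nonzero(conn_i)
    w_inh = sparse.csr_matrix(
        (np.full(len(post_e), inh_weight),
         (exc_idx[post_e], inh_idx[pre_col])),
        shape=(n, n),
    )
    return Network(
        positions=positions, is_excitatory=is_exc, layer=labels,
        w_exc=w_exc, w_inh=w_inh, seed=seed,
    )


def _biexp_norm(tau1_ms: float, tau2_ms: float) -> float:
    """Normalization so a unit increment yields a unit-peak conductance."""
    t_pk = np.log(tau2_ms / tau1_ms) * tau1_ms * tau2_ms / (tau2_ms - tau1_ms)
    return 1.0 / (np.exp(-t_pk / tau2_ms) - np.exp(-t_pk / tau1_ms))


def simulate_network(
    net: Network,
    duration_ms: float = 140.0,
    dt_ms: float = 0.1,
    drive: Optional[DriveParams] = None,
    seed: int = 0,
    exc_synapse: SynapseParams = DEFAULT_EXC_SYNAPSE,
    inh_synapse: SynapseParams = DEFAULT_INH_SYNAPSE,
    g_scale: float = 1e-4,
    tau_m_ms: float = 20.0,
    v_rest_mV: float = -65.0,
    v_thresh_mV: float = -50.0,
    v_reset_mV: float = -65.0,
    refractory_ms: float = 3.0,
    adapt_increment_mV: float = 10.0,
    adapt_tau_ms: float = 15.0,
    rate_ceiling_hz: float = 200.0,
) -> SpikeRaster:
    """Leaky integrate-and-fire surrogate dynamics on the column network.

    Conductance-based synapses g * (E_rev - V) with bi-exponential gating;
    synaptic weights enter as g_scale * weight (dimensionless, relative to
    the leak).  A subtractive spike-frequency-adaptation current
    (``adapt_increment_mV`` per spike, decaying with ``adapt_tau_ms``)
    terminates population bursts, which the second-scale synaptic decay
    cannot do within the simulated window.  Deterministic for a fixed seed.
    Aborts with a diagnostic if the population rate exceeds
    ``rate_ceiling_hz`` (runaway excitation).
    """
    if dt_ms > 1.0:
        raise ValueError("dt_ms must be <= 1 ms")
    drive = drive or DriveParams()
    rng = np.random.default_rng(seed)
    n = net.n_cells
    n_steps = int(round(duration_ms / dt_ms))

    t1e, t2e = exc_synapse.taus_ms()
    t1i, t2i = inh_synapse.taus_ms()
    dec = [np.exp(-dt_ms / tau) for tau in (t2e, t1e, t2i, t1i)]
    norm_e, norm_i = _biexp_norm(t1e, t2e), _biexp_norm(t1i, t2i)

    V = np.full(n, v_rest_mV) + rng.uniform(-5.0, 5.0, n)
    ae = np.zeros(n); be = np.zeros(n)
    ai = np.zeros(n); bi = np.zeros(n)
    # Adaptation starts at a randomized partially-recovered level, as if the
    # network had been running before the window; otherwise the first burst
    # (from a fully rested population) dwarfs the later ones.
    adapt = adapt_increment_mV * rng.uniform(0.0, 1.0, n)
    adapt_decay = np.exp(-dt_ms / adapt_tau_ms)
    refr = np.zeros(n)
    ou = float(rng.standard_normal())
    ou_decay = np.exp(-dt_ms / drive.common_tau_ms)
    ou_sigma = np.sqrt(1.0 - ou_decay**2)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    spike_cells, spike_times = [], []
    sq = np.sqrt(dt_ms)
    for step in range(n_steps):
        t = step * dt_ms
        ou = ou * ou_decay + ou_sigma * rng.standard_normal()
        ge = g_scale * norm_e * (ae - be)
        gi = g_scale * norm_i * (ai - bi)
        osc = max(np.sin(2.0 * np.pi * t / drive.osc_period_ms + phase), 0.0)
        I = (
            drive.mean_mV
            + drive.osc_amp_mV * osc
            + drive.common_amp_mV * ou
            + ge * (exc_synapse.v_rev_mV - V)
            + gi * (inh_synapse.v_rev_mV - V)
            - adapt
        )
        noise = drive.noise_sigma_mV * sq * rng.standard_normal(n)
        dV = (-(V - v_rest_mV) + I) * (dt_ms / tau_m_ms)
        active = refr <= 0.0
        V = np.where(active, V + dV + noise, V)
        refr = np.maximum(refr - dt_ms, 0.0)

        fired = active & (V >= v_thresh_mV)
        if np.any(fired):
            idx = np.flatnonzero(fired)
            spike_cells.append(idx)
            spike_times.append(np.full(len(idx), t))
            V[idx] = v_reset_mV
            refr[idx] = refractory_ms
            adapt[idx] += adapt_increment_mV
            svec = np.zeros(n)
            svec[idx] = 1.0
            inc_e = net.w_exc @ svec
            inc_i = net.w_inh @ svec
            ae += inc_e; be += inc_e
            ai += inc_i; bi += inc_i
        ae *= dec[0]; be *= dec[1]
        ai *= dec[2]; bi *= dec[3]
        adapt *= adapt_decay

    cells = np.concatenate(spike_cells) if spike_cells else np.array([], int)
    times = np.concatenate(spike_times) if spike_times else np.array([], float)
    raster = SpikeRaster(
        cell=cells, time_ms=times, n_cells=n, duration_ms=duration_ms,
        is_excitatory=net.is_excitatory, layer=net.layer,
    )
    mean_rate = raster.mean_rate_hz()
    if mean_rate > rate_ceiling_hz:
        raise RuntimeError(
            f"unstable parameters: population rate {mean_rate:.1f} Hz exceeds "
            f"the {rate_ceiling_hz:.0f} Hz ceiling"
        )
    return raster


def population_rate(
    raster: SpikeRaster, bin_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Population firing rate (Hz per cell) in fixed bins; returns (t, rate)."""
    edges = np.arange(0.0, raster.duration_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(raster.time_ms, bins=edges)
    rate = counts / raster.n_cells / (bin_ms * 1e-3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def detect_bursts(
    raster: SpikeRaster,
    bin_ms: float = 1.0,
    smooth_sigma_ms: float = 2.0,
    n_sd: float = 2.0,
    min_ratio: float = 2.0,
    min_separation_ms: float = 10.0,
) -> np.ndarray:
    """Burst peak times: smoothed population-rate peaks above mean + n_sd * SD.

    A peak must additionally exceed ``min_ratio`` times the mean rate — a
    burst is a multiplicative elevation of population activity, which keeps
    ordinary fluctuations of a featureless (Poisson-like) raster from being
    flagged.  Peaks closer than ``min_separation_ms`` are merged into the
    higher one.  Returns times in ms (empty for an empty raster).
    """
    if raster.n_spikes == 0:
        return np.array([])
    t, rate = population_rate(raster, bin_ms)
    smooth = gaussian_filter1d(rate, smooth_sigma_ms / bin_ms)
    thresh = max(smooth.mean() + n_sd * smooth.std(), min_ratio * smooth.mean())
    peaks, _ = find_peaks(
        smooth, height=thresh, distance=max(int(min_separation_ms / bin_ms), 1)
    )
    return t[peaks]


def cell_source_currents(
    raster: SpikeRaster,
    net: Network,
    times_ms: np.ndarray,
    amplitude_nA: float = 1.0,
    dipole_len_um: float = 100.0,
    width_ms: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Map point-neuron spikes to balanced current dipoles for the field solver.

    Each cell is a two-pole source: a biphasic spike current at the soma and
    its exact negative at a return pole ``dipole_len_um`` deeper along the
    cortical depth axis, so every cell is charge-balanced at every instant.
    Returns (source_positions (2n, 3) um, currents (2n, n_t) nA).
    """
    times_ms = np.asarray(times_ms, float)
    n = net.n_cells
    I_cell = np.zeros((n, len(times_ms)))
    support = 8.0 * width_ms
    for c, ts in zip(raster.cell, raster.time_ms):
        rel = times_ms - ts
        mask = (rel >= 0.0) & (rel <= support)
        if np.any(mask):
            I_cell[c, mask] += amplitude_nA * biphasic_waveform(rel[mask], width_ms)
    pos = np.vstack([net.positions,
                     net.positions + np.array([0.0, dipole_len_um, 0.0])])
    currents = np.vstack([I_cell, -I_cell])
    return pos, currents


def network_potential(
    net: Network,
    raster: SpikeRaster,
    grid: FieldGrid,
    sigma_ext: float = 0.3,
    amplitude_nA: float = 1.0,
    dipole_len_um: float = 100.0,
    min_distance_um: float = 2.5,
) -> FieldGrid:
    """Extracellular potential of the spiking column on the recording lattice.

    Point-source superposition of all cell dipole poles; distances are
    clamped to ``min_distance_um`` (half the default lattice spacing) to
    keep sites that coincide with a source finite.  Populates ``grid.phi``
    (mV) and returns the grid.
    """
    pos, I = cell_source_currents(
        raster, net, grid.times_ms, amplitude_nA, dipole_len_um
    )
    sites = grid.sites
    phi = np.zeros((len(sites), len(grid.times_ms)))
    # Block over sources to bound the distance-matrix memory footprint.
    block = 512
    for i in range(0, len(pos), block):
        d = np.linalg.norm(sites[:, None, :] - pos[None, i:i + block, :], axis=2)
        d = np.maximum(d, min_distance_um)
        phi += (1.0 / (4.0 * np.pi * sigma_ext * d)) @ I[i:i + block]
    grid.phi = phi
    grid.sigma_ext = sigma_ext
    return grid


@dataclass
class VoxelSignal:
    """Mean +- SD magnetization trace over the voxel, with a 2-D histogram.

    Amplitudes in uA/m.  The histogram covers the linear regime [-1, 1] mA/m
    with 1 ms x 5 uA/m bins; each column sums to the site count.
    """

    time_ms: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    hist: np.ndarray
    time_edges_ms: np.ndarray
    amp_edges_uA_per_m: np.ndarray
    site_traces: Optional[np.ndarray] = None

    def to_text(self, path: str) -> None:
        np.savetxt(
            path,
            np.column_stack([self.time_ms, self.mean, self.sd]),
            header="time_ms mean_uA_per_m sd_uA_per_m",
        )


def voxel_signal(
    mag_field: MagnetizationField,
    time_bin_ms: float = 1.0,
    amp_bin_uA: float = 5.0,
    amp_range_uA: float = 1000.0,
    keep_site_traces: int = 0,
) -> VoxelSignal:
    """Collapse a magnetization field to its voxel-mean signal.

    Per-time mean and SD over sites (uA/m), plus the 2-D site-count
    histogram.  ``keep_site_traces`` optionally retains that many per-site
    traces ordered by distance from the voxel center (nearest first).
    """
    dm = mag_field.dm
    if dm.size == 0:
        raise ValueError("magnetization field is empty")
    dm_u = dm * 1e6  # A/m -> uA/m
    t = mag_field.grid.times_ms
    mean = dm_u.mean(axis=0)
    sd = dm_u.std(axis=0)
    t_edges = np.arange(t[0], t[-1] + 2 * time_bin_ms, time_bin_ms)
    a_edges = np.arange(-amp_range_uA, amp_range_uA + amp_bin_uA, amp_bin_uA)
    tt = np.broadcast_to(t, dm_u.shape).ravel()
    clipped = np.clip(dm_u.ravel(), -amp_range_uA, amp_range_uA - 1e-12)
    hist, _, _ = np.histogram2d(tt, clipped, bins=[t_edges, a_edges])
    traces = None
    if keep_site_traces:
        sites = mag_field.grid.sites
        center = sites.mean(axis=0)
        order = np.argsort(np.linalg.norm(sites - center, axis=1))
        traces = dm_u[order[:keep_site_traces]]
    return VoxelSignal(
        time_ms=t, mean=mean, sd=sd, hist=hist,
        time_edges_ms=t_edges, amp_edges_uA_per_m=a_edges,
        site_traces=traces,
    )
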