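"""2D monodomain solver on atrial tissue sheets with the modified
Courtemanche ionic model.

Each atrium is a flat square sheet (a stand-in for the 3D bilayer surface,
working directly on the unfolded-coordinate grid) with per-node conductivity,
conducting mask, and ionic-conductance multipliers derived from the fibrosis
map.  The solver integrates

    dV/dt = div( sigma / chi * grad V ) - I_ion / C_m + I_stim

with a 5-point Laplacian, no-flux boundaries (non-conducting nodes carry no
flux), operator splitting (explicit diffusion, Rush-Larsen reaction), and a
configurable set of interatrial bridge couplings.  ``chi`` is the single free
surface-to-volume x capacitance product, calibrated once so that planar CV at
0.40 S/m equals 0.81 m/s on a reference 1D strand (:func:`calibrate_chi`).

AF episodes are initiated by seeding Archimedean spiral-wave phase fields
mapped onto a precomputed single-cell limit cycle; sustainability uses the
"electrical activity over at least 60% of the episode" rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import courtemanche as crn
from .remodeling import (AF_REMODELING_SCALING, BASELINE_SCALING, IonicScaling,
                         conductivity_from_iir, ionic_scaling_fields)

#: Calibrated surface-to-volume x capacitance product (S*ms/(m*mm^2)); the
#: value such that planar CV at 0.40 S/m is 0.81 m/s on the reference strand
#: (see calibrate_chi; recomputed from scratch by the acceptance script).
DEFAULT_CHI = 2.283

#: AF-remodeled bulk scaling (no fibrotic layer) used for CV calibration.
CV_CAL_SCALING = BASELINE_SCALING.compose(AF_REMODELING_SCALING)

ACTIVATION_THRESHOLD_MV = -40.0


class SimulationInstabilityError(RuntimeError):
    pass


class ConductionBlockError(RuntimeError):
    pass


@dataclass
class TissueParams:
    """Per-node tissue description on one sheet."""

    conductivity: np.ndarray        # S/m
    conducting: np.ndarray          # bool
    scaling: dict[str, np.ndarray]  # multiplier field per scaled conductance


@dataclass
class TissueSheet:
    """One atrium as a 2D lattice (default: map grid upsampled x2, 0.5 mm)."""

    name: str
    params: TissueParams
    spacing_mm: float = 0.5

    @property
    def shape(self) -> tuple[int, int]:
        return self.params.conducting.shape

    @classmethod
    def from_fibrosis_map(cls, fmap, name: str = "LA", upsample: int = 2,
                          spacing_mm: float = 0.5, af_remodeling: bool = True,
                          ablation_mask: np.ndarray | None = None) -> "TissueSheet":
        values = fmap.values if hasattr(fmap, "values") else np.asarray(fmap, float)
        iir = np.kron(values, np.ones((upsample, upsample)))
        conducting = np.ones(iir.shape, dtype=bool)
        if ablation_mask is not None:
            mask = np.kron(np.asarray(ablation_mask, bool),
                           np.ones((upsample, upsample))).astype(bool)
            conducting &= ~mask
        params = TissueParams(
            conductivity=conductivity_from_iir(iir),
            conducting=conducting,
            scaling=ionic_scaling_fields(iir, af_remodeling),
        )
        return cls(name, params, spacing_mm)


@dataclass
class Bridge:
    """Point coupling between two sheets (interatrial connection)."""

    node_a: tuple[int, int, int]  # (sheet index, row, col)
    node_b: tuple[int, int, int]
    conductivity: float = 0.40    # S/m


def default_bridges(shapes: list[tuple[int, int]]) -> list[Bridge]:
    """Three bridges joining the LA right edge to the RA left edge."""
    if len(shapes) < 2:
        return []
    (ny0, nx0), (ny1, nx1) = shapes[0], shapes[1]
    out = []
    for fy in (0.25, 0.5, 0.75):
        out.append(Bridge((0, int(fy * ny0), nx0 - 1), (1, int(fy * ny1), 0)))
    return out


@dataclass
class Stimulus:
    """Rectangular-pulse current stimulus on a node subset (pA/pF)."""

    masks: list[np.ndarray]
    t_start_ms: float
    duration_ms: float
    amplitude: float = 40.0
    period_ms: float | None = None  # repeat period for pacing trains

    def active(self, t_ms: float) -> bool:
        if self.period_ms:
            t_ms = t_ms % self.period_ms
        return self.t_start_ms <= t_ms < self.t_start_ms + self.duration_ms


@dataclass
class SimulationResult:
    """Voltage recordings and activation summaries for a multi-sheet run."""

    voltages: list[np.ndarray]       # per sheet: (frames, ny, nx) float32
    last_activation: list[np.ndarray]  # per sheet: (ny, nx), NaN = never
    conducting: list[np.ndarray]
    duration_ms: float
    dt_ms: float
    downsample_ms: float
    sheet_names: list[str]
    final_state: list[np.ndarray] | None = None  # per sheet (21, ny, nx)

    @property
    def n_frames(self) -> int:
        return self.voltages[0].shape[0]

    def to_hdf5(self, path, **attrs) -> None:
        with h5py.File(path, "w") as f:
            f.attrs.update({"duration_ms": self.duration_ms, "dt_ms": self.dt_ms,
                            "downsample_ms": self.downsample_ms, **attrs})
            for i, name in enumerate(self.sheet_names):
                g = f.create_group(name)
                g.create_dataset("voltage", data=self.voltages[i],
                                 compression="gzip")
                g.create_dataset("last_activation", data=self.last_activation[i])
                g.create_dataset("conducting", data=self.conducting[i])
                if self.final_state is not None:
                    g.create_dataset("final_state", data=self.final_state[i])

    @classmethod
    def from_hdf5(cls, path) -> "SimulationResult":
        with h5py.File(path, "r") as f:
            names = list(f.keys())
            volts, last, cond, final = [], [], [], []
            has_final = all("final_state" in f[n] for n in names)
            for n in names:
                volts.append(f[n]["voltage"][...])
                last.append(f[n]["last_activation"][...])
                cond.append(f[n]["conducting"][...].astype(bool))
                if has_final:
                    final.append(f[n]["final_state"][...])
            return cls(volts, last, cond, float(f.attrs["duration_ms"]),
                       float(f.attrs["dt_ms"]), float(f.attrs["downsample_ms"]),
                       names, final if has_final else None)


# ---------------------------------------------------------------------------
# Core integration
# ---------------------------------------------------------------------------

def _masked_laplacian(V: np.ndarray, D: np.ndarray, cond: np.ndarray,
                      h: float) -> np.ndarray:
    """5-point flux-form Laplacian; flux only between conducting neighbors."""
    out = np.zeros_like(V)
    inv_h2 = 1.0 / (h * h)
    pairs = (((slice(1, None), slice(None)), (slice(None, -1), slice(None))),
             ((slice(None), slice(1, None)), (slice(None), slice(None, -1))))
    for a, b in pairs:
        valid = cond[a] & cond[b]
        davg = 0.5 * (D[a] + D[b])
        flux = np.where(valid, davg * (V[b] - V[a]) * inv_h2, 0.0)
        out[a] += flux
        out[b] -= flux
    return out


def run_monodomain(
    sheets: list[TissueSheet],
    duration_ms: float,
    dt_ms: float = 0.02,
    diffusion_dt_ms: float = 0.1,
    init_states: list[np.ndarray] | None = None,
    stimuli: list[Stimulus] | None = None,
    bridges: list[Bridge] | None = None,
    chi: float = DEFAULT_CHI,
    downsample_ms: float = 1.0,
    frozen_reaction: bool = False,
    keep_final_state: bool = True,
) -> SimulationResult:
    """Integrate the coupled sheets; deterministic for fixed inputs.

    ``init_states`` are (21, ny, nx) per sheet (default: resting).
    ``frozen_reaction`` switches I_ion off (pure diffusion; used by
    conservation tests).  Raises :class:`SimulationInstabilityError` naming
    the first offending step if the state leaves physical bounds.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    shapes = [s.shape for s in sheets]
    sizes = [ny * nx for ny, nx in shapes]
    offs = np.cumsum([0] + sizes)
    n_total = offs[-1]

    state = np.empty((crn.N_STATES, n_total))
    for i, sheet in enumerate(sheets):
        if init_states is None:
            state[:, offs[i]:offs[i + 1]] = crn.INITIAL_STATE[:, None]
        else:
            state[:, offs[i]:offs[i + 1]] = init_states[i].reshape(crn.N_STATES, -1)

    mult = {k: np.concatenate([s.params.scaling[k].ravel() for s in sheets])
            for k in ("g_Na", "g_K1", "g_to", "g_Kur", "g_CaL")}
    conds = [s.params.conducting for s in sheets]
    Ds = [s.params.conductivity / chi for s in sheets]
    cond_flat = np.concatenate([c.ravel() for c in conds])

    bridges = default_bridges(shapes) if bridges is None else bridges
    h = sheets[0].spacing_mm

    diffusion_every = max(1, int(round(diffusion_dt_ms / dt_ms)))
    n_steps = int(round(duration_ms / dt_ms))
    frame_every = max(1, int(round(downsample_ms / dt_ms)))
    n_frames = n_steps // frame_every + 1

    volts = [np.empty((n_frames, ny, nx), dtype=np.float32) for ny, nx in shapes]
    last_act = np.full(n_total, np.nan)
    prev_V = state[0].copy()

    stim_masks = []
    for stim in stimuli or []:
        flat = np.concatenate([m.ravel() for m in stim.masks]).astype(float)
        stim_masks.append(flat * cond_flat)  # no stimulus into ablated tissue

    frame = 0
    for i, (ny, nx) in enumerate(shapes):
        volts[i][0] = state[0, offs[i]:offs[i + 1]].reshape(ny, nx)
    frame = 1

    for step in range(n_steps):
        t = step * dt_ms
        istim = np.zeros(n_total)
        for stim, mask in zip(stimuli or [], stim_masks):
            if stim.active(t):
                istim += stim.amplitude * mask
        if not frozen_reaction:
            crn.step_rush_larsen_fast(state, dt_ms, mult["g_Na"], mult["g_K1"],
                                      mult["g_to"], mult["g_Kur"],
                                      mult["g_CaL"], istim)
        elif np.any(istim):
            state[0] += dt_ms * istim

        if (step + 1) % diffusion_every == 0:
            dtd = diffusion_every * dt_ms
            V = state[0]
            dV = np.empty_like(V)
            for i, (ny, nx) in enumerate(shapes):
                Vi = V[offs[i]:offs[i + 1]].reshape(ny, nx)
                dV[offs[i]:offs[i + 1]] = _masked_laplacian(
                    Vi, Ds[i], conds[i], h).ravel()
            for br in bridges:
                (sa, ya, xa), (sb, yb, xb) = br.node_a, br.node_b
                ia = offs[sa] + ya * shapes[sa][1] + xa
                ib = offs[sb] + yb * shapes[sb][1] + xb
                if cond_flat[ia] and cond_flat[ib]:
                    f = (br.conductivity / chi) * (V[ib] - V[ia]) / (h * h)
                    dV[ia] += f
                    dV[ib] -= f
            V += dtd * dV * cond_flat

        # upstroke detection at reaction resolution
        crossed = (prev_V < ACTIVATION_THRESHOLD_MV) & \
                  (state[0] >= ACTIVATION_THRESHOLD_MV) & cond_flat
        last_act[crossed] = t + dt_ms
        prev_V = state[0].copy()

        if (step + 1) % frame_every == 0 and frame < n_frames:
            V = state[0]
            if not np.all(np.isfinite(V)) or np.max(np.abs(V)) > 200.0:
                bad = int(np.argmax(~np.isfinite(V) | (np.abs(V) > 200.0)))
                raise SimulationInstabilityError(
                    f"instability at step {step + 1} (t={t + dt_ms:.3f} ms), "
                    f"node {bad}: V={V[bad]!r}")
            for i, (ny, nx) in enumerate(shapes):
                volts[i][frame] = V[offs[i]:offs[i + 1]].reshape(ny, nx)
            frame += 1

    final = None
    if keep_final_state:
        final = [state[:, offs[i]:offs[i + 1]].reshape(crn.N_STATES, ny, nx)
                 for i, (ny, nx) in enumerate(shapes)]
    return SimulationResult(
        voltages=volts,
        last_activation=[last_act[offs[i]:offs[i + 1]].reshape(ny, nx)
                         for i, (ny, nx) in enumerate(shapes)],
        conducting=conds,
        duration_ms=duration_ms,
        dt_ms=dt_ms,
        downsample_ms=downsample_ms,
        sheet_names=[s.name for s in sheets],
        final_state=final,
    )


# ---------------------------------------------------------------------------
# Conduction velocity on a 1D reference strand
# ---------------------------------------------------------------------------

def measure_cv(
    conductivity_s_per_m: float,
    scaling: IonicScaling = CV_CAL_SCALING,
    n_nodes: int = 100,
    spacing_mm: float = 0.25,
    chi: float = DEFAULT_CHI,
    dt_ms: float = 0.02,
    max_time_ms: float = 200.0,
) -> float:
    """Planar CV (m/s) on a 1D strand from two interior activation times.

    A stimulus at one end launches a wave; activation (upstroke through
    -40 mV) is timed at probes 20 nodes from each boundary.  EP fibrotic
    remodeling is excluded by default: the printed CV targets are
    structural-remodeling calibrations.
    """
    D = conductivity_s_per_m / chi  # mm^2/ms
    state = crn.initial_state(n_nodes)
    one = np.ones(n_nodes)
    mults = (scaling.g_Na * one, scaling.g_K1 * one, scaling.g_to * one,
             scaling.g_Kur * one, scaling.g_CaL * one)
    p0, p1 = 30, n_nodes - 30
    act = np.full(n_nodes, np.nan)
    prev = state[0].copy()
    inv_h2 = 1.0 / spacing_mm ** 2
    n_steps = int(max_time_ms / dt_ms)
    for step in range(n_steps):
        t = step * dt_ms
        istim = np.zeros(n_nodes)
        if t < 2.0:
            istim[:3] = 60.0
        crn.step_rush_larsen_fast(state, dt_ms, *mults, istim)
        V = state[0]
        lap = np.zeros(n_nodes)
        lap[1:] += D * (V[:-1] - V[1:]) * inv_h2
        lap[:-1] += D * (V[1:] - V[:-1]) * inv_h2
        V += dt_ms * lap
        crossed = (prev < ACTIVATION_THRESHOLD_MV) & (V >= ACTIVATION_THRESHOLD_MV)
        newly = crossed & np.isnan(act)
        act[newly] = t + dt_ms
        prev = V.copy()
        if not math.isnan(act[p1]):
            break
    if math.isnan(act[p0]) or math.isnan(act[p1]) or act[p1] <= act[p0]:
        raise ConductionBlockError(
            f"wave failed to propagate at sigma={conductivity_s_per_m} S/m")
    dist_mm = (p1 - p0) * spacing_mm
    return dist_mm / (act[p1] - act[p0])  # mm/ms == m/s


def calibrate_chi(
    anchor_sigma: float = 0.40,
    anchor_cv: float = 0.81,
    chi0: float = 2.0,
    tol: float = 1e-3,
    max_iter: int = 6,
    **cv_kwargs,
) -> float:
    """Find chi so CV(anchor_sigma) = anchor_cv, exploiting CV ~ sqrt(D)."""
    chi = chi0
    for _ in range(max_iter):
        cv = measure_cv(anchor_sigma, chi=chi, **cv_kwargs)
        if abs(cv - anchor_cv) / anchor_cv < tol:
            break
        chi *= (cv / anchor_cv) ** 2
    return chi


# ---------------------------------------------------------------------------
# Spiral-wave initiation
# ---------------------------------------------------------------------------

def limit_cycle_trajectory(
    scaling: IonicScaling = CV_CAL_SCALING,
    cycle_length_ms: float = 300.0,
    sample_ms: float = 1.0,
    dt_ms: float = 0.02,
) -> np.ndarray:
    """One action-potential cycle of the single cell, (21, n_samples).

    The cell is paced twice at the cycle length; the second beat (from its
    upstroke) is sampled and used as the phase -> state lookup for spiral
    initiation: phase -pi maps to the upstroke, +pi to the end of the cycle.
    """
    n_steps = int(round(2.5 * cycle_length_ms / dt_ms))
    state = crn.initial_state(1)
    one = np.ones(1)
    mults = (scaling.g_Na * one, scaling.g_K1 * one, scaling.g_to * one,
             scaling.g_Kur * one, scaling.g_CaL * one)
    record_every = max(1, int(round(sample_ms / dt_ms)))
    traj = []
    for step in range(n_steps):
        t = step * dt_ms
        phase_t = t % cycle_length_ms
        istim = one * (40.0 if (phase_t < 2.0 and t < 2 * cycle_length_ms) else 0.0)
        crn.step_rush_larsen_fast(state, dt_ms, *mults, istim)
        if step % record_every == 0:
            traj.append(state[:, 0].copy())
    traj = np.array(traj).T  # (21, n)
    start = int(round(cycle_length_ms / sample_ms))
    stop = start + int(round(cycle_length_ms / sample_ms))
    return traj[:, start:stop]


def initiate_spirals(
    sheets: list[TissueSheet],
    n_spirals: int = 4,
    seed: int = 0,
    k_rad_per_px: float | None = None,
    trajectory: np.ndarray | None = None,
    cores: list[list[tuple[float, float]]] | None = None,
) -> list[np.ndarray]:
    """Archimedean-spiral initial states, (21, ny, nx) per sheet.

    Each node gets a phase phi = atan2(y-yc, x-xc) - k*r relative to its
    nearest core, mapped onto a precomputed single-cell limit cycle.  Cores
    are placed seeded-uniform in the sheet interior, split as evenly as
    possible across sheets (4 spirals -> 2 per atrium).
    """
    if n_spirals < 1:
        raise ValueError("n_spirals must be >= 1")
    rng = np.random.default_rng(seed)
    k = k_rad_per_px if k_rad_per_px is not None else 2.0 * math.pi / 40.0
    traj = trajectory if trajectory is not None else limit_cycle_trajectory()
    n_samples = traj.shape[1]

    per_sheet = [n_spirals // len(sheets)] * len(sheets)
    for i in range(n_spirals % len(sheets)):
        per_sheet[i] += 1

    states = []
    for si, sheet in enumerate(sheets):
        ny, nx = sheet.shape
        if cores is not None:
            sheet_cores = cores[si]
            for cy, cx in sheet_cores:
                if not (0 <= cy < ny and 0 <= cx < nx):
                    raise ValueError("spiral core outside the grid")
        else:
            sheet_cores = [
                (rng.uniform(0.2 * ny, 0.8 * ny), rng.uniform(0.2 * nx, 0.8 * nx))
                for _ in range(per_sheet[si])
            ]
        if sheet_cores:
            phi = spiral_phase_field((ny, nx), sheet_cores, k)
            idx = np.clip(((phi + math.pi) / (2 * math.pi) * (n_samples - 1))
                          .astype(int), 0, n_samples - 1)
        else:
            idx = np.zeros((ny, nx), dtype=int)
        states.append(traj[:, idx.ravel()].reshape(crn.N_STATES, ny, nx))
    return states


def spiral_phase_field(shape: tuple[int, int],
                       cores: list[tuple[float, float]],
                       k_rad_per_px: float = 2.0 * math.pi / 40.0) -> np.ndarray:
    """Archimedean multi-spiral phase field in (-pi, pi].

    Per-core phases (angle minus k*radius) are summed with alternating
    chirality before wrapping: the sum is smooth away from the cores, so the
    field contains exactly one +-1 singularity per core (a nearest-core
    patchwork would add spurious seam singularities)."""
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx]
    phi = np.zeros((ny, nx))
    for ci, (cy, cx) in enumerate(cores):
        chirality = 1.0 if ci % 2 == 0 else -1.0
        phi += chirality * np.arctan2(y - cy, x - cx) \
            - k_rad_per_px * np.hypot(y - cy, x - cx)
    return np.angle(np.exp(1j * phi))


def is_sustained(result: SimulationResult, fraction: float = 0.6) -> bool:
    """True iff the latest upstroke over all conducting nodes occurs at or
    after ``fraction`` of the episode duration."""
    if result.duration_ms <= 0:
        raise ValueError("zero-duration result")
    latest = -np.inf
    for la, cond in zip(result.last_activation, result.conducting):
        vals = la[cond & np.isfinite(la)]
        if vals.size:
            latest = max(latest, float(vals.max()))
    if not np.isfinite(latest):
        return False
    return latest >= fraction * result.duration_ms
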