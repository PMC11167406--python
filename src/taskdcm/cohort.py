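"""Forward simulation of synthetic task-fMRI cohorts.

Ground truth for each subject is a bilinear neural-mass model

    dz/dt = (A + sum_k u_k(t) B_k) z + C u(t)

whose states are passed through a balloon-Windkessel hemodynamic model and
rendered into multi-voxel ROI clouds with confounds and measurement noise.
The same integrator (`simulate_bold`) is the generative model used by the
model-inversion code, so simulation and inversion share one code path.

Self-connections are parameterized on a log scale: the diagonal entries of
the A matrix store unitless scalings a_ii and the effective self-coupling is
-0.5 * exp(a_ii) Hz, which keeps every sampled subject's uncoupled dynamics
stable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import StimulusSet
from .rois import ROITemplate, DRIVING_NODES
from ._integrator import HAVE_NUMBA as _HAVE_FAST
from ._integrator import integrate_batched as _integrate_batched


class DivergenceError(RuntimeError):
    """Neural or hemodynamic integration produced a non-finite state."""


@dataclass(frozen=True)
class DCMParameters:
    """Bilinear model parameters.

    ``A`` is n x n; its off-diagonal entries are couplings in Hz while the
    diagonal stores log-scalings of the -0.5 Hz self-decay.  ``B`` is
    (k, n, n) modulatory couplings (Hz), ``C`` is (n, m) driving weights.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.A, float)
        B = np.atleast_3d(np.asarray(self.B, float))
        C = np.asarray(self.C, float)
        if C.ndim == 1:
            C = C[:, None]
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B if B.shape[-1] == A.shape[0] else B)
        object.__setattr__(self, "C", C)
        n = A.shape[0]
        if A.shape != (n, n) or self.B.shape[1:] != (n, n) or C.shape[0] != n:
            raise ValueError("A, B, C dimensions are inconsistent")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]

    def effective_A(self) -> np.ndarray:
        """A with the self-connection transform applied to the diagonal."""
        return effective_A(self.A)


def effective_A(A: np.ndarray) -> np.ndarray:
    """Map stored A (log-scaled diagonal) to the dynamical coupling matrix."""
    A = np.asarray(A, float)
    out = A.copy()
    idx = np.arange(A.shape[-1])
    out[..., idx, idx] = -0.5 * np.exp(A[..., idx, idx])
    return out


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel constants (widely used defaults).

    kappa: vasodilatory signal decay (1/s); gamma: flow autoregulation
    (1/s); tau: venous transit time (s); alpha: vessel stiffness exponent;
    e0: resting oxygen extraction; v0: resting venous volume fraction;
    k1-k3: BOLD read-out gains; epsilon: regional read-out gain ratio.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    v0: float = 0.04
    k1: float | None = None  # defaults to 7 * e0
    k2: float = 2.0
    k3: float | None = None  # defaults to 2 * e0 - 0.2
    epsilon: float = 1.0

    def __post_init__(self):
        if min(self.kappa, self.gamma, self.tau, self.v0, self.epsilon) <= 0:
            raise ValueError("rates, times and gains must be strictly positive")
        if not (0 < self.e0 < 1):
            raise ValueError("e0 must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.k1 is None:
            object.__setattr__(self, "k1", 7.0 * self.e0)
        if self.k3 is None:
            object.__setattr__(self, "k3", 2.0 * self.e0 - 0.2)


@dataclass(frozen=True)
class NeuralTrajectory:
    times: np.ndarray
    z: np.ndarray  # (n_bins, n_nodes)


def _deriv_neural(z, Aeff, B, C, u_mod, u_drv):
    """dz/dt for (batched) states. u_mod: (..., k); u_drv: (..., m)."""
    M = Aeff + np.einsum("...k,...kij->...ij", u_mod, B)
    dz = np.einsum("...ij,...j->...i", M, z)
    dz += np.einsum("...im,...m->...i", C, u_drv)
    return dz


def integrate_neural(
    params: DCMParameters, stimuli: StimulusSet, method: str = "heun"
) -> NeuralTrajectory:
    """Integrate the bilinear neural model on the microtime grid.

    Fixed-step integration (Heun's method by default; "euler" available)
    from z(0) = 0.  Inputs are piecewise-constant boxcars, so a fixed step
    at the microtime resolution is appropriate; accuracy is documented by
    the step-halving check in the test suite.
    """
    if stimuli.driving_u.shape[1] != params.n_inputs:
        raise ValueError("stimuli and parameters are dimensionally inconsistent")
    if stimuli.modulatory_u.shape[1] != params.B.shape[0]:
        raise ValueError("modulatory inputs do not match the number of B matrices")
    Aeff = params.effective_A()
    dt = stimuli.dt_microtime
    n_bins = stimuli.n_bins
    z = np.zeros(params.n_nodes)
    traj = np.empty((n_bins, params.n_nodes))
    traj[0] = z
    um, ud = stimuli.modulatory_u, stimuli.driving_u
    for t in range(n_bins - 1):
        d1 = _deriv_neural(z, Aeff, params.B, params.C, um[t], ud[t])
        if method == "euler":
            z = z + dt * d1
        else:
            zp = z + dt * d1
            d2 = _deriv_neural(zp, Aeff, params.B, params.C, um[t], ud[t])
            z = z + 0.5 * dt * (d1 + d2)
        traj[t + 1] = z
        if not np.all(np.isfinite(z)):
            raise DivergenceError(f"non-finite neural state at bin {t + 1}")
    return NeuralTrajectory(times=stimuli.times, z=traj)


def hemodynamics(
    traj: NeuralTrajectory,
    hparams: HemodynamicParameters | None = None,
    tr_seconds: float = 2.03,
) -> np.ndarray:
    """Convolve a neural trajectory through the balloon model.

    Returns percent-signal BOLD sampled at volume acquisition times,
    (n_volumes, n_nodes).  z = 0 leaves the system at its resting fixed
    point and yields identically zero BOLD.
    """
    if not np.all(np.isfinite(traj.z)):
        raise DivergenceError("trajectory contains non-finite values")
    hp = hparams or HemodynamicParameters()
    dt = float(traj.times[1] - traj.times[0])
    y = _hemodynamics_grid(traj.z[None], hp, dt)[0]
    stride = max(1, int(round(tr_seconds / dt)))
    return y[::stride]


def _hemo_deriv(state, z, hp, epsilon=None):
    """Balloon-model derivatives in (s, ln f, ln v, ln q) coordinates."""
    s, lnf, lnv, lnq = state
    f = np.exp(lnf)
    v = np.exp(lnv)
    ds = z - hp.kappa * s - hp.gamma * (f - 1.0)
    dlnf = s / f
    fv = v ** (1.0 / hp.alpha)
    dlnv = (f - fv) / (hp.tau * v)
    E = 1.0 - (1.0 - hp.e0) ** (1.0 / f)
    dlnq = (f * E / hp.e0 - fv * np.exp(lnq - lnv)) / (hp.tau * np.exp(lnq))
    return ds, dlnf, dlnv, dlnq


def _hemo_bold(lnv, lnq, hp, epsilon=None):
    v = np.exp(lnv)
    q = np.exp(lnq)
    eps = hp.epsilon if epsilon is None else epsilon
    y = hp.v0 * (hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v) + hp.k3 * (1.0 - v))
    return 100.0 * eps * y


def _hemodynamics_grid(z, hp, dt, epsilon=None, method="heun"):
    """Integrate the balloon model on the full microtime grid.

    ``z``: (batch, n_bins, n) neural states; returns (batch, n_bins, n)
    percent BOLD.  Log-space integration of f, v, q keeps them positive.
    """
    batch, n_bins, n = z.shape
    shape = (batch, n)
    state = [np.zeros(shape), np.zeros(shape), np.zeros(shape), np.zeros(shape)]
    out = np.empty((batch, n_bins, n))
    out[:, 0] = _hemo_bold(state[2], state[3], hp, epsilon)
    for t in range(n_bins - 1):
        d1 = _hemo_deriv(state, z[:, t], hp)
        if method == "euler":
            state = [x + dt * dx for x, dx in zip(state, d1)]
        else:
            pred = [x + dt * dx for x, dx in zip(state, d1)]
            d2 = _hemo_deriv(pred, z[:, t + 1], hp)
            state = [
                x + 0.5 * dt * (da + db) for x, da, db in zip(state, d1, d2)
            ]
        out[:, t + 1] = _hemo_bold(state[2], state[3], hp, epsilon)
    if not np.all(np.isfinite(out)):
        raise DivergenceError("hemodynamic integration diverged")
    return out


def simulate_bold(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    stimuli: StimulusSet,
    hparams: HemodynamicParameters,
    tr_seconds: float,
    n_volumes: int | None = None,
    epsilon: np.ndarray | None = None,
    transit_scale: np.ndarray | None = None,
    method: str = "heun",
) -> np.ndarray:
    """Batched neural + hemodynamic forward model.

    ``A``: (..., n, n) with log-scaled diagonal, ``B``: (..., k, n, n),
    ``C``: (..., n, m).  Optional per-node hemodynamic deviations:
    ``transit_scale`` multiplies the transit time tau and ``epsilon`` scales
    the read-out, each broadcastable to (..., n).  Returns percent BOLD at
    volume times, shape (..., n_volumes, n).  This is the single forward
    code path shared by cohort simulation and model inversion.
    """
    A = np.asarray(A, float)
    single = A.ndim == 2
    if single:
        A = A[None]
        B = np.asarray(B, float)[None]
        C = np.asarray(C, float)[None]
        if epsilon is not None:
            epsilon = np.asarray(epsilon, float)[None]
        if transit_scale is not None:
            transit_scale = np.asarray(transit_scale, float)[None]
    else:
        B = np.asarray(B, float)
        C = np.asarray(C, float)
    batch, n = A.shape[0], A.shape[-1]
    Aeff = effective_A(A)
    dt = stimuli.dt_microtime
    n_bins = stimuli.n_bins
    um, ud = stimuli.modulatory_u, stimuli.driving_u
    hp = hparams

    tau = hp.tau * (transit_scale if transit_scale is not None else 1.0)
    eps = hp.epsilon * (epsilon if epsilon is not None else 1.0)

    if _HAVE_FAST:
        stride = max(1, int(round(tr_seconds / dt)))
        n_vol = n_volumes or (n_bins + stride - 1) // stride
        tau_b = np.broadcast_to(np.asarray(tau, float), (batch, n))
        eps_b = np.broadcast_to(np.asarray(eps, float), (batch, n))
        out = _integrate_batched(
            Aeff, B, C, um, ud, dt, stride, n_vol, hp, tau_b, eps_b, method
        )
        if not np.all(np.isfinite(out)):
            raise DivergenceError("forward simulation diverged")
        return out[0] if single else out

    z = np.zeros((batch, n))
    s = np.zeros((batch, n))
    lnf = np.zeros((batch, n))
    lnv = np.zeros((batch, n))
    lnq = np.zeros((batch, n))
    inv_alpha = 1.0 / hp.alpha
    ln1mE0 = np.log1p(-hp.e0)

    def deriv(z_, s_, lnf_, lnv_, lnq_, umt, udt):
        M = Aeff + np.einsum("k,bkij->bij", umt, B)
        dz = np.einsum("bij,bj->bi", M, z_) + np.einsum("bim,m->bi", C, udt)
        f = np.exp(lnf_)
        v = np.exp(lnv_)
        ds = z_ - hp.kappa * s_ - hp.gamma * (f - 1.0)
        dlnf = s_ / f
        fv = np.exp(inv_alpha * lnv_)
        dlnv = (f - fv) / (tau * v)
        E = 1.0 - np.exp(ln1mE0 / f)
        dlnq = (f * E / hp.e0 - fv * np.exp(lnq_ - lnv_)) / (tau * np.exp(lnq_))
        return dz, ds, dlnf, dlnv, dlnq

    stride = max(1, int(round(tr_seconds / dt)))
    n_vol = n_volumes or (n_bins + stride - 1) // stride
    out = np.empty((batch, n_vol, n))

    def bold(lnv_, lnq_):
        v = np.exp(lnv_)
        q = np.exp(lnq_)
        return 100.0 * eps * hp.v0 * (
            hp.k1 * (1.0 - q) + hp.k2 * (1.0 - q / v) + hp.k3 * (1.0 - v)
        )

    vol = 0
    if 0 % stride == 0:
        out[:, 0] = bold(lnv, lnq)
        vol = 1
    for t in range(n_bins - 1):
        d1 = deriv(z, s, lnf, lnv, lnq, um[t], ud[t])
        if method == "euler":
            z = z + dt * d1[0]
            s = s + dt * d1[1]
            lnf = lnf + dt * d1[2]
            lnv = lnv + dt * d1[3]
            lnq = lnq + dt * d1[4]
        else:
            zp = z + dt * d1[0]
            sp = s + dt * d1[1]
            lnfp = lnf + dt * d1[2]
            lnvp = lnv + dt * d1[3]
            lnqp = lnq + dt * d1[4]
            d2 = deriv(zp, sp, lnfp, lnvp, lnqp, um[t], ud[t])
            z = z + 0.5 * dt * (d1[0] + d2[0])
            s = s + 0.5 * dt * (d1[1] + d2[1])
            lnf = lnf + 0.5 * dt * (d1[2] + d2[2])
            lnv = lnv + 0.5 * dt * (d1[3] + d2[3])
            lnq = lnq + 0.5 * dt * (d1[4] + d2[4])
        if (t + 1) % stride == 0 and vol < n_vol:
            out[:, vol] = bold(lnv, lnq)
            vol += 1
    while vol < n_vol:  # pad if the grid ends mid-TR
        out[:, vol] = bold(lnv, lnq)
        vol += 1
    if not np.all(np.isfinite(out)):
        raise DivergenceError("forward simulation diverged")
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Cohort specification and sampling

def default_group_mean(template: ROITemplate | None = None) -> DCMParameters:
    """Generic ground-truth group-mean parameters for the 9-node network.

    These effect sizes are this package's own simulation defaults (the
    magnitudes of real task networks are not published for this paradigm):
    feed-forward coupling from the driving IPS nodes to ipsilateral targets,
    weak homotopic coupling, weak feedback, five strong event-locked
    modulatory edges and driving input confined to bilateral IPS.
    """
    template = template or ROITemplate()
    names = template.names
    n = len(names)
    idx = {nm: i for i, nm in enumerate(names)}
    A = np.zeros((n, n))
    for src, targets in {
        "LIPS": ("LPMC", "LDLPFC", "LAI", "AMCC"),
        "RIPS": ("RPMC", "RDLPFC", "RAI", "AMCC"),
    }.items():
        for tgt in targets:
            A[idx[tgt], idx[src]] = 0.25
            A[idx[src], idx[tgt]] = -0.05
    A[idx["LIPS"], idx["RIPS"]] = A[idx["RIPS"], idx["LIPS"]] = 0.10
    for l_, r_ in (("LPMC", "RPMC"), ("LDLPFC", "RDLPFC"), ("LAI", "RAI")):
        A[idx[l_], idx[r_]] = A[idx[r_], idx[l_]] = 0.05
    B = np.zeros((1, n, n))
    for (src, tgt), w in default_planted_edges().items():
        B[0, idx[tgt], idx[src]] = w
    C = np.zeros((n, 1))
    for nm in DRIVING_NODES:
        C[idx[nm], 0] = 1.0
    return DCMParameters(A=A, B=B, C=C)


def default_planted_edges() -> dict[tuple[str, str], float]:
    """Ground-truth modulatory edges (from-node, to-node) -> weight in Hz.

    Modulation is concentrated on connections of the driving IPS nodes —
    positive feed-forward, negative feedback — the pattern task-network
    analyses of this paradigm report.  Magnitudes sit at the strong end
    of the bilinear-model range so that the scaled-down cohorts retain
    statistical power (see the methods note).
    """
    return {
        ("LIPS", "LPMC"): 0.9,
        ("RIPS", "RPMC"): 0.9,
        ("LIPS", "LDLPFC"): 0.8,
        ("RIPS", "RDLPFC"): 0.8,
        ("RIPS", "AMCC"): 0.7,
        ("LIPS", "AMCC"): 0.7,
        ("LIPS", "LAI"): 0.7,
        ("RIPS", "RAI"): 0.7,
        ("LPMC", "LIPS"): -0.6,
        ("RPMC", "RIPS"): -0.6,
        ("LDLPFC", "LIPS"): -0.5,
        ("AMCC", "RIPS"): -0.5,
    }


@dataclass(frozen=True)
class GroupSpec:
    """Cohort-level generative specification.

    Between-subject variation is additive Gaussian per parameter class;
    observation noise and confound amplitudes are in percent-signal units.
    """

    mean: DCMParameters
    sd_a: float = 0.02
    sd_self: float = 0.05
    sd_b: float = 0.08
    sd_c: float = 0.08
    noise_sd: float = 0.1
    global_amp: float = 0.5
    motion_amp: float = 0.15
    nuisance_amp: float = 0.1
    n_subjects: int = 20
    n_motion: int = 6
    voxel_spacing_mm: float = 4.0
    peak_jitter_sd_mm: float = 2.5
    weight_fwhm_mm: float = 10.0
    max_stability_retries: int = 50

    def __post_init__(self):
        if min(self.sd_a, self.sd_self, self.sd_b, self.sd_c,
               self.noise_sd, self.global_amp, self.motion_amp) < 0:
            raise ValueError("standard deviations and amplitudes must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def _is_stable(params: DCMParameters) -> bool:
    """Largest real eigenvalue of A (and A + each B) must be negative."""
    Aeff = params.effective_A()
    mats = [Aeff] + [Aeff + Bk for Bk in params.B]
    return all(np.max(np.linalg.eigvals(M).real) < 0 for M in mats)


def sample_subject_parameters(
    group: GroupSpec, seed: int = 0
) -> list[DCMParameters]:
    """Draw per-subject parameters: group mean + Gaussian random effects.

    Subjects whose coupling matrices destabilize the dynamics are redrawn,
    up to ``group.max_stability_retries`` attempts each.
    """
    rng = np.random.default_rng(seed)
    mean = group.mean
    n = mean.n_nodes
    off = ~np.eye(n, dtype=bool)
    c_mask = mean.C != 0.0  # random effects only on driving rows
    out = []
    for _ in range(group.n_subjects):
        for attempt in range(group.max_stability_retries):
            A = mean.A.copy()
            A[off] += rng.normal(0.0, group.sd_a, off.sum())
            A[np.eye(n, dtype=bool)] += rng.normal(0.0, group.sd_self, n)
            B = mean.B + rng.normal(0.0, group.sd_b, mean.B.shape)
            C = mean.C + rng.normal(0.0, group.sd_c, mean.C.shape) * c_mask
            cand = DCMParameters(A=A, B=B, C=C)
            if _is_stable(cand):
                out.append(cand)
                break
        else:
            raise RuntimeError(
                "could not draw stable coupling matrices (class: A/B); "
                "reduce sd_a or sd_b"
            )
    return out


# ---------------------------------------------------------------------------
# Voxel-level rendering

@dataclass(frozen=True)
class SubjectVoxelData:
    """Multi-voxel ROI data for one subject.

    ``coords_mm[j]``: (V_j, 3) voxel positions of node j; ``bold[j]``:
    (n_volumes, V_j) signals; ``lattice[j]``: integer lattice offsets used
    for face-adjacency in cluster formation.  ``confounds`` is a
    (n_volumes, n_conf) DataFrame of nuisance regressors (the generated
    global, motion-like and slow nuisance series).
    """

    coords_mm: tuple[np.ndarray, ...]
    lattice: tuple[np.ndarray, ...]
    bold: tuple[np.ndarray, ...]
    confounds: pd.DataFrame
    true_peaks_mm: np.ndarray
    tr_seconds: float
    node_names: tuple[str, ...]

    @property
    def n_volumes(self) -> int:
        return self.bold[0].shape[0]

    @property
    def n_nodes(self) -> int:
        return len(self.bold)

    def stacked(self) -> np.ndarray:
        """(n_volumes, total_voxels) concatenation over nodes."""
        return np.concatenate(self.bold, axis=1)


def _lattice_offsets(radius_mm: float, spacing_mm: float) -> np.ndarray:
    r = int(np.floor(radius_mm / spacing_mm))
    axes = np.arange(-r, r + 1)
    grid = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"), -1).reshape(-1, 3)
    keep = (grid ** 2).sum(1) * spacing_mm ** 2 <= radius_mm ** 2
    return grid[keep]


def _smooth_noise(rng, n, scale_vols=10):
    """Slow nuisance series: white noise convolved with a Gaussian window."""
    x = rng.normal(size=n + 4 * scale_vols)
    w = np.exp(-0.5 * (np.arange(-2 * scale_vols, 2 * scale_vols + 1) / scale_vols) ** 2)
    y = np.convolve(x, w / w.sum(), mode="same")[2 * scale_vols:2 * scale_vols + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def render_voxels(
    node_bold: np.ndarray,
    template: ROITemplate,
    group: GroupSpec,
    seed: int = 0,
) -> SubjectVoxelData:
    """Render node-level BOLD into per-node voxel clouds with confounds.

    Each node's voxels lie on a jittered lattice inside the 10-mm group
    sphere; voxel weights fall off as a Gaussian (FWHM ``weight_fwhm_mm``)
    around a subject-specific true peak.  Voxel signal = weight x node BOLD
    + global + motion-like + slow nuisance confounds + white noise.
    """
    node_bold = np.asarray(node_bold, float)
    T, n = node_bold.shape
    if n != template.n_nodes:
        raise ValueError("node_bold must have one column per template node")
    rng = np.random.default_rng(seed)
    sigma = group.weight_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    glob = _smooth_noise(rng, T, scale_vols=8)
    motions = np.column_stack(
        [np.cumsum(rng.normal(0, 1, T)) for _ in range(group.n_motion)]
    )
    motions -= motions.mean(0)
    motions /= np.maximum(motions.std(0), 1e-12)
    slow = np.column_stack([_smooth_noise(rng, T, 16) for _ in range(2)])
    conf = pd.DataFrame(
        np.column_stack([glob, motions, slow]),
        columns=["global"]
        + [f"motion{i + 1}" for i in range(group.n_motion)]
        + ["wm", "csf"],
    )

    offsets = _lattice_offsets(template.group_radius_mm, group.voxel_spacing_mm)
    coords_all, lattice_all, bold_all, peaks = [], [], [], []
    for j in range(n):
        center = template.centers()[j]
        shift = rng.uniform(-1.0, 1.0, 3)
        coords = center + shift + offsets * group.voxel_spacing_mm
        dist_c = np.linalg.norm(coords - center, axis=1)
        keep = dist_c <= template.group_radius_mm
        coords, lat = coords[keep], offsets[keep]
        peak = center + np.clip(
            rng.normal(0.0, group.peak_jitter_sd_mm, 3), -6.0, 6.0
        )
        d = np.linalg.norm(coords - peak, axis=1)
        w = np.exp(-0.5 * (d / sigma) ** 2)
        v = len(coords)
        sig = w[None, :] * node_bold[:, [j]]
        sig = sig + group.global_amp * rng.normal(1.0, 0.1, v)[None, :] * glob[:, None]
        sig = sig + motions @ rng.normal(0.0, group.motion_amp, (group.n_motion, v))
        sig = sig + slow @ rng.normal(0.0, group.nuisance_amp, (2, v))
        sig = sig + rng.normal(0.0, group.noise_sd, (T, v))
        coords_all.append(coords)
        lattice_all.append(lat)
        bold_all.append(sig)
        peaks.append(peak)
    return SubjectVoxelData(
        coords_mm=tuple(coords_all),
        lattice=tuple(lattice_all),
        bold=tuple(bold_all),
        confounds=conf,
        true_peaks_mm=np.asarray(peaks),
        tr_seconds=2.03,
        node_names=template.names,
    )


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    params: DCMParameters
    node_bold: np.ndarray  # noiseless node-level percent BOLD (T, n)
    voxels: SubjectVoxelData


def simulate_cohort(
    group: GroupSpec,
    stimuli: StimulusSet,
    template: ROITemplate,
    tr_seconds: float,
    n_volumes: int,
    hparams: HemodynamicParameters | None = None,
    seed: int = 0,
) -> list[SimulatedSubject]:
    """Simulate a full cohort: parameters -> dynamics -> BOLD -> voxels."""
    hp = hparams or HemodynamicParameters()
    params = sample_subject_parameters(group, seed=seed)
    A = np.stack([p.A for p in params])
    B = np.stack([p.B for p in params])
    C = np.stack([p.C for p in params])
    bold = simulate_bold(A, B, C, stimuli, hp, tr_seconds, n_volumes=n_volumes)
    subjects = []
    for i, p in enumerate(params):
        vox = render_voxels(bold[i], template, group, seed=seed + 1000 + i)
        vox = replace(vox, tr_seconds=tr_seconds)
        subjects.append(
            SimulatedSubject(
                subject_id=f"sub-{i + 1:03d}",
                params=p,
                node_bold=bold[i],
                voxels=vox,
            )
        )
    return subjects


def subject_voxels_to_npz(voxels: SubjectVoxelData, path) -> None:
    """Export one subject's voxel data as a compressed tabular archive."""
    arrays = {"tr_seconds": np.asarray(voxels.tr_seconds),
              "true_peaks_mm": voxels.true_peaks_mm,
              "confounds": voxels.confounds.to_numpy(),
              "confound_names": np.asarray(list(voxels.confounds.columns), dtype=str),
              "node_names": np.asarray(list(voxels.node_names), dtype=str)}
    for j, nm in enumerate(voxels.node_names):
        arrays[f"coords_{nm}"] = voxels.coords_mm[j]
        arrays[f"lattice_{nm}"] = voxels.lattice[j]
        arrays[f"bold_{nm}"] = voxels.bold[j]
    np.savez_compressed(path, **arrays)


def subject_voxels_from_npz(path) -> SubjectVoxelData:
    with np.load(path, allow_pickle=False) as z:
        names = tuple(str(x) for x in z["node_names"])
        return SubjectVoxelData(
            coords_mm=tuple(z[f"coords_{nm}"] for nm in names),
            lattice=tuple(z[f"lattice_{nm}"] for nm in names),
            bold=tuple(z[f"bold_{nm}"] for nm in names),
            confounds=pd.DataFrame(
                z["confounds"],
                columns=[str(c) for c in z["confound_names"]],
            ),
            true_peaks_mm=z["true_peaks_mm"],
            tr_seconds=float(z["tr_seconds"]),
            node_names=names,
        )


def node_bold_to_tsv(node_bold: np.ndarray, names, path) -> None:
    pd.DataFrame(node_bold, columns=list(names)).to_csv(path, sep="\t", index=False)


def node_bold_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
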