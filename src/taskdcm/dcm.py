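"""Bilinear DCM specification and variational-Laplace inversion.

A fully connected nine-node bilinear model (all intrinsic and modulatory
couplings free, driving input restricted to bilateral IPS) is fitted to
each subject's node time series.  Inference is fixed-form variational
Bayes under the Laplace approximation: the posterior over parameters is
Gaussian N(mu, Sigma), optimized by Gauss-Newton ascent on the free-energy
bound F = accuracy - complexity, with per-node observation-noise log
precisions updated alongside.  Derivatives of the forward map are obtained
by finite differences, batched through the same integrator used for cohort
simulation, so that inversion and simulation share one forward code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    DivergenceError,
    HemodynamicParameters,
    simulate_bold,
)
from .firstlevel import NodeTimeSeriesSet, dct_drift_basis
from .protocol import StimulusSet
from .rois import ROITemplate, DRIVING_NODES


@dataclass(frozen=True)
class DCMModelSpec:
    """Structure of the full-connection model bound to its inputs."""

    node_names: tuple[str, ...]
    a_mask: np.ndarray  # (n, n) off-diagonal couplings enabled
    b_masks: np.ndarray  # (k, n, n)
    c_mask: np.ndarray  # (n, m)
    stimuli: StimulusSet
    tr_seconds: float
    hparams: HemodynamicParameters = field(default_factory=HemodynamicParameters)
    fit_hemodynamics: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_mod_inputs(self) -> int:
        return self.b_masks.shape[0]


def specify_full_model(
    template: ROITemplate,
    stimuli: StimulusSet,
    driving_nodes: Sequence[str] = DRIVING_NODES,
    tr_seconds: float = 2.03,
    hparams: HemodynamicParameters | None = None,
    fit_hemodynamics: bool = True,
) -> DCMModelSpec:
    """Full-connection model: every coupling free, driving input on IPS.

    All off-diagonal A couplings, all self-connection scalings and every B
    entry are enabled; the C matrix has free rows only for the designated
    driving nodes.  The modulatory input binding (which events enter u_k)
    is carried by ``stimuli`` and thus follows the processing condition's
    design and contrast.
    """
    n = template.n_nodes
    if len(driving_nodes) == 0:
        raise ValueError("at least one driving node is required")
    for nm in driving_nodes:
        if nm not in template.names:
            raise ValueError(f"unknown node name {nm!r}")
    a_mask = ~np.eye(n, dtype=bool)
    k = stimuli.modulatory_u.shape[1]
    b_masks = np.ones((k, n, n), dtype=bool)
    m = stimuli.driving_u.shape[1]
    c_mask = np.zeros((n, m), dtype=bool)
    for nm in driving_nodes:
        c_mask[template.index(nm), :] = True
    return DCMModelSpec(
        node_names=template.names,
        a_mask=a_mask,
        b_masks=b_masks,
        c_mask=c_mask,
        stimuli=stimuli,
        tr_seconds=tr_seconds,
        hparams=hparams or HemodynamicParameters(),
        fit_hemodynamics=fit_hemodynamics,
    )


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian shrinkage priors per parameter class (zero-mean).

    Variances follow common practice for bilinear fMRI models: tight
    priors on intrinsic couplings (SD 1/8 Hz), broad priors on modulatory
    and driving weights (task effects are the quantities under study and
    carry unit-variance priors in standard bilinear implementations), and
    tight log-scale priors on self-connections and hemodynamic deviations.
    The observation noise is parameterized by per-node log precisions with
    a Gaussian hyperprior.
    """

    var_a_offdiag: float = 1.0 / 64.0
    var_a_self: float = 1.0 / 256.0
    var_b: float = 1.0
    var_c: float = 1.0
    var_transit: float = 1.0 / 256.0
    var_epsilon: float = 1.0 / 256.0
    noise_logprec_mean: float = 4.0
    noise_logprec_var: float = 1.0

    def __post_init__(self):
        for v in (self.var_a_offdiag, self.var_a_self, self.var_b,
                  self.var_c, self.var_transit, self.var_epsilon,
                  self.noise_logprec_var):
            if v <= 0:
                raise ValueError("prior variances must be positive")


class ParamLayout:
    """Maps between the flat free-parameter vector and model matrices.

    Naming convention is stable across runs: ``A:src->tgt``,
    ``Aself:node``, ``B1:src->tgt``, ``C:node``, ``transit:node``,
    ``epsilon``.
    """

    def __init__(self, spec: DCMModelSpec, priors: PriorSpec):
        self.spec = spec
        names: list[str] = []
        variances: list[float] = []
        n = spec.n_nodes
        nodes = spec.node_names
        self._a_idx = np.argwhere(spec.a_mask)
        for i, j in self._a_idx:
            names.append(f"A:{nodes[j]}->{nodes[i]}")
            variances.append(priors.var_a_offdiag)
        for i in range(n):
            names.append(f"Aself:{nodes[i]}")
            variances.append(priors.var_a_self)
        self._b_idx = np.argwhere(spec.b_masks)
        for k, i, j in self._b_idx:
            names.append(f"B{k + 1}:{nodes[j]}->{nodes[i]}")
            variances.append(priors.var_b)
        self._c_idx = np.argwhere(spec.c_mask)
        for i, m in self._c_idx:
            names.append(f"C:{nodes[i]}" + (f"#{m}" if spec.c_mask.shape[1] > 1 else ""))
            variances.append(priors.var_c)
        if spec.fit_hemodynamics:
            for i in range(n):
                names.append(f"transit:{nodes[i]}")
                variances.append(priors.var_transit)
            names.append("epsilon")
            variances.append(priors.var_epsilon)
        self.names = tuple(names)
        self.prior_mean = np.zeros(len(names))
        self.prior_var = np.asarray(variances)
        self.n_params = len(names)

    def b_offdiag_indices(self) -> np.ndarray:
        """Indices of off-diagonal modulatory couplings in the flat vector."""
        start = len(self._a_idx) + self.spec.n_nodes
        rel = np.nonzero(self._b_idx[:, 1] != self._b_idx[:, 2])[0]
        return start + rel

    def b_indices(self) -> np.ndarray:
        start = len(self._a_idx) + self.spec.n_nodes
        return start + np.arange(len(self._b_idx))

    def index(self, name: str) -> int:
        return self.names.index(name)

    def unpack(self, theta: np.ndarray):
        """theta (..., p) -> batched A, B, C, transit_scale, epsilon."""
        theta = np.atleast_2d(theta)
        batch = theta.shape[0]
        n = self.spec.n_nodes
        k = self.spec.n_mod_inputs
        m = self.spec.c_mask.shape[1]
        A = np.zeros((batch, n, n))
        ofs = 0
        na = len(self._a_idx)
        A[:, self._a_idx[:, 0], self._a_idx[:, 1]] = theta[:, :na]
        ofs += na
        idx = np.arange(n)
        A[:, idx, idx] = theta[:, ofs:ofs + n]
        ofs += n
        B = np.zeros((batch, k, n, n))
        nb = len(self._b_idx)
        B[:, self._b_idx[:, 0], self._b_idx[:, 1], self._b_idx[:, 2]] = (
            theta[:, ofs:ofs + nb]
        )
        ofs += nb
        C = np.zeros((batch, n, m))
        nc = len(self._c_idx)
        C[:, self._c_idx[:, 0], self._c_idx[:, 1]] = theta[:, ofs:ofs + nc]
        ofs += nc
        if self.spec.fit_hemodynamics:
            transit = np.exp(theta[:, ofs:ofs + n])
            ofs += n
            eps = np.exp(theta[:, [ofs]])
        else:
            transit = np.ones((batch, n))
            eps = np.ones((batch, 1))
        return A, B, C, transit, eps

    def pack(self, A, B, C, transit_log=None, epsilon_log=0.0) -> np.ndarray:
        n = self.spec.n_nodes
        theta = np.zeros(self.n_params)
        na = len(self._a_idx)
        theta[:na] = A[self._a_idx[:, 0], self._a_idx[:, 1]]
        ofs = na
        theta[ofs:ofs + n] = np.diag(A)
        ofs += n
        nb = len(self._b_idx)
        theta[ofs:ofs + nb] = B[self._b_idx[:, 0], self._b_idx[:, 1], self._b_idx[:, 2]]
        ofs += nb
        nc = len(self._c_idx)
        theta[ofs:ofs + nc] = C[self._c_idx[:, 0], self._c_idx[:, 1]]
        ofs += nc
        if self.spec.fit_hemodynamics:
            theta[ofs:ofs + n] = 0.0 if transit_log is None else transit_log
            theta[-1] = epsilon_log
        return theta


def predict_bold(
    theta: np.ndarray,
    spec: DCMModelSpec,
    layout: ParamLayout | None = None,
    n_volumes: int | None = None,
) -> np.ndarray:
    """Deterministic forward prediction for flat parameter vector(s).

    Integrates the bilinear neural model and the balloon hemodynamics on
    the stimulus microtime grid and samples at volume times; identical
    machinery to the cohort simulator.
    """
    layout = layout or ParamLayout(spec, PriorSpec())
    theta = np.asarray(theta, float)
    single = theta.ndim == 1
    A, B, C, transit, eps = layout.unpack(theta)
    y = simulate_bold(
        A, B, C, spec.stimuli, spec.hparams, spec.tr_seconds,
        n_volumes=n_volumes, epsilon=eps, transit_scale=transit,
    )
    return y[0] if single else y


@dataclass(frozen=True)
class DCMPosterior:
    """Gaussian posterior over the free parameters of one subject."""

    mu: np.ndarray
    Sigma: np.ndarray
    #: F at the prior expansion point followed by each accepted step's F
    F_trace: tuple[float, ...]
    #: per accepted step: F gain over the same iteration's expansion point
    #: (nonnegative by construction of the step-halving rule)
    step_improvements: tuple[float, ...]
    converged: bool
    param_names: tuple[str, ...]
    noise_logprec: np.ndarray
    prediction: np.ndarray | None = None  # drift-projected, (T, n)
    data: np.ndarray | None = None  # drift-projected data it was fit to
    ev_percent: float = np.nan
    subject_id: str = ""

    @property
    def F(self) -> float:
        return self.F_trace[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": self.mu,
                "sd": np.sqrt(np.diag(self.Sigma)),
            }
        )

    def save(self, path) -> None:
        """Archive the posterior (mean, dense covariance, F trace, EV)."""
        np.savez_compressed(
            path,
            mu=self.mu,
            Sigma=self.Sigma,
            F_trace=np.asarray(self.F_trace),
            step_improvements=np.asarray(self.step_improvements),
            converged=np.asarray(self.converged),
            param_names=np.asarray(self.param_names),
            noise_logprec=self.noise_logprec,
            ev_percent=np.asarray(self.ev_percent),
            subject_id=np.asarray(self.subject_id),
        )

    @classmethod
    def load(cls, path) -> "DCMPosterior":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                mu=z["mu"],
                Sigma=z["Sigma"],
                F_trace=tuple(float(x) for x in z["F_trace"]),
                step_improvements=tuple(
                    float(x) for x in z["step_improvements"]
                ),
                converged=bool(z["converged"]),
                param_names=tuple(str(x) for x in z["param_names"]),
                noise_logprec=z["noise_logprec"],
                ev_percent=float(z["ev_percent"]),
                subject_id=str(z["subject_id"]),
            )


@dataclass(frozen=True)
class VLOptions:
    max_iter: int = 32
    #: do not declare convergence before this many iterations when the
    #: noise precisions are still being adapted (their damped walk needs a
    #: few iterations to settle)
    min_iter: int = 8
    tol_F: float = 0.05
    fd_step: float = 1e-3
    max_halvings: int = 6
    update_noise: bool = True
    #: largest per-iteration change of any single parameter (trust region)
    mu_step_max: float = 1.0
    #: damped Newton step cap and hard bounds for the noise log precisions
    lam_step_max: float = 2.0
    lam_bounds: tuple[float, float] = (-8.0, 16.0)
    #: project a DCT drift basis (plus constant) out of data and prediction
    confound_drift: bool = True
    drift_cutoff_s: float = 128.0


def _free_energy(r_flat, mu, Sigma, m0, Pi0, lam, lam0, lam_var,
                 JSJ_tr_per_node, T, n):
    """Variational free energy for the Gaussian observation model.

    r_flat: residual (T*n,) ordered node-major; Pi_vox: per-sample
    precision; JSJ_tr_per_node: per node tr(J Sigma J^T) correction.
    """
    acc = 0.0
    for i in range(n):
        sl = slice(i * T, (i + 1) * T)
        E = float(r_flat[sl] @ r_flat[sl]) + JSJ_tr_per_node[i]
        acc += -0.5 * np.exp(lam[i]) * E + 0.5 * T * lam[i] - 0.5 * T * np.log(2 * np.pi)
    d = mu - m0
    sign, logdet_S = np.linalg.slogdet(Sigma)
    kl_theta = 0.5 * (
        float(d @ (Pi0 * d))
        + float(np.sum(Pi0 * np.diag(Sigma)))
        - len(mu)
        - logdet_S
        - float(np.sum(np.log(Pi0)))
    )
    kl_lam = float(np.sum((lam - lam0) ** 2)) / (2.0 * lam_var)
    return acc - kl_theta - kl_lam


def invert_vl(
    data: NodeTimeSeriesSet,
    spec: DCMModelSpec,
    priors: PriorSpec | None = None,
    opts: VLOptions | None = None,
    forward: Callable[[np.ndarray], np.ndarray] | None = None,
    layout: ParamLayout | None = None,
) -> DCMPosterior:
    """Variational-Laplace inversion of the DCM for one subject.

    Gauss-Newton ascent on the free energy with step-halving whenever a
    proposed update lowers F; per-node noise log-precisions are updated by
    Newton steps between parameter updates.  Stops when the F improvement
    falls below ``opts.tol_F`` or after ``opts.max_iter`` iterations.  If F
    cannot be improved at all, returns the prior-centred posterior with
    ``converged=False`` rather than raising.

    ``forward`` may replace the generative model by any map
    theta-batch -> (batch, T, n); with a linear map and fixed noise this
    reproduces the analytic Bayesian linear-regression posterior.
    """
    if data.series is None:
        raise ValueError("subject is not qualified (no extracted series)")
    priors = priors or PriorSpec()
    opts = opts or VLOptions()
    layout = layout or ParamLayout(spec, priors)
    Y = np.asarray(data.series, float)
    T, n = Y.shape

    if opts.confound_drift:
        D = dct_drift_basis(T, data.tr_seconds, opts.drift_cutoff_s)

        def project(G):
            return G - np.einsum("td,...dn->...tn", D, np.einsum("td,...tn->...dn", D, G))
    else:
        def project(G):
            return G

    Yp = project(Y)

    if forward is None:
        def forward(theta_batch):
            return predict_bold(np.atleast_2d(theta_batch), spec, layout, n_volumes=T)

    m0 = layout.prior_mean.copy()
    Pi0 = 1.0 / layout.prior_var
    p = layout.n_params
    lam0 = priors.noise_logprec_mean
    lam = np.full(n, lam0)
    lam_var = priors.noise_logprec_var

    mu = m0.copy()
    F_trace: list[float] = []
    converged = False
    Sigma = np.diag(layout.prior_var)
    g0 = None

    def fwd_proj(theta_batch):
        return project(forward(theta_batch))

    def residual(g):
        return (Yp - g).T.reshape(-1)  # node-major flat

    def update_lambda(r_flat, JSJ_tr):
        # one damped, clamped Newton step per VL iteration keeps the
        # precision search stable while the linearization is still moving
        for i in range(n):
            sl = slice(i * T, (i + 1) * T)
            E = float(r_flat[sl] @ r_flat[sl]) + JSJ_tr[i]
            e = np.exp(lam[i])
            grad = -0.5 * e * E + 0.5 * T - (lam[i] - lam0) / lam_var
            hess = -0.5 * e * E - 1.0 / lam_var
            step = np.clip(grad / hess, -opts.lam_step_max, opts.lam_step_max)
            lam[i] = float(np.clip(lam[i] - step, *opts.lam_bounds))

    def _sigma_and_tr(Jf, w):
        H = (Jf.T * w) @ Jf + np.diag(Pi0)
        S = np.linalg.inv(H)
        S = 0.5 * (S + S.T)
        tr = np.array(
            [
                np.sum((Jf[i * T:(i + 1) * T] @ S) * Jf[i * T:(i + 1) * T])
                for i in range(n)
            ]
        )
        return S, tr

    improvements: list[float] = []
    eye_p = np.eye(p)
    for it in range(opts.max_iter):
        # batched forward + finite-difference Jacobian
        batch = np.vstack([mu[None], mu[None] + eye_p * opts.fd_step])
        try:
            G = fwd_proj(batch)
        except DivergenceError:
            break
        g0 = G[0]
        J = (G[1:] - G[0][None]) / opts.fd_step  # (p, T, n)
        Jf = J.transpose(0, 2, 1).reshape(p, n * T).T  # (n*T, p) node-major
        r = residual(g0)

        w = np.repeat(np.exp(lam), T)
        Sigma_new, JSJ_tr = _sigma_and_tr(Jf, w)
        if opts.update_noise:
            update_lambda(r, JSJ_tr)
            w = np.repeat(np.exp(lam), T)
            Sigma_new, JSJ_tr = _sigma_and_tr(Jf, w)
        grad = (Jf.T * w) @ r - Pi0 * (mu - m0)
        dmu = Sigma_new @ grad
        step_max = float(np.abs(dmu).max())
        if step_max > opts.mu_step_max:  # trust-region style cap
            dmu = dmu * (opts.mu_step_max / step_max)

        # F at the current expansion point under this iteration's
        # linearization and hyperparameters; accepted steps must beat it
        F_here = _free_energy(
            r, mu, Sigma_new, m0, Pi0, lam, lam0, lam_var, JSJ_tr, T, n
        )
        if it == 0:
            F_trace.append(F_here)
            Sigma = Sigma_new
        accepted = False
        for _ in range(opts.max_halvings + 1):
            mu_try = mu + dmu
            try:
                g_try = fwd_proj(mu_try[None])[0]
            except DivergenceError:
                dmu = dmu / 2.0
                continue
            r_try = residual(g_try)
            F_try = _free_energy(
                r_try, mu_try, Sigma_new, m0, Pi0, lam, lam0, lam_var,
                JSJ_tr, T, n
            )
            if F_try > F_here:
                mu = mu_try
                g0 = g_try
                Sigma = Sigma_new
                accepted = True
                break
            dmu = dmu / 2.0
        if not accepted:
            # no step improves F: converged if past the first iteration,
            # otherwise the prior-centred posterior is returned as-is
            converged = it > 0
            break
        improvement = F_try - F_here
        improvements.append(improvement)
        F_trace.append(F_try)
        if improvement < opts.tol_F and not opts.update_noise:
            converged = True
            break
        if improvement < opts.tol_F and it >= opts.min_iter:
            converged = True
            break

    if g0 is None:  # forward model failed outright: prior-centred fallback
        F_trace = F_trace or [-np.inf]
        mu = m0.copy()
        g0 = fwd_proj(mu[None])[0]
    if not F_trace:
        F_trace = [-np.inf]

    ev = explained_variance_arrays(g0, Yp)
    return DCMPosterior(
        mu=mu,
        Sigma=Sigma,
        F_trace=tuple(F_trace),
        step_improvements=tuple(improvements),
        converged=converged,
        param_names=layout.names,
        noise_logprec=lam.copy(),
        prediction=g0,
        data=Yp,
        ev_percent=ev,
        subject_id=data.subject_id,
    )


def explained_variance_arrays(pred: np.ndarray, data: np.ndarray) -> float:
    """Percent variance explained, pooled over nodes.

    EV = 100 (1 - SS_res / SS_tot) with SS_tot about each node's mean.
    Negative values indicate a fit worse than the per-node mean.
    """
    pred = np.asarray(pred, float)
    data = np.asarray(data, float)
    ss_tot = float(((data - data.mean(0)) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("data has zero variance; EV undefined")
    ss_res = float(((data - pred) ** 2).sum())
    return 100.0 * (1.0 - ss_res / ss_tot)


def explained_variance(post: DCMPosterior, data: NodeTimeSeriesSet | None = None) -> float:
    """EV of a fitted posterior (against its stored drift-projected data)."""
    if post.prediction is None:
        raise ValueError("posterior holds no prediction")
    target = post.data if data is None else np.asarray(data.series, float)
    return explained_variance_arrays(post.prediction, target)


def qualify_subjects(
    posteriors: Sequence[DCMPosterior], threshold: float = 10.0
) -> tuple[list[DCMPosterior], pd.DataFrame]:
    """Apply the explained-variance qualification filter.

    Subjects whose model explains less than ``threshold`` percent of their
    signal variance are excluded; the log records both bookkeeping stages
    (extraction-qualified input count vs EV-qualified output count).
    """
    kept, rows = [], []
    for post in posteriors:
        ok = post.ev_percent >= threshold
        rows.append(
            {
                "subject": post.subject_id,
                "ev_percent": post.ev_percent,
                "qualified": ok,
                "reason": "" if ok else f"EV {post.ev_percent:.1f}% < {threshold:g}%",
            }
        )
        if ok:
            kept.append(post)
    return kept, pd.DataFrame(rows)
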