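"""Group-level inference: parametric empirical Bayes and Bayesian data
comparison.

The hierarchical model expresses each subject's connectivity parameters as
group effects plus Gaussian random effects,

    theta_i = (x_i^T kron I) beta + eps_i,   eps_i ~ N(0, D^{-1}),

where x_i is the subject's row of the between-subject design matrix and D
is a per-parameter-class scalar random-effect precision, optimized by
maximizing the hierarchical free energy.  Subject-level evidence enters
through the first-level posterior means and covariances.  Group effects are
judged by the posterior probability (PP) that including the effect improves
model evidence, computed by analytic Bayesian model reduction: the effect's
prior is clamped to zero and PP = 1 / (1 + exp(-dF)).  Parameter certainty
between two processings of the same subjects is compared by the difference
of Gaussian posterior negentropies in nats (Bayesian data comparison),
classified by the conventional 1.1 / 3 / 5-nat evidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .dcm import DCMPosterior

#: evidence bands (nats) for certainty differences
BDC_BANDS = (1.1, 3.0, 5.0)

#: number of off-diagonal edges in a fully connected 9-node network
def n_offdiagonal_edges(n_nodes: int = 9) -> int:
    return n_nodes * (n_nodes - 1)


def edge_fraction_percent(count: int, n_nodes: int = 9) -> float:
    """Evident-edge count as percent of the network's off-diagonal capacity."""
    return 100.0 * count / n_offdiagonal_edges(n_nodes)


# ---------------------------------------------------------------------------
# Gaussian model reduction

def reduced_log_evidence(
    mu: np.ndarray,
    Sigma: np.ndarray,
    mu0: np.ndarray,
    Sigma0: np.ndarray,
    mu0_r: np.ndarray,
    Sigma0_r: np.ndarray,
) -> float:
    """Change in log evidence when the prior is replaced by a reduced prior.

    Analytic Gaussian identity: with posterior q = N(mu, Sigma) obtained
    under prior p0 = N(mu0, Sigma0), the evidence under a reduced prior
    p0r = N(mu0_r, Sigma0_r) differs by

        ln Z_r - ln Z = ln  E_q[ p0r(theta) / p0(theta) ],

    which has a closed form for Gaussians.  Returns ln Z_r - ln Z.
    """
    Pi_q = np.linalg.inv(Sigma)
    Pi_0 = np.linalg.inv(Sigma0)
    Pi_r = np.linalg.inv(Sigma0_r)
    Pi_t = Pi_q + Pi_r - Pi_0
    b = Pi_q @ mu + Pi_r @ mu0_r - Pi_0 @ mu0
    sign_t, ld_t = np.linalg.slogdet(Pi_t)
    if sign_t <= 0:
        return -np.inf  # reduced model incompatible with the posterior
    _, ld_q = np.linalg.slogdet(Pi_q)
    _, ld_r = np.linalg.slogdet(Pi_r)
    _, ld_0 = np.linalg.slogdet(Pi_0)
    quad = float(b @ np.linalg.solve(Pi_t, b))
    quad -= float(mu @ Pi_q @ mu)
    quad -= float(mu0_r @ Pi_r @ mu0_r)
    quad += float(mu0 @ Pi_0 @ mu0)
    return 0.5 * (ld_q + ld_r - ld_0 - ld_t) + 0.5 * quad


# ---------------------------------------------------------------------------
# PEB

@dataclass(frozen=True)
class PEBDesign:
    """Between-subject design matrix (first column all ones)."""

    X: np.ndarray
    covariate_labels: tuple[str, ...]

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, float))
        object.__setattr__(self, "X", X)
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first design column must be all ones (group mean)")
        if X.shape[1] > 1 and not np.allclose(X[:, 1:].mean(0), 0.0, atol=1e-9):
            raise ValueError("covariate columns must be mean-centred")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("between-subject design is rank deficient")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


def mean_design(n_subjects: int) -> PEBDesign:
    return PEBDesign(X=np.ones((n_subjects, 1)), covariate_labels=("mean",))


def group_design(group_labels: Sequence[int]) -> PEBDesign:
    """Ones column plus a mean-centred group-membership column."""
    g = np.asarray(group_labels, float)
    gc = g - g.mean()
    return PEBDesign(
        X=np.column_stack([np.ones(len(g)), gc]),
        covariate_labels=("mean", "group"),
    )


@dataclass(frozen=True)
class PEBPosterior:
    """Posterior over group-level (covariate x parameter) effects."""

    mu: np.ndarray  # (n_cov * n_param,), covariate-major
    Sigma: np.ndarray
    effect_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    covariate_labels: tuple[str, ...]
    pp: np.ndarray  # posterior probability per effect
    random_effect_logprec: float
    free_energy: float
    prior_var: np.ndarray
    n_subjects: int

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": self.effect_names,
                "estimate": self.mu,
                "sd": np.sqrt(np.diag(self.Sigma)),
                "pp": self.pp,
            }
        )

    def covariate_slice(self, label: str) -> slice:
        k = self.covariate_labels.index(label)
        p = len(self.parameter_names)
        return slice(k * p, (k + 1) * p)


def _select_parameters(
    posteriors: Sequence[DCMPosterior], parameter_selection
) -> tuple[tuple[str, ...], list[np.ndarray], list[np.ndarray]]:
    """Marginal first-level posteriors over the selected parameters."""
    ref = posteriors[0].param_names
    for post in posteriors[1:]:
        if post.param_names != ref:
            first = next(
                (a for a, b in zip(ref, post.param_names) if a != b), "length"
            )
            raise ValueError(f"parameter layouts differ (first mismatch: {first})")
    if parameter_selection in (None, "all"):
        idx = np.arange(len(ref))
    elif parameter_selection == "B":
        idx = np.array([i for i, nm in enumerate(ref) if nm.startswith("B")])
    elif parameter_selection == "A":
        idx = np.array([i for i, nm in enumerate(ref) if nm.startswith("A:")])
    else:
        idx = np.array([ref.index(nm) for nm in parameter_selection])
    names = tuple(ref[i] for i in idx)
    mus = [post.mu[idx] for post in posteriors]
    Sigmas = [post.Sigma[np.ix_(idx, idx)] for post in posteriors]
    return names, mus, Sigmas


def _peb_free_energy_and_posterior(
    mus, Sigmas, X, prior_var_param, log_prec
):
    """Free energy of the hierarchical model at a random-effect precision.

    Marginalizing beta analytically: theta_i ~ N(X_i beta, Sigma_i + D^-1)
    with beta ~ N(0, diag(prior var)).  Returns (F, mu_beta, Sigma_beta).
    """
    n_sub = len(mus)
    p = len(mus[0])
    k = X.shape[1]
    D_inv = np.exp(-log_prec) * np.eye(p)
    prior_var = np.concatenate([prior_var_param for _ in range(k)])
    Pi_b = np.diag(1.0 / prior_var)
    H = Pi_b.copy()
    b = np.zeros(k * p)
    ll = 0.0
    for i in range(n_sub):
        Ci = Sigmas[i] + D_inv
        Li = np.linalg.cholesky(Ci)
        Ci_inv = np.linalg.inv(Ci)
        ll += -0.5 * (
            2.0 * np.log(np.diag(Li)).sum()
            + float(mus[i] @ Ci_inv @ mus[i])
            + p * np.log(2.0 * np.pi)
        )
        for a in range(k):
            b[a * p:(a + 1) * p] += X[i, a] * (Ci_inv @ mus[i])
            for c in range(k):
                H[a * p:(a + 1) * p, c * p:(c + 1) * p] += (
                    X[i, a] * X[i, c] * Ci_inv
                )
    Sigma_beta = np.linalg.inv(H)
    Sigma_beta = 0.5 * (Sigma_beta + Sigma_beta.T)
    mu_beta = Sigma_beta @ b
    _, ld_H = np.linalg.slogdet(H)
    ld_prior = np.log(prior_var).sum()
    F = ll + 0.5 * float(b @ mu_beta) - 0.5 * ld_H - 0.5 * ld_prior
    return F, mu_beta, Sigma_beta


def peb_fit(
    posteriors: Sequence[DCMPosterior],
    parameter_selection="B",
    design: PEBDesign | None = None,
    prior_var_scale: float = 4.0,
    logprec_bounds: tuple[float, float] = (-6.0, 10.0),
) -> PEBPosterior:
    """Fit the hierarchical (empirical Bayes) group model.

    ``parameter_selection`` chooses the first-level parameters modelled at
    the group level ("B" by default, "A", "all", or an explicit name list).
    Group-effect priors are zero-mean with variance equal to the pooled
    first-level posterior variance scale of the selected parameters times
    ``prior_var_scale``.  The scalar random-effect log precision is chosen
    by maximizing the hierarchical free energy (bounded scalar search).
    PP per effect comes from analytic Bayesian model reduction.
    """
    if len(posteriors) < 2:
        raise ValueError("PEB needs at least two subjects")
    design = design or mean_design(len(posteriors))
    if design.n_subjects != len(posteriors):
        raise ValueError("design rows must match the number of subjects")
    names, mus, Sigmas = _select_parameters(posteriors, parameter_selection)
    if len(names) == 0:
        raise ValueError("parameter selection is empty")
    p = len(names)
    X = design.X
    k = X.shape[1]
    # group-effect prior: zero-mean with an empirical-Bayes variance broad
    # enough to cover the observed first-level scale (uncertainty, spread
    # and magnitude of the subject means), so genuine group effects are
    # not shrunk away while the reduction test retains an Occam penalty
    scale = float(np.mean([np.diag(S).mean() for S in Sigmas]))
    spread = float(np.var(np.stack(mus), axis=0).mean())
    magnitude = float(np.mean(np.stack(mus) ** 2))
    prior_var_param = np.full(
        p, prior_var_scale * max(scale + spread + magnitude, 1e-6)
    )

    def neg_F(log_prec):
        F, *_ = _peb_free_energy_and_posterior(
            mus, Sigmas, X, prior_var_param, log_prec
        )
        return -F

    res = minimize_scalar(
        neg_F, bounds=logprec_bounds, method="bounded",
        options={"xatol": 1e-2},
    )
    log_prec = float(res.x)
    F, mu_b, Sigma_b = _peb_free_energy_and_posterior(
        mus, Sigmas, X, prior_var_param, log_prec
    )
    prior_var_full = np.concatenate([prior_var_param for _ in range(k)])
    effect_names = tuple(
        f"{cov}:{nm}" for cov in design.covariate_labels for nm in names
    )
    pp = np.array(
        [
            posterior_probability_from_moments(
                mu_b, Sigma_b, prior_var_full, j
            )
            for j in range(k * p)
        ]
    )
    return PEBPosterior(
        mu=mu_b,
        Sigma=Sigma_b,
        effect_names=effect_names,
        parameter_names=names,
        covariate_labels=design.covariate_labels,
        pp=pp,
        random_effect_logprec=log_prec,
        free_energy=F,
        prior_var=prior_var_full,
        n_subjects=len(posteriors),
    )


def posterior_probability_from_moments(
    mu: np.ndarray, Sigma: np.ndarray, prior_var: np.ndarray, effect: int
) -> float:
    """PP that a single effect is present, by Bayesian model reduction.

    dF = ln Z(full) - ln Z(effect clamped at 0); PP = 1/(1 + exp(-dF)).
    """
    mu0 = np.zeros(len(mu))
    Sigma0 = np.diag(prior_var)
    var_r = prior_var.copy()
    var_r[effect] = 1e-8
    dF_reduced = reduced_log_evidence(
        mu, Sigma, mu0, Sigma0, mu0, np.diag(var_r)
    )
    dF = -dF_reduced  # full minus reduced
    return float(1.0 / (1.0 + np.exp(-np.clip(dF, -700, 700))))


def posterior_probability(peb: PEBPosterior, effect: int | str) -> float:
    """PP of one group-level effect (by index or effect name)."""
    j = effect if isinstance(effect, int) else peb.effect_names.index(effect)
    return float(peb.pp[j])


def count_evident_edges(
    peb: PEBPosterior,
    covariate: str = "mean",
    threshold: float = 0.95,
    exclude_self: bool = True,
) -> int:
    """Number of modulatory couplings with PP above threshold.

    Counts effects of the given covariate over B-matrix parameters,
    excluding self-connections by default (upper bound 72 for nine nodes).
    """
    sl = peb.covariate_slice(covariate)
    count = 0
    for nm, pp in zip(peb.parameter_names, peb.pp[sl]):
        if not nm.startswith("B"):
            continue
        src_tgt = nm.split(":", 1)[1]
        src, tgt = src_tgt.split("->")
        if exclude_self and src == tgt:
            continue
        if pp > threshold:
            count += 1
    return count


def mean_abs_evident(
    peb: PEBPosterior, covariate: str = "mean", threshold: float = 0.95
) -> float:
    """Mean |estimate| over evident (PP > threshold) off-diagonal B effects."""
    sl = peb.covariate_slice(covariate)
    vals = []
    for nm, pp, est in zip(
        peb.parameter_names, peb.pp[sl], peb.mu[sl]
    ):
        if not nm.startswith("B"):
            continue
        src, tgt = nm.split(":", 1)[1].split("->")
        if src == tgt:
            continue
        if pp > threshold:
            vals.append(abs(est))
    return float(np.mean(vals)) if vals else 0.0


def peb_between(
    posteriors_a: Sequence[DCMPosterior],
    posteriors_b: Sequence[DCMPosterior],
    parameter_selection="B",
    **kwargs,
) -> PEBPosterior:
    """Between-group PEB: difference effects via a mean-centred indicator.

    Stacks both sets as one hierarchical model with design
    [ones, centred group indicator]; the "group" covariate effects are the
    between-group differences (a - b direction positive).
    """
    if not posteriors_a or not posteriors_b:
        raise ValueError("both condition sets must be nonempty")
    for grp in (posteriors_a, posteriors_b):
        ids = [p.subject_id for p in grp]
        dup = {i for i in ids if i and ids.count(i) > 1}
        if dup:
            raise ValueError(f"subject(s) {sorted(dup)} present twice in one group")
    labels = [0.5] * len(posteriors_a) + [-0.5] * len(posteriors_b)
    design = PEBDesign(
        X=np.column_stack(
            [np.ones(len(labels)), np.asarray(labels) - np.mean(labels)]
        ),
        covariate_labels=("mean", "group"),
    )
    return peb_fit(
        list(posteriors_a) + list(posteriors_b),
        parameter_selection=parameter_selection,
        design=design,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Bayesian data comparison

@dataclass(frozen=True)
class BDCResult:
    certainty_diff_nats: float
    evidence_class: str
    n_subjects: int
    per_subject: np.ndarray

    def __post_init__(self):
        pass


def classify_nats(value: float) -> str:
    v = abs(value)
    if v < BDC_BANDS[0]:
        return "none"
    if v < BDC_BANDS[1]:
        return "positive"
    if v < BDC_BANDS[2]:
        return "strong"
    return "very strong"


def bdc_compare(
    posteriors_a: Sequence[DCMPosterior],
    posteriors_b: Sequence[DCMPosterior],
    common_subject_ids: Sequence[str] | None = None,
    parameter_selection="B",
) -> BDCResult:
    """Relative parameter certainty between two conditions, in nats.

    For each common subject the certainty difference is the negentropy
    difference of the Gaussian parameter posteriors,
    -H[q_a] + H[q_b] = 0.5 (ln det Sigma_b - ln det Sigma_a), over the
    selected parameter block; positive values mean condition a's
    parameters are more certain.  The subject-wise values are averaged and
    classified by the 1.1 / 3 / 5-nat evidence bands.  Antisymmetric under
    swapping the conditions.
    """
    by_id_a = {p.subject_id: p for p in posteriors_a}
    by_id_b = {p.subject_id: p for p in posteriors_b}
    if common_subject_ids is None:
        common_subject_ids = [i for i in by_id_a if i in by_id_b]
    if len(common_subject_ids) == 0:
        raise ValueError("no common subjects between the two conditions")
    diffs = []
    for sid in common_subject_ids:
        pa, pb = by_id_a[sid], by_id_b[sid]
        names_a, _, Sig_a = _select_parameters([pa], parameter_selection)
        names_b, _, Sig_b = _select_parameters([pb], parameter_selection)
        if names_a != names_b:
            raise ValueError("parameter layouts differ between conditions")
        sa, ld_a = np.linalg.slogdet(Sig_a[0])
        sb, ld_b = np.linalg.slogdet(Sig_b[0])
        if sa <= 0 or sb <= 0:
            raise ValueError(f"singular posterior covariance for {sid}")
        diffs.append(0.5 * (ld_b - ld_a))
    diffs = np.asarray(diffs)
    mean = float(diffs.mean())
    return BDCResult(
        certainty_diff_nats=mean,
        evidence_class=classify_nats(mean),
        n_subjects=len(diffs),
        per_subject=diffs,
    )
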