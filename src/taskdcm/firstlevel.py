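"""First-level fMRI analysis: nuisance regression, GLM, thresholding and
node time-series extraction.

The stages mirror a standard single-subject task pipeline: (i) voxel-wise
removal of nuisance regressors (optionally including the global signal) and
high-pass filtering with a 128-s cutoff via a discrete-cosine drift basis;
(ii) a GLM whose task regressors are stimulus boxcars convolved with the
canonical double-gamma HRF plus their temporal derivatives; (iii) one-sided
t-contrast maps thresholded either voxel-wise (uncorrected p < .05) or by
cluster extent calibrated with sign-flip permutations; (iv) extraction of
one representative time series per network node as the first eigenvariate
of suprathreshold voxels inside a subject-specific 4-mm sphere centred on
the individual local maximum within the 10-mm group sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectVoxelData
from .protocol import (
    BehavioralRecord,
    TaskProtocol,
    default_dt_microtime,
)
from .rois import ROITemplate

CONTRAST_NAMES = ("Anti", "Pro", "AntiPlusPro", "AntiMinusPro")
THRESHOLD_METHODS = ("uncorrected_p05", "cluster_corrected_p05")


# ---------------------------------------------------------------------------
# Preprocessing

def dct_drift_basis(n: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine basis spanning fluctuations slower than ``cutoff_s``.

    Columns are the constant term plus cosines with periods >= cutoff;
    regressing them out implements a high-pass filter with the given cutoff.
    """
    order = int(np.floor(2.0 * n * tr / cutoff_s))
    t = np.arange(n)
    cols = [np.ones(n) / np.sqrt(n)]
    for k in range(1, order + 1):
        c = np.sqrt(2.0 / n) * np.cos(np.pi * k * (t + 0.5) / n)
        cols.append(c)
    return np.column_stack(cols)


def residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project out the column space of X from each column of y (OLS)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def preprocess_timeseries(
    voxels: SubjectVoxelData,
    gsr: bool = True,
    highpass_cutoff_s: float = 128.0,
) -> SubjectVoxelData:
    """Nuisance regression and high-pass filtering of all voxel series.

    The confound set is every regressor stored with the subject (generated
    motion-like and slow nuisance series), with the global regressor
    included iff ``gsr``.  High-pass filtering removes the DCT drift basis
    with a 128-s cutoff.  Returns a copy holding residual series.
    """
    conf = voxels.confounds
    cols = [c for c in conf.columns if gsr or c != "global"]
    C = conf[cols].to_numpy()
    C = np.column_stack([np.ones(len(C)), C])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        raise ValueError(
            f"confound matrix is rank deficient (rank {rank} < {C.shape[1]}); "
            f"columns: {['const'] + cols}"
        )
    D = dct_drift_basis(voxels.n_volumes, voxels.tr_seconds, highpass_cutoff_s)
    X = np.column_stack([C, D[:, 1:]])  # constant already present
    new_bold = tuple(residualize(b, X) for b in voxels.bold)
    return replace(voxels, bold=new_bold)


# ---------------------------------------------------------------------------
# HRF and design matrices

def hrf_kernel(dt: float, length_s: float = 32.0) -> tuple[np.ndarray, np.ndarray]:
    """Canonical double-gamma HRF and its temporal derivative, sampled at dt.

    Difference of two gamma densities (response peak ~5 s, undershoot
    ~15 s, ratio 1/6), normalized to unit peak.  The derivative is the
    finite difference of the kernel, which integrates to ~0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length_s, dt)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    h = h / h.max()
    dh = np.gradient(h, dt)
    return h, dh


@dataclass(frozen=True)
class DesignMatrix:
    """Volume-sampled GLM design with labelled columns.

    Task regressors of interest come first, then their temporal
    derivatives, then confound/drift columns (here: intercept).
    """

    X: np.ndarray
    task_columns: tuple[str, ...]
    derivative_columns: tuple[str, ...]
    confound_columns: tuple[str, ...]
    design_type: str
    empty_columns: tuple[str, ...] = ()

    @property
    def columns(self) -> tuple[str, ...]:
        return self.task_columns + self.derivative_columns + self.confound_columns

    @property
    def n_task(self) -> int:
        return len(self.task_columns)

    def task_index(self, name: str) -> int:
        return self.task_columns.index(name)


def _design_events(
    protocol: TaskProtocol,
    behavior: BehavioralRecord | None,
    design_type: str,
) -> dict[str, tuple[list[float], list[float]]]:
    """Regressor name -> (onsets, durations) for the requested design."""
    if design_type == "Blocks":
        out: dict[str, tuple[list[float], list[float]]] = {
            "Anti": ([], []), "Pro": ([], [])
        }
        for b in protocol.blocks:
            out[b.condition][0].append(b.onset_s)
            out[b.condition][1].append(b.duration_s)
        return out
    trials = protocol.trial_table()
    keep = np.ones(len(trials), bool)
    if design_type == "STrials":
        if behavior is None:
            raise ValueError("STrials design requires behaviour")
        keep = behavior.correct.copy()
    out = {f"{c}-{s}": ([], []) for c in ("Anti", "Pro") for s in ("L", "R")}
    for i, row in enumerate(trials.itertuples()):
        if keep[i]:
            key = f"{row.condition}-{row.side}"
            out[key][0].append(float(row.onset))
            out[key][1].append(float(row.duration))
    return out


def build_design(
    protocol: TaskProtocol,
    behavior: BehavioralRecord | None,
    design_type: str,
    tr_seconds: float | None = None,
    dt_microtime: float | None = None,
) -> DesignMatrix:
    """Construct the convolved GLM design sampled at volume times.

    Event designs carry four regressors of interest (Anti/Pro x L/R
    stimulus side); the block design carries two (Anti, Pro).  Each task
    regressor is paired with its temporal derivative; an intercept is
    appended.  Regressors left without any events (possible for STrials
    with extreme error rates) are flagged in ``empty_columns``.
    """
    tr = tr_seconds or protocol.tr_seconds
    dt = dt_microtime or default_dt_microtime(tr)
    n_bins = int(round(protocol.duration_s / dt))
    times = np.arange(n_bins) * dt
    h, dh = hrf_kernel(dt)
    vol_idx = (np.arange(protocol.n_volumes) * tr / dt).round().astype(int)
    vol_idx = np.clip(vol_idx, 0, n_bins - 1)

    events = _design_events(protocol, behavior, design_type)
    task_cols, deriv_cols, empty = [], [], []
    Xt, Xd = [], []
    for name, (onsets, durs) in events.items():
        u = np.zeros(n_bins)
        for onset, dur in zip(onsets, durs):
            i0 = int(np.floor(onset / dt))
            i1 = max(i0 + 1, int(np.ceil((onset + dur) / dt)))
            u[i0:min(i1, n_bins)] = 1.0
        if not onsets:
            empty.append(name)
        conv = np.convolve(u, h)[:n_bins] * dt
        dconv = np.convolve(u, dh)[:n_bins] * dt
        task_cols.append(name)
        deriv_cols.append(name + "_deriv")
        Xt.append(conv[vol_idx])
        Xd.append(dconv[vol_idx])
    X = np.column_stack(Xt + Xd + [np.ones(protocol.n_volumes)])
    return DesignMatrix(
        X=X,
        task_columns=tuple(task_cols),
        derivative_columns=tuple(deriv_cols),
        confound_columns=("intercept",),
        design_type=design_type,
        empty_columns=tuple(empty),
    )


@dataclass(frozen=True)
class Contrast:
    name: str
    weights: np.ndarray  # over all design columns

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, float))


def make_contrast(design: DesignMatrix, name: str) -> Contrast:
    """Build one of the four task contrasts over the design's columns.

    Weights are nonzero only on the task regressors of interest and are
    scaled to average the condition's regressors (so estimates are mean
    responses).  The difference contrast Anti - Pro sums to zero.
    """
    if name not in CONTRAST_NAMES:
        raise ValueError(f"unknown contrast {name!r}")
    w = np.zeros(design.X.shape[1])
    anti = [i for i, c in enumerate(design.task_columns) if c.startswith("Anti")]
    pro = [i for i, c in enumerate(design.task_columns) if c.startswith("Pro")]
    if name == "Anti":
        w[anti] = 1.0 / len(anti)
    elif name == "Pro":
        w[pro] = 1.0 / len(pro)
    elif name == "AntiPlusPro":
        w[anti] = 1.0 / len(anti)
        w[pro] = 1.0 / len(pro)
    else:
        w[anti] = 1.0 / len(anti)
        w[pro] = -1.0 / len(pro)
    return Contrast(name=name, weights=w)


# ---------------------------------------------------------------------------
# GLM fitting and thresholding

@dataclass(frozen=True)
class TContrastMap:
    estimate: np.ndarray  # per voxel, concatenated over nodes
    t: np.ndarray
    df: int
    node_slices: tuple[slice, ...]
    residuals: np.ndarray | None = None  # (volumes, voxels), for permutation
    design: DesignMatrix | None = None
    contrast: Contrast | None = None
    infinite_t: np.ndarray | None = None


def _node_slices(voxels: SubjectVoxelData) -> tuple[slice, ...]:
    out, start = [], 0
    for b in voxels.bold:
        out.append(slice(start, start + b.shape[1]))
        start += b.shape[1]
    return tuple(out)


def fit_glm(
    voxels: SubjectVoxelData,
    design: DesignMatrix,
    contrast: Contrast,
    prewhiten_ar1: bool = False,
) -> TContrastMap:
    """Voxel-wise OLS with a t-statistic for the given contrast.

    ``prewhiten_ar1`` applies a single-pass AR(1) prewhitening (coefficient
    pooled over voxels) before refitting; the default is plain OLS because
    the simulated noise is white.
    """
    Y = voxels.stacked()
    X = design.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if prewhiten_ar1:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        res = Y - X @ beta
        num = (res[1:] * res[:-1]).sum()
        den = (res[:-1] ** 2).sum()
        rho = float(np.clip(num / max(den, 1e-12), -0.97, 0.97))
        W_first = np.sqrt(1.0 - rho ** 2)
        Yw = np.vstack([Y[:1] * W_first, Y[1:] - rho * Y[:-1]])
        Xw = np.vstack([X[:1] * W_first, X[1:] - rho * X[:-1]])
        X, Y = Xw, Yw
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    res = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = (res ** 2).sum(0) / df
    c = contrast.weights
    est = c @ beta
    var = sigma2 * float(c @ XtX_inv @ c)
    zero_var = var <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / np.sqrt(var)
    t = np.where(zero_var & (est != 0), np.inf * np.sign(est), t)
    t = np.where(zero_var & (est == 0), 0.0, t)
    return TContrastMap(
        estimate=est,
        t=t,
        df=df,
        node_slices=_node_slices(voxels),
        residuals=res,
        design=design,
        contrast=contrast,
        infinite_t=zero_var,
    )


@dataclass(frozen=True)
class ThresholdedMap:
    mask: np.ndarray  # boolean, concatenated voxels
    cluster_labels: np.ndarray  # 0 = background
    method: str
    node_slices: tuple[slice, ...]


def _clusters_from_mask(
    mask: np.ndarray, voxels: SubjectVoxelData, node_slices
) -> np.ndarray:
    """Face-connected components on each node's integer lattice."""
    labels = np.zeros(len(mask), dtype=int)
    next_label = 1
    for sl, lat in zip(node_slices, voxels.lattice):
        idx = np.nonzero(mask[sl])[0]
        if len(idx) == 0:
            continue
        pos = {tuple(lat[i]): i for i in idx}
        seen: set[int] = set()
        for i in idx:
            if i in seen:
                continue
            stack = [i]
            seen.add(i)
            while stack:
                j = stack.pop()
                labels[sl.start + j] = next_label
                p = lat[j]
                for ax in range(3):
                    for d in (-1, 1):
                        q = (p[0] + d * (ax == 0), p[1] + d * (ax == 1),
                             p[2] + d * (ax == 2))
                        k = pos.get(q)
                        if k is not None and k not in seen:
                            seen.add(k)
                            stack.append(k)
            next_label += 1
    return labels


def _null_max_extent(
    tmap: TContrastMap,
    voxels: SubjectVoxelData,
    t_form: float,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """Max suprathreshold cluster extent under sign-flipped residuals."""
    if tmap.residuals is None or tmap.design is None:
        raise ValueError("t-map lacks residuals; refit with fit_glm")
    X = tmap.design.X
    c = tmap.contrast.weights
    XtX_inv = np.linalg.inv(X.T @ X)
    proj = XtX_inv @ X.T
    cvar = float(c @ XtX_inv @ c)
    df = tmap.df
    R = tmap.residuals
    rng = np.random.default_rng(seed)
    out = np.empty(n_permutations)
    for p in range(n_permutations):
        s = rng.choice([-1.0, 1.0], size=R.shape[0])
        Yp = R * s[:, None]
        beta = proj @ Yp
        resp = Yp - X @ beta
        sigma2 = (resp ** 2).sum(0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            tnull = (c @ beta) / np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
        mask = tnull > t_form
        if not mask.any():
            out[p] = 0
            continue
        labels = _clusters_from_mask(mask, voxels, tmap.node_slices)
        sizes = np.bincount(labels)[1:]
        out[p] = sizes.max() if len(sizes) else 0
    return out


def threshold_individual(
    tmap: TContrastMap,
    method: str = "uncorrected_p05",
    voxels: SubjectVoxelData | None = None,
    cluster_forming_p: float = 0.01,
    n_permutations: int = 200,
    seed: int = 0,
) -> ThresholdedMap:
    """Threshold an individual t-map.

    ``uncorrected_p05``: one-sided p < .05 voxel-wise.  ``cluster_corrected
    _p05``: clusters formed at one-sided ``cluster_forming_p``; a cluster
    survives if its extent exceeds the 95th percentile of the max-extent
    null distribution obtained from sign-flip permutations of the GLM
    residuals.  The corrected mask is always a subset of the uncorrected
    one (the forming threshold is stricter than p < .05).
    """
    if method not in THRESHOLD_METHODS:
        raise ValueError(f"unknown thresholding method {method!r}")
    if tmap.df <= 0:
        raise ValueError("degrees of freedom must be positive")
    t05 = stats.t.ppf(0.95, tmap.df)
    if method == "uncorrected_p05":
        mask = tmap.t > t05
        labels = np.zeros(len(mask), int)
        if voxels is not None:
            labels = _clusters_from_mask(mask, voxels, tmap.node_slices)
        return ThresholdedMap(mask, labels, method, tmap.node_slices)
    if voxels is None:
        raise ValueError("cluster correction needs voxel geometry")
    t_form = stats.t.ppf(1.0 - cluster_forming_p, tmap.df)
    mask_form = tmap.t > t_form
    labels = _clusters_from_mask(mask_form, voxels, tmap.node_slices)
    null_ext = _null_max_extent(tmap, voxels, t_form, n_permutations, seed)
    crit = np.quantile(null_ext, 0.95)
    sizes = np.bincount(labels)
    keep = np.zeros(len(mask_form), bool)
    for lab in range(1, labels.max() + 1):
        if sizes[lab] > crit:
            keep |= labels == lab
    labels_out = np.where(keep, labels, 0)
    return ThresholdedMap(keep, labels_out, method, tmap.node_slices)


# ---------------------------------------------------------------------------
# Eigenvariate and node time-series extraction

def first_eigenvariate(Y: np.ndarray) -> np.ndarray:
    """Leading singular component of a (time x voxel) matrix.

    The component is scaled to the root-mean-square amplitude of the input
    signals and sign-aligned so that its correlation with the voxel-mean
    series is nonnegative; invariant to voxel ordering.
    """
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 1:
        raise ValueError("need a (time x voxel) matrix with >= 2 time points")
    if not np.any(Y):
        raise ValueError("all-zero matrix has no eigenvariate")
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    u = U[:, 0] * S[0]
    rms = np.sqrt((Y ** 2).sum() / Y.shape[1])
    e = u / np.linalg.norm(u) * rms
    mean_series = Y.mean(1)
    if float(e @ mean_series) < 0:
        e = -e
    return e


@dataclass(frozen=True)
class NodeTimeSeriesSet:
    """Per-node eigenvariate series for one subject, plus qualification."""

    series: np.ndarray | None  # (volumes, nodes) or None if excluded
    peak_coords_mm: np.ndarray | None
    voxel_counts: tuple[int, ...]
    qualified: bool
    exclusion_reason: str | None
    node_names: tuple[str, ...]
    tr_seconds: float
    subject_id: str = ""

    def to_tsv(self, path) -> None:
        if self.series is None:
            raise ValueError("excluded subject has no series")
        pd.DataFrame(self.series, columns=list(self.node_names)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, tr_seconds: float,
                 subject_id: str = "") -> "NodeTimeSeriesSet":
        """Load externally extracted node series (time x node table with a
        header row of node names); the subject is taken as qualified."""
        df = pd.read_csv(path, sep="\t")
        return cls(
            series=df.to_numpy(float),
            peak_coords_mm=None,
            voxel_counts=(),
            qualified=True,
            exclusion_reason=None,
            node_names=tuple(df.columns),
            tr_seconds=tr_seconds,
            subject_id=subject_id,
        )


def extract_node_series(
    voxels: SubjectVoxelData,
    tmap: TContrastMap,
    thresholded: ThresholdedMap,
    template: ROITemplate,
    use_voxel_mean: bool = False,
    subject_id: str = "",
) -> NodeTimeSeriesSet:
    """Extract one representative series per node, or mark the subject
    excluded.

    Per node: intersect the 10-mm group sphere (the node's voxel cloud)
    with the suprathreshold mask; an empty intersection excludes the
    subject.  The maximal-t voxel of the intersection becomes the
    individual peak; suprathreshold voxels within 4 mm of it contribute to
    the first eigenvariate (or plain voxel mean if ``use_voxel_mean``).
    """
    T = voxels.n_volumes
    series = np.empty((T, voxels.n_nodes))
    peaks = np.empty((voxels.n_nodes, 3))
    counts = []
    for j, sl in enumerate(thresholded.node_slices):
        mask = thresholded.mask[sl]
        if not mask.any():
            return NodeTimeSeriesSet(
                series=None,
                peak_coords_mm=None,
                voxel_counts=(),
                qualified=False,
                exclusion_reason=(
                    f"no suprathreshold voxels in group sphere of "
                    f"{voxels.node_names[j]}"
                ),
                node_names=voxels.node_names,
                tr_seconds=voxels.tr_seconds,
                subject_id=subject_id,
            )
        t_node = tmap.t[sl]
        cand = np.where(mask, t_node, -np.inf)
        peak_idx = int(np.argmax(cand))
        peak = voxels.coords_mm[j][peak_idx]
        d = np.linalg.norm(voxels.coords_mm[j] - peak, axis=1)
        inner = mask & (d <= template.individual_radius_mm)
        Y = voxels.bold[j][:, inner]
        series[:, j] = Y.mean(1) if use_voxel_mean else first_eigenvariate(Y)
        peaks[j] = peak
        counts.append(int(inner.sum()))
    return NodeTimeSeriesSet(
        series=series,
        peak_coords_mm=peaks,
        voxel_counts=tuple(counts),
        qualified=True,
        exclusion_reason=None,
        node_names=voxels.node_names,
        tr_seconds=voxels.tr_seconds,
        subject_id=subject_id,
    )
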