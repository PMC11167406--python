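"""Orchestration of the processing-condition grid over a synthetic cohort.

One cohort is simulated once and then processed under every combination of
the four analysis factors — global signal regression (with/without), GLM
design (AllTrials / STrials / Blocks), activation contrast used for node
extraction and modulatory input (Anti / Anti+Pro), and individual
significance thresholding (corrected / uncorrected) — a 2 x 3 x 2 x 2 = 24
condition grid.  Per condition the full first-level + DCM + group-PEB
pipeline runs; conditions can then be compared pairwise by between-group
PEB (connectivity differences) and Bayesian data comparison (parameter
certainty).  Inversion results are cached by content hash so conditions
that yield identical extracted series reuse each other's model fits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import dcm as dcm_mod
from . import firstlevel as fl
from . import peb as peb_mod
from .config import PipelineConfig, config_hash
from .protocol import (
    BehavioralRecord,
    TaskProtocol,
    generate_protocol,
    simulate_behavior,
    stimulus_functions,
)
from .rois import ROITemplate


@dataclass(frozen=True)
class Condition:
    gsr: str  # "with" | "without"
    design: str  # "AllTrials" | "STrials" | "Blocks"
    contrast: str  # "Anti" | "AntiPlusPro"
    thresholding: str  # "corrected" | "uncorrected"

    @property
    def name(self) -> str:
        return f"{self.gsr}GSR_{self.design}_{self.contrast}_{self.thresholding}"


@dataclass(frozen=True)
class ConditionGrid:
    conditions: tuple[Condition, ...]

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)


_FACTOR_LEVELS = {
    "gsr": ("with", "without"),
    "design": ("AllTrials", "STrials", "Blocks"),
    "contrast": ("Anti", "AntiPlusPro"),
    "thresholding": ("corrected", "uncorrected"),
}


def enumerate_conditions(config: PipelineConfig | None = None) -> ConditionGrid:
    """Full factorial of processing conditions, in stable order
    (gsr-major, then design, contrast, thresholding)."""
    g = config.grid if config is not None else None
    levels = {
        "gsr": g.gsr_levels if g else _FACTOR_LEVELS["gsr"],
        "design": g.design_levels if g else _FACTOR_LEVELS["design"],
        "contrast": g.contrast_levels if g else _FACTOR_LEVELS["contrast"],
        "thresholding": g.thresholding_levels if g else _FACTOR_LEVELS["thresholding"],
    }
    for factor, lv in levels.items():
        for item in lv:
            if item not in _FACTOR_LEVELS[factor]:
                raise ValueError(f"unknown {factor} level {item!r}")
    conds = tuple(
        Condition(gsr=a, design=b, contrast=c, thresholding=d)
        for a, b, c, d in product(
            levels["gsr"], levels["design"], levels["contrast"],
            levels["thresholding"],
        )
    )
    return ConditionGrid(conditions=conds)


@dataclass
class CohortData:
    """A simulated cohort plus everything needed to reprocess it."""

    protocol: TaskProtocol
    behaviors: list[BehavioralRecord]
    subjects: list[cohort_mod.SimulatedSubject]
    template: ROITemplate
    config: PipelineConfig
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.subjects:
            h.update(np.ascontiguousarray(s.node_bold).tobytes())
        return h.hexdigest()[:16]


def simulate_src_cohort(
    config: PipelineConfig | None = None, seed: int | None = None
) -> CohortData:
    """Simulate one cohort under the configured ground truth.

    The generative modulatory input follows ``config.truth_design`` and
    ``config.truth_contrast`` (event-locked Anti modulation by default).
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    protocol = generate_protocol(config.protocol, seed=seed)
    behaviors = [
        simulate_behavior(protocol, config.error_rate, config.rt,
                          seed=seed + 10_000 + i)
        for i in range(config.group.n_subjects)
    ]
    truth_stim = stimulus_functions(
        protocol, None, design_type=config.truth_design,
        modulatory_contrast=config.truth_contrast,
    )
    template = ROITemplate()
    group = config.group.build()
    subjects = cohort_mod.simulate_cohort(
        group, truth_stim, template, protocol.tr_seconds, protocol.n_volumes,
        hparams=config.hemo, seed=seed,
    )
    return CohortData(
        protocol=protocol,
        behaviors=behaviors,
        subjects=subjects,
        template=template,
        config=config,
        seed=seed,
    )


@dataclass
class ConditionResult:
    condition: Condition
    series: list[fl.NodeTimeSeriesSet]
    posteriors: list[dcm_mod.DCMPosterior]  # EV-qualified
    extraction_qualified: int
    ev_qualified: int
    peb: peb_mod.PEBPosterior | None
    exclusions: pd.DataFrame
    errors: list[str] = field(default_factory=list)

    @property
    def evident_edges(self) -> int:
        return (
            peb_mod.count_evident_edges(self.peb) if self.peb is not None else 0
        )


class InversionCache(dict):
    """Content-addressed cache of subject inversions."""

    @staticmethod
    def key(series: np.ndarray, stim_mod: np.ndarray, stim_drv: np.ndarray,
            extra: str = "") -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(series).tobytes())
        h.update(np.ascontiguousarray(stim_mod).tobytes())
        h.update(np.ascontiguousarray(stim_drv).tobytes())
        h.update(extra.encode())
        return h.hexdigest()


def run_condition(
    cohort: CohortData,
    condition: Condition,
    config: PipelineConfig | None = None,
    cache: InversionCache | None = None,
    fit_group: bool = True,
) -> ConditionResult:
    """Run the full pipeline for one processing condition.

    Per subject: nuisance regression (GSR per the condition) and high-pass
    filtering, GLM with the condition's design, t-map for the condition's
    contrast, individual thresholding, node extraction, DCM inversion with
    the matching stimulus binding, then the explained-variance filter;
    finally a single-group PEB over the surviving subjects.  Stage errors
    are recorded per subject and the run continues.
    """
    config = config or cohort.config
    cache = cache if cache is not None else InversionCache()
    gsr = condition.gsr == "with"
    method = (
        "cluster_corrected_p05"
        if condition.thresholding == "corrected"
        else "uncorrected_p05"
    )
    series_list: list[fl.NodeTimeSeriesSet] = []
    posteriors: list[dcm_mod.DCMPosterior] = []
    errors: list[str] = []
    excl_rows = []

    design_cache: dict[int, fl.DesignMatrix] = {}
    for i, subj in enumerate(cohort.subjects):
        sid = subj.subject_id
        try:
            vox = fl.preprocess_timeseries(
                subj.voxels, gsr=gsr,
                highpass_cutoff_s=config.glm.highpass_cutoff_s,
            )
            behavior = cohort.behaviors[i]
            key = i if condition.design == "STrials" else -1
            if key not in design_cache:
                design_cache[key] = fl.build_design(
                    cohort.protocol, behavior, condition.design
                )
            design = design_cache[key]
            contrast = fl.make_contrast(design, condition.contrast)
            tmap = fl.fit_glm(vox, design, contrast,
                              prewhiten_ar1=config.glm.prewhiten_ar1)
            thr = fl.threshold_individual(
                tmap, method, voxels=vox,
                cluster_forming_p=config.glm.cluster_forming_p,
                n_permutations=config.glm.n_permutations,
                seed=cohort.seed + 77_000 + i,
            )
            nts = fl.extract_node_series(
                vox, tmap, thr, cohort.template, subject_id=sid
            )
            series_list.append(nts)
            if not nts.qualified:
                excl_rows.append(
                    {"subject": sid, "stage": "extraction",
                     "reason": nts.exclusion_reason}
                )
                continue
            stim = stimulus_functions(
                cohort.protocol, behavior,
                design_type=condition.design,
                modulatory_contrast=condition.contrast,
            )
            ckey = InversionCache.key(
                nts.series, stim.modulatory_u, stim.driving_u,
                extra=json.dumps(dataclasses.asdict(config.priors))
                + json.dumps(dataclasses.asdict(config.vl)),
            )
            if ckey in cache:
                post = dataclasses.replace(cache[ckey], subject_id=sid)
            else:
                spec = dcm_mod.specify_full_model(
                    cohort.template, stim,
                    tr_seconds=cohort.protocol.tr_seconds,
                    hparams=config.hemo,
                )
                post = dcm_mod.invert_vl(
                    nts, spec, priors=config.priors, opts=config.vl
                )
                cache[ckey] = post
            posteriors.append(post)
        except Exception as exc:  # keep processing the remaining subjects
            errors.append(f"{sid}: {exc}")
            excl_rows.append({"subject": sid, "stage": "error", "reason": str(exc)})

    kept, ev_log = dcm_mod.qualify_subjects(
        posteriors, threshold=config.ev_threshold_percent
    )
    for row in ev_log.itertuples():
        if not row.qualified:
            excl_rows.append(
                {"subject": row.subject, "stage": "ev", "reason": row.reason}
            )
    peb = None
    if fit_group and len(kept) >= 2:
        peb = peb_mod.peb_fit(kept, parameter_selection="B")
    return ConditionResult(
        condition=condition,
        series=series_list,
        posteriors=kept,
        extraction_qualified=sum(1 for s in series_list if s.qualified),
        ev_qualified=len(kept),
        peb=peb,
        exclusions=pd.DataFrame(
            excl_rows, columns=["subject", "stage", "reason"]
        ),
        errors=errors,
    )


def run_grid(
    cohort: CohortData,
    conditions: ConditionGrid | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, ConditionResult]:
    config = config or cohort.config
    conditions = conditions or enumerate_conditions(config)
    cache = InversionCache()
    return {
        c.name: run_condition(cohort, c, config, cache=cache)
        for c in conditions
    }


def compare_conditions(
    results: dict[str, ConditionResult],
    pairs: Sequence[tuple[str, str]],
    mode: str = "peb",
) -> pd.DataFrame:
    """Pairwise condition comparisons.

    ``mode="peb"``: between-group PEB difference effects with PP per edge
    (one row per pair x edge).  ``mode="bdc"``: certainty difference in
    nats over common EV-qualified subjects (one row per pair).  Note the
    two "groups" are the same cohort processed twice; the induced
    dependence is not modelled.
    """
    rows = []
    for a, b in pairs:
        ra, rb = results[a], results[b]
        if mode == "bdc":
            res = peb_mod.bdc_compare(ra.posteriors, rb.posteriors)
            rows.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "nats": res.certainty_diff_nats,
                    "evidence_class": res.evidence_class,
                    "n_common": res.n_subjects,
                }
            )
        elif mode == "peb":
            peb = peb_mod.peb_between(ra.posteriors, rb.posteriors)
            sl = peb.covariate_slice("group")
            for nm, est, pp in zip(
                peb.parameter_names, peb.mu[sl], peb.pp[sl]
            ):
                rows.append(
                    {
                        "condition_a": a,
                        "condition_b": b,
                        "effect": nm,
                        "estimate": est,
                        "pp": pp,
                    }
                )
        else:
            raise ValueError(f"unknown comparison mode {mode!r}")
    return pd.DataFrame(rows)


def run_report(
    results: dict[str, ConditionResult],
    cohort: CohortData,
) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "condition": name,
                "extraction_qualified": r.extraction_qualified,
                "ev_qualified": r.ev_qualified,
                "evident_edges": r.evident_edges,
                "mean_abs_mec": (
                    peb_mod.mean_abs_evident(r.peb) if r.peb is not None else np.nan
                ),
                "n_errors": len(r.errors),
            }
        )
    df = pd.DataFrame(rows)
    bad = df["ev_qualified"] > df["extraction_qualified"]
    if bad.any():
        raise AssertionError("EV-qualified n exceeded extraction-qualified n")
    return df


def report(
    results: dict[str, ConditionResult],
    out_dir,
    cohort: CohortData,
    comparisons: pd.DataFrame | None = None,
    make_figures: bool = False,
) -> dict[str, str]:
    """Write CSV tables and a JSON summary of a grid run."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    files = {}
    table = run_report(results, cohort)
    p = out / "condition_summary.csv"
    table.to_csv(p, index=False)
    files["condition_summary"] = str(p)

    edges_rows = []
    for name, r in results.items():
        if r.peb is None:
            continue
        sl = r.peb.covariate_slice("mean")
        for nm, est, pp in zip(r.peb.parameter_names, r.peb.mu[sl], r.peb.pp[sl]):
            if nm.startswith("B") and "->" in nm:
                src, tgt = nm.split(":", 1)[1].split("->")
                if src != tgt and pp > 0.95:
                    edges_rows.append(
                        {"condition": name, "from": src, "to": tgt,
                         "value": est, "PP": pp}
                    )
    p = out / "evident_edges.csv"
    pd.DataFrame(edges_rows, columns=["condition", "from", "to", "value", "PP"]
                 ).to_csv(p, index=False)
    files["evident_edges"] = str(p)

    if comparisons is not None:
        p = out / "comparisons.csv"
        comparisons.to_csv(p, index=False)
        files["comparisons"] = str(p)

    excl = pd.concat(
        [r.exclusions.assign(condition=name) for name, r in results.items()],
        ignore_index=True,
    )
    p = out / "exclusions.csv"
    excl.to_csv(p, index=False)
    files["exclusions"] = str(p)

    summary = {
        "seed": cohort.seed,
        "config_hash": config_hash(cohort.config),
        "cohort_hash": cohort.content_hash(),
        "n_subjects": cohort.n_subjects,
        "conditions": {
            name: {
                "extraction_qualified": r.extraction_qualified,
                "ev_qualified": r.ev_qualified,
                "evident_edges": r.evident_edges,
            }
            for name, r in results.items()
        },
    }
    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2)
    files["summary"] = str(p)

    if make_figures:
        files.update(_figures(results, out))
    return files


def _figures(results, out: Path) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = {}
    names = list(results)
    counts = [results[n].evident_edges for n in names]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * len(names))))
    ax.barh(names, counts)
    ax.set_xlabel("evident modulatory edges (PP > 95%)")
    fig.tight_layout()
    p = out / "evident_edges.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    files["figure_edges"] = str(p)
    return files
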