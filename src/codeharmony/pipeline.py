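"""End-to-end orchestration: detect -> embed -> align -> map -> validate.

`harmonize` is the in-memory engine used by the CLI, the test harness and
the reproduction script; `run_pipeline` is its file-based wrapper that
writes one artifact per stage plus a run manifest.  One seed controls the
generator, the CV folds, and every other stochastic step.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import (AlignmentMap, apply_alignment, projection_align,
                    rotation_align, select_anchors, within_group_similarity)
from .confusion import ValidationReport, baseline_overlap_auc, site_auc
from .detect import (bonferroni_adjust, fit_null_model,
                     pooled_group_tests, smoothed_frequency_ratio,
                     weighted_rate_tests)
from .embed import EmbeddingSet, site_embeddings
from .mapping import (HarmonizationOperator, MappingSpec, SimilarityMatrix,
                      apply_harmonizer, build_harmonizer,
                      directional_similarity, frequency_refine,
                      regression_similarity, select_threshold_cv, select_topk)
from .store import (CodeMatrix, CovariateTable, EventTable, GroupCatalog,
                    patient_code_matrix, read_code_groups, read_covariates,
                    read_events, summarize_frequencies, write_code_groups,
                    write_covariates, write_events)
from .synth import SCENARIOS, generate_cohort

logger = logging.getLogger(__name__)

#: Named method variants: alignment x similarity.
METHODS = {
    "rads": ("rotation", "DS"),
    "pads": ("projection", "DS"),
    "rars": ("rotation", "RS"),
}


@dataclass
class RunConfig:
    """Flat configuration with defaults matching the module-level choices."""

    events_a: str = ""
    covars_a: str = ""
    events_b: str = ""
    covars_b: str = ""
    groups: str = ""
    out_dir: str = "run"
    min_frequency: int = 10
    window_days: int = 30
    dimension: int = 20
    pmi_mode: str = "PMI"
    pmi_shift: float = 1.0
    method: str = "rads"
    align_ridge: float = 1e-6
    map_ridge: float = 1e-6
    refine_gamma: float = 0.5
    selection: str = "top1"  # top1 | top2 | topK | threshold
    K: int = 2
    cv_folds: int = 5
    validate_folds: int = 5
    feature_transform: str = "log1p_count"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        canon = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class HarmonizationResult:
    embeddings: dict[str, EmbeddingSet]
    alignment: AlignmentMap
    similarity: SimilarityMatrix
    spec: MappingSpec
    operator: HarmonizationOperator
    validation_vocab: list[str]
    baseline: ValidationReport
    harmonized: ValidationReport
    diagnostics: dict = field(default_factory=dict)


def detect_report(
    events_a: EventTable,
    covars_a: CovariateTable,
    events_b: EventTable,
    covars_b: CovariateTable,
    groups: GroupCatalog,
    kappa: int = 10,
) -> pd.DataFrame:
    """Code-level ratios + weighted t-tests and group-level burden/SKAT,
    Bonferroni-adjusted within each family (codes vs groups)."""
    freq_a = summarize_frequencies(events_a, covars_a)
    freq_b = summarize_frequencies(events_b, covars_b)
    vocab = sorted(set(freq_a.frame.index) | set(freq_b.frame.index))
    Xa = patient_code_matrix(events_a, covars_a, vocab, "count")
    Xb = patient_code_matrix(events_b, covars_b, vocab, "count")
    counts = np.vstack([Xa.values, Xb.values])
    pt = np.r_[covars_a.person_time.to_numpy(), covars_b.person_time.to_numpy()]
    rates = counts / pt[:, None]
    site = np.r_[np.ones(len(Xa.patients)), np.zeros(len(Xb.patients))]
    Z = np.vstack(
        [covars_a.design_matrix(True), covars_b.design_matrix(True)]
    )
    tres = weighted_rate_tests(rates, site, Z, pt, codes=vocab)
    code_rows = pd.DataFrame(
        {
            "unit": vocab,
            "kind": "weighted_t",
            "statistic": tres["t"].to_numpy(),
            "p": tres["p"].to_numpy(),
            "p_adj": bonferroni_adjust(tres["p"].to_numpy()),
            "ratio": [
                smoothed_frequency_ratio(
                    freq_a.frequency(c), freq_b.frequency(c),
                    freq_a.person_time, freq_b.person_time, kappa
                ).ratio
                for c in vocab
            ],
        }
    )
    null = fit_null_model(Z, site)
    G = CodeMatrix(values=counts, patients=list(Xa.patients) + list(Xb.patients),
                   vocabulary=vocab, transform="count")
    gres = pooled_group_tests(null, G, groups)
    group_rows = pd.DataFrame(
        {
            "unit": [r.unit for r in gres],
            "kind": [r.kind for r in gres],
            "statistic": [r.statistic for r in gres],
            "p": [r.p for r in gres],
            "ratio": [
                smoothed_frequency_ratio(
                    sum(freq_a.frequency(c) for c in groups.members(r.unit)),
                    sum(freq_b.frequency(c) for c in groups.members(r.unit)),
                    freq_a.person_time, freq_b.person_time, kappa
                ).ratio
                for r in gres
            ],
        }
    )
    for kind in ("burden_score", "skat_Q"):
        sel = group_rows["kind"] == kind
        group_rows.loc[sel, "p_adj"] = bonferroni_adjust(group_rows.loc[sel, "p"].to_numpy())
    return pd.concat([code_rows, group_rows], ignore_index=True)


def mappable_reference_vocab(
    source_vocab: list[str], reference_vocab: list[str], groups: GroupCatalog
) -> list[str]:
    """Reference codes whose clinical group contains at least one source
    code: the universe on which harmonization can act, and hence the fair
    universe for the confusion check (site-exclusive ungrouped codes would
    trivially identify their site)."""
    source_groups = {groups.group_of(c) for c in source_vocab}
    return [
        c
        for c in reference_vocab
        if groups.group_of(c) in source_groups or c in set(source_vocab)
    ]


def harmonize(
    events_src: EventTable,
    covars_src: CovariateTable,
    events_ref: EventTable,
    covars_ref: CovariateTable,
    groups: GroupCatalog,
    min_frequency: int = 10,
    window_days: int = 30,
    dimension: int = 20,
    pmi_mode: str = "PMI",
    pmi_shift: float = 1.0,
    method: str = "rads",
    align_ridge: float = 1e-6,
    map_ridge: float = 1e-6,
    refine_gamma: float = 0.5,
    selection: str = "top1",
    K: int = 2,
    cv_folds: int = 5,
    validate_folds: int = 5,
    seed: int = 0,
) -> HarmonizationResult:
    """Embed -> align -> map -> validate for a source site against a
    reference site.  The reference embedding is never transformed."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(METHODS)}")
    align_kind, sim_kind = METHODS[method]
    freq_src = summarize_frequencies(events_src, covars_src)
    freq_ref = summarize_frequencies(events_ref, covars_ref)
    vocab_src = freq_src.nonrare_codes(min_frequency)
    vocab_ref = freq_ref.nonrare_codes(min_frequency)
    E_src = site_embeddings(events_src, vocab_src, window_days,
                            min(dimension, len(vocab_src)), pmi_mode, pmi_shift)
    E_ref = site_embeddings(events_ref, vocab_ref, window_days,
                            min(dimension, len(vocab_ref)), pmi_mode, pmi_shift)
    # positive-spectrum rank can differ between sites; truncate to common d
    d_common = min(E_src.dimension, E_ref.dimension)
    for E in (E_src, E_ref):
        if E.dimension > d_common:
            E.V = E.V[:, :d_common]
            E.dimension = d_common
    anchors = select_anchors(E_src, E_ref)
    if align_kind == "rotation":
        amap = rotation_align(E_src, E_ref, anchors)
    else:
        amap = projection_align(E_src, E_ref, anchors, ridge=align_ridge)
    E_src_aligned = apply_alignment(E_src, amap)
    wgs_before = within_group_similarity(E_src, E_ref, groups)
    wgs_after = within_group_similarity(E_src_aligned, E_ref, groups)
    if sim_kind == "DS":
        sim = directional_similarity(E_src_aligned, E_ref, groups)
    else:
        sim = regression_similarity(E_src_aligned, E_ref, groups, ridge=map_ridge)
    if refine_gamma > 0:
        sim = frequency_refine(sim, freq_src, freq_ref, gamma=refine_gamma)

    val_vocab = mappable_reference_vocab(vocab_src, vocab_ref, groups)
    X_src_counts = patient_code_matrix(events_src, covars_src, vocab_src, "count")
    X_ref_counts = patient_code_matrix(events_ref, covars_ref, val_vocab, "count")

    if selection == "threshold":
        tau, spec = select_threshold_cv(
            sim, X_src_counts, X_ref_counts,
            folds=cv_folds, seed=seed, ref_freq=freq_ref,
        )
    else:
        k = 1 if selection == "top1" else (2 if selection == "top2" else K)
        spec = select_topk(sim, k, ref_freq=freq_ref)
    operator = build_harmonizer(spec, sim)
    harmonized_counts = apply_harmonizer(X_src_counts, operator)
    X_src_val = _log1p(_restrict(harmonized_counts, val_vocab))
    X_ref_val = _log1p(X_ref_counts)
    harmonized_report = site_auc(X_ref_val, X_src_val, folds=validate_folds, seed=seed)
    baseline_report = baseline_overlap_auc(
        events_src, events_ref, covars_src, covars_ref,
        vocab=val_vocab, folds=validate_folds, seed=seed,
    )
    return HarmonizationResult(
        embeddings={"source": E_src, "reference": E_ref, "source_aligned": E_src_aligned},
        alignment=amap,
        similarity=sim,
        spec=spec,
        operator=operator,
        validation_vocab=val_vocab,
        baseline=baseline_report,
        harmonized=harmonized_report,
        diagnostics={
            "within_group_similarity_before": wgs_before,
            "within_group_similarity_after": wgs_after,
            "anchors": len(anchors.codes),
        },
    )


def _restrict(X: CodeMatrix, vocab: list[str]) -> CodeMatrix:
    idx = {c: j for j, c in enumerate(X.vocabulary)}
    cols = [idx[c] for c in vocab if c in idx]
    values = X.values[:, cols]
    present = [c for c in vocab if c in idx]
    missing = [c for c in vocab if c not in idx]
    if missing:  # pad absent codes with zero columns, preserving order
        values = np.zeros((X.values.shape[0], len(vocab)))
        for j, c in enumerate(vocab):
            if c in idx:
                values[:, j] = X.values[:, idx[c]]
        present = list(vocab)
    return CodeMatrix(values=values, patients=X.patients, vocabulary=present,
                      transform=X.transform)


def _log1p(X: CodeMatrix) -> CodeMatrix:
    return CodeMatrix(values=np.log1p(X.values), patients=X.patients,
                      vocabulary=X.vocabulary, transform="log1p_count")


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------


def run_synthesize(scenario: str, out_dir: str | Path, n_patients: int = 1000,
                   seed: int = 0) -> Path:
    """Write one scenario's fixture directory: per-site events/covariates
    CSVs, the group catalog, and ground_truth.json."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; options: {sorted(SCENARIOS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SCENARIOS[scenario](n_patients=n_patients, seed=seed)
    ev_a, cov_a, ev_b, cov_b, truth = generate_cohort(config)
    write_events(ev_a, out / "events_a.csv")
    write_events(ev_b, out / "events_b.csv")
    write_covariates(cov_a, out / "covariates_a.csv")
    write_covariates(cov_b, out / "covariates_b.csv")
    write_code_groups(config.group_catalog(), out / "groups.csv")
    (out / "ground_truth.json").write_text(truth.to_json())
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full detect/embed/align/map/validate sequence on the
    configured inputs, writing one artifact per stage plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load"
    try:
        events_a = read_events(config.events_a, "A")
        covars_a = read_covariates(config.covars_a)
        events_b = read_events(config.events_b, "B")
        covars_b = read_covariates(config.covars_b)
        groups = read_code_groups(config.groups)

        stage = "detect"
        report = detect_report(events_a, covars_a, events_b, covars_b, groups)
        report.to_csv(out / "detect_report.csv", index=False)

        stage = "harmonize"
        result = harmonize(
            events_a, covars_a, events_b, covars_b, groups,
            min_frequency=config.min_frequency,
            window_days=config.window_days,
            dimension=config.dimension,
            pmi_mode=config.pmi_mode,
            pmi_shift=config.pmi_shift,
            method=config.method,
            align_ridge=config.align_ridge,
            map_ridge=config.map_ridge,
            refine_gamma=config.refine_gamma,
            selection=config.selection,
            K=config.K,
            cv_folds=config.cv_folds,
            validate_folds=config.validate_folds,
            seed=config.seed,
        )
        stage = "write_artifacts"
        for name, E in result.embeddings.items():
            E.to_frame().to_csv(out / f"embedding_{name}.csv")
        pd.DataFrame(result.alignment.T).to_csv(out / "alignment.csv", index=False)
        (out / "alignment.json").write_text(json.dumps({
            "method": result.alignment.method,
            "objective": result.alignment.objective,
            "n_anchors": result.alignment.n_anchors,
            "ridge": result.alignment.ridge,
        }, indent=2))
        rows = [
            {"source_code": s, "reference_code": r, "similarity": v, "rank": k + 1,
             "selected_by": result.spec.rule}
            for s, sel in sorted(result.spec.selections.items())
            for k, (r, v) in enumerate(sel)
        ]
        pd.DataFrame(rows).to_csv(out / "mapping.csv", index=False)
        op = result.operator
        nz = np.argwhere(op.M > 0)
        pd.DataFrame(
            {
                "source_code": [op.source_vocab[i] for i, _ in nz],
                "reference_code": [op.reference_vocab[j] for _, j in nz],
                "weight": [op.M[i, j] for i, j in nz],
            }
        ).to_csv(out / "operator.csv", index=False)
        (out / "validation.json").write_text(json.dumps({
            "baseline": result.baseline.__dict__,
            "harmonized": result.harmonized.__dict__,
            "diagnostics": result.diagnostics,
        }, indent=2))
        manifest = {
            "config": config.__dict__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "wall_time_s": round(time.time() - t0, 3),
            "artifacts": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
                for p in sorted(out.iterdir())
                if p.is_file() and p.name != "manifest.json"
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
    return out
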