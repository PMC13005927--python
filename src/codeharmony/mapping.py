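"""Cross-site code similarity, mapping selection, and the harmonization
operator.

Candidate targets for a source code are the reference-vocabulary members
of its own clinical group (codes with no group are candidates only for
themselves), so mappings never jump across clinical categories.  Three
similarity flavors are supported:

* directional (DS): cosine between the aligned source vector and each
  candidate's reference vector — an unadjusted association;
* regression (RS): ridge coefficients of the source vector on all of its
  candidates jointly — each candidate's association adjusted for the
  others in the category;
* frequency-refined: either similarity damped by how far apart the two
  codes' population coding rates are, exp(-gamma |log rate ratio|).

Selection is top-K or a global threshold tuned by cross-validation against
the domain-confusion criterion (site-classifier AUC as close to 0.5 as
possible).  The selected mapping becomes a nonnegative row-stochastic
operator M; harmonized source data is simply X @ M, which conserves each
patient's mapped count mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import DEFAULT_KAPPA
from .embed import EmbeddingSet
from .store import UNGROUPED, CodeMatrix, FrequencyTable, GroupCatalog


@dataclass
class SimilarityMatrix:
    """Masked source x reference similarity; entries outside the candidate
    mask are NaN."""

    source_vocab: list[str]
    reference_vocab: list[str]
    values: np.ndarray  # NaN where not a candidate
    kind: str  # "DS" | "RS" | "refined_DS" | "refined_RS"

    def candidates(self, source_code: str) -> list[str]:
        i = self.source_vocab.index(source_code)
        cols = np.flatnonzero(~np.isnan(self.values[i]))
        return [self.reference_vocab[j] for j in cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.source_vocab, columns=self.reference_vocab)


@dataclass
class MappingSpec:
    """Per source code, the selected reference codes in descending
    similarity order."""

    selections: dict[str, list[tuple[str, float]]]
    rule: str  # "topK" | "threshold"
    K: int | None = None
    tau: float | None = None

    def top1(self, source_code: str) -> str | None:
        sel = self.selections.get(source_code)
        return sel[0][0] if sel else None


@dataclass
class HarmonizationOperator:
    """Nonnegative row-stochastic source -> reference mapping matrix."""

    source_vocab: list[str]
    reference_vocab: list[str]
    M: np.ndarray
    unmapped: dict[str, str] = field(default_factory=dict)  # code -> policy applied

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.source_vocab, columns=self.reference_vocab)


def candidate_mask(
    source_vocab: list[str], reference_vocab: list[str], groups: GroupCatalog
) -> np.ndarray:
    """Boolean mask of same-clinical-category pairs; ungrouped codes are
    candidates only for their identically named reference code."""
    ref_idx = {c: j for j, c in enumerate(reference_vocab)}
    ref_groups = np.array([groups.group_of(c) for c in reference_vocab], dtype=object)
    mask = np.zeros((len(source_vocab), len(reference_vocab)), dtype=bool)
    for i, code in enumerate(source_vocab):
        g = groups.group_of(code)
        if g == UNGROUPED:
            if code in ref_idx:
                mask[i, ref_idx[code]] = True
        else:
            mask[i] = ref_groups == g
    return mask


def directional_similarity(
    E_src_aligned: EmbeddingSet,
    E_ref: EmbeddingSet,
    groups: GroupCatalog,
) -> SimilarityMatrix:
    """Cosine similarity on candidate pairs in the common space."""
    mask = candidate_mask(E_src_aligned.vocabulary, E_ref.vocabulary, groups)
    na = np.linalg.norm(E_src_aligned.V, axis=1)
    nb = np.linalg.norm(E_ref.V, axis=1)
    dead_src = [c for c, z in zip(E_src_aligned.vocabulary, na) if z == 0]
    if dead_src:
        warnings.warn(f"zero-norm embedding rows; similarity undefined for {dead_src}")
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = (E_src_aligned.V @ E_ref.V.T) / np.outer(na, nb)
    values = np.where(mask, cos, np.nan)
    return SimilarityMatrix(
        source_vocab=list(E_src_aligned.vocabulary),
        reference_vocab=list(E_ref.vocabulary),
        values=values,
        kind="DS",
    )


def regression_similarity(
    E_src_aligned: EmbeddingSet,
    E_ref: EmbeddingSet,
    groups: GroupCatalog,
    ridge: float = 0.0,
) -> SimilarityMatrix:
    """Per source code i, sigma_ij = beta_j from the ridge regression of
    x_i on its candidates' reference vectors jointly."""
    mask = candidate_mask(E_src_aligned.vocabulary, E_ref.vocabulary, groups)
    values = np.full(mask.shape, np.nan)
    for i, code in enumerate(E_src_aligned.vocabulary):
        cols = np.flatnonzero(mask[i])
        if cols.size == 0:
            continue
        Y = E_ref.V[cols]  # candidates x d
        x = E_src_aligned.V[i]
        gram = Y @ Y.T + ridge * np.eye(cols.size)
        if ridge == 0 and np.linalg.matrix_rank(gram) < cols.size:
            raise np.linalg.LinAlgError(
                f"collinear candidates for {code}; use ridge > 0"
            )
        beta = np.linalg.solve(gram, Y @ x)
        values[i, cols] = beta
    return SimilarityMatrix(
        source_vocab=list(E_src_aligned.vocabulary),
        reference_vocab=list(E_ref.vocabulary),
        values=values,
        kind="RS",
    )


def frequency_refine(
    sim: SimilarityMatrix,
    freq_src: FrequencyTable,
    freq_ref: FrequencyTable,
    gamma: float = 0.5,
    kappa: int = DEFAULT_KAPPA,
) -> SimilarityMatrix:
    """Damp similarities between codes whose population coding rates
    differ: sigma' = sigma * exp(-gamma |log(rate_src / rate_ref)|).

    Rates are smoothed with the same +kappa count used by the descriptive
    frequency ratio so zero-frequency codes stay finite.  gamma = 0 leaves
    the similarities unchanged; the multiplier never changes sign and is
    monotone decreasing in the absolute log rate ratio.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    rate_src = np.array(
        [(freq_src.frequency(c) + kappa) / freq_src.person_time for c in sim.source_vocab]
    )
    rate_ref = np.array(
        [(freq_ref.frequency(c) + kappa) / freq_ref.person_time for c in sim.reference_vocab]
    )
    logdiff = np.abs(np.log(rate_src)[:, None] - np.log(rate_ref)[None, :])
    values = sim.values * np.exp(-gamma * logdiff)
    return SimilarityMatrix(
        source_vocab=sim.source_vocab,
        reference_vocab=sim.reference_vocab,
        values=values,
        kind=f"refined_{sim.kind}",
    )


def _ordered_candidates(
    sim: SimilarityMatrix, i: int, ref_freq: FrequencyTable | None
) -> list[tuple[str, float]]:
    """Candidates of source row i sorted by similarity, ties broken by
    higher reference frequency then lexicographic code."""
    cols = np.flatnonzero(~np.isnan(sim.values[i]))
    entries = []
    for j in cols:
        code = sim.reference_vocab[j]
        f = ref_freq.frequency(code) if ref_freq is not None else 0
        entries.append((code, float(sim.values[i, j]), f))
    entries.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return [(c, s) for c, s, _ in entries]


def select_topk(
    sim: SimilarityMatrix, K: int, ref_freq: FrequencyTable | None = None
) -> MappingSpec:
    """Keep each source code's K most similar candidates (all of them if
    fewer than K exist)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    selections = {}
    for i, code in enumerate(sim.source_vocab):
        ordered = _ordered_candidates(sim, i, ref_freq)
        if ordered:
            selections[code] = ordered[:K]
    return MappingSpec(selections=selections, rule="topK", K=K)


def select_threshold(
    sim: SimilarityMatrix, tau: float, ref_freq: FrequencyTable | None = None
) -> MappingSpec:
    """Keep all candidates with similarity strictly above tau."""
    selections = {}
    for i, code in enumerate(sim.source_vocab):
        ordered = [(c, s) for c, s in _ordered_candidates(sim, i, ref_freq) if s > tau]
        if ordered:
            selections[code] = ordered
    return MappingSpec(selections=selections, rule="threshold", tau=tau)


def select_threshold_cv(
    sim: SimilarityMatrix,
    X_src: CodeMatrix,
    X_ref: CodeMatrix,
    folds: int = 5,
    grid: np.ndarray | None = None,
    seed: int = 0,
    ref_freq: FrequencyTable | None = None,
) -> tuple[float, MappingSpec]:
    """Data-driven threshold: for each candidate tau, harmonize the source
    data and score the cross-validated site-classifier AUC; choose the tau
    whose AUC is closest to 0.5 (smallest tau wins ties).  Deterministic
    given the seed.

    ``X_src`` holds source counts over the similarity's source vocabulary;
    ``X_ref`` holds reference counts over (a subset of) the reference
    vocabulary — the classifier runs on log1p counts of that subset.
    """
    from .confusion import site_auc  # local import to avoid a cycle

    finite = sim.values[~np.isnan(sim.values)]
    if grid is None:
        grid = np.unique(np.quantile(finite, np.linspace(0.0, 0.9, 10)))
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    ref_cols = {c: j for j, c in enumerate(sim.reference_vocab)}
    cols = [ref_cols[c] for c in X_ref.vocabulary]
    X_ref_log = CodeMatrix(np.log1p(X_ref.values), X_ref.patients,
                           list(X_ref.vocabulary), "log1p_count")
    best: tuple[float, float, MappingSpec] | None = None
    for tau in np.sort(grid):
        spec = select_threshold(sim, float(tau), ref_freq)
        if not spec.selections:
            continue
        op = build_harmonizer(spec, sim)
        harmonized = apply_harmonizer(X_src, op)
        H = CodeMatrix(np.log1p(harmonized.values[:, cols]), X_src.patients,
                       list(X_ref.vocabulary), "log1p_count")
        report = site_auc(X_ref_log, H, folds=folds, seed=seed)
        gap = abs(report.auc - 0.5)
        if best is None or gap < best[0] - 1e-12:
            best = (gap, float(tau), spec)
    if best is None:
        raise ValueError("no threshold on the grid selects any mapping")
    return best[1], best[2]


def build_harmonizer(
    spec: MappingSpec,
    sim: SimilarityMatrix,
    unmapped_policy: str = "identity-carry",
) -> HarmonizationOperator:
    """Row-stochastic operator from the selected mappings.

    Mapped rows weight their selected reference codes proportionally to
    max(similarity, 0).  Unmapped source codes either carry to the
    identically named reference code (if it exists) or drop to a zero row.
    """
    if unmapped_policy not in ("identity-carry", "drop"):
        raise ValueError("unmapped_policy must be identity-carry or drop")
    ref_idx = {c: j for j, c in enumerate(sim.reference_vocab)}
    M = np.zeros((len(sim.source_vocab), len(sim.reference_vocab)))
    unmapped: dict[str, str] = {}
    for i, code in enumerate(sim.source_vocab):
        weights = {}
        for ref, s in spec.selections.get(code, []):
            w = max(s, 0.0)
            if w > 0:
                weights[ref_idx[ref]] = w
        if weights:
            total = sum(weights.values())
            for j, w in weights.items():
                M[i, j] = w / total
        else:
            if spec.selections.get(code):
                warnings.warn(
                    f"all selected similarities nonpositive for {code}; "
                    f"falling back to {unmapped_policy}"
                )
            if unmapped_policy == "identity-carry" and code in ref_idx:
                M[i, ref_idx[code]] = 1.0
                unmapped[code] = "identity-carry"
            else:
                unmapped[code] = "drop"
    return HarmonizationOperator(
        source_vocab=list(sim.source_vocab),
        reference_vocab=list(sim.reference_vocab),
        M=M,
        unmapped=unmapped,
    )


def apply_harmonizer(X: CodeMatrix, op: HarmonizationOperator) -> CodeMatrix:
    """Harmonized features X @ M over the reference vocabulary; mapped rows
    conserve count mass because M is row-stochastic."""
    if X.vocabulary != op.source_vocab:
        raise ValueError("code matrix vocabulary does not match operator rows")
    return CodeMatrix(
        values=X.values @ op.M,
        patients=X.patients,
        vocabulary=list(op.reference_vocab),
        transform=X.transform,
    )
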