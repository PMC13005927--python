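"""Align two sites' embedding spaces into a common coordinate system.

Rotation-based alignment solves the orthogonal Procrustes problem on the
anchor codes (codes present in both vocabularies), which preserves lengths
and angles and is therefore robust to scale differences between the
site-specific embeddings.  Projection-based alignment is the unconstrained
ridge-regression analog.  The reference site (B) is never transformed;
only the source space is mapped into reference coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .embed import EmbeddingSet
from .store import GroupCatalog


@dataclass
class AnchorSet:
    codes: list[str]
    idx_source: np.ndarray
    idx_reference: np.ndarray


@dataclass
class AlignmentMap:
    """Learned transform from source embedding coordinates to reference
    coordinates: rotation (orthogonal) or projection (ridge)."""

    method: str  # "rotation" | "projection"
    T: np.ndarray
    objective: float  # Frobenius residual on (normalized) anchor rows
    n_anchors: int
    ridge: float = 0.0


def select_anchors(E_src: EmbeddingSet, E_ref: EmbeddingSet) -> AnchorSet:
    """Anchors = intersection of the two vocabularies, lexicographic order."""
    shared = sorted(set(E_src.vocabulary) & set(E_ref.vocabulary))
    if not shared:
        raise ValueError("vocabularies share no codes; cannot align")
    si = {c: i for i, c in enumerate(E_src.vocabulary)}
    ri = {c: i for i, c in enumerate(E_ref.vocabulary)}
    return AnchorSet(
        codes=shared,
        idx_source=np.array([si[c] for c in shared]),
        idx_reference=np.array([ri[c] for c in shared]),
    )


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    return np.where(norms > 0, X / np.maximum(norms, 1e-300), X)


def rotation_align(
    E_src: EmbeddingSet, E_ref: EmbeddingSet, anchors: AnchorSet | None = None
) -> AlignmentMap:
    """Orthogonal Procrustes fit on unit-normalized anchor rows:
    T = argmin_{T'T=I} ||X_src T - X_ref||_F."""
    if E_src.V.shape[1] != E_ref.V.shape[1]:
        raise ValueError("rotation alignment requires equal embedding dimensions")
    if anchors is None:
        anchors = select_anchors(E_src, E_ref)
    Xa = _unit_rows(E_src.V[anchors.idx_source])
    Xb = _unit_rows(E_ref.V[anchors.idx_reference])
    if len(anchors.codes) < E_src.V.shape[1]:
        warnings.warn(
            f"{len(anchors.codes)} anchors for dimension {E_src.V.shape[1]}; "
            "rotation is under-determined but still defined"
        )
    T, _scale = orthogonal_procrustes(Xa, Xb)
    obj = float(np.linalg.norm(Xa @ T - Xb, "fro"))
    return AlignmentMap(method="rotation", T=T, objective=obj, n_anchors=len(anchors.codes))


def projection_align(
    E_src: EmbeddingSet,
    E_ref: EmbeddingSet,
    anchors: AnchorSet | None = None,
    ridge: float = 0.0,
) -> AlignmentMap:
    """Ridge-regression fit T = argmin ||X_src T - X_ref||_F^2 + ridge ||T||_F^2."""
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    if anchors is None:
        anchors = select_anchors(E_src, E_ref)
    Xa = E_src.V[anchors.idx_source]
    Xb = E_ref.V[anchors.idx_reference]
    gram = Xa.T @ Xa + ridge * np.eye(Xa.shape[1])
    if ridge == 0 and np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise np.linalg.LinAlgError(
            "anchor design is singular; use ridge > 0 for projection alignment"
        )
    T = np.linalg.solve(gram, Xa.T @ Xb)
    obj = float(np.linalg.norm(Xa @ T - Xb, "fro"))
    return AlignmentMap(
        method="projection", T=T, objective=obj, n_anchors=len(anchors.codes), ridge=ridge
    )


def apply_alignment(E_src: EmbeddingSet, amap: AlignmentMap) -> EmbeddingSet:
    """Map the full source embedding set into reference coordinates."""
    prov = dict(E_src.provenance)
    prov["aligned"] = amap.method
    return EmbeddingSet(
        vocabulary=list(E_src.vocabulary),
        V=E_src.V @ amap.T,
        dimension=amap.T.shape[1],
        provenance=prov,
    )


def within_group_similarity(
    E_src_aligned: EmbeddingSet, E_ref: EmbeddingSet, groups: GroupCatalog
) -> float:
    """Average cosine over cross-site code pairs that share a clinical
    group, averaged within group first and then across groups.  Used as a
    before/after-alignment diagnostic."""
    Xa = _unit_rows(E_src_aligned.V)
    Xb = _unit_rows(E_ref.V)
    si = {c: i for i, c in enumerate(E_src_aligned.vocabulary)}
    ri = {c: i for i, c in enumerate(E_ref.vocabulary)}
    group_means = []
    for gid in groups.groups:
        members = groups.members(gid)
        a_idx = [si[c] for c in members if c in si]
        b_idx = [ri[c] for c in members if c in ri]
        if not a_idx or not b_idx:
            continue
        cos = Xa[a_idx] @ Xb[b_idx].T
        group_means.append(float(cos.mean()))
    if not group_means:
        raise ValueError("no clinical group is represented in both vocabularies")
    return float(np.mean(group_means))
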