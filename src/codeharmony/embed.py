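"""Per-site code embeddings from within-patient temporal co-occurrence.

The embedding route mirrors word-embedding practice: count how often two
codes appear close together in the same patient's record, convert the
counts to a pointwise mutual information (PMI) association matrix, and
factorize it.  Two EHR-specific choices depart from NLP convention:

* event-pair counting — each qualifying pair of events counts once, so
  that a code's frequency information is preserved rather than collapsed
  to patient-level presence;
* default mode is plain PMI with no shift and no row zeroing: the SPPMI
  habit of zeroing rows of extremely common tokens discards exactly the
  high-frequency codes (common chronic conditions, routine labs) that
  matter most in EHR data.  SPPMI remains available behind a flag, and
  :func:`zeroed_rows` reports how many codes an SPPMI truncation silences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .store import EventTable

DEFAULT_WINDOW_DAYS = 30
DEFAULT_DIMENSION = 20


@dataclass
class CooccurrenceMatrix:
    """Symmetric within-window event-pair counts over a vocabulary.

    ``n`` holds each code's pair participation (row sums) and ``total`` the
    number of unordered pairs, sum(C) / 2.
    """

    vocabulary: list[str]
    C: np.ndarray
    window_days: int

    @property
    def n(self) -> np.ndarray:
        return self.C.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.C.sum()) / 2.0


@dataclass
class PMIMatrix:
    vocabulary: list[str]
    P: np.ndarray
    mode: str  # "PMI" | "SPPMI"
    shift: float


@dataclass
class EmbeddingSet:
    """Codes x d matrix of embedding vectors with provenance."""

    vocabulary: list[str]
    V: np.ndarray
    dimension: int
    provenance: dict

    def row(self, code: str) -> np.ndarray:
        return self.V[self.vocabulary.index(code)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.V, index=self.vocabulary,
            columns=[f"v{k + 1}" for k in range(self.V.shape[1])],
        )


def count_cooccurrence(
    events: EventTable, vocab: list[str], window_days: int = DEFAULT_WINDOW_DAYS
) -> CooccurrenceMatrix:
    """C_ij = number of event pairs of distinct codes i != j for the same
    patient within ``window_days`` calendar days; each unordered pair of
    events counts once.  Same-code pairs are ignored (C_ii = 0)."""
    if window_days < 0:
        raise ValueError("window must be nonnegative")
    idx = {c: j for j, c in enumerate(vocab)}
    m = len(vocab)
    C = np.zeros((m, m))
    frame = events.frame
    keep = frame["code"].isin(idx)
    if not keep.any():
        return CooccurrenceMatrix(vocabulary=list(vocab), C=C, window_days=window_days)
    sub = frame.loc[keep, ["patient_id", "date", "code"]].copy()
    sub["day"] = (sub["date"] - sub["date"].min()).dt.days
    sub["j"] = sub["code"].map(idx)
    sub = sub.sort_values(["patient_id", "day"], kind="stable")
    days_all = sub["day"].to_numpy()
    codes_all = sub["j"].to_numpy()
    starts = np.flatnonzero(
        np.r_[True, sub["patient_id"].to_numpy()[1:] != sub["patient_id"].to_numpy()[:-1]]
    )
    bounds = np.r_[starts, len(sub)]
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        days = days_all[s:e]
        codes = codes_all[s:e]
        ends = np.searchsorted(days, days + window_days, side="right")
        for a in range(len(days)):
            b = ends[a]
            if b > a + 1:
                partners = codes[a + 1 : b]
                partners = partners[partners != codes[a]]
                if partners.size:
                    ii.append(np.full(partners.size, codes[a]))
                    jj.append(partners)
    if ii:
        i_arr = np.concatenate(ii)
        j_arr = np.concatenate(jj)
        np.add.at(C, (i_arr, j_arr), 1.0)
        np.add.at(C, (j_arr, i_arr), 1.0)
    return CooccurrenceMatrix(vocabulary=list(vocab), C=C, window_days=window_days)


def pmi_matrix(C: CooccurrenceMatrix, mode: str = "PMI", shift: float = 1.0) -> PMIMatrix:
    """PMI_ij = log( (C_ij / N) / ((n_i / N)(n_j / N)) ) on observed pairs,
    with N the total pair mass; unobserved pairs stay exactly 0.

    SPPMI applies max(PMI - log shift, 0).  No rows are ever zeroed out for
    high-frequency codes.
    """
    if mode not in ("PMI", "SPPMI"):
        raise ValueError("mode must be PMI or SPPMI")
    if shift < 1:
        raise ValueError("shift must be >= 1")
    N = C.total
    if N <= 0:
        raise ValueError("empty co-occurrence matrix")
    n = C.n
    P = np.zeros_like(C.C)
    obs = C.C > 0
    with np.errstate(divide="ignore"):
        P[obs] = np.log(C.C[obs] * N / np.outer(n, n)[obs])
    if mode == "SPPMI":
        P[obs] = np.maximum(P[obs] - np.log(shift), 0.0)
    return PMIMatrix(vocabulary=list(C.vocabulary), P=P, mode=mode, shift=shift)


def embed(P: PMIMatrix, d: int = DEFAULT_DIMENSION) -> EmbeddingSet:
    """Truncated symmetric factorization V = U_d sqrt(sigma_d) keeping the
    d largest positive eigenvalues, so that V V' is the best rank-d
    approximation of the positive-semidefinite part of P.

    Restricting to the positive spectrum keeps dot products (and hence
    cosines) faithful to the PMI association structure: a symmetric PMI
    matrix with a structurally zero diagonal has paired negative
    eigenvalues whose components would otherwise contribute with the wrong
    sign to code-code inner products.  Deterministic: each column's sign is
    fixed so its largest-magnitude entry is positive.  For a positive
    semidefinite input at full rank this reconstructs P exactly (V V' = P).
    """
    m = len(P.vocabulary)
    if not 1 <= d <= m:
        raise ValueError(f"dimension must lie in [1, {m}]")
    evals, evecs = np.linalg.eigh((P.P + P.P.T) / 2)
    order = np.argsort(-evals, kind="stable")
    rank = int(np.sum(evals > 1e-10 * max(1.0, np.abs(evals).max())))
    if d > rank:
        warnings.warn(f"requested dimension {d} exceeds positive rank {rank}; reduced")
        d = max(rank, 1)
    sel = order[:d]
    U = evecs[:, sel]
    s = np.sqrt(np.maximum(evals[sel], 0.0))
    # sign convention: largest-|entry| of each column positive
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    V = U * flip[None, :] * s[None, :]
    return EmbeddingSet(
        vocabulary=list(P.vocabulary),
        V=V,
        dimension=d,
        provenance={"mode": P.mode, "shift": P.shift, "rank": rank},
    )


def zeroed_rows(P: PMIMatrix) -> list[str]:
    """Codes whose SPPMI row is entirely zero (silenced by the truncation)."""
    dead = np.flatnonzero(~P.P.any(axis=1))
    return [P.vocabulary[i] for i in dead]


def site_embeddings(
    events: EventTable,
    vocab: list[str],
    window_days: int = DEFAULT_WINDOW_DAYS,
    d: int = DEFAULT_DIMENSION,
    mode: str = "PMI",
    shift: float = 1.0,
) -> EmbeddingSet:
    """Convenience: co-occurrence -> PMI -> embedding for one site."""
    C = count_cooccurrence(events, vocab, window_days)
    P = pmi_matrix(C, mode=mode, shift=shift)
    E = embed(P, d=min(d, len(vocab)))
    E.provenance["window_days"] = window_days
    return E
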