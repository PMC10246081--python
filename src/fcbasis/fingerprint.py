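"""Connectome fingerprinting: same-subject, different-scan identification.

Each scan's feature vector (vectorized FC, reconstruction, or residual) is a
query; candidates are all scans with a *different* scan label (session/task).
The query scores a hit when its nearest candidate by cosine similarity belongs
to the same subject.  The residual of the angle-basis decomposition strips the
population-common low-rank structure from FC and concentrates the stable,
subject-unique part, which is why residual features identify subjects better
than raw FC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanFeatureSet", "IdentificationResult", "cosine_similarity_matrix", "identification_rate"]


@dataclass(frozen=True)
class ScanFeatureSet:
    """M scans x F features with subject and scan labels per row."""

    features: np.ndarray
    subject_ids: list
    scan_ids: list

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 2 or feats.shape[1] < 1:
            raise ValueError("features must be a 2-D M x F matrix with F >= 1")
        m = feats.shape[0]
        subj = list(self.subject_ids)
        scan = list(self.scan_ids)
        if len(subj) != m or len(scan) != m:
            raise ValueError("subject_ids and scan_ids must have one entry per row")
        pairs = list(zip(subj, scan))
        if len(set(pairs)) != m:
            raise ValueError("duplicate (subject_id, scan_id) pair")
        if not np.all(np.isfinite(feats)):
            raise ValueError("features contain non-finite values")
        feats = feats.copy()
        feats.flags.writeable = False
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "subject_ids", subj)
        object.__setattr__(self, "scan_ids", scan)

    @property
    def n_scans(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class IdentificationResult:
    """Identification rate plus the similarity pools behind the histograms."""

    rate: float
    per_query_hits: list[bool]
    same_subject_similarities: np.ndarray
    different_subject_similarities: np.ndarray
    n_queries: int = field(default=0)


def cosine_similarity_matrix(features: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity S_ab = <f_a, f_b> / (|f_a| |f_b|)."""
    feats = np.asarray(features, dtype=float)
    if feats.ndim != 2:
        raise ValueError("features must be 2-D")
    norms = np.linalg.norm(feats, axis=1)
    if np.any(norms == 0):
        row = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"zero-norm feature row {row}")
    unit = feats / norms[:, None]
    sim = unit @ unit.T
    sim = 0.5 * (sim + sim.T)
    np.fill_diagonal(sim, 1.0)
    return sim


def identification_rate(fs: ScanFeatureSet) -> IdentificationResult:
    """Top-1 nearest-neighbor identification over different-scan candidates.

    Every scan of a subject with >= 2 scans is a query; candidate set = scans
    whose scan_id differs from the query's (same-task pairs are never
    compared).  Ties in similarity are broken by lowest row index.  The
    same/different-subject similarity pools partition all admissible pairs
    (distinct scan_ids) exactly once.
    """
    subj = np.asarray(fs.subject_ids, dtype=object)
    scan = np.asarray(fs.scan_ids, dtype=object)
    if len(set(subj.tolist())) < 2:
        raise ValueError("identification needs at least 2 subjects")
    sim = cosine_similarity_matrix(fs.features)
    m = fs.n_scans

    counts = {s: int(np.sum(subj == s)) for s in set(subj.tolist())}
    singletons = {s for s, k in counts.items() if k < 2}
    if singletons:
        warnings.warn(
            f"{len(singletons)} subject(s) with a single scan excluded from queries",
            stacklevel=2,
        )

    same_subject = subj[:, None] == subj[None, :]
    diff_scan = scan[:, None] != scan[None, :]

    hits: list[bool] = []
    for a in range(m):
        if subj[a] in singletons:
            continue
        cand = np.flatnonzero(diff_scan[a])
        if cand.size == 0:
            continue
        best = cand[int(np.argmax(sim[a, cand]))]  # argmax takes lowest index on ties
        hits.append(bool(subj[best] == subj[a]))
    if not hits:
        raise ValueError("no admissible queries (all candidate sets empty)")

    iu, ju = np.triu_indices(m, k=1)
    admissible = diff_scan[iu, ju]
    same = same_subject[iu, ju]
    vals = sim[iu, ju]
    return IdentificationResult(
        rate=float(np.mean(hits)),
        per_query_hits=hits,
        same_subject_similarities=vals[admissible & same],
        different_subject_similarities=vals[admissible & ~same],
        n_queries=len(hits),
    )
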