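"""De novo mutational-signature extraction and reference matching.

Signatures are extracted from 96-context catalogs by bootstrapped
non-negative matrix factorization: each bootstrap resamples every
sample's catalog multinomially (conserving its total), factorizes it by
multiplicative updates minimizing the generalized Kullback-Leibler
(Poisson) divergence, and the pooled per-bootstrap signatures are
clustered into k consensus signatures by partitioning around medoids
under cosine distance.  Cluster stability is the mean silhouette width.
Per-sample exposures are then refit on the original catalog by
non-negative least squares.  De novo signatures are matched to a
reference set (e.g. the 30 COSMIC v2 signatures) by cosine correlation
similarity (CCS = 1 - cosine distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.metrics import silhouette_samples

from .cohort_io import ReferenceSignatureSet
from .mutation_catalog import TrinucleotideCatalog

__all__ = [
    "DeNovoSignatureSet",
    "ExposureMatrix",
    "SignatureMatch",
    "cosine_similarity",
    "nmf_kl",
    "extract_signatures",
    "match_to_reference",
    "estimate_exposures",
    "call_dominance",
]

_EPS = np.finfo(float).tiny


@dataclass
class DeNovoSignatureSet:
    profiles: np.ndarray  # (k, 96), rows sum to 1
    stability: np.ndarray  # (k,) mean silhouette widths in [-1, 1]
    k: int
    seed: int
    n_bootstrap: int
    converged: bool = True
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if (self.profiles < 0).any():
            raise ValueError("profiles must be non-negative")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("profile rows must sum to 1")
        if not self.names:
            self.names = [f"Sign.{i + 1:02d}" for i in range(self.k)]


@dataclass
class ExposureMatrix:
    values: np.ndarray  # (n_samples, k), non-negative
    sample_ids: list[str]
    sample_totals: np.ndarray
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < -1e-9).any():
            raise ValueError("exposures must be non-negative")


@dataclass
class SignatureMatch:
    denovo_name: str
    best_reference_name: str
    ccs: float
    full_ccs_row: np.ndarray


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine correlation similarity between two non-negative profiles.

    1 means identical shape, 0 disjoint support; invariant to scaling
    of either argument.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def nmf_kl(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 10_000,
    tol: float = 1e-9,
    check_monotone: bool = False,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Factorize V (contexts x samples) ~= W H by multiplicative updates.

    Minimizes the generalized KL divergence; W columns are normalized to
    sum 1 on exit (scale moved into H).  Returns (W, H, converged).
    When ``check_monotone`` is set the objective is asserted
    non-increasing every 100 iterations.
    """
    m, n = V.shape
    W = rng.uniform(0.1, 1.0, size=(m, k))
    H = rng.uniform(0.1, 1.0, size=(k, n))
    prev_obj = _kl_divergence(V, W @ H)
    last_checked = prev_obj
    converged = False
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if it % 10 == 0 or it == max_iter:
            obj = _kl_divergence(V, W @ H)
            if check_monotone and it % 100 == 0:
                if obj > last_checked + 1e-8 * max(1.0, abs(last_checked)):
                    raise AssertionError("KL objective increased")
                last_checked = obj
            if abs(prev_obj - obj) <= tol * max(1.0, abs(prev_obj)):
                converged = True
                break
            prev_obj = obj
    scale = np.maximum(W.sum(axis=0), _EPS)
    W = W / scale
    H = H * scale[:, None]
    return W, H, converged


def _pam_cosine(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    """Partitioning around medoids under cosine distance.

    Medoids are seeded greedily (farthest-point style from a seeded
    start) and refined by alternating assignment and medoid update.
    Returns (labels, medoid_indices, distance_matrix).
    """
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.maximum(norms, _EPS)
    D = 1.0 - Xn @ Xn.T
    np.fill_diagonal(D, 0.0)
    n = X.shape[0]
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        d_min = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(d_min)))
    medoids = np.array(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(labels == j)
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[int(np.argmin(within))]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels, medoids, D


def extract_signatures(
    catalog: TrinucleotideCatalog,
    k: int,
    n_bootstrap: int = 100,
    max_iter: int = 10_000,
    tol: float = 1e-9,
    seed: int = 0,
    name_prefix: str = "Sign",
) -> tuple[DeNovoSignatureSet, ExposureMatrix]:
    """Bootstrapped consensus NMF signature extraction.

    See the module docstring for the procedure.  ``k`` must not exceed
    the number of samples; every sample must carry at least one SNV.
    """
    V0 = catalog.counts.T.astype(float)  # contexts x samples
    n_samples = V0.shape[1]
    if k < 1 or k > min(n_samples, 96):
        raise ValueError(f"k must be in [1, min(n_samples, 96)], got {k}")
    totals = V0.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("every sample must have >= 1 SNV for extraction")
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    all_converged = True
    for _ in range(n_bootstrap):
        Vb = np.empty_like(V0)
        for s in range(n_samples):
            p = V0[:, s] / totals[s]
            Vb[:, s] = rng.multinomial(int(totals[s]), p)
        W, _, conv = nmf_kl(Vb, k, rng, max_iter=max_iter, tol=tol)
        all_converged &= conv
        pooled.append(W.T)  # k rows of unit-sum signatures
    P = np.vstack(pooled)  # (n_bootstrap * k, 96)
    if k == 1:
        profiles = P.mean(axis=0, keepdims=True)
        stability = np.array([1.0])
    else:
        labels, _, D = _pam_cosine(P, k, rng)
        sil = silhouette_samples(D, labels, metric="precomputed")
        profiles = np.vstack([P[labels == j].mean(axis=0) for j in range(k)])
        stability = np.array([float(sil[labels == j].mean()) for j in range(k)])
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    # order by decreasing total attribution so naming is deterministic
    expo = estimate_exposures(catalog, profiles)
    order = np.argsort(-expo.values.sum(axis=0), kind="stable")
    profiles, stability = profiles[order], stability[order]
    denovo = DeNovoSignatureSet(
        profiles=profiles,
        stability=stability,
        k=k,
        seed=seed,
        n_bootstrap=n_bootstrap,
        converged=all_converged,
        names=[f"{name_prefix}.{i + 1:02d}" for i in range(k)],
    )
    exposures = estimate_exposures(catalog, profiles)
    return denovo, exposures


def match_to_reference(
    denovo: DeNovoSignatureSet, refset: ReferenceSignatureSet
) -> list[SignatureMatch]:
    """Best reference match per de novo signature by CCS.

    Ties at machine precision resolve to the lowest reference index.
    """
    if denovo.profiles.shape[1] != refset.profiles.shape[1]:
        raise ValueError("dimension mismatch between de novo and reference set")
    matches = []
    for name, prof in zip(denovo.names, denovo.profiles):
        row = np.array([cosine_similarity(prof, r) for r in refset.profiles])
        best = int(np.argmax(row))  # argmax returns the first (lowest) index on ties
        matches.append(
            SignatureMatch(
                denovo_name=name,
                best_reference_name=refset.names[best],
                ccs=float(row[best]),
                full_ccs_row=row,
            )
        )
    return matches


def estimate_exposures(
    catalog: TrinucleotideCatalog, profiles: np.ndarray
) -> ExposureMatrix:
    """Per-sample NNLS attribution of mutations to signature profiles.

    Each sample's 96-vector is regressed on the (row-normalized)
    profiles under non-negativity; exposures are rescaled so they sum to
    the sample's SNV count.  All-zero samples get zero exposures.
    """
    profiles = np.asarray(profiles, dtype=float)
    A = profiles.T  # 96 x k
    values = np.zeros((catalog.counts.shape[0], profiles.shape[0]))
    residuals = np.zeros(catalog.counts.shape[0])
    totals = catalog.totals.astype(float)
    for i, row in enumerate(catalog.counts):
        if row.sum() == 0:
            continue
        x, res = nnls(A, row.astype(float))
        if x.sum() > 0:
            x = x * (row.sum() / x.sum())
        values[i] = x
        residuals[i] = res
    return ExposureMatrix(
        values=values,
        sample_ids=list(catalog.sample_ids),
        sample_totals=totals,
        residuals=residuals,
    )


def call_dominance(
    exposures: ExposureMatrix, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Dominance calls: signature active in a sample iff its exposure
    share is >= threshold (inclusive; default half the mutations).

    Returns (boolean samples x signatures matrix, per-signature fraction
    of samples active).  Zero-total samples are excluded from the
    denominator.
    """
    totals = exposures.values.sum(axis=1)
    nonzero = totals > 0
    share = np.zeros_like(exposures.values)
    share[nonzero] = exposures.values[nonzero] / totals[nonzero, None]
    active = (share >= threshold) & nonzero[:, None]
    denom = max(int(nonzero.sum()), 1)
    frac = active[nonzero].sum(axis=0) / denom if nonzero.any() else np.zeros(
        exposures.values.shape[1]
    )
    return active, frac
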