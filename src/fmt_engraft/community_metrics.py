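"""Alpha diversity and pairwise community comparison.

Shannon index (natural log) for within-sample diversity, Bray–Curtis on
log-transformed abundances and cosine similarity on raw abundances for
between-sample comparison, Euclidean distances for the direction of the
post-FMT shift, and the tie-corrected Kruskal–Wallis H test for multigroup
diversity comparisons.

The log transform uses a pseudo-abundance ``x0 = 1e-6``.  The default
variant is ``shifted_log``, ``log(1 + x/x0)``, which is zero at zero and
keeps Bray–Curtis in [0, 1]; the literal ``raw_log`` variant ``log(x + x0)``
(negative for small abundances, on which Bray–Curtis is ill-behaved) is
retained behind a flag for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import UndefinedInputError, ValidationError


@dataclass(frozen=True)
class TransformSpec:
    """Log transform applied to relative abundances before distances.

    x0: pseudo-abundance (default 1e-6, roughly the detection floor of a
        shotgun profile).
    variant: ``shifted_log`` = log(1 + x/x0) (default, nonnegative) or
        ``raw_log`` = log(x + x0).
    """

    x0: float = 1e-6
    variant: str = "shifted_log"

    def __post_init__(self) -> None:
        if self.x0 <= 0:
            raise ValidationError(f"x0 must be > 0, got {self.x0}")
        if self.variant not in ("shifted_log", "raw_log"):
            raise ValidationError(f"unknown transform variant {self.variant!r}")

    def apply(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.variant == "shifted_log":
            return np.log1p(x / self.x0)
        return np.log(x + self.x0)


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(arr).all():
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def shannon_index(profile) -> float:
    """Shannon diversity H = -sum(p_i ln p_i) in nats.

    The profile is renormalised internally; zero entries contribute nothing.
    """
    p = _as_vector(profile, "profile")
    if (p < 0).any():
        raise ValidationError("profile must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise UndefinedInputError("Shannon index undefined for an all-zero profile")
    return float(scipy.stats.entropy(p / total))


def bray_curtis(a, b, transform: TransformSpec | None = None) -> float:
    """Bray–Curtis dissimilarity on transformed abundances.

    BC = sum|a' - b'| / sum(a' + b') with a', b' the transformed vectors.
    In [0, 1] for the nonnegative ``shifted_log`` transform.
    """
    transform = transform or TransformSpec()
    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    if not a.any() and not b.any():
        raise UndefinedInputError("Bray–Curtis undefined for two all-zero profiles")
    ta = transform.apply(a)
    tb = transform.apply(b)
    denom = (ta + tb).sum()
    if denom == 0:
        raise UndefinedInputError("Bray–Curtis denominator is zero after transform")
    return float(np.abs(ta - tb).sum() / denom)


def cosine_similarity(a, b) -> float:
    """Cosine similarity dot(a,b)/(|a||b|) on raw relative abundances."""
    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedInputError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass(frozen=True)
class EuclideanShift:
    """The three pairwise distances around one post-FMT sample.

    Callers interpret direction: a post sample that moved toward its donor
    has d_post_donor < d_pre_donor.
    """

    d_pre_post: float
    d_post_donor: float
    d_pre_donor: float


def euclidean_shift(pre, post, donor, transform: TransformSpec | None = None) -> EuclideanShift:
    """Euclidean distances among (pre, post, donor) on transformed vectors."""
    transform = transform or TransformSpec()
    pre = _as_vector(pre, "pre")
    post = _as_vector(post, "post")
    donor = _as_vector(donor, "donor")
    if not (pre.shape == post.shape == donor.shape):
        raise ValidationError(
            f"length mismatch: pre={pre.size}, post={post.size}, donor={donor.size}"
        )
    tp, tq, td = transform.apply(pre), transform.apply(post), transform.apply(donor)
    return EuclideanShift(
        d_pre_post=float(np.linalg.norm(tp - tq)),
        d_post_donor=float(np.linalg.norm(tq - td)),
        d_pre_donor=float(np.linalg.norm(tp - td)),
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p-value (k-1 df).

    The degenerate case of every observation identical returns (0.0, 1.0).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every group needs at least one observation")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = scipy.stats.kruskal(*groups)
    return float(stat), float(p)


def distance_matrix(table, metric: str = "bray_curtis", transform: TransformSpec | None = None):
    """All-pairs sample distance matrix over an AbundanceTable.

    metric: 'bray_curtis', 'cosine' (similarity) or 'euclidean'.
    """
    import pandas as pd

    transform = transform or TransformSpec()
    samples = table.sample_ids
    n = len(samples)
    out = np.zeros((n, n))
    vectors = [table.data[s].to_numpy() for s in samples]
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "bray_curtis":
                v = bray_curtis(vectors[i], vectors[j], transform)
            elif metric == "cosine":
                v = cosine_similarity(vectors[i], vectors[j])
            elif metric == "euclidean":
                v = float(
                    np.linalg.norm(transform.apply(vectors[i]) - transform.apply(vectors[j]))
                )
            else:
                raise ValidationError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = v
    if metric == "cosine":
        np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=samples, columns=samples)
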