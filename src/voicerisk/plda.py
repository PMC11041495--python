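"""Two-covariance Gaussian PLDA.

The model: each speaker s has a latent identity vector ``y_s ~ N(mu, Phi_b)``
and every recording of that speaker is ``x = y_s + eps`` with
``eps ~ N(0, Phi_w)``.  ``Phi_b`` (between-speaker) carries the identity
information; ``Phi_w`` (within-speaker) carries session, task and channel
variability.  Verification scores are the log-likelihood ratio of the
same-speaker against the different-speaker hypothesis for a pair of vectors —
exactly computable because both hypotheses are joint Gaussians.

Fitting is maximum likelihood via EM with the global mean fixed at the
arithmetic mean of the training embeddings.  The per-speaker marginal
likelihood factorises (through an orthonormal change of variables) into a term
for the speaker mean, ``N(xbar; mu, Phi_b + Phi_w / n)``, and ``n - 1``
deviation terms ``N(., 0, Phi_w)``, which is what `_log_likelihood` evaluates.

Enrollment follows the usual multi-session recipe: a speaker's enrollment
recordings are averaged into a single vector, and scoring accounts for the
averaging by shrinking the enrolled vector's within-covariance by the number
of averaged recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .exceptions import DegenerateDataError, ValidationError
from .synthetic_embeddings import EmbeddingCohort, empirical_covariances

__all__ = [
    "PLDAModel",
    "EnrollmentTable",
    "fit_plda",
    "enroll",
    "score_llr",
    "score_matrix",
]

logger = logging.getLogger(__name__)

_MONOTONE_SLACK = 1e-8


@dataclass
class PLDAModel:
    """Fitted two-covariance model: global mean plus Phi_b and Phi_w."""

    mean: np.ndarray
    between_cov: np.ndarray
    within_cov: np.ndarray
    fit_log: list[float] = field(default_factory=list)
    regularized: bool = False

    @property
    def dim(self) -> int:
        return len(self.mean)

    def validate(self) -> None:
        d = self.dim
        for name, m in (("between_cov", self.between_cov), ("within_cov", self.within_cov)):
            if m.shape != (d, d):
                raise ValidationError(f"{name} has shape {m.shape}, expected ({d}, {d})")
            if not np.allclose(m, m.T, atol=1e-8 * (1 + np.abs(m).max())):
                raise ValidationError(f"{name} is not symmetric")
            if not np.all(np.isfinite(m)):
                raise ValidationError(f"{name} has non-finite entries")
        np.linalg.cholesky(self.within_cov)  # must be invertible (PD)
        for prev, cur in zip(self.fit_log, self.fit_log[1:]):
            if cur < prev - _MONOTONE_SLACK * max(1.0, abs(prev)):
                raise ValidationError("fit_log is not non-decreasing")


@dataclass
class EnrollmentTable:
    """Speaker-averaged enrollment vectors; one row per known speaker."""

    speaker_ids: np.ndarray
    vectors: np.ndarray
    n_averaged: np.ndarray

    def __post_init__(self) -> None:
        self.speaker_ids = np.asarray(self.speaker_ids, dtype=object)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.n_averaged = np.asarray(self.n_averaged, dtype=int)
        if len(set(self.speaker_ids)) != len(self.speaker_ids):
            raise ValidationError("enrollment requires one row per speaker")
        if np.any(self.n_averaged < 1):
            raise ValidationError("n_averaged must be >= 1")

    def __len__(self) -> int:
        return len(self.speaker_ids)


def _group_by_speaker(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    uniq, inverse = np.unique(np.asarray(labels).astype(str), return_inverse=True)
    counts = np.bincount(inverse)
    return uniq, inverse, counts


def _log_likelihood(
    centered_means: np.ndarray,
    counts: np.ndarray,
    ssw: np.ndarray,
    n_total: int,
    between: np.ndarray,
    within: np.ndarray,
) -> float:
    """Exact marginal log-likelihood from per-speaker sufficient statistics."""
    d = within.shape[0]
    n_speakers = len(counts)
    cw = cho_factor(within, lower=True)
    logdet_w = 2.0 * np.sum(np.log(np.diag(cw[0])))
    ll = -0.5 * (
        n_total * d * np.log(2.0 * np.pi)
        + (n_total - n_speakers) * logdet_w
        + float(np.trace(cho_solve(cw, ssw)))
    )
    for n in np.unique(counts):
        sel = counts == n
        g = within + n * between
        cg = cho_factor(g, lower=True)
        logdet_g = 2.0 * np.sum(np.log(np.diag(cg[0])))
        m = centered_means[sel]
        quad = float(np.sum(m * cho_solve(cg, m.T).T))
        ll += -0.5 * (int(sel.sum()) * logdet_g + n * quad)
    return ll


def _ensure_pd(m: np.ndarray, what: str) -> tuple[np.ndarray, bool]:
    """Add lam*I (lam = 1e-6 x mean diagonal) when m is not safely PD."""
    m = 0.5 * (m + m.T)
    eig_min = float(np.linalg.eigvalsh(m)[0])
    mean_diag = float(np.trace(m)) / m.shape[0]
    if eig_min <= 1e-10 * max(mean_diag, 1.0):
        lam = 1e-6 * max(mean_diag, 1.0)
        logger.warning("regularizing %s with lambda=%.3g (min eig %.3g)", what, lam, eig_min)
        return m + lam * np.eye(m.shape[0]), True
    return m, False


def fit_plda(
    embeddings: np.ndarray | Sequence[Sequence[float]],
    speaker_labels: Sequence,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> PLDAModel:
    """Fit the two-covariance model by EM.

    Parameters
    ----------
    embeddings
        (n_records, dim) array of embedding vectors.
    speaker_labels
        Speaker id per row; at least two distinct speakers, and at least one
        speaker with two or more recordings.
    max_iter, tol
        EM stops after ``max_iter`` iterations or when the log-likelihood
        gain drops below ``tol`` (absolute).

    Returns
    -------
    PLDAModel
        With ``fit_log`` holding the per-iteration log-likelihood (non-
        decreasing up to numerical slack) evaluated at the updated parameters.
    """
    x = np.asarray(embeddings, dtype=float)
    if x.ndim != 2:
        raise ValidationError("embeddings must form a (n_records, dim) array")
    labels = np.asarray(speaker_labels)
    if len(labels) != x.shape[0]:
        raise ValidationError("speaker_labels length must match embeddings")
    uniq, inverse, counts = _group_by_speaker(labels)
    n_speakers, n_total, d = len(uniq), x.shape[0], x.shape[1]
    if n_speakers < 2:
        raise DegenerateDataError("PLDA needs >= 2 speakers to estimate Phi_b")
    if n_total - n_speakers < 1:
        raise DegenerateDataError(
            "PLDA needs at least one speaker with >= 2 recordings to estimate Phi_w"
        )

    mu = x.mean(axis=0)
    centered = x - mu
    sums = np.zeros((n_speakers, d))
    np.add.at(sums, inverse, centered)
    cmeans = sums / counts[:, None]
    ssw = centered.T @ centered - cmeans.T @ sums

    # Moment (ANOVA) initialisation; deterministic.
    cohort_like = EmbeddingCohort(
        recording_ids=np.arange(n_total).astype(object),
        speaker_ids=labels.astype(object),
        tasks=np.zeros(n_total, dtype=object),
        X=x,
    )
    between0, within0 = empirical_covariances(cohort_like)
    within, reg_w = _ensure_pd(within0, "within_cov")
    # Floor Phi_b eigenvalues slightly above zero: the zero matrix is an EM
    # fixed point, so a degenerate start would never move.
    w_b, q_b = np.linalg.eigh(0.5 * (between0 + between0.T))
    floor = 1e-6 * max(float(np.trace(within)) / d, 1.0)
    between = (q_b * np.clip(w_b, floor, None)) @ q_b.T
    regularized = reg_w

    fit_log: list[float] = []
    for _ in range(max_iter):
        # E-step, grouped by per-speaker recording count.
        sum_eyy = np.zeros((d, d))
        cross = np.zeros((d, d))  # sum_s n_s (cbar yhat' + yhat cbar' - yhat yhat' - Sigma_n)
        for n in np.unique(counts):
            sel = counts == n
            m = cmeans[sel]
            cq = cho_factor(between + within / n, lower=True)
            gain = cho_solve(cq, between).T  # B (B + W/n)^{-1}
            yhat = m @ gain.T
            post_cov = between - gain @ between
            post_cov = 0.5 * (post_cov + post_cov.T)
            k = int(sel.sum())
            sum_eyy += yhat.T @ yhat + k * post_cov
            mc = m.T @ yhat
            cross += n * (mc + mc.T - yhat.T @ yhat - k * post_cov)
        between_new = sum_eyy / n_speakers
        # sum_s sum_i E[(c_i - y)(c_i - y)'] = SSW + sum_s n_s cbar cbar' - cross
        weighted_means = (cmeans * counts[:, None]).T @ cmeans
        within_new = (ssw + weighted_means - cross) / n_total
        between, _ = _ensure_pd(between_new, "between_cov")
        within, reg = _ensure_pd(within_new, "within_cov")
        regularized = regularized or reg

        ll = _log_likelihood(cmeans, counts, ssw, n_total, between, within)
        fit_log.append(ll)
        if len(fit_log) >= 2 and fit_log[-1] - fit_log[-2] < tol:
            break

    model = PLDAModel(
        mean=mu,
        between_cov=between,
        within_cov=within,
        fit_log=fit_log,
        regularized=regularized,
    )
    model.validate()
    return model


def enroll(
    cohort: EmbeddingCohort,
    speakers: Sequence[str] | None = None,
    exclude_recordings: Sequence[str] | None = None,
) -> EnrollmentTable:
    """Average each speaker's enrollment embeddings into a single vector.

    ``exclude_recordings`` supports probe withholding: recordings listed there
    (e.g. an overlap speaker's probe) never enter the average.  A speaker left
    with no recordings after exclusion is an error.
    """
    excluded = set(map(str, exclude_recordings)) if exclude_recordings else set()
    by_speaker = cohort.indices_by_speaker()
    wanted = [str(s) for s in speakers] if speakers is not None else sorted(by_speaker)
    vectors, n_avg = [], []
    for sid in wanted:
        if sid not in by_speaker:
            raise DegenerateDataError(f"speaker {sid!r} has no recordings in the cohort")
        idx = by_speaker[sid]
        if excluded:
            idx = idx[[str(r) not in excluded for r in cohort.recording_ids[idx]]]
        if len(idx) == 0:
            raise DegenerateDataError(
                f"speaker {sid!r} has no enrollment recordings after exclusions"
            )
        vectors.append(cohort.X[idx].mean(axis=0))
        n_avg.append(len(idx))
    return EnrollmentTable(
        speaker_ids=np.array(wanted, dtype=object),
        vectors=np.vstack(vectors),
        n_averaged=np.array(n_avg, dtype=int),
    )


def _llr_blocks(
    model: PLDAModel, probes: np.ndarray, enrolled: np.ndarray, m: int
) -> np.ndarray:
    """LLR matrix (n_probes x n_enrolled) for a fixed averaging count m.

    Uses the conditional decomposition: LLR = log N(p | e, same) - log N(p),
    with the enrolled vector's within-covariance scaled by 1/m.
    """
    phi_b, phi_w = model.between_cov, model.within_cov
    q = phi_b + phi_w / m  # marginal covariance of the averaged enrollment
    cq = cho_factor(q, lower=True)
    gain = cho_solve(cq, phi_b).T  # A = Phi_b Q^{-1}
    cond = phi_b + phi_w - gain @ phi_b  # conditional covariance of p given e
    cond = 0.5 * (cond + cond.T)
    marg = phi_b + phi_w

    cc = cho_factor(cond, lower=True)
    cm = cho_factor(marg, lower=True)
    logdet_c = 2.0 * np.sum(np.log(np.diag(cc[0])))
    logdet_m = 2.0 * np.sum(np.log(np.diag(cm[0])))

    p = probes - model.mean
    e_proj = (enrolled - model.mean) @ gain.T  # A e~, one row per enrollment

    sol_p = cho_solve(cc, p.T).T
    quad_p_cond = np.sum(p * sol_p, axis=1)
    quad_p_marg = np.sum(p * cho_solve(cm, p.T).T, axis=1)
    quad_e = np.sum(e_proj * cho_solve(cc, e_proj.T).T, axis=1)
    cross = sol_p @ e_proj.T

    return (
        -0.5 * (logdet_c - logdet_m)
        - 0.5 * (quad_p_cond[:, None] - 2.0 * cross + quad_e[None, :] - quad_p_marg[:, None])
    )


def score_matrix(
    model: PLDAModel,
    enrollments: EnrollmentTable,
    probes: np.ndarray,
) -> np.ndarray:
    """LLR scores for every probe x enrollment pair.

    Returns an (n_probes, n_enrolled) matrix; entry (i, j) is the same-speaker
    vs different-speaker log-likelihood ratio of probe i against enrollment j.
    """
    probes = np.atleast_2d(np.asarray(probes, dtype=float))
    if len(enrollments) == 0 or probes.shape[0] == 0:
        raise ValidationError("score_matrix requires >= 1 probe and >= 1 enrollment")
    if probes.shape[1] != model.dim or enrollments.vectors.shape[1] != model.dim:
        raise ValidationError(
            f"dimension mismatch: model dim {model.dim}, "
            f"probes {probes.shape[1]}, enrollments {enrollments.vectors.shape[1]}"
        )
    out = np.empty((probes.shape[0], len(enrollments)))
    for m in np.unique(enrollments.n_averaged):
        sel = enrollments.n_averaged == m
        out[:, sel] = _llr_blocks(model, probes, enrollments.vectors[sel], int(m))
    if not np.all(np.isfinite(out)):
        raise ValidationError("non-finite LLR scores produced")
    return out


def score_llr(
    model: PLDAModel,
    enrolled: np.ndarray,
    probe: np.ndarray,
    n_averaged: int = 1,
) -> float:
    """Same-vs-different speaker LLR for a single enrollment/probe pair.

    Symmetric in its two vector arguments when ``n_averaged == 1``.
    """
    if n_averaged < 1:
        raise ValidationError("n_averaged must be >= 1")
    enrolled = np.asarray(enrolled, dtype=float).reshape(-1)
    probe = np.asarray(probe, dtype=float).reshape(-1)
    if enrolled.shape[0] != model.dim or probe.shape[0] != model.dim:
        raise ValidationError("vector dimension does not match the model")
    table = EnrollmentTable(
        speaker_ids=np.array(["_e"], dtype=object),
        vectors=enrolled[None, :],
        n_averaged=np.array([n_averaged]),
    )
    return float(score_matrix(model, table, probe[None, :])[0, 0])
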