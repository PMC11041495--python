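"""Accept/reject threshold selection for the verifier.

An adversary running a linkage attack must decide which pairwise scores count
as matches.  The detection cost function

    DCF(t) = C_FR * FR(t) * prior + C_FA * FA(t) * (1 - prior)

weighs missed genuine matches (false rejections) against spurious ones (false
acceptances); minimising it over thresholds gives the minDCF operating point.
Two presets mirror common practice: a *default* configuration (C_FA=1, C_FR=1,
prior=0.01) and a *strict* one (C_FA=10, C_FR=0.1, prior=0.001) that penalises
false acceptances heavily — the calibration an adversary who values precision
over recall would pick.  The equal error rate (FAR = FRR) is provided as the
conventional alternative.

Because computing one threshold over an entire large training population is
expensive and unrepresentative, the threshold is bootstrapped: repeatedly
sample two speaker subsets, enroll one against held-out probes of the other,
take the per-run minDCF threshold, and average over runs.  Runs whose two
subsets share no speaker contain no genuine trial and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import CalibrationError, ConfigurationError, ValidationError
from .plda import EnrollmentTable, PLDAModel, score_matrix
from .synthetic_embeddings import EmbeddingCohort

__all__ = [
    "ThresholdSpec",
    "CalibratedThreshold",
    "DEFAULT_SPEC",
    "STRICT_SPEC",
    "detection_cost",
    "candidate_thresholds",
    "min_dcf_threshold",
    "eer_threshold",
    "bootstrap_threshold",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Cost/prior parameters of the detection cost function.

    ``mode`` selects whether FR and FA enter the cost as error *rates*
    (normalised by the genuine / impostor trial counts — the convention of
    standard minDCF implementations, and the default) or as raw *counts*.
    """

    c_fa: float = 1.0
    c_fr: float = 1.0
    prior_target: float = 0.01
    mode: str = "rates"

    def __post_init__(self) -> None:
        if not self.c_fa > 0 or not self.c_fr > 0:
            raise ConfigurationError("costs C_FA and C_FR must be positive")
        if not 0.0 < self.prior_target < 1.0:
            raise ConfigurationError("prior_target must lie strictly inside (0, 1)")
        if self.mode not in ("rates", "counts"):
            raise ConfigurationError("mode must be 'rates' or 'counts'")


DEFAULT_SPEC = ThresholdSpec(c_fa=1.0, c_fr=1.0, prior_target=0.01)
STRICT_SPEC = ThresholdSpec(c_fa=10.0, c_fr=0.1, prior_target=0.001)


@dataclass
class CalibratedThreshold:
    """Bootstrap-averaged acceptance threshold with run bookkeeping."""

    value: float
    method: str
    per_run_thresholds: list[float] = field(default_factory=list)
    runs_attempted: int = 0
    runs_used: int = 0
    runs_discarded: int = 0

    def __post_init__(self) -> None:
        if self.runs_used + self.runs_discarded != self.runs_attempted:
            raise ValidationError("runs_used + runs_discarded must equal runs_attempted")
        if self.per_run_thresholds and not np.isclose(
            self.value, float(np.mean(self.per_run_thresholds))
        ):
            raise ValidationError("value must be the mean of per_run_thresholds")

    def report(self) -> dict:
        return {
            "value": self.value,
            "method": self.method,
            "runs_attempted": self.runs_attempted,
            "runs_used": self.runs_used,
            "runs_discarded": self.runs_discarded,
            "per_run_thresholds": list(self.per_run_thresholds),
        }


def _split_scores(
    scores: Sequence[float], labels: Sequence
) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind == "b":
        genuine_mask = lab
    else:
        genuine_mask = np.array([str(v) == "genuine" or v is True or v == 1 for v in lab])
    if scores.shape != genuine_mask.shape:
        raise ValidationError("scores and labels must have equal length")
    genuine = np.sort(scores[genuine_mask])
    impostor = np.sort(scores[~genuine_mask])
    if len(genuine) == 0:
        raise ValidationError("trial set contains no genuine trials")
    if len(impostor) == 0:
        raise ValidationError("trial set contains no impostor trials")
    return genuine, impostor


def _error_profile(
    genuine: np.ndarray, impostor: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(false-reject count, false-accept count) at each threshold.

    Acceptance rule: score >= threshold.
    """
    fr = np.searchsorted(genuine, thresholds, side="left").astype(float)
    fa = len(impostor) - np.searchsorted(impostor, thresholds, side="left").astype(float)
    return fr, fa


def detection_cost(
    scores: Sequence[float],
    labels: Sequence,
    threshold: float,
    spec: ThresholdSpec,
) -> float:
    """Evaluate the detection cost function at one threshold.

    In ``rates`` mode FR and FA are the miss rate (genuine trials scored
    below the threshold over genuine count) and false-accept rate (impostor
    trials at or above the threshold over impostor count); in ``counts`` mode
    the raw counts are used.
    """
    genuine, impostor = _split_scores(scores, labels)
    fr, fa = _error_profile(genuine, impostor, np.array([float(threshold)]))
    fr_val, fa_val = float(fr[0]), float(fa[0])
    if spec.mode == "rates":
        fr_val /= len(genuine)
        fa_val /= len(impostor)
    return spec.c_fr * fr_val * spec.prior_target + spec.c_fa * fa_val * (
        1.0 - spec.prior_target
    )


def candidate_thresholds(scores: Sequence[float]) -> np.ndarray:
    """Midpoints of adjacent sorted unique scores, plus -inf/+inf sentinels."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[1:] + uniq[:-1]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _costs_over_candidates(
    genuine: np.ndarray, impostor: np.ndarray, cands: np.ndarray, spec: ThresholdSpec
) -> np.ndarray:
    fr, fa = _error_profile(genuine, impostor, cands)
    if spec.mode == "rates":
        fr = fr / len(genuine)
        fa = fa / len(impostor)
    return spec.c_fr * fr * spec.prior_target + spec.c_fa * fa * (1.0 - spec.prior_target)


def min_dcf_threshold(
    scores: Sequence[float],
    labels: Sequence,
    spec: ThresholdSpec,
) -> tuple[float, float]:
    """Threshold minimising the detection cost over the candidate set.

    Candidates are the midpoints of adjacent sorted unique scores plus the
    two infinite sentinels; cost ties are broken toward the largest threshold
    (the most conservative acceptance rule).
    """
    genuine, impostor = _split_scores(scores, labels)
    cands = candidate_thresholds(np.concatenate([genuine, impostor]))
    costs = _costs_over_candidates(genuine, impostor, cands, spec)
    best = costs.min()
    idx = int(np.flatnonzero(costs == best).max())
    return float(cands[idx]), float(best)


def _min_dcf_finite(
    genuine: np.ndarray, impostor: np.ndarray, spec: ThresholdSpec
) -> float:
    """Per-run minDCF threshold restricted to data-supported operating points.

    Bootstrap runs average thresholds arithmetically, so each run must yield
    a finite value.  Restricting candidates to the finite midpoints mirrors
    toolkit minDCF implementations, which sweep the observed scores and have
    no reject-everything operating point; without this, a strict cost
    configuration on a run whose top-scoring trial is an impostor would pick
    the +inf sentinel and poison the average.
    """
    cands = candidate_thresholds(np.concatenate([genuine, impostor]))[1:-1]
    if len(cands) == 0:  # all scores identical
        return float(genuine[0])
    costs = _costs_over_candidates(genuine, impostor, cands, spec)
    idx = int(np.flatnonzero(costs == costs.min()).max())
    return float(cands[idx])


def eer_threshold(
    scores: Sequence[float],
    labels: Sequence,
) -> tuple[float, float]:
    """Equal-error-rate operating point.

    Picks the candidate threshold minimising |FAR - FRR| (ties toward the
    largest threshold) and reports the EER as (FAR + FRR) / 2 there.
    """
    genuine, impostor = _split_scores(scores, labels)
    cands = candidate_thresholds(np.concatenate([genuine, impostor]))
    fr, fa = _error_profile(genuine, impostor, cands)
    frr = fr / len(genuine)
    far = fa / len(impostor)
    gap = np.abs(far - frr)
    best = gap.min()
    idx = int(np.flatnonzero(gap == best).max())
    return float(cands[idx]), float((far[idx] + frr[idx]) / 2.0)


def _independent_subsets(
    rng: np.random.Generator, speakers: np.ndarray, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two speaker subsets, drawn independently (so overlap is possible),
    each without replacement."""
    a = rng.choice(speakers, size=size, replace=False)
    b = rng.choice(speakers, size=size, replace=False)
    return a, b


def bootstrap_threshold(
    known_cohort: EmbeddingCohort,
    model: PLDAModel,
    spec: ThresholdSpec,
    subset_size: int = 100,
    runs: int = 200,
    seed: int = 0,
    converge_tol: float | None = None,
    converge_window: int = 25,
    _draw_subsets: Callable[..., tuple[np.ndarray, np.ndarray]] | None = None,
) -> CalibratedThreshold:
    """Bootstrap the minDCF threshold over random speaker-subset pairs.

    Per run: draw two subsets of ``subset_size`` speakers from the known
    cohort (independently, so they may overlap), enroll subset A by speaker
    averaging, pick one held probe recording per subset-B speaker (withheld
    from that speaker's enrollment average when possible), score every
    enrollment against every probe, and take the run's minDCF threshold
    (restricted to finite, data-supported candidates; see
    :func:`_min_dcf_finite`).
    Runs with no genuine trial (disjoint subsets) are discarded.  The final
    threshold is the arithmetic mean over retained runs.

    With ``converge_tol`` set, sampling stops early once the running mean
    moved by less than the tolerance over the last ``converge_window``
    retained runs.

    Raises
    ------
    CalibrationError
        If every run is discarded; use larger subsets (more likely to
        overlap) or more runs.
    """
    if runs < 1:
        raise ConfigurationError("runs must be >= 1")
    by_speaker = known_cohort.indices_by_speaker()
    speakers = np.array(sorted(by_speaker), dtype=object)
    if len(speakers) < subset_size:
        raise ConfigurationError(
            f"known cohort has {len(speakers)} speakers < subset_size {subset_size}"
        )
    draw = _draw_subsets or _independent_subsets
    rng = np.random.default_rng(seed)
    sums = {s: known_cohort.X[idx].sum(axis=0) for s, idx in by_speaker.items()}
    counts = {s: len(idx) for s, idx in by_speaker.items()}

    per_run: list[float] = []
    running_means: list[float] = []
    attempted = discarded = 0
    for _ in range(runs):
        attempted += 1
        subset_a, subset_b = draw(rng, speakers, subset_size)
        probe_rows = {
            str(s): int(rng.choice(by_speaker[str(s)])) for s in subset_b
        }
        a_set = {str(s) for s in subset_a}
        if not (a_set & set(probe_rows)):
            discarded += 1
            continue
        vecs, n_avg = [], []
        for s in subset_a:
            s = str(s)
            total, k = sums[s], counts[s]
            if s in probe_rows and k >= 2:
                total = total - known_cohort.X[probe_rows[s]]
                k -= 1
            vecs.append(total / k)
            n_avg.append(k)
        enr = EnrollmentTable(
            speaker_ids=np.asarray(subset_a, dtype=object),
            vectors=np.vstack(vecs),
            n_averaged=np.array(n_avg),
        )
        probe_speakers = list(probe_rows)
        probes = known_cohort.X[[probe_rows[s] for s in probe_speakers]]
        scores = score_matrix(model, enr, probes)
        genuine = (
            np.asarray(probe_speakers, dtype=object)[:, None]
            == np.asarray(subset_a, dtype=object)[None, :]
        )
        g_scores = np.sort(scores[genuine])
        i_scores = np.sort(scores[~genuine])
        per_run.append(_min_dcf_finite(g_scores, i_scores, spec))
        running_means.append(float(np.mean(per_run)))
        if (
            converge_tol is not None
            and len(running_means) > converge_window
            and abs(running_means[-1] - running_means[-1 - converge_window]) < converge_tol
        ):
            break

    if not per_run:
        raise CalibrationError(
            "every bootstrap run was discarded (no overlapping speakers between "
            "subsets); increase subset_size or runs"
        )
    return CalibratedThreshold(
        value=float(np.mean(per_run)),
        method="minDCF",
        per_run_thresholds=per_run,
        runs_attempted=attempted,
        runs_used=len(per_run),
        runs_discarded=discarded,
    )
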