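"""Marketer-attack execution and outcome accounting.

Given a fitted verifier, a calibrated threshold and a speaker split, the
attack scores every probe against every enrolled known speaker and applies an
acceptance rule:

* ``"all"`` — accept every pair scoring at or above the threshold (the
  adversary does not know the overlap size and must consider everything);
* ``"rank1"`` — accept at most the best-scoring known speaker per probe;
* ``"topN"`` — keep only the N highest-scoring acceptances across all probes
  (the adversary knows the overlap size N).

Outcomes are counted in the standard confusion terms: a true acceptance (TA)
is an accepted pair whose probe and known speaker coincide; a false
acceptance (FA) is any other accepted pair.  The false-acceptance rate (FAR)
divides FA by the number of impostor comparisons, and precision = TA/(TA+FA)
quantifies how trustworthy the adversary's accepted matches are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohorts import SpeakerSplit
from .exceptions import ConfigurationError, ValidationError
from .plda import EnrollmentTable, PLDAModel, enroll, score_matrix
from .synthetic_embeddings import EmbeddingCohort

__all__ = [
    "MatchTable",
    "RiskSummary",
    "match_table_from_scores",
    "run_attack",
    "count_outcomes",
    "search_space",
]

VARIANTS = ("all", "rank1", "topN")


@dataclass
class MatchTable:
    """Scored probe x known comparisons with accept decisions.

    ``table`` has one row per comparison with columns ``probe_id``,
    ``probe_speaker``, ``known_speaker``, ``score``, ``rank`` (1-based within
    probe, descending score, ties broken by known speaker id) and
    ``accepted``.
    """

    table: pd.DataFrame
    threshold: float
    variant: str
    n_best: Optional[int] = None

    def accepted(self) -> pd.DataFrame:
        return self.table[self.table["accepted"]]

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if (self.table.loc[self.table["accepted"], "score"] < self.threshold).any():
            raise ValidationError("accepted rows must score at or above the threshold")
        for _, grp in self.table.groupby("probe_id", sort=False):
            ranks = np.sort(grp["rank"].to_numpy())
            if not np.array_equal(ranks, np.arange(1, len(grp) + 1)):
                raise ValidationError("ranks must be a permutation of 1..n_known per probe")


def match_table_from_scores(
    scores: np.ndarray,
    probe_ids: np.ndarray,
    probe_speakers: np.ndarray,
    known_speakers: np.ndarray,
    threshold: float,
    variant: str = "all",
    n_best: Optional[int] = None,
) -> MatchTable:
    """Apply the acceptance rule to a ready-made score matrix.

    Exposed separately from :func:`run_attack` so the decision logic can be
    exercised on hand-built score matrices.
    """
    scores = np.asarray(scores, dtype=float)
    if math.isnan(threshold):
        raise ConfigurationError("threshold must not be NaN")
    if variant not in VARIANTS:
        raise ConfigurationError(f"variant must be one of {VARIANTS}")
    if variant == "topN" and (n_best is None or n_best < 1):
        raise ConfigurationError("variant 'topN' requires N >= 1")
    n_probes, n_known = scores.shape
    if n_probes == 0 or n_known == 0:
        raise ValidationError("attack requires >= 1 probe and >= 1 known speaker")

    known_str = np.asarray(known_speakers).astype(str)
    rank = np.empty_like(scores, dtype=int)
    for i in range(n_probes):
        order = np.lexsort((known_str, -scores[i]))
        rank[i, order] = np.arange(1, n_known + 1)

    above = scores >= threshold
    if variant == "all":
        accepted = above
    elif variant == "rank1":
        accepted = above & (rank == 1)
    else:  # topN: N highest-scoring acceptances across all probes
        accepted = np.zeros_like(above)
        cand = np.argwhere(above)
        if len(cand):
            cand_scores = scores[above]
            # deterministic order: score desc, then probe index, then known id
            order = np.lexsort((known_str[cand[:, 1]], cand[:, 0], -cand_scores))
            keep = cand[order[: int(n_best)]]
            accepted[keep[:, 0], keep[:, 1]] = True

    probe_ids = np.asarray(probe_ids).astype(str)
    probe_speakers = np.asarray(probe_speakers).astype(str)
    table = pd.DataFrame(
        {
            "probe_id": np.repeat(probe_ids, n_known),
            "probe_speaker": np.repeat(probe_speakers, n_known),
            "known_speaker": np.tile(known_str, n_probes),
            "score": scores.ravel(),
            "rank": rank.ravel(),
            "accepted": accepted.ravel(),
        }
    )
    mt = MatchTable(table=table, threshold=float(threshold), variant=variant, n_best=n_best)
    mt.validate()
    return mt


def _probe_vectors(
    cohort: EmbeddingCohort, split: SpeakerSplit, pool_probes: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rec_index = cohort.index_by_recording()
    probe_ids, probe_speakers, vectors = [], [], []
    by_speaker = cohort.indices_by_speaker() if pool_probes else None
    enrolled_recs = {
        r for recs in split.known_enrollment.values() for r in recs
    }
    for spk, rec in split.unknown_probes:
        probe_speakers.append(spk)
        if pool_probes:
            # Link all of the speaker's shareable recordings (those not sitting
            # in the adversary's enrollment data) and average their embeddings.
            idx = by_speaker[spk]
            idx = idx[[str(r) not in enrolled_recs for r in cohort.recording_ids[idx]]]
            if len(idx) == 0:
                idx = np.array([rec_index[rec]])
            vectors.append(cohort.X[idx].mean(axis=0))
            probe_ids.append(f"{spk}-pooled")
        else:
            vectors.append(cohort.X[rec_index[rec]])
            probe_ids.append(rec)
    return (
        np.array(probe_ids, dtype=object),
        np.array(probe_speakers, dtype=object),
        np.vstack(vectors),
    )


def run_attack(
    model: PLDAModel,
    split: SpeakerSplit,
    cohort: EmbeddingCohort,
    threshold: float,
    variant: str = "all",
    n_best: Optional[int] = None,
    pool_probes: bool = False,
) -> MatchTable:
    """Score a split's probes against its known enrollments and decide matches.

    With ``pool_probes`` each unknown speaker's probe is replaced by the mean
    embedding of all their shareable recordings (linkage across tasks).
    """
    if not split.unknown_probes:
        raise ValidationError("split has an empty probe set")
    exclude = [
        rec for spk, rec in split.unknown_probes if spk in split.overlap_speakers
    ]
    enrollment_recs = [r for recs in split.known_enrollment.values() for r in recs]
    rec_index = cohort.index_by_recording()
    sub = cohort.subset(np.array([rec_index[r] for r in enrollment_recs], dtype=int))
    enrollments = enroll(sub, speakers=sorted(split.known_speakers), exclude_recordings=exclude)
    probe_ids, probe_speakers, vectors = _probe_vectors(cohort, split, pool_probes)
    scores = score_matrix(model, enrollments, vectors)
    return match_table_from_scores(
        scores,
        probe_ids,
        probe_speakers,
        enrollments.speaker_ids,
        threshold,
        variant=variant,
        n_best=n_best,
    )


@dataclass
class RiskSummary:
    """Risk metrics of one attack run.

    ``precision`` is ``None`` (undefined, not zero) when nothing was
    accepted; ``fa_ta_ratio`` is ``None`` when both counts are zero and
    ``+inf`` when FA > 0 = TA.
    """

    ta: int
    fa: int
    comparisons: int
    genuine_pairs: int
    far: float
    precision: Optional[float]
    fa_ta_ratio: Optional[float]
    n_known: int
    n_unknown: int
    n_overlap: int
    descriptor: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.ta > self.genuine_pairs:
            raise ValidationError("TA cannot exceed the number of genuine pairs")
        if self.fa > self.comparisons - self.genuine_pairs:
            raise ValidationError("FA cannot exceed the number of impostor pairs")
        if self.precision is not None and not 0.0 <= self.precision <= 1.0:
            raise ValidationError("precision must lie in [0, 1]")


def count_outcomes(
    table: MatchTable, split: SpeakerSplit, descriptor: dict | None = None
) -> RiskSummary:
    """Tabulate TA/FA, FAR, precision and the FA/TA ratio for one attack run.

    Genuine pairs number exactly one per overlap speaker (one probe, one
    enrollment row); the FAR denominator is the impostor comparison count.
    """
    probe_speakers = {s for s, _ in split.unknown_probes}
    table_probes = set(table.table["probe_speaker"].unique())
    if table_probes != probe_speakers:
        raise ValidationError("match table probes do not correspond to the split")
    known_in_table = set(table.table["known_speaker"].unique())
    if known_in_table != set(split.known_speakers):
        raise ValidationError("match table known speakers do not correspond to the split")

    acc = table.accepted()
    ta = int((acc["probe_speaker"] == acc["known_speaker"]).sum())
    fa = len(acc) - ta
    comparisons = split.n_unknown * split.n_known
    genuine_pairs = split.n_overlap
    impostor = comparisons - genuine_pairs
    far = fa / impostor if impostor > 0 else 0.0
    precision = ta / (ta + fa) if (ta + fa) > 0 else None
    if ta > 0:
        ratio: Optional[float] = fa / ta
    elif fa > 0:
        ratio = math.inf
    else:
        ratio = None
    summary = RiskSummary(
        ta=ta,
        fa=fa,
        comparisons=comparisons,
        genuine_pairs=genuine_pairs,
        far=far,
        precision=precision,
        fa_ta_ratio=ratio,
        n_known=split.n_known,
        n_unknown=split.n_unknown,
        n_overlap=split.n_overlap,
        descriptor=dict(descriptor or {}),
    )
    summary.validate()
    return summary


def search_space(
    n_known: int,
    n_unknown: int,
    stratum_fraction_known: Optional[float] = None,
    stratum_fraction_unknown: Optional[float] = None,
) -> tuple[float, Optional[float]]:
    """Comparison count of an attack, optionally under demographic stratification.

    Without fractions, returns ``(n_known * n_unknown, None)``.  With
    fractions (e.g. restricting both sides to the male speakers under a 50:50
    gender balance), the stratum search space is
    ``(f_k * n_known) * (f_u * n_unknown)`` and the reduction percentage is
    ``100 * (1 - f_k * f_u)`` — 75% for f_k = f_u = 0.5.
    """
    if n_known < 0 or n_unknown < 0:
        raise ConfigurationError("set sizes must be non-negative")
    if stratum_fraction_known is None and stratum_fraction_unknown is None:
        return float(n_known * n_unknown), None
    f_k = 1.0 if stratum_fraction_known is None else stratum_fraction_known
    f_u = 1.0 if stratum_fraction_unknown is None else stratum_fraction_unknown
    for name, f in (("stratum_fraction_known", f_k), ("stratum_fraction_unknown", f_u)):
        if not 0.0 < f <= 1.0:
            raise ConfigurationError(f"{name} must lie in (0, 1]")
    comparisons = (f_k * n_known) * (f_u * n_unknown)
    return comparisons, 100.0 * (1.0 - f_k * f_u)
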