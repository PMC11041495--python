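"""Speaker-set sampling for the marketer attack.

One attack instance is a :class:`SpeakerSplit`:

* **known set** — identified speakers the adversary enrolls, using all of
  their eligible recordings;
* **unknown set** — the shared, de-identified probes, exactly one recording
  per unknown speaker; it is the disjoint union of
* **unknown-only speakers** (no true match exists) and
* **overlap speakers** (also present in the known set — the only probes a
  correct match exists for).

For overlap speakers the probe recording is withheld from that speaker's
enrollment set, mirroring the fact that the shared recording would not also
sit in the adversary's reference collection.

Task filters support cross-task and within-task designs: ``enroll_task``
restricts the recordings used for enrollment, ``probe_task`` restricts probe
candidates, and ``exclude_recordings`` removes specific recordings from the
enrollment pool (e.g. a sentence held out for probing across the whole
cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, DegenerateDataError, ValidationError
from .synthetic_embeddings import EmbeddingCohort

__all__ = ["SpeakerSplit", "make_split", "make_split_series"]


@dataclass(frozen=True)
class SpeakerSplit:
    """One sampled attack instance; see the module docstring for the roles."""

    known_enrollment: dict[str, tuple[str, ...]]
    unknown_probes: tuple[tuple[str, str], ...]
    overlap_speakers: frozenset[str]
    unknown_only_speakers: frozenset[str]
    seed: int
    requested: tuple[int, int, int] = (0, 0, 0)
    probe_task: str | None = None
    enroll_task: str | None = None
    shortfall: int = 0

    @property
    def known_speakers(self) -> frozenset[str]:
        return frozenset(self.known_enrollment)

    @property
    def n_known(self) -> int:
        return len(self.known_enrollment)

    @property
    def n_unknown(self) -> int:
        return len(self.unknown_probes)

    @property
    def n_overlap(self) -> int:
        return len(self.overlap_speakers)

    def validate(self, cohort: EmbeddingCohort | None = None) -> None:
        known = self.known_speakers
        unknown_speakers = [s for s, _ in self.unknown_probes]
        if len(set(unknown_speakers)) != len(unknown_speakers):
            raise ValidationError("exactly one probe per unknown speaker is required")
        if set(unknown_speakers) != self.overlap_speakers | self.unknown_only_speakers:
            raise ValidationError("unknown set must equal overlap union unknown-only")
        if self.overlap_speakers & self.unknown_only_speakers:
            raise ValidationError("overlap and unknown-only sets must be disjoint")
        if self.unknown_only_speakers & known:
            raise ValidationError("unknown-only speakers must not appear in the known set")
        if not self.overlap_speakers <= known:
            raise ValidationError("overlap speakers must be a subset of the known set")
        probe_by_speaker = dict(self.unknown_probes)
        for spk in self.overlap_speakers:
            recs = self.known_enrollment[spk]
            if not recs:
                raise ValidationError(f"overlap speaker {spk!r} has no enrollment recordings")
            if probe_by_speaker[spk] in recs:
                raise ValidationError(
                    f"probe recording of overlap speaker {spk!r} leaked into enrollment"
                )
        for spk, recs in self.known_enrollment.items():
            if not recs:
                raise ValidationError(f"known speaker {spk!r} has no enrollment recordings")
        if cohort is not None:
            rec_index = cohort.index_by_recording()
            sid = {str(r): str(s) for r, s in zip(cohort.recording_ids, cohort.speaker_ids)}
            for spk, recs in self.known_enrollment.items():
                for r in recs:
                    if r not in rec_index or sid[r] != spk:
                        raise ValidationError(f"enrollment recording {r!r} invalid for {spk!r}")
            for spk, r in self.unknown_probes:
                if r not in rec_index or sid[r] != spk:
                    raise ValidationError(f"probe recording {r!r} invalid for {spk!r}")


def _pools(
    cohort: EmbeddingCohort,
    probe_task: str | None,
    enroll_task: str | None,
    exclude_recordings: Sequence[str] | None,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    excluded = set(map(str, exclude_recordings)) if exclude_recordings else set()
    tasks = cohort.tasks.astype(str)
    sids = cohort.speaker_ids.astype(str)
    recs = cohort.recording_ids.astype(str)
    enroll_pool: dict[str, list[str]] = {}
    probe_pool: dict[str, list[str]] = {}
    for rec, spk, task in zip(recs, sids, tasks):
        if (enroll_task is None or task == enroll_task) and rec not in excluded:
            enroll_pool.setdefault(spk, []).append(rec)
        if probe_task is None or task == probe_task:
            probe_pool.setdefault(spk, []).append(rec)
    for pool in (enroll_pool, probe_pool):
        for v in pool.values():
            v.sort()
    return enroll_pool, probe_pool


def make_split(
    cohort: EmbeddingCohort,
    n_known: int,
    n_unknown: int,
    n_overlap: int,
    probe_task: str | None = None,
    enroll_task: str | None = None,
    seed: int = 0,
    exclude_recordings: Sequence[str] | None = None,
    allow_shortfall: bool = True,
) -> SpeakerSplit:
    """Sample one attack instance from a cohort.

    Overlap speakers are drawn uniformly from the sampled known set (among
    those with a viable probe), unknown-only speakers from the remaining
    probe-eligible speakers.  Enrollment uses *all* eligible recordings per
    known speaker; each unknown speaker contributes exactly one probe
    recording, withheld from enrollment for overlap speakers.

    When fewer speakers are eligible for the known set than requested and
    ``allow_shortfall`` is true, all eligible speakers are used and the
    shortfall is recorded on the split.
    """
    if n_known < 1 or n_unknown < 1:
        raise ConfigurationError("n_known and n_unknown must be >= 1")
    if not 0 <= n_overlap <= min(n_known, n_unknown):
        raise ConfigurationError(
            f"n_overlap must lie in [0, min(n_known, n_unknown)] = "
            f"[0, {min(n_known, n_unknown)}]"
        )
    enroll_pool, probe_pool = _pools(cohort, probe_task, enroll_task, exclude_recordings)
    rng = np.random.default_rng(seed)

    known_eligible = np.array(sorted(enroll_pool), dtype=object)
    shortfall = 0
    if len(known_eligible) < n_known:
        if not allow_shortfall:
            raise DegenerateDataError(
                f"only {len(known_eligible)} speakers eligible for the known set, "
                f"{n_known} requested"
            )
        shortfall = n_known - len(known_eligible)
        known = known_eligible
    else:
        known = rng.choice(known_eligible, size=n_known, replace=False)
    known_set = {str(s) for s in known}

    def overlap_probe_candidates(spk: str) -> list[str]:
        # probe choices that leave the speaker's enrollment non-empty
        enr = enroll_pool[spk]
        return [p for p in probe_pool.get(spk, []) if len(enr) >= 2 or p not in enr]

    overlap_eligible = np.array(
        sorted(s for s in known_set if overlap_probe_candidates(s)), dtype=object
    )
    if len(overlap_eligible) < n_overlap:
        raise DegenerateDataError(
            f"only {len(overlap_eligible)} known speakers have a viable probe "
            f"recording; {n_overlap} overlap speakers requested"
        )
    overlap = rng.choice(overlap_eligible, size=n_overlap, replace=False) if n_overlap else np.array([], dtype=object)
    overlap_set = {str(s) for s in overlap}

    unknown_only_pool = np.array(
        sorted(s for s in probe_pool if s not in known_set), dtype=object
    )
    n_unknown_only = n_unknown - n_overlap
    if len(unknown_only_pool) < n_unknown_only:
        raise DegenerateDataError(
            f"only {len(unknown_only_pool)} speakers are eligible for the "
            f"unknown-only set; {n_unknown_only} requested"
        )
    unknown_only = (
        rng.choice(unknown_only_pool, size=n_unknown_only, replace=False)
        if n_unknown_only
        else np.array([], dtype=object)
    )
    unknown_only_set = {str(s) for s in unknown_only}

    probes: list[tuple[str, str]] = []
    withheld: dict[str, str] = {}
    for spk in sorted(overlap_set):
        probe = str(rng.choice(np.array(overlap_probe_candidates(spk), dtype=object)))
        probes.append((spk, probe))
        withheld[spk] = probe
    for spk in sorted(unknown_only_set):
        probes.append((spk, str(rng.choice(np.array(probe_pool[spk], dtype=object)))))

    known_enrollment = {
        str(spk): tuple(r for r in enroll_pool[str(spk)] if r != withheld.get(str(spk)))
        for spk in sorted(known_set)
    }
    split = SpeakerSplit(
        known_enrollment=known_enrollment,
        unknown_probes=tuple(probes),
        overlap_speakers=frozenset(overlap_set),
        unknown_only_speakers=frozenset(unknown_only_set),
        seed=seed,
        requested=(n_known, n_unknown, n_overlap),
        probe_task=probe_task,
        enroll_task=enroll_task,
        shortfall=shortfall,
    )
    split.validate(cohort)
    return split


def make_split_series(
    cohort: EmbeddingCohort,
    sizes: Sequence[tuple[int, int, int]],
    splits_per_size: int,
    seed: int = 0,
    **split_kwargs,
) -> list[SpeakerSplit]:
    """Independent splits for each (n_known, n_unknown, n_overlap) size.

    Child seeds are derived deterministically from the master seed, so the
    full series is reproducible and insensitive to how the caller iterates.
    """
    if splits_per_size < 1:
        raise ConfigurationError("splits_per_size must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(sizes) * splits_per_size)
    out = []
    k = 0
    for n_known, n_unknown, n_overlap in sizes:
        for _ in range(splits_per_size):
            out.append(
                make_split(
                    cohort,
                    n_known,
                    n_unknown,
                    n_overlap,
                    seed=int(child_seeds[k]),
                    **split_kwargs,
                )
            )
            k += 1
    return out
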