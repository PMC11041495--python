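"""Synthetic speaker-embedding cohorts.

Real speaker-verification pipelines turn each recording into a fixed-length
embedding (an x-vector) whose geometry is well described by a two-covariance
Gaussian model: a speaker draws a latent identity vector from a between-speaker
distribution, and each of their recordings scatters around it with
within-speaker covariance.  This module simulates cohorts with exactly that
structure so the downstream verifier, calibration and attack machinery can be
exercised without audio or a neural embedding extractor.

Elicited speech tasks (reading passage, sentence repetition, word repetition,
sequential/alternating motion rates, vowel prolongation) differ in how similar
they are to natural connected speech.  Two mechanisms model this:

* a task-specific **rotation** of the speaker latent — by the task angle in
  each of floor(d/2) orthogonal 2-planes drawn once from the seed — so large
  angles make a speaker's vowel-prolongation embeddings point away from their
  connected-speech embeddings (cross-task mismatch; expected cosine to the
  reference task is cos(theta)) while preserving the within-task geometry;
* a task-specific **within-speaker scale** — stereotyped tasks with few dynamic
  speaker factors (e.g. sustained vowels) produce tightly clustered recordings.

A task offset and an isotropic channel-noise term complete the model:

    x = R(theta_t) @ y_s + b_t + eps,   y_s ~ N(0, Phi_b),
    eps ~ N(0, sigma_t^2 Phi_w + c^2 I)

Cohorts are reproducible: identical (config, seed) pairs yield bit-identical
embeddings.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateDataError, ValidationError

__all__ = [
    "TaskConfig",
    "GeneratorConfig",
    "EmbeddingCohort",
    "generate_cohort",
    "empirical_covariances",
    "mayo_like_tasks",
]


@dataclass(frozen=True)
class TaskConfig:
    """One elicited speech task in a generator configuration.

    Parameters
    ----------
    name
        Task label (e.g. ``"sentence"``).
    recordings_per_speaker
        Number of recordings of this task per speaker (may be zero).
    rotation_angle
        Rotation of the speaker latent within the cohort's fixed set of
        orthogonal 2-planes, in radians, restricted to ``[0, pi/2]``.  Zero
        for the reference task.
    within_scale
        Multiplier on the within-speaker standard deviation for this task;
        values below one model stereotyped tasks.
    offset_magnitude
        Length of the task-specific mean offset shared by all speakers.
    """

    name: str
    recordings_per_speaker: int
    rotation_angle: float = 0.0
    within_scale: float = 1.0
    offset_magnitude: float = 0.0

    def validate(self) -> None:
        if not self.name:
            raise ConfigurationError("task name must be non-empty")
        if self.recordings_per_speaker < 0:
            raise ConfigurationError(
                f"task {self.name!r}: recordings_per_speaker must be >= 0"
            )
        if not 0.0 <= self.rotation_angle <= np.pi / 2 + 1e-12:
            raise ConfigurationError(
                f"task {self.name!r}: rotation_angle must lie in [0, pi/2]"
            )
        if not self.within_scale > 0:
            raise ConfigurationError(
                f"task {self.name!r}: within_scale must be positive"
            )
        if self.offset_magnitude < 0:
            raise ConfigurationError(
                f"task {self.name!r}: offset_magnitude must be >= 0"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic embedding cohort.

    ``between_cov`` and ``within_cov`` accept either a scalar (isotropic
    variance) or a full matrix.  The between-speaker covariance must be
    positive semidefinite, the within-speaker covariance positive definite.
    The default dimensionality of 192 matches the x-vectors produced by
    ECAPA-TDNN style extractors.
    """

    n_speakers: int
    tasks: tuple[TaskConfig, ...]
    dim: int = 192
    between_cov: float | np.ndarray = 1.0
    within_cov: float | np.ndarray = 1.0
    channel_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tasks", tuple(self.tasks))

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.dim < 1:
            raise ConfigurationError("dim must be a positive integer")
        if self.n_speakers < 1:
            raise ConfigurationError("n_speakers must be a positive integer")
        if not self.tasks:
            raise ConfigurationError("at least one task is required")
        names = [t.name for t in self.tasks]
        if len(set(names)) != len(names):
            raise ConfigurationError("task names must be unique")
        for t in self.tasks:
            t.validate()
        if sum(t.recordings_per_speaker for t in self.tasks) < 1:
            raise ConfigurationError("every speaker needs at least one recording")
        if self.channel_noise_sd < 0:
            raise ConfigurationError("channel_noise_sd must be >= 0")
        if self.dim < 2 and any(t.rotation_angle > 0 for t in self.tasks):
            raise ConfigurationError("rotations require dim >= 2")
        resolve_covariance(self.between_cov, self.dim, "between_cov", positive_definite=False)
        resolve_covariance(self.within_cov, self.dim, "within_cov", positive_definite=True)

    @property
    def n_records(self) -> int:
        return self.n_speakers * sum(t.recordings_per_speaker for t in self.tasks)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("between_cov", "within_cov"):
            v = d[key]
            if isinstance(v, np.ndarray):
                d[key] = v.tolist()
        d["tasks"] = [dataclasses.asdict(t) for t in self.tasks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["tasks"] = tuple(TaskConfig(**t) for t in d.get("tasks", ()))
        for key in ("between_cov", "within_cov"):
            v = d.get(key)
            if isinstance(v, list):
                d[key] = np.asarray(v, dtype=float)
        return cls(**d)


def resolve_covariance(
    spec: float | np.ndarray, dim: int, name: str, *, positive_definite: bool
) -> np.ndarray:
    """Expand a scalar-or-matrix covariance spec to a validated dim x dim matrix."""
    if np.isscalar(spec):
        v = float(spec)
        if positive_definite and not v > 0:
            raise ValidationError(f"{name}: isotropic variance must be positive")
        if not positive_definite and v < 0:
            raise ValidationError(f"{name}: isotropic variance must be >= 0")
        return v * np.eye(dim)
    m = np.asarray(spec, dtype=float)
    if m.shape != (dim, dim):
        raise ValidationError(f"{name}: expected shape ({dim}, {dim}), got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-10 * (1.0 + np.abs(m).max())):
        raise ValidationError(f"{name}: matrix must be symmetric")
    eig = np.linalg.eigvalsh(m)
    floor = -1e-10 * max(1.0, float(eig[-1]))
    if positive_definite and eig[0] <= 0:
        raise ValidationError(f"{name}: matrix must be positive definite")
    if eig[0] < floor:
        raise ValidationError(f"{name}: matrix must be positive semidefinite")
    return m


@dataclass
class EmbeddingCohort:
    """A labelled set of recordings with fixed-dimension embeddings.

    This is the universe both the defender (sharing organisation) and the
    attacker sample from.  ``X`` holds one embedding per row, aligned with
    ``recording_ids`` / ``speaker_ids`` / ``tasks``.
    """

    recording_ids: np.ndarray
    speaker_ids: np.ndarray
    tasks: np.ndarray
    X: np.ndarray
    provenance: GeneratorConfig | str | None = None

    def __post_init__(self) -> None:
        self.recording_ids = np.asarray(self.recording_ids, dtype=object)
        self.speaker_ids = np.asarray(self.speaker_ids, dtype=object)
        self.tasks = np.asarray(self.tasks, dtype=object)
        self.X = np.asarray(self.X, dtype=float)

    # -- contracts ----------------------------------------------------------

    def validate(self) -> None:
        n = len(self.recording_ids)
        if not (len(self.speaker_ids) == len(self.tasks) == self.X.shape[0] == n):
            raise ValidationError("cohort columns have inconsistent lengths")
        if n == 0:
            raise ValidationError("cohort is empty")
        if len(set(self.recording_ids)) != n:
            raise ValidationError("recording_ids must be unique")
        if self.X.ndim != 2:
            raise ValidationError("embeddings must form a 2-D array")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("embeddings must be finite")

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def speakers(self) -> np.ndarray:
        """Unique speaker ids, sorted."""
        return np.unique(self.speaker_ids.astype(str))

    def subset(self, index: np.ndarray) -> "EmbeddingCohort":
        """Row subset (boolean mask or integer index array)."""
        return EmbeddingCohort(
            recording_ids=self.recording_ids[index],
            speaker_ids=self.speaker_ids[index],
            tasks=self.tasks[index],
            X=self.X[index],
            provenance=self.provenance,
        )

    def for_task(self, task: str) -> "EmbeddingCohort":
        return self.subset(self.tasks.astype(str) == task)

    def index_by_recording(self) -> dict[str, int]:
        return {str(r): i for i, r in enumerate(self.recording_ids)}

    def indices_by_speaker(self) -> dict[str, np.ndarray]:
        order = np.argsort(self.speaker_ids.astype(str), kind="stable")
        out: dict[str, np.ndarray] = {}
        sorted_sids = self.speaker_ids.astype(str)[order]
        bounds = np.flatnonzero(
            np.r_[True, sorted_sids[1:] != sorted_sids[:-1], True]
        )
        for a, b in zip(bounds[:-1], bounds[1:]):
            out[sorted_sids[a]] = order[a:b]
        return out

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the cohort as a TSV table plus a JSON sidecar with provenance.

        Columns: recording_id, speaker_id, task, e_0 ... e_{dim-1}.  The
        sidecar defaults to ``<path>.json`` and records the generating
        configuration (or an external-source tag).
        """
        path = Path(path)
        cols = {"recording_id": self.recording_ids.astype(str),
                "speaker_id": self.speaker_ids.astype(str),
                "task": self.tasks.astype(str)}
        frame = pd.DataFrame(cols)
        emb = pd.DataFrame(self.X, columns=[f"e_{j}" for j in range(self.dim)])
        pd.concat([frame, emb], axis=1).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
        sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(
            path.suffix + ".json"
        )
        if isinstance(self.provenance, GeneratorConfig):
            meta = {"source": "synthetic", "generator": self.provenance.to_dict()}
        else:
            meta = {"source": self.provenance or "external"}
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path | None = None) -> "EmbeddingCohort":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"recording_id", "speaker_id", "task"}
        if not required.issubset(frame.columns):
            raise ValidationError(f"cohort TSV must contain columns {sorted(required)}")
        emb_cols = [c for c in frame.columns if c.startswith("e_")]
        emb_cols.sort(key=lambda c: int(c.split("_", 1)[1]))
        provenance: GeneratorConfig | str | None = None
        sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(
            path.suffix + ".json"
        )
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if meta.get("source") == "synthetic" and "generator" in meta:
                provenance = GeneratorConfig.from_dict(meta["generator"])
            else:
                provenance = meta.get("source")
        cohort = cls(
            recording_ids=frame["recording_id"].to_numpy(dtype=object),
            speaker_ids=frame["speaker_id"].to_numpy(dtype=object),
            tasks=frame["task"].to_numpy(dtype=object),
            X=frame[emb_cols].to_numpy(dtype=float),
            provenance=provenance,
        )
        cohort.validate()
        return cohort


def _rotation_matrix(basis: np.ndarray, theta: float) -> np.ndarray:
    """Simultaneous rotation by ``theta`` in floor(d/2) orthogonal 2-planes.

    ``basis`` is an orthogonal matrix whose consecutive column pairs span the
    planes (one odd leftover coordinate stays fixed).  Rotating every plane by
    the same angle makes the expected cosine between a latent vector and its
    rotated image equal cos(theta), so the task angle directly controls
    cross-task similarity; a rotation confined to a single plane would touch
    only 2/d of the latent energy and could never attenuate high-dimensional
    embeddings appreciably.
    """
    d = basis.shape[0]
    block = np.eye(d)
    c, s = np.cos(theta), np.sin(theta)
    for k in range(0, d - 1, 2):
        block[k, k] = block[k + 1, k + 1] = c
        block[k, k + 1] = -s
        block[k + 1, k] = s
    return basis @ block @ basis.T


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """A factor L with L @ L.T = m, valid for singular PSD matrices."""
    w, q = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return q * np.sqrt(w)


def generate_cohort(config: GeneratorConfig) -> EmbeddingCohort:
    """Draw a cohort from the generative model described in the module docstring.

    The random stream is consumed in a fixed order — rotation-plane basis,
    task offset directions, speaker latents, then per-task noise — so that cohorts
    generated with different rotation angles but the same seed share latents
    and noise, which keeps cross-task comparisons paired.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    d, n_spk = config.dim, config.n_speakers

    between = resolve_covariance(config.between_cov, d, "between_cov", positive_definite=False)
    within = resolve_covariance(config.within_cov, d, "within_cov", positive_definite=True)
    l_between = _psd_factor(between)
    l_within = np.linalg.cholesky(within)

    if d >= 2:
        basis, _ = np.linalg.qr(rng.standard_normal((d, d)))
    else:
        basis = np.eye(d)

    offsets = {}
    for task in config.tasks:
        direction = rng.standard_normal(d)
        norm = np.linalg.norm(direction)
        offsets[task.name] = task.offset_magnitude * direction / norm

    latents = rng.standard_normal((n_spk, d)) @ l_between.T

    speakers = np.array([f"S{i:05d}" for i in range(n_spk)], dtype=object)
    blocks, rec_ids, spk_col, task_col = [], [], [], []
    for task in config.tasks:
        rotated = latents if task.rotation_angle == 0.0 else latents @ _rotation_matrix(
            basis, task.rotation_angle
        ).T
        for rep in range(task.recordings_per_speaker):
            noise = rng.standard_normal((n_spk, d)) @ (task.within_scale * l_within).T
            channel = config.channel_noise_sd * rng.standard_normal((n_spk, d))
            blocks.append(rotated + offsets[task.name] + noise + channel)
            rec_ids.extend(f"{s}-{task.name}-r{rep}" for s in speakers)
            spk_col.extend(speakers)
            task_col.extend([task.name] * n_spk)

    cohort = EmbeddingCohort(
        recording_ids=np.array(rec_ids, dtype=object),
        speaker_ids=np.array(spk_col, dtype=object),
        tasks=np.array(task_col, dtype=object),
        X=np.vstack(blocks),
        provenance=config,
    )
    cohort.validate()
    return cohort


def empirical_covariances(cohort: EmbeddingCohort) -> tuple[np.ndarray, np.ndarray]:
    """One-way ANOVA moment estimates of (between, within) speaker covariances.

    ``within`` is the pooled covariance of recordings about their speaker
    means, SSW / (N - S).  ``between`` is the mean-square between-speaker
    scatter corrected for within-speaker sampling noise,
    (MSB - within) / n0 with n0 = (N - sum n_s^2 / N) / (S - 1).

    Raises
    ------
    DegenerateDataError
        If the cohort has a single speaker, or no speaker has a repeated
        recording (within-speaker scatter unidentifiable).
    """
    sids = cohort.speaker_ids.astype(str)
    uniq, inverse = np.unique(sids, return_inverse=True)
    n_speakers = len(uniq)
    n = cohort.n_records
    if n_speakers < 2:
        raise DegenerateDataError(
            "between-speaker covariance requires at least two speakers"
        )
    if n - n_speakers < 1:
        raise DegenerateDataError(
            "within-speaker covariance requires a speaker with >= 2 recordings"
        )
    d = cohort.dim
    counts = np.bincount(inverse).astype(float)
    sums = np.zeros((n_speakers, d))
    np.add.at(sums, inverse, cohort.X)
    means = sums / counts[:, None]

    total_sq = cohort.X.T @ cohort.X
    ssw = total_sq - means.T @ sums  # sum x x' - sum n m m'
    within = ssw / (n - n_speakers)
    within = 0.5 * (within + within.T)

    grand = cohort.X.mean(axis=0)
    centered = means - grand
    ssb = (centered * counts[:, None]).T @ centered
    msb = ssb / (n_speakers - 1)
    n0 = (n - float(counts @ counts) / n) / (n_speakers - 1)
    between = (msb - within) / n0
    between = 0.5 * (between + between.T)
    return between, within


def mayo_like_tasks(
    recordings: dict[str, int] | None = None,
) -> tuple[TaskConfig, ...]:
    """Six elicited speech tasks on the connectedness ordering.

    Reading passage > sentence repetition > word repetition > SMR > AMR >
    vowel prolongation.  Sentence repetition is the reference task (zero
    rotation); rotation angles grow and within-speaker scales shrink as tasks
    become less like connected speech, so a task like vowel prolongation is
    maximally mismatched against connected-speech enrollment yet highly
    stereotyped (and hence discriminative) within-task.
    """
    reps = {"reading": 2, "sentence": 4, "word": 2, "smr": 2, "amr": 3, "vowel": 2}
    if recordings:
        reps.update(recordings)
    params = {
        #          theta  sigma  offset
        "reading": (0.08, 1.05, 0.10),
        "sentence": (0.00, 1.00, 0.00),
        "word": (0.25, 0.90, 0.15),
        "smr": (0.45, 0.75, 0.20),
        "amr": (0.65, 0.60, 0.25),
        "vowel": (0.90, 0.45, 0.30),
    }
    return tuple(
        TaskConfig(
            name=name,
            recordings_per_speaker=reps[name],
            rotation_angle=theta,
            within_scale=sigma,
            offset_magnitude=offset,
        )
        for name, (theta, sigma, offset) in params.items()
    )
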