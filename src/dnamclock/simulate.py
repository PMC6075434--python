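"""Synthetic array-like methylation data with known ground truth.

The generator emulates the statistical structure a clock exploits:
*causal* CpGs whose mean beta follows a logistic curve in calibrated age,

    E[beta_ij] = logistic(a_j + b_j * z_i),
    z_i = F(age_i) + disease_offset * 1[case_i] + tissue_offset[tissue_i],

with intercepts ``a_j`` and balanced-sign slopes ``b_j`` drawn from seeded
ranges, *null* CpGs with age-independent means, additive Gaussian noise
clamped to [0, 1], and two overlapping platform manifests realizing a
configurable split of probes private to one platform.  The disease offset
acts on the transformed-age scale, so the implied acceleration in years
shrinks with age — strongest in young samples, as in progeroid cohorts.

Every planted quantity (causal probes, their slopes, per-sample true
biological age) is returned in a :class:`GroundTruth` record so recovery
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dnamclock.exvivo import PassageRecord, cumulative_pd, population_doubling
from dnamclock.io import BetaMatrix, ProbeManifest
from dnamclock.transform import AgeTransform, inverse_transform_age, transform_age

__all__ = ["SyntheticSpec", "GroundTruth", "generate_dataset", "generate_pd_series"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic methylation study.

    ``ages`` is either a (min, max) range in years or an explicit list
    (which fixes ``n_samples``); ``noise_sd`` is on the beta scale;
    tissue offsets and ``disease_offset`` are in transformed-age units.
    """

    n_samples: int = 100
    n_causal: int = 50
    n_null: int = 450
    ages: tuple = (0.0, 90.0)
    noise_sd: float = 0.03
    tissue_labels: tuple = ("fibroblast",)
    tissue_offsets: tuple = (0.0,)
    disease_frac: float = 0.0
    disease_offset: float = 0.0
    platform_split: float = 0.1
    adult_age: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_causal, self.n_null) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_causal + self.n_null == 0:
            raise ValueError("need at least one probe")
        if not 0 <= self.disease_frac <= 1:
            raise ValueError("disease_frac must be in [0,1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.platform_split <= 1:
            raise ValueError("platform_split must be in [0,1]")
        if len(self.tissue_labels) != len(self.tissue_offsets):
            raise ValueError("tissue_labels and tissue_offsets differ in length")
        if len(self.tissue_labels) == 0:
            raise ValueError("need at least one tissue label")

    @property
    def n_probes(self) -> int:
        return self.n_causal + self.n_null

    @property
    def transform(self) -> AgeTransform:
        return AgeTransform(self.adult_age)


@dataclass
class GroundTruth:
    """Everything planted by the generator, sufficient to rescore recovery."""

    causal_probes: list[str]
    intercepts: np.ndarray  # a_j, causal probes
    slopes: np.ndarray  # b_j (logit units per transformed-age unit)
    null_means: np.ndarray
    samples: pd.DataFrame  # sample_id, age, tissue, disease, z (transformed bio-age), bio_age
    manifests: tuple[ProbeManifest, ProbeManifest] = field(default=None)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_probes(spec: SyntheticSpec):
    """Probe identities and response parameters; a fixed stream per seed.

    Kept separate from the sample stream so that cross-sectional and
    passage-series datasets built from the same spec share probes.
    """
    rng = np.random.default_rng([spec.seed, 0])
    width = max(7, len(str(spec.n_probes)))
    probe_ids = [f"cg{i:0{width}d}" for i in range(1, spec.n_probes + 1)]
    causal = probe_ids[: spec.n_causal]
    a = rng.uniform(-1.0, 1.0, spec.n_causal)
    b = rng.uniform(0.25, 0.6, spec.n_causal)
    signs = np.ones(spec.n_causal)
    signs[1::2] = -1  # balanced slope signs
    b *= signs
    null_means = rng.uniform(0.05, 0.95, spec.n_null)
    split = rng.permutation(spec.n_probes)
    n_private = int(round(spec.platform_split * spec.n_probes))
    only_a = set(split[: n_private // 2])
    only_b = set(split[n_private // 2 : n_private])
    m450 = frozenset(p for i, p in enumerate(probe_ids) if i not in only_b)
    mepic = frozenset(p for i, p in enumerate(probe_ids) if i not in only_a)
    manifests = (ProbeManifest("450K-like", m450), ProbeManifest("EPIC-like", mepic))
    return probe_ids, causal, a, b, null_means, manifests


def _mean_betas(spec: SyntheticSpec, a, b, null_means, z: np.ndarray) -> np.ndarray:
    mean = np.empty((spec.n_probes, len(z)))
    mean[: spec.n_causal] = _logistic(a[:, None] + b[:, None] * z[None, :])
    mean[spec.n_causal :] = np.repeat(null_means[:, None], len(z), axis=1)
    return mean


def generate_dataset(spec: SyntheticSpec) -> tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Draw one cross-sectional dataset: betas, annotation, ground truth.

    Deterministic in ``spec.seed``: the same spec yields bitwise-identical
    output.
    """
    probe_ids, causal, a, b, null_means, manifests = _draw_probes(spec)
    rng = np.random.default_rng([spec.seed, 1])

    if len(spec.ages) == 2 and not isinstance(spec.ages[0], (list, tuple)):
        try:
            lo, hi = float(spec.ages[0]), float(spec.ages[1])
            explicit = None
        except TypeError:
            explicit = np.asarray(spec.ages, dtype=float)
    else:
        explicit = np.asarray(spec.ages, dtype=float)
    if explicit is not None:
        ages = explicit
        n = len(ages)
    else:
        n = spec.n_samples
        ages = rng.uniform(lo, hi, n)
    if np.any(ages <= -1):
        raise ValueError("ages must be > -1")

    tissues = np.asarray(spec.tissue_labels)[rng.integers(0, len(spec.tissue_labels), n)]
    offset_of = dict(zip(spec.tissue_labels, spec.tissue_offsets))
    disease = rng.random(n) < spec.disease_frac

    z_age = np.asarray(transform_age(ages, spec.transform))
    z_bio = z_age + spec.disease_offset * disease
    z = z_bio + np.array([offset_of[t] for t in tissues])

    betas = _mean_betas(spec, a, b, null_means, z)
    if spec.noise_sd > 0:
        betas = betas + rng.normal(0.0, spec.noise_sd, betas.shape)
    betas = np.clip(betas, 0.0, 1.0)

    sample_ids = [f"s{i:04d}" for i in range(n)]
    m = BetaMatrix(probe_ids, sample_ids, betas)
    ann = pd.DataFrame({
        "sample_id": sample_ids,
        "age": ages,
        "sex": "unknown",
        "tissue": tissues,
        "disease": np.where(disease, "case", "control"),
        "pdl": np.nan,
    })
    truth_samples = ann[["sample_id", "age", "tissue", "disease"]].copy()
    truth_samples["z"] = z_bio
    truth_samples["bio_age"] = inverse_transform_age(z_bio, spec.transform)
    truth = GroundTruth(list(causal), a, b, null_means, truth_samples, manifests)
    return m, ann, truth


def generate_pd_series(
    spec: SyntheticSpec,
    n_passages: int = 10,
    drift_per_pd: float = 0.02,
    pd_per_passage: float = 1.0,
    start_age: float = 0.0,
    cells_seeded: int = 10_000,
    pd_jitter: float = 0.05,
    seed: int | None = None,
) -> tuple[list[PassageRecord], BetaMatrix, pd.DataFrame]:
    """Simulate an ex vivo passage series with drifting clock CpGs.

    Causal-probe logits drift linearly in cumulative population doubling
    (``drift_per_pd`` in transformed-age units per doubling); harvest
    counts are drawn so each passage achieves roughly ``pd_per_passage``
    doublings from ``cells_seeded`` cells.  Returns the passage records,
    one beta-matrix sample per passage, and a truth table with the
    cumulative PD and drifted transformed age of each passage.
    """
    if n_passages < 1:
        raise ValueError("need at least one passage")
    probe_ids, causal, a, b, null_means, _ = _draw_probes(spec)
    rng = np.random.default_rng([spec.seed if seed is None else seed, 2])

    records = []
    for p in range(n_passages):
        target = pd_per_passage + rng.normal(0.0, pd_jitter)
        harvested = max(int(round(cells_seeded * 2.0**target)), 1)
        records.append(PassageRecord(p, cells_seeded, harvested, f"passage{p:03d}"))
    cum = cumulative_pd(records)

    z0 = float(transform_age(start_age, spec.transform))
    z = z0 + drift_per_pd * cum
    betas = _mean_betas(spec, a, b, null_means, z)
    if spec.noise_sd > 0:
        betas = betas + rng.normal(0.0, spec.noise_sd, betas.shape)
    betas = np.clip(betas, 0.0, 1.0)
    m = BetaMatrix(probe_ids, [r.sample_id for r in records], betas)
    truth = pd.DataFrame({
        "sample_id": [r.sample_id for r in records],
        "passage": [r.passage for r in records],
        "pd": [population_doubling(r.cells_seeded, r.cells_harvested) for r in records],
        "cum_pd": cum,
        "z": z,
        "bio_age": inverse_transform_age(z, spec.transform),
    })
    return records, m, truth
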