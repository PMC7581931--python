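"""Synthetic habitat-labeled references and communities with known truth.

The generator creates, per environmental category, a pool of ancestor
sequences (i.i.d. uniform nucleotides, full-length 16S scale by
default).  Habitat sharing between categories is controlled by a
symmetric overlap matrix: with probability ``overlap[a][b]`` a given
ancestor slot is shared between categories a and b, emulating taxa that
occur in several environments.  Reference sequences and community
features are independently mutated copies of ancestors (substitutions
at a fixed per-base rate), so the expected percent identity between a
feature and its matching reference is ``100 * (1 - mutation_rate)``
... squarely above the 97% search threshold at the 1% default rate.

Communities are read-count tables: features are allocated to categories
in the requested mixture proportions (largest-remainder rounding), and
reads are drawn multinomially, so the generating mixture is recoverable
from habitat scores up to search/sampling noise.  Gradient studies
interpolate linearly between two mixtures across samples, emulating
designs such as salinity transects.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as hio
from .reference_db import LabeledReference, ReferenceDatabase
from .scoring import CommunityProfile

__all__ = [
    "SimulationConfig",
    "ReferenceGroundTruth",
    "generate_reference_db",
    "generate_community",
    "generate_gradient_study",
    "write_study",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the reference-database generator.

    ``overlap`` is an (n_categories x n_categories) symmetric matrix of
    pairwise ancestor-sharing probabilities with unit diagonal; the
    default (identity) makes category pools pairwise disjoint.
    """

    n_categories: int = 3
    pool_size_per_category: int = 50
    overlap: np.ndarray | None = None
    seq_length: int = 1500
    n_projects_per_category: int = 3
    mutation_rate: float = 0.01
    indel_rate: float = 0.0
    seed: int = 0
    category_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate <= 0.25):
            raise ValueError("mutation_rate must be in [0, 0.25]")
        if not (0 <= self.indel_rate <= 0.05):
            raise ValueError("indel_rate must be in [0, 0.05]")
        if self.overlap is not None:
            ov = np.asarray(self.overlap, dtype=float)
            n = self.n_categories
            if ov.shape != (n, n):
                raise ValueError(f"overlap must be {n}x{n}")
            if not np.allclose(ov, ov.T) or not np.allclose(np.diag(ov), 1.0):
                raise ValueError("overlap must be symmetric with unit diagonal")
            object.__setattr__(self, "overlap", ov)

    @property
    def categories(self) -> list[str]:
        if self.category_names is not None:
            if len(self.category_names) != self.n_categories:
                raise ValueError("category_names length mismatch")
            return list(self.category_names)
        return [f"category_{i}" for i in range(self.n_categories)]


@dataclass(frozen=True)
class ReferenceGroundTruth:
    """A generated database together with its ancestor pools."""

    db: ReferenceDatabase
    ancestors: Mapping[str, list[str]]
    config: SimulationConfig

    @property
    def categories(self) -> list[str]:
        return list(self.ancestors.keys())


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(
    rng: np.random.Generator, sequence: str, rate: float,
    indel_rate: float = 0.0,
) -> str:
    """Substitute each base independently with probability ``rate``.

    A mutated base is always replaced by a different base, so the
    number of mismatches to the ancestor is Binomial(len, rate).  With
    ``indel_rate`` > 0 each position additionally suffers a single-base
    insertion or deletion (equally likely) with that probability, for
    exercising gapped-alignment handling.
    """
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    if rate > 0:
        hit = np.nonzero(rng.random(arr.size) < rate)[0]
        for i in hit:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    if indel_rate > 0:
        out = []
        for b in arr:
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                out.append(b)
                out.append(rng.choice(_BASES))  # insertion after
            else:
                out.append(b)
        arr = np.array(out, dtype="S1")
    return arr.tobytes().decode()


def generate_reference_db(config: SimulationConfig) -> ReferenceGroundTruth:
    """Generate a labeled reference database from per-category ancestor pools.

    Each category gets ``pool_size_per_category`` ancestor slots; slot i
    of category b is shared with (copied from) category a with
    probability ``overlap[a][b]`` for a < b.  Every reference sequence
    is one mutated copy of one ancestor, assigned round-robin to
    ``n_projects_per_category`` projects.
    """
    rng = np.random.default_rng(config.seed)
    cats = config.categories
    pools: dict[str, list[str]] = {
        c: [_random_sequence(rng, config.seq_length)
            for _ in range(config.pool_size_per_category)]
        for c in cats
    }
    if config.overlap is not None:
        ov = config.overlap
        for a in range(len(cats)):
            for b in range(a + 1, len(cats)):
                if ov[a, b] <= 0:
                    continue
                share = rng.random(config.pool_size_per_category) < ov[a, b]
                for i in np.nonzero(share)[0]:
                    pools[cats[b]][i] = pools[cats[a]][i]
    refs = []
    for c in cats:
        for i, ancestor in enumerate(pools[c]):
            refs.append(
                LabeledReference(
                    sequence_id=f"{c}_ref{i:04d}",
                    sequence=_mutate(rng, ancestor, config.mutation_rate,
                                     config.indel_rate),
                    category=c,
                    project_id=f"{c}_proj{i % config.n_projects_per_category}",
                )
            )
    return ReferenceGroundTruth(
        db=ReferenceDatabase(refs), ancestors=pools, config=config
    )


def _allocate_features(
    mixture: Mapping[str, float], n_features: int
) -> dict[str, int]:
    """Largest-remainder allocation of feature slots to categories."""
    cats = list(mixture)
    exact = np.array([mixture[c] * n_features for c in cats])
    base = np.floor(exact).astype(int)
    short = n_features - int(base.sum())
    remainders = exact - base
    for i in np.argsort(-remainders, kind="stable")[:short]:
        base[i] += 1
    return {c: int(n) for c, n in zip(cats, base)}


def _check_mixture(mixture: Mapping[str, float], gt: ReferenceGroundTruth) -> None:
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture proportions sum to {total}, not 1")
    unknown = [c for c in mixture if c not in gt.ancestors]
    if unknown:
        raise ValueError(f"mixture names unknown categories: {unknown}")
    if any(v < 0 for v in mixture.values()):
        raise ValueError("mixture proportions must be non-negative")


def _draw_features(
    rng: np.random.Generator,
    gt: ReferenceGroundTruth,
    allocation: Mapping[str, int],
    mutation_rate: float,
    indel_rate: float = 0.0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Create mutated-pool-copy feature sequences per allocated category.

    Returns (feature_id -> sequence, feature_id -> source category).
    """
    features: dict[str, str] = {}
    truth: dict[str, str] = {}
    counter = 0
    for cat, n in allocation.items():
        pool = gt.ancestors[cat]
        for _ in range(n):
            ancestor = pool[int(rng.integers(len(pool)))]
            fid = f"feature_{counter:04d}"
            features[fid] = _mutate(rng, ancestor, mutation_rate, indel_rate)
            truth[fid] = cat
            counter += 1
    return features, truth


def generate_community(
    gt: ReferenceGroundTruth,
    mixture: Mapping[str, float],
    n_features: int = 40,
    total_reads: int = 10_000,
    mutation_rate: float | None = None,
    seed: int = 0,
    sample_id: str = "sample_1",
) -> tuple[CommunityProfile, dict[str, float]]:
    """Generate one community sample with a known category mixture.

    Features are allocated to categories in the given proportions, each
    feature sequence is a fresh mutated copy of a pool ancestor, and
    ``total_reads`` reads are spread over features by a multinomial
    whose per-category expectation equals the mixture.  Returns the
    profile and the per-feature ground-truth category map.
    """
    _check_mixture(mixture, gt)
    rng = np.random.default_rng(seed)
    rate = gt.config.mutation_rate if mutation_rate is None else mutation_rate
    allocation = _allocate_features(mixture, n_features)
    features, truth = _draw_features(rng, gt, allocation, rate,
                                     gt.config.indel_rate)
    probs = np.zeros(len(features))
    for i, fid in enumerate(features):
        cat = truth[fid]
        probs[i] = mixture[cat] / allocation[cat] if allocation[cat] else 0.0
    probs = probs / probs.sum()
    reads = rng.multinomial(total_reads, probs)
    counts = pd.DataFrame({sample_id: reads}, index=list(features))
    counts.index.name = "feature_id"
    return CommunityProfile(counts, features), truth


def generate_gradient_study(
    gt: ReferenceGroundTruth,
    n_samples: int,
    from_mixture: Mapping[str, float],
    to_mixture: Mapping[str, float],
    n_features_per_category: int = 15,
    reads_per_sample: int = 10_000,
    mutation_rate: float | None = None,
    seed: int = 0,
) -> tuple[CommunityProfile, pd.DataFrame]:
    """Generate a multi-sample study along a linear mixture gradient.

    Sample i (of n) has mixture ``(1 - t) * from + t * to`` with
    ``t = i / (n - 1)``.  All samples share one feature catalogue
    (``n_features_per_category`` features per category involved), so a
    feature is scored once and abundances carry the gradient.  The
    metadata table records the interpolation coordinate t as the
    ``gradient`` covariate.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for a gradient study")
    _check_mixture(from_mixture, gt)
    _check_mixture(to_mixture, gt)
    rng = np.random.default_rng(seed)
    rate = gt.config.mutation_rate if mutation_rate is None else mutation_rate
    involved = sorted(
        {c for c, v in from_mixture.items() if v > 0}
        | {c for c, v in to_mixture.items() if v > 0}
    )
    allocation = {c: n_features_per_category for c in involved}
    features, truth = _draw_features(rng, gt, allocation, rate,
                                     gt.config.indel_rate)
    feature_ids = list(features)
    columns = {}
    ts = np.linspace(0.0, 1.0, n_samples)
    for i, t in enumerate(ts):
        mix = {
            c: (1 - t) * from_mixture.get(c, 0.0) + t * to_mixture.get(c, 0.0)
            for c in involved
        }
        probs = np.array(
            [mix[truth[f]] / n_features_per_category for f in feature_ids]
        )
        probs = probs / probs.sum()
        columns[f"sample_{i:02d}"] = rng.multinomial(reads_per_sample, probs)
    counts = pd.DataFrame(columns, index=feature_ids)
    counts.index.name = "feature_id"
    metadata = pd.DataFrame(
        {"gradient": ts}, index=pd.Index(columns.keys(), name="sample_id")
    )
    return CommunityProfile(counts, features), metadata


def write_study(
    out_dir,
    gt: ReferenceGroundTruth,
    profile: CommunityProfile,
    metadata: pd.DataFrame | None = None,
) -> None:
    """Write a ready-to-run study directory in the pipeline's formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .reference_db import write_db

    write_db(gt.db, out / "reference_db",
             extra_manifest={"seed": gt.config.seed})
    hio.write_fasta(profile.feature_sequences, out / "features.fasta")
    hio.write_feature_table(profile.counts, out / "feature_table.tsv")
    if metadata is not None:
        metadata.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")
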