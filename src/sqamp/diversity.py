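"""Subsampled (rarefied) alpha diversity of feature count tables.

Richness, Shannon (natural log) and Gini-Simpson (1 - sum p^2) are computed
on libraries subsampled without replacement to fixed depths, replicated to
quantify subsampling noise; samples shallower than a requested depth are
skipped with a warning rather than failing the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts with optional
    per-sample condition labels."""

    counts: pd.DataFrame                      # index: features, columns: samples
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        unknown = set(self.condition) - set(self.counts.columns)
        if unknown:
            raise ValueError(f"condition labels for unknown samples: {sorted(unknown)}")

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, counts_tsv, condition_tsv=None) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        cond = {}
        if condition_tsv is not None:
            df = pd.read_csv(condition_tsv, sep="\t", dtype=str)
            cond = dict(zip(df["sample"], df["condition"]))
        return cls(counts=counts.astype(int), condition=cond)

    def to_tsv(self, counts_tsv, condition_tsv=None) -> None:
        self.counts.to_csv(counts_tsv, sep="\t")
        if condition_tsv is not None and self.condition:
            pd.DataFrame({"sample": list(self.condition),
                          "condition": list(self.condition.values())}
                         ).to_csv(condition_tsv, sep="\t", index=False)


def subsample(counts: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Rarefy a count vector to `depth` reads without replacement
    (multivariate hypergeometric draw); reproducible for a fixed seed."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds library size {total}")
    if depth == total:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def alpha_metrics(counts: np.ndarray) -> tuple[int, float, float]:
    """(observed richness, Shannon in nats, Gini-Simpson) of a count vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = counts[counts > 0] / total
    observed = int(p.size)
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p ** 2).sum())
    return observed, shannon, simpson


def rarefaction_profile(matrix: CountMatrix, depths: Iterable[int],
                        reps: int = 10, seed: int = 0) -> pd.DataFrame:
    """Alpha diversity per sample x depth x replicate (long format).

    Samples with fewer reads than a depth are skipped for that depth with a
    logged warning.  Replicate seeds are spawned deterministically from the
    base seed, so the profile is bit-reproducible.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    ss = np.random.SeedSequence(seed)
    # one child seed per (sample, depth, rep), in a fixed order
    for si, sample in enumerate(matrix.samples):
        vec = matrix.counts[sample].to_numpy()
        library = int(vec.sum())
        for depth in depths:
            if depth > library:
                logger.warning("sample %s: library %d < depth %d, skipped",
                               sample, library, depth)
                continue
            for rep in range(reps):
                child = np.random.SeedSequence(
                    entropy=ss.entropy, spawn_key=(si, int(depth), rep))
                sub = subsample(vec, depth,
                                int(child.generate_state(1)[0] % 2**31))
                obs, sh, si_ = alpha_metrics(sub)
                rows.append({"sample": sample, "depth": int(depth),
                             "replicate": rep, "observed": obs,
                             "shannon": sh, "simpson": si_})
    return pd.DataFrame(rows, columns=["sample", "depth", "replicate",
                                       "observed", "shannon", "simpson"])


def rarefaction_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd per sample x depth cell."""
    return (profile
            .groupby(["sample", "depth"])[["observed", "shannon", "simpson"]]
            .agg(["mean", "std"]).reset_index())
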