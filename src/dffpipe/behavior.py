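"""Mounting-behavior scoring and nonparametric group comparisons.

The rank tests are implemented here rather than delegated so that their exact
conventions (midranks, tie correction, continuity correction, the exact-path
switch) are part of the package contract; scipy serves as an independent
oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N = 12  # exact Mann-Whitney enumeration up to this combined n


@dataclass
class BehaviorEventTable:
    """Per-animal mount events plus the roster of all tested animals.

    ``animals`` lists every animal (so zero-mount animals are retained);
    ``events`` holds one row per mount with start/end in seconds.
    """

    animals: pd.DataFrame  # columns: animal_id, group
    events: pd.DataFrame  # columns: animal_id, group, event_start_s, event_end_s
    session_length: float

    def to_csv(self, path: str | Path) -> None:
        """Single CSV; animals without events appear with blank event fields."""
        with_events = set(self.events["animal_id"])
        silent = self.animals[~self.animals["animal_id"].isin(with_events)].copy()
        silent["event_start_s"] = np.nan
        silent["event_end_s"] = np.nan
        df = pd.concat([self.events, silent], ignore_index=True)
        df = df.sort_values(["animal_id", "event_start_s"], kind="stable")
        df.insert(0, "session_length_s", self.session_length)
        df.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehaviorEventTable":
        df = pd.read_csv(path)
        session = float(df["session_length_s"].iloc[0])
        animals = df[["animal_id", "group"]].drop_duplicates().reset_index(drop=True)
        events = df.dropna(subset=["event_start_s", "event_end_s"])[
            ["animal_id", "group", "event_start_s", "event_end_s"]
        ].reset_index(drop=True)
        return cls(animals=animals, events=events, session_length=session)


@dataclass
class MountSummary:
    animal_id: str
    group: str
    n_mounts: int
    total_duration: float  # seconds
    latency: float  # first event start; session_length if no events


def score_mounting(table: BehaviorEventTable) -> list[MountSummary]:
    """Per-animal mount count, summed duration, and latency to first mount."""
    session = table.session_length
    by_animal = {aid: [] for aid in table.animals["animal_id"]}
    for row in table.events.itertuples(index=False):
        start, end = float(row.event_start_s), float(row.event_end_s)
        if not (0.0 <= start < end <= session):
            raise ValueError(
                f"animal {row.animal_id!r}: event ({start:g}, {end:g}) outside "
                f"[0, {session:g}] or empty"
            )
        by_animal.setdefault(row.animal_id, []).append((start, end))
    out = []
    group_of = dict(zip(table.animals["animal_id"], table.animals["group"]))
    for aid, events in by_animal.items():
        events.sort()
        prev_end = -np.inf
        for start, end in events:
            if start < prev_end:
                raise ValueError(f"animal {aid!r}: overlapping mount events")
            prev_end = end
        out.append(
            MountSummary(
                animal_id=aid,
                group=group_of.get(aid, ""),
                n_mounts=len(events),
                total_duration=float(sum(e - s for s, e in events)),
                latency=float(events[0][0]) if events else float(session),
            )
        )
    return out


def summaries_to_frame(summaries: list[MountSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "group": s.group,
                "n_mounts": s.n_mounts,
                "total_duration_s": s.total_duration,
                "latency_s": s.latency,
            }
            for s in summaries
        ]
    )


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p: float  # two-sided
    method: str  # "exact" | "normal"


@dataclass
class KruskalResult:
    h: float
    p: float
    df: int
    method: str  # "chi2" | "permutation"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of all rank assignments when the combined sample
    size is <= 12 and there are no ties; otherwise a normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    has_ties = len(np.unique(combined)) < n
    if n <= EXACT_MAX_N and not has_ties:
        all_ranks = np.arange(1, n + 1)
        base = n1 * (n1 + 1) / 2.0
        us = np.array([sum(c) - base for c in combinations(all_ranks, n1)])
        p_le = float(np.mean(us <= u + 1e-9))
        p_ge = float(np.mean(us >= u - 1e-9))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u=u, p=p, method="exact")

    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return MannWhitneyResult(u=u, p=1.0, method="normal")
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(stats.norm.sf(z)))
    return MannWhitneyResult(u=u, p=p, method="normal")


def kruskal_wallis(
    groups,
    permutation: bool = False,
    n_permutations: int = 10000,
    seed: int = 0,
) -> KruskalResult:
    """Kruskal-Wallis H test with midranks and tie correction.

    p from the chi-squared approximation with k-1 df; with
    ``permutation=True``, a seeded permutation p-value (group labels shuffled
    over the pooled ranks) is returned instead.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in samples):
        raise ValueError("all groups must be non-empty")
    sizes = np.array([len(g) for g in samples])
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = stats.rankdata(pooled)

    def h_statistic(rk: np.ndarray) -> float:
        h = 0.0
        start = 0
        for sz in sizes:
            rsum = rk[start : start + sz].sum()
            h += rsum**2 / sz
            start += sz
        return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)

    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if correction == 0.0:  # all observations identical
        return KruskalResult(h=0.0, p=1.0, df=len(samples) - 1, method="chi2")
    h = h_statistic(ranks) / correction
    df = len(samples) - 1

    if permutation:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ranks)
            if h_statistic(perm) / correction >= h - 1e-12:
                count += 1
        p = (1 + count) / (n_permutations + 1)
        return KruskalResult(h=h, p=p, df=df, method="permutation")

    p = float(stats.chi2.sf(h, df))
    return KruskalResult(h=h, p=p, df=df, method="chi2")
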