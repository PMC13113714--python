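"""Cross-group comparison of resonant-frequency ranges.

Groups of airway spectra (e.g. adult lambeosaurines vs. saurolophines vs.
non-hadrosaurid hadrosauroids) are compared harmonic rank by harmonic rank:
the per-group frequency envelope, a two-sample t-test on the per-airway
rank-k frequencies, and an interval-overlap statistic that formalizes
"partial overlap" statements about frequency domains.

The unit of observation in the tests is one airway pathway (one f_k value
per airway per rank); specimens contributing several routes contribute one
observation per route.  Group-level contrasts use adult specimens only by
default, since ontogenetically immature crests shorten the airways and mix
distributions; ``adults_only=False`` pools all stages.

Raw p-values are reported.  Holm or Bonferroni adjustment across the table
is available as an option for reuse, but is off by default.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AcousticsError, InsufficientSampleError
from .resonance import FrequencyRange, HarmonicSpectrum, integrated_range

TEST_VARIANTS = ("pooled", "welch")


@dataclass(frozen=True)
class GroupSpectra:
    """All member spectra of one comparison group."""

    label: str
    spectra: tuple[HarmonicSpectrum, ...]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise AcousticsError(f"group {self.label!r} has no spectra")
        Ks = {s.K for s in self.spectra}
        if len(Ks) != 1:
            raise AcousticsError(
                f"group {self.label!r} mixes harmonic counts {sorted(Ks)}"
            )
        object.__setattr__(self, "spectra", tuple(self.spectra))

    @property
    def K(self) -> int:
        return self.spectra[0].K

    def values(self, k: int) -> np.ndarray:
        """Per-airway frequencies at rank ``k``."""
        return np.array([s.f(k) for s in self.spectra])


def group_spectra(spectra: Iterable[HarmonicSpectrum],
                  adults_only: bool = True) -> dict[str, GroupSpectra]:
    """Partition spectra by taxonomic group label."""
    buckets: dict[str, list[HarmonicSpectrum]] = {}
    for s in spectra:
        if adults_only and s.pathway.stage != "adult":
            continue
        buckets.setdefault(s.pathway.group, []).append(s)
    return {g: GroupSpectra(g, tuple(v)) for g, v in sorted(buckets.items())}


def group_range(group: GroupSpectra, k: int) -> FrequencyRange:
    """Min/max envelope of the rank-``k`` frequencies over group members."""
    return integrated_range(group.spectra, k)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample test result at one harmonic rank."""

    group_a: str
    group_b: str
    k: int
    t: float
    df: float
    p: float
    variant: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise AcousticsError(f"p-value outside [0, 1]: {self.p}")


def per_harmonic_test(a: GroupSpectra, b: GroupSpectra, k: int,
                      variant: str = "pooled") -> GroupComparison:
    """Two-sided two-sample t-test on per-airway rank-``k`` frequencies.

    ``variant='pooled'`` is the classical equal-variance Student test;
    ``'welch'`` drops the equal-variance assumption.
    """
    if variant not in TEST_VARIANTS:
        raise AcousticsError(
            f"unknown test variant {variant!r}; expected one of {TEST_VARIANTS}"
        )
    xa, xb = a.values(k), b.values(k)
    if len(xa) < 2 or len(xb) < 2:
        raise InsufficientSampleError(
            f"t-test needs ≥2 observations per group at rank {k} "
            f"(got {len(xa)} and {len(xb)})"
        )
    res = stats.ttest_ind(xa, xb, equal_var=(variant == "pooled"))
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if np.isnan(t):  # both groups constant and equal: no evidence of difference
        t, p = 0.0, 1.0
    return GroupComparison(a.label, b.label, k, t=t, df=df, p=p,
                           variant=variant)


def _holm(pvals: Sequence[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def comparison_table(groups: Mapping[str, GroupSpectra],
                     K: int | None = None,
                     variant: str = "pooled",
                     correction: str | None = None) -> pd.DataFrame:
    """All pairwise tests over ``k = 1..K``.

    One row per (group pair, rank), pairs in lexicographic order, ranks
    ascending.  ``correction`` ∈ {None, 'bonferroni', 'holm'} adds a
    ``p_adj`` column over the whole table.
    """
    if len(groups) < 2:
        raise InsufficientSampleError("need at least two groups to compare")
    labels = sorted(groups)
    if K is None:
        K = groups[labels[0]].K
    rows = []
    for ga, gb in combinations(labels, 2):
        for k in range(1, K + 1):
            c = per_harmonic_test(groups[ga], groups[gb], k, variant)
            rows.append([c.group_a, c.group_b, c.k, c.t, c.df, c.p])
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "k", "t", "df", "p"])
    if correction == "bonferroni":
        df["p_adj"] = np.minimum(1.0, df["p"] * len(df))
    elif correction == "holm":
        df["p_adj"] = _holm(df["p"].tolist())
    elif correction is not None:
        raise AcousticsError(f"unknown correction {correction!r}")
    return df


def range_table(groups: Mapping[str, GroupSpectra],
                K: int | None = None) -> pd.DataFrame:
    """Per-group frequency envelope table: ``group,k,lo_hz,hi_hz``."""
    if not groups:
        raise AcousticsError("no groups supplied")
    labels = sorted(groups)
    if K is None:
        K = groups[labels[0]].K
    rows = []
    for g in labels:
        for k in range(1, K + 1):
            r = group_range(groups[g], k)
            rows.append([g, k, r.lo, r.hi])
    return pd.DataFrame(rows, columns=["group", "k", "lo_hz", "hi_hz"])


@dataclass(frozen=True)
class OverlapReport:
    """Interval overlap of range ``a`` with range ``b``.

    ``fraction`` is the overlapped share of ``a``'s width (asymmetric); a
    degenerate ``a`` scores 1 inside ``b`` and 0 outside.
    """

    range_a: FrequencyRange
    range_b: FrequencyRange
    overlap_hz: float
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise AcousticsError(f"overlap fraction outside [0, 1]: {self.fraction}")


def overlap(a: FrequencyRange, b: FrequencyRange) -> OverlapReport:
    """Overlap length ``max(0, min(hi) − max(lo))`` and fraction of ``a``."""
    length = max(0.0, min(a.hi, b.hi) - max(a.lo, b.lo))
    if a.width > 0:
        fraction = length / a.width
    else:  # degenerate range: inside-b test
        fraction = 1.0 if b.lo <= a.lo <= b.hi else 0.0
    return OverlapReport(a, b, overlap_hz=length, fraction=fraction)


def overlap_table(groups: Mapping[str, GroupSpectra],
                  K: int | None = None) -> pd.DataFrame:
    """Pairwise (ordered) range overlaps per rank:
    ``group_a,group_b,k,overlap_hz,fraction_of_a``."""
    if len(groups) < 2:
        raise InsufficientSampleError("need at least two groups to compare")
    labels = sorted(groups)
    if K is None:
        K = groups[labels[0]].K
    rows = []
    for ga in labels:
        for gb in labels:
            if ga == gb:
                continue
            for k in range(1, K + 1):
                rep = overlap(group_range(groups[ga], k),
                              group_range(groups[gb], k))
                rows.append([ga, gb, k, rep.overlap_hz, rep.fraction])
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "k", "overlap_hz", "fraction_of_a"]
    )
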