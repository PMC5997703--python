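"""Ancient-DNA authenticity estimators.

Two quality-control statistics standard in archaeogenetics:

* a mitochondrial contamination point estimate from "private consensus
  allele" sites — positions where the sample's consensus base is rare
  (< 5% by default) in a panel of modern mitogenomes, so that reads
  carrying the panel-common base are best explained by modern
  contamination.  Sites whose consensus/alternative relationship is a
  transition (C<->T or G<->A) are excluded because post-mortem cytosine
  deamination produces exactly those mismatches;

* the Ry statistic for biological sex: the fraction of sex-chromosome
  reads mapping to the Y.  Females carry no Y, so Ry ~ 0 up to
  mismapping noise; males carry one X and one Y and sit in a distinctly
  higher band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MetadataError, NoInformativeSitesError

BASES = ("A", "C", "G", "T")
TRANSITION_PAIRS = frozenset({("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")})

#: Default Ry decision thresholds: call female when the CI upper bound is
#: below 0.016, male when the lower bound exceeds 0.075 (the standard
#: shotgun-sex-assignment cutoffs); anything straddling is indeterminate.
FEMALE_MAX = 0.016
MALE_MIN = 0.075


@dataclass(frozen=True)
class SitePileup:
    """Base-quality-filtered read counts at one mtDNA position."""

    position: int
    counts: dict[str, int]  # reads per base A/C/G/T
    consensus_base: str
    panel_freq: float  # frequency of consensus_base in the modern panel

    def __post_init__(self) -> None:
        if self.consensus_base not in BASES:
            raise ValueError(f"bad consensus base {self.consensus_base!r}")
        if not 0.0 <= self.panel_freq <= 1.0:
            raise ValueError("panel_freq must be in [0,1]")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")
        cons = self.counts.get(self.consensus_base, 0)
        if any(self.counts.get(b, 0) > cons for b in BASES):
            raise ValueError("consensus base must have the maximal count")

    @property
    def depth(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES)


@dataclass(frozen=True)
class SexCounts:
    """Reads mapping to the Y and X chromosomes for one sample."""

    n_y: int
    n_x: int

    def __post_init__(self) -> None:
        if self.n_y < 0 or self.n_x < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_y + self.n_x == 0:
            raise ValueError("n_y + n_x must be positive")


@dataclass(frozen=True)
class ContaminationEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n_sites: int
    n_consensus_reads: int
    n_alternative_reads: int


@dataclass(frozen=True)
class SexCall:
    ry: float
    ci_low: float
    ci_high: float
    call: str  # female | male | indeterminate


def _wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Stable at small counts and at k = 0 or k = n, where the Wald interval
    collapses.
    """
    if n == 0:
        return (0.0, 1.0)
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def contamination_estimate(
    pileups: Iterable[SitePileup],
    panel_threshold: float = 0.05,
    min_depth: int = 10,
    exclude_transitions: bool = True,
    conf: float = 0.95,
) -> ContaminationEstimate:
    """Pooled contamination point estimate over panel-rare consensus sites.

    Sites are retained when the consensus base is rarer than
    ``panel_threshold`` in the modern panel and total depth is at least
    ``min_depth``.  When ``exclude_transitions`` is set, alternative bases
    forming a transition pair with the consensus are zeroed (deamination
    damage mimics contamination at those bases); a site whose every
    alternative is a transition contributes only consensus reads.  The
    estimate is

        sum(alternative reads) / sum(consensus + alternative reads)

    pooled across retained sites, with a Wilson score CI on the pooled
    binomial counts.
    """
    n_cons = 0
    n_alt = 0
    n_sites = 0
    for site in pileups:
        if site.panel_freq >= panel_threshold:
            continue
        if site.depth < min_depth:
            continue
        cons = site.counts.get(site.consensus_base, 0)
        alt = 0
        for b in BASES:
            if b == site.consensus_base:
                continue
            if exclude_transitions and (site.consensus_base, b) in TRANSITION_PAIRS:
                continue
            alt += site.counts.get(b, 0)
        n_cons += cons
        n_alt += alt
        n_sites += 1
    total = n_cons + n_alt
    if n_sites == 0 or total == 0:
        raise NoInformativeSitesError(
            "no informative sites: nothing passed the panel-frequency/depth "
            "filters (or all retained sites had zero usable reads)"
        )
    lo, hi = _wilson_ci(n_alt, total, conf)
    return ContaminationEstimate(
        estimate=n_alt / total,
        ci_low=lo,
        ci_high=hi,
        n_sites=n_sites,
        n_consensus_reads=n_cons,
        n_alternative_reads=n_alt,
    )


def ry_sex(
    counts: SexCounts,
    female_max: float = FEMALE_MAX,
    male_min: float = MALE_MIN,
    conf: float = 0.95,
) -> SexCall:
    """Assign biological sex from the Y fraction of sex-chromosome reads.

    Ry = n_y / (n_x + n_y) with a normal-approximation CI; female when the
    CI lies wholly below ``female_max``, male when wholly above
    ``male_min``, otherwise indeterminate.
    """
    n = counts.n_x + counts.n_y
    ry = counts.n_y / n
    z = stats.norm.ppf(0.5 + conf / 2.0)
    se = math.sqrt(ry * (1.0 - ry) / n)
    lo = max(0.0, ry - z * se)
    hi = min(1.0, ry + z * se)
    if hi < female_max:
        call = "female"
    elif lo > male_min:
        call = "male"
    else:
        call = "indeterminate"
    return SexCall(ry=ry, ci_low=lo, ci_high=hi, call=call)


# ---------------------------------------------------------------------------
# tabular I/O


def read_pileups(path: str | Path) -> list[SitePileup]:
    """Read a pileup TSV: position, A, C, G, T, consensus_base, panel_freq."""
    df = pd.read_csv(path, sep="\t")
    needed = {"position", "A", "C", "G", "T", "consensus_base", "panel_freq"}
    missing = needed - set(df.columns)
    if missing:
        raise MetadataError(f"pileup table missing columns: {sorted(missing)}")
    return [
        SitePileup(
            position=int(row.position),
            counts={b: int(getattr(row, b)) for b in BASES},
            consensus_base=str(row.consensus_base),
            panel_freq=float(row.panel_freq),
        )
        for row in df.itertuples()
    ]


def read_sex_counts(path: str | Path) -> dict[str, SexCounts]:
    """Read a sex-count TSV: sample_id, n_y, n_x."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "n_y", "n_x"} - set(df.columns)
    if missing:
        raise MetadataError(f"sex-count table missing columns: {sorted(missing)}")
    return {
        row.sample_id: SexCounts(n_y=int(row.n_y), n_x=int(row.n_x))
        for row in df.itertuples()
    }
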