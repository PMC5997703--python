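"""Serial (heterochronous) coalescent simulation for a haploid locus.

Simulates genealogies of serially sampled mitochondrial genomes under a
single panmictic population with piecewise-exponential size history, then
drops finite-sites Jukes–Cantor mutations on the branches.  Time runs
backwards in generations from the youngest sample (t = 0); population
sizes are haploid female effective sizes, the natural unit for maternally
inherited mtDNA.

The size trajectory is N(t) = N_recent · exp(−r·t) for 0 ≤ t ≤ anchor_gen
with r = ln(N_recent / N_anchor) / anchor_gen, and constant N_anchor for
t > anchor_gen (keeping the coalescence hazard finite in the deep past).
With k active lineages the pairwise coalescence rate is k(k−1)/2 · 1/N(t);
waiting times are drawn exactly by inverting the cumulative hazard in
closed form, so no time discretization is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import Generator, default_rng
from scipy.spatial.distance import pdist, squareform

from .exceptions import ModelError, PartitionError
from .io_meta import HaplotypeAlignment
from .popgen import _amova_phi

#: mtDNA mutation rate, substitutions per site per generation (whole molecule).
MU_MT = 3.4e-7
#: Human generation time in years.
GEN_TIME = 25.0
#: rCRS mitogenome length in base pairs.
MT_LENGTH = 16569

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-exponential haploid size history.

    Parameters
    ----------
    n_recent
        Haploid effective size at t = 0 (the youngest sampling time).
    n_anchor
        Haploid effective size at the ancient anchor time.
    anchor_gen
        Generations before t = 0 of the anchor; the population grows (or
        shrinks) exponentially between the anchor and t = 0 and is constant
        at ``n_anchor`` earlier.
    mu, seq_len, gen_time
        Mutation rate per site per generation, number of sites, and years
        per generation (defaults: 3.4e-7, 16,569 bp, 25 y).
    """

    n_recent: float
    n_anchor: float
    anchor_gen: float
    mu: float = MU_MT
    seq_len: int = MT_LENGTH
    gen_time: float = GEN_TIME

    def __post_init__(self) -> None:
        if self.n_recent < 2 or self.n_anchor < 2:
            raise ModelError("effective sizes must be >= 2")
        if self.anchor_gen <= 0:
            raise ModelError("anchor_gen must be positive")
        if self.mu <= 0:
            raise ModelError("mutation rate must be positive")
        if self.seq_len < 1:
            raise ModelError("sequence length must be >= 1")
        if self.gen_time <= 0:
            raise ModelError("generation time must be positive")

    @property
    def growth_rate(self) -> float:
        """Per-generation exponential rate r = ln(N_recent/N_anchor)/anchor_gen."""
        return math.log(self.n_recent / self.n_anchor) / self.anchor_gen

    def size_at(self, t: float) -> float:
        """Haploid size at backwards time t generations."""
        if t >= self.anchor_gen:
            return self.n_anchor
        return self.n_recent * math.exp(-self.growth_rate * t)


@dataclass(frozen=True)
class SamplingSchedule:
    """Heterochronous sampling groups: (label, n_samples, age in generations)."""

    groups: tuple[tuple[str, int, float], ...]

    def __post_init__(self) -> None:
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ModelError("sampling group labels must be unique")
        for label, n, age in self.groups:
            if n < 1:
                raise ModelError(f"group {label}: n_samples must be >= 1")
            if age < 0:
                raise ModelError(f"group {label}: age_gen must be >= 0")

    @classmethod
    def from_ages_bp(
        cls,
        groups: Sequence[tuple[str, int, float]],
        gen_time: float = GEN_TIME,
        reference_bp: float | None = None,
    ) -> "SamplingSchedule":
        """Build a schedule from ages in years BP.

        Ages are shifted so the youngest group sits at t = 0 (or at its
        age relative to ``reference_bp`` when given) and rounded to the
        nearest generation.
        """
        ref = min(g[2] for g in groups) if reference_bp is None else reference_bp
        return cls(
            tuple(
                (label, int(n), float(round((age - ref) / gen_time)))
                for label, n, age in groups
            )
        )

    @property
    def n_total(self) -> int:
        return sum(g[1] for g in self.groups)


@dataclass
class Genealogy:
    """Binary coalescent tree over serially sampled tips.

    Tips are nodes ``0..n_tips-1`` in schedule order; internal nodes follow
    in coalescence order with the root last.  Times are in generations
    backwards from t = 0.
    """

    parent: np.ndarray  # parent node id, -1 at the root
    time: np.ndarray  # node times (generations)
    n_tips: int
    tip_group: np.ndarray  # group index per tip
    group_labels: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def branch_lengths(self) -> np.ndarray:
        """Branch length above each non-root node, in generations."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, par in enumerate(self.parent):
            if par >= 0:
                ch[par].append(node)
        return ch

    def tip_labels(self) -> list[str]:
        counters = {lab: 0 for lab in self.group_labels}
        labels = []
        for g in self.tip_group:
            lab = self.group_labels[g]
            counters[lab] += 1
            labels.append(f"{lab}_{counters[lab]:03d}")
        return labels

    def to_newick(self) -> str:
        """Newick string with branch lengths in generations."""
        ch = self.children()
        names = self.tip_labels()

        def render(node: int) -> str:
            if node < self.n_tips:
                label = names[node]
            else:
                label = ""
            if ch[node]:
                inner = ",".join(render(c) for c in ch[node])
                label = f"({inner}){label}"
            par = self.parent[node]
            if par < 0:
                return label
            return f"{label}:{self.time[par] - self.time[node]:.6f}"

        return render(self.root) + ";"


def _coalescence_time(
    t0: float, k: int, e_unit: float, model: DemographicModel
) -> float:
    """Invert the cumulative coalescence hazard from time t0 with k lineages."""
    c = k * (k - 1) / 2.0
    r = model.growth_rate
    anchor = model.anchor_gen
    if r == 0.0:
        return t0 + e_unit * model.n_recent / c
    if t0 < anchor:
        # hazard available inside the exponential segment
        seg = c / (model.n_recent * r) * (
            math.exp(r * anchor) - math.exp(r * t0)
        )
        if e_unit <= seg:
            arg = math.exp(r * t0) + e_unit * model.n_recent * r / c
            if arg <= 0 or not math.isfinite(arg):
                raise ModelError(
                    f"non-finite waiting time (r={r:.3g}, t0={t0:.3g}); "
                    "check model sizes"
                )
            return math.log(arg) / r
        e_unit -= seg
        t0 = anchor
    return t0 + e_unit * model.n_anchor / c


def simulate_genealogy(
    model: DemographicModel,
    schedule: SamplingSchedule,
    seed: int | Generator | None = None,
) -> Genealogy:
    """Simulate one heterochronous coalescent genealogy.

    Lineages activate (backwards in time) at their sampling ages; while k
    lineages are active the next coalescence is drawn by closed-form
    time-rescaling inversion under the model's size trajectory.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    n_tips = schedule.n_total
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    tip_group = np.zeros(n_tips, dtype=np.int64)

    # tips in schedule order; sampling events sorted by age
    events: list[tuple[float, list[int]]] = []
    tip = 0
    for gi, (label, n, age) in enumerate(schedule.groups):
        ids = list(range(tip, tip + n))
        for i in ids:
            tip_group[i] = gi
            time[i] = age
        events.append((age, ids))
        tip += n
    events.sort(key=lambda e: e[0])

    active: list[int] = []
    next_node = n_tips
    ev = 0
    t = events[0][0]
    while True:
        if len(active) < 2:
            if ev >= len(events):
                break
            t = events[ev][0]
            active.extend(events[ev][1])
            ev += 1
            continue
        e_unit = rng.exponential()
        tc = _coalescence_time(t, len(active), e_unit, model)
        if ev < len(events) and events[ev][0] < tc:
            t = events[ev][0]
            active.extend(events[ev][1])
            ev += 1
            continue
        k = len(active)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = next_node
        parent[b] = next_node
        time[next_node] = tc
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(next_node)
        next_node += 1
        t = tc
    return Genealogy(
        parent=parent,
        time=time,
        n_tips=n_tips,
        tip_group=tip_group,
        group_labels=tuple(g[0] for g in schedule.groups),
    )


def mutate_segregating(
    tree: Genealogy,
    mu: float,
    seq_len: int,
    rng: Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Drop Jukes–Cantor mutations; return only the mutated columns.

    Returns ``(positions, genotypes)`` where ``genotypes`` is an
    ``(n_tips, n_mutated_sites)`` array of base codes 0–3.  Columns that
    experienced mutation but ended invariant (back mutation) are retained;
    they contribute nothing to distances.  The per-branch mutation count is
    Poisson(mu · seq_len · branch length); positions are uniform; each hit
    replaces the current base by one of the other three uniformly.
    """
    bl = tree.branch_lengths()
    n_mut = rng.poisson(mu * seq_len * bl)
    total = int(n_mut.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty((tree.n_tips, 0), dtype=np.uint8)
    positions = rng.integers(0, seq_len, size=total)
    shifts = rng.integers(1, 4, size=total).astype(np.uint8)  # one of the other 3
    sites, site_idx = np.unique(positions, return_inverse=True)
    S = len(sites)

    # events are drawn in node order: per-branch events are contiguous slices
    offsets = np.zeros(tree.n_nodes + 1, dtype=np.int64)
    np.cumsum(n_mut, out=offsets[1:])

    state = rng.integers(0, 4, size=S).astype(np.uint8)  # root bases at mutated sites
    geno = np.empty((tree.n_tips, S), dtype=np.uint8)
    ch = tree.children()
    # iterative DFS applying/undoing branch mutations
    stack: list[tuple[int, bool]] = [(tree.root, False)]
    undo: list[tuple[np.ndarray, np.ndarray]] = []
    while stack:
        node, done = stack.pop()
        if done:
            s_idx, prev = undo.pop()
            state[s_idx] = prev
            continue
        lo, hi = offsets[node], offsets[node + 1]
        s_idx = site_idx[lo:hi]
        undo.append((s_idx, state[s_idx].copy()))
        if len(s_idx) <= 1 or len(np.unique(s_idx)) == len(s_idx):
            state[s_idx] = (state[s_idx] + shifts[lo:hi]) % 4
        else:  # repeated hits on one branch must apply sequentially
            for s, sh in zip(s_idx, shifts[lo:hi]):
                state[s] = (state[s] + sh) % 4
        stack.append((node, True))
        if node < tree.n_tips:
            geno[node] = state
        else:
            for c in ch[node]:
                stack.append((c, False))
    return sites, geno


def drop_mutations(
    tree: Genealogy,
    mu: float,
    seq_len: int,
    seed: int | Generator | None = None,
) -> HaplotypeAlignment:
    """Simulate full haplotypes of length ``seq_len`` for every tip.

    The root sequence is uniform random; Jukes–Cantor substitutions are
    applied along the branches.  Sample ids follow the sampling-group
    labels.
    """
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    sites, geno = mutate_segregating(tree, mu, seq_len, rng)
    root = rng.integers(0, 4, size=seq_len).astype(np.uint8)
    matrix = np.tile(_BASES[root], (tree.n_tips, 1))
    if len(sites):
        matrix[:, sites] = _BASES[geno]
    return HaplotypeAlignment(tree.tip_labels(), matrix, coord_offset=1)


@dataclass(frozen=True)
class FstReplicates:
    """ΦST values from repeated drift-only simulations of two samples."""

    values: np.ndarray
    monomorphic: np.ndarray  # True where the replicate had no variation

    @property
    def n_reps(self) -> int:
        return len(self.values)


def _replicate_phi(
    model: DemographicModel,
    schedule: SamplingSchedule,
    rng: Generator,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
) -> tuple[float, bool]:
    tree = simulate_genealogy(model, schedule, rng)
    _, geno = mutate_segregating(tree, model.mu, model.seq_len, rng)
    if geno.shape[1] == 0:
        return 0.0, True
    d = squareform(pdist(geno, metric="hamming") * geno.shape[1], checks=False)
    if not d.any():
        return 0.0, True
    return _amova_phi(d, [idx_a, idx_b]), False


def simulate_fst_replicates(
    model: DemographicModel,
    schedule: SamplingSchedule,
    n_reps: int,
    seed: int | Generator | None = None,
    observed_fst: float | None = None,
    stop_at_exceedances: int | None = None,
) -> FstReplicates:
    """Null distribution of ΦST between two serial samples of one population.

    Each replicate draws both groups from a single genealogy under the
    model, mutates it, and computes ΦST on the two-group partition.
    Monomorphic replicates (no segregating variation) have no variance to
    partition; their ΦST is recorded as 0 and flagged.

    ``stop_at_exceedances`` (requires ``observed_fst``) stops early once
    that many replicates reached ΦST >= observed — used when only the
    comparison with a threshold count is needed, not the full
    distribution.
    """
    if len(schedule.groups) != 2:
        raise PartitionError("simulate_fst_replicates expects exactly two groups")
    if any(g[1] < 2 for g in schedule.groups):
        raise PartitionError("each sampled group needs >= 2 haplotypes")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    na = schedule.groups[0][1]
    nb = schedule.groups[1][1]
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + nb)
    values = []
    mono = []
    exceed = 0
    for _ in range(n_reps):
        phi, is_mono = _replicate_phi(model, schedule, rng, idx_a, idx_b)
        values.append(phi)
        mono.append(is_mono)
        if stop_at_exceedances is not None and observed_fst is not None:
            if phi >= observed_fst:
                exceed += 1
                if exceed >= stop_at_exceedances:
                    break
    return FstReplicates(np.array(values), np.array(mono, dtype=bool))
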