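"""Training-set construction: random, stratified, CDmean, PEVmean, StratCDmean.

All selectors operate on a :class:`Partition` of the panel into a calibration
set (CS, genotyped candidates for phenotyping) and a test set (TS, where
predictions are evaluated).  The chosen training set (TRS) is a subset of the
CS; the remaining set RS = CS - TRS provides the contrasts the reliability
criteria score: one contrast per RS genotype against the CS mean,
c = e_i - (1/N) 1.

The CDmean/PEVmean selectors run a stochastic exchange algorithm (Rincent et
al. 2012): start from a random TRS of the target size, repeatedly propose
swapping one uniformly chosen TRS member with one uniformly chosen RS member,
and accept the swap iff the criterion strictly improves.  The accepted
criterion values therefore form a monotone trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .gblup_core import inv_spd
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

CRITERIA = ("cdmean", "pevmean")


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """Nested id sets: CS/TS at the top, TRS/RS inside the CS."""

    cs_ids: tuple[str, ...]
    ts_ids: tuple[str, ...] = ()
    trs_ids: tuple[str, ...] = ()
    cluster_of: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cs_ids", tuple(str(i) for i in self.cs_ids))
        object.__setattr__(self, "ts_ids", tuple(str(i) for i in self.ts_ids))
        object.__setattr__(self, "trs_ids", tuple(str(i) for i in self.trs_ids))
        cs, ts, trs = set(self.cs_ids), set(self.ts_ids), set(self.trs_ids)
        if len(cs) != len(self.cs_ids) or len(ts) != len(self.ts_ids) or len(trs) != len(self.trs_ids):
            raise ValueError("duplicate ids within a partition set")
        if cs & ts:
            raise ValueError(f"CS and TS overlap: {sorted(cs & ts)[:5]}")
        if not trs <= cs:
            raise ValueError(f"TRS members outside the CS: {sorted(trs - cs)[:5]}")

    @property
    def rs_ids(self) -> tuple[str, ...]:
        trs = set(self.trs_ids)
        return tuple(i for i in self.cs_ids if i not in trs)

    def with_trs(self, trs_ids) -> "Partition":
        return replace(self, trs_ids=tuple(str(i) for i in trs_ids))

    def cluster_labels(self, ids=None) -> np.ndarray:
        if self.cluster_of is None:
            raise ValueError("partition carries no cluster labels")
        ids = self.cs_ids if ids is None else ids
        try:
            return np.array([self.cluster_of[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise ValueError(f"id {exc.args[0]!r} has no cluster label") from None


@dataclass
class Trajectory:
    """Record of one exchange-algorithm run."""

    criterion: str
    initial_value: float
    values: np.ndarray  # criterion of the accepted state after each proposal
    accepted: np.ndarray  # acceptance flag per proposal
    trs_ids: tuple[str, ...]
    seed: object = None
    stopped_early: bool = False

    @property
    def final_value(self) -> float:
        return float(self.values[-1]) if self.values.size else self.initial_value

    @property
    def n_proposals(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


def build_contrasts(partition: Partition) -> np.ndarray:
    """One contrast per RS genotype against the CS mean, as an N x |RS| matrix.

    Column for RS genotype i is c = e_i - (1/N) 1 over the N CS genotypes in
    CS order; every column sums to zero.
    """
    rs = partition.rs_ids
    if not rs:
        raise ValueError("remaining set is empty: nothing to predict")
    N = len(partition.cs_ids)
    pos = {g: i for i, g in enumerate(partition.cs_ids)}
    C = np.full((N, len(rs)), -1.0 / N)
    for j, g in enumerate(rs):
        C[pos[g], j] += 1.0
    return C


# ---------------------------------------------------------------------------
# simple selectors
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def select_random(partition: Partition, n: int, seed=None) -> Partition:
    """Uniform sample of n training-set members from the CS, without replacement."""
    if n > len(partition.cs_ids):
        raise ValueError(f"requested TRS size {n} exceeds |CS| = {len(partition.cs_ids)}")
    rng = _as_rng(seed)
    chosen = rng.choice(len(partition.cs_ids), size=n, replace=False)
    chosen.sort()
    return partition.with_trs(tuple(partition.cs_ids[i] for i in chosen))


def allocate_proportional(cluster_sizes, n: int):
    """Largest-remainder apportionment of n training slots over clusters.

    Counts sum to n, never exceed the cluster size, and deviate from the
    exact quota n * N_k / sum(N) by less than one (except when a saturated
    cluster forces the leftover onto others).  Accepts a mapping
    label -> size (returns a mapping) or a sequence (returns a list).
    """
    is_mapping = isinstance(cluster_sizes, Mapping)
    labels = list(cluster_sizes.keys()) if is_mapping else list(range(len(cluster_sizes)))
    sizes = np.array([cluster_sizes[k] for k in labels] if is_mapping else list(cluster_sizes),
                     dtype=int)
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    total = int(sizes.sum())
    if n > total:
        raise ValueError(f"cannot allocate {n} slots over {total} genotypes")
    quota = n * sizes / total
    counts = np.minimum(np.floor(quota).astype(int), sizes)
    leftover = n - int(counts.sum())
    # distribute the leftover by descending remainder; ties broken by larger
    # cluster then original order, cascading past saturated clusters
    remainder = quota - np.floor(quota)
    order = sorted(range(len(sizes)), key=lambda k: (-remainder[k], -sizes[k], k))
    while leftover > 0:
        progressed = False
        for k in order:
            if leftover == 0:
                break
            if counts[k] < sizes[k]:
                counts[k] += 1
                leftover -= 1
                progressed = True
        if not progressed:
            raise ValueError("allocation infeasible: all clusters saturated")
    if is_mapping:
        return {lab: int(c) for lab, c in zip(labels, counts)}
    return [int(c) for c in counts]


def select_stratified(partition: Partition, n: int, seed=None) -> Partition:
    """Proportional stratified sampling: allocate per cluster, sample uniformly inside.

    Clusters with more genotypes get proportionally larger representation in
    the TRS, so the sample preserves the panel's subpopulation make-up.
    """
    labels = partition.cluster_labels()
    rng = _as_rng(seed)
    uniq = sorted(set(labels.tolist()))
    sizes = {lab: int((labels == lab).sum()) for lab in uniq}
    alloc = allocate_proportional(sizes, n)
    chosen: list[str] = []
    for lab in uniq:
        members = [g for g, l in zip(partition.cs_ids, labels) if l == lab]
        take = alloc[lab]
        if take:
            idx = rng.choice(len(members), size=take, replace=False)
            chosen.extend(members[i] for i in sorted(idx.tolist()))
    pos = {g: i for i, g in enumerate(partition.cs_ids)}
    chosen.sort(key=pos.__getitem__)
    return partition.with_trs(tuple(chosen))


# ---------------------------------------------------------------------------
# exchange optimizer
# ---------------------------------------------------------------------------


class _CriterionEvaluator:
    """CDmean / PEVmean of mean-contrasts for candidate training sets.

    Precomputes lambda * G^-1 once; per candidate TRS only the small update
    Z'MZ = D_t - t t'/n (intercept-only fixed effect, one record per
    genotype) is added and the resulting system inverted.  Contrast
    quadratic forms c'Ac for c = e_i - (1/N)1 reduce to
    A_ii - 2 rowmean_i(A) + mean(A), which is evaluated vectorized.
    """

    def __init__(self, G: np.ndarray, lam: float):
        self.G = np.asarray(G, dtype=float)
        self.N = self.G.shape[0]
        self.lam = float(lam)
        self.lam_Ginv = lam * inv_spd(self.G, name="G")
        self.G_diag = np.diag(self.G).copy()
        self.G_rowmean = self.G.mean(axis=1)
        self.G_mean = float(self.G.mean())
        self._eye = np.arange(self.N)

    def theta(self, trs_idx: np.ndarray) -> np.ndarray:
        n = trs_idx.size
        A = self.lam_Ginv.copy()
        A[trs_idx, trs_idx] += 1.0
        t = np.zeros(self.N)
        t[trs_idx] = 1.0
        A -= np.outer(t, t) / n
        return inv_spd(A, name="Z'MZ + lambda*G^-1")

    def value(self, trs_idx: np.ndarray, eval_idx: np.ndarray, criterion: str) -> float:
        th = self.theta(trs_idx)
        th_rowmean = th.mean(axis=1)
        q_theta = np.diag(th)[eval_idx] - 2.0 * th_rowmean[eval_idx] + float(th_rowmean.mean())
        if criterion == "pevmean":
            cc = 1.0 - 1.0 / self.N  # c'c of a mean contrast, identical for all i
            return float(np.mean(q_theta / cc))  # sigma_e^2 = 1 convention
        if criterion == "cdmean":
            qG = self.G_diag[eval_idx] - 2.0 * self.G_rowmean[eval_idx] + self.G_mean
            return float(np.mean((qG - self.lam * q_theta) / qG))
        raise ValueError(f"unknown criterion {criterion!r}")


def _improved(criterion: str, new: float, cur: float) -> bool:
    # strict improvement only: exact ties are rejected
    return new > cur if criterion == "cdmean" else new < cur


def optimize_exchange(
    partition: Partition,
    G: KinshipMatrix,
    lam: float,
    n: int,
    criterion: str = "cdmean",
    iterations: int = 2000,
    seed=None,
    restrict_to_cluster: int | None = None,
    patience: int | None = None,
    initial_trs=None,
) -> Trajectory:
    """Stochastic exchange optimization of CDmean (maximize) or PEVmean (minimize).

    Starts from a uniform random TRS of size ``n`` (or ``initial_trs``) and
    runs exactly ``iterations`` swap proposals, each exchanging one uniformly
    chosen TRS member with one uniformly chosen RS member; a proposal is
    accepted iff the criterion strictly improves.  With
    ``restrict_to_cluster`` both the exchangeable members and the scored RS
    contrasts are limited to that cluster, while the contrast target stays
    the full-CS mean and the full-CS kinship is used.  ``patience`` adds an
    optional early stop after that many consecutive rejections.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    cs = partition.cs_ids
    idx_of = {g: i for i, g in enumerate(cs)}
    if restrict_to_cluster is None:
        eligible = np.arange(len(cs))
    else:
        labels = partition.cluster_labels()
        eligible = np.flatnonzero(labels == restrict_to_cluster)
        if eligible.size == 0:
            raise ValueError(f"cluster {restrict_to_cluster} has no CS members")
    if not 0 < n < eligible.size:
        raise ValueError(f"TRS size {n} must be in (0, {eligible.size}) for the eligible set")

    Gcs = G.submatrix(cs) if G.individual_ids != cs else G
    ev = _CriterionEvaluator(Gcs.matrix, lam)
    rng = _as_rng(seed)

    if initial_trs is None:
        trs = rng.choice(eligible, size=n, replace=False)
    else:
        trs = np.array([idx_of[str(g)] for g in initial_trs], dtype=int)
        if not set(trs) <= set(eligible.tolist()):
            raise ValueError("initial TRS contains non-eligible members")
    trs = np.sort(trs)

    def rs_pool(cur_trs: np.ndarray) -> np.ndarray:
        return np.setdiff1d(eligible, cur_trs, assume_unique=True)

    cur = ev.value(trs, rs_pool(trs), criterion)
    initial_value = cur
    values = np.empty(iterations)
    accepted = np.zeros(iterations, dtype=bool)
    streak = 0
    n_done = 0
    for it in range(iterations):
        pool = rs_pool(trs)
        i = rng.integers(trs.size)
        j = rng.integers(pool.size)
        cand = trs.copy()
        cand[i] = pool[j]
        cand.sort()
        val = ev.value(cand, rs_pool(cand), criterion)
        if _improved(criterion, val, cur):
            trs = cand
            cur = val
            accepted[it] = True
            streak = 0
        else:
            streak += 1
        values[it] = cur
        n_done = it + 1
        if patience is not None and streak >= patience:
            break

    return Trajectory(
        criterion=criterion,
        initial_value=initial_value,
        values=values[:n_done],
        accepted=accepted[:n_done],
        trs_ids=tuple(cs[i] for i in trs),
        seed=seed,
        stopped_early=n_done < iterations,
    )


def select_strat_cdmean(
    partition: Partition,
    G: KinshipMatrix,
    lam: float,
    n: int,
    iterations: int = 2000,
    seed=None,
    patience: int | None = None,
) -> tuple[Partition, dict[int, Trajectory | None]]:
    """Stratified CDmean: proportional allocation, then CDmean exchange per cluster.

    Slots are apportioned to clusters by largest remainder; within each
    cluster an exchange run optimizes CDmean with swaps restricted to the
    cluster's members and contrasts restricted to the cluster's RS genotypes
    (still against the full-CS mean, on the full-CS kinship).  Clusters are
    optimized sequentially; members already selected in other clusters stay
    in the training set during each cluster's run.
    """
    labels = partition.cluster_labels()
    uniq = sorted(set(labels.tolist()))
    sizes = {lab: int((labels == lab).sum()) for lab in uniq}
    alloc = allocate_proportional(sizes, n)
    seeds = np.random.SeedSequence(_seed_entropy(seed)).spawn(len(uniq) + 1)
    start = select_stratified(partition, n, seed=np.random.default_rng(seeds[0]))
    cs = partition.cs_ids
    idx_of = {g: i for i, g in enumerate(cs)}
    current = set(start.trs_ids)
    Gcs = G.submatrix(cs) if G.individual_ids != cs else G
    ev = _CriterionEvaluator(Gcs.matrix, lam)

    trajectories: dict[int, Trajectory | None] = {}
    for lab, child in zip(uniq, seeds[1:]):
        members = np.flatnonzero(labels == lab)
        take = alloc[lab]
        member_ids = {cs[i] for i in members}
        if take == 0:
            current -= member_ids
            trajectories[lab] = None
            continue
        if take == sizes[lab]:
            # allocation saturates the cluster: every member enters the TRS
            logger.info("cluster %s fully enters the TRS (allocation %d = cluster size)", lab, take)
            current |= member_ids
            trajectories[lab] = None
            continue
        rng = np.random.default_rng(child)
        sub = np.array(sorted(idx_of[g] for g in current & member_ids), dtype=int)
        fixed = np.array(sorted(idx_of[g] for g in current - member_ids), dtype=int)
        traj = _exchange_restricted(ev, cs, members, sub, fixed, iterations, rng, patience)
        current = (current - member_ids) | set(traj.trs_ids)
        trajectories[lab] = traj

    chosen = sorted(current, key=idx_of.__getitem__)
    return partition.with_trs(tuple(chosen)), trajectories


def _exchange_restricted(
    ev: _CriterionEvaluator,
    cs: tuple[str, ...],
    members: np.ndarray,
    sub_trs: np.ndarray,
    fixed: np.ndarray,
    iterations: int,
    rng: np.random.Generator,
    patience: int | None,
) -> Trajectory:
    """Exchange run over one cluster with the rest of the TRS held fixed."""

    def full(sub: np.ndarray) -> np.ndarray:
        return np.sort(np.concatenate([sub, fixed]))

    def cluster_rs(sub: np.ndarray) -> np.ndarray:
        return np.setdiff1d(members, sub, assume_unique=True)

    trs = np.sort(sub_trs)
    cur = ev.value(full(trs), cluster_rs(trs), "cdmean")
    initial = cur
    values = np.empty(iterations)
    accepted = np.zeros(iterations, dtype=bool)
    streak = 0
    n_done = 0
    for it in range(iterations):
        pool = cluster_rs(trs)
        cand = trs.copy()
        cand[rng.integers(trs.size)] = pool[rng.integers(pool.size)]
        cand.sort()
        val = ev.value(full(cand), cluster_rs(cand), "cdmean")
        if val > cur:
            trs, cur = cand, val
            accepted[it] = True
            streak = 0
        else:
            streak += 1
        values[it] = cur
        n_done = it + 1
        if patience is not None and streak >= patience:
            break
    return Trajectory(
        criterion="cdmean",
        initial_value=initial,
        values=values[:n_done],
        accepted=accepted[:n_done],
        trs_ids=tuple(cs[i] for i in trs),
        stopped_early=n_done < iterations,
    )


def _seed_entropy(seed) -> int | None:
    """Derive integer entropy from seeds or generators for SeedSequence spawning."""
    if seed is None or isinstance(seed, int):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return seed.entropy
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(2**31 - 1))
    raise TypeError(f"unsupported seed type {type(seed)!r}")
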