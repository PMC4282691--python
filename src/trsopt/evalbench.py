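"""Cross-validation benchmark comparing training-set selection methods.

For each repetition the panel is split once into a calibration set (CS) and a
test set (TS); every method and every training-set size then works from that
identical split.  A method selects its TRS from the CS using marker data
only, a GBLUP model is fitted on the TRS phenotypes, and accuracy is the
Pearson correlation between predicted GEBVs and the observed TS phenotypes.
Per-genotype selection counts across repetitions feed the
selection-frequency and phenotypic-variance-ratio diagnostics.
"""

from __future__ import annotations

import hashlib
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .gblup_core import lambda_from_h2, predict_gebv, solve_mme
from .kinship import KinshipMatrix, center_markers, compute_G, recode_and_filter
from .selectors import (
    Partition,
    allocate_proportional,
    optimize_exchange,
    select_random,
    select_strat_cdmean,
    select_stratified,
)
from .structure import euclidean_distance, ward_cluster

METHODS = ("random", "stratified", "cdmean", "pevmean", "stratcdmean")
_CLUSTER_METHODS = {"stratified", "stratcdmean"}


@dataclass
class EvalResult:
    """Accuracies and selected training sets over the method x size x rep grid."""

    accuracy: dict[tuple[str, int, int], float]
    selected: dict[tuple[str, int, int], tuple[str, ...]]
    splits: dict[int, tuple[tuple[str, ...], tuple[str, ...]]]
    rep_seeds: dict[int, int]
    panel_ids: tuple[str, ...]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [k for k, a in self.accuracy.items() if not -1.0 - 1e-12 <= a <= 1.0 + 1e-12]
        if bad:
            raise ValueError(f"accuracy outside [-1, 1] for {bad[:3]}")

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(sorted({m for m, _, _ in self.accuracy}))

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(sorted({s for _, s, _ in self.accuracy}))

    def accuracies(self, method: str, size: int) -> np.ndarray:
        vals = [a for (m, s, r), a in sorted(self.accuracy.items()) if m == method and s == size]
        if not vals:
            raise KeyError(f"no accuracies recorded for ({method}, {size})")
        return np.array(vals)

    def mean_accuracy(self, method: str, size: int) -> float:
        return float(self.accuracies(method, size).mean())

    def selection_count(self, method: str, size: int | None = None) -> Counter:
        """Times each genotype entered the TRS for a method (optionally one size)."""
        counts: Counter = Counter()
        for (m, s, _), ids in self.selected.items():
            if m == method and (size is None or s == size):
                counts.update(ids)
        return counts

    def split_digest(self, rep: int) -> str:
        cs, ts = self.splits[rep]
        h = hashlib.sha256()
        h.update("|".join(cs).encode())
        h.update(b"#")
        h.update("|".join(ts).encode())
        return h.hexdigest()


@dataclass
class VarianceRatioDiagnostic:
    """Phenotypic variance captured by the most-selected genotypes, vs accuracy gain.

    ``ratio`` above 1 means extreme phenotypes are overrepresented among the
    genotypes a criterion selects most often; ``relative_accuracy`` is the
    mean accuracy of the method divided by the baseline's at the same size.
    """

    ratio: float
    relative_accuracy: float
    top_ids: tuple[str, ...]
    method: str
    baseline: str
    size: int
    top_n: int

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("variance ratio must be positive")


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_cs_ts(
    ids: Sequence[str],
    fraction: float,
    seed=None,
    preserve_structure: bool = False,
    labels: Mapping[str, int] | None = None,
) -> Partition:
    """Random CS/TS split of the panel; optionally stratified by cluster.

    With ``preserve_structure`` the CS takes a proportional share of every
    cluster (largest-remainder counts, within one of exact proportionality)
    so CS and TS share the panel's subpopulation make-up.  Clusters with
    fewer than two members cannot be split and are kept whole in the CS with
    a warning.
    """
    ids = tuple(str(i) for i in ids)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cs = int(round(fraction * len(ids)))
    if preserve_structure:
        if labels is None:
            raise ValueError("preserve_structure requires cluster labels")
        labs = np.array([labels[i] for i in ids], dtype=int)
        uniq = sorted(set(labs.tolist()))
        whole: list[int] = []
        splittable: dict[int, int] = {}
        for lab in uniq:
            size = int((labs == lab).sum())
            if size < 2:
                warnings.warn(f"cluster {lab} has {size} member(s); kept whole in the CS",
                              stacklevel=2)
                whole.append(lab)
            else:
                splittable[lab] = size
        n_whole = int(sum((labs == lab).sum() for lab in whole))
        alloc = allocate_proportional(splittable, max(n_cs - n_whole, 0)) if splittable else {}
        cs_idx: list[int] = []
        for lab in uniq:
            members = np.flatnonzero(labs == lab)
            if lab in whole:
                cs_idx.extend(members.tolist())
            else:
                take = alloc.get(lab, 0)
                pick = rng.choice(members.size, size=take, replace=False)
                cs_idx.extend(members[np.sort(pick)].tolist())
        cs_set = set(cs_idx)
    else:
        pick = rng.choice(len(ids), size=n_cs, replace=False)
        cs_set = set(pick.tolist())
    cs = tuple(ids[i] for i in range(len(ids)) if i in cs_set)
    ts = tuple(ids[i] for i in range(len(ids)) if i not in cs_set)
    cluster_of = dict(labels) if labels is not None else None
    return Partition(cs_ids=cs, ts_ids=ts, cluster_of=cluster_of)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_and_score(
    G: KinshipMatrix,
    phenotypes: Mapping[str, float] | pd.Series,
    trs_ids: Sequence[str],
    ts_ids: Sequence[str],
    lam: float,
) -> tuple[float, np.ndarray]:
    """Fit GBLUP on the TRS phenotypes and score Pearson accuracy on the TS."""
    pheno = pd.Series(phenotypes)
    y = pheno.loc[list(trs_ids)].to_numpy()
    sol = solve_mme(G, trs_ids, y=y, lam=lam)
    gebv = predict_gebv(sol, ts_ids)
    obs = pheno.loc[list(ts_ids)].to_numpy()
    acc = float(pearsonr(gebv, obs).statistic)
    return acc, gebv


def _select_trs(
    method: str,
    partition: Partition,
    size: int,
    G: KinshipMatrix,
    lam: float,
    iterations: int,
    rng: np.random.Generator,
    patience: int | None,
) -> tuple[str, ...]:
    if method == "random":
        return select_random(partition, size, seed=rng).trs_ids
    if method == "stratified":
        return select_stratified(partition, size, seed=rng).trs_ids
    if method in ("cdmean", "pevmean"):
        traj = optimize_exchange(partition, G, lam, n=size, criterion=method,
                                 iterations=iterations, seed=rng, patience=patience)
        return traj.trs_ids
    if method == "stratcdmean":
        part, _ = select_strat_cdmean(partition, G, lam, n=size,
                                      iterations=iterations, seed=rng, patience=patience)
        return part.trs_ids
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_benchmark(
    markers,
    phenotypes: Mapping[str, float] | pd.Series,
    methods: Sequence[str],
    sizes: Sequence[int],
    reps: int,
    h2: float,
    n_clusters: int | None = None,
    labels: Mapping[str, int] | None = None,
    fraction: float = 0.5,
    iterations: int = 2000,
    seed: int | None = 0,
    maf_min: float = 0.0,
    preserve_structure: bool = True,
    patience: int | None = None,
) -> EvalResult:
    """Compare TRS selection methods over a method x size x repetition grid.

    ``markers`` is the raw panel :class:`~trsopt.geno_io.MarkerMatrix` (the
    kinship matrix is built once, on the full panel, so all splits share one
    marker coding); ``phenotypes`` maps every panel id to its trait value,
    but only TRS phenotypes are used at fit time.  Cluster labels for
    stratified methods and structure-preserving splits come from ``labels``
    or, when absent, from a Ward clustering of the panel into ``n_clusters``
    groups.  Per-repetition seeds are spawned from ``seed`` so the method
    order cannot perturb the randomness.
    """
    methods = tuple(methods)
    sizes = tuple(int(s) for s in sizes)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; expected subset of {METHODS}")
    pheno = pd.Series(phenotypes)

    recoded = recode_and_filter(markers, maf_min=maf_min)
    G = compute_G(center_markers(recoded))
    panel_ids = G.individual_ids
    missing_pheno = [i for i in panel_ids if i not in pheno.index]
    if missing_pheno:
        raise ValueError(f"phenotype missing for panel id(s) {missing_pheno[:5]}")

    needs_labels = bool(_CLUSTER_METHODS & set(methods)) or preserve_structure
    if labels is None and needs_labels:
        if n_clusters is None:
            raise ValueError("methods needing clusters require labels or n_clusters")
        if n_clusters > 1:
            model = ward_cluster(euclidean_distance(recoded), n_clusters)
            labels = model.labels
        else:
            labels = {i: 1 for i in panel_ids}

    lam = lambda_from_h2(h2)
    root = np.random.SeedSequence(seed)
    rep_streams = root.spawn(reps)

    accuracy: dict[tuple[str, int, int], float] = {}
    selected: dict[tuple[str, int, int], tuple[str, ...]] = {}
    splits: dict[int, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    rep_seeds: dict[int, int] = {}

    for rep, stream in enumerate(rep_streams):
        rep_seeds[rep] = int(stream.generate_state(1)[0] % (2**31 - 1))
        split_rng, *method_streams = stream.spawn(1 + len(methods) * len(sizes))
        part = split_cs_ts(panel_ids, fraction, seed=np.random.default_rng(split_rng),
                           preserve_structure=preserve_structure and labels is not None,
                           labels=labels)
        splits[rep] = (part.cs_ids, part.ts_ids)
        G_cs = G.submatrix(part.cs_ids)
        k = 0
        for method in methods:
            for size in sizes:
                rng = np.random.default_rng(method_streams[k])
                k += 1
                trs = _select_trs(method, part, size, G_cs, lam, iterations, rng, patience)
                acc, _ = fit_and_score(G, pheno, trs, part.ts_ids, lam)
                accuracy[(method, size, rep)] = acc
                selected[(method, size, rep)] = trs

    config = {
        "methods": list(methods),
        "sizes": list(sizes),
        "reps": reps,
        "h2": h2,
        "lambda": lam,
        "fraction": fraction,
        "iterations": iterations,
        "seed": seed,
        "maf_min": maf_min,
        "preserve_structure": preserve_structure,
        "n_clusters": n_clusters,
    }
    return EvalResult(accuracy=accuracy, selected=selected, splits=splits,
                      rep_seeds=rep_seeds, panel_ids=panel_ids, config=config)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def selection_frequency(result: EvalResult, method: str, threshold: int,
                        size: int | None = None) -> set[str]:
    """Genotypes selected more than ``threshold`` times by a method."""
    if method not in {m for m, _, _ in result.selected}:
        raise KeyError(f"no selections recorded for method {method!r}")
    counts = result.selection_count(method, size)
    return {gid for gid, c in counts.items() if c > threshold}


def variance_ratio_diagnostic(
    result: EvalResult,
    phenotypes: Mapping[str, float] | pd.Series,
    method: str = "cdmean",
    top_n: int = 40,
    baseline: str = "random",
    size: int | None = None,
) -> VarianceRatioDiagnostic:
    """Ratio of phenotypic variance in the most-selected genotypes to the panel's.

    A ratio above 1 means the criterion overrepresents extreme phenotypes in
    its training sets; paired with the accuracy of the method relative to the
    baseline it diagnoses when criterion-driven selection pays off.  Ties in
    selection count are broken by id for determinism; when fewer than
    ``top_n`` genotypes were ever selected, all of them are used (with a
    warning).
    """
    sizes = result.sizes
    size = sizes[0] if size is None else int(size)
    for m in (method, baseline):
        result.accuracies(m, size)  # raises if absent
    pheno = pd.Series(phenotypes)
    counts = result.selection_count(method, size)
    ranked = sorted(counts, key=lambda g: (-counts[g], g))
    if len(ranked) < top_n:
        warnings.warn(f"only {len(ranked)} genotypes ever selected; using all of them",
                      stacklevel=2)
    top = tuple(ranked[:top_n])
    num = float(pheno.loc[list(top)].var(ddof=1))
    den = float(pheno.loc[list(result.panel_ids)].var(ddof=1))
    rel = result.mean_accuracy(method, size) / result.mean_accuracy(baseline, size)
    return VarianceRatioDiagnostic(ratio=num / den, relative_accuracy=float(rel),
                                   top_ids=top, method=method, baseline=baseline,
                                   size=size, top_n=top_n)
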