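"""Readers and writers for genotypes, phenotypes, clusters, results and run configuration.

Genotype calls are allele dosages in {0, 1, 2} (number of copies of one of the
two alleles of a biallelic marker; minor-allele orientation is applied later by
:func:`trsopt.kinship.recode_and_filter`).  Three on-disk layouts are
understood: a plain delimited matrix (rows = individuals, columns = markers),
VCF 4.x, and HapMap-style tab tables.  Phenotypes are CSV, either long
(``id, trait, value`` with optional ``environment``/``replicate`` columns) or
wide (``id`` plus one column per trait).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

_MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "."}

#: IUPAC ambiguity codes that denote a heterozygote in single-letter HapMap calls
_IUPAC_HET = set("RYSWKM")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMatrix:
    """Biallelic genotype calls for a panel of individuals.

    ``calls`` is an ``n x m`` float array; missing calls are NaN.  Before
    imputation every non-missing call is an integer in {0, 1, 2}; after
    column-mean imputation (``imputed=True``) calls are real-valued.
    ``minor_allele_coded`` records whether columns have been oriented so that
    the counted allele is the minor one.
    """

    individual_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    calls: np.ndarray
    minor_allele_coded: bool = False
    imputed: bool = False

    def __post_init__(self) -> None:
        self.individual_ids = tuple(str(i) for i in self.individual_ids)
        self.marker_ids = tuple(str(m) for m in self.marker_ids)
        self.calls = np.asarray(self.calls, dtype=float)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if self.calls.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        finite = self.calls[~np.isnan(self.calls)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            bad = finite[(finite < 0) | (finite > 2)][0]
            raise ValueError(f"genotype call {bad!r} outside [0, 2]")
        if not self.imputed and finite.size and not np.allclose(finite, np.round(finite)):
            bad = finite[~np.isclose(finite, np.round(finite))][0]
            raise ValueError(f"non-integer dosage {bad!r} in unimputed marker matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``n x m`` mask, True where the call is missing."""
        return np.isnan(self.calls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=list(self.individual_ids), columns=list(self.marker_ids))


@dataclass
class PhenotypeTable:
    """Long-format phenotype records: (id, trait, environment, replicate, value)."""

    records: pd.DataFrame

    KEY = ["id", "trait", "environment", "replicate"]

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in ("environment", "replicate"):
            if col not in df.columns:
                df[col] = pd.NA
        df = df[["id", "trait", "environment", "replicate", "value"]]
        df["id"] = df["id"].astype(str)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        if not np.isfinite(df["value"].to_numpy()).all():
            raise ValueError("non-finite phenotype value")
        dup = df.duplicated(subset=self.KEY, keep=False)
        if dup.any():
            key = df.loc[dup, self.KEY].iloc[0].tolist()
            raise ValueError(f"duplicate phenotype record for key {tuple(key)}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.records["trait"]))

    def line_means(self, trait: str) -> pd.Series:
        """Per-individual mean of a trait across environments/replicates."""
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} not present")
        return sub.groupby("id", sort=False)["value"].mean()


@dataclass
class RunConfig:
    """Configuration of a benchmark/optimization run (flat key-value file)."""

    trait: str = "trait"
    h2: float = 0.5
    sizes: tuple[int, ...] = (25,)
    reps: int = 1
    iterations: int = 2000
    n_clusters: int = 1
    fraction: float = 0.5
    seed: int = 0
    methods: tuple[str, ...] = ("random",)
    geno: str | None = None
    pheno: str | None = None
    clusters: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.sizes = tuple(int(s) for s in self.sizes)
        self.methods = tuple(str(m) for m in self.methods)
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("TRS sizes must be positive")
        if self.reps < 1:
            raise ValueError("repetitions must be >= 1")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("CS fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# genotype readers
# ---------------------------------------------------------------------------


def read_marker_matrix(path: str | Path, format: str | None = None) -> MarkerMatrix:
    """Read a genotype matrix from CSV/TSV, VCF or a HapMap-style table.

    The format is inferred from the file name when not given (``.vcf`` /
    ``.vcf.gz`` -> vcf, ``.hmp.txt`` / ``.hapmap`` -> hapmap, anything else a
    delimited matrix).  Multiallelic VCF/HapMap records are skipped with a
    logged count.  Missing genotypes are masked (NaN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_matrix_delimited(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "hapmap":
        return _read_hapmap(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
        return "vcf"
    if name.endswith((".hmp.txt", ".hapmap", ".hmp")):
        return "hapmap"
    return "csv"


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _read_matrix_delimited(path: Path) -> MarkerMatrix:
    sep = _sniff_delimiter(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    markers_in_header = header[1:]
    if len(set(markers_in_header)) != len(markers_in_header):
        dup = next(m for m in markers_in_header if markers_in_header.count(m) > 1)
        raise ParseError(f"{path}: duplicate marker id {dup!r} in header (line 1)")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw = df.to_numpy()
    calls = np.full(raw.shape, np.nan)
    for (i, j), tok in np.ndenumerate(raw):
        tok = tok.strip()
        if tok in _MISSING_TOKENS:
            continue
        try:
            val = float(tok)
        except ValueError as exc:
            raise ParseError(f"{path}: unparseable call {tok!r} for "
                             f"({df.index[i]}, {df.columns[j]})") from exc
        if val != int(val):
            raise ValueError(f"{path}: non-integer dosage {tok!r} for ({df.index[i]}, {df.columns[j]})")
        if int(val) not in (0, 1, 2):
            raise ValueError(f"{path}: call {tok!r} not in {{0,1,2}} for ({df.index[i]}, {df.columns[j]})")
        calls[i, j] = val
    return MarkerMatrix(tuple(df.index), tuple(df.columns), calls)


def _read_vcf(path: Path) -> MarkerMatrix:
    from cyvcf2 import VCF  # deferred: only needed for this format

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        dos = np.full(len(samples), np.nan)
        for s, gt in enumerate(variant.genotypes):
            a = gt[:-1]  # last entry is the phased flag
            if len(a) != 2 or min(a) < 0:
                continue  # half-missing (./1) treated as missing
            dos[s] = float((a[0] > 0) + (a[1] > 0))
        mid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        marker_ids.append(mid)
        rows.append(dos)
    vcf.close()
    if skipped:
        logger.info("skipped %d multiallelic VCF record(s) in %s", skipped, path)
    calls = np.array(rows).T if rows else np.empty((len(samples), 0))
    return MarkerMatrix(tuple(samples), tuple(marker_ids), calls)


def _read_hapmap(path: Path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 12:
        raise ParseError(f"{path}: HapMap table needs 11 annotation columns plus samples (line 1)")
    samples = list(df.columns[11:])
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for _, rec in df.iterrows():
        alleles = str(rec.iloc[1]).split("/")
        if len(alleles) != 2:
            skipped += 1
            continue
        ref, alt = alleles
        dos = np.full(len(samples), np.nan)
        for s, tok in enumerate(rec.iloc[11:]):
            tok = str(tok).strip()
            if tok in _MISSING_TOKENS or set(tok) == {"N"}:
                continue
            if len(tok) == 2:
                if any(ch not in (ref, alt) for ch in tok):
                    raise ValueError(f"{path}: genotype {tok!r} inconsistent with alleles "
                                     f"{ref}/{alt} at marker {rec.iloc[0]}")
                dos[s] = float(tok.count(alt))
            elif len(tok) == 1:
                if tok == ref:
                    dos[s] = 0.0
                elif tok == alt:
                    dos[s] = 2.0
                elif tok in _IUPAC_HET:
                    dos[s] = 1.0
                else:
                    raise ValueError(f"{path}: unknown single-letter call {tok!r} at marker {rec.iloc[0]}")
            else:
                raise ValueError(f"{path}: unparseable genotype {tok!r} at marker {rec.iloc[0]}")
        marker_ids.append(str(rec.iloc[0]))
        rows.append(dos)
    if skipped:
        logger.info("skipped %d non-biallelic HapMap record(s) in %s", skipped, path)
    calls = np.array(rows).T if rows else np.empty((len(samples), 0))
    return MarkerMatrix(tuple(samples), tuple(marker_ids), calls)


def write_marker_matrix(markers: MarkerMatrix, path: str | Path) -> None:
    """Write a marker matrix as CSV (missing calls left blank)."""
    df = markers.to_frame()
    finite = df.to_numpy()[~np.isnan(df.to_numpy())]
    if finite.size == 0 or np.allclose(finite, np.round(finite)):
        df = df.astype("Int64")  # clean integer round-trip
    df.to_csv(path, index_label="id", na_rep="")


# ---------------------------------------------------------------------------
# phenotypes, clusters, config
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype CSV; wide files (one column per trait) are melted to long."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols:
        raise ParseError(f"{path}: header must contain an 'id' column (line 1)")
    df = df.rename(columns={cols["id"]: "id"})
    lower = {c.lower(): c for c in df.columns}
    if "trait" in lower and "value" in lower:
        df = df.rename(columns={lower["trait"]: "trait", lower["value"]: "value"})
        for opt in ("environment", "replicate"):
            if opt in lower:
                df = df.rename(columns={lower[opt]: opt})
        return PhenotypeTable(df)
    id_vars = ["id"] + [lower[c] for c in ("environment", "replicate") if c in lower]
    value_vars = [c for c in df.columns if c not in id_vars]
    if not value_vars:
        raise ParseError(f"{path}: no trait columns found")
    long = df.melt(id_vars=id_vars, value_vars=value_vars, var_name="trait", value_name="value")
    long = long.rename(columns={c: c.lower() for c in id_vars})
    return PhenotypeTable(long)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


def read_clusters(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "cluster" not in cols:
        raise ParseError(f"{path}: cluster file needs 'id' and 'cluster' columns")
    return {str(r[cols["id"]]): int(r[cols["cluster"]]) for _, r in df.iterrows()}


def write_clusters(labels: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame({"id": list(labels), "cluster": [labels[i] for i in labels]}).to_csv(path, index=False)


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key-value (YAML) run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a flat mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(result, out_dir: str | Path, config: Mapping | None = None) -> dict[str, Path]:
    """Write an :class:`~trsopt.evalbench.EvalResult` to ``out_dir``.

    Emits ``accuracies.csv`` (method, size, rep, accuracy), per-genotype
    ``selection_counts.csv``, the raw per-run ``selected.csv`` id lists, and a
    JSON manifest carrying the configuration and seeds for exact re-runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    acc_rows = [
        {"method": m, "size": s, "rep": r, "accuracy": a}
        for (m, s, r), a in sorted(result.accuracy.items())
    ]
    acc = pd.DataFrame(acc_rows, columns=["method", "size", "rep", "accuracy"])
    paths["accuracies"] = out_dir / "accuracies.csv"
    acc.to_csv(paths["accuracies"], index=False)

    count_rows = []
    for method in sorted({m for m, _, _ in result.selected}):
        counts = result.selection_count(method)
        count_rows.extend(
            {"method": method, "id": gid, "count": counts[gid]} for gid in sorted(counts)
        )
    cnt = pd.DataFrame(count_rows, columns=["method", "id", "count"])
    paths["selection_counts"] = out_dir / "selection_counts.csv"
    cnt.to_csv(paths["selection_counts"], index=False)

    sel_rows = [
        {"method": m, "size": s, "rep": r, "ids": ";".join(ids)}
        for (m, s, r), ids in sorted(result.selected.items())
    ]
    sel = pd.DataFrame(sel_rows, columns=["method", "size", "rep", "ids"])
    paths["selected"] = out_dir / "selected.csv"
    sel.to_csv(paths["selected"], index=False)

    from . import __version__

    manifest = {
        "config": dict(config) if config is not None else dict(result.config),
        "rep_seeds": {str(k): int(v) for k, v in sorted(result.rep_seeds.items())},
        "trsopt_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    paths["manifest"] = out_dir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
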