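"""Community data model and basic transforms.

Holds ASV count tables with per-sample collection dates, taxonomy maps
assigning each ASV a SAR11 ecotype label, and environmental metadata.
Provides file I/O (TSV/CSV and BIOM v1 JSON), rarefaction by subsampling
without replacement, relative abundance, ecotype-level aggregation, and
the per-sample SAR11 fraction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("sarcycle")

#: Controlled vocabulary of SAR11 ecotype labels; "other" marks non-SAR11 taxa.
ECOTYPE_VOCABULARY = (
    "Ia.1", "Ia.3", "Ia.4", "Ib", "Ib.2", "I", "II", "IIa",
    "IIa.A", "IIa.B", "IIb", "IIIa", "IV", "other",
)

SAR11_ECOTYPES = tuple(e for e in ECOTYPE_VOCABULARY if e != "other")


class CommunityDataError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Samples x ASVs integer count table with one collection date per sample.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are ASV ids, integer counts.
    dates
        Series of timezone-naive calendar dates aligned to ``counts.index``.
    """

    counts: pd.DataFrame
    dates: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise CommunityDataError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise CommunityDataError(f"duplicate ASV ids: {dups}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CommunityDataError("counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise CommunityDataError("counts contain missing values")
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise CommunityDataError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"ASV {self.counts.columns[j]!r}"
            )
        frac = np.argwhere(arr.astype(float) != np.floor(arr.astype(float)))
        if frac.size:
            i, j = frac[0]
            raise CommunityDataError(
                f"non-integer count at sample {self.counts.index[i]!r}, "
                f"ASV {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        dates = pd.to_datetime(pd.Series(self.dates), errors="raise")
        dates.index = pd.Index(self.dates.index)
        missing = self.counts.index.difference(dates.index)
        if len(missing):
            raise CommunityDataError(f"samples without a date: {missing.tolist()}")
        self.dates = dates.reindex(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def sort_by_date(self) -> "CountMatrix":
        order = self.dates.sort_values(kind="stable").index
        return CountMatrix(self.counts.loc[order], self.dates.loc[order])


@dataclass
class TaxonomyMap:
    """Total mapping from ASV id to an ecotype label from the vocabulary.

    Labels outside the controlled vocabulary are coerced to ``"other"`` with
    a warning so that dialectal spellings do not abort a run.
    """

    labels: dict[str, str]

    def __post_init__(self) -> None:
        coerced = {}
        unknown = []
        for asv, lab in self.labels.items():
            lab = str(lab)
            if lab not in ECOTYPE_VOCABULARY:
                unknown.append(lab)
                lab = "other"
            coerced[str(asv)] = lab
        if unknown:
            warnings.warn(
                f"unknown ecotype labels mapped to 'other': {sorted(set(unknown))}",
                stacklevel=2,
            )
        self.labels = coerced

    def __getitem__(self, asv_id: str) -> str:
        return self.labels[asv_id]

    def require_total(self, asv_ids) -> None:
        missing = [a for a in asv_ids if a not in self.labels]
        if missing:
            raise CommunityDataError(f"ASVs missing from taxonomy: {missing}")

    def is_sar11(self, asv_id: str) -> bool:
        return self.labels[asv_id] != "other"


@dataclass
class RelAbundanceMatrix:
    """Per-sample proportions on the same axes as a CountMatrix.

    ``zero_total`` flags samples whose count total was zero; their rows are
    all-zero rather than NaN and must not be interpreted as compositions.
    """

    values: pd.DataFrame
    dates: pd.Series
    zero_total: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zero_total is None:
            self.zero_total = pd.Series(False, index=self.values.index)
        sums = self.values.sum(axis=1).to_numpy()
        ok = np.isclose(sums, 1.0, atol=1e-9) | self.zero_total.to_numpy()
        if not ok.all():
            bad = self.values.index[~ok].tolist()
            raise CommunityDataError(f"rows do not sum to 1: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class EnvMatrix:
    """Samples x environmental variables, dates aligned by sample id.

    Missing values are permitted; ``units`` is free-form metadata keyed by
    variable name.
    """

    values: pd.DataFrame
    dates: pd.Series
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise CommunityDataError("duplicate environmental variable names")
        dates = pd.to_datetime(pd.Series(self.dates), errors="raise")
        dates.index = pd.Index(self.dates.index)
        self.dates = dates.reindex(self.values.index)
        if self.dates.isna().any():
            missing = self.values.index[self.dates.isna()].tolist()
            raise CommunityDataError(f"env samples without a date: {missing}")
        self.values = self.values.astype(float)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "samples_as_rows",
) -> CountMatrix:
    """Read a count table with a ``date`` column (TSV/CSV) or BIOM v1 JSON.

    For delimited files, samples are rows by default; pass
    ``orientation="asvs_as_rows"`` for the transposed layout (then dates must
    appear in a ``date`` row). BIOM files carry dates in per-sample metadata
    under the key ``date``.
    """
    path = Path(path)
    if format == "biom-json":
        cm = _read_biom_json(path)
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if orientation == "asvs_as_rows":
            df = df.T
        elif orientation != "samples_as_rows":
            raise ValueError(f"unknown orientation: {orientation!r}")
        if "date" not in df.columns:
            raise CommunityDataError("count table must contain a 'date' column")
        dates = pd.to_datetime(df.pop("date"))
        df.index.name = None
        df.columns.name = None
        cm = CountMatrix(df, dates)
    else:
        raise ValueError(f"unknown count table format: {format!r}")
    logger.info(
        "read count table %s: %d samples, %d ASVs, %d total reads",
        path, len(cm.sample_ids), len(cm.asv_ids), int(cm.counts.to_numpy().sum()),
    )
    return cm


def write_count_table(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "biom-json":
        _write_biom_json(cm, path)
        return
    sep = "\t" if format == "tsv" else ","
    out = cm.counts.copy()
    out.insert(0, "date", cm.dates.dt.strftime("%Y-%m-%d"))
    out.to_csv(path, sep=sep, index_label="sample_id")


def _read_biom_json(path: Path) -> CountMatrix:
    with open(path) as fh:
        doc = json.load(fh)
    sample_ids = [c["id"] for c in doc["columns"]]
    asv_ids = [r["id"] for r in doc["rows"]]
    n_rows, n_cols = doc["shape"]
    mat = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=asv_ids)
    dates = pd.Series(
        [(c.get("metadata") or {}).get("date") for c in doc["columns"]],
        index=sample_ids,
    )
    if dates.isna().any():
        raise CommunityDataError("BIOM sample metadata missing 'date' entries")
    return CountMatrix(counts, pd.to_datetime(dates))


def _write_biom_json(cm: CountMatrix, path: Path) -> None:
    # BIOM v1 stores features (ASVs) as rows; sparse triples keep files small.
    arr = cm.counts.to_numpy().T
    data = [
        [int(r), int(c), int(arr[r, c])]
        for r, c in zip(*np.nonzero(arr))
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "sarcycle",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [arr.shape[0], arr.shape[1]],
        "rows": [{"id": a, "metadata": None} for a in cm.asv_ids],
        "columns": [
            {"id": s, "metadata": {"date": d.strftime("%Y-%m-%d")}}
            for s, d in zip(cm.sample_ids, cm.dates)
        ],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV (asv_id, ecotype) into a TaxonomyMap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["asv_id", "ecotype"],
                     dtype=str, comment="#")
    if df["asv_id"].duplicated().any():
        dups = df.loc[df["asv_id"].duplicated(), "asv_id"].tolist()
        raise CommunityDataError(f"duplicate ASV ids in taxonomy: {dups}")
    return TaxonomyMap(dict(zip(df["asv_id"], df["ecotype"])))


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for asv, lab in tax.labels.items():
            fh.write(f"{asv}\t{lab}\n")


def read_env_table(path: str | Path) -> EnvMatrix:
    """Read an environmental CSV with a ``date`` column, samples as rows."""
    df = pd.read_csv(path, index_col=0)
    if "date" not in df.columns:
        raise CommunityDataError("env table must contain a 'date' column")
    dates = pd.to_datetime(df.pop("date"))
    df.index.name = None
    df.columns.name = None
    return EnvMatrix(df, dates)


def write_env_table(env: EnvMatrix, path: str | Path) -> None:
    out = env.values.copy()
    out.insert(0, "date", env.dates.dt.strftime("%Y-%m-%d"))
    out.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def rarefy(cm: CountMatrix, depth: int | None = None, seed: int = 0,
           min_depth_floor: int = 1000) -> CountMatrix:
    """Subsample each sample to a common depth without replacement.

    Each retained sample's reads are drawn by a multivariate hypergeometric
    subsample summing exactly to ``depth``. Samples with totals below
    ``depth`` are dropped and reported. When ``depth`` is None it defaults to
    the minimum total among samples with at least ``min_depth_floor`` reads
    (samples below the floor are dropped first).

    Deterministic given ``seed``.
    """
    totals = cm.sample_totals
    if depth is None:
        eligible = totals[totals >= min_depth_floor]
        if eligible.empty:
            raise CommunityDataError("no samples retained: all below depth floor")
        depth = int(eligible.min())
    if depth < 1:
        raise ValueError("depth must be >= 1")
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(keep) == 0:
        raise CommunityDataError("no samples retained: depth exceeds every total")
    if len(dropped):
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, list(dropped))
    rng = np.random.default_rng(seed)
    sub = cm.counts.loc[keep].to_numpy()
    out = np.empty_like(sub)
    for i in range(sub.shape[0]):
        out[i] = rng.multivariate_hypergeometric(sub[i], depth)
    rare = pd.DataFrame(out, index=keep, columns=cm.counts.columns)
    return CountMatrix(rare, cm.dates.loc[keep])


def relative_abundance(cm: CountMatrix) -> RelAbundanceMatrix:
    """Convert counts to per-sample proportions; zero-total samples flagged."""
    totals = cm.sample_totals
    zero = totals == 0
    safe = totals.replace(0, 1)
    values = cm.counts.div(safe, axis=0)
    return RelAbundanceMatrix(values, cm.dates, zero_total=zero)


def collapse_by_ecotype(cm: CountMatrix, tax: TaxonomyMap) -> CountMatrix:
    """Sum ASV counts within each ecotype label; per-sample totals conserved."""
    tax.require_total(cm.asv_ids)
    labels = [tax[a] for a in cm.asv_ids]
    collapsed = cm.counts.T.groupby(pd.Index(labels, name="ecotype")).sum().T
    order = [e for e in ECOTYPE_VOCABULARY if e in collapsed.columns]
    return CountMatrix(collapsed[order], cm.dates)


def sar11_fraction(cm: CountMatrix, tax: TaxonomyMap) -> pd.Series:
    """Per-sample fraction of reads assigned to SAR11 ecotypes.

    Returns NaN for zero-total samples (flagged in the log).
    """
    tax.require_total(cm.asv_ids)
    sar11_cols = [a for a in cm.asv_ids if tax.is_sar11(a)]
    totals = cm.sample_totals
    frac = cm.counts[sar11_cols].sum(axis=1) / totals.where(totals > 0)
    if frac.isna().any():
        logger.warning("sar11_fraction: zero-total samples reported as missing: %s",
                       frac.index[frac.isna()].tolist())
    return frac
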