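"""Data model and I/O for K×S tables of CDR3 type counts.

Counts arise from four sources, indexed by cell type (wild-type WT vs
HPRT-mutant MT) and protocol (mass culture MC vs single-cell-derived
isolates SC).  WT counts and MT-SC counts are plain multinomial samples;
MT-MC counts are distorted by a Poisson bottleneck (6-thioguanine
selection) followed by Dirichlet-multinomial clonal growth.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SOURCE_TAGS = ("WT-MC", "MT-MC", "WT-SC", "MT-SC")


class FormatError(ValueError):
    """Raised when a count-table or metadata file is malformed."""


class ConsistencyError(ValueError):
    """Raised when tables/metadata disagree (labels, totals, category lists)."""


@dataclass
class CountTable:
    """A K×S matrix of non-negative integer sequence counts.

    Rows are CDR3 categories (J-region: K=13; V-region: K=48), columns are
    tissue samples (subjects).
    """

    categories: list[str]
    samples: list[str]
    counts: np.ndarray  # (K, S) int64
    source_tag: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a K×S matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            k, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at category {self.categories[k]!r}, "
                f"sample {self.samples[s]!r}"
            )
        if self.counts.shape != (len(self.categories), len(self.samples)):
            raise FormatError("label lists do not match matrix shape")
        if len(set(self.categories)) != len(self.categories):
            raise FormatError("duplicate category labels")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample labels")
        if self.source_tag not in SOURCE_TAGS:
            raise FormatError(f"unknown source tag {self.source_tag!r}")

    @property
    def K(self) -> int:
        return len(self.categories)

    @property
    def S(self) -> int:
        return len(self.samples)

    @property
    def totals(self) -> np.ndarray:
        """Per-sample sequencing totals (column sums)."""
        return self.counts.sum(axis=0)

    def reindex(self, categories: Sequence[str]) -> "CountTable":
        """Return a table on the given ordered category list, zero-filling
        categories absent from this table."""
        missing = set(self.categories) - set(categories)
        if missing:
            raise ConsistencyError(f"categories {sorted(missing)} not in target list")
        pos = {c: i for i, c in enumerate(self.categories)}
        out = np.zeros((len(categories), self.S), dtype=np.int64)
        for j, c in enumerate(categories):
            if c in pos:
                out[j] = self.counts[pos[c]]
        return CountTable(list(categories), list(self.samples), out, self.source_tag)


@dataclass
class SampleMeta:
    """Per-sample bottleneck inputs.

    s is the number of cells subjected to 6-TG treatment, f the HPRT-mutant
    frequency; their product s·f is the expected number of mutant survivors
    seeding the mass culture.  Totals (m_mc, m_sc, n_mc, n_sc) are the
    realized sequencing depths and, when set, must match the table columns.
    """

    sample: str
    s: float
    f: float
    n_mc: int | None = None
    n_sc: int | None = None
    m_mc: int | None = None
    m_sc: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.f < 1.0):
            raise FormatError(f"mutant frequency f={self.f} outside (0,1)")
        if self.s <= 0:
            raise FormatError(f"treated-cell count s={self.s} must be positive")

    @property
    def sf(self) -> float:
        """Poisson bottleneck mean multiplier s·f (expected mutant survivors)."""
        return self.s * self.f


@dataclass
class Dataset:
    """The four count tables on one shared ordered category list, plus
    optional per-sample metadata."""

    tables: dict[str, CountTable]
    meta: dict[str, SampleMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cats = None
        for tag, tab in self.tables.items():
            if tab.source_tag != tag:
                raise ConsistencyError(f"table under key {tag!r} is tagged {tab.source_tag!r}")
            if cats is None:
                cats = tab.categories
            elif tab.categories != cats:
                raise ConsistencyError("tables do not share one ordered category list")
        for sm in self.meta.values():
            for attr, tag in (("n_mc", "MT-MC"), ("n_sc", "MT-SC"),
                              ("m_mc", "WT-MC"), ("m_sc", "WT-SC")):
                want = getattr(sm, attr)
                tab = self.tables.get(tag)
                if want is not None and tab is not None and sm.sample in tab.samples:
                    got = int(tab.totals[tab.samples.index(sm.sample)])
                    if got != want:
                        raise ConsistencyError(
                            f"{tag} total for sample {sm.sample!r} is {got}, "
                            f"metadata says {want}"
                        )

    @property
    def categories(self) -> list[str]:
        return next(iter(self.tables.values())).categories

    @property
    def K(self) -> int:
        return len(self.categories)

    def table(self, tag: str) -> CountTable | None:
        return self.tables.get(tag)

    def with_meta(self, meta: Mapping[str, SampleMeta]) -> "Dataset":
        return Dataset(dict(self.tables), dict(meta))


def harmonize(tables: Iterable[CountTable]) -> dict[str, CountTable]:
    """Put tables on one shared ordered category list (union, first-appearance
    order), zero-filling missing categories."""
    tables = list(tables)
    cats: list[str] = []
    for t in tables:
        for c in t.categories:
            if c not in cats:
                cats.append(c)
    return {t.source_tag: t.reindex(cats) for t in tables}


# ---------------------------------------------------------------------------
# TSV I/O (tab-separated, UTF-8, '#' comment lines ignored)

def read_count_table(path: str | Path, source_tag: str) -> CountTable:
    """Read a count table: first column category labels, header row sample
    labels, integer body."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0,
                         dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows (header only)")
    counts = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (cat, raw) in enumerate(df[col].items()):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer value {raw!r} at row {cat!r}, column {col!r}"
                )
            if v < 0:
                raise FormatError(
                    f"{path}: negative count {v} at row {cat!r}, column {col!r}"
                )
            counts[i, j] = v
    cats = [str(c) for c in df.index]
    samples = [str(c) for c in df.columns]
    if len(set(cats)) != len(cats):
        raise FormatError(f"{path}: duplicate category labels")
    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample labels")
    return CountTable(cats, samples, counts, source_tag)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, index=table.categories, columns=table.samples)
    df.index.name = "type"
    df.to_csv(path, sep="\t")


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    """Read per-sample metadata: columns `sample`, `s`, `f` and optionally
    `n_mc`, `n_sc`, `m_mc`, `m_sc`."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    need = {"sample", "s", "f"}
    if not need.issubset(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(need)}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        kw = {}
        for tot in ("n_mc", "n_sc", "m_mc", "m_sc"):
            if tot in df.columns and not pd.isna(row[tot]):
                kw[tot] = int(row[tot])
        sm = SampleMeta(sample=str(row["sample"]), s=float(row["s"]),
                        f=float(row["f"]), **kw)
        if sm.sample in out:
            raise FormatError(f"{path}: duplicate sample {sm.sample!r}")
        out[sm.sample] = sm
    return out


def default_bottleneck_meta(samples: Sequence[str], s: float = 1e6,
                            f: float = 1e-5) -> dict[str, SampleMeta]:
    """Documented default metadata (s=1e6 treated cells, mutant frequency
    f=1e-5, within the reported 1e-6..1e-5 range) for use when per-sample
    values are not supplied.  Must be requested explicitly; never applied
    silently."""
    return {x: SampleMeta(sample=x, s=s, f=f) for x in samples}


# ---------------------------------------------------------------------------
# Pooling and fixture

def pool_wildtype(dataset: Dataset) -> tuple[np.ndarray, int]:
    """Pool WT counts across protocols and samples: X_t = Σ_i (X^mc + X^sc).

    WT counts are multinomial with one common probability vector, so the
    pooled vector retains the multinomial form.
    """
    wt_mc = dataset.table("WT-MC")
    wt_sc = dataset.table("WT-SC")
    if wt_mc is None and wt_sc is None:
        raise ConsistencyError("dataset has no WT tables")
    x = np.zeros(dataset.K, dtype=np.int64)
    for tab in (wt_mc, wt_sc):
        if tab is not None:
            if tab.categories != dataset.categories:
                raise ConsistencyError("WT table not on the shared category list")
            x += tab.counts.sum(axis=1)
    return x, int(x.sum())


def pool_mutant(dataset: Dataset) -> tuple[np.ndarray, int]:
    """Pool MT counts (MC + SC) across samples, for the Fisher baseline."""
    y = np.zeros(dataset.K, dtype=np.int64)
    seen = False
    for tag in ("MT-MC", "MT-SC"):
        tab = dataset.table(tag)
        if tab is not None:
            y += tab.counts.sum(axis=1)
            seen = True
    if not seen:
        raise ConsistencyError("dataset has no MT tables")
    return y, int(y.sum())


_FIXTURE_FILES = {
    "WT-MC": "jregion_wt_mc.tsv",
    "MT-MC": "jregion_mt_mc.tsv",
    "WT-SC": "jregion_wt_sc.tsv",
    "MT-SC": "jregion_mt_sc.tsv",
}


def load_fixture_jregion() -> Dataset:
    """The packaged six-patient, 13-category J-region dataset (blood).

    Ships without per-sample bottleneck metadata (s_i, f_i): those values were
    not published with the count tables.  Analyses touching MT-MC data need a
    metadata file, or the explicit documented default
    (:func:`default_bottleneck_meta`).
    """
    tables = {}
    for tag, fname in _FIXTURE_FILES.items():
        with resources.as_file(resources.files("cpmult.data") / fname) as p:
            tables[tag] = read_count_table(p, tag)
    return Dataset(harmonize(tables.values()))
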