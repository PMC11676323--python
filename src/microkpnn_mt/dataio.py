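"""Reading, quality filtering and fold construction for abundance + metadata tables.

Abundance tables are sample x species relative abundances on the percent
scale.  Quality control drops samples whose abundances sum to less than 90%
(incomplete taxonomic assignment) and phenotypes with fewer than 50 samples.
Numeric age and BMI are binned into the standard qualitative categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_CLASSES",
    "BMI_CLASSES",
    "GENDER_CLASSES",
    "METADATA_TASKS",
    "AbundanceTable",
    "Dataset",
    "EncodedData",
    "read_abundance",
    "read_metadata",
    "filter_samples",
    "filter_rare_phenotypes",
    "categorize_age",
    "categorize_bmi",
    "stratified_folds",
    "split_by_project",
]

AGE_CLASSES = ("infant", "children_adolescents", "young_adult", "middle_aged", "senior", "elderly")
BMI_CLASSES = ("underweight", "healthy_weight", "overweight", "obesity")
GENDER_CLASSES = ("female", "male")
METADATA_TASKS = ("age", "gender", "bmi", "body_site")

_MISSING_TOKENS = {"", "na", "nan", "none", "null"}

METADATA_COLUMNS = ("age", "gender", "bmi", "body_site", "phenotype", "project_id")


@dataclass
class AbundanceTable:
    """Sample x species relative abundances (percent scale)."""

    values: np.ndarray  # (n_samples, n_species)
    sample_ids: list[str]
    species_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.species_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(
            values=df.to_numpy(dtype=np.float64),
            sample_ids=[str(s) for s in df.index],
            species_ids=[str(s) for s in df.columns],
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Dataset:
    """Abundances plus aligned per-sample metadata.

    ``metadata`` is indexed by sample id with columns age, gender, bmi,
    body_site (categorical strings or NA), phenotype (never NA) and
    project_id.
    """

    abundance: AbundanceTable
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.metadata.index) != self.abundance.sample_ids:
            self.metadata = self.metadata.loc[self.abundance.sample_ids]
        if self.metadata["phenotype"].isna().any():
            raise ValueError("phenotype must be present for every sample")

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    def subset(self, sample_ids: Sequence[str]) -> "Dataset":
        idx = [self.abundance.sample_ids.index(s) for s in sample_ids]
        table = AbundanceTable(
            values=self.abundance.values[idx],
            sample_ids=list(sample_ids),
            species_ids=list(self.abundance.species_ids),
        )
        return Dataset(table, self.metadata.loc[list(sample_ids)].copy())

    def subset_bool(self, keep: np.ndarray) -> "Dataset":
        ids = [s for s, k in zip(self.abundance.sample_ids, keep) if k]
        table = AbundanceTable(
            values=self.abundance.values[np.asarray(keep, dtype=bool)],
            sample_ids=ids,
            species_ids=list(self.abundance.species_ids),
        )
        return Dataset(table, self.metadata.loc[ids].copy())

    def encode(self, vocabs: Mapping[str, Sequence[str]] | None = None, renormalize: bool = True) -> "EncodedData":
        return EncodedData.from_dataset(self, vocabs=vocabs, renormalize=renormalize)


@dataclass
class EncodedData:
    """Numeric arrays ready for the model.

    Metadata labels are integer-encoded with ``-1`` marking a missing value;
    the disease label is always present.  Abundance rows are optionally
    renormalized to sum to one (QC keeps the percent scale; the model sees
    compositions).
    """

    X: np.ndarray                       # (n, n_species)
    y_disease: np.ndarray               # (n,), int
    observed: dict[str, np.ndarray]     # task -> (n,), int, -1 = missing
    vocabs: dict[str, list[str]]        # task and "disease" -> label list
    sample_ids: list[str]
    species_ids: list[str]
    projects: np.ndarray

    @classmethod
    def from_dataset(
        cls,
        ds: Dataset,
        vocabs: Mapping[str, Sequence[str]] | None = None,
        renormalize: bool = True,
    ) -> "EncodedData":
        meta = ds.metadata
        if vocabs is None:
            vocabs = {
                "age": list(AGE_CLASSES),
                "gender": list(GENDER_CLASSES),
                "bmi": list(BMI_CLASSES),
                "body_site": sorted(meta["body_site"].dropna().unique()),
                "disease": sorted(meta["phenotype"].unique()),
            }
        vocabs = {k: list(v) for k, v in vocabs.items()}
        X = ds.abundance.values.astype(np.float64).copy()
        if renormalize:
            sums = X.sum(axis=1, keepdims=True)
            sums[sums == 0] = 1.0
            X = X / sums
        observed: dict[str, np.ndarray] = {}
        for task, col in zip(METADATA_TASKS, ("age", "gender", "bmi", "body_site")):
            lookup = {lab: i for i, lab in enumerate(vocabs[task])}
            vals = np.full(len(meta), -1, dtype=np.int64)
            for i, v in enumerate(meta[col]):
                if pd.isna(v):
                    continue
                if v not in lookup:
                    raise ValueError(f"unknown {task} label {v!r}")
                vals[i] = lookup[v]
            observed[task] = vals
        dlookup = {lab: i for i, lab in enumerate(vocabs["disease"])}
        y = np.array([dlookup[v] for v in meta["phenotype"]], dtype=np.int64)
        return cls(
            X=X,
            y_disease=y,
            observed=observed,
            vocabs=vocabs,
            sample_ids=list(ds.abundance.sample_ids),
            species_ids=list(ds.abundance.species_ids),
            projects=meta["project_id"].to_numpy(),
        )

    def take(self, idx: np.ndarray) -> "EncodedData":
        return EncodedData(
            X=self.X[idx],
            y_disease=self.y_disease[idx],
            observed={t: v[idx] for t, v in self.observed.items()},
            vocabs=self.vocabs,
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
            species_ids=self.species_ids,
            projects=self.projects[idx],
        )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


# -- reading ------------------------------------------------------------------


def read_abundance(path: str | Path) -> AbundanceTable:
    """Read a delimited abundance table (samples in rows, species in columns).

    The first column holds sample ids and the header row species ids.
    Non-numeric or negative cells are reported with their coordinates.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric abundance at sample {row!r}, species {col!r}")
        df[col] = coerced
    values = df.to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(f"{path}: missing abundance at sample {df.index[i]!r}, species {df.columns[j]!r}")
    if (values < 0).any():
        i, j = map(int, np.argwhere(values < 0)[0])
        raise ValueError(f"{path}: negative abundance at sample {df.index[i]!r}, species {df.columns[j]!r}")
    return AbundanceTable.from_frame(df)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    table.to_frame().to_csv(path, sep=sep)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV.

    Expected columns: sample_id, age, gender, bmi, body_site, phenotype,
    project_id.  Age and BMI may be raw numeric values (categorized on load)
    or already-categorized strings.  Empty cells and the literal "NA" denote
    missing values; phenotype must never be missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata must have a sample_id column")
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing metadata columns {missing_cols}")
    df = df.set_index("sample_id")

    def clean(v: str) -> str | None:
        return None if v.strip().lower() in _MISSING_TOKENS else v.strip()

    out = pd.DataFrame(index=df.index)
    for col in METADATA_COLUMNS:
        out[col] = [clean(v) for v in df[col]]
    out["age"] = [
        None if v is None else (v if v in AGE_CLASSES else categorize_age(float(v)))
        for v in out["age"]
    ]
    out["bmi"] = [
        None if v is None else (v if v in BMI_CLASSES else categorize_bmi(float(v)))
        for v in out["bmi"]
    ]
    for v in out["gender"]:
        if v is not None and v not in GENDER_CLASSES:
            raise ValueError(f"{path}: unknown gender label {v!r}")
    if out["phenotype"].isna().any():
        raise ValueError(f"{path}: phenotype missing for some samples")
    return out


# -- filters and categorization -----------------------------------------------


def filter_samples(table: AbundanceTable, threshold: float = 90.0) -> AbundanceTable:
    """Drop samples whose relative abundances sum to strictly less than
    ``threshold`` percent (default 90%, i.e. poorly characterised samples)."""
    sums = table.values.sum(axis=1)
    keep = sums >= threshold
    if not keep.any():
        warnings.warn("all samples fall below the abundance-sum threshold", stacklevel=2)
    return AbundanceTable(
        values=table.values[keep],
        sample_ids=[s for s, k in zip(table.sample_ids, keep) if k],
        species_ids=list(table.species_ids),
    )


def filter_rare_phenotypes(meta: pd.DataFrame, min_samples: int = 50) -> pd.DataFrame:
    """Drop samples whose phenotype has strictly fewer than ``min_samples``
    samples.  Applied uniformly to every phenotype label, including healthy."""
    counts = meta["phenotype"].value_counts()
    keep_labels = set(counts[counts >= min_samples].index)
    return meta[meta["phenotype"].isin(keep_labels)].copy()


def categorize_age(age: float) -> str:
    """Bin an age in years: infant (<=3), children/adolescents (3, 18],
    young adult (18, 35], middle aged (35, 50], senior (50, 65],
    elderly (>65)."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if age <= 3:
        return "infant"
    if age <= 18:
        return "children_adolescents"
    if age <= 35:
        return "young_adult"
    if age <= 50:
        return "middle_aged"
    if age <= 65:
        return "senior"
    return "elderly"


def categorize_bmi(bmi: float) -> str:
    """Bin a BMI in kg/m^2: underweight (<18.5), healthy weight [18.5, 25),
    overweight [25, 30), obesity (>=30)."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "healthy_weight"
    if bmi < 30:
        return "overweight"
    return "obesity"


# -- folds and project splits -------------------------------------------------


def stratified_folds(phenotypes: Sequence[str], k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign samples to ``k`` folds keeping the per-phenotype counts within
    one of each other across folds.  Deterministic given ``seed``."""
    if k < 2:
        raise ValueError("k must be at least 2")
    y = np.asarray(phenotypes)
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        warnings.warn(
            f"some phenotype has fewer samples ({counts.min()}) than folds ({k})",
            stacklevel=2,
        )
    # per-class shuffled round-robin with a rotating offset: per-class fold
    # counts differ by at most one, and small classes (< k members) are
    # tolerated rather than rejected
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=np.int64)
    start = 0
    for c in sorted(map(str, set(y))):
        idx = np.nonzero(y.astype(str) == c)[0]
        rng.shuffle(idx)
        assignment[idx] = (np.arange(len(idx)) + start) % k
        start = (start + len(idx)) % k
    return assignment


def split_by_project(
    ds: Dataset,
    train_projects: Sequence[str],
    test_projects: Sequence[str],
) -> tuple[Dataset, Dataset]:
    """Partition a dataset into project-disjoint train and test subsets."""
    train_set, test_set = set(train_projects), set(test_projects)
    overlap = train_set & test_set
    if overlap:
        raise ValueError(f"train and test project sets overlap: {sorted(overlap)}")
    projects = ds.metadata["project_id"]
    unused = set(projects) - train_set - test_set
    if unused:
        warnings.warn(f"projects in neither split: {sorted(unused)}", stacklevel=2)
    train = ds.subset_bool(projects.isin(train_set).to_numpy())
    test = ds.subset_bool(projects.isin(test_set).to_numpy())
    return train, test
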