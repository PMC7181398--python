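"""Domain containers, file I/O, normalization and abundance filtering.

The analysis operates on feature-by-sample abundance tables holding two
feature kinds — microbial genera and KEGG-ortholog (KO) genes — together
with per-animal metadata (breed, diet, methane yield in g CH4 per kg dry
matter intake) and optional feature annotation (taxonomic domain or KO
description).

Two filtering rules precede any network analysis:

* prevalence — features with zero abundance in more than ``max_zero_samples``
  animals are dropped (co-abundance estimates are unstable on sparse rows);
* minimum abundance — gene features whose mean relative abundance does not
  exceed a small percentage threshold are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "FeatureAnnotation",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "read_annotation",
    "normalize_relative",
    "filter_prevalence",
    "filter_min_abundance",
    "merge_tables",
]

FeatureKind = Literal["gene", "genus"]
Units = Literal["counts", "percent"]

BREEDS = ("AA", "LIM")
DIETS = ("FOR", "CONC")
DOMAINS = ("bacteria", "archaea", "fungi", "protist", "gene")

_PERCENT_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class AbundanceTable:
    """Feature-by-sample table of nonnegative abundances.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples (animals).
    feature_kind : pandas.Series or str
        Per-feature kind tag (``"gene"`` or ``"genus"``); a single string
        applies to all features.
    units : {"counts", "percent"}
        When ``"percent"`` every sample column must sum to 100 within each
        feature kind.
    """

    values: pd.DataFrame
    feature_kind: pd.Series
    units: Units = "counts"

    def __post_init__(self) -> None:
        if isinstance(self.feature_kind, str):
            self.feature_kind = pd.Series(
                self.feature_kind, index=self.values.index, dtype=object
            )
        self.values = self.values.astype(float)
        self.feature_kind = self.feature_kind.reindex(self.values.index)
        self._validate()

    def _validate(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite abundance values present")
        if (arr < 0).any():
            bad = self.values.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative abundance in feature {bad!r}")
        bad_kind = set(self.feature_kind.dropna()) - {"gene", "genus"}
        if bad_kind or self.feature_kind.isna().any():
            raise ValidationError(f"invalid feature_kind entries: {bad_kind or 'missing'}")
        if self.units not in ("counts", "percent"):
            raise ValidationError(f"unknown units {self.units!r}")
        if self.units == "percent" and len(idx) and len(cols):
            # closure holds exactly after normalize_relative; filtered tables
            # keep surviving values untouched, so sums may fall below 100
            for kind, sub in self.values.groupby(self.feature_kind, sort=False):
                sums = sub.sum(axis=0)
                if (sums > 100.0 + _PERCENT_TOL).any():
                    j = sums.index[np.argmax(sums.to_numpy())]
                    raise ValidationError(
                        f"{kind} abundances in sample {j!r} sum to {sums[j]:.6f} > 100"
                    )

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, ids: Iterable[str]) -> "AbundanceTable":
        ids = list(ids)
        return AbundanceTable(self.values.loc[ids], self.feature_kind.loc[ids], self.units)

    def subset_samples(self, ids: Iterable[str]) -> "AbundanceTable":
        ids = list(ids)
        return AbundanceTable(self.values[ids], self.feature_kind.copy(), self.units)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kinds = self.feature_kind.value_counts().to_dict()
        return (
            f"AbundanceTable({self.n_features} features {kinds}, "
            f"{self.n_samples} samples, units={self.units!r})"
        )


@dataclass
class SampleMetadata:
    """Per-animal metadata: breed, diet and methane yield (g CH4 / kg DMI)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal_id", "breed", "diet", "ch4"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        f = self.frame.reset_index(drop=True).copy()
        if f["animal_id"].duplicated().any():
            raise ValidationError("duplicate animal_id in metadata")
        if not set(f["breed"]) <= set(BREEDS):
            raise ValidationError(f"breed must be one of {BREEDS}")
        if not set(f["diet"]) <= set(DIETS):
            raise ValidationError(f"diet must be one of {DIETS}")
        ch4 = f["ch4"].astype(float)
        if not np.all(np.isfinite(ch4)) or (ch4 <= 0).any():
            raise ValidationError("ch4 must be finite and positive")
        f["ch4"] = ch4
        self.frame = f

    @property
    def animal_ids(self) -> list[str]:
        return list(self.frame["animal_id"])

    def aligned_to(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Rows reordered to ``sample_ids``; errors on missing animals."""
        f = self.frame.set_index("animal_id")
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(f.index)
        if missing:
            raise ValidationError(f"animals without metadata: {sorted(missing)}")
        return f.loc[sample_ids].reset_index()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class FeatureAnnotation:
    """Feature labels and taxonomic domain (or 'gene' for KO features)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"feature_id", "label", "domain"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        f = self.frame.reset_index(drop=True).copy()
        if f["feature_id"].duplicated().any():
            raise ValidationError("duplicate feature_id in annotation")
        bad = set(f["domain"]) - set(DOMAINS)
        if bad:
            raise ValidationError(f"unknown annotation domains: {sorted(bad)}")
        if "phylum_or_pathway" not in f.columns:
            f["phylum_or_pathway"] = pd.NA
        self.frame = f

    def domain_of(self) -> pd.Series:
        return self.frame.set_index("feature_id")["domain"]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path: str | Path, kind: FeatureKind, units: Units) -> AbundanceTable:
    """Read a feature x sample TSV (header = sample ids, first column = feature ids)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.isna().any().any():
        i, j = np.argwhere(raw.isna().to_numpy())[0]
        raise ValidationError(
            f"{path.name}: missing cell at feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    try:
        values = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path.name}: malformed numeric cell {cell!r} at "
                        f"feature {raw.index[i]!r}, sample {col!r}"
                    ) from None
        raise
    return AbundanceTable(values, kind, units)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the animal metadata CSV (animal_id, breed, diet, ch4_g_per_kg_dmi)."""
    f = pd.read_csv(path, dtype={"animal_id": str})
    if "ch4_g_per_kg_dmi" in f.columns:
        f = f.rename(columns={"ch4_g_per_kg_dmi": "ch4"})
    return SampleMetadata(f)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    f = metadata.frame.rename(columns={"ch4": "ch4_g_per_kg_dmi"})
    f.to_csv(path, index=False)


def read_annotation(path: str | Path) -> FeatureAnnotation:
    return FeatureAnnotation(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# Normalization and filters
# ---------------------------------------------------------------------------

def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to relative abundance in percent, per feature kind.

    Each sample column is closed to 100% separately within genes and within
    genera (the two assays are normalized independently before merging).
    Zeros are preserved; an all-zero column is an error. Idempotent on
    already-normalized percent tables.
    """
    out = table.values.copy()
    for kind, sub in table.values.groupby(table.feature_kind, sort=False):
        sums = sub.sum(axis=0)
        zero = sums[sums == 0]
        if len(zero):
            raise ValidationError(
                f"sample {zero.index[0]!r} has zero total {kind} abundance"
            )
        out.loc[sub.index] = 100.0 * sub / sums
    return AbundanceTable(out, table.feature_kind.copy(), "percent")


@dataclass
class FilterReport:
    """Which features a filter removed and why."""

    rule: str
    removed: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_prevalence(
    table: AbundanceTable, max_zero_samples: int = 2
) -> tuple[AbundanceTable, FilterReport]:
    """Drop features with zeros in more than ``max_zero_samples`` samples.

    The default keeps features with at most 2 zero-count animals, i.e.
    removes those at zero in 3 or more of the samples.
    """
    zeros = (table.values.to_numpy() == 0).sum(axis=1)
    keep = zeros <= max_zero_samples
    report = FilterReport(
        rule=f"prevalence: zero in > {max_zero_samples} samples",
        removed=list(table.values.index[~keep]),
        kept=list(table.values.index[keep]),
    )
    return table.subset_features(report.kept), report


def filter_min_abundance(
    table: AbundanceTable,
    threshold_percent: float = 0.001,
    per_sample: bool = False,
) -> tuple[AbundanceTable, FilterReport]:
    """Drop features whose mean relative abundance is <= ``threshold_percent``.

    Requires a percent-normalized table (the threshold is a percentage).
    With ``per_sample=True`` a feature is kept if it exceeds the threshold
    in every sample instead of on the mean.
    """
    if table.units != "percent":
        raise ValidationError("minimum-abundance filter requires percent units")
    if per_sample:
        keep = (table.values.to_numpy() > threshold_percent).all(axis=1)
    else:
        keep = table.values.mean(axis=1).to_numpy() > threshold_percent
    report = FilterReport(
        rule=f"min abundance: mean <= {threshold_percent}%"
        + (" (per-sample)" if per_sample else ""),
        removed=list(table.values.index[~keep]),
        kept=list(table.values.index[keep]),
    )
    return table.subset_features(report.kept), report


def merge_tables(genes: AbundanceTable, genera: AbundanceTable) -> AbundanceTable:
    """Stack gene and genus tables over the same samples.

    Feature ids are namespaced (``gene:K00399``, ``genus:Prevotella``) so the
    merged feature space cannot collide. Sample sets must match exactly.
    """
    a, b = set(genes.sample_ids), set(genera.sample_ids)
    if a != b:
        raise ValidationError(
            f"sample mismatch: only in genes {sorted(a - b)}, only in genera {sorted(b - a)}"
        )
    if genes.units != genera.units:
        raise ValidationError("cannot merge tables with different units")

    def _namespace(t: AbundanceTable) -> pd.DataFrame:
        v = t.values.copy()
        v.index = [f"{k}:{i}" for i, k in zip(t.values.index, t.feature_kind)]
        return v

    gv = _namespace(genes)
    uv = _namespace(genera)
    if genes.n_features and genera.n_features:
        values = pd.concat([gv, uv[gv.columns]])
    elif genes.n_features:
        values = gv
    else:
        values = uv
    kind = pd.Series(
        list(genes.feature_kind) + list(genera.feature_kind), index=values.index, dtype=object
    )
    return AbundanceTable(values, kind, genes.units)


def strip_namespace(feature_id: str) -> str:
    """Inverse of the merge namespacing for display purposes."""
    return feature_id.split(":", 1)[1] if ":" in feature_id else feature_id
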