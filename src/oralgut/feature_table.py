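"""ASV feature tables, sample metadata, taxonomy, and the normalization chain.

The central container is :class:`FeatureTable`, a features x samples matrix of
read counts with a transform-state flag.  Analyses downstream expect the fixed
transform chain

    counts -> percent (per-sample relative abundance) -> sqrt_percent

enforced as a small state machine so a table can never be normalized or
square-root transformed twice.  Percent normalization removes the effect of
variable sequencing depth between samples; the square root damps the influence
of the most abundant taxa before Bray-Curtis resemblance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STATES = ("counts", "percent", "sqrt_percent")
HABITATS = ("oral", "gut")
RANKS = ("phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

#: header tokens accepted for the feature-id column of a QIIME-2-style export
_FEATURE_HEADER_TOKENS = {"#otu id", "feature-id", "feature id", "#asv id", "asv-id"}


class StateError(ValueError):
    """Raised when an operation is applied to a table in the wrong transform state."""


def _check_unique(labels: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {kind} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class FeatureTable:
    """Features x samples abundance matrix with explicit transform state.

    Parameters
    ----------
    feature_ids : list of str
        ASV identifiers (opaque; conventionally a hash of the denoised sequence).
    sample_ids : list of str
    values : ndarray, shape (n_features, n_samples)
        Non-negative counts or abundances, depending on ``state``.
    state : {"counts", "percent", "sqrt_percent"}
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    state: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if np.any(self.values < 0):
            f, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at feature {self.feature_ids[f]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.state == "counts" and not np.allclose(self.values, np.round(self.values)):
            raise ValueError("state='counts' requires integer values")
        if self.state == "percent":
            sums = self.values.sum(axis=0)
            bad = ~np.isclose(sums, 100.0, atol=1e-9) & (sums != 0.0)
            if np.any(bad):
                j = int(np.argwhere(bad)[0])
                raise ValueError(
                    f"percent column {self.sample_ids[j]!r} sums to {sums[j]}, not 100"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.feature_ids), list(self.sample_ids), self.values.copy(), self.state
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        """Sub-table restricted to the given samples, in the given order."""
        wanted = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [pos[s] for s in wanted]
        return FeatureTable(list(self.feature_ids), wanted, self.values[:, idx], self.state)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, orientation: str = "auto") -> FeatureTable:
    """Read a tab-separated ASV count table (QIIME-2 export dialect).

    First column holds feature IDs, remaining columns samples.  A leading
    ``# Constructed from biom file`` comment line is skipped.  ``orientation``
    may be ``"features_as_rows"`` (the convention), ``"samples_as_rows"``
    (table is transposed on read) or ``"auto"`` which trusts the header token
    only — never value heuristics.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        skip = 1 if first.lstrip().startswith("# Constructed from biom") else 0
        header = (fh.readline() if skip else first).rstrip("\n").split("\t")
    _check_unique(header[1:], "sample")  # pandas would silently mangle duplicates
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, dtype=str)
    header = str(df.index.name or "").strip().lower()
    if orientation == "auto":
        orientation = "features_as_rows"  # header token is the only accepted signal
        if header and header not in _FEATURE_HEADER_TOKENS and header in {"sample-id", "#sampleid"}:
            orientation = "samples_as_rows"
    if orientation == "samples_as_rows":
        df = df.T
    elif orientation != "features_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    _check_unique(df.index, "feature")
    _check_unique(df.columns, "sample")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, fid in enumerate(df.index):
            for j, sid in enumerate(df.columns):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at feature {fid!r}, sample {sid!r}: "
                        f"{df.iat[i, j]!r}"
                    ) from None
        raise
    if np.any(values < 0):
        f, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at feature {df.index[f]!r}, sample {df.columns[s]!r}"
        )
    return FeatureTable(list(df.index), list(df.columns), values, state="counts")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table as TSV with a ``#OTU ID`` header cell (counts as integers)."""
    df = table.to_dataframe()
    if table.state == "counts":
        df = df.astype(int)
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

SEXES = ("female", "male")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese", "missing")
AGE_GROUPS = ("child", "adult")
ADULT_AGE_BINS = ("le44", "ge45", "n/a")


@dataclass
class SampleMetadata:
    """Per-sample attributes linking samples to individuals and strata.

    Wraps a DataFrame indexed by sample ID with columns ``individual_id``,
    ``habitat``, ``age_years``, ``age_group``, ``adult_age_bin``, ``sex``,
    ``bmi_category``.  Pairing invariant: each individual has at most one oral
    and at most one gut sample.
    """

    frame: pd.DataFrame
    child_age_range: tuple[float, float] = (5.0, 10.0)

    def __post_init__(self) -> None:
        df = self.frame
        required = {"individual_id", "habitat", "age_years", "sex"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing required column(s): {sorted(missing)}")
        _check_unique(df.index, "sample")
        bad_hab = set(df["habitat"]) - set(HABITATS)
        if bad_hab:
            raise ValueError(f"unknown habitat value(s): {sorted(bad_hab)}")
        lo, hi = self.child_age_range
        if "age_group" not in df.columns:
            df = df.assign(
                age_group=np.where((df["age_years"] >= lo) & (df["age_years"] <= hi),
                                   "child", "adult")
            )
        else:
            derived = np.where((df["age_years"] >= lo) & (df["age_years"] <= hi),
                               "child", "adult")
            clash = df["age_group"] != derived
            if clash.any():
                sid = df.index[clash][0]
                raise ValueError(
                    f"age_group inconsistent with age for sample {sid!r}: "
                    f"age {df.loc[sid, 'age_years']} labelled {df.loc[sid, 'age_group']!r}"
                )
        if "adult_age_bin" not in df.columns:
            df = df.assign(
                adult_age_bin=np.where(
                    df["age_group"] == "child", "n/a",
                    np.where(df["age_years"] <= 44, "le44", "ge45"),
                )
            )
        if "bmi_category" not in df.columns:
            df = df.assign(bmi_category="missing")
        dup = df.groupby(["individual_id", "habitat"]).size()
        if (dup > 1).any():
            ind, hab = dup[dup > 1].index[0]
            raise ValueError(
                f"individual {ind!r} has {dup[(ind, hab)]} {hab} samples; "
                "at most one per habitat allowed"
            )
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.frame["individual_id"]))

    def samples_where(self, **criteria) -> list[str]:
        """Sample IDs matching equality criteria on metadata columns."""
        mask = np.ones(len(self.frame), dtype=bool)
        for col, val in criteria.items():
            mask &= (self.frame[col] == val).to_numpy()
        return list(self.frame.index[mask])

    def paired_individuals(self) -> dict[str, dict[str, str]]:
        """individual_id -> {"oral": sample, "gut": sample} for fully paired individuals."""
        out: dict[str, dict[str, str]] = {}
        for ind, sub in self.frame.groupby("individual_id"):
            habs = dict(zip(sub["habitat"], sub.index))
            if set(habs) == set(HABITATS):
                out[ind] = habs
            else:
                logger.warning(
                    "individual %s lacks a %s sample; excluded from paired analyses",
                    ind, (set(HABITATS) - set(habs)).pop(),
                )
        return out


_META_COLMAP = {
    "sample-id": "sample_id", "sampleid": "sample_id", "#sampleid": "sample_id",
    "individual-id": "individual_id", "subject-id": "individual_id",
    "habitat": "habitat", "body-site": "habitat",
    "age": "age_years", "age-years": "age_years",
    "age-group": "age_group", "adult-age-bin": "adult_age_bin",
    "sex": "sex", "bmi-category": "bmi_category", "bmi": "bmi",
}


def read_metadata(path: str | Path,
                  child_age_range: tuple[float, float] = (5.0, 10.0)) -> SampleMetadata:
    """Read a sample-metadata TSV (mandatory: sample-id, individual-id, habitat, age, sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [_META_COLMAP.get(c.strip().lower(), c.strip().lower().replace("-", "_"))
                  for c in df.columns]
    if "sample_id" not in df.columns:
        raise ValueError("metadata must have a 'sample-id' column")
    df = df.set_index("sample_id")
    df["age_years"] = df["age_years"].astype(float)
    return SampleMetadata(df, child_age_range=child_age_range)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.frame.copy()
    df.index.name = "sample-id"
    df = df.rename(columns={
        "individual_id": "individual-id", "age_years": "age",
        "age_group": "age-group", "adult_age_bin": "adult-age-bin",
        "bmi_category": "bmi-category",
    })
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

_RANK_PREFIX = {"p": "phylum", "c": "class", "o": "order", "f": "family", "g": "genus"}


@dataclass
class TaxonomyTable:
    """feature_id -> {phylum..genus}; unassigned ranks are explicit "unclassified"."""

    assignments: dict[str, dict[str, str]] = field(default_factory=dict)

    def rank_label(self, feature_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.assignments.get(feature_id, {}).get(rank, UNCLASSIFIED) or UNCLASSIFIED

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.assignments


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a Greengenes-style lineage string (``p__...; c__...; ...; g__...``)."""
    ranks = {r: UNCLASSIFIED for r in RANKS}
    for token in str(lineage).split(";"):
        token = token.strip()
        if "__" in token:
            prefix, _, name = token.partition("__")
            rank = _RANK_PREFIX.get(prefix.strip().lower())
            if rank and name.strip():
                ranks[rank] = name.strip()
    return ranks


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a two-column (feature-id, lineage) taxonomy TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fid_col, lin_col = df.columns[0], df.columns[1]
    assignments = {str(r[fid_col]): parse_lineage(r[lin_col]) for _, r in df.iterrows()}
    return TaxonomyTable(assignments)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    rows = []
    for fid, ranks in taxonomy.assignments.items():
        lineage = "; ".join(
            f"{p}__{ranks.get(r, UNCLASSIFIED)}" for p, r in
            zip(("p", "c", "o", "f", "g"), RANKS)
        )
        rows.append((fid, lineage))
    pd.DataFrame(rows, columns=["feature-id", "taxonomy"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transform chain and derived matrices
# ---------------------------------------------------------------------------

def to_relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample percentages (each column sums to 100).

    All-zero sample columns are kept as-is with a logged warning; silently
    dropping them would hide upstream failures.
    """
    if table.state != "counts":
        raise StateError(f"to_relative_abundance requires state='counts', got {table.state!r}")
    sums = table.values.sum(axis=0)
    zero = sums == 0
    if np.any(zero):
        for sid in np.asarray(table.sample_ids)[zero]:
            logger.warning("sample %s has zero total reads; left all-zero", sid)
    safe = np.where(zero, 1.0, sums)
    values = 100.0 * table.values / safe
    return FeatureTable(list(table.feature_ids), list(table.sample_ids), values, "percent")


def sqrt_transform(table: FeatureTable) -> FeatureTable:
    """Element-wise square root of a percent table (state -> sqrt_percent)."""
    if table.state != "percent":
        raise StateError(f"sqrt_transform requires state='percent', got {table.state!r}")
    return FeatureTable(
        list(table.feature_ids), list(table.sample_ids), np.sqrt(table.values), "sqrt_percent"
    )


def presence_matrix(table: FeatureTable, min_count: int = 1) -> pd.DataFrame:
    """Boolean features x samples presence matrix.

    For count tables, presence means count >= ``min_count`` (default 1: the
    table is assumed already denoised, so a single read is evidence).  For a
    percent-state table (e.g. a generator's expected compositions), presence
    means abundance > 0 and ``min_count`` must be 1.
    """
    if table.state == "counts":
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        mask = table.values >= min_count
    elif table.state == "percent":
        if min_count != 1:
            raise ValueError("min_count thresholds only apply to count tables")
        mask = table.values > 0
    else:
        raise StateError(f"presence_matrix requires counts or percent, got {table.state!r}")
    return pd.DataFrame(mask, index=table.feature_ids, columns=table.sample_ids)


def aggregate_taxon(table: FeatureTable, taxonomy: TaxonomyTable, rank: str) -> FeatureTable:
    """Sum percent rows within identical taxon labels at ``rank``.

    Features missing from the taxonomy are assigned to "unclassified" with a
    warning.  Per-sample column totals are conserved exactly.
    """
    if table.state != "percent":
        raise StateError(f"aggregate_taxon requires state='percent', got {table.state!r}")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = []
    for fid in table.feature_ids:
        if fid not in taxonomy:
            warnings.warn(f"feature {fid!r} missing from taxonomy; using 'unclassified'")
        labels.append(taxonomy.rank_label(fid, rank))
    df = table.to_dataframe()
    grouped = df.groupby(pd.Index(labels, name=rank), sort=True).sum()
    return FeatureTable(list(grouped.index), list(table.sample_ids),
                        grouped.to_numpy(), "percent")
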