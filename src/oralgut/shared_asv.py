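"""Habitat-exclusive / shared ASV accounting across paired oral and gut samples.

An ASV can be "shared" between habitats in two distinct senses:

* **cross-habitat** — detected in the gut of at least one participant and in
  the oral cavity of at least one (possibly different) participant;
* **within-individual shared** — detected in both the saliva and the stool
  sample of the *same* participant, the stronger signal of oral-gut
  translocation.

This module computes both sets, classifies each within-individual shared ASV
by abundance directionality (which habitat shows the higher mean relative
abundance), partitions the shared set by age-group persistence, and derives
the cohort-level count summary with its printed-percentage conventions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, SampleMetadata, TaxonomyTable, StateError

logger = logging.getLogger(__name__)

DIRECTIONS = ("oral_dominant", "gut_dominant", "tied")
AGE_PARTITIONS = ("child_only", "adult_only", "both")


def habitat_sets(presence: pd.DataFrame, metadata: SampleMetadata
                 ) -> tuple[set[str], set[str], set[str]]:
    """ASVs detected in >=1 gut sample, >=1 oral sample, and both habitats.

    Returns ``(gut_set, oral_set, both_environments_set)``; the last is the
    intersection, i.e. the cross-habitat shared set regardless of individual.
    """
    out = {}
    for habitat in ("gut", "oral"):
        samples = metadata.samples_where(habitat=habitat)
        if not samples:
            raise ValueError(f"no {habitat} samples in metadata")
        cols = [s for s in samples if s in presence.columns]
        if not cols:
            raise ValueError(f"no {habitat} samples present in the feature table")
        out[habitat] = set(presence.index[presence[cols].any(axis=1)])
    return out["gut"], out["oral"], out["gut"] & out["oral"]


def within_individual_shared(presence: pd.DataFrame, metadata: SampleMetadata
                             ) -> dict[str, set[str]]:
    """Map feature_id -> individuals in whose *own* oral AND gut samples it appears.

    Only ASVs co-detected in at least one individual are returned.  Individuals
    lacking one habitat are skipped (with a warning from the pairing logic);
    an individual with two samples of the same habitat is rejected upstream by
    the metadata invariant.
    """
    pairs = metadata.paired_individuals()
    result: dict[str, set[str]] = {}
    for ind, habs in pairs.items():
        oral, gut = habs["oral"], habs["gut"]
        if oral not in presence.columns or gut not in presence.columns:
            logger.warning("individual %s has samples missing from the table; skipped", ind)
            continue
        co = presence[oral] & presence[gut]
        for fid in presence.index[co]:
            result.setdefault(fid, set()).add(ind)
    return result


def classify_directionality(table: FeatureTable, metadata: SampleMetadata,
                            shared_set: set[str], tie_tol: float = 1e-12,
                            detected_only: bool = False) -> dict[str, str]:
    """Classify each shared ASV as oral_dominant / gut_dominant / tied.

    The default compares habitat-wide means of relative abundance with zeros
    included (every oral sample vs every gut sample).  ``detected_only=True``
    instead averages over samples where the ASV is present — a sensitivity
    variant, since "frequency values" admits either reading.
    """
    if table.state != "percent":
        raise StateError(f"classify_directionality requires state='percent', got {table.state!r}")
    if tie_tol < 0:
        raise ValueError("tie_tol must be >= 0")
    df = table.to_dataframe()
    means = {}
    for habitat in ("oral", "gut"):
        cols = [s for s in metadata.samples_where(habitat=habitat) if s in df.columns]
        if not cols:
            raise ValueError(f"no {habitat} samples available")
        sub = df[cols]
        if detected_only:
            m = sub.where(sub > 0).mean(axis=1).fillna(0.0)
        else:
            m = sub.mean(axis=1)
        means[habitat] = m
    out: dict[str, str] = {}
    for fid in shared_set:
        o, g = float(means["oral"].get(fid, 0.0)), float(means["gut"].get(fid, 0.0))
        if o > g + tie_tol:
            out[fid] = "oral_dominant"
        elif g > o + tie_tol:
            out[fid] = "gut_dominant"
        else:
            out[fid] = "tied"
    return out


def partition_by_age(presence: pd.DataFrame, metadata: SampleMetadata,
                     shared_set: set[str]) -> dict[str, str]:
    """Partition shared ASVs into child_only / adult_only / both.

    Membership counts detection in >=1 sample (either habitat) belonging to an
    individual of that age group.
    """
    groups = {}
    for grp in ("child", "adult"):
        cols = [s for s in metadata.samples_where(age_group=grp) if s in presence.columns]
        if not cols:
            raise ValueError(f"no samples for age group {grp!r}")
        groups[grp] = presence[cols].any(axis=1)
    out: dict[str, str] = {}
    for fid in shared_set:
        in_child = bool(groups["child"].get(fid, False))
        in_adult = bool(groups["adult"].get(fid, False))
        if in_child and in_adult:
            out[fid] = "both"
        elif in_child:
            out[fid] = "child_only"
        else:
            out[fid] = "adult_only"
    return out


def sharing_prevalence(within_individual_map: Mapping[str, set[str]],
                       metadata: SampleMetadata) -> tuple[int, int, int]:
    """(n individuals with >=1 shared ASV, n individuals total, percent to nearest integer)."""
    with_shared: set[str] = set()
    for inds in within_individual_map.values():
        with_shared |= set(inds)
    n_total = len(metadata.individuals)
    n_with = len(with_shared)
    pct = int(round(100.0 * n_with / n_total)) if n_total else 0
    return n_with, n_total, pct


# ---------------------------------------------------------------------------
# Count summary
# ---------------------------------------------------------------------------

@dataclass
class CountSummary:
    """Cohort-level ASV accounting with the derived printed percentages.

    Percentages of the whole detected-ASV pool are given to one decimal;
    percentages of the shared subset and participant prevalence are rounded
    to the nearest integer.
    """

    n_gut_detected: int
    n_oral_detected: int
    n_both_environments: int
    n_within_individual_shared: int
    n_oral_dominant: int
    n_gut_dominant: int
    n_tied: int
    n_child_only: int
    n_adult_only: int
    n_both_ages: int
    n_individuals_total: int
    n_individuals_with_shared: int
    # derived
    total_asvs: int = 0
    n_gut_exclusive: int = 0
    n_oral_exclusive: int = 0
    pct_shared: float = 0.0
    pct_persistent: float = 0.0
    pct_oral_dominant: int = 0
    pct_gut_dominant: int = 0
    pct_both_ages_of_shared: int = 0
    pct_individuals_with_shared: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def summarize_counts(n_gut_detected: int, n_oral_detected: int,
                     n_both_environments: int, n_within_individual_shared: int,
                     n_oral_dominant: int = 0, n_gut_dominant: int = 0,
                     n_tied: int | None = None,
                     n_child_only: int = 0, n_adult_only: int = 0,
                     n_both_ages: int | None = None,
                     n_individuals_total: int = 0,
                     n_individuals_with_shared: int = 0) -> CountSummary:
    """Derive exclusive counts and printed percentages from raw counts.

    ``n_tied`` and ``n_both_ages`` default to the remainders of the shared set
    so that the three-way partitions always close.  Raises on any violated
    identity, naming it.
    """
    if n_tied is None:
        n_tied = n_within_individual_shared - n_oral_dominant - n_gut_dominant
    if n_both_ages is None:
        n_both_ages = n_within_individual_shared - n_child_only - n_adult_only
    counts = dict(
        n_gut_detected=n_gut_detected, n_oral_detected=n_oral_detected,
        n_both_environments=n_both_environments,
        n_within_individual_shared=n_within_individual_shared,
        n_oral_dominant=n_oral_dominant, n_gut_dominant=n_gut_dominant, n_tied=n_tied,
        n_child_only=n_child_only, n_adult_only=n_adult_only, n_both_ages=n_both_ages,
        n_individuals_total=n_individuals_total,
        n_individuals_with_shared=n_individuals_with_shared,
    )
    for name, v in counts.items():
        if v < 0:
            raise ValueError(f"negative count: {name} = {v}")
    if n_both_environments > min(n_gut_detected, n_oral_detected):
        raise ValueError(
            "violated identity: n_both_environments <= min(n_gut_detected, n_oral_detected)"
        )
    if n_within_individual_shared > n_both_environments:
        raise ValueError(
            "violated identity: n_within_individual_shared <= n_both_environments"
        )
    if n_oral_dominant + n_gut_dominant + n_tied != n_within_individual_shared:
        raise ValueError(
            "violated identity: n_oral_dominant + n_gut_dominant + n_tied "
            "= n_within_individual_shared"
        )
    if n_child_only + n_adult_only + n_both_ages != n_within_individual_shared:
        raise ValueError(
            "violated identity: n_child_only + n_adult_only + n_both_ages "
            "= n_within_individual_shared"
        )
    if n_individuals_with_shared > n_individuals_total:
        raise ValueError(
            "violated identity: n_individuals_with_shared <= n_individuals_total"
        )
    total = n_gut_detected + n_oral_detected - n_both_environments
    if total <= 0:
        raise ValueError("no ASVs detected: total_asvs must be positive")
    s = CountSummary(**counts)
    s.total_asvs = total
    s.n_gut_exclusive = n_gut_detected - n_both_environments
    s.n_oral_exclusive = n_oral_detected - n_both_environments
    s.pct_shared = round(100.0 * n_within_individual_shared / total, 1)
    s.pct_persistent = round(100.0 * n_both_ages / total, 1)
    if n_within_individual_shared:
        s.pct_oral_dominant = int(round(100.0 * n_oral_dominant / n_within_individual_shared))
        s.pct_gut_dominant = int(round(100.0 * n_gut_dominant / n_within_individual_shared))
        s.pct_both_ages_of_shared = int(round(100.0 * n_both_ages / n_within_individual_shared))
    if n_individuals_total:
        s.pct_individuals_with_shared = int(
            round(100.0 * n_individuals_with_shared / n_individuals_total)
        )
    return s


# ---------------------------------------------------------------------------
# Full per-ASV report
# ---------------------------------------------------------------------------

@dataclass
class SharedAsvReport:
    """Per-ASV record for the within-individual shared set plus the CountSummary."""

    records: pd.DataFrame  # index: feature_id
    summary: CountSummary

    def write_tsv(self, path: str | Path) -> None:
        df = self.records.copy()
        df.index.name = "feature-id"
        df.to_csv(path, sep="\t")


def build_report(counts: FeatureTable, metadata: SampleMetadata,
                 taxonomy: TaxonomyTable | None = None, min_count: int = 1,
                 tie_tol: float = 1e-12, detected_only: bool = False,
                 percent: FeatureTable | None = None) -> SharedAsvReport:
    """Run the full shared-ASV accounting on a cohort.

    ``counts`` may be a counts-state table (normalized internally) or, when
    ``percent`` is supplied, presence is taken from ``counts`` and abundance
    directionality from ``percent``.
    """
    from .feature_table import presence_matrix, to_relative_abundance

    if percent is None:
        if counts.state == "counts":
            percent = to_relative_abundance(counts)
        elif counts.state == "percent":
            percent = counts
        else:
            raise StateError("build_report requires a counts or percent table")
    pres = presence_matrix(counts, min_count=min_count)

    gut_set, oral_set, both_env = habitat_sets(pres, metadata)
    co_map = within_individual_shared(pres, metadata)
    shared = set(co_map)
    direction = classify_directionality(percent, metadata, shared,
                                        tie_tol=tie_tol, detected_only=detected_only)
    ages = partition_by_age(pres, metadata, shared)
    n_with, n_total, _ = sharing_prevalence(co_map, metadata)

    rows = []
    for fid in sorted(shared):
        rows.append({
            "genus": taxonomy.rank_label(fid, "genus") if taxonomy else "unclassified",
            "phylum": taxonomy.rank_label(fid, "phylum") if taxonomy else "unclassified",
            "directionality": direction[fid],
            "age_partition": ages[fid],
            "n_co_detected_individuals": len(co_map[fid]),
            "co_detected_individuals": ",".join(sorted(co_map[fid])),
        })
    records = pd.DataFrame(rows, index=sorted(shared)) if rows else pd.DataFrame(
        columns=["genus", "phylum", "directionality", "age_partition",
                 "n_co_detected_individuals", "co_detected_individuals"])

    ndir = {d: sum(1 for v in direction.values() if v == d) for d in DIRECTIONS}
    nage = {a: sum(1 for v in ages.values() if v == a) for a in AGE_PARTITIONS}
    summary = summarize_counts(
        n_gut_detected=len(gut_set), n_oral_detected=len(oral_set),
        n_both_environments=len(both_env), n_within_individual_shared=len(shared),
        n_oral_dominant=ndir["oral_dominant"], n_gut_dominant=ndir["gut_dominant"],
        n_tied=ndir["tied"], n_child_only=nage["child_only"],
        n_adult_only=nage["adult_only"], n_both_ages=nage["both"],
        n_individuals_total=n_total, n_individuals_with_shared=n_with,
    )
    return SharedAsvReport(records=records, summary=summary)
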