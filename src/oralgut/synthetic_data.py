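"""Synthetic paired oral/gut cohorts with planted ground truth.

The generator emulates the structure of a two-habitat, two-age-group 16S
cohort: habitat-specific ASV pools with log-normal rank-abundance curves,
individual-level occupancy and abundance noise, and a planted set of
cross-habitat shared ASVs whose oral and gut abundances are linked by a
transfer factor.  Read counts are drawn multinomially at a negative-binomial
sequencing depth, so rare taxa genuinely drop out.  The planted truth
(shared IDs, directionality, age partitions, pool memberships, expected
compositions) is returned alongside the data so recovery can be scored.

Guarantees by construction (before sequencing noise):

* habitat pools are strictly habitat-exclusive; only planted shared ASVs
  occur in both habitats;
* a shared ASV is carried by an individual in *both* of their samples, with
  the same individual-level noise factor in both habitats, so the planted
  abundance directionality holds exactly in the expected compositions;
* age-partition labels are exact: child-only ASVs are carried only by
  children, and "both" ASVs get at least one child and one adult carrier;
* every individual carries at least one age-compatible shared ASV (when any
  exists), so sharing prevalence is 100% at infinite depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, SampleMetadata, TaxonomyTable

# The 18 genera reported for persistently shared oral-gut ASVs, with phyla.
SHARED_GENUS_PHYLUM = [
    ("Actinomyces", "Actinomycetota"), ("Rothia", "Actinomycetota"),
    ("Bacteroides", "Bacteroidota"), ("Porphyromonas", "Bacteroidota"),
    ("Prevotella", "Bacteroidota"), ("Alistipes", "Bacteroidota"),
    ("Fusobacterium", "Fusobacteriota"), ("Neisseria", "Pseudomonadota"),
    ("Haemophilus", "Pseudomonadota"), ("Akkermansia", "Verrucomicrobiota"),
    ("Solobacterium", "Bacillota"), ("Granulicatella", "Bacillota"),
    ("Streptococcus", "Bacillota"), ("Gemella", "Bacillota"),
    ("Mogibacterium", "Bacillota"), ("Dialister", "Bacillota"),
    ("Veillonella", "Bacillota"), ("Christensenellaceae R-7 group", "Bacillota"),
]

_GUT_PHYLA = (("Bacillota", 0.45), ("Bacteroidota", 0.35),
              ("Actinomycetota", 0.10), ("Pseudomonadota", 0.10))
_ORAL_PHYLA = (("Bacteroidota", 0.35), ("Pseudomonadota", 0.30),
               ("Bacillota", 0.25), ("Fusobacteriota", 0.10))


@dataclass
class CohortSpec:
    """Parameters of a simulated paired cohort.

    ``age_exclusive_fractions`` is the (child_only, adult_only, both) mixture
    over shared ASVs.  ``transfer_factor`` is the expected gut/oral abundance
    ratio of an oral-dominant shared ASV (its reciprocal for gut-dominant).
    ``read_depth=None`` disables sequencing noise: the expected percentage
    compositions are emitted directly as a percent-state table.
    """

    n_children: int = 39
    n_adults: int = 97
    n_gut_pool: int = 300
    n_oral_pool: int = 200
    n_shared: int = 20
    oral_dominant_fraction: float = 0.62
    transfer_factor: float = 0.1
    age_exclusive_fractions: tuple[float, float, float] = (0.25, 0.33, 0.42)
    read_depth: float | None = 50_000
    depth_dispersion: float = 0.3
    rank_abundance_sigma: float = 1.5
    individual_sigma: float = 0.7
    occupancy: float = 0.3
    carrier_prob: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_children + self.n_adults < 1:
            raise ValueError("cohort must contain at least one individual")
        if self.n_gut_pool < 1 or self.n_oral_pool < 1:
            raise ValueError("habitat pools must be non-empty")
        if self.n_shared < 0:
            raise ValueError("n_shared must be >= 0")
        if not 0 <= self.oral_dominant_fraction <= 1:
            raise ValueError("oral_dominant_fraction must lie in [0, 1]")
        if not 0 < self.transfer_factor < 1:
            raise ValueError("transfer_factor must lie in (0, 1)")
        fr = self.age_exclusive_fractions
        if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("age_exclusive_fractions must be >= 0 and sum to 1")
        if self.n_shared > 0:
            if fr[0] > 0 and self.n_children == 0:
                raise ValueError("child-only shared ASVs require children in the cohort")
            if fr[1] > 0 and self.n_adults == 0:
                raise ValueError("adult-only shared ASVs require adults in the cohort")
            if fr[2] > 0 and (self.n_children == 0 or self.n_adults == 0):
                raise ValueError("'both'-age shared ASVs require both age groups")
        if self.read_depth is not None and self.read_depth <= 0:
            raise ValueError("read_depth must be positive (or None to disable sampling)")


@dataclass
class CohortTruth:
    """Planted ground truth for a generated cohort."""

    shared_asv_ids: list[str]
    directionality: dict[str, str]  # feature_id -> oral_dominant | gut_dominant
    age_partition: dict[str, str]   # feature_id -> child_only | adult_only | both
    carriers: dict[str, list[str]]  # feature_id -> individual_ids
    gut_pool_ids: list[str]
    oral_pool_ids: list[str]
    expected_percent: pd.DataFrame | None = None  # features x samples

    @property
    def oral_dominant_fraction(self) -> float:
        if not self.shared_asv_ids:
            return float("nan")
        n_oral = sum(1 for v in self.directionality.values() if v == "oral_dominant")
        return n_oral / len(self.shared_asv_ids)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "shared_asv_ids": self.shared_asv_ids,
            "directionality": self.directionality,
            "age_partition": self.age_partition,
            "carriers": self.carriers,
            "gut_pool_ids": self.gut_pool_ids,
            "oral_pool_ids": self.oral_pool_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def paper_shaped_spec(read_depth: float | None = 50_000, seed: int = 0) -> CohortSpec:
    """The documented default cohort: 39 children + 97 adults, 61 planted
    shared ASVs with a 38/61 oral-dominant split and a (15, 20, 26)/61 age
    mixture; pools sized so expected detected totals are ~2.4k gut and ~1.4k
    oral ASVs."""
    return CohortSpec(
        n_children=39, n_adults=97,
        n_gut_pool=2363, n_oral_pool=1377, n_shared=61,
        oral_dominant_fraction=38 / 61,
        age_exclusive_fractions=(15 / 61, 20 / 61, 26 / 61),
        transfer_factor=0.1, read_depth=read_depth,
        depth_dispersion=0.3, rank_abundance_sigma=1.5,
        individual_sigma=0.7, occupancy=0.3, carrier_prob=0.3, seed=seed,
    )


def _partition_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    a = int(round(n * fractions[0]))
    b = int(round(n * fractions[1]))
    a, b = min(a, n), min(b, n - min(a, n))
    return a, b, n - a - b


def generate_cohort(spec: CohortSpec
                    ) -> tuple[FeatureTable, SampleMetadata, TaxonomyTable, CohortTruth]:
    """Simulate a paired cohort; same spec (incl. seed) gives identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # --- individuals and samples -----------------------------------------
    children = [f"C{i + 1:03d}" for i in range(spec.n_children)]
    adults = [f"A{i + 1:03d}" for i in range(spec.n_adults)]
    individuals = children + adults
    is_child = np.array([True] * spec.n_children + [False] * spec.n_adults)

    ages = np.concatenate([
        rng.integers(5, 11, size=spec.n_children),
        rng.integers(20, 62, size=spec.n_adults),
    ]).astype(float)
    sex = np.concatenate([
        rng.choice(["male", "female"], size=spec.n_children, p=[0.564, 0.436]),
        rng.choice(["male", "female"], size=spec.n_adults, p=[0.32, 0.68]),
    ])
    bmi = np.concatenate([
        rng.choice(["missing", "normal", "overweight", "obese"],
                   size=spec.n_children, p=[0.205, 0.612, 0.080, 0.103]),
        rng.choice(["underweight", "normal", "overweight"],
                   size=spec.n_adults, p=[0.04, 0.68, 0.28]),
    ])

    rows = []
    for i, ind in enumerate(individuals):
        for habitat in ("gut", "oral"):
            rows.append({
                "sample_id": f"{ind}.{habitat}", "individual_id": ind,
                "habitat": habitat, "age_years": ages[i],
                "age_group": "child" if is_child[i] else "adult",
                "adult_age_bin": "n/a" if is_child[i] else
                                 ("le44" if ages[i] <= 44 else "ge45"),
                "sex": sex[i], "bmi_category": bmi[i],
            })
    meta_df = pd.DataFrame(rows).set_index("sample_id")
    metadata = SampleMetadata(meta_df)
    gut_samples = [f"{ind}.gut" for ind in individuals]
    oral_samples = [f"{ind}.oral" for ind in individuals]

    # --- feature pools -----------------------------------------------------
    gut_ids = [f"gutASV{i + 1:05d}" for i in range(spec.n_gut_pool)]
    oral_ids = [f"oralASV{i + 1:05d}" for i in range(spec.n_oral_pool)]
    shared_ids = [f"sharedASV{i + 1:03d}" for i in range(spec.n_shared)]
    feature_ids = gut_ids + oral_ids + shared_ids
    n_ind = len(individuals)

    sigma = spec.rank_abundance_sigma
    gut_base = rng.lognormal(0.0, sigma, size=spec.n_gut_pool)
    oral_base = rng.lognormal(0.0, sigma, size=spec.n_oral_pool)
    shared_base = rng.lognormal(0.0, sigma, size=spec.n_shared)

    # --- planted labels ----------------------------------------------------
    n_oral_dom = int(round(spec.n_shared * spec.oral_dominant_fraction))
    direction = np.array(["oral_dominant"] * n_oral_dom +
                         ["gut_dominant"] * (spec.n_shared - n_oral_dom))
    rng.shuffle(direction)
    n_child, n_adult, n_both = _partition_counts(spec.n_shared,
                                                 spec.age_exclusive_fractions)
    ages_lab = np.array(["child_only"] * n_child + ["adult_only"] * n_adult +
                        ["both"] * n_both)
    rng.shuffle(ages_lab)

    # --- occupancy and carriers -------------------------------------------
    occ_gut = rng.random((spec.n_gut_pool, n_ind)) < spec.occupancy
    occ_oral = rng.random((spec.n_oral_pool, n_ind)) < spec.occupancy

    child_idx = np.flatnonzero(is_child)
    adult_idx = np.flatnonzero(~is_child)
    carriers = np.zeros((spec.n_shared, n_ind), dtype=bool)
    for k in range(spec.n_shared):
        if ages_lab[k] == "child_only":
            allowed = child_idx
        elif ages_lab[k] == "adult_only":
            allowed = adult_idx
        else:
            allowed = np.arange(n_ind)
        carriers[k, allowed] = rng.random(len(allowed)) < spec.carrier_prob
        if ages_lab[k] == "both":
            # a "both" label must be realized in each age group
            if not carriers[k, child_idx].any():
                carriers[k, rng.choice(child_idx)] = True
            if not carriers[k, adult_idx].any():
                carriers[k, rng.choice(adult_idx)] = True
        elif not carriers[k, allowed].any():
            carriers[k, rng.choice(allowed)] = True
    # every individual carries >=1 age-compatible shared ASV
    if spec.n_shared:
        for i in range(n_ind):
            if not carriers[:, i].any():
                ok = np.flatnonzero(
                    (ages_lab == "both") |
                    (ages_lab == ("child_only" if is_child[i] else "adult_only"))
                )
                if len(ok):
                    carriers[rng.choice(ok), i] = True

    # --- expected compositions ---------------------------------------------
    ind_sig = spec.individual_sigma
    noise_gut = rng.lognormal(0.0, ind_sig, size=(spec.n_gut_pool, n_ind))
    noise_oral = rng.lognormal(0.0, ind_sig, size=(spec.n_oral_pool, n_ind))
    # one noise factor per (shared ASV, individual), reused in both habitats,
    # so the planted directionality survives per-sample normalization
    noise_shared = rng.lognormal(0.0, ind_sig, size=(spec.n_shared, n_ind))

    tf = spec.transfer_factor
    gut_factor = np.where(direction == "gut_dominant", 1.0, tf)[:, None]
    oral_factor = np.where(direction == "oral_dominant", 1.0, tf)[:, None]
    shared_raw = shared_base[:, None] * noise_shared * carriers

    raw_gut = np.vstack([
        gut_base[:, None] * noise_gut * occ_gut,
        np.zeros((spec.n_oral_pool, n_ind)),
        shared_raw * gut_factor,
    ])
    raw_oral = np.vstack([
        np.zeros((spec.n_gut_pool, n_ind)),
        oral_base[:, None] * noise_oral * occ_oral,
        shared_raw * oral_factor,
    ])

    def _to_percent(raw: np.ndarray) -> np.ndarray:
        tot = raw.sum(axis=0)
        tot[tot == 0] = 1.0
        return 100.0 * raw / tot

    pct_gut, pct_oral = _to_percent(raw_gut), _to_percent(raw_oral)
    sample_ids = gut_samples + oral_samples
    expected = np.hstack([pct_gut, pct_oral])
    expected_df = pd.DataFrame(expected, index=feature_ids, columns=sample_ids)

    # --- sequencing --------------------------------------------------------
    if spec.read_depth is None:
        table = FeatureTable(feature_ids, sample_ids, expected, state="percent")
    else:
        k = 1.0 / spec.depth_dispersion
        depths = rng.poisson(rng.gamma(k, spec.read_depth * spec.depth_dispersion,
                                       size=len(sample_ids)))
        counts = np.zeros((len(feature_ids), len(sample_ids)))
        for j in range(len(sample_ids)):
            p = expected[:, j] / 100.0
            s = p.sum()
            if s > 0 and depths[j] > 0:
                counts[:, j] = rng.multinomial(int(depths[j]), p / s)
        table = FeatureTable(feature_ids, sample_ids, counts, state="counts")

    # --- taxonomy -----------------------------------------------------------
    assignments: dict[str, dict[str, str]] = {}
    for pool_ids, phyla, stem in ((gut_ids, _GUT_PHYLA, "GutGenus"),
                                  (oral_ids, _ORAL_PHYLA, "OralGenus")):
        names = [p for p, _ in phyla]
        weights = [w for _, w in phyla]
        phy = rng.choice(names, size=len(pool_ids), p=weights)
        for i, fid in enumerate(pool_ids):
            assignments[fid] = {
                "phylum": str(phy[i]), "class": "unclassified",
                "order": "unclassified", "family": "unclassified",
                "genus": f"{stem}{(i % max(1, len(pool_ids) // 5)) + 1:04d}",
            }
    for i, fid in enumerate(shared_ids):
        genus, phylum = SHARED_GENUS_PHYLUM[i % len(SHARED_GENUS_PHYLUM)]
        assignments[fid] = {
            "phylum": phylum, "class": "unclassified", "order": "unclassified",
            "family": "unclassified", "genus": genus,
        }
    taxonomy = TaxonomyTable(assignments)

    truth = CohortTruth(
        shared_asv_ids=list(shared_ids),
        directionality={fid: str(direction[k]) for k, fid in enumerate(shared_ids)},
        age_partition={fid: str(ages_lab[k]) for k, fid in enumerate(shared_ids)},
        carriers={fid: [individuals[i] for i in np.flatnonzero(carriers[k])]
                  for k, fid in enumerate(shared_ids)},
        gut_pool_ids=list(gut_ids), oral_pool_ids=list(oral_ids),
        expected_percent=expected_df,
    )
    return table, metadata, taxonomy, truth
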