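"""Core domain containers shared by every pipeline stage.

The analysis operates on four kinds of objects: OTU-by-sample count tables
with plot metadata (one per field experiment / location), rooted phylogenies
with branch lengths in expected substitutions per site, per-OTU log2
treatment/control response ratios with derived direction labels, and
taxonomy tables at the five ranks phylum..genus.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

RANKS = ("phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

CONTROL = "control"
TREATMENT = "treatment"


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class CountTable:
    """OTU x sample non-negative integer counts for one location.

    ``counts`` is a DataFrame indexed by OTU id with sample-id columns;
    ``sample_meta`` is indexed by sample id with ``location`` and ``arm``
    columns, ``arm`` in {control, treatment}.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.sample_meta = self.sample_meta.copy()
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate OTU ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count table")
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.number)):
            raise ValidationError("non-numeric cells in count table")
        if vals.size:
            if np.any(vals < 0):
                i, j = np.argwhere(vals < 0)[0]
                raise ValidationError(
                    f"negative count {vals[i, j]} at OTU "
                    f"{self.counts.index[i]!r}, sample {self.counts.columns[j]!r}"
                )
            if np.any(vals != np.floor(vals)):
                i, j = np.argwhere(vals != np.floor(vals))[0]
                raise ValidationError(
                    f"non-integer count {vals[i, j]} at OTU "
                    f"{self.counts.index[i]!r}, sample {self.counts.columns[j]!r}"
                )
        self.counts = self.counts.astype(np.int64)
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        for col in ("location", "arm"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks column {col!r}")
        bad = set(self.sample_meta["arm"]) - {CONTROL, TREATMENT}
        if bad:
            raise ValidationError(f"unknown arm labels: {sorted(bad)}")
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def location(self) -> str:
        locs = self.sample_meta["location"].unique()
        return str(locs[0]) if len(locs) == 1 else "multiple"

    def arms(self) -> pd.Series:
        """Per-sample arm labels aligned to the count-table columns."""
        return self.sample_meta["arm"]

    def samples_in_arm(self, arm: str) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["arm"] == arm])

    def subset_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(otu_ids)], self.sample_meta)


def directions_from_log2fc(log2fc: pd.Series) -> pd.Series:
    """Direction label per OTU: '+' if log2fc>0, '-' if <0, '0' if exactly 0."""
    return pd.Series(
        np.where(log2fc > 0, "+", np.where(log2fc < 0, "-", "0")),
        index=log2fc.index,
        name="direction",
    )


@dataclass
class ResponseSet:
    """Per-OTU log2 treatment/control response ratios for one location.

    ``location`` is the experiment label, or ``"merged"`` for the
    cross-location average. Direction is derived, never stored stale.
    """

    log2fc: pd.Series
    location: str = "unknown"

    def __post_init__(self) -> None:
        self.log2fc = pd.Series(self.log2fc, dtype=float)
        if self.log2fc.index.has_duplicates:
            raise ValidationError("duplicate OTU ids in response set")
        if self.log2fc.isna().any():
            missing = list(self.log2fc.index[self.log2fc.isna()])
            raise ValidationError(f"missing log2fc for OTUs: {missing[:5]}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def direction(self) -> pd.Series:
        return directions_from_log2fc(self.log2fc)

    def subset(self, otu_ids: Sequence[str]) -> "ResponseSet":
        return ResponseSet(self.log2fc.loc[list(otu_ids)], self.location)

    def flipped(self) -> "ResponseSet":
        return ResponseSet(-self.log2fc, self.location)


@dataclass
class TaxonomyTable:
    """Rank assignments per OTU (phylum..genus; 'unassigned' allowed)."""

    assignments: pd.DataFrame

    def __post_init__(self) -> None:
        self.assignments = self.assignments.copy()
        for rank in RANKS:
            if rank not in self.assignments.columns:
                raise ValidationError(f"taxonomy table lacks rank column {rank!r}")
        self.assignments = self.assignments[list(RANKS)].fillna(UNASSIGNED)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.assignments.index)

    def group_of(self, otu_id: str, rank: str) -> str:
        return str(self.assignments.at[otu_id, rank])


@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal, labelled rows."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("nonzero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class FilterReport:
    """Record of which occupancy rule fired during OTU filtering."""

    n_input_otus: int
    n_after_primary: int
    rule_applied: str  # "primary" | "relaxed"
    threshold_used: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.R2 <= 1.0 + 1e-12):
            raise ValidationError(f"R2 out of range: {self.R2}")


@dataclass
class ConsensusClade:
    """One consensus clade (or singleton tip) with its genetic depth."""

    node: str
    direction: str  # '+' or '-'
    genetic_depth: float
    n_tips: int
    is_singleton: bool

    def __post_init__(self) -> None:
        if self.genetic_depth < 0:
            raise ValidationError("negative genetic depth")
        if self.is_singleton != (self.n_tips == 1):
            raise ValidationError("is_singleton inconsistent with n_tips")


@dataclass
class ConsenTraitResult:
    """Consensus clades, tau_D per direction, and the permutation null."""

    clades: list[ConsensusClade]
    tau_pos: float | None
    tau_neg: float | None
    null_tau_pos: list[float] = field(default_factory=list)
    null_tau_neg: list[float] = field(default_factory=list)
    p_pos: float | None = None
    p_neg: float | None = None
    n_randomizations: int = 0

    def tau(self, direction: str) -> float | None:
        return self.tau_pos if direction == "+" else self.tau_neg

    def mean_tau(self) -> float:
        """Average of the positive- and negative-response tau_D."""
        if self.tau_pos is None or self.tau_neg is None:
            raise ValidationError("tau_D undefined for one direction")
        return 0.5 * (self.tau_pos + self.tau_neg)


@dataclass
class GroupTest:
    rank: str
    group_name: str
    n_pos: int
    n_neg: int
    p_value: float
    direction_call: str  # '+', '-', or 'none'


@dataclass
class ContextDependence:
    """Depth lost (or gained) when per-location responses are merged."""

    mean_individual_tau: float
    merged_tau: float

    @property
    def delta(self) -> float:
        return self.mean_individual_tau - self.merged_tau


@dataclass
class PlantedClade:
    node: str
    direction: str
    genetic_depth: float
    n_tips: int
    tip_ids: list[str]


@dataclass
class TruthRecord:
    """Ground truth planted by the simulator, for recovery testing."""

    planted_clades: list[PlantedClade]
    fidelity: float
    target_depth: float
    true_log2fc: pd.Series
    occupancy: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.5 < self.fidelity <= 1.0):
            raise ValidationError("fidelity must lie in (0.5, 1.0]")

    @property
    def mean_planted_depth(self) -> float:
        return float(np.mean([c.genetic_depth for c in self.planted_clades]))
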