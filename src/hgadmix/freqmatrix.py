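"""Population x haplogroup frequency matrices from per-individual records.

The input is a table of individuals (sample id, population id, observed
haplogroup label).  From it we derive

1. a *candidate basis*: every observed label truncated to a maximal
   phylogenetic depth (default 3) and deduplicated;
2. a *prevalence filter*: candidates kept only when strictly more than a
   fraction (default 0.0005) of the whole database is assigned to them;
3. a frequency matrix: one row per population, one column per basis label,
   cell = fraction of that population's individuals assigned to the label.

Frequencies are by default normalized over the *classified* individuals of a
population, so usable rows sum to one; normalizing over all individuals
(``total``) is available for sensitivity analysis.  Populations with no
classifiable individual are flagged unusable rather than dropped silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .nomenclature import (
    UNASSIGNED,
    HgBasis,
    HgLabel,
    MalformedLabelError,
    assign_to_basis,
    tokenize_label,
    truncate_label,
)

__all__ = [
    "IndividualTable",
    "FrequencyMatrix",
    "read_individuals",
    "candidate_basis",
    "prevalence_filter",
    "build_frequency_matrix",
]

_LABEL_COLUMN_ALIASES = ("haplogroup", "haplogroup_label", "label", "hg")


@dataclass
class IndividualTable:
    """Per-individual records with parsed haplogroup labels.

    ``data`` holds columns ``sample_id``, ``population_id``, ``raw_label``
    and ``label`` (an :class:`~hgadmix.nomenclature.HgLabel`).
    """

    data: pd.DataFrame
    n_rejected: int = 0
    rejected: list = field(default_factory=list)

    def __post_init__(self):
        dup = self.data["sample_id"].duplicated()
        if dup.any():
            raise ValueError(
                "duplicate sample_id values: "
                + ", ".join(map(str, self.data.loc[dup, "sample_id"].head(5)))
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.data["population_id"]))

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]


def read_individuals(
    source,
    sep: Optional[str] = None,
) -> IndividualTable:
    """Read a delimited per-individual table into an :class:`IndividualTable`.

    The header must contain ``sample_id``, ``population_id`` and a haplogroup
    column (``haplogroup``, ``haplogroup_label``, ``label`` or ``hg``).  Rows
    whose label does not parse are skipped with a warning and counted in
    ``n_rejected``.

    ``sep=None`` lets pandas sniff the delimiter (tabs and commas both work).
    """
    if isinstance(source, str):
        df = pd.read_csv(source, sep=sep, engine="python", dtype=str)
    else:
        df = pd.read_csv(source, sep=sep, engine="python", dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("sample_id", "population_id"):
        if required not in cols:
            raise ValueError(f"missing required column {required!r} in header")
    label_col = next((cols[a] for a in _LABEL_COLUMN_ALIASES if a in cols), None)
    if label_col is None:
        raise ValueError(
            "missing haplogroup column (expected one of "
            + ", ".join(_LABEL_COLUMN_ALIASES)
            + ")"
        )
    records = []
    rejected = []
    for row in df.itertuples(index=False):
        sample = getattr(row, cols["sample_id"])
        popid = getattr(row, cols["population_id"])
        raw = getattr(row, label_col)
        try:
            label = tokenize_label(raw if isinstance(raw, str) else "")
        except MalformedLabelError as exc:
            rejected.append((sample, raw, str(exc)))
            continue
        records.append((sample, popid, raw, label))
    if rejected:
        warnings.warn(
            f"skipped {len(rejected)} rows with malformed haplogroup labels "
            f"(first: {rejected[0][1]!r})",
            stacklevel=2,
        )
    data = pd.DataFrame(
        records, columns=["sample_id", "population_id", "raw_label", "label"]
    )
    return IndividualTable(data=data, n_rejected=len(rejected), rejected=rejected)


def candidate_basis(table: IndividualTable, max_depth: int = 3) -> HgBasis:
    """All observed labels truncated to ``max_depth``, deduplicated, sorted."""
    if len(table) == 0:
        raise ValueError("individual table is empty")
    truncated = (truncate_label(lab, max_depth) for lab in table.labels)
    return HgBasis.sorted_from(truncated)


def _assign_series(
    labels: pd.Series, basis: HgBasis, mode: str
) -> pd.Series:
    """Vectorized assignment: map each distinct label once."""
    uniq = {}
    for lab in labels:
        if lab.tokens not in uniq:
            uniq[lab.tokens] = assign_to_basis(lab, basis, mode)
    return labels.map(lambda lab: uniq[lab.tokens])


def prevalence_filter(
    table: IndividualTable,
    basis: HgBasis,
    threshold: float = 0.0005,
    mode: str = "cumulating",
) -> HgBasis:
    """Keep basis labels whose database-wide assigned frequency exceeds
    ``threshold`` (strictly).

    Counts are pooled over the whole table, under the same assignment
    ``mode`` that will be used downstream, and divided by the total number
    of individuals (classified or not).
    """
    if len(table) == 0:
        raise ValueError("individual table is empty")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    assigned = _assign_series(table.labels, basis, mode)
    counts: dict[tuple[str, ...], int] = {}
    for a in assigned:
        if a is not UNASSIGNED:
            counts[a.tokens] = counts.get(a.tokens, 0) + 1
    total = len(table)
    kept = [
        lab for lab in basis.labels if counts.get(lab.tokens, 0) / total > threshold
    ]
    return HgBasis(kept)


@dataclass
class FrequencyMatrix:
    """Populations x basis-haplogroups matrix of frequencies.

    ``values`` is a DataFrame indexed by population id with one column per
    basis label, in basis order.  ``classified_counts`` gives, per
    population, how many individuals were assigned to some basis label; rows
    with zero classified individuals are unusable and left all-zero.
    """

    values: pd.DataFrame
    basis: HgBasis
    classified_counts: pd.Series
    total_counts: pd.Series
    normalization: str = "classified"

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    @property
    def usable(self) -> pd.Series:
        """Boolean mask of populations with at least one classified member."""
        return self.classified_counts > 0

    @property
    def unusable_populations(self) -> list[str]:
        return list(self.classified_counts.index[self.classified_counts == 0])

    def usable_values(self) -> pd.DataFrame:
        return self.values.loc[self.usable]

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="population_id")

    @classmethod
    def from_csv(cls, path) -> "FrequencyMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        basis = HgBasis(df.columns)
        counts = (df.sum(axis=1) > 0).astype(int)
        return cls(
            values=df,
            basis=basis,
            classified_counts=counts,
            total_counts=counts.copy(),
        )


def build_frequency_matrix(
    table: IndividualTable,
    basis: HgBasis,
    mode: str = "cumulating",
    normalization: str = "classified",
    populations: Optional[list[str]] = None,
) -> FrequencyMatrix:
    """Classify every individual against ``basis`` and tabulate frequencies.

    Parameters
    ----------
    mode
        ``cumulating`` (nearest basis ancestor) or ``cutting`` (exact match).
    normalization
        ``classified`` divides by the classified count of the population
        (rows of usable populations sum to 1); ``total`` divides by the
        population's full size.
    populations
        Restrict/order the rows; every requested population must occur in
        the table.
    """
    if len(basis) == 0:
        raise ValueError("basis is empty")
    if normalization not in ("classified", "total"):
        raise ValueError(f"unknown normalization: {normalization!r}")
    present = table.populations
    if populations is None:
        populations = present
    else:
        missing = sorted(set(populations) - set(present))
        if missing:
            raise ValueError(
                "populations absent from table: " + ", ".join(missing)
            )
    assigned = _assign_series(table.labels, basis, mode)
    df = table.data[["population_id"]].copy()
    df["assigned"] = [
        a.raw if a is not UNASSIGNED else None for a in assigned
    ]
    raw_cols = basis.raw_labels
    count_mat = pd.DataFrame(
        0, index=pd.Index(populations, name="population_id"), columns=raw_cols,
        dtype=float,
    )
    grouped = (
        df.dropna(subset=["assigned"])
        .groupby(["population_id", "assigned"], sort=False)
        .size()
    )
    for (pop, lab), n in grouped.items():
        if pop in count_mat.index:
            count_mat.at[pop, lab] = n
    totals = df.groupby("population_id", sort=False).size().reindex(populations).fillna(0)
    classified = count_mat.sum(axis=1)
    if (classified == 0).any():
        warnings.warn(
            "populations with no classifiable individuals: "
            + ", ".join(map(str, classified.index[classified == 0])),
            stacklevel=2,
        )
    denom = classified if normalization == "classified" else totals
    values = count_mat.div(denom.replace(0, np.nan), axis=0).fillna(0.0)
    return FrequencyMatrix(
        values=values,
        basis=basis,
        classified_counts=classified.astype(int),
        total_counts=totals.astype(int),
        normalization=normalization,
    )
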