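"""Core data containers for methylation-array analysis.

The pipeline moves between two value scales: beta values (methylation
proportions in [0, 1], the intuitive scale used for effect sizes) and
M-values (log2 odds, the variance-stabilised scale used for statistical
testing).  Containers here are thin, validated wrappers around pandas
DataFrames so that every stage can rely on the same invariants: unique
identifiers, finite values, closed annotation vocabularies and consistent
coordinate conventions (BED intervals are 0-based half-open; CpG positions
are 1-based points).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


#: Promoter-proximal feature groups used for the promoter-level calls.
PROMOTER_FEATURES: tuple[str, ...] = ("TSS1500", "TSS200", "5'UTR", "1stExon")

#: Closed vocabulary of genomic feature groups (Illumina UCSC_RefGene style).
FEATURE_GROUPS: tuple[str, ...] = PROMOTER_FEATURES + ("Body", "3'UTR", "IGR")

#: Closed vocabulary of CpG-island relations.
CGI_RELATIONS: tuple[str, ...] = (
    "Island",
    "N_Shore",
    "S_Shore",
    "N_Shelf",
    "S_Shelf",
    "OpenSea",
)


def _check_unique(values: pd.Index, what: str) -> None:
    if values.has_duplicates:
        dup = values[values.duplicated()].unique()[:5].tolist()
        raise ValidationError(f"duplicate {what}: {dup}")


class _MatrixBase:
    """Feature x sample numeric matrix with unique axis labels."""

    _value_name = "value"

    def __init__(self, frame: pd.DataFrame):
        frame = frame.astype(float)
        _check_unique(frame.index, f"{self._row_name} ids")
        _check_unique(frame.columns, "sample ids")
        self._validate_values(frame)
        self.frame = frame

    _row_name = "feature"

    def _validate_values(self, frame: pd.DataFrame) -> None:
        if not np.isfinite(frame.to_numpy()).all():
            bad = frame.index[~np.isfinite(frame.to_numpy()).all(axis=1)][:5]
            raise ValidationError(
                f"non-finite {self._value_name} for {self._row_name}s {bad.tolist()}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def subset_samples(self, sample_ids: Sequence[str]):
        return type(self)(self.frame.loc[:, list(sample_ids)])


class BetaMatrix(_MatrixBase):
    """CpG x sample methylation proportions (beta values) in [0, 1]."""

    _row_name = "cpg"
    _value_name = "beta"

    def _validate_values(self, frame: pd.DataFrame) -> None:
        super()._validate_values(frame)
        arr = frame.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            rows = frame.index[bad.any(axis=1)][:5].tolist()
            raise ValidationError(f"beta values outside [0, 1] at CpGs {rows}")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.frame.index)


class MValueMatrix(_MatrixBase):
    """CpG x sample M-values, M = log2(beta / (1 - beta))."""

    _row_name = "cpg"
    _value_name = "m-value"

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.frame.index)


class ExpressionMatrix(_MatrixBase):
    """Gene x sample log2 normalised expression."""

    _row_name = "gene"
    _value_name = "expression"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)


def beta_to_mvalue(beta: BetaMatrix, epsilon: float = 1e-3) -> MValueMatrix:
    """Logit-transform beta values to M-values.

    Betas are clipped to ``[epsilon, 1 - epsilon]`` first so that boundary
    values (fully un/methylated CpGs) stay finite.  The transform is
    antisymmetric on the clipped scale: M(b) + M(1 - b) = 0.
    """
    if not 0 < epsilon < 0.5:
        raise ValidationError(f"epsilon must be in (0, 0.5), got {epsilon}")
    clipped = np.clip(beta.values, epsilon, 1 - epsilon)
    m = np.log2(clipped / (1 - clipped))
    return MValueMatrix(
        pd.DataFrame(m, index=beta.frame.index, columns=beta.frame.columns)
    )


def mvalue_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse-logit an M-value matrix back to betas."""
    b = 1.0 / (1.0 + np.power(2.0, -m.values))
    return BetaMatrix(pd.DataFrame(b, index=m.frame.index, columns=m.frame.columns))


class CpGAnnotation:
    """Per-CpG genomic annotation (manifest-style).

    One row per CpG: chromosome, 1-based position, zero or more gene
    symbols with positionally aligned feature groups, and a CpG-island
    relation.  Multi-gene CpGs contribute to every annotated gene
    independently.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "pos", "genes", "feature_groups", "cgi_relation"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        _check_unique(frame.index, "cpg ids")
        if (frame["pos"] < 1).any():
            bad = frame.index[frame["pos"] < 1][:5].tolist()
            raise ValidationError(f"positions must be >= 1; offending CpGs {bad}")
        for cpg, genes, feats in zip(frame.index, frame["genes"], frame["feature_groups"]):
            if len(genes) != len(feats):
                raise ValidationError(
                    f"CpG {cpg}: {len(genes)} genes but {len(feats)} feature groups"
                )
            for f in feats:
                if f not in FEATURE_GROUPS:
                    raise ValidationError(f"CpG {cpg}: unknown feature group {f!r}")
        bad_cgi = ~frame["cgi_relation"].isin(CGI_RELATIONS)
        if bad_cgi.any():
            raise ValidationError(
                f"unknown CGI relation for CpGs {frame.index[bad_cgi][:5].tolist()}"
            )
        self.frame = frame

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, cpg_ids: Sequence[str]) -> "CpGAnnotation":
        return CpGAnnotation(self.frame.loc[list(cpg_ids)])

    def gene_map(self) -> pd.DataFrame:
        """Long-format cpg_id/gene/feature_group table (one row per mapping)."""
        rows = []
        for cpg, genes, feats in zip(
            self.frame.index, self.frame["genes"], self.frame["feature_groups"]
        ):
            for g, f in zip(genes, feats):
                rows.append((cpg, g, f))
        return pd.DataFrame(rows, columns=["cpg_id", "gene", "feature_group"])

    def primary_feature(self) -> pd.Series:
        """One feature group per CpG: promoter-most annotated group, IGR if none."""
        order = {f: i for i, f in enumerate(FEATURE_GROUPS)}

        def pick(feats: tuple) -> str:
            return min(feats, key=lambda f: order[f]) if feats else "IGR"

        return self.frame["feature_groups"].map(pick)


class SampleSheet:
    """Sample design table: sample_id, group, condition, patient_id."""

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "group", "condition", "patient_id"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(pd.Index(frame["sample_id"]), "sample ids")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_in(self, label: str, on: str = "group") -> list[str]:
        return list(self.frame.loc[self.frame[on] == label, "sample_id"])

    def check_matches(self, matrix: _MatrixBase) -> None:
        matrix_samples = set(matrix.sample_ids)
        missing = [s for s in self.sample_ids if s not in matrix_samples]
        if missing:
            raise ValidationError(f"sheet samples missing from matrix: {missing}")


@dataclass
class RegionSet:
    """A named collection of genomic intervals (0-based half-open)."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end, name
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            row = self.intervals.loc[bad].iloc[0]
            raise ValidationError(
                f"region set {self.name!r}: start >= end at "
                f"{row['chrom']}:{row['start']}-{row['end']}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def _chrom_index(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Merged, sorted interval arrays for one chromosome."""
        if chrom not in self._index:
            sub = self.intervals.loc[self.intervals["chrom"] == chrom]
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            order = np.argsort(starts, kind="stable")
            starts, ends = starts[order], ends[order]
            m_starts, m_ends = [], []
            for s, e in zip(starts, ends):
                if m_ends and s <= m_ends[-1]:
                    m_ends[-1] = max(m_ends[-1], e)
                else:
                    m_starts.append(s)
                    m_ends.append(e)
            self._index[chrom] = (
                np.asarray(m_starts, dtype=np.int64),
                np.asarray(m_ends, dtype=np.int64),
            )
        return self._index[chrom]

    def contains_points(self, chroms: np.ndarray, pos1: np.ndarray) -> np.ndarray:
        """Membership of 1-based point positions in the interval union.

        A 1-based position p falls in interval [start, end) iff
        start < p <= end, i.e. p - 1 in [start, end).
        """
        result = np.zeros(len(pos1), dtype=bool)
        p0 = np.asarray(pos1, dtype=np.int64) - 1
        for chrom in np.unique(chroms):
            starts, ends = self._chrom_index(str(chrom))
            mask = chroms == chrom
            if starts.size == 0:
                continue
            idx = np.searchsorted(starts, p0[mask], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(mask.sum(), dtype=bool)
            hit[ok] = p0[mask][ok] < ends[idx[ok]]
            result[mask] = hit
        return result


class RegionSetCollection(Mapping):
    """Ordered mapping of set name -> :class:`RegionSet`."""

    def __init__(self, sets: Iterable[RegionSet]):
        self._sets: dict[str, RegionSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValidationError(f"duplicate region set name {s.name!r}")
            self._sets[s.name] = s

    def __getitem__(self, name: str) -> RegionSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)
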