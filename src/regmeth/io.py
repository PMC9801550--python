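"""Readers and writers for the pipeline's plain-text dialects.

Matrices are TSV with an id column followed by one column per sample.
Annotation is a manifest-style TSV (semicolon-separated multi-gene
mappings, positionally aligned feature groups).  Sample sheets are CSV.
Region sets are BED3+ (0-based half-open); gene sets are GMT.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .containers import (
    BetaMatrix,
    CpGAnnotation,
    ExpressionMatrix,
    RegionSet,
    RegionSetCollection,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger("regmeth")

#: to_csv float format shared by every writer, so repeated runs are byte-identical
FLOAT_FORMAT = "%.10g"


def _read_matrix_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    return BetaMatrix(_read_matrix_frame(path))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(_read_matrix_frame(path))


def _parse_multi(value) -> tuple[str, ...]:
    if pd.isna(value) or value == "":
        return ()
    return tuple(str(value).split(";"))


def read_annotation(path: str | Path) -> CpGAnnotation:
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"cpg_id", "chrom", "pos", "gene", "feature_group", "cgi_relation"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"annotation file missing columns: {sorted(missing)}")
    frame = pd.DataFrame(
        {
            "chrom": raw["chrom"].to_numpy(),
            "pos": raw["pos"].astype(int).to_numpy(),
            "genes": raw["gene"].map(_parse_multi).to_numpy(),
            "feature_groups": raw["feature_group"].map(_parse_multi).to_numpy(),
            "cgi_relation": raw["cgi_relation"].to_numpy(),
        },
        index=pd.Index(raw["cpg_id"], name="cpg_id"),
    )
    return CpGAnnotation(frame)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, dtype=str).fillna("")
    return SampleSheet(frame)


def load_dataset(
    beta_path: str | Path,
    annotation_path: str | Path,
    sheet_path: str | Path,
) -> tuple[BetaMatrix, CpGAnnotation, SampleSheet]:
    """Load and cross-reference a beta matrix, annotation and sample sheet.

    CpGs present in the matrix but absent from the annotation are dropped
    (with a logged count); sample columns are reordered to follow the
    sheet.  A sheet sample missing from the matrix is an error.
    """
    beta = read_beta_matrix(beta_path)
    annot = read_annotation(annotation_path)
    sheet = read_sample_sheet(sheet_path)
    sheet.check_matches(beta)

    annotated = beta.frame.index.intersection(annot.frame.index)
    dropped = len(beta.frame) - len(annotated)
    if dropped:
        logger.info("dropping %d CpGs absent from annotation", dropped)
    beta = BetaMatrix(beta.frame.loc[annotated, sheet.sample_ids])
    annot = annot.subset(list(annotated))
    return beta, annot, sheet


def read_region_sets(bed_paths: Sequence[str | Path]) -> RegionSetCollection:
    """Read one named region set per BED file (name = file stem)."""
    sets = []
    for path in bed_paths:
        path = Path(path)
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValidationError(
                        f"{path.name}:{lineno}: BED line has fewer than 3 columns"
                    )
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValidationError(
                        f"{path.name}:{lineno}: malformed coordinates"
                    ) from exc
                if start >= end:
                    raise ValidationError(
                        f"{path.name}:{lineno}: start >= end ({start} >= {end})"
                    )
                name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
                rows.append((chrom, start, end, name))
        intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        sets.append(RegionSet(path.stem, intervals))
        logger.info("region set %s: %d intervals", path.stem, len(intervals))
    return RegionSetCollection(sets)


def read_gene_sets(
    gmt_path: str | Path, min_size: int = 15, max_size: int = 2000
) -> dict[str, set[str]]:
    """Read GMT gene sets, excluding sets outside [min_size, max_size]."""
    gene_sets: dict[str, set[str]] = {}
    n_lines = 0
    with open(gmt_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"GMT line with fewer than 3 fields: {line[:60]}")
            name, members = fields[0], {g for g in fields[2:] if g}
            if not min_size <= len(members) <= max_size:
                logger.info(
                    "excluding gene set %s (size %d outside [%d, %d])",
                    name, len(members), min_size, max_size,
                )
                continue
            gene_sets[name] = members
    if n_lines == 0:
        raise ValidationError(f"empty GMT file: {gmt_path}")
    return gene_sets


def write_matrix(matrix, path: str | Path, id_name: str = "id") -> None:
    frame = matrix.frame.copy()
    frame.index.name = id_name
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_annotation(annot: CpGAnnotation, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "cpg_id": annot.frame.index,
            "chrom": annot.frame["chrom"].to_numpy(),
            "pos": annot.frame["pos"].to_numpy(),
            "gene": [";".join(g) for g in annot.frame["genes"]],
            "feature_group": [";".join(f) for f in annot.frame["feature_groups"]],
            "cgi_relation": annot.frame["cgi_relation"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False)


def write_region_set(region_set: RegionSet, path: str | Path) -> None:
    region_set.intervals.to_csv(path, sep="\t", index=False, header=False)


def write_gene_sets(gene_sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
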