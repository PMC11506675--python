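"""Tabular input/output.

All artifacts are plain TSV with "NA" as the missing-value token.
Annotation files follow the Mercator/MapMan convention of a two-column
``protein_id<TAB>bin name`` table where the bin name may be a
dot-separated path into the ontology; only the coarsest (level-1)
process label is used here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DESIGN_COLUMNS, design_frame, samples_from_frame
from .matrix import AbundanceMatrix

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

#: Label given to proteins absent from the annotation file.
NOT_ASSIGNED = "not assigned"

_FLOAT_FMT = "%.10g"


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path,
    log_scale: bool = False,
) -> AbundanceMatrix:
    """Load a protein x sample TSV together with its sample metadata.

    The first column of the table holds protein ids; remaining columns
    are samples and must each have a row in the metadata file.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicated protein id {dup!r} in {path}")
    bad = table.columns[[not np.issubdtype(dt, np.number) for dt in table.dtypes]]
    if len(bad):
        raise ValueError(f"non-numeric values in sample column(s) {list(bad)[:5]}")
    meta = read_metadata(metadata_path)
    unmatched = [c for c in table.columns if c not in meta.index]
    if unmatched:
        raise ValueError(f"samples without metadata rows: {unmatched[:5]}")
    return AbundanceMatrix(table.astype(float), meta.loc[table.columns], log_scale=log_scale)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={"zone": int, "replicate": int})
    missing = [c for c in DESIGN_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks column(s) {missing}")
    if meta.index.has_duplicates:
        raise ValueError("duplicated sample_id in metadata")
    meta.index.name = "sample_id"
    samples_from_frame(meta)  # validates factor levels
    return meta


def write_abundance_table(matrix: AbundanceMatrix, path: str | Path, metadata_path: str | Path | None = None) -> None:
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=_FLOAT_FMT)
    if metadata_path is not None:
        write_metadata(matrix.design, metadata_path)


def write_metadata(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read protein -> MapMan level-1 bin, resolving deeper bin paths.

    A bin name like ``"Protein biosynthesis.ribosome"`` maps to its
    level-1 prefix ``"Protein biosynthesis"``. Proteins listed more than
    once keep the first level-1 bin (a warning is logged when the bins
    disagree). Callers label proteins absent from the file via
    :func:`annotate_proteins`.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise ValueError(f"empty annotation file {path}")
    start = 0
    first = lines[0].split("\t")[0].strip().lower()
    if first in {"protein_id", "identifier"}:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip():
            raise ValueError(f"malformed annotation line {lineno} in {path}: {line!r}")
        pid = parts[0].strip().strip("'\"")
        bin_label = parts[1].strip().strip("'\"")
        level1 = bin_label.split(".")[0].strip() or NOT_ASSIGNED
        if pid in mapping:
            if mapping[pid] != level1:
                logger.warning(
                    "protein %s annotated with multiple level-1 bins (%r, %r); keeping first",
                    pid, mapping[pid], level1,
                )
            continue
        mapping[pid] = level1
    return mapping


def annotate_proteins(protein_ids, annotation: Mapping[str, str]) -> pd.Series:
    """Level-1 bin per protein; unannotated proteins get "not assigned"."""
    return pd.Series(
        [annotation.get(p, NOT_ASSIGNED) for p in protein_ids],
        index=pd.Index(protein_ids, name="protein_id"),
        name="bin",
    )


def read_ko_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV protein_id -> KEGG KO identifier (may be partial)."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"KO map {path} needs two columns")
    first = str(table.iloc[0, 0]).strip().lower()
    if first in {"protein_id", "identifier"}:
        table = table.iloc[1:]
    return dict(zip(table.iloc[:, 0].str.strip(), table.iloc[:, 1].str.strip()))


def write_kegg_mapping(
    dep_directions: Mapping[str, int],
    ko_map: Mapping[str, str],
    path: str | Path,
) -> int:
    """Write the two-column KO / direction table used for pathway mapping.

    ``dep_directions`` maps each differentially expressed protein to +1
    (more abundant under water deficit) or -1 (less abundant). Proteins
    without a KO are skipped; the number skipped is returned and logged.
    """
    bad = {p: d for p, d in dep_directions.items() if d not in (1, -1)}
    if bad:
        raise ValueError(f"direction values must be +1 or -1, got {bad}")
    skipped = 0
    rows = []
    for pid, direction in dep_directions.items():
        ko = ko_map.get(pid)
        if ko is None:
            skipped += 1
            continue
        rows.append((ko, direction))
    with Path(path).open("w") as handle:
        handle.write("ko\tdirection\n")
        for ko, direction in rows:
            handle.write(f"{ko}\t{direction:+d}\n")
    if skipped:
        logger.info("KEGG export: %d protein(s) without a KO skipped", skipped)
    return skipped


def write_design(samples, path: str | Path) -> None:
    write_metadata(design_frame(samples), path)
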