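"""Peptide-level XIC filtering and protein abundance computation.

Protein relative abundances are obtained by summing the XIC of peptides
that are (i) specific to the protein, (ii) reproducible — missing in
strictly less than 10% of samples by default — and (iii) coherent with
each other, i.e. every retained pair of peptides correlates with
Pearson r above 0.5. The coherence rule is operationalised as the
maximum clique of the peptide correlation graph (exhaustive for small
peptide sets, greedy above), since the filter phrase "correlation to
each other" does not by itself define a selection procedure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .design import DESIGN_COLUMNS
from .io import NA_TOKEN, read_metadata, _FLOAT_FMT
from .matrix import AbundanceMatrix

logger = logging.getLogger(__name__)

#: Peptide count above which clique search switches to the greedy heuristic.
_EXHAUSTIVE_LIMIT = 15

#: Minimum shared samples for a peptide-pair correlation to count.
_MIN_SHARED = 3


@dataclass
class PeptideMatrix:
    """Peptide x sample XIC values with the peptide -> protein map.

    ``peptides`` is indexed like ``values`` and has columns
    ``protein_id`` and ``specific`` (bool).
    """

    values: pd.DataFrame
    peptides: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.peptides.index):
            raise ValueError("values and peptide map must share the same index")
        if (self.peptides["protein_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty parent protein id")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise ValueError("XIC values must be >= 0 where present")
        missing_meta = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing_meta:
            raise ValueError(f"design lacks columns {missing_meta}")

    @property
    def n_peptides(self) -> int:
        return self.values.shape[0]

    def subset(self, peptide_ids) -> "PeptideMatrix":
        return PeptideMatrix(
            self.values.loc[peptide_ids],
            self.peptides.loc[peptide_ids],
            self.design,
        )


def read_peptide_table(path: str | Path, metadata_path: str | Path) -> PeptideMatrix:
    """TSV with columns peptide_id, protein_id, specific (0/1), then samples."""
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    for col in ("protein_id", "specific"):
        if col not in table.columns:
            raise ValueError(f"peptide table lacks column {col!r}")
    meta = read_metadata(metadata_path)
    sample_cols = [c for c in table.columns if c not in ("protein_id", "specific")]
    unmatched = [c for c in sample_cols if c not in meta.index]
    if unmatched:
        raise ValueError(f"samples without metadata rows: {unmatched[:5]}")
    peptides = pd.DataFrame(
        {"protein_id": table["protein_id"].astype(str),
         "specific": table["specific"].astype(int).astype(bool)},
        index=table.index,
    )
    values = table[sample_cols].astype(float)
    return PeptideMatrix(values, peptides, meta.loc[sample_cols])


def write_peptide_table(matrix: PeptideMatrix, path: str | Path) -> None:
    out = matrix.peptides.copy()
    out["specific"] = out["specific"].astype(int)
    out = pd.concat([out, matrix.values], axis=1)
    out.index.name = "peptide_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=_FLOAT_FMT)


def filter_reproducible(peptides: PeptideMatrix, max_missing_frac: float = 0.10) -> PeptideMatrix:
    """Keep specific peptides missing in strictly less than the given fraction."""
    if peptides.n_peptides == 0:
        raise ValueError("empty peptide matrix")
    if not 0.0 <= max_missing_frac < 1.0:
        raise ValueError("max_missing_frac must be in [0, 1)")
    missing_frac = peptides.values.isna().mean(axis=1)
    keep = peptides.peptides["specific"] & (missing_frac < max_missing_frac)
    logger.info(
        "reproducibility filter: %d/%d peptides kept (specific, missing < %.0f%%)",
        int(keep.sum()), peptides.n_peptides, 100 * max_missing_frac,
    )
    return peptides.subset(peptides.values.index[keep])


def _pairwise_r(values: np.ndarray) -> np.ndarray:
    """Pearson r over pairwise-complete samples; NaN when < 3 shared."""
    n = values.shape[0]
    r = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)
    for i, j in itertools.combinations(range(n), 2):
        mask = np.isfinite(values[i]) & np.isfinite(values[j])
        if mask.sum() < _MIN_SHARED:
            continue
        xi, xj = values[i, mask], values[j, mask]
        if xi.std() == 0 or xj.std() == 0:
            continue
        r[i, j] = r[j, i] = np.corrcoef(xi, xj)[0, 1]
    return r


def _best_clique(r: np.ndarray, ids: list[str], min_corr: float) -> list[int]:
    """Largest index subset with all pairwise r > min_corr.

    Exhaustive over maximal cliques up to 15 peptides, greedy
    (degree-ordered) above. Ties go to the subset with the higher mean
    pairwise r, then to the lexicographically smallest id tuple.
    """
    n = r.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if np.isfinite(r[i, j]) and r[i, j] > min_corr:
            graph.add_edge(i, j)

    def sort_key(clique: list[int]):
        members = sorted(clique)
        if len(members) < 2:
            mean_r = -np.inf
        else:
            mean_r = float(np.mean([r[a, b] for a, b in itertools.combinations(members, 2)]))
        # larger first, then higher mean r, then lexicographically smallest ids
        return (-len(members), -mean_r, tuple(ids[m] for m in members))

    if n <= _EXHAUSTIVE_LIMIT:
        candidates = [sorted(c) for c in nx.find_cliques(graph)]
        return min(candidates, key=sort_key)

    order = sorted(graph.nodes, key=lambda v: (-graph.degree[v], ids[v]))
    clique: list[int] = []
    for v in order:
        if all(graph.has_edge(v, u) for u in clique):
            clique.append(v)
    return sorted(clique)


def filter_coherent(peptides: PeptideMatrix, min_corr: float = 0.5) -> PeptideMatrix:
    """Per protein, keep the largest mutually correlated peptide subset.

    Proteins left with fewer than two peptides are dropped entirely
    (one peptide cannot corroborate itself).
    """
    if not -1.0 < min_corr < 1.0:
        raise ValueError("min_corr must be in (-1, 1)")
    kept: list[str] = []
    dropped_proteins = 0
    values = peptides.values
    for protein, group in peptides.peptides.groupby("protein_id", sort=False):
        pep_ids = list(group.index)
        if len(pep_ids) < 2:
            dropped_proteins += 1
            logger.info("protein %s dropped: only %d peptide(s)", protein, len(pep_ids))
            continue
        r = _pairwise_r(values.loc[pep_ids].to_numpy(dtype=float))
        clique = _best_clique(r, pep_ids, min_corr)
        if len(clique) < 2:
            dropped_proteins += 1
            logger.info("protein %s dropped: no coherent peptide pair", protein)
            continue
        kept.extend(pep_ids[i] for i in clique)
    logger.info(
        "coherence filter: %d/%d peptides kept, %d protein(s) dropped",
        len(kept), peptides.n_peptides, dropped_proteins,
    )
    if not kept:
        raise ValueError("no protein retained a coherent peptide pair")
    return peptides.subset(kept)


def aggregate_protein(peptides: PeptideMatrix) -> AbundanceMatrix:
    """Protein abundance = sum of retained peptide XICs per sample.

    The sum runs over peptides observed in that sample (a partial sum
    when some retained peptides are missing); the entry is missing only
    when every retained peptide is missing.
    """
    sums = peptides.values.groupby(peptides.peptides["protein_id"], sort=False).sum(min_count=1)
    sums.index.name = "protein_id"
    n_partial = int(
        (peptides.values.isna().groupby(peptides.peptides["protein_id"], sort=False).sum() > 0)
        .sum().sum()
    )
    logger.info(
        "aggregation: %d proteins from %d peptides (%d partial sums)",
        sums.shape[0], peptides.n_peptides, n_partial,
    )
    return AbundanceMatrix(sums, peptides.design.copy(), log_scale=False)


def normalize_samples(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Median-of-ratios sample alignment on the log scale.

    Each sample is shifted by the median of its log-ratios to a
    reference profile (the per-protein median across samples), so the
    post-normalisation per-sample median log-ratio to that reference is
    zero. This is a declared stand-in for the original normalisation and
    is labelled as such in run logs.
    """
    if not matrix.log_scale:
        raise ValueError("normalize_samples expects a log-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    if np.all(np.isnan(vals), axis=0).any():
        bad = matrix.values.columns[np.all(np.isnan(vals), axis=0)][0]
        raise ValueError(f"sample {bad!r} has no observed values")
    reference = np.nanmedian(vals, axis=1)
    shifts = np.nanmedian(vals - reference[:, None], axis=0)
    logger.info(
        "normalisation (median-of-ratios stand-in): shifts in [%.3f, %.3f] log2",
        float(np.min(shifts)), float(np.max(shifts)),
    )
    out = pd.DataFrame(
        vals - shifts[None, :], index=matrix.values.index, columns=matrix.values.columns
    )
    return AbundanceMatrix(out, matrix.design.copy(), log_scale=True)


def quantify_peptides(
    peptides: PeptideMatrix,
    max_missing_frac: float = 0.10,
    min_corr: float = 0.5,
    normalize: bool = True,
) -> AbundanceMatrix:
    """Full quantification chain: filters, summation, log2, normalisation."""
    filtered = filter_coherent(filter_reproducible(peptides, max_missing_frac), min_corr)
    proteins = aggregate_protein(filtered).to_log2()
    return normalize_samples(proteins) if normalize else proteins
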