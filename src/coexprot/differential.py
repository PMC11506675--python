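"""Per-protein factorial ANOVA with Type III sums of squares.

The model for one protein's log2 abundance is

    Y ~ mu + condition + day + zone + condition:day + condition:zone + day:zone + eps

with all factors categorical, sum-to-zero contrasts, and no three-way
interaction. Type III (marginal) sums of squares are computed by
comparing the full model with the model lacking each term's contrast
columns; with sum-to-zero coding this is the marginal hypothesis that
the term's effects vanish, and it remains well defined for the
unbalanced design created by the aborted (WD, SE5, zone 5) cell.

P-values are Benjamini-Hochberg adjusted per model term across proteins
(six separate families): results are reported as per-effect counts, so
each effect forms its own multiple-testing family. This choice is
switchable via ``bh_per_term``.

The engine is vectorised across proteins: residual-maker matrices for
the full and reduced models are computed once per design (and per
missing-data pattern) and applied to all protein columns at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS, DAYS, ZONES, SampleDesign, design_frame
from .matrix import AbundanceMatrix, cell_means

logger = logging.getLogger(__name__)

TERMS: tuple[str, ...] = (
    "condition", "day", "zone", "condition:day", "condition:zone", "day:zone",
)

_FACTOR_LEVELS = {"condition": list(CONDITIONS), "day": list(DAYS), "zone": list(ZONES)}


def _sum_coding(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n x (L-1) columns."""
    X = np.zeros((codes.size, n_levels - 1))
    for j in range(n_levels - 1):
        X[codes == j, j] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


@dataclass
class _MaskFit:
    rank_full: int
    df_resid: int
    resid_maker_full: np.ndarray
    term_df: dict[str, int]
    resid_maker_reduced: dict[str, np.ndarray]


class FactorialAnova:
    """Type III ANOVA machinery for one fixed sample design.

    Factors observed at a single level (e.g. a toy 2x2 design with one
    zone) are dropped along with the terms involving them; the
    remaining terms are fitted as usual.
    """

    def __init__(self, design: pd.DataFrame):
        self.design = design
        self._factor_codes: dict[str, np.ndarray] = {}
        self._factor_nlev: dict[str, int] = {}
        for fac, levels in _FACTOR_LEVELS.items():
            observed = [l for l in levels if (design[fac] == l).any()]
            codes = np.array([observed.index(v) for v in design[fac]])
            self._factor_codes[fac] = codes
            self._factor_nlev[fac] = len(observed)
        self.terms = [t for t in TERMS if self._term_available(t)]
        self._blocks: dict[str, np.ndarray] = {}
        cols = [np.ones((len(design), 1))]
        for term in self.terms:
            block = self._term_columns(term)
            self._blocks[term] = block
            cols.append(block)
        self._X = np.hstack(cols)
        self._fits: dict[bytes, _MaskFit] = {}

    def _term_available(self, term: str) -> bool:
        return all(self._factor_nlev[f] > 1 for f in term.split(":"))

    def _term_columns(self, term: str) -> np.ndarray:
        parts = term.split(":")
        mat = _sum_coding(self._factor_codes[parts[0]], self._factor_nlev[parts[0]])
        for fac in parts[1:]:
            other = _sum_coding(self._factor_codes[fac], self._factor_nlev[fac])
            mat = np.einsum("ni,nj->nij", mat, other).reshape(len(other), -1)
        return mat

    @staticmethod
    def _resid_maker(X: np.ndarray) -> tuple[np.ndarray, int]:
        rank = int(np.linalg.matrix_rank(X))
        hat = X @ np.linalg.pinv(X)
        return np.eye(X.shape[0]) - hat, rank

    def _fit_for_mask(self, mask: np.ndarray) -> _MaskFit:
        key = mask.tobytes()
        fit = self._fits.get(key)
        if fit is not None:
            return fit
        X = self._X[mask]
        M_full, rank_full = self._resid_maker(X)
        term_df: dict[str, int] = {}
        reduced: dict[str, np.ndarray] = {}
        offset = 1
        for term in self.terms:
            width = self._blocks[term].shape[1]
            keep = np.ones(self._X.shape[1], dtype=bool)
            keep[offset:offset + width] = False
            offset += width
            M_red, rank_red = self._resid_maker(self._X[mask][:, keep])
            term_df[term] = rank_full - rank_red
            reduced[term] = M_red
        fit = _MaskFit(
            rank_full=rank_full,
            df_resid=int(mask.sum()) - rank_full,
            resid_maker_full=M_full,
            term_df=term_df,
            resid_maker_reduced=reduced,
        )
        self._fits[key] = fit
        return fit

    def fit(self, Y: pd.DataFrame) -> pd.DataFrame:
        """Fit every row of a proteins x samples matrix.

        Returns a long DataFrame with one row per protein and term
        (plus a ``residual`` row per protein). Terms whose marginal
        hypothesis is not estimable under a missing-data pattern carry
        df = 0 and missing F/p.
        """
        if list(Y.columns) != list(self.design.index):
            Y = Y.loc[:, self.design.index]
        values = Y.to_numpy(dtype=float)
        finite = np.isfinite(values)
        records: list[tuple] = []
        groups: dict[bytes, list[int]] = {}
        for i, m in enumerate(finite):
            groups.setdefault(m.tobytes(), []).append(i)
        for key, row_list in groups.items():
            mask = np.frombuffer(key, dtype=bool)
            rows = np.asarray(row_list)
            if mask.sum() == 0:
                for r in rows:
                    for term in self.terms:
                        records.append((Y.index[r], term, np.nan, 0, np.nan, np.nan))
                    records.append((Y.index[r], "residual", np.nan, 0, np.nan, np.nan))
                continue
            fit = self._fit_for_mask(mask)
            sub = values[np.ix_(rows, np.flatnonzero(mask))].T  # obs x prot
            sse_full = np.einsum("ij,ij->j", fit.resid_maker_full @ sub, sub)
            mse = np.full_like(sse_full, np.nan)
            if fit.df_resid > 0:
                mse = sse_full / fit.df_resid
            for term in self.terms:
                df_t = fit.term_df[term]
                sse_red = np.einsum("ij,ij->j", fit.resid_maker_reduced[term] @ sub, sub)
                ss = np.maximum(sse_red - sse_full, 0.0)
                if df_t > 0 and fit.df_resid > 0:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        F = (ss / df_t) / mse
                    p = stats.f.sf(F, df_t, fit.df_resid)
                else:
                    F = np.full_like(ss, np.nan)
                    p = np.full_like(ss, np.nan)
                for i, r in enumerate(rows):
                    records.append((Y.index[r], term, ss[i], df_t, F[i], p[i]))
            for i, r in enumerate(rows):
                records.append((Y.index[r], "residual", sse_full[i], fit.df_resid,
                                np.nan, np.nan))
        table = pd.DataFrame(
            records, columns=["protein_id", "term", "ss", "df", "F", "p"]
        )
        # regroup rows per protein in input order (terms already ordered
        # within each protein by construction)
        table = (
            table.set_index("protein_id").loc[Y.index]
            .rename_axis("protein_id").reset_index()
        )
        return table


def fit_type3_anova(
    y: pd.Series | np.ndarray,
    design: list[SampleDesign] | pd.DataFrame,
) -> pd.DataFrame:
    """Type III ANOVA of a single protein; returns a term-indexed table."""
    frame = design if isinstance(design, pd.DataFrame) else design_frame(design)
    if isinstance(y, pd.Series):
        y = y.loc[frame.index]
    Y = pd.DataFrame([np.asarray(y, dtype=float)], index=["y"], columns=frame.index)
    table = FactorialAnova(frame).fit(Y)
    return table.drop(columns="protein_id").set_index("term")


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing entries pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if finite.sum():
        out[finite] = stats.false_discovery_control(p[finite], method="bh")
    return out


@dataclass
class AnovaResult:
    """Long-format ANOVA table plus per-protein WD direction."""

    table: pd.DataFrame          # protein_id, term, ss, df, F, p, p_adj, significant
    direction: pd.Series         # +1 where WD mean > WW mean, else -1
    alpha: float = 0.05
    terms: tuple[str, ...] = field(default=TERMS)

    def significant(self, term: str) -> set[str]:
        t = self.table
        mask = (t["term"] == term) & t["significant"]
        return set(t.loc[mask, "protein_id"])


def condition_direction(matrix: AbundanceMatrix) -> pd.Series:
    """Sign of (WD - WW) marginal means over the day x zone cells shared
    by both conditions (zero differences count as +1)."""
    cm = cell_means(matrix).values
    by_cond = {}
    for cond in CONDITIONS:
        sub = cm.loc[:, cm.columns.get_level_values("condition") == cond]
        by_cond[cond] = {c[1:]: sub[c] for c in sub.columns}
    shared = sorted(set(by_cond["WW"]) & set(by_cond["WD"]))
    ww = pd.concat([by_cond["WW"][c] for c in shared], axis=1).mean(axis=1)
    wd = pd.concat([by_cond["WD"][c] for c in shared], axis=1).mean(axis=1)
    diff = wd - ww
    return pd.Series(np.where(diff >= 0, 1, -1), index=cm.index, name="direction")


def anova_table(
    matrix: AbundanceMatrix,
    alpha: float = 0.05,
    bh_per_term: bool = True,
) -> AnovaResult:
    """Fit every protein, BH-adjust, and flag significant effects.

    ``bh_per_term=True`` (default) adjusts each model term across
    proteins as its own family; ``False`` pools all six terms into one
    family.
    """
    if not matrix.log_scale:
        logger.warning("ANOVA on raw-scale abundances; log2 transform is recommended")
    engine = FactorialAnova(matrix.design)
    table = engine.fit(matrix.values)
    is_term = table["term"] != "residual"
    table["p_adj"] = np.nan
    if bh_per_term:
        for term in engine.terms:
            mask = table["term"] == term
            table.loc[mask, "p_adj"] = adjust_bh(table.loc[mask, "p"])
    else:
        table.loc[is_term, "p_adj"] = adjust_bh(table.loc[is_term, "p"])
    table["significant"] = (table["p_adj"] < alpha).fillna(False) & is_term
    return AnovaResult(
        table=table,
        direction=condition_direction(matrix),
        alpha=alpha,
        terms=tuple(engine.terms),
    )


def call_significant(result: AnovaResult, alpha: float | None = None) -> dict[str, set[str]]:
    """Per-term significant protein sets plus the union "WD-affected" set.

    "WD-affected" is the union of the terms involving the watering
    condition (main effect and both interactions); its members' up/down
    direction lives in ``result.direction``. The threshold is strict
    (adjusted p exactly equal to alpha is not significant).
    """
    alpha = result.alpha if alpha is None else alpha
    t = result.table
    sets: dict[str, set[str]] = {}
    for term in result.terms:
        mask = (t["term"] == term) & (t["p_adj"] < alpha)
        sets[term] = set(t.loc[mask, "protein_id"])
    sets["WD_affected"] = set().union(
        *(sets.get(term, set())
          for term in ("condition", "condition:day", "condition:zone"))
    )
    return sets


def dep_directions(result: AnovaResult, proteins: set[str] | None = None) -> dict[str, int]:
    """Map WD-affected proteins to +1 (up in WD) or -1 (down in WD)."""
    if proteins is None:
        proteins = call_significant(result)["WD_affected"]
    return {p: int(result.direction.loc[p]) for p in sorted(proteins)}
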