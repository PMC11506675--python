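"""Calibration and recovery experiments on synthetic data.

The study's raw data cannot be regenerated from published tables, so
the statistical machinery is validated on simulations run under the
study conditions (57 samples in the 19-cell unbalanced design, log2
Gaussian noise): false-discovery control on fully null data, recall of
planted condition effects, recovery of a planted condition-specific
co-expression module, and the behaviour of the peptide filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import compare as cmp
from . import coexpression as coex
from . import quantify as quant
from . import simulate as sim
from .design import design_frame, generate_design
from .differential import FactorialAnova, adjust_bh
from .io import annotate_proteins

_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def _study_design():
    return design_frame(generate_design(3, drop_cell=True))


@dataclass
class FdrCalibration:
    per_term_fdr: dict[str, float]
    per_term_se: dict[str, float]
    n_datasets: int

    def worst_term(self) -> tuple[str, float, float]:
        term = max(self.per_term_fdr, key=self.per_term_fdr.get)
        return term, self.per_term_fdr[term], self.per_term_se[term]


def null_fdr_calibration(
    n_datasets: int = 200,
    n_proteins: int = 500,
    sigma: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
) -> FdrCalibration:
    """Empirical FDR of BH-adjusted effect calls on fully null data.

    Every protein is null, so the false-discovery proportion of one
    dataset is 1 whenever any protein is called and 0 otherwise; its
    mean over datasets estimates the FDR, which BH bounds by alpha.
    """
    design = _study_design()
    engine = FactorialAnova(design)
    fdp: dict[str, list[float]] = {t: [] for t in engine.terms}
    for rep in range(n_datasets):
        truth = sim.generate_null_truth(n_proteins, sigma=sigma,
                                        seed=(seed * 100003 + rep) & _MASK)
        matrix = sim.simulate_abundances(design, truth,
                                         seed=(seed * 100003 + 50000 + rep) & _MASK)
        table = engine.fit(matrix.values)
        for term in engine.terms:
            p = table.loc[table["term"] == term, "p"].to_numpy()
            n_called = int((adjust_bh(p) < alpha).sum())
            fdp[term].append(1.0 if n_called > 0 else 0.0)
    means = {t: float(np.mean(v)) for t, v in fdp.items()}
    ses = {t: float(np.std(v, ddof=1) / np.sqrt(len(v))) for t, v in fdp.items()}
    return FdrCalibration(per_term_fdr=means, per_term_se=ses, n_datasets=n_datasets)


@dataclass
class EffectRecovery:
    recall: float
    null_fdp: float
    n_planted: int
    n_null: int


def condition_effect_recovery(
    n_proteins: int = 400,
    planted_fraction: float = 0.5,
    effect_log2: float = 1.5,   # WD-WW difference = 6 sigma, per-level 3 sigma
    sigma: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
) -> EffectRecovery:
    """Recall of planted condition effects and FDP among the calls."""
    design = _study_design()
    spec = sim.EffectSpec(
        frac_condition=planted_fraction, frac_day=0.0, frac_zone=0.0,
        frac_cond_day=0.0, frac_cond_zone=0.0, frac_day_zone=0.0,
        effect_low=effect_log2, effect_high=effect_log2, sigma=sigma,
    )
    truth = sim.generate_truth(n_proteins, spec, seed=seed & _MASK)
    matrix = sim.simulate_abundances(design, truth, seed=(seed + 1) & _MASK)
    engine = FactorialAnova(design)
    table = engine.fit(matrix.values)
    p = table.loc[table["term"] == "condition", "p"].to_numpy()
    called = adjust_bh(p) < alpha
    planted = truth.effects.affected("condition")
    tp = int((called & planted).sum())
    fp = int((called & ~planted).sum())
    n_called = int(called.sum())
    return EffectRecovery(
        recall=tp / int(planted.sum()),
        null_fdp=fp / max(n_called, 1),
        n_planted=int(planted.sum()),
        n_null=int((~planted).sum()),
    )


@dataclass
class ModuleRecovery:
    module_bin: str
    wd_enrichment_p_adj: float
    ww_enrichment_p_adj: float
    change_p_adj: float
    change_direction: float


def wd_module_recovery(
    n_proteins: int = 800,
    module_size: int = 10,
    loading: float = 1.0,
    n_background_modules: int = 4,
    sigma: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
) -> ModuleRecovery:
    """Recovery of a planted WD-only co-expression module.

    The module's proteins share one functional bin; recovery means the
    intra-bin pair is hypergeometrically over-connected in the WD
    network and its WW-vs-WD connectivity change is significant.
    Background modules active in both conditions give each network the
    baseline edges the 2x2 change test conditions on.
    """
    design = _study_design()
    modules = [sim.ModuleSpec(module_size, 0.0, loading)] + [
        sim.ModuleSpec(module_size, loading, loading)
        for _ in range(n_background_modules)
    ]
    truth = sim.generate_truth(
        n_proteins, sim.EffectSpec(null_fraction=1.0, sigma=sigma),
        module_specs=modules,
        seed=seed & _MASK,
    )
    matrix = sim.simulate_abundances(design, truth, seed=(seed + 1) & _MASK)
    annotation = annotate_proteins(
        truth.protein_ids, sim.simulate_annotation(truth, seed=(seed + 2) & _MASK)
    )
    module_bin = annotation.loc[truth.modules[0].members[0]]

    nets = {c: coex.build_network(matrix, c, alpha=alpha) for c in ("WW", "WD")}
    enr = {
        c: cmp.term_pair_enrichment(nets[c], annotation, alpha=alpha)
        .set_index(["term_a", "term_b"])
        for c in nets
    }
    change = cmp.compare_term_pair_connectivity(
        nets["WW"], nets["WD"], annotation, alpha=alpha
    ).set_index(["term_a", "term_b"])
    key = (module_bin, module_bin)
    return ModuleRecovery(
        module_bin=module_bin,
        wd_enrichment_p_adj=float(enr["WD"].loc[key, "p_over_adj"]),
        ww_enrichment_p_adj=float(enr["WW"].loc[key, "p_over_adj"]),
        change_p_adj=float(change.loc[key, "p_adj"]),
        change_direction=float(change.loc[key, "direction"]),
    )


@dataclass
class FilterPerformance:
    outlier_removal_rate: float
    high_missing_removal_rate: float
    n_outliers: int
    n_high_missing: int


def peptide_filter_performance(
    n_proteins: int = 200,
    outlier_frac: float = 0.25,
    seed: int = 0,
) -> FilterPerformance:
    """Removal rates of the two peptide filters on synthetic data.

    Outlier (uncorrelated) peptides should fall to the r > 0.5
    coherence rule; peptides observed missing in >= 10% of samples must
    all fall to the reproducibility rule (a deterministic check).
    """
    design = _study_design()
    truth = sim.generate_null_truth(n_proteins, seed=seed & _MASK)
    matrix = sim.simulate_abundances(design, truth, seed=(seed + 1) & _MASK)
    spec = sim.PeptideSpec(outlier_frac=outlier_frac)
    peptides, pep_truth = sim.simulate_peptides(matrix, spec, seed=(seed + 2) & _MASK)

    reproducible = quant.filter_reproducible(peptides, 0.10)
    observed_missing = peptides.values.isna().mean(axis=1)
    high_missing = peptides.values.index[
        peptides.peptides["specific"] & (observed_missing >= 0.10)
    ]
    removed_high = [p for p in high_missing if p not in reproducible.values.index]

    coherent = quant.filter_coherent(reproducible, 0.5)
    outliers = [
        p for p in pep_truth.index[pep_truth["outlier"]]
        if p in reproducible.values.index
    ]
    removed_outliers = [p for p in outliers if p not in coherent.values.index]
    return FilterPerformance(
        outlier_removal_rate=len(removed_outliers) / max(len(outliers), 1),
        high_missing_removal_rate=len(removed_high) / max(len(high_missing), 1),
        n_outliers=len(outliers),
        n_high_missing=len(high_missing),
    )
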