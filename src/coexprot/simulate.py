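"""Synthetic data with the study's factorial structure and ground truth.

The generator emulates the study conditions: a 2 (condition) x 2 (day) x
5 (zone) factorial with 3 replicates and the aborted (WD, SE5, zone 5)
cell, ~800 quantified proteins, cluster-structured condition / day /
zone effects on the log2 scale, planted co-expression modules driven by
cell-level latent factors, and peptide-level XIC observation noise with
missingness and occasional uncorrelated (outlier) peptides.

Effects are drawn on the log2-abundance scale. The fraction of proteins
affected by each model term defaults to the prevalences reported for
the real dataset (condition 481/800, day 327/800, zone 162/800,
day x zone 52/800, condition x day 21/800, condition x zone 2/800).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .design import CONDITIONS, DAYS, ZONES, SampleDesign, design_frame, generate_design
from .matrix import AbundanceMatrix

__all__ = [
    "EffectSpec",
    "ModuleSpec",
    "PeptideSpec",
    "EffectTruth",
    "ModuleTruth",
    "SimulationTruth",
    "generate_design",
    "generate_truth",
    "simulate_abundances",
    "simulate_peptides",
    "simulate_annotation",
    "MAPMAN_LEVEL1_BINS",
]

#: Level-1 MapMan process names used to annotate synthetic proteins.
MAPMAN_LEVEL1_BINS: tuple[str, ...] = (
    "Photosynthesis", "Cellular respiration", "Carbohydrate metabolism",
    "Amino acid metabolism", "Lipid metabolism", "Nucleotide metabolism",
    "Coenzyme metabolism", "Polyamine metabolism", "Secondary metabolism",
    "Redox homeostasis", "Phytohormone action", "Chromatin organisation",
    "Cell cycle organisation", "DNA damage response", "RNA biosynthesis",
    "RNA processing", "Protein biosynthesis", "Protein modification",
    "Protein homeostasis", "Protein translocation", "Vesicle trafficking",
    "Cytoskeleton organisation", "Cell wall organisation", "Cell division",
    "External stimuli response", "Solute transport", "Nutrient uptake",
    "Plant reproduction", "Enzyme classification",
)


@dataclass
class EffectSpec:
    """Distributional parameters of the planted factorial effects."""

    frac_condition: float = 481 / 800
    frac_day: float = 327 / 800
    frac_zone: float = 162 / 800
    frac_day_zone: float = 52 / 800
    frac_cond_day: float = 21 / 800
    frac_cond_zone: float = 2 / 800
    effect_low: float = 0.5   # |log2 effect| lower bound
    effect_high: float = 2.0  # |log2 effect| upper bound
    sigma: float = 0.25       # residual SD, log2 scale
    baseline_mean: float = 20.0
    baseline_sd: float = 1.5
    null_fraction: float | None = None  # when set, overrides all frac_* with 1-null

    def resolved_fractions(self) -> dict[str, float]:
        if self.null_fraction is not None:
            f = 1.0 - self.null_fraction
            return {t: f for t in ("condition", "day", "zone",
                                   "day_zone", "cond_day", "cond_zone")}
        return {
            "condition": self.frac_condition,
            "day": self.frac_day,
            "zone": self.frac_zone,
            "day_zone": self.frac_day_zone,
            "cond_day": self.frac_cond_day,
            "cond_zone": self.frac_cond_zone,
        }


@dataclass
class ModuleSpec:
    """A planted co-expression module.

    ``loading_ww`` / ``loading_wd`` scale a shared cell-level latent
    N(0,1) factor; a zero loading makes the module silent in that
    condition, producing condition-specific co-expression.
    """

    size: int
    loading_ww: float
    loading_wd: float

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ValueError("modules need at least 3 members")


def default_module_specs() -> list[ModuleSpec]:
    """One shared, one WW-only and one WD-only module of 10 proteins."""
    return [
        ModuleSpec(10, 1.0, 1.0),
        ModuleSpec(10, 1.0, 0.0),
        ModuleSpec(10, 0.0, 1.0),
    ]


@dataclass
class EffectTruth:
    """Sum-to-zero factorial effects for every protein (log2 scale)."""

    protein_ids: pd.Index
    mu: np.ndarray                 # (P,)
    condition: np.ndarray          # (P, 2) over CONDITIONS
    day: np.ndarray                # (P, 2) over DAYS
    zone: np.ndarray               # (P, 5) over ZONES
    cond_day: np.ndarray           # (P, 2, 2)
    cond_zone: np.ndarray          # (P, 2, 5)
    day_zone: np.ndarray           # (P, 2, 5)
    sigma: np.ndarray              # (P,)
    module_id: np.ndarray          # (P,), -1 = none

    def cell_mean(self, condition: str, day: str, zone: int) -> np.ndarray:
        """Model mean for every protein in one design cell."""
        i = CONDITIONS.index(condition)
        k = DAYS.index(day)
        j = ZONES.index(zone)
        return (
            self.mu
            + self.condition[:, i]
            + self.day[:, k]
            + self.zone[:, j]
            + self.cond_day[:, i, k]
            + self.cond_zone[:, i, j]
            + self.day_zone[:, k, j]
        )

    def affected(self, term: str) -> np.ndarray:
        """Boolean mask of proteins with a nonzero effect for a term."""
        arr = {
            "condition": self.condition,
            "day": self.day,
            "zone": self.zone,
            "condition:day": self.cond_day,
            "condition:zone": self.cond_zone,
            "day:zone": self.day_zone,
        }[term]
        return np.abs(arr).reshape(arr.shape[0], -1).max(axis=1) > 0


@dataclass
class ModuleTruth:
    module_id: int
    members: list[str]
    loading_ww: float
    loading_wd: float

    def loading(self, condition: str) -> float:
        return self.loading_ww if condition == "WW" else self.loading_wd


@dataclass
class SimulationTruth:
    effects: EffectTruth
    modules: list[ModuleTruth] = field(default_factory=list)

    @property
    def protein_ids(self) -> pd.Index:
        return self.effects.protein_ids

    def to_dict(self) -> dict:
        eff = self.effects
        return {
            "protein_ids": list(eff.protein_ids),
            "sigma": eff.sigma.tolist(),
            "affected": {t: eff.affected(t).tolist()
                         for t in ("condition", "day", "zone",
                                   "condition:day", "condition:zone", "day:zone")},
            "condition_direction": np.sign(
                eff.condition[:, CONDITIONS.index("WD")]
            ).astype(int).tolist(),
            "modules": [asdict(m) for m in self.modules],
        }


def _signed_amplitudes(rng, mask, low, high):
    amp = np.zeros(mask.size)
    n = int(mask.sum())
    amp[mask] = rng.uniform(low, high, n) * rng.choice([-1.0, 1.0], n)
    return amp


def generate_truth(
    n_proteins: int = 800,
    effect_spec: EffectSpec | None = None,
    module_specs: Sequence[ModuleSpec] | None = None,
    seed: int = 0,
) -> SimulationTruth:
    """Draw per-protein factorial effects and disjoint module memberships.

    Zone (and zone-interaction) effects are monotone gradients over the
    five zones, mirroring the developmental gradient along the ear.
    """
    spec = effect_spec if effect_spec is not None else EffectSpec()
    modules = list(module_specs) if module_specs is not None else []
    needed = sum(m.size for m in modules)
    if needed > n_proteins:
        raise ValueError(f"module sizes total {needed} > n_proteins {n_proteins}")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    pids = pd.Index([f"P{i:04d}" for i in range(n_proteins)], name="protein_id")
    frac = spec.resolved_fractions()

    def pick(f):
        return rng.random(n_proteins) < f

    mu = rng.normal(spec.baseline_mean, spec.baseline_sd, n_proteins)
    sigma = np.full(n_proteins, spec.sigma)

    half = np.array([-0.5, 0.5])
    gradient = np.linspace(-0.5, 0.5, 5)

    a_cond = _signed_amplitudes(rng, pick(frac["condition"]), spec.effect_low, spec.effect_high)
    condition = np.outer(a_cond, half)  # (P,2): WD mean minus WW mean = a_cond

    a_day = _signed_amplitudes(rng, pick(frac["day"]), spec.effect_low, spec.effect_high)
    day = np.outer(a_day, half)

    a_zone = _signed_amplitudes(rng, pick(frac["zone"]), spec.effect_low, spec.effect_high)
    zone = np.outer(a_zone, gradient)

    a_cd = _signed_amplitudes(rng, pick(frac["cond_day"]), spec.effect_low, spec.effect_high)
    cond_day = a_cd[:, None, None] * (half[:, None] * half[None, :])

    a_cz = _signed_amplitudes(rng, pick(frac["cond_zone"]), spec.effect_low, spec.effect_high)
    cond_zone = a_cz[:, None, None] * (half[:, None] * gradient[None, :])

    a_dz = _signed_amplitudes(rng, pick(frac["day_zone"]), spec.effect_low, spec.effect_high)
    day_zone = a_dz[:, None, None] * (half[:, None] * gradient[None, :])

    module_id = np.full(n_proteins, -1, dtype=int)
    module_truths: list[ModuleTruth] = []
    if modules:
        chosen = rng.choice(n_proteins, size=needed, replace=False)
        start = 0
        for mid, mspec in enumerate(modules):
            members = chosen[start:start + mspec.size]
            start += mspec.size
            module_id[members] = mid
            module_truths.append(
                ModuleTruth(mid, [pids[i] for i in sorted(members)],
                            mspec.loading_ww, mspec.loading_wd)
            )

    effects = EffectTruth(
        protein_ids=pids, mu=mu, condition=condition, day=day, zone=zone,
        cond_day=cond_day, cond_zone=cond_zone, day_zone=day_zone,
        sigma=sigma, module_id=module_id,
    )
    return SimulationTruth(effects=effects, modules=module_truths)


def generate_null_truth(n_proteins: int, sigma: float = 0.25, seed: int = 0) -> SimulationTruth:
    """All factor effects exactly zero (for calibration experiments)."""
    spec = EffectSpec(null_fraction=1.0, sigma=sigma)
    return generate_truth(n_proteins, spec, module_specs=[], seed=seed)


def simulate_abundances(
    design: Sequence[SampleDesign] | pd.DataFrame,
    truth: SimulationTruth,
    seed: int = 0,
) -> AbundanceMatrix:
    """Draw a log2 abundance matrix under the factorial model.

    Each sample's value is the model cell mean, plus the module latent
    contribution (condition-specific loading times a latent value shared
    by all samples of a design cell, so replicate averaging preserves
    module correlation), plus Gaussian residual noise.
    """
    frame = design if isinstance(design, pd.DataFrame) else design_frame(design)
    eff = truth.effects
    n_prot = len(eff.protein_ids)
    n_samp = len(frame)

    ss = np.random.SeedSequence(seed)
    latent_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    cells = sorted({(r.condition, r.day, int(r.zone)) for r in frame.itertuples()})
    cell_index = {c: i for i, c in enumerate(cells)}
    latent = latent_rng.standard_normal((len(truth.modules), len(cells)))

    values = np.empty((n_prot, n_samp))
    for s, row in enumerate(frame.itertuples()):
        cell = (row.condition, row.day, int(row.zone))
        col = eff.cell_mean(*cell).copy()
        for m, mod in enumerate(truth.modules):
            idx = np.flatnonzero(eff.module_id == mod.module_id)
            col[idx] += mod.loading(row.condition) * latent[m, cell_index[cell]]
        values[:, s] = col
    values += noise_rng.standard_normal((n_prot, n_samp)) * eff.sigma[:, None]

    vals = pd.DataFrame(values, index=eff.protein_ids, columns=frame.index)
    return AbundanceMatrix(vals, frame.copy(), log_scale=True)


@dataclass
class PeptideSpec:
    """Observation model mapping protein abundance to peptide XIC."""

    n_peptides_min: int = 3
    n_peptides_max: int = 6
    coef_low: float = 0.2           # peptide response coefficient (x protein XIC)
    coef_high: float = 1.0
    noise_sd_log2: float = 0.2      # multiplicative XIC noise
    missing_low: tuple[float, float] = (0.0, 0.05)
    missing_high: tuple[float, float] = (0.12, 0.30)
    frac_high_missing: float = 0.15
    outlier_frac: float = 0.10      # peptides uncorrelated with their protein
    nonspecific_frac: float = 0.10  # peptides shared with other proteins

    def __post_init__(self) -> None:
        if self.n_peptides_min < 2:
            raise ValueError("need at least 2 peptides per protein")
        if self.n_peptides_max < self.n_peptides_min:
            raise ValueError("n_peptides_max < n_peptides_min")


def simulate_peptides(
    protein_matrix: AbundanceMatrix,
    pep_spec: PeptideSpec | None = None,
    seed: int = 0,
):
    """Observe each protein through noisy peptide XIC measurements.

    Peptide XIC = coefficient x protein abundance (raw scale) x
    multiplicative log-normal noise; entries go missing independently at
    the peptide's missing probability. Outlier peptides are drawn from
    an independent profile around the protein's mean level, so they do
    not correlate with their siblings. The first two peptides of every
    protein are forced specific, non-outlier and low-missing so each
    protein stays quantifiable.

    Returns a :class:`~coexprot.quantify.PeptideMatrix` and a truth
    DataFrame (one row per peptide).
    """
    from .quantify import PeptideMatrix  # deferred: quantify does not import simulate

    spec = pep_spec if pep_spec is not None else PeptideSpec()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    log_matrix = protein_matrix if protein_matrix.log_scale else protein_matrix.to_log2()
    raw = np.power(2.0, log_matrix.values.to_numpy(dtype=float))
    n_samp = raw.shape[1]

    pep_rows, truth_rows, values = [], [], []
    for p, pid in enumerate(log_matrix.protein_ids):
        n_pep = int(rng.integers(spec.n_peptides_min, spec.n_peptides_max + 1))
        for j in range(n_pep):
            protected = j < 2  # keeps the protein quantifiable
            outlier = (not protected) and rng.random() < spec.outlier_frac
            specific = protected or rng.random() >= spec.nonspecific_frac
            if protected or rng.random() >= spec.frac_high_missing:
                miss_p = rng.uniform(*spec.missing_low)
            else:
                miss_p = rng.uniform(*spec.missing_high)
            coef = rng.uniform(spec.coef_low, spec.coef_high)

            if outlier:
                base_log = np.nanmean(np.log2(raw[p])) + rng.standard_normal(n_samp)
                signal = np.power(2.0, base_log)
            else:
                signal = raw[p]
            noise = np.power(2.0, rng.standard_normal(n_samp) * spec.noise_sd_log2)
            xic = coef * signal * noise
            xic[rng.random(n_samp) < miss_p] = np.nan

            pep_id = f"{pid}_pep{j + 1}"
            pep_rows.append((pep_id, pid, specific))
            truth_rows.append((pep_id, pid, specific, outlier, coef, miss_p))
            values.append(xic)

    index = pd.Index([r[0] for r in pep_rows], name="peptide_id")
    matrix = pd.DataFrame(np.vstack(values), index=index, columns=log_matrix.values.columns)
    peptides = pd.DataFrame(
        {"protein_id": [r[1] for r in pep_rows], "specific": [r[2] for r in pep_rows]},
        index=index,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["peptide_id", "protein_id", "specific", "outlier", "coef", "missing_prob"],
    ).set_index("peptide_id")
    return PeptideMatrix(matrix, peptides, log_matrix.design.copy()), truth


def simulate_annotation(
    truth: SimulationTruth,
    seed: int = 0,
    not_assigned_frac: float = 0.15,
) -> dict[str, str]:
    """Assign level-1 bins: one bin per module, the rest at random.

    A fraction of non-module proteins is left out of the map entirely so
    downstream code exercises the "not assigned" default.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bins = list(MAPMAN_LEVEL1_BINS)
    module_bins = rng.choice(len(bins), size=len(truth.modules), replace=False)
    mapping: dict[str, str] = {}
    by_module = {m.module_id: bins[b] for m, b in zip(truth.modules, module_bins)}
    for pid, mid in zip(truth.protein_ids, truth.effects.module_id):
        if mid >= 0:
            mapping[pid] = by_module[mid]
        elif rng.random() >= not_assigned_frac:
            mapping[pid] = bins[int(rng.integers(len(bins)))]
    return mapping
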