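"""Run configuration shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Thresholds and switches controlling a full pipeline run.

    Parameters
    ----------
    alpha
        Significance level applied to BH-adjusted p-values everywhere
        (ANOVA effect calls, co-expression edges, enrichment tests).
    k_clusters
        Number of k-means clusters for abundance-profile clustering.
    min_missing_frac
        A peptide is "reproducible" when its missing fraction across all
        samples is strictly below this value.
    min_pep_corr
        Peptides of a protein are "coherent" when every pairwise Pearson
        correlation within the retained subset exceeds this value.
    rng_seed
        Global seed; all stochastic sub-steps derive child seeds from it.
    log_transform
        Run downstream statistics on log2 abundances (raw XIC sums are
        log-normal; the log scale stabilises variance).
    yates_correction
        Apply the Yates continuity correction in 2x2 chi-squared tests of
        connectivity change between networks.
    """

    alpha: float = 0.05
    k_clusters: int = 8
    min_missing_frac: float = 0.10
    min_pep_corr: float = 0.5
    rng_seed: int = 0
    log_transform: bool = True
    yates_correction: bool = True
    kmeans_restarts: int = field(default=25, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.k_clusters < 1:
            raise ValueError(f"k_clusters must be >= 1, got {self.k_clusters}")
        if not 0.0 <= self.min_missing_frac < 1.0:
            raise ValueError(
                f"min_missing_frac must be in [0, 1), got {self.min_missing_frac}"
            )
        if not -1.0 < self.min_pep_corr < 1.0:
            raise ValueError(
                f"min_pep_corr must be in (-1, 1), got {self.min_pep_corr}"
            )
        if self.kmeans_restarts < 1:
            raise ValueError("kmeans_restarts must be >= 1")
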