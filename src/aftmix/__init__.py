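"""Sparse finite mixtures of AFT regressions for right-censored survival.

The package implements a survival-heterogeneity analysis for promoter
methylation covariates: censoring-aware heterogeneity diagnostics,
correlation-adjusted score screening, and a sparse (SCAD-penalized) finite
mixture of log-normal accelerated failure time regressions fitted by EM,
with component-wise BIC tuning and BIC order selection. A synthetic-data
module generates censored mixture cohorts with known truth.
"""

from importlib import resources

import pandas as pd

from .survival_data import (  # noqa: F401
    GeneMethylationMatrix,
    PromoterMap,
    SurvivalDataset,
    SurvivalRecord,
    aggregate_promoter_methylation,
    build_dataset,
    read_dataset,
    read_methylation_matrix,
    read_promoter_bed,
    read_survival_table,
    write_dataset,
)
from .synthetic import (  # noqa: F401
    SimConfig,
    SimulatedDataset,
    default_scenario,
    simulate_covariates,
    simulate_dataset,
    simulate_survival,
)
from .diagnostics import (  # noqa: F401
    BicScan,
    StepFunction,
    gaussian_mixture_bic_scan,
    ipc_weights,
    kaplan_meier,
    weighted_log_density,
)
from .screening import (  # noqa: F401
    ScreeningResult,
    car_scores,
    ipcw_marginal_correlations,
    screen_dataset,
    select_top,
)
from .mixture import (  # noqa: F401
    FitResult,
    MixtureAFTModel,
    OrderSelection,
    PenaltyConfig,
    active_genes,
    censored_moments,
    classify,
    component_loglik,
    e_step,
    fit_em,
    m_step,
    mixture_loglik,
    penalized_loglik,
    scad,
    scad_deriv,
    select_order,
    tune_lambdas,
)

__version__ = "0.1.0"


def load_crc_coefficients() -> pd.DataFrame:
    """Published two-component coefficient estimates for the 99 CRC genes.

    A transcription of the coefficient table from the colorectal-cancer
    methylation study this package's analysis follows: one row per gene with
    the estimated effect in each mixture component (``beta_component1``,
    ``beta_component2``). Used for active-set counting demonstrations.
    """
    ref = resources.files("aftmix.data") / "crc_two_component_coefficients.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def crc_coefficient_model() -> MixtureAFTModel:
    """The published coefficient table wrapped as a two-component model.

    Intercepts, scales and mixing proportions are placeholders (the source
    reports only the gene effects); the object supports active-set queries.
    """
    import numpy as np

    df = load_crc_coefficients()
    beta = np.vstack([df["beta_component1"].to_numpy(),
                      df["beta_component2"].to_numpy()])
    return MixtureAFTModel(K=2, pi=np.array([0.46, 0.54]),
                           beta0=np.zeros(2), beta=beta,
                           sigma=np.ones(2), gene_names=list(df["gene"]))
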