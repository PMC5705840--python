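"""Deterministic forward model of cellular bioenergetics under heteroplasmy.

A single mutant-load fraction h drives a chain of algebraic relations:
wild-type mtDNA N+ = N(1-h); ETC mRNA set by the balance of transcription
and a sigmoidally decreasing degradation rate; ETC protein scaling with
both N+ and ETC mRNA; glycolysis mRNA following a continuous
constant-then-linear changepoint spline at the critical heteroplasmy
h_star; cell volume as the weighted power-supply sum of OXPHOS protein and
glycolysis transcripts (supply = demand); growth rate inversely
proportional to volume; and maximum respiratory capacity linear in ETC
protein.

All functions accept scalar or array heteroplasmy and broadcast.  Outputs
are in normalized per-cell units (N = 1); the observable features are fit
as fold-changes relative to h = 0, see :func:`normalized_predictions`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .parameters import FixedConstants, ModelParameters

__all__ = [
    "FEATURES",
    "OBSERVABLE_FEATURES",
    "wildtype_copy_number",
    "mrna_degradation_rate",
    "etc_mrna",
    "etc_protein",
    "glycolysis_mrna",
    "cell_volume",
    "growth_rate",
    "max_respiratory_capacity",
    "oxphos_fraction",
    "predict_all",
    "normalized_predictions",
    "predictions_to_tidy",
]

#: The seven observable features the model describes.
OBSERVABLE_FEATURES: tuple[str, ...] = (
    "N_plus",
    "M_ETC",
    "P_plus",
    "M_gly",
    "V",
    "G",
    "R_max",
)

#: All prediction columns, including derived diagnostic quantities.
FEATURES: tuple[str, ...] = OBSERVABLE_FEATURES + (
    "delta_m",
    "density",
    "oxphos_fraction",
)


def _check_h(h) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("heteroplasmy h must lie in [0, 1]")
    return h


def wildtype_copy_number(h, N: float = 1.0):
    """Wild-type mtDNA copy number N+ = N (1 - h)."""
    h = _check_h(h)
    if not N > 0:
        raise ValueError(f"N must be positive, got {N}")
    return N * (1.0 - h)


def mrna_degradation_rate(h, params: ModelParameters):
    """Sigmoidal ETC mRNA degradation rate.

    delta_m(h) = k_mRNA / (1 + exp(k_m (h - h0))).  Evaluated through the
    logistic function so extreme steepness returns the exact asymptotes
    (0 and k_mRNA) instead of overflowing.
    """
    h = _check_h(h)
    return params.k_mRNA * expit(-params.k_m * (h - params.h0))


def etc_mrna(h, params: ModelParameters, N: float = 1.0):
    """ETC mRNA pool size M_ETC = beta / (delta_m(h) + 1) * N+(h)."""
    h = _check_h(h)
    return params.beta / (mrna_degradation_rate(h, params) + 1.0) * wildtype_copy_number(h, N)


def etc_protein(h, params: ModelParameters, N: float = 1.0):
    """ETC protein P+ = N+(h) M_ETC(h) / delta_p.

    Protein synthesis scales with both the wild-type template count and the
    transcript pool (a strong local genotype-phenotype link), giving the
    quadratic-in-N+ structure.
    """
    if not params.delta_p > 0:
        raise ValueError(f"delta_p must be positive, got {params.delta_p}")
    h = _check_h(h)
    return wildtype_copy_number(h, N) * etc_mrna(h, params, N) / params.delta_p


def glycolysis_mrna(h, params: ModelParameters):
    """Glycolysis mRNA: constant c1 up to h_star, then linear.

    M_gly = c1 for h <= h_star and m2 h + c2 for h > h_star with
    c2 = c1 - m2 h_star, so the spline is continuous; the boundary point
    itself belongs to the constant branch.
    """
    h = _check_h(h)
    return np.where(h <= params.h_star, params.c1, params.m2 * h + params.c2)


def cell_volume(P_plus, M_gly, params: ModelParameters):
    """Cell volume from power supply = power demand: V = k_o P+ + k_g M_gly."""
    P_plus = np.asarray(P_plus, dtype=float)
    M_gly = np.asarray(M_gly, dtype=float)
    if np.any(P_plus < 0) or np.any(M_gly < 0):
        raise ValueError("P_plus and M_gly must be non-negative")
    return params.k_o * P_plus + params.k_g * M_gly

def growth_rate(V, params: ModelParameters):
    """Population growth rate G = k_gr / V (smaller cells proliferate faster)."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("cell volume must be strictly positive")
    return params.k_gr / V


def max_respiratory_capacity(P_plus, params: ModelParameters):
    """Maximum respiratory capacity R_max = k_p P+."""
    P_plus = np.asarray(P_plus, dtype=float)
    if np.any(P_plus < 0):
        raise ValueError("P_plus must be non-negative")
    return params.k_p * P_plus


def oxphos_fraction(P_plus, M_gly, params: ModelParameters):
    """Relative OXPHOS contribution to power supply.

    k_o P+ / (k_o P+ + k_g M_gly), in [0, 1].  Raises on a zero
    denominator (no power supply at all).
    """
    supply_o = params.k_o * np.asarray(P_plus, dtype=float)
    supply_g = params.k_g * np.asarray(M_gly, dtype=float)
    total = supply_o + supply_g
    if np.any(total <= 0):
        raise ValueError("total power supply must be positive")
    return supply_o / total


def predict_all(
    h_grid,
    params: ModelParameters,
    constants: FixedConstants = FixedConstants(),
) -> pd.DataFrame:
    """Evaluate every model feature on a heteroplasmy grid.

    Returns a DataFrame indexed by ``h`` with one column per entry of
    :data:`FEATURES`: the seven observables plus the degradation rate,
    wild-type mtDNA density N+/V and the OXPHOS supply fraction.
    """
    h = _check_h(np.atleast_1d(h_grid))
    N = constants.N
    n_plus = wildtype_copy_number(h, N)
    delta_m = mrna_degradation_rate(h, params)
    m_etc = etc_mrna(h, params, N)
    p_plus = etc_protein(h, params, N)
    m_gly = glycolysis_mrna(h, params)
    volume = cell_volume(p_plus, m_gly, params)
    return pd.DataFrame(
        {
            "N_plus": n_plus,
            "M_ETC": m_etc,
            "P_plus": p_plus,
            "M_gly": m_gly,
            "V": volume,
            "G": growth_rate(volume, params),
            "R_max": max_respiratory_capacity(p_plus, params),
            "delta_m": delta_m,
            "density": n_plus / volume,
            "oxphos_fraction": oxphos_fraction(p_plus, m_gly, params),
        },
        index=pd.Index(h, name="h"),
    )


def normalized_predictions(
    h_grid,
    params: ModelParameters,
    constants: FixedConstants = FixedConstants(),
    features: tuple[str, ...] = OBSERVABLE_FEATURES,
) -> pd.DataFrame:
    """Observable features as fold-changes relative to h = 0.

    This is the scale on which the data are fit: every observable equals 1
    at h = 0.  The grid need not contain 0; the reference is always
    evaluated at h = 0 exactly.
    """
    h = np.atleast_1d(np.asarray(h_grid, dtype=float))
    pred = predict_all(h, params, constants)
    ref = predict_all([0.0], params, constants).iloc[0]
    return pred[list(features)] / ref[list(features)]


def predictions_to_tidy(pred: pd.DataFrame) -> pd.DataFrame:
    """Reshape a prediction table to tidy (h, feature, value) rows."""
    return (
        pred.reset_index()
        .melt(id_vars="h", var_name="feature", value_name="value")
        .sort_values(["feature", "h"], kind="stable")
        .reset_index(drop=True)
    )
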