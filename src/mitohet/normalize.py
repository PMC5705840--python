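"""Raw tables -> normalized per-cell feature table with uncertainties.

The pipeline has four stages:

1. Pathway-level expression: per-gene RPKM is normalized to its own h = 0
   replicate mean and averaged over genes and replicates, yielding a
   dimensionless fold-change E-bar whose value at h = 0 is exactly 1, with
   a standard error over technical replicates.
2. Per-cell transform: RPKM (and normalized Western-blot protein) are
   concentrations, so per-cell amounts are obtained by multiplying by mean
   cell volume; first-order Gaussian error propagation combines the
   expression SEM with the volume SEM.
3. Growth rate: ordinary least squares of log cell count on day, truncated
   at day 5 where growth saturates; the slope's standard error is the
   uncertainty.
4. Assembly: all seven features are re-scaled so the h = 0 value is 1
   (fold-change scale) and rows above the model's domain limit h = 0.9 are
   flagged as excluded from fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import RawStudyBundle

__all__ = [
    "normalized_pathway_expression",
    "pathway_expression_sem",
    "per_cell_transform",
    "propagate_uncertainty",
    "protein_feature",
    "growth_rate_regression",
    "assemble_feature_table",
    "write_feature_table",
    "read_feature_table",
]

#: ETC complexes whose protein levels enter the model (ATP synthase excluded).
PROTEIN_COMPLEXES = frozenset({"I", "III", "IV"})
_ATP_SYNTHASE_NAMES = frozenset({"V", "ATP synthase", "ATP_SYNTHASE", "CV"})

H_FIT_MAX = 0.9  # model domain limit; h = 1 data are never fit


def _reference_gene_means(reference: pd.DataFrame) -> pd.Series:
    means = reference.groupby("gene")["rpkm"].mean()
    zero = means[means <= 0]
    if len(zero):
        raise ZeroDivisionError(
            "h = 0 replicate mean is non-positive for gene(s): "
            + ", ".join(zero.index.astype(str))
        )
    return means


def _replicate_sums(records: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Per-replicate sums over genes of e_{i,k}(h) / mean_l e_{i,l}(0)."""
    ref_means = _reference_gene_means(reference)
    genes_h = set(records["gene"])
    if genes_h != set(ref_means.index):
        raise ValueError(
            "gene sets differ between measurement and h = 0 reference: "
            f"only-at-h={sorted(genes_h - set(ref_means.index))}, "
            f"only-at-reference={sorted(set(ref_means.index) - genes_h)}"
        )
    ratios = records["rpkm"] / records["gene"].map(ref_means)
    return ratios.groupby(records["replicate"]).sum().to_numpy()


def normalized_pathway_expression(records: pd.DataFrame, reference: pd.DataFrame) -> float:
    """Fold-change pathway expression E-bar at one heteroplasmy level.

    E-bar = (1/N)(1/n_r) sum_k sum_i e_{i,k}(h) / [(1/n_r') sum_l e_{i,l}(0)]
    with N genes and n_r technical replicates.  Normalizing each gene by its
    own h = 0 mean prevents highly expressed genes from dominating; the 1/N
    factor makes E-bar equal 1 at h = 0.  The reference may carry a
    different replicate count than the measurement.
    """
    n_genes = records["gene"].nunique()
    sums = _replicate_sums(records, reference)
    return float(sums.mean() / n_genes)


def pathway_expression_sem(records: pd.DataFrame, reference: pd.DataFrame) -> float:
    """Standard error of E-bar over technical replicates.

    s = (1/N) sqrt( (1/n_r) Var_k[ sum_i e_{i,k}(h)/ref_i ] ) with Var_k the
    sample variance over replicates; undefined for a single replicate.
    """
    n_genes = records["gene"].nunique()
    sums = _replicate_sums(records, reference)
    if len(sums) < 2:
        raise ValueError(
            "expression SEM requires >= 2 technical replicates; "
            "use a surrogate uncertainty for single-replicate data"
        )
    return float(np.sqrt(sums.var(ddof=1) / len(sums)) / n_genes)


def per_cell_transform(e_bar: float, V: float) -> float:
    """Concentration fold-change -> per-cell amount: multiply by cell volume."""
    if not V > 0:
        raise ValueError(f"cell volume must be positive, got {V}")
    return e_bar * V


def propagate_uncertainty(e_bar: float, s_e_bar: float, V: float, s_V: float) -> float:
    """First-order uncertainty of the product e_bar * V.

    sqrt(e_bar^2 s_V^2 + V^2 s_e_bar^2); symmetric under exchanging
    (e_bar, s_V) with (V, s_e_bar).
    """
    if min(e_bar, s_e_bar, V, s_V) < 0:
        raise ValueError("all inputs must be non-negative")
    return float(np.sqrt(e_bar**2 * s_V**2 + V**2 * s_e_bar**2))


def protein_feature(protein_records: pd.DataFrame, V: float, s_V: float) -> tuple[float, float]:
    """Per-cell ETC protein value and surrogate uncertainty at one level.

    Western-blot levels are single-replicate, so no SEM exists; the value is
    the sample mean over complexes I, III and IV times cell volume, and the
    uncertainty surrogate is the normalized protein value multiplied by the
    volume SEM.
    """
    present = set(protein_records["complex"].astype(str))
    atp = present & _ATP_SYNTHASE_NAMES
    if atp:
        raise ValueError(
            f"ATP synthase rows present ({sorted(atp)}): ATP synthase is excluded "
            "from ETC protein data because it is regulated independently of "
            "respiratory activity"
        )
    if present != PROTEIN_COMPLEXES:
        raise ValueError(
            f"expected exactly complexes I, III, IV; got {sorted(present)}"
        )
    normalized = float(protein_records["level"].mean())
    return per_cell_transform(normalized, V), normalized * s_V


def growth_rate_regression(growth_records: pd.DataFrame, day_max: float = 5.0) -> tuple[float, float]:
    """Exponential growth rate by log-lin OLS on days 0..day_max.

    Growth saturates beyond day 5, so later observations are discarded
    before regressing ln(count) on day.  Returns (slope, SE of slope).
    """
    kept = growth_records[growth_records["day"] <= day_max]
    if len(kept) < 3:
        raise ValueError(f"need >= 3 observations at day <= {day_max}, got {len(kept)}")
    counts = kept["count"].to_numpy(dtype=float)
    if np.any(counts <= 0):
        raise ValueError("cell counts must be strictly positive for log-lin regression")
    fit = stats.linregress(kept["day"].to_numpy(dtype=float), np.log(counts))
    stderr = 0.0 if np.isnan(fit.stderr) else float(fit.stderr)
    return float(fit.slope), stderr


def _volume_at(volumes: pd.DataFrame, h: float) -> tuple[float, float]:
    row = volumes[volumes["h"] == h]
    if len(row) != 1:
        raise ValueError(f"expected exactly one volume row at h={h}, got {len(row)}")
    return float(row["volume"].iloc[0]), float(row["sem"].iloc[0])


def assemble_feature_table(
    bundle: RawStudyBundle,
    renormalize_rates: bool = True,
    h_fit_max: float = H_FIT_MAX,
) -> pd.DataFrame:
    """Build the normalized per-cell feature table from a raw bundle.

    Returns tidy rows (h, feature, value, uncertainty, excluded_from_fit)
    for the seven features N_plus, M_ETC, P_plus, M_gly, V, G, R_max.  Every
    feature is scaled so its h = 0 value is exactly 1 (uncertainties scaled
    by the same factor); with ``renormalize_rates=False`` growth rate and
    respiratory capacity keep their measured units.  N_plus carries the
    parameter-free line 1 - h with zero uncertainty and is never part of the
    likelihood.  Rows with h > h_fit_max are flagged excluded_from_fit but
    retained for plotting.
    """
    h_levels = sorted(set(bundle.volumes["h"]))
    gaps = []
    for name, col in (("expression", "h"), ("growth", "h"), ("protein", "h"), ("respiration", "h")):
        missing = set(h_levels) - set(getattr(bundle, name)[col])
        if missing:
            gaps.append(f"{name}: missing h levels {sorted(missing)}")
    if 0.0 not in h_levels:
        gaps.append("volumes: no h = 0 reference level")
    if gaps:
        raise ValueError("incomplete bundle: " + "; ".join(gaps))

    expr = bundle.expression
    rows: list[dict] = []
    for pathway, feature in (("etc", "M_ETC"), ("glycolysis", "M_gly")):
        sub = expr[expr["pathway"] == pathway]
        if sub.empty:
            raise ValueError(f"incomplete bundle: no expression rows for pathway {pathway!r}")
        reference = sub[sub["h"] == 0.0]
        for h in h_levels:
            rec = sub[sub["h"] == h]
            e_bar = normalized_pathway_expression(rec, reference)
            s_e = pathway_expression_sem(rec, reference)
            V, s_V = _volume_at(bundle.volumes, h)
            rows.append(
                {
                    "h": h,
                    "feature": feature,
                    "value": per_cell_transform(e_bar, V),
                    "uncertainty": propagate_uncertainty(e_bar, s_e, V, s_V),
                }
            )

    for h in h_levels:
        V, s_V = _volume_at(bundle.volumes, h)
        value, unc = protein_feature(bundle.protein[bundle.protein["h"] == h], V, s_V)
        rows.append({"h": h, "feature": "P_plus", "value": value, "uncertainty": unc})
        rows.append({"h": h, "feature": "V", "value": V, "uncertainty": s_V})
        slope, se = growth_rate_regression(bundle.growth[bundle.growth["h"] == h])
        rows.append({"h": h, "feature": "G", "value": slope, "uncertainty": se})
        resp = bundle.respiration[bundle.respiration["h"] == h]["value"].to_numpy(dtype=float)
        sem = float(resp.std(ddof=1) / np.sqrt(len(resp))) if len(resp) > 1 else 0.0
        rows.append({"h": h, "feature": "R_max", "value": float(resp.mean()), "uncertainty": sem})
        rows.append({"h": h, "feature": "N_plus", "value": 1.0 - h, "uncertainty": 0.0})

    table = pd.DataFrame(rows)

    # rescale to fold-change vs h = 0 (N_plus is already on that scale)
    always = {"M_ETC", "M_gly", "P_plus", "V"}
    rates = {"G", "R_max"} if renormalize_rates else set()
    for feature in always | rates:
        mask = table["feature"] == feature
        ref = float(table.loc[mask & (table["h"] == 0.0), "value"].iloc[0])
        if not ref > 0:
            raise ValueError(f"h = 0 reference value for {feature} must be positive, got {ref}")
        table.loc[mask, ["value", "uncertainty"]] /= ref

    table["excluded_from_fit"] = table["h"] > h_fit_max
    return (
        table.sort_values(["feature", "h"], kind="stable").reset_index(drop=True)
    )


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"h", "feature", "value", "uncertainty", "excluded_from_fit"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return table
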