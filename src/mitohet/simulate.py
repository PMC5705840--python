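"""Synthetic cybrid-study generator.

The cybrid dataset the model was designed around is not publicly deposited,
so every downstream stage is exercised on synthetic bundles with the same
structure: per-gene RPKM for the mitochondrially encoded ETC panel and a
glycolysis panel across ~7 heteroplasmy levels with technical replicates,
mean cell volume with SEM, daily cell counts that saturate after day 5,
normalized ETC protein for complexes I/III/IV (single replicate), and
per-cell maximum respiratory capacity.

RPKM is treated as a concentration: the generator takes the model's
per-cell feature F(h), converts it to a concentration fold-change
F(h)/F(0) * V(0)/V(h), and scales by a per-gene baseline, so that the
per-cell normalization pipeline inverts the construction exactly when
noise is switched off.  The true generating parameters travel with the
bundle as ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import normalized_predictions, predict_all
from .parameters import FixedConstants, ModelParameters

__all__ = [
    "ETC_GENES",
    "GLYCOLYSIS_GENES",
    "SyntheticStudyConfig",
    "RawStudyBundle",
    "default_true_parameters",
    "generate_expression",
    "generate_volumes",
    "generate_growth_curves",
    "generate_protein",
    "generate_respiration",
    "generate_study",
    "write_bundle",
    "read_bundle",
]

#: Mitochondrially encoded ETC subunit panel (ATP synthase excluded).
ETC_GENES: tuple[str, ...] = (
    "COX3", "ND2", "ND5", "CYTB", "ND3", "ND6",
    "COX1", "ND4", "COX2", "ND1", "ND4L",
)

#: Glycolysis enzyme/transporter panel.
GLYCOLYSIS_GENES: tuple[str, ...] = (
    "PKM2", "ENO1", "PGAM4", "PGK1", "GAPDH",
    "ALDOA", "PFKP", "GPI", "HK2", "SLC2A1",
)

# Fixed plausible baseline RPKM per gene; mitochondrial transcripts are
# highly expressed relative to nuclear glycolysis genes.
_DEFAULT_BASELINES: dict[str, float] = {
    **{g: b for g, b in zip(ETC_GENES, (820.0, 410.0, 350.0, 640.0, 290.0, 180.0,
                                        950.0, 470.0, 700.0, 530.0, 240.0))},
    **{g: b for g, b in zip(GLYCOLYSIS_GENES, (160.0, 210.0, 45.0, 130.0, 390.0,
                                               240.0, 75.0, 110.0, 60.0, 95.0))},
}


def default_true_parameters() -> ModelParameters:
    """Ground-truth parameters used by default for synthetic studies.

    Chosen so the forward model reproduces the qualitative phenotype of
    MELAS cybrids: ETC transcripts dip then transiently recover, glycolysis
    doubles by h = 0.9, cell volume reaches its minimum near the critical
    heteroplasmy h* = 0.4, and the degradation sigmoid collapses shortly
    above h*.
    """
    return ModelParameters(
        beta=1.0,
        k_mRNA=4.0,
        k_m=20.0,
        h0=0.42,
        delta_p=1.0,
        c1=1.0,
        m2=2.0,
        h_star=0.4,
        k_o=5.0,
        k_g=1.0,
        k_gr=1.0,
        k_p=1.0,
    )


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Everything needed to generate one synthetic cybrid study."""

    true_params: ModelParameters = field(default_factory=default_true_parameters)
    h_grid: tuple[float, ...] = (0.0, 0.2, 0.3, 0.5, 0.6, 0.9, 1.0)
    n_replicates: int = 3
    etc_genes: tuple[str, ...] = ETC_GENES
    gly_genes: tuple[str, ...] = GLYCOLYSIS_GENES
    gene_baselines: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINES))
    rna_cv: float = 0.05
    volume_cv: float = 0.03
    protein_cv: float = 0.05
    respiration_cv: float = 0.05
    count_cv: float = 0.02
    initial_count: float = 5e4
    days: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    capacity: float = 5e6
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.h_grid:
            raise ValueError("h_grid must contain the h = 0 reference level")
        for name in ("rna_cv", "volume_cv", "protein_cv", "respiration_cv", "count_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        missing = [g for g in self.etc_genes + self.gly_genes if g not in self.gene_baselines]
        if missing:
            raise ValueError(f"gene_baselines missing entries for {missing}")
        if any(b <= 0 for b in self.gene_baselines.values()):
            raise ValueError("all gene baselines must be positive")

    def without_noise(self) -> "SyntheticStudyConfig":
        return dataclasses.replace(
            self, rna_cv=0.0, volume_cv=0.0, protein_cv=0.0,
            respiration_cv=0.0, count_cv=0.0,
        )

    def replace(self, **changes) -> "SyntheticStudyConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class RawStudyBundle:
    """Raw tables of one (synthetic) study plus its generating ground truth."""

    expression: pd.DataFrame   # pathway, gene, h, replicate, rpkm
    volumes: pd.DataFrame      # h, volume, sem
    growth: pd.DataFrame       # h, day, count
    protein: pd.DataFrame      # complex, h, level
    respiration: pd.DataFrame  # h, replicate, value
    ground_truth_params: ModelParameters | None = None
    ground_truth_features: pd.DataFrame | None = None  # tidy h, feature, value


def _rng(config: SyntheticStudyConfig, stream: int) -> np.random.Generator:
    # per-table streams so each generator is independently reproducible
    return np.random.default_rng([config.seed, stream])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative mean-1 log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_expression(
    config: SyntheticStudyConfig,
    pathway: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene RPKM records for one pathway.

    rpkm(i, k, h) = baseline_i * F(h)/F(0) * V(0)/V(h) * noise, where F is
    the per-cell model feature of the pathway (M_ETC or M_gly) and the
    volume ratio converts the per-cell amount to a concentration.
    """
    if pathway == "etc":
        genes, feature, stream = config.etc_genes, "M_ETC", 1
    elif pathway == "glycolysis":
        genes, feature, stream = config.gly_genes, "M_gly", 2
    else:
        raise ValueError(f"unknown pathway {pathway!r}; expected 'etc' or 'glycolysis'")
    if rng is None:
        rng = _rng(config, stream)

    h = np.asarray(config.h_grid, dtype=float)
    pred = predict_all(h, config.true_params)
    ref = predict_all([0.0], config.true_params).iloc[0]
    concentration = (pred[feature] / ref[feature]) * (ref["V"] / pred["V"])

    rows = []
    for hv, conc in zip(h, concentration.to_numpy()):
        noise = _lognormal_factor(rng, config.rna_cv, (len(genes), config.n_replicates))
        for i, gene in enumerate(genes):
            for k in range(config.n_replicates):
                rows.append(
                    {
                        "pathway": pathway,
                        "gene": gene,
                        "h": hv,
                        "replicate": k + 1,
                        "rpkm": config.gene_baselines[gene] * conc * noise[i, k],
                    }
                )
    return pd.DataFrame(rows)


def generate_volumes(
    config: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Mean cell volume with SEM per heteroplasmy level."""
    if rng is None:
        rng = _rng(config, 3)
    h = np.asarray(config.h_grid, dtype=float)
    v_true = predict_all(h, config.true_params)["V"].to_numpy()
    sem = config.volume_cv * v_true
    volume = v_true + rng.normal(0.0, sem) if config.volume_cv > 0 else v_true.copy()
    return pd.DataFrame({"h": h, "volume": volume, "sem": sem})


def generate_growth_curves(
    config: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Daily cell counts: exponential through day 5, logistic saturation after.

    Days 0-5 follow n0 exp(G(h) t) exactly (up to multiplicative noise);
    later days continue along a logistic curve capped at the configured
    carrying capacity, emulating the saturation that motivates the day-5
    truncation in the growth-rate regression.
    """
    if rng is None:
        rng = _rng(config, 4)
    h = np.asarray(config.h_grid, dtype=float)
    g_true = growth_rates_from_truth(config)
    rows = []
    for hv, g in zip(h, g_true):
        n5 = config.initial_count * np.exp(g * 5.0)
        for day in config.days:
            if day <= 5 or not np.isfinite(config.capacity):
                count = config.initial_count * np.exp(g * day)
            else:
                grown = np.exp(g * (day - 5.0))
                count = config.capacity * n5 * grown / (config.capacity + n5 * (grown - 1.0))
            count *= _lognormal_factor(rng, config.count_cv, ())
            rows.append({"h": hv, "day": day, "count": count})
    return pd.DataFrame(rows)


def growth_rates_from_truth(config: SyntheticStudyConfig) -> np.ndarray:
    """True growth rate G(h) on the configured grid."""
    h = np.asarray(config.h_grid, dtype=float)
    return predict_all(h, config.true_params)["G"].to_numpy()


def generate_protein(
    config: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Normalized ETC protein levels for complexes I, III and IV.

    Western-blot data arrive already normalized and concentration-like: the
    shared mean is [P+(h)/V(h)] / [P+(0)/V(0)], one technical replicate per
    complex, so the per-cell transform and h = 0 renormalization downstream
    recover P+(h)/P+(0).
    """
    if rng is None:
        rng = _rng(config, 5)
    h = np.asarray(config.h_grid, dtype=float)
    pred = predict_all(h, config.true_params)
    ref = predict_all([0.0], config.true_params).iloc[0]
    level = (pred["P_plus"] / pred["V"]).to_numpy() / (ref["P_plus"] / ref["V"])
    rows = []
    for cx in ("I", "III", "IV"):
        noise = _lognormal_factor(rng, config.protein_cv, len(h))
        for hv, mean, nz in zip(h, level, noise):
            rows.append({"complex": cx, "h": hv, "level": mean * nz})
    return pd.DataFrame(rows)


def generate_respiration(
    config: SyntheticStudyConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-cell maximum respiratory capacity, replicated measurements.

    Respirometry is already per-cell, so values are k_p P+(h) plus additive
    Gaussian noise — no volume transform applies downstream.
    """
    if rng is None:
        rng = _rng(config, 6)
    h = np.asarray(config.h_grid, dtype=float)
    r_true = predict_all(h, config.true_params)["R_max"].to_numpy()
    rows = []
    for hv, r in zip(h, r_true):
        for k in range(config.n_replicates):
            noise = rng.normal(0.0, config.respiration_cv * r) if config.respiration_cv > 0 else 0.0
            rows.append({"h": hv, "replicate": k + 1, "value": r + noise})
    return pd.DataFrame(rows)


def generate_study(config: SyntheticStudyConfig) -> RawStudyBundle:
    """Compose all tables into a bundle, attaching the generating truth."""
    etc = generate_expression(config, "etc")
    gly = generate_expression(config, "glycolysis")
    truth = normalized_predictions(config.h_grid, config.true_params)
    truth_tidy = (
        truth.reset_index()
        .melt(id_vars="h", var_name="feature", value_name="value")
        .sort_values(["feature", "h"], kind="stable")
        .reset_index(drop=True)
    )
    return RawStudyBundle(
        expression=pd.concat([etc, gly], ignore_index=True),
        volumes=generate_volumes(config),
        growth=generate_growth_curves(config),
        protein=generate_protein(config),
        respiration=generate_respiration(config),
        ground_truth_params=config.true_params,
        ground_truth_features=truth_tidy,
    )


_TABLES = ("expression", "volumes", "growth", "protein", "respiration")


def write_bundle(bundle: RawStudyBundle, out_dir: str | Path) -> dict[str, int]:
    """Write the bundle as tidy TSVs plus ground_truth.json; return row counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name in _TABLES:
        df: pd.DataFrame = getattr(bundle, name)
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        manifest[name] = len(df)
    if bundle.ground_truth_params is not None:
        truth = {"params": bundle.ground_truth_params.to_dict()}
        if bundle.ground_truth_features is not None:
            truth["features"] = bundle.ground_truth_features.to_dict(orient="list")
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return manifest


def read_bundle(in_dir: str | Path) -> RawStudyBundle:
    """Read a bundle previously written by :func:`write_bundle`."""
    src = Path(in_dir)
    tables = {}
    for name in _TABLES:
        path = src / f"{name}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"bundle table missing: {path}")
        tables[name] = pd.read_csv(path, sep="\t")
    params = features = None
    gt = src / "ground_truth.json"
    if gt.exists():
        payload = json.loads(gt.read_text())
        params = ModelParameters.from_dict(payload["params"])
        if "features" in payload:
            features = pd.DataFrame(payload["features"])
    return RawStudyBundle(
        **tables, ground_truth_params=params, ground_truth_features=features
    )
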