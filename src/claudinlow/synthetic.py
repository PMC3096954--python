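"""Synthetic expression cohorts with claudin-low-style subtype structure.

The generator emulates the statistical shape of an intrinsic-subtype breast
cancer compendium: six tumor subtypes (luminal A/B, HER2-enriched, basal-like,
claudin-low and a normal breast-like group) whose expression differs through
coherent shifts of small gene modules (luminal differentiation, proliferation,
basal keratins, claudin/adhesion, EMT, immune, stromal, stem-cell), on top of
a large background of null genes with pure noise.  Claudin-low tumors are
built with low claudin/adhesion and luminal modules, high EMT/immune/stromal/
stem modules and low proliferation; basal-like tumors with high basal keratins
and proliferation and low luminal expression.

Companion generators produce a contamination-free cell-line panel (no immune/
stromal admixture, no normal-like class) and FACS-purified mammary epithelial
populations (MaSC, pL, mL) with ordered luminal differentiation, plus clinical
tables with subtype-dependent receptor status, pathological complete response
and exponential survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SUBTYPES",
    "MODULES",
    "SyntheticConfig",
    "gene_modules",
    "generate_tumor_cohort",
    "generate_cell_line_panel",
    "generate_sorted_populations",
]

SUBTYPES = ("LumA", "LumB", "HER2E", "Basal", "ClaudinLow", "NormalLike")
MODULES = (
    "luminal",
    "proliferation",
    "basal_keratin",
    "claudin_adhesion",
    "emt",
    "immune",
    "stromal",
    "stem",
)
#: single dedicated HER2 amplicon marker gene (ERBB2 analog)
HER2_MARKER = "ERBB2_MARKER"
#: analogs used for the CD44/CD24 stemness contrast in the cell-line panel
CD44_ANALOG = "STEM_001"
CD24_ANALOG = "LUM_001"

_MODULE_PREFIX = {
    "luminal": "LUM",
    "proliferation": "PROLIF",
    "basal_keratin": "KRT",
    "claudin_adhesion": "CLDN",
    "emt": "EMT",
    "immune": "IMM",
    "stromal": "STROMA",
    "stem": "STEM",
}

# per-subtype module shifts, in units of effect_size
_TUMOR_PATTERN: dict[str, dict[str, float]] = {
    "LumA": {"luminal": 1.0, "proliferation": -0.5},
    "LumB": {"luminal": 1.0, "proliferation": 1.0},
    "HER2E": {"luminal": 0.25, "proliferation": 0.5},
    # basal-like keeps partial luminal keratin expression (-0.75); claudin-low
    # loses luminal differentiation markers entirely (-1.0)
    "Basal": {"basal_keratin": 1.0, "luminal": -0.75, "proliferation": 1.0},
    "ClaudinLow": {
        "claudin_adhesion": -1.0,
        "luminal": -1.0,
        "emt": 1.0,
        "immune": 1.0,
        "stromal": 1.0,
        "stem": 1.0,
        "proliferation": -0.5,
    },
    "NormalLike": {
        "stromal": 1.0,
        "immune": 0.5,
        "luminal": 0.5,
        "proliferation": -0.5,
        "claudin_adhesion": 0.25,
    },
}

# immune/stromal admixture profile added to tumors (convex mixture)
_CONTAMINATION_PATTERN = {"immune": 1.0, "stromal": 1.0}

_SORTED_PATTERN = {
    "MaSC": {"luminal": -1.0, "stem": 1.0, "emt": 1.0},
    "pL": {},
    "mL": {"luminal": 1.0, "stem": -1.0, "emt": -1.0},
    "Stromal": {"stromal": 1.0, "immune": 0.5, "luminal": -1.0, "stem": 0.5},
}

# receptor-status probabilities: (P(triple negative), P(er), P(pr|er), P(her2))
_RECEPTORS = {
    "LumA": (0.0, 0.90, 0.85, 0.10),
    "LumB": (0.0, 0.90, 0.70, 0.20),
    "HER2E": (0.0, 0.30, 0.50, 0.90),
    "Basal": (0.85, 0.30, 0.40, 0.30),
    "ClaudinLow": (0.85, 0.30, 0.40, 0.30),
    "NormalLike": (0.0, 0.60, 0.70, 0.10),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the log2 shift of a fully activated/repressed module;
    ``noise_sd`` the per-gene Gaussian noise; ``contamination_fraction`` the
    convex immune/stromal admixture applied to tumors (never to cell lines).
    pCR probabilities default to the neoadjuvant response rates of claudin-low
    (38.9%) and basal-like (73.3%) tumors, with luminal tumors far lower.
    Survival is exponential with per-subtype monthly hazards scaled so that
    claudin-low carries roughly a 2.8-fold relapse hazard versus luminal A.
    """

    n_per_subtype: dict[str, int] = field(
        default_factory=lambda: {s: 30 for s in SUBTYPES}
    )
    module_sizes: dict[str, int] = field(
        default_factory=lambda: {m: 10 for m in MODULES}
    )
    n_null_genes: int = 900
    effect_size: float = 2.0
    noise_sd: float = 0.5
    contamination_fraction: float = 0.15
    pcr_prob: dict[str, float] = field(
        default_factory=lambda: {
            "LumA": 0.05,
            "LumB": 0.15,
            "HER2E": 0.35,
            "Basal": 0.733,
            "ClaudinLow": 0.389,
            "NormalLike": 0.05,
        }
    )
    hazard_scale: dict[str, float] = field(
        default_factory=lambda: {
            "LumA": 0.004,
            "LumB": 0.010,
            "HER2E": 0.012,
            "Basal": 0.012,
            "ClaudinLow": 0.0113,
            "NormalLike": 0.005,
        }
    )
    n_cell_lines_per_subtype: dict[str, int] = field(
        default_factory=lambda: {
            "LumA": 10,
            "LumB": 8,
            "HER2E": 8,
            "Basal": 12,
            "ClaudinLow": 9,
        }
    )
    n_per_population: int = 20
    include_stromal_population: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (("pcr_prob", self.pcr_prob),):
            for k, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{k}]={p} outside [0, 1]")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction outside [0, 1]")
        for m, size in self.module_sizes.items():
            if size < 1:
                raise ValueError(f"module_sizes[{m}] must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gene_modules(cfg: SyntheticConfig) -> dict[str, list[str]]:
    """Gene identifiers of every module (plus HER2 marker and null genes)."""
    modules = {
        m: [f"{_MODULE_PREFIX[m]}_{i + 1:03d}" for i in range(cfg.module_sizes[m])]
        for m in MODULES
    }
    modules["her2_marker"] = [HER2_MARKER]
    modules["null"] = [f"NULL_{i + 1:04d}" for i in range(cfg.n_null_genes)]
    return modules


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _mean_vector(
    cfg: SyntheticConfig, modules: dict[str, list[str]], pattern: dict[str, float]
) -> pd.Series:
    genes = [g for ids in modules.values() for g in ids]
    mu = pd.Series(0.0, index=genes)
    for module, coef in pattern.items():
        mu.loc[modules[module]] = coef * cfg.effect_size
    return mu


def _expression(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    modules: dict[str, list[str]],
    sample_labels: list[tuple[str, str]],
    patterns: dict[str, dict[str, float]],
    contamination: float,
) -> pd.DataFrame:
    means = {
        label: _mean_vector(cfg, modules, patterns[label])
        for label in {lab for _, lab in sample_labels}
    }
    contam = _mean_vector(cfg, modules, _CONTAMINATION_PATTERN)
    cols = {}
    for sample_id, label in sample_labels:
        mu = (1.0 - contamination) * means[label] + contamination * contam
        cols[sample_id] = mu + rng.normal(0.0, cfg.noise_sd, size=len(mu))
    m = pd.DataFrame(cols)
    m.index = means[sample_labels[0][1]].index
    m.index.name = "gene_id"
    return m


def _sample_labels(counts: dict[str, int], prefix: str) -> list[tuple[str, str]]:
    out = []
    for label, n in counts.items():
        if n < 1:
            raise ValueError(f"requested {n} samples for {label}")
        out.extend((f"{prefix}_{label}_{i + 1:03d}", label) for i in range(n))
    return out


def _clinical(
    cfg: SyntheticConfig, rng: np.random.Generator, labels: pd.Series, cohort: str
) -> pd.DataFrame:
    rows = []
    for sample_id, subtype in labels.items():
        p_tn, p_er, p_pr_if_er, p_her2 = _RECEPTORS[subtype]
        if rng.random() < p_tn:
            er = pr = her2 = 0
        else:
            er = int(rng.random() < p_er)
            pr = int(rng.random() < (p_pr_if_er if er else 0.1))
            her2 = int(rng.random() < p_her2)
        pcr = int(rng.random() < cfg.pcr_prob[subtype])
        rate = cfg.hazard_scale[subtype]
        t_rfs = rng.exponential(1.0 / rate)
        t_os = rng.exponential(1.0 / (0.7 * rate))
        c_rfs = rng.uniform(12.0, 120.0)
        c_os = rng.uniform(12.0, 120.0)
        rows.append(
            {
                "sample_id": sample_id,
                "true_subtype": subtype,
                "er": er,
                "pr": pr,
                "her2": her2,
                "pcr": pcr,
                "rfs_time": min(t_rfs, c_rfs),
                "rfs_event": int(t_rfs <= c_rfs),
                "os_time": min(t_os, c_os),
                "os_event": int(t_os <= c_os),
                "cohort": cohort,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_tumor_cohort(
    cfg: SyntheticConfig, cohort: str = "SYN"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a tumor cohort: expression matrix, clinical table, subtype labels.

    Tumors receive an additive immune/stromal contamination admixture at
    ``cfg.contamination_fraction``; triple-negative receptor status is drawn
    with high probability for claudin-low and basal-like tumors, and survival
    times are exponential with subtype-specific hazards under independent
    uniform censoring on [12, 120] months.
    """
    modules = gene_modules(cfg)
    pairs = _sample_labels(cfg.n_per_subtype, cohort)
    rng = _rng(cfg, 1)
    expr = _expression(cfg, rng, modules, pairs, _TUMOR_PATTERN, cfg.contamination_fraction)
    labels = pd.Series({s: lab for s, lab in pairs}, name="true_subtype")
    labels = labels.loc[expr.columns]
    clinical = _clinical(cfg, _rng(cfg, 2), labels, cohort)
    return expr, clinical, labels


def generate_cell_line_panel(cfg: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a contamination-free cell-line panel (no normal-like class).

    Cell cultures contain no admixed immune or stromal cells, so the
    contamination fraction is forced to zero and the immune/stromal modules
    stay at baseline in every line.  The default panel contains nine
    claudin-low lines with high stem (CD44-analog) and low luminal
    (CD24-analog) expression.
    """
    modules = gene_modules(cfg)
    counts = dict(cfg.n_cell_lines_per_subtype)
    counts.pop("NormalLike", None)
    pairs = _sample_labels(counts, "CL")
    # epithelial-only profiles: strip the immune/stromal components
    patterns = {
        s: {m: c for m, c in pat.items() if m not in ("immune", "stromal")}
        for s, pat in _TUMOR_PATTERN.items()
        if s != "NormalLike"
    }
    rng = _rng(cfg, 3)
    expr = _expression(cfg, rng, modules, pairs, patterns, contamination=0.0)
    labels = pd.Series({s: lab for s, lab in pairs}, name="true_subtype").loc[expr.columns]
    return expr, labels


def generate_sorted_populations(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate purified mammary populations: MaSC, pL, mL (optional stromal).

    Luminal-module means increase strictly MaSC < pL < mL while stem and EMT
    modules decrease, reproducing the luminal differentiation hierarchy the
    differentiation predictor is trained on.
    """
    if cfg.n_per_population < 3:
        raise ValueError("need at least 3 samples per sorted population")
    modules = gene_modules(cfg)
    pops = ["MaSC", "pL", "mL"] + (
        ["Stromal"] if cfg.include_stromal_population else []
    )
    pairs = _sample_labels({p: cfg.n_per_population for p in pops}, "POP")
    rng = _rng(cfg, 4)
    expr = _expression(cfg, rng, modules, pairs, _SORTED_PATTERN, contamination=0.0)
    labels = pd.Series({s: lab for s, lab in pairs}, name="population").loc[expr.columns]
    return expr, labels
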