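"""Synthetic multi-batch TMT study generator with ground truth.

Emulates a 4-batch, 18-channel isobaric-tag design with pooled global internal
standard (GIS) channels: 67 biological samples (28 control / 21 AD / 18 PSP),
planted co-expression modules built from a latent factor model, per-protein
batch effects, covariate and diagnosis effects, designated cell-type marker
blocks tied to true mixing proportions, neuron-contaminated outlier samples,
and intensity-dependent (missing-not-at-random) missingness.  Every downstream
stage of the pipeline is testable against the returned ground truth without
downloading anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import AbundanceMatrix

CELL_TYPES = (
    "endothelial",
    "pericyte",
    "smc",
    "fibroblast",
    "astrocyte",
    "microglia",
    "neuron",
    "oligodendrocyte",
    "opc",
)

#: endothelial-dominant mean composition of an isolated-vessel preparation
VASCULAR_MEAN_PROPORTIONS = {
    "endothelial": 0.40,
    "pericyte": 0.08,
    "smc": 0.10,
    "fibroblast": 0.07,
    "astrocyte": 0.09,
    "microglia": 0.07,
    "neuron": 0.06,
    "oligodendrocyte": 0.09,
    "opc": 0.04,
}

#: neuron/oligodendrocyte-dominant composition of bulk cortex
BULK_MEAN_PROPORTIONS = {
    "endothelial": 0.05,
    "pericyte": 0.02,
    "smc": 0.02,
    "fibroblast": 0.02,
    "astrocyte": 0.15,
    "microglia": 0.07,
    "neuron": 0.35,
    "oligodendrocyte": 0.24,
    "opc": 0.08,
}


@dataclass
class StudyConfig:
    """Parameters of the synthetic study.

    The defaults are the study conditions every recovery test runs under; see
    the methods note for the rationale behind each value.
    """

    n_batches: int = 4
    channels_per_batch: int = 18
    gis_per_batch: int = 1
    extra_gis_last_batch: int = 1
    n_control: int = 28
    n_ad: int = 21
    n_psp: int = 18
    n_proteins: int = 2000
    module_sizes: tuple[int, ...] = (300, 150, 80, 40, 20)
    loading_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 0.4
    batch_sd: float = 0.6  # sd of per-protein per-batch log2 effects
    gis_noise_sd: float = 0.05
    # additive log2 diagnosis effects per module; M1 mimics the
    # amyloid/matrisome signature (strongly up in AD, mildly up in PSP, so all
    # three pairwise contrasts separate for its members)
    ad_effects: dict = field(default_factory=lambda: {"M1": 1.0, "M2": -0.8})
    psp_effects: dict = field(default_factory=lambda: {"M4": 0.8, "M1": 0.45})
    # per-module covariate slopes (log2 per unit of the centered covariate)
    age_effects: dict = field(default_factory=lambda: {"M3": 0.05})
    sex_effects: dict = field(default_factory=lambda: {"M4": 0.4})
    pmi_effects: dict = field(default_factory=lambda: {"M5": 0.03})
    n_outliers: int = 5
    missing_fraction: float = 0.10  # overall target; MNAR in intensity
    missing_steepness: float = 1.5
    markers_per_type: int = 15
    marker_floor: float = 0.05  # epsilon in log2(epsilon + scale * proportion)
    marker_scale: float = 4.0
    # cell-type gene lists for enrichment: dedicated markers plus members of
    # the type's associated co-expression module (deconvolution signatures
    # and enrichment lists are distinct, as with scRNA-derived lists)
    celltype_module_map: dict = field(default_factory=lambda: {
        "pericyte": "M1", "fibroblast": "M2", "astrocyte": "M3",
        "smc": "M4", "endothelial": "M5",
    })
    celltype_members_per_set: int = 25
    proportion_concentration: float = 60.0
    outlier_neuron_proportion: float = 0.55
    outlier_endothelial_proportion: float = 0.03
    # paired-bulk structure
    n_vascular_enriched: int = 60
    vascular_enrichment_log2: float = 2.0  # 4-fold
    bulk_absent_modules: tuple[str, ...] = ("M5",)
    # the vascular-enriched M1 subset mimics strongly amyloid-associated
    # proteins: large fold changes in both proteinopathies, AD > PSP
    strong_ad_effect: float = 1.6
    strong_psp_effect: float = 0.8
    # peptide-level structure (see generate_peptide_table)
    abeta40_vascular_fold: float = 4.5
    abeta42_vascular_fold: float = 1.0 / 4.5
    abeta_ratio_ad_fold: float = 2.0
    n_filler_peptides: int = 48
    loading_sd: float = 0.3
    peptide_noise_sd: float = 0.2
    seed: int = 0

    @property
    def n_gis(self) -> int:
        return self.n_batches * self.gis_per_batch + self.extra_gis_last_batch

    @property
    def n_channels(self) -> int:
        return self.n_batches * self.channels_per_batch

    @property
    def n_biological(self) -> int:
        return self.n_control + self.n_ad + self.n_psp

    @property
    def module_labels(self) -> list[str]:
        return [f"M{i + 1}" for i in range(len(self.module_sizes))]

    def validate(self) -> None:
        if self.n_biological != self.n_channels - self.n_gis:
            raise ValueError(
                f"group sizes ({self.n_biological}) must equal channels minus GIS "
                f"({self.n_channels - self.n_gis})"
            )
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError("module sizes exceed n_proteins")
        n_markers = len(CELL_TYPES) * self.markers_per_type
        if sum(self.module_sizes) + n_markers > self.n_proteins:
            raise ValueError("module + marker blocks exceed n_proteins")
        for name, eff in [("ad", self.ad_effects), ("psp", self.psp_effects),
                          ("age", self.age_effects), ("sex", self.sex_effects),
                          ("pmi", self.pmi_effects)]:
            unknown = set(eff) - set(self.module_labels)
            if unknown:
                raise ValueError(f"{name}_effects refer to unknown modules {unknown}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study."""

    module_labels: pd.Series  # protein -> planted module label or "background"
    factor_scores: pd.DataFrame  # biological sample x module
    loadings: pd.Series  # protein -> lambda (0 for background)
    batch_log2_factors: pd.DataFrame  # protein x batch
    ad_effects: dict
    psp_effects: dict
    covariate_effects: dict  # {"age": {...}, "sex": {...}, "pmi": {...}}
    proportions: pd.DataFrame  # biological sample x cell type, rows sum to 1
    outlier_flags: pd.Series  # biological sample -> bool
    vascular_enrichment_log2: pd.Series  # protein -> planted log2(vasc/bulk)
    marker_sets: dict
    ad_effect_per_protein: pd.Series | None = None
    psp_effect_per_protein: pd.Series | None = None


@dataclass
class StudyData:
    """Everything :func:`generate_study` produces.

    ``abundance`` / ``meta`` / ``traits`` / ``markers`` / ``truth`` are the
    study proper; ``bulk_abundance`` is the paired bulk-tissue counterpart used
    as module-preservation target and for vascular/bulk enrichment.
    """

    abundance: AbundanceMatrix  # linear scale, proteins x channels (incl. GIS)
    meta: pd.DataFrame
    traits: pd.DataFrame
    markers: dict  # deconvolution signatures (dedicated marker blocks)
    truth: SyntheticTruth
    bulk_abundance: AbundanceMatrix
    celltype_sets: dict = field(default_factory=dict)  # enrichment gene lists


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def _dirichlet(rng: np.random.Generator, mean: dict, conc: float, n: int) -> np.ndarray:
    alpha = np.array([mean[t] for t in CELL_TYPES]) * conc
    return rng.dirichlet(alpha, size=n)


def _mnar_mask(rng: np.random.Generator, x: np.ndarray, target: float, steepness: float) -> np.ndarray:
    """Missing-not-at-random mask: P(missing) logistic in -(standardized log2)."""
    if target <= 0:
        return np.zeros_like(x, dtype=bool)
    z = (x - x.mean()) / x.std()
    lo, hi = -20.0, 20.0
    for _ in range(60):
        theta = 0.5 * (lo + hi)
        if expit(steepness * (theta - z)).mean() < target:
            lo = theta
        else:
            hi = theta
    p = expit(steepness * (theta - z))
    return rng.random(x.shape) < p


def generate_study(config: StudyConfig | None = None, seed: int | None = None) -> StudyData:
    """Generate the full synthetic study; deterministic given ``seed``.

    The log2 abundance of protein *i* in biological channel *j* is

        mu_i + lambda_i * f_{m(i)}(j) + covariate terms + diagnosis terms
             + batch_{i, b(j)} + eps_ij,       eps ~ Normal(0, sigma^2),

    with factor scores ``f_m`` standard normal per sample, shared within a
    module, and re-centered within each diagnosis group so planted diagnosis
    contrasts are exactly the configured effects.  Cell-type marker proteins
    replace the factor term with ``log2(eps0 + scale * proportion)``.  GIS
    channels carry the per-batch mean of the biological channels plus small
    noise.  Outlier samples have neuron-dominant, endothelial-depleted true
    proportions.  Missingness is injected intensity-dependently.
    """
    config = config or StudyConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    n_prot = config.n_proteins
    protein_ids = _protein_ids(n_prot)
    labels = np.array(["background"] * n_prot, dtype=object)
    pos = 0
    for lab, size in zip(config.module_labels, config.module_sizes):
        labels[pos:pos + size] = lab
        pos += size
    marker_sets: dict[str, list[str]] = {}
    marker_type = np.array([""] * n_prot, dtype=object)
    for t in CELL_TYPES:
        idx = slice(pos, pos + config.markers_per_type)
        marker_type[idx] = t
        marker_sets[t] = protein_ids[idx]
        pos += config.markers_per_type

    # --- sample design -----------------------------------------------------
    rows = []
    for b in range(config.n_batches):
        n_gis = config.gis_per_batch + (config.extra_gis_last_batch if b == config.n_batches - 1 else 0)
        for c in range(config.channels_per_batch):
            is_gis = c < n_gis
            rows.append({
                "sample_id": f"b{b + 1}.{c + 1:02d}",
                "batch": f"batch{b + 1}",
                "channel": f"ch{c + 1:02d}",
                "is_gis": is_gis,
            })
    meta = pd.DataFrame(rows)
    bio_mask = ~meta["is_gis"].to_numpy()
    bio_ids = meta.loc[bio_mask, "sample_id"].to_numpy()
    n_bio = len(bio_ids)

    diagnosis = np.array(
        ["control"] * config.n_control + ["AD"] * config.n_ad + ["PSP"] * config.n_psp,
        dtype=object,
    )
    rng.shuffle(diagnosis)
    meta["diagnosis"] = "GIS"
    meta.loc[bio_mask, "diagnosis"] = diagnosis
    meta["age"] = np.round(np.clip(rng.normal(75, 8, len(meta)), 55, 95), 1)
    meta["sex"] = rng.binomial(1, 0.45, len(meta))
    meta["pmi"] = np.round(np.clip(rng.normal(12, 4, len(meta)), 2, 30), 1)

    # --- latent structure --------------------------------------------------
    n_mod = len(config.module_sizes)
    factors = rng.normal(0.0, 1.0, size=(n_bio, n_mod))
    for dx in ("control", "AD", "PSP"):
        grp = diagnosis == dx
        factors[grp] -= factors[grp].mean(axis=0, keepdims=True)
    factors_df = pd.DataFrame(factors, index=bio_ids, columns=config.module_labels)

    lam = np.zeros(n_prot)
    in_module = labels != "background"
    lam[in_module] = rng.uniform(*config.loading_range, size=int(in_module.sum()))

    batch_fx = rng.normal(0.0, config.batch_sd, size=(n_prot, config.n_batches))

    # true proportions; outliers are neuron-contaminated, endothelium-poor
    props = _dirichlet(rng, VASCULAR_MEAN_PROPORTIONS, config.proportion_concentration, n_bio)
    outlier_idx = rng.choice(n_bio, size=config.n_outliers, replace=False)
    for j in outlier_idx:
        p = props[j].copy()
        i_neu = CELL_TYPES.index("neuron")
        i_end = CELL_TYPES.index("endothelial")
        rest = np.ones(len(CELL_TYPES), dtype=bool)
        rest[[i_neu, i_end]] = False
        remaining = 1.0 - config.outlier_neuron_proportion - config.outlier_endothelial_proportion
        p[rest] = p[rest] / p[rest].sum() * remaining
        p[i_neu] = config.outlier_neuron_proportion
        p[i_end] = config.outlier_endothelial_proportion
        props[j] = p
    props_df = pd.DataFrame(props, index=bio_ids, columns=CELL_TYPES)
    outlier_flags = pd.Series(False, index=bio_ids)
    outlier_flags.iloc[outlier_idx] = True

    # --- traits ------------------------------------------------------------
    is_ad = (diagnosis == "AD").astype(int)
    is_psp = (diagnosis == "PSP").astype(int)
    f1 = factors[:, 0]
    cerad = np.where(is_ad, rng.choice([2, 3], n_bio, p=[0.3, 0.7]),
                     rng.choice([0, 1], n_bio, p=[0.8, 0.2]))
    braak = np.select(
        [is_ad == 1, is_psp == 1],
        [rng.choice([4, 5, 6], n_bio), rng.choice([2, 3, 4], n_bio)],
        default=rng.choice([0, 1, 2], n_bio),
    )
    caa_latent = np.where(is_ad, 1.7 + 0.8 * f1 + 0.4 * rng.normal(size=n_bio),
                          0.15 + 0.25 * rng.random(n_bio))
    caa = np.clip(np.round(caa_latent), 0, 3).astype(int)
    gliosis = np.where((is_ad | is_psp).astype(bool),
                       rng.choice([1, 2, 3], n_bio), rng.choice([0, 1, 2], n_bio))
    apoe = np.where(is_ad, rng.choice([0, 1, 2], n_bio, p=[0.3, 0.5, 0.2]),
                    rng.choice([0, 1, 2], n_bio, p=[0.7, 0.25, 0.05]))
    traits = pd.DataFrame({
        "sample_id": bio_ids,
        "cerad": cerad, "braak": braak, "caa": caa, "gliosis": gliosis,
        "apoe4_dose": apoe,
        "is_ad": is_ad, "is_psp": is_psp,
        "is_control": (diagnosis == "control").astype(int),
    })

    # --- assemble log2 abundances ------------------------------------------
    mu = rng.normal(20.0, 1.5, size=n_prot)
    batch_of_bio = meta.loc[bio_mask, "batch"].str.removeprefix("batch").astype(int).to_numpy() - 1
    age_c = meta.loc[bio_mask, "age"].to_numpy() - meta.loc[bio_mask, "age"].mean()
    sex_c = meta.loc[bio_mask, "sex"].to_numpy() - meta.loc[bio_mask, "sex"].mean()
    pmi_c = meta.loc[bio_mask, "pmi"].to_numpy() - meta.loc[bio_mask, "pmi"].mean()

    module_index = {lab: k for k, lab in enumerate(config.module_labels)}

    # planted vascular/bulk enrichment: half from the amyloid-linked module,
    # half from the background (excluding marker blocks)
    venrich = np.zeros(n_prot)
    bg_pool = np.nonzero((labels == "background") & (marker_type == ""))[0]
    n_half = config.n_vascular_enriched // 2
    enriched_idx = np.concatenate([
        np.nonzero(labels == "M1")[0][:n_half],
        rng.choice(bg_pool, size=config.n_vascular_enriched - n_half, replace=False),
    ])
    venrich[enriched_idx] = config.vascular_enrichment_log2

    ad_vec = np.array([config.ad_effects.get(lab, 0.0) for lab in labels])
    psp_vec = np.array([config.psp_effects.get(lab, 0.0) for lab in labels])
    strong = np.zeros(n_prot, dtype=bool)
    strong[np.nonzero(labels == "M1")[0][:n_half]] = True
    ad_vec[strong] = config.strong_ad_effect
    psp_vec[strong] = config.strong_psp_effect

    def build_matrix(rng: np.random.Generator, bulk: bool) -> np.ndarray:
        x = np.tile(mu[:, None], (1, n_bio))
        x += ad_vec[:, None] * is_ad[None, :]
        x += psp_vec[:, None] * is_psp[None, :]
        for i in range(n_prot):
            lab = labels[i]
            if lab != "background":
                k = module_index[lab]
                att = 0.0 if (bulk and lab in config.bulk_absent_modules) else 1.0
                x[i] += lam[i] * att * factors[:, k]
                x[i] += config.age_effects.get(lab, 0.0) * age_c
                x[i] += config.sex_effects.get(lab, 0.0) * sex_c
                x[i] += config.pmi_effects.get(lab, 0.0) * pmi_c
        # marker blocks: additive signal set by the true proportions
        mean_props = BULK_MEAN_PROPORTIONS if bulk else None
        if bulk:
            bprops = _dirichlet(rng, mean_props, config.proportion_concentration, n_bio)
        for t in CELL_TYPES:
            rows_t = np.nonzero(marker_type == t)[0]
            p_t = (bprops if bulk else props)[:, CELL_TYPES.index(t)]
            x[rows_t] = mu[rows_t][:, None] + np.log2(config.marker_floor + config.marker_scale * p_t)[None, :]
        fx = rng.normal(0.0, config.batch_sd, size=(n_prot, config.n_batches)) if bulk else batch_fx
        x += fx[:, batch_of_bio]
        x += rng.normal(0.0, config.noise_sd, size=x.shape)
        return x

    x_vasc = build_matrix(rng, bulk=False)
    x_bulk = build_matrix(rng, bulk=True) - venrich[:, None]

    def with_gis(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        full = np.empty((n_prot, len(meta)))
        full[:, bio_mask] = x
        gis_cols = np.nonzero(~bio_mask)[0]
        batches_all = meta["batch"].to_numpy()
        for g in gis_cols:
            in_batch = bio_mask & (batches_all == batches_all[g])
            full[:, g] = full[:, in_batch].mean(axis=1) + rng.normal(0, config.gis_noise_sd, n_prot)
        return full

    full_vasc = with_gis(x_vasc, rng)
    full_bulk = with_gis(x_bulk, rng)

    for full in (full_vasc, full_bulk):
        mask = _mnar_mask(rng, full, config.missing_fraction, config.missing_steepness)
        full[mask] = np.nan

    abundance = AbundanceMatrix(
        pd.DataFrame(np.exp2(full_vasc), index=protein_ids, columns=meta["sample_id"].to_numpy()),
        scale="linear",
    )
    bulk_abundance = AbundanceMatrix(
        pd.DataFrame(np.exp2(full_bulk), index=protein_ids, columns=meta["sample_id"].to_numpy()),
        scale="linear",
    )

    truth = SyntheticTruth(
        module_labels=pd.Series(labels, index=protein_ids, name="module"),
        factor_scores=factors_df,
        loadings=pd.Series(lam, index=protein_ids, name="loading"),
        batch_log2_factors=pd.DataFrame(
            batch_fx, index=protein_ids, columns=[f"batch{b + 1}" for b in range(config.n_batches)]
        ),
        ad_effects=dict(config.ad_effects),
        psp_effects=dict(config.psp_effects),
        covariate_effects={
            "age": dict(config.age_effects),
            "sex": dict(config.sex_effects),
            "pmi": dict(config.pmi_effects),
        },
        proportions=props_df,
        outlier_flags=outlier_flags,
        vascular_enrichment_log2=pd.Series(venrich, index=protein_ids, name="log2_vasc_over_bulk"),
        marker_sets=marker_sets,
        ad_effect_per_protein=pd.Series(ad_vec, index=protein_ids, name="ad_effect"),
        psp_effect_per_protein=pd.Series(psp_vec, index=protein_ids, name="psp_effect"),
    )
    celltype_sets = {}
    for t in CELL_TYPES:
        members = list(marker_sets[t])
        mod = config.celltype_module_map.get(t)
        if mod is not None and mod in config.module_labels:
            pool = [p for p, lab in zip(protein_ids, labels) if lab == mod]
            extra = rng.choice(pool, size=min(config.celltype_members_per_set, len(pool)),
                               replace=False)
            members += list(extra)
        celltype_sets[t] = members
    return StudyData(abundance, meta, traits, marker_sets, truth, bulk_abundance, celltype_sets)


# ---------------------------------------------------------------------------
# auxiliary generators
# ---------------------------------------------------------------------------


def generate_gwas_table(
    n_genes: int,
    enriched_module_labels: Sequence[str],
    truth: SyntheticTruth,
    effect: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level association p-value table (symbol, p).

    Background genes draw p ~ Uniform(0, 1); genes in enriched modules draw
    from the left-skewed Beta(0.1 * effect, 1) (uniform when effect = 0).  One
    gene symbol per network protein; extra genes beyond the proteome get fresh
    symbols and background p values.
    """
    rng = np.random.default_rng(seed)
    known = set(truth.module_labels.unique())
    unknown = set(enriched_module_labels) - known
    if unknown:
        raise ValueError(f"unknown module labels: {sorted(unknown)}")
    proteins = list(truth.module_labels.index)
    if n_genes <= len(proteins):
        symbols = proteins[:n_genes]
    else:
        symbols = proteins + [f"G{i:04d}" for i in range(n_genes - len(proteins))]
    p = rng.uniform(0.0, 1.0, size=n_genes)
    if effect > 0:
        enriched = truth.module_labels.reindex(symbols).isin(enriched_module_labels).to_numpy()
        p[enriched] = rng.beta(0.1 * effect, 1.0, size=int(enriched.sum()))
    return pd.DataFrame({"symbol": symbols, "p": p})


def generate_biofluid_tables(
    truth: SyntheticTruth,
    overlap_modules: Sequence[str] = ("M1",),
    seed: int = 0,
    discordant_modules: Sequence[str] = ("M2",),
    background_fraction: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plasma and CSF differential-abundance tables (protein, log2_effect, p).

    Members of ``overlap_modules`` are preferentially significant and
    direction-concordant with their planted brain effect.  ``discordant_modules``
    are planted brain-down / plasma-up (the plasma table flips their sign),
    mimicking the divergent extracellular-matrix signature seen between brain
    vasculature and plasma.
    """
    rng = np.random.default_rng(seed)
    known = set(truth.module_labels.unique())
    for m in list(overlap_modules) + list(discordant_modules):
        if m not in known:
            raise ValueError(f"unknown module label: {m}")
    brain_sign = {m: np.sign(truth.ad_effects.get(m, 1.0)) or 1.0 for m in known}

    tables = []
    for fluid in ("plasma", "csf"):
        rows = []
        for prot, mod in truth.module_labels.items():
            in_overlap = mod in overlap_modules or mod in discordant_modules
            if in_overlap:
                if rng.random() > 0.9:
                    continue  # ~10% of module members not quantified in the fluid
                sig = rng.random() < 0.85
                p = rng.uniform(0.0, 0.04) if sig else rng.uniform(0.05, 1.0)
                sign = brain_sign[mod]
                if fluid == "plasma" and mod in discordant_modules and rng.random() < 0.95:
                    sign = -sign
                eff = sign * abs(rng.normal(1.0, 0.3))
            else:
                if rng.random() > background_fraction:
                    continue
                p = rng.uniform(0.0, 1.0)
                eff = rng.normal(0.0, 0.3)
            rows.append({"protein": prot, "log2_effect": eff, "p": p})
        tables.append(pd.DataFrame(rows))
    return tables[0], tables[1]


AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ABETA40_PEPTIDE = "GAIIGLMVGGVV"
ABETA42_PEPTIDE = "GAIIGLMVGGVVIA"


def generate_peptide_table(
    truth: SyntheticTruth,
    meta: pd.DataFrame,
    config: StudyConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired vascular / bulk peptide reporter-intensity tables.

    Rows are peptide sequences (the two amyloid-beta C-terminal tryptic
    peptides plus filler peptides), columns the study channels.  Planted
    structure: vascular/bulk enrichment of ``abeta40_vascular_fold`` for the
    Abeta40 peptide and ``abeta42_vascular_fold`` for Abeta42, and an
    ``abeta_ratio_ad_fold`` elevation of vascular Abeta40/Abeta42 in AD
    samples.  Random per-channel loading factors exercise the reporter-ion
    scaling step; GIS channels carry per-batch means.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    fillers = ["".join(rng.choice(list(AA_ALPHABET), size=rng.integers(8, 15)))
               for _ in range(config.n_filler_peptides)]
    peptides = [ABETA40_PEPTIDE, ABETA42_PEPTIDE] + fillers
    n_pep = len(peptides)

    sample_ids = meta["sample_id"].to_numpy()
    bio_mask = ~meta["is_gis"].to_numpy()
    batches = meta["batch"].to_numpy()
    dx = meta["diagnosis"].to_numpy()
    n_all = len(sample_ids)

    base = rng.normal(20.0, 0.7, size=n_pep)
    batch_fx = {b: rng.normal(0.0, 0.5, size=n_pep) for b in np.unique(batches)}

    def build(fraction: str) -> np.ndarray:
        x = np.tile(base[:, None], (1, n_all))
        if fraction == "vascular":
            x[0] += np.log2(config.abeta40_vascular_fold)
            x[1] += np.log2(config.abeta42_vascular_fold)
            x[0, (dx == "AD")] += np.log2(config.abeta_ratio_ad_fold)
        for b, fx in batch_fx.items():
            x[:, batches == b] += fx[:, None]
        x[:, bio_mask] += rng.normal(0.0, config.peptide_noise_sd, size=(n_pep, int(bio_mask.sum())))
        # GIS channels: per-batch mean of biological channels + small noise
        for g in np.nonzero(~bio_mask)[0]:
            in_b = bio_mask & (batches == batches[g])
            x[:, g] = x[:, in_b].mean(axis=1) + rng.normal(0, config.gis_noise_sd, n_pep)
        loading = rng.normal(0.0, config.loading_sd, size=n_all)
        x += loading[None, :]
        return np.exp2(x)

    vasc = pd.DataFrame(build("vascular"), index=peptides, columns=sample_ids)
    bulk = pd.DataFrame(build("bulk"), index=peptides, columns=sample_ids)
    return vasc, bulk


def generate_deconvolution_benchmark(
    n_cohort: int = 80,
    mixtures: Sequence[dict] | None = None,
    config: StudyConfig | None = None,
    seed: int = 0,
) -> tuple[AbundanceMatrix, dict, pd.DataFrame]:
    """Marker-block cohort with known proportions for deconvolution accuracy.

    Cohort samples draw symmetric Dirichlet proportions over the nine cell
    types (so no type dominates and z-scored marker signals are comparable
    across types); additional ``mixtures`` samples carry exact user-specified
    proportions, e.g. a 50/50 endothelial/neuron mixture.  Returns the log2
    marker abundance matrix, the marker sets, and the true proportions.
    """
    config = config or StudyConfig()
    rng = np.random.default_rng(seed)
    if mixtures is None:
        mixtures = [{"endothelial": 0.5, "neuron": 0.5}]
    n_types = len(CELL_TYPES)
    props = rng.dirichlet(np.full(n_types, 1.5), size=n_cohort)
    for mix in mixtures:
        row = np.array([mix.get(t, 0.0) for t in CELL_TYPES])
        if not np.isclose(row.sum(), 1.0):
            raise ValueError("mixture proportions must sum to 1")
        props = np.vstack([props, row])
    sample_ids = [f"s{j:03d}" for j in range(len(props))]

    marker_ids, rows = [], []
    marker_sets: dict[str, list[str]] = {}
    for t in CELL_TYPES:
        ids = [f"{t[:4].upper()}_{k}" for k in range(config.markers_per_type)]
        marker_sets[t] = ids
        marker_ids.extend(ids)
        p_t = props[:, CELL_TYPES.index(t)]
        mu_t = rng.normal(20.0, 1.0, size=config.markers_per_type)
        block = mu_t[:, None] + np.log2(config.marker_floor + config.marker_scale * p_t)[None, :]
        rows.append(block)
    x = np.vstack(rows) + rng.normal(0.0, config.noise_sd, size=(len(marker_ids), len(props)))
    matrix = AbundanceMatrix(pd.DataFrame(x, index=marker_ids, columns=sample_ids), scale="log2")
    truth = pd.DataFrame(props, index=sample_ids, columns=CELL_TYPES)
    return matrix, marker_sets, truth
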