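"""Synthetic cross-sectional aging cohort with paired mRNA and protein data.

The generator emulates the design of a diversity-outbred mouse kidney aging
study: 188 animals split over ages 6/12/18 months and both sexes, mRNA
measured as RNA-seq counts (negative binomial, with a 2-level sequencing
batch and log-normal library-size variation) and protein measured on a
continuous scale (with a ~16-level mass-spec labeling tag and a 5-level DO
generation as grouping factors).  Every simulated gene belongs to a named
class, recorded in a truth table, so downstream estimates can be compared
against known slopes:

* ``concordant_up`` / ``concordant_down`` — mRNA and protein both trend with
  age in the same direction, the protein trend being a *direct* age effect
  (not routed through mRNA).
* ``mrna_down_protein_up`` / ``mrna_up_protein_down`` — discordant signs,
  protein again trending directly.
* ``mediated`` — the protein's entire age signal arrives through its mRNA
  (direct age term zero, transfer coefficient lambda != 0).
* ``null`` — no age effect on either platform.

Sex differences are simulated as *mRNA-driven* throughout: the protein sex
signal is lambda times the mRNA sex component.  Together with direct-age
protein trends for the non-mediated classes this reproduces the qualitative
contrast the mediation scan is designed to detect — age effects on protein
that survive adjustment for mRNA, sex effects that do not.

mRNA and protein share a per-gene, per-sample latent biological term, so
they correlate within age groups even for null genes.  The protein couples
to the latent *log-mean* of the mRNA, not the sampled count, so counting
noise attenuates but does not destroy that correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSimConfig",
    "simulate_cohort",
    "simulate_reference_profiles",
    "simulate_urine",
]

GENE_CLASSES = (
    "concordant_up",
    "mrna_down_protein_up",
    "mrna_up_protein_down",
    "concordant_down",
    "mediated",
    "null",
)

#: (age_months, sex, n) cells of the study design: 188 animals total.
DEFAULT_CELLS = (
    (6, "M", 30), (6, "F", 33),
    (12, "M", 31), (12, "F", 31),
    (18, "M", 34), (18, "F", 29),
)

AGE_CODES = {6: -0.5, 12: 0.0, 18: 0.5}


@dataclass
class CohortSimConfig:
    """Simulation settings; defaults mirror the emulated study design."""

    cells: tuple = DEFAULT_CELLS
    n_genes_per_class: dict = field(default_factory=lambda: {
        "concordant_up": 300,
        "mrna_down_protein_up": 200,
        "mrna_up_protein_down": 100,
        "concordant_down": 350,
        "mediated": 250,
        "null": 5300,
    })
    mrna_age_effect: float = 0.5        # |log-mean slope| per year (natural log)
    protein_age_effect: float = 0.5     # |direct protein slope| per year, residual-SD units
    mrna_sex_effect: float = 0.8        # |log-mean M-F shift|; protein sex arrives via lambda
    sex_effect_fraction: float = 0.8    # fraction of genes given a sex effect
    mediation_lambda: float = 0.7       # mRNA->protein transfer coefficient
    batch_sd: float = 0.3
    tag_sd: float = 0.3
    generation_sd: float = 0.2
    bio_sd: float = 0.3                 # shared latent biological variation
    protein_noise_sd: float = 0.5
    dispersion_range: tuple = (0.05, 0.3)
    libsize_log_sd: float = 0.3
    baseline_log_range: tuple = (np.log(20.0), np.log(2000.0))
    n_batches: int = 2
    n_tags: int = 16
    n_generations: int = 5
    seed: int = 0

    def validate(self) -> None:
        counts = self.n_genes_per_class
        if set(counts) - set(GENE_CLASSES):
            raise ValueError(f"unknown gene classes: {set(counts) - set(GENE_CLASSES)}")
        if any(v < 0 for v in counts.values()):
            raise ValueError("gene-class counts must be >= 0")
        if sum(counts.values()) == 0:
            raise ValueError("total gene count is zero")
        if any(n < 2 for _, _, n in self.cells):
            raise ValueError("every (age, sex) cell needs n >= 2 (models unidentifiable)")
        lo, hi = self.dispersion_range
        if lo <= 0 or hi < lo:
            raise ValueError("dispersion range must be positive and ordered")


def _make_metadata(config: CohortSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for age, sex, n in config.cells:
        for _ in range(n):
            rows.append({"sample_id": f"S{i:04d}", "age_months": age,
                         "age_coded": AGE_CODES.get(age), "sex": sex})
            i += 1
    meta = pd.DataFrame(rows).set_index("sample_id")
    if meta["age_coded"].isna().any():
        ages = sorted({a for a, _, _ in config.cells})
        coded = np.linspace(-0.5, 0.5, len(ages))
        meta["age_coded"] = meta["age_months"].map(dict(zip(ages, coded)))
    n = len(meta)
    meta["batch"] = [f"B{b}" for b in rng.integers(0, config.n_batches, n)]
    meta["tag"] = [f"T{t:02d}" for t in rng.integers(0, config.n_tags, n)]
    meta["generation"] = [f"G{g}" for g in rng.integers(0, config.n_generations, n)]
    return meta


def simulate_cohort(config: CohortSimConfig | None = None):
    """Simulate paired mRNA counts and protein abundances plus metadata and truth.

    Returns ``(mrna_counts, protein, metadata, truth)``:

    * ``mrna_counts`` — genes x samples integer counts, NB with log-mean
      ``baseline + age_coded*slope + sex + batch + bio + log(libsize)``;
    * ``protein`` — genes x samples continuous abundances,
      ``lambda*(core) + direct_age*age_coded + tag + generation + noise``
      where ``core`` carries the mRNA sex component, the shared biological
      term and — for mediated genes only — the mRNA age component;
    * ``metadata`` — per-sample covariates;
    * ``truth`` — per-gene class, true slopes (mRNA on log2-per-year scale),
      mediation flag and sex effects.  For mediated genes
      ``protein_age_slope = lambda * mrna_age_slope_ln``.
    """
    config = config or CohortSimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _make_metadata(config, rng)
    n = len(meta)

    classes = np.concatenate([
        np.full(config.n_genes_per_class.get(c, 0), c) for c in GENE_CLASSES
    ])
    n_genes = classes.size
    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)])

    signs_mrna = {"concordant_up": 1.0, "mrna_down_protein_up": -1.0,
                  "mrna_up_protein_down": 1.0, "concordant_down": -1.0,
                  "mediated": 1.0, "null": 0.0}
    signs_prot = {"concordant_up": 1.0, "mrna_down_protein_up": 1.0,
                  "mrna_up_protein_down": -1.0, "concordant_down": -1.0,
                  "mediated": 0.0, "null": 0.0}
    mrna_slope = np.array([signs_mrna[c] for c in classes]) * config.mrna_age_effect
    direct_prot_slope = np.array([signs_prot[c] for c in classes]) * config.protein_age_effect
    mediated = classes == "mediated"
    # mediated genes alternate sign so the class is not one-directional
    flip = mediated & (np.arange(n_genes) % 2 == 1)
    mrna_slope[flip] *= -1.0

    has_sex = rng.random(n_genes) < config.sex_effect_fraction
    sex_dir = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    mrna_sex = np.where(has_sex, sex_dir * config.mrna_sex_effect, 0.0)

    age = meta["age_coded"].to_numpy()
    sex_ind = (meta["sex"] == "M").to_numpy(dtype=float)
    batch_eff = {b: rng.normal(0.0, config.batch_sd) for b in sorted(meta["batch"].unique())}
    tag_eff = {t: rng.normal(0.0, config.tag_sd) for t in sorted(meta["tag"].unique())}
    gen_eff = {g: rng.normal(0.0, config.generation_sd) for g in sorted(meta["generation"].unique())}
    batch_v = meta["batch"].map(batch_eff).to_numpy()
    tag_v = meta["tag"].map(tag_eff).to_numpy()
    gen_v = meta["generation"].map(gen_eff).to_numpy()
    log_libsize = rng.normal(0.0, config.libsize_log_sd, n)

    baseline = rng.uniform(*config.baseline_log_range, n_genes)
    dispersion = rng.uniform(*config.dispersion_range, n_genes)
    bio = rng.normal(0.0, config.bio_sd, (n_genes, n))

    age_term = mrna_slope[:, None] * age[None, :]
    sex_term = mrna_sex[:, None] * sex_ind[None, :]
    log_mu = (baseline[:, None] + age_term + sex_term + bio
              + batch_v[None, :] + log_libsize[None, :])
    mu = np.exp(log_mu)
    # NB via gamma-Poisson mixture: Var = mu + alpha*mu^2
    shape = 1.0 / dispersion[:, None]
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    lam_c = config.mediation_lambda
    core = sex_term + bio + np.where(mediated[:, None], age_term, 0.0)
    noise = rng.normal(0.0, config.protein_noise_sd, (n_genes, n))
    protein = (lam_c * core + direct_prot_slope[:, None] * age[None, :]
               + tag_v[None, :] + gen_v[None, :] + noise)

    mrna = pd.DataFrame(counts, index=gene_ids, columns=meta.index)
    prot = pd.DataFrame(protein, index=gene_ids, columns=meta.index)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "gene_class": classes,
        "mrna_age_slope_ln": mrna_slope,
        "mrna_age_slope_log2": mrna_slope / np.log(2.0),
        "protein_age_slope": np.where(mediated, lam_c * mrna_slope, direct_prot_slope),
        "mediated": mediated,
        "mrna_sex_effect": mrna_sex,
        "protein_sex_effect": lam_c * mrna_sex,
    }).set_index("gene_id")
    return mrna, prot, meta, truth


def simulate_reference_profiles(
    n_types: int, n_genes: int, markers_per_type: int, seed: int = 0, fold: float = 8.0
):
    """Cell-type mean-expression profiles with planted marker genes.

    Each type receives ``markers_per_type`` genes whose mean is ``fold``-fold
    (>= 5) above every other type; remaining genes get exchangeable means.
    Returns ``(profiles, marker_map)`` where profiles is genes x types and
    marker_map maps type -> list of its true marker genes.
    """
    if n_types < 1 or markers_per_type < 1:
        raise ValueError("need >=1 type and >=1 marker per type")
    if fold < 5.0:
        raise ValueError("marker fold change must be >= 5")
    if markers_per_type * n_types > n_genes:
        raise ValueError(
            f"cannot plant {markers_per_type} markers in each of {n_types} types "
            f"with only {n_genes} genes"
        )
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    types = [f"type{t}" for t in range(n_types)]
    base = rng.uniform(0.5, 2.0, (n_genes, n_types))
    marker_map: dict[str, list[str]] = {}
    pool = rng.permutation(n_genes)
    k = 0
    for t, tname in enumerate(types):
        idx = pool[k:k + markers_per_type]
        k += markers_per_type
        row_base = base[idx].max(axis=1)
        base[idx, :] = base[idx] * 0.0 + rng.uniform(0.5, 1.0, (markers_per_type, n_types))
        base[idx, t] = row_base * fold * rng.uniform(1.0, 1.5, markers_per_type)
        marker_map[tname] = [gene_ids[i] for i in idx]
    profiles = pd.DataFrame(base, index=gene_ids, columns=types)
    return profiles, marker_map


def simulate_bulk_mixture(
    profiles: pd.DataFrame,
    proportions: pd.DataFrame,
    noise_log_sd: float = 0.2,
    libsize_log_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk expression as a noisy mixture of cell-type mean profiles.

    ``profiles`` is genes x types (non-negative means), ``proportions`` is
    types x samples with columns summing to 1.  The bulk signal is the
    matrix product, multiplied gene-and-sample-wise by log-normal noise and
    per-sample by a log-normal library-size factor (which downstream
    library-size normalization is expected to remove).
    """
    if list(profiles.columns) != list(proportions.index):
        raise ValueError("profile columns and proportion rows must name the same cell types")
    props = proportions.to_numpy(dtype=float)
    if (props < 0).any() or not np.allclose(props.sum(axis=0), 1.0):
        raise ValueError("proportions must be non-negative and sum to 1 per sample")
    rng = np.random.default_rng(seed)
    signal = profiles.to_numpy(dtype=float) @ props
    noise = np.exp(rng.normal(0.0, noise_log_sd, signal.shape))
    libsize = np.exp(rng.normal(0.0, libsize_log_sd, signal.shape[1]))
    return pd.DataFrame(signal * noise * libsize[None, :],
                        index=profiles.index, columns=proportions.columns)


def simulate_urine(
    metadata: pd.DataFrame,
    protein_row,
    effect: float,
    seed: int = 0,
    below_detection_fraction: float = 0.8,
    detection_threshold: float = 1.0,
    noise_sd: float = 1.0,
    sex_effect: float = 0.3,
) -> pd.DataFrame:
    """Simulate urinary albumin, phosphate and creatinine for each sample.

    log-phosphate = intercept + effect * standardized(protein_row) + sex + noise,
    creatinine is positive log-normal, and albumin is drawn so that about
    ``below_detection_fraction`` of samples fall below ``detection_threshold``
    (mimicking a detection limit; most healthy animals show no albuminuria).
    Analytes are returned on the raw scale, unadjusted for creatinine.
    """
    prot = np.asarray(protein_row, dtype=float)
    if prot.shape[0] != len(metadata):
        raise ValueError("protein_row and metadata are misaligned")
    rng = np.random.default_rng(seed)
    n = len(metadata)
    sex_ind = (metadata["sex"] == "M").to_numpy(dtype=float)
    z = (prot - prot.mean()) / (prot.std() if prot.std() > 0 else 1.0)
    log_phos = 1.0 + effect * z + sex_effect * sex_ind + rng.normal(0.0, noise_sd, n)
    creatinine = np.exp(rng.normal(0.0, 0.4, n))
    # albumin: log-normal located so the requested fraction sits below threshold
    from scipy import stats as _stats
    q = _stats.norm.ppf(below_detection_fraction)
    alb_sd = 0.8
    alb_mu = np.log(detection_threshold) - q * alb_sd
    albumin = np.exp(rng.normal(alb_mu, alb_sd, n))
    return pd.DataFrame({
        "albumin": albumin,
        "phosphate": np.exp(log_phos) * creatinine,  # raw analyte scales with urine concentration
        "creatinine": creatinine,
    }, index=metadata.index)
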