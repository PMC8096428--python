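"""End-to-end orchestration: normalize -> trend tests -> concordance ->
mediation -> structure, writing one delimited table per analysis plus a run
log that records the seed, thresholds and sample/feature counts at every
stage, so each run is self-describing and bit-reproducible."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as conc
from . import io as dio
from . import mediation as med
from . import structure as struct
from . import transforms as tf
from . import trendtest as tt
from .config import PipelineConfig

__all__ = ["run_pipeline"]

logger = logging.getLogger("duotrend")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # abort with the stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(
    config: PipelineConfig,
    mrna: pd.DataFrame | None = None,
    protein: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    reference: pd.DataFrame | None = None,
) -> dict:
    """Run every analysis stage and write the result tables to ``config.out_dir``.

    Inputs may be passed in memory or read from the paths in ``config``
    (in-memory arguments win).  mRNA counts, protein abundances and sample
    metadata are required; phenotype and cell-type-reference tables are
    optional and their stages are skipped when absent.

    Returns a dict of result tables keyed by output name; the same tables
    are written as TSV under ``config.out_dir`` together with ``run_log.txt``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config: {config.to_dict()}"]

    mrna, protein, metadata, phenotypes, reference = _load_inputs(
        config, mrna, protein, metadata, phenotypes, reference
    )
    mrna, protein, metadata, phenotypes = _align(mrna, protein, metadata, phenotypes)
    log_lines.append(
        f"aligned: {len(metadata)} samples, {mrna.shape[0]} mRNA features, "
        f"{protein.shape[0]} protein features"
    )

    results: dict[str, pd.DataFrame] = {}

    size_factors = _stage("normalization")(tf.median_ratio_size_factors)(mrna)
    protein_rn = _stage("normalization")(tf.rank_normal_matrix)(protein, config.rank_offset)
    log_lines.append(f"size factors: gmean=1, range [{size_factors.min():.4g}, {size_factors.max():.4g}]")

    results["mrna_trends"] = _stage("mrna_trends")(tt.nb_trend_table)(
        mrna, size_factors, metadata, tt.MRNA_SPEC
    )
    results["protein_trends"] = _stage("protein_trends")(tt.lmm_trend_table)(
        protein_rn.values, metadata, tt.PROTEIN_SPEC
    )
    for name in ("mrna_trends", "protein_trends"):
        t = results[name]
        n_flag = int((~t["fit_flag"].isin(["ok", "vc_boundary"])).sum())
        n_fw = int((t["p_holm"] < config.alpha).sum())
        n_fdr = int((t["q_bh"] < config.fdr_q).sum())
        log_lines.append(
            f"{name}: {len(t)} features, {n_flag} flagged, "
            f"{n_fw} Holm<{config.alpha}, {n_fdr} BH<{config.fdr_q}"
        )

    results["concordance"] = _stage("concordance")(conc.classify_groups)(
        results["mrna_trends"], results["protein_trends"], config.fdr_q
    )
    frac = conc.group_fractions(results["concordance"])
    log_lines.append(f"concordance: {frac}")

    # mediation scan needs both platforms on the rank-normal scale
    vst = _stage("mediation")(tf.variance_stabilize)(mrna, size_factors)
    mrna_rn = _stage("mediation")(tf.rank_normal_matrix)(vst.values, config.rank_offset)
    med_tables = []
    for focal in ("age_coded", "sex"):
        t = _stage("mediation")(med.mediation_scan)(
            protein_rn.values, mrna_rn.values, metadata, focal
        )
        med_tables.append(t)
        summary = med.mediation_summary(t) if len(t.dropna(subset=["delta"])) >= 10 else {}
        log_lines.append(f"mediation focal={focal}: {summary}")
    results["mediation"] = pd.concat(med_tables, ignore_index=True)

    results["pca_summary"] = _stage("structure")(_pca_summary)(
        mrna_rn.values, metadata, config.pca_components
    )
    log_lines.append(f"pca: top fractions {results['pca_summary']['variance_fraction'].tolist()}")

    if reference is not None:
        markers = _stage("deconvolution")(struct.select_markers)(reference)
        bulk_uq = _stage("deconvolution")(tf.upper_quartile_normalize)(mrna)
        results["spv"] = _stage("deconvolution")(struct.spv_table)(bulk_uq, markers, metadata)
        log_lines.append(f"spv: {len(results['spv'])} cell types")

    if phenotypes is not None:
        results["phenotype_mediation"] = _stage("phenotype_mediation")(_phenotype_stage)(
            phenotypes, protein_rn.values, metadata
        )
        log_lines.append(f"phenotype mediation: {len(results['phenotype_mediation'])} rows")

    for name, table in results.items():
        dio.write_table(_rounded(table), out / f"{name}.tsv", index=False)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return results


def _load_inputs(config, mrna, protein, metadata, phenotypes, reference):
    if mrna is None:
        if config.mrna_path is None:
            raise StageError("stage 'input' failed: no mRNA matrix given")
        mrna = dio.read_expression_table(config.mrna_path)
    if protein is None:
        if config.protein_path is None:
            raise StageError("stage 'input' failed: no protein matrix given")
        protein = dio.read_expression_table(config.protein_path)
    if metadata is None:
        if config.metadata_path is None:
            raise StageError("stage 'input' failed: no metadata table given")
        metadata = dio.read_metadata(config.metadata_path)
    if phenotypes is None and config.phenotype_path is not None:
        phenotypes = dio.read_metadata(config.phenotype_path)
    if reference is None and config.reference_path is not None:
        reference = dio.read_expression_table(config.reference_path)
    return mrna, protein, metadata, phenotypes, reference


def _align(mrna, protein, metadata, phenotypes):
    samples = metadata.index.intersection(mrna.columns).intersection(protein.columns)
    if len(samples) == 0:
        raise StageError("stage 'input' failed: zero overlapping samples across inputs")
    metadata = metadata.loc[samples]
    mrna = mrna[samples]
    protein = protein[samples]
    if phenotypes is not None:
        phenotypes = phenotypes.reindex(samples)
    return mrna, protein, metadata, phenotypes


def _pca_summary(matrix: pd.DataFrame, metadata: pd.DataFrame, k: int) -> pd.DataFrame:
    res = struct.pca_variance(matrix, k)
    rows = []
    for j, comp in enumerate(res.scores.columns):
        s = res.scores[comp].to_numpy()
        rows.append({
            "component": comp,
            "variance_fraction": float(res.variance_fraction[j]),
            "p_age": struct.pc_association(s, metadata["age_coded"]),
            "p_sex": struct.pc_association(s, metadata["sex"].astype(str)),
        })
    return pd.DataFrame(rows)


def _phenotype_stage(phenotypes, protein_rn, metadata):
    rows = []
    for analyte in ("phosphate", "albumin"):
        if analyte not in phenotypes.columns or "creatinine" not in phenotypes.columns:
            continue
        adjusted = tf.adjust_urine_analyte(
            phenotypes[analyte].to_numpy(dtype=float),
            phenotypes["creatinine"].to_numpy(dtype=float),
            method="residual",
            floor=0.5,
        )
        # candidate mediator: protein with the strongest sex-adjusted partial r
        sex_ind = (metadata["sex"] == metadata["sex"].iloc[0]).to_numpy(dtype=float)[:, None]
        best, best_r = None, 0.0
        for g in protein_rn.index:
            r, _ = med.partial_correlation(adjusted, protein_rn.loc[g].to_numpy(), sex_ind)
            if abs(r) > abs(best_r):
                best, best_r = g, r
        res = med.phenotype_mediation_test(
            adjusted, protein_rn.loc[best].to_numpy(), metadata,
            phenotype_name=analyte, protein_id=str(best),
        )
        rows.append(res)
    return pd.DataFrame(rows)


def _rounded(table: pd.DataFrame) -> pd.DataFrame:
    # float_format in write_table already fixes the representation; nothing to do
    return table
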