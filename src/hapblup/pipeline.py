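"""End-to-end pipeline: select markers, phase, fit all models, evaluate.

Stage order follows the haplotype-assisted selection workflow: MAF filter,
complete-LD grouping, EM haplotype inference, the 1% haplotype frequency
filter, the four prediction models, and Pearson-correlation evaluation on
the training and masked validation sets. The run is fully determined by
the configuration (and seed, when the dataset is simulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import selection
from .config import SimulationConfig
from .datatypes import (
    DiplotypeAssignment,
    GenotypeDataset,
    HaplotypeDesign,
    LDSubset,
    ModelFit,
    SubsetCatalog,
    TruthBundle,
    VarianceComponents,
)
from .errors import HapblupError, ValidationError
from .evaluate import correlation_table
from .models import (
    build_design,
    build_numerator_relationship,
    fit_animal_model,
    fit_fixed_model,
    fit_random_model,
    rm2_scale_factors,
)
from .phasing import filter_haplotypes_by_frequency, phase_subsets
from .simulate import simulate_dataset

ALL_MODELS = ("FM", "RM1", "RM2", "AM")


class StageError(HapblupError):
    """Failure attributed to a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """Everything a full run produces, plus a JSON-ready summary."""

    dataset: GenotypeDataset
    truth: TruthBundle | None
    maf_records: pd.DataFrame
    retained_markers: np.ndarray
    subsets: list[LDSubset]
    catalogs: list[SubsetCatalog]
    assignments: list[DiplotypeAssignment]
    design: HaplotypeDesign
    fits: dict[str, ModelFit]
    predictions: dict[str, np.ndarray]
    breeding_values: dict[str, np.ndarray]
    correlations: pd.DataFrame
    bv_correlations: pd.DataFrame | None
    summary: dict = field(default_factory=dict)


def _align_to_dataset(fit: ModelFit, dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Predicted phenotypes and breeding values reordered to dataset ids."""
    index = {int(i): k for k, i in enumerate(fit.individual_ids)}
    order = np.array([index[int(i)] for i in dataset.ids])
    return fit.predicted_phenotypes[order], fit.breeding_values[order]


def run_pipeline(
    source: SimulationConfig | GenotypeDataset,
    truth: TruthBundle | None = None,
    maf_threshold: float = selection.DEFAULT_MAF_THRESHOLD,
    r2_tolerance: float = selection.DEFAULT_R2_TOLERANCE,
    freq_threshold: float = 0.01,
    models: tuple[str, ...] = ALL_MODELS,
    rm2_scale: str = "length_over_count",
    fixed_lambda: float | None = None,
    alpha: float = 0.05,
) -> PipelineResult:
    """Run the full analysis and return all intermediate and final results.

    ``source`` is either a simulation configuration (the dataset is
    generated, with ground truth) or an existing dataset (pass ``truth``
    for truth-based evaluation, or leave None to evaluate only among
    models and observed phenotypes). ``fixed_lambda`` bypasses REML with a
    user-chosen variance ratio for the random models.
    """
    if isinstance(source, SimulationConfig):
        try:
            dataset, truth = simulate_dataset(source)
        except Exception as exc:
            raise StageError("simulate", exc) from exc
    else:
        dataset = source
    if dataset.phenotypes is None or dataset.known_mask is None:
        raise ValidationError("pipeline needs phenotypes with a known/unknown mask")
    unknown = [m for m in models if m not in ALL_MODELS]
    if unknown:
        raise ValidationError(f"unknown models {unknown}; choose from {ALL_MODELS}")

    try:
        maf_records = selection.compute_maf(dataset)
        retained = selection.filter_by_maf(maf_records, threshold=maf_threshold)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("maf-filter", exc) from exc

    try:
        subsets = selection.group_perfect_ld(dataset, retained, tolerance=r2_tolerance)
    except Exception as exc:
        raise StageError("ld-grouping", exc) from exc

    try:
        catalogs, assignments = phase_subsets(dataset, subsets)
        hap_table = filter_haplotypes_by_frequency(catalogs, threshold=freq_threshold)
    except Exception as exc:
        raise StageError("phasing", exc) from exc

    try:
        design = build_design(dataset, catalogs, assignments)
    except Exception as exc:
        raise StageError("design", exc) from exc

    known = dataset.known_mask
    y = dataset.phenotypes[known]
    X_train = design.matrix[known]

    fits: dict[str, ModelFit] = {}
    vc_fixed = None
    if fixed_lambda is not None:
        vc_fixed = VarianceComponents(
            sigma2_g=1.0, sigma2_e=float(fixed_lambda), method="fixed-lambda"
        )
    try:
        if "FM" in models:
            fits["FM"] = fit_fixed_model(y, X_train, X_full=design.matrix, ids=dataset.ids)
        if "RM1" in models:
            fits["RM1"] = fit_random_model(
                y, X_train, variance_components=vc_fixed,
                X_full=design.matrix, ids=dataset.ids, model="RM1",
            )
        if "RM2" in models:
            fits["RM2"] = fit_random_model(
                y, X_train, scale_factors=rm2_scale_factors(design, mode=rm2_scale),
                variance_components=vc_fixed, X_full=design.matrix, ids=dataset.ids, model="RM2",
            )
        if "AM" in models:
            A = build_numerator_relationship(dataset.pedigree)
            fits["AM"] = fit_animal_model(
                y, dataset.pedigree, dataset.ids[known], A=A, variance_components=vc_fixed
            )
    except Exception as exc:
        raise StageError("model-fit", exc) from exc

    predictions: dict[str, np.ndarray] = {}
    breeding_values: dict[str, np.ndarray] = {}
    for name, fit in fits.items():
        pred, bv = _align_to_dataset(fit, dataset)
        predictions[name] = pred
        breeding_values[name] = bv

    try:
        correlations = correlation_table(
            predictions, dataset.phenotypes, known, alpha=alpha, reference_label="true"
        )
        bv_correlations = None
        if truth is not None:
            bv_correlations = correlation_table(
                breeding_values,
                truth.true_breeding_values,
                known,
                alpha=alpha,
                reference_label="true_bv",
            )
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    summary = _build_summary(
        dataset, maf_records, retained, subsets, hap_table, design, fits,
        correlations, bv_correlations,
        thresholds={
            "maf_threshold": maf_threshold,
            "r2_tolerance": r2_tolerance,
            "freq_threshold": freq_threshold,
            "alpha": alpha,
            "rm2_scale": rm2_scale,
        },
    )
    return PipelineResult(
        dataset=dataset,
        truth=truth,
        maf_records=maf_records,
        retained_markers=retained,
        subsets=subsets,
        catalogs=catalogs,
        assignments=assignments,
        design=design,
        fits=fits,
        predictions=predictions,
        breeding_values=breeding_values,
        correlations=correlations,
        bv_correlations=bv_correlations,
        summary=summary,
    )


def _build_summary(
    dataset: GenotypeDataset,
    maf_records: pd.DataFrame,
    retained: np.ndarray,
    subsets: list[LDSubset],
    hap_table: pd.DataFrame,
    design: HaplotypeDesign,
    fits: dict[str, ModelFit],
    correlations: pd.DataFrame,
    bv_correlations: pd.DataFrame | None,
    thresholds: dict,
) -> dict:
    chroms = list(pd.unique(dataset.marker_map["chrom"]))
    chrom_col = dataset.marker_map["chrom"].to_numpy()
    per_chrom = {}
    for c in chroms:
        in_ld = sum(s.size for s in subsets if s.chrom == str(c))
        per_chrom[str(c)] = {
            "all_markers": int((chrom_col == c).sum()),
            "maf_retained": int((chrom_col[retained] == c).sum()),
            "complete_ld": int(in_ld),
        }
    size_hist = selection.subset_size_histogram(subsets)
    summary = {
        "n_individuals": int(dataset.n_individuals),
        "n_known": int(dataset.known_mask.sum()),
        "n_unknown": int((~dataset.known_mask).sum()),
        "thresholds": thresholds,
        "markers": per_chrom,
        "n_subsets": len(subsets),
        "subset_sizes": {
            str(c): {int(r["size"]): int(r["count"])
                     for _, r in size_hist[size_hist["chrom"] == str(c)].iterrows()}
            for c in chroms
        },
        "n_haplotypes": int(hap_table["n_haplotypes"].sum()) if len(hap_table) else 0,
        "n_retained_haplotypes": int(hap_table["n_retained"].sum()) if len(hap_table) else 0,
        "haplotype_counts": hap_table.to_dict(orient="records"),
        "design_columns": int(design.n_columns),
        "models": {
            name: {
                "mu": float(fit.mu),
                "sigma2_g": float(fit.variance_components.sigma2_g),
                "sigma2_e": float(fit.variance_components.sigma2_e),
                "vc_method": fit.variance_components.method,
                "vc_converged": bool(fit.variance_components.converged),
            }
            for name, fit in fits.items()
        },
        "correlations": correlations.to_dict(orient="records"),
    }
    if bv_correlations is not None:
        summary["breeding_value_correlations"] = bv_correlations.to_dict(orient="records")
    return summary
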