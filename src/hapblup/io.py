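"""File formats: TSV dataset bundle, optional VCF import, report tables.

All files are UTF-8, tab-separated, with '#' comment lines permitted.
The bundle written/read by this module:

* ``genotypes.tsv``  — id column + one dosage column per marker (0/1/2).
* ``map.tsv``        — chrom, marker, pos (1-based in files, 0-based in
  memory).
* ``pedigree.tsv``   — id, sire, dam (0 = unknown parent).
* ``phenotypes.tsv`` — id, phenotype (NA = missing), known (1/0).
* ``truth.tsv``      — id, true_bv (evaluation only).

Reports mirror the pipeline's four result tables: per-chromosome marker
reduction counts, the subset-size histogram, haplotype counts by
chromosome and length, and the model correlation matrix, plus a
machine-readable JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, Pedigree, TruthBundle
from .errors import PedigreeError, ValidationError
from .evaluate import format_correlation_matrix

GENOTYPES_FILE = "genotypes.tsv"
MAP_FILE = "map.tsv"
PEDIGREE_FILE = "pedigree.tsv"
PHENOTYPES_FILE = "phenotypes.tsv"
TRUTH_FILE = "truth.tsv"

_READ_OPTS = dict(sep="\t", comment="#", encoding="utf-8")


def _toposort(ids: np.ndarray, sires: np.ndarray, dams: np.ndarray) -> np.ndarray:
    """Row order placing parents before offspring; raises on cycles."""
    known = set(ids.tolist())
    depth: dict[int, int] = {}
    visiting: set[int] = set()
    parent = {int(i): (int(s), int(d)) for i, s, d in zip(ids, sires, dams)}

    def resolve(i: int) -> int:
        if i in depth:
            return depth[i]
        if i in visiting:
            raise PedigreeError(f"pedigree cycle involving individual {i}")
        visiting.add(i)
        s, d = parent[i]
        ps = resolve(s) if s in known else -1
        pd_ = resolve(d) if d in known else -1
        visiting.discard(i)
        depth[i] = max(ps, pd_) + 1
        return depth[i]

    for i in parent:
        resolve(i)
    order = np.argsort([depth[int(i)] for i in ids], kind="stable")
    return order


def read_pedigree(path: str | Path) -> Pedigree:
    """Read and topologically sort a three-column pedigree file."""
    df = pd.read_csv(path, **_READ_OPTS)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValidationError(f"pedigree file needs columns {sorted(required)}, has {list(df.columns)}")
    ids = df["id"].to_numpy(dtype=np.int64)
    sires = df["sire"].to_numpy(dtype=np.int64)
    dams = df["dam"].to_numpy(dtype=np.int64)
    if ids.size != np.unique(ids).size:
        dup = pd.Series(ids)
        raise PedigreeError(f"duplicated pedigree ids: {dup[dup.duplicated()].tolist()[:5]}")
    order = _toposort(ids, sires, dams)
    ped = Pedigree(ids=ids[order], sires=sires[order], dams=dams[order])
    ped.validate()
    return ped


def write_dataset(dataset: GenotypeDataset, out_dir: str | Path, truth: TruthBundle | None = None) -> Path:
    """Write the standard dataset bundle; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    markers = dataset.marker_map["marker"].tolist()
    geno = pd.DataFrame(dataset.dosages, columns=markers)
    geno.insert(0, "id", dataset.ids)
    geno.to_csv(out / GENOTYPES_FILE, sep="\t", index=False)

    map_out = dataset.marker_map.copy()
    map_out["pos"] = map_out["pos"].astype(np.int64) + 1  # 1-based on disk
    map_out.to_csv(out / MAP_FILE, sep="\t", index=False)

    ped = dataset.pedigree
    pd.DataFrame({"id": ped.ids, "sire": ped.sires, "dam": ped.dams}).to_csv(
        out / PEDIGREE_FILE, sep="\t", index=False
    )

    if dataset.phenotypes is not None:
        values = [
            "NA" if np.isnan(v) else repr(float(v)) for v in dataset.phenotypes
        ]
        pd.DataFrame(
            {
                "id": dataset.ids,
                "phenotype": values,
                "known": dataset.known_mask.astype(int),
            }
        ).to_csv(out / PHENOTYPES_FILE, sep="\t", index=False)

    if truth is not None:
        pd.DataFrame(
            {"id": dataset.ids, "true_bv": [repr(float(v)) for v in truth.true_breeding_values]}
        ).to_csv(out / TRUTH_FILE, sep="\t", index=False)
    return out


def read_dataset(directory: str | Path) -> GenotypeDataset:
    """Read and fully validate a dataset bundle written by :func:`write_dataset`."""
    d = Path(directory)
    for name in (GENOTYPES_FILE, MAP_FILE, PEDIGREE_FILE):
        if not (d / name).exists():
            raise ValidationError(f"missing required file {name} in {d}")

    marker_map = pd.read_csv(d / MAP_FILE, dtype={"chrom": str, "marker": str}, **_READ_OPTS)
    required = {"chrom", "marker", "pos"}
    if not required.issubset(marker_map.columns):
        raise ValidationError(f"map file needs columns {sorted(required)}")
    if marker_map["pos"].min() < 1:
        raise ValidationError("map positions must be 1-based and positive on disk")
    marker_map = marker_map[["chrom", "marker", "pos"]].copy()
    marker_map["pos"] = marker_map["pos"].astype(np.int64) - 1  # 0-based in memory

    geno = pd.read_csv(d / GENOTYPES_FILE, **_READ_OPTS)
    if "id" not in geno.columns:
        raise ValidationError("genotype file needs an 'id' first column")
    file_markers = [c for c in geno.columns if c != "id"]
    if file_markers != marker_map["marker"].tolist():
        raise ValidationError("genotype columns do not match the marker map (names or order)")
    ids = geno["id"].to_numpy(dtype=np.int64)
    dosages = geno[file_markers].to_numpy()
    if not np.issubdtype(dosages.dtype, np.integer):
        raise ValidationError("genotype dosages must be integers")
    dosages = dosages.astype(np.int8)

    pedigree = read_pedigree(d / PEDIGREE_FILE)

    phenotypes = known = None
    if (d / PHENOTYPES_FILE).exists():
        phen = pd.read_csv(d / PHENOTYPES_FILE, na_values=["NA"], **_READ_OPTS)
        if not {"id", "phenotype", "known"}.issubset(phen.columns):
            raise ValidationError("phenotype file needs columns id, phenotype, known")
        phen = phen.set_index("id").reindex(ids)
        if phen["known"].isna().any():
            missing = set(ids.tolist()) - set(pd.read_csv(d / PHENOTYPES_FILE, **_READ_OPTS)["id"])
            raise ValidationError(f"phenotype rows missing for individuals {sorted(missing)[:5]}")
        phenotypes = phen["phenotype"].to_numpy(dtype=np.float64)
        known = phen["known"].to_numpy(dtype=np.int64).astype(bool)

    dataset = GenotypeDataset(
        ids=ids,
        marker_map=marker_map,
        dosages=dosages,
        pedigree=pedigree,
        phenotypes=phenotypes,
        known_mask=known,
    )
    dataset.validate()
    return dataset


def read_truth(directory: str | Path, ids: np.ndarray) -> np.ndarray:
    """True breeding values aligned to the given individual order."""
    df = pd.read_csv(Path(directory) / TRUTH_FILE, **_READ_OPTS).set_index("id")
    return df["true_bv"].reindex(ids).to_numpy(dtype=np.float64)


def dataset_from_vcf(
    vcf_path: str | Path,
    pedigree: Pedigree,
    phenotypes: np.ndarray | None = None,
    known_mask: np.ndarray | None = None,
) -> GenotypeDataset:
    """Build a dataset from a VCF (GT field only; ALT is the counted allele)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = np.array([int(s) for s in vcf.samples], dtype=np.int64)
    rows = []
    chroms, names, positions = [], [], []
    for variant in vcf:
        gt = variant.gt_types  # 0=hom ref, 1=het, 2=hom alt, 3=unknown
        if (gt == 3).any():
            raise ValidationError(f"missing genotype at {variant.CHROM}:{variant.POS}")
        rows.append(gt.astype(np.int8))
        chroms.append(str(variant.CHROM))
        names.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        positions.append(variant.POS - 1)
    marker_map = pd.DataFrame({"chrom": chroms, "marker": names, "pos": positions})
    dataset = GenotypeDataset(
        ids=sample_ids,
        marker_map=marker_map,
        dosages=np.array(rows).T,
        pedigree=pedigree,
        phenotypes=phenotypes,
        known_mask=known_mask,
    )
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# reports


def write_reports(result, out_dir: str | Path) -> dict[str, Path]:
    """Write the four result tables and the JSON summary.

    ``result`` is a :class:`~hapblup.pipeline.PipelineResult`; stages that
    did not run produce no table and are flagged absent in the summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    absent: list[str] = []

    summary = dict(result.summary) if getattr(result, "summary", None) else {}

    markers = summary.get("markers")
    if markers:
        chroms = list(markers)
        tbl = pd.DataFrame(
            {
                "criterion": ["all markers", "MAF-retained", "complete-LD"],
                **{
                    c: [markers[c]["all_markers"], markers[c]["maf_retained"], markers[c]["complete_ld"]]
                    for c in chroms
                },
            }
        )
        tbl.to_csv(out / "table1_marker_reduction.tsv", sep="\t", index=False)
        written["table1"] = out / "table1_marker_reduction.tsv"
    else:
        absent.append("table1")

    subsets = getattr(result, "subsets", None)
    if subsets is not None:
        from .selection import subset_size_histogram

        hist = subset_size_histogram(subsets)
        if len(hist):
            wide = hist.pivot(index="chrom", columns="size", values="count").fillna(0).astype(int)
            wide.insert(0, "all", wide.sum(axis=1))
            wide.columns = ["all"] + [f"{s}-SNP" for s in wide.columns[1:]]
        else:
            wide = pd.DataFrame(columns=["all"])
        wide.to_csv(out / "table2_subset_sizes.tsv", sep="\t")
        written["table2"] = out / "table2_subset_sizes.tsv"
    else:
        absent.append("table2")

    catalogs = getattr(result, "catalogs", None)
    if catalogs is not None:
        from .phasing import haplotype_count_table

        haplotype_count_table(catalogs).to_csv(
            out / "table3_haplotype_counts.tsv", sep="\t", index=False
        )
        written["table3"] = out / "table3_haplotype_counts.tsv"
    else:
        absent.append("table3")

    correlations = getattr(result, "correlations", None)
    if correlations is not None and len(correlations):
        labels = ["true"] + [m for m in ("FM", "RM1", "RM2", "AM") if m in getattr(result, "fits", {})]
        format_correlation_matrix(correlations, labels).to_csv(
            out / "table4_correlations.tsv", sep="\t"
        )
        written["table4"] = out / "table4_correlations.tsv"
    else:
        absent.append("table4")

    summary["absent_reports"] = absent
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    written["summary"] = out / "summary.json"
    return written
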