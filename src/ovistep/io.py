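"""Readers and writers for the pipeline's plain-text formats.

Pedigree/phenotype/truth tables travel as CSV, genotypes as PLINK-style
.ped/.map text or a compact matrix TSV (rows = animals, columns = SNPs,
values 0/1/2/NA), and the pipeline configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genoqc import GenotypePanel, default_snp_meta
from .pedigree import Pedigree, sort_and_validate

UNKNOWN_OUT = "0"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    return sort_and_validate(df)


# ---------------------------------------------------------------------------
# phenotypes / truth
# ---------------------------------------------------------------------------

def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"animal": str})


def write_truth(truth, path) -> None:
    rows = []
    for trait, s in truth.breeding.items():
        df = pd.DataFrame({"animal": s.index, "trait": trait, "true_bv": s.to_numpy()})
        if trait in truth.maternal:
            df["true_maternal"] = truth.maternal[trait].reindex(s.index).to_numpy()
        if trait in truth.permanent_env:
            df["true_pe"] = truth.permanent_env[trait].reindex(s.index).to_numpy()
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes(panel: GenotypePanel, prefix, dialect: str = "plink") -> None:
    """Write a panel as PLINK .ped/.map (plus array-label sidecar) or matrix TSV."""
    prefix = Path(prefix)
    if dialect == "plink":
        meta = panel.snp_meta
        with open(prefix.with_suffix(".map"), "w") as fh:
            for s in panel.snp_ids:
                fh.write(f"{meta.loc[s, 'chrom']}\t{s}\t0\t{meta.loc[s, 'pos']}\n")
        aa = meta["allele_a"].to_numpy()
        bb = meta["allele_b"].to_numpy()
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, animal in enumerate(panel.animal_ids):
                fields = ["FAM", animal, "0", "0", "0", "-9"]
                g = panel.calls[i]
                for j in range(panel.n_snps):
                    if g[j] < 0:
                        fields.extend(["0", "0"])
                    else:
                        fields.extend([bb[j] if g[j] >= 1 else aa[j],
                                       bb[j] if g[j] == 2 else aa[j]])
                fh.write(" ".join(fields) + "\n")
        pd.DataFrame({"sample": panel.animal_ids, "array": panel.array_labels}).to_csv(
            str(prefix) + ".arrays.tsv", sep="\t", index=False
        )
        meta.reset_index().rename(columns={meta.index.name or "index": "snp"})[
            ["snp", "allele_a", "allele_b"]
        ].to_csv(str(prefix) + ".alleles.tsv", sep="\t", index=False)
    elif dialect == "matrix":
        df = pd.DataFrame(panel.calls, index=panel.animal_ids, columns=panel.snp_ids)
        df = df.replace(-1, pd.NA)
        df.insert(0, "array", panel.array_labels)
        df.to_csv(str(prefix) + ".genotypes.tsv", sep="\t", index_label="animal", na_rep="NA")
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def read_genotypes(path, dialect: str | None = None) -> GenotypePanel:
    """Read genotypes from a PLINK .ped/.map prefix or a matrix TSV file.

    PLINK allele pairs become counted-allele dosages using the
    ``<prefix>.alleles.tsv`` sidecar when present, otherwise the counted
    allele of each SNP is the lexicographically later allele observed.
    """
    path = Path(path)
    if dialect is None:
        dialect = "matrix" if path.suffix == ".tsv" else "plink"
    if dialect == "matrix":
        df = pd.read_csv(path, sep="\t", dtype={"animal": str})
        if "animal" not in df.columns:
            raise ParseError(f"{path}: matrix dialect needs an 'animal' column")
        animals = df["animal"].tolist()
        labels = df["array"].tolist() if "array" in df.columns else ["50K"] * len(animals)
        snps = [c for c in df.columns if c not in ("animal", "array")]
        calls = df[snps].to_numpy(dtype=float)
        calls = np.where(np.isnan(calls), -1, calls).astype(np.int8)
        return GenotypePanel(animals, snps, calls, labels)

    prefix = path.with_suffix("") if path.suffix in (".ped", ".map") else path
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    snps: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chroms.append(parts[0])
            snps.append(parts[1])
            poss.append(int(parts[3]))
    m = len(snps)

    allele_map: dict[str, tuple[str, str]] = {}
    sidecar = Path(str(prefix) + ".alleles.tsv")
    if sidecar.exists():
        adf = pd.read_csv(sidecar, sep="\t", dtype=str)
        allele_map = {r.snp: (r.allele_a, r.allele_b) for r in adf.itertuples()}

    animals: list[str] = []
    raw_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            animals.append(parts[1])
            raw_pairs.append([(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)])

    # counted allele per SNP: sidecar allele_b, else lexicographically later
    counted: list[str] = []
    other: list[str] = []
    for j, s in enumerate(snps):
        if s in allele_map:
            a, b = allele_map[s]
        else:
            seen = sorted({al for row in raw_pairs for al in row[j] if al != "0"})
            if len(seen) > 2:
                raise ParseError(f"{ped_path}: SNP {s} has more than two alleles: {seen}")
            seen = (seen + ["A", "B"])[:2] if len(seen) < 2 else seen
            a, b = seen[0], seen[1]
        counted.append(b)
        other.append(a)

    calls = np.full((len(animals), m), -1, dtype=np.int8)
    for i, row in enumerate(raw_pairs):
        for j, (x, y) in enumerate(row):
            if x == "0" or y == "0":
                continue
            dose = 0
            for al in (x, y):
                if al == counted[j]:
                    dose += 1
                elif al != other[j]:
                    raise ParseError(
                        f"{ped_path}: sample {animals[i]} SNP {snps[j]} has "
                        f"unexpected allele {al!r}"
                    )
            calls[i, j] = dose

    arrays_path = Path(str(prefix) + ".arrays.tsv")
    if arrays_path.exists():
        adf = pd.read_csv(arrays_path, sep="\t", dtype=str).set_index("sample")
        labels = [adf.loc[a, "array"] if a in adf.index else "50K" for a in animals]
    else:
        labels = ["50K"] * len(animals)
    meta = default_snp_meta(snps)
    meta["chrom"] = chroms
    meta["pos"] = poss
    meta["allele_a"] = other
    meta["allele_b"] = counted
    return GenotypePanel(animals, snps, calls, labels, meta)


# ---------------------------------------------------------------------------
# matrices / results
# ---------------------------------------------------------------------------

def write_symmetric_triplets(ids, values: np.ndarray, path) -> None:
    """Upper-triangle triplet TSV (row id, col id, value) for inspection."""
    with open(path, "w") as fh:
        fh.write("row\tcol\tvalue\n")
        n = len(ids)
        for i in range(n):
            for j in range(i, n):
                v = values[i, j]
                if v != 0.0:
                    fh.write(f"{ids[i]}\t{ids[j]}\t{v:.10g}\n")


def write_evaluation(result, path) -> None:
    df = pd.DataFrame(
        {
            "animal": result.ebv.index,
            "trait": result.trait,
            "method": result.method,
            "ebv": result.ebv.to_numpy(),
            "reliability": result.reliability.reindex(result.ebv.index).to_numpy(),
            "accuracy": result.accuracy.reindex(result.ebv.index).to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths, thresholds and mode flags for the end-to-end pipeline."""

    output_dir: str = "ovistep_out"
    pedigree_path: str | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    simulate: bool = True
    traits: list[str] = field(default_factory=lambda: ["swt"])
    call_rate: float = 0.894
    maf: float = 0.05
    hwe_alpha: float = 0.05
    oh_threshold: float = 0.01
    blend_weight: float = 0.95
    cg_min: int = 5
    run_reml: bool = False
    seed: int = 2024
    sim: dict = field(default_factory=dict)
    components: dict = field(default_factory=dict)  # trait -> {sigma2_a, sigma2_e, ...}

    def validate(self) -> None:
        for name, lo, hi in (
            ("call_rate", 0.0, 1.0), ("maf", 0.0, 0.5), ("hwe_alpha", 0.0, 1.0),
            ("oh_threshold", 0.0, 1.0), ("blend_weight", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if not self.simulate:
            for p in (self.pedigree_path, self.phenotype_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"required input path missing: {p}")


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig(**data)
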