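"""End-to-end orchestration: simulate/load -> QC -> parentage -> GRM/PCA ->
(REML) -> evaluate under both relationship structures -> accuracy comparison.

Each stage writes its artifact into the output directory and logs input and
output counts; a manifest records which stages completed, and reruns with
the same configuration and seed reproduce identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .genoqc import filter_samples_by_call_rate, filter_snps, verify_and_discover_parentage
from .grm import allele_frequencies, genomic_relationship_vanraden1, principal_components
from .mme import TRAIT_SPECS, ModelSpec, run_evaluation
from .reliability import compare_accuracies
from .simulate import SimConfig, drop_genotypes, simulate_pedigree, simulate_traits
from .varcomp import VarianceComponents, reml_univariate

log = logging.getLogger("ovistep")


def _components_from_dict(d: dict) -> VarianceComponents:
    return VarianceComponents(
        sigma2_a=float(d["sigma2_a"]), sigma2_e=float(d["sigma2_e"]),
        sigma2_m=float(d["sigma2_m"]) if d.get("sigma2_m") else None,
        sigma2_pe=float(d["sigma2_pe"]) if d.get("sigma2_pe") else None,
    )


def run_pipeline(config: oio.PipelineConfig) -> dict:
    """Run every stage; returns a manifest of artifacts written."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def done(stage: str, path: Path, n_in: int, n_out: int) -> None:
        manifest[stage] = str(path)
        log.info("%s: in=%d out=%d -> %s", stage, n_in, n_out, path)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    components = {
        t: _components_from_dict(d) if isinstance(d, dict) else d
        for t, d in config.components.items()
    }
    if not components:
        components = {"swt": VarianceComponents(sigma2_a=8.97, sigma2_e=18.58)}

    if config.simulate:
        sim = SimConfig(seed=config.seed, trait_components=components, **config.sim)
        ped = simulate_pedigree(sim)
        panel = drop_genotypes(ped, sim)
        phen, truth = simulate_traits(ped, sim, traits=list(config.traits))
        oio.write_pedigree(ped, out / "pedigree.csv")
        oio.write_genotypes(panel, out / "genotypes", dialect="matrix")
        oio.write_phenotypes(phen, out / "phenotypes.csv")
        oio.write_truth(truth, out / "truth.csv")
        done("simulate", out / "pedigree.csv", 0, ped.n)
    else:
        ped = oio.read_pedigree(config.pedigree_path)
        phen = oio.read_phenotypes(config.phenotype_path)
        panel = oio.read_genotypes(config.genotype_path) if config.genotype_path else None

    if panel is not None:
        n0 = panel.n_samples
        panel, rep_s = filter_samples_by_call_rate(panel, config.call_rate)
        ped, rep_p = verify_and_discover_parentage(panel, ped, config.oh_threshold)
        panel, rep_q = filter_snps(panel, config.call_rate, config.maf, config.hwe_alpha)
        qc = pd.concat(
            [v.assign(stage=k) for r in (rep_s, rep_p, rep_q)
             for k, v in r.to_frames().items() if len(v)],
            ignore_index=True,
        ) if any(len(v) for r in (rep_s, rep_p, rep_q) for v in r.to_frames().values()) else pd.DataFrame()
        qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        done("qc", out / "qc_report.tsv", n0, panel.n_samples)

        G = genomic_relationship_vanraden1(panel, allele_frequencies(panel))
        np.savetxt(out / "grm_diag.tsv", np.diag(G.values), fmt="%.6g")
        scores, fractions = principal_components(panel, k=2)
        pd.DataFrame(
            {"animal": panel.animal_ids, "pc1": scores[:, 0], "pc2": scores[:, 1]}
        ).to_csv(out / "pca_scores.csv", index=False)
        (out / "pca_variance.txt").write_text(
            "\n".join(f"PC{k + 1}\t{f:.4f}" for k, f in enumerate(fractions)) + "\n"
        )
        done("grm_pca", out / "pca_scores.csv", panel.n_samples, len(scores))

    results = {}
    for trait in config.traits:
        spec = TRAIT_SPECS.get(trait, ModelSpec(trait=trait))
        vc = components.get(trait)
        if config.run_reml:
            vc = reml_univariate(phen, spec, ped, init=vc)
            pd.DataFrame([{"trait": trait, "sigma2_a": vc.sigma2_a,
                           "sigma2_m": vc.sigma2_m, "sigma2_pe": vc.sigma2_pe,
                           "sigma2_e": vc.sigma2_e, "sigma2_p": vc.sigma2_p,
                           "h2": vc.h2}]).to_csv(out / f"varcomp_{trait}.csv", index=False)
            done(f"reml_{trait}", out / f"varcomp_{trait}.csv", len(phen), 1)
        if vc is None:
            raise ValueError(f"no variance components for trait {trait!r}")
        res_p = run_evaluation(ped, panel, phen, spec, vc, mode="pblup")
        oio.write_evaluation(res_p, out / f"ebv_{trait}_pblup.tsv")
        results[(trait, "pblup")] = res_p
        if panel is not None:
            res_ss = run_evaluation(ped, panel, phen, spec, vc, mode="ssblup",
                                    blend_weight=config.blend_weight)
            oio.write_evaluation(res_ss, out / f"ebv_{trait}_ssblup.tsv")
            results[(trait, "ssblup")] = res_ss
            cmp_res = compare_accuracies(res_p, res_ss)
            cmp_res.strata.to_csv(out / f"accuracy_comparison_{trait}.tsv",
                                  sep="\t", index=False)
            done(f"compare_{trait}", out / f"accuracy_comparison_{trait}.tsv",
                 ped.n, len(cmp_res.per_animal))
        done(f"evaluate_{trait}", out / f"ebv_{trait}_pblup.tsv", len(phen), ped.n)
    return manifest
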