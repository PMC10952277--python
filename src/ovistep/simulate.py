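"""Synthetic flock data with the exact statistical structure the evaluation
model assumes: a multi-flock hierarchical-mating pedigree, gene-dropped SNP
genotypes, phenotypes built from additive + maternal + permanent-environment
+ residual effects, ordinal hoof/udder health scores on the ln(sum+1) scale,
and deliberately planted pedigree errors for parentage-verification tests.

Every operation is deterministic given the configuration seed, so the
simulator doubles as a ground-truth test bed for the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genoqc import GenotypePanel
from .pedigree import Pedigree, inbreeding_array
from .varcomp import VarianceComponents

ARRAY_LABELS = ("HD", "50K", "LDv1", "LDv2")
ARRAY_PROBS = (0.12, 0.29, 0.24, 0.35)
#: per-trait number of scored sites (hooves / udder halves)
HEALTH_SITES = {"footrot": 4, "cmt": 2}
#: baseline trait means (kg / mm), placing phenotypes inside biological ranges
TRAIT_MEANS = {"bwt": 5.0, "eww": 22.0, "swt": 42.0, "md": 30.0, "fd": 3.5}


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic flock.

    Demographic defaults describe a small multi-flock purebred population
    with hierarchical matings (each sire serving ``dams_per_sire`` dams
    within flock, a fraction of sires exchanged across flocks to create the
    genetic links contemporary-group models rely on).
    """

    n_founders: int = 80
    n_generations: int = 3
    n_flocks: int = 4
    dams_per_sire: int = 10
    progeny_per_dam: int = 2
    n_snps: int = 500
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_error_rate: float = 0.001
    missing_rate: float = 0.01
    pedigree_error_rate: float = 0.0
    prop_genotyped: float = 0.35
    prop_phenotyped: float = 0.85
    trait_components: dict = field(default_factory=dict)
    seed: int = 2024
    # secondary knobs (documented defaults, not calibrated to any real flock)
    sire_exchange_frac: float = 0.15
    fixed_effect_sd: float = 1.0
    young_phenotyped_factor: float = 0.25
    foster_rate: float = 0.02
    et_rate: float = 0.01
    base_year: int = 2015
    health_mean: float = 0.6
    health_fixed_sd: float = 0.1
    visits_range: tuple[int, int] = (1, 5)
    #: "marker": direct genetic values are sums of SNP effects over the
    #: gene-dropped genome (genomic information is real); "polygenic":
    #: pedigree recursion only (markers carry no trait signal)
    genetic_architecture: str = "marker"

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "n_flocks", "dams_per_sire",
                     "progeny_per_dam", "n_snps"):
            if getattr(self, name) < (0 if name == "n_generations" else 1):
                raise ConfigError(f"{name} must be >= 1")
        for name in ("genotyping_error_rate", "missing_rate", "pedigree_error_rate",
                     "prop_genotyped", "prop_phenotyped"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be a probability in [0,1], got {v}")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("founder_maf_range must lie within (0, 0.5]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TrueValues:
    """Simulated genetic truth, keyed trait -> Series over animal ids."""

    breeding: dict = field(default_factory=dict)
    maternal: dict = field(default_factory=dict)
    permanent_env: dict = field(default_factory=dict)

    def true_breeding_value(self, animal: str, trait: str) -> float:
        return float(self.breeding[trait][animal])


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation multi-flock pedigree with hierarchical matings."""
    rng = config.rng(0)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[str] = []
    flock: list[str] = []
    by: list[int] = []

    def add(s: int, d: int, sx: str, fl: str, year: int) -> int:
        ids.append(f"A{len(ids) + 1:06d}")
        sire.append(s)
        dam.append(d)
        sex.append(sx)
        flock.append(fl)
        by.append(year)
        return len(ids) - 1

    per_flock = [config.n_founders // config.n_flocks] * config.n_flocks
    for k in range(config.n_founders % config.n_flocks):
        per_flock[k] += 1
    generation = []
    for f, nf in enumerate(per_flock):
        n_male = max(1, round(nf / (2 + config.dams_per_sire / 2)))
        for j in range(nf):
            sx = "M" if j < n_male else "F"
            generation.append(add(-1, -1, sx, f"FL{f + 1}", config.base_year))

    for g in range(1, config.n_generations + 1):
        year = config.base_year + g
        males = {f: [i for i in generation if sex[i] == "M" and flock[i] == f"FL{f + 1}"]
                 for f in range(config.n_flocks)}
        nxt: list[int] = []
        for f in range(config.n_flocks):
            fl = f"FL{f + 1}"
            dams = [i for i in generation if sex[i] == "F" and flock[i] == fl]
            if not dams:
                continue
            n_sires = math.ceil(len(dams) / config.dams_per_sire)
            pool = males[f]
            chosen: list[int] = []
            for _ in range(n_sires):
                if rng.random() < config.sire_exchange_frac or not pool:
                    others = [i for ff, ms in males.items() if ff != f for i in ms]
                    src = others if others else pool
                else:
                    src = pool
                chosen.append(int(rng.choice(src)))
            order = rng.permutation(len(dams))
            for k, di in enumerate(order):
                d = dams[di]
                s = chosen[k // config.dams_per_sire]
                litter = 1 + min(int(rng.poisson(max(config.progeny_per_dam - 1, 0))), 4)
                for _ in range(litter):
                    sx = "M" if rng.random() < 0.5 else "F"
                    nxt.append(add(s, d, sx, fl, year))
        generation = nxt
        if not generation:
            break

    return Pedigree(ids, np.array(sire), np.array(dam), np.array(sex, dtype=object),
                    np.array(flock, dtype=object), np.array(by))


def _gene_drop(ped: Pedigree, config: SimConfig):
    """True (error-free) gene-dropped genotype matrix and founder frequencies.

    Drawn from a dedicated seed stream so genotype- and trait-simulation see
    the identical realized genome.
    """
    if not np.all(ped.sire < np.arange(ped.n)) or not np.all(ped.dam < np.arange(ped.n)):
        raise ValueError("pedigree is not topologically sorted")
    rng = config.rng(1)
    m = config.n_snps
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, m)
    G = np.zeros((ped.n, m), dtype=np.int8)
    for i in range(ped.n):
        alleles = np.zeros(m, dtype=np.int8)
        for parent in (ped.sire[i], ped.dam[i]):
            if parent < 0:
                alleles += (rng.random(m) < p).astype(np.int8)
            else:
                alleles += (rng.random(m) < G[parent] / 2.0).astype(np.int8)
        G[i] = alleles
    return G, p, rng


def drop_genotypes(
    ped: Pedigree, config: SimConfig, apply_noise: bool = True, all_animals: bool = False
) -> GenotypePanel:
    """Gene-drop biallelic genotypes through the pedigree.

    Founders are drawn from Hardy-Weinberg proportions at per-SNP founder
    frequencies; every non-founder receives one Mendelian-sampled allele per
    parent (an unknown parent is a base-population draw).  Genotyping error
    (single-allele flips), missingness and the ungenotyped mask are then
    applied at the configured rates.
    """
    G, p, rng = _gene_drop(ped, config)
    m = config.n_snps
    calls = G.copy()
    if apply_noise:
        if config.genotyping_error_rate > 0:
            err = rng.random(calls.shape) < config.genotyping_error_rate
            direction = rng.random(calls.shape) < 0.5
            flipped = np.where(calls == 1, np.where(direction, 0, 2),
                               np.where(calls == 0, 1, 1))
            calls = np.where(err, flipped, calls).astype(np.int8)
        if config.missing_rate > 0:
            calls = np.where(rng.random(calls.shape) < config.missing_rate,
                             np.int8(-1), calls)

    if all_animals:
        chosen = np.arange(ped.n)
    else:
        n_geno = int(round(config.prop_genotyped * ped.n))
        weights = 1.0 + (ped.birth_year - ped.birth_year.min()).astype(float)
        weights /= weights.sum()
        chosen = np.sort(rng.choice(ped.n, size=n_geno, replace=False, p=weights))
    labels = [str(rng.choice(ARRAY_LABELS, p=ARRAY_PROBS)) for _ in chosen]
    return GenotypePanel(
        [ped.ids[i] for i in chosen],
        [f"SNP{j + 1:05d}" for j in range(m)],
        calls[chosen],
        labels,
    )


def _marker_breeding_values(
    genomes: np.ndarray, p: np.ndarray, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive values as a sum of SNP effects over the gene-dropped genome.

    Effects are drawn i.i.d. normal and rescaled so the base-population
    additive variance (2 sum p(1-p) alpha^2 under founder HWE) is exactly
    ``sigma2``.  Because offspring genotypes are Mendelian samples of the
    parents', these values satisfy the usual additive recursion
    a = 0.5(a_s + a_d) + Mendelian deviation, while being genuinely encoded
    in the markers - which is what single-step evaluation exploits.
    """
    if sigma2 <= 0:
        return np.zeros(genomes.shape[0])
    m = genomes.shape[1]
    alpha = rng.normal(0.0, 1.0, m)
    scale2 = float(np.sum(2.0 * p * (1 - p) * alpha**2))
    alpha *= math.sqrt(sigma2 / scale2)
    return (genomes - 2.0 * p) @ alpha


def _breeding_values(ped: Pedigree, sigma2: float, F: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Additive values by the pedigree recursion with Mendelian sampling.

    Used for effects that are not tied to the markers (the maternal genetic
    effect, and all traits under the polygenic architecture).  Unknown
    parents are replaced by fresh base-population draws, keeping the
    unconditional variance at sigma2 for non-inbred lines.
    """
    sd = math.sqrt(sigma2) if sigma2 > 0 else 0.0
    a = np.zeros(ped.n)
    if sd == 0:
        return a
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            a[i] = rng.normal(0.0, sd)
            continue
        pa_s = a[s] if s >= 0 else rng.normal(0.0, sd)
        pa_d = a[d] if d >= 0 else rng.normal(0.0, sd)
        Fs = F[s] if s >= 0 else 0.0
        Fd = F[d] if d >= 0 else 0.0
        ms_var = 0.5 * sigma2 * (1.0 - (Fs + Fd) / 2.0)
        a[i] = 0.5 * (pa_s + pa_d) + rng.normal(0.0, math.sqrt(ms_var))
    return a


def _level_effects(keys, sd: float, rng: np.random.Generator) -> dict:
    return {k: rng.normal(0.0, sd) for k in sorted(set(keys))}


def simulate_traits(
    ped: Pedigree, config: SimConfig, traits: list[str] | None = None
) -> tuple[pd.DataFrame, TrueValues]:
    """Single-record production phenotypes from the evaluation model.

    y = fixed effects (contemporary group, litter size, dam age, dam breed,
    each level drawn once from N(0, fixed_effect_sd^2)) + direct genetic +
    maternal genetic (dam) + dam permanent environment + residual.  A
    configured fraction of animals, biased toward the youngest generation,
    has phenotypes withheld.
    """
    if traits is None:
        traits = [t for t in config.trait_components if t not in HEALTH_SITES]
    for t in traits:
        if t not in config.trait_components:
            raise ConfigError(f"no variance components configured for trait {t!r}")
    rng = config.rng(2)
    F = inbreeding_array(ped)
    truth = TrueValues()
    genomes = freqs = None
    if config.genetic_architecture == "marker":
        genomes, freqs, _ = _gene_drop(ped, config)

    # shared demographic covariates
    litter_key = [
        (ped.dam[i], ped.birth_year[i]) if ped.dam[i] >= 0 else (-(i + 1), ped.birth_year[i])
        for i in range(ped.n)
    ]
    litter_counts = pd.Series(litter_key).value_counts()
    lsb = np.array([int(litter_counts[k]) for k in litter_key])
    dam_age = np.array([
        ped.birth_year[i] - ped.birth_year[ped.dam[i]] if ped.dam[i] >= 0 else 0
        for i in range(ped.n)
    ])
    breeds = np.where(rng.random(ped.n) < 0.9, "TEX", "TEXX")
    dam_breed = np.array([
        breeds[ped.dam[i]] if ped.dam[i] >= 0 else "TEX" for i in range(ped.n)
    ])
    cg = np.array([f"{ped.flock[i]}-{ped.birth_year[i]}-{ped.sex[i]}" for i in range(ped.n)])
    foster = (rng.random(ped.n) < config.foster_rate).astype(int)
    et = (rng.random(ped.n) < config.et_rate).astype(int)
    age_at_scan = rng.normal(150.0, 10.0, ped.n).round(1)

    max_year = ped.birth_year.max()
    p_phen = np.where(
        ped.birth_year == max_year,
        config.prop_phenotyped * config.young_phenotyped_factor,
        config.prop_phenotyped,
    )
    phenotyped = rng.random(ped.n) < p_phen

    rows = []
    for trait in traits:
        vc: VarianceComponents = config.trait_components[trait]
        if genomes is not None:
            a = _marker_breeding_values(genomes, freqs, vc.sigma2_a, rng)
        else:
            a = _breeding_values(ped, vc.sigma2_a, F, rng)
        mat = _breeding_values(ped, vc.sigma2_m or 0.0, F, rng)
        pe_dam = (
            rng.normal(0.0, math.sqrt(vc.sigma2_pe), ped.n) if vc.sigma2_pe else np.zeros(ped.n)
        )
        truth.breeding[trait] = pd.Series(a, index=ped.ids)
        truth.maternal[trait] = pd.Series(mat, index=ped.ids)
        truth.permanent_env[trait] = pd.Series(pe_dam, index=ped.ids)

        eff_cg = _level_effects(cg, config.fixed_effect_sd, rng)
        eff_lsb = _level_effects(lsb, 0.5 * config.fixed_effect_sd, rng)
        eff_da = _level_effects(dam_age, 0.5 * config.fixed_effect_sd, rng)
        eff_br = _level_effects(dam_breed, 0.5 * config.fixed_effect_sd, rng)
        slope = 0.05 * config.fixed_effect_sd

        e = rng.normal(0.0, math.sqrt(vc.sigma2_e), ped.n)
        mu = TRAIT_MEANS.get(trait, 0.0)
        for i in np.flatnonzero(phenotyped):
            d = ped.dam[i]
            val = (
                mu + eff_cg[cg[i]] + eff_lsb[lsb[i]] + eff_da[dam_age[i]] + eff_br[dam_breed[i]]
                + slope * (age_at_scan[i] - 150.0)
                + a[i]
                + (mat[d] if d >= 0 else 0.0)
                + (pe_dam[d] if d >= 0 else 0.0)
                + e[i]
            )
            rows.append(
                {
                    "animal": ped.ids[i], "trait": trait, "value": val, "visit": 1,
                    "cg": cg[i], "lsb": lsb[i], "dam_age": dam_age[i],
                    "dam_breed": dam_breed[i], "foster": foster[i], "et": et[i],
                    "age_at_scan": age_at_scan[i], "sex": ped.sex[i],
                    "flock": ped.flock[i], "birth_year": ped.birth_year[i],
                }
            )
    return pd.DataFrame(rows), truth


def simulate_scores(
    ped: Pedigree, trait: str, config: SimConfig
) -> tuple[pd.DataFrame, TrueValues]:
    """Repeated 0-4 ordinal health scores for adult ewes.

    A latent value per ewe-visit is simulated from the evaluation model on
    the ln(sum of site scores + 1) scale and mapped to per-site scores by a
    deterministic greedy decomposition, so ln(1 + sum) recovers the latent
    value at the nearest representable grid point.  Visit counts are uniform
    on the configured range (1-5).
    """
    if trait not in HEALTH_SITES:
        raise ConfigError(f"{trait!r} is not a health trait (expected one of {sorted(HEALTH_SITES)})")
    if trait not in config.trait_components:
        raise ConfigError(f"no variance components configured for trait {trait!r}")
    sites = HEALTH_SITES[trait]
    vc: VarianceComponents = config.trait_components[trait]
    rng = config.rng(3)
    F = inbreeding_array(ped)
    if config.genetic_architecture == "marker":
        genomes, freqs, _ = _gene_drop(ped, config)
        a = _marker_breeding_values(genomes, freqs, vc.sigma2_a, rng)
    else:
        a = _breeding_values(ped, vc.sigma2_a, F, rng)
    pe = rng.normal(0.0, math.sqrt(vc.sigma2_pe), ped.n) if vc.sigma2_pe else np.zeros(ped.n)
    truth = TrueValues(breeding={trait: pd.Series(a, index=ped.ids)},
                       permanent_env={trait: pd.Series(pe, index=ped.ids)})

    max_year = ped.birth_year.max()
    ewes = np.flatnonzero(
        (ped.sex == "F") & (ped.birth_year < max_year)
        & (rng.random(ped.n) < config.prop_phenotyped)
    )
    smax = 4 * sites
    lo_v, hi_v = config.visits_range
    rows = []
    scorers = [f"S{k}" for k in range(1, 6)]
    eff_scorer = _level_effects(scorers, config.health_fixed_sd, rng)
    for i in ewes:
        n_visits = int(rng.integers(lo_v, hi_v + 1))
        for v in range(1, n_visits + 1):
            month = int(rng.integers(1, 13))
            year = int(ped.birth_year[i] + 1 + (v - 1) % 3)
            scorer = scorers[int(rng.integers(0, len(scorers)))]
            latent = (
                config.health_mean + eff_scorer[scorer] + a[i] + pe[i]
                + rng.normal(0.0, math.sqrt(vc.sigma2_e))
            )
            total = int(round(math.exp(latent) - 1.0))
            if total < 0 or total > smax:
                total = min(max(total, 0), smax)
            site_scores = []
            left = total
            for _ in range(sites):
                s = min(4, left)
                site_scores.append(s)
                left -= s
            row = {
                "animal": ped.ids[i], "trait": trait,
                "value": math.log1p(total), "visit": v,
                "scorer": scorer, "vax": int(rng.random() < 0.5),
                "lambing": int(min(dam_parity := 1 + (v - 1) % 3, 3)),
                "lsb": 1 + int(rng.integers(0, 3)),
                "dam_age": int(ped.birth_year[i] - (ped.birth_year[ped.dam[i]] if ped.dam[i] >= 0 else ped.birth_year.min())),
                "cg2": f"{month:02d}-{year}",
                "farm_year": f"{ped.flock[i]}-{year}",
                "flock": ped.flock[i], "sex": "F", "birth_year": ped.birth_year[i],
            }
            for k, s in enumerate(site_scores, start=1):
                row[f"site{k}"] = s
            rows.append(row)
    return pd.DataFrame(rows), truth


def corrupt_pedigree(
    ped: Pedigree, panel: GenotypePanel, rate: float, seed: int
) -> tuple[Pedigree, list[dict]]:
    """Plant recorded-parent errors for a random fraction of genotyped animals.

    The sire or dam is swapped to a random same-sex non-parent (genotyped
    where possible, born before the animal); the planted-error list is
    returned so tests can score detection recall.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng([int(seed), 99])
    new_ped = ped.copy()
    planted: list[dict] = []
    genotyped = set(panel.animal_ids)
    gpos = {ped.index[a] for a in panel.animal_ids}
    for a in panel.animal_ids:
        if rng.random() >= rate:
            continue
        i = ped.index[a]
        slots = [s for s, arr in (("sire", ped.sire), ("dam", ped.dam)) if arr[i] >= 0]
        if not slots:
            continue
        slot = slots[int(rng.integers(0, len(slots)))]
        old = ped.sire[i] if slot == "sire" else ped.dam[i]
        want = "M" if slot == "sire" else "F"
        cands = [
            j for j in range(ped.n)
            if ped.sex[j] == want and ped.birth_year[j] < ped.birth_year[i]
            and j != old and j != i and j in gpos
        ]
        if not cands:
            cands = [
                j for j in range(ped.n)
                if ped.sex[j] == want and ped.birth_year[j] < ped.birth_year[i]
                and j != old and j != i
            ]
        if not cands:
            continue
        wrong = int(cands[int(rng.integers(0, len(cands)))])
        if slot == "sire":
            new_ped.sire[i] = wrong
        else:
            new_ped.dam[i] = wrong
        planted.append(
            {"animal": a, "slot": slot, "true_parent": ped.ids[old],
             "wrong_parent": ped.ids[wrong],
             "true_parent_genotyped": ped.ids[old] in genotyped}
        )
    return new_ped, planted
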